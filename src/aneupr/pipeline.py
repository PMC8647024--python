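"""Configuration-driven pipeline runner.

Chains simulate -> SCNA scoring -> expression scores -> differential
co-expression -> pathway scores -> association models, writing each stage's
tables plus a manifest (input hashes, seeds, package version, wall clock)
sufficient to reproduce the run. A pre-flight validation pass checks that
all referenced inputs exist and that sample ids are consistent across
files before any stage executes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import aneupr
from aneupr import coexpression, expression, pathways, scna
from aneupr.association import ols_fit, spearman_bh
from aneupr.genesets import BRANCHES, CYT_SET, UPR_SET, load_default_genesets
from aneupr.io import (
    read_arm_table,
    read_expression,
    read_metadata,
    read_seg,
    write_arm_table,
    write_expression,
    write_gmt,
    write_metadata,
    write_seg,
)
from aneupr.simulate import CohortConfig, default_arm_table, simulate_cohort

log = logging.getLogger("aneupr.pipeline")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class RunConfig:
    """Pipeline run settings; every stochastic stage carries an explicit seed."""

    out_dir: str
    seed: int
    simulate: bool = True
    stages: list[str] = field(
        default_factory=lambda: ["scna", "scores", "coexpr", "pathway", "associate"]
    )
    seg_path: str | None = None
    expr_path: str | None = None
    meta_path: str | None = None
    arms_path: str | None = None
    # analysis parameters (paper defaults)
    lo_pct: float = 30.0
    hi_pct: float = 70.0
    beta: float = 4.0
    n_perm: int = 1000
    min_types: int = 9
    msi_threshold: float = 0.4
    focal_fraction: float = 1.0
    cv_folds: int = 10
    simulate_config: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class PreflightError(RuntimeError):
    """Raised when input validation fails before any stage runs."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(cfg: RunConfig) -> None:
    problems = []
    if not cfg.simulate:
        needed = {"seg": cfg.seg_path, "expr": cfg.expr_path, "meta": cfg.meta_path}
        if "coexpr" in cfg.stages and cfg.expr_path is None:
            problems.append("coexpr stage enabled but no expression path given")
        for name, p in needed.items():
            if p is None:
                problems.append(f"missing input path: {name}")
            elif not Path(p).exists():
                problems.append(f"input does not exist: {p}")
        if not problems and cfg.expr_path and cfg.meta_path:
            expr = read_expression(cfg.expr_path)
            meta = read_metadata(cfg.meta_path)
            extra = sorted(set(expr.samples) - set(meta.samples))
            if extra:
                problems.append(
                    f"expression samples missing from metadata: {extra[:5]}"
                    + ("..." if len(extra) > 5 else "")
                )
            if cfg.seg_path:
                seg = read_seg(cfg.seg_path)
                extra = sorted(set(seg) - set(meta.samples))
                if extra:
                    problems.append(
                        f"SEG samples missing from metadata: {extra[:5]}"
                        + ("..." if len(extra) > 5 else "")
                    )
    if problems:
        raise PreflightError("; ".join(problems))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)

    _preflight(cfg)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))

    manifest: dict = {
        "version": aneupr.__version__,
        "seed": cfg.seed,
        "stages": [],
        "artifacts": {},
        "input_hashes": {},
    }

    genesets = load_default_genesets()

    if cfg.simulate:
        log.info("stage simulate: generating synthetic cohort")
        sim_cfg = CohortConfig(seed=cfg.seed, **cfg.simulate_config)
        profiles, expr, meta, truth = simulate_cohort(sim_cfg)
        arms = default_arm_table()
        write_seg(profiles, out / "cohort.seg")
        write_expression(expr, out / "expression.tsv")
        write_metadata(meta, out / "metadata.tsv")
        write_arm_table(arms, out / "arms.tsv")
        write_gmt(genesets, out / "genesets.gmt")
        truth.to_json(out / "ground_truth.json")
        manifest["stages"].append("simulate")
        for f in ("cohort.seg", "expression.tsv", "metadata.tsv", "arms.tsv",
                  "genesets.gmt", "ground_truth.json"):
            manifest["artifacts"][f] = str(out / f)
    else:
        profiles = read_seg(cfg.seg_path)
        expr = read_expression(cfg.expr_path)
        meta = read_metadata(cfg.meta_path)
        arms = (
            read_arm_table(cfg.arms_path) if cfg.arms_path else default_arm_table()
        )
        for name, p in (("seg", cfg.seg_path), ("expr", cfg.expr_path),
                        ("meta", cfg.meta_path)):
            manifest["input_hashes"][name] = _sha256(Path(p))

    scores_df = None
    cyt = None
    strata = None

    try:
        if "scna" in cfg.stages:
            log.info("stage scna: event classification and burden scores")
            tumor_ids = [s for s in profiles if meta.table.loc[s, "is_tumor"]]
            counts = [
                scna.classify_sample_events(
                    profiles[s], arms, focal_fraction=cfg.focal_fraction
                )
                for s in tumor_ids
            ]
            scores_df = scna.cohort_scna_scores(counts)
            scores_df.to_csv(out / "scna_scores.tsv", sep="\t")
            manifest["stages"].append("scna")
            manifest["artifacts"]["scna_scores.tsv"] = str(out / "scna_scores.tsv")

        if "scores" in cfg.stages:
            log.info("stage scores: CYT and P53 activity")
            cyt = expression.cyt_score(expr)
            tp53 = expression.tp53_activity(expr, meta, genesets)
            tab = pd.concat([cyt, tp53], axis=1)
            tab.to_csv(out / "expression_scores.tsv", sep="\t")
            manifest["stages"].append("scores")
            manifest["artifacts"]["expression_scores.tsv"] = str(
                out / "expression_scores.tsv"
            )

        if "coexpr" in cfg.stages and scores_df is not None:
            log.info("stage coexpr: differential co-expression of UPR genes")
            strata = coexpression.stratify(
                scores_df["combined"], meta, cfg.lo_pct, cfg.hi_pct
            )
            genes = [g for g in genesets[UPR_SET] if g in expr.genes]
            results = coexpression.permutation_test(
                expr, strata, genes, n_perm=cfg.n_perm, seed=cfg.seed, beta=cfg.beta
            )
            table = coexpression.classify_pairs(results, min_types=cfg.min_types)
            table.to_csv(out / "coexpression_pairs.tsv", sep="\t")
            edges = table[table["status"] != "neither"].reset_index()
            edges.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
            manifest["stages"].append("coexpr")
            manifest["artifacts"]["coexpression_pairs.tsv"] = str(
                out / "coexpression_pairs.tsv"
            )

        if "pathway" in cfg.stages:
            log.info("stage pathway: UPR branch pathway scores")
            branch_sets = {b: genesets[b] for b in BRANCHES}
            score_table, models = pathways.score_cohort(
                expr, meta, branch_sets, cv_folds=cfg.cv_folds, seed=cfg.seed
            )
            score_table.to_csv(out / "pathway_scores.tsv", sep="\t")
            coef_rows = []
            for (ttype, pw), model in models.items():
                for gene, w in model.coefficients.items():
                    if w != 0:
                        coef_rows.append(
                            {"tumor_type": ttype, "pathway": pw, "gene": gene,
                             "coefficient": w}
                        )
            pd.DataFrame(coef_rows).to_csv(
                out / "pathway_coefficients.tsv", sep="\t", index=False
            )
            if scores_df is not None and cyt is not None:
                corr = pathways.pathway_correlations(
                    score_table, scores_df["combined"], cyt, meta
                )
                corr.to_csv(out / "pathway_correlations.tsv", sep="\t", index=False)
            manifest["stages"].append("pathway")
            manifest["artifacts"]["pathway_scores.tsv"] = str(
                out / "pathway_scores.tsv"
            )

        if "associate" in cfg.stages and scores_df is not None and cyt is not None:
            log.info("stage associate: stage/type OLS and per-type correlations")
            tumor_ids = [s for s in scores_df.index if meta.table.loc[s, "is_tumor"]]
            cov = meta.table.loc[tumor_ids, ["tumor_type", "stage"]]
            reports = {}
            for name, resp in (
                ("SCNA", scores_df.loc[tumor_ids, "combined"]),
                ("CYT", cyt[tumor_ids]),
            ):
                rep = ols_fit(resp, cov, baseline_levels={"stage": "I"})
                reports[name] = rep
                rep.terms.to_csv(out / f"ols_{name.lower()}_stage.tsv", sep="\t")
            x_by = {}
            y_by = {}
            for ttype in meta.tumor_types():
                ids = [s for s in meta.tumor_samples(ttype) if s in scores_df.index]
                x_by[ttype] = scores_df.loc[ids, "combined"]
                y_by[ttype] = cyt[ids]
            sp = spearman_bh(x_by, y_by)
            sp.to_csv(out / "scna_cyt_spearman.tsv", sep="\t")
            manifest["stages"].append("associate")
            manifest["artifacts"]["scna_cyt_spearman.tsv"] = str(
                out / "scna_cyt_spearman.tsv"
            )
    except Exception:
        log.exception("stage failed; see %s", out / "run.log")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()

    manifest["wall_clock_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
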