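"""Synthetic cohort generator with exposed ground truth.

Emulates the statistical structure the analysis assumes so every pipeline
stage is testable without external downloads: stage-graded SCNA burden
realized as segmented copy-number profiles, negative SCNA-CYT rank
coupling through a Gaussian copula, SCNA-stratum-dependent co-expression
blocks among the UPR genes, tumor-vs-normal mean shifts on informative
pathway genes, MSI-stratum-specific mutation-burden coupling, and a
two-population single-cell matrix with reduced RIDD-target expression in
macrophages. All generators are pure functions of (config, seed): the same
configuration reproduces byte-identical outputs.

The defaults are the study conditions: 334 tumor samples per type, so that
a 30/70 percentile split yields SCNA-low and SCNA-high strata of 100
samples each (a typical tumor-type cohort runs 250-300 samples), stage
effects of +0.5 / +0.55 / +0.8 on raw event rates for stages II-IV
versus I, an SCNA-CYT rank correlation target of -0.3, co-expression
blocks moving from latent correlation 0.7 (SCNA-low) to 0.1 (SCNA-high) in
10 of 12 tumor types, and 1.5-sigma tumor-vs-normal shifts on half of each
UPR branch's genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from aneupr.genesets import BRANCHES, RIDD_SET, UPR_SET, load_default_genesets
from aneupr.io import (
    ArmTable,
    ExpressionMatrix,
    SampleMetadata,
    SegmentedProfile,
)

# Approximate chromosome lengths in Mb (hg-like scale); acrocentric
# chromosomes get short p arms.
_CHROM_MB = {
    "1": 249, "2": 243, "3": 198, "4": 190, "5": 182, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 133, "13": 114,
    "14": 107, "15": 102, "16": 90, "17": 83, "18": 80, "19": 59,
    "20": 64, "21": 47, "22": 51, "X": 156,
}
_ACROCENTRIC = {"13", "14", "15", "21", "22"}
_MB = 1_000_000

STAGE_LEVELS = ("I", "II", "III", "IV")


def default_arm_table() -> ArmTable:
    """A synthetic chromosome-arm boundary table on an hg-like length scale."""
    rows = {}
    for chrom, mb in _CHROM_MB.items():
        total = mb * _MB
        frac = 0.15 if chrom in _ACROCENTRIC else 0.4
        p_end = int(total * frac)
        rows[chrom] = {
            "p_start": 1,
            "p_end": p_end,
            "q_start": p_end + 1,
            "q_end": total,
        }
    return ArmTable(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class CohortConfig:
    """Generator settings; defaults are the study conditions."""

    seed: int
    n_tumor_types: int = 12
    samples_per_type: int = 334
    normals_per_type: int = 30
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {"I": 0.35, "II": 0.30, "III": 0.20, "IV": 0.15}
    )
    stage_scna_effects: dict[str, float] = field(
        default_factory=lambda: {"I": 0.0, "II": 0.5, "III": 0.55, "IV": 0.8}
    )
    scna_cyt_rho: float = -0.3
    # co-expression blocks among UPR genes
    n_coex_blocks: int = 4
    coex_block_size: int = 5
    coex_rho_low: float = 0.7
    coex_rho_high: float = 0.1
    n_differential_types: int = 10
    # tumor-vs-normal pathway shifts (sigma units) and informative fraction
    pathway_shift: dict[str, float] = field(
        default_factory=lambda: {b: 1.5 for b in BRANCHES}
    )
    frac_informative_genes: float = 0.5
    # mutation / MSI structure
    msi_h_fraction: float = 0.05
    msi_mutation_slopes: dict[str, float] = field(
        default_factory=lambda: {"MSS": 0.5, "MSI-H": -0.5}
    )
    # event-rate baselines (per chromosome / arm / sample)
    p_chromosomal: float = 0.08
    p_arm: float = 0.10
    focal_rate: float = 6.0
    n_background_genes: int = 200
    stage_missing_rate: float = 0.05
    tp53_shift: float = 1.0
    realize_segments: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r in (self.scna_cyt_rho, self.coex_rho_low, self.coex_rho_high):
            if not -1 < r < 1:
                raise ValueError("correlation targets must be in (-1, 1)")


@dataclass
class GroundTruth:
    """Planted quantities, recoverable by accessors and serializable to JSON."""

    event_counts: pd.DataFrame  # sample x (chromosomal, arm, focal)
    combined_score: pd.Series  # planted min-max-combined burden (tumors)
    strata: pd.Series  # sample -> low / middle / high within type
    coex_pairs: pd.DataFrame  # gene_a, gene_b, rho_low, rho_high, differential
    differential_types: list[str]
    pathway_informative: dict[str, list[str]]
    pathway_shift: dict[str, float]
    stage_effects: dict[str, float]
    scna_cyt_rho: float
    msi_mutation_slopes: dict[str, float]

    def planted_pairs(self, differential_only: bool = True) -> pd.DataFrame:
        df = self.coex_pairs
        return df[df["differential"]] if differential_only else df

    def to_json(self, path) -> None:
        payload = {
            "event_counts": self.event_counts.to_dict(orient="index"),
            "combined_score": self.combined_score.to_dict(),
            "strata": self.strata.to_dict(),
            "coex_pairs": self.coex_pairs.to_dict(orient="records"),
            "differential_types": self.differential_types,
            "pathway_informative": self.pathway_informative,
            "pathway_shift": self.pathway_shift,
            "stage_effects": self.stage_effects,
            "scna_cyt_rho": self.scna_cyt_rho,
            "msi_mutation_slopes": self.msi_mutation_slopes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def _realize_profile(
    sample_id: str,
    events: dict,
    arms: ArmTable,
    rng: np.random.Generator,
) -> SegmentedProfile:
    """Realize planted events as non-overlapping SEG regions.

    Whole-chromosome and arm events become full-arm segments with log2FC in
    the single-event band (~+/-0.35) or double-event band (~+/-1.5); focal
    events are short segments embedded in otherwise neutral arms, with
    lengths bounded so that their contribution to the arm's weighted
    intensity cannot create a spurious arm-level event; remaining coverage
    is filled with near-zero background segments.
    """
    rows: list[tuple[str, int, int, float]] = []

    def fc_for(magnitude: int, direction: int) -> float:
        center = 0.35 if magnitude == 1 else 1.5
        val = rng.normal(center, 0.05)
        val = float(np.clip(val, 0.15, 0.95) if magnitude == 1 else np.clip(val, 1.1, 1.9))
        return direction * val

    for chrom in arms.table.index:
        for arm in ("p", "q"):
            a_start, a_end = arms.arm_interval(chrom, arm)
            key = (chrom, arm)
            kind = events["arm_kind"].get(key)
            if kind is not None:
                magnitude, direction = kind
                rows.append((chrom, a_start, a_end, fc_for(magnitude, direction)))
                continue
            focals = events["focal"].get(key, [])
            if not focals:
                rows.append((chrom, a_start, a_end, float(rng.normal(0, 0.008))))
                continue
            # place focal segments at sorted, non-overlapping positions
            # evenly spaced placement always fits (total focal length is
            # budget-bounded far below the arm length)
            placed: list[tuple[int, int, float]] = []
            total_len = sum(length for _, _, length in focals)
            gap = (a_end - a_start + 1 - total_len) // (len(focals) + 1)
            cursor = a_start
            for magnitude, direction, length in focals:
                start = cursor + gap
                placed.append((start, start + length - 1, fc_for(magnitude, direction)))
                cursor = start + length
            # fill background around focal segments
            prev = a_start
            for s, e, fc in placed:
                if s > prev:
                    rows.append((chrom, prev, s - 1, float(rng.normal(0, 0.008))))
                rows.append((chrom, s, e, fc))
                prev = e + 1
            if prev <= a_end:
                rows.append((chrom, prev, a_end, float(rng.normal(0, 0.008))))
    regions = pd.DataFrame(rows, columns=["chromosome", "start", "end", "log2fc"])
    return SegmentedProfile(sample_id=sample_id, regions=regions)


def _draw_events(
    rng: np.random.Generator,
    arms: ArmTable,
    shift: float,
    cfg: CohortConfig,
) -> tuple[dict, int, int, int]:
    """Draw planted events for one sample; returns (layout, n_chrom, n_arm, n_focal)."""
    chroms = list(arms.table.index)
    scale = 1.0 + shift
    arm_kind: dict[tuple[str, str], tuple[int, int]] = {}
    focal: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    n_chrom = n_arm = n_focal = 0
    free_arms: list[tuple[str, str]] = []
    for chrom in chroms:
        if rng.random() < min(1.0, cfg.p_chromosomal * scale):
            magnitude = 1 if rng.random() < 0.8 else 2
            direction = 1 if rng.random() < 0.5 else -1
            arm_kind[(chrom, "p")] = (magnitude, direction)
            arm_kind[(chrom, "q")] = (magnitude, direction)
            n_chrom += magnitude  # whole-chromosome events count once per chromosome
            continue
        drawn = []
        for arm in ("p", "q"):
            if rng.random() < min(1.0, cfg.p_arm * scale):
                magnitude = 1 if rng.random() < 0.85 else 2
                direction = 1 if rng.random() < 0.5 else -1
                drawn.append((arm, magnitude, direction))
        if len(drawn) == 2 and drawn[0][2] == drawn[1][2]:
            # same direction on both arms would re-classify as whole-chromosome
            drawn[1] = (drawn[1][0], drawn[1][1], -drawn[1][2])
        for arm, magnitude, direction in drawn:
            arm_kind[(chrom, arm)] = (magnitude, direction)
            n_arm += magnitude
        for arm in ("p", "q"):
            if (chrom, arm) not in arm_kind:
                free_arms.append((chrom, arm))
    # focal events on arms without full-arm segments, with an intensity budget
    budget = {key: 0.06 for key in free_arms}
    n_requested = rng.poisson(cfg.focal_rate * scale)
    for _ in range(n_requested):
        if not free_arms:
            break
        for _try in range(10):
            key = free_arms[int(rng.integers(len(free_arms)))]
            chrom, arm = key
            a_start, a_end = arms.arm_interval(chrom, arm)
            arm_len = a_end - a_start + 1
            magnitude = 1 if rng.random() < 0.8 else 2
            direction = 1 if rng.random() < 0.5 else -1
            fc_abs = 0.5 if magnitude == 1 else 1.5
            max_len = min(8 * _MB, int(budget[key] * arm_len / fc_abs), arm_len // 4)
            if max_len < _MB // 2:
                continue
            length = int(rng.integers(_MB // 2, max_len + 1))
            budget[key] -= fc_abs * length / arm_len
            focal.setdefault(key, []).append((magnitude, direction, length))
            n_focal += magnitude
            break
    return {"arm_kind": arm_kind, "focal": focal}, n_chrom, n_arm, n_focal


def simulate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, SegmentedProfile], ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Generate a full synthetic cohort with ground truth.

    Returns (segmented profiles, expression matrix, metadata, ground truth).
    With ``config.realize_segments=False`` the profile dict is empty and
    planted event counts are available only through the ground truth —
    useful when only the expression stages are under study.
    """
    cfg = config
    arms = default_arm_table()
    genesets = load_default_genesets()
    upr_genes = genesets[UPR_SET]
    rng_master = np.random.default_rng([cfg.seed, 0])

    types = [f"T{i + 1:02d}" for i in range(cfg.n_tumor_types)]
    diff_types = types[: cfg.n_differential_types]

    # --- planted co-expression blocks over UPR genes -----------------------
    block_rng = np.random.default_rng([cfg.seed, 1])
    n_block_genes = cfg.n_coex_blocks * cfg.coex_block_size
    if n_block_genes > len(upr_genes):
        raise ValueError("co-expression blocks exceed the UPR gene set")
    block_genes = list(
        np.array(upr_genes)[
            block_rng.choice(len(upr_genes), size=n_block_genes, replace=False)
        ]
    )
    blocks = [
        block_genes[i * cfg.coex_block_size : (i + 1) * cfg.coex_block_size]
        for i in range(cfg.n_coex_blocks)
    ]
    for r in (cfg.coex_rho_low, cfg.coex_rho_high):
        if r < 0:
            raise ValueError("equicorrelated blocks require non-negative rho")

    # --- gene universe -----------------------------------------------------
    universe: list[str] = []
    for name in genesets:
        for g in genesets[name]:
            if g not in universe:
                universe.append(g)
    universe += [f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)]
    gene_idx = {g: i for i, g in enumerate(universe)}
    n_genes = len(universe)
    base_mu = np.random.default_rng([cfg.seed, 2]).uniform(3.0, 8.0, size=n_genes)

    pathway_informative: dict[str, list[str]] = {}
    for branch in BRANCHES:
        genes = genesets[branch]
        k = max(1, int(np.ceil(cfg.frac_informative_genes * len(genes))))
        pathway_informative[branch] = genes[:k]

    # --- per-sample structure ----------------------------------------------
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    counts_rows: list[dict] = []
    profiles: dict[str, SegmentedProfile] = {}
    sample_type: list[str] = []
    is_tumor_flags: list[bool] = []

    stage_names = list(cfg.stage_probs)
    stage_p = np.array([cfg.stage_probs[s] for s in stage_names])
    stage_p = stage_p / stage_p.sum()

    for t_idx, ttype in enumerate(types):
        t_rng = np.random.default_rng([cfg.seed, 3, t_idx])
        normal_ids = [f"{ttype}-N{j + 1:03d}" for j in range(cfg.normals_per_type)]
        for j in range(cfg.samples_per_type):
            sid = f"{ttype}-S{j + 1:03d}"
            stage = stage_names[int(t_rng.choice(len(stage_names), p=stage_p))]
            shift = cfg.stage_scna_effects.get(stage, 0.0)
            layout, n_c, n_a, n_f = _draw_events(t_rng, arms, shift, cfg)
            if cfg.realize_segments:
                profiles[sid] = _realize_profile(sid, layout, arms, t_rng)
            counts_rows.append(
                {"sample": sid, "chromosomal": n_c, "arm": n_a, "focal": n_f}
            )
            missing_stage = t_rng.random() < cfg.stage_missing_rate
            meta_rows.append(
                {
                    "sample": sid,
                    "tumor_type": ttype,
                    "stage": (np.nan if missing_stage else stage),
                    "is_tumor": True,
                    "matched_normal_id": normal_ids[j % len(normal_ids)],
                    "purity_ihc": float(t_rng.beta(8, 2)),
                }
            )
            sample_ids.append(sid)
            sample_type.append(ttype)
            is_tumor_flags.append(True)
        for nid in normal_ids:
            if cfg.realize_segments:
                layout = {"arm_kind": {}, "focal": {}}
                profiles[nid] = _realize_profile(nid, layout, arms, t_rng)
            counts_rows.append({"sample": nid, "chromosomal": 0, "arm": 0, "focal": 0})
            meta_rows.append(
                {
                    "sample": nid,
                    "tumor_type": ttype,
                    "stage": np.nan,
                    "is_tumor": False,
                    "matched_normal_id": np.nan,
                    "purity_ihc": np.nan,
                }
            )
            sample_ids.append(nid)
            sample_type.append(ttype)
            is_tumor_flags.append(False)

    counts = pd.DataFrame(counts_rows).set_index("sample")
    meta_df = pd.DataFrame(meta_rows).set_index("sample")
    is_tumor = np.array(is_tumor_flags)
    tumor_ids = [s for s, t in zip(sample_ids, is_tumor) if t]

    # --- planted combined burden score (tumors; min-max per category) ------
    tum_counts = counts.loc[tumor_ids]
    combined = pd.Series(0.0, index=tum_counts.index, name="combined")
    for cat in ("chromosomal", "arm", "focal"):
        combined += _minmax(tum_counts[cat].to_numpy(dtype=float))

    # --- strata (within type, 30/70 split of the planted score) ------------
    strata = pd.Series("middle", index=pd.Index(tumor_ids, name="sample"))
    for ttype in types:
        ids = [s for s in tumor_ids if s.startswith(ttype + "-")]
        vals = combined[ids]
        lo = np.percentile(vals, 30)
        hi = np.percentile(vals, 70)
        strata[vals.index[vals <= lo]] = "low"
        strata[vals.index[vals >= hi]] = "high"

    # normal-score z for copulas, per type over tumors
    z_burden = pd.Series(0.0, index=pd.Index(tumor_ids))
    for ttype in types:
        ids = [s for s in tumor_ids if s.startswith(ttype + "-")]
        ranks = stats.rankdata(combined[ids])
        z_burden[ids] = stats.norm.ppf((ranks - 0.5) / len(ids))

    # --- expression matrix --------------------------------------------------
    expr_rng = np.random.default_rng([cfg.seed, 4])
    x = base_mu[:, None] + expr_rng.normal(0.0, 1.0, size=(n_genes, len(sample_ids)))

    rho_mid = 0.5 * (cfg.coex_rho_low + cfg.coex_rho_high)
    col_of = {s: i for i, s in enumerate(sample_ids)}
    for t_idx, ttype in enumerate(types):
        differential = ttype in diff_types
        ids = [s for s in tumor_ids if s.startswith(ttype + "-")]
        cols = np.array([col_of[s] for s in ids])
        # planted rho targets are Spearman correlations; invert the Gaussian
        # copula relation (rho_pearson = 2 sin(pi rho_s / 6)) so the realized
        # rank correlation matches the planted value
        to_latent = lambda r: 2.0 * np.sin(np.pi * r / 6.0)  # noqa: E731
        regime_rho = np.where(
            strata[ids] == "low",
            to_latent(cfg.coex_rho_low if differential else rho_mid),
            np.where(
                strata[ids] == "high",
                to_latent(cfg.coex_rho_high if differential else rho_mid),
                to_latent(rho_mid),
            ),
        ).astype(float)
        b_rng = np.random.default_rng([cfg.seed, 5, t_idx])
        for block in blocks:
            factor = b_rng.normal(0.0, 1.0, size=len(ids))
            for g in block:
                gi = gene_idx[g]
                eps = b_rng.normal(0.0, 1.0, size=len(ids))
                x[gi, cols] = base_mu[gi] + (
                    np.sqrt(regime_rho) * factor
                    + np.sqrt(1.0 - regime_rho) * eps
                )

    # CYT genes coupled to burden through a Gaussian copula
    rho_s = cfg.scna_cyt_rho
    rho_pearson = 2.0 * np.sin(np.pi * rho_s / 6.0)
    cyt_rng = np.random.default_rng([cfg.seed, 6])
    latent = rho_pearson * z_burden.to_numpy() + np.sqrt(
        1 - rho_pearson**2
    ) * cyt_rng.normal(0.0, 1.0, size=len(tumor_ids))
    tum_cols = np.array([col_of[s] for s in tumor_ids])
    for g in ("GZMA", "PRF1"):
        gi = gene_idx[g]
        x[gi, tum_cols] = (
            base_mu[gi] + latent + cyt_rng.normal(0.0, 0.15, size=len(tumor_ids))
        )

    # tumor-vs-normal pathway shifts on informative genes
    for branch, shift in cfg.pathway_shift.items():
        for g in pathway_informative[branch]:
            gi = gene_idx[g]
            x[gi, tum_cols] += shift

    # TP53: mutants more aneuploid, repressed signature up in mutants
    tp_rng = np.random.default_rng([cfg.seed, 7])
    p_mut = 1.0 / (1.0 + np.exp(-(-0.4 + 0.8 * z_burden.to_numpy())))
    tp53_mut = tp_rng.random(len(tumor_ids)) < p_mut
    for g in genesets["TP53_REPRESSED_10"]:
        gi = gene_idx[g]
        x[gi, tum_cols] += cfg.tp53_shift * tp53_mut

    x = np.clip(x, 0.0, None)
    expr = ExpressionMatrix(
        pd.DataFrame(x, index=pd.Index(universe, name="gene"), columns=sample_ids)
    )

    # --- mutations and MSI ---------------------------------------------------
    mut_rng = np.random.default_rng([cfg.seed, 8])
    msi_h = mut_rng.random(len(tumor_ids)) < cfg.msi_h_fraction
    msi_score = np.where(
        msi_h,
        mut_rng.uniform(0.4, 1.0, size=len(tumor_ids)),
        mut_rng.uniform(0.0, 0.39, size=len(tumor_ids)),
    )
    slope = np.where(
        msi_h,
        cfg.msi_mutation_slopes["MSI-H"],
        cfg.msi_mutation_slopes["MSS"],
    )
    base_log = np.where(msi_h, 6.0, 3.0)
    lam = np.exp(base_log + slope * z_burden.to_numpy())
    mutations = mut_rng.poisson(lam)

    meta_df.loc[tumor_ids, "msi_score"] = msi_score
    meta_df.loc[tumor_ids, "tp53_mutant"] = tp53_mut
    meta_df.loc[tumor_ids, "nonsilent_mutations"] = mutations.astype(float)
    meta = SampleMetadata(meta_df)

    # --- ground truth --------------------------------------------------------
    pair_rows = []
    seen = set()
    for block in blocks:
        for i, ga in enumerate(block):
            for gb in block[i + 1 :]:
                key = tuple(sorted((ga, gb)))
                if key in seen:
                    continue
                seen.add(key)
                pair_rows.append(
                    {
                        "gene_a": key[0],
                        "gene_b": key[1],
                        "rho_low": cfg.coex_rho_low,
                        "rho_high": cfg.coex_rho_high,
                        "differential": True,
                    }
                )
    truth = GroundTruth(
        event_counts=counts,
        combined_score=combined,
        strata=strata,
        coex_pairs=pd.DataFrame(pair_rows),
        differential_types=diff_types,
        pathway_informative=pathway_informative,
        pathway_shift=dict(cfg.pathway_shift),
        stage_effects=dict(cfg.stage_scna_effects),
        scna_cyt_rho=cfg.scna_cyt_rho,
        msi_mutation_slopes=dict(cfg.msi_mutation_slopes),
    )
    return profiles, expr, meta, truth


def simulate_singlecell(
    n_tumor: int = 1257,
    n_macrophage: int = 119,
    ridd_shift: float = 1.5,
    seed: int = 0,
    genes: list[str] | None = None,
):
    """Two-population single-cell RIDD expression matrix.

    TPM is drawn log-normally per gene; macrophages have RIDD targets
    shifted down by ``ridd_shift`` (in units of the per-gene log2 sd),
    except the excluded counter-regulated genes (ITGB2, TAPBP) which shift
    up. Returns a :class:`~aneupr.singlecell.SingleCellMatrix`.
    """
    from aneupr.genesets import SC_RIDD_EXCLUDE
    from aneupr.singlecell import sc_transform

    if n_tumor < 2 or n_macrophage < 2:
        raise ValueError("each population needs >= 2 cells")
    if not np.isfinite(ridd_shift):
        raise ValueError("ridd_shift must be finite")
    if genes is None:
        genes = load_default_genesets()[RIDD_SET]
    rng = np.random.default_rng([seed, 9])
    n_cells = n_tumor + n_macrophage
    mu = rng.uniform(3.0, 7.0, size=len(genes))
    sigma = 1.0
    log2_tpm = mu[None, :] + rng.normal(0.0, sigma, size=(n_cells, len(genes)))
    macro = np.zeros(n_cells, dtype=bool)
    macro[n_tumor:] = True
    for gi, g in enumerate(genes):
        delta = ridd_shift * sigma if g not in SC_RIDD_EXCLUDE else -ridd_shift * sigma
        log2_tpm[macro, gi] -= delta
    tpm = np.power(2.0, log2_tpm)
    cells = [f"TUM{i + 1:04d}" for i in range(n_tumor)] + [
        f"MAC{i + 1:04d}" for i in range(n_macrophage)
    ]
    labels = pd.Series(
        ["tumor"] * n_tumor + ["macrophage"] * n_macrophage,
        index=pd.Index(cells, name="cell"),
    )
    df = pd.DataFrame(tpm, index=labels.index, columns=genes)
    return sc_transform(df, labels)


def simulate_ols_design(
    n_types: int = 25,
    n_samples: int = 6000,
    stage_effects: dict[str, float] | None = None,
    type_effect_sd: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame, dict[str, float]]:
    """Direct OLS recovery design: response = type effect + stage effect + noise.

    Mirrors the stage-progression model (score ~ TumorType + TumorStage with
    Stage I baseline). Returns (response, covariates, planted stage effects).
    """
    if stage_effects is None:
        stage_effects = {"I": 0.0, "II": 0.5, "III": 0.55, "IV": 0.8}
    rng = np.random.default_rng([seed, 10])
    types = [f"T{i + 1:02d}" for i in range(n_types)]
    type_eff = {t: rng.normal(0.0, type_effect_sd) for t in types}
    ttype = rng.choice(types, size=n_samples)
    stage = rng.choice(list(stage_effects), size=n_samples)
    y = (
        np.array([type_eff[t] for t in ttype])
        + np.array([stage_effects[s] for s in stage])
        + rng.normal(0.0, noise_sd, size=n_samples)
    )
    idx = pd.Index([f"S{i + 1:05d}" for i in range(n_samples)], name="sample")
    covariates = pd.DataFrame({"tumor_type": ttype, "stage": stage}, index=idx)
    response = pd.Series(y, index=idx, name="score")
    return response, covariates, dict(stage_effects)
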