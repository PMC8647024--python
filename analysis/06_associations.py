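#!/usr/bin/env python
"""Cohort-level association models.

Fits the stage-progression OLS models (score ~ TumorType + TumorStage,
Stage I baseline) for both the SCNA and CYT scores — first on the SEG-based
cohort from step 01, then on the dedicated large OLS design (25 types,
n = 6,000) where the planted stage coefficients are known — and the
CYT ~ pathways + SCNA (+ purity) + TumorType models. Writes coefficient
tables under results/.
"""

from pathlib import Path

import pandas as pd

from aneupr.association import ols_fit
from aneupr.io import read_expression, read_metadata
from aneupr.simulate import simulate_ols_design

SEED = 20260924
BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = BASE / "cohort"
    meta = read_metadata(cohort / "metadata.tsv")
    scna = pd.read_csv(BASE / "scna_scores.tsv", sep="\t", index_col=0)["combined"]
    scores = pd.read_csv(BASE / "expression_scores.tsv", sep="\t", index_col=0)
    pathway = pd.read_csv(BASE / "pathway_scores.tsv", sep="\t", index_col=0)

    tumor_ids = [s for s in meta.tumor_samples() if s in scna.index]
    cov = meta.table.loc[tumor_ids, ["tumor_type", "stage"]]
    for name, resp in (("SCNA", scna[tumor_ids]), ("CYT", scores.loc[tumor_ids, "CYT"])):
        rep = ols_fit(resp, cov, baseline_levels={"stage": "I"})
        rep.terms.to_csv(BASE / f"ols_{name.lower()}_stage.tsv", sep="\t")
        stage_terms = rep.terms.loc[
            [t for t in rep.terms.index if t.startswith("stage[")]
        ]
        print(
            f"{name} ~ type + stage (n={rep.n}, {rep.n_dropped} dropped): "
            + ", ".join(
                f"{t}={stage_terms.loc[t, 'coefficient']:+.3f}"
                for t in stage_terms.index
            )
        )

    # large planted design: recovery of the known stage effects
    resp, cov_big, truth = simulate_ols_design(seed=SEED)
    rep = ols_fit(resp, cov_big, baseline_levels={"stage": "I"})
    rep.terms.to_csv(BASE / "ols_planted_stage.tsv", sep="\t")
    inside = sum(
        rep.ci(f"stage[{s}]")[0] <= truth[s] <= rep.ci(f"stage[{s}]")[1]
        for s in ("II", "III", "IV")
    )
    print(f"planted stage design (n={rep.n}): {inside}/3 true effects inside 95% CIs")

    # CYT ~ pathways + SCNA (+ purity) + tumor type
    data = pathway.loc[tumor_ids].join(meta.table[["tumor_type", "purity_ihc"]])
    data["SCNA"] = scna[tumor_ids]
    for label, cols in (
        ("with_purity", list(pathway.columns) + ["SCNA", "purity_ihc", "tumor_type"]),
        ("without_purity", list(pathway.columns) + ["SCNA", "tumor_type"]),
    ):
        rep = ols_fit(scores.loc[tumor_ids, "CYT"], data[cols])
        rep.terms.to_csv(BASE / f"ols_cyt_pathways_{label}.tsv", sep="\t")
        print(
            f"CYT ~ pathways + SCNA {label} (n={rep.n}): "
            f"SCNA coefficient {rep.coefficient('SCNA'):+.3f} "
            f"(p={rep.terms.loc['SCNA', 'p']:.2e})"
        )


if __name__ == "__main__":
    main()
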