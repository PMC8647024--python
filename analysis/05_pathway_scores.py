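#!/usr/bin/env python
"""UPR branch pathway activity scores and their SCNA / CYT correlations.

Fits per-(tumor type, branch) Lasso tumor-vs-normal models on the cohort
written by step 01, scores every sample by coefficient-matrix
multiplication, and correlates the scores with SCNA burden and cytolytic
activity per tumor type (BH across types).
"""

from pathlib import Path

import pandas as pd

from aneupr.genesets import BRANCHES, load_default_genesets
from aneupr.io import read_expression, read_metadata
from aneupr.pathways import pathway_correlations, score_cohort

SEED = 20260924
BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = BASE / "cohort"
    expr = read_expression(cohort / "expression.tsv")
    meta = read_metadata(cohort / "metadata.tsv")
    genesets = load_default_genesets()
    scna = pd.read_csv(BASE / "scna_scores.tsv", sep="\t", index_col=0)["combined"]
    cyt = pd.read_csv(BASE / "expression_scores.tsv", sep="\t", index_col=0)["CYT"]

    branch_sets = {b: genesets[b] for b in BRANCHES}
    scores, models = score_cohort(expr, meta, branch_sets, seed=SEED)
    scores.to_csv(BASE / "pathway_scores.tsv", sep="\t")

    coef_rows = [
        {"tumor_type": tt, "pathway": pw, "gene": g, "coefficient": w}
        for (tt, pw), m in models.items()
        for g, w in m.coefficients.items()
        if w != 0
    ]
    pd.DataFrame(coef_rows).to_csv(
        BASE / "pathway_coefficients.tsv", sep="\t", index=False
    )
    n_deg = sum(m.degenerate for m in models.values())
    print(
        f"fit {len(models)} (type, branch) models ({n_deg} degenerate); "
        f"median support "
        f"{int(pd.Series([len(m.support) for m in models.values()]).median())} genes"
    )

    corr = pathway_correlations(scores, scna, cyt, meta)
    corr.to_csv(BASE / "pathway_correlations.tsv", sep="\t", index=False)
    for target in ("SCNA", "CYT"):
        sub = corr[corr["target"] == target]
        print(
            f"pathway-{target} Spearman: median rho by branch: "
            + ", ".join(
                f"{pw}: {sub[sub['pathway'] == pw]['rho'].median():.2f}"
                for pw in sorted(sub["pathway"].unique())
            )
        )


if __name__ == "__main__":
    main()
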