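#!/usr/bin/env python
"""Expression-derived scores and their link to aneuploidy burden.

Computes the cytolytic activity (CYT) and P53 activity scores, the
per-tumor-type SCNA-CYT Spearman correlations with BH correction, the
HSPA5-style tumor-vs-normal comparison, the partial SCNA-CYT correlation
controlling for P53 activity, and the MSI-stratified mutation-SCNA
correlation. Writes everything under results/.
"""

from pathlib import Path

import pandas as pd

from aneupr.association import msi_stratified_corr, partial_spearman, spearman_bh
from aneupr.expression import cyt_score, tp53_activity, tumor_vs_normal_test
from aneupr.genesets import load_default_genesets
from aneupr.io import read_expression, read_metadata

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = BASE / "cohort"
    expr = read_expression(cohort / "expression.tsv")
    meta = read_metadata(cohort / "metadata.tsv")
    genesets = load_default_genesets()
    scna = pd.read_csv(BASE / "scna_scores.tsv", sep="\t", index_col=0)["combined"]

    cyt = cyt_score(expr)
    tp53 = tp53_activity(expr, meta, genesets)
    pd.concat([cyt, tp53], axis=1).to_csv(BASE / "expression_scores.tsv", sep="\t")

    x_by, y_by = {}, {}
    for ttype in meta.tumor_types():
        ids = [s for s in meta.tumor_samples(ttype) if s in scna.index]
        x_by[ttype] = scna[ids]
        y_by[ttype] = cyt[ids]
    corr = spearman_bh(x_by, y_by)
    corr.to_csv(BASE / "scna_cyt_spearman.tsv", sep="\t")
    n_neg = int(((corr["rho"] < 0) & corr["significant"]).sum())
    print(
        f"SCNA-CYT: significant negative correlation in {n_neg}/{len(corr)} "
        f"tumor types (median rho = {corr['rho'].median():.3f})"
    )

    hspa5 = tumor_vs_normal_test(expr, meta, "HSPA5")
    hspa5.to_csv(BASE / "hspa5_tumor_vs_normal.tsv", sep="\t")
    print(
        f"HSPA5 higher in tumors in "
        f"{int((hspa5['mean_diff'] > 0).sum())}/{len(hspa5)} types "
        f"({int(hspa5['significant'].sum())} significant after BH)"
    )

    tumor_ids = [s for s in meta.tumor_samples() if s in scna.index]
    rho_p, p_p = partial_spearman(
        scna[tumor_ids], cyt[tumor_ids], tp53[tumor_ids].to_frame("tp53")
    )
    print(f"SCNA-CYT partial correlation given P53 activity: rho = {rho_p:.3f}")

    tab = meta.table.loc[tumor_ids]
    msi = msi_stratified_corr(
        tab["nonsilent_mutations"], scna[tumor_ids], tab["msi_score"]
    )
    msi.to_csv(BASE / "msi_mutation_scna.tsv", sep="\t")
    print(
        "mutation-SCNA Spearman: "
        + ", ".join(
            f"{s}: {msi.loc[s, 'rho']:.3f}" for s in msi.index if msi.loc[s, "testable"]
        )
    )


if __name__ == "__main__":
    main()
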