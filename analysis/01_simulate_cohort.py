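#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes segmented copy-number profiles (SEG), a log2(TPM+1) expression
matrix, sample metadata, the chromosome-arm table, the bundled gene sets
and the generator's ground truth to results/cohort/. The cohort carries
the structure the downstream analyses assume: stage-graded SCNA burden,
negative SCNA-CYT coupling, SCNA-stratum-dependent UPR co-expression
blocks, and tumor-vs-normal pathway shifts.
"""

from pathlib import Path

from aneupr.genesets import load_default_genesets
from aneupr.io import (
    write_arm_table,
    write_expression,
    write_gmt,
    write_metadata,
    write_seg,
)
from aneupr.simulate import CohortConfig, default_arm_table, simulate_cohort

SEED = 20260924
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    # 3 tumor types at reduced size keep the SEG file compact; the full
    # 12-type cohort is regenerated in memory by later steps where needed.
    cfg = CohortConfig(
        seed=SEED, n_tumor_types=3, samples_per_type=120, normals_per_type=30
    )
    profiles, expr, meta, truth = simulate_cohort(cfg)
    write_seg(profiles, OUT / "cohort.seg")
    write_expression(expr, OUT / "expression.tsv")
    write_metadata(meta, OUT / "metadata.tsv")
    write_arm_table(default_arm_table(), OUT / "arms.tsv")
    write_gmt(load_default_genesets(), OUT / "genesets.gmt")
    truth.to_json(OUT / "ground_truth.json")
    n_tumor = meta.table["is_tumor"].sum()
    print(
        f"wrote cohort: {len(profiles)} profiles ({n_tumor} tumors), "
        f"expression {expr.data.shape[0]} genes x {expr.data.shape[1]} samples"
    )


if __name__ == "__main__":
    main()
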