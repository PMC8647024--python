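"""Per-sample expression-derived scores: cytolytic activity and P53 activity.

The cytolytic activity (CYT) score is the geometric mean of GZMA and PRF1
expression on the log2(TPM+1) scale — a transcriptomic proxy for local
cytotoxic immune activity. P53 activity is inferred from a 10-gene signature
of genes P53 represses: high signature expression implies low P53 activity,
so the negated sum of within-tumor-type z-scores, min-max rescaled over the
cohort, serves as the activity score. A per-tumor-type tumor-vs-normal
t-test (with BH correction across types) supports single-gene comparisons
such as the ER chaperone HSPA5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from aneupr._stats import bh_adjust
from aneupr.io import ExpressionMatrix, GeneSetCollection, SampleMetadata

CYT_GENES = ("GZMA", "PRF1")


def cyt_score(expr: ExpressionMatrix) -> pd.Series:
    """Cytolytic activity per sample: sqrt(GZMA * PRF1) on the log2(TPM+1) scale."""
    for gene in CYT_GENES:
        if gene not in expr.genes:
            raise KeyError(f"cytolytic gene {gene} absent from expression matrix")
    gzma = expr.data.loc["GZMA"]
    prf1 = expr.data.loc["PRF1"]
    score = np.sqrt(gzma * prf1)
    score.name = "CYT"
    return score


def tp53_activity(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    genesets: GeneSetCollection,
    signature: str = "TP53_REPRESSED_10",
    per_tumor_type: bool = True,
) -> pd.Series:
    """P53 activity score from the 10-gene repressed signature.

    Signature genes are z-scored (within tumor type by default, cohort-wide
    with ``per_tumor_type=False``), summed per sample, negated (repression of
    these genes indicates P53 activity) and min-max rescaled to [0, 1].
    """
    genes = [g for g in genesets[signature] if g in expr.genes]
    missing = sorted(set(genesets[signature]) - set(genes))
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    samples = [s for s in expr.samples if s in meta.samples]
    mat = expr.data.loc[genes, samples]

    def _z(block: pd.DataFrame) -> pd.DataFrame:
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        if (sd == 0).any():
            warnings.warn(
                "zero-variance signature gene(s); z-score set to 0", stacklevel=3
            )
        z = block.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
        return z.fillna(0.0)

    if per_tumor_type:
        groups = meta.table.loc[samples, "tumor_type"]
        parts = []
        for _, ids in groups.groupby(groups).groups.items():
            ids = list(ids)
            if len(ids) < 3:
                raise ValueError(
                    "tumor types need >= 3 samples for within-type z-scoring"
                )
            parts.append(_z(mat[ids]))
        z = pd.concat(parts, axis=1)[samples]
    else:
        z = _z(mat)
    raw = -z.sum(axis=0)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        scaled = pd.Series(0.0, index=raw.index)
    else:
        scaled = (raw - lo) / (hi - lo)
    scaled.name = "TP53_activity"
    return scaled


def tumor_vs_normal_test(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    gene: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-tumor-type tumor-vs-normal comparison of one gene's expression.

    Student's t-test per tumor type with BH correction across the testable
    types; types with fewer than 2 tumor or 2 normal samples are reported as
    untestable. Returns a DataFrame indexed by tumor type with columns
    n_tumor, n_normal, mean_diff, t, p, q, significant, testable.
    """
    if gene not in expr.genes:
        raise KeyError(f"gene {gene} absent from expression matrix")
    values = expr.data.loc[gene]
    rows = []
    for ttype in meta.tumor_types():
        tum = [s for s in meta.tumor_samples(ttype) if s in values.index]
        nor = [s for s in meta.normal_samples(ttype) if s in values.index]
        rec = {"tumor_type": ttype, "n_tumor": len(tum), "n_normal": len(nor)}
        if len(tum) >= 2 and len(nor) >= 2:
            t, p = stats.ttest_ind(values[tum], values[nor])
            rec.update(
                mean_diff=float(values[tum].mean() - values[nor].mean()),
                t=float(t),
                p=float(p),
                testable=True,
            )
        else:
            rec.update(mean_diff=np.nan, t=np.nan, p=np.nan, testable=False)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("tumor_type")
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < alpha
    return out
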