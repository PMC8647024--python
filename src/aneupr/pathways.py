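"""UPR branch pathway activity scores from sparse tumor-vs-normal regression.

Per tumor type and pathway, an L1-penalized (Lasso) linear regression of a
binary tumor indicator (normal = 0, tumor = 1) on the pathway genes'
log2(TPM+1) expression selects the genes that discriminate tumor from
matched normal tissue; the penalty is chosen by 10-fold class-stratified
cross-validation. A sample's pathway score is the inner product of its
expression over the selected genes with the coefficient vector (intercept
excluded) — geometrically, a signed distance from the origin along the
tumor-vs-normal discriminating direction. Models whose coefficients are all
zero are flagged degenerate and excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import StratifiedKFold

from aneupr._stats import bh_adjust
from aneupr.io import ExpressionMatrix, SampleMetadata


@dataclass
class PathwayModel:
    """Sparse gene-coefficient vector for one (tumor type, pathway) fit.

    ``coefficients`` are on the original expression scale (predictors are
    standardized internally for penalization; coefficients are mapped back).
    """

    pathway: str
    tumor_type: str
    coefficients: pd.Series
    coefficients_standardized: pd.Series
    penalty: float
    n_tumor: int
    n_normal: int

    @property
    def degenerate(self) -> bool:
        return bool((self.coefficients == 0).all())

    @property
    def support(self) -> list[str]:
        return self.coefficients.index[self.coefficients != 0].tolist()


def fit_pathway_model(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    gene_set: list[str],
    tumor_type: str,
    pathway: str = "pathway",
    cv_folds: int = 10,
    seed: int = 0,
) -> PathwayModel:
    """Fit the Lasso tumor-vs-normal model for one tumor type and pathway."""
    genes = [g for g in gene_set if g in expr.genes]
    dropped = sorted(set(gene_set) - set(genes))
    if dropped:
        warnings.warn(
            f"{pathway}/{tumor_type}: dropping absent genes {dropped}", stacklevel=2
        )
    if not genes:
        raise ValueError(f"{pathway}/{tumor_type}: no pathway genes in matrix")
    tumors = [s for s in meta.tumor_samples(tumor_type) if s in expr.samples]
    normals = [s for s in meta.normal_samples(tumor_type) if s in expr.samples]
    if not normals:
        raise ValueError(
            f"tumor type {tumor_type} has no matched normal samples; "
            "pathway model cannot be fit"
        )
    if len(tumors) < 2 or len(normals) < 2 or len(tumors) + len(normals) < cv_folds:
        raise ValueError(
            f"tumor type {tumor_type}: insufficient samples for "
            f"{cv_folds}-fold cross-validation"
        )
    samples = tumors + normals
    x = expr.data.loc[genes, samples].T.to_numpy()
    y = np.array([1.0] * len(tumors) + [0.0] * len(normals))
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    usable = sd > 0
    if not usable.any():
        zero = pd.Series(0.0, index=pd.Index(genes, name="gene"))
        return PathwayModel(pathway, tumor_type, zero, zero.copy(), np.nan,
                            len(tumors), len(normals))
    xs = (x[:, usable] - mu[usable]) / sd[usable]
    n_splits = min(cv_folds, len(tumors), len(normals))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % 2**31)
    folds = list(skf.split(xs, y))
    model = LassoCV(cv=folds, random_state=seed % 2**31, max_iter=10000)
    model.fit(xs, y)
    coef_std = np.zeros(len(genes))
    coef_std[usable] = model.coef_
    coef_orig = np.zeros(len(genes))
    coef_orig[usable] = model.coef_ / sd[usable]
    idx = pd.Index(genes, name="gene")
    return PathwayModel(
        pathway=pathway,
        tumor_type=tumor_type,
        coefficients=pd.Series(coef_orig, index=idx),
        coefficients_standardized=pd.Series(coef_std, index=idx),
        penalty=float(model.alpha_),
        n_tumor=len(tumors),
        n_normal=len(normals),
    )


def score_samples(model: PathwayModel, expr: ExpressionMatrix) -> pd.Series:
    """Pathway score per sample: expression . coefficients over the support genes."""
    if model.degenerate:
        raise ValueError(
            f"model {model.pathway}/{model.tumor_type} is degenerate "
            "(all coefficients zero); samples cannot be scored"
        )
    support = model.support
    missing = [g for g in support if g not in expr.genes]
    if missing:
        raise KeyError(f"support genes absent from expression matrix: {missing}")
    scores = expr.data.loc[support].T @ model.coefficients[support]
    scores.name = f"{model.pathway}"
    return scores


def score_cohort(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    genesets: dict[str, list[str]],
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], PathwayModel]]:
    """Fit per-(type, pathway) models and score every sample of that type.

    Returns a sample x pathway score table (NaN where no non-degenerate
    model exists for the sample's tumor type) and the fitted models.
    """
    models: dict[tuple[str, str], PathwayModel] = {}
    table = pd.DataFrame(
        np.nan, index=expr.samples, columns=sorted(genesets)
    )
    for ttype in meta.tumor_types():
        type_samples = [
            s
            for s in meta.tumor_samples(ttype) + meta.normal_samples(ttype)
            if s in expr.samples
        ]
        for pathway, genes in sorted(genesets.items()):
            try:
                model = fit_pathway_model(
                    expr, meta, genes, ttype, pathway=pathway,
                    cv_folds=cv_folds, seed=seed,
                )
            except ValueError as exc:
                warnings.warn(str(exc), stacklevel=2)
                continue
            models[(ttype, pathway)] = model
            if model.degenerate:
                continue
            sub = expr.subset(samples=type_samples)
            table.loc[type_samples, pathway] = score_samples(model, sub)
    return table, models


def pathway_correlations(
    scores: pd.DataFrame,
    scna: pd.Series,
    cyt: pd.Series,
    meta: SampleMetadata,
    min_samples: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(tumor type, pathway) Spearman correlation with SCNA and CYT scores.

    BH correction is applied across tumor types separately for each
    (pathway, target) combination. Tumor types with degenerate (constant)
    pathway scores are skipped with a warning.
    """
    from scipy import stats

    rows = []
    for ttype in meta.tumor_types():
        ids = [
            s
            for s in meta.tumor_samples(ttype)
            if s in scores.index and s in scna.index and s in cyt.index
        ]
        for pathway in scores.columns:
            vals = scores.loc[ids, pathway].dropna()
            if len(vals) < min_samples:
                continue
            if vals.nunique() == 1:
                warnings.warn(
                    f"{ttype}/{pathway}: constant pathway scores, skipped",
                    stacklevel=2,
                )
                continue
            for target_name, target in (("SCNA", scna), ("CYT", cyt)):
                rho, p = stats.spearmanr(vals, target[vals.index])
                rows.append(
                    {
                        "tumor_type": ttype,
                        "pathway": pathway,
                        "target": target_name,
                        "n": len(vals),
                        "rho": float(rho),
                        "p": float(p),
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    for (_, _), idx in out.groupby(["pathway", "target"]).groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"])
    out["significant"] = out["q"] < alpha
    return out
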