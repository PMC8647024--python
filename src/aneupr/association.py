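"""Cross-variable association models: OLS with categorical covariates,
Spearman with BH across tumor types, partial Spearman correlation, and
MSI-stratified mutation-burden correlation.

These back the cohort-level claims of the analysis: aneuploidy burden rises
with tumor stage while cytolytic activity falls (OLS of score on tumor type
+ stage, Stage I baseline); SCNA and CYT are negatively rank-correlated
within most tumor types; the SCNA-CYT link persists after controlling for
confounders (partial Spearman); and the SCNA-mutation relationship differs
between microsatellite-stable and MSI-high tumors (split at MSI score 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from aneupr._stats import bh_adjust
from aneupr.coexpression import StratifiedCohort
from aneupr.io import ExpressionMatrix


@dataclass
class ModelReport:
    """Fitted OLS summary: per-term coefficient, p-value and 95% CI."""

    terms: pd.DataFrame  # columns: coefficient, p, ci_low, ci_high
    n: int
    n_dropped: int
    formula: str
    r_squared: float

    def coefficient(self, term: str) -> float:
        return float(self.terms.loc[term, "coefficient"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def ols_fit(
    response: pd.Series,
    covariates: pd.DataFrame,
    baseline_levels: dict[str, str] | None = None,
) -> ModelReport:
    """OLS of a score on mixed numeric/categorical covariates.

    Categorical covariates (object/categorical dtype) are dummy-coded
    against the declared baseline level (``baseline_levels``, defaulting to
    the lexicographically first level). Rows with missing values are dropped
    listwise and counted. Rank-deficient designs raise with the aliased
    columns named.
    """
    baseline_levels = baseline_levels or {}
    data = covariates.copy()
    data["_y"] = response
    n_before = len(data)
    data = data.dropna()
    n_dropped = n_before - len(data)
    y = data.pop("_y").astype(float)
    parts = [pd.Series(1.0, index=data.index, name="Intercept")]
    term_names = []
    for col in covariates.columns:
        series = data[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"categorical covariate {col} has < 2 levels")
            base = baseline_levels.get(col, levels[0])
            if base not in levels:
                raise ValueError(f"baseline {base!r} not a level of {col}")
            for lev in levels:
                if lev == base:
                    continue
                name = f"{col}[{lev}]"
                parts.append((series.astype(str) == lev).astype(float).rename(name))
                term_names.append(name)
        else:
            parts.append(series.astype(float).rename(col))
            term_names.append(col)
    design = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify aliased columns by greedy rank check
        aliased = []
        kept: list[str] = []
        for col in design.columns:
            cand = design[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(col)
            else:
                aliased.append(col)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = pd.DataFrame(
        {
            "coefficient": fit.params,
            "p": fit.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    formula = "y ~ " + " + ".join(covariates.columns)
    return ModelReport(
        terms=terms,
        n=int(fit.nobs),
        n_dropped=n_dropped,
        formula=formula,
        r_squared=float(fit.rsquared),
    )


def spearman_bh(
    x_by_type: dict[str, pd.Series],
    y_by_type: dict[str, pd.Series],
    min_pairs: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-tumor-type Spearman correlation with BH correction across types.

    p-values come from the Student's t approximation with df = n - 2 (as
    scipy computes for Spearman). Types with constant vectors or fewer than
    ``min_pairs`` complete pairs are reported untestable.
    """
    rows = []
    for ttype in sorted(x_by_type):
        x = x_by_type[ttype]
        y = y_by_type[ttype]
        common = x.dropna().index.intersection(y.dropna().index)
        rec = {"tumor_type": ttype, "n": len(common)}
        if len(common) < min_pairs or x[common].nunique() == 1 or y[common].nunique() == 1:
            rec.update(rho=np.nan, p=np.nan, testable=False)
        else:
            rho, p = stats.spearmanr(x[common], y[common])
            rec.update(rho=float(rho), p=float(p), testable=True)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("tumor_type")
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < alpha
    return out


def partial_spearman(
    x: pd.Series, y: pd.Series, controls: pd.DataFrame | pd.Series
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given control variables.

    All variables are rank-transformed; x and y ranks are residualized on
    the control ranks (plus intercept) by least squares and the residuals
    correlated. The p-value uses Student's t with df = n - 2 - #controls.
    """
    if isinstance(controls, pd.Series):
        controls = controls.to_frame()
    data = pd.concat([x.rename("_x"), y.rename("_y"), controls], axis=1).dropna()
    n = len(data)
    k = controls.shape[1]
    if n < 5:
        raise ValueError("partial correlation requires >= 5 complete observations")
    if (data.iloc[:, 2:].nunique() == 1).any():
        raise ValueError("constant control variable")
    ranks = data.apply(lambda s: stats.rankdata(s), axis=0, result_type="expand")
    ranks.columns = data.columns
    z = np.column_stack([np.ones(n), ranks.iloc[:, 2:].to_numpy()])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("collinear control variables")
    coef_x, *_ = np.linalg.lstsq(z, ranks["_x"].to_numpy(), rcond=None)
    coef_y, *_ = np.linalg.lstsq(z, ranks["_y"].to_numpy(), rcond=None)
    rx = ranks["_x"].to_numpy() - z @ coef_x
    ry = ranks["_y"].to_numpy() - z @ coef_y
    # residuals that are pure numerical noise mean the controls explain
    # everything: the partial correlation is 0 by convention
    tot_x = ((ranks["_x"] - ranks["_x"].mean()) ** 2).sum()
    tot_y = ((ranks["_y"] - ranks["_y"].mean()) ** 2).sum()
    if (rx**2).sum() <= 1e-12 * max(tot_x, 1.0) or (ry**2).sum() <= 1e-12 * max(
        tot_y, 1.0
    ):
        return 0.0, 1.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float((rx * ry).sum() / denom)
    df = n - 2 - k
    if df <= 0:
        return rho, np.nan
    r = np.clip(rho, -0.999999, 0.999999)
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=df)
    return rho, float(p)


def msi_stratified_corr(
    mutations: pd.Series,
    scna: pd.Series,
    msi_scores: pd.Series,
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Spearman correlation of non-silent mutation count with SCNA burden,
    separately in MSS (MSI score < threshold) and MSI-H (>= threshold) samples.

    Returns a DataFrame indexed by stratum with n, rho, p, testable.
    """
    common = mutations.dropna().index.intersection(scna.index).intersection(
        msi_scores.dropna().index
    )
    msi_h = msi_scores[common] >= threshold
    rows = []
    for name, ids in (
        ("MSS", common[~msi_h]),
        ("MSI-H", common[msi_h]),
    ):
        rec = {"stratum": name, "n": len(ids)}
        if len(ids) < 5 or mutations[ids].nunique() == 1 or scna[ids].nunique() == 1:
            rec.update(rho=np.nan, p=np.nan, testable=False)
        else:
            rho, p = stats.spearmanr(mutations[ids], scna[ids])
            rec.update(rho=float(rho), p=float(p), testable=True)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("stratum")


def scna_group_expression_test(
    expr: ExpressionMatrix,
    strata: StratifiedCohort,
    genes: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum test of each gene between pooled SCNA-low and SCNA-high samples.

    Low (high) samples are pooled across tumor types; BH correction is
    applied across genes. Constant genes are reported untestable.
    """
    low: list[str] = []
    high: list[str] = []
    for ttype in strata.types():
        lo, hi = strata.groups[ttype]
        low.extend(s for s in lo if s in expr.samples)
        high.extend(s for s in hi if s in expr.samples)
    if len(low) < 2 or len(high) < 2:
        raise ValueError("both SCNA strata need >= 2 samples")
    rows = []
    for gene in genes:
        if gene not in expr.genes:
            raise KeyError(f"gene {gene} absent from expression matrix")
        a = expr.data.loc[gene, low]
        b = expr.data.loc[gene, high]
        rec = {"gene": gene, "mean_low": float(a.mean()), "mean_high": float(b.mean())}
        if pd.concat([a, b]).nunique() == 1:
            rec.update(statistic=np.nan, p=np.nan, testable=False)
        else:
            stat, p = stats.ranksums(a, b)
            rec.update(statistic=float(stat), p=float(p), testable=True)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < alpha
    return out
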