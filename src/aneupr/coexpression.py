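"""Differential co-expression of a gene set between SCNA-low and SCNA-high tumors.

Samples are split within each tumor type at the 30th/70th percentiles of
the SCNA burden score. For each stratum a Spearman adjacency matrix is
built; the differential statistic for a gene pair is

    D_ij = ( 1/2 | sign(c_low) c_low^2 - sign(c_high) c_high^2 | ) ** beta

with beta = 4. Significance is assessed by permuting low/high group
membership within each tumor type (1,000 permutations by default), with
Benjamini-Hochberg correction across gene pairs within the type. Pairs
significant in at least ``min_types`` tumor types are classified as
recurrently perturbed; pairs whose correlation is BH-significant in both
strata of every type (and that are not perturbed) are preserved. Control
pathways run under identical settings provide an empirical false-discovery
estimate for the recurrence rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aneupr._stats import bh_adjust, spearman_matrix, spearman_t_pvalue
from aneupr.io import ExpressionMatrix, SampleMetadata


@dataclass
class StratifiedCohort:
    """Per-tumor-type SCNA-low / SCNA-high sample groups and thresholds."""

    groups: dict[str, tuple[list[str], list[str]]]
    thresholds: dict[str, tuple[float, float]]
    skipped: list[str] = field(default_factory=list)

    def types(self) -> list[str]:
        return sorted(self.groups)


@dataclass
class DiffCoexResult:
    """Stratified co-expression result for one tumor type.

    Matrices are gene x gene DataFrames: ``c_low``/``c_high`` Spearman
    adjacencies, ``delta`` = c_low - c_high, ``d`` the differential
    statistic, ``perm_p``/``perm_q`` permutation p-values and BH q-values,
    and ``p_low``/``p_high`` the per-stratum correlation p-values.
    """

    tumor_type: str
    n_low: int
    n_high: int
    c_low: pd.DataFrame
    c_high: pd.DataFrame
    delta: pd.DataFrame
    d: pd.DataFrame
    perm_p: pd.DataFrame
    perm_q: pd.DataFrame
    p_low: pd.DataFrame
    p_high: pd.DataFrame


def stratify(
    scores: pd.Series,
    meta: SampleMetadata,
    lo_pct: float = 30.0,
    hi_pct: float = 70.0,
    min_samples: int = 10,
) -> StratifiedCohort:
    """Split tumor samples into SCNA-low / SCNA-high groups per tumor type.

    low = samples with score <= the ``lo_pct`` percentile of their tumor
    type, high = samples with score >= the ``hi_pct`` percentile; the middle
    belongs to neither group. Types with fewer than ``min_samples`` scored
    tumor samples are skipped (and reported).
    """
    if not 0 <= lo_pct <= hi_pct <= 100:
        raise ValueError("percentiles must satisfy 0 <= lo <= hi <= 100")
    groups: dict[str, tuple[list[str], list[str]]] = {}
    thresholds: dict[str, tuple[float, float]] = {}
    skipped: list[str] = []
    for ttype in meta.tumor_types():
        ids = [s for s in meta.tumor_samples(ttype) if s in scores.index]
        if len(ids) < min_samples:
            skipped.append(ttype)
            continue
        vals = scores[ids]
        p_lo = float(np.percentile(vals, lo_pct))
        p_hi = float(np.percentile(vals, hi_pct))
        low = [s for s in ids if vals[s] <= p_lo]
        high = [s for s in ids if vals[s] >= p_hi]
        if not low or not high or not set(low).isdisjoint(high):
            raise ValueError(
                f"tumor type {ttype}: degenerate SCNA stratification "
                f"(ties at the percentile thresholds)"
            )
        groups[ttype] = (low, high)
        thresholds[ttype] = (p_lo, p_hi)
    if skipped:
        warnings.warn(
            f"skipping tumor types with < {min_samples} samples: {skipped}",
            stacklevel=2,
        )
    return StratifiedCohort(groups=groups, thresholds=thresholds, skipped=skipped)


def adjacency(
    expr: ExpressionMatrix, samples: list[str], genes: list[str]
) -> pd.DataFrame:
    """Spearman co-expression adjacency matrix over the given samples and genes."""
    if len(samples) < 5:
        raise ValueError("adjacency requires >= 5 samples")
    missing = [g for g in genes if g not in expr.genes]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    x = expr.data.loc[genes, samples].to_numpy()
    if (x.std(axis=1) == 0).any():
        warnings.warn("constant gene(s); correlations set to 0", stacklevel=2)
    c = spearman_matrix(x)
    return pd.DataFrame(c, index=genes, columns=genes)


def diff_matrix(
    c_low: pd.DataFrame, c_high: pd.DataFrame, beta: float = 4.0
) -> pd.DataFrame:
    """Differential co-expression statistic D from the two stratum adjacencies."""
    if c_low.shape != c_high.shape:
        raise ValueError("adjacency matrices have mismatched shapes")
    sl = np.sign(c_low.to_numpy()) * c_low.to_numpy() ** 2
    sh = np.sign(c_high.to_numpy()) * c_high.to_numpy() ** 2
    d = (0.5 * np.abs(sl - sh)) ** beta
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=c_low.index, columns=c_low.columns)


def _d_stat(x_low: np.ndarray, x_high: np.ndarray, beta: float) -> np.ndarray:
    cl = spearman_matrix(x_low)
    ch = spearman_matrix(x_high)
    return (0.5 * np.abs(np.sign(cl) * cl**2 - np.sign(ch) * ch**2)) ** beta


def permutation_test(
    expr: ExpressionMatrix,
    cohort: StratifiedCohort,
    genes: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    beta: float = 4.0,
) -> dict[str, DiffCoexResult]:
    """Permutation test for differential co-expression, per tumor type.

    Low/high group labels are shuffled ``n_perm`` times within each tumor
    type; the pair-level p-value is (1 + #{D_perm >= D_obs}) / (n_perm + 1),
    BH-adjusted across the unordered gene pairs within the type. Random
    streams are seeded per (tumor type, permutation index) so results do not
    depend on execution order. Types with a group smaller than 5 samples are
    skipped with a warning.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm = {n_perm} gives coarse p-value resolution", stacklevel=2
        )
    genes = list(genes)
    g = len(genes)
    iu = np.triu_indices(g, k=1)
    results: dict[str, DiffCoexResult] = {}
    for type_idx, ttype in enumerate(cohort.types()):
        low, high = cohort.groups[ttype]
        n_low, n_high = len(low), len(high)
        if min(n_low, n_high) < 5:
            warnings.warn(
                f"tumor type {ttype}: group smaller than 5 samples, skipped",
                stacklevel=2,
            )
            continue
        x = expr.data.loc[genes, low + high].to_numpy()
        x_low, x_high = x[:, :n_low], x[:, n_low:]
        c_low = spearman_matrix(x_low)
        c_high = spearman_matrix(x_high)
        d_obs = (
            0.5 * np.abs(np.sign(c_low) * c_low**2 - np.sign(c_high) * c_high**2)
        ) ** beta
        exceed = np.zeros_like(d_obs)
        n_total = n_low + n_high
        for p_idx in range(n_perm):
            rng = np.random.default_rng([seed, type_idx, p_idx])
            perm = rng.permutation(n_total)
            d_perm = _d_stat(x[:, perm[:n_low]], x[:, perm[n_low:]], beta)
            exceed += d_perm >= d_obs
        p = (1.0 + exceed) / (n_perm + 1.0)
        q_flat = bh_adjust(p[iu])
        q = np.ones_like(p)
        q[iu] = q_flat
        q.T[iu] = q_flat
        np.fill_diagonal(p, 1.0)
        np.fill_diagonal(q, 1.0)

        def _pmat(c: np.ndarray, n: int) -> np.ndarray:
            out = np.ones_like(c)
            flat = np.array([spearman_t_pvalue(r, n) for r in c[iu]])
            out[iu] = flat
            out.T[iu] = flat
            return out

        mk = lambda a: pd.DataFrame(a, index=genes, columns=genes)  # noqa: E731
        results[ttype] = DiffCoexResult(
            tumor_type=ttype,
            n_low=n_low,
            n_high=n_high,
            c_low=mk(c_low),
            c_high=mk(c_high),
            delta=mk(c_low - c_high),
            d=mk(np.where(np.eye(g, dtype=bool), 0.0, d_obs)),
            perm_p=mk(p),
            perm_q=mk(q),
            p_low=mk(_pmat(c_low, n_low)),
            p_high=mk(_pmat(c_high, n_high)),
        )
    return results


def classify_pairs(
    results: dict[str, DiffCoexResult],
    min_types: int = 9,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Classify gene pairs as recurrently perturbed, preserved, or neither.

    Perturbed: permutation q < ``q_thresh`` in at least ``min_types`` tumor
    types, with direction taken by majority sign of delta = c_low - c_high
    among the significant types (positive delta = reduced co-expression
    under high SCNA; ties = mixed). Preserved: stratum correlations
    BH-significant in both strata of every analyzed type, and not perturbed.
    Returns a DataFrame indexed by (gene_a, gene_b) unordered pairs.
    """
    if not results:
        raise ValueError("no differential co-expression results to classify")
    types = sorted(results)
    genes = list(results[types[0]].d.index)
    iu = np.triu_indices(len(genes), k=1)
    # canonical unordered pair keys: lexicographically sorted gene names
    a_names = np.array(genes)[iu[0]]
    b_names = np.array(genes)[iu[1]]
    swap = a_names > b_names
    lo = np.where(swap, b_names, a_names)
    hi = np.where(swap, a_names, b_names)
    pairs = pd.MultiIndex.from_arrays([lo, hi], names=["gene_a", "gene_b"])
    n_sig = np.zeros(len(pairs), dtype=int)
    sign_sum = np.zeros(len(pairs))
    preserved_all = np.ones(len(pairs), dtype=bool)
    for ttype in types:
        res = results[ttype]
        q = res.perm_q.to_numpy()[iu]
        delta = res.delta.to_numpy()[iu]
        sig = q < q_thresh
        n_sig += sig
        sign_sum += np.where(sig, np.sign(delta), 0.0)
        ql = bh_adjust(res.p_low.to_numpy()[iu]) < q_thresh
        qh = bh_adjust(res.p_high.to_numpy()[iu]) < q_thresh
        preserved_all &= ql & qh
    perturbed = n_sig >= min_types
    direction = np.where(
        perturbed & (sign_sum > 0),
        "reduced",
        np.where(perturbed & (sign_sum < 0), "augmented", "mixed"),
    )
    direction = np.where(perturbed, direction, "none")
    status = np.where(
        perturbed, "perturbed", np.where(preserved_all, "preserved", "neither")
    )
    return pd.DataFrame(
        {
            "n_significant_types": n_sig,
            "direction": direction,
            "status": status,
        },
        index=pairs,
    )


@dataclass(frozen=True)
class EmpiricalFdr:
    """Control-pathway empirical false-discovery estimate for the recurrence rule."""

    gene_rate: float
    pair_rate: float
    n_flagged_genes: int
    n_control_genes: int
    n_flagged_pairs: int
    n_control_pairs: int


def empirical_fdr(control_results: dict[str, pd.DataFrame]) -> EmpiricalFdr:
    """Fraction of control-pathway genes (and pairs) flagged as perturbed.

    ``control_results`` maps control-pathway name to the classification
    table from :func:`classify_pairs` run under identical settings.
    """
    if not control_results:
        raise ValueError("no control pathways provided")
    flagged_genes: set[str] = set()
    all_genes: set[str] = set()
    n_flagged_pairs = 0
    n_pairs = 0
    for table in control_results.values():
        genes = set(table.index.get_level_values(0)) | set(
            table.index.get_level_values(1)
        )
        all_genes |= genes
        mask = table["status"] == "perturbed"
        n_flagged_pairs += int(mask.sum())
        n_pairs += len(table)
        for ga, gb in table.index[mask]:
            flagged_genes.update((ga, gb))
    return EmpiricalFdr(
        gene_rate=len(flagged_genes) / len(all_genes),
        pair_rate=n_flagged_pairs / n_pairs,
        n_flagged_genes=len(flagged_genes),
        n_control_genes=len(all_genes),
        n_flagged_pairs=n_flagged_pairs,
        n_control_pairs=n_pairs,
    )
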