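"""Somatic copy-number alteration (SCNA) event scoring and the combined burden score.

A segment is an *event* when its log2 intensity ratio clears a threshold:
one event for |log2FC| > 0.1, two events for |log2FC| > 1 (strict
inequalities). Arms are scored on the fractional-length-weighted mean log2FC
of their segments. A chromosome where both arms qualify in the same
direction contributes whole-chromosome events; a chromosome where one arm
qualifies (or the arms disagree in direction) contributes arm events; and
any individual qualifying segment shorter than its arm's covered extent
contributes focal events, independent of the larger categories. Per-sample
category totals (0-46 chromosomal, 0-92 arm, unbounded focal) are min-max
rescaled over the cohort and summed into a single SCNA burden score in
[0, 3].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from aneupr.io import CHROMOSOMES, ArmTable, SegmentedProfile


@dataclass(frozen=True)
class EventCounts:
    """Per-sample SCNA event counts by category."""

    sample_id: str
    chromosomal: int
    arm: int
    focal: int

    def __post_init__(self) -> None:
        if min(self.chromosomal, self.arm, self.focal) < 0:
            raise ValueError("event counts must be non-negative")
        if self.chromosomal > 46:
            raise ValueError("chromosomal events exceed the 0-46 bound")
        if self.arm > 92:
            raise ValueError("arm events exceed the 0-92 bound")


def region_events(log2fc: float) -> tuple[int, int]:
    """Event count and direction for one region's log2 fold change.

    Returns ``(count, direction)`` with count in {0, 1, 2} and direction in
    {-1, 0, +1}. Thresholds are strict: a log2FC of exactly +/-0.1 (or +/-1)
    stays in the lower category.
    """
    x = float(log2fc)
    if not np.isfinite(x):
        raise ValueError("log2fc must be finite")
    if x > 1.0 or x < -1.0:
        count = 2
    elif x > 0.1 or x < -0.1:
        count = 1
    else:
        count = 0
    direction = int(np.sign(x)) if count else 0
    return count, direction


def _region_events_vec(log2fc: np.ndarray) -> np.ndarray:
    """Vectorized event counts per region (same thresholds as region_events)."""
    x = np.asarray(log2fc, dtype=float)
    return np.where(np.abs(x) > 1.0, 2, np.where(np.abs(x) > 0.1, 1, 0))


def _clip_regions(regions: pd.DataFrame, start: int, end: int) -> pd.DataFrame:
    """Regions clipped to [start, end] (1-based inclusive); empty clips dropped."""
    s = regions["start"].clip(lower=start)
    e = regions["end"].clip(upper=end)
    keep = s <= e
    out = regions.loc[keep, ["log2fc"]].copy()
    out["start"] = s[keep]
    out["end"] = e[keep]
    out["length"] = out["end"] - out["start"] + 1
    return out


def arm_intensity(
    profile: SegmentedProfile,
    chromosome: str,
    arm: str,
    arms: ArmTable,
) -> tuple[float, bool]:
    """Length-weighted mean log2FC of a chromosome arm.

    Returns ``(intensity, covered)``. The intensity is
    sum(log2FC_i * length_i) / total covered length, with regions clipped to
    the arm interval. An arm with no overlapping region returns
    ``(0.0, False)``.
    """
    a_start, a_end = arms.arm_interval(chromosome, arm)
    regions = profile.regions[profile.regions["chromosome"] == str(chromosome)]
    clipped = _clip_regions(regions, a_start, a_end)
    total = int(clipped["length"].sum()) if len(clipped) else 0
    if total == 0:
        return 0.0, False
    intensity = float((clipped["log2fc"] * clipped["length"]).sum() / total)
    return intensity, True


def classify_sample_events(
    profile: SegmentedProfile,
    arms: ArmTable,
    focal_fraction: float = 1.0,
) -> EventCounts:
    """Categorize one sample's SCNA events into chromosomal / arm / focal counts.

    Per chromosome, both arm intensities are computed and thresholded. Both
    arms qualifying in the same direction yields whole-chromosome events,
    counted by thresholding the length-weighted whole-chromosome intensity;
    otherwise each qualifying arm contributes its own events. Independently,
    every qualifying region whose clipped extent is strictly below
    ``focal_fraction`` of its arm's covered extent adds focal events —
    focal counting is not constrained by the larger categories.
    """
    if not 0.0 < focal_fraction <= 1.0:
        raise ValueError("focal_fraction must be in (0, 1]")
    chromosomal = 0
    arm_events = 0
    focal = 0
    by_chrom = {
        chrom: (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["log2fc"].to_numpy(float),
        )
        for chrom, grp in profile.regions.groupby("chromosome", sort=False)
    }
    counts_vec = _region_events_vec
    for chrom in CHROMOSOMES:
        if chrom not in by_chrom:
            continue
        starts, ends, fc = by_chrom[chrom]
        arm_info = []
        for arm in ("p", "q"):
            a_start, a_end = arms.arm_interval(chrom, arm)
            cs = np.maximum(starts, a_start)
            ce = np.minimum(ends, a_end)
            lengths = ce - cs + 1
            keep = lengths > 0
            covered = int(lengths[keep].sum())
            if covered:
                intensity = float((fc[keep] * lengths[keep]).sum() / covered)
                count, direction = region_events(intensity)
            else:
                intensity, count, direction = 0.0, 0, 0
            arm_info.append(
                (covered, intensity, count, direction, fc[keep], lengths[keep])
            )
        p, q = arm_info
        whole = p[2] > 0 and q[2] > 0 and p[3] == q[3]
        if whole:
            total = p[0] + q[0]
            mean_fc = (p[1] * p[0] + q[1] * q[0]) / total
            chromosomal += region_events(mean_fc)[0]
        else:
            arm_events += (p[2] if p[2] else 0) + (q[2] if q[2] else 0)
        # focal events: qualifying regions shorter than their arm's covered extent
        for covered, _, _, _, reg_fc, reg_len in (p, q):
            if not covered:
                continue
            cnt = counts_vec(reg_fc)
            is_focal = (cnt > 0) & (reg_len < focal_fraction * covered)
            focal += int(cnt[is_focal].sum())
    return EventCounts(
        sample_id=profile.sample_id,
        chromosomal=chromosomal,
        arm=arm_events,
        focal=focal,
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn(
            "degenerate event category (max == min); scaled component set to 0",
            stacklevel=3,
        )
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def cohort_scna_scores(counts: list[EventCounts] | dict[str, EventCounts]) -> pd.DataFrame:
    """Cohort-wide SCNA scores: min-max rescaled categories and their sum.

    Returns a DataFrame indexed by sample with columns chromosomal, arm,
    focal (raw counts), scaled_chromosomal, scaled_arm, scaled_focal (each
    in [0, 1] over the cohort) and combined = sum of the three scaled
    components (in [0, 3]).
    """
    if isinstance(counts, dict):
        counts = [counts[k] for k in sorted(counts)]
    if len(counts) < 2:
        raise ValueError("cohort rescaling requires at least 2 samples")
    df = pd.DataFrame(
        {
            "chromosomal": [c.chromosomal for c in counts],
            "arm": [c.arm for c in counts],
            "focal": [c.focal for c in counts],
        },
        index=pd.Index([c.sample_id for c in counts], name="sample"),
    )
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in event counts")
    for cat in ("chromosomal", "arm", "focal"):
        df[f"scaled_{cat}"] = _minmax(df[cat].to_numpy(dtype=float))
    df["combined"] = (
        df["scaled_focal"] + df["scaled_arm"] + df["scaled_chromosomal"]
    )
    return df
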