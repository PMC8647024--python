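"""Independent brute-force re-derivations used as test oracles.

These deliberately re-implement the scoring rules from their definitions
with plain Python loops, independent of the package's vectorized code
paths.
"""

from __future__ import annotations

import numpy as np


def brute_event_count(log2fc: float) -> int:
    if log2fc > 1 or log2fc < -1:
        return 2
    if log2fc > 0.1 or log2fc < -0.1:
        return 1
    return 0


def brute_classify(regions, arm_table) -> tuple[int, int, int]:
    """Brute-force event classification.

    ``regions``: iterable of (chromosome, start, end, log2fc).
    ``arm_table``: mapping chromosome -> {"p": (start, end), "q": (start, end)}.
    Returns (chromosomal, arm, focal) counts.
    """
    chromosomal = arm_total = focal = 0
    for chrom, arms in arm_table.items():
        chrom_regions = [r for r in regions if r[0] == chrom]
        if not chrom_regions:
            continue
        per_arm = {}
        for arm_name, (a_start, a_end) in arms.items():
            pieces = []
            for _, start, end, fc in chrom_regions:
                s = max(start, a_start)
                e = min(end, a_end)
                if s <= e:
                    pieces.append((e - s + 1, fc))
            covered = sum(length for length, _ in pieces)
            if covered:
                intensity = sum(length * fc for length, fc in pieces) / covered
                count = brute_event_count(intensity)
                sign = 0 if count == 0 else (1 if intensity > 0 else -1)
            else:
                intensity, count, sign = 0.0, 0, 0
            per_arm[arm_name] = (covered, intensity, count, sign, pieces)
        p_cov, p_int, p_cnt, p_sgn, p_pieces = per_arm["p"]
        q_cov, q_int, q_cnt, q_sgn, q_pieces = per_arm["q"]
        if p_cnt > 0 and q_cnt > 0 and p_sgn == q_sgn:
            whole = (p_int * p_cov + q_int * q_cov) / (p_cov + q_cov)
            chromosomal += brute_event_count(whole)
        else:
            if p_cnt > 0:
                arm_total += p_cnt
            if q_cnt > 0:
                arm_total += q_cnt
        for covered, _, _, _, pieces in ((p_cov, 0, 0, 0, p_pieces), (q_cov, 0, 0, 0, q_pieces)):
            for length, fc in pieces:
                c = brute_event_count(fc)
                if c and length < covered:
                    focal += c
    return chromosomal, arm_total, focal


def brute_spearman(x, y) -> float:
    """Spearman correlation via explicit average ranks and the Pearson formula."""

    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def random_profile_regions(rng: np.random.Generator, arm_table, max_regions=50):
    """Random region list exercising all event categories."""
    chroms = list(arm_table)
    n = int(rng.integers(1, max_regions + 1))
    regions = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        arm = "p" if rng.random() < 0.5 else "q"
        a_start, a_end = arm_table[chrom][arm]
        arm_len = a_end - a_start + 1
        mode = rng.random()
        if mode < 0.3:  # full-arm segment
            start, end = a_start, a_end
        else:  # random sub-segment
            length = int(rng.integers(1, max(2, arm_len // 3)))
            start = int(rng.integers(a_start, a_end - length + 2))
            end = start + length - 1
        if any(s <= end and start <= e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        fc = float(rng.choice([0.0, 0.05, 0.2, -0.2, 0.5, -0.5, 1.5, -1.5]))
        fc += float(rng.normal(0, 0.02))
        regions.append((chrom, start, end, fc))
    return regions
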