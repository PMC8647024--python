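"""Readers, writers and validated in-memory containers for the pipeline's file formats.

Formats handled: SEG (tab-delimited segmented copy number, 1-based inclusive
coordinates), TSV expression matrices on the log2(TPM+1) scale, GMT gene
sets, TSV sample metadata and a TSV chromosome-arm boundary table. All
writers emit UTF-8, tab-delimited text with '.' decimals and a deterministic
column order, so that write->read round-trips are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The 23 scored chromosomes: autosomes 1-22 plus X. Y and mitochondrial
#: segments carry no aneuploidy-burden information here and are dropped.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


def _normalize_chromosome(label) -> str:
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "23":
        s = "X"
    return s


# ---------------------------------------------------------------------------
# Segmented copy-number profiles
# ---------------------------------------------------------------------------

@dataclass
class SegmentedProfile:
    """One sample's contiguous copy-number regions with log2 intensity ratios.

    ``regions`` has columns chromosome, start, end, log2fc with 1-based
    inclusive coordinates, sorted by chromosome then start. Regions on a
    chromosome must not overlap.
    """

    sample_id: str
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["chromosome", "start", "end", "log2fc"]
        missing = [c for c in req if c not in self.regions.columns]
        if missing:
            raise FormatError(f"regions missing columns: {missing}")
        df = self.regions[req].copy()
        df["chromosome"] = df["chromosome"].map(_normalize_chromosome)
        bad = sorted(set(df["chromosome"]) - set(CHROMOSOMES))
        if bad:
            raise ValidationError(
                f"sample {self.sample_id}: unsupported chromosome labels {bad}"
            )
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["log2fc"] = df["log2fc"].astype(float)
        if not np.isfinite(df["log2fc"]).all():
            raise ValidationError(f"sample {self.sample_id}: non-finite segment mean")
        if (df["start"] > df["end"]).any():
            row = df[df["start"] > df["end"]].iloc[0]
            raise ValidationError(
                f"sample {self.sample_id}: start > end at "
                f"chr{row.chromosome}:{row.start}-{row.end}"
            )
        df = df.sort_values(
            ["chromosome", "start"],
            key=lambda s: s.map({c: i for i, c in enumerate(CHROMOSOMES)})
            if s.name == "chromosome"
            else s,
            kind="mergesort",
        ).reset_index(drop=True)
        for chrom, grp in df.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            overlap = starts[1:] <= ends[:-1]
            if overlap.any():
                i = int(np.argmax(overlap))
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping regions on chr{chrom} "
                    f"({starts[i]}-{ends[i]} and {starts[i + 1]}-{ends[i + 1]})"
                )
        object.__setattr__(self, "regions", df)

    def __len__(self) -> int:
        return len(self.regions)


_SEG_ALIASES = {
    "sample": ("sample", "id", "sample_id"),
    "chromosome": ("chromosome", "chrom", "chr"),
    "start": ("start", "loc.start", "loc_start"),
    "end": ("end", "loc.end", "loc_end"),
    "log2fc": ("log2fc", "seg.mean", "seg_mean", "segment_mean", "mean"),
}


def read_seg(path) -> dict[str, SegmentedProfile]:
    """Read a SEG file into one :class:`SegmentedProfile` per sample.

    Chromosome "23" is normalized to "X"; rows on unscored chromosomes
    (Y, MT) are dropped with a warning. Overlapping regions within a
    sample+chromosome raise :class:`ValidationError`.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in raw.columns}
    cols = {}
    for canon, aliases in _SEG_ALIASES.items():
        for a in aliases:
            if a in lower:
                cols[canon] = lower[a]
                break
        else:
            raise FormatError(f"{path.name}: missing required column '{canon}'")
    df = raw[[cols[k] for k in _SEG_ALIASES]].copy()
    df.columns = list(_SEG_ALIASES)
    df["chromosome"] = df["chromosome"].map(_normalize_chromosome)
    unsupported = ~df["chromosome"].isin(CHROMOSOMES)
    if unsupported.any():
        dropped = sorted(df.loc[unsupported, "chromosome"].unique())
        warnings.warn(
            f"{path.name}: dropping {int(unsupported.sum())} rows on unscored "
            f"chromosomes {dropped}",
            stacklevel=2,
        )
        df = df[~unsupported]
    try:
        df["log2fc"] = df["log2fc"].astype(float)
    except ValueError:
        bad = pd.to_numeric(df["log2fc"], errors="coerce").isna()
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(f"{path.name}: non-numeric segment mean at line {line}")
    profiles: dict[str, SegmentedProfile] = {}
    for sample, grp in df.groupby("sample", sort=True):
        profiles[str(sample)] = SegmentedProfile(
            sample_id=str(sample),
            regions=grp[["chromosome", "start", "end", "log2fc"]],
        )
    return profiles


def write_seg(profiles: Mapping[str, SegmentedProfile] | Iterable[SegmentedProfile], path) -> None:
    """Write profiles to a Broad-dialect SEG file (deterministic order)."""
    if isinstance(profiles, Mapping):
        profiles = [profiles[k] for k in sorted(profiles)]
    frames = []
    for prof in profiles:
        df = prof.regions.copy()
        df.insert(0, "sample", prof.sample_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.columns = ["sample", "chromosome", "start", "end", "log2fc"]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2(TPM+1) expression values (all >= 0)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.empty:
            raise ValidationError("expression matrix is empty")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            warnings.warn(
                f"collapsing duplicated gene rows by mean: {dups}", stacklevel=2
            )
            df = df.groupby(level=0, sort=False).mean()
        if df.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        df = df.astype(float)
        if df.isna().any().any():
            n = int(df.isna().any(axis=1).sum())
            warnings.warn(f"dropping {n} gene rows with missing values", stacklevel=2)
            df = df.dropna(axis=0)
            if df.empty:
                raise ValidationError("expression matrix empty after dropping NaNs")
        if (df.to_numpy() < 0).any():
            raise ValidationError(
                "negative expression value; input contract is log2(TPM+1) >= 0"
            )
        object.__setattr__(self, "data", df)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            df = df.loc[[g for g in genes if g in df.index]]
        if samples is not None:
            df = df.loc[:, [s for s in samples if s in df.columns]]
        return ExpressionMatrix(df)


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids) into an ExpressionMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets; ids unique within a set, sets non-empty."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: list[str] = []
            for g in genes:
                if g in seen:
                    warnings.warn(
                        f"gene set {name}: duplicated gene {g} deduplicated",
                        stacklevel=2,
                    )
                else:
                    seen.append(g)
            if not seen:
                raise ValidationError(f"gene set {name} is empty")
            clean[name] = seen
        object.__setattr__(self, "sets", clean)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, tab-separated gene ids)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        warnings.warn(f"{path.name}: empty GMT file", stacklevel=2)
        return GeneSetCollection({})
    for i, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path.name}: line {i} has fewer than 3 fields")
        name, _desc, *genes = fields
        sets[name] = [g for g in genes if g]
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

STAGES = ("I", "II", "III", "IV")

_META_COLUMNS = [
    "tumor_type",
    "stage",
    "is_tumor",
    "matched_normal_id",
    "purity_ihc",
    "msi_score",
    "tp53_mutant",
    "nonsilent_mutations",
]


@dataclass
class SampleMetadata:
    """Per-sample annotations: tumor type, stage, tumor/normal flag, links and scores.

    ``table`` is indexed by sample id. ``stage`` is one of I-IV or NaN;
    ``matched_normal_id`` (when present) must resolve to a sample with
    ``is_tumor == False``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        for col in _META_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[_META_COLUMNS]
        # samples without an explicit flag are assumed tumor
        df["is_tumor"] = df["is_tumor"].fillna(True).astype(bool)
        stages = df["stage"].dropna().astype(str)
        bad = sorted(set(stages) - set(STAGES))
        if bad:
            raise ValidationError(f"unknown stage labels {bad}")
        linked = df["matched_normal_id"].dropna()
        for sample, normal in linked.items():
            if normal not in df.index:
                raise ValidationError(
                    f"sample {sample}: matched normal {normal} not in metadata"
                )
            if df.loc[normal, "is_tumor"]:
                raise ValidationError(
                    f"sample {sample}: matched normal {normal} is flagged as tumor"
                )
        object.__setattr__(self, "table", df)

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def tumor_samples(self, tumor_type: str | None = None) -> list[str]:
        df = self.table
        mask = df["is_tumor"].to_numpy()
        if tumor_type is not None:
            mask = mask & (df["tumor_type"] == tumor_type).to_numpy()
        return df.index[mask].tolist()

    def normal_samples(self, tumor_type: str | None = None) -> list[str]:
        df = self.table
        mask = ~df["is_tumor"].to_numpy()
        if tumor_type is not None:
            mask = mask & (df["tumor_type"] == tumor_type).to_numpy()
        return df.index[mask].tolist()

    def tumor_types(self) -> list[str]:
        return sorted(self.table.loc[self.table["is_tumor"], "tumor_type"].unique())


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "is_tumor" in df.columns and df["is_tumor"].dtype == object:
        df["is_tumor"] = df["is_tumor"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Chromosome-arm boundary table
# ---------------------------------------------------------------------------

@dataclass
class ArmTable:
    """Per-chromosome p/q arm intervals (1-based inclusive base pairs).

    ``table`` is indexed by chromosome with columns p_start, p_end, q_start,
    q_end. All 23 scored chromosomes must be present and p_end < q_start.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        df.index = df.index.map(_normalize_chromosome)
        missing = sorted(set(CHROMOSOMES) - set(df.index))
        if missing:
            raise ValidationError(f"arm table missing chromosomes {missing}")
        df = df.loc[list(CHROMOSOMES)]
        for col in ("p_start", "p_end", "q_start", "q_end"):
            df[col] = df[col].astype(np.int64)
        if (df["p_end"] >= df["q_start"]).any():
            bad = df.index[df["p_end"] >= df["q_start"]].tolist()
            raise ValidationError(f"arm table: p/q overlap on chromosomes {bad}")
        if (df["p_start"] > df["p_end"]).any() or (df["q_start"] > df["q_end"]).any():
            raise ValidationError("arm table: inverted arm interval")
        object.__setattr__(self, "table", df)

    def arm_interval(self, chromosome: str, arm: str) -> tuple[int, int]:
        chromosome = _normalize_chromosome(chromosome)
        if chromosome not in self.table.index:
            raise KeyError(f"chromosome {chromosome} not in arm table")
        if arm not in ("p", "q"):
            raise KeyError(f"arm must be 'p' or 'q', got {arm!r}")
        row = self.table.loc[chromosome]
        return int(row[f"{arm}_start"]), int(row[f"{arm}_end"])


def read_arm_table(path) -> ArmTable:
    """Read a long-format arm table TSV: chromosome, arm, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "arm": str})
    for col in ("chromosome", "arm", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"arm table missing column '{col}'")
    wide = {}
    for _, row in df.iterrows():
        chrom = _normalize_chromosome(row["chromosome"])
        rec = wide.setdefault(chrom, {})
        rec[f"{row['arm']}_start"] = int(row["start"])
        rec[f"{row['arm']}_end"] = int(row["end"])
    table = pd.DataFrame.from_dict(wide, orient="index")
    return ArmTable(table)


def write_arm_table(arms: ArmTable, path) -> None:
    rows = []
    for chrom in arms.table.index:
        for arm in ("p", "q"):
            s, e = arms.arm_interval(chrom, arm)
            rows.append({"chromosome": chrom, "arm": arm, "start": s, "end": e})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
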