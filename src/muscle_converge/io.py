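"""Readers and writers for the tabular formats the pipeline touches.

Everything is tab-separated (gene descriptions may contain commas). Readers
validate and reject malformed input rather than repairing it; error messages
carry the offending file position. Group labels are fixed to the four-group
vocabulary {SDM, SDGM, SDF, SDGF} (sex M/F crossed with standard diet SD and
grape-supplemented diet SDG). Gene identifiers are opaque, case-sensitive
strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: The four experimental groups, in canonical column order.
GROUPS = ("SDM", "SDGM", "SDF", "SDGF")

SEXES = ("M", "F")
DIETS = ("SD", "SDG")

#: (sex, diet) -> group label.
GROUP_OF = {
    ("M", "SD"): "SDM",
    ("M", "SDG"): "SDGM",
    ("F", "SD"): "SDF",
    ("F", "SDG"): "SDGF",
}

#: The six unordered group pairs as canonical (B, A) contrasts, named B_vs_A.
CONTRASTS = (
    ("SDF", "SDM"),
    ("SDGF", "SDGM"),
    ("SDGM", "SDM"),
    ("SDGF", "SDF"),
    ("SDGM", "SDF"),
    ("SDGF", "SDM"),
)


def contrast_name(group_b: str, group_a: str) -> str:
    return f"{group_b}_vs_{group_a}"


def canonical_contrast(group_a: str, group_b: str) -> tuple[str, str]:
    """Return the canonical (B, A) orientation for an unordered group pair."""
    for b, a in CONTRASTS:
        if {a, b} == {group_a, group_b}:
            return (b, a)
    raise ValueError(f"unknown contrast: {group_a!r} vs {group_b!r}")


def _check_group_row(sample: str, sex: str, diet: str, group: str) -> None:
    if sex not in SEXES:
        raise FormatError(f"sample {sample!r}: unknown sex {sex!r} (expected M or F)")
    if diet not in DIETS:
        raise FormatError(f"sample {sample!r}: unknown diet {diet!r} (expected SD or SDG)")
    if group not in GROUPS:
        raise FormatError(f"sample {sample!r}: unknown group {group!r} (expected one of {GROUPS})")
    if GROUP_OF[(sex, diet)] != group:
        raise FormatError(
            f"sample {sample!r}: group {group!r} inconsistent with sex={sex!r}, diet={diet!r}"
        )


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    ``counts`` is a genes-by-samples DataFrame of integers; ``samples`` is a
    DataFrame indexed by sample id with columns ``sex``, ``diet``, ``group``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.isnan(vals.astype(float)).any():
            g, s = np.argwhere(np.isnan(vals.astype(float)))[0]
            raise FormatError(
                f"missing count at gene {self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
            )
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count {vals[g, s]} at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        frac = vals.astype(float) - np.floor(vals.astype(float))
        if (frac != 0).any():
            g, s = np.argwhere(frac != 0)[0]
            raise FormatError(
                f"non-integer count {vals[g, s]} at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise FormatError(f"samples absent from sample sheet: {missing}")
        self.samples = self.samples.loc[list(self.counts.columns)]
        for sample, row in self.samples.iterrows():
            _check_group_row(str(sample), row["sex"], row["diet"], row["group"])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        """Sample ids belonging to one of the four groups."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r} (expected one of {GROUPS})")
        return list(self.samples.index[self.samples["group"] == group])


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents): set id -> (description, members)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column gene id) plus its sample sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, dtype=str)
    num = pd.DataFrame(index=counts.index)
    for col in counts.columns:
        coerced = pd.to_numeric(counts[col], errors="coerce")
        bad = coerced.isna() & counts[col].notna()
        if bad.any():
            gene = counts.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{counts_path}: non-numeric count {counts.loc[gene, col]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        num[col] = coerced
    samples = read_sample_sheet(samples_path)
    return CountMatrix(counts=num, samples=samples)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "sex", "diet", "group"}
    if not required.issubset(sheet.columns):
        raise FormatError(f"{path}: sample sheet must have columns {sorted(required)}")
    if sheet["sample"].duplicated().any():
        dup = sheet["sample"][sheet["sample"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return sheet.set_index("sample")


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.samples.rename_axis("sample").to_csv(samples_path, sep="\t")


def read_annotation(path: str | Path) -> pd.Series:
    """Gene annotation TSV (gene_id, length_bp) -> Series of lengths."""
    tab = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length_bp"}.issubset(tab.columns):
        raise FormatError(f"{path}: annotation must have columns gene_id, length_bp")
    if tab["gene_id"].duplicated().any():
        dup = tab["gene_id"][tab["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    lengths = tab.set_index("gene_id")["length_bp"]
    if (lengths < 1).any():
        gene = lengths.index[(lengths < 1).to_numpy().argmax()]
        raise FormatError(f"{path}: transcript length < 1 bp for gene {gene!r}")
    return lengths.astype(float)


def write_annotation(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").rename_axis("gene_id").to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_id TAB description TAB member TAB member...

    Duplicate members within a line are stored once (with a logged warning);
    a line with fewer than three fields is a format error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; "
                    "expected set_id, description, and at least one member"
                )
            set_id, description = fields[0], fields[1]
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    logger.warning("%s:%d: duplicate member %r in set %r", path, lineno, m, set_id)
                    continue
                seen.add(m)
                members.append(m)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {set_id!r} has no members")
            sets[set_id] = GeneSet(set_id, description, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


def write_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV with >= 6 significant digits."""
    result.to_csv(path, sep="\t", float_format="%.6g", index=not isinstance(
        result.index, pd.RangeIndex))


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
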