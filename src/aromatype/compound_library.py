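"""GC-MS volatile compound library: loading, validation, and summaries.

The library is a table of identified volatiles, one row per compound, carrying
identity (name, retention index, formula, CAS), a chemical category, literature
odor descriptors, an odor threshold in water (μg/L), and per-aroma-type content
statistics (mean ± SD of the internal-standard semi-quantified content).

Sentinel conventions of the source tables are preserved on load:

* ``ND`` (not detected) becomes an exact-zero measurement with ``detected=False``;
* ``n.f.`` (no literature value found) becomes a missing odor threshold;
* ``——`` becomes an empty descriptor list.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

GROUPS = ("A", "B", "C")

CATEGORIES = (
    "Aldehydes",
    "Ketones",
    "Alcohols",
    "Esters",
    "Alkanes",
    "Alkenes",
    "Aromatics",
    "Heterocyclic",
)

#: Optional descriptor exclusions for :func:`descriptor_presence`. Empty by
#: default: in the packaged 74-compound table exactly 22 compounds carry no
#: descriptor ("——"), and counting every non-empty descriptor list — including
#: Decane's bare "Alkane" annotation — reproduces the published 52
#: flavor-characterized compounds. Callers can exclude bare class labels by
#: passing e.g. ``exclude={"Alkane"}``.
BARE_CLASS_DESCRIPTORS: frozenset[str] = frozenset()

#: Sentinels used by the source tables.
ND = "ND"
NOT_FOUND = "n.f."
NO_DESCRIPTOR = "——"

_MEAN_SD_RE = re.compile(r"^\s*([0-9.]+)\s*±\s*([0-9.]+)\s*$")


class LibraryValidationError(ValueError):
    """Raised when a compound table fails schema or invariant checks."""


@dataclass(frozen=True)
class GroupContent:
    """Per-aroma-type content summary for one compound."""

    mean: float
    sd: float
    detected: bool

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise LibraryValidationError(f"negative sd {self.sd}")
        if not self.detected and (self.mean != 0 or self.sd != 0):
            raise LibraryValidationError("not-detected content must be stored as 0")


@dataclass(frozen=True)
class CompoundRecord:
    """One identified GC-MS volatile."""

    name: str
    retention_index: float
    formula: str
    cas: str
    category: str
    odor_descriptors: tuple[str, ...]
    odor_threshold: float | None  # μg/L; None where the source prints "n.f."
    group_content: Mapping[str, GroupContent]

    def __post_init__(self) -> None:
        if self.retention_index <= 0:
            raise LibraryValidationError(
                f"{self.name}: retention index must be positive"
            )
        if self.category not in CATEGORIES:
            raise LibraryValidationError(
                f"{self.name}: unknown category {self.category!r}"
            )
        if self.odor_threshold is not None and self.odor_threshold <= 0:
            raise LibraryValidationError(f"{self.name}: non-positive odor threshold")


@dataclass(frozen=True)
class InternalStandard:
    """Internal standard spiked into every sample for semi-quantification."""

    name: str = "2-Methyl-3-heptanone"
    mass_ug: float = 0.816
    sample_mass_g: float = 2.0


@dataclass
class GcmsLibrary:
    """A validated collection of :class:`CompoundRecord`."""

    records: list[CompoundRecord]
    internal_standard: InternalStandard = field(default_factory=InternalStandard)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LibraryValidationError(f"duplicate compound names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def group_means(self, group: str) -> dict[str, float]:
        """Mean content of every compound in one aroma type (ND compounds -> 0)."""
        return {r.name: r.group_content[group].mean for r in self.records}

    def thresholds(self) -> dict[str, float | None]:
        return {r.name: r.odor_threshold for r in self.records}


@dataclass(frozen=True)
class CategoryDistribution:
    """Counts and one-decimal-truncated percentages per chemical category."""

    counts: Mapping[str, int]
    percents: Mapping[str, float]


def packaged_fixture(name: str) -> Path:
    """Path to a packaged data table (e.g. ``table3_gcms.tsv``)."""
    return Path(str(resources.files("aromatype.data").joinpath(name)))


def _parse_content(cell: str, *, row: str, column: str) -> GroupContent:
    cell = cell.strip()
    if cell == ND:
        return GroupContent(mean=0.0, sd=0.0, detected=False)
    m = _MEAN_SD_RE.match(cell)
    if m is None:
        raise LibraryValidationError(
            f"row {row!r}, column {column!r}: malformed mean±SD cell {cell!r}"
        )
    return GroupContent(mean=float(m.group(1)), sd=float(m.group(2)), detected=True)


def _parse_threshold(cell: str, *, row: str) -> float | None:
    cell = str(cell).strip()
    if cell == NOT_FOUND:
        return None
    try:
        return float(cell.replace(",", ""))
    except ValueError as exc:
        raise LibraryValidationError(
            f"row {row!r}, column 'odor_threshold': malformed value {cell!r}"
        ) from exc


def _parse_descriptors(cell: str) -> tuple[str, ...]:
    cell = str(cell).strip()
    if not cell or cell == NO_DESCRIPTOR:
        return ()
    return tuple(d.strip() for d in cell.split(",") if d.strip())


def load_gcms_table(path: str | Path) -> GcmsLibrary:
    """Load a GC-MS compound table in the packaged schema.

    The file is a UTF-8 TSV/CSV with columns ``name``, ``ri``, ``formula``,
    ``cas``, ``category``, ``odor_description``, ``odor_threshold`` and one
    ``content_<group>`` column per aroma type holding ``mean ± sd`` or ``ND``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"name", "ri", "category", "odor_description", "odor_threshold"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryValidationError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise LibraryValidationError("no records")

    content_cols = {
        c.removeprefix("content_").upper(): c
        for c in df.columns
        if c.startswith("content_")
    }
    if not content_cols:
        raise LibraryValidationError("no content_<group> columns")

    records = []
    for _, row in df.iterrows():
        name = row["name"].strip()
        try:
            ri = float(row["ri"])
        except ValueError as exc:
            raise LibraryValidationError(
                f"row {name!r}, column 'ri': malformed value {row['ri']!r}"
            ) from exc
        content = {
            g: _parse_content(row[col], row=name, column=col)
            for g, col in content_cols.items()
        }
        records.append(
            CompoundRecord(
                name=name,
                retention_index=ri,
                formula=row.get("formula", "").strip(),
                cas=row.get("cas", "").strip(),
                category=row["category"].strip(),
                odor_descriptors=_parse_descriptors(row["odor_description"]),
                odor_threshold=_parse_threshold(row["odor_threshold"], row=name),
                group_content=content,
            )
        )
    return GcmsLibrary(records=records)


def write_gcms_table(library: GcmsLibrary, path: str | Path) -> None:
    """Write a library back to the tabular schema read by :func:`load_gcms_table`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    rows = []
    for i, r in enumerate(library.records, start=1):
        row = {
            "no": i,
            "name": r.name,
            "ri": _fmt_number(r.retention_index),
            "formula": r.formula,
            "cas": r.cas,
            "category": r.category,
            "odor_description": ", ".join(r.odor_descriptors) or NO_DESCRIPTOR,
            "odor_threshold": (
                NOT_FOUND if r.odor_threshold is None else _fmt_number(r.odor_threshold)
            ),
        }
        for g, c in r.group_content.items():
            row[f"content_{g.lower()}"] = (
                ND if not c.detected else f"{c.mean:.2f} ± {c.sd:.2f}"
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def load_packaged_library() -> GcmsLibrary:
    """The 74-compound GC-MS table shipped with the package."""
    return load_gcms_table(packaged_fixture("table3_gcms.tsv"))


def truncate1(percent: float) -> float:
    """Truncate a percentage toward zero at one decimal (20.27 -> 20.2)."""
    return math.trunc(percent * 10) / 10


def category_distribution(library: GcmsLibrary) -> CategoryDistribution:
    """Category counts and truncated percentages across the library.

    Percentages are truncated (not rounded) toward zero at one decimal; integer
    arithmetic is used so 15/74 -> 20.2 exactly rather than 20.200000000000003.
    """
    if len(library) == 0:
        raise LibraryValidationError("empty library")
    counts = {c: 0 for c in CATEGORIES}
    for r in library:
        counts[r.category] += 1
    total = len(library)
    percents = {c: (1000 * n) // total / 10 for c, n in counts.items()}
    return CategoryDistribution(counts=counts, percents=percents)


def descriptor_presence(
    record: CompoundRecord, exclude: frozenset[str] | set[str] = BARE_CLASS_DESCRIPTORS
) -> bool:
    """Whether a compound has flavor characteristics.

    A compound counts as flavor-characterized when its descriptor list is
    non-empty, ignoring any descriptors in ``exclude`` (empty by default).
    """
    return bool(set(record.odor_descriptors) - set(exclude))


def flavor_characterized_fraction(library: GcmsLibrary) -> tuple[int, float]:
    """Count and percentage (2 decimals) of flavor-characterized compounds."""
    if len(library) == 0:
        raise LibraryValidationError("empty library")
    count = sum(descriptor_presence(r) for r in library)
    return count, round(100 * count / len(library), 2)


def load_sample_roster(path: str | Path | None = None) -> pd.DataFrame:
    """Sample codes, varieties, and aroma-type labels (packaged roster by default)."""
    if path is None:
        path = packaged_fixture("table1_samples.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"sample_code": str})
    if df["sample_code"].duplicated().any():
        raise LibraryValidationError("duplicate sample codes")
    return df


def load_descriptor_definitions(path: str | Path | None = None) -> pd.DataFrame:
    """The ten QDA aroma descriptors with definitions and reference standards."""
    if path is None:
        path = packaged_fixture("table2_descriptors.tsv")
    return pd.read_csv(path, sep="\t")


def load_differential_table(path: str | Path | None = None) -> pd.DataFrame:
    """The published differential-compound table (ANOVA p, Q, group contents).

    The printed p/Q values are reported pass-through; they are not recomputable
    from the summary statistics and are never recomputed here.
    """
    if path is None:
        path = packaged_fixture("table4_differential.tsv")
    return pd.read_csv(path, sep="\t")
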