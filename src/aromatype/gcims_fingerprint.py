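"""GC-IMS peak-table analysis: fingerprints, monomer/dimer pairs, differences.

GC-IMS separates volatiles by GC retention time and ion drift time
(RIP-normalized). Abundant or high-proton-affinity analytes produce several
signals — a protonated monomer and a proton-bound dimer — recorded in peak
tables with ``-M``/``-D`` name suffixes. This module starts from such peak
tables (what the vendor software exports): it parses the signal forms, builds
group x signal fingerprint matrices, computes signed difference matrices
against a reference, and counts signals per chemical class using a packaged
curated name → class map (the source table carries no class column).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

IMS_CLASSES = (
    "ketone",
    "alcohol",
    "ester",
    "aldehyde",
    "heterocyclic",
    "aromatic hydrocarbon",
    "other",
)


@dataclass(frozen=True)
class ImsPeakRecord:
    """One GC-IMS signal: identity, form, position, per-group peak volume."""

    base_name: str
    form: str  # monomer | dimer | unspecified
    retention_index: float
    retention_time: float  # s
    drift_time: float  # ms, RIP-normalized
    peak_volume: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.retention_time <= 0 or self.drift_time <= 0:
            raise ValueError(f"{self.signal}: times must be positive")
        if any(v < 0 for v in self.peak_volume.values()):
            raise ValueError(f"{self.signal}: negative peak volume")

    @property
    def signal(self) -> str:
        """Unique signal label: base name plus -M/-D suffix where applicable."""
        suffix = {"monomer": "-M", "dimer": "-D"}.get(self.form, "")
        return self.base_name + suffix


def parse_signal_name(name: str) -> tuple[str, str]:
    """Split a peak-table name into (base_name, form) via the -M/-D suffix."""
    if name.endswith("-M"):
        return name[:-2], "monomer"
    if name.endswith("-D"):
        return name[:-2], "dimer"
    return name, "unspecified"


def load_ims_table(path: str | Path | None = None) -> list[ImsPeakRecord]:
    """Load a GC-IMS peak table (packaged 55-signal fixture by default).

    Expected columns: ``name``, ``ri``, ``rt_s``, ``drift_time_ms`` and one
    ``volume_<group>`` column per sample group.
    """
    if path is None:
        path = Path(str(resources.files("aromatype.data").joinpath("table5_ims.tsv")))
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"name": str})
    volume_cols = {
        c.removeprefix("volume_").upper(): c
        for c in df.columns
        if c.startswith("volume_")
    }
    records = []
    for _, row in df.iterrows():
        base, form = parse_signal_name(row["name"].strip())
        try:
            records.append(
                ImsPeakRecord(
                    base_name=base,
                    form=form,
                    retention_index=float(row["ri"]),
                    retention_time=float(row["rt_s"]),
                    drift_time=float(row["drift_time_ms"]),
                    peak_volume={g: float(row[c]) for g, c in volume_cols.items()},
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {row['name']!r}: {exc}") from exc
    return records


def pair_monomer_dimer(
    records: Iterable[ImsPeakRecord],
) -> tuple[list[tuple[str, ImsPeakRecord, ImsPeakRecord]], list[ImsPeakRecord]]:
    """Pair monomer and dimer signals of the same compound.

    Returns (pairs, orphans): one (base_name, monomer, dimer) triple per
    compound with both forms, plus a list of -M/-D signals missing their
    partner. Duplicate (base_name, form) entries are an error.
    """
    by_form: dict[tuple[str, str], ImsPeakRecord] = {}
    for r in records:
        key = (r.base_name, r.form)
        if r.form != "unspecified" and key in by_form:
            raise ValueError(f"duplicate signal {r.signal}")
        by_form[key] = r
    bases = sorted({b for b, f in by_form if f in ("monomer", "dimer")})
    pairs, orphans = [], []
    for b in bases:
        m = by_form.get((b, "monomer"))
        d = by_form.get((b, "dimer"))
        if m and d:
            pairs.append((b, m, d))
        else:
            orphans.append(m or d)
    return pairs, orphans


def load_class_map(path: str | Path | None = None) -> dict[str, str]:
    """Curated base_name → chemical class map (packaged map by default)."""
    if path is None:
        path = Path(
            str(resources.files("aromatype.data").joinpath("ims_class_map.tsv"))
        )
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["base_name"], df["compound_class"]))


def ims_class_counts(
    records: Iterable[ImsPeakRecord], class_map: Mapping[str, str] | None = None
) -> dict[str, int]:
    """Signal counts per chemical class (monomers and dimers counted separately)."""
    class_map = class_map if class_map is not None else load_class_map()
    records = list(records)
    unmapped = sorted({r.base_name for r in records if r.base_name not in class_map})
    if unmapped:
        raise ValueError(f"compounds missing from the class map: {unmapped}")
    counts = {c: 0 for c in IMS_CLASSES}
    for r in records:
        counts.setdefault(class_map[r.base_name], 0)
        counts[class_map[r.base_name]] += 1
    return {c: n for c, n in counts.items() if n > 0}


def build_fingerprint(records: Sequence[ImsPeakRecord]) -> pd.DataFrame:
    """Groups x signals fingerprint matrix of peak volumes.

    Columns (signals) are ordered by retention time, then drift time, so the
    layout is stable under input shuffling.
    """
    if not records:
        raise ValueError("no records")
    ordered = sorted(records, key=lambda r: (r.retention_time, r.drift_time))
    labels = [r.signal for r in ordered]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate signal labels")
    groups = list(ordered[0].peak_volume)
    if any(list(r.peak_volume) != groups for r in ordered):
        raise ValueError("inconsistent group columns across records")
    data = {r.signal: [r.peak_volume[g] for g in groups] for r in ordered}
    out = pd.DataFrame(data, index=groups)
    out.index.name = "group"
    return out


def difference_matrix(
    fingerprint: pd.DataFrame, reference_row: str
) -> pd.DataFrame:
    """Signed differences of every row against a reference row.

    Positive cells mean the signal is stronger than in the reference (rendered
    red in the instrument software), negative weaker (blue); the reference row
    itself maps to zeros.
    """
    if reference_row not in fingerprint.index:
        raise ValueError(f"reference row {reference_row!r} not in fingerprint")
    return fingerprint - fingerprint.loc[reference_row]


def records_table(records: Sequence[ImsPeakRecord]) -> pd.DataFrame:
    """Flat signals table (signal, base_name, form, ri, rt, drift, volumes)."""
    rows = []
    for r in records:
        row = {
            "signal": r.signal,
            "base_name": r.base_name,
            "form": r.form,
            "ri": r.retention_index,
            "rt_s": r.retention_time,
            "drift_time_ms": r.drift_time,
        }
        row.update({f"volume_{g.lower()}": v for g, v in r.peak_volume.items()})
        rows.append(row)
    return pd.DataFrame(rows)
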