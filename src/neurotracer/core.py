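"""Data model, label-pattern parsing, and tabular I/O.

All interchange formats are plain CSV/TSV (UTF-8, header required, comma
default with tab auto-detection).  The central identity is the
:class:`LabelPattern` — a metabolite name plus the set of carbon positions
carrying a ``13C`` label — whose canonical string form (``"[4,5-13C]Glu"``)
is used in every file format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METABOLITE_CARBONS",
    "LabelPattern",
    "parse_pattern",
    "IsotopomerTable",
    "TotalPoolTable",
    "CalibrationTable",
    "PeakTable",
    "SummaryTable",
    "read_isotopomer_table",
    "read_total_pool_table",
    "read_calibration_table",
    "read_peak_table",
    "read_summary_table",
    "write_report",
    "read_report",
]

#: Carbon count per supported metabolite (1-based positions, C1 = carboxyl
#: or anomeric carbon by standard biochemical numbering).
METABOLITE_CARBONS: dict[str, int] = {
    "Glu": 5,
    "Gln": 5,
    "Asp": 4,
    "NAA": 6,
    "GABA": 4,
    "MI": 6,
    "Ala": 3,
    "Lac": 3,
    "Glc": 6,
}

_METABOLITE_LOOKUP = {name.lower(): name for name in METABOLITE_CARBONS}

# Accepts "[4-13C]Glu", "[1,2-13C]GABA", caret markup "[4-^13^C]Glu",
# hyphen-separated positions "[4-5-13C]Glu", and the aggregate class
# "[other-13C]Glu".
_PATTERN_RE = re.compile(
    r"\[\s*(?P<pos>other|\d+(?:\s*[,\-]\s*\d+)*)\s*-\s*"
    r"(?:\^?13\^?\s*C|¹³C)\s*\]\s*(?P<met>[A-Za-z]+)"
)


@dataclass(frozen=True, order=True)
class LabelPattern:
    """A metabolite plus the set of 13C-labeled carbon positions.

    ``positions`` is a sorted tuple of 1-based carbon indices.  An empty
    tuple denotes the aggregate "other" class used by the simulator for
    NMR-unobservable labeling patterns (three or more labels, or
    non-adjacent doubles outside the reported classes); ordinary patterns
    must be non-empty.
    """

    metabolite: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.metabolite not in METABOLITE_CARBONS:
            raise ValueError(f"unknown metabolite abbreviation: {self.metabolite!r}")
        pos = tuple(sorted(set(int(p) for p in self.positions)))
        object.__setattr__(self, "positions", pos)
        n = METABOLITE_CARBONS[self.metabolite]
        for p in pos:
            if not 1 <= p <= n:
                raise ValueError(
                    f"position {p} out of range for {self.metabolite} (1..{n})"
                )

    @classmethod
    def other(cls, metabolite: str) -> "LabelPattern":
        """The aggregate class for unobservable patterns of ``metabolite``."""
        return cls(metabolite, ())

    @property
    def is_other(self) -> bool:
        return not self.positions

    def __str__(self) -> str:
        pos = "other" if self.is_other else ",".join(str(p) for p in self.positions)
        return f"[{pos}-13C]{self.metabolite}"

    def bits(self) -> tuple[int, ...]:
        """Binary label vector, one bit per carbon."""
        n = METABOLITE_CARBONS[self.metabolite]
        return tuple(1 if i + 1 in self.positions else 0 for i in range(n))


def parse_pattern(text: str) -> LabelPattern:
    """Parse a pattern string like ``"[1,2-13C]GABA"`` into a LabelPattern.

    Accepts comma or hyphen position separators and optional caret markup
    around the 13; emits the canonical comma form on ``str()``.
    """
    m = _PATTERN_RE.fullmatch(text.strip())
    if m is None:
        raise ValueError(f"malformed pattern string: {text!r}")
    met_raw = m.group("met")
    met = _METABOLITE_LOOKUP.get(met_raw.lower())
    if met is None:
        raise ValueError(f"unknown metabolite abbreviation: {met_raw!r}")
    pos_text = m.group("pos")
    if pos_text == "other":
        return LabelPattern.other(met)
    positions = tuple(int(p) for p in re.split(r"[,\-]", pos_text))
    if not positions:
        raise ValueError(f"empty position list in {text!r}")
    return LabelPattern(met, positions)


def canonical_pattern(value: "LabelPattern | str") -> str:
    """Canonical string form of a pattern given either representation."""
    if isinstance(value, LabelPattern):
        return str(value)
    return str(parse_pattern(value))


# ---------------------------------------------------------------------------
# Tabular containers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV file with delimiter auto-detection."""
    return pd.read_csv(path, sep=None, engine="python")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


@dataclass
class IsotopomerTable:
    """Replicate-level 13C isotopomer concentrations (mM).

    Columns: ``group``, ``replicate``, ``pattern`` (canonical string),
    ``conc_mM``.  Keys ``(group, replicate, pattern)`` are unique and
    concentrations are finite and non-negative.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    COLUMNS = ("group", "replicate", "pattern", "conc_mM")

    def __post_init__(self) -> None:
        _require_columns(self.df, self.COLUMNS, "isotopomer table")
        df = self.df.loc[:, list(self.COLUMNS)].copy()
        df["pattern"] = df["pattern"].map(canonical_pattern)
        conc = pd.to_numeric(df["conc_mM"])
        if not np.isfinite(conc).all():
            raise ValueError("isotopomer table: non-finite concentration")
        if (conc < 0).any():
            raise ValueError("isotopomer table: negative concentration")
        df["conc_mM"] = conc.astype(float)
        dup = df.duplicated(subset=["group", "replicate", "pattern"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["group", "replicate", "pattern"]].tolist()
            raise ValueError(f"isotopomer table: duplicate key {tuple(key)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, "LabelPattern | str", float]],
        meta: dict | None = None,
    ) -> "IsotopomerTable":
        rows = [
            {"group": g, "replicate": r, "pattern": canonical_pattern(p), "conc_mM": c}
            for g, r, p, c in records
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)), meta or {})

    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique())

    def group_means(self) -> pd.DataFrame:
        """Mean concentration per (group, pattern), wide on nothing."""
        return (
            self.df.groupby(["group", "pattern"], sort=True)["conc_mM"]
            .mean()
            .reset_index()
        )

    def mean(self, group: str, pattern: "LabelPattern | str") -> float:
        pat = canonical_pattern(pattern)
        sel = self.df[(self.df["group"] == group) & (self.df["pattern"] == pat)]
        if sel.empty:
            raise KeyError(f"pattern {pat} absent for group {group!r}")
        return float(sel["conc_mM"].mean())

    def write(self, path: str | Path) -> None:
        write_report(self.df, path)


@dataclass
class TotalPoolTable:
    """Total (12C + 13C) metabolite concentrations per replicate, in mM."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    COLUMNS = ("group", "replicate", "metabolite", "total_mM")

    def __post_init__(self) -> None:
        _require_columns(self.df, self.COLUMNS, "total-pool table")
        df = self.df.loc[:, list(self.COLUMNS)].copy()
        unknown = set(df["metabolite"]) - set(METABOLITE_CARBONS)
        if unknown:
            raise ValueError(f"total-pool table: unknown metabolite(s) {sorted(unknown)}")
        total = pd.to_numeric(df["total_mM"])
        if not np.isfinite(total).all() or (total < 0).any():
            raise ValueError("total-pool table: totals must be finite and non-negative")
        df["total_mM"] = total.astype(float)
        if df.duplicated(subset=["group", "replicate", "metabolite"]).any():
            raise ValueError("total-pool table: duplicate (group, replicate, metabolite)")
        self.df = df.reset_index(drop=True)

    def write(self, path: str | Path) -> None:
        write_report(self.df, path)


@dataclass
class CalibrationTable:
    """Known 13C concentration vs observed peak area per (metabolite, carbon)."""

    df: pd.DataFrame

    COLUMNS = ("metabolite", "carbon", "conc_mM", "area")

    def __post_init__(self) -> None:
        _require_columns(self.df, self.COLUMNS, "calibration table")
        df = self.df.loc[:, list(self.COLUMNS)].copy()
        if (pd.to_numeric(df["area"]) < 0).any():
            raise ValueError("calibration table: negative peak area")
        for (met, carbon), sub in df.groupby(["metabolite", "carbon"]):
            if sub["conc_mM"].nunique() < 2:
                raise ValueError(
                    f"calibration table: need >= 2 distinct concentrations "
                    f"for ({met}, C{carbon})"
                )
        self.df = df.reset_index(drop=True)

    def pairs(self) -> set[tuple[str, int]]:
        return {(m, int(c)) for m, c in zip(self.df["metabolite"], self.df["carbon"])}

    def write(self, path: str | Path) -> None:
        write_report(self.df, path)


@dataclass
class PeakTable:
    """Integrated NMR peak areas with per-spectrum internal-standard areas.

    One spectrum corresponds to one (group, replicate) extract; every row of
    a spectrum shares a single internal-standard area (> 0).  ``multiplet``
    is ``singlet`` or ``doublet``; ``pattern`` records the isotopomer
    assignment the peak belongs to.
    """

    df: pd.DataFrame

    COLUMNS = (
        "spectrum",
        "group",
        "replicate",
        "metabolite",
        "carbon",
        "pattern",
        "multiplet",
        "area",
        "is_area",
    )

    def __post_init__(self) -> None:
        _require_columns(self.df, self.COLUMNS, "peak table")
        df = self.df.loc[:, list(self.COLUMNS)].copy()
        if (pd.to_numeric(df["is_area"]) <= 0).any():
            raise ValueError("peak table: internal-standard area must be > 0")
        bad = set(df["multiplet"]) - {"singlet", "doublet"}
        if bad:
            raise ValueError(f"peak table: unknown multiplet class(es) {sorted(bad)}")
        for spectrum, sub in df.groupby("spectrum"):
            if sub["is_area"].nunique() > 1:
                raise ValueError(
                    f"peak table: spectrum {spectrum!r} has multiple "
                    "internal-standard areas"
                )
        df["pattern"] = df["pattern"].map(canonical_pattern)
        self.df = df.reset_index(drop=True)

    def write(self, path: str | Path) -> None:
        write_report(self.df, path)


@dataclass
class SummaryTable:
    """Group-level summary concentrations: mean ± dispersion with n.

    ``dispersion_kind`` is stored verbatim (``sd``, ``sem``, or
    ``sd_or_sem`` when the source does not disambiguate) rather than being
    resolved at ingestion.
    """

    df: pd.DataFrame

    COLUMNS = ("group", "pattern", "mean_mM", "dispersion", "dispersion_kind", "n")

    def __post_init__(self) -> None:
        _require_columns(self.df, self.COLUMNS, "summary table")
        df = self.df.loc[:, list(self.COLUMNS)].copy()
        df["pattern"] = df["pattern"].map(canonical_pattern)
        if (pd.to_numeric(df["mean_mM"]) < 0).any():
            raise ValueError("summary table: negative mean concentration")
        if (pd.to_numeric(df["n"]) < 2).any():
            raise ValueError("summary table: n must be >= 2")
        self.df = df.reset_index(drop=True)

    def to_mean_isotopomer_table(self) -> IsotopomerTable:
        """Collapse to an IsotopomerTable with a single 'mean' replicate."""
        return IsotopomerTable.from_records(
            (row.group, "mean", row.pattern, row.mean_mM)
            for row in self.df.itertuples()
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_isotopomer_table(path: str | Path) -> IsotopomerTable:
    """Read and validate an isotopomer-concentration CSV/TSV file."""
    return IsotopomerTable(_read_table(path))


def read_total_pool_table(path: str | Path) -> TotalPoolTable:
    return TotalPoolTable(_read_table(path))


def read_calibration_table(path: str | Path) -> CalibrationTable:
    return CalibrationTable(_read_table(path))


def read_peak_table(path: str | Path) -> PeakTable:
    return PeakTable(_read_table(path))


def read_summary_table(path: str | Path) -> SummaryTable:
    return SummaryTable(_read_table(path))


def write_report(
    results: pd.DataFrame | Mapping[str, Sequence] | Iterable[Mapping],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a results table as CSV with deterministic column order.

    Floats are formatted at 6 significant digits so reports are stable and
    re-readable; an empty result set still yields a header-only file.
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
    if columns is not None:
        df = df.loc[:, list(columns)]
    df.to_csv(path, index=False, float_format="%.6g")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
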