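"""Peak-area quantification and fractional enrichment.

Peak areas are converted to 13C concentrations through per-carbon standard
curves (ordinary least squares of area versus known concentration) after
normalization by the spectrum's internal-standard area.  Fractional
enrichment expresses each isotopomer concentration as a percentage of the
metabolite's total (12C + 13C) pool measured by HPLC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CalibrationTable,
    IsotopomerTable,
    PeakTable,
    TotalPoolTable,
    parse_pattern,
)

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "areas_to_concentrations",
    "fractional_enrichment",
]

logger = logging.getLogger(__name__)

#: Metabolites with HPLC totals available for enrichment.
ENRICHMENT_METABOLITES = ("Glu", "Gln", "GABA", "Asp")

#: Natural abundance of 13C, used by the optional background correction.
NATURAL_ABUNDANCE_13C = 0.011


@dataclass(frozen=True)
class StandardCurve:
    """Fitted line of peak area versus known 13C concentration."""

    metabolite: str
    carbon: int
    slope: float  # area units per mM
    intercept: float  # area units
    r_squared: float

    def invert(self, area: float) -> float:
        """Concentration (mM) for a normalized area; may be negative."""
        return (area - self.intercept) / self.slope


def fit_standard_curve(
    calibration: CalibrationTable,
) -> dict[tuple[str, int], StandardCurve]:
    """Fit one OLS line per (metabolite, carbon) in the calibration table."""
    curves: dict[tuple[str, int], StandardCurve] = {}
    for (met, carbon), sub in calibration.df.groupby(["metabolite", "carbon"]):
        x = sub["conc_mM"].to_numpy(dtype=float)
        y = sub["area"].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(
                f"cannot fit standard curve for ({met}, C{carbon}): "
                "need >= 2 distinct concentrations"
            )
        fit = stats.linregress(x, y)
        if fit.slope <= 0:
            raise ValueError(
                f"standard curve for ({met}, C{carbon}) has non-positive slope"
            )
        curves[(met, int(carbon))] = StandardCurve(
            metabolite=met,
            carbon=int(carbon),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue) ** 2,
        )
    return curves


def areas_to_concentrations(
    peaks: PeakTable,
    curves: dict[tuple[str, int], StandardCurve],
    reference_is_area: float,
) -> IsotopomerTable:
    """Convert peak areas to isotopomer concentrations (mM).

    Each area is rescaled by ``reference_is_area / spectrum_is_area`` (the
    internal-standard normalization) and inverted through its carbon's
    standard curve.  A pattern's concentration is the mean over its labeled
    carbons.  Negative inverted concentrations are floored at zero and
    counted in the returned table's ``meta['n_floored']``.
    """
    if reference_is_area <= 0:
        raise ValueError("reference internal-standard area must be > 0")
    n_floored = 0
    records: list[tuple[str, str, str, float]] = []
    grouped = peaks.df.groupby(["group", "replicate", "pattern"], sort=True)
    for (group, replicate, pattern), sub in grouped:
        concs = []
        for row in sub.itertuples():
            key = (row.metabolite, int(row.carbon))
            if key not in curves:
                raise KeyError(f"no standard curve for {key[0]} C{key[1]}")
            scaled = row.area * (reference_is_area / row.is_area)
            conc = curves[key].invert(scaled)
            if conc < 0:
                n_floored += 1
                conc = 0.0
            concs.append(conc)
        records.append((group, replicate, pattern, float(np.mean(concs))))
    table = IsotopomerTable.from_records(records)
    table.meta["n_floored"] = n_floored
    return table


def fractional_enrichment(
    iso: IsotopomerTable,
    totals: TotalPoolTable,
    nat_abundance_correction: bool = False,
) -> pd.DataFrame:
    """Percent 13C enrichment of each isotopomer against its total pool.

    Joins at replicate level when the isotopomer and total tables share
    replicate ids; otherwise falls back to group-mean totals (logged).
    Metabolites without totals (everything outside Glu/Gln/GABA/Asp) are
    skipped with a warning.  Values are clipped to [0, 100] with a
    ``clipped`` audit flag.  The optional natural-abundance correction
    subtracts 1.1% of the total pool per labeled carbon before dividing.

    Returns a DataFrame with columns ``group, replicate, pattern,
    enrichment_pct, clipped``.
    """
    iso_df = iso.df.copy()
    iso_df["metabolite"] = [parse_pattern(p).metabolite for p in iso_df["pattern"]]
    with_totals = iso_df[iso_df["metabolite"].isin(ENRICHMENT_METABOLITES)]
    skipped = sorted(set(iso_df["metabolite"]) - set(ENRICHMENT_METABOLITES))
    if skipped:
        logger.warning("no totals for %s; skipped in enrichment", skipped)

    tot = totals.df
    if (tot["total_mM"] <= 0).any():
        raise ValueError("total concentrations must be > 0 for enrichment")

    iso_keys = set(zip(with_totals["group"], with_totals["replicate"]))
    tot_keys = set(zip(tot["group"], tot["replicate"]))
    if iso_keys <= tot_keys:
        merged = with_totals.merge(tot, on=["group", "replicate", "metabolite"])
    else:
        logger.info("replicate ids do not align; using group-mean totals")
        group_means = (
            tot.groupby(["group", "metabolite"], sort=True)["total_mM"]
            .mean()
            .reset_index()
        )
        merged = with_totals.merge(group_means, on=["group", "metabolite"])
    missing = set(with_totals["metabolite"]) - set(merged["metabolite"])
    if missing:
        raise ValueError(f"missing totals for metabolite(s) {sorted(missing)}")

    conc = merged["conc_mM"].to_numpy(dtype=float)
    if nat_abundance_correction:
        n_labels = np.array(
            [len(parse_pattern(p).positions) for p in merged["pattern"]]
        )
        conc = conc - n_labels * NATURAL_ABUNDANCE_13C * merged["total_mM"].to_numpy()
    raw = 100.0 * conc / merged["total_mM"].to_numpy(dtype=float)
    clipped = (raw < 0.0) | (raw > 100.0)
    return pd.DataFrame(
        {
            "group": merged["group"],
            "replicate": merged["replicate"],
            "pattern": merged["pattern"],
            "enrichment_pct": np.clip(raw, 0.0, 100.0),
            "clipped": clipped,
        }
    )
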