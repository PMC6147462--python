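"""Bundled reference dataset.

Group-level (mean ± dispersion) brain isotopomer concentrations measured by
13C NMR after a 150-min dual-tracer infusion ([1-13C]glucose plus
[1,2-13C]acetate) in control (``CTL``) and hypermetabolic-knockout (``KO``)
mice, n = 4 per group, together with HPLC total-pool (12C + 13C)
concentrations for Glu, Gln, Asp, and GABA.

The source prints the dispersion column ambiguously (labelled SEM in one
place and SD in another), so it is carried with ``dispersion_kind``
``"sd_or_sem"``; callers that need an SD must choose an interpretation
explicitly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import IsotopomerTable, SummaryTable, TotalPoolTable

__all__ = [
    "CONTROL_GROUP",
    "KNOCKOUT_GROUP",
    "N_PER_GROUP",
    "DISPERSION_KIND",
    "load_reference_summary",
    "load_reference_totals",
    "reference_summary_table",
    "reference_isotopomer_table",
    "reference_total_pool_table",
]

CONTROL_GROUP = "CTL"
KNOCKOUT_GROUP = "KO"
N_PER_GROUP = 4
DISPERSION_KIND = "sd_or_sem"


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("neurotracer.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_summary() -> pd.DataFrame:
    """Wide reference table: one row per isotopomer pattern.

    Columns: ``pattern``, ``ctl_mean_mM``, ``ctl_disp``, ``ko_mean_mM``,
    ``ko_disp``, ``p_reported``, ``pct_change_reported``.
    """
    return _load_csv("isotopomer_reference.csv")


def load_reference_totals() -> pd.DataFrame:
    """Wide total-pool reference: metabolite, per-group mean ± SD, p."""
    return _load_csv("totals_reference.csv")


def reference_summary_table() -> SummaryTable:
    """Reference concentrations as a long-format SummaryTable."""
    wide = load_reference_summary()
    rows = []
    for row in wide.itertuples():
        rows.append(
            {
                "group": CONTROL_GROUP,
                "pattern": row.pattern,
                "mean_mM": row.ctl_mean_mM,
                "dispersion": row.ctl_disp,
                "dispersion_kind": DISPERSION_KIND,
                "n": N_PER_GROUP,
            }
        )
        rows.append(
            {
                "group": KNOCKOUT_GROUP,
                "pattern": row.pattern,
                "mean_mM": row.ko_mean_mM,
                "dispersion": row.ko_disp,
                "dispersion_kind": DISPERSION_KIND,
                "n": N_PER_GROUP,
            }
        )
    return SummaryTable(pd.DataFrame(rows))


def reference_isotopomer_table() -> IsotopomerTable:
    """Reference group means as an IsotopomerTable (replicate id 'mean')."""
    return reference_summary_table().to_mean_isotopomer_table()


def reference_total_pool_table() -> TotalPoolTable:
    """Reference totals as a TotalPoolTable (replicate id 'mean')."""
    wide = load_reference_totals()
    rows = []
    for row in wide.itertuples():
        rows.append(
            {
                "group": CONTROL_GROUP,
                "replicate": "mean",
                "metabolite": row.metabolite,
                "total_mM": row.ctl_mean_mM,
            }
        )
        rows.append(
            {
                "group": KNOCKOUT_GROUP,
                "replicate": "mean",
                "metabolite": row.metabolite,
                "total_mM": row.ko_mean_mM,
            }
        )
    return TotalPoolTable(pd.DataFrame(rows))
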