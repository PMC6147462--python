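"""Metabolic ratios, group comparisons, and small scalar assays.

The four printed ratio formulas:

* glucose cycling ratio: ``([3-13C]X - [1,2-13C]X) / [4-13C]Glu`` for
  X in {Glu, Gln} — the denominator is the glutamate C4 pool as printed;
  ``matched_denominator=True`` switches the Gln variant to ``[4-13C]Gln``;
* acetate cycling ratio: ``[1,2-13C]X / [4,5-13C]X``;
* acetate-versus-glucose index: ``[4,5-13C]X / [4-13C]X`` for Glu/Gln and
  ``[1,2-13C]GABA / [2-13C]GABA``;
* glycolytic index: between-group percent change of ``[3-13C]Ala``.

Ratios are computed on group mean concentrations.  Group comparisons report
per-pattern percent change and a two-tailed two-sample t-test (Student
pooled-variance by default, Welch behind a flag), from either raw replicate
values or summary statistics (mean, SD, n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import IsotopomerTable, LabelPattern, parse_pattern

__all__ = [
    "TTestResult",
    "glucose_cycling_ratio",
    "acetate_cycling_ratio",
    "acetate_vs_glucose_index",
    "glycolytic_index",
    "percent_change",
    "two_tailed_t",
    "two_tailed_t_from_summary",
    "benjamini_hochberg",
    "compare_groups",
    "compare_groups_from_summary",
    "ratio_report",
    "suv",
    "pakt_ratio",
]


def _group_mean(iso: IsotopomerTable, group: str, pattern: str) -> float:
    try:
        return iso.mean(group, pattern)
    except KeyError as exc:
        raise KeyError(f"required pattern missing: {exc}") from exc


def glucose_cycling_ratio(
    iso: IsotopomerTable,
    group: str,
    target: str = "Glu",
    matched_denominator: bool = False,
) -> float:
    """Cycling ratio for glucose-derived label (later-turn vs first-turn).

    ``([3-13C]target - [1,2-13C]target) / [4-13C]Glu``; with
    ``matched_denominator`` the Gln variant divides by ``[4-13C]Gln``.
    Missing later-turn patterns count as zero (a one-turn system has no C3
    or C1,C2 label by construction); the denominator pattern must exist.
    """
    if target not in ("Glu", "Gln"):
        raise ValueError("target must be 'Glu' or 'Gln'")
    denom_met = target if matched_denominator else "Glu"
    denom = _group_mean(iso, group, f"[4-13C]{denom_met}")
    if denom <= 0:
        raise ZeroDivisionError(f"[4-13C]{denom_met} denominator is zero for {group!r}")

    def mean_or_zero(pattern: str) -> float:
        try:
            return iso.mean(group, pattern)
        except KeyError:
            return 0.0

    c3 = mean_or_zero(f"[3-13C]{target}")
    c12 = mean_or_zero(f"[1,2-13C]{target}")
    return (c3 - c12) / denom


def acetate_cycling_ratio(iso: IsotopomerTable, group: str, target: str = "Glu") -> float:
    """``[1,2-13C]target / [4,5-13C]target`` for target in {Glu, Gln}."""
    if target not in ("Glu", "Gln"):
        raise ValueError("target must be 'Glu' or 'Gln'")
    denom = _group_mean(iso, group, f"[4,5-13C]{target}")
    if denom <= 0:
        raise ZeroDivisionError(f"[4,5-13C]{target} denominator is zero for {group!r}")
    try:
        num = iso.mean(group, f"[1,2-13C]{target}")
    except KeyError:
        num = 0.0
    return num / denom


def acetate_vs_glucose_index(
    iso: IsotopomerTable, group: str, target: str = "Glu"
) -> float:
    """Relative astrocytic-vs-neuronal contribution to a transmitter pool.

    ``[4,5-13C]X / [4-13C]X`` for Glu/Gln; ``[1,2-13C]GABA / [2-13C]GABA``.
    """
    if target in ("Glu", "Gln"):
        num_pat, den_pat = f"[4,5-13C]{target}", f"[4-13C]{target}"
    elif target == "GABA":
        num_pat, den_pat = "[1,2-13C]GABA", "[2-13C]GABA"
    else:
        raise ValueError("target must be 'Glu', 'Gln', or 'GABA'")
    denom = _group_mean(iso, group, den_pat)
    if denom <= 0:
        raise ZeroDivisionError(f"{den_pat} denominator is zero for {group!r}")
    try:
        num = iso.mean(group, num_pat)
    except KeyError:
        num = 0.0
    return num / denom


def glycolytic_index(iso: IsotopomerTable, control: str, treated: str) -> float:
    """Between-group percent change in [3-13C]alanine."""
    ctl = _group_mean(iso, control, "[3-13C]Ala")
    ko = _group_mean(iso, treated, "[3-13C]Ala")
    return percent_change(ctl, ko)


def percent_change(control_mean: float, treated_mean: float) -> float:
    """``100 * (treated - control) / control``."""
    if control_mean == 0:
        raise ZeroDivisionError("percent change undefined for zero control mean")
    return 100.0 * (treated_mean - control_mean) / control_mean


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    flavor: str
    degenerate: bool = False  # both SDs zero with equal means


def two_tailed_t(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    flavor: str = "student",
) -> TTestResult:
    """Two-sample two-tailed t-test on raw values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    return two_tailed_t_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, flavor
    )


def two_tailed_t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    flavor: str = "student",
) -> TTestResult:
    """Two-sample t-test from summary statistics (mean, SD, n).

    Provided because published tables often store only mean ± dispersion.
    When both SDs are zero and the means are equal, p = 1 by convention and
    the result is flagged degenerate.
    """
    if flavor not in ("student", "welch"):
        raise ValueError("flavor must be 'student' or 'welch'")
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return TTestResult(0.0, 1.0, n_a + n_b - 2, flavor, degenerate=True)
        return TTestResult(np.inf, 0.0, n_a + n_b - 2, flavor, degenerate=True)
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(flavor == "student")
    )
    if flavor == "student":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TTestResult(float(res.statistic), float(res.pvalue), float(df), flavor)


def benjamini_hochberg(p_values: np.ndarray | list[float]) -> np.ndarray:
    """BH-adjusted p values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


_COMPARISON_COLUMNS = [
    "pattern",
    "control_mean",
    "control_sd",
    "control_n",
    "treated_mean",
    "treated_sd",
    "treated_n",
    "pct_change",
    "t",
    "p",
    "sig_05",
    "sig_01",
]


def compare_groups(
    iso: IsotopomerTable,
    control: str,
    treated: str,
    flavor: str = "student",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-pattern comparison of two groups from replicate-level data.

    Returns one row per pattern present in both groups: group means and
    SDs, percent change, t statistic, p value, and significance flags at
    0.05 and 0.01.  No multiple-testing correction by default; BH-adjusted
    p values are added as ``p_adj`` when requested.
    """
    rows = []
    df = iso.df
    patterns = sorted(
        set(df.loc[df["group"] == control, "pattern"])
        & set(df.loc[df["group"] == treated, "pattern"]),
        key=lambda s: (parse_pattern(s).metabolite, parse_pattern(s).positions),
    )
    for pattern in patterns:
        a = df[(df["group"] == control) & (df["pattern"] == pattern)]["conc_mM"]
        b = df[(df["group"] == treated) & (df["pattern"] == pattern)]["conc_mM"]
        if a.size >= 2 and b.size >= 2:
            test = two_tailed_t(a, b, flavor=flavor)
        else:
            # mean-only input (e.g. a published summary): no test possible
            test = TTestResult(np.nan, np.nan, np.nan, flavor, degenerate=True)
        rows.append(
            {
                "pattern": pattern,
                "control_mean": a.mean(),
                "control_sd": a.std(ddof=1),
                "control_n": a.size,
                "treated_mean": b.mean(),
                "treated_sd": b.std(ddof=1),
                "treated_n": b.size,
                "pct_change": percent_change(a.mean(), b.mean())
                if a.mean() != 0
                else np.nan,
                "t": test.t,
                "p": test.p,
                "sig_05": test.p <= 0.05,
                "sig_01": test.p <= 0.01,
            }
        )
    out = pd.DataFrame(rows, columns=_COMPARISON_COLUMNS)
    if bh_correction and not out.empty:
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def compare_groups_from_summary(
    summary: pd.DataFrame,
    dispersion_is: str = "sd",
    flavor: str = "student",
    n: int | None = None,
) -> pd.DataFrame:
    """Group comparison from a wide summary table.

    Expects columns ``pattern, ctl_mean_mM, ctl_disp, ko_mean_mM, ko_disp``
    plus either an ``n`` column or the ``n`` argument.  ``dispersion_is``
    declares how to read the dispersion column (``"sd"`` or ``"sem"``); SEM
    values are converted to SD via ``sd = sem * sqrt(n)``.
    """
    if dispersion_is not in ("sd", "sem"):
        raise ValueError("dispersion_is must be 'sd' or 'sem'")
    rows = []
    for row in summary.itertuples():
        n_row = int(getattr(row, "n", n if n is not None else 0))
        if n_row < 2:
            raise ValueError("n must be >= 2 (pass n= or include an n column)")
        scale = np.sqrt(n_row) if dispersion_is == "sem" else 1.0
        sd_a, sd_b = row.ctl_disp * scale, row.ko_disp * scale
        test = two_tailed_t_from_summary(
            row.ctl_mean_mM, sd_a, n_row, row.ko_mean_mM, sd_b, n_row, flavor
        )
        rows.append(
            {
                "pattern": str(parse_pattern(row.pattern)),
                "control_mean": row.ctl_mean_mM,
                "control_sd": sd_a,
                "control_n": n_row,
                "treated_mean": row.ko_mean_mM,
                "treated_sd": sd_b,
                "treated_n": n_row,
                "pct_change": percent_change(row.ctl_mean_mM, row.ko_mean_mM),
                "t": test.t,
                "p": test.p,
                "sig_05": test.p <= 0.05,
                "sig_01": test.p <= 0.01,
            }
        )
    return pd.DataFrame(rows, columns=_COMPARISON_COLUMNS)


def ratio_report(
    iso: IsotopomerTable,
    control: str,
    treated: str,
    matched_denominator: bool = False,
) -> pd.DataFrame:
    """All ratio metrics for both groups plus the glycolytic index.

    Per-group ratios get one row per group; the glycolytic index (a
    between-group scalar) is reported once with group ``<between>``.
    Metrics whose patterns are absent from the table are skipped.
    """
    rows = []
    for group in (control, treated):
        metric_fns = {
            "glucose_cycling_Glu": lambda g=group: glucose_cycling_ratio(
                iso, g, "Glu", matched_denominator
            ),
            "glucose_cycling_Gln": lambda g=group: glucose_cycling_ratio(
                iso, g, "Gln", matched_denominator
            ),
            "acetate_cycling_Glu": lambda g=group: acetate_cycling_ratio(iso, g, "Glu"),
            "acetate_cycling_Gln": lambda g=group: acetate_cycling_ratio(iso, g, "Gln"),
            "acetate_vs_glucose_Glu": lambda g=group: acetate_vs_glucose_index(
                iso, g, "Glu"
            ),
            "acetate_vs_glucose_Gln": lambda g=group: acetate_vs_glucose_index(
                iso, g, "Gln"
            ),
            "acetate_vs_glucose_GABA": lambda g=group: acetate_vs_glucose_index(
                iso, g, "GABA"
            ),
        }
        for metric, fn in metric_fns.items():
            try:
                rows.append({"group": group, "metric": metric, "value": fn()})
            except (KeyError, ZeroDivisionError):
                continue
    try:
        rows.append(
            {
                "group": "<between>",
                "metric": "glycolytic_index_pct",
                "value": glycolytic_index(iso, control, treated),
            }
        )
    except (KeyError, ZeroDivisionError):
        pass
    return pd.DataFrame(rows, columns=["group", "metric", "value"])


def suv(
    tissue_activity_conc: float, injected_activity: float, body_weight: float
) -> float:
    """Standardized uptake value: tissue activity concentration divided by
    injected activity per unit body weight."""
    for name, v in (
        ("tissue activity concentration", tissue_activity_conc),
        ("injected activity", injected_activity),
        ("body weight", body_weight),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return tissue_activity_conc / (injected_activity / body_weight)


def pakt_ratio(phospho_signal: float, total_signal: float) -> float:
    """Phospho/total AKT signal ratio."""
    if total_signal <= 0:
        raise ValueError("total signal must be > 0")
    return phospho_signal / total_signal
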