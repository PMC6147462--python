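"""fEPSP slope extraction, I/O curves, and theta-burst LTP quantification.

An :class:`LTPRecording` holds per-sweep fEPSP slopes (one sweep every 20 s
by default) around a theta-burst stimulation (TBS) marker.  LTP is the mean
of the final post-TBS window of slopes normalized to the pre-TBS baseline
mean, expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import TTestResult, two_tailed_t

__all__ = [
    "LTPRecording",
    "IOCurve",
    "DEFAULT_INTENSITY_GRID",
    "fepsp_slope",
    "io_curve",
    "normalize_ltp",
    "ltp_value",
    "ltp_group_test",
    "simulate_recording",
    "sigmoid_trace",
]

#: Stimulus grid used for I/O curves (μA).
DEFAULT_INTENSITY_GRID = (100, 150, 200, 250, 300, 350)

#: TBS protocol recorded as metadata: ten trains of five 100 Hz pulses at 5 Hz.
TBS_PROTOCOL = {"trains": 10, "pulses_per_train": 5, "pulse_hz": 100, "train_hz": 5}


@dataclass
class LTPRecording:
    """Per-sweep fEPSP slopes around a TBS marker.

    ``sweep_times_s`` are seconds from recording start, strictly increasing;
    the baseline window is the ``baseline_window_min`` minutes immediately
    before ``tbs_time_s``.
    """

    sweep_times_s: np.ndarray
    slopes_mV_per_ms: np.ndarray
    tbs_time_s: float
    baseline_window_min: float = 10.0
    intensity_uA: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweep_times_s = np.asarray(self.sweep_times_s, dtype=float)
        self.slopes_mV_per_ms = np.asarray(self.slopes_mV_per_ms, dtype=float)
        if self.sweep_times_s.shape != self.slopes_mV_per_ms.shape:
            raise ValueError("sweep times and slopes must have matching shapes")
        if np.any(np.diff(self.sweep_times_s) <= 0):
            raise ValueError("sweeps must be strictly time-ordered")
        if not self._baseline_mask().any():
            raise ValueError("need >= 1 sweep in the pre-TBS baseline window")

    def _baseline_mask(self) -> np.ndarray:
        start = self.tbs_time_s - self.baseline_window_min * 60.0
        return (self.sweep_times_s >= start) & (self.sweep_times_s < self.tbs_time_s)

    def baseline_mean(self) -> float:
        return float(self.slopes_mV_per_ms[self._baseline_mask()].mean())

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, tbs_time_s: float, baseline_window_min: float = 10.0
    ) -> "LTPRecording":
        """Build from a table with columns ``sweep_time_s, slope_mV_per_ms``
        and optionally ``intensity_uA``."""
        intensity = (
            df["intensity_uA"].to_numpy(dtype=float)
            if "intensity_uA" in df.columns
            else None
        )
        return cls(
            df["sweep_time_s"].to_numpy(dtype=float),
            df["slope_mV_per_ms"].to_numpy(dtype=float),
            tbs_time_s,
            baseline_window_min,
            intensity,
        )


@dataclass
class IOCurve:
    """Input/output relation: mean fEPSP slope per stimulus intensity."""

    intensities_uA: np.ndarray
    mean_slopes: np.ndarray
    per_intensity_values: dict[float, np.ndarray]
    fitted_slope: float  # (mV/ms) per μA, least squares through the means

    def __post_init__(self) -> None:
        if np.any(np.diff(self.intensities_uA) <= 0):
            raise ValueError("intensities must be strictly increasing")


def fepsp_slope(
    time_ms: np.ndarray, voltage_mV: np.ndarray, cursor_separation_ms: float = 1.0
) -> float:
    """Slope of the ascending phase of an fEPSP trace, in mV/ms.

    Operationalizes the two-cursor rule: find the response onset (first
    crossing of 10% of peak), take the longest strictly increasing run
    between onset and peak, and center two cursors ``cursor_separation_ms``
    apart on it; the slope is their voltage difference over the separation.
    """
    t = np.asarray(time_ms, dtype=float)
    v = np.asarray(voltage_mV, dtype=float)
    if t.size < 2 or t[-1] - t[0] < cursor_separation_ms:
        raise ValueError("trace shorter than the cursor separation")
    peak_idx = int(np.argmax(v))
    peak = v[peak_idx]
    if peak <= v[0] or np.all(np.diff(v) <= 0):
        raise ValueError("no detectable ascending phase")
    onset_candidates = np.nonzero(v[: peak_idx + 1] >= 0.1 * peak)[0]
    onset_idx = int(onset_candidates[0]) if onset_candidates.size else 0

    # longest strictly increasing run within [onset, peak]
    best_start, best_end = onset_idx, onset_idx
    run_start = onset_idx
    for i in range(onset_idx + 1, peak_idx + 1):
        if v[i] > v[i - 1]:
            if i - run_start > best_end - best_start:
                best_start, best_end = run_start, i
        else:
            run_start = i
    if t[best_end] - t[best_start] < cursor_separation_ms:
        raise ValueError("ascending phase shorter than the cursor separation")

    mid = 0.5 * (t[best_start] + t[best_end])
    t1 = mid - cursor_separation_ms / 2.0
    t2 = mid + cursor_separation_ms / 2.0
    v1 = float(np.interp(t1, t, v))
    v2 = float(np.interp(t2, t, v))
    return (v2 - v1) / cursor_separation_ms


def io_curve(
    responses: pd.DataFrame,
    intensity_grid: tuple[float, ...] = DEFAULT_INTENSITY_GRID,
) -> IOCurve:
    """I/O curve from a table with columns ``intensity_uA, slope_mV_per_ms``.

    Only intensities on the grid that actually have responses are used; at
    least two are required.  The overall I/O slope is the least-squares
    line through the per-intensity means.
    """
    present = [
        i for i in intensity_grid if (responses["intensity_uA"] == i).any()
    ]
    if len(present) < 2:
        raise ValueError("need responses at >= 2 grid intensities")
    means = []
    per_intensity = {}
    for i in present:
        vals = responses.loc[
            responses["intensity_uA"] == i, "slope_mV_per_ms"
        ].to_numpy(dtype=float)
        per_intensity[float(i)] = vals
        means.append(vals.mean())
    intensities = np.asarray(present, dtype=float)
    means = np.asarray(means)
    fit = stats.linregress(intensities, means)
    return IOCurve(intensities, means, per_intensity, float(fit.slope))


def normalize_ltp(recording: LTPRecording) -> pd.DataFrame:
    """Express every sweep as percent of the pre-TBS baseline mean."""
    base = recording.baseline_mean()
    if base == 0:
        raise ZeroDivisionError("baseline mean slope is zero")
    return pd.DataFrame(
        {
            "sweep_time_s": recording.sweep_times_s,
            "pct_of_baseline": 100.0 * recording.slopes_mV_per_ms / base,
            "post_tbs": recording.sweep_times_s >= recording.tbs_time_s,
        }
    )


def ltp_value(recording: LTPRecording, final_window_min: float = 5.0) -> float:
    """LTP magnitude: mean percent-of-baseline over the final post-TBS window."""
    post_extent_s = recording.sweep_times_s[-1] - recording.tbs_time_s
    if post_extent_s < final_window_min * 60.0:
        raise ValueError(
            f"post-TBS duration {post_extent_s / 60.0:.1f} min shorter than "
            f"the {final_window_min:g}-min final window"
        )
    norm = normalize_ltp(recording)
    cutoff = recording.sweep_times_s[-1] - final_window_min * 60.0
    window = norm[(norm["sweep_time_s"] > cutoff) & norm["post_tbs"]]
    return float(window["pct_of_baseline"].mean())


def ltp_group_test(
    group_a_values: list[float], group_b_values: list[float], flavor: str = "student"
) -> TTestResult:
    """Between-group two-tailed t-test on per-slice LTP values."""
    return two_tailed_t(group_a_values, group_b_values, flavor=flavor)


def simulate_recording(
    baseline_slope: float = 0.5,
    potentiation_factor: float = 1.5,
    noise_sd_fraction: float = 0.0,
    baseline_min: float = 10.0,
    post_min: float = 30.0,
    sweep_interval_s: float = 20.0,
    decay_to: float | None = None,
    decay_tau_min: float = 5.0,
    seed: int | None = None,
) -> LTPRecording:
    """Synthetic TBS recording: flat baseline, stepped potentiation after TBS.

    Slopes are ``baseline_slope`` before TBS and ``baseline_slope *
    potentiation_factor`` after (optionally decaying exponentially toward
    ``baseline_slope * decay_to`` with time constant ``decay_tau_min``),
    plus additive Gaussian noise with SD ``noise_sd_fraction *
    baseline_slope``.  Deterministic for a fixed seed.
    """
    if baseline_min < 10.0 or post_min < 30.0:
        raise ValueError("need >= 10 min baseline and >= 30 min post-TBS")
    rng = np.random.default_rng(seed)
    tbs_time_s = baseline_min * 60.0
    total_s = (baseline_min + post_min) * 60.0
    times = np.arange(0.0, total_s + sweep_interval_s / 2.0, sweep_interval_s)
    slopes = np.full(times.shape, baseline_slope)
    post = times >= tbs_time_s
    if decay_to is None:
        slopes[post] = baseline_slope * potentiation_factor
    else:
        dt_min = (times[post] - tbs_time_s) / 60.0
        plateau = baseline_slope * decay_to
        peak = baseline_slope * potentiation_factor
        slopes[post] = plateau + (peak - plateau) * np.exp(-dt_min / decay_tau_min)
    if noise_sd_fraction > 0.0:
        slopes = slopes + rng.normal(
            0.0, noise_sd_fraction * baseline_slope, size=slopes.shape
        )
    return LTPRecording(
        times,
        slopes,
        tbs_time_s,
        baseline_window_min=baseline_min,
        meta={"seed": seed, "tbs_protocol": dict(TBS_PROTOCOL)},
    )


def sigmoid_trace(
    amplitude_mV: float = 40.0,
    steepness_per_ms: float = 0.2,
    midpoint_ms: float = 25.0,
    sampling_khz: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Analytic fEPSP-like trace for validation: sigmoidal rise to a peak
    followed by a linear fall-off.

    The rise is truncated symmetrically around the midpoint (so the
    detected ascending run is centered on the steepest point), then decays.
    Returns ``(time_ms, voltage_mV, max_rise)`` where ``max_rise =
    amplitude * steepness / 4`` is the analytic maximum derivative at the
    midpoint.
    """
    k = steepness_per_ms
    half_rise_ms = np.log(9.0) / k  # sigmoid at 90% of amplitude
    t_peak = midpoint_ms + half_rise_ms
    duration_ms = t_peak + 10.0
    t = np.arange(0.0, duration_ms, 1.0 / sampling_khz)
    v = amplitude_mV / (1.0 + np.exp(-k * (t - midpoint_ms)))
    peak_v = amplitude_mV / (1.0 + np.exp(-k * half_rise_ms))
    falling = t > t_peak
    v[falling] = peak_v - 0.5 * amplitude_mV * k * (t[falling] - t_peak)
    return t, v, amplitude_mV * k / 4.0
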