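"""Interpretation of DP/CP/INEPT spectrum triplets.

Turns a triplet of processed spectra into per-signature-window amplitude
triplets and dynamic-state calls (the presence of INEPT signal is the
operational definition of "mobile"; CP marks rigid or anisotropic segments),
and aggregates series of samples into hydration/temperature trend reports
with abrupt-transition detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import EfficiencyTriplet, RegimeThresholds, classify_regime
from .peaks import SignatureSet
from .processing import Spectrum
from .simulate import SampleState

__all__ = [
    "SpectrumTriplet",
    "PeakMeasurement",
    "measure_peak",
    "classify_peaks",
    "series_report",
    "detect_transition",
    "STATE_COLORS",
]

#: Color code of the published overlays: rigid = blue, mobile = red.
STATE_COLORS = {
    "rigid_slow": "blue",
    "mobile_isotropic": "red",
    "mobile_anisotropic": "red",
    "intermediate": "white",
    "ambiguous": "grey",
}


@dataclass(frozen=True)
class SpectrumTriplet:
    """Processed DP/CP/INEPT spectra of one sample on a common axis."""

    dp: Spectrum
    cp: Spectrum
    inept: Spectrum
    sample_state: SampleState | None = None

    def __post_init__(self) -> None:
        if not (np.array_equal(self.dp.ppm_axis, self.cp.ppm_axis)
                and np.array_equal(self.dp.ppm_axis, self.inept.ppm_axis)):
            raise ValueError("DP/CP/INEPT spectra must share an identical ppm axis")


@dataclass(frozen=True)
class PeakMeasurement:
    """Baseline-subtracted areas of one signature window in all three schemes."""

    window: tuple[float, float]
    amp_dp: float
    amp_cp: float
    amp_inept: float
    state_call: str
    group: str
    label: str = ""
    raw_areas: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0), compare=False)


def _window_slice(spectrum: Spectrum, lo: float, hi: float) -> np.ndarray:
    ppm = spectrum.ppm_axis
    if lo < ppm.min() or hi > ppm.max():
        raise ValueError(f"window ({lo}, {hi}) outside ppm axis "
                         f"[{ppm.min():.1f}, {ppm.max():.1f}]")
    return np.flatnonzero((ppm >= lo) & (ppm <= hi))


def measure_peak(spectrum: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal peak area over ``window`` after local linear baseline.

    The baseline is the straight line between the window-edge intensities;
    negative net areas are floored at zero (use :func:`measure_peak_raw` for
    the signed value).
    """
    return max(measure_peak_raw(spectrum, window), 0.0)


def measure_peak_raw(spectrum: Spectrum, window: tuple[float, float]) -> float:
    lo, hi = sorted(window)
    idx = _window_slice(spectrum, lo, hi)
    if idx.size < 3:
        return 0.0
    # ascending-ppm view of the window
    x = spectrum.ppm_axis[idx]
    y = spectrum.intensity[idx]
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    # edge levels averaged over up to 3 points for noise robustness
    k = min(3, y.size // 3) or 1
    y0, y1 = float(y[:k].mean()), float(y[-k:].mean())
    baseline = y0 + (y1 - y0) * (x - x[0]) / (x[-1] - x[0])
    return float(np.trapezoid(y - baseline, x))


def area_noise_bound(spectrum: Spectrum, width_ppm: float,
                     quiet_region: tuple[float, float] = (75.0, 122.0)) -> float:
    """Standard deviation of window areas measured in a signal-free region.

    Used as the noise-derived significance bound for peak detection: an area
    only counts as real signal when it exceeds ~3x this bound.
    """
    lo, hi = quiet_region
    lo = max(lo, float(spectrum.ppm_axis.min()))
    hi = min(hi, float(spectrum.ppm_axis.max()))
    if hi - lo < 3 * width_ppm:
        return 0.0
    edges = np.arange(lo, hi - width_ppm, width_ppm)
    areas = [measure_peak_raw(spectrum, (e, e + width_ppm)) for e in edges]
    return float(np.std(areas))


def total_dp_area(spectrum: Spectrum) -> float:
    """Integral of the DP spectrum over the full axis (scan-invariant scale)."""
    x = spectrum.ppm_axis
    y = spectrum.intensity
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return float(np.trapezoid(y, x))


def classify_peaks(triplet: SpectrumTriplet, signatures: list[SignatureSet],
                   fraction: float = 0.05, dp_floor: float = 0.001,
                   quiet_region: tuple[float, float] = (75.0, 122.0),
                   noise_sigmas: float = 3.0) -> list[PeakMeasurement]:
    """Per-window DP/CP/INEPT amplitude triplets and dynamic-state calls.

    CP and INEPT areas are normalized by the window's DP area (making the
    call invariant to any uniform rescaling of all three spectra) and fed to
    the regime classifier: INEPT without matching CP means nearly isotropic
    reorientation, matching CP and INEPT of comparable amplitude means
    anisotropic mobility, CP alone means rigid.  A scheme only counts as "on"
    if its area also exceeds ``noise_sigmas`` times the noise-derived area
    bound estimated from the signal-free ``quiet_region``.  Windows whose DP
    area falls below ``dp_floor`` of the sample's total DP area (or below the
    noise bound) are called ambiguous.
    """
    out: list[PeakMeasurement] = []
    windows = [(sig, w, e) for sig in signatures
               for w, e in zip(sig.peak_windows(), sig.entries)]
    total_dp = total_dp_area(triplet.dp)
    if total_dp <= 0:
        total_dp = 1.0
    width = float(np.median([hi - lo for _, (lo, hi), _ in windows]))
    bounds = {name: noise_sigmas * area_noise_bound(s, width, quiet_region)
              for name, s in (("dp", triplet.dp), ("cp", triplet.cp),
                              ("inept", triplet.inept))}
    for sig, window, entry in windows:
        a_dp = measure_peak(triplet.dp, window)
        a_cp = measure_peak(triplet.cp, window)
        a_inept = measure_peak(triplet.inept, window)
        if a_dp < max(dp_floor * total_dp, bounds["dp"]):
            call = "ambiguous"
        else:
            eff = EfficiencyTriplet(
                i_dp=1.0,
                i_cp=(a_cp if a_cp >= bounds["cp"] else 0.0) / a_dp,
                i_inept=(a_inept if a_inept >= bounds["inept"] else 0.0) / a_dp,
            )
            thr = RegimeThresholds.for_segment(
                _segment_for_entry(entry), fraction=fraction)
            call = classify_regime(eff, thr)
        out.append(PeakMeasurement(
            window=tuple(window), amp_dp=a_dp, amp_cp=a_cp, amp_inept=a_inept,
            state_call=call, group=sig.group, label=entry.moiety,
            raw_areas=(measure_peak_raw(triplet.dp, window),
                       measure_peak_raw(triplet.cp, window),
                       measure_peak_raw(triplet.inept, window)),
        ))
    return out


def _segment_for_entry(entry) -> "SpinSegment":
    from .dynamics import SpinSegment
    return SpinSegment(multiplicity=entry.multiplicity, shift_ppm=entry.shift_ppm,
                       label=entry.moiety)


def _group_series(reports: list[list[PeakMeasurement]], group: str,
                  totals: list[float], which: str = "amp_inept") -> np.ndarray:
    """Per-state group amplitude, normalized by each state's full-axis DP
    area (the DP integral tracks the total 13C count, so it is the stable
    per-scan scale)."""
    series = []
    for measurements, total in zip(reports, totals):
        series.append(sum(getattr(m, which) for m in measurements
                          if m.group == group) / (total or 1.0))
    return np.asarray(series)


def _trend(values: np.ndarray, tol: float = 0.05) -> str:
    if values.size < 2:
        return "flat"
    span = float(values.max() - values.min())
    scale = float(np.abs(values).max()) or 1.0
    if span < tol * scale:
        return "flat"
    diffs = np.diff(values)
    if np.all(diffs >= -tol * scale):
        return "increasing"
    if np.all(diffs <= tol * scale):
        return "decreasing"
    return "non-monotonic"


def series_report(triplets: list[SpectrumTriplet], signatures: list[SignatureSet],
                  order_by: str = "rh") -> dict:
    """Trend report over an ordered series of sample states.

    Returns a JSON-serializable dict: per signature group the state calls,
    normalized INEPT amplitude trajectory, its trend flag, and the
    rigid/mobile color code per state (rigid = blue, mobile = red).
    """
    if len(triplets) < 2:
        raise ValueError("series_report needs at least 2 states")
    states = [t.sample_state for t in triplets]
    if any(s is None for s in states):
        raise ValueError("all triplets need sample_state metadata")
    key = {"rh": lambda s: s.rh_percent,
           "temperature": lambda s: s.temperature_c}[order_by]
    values = [key(s) for s in states]
    if sorted(values) != values:
        raise ValueError(f"series must be ordered by {order_by}")
    reports = [classify_peaks(t, signatures) for t in triplets]
    totals = [total_dp_area(t.dp) for t in triplets]
    groups = sorted({sig.group for sig in signatures})
    out: dict = {"order_by": order_by, "axis": values, "groups": {}}
    for group in groups:
        inept = _group_series(reports, group, totals, "amp_inept")
        cp = _group_series(reports, group, totals, "amp_cp")
        calls = [_majority_call([m for m in rep if m.group == group]) for rep in reports]
        out["groups"][group] = {
            "state_calls": calls,
            "colors": [STATE_COLORS[c] for c in calls],
            "inept_amplitude": [float(x) for x in inept],
            "cp_amplitude": [float(x) for x in cp],
            "inept_trend": _trend(inept),
            "cp_trend": _trend(cp),
            "transition": detect_transition_from_series(values, inept),
        }
    return out


def _majority_call(measurements: list[PeakMeasurement]) -> str:
    """Group-level call: DP-area-weighted majority over the group's windows."""
    weights: dict[str, float] = {}
    for m in measurements:
        if m.state_call != "ambiguous":
            weights[m.state_call] = weights.get(m.state_call, 0.0) + m.amp_dp
    if not weights:
        return "ambiguous"
    return max(weights, key=weights.get)


def detect_transition_from_series(axis: list[float], areas: np.ndarray,
                                  onset_fraction: float = 0.2,
                                  noise_floor: float = 0.02) -> tuple[float, float] | None:
    """First adjacent axis pair where ``areas`` rises from below to above
    ``onset_fraction`` of the series maximum; None when there is no crossing
    or the whole series sits at the noise floor."""
    areas = np.asarray(areas, dtype=float)
    peak = float(areas.max())
    if peak <= noise_floor:
        return None
    threshold = onset_fraction * peak
    for i in range(len(areas) - 1):
        if areas[i] < threshold <= areas[i + 1]:
            return (axis[i], axis[i + 1])
    return None


def detect_transition(triplets: list[SpectrumTriplet], group: str,
                      signatures: list[SignatureSet],
                      onset_fraction: float = 0.2) -> tuple[float, float] | None:
    """Detect an abrupt mobility onset for one signature group along an
    RH-ordered series (e.g. the keratin-terminal step between RH 80 and 85%).
    """
    states = [t.sample_state for t in triplets]
    if any(s is None for s in states):
        raise ValueError("all triplets need sample_state metadata")
    rh = [s.rh_percent for s in states]
    if sorted(rh) != rh:
        raise ValueError("series must be ordered by rh")
    if not math.isclose(onset_fraction, 0.0) and not 0.0 < onset_fraction < 1.0:
        raise ValueError("onset_fraction must be in (0, 1)")
    reports = [classify_peaks(t, signatures) for t in triplets]
    totals = [total_dp_area(t.dp) for t in triplets]
    areas = _group_series(reports, group, totals, "amp_inept")
    return detect_transition_from_series(rh, areas, onset_fraction)
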