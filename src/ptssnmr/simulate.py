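"""Synthetic stratum-corneum spectrum generator.

Builds DP/CP/INEPT FIDs for SC-like samples whose segmental mobilities follow
the hydration/temperature behaviour of intact pig SC: a dominant rigid
all-trans lipid pool coexisting with a small mobile lipid pool that grows with
hydration and temperature, keratin filament cores that stay rigid throughout,
terminal domains that switch abruptly from rigid to mobile between 80 and 85%
relative humidity, and cholesterol that is mobile only in a narrow hydration
window around RH = 85%.

Quantitative pool fractions are free parameters of the generator (the source
observations are qualitative); the defaults below are synthetic placeholders
chosen to make simulated hydration/temperature series visually comparable to
the published ones, and are flagged as such in output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (EfficiencyTriplet, ExperimentSettings, MotionModel,
                       SpinSegment, efficiency_triplet, relaxation_parameters)
from .processing import FID

__all__ = [
    "ComponentSpec",
    "SampleState",
    "SCHEMES",
    "rh_for_nacl_molality",
    "water_content",
    "water_wt_percent_for_rh",
    "sc_sample",
    "simulate_fid",
    "simulate_triplet",
    "sigma_for_snr",
]

SCHEMES = ("DP", "CP", "INEPT")

#: NaCl molality (mol/kg) -> relative humidity (%) at 32 C.
NACL_RH_TABLE: tuple[tuple[float, float], ...] = (
    (5.12, 80.0),
    (4.02, 85.0),
    (2.81, 90.0),
    (2.02, 93.0),
    (1.19, 96.0),
    (0.156, 99.5),
)

#: RH (%) -> SC water content (wt%).  The six non-zero rows are measured
#: values; the dry anchor is a synthetic placeholder.
RH_WATER_TABLE: tuple[tuple[float, float], ...] = (
    (0.0, 2.0),
    (80.0, 24.0),
    (85.0, 30.0),
    (90.0, 37.0),
    (93.0, 46.0),
    (96.0, 50.0),
    (99.5, 55.0),
)


def rh_for_nacl_molality(molality: float) -> float:
    """RH (%) regulated by a NaCl solution of the given molality.

    Monotone (PCHIP) interpolation between the six tabulated pairs;
    extrapolation outside [0.156, 5.12] mol/kg is refused.
    """
    mol = np.array([m for m, _ in NACL_RH_TABLE])
    rh = np.array([r for _, r in NACL_RH_TABLE])
    if not (mol.min() <= molality <= mol.max()):
        raise ValueError(f"molality {molality} outside tabulated range "
                         f"[{mol.min()}, {mol.max()}] mol/kg; extrapolation refused")
    from scipy.interpolate import PchipInterpolator
    order = np.argsort(mol)
    return float(PchipInterpolator(mol[order], rh[order])(molality))


def water_content(m_dry: float, m_humid: float) -> float:
    """Water weight fraction: (m_humid - m_dry) / m_humid."""
    if not m_dry > 0:
        raise ValueError("m_dry must be > 0")
    if m_humid < m_dry:
        raise ValueError("m_humid must be >= m_dry")
    return (m_humid - m_dry) / m_humid


def water_wt_percent_for_rh(rh_percent: float) -> float:
    """SC water content (wt%) at the given RH (monotone interpolation)."""
    rh = np.array([r for r, _ in RH_WATER_TABLE])
    w = np.array([x for _, x in RH_WATER_TABLE])
    if not (0.0 <= rh_percent <= 100.0):
        raise ValueError("rh_percent must be within [0, 100]")
    return float(np.interp(rh_percent, rh, w))


@dataclass(frozen=True)
class SampleState:
    """External conditions of one SC sample."""

    rh_percent: float  # 0 == dry
    temperature_c: float = 32.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh_percent <= 100.0:
            raise ValueError(f"rh_percent must be in [0, 100], got {self.rh_percent}")

    @property
    def water_wt_percent(self) -> float:
        return water_wt_percent_for_rh(self.rh_percent)


@dataclass(frozen=True)
class ComponentSpec:
    """Segments of one synthetic sample: (segment, motion, abundance) rows."""

    segments: tuple[tuple[SpinSegment, MotionModel, float], ...]
    state: SampleState | None = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        total = sum(a for _, _, a in self.segments)
        if not total > 0:
            raise ValueError("abundances must sum to a positive total")
        if any(a < 0 for _, _, a in self.segments):
            raise ValueError("abundances must be non-negative")


# -- default motional states ------------------------------------------------

RIGID = MotionModel(order_parameter=0.95, tau_c=2.0e-9, tau_s=1.0)


def _mobile(tau_c: float) -> MotionModel:
    return MotionModel(order_parameter=0.005, tau_c=tau_c, tau_s=1.0)


def _mobile_lipid_fraction(rh: float, temperature_c: float) -> float:
    """Fluid fraction of the lipid pool; grows smoothly with hydration and T."""
    rh_pts = [0.0, 80.0, 85.0, 90.0, 93.0, 96.0, 99.5]
    f_pts = [0.12, 0.18, 0.30, 0.38, 0.44, 0.50, 0.54]
    f = float(np.interp(rh, rh_pts, f_pts))
    f *= 1.0 + 0.012 * max(temperature_c - 32.0, 0.0)
    return min(f, 0.95)


def sc_sample(state: SampleState, seed: int = 0) -> ComponentSpec:
    """Synthetic SC composition for one hydration/temperature state.

    Encodes the qualitative rules: (i) a rigid all-trans methylene pool at
    33.4 ppm, melted away at 60 C once the sample is well hydrated; (ii) a
    mobile lipid pool (30.5 / 23.3 / 14.6 ppm) growing with RH and
    temperature, its chain-middle dynamics slowing down at high hydration;
    (iii) rigid keratin core markers at all states; (iv) keratin terminal
    markers rigid up to RH = 80% and mobile from RH = 85%; (v) mobile
    cholesterol entries only in the hydration window around RH = 85%.
    Deterministic for a given (state, seed): the seed only applies a small
    abundance jitter emulating sample-to-sample variability.
    """
    rng = np.random.default_rng(seed)
    rh, temp = state.rh_percent, state.temperature_c
    water = state.water_wt_percent
    rows: list[tuple[SpinSegment, MotionModel, float]] = []

    # --- lipids --------------------------------------------------------------
    lipid_total = 24.0
    f_mob = _mobile_lipid_fraction(rh, temp)
    rigid_lipid = lipid_total * (1.0 - f_mob)
    if temp >= 60.0:
        # solid-to-liquid transition: all-trans pool gone when well hydrated
        rigid_lipid = 0.0 if water >= 30.0 else rigid_lipid * 0.35
    elif temp >= 42.0:
        rigid_lipid *= 0.8
    mobile_lipid = lipid_total - rigid_lipid

    # chain-middle correlation time slows with hydration (fluid phase gains
    # long-chain species), speeds up with temperature
    t_factor = max(1.0 - 0.015 * (temp - 32.0), 0.4)
    tau_chain = (2.0e-9 + 1.0e-8 * water / 50.0) * t_factor
    if rigid_lipid > 0:
        rows.append((SpinSegment(2, 33.4, label="(CH2)n all-trans"), RIGID, rigid_lipid))
    rows.append((SpinSegment(2, 30.5, label="(CH2)n trans/gauche"),
                 _mobile(tau_chain), mobile_lipid * 0.6))
    rows.append((SpinSegment(2, 23.3, label="(omega-1) CH2"),
                 _mobile(1.5e-9 * t_factor), mobile_lipid * 0.2))
    rows.append((SpinSegment(3, 14.6, label="omega CH3"),
                 _mobile(1.0e-9 * t_factor), mobile_lipid * 0.2))

    # --- keratin core: rigid at all states ------------------------------------
    rows.append((SpinSegment(2, 40.6, label="Leu C_beta + Lys C_epsilon"), RIGID, 12.0))
    rows.append((SpinSegment(1, 58.6, label="keratin C_alpha core"), RIGID, 18.0))

    # --- keratin terminals: abrupt rigid -> mobile between RH 80 and 85 -------
    terminals = [
        (SpinSegment(2, 43.7, label="Gly C_alpha"), 10.0),
        (SpinSegment(1, 56.7, label="Ser C_alpha"), 6.0),
        (SpinSegment(2, 62.4, label="Ser C_beta"), 6.0),
    ]
    if rh >= 85.0:
        tau_term = (4.0e-9 - 2.5e-9 * min((rh - 85.0) / 11.0, 1.0)) * t_factor
        term_motion, mobile_frac = _mobile(tau_term), 1.0
    elif temp >= 60.0:
        term_motion, mobile_frac = _mobile(4.0e-9), 0.2
    else:
        term_motion, mobile_frac = RIGID, 0.0
    for seg, abundance in terminals:
        if mobile_frac < 1.0:
            rows.append((seg, RIGID, abundance * (1.0 - mobile_frac)))
        if mobile_frac > 0.0:
            rows.append((seg, term_motion, abundance * mobile_frac))

    # --- cholesterol: mobile only near RH = 85 --------------------------------
    if 82.0 <= rh <= 88.0:
        for seg in (SpinSegment(2, 40.65, label="cholesterol C24/C12"),
                    SpinSegment(2, 42.8, label="cholesterol C4"),
                    SpinSegment(1, 51.8, label="cholesterol C9"),
                    SpinSegment(1, 57.6, label="cholesterol C14/C17")):
            rows.append((seg, _mobile(3.0e-9), 2.5))

    jitter = rng.uniform(0.97, 1.03, size=len(rows))
    rows = [(seg, mot, ab * j) for (seg, mot, ab), j in zip(rows, jitter)]
    meta = {"rh_percent": rh, "temperature_c": temp, "water_wt_percent": water,
            "seed": seed, "abundances": "synthetic placeholder defaults"}
    return ComponentSpec(segments=tuple(rows), state=state, metadata=meta)


# ---------------------------------------------------------------------------
# FID synthesis
# ---------------------------------------------------------------------------

#: spectral width 250 ppm at 125 MHz -> 31.25 kHz; 1597 points -> ~51 ms
DEFAULT_SW_PPM = 250.0
DEFAULT_N_POINTS = 1597
LINEWIDTH_BOUNDS_HZ = (12.0, 100.0)


def _segment_linewidth(motion: MotionModel, segment: SpinSegment,
                       settings: ExperimentSettings) -> float:
    """Observed linewidth (Hz) for one segment, 1/(pi*T2C) clipped to the
    range seen under high-power decoupling (field inhomogeneity floor,
    decoupling-limited ceiling)."""
    t2c = relaxation_parameters(motion, segment, settings).t2_c
    return float(np.clip(1.0 / (math.pi * t2c), *LINEWIDTH_BOUNDS_HZ))


def _scheme_amplitude(trip: EfficiencyTriplet, scheme: str) -> float:
    try:
        return {"DP": trip.i_dp, "CP": trip.i_cp, "INEPT": trip.i_inept}[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}") from None


def simulate_fid(spec: ComponentSpec, scheme: str,
                 settings: ExperimentSettings | None = None,
                 noise_sigma: float = 0.0, seed: int = 0,
                 n_points: int = DEFAULT_N_POINTS,
                 sw_ppm: float = DEFAULT_SW_PPM) -> FID:
    """Synthesize the FID of one sample under one pulse scheme.

    Each segment contributes an exponentially decaying complex sinusoid at
    its chemical shift, with amplitude = abundance x the scheme's model
    intensity and decay constant from its predicted 13C linewidth.  Circular
    Gaussian noise with standard deviation ``noise_sigma`` per complex point
    is added using the given seed.
    """
    settings = settings or ExperimentSettings()
    larmor_mhz = settings.larmor_c / 1.0e6
    sw_hz = sw_ppm * larmor_mhz
    dwell = 1.0 / sw_hz
    carrier_ppm = sw_ppm / 2.0
    t = np.arange(n_points) * dwell
    signal = np.zeros(n_points, dtype=complex)
    for segment, motion, abundance in spec.segments:
        trip = efficiency_triplet(motion, segment, settings)
        amp = abundance * _scheme_amplitude(trip, scheme)
        if amp <= 0.0:
            continue
        lw = _segment_linewidth(motion, segment, settings)
        f_hz = (segment.shift_ppm - carrier_ppm) * larmor_mhz
        signal += amp * np.exp((2j * math.pi * f_hz - math.pi * lw) * t)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sigma * (rng.standard_normal(n_points)
                                         + 1j * rng.standard_normal(n_points))
    return FID(points=signal, dwell_time=dwell, scheme=scheme,
               larmor_c=settings.larmor_c, carrier_ppm=carrier_ppm)


def simulate_triplet(spec: ComponentSpec,
                     settings: ExperimentSettings | None = None,
                     noise_sigma: float = 0.0, seed: int = 0,
                     n_points: int = DEFAULT_N_POINTS) -> dict[str, FID]:
    """DP, CP and INEPT FIDs of one sample (independent noise per scheme)."""
    return {scheme: simulate_fid(spec, scheme, settings, noise_sigma,
                                 seed=seed * 3 + i, n_points=n_points)
            for i, scheme in enumerate(SCHEMES)}


def ground_truth_calls(spec: ComponentSpec, signatures,
                       settings: ExperimentSettings | None = None) -> dict:
    """Expected dynamic-state call per signature window.

    For each window the truth is the regime of the composite signal: the
    abundance-weighted sum of the model DP/CP/INEPT intensities of every
    segment whose shift falls inside the window (what an experiment actually
    integrates there).  Windows containing no segment are 'ambiguous'.
    """
    from .dynamics import RegimeThresholds, classify_regime, EfficiencyTriplet

    settings = settings or ExperimentSettings()
    out: dict[tuple[float, float], str] = {}
    for sig in signatures:
        for window, entry in zip(sig.peak_windows(), sig.entries):
            lo, hi = window
            sums = np.zeros(3)
            for segment, motion, abundance in spec.segments:
                if lo <= segment.shift_ppm <= hi:
                    trip = efficiency_triplet(motion, segment, settings)
                    sums += abundance * np.array([trip.i_dp, trip.i_cp, trip.i_inept])
            if sums[0] <= 0:
                out[tuple(window)] = "ambiguous"
                continue
            eff = EfficiencyTriplet(1.0, sums[1] / sums[0], sums[2] / sums[0])
            thr = RegimeThresholds.for_segment(
                SpinSegment(multiplicity=entry.multiplicity,
                            shift_ppm=entry.shift_ppm, label=entry.moiety))
            out[tuple(window)] = classify_regime(eff, thr)
    return out


def sigma_for_snr(spec: ComponentSpec, snr: float,
                  settings: ExperimentSettings | None = None,
                  n_points: int = DEFAULT_N_POINTS) -> float:
    """Time-domain noise sigma giving the requested spectral SNR.

    SNR is defined on the DP spectrum: tallest peak height over the standard
    deviation of the spectral noise (which is sigma * sqrt(n_points) for
    white complex noise).
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    from .processing import process_fid
    fid = simulate_fid(spec, "DP", settings, noise_sigma=0.0, n_points=n_points)
    spectrum = process_fid(fid, phase=False, baseline=False)
    peak = float(spectrum.intensity.max())
    return peak / (snr * math.sqrt(n_points))
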