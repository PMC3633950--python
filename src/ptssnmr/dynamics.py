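"""Forward model for polarization-transfer ssNMR signal intensities.

Maps segmental motion parameters (order parameter |S_CH|, fast correlation
time tau_c, slow correlation time tau_s) plus experimental settings onto the
normalized intensities observed with the DP, CP and INEPT pulse sequences for
one C-Hn moiety under magic-angle spinning.

The chain is:

    two-step correlation function  ->  reduced spectral density
        ->  dipolar relaxation/transfer times (T2H, T2C, T1rho_H, T_CH)
        ->  CP two-reservoir kinetics / refocused-INEPT product formula

All intensities are normalized so that the single-scan DP amplitude of the
segment is 1.0; CP and INEPT are then bounded by the gyromagnetic ratio
gamma_H/gamma_C (~4 for 13C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MotionModel",
    "SpinSegment",
    "ExperimentSettings",
    "RelaxationSet",
    "EfficiencyTriplet",
    "RegimeThresholds",
    "correlation_function",
    "spectral_density",
    "relaxation_parameters",
    "cp_intensity",
    "inept_intensity",
    "dp_intensity",
    "efficiency_triplet",
    "efficiency_map",
    "classify_regime",
    "REGIMES",
]

# ---------------------------------------------------------------------------
# Physical constants (SI)
# ---------------------------------------------------------------------------

GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_C = 6.728284e7  # 13C gyromagnetic ratio, rad s^-1 T^-1
HBAR = 1.054571817e-34  # J s
MU0_OVER_4PI = 1.0e-7  # T m A^-1

#: Geminal / nearest-neighbour H-H distance used for the proton bath, m.
R_HH = 1.78e-10

# ---------------------------------------------------------------------------
# Model constants.  These three numbers are the only free parameters of the
# relaxation model; they were calibrated once against the published regime
# thresholds of the efficiency map (CP/INEPT equality near |S_CH| ~ 0.1 at
# tau_c = 1 ns; CP negligible below 0.01 and maximal above 0.5; joint dip at
# tau_c ~ 1 us).  See docs/methods.md for the rationale of each.
# ---------------------------------------------------------------------------

#: Residual librational order parameter: even a "fully ordered" segment keeps
#: fast small-angle librations, so the relaxation-active fluctuation never
#: vanishes entirely.  Multiplies |S_CH| wherever a residual coupling enters
#: a relaxation rate.
LIBRATION_ORDER = 0.9

#: Dimensionless CP transfer-efficiency constant (absorbs the Hartmann-Hahn
#: ramp efficiency at the n = +-1 sideband condition).
ZETA_CP = 0.035

#: Exponent of the residual order parameter in the CP build-up rate.  The
#: sudden (rate) limit would give 2, the adiabatic-passage limit 1; the ramped
#: contact sweeping through the sideband condition sits in between.
ALPHA_CP = 1.4

#: Exponent of the Lorentzian MAS-coherence gate applied to the residual
#: (static) second moment: couplings well below the spinning rate are spun
#: out and echoed away, couplings above it broaden homogeneously.
MAS_GATE_EXPONENT = 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionModel:
    """Two-step motional model of one C-H bond.

    Parameters
    ----------
    order_parameter : float
        |S_CH| in [0, 1]; 0 = isotropic reorientation, 1 = rigid.
    tau_c : float
        Fast (local) reorientational correlation time, s.
    tau_s : float
        Slow (global) correlation time, s.  Defaults to 1 s, i.e. an
        effectively static residual coupling.  May be ``math.inf``.
    """

    order_parameter: float
    tau_c: float
    tau_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.order_parameter <= 1.0:
            raise ValueError(f"order_parameter must be in [0, 1], got {self.order_parameter}")
        if not self.tau_c > 0.0:
            raise ValueError(f"tau_c must be > 0, got {self.tau_c}")
        if not self.tau_s >= self.tau_c:
            raise ValueError("tau_s must be >= tau_c")


@dataclass(frozen=True)
class SpinSegment:
    """One C-Hn moiety: what the 13C nucleus is directly bonded to."""

    multiplicity: int
    shift_ppm: float = 30.0
    j_ch: float = 139.0  # one-bond scalar coupling, Hz; 1/(4J) ~ 1.8 ms
    r_ch: float = 1.09e-10  # C-H distance, m
    label: str = ""

    def __post_init__(self) -> None:
        if self.multiplicity not in (1, 2, 3):
            raise ValueError(f"multiplicity must be 1, 2 or 3, got {self.multiplicity}")
        if not 100.0 <= self.j_ch <= 250.0:
            raise ValueError(f"j_ch must be within [100, 250] Hz, got {self.j_ch}")
        if not 1.0e-10 <= self.r_ch <= 1.2e-10:
            raise ValueError(f"r_ch must be within [1.0, 1.2] Angstrom, got {self.r_ch}")


@dataclass(frozen=True)
class ExperimentSettings:
    """Acquisition parameters; defaults match the 11.74 T / 5 kHz MAS setup."""

    b0: float = 11.74  # static field, T
    larmor_c: float = 125.0e6  # 13C resonance frequency, Hz
    larmor_h: float = 500.0e6  # 1H resonance frequency, Hz
    mas_rate: float = 5000.0  # omega_R / 2pi, Hz
    t_cp: float = 1.0e-3  # CP contact time, s
    nut_c: float = 80.0e3  # 13C nutation frequency, Hz
    nut_h_start: float = 72.0e3  # 1H ramp start, Hz
    nut_h_end: float = 88.0e3  # 1H ramp end, Hz
    inept_tau: float = 1.8e-3  # INEPT tau, s
    inept_tau_prime: float = 1.2e-3  # INEPT tau', s

    def __post_init__(self) -> None:
        for name in ("b0", "larmor_c", "larmor_h", "mas_rate", "t_cp", "nut_c",
                     "nut_h_start", "nut_h_end", "inept_tau", "inept_tau_prime"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.nut_h_start > self.nut_h_end:
            raise ValueError("nut_h_start must be <= nut_h_end")

    @property
    def gamma_ratio(self) -> float:
        """gamma_H / gamma_C, the maximum polarization-transfer enhancement."""
        return self.larmor_h / self.larmor_c

    @property
    def nut_h_mid(self) -> float:
        """Ramp midpoint of the 1H spin-lock nutation frequency, Hz."""
        return 0.5 * (self.nut_h_start + self.nut_h_end)

    def with_overrides(self, **kwargs: float) -> "ExperimentSettings":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RelaxationSet:
    """Relaxation and polarization-transfer time constants, seconds."""

    t2_h: float
    t2_c: float
    t1rho_h: float
    t_ch: float

    def __post_init__(self) -> None:
        for name in ("t2_h", "t2_c", "t1rho_h", "t_ch"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class EfficiencyTriplet:
    """Normalized DP/CP/INEPT intensities of one segment (DP = 1 reference)."""

    i_dp: float
    i_cp: float
    i_inept: float
    # Signed (pre-clipping) values kept for debugging.
    raw_cp: float = field(default=math.nan, compare=False)
    raw_inept: float = field(default=math.nan, compare=False)


REGIMES = ("mobile_isotropic", "mobile_anisotropic", "rigid_slow", "intermediate", "ambiguous")


@dataclass(frozen=True)
class RegimeThresholds:
    """On/off thresholds for regime classification.

    A scheme counts as "on" when its intensity exceeds ``fraction`` of that
    scheme's reference maximum.  The reference maxima default to the
    theoretical ceilings for a CH2 segment under the default settings.
    """

    fraction: float = 0.05
    cp_max: float = 4.0
    inept_max: float = 1.7320508  # gamma_ratio * sin(pi J tau2) F2(pi J tau2')
    dp_floor: float = 1.0e-3

    @classmethod
    def for_segment(cls, segment: SpinSegment,
                    settings: ExperimentSettings | None = None,
                    fraction: float = 0.05) -> "RegimeThresholds":
        settings = settings or ExperimentSettings()
        g = settings.gamma_ratio
        x = math.pi * segment.j_ch * 2.0 * settings.inept_tau
        y = math.pi * segment.j_ch * 2.0 * settings.inept_tau_prime
        inept_max = abs(g * math.sin(x) * _refocus_factor(segment.multiplicity, y))
        return cls(fraction=fraction, cp_max=g, inept_max=max(inept_max, 1e-12))


# ---------------------------------------------------------------------------
# Correlation function and spectral density
# ---------------------------------------------------------------------------


def correlation_function(motion: MotionModel, t: float | np.ndarray) -> float | np.ndarray:
    """Two-step correlation function C(t).

    C(t) = (1 - S^2) exp(-t/tau_c) + S^2 exp(-t/tau_s); C(0) = 1, and C is
    non-increasing for t >= 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    s2 = motion.order_parameter**2
    slow = np.exp(-t_arr / motion.tau_s) if math.isfinite(motion.tau_s) else np.ones_like(t_arr)
    out = (1.0 - s2) * np.exp(-t_arr / motion.tau_c) + s2 * slow
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def spectral_density(motion: MotionModel, omega: float | np.ndarray) -> float | np.ndarray:
    """Reduced spectral density J(omega), seconds.

    J(omega) = (2/5) [ (1-S^2) tau_c / (1 + omega^2 tau_c^2)
                       + S^2 tau_s / (1 + omega^2 tau_s^2) ]

    The 2/5 reduced convention is used throughout; all dipolar prefactors are
    carried by :func:`relaxation_parameters`.  J is even in omega and
    non-increasing in |omega|.
    """
    w = np.asarray(omega, dtype=float)
    s2 = motion.order_parameter**2
    fast = (1.0 - s2) * motion.tau_c / (1.0 + (w * motion.tau_c) ** 2)
    if math.isfinite(motion.tau_s):
        slow = s2 * motion.tau_s / (1.0 + (w * motion.tau_s) ** 2)
        slow = np.where(w == 0.0, s2 * motion.tau_s, slow)
    else:
        # Infinite tau_s: the rigid fraction carries no finite-frequency density.
        slow = np.where(w == 0.0, np.inf if s2 > 0 else 0.0, 0.0)
    out = 0.4 * (fast + slow)
    return float(out) if np.isscalar(omega) or w.ndim == 0 else out


# ---------------------------------------------------------------------------
# Dipolar couplings and effective motional parameters
# ---------------------------------------------------------------------------


def dipolar_coupling(gamma1: float, gamma2: float, r: float) -> float:
    """Dipolar coupling constant d = (mu0/4pi) gamma1 gamma2 hbar / r^3, rad/s."""
    return MU0_OVER_4PI * gamma1 * gamma2 * HBAR / r**3


def _refocus_factor(multiplicity: int, y: float) -> float:
    """Multiplicity-dependent refocusing factor F_n(y) of refocused INEPT."""
    if multiplicity == 1:
        return math.sin(y)
    if multiplicity == 2:
        return math.sin(y) * math.cos(y)
    if multiplicity == 3:
        return math.sin(y) * math.cos(y) ** 2
    raise ValueError(f"multiplicity must be 1, 2 or 3, got {multiplicity}")


def _effective_order(motion: MotionModel, d_loc: float) -> float:
    """Residual order parameter as seen on the polarization-transfer timescale.

    Local motion only pre-averages the dipolar coupling if it is fast compared
    to the coupling strength itself.  The crossover weight
    w = d*tau_c / (1 + d*tau_c) interpolates between the motionally averaged
    limit (S_eff -> S for d*tau_c << 1) and the slow-motion limit where the
    full coupling survives (S_eff -> 1).
    """
    w = d_loc * motion.tau_c / (1.0 + d_loc * motion.tau_c)
    s2 = motion.order_parameter**2
    return math.sqrt(s2 + (1.0 - s2) * w)


def _j_eff(omega: float, tau_c: float, tau_s: float, variance: float, plateau: float) -> float:
    """Reduced spectral density of the effective (libration-corrected) motion."""
    fast = variance * tau_c / (1.0 + (omega * tau_c) ** 2)
    slow = plateau * tau_s / (1.0 + (omega * tau_s) ** 2) if math.isfinite(tau_s) else 0.0
    return 0.4 * (fast + slow)


def _coherent_rate(m2: float, omega_r: float) -> float:
    """Residual-coupling dephasing rate under MAS.

    sqrt(M2) is the static linewidth; the Lorentzian gate
    (M2 / (M2 + omega_R^2))^q switches it off once the residual coupling falls
    well below the spinning rate (spun out / refocused by the echo train) and
    leaves it fully on in the homogeneous strong-coupling regime.
    """
    if m2 <= 0.0:
        return 0.0
    gate = (m2 / (m2 + omega_r**2)) ** MAS_GATE_EXPONENT
    return math.sqrt(m2) * gate


# ---------------------------------------------------------------------------
# Relaxation parameters
# ---------------------------------------------------------------------------


def relaxation_parameters(motion: MotionModel, segment: SpinSegment,
                          settings: ExperimentSettings) -> RelaxationSet:
    """Compute T2H, T2C, T1rho_H and T_CH for one segment.

    Rates combine (i) Redfield-type motional contributions from the reduced
    spectral density, with secular (zero-frequency) terms evaluated at the MAS
    frequencies omega_R and 2*omega_R, and (ii) coherent residual-coupling
    contributions gated by the MAS coherence factor.  T1rho_H samples the
    spectral density at twice the 1H spin-lock nutation frequency (ramp
    midpoint) combined with the MAS sidebands.  T_CH follows the residual
    heteronuclear coupling through the ramped Hartmann-Hahn sideband match.
    """
    n = segment.multiplicity
    k_hh = 2 * n  # effective number of bath protons coupled to each 1H

    d_ch = dipolar_coupling(GAMMA_H, GAMMA_C, segment.r_ch)
    d_hh = dipolar_coupling(GAMMA_H, GAMMA_H, R_HH)

    omega_h = 2.0 * math.pi * settings.larmor_h
    omega_c = 2.0 * math.pi * settings.larmor_c
    omega_r = 2.0 * math.pi * settings.mas_rate
    omega_sl = 2.0 * math.pi * settings.nut_h_mid  # spin-lock nutation, rad/s

    s_m = _effective_order(motion, d_ch)
    s_res = LIBRATION_ORDER * s_m  # libration-corrected residual order
    variance = 1.0 - s_res**2
    plateau = s_res**2
    tau_c, tau_s = motion.tau_c, motion.tau_s

    def j(omega: float) -> float:
        return _j_eff(omega, tau_c, tau_s, variance, plateau)

    # MAS-averaged secular density.
    j0 = 0.5 * (j(omega_r) + j(2.0 * omega_r))

    # --- 1H transverse relaxation (homonuclear dipolar, like spins) ---------
    r2h_motional = (d_hh**2 / 8.0) * k_hh * (3.0 * j0 + 5.0 * j(omega_h) + 2.0 * j(2.0 * omega_h))
    m2_hh = 0.45 * k_hh * (s_res * d_hh) ** 2
    r2h = r2h_motional + _coherent_rate(m2_hh, omega_r)

    # --- 13C transverse relaxation (heteronuclear dipolar to n protons) -----
    r2c_motional = (d_ch**2 / 8.0) * n * (
        4.0 * j0 + j(omega_h - omega_c) + 3.0 * j(omega_c)
        + 6.0 * j(omega_h) + 6.0 * j(omega_h + omega_c)
    )
    m2_ch = 0.2 * n * (s_res * d_ch) ** 2
    r2c = r2c_motional + _coherent_rate(m2_ch, omega_r)

    # --- 1H rotating-frame relaxation ---------------------------------------
    j_sl = 0.25 * (
        j(2.0 * omega_sl + omega_r) + j(abs(2.0 * omega_sl - omega_r))
        + j(2.0 * omega_sl + 2.0 * omega_r) + j(abs(2.0 * omega_sl - 2.0 * omega_r))
    )
    r1rho = (d_hh**2 / 8.0) * k_hh * (3.0 * j_sl + 5.0 * j(omega_h) + 2.0 * j(2.0 * omega_h))

    # --- CP build-up time constant ------------------------------------------
    # Residual coupling s_m * d_ch drives transfer through the ramped n = +-1
    # sideband match; the proton bath width sets the matching bandwidth.
    omega_bath = math.sqrt(0.45 * k_hh) * d_hh
    r_ch_rate = ZETA_CP * n * d_ch**2 / omega_bath * s_m**ALPHA_CP

    tiny = 1.0e-30
    return RelaxationSet(
        t2_h=1.0 / max(r2h, tiny),
        t2_c=1.0 / max(r2c, tiny),
        t1rho_h=1.0 / max(r1rho, tiny),
        t_ch=1.0 / max(r_ch_rate, tiny),
    )


# ---------------------------------------------------------------------------
# Scheme intensities
# ---------------------------------------------------------------------------


def cp_intensity(relax: RelaxationSet, settings: ExperimentSettings,
                 gamma_ratio: float | None = None) -> float:
    """Two-reservoir CP kinetics evaluated at the contact time.

    I_CP = g (1 - T_CH/T1rho)^-1 [exp(-t_CP/T1rho) - exp(-t_CP/T_CH)],
    clipped at zero; the removable singularity T_CH = T1rho is handled by its
    analytic limit g (t_CP/T1rho) exp(-t_CP/T1rho).
    """
    g = settings.gamma_ratio if gamma_ratio is None else gamma_ratio
    t = settings.t_cp
    t_ch, t1r = relax.t_ch, relax.t1rho_h
    ratio = t_ch / t1r
    if abs(1.0 - ratio) < 1.0e-9:
        val = g * (t / t1r) * math.exp(-t / t1r)
    else:
        val = g / (1.0 - ratio) * (math.exp(-t / t1r) - math.exp(-t / t_ch))
    return max(val, 0.0)


def inept_intensity(relax: RelaxationSet, segment: SpinSegment,
                    settings: ExperimentSettings,
                    gamma_ratio: float | None = None) -> float:
    """Refocused-INEPT amplitude with transverse-relaxation damping.

    I = g sin(pi J tau2) F_n(pi J tau2') exp(-tau2/T2H) exp(-tau2'/T2C), with
    tau2 = 2 tau and tau2' = 2 tau'; F_n is the multiplicity refocusing factor.
    """
    g = settings.gamma_ratio if gamma_ratio is None else gamma_ratio
    tau2 = 2.0 * settings.inept_tau
    tau2p = 2.0 * settings.inept_tau_prime
    x = math.pi * segment.j_ch * tau2
    y = math.pi * segment.j_ch * tau2p
    val = (g * math.sin(x) * _refocus_factor(segment.multiplicity, y)
           * math.exp(-tau2 / relax.t2_h) * math.exp(-tau2p / relax.t2_c))
    return max(val, 0.0)


def dp_intensity(relax: RelaxationSet, visibility_linewidth_hz: float | None = None) -> float:
    """Direct-polarization reference amplitude.

    Returns 1.0 (DP excites all 13C).  If ``visibility_linewidth_hz`` is set,
    segments broadened beyond that resolvable linewidth are attenuated by the
    visibility factor min(1, pi * lw * T2C / 2); default off.
    """
    if visibility_linewidth_hz is None:
        return 1.0
    return min(1.0, 0.5 * math.pi * visibility_linewidth_hz * relax.t2_c)


def efficiency_triplet(motion: MotionModel, segment: SpinSegment,
                       settings: ExperimentSettings | None = None) -> EfficiencyTriplet:
    """DP/CP/INEPT intensities for one segment; deterministic composition."""
    settings = settings or ExperimentSettings()
    relax = relaxation_parameters(motion, segment, settings)
    g = settings.gamma_ratio
    tau2 = 2.0 * settings.inept_tau
    tau2p = 2.0 * settings.inept_tau_prime
    x = math.pi * segment.j_ch * tau2
    y = math.pi * segment.j_ch * tau2p
    raw_inept = (g * math.sin(x) * _refocus_factor(segment.multiplicity, y)
                 * math.exp(-tau2 / relax.t2_h) * math.exp(-tau2p / relax.t2_c))
    t, t_ch, t1r = settings.t_cp, relax.t_ch, relax.t1rho_h
    ratio = t_ch / t1r
    if abs(1.0 - ratio) < 1.0e-9:
        raw_cp = g * (t / t1r) * math.exp(-t / t1r)
    else:
        raw_cp = g / (1.0 - ratio) * (math.exp(-t / t1r) - math.exp(-t / t_ch))
    return EfficiencyTriplet(
        i_dp=dp_intensity(relax),
        i_cp=max(raw_cp, 0.0),
        i_inept=max(raw_inept, 0.0),
        raw_cp=raw_cp,
        raw_inept=raw_inept,
    )


def efficiency_map(tau_grid: np.ndarray, s_grid: np.ndarray,
                   segment: SpinSegment | None = None,
                   settings: ExperimentSettings | None = None) -> dict[str, np.ndarray]:
    """Dense efficiency map over (tau_c, |S_CH|).

    Returns a dict with keys ``tau_c`` (n_tau,), ``s`` (n_s,), and the
    intensity matrices ``i_dp``, ``i_cp``, ``i_inept`` of shape
    (n_s, n_tau): rows follow the S grid, columns the tau_c grid.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    if tau_grid.size == 0 or s_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(tau_grid < 1e-12) or np.any(tau_grid > 1.0):
        raise ValueError("tau_c grid must lie within [1e-12, 1] s")
    if np.any(s_grid < 1e-3) or np.any(s_grid > 1.0):
        raise ValueError("S grid must lie within [1e-3, 1]")
    segment = segment or SpinSegment(multiplicity=2, label="CH2")
    settings = settings or ExperimentSettings()
    shape = (s_grid.size, tau_grid.size)
    i_dp = np.empty(shape)
    i_cp = np.empty(shape)
    i_inept = np.empty(shape)
    for i, s in enumerate(s_grid):
        for k, tau in enumerate(tau_grid):
            trip = efficiency_triplet(MotionModel(s, tau), segment, settings)
            i_dp[i, k] = trip.i_dp
            i_cp[i, k] = trip.i_cp
            i_inept[i, k] = trip.i_inept
    return {"tau_c": tau_grid, "s": s_grid, "i_dp": i_dp, "i_cp": i_cp, "i_inept": i_inept}


def classify_regime(triplet: EfficiencyTriplet,
                    thresholds: RegimeThresholds | None = None) -> str:
    """Map an intensity triplet onto a dynamic-regime label.

    INEPT-only -> mobile_isotropic; both CP and INEPT -> mobile_anisotropic;
    CP-only -> rigid_slow; neither but DP present -> intermediate; nothing at
    all -> ambiguous.  "On" means exceeding ``fraction`` of the per-scheme
    reference maximum.
    """
    thr = thresholds or RegimeThresholds()
    cp_on = triplet.i_cp >= thr.fraction * thr.cp_max
    inept_on = triplet.i_inept >= thr.fraction * thr.inept_max
    dp_on = triplet.i_dp >= thr.dp_floor
    if inept_on and not cp_on:
        return "mobile_isotropic"
    if inept_on and cp_on:
        return "mobile_anisotropic"
    if cp_on:
        return "rigid_slow"
    if dp_on:
        return "intermediate"
    return "ambiguous"
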