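"""Forward signal models for quantitative UTE-MRI of short-T2 tissue.

This module contains the physics layer of the package:

* absorption lineshapes of the semisolid (macromolecular) proton pool —
  super-Lorentzian, Gaussian and Lorentzian;
* the continuous-wave power equivalent (CWPE) of a pulsed off-resonance
  saturation train;
* the closed-form steady-state signal of the two-pool magnetization-transfer
  (MT) model under CWPE saturation, from which the macromolecular fraction
  (MMF) is estimated;
* the spoiled gradient echo (SPGR) signal used for variable-flip-angle (VFA)
  T1 mapping, the actual-flip-angle-imaging (AFI) ratio used for B1 mapping,
  and the mono-exponential multi-echo decay used for T2* mapping.

It also defines the acquisition-protocol container mirroring the 3D UTE-MT /
multi-echo UTE / UTE-VFA / AFI knee exam, loadable from a YAML file.  All
internal units are SI: times in seconds, frequency offsets in Hz, saturation
amplitudes in rad/s.  The reporting layer converts MMF to percent and T2* to
milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import yaml
from scipy import integrate
from scipy.interpolate import CubicSpline

from .exceptions import InvalidInputError

__all__ = [
    "LINESHAPES",
    "R1_BOUND_DEFAULT",
    "TwoPoolParams",
    "SaturationCondition",
    "MTPulseShape",
    "AcquisitionProtocol",
    "lineshape_value",
    "cw_power_equivalent",
    "mt_steady_state_signal",
    "mt_grid_signals",
    "spgr_signal",
    "ernst_angle_deg",
    "afi_ratio",
    "multiecho_signal",
    "default_protocol",
    "load_protocol",
]

LINESHAPES = ("super_lorentzian", "gaussian", "lorentzian")

#: Longitudinal relaxation rate of the semisolid pool, 1/s.  Not identifiable
#: from the saturation data and conventionally pinned at 1/s in qMT fitting.
R1_BOUND_DEFAULT = 1.0

#: Offsets closer to resonance than this are evaluated at this offset when the
#: super-Lorentzian is requested (its on-resonance value diverges).  The
#: protocol offsets start at 2 kHz, so the clamp never triggers in-protocol.
_SL_MIN_OFFSET_HZ = 1000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoPoolParams:
    """Voxel-level biophysical state of the two-pool MT model.

    Attributes
    ----------
    f:
        Macromolecular (bound-pool) proton fraction, dimensionless in [0, 1).
        Reported downstream as MMF = 100·f percent.
    r_exch:
        Fundamental exchange rate constant between pools, 1/s.  The directional
        rates are k_ab = r_exch·M0b and k_ba = r_exch·M0a.
    t2mm_s:
        Transverse relaxation time of the semisolid pool, s (order 10 µs).
    t1w_s:
        Observed longitudinal relaxation time of the water pool, s; taken from
        the measured VFA/AFI T1 map.
    t2w_s:
        Transverse relaxation time of the water pool, s.
    m0:
        Signal scale (fully relaxed, unsaturated magnitude), arbitrary units.
    """

    f: float
    r_exch: float
    t2mm_s: float
    t1w_s: float
    t2w_s: float = 0.030
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f < 1.0:
            raise InvalidInputError(f"macromolecular fraction f={self.f} outside [0, 1)")
        for name in ("r_exch", "t2mm_s", "t1w_s", "t2w_s"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive, got {getattr(self, name)}")
        if self.t2mm_s >= self.t2w_s:
            raise InvalidInputError(
                f"semisolid T2 ({self.t2mm_s} s) must be shorter than water T2 ({self.t2w_s} s)"
            )
        if self.m0 < 0:
            raise InvalidInputError("m0 must be non-negative")


@dataclass(frozen=True)
class MTPulseShape:
    """Saturation pulse envelope summary.

    ``p1`` is the ratio of the mean amplitude to the peak amplitude and ``p2``
    the ratio of the mean squared amplitude to the squared peak amplitude over
    the pulse duration; both are 1 for a rectangular pulse.  The default is a
    Fermi envelope of 8 ms.
    """

    name: str = "fermi"
    p1: float = 0.7
    p2: float = 0.6
    duration_s: float = 0.008

    def __post_init__(self) -> None:
        if not (0 < self.p1 <= 1 and 0 < self.p2 <= 1):
            raise InvalidInputError("pulse shape factors p1, p2 must lie in (0, 1]")
        if self.duration_s <= 0:
            raise InvalidInputError("pulse duration must be positive")


@dataclass(frozen=True)
class SaturationCondition:
    """One point of the MT saturation grid."""

    mt_flip_deg: float
    offset_hz: float
    omega1_cwpe: float
    lineshape: str = "super_lorentzian"

    def __post_init__(self) -> None:
        if self.offset_hz <= 0:
            raise InvalidInputError("offset_hz must be positive")
        if self.omega1_cwpe < 0:
            raise InvalidInputError("omega1_cwpe must be non-negative")
        if (self.omega1_cwpe == 0) != (self.mt_flip_deg == 0):
            raise InvalidInputError("omega1_cwpe must vanish exactly when mt_flip_deg is zero")
        if self.lineshape not in LINESHAPES:
            raise InvalidInputError(f"unknown lineshape {self.lineshape!r}")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence parameters of the quantitative UTE knee exam.

    The MT arm acquires 15 saturation conditions (3 MT flip angles × 5
    offsets) plus an MT-off reference; MTR uses the 1500°/2 kHz condition
    against MT-off.  The multi-echo arm acquires six echoes for T2*; the VFA
    arm four flip angles for T1; the AFI pair maps B1.  Geometry entries are
    carried as metadata only.
    """

    mt_flips_deg: tuple[float, ...] = (500.0, 1000.0, 1500.0)
    mt_offsets_hz: tuple[float, ...] = (2000.0, 5000.0, 10000.0, 20000.0, 50000.0)
    tr_mt_s: float = 0.102
    te_mt_s: float = 3.2e-5
    excitation_flip_deg: float = 7.0
    n_spokes: int = 11
    spoke_interval_s: float = 0.006
    mt_pulse: MTPulseShape = field(default_factory=MTPulseShape)
    lineshape: str = "super_lorentzian"
    te_list_ms: tuple[float, ...] = (0.032, 4.4, 8.8, 13.2, 17.6, 22.0)
    tr_t2star_s: float = 0.033
    flip_t2star_deg: float = 10.0
    vfa_flips_deg: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0)
    tr_vfa_s: float = 0.020
    afi_tr1_s: float = 0.020
    afi_tr2_s: float = 0.100
    afi_nominal_flip_deg: float = 45.0
    geometry: tuple[tuple[str, str], ...] = (
        ("fov_cm", "15 x 15 x 10.8"),
        ("matrix", "256 x 256 x 36"),
        ("slice_thickness_mm", "3.0"),
    )

    def __post_init__(self) -> None:
        for name in ("tr_mt_s", "te_mt_s", "tr_t2star_s", "tr_vfa_s", "afi_tr1_s", "afi_tr2_s"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if list(self.te_list_ms) != sorted(set(self.te_list_ms)):
            raise InvalidInputError("te_list_ms must be strictly increasing")
        if self.afi_tr2_s <= self.afi_tr1_s:
            raise InvalidInputError("AFI requires tr2 > tr1")
        if self.mt_pulse.duration_s > self.tr_mt_s:
            raise InvalidInputError("MT pulse duration cannot exceed the MT TR")

    @property
    def afi_tr_ratio(self) -> float:
        return self.afi_tr2_s / self.afi_tr1_s

    def saturation(self, mt_flip_deg: float, offset_hz: float) -> SaturationCondition:
        """Build one saturation condition with its CWPE amplitude."""
        w1 = cw_power_equivalent(
            mt_flip_deg,
            self.mt_pulse.duration_s,
            self.mt_pulse.p1,
            self.mt_pulse.p2,
            self.tr_mt_s,
        )
        return SaturationCondition(mt_flip_deg, offset_hz, w1, self.lineshape)

    def mt_grid(self) -> list[SaturationCondition]:
        """The 15-point saturation grid, flip-angle major, offsets ascending."""
        return [
            self.saturation(flip, off)
            for flip in self.mt_flips_deg
            for off in self.mt_offsets_hz
        ]

    def mtr_on_condition(self) -> SaturationCondition:
        """The MT-on condition used for MTR (highest power, lowest offset)."""
        return self.saturation(max(self.mt_flips_deg), min(self.mt_offsets_hz))


# ---------------------------------------------------------------------------
# lineshapes
# ---------------------------------------------------------------------------


def _sl_integrand(u: float, x: float) -> float:
    # x = |offset| * T2mm (dimensionless); singular direction cosine at 3u²=1
    s = 3.0 * u * u - 1.0
    if s == 0.0:
        return 0.0
    arg = 2.0 * (2.0 * math.pi * x / s) ** 2
    if arg > 700.0:
        return 0.0
    return math.sqrt(2.0 / math.pi) / abs(s) * math.exp(-arg)


def _sl_reduced(x: float) -> float:
    """Reduced super-Lorentzian φ(x) with g(Δ, T2) = T2·φ(Δ·T2)."""
    val, _ = integrate.quad(
        _sl_integrand, 0.0, 1.0, args=(x,), points=[1.0 / math.sqrt(3.0)], limit=200
    )
    return val


@lru_cache(maxsize=1)
def _sl_spline() -> CubicSpline:
    # log-log spline of the reduced lineshape; covers the full protocol range
    # of x = offset*T2mm with generous margins.  Relative accuracy ~1e-8.
    x = np.logspace(-4.5, 1.0, 700)
    phi = np.array([_sl_reduced(float(xi)) for xi in x])
    phi = np.clip(phi, 1e-300, None)
    return CubicSpline(np.log(x), np.log(phi))


def _sl_fast(x: np.ndarray | float) -> np.ndarray | float:
    """Spline-backed reduced super-Lorentzian, vectorized over x."""
    spl = _sl_spline()
    xa = np.clip(np.asarray(x, dtype=float), 10 ** -4.5, 10.0)
    out = np.exp(spl(np.log(xa)))
    return out if np.ndim(x) else float(out)


def lineshape_value(
    offset_hz: float, t2mm_s: float, kind: str = "super_lorentzian"
) -> float:
    """Absorption lineshape g(Δ) of the semisolid pool, in seconds.

    Normalized so that the integral over angular offset (both signs) is 1.
    The super-Lorentzian is evaluated by adaptive quadrature of its defining
    orientation-average integral, split at the singular direction cosine.
    Offsets with |Δ| < 1 kHz are clamped to 1 kHz for the super-Lorentzian
    (constant near-resonance extrapolation); Δ = 0 is rejected outright.
    """
    if t2mm_s <= 0:
        raise InvalidInputError("t2mm_s must be positive")
    if kind not in LINESHAPES:
        raise InvalidInputError(f"unknown lineshape {kind!r}")
    delta = abs(float(offset_hz))
    if kind == "super_lorentzian":
        if delta == 0.0:
            raise InvalidInputError("super-Lorentzian is singular on resonance (offset 0)")
        delta = max(delta, _SL_MIN_OFFSET_HZ)
        return t2mm_s * _sl_reduced(delta * t2mm_s)
    w = 2.0 * math.pi * delta * t2mm_s
    if kind == "gaussian":
        return t2mm_s / math.sqrt(2.0 * math.pi) * math.exp(-0.5 * w * w)
    return t2mm_s / math.pi / (1.0 + w * w)  # lorentzian


def _lineshape_array(offsets_hz: np.ndarray, t2mm_s: float, kind: str) -> np.ndarray:
    """Fast vectorized lineshape over an offset grid (fit/simulation path)."""
    delta = np.abs(np.asarray(offsets_hz, dtype=float))
    if kind == "super_lorentzian":
        delta = np.maximum(delta, _SL_MIN_OFFSET_HZ)
        return t2mm_s * np.asarray(_sl_fast(delta * t2mm_s))
    w = 2.0 * np.pi * delta * t2mm_s
    if kind == "gaussian":
        return t2mm_s / math.sqrt(2.0 * math.pi) * np.exp(-0.5 * w * w)
    return t2mm_s / math.pi / (1.0 + w * w)


# ---------------------------------------------------------------------------
# saturation power
# ---------------------------------------------------------------------------


def cw_power_equivalent(
    mt_flip_deg: float,
    pulse_duration_s: float,
    p1: float,
    p2: float,
    period_s: float,
) -> float:
    """Continuous-wave power-equivalent amplitude ω1_CWPE of a pulse train, rad/s.

    The peak amplitude follows from the nominal flip angle,
    ω1max = θ/(p1·τp), and the CW equivalent matches the mean squared
    amplitude over the repetition period: ω1_CWPE = ω1max·sqrt(p2·τp/TR).
    """
    if not (0 < pulse_duration_s <= period_s):
        raise InvalidInputError("pulse duration must lie in (0, period]")
    if not (0 < p1 <= 1 and 0 < p2 <= 1):
        raise InvalidInputError("shape factors p1, p2 must lie in (0, 1]")
    if mt_flip_deg < 0:
        raise InvalidInputError("mt_flip_deg must be non-negative")
    w1max = math.radians(mt_flip_deg) / (p1 * pulse_duration_s)
    return w1max * math.sqrt(p2 * pulse_duration_s / period_s)


# ---------------------------------------------------------------------------
# two-pool steady state
# ---------------------------------------------------------------------------


def _two_pool_signal(
    f: np.ndarray | float,
    r_exch: np.ndarray | float,
    t2mm_s: np.ndarray | float,
    m0: np.ndarray | float,
    t1w_s: np.ndarray | float,
    t2w_s: np.ndarray | float,
    omega1: np.ndarray | float,
    offset_hz: np.ndarray | float,
    g: np.ndarray | float,
    r1_bound: float = R1_BOUND_DEFAULT,
):
    """Closed-form steady-state water signal of the CWPE two-pool model.

    Solves the coupled longitudinal rate equations

        0 = Ra(M0a − Mza) − kab·Mza + kba·Mzb − Wa·Mza
        0 = Rb(M0b − Mzb) − kba·Mzb + kab·Mza − Wb·Mzb

    with bound-pool saturation rate Wb = π·ω1²·g(Δ, T2mm) and water direct
    saturation Wa = ω1²/((2πΔ)²·T2w) (far-offset Lorentzian), and returns
    m0·Mza/M0a.  Broadcasting numpy expression; all inputs may be arrays.
    """
    f = np.asarray(f, dtype=float)
    m0a = 1.0 - f
    m0b = f
    ra = 1.0 / np.asarray(t1w_s, dtype=float)
    rb = r1_bound
    kab = np.asarray(r_exch, dtype=float) * m0b
    kba = np.asarray(r_exch, dtype=float) * m0a
    w1 = np.asarray(omega1, dtype=float)
    delta = np.abs(np.asarray(offset_hz, dtype=float))
    wb = math.pi * w1**2 * np.asarray(g, dtype=float)
    wa = (w1 / (2.0 * math.pi * delta)) ** 2 / np.asarray(t2w_s, dtype=float)
    a = ra + kab + wa
    b = rb + kba + wb
    mza = (ra * m0a * b + kba * rb * m0b) / (a * b - kab * kba)
    return np.asarray(m0, dtype=float) * mza / m0a


def mt_steady_state_signal(
    params: TwoPoolParams,
    sat: SaturationCondition,
    protocol: AcquisitionProtocol | None = None,
    *,
    r1_bound: float = R1_BOUND_DEFAULT,
) -> float:
    """Steady-state magnitude signal under one pulsed-MT saturation condition.

    Uses the CWPE closed form (see :func:`_two_pool_signal`).  At ω1 = 0 the
    signal equals ``params.m0``; for f = 0 it reduces to the single-pool
    direct-saturation factor m0/(1 + Wa·T1w).  ``protocol`` is accepted for
    interface symmetry; the condition already carries its CWPE amplitude.
    """
    g = _lineshape_array(np.array([sat.offset_hz]), params.t2mm_s, sat.lineshape)[0]
    return float(
        _two_pool_signal(
            params.f,
            params.r_exch,
            params.t2mm_s,
            params.m0,
            params.t1w_s,
            params.t2w_s,
            sat.omega1_cwpe,
            sat.offset_hz,
            g,
            r1_bound=r1_bound,
        )
    )


def mt_grid_signals(
    params: TwoPoolParams,
    protocol: AcquisitionProtocol,
    *,
    r1_bound: float = R1_BOUND_DEFAULT,
) -> np.ndarray:
    """Signals over the protocol's 15-point MT grid (grid order)."""
    grid = protocol.mt_grid()
    w1 = np.array([c.omega1_cwpe for c in grid])
    off = np.array([c.offset_hz for c in grid])
    g = _lineshape_array(off, params.t2mm_s, protocol.lineshape)
    return np.asarray(
        _two_pool_signal(
            params.f,
            params.r_exch,
            params.t2mm_s,
            params.m0,
            params.t1w_s,
            params.t2w_s,
            w1,
            off,
            g,
            r1_bound=r1_bound,
        )
    )


# ---------------------------------------------------------------------------
# SPGR / AFI / multi-echo
# ---------------------------------------------------------------------------


def spgr_signal(m0, t1_s, tr_s, flip_deg, b1_scale=1.0):
    """Spoiled gradient echo magnitude: S = M0·sin(b1·α)(1−E1)/(1−E1·cos(b1·α))."""
    t1_s = np.asarray(t1_s, dtype=float)
    flip_deg = np.asarray(flip_deg, dtype=float)
    if np.any(t1_s <= 0) or tr_s <= 0:
        raise InvalidInputError("t1_s and tr_s must be positive")
    if np.any(np.asarray(b1_scale) <= 0):
        raise InvalidInputError("b1_scale must be positive")
    alpha = np.radians(flip_deg) * b1_scale
    if np.any(alpha < 0) or np.any(alpha >= math.pi):
        raise InvalidInputError("effective flip must lie in [0°, 180°)")
    e1 = np.exp(-tr_s / t1_s)
    return m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def ernst_angle_deg(tr_s: float, t1_s: float) -> float:
    """Flip angle maximizing the SPGR signal: cos α = exp(−TR/T1)."""
    return math.degrees(math.acos(math.exp(-tr_s / t1_s)))


def afi_ratio(flip_deg, n):
    """AFI steady-state signal ratio r = S2/S1 = (1 + n·cos α)/(n + cos α).

    ``n`` is the TR ratio TR2/TR1 (> 1).  The relation inverts as
    cos α = (r·n − 1)/(n − r), the basis of AFI B1 mapping.
    """
    if n <= 1:
        raise InvalidInputError("AFI TR ratio n must exceed 1")
    flip_deg = np.asarray(flip_deg, dtype=float)
    if np.any(flip_deg <= 0) or np.any(flip_deg >= 180):
        raise InvalidInputError("flip must lie in (0°, 180°)")
    c = np.cos(np.radians(flip_deg))
    out = (1.0 + n * c) / (n + c)
    return float(out) if np.ndim(flip_deg) == 0 else out


def multiecho_signal(s0, t2star_ms, te_ms):
    """Mono-exponential magnitude decay S(TE) = S0·exp(−TE/T2*)."""
    t2star_ms = np.asarray(t2star_ms, dtype=float)
    te_ms = np.asarray(te_ms, dtype=float)
    if np.any(t2star_ms <= 0):
        raise InvalidInputError("t2star_ms must be positive")
    if np.any(te_ms < 0):
        raise InvalidInputError("te_ms must be non-negative")
    return s0 * np.exp(-te_ms / t2star_ms)


# ---------------------------------------------------------------------------
# protocol I/O
# ---------------------------------------------------------------------------


def default_protocol() -> AcquisitionProtocol:
    """The default knee-exam protocol."""
    return AcquisitionProtocol()


def load_protocol(path: str | Path) -> AcquisitionProtocol:
    """Load an :class:`AcquisitionProtocol` from a YAML file.

    Keys mirror the dataclass fields; missing keys keep defaults.  The MT
    pulse is given as a ``mt_pulse`` mapping with ``name``, ``p1``, ``p2``,
    ``duration_s``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return default_protocol()
    if not isinstance(raw, dict):
        raise InvalidInputError("protocol file must contain a mapping")
    kwargs = dict(raw)
    if "mt_pulse" in kwargs:
        kwargs["mt_pulse"] = MTPulseShape(**kwargs["mt_pulse"])
    if "geometry" in kwargs:
        kwargs["geometry"] = tuple((str(k), str(v)) for k, v in dict(kwargs["geometry"]).items())
    for key in ("mt_flips_deg", "mt_offsets_hz", "te_list_ms", "vfa_flips_deg"):
        if key in kwargs:
            kwargs[key] = tuple(float(v) for v in kwargs[key])
    try:
        return AcquisitionProtocol(**kwargs)
    except TypeError as exc:
        raise InvalidInputError(f"bad protocol file {path}: {exc}") from exc
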