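"""Voxelwise and ROI-wise inversion of the forward signal models.

Estimators:

* :func:`compute_mtr` — magnetization transfer ratio from the MT-off / MT-on
  pair, in percent;
* :func:`fit_t2star` — mono-exponential (single-component) T2* from the
  six-echo UTE magnitudes;
* :func:`afi_b1` — B1 scale from the AFI signal pair;
* :func:`fit_t1_vfa` — T1 from the VFA series with B1-corrected flip angles;
* :func:`fit_mmf` — macromolecular fraction (with exchange rate, semisolid
  T2 and signal scale) from the 15-point MT saturation grid, with the
  measured T1 as a fixed input;
* :func:`fit_volume` — maps the scalar fitters over a masked 3D volume into a
  :class:`ParameterMap`.

All nonlinear fits use bounded trust-region least squares
(``scipy.optimize.least_squares``) with analytically sensible initializers;
the MMF fit adds a deterministic multi-start over the bound-pool fraction.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitFailureError, InvalidInputError
from .signal_models import (
    R1_BOUND_DEFAULT,
    AcquisitionProtocol,
    _lineshape_array,
    _two_pool_signal,
    spgr_signal,
)

__all__ = [
    "FitResult",
    "ParameterMap",
    "compute_mtr",
    "fit_t2star",
    "afi_b1",
    "fit_t1_vfa",
    "fit_mmf",
    "fit_volume",
    "mtr_map",
    "afi_b1_map",
    "T2STAR_BOUNDS_MS",
    "T1_BOUNDS_S",
    "MMF_BOUNDS",
]

log = logging.getLogger(__name__)

#: Physical search bounds.  T2* in ms, T1 in s; MMF-fit bounds for
#: (f, r_exch 1/s, t2mm µs).
T2STAR_BOUNDS_MS = (0.1, 200.0)
T1_BOUNDS_S = (0.05, 5.0)
MMF_BOUNDS = ((0.0, 0.5), (1.0, 500.0), (1.0, 50.0))

#: Deterministic multi-start grid for the bound-pool fraction.
MMF_STARTS = (0.05, 0.10, 0.15, 0.25)

_BOUND_RTOL = 1e-6


@dataclass
class FitResult:
    """Outcome of one scalar model fit."""

    estimate: dict[str, float]
    residual_norm: float
    converged: bool
    n_iter: int
    bounds_hit: list[str] = field(default_factory=list)
    message: str = ""


@dataclass
class ParameterMap:
    """A single-biomarker 3D map with validity mask and provenance."""

    values: np.ndarray
    mask: np.ndarray
    biomarker_name: str
    units: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise InvalidInputError("values and mask shapes differ")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def _near(x: float, bound: float, scale: float) -> bool:
    return abs(x - bound) <= _BOUND_RTOL * max(abs(scale), 1.0)


# ---------------------------------------------------------------------------
# MTR
# ---------------------------------------------------------------------------


def compute_mtr(s_off: float, s_on: float) -> float:
    """Magnetization transfer ratio MTR = 100·(S_off − S_on)/S_off, percent."""
    if s_off <= 0:
        raise InvalidInputError("MT-off signal must be positive")
    if s_on < 0:
        raise InvalidInputError("MT-on signal must be non-negative")
    return 100.0 * (s_off - s_on) / s_off


def mtr_map(
    stack_off: np.ndarray,
    stack_on: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    noise_floor: float = 0.0,
) -> ParameterMap:
    """Vectorized MTR over a volume; voxels with S_off ≤ noise floor are masked."""
    if stack_off.shape != stack_on.shape:
        raise InvalidInputError("MT-off and MT-on volumes must share a grid")
    valid = stack_off > max(noise_floor, 0.0)
    if mask is not None:
        valid &= mask.astype(bool)
    values = np.full(stack_off.shape, np.nan)
    values[valid] = 100.0 * (stack_off[valid] - stack_on[valid]) / stack_off[valid]
    return ParameterMap(values, valid, "MTR", "%", {"noise_floor": noise_floor})


# ---------------------------------------------------------------------------
# T2*
# ---------------------------------------------------------------------------


def fit_t2star(
    signals: Sequence[float],
    te_list_ms: Sequence[float],
    *,
    with_offset: bool = False,
) -> FitResult:
    """Single-component T2* fit, S(TE) = S0·exp(−TE/T2*) (+ optional offset).

    A log-linear regression initializes (S0, T2*); bounded least squares
    refines.  A best fit pinned at the upper T2* bound (non-decaying input)
    is flagged as non-converged.
    """
    s = np.asarray(signals, dtype=float)
    te = np.asarray(te_list_ms, dtype=float)
    if s.ndim != 1 or s.shape != te.shape or s.size < 3:
        raise InvalidInputError("need >= 3 echoes with matching TE list")
    if np.any(s <= 0):
        raise InvalidInputError("log-linear initializer requires positive signals")

    slope, intercept = np.polyfit(te, np.log(s), 1)
    lo, hi = T2STAR_BOUNDS_MS
    t2_init = float(np.clip(-1.0 / slope if slope < 0 else hi, lo * 1.01, hi * 0.999))
    s0_init = float(np.exp(intercept))

    if with_offset:
        def resid(p):
            return p[0] * np.exp(-te / p[1]) + p[2] - s
        x0 = [s0_init, t2_init, 0.0]
        lb, ub = [1e-12, lo, -np.inf], [np.inf, hi, np.inf]
        names = ["s0", "t2star_ms", "offset"]
    else:
        def resid(p):
            return p[0] * np.exp(-te / p[1]) - s
        x0 = [s0_init, t2_init]
        lb, ub = [1e-12, lo], [np.inf, hi]
        names = ["s0", "t2star_ms"]

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    est = dict(zip(names, map(float, sol.x)))
    bounds_hit = []
    if _near(est["t2star_ms"], hi, hi) or _near(est["t2star_ms"], lo, hi):
        bounds_hit.append("t2star_ms")
    converged = sol.success and not bounds_hit
    if bounds_hit:
        warnings.warn("T2* estimate pinned at a bound (non-decaying or degenerate input)")
    return FitResult(
        estimate=est,
        residual_norm=float(np.sqrt(np.mean(sol.fun**2))),
        converged=converged,
        n_iter=int(sol.nfev),
        bounds_hit=bounds_hit,
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# AFI B1
# ---------------------------------------------------------------------------


def afi_b1(
    s1: float,
    s2: float,
    tr1_s: float,
    tr2_s: float,
    nominal_flip_deg: float,
) -> float:
    """B1 scale from the AFI pair: α = arccos((r·n − 1)/(n − r)), b1 = α/α_nom.

    Returns NaN for ratios outside (1/n, 1) — noise-dominated or degenerate
    voxels (r = 1 maps to α = 0) — which volume mode masks out.
    """
    if tr1_s <= 0 or tr2_s <= tr1_s:
        raise InvalidInputError("AFI requires 0 < tr1 < tr2")
    if nominal_flip_deg <= 0:
        raise InvalidInputError("nominal flip must be positive")
    if s1 <= 0:
        return float("nan")
    n = tr2_s / tr1_s
    r = s2 / s1
    if not (1.0 / n < r < 1.0):
        return float("nan")
    cosa = (r * n - 1.0) / (n - r)
    if not (-1.0 < cosa < 1.0):
        return float("nan")
    return math.degrees(math.acos(cosa)) / nominal_flip_deg


def afi_b1_map(
    stack: np.ndarray,
    tr1_s: float,
    tr2_s: float,
    nominal_flip_deg: float,
    mask: np.ndarray | None = None,
) -> ParameterMap:
    """Vectorized AFI B1 map from a (..., 2) stack of the two interleaves."""
    if stack.shape[-1] != 2:
        raise InvalidInputError("AFI stack must have two volumes along the last axis")
    s1, s2 = stack[..., 0], stack[..., 1]
    n = tr2_s / tr1_s
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(s1 > 0, s2 / np.where(s1 > 0, s1, 1.0), np.nan)
        valid = (s1 > 0) & (r > 1.0 / n) & (r < 1.0)
        cosa = np.clip((r * n - 1.0) / (n - r), -1.0, 1.0)
        b1 = np.degrees(np.arccos(cosa)) / nominal_flip_deg
    if mask is not None:
        valid &= mask.astype(bool)
    values = np.where(valid, b1, np.nan)
    return ParameterMap(values, valid, "B1", "", {"tr_ratio": n})


# ---------------------------------------------------------------------------
# VFA T1
# ---------------------------------------------------------------------------


def fit_t1_vfa(
    signals: Sequence[float],
    flips_deg: Sequence[float],
    tr_s: float,
    b1_scale: float = 1.0,
) -> FitResult:
    """T1 from the VFA series: linearized SPGR (S/sin α vs S/tan α) then NLLS.

    ``b1_scale`` multiplies the nominal flip angles (AFI correction); fitting
    with the wrong B1 biases T1, which is the reason the AFI arm exists.
    """
    s = np.asarray(signals, dtype=float)
    flips = np.asarray(flips_deg, dtype=float)
    if s.shape != flips.shape or np.unique(flips).size < 2:
        raise InvalidInputError("need signals at >= 2 distinct flip angles")
    if b1_scale <= 0:
        raise InvalidInputError("b1_scale must be positive")

    alpha = np.radians(flips) * b1_scale
    lo, hi = T1_BOUNDS_S
    y = s / np.sin(alpha)
    x = s / np.tan(alpha)
    slope, intercept = np.polyfit(x, y, 1)
    if 0 < slope < 1:
        t1_init = float(np.clip(-tr_s / np.log(slope), lo * 1.01, hi * 0.999))
        m0_init = float(intercept / (1.0 - slope))
    else:
        t1_init, m0_init = 1.0, float(np.max(y))
    m0_init = max(m0_init, 1e-9)

    def resid(p):
        return spgr_signal(p[0], p[1], tr_s, flips, b1_scale) - s

    sol = least_squares(
        resid,
        [m0_init, t1_init],
        bounds=([1e-12, lo], [np.inf, hi]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        x_scale=[max(m0_init, 1.0), 1.0],
    )
    est = {"m0": float(sol.x[0]), "t1_s": float(sol.x[1])}
    bounds_hit = [
        name
        for name, val, b in (("t1_s", est["t1_s"], lo), ("t1_s", est["t1_s"], hi))
        if _near(val, b, hi)
    ]
    converged = sol.success and not bounds_hit
    return FitResult(
        estimate=est,
        residual_norm=float(np.sqrt(np.mean(sol.fun**2))),
        converged=converged,
        n_iter=int(sol.nfev),
        bounds_hit=sorted(set(bounds_hit)),
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# MMF (two-pool MT)
# ---------------------------------------------------------------------------


def _mmf_model(theta: np.ndarray, w1: np.ndarray, off: np.ndarray, lineshape: str,
               t1w_s: float, t2w_s: float, r1_bound: float) -> np.ndarray:
    f, r_exch, t2mm_us, m0 = theta
    g = _lineshape_array(off, t2mm_us * 1e-6, lineshape)
    return np.asarray(
        _two_pool_signal(f, r_exch, t2mm_us * 1e-6, m0, t1w_s, t2w_s, w1, off, g,
                         r1_bound=r1_bound)
    )


def fit_mmf(
    signal_grid: Sequence[float],
    protocol: AcquisitionProtocol,
    t1w_s: float,
    *,
    t2w_s: float = 0.030,
    r1_bound: float = R1_BOUND_DEFAULT,
    starts: Sequence[float] = MMF_STARTS,
) -> FitResult:
    """Two-pool MT fit of {f, R_exch, T2mm, M0} on the 15-point MT grid.

    ``signal_grid`` must follow :meth:`AcquisitionProtocol.mt_grid` order
    (flip-angle major, offsets ascending).  The measured water T1 enters as a
    fixed input; the water T2 is pinned (30 ms default) since the saturation
    data barely constrain it.  A deterministic multi-start over the bound-pool
    fraction guards against local minima; ties go to the smallest f.
    """
    s = np.asarray(signal_grid, dtype=float)
    grid = protocol.mt_grid()
    if s.ndim != 1 or s.size != len(grid):
        raise InvalidInputError(
            f"signal_grid must provide all {len(grid)} MT grid points in protocol order"
        )
    if not (T1_BOUNDS_S[0] < t1w_s <= T1_BOUNDS_S[1]):
        raise InvalidInputError(f"t1w_s={t1w_s} outside plausible range {T1_BOUNDS_S}")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise InvalidInputError("MT grid signals must be finite and positive")

    w1 = np.array([c.omega1_cwpe for c in grid])
    off = np.array([c.offset_hz for c in grid])
    lineshape = protocol.lineshape

    def resid(theta):
        return _mmf_model(theta, w1, off, lineshape, t1w_s, t2w_s, r1_bound) - s

    (f_lo, f_hi), (r_lo, r_hi), (t_lo, t_hi) = MMF_BOUNDS
    lb = [f_lo, r_lo, t_lo, 1e-12]
    ub = [f_hi, r_hi, t_hi, np.inf]
    m0_init = float(np.max(s)) * 1.05

    best = None
    best_key = None
    total_nfev = 0
    for f0 in starts:
        sol = least_squares(
            resid,
            [f0, 50.0, 10.0, m0_init],
            bounds=(lb, ub),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            x_scale=[0.1, 50.0, 10.0, max(m0_init, 1.0)],
        )
        total_nfev += sol.nfev
        key = (round(float(sol.cost), 12), float(sol.x[0]))  # ties -> smallest f
        if best is None or key < best_key:
            best, best_key = sol, key

    est = {
        "f": float(best.x[0]),
        "r_exch": float(best.x[1]),
        "t2mm_us": float(best.x[2]),
        "m0": float(best.x[3]),
    }
    bounds_hit = []
    for name, val, (blo, bhi) in (
        ("f", est["f"], (f_lo, f_hi)),
        ("r_exch", est["r_exch"], (r_lo, r_hi)),
        ("t2mm_us", est["t2mm_us"], (t_lo, t_hi)),
    ):
        if (name != "f" and _near(val, blo, bhi)) or _near(val, bhi, bhi):
            bounds_hit.append(name)
    converged = best.success and not bounds_hit
    return FitResult(
        estimate=est,
        residual_norm=float(np.sqrt(np.mean(best.fun**2))),
        converged=converged,
        n_iter=total_nfev,
        bounds_hit=bounds_hit,
        message=best.message,
    )


# ---------------------------------------------------------------------------
# volume fitting
# ---------------------------------------------------------------------------


def fit_volume(
    stacks: Mapping[str, np.ndarray],
    mask: np.ndarray,
    model: str,
    protocol: AcquisitionProtocol,
    settings: Mapping | None = None,
) -> ParameterMap:
    """Map a scalar fitter over every masked-in voxel of a volume.

    ``model`` selects the biomarker: ``"t2star"`` (needs ``stacks["multiecho"]``,
    (...,6)), ``"t1_vfa"`` (needs ``stacks["vfa"]`` and a ``b1_map`` in settings
    or ``stacks["afi"]``), or ``"mmf"`` (needs ``stacks["mt"]`` with MT-off as
    volume 0 followed by the 15 grid volumes, plus ``t1w_map`` in settings).
    Non-converged voxels are dropped from the output mask and counted in the
    provenance log.  Output units: T2* ms, T1 s, MMF percent.
    """
    settings = dict(settings or {})
    mask = np.asarray(mask, dtype=bool)
    if model not in ("t2star", "t1_vfa", "mmf"):
        raise InvalidInputError(f"unknown model {model!r}")

    if model == "t2star":
        stack = _require_stack(stacks, "multiecho", mask, len(protocol.te_list_ms))
    elif model == "t1_vfa":
        stack = _require_stack(stacks, "vfa", mask, len(protocol.vfa_flips_deg))
        if "b1_map" in settings:
            b1 = np.asarray(settings["b1_map"], dtype=float)
        elif "afi" in stacks:
            b1 = afi_b1_map(
                np.asarray(stacks["afi"], dtype=float),
                protocol.afi_tr1_s,
                protocol.afi_tr2_s,
                protocol.afi_nominal_flip_deg,
            ).values
        else:
            b1 = np.ones(mask.shape)
    else:
        stack = _require_stack(stacks, "mt", mask, 16)
        if "t1w_map" not in settings:
            raise InvalidInputError("mmf model requires a t1w_map in settings")
        t1w = np.asarray(settings["t1w_map"], dtype=float)

    values = np.full(mask.shape, np.nan)
    out_mask = np.zeros(mask.shape, dtype=bool)
    n_fit = n_conv = 0
    idx = np.argwhere(mask)
    if idx.size == 0:
        log.warning("fit_volume(%s): empty mask, returning empty map", model)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, j, k in idx:
            n_fit += 1
            try:
                if model == "t2star":
                    res = fit_t2star(stack[i, j, k, :], protocol.te_list_ms)
                    val = res.estimate["t2star_ms"]
                elif model == "t1_vfa":
                    b1v = b1[i, j, k] if np.ndim(b1) == 3 else float(b1)
                    if not np.isfinite(b1v):
                        continue
                    res = fit_t1_vfa(
                        stack[i, j, k, :], protocol.vfa_flips_deg, protocol.tr_vfa_s, b1v
                    )
                    val = res.estimate["t1_s"]
                else:
                    t1v = float(t1w[i, j, k])
                    if not np.isfinite(t1v):
                        continue
                    res = fit_mmf(
                        stack[i, j, k, 1:],
                        protocol,
                        t1v,
                        t2w_s=settings.get("t2w_s", 0.030),
                    )
                    val = 100.0 * res.estimate["f"]
            except InvalidInputError:
                continue
            if res.converged:
                n_conv += 1
                values[i, j, k] = val
                out_mask[i, j, k] = True

    name, units = {
        "t2star": ("T2*", "ms"),
        "t1_vfa": ("T1", "s"),
        "mmf": ("MMF", "%"),
    }[model]
    prov = {
        "model": model,
        "n_attempted": n_fit,
        "n_converged": n_conv,
        "n_rejected": n_fit - n_conv,
        "settings": json.dumps(
            {k: v for k, v in settings.items() if np.ndim(v) == 0}, sort_keys=True
        ),
    }
    log.info("fit_volume(%s): %d/%d voxels converged", model, n_conv, n_fit)
    return ParameterMap(values, out_mask, name, units, prov)


def _require_stack(
    stacks: Mapping[str, np.ndarray], key: str, mask: np.ndarray, n_vols: int
) -> np.ndarray:
    if key not in stacks:
        raise InvalidInputError(f"missing protocol arm {key!r}")
    stack = np.asarray(stacks[key], dtype=float)
    if stack.ndim != 4 or stack.shape[:3] != mask.shape:
        raise InvalidInputError(f"stack {key!r} not congruent with mask grid")
    if stack.shape[3] != n_vols:
        raise InvalidInputError(f"stack {key!r} must have {n_vols} volumes, got {stack.shape[3]}")
    return stack
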