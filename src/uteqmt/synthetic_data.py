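"""Digital phantoms and simulated patient cohorts.

Two generators stand in for the (non-public) in vivo data:

* :func:`make_phantom` builds a layered slab phantom of the osteochondral
  junction (OCJ): superficial cartilage / OCJ band / subchondral bone over a
  background, each layer carrying two-pool MT parameters, T1 and T2* inside
  the ranges observed in vivo.  :func:`simulate_protocol` evaluates the
  forward models on the full acquisition grid and adds Rician noise, giving
  image stacks the fitting pipeline can invert back to the truth maps.

* :func:`draw_cohort` draws per-subject biomarker triplets (MMF %, MTR %,
  T2* ms) for the two radiographic osteoarthritis groups — normal/subtle
  (Kellgren–Lawrence 0–1, n = 21, KL counts 17/4) and mild-to-moderate
  (KL 2–3, n = 24, KL counts 9/15) — from truncated normal distributions
  with the observed group means and SDs.  :func:`add_reader_noise` appends a
  synthetic second-reader pair calibrated to a target intraclass correlation.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError
from .signal_models import (
    AcquisitionProtocol,
    _lineshape_array,
    _two_pool_signal,
    afi_ratio,
    spgr_signal,
)

__all__ = [
    "LAYERS",
    "PhantomSpec",
    "Phantom",
    "GroupDefinition",
    "table1_groups",
    "make_phantom",
    "simulate_protocol",
    "rician",
    "draw_cohort",
    "add_reader_noise",
    "COHORT_COLUMNS",
    "BIOMARKER_COLUMNS",
]

#: Layer codes in the label volume.
LAYERS = {"background": 0, "superficial_cartilage": 1, "ocj": 2, "subchondral_bone": 3}

#: Cohort CSV schema (order matters for the documented header).
BIOMARKER_COLUMNS = ("mmf_percent", "mtr_percent", "t2star_ms")
COHORT_COLUMNS = ("subject_id", "kl_grade", "group") + BIOMARKER_COLUMNS


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerTruth:
    """Ground-truth tissue parameters of one phantom layer."""

    f: float
    r_exch: float
    t2mm_us: float
    t1w_s: float
    t2star_ms: float


_DEFAULT_LAYERS: dict[str, LayerTruth] = {
    # deep cartilage above the junction: more water, longer T2*
    "superficial_cartilage": LayerTruth(f=0.11, r_exch=40.0, t2mm_us=12.0, t1w_s=1.4, t2star_ms=24.0),
    # OCJ band: collagen-rich, high bound fraction, short T2*
    "ocj": LayerTruth(f=0.16, r_exch=60.0, t2mm_us=10.0, t1w_s=1.0, t2star_ms=17.0),
    # subchondral bone plate: lowest water content
    "subchondral_bone": LayerTruth(f=0.18, r_exch=70.0, t2mm_us=9.0, t1w_s=0.8, t2star_ms=15.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of the layered OCJ slab phantom.

    Layers are stacked along axis 0: background margin, superficial
    (deep-articular) cartilage, the 2–3 voxel OCJ band, subchondral bone,
    and a trailing background margin.  ``noise_sigma`` is the Rician noise
    scale relative to the signal scale ``m0``.
    """

    shape: tuple[int, int, int] = (64, 64, 8)
    n_bg_top: int = 20
    n_superficial: int = 16
    n_ocj: int = 3
    n_bone: int = 16
    layers: Mapping[str, LayerTruth] = field(default_factory=lambda: dict(_DEFAULT_LAYERS))
    m0: float = 100.0
    t2w_s: float = 0.030
    b1_range: tuple[float, float] = (0.95, 1.05)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_superficial, self.n_ocj, self.n_bone) < 1:
            raise InvalidInputError("every tissue layer must be at least 1 voxel thick")
        if self.n_bg_top + self.n_superficial + self.n_ocj + self.n_bone > self.shape[0]:
            raise InvalidInputError("layers exceed the grid along axis 0")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be non-negative")
        missing = set(_DEFAULT_LAYERS) - set(self.layers)
        if missing:
            raise InvalidInputError(f"missing layer definitions: {sorted(missing)}")


@dataclass
class Phantom:
    """Truth maps (per-voxel tissue parameters) plus the layer label volume."""

    labels: np.ndarray  # int codes per LAYERS
    maps: dict[str, np.ndarray]  # f, r_exch, t2mm_s, t1w_s, t2star_ms, m0, b1
    spec: PhantomSpec

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def layer_mask(self, name: str) -> np.ndarray:
        return self.labels == LAYERS[name]


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the layered slab phantom (deterministic; the seed only drives noise)."""
    labels = np.zeros(spec.shape, dtype=np.int8)
    i0 = spec.n_bg_top
    bands = (
        ("superficial_cartilage", spec.n_superficial),
        ("ocj", spec.n_ocj),
        ("subchondral_bone", spec.n_bone),
    )
    for name, n in bands:
        labels[i0 : i0 + n] = LAYERS[name]
        i0 += n

    maps = {
        key: np.zeros(spec.shape)
        for key in ("f", "r_exch", "t2mm_s", "t1w_s", "t2star_ms", "m0")
    }
    # background keeps harmless placeholders so the forward model stays finite
    maps["t1w_s"][:] = 1.0
    maps["t2mm_s"][:] = 10e-6
    maps["t2star_ms"][:] = 20.0
    maps["r_exch"][:] = 50.0
    for name, truth in spec.layers.items():
        sel = labels == LAYERS[name]
        maps["f"][sel] = truth.f
        maps["r_exch"][sel] = truth.r_exch
        maps["t2mm_s"][sel] = truth.t2mm_us * 1e-6
        maps["t1w_s"][sel] = truth.t1w_s
        maps["t2star_ms"][sel] = truth.t2star_ms
        maps["m0"][sel] = spec.m0
    # smooth transmit-field gradient along axis 1
    b1_line = np.linspace(*spec.b1_range, spec.shape[1])
    maps["b1"] = np.broadcast_to(b1_line[None, :, None], spec.shape).copy()
    return Phantom(labels=labels, maps=maps, spec=spec)


# ---------------------------------------------------------------------------
# protocol simulation
# ---------------------------------------------------------------------------


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rician sample: |signal + N(0, σ) + i·N(0, σ)| applied elementwise."""
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, np.shape(signal))
    im = rng.normal(0.0, sigma, np.shape(signal))
    return np.hypot(re, im)


def simulate_protocol(
    phantom: Phantom,
    protocol: AcquisitionProtocol,
    noise_sigma: float | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Simulate the four acquisition arms on a phantom's truth maps.

    Returns 4D stacks: ``mt`` (MT-off then the 15 grid conditions, 16
    volumes), ``multiecho`` (6 echoes), ``vfa`` (4 flips), ``afi`` (2
    interleaves).  Noiseless output equals the forward models exactly; with
    ``noise_sigma`` σ (absolute scale σ·m0), every magnitude sample is Rician.
    Per-arm signal scales are arbitrary and independent, as in practice.
    """
    if noise_sigma is None:
        noise_sigma = phantom.spec.noise_sigma
    if noise_sigma < 0:
        raise InvalidInputError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    m = phantom.maps
    shape = phantom.labels.shape
    sigma_abs = noise_sigma * phantom.spec.m0
    t2w = phantom.spec.t2w_s

    # --- MT arm -----------------------------------------------------------
    grid = protocol.mt_grid()
    mt = np.zeros(shape + (1 + len(grid),))
    mt[..., 0] = m["m0"]  # MT-off: unsaturated steady state
    for j, cond in enumerate(grid, start=1):
        mt[..., j] = _mt_condition_volume(m, cond, t2w)
    # --- multi-echo arm ---------------------------------------------------
    te = np.asarray(protocol.te_list_ms)
    me = m["m0"][..., None] * np.exp(-te[None, None, None, :] / m["t2star_ms"][..., None])
    # --- VFA arm ----------------------------------------------------------
    vfa = np.stack(
        [
            spgr_signal(m["m0"], m["t1w_s"], protocol.tr_vfa_s, flip, m["b1"])
            for flip in protocol.vfa_flips_deg
        ],
        axis=-1,
    )
    # --- AFI pair ---------------------------------------------------------
    alpha_eff = m["b1"] * protocol.afi_nominal_flip_deg
    ratio = afi_ratio(np.clip(alpha_eff, 1e-3, 179.0), protocol.afi_tr_ratio)
    s1 = 0.5 * m["m0"]
    afi = np.stack([s1, s1 * ratio], axis=-1)

    stacks = {"mt": mt, "multiecho": me, "vfa": vfa, "afi": afi}
    if sigma_abs > 0:
        stacks = {k: rician(v, sigma_abs, rng) for k, v in stacks.items()}
    return stacks


def _mt_condition_volume(m: Mapping[str, np.ndarray], cond, t2w_s: float) -> np.ndarray:
    """Two-pool steady state for one saturation condition over a whole volume.

    The lineshape depends on voxelwise T2mm; layered phantoms carry only a
    handful of distinct values, so evaluate per unique T2mm.
    """
    t2mm = m["t2mm_s"]
    out = np.zeros(t2mm.shape)
    for val in np.unique(t2mm):
        sel = t2mm == val
        g = _lineshape_array(np.array([cond.offset_hz]), float(val), cond.lineshape)[0]
        out[sel] = _two_pool_signal(
            m["f"][sel], m["r_exch"][sel], val, m["m0"][sel], m["t1w_s"][sel],
            t2w_s, cond.omega1_cwpe, cond.offset_hz, g,
        )
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupDefinition:
    """Population model of one radiographic OA group."""

    name: str
    n_subjects: int
    kl_composition: Mapping[int, int]
    mmf_mean: float
    mmf_sd: float
    mtr_mean: float
    mtr_sd: float
    t2star_mean: float
    t2star_sd: float

    def __post_init__(self) -> None:
        if sum(self.kl_composition.values()) != self.n_subjects:
            raise InvalidInputError(f"group {self.name}: KL counts must sum to n_subjects")
        if min(self.mmf_sd, self.mtr_sd, self.t2star_sd) <= 0:
            raise InvalidInputError(f"group {self.name}: SDs must be positive")

    def moments(self, column: str) -> tuple[float, float]:
        return {
            "mmf_percent": (self.mmf_mean, self.mmf_sd),
            "mtr_percent": (self.mtr_mean, self.mtr_sd),
            "t2star_ms": (self.t2star_mean, self.t2star_sd),
        }[column]


def table1_groups() -> list[GroupDefinition]:
    """The study's two-group population model (group means ± SD; KL counts).

    Normal/subtle (KL 0–1): MMF 15.8 ± 1.4 %, MTR 42.5 ± 2.5 %,
    T2* 19.7 ± 2.6 ms, n = 21 (17 KL0 + 4 KL1).  Mild-to-moderate (KL 2–3):
    MMF 13.6 ± 1.2 %, MTR 38.3 ± 2.9 %, T2* 21.6 ± 3.8 ms, n = 24
    (9 KL2 + 15 KL3).
    """
    return [
        GroupDefinition(
            name="normal_subtle",
            n_subjects=21,
            kl_composition={0: 17, 1: 4},
            mmf_mean=15.8, mmf_sd=1.4,
            mtr_mean=42.5, mtr_sd=2.5,
            t2star_mean=19.7, t2star_sd=2.6,
        ),
        GroupDefinition(
            name="mild_moderate",
            n_subjects=24,
            kl_composition={2: 9, 3: 15},
            mmf_mean=13.6, mmf_sd=1.2,
            mtr_mean=38.3, mtr_sd=2.9,
            t2star_mean=21.6, t2star_sd=3.8,
        ),
    ]


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal truncated below at 0 (biomarkers are positive quantities)."""
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def draw_cohort(
    groups: Sequence[GroupDefinition] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-subject cohort table from the group population models.

    One row per subject with columns :data:`COHORT_COLUMNS`; KL grades are
    assigned exactly per composition and group membership is the deterministic
    function of KL grade (0–1 normal/subtle, 2–3 mild-to-moderate).
    Biomarkers are independent truncated-normal draws (no between-biomarker
    correlation by default).
    """
    if groups is None:
        groups = table1_groups()
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for grp in groups:
        kl = np.concatenate([np.full(cnt, grade) for grade, cnt in sorted(grp.kl_composition.items())])
        draws = {col: _truncated_normal(*grp.moments(col), grp.n_subjects, rng) for col in BIOMARKER_COLUMNS}
        for i in range(grp.n_subjects):
            sid += 1
            rows.append(
                {
                    "subject_id": f"S{sid:03d}",
                    "kl_grade": int(kl[i]),
                    "group": grp.name,
                    **{col: float(draws[col][i]) for col in BIOMARKER_COLUMNS},
                }
            )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def add_reader_noise(
    cohort: pd.DataFrame,
    icc_target: float,
    seed: int = 0,
    biomarkers: Sequence[str] = BIOMARKER_COLUMNS,
) -> pd.DataFrame:
    """Append two synthetic reader columns per biomarker at a target ICC.

    Each reading is truth + independent N(0, σ_e²) with
    σ_e² = σ_between²·(1 − ICC)/ICC, so the population two-way single-measure
    ICC of the pair equals ``icc_target`` exactly.  In the ICC → 1 limit both
    readings coincide with the truth column.
    """
    if not 0.0 < icc_target < 1.0:
        raise InvalidInputError("icc_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for col in biomarkers:
        truth = cohort[col].to_numpy(dtype=float)
        var_b = float(np.var(truth, ddof=1))
        if var_b == 0:
            raise InvalidInputError(f"degenerate cohort: zero variance in {col}")
        sd_e = np.sqrt(var_b * (1.0 - icc_target) / icc_target)
        for reader in (1, 2):
            out[f"{col}_reader{reader}"] = truth + rng.normal(0.0, sd_e, truth.size)
    return out
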