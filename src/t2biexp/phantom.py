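"""Synthetic multi-echo phantoms and two-group cohorts.

Stands in for clinical temporomandibular-joint (TMJ) relaxometry data:
rectangular regions of interest (ROIs) on a small voxel grid, each
filled with biexponential decay curves whose parameters are drawn from
published reference distributions for seven stomatognathic structures
(disk, retrodiscal tissue, condylar bone marrow, masseter, lateral and
medial pterygoid muscles, molar pulp), in two clinical groups: joints
with and joints without disk displacement.

Amplitudes are normalised so that ``amp_short + amp_long = 1`` per
voxel, making amplitudes directly the component fractions.  Between-
subject variability is modelled at the ROI-mean level with the
published across-study standard deviations; within-ROI voxel scatter is
a separate knob that defaults to zero because no voxelwise scatter is
reported for these tissues.  Acquisition noise is additive Gaussian by
default (a high-SNR approximation for magnitude MRI), with a Rician
option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal import BiexpParams, EchoTimes, biexp_signal

__all__ = [
    "STRUCTURES",
    "GROUPS",
    "TissueSpec",
    "ROIPlacement",
    "PhantomSpec",
    "CohortSpec",
    "TruthMaps",
    "reference_tissue",
    "sample_voxel_params",
    "make_phantom",
    "add_noise",
    "make_cohort",
]

STRUCTURES = (
    "disk",
    "retrodiscal_tissue",
    "bone_marrow",
    "masseter",
    "pterygoid_lateralis",
    "pterygoid_medialis",
    "pulp",
)
GROUPS = ("displacement", "no_displacement")

#: Minimum admissible T2 draw (ms); normal draws are truncated above this.
_T2_FLOOR_MS = 1.0
#: Fraction draws are truncated to this open interval.
_FRAC_LO, _FRAC_HI = 0.01, 0.99


@dataclass(frozen=True)
class TissueSpec:
    """Generative truth for one structure in one clinical group.

    Means and standard deviations describe the across-subject
    distribution of ROI-mean short/long T2 (ms) and of the short
    fraction.  The long fraction is ``1 - frac_short`` by construction,
    since per-voxel fractions must sum to one.
    """

    name: str
    group: str
    mean_t2_short: float
    sd_t2_short: float
    mean_t2_long: float
    sd_t2_long: float
    mean_frac_short: float
    sd_frac_short: float

    def __post_init__(self) -> None:
        if self.mean_t2_short <= 0 or self.mean_t2_long <= 0:
            raise ValueError("mean T2 values must be positive")
        if self.mean_t2_short >= self.mean_t2_long:
            raise ValueError("mean_t2_short must be below mean_t2_long")
        if min(self.sd_t2_short, self.sd_t2_long, self.sd_frac_short) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 < self.mean_frac_short < 1.0:
            raise ValueError("mean_frac_short must lie in (0, 1)")

    def zero_sd(self) -> "TissueSpec":
        """Copy of the spec with all variability removed."""
        return replace(self, sd_t2_short=0.0, sd_t2_long=0.0,
                       sd_frac_short=0.0)


# Reference ROI-mean values (short T2 mean/SD, long T2 mean/SD, short
# fraction mean/SD) per structure and group, from published 1.5 T TMJ
# biexponential relaxometry of 18 displaced / 32 non-displaced joints.
_REFERENCE_ROWS = {
    # (structure, group): (t2s, sd, t2l, sd, frac_s, sd)
    ("disk", "displacement"): (13.3, 4.5, 105.9, 15.5, 0.708, 0.043),
    ("disk", "no_displacement"): (12.9, 2.1, 107.8, 16.6, 0.718, 0.033),
    ("retrodiscal_tissue", "displacement"): (22.6, 5.2, 105.7, 12.4, 0.637, 0.039),
    ("retrodiscal_tissue", "no_displacement"): (17.6, 3.0, 105.3, 12.0, 0.666, 0.030),
    ("bone_marrow", "displacement"): (37.8, 7.3, 123.7, 19.6, 0.411, 0.042),
    ("bone_marrow", "no_displacement"): (42.4, 5.3, 114.4, 7.4, 0.392, 0.033),
    ("masseter", "displacement"): (25.3, 4.8, 94.9, 11.6, 0.606, 0.043),
    ("masseter", "no_displacement"): (23.6, 3.3, 92.0, 6.5, 0.614, 0.020),
    ("pterygoid_lateralis", "displacement"): (25.9, 3.1, 98.8, 7.9, 0.583, 0.027),
    ("pterygoid_lateralis", "no_displacement"): (26.5, 2.6, 99.3, 6.4, 0.589, 0.024),
    ("pterygoid_medialis", "displacement"): (25.3, 2.0, 99.5, 7.7, 0.604, 0.021),
    ("pterygoid_medialis", "no_displacement"): (22.3, 2.1, 97.1, 5.0, 0.607, 0.019),
    ("pulp", "displacement"): (26.8, 4.8, 146.7, 16.8, 0.773, 0.051),
    ("pulp", "no_displacement"): (21.6, 3.2, 147.0, 11.1, 0.489, 0.053),
}


def reference_tissue(name: str, group: str) -> TissueSpec:
    """Look up the reference :class:`TissueSpec` for a structure/group."""
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
    try:
        row = _REFERENCE_ROWS[(name, group)]
    except KeyError:
        raise KeyError(
            f"unknown structure {name!r}; expected one of {STRUCTURES}"
        ) from None
    return TissueSpec(name, group, *row)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=1000) -> float:
    """Draw from N(mean, sd) restricted to (lo, hi) by rejection."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    # Pathological spec (mass almost entirely outside the band); clip.
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_voxel_params(tissue: TissueSpec, seed) -> BiexpParams:
    """Draw one voxel's biexponential truth from a tissue distribution.

    T2 values come from normals truncated below at 1 ms, re-drawn as a
    pair until ``t2_short < t2_long``; the short fraction is truncated
    to (0.01, 0.99); amplitudes are ``(frac_short, 1 - frac_short)``.
    With all SD fields zero the draw equals the configured means
    exactly.  Deterministic for a fixed seed or generator state.
    """
    rng = _rng(seed)
    for _ in range(1000):
        t2s = _truncated_normal(rng, tissue.mean_t2_short, tissue.sd_t2_short,
                                _T2_FLOOR_MS, np.inf)
        t2l = _truncated_normal(rng, tissue.mean_t2_long, tissue.sd_t2_long,
                                _T2_FLOOR_MS, np.inf)
        if t2s < t2l or (tissue.sd_t2_short == 0 and tissue.sd_t2_long == 0):
            break
    else:  # pragma: no cover - requires overlapping distributions
        t2s, t2l = sorted((t2s, t2l))
    fs = _truncated_normal(rng, tissue.mean_frac_short, tissue.sd_frac_short,
                           _FRAC_LO, _FRAC_HI)
    return BiexpParams(amp_short=fs, amp_long=1.0 - fs,
                       t2_short=t2s, t2_long=t2l)


@dataclass(frozen=True)
class ROIPlacement:
    """Axis-aligned box ROI, half-open voxel index ranges per axis."""

    label: int
    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("ROI labels must be positive integers")
        for lo, hi in (self.x, self.y, self.z):
            if hi <= lo or lo < 0:
                raise ValueError("ROI ranges must be non-empty and >= 0")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.x), slice(*self.y), slice(*self.z))

    @property
    def n_voxels(self) -> int:
        return ((self.x[1] - self.x[0]) * (self.y[1] - self.y[0])
                * (self.z[1] - self.z[0]))


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and acquisition model of one synthetic multi-echo volume.

    The default grid is deliberately small (32 x 32 x 1 voxels rather
    than an acquisition-sized matrix) because per-voxel physics does
    not depend on matrix size.  ``sigmas`` is either a scalar or one
    value per echo; ``noise`` selects the noise model.
    """

    rois: tuple[tuple[TissueSpec, ROIPlacement], ...]
    shape: tuple[int, int, int] = (32, 32, 1)
    echo_times: EchoTimes = field(default_factory=EchoTimes.default)
    noise: str = "none"  # none | gaussian | rician
    sigmas: float | tuple[float, ...] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        occupancy = np.zeros(self.shape, dtype=int)
        for _, roi in self.rois:
            sl = roi.slices
            if (roi.x[1] > self.shape[0] or roi.y[1] > self.shape[1]
                    or roi.z[1] > self.shape[2]):
                raise ValueError(f"ROI {roi.label} exceeds grid {self.shape}")
            occupancy[sl] += 1
        if np.any(occupancy > 1):
            raise ValueError("ROIs overlap")

    def sigma_vector(self) -> np.ndarray:
        n = len(self.echo_times)
        sig = np.broadcast_to(np.asarray(self.sigmas, dtype=float), (n,))
        if np.any(sig < 0):
            raise ValueError("noise sigmas must be non-negative")
        return np.array(sig)


@dataclass
class TruthMaps:
    """Per-voxel generative truth recorded alongside a phantom."""

    t2_short: np.ndarray
    t2_long: np.ndarray
    frac_short: np.ndarray
    labels: np.ndarray  # int, 0 = background


def make_phantom(spec: PhantomSpec, seed=None) -> tuple[np.ndarray, TruthMaps]:
    """Render a 4-D multi-echo volume (x, y, z, echo) plus truth maps.

    ROI voxels carry the noiseless closed-form decay of their sampled
    parameters; background voxels are zero before noise.  Noise is
    applied per the spec's model and sigmas.
    """
    rng = _rng(spec.seed if seed is None else seed)
    nx, ny, nz = spec.shape
    n_echo = len(spec.echo_times)
    vol = np.zeros((nx, ny, nz, n_echo))
    truth = TruthMaps(
        t2_short=np.full(spec.shape, np.nan),
        t2_long=np.full(spec.shape, np.nan),
        frac_short=np.full(spec.shape, np.nan),
        labels=np.zeros(spec.shape, dtype=np.int16),
    )
    for tissue, roi in spec.rois:
        sl = roi.slices
        truth.labels[sl] = roi.label
        idx = np.argwhere(truth.labels == roi.label)
        for i, j, k in idx:
            p = sample_voxel_params(tissue, rng)
            vol[i, j, k, :] = biexp_signal(p, spec.echo_times)
            truth.t2_short[i, j, k] = p.t2_short
            truth.t2_long[i, j, k] = p.t2_long
            truth.frac_short[i, j, k] = p.amp_short / p.total_amplitude
    if spec.noise != "none":
        vol = add_noise(vol, spec.sigma_vector(), spec.noise, rng)
    return vol, truth


def add_noise(volume: np.ndarray, sigmas, model: str, seed) -> np.ndarray:
    """Apply seeded acquisition noise to a multi-echo volume.

    ``gaussian``: additive zero-mean noise per echo.  ``rician``: the
    magnitude of the complex signal with independent Gaussian noise on
    both quadratures, ``|S + n1 + i n2|`` — on zero signal this yields
    Rayleigh-distributed magnitudes with mean ``sigma * sqrt(pi/2)``.
    """
    rng = _rng(seed)
    vol = np.asarray(volume, dtype=float)
    n_echo = vol.shape[-1]
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), (n_echo,))
    if np.asarray(sigmas).ndim == 1 and len(np.asarray(sigmas)) != n_echo:
        raise ValueError(
            f"got {len(np.asarray(sigmas))} sigmas for {n_echo} echoes")
    if np.any(sig < 0):
        raise ValueError("noise sigmas must be non-negative")
    if model == "gaussian":
        return vol + rng.normal(0.0, 1.0, vol.shape) * sig
    if model == "rician":
        n1 = rng.normal(0.0, 1.0, vol.shape) * sig
        n2 = rng.normal(0.0, 1.0, vol.shape) * sig
        return np.hypot(vol + n1, n2)
    if model == "none":
        return vol.copy()
    raise ValueError(f"unknown noise model {model!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort layout: joints with and without disk displacement.

    Defaults reproduce the reference study design: 18 displaced and 32
    non-displaced joints, every structure measured in every subject.
    Subject-level ROI means are drawn from the reference tissue
    distributions (the across-study SD columns).
    """

    n_displacement: int = 18
    n_no_displacement: int = 32
    structures: tuple[str, ...] = STRUCTURES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_displacement < 1 or self.n_no_displacement < 1:
            raise ValueError("both groups need at least one subject")


def make_cohort(spec: CohortSpec, seed=None,
                tissue_overrides: dict | None = None) -> pd.DataFrame:
    """Draw per-subject ROI-mean parameter sets for a two-group cohort.

    Returns a tidy frame with one row per subject x structure and
    columns ``subject, group, structure, t2_short, t2_long, frac_short,
    frac_long``.  ``tissue_overrides`` maps ``(structure, group)`` to a
    replacement :class:`TissueSpec` (e.g. for null simulations where
    both groups share one distribution).
    """
    rng = _rng(spec.seed if seed is None else seed)
    overrides = tissue_overrides or {}
    rows = []
    sizes = {"displacement": spec.n_displacement,
             "no_displacement": spec.n_no_displacement}
    subject = 0
    for group in GROUPS:
        for _ in range(sizes[group]):
            subject += 1
            for structure in spec.structures:
                tissue = overrides.get((structure, group),
                                       reference_tissue(structure, group))
                p = sample_voxel_params(tissue, rng)
                fs = p.amp_short / p.total_amplitude
                rows.append({
                    "subject": subject,
                    "group": group,
                    "structure": structure,
                    "t2_short": p.t2_short,
                    "t2_long": p.t2_long,
                    "frac_short": fs,
                    "frac_long": 1.0 - fs,
                })
    return pd.DataFrame(rows)
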