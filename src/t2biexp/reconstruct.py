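"""Voxelwise weighted mono-/biexponential fitting and map assembly.

Each voxel's multi-echo decay is fitted twice by minimising a weighted
mean squared error (MSE) with Powell's conjugate-direction method: a
2-parameter monoexponential fit and a 4-parameter biexponential fit.
Echo weights, proportional to the inverse noise variance of each echo
image, compensate for differing noise levels between echoes.  The
reconstruction is purely voxel-independent — no spatial coupling — so
boundaries of uniform regions are preserved by construction.

A voxel is demoted from biexponential to monoexponential/degenerate
when the two-pool fit collapses: a relaxation time at zero, the two T2
components closer than 1 ms, a vanishing amplitude, or a mono fit with
lower MSE than the biexponential fit.  Demoted voxels are excluded
from the biexponential maps (NaN sentinel, validity=False).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .optimize import powell_minimize
from .signal import BiexpParams, EchoTimes, MonoParams, _tes_array

__all__ = [
    "T2_MIN_MS",
    "T2_MAX_MS",
    "MonoFit",
    "BiexpFit",
    "FitResult",
    "MapStack",
    "estimate_weights",
    "weighted_mse",
    "fit_mono",
    "fit_biexp",
    "classify_voxel",
    "fit_voxel",
    "reconstruct_volume",
]

#: Admissible T2 search range (ms).  The echo grid (13..104 ms) carries
#: sensitivity to roughly 5-500 ms; the bounds leave generous margin.
T2_MIN_MS = 0.01
T2_MAX_MS = 2000.0

#: Demotion thresholds: a T2 at the lower search bound counts as "zero",
#: and an amplitude below 1e-6 of the amplitude sum counts as zero.
EPS_T2_MS = 0.01
EPS_AMP_REL = 1e-6
#: Minimum separation (ms) between T2 components of a genuine two-pool fit.
MIN_T2_SEPARATION_MS = 1.0

#: Deterministic coarse (t2_short, t2_long) multistart lattice (ms).
_START_LATTICE = ((10.0, 80.0), (30.0, 150.0), (15.0, 120.0), (45.0, 90.0))

_MODEL_CODES = {"degenerate": 0, "monoexponential": 1, "biexponential": 2}


@dataclass
class MonoFit:
    params: MonoParams | None
    mse: float
    degenerate: bool = False


@dataclass
class BiexpFit:
    params: BiexpParams
    mse: float
    converged: bool
    n_restarts: int = 0


@dataclass
class FitResult:
    """Combined per-voxel fit: both models plus the adjudicated label."""

    model: str  # biexponential | monoexponential | degenerate
    biexp: BiexpFit | None
    mono: MonoFit


def estimate_weights(sigmas=None, *, background=None) -> np.ndarray:
    """Per-echo weights proportional to the inverse noise variance.

    Either pass per-echo noise ``sigmas`` directly, or a ``background``
    array of shape (n_echoes, n_voxels) of signal-free voxels from
    which each echo's sigma is estimated as the standard deviation
    (at least 20 voxels per echo).  Weights are normalised to mean 1.
    """
    if (sigmas is None) == (background is None):
        raise ValueError("pass exactly one of sigmas or background")
    if sigmas is not None:
        sig = np.asarray(sigmas, dtype=float)
        if np.any(sig <= 0):
            raise ValueError("sigmas must be positive")
    else:
        bg = np.asarray(background, dtype=float)
        if bg.ndim != 2 or bg.shape[1] < 20:
            raise ValueError("background needs >= 20 voxels per echo")
        sig = bg.std(axis=1, ddof=1)
        if np.any(sig == 0):
            raise ValueError("zero-variance background; cannot estimate noise")
    w = 1.0 / sig**2
    return w / w.mean()


def _weights_array(w, n: int) -> np.ndarray:
    if w is None:
        return np.ones(n)
    arr = np.asarray(w, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {arr.shape}")
    if np.any(arr < 0) or not np.any(arr > 0):
        raise ValueError("weights must be non-negative with at least one > 0")
    return arr


def weighted_mse(observed, predicted, weights=None) -> float:
    """Weighted mean squared error: sum_i w_i (obs_i - pred_i)^2 / n."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    w = _weights_array(weights, obs.size)
    r = obs - pred
    return float(np.sum(w * r * r) / obs.size)


def _loglinear_seed(te, sig, w) -> tuple[float, float] | None:
    """Weighted log-linear regression -> (amp, t2), or None if unusable."""
    pos = sig > 0
    if pos.sum() < 2:
        return None
    t, y = te[pos], np.log(sig[pos])
    ww = w[pos] * sig[pos] ** 2  # delta-method weights for the log transform
    try:
        slope, intercept = np.polyfit(t, y, 1, w=np.sqrt(ww))
    except (np.linalg.LinAlgError, ValueError):
        return None
    if slope >= 0:
        return float(np.exp(intercept)), T2_MAX_MS
    t2 = float(np.clip(-1.0 / slope, T2_MIN_MS, T2_MAX_MS))
    return float(np.exp(intercept)), t2


def fit_mono(signal, tes, weights=None, *, max_cycles=60) -> MonoFit:
    """Weighted 2-parameter monoexponential fit.

    Seeded by log-linear regression on the strictly positive samples,
    refined with Powell.  An all-nonpositive curve yields a degenerate
    result (no parameters, zero-amplitude MSE).
    """
    te = _tes_array(tes)
    sig = np.asarray(signal, dtype=float)
    w = _weights_array(weights, te.size)
    if sig.shape != te.shape:
        raise ValueError("signal and echo-time lengths differ")
    n = te.size
    if np.max(sig) <= 0:
        return MonoFit(params=None,
                       mse=float(np.sum(w * sig * sig) / n),
                       degenerate=True)
    seed = _loglinear_seed(te, sig, w)
    if seed is None:
        seed = (float(sig.max()), 50.0)
    amp_hi = 10.0 * float(sig.max())
    lo = np.array([0.0, T2_MIN_MS])
    hi = np.array([amp_hi, T2_MAX_MS])

    def obj(x):
        a, t2 = np.clip(x, lo, hi)
        r = sig - a * np.exp(-te / t2)
        return np.sum(w * r * r) / n

    x0 = np.clip(np.array(seed), lo, hi)
    step = np.maximum(0.1 * np.abs(x0), [0.01 * sig.max(), 1.0])
    res = powell_minimize(obj, x0, max_cycles=max_cycles, initial_step=step)
    a, t2 = np.clip(res.x, lo, hi)
    return MonoFit(params=MonoParams(amp=float(a), t2=float(t2)),
                   mse=float(res.fun))


def _split_seed(te, sig, w) -> np.ndarray:
    """Two-segment log-linear start: tail -> long pool, head residual -> short."""
    scale = float(sig.max())
    tail = _loglinear_seed(te[-3:], sig[-3:], w[-3:])
    if tail is None:
        a_l, t2_l = 0.4 * scale, 100.0
    else:
        a_l, t2_l = tail
        t2_l = float(np.clip(t2_l, 20.0, T2_MAX_MS))
    resid = sig[:3] - a_l * np.exp(-te[:3] / t2_l)
    head = _loglinear_seed(te[:3], np.maximum(resid, 0.0), w[:3])
    if head is None:
        a_s, t2_s = 0.6 * scale, 15.0
    else:
        a_s, t2_s = head
        t2_s = float(np.clip(t2_s, 1.0, 0.9 * t2_l))
    return np.array([a_s, a_l, t2_s, t2_l])


def _nnls_amplitudes(te, sig, w, t2_s, t2_l) -> tuple[float, float]:
    """Best non-negative amplitudes for fixed T2 pair (weighted NNLS)."""
    design = np.column_stack([np.exp(-te / t2_s), np.exp(-te / t2_l)])
    sw = np.sqrt(w)
    coef, _ = nnls(design * sw[:, None], sig * sw)
    return float(coef[0]), float(coef[1])


def fit_biexp(signal, tes, weights=None, *, mono_seed: MonoParams | None = None,
              max_cycles=60, n_extra_restarts=0, perfect_mse=None) -> BiexpFit:
    """Weighted 4-parameter biexponential fit by multistart Powell.

    Starts from (i) a two-segment log-linear split seed, (ii) four
    deterministic points of a coarse (t2_short, t2_long) lattice with
    NNLS-optimal amplitudes, and (iii) optionally a split of a prior
    monoexponential solution; the best restart wins.  Amplitudes are
    constrained non-negative and T2 to [0.01, 2000] ms by clipping
    inside the line search; components are order-normalised afterwards
    so ``t2_short <= t2_long``.

    ``perfect_mse`` short-circuits remaining restarts once a fit
    reaches that MSE (used for noise-free data).  ``n_extra_restarts``
    appends deterministic jittered lattice starts, used to re-try
    voxels whose biexponential MSE came out above the mono MSE.
    """
    te = _tes_array(tes)
    sig = np.asarray(signal, dtype=float)
    if sig.shape != te.shape:
        raise ValueError("signal and echo-time lengths differ")
    n = te.size
    if n < 5:
        raise ValueError("biexponential fit needs at least 5 echoes "
                         f"(got {n}): 4 free parameters")
    w = _weights_array(weights, n)
    scale = float(sig.max())
    if scale <= 0:
        raise ValueError("all-nonpositive signal; voxel is degenerate")
    amp_hi = 10.0 * scale
    lo = np.array([0.0, 0.0, T2_MIN_MS, T2_MIN_MS])
    hi = np.array([amp_hi, amp_hi, T2_MAX_MS, T2_MAX_MS])

    def obj(x):
        a1, a2, t1, t2 = np.clip(x, lo, hi)
        r = sig - a1 * np.exp(-te / t1) - a2 * np.exp(-te / t2)
        return np.sum(w * r * r) / n

    starts = [_split_seed(te, sig, w)]
    lattice = list(_START_LATTICE)
    if n_extra_restarts:
        # Deterministic jitter of the lattice for retry rounds.
        for k in range(n_extra_restarts):
            t2s, t2l = _START_LATTICE[k % len(_START_LATTICE)]
            lattice.append((t2s * (1.18 ** (k + 1)), t2l / (1.13 ** (k + 1))))
    for t2s, t2l in lattice:
        a_s, a_l = _nnls_amplitudes(te, sig, w, t2s, t2l)
        starts.append(np.array([a_s, a_l, t2s, t2l]))
    if mono_seed is not None and mono_seed.amp > 0:
        starts.append(np.array([0.5 * mono_seed.amp, 0.5 * mono_seed.amp,
                                np.clip(0.5 * mono_seed.t2, T2_MIN_MS, T2_MAX_MS),
                                np.clip(1.8 * mono_seed.t2, T2_MIN_MS, T2_MAX_MS)]))

    best = None
    n_used = 0
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        step = np.maximum(0.1 * np.abs(x0),
                          [0.02 * scale, 0.02 * scale, 1.0, 2.0])
        res = powell_minimize(obj, x0, max_cycles=max_cycles,
                              initial_step=step)
        n_used += 1
        if best is None or res.fun < best.fun:
            best = res
        if perfect_mse is not None and best.fun <= perfect_mse:
            break
    a1, a2, t1, t2 = np.clip(best.x, lo, hi)
    params = BiexpParams(amp_short=float(a1), amp_long=float(a2),
                         t2_short=float(t1), t2_long=float(t2)).ordered()
    return BiexpFit(params=params, mse=float(best.fun),
                    converged=best.converged, n_restarts=n_used - 1)


def classify_voxel(biexp: BiexpFit | None, mono: MonoFit,
                   eps_t2: float = EPS_T2_MS,
                   eps_amp_rel: float = EPS_AMP_REL) -> str:
    """Adjudicate the per-voxel model by the degeneracy rules (logical OR).

    The voxel is *not* biexponential when any of: a T2 component at
    zero (below ``eps_t2``, i.e. pinned to the lower search bound); the
    two T2 components closer than 1 ms; an amplitude at zero (below
    ``eps_amp_rel`` of the amplitude sum); or the monoexponential MSE
    below the biexponential MSE.  Rule order is irrelevant.
    """
    if mono is None or biexp is None:
        raise ValueError("both fits are required for classification")
    if mono.degenerate:
        return "degenerate"
    p = biexp.params
    eps_amp = eps_amp_rel * (p.amp_short + p.amp_long)
    if (p.t2_short <= eps_t2 or p.t2_long <= eps_t2
            or abs(p.t2_long - p.t2_short) < MIN_T2_SEPARATION_MS
            or p.amp_short <= eps_amp or p.amp_long <= eps_amp
            or mono.mse < biexp.mse):
        return "monoexponential"
    return "biexponential"


def fit_voxel(signal, tes, weights=None, *, max_retries=2,
              perfect_mse=None) -> FitResult:
    """Fit one voxel with both models and classify it.

    The biexponential fit nests the monoexponential model, so a
    converged two-pool fit can never have a truly higher MSE; when the
    optimiser nevertheless returns one (a collapse onto a poor local
    minimum), the fit is retried with extra deterministic restarts
    before the mono-beats-bi rule is allowed to fire.
    """
    te = _tes_array(tes)
    sig = np.asarray(signal, dtype=float)
    w = _weights_array(weights, te.size)
    mono = fit_mono(sig, te, w)
    if mono.degenerate:
        return FitResult(model="degenerate", biexp=None, mono=mono)
    biexp = fit_biexp(sig, te, w, mono_seed=mono.params,
                      perfect_mse=perfect_mse)
    retry = 0
    while biexp.mse > mono.mse + 1e-10 and retry < max_retries:
        retry += 1
        again = fit_biexp(sig, te, w, mono_seed=mono.params,
                          n_extra_restarts=2 * retry, perfect_mse=perfect_mse)
        if again.mse < biexp.mse:
            biexp = again
    biexp.n_restarts += retry
    model = classify_voxel(biexp, mono)
    return FitResult(model=model, biexp=biexp, mono=mono)


@dataclass
class MapStack:
    """Voxel maps assembled from per-voxel fits.

    Biexponential maps carry NaN at voxels not classified
    biexponential; ``validity`` is True exactly where they are.
    ``model_code`` is 0=degenerate, 1=monoexponential, 2=biexponential.
    Monoexponential maps and both MSE maps are kept for diagnostics and
    for the mono-vs-bi comparison report.
    """

    t2_short: np.ndarray
    t2_long: np.ndarray
    amp_short: np.ndarray
    amp_long: np.ndarray
    frac_short: np.ndarray
    frac_long: np.ndarray
    validity: np.ndarray
    model_code: np.ndarray
    mono_t2: np.ndarray
    mono_amp: np.ndarray
    mse_mono: np.ndarray
    mse_biexp: np.ndarray

    MAP_NAMES = ("t2_short", "t2_long", "amp_short", "amp_long",
                 "frac_short", "frac_long", "mono_t2", "mono_amp",
                 "mse_mono", "mse_biexp")


def reconstruct_volume(volume, tes, weights=None, *, perfect_mse=None,
                       progress=False) -> MapStack:
    """Voxelwise mono+bi fitting and classification over a 4-D volume.

    ``volume`` has shape (x, y, z, echo).  Voxels without positive
    signal are degenerate and skipped.  Non-biexponential voxels are
    masked (NaN) out of all biexponential maps; fraction maps are the
    amplitude maps over their sum.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4-D multi-echo volume, got {vol.ndim}-D")
    te = _tes_array(tes)
    if vol.shape[-1] != te.size:
        raise ValueError(f"volume has {vol.shape[-1]} echoes but "
                         f"{te.size} echo times given")
    w = _weights_array(weights, te.size)
    shape = vol.shape[:3]
    nan = np.full(shape, np.nan)
    stack = MapStack(
        t2_short=nan.copy(), t2_long=nan.copy(),
        amp_short=nan.copy(), amp_long=nan.copy(),
        frac_short=nan.copy(), frac_long=nan.copy(),
        validity=np.zeros(shape, dtype=bool),
        model_code=np.zeros(shape, dtype=np.int8),
        mono_t2=nan.copy(), mono_amp=nan.copy(),
        mse_mono=nan.copy(), mse_biexp=nan.copy(),
    )
    flat = vol.reshape(-1, te.size)
    candidates = np.flatnonzero(flat.max(axis=1) > 0)
    it = candidates
    if progress:
        try:
            from tqdm import tqdm
            it = tqdm(candidates, desc="fit voxels")
        except ImportError:  # pragma: no cover
            pass
    for idx in it:
        res = fit_voxel(flat[idx], te, w, perfect_mse=perfect_mse)
        i, j, k = np.unravel_index(idx, shape)
        stack.model_code[i, j, k] = _MODEL_CODES[res.model]
        stack.mse_mono[i, j, k] = res.mono.mse
        if res.mono.params is not None:
            stack.mono_t2[i, j, k] = res.mono.params.t2
            stack.mono_amp[i, j, k] = res.mono.params.amp
        if res.biexp is not None:
            stack.mse_biexp[i, j, k] = res.biexp.mse
        if res.model == "biexponential":
            p = res.biexp.params
            total = p.amp_short + p.amp_long
            stack.t2_short[i, j, k] = p.t2_short
            stack.t2_long[i, j, k] = p.t2_long
            stack.amp_short[i, j, k] = p.amp_short
            stack.amp_long[i, j, k] = p.amp_long
            stack.frac_short[i, j, k] = p.amp_short / total
            stack.frac_long[i, j, k] = p.amp_long / total
            stack.validity[i, j, k] = True
    return stack
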