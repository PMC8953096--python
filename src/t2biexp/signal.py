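"""Mono- and biexponential transverse-relaxation signal models.

The measured magnitude signal of a multi-echo spin-echo acquisition is
modelled, per voxel, as a sum of exponentially decaying water pools:

    S(TE) = A_s * exp(-TE / T2_s) + A_l * exp(-TE / T2_l)

with a short component (T2_s, amplitude A_s) and a long component
(T2_l, amplitude A_l).  The monoexponential special case has a single
pool.  Component *fractions* are the amplitudes normalised by their sum.

All relaxation times are in milliseconds; amplitudes are in arbitrary
signal units.  Decay curves are plain 1-D float arrays, one sample per
echo time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_ECHO_TIMES_MS",
    "EchoTimes",
    "BiexpParams",
    "MonoParams",
    "biexp_signal",
    "mono_signal",
    "fractions",
]

#: Echo-time grid of the turbo-spin-echo protocol the simulator emulates:
#: eight echoes, 13 ms spacing.
DEFAULT_ECHO_TIMES_MS: tuple[float, ...] = (
    13.0, 26.0, 39.0, 52.0, 65.0, 78.0, 91.0, 104.0,
)


@dataclass(frozen=True)
class EchoTimes:
    """Strictly increasing, positive echo times in milliseconds."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("echo times must be a non-empty 1-D sequence")
        if np.any(arr <= 0):
            raise ValueError("echo times must be positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "values", arr)

    @classmethod
    def default(cls) -> "EchoTimes":
        return cls(np.array(DEFAULT_ECHO_TIMES_MS))

    def __len__(self) -> int:
        return int(self.values.size)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.values, dtype=dtype)


@dataclass(frozen=True)
class BiexpParams:
    """Two-pool relaxation parameters.

    Amplitudes must be non-negative and the T2 times positive.  The
    canonical form after fitting has ``t2_short <= t2_long``; use
    :meth:`ordered` to normalise.
    """

    amp_short: float
    amp_long: float
    t2_short: float
    t2_long: float

    def __post_init__(self) -> None:
        if self.t2_short <= 0 or self.t2_long <= 0:
            raise ValueError("T2 times must be positive")
        if self.amp_short < 0 or self.amp_long < 0:
            raise ValueError("amplitudes must be non-negative")

    def ordered(self) -> "BiexpParams":
        """Return an equivalent parameter set with t2_short <= t2_long."""
        if self.t2_short <= self.t2_long:
            return self
        return BiexpParams(self.amp_long, self.amp_short,
                           self.t2_long, self.t2_short)

    @property
    def total_amplitude(self) -> float:
        return self.amp_short + self.amp_long


@dataclass(frozen=True)
class MonoParams:
    """Single-pool relaxation parameters."""

    amp: float
    t2: float

    def __post_init__(self) -> None:
        if self.t2 <= 0:
            raise ValueError("T2 must be positive")
        if self.amp < 0:
            raise ValueError("amplitude must be non-negative")


def _tes_array(tes) -> np.ndarray:
    if isinstance(tes, EchoTimes):
        return tes.values
    return EchoTimes(np.asarray(tes, dtype=float)).values


def biexp_signal(params: BiexpParams, tes) -> np.ndarray:
    """Evaluate the two-pool decay ``S(TE)`` on an echo-time grid.

    Returns one non-negative magnitude per echo; ``S(0)`` would equal
    ``amp_short + amp_long``.
    """
    t = _tes_array(tes)
    return (params.amp_short * np.exp(-t / params.t2_short)
            + params.amp_long * np.exp(-t / params.t2_long))


def mono_signal(params: MonoParams, tes) -> np.ndarray:
    """Evaluate the single-pool decay ``S(TE) = amp * exp(-TE/t2)``."""
    t = _tes_array(tes)
    return params.amp * np.exp(-t / params.t2)


def fractions(amp_short: float, amp_long: float) -> tuple[float, float]:
    """Component fractions: each amplitude over the amplitude sum.

    The two fractions lie in [0, 1] and sum to 1 exactly.  Raises
    ``ValueError`` when both amplitudes are zero (such a voxel is
    degenerate and carries no fraction).
    """
    if amp_short < 0 or amp_long < 0:
        raise ValueError("amplitudes must be non-negative")
    total = amp_short + amp_long
    if total <= 0:
        raise ValueError("undefined fractions: amplitude sum is zero")
    frac_short = amp_short / total
    return frac_short, 1.0 - frac_short
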