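"""Acquisition protocols and raw signal-series containers.

The study protocol this package models acquires, per disc:

* an inversion-recovery turbo-spin-echo series for T1 (15 inversion times,
  50-1900 ms, TR 2100 ms, echo spacing 6.3 ms, 8 refocusing pulses, 180 deg),
* a multi-echo spin-echo series for T2 (10 echoes every 15 ms, TR 2000 ms),
* a magnetization-transfer pair (saturation pulse on / off),
* a diffusion-weighted series (b = 1000 s/mm^2, 15 non-collinear directions
  plus one b = 0 image).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "SignalSeries",
    "fibonacci_directions",
    "default_protocol",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_directions(n: int = 15) -> np.ndarray:
    """Deterministic, well-spread set of ``n`` unit gradient directions.

    Points of a spherical Fibonacci lattice restricted to the upper
    hemisphere (diffusion encoding is antipodally symmetric, so a
    hemisphere suffices).  The construction is closed-form, hence
    bit-reproducible, and spans rank 3 for any ``n >= 6``.
    """
    if n < 6:
        raise ValueError("at least 6 directions are required for a rank-3 design")
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere only
    r = np.sqrt(1.0 - z**2)
    phi = i * _GOLDEN_ANGLE
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and encoding parameters of the four quantitative sequences.

    Times are in milliseconds, ``b_value`` in s/mm^2, ``mt_offset`` in Hz
    (metadata only -- the saturation pulse is not modelled explicitly).
    """

    inversion_times: tuple[float, ...]
    echo_times_t2: tuple[float, ...]
    tr: float
    te_readout: float
    n_refocus: int
    flip_alpha: float
    mt_offset: float
    b_value: float
    gradient_dirs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ti = np.asarray(self.inversion_times, float)
        te = np.asarray(self.echo_times_t2, float)
        if ti.size and (np.any(ti <= 0) or np.any(np.diff(ti) <= 0)):
            raise ValueError("inversion times must be positive and strictly increasing")
        if te.size and (np.any(te <= 0) or np.any(np.diff(te) <= 0)):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.n_refocus < 1:
            raise ValueError("n_refocus must be >= 1")
        if self.b_value < 0:
            raise ValueError("b_value must be >= 0")
        g = np.asarray(self.gradient_dirs, float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError("gradient_dirs must be an (n, 3) array")
        if np.any(np.abs(np.linalg.norm(g, axis=1) - 1.0) > 1e-9):
            raise ValueError("gradient directions must have unit norm (1e-9)")
        object.__setattr__(self, "gradient_dirs", g)
        object.__setattr__(self, "inversion_times", tuple(float(x) for x in ti))
        object.__setattr__(self, "echo_times_t2", tuple(float(x) for x in te))


def default_protocol() -> AcquisitionProtocol:
    """The study's acquisition protocol (3T IR-TSE / multi-echo TSE / MT / DWI)."""
    return AcquisitionProtocol(
        inversion_times=tuple(np.linspace(50.0, 1900.0, 15)),
        echo_times_t2=tuple(15.0 * np.arange(1, 11)),
        tr=2100.0,
        te_readout=6.3,
        n_refocus=8,
        flip_alpha=180.0,
        mt_offset=1100.0,
        b_value=1000.0,
        gradient_dirs=fibonacci_directions(15),
    )


#: sentinel x-coordinate for the unweighted (b=0) sample of a DWI series
B0_INDEX = -1

_KINDS = ("IR", "ECHO", "MT", "DWI")


@dataclass
class SignalSeries:
    """One voxel's (or ROI-mean) raw measurements for one sequence.

    ``x`` holds the acquisition coordinate appropriate to ``kind``:
    inversion time (ms) for IR, echo time (ms) for ECHO, 0/1 for MT off/on,
    and for DWI the index into ``protocol.gradient_dirs`` with ``-1``
    marking the b = 0 sample.
    """

    kind: str
    x: np.ndarray
    y: np.ndarray
    protocol: AcquisitionProtocol | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("signal intensities must be finite")

    def __len__(self) -> int:
        return self.x.size
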