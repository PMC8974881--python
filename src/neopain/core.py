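"""Shared containers for stimulus-locked sampled signals.

All times are seconds relative to stimulus onset (t = 0); windows are
half-open ``[a, b)``.  A :class:`Trace` is a uniformly sampled signal; an
epoch (a stimulus-locked cut-out of a trace) is represented by the same
class.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: tolerance (in samples) used when converting window edges to indices, so
#: that exact edges are not lost to float rounding
_EDGE_TOL = 1e-9


@dataclass
class Trace:
    """A uniformly sampled signal locked to stimulus onset.

    Parameters
    ----------
    samples:
        Sample values.
    fs:
        Sampling rate in Hz.
    t_start:
        Time of the first sample, in seconds relative to stimulus onset
        (negative = prestimulus).
    """

    samples: np.ndarray
    fs: float
    t_start: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Trace samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def t_end(self) -> float:
        """Time just past the final sample (half-open end of the span)."""
        return self.t_start + self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n) / self.fs

    # ------------------------------------------------------------------
    def index_range(self, a: float, b: float) -> tuple[int, int]:
        """Sample indices ``[i0, i1)`` whose times fall in ``[a, b)``."""
        i0 = int(np.ceil((a - self.t_start) * self.fs - _EDGE_TOL))
        i1 = int(np.ceil((b - self.t_start) * self.fs - _EDGE_TOL))
        return max(i0, 0), min(max(i1, 0), self.n)

    def covers(self, a: float, b: float) -> bool:
        """Whether the trace contains every sample of ``[a, b)``."""
        half = 0.5 / self.fs
        return self.t_start <= a + half and self.t_end >= b - half

    def window(self, a: float, b: float) -> np.ndarray:
        """Samples with times in ``[a, b)`` (view, no copy)."""
        i0, i1 = self.index_range(a, b)
        return self.samples[i0:i1]

    def slice(self, a: float, b: float) -> "Trace":
        """Sub-trace over ``[a, b)``; raises if the span is not covered."""
        if not self.covers(a, b):
            raise ValueError(
                f"trace spans [{self.t_start:g}, {self.t_end:g}) s but "
                f"[{a:g}, {b:g}) s was requested"
            )
        i0, i1 = self.index_range(a, b)
        return Trace(self.samples[i0:i1].copy(), self.fs, self.t_start + i0 / self.fs)

    def copy(self) -> "Trace":
        return Trace(self.samples.copy(), self.fs, self.t_start)


#: An epoch is simply a trace cut to a stimulus-locked window.
Epoch = Trace
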