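"""Melt-curve containers for methylation-sensitive high-resolution melting.

A normalized HRM curve starts at fluorescence 1 (double-stranded, below
both melting temperatures) and decays to 0. Methylated template retains
CG pairs through bisulfite conversion and therefore melts at a higher
temperature than unmethylated template; a sample's curve is a mixture of
the two components weighted by its methylation fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MeltCurve:
    temperature: np.ndarray  # degrees C, strictly increasing
    fluorescence: np.ndarray  # normalized to [0, 1], ~1 at start, ~0 at end
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("temperature and fluorescence must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "fluorescence", f)

    def normalized(self) -> "MeltCurve":
        """Linear rescale so the first point is 1 and the last is 0."""
        f = self.fluorescence
        span = f[0] - f[-1]
        if span <= 0:
            raise ValueError(f"curve {self.label!r} does not decay (start <= end)")
        return MeltCurve(self.temperature, (f - f[-1]) / span, self.label)


@dataclass(frozen=True)
class StandardCurveSet:
    """Melt curves of known methylated/unmethylated mixtures on one grid."""

    mixtures: list[tuple[float, MeltCurve]] = field(default_factory=list)

    def __post_init__(self) -> None:
        fracs = [m for m, _ in self.mixtures]
        if len(fracs) < 2:
            raise ValueError("need at least two standards")
        if any(not 0 <= m <= 1 for m in fracs):
            raise ValueError("standard fractions must lie in [0, 1]")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("standard fractions must be strictly increasing")
        grid = self.mixtures[0][1].temperature
        for _, c in self.mixtures[1:]:
            if c.temperature.shape != grid.shape or not np.allclose(c.temperature, grid):
                raise ValueError("all standards must share one temperature grid")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([m for m, _ in self.mixtures])

    @property
    def temperature(self) -> np.ndarray:
        return self.mixtures[0][1].temperature

    def curve_matrix(self) -> np.ndarray:
        return np.vstack([c.fluorescence for _, c in self.mixtures])
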