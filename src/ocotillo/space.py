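"""Continuous search spaces and bounds handling.

A :class:`SearchSpace` is an axis-aligned box ``[lower_j, upper_j]`` per
coordinate.  Positions that leave the box after an update are repaired either
by clipping or by a single mirror reflection about the violated bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError, InvalidParameterError

BOUNDS_MODES = ("clip", "reflect")


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box constraint for continuous optimization.

    Parameters
    ----------
    dim : int
        Number of coordinates.
    lower, upper : array-like of shape (dim,)
        Per-coordinate bounds with ``lower_j < upper_j``.
    """

    dim: int
    lower: np.ndarray = field(repr=False)
    upper: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise InvalidSpecError("dim must be a positive integer")
        lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        if not np.all(lower < upper):
            raise InvalidSpecError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def cube(cls, dim: int, lower: float, upper: float) -> "SearchSpace":
        return cls(dim=dim, lower=np.full(dim, float(lower)), upper=np.full(dim, float(upper)))

    @classmethod
    def unit(cls, dim: int) -> "SearchSpace":
        return cls.cube(dim, 0.0, 1.0)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform sample of ``n`` positions within the box, shape ``(n, dim)``."""
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def contains(self, theta: np.ndarray, atol: float = 0.0) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower - atol) and np.all(theta <= self.upper + atol))


def apply_bounds(theta: np.ndarray, space: SearchSpace, mode: str = "clip") -> np.ndarray:
    """Repair out-of-range coordinates.

    ``clip`` clamps to the box.  ``reflect`` mirrors the coordinate once about
    the violated bound and then clamps (so excursions larger than the box
    width end up on the opposite bound).
    """
    theta = np.asarray(theta, dtype=float)
    if mode == "clip":
        return np.clip(theta, space.lower, space.upper)
    if mode == "reflect":
        lo, hi = space.lower, space.upper
        out = np.where(theta < lo, 2.0 * lo - theta, theta)
        out = np.where(out > hi, 2.0 * hi - out, out)
        return np.clip(out, lo, hi)
    raise InvalidParameterError(f"unknown bounds mode {mode!r}; expected one of {BOUNDS_MODES}")
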