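"""Periodic lattice geometry (ring in 1-D, torus in 2-D)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry"]


@dataclass(frozen=True)
class GridGeometry:
    """A periodic lattice of patches.

    Parameters
    ----------
    ndim : {1, 2}
        Lattice dimensionality: 1 gives a ring, 2 a torus.
    extent : tuple of int
        Number of grid-points per dimension; length must equal ``ndim``.
    h : float
        Lattice spacing between neighbouring patches (default 1).
    """

    ndim: int = 1
    extent: tuple[int, ...] = (50,)
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.ndim not in (1, 2):
            raise ValueError(f"ndim must be 1 or 2, got {self.ndim}")
        object.__setattr__(self, "extent", tuple(int(e) for e in self.extent))
        if len(self.extent) != self.ndim:
            raise ValueError(
                f"extent {self.extent} inconsistent with ndim={self.ndim}"
            )
        if any(e < 1 for e in self.extent):
            raise ValueError(f"extents must be >= 1, got {self.extent}")
        if not self.h > 0:
            raise ValueError(f"lattice spacing h must be positive, got {self.h}")

    @property
    def n_points(self) -> int:
        """Total number of grid-points M."""
        return int(np.prod(self.extent))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.extent

    def to_dict(self) -> dict:
        return {"ndim": self.ndim, "extent": list(self.extent), "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(ndim=int(d["ndim"]), extent=tuple(d["extent"]), h=float(d["h"]))

    @classmethod
    def ring(cls, length: int, h: float = 1.0) -> "GridGeometry":
        return cls(ndim=1, extent=(length,), h=h)

    @classmethod
    def torus(cls, nx: int, ny: int, h: float = 1.0) -> "GridGeometry":
        return cls(ndim=2, extent=(nx, ny), h=h)

    @classmethod
    def single_point(cls) -> "GridGeometry":
        """Degenerate one-patch geometry (the non-spatial limit)."""
        return cls(ndim=1, extent=(1,), h=1.0)
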