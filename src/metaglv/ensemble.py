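"""Random community and dispersal-profile generators.

All samplers are pure functions of their arguments including the seed:
the same call always returns bit-identical arrays.  A master seed is split
deterministically into independent sub-streams (interaction matrix,
diffusion rates, relative spread, initial conditions) so any component can
be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from metaglv.grids import GridGeometry

__all__ = [
    "Community",
    "DispersalProfile",
    "sample_interaction_matrix",
    "sample_diffusion_rates",
    "sample_relative_spread",
    "build_system",
    "child_rng",
    "STREAMS",
]

# Sub-stream tags for deterministic master-seed splitting.
STREAMS = {"matrix": 0, "diffusion": 1, "initial": 2, "spread": 3, "restarts": 4}

SQRT3 = float(np.sqrt(3.0))


def child_rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Deterministic child generator for a named sub-stream of ``seed``.

    ``extra`` integers extend the spawn key (e.g. a diffusion-level index),
    keeping streams for different purposes statistically independent.
    """
    if stream not in STREAMS:
        raise KeyError(f"unknown stream {stream!r}; one of {sorted(STREAMS)}")
    ss = np.random.SeedSequence([int(seed), STREAMS[stream], *map(int, extra)])
    return np.random.default_rng(ss)


@dataclass
class Community:
    """A species pool: interaction web plus logistic self-regulation.

    Attributes
    ----------
    N : int
        Maximum number of species.
    A : (N, N) ndarray
        Dimensionless interaction coefficients at unit-variance scale;
        diagonal is identically zero (self-limitation is carried by r, K).
    r : (N,) ndarray
        Intrinsic growth rates, strictly positive.
    K : (N,) ndarray
        Carrying capacities, strictly positive.
    sigma : float
        Interaction-strength standard deviation multiplier (>= 0).
    c : float
        Connection density of the off-diagonal entries.
    mu : float
        Mean of the non-zero entries of ``A``.
    """

    N: int
    A: np.ndarray
    r: np.ndarray = None  # type: ignore[assignment]
    K: np.ndarray = None  # type: ignore[assignment]
    sigma: float = 0.0
    c: float = 0.5
    mu: float = -0.5

    def __post_init__(self) -> None:
        self.N = int(self.N)
        if self.N < 1:
            raise ValueError(f"N must be a positive integer, got {self.N}")
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.N, self.N):
            raise ValueError(f"A must be {self.N}x{self.N}, got {self.A.shape}")
        if self.r is None:
            self.r = np.ones(self.N)
        if self.K is None:
            self.K = np.ones(self.N)
        self.r = np.asarray(self.r, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        for name, v in (("r", self.r), ("K", self.K)):
            if v.shape != (self.N,):
                raise ValueError(f"{name} must have shape ({self.N},), got {v.shape}")
        # r = 0 is permitted so pure-dispersal (transport-only) systems can be
        # expressed; K must stay positive (it divides the logistic term)
        if np.any(self.r < 0):
            raise ValueError("r must be non-negative")
        if not np.all(self.K > 0):
            raise ValueError("K must be strictly positive")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must lie in [0, 1], got {self.c}")
        if np.any(np.diag(self.A) != 0.0):
            raise ValueError("A must have an exactly zero diagonal")

    def with_sigma(self, sigma: float) -> "Community":
        """Copy of this community at a different interaction-strength scale."""
        return Community(
            N=self.N, A=self.A.copy(), r=self.r.copy(), K=self.K.copy(),
            sigma=float(sigma), c=self.c, mu=self.mu,
        )


@dataclass
class DispersalProfile:
    """Per-species diffusion rates plus their generating parameters.

    ``D`` is drawn i.i.d. uniform on ``[mu_D(1 - sqrt(3) b), mu_D(1 + sqrt(3) b)]``,
    the uniform distribution with mean ``mu_D`` and standard deviation
    ``b * mu_D``.  ``mu_D = 0`` forces ``D = 0`` exactly (disconnected grid).
    """

    D: np.ndarray
    mu_D: float
    b: float = 0.35

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 1:
            raise ValueError("D must be a 1-D vector")
        if self.mu_D < 0:
            raise ValueError(f"mu_D must be non-negative, got {self.mu_D}")
        if np.any(self.D < 0):
            raise ValueError("diffusion rates must be non-negative")
        if self.mu_D == 0 and np.any(self.D != 0):
            raise ValueError("mu_D = 0 requires D identically zero")

    @property
    def N(self) -> int:
        return self.D.shape[0]


def _check_spread(b: float) -> None:
    # Open lower end keeps consecutive decade intervals disjoint; b = 0.4 is
    # allowed because it is used for the mu_D = 2.5 sigma_D experiment presets.
    if not 0.3 < b <= 0.4:
        raise ValueError(
            f"relative spread b must satisfy 0.3 < b <= 0.4 (got {b}); outside this "
            "range diffusion intervals for consecutive decade means overlap"
        )


def sample_interaction_matrix(
    N: int, c: float, mu: float, seed: int
) -> np.ndarray:
    """Draw a random N x N interaction matrix.

    Each off-diagonal entry is independently non-zero with probability ``c``;
    non-zero entries are Normal(``mu``, 1).  The diagonal is exactly zero.

    Returns the matrix; deterministic given ``seed``.
    """
    N = int(N)
    if N < 1:
        raise ValueError(f"N must be a positive integer, got {N}")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"connection density c must lie in [0, 1], got {c}")
    rng = child_rng(seed, "matrix")
    mask = rng.random((N, N)) < c
    values = rng.normal(loc=mu, scale=1.0, size=(N, N))
    A = np.where(mask, values, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def sample_diffusion_rates(
    N: int, mu_D: float, b: float, seed: int
) -> np.ndarray:
    """Draw per-species diffusion rates.

    Entries are i.i.d. uniform on ``[mu_D(1 - sqrt(3) b), mu_D(1 + sqrt(3) b)]``
    — mean ``mu_D``, standard deviation ``b * mu_D``.  ``mu_D = 0`` returns an
    exact zero vector (the non-spatial limit).
    """
    N = int(N)
    if N < 1:
        raise ValueError(f"N must be a positive integer, got {N}")
    if mu_D < 0:
        raise ValueError(f"mu_D must be non-negative, got {mu_D}")
    if mu_D == 0:
        return np.zeros(N)
    _check_spread(b)
    lo = mu_D * (1.0 - SQRT3 * b)
    hi = mu_D * (1.0 + SQRT3 * b)
    rng = child_rng(seed, "diffusion")
    return rng.uniform(lo, hi, size=N)


def sample_relative_spread(seed: int) -> float:
    """Draw the relative spread b uniformly from the open interval (0.3, 0.4)."""
    rng = child_rng(seed, "spread")
    b = 0.3 + 0.1 * rng.random()
    while not 0.3 < b < 0.4:  # pragma: no cover - measure-zero endpoints
        b = 0.3 + 0.1 * rng.random()
    return float(b)


def build_system(
    N: int = 20,
    c: float = 0.5,
    mu: float = -0.5,
    sigma: float = 0.0,
    mu_D: float = 0.0,
    b: float | None = None,
    geometry: GridGeometry | dict | None = None,
    seed: int = 0,
    r: np.ndarray | None = None,
    K: np.ndarray | None = None,
) -> tuple[Community, DispersalProfile, GridGeometry]:
    """Assemble a fully specified random system from a single master seed.

    The matrix, diffusion and spread draws come from independent sub-streams
    of ``seed``.  ``b=None`` draws the relative spread once from its stream;
    ``geometry=None`` selects the default ring of 50 points.  ``r`` and ``K``
    default to all-ones.
    """
    if geometry is None:
        geometry = GridGeometry.ring(50)
    elif isinstance(geometry, dict):
        geometry = GridGeometry.from_dict(geometry)
    A = sample_interaction_matrix(N, c, mu, seed)
    community = Community(N=N, A=A, r=r, K=K, sigma=float(sigma), c=c, mu=mu)
    if b is None:
        b = 0.35 if mu_D == 0 else sample_relative_spread(seed)
    D = sample_diffusion_rates(N, mu_D, b, seed)
    dispersal = DispersalProfile(D=D, mu_D=float(mu_D), b=float(b))
    return community, dispersal, geometry
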