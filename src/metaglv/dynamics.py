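"""Dynamical core: GLV right-hand sides, periodic Laplacians, equilibria.

State convention: a spatial state is an array of shape ``(M, N)`` — grid-point
index first, species second — with ``M`` the number of lattice points of the
:class:`~metaglv.grids.GridGeometry`.  The non-spatial model is the ``M = 1``
special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from metaglv.ensemble import Community, DispersalProfile, child_rng
from metaglv.grids import GridGeometry

__all__ = [
    "Trajectory",
    "SingularEquilibriumError",
    "glv_rhs_nonspatial",
    "discrete_laplacian",
    "glv_rhs_spatial",
    "solve_feasible_fixed_point",
    "jacobian_at",
    "is_linearly_stable",
    "default_initial_state",
    "integrate",
]

#: eigenvalue real parts must fall below -STABILITY_MARGIN to count as stable
STABILITY_MARGIN = 1e-9

#: undershoot below this is treated as a solver artefact and clipped to zero
CLIP_TOLERANCE = 1e-12

#: abundance magnitude at which a run is declared diverged
BLOWUP_THRESHOLD = 1e8


class SingularEquilibriumError(np.linalg.LinAlgError):
    """The interior-equilibrium linear system has no unique solution."""


@dataclass
class Trajectory:
    """Abundances on a uniform output time grid.

    ``phi`` has shape ``(T, M, N)``: time sample x grid-point x species.
    ``diverged`` marks runs whose integration failed or blew up; the partial
    trajectory up to the failure is retained for diagnosis.
    """

    times: np.ndarray
    phi: np.ndarray
    geometry: GridGeometry
    diverged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be a 1-D vector")
        if self.phi.ndim != 3 or self.phi.shape[0] != self.times.size:
            raise ValueError(
                f"phi must be (T, M, N) with T = len(times); got {self.phi.shape}"
            )
        if self.phi.shape[1] != self.geometry.n_points:
            raise ValueError(
                f"phi has {self.phi.shape[1]} grid-points but geometry has "
                f"{self.geometry.n_points}"
            )
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1e-300):
                raise ValueError("output time grid must be uniform")
        if np.any(self.phi < 0):
            raise ValueError("trajectory contains negative abundances")

    @property
    def n_points(self) -> int:
        return self.phi.shape[1]

    @property
    def n_species(self) -> int:
        return self.phi.shape[2]

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("trajectory has fewer than 2 samples")
        return float(self.times[1] - self.times[0])

    def after(self, t_min: float) -> "Trajectory":
        """Sub-trajectory with ``times >= t_min`` (transient removal)."""
        keep = self.times >= t_min
        return Trajectory(
            times=self.times[keep],
            phi=self.phi[keep],
            geometry=self.geometry,
            diverged=self.diverged,
            meta=dict(self.meta),
        )


def _check_state(phi: np.ndarray, N: int) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.shape[-1] != N:
        raise ValueError(f"state has {phi.shape[-1]} species, community has {N}")
    return phi


def glv_rhs_nonspatial(phi: np.ndarray, community: Community) -> np.ndarray:
    """Time derivative of the well-mixed model.

    Component i is ``phi_i r_i (1 - phi_i / K_i) + sigma phi_i sum_j A_ij phi_j``.
    Accepts a single state ``(N,)`` or a stack ``(M, N)`` evaluated row-wise.
    """
    phi = _check_state(phi, community.N)
    interaction = phi @ community.A.T
    return phi * (community.r * (1.0 - phi / community.K)
                  + community.sigma * interaction)


def _grid_laplacian(field: np.ndarray, geometry: GridGeometry) -> np.ndarray:
    """Periodic stencil applied along the leading grid axes of ``field``."""
    h2 = geometry.h ** 2
    if geometry.ndim == 1:
        return (np.roll(field, 1, axis=0) + np.roll(field, -1, axis=0)
                - 2.0 * field) / h2
    return (np.roll(field, 1, axis=0) + np.roll(field, -1, axis=0)
            + np.roll(field, 1, axis=1) + np.roll(field, -1, axis=1)
            - 4.0 * field) / h2


def discrete_laplacian(field: np.ndarray, geometry: GridGeometry) -> np.ndarray:
    """Discrete periodic Laplacian of a field over grid-points.

    Three-point stencil on the ring, five-point stencil on the torus, wrapped
    periodically and divided by ``h**2``.  ``field`` may carry trailing axes
    (e.g. species) which are mapped element-wise; its leading axes must match
    ``geometry.shape`` or be the flattened point count ``(M, ...)``.
    """
    field = np.asarray(field, dtype=float)
    shape = geometry.shape
    if field.shape[: geometry.ndim] == shape:
        return _grid_laplacian(field, geometry)
    if field.shape[0] == geometry.n_points:
        trailing = field.shape[1:]
        out = _grid_laplacian(field.reshape(shape + trailing), geometry)
        return out.reshape((geometry.n_points,) + trailing)
    raise ValueError(
        f"field shape {field.shape} incompatible with geometry {shape}"
    )


def glv_rhs_spatial(
    phi: np.ndarray,
    community: Community,
    dispersal: DispersalProfile,
    geometry: GridGeometry,
) -> np.ndarray:
    """Time derivative of the lattice model for a state of shape ``(M, N)``.

    Per grid-point the local well-mixed term, plus ``D_i`` times the discrete
    periodic Laplacian of species i's abundance field (nearest-neighbour
    dispersal only).
    """
    phi = _check_state(phi, community.N)
    if phi.ndim != 2 or phi.shape[0] != geometry.n_points:
        raise ValueError(
            f"state shape {phi.shape} incompatible with geometry "
            f"({geometry.n_points} points)"
        )
    if dispersal.N != community.N:
        raise ValueError("dispersal profile and community disagree on N")
    local = glv_rhs_nonspatial(phi, community)
    if np.all(dispersal.D == 0):
        return local
    return local + dispersal.D * discrete_laplacian(phi, geometry)


def solve_feasible_fixed_point(community: Community) -> tuple[np.ndarray, bool]:
    """Interior equilibrium of the well-mixed model by linear solve.

    Solves ``r_i (1 - phi_i / K_i) + sigma sum_j A_ij phi_j = 0``, i.e.
    ``(diag(r/K) - sigma A) phi = r``.  Returns ``(phi_star, feasible)`` where
    ``feasible`` is True iff every component is strictly positive.

    Raises
    ------
    SingularEquilibriumError
        If the linear system has no unique solution (this is *not* the same
        as infeasibility and is signalled separately).
    """
    M = np.diag(community.r / community.K) - community.sigma * community.A
    try:
        phi_star = np.linalg.solve(M, community.r)
    except np.linalg.LinAlgError as exc:
        raise SingularEquilibriumError(
            "no unique interior equilibrium: interaction matrix is singular "
            f"at sigma={community.sigma}"
        ) from exc
    # solve() only errors on exact singularity; guard near-singular results
    if not np.all(np.isfinite(phi_star)):
        raise SingularEquilibriumError(
            "no unique interior equilibrium: non-finite linear solve"
        )
    return phi_star, bool(np.all(phi_star > 0))


def jacobian_at(phi: np.ndarray, community: Community) -> np.ndarray:
    """Jacobian of the well-mixed right-hand side at state ``phi``."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (community.N,):
        raise ValueError(f"phi must have shape ({community.N},), got {phi.shape}")
    r, K, A, sigma = community.r, community.K, community.A, community.sigma
    diag = r * (1.0 - 2.0 * phi / K) + sigma * (A @ phi)
    J = sigma * phi[:, None] * A
    J[np.diag_indices_from(J)] += diag
    return J


def is_linearly_stable(
    phi: np.ndarray, community: Community, margin: float = STABILITY_MARGIN
) -> bool:
    """True iff all Jacobian eigenvalues at ``phi`` have real part < -margin."""
    eigs = np.linalg.eigvals(jacobian_at(phi, community))
    return bool(np.all(eigs.real < -margin))


def default_initial_state(
    community: Community,
    geometry: GridGeometry,
    seed: int,
    noise_sd: float = 0.2,
    kind: str = "fixed_point",
) -> np.ndarray:
    """Seeded initial condition of shape ``(M, N)``.

    ``kind="fixed_point"`` (default): the interior equilibrium (absolute value
    if infeasible, all-ones if singular) perturbed multiplicatively per
    grid-point and species by i.i.d. lognormal noise of s.d. ``noise_sd``.
    The per-point perturbation is essential — a spatially uniform start would
    stay on the synchronised manifold forever.

    ``kind="uniform"``: i.i.d. uniform draws in (0, 1].
    """
    M, N = geometry.n_points, community.N
    rng = child_rng(seed, "initial")
    if kind == "uniform":
        return 1.0 - rng.random((M, N))  # uniform on (0, 1]
    if kind != "fixed_point":
        raise ValueError(f"unknown initial-condition kind {kind!r}")
    try:
        phi_star, feasible = solve_feasible_fixed_point(community)
        base = phi_star if feasible else np.abs(phi_star)
        base = np.where(base > 1e-12, base, 1e-3)
    except SingularEquilibriumError:
        base = np.ones(N)
    log_sd = float(np.sqrt(np.log1p(noise_sd ** 2)))
    noise = rng.lognormal(mean=-0.5 * log_sd ** 2, sigma=log_sd, size=(M, N))
    return base * noise


def integrate(
    community: Community,
    dispersal: DispersalProfile | None,
    geometry: GridGeometry,
    phi0: np.ndarray,
    t_end: float,
    output_dt: float = 0.5,
    t_start: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the lattice model and resample onto a uniform output grid.

    ``dispersal=None`` (or all-zero D) integrates M decoupled well-mixed
    copies.  Solver failure or abundance blow-up flags the trajectory
    ``diverged`` and retains the partial output for diagnosis.  Small
    negative undershoots (above ``-CLIP_TOLERANCE`` before clipping would
    matter) are clipped to zero in the output.
    """
    M, N = geometry.n_points, community.N
    phi0 = np.asarray(phi0, dtype=float)
    if phi0.shape == (N,) and M == 1:
        phi0 = phi0[None, :]
    if phi0.shape != (M, N):
        raise ValueError(f"phi0 must have shape ({M}, {N}), got {phi0.shape}")
    if np.any(phi0 < 0):
        raise ValueError("initial state must be non-negative")
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")

    if dispersal is None:
        dispersal = DispersalProfile(D=np.zeros(N), mu_D=0.0)
    A_T = np.ascontiguousarray(community.A.T)
    r, K, sig, D = community.r, community.K, community.sigma, dispersal.D
    spatial = M > 1 and np.any(D != 0)
    grid_shape = geometry.shape
    h2 = geometry.h ** 2
    two_d = geometry.ndim == 2

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        phi = y.reshape(M, N)
        out = phi * (r * (1.0 - phi / K) + sig * (phi @ A_T))
        if spatial:
            f = phi.reshape(grid_shape + (N,))
            lap = np.roll(f, 1, axis=0) + np.roll(f, -1, axis=0) - 2.0 * f
            if two_d:
                lap += np.roll(f, 1, axis=1) + np.roll(f, -1, axis=1) - 2.0 * f
            out += D * lap.reshape(M, N) / h2
        return out.ravel()

    def blowup(t: float, y: np.ndarray) -> float:
        return float(BLOWUP_THRESHOLD - np.max(np.abs(y)))

    blowup.terminal = True  # type: ignore[attr-defined]

    n_out = int(round((t_end - t_start) / output_dt))
    t_eval = t_start + output_dt * np.arange(n_out + 1)

    sol = solve_ivp(
        rhs, (t_start, t_end), phi0.ravel(),
        method=method, rtol=rtol, atol=atol, t_eval=t_eval,
        events=[blowup],
    )
    diverged = (sol.status != 0) or (not np.all(np.isfinite(sol.y)))
    times = sol.t
    phi = sol.y.T.reshape(-1, M, N)
    finite = np.all(np.isfinite(phi), axis=(1, 2))
    if not finite.all():
        cut = int(np.argmin(finite))
        times, phi = times[:cut], phi[:cut]
    min_phi = float(phi.min()) if phi.size else 0.0
    phi = np.maximum(phi, 0.0)
    meta = {
        "method": method, "rtol": rtol, "atol": atol,
        "output_dt": output_dt, "min_raw_abundance": min_phi,
        "solver_status": int(sol.status), "n_rhs_evals": int(sol.nfev),
    }
    if min_phi < -1e-6:
        meta["large_undershoot"] = True
    return Trajectory(times=times, phi=phi, geometry=geometry,
                      diverged=bool(diverged), meta=meta)
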