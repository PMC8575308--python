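"""Interaction-strength regime structure of the well-mixed model.

Locates the feasibility boundary (largest sigma with a feasible, linearly
stable all-species equilibrium), scans a sigma grid for the three regimes —
feasible, structurally unstable (stable fixed point with extinctions),
collapsed/oscillatory — and labels spatial runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from metaglv.dynamics import (
    STABILITY_MARGIN,
    SingularEquilibriumError,
    default_initial_state,
    integrate,
    is_linearly_stable,
    jacobian_at,
    solve_feasible_fixed_point,
)
from metaglv.ensemble import Community, child_rng
from metaglv.grids import GridGeometry
from metaglv.measures import DEFAULT_EXTINCT_THRESHOLD, RunSummary

__all__ = [
    "BoundaryEstimate",
    "RegimeReport",
    "feasibility_boundary",
    "stability_scan",
    "spatial_regime",
    "find_fixed_point",
    "saturated_equilibrium",
]

LABEL_FEASIBLE = "feasible"
LABEL_STRUCTURAL = "structurally_unstable"
LABEL_COLLAPSED = "collapsed_oscillatory"

#: spatial-regime labels
SPATIAL_LABELS = (
    "fixed_point",
    "synchronised_oscillation",
    "unsynchronised_oscillation",
    "mixed",
    "collapsed",
)


class BoundaryEstimate(NamedTuple):
    sigma: float
    bracketed: bool


@dataclass
class RegimeReport:
    """Result of a non-spatial sigma scan.

    ``sigma_feasibility``: largest scanned sigma labelled feasible (0 if
    none).  ``sigma_stability``: largest scanned sigma at which any stable
    fixed point was found, or ``None`` when stability was never lost within
    the scanned range (boundary not bracketed).
    """

    sigma_grid: np.ndarray
    labels: list[str]
    diversity: list[int | None]
    n_restarts_agreeing: list[int]
    sigma_feasibility: float = 0.0
    sigma_stability: float | None = None
    flags: dict = field(default_factory=dict)

    @property
    def regime_labels(self) -> dict[float, str]:
        return {float(s): l for s, l in zip(self.sigma_grid, self.labels)}

    def to_dict(self) -> dict:
        return {
            "sigma_grid": np.asarray(self.sigma_grid).tolist(),
            "labels": list(self.labels),
            "diversity": [None if d is None else int(d) for d in self.diversity],
            "n_restarts_agreeing": [int(x) for x in self.n_restarts_agreeing],
            "sigma_feasibility": float(self.sigma_feasibility),
            "sigma_stability": (
                None if self.sigma_stability is None else float(self.sigma_stability)
            ),
            "flags": self.flags,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegimeReport":
        return cls(
            sigma_grid=np.asarray(d["sigma_grid"], dtype=float),
            labels=list(d["labels"]),
            diversity=[None if x is None else int(x) for x in d["diversity"]],
            n_restarts_agreeing=[int(x) for x in d["n_restarts_agreeing"]],
            sigma_feasibility=float(d["sigma_feasibility"]),
            sigma_stability=(
                None if d["sigma_stability"] is None else float(d["sigma_stability"])
            ),
            flags=dict(d.get("flags", {})),
        )


def _feasible_and_stable(community: Community, sigma: float) -> bool:
    c = community.with_sigma(sigma)
    try:
        phi_star, feasible = solve_feasible_fixed_point(c)
    except SingularEquilibriumError:
        return False
    return feasible and is_linearly_stable(phi_star, c)


def feasibility_boundary(
    community: Community,
    sigma_max: float = 2.0,
    tol: float = 1e-3,
) -> BoundaryEstimate:
    """Bisection estimate of the feasibility/stability threshold in sigma.

    The predicate is "the interior equilibrium exists, is strictly positive
    and is linearly stable".  Returns ``(sigma, bracketed)``; when the
    predicate still holds at ``sigma_max`` the estimate is ``sigma_max`` with
    ``bracketed=False``.
    """
    if not _feasible_and_stable(community, 0.0):
        raise ValueError("community must be feasible and stable at sigma = 0")
    if _feasible_and_stable(community, sigma_max):
        return BoundaryEstimate(sigma=float(sigma_max), bracketed=False)
    lo, hi = 0.0, float(sigma_max)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _feasible_and_stable(community, mid):
            lo = mid
        else:
            hi = mid
    return BoundaryEstimate(sigma=0.5 * (lo + hi), bracketed=True)


def _subcommunity(community: Community, mask: np.ndarray) -> Community:
    return Community(
        N=int(mask.sum()),
        A=community.A[np.ix_(mask, mask)],
        r=community.r[mask], K=community.K[mask],
        sigma=community.sigma, c=community.c, mu=community.mu,
    )


def _saturated_check(
    community: Community, mask: np.ndarray
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Interior equilibrium of the ``mask`` subcommunity, if solvable.

    Returns ``(phi_full, invasion_growth)`` where ``phi_full`` has zeros for
    excluded species, or ``(None, None)`` on a singular subsystem.
    """
    sub = _subcommunity(community, mask)
    try:
        phi_sub, _ = solve_feasible_fixed_point(sub)
    except SingularEquilibriumError:
        return None, None
    full = np.zeros(community.N)
    full[mask] = phi_sub
    growth = community.r * (1.0 - full / community.K) + community.sigma * (
        community.A @ full
    )
    return full, growth


def saturated_equilibrium(
    community: Community, max_iter: int | None = None
) -> tuple[np.ndarray, int] | None:
    """Deterministic greedy search for a saturated stable equilibrium.

    Starting from the full species set, repeatedly drops the most negative
    equilibrium component while the subcommunity equilibrium is infeasible,
    and re-admits the most strongly invading excluded species when one can
    grow.  Accepts a candidate iff the subcommunity Jacobian is stable and no
    excluded species has positive invasion growth.  Returns ``(phi, n)`` or
    ``None`` when the greedy path finds no such point.
    """
    N = community.N
    mask = np.ones(N, dtype=bool)
    if max_iter is None:
        max_iter = 4 * N
    seen: set[bytes] = set()
    for _ in range(max_iter):
        if not mask.any():
            return None
        key = mask.tobytes()
        if key in seen:  # re-admission cycle: give up on this path
            return None
        seen.add(key)
        full, growth = _saturated_check(community, mask)
        if full is None:
            return None
        inside = np.flatnonzero(mask)
        if np.any(full[inside] <= 0):
            mask[inside[np.argmin(full[inside])]] = False
            continue
        outside = np.flatnonzero(~mask)
        if outside.size and np.max(growth[outside]) > STABILITY_MARGIN:
            mask[outside[np.argmax(growth[outside])]] = True
            continue
        sub = _subcommunity(community, mask)
        eigvals, eigvecs = np.linalg.eig(jacobian_at(full[mask], sub))
        lead = int(np.argmax(eigvals.real))
        if eigvals.real[lead] < -STABILITY_MARGIN:
            return full, int(mask.sum())
        # unstable: drop the species dominating the unstable mode and retry
        mask[inside[int(np.argmax(np.abs(eigvecs[:, lead])))]] = False
    return None


def find_fixed_point(
    community: Community,
    phi0: np.ndarray,
    extinct_threshold: float = DEFAULT_EXTINCT_THRESHOLD,
    chunk: float = 100.0,
    max_time: float = 600.0,
    conv_rel_tol: float = 1e-6,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> tuple[str, np.ndarray | None, int | None]:
    """Search for a stable fixed point of the well-mixed model by simulation.

    Integrates from ``phi0`` in chunks until the state stops moving, then
    polishes the candidate on its surviving species subset via the linear
    solve and verifies (a) linear stability of the subcommunity Jacobian and
    (b) negative invasion growth for every excluded species — the saturated-
    equilibrium condition.

    Returns ``(status, phi, n_extant)`` with status in
    ``{"fp", "no_fp", "diverged"}``.
    """
    geometry = GridGeometry.single_point()
    phi = np.asarray(phi0, dtype=float).reshape(1, -1)
    t = 0.0
    while t < max_time:
        traj = integrate(
            community, None, geometry, phi, t_start=t, t_end=t + chunk,
            output_dt=chunk / 50.0, rtol=rtol, atol=atol,
        )
        if traj.diverged:
            return "diverged", None, None
        t += chunk
        phi_new = traj.phi[-1]
        tail = traj.phi[traj.times >= t - 0.2 * chunk]  # last fifth of chunk
        scale = np.maximum(tail.mean(axis=0), extinct_threshold)
        move = np.max((tail.max(axis=0) - tail.min(axis=0)) / scale)
        phi = phi_new
        if move < conv_rel_tol:
            break
    else:
        return "no_fp", None, None

    state = phi.ravel()
    extant = state > extinct_threshold
    if not extant.any():
        return "no_fp", None, None
    sub = Community(
        N=int(extant.sum()),
        A=community.A[np.ix_(extant, extant)],
        r=community.r[extant], K=community.K[extant],
        sigma=community.sigma, c=community.c, mu=community.mu,
    )
    try:
        phi_sub, feasible = solve_feasible_fixed_point(sub)
    except SingularEquilibriumError:
        return "no_fp", None, None
    if not feasible:
        return "no_fp", None, None
    if np.max(np.abs(phi_sub - state[extant]) / np.maximum(phi_sub, 1e-12)) > 0.05:
        return "no_fp", None, None  # simulation settled elsewhere
    if not is_linearly_stable(phi_sub, sub):
        return "no_fp", None, None
    full = np.zeros(community.N)
    full[extant] = phi_sub
    # invasion growth rate of each excluded species at the candidate point
    if (~extant).any():
        growth = community.r + community.sigma * (community.A @ full)
        if np.any(growth[~extant] > -STABILITY_MARGIN):
            return "no_fp", None, None
    return "fp", full, int(extant.sum())


def stability_scan(
    community: Community,
    sigma_grid: np.ndarray,
    n_restarts: int = 5,
    seed: int = 0,
    collapse_fraction: float = 0.5,
    extinct_threshold: float = DEFAULT_EXTINCT_THRESHOLD,
    ic_noise_sd: float = 0.2,
    max_time: float = 600.0,
) -> RegimeReport:
    """Label each sigma on an increasing grid with its non-spatial regime.

    Per sigma, a deterministic greedy saturated-equilibrium search runs
    first, then ``n_restarts`` seeded initial conditions are integrated to
    convergence (skipped when the greedy search already certifies the all-N
    point).  Labels: ``feasible`` if an all-N stable fixed point is found;
    ``structurally_unstable`` if the best stable fixed point keeps at least
    ``collapse_fraction`` of the species; otherwise
    ``collapsed_oscillatory`` (persistent oscillations, divergence, or a drop
    to a substantially smaller community).
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.ndim != 1 or np.any(np.diff(sigma_grid) <= 0):
        raise ValueError("sigma_grid must be 1-D and strictly increasing")
    geometry = GridGeometry.single_point()
    N = community.N
    labels: list[str] = []
    diversity: list[int | None] = []
    agreeing: list[int] = []
    flags: dict = {}
    for k, sigma in enumerate(sigma_grid):
        comm = community.with_sigma(sigma)
        outcomes: list[tuple[str, int | None]] = []
        n_div = 0
        # deterministic existence check first: greedy saturated equilibrium
        sat = saturated_equilibrium(comm)
        if sat is not None:
            outcomes.append(("fp", sat[1]))
        for j in range(n_restarts if (sat is None or sat[1] < N) else 0):
            rng = child_rng(seed, "restarts", k, j)
            ic_seed = int(rng.integers(0, 2**31 - 1))
            phi0 = default_initial_state(comm, geometry, ic_seed,
                                         noise_sd=ic_noise_sd)
            status, _, n_ext = find_fixed_point(
                comm, phi0, extinct_threshold=extinct_threshold,
                max_time=max_time,
            )
            if status == "diverged":
                n_div += 1
            else:
                outcomes.append((status, n_ext))
        fps = [n for s, n in outcomes if s == "fp"]
        if fps and max(fps) == N:
            label, best = LABEL_FEASIBLE, N
        elif fps and max(fps) >= collapse_fraction * N:
            label, best = LABEL_STRUCTURAL, max(fps)
        else:
            label, best = LABEL_COLLAPSED, (max(fps) if fps else None)
        labels.append(label)
        diversity.append(best)
        agreeing.append(sum(1 for s, n in outcomes
                            if (s == "fp" and n == best) or
                               (s == "no_fp" and label == LABEL_COLLAPSED)))
        if n_div:
            flags[float(sigma)] = f"{n_div}/{n_restarts} restarts diverged"

    feas = [s for s, l in zip(sigma_grid, labels) if l == LABEL_FEASIBLE]
    stable = [s for s, l in zip(sigma_grid, labels)
              if l in (LABEL_FEASIBLE, LABEL_STRUCTURAL)]
    sigma_feasibility = float(max(feas)) if feas else 0.0
    if stable and labels[-1] == LABEL_COLLAPSED:
        sigma_stability: float | None = float(max(stable))
    else:
        sigma_stability = None  # not bracketed within the scanned range
    return RegimeReport(
        sigma_grid=sigma_grid, labels=labels, diversity=diversity,
        n_restarts_agreeing=agreeing, sigma_feasibility=sigma_feasibility,
        sigma_stability=sigma_stability, flags=flags,
    )


def spatial_regime(
    run_summary: RunSummary,
    nonspatial_report: RegimeReport | None = None,
    sigma: float | None = None,
    sync_threshold: float = np.pi / 8.0,
    collapse_fraction: float = 0.5,
) -> str:
    """Classify one spatial run into the qualitative regime table.

    Rule (thresholds configurable): diverged or diversity below
    ``collapse_fraction`` of the feasible (all-species) diversity →
    ``collapsed``; no oscillating point → ``fixed_point``; oscillating and
    fixed points coexisting → ``mixed``; otherwise the synchronisation index
    decides between ``synchronised_oscillation`` (< ``sync_threshold``) and
    ``unsynchronised_oscillation``.
    """
    if run_summary.diverged_flag:
        return "collapsed"
    n_ref = run_summary.n_species
    if nonspatial_report is not None:
        feas_div = [d for d, l in zip(nonspatial_report.diversity,
                                      nonspatial_report.labels)
                    if l == LABEL_FEASIBLE and d is not None]
        if feas_div:
            n_ref = max(feas_div)
    if n_ref and run_summary.diversity < collapse_fraction * n_ref:
        return "collapsed"
    M = run_summary.n_points or len(run_summary.per_point_class)
    if run_summary.n_osc_points == 0:
        return "fixed_point"
    if run_summary.n_osc_points < M:
        return "mixed"
    if run_summary.sync_index is None or run_summary.sync_index < sync_threshold:
        return "synchronised_oscillation"
    return "unsynchronised_oscillation"
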