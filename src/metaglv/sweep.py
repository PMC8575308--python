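"""Experiment runner: single-system presets and the parameter-plane sweep.

A sweep evaluates ``n_systems`` independent random communities at every cell
of a (sigma x diffusion level) grid.  Within one system index the community
(interaction matrix) is held fixed across diffusion levels — isolating the
diffusion effect — while the per-species dispersal vector is redrawn for
each level from that level's decade.  Every cell is reproducible from the
config and its seeds alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from metaglv.boundaries import feasibility_boundary, find_fixed_point
from metaglv.dynamics import Trajectory, default_initial_state, integrate
from metaglv.ensemble import (
    Community,
    DispersalProfile,
    child_rng,
    sample_diffusion_rates,
    sample_interaction_matrix,
    sample_relative_spread,
)
from metaglv.grids import GridGeometry
from metaglv.measures import (
    DEFAULT_EXTINCT_THRESHOLD,
    DEFAULT_REL_TOL,
    RunSummary,
    global_mean_abundance,
    summarise_run,
)

__all__ = [
    "SweepConfig",
    "SweepResult",
    "derive_seed",
    "system_seed",
    "run_cell",
    "run_sweep",
    "preset_fig3",
    "preset_fig4",
    "FIG4_DIFFUSION_LEVELS",
]

#: the four diffusion means of the single-system diffusion scan (b = 0.4,
#: i.e. the mean equals 2.5 standard deviations)
FIG4_DIFFUSION_LEVELS = (1e-5, 1e-3, 1e-1, 1.0)

RECORD_COLUMNS = [
    "system", "community_seed", "sigma", "mu_D",
    "n_osc_points", "sync_index", "mean_amplitude", "diversity",
    "mean_local_diversity", "diverged", "wall_time",
]

PANEL_COLUMNS = [
    "n_osc_points", "sync_index", "mean_amplitude", "diversity",
    "mean_local_diversity",
]


def _float_tag(x: float) -> int:
    """Deterministic non-negative integer tag for a float (bit pattern)."""
    return int(np.float64(x).view(np.uint64))


def derive_seed(*parts: int) -> int:
    """Deterministic 63-bit seed derived from a tuple of integers."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1, dtype=np.uint64)[0] >> 1)


@dataclass
class SweepConfig:
    """Full specification of a parameter-plane experiment."""

    N: int = 20
    c: float = 0.5
    mu: float = -0.5
    sigma_grid: tuple[float, ...] = (0.25, 0.35, 0.45, 0.55)
    diffusion_levels: tuple[float, ...] = (0.0, 1e-3, 1e-2, 1e-1, 1.0)
    n_systems: int = 10
    b: float | None = None  # None: drawn per system from (0.3, 0.4)
    ring_length: int = 50
    ndim: int = 1
    t_end: float = 2000.0
    output_dt: float = 0.5
    transient_fraction: float = 0.5
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "RK45"
    rel_tol: float = DEFAULT_REL_TOL
    extinct_threshold: float = DEFAULT_EXTINCT_THRESHOLD
    ic_noise_sd: float = 0.2
    ic_kind: str = "fixed_point"  # or "uniform"
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.sigma_grid = tuple(float(s) for s in self.sigma_grid)
        self.diffusion_levels = tuple(float(d) for d in self.diffusion_levels)
        if not self.sigma_grid:
            raise ValueError("sigma_grid must be non-empty")
        if any(np.diff(self.sigma_grid) <= 0) or self.sigma_grid[0] <= 0:
            raise ValueError("sigma_grid must be positive and increasing")
        if any(d < 0 for d in self.diffusion_levels):
            raise ValueError("diffusion levels must be non-negative")
        if self.n_systems < 1:
            raise ValueError("n_systems must be >= 1")

    @property
    def geometry(self) -> GridGeometry:
        if self.ndim == 1:
            return GridGeometry.ring(self.ring_length)
        return GridGeometry.torus(self.ring_length, self.ring_length)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigma_grid"] = list(self.sigma_grid)
        d["diffusion_levels"] = list(self.diffusion_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SweepConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def system_seed(config: SweepConfig, system_index: int) -> int:
    """Seed of the ``system_index``-th community of a sweep."""
    return derive_seed(config.master_seed, 1, system_index)


def _build_cell(
    community_seed: int, sigma: float, mu_D: float, config: SweepConfig
) -> tuple[Community, DispersalProfile, GridGeometry, int]:
    A = sample_interaction_matrix(config.N, config.c, config.mu, community_seed)
    community = Community(N=config.N, A=A, sigma=float(sigma),
                          c=config.c, mu=config.mu)
    b = config.b if config.b is not None else sample_relative_spread(community_seed)
    d_seed = derive_seed(community_seed, 2, _float_tag(mu_D))
    D = sample_diffusion_rates(config.N, mu_D, b, d_seed)
    dispersal = DispersalProfile(D=D, mu_D=float(mu_D), b=float(b))
    ic_seed = derive_seed(community_seed, 3, _float_tag(mu_D), _float_tag(sigma))
    return community, dispersal, config.geometry, ic_seed


def run_cell(
    community_seed: int,
    sigma: float,
    mu_D: float,
    config: SweepConfig,
    return_trajectory: bool = False,
) -> RunSummary | tuple[RunSummary, Trajectory]:
    """Simulate and measure one (community, sigma, diffusion level) cell."""
    community, dispersal, geometry, ic_seed = _build_cell(
        community_seed, sigma, mu_D, config
    )
    phi0 = default_initial_state(community, geometry, ic_seed,
                                 noise_sd=config.ic_noise_sd,
                                 kind=config.ic_kind)
    trajectory = integrate(
        community, dispersal, geometry, phi0,
        t_end=config.t_end, output_dt=config.output_dt,
        rtol=config.rtol, atol=config.atol, method=config.method,
    )
    summary = summarise_run(
        trajectory,
        rel_tol=config.rel_tol,
        extinct_threshold=config.extinct_threshold,
        transient=config.transient_fraction * config.t_end,
    )
    summary.extras.update(
        community_seed=int(community_seed), sigma=float(sigma),
        mu_D=float(mu_D), b=float(dispersal.b), ic_seed=int(ic_seed),
    )
    if return_trajectory:
        return summary, trajectory
    return summary


@dataclass
class SweepResult:
    """All per-cell records of a sweep plus their panel aggregates."""

    config: SweepConfig
    records: pd.DataFrame
    aggregates: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.aggregates is None:
            self.aggregates = aggregate_records(self.records)


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(sigma, mu_D) means, dispersions and counts of the four panels."""
    ok = records[~records["diverged"].astype(bool)]
    grouped = ok.groupby(["sigma", "mu_D"])[PANEL_COLUMNS]
    agg = grouped.agg(["mean", "std", "count"])
    agg.columns = ["_".join(col) for col in agg.columns]
    return agg.reset_index()


def _summary_record(
    system: int, community_seed: int, sigma: float, mu_D: float,
    summary: RunSummary, wall_time: float,
) -> dict:
    return {
        "system": system,
        "community_seed": community_seed,
        "sigma": sigma,
        "mu_D": mu_D,
        "n_osc_points": summary.n_osc_points if not summary.diverged_flag else np.nan,
        "sync_index": np.nan if summary.sync_index is None else summary.sync_index,
        "mean_amplitude": (
            np.nan if summary.mean_amplitude is None else summary.mean_amplitude
        ),
        "diversity": summary.diversity if not summary.diverged_flag else np.nan,
        "mean_local_diversity": (
            np.nan if summary.per_point_diversity is None
            else float(np.mean(summary.per_point_diversity))
        ),
        "diverged": bool(summary.diverged_flag),
        "wall_time": wall_time,
    }


def run_sweep(
    config: SweepConfig,
    records_path: str | Path | None = None,
    progress: bool = False,
    log=None,
) -> SweepResult:
    """Run every (system, sigma, diffusion) cell of the configured sweep.

    With ``records_path`` each finished cell is appended to a CSV as it
    completes; re-running with the same path resumes, skipping cells already
    on disk, and the resumed result is identical to an uninterrupted run.
    Failed (diverged) cells are flagged in their record, never dropped.
    """
    done: set[tuple[int, float, float]] = set()
    rows: list[dict] = []
    path = Path(records_path) if records_path is not None else None
    if path is not None and path.exists():
        existing = pd.read_csv(path)
        rows = existing.to_dict("records")
        done = {
            (int(r["system"]), float(r["sigma"]), float(r["mu_D"]))
            for r in rows
        }

    cells = [
        (s, sigma, mu_D)
        for s in range(config.n_systems)
        for sigma in config.sigma_grid
        for mu_D in config.diffusion_levels
    ]
    iterator = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc="sweep")
    for system, sigma, mu_D in iterator:
        if (system, sigma, mu_D) in done:
            continue
        seed = system_seed(config, system)
        t0 = time.perf_counter()
        summary = run_cell(seed, sigma, mu_D, config)
        wall = time.perf_counter() - t0
        row = _summary_record(system, seed, sigma, mu_D, summary, wall)
        rows.append(row)
        if log is not None:
            log(
                f"cell system={system} seed={seed} sigma={sigma:g} "
                f"mu_D={mu_D:g} wall={wall:.2f}s "
                f"outcome={'diverged' if summary.diverged_flag else 'ok'}"
            )
        if path is not None:
            frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
            tmp = path.with_suffix(path.suffix + ".tmp")
            frame.to_csv(tmp, index=False)
            tmp.replace(path)

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records = records.sort_values(["system", "sigma", "mu_D"]).reset_index(drop=True)
    return SweepResult(config=config, records=records)


# ---------------------------------------------------------------------------
# single-system experiment presets
# ---------------------------------------------------------------------------


def _global_stats(
    trajectory: Trajectory, transient: float, extinct_threshold: float
) -> dict:
    """Post-transient global-mean series statistics per species."""
    traj = trajectory.after(transient)
    series = global_mean_abundance(traj)  # (T, N)
    mean = series.mean(axis=0)
    std = series.std(axis=0)
    cv = np.where(mean > extinct_threshold, std / np.maximum(mean, 1e-300), 0.0)
    amp_pp = (traj.phi.max(axis=0) - traj.phi.min(axis=0)) / 2.0  # (M, N)
    return {
        "global_mean": mean,
        "global_std": std,
        "global_cv": cv,
        "global_amplitude": (series.max(axis=0) - series.min(axis=0)) / 2.0,
        "mean_point_amplitude": amp_pp.mean(axis=0),
        "extant": mean > extinct_threshold,
    }


def preset_fig4(
    seed: int,
    config: SweepConfig | None = None,
    levels: tuple[float, ...] = FIG4_DIFFUSION_LEVELS,
) -> dict:
    """One community run across the four diffusion decades (b = 0.4).

    With b = 0.4 the uniform-draw mean equals 2.5 standard deviations.
    Returns a bundle: per level the trajectory, its summary and global-mean
    statistics, ordered by increasing diffusion.
    """
    if config is None:
        config = SweepConfig(b=0.4, t_end=400.0, output_dt=0.25, rtol=1e-7,
                             atol=1e-9, master_seed=seed)
    else:
        config = replace(config, b=0.4, master_seed=seed)
    community_seed = derive_seed(seed, 41)
    # pick sigma just beyond the feasibility boundary so oscillations exist
    A = sample_interaction_matrix(config.N, config.c, config.mu, community_seed)
    community = Community(N=config.N, A=A, c=config.c, mu=config.mu)
    sigma_f = feasibility_boundary(community, sigma_max=2.0).sigma
    sigma = 1.25 * sigma_f
    transient = config.transient_fraction * config.t_end
    bundle = {"seed": int(seed), "community_seed": community_seed,
              "sigma": float(sigma), "sigma_feasibility": float(sigma_f),
              "b": 0.4, "levels": []}
    for mu_D in levels:
        summary, trajectory = run_cell(
            community_seed, sigma, mu_D, config, return_trajectory=True
        )
        entry = {
            "mu_D": float(mu_D),
            "summary": summary,
            "trajectory": trajectory,
        }
        if not trajectory.diverged:
            entry.update(_global_stats(trajectory, transient,
                                       config.extinct_threshold))
        bundle["levels"].append(entry)
    return bundle


def _nonspatial_summary(
    community: Community, ic_seed: int, config: SweepConfig
) -> RunSummary:
    geometry = GridGeometry.single_point()
    phi0 = default_initial_state(community, geometry, ic_seed,
                                 noise_sd=config.ic_noise_sd)
    traj = integrate(
        community, None, geometry, phi0, t_end=config.t_end,
        output_dt=config.output_dt, rtol=config.rtol, atol=config.atol,
    )
    return summarise_run(
        traj, rel_tol=config.rel_tol,
        extinct_threshold=config.extinct_threshold,
        transient=config.transient_fraction * config.t_end,
    )




def _fig3_checks(
    summary: RunSummary,
    trajectory: Trajectory,
    ns_diversity: int,
    transient: float,
    extinct_threshold: float,
    rel_tol: float,
    cv_max: float,
    ratio_min: float,
) -> tuple[dict, dict]:
    """Evaluate the stabilisation checks on one spatial run.

    Returns ``(checks, diag)``: boolean checks and numeric diagnostics.
    """
    stats = _global_stats(trajectory, transient, extinct_threshold)
    extant = stats["extant"]
    osc = extant & (
        stats["mean_point_amplitude"]
        > rel_tol * np.maximum(stats["global_mean"], 1e-12)
    )
    diag = {
        "spatial_diversity": summary.diversity,
        "n_osc_points": summary.n_osc_points,
        "sync_index": summary.sync_index,
        "max_global_cv": (
            float(stats["global_cv"][extant].max()) if extant.any() else np.nan
        ),
    }
    checks = {
        "oscillatory": summary.n_osc_points > 0,
        "unsynchronised": (summary.sync_index is not None
                           and summary.sync_index >= np.pi / 8.0),
        "global_cv": bool(extant.any()
                          and np.all(stats["global_cv"][extant] < cv_max)),
        "amplitude_ratio": False,
        "diversity": summary.diversity >= ns_diversity,
    }
    if osc.any():
        scale = np.maximum(stats["global_std"][osc], 1e-12)
        ratios = stats["mean_point_amplitude"][osc] / scale
        diag["median_amplitude_ratio"] = float(np.median(ratios))
        checks["amplitude_ratio"] = bool(np.median(ratios) > ratio_min)
    diag["stats"] = stats
    return checks, diag


def preset_fig3(
    seed: int,
    budget: int = 50,
    config: SweepConfig | None = None,
    mu_D: float = 1e-2,
    cv_max: float = 0.05,
    amplitude_ratio_min: float = 10.0,
    sigma_factors: tuple[float, ...] = (4.5, 5.0, 5.5, 6.0),
    screen_ratio_min: float = 5.0,
    confirm_ring_lengths: tuple[int, ...] = (400, 600),
    probe_restarts: int = 2,
    probe_max_time: float = 300.0,
) -> dict:
    """Search seeded communities for the unsynchronised-stabilisation bundle.

    Looks for an N = 20 community and a sigma beyond the non-spatial
    fixed-point range where the spatial run (mu_D = 1e-2, b = 0.4) shows
    unsynchronised local oscillations whose global means are nearly constant
    — CV below ``cv_max`` for every extant species and per-point oscillation
    amplitudes more than ``amplitude_ratio_min`` times the global fluctuation
    scale — at diversity no lower than the non-spatial run at the same sigma.

    The search is two-stage: candidate (community, sigma) pairs are screened
    cheaply on the default 50-point ring, and promising ones are confirmed on
    long rings (where phase decorrelation fully averages the global means).
    Returns a bundle dict with ``success`` True and the paired spatial /
    non-spatial trajectories and summaries, or ``success`` False with
    per-candidate diagnostics.  Deterministic given ``seed``.
    """
    if config is None:
        config = SweepConfig(b=0.4, t_end=600.0, output_dt=0.5, rtol=1e-5,
                             atol=1e-8, ic_kind="uniform", master_seed=seed)
    else:
        config = replace(config, b=0.4, master_seed=seed)
    transient = config.transient_fraction * config.t_end
    confirm_config = replace(config, t_end=max(config.t_end, 800.0))
    confirm_transient = confirm_config.transient_fraction * confirm_config.t_end
    diagnostics: list[dict] = []

    for k in range(budget):
        community_seed = derive_seed(seed, 31, k)
        diag: dict = {"candidate": k, "community_seed": community_seed}
        A = sample_interaction_matrix(config.N, config.c, config.mu,
                                      community_seed)
        community = Community(N=config.N, A=A, c=config.c, mu=config.mu)
        est = feasibility_boundary(community, sigma_max=2.0)
        diag["sigma_feasibility"] = est.sigma
        if not est.bracketed:
            diag["reject"] = "feasibility boundary not bracketed"
            diagnostics.append(diag)
            continue

        # sigma values (beyond the boundary) with no stable non-spatial FP
        candidates: list[float] = []
        for factor in sigma_factors:
            sigma = factor * est.sigma
            comm = community.with_sigma(sigma)
            found_fp = False
            for j in range(probe_restarts):
                rng = child_rng(community_seed, "restarts", 97, j)
                phi0 = default_initial_state(
                    comm, GridGeometry.single_point(),
                    int(rng.integers(0, 2**31 - 1)),
                    noise_sd=config.ic_noise_sd,
                )
                status, _, _ = find_fixed_point(
                    comm, phi0, extinct_threshold=config.extinct_threshold,
                    max_time=probe_max_time,
                )
                if status == "fp":
                    found_fp = True
                    break
            if not found_fp:
                candidates.append(sigma)
        if not candidates:
            diag["reject"] = "non-spatial fixed points persist at all probed sigma"
            diagnostics.append(diag)
            continue

        for sigma_test in candidates:
            trial = dict(diag, sigma_test=sigma_test, stage="screen")
            comm = community.with_sigma(sigma_test)
            ns_summary = _nonspatial_summary(
                comm, derive_seed(community_seed, 98), config
            )
            trial["nonspatial_diversity"] = ns_summary.diversity

            summary, trajectory = run_cell(
                community_seed, sigma_test, mu_D, config,
                return_trajectory=True,
            )
            if trajectory.diverged:
                trial["reject"] = "spatial run diverged"
                diagnostics.append(trial)
                continue
            checks, info = _fig3_checks(
                summary, trajectory, ns_summary.diversity, transient,
                config.extinct_threshold, config.rel_tol,
                cv_max, screen_ratio_min,
            )
            info.pop("stats")
            trial.update(info, checks=checks)
            diagnostics.append(trial)
            if not all(checks.values()):
                continue

            # confirmation on long rings: the decisive amplitude-ratio and
            # CV thresholds are applied here at full decorrelation
            for L in confirm_ring_lengths:
                cfg_L = replace(confirm_config, ring_length=L)
                c_summary, c_traj = run_cell(
                    community_seed, sigma_test, mu_D, cfg_L,
                    return_trajectory=True,
                )
                c_trial = dict(diag, sigma_test=sigma_test, stage=f"confirm_L{L}")
                if c_traj.diverged:
                    c_trial["reject"] = "confirmation run diverged"
                    diagnostics.append(c_trial)
                    continue
                c_ns = _nonspatial_summary(
                    comm, derive_seed(community_seed, 98), cfg_L
                )
                c_checks, c_info = _fig3_checks(
                    c_summary, c_traj, c_ns.diversity, confirm_transient,
                    cfg_L.extinct_threshold, cfg_L.rel_tol,
                    cv_max, amplitude_ratio_min,
                )
                stats = c_info.pop("stats")
                c_trial.update(c_info, checks=c_checks)
                diagnostics.append(c_trial)
                if all(c_checks.values()):
                    return {
                        "success": True,
                        "seed": int(seed),
                        "community_seed": community_seed,
                        "sigma": float(sigma_test),
                        "sigma_feasibility": float(est.sigma),
                        "mu_D": float(mu_D),
                        "ring_length": int(L),
                        "spatial_summary": c_summary,
                        "spatial_trajectory": c_traj,
                        "nonspatial_summary": c_ns,
                        "global_stats": stats,
                        "diagnostics": diagnostics,
                        "config": replace(cfg_L, master_seed=seed),
                    }
    return {"success": False, "seed": int(seed), "diagnostics": diagnostics,
            "config": config}
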