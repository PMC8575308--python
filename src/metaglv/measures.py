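"""Measurement suite for simulated trajectories.

Per-grid-point dynamics classification, oscillation amplitudes, dominant
frequencies, Fourier phase-shift synchronisation statistics, diversity and
global (spatial-mean) abundances.  All spectral estimates remove the sample
mean and apply a Hann window before the transform to limit leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from metaglv.dynamics import Trajectory

__all__ = [
    "RunSummary",
    "classify_gridpoint",
    "oscillation_amplitude",
    "dominant_frequency",
    "phase_shift_pair",
    "sync_index",
    "diversity_count",
    "global_mean_abundance",
    "summarise_run",
    "DEFAULT_REL_TOL",
    "DEFAULT_EXTINCT_THRESHOLD",
]

#: relative fluctuation range below which a series counts as a fixed point
DEFAULT_REL_TOL = 1e-3

#: time-averaged abundance below which a species counts as locally extinct
DEFAULT_EXTINCT_THRESHOLD = 1e-4


@dataclass
class RunSummary:
    """One run's measurement record (one pixel of the parameter plane).

    ``sync_index`` and ``mean_amplitude`` are ``None`` (reported missing, not
    zero) when no grid-point oscillates.
    """

    n_osc_points: int
    sync_index: float | None
    mean_amplitude: float | None
    diversity: int
    global_mean_abundance: np.ndarray
    per_point_class: list[str]
    diverged_flag: bool = False
    extant_mask: np.ndarray | None = None
    per_point_diversity: np.ndarray | None = None
    amplitude_by_species: np.ndarray | None = None
    n_points: int = 0
    n_species: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diverged_flag:
            return
        if not 0 <= self.n_osc_points <= max(self.n_points, len(self.per_point_class)):
            raise ValueError("n_osc_points out of range")
        if self.sync_index is not None and not 0.0 <= self.sync_index <= np.pi + 1e-12:
            raise ValueError(f"sync_index {self.sync_index} outside [0, pi]")
        if self.mean_amplitude is not None and self.mean_amplitude < 0:
            raise ValueError("mean_amplitude must be non-negative")
        if self.diversity < 0 or (self.n_species and self.diversity > self.n_species):
            raise ValueError("diversity out of range")

    def to_dict(self) -> dict:
        def _arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "n_osc_points": int(self.n_osc_points),
            "sync_index": None if self.sync_index is None else float(self.sync_index),
            "mean_amplitude": (
                None if self.mean_amplitude is None else float(self.mean_amplitude)
            ),
            "diversity": int(self.diversity),
            "global_mean_abundance": _arr(self.global_mean_abundance),
            "per_point_class": list(self.per_point_class),
            "diverged_flag": bool(self.diverged_flag),
            "extant_mask": _arr(self.extant_mask),
            "per_point_diversity": _arr(self.per_point_diversity),
            "amplitude_by_species": _arr(self.amplitude_by_species),
            "n_points": int(self.n_points),
            "n_species": int(self.n_species),
            "extras": self.extras,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunSummary":
        def _arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            n_osc_points=int(d["n_osc_points"]),
            sync_index=None if d["sync_index"] is None else float(d["sync_index"]),
            mean_amplitude=(
                None if d["mean_amplitude"] is None else float(d["mean_amplitude"])
            ),
            diversity=int(d["diversity"]),
            global_mean_abundance=_arr(d["global_mean_abundance"]),
            per_point_class=list(d["per_point_class"]),
            diverged_flag=bool(d["diverged_flag"]),
            extant_mask=_arr(d["extant_mask"]),
            per_point_diversity=_arr(d["per_point_diversity"]),
            amplitude_by_species=_arr(d["amplitude_by_species"]),
            n_points=int(d.get("n_points", 0)),
            n_species=int(d.get("n_species", 0)),
            extras=dict(d.get("extras", {})),
        )


def _as_series_matrix(series: np.ndarray) -> np.ndarray:
    """Coerce (T,) or (T, k) input to (T, k)."""
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        return series[:, None]
    if series.ndim == 2:
        return series
    raise ValueError(f"expected a (T,) or (T, k) series array, got {series.shape}")


def relative_fluctuation(series: np.ndarray, floor: float = DEFAULT_EXTINCT_THRESHOLD) -> np.ndarray:
    """Per-column relative fluctuation range (max - min) / max(mean, floor)."""
    s = _as_series_matrix(series)
    rng = s.max(axis=0) - s.min(axis=0)
    denom = np.maximum(s.mean(axis=0), floor)
    return rng / denom


def classify_gridpoint(
    trajectory_slice: np.ndarray,
    rel_tol: float = DEFAULT_REL_TOL,
    extinct_threshold: float = DEFAULT_EXTINCT_THRESHOLD,
) -> str:
    """Classify one grid-point's post-transient series as fixed point or oscillation.

    ``fixed_point`` iff every locally extant species' relative fluctuation
    range stays below ``rel_tol``; an all-extinct point is the zero fixed
    point.  Input shape ``(T, N)`` (or ``(T,)`` for one species).
    """
    s = _as_series_matrix(trajectory_slice)
    extant = s.mean(axis=0) > extinct_threshold
    if not extant.any():
        return "fixed_point"
    fluct = relative_fluctuation(s[:, extant], floor=extinct_threshold)
    return "oscillation" if np.any(fluct >= rel_tol) else "fixed_point"


def oscillation_amplitude(series: np.ndarray) -> float:
    """Half the peak-to-peak range over the analysis window."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("oscillation_amplitude expects a single (T,) series")
    return float((series.max() - series.min()) / 2.0)


def _windowed_rfft(series: np.ndarray) -> np.ndarray:
    """rfft of the mean-removed, Hann-windowed series (columns independent)."""
    s = _as_series_matrix(series)
    s = s - s.mean(axis=0)
    window = np.hanning(s.shape[0])
    return np.fft.rfft(s * window[:, None], axis=0)


def dominant_frequency(
    series: np.ndarray,
    dt: float,
    rel_tol: float = DEFAULT_REL_TOL,
) -> float:
    """Frequency (cycles per unit time) of the largest non-zero spectral bin.

    Returns 0 for a sub-tolerance (fixed-point) series.  Requires at least
    4 uniform samples.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("dominant_frequency expects a single (T,) series")
    if series.size < 4:
        raise ValueError("series too short for spectral analysis")
    if relative_fluctuation(series)[0] < rel_tol:
        return 0.0
    spec = _windowed_rfft(series)[:, 0]
    freqs = np.fft.rfftfreq(series.size, d=dt)
    k = 1 + int(np.argmax(np.abs(spec[1:])))
    return float(freqs[k])


def _freq_bin(n_samples: int, dt: float, freq: float) -> int:
    """Index of the rfft bin nearest ``freq``; rejects unresolvable bands."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    nyquist = 0.5 / dt
    if freq > nyquist:
        raise ValueError(f"freq {freq} above Nyquist {nyquist}")
    k = int(round(freq * n_samples * dt))
    if k < 1:
        raise ValueError(
            f"freq {freq} below the resolvable band (window too short)"
        )
    return min(k, n_samples // 2)


def _wrap_phase(delta: np.ndarray) -> np.ndarray:
    """Fold phase differences into [0, pi] (lags d and 2 pi - d coincide)."""
    d = np.abs(np.mod(delta, 2.0 * np.pi))
    return np.minimum(d, 2.0 * np.pi - d)


def phase_shift_pair(
    series_a: np.ndarray,
    series_b: np.ndarray,
    dt: float,
    freq: float,
) -> float:
    """Absolute Fourier-argument difference of two series at ``freq``.

    Both series must share the same uniform time grid; the result is wrapped
    into [0, pi].
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and share one time grid")
    k = _freq_bin(a.size, dt, freq)
    spec = _windowed_rfft(np.column_stack([a, b]))
    delta = np.angle(spec[k, 0]) - np.angle(spec[k, 1])
    return float(_wrap_phase(np.asarray(delta)))


def _species_phase_stats(
    phi: np.ndarray,
    dt: float,
    extant_local: np.ndarray,
    rel_tol: float,
) -> tuple[float | None, float]:
    """Max pairwise phase shift and dominant frequency for one species.

    ``phi``: (T, M) series of the species at every grid-point.
    ``extant_local``: (M,) bool mask of points where it is locally extant.
    Returns (max phase shift or None if < 2 oscillating points, frequency).
    """
    fluct = relative_fluctuation(phi)
    osc = extant_local & (fluct >= rel_tol)
    if osc.sum() < 2:
        return None, 0.0
    spec = _windowed_rfft(phi[:, osc])
    power = np.abs(spec[1:]) ** 2
    k = 1 + int(np.argmax(power.mean(axis=1)))
    freqs = np.fft.rfftfreq(phi.shape[0], d=dt)
    phases = np.angle(spec[k])
    pairwise = _wrap_phase(phases[:, None] - phases[None, :])
    return float(pairwise.max()), float(freqs[k])


def sync_index(
    trajectory: Trajectory,
    extant_mask: np.ndarray | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
    extinct_threshold: float = DEFAULT_EXTINCT_THRESHOLD,
) -> float | None:
    """Mean over extant species of the maximum between-point phase shift.

    For each extant species the dominant oscillation frequency is estimated
    from the grid-point-averaged power spectrum (over points where it is
    locally extant and oscillating), and the maximum of the pairwise wrapped
    phase differences at that frequency is taken over all such point pairs.
    The index is the mean of these maxima over contributing species: 0 for a
    fully synchronised grid, pi for anti-phase.  Returns ``None`` when no
    species oscillates at two or more points (undefined, not zero).
    """
    phi = trajectory.phi  # (T, M, N)
    tmean = phi.mean(axis=0)  # (M, N)
    if extant_mask is None:
        extant_mask = np.any(tmean > extinct_threshold, axis=0)
    dt = trajectory.dt
    maxima = []
    for i in np.flatnonzero(extant_mask):
        shift, _ = _species_phase_stats(
            phi[:, :, i], dt, tmean[:, i] > extinct_threshold, rel_tol
        )
        if shift is not None:
            maxima.append(shift)
    if not maxima:
        return None
    return float(np.mean(maxima))


def diversity_count(
    trajectory: Trajectory,
    extinct_threshold: float = DEFAULT_EXTINCT_THRESHOLD,
) -> tuple[int, np.ndarray]:
    """Global diversity and the per-species extant mask.

    A species is extant iff its time-averaged abundance exceeds the threshold
    at one or more grid-points (spatial-rescue semantics: locally extinct but
    abundant elsewhere still counts).
    """
    tmean = trajectory.phi.mean(axis=0)  # (M, N)
    mask = np.any(tmean > extinct_threshold, axis=0)
    return int(mask.sum()), mask


def global_mean_abundance(trajectory: Trajectory) -> np.ndarray:
    """Unweighted spatial mean at each output time; shape ``(T, N)``."""
    return trajectory.phi.mean(axis=1)


def summarise_run(
    trajectory: Trajectory,
    rel_tol: float = DEFAULT_REL_TOL,
    extinct_threshold: float = DEFAULT_EXTINCT_THRESHOLD,
    transient: float | None = None,
) -> RunSummary:
    """Assemble the full measurement record for one completed run.

    ``transient``: time before which samples are discarded; defaults to the
    midpoint of the simulated span.  A diverged trajectory yields a record
    with ``diverged_flag`` set and all measures missing.
    """
    if trajectory.diverged:
        return RunSummary(
            n_osc_points=0, sync_index=None, mean_amplitude=None,
            diversity=0, global_mean_abundance=None, per_point_class=[],
            diverged_flag=True,
            n_points=trajectory.n_points, n_species=trajectory.n_species,
        )
    if transient is None:
        transient = 0.5 * (trajectory.times[0] + trajectory.times[-1])
    traj = trajectory.after(transient)
    phi = traj.phi
    T, M, N = phi.shape
    tmean = phi.mean(axis=0)
    local_extant = tmean > extinct_threshold  # (M, N)

    classes = [
        classify_gridpoint(phi[:, m, :], rel_tol, extinct_threshold)
        for m in range(M)
    ]
    n_osc = sum(1 for c in classes if c == "oscillation")

    diversity, extant = diversity_count(traj, extinct_threshold)
    sync = sync_index(traj, extant, rel_tol, extinct_threshold)

    # amplitudes over locally-extant, fluctuating (species, point) series
    fluct = np.stack([relative_fluctuation(phi[:, m, :]) for m in range(M)])
    osc_cells = local_extant & (fluct >= rel_tol)  # (M, N)
    amp_cells = (phi.max(axis=0) - phi.min(axis=0)) / 2.0
    if osc_cells.any():
        mean_amp = float(amp_cells[osc_cells].mean())
        by_species = np.array([
            amp_cells[osc_cells[:, i], i].mean() if osc_cells[:, i].any() else np.nan
            for i in range(N)
        ])
    else:
        mean_amp, by_species = None, np.full(N, np.nan)

    return RunSummary(
        n_osc_points=n_osc,
        sync_index=sync,
        mean_amplitude=mean_amp,
        diversity=diversity,
        global_mean_abundance=global_mean_abundance(traj).mean(axis=0),
        per_point_class=classes,
        diverged_flag=False,
        extant_mask=extant,
        per_point_diversity=local_extant.sum(axis=1),
        amplitude_by_species=by_species,
        n_points=M,
        n_species=N,
        extras={"transient": float(transient), "window": float(traj.times[-1] - traj.times[0])},
    )
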