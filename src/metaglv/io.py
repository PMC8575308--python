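"""Serialisation: system description files, trajectory containers, summaries.

System descriptions are a single JSON document — a header of scalar
parameters plus an embedded array block for ``A`` and ``D`` — chosen over a
binary sidecar so that saved systems are diffable and survive text-only
archiving.  Floats round-trip bit-exactly through JSON's shortest-repr
encoding.  Trajectories (large numeric blocks) use NumPy ``.npz``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from metaglv import __version__ as _pkg_version
from metaglv.dynamics import Trajectory
from metaglv.ensemble import Community, DispersalProfile
from metaglv.grids import GridGeometry
from metaglv.measures import RunSummary

__all__ = [
    "FORMAT_VERSION",
    "save_system",
    "load_system",
    "save_trajectory",
    "load_trajectory",
    "save_summary",
    "load_summary",
]

FORMAT_VERSION = 1


def save_system(
    path: str | Path,
    community: Community,
    dispersal: DispersalProfile,
    geometry: GridGeometry,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    doc = {
        "format": "metaglv-system",
        "format_version": FORMAT_VERSION,
        "package_version": _pkg_version,
        "header": {
            "N": community.N,
            "c": community.c,
            "mu": community.mu,
            "sigma": community.sigma,
            "mu_D": dispersal.mu_D,
            "b": dispersal.b,
            "geometry": geometry.to_dict(),
            "seed": seed,
        },
        "arrays": {
            "A": community.A.tolist(),
            "D": dispersal.D.tolist(),
            "r": community.r.tolist(),
            "K": community.K.tolist(),
        },
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_system(
    path: str | Path,
) -> tuple[Community, DispersalProfile, GridGeometry, dict]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "metaglv-system":
        raise ValueError(f"{path} is not a metaglv system file")
    h = doc["header"]
    arrays = doc["arrays"]
    community = Community(
        N=int(h["N"]),
        A=np.asarray(arrays["A"], dtype=float),
        r=np.asarray(arrays["r"], dtype=float),
        K=np.asarray(arrays["K"], dtype=float),
        sigma=float(h["sigma"]),
        c=float(h["c"]),
        mu=float(h["mu"]),
    )
    dispersal = DispersalProfile(
        D=np.asarray(arrays["D"], dtype=float),
        mu_D=float(h["mu_D"]),
        b=float(h["b"]),
    )
    geometry = GridGeometry.from_dict(h["geometry"])
    return community, dispersal, geometry, doc


def save_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    np.savez_compressed(
        path,
        times=trajectory.times,
        phi=trajectory.phi,
        geometry=json.dumps(trajectory.geometry.to_dict()),
        diverged=np.array(trajectory.diverged),
        meta=json.dumps(trajectory.meta),
        format_version=np.array(FORMAT_VERSION),
    )


def load_trajectory(path: str | Path) -> Trajectory:
    with np.load(path, allow_pickle=False) as z:
        return Trajectory(
            times=z["times"],
            phi=z["phi"],
            geometry=GridGeometry.from_dict(json.loads(str(z["geometry"]))),
            diverged=bool(z["diverged"]),
            meta=json.loads(str(z["meta"])),
        )


def save_summary(path: str | Path, summary: RunSummary, extra: dict | None = None) -> None:
    doc = {
        "format": "metaglv-summary",
        "format_version": FORMAT_VERSION,
        "summary": summary.to_dict(),
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_summary(path: str | Path) -> RunSummary:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "metaglv-summary":
        raise ValueError(f"{path} is not a metaglv summary file")
    return RunSummary.from_dict(doc["summary"])
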