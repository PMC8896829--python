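"""Serialization of geometries, trajectories and experiment results.

Trajectories are stored as numpy ``.npz`` archives (per-state vertex
arrays plus convergence metadata, geometry arrays and a JSON-encoded
parameter block) and round-trip bit-exactly.  Metrics tables are
exported as UTF-8 CSV with '.' decimal separators.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .equilibrate import EquilibriumState, Trajectory
from .geometry import EmbryoGeometry, TissueAnnotation
from .mechanics import ModelParams

__all__ = [
    "write_geometry",
    "read_geometry",
    "write_trajectory",
    "read_trajectory",
    "TrajectoryFormatError",
]

_FORMAT_VERSION = 1


class TrajectoryFormatError(RuntimeError):
    """Raised when an archive is missing, truncated or from another version."""


def write_geometry(geom: EmbryoGeometry, path: str | Path) -> None:
    """Store a geometry as an ``.npz`` archive (bit-exact round trip)."""
    np.savez(
        Path(path),
        format_version=np.int64(_FORMAT_VERSION),
        apical=geom.apical,
        basal=geom.basal,
        rest_apical=geom.rest_apical,
        rest_basal=geom.rest_basal,
        rest_lateral=geom.rest_lateral,
        rest_area=geom.rest_area,
        rest_yolk_area=np.float64(geom.rest_yolk_area),
        vitelline_radius=np.float64(geom.vitelline_radius),
    )


def read_geometry(path: str | Path) -> EmbryoGeometry:
    with np.load(Path(path)) as z:
        _check_version(z)
        return EmbryoGeometry(
            apical=z["apical"],
            basal=z["basal"],
            rest_apical=z["rest_apical"],
            rest_basal=z["rest_basal"],
            rest_lateral=z["rest_lateral"],
            rest_area=z["rest_area"],
            rest_yolk_area=float(z["rest_yolk_area"]),
            vitelline_radius=float(z["vitelline_radius"]),
        )


def _check_version(z) -> None:
    if "format_version" not in z:
        raise TrajectoryFormatError("archive has no format_version field")
    v = int(z["format_version"])
    if v != _FORMAT_VERSION:
        raise TrajectoryFormatError(
            f"archive format version {v} != supported {_FORMAT_VERSION}"
        )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Store a trajectory (states + geometry + parameters) as ``.npz``."""
    geom = traj.geometry
    np.savez(
        Path(path),
        format_version=np.int64(_FORMAT_VERSION),
        vertices=np.stack([s.vertices for s in traj.states]),
        schedule=np.asarray(traj.schedule, float),
        energy=np.asarray([s.energy for s in traj.states]),
        grad_norm=np.asarray([s.grad_norm for s in traj.states]),
        n_iter=np.asarray([s.n_iter for s in traj.states], dtype=np.int64),
        converged=np.asarray([s.converged for s in traj.states], dtype=bool),
        phi=traj.annotation.phi,
        activity=traj.annotation.activity,
        params=np.str_(json.dumps(dataclasses.asdict(traj.params))),
        perturbation=np.str_(json.dumps(traj.perturbation)),
        apical=geom.apical,
        basal=geom.basal,
        rest_apical=geom.rest_apical,
        rest_basal=geom.rest_basal,
        rest_lateral=geom.rest_lateral,
        rest_area=geom.rest_area,
        rest_yolk_area=np.float64(geom.rest_yolk_area),
        vitelline_radius=np.float64(geom.vitelline_radius),
    )


def read_trajectory(path: str | Path) -> Trajectory:
    """Load a trajectory archive written by :func:`write_trajectory`.

    Corrupted or truncated files raise :class:`TrajectoryFormatError`.
    """
    path = Path(path)
    try:
        z = np.load(path, allow_pickle=False)
    except Exception as exc:
        raise TrajectoryFormatError(f"cannot read trajectory archive {path}: {exc}") from exc
    with z:
        _check_version(z)
        try:
            geom = EmbryoGeometry(
                apical=z["apical"],
                basal=z["basal"],
                rest_apical=z["rest_apical"],
                rest_basal=z["rest_basal"],
                rest_lateral=z["rest_lateral"],
                rest_area=z["rest_area"],
                rest_yolk_area=float(z["rest_yolk_area"]),
                vitelline_radius=float(z["vitelline_radius"]),
            )
            ann = TissueAnnotation(phi=z["phi"], activity=z["activity"])
            params = ModelParams(**json.loads(str(z["params"])))
            perturbation = json.loads(str(z["perturbation"]))
            schedule = [float(v) for v in z["schedule"]]
            vertices = z["vertices"]
            states = [
                EquilibriumState(
                    vertices=vertices[i],
                    Kb=float(z["schedule"][i]),
                    energy=float(z["energy"][i]),
                    grad_norm=float(z["grad_norm"][i]),
                    n_iter=int(z["n_iter"][i]),
                    converged=bool(z["converged"][i]),
                )
                for i in range(vertices.shape[0])
            ]
        except KeyError as exc:
            raise TrajectoryFormatError(
                f"trajectory archive {path} is missing field {exc}"
            ) from exc
    return Trajectory(
        states=states,
        schedule=schedule,
        params=params,
        geometry=geom,
        annotation=ann,
        perturbation=perturbation,
    )
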