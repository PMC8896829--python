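"""Tissue- and cell-level readouts on simulated equilibrium states.

The primary furrow-progress readout is the invagination depth D: the
radial distance between the vitelline membrane and the apex of the
tissue at the ventral midline.  Per-cell shape descriptors (edge
lengths, areas, tilt of the apicobasal axis) quantify the morphologies
the model produces, and angular sector areas of the cell layer provide
a thickness proxy for the lateral ectoderm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .equilibrate import EquilibriumState, Trajectory
from .geometry import EmbryoGeometry, midline_offsets, polygon_areas
from .mechanics import Configuration

__all__ = [
    "invagination_depth",
    "cell_shape_metrics",
    "ectoderm_sector_area",
    "count_constricting_cells",
    "tissue_metrics",
]


def _vertices(s: EquilibriumState | Configuration | np.ndarray) -> np.ndarray:
    if isinstance(s, EquilibriumState):
        return s.vertices
    if isinstance(s, Configuration):
        return s.vertices
    return np.asarray(s, float)


def invagination_depth(s, geom: EmbryoGeometry) -> float:
    """Invagination depth D: shell radius minus the apical midline radius.

    The midline apex is the apical vertex shared by the two
    midline-adjacent cells (vertex 0 in the ring numbering).  D is zero
    on the initial configuration, where all apices sit on the shell.
    """
    x = _vertices(s)
    apex_r = float(np.linalg.norm(x[0]))
    return geom.vitelline_radius - apex_r


def cell_shape_metrics(s, geom: EmbryoGeometry) -> pd.DataFrame:
    """Per-cell shape table: edge lengths, area and apicobasal tilt.

    Tilt is the unsigned angle (radians) between the cell's apicobasal
    axis (apical edge midpoint minus basal edge midpoint) and the local
    radial direction at the cell centroid; it is zero for the initial
    radial wedges.
    """
    x = _vertices(s)
    n = geom.n_cells
    c = Configuration(x)
    a = c.apical_lengths()
    b = c.basal_lengths()
    lat = c.lateral_lengths()
    mean_lateral = 0.5 * (lat + np.roll(lat, -1))
    area = c.cell_areas(geom)

    A, B = x[:n], x[n:]
    mid_apical = 0.5 * (A + np.roll(A, -1, axis=0))
    mid_basal = 0.5 * (B + np.roll(B, -1, axis=0))
    axis = mid_apical - mid_basal
    centroid = 0.5 * (mid_apical + mid_basal)
    rad = centroid / np.maximum(np.linalg.norm(centroid, axis=1), 1e-300)[:, None]
    axis_n = axis / np.maximum(np.linalg.norm(axis, axis=1), 1e-300)[:, None]
    cosang = np.clip(np.sum(axis_n * rad, axis=1), -1.0, 1.0)
    tilt = np.arccos(cosang)

    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "apical": a,
            "basal": b,
            "lateral": mean_lateral,
            "area": area,
            "tilt": tilt,
        }
    )


def _centroid_angle_from_midline(x: np.ndarray, n: int) -> np.ndarray:
    """Unsigned angle (degrees) of each cell centroid from the ventral midline.

    Measured on the *initial* wedge positions would be trivial; here it
    uses the current centroid, with the midline along the negative-y
    axis.  Returns angles in [0, 180] and the side sign (negative x =
    left, positive x = right).
    """
    A, B = x[:n], x[n:]
    centroid = 0.25 * (A + np.roll(A, -1, axis=0) + B + np.roll(B, -1, axis=0))
    ang = np.degrees(np.arctan2(centroid[:, 0], -centroid[:, 1]))
    return ang  # signed: positive to the right of the midline


def ectoderm_sector_area(
    s,
    geom: EmbryoGeometry,
    angle_window: tuple[float, float] = (60.0, 90.0),
    side: str = "both",
) -> float:
    """Total cell-layer area in an angular window from the ventral midline.

    Cells belong to the window when their centroid angle (degrees from
    the midline axis, 0 = ventral pole, 180 = dorsal pole) lies in
    ``[lo, hi)``.  ``side`` selects the left (x < 0), right (x > 0) or
    both halves.  A full partition of windows over (0, 180] on both
    sides recovers the total cell-layer area exactly.
    """
    lo, hi = angle_window
    if not (0.0 <= lo < hi <= 180.0):
        raise ValueError(f"invalid angular window {angle_window}")
    if side not in ("left", "right", "both"):
        raise ValueError(f"side must be left/right/both, got {side!r}")
    x = _vertices(s)
    n = geom.n_cells
    signed = _centroid_angle_from_midline(x, n)
    ang = np.abs(signed)
    in_window = (ang >= lo) & (ang < hi)
    # the dorsal pole cell (angle exactly 180) belongs to the topmost window
    if hi == 180.0:
        in_window |= ang == 180.0
    if side == "left":
        in_window &= signed < 0
    elif side == "right":
        in_window &= signed >= 0
    areas = polygon_areas(x, geom.cell_vertex_indices)
    return float(np.sum(areas[in_window]))


def count_constricting_cells(traj: Trajectory, threshold_fraction: float = 0.5) -> int:
    """Number of cells whose final apical length dropped below a fraction
    of its initial value.

    With the Gaussian contractility profile only the ventral-most cells
    constrict appreciably, even though the mesoderm domain is wider.
    """
    geom = traj.geometry
    final = Configuration(traj.final.vertices).apical_lengths()
    initial = Configuration(geom.vertices).apical_lengths()
    return int(np.sum(final < threshold_fraction * initial))


def tissue_metrics(traj: Trajectory) -> pd.DataFrame:
    """Per-state tissue summary: Kb, energy, D, yolk area, convergence."""
    geom = traj.geometry
    rows = []
    for idx, (kb, st) in enumerate(zip(traj.schedule, traj.states)):
        cfg = Configuration(st.vertices)
        rows.append(
            {
                "state_index": idx,
                "Kb": kb,
                "D": invagination_depth(st, geom),
                "energy": st.energy,
                "yolk_area": cfg.yolk_area(),
                "grad_norm": st.grad_norm,
                "n_iter": st.n_iter,
                "converged": st.converged,
            }
        )
    return pd.DataFrame(rows)


def per_cell_metrics(traj: Trajectory) -> pd.DataFrame:
    """Long-format per-cell table across all states of a trajectory."""
    frames = []
    for idx, st in enumerate(traj.states):
        df = cell_shape_metrics(st, traj.geometry)
        df.insert(0, "state_index", idx)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
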