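"""Summary figures: cross-section panels and depth-vs-state curves.

Figures are deterministic for fixed inputs (fixed canvas, no
timestamps) so repeated renders are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np

from .equilibrate import Trajectory
from .metrics import invagination_depth

__all__ = ["plot_cross_section", "plot_depth_curve", "render_summary"]

_SAVEFIG = dict(dpi=110, metadata={"Software": None})


def _draw_state(ax, traj: Trajectory, index: int) -> None:
    geom = traj.geometry
    n = geom.n_cells
    x = traj.states[index].vertices
    shell = plt.Circle((0, 0), geom.vitelline_radius, fill=False,
                       color="0.55", lw=0.8, ls="--")
    ax.add_patch(shell)
    quads = geom.cell_vertex_indices
    meso = traj.annotation.phi.astype(bool)
    for i in range(n):
        poly = x[quads[i]]
        ax.fill(poly[:, 0], poly[:, 1],
                facecolor="#d95f5f" if meso[i] else "#9ecae1",
                edgecolor="k", lw=0.3)
    ax.set_aspect("equal")
    lim = geom.vitelline_radius * 1.08
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.invert_yaxis()  # ventral side up
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"state {index}, Kb={traj.schedule[index]:g}", fontsize=8)


def plot_cross_section(traj: Trajectory, path: str | Path,
                       indices: tuple[int, ...] | None = None) -> Path:
    """Panel of embryo cross-sections at selected schedule states."""
    if indices is None:
        last = traj.n_states - 1
        indices = tuple(sorted({0, last // 3, 2 * last // 3, last}))
    fig, axes = plt.subplots(1, len(indices), figsize=(2.6 * len(indices), 2.8))
    axes = np.atleast_1d(axes)
    for ax, idx in zip(axes, indices):
        _draw_state(ax, traj, idx)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)
    return path


def plot_depth_curve(traj: Trajectory, path: str | Path) -> Path:
    """Invagination depth D versus schedule state."""
    geom = traj.geometry
    D = [invagination_depth(s, geom) for s in traj.states]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(range(len(D)), D, "o-", color="#333333", ms=4)
    if traj.perturbation and "from_index" in traj.perturbation:
        ax.axvline(traj.perturbation["from_index"], color="#d95f5f", ls=":",
                   label="inhibition")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("schedule state (decreasing Kb)")
    ax.set_ylabel("invagination depth D (um)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)
    return path


def render_summary(result, out_dir: str | Path, stem: str = "summary") -> list[Path]:
    """Render the standard panels for an experiment result.

    Returns the list of files written.  Plot failures are reported but
    never abort the caller.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    traj = result.trajectory if hasattr(result, "trajectory") else result
    try:
        written.append(plot_cross_section(traj, out_dir / f"{stem}_states.png"))
        written.append(plot_depth_curve(traj, out_dir / f"{stem}_depth.png"))
    except Exception as exc:  # pragma: no cover - defensive
        import logging

        logging.getLogger(__name__).warning("plotting failed: %s", exc)
    return written
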