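"""Synthetic embryo cross-section geometry.

The model operates on a 2D cross-section of a cellularized *Drosophila*
embryo: a ring of congruent wedge-shaped cells sandwiched between the
vitelline membrane (a rigid outer circle, the eggshell) and the yolk (the
inner disc).  Each cell is a quadrilateral with one apical edge on the
outer circle, one basal edge on the inner circle and two lateral edges
shared with its neighbours.

Conventions
-----------
* All lengths are in micrometres, areas in square micrometres.
* Cells are numbered ``0 .. n-1`` counter-clockwise starting at the
  ventral midline, which points along the negative-y axis.  Cell ``i``
  spans polar angles ``[-90 deg + i*w, -90 deg + (i+1)*w]`` with
  ``w = 360/n`` degrees.
* Vertex ``j`` (apical or basal) sits at angle ``-90 deg + j*w``; cell
  ``i`` owns apical vertices ``i, i+1`` and basal vertices ``i, i+1``.
* Lateral edge ``j`` joins apical vertex ``j`` to basal vertex ``j`` and
  is shared by cells ``j-1`` and ``j`` (mod n).  Each lateral edge is
  stored exactly once.

The mesoderm (prospective ventral furrow) is the block of cells
straddling the midline; apical contractility follows a Gaussian profile
centred on the midline.  Because the cell count is even, the midline
falls on the boundary between two cells and Gaussian offsets are
half-integers (+-0.5, +-1.5, ...), which keeps the profile exactly
mirror-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryParams",
    "EmbryoGeometry",
    "TissueAnnotation",
    "build_initial_geometry",
    "mesoderm_mask",
    "contractility_profile",
    "midline_offsets",
    "mirror_permutation",
    "mirror_vertices",
    "constriction_lateral_edges",
    "ectoderm_lateral_edges",
]


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the initial cross-section.

    Attributes
    ----------
    n_cells:
        Number of wedge cells in the ring (even, >= 8).
    vitelline_radius:
        Radius of the vitelline membrane (eggshell), micrometres.
    cell_length:
        Initial apicobasal cell length, micrometres; the yolk radius is
        ``vitelline_radius - cell_length``.
    yolk:
        The yolk disc is always present; kept as an explicit flag for
        config round-tripping.
    """

    n_cells: int = 80
    vitelline_radius: float = 90.0
    cell_length: float = 35.0
    yolk: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 8 or self.n_cells % 2 != 0:
            raise ValueError(f"n_cells must be even and >= 8, got {self.n_cells}")
        if not 0.0 < self.cell_length < self.vitelline_radius:
            raise ValueError(
                "cell_length must satisfy 0 < cell_length < vitelline_radius "
                f"(got {self.cell_length} vs {self.vitelline_radius})"
            )
        if not self.yolk:
            raise ValueError("the model requires a yolk disc (yolk=True)")


@dataclass
class EmbryoGeometry:
    """Reference (rest) geometry and connectivity of the cell ring.

    Rest lengths and areas are set to the constructed initial values;
    they are the ``a0, b0, l0, V0`` entering the elastic energy.
    """

    apical: np.ndarray        # (n, 2) initial apical vertex positions
    basal: np.ndarray         # (n, 2) initial basal vertex positions
    rest_apical: np.ndarray   # (n,)  apical rest lengths a0
    rest_basal: np.ndarray    # (n,)  basal rest lengths b0
    rest_lateral: np.ndarray  # (n,)  lateral rest lengths l0
    rest_area: np.ndarray     # (n,)  cell rest areas V0
    rest_yolk_area: float     # yolk rest area V0_yolk
    vitelline_radius: float

    @property
    def n_cells(self) -> int:
        return self.apical.shape[0]

    @property
    def vertices(self) -> np.ndarray:
        """Initial vertex array of shape (2n, 2): apical block then basal."""
        return np.vstack([self.apical, self.basal])

    @property
    def cell_vertex_indices(self) -> np.ndarray:
        """(n, 4) vertex indices of each cell polygon, counter-clockwise.

        Order: apical i, apical i+1, basal i+1, basal i, indexing into
        the stacked ``vertices`` array.
        """
        n = self.n_cells
        i = np.arange(n)
        j = (i + 1) % n
        return np.stack([i, j, n + j, n + i], axis=1)

    def copy(self) -> "EmbryoGeometry":
        return EmbryoGeometry(
            apical=self.apical.copy(),
            basal=self.basal.copy(),
            rest_apical=self.rest_apical.copy(),
            rest_basal=self.rest_basal.copy(),
            rest_lateral=self.rest_lateral.copy(),
            rest_area=self.rest_area.copy(),
            rest_yolk_area=float(self.rest_yolk_area),
            vitelline_radius=float(self.vitelline_radius),
        )


@dataclass
class TissueAnnotation:
    """Mesoderm/ectoderm partition and the contractility pattern.

    ``phi`` is the 0/1 mesoderm indicator.  ``activity`` is a per-cell
    multiplier on the contractility weight, normally 1 inside the
    mesoderm; perturbation experiments use it to silence individual
    cells (e.g. every other constricting cell).  The actual energy
    weights ``mu_i * phi_i`` depend on the model parameters
    (amplitude mu0 and Gaussian width sigma) and are computed by
    :meth:`contractility_weights`, so that zeroing ``mu0`` — the
    in-silico optogenetic inhibition — acts instantaneously.
    """

    phi: np.ndarray                 # (n,) int 0/1 mesoderm indicator
    activity: np.ndarray = None     # (n,) float pattern multiplier, >= 0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=int)
        if self.activity is None:
            self.activity = np.ones(self.phi.shape[0])
        self.activity = np.asarray(self.activity, dtype=float)
        if self.phi.shape != self.activity.shape:
            raise ValueError("phi and activity must have the same length")
        if np.any(self.activity < 0):
            raise ValueError("activity multipliers must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.phi.shape[0]

    @property
    def mesoderm_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phi == 1)

    @property
    def ectoderm_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phi == 0)

    def contractility_weights(self, mu0: float, sigma: float) -> np.ndarray:
        """Per-cell weights ``mu_i * phi_i`` of the apical term."""
        return contractility_profile(mu0, sigma, self.phi) * self.activity


def build_initial_geometry(p: GeometryParams) -> EmbryoGeometry:
    """Construct the ring of congruent wedge cells between two circles.

    The apical vertices sit on the vitelline circle, the basal vertices
    on the yolk circle of radius ``vitelline_radius - cell_length``.
    Rest lengths and areas equal the constructed initial values, so the
    rest configuration is stress-free for the purely elastic terms.
    """
    n = p.n_cells
    R = p.vitelline_radius
    r = R - p.cell_length

    theta = -np.pi / 2 + 2 * np.pi * np.arange(n) / n
    unit = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    apical = R * unit
    basal = r * unit

    nxt = np.roll(np.arange(n), -1)
    rest_apical = np.linalg.norm(apical[nxt] - apical, axis=1)
    rest_basal = np.linalg.norm(basal[nxt] - basal, axis=1)
    rest_lateral = np.full(n, p.cell_length, dtype=float)

    geom = EmbryoGeometry(
        apical=apical,
        basal=basal,
        rest_apical=rest_apical,
        rest_basal=rest_basal,
        rest_lateral=rest_lateral,
        rest_area=np.zeros(n),
        rest_yolk_area=0.0,
        vitelline_radius=R,
    )
    geom.rest_area = polygon_areas(geom.vertices, geom.cell_vertex_indices)
    geom.rest_yolk_area = float(polygon_area(basal))
    return geom


def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (m, 2) vertices."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_areas(vertices: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed shoelace areas of many polygons sharing a vertex pool.

    ``quads`` is (n_poly, k) of vertex indices in traversal order.
    """
    poly = vertices[quads]  # (n_poly, k, 2)
    nxt = np.roll(poly, -1, axis=1)
    return 0.5 * np.sum(poly[:, :, 0] * nxt[:, :, 1] - nxt[:, :, 0] * poly[:, :, 1], axis=1)


def midline_offsets(n_cells: int) -> np.ndarray:
    """Half-integer distance of each cell centre from the ventral midline.

    With an even cell count the midline is the boundary between cells
    ``n-1`` and ``0``, so cell centres sit at offsets 0.5, 1.5, ... on
    either side.
    """
    i = np.arange(n_cells)
    return np.minimum(i, n_cells - i - 1) + 0.5


def mesoderm_mask(n_cells: int, half_width: int = 9) -> TissueAnnotation:
    """Mesoderm indicator: ``half_width`` cells on each side of the midline."""
    if 2 * half_width >= n_cells:
        raise ValueError(
            f"mesoderm half-width {half_width} too large for {n_cells} cells"
        )
    phi = (midline_offsets(n_cells) < half_width).astype(int)
    return TissueAnnotation(phi=phi)


def contractility_profile(mu0: float, sigma: float, phi: np.ndarray) -> np.ndarray:
    """Gaussian apical-contractility weights ``mu_i * phi_i``.

    mu_i = mu0 * exp(-d_i^2 / (2 sigma^2)) with d_i the (half-integer)
    offset of cell i from the ventral midline; weights vanish outside
    the mesoderm.  The profile peaks at the two midline-adjacent cells
    and is exactly mirror-symmetric.
    """
    if mu0 < 0:
        raise ValueError("mu0 must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    phi = np.asarray(phi)
    d = midline_offsets(phi.shape[0])
    return mu0 * np.exp(-(d**2) / (2.0 * sigma**2)) * phi




def mirror_permutation(n_cells: int) -> np.ndarray:
    """Vertex permutation induced by reflection about the midline axis.

    Reflection across the y-axis maps vertex ``j`` to vertex
    ``(n - j) mod n`` (apical and basal blocks alike) and negates the
    x-coordinate.
    """
    j = np.arange(n_cells)
    p = (n_cells - j) % n_cells
    return np.concatenate([p, n_cells + p])


def mirror_vertices(x: np.ndarray, n_cells: int) -> np.ndarray:
    """Image of a stacked (2n, 2) vertex array under midline reflection."""
    out = x[mirror_permutation(n_cells)].copy()
    out[:, 0] = -out[:, 0]
    return out


def constriction_lateral_edges(phi: np.ndarray) -> np.ndarray:
    """Boolean mask of lateral edges in the constriction (mesoderm) domain.

    Lateral edge ``j`` separates cells ``j-1`` and ``j``; edges interior
    to the mesoderm and mesoderm-ectoderm boundary edges are both
    assigned to the constriction domain.
    """
    phi = np.asarray(phi).astype(bool)
    return phi | np.roll(phi, 1)


def ectoderm_lateral_edges(phi: np.ndarray, mode: str = "all") -> np.ndarray:
    """Indices of lateral edges subject to ectodermal rest-length shortening.

    ``mode='all'`` targets every lateral edge outside the constriction
    domain.  ``mode='exclude_flanking'`` additionally drops the edges of
    the two ectodermal cells adjacent to the mesoderm, leaving a
    60-cell ectodermal band for the default 80-cell / 18-mesoderm ring.
    """
    phi = np.asarray(phi).astype(bool)
    n = phi.shape[0]
    ecto_cell = ~phi
    if mode == "exclude_flanking":
        boundary = ecto_cell & (np.roll(phi, 1) | np.roll(phi, -1))
        ecto_cell = ecto_cell & ~boundary
    elif mode != "all":
        raise ValueError(f"unknown ectoderm shortening mode {mode!r}")
    # edge j is targeted when both adjoining cells are in the target band
    mask = ecto_cell & np.roll(ecto_cell, 1)
    return np.flatnonzero(mask)
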