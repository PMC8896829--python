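"""Mechanical energy of the cell ring and its analytic gradient.

The total energy of a vertex configuration is

    E = sum_i phi_i mu_i a_i^2                        (apical contractility)
      + sum_i Ka (a_i - a0)^2                         (apical elasticity)
      + sum_i Kb (b_i - b0)^2                         (basal elasticity)
      + sum_{ectoderm lat} Kl (l_j - l0_j)^2          (passive lateral, ectoderm)
      + sum_{constriction lat} KL_passive (l_j - l0_j)^2
      + sum_{constriction lat} KL_active l_j^2        (active lateral, rest length 0)
      + sum_i Kv (V_i - V0)^2 + KY (V_yolk - V0_yolk)^2

with a, b, l the apical, basal and lateral edge lengths, V the cell
areas (2D volumes) and V_yolk the area enclosed by the basal polygon.
All terms use the energy convention K (x - x0)^2; the corresponding
force magnitude carries a factor 2 relative to the stiffness constant.
Apical constriction (the mu term) is the sole active driver; the active
lateral spring of the constriction domain (zero rest length, stiffness
KL_active) models myosin-dependent lateral tension and is switched off
together with mu on in-silico myosin inhibition.

Ectodermal in-plane compression is produced by shortening the lateral
rest lengths of ectodermal cells by a fraction deltaL: area conservation
then widens those cells, compressing the ring.

The vitelline shell is *not* part of the energy; confinement is imposed
as a hard constraint by the minimizer (see :mod:`furrowsim.equilibrate`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    EmbryoGeometry,
    TissueAnnotation,
    constriction_lateral_edges,
    ectoderm_lateral_edges,
    polygon_areas,
)

__all__ = [
    "ModelParams",
    "Configuration",
    "apply_ectoderm_shortening",
    "total_energy",
    "energy_breakdown",
    "energy_gradient",
    "energy_and_gradient",
    "lateral_shortening_force",
]

_TERMS = (
    "apical_contractility",
    "apical_elastic",
    "basal_elastic",
    "lateral_passive",
    "lateral_active",
    "cell_area_penalty",
    "yolk_penalty",
)

try:  # optional compiled kernels; the numpy path below is the reference
    import numba as _numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class ModelParams:
    """Spring constants and loading parameters of the vertex model.

    Defaults are the standard parameter set: Ka=30, Kl=20, mu0=5000,
    sigma=3, Kv=5000, KY=1, with the basal stiffness Kb controlled by
    the adiabatic schedule (2^10 down to 2^0).  KL_active / KL_passive
    are the active and passive lateral stiffnesses of the constriction
    domain; KL_active=0 recovers the base model in which mesodermal
    lateral edges behave like ectodermal ones with stiffness KL_passive.
    deltaL is the fractional ectodermal lateral rest-length reduction
    that generates in-plane compression.
    """

    Ka: float = 30.0
    Kl: float = 20.0
    Kb: float = 1024.0
    mu0: float = 5000.0
    sigma: float = 3.0
    Kv: float = 5000.0
    KY: float = 1.0
    KL_active: float = 2.0
    KL_passive: float = 20.0
    deltaL: float = 0.20

    def __post_init__(self) -> None:
        for name in ("Ka", "Kl", "Kb", "mu0", "Kv", "KY", "KL_active", "KL_passive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.deltaL < 1.0:
            raise ValueError("deltaL must lie in [0, 1)")

    def with_kb(self, kb: float) -> "ModelParams":
        return replace(self, Kb=float(kb))

    def inhibited(self) -> "ModelParams":
        """Parameters after in-silico myosin inhibition (mu0 = KL_active = 0)."""
        return replace(self, mu0=0.0, KL_active=0.0)


class Configuration:
    """A vertex configuration of the ring: stacked (2n, 2) coordinates.

    Rows 0..n-1 are apical vertices, rows n..2n-1 basal vertices.
    Derived quantities (edge lengths, shoelace areas) are computed on
    demand from the coordinates.
    """

    def __init__(self, vertices: np.ndarray):
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] % 2:
            raise ValueError("vertices must have shape (2n, 2)")
        if not np.all(np.isfinite(vertices)):
            raise ValueError("vertex coordinates must be finite")
        self.vertices = vertices

    @property
    def n_cells(self) -> int:
        return self.vertices.shape[0] // 2

    @property
    def apical(self) -> np.ndarray:
        return self.vertices[: self.n_cells]

    @property
    def basal(self) -> np.ndarray:
        return self.vertices[self.n_cells:]

    def apical_lengths(self) -> np.ndarray:
        a = self.apical
        return np.linalg.norm(np.roll(a, -1, axis=0) - a, axis=1)

    def basal_lengths(self) -> np.ndarray:
        b = self.basal
        return np.linalg.norm(np.roll(b, -1, axis=0) - b, axis=1)

    def lateral_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.apical - self.basal, axis=1)

    def cell_areas(self, geom: EmbryoGeometry) -> np.ndarray:
        return polygon_areas(self.vertices, geom.cell_vertex_indices)

    def yolk_area(self) -> float:
        from .geometry import polygon_area

        return float(polygon_area(self.basal))


def apply_ectoderm_shortening(
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    delta_l: float,
    targets: np.ndarray | None = None,
    mode: str = "all",
) -> EmbryoGeometry:
    """Shorten ectodermal lateral rest lengths by the fraction ``delta_l``.

    Returns a new geometry whose targeted rest lateral lengths are
    scaled by ``(1 - delta_l)``; all other rest quantities are
    unchanged.  Targets default to every lateral edge outside the
    constriction domain (``mode='exclude_flanking'`` restricts to the
    60-cell ectodermal band).  Targets overlapping mesodermal lateral
    edges are rejected.
    """
    if not 0.0 <= delta_l < 1.0:
        raise ValueError("delta_l must lie in [0, 1)")
    if targets is None:
        targets = ectoderm_lateral_edges(ann.phi, mode=mode)
    targets = np.asarray(targets, dtype=int)
    meso_edges = constriction_lateral_edges(ann.phi)
    if targets.size and np.any(meso_edges[targets]):
        bad = targets[meso_edges[targets]]
        raise ValueError(f"shortening targets include mesodermal lateral edges {bad.tolist()}")
    out = geom.copy()
    out.rest_lateral[targets] *= 1.0 - delta_l
    return out


def _lateral_constants(ann: TissueAnnotation, p: ModelParams):
    """Per-lateral-edge passive stiffness and active-spring mask."""
    meso = constriction_lateral_edges(ann.phi)
    k_passive = np.where(meso, p.KL_passive, p.Kl)
    return k_passive, meso


if _HAVE_NUMBA:

    @_numba.njit(cache=True, fastmath=False)
    def _kernel_energy_grad(x, n, ra, rb, rl, rA, rY, mu, kpas, act,
                            Ka, Kb, Kv, KY, KLa):  # pragma: no cover - exercised via dispatch
        g = np.zeros_like(x)
        e = np.zeros(7)
        for i in range(n):
            j = i + 1 if i + 1 < n else 0
            # apical edge i -> j
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            a = (dx * dx + dy * dy) ** 0.5
            if a < 1e-300:
                a = 1e-300
            e[0] += mu[i] * a * a
            da = a - ra[i]
            e[1] += Ka * da * da
            c = (2.0 * Ka * da + 2.0 * mu[i] * a) / a
            g[j, 0] += c * dx
            g[j, 1] += c * dy
            g[i, 0] -= c * dx
            g[i, 1] -= c * dy
            # basal edge i -> j
            bx = x[n + j, 0] - x[n + i, 0]
            by = x[n + j, 1] - x[n + i, 1]
            b = (bx * bx + by * by) ** 0.5
            if b < 1e-300:
                b = 1e-300
            db = b - rb[i]
            e[2] += Kb * db * db
            c = 2.0 * Kb * db / b
            g[n + j, 0] += c * bx
            g[n + j, 1] += c * by
            g[n + i, 0] -= c * bx
            g[n + i, 1] -= c * by
            # lateral edge i (apical i -> basal i)
            lx = x[i, 0] - x[n + i, 0]
            ly = x[i, 1] - x[n + i, 1]
            l = (lx * lx + ly * ly) ** 0.5
            if l < 1e-300:
                l = 1e-300
            dl = l - rl[i]
            e[3] += kpas[i] * dl * dl
            c = 2.0 * kpas[i] * dl
            if act[i]:
                e[4] += KLa * l * l
                c += 2.0 * KLa * l
            c /= l
            g[i, 0] += c * lx
            g[i, 1] += c * ly
            g[n + i, 0] -= c * lx
            g[n + i, 1] -= c * ly
            # cell area (quad A_i, A_j, B_j, B_i)
            ax, ay = x[i, 0], x[i, 1]
            bx2, by2 = x[j, 0], x[j, 1]
            cx, cy = x[n + j, 0], x[n + j, 1]
            dx2, dy2 = x[n + i, 0], x[n + i, 1]
            V = 0.5 * ((ax * by2 - bx2 * ay) + (bx2 * cy - cx * by2)
                       + (cx * dy2 - dx2 * cy) + (dx2 * ay - ax * dy2))
            dV = V - rA[i]
            e[5] += Kv * dV * dV
            cc = Kv * dV
            g[i, 0] += cc * (by2 - dy2)
            g[i, 1] += cc * (dx2 - bx2)
            g[j, 0] += cc * (cy - ay)
            g[j, 1] += cc * (ax - cx)
            g[n + j, 0] += cc * (dy2 - by2)
            g[n + j, 1] += cc * (bx2 - dx2)
            g[n + i, 0] += cc * (ay - cy)
            g[n + i, 1] += cc * (cx - ax)
        # yolk area over the basal ring
        Vy = 0.0
        for i in range(n):
            j = i + 1 if i + 1 < n else 0
            Vy += x[n + i, 0] * x[n + j, 1] - x[n + j, 0] * x[n + i, 1]
        Vy *= 0.5
        dVy = Vy - rY
        e[6] = KY * dVy * dVy
        for i in range(n):
            j = i + 1 if i + 1 < n else 0
            k = i - 1 if i > 0 else n - 1
            g[n + i, 0] += KY * dVy * (x[n + j, 1] - x[n + k, 1])
            g[n + i, 1] += KY * dVy * (x[n + k, 0] - x[n + j, 0])
        return e, g

    @_numba.njit(cache=True, fastmath=False)
    def _kernel_hessian(x, n, ra, rb, rl, rA, rY, mu, kpas, act,
                        Ka, Kb, Kv, KY, KLa):  # pragma: no cover - exercised via dispatch
        m = 2 * n
        H = np.zeros((2 * m, 2 * m))

        def _edge_block(H, pidx, qidx, dx, dy, L, fp, fs):
            ux = dx / L
            uy = dy / L
            hxx = fs * ux * ux + fp / L * (1.0 - ux * ux)
            hxy = fs * ux * uy - fp / L * ux * uy
            hyy = fs * uy * uy + fp / L * (1.0 - uy * uy)
            for (r, c, v) in ((0, 0, hxx), (0, 1, hxy), (1, 0, hxy), (1, 1, hyy)):
                H[2 * pidx + r, 2 * pidx + c] += v
                H[2 * qidx + r, 2 * qidx + c] += v
                H[2 * pidx + r, 2 * qidx + c] -= v
                H[2 * qidx + r, 2 * pidx + c] -= v

        for i in range(n):
            j = i + 1 if i + 1 < n else 0
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            a = max((dx * dx + dy * dy) ** 0.5, 1e-300)
            _edge_block(H, i, j, dx, dy, a,
                        2.0 * Ka * (a - ra[i]) + 2.0 * mu[i] * a,
                        2.0 * Ka + 2.0 * mu[i])
            bx = x[n + j, 0] - x[n + i, 0]
            by = x[n + j, 1] - x[n + i, 1]
            b = max((bx * bx + by * by) ** 0.5, 1e-300)
            _edge_block(H, n + i, n + j, bx, by, b,
                        2.0 * Kb * (b - rb[i]), 2.0 * Kb)
            lx = x[i, 0] - x[n + i, 0]
            ly = x[i, 1] - x[n + i, 1]
            l = max((lx * lx + ly * ly) ** 0.5, 1e-300)
            fp = 2.0 * kpas[i] * (l - rl[i])
            fs = 2.0 * kpas[i]
            if act[i]:
                fp += 2.0 * KLa * l
                fs += 2.0 * KLa
            _edge_block(H, i, n + i, lx, ly, l, fp, fs)

        # cell-area penalty: rank-one + shoelace curvature per quad
        vid = np.empty(4, dtype=np.int64)
        dA = np.empty((4, 2))
        for i in range(n):
            j = i + 1 if i + 1 < n else 0
            vid[0] = i
            vid[1] = j
            vid[2] = n + j
            vid[3] = n + i
            ax, ay = x[i, 0], x[i, 1]
            bx2, by2 = x[j, 0], x[j, 1]
            cx, cy = x[n + j, 0], x[n + j, 1]
            dx2, dy2 = x[n + i, 0], x[n + i, 1]
            V = 0.5 * ((ax * by2 - bx2 * ay) + (bx2 * cy - cx * by2)
                       + (cx * dy2 - dx2 * cy) + (dx2 * ay - ax * dy2))
            dV = V - rA[i]
            dA[0, 0] = 0.5 * (by2 - dy2)
            dA[0, 1] = 0.5 * (dx2 - bx2)
            dA[1, 0] = 0.5 * (cy - ay)
            dA[1, 1] = 0.5 * (ax - cx)
            dA[2, 0] = 0.5 * (dy2 - by2)
            dA[2, 1] = 0.5 * (bx2 - dx2)
            dA[3, 0] = 0.5 * (ay - cy)
            dA[3, 1] = 0.5 * (cx - ax)
            for kk in range(4):
                for ll in range(4):
                    for aa in range(2):
                        for bb in range(2):
                            H[2 * vid[kk] + aa, 2 * vid[ll] + bb] += (
                                2.0 * Kv * dA[kk, aa] * dA[ll, bb]
                            )
            cdv = Kv * dV
            for kk in range(4):
                ll = (kk + 1) % 4
                vk = vid[kk]
                vl = vid[ll]
                # block(k, k+1) = Kv*dV*P with P = [[0,1],[-1,0]]
                H[2 * vk, 2 * vl + 1] += cdv
                H[2 * vk + 1, 2 * vl] -= cdv
                H[2 * vl + 1, 2 * vk] += cdv
                H[2 * vl, 2 * vk + 1] -= cdv

        # yolk penalty: global rank-one over the basal ring + curvature
        Vy = 0.0
        for i in range(n):
            j = i + 1 if i + 1 < n else 0
            Vy += x[n + i, 0] * x[n + j, 1] - x[n + j, 0] * x[n + i, 1]
        Vy *= 0.5
        dVy = Vy - rY
        w = np.empty((n, 2))
        for i in range(n):
            j = i + 1 if i + 1 < n else 0
            k = i - 1 if i > 0 else n - 1
            w[i, 0] = 0.5 * (x[n + j, 1] - x[n + k, 1])
            w[i, 1] = 0.5 * (x[n + k, 0] - x[n + j, 0])
        for i in range(n):
            for j2 in range(n):
                for aa in range(2):
                    for bb in range(2):
                        H[2 * (n + i) + aa, 2 * (n + j2) + bb] += (
                            2.0 * KY * w[i, aa] * w[j2, bb]
                        )
        cdv = KY * dVy
        for i in range(n):
            j = i + 1 if i + 1 < n else 0
            H[2 * (n + i), 2 * (n + j) + 1] += cdv
            H[2 * (n + i) + 1, 2 * (n + j)] -= cdv
            H[2 * (n + j) + 1, 2 * (n + i)] += cdv
            H[2 * (n + j), 2 * (n + i) + 1] -= cdv
        return H


def energy_and_gradient(
    x: np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
    want_breakdown: bool = False,
):
    """Fused evaluation of the total energy and its vertex gradient.

    This is the kernel the minimizer calls; :func:`total_energy`,
    :func:`energy_breakdown` and :func:`energy_gradient` are thin views
    over it.  Returns ``(E, grad)`` or ``(E, grad, breakdown)``.
    Dispatches to a numba-compiled kernel when available; the pure-numpy
    implementation (:func:`energy_and_gradient_numpy`) is the reference.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite vertex coordinates")
    if _HAVE_NUMBA:
        n = geom.n_cells
        mu = ann.contractility_weights(p.mu0, p.sigma)
        k_passive, active_mask = _lateral_constants(ann, p)
        e = _kernel_energy_grad(
            np.ascontiguousarray(x), n,
            geom.rest_apical, geom.rest_basal, geom.rest_lateral,
            geom.rest_area, float(geom.rest_yolk_area),
            mu, k_passive.astype(float), active_mask.astype(np.bool_),
            p.Ka, p.Kb, p.Kv, p.KY, p.KL_active,
        )
        terms_vec, g = e
        E = float(terms_vec.sum())
        if want_breakdown:
            return E, g, dict(zip(_TERMS, (float(v) for v in terms_vec)))
        return E, g
    return energy_and_gradient_numpy(x, geom, ann, p, want_breakdown)


def energy_and_gradient_numpy(
    x: np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
    want_breakdown: bool = False,
):
    """Reference numpy implementation of :func:`energy_and_gradient`."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite vertex coordinates")
    n = geom.n_cells
    A = x[:n]
    B = x[n:]
    g = np.zeros_like(x)
    mu = ann.contractility_weights(p.mu0, p.sigma)

    # every scatter below follows a cyclic pattern (edge i joins vertex i
    # to vertex i+1 mod n), so accumulation uses np.roll rather than
    # fancy-index np.add.at

    # --- apical edges: elastic + contractility -------------------------
    da = np.roll(A, -1, axis=0) - A
    a = np.linalg.norm(da, axis=1)
    ua = da / np.maximum(a, 1e-300)[:, None]
    e_contract = float(np.sum(mu * a**2))
    e_apical = float(p.Ka * np.sum((a - geom.rest_apical) ** 2))
    fa = (2.0 * p.Ka * (a - geom.rest_apical) + 2.0 * mu * a)[:, None] * ua
    g[:n] += np.roll(fa, 1, axis=0) - fa

    # --- basal edges ---------------------------------------------------
    db = np.roll(B, -1, axis=0) - B
    b = np.linalg.norm(db, axis=1)
    ub = db / np.maximum(b, 1e-300)[:, None]
    e_basal = float(p.Kb * np.sum((b - geom.rest_basal) ** 2))
    fb = (2.0 * p.Kb * (b - geom.rest_basal))[:, None] * ub
    g[n:] += np.roll(fb, 1, axis=0) - fb

    # --- lateral edges -------------------------------------------------
    dl = A - B
    l = np.linalg.norm(dl, axis=1)
    ul = dl / np.maximum(l, 1e-300)[:, None]
    k_passive, active_mask = _lateral_constants(ann, p)
    e_lat_passive = float(np.sum(k_passive * (l - geom.rest_lateral) ** 2))
    e_lat_active = float(p.KL_active * np.sum(l[active_mask] ** 2))
    dEdl = 2.0 * k_passive * (l - geom.rest_lateral)
    dEdl[active_mask] += 2.0 * p.KL_active * l[active_mask]
    g[:n] += dEdl[:, None] * ul
    g[n:] -= dEdl[:, None] * ul

    # --- cell-area penalty (shoelace on quads A_i, A_i+1, B_i+1, B_i) ---
    An, Bn = np.roll(A, -1, axis=0), np.roll(B, -1, axis=0)
    cross = lambda u, v: u[:, 0] * v[:, 1] - v[:, 0] * u[:, 1]
    V = 0.5 * (cross(A, An) + cross(An, Bn) + cross(Bn, B) + cross(B, A))
    dV = V - geom.rest_area
    e_area = float(p.Kv * np.sum(dV**2))
    c = 2.0 * p.Kv * dV
    # dA/dv_k = 0.5 * rot90(v_{k+1} - v_{k-1}) with rot90 (x,y)->(y,-x) ...
    # accumulated per quad corner, then rolled onto the shared vertices
    perp = lambda v: np.stack([v[:, 1], -v[:, 0]], axis=1)
    gA0 = 0.5 * c[:, None] * perp(An - B)   # corner A_i
    gA1 = 0.5 * c[:, None] * perp(Bn - A)   # corner A_{i+1}
    gB1 = 0.5 * c[:, None] * perp(B - An)   # corner B_{i+1}
    gB0 = 0.5 * c[:, None] * perp(A - Bn)   # corner B_i
    g[:n] += gA0 + np.roll(gA1, 1, axis=0)
    g[n:] += gB0 + np.roll(gB1, 1, axis=0)

    # --- yolk-area penalty ---------------------------------------------
    Bn = np.roll(B, -1, axis=0)
    Bp = np.roll(B, 1, axis=0)
    Vy = 0.5 * float(np.sum(B[:, 0] * Bn[:, 1] - Bn[:, 0] * B[:, 1]))
    dVy = Vy - geom.rest_yolk_area
    e_yolk = float(p.KY * dVy**2)
    g[n:, 0] += p.KY * dVy * (Bn[:, 1] - Bp[:, 1])
    g[n:, 1] += p.KY * dVy * (Bp[:, 0] - Bn[:, 0])

    terms = {
        "apical_contractility": e_contract,
        "apical_elastic": e_apical,
        "basal_elastic": e_basal,
        "lateral_passive": e_lat_passive,
        "lateral_active": e_lat_active,
        "cell_area_penalty": e_area,
        "yolk_penalty": e_yolk,
    }
    E = float(sum(terms.values()))
    if want_breakdown:
        return E, g, terms
    return E, g


def total_energy(
    c: Configuration | np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
) -> float:
    """Total mechanical energy of a configuration."""
    x = c.vertices if isinstance(c, Configuration) else np.asarray(c, float)
    E, _ = energy_and_gradient(x, geom, ann, p)
    return E


def energy_breakdown(
    c: Configuration | np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
) -> dict[str, float]:
    """Per-term decomposition of the total energy (terms sum to the total)."""
    x = c.vertices if isinstance(c, Configuration) else np.asarray(c, float)
    _, _, terms = energy_and_gradient(x, geom, ann, p, want_breakdown=True)
    return terms


def energy_gradient(
    c: Configuration | np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
) -> np.ndarray:
    """Analytic gradient of the total energy w.r.t. every vertex, (2n, 2)."""
    x = c.vertices if isinstance(c, Configuration) else np.asarray(c, float)
    _, g = energy_and_gradient(x, geom, ann, p)
    return g


def energy_hessian(
    c: Configuration | np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
) -> np.ndarray:
    """Dense analytic Hessian of the total energy, shape (4n, 4n).

    Dispatches to the numba kernel when available; see
    :func:`energy_hessian_numpy` for the reference implementation.
    """
    x = c.vertices if isinstance(c, Configuration) else np.asarray(c, float)
    if _HAVE_NUMBA:
        n = geom.n_cells
        mu = ann.contractility_weights(p.mu0, p.sigma)
        k_passive, active_mask = _lateral_constants(ann, p)
        return _kernel_hessian(
            np.ascontiguousarray(x), n,
            geom.rest_apical, geom.rest_basal, geom.rest_lateral,
            geom.rest_area, float(geom.rest_yolk_area),
            mu, k_passive.astype(float), active_mask.astype(np.bool_),
            p.Ka, p.Kb, p.Kv, p.KY, p.KL_active,
        )
    return energy_hessian_numpy(x, geom, ann, p)


def energy_hessian_numpy(
    c: Configuration | np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
) -> np.ndarray:
    """Reference numpy implementation of the dense analytic Hessian.

    Coordinates are flattened row-major from the stacked (2n, 2) vertex
    array.  At 80 cells the system has 320 degrees of freedom, so a
    dense matrix is cheap and lets the equilibrium solver use direct
    factorizations.  Structure: edge terms couple edge endpoints, the
    area penalties contribute per-cell rank-one blocks plus the constant
    curvature of the shoelace form, and the yolk penalty adds a global
    rank-one coupling over the basal ring.
    """
    x = c.vertices if isinstance(c, Configuration) else np.asarray(c, float)
    n = geom.n_cells
    m = x.shape[0]
    H = np.zeros((m, m, 2, 2))
    I2 = np.eye(2)
    mu = ann.contractility_weights(p.mu0, p.sigma)

    def add_edge_terms(idx_p, idx_q, d, L, fprime, fsecond):
        u = d / np.maximum(L, 1e-300)[:, None]
        uu = u[:, :, None] * u[:, None, :]
        M = fsecond[:, None, None] * uu + (fprime / np.maximum(L, 1e-300))[
            :, None, None
        ] * (I2 - uu)
        np.add.at(H, (idx_p, idx_p), M)
        np.add.at(H, (idx_q, idx_q), M)
        np.add.at(H, (idx_p, idx_q), -M)
        np.add.at(H, (idx_q, idx_p), -M)

    A, B = x[:n], x[n:]
    i = np.arange(n)
    j = (i + 1) % n

    da = A[j] - A[i]
    a = np.linalg.norm(da, axis=1)
    add_edge_terms(i, j, da, a,
                   2.0 * p.Ka * (a - geom.rest_apical) + 2.0 * mu * a,
                   2.0 * p.Ka + 2.0 * mu)
    db = B[j] - B[i]
    b = np.linalg.norm(db, axis=1)
    add_edge_terms(n + i, n + j, db, b,
                   2.0 * p.Kb * (b - geom.rest_basal),
                   np.full(n, 2.0 * p.Kb))
    dl = A - B
    l = np.linalg.norm(dl, axis=1)
    k_passive, active_mask = _lateral_constants(ann, p)
    fp = 2.0 * k_passive * (l - geom.rest_lateral) + 2.0 * p.KL_active * l * active_mask
    fs = 2.0 * k_passive + 2.0 * p.KL_active * active_mask
    add_edge_terms(i, n + i, dl, l, fp, fs)

    # shoelace curvature: d2A/dv_k dv_{k+1} = P/2 with P = [[0,1],[-1,0]]
    P = np.array([[0.0, 1.0], [-1.0, 0.0]])

    quads = geom.cell_vertex_indices  # (n, 4)
    poly = x[quads]
    nxt = np.roll(poly, -1, axis=1)
    prv = np.roll(poly, 1, axis=1)
    V = 0.5 * np.sum(poly[:, :, 0] * nxt[:, :, 1] - nxt[:, :, 0] * poly[:, :, 1], axis=1)
    dV = V - geom.rest_area
    dAdx = 0.5 * np.stack(
        [nxt[:, :, 1] - prv[:, :, 1], prv[:, :, 0] - nxt[:, :, 0]], axis=-1
    )  # (n, 4, 2)
    # rank-one part 2 Kv (dA)(dA)^T per cell
    outer = dAdx[:, :, None, :, None] * dAdx[:, None, :, None, :]  # (n,4,4,2,2)
    np.add.at(H, (quads[:, :, None], quads[:, None, :]), 2.0 * p.Kv * outer)
    # constant-curvature part 2 Kv dV * d2A
    for k in range(4):
        kn = (k + 1) % 4
        blk = (2.0 * p.Kv * dV)[:, None, None] * (0.5 * P)
        np.add.at(H, (quads[:, k], quads[:, kn]), blk)
        np.add.at(H, (quads[:, kn], quads[:, k]), -blk)

    # yolk: 2 KY (dVy)(dVy)^T (global rank one over basal ring) + curvature
    Bn = np.roll(B, -1, axis=0)
    Bp = np.roll(B, 1, axis=0)
    Vy = 0.5 * float(np.sum(B[:, 0] * Bn[:, 1] - Bn[:, 0] * B[:, 1]))
    dVy = Vy - geom.rest_yolk_area
    w = 0.5 * np.stack([Bn[:, 1] - Bp[:, 1], Bp[:, 0] - Bn[:, 0]], axis=-1)  # (n,2)
    H[n:, n:] += 2.0 * p.KY * (w[:, None, :, None] * w[None, :, None, :])
    byolk = 2.0 * p.KY * dVy * (0.5 * P)
    np.add.at(H, (n + i, n + j), byolk[None, :, :])
    np.add.at(H, (n + j, n + i), -byolk[None, :, :])

    return H.transpose(0, 2, 1, 3).reshape(2 * m, 2 * m)


def lateral_shortening_force(
    l: float | np.ndarray,
    l0: float | np.ndarray,
    KL_active: float,
    KL_passive: float,
):
    """Lateral shortening force in a constricting cell (diagnostic form).

    F = KL_active * l + KL_passive * (l - l0): the active zero-rest-length
    spring plus the passive restoring spring.  Note the energy terms use
    the K (x - x0)^2 convention, whose force carries an extra factor 2;
    this helper reports the conventional force form with the stiffness
    constants as given.
    """
    return KL_active * np.asarray(l, float) + KL_passive * (
        np.asarray(l, float) - np.asarray(l0, float)
    )
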