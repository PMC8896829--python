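"""In-silico perturbation experiments on the furrow model.

The central experiment mimics acute optogenetic inhibition of myosin:
at a chosen intermediate equilibrium state the apical contractility
amplitude mu0 and the active lateral stiffness KL_active are set to
zero, and the adiabatic Kb schedule is continued to its end.  The final
state either relaxes back toward the undeformed configuration or goes
on to invaginate — the binary signature of mechanical bistability.

Other experiments sweep the ectodermal shortening fraction deltaL, the
active/passive lateral stiffness of the constriction domain, and the
spatial pattern of apical contractility (narrower Gaussian, every other
cell silenced).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .equilibrate import (
    EquilibriumState,
    Trajectory,
    continue_schedule,
    run_schedule,
)
from .geometry import (
    EmbryoGeometry,
    GeometryParams,
    TissueAnnotation,
    build_initial_geometry,
    mesoderm_mask,
)
from .mechanics import ModelParams, apply_ectoderm_shortening
from .metrics import invagination_depth

__all__ = [
    "PerturbationSpec",
    "ExperimentResult",
    "prepare_model",
    "classify_response",
    "inhibit_at_state",
    "find_transition",
    "sweep_deltaL",
    "sweep_lateral",
    "perturb_constriction",
]

#: Fractions of the reference depth separating the response classes.
RESPONSE_THRESHOLDS = (0.2, 0.8)


@dataclass(frozen=True)
class PerturbationSpec:
    """Declarative record of which perturbation an experiment applied."""

    kind: str                       # inhibit_contractility, no_compression, ...
    inhibit_at: int | None = None   # schedule index of in-silico inhibition
    deltaL: float | None = None
    KL_active: float | None = None
    KL_passive: float | None = None
    sigma_override: float | None = None
    phi_pattern: str | None = None  # e.g. "alternate_cells"


@dataclass
class ExperimentResult:
    """Outcome of one perturbation experiment."""

    spec: PerturbationSpec
    trajectory: Trajectory
    response: str | None        # relaxed / paused / invaginated
    D_final: float
    D_reference: float | None = None
    k_star: int | None = None

    @property
    def bistable(self) -> bool:
        return self.k_star is not None


def prepare_model(
    gparams: GeometryParams | None = None,
    params: ModelParams | None = None,
    shortening_mode: str = "all",
) -> tuple[EmbryoGeometry, TissueAnnotation, ModelParams]:
    """Build geometry + annotation with ectodermal shortening applied.

    This is the standard entry point for experiments: an 80-cell ring
    with the 18-cell mesoderm, ectodermal lateral rest lengths
    shortened by ``params.deltaL``.
    """
    gparams = gparams or GeometryParams()
    params = params or ModelParams()
    geom = build_initial_geometry(gparams)
    ann = mesoderm_mask(gparams.n_cells)
    if params.deltaL > 0:
        geom = apply_ectoderm_shortening(geom, ann, params.deltaL, mode=shortening_mode)
    return geom, ann, params


def classify_response(
    D_final: float,
    D_reference: float,
    thresholds: tuple[float, float] = RESPONSE_THRESHOLDS,
) -> str:
    """Classify a post-perturbation final state against a reference depth.

    relaxed if D_final < lo * D_ref, invaginated if D_final > hi * D_ref,
    paused otherwise.  The reference is the final depth of the
    unperturbed trajectory under the same parameters.
    """
    if D_reference <= 0:
        raise ValueError("reference depth must be positive (no reference furrow)")
    lo, hi = thresholds
    if D_final < lo * D_reference:
        return "relaxed"
    if D_final > hi * D_reference:
        return "invaginated"
    return "paused"


def classify_states(
    final: EquilibriumState,
    reference_final: EquilibriumState,
    geom: EmbryoGeometry,
    thresholds: tuple[float, float] = RESPONSE_THRESHOLDS,
) -> str:
    """State-level wrapper around :func:`classify_response`."""
    return classify_response(
        invagination_depth(final, geom),
        invagination_depth(reference_final, geom),
        thresholds,
    )


def inhibit_at_state(
    base: Trajectory,
    k: int,
    thresholds: tuple[float, float] = RESPONSE_THRESHOLDS,
    gtol: float | None = None,
) -> ExperimentResult:
    """Acute in-silico myosin inhibition at intermediate state ``k``.

    Contractility (mu0) and the active lateral spring (KL_active) are
    zeroed at state ``k`` and the remaining Kb schedule is continued to
    its final value; the response is classified on the final state
    against the unperturbed final state of ``base``.
    """
    if not base.states[k].converged:
        raise ValueError(f"base trajectory not converged at state {k}")
    p_inh = base.params.inhibited()
    cont = continue_schedule(
        base, k, p_inh, gtol=gtol,
        perturbation={"kind": "inhibit_contractility", "inhibit_at": k},
    )
    geom = base.geometry
    D_ref = invagination_depth(base.final, geom)
    D_fin = invagination_depth(cont.final, geom)
    return ExperimentResult(
        spec=PerturbationSpec(kind="inhibit_contractility", inhibit_at=k),
        trajectory=cont,
        response=classify_response(D_fin, D_ref, thresholds),
        D_final=D_fin,
        D_reference=D_ref,
    )


def find_transition(
    base: Trajectory,
    thresholds: tuple[float, float] = RESPONSE_THRESHOLDS,
    method: str = "scan",
    gtol: float | None = None,
) -> tuple[int | None, dict[int, ExperimentResult]]:
    """Transitional schedule index k*: the smallest k whose inhibition
    still yields an invaginated final state.

    Returns ``(k_star, results)`` where results maps each probed index
    to its experiment; ``k_star`` is None when no index invaginates (no
    bistability).  ``method='scan'`` probes every index ascending (and
    verifies the dichotomy); ``method='bisect'`` assumes the response is
    monotone in k and uses binary search (log cost).
    """
    n = base.n_states
    results: dict[int, ExperimentResult] = {}

    def probe(k: int) -> str:
        if k not in results:
            results[k] = inhibit_at_state(base, k, thresholds, gtol=gtol)
        return results[k].response

    if method == "scan":
        k_star = None
        for k in range(n):
            if probe(k) == "invaginated" and k_star is None:
                k_star = k
        return k_star, results
    if method != "bisect":
        raise ValueError(f"unknown method {method!r}")

    if probe(n - 1) != "invaginated":
        return None, results
    lo, hi = 0, n - 1  # hi always invaginated
    if probe(0) == "invaginated":
        return 0, results
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if probe(mid) == "invaginated":
            hi = mid
        else:
            lo = mid
    return hi, results


def sweep_deltaL(
    values: Sequence[float] = (0.0, 0.05, 0.10, 0.20),
    gparams: GeometryParams | None = None,
    params: ModelParams | None = None,
    method: str = "bisect",
    schedule: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Bistability as a function of the ectodermal shortening fraction.

    For each deltaL the full schedule is run, the transitional index
    searched, and (when bistable) the late-inhibition final depth
    recorded.  Rows: deltaL, k_star, D_final_late, bistable.
    """
    params = params or ModelParams()
    rows = []
    for dl in values:
        p = replace(params, deltaL=float(dl))
        geom, ann, p = prepare_model(gparams, p)
        traj = run_schedule(geom, ann, p, schedule=schedule)
        k_star, results = find_transition(traj, method=method)
        rows.append(
            {
                "deltaL": dl,
                "k_star": k_star,
                "D_final_late": results[k_star].D_final if k_star is not None else np.nan,
                "D_unperturbed": invagination_depth(traj.final, geom),
                "bistable": k_star is not None,
            }
        )
    return pd.DataFrame(rows)


def sweep_lateral(
    KL_active_values: Sequence[float] = (0.0, 2.0),
    KL_passive_values: Sequence[float] = (0.2, 2.0, 20.0),
    gparams: GeometryParams | None = None,
    params: ModelParams | None = None,
    method: str = "bisect",
    morphology_fraction: float = 0.75,
    schedule: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Grid over the active/passive lateral stiffness of the constriction
    domain.

    For each (KL_active, KL_passive) cell the unperturbed run and the
    late-inhibition (first post-transitional) response are computed.
    ``normal_morphology`` flags conditions whose unperturbed final depth
    reaches ``morphology_fraction`` of the deepest unperturbed furrow in
    the grid — an operational stand-in for a visual morphology check.
    """
    params = params or ModelParams()
    rows = []
    for kla in KL_active_values:
        for klp in KL_passive_values:
            p = replace(params, KL_active=float(kla), KL_passive=float(klp))
            geom, ann, p = prepare_model(gparams, p)
            traj = run_schedule(geom, ann, p, schedule=schedule)
            k_star, results = find_transition(traj, method=method)
            if k_star is not None:
                late = results[k_star]
                response_late, d_late = late.response, late.D_final
            else:
                response_late, d_late = None, np.nan
            rows.append(
                {
                    "KL_active": kla,
                    "KL_passive": klp,
                    "D_unperturbed": invagination_depth(traj.final, geom),
                    "k_star": k_star,
                    "bistable": k_star is not None,
                    "response_late": response_late,
                    "D_final_late": d_late,
                }
            )
    df = pd.DataFrame(rows)
    df["normal_morphology"] = df["D_unperturbed"] >= morphology_fraction * df["D_unperturbed"].max()
    return df


def perturb_constriction(
    mode: str,
    with_compression: bool = True,
    gparams: GeometryParams | None = None,
    params: ModelParams | None = None,
    sigma_value: float | None = 1.5,
    schedule: Sequence[float] | None = None,
) -> ExperimentResult:
    """Impaired apical-constriction patterns.

    ``mode='narrow_sigma'`` shrinks the Gaussian width (fewer cells
    constrict); ``mode='alternate_cells'`` silences every other cell of
    the 18-cell mesoderm domain, mimicking weakened, uncoordinated
    constriction.  ``with_compression`` toggles ectodermal shortening.
    The result records the final invagination depth of the full
    unperturbed schedule under the modified pattern.
    """
    gparams = gparams or GeometryParams()
    params = params or ModelParams()
    if not with_compression:
        params = replace(params, deltaL=0.0)

    if mode == "narrow_sigma":
        sigma = params.sigma if sigma_value is None else float(sigma_value)
        params = replace(params, sigma=sigma)
        spec = PerturbationSpec(kind="narrow_domain", deltaL=params.deltaL,
                                sigma_override=sigma)
        geom, ann, params = prepare_model(gparams, params)
    elif mode == "alternate_cells":
        spec = PerturbationSpec(kind="alternate_cells", deltaL=params.deltaL,
                                phi_pattern="alternate_cells")
        geom, ann, params = prepare_model(gparams, params)
        # silence cells at even offset ranks (1.5, 3.5, ... on each side),
        # keeping the two midline-adjacent cells active and the pattern
        # mirror-symmetric
        from .geometry import midline_offsets

        offsets = midline_offsets(gparams.n_cells)
        activity = np.where((np.round(offsets - 0.5).astype(int) % 2) == 1, 0.0, 1.0)
        ann = TissueAnnotation(phi=ann.phi, activity=activity)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")

    traj = run_schedule(geom, ann, params, schedule=schedule)
    D_fin = invagination_depth(traj.final, geom)
    return ExperimentResult(
        spec=spec,
        trajectory=traj,
        response=None,
        D_final=D_fin,
    )
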