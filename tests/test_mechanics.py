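"""Energy terms, analytic derivatives and the lateral force law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from furrowsim import (
    Configuration,
    ModelParams,
    apply_ectoderm_shortening,
    energy_breakdown,
    energy_gradient,
    energy_hessian,
    lateral_shortening_force,
    mesoderm_mask,
    total_energy,
)
from furrowsim.geometry import contractility_profile, ectoderm_lateral_edges
from furrowsim.mechanics import (
    energy_and_gradient,
    energy_and_gradient_numpy,
    energy_hessian_numpy,
)


@pytest.fixture(scope="module")
def unloaded():
    """Parameters with every active/loading term switched off."""
    return ModelParams(mu0=0.0, KL_active=0.0, deltaL=0.0)


class TestTotalEnergy:
    def test_rest_energy_vanishes_unloaded(self, geom, ann, unloaded):
        assert total_energy(geom.vertices, geom, ann, unloaded) == pytest.approx(0.0, abs=1e-18)

    def test_rest_energy_is_pure_contractility(self, geom, ann):
        # with only mu0 active, E at rest is the hand-summed
        # sum of Gaussian weights times a0^2 over the 18 mesodermal cells
        p = ModelParams(KL_active=0.0, deltaL=0.0)
        expected = 0.0
        weights = contractility_profile(p.mu0, p.sigma, ann.phi)
        for i in range(geom.n_cells):
            expected += weights[i] * geom.rest_apical[i] ** 2
        assert total_energy(geom.vertices, geom, ann, p) == pytest.approx(expected, rel=1e-12)
        bd = energy_breakdown(geom.vertices, geom, ann, p)
        assert bd["apical_contractility"] == pytest.approx(expected, rel=1e-12)
        assert sum(v for k, v in bd.items() if k != "apical_contractility") == pytest.approx(0.0, abs=1e-15)

    def test_quadratic_scaling_of_elastic_deviation(self, geom, ann, unloaded, rng):
        # doubling every elastic deviation at fixed rests multiplies each
        # elastic term by exactly 4; verified on a radially-scaled state
        # (edge lengths scale linearly with the radial factor)
        x1 = geom.vertices * 1.01
        x2 = geom.vertices * 1.02
        for term in ("apical_elastic", "basal_elastic", "lateral_passive"):
            e1 = energy_breakdown(x1, geom, ann, unloaded)[term]
            e2 = energy_breakdown(x2, geom, ann, unloaded)[term]
            assert e2 == pytest.approx(4.0 * e1, rel=1e-9)

    def test_non_finite_coordinates_rejected(self, geom, ann, params):
        x = geom.vertices.copy()
        x[3, 0] = np.nan
        with pytest.raises(FloatingPointError):
            total_energy(x, geom, ann, params)

    def test_monotone_in_deltaL_at_rest(self, geom, ann):
        # at the unrelaxed rest configuration the compression energy grows
        # monotonically with the shortening fraction
        energies = []
        for dl in np.linspace(0.0, 0.5, 11):
            g = apply_ectoderm_shortening(geom, ann, dl)
            energies.append(total_energy(g.vertices, g, ann, ModelParams(mu0=0.0, KL_active=0.0)))
        assert np.all(np.diff(energies) >= -1e-12)


class TestEnergyBreakdown:
    def test_all_terms_zero_at_unloaded_rest(self, geom, ann, unloaded):
        bd = energy_breakdown(geom.vertices, geom, ann, unloaded)
        assert set(bd) == {
            "apical_contractility", "apical_elastic", "basal_elastic",
            "lateral_passive", "lateral_active", "cell_area_penalty",
            "yolk_penalty",
        }
        assert all(v == pytest.approx(0.0, abs=1e-15) for v in bd.values())

    def test_shortening_energy_oracle(self, geom, ann):
        # direct substitution: before relaxation only the targeted lateral
        # springs store energy, Kl * (0.2 * l_init)^2 each
        p = ModelParams(mu0=0.0, KL_active=0.0, deltaL=0.2)
        g = apply_ectoderm_shortening(geom, ann, 0.2)
        n_targets = len(ectoderm_lateral_edges(ann.phi))
        expected = p.Kl * n_targets * (0.2 * 35.0) ** 2
        bd = energy_breakdown(g.vertices, g, ann, p)
        assert bd["lateral_passive"] == pytest.approx(expected, rel=1e-12)
        assert bd["cell_area_penalty"] == pytest.approx(0.0, abs=1e-12)

    def test_terms_sum_to_total(self, geom, ann, params, rng):
        x = geom.vertices + 0.5 * rng.standard_normal(geom.vertices.shape)
        bd = energy_breakdown(x, geom, ann, params)
        total = total_energy(x, geom, ann, params)
        assert abs(sum(bd.values()) - total) / max(1.0, abs(total)) < 1e-9

    def test_terms_non_negative_on_random_states(self, geom, ann, params, rng):
        for _ in range(50):
            x = geom.vertices + rng.uniform(-2, 2, geom.vertices.shape)
            bd = energy_breakdown(x, geom, ann, params)
            assert all(v >= 0.0 for v in bd.values())


class TestEnergyGradient:
    def test_zero_at_unloaded_rest(self, geom, ann, unloaded):
        g = energy_gradient(geom.vertices, geom, ann, unloaded)
        assert np.max(np.abs(g)) < 1e-9

    def test_matches_finite_differences(self, geom, ann, params, rng):
        # central finite differences as the brute-force oracle
        x = geom.vertices + 0.1 * rng.standard_normal(geom.vertices.shape)
        g = energy_gradient(x, geom, ann, params)
        eps = 1e-6
        z = x.reshape(-1)
        fd = np.empty_like(z)
        for k in range(z.size):
            zp, zm = z.copy(), z.copy()
            zp[k] += eps
            zm[k] -= eps
            fd[k] = (
                total_energy(zp.reshape(-1, 2), geom, ann, params)
                - total_energy(zm.reshape(-1, 2), geom, ann, params)
            ) / (2 * eps)
        assert np.max(np.abs(g.reshape(-1) - fd)) / np.max(np.abs(fd)) < 1e-6

    def test_mirror_symmetric_state_has_mirror_symmetric_gradient(self, geom, ann, params):
        from furrowsim.geometry import mirror_vertices

        x = geom.vertices * 0.99  # symmetric, non-rest
        g = energy_gradient(x, geom, ann, params)
        gm = mirror_vertices(g, geom.n_cells)
        assert np.allclose(g, gm, atol=1e-9 * np.max(np.abs(g)))

    def test_translation_invariance(self, geom, ann, params, rng):
        x = geom.vertices + 0.3 * rng.standard_normal(geom.vertices.shape)
        e0 = total_energy(x, geom, ann, params)
        e1 = total_energy(x + np.array([2.5, -1.0]), geom, ann, params)
        assert abs(e1 - e0) / abs(e0) < 1e-9


class TestEnergyHessian:
    def test_matches_gradient_finite_differences(self, geom, ann, params, rng):
        x = geom.vertices + 0.2 * rng.standard_normal(geom.vertices.shape)
        H = energy_hessian(x, geom, ann, params)
        assert np.allclose(H, H.T, atol=1e-8)
        z = x.reshape(-1)
        eps = 1e-6
        cols = rng.choice(z.size, 30, replace=False)
        for k in cols:
            zp, zm = z.copy(), z.copy()
            zp[k] += eps
            zm[k] -= eps
            col = (
                energy_gradient(zp.reshape(-1, 2), geom, ann, params)
                - energy_gradient(zm.reshape(-1, 2), geom, ann, params)
            ).reshape(-1) / (2 * eps)
            scale = max(1.0, np.max(np.abs(col)))
            assert np.max(np.abs(col - H[:, k])) / scale < 1e-5

    def test_compiled_and_numpy_paths_agree(self, geom, ann, params, rng):
        x = geom.vertices + 0.4 * rng.standard_normal(geom.vertices.shape)
        E1, g1, t1 = energy_and_gradient(x, geom, ann, params, want_breakdown=True)
        E2, g2, t2 = energy_and_gradient_numpy(x, geom, ann, params, want_breakdown=True)
        assert E1 == pytest.approx(E2, rel=1e-12)
        assert np.allclose(g1, g2, rtol=1e-10, atol=1e-8)
        for k in t1:
            assert t1[k] == pytest.approx(t2[k], rel=1e-10, abs=1e-8)
        H1 = energy_hessian(x, geom, ann, params)
        H2 = energy_hessian_numpy(x, geom, ann, params)
        assert np.allclose(H1, H2, rtol=1e-10, atol=1e-8)


class TestEctodermShortening:
    def test_identity_at_zero(self, geom, ann):
        g = apply_ectoderm_shortening(geom, ann, 0.0)
        assert np.allclose(g.rest_lateral, geom.rest_lateral)

    @pytest.mark.parametrize("dl", [0.05, 0.10, 0.20])
    def test_exact_scaling(self, geom, ann, dl):
        g = apply_ectoderm_shortening(geom, ann, dl)
        targets = ectoderm_lateral_edges(ann.phi)
        assert np.allclose(g.rest_lateral[targets], (1 - dl) * geom.rest_lateral[targets])
        others = np.setdiff1d(np.arange(geom.n_cells), targets)
        assert np.allclose(g.rest_lateral[others], geom.rest_lateral[others])
        # all other rest quantities untouched
        assert np.allclose(g.rest_apical, geom.rest_apical)
        assert np.allclose(g.rest_area, geom.rest_area)

    def test_mesodermal_targets_rejected(self, geom, ann):
        with pytest.raises(ValueError, match="mesodermal"):
            apply_ectoderm_shortening(geom, ann, 0.2, targets=np.array([0, 30]))

    def test_invalid_fraction_rejected(self, geom, ann):
        with pytest.raises(ValueError):
            apply_ectoderm_shortening(geom, ann, 1.0)


class TestLateralShorteningForce:
    @pytest.mark.parametrize(
        "l,l0,kla,klp,expected",
        [
            (8.0, 8.0, 0.0, 20.0, 0.0),        # at rest, no active spring
            (10.0, 8.0, 2.0, 20.0, 60.0),      # 2*10 + 20*2
            (8.0, 8.0, 2.0, 20.0, 16.0),       # residual active tension at rest
        ],
    )
    def test_printed_force_law(self, l, l0, kla, klp, expected):
        assert lateral_shortening_force(l, l0, kla, klp) == pytest.approx(expected)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.7, 1.3), shift_x=st.floats(-5, 5), shift_y=st.floats(-5, 5))
def test_energy_properties_under_similarity(scale, shift_x, shift_y):
    """Energy is finite, non-negative per term, and translation invariant."""
    from furrowsim import GeometryParams, build_initial_geometry

    geom = build_initial_geometry(GeometryParams(n_cells=16))
    ann = mesoderm_mask(16, 2)
    p = ModelParams()
    x = geom.vertices * scale
    bd = energy_breakdown(x, geom, ann, p)
    assert all(np.isfinite(v) and v >= 0 for v in bd.values())
    e0 = total_energy(x, geom, ann, p)
    e1 = total_energy(x + np.array([shift_x, shift_y]), geom, ann, p)
    assert e1 == pytest.approx(e0, rel=1e-9, abs=1e-9)
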