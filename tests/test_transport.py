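import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tanwell import ConfigurationError, Geometry, build_grid
from tanwell.kinetics import FIELDS, IDX
from tanwell.transport import (
    TransportOperator,
    diffusive_flux,
    divergence,
    membrane_flux,
    saturating_taxis_flux,
)


class TestDiffusiveFlux:
    def test_uniform_field_has_no_flux(self):
        assert not np.any(diffusive_flux(np.ones(10), 0.5, 0.1))

    def test_linear_profile_gives_constant_flux(self):
        x = np.linspace(0.05, 0.95, 10)
        F = diffusive_flux(x, 0.5, 0.1)
        assert np.allclose(F[1:-1], -0.5)
        assert F[0] == F[-1] == 0.0  # sealed exterior

    def test_checkerboard_alternates(self):
        F = diffusive_flux(np.array([0.0, 1.0, 0.0, 1.0]), 2.0, 0.1)
        assert np.allclose(F[1:-1], [-20.0, 20.0, -20.0])

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ConfigurationError):
            diffusive_flux(np.ones(4), -1.0, 0.1)


class TestSaturatingTaxisFlux:
    def test_uniform_attractant_gives_no_flux(self):
        F = saturating_taxis_flux(np.ones(6), np.ones(6), 1.0, 1.0, 1.0,
                                  np.ones(6), 0.1)
        assert not np.any(F)

    def test_direct_evaluation(self):
        # u_face = 2 (upwind), g = 3, chi = 1, delta = 1, sigma = 1 -> 6/4
        u = np.array([2.0, 0.5])
        s = np.array([0.0, 0.3])  # gradient 3 over h = 0.1
        F = saturating_taxis_flux(u, s, 1.0, 1.0, 1.0, np.ones(2), 0.1)
        assert F[1] == pytest.approx(2.0 * 3.0 / (1.0 + 3.0))

    def test_large_gradient_saturates_advection_speed(self):
        u = np.array([1.0, 1.0])
        s = np.array([0.0, 1e9])
        F = saturating_taxis_flux(u, s, 0.05, 0.1, 1.0, np.ones(2), 0.01)
        assert F[1] == pytest.approx(0.05, rel=1e-6)  # chi/sigma cap

    def test_upwinding_follows_flux_direction(self):
        u = np.array([3.0, 7.0])
        down = saturating_taxis_flux(u, np.array([1.0, 0.0]), 1.0, 1.0, 1.0,
                                     np.ones(2), 0.1)
        assert down[1] < 0 and abs(down[1]) == pytest.approx(7.0 * 10 / 11)

    def test_mask_active_on_region_closure(self):
        # the face between an outside and an inside cell carries the edge flux
        mask = np.array([0.0, 1.0, 1.0, 0.0])
        s = np.array([0.0, 1.0, 1.0, 0.0])
        F = saturating_taxis_flux(np.ones(4), s, 1.0, 1.0, 1.0, mask, 0.1)
        assert F[1] > 0 and F[3] < 0  # edge capture, pointing into the region

    def test_fully_outside_faces_carry_nothing(self):
        mask = np.array([0.0, 0.0, 1.0])
        s = np.array([0.0, 1.0, 2.0])
        F = saturating_taxis_flux(np.ones(3), s, 1.0, 1.0, 1.0, mask, 0.1)
        assert F[1] == 0.0

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ConfigurationError):
            saturating_taxis_flux(np.ones(2), np.ones(2), 1.0, 0.0, 1.0,
                                  np.ones(2), 0.1)


class TestMembraneFlux:
    def test_equal_sides_no_flux(self):
        assert membrane_flux(0.7, 0.7, 785.0) == 0.0

    def test_impermeable_membrane_seals(self):
        assert membrane_flux(1.0, 0.0, 0.0) == 0.0

    def test_jump_law(self):
        assert membrane_flux(1.0, 0.0, 785.0) == pytest.approx(785.0)


class TestDivergence:
    def test_constant_flux_is_divergence_free(self):
        assert not np.any(divergence(np.full(11, 3.0), 0.1))

    def test_single_face_flux_moves_mass_between_neighbors(self):
        F = np.zeros(5)
        F[2] = 1.0
        d = divergence(F, 0.1)
        assert d[1] == pytest.approx(-10.0)
        assert d[2] == pytest.approx(10.0)
        assert d.sum() * 0.1 == pytest.approx(0.0)

    def test_sealed_exterior_conserves_mass(self, rng):
        F = np.concatenate([[0.0], rng.normal(size=9), [0.0]])
        assert divergence(F, 0.1).sum() * 0.1 == pytest.approx(0.0, abs=1e-14)


def _transport_only_step(op, u, t_end, dt):
    n = round(t_end / dt)
    for _ in range(n):
        u = op.step(u, dt)
    return u


class TestTransportOperator:
    def test_global_conservation_with_membrane(self, params, grid, rng):
        op = TransportOperator(params, grid)
        u = rng.uniform(0.0, 2.0, (len(FIELDS), grid.n_cells))
        total0 = u.sum(axis=1)
        u1 = _transport_only_step(op, u, 0.05, op.stable_dt())
        assert np.allclose(u1.sum(axis=1), total0, rtol=1e-12, atol=1e-12)

    def test_zero_permeability_seals_the_chambers(self, params, grid, rng):
        p = params.replace(gamma_cells=0.0, gamma_mol=0.0,
                           chi_E=0.0, chi_rho=0.0, chi_N1=0.0, chi_N2=0.0)
        op = TransportOperator(p, grid)
        u = rng.uniform(0.0, 2.0, (len(FIELDS), grid.n_cells))
        lower = grid.lower_mask()
        m0 = (u * lower).sum(axis=1)
        u1 = _transport_only_step(op, u, 0.1, op.stable_dt())
        assert np.allclose((u1 * lower).sum(axis=1), m0, rtol=1e-12, atol=1e-12)

    def test_huge_permeability_matches_single_domain_diffusion(self, params, grid):
        """gamma -> infinity limit: the membrane becomes transparent."""
        D = 2e-3
        p = params.replace(gamma_cells=1e6, gamma_mol=1e6, D_C=D,
                           chi_E=0.0, chi_rho=0.0, chi_N1=0.0, chi_N2=0.0)
        op = TransportOperator(p, grid)
        x = grid.cell_centers
        u = np.zeros((len(FIELDS), grid.n_cells))
        u[IDX["C"]] = np.exp(-((x - 0.3) ** 2) / 0.01)
        dt = op.stable_dt()
        out = _transport_only_step(op, u, 1.0, dt)[IDX["C"]]
        # oracle: matrix exponential of the Neumann Laplacian, no membrane
        h = grid.h
        n = grid.n_cells
        L = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                L[i, i - 1] += D / h**2
                L[i, i] -= D / h**2
            if i < n - 1:
                L[i, i + 1] += D / h**2
                L[i, i] -= D / h**2
        ref = scipy.linalg.expm(L * 1.0) @ u[IDX["C"]]
        assert np.linalg.norm(out - ref) / np.linalg.norm(ref) < 1e-3

    def test_cosine_mode_decay_matches_closed_form(self, params, grid):
        """Sealed-chamber diffusion decays Neumann cosine modes at D*(m*pi/L)^2."""
        D = 2.25e-3
        p = params.replace(gamma_cells=0.0, gamma_mol=0.0, D_C=D,
                           chi_E=0.0, chi_rho=0.0, chi_N1=0.0, chi_N2=0.0)
        op = TransportOperator(p, grid)
        x = grid.cell_centers
        lower = grid.lower_mask().astype(bool)
        mode = np.where(lower, np.cos(2 * np.pi * x / 0.5), 0.0)
        u = np.zeros((len(FIELDS), grid.n_cells))
        u[IDX["C"]] = 1.0 + mode  # keep the field non-negative
        t_end = 1.0
        out = _transport_only_step(op, u, t_end, op.stable_dt())[IDX["C"]]
        amp = np.sum((out[lower] - 1.0) * mode[lower]) / np.sum(mode[lower] ** 2)
        rate = D * (2 * np.pi / 0.5) ** 2
        assert amp == pytest.approx(np.exp(-rate * t_end), rel=0.01)

    @settings(max_examples=20, deadline=None)
    @given(u=arrays(float, (len(FIELDS), 20), elements=st.floats(0.0, 5.0)))
    def test_positivity_preserved_under_cfl(self, u, params):
        grid = build_grid(Geometry(), 0.05)
        op = TransportOperator(params, grid)
        out = _transport_only_step(op, u, 0.02, op.stable_dt())
        assert np.all(out >= 0.0)
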