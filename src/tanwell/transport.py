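"""Finite-volume spatial operators on the two-chamber mesh.

Fluxes live on faces (positive = toward +x, i.e. lower -> upper
chamber).  Exterior faces carry zero flux (sealed assay walls).  At the
membrane face the whole flux — diffusive plus tactic — is replaced by
the semi-permeable jump law ``J = gamma * (u_lower - u_upper)``: the
membrane resistance, not the bulk gradient, governs exchange there.

Chemotaxis and haptotaxis use the saturating flux
``chi * u * g / (delta + sigma * |g|)`` with a two-point face gradient
``g`` and first-order upwinding of the carried density; the saturation
caps the advection speed at ``chi / sigma`` under steep gradients, which
keeps fronts bounded.  A mask restricts where a tactic flux operates; a
face is active when either adjacent cell is inside the mask, so the flux
acts on the closure of the region (the ECM band's edge faces carry the
haptotactic edge gradient).
"""

from __future__ import annotations

import numpy as np

from .geometry import ConfigurationError, Grid
from .kinetics import IDX
from .parameters import ParameterSet, TRANSPORTED_FIELDS

__all__ = [
    "diffusive_flux",
    "saturating_taxis_flux",
    "membrane_flux",
    "divergence",
    "TransportOperator",
]


def diffusive_flux(u: np.ndarray, Dcoef: float, h: float) -> np.ndarray:
    """Fickian face flux ``-D du/dx``; zero on the exterior faces."""
    if Dcoef < 0:
        raise ConfigurationError("diffusivity must be non-negative")
    u = np.asarray(u, float)
    F = np.zeros(u.size + 1)
    F[1:-1] = -Dcoef * np.diff(u) / h
    return F


def saturating_taxis_flux(
    u: np.ndarray,
    s: np.ndarray,
    chi: float,
    delta: float,
    sigma: float,
    mask: np.ndarray,
    h: float,
) -> np.ndarray:
    """Saturating tactic face flux up the gradient of the attractant ``s``.

    ``mask`` is a per-cell indicator; a face is active when either
    neighboring cell is inside it.  The carried density is upwinded with
    respect to the face velocity.
    """
    if delta <= 0:
        raise ConfigurationError("taxis scale delta must be positive")
    u, s = np.asarray(u, float), np.asarray(s, float)
    mask = np.asarray(mask, float)
    F = np.zeros(u.size + 1)
    g = np.diff(s) / h
    v = chi * g / (delta + sigma * np.abs(g))
    face_on = (mask[:-1] > 0) | (mask[1:] > 0)
    upwind = np.where(v > 0, u[:-1], u[1:])
    F[1:-1] = np.where(face_on, v * upwind, 0.0)
    return F


def membrane_flux(u_lower: float, u_upper: float, gamma: float) -> float:
    """Jump-law flux through the membrane (positive = into upper chamber)."""
    if gamma < 0:
        raise ConfigurationError("membrane permeability must be non-negative")
    return gamma * (u_lower - u_upper)


def divergence(flux: np.ndarray, h: float) -> np.ndarray:
    """Per-cell rate ``-dF/dx`` from a face flux field."""
    flux = np.asarray(flux, float)
    return -np.diff(flux) / h


def _composite_gamma(gamma: float, Dcoef: float, h: float) -> float:
    """Cell-center-to-cell-center membrane conductance.

    The jump law relates the flux to the concentration jump between the
    membrane *traces*; the adjacent cell centers sit half a cell away on
    each side, adding two half-cell diffusive resistances in series:
    ``1/gamma_eff = 1/gamma + h/D``.  As ``gamma -> inf`` the face reduces
    exactly to a regular diffusive face, and the conductance is bounded
    by ``D/h``, so the ordinary diffusion CFL bound covers the membrane.
    """
    if gamma == 0.0:
        return 0.0
    if Dcoef == 0.0:
        return gamma
    return 1.0 / (1.0 / gamma + h / Dcoef)


class TransportOperator:
    """Precomputed explicit transport update for the full state.

    Taxis couplings: tumor cells follow NE gradients everywhere and ECM
    gradients on the gel band; both neutrophil phenotypes follow CXCL8
    gradients.  Molecules only diffuse.  The ECM field ``rho`` does not
    move.
    """

    def __init__(self, p: ParameterSet, grid: Grid):
        self.p = p
        self.grid = grid
        self.h = grid.h
        self.mf = grid.membrane_face_index
        self.perm = p.permeability_map()
        self.ones = np.ones(grid.n_cells)
        self.S_mask = grid.ecm_mask()
        # (carried field, attractant field, chi, delta, sigma, mask)
        self.taxis = {
            "n": [
                ("E", p.chi_E, p.delta_E, p.sigma_E, self.ones),
                ("rho", p.chi_rho, p.delta_rho, p.sigma_rho, self.S_mask),
            ],
            "N1": [("C", p.chi_N1, p.delta_N1, p.sigma_C, self.ones)],
            "N2": [("C", p.chi_N2, p.delta_N2, p.sigma_C, self.ones)],
        }
        self.diffusivity = {
            "n": p.D_n, "N1": p.D_N1, "N2": p.D_N2, "C": p.D_C, "G": p.D_G,
            "E": p.D_E, "D": p.D_D, "P": p.D_P, "M": p.D_M, "A": p.D_A,
        }

    def max_diffusivity(self) -> float:
        return max(self.diffusivity.values())

    def max_taxis_speed(self) -> float:
        """Upper bound chi/sigma on any tactic advection speed."""
        speeds = []
        for terms in self.taxis.values():
            for (_, chi, delta, sigma, _) in terms:
                # sigma = 0 removes the saturation; bound by the steepest
                # gradient the mesh can represent
                speeds.append(chi / sigma if sigma > 0 else 2.0 * chi / (delta * self.h))
        return max(speeds) if speeds else 0.0

    def stable_dt(self, cfl: float = 0.3) -> float:
        """Explicit stability bound over diffusion and taxis."""
        h = self.h
        dt_diff = h * h / (2.0 * max(self.max_diffusivity(), 1e-300))
        dt_adv = h / max(self.max_taxis_speed(), 1e-300)
        return cfl * min(dt_diff, dt_adv)

    def fluxes(self, u: np.ndarray) -> np.ndarray:
        """Face fluxes for every transported field, ``(11, n_faces)``.

        The membrane face is overridden by the jump law (with the
        half-cell diffusive resistances composed in); ``rho`` rows stay
        zero.
        """
        h, mf = self.h, self.mf
        F = np.zeros((u.shape[0], u.shape[1] + 1))
        for name in TRANSPORTED_FIELDS:
            i = IDX[name]
            ui = u[i]
            Fi = diffusive_flux(ui, self.diffusivity[name], h)
            for (attr, chi, delta, sigma, mask) in self.taxis.get(name, ()):
                if chi != 0.0:
                    Fi += saturating_taxis_flux(
                        ui, u[IDX[attr]], chi, delta, sigma, mask, h
                    )
            g_eff = _composite_gamma(self.perm[name], self.diffusivity[name], h)
            Fi[mf] = membrane_flux(ui[mf - 1], ui[mf], g_eff)
            F[i] = Fi
        return F

    def step(self, u: np.ndarray, dt: float) -> np.ndarray:
        """One explicit substep; caller guarantees ``dt <= stable_dt()``."""
        F = self.fluxes(u)
        return u - dt * np.diff(F, axis=1) / self.h
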