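"""Pointwise (non-transport) reaction kinetics.

Eleven interacting fields: tumor cells ``n``, anti-tumor ``N1`` and
tumor-promoting ``N2`` neutrophils, ECM ``rho`` (defined on the gel band
S), CXCL8 ``C``, TGF-beta ``G``, NET/NE ``E``, NE inhibitor (DNase I)
``D``, MMP ``P``, TIMP ``M`` and the TGF-beta antibody ``A``.

The biology, in brief: tumor cells secrete CXCL8 (attracting
neutrophils) and TGF-beta (driving the N1->N2 phenotype switch); N2
neutrophils release NET/NE and MMP, which degrade the gel and — via NE —
boost tumor proliferation and chemoattract tumor cells; N1 neutrophils
kill tumor cells.  DNase I consumes NE, TIMP consumes MMP and the
antibody consumes TGF-beta, each through saturating (Hill) kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import FIELDS, ParameterSet

__all__ = [
    "State",
    "TreatmentFlags",
    "IDX",
    "tumor_reaction",
    "neutrophil_reactions",
    "ecm_decay",
    "chemokine_reactions",
    "reaction_rates",
    "reaction_jacobian",
]

IDX = {name: i for i, name in enumerate(FIELDS)}


@dataclass
class State:
    """All fields on the grid at one time, stacked as ``(11, n_cells)``."""

    fields: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        if self.fields.ndim != 2 or self.fields.shape[0] != len(FIELDS):
            raise ValueError(f"state array must be ({len(FIELDS)}, n_cells)")

    @classmethod
    def zeros(cls, n_cells: int, t: float = 0.0) -> "State":
        return cls(np.zeros((len(FIELDS), n_cells)), t)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.fields[IDX[name]]

    def __setitem__(self, name: str, value) -> None:
        self.fields[IDX[name]] = value

    def copy(self) -> "State":
        return State(self.fields.copy(), self.t)


@dataclass(frozen=True)
class TreatmentFlags:
    """Which constant sources are switched on (active from t = 0)."""

    dnase: bool = False
    timp: bool = False
    antibody: bool = False


def _hill(x: np.ndarray, k: float, m: int) -> np.ndarray:
    xm = x**m
    return xm / (k**m + xm)


def _hill_deriv(x: np.ndarray, k: float, m: int) -> np.ndarray:
    xm = x**m
    return m * k**m * x ** (m - 1) / (k**m + xm) ** 2


def tumor_reaction(n, E, N1, p: ParameterSet):
    """NE-boosted logistic growth minus N1 killing."""
    boost = 1.0 + p.r_E * _hill(np.asarray(E, float), p.k_E, p.m_E)
    n = np.asarray(n, float)
    return p.r * boost * n * (1.0 - n / p.n_cap) - p.mu_n * np.asarray(N1, float) * n


def neutrophil_reactions(N1, N2, G, p: ParameterSet):
    """(rate_N1, rate_N2): proliferation and the TGF-beta-driven switch."""
    N1 = np.asarray(N1, float)
    trans = p.lam_12 * np.asarray(G, float) * N1
    return p.lam_1 * N1 - trans, trans + p.lam_2 * np.asarray(N2, float)


def ecm_decay(rho, E, P, n, p: ParameterSet, S_mask):
    """Proteolytic gel degradation by NE and MMP, restricted to S.

    The rate has no rho dependence; the integrator clamps rho at zero.
    """
    rate = -(p.mu_rho1 * np.asarray(E, float) + p.mu_rho2 * np.asarray(P, float)) * np.asarray(n, float)
    return rate * np.asarray(S_mask, float)


def chemokine_reactions(
    n, N2, C, G, E, D, P, M, A,
    p: ParameterSet,
    injection_mask,
    flags: TreatmentFlags = TreatmentFlags(),
    g_source=0.0,
):
    """Rates for (C, G, E, D, P, M, A).

    ``g_source`` is an optional exogenous TGF-beta supply (uniform or
    per-cell), used by the TGF-beta dose-response sweep.
    """
    n, N2 = np.asarray(n, float), np.asarray(N2, float)
    C, G, E = np.asarray(C, float), np.asarray(G, float), np.asarray(E, float)
    D, P, M, A = (np.asarray(v, float) for v in (D, P, M, A))
    rate_C = p.lam_C * n - p.mu_C * C
    rate_G = p.lam_G * n - p.mu_G * G - p.mu_AG * A * G + g_source
    rate_E = p.lam_E * N2 - p.mu_E * E - p.mu_ED * E * _hill(D, p.K_D, p.l_D)
    rate_D = (p.lam_D if flags.dnase else 0.0) * np.asarray(injection_mask, float) - p.mu_D * D
    rate_P = p.lam_P * N2 - p.mu_PM * P * _hill(M, p.K_M, p.m_M) - p.mu_P * P
    rate_M = (p.lam_M if flags.timp else 0.0) - p.mu_M * M
    rate_A = (p.lam_A if flags.antibody else 0.0) - p.mu_A * A
    return rate_C, rate_G, rate_E, rate_D, rate_P, rate_M, rate_A


def reaction_rates(
    u: np.ndarray,
    p: ParameterSet,
    S_mask: np.ndarray,
    injection_mask: np.ndarray,
    flags: TreatmentFlags,
    g_source=0.0,
) -> np.ndarray:
    """Full reaction right-hand side, ``(11, n_cells)``."""
    n, N1, N2, rho, C, G, E, D, P, M, A = u
    out = np.empty_like(u)
    out[IDX["n"]] = tumor_reaction(n, E, N1, p)
    out[IDX["N1"]], out[IDX["N2"]] = neutrophil_reactions(N1, N2, G, p)
    out[IDX["rho"]] = ecm_decay(rho, E, P, n, p, S_mask)
    (out[IDX["C"]], out[IDX["G"]], out[IDX["E"]], out[IDX["D"]],
     out[IDX["P"]], out[IDX["M"]], out[IDX["A"]]) = chemokine_reactions(
        n, N2, C, G, E, D, P, M, A, p, injection_mask, flags, g_source
    )
    return out


def reaction_jacobian(
    u: np.ndarray,
    p: ParameterSet,
    S_mask: np.ndarray,
) -> np.ndarray:
    """Analytic Jacobian of :func:`reaction_rates`, ``(n_cells, 11, 11)``.

    Treatment sources and the exogenous TGF-beta supply are constants
    and do not enter the Jacobian.
    """
    n, N1, N2, rho, C, G, E, D, P, M, A = u
    nc = u.shape[1]
    J = np.zeros((nc, len(FIELDS), len(FIELDS)))
    i = IDX

    H_E = _hill(E, p.k_E, p.m_E)
    boost = 1.0 + p.r_E * H_E
    J[:, i["n"], i["n"]] = p.r * boost * (1.0 - 2.0 * n / p.n_cap) - p.mu_n * N1
    J[:, i["n"], i["N1"]] = -p.mu_n * n
    J[:, i["n"], i["E"]] = (
        p.r * p.r_E * _hill_deriv(E, p.k_E, p.m_E) * n * (1.0 - n / p.n_cap)
    )

    J[:, i["N1"], i["N1"]] = p.lam_1 - p.lam_12 * G
    J[:, i["N1"], i["G"]] = -p.lam_12 * N1
    J[:, i["N2"], i["N1"]] = p.lam_12 * G
    J[:, i["N2"], i["G"]] = p.lam_12 * N1
    J[:, i["N2"], i["N2"]] = p.lam_2

    J[:, i["rho"], i["n"]] = -(p.mu_rho1 * E + p.mu_rho2 * P) * S_mask
    J[:, i["rho"], i["E"]] = -p.mu_rho1 * n * S_mask
    J[:, i["rho"], i["P"]] = -p.mu_rho2 * n * S_mask

    J[:, i["C"], i["n"]] = p.lam_C
    J[:, i["C"], i["C"]] = -p.mu_C

    J[:, i["G"], i["n"]] = p.lam_G
    J[:, i["G"], i["G"]] = -p.mu_G - p.mu_AG * A
    J[:, i["G"], i["A"]] = -p.mu_AG * G

    J[:, i["E"], i["N2"]] = p.lam_E
    J[:, i["E"], i["E"]] = -p.mu_E - p.mu_ED * _hill(D, p.K_D, p.l_D)
    J[:, i["E"], i["D"]] = -p.mu_ED * E * _hill_deriv(D, p.K_D, p.l_D)

    J[:, i["D"], i["D"]] = -p.mu_D

    J[:, i["P"], i["N2"]] = p.lam_P
    J[:, i["P"], i["P"]] = -p.mu_P - p.mu_PM * _hill(M, p.K_M, p.m_M)
    J[:, i["P"], i["M"]] = -p.mu_PM * P * _hill_deriv(M, p.K_M, p.m_M)

    J[:, i["M"], i["M"]] = -p.mu_M
    J[:, i["A"], i["A"]] = -p.mu_A
    return J
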