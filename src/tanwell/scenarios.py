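"""Experiment definitions and derived observables.

A :class:`Scenario` bundles initial conditions, treatment switches,
parameter overrides and the run horizon for one transwell experiment.
The named scenarios reproduce the assay layouts: tumor cells seeded at
carrying capacity on the gel-coated upper-chamber region, the ECM band
intact, all signaling molecules initially zero, and (for the ``tan``
family) N1 neutrophils seeded uniformly in the lower chamber.  The
transwell scenarios seal the membrane to neutrophils (sub-cell-size
pores), while tumor cells and molecules pass with their respective
permeabilities.

Observables follow the assay readouts: spatial integrals of each field
over the whole domain, and the *invasive* tumor population — tumor mass
integrated over the lower chamber — whose value at the 22 h endpoint is
the transfilter migration readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .geometry import ConfigurationError, Geometry, Grid, build_grid, region_mask
from .kinetics import FIELDS, State, TreatmentFlags
from .parameters import ParameterSet, default_dimensionless_parameters, scenario_overrides
from .solver import SolverConfig, Trajectory, run

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "make_scenario",
    "run_scenario",
    "integrate_population",
    "percent_change",
    "observable_series",
    "sweep_scenarios",
    "tgfb_sweep",
    "DEFAULT_T_END",
    "HIGH_DOSE_LAM_A",
]

#: Assay endpoint: 22 h in units of the one-hour reference time.
DEFAULT_T_END = 22.0
#: High-dose antibody supply rate (top of the published dose sweep).
HIGH_DOSE_LAM_A = 10.0

SCENARIO_NAMES = (
    "control", "tan", "tan_dnase", "ab", "ab_dnase", "timp", "timp_ab", "cxcl8_ko",
)


@dataclass(frozen=True)
class Scenario:
    """One transwell experiment: who is seeded where, and what is dosed."""

    name: str
    #: field -> list of (interval, magnitude) seeded uniformly on the interval
    initial: dict = dc_field(default_factory=dict)
    flags: TreatmentFlags = TreatmentFlags()
    overrides: dict = dc_field(default_factory=dict)
    t_end: float = DEFAULT_T_END
    output_times: tuple = ()
    #: exogenous TGF-beta level (dose-response sweep); 0 = none
    tgfb_level: float = 0.0
    tgfb_mode: str = "source"  # or "clamp"

    def build_initial(self, grid: Grid) -> State:
        state = State.zeros(grid.n_cells)
        for name, pieces in self.initial.items():
            if name not in FIELDS:
                raise ConfigurationError(f"unknown field {name!r} in initial condition")
            for interval, magnitude in pieces:
                if magnitude < 0:
                    raise ConfigurationError("initial magnitudes must be non-negative")
                state[name] = state[name] + magnitude * region_mask(grid, interval)
        return state

    def resolve_parameters(self, p: ParameterSet) -> ParameterSet:
        return scenario_overrides(p, self.overrides)

    def g_source(self, p: ParameterSet):
        """Exogenous TGF-beta supply implementing the nominal dose level.

        ``source`` mode adds ``level * mu_G`` so the sustained exogenous
        contribution equals the nominal level; ``clamp`` mode relaxes G
        stiffly toward the level (handled via overrides in
        :func:`make_scenario`).
        """
        if self.tgfb_level == 0.0:
            return 0.0
        if self.tgfb_mode == "clamp":
            return self._clamp_rate * self.tgfb_level
        return self.tgfb_level * p.mu_G

    _clamp_rate = 100.0


def _base_initial(geometry: Geometry, n0: float, N1_0: float, rho0: float) -> dict:
    ecm_top = geometry.ecm_interval[1]
    initial = {
        "n": [((ecm_top, geometry.x_max), n0)],
        "rho": [(geometry.ecm_interval, rho0)],
    }
    if N1_0 > 0:
        initial["N1"] = [(geometry.lower_interval, N1_0)]
    return initial


def make_scenario(
    name: str,
    geometry: Geometry | None = None,
    overrides: dict | None = None,
    t_end: float = DEFAULT_T_END,
    output_times: tuple = (),
    n0: float = 1.0,
    N1_0: float = 1.0,
    rho0: float = 1.0,
    lam_A: float = HIGH_DOSE_LAM_A,
    tgfb_level: float = 0.0,
    tgfb_mode: str = "source",
) -> Scenario:
    """Build a named transwell experiment.

    ``control``: tumor only.  ``tan``: + N1 in the lower chamber.
    ``tan_dnase``: + DNase source on the injection region.  ``ab`` /
    ``ab_dnase``: antibody supply (rate ``lam_A``) without / with DNase.
    ``timp`` / ``timp_ab``: TIMP supply without / with antibody.
    ``cxcl8_ko``: CXCL8 secretion silenced (lam_C = 0).
    """
    if name not in SCENARIO_NAMES:
        raise ConfigurationError(
            f"unknown scenario {name!r}; valid names: {SCENARIO_NAMES}"
        )
    geometry = geometry or Geometry()
    ov: dict = {"neutrophils_sealed": True}
    flags = TreatmentFlags(
        dnase=name in ("tan_dnase", "ab_dnase"),
        timp=name in ("timp", "timp_ab"),
        antibody=name in ("ab", "ab_dnase", "timp_ab"),
    )
    if flags.antibody:
        ov["lam_A"] = lam_A
    if name == "cxcl8_ko":
        ov["lam_C"] = 0.0
    if tgfb_mode == "clamp" and tgfb_level > 0:
        ov["mu_G"] = Scenario._clamp_rate
    ov.update(overrides or {})
    initial = _base_initial(geometry, n0, 0.0 if name == "control" else N1_0, rho0)
    return Scenario(
        name=name, initial=initial, flags=flags, overrides=ov, t_end=t_end,
        output_times=tuple(output_times), tgfb_level=tgfb_level, tgfb_mode=tgfb_mode,
    )


def run_scenario(
    scenario: Scenario,
    p: ParameterSet | None = None,
    geometry: Geometry | None = None,
    h: float = 0.01,
    cfg: SolverConfig | None = None,
) -> Trajectory:
    """Integrate one scenario and return its trajectory."""
    p = p or default_dimensionless_parameters()
    geometry = geometry or Geometry()
    grid = build_grid(geometry, h)
    p_run = scenario.resolve_parameters(p)
    initial = scenario.build_initial(grid)
    traj = run(
        initial, p_run, grid, scenario.t_end, cfg=cfg,
        output_times=np.asarray(scenario.output_times) if scenario.output_times else None,
        flags=scenario.flags, g_source=scenario.g_source(p_run),
        metadata={"scenario": scenario.name, "overrides": dict(scenario.overrides)},
    )
    traj.metadata["grid_h"] = h
    return traj


# ---------------------------------------------------------------------------
# observables


def integrate_population(field_values: np.ndarray, mask: np.ndarray, h: float) -> float:
    """Midpoint-rule integral of a field restricted to a masked region."""
    return float(np.sum(np.asarray(field_values) * np.asarray(mask) * h))


def percent_change(treated: float, reference: float) -> float:
    """Signed percent change of ``treated`` relative to ``reference``."""
    if reference <= 0:
        raise ConfigurationError("reference must be positive for a percent change")
    return 100.0 * (treated - reference) / reference


def observable_series(traj: Trajectory, grid: Grid) -> pd.DataFrame:
    """Chamber-integrated time series for every field, plus the invasive
    tumor population (tumor mass in the lower chamber)."""
    lower = grid.lower_mask()
    ones = np.ones(grid.n_cells)
    rows = []
    for state in traj.states:
        row = {"t": state.t}
        for name in FIELDS:
            row[f"{name}_hat"] = integrate_population(state[name], ones, grid.h)
        row["n_inv"] = integrate_population(state["n"], lower, grid.h)
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_scenarios(base: str, symbol: str, values, **kwargs) -> list[Scenario]:
    """One scenario per value of a swept parameter symbol."""
    base_overrides = dict(kwargs.pop("overrides", {}) or {})
    out = []
    for v in values:
        ov = dict(base_overrides)
        ov[symbol] = v
        sc = make_scenario(base, overrides=ov, **kwargs)
        out.append(Scenario(**{**sc.__dict__, "name": f"{base}[{symbol}={v:g}]"}))
    return out


#: transition-rate values of the published N1->N2 sweep
LAM_12_SWEEP = (1.6e-4, 1.6e-3, 1.6e-2, 1.6e-1)

#: growth rate used for the high-growth antibody comparison
HIGH_GROWTH_R = 1.5


def run_transwell_panel(
    p: ParameterSet | None = None,
    h: float = 0.01,
    t_end: float = DEFAULT_T_END,
) -> dict[str, pd.Series]:
    """Run the full in-silico experiment panel to the assay endpoint.

    Returns the final-time observable row for every named scenario, the
    antibody pair at the high growth rate, and the N1->N2 transition-rate
    sweep (keys ``lam12=<value>``).
    """
    p = p or default_dimensionless_parameters()
    grid = build_grid(Geometry(), h)

    def final(name, pset, **kw):
        sc = make_scenario(name, t_end=t_end, **kw)
        traj = run_scenario(sc, p=pset, h=h)
        return observable_series(traj, grid).iloc[-1]

    panel: dict[str, pd.Series] = {}
    for name in SCENARIO_NAMES:
        panel[name] = final(name, p)
    p_fast = p.replace(r=HIGH_GROWTH_R)
    panel["tan_high_growth"] = final("tan", p_fast)
    panel["ab_high_growth"] = final("ab", p_fast)
    for value in LAM_12_SWEEP:
        panel[f"lam12={value:g}"] = final("tan", p, overrides={"lam_12": value})
    return panel


def headline_comparisons(panel: dict[str, pd.Series]) -> dict[str, float]:
    """The study's headline endpoint comparisons, from a finished panel.

    Fold changes are ratios; ``pct_reduction_*`` values are positive
    percentages (treated below reference).
    """
    def red(treated, reference, column="n_inv"):
        return -percent_change(panel[treated][column], panel[reference][column])

    lam_lo, lam_hi = f"lam12={LAM_12_SWEEP[0]:g}", f"lam12={LAM_12_SWEEP[-1]:g}"
    return {
        "fold_invasion_tan_vs_control":
            panel["tan"]["n_inv"] / panel["control"]["n_inv"],
        "pct_reduction_invasion_dnase": red("tan_dnase", "tan"),
        "pct_reduction_invasion_antibody_high_growth":
            red("ab_high_growth", "tan_high_growth"),
        "pct_reduction_invasion_antibody": red("ab", "tan"),
        "pct_reduction_invasion_antibody_dnase": red("ab_dnase", "tan"),
        "pct_reduction_invasion_timp": red("timp", "tan"),
        "pct_reduction_mmp_timp": red("timp", "tan", column="P_hat"),
        "pct_reduction_invasion_timp_antibody": red("timp_ab", "tan"),
        "pct_reduction_invasion_low_vs_high_transition": red(lam_lo, lam_hi),
        "pct_reduction_ne_cxcl8_ko": red("cxcl8_ko", "tan", column="E_hat"),
        "pct_reduction_tgfb_cxcl8_ko": red("cxcl8_ko", "tan", column="G_hat"),
    }


def tgfb_sweep(
    levels,
    p: ParameterSet | None = None,
    mode: str = "source",
    h: float = 0.01,
    t_end: float = DEFAULT_T_END,
) -> pd.DataFrame:
    """Invasive tumor and N1/N2 populations versus exogenous TGF-beta dose.

    Each level runs the ``tan`` scenario with an added uniform TGF-beta
    supply proportional to the level (``source`` mode; ``clamp`` mode
    pins G near the level instead).
    """
    rows = []
    for level in levels:
        if level < 0:
            raise ConfigurationError("TGF-beta levels must be non-negative")
        sc = make_scenario("tan", tgfb_level=float(level), tgfb_mode=mode, t_end=t_end)
        traj = run_scenario(sc, p=p, h=h)
        grid = build_grid(Geometry(), h)
        obs = observable_series(traj, grid).iloc[-1]
        rows.append({
            "level": float(level),
            "n_inv": obs["n_inv"],
            "N1_hat": obs["N1_hat"],
            "N2_hat": obs["N2_hat"],
        })
    return pd.DataFrame(rows)
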