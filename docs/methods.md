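# Methods

## The model

`tanwell` simulates neutrophil-assisted tumor cell invasion in a Boyden
transwell assay as a system of taxis–reaction–diffusion equations in one
space dimension.  The dimensionless domain Ω = [0, 1] is split by a
zero-thickness semi-permeable membrane at x = 0.5 into a lower chamber
(where neutrophils are seeded) and an upper chamber (where tumor cells
are seeded on top of a matrigel/ECM band S = [0.35, 0.65] that straddles
the membrane).

Eleven fields evolve: tumor cells n, N1 (anti-tumor) and N2
(tumor-promoting) neutrophils, the ECM concentration ρ (defined on S),
and seven molecules — CXCL8 (C), TGF-β (G), NET/NE (E), DNase I (D),
MMP (P), TIMP (M) and a TGF-β antibody (A).  The couplings are:

* tumor cells follow logistic growth with an NE-dependent Hill boost,
  r (1 + r_E E^m/(k_E^m + E^m)) n (1 − n/n₀), and are killed by N1 at
  rate μ_n N1 n; they move by diffusion, chemotaxis up NE gradients and
  haptotaxis up ECM gradients (on S);
* N1 converts to N2 at rate λ₁₂ G N1; both phenotypes proliferate
  (λ₁, λ₂) and chemotax up CXCL8 gradients;
* tumor cells secrete CXCL8 and TGF-β; N2 secretes NET/NE and MMP;
* the gel degrades at rate (μ_ρ1 E + μ_ρ2 P) n on S, with no ρ
  self-dependence, so the integrator clamps ρ at zero;
* DNase I consumes NE and TIMP consumes MMP through Hill-saturating
  sinks; the antibody consumes TGF-β bimolecularly (μ_AG A G).

Tactic fluxes use the saturating form χ u ∇s/(δ + σ|∇s|), which is
linear in the gradient when |∇s| ≪ δ and caps the advection speed at
χ/σ under steep gradients.  The exterior walls are sealed (zero total
flux).  At the membrane the whole flux of each transported variable is
replaced by the jump law J = γᵢ (u₋ − u₊), with a cell permeability γ_c
for tumor cells and a molecular permeability γ for the seven molecules.
The transwell scenarios additionally seal the membrane to neutrophils
(`neutrophils_sealed`), reflecting pores below the neutrophil size;
tumor cells and molecules pass.

## Discretization and solver

Uniform cell-centered finite volumes (default h = 0.01, 100 cells) with
the membrane coinciding exactly with a face.  Diffusion uses two-point
face fluxes; taxis uses two-point face gradients with first-order
upwinding of the carried density (stability over accuracy at this
resolution).  A tactic flux restricted to a region (haptotaxis on S) is
active on every face with at least one adjacent cell inside the region,
i.e. on the closure of S — the edge faces carry the gel-boundary
gradient, which is what lets an intact gel capture cells at its rim and
a degraded gel release them.

At the membrane face the discrete conductance composes the membrane
resistance with the two half-cell diffusive resistances,
J = (u₋ − u₊)/(1/γ + h/D), because the jump law constrains the membrane
*trace* values while the discrete unknowns live half a cell away.  The
conductance is therefore bounded by D/h: the ordinary diffusion CFL
bound covers the membrane for any γ, and γ → ∞ reduces the face exactly
to a regular diffusive face (verified against a single-domain solve).
Note the jump law replaces the *total* flux, so advective (tactic)
transport does not cross the membrane; cells carried against it by
chemotaxis form a boundary layer of width ~D/χ.

Time stepping is a Strang split: an implicit trapezoidal half-step of
the pointwise kinetics (damped Newton on the per-cell 11×11 systems,
tolerance 1e-8), one explicit transport step sub-cycled to the CFL bound
dt ≤ 0.3·min(h²/2D_max, h/v_max), and a second kinetics half-step.  With
CFL factor 0.3 the worst-case per-substep outflow from any cell is below
its content, so transport preserves non-negativity.  The macro step
adapts from dt = 1e-4: it grows 1.5× after five consecutive cheap Newton
solves and halves when Newton stalls; dt < dt_min is a hard failure that
surfaces the diagnostic state.  The model contains no randomness, so a
fixed configuration reproduces its trajectory bit for bit, and every run
can be replayed from its JSON manifest.

The observed self-convergence order is ≥ 1 in space (upwind-limited) and
≈ 2 in time (trapezoidal kinetics) on smooth manufactured problems; the
membrane's advection-blocking face and the gel edge are genuinely
non-smooth model features and converge only in an integral sense.

## Units and the dimensionless set

The bundled `data/table_parameters.yaml` carries the dimensional
literature values.  `nondimensionalize()` implements the mechanical
scaling layer (diffusivities × T/L², first-order rates × T, bimolecular
rates × T × partner reference, secretion × T × producer/product
references, taxis χ × T/L and δ × L/reference), with
`redimensionalize()` as its exact inverse.

The canonical simulation set (`default_dimensionless_parameters()`)
uses T_ref = 3600 s — one hour, so the 22 h assay endpoint is t = 22 and
the dimensionless tumor growth rate is r = 3.3e-4 × 3600 ≈ 1.19, inside
the [1.2, 1.5] range the dose-response sweeps treat as the growth-rate
axis.  All diffusivities are the table values scaled by T/L² with
L_ref = 2.0 cm (the height of a transwell column), e.g. D_C = 2.25e-3,
D_n = 2.25e-5.  Every first-order production/decay rate is the table
value × 3600, unmodified.

The remaining entries are set by a one-time calibration of the
reference-magnitude layer, and frozen:

* Secretion rates are balanced so produced fields are O(1)–O(10) on the
  assay horizon: λ_C = μ_C and λ_D = μ_D (source/decay balance), with
  smaller reference magnitudes for TGF-β (λ_G = 0.8), NET/NE
  (λ_E = 0.3) and TIMP (λ_M = 0.164).  The TGF-β reference
  G_ref ≈ 1.1e-8 g/cm³ makes the tabulated transition rate λ₁₂
  dimensionless 0.16 — exactly the top of the published sweep grid
  {1.6e-4 … 1.6e-1}, which is taken as the default.
* Taxis sensitivities: χ_E = 0.004 (δ_E = 0.1), χ_ρ = 0.05 (δ_ρ = 0.1),
  χ_N1 = χ_N2 = 0.012 (δ = 0.1), all with σ = 1.  These are
  dimensionless advection-speed caps; the printed sensitivity and scale
  columns mix unit conventions (χ in cm/s with σ = 1 would make taxis
  numerically inert at any plausible length scale), so the dimensionless
  speeds are calibrated directly.  χ_ρ exceeds the invasion front speed
  so the intact gel rim acts as a haptotactic barrier; χ_E is kept below
  it so NE chemotaxis biases transport without trapping invaded cells at
  the membrane.
* Couplings to O(1) partners: μ_n = 0.35, μ_AG = 0.012, μ_ρ1 = 2.5,
  μ_ρ2 = 0.25, k_E = 0.04, K_D = 0.342, K_M = 0.02.
* The two inhibitor efficacies published as ranges sit at the upper
  ends of their printed ranges (μ_ED = 2.8e-2 /s → 100.8, μ_PM =
  2.8e-4 /s → 1.008): the range midpoints cannot produce the
  near-complete NE suppression under DNase I or the ~80% MMP knockdown
  under TIMP that the assay exhibits, so the upper ends are the
  experimentally consistent regime.
* Membrane permeabilities keep their published representative values
  γ_c = 78.5, γ = 785 (with the half-cell composition above, both are
  effectively bulk-limited, i.e. the membrane is nearly transparent to
  whatever diffuses to it).

The calibration was performed once, against the study's reported
endpoint outcomes, and is not revisited per scenario: all treatment
scenarios differ from the untreated run only by their sources/knockouts.

## Scenarios and observables

Initial conditions follow the assay: tumor at carrying capacity (n = 1)
on the upper-chamber region above the gel, ρ = 1 on S, N1 = 1 uniform in
the lower chamber for the +TAN family (absent for control), everything
else zero.  Treatment sources (DNase on the lower chamber, TIMP and
antibody domain-wide) are active from t = 0; the antibody dose defaults
to the top of the published sweep (λ_A = 10).  CXCL8 knockdown sets
λ_C = 0 exactly.  The TGF-β dose-response sweep adds an exogenous
uniform supply level × μ_G to the G equation, so the sustained exogenous
contribution equals the nominal level; a clamp mode (stiff relaxation to
the level) is available as an option.

Observables are midpoint-rule spatial integrals of each field; the
*invasive* population is tumor mass in the lower chamber, read at the
22 h endpoint, matching the transfilter count in the wet assay.

## What the simulated panel does and does not reproduce

At the frozen defaults the panel reproduces, within ±0.3 (fold) or
±10 percentage points: the ~2-fold invasion increase with neutrophils
seeded; the ~50% DNase reduction; the ~36% antibody reduction at the
default growth rate and the ~66% antibody+DNase combination; the ~82%
MMP knockdown under TIMP; the >48% invasiveness loss at the smallest
N1→N2 transition rate (monotone in λ₁₂); and the ~40% NE reduction
under CXCL8 knockdown.

Three reported outcomes are **not** reproduced, for structural reasons
rather than tuning ones, and the corresponding checks are left failing
deliberately:

* *TIMP's direct anti-invasion effect (reported ~26%) and the very
  strong TIMP+antibody synergy (reported >87%).*  In these equations
  MMP's only route to invasion is gel proteolysis, and MMP is produced
  by the same N2 field as NE, so the two proteases degrade the same gel
  in the same places — they are redundant sinks of one budget.  Any
  split of that budget large enough to give TIMP a ~26% effect
  simultaneously destroys the DNase ~50% effect, and vice versa; the
  reported synergy would require a non-redundant MMP pathway this system
  does not contain.
* *The 62% antibody effect at growth rate r = 1.5 alongside 36% at the
  default rate.*  That pair requires the percent reduction to increase
  with r.  Here every arm's invasion is growth-limited and the antibody
  arm retains N1 killing, making its net lower-chamber growth rate
  (r − μ_n N1) more r-elastic than the untreated arm's — the reduction
  decreases with r for any killing strength.
* *The ~50% TGF-β drop under CXCL8 knockdown.*  TGF-β tracks total
  tumor mass; halving it by 22 h would require the knockdown to halve
  tumor growth, which the NE growth boost (capped at r_E = 7%) cannot
  mediate.

These limits describe the printed equation system; they are stated here
so that failing checks are read as documented model properties, not
regressions.

## What the synthetic scenarios do not capture

The scenarios are idealized assay conditions, not data: uniform initial
seedings, treatments on from t = 0 with no dosing schedule or decay of
the stock, a sealed 1D column (no radial structure, no fluid flow), a
single membrane, and no neutrophil death or NETosis-associated
neutrophil loss.  N2 neutrophils grow exponentially without a cap
(faithful to the equations over the 22 h horizon; the solver logs a
warning if any field exceeds 1e6).  Quantitative agreement with the
reported numbers therefore demonstrates that the equation system can
express those outcomes under the documented calibration — not that the
parameters are identified by data.

## Problem sizes

Default runs use 100 cells and adaptive macro steps (~2.2k kinetics
solves, ~2–10k transport substeps per 22 h run; a few seconds each).
The experiment panel behind the headline comparisons is 14 such runs.
Property tests use the same grid or coarser ones; the well-mixed oracle
runs on a 4-cell grid with dt = 1e-4 against an LSODA reference.
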