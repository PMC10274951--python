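# Model and methods

`tumorvasc` simulates vascular tumor growth and its response to combined
Doxorubicin (DOX) / Trastuzumab (TRA) therapy as a hybrid model: discrete
agents (spherical tumor cells, cylindrical vessel segments) coupled in both
directions to four continuum concentration fields (nutrients, VEGF, DOX,
TRA).  This note records the model equations as implemented, the numerical
choices, the default parameters and their rationale, and what the synthetic
scenarios do and do not establish.

## Tumor cells

Each cell carries a position, three radii (nuclear r_n, physical r_p, action
r_a), a categorical state s in {Q, SG2, G1, H, D} and a clock Δt_s counting
hours since the last state change.  Default radii are r_p = 9.953 µm,
r_n = 5.296 µm, r_a = 12.083 µm for BT-474-like breast cancer cells.  (The
source that motivated these numbers lists them in an order that would make
the nuclear radius exceed the physical one; we treat that as a transposition
and expose all three as free parameters.)

### Deterministic transitions

* SG2 → G1 when Δt_s ≥ T_SG2 (default 10 h): volume-preserving division.
  Mother and daughter each take half the mother's volume (radii scaled by
  2^(−1/3)); the daughter is placed at distance r_p along a uniformly random
  direction.  Both enter G1 and regrow linearly to natural size over T_G1.
* G1 → Q when Δt_s ≥ T_G1 (default 7 h).
* Q → H when u_n < u_n_hypoxic; H → Q when u_n ≥ u_n_hypoxic.

### Stochastic transitions

Two rate shapes generate per-step probabilities (Δt the step in hours):

* smoothed Heaviside (decreasing):
  ς(x; a, b, x̄) = 1 − exp(−(a + 1/(1 + e^{2b(x−x̄)})) Δt)
* linear ramp (increasing):
  ϱ(x; c, x̄) = 1 − exp(−max(c (x−x̄)/(1−x̄), 0) Δt)

with x, x̄ dimensionless concentrations in [0, 1].  The five stochastic
transitions (each clamped to [0, 1]):

* P(Q→SG2)  = ϱ(u_n; c, x̄) · exp(−λ u_t)   — TRA arrests the cycle
* P(Q→D)    = ς(u_n; a, b, x̄) · (1 + ξ_d u_d + ξ_t u_t + ξ_dt u_d u_t)
* P(SG2→SG2)= ϱ(u_d; c, x̄)                  — DOX interrupts DNA duplication
                                              (clock reset)
* P(SG2→D)  = ϱ(u_n; c, x̄)
* P(H→D)    = r_HD Δt · (1 + ξ_d u_d + ξ_t u_t + ξ_dt u_d u_t)

The cycle has exactly 20 scalar parameters.  P(SG2→D) is a ramp in the
*nutrient* concentration, following the printed form of the source model
even though its motivation (death after failed DNA duplication) would
suggest the DOX concentration; with the small default slope (1e-3/h) the
term is negligible either way.

Rule order within a step is fixed: G1 regrowth, deterministic timers,
hypoxia switch, then at most one stochastic draw per still-unchanged cell
(a single uniform variate against sequential thresholds).  This makes a step
reproducible and caps every cell at one state change per step.  Dead cells
never change, keep their mechanical presence (preserving necrotic-core
volume) and are excluded from all continuum coupling.

### Pharmacodynamic defaults

The drug constants are calibrated to reproduce, at desk scale, the
qualitative clinical ordering of the four protocols (see "Treatment
scenario" below): λ_Q→SG2 = 60 (strong cycle arrest at the low TRA
concentrations that penetrate tissue), ξ_d = ξ_t = 0.5 (small linear kill
terms: DOX alone is nearly ineffective), ξ_dt = 6000 (strong synergy:
deaths concentrate where both drugs overlap), baseline death offset
a_Q→D = 1e-3/h, hypoxic death rate r_HD = 0.01/h (~4 day mean hypoxic
survival).  The large cross-term constant compensates for the small
dimensionless drug concentrations reached inside tissue (u_d u_t ~ 1e-3);
only the products ξ·u are meaningful.

## Cell–cell mechanics

The pairwise force acts along the center line, is zero for center distance
d ≥ RA (sum of action radii) and is continuous:

* d < RP (sum of physical radii):  f = c_rep (RP − d)/RP  (repulsion)
* RP ≤ d < RA:  f = −c_adh (RA − d)(d − RP)/(RA − RP)²  (adhesive well)

The exact polynomial of the model this force emulates is not published in
the text we worked from; this surrogate preserves its contracted properties
(compact support, antisymmetry, repulsion under overlap, adhesion in the
action shell, continuity, equilibrium at d = RP).  Neighbor search uses a
uniform spatial hash with bucket edge 2·max(r_a), rebuilt every step, and is
exactly equivalent to the all-pairs sum.  Positions follow the overdamped
update x ← x + η F Δt (η = 2 µm per force unit per hour by default).  Cells
are reflected into the simulation cube so that concentration lookups stay
defined; vessels are rigid and exchange no forces with cells.

## Vasculature and angiogenesis

Vessels form a forest of cylindrical agents (one optional mother, up to two
daughters; 0/1/2 daughters = tip / regular segment / branching point).
Segment geometry is immutable except at tips.

* **Branching.**  A regular segment may sprout when (i) u_v at its midpoint
  ≥ u_v_threshold, (ii) the nearest tip is farther than d_tip from the
  midpoint (+∞ for no tips), and (iii) the arc length to the preceding and
  succeeding branching point both exceed d_branch (tree ends count as +∞).
  Sprouting succeeds with probability p_s_rate·Δt; the new ~1 µm daughter's
  axis lies on a cone (default half-angle 30°) around the VEGF gradient
  (uniform azimuth; zero gradient falls back to the uniform sphere), with
  diameter max(5, min(0.8 d0, 20)) µm.
* **Tip growth.**  Tips elongate at `speed` along the normalized direction
  w1 ∇u_v + w2 a + w3 X3 (a the current axis, X3 ~ U(−1,1)³), only while
  g_min ≤ |∇u_v| < g_stop; reaching g_stop stops that tip permanently (the
  stopping criterion that proved effective: tips park where the signal is
  strongest).  At length 10 µm a tip splits into a 9 µm segment plus a 1 µm
  tip with diameter max(5, min(0.98 d0, 20)) µm; no sub-step residual is
  carried.  The default extension speed is 2 µm/h (literature estimate);
  the angiogenesis scenario uses 6 µm/h so the network forms within its
  7-day horizon.
* Anastomosis, flow and pruning are not modeled; tips never fuse.

## Continuum fields

Each substance u ∈ [0,1] obeys ∂u/∂t = D∇²u − λu + (1−u)A⁺ − uA⁻ on a
shared uniform cubic lattice, advanced by the explicit FTCS stencil

u' = (1 − λΔt)u + (DΔt/h²)·Lap6(u) + Δt(1−u)A⁺ − Δt·u·A⁻

with zero-flux Neumann boundaries (ghost-node mirroring) or fixed-value
Dirichlet boundaries.  A step is rejected unless (λ + 12D/h²)Δt ≤ 2 (von
Neumann bound).  The engine substeps each substance with the smallest count
satisfying both that bound and the monotonicity bound
(λ + 6D/h² + max(A⁺+A⁻))Δt' ≤ 1, which keeps u in [0,1] under arbitrarily
strong point sources; agent fields are held fixed across substeps (operator
splitting).  Point lookups use the nearest lattice node (ties toward the
lower index); gradients are central differences at that node, one-sided at
boundaries.

Diffusion coefficients come from the mass-scaling rule D ∼ m^(−1/3)
anchored at glucose (180 g/mol, D = 50 µm²/h): VEGF monomer 10.5, DOX 34.6,
TRA 5.4 µm²/h.  (The reference tabulation lists DOX at 42.5 µm²/h, which is
inconsistent with its own printed scale factor 0.69; we use the rule value.)
Decay constants: VEGF 0.01/h; DOX 0.012/h, inside the 20–48 h half-life
window (ln 2 / t½ ∈ [14.4, 34.7]·10⁻³/h); TRA 0.004/h, inside the
1.7–28 day window ([1.0, 17.0]·10⁻³/h) — a slow TRA decay is what lets the
antibody persist between delivery slots.

## Agent–continuum coupling

Discrete δ sources deposit onto the single nearest lattice node.  Every
living cell contributes its α to the nutrient/DOX/TRA sink fields; only
hypoxic cells secrete VEGF (α_v); dead cells contribute nothing.  A vessel
segment of length l and radius r is reduced to m = max(3, ceil(2l/h + 1))
points carrying 2πrl/m each (the lateral surface split evenly), placed at
the uniform midpoints ((k−½)/m, k = 1..m) of its center line.  (The printed
formula for these sample points, x_k = x_s + (k+1)(x_e−x_s)/m, runs past the
segment end; the midpoint rule preserves the intended uniform coverage and
the exact surface total.)  Vessels source nutrients (β_n), DOX (φ(t)·β_d,
only inside DOX windows) and TRA (β_t, TRA windows), and sink VEGF (β_v).

The homogenized view: ignoring diffusion, N cells of consumption r per
volume V act as an effective decay λ' = λ + rρ with ρ the cell density —
the bridge used to compare the sink constants against exponential fits.

## Treatment model

TRA normalizes the vasculature and transiently improves DOX delivery.  The
supply state χ obeys the capacitor ODE dχ/dt = (χ_max − χ)/τ↑ during TRA
delivery and −χ/τ↓ otherwise (explicit Euler, clamped to [0, χ_max]); the
DOX vessel source is multiplied by φ = 1 + χ ≥ 1.  χ never reads the DOX
state.  Defaults χ_max = 0.75 (up to 75% extra DOX), τ↑ = 12 h, τ↓ = 48 h —
free parameters chosen so that two day-long TRA slots charge χ near its
ceiling and a following DOX slot still sees φ ≈ 1.4.  Windows are half-open
[start, end) so back-to-back windows are unambiguous.

## Initial state and synthetic vasculature

Spheroids: N cells uniform in a ball of radius r_cell (N/0.64)^(1/3) (random
close packing), all in Q for nutrient-supplied scenarios and in H for
no-nutrient starts.  The synthetic vasculature generator traces parent
vessels as bounded random walks (entry on a random domain face, ~10 µm
segments, angular waviness, diameters 10–22 µm tapering at 0.98 per segment
with a 5 µm floor), rejects steps entering the exclusion ball around the
tumor seed, and adds vessels until the total length density is within 20%
of a target.  It is an original stand-in constrained by the qualitative
description of the data-derived network it emulates (sparse connected
cylinders, 5–20+ µm diameters, empty center); orientation statistics and
radial density profiles of real capillary beds are *not* matched, so
network-structure results should be read as qualitative.

## Engine

One agent step (default 6–15 min): (1) assemble A± from the current agents
(treatment flags at the step's start, φ from the previous χ); (2) advance
each enabled substance by its stable substeps; (3) update χ; (4) cell-cycle
updates; (5) vessel branching and tip growth unless past the shutoff day;
(6) forces and displacement with reflection into the domain.  A single RNG
stream is consumed in fixed order (division directions, cell draws,
branching candidates by ascending id, tips by ascending id), so
(config, seed) → outputs is a pure function.  Non-tip vessel deposition is
cached and rebuilt only on topology changes.

## Reference scenarios (shipped presets)

Scaled-down study conditions used by the test suite and the acceptance
script; sizes chosen so the full suite runs on one CPU in minutes.

* **Spheroid sweep** — 200 cells, 40³ lattice over a 600 µm cube, Δt = 6
  min, 30 days, Dirichlet nutrients at 0.5.  Hypoxic thresholds {0.40,
  0.05} bracket the two regimes: at 0.40 the hypoxic level set overtakes
  the spheroid (living count peaks, then declines toward zero); at 0.05 a
  proliferative surface population persists over a necrotic core.  The
  original experiment uses 500 cells, 200 days and thresholds 0.11–0.15;
  at 30 days those thresholds do not yet separate, so the scaled sweep
  widens the bracket rather than lengthening the run.
* **Angiogenesis contrast** — 100 permanently hypoxic cells (death rate
  zeroed so the VEGF source is stationary) inside a synthetic network,
  7 days, with the VEGF vessel-sink coupling on vs. off.  With the sink,
  vessels deplete VEGF locally, gradients steer sprouts away from existing
  vessels and new tips disperse around the tumor; without it they converge
  on the center along nearly identical paths.  Measured as mean pairwise
  distance among newly created tip endpoints.
* **Treatment comparison** — 100 cells, static supplying network
  (angiogenesis off), 16 days, three day-long delivery slots at days 8–9,
  10–11, 12–13.  Protocols assign drugs per slot: DOX-DOX-DOX,
  TRA-TRA-TRA, TRA-TRA-DOX, DOX-TRA-TRA.  Expected ordering of final
  living counts: TRA→DOX < TRA-only ≈ DOX→TRA < DOX-only ≈ untreated.

## Known limitations

* No healthy tissue, stress or pressure; cells float in free space, so
  mechanical confinement effects are absent.
* No cell migration; no detailed death/lysis (dead cells persist rigidly).
* No blood flow, vessel pruning or anastomosis; late-stage networks keep
  growing wherever VEGF is high unless the shutoff day is set.
* No cell–vessel forces.
* The drug terms act through local concentrations only; order-dependent
  intracellular interactions (e.g. DOX degrading later TRA efficacy) are
  not representable, so DOX-then-TRA behaves like TRA-only here.
* Passing the scaled scenarios demonstrates the mechanisms and their
  couplings, not quantitative agreement with any animal or clinical data.
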