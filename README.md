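# tumorvasc

A hybrid agent-based / continuum simulator of 3-D vascular tumor growth and
response to combined **Doxorubicin (DOX)** / **Trastuzumab (TRA)** therapy,
for computational oncology researchers who want a desk-scale (10³–10⁵ agent)
testbed for hypotheses about the interplay of tumor growth, sprouting
angiogenesis and drug scheduling in HER2+ breast cancer.

## The model

Three coupled layers:

* **Tumor cells** — spherical agents with a five-state stochastic cell
  cycle, s ∈ {Q, SG2, G1, H, D}: quiescent, proliferative (DNA duplication,
  then post-division growth), hypoxic and dead.  Deterministic timers drive
  SG2→G1 (volume-preserving division) and G1→Q; the nutrient threshold
  u_n^H switches Q↔H.  Stochastic transitions use a smoothed Heaviside
  ς(x; a, b, x̄) and a linear ramp ϱ(x; c, x̄) of the local concentrations,
  e.g. P(Q→SG2) = ϱ(u_n)·exp(−λ u_t) (TRA arrests the cycle) and
  P(Q→D) = ς(u_n)·(1 + ξ_d u_d + ξ_t u_t + ξ_dt u_d u_t) (drug kill with a
  synergy cross term).  Cells interact via compact-support
  adhesion/repulsion forces with overdamped dynamics x ← x + ηFΔt.
* **Vasculature** — a linked tree of rigid cylindrical segments.  Regular
  segments sprout new tips (probability p_s,rate·Δt, axis on a cone around
  ∇u_v) when local VEGF, tip spacing and branch spacing criteria hold; tips
  elongate along w₁∇u_v + w₂a + w₃X₃, split at 10 µm into 9 + 1 µm
  cylinders, and stop in high-gradient regions.  Diameters follow
  max(5, min(0.8 d₀, 20)) µm at branches and max(5, min(0.98 d₀, 20)) µm
  along vessels.
* **Continuum fields** — nutrients, VEGF, DOX and TRA obey
  ∂u/∂t = D∇²u − λu + (1−u)A⁺ − uA⁻ on a uniform cubic lattice (explicit
  FTCS scheme, stability bound (λ + 12D/h²)Δt ≤ 2).  Agents enter as
  nearest-node δ sources: cells consume nutrients and drugs, hypoxic cells
  secrete VEGF, vessels supply nutrients and drugs (as weighted line-δs
  over their lateral surface 2πrl) and consume VEGF.  TRA charges a
  capacitor-like supply state χ (dχ/dt = (χ_max−χ)/τ↑ during delivery,
  −χ/τ↓ after) that multiplies the DOX vessel source by φ = 1 + χ, encoding
  vascular normalization.

Diffusion coefficients follow the mass-scaling rule D ∼ m^(−1/3) anchored
at glucose (180 g/mol, 50 µm²/h); decay constants derive from terminal
half-lives via λ = ln 2 / t½.  See `docs/methods.md` for the full model
description, parameter defaults and limitations.

## Worked example

Derive the continuum parameters from molecular masses and half-lives:

```text
$ tumorvasc derive-params
substance             mass [g/mol]   alpha  alpha^-1/3  D [um^2/h]
glucose (nutrients)            180       1        1.00        50.0
VEGF (monomer)               19300     107        0.21        10.5
VEGF (dimer)                 38600     214        0.17         8.5
DOX                            543       3        0.69        34.5
TRA                         145000     806        0.11         5.5

half-life -> decay constant [1/h]:
  DOX 20 h   lambda' = 3.4657e-02
  DOX 48 h   lambda' = 1.4441e-02
  TRA 1.7 d  lambda' = 1.6989e-02
  TRA 28 d   lambda' = 1.0315e-03
```

`alpha` is each molecule's mass in units of the glucose mass; its −1/3 power
scales the glucose diffusivity down to the heavier species (VEGF diffuses at
10.5 µm²/h, the TRA antibody at ~5.5 µm²/h).  The decay rows bracket the
admissible DOX and TRA decay constants from their published terminal
half-lives.

Run a vascularized tumor for 16 simulated days under the TRA-TRA-DOX
protocol (two trastuzumab slots, then one doxorubicin slot) and under no
treatment:

```text
$ tumorvasc run --preset treatment-tra_dox --seed 1 --out out_tra_dox
day 16.0: 330 living / 534 total cells, 414 vessel agents -> out_tra_dox

$ tumorvasc run --preset treatment-untreated --seed 1 --out out_untreated
day 16.0: 530 living / 680 total cells, 414 vessel agents -> out_untreated
```

Starting from 100 cells, the untreated tumor grows to 530 living cells; the
TRA-primed DOX dose leaves 330 — the sequencing benefit appears because TRA
both stalls proliferation and charges the supply factor φ, so the following
DOX slot delivers more drug into tissue that still holds TRA (the ξ_dt
synergy term).  Each output directory contains the per-day state-count
series (`state_series.csv`), final cell and vessel snapshots, field
snapshots and a run manifest (config hash + seed).

Other subcommands: `gen-vasc` (write a synthetic vessel network),
`validate-config`, `write-preset`; ready-made scenario configs live in
`configs/`.

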