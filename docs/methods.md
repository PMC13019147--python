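# Methods

This note documents the models, the numerical choices, and what the
synthetic machinery does and does not emulate.

## Problem setting

In boron neutron capture therapy (BNCT) the tumor dose has four components:
the ¹⁰B(n,α)⁷Li capture dose (B), the ¹⁴N(n,p)¹⁴C proton dose (N), fast
recoil protons from hydrogen scattering (H), and photons (γ). The capture
fragments (α of 1.47/1.78 MeV, ⁷Li of 0.84/1.02 MeV) have ranges below
10 μm, so the dose that matters biologically — the dose to the cell
nucleus — depends on where the boron sits relative to the nuclei and on the
cellular geometry, neither of which a macroscopic kerma-based treatment
plan sees.

The package's core is a precomputed bridge between the two scales: a
cellular-scale Monte Carlo tabulates, over a grid of cell morphologies,

* the nucleus-dose ratios `R_n, R_c, R_e` — nucleus dose per capture when
  boron is localized in nucleus / cytoplasm / extracellular space, relative
  to the same dose under uniformly distributed boron, and
* the microdosimetric moments of the single-event specific-energy
  distributions in the nucleus (`z̄_n,D`) and in sub-nuclear spherical
  domains (`z̄_d,D`, saturation-corrected `z̄*_d,D`),

and a multilinear interpolator serves these for arbitrary morphologies and
boron distributions. The macroscopic-to-nucleus boron dose conversion is

    κ = N_n R_n + N_c R_c + N_e R_e,     N_n + N_c + N_e = 1,

with `N_j` the fraction of boron (hence captures) per compartment,
decomposed into `κ_intra = N_n R_n + N_c R_c` and `κ_extra = N_e R_e`.
Survival under a mixed field then follows from the stochastic
microdosimetric kinetic (SMK) model, and the photon isoeffective dose
`D_isoE = −ln S / (α + βX)` expresses it as the equivalent fractionated
photon course.

## Cell model

Tissue is an 11×11×11 array of cubic cells in extracellular medium, all of
unit density. A morphology is set by the nuclear cross-sectional area
`S_nucl` (nucleus edge `a_n = √S_nucl`), the area ratio `S_nucl/S_cell`
(cell edge `a_c = √(S_nucl/ratio)`), and the intercellular gap (lattice
pitch `p = a_c + gap`), giving `V_cell/V_total = (a_c/p)³`. The nucleus is
a cube concentric with its cell; this keeps the area ratio exact and all
volume fractions closed-form. The default table grid is
`S_nucl ∈ {9, 36, 81, 144} μm²`, ratio `0.1…0.8` (step 0.1), and 16 gaps
from 0.1 to 14 μm — 512 models spanning occupancies ~0.02–0.99.

The nucleus shape and the lattice-boundary treatment are modeling choices:
the tally exploits translation invariance and scores the periodic lattice
(see below), which corresponds to the interior of a large array; edge
effects of a finite array are therefore absent by construction.

## Transport surrogate

Charged particles travel in straight lines and slow down continuously along
a per-species monotone range–energy relation `R(E)`; the energy deposited
between path lengths `s₁ < s₂` is `E(R₀−s₁) − E(R₀−s₂)` through the
inverse relation. Built-in power-law fits (μm, MeV) reproduce literature
CSDA ranges at the relevant energies:

| species  | R(E)            | anchor                   |
|----------|-----------------|--------------------------|
| α        | 5.0·E^1.17      | 9.8 μm at 1.78 MeV       |
| ⁷Li      | 4.6·E^1.05      | 4.7 μm at 1.02 MeV       |
| proton   | 24·E^1.60       | ~10 μm at 0.58 MeV, 73 μm at 2 MeV |
| electron | E/LET, LET = 0.2 keV/μm (constant) | low-LET photon secondaries |

Custom tables can be loaded from two-column CSV. Delta rays are not
followed (energy stays on the ion path — an amorphous-track picture
adequate at domain diameters ≥ 0.05 μm), energy-loss straggling is not
modeled, and the 478 keV de-excitation photon of the dominant capture
branch is not transported (its cellular-scale deposition is negligible;
photons are carried by the separate γ component). Capture kinematics are
exact two-body: branch probabilities 0.937 (excited, Q = 2.314 MeV) and
0.063 (ground, Q = 2.792 MeV), energies split 7:4 between α and ⁷Li,
emitted back-to-back from the capture point.

The N component is the 0.584 MeV ¹⁴N(n,p) proton. The H recoil-proton
spectrum and the γ-secondary electron energy are configuration (defaults:
uniform 0.1–2 MeV; 0.3 MeV electrons): the real spectra come from a
macroscale phantom simulation that is outside this package's scope, and no
quantitative claim rests on them.

## Tally

One history is one capture (correlated α/⁷Li pair) or one background
primary. Rather than re-randomizing the source position against a fixed
scored nucleus, the engine emits from the central cell (or uniformly over
one lattice period for background components) and scores energy deposited
in *all* nuclei of the periodic array — identical in expectation by
translation invariance, with every history contributing. Tracks are
diced into sub-steps (0.05–0.1 μm for ions, capped at 1200 steps for long
electron tracks); each sub-step's energy comes from exact residual-range
differences, so energy is conserved exactly, and its midpoint is classified
by periodic membership tests (first-order unbiased at boundaries; the
measured bias on mean nucleus dose is < 0.2% even at 0.2 μm steps).

Each (history, nucleus) pair with nonzero deposit is one single-event
sample `z = E/m_nucleus` of `f_n,1`; zero-deposit histories are excluded
from the density but counted in the event frequency, so that
`z̄_n,F · (events/history)` equals the mean nucleus dose per capture
exactly. Histograms are log-spaced, 60 bins per decade over 10⁻⁶–10⁶ Gy.

Domain spectra use spherical sites inside nuclei. Sphere centers uniform
in the nucleus, conditioned on a nonzero chord, are equivalent to sampling
uniformly along the in-nucleus track length with the impact parameter
drawn from the disc distribution `b = r√U`; the chord is `2√(r²−b²)`
(mean 2d/3, the Cauchy mean-chord value, verified to 1%) and the local LET
converts it to energy. Track-end and boundary effects on the chord are
neglected. Eight domain diameters (0.05–1 μm) are tallied by default;
moments are linearly interpolated across diameter when the requested
`2·r_d` falls between tallied sizes.

The uniform-boron reference is the volume-fraction-weighted mixture of the
three compartment tallies, so `f_n R_n + f_c R_c + f_e R_e = 1` is an
algebraic identity at every node — the basis of the κ = 1 benchmark.

Statistics: the boron history budget adapts per node — compartments are
re-run with a larger budget until each one's contribution to the κ
statistical error is near 1% (64k-history cap), mirroring the <1%
statistical-quality convention for the tallies.

## Moments and saturation

`z̄_n,D` is computed as the first moment of `f_n,1` (the printed form of
the defining equation); since the conventional "dose-mean" is the
second-to-first moment ratio, that ratio is computed and stored as well
(`zbar_n_M2`), so the survival stage can use either. Domain moments
`z̄_d,D = M₂/M₁`, `z̄_d,F = M₁`, and the saturation-corrected

    z̄*_d,D = z₀² ∫ (1 − e^{−(z/z₀)²}) f_d,1(z) dz / z̄_d,F

all come from the same binned density by midpoint quadrature, which makes
`z̄*_d,D ≤ z̄_d,D` exact. The saturation parameter is quoted as a lineal
energy `y₀` [keV/μm] and converted through the spherical mean chord:
`z₀ = 0.2039·y₀/(2 r_d)²` Gy (unit density); this conversion is a package
convention, not taken from any single source. With `y₀ = 10⁴ keV/μm` the
correction is numerically inert (z̄* ≡ z̄_d,D within 0.5% for all tallied
spectra), which is the convention used to treat the two as equivalent.
Defaults `r_d = 0.24 μm`, `y₀ = 125 keV/μm` (z₀ ≈ 110.7 Gy) are the SCC VII
fit values customarily used with the SMK model.

## Table and interpolation

The table stores, per grid node: `R_n, R_c, R_e` and the moment set per
boron source compartment plus per background component and domain
diameter. Serialization is a plain-text directory (long-format
`table.csv` + `meta.json` with axes, provenance, seeds, config hash).

Queries are `(S_nucl, S_nucl/S_cell, V_cell/V_total)` plus the two boron
uptake ratios (`C_cell/C_extra` or `A_cell/A_extra`, and `C_nucl/C_cyto`
or `A_nucl/A_cyto`). Interpolation is trilinear: along the
`V_cell/V_total` knot line of each of the four surrounding
`(S_nucl, ratio)` corners, then bilinear across the corners; node queries
reproduce stored values bit-for-bit. Out-of-hull queries clamp with a
warning (configurable to a hard error). Compartment weights `N_j` are
computed exactly from the query (never interpolated): under the
concentration convention the extracellular concentration is the reference,
the nuclear ratio scales nucleus vs cytoplasm, and the cell concentration
is the volume-weighted mean of the two so the user's `C_cell/C_extra` is
honored exactly — the minimal closure, since two ratios under-determine
three concentrations. Boron moments are interpolated per source
compartment and combined with the query's nucleus-dose shares
`N_j R_j / κ`, so changing the boron distribution never requires a table
rebuild.

### Interpolation accuracy (what the validation shows)

With uniform boron, κ = 1 identically at nodes; off-node deviation
measures interpolation + Monte Carlo error. On the full 512-node table at
axis-midpoint queries (extrapolating queries excluded): deviations are
≤ ~2.3% along the occupancy and `S_nucl` axes everywhere, ≤ ~3% at area-
ratio midpoints away from the 0.1–0.2 band, ~5.7% at ratio-midpoint 0.25,
and up to ~16% inside the 0.1–0.2 band — reproducible across independent
build seeds, i.e. systematic. The mechanism is the convexity of the
nuclear-localization ratio `R_n ∝ 1/f_n` at small area ratios, which
linear interpolation overestimates; the low-ratio band should be treated
as a reduced-accuracy region. Likewise, the relative disagreement between
direct simulation and interpolation for extracellular-localized boron
diverges where `R_e → 0` (large nuclei/gaps at ratio ≤ 0.25, where the
fragments physically cannot reach the nucleus); there the *absolute* κ
error is negligible but a relative metric is meaningless, so validation
points for the direct-vs-interpolated comparison are chosen where the
extracellular channel is dosimetrically non-degenerate.

## Survival and isoeffective dose

Conditional on the accumulated nucleus specific energy `z_n`, the SMK
survival kernel is
`s(z_n) = exp(−(α₀ + β₀ z̄*_d,D) z_n − β₀ z_n²)`, and `S = E[s(z_n)]` with
`z_n` a compound Poisson sum of single events (rate `D/z̄_n,F`). Two
evaluation paths:

* `survival_mc` — direct compound-Poisson simulation from `f_n,1`
  (reference; mixed fields mix per-component densities by event rate);
* `survival_moment` — a second-order expansion usable when only summary
  moments are available (the table's situation):
  `−ln S = A D + β₀ D² + β₀σ² − ½(A + 2β₀D)² σ²` with
  `A = α₀ + β₀ z̄*` and `σ² = z̄_n,D·D` (the compound-Poisson variance).
  It is exact at zero variance (the deterministic MK closed form) and
  raises an error outside its validity region (−ln S < 0) instead of
  returning a wrong number. Against the MC reference it agrees within 5%
  on −ln S over the small-variance regime exercised in the tests.

Mixed-field moments are dose-weighted over the components' nucleus doses;
the boron nucleus dose is `(κ_intra + κ_extra) · D_B`; N, H, γ are uniform
at cell scale (κ ≡ 1). `D_isoE = −ln S/(α + βX)` is the total reference
photon dose delivered in X-Gy fractions with equal survival. Defaults
(α₀ = 0.0422 Gy⁻¹, β₀ = 0.00822 Gy⁻², α = 0.0633 Gy⁻¹, β = 0.00822 Gy⁻²,
X = 2 Gy) are the customary SCC VII / reference-photon values; X is a user
choice.

Weighted doses use fixed CBE/RBE factors (tumor: 3.8/2.5/2.5/2.5 for
B/N/H/γ; skin: 2.5/2.5/2.5/1). Depth profiles are normalized so the
weighted skin dose at the surface reaches 12 Gy-Eq with 20 ppm blood boron
and a 1.1 skin-to-blood ratio (22 ppm skin).

## Synthetic field

The depth-dose generator emulates an epithermal beam on a tissue phantom:
thermal-driven components (B per ppm, N) follow
`A(1 − 0.9 e^{−z/1.4}) e^{−z/5}` (cm), peaking at 2 cm with a
peak-to-surface ratio ≈ 3.5–5; γ has a softer buildup and 8 cm attenuation;
H decays with 6 cm. The per-ppm boron amplitude is set so that at tens of
ppm the boron component dominates the weighted tumor dose at the thermal
peak, as in clinical fields. What it does **not** emulate: any specific
reactor or accelerator spectrum, beam-size/scatter effects, or absolute
normalization chains — so absolute D_isoE values computed from it are
illustrative, and only internal-consistency and sensitivity-shape
conclusions transfer to real fields. Real depth-dose tables from any
transport code can be supplied as CSV
(`depth_cm, dose_B_per_ppm, dose_N, dose_H, dose_gamma`).

## Problem sizes used in the shipped checks

The test suite builds a 2×3×4-node table with all components (reduced
histories) for pipeline checks and the full 512-node boron-only table at
4 000 base histories per compartment for the interpolation and sensitivity
checks; the acceptance script rebuilds the full boron-only table the same
way and runs four 48 000-history direct validation simulations. These
budgets give per-node κ statistical errors near 1%; production tables
(all components, eight domain diameters, larger budgets) take
proportionally longer.

## Known limitations

* Straight amorphous tracks without straggling slightly sharpen the
  localization structure (R ratios, domain spectra) relative to a full
  transport engine.
* The H and γ source spectra are placeholders (configuration, not
  physics).
* `z̄_n,D` follows the printed first-moment definition; users wanting the
  conventional dose-mean nucleus moment should read `zbar_n_M2`.
* The table freezes `y₀` and the domain-diameter set at build time;
  querying a different `y₀` requires a rebuild (the uncorrected `z̄_d,D`
  is always available).
* Relative validation of κ for extracellular boron is meaningless in the
  `R_e → 0` corner (see above); interpolation in the area-ratio band
  0.1–0.2 carries up to ~16–20% κ error for nucleus-localized boron.
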