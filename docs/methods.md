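# Methods

## The block WSME ensemble

The model treats each block of `block_length = 3` consecutive residues as a
binary folding unit and restricts the ensemble to microstates with at most
two contiguous folded islands: the fully unfolded state, all
single-sequence states, and all double-sequence states, the latter counted
twice — once with the islands independent and once with native interactions
across the gap switched on. The count is exactly
`2·C(n+1,4) + C(n+1,2) + 1` for `n` blocks; the enumerator streams states in
a fixed lexicographic order (island-1 start/end, island-2 start/end,
non-interacting before interacting) so state indexing is reproducible, and
the closed form and the stream are cross-checked in the tests for every
`n ≤ 60`.

Blocking uses floor division with the remainder merged into the terminal
block; an explicit boundary list (`BlockScheme.from_boundaries`) reproduces
any reference blocking, since the residue window that yields a particular
published block count for a real structure is generally not recoverable
from the chain length alone. Reproduction of residue-resolved landscape
figures for the real protein is therefore qualitative (the pattern of
early-folding regions), not bit-exact.

## Energy function

Relative to the fully unfolded reference (ΔF = 0 by construction),

    ΔF = Σ_active n_ij·[ξ + ΔCp·((T − T_ref) − T·ln(T/T_ref))]
       + Σ_active E_elec(i, j)
       − T·Σ_folded ΔS(r)

* **Contacts.** `n_ij` counts heavy-atom pairs within 6 Å between residues
  separated by at least `min_separation = 2` positions (i, i+1 covalent
  neighbors excluded — standard WSME practice). ξ multiplies the atomic
  contact count, not the residue pair; per-contact magnitudes of tens of
  J mol⁻¹ for an all-atom map only make sense on that convention. A
  `per_pair_xi` switch applies ξ once per residue pair instead.
* **Solvation.** ΔCp = −0.36 J mol⁻¹ K⁻¹ per atomic contact with reference
  temperature `T_ref = 385 K` (the standard value in this model lineage;
  the term vanishes identically at `T = T_ref`, which is tested).
* **Electrostatics.** Screened Coulomb
  `332.0637·q_i·q_j/(ε_eff·r_ij)·exp(−κ·r_ij)` kcal mol⁻¹ (converted to
  J mol⁻¹) between charged-group centroids (Asp/Glu −1, Lys/Arg +1, His
  configurable, termini optional), `ε_eff = 29`, κ from the Debye
  expression at ionic strength 0.1 M and the run temperature. The term is
  applied "all-to-all" among charged pairs, but only when both residues are
  structured and island-connected under the same rule as contacts — this
  keeps the unfolded reference at exactly zero.
* **Entropy.** ΔS_conf = −13.6 J mol⁻¹ K⁻¹ per folded residue;
  residues in a metal-binding loop whose metal is absent pay
  ΔS_loop = −19.7 J mol⁻¹ K⁻¹ instead; prolines pay zero. The four
  variants are pure entropy maps: holo orders both loops, `zn_bound` the
  Zn loop only, `cu_bound` the Cu loop only, apo neither. For SOD1 the
  loops are residues 49–82 (Zn, loop IV) and 121–142 (Cu, loop VII); an
  alternative published delimitation of loop IV (58–83) exists, and the
  49–82 convention used by the model is adopted here.

A contact or charge pair is *active* iff both residues lie in folded
blocks of the same island, or of two islands in an interacting
double-sequence state.

## Accumulation and observables

Weights `exp(−ΔF/RT)` are accumulated strictly in log space
(`R = 8.314 J mol⁻¹ K⁻¹`). Per-state energies are evaluated vectorized via
a symmetric block-pair interaction matrix and its 2-D prefix sums (O(1) per
state after precomputation); the tests pin this machinery against a fully
independent term-by-term direct summation over contacts, charges, and
residues at relative 1e-12 for every system with ≤ 6 blocks.

Observables: per-residue folding probability `P_fold(r)`; the free-energy
profile `F(n) = −RT·ln Σ_{states with n folded blocks} w`; and the
conditional matrix `P(residue folded | n folded blocks)`. The invariants
`0 ≤ P ≤ 1` and `Σ_n exp(−F(n)/RT) = Z` are tested directly.

**Stability** splits the profile at its highest interior maximum; a point
is treated as a barrier only if it exceeds both end states, otherwise the
end-state difference `F(0) − F(n_max)` is used (logged). Basin free
energies are log-sum-exp aggregates, not single minima.

**Calibration** bisects ξ deterministically until the stability matches the
target (25 kJ mol⁻¹ at 298 K by default) within 1 J mol⁻¹. The default
bracket is (−12,000, 0) J mol⁻¹: Cα-only toy structures carry roughly one
atomic contact per residue pair, so their per-contact ξ is ~50× the
all-atom scale. The bracket is validated for a sign change and the error
message suggests widening it otherwise.

## The toy two-loop structure

`synthetic_data.toy_structure("two_loop_protein")` is a 60-residue
serpentine β-meander: six antiparallel rows of ten residues, rows 4.8 Å
apart, every residue in contact with the adjacent rows. Rows 3–4
(residues 21–40) are the designated "Zn loop" with a pseudo-Zn site packed
against them; row 6 (residues 51–60) is the "Cu loop" with a pseudo-Cu
site. The design constraints were: (i) no contact-free segments — dead
regions cost entropy without energy and carve deep intermediate basins
into F(n), making stability discontinuous in ξ; (ii) the Zn loop interior
(two stacking interfaces) is the natural contact-density maximum, so the
ordered variants nucleate folding there; (iii) the Zn loop is twice the Cu
loop's size, mirroring the real protein's loop IV vs loop VII asymmetry,
which is what makes the calibrated |ξ| ordering
holo < Zn-bound < Cu-bound < apo meaningful.

On this structure the variant schemes reproduce the qualitative mechanism
switch: holo and Zn-bound fold the Zn-loop rows first, Cu-bound and apo
nucleate in the N-terminal core. "Early-folding region" is operationalized
as the top 30 % of residues by conditional folding probability at
`n = round(0.25·n_blocks)` structured blocks, compared across variants by
Jaccard overlap. These fractions are reporting conventions, not fitted
quantities; the switch is robust to moderate changes in either.

## Assay fits

All fits use deterministic initial guesses from data quantiles (no random
restarts), so results are bit-reproducible. Nonlinear least squares is
delegated to lmfit/scipy.

* **Stern–Volmer** — ordinary least squares of I₀/I vs [Q]; the intercept
  is reported as a diagnostic even though the model fixes it at 1.
  Reported ratios K_sv/K_svm are rounded to 2 decimals alongside the raw
  value.
* **Two-state unfolding** — the standard two-state form with linear
  baselines and exponent `(ΔG⁰ − m·x)/0.5826` (kcal mol⁻¹; the denominator
  constant is kept fixed at the conventional printed value). ΔG⁰, m > 0;
  `Cm = ΔG⁰/m`. The fitted curve at `x = Cm` equals the mean of the two
  baselines, which is tested. The published form of this equation contains
  an internally inconsistent unfolded baseline term; the standard form that
  reproduces its intended limits is implemented.
* **Calcein release** — `100·(I_F − I_B)/(I_T − I_B)`, affine-invariant in
  the intensities (property-tested); the leakage time course is fit to a
  single-exponential growth, rate in s⁻¹ (the time-domain unit; one
  published mention of cm⁻¹ for this rate is a typographical slip).
* **FCS** — 3-D diffusion autocorrelation
  `G(τ) = 1 + (1/N)·Σ f_i·(1+τ/τ_Di)⁻¹·(1+τ/(S²τ_Di))^(−1/2)` with the
  structure parameter S the depth-to-diameter ratio of the observation
  volume; one or two components sharing one N and one S, Σf_i = 1
  enforced. Components closer than 3× in τ_D trigger an identifiability
  warning. `τ_D = ω²/4D` and Stokes–Einstein convert diffusion times to
  radii; the radius→τ_D→radius round-trip is exact to 1e-12.
* **Binding isotherm** — Hill form `100·(K_a·L)^h/(1+(K_a·L)^h)` with
  h ∈ [0.5, 4] free; K_a is defined as 1/L_half at the fitted h (the
  sigmoid family and K_a definition are not uniquely determined by the
  source description; this is the package's convention).
* **ThT kinetics** — Boltzmann sigmoid; `lag = t50 − 2τ`. A trace is "Not
  detectable" when the fitted amplitude is below 3× the standard deviation
  of the first 10 % of points (configurable); detectability is monotone in
  amplitude (tested).
* **GUV deformation** — I_ptp(t) is the max-minus-min of each line profile
  averaged over lines (≥ 3 recommended); λ comes from a sigmoidal-decay
  fit. Flat stacks give λ = 0.
* **FTIR amide-I deconvolution** — Savitzky–Golay second derivative
  (window 13 points, polyorder 3) over 1600–1700 cm⁻¹; minima passing a
  5 % depth filter inside 1615–1690 cm⁻¹ seed a Gaussian mixture whose
  centers may move ±4 cm⁻¹; areas pool into β-sheet (1627–1641), α-helix
  (1648–1660), and disorder + turns/loops (1641–1648 and 1660–1680)
  percentages summing to 100 ± 0.5.

## Synthetic data

Every assay generator draws exactly from its fit model plus Gaussian noise;
a manifest (truth, noise, n, seed) accompanies every dataset, and identical
specs are byte-identical. Defaults are the reported study values where
available: WT K_sv 6.8 M⁻¹, apo ThT midpoint 112.8 h, binding K_a
4.1×10⁶ M⁻¹, GUV λ 1.8×10⁻³ s⁻¹, free-monomer r_H 13.5 Å (as the fast FCS
τ_D at ω = 0.3 µm), amide-I area shares 38/10/52 (β/helix/other).

Two generator parameters were set by explicit calibration rather than
published values: the unfolding melt grid (40 points over 0–6 M, chosen so
that the documented 2 % Cm recovery tolerance sits at the Monte-Carlo 95 %
quantile at σ = 0.01) and the amide-I component width (σ = 3 cm⁻¹, FWHM
≈ 7 cm⁻¹ — a realistic component width; much wider bands are not
second-derivative-resolvable even without noise, which would contradict the
peak-picking procedure the pipeline implements). Monte-Carlo coverage at
the documented tolerances (60–80 replicates per assay): Stern–Volmer,
FCS, ThT, GUV, FTIR, leakage ≥ 99 %; unfolding 93 %; binding 95 %.

What the generators deliberately do **not** emulate: photon shot noise and
afterpulsing in FCS, instrument drift and baseline curvature in FTIR,
vesicle-to-vesicle heterogeneity in GUV imaging, secondary nucleation
deviations from a single sigmoid in ThT. Passing recovery tests therefore
demonstrates correct model inversion at realistic noise, not robustness to
every artifact of real instruments.

## Correlation stage

The packaged mutant table (17 rows: 15 ALS disease mutants plus the two
single-metal mimics) carries mutation-site distances to the Zn and Cu
centers and water-to-bilayer transfer energies; transfer energies are
consumed as given (their computation is a membrane-positioning calculation
outside this package's scope). The distance atom convention behind the
published table is unstated; `metal_distance` defaults to the minimum
heavy-atom distance (the only convention compatible with the table's
shortest entries) with a Cα alternative, and the packaged distances are
treated as data, not as regression targets for the geometry code. Survival
times are packaged only for the three mutants whose values are stated in
the source narrative (G37R 17 y, G85R 6 y, I113T 4.3 y); the full
literature series is user-suppliable. Trends are ordinary least squares
with Pearson r; the two-sided p-value is reported but never used as a
pass/fail gate (n is small), and the headline claims are validated as
signs and orderings, not as printed regression statistics (none are
available).

## Problem sizes and determinism

The full 49-block enumeration (461,826 states) runs in well under a second;
ensembles are computed exactly (never sampled), so the only stochastic
elements anywhere are the synthetic-noise draws, all seeded. Test-suite
landscape work uses the 20-block toy (12,181 states) for which exhaustive
cross-checks are instantaneous; oracle-equivalence tests use ≤ 6-block
systems where the brute-force state list is enumerable.

## Known limitations

* Single-chain, monomer-only: no dimerization, no inter-chain contacts.
* No kinetics: the landscape yields mechanism and stability, not rates.
* Residue-level (non-block) mode exists only as the counting formula.
* mmCIF, insertion codes, and multi-model averaging are unsupported
  (first model used, insertion codes rejected loudly).
* The electrostatics parameters (ε_eff, ionic strength) are model-lineage
  defaults, not fitted to any dataset in this package.
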