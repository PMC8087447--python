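# sodscape

Statistical-mechanical folding landscapes of Cu/Zn superoxide dismutase
(SOD1) metal-occupancy variants, together with the curve-fitting machinery
for the membrane-association and aggregation assays used to probe them, and
a correlation stage linking mutation geometry to membrane binding and ALS
disease severity.

SOD1 aggregation is implicated in amyotrophic lateral sclerosis (ALS). The
package is aimed at structural biophysicists who want to explore, on desk
scale, the hypothesis that losing the **Zn** cofactor (but not Cu)
destabilizes the metal-binding loops, reroutes the folding mechanism through
aggregation-prone partially folded states, and drives membrane-mediated
toxicity.

## The model

The core is a **block Wako–Saitô–Muñoz–Eaton (bWSME)** model. Each block of
3 consecutive residues is folded (1) or unfolded (0), and the ensemble is
restricted to microstates with at most two folded islands — the
single-sequence approximation, the double-sequence approximation (DSA), and
DSA with cross-island interactions, each two-island configuration counted
in both a non-interacting and an interacting variant. The ensemble size is

    N(n) = 2·C(n+1, 4) + C(n+1, 2) + 1

which is 461,826 for a 49-block chain versus 42,759,577 (> 42.7 million) at
the residue level for 151 residues.

The free energy of a microstate relative to the fully unfolded state is

    ΔF = Σ_active n_ij·[ξ + ΔCp·((T − T_ref) − T·ln(T/T_ref))]
       + Σ_active screened-Coulomb(q_i, q_j, r_ij)
       − T·Σ_folded ΔS(residue)

with `n_ij` the heavy-atom contact count at a 6 Å cutoff, ξ the mean van der
Waals energy per atomic contact, ΔCp = −0.36 J mol⁻¹ K⁻¹ per contact,
ΔS_conf = −13.6 J mol⁻¹ K⁻¹ per folded residue, and Debye–Hückel screened
electrostatics between charged-group centroids. Metal occupancy enters only
through entropy: the Zn-binding loop (residues 49–82) and the Cu-binding
loop (121–142) pay an excess penalty of −19.7 J mol⁻¹ K⁻¹ per residue when
their metal is absent (holo: neither loop; Zn-bound: Cu loop only;
Cu-bound: Zn loop only; apo: both). Prolines pay zero. Iso-stability
calibration bisects ξ per variant until the folded basin is 25 kJ mol⁻¹
more stable than the unfolded basin at 298 K, so variants differ only in
mechanism, not stability.

Around the model sit the assay fits (Stern–Volmer quenching, two-state
GdmCl melts, calcein leakage, FCS diffusion with Stokes–Einstein radii,
Hill binding isotherms, ThT aggregation sigmoids, GUV peak-to-peak
deformation decay, amide-I FTIR Gaussian deconvolution), a synthetic-data
module that draws every assay trace from its fit model with stated noise
and seeds, and a correlation stage joining mutation-site-to-metal distances
with membrane transfer energies and patient survival times.

## Worked example

Calibrated landscapes for all four variants on the packaged toy two-loop
structure (a 60-residue serpentine meander with designated Zn/Cu loops):

```
$ sodscape landscape --out run/
{
  "xi": {"holo": -1970.7, "zn_bound": -2071.2,
         "cu_bound": -2253.6, "apo": -2371.2},
  "stability_J_mol": {"holo": 24999.3, "zn_bound": 24999.8,
                      "cu_bound": 25001.0, "apo": 24999.7},
  "overlap_with_holo": {"holo": 1.0, "zn_bound": 0.5,
                        "cu_bound": 0.0, "apo": 0.091},
  "apo_pathway_differs_from_holo": true, ...
}
```

Every variant hits the 25 kJ mol⁻¹ iso-stability target, and |ξ| grows
strictly with the entropy a variant must pay (holo < Zn-bound < Cu-bound <
apo), mirroring the ordering of the published all-atom parameterization.
The early-folding region (top residues by conditional folding probability a
quarter of the way along the reaction coordinate) shows the mechanism
switch: the holo and Zn-bound proteins nucleate in the Zn loop (Jaccard
overlap 0.5), while the Cu-bound and apo proteins reroute through the
N-terminal core (overlap 0.0 and 0.09) — losing Zn, not Cu, changes how the
protein folds.

The correlation stage on the packaged 17-mutant table:

```
$ sodscape correlate
{
  "zn_distance_vs_dG": {"pearson_r": 0.613, "slope": 0.069, "n": 17, ...},
  "cu_distance_vs_dG": {"pearson_r": -0.004, ...},
  "zn_distance_vs_survival": {"slope": 0.735, "pearson_r": 0.805, "n": 3},
  "zn_dominates_cu": true
}
```

Membrane binding weakens linearly with distance from the Zn center
(r = +0.61: mutations near Zn bind membranes most strongly), is flat in the
Cu distance (r ≈ 0), and patient survival lengthens with Zn distance
(+0.73 years per Å across the three mutants with packaged survival times).

Synthetic assay data and fits:

```
$ sodscape simulate tht --param t50=90.8 --seed 7 --out tht.csv
$ sodscape fit tht tht.csv
{"t50_h": 91.1, "lag_h": 73.8, "label": "91.1"}
```

## Layout

- `sodscape.structure_contacts` — PDB parsing (gemmi), heavy-atom contact
  maps, charge assignment, metal distances.
- `sodscape.bwsme_engine` — microstate enumeration/counting, free energies,
  log-space partition-function accumulation, stability, ξ calibration.
- `sodscape.assay_fits` — all assay fitting equations and FTIR processing.
- `sodscape.correlations` — packaged mutant table, OLS/Pearson trends,
  survival joins.
- `sodscape.synthetic_data` — toy structures and seeded assay generators.
- `sodscape.workflow` / `sodscape.cli` — run orchestration and the
  `sodscape` command.
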