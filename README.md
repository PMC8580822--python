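# gpcrstates

Comparative structural analysis of G-protein-coupled receptor (GPCR)
activation across the four structurally covered classes (A, B1, C, F).

GPCRs switch between inactive and active conformations of a common
seven-transmembrane-helix (7TM) scaffold. Given an annotated corpus of
receptor structures, this package answers, at two scales, *what holds a
receptor in one state*:

* **Helix "macroswitches"** — for each receptor with an inactive and an
  active structure, every helix TM1–TM7 is measured at its extracellular
  end, membrane mid and cytosolic end: rigid-body translation (Å) of the
  region's Cα centroid after a mid-membrane core superposition, and
  rotation (°) about the local helix axis after removing axis tilt.
* **Residue "microswitches"** — typed residue–residue contacts (van der
  Waals, hydrophobic, hydrogen bond, ionic, aromatic) are detected per
  structure and keyed by generic residue numbers (`3x50` is the reference
  position 50 of TM3, `45x51` sits in ECL2). Per class, the contact
  frequency of a generic pair is compared between the inactive and active
  representative ensembles:

  ```
  f_state(pair) = 100 · (# templates forming the contact) /
                        (# templates with both positions resolved)
  ```

  Pairs whose frequency difference `f_inactive − f_active` reaches the
  class threshold (A 40, B1 67, C 75, F 100 percentage points, matching
  each class's structural coverage) are *state-specific*; a conservation
  cut-off then requires the observed amino-acid pairs in ≥ 30 % of the
  class's receptors. Positions are classified as **inactivators**
  (inactive-state contacts only), **activators** (active only) or
  **switches** (both), and overlaid on ligand- and G-protein-interacting
  positions.

Upstream of both analyses, a representative inactive/active template per
receptor is selected from an annotation catalog by quality filters
(receptor/G-protein completeness ≥ 83 %/≥ 43 %, sequence identity > 90 %
to human, resolution ≤ 3.6 Å, degree-active ≤ 20 % or ≥ 90 %, modality
consistency, G-protein complex required for active templates). A
two-group exact Wilcoxon rank-sum module compares potency/efficacy shifts
(Δlog EC50, ΔEmax) of predicted state-changing versus nonstate-changing
mutants.

Every stage has a synthetic-data generator (`gpcrstates.fixture_factory`)
producing ideal helical bundles with imposed inter-state motions,
contact ensembles with programmed frequencies, alignments with programmed
conservation, an annotation catalog straddling every filter boundary, and
two-group mutant tables with known shifts — so each computation can be
verified against exact ground truth.

## Worked example

Measure a 7 Å cytosolic TM6 opening with a 38° axial rotation — the
hallmark of receptor activation — on a synthetic receptor pair:

```python
from gpcrstates.fixture_factory import (BundleSpec, apply_motion,
    make_ideal_bundle, motion_with_measured_translation, make_mutant_table)
from gpcrstates.helix_geometry import (superpose_pair, region_translation,
    region_rotation)
from gpcrstates.mutation_stats import compare_groups

bundle = make_ideal_bundle(BundleSpec())
motion = motion_with_measured_translation(bundle, "TM6", "ic_end",
                                          7.0, rotation_deg=38.0)
pair = superpose_pair(bundle, apply_motion(bundle, motion), receptor="demo")
print("core RMSD (A):", round(pair.rmsd, 3))
for region in ("ec_end", "mid", "ic_end"):
    print(f"TM6 {region}: translation = "
          f"{region_translation(pair, 'TM6', region):.2f} A, rotation = "
          f"{region_rotation(pair, 'TM6', region):.1f} deg")

gs = compare_groups(make_mutant_table(seed=0))["Gs"]
print("Gs potency shift (state-changing vs nonstate):",
      round(gs.mean_delta_log_ec50["state_changing"], 2), "vs",
      round(gs.mean_delta_log_ec50["nonstate_changing"], 2),
      "p =", round(gs.p_potency, 4))
```

prints

```
core RMSD (A): 0.0
TM6 ec_end: translation = 0.00 A, rotation = -0.0 deg
TM6 mid: translation = 0.00 A, rotation = 0.0 deg
TM6 ic_end: translation = 7.00 A, rotation = 38.0 deg
Gs potency shift (state-changing vs nonstate): 1.07 vs 0.22 p = 0.0195
```

The superposition core (mid-membrane Cα of the static helices) is exact,
the imposed motion is recovered only where it was imposed, and the mutant
comparison shows state-changing positions losing ~1 log unit of agonist
potency where control positions do not (exact rank-sum test, n = 6 + 6).

A command-line interface wraps the same stages:

```sh
gpcrstates fixtures --out fx          # write synthetic inputs
gpcrstates select fx/annotation_catalog.tsv --out sel
gpcrstates mutstats fx/mutant_table.tsv --out mutstats.tsv
gpcrstates run-all --out run --seed 1 # end-to-end on synthetic inputs
```

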