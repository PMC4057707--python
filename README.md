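# seventm

α-bulge detection and activation-motion analysis for seven-transmembrane
(7TM) helix bundles — the Class A G protein-coupled receptor (GPCR) fold.

## The problem

The transmembrane helices of Class A GPCRs are far from ideal α-helices:
many carry **α-bulges** — local widenings in which one extra residue is
accommodated, switching the hydrogen bonding from the α-helical
CO(i)→NH(i+4) pattern to the π-helical CO(i)→NH(i+5) pattern.  Bulges
cluster near the ligand-binding site (helices II and V), appear or
disappear during activation, and break the textbook assumption that
helices contain no insertions or deletions.  Activation itself involves a
characteristic set of motions: the cytosolic end of helix VI swings
outward (a rotation of the *entire* helix, not a kink), and helix III
slides toward the extracellular side.

`seventm` packages the computational side of that analysis for anyone
comparing ensembles of receptor structures:

* **Secondary structure with π preference** — a Kabsch–Sander
  hydrogen-bond assignment in which the electrostatic bond energy is

  ```
  E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol
  ```

  with a bond below −0.5 kcal/mol, and overlapping π (I) and α (H)
  patterns resolve to π.  A maximal I run inside a TM helix is an α-bulge;
  `bulge_census` tabulates them per structure per helix (TM1…TM7).
* **Superposition** — closed-form Kabsch fits (global, per-helix, and a
  bulge-aware variant that excludes residues inside a bulge present in
  only one partner), helix-axis fitting, and whole-helix rotation angles.
* **Distance features** — for n residues common to all structures (shared
  GPCRDB-style generic numbers, helix×100+position), the n(n−1)/2 pairwise
  Cα distances per structure; redundant features are pruned by iteratively
  removing one member of the most Pearson-correlated pair (seeded) until
  no correlation exceeds 0.90.
* **Random-forest ranking** — a 1000-tree forest (scikit-learn) separates
  user-defined structure classes; features are ranked by Gini importance
  (mean decrease in impurity) and annotated with their direction of change
  from raw class means, exportable as a PyMOL vector script.
* **Synthetic data** — ideal-geometry 7-helix bundles built from internal
  coordinates, with planted π-bulges and planted activation motions, so
  every step of the pipeline can be validated against known ground truth.

## Worked example

```python
from seventm import (BundleSpec, HelixSpec, ActivationSpec, simulate_ensemble,
                     bundle_segments, bulge_census, build_bundle,
                     local_helix_superpose, helix_rotation_angle,
                     common_residues, build_feature_table, prune_correlated,
                     PruneConfig, ActivationForest, RFConfig)

# a rhodopsin-like bundle: alpha-bulges planted mid-helix in TM2 and TM5
spec = BundleSpec(tuple(
    HelixSpec(n_residues=29, bulge_positions=(14,) if h in (2, 5) else ())
    for h in range(1, 8)), noise_sd=0.05, seed=0)
bundle = build_bundle(spec, "demo")
segments = bundle_segments(spec)
print(bulge_census([bundle], segments))

# a two-class ensemble with the activation motions planted
spec = BundleSpec(tuple(HelixSpec(n_residues=12) for _ in range(7)),
                  noise_sd=0.1, seed=0)
structures, labels, truth = simulate_ensemble(
    spec, ActivationSpec(tm6_rotation_deg=30.0, tm3_translation_A=1.0),
    n_per_class=8, seed=11)
segments = bundle_segments(spec)

inactive, active = structures[0], structures[8]
tm6 = local_helix_superpose(inactive, active, "TM6", segments)
print(f"TM6 local RMSD: {tm6.rmsd:.2f} A over {tm6.n_atoms} Calpha")
print(f"TM6 rotation:   {helix_rotation_angle(inactive, active, 'TM6', segments):.1f} deg")

residues = common_residues(structures)
table = build_feature_table(structures, residues)
pruned, log = prune_correlated(table, PruneConfig(threshold=0.90, seed=1))
print(f"features: {table.n_features} -> {pruned.n_features} after pruning")
report = ActivationForest(pruned, labels).fit(RFConfig(n_trees=1000, seed=1))
print(f"OOB error: {report.oob_error:.3f}")
print(report.summary().head(5).to_string(index=False))
```

Output:

```
      TM1  TM2  TM3  TM4  TM5  TM6  TM7
demo    0    1    0    0    1    0    0
TM6 local RMSD: 0.23 A over 12 Calpha
TM6 rotation:   28.7 deg
features: 3486 -> 2384 after pruning
OOB error: 0.000
   pair  gini_importance direction  mean_diff_A  negligible
306-512         0.013000 increases     0.460612       False
411-604         0.013000 increases     0.375601       False
308-503         0.012222 decreases    -0.561436       False
302-404         0.012000 increases     0.754068       False
104-308         0.011000 decreases    -0.333666       False
```

Reading the numbers: the census row reproduces the planted bulge pattern
(one bulge each in TM2 and TM5, none elsewhere).  In the activation
ensemble, the whole of helix VI superposes onto its rotated counterpart
at 0.23 Å — the helix moved rigidly — while the measured rotation is the
planted ~30°.  The forest separates the classes perfectly (OOB error 0)
and every top-ranked distance involves a residue from helix III (3xx) or
helix VI (6xx), the two helices that were actually moved; distances from
helix VI to its neighbours *increase* (the outward swing), and several
helix III distances *decrease* (the extracellular slide).

The same pipeline runs from the shell on real coordinate files
(`seventm census`, `seventm superpose`, `seventm run-all …`) given a
generic-number mapping TSV and, optionally, a TM segment table; a
reconstruction of typical Class A segment ranges ships as the default
(`seventm.default_segments()`).

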