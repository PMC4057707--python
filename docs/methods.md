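# Methods

This note records the models and procedures `seventm` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Secondary structure and α-bulges

Assignment follows the Kabsch–Sander scheme.  The amide hydrogen of
residue i is placed 1.0 Å from N(i) along the unit vector from O(i−1) to
C(i−1); prolines and fragment-initial residues have no donor hydrogen.
Every NH···OC contact with Cα separation under 9 Å and chain separation
≥ 2 is scored with the partial-charge electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, clamped at
−9.9; a hydrogen bond exists below −0.5 kcal/mol.  Each NH keeps its two
best acceptors, and those stored bonds define all patterns.  An n-turn at
i (n ∈ {3, 4, 5}) is the bond CO(i)→NH(i+n); two consecutive n-turns make
a minimal helix covering residues i…i+n−1.  Bridges follow the classic
parallel/antiparallel patterns (E in ladders of length ≥ 2, B isolated);
T marks loop residues inside any single turn span; S marks bends where
the virtual-bond angle Cα(i−2)–Cα(i)–Cα(i+2) exceeds 70°.

The one deliberate departure from the classic priority order is the **π
preference**: where 5-turn and 4-turn patterns overlap, the π code I wins
over H (G and I runs otherwise only claim spans whose residues are still
free, the classic rule).  This flip is the mechanism that makes α-bulges
— helix widenings with i→i+5 bonding — visible as I runs instead of being
swallowed by surrounding H.  With `pi_priority=False` the classic
ordering is restored; on the test battery of generated fixtures the
package then — and, as it turns out, also with the preference enabled —
agrees per-residue with mdtraj's independently implemented DSSP (which
itself prefers π over α) at 100%, comfortably above the 99.9% concordance
asserted in the tests.

An **α-bulge record** is a maximal I run whose first residue's generic
number falls inside a TM segment; a run straddling a segment boundary
counts for the segment containing its start.  The census tabulates run
counts per structure per helix TM1…TM7.  3₁₀ (G) runs are tabulated by a
parallel function but never folded into the bulge count.

Chain breaks are declared where the C(i)→N(i+1) distance exceeds 2.5 Å (a
peptide bond is ~1.33 Å); no hydrogen placement, turn or bridge pattern
crosses a break.

## Numbering, segments, pairing

All cross-structure pairing is by GPCRDB-style generic numbers
(helix×100 + position), never by sequence alignment: the numbering scheme
exists precisely so homologous residues share numbers.  Author numbering
is preserved verbatim (1-based, insertion codes kept); internal sequence
indices are 0-based.  Structure reading keeps amino-acid residues only,
resolves alternate locations to the highest-occupancy conformer (ties:
first in file order), maps modified standard residues (MSE…) to their
parent amino acid and drops other non-standard residues with a warning.

No authoritative TM boundary list exists for the common-residue set, so
the shipped default segment table is a documented reconstruction anchored
on conserved landmarks (DRY 339–341 at the cytosolic end of TM3, P520 in
TM5, W618/P620 in TM6, the NPxxY motif ending at 733 in TM7); users with
their own boundary definitions supply a TSV.  Synthetic bundles generate
their own exact segment table.

## Superposition and rotation

Rigid fits use the closed-form Kabsch solution (SVD of the covariance,
smallest singular value sign-corrected so no reflection is returned);
collinear inputs are flagged rank-deficient.  The per-helix variant pairs
Cα atoms by generic number; with bulge skipping enabled, bulges are
detected in both partners and residues inside a bulge present in only one
(two bulges are "shared" when their generic ranges overlap) are excluded
from the pairing, preventing a widening in one structure from inflating
or misregistering the fit.

Helix axes are the principal component of the Cα cloud, sign-fixed from
first to last residue so angles are well defined; a fit needs ≥ 5
residues.  The rotation angle between two structures is measured after a
global superposition over all shared Cα (the caller may instead supply a
transform, e.g. the identity when both structures already live in a
common frame, as synthetic ensembles do).  "Cytosolic half" is the half
of the shared residues nearer the cytosolic terminus by generic number
(rounded down); the cytosolic end is the high-numbered end for odd
helices and the low-numbered end for even ones, following the topology in
which the N-terminus is extracellular.  Note that a global fit absorbs
part of a single-helix motion — with one helix of seven rotated 30°, the
internally fitted angle reads ~2–3° low; the known-frame measurement
recovers the planted angle exactly.

## Distance features and pruning

For n common residues, all n(n−1)/2 unordered Cα–Cα distances per
structure, pair order lexicographic (203 residues → 20,503 features).
Pruning repeatedly finds the most correlated feature pair and removes one
member uniformly at random until the maximum Pearson correlation is at or
below the threshold (default 0.90).  Decisions taken where the procedure
was underspecified:

* **Signed r, not |r|** by default: distance vectors that co-vary
  negatively carry distinct geometric information; `absolute=True` gives
  the stricter variant.
* **Tie-break**: among equally maximal pairs, the lowest lexicographic
  pair of column indices; the member to drop is a seeded coin flip.  The
  procedure is bit-reproducible given the seed, and the survivor set is
  verified in tests against an independent brute-force re-implementation.
* Zero-variance features are removed up front with a log entry.
* The full correlation matrix is held in memory with per-column maxima
  updated incrementally — O(p²) memory, suitable up to a few tens of
  thousands of features.

Correlations are computed across the whole ensemble, not within classes.

## Forest ranking

Classification and importance are delegated to scikit-learn's
`RandomForestClassifier` (1000 trees, Gini criterion, bootstrap, seeded);
the package's contribution is the surrounding procedure — prune → fit →
Gini ranking → direction annotation → projection.  Direction of change
uses raw class means (mean(other) − mean(reference); ≥ 0 reads
"increases", with differences under 0.1 Å flagged negligible), not model
internals.  The out-of-bag error is always reported so inseparable
classes are visible; no class reweighting by default (a flag enables
balanced weights).  Multi-class problems are supported by the forest;
direction annotation is two-class only.

## Synthetic data: what it emulates, and what it does not

Backbones are grown by NeRF chain extension with standard geometry (N–Cα
1.458, Cα–C 1.525, C–N 1.329 Å; angles 111°/117°/121°; ω = 180°; carbonyl
O in the peptide plane opposite the next N).  The α dihedrals (−57°,
−47°) give a rise of ~1.5 Å/residue.  An α-bulge is planted by switching
a 5-residue window to π dihedrals (−76°, −55°) at constant residue count;
this window was calibrated once against the assignment module — the
narrower 3-residue window suggested by textbook π values produces only a
single 5-turn and is invisible to the two-consecutive-turns rule, and a
ψ of −41° none at all — and is frozen by a regression test.  Detection of
planted bulges is complete with zero false positives up to isotropic
coordinate noise of 0.15 Å (the calibrated bound used in the tests; at
that noise level rare total losses, ~0.3% of fixtures, exist in larger
seed sweeps).

Bundles place seven helices on an 11 Å ring, alternating up/down, with
generic numbers h×100+1…; the default helix length of 29 residues gives
exactly 203 numbered residues, the size of the common set the distance
analysis is designed around.  Activation ensembles rotate the whole of
TM6 about the membrane-parallel ring tangent through its midpoint (so the
cytosolic end swings radially outward; default 30°) and translate TM3
along the membrane normal toward the extracellular side (default 1 Å);
inactive and active replicates then receive independent isotropic
Gaussian noise (default 0.1 Å).  The optional proline accompanying a
planted bulge is placed where the regular helix resumes, i.e. the first
residue after the π window.

Not emulated: side chains, membrane and solvent, crystallographic
artifacts (structured anisotropic error, lattice contacts, fusion
partners), loops connecting the helices, and sequence variation.  Passing
tests therefore demonstrate that the *pipeline* recovers planted
geometric signals under isotropic noise — not that real crystallographic
ensembles are free of confounders; on real data the curation steps
(keep-ranges, mapping tables, class labels) remain the user's
responsibility.

## Problem sizes and run times

The test suite and the acceptance script run on desk-scale problems
chosen to exercise every code path: full-size 203-residue bundles for
feature counting, census and superposition; 12-residue helices (84
residues, 3,486 features) for the ensemble analyses, where pruning plus a
1000-tree forest completes in a few seconds.  The pruning implementation
handles the full 20,503-feature table if given the memory (the
correlation matrix is ~3.4 GB in double precision).

## Known limitations

* The exact rule set of the π-preferring DSSP variants differs in corner
  cases (e.g. treatment of isolated 5-turn pairs deep inside long H
  runs); the implementation is validated against mdtraj's DSSP on
  generated fixtures, not against any proprietary binary's internals.
* Bulge-skipping assumes homology-aware numbering around the bulge (the
  extra residue carries no generic number); with naive sequential
  numbering the downstream flank misregisters and no local exclusion can
  repair it — the tests demonstrate exactly this contrast.
* The whole-helix rotation measurement reports the angle between
  principal axes; it does not decompose the motion into rotation about
  the axis (roll) versus tilting of the axis.
* Sheet topology (ladder/sheet lettering, β-bulge extension) is not
  reproduced beyond E/B codes; TM analysis never consumes it.
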