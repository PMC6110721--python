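# Methods

## Scores and models

### Aggregation profiling

Aggregation-prone regions are predicted from sequence alone with an
Aggrescan-style procedure.  Each residue receives an intrinsic aggregation
propensity from a published 20-residue scale (hydrophobics and aromatics
positive — Ile 1.822, Phe 1.754, Val 1.594 — charged residues and proline
strongly negative).  A sliding window averages the propensities and assigns
the mean to the central residue; the window size is banded by sequence
length (≤ 75 aa → 5, ≤ 175 → 7, ≤ 300 → 9, longer → 11), and windows shrink
at the termini rather than padding, so terminal residues average over the
residues that exist.  A *hot spot* is a maximal run of at least five
consecutive residues whose window average exceeds the hot-spot threshold
(−0.02) and that contains no proline (an aggregation breaker).  Residues
inside hot spots are the aggregation-prone set; unknown residues (`X`) get
the scale mean as propensity but can never join a hot spot.

The profiling constants live in `saapqa.config` and can be overridden per
run; they are recorded in every run's metadata.

### Solvent accessibility

Per-atom SASA uses Shrake–Rupley point sampling (960 points per atom by
default, 1.4 Å water probe) over Chothia-style van der Waals radii
(N 1.65 Å, O 1.40 Å, S 1.85 Å, tetrahedral C 1.87 Å, carbonyl/aromatic
C 1.76 Å).  Side-chain SASA per residue sums the side-chain heavy atoms;
for glycine the Cα is counted as the side chain.  Relative side-chain
accessibility divides by a reference maximum for the residue type, taken
from the extended Ala-X-Ala tripeptide convention.  The reference table is
computed at first use by building the twenty tripeptides with the package's
own ideal-geometry builder and scoring them with the same SASA routine,
then cached; a fully extended side chain therefore scores exactly 100 % by
construction, and the exposure criterion is self-consistent across residue
types regardless of small absolute differences from other SASA programs.
Models with truncated side chains are scored from the atoms present and
flagged rather than dropped — predicted models frequently lack side-chain
atoms and silently skipping them would bias the score.

A residue counts as *surface exposed* when its relative side-chain
accessibility strictly exceeds 50 %.  Exactly 50 % counts as buried: the
defining rule enumerates only the > 50 and < 50 cases, and the gap is
closed on the conservative (buried) side.

### SAAP_p

`SAAP_p = 100 · Σ SAAP_i / AggreProne_T`, where `SAAP_i` is 1 iff residue
i is aggregation-prone *and* surface exposed.  Aggregation flags always
come from the full target sequence, not the model: positions unresolved in
the model contribute 0 to the numerator but stay in the denominator, so
incomplete models cannot hide exposed patches by omission.  When a sequence
has no hot spots at all the score is undefined and reported as such
(surveys of native structures show a few percent of proteins in this
class); undefined rows are excluded from training and summaries.  Scores
are reported to one decimal, computed at full precision.

### Secondary structure and descriptors

Three-state secondary structure comes from a reduced DSSP-style assigner:
amide hydrogens are rebuilt from the backbone (1 Å from N, anti to the
preceding carbonyl), backbone H-bonds are scored with the Kabsch–Sander
electrostatic energy (0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN), bond
if E < −0.5 kcal/mol), helices require two consecutive 3-/4-/5-turns,
strands come from parallel/antiparallel bridge patterns, and the 8 states
collapse to H/E/C.  Residues with incomplete backbones are coil;
structures with under 90 % complete backbones are rejected.  The 3-state
*fractions* used downstream are robust to the choice of assigner, which is
why a reduced assigner suffices; an external assigner can be swapped in
behind the same interface.

The regression input is a fixed-order six-vector: SAAP_p, helix fraction,
sheet fraction, loop fraction (fractions of the model's resolved residues
— the only length computable from a model alone), loop content (residue
count), and SAAP_p / loop content.  For all-helix/sheet models with zero
loop residues the ratio divides by 1 instead, keeping the feature finite;
this is recorded in output metadata.

### GDT_TS

GDT_TS is the mean over the 1/2/4/8 Å cutoffs of the maximal percentage of
Cα atoms superimposable within the cutoff.  Residues pair strictly by
author numbering (plus insertion code); the denominator is the reference
residue count, so models missing residues are penalised.  The
maximisation is approximated: least-squares (Kabsch, SVD) fits are seeded
from contiguous windows of lengths 3/5/7 (strided) and from the full
alignment, then each seed iterates fit-on-inliers → reselect inliers until
stable (≤ 20 iterations), and the best over seeds is taken.  For chains of
at most 10 residues every subset of ≥ 3 residues is seeded, making the
search exhaustive — this both bounds the heuristic's error and provides an
exactness guarantee at the scale where the test-suite oracle can verify
it.  Label noise well under one GDT unit is immaterial for forest
training.

### Quality-assessment model

A random-forest regressor with 700 trees and 2 candidate features per
split maps the descriptor vector to GDT.  Splits and folds are always at
the target level — no protein contributes models to both sides — and
target-disjointness is asserted programmatically.  Training requires at
least 50 rows; constant labels are degenerate but allowed (the forest then
predicts the constant).  Rankings sort by predicted GDT with ties broken
lexicographically by model id for reproducibility.  Evaluation reports
per-target and global Pearson correlations, AUC via the Mann–Whitney rank
statistic (ties averaged; undefined and reported as such when only one
class is present) against the label true GDT > 50, and top-k GDT loss
(best true GDT in the pool minus best true GDT among the top-k ranked).
The ROC sweeps thresholds on *predicted* GDT as the score — the standard
construction.  Target admission follows the benchmark conventions: domain
mode drops targets under 100 residues (no significant hydrophobic core) or
with under 20 % aggregation-prone sequence; whole-structure mode drops
targets under 50 or over 500 residues.

## Synthetic benchmark

The generator builds the study conditions for all quantitative tests:
20 targets, 50 models per target, chain length 120 ± 12 residues, one
seed for everything.

A reference "native" is a five-helix bundle from ideal geometry: a fully
hydrophobic central helix — the sequence-level aggregation hot spot —
surrounded by four amphipathic helices (outer axes 9.8 Å from the centre)
whose core-facing residues are mildly hydrophobic and whose solvent faces
are polar or charged, joined by proline-containing loops.  Sequence design
is retried (up to 5 deterministic attempts) until the built structure
scores SAAP_p < 30, the regime native structures occupy; failure raises
with diagnostics rather than emitting an unrepresentative reference.

Decoys come in five noise tiers (σ = 0.5, 1, 2, 4, 8 Å) with growing
unfolding fractions (0, 0.08, 0.2, 0.4, 0.65).  Unfolding randomises the
backbone torsions of a contiguous window into the extended coil basin and
re-embeds the chain from internal coordinates (extraction → edit → rebuild
is exact to machine precision), which genuinely exposes buried patches —
Cartesian noise alone changes GDT but barely changes burial.  On top,
residue-correlated Gaussian noise (iid per-residue offsets smoothed along
the chain with a 5-residue window, rescaled to marginal σ) degrades the
global fold while preserving local geometry.  True GDT labels are computed
against the reference with the package's own GDT implementation.  Pools
span true GDT from roughly 5 to 95 with means decreasing strictly across
tiers.

What the generator does *not* emulate: decoys are not energy-minimised and
have no realistic rotamers (side chains are extended templates), loops are
geometric rather than peptide-ideal, and heavy perturbation destroys
backbone H-bonding faster than in real server models, so secondary-
structure features separate quality tiers more cleanly than they would on
real decoy sets.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the burial-of-aggregation-patches signal
behaves as designed — not that the quantitative performance transfers to
CASP-scale external data, which would require bulk model downloads.

## Numerical choices

- SASA sampling: 960 points balances cost against a per-atom
  discretisation quantum of ~0.15–0.35 Å²; buried atoms carry a few quanta
  of shot noise, which the 50 % exposure cutoff renders irrelevant.
- Exposure at exactly 50 %: buried (see above).
- GDT seeds are strided (every third window by default) for speed; the
  full-alignment seed is always included, so the single-superposition
  lower bound always holds.
- Kabsch degenerate inputs (< 3 pairs, collinear sets) raise rather than
  returning an arbitrary frame.
- Random-forest determinism: a fixed seed fixes the forest; re-training on
  identical data and seed reproduces predictions bit-for-bit.
- All generator randomness derives from one integer seed via seed
  sequences; per-target and per-model streams are independent spawns.

## Problem sizes

The default study conditions (20 × 50 models of ~120 residues, 960-point
SASA, strided GDT seeding) were chosen so a complete benchmark — decoy
generation, labelling, feature computation, training and evaluation —
runs in about ten minutes on one CPU, which is the scale at which the
package's own test suite exercises it.

## Known limitations

- Aggregation profiling constants come from the published Aggrescan scale;
  parity with the Aggrescan web service on arbitrary sequences is expected
  but can only be validated against published per-protein counts.
- The SASA reference state is the package's own extended tripeptide, not
  another program's table; relative accessibilities are self-consistent
  but absolute parity with e.g. naccess output is approximate.
- The DSSP-style assigner implements the core helix/bridge patterns, not
  the full 8-state automaton (no π/3₁₀ disambiguation, no bends).
- GDT uses a heuristic search above 10 residues; it is exact on small
  chains and bounded below by the global-superposition fit, but can in
  principle undershoot the LGA optimum on adversarial cases.
- Single chains only; no mmCIF; no consensus or per-residue local quality.
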