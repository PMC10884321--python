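# Methods

## The model

The package computes a phenetic dissimilarity index over discrete anatomical
character states.  A *species profile* is a set of structures (here: twelve
intrinsic hand muscles in three groups of four — central, hypothenar,
thenar), each scored on five attributes: innervation, origin, insertion,
vascularization and the number of structures per hand.  Attribute *k* of
structure *j* in species *i* carries a relative frequency
P<sub>ijk</sub> = r<sub>v</sub>/N ∈ [0, 1], the frequency of the control
species' modal state among examined specimens.

The weighted attribute-frequency average of one structure is
PAF = P<sub>w(ij)</sub> = Σ w<sub>k</sub>·P<sub>ijk</sub> / Σ w<sub>k</sub>,
and the Comparative Anatomy Index between control *i* and comparison *i′* is
CAI<sub>ii′</sub> = |P<sub>w(ij)</sub> − P<sub>w(i′j)</sub>|.  The group
index GCAI is |mean P<sub>w(i)</sub> − mean P<sub>w(i′)</sub>| over the
m = 4 structures of a group.

**Modal-control convention.**  The control's frequencies are fixed at 1 even
where its own observation frequency is sub-modal (the capuchin lumbrical
innervation pattern was seen in 12 of 16 hands).  Every published index
value is consistent only with this convention; the raw r<sub>v</sub>/N is
kept as metadata on the state.  A consequence is that all signed differences
share one sign, so the GCAI group formula coincides exactly with the
arithmetic mean of member CAIs (asserted for all packaged comparisons).

## Weights

w = (3, 2, 2, 1, 1) in attribute order.  Innervation is the most
phylogenetically conserved character and carries the most weight; origin and
insertion are intermediate; vascularization and count vary most and carry
the least.  The index is invariant to rescaling all weights by a positive
constant (property-tested).  `WeightScheme` accepts any positive weights.

## Deviation rules

Comparison-species frequencies are expressed as deviations
d<sub>k</sub> = 1 − P<sub>i′jk</sub>:

* **Component attributes** (innervation, origin, insertion): component
  labels are free text, normalized (lowercase, trimmed, whitespace
  collapsed); equality after normalization is the equality test.  The
  deviation is ¼ per differing component — by default the symmetric
  difference of the two sets; a `missing_only` mode counts only control
  components absent from the comparison — capped at 1.  Two non-empty sets
  with **no shared component** are a completely different state and score
  the full cap directly: this is what makes the opponens pollicis insertion
  cells (0.278/0.278/0.278/0.222) come out of the rules rather than from
  per-cell pins.
* **Count**: d = min(1, ¼·|k<sub>control</sub> − k<sub>other</sub>|), with
  count ranges ("6–7") collapsed to their midpoint.  The penalty floors at
  zero; a structure entirely absent in the comparison species (count 0)
  short-circuits to CAI = 1 rather than passing through the formula.
* **Vascularization** is decided at species level by the number of palmar
  arterial arches (one in capuchins and baboons, two in apes and humans):
  deviation 0 when equal, ½ otherwise — even for muscles whose arterial
  supply is nominally identical, since the published cells are reproducible
  only under the arch-level rule.
* **Variant heads**: where a muscle has an extra head with frequency *f* in
  one species (the two-headed flexor pollicis brevis), innervation, origin
  and count score d = ¾·|Δf| instead of set comparison.  The difference of
  the two species' variant frequencies is used so that self-comparison stays
  at zero.  The credited frequency 1 − ¾f is carried at the 3-decimal
  working precision of the reported tables (13/16 enters as 0.813), which
  reproduces both published cells (0.180, 0.087) exactly at their printed
  precision.

## Reporting precision

Internal arithmetic is full floating precision.  Reported values round half
away from zero; per-muscle values at 3 decimals (4 where the source table
prints 4, e.g. 0.0278).  The reported group value `gcai_reported` averages
the member CAIs *after* rounding them to 3 decimals — the convention under
which the published group values are internally consistent with their
printed member cells (e.g. thenar vs human: (0.111 + 0.222 + 0.278 +
0.167)/4 = 0.1945 → 0.195).  The full-precision mean (`gcai_mean`) and the
group-formula value (`gcai_formula`) are always carried alongside.

## The packaged dataset and its override ledger

The dataset (CSV + JSON under `caindex/data/`) encodes the modal character
states of five species × twelve muscles, each row citing its source-table
cell, plus all 60 published index values with their printed precision.
Absent muscles (human and gorilla contrahentes) are encoded as count 0 with
empty component sets so groups keep m = 4.

33 of the 48 per-muscle cells follow from the counting rules alone.  The
remaining 15 are pinned by `DeviationOverride` entries — per-cell deviations
with a note citing the cell — because the source tables count variations
inconsistently (additions vs omissions, prose vs character-table encodings).
Two deserve mention: the gorilla lumbricals cell (0.139) is not reproducible
from any stated rule (nearest rule value 0.111) and is pinned at origin
deviation 0.375; the baboon palmar interossei cell prints 0.31 while its
group value 0.085 implies a member value of 0.3125, so the count deviation
is pinned at 0.8125 (the origin term stays rule-derived).  Overrides carry
the control species they are relative to and never fire for other control
choices; every overridden value is flagged (`*` in text reports, a boolean
column in machine output) so pinned and rule-derived numbers are never
conflated.  One encoding choice of the same kind: the human palmar
interossei count is encoded as 3 (required by the printed cell 0.083 and the
results-table prose) although the character table prints 4; the row's source
note records the conflict.

## Distance matrices and trees

`pairwise_matrix` generalizes the control-relative index to all ordered
species pairs, taking each species in turn as control.  The directed matrix
need not be symmetric (the control role matters when variant frequencies or
overrides differ), so the reported matrix is symmetrized as (M + Mᵀ)/2; the
directed matrix and the maximum asymmetry are exposed alongside.  UPGMA
(average linkage) runs on the symmetrized matrix via scipy, with labels
pre-sorted so tied merges resolve deterministically by label order; trees
are scikit-bio `TreeNode`s, exported as newick with 6-decimal branch
lengths.  NEXUS export writes a standard morphological DATA block with one
character per structure × attribute, states 0–4 (deviation from the control
in quarter units); it is export-only because morphological NEXUS dialects
vary too much for a faithful general reader.

## Synthetic data

The generator emulates the statistical shape of the real character table —
five attributes per structure, quarter-unit component divergences,
occasional count jitter, species-level arch flips, whole-structure absences
— with a single divergence parameter θ: each attribute of each non-control
species perturbs independently with probability θ (component operation drawn
uniformly from add/remove/replace, floored at one remaining component);
whole structures go absent with probability θ²; arches flip with probability
θ per species.  Defaults: 2 species, 6 structures, 3 components per set,
count jitter 1, base count 4.  Each species draws from its own spawned
random stream, so adding species never changes earlier draws.

For the defaults the expected per-structure index has the closed form
E[CAI] = θ² + (1 − θ²)·37θ/108 (component attributes contribute θ/3 each,
count θ/4, vascularization θ/2, weighted by (3,2,2,1,1)/9); the simulation
mean at 500 replicates agrees within three standard errors, and the recovery
experiment's mean-GCAI column is strictly increasing over the grid
θ = 0, 0.5, 1 at 200 replicates (both asserted in the suite).  What the
generator does **not** emulate: real anatomical nomenclature, correlated
evolution among attributes or structures, tree-structured divergence between
more than two species, and observation error in r<sub>v</sub>/N — so
passing recovery tests show the engine responds monotonically to divergence,
not that the index has any particular power on real clades.

## Degenerate inputs and numerical choices

N = 0 observation frequencies raise; negative counts and inverted count
ranges surface as validation findings, not exceptions.  Empty-vs-non-empty
component sets score the cap; two empty sets score 0 (only absent structures
have empty sets, and absence short-circuits first).  Matrices fed to UPGMA
must be square, symmetric (tolerance 1e−12), zero-diagonal and non-negative.
Problem sizes throughout are desk scale: the full suite, including the
200-replicate recovery experiment and the 500-replicate closed-form check,
runs in well under a minute.

## Known limitations

No uncertainty accompanies the index (no resampling scheme is defined for
it); the override ledger makes the published tables reproducible but also
means 15 of 48 cells are pinned rather than derived — users applying the
engine to new data get pure rule-derived values with no overrides unless
they write their own ledger; and the UPGMA summary is phenetic, not a
phylogenetic inference.
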