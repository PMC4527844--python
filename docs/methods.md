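# Methods

This note records the models, conventions and numerical choices behind
granulinkit, and what the synthetic data do and do not establish.

## Motif model and detection

The granulin module is modelled as an ordered cysteine scaffold
`C1 C2 C3C4 C5C6 | C7C8 C9C10 C11 C12` with seven variable inter-cysteine
regions.  Spacing is not fixed by the family's literature; the shipped
defaults (`data/motif_spacing.json`) are inclusive min/max residue counts
per region, wide enough to accept every supported module form, with the
length-variable regions being C1–C2, C4–C5 and C11–C12.  All ranges are
user-overridable.

Detection is deterministic pattern matching over the cysteine positions of
a sequence — no PSSM or profile HMM, because the target motif is defined
by the cysteine scaffold itself.  Scanning is greedy left-to-right;
within one candidate, backtracking is limited to the optional treatment of
`X` residues.  Full-module patterns are tried before half patterns, in the
order g, g\*, g″, ğ; this order is immaterial in practice because the
patterns have mutually exclusive cysteine-count shapes.  `X` never matches
a cysteine in strict mode; a lenient flag (off by default) allows at most
one X-for-C substitution per motif.

Variant forms and their per-half cysteine counts:

| form | N-half | C-half | note |
| --- | --- | --- | --- |
| g | 6 | 6 | canonical 12-Cys module |
| g\* | 5 | 5 | common 10-Cys form |
| g″ | 4 | 6 | missing the first double Cys |
| ğ | 8 | 6 | plant-type form, one extra double Cys |
| p | 6 | – | unpaired N-half (paragranulin) |
| q | – | 6 | unpaired C-half |

Which cysteine is absent in the 10-Cys form is not structurally
determined by counts alone; **classification uses per-half counts only**.
For pattern matching and template construction the package adopts the
convention that the variable single cysteines C2 and C11 are the absent
ones.  Counts that match no known form classify as `nonconforming` with
the counts attached, never silently dropped.

Boundary conventions: a module span includes 2 flanking residues on each
side of the outermost cysteines.  The N/C junction falls 4 residues beyond
the second double Cys (C5C6); paragranulins keep 5 tail residues, which
aligns them best against other N-halves.  When a gene model places an exon
boundary between C6 and C7, that boundary *is* the junction (the closest
to the default, if several) — the junction of a module is naturally an
exon boundary in this family.

## Exon grammar

Exon structures are hyphen-separated tokens over half-module symbols
(`s n c x y t`, modifiers `* " ň`, parentheses for split fragments).  The
splicing grammar flattens tokens into a half-symbol stream and pairs each
n-type symbol with an immediately following c-type symbol into a full
module; dangling n-halves emit `p`, orphan c-halves emit `q`.  Design
choices where the notation is open:

* `x` (interposed non-granulin sequence) breaks n–c pairing: an n before
  x emits p.  All curated rows are consistent with this reading.
* `y` and `t` (short exons, terminal sequences) are transparent: they emit
  nothing and do not break pairing.  A terminal `t` after a dangling n is
  unattested; it is treated as not emitting.
* Mixed modifier pairings (e.g. `n*`+`c`) are unattested; they emit a full
  module carrying the N-half's variant plus a warning, never a hard error.
* Case-insensitive comparison; single-module architectures render as `g`.
* The exon classification threshold separating short `y` exons from
  non-granulin `x` exons defaults to 15 codons; the first exon carries the
  signal prefix `s`, with an `x` appended when it has more than 30 codons
  of non-motif sequence (a nominal signal-peptide allowance).
* The lancelet-style prime notation for single cysteines split across exon
  boundaries is out of scope and not parsed.

`annotate_gene` requires every half-module's cysteines to lie in a single
exon; a half split across an intron is an unsupported-structure error
rather than a silent truncation.

## Anchored alignment

Cysteine anchors are pinned to common columns; each variable region takes
the maximum observed width.  The compact, minimum-gap convention is made
reproducible and aligner-independent as follows: sequences that fill a
region exactly define a per-column position-frequency profile; each
length-deficient sequence places one contiguous gap block at the position
minimizing mismatches against the profile's modal residues, ties breaking
to the leftmost column.  Multi-residue deficits use contiguous gap
extension at the chosen position.  Rows of a variant form lacking an
anchor carry `-` placeholders at the absent anchor columns, and their gap
block is constrained to cover those columns.  Rare manual edits are
supported only as explicit per-sequence directives, never inferred.

## Distances

**JTT ML distance.**  The Jones–Taylor–Thornton replacement model ships as
a data asset (`data/jtt.json`: 190 symmetric exchangeabilities and 20
equilibrium frequencies, the standard values distributed with PAML-format
`jones.dat` and the phangorn R package; PAML residue order).  The rate
matrix is `Q_ij = s_ij π_j`, scaled to one expected substitution per site
at equilibrium; `expm(Qt)` goes through the symmetric-form
eigendecomposition, computed once per model.  The pairwise distance
maximizes `Σ_sites log(π_a P(t)_{ab})`, bracketed on `[0, 10]` with
tolerance 1e-6 on t; optima at the bracket end are flagged saturated.  A
vectorized matrix path (common geometric grid of 400 branch lengths plus
per-pair parabolic refinement) agrees with the scalar optimizer to about
1e-2 substitutions/site and is the default for all-pairs matrices.

**LogDet distance.**  `d = -¼ [ln det F − ½(ln det D_a + ln det D_b)]`
with F the joint relative-frequency matrix of the comparable sites.  When
a base class is entirely absent, a pseudocount of 0.5 is added to every
cell of the count matrix and the pair is flagged (sparse-pair behaviour in
the classic distance programs is similar; the exact convention is not
standardized).  A non-positive determinant yields NaN with an `undefined`
flag — never a silent zero.  Summaries exclude such pairs and report them
in an `n_undefined` column.

**Gaps.**  Pairwise deletion per pair is the default, matching classic
distance-program behaviour; complete deletion is available as a flag.
No gamma rate heterogeneity — the distance analyses this package targets
did not use it.

**Summaries.**  Per-set mean, SD, median, quartiles, extremes over the
n(n−1)/2 pairwise distances.  The SD is the sample (n−1) formula; whether
to use sample or population SD is otherwise arbitrary, and this choice is
documented rather than configurable.

**Declarative trims.**  The mammalian half-module sets are length-equalized
before distance analysis by a per-set codon-removal table
(`data/mammalian_trims.json`): codon 4 from the N-half sets of modules 2
and 3, codon 18 from every C-half set except c5.  After these trims all
eight N-half coding sets are 90 bases and all seven C-half sets 75 bases
on the default template.

## Consensus

Column consensus at threshold T: the single residue reaching T (over
non-gap entries), else the first residue class whose aggregate frequency
reaches T, else a dot.  The class sets (`data/residue_classes.json`) are
the Taylor-style sets used by the MView consensus engine — the notation
(o alcohol, l aliphatic, a aromatic, h hydrophobic, − negative,
+ positive, c charged, p polar, s small, u tiny, t turnlike, dot any) is
standard, the member sets are frozen here as a versioned asset.
Evaluation order is most-specific-first (ascending member count, ties by
symbol code).  Ties between equally frequent residues break
alphabetically (tie handling differs across consensus tools and is
version-dependent; alphabetical is deterministic).  A column with at
least 50 % gaps renders a dot regardless.  Default thresholds are 50–100 %
in steps of 10 (six rows).

## Trees

Neighbour joining with a deterministic tie-break (lowest label-index pair
on equal Q) recovers additive matrices exactly; negative branch estimates
are clamped to zero and recorded.  Least-squares refitting solves the
non-negative least-squares problem on the path-incidence design, which
subsumes clamp-and-refit.  Majority-rule consensus retains bipartitions in
more than half of the input trees; extended mode adds remaining compatible
bipartitions greedily in frequency order (ties by first appearance), each
annotated with its support count.  Full maximum-likelihood tree search and
rogue-taxon pruning are out of scope; externally produced Newick tree sets
can be imported into the consensus step, preserving the shape of a
larger ML workflow.  NJ and the least-squares refit are desk-scale
stand-ins for Fitch–Margoliash-style programs.

## Synthetic data generator

The generator is the package's study-condition definition, not a tuning
dial.  Defaults emulate a 37-species mammalian-like progranulin family:
architecture `sn-n*-c*-n-c-n-c-n-cn-cn-cn-c` (paragranulin + 7 modules,
module 1 the 10-Cys form), star phylogeny of height 0.3 expected
substitutions/site, transition/transversion ratio κ = 2, and a reviewable
spacing profile (`data/mammalian_profile.json`) calibrated once so that
the declarative trims produce the 90/75-base length arithmetic above
(inter-cysteine spacings of 6/5/7 residues in default N-halves, 7/5/7 in
modules 2–3, 5/5/7 in the paragranulin; 8/6/4/4 in default C-halves,
8/6/4/3 in c5; 17-residue signal, 6-residue linkers, 2-residue flanks).
Where the family's printed record fixes no value (signal and linker
lengths, κ, tree height), values were chosen once at realistic magnitudes
for mammalian orthologue families and are not revisited.

Substitutions are simulated on DNA so that one simulation coherently feeds
both the DNA (LogDet) and protein (JTT) pipelines: per-site Poisson event
counts at rate `global_rate × module multiplier`, K2P jump chain per event
(the jump chain is exact for K2P because every base has the same total
leaving rate under the normalized model).  Proposals creating a stop
codon, creating a new cysteine, or removing an anchored cysteine are
rejected; cysteine content is therefore invariant, which keeps the motif
scaffold — and hence the ground-truth architecture — intact in every
descendant.  Rejection slightly deflates the realized rate at constrained
sites relative to the nominal branch length; distance-consistency checks
therefore use the unconstrained simulators (`jukes_cantor_pair`, the
model's own `simulate_aligned_pair`), and the constrained simulation is
used only where relative rates matter (rate-rank recovery).

The generator supports architectures over `s n c x y` tokens with variant
modifiers.  Split-fragment parentheses and terminal `t` tokens parse in
the grammar but cannot be generated.  Tandem duplication copies a module
together with its preceding linker and replicates the local exon pattern,
so separate N/C exons stay separate and CN chains extend by CN tokens;
optional per-copy protein-changing mutations (applied to the module, not
the linker) emulate tandem repeats of nearly identical modules.  No indels
are simulated outside the designated variable regions, and no selection
models — synthetic families have identical half-module coordinates across
species, so alignment on synthetic data exercises the anchoring machinery
but not indel placement.  Passing tests on these families demonstrate
correct bookkeeping and estimator behaviour under the generating model;
they do not validate performance on real, indel-bearing, compositionally
heterogeneous sequences.

## Problem sizes and determinism

The test suite runs the statistical checks at the sizes the package
documents as its reference experiments: 100 replicates × 10,000 sites for
estimator consistency (Jukes–Cantor at t = 0.3, JTT at t = 0.5), 50 random
pairs for the optimizer-vs-grid oracle (grid step 1e-4, agreement 1e-3),
exhaustive unrooted topologies through 8 taxa for NJ additivity, and
100 seeded replicates of the 37-species module-6 rate-recovery experiment
(multiplier 0.2, lowest mean required in ≥95).  All randomness flows
from explicitly passed seeded generators; pipeline reruns with the same
configuration produce bit-identical outputs and manifest hashes.

## Known limitations

* Detection is scaffold-based: degenerate motifs that a human curator
  might accept on judgement (atypical spacing, unusual cysteine counts)
  are reported as nonconforming or missed, by design.
* The anchored aligner assumes all sequences share the outermost anchor
  slots of their set; sets mixing, e.g., N-halves with full modules are
  rejected rather than partially aligned.
* The guide-profile gap rule reproduces the *stated* majority convention;
  equivalence with any particular semi-manual alignment workflow is
  claimed only at the level of those rules.
* LogDet pairs with singular divergence matrices are flagged, not
  rescued; at the 75–90-base half-module lengths this occurs occasionally
  for small families and is visible in `n_undefined`.
* PHYLIP output uses the classic 10-character name field; longer names go
  to a sidecar label map rather than being truncated.
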