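# Methods

## Scope and overall design

The package mechanizes a curation workflow that is usually done by eye:
deciding, for a lophotrochozoan protein sequence, whether it is a Pax
protein, which of the six subfamilies it belongs to, and whether a tree
built from curated paired-domain alignments supports that assignment.  Each
stage is a small, deterministic operation with an explicit contract, so the
whole pipeline is a pure function of its inputs and one seed.

Coordinates are 0-based and half-open everywhere.  Residues are the 20
canonical amino acids plus `X` (unknown); `X` never matches a literal or a
residue class but always matches a wildcard, because an unknown residue must
not count as positive evidence.

## Consensus motif language

Diagnostic motifs are written in the bracket notation used in the Pax
literature: uppercase literals, classes such as `[TS]`, and counted
wildcards (`X2`; the subscripted typesetting `X_2_` is accepted on input and
canonicalized to `X2`).  Matching is windowed and ungapped.  Mismatches are
counted **per pattern element**, so a failed class costs 1 regardless of its
repeat count — the simplest semantics consistent with consensus notation.
Default mismatch allowances are 0 for motifs shorter than 10 elements and 2
for the 31-column Paxβ motif; short motifs are essentially exact signatures
while long ones are matched by similarity.  No published mismatch tolerance
exists for these motifs, so the defaults are package choices, fixed once.
All windows are reported (overlaps included); consumers take the best.

The "quadribasic/diacid" and "tribasic" signals are operationalized as the
leftmost length-4 window containing at least `min_basic` K/R residues.  The
classifier uses `min_basic = 3` throughout: the published Paxβ example
signal `KRKHEDED` contains only three K/R (the histidine is what makes it
"quadribasic" in the looser physiological sense), and the tribasic
PoxNeuro signal is by definition 3-of-4.  The PoxNeuro "first helix" is not
delimited in the literature, so the tribasic search window is the first 20
PRD columns, where the PAI N-terminal helix lies.

## Domain detection

The PRD is found by ungapped position-profile scanning.  A profile is a
per-column residue frequency table with pseudocount normalization
(`(count + pc) / (n + 20·pc)`); scores are mean log-odds per aligned column
against a uniform background, which makes them invariant to sequence
padding outside the window and comparable between complete and truncated
hits.  Terminal truncations are allowed down to 25% profile coverage and
reported as incomplete.  No insert/delete states are modelled: the PRD is
conserved enough for ungapped scanning, and downstream curation discards
indel-ambiguous regions anyway.

Because PoxNeuro carries an insertion (the exon2/exon3 junction, `KPKQVAT`)
between the PRD halves, the PRD is detected compositely: the PAI (columns
0–64) and RED (columns 64–128) sub-profiles are scanned independently and a
PAI hit followed by a RED hit within 20 residues forms one PRD.  The
junction motif is then searched within ±10 columns of the PAI/RED boundary.
The acceptance threshold for de novo sub-profile hits is data-driven — mean
reference self-score minus three standard deviations — avoiding a magic
constant.  Because that threshold is estimated from few reference rows, a
lone above-threshold half additionally anchors a local search for its
sister half at the expected offset, and the pair is accepted when the
composite score clears the composite threshold.  This anchored rescue is
what keeps PRD-start recovery above 95% at 5% point-mutation noise without
loosening the de novo threshold.

The HD model is 60 columns, paired-type; a hit covering less than half the
model is a "partial HD", kept distinct from absence because chordate
Pax2/5/8 carries a partial HD while the lophotrochozoan family forbids one.

`percent_identity` treats equal-length inputs as aligned; unequal-length
inputs are globally aligned first (BLOSUM62, gap open −10, extend −0.5).
The denominator excludes double-gap columns; single-gap columns count as
mismatches; the result is rounded half-up.  The original convention behind
the published identity values is unstated, so this one is documented and
fixed.

## Family assignment

Each family is a profile of required, forbidden and optional evidence keys
(see README table).  The winner is the family whose required set is fully
satisfied with no forbidden evidence present.  Two refinements:

* **Specificity.**  Pax3/7's requirements (PRD + HD) are a strict subset of
  Pax4/6's (PRD + HD + MDKL), so a candidate whose required set is strictly
  contained in another satisfied candidate's is dropped before tie-breaking.
  Without this, every canonical Pax4/6 would be ambiguous.
* **Noise-proof vetoes.**  Forbidden HD only counts hits above the profile
  threshold, so a chance low-scoring window cannot veto a call.

Remaining ties go to the higher diagnostic score and are decorated `?`.
A PRD with no family evidence gives the indeterminate call `Pax`; fragments
(incomplete PRD, or a sequence ending inside the HD) demote confidence to
weak and append `(f)`.  Paxβ requires only 2 of its 3 motifs, mirroring the
fact that real Paxβ members have been accepted on tree evidence despite
missing motifs; the motifs without any PRD give `Paxβlike` (a configuration
observed in a real gastropod entry).  A duplicated-PRD configuration is
flagged `eyg?` and never auto-confirmed, since eyegone status in this clade
is unsettled.

## Alignment curation

The block filter reimplements the published curation settings: minimum
block length 10, no gap columns, maximal non-conserved runs longer than 8
rejected, flank agreement 85%.  Conservation is identity-based (no
similarity groups).  The conservation threshold itself is not stated in the
source settings; the canonical "more than half the sequences" rule is used,
implemented as modal frequency strictly greater than 0.5 (exactly
equivalent to count ≥ ⌊n/2⌋+1) and exposed as a parameter.  Rule order is
fixed and documented: gap columns and adjacent non-conserved stretches go
first, then long non-conserved runs, then flank trimming, then the length
floor.  The filter promises the published *parameters*, not bit-for-bit
equivalence with any particular legacy binary; its behaviour is instead
pinned by an independent rule-by-rule oracle in the tests and by an
idempotence property (filtering a filtered alignment is the identity).

## Trees

Tree inference for these data is usually maximum likelihood with an aLRT
(SH-like) branch test.  That stage is deliberately not reimplemented: the
downstream claims this package checks are qualitative clade statements, for
which distance NJ with nonparametric bootstrap is sufficient and much
cheaper.  Supports are labelled "bootstrap (NJ)" to avoid conflation with
aLRT values, and the ML nuisance estimates reported for such alignments are
carried only as reference constants (gamma shape 0.716, invariant
proportion 0.088); the
gamma shape doubles as the default α for gamma-corrected distances.

NJ is deterministic: Q-criterion ties break on the lexicographically
smallest pair of cluster labels, and negative branch lengths are clamped to
zero with the deficit transferred to the sister edge so path lengths are
preserved.  Distances use pairwise gap deletion (curated alignments are
gap-free by construction, but the operation stays safe on raw input); a
saturated pair under gamma correction is a named error rather than a NaN.
Bootstrap resamples columns with replacement, seeded; supports are the
percentage of replicates containing each original split; branches below the
collapse threshold (default 50%) become polytomies.  Monophyly of a family
is tested as a split of the unrooted tree (clade under some rooting), with
the supporting edge's bootstrap value and, on failure, the intruding taxa.

## Synthetic benchmark

The generator plants the exact architectures of the table above: a 128-aa
PRD (PoxNeuro's with the 7-aa junction insert), linkers of 10–30 aa between
elements, a Paxβ variable region of 150–260 aa carrying the three motifs in
order at random spacings, and N-/C-terminal extensions.  Defaults are 5
records per family, mutation rate 0, fragment probability 0 — the noise-free
reference condition — with the recovery experiments run at mutation rates
{0, 0.02, 0.05, 0.10} and fragments generated by truncation at a uniform
position inside the PRD.

The per-family reference PRD consensi are diverged copies of one random
ancestor (15% between families, 30% for eyg), generated once from a fixed
seed.  Two deterministic curation steps keep the benchmark diagnostic: the
PoxNeuro consensus carries a planted tribasic helix-1 signal, and chance
tribasic runs are scrubbed from the first 20 columns of every other
consensus (a hand-curated separability guarantee, asserted in tests).
Point mutations spare a 2-residue guard at the ends of planted short
motifs, keeping coordinate-recovery assertions crisp; the guard is a
config switch.  Linker composition is uniform over the 20 residues.

What the benchmark does *not* emulate: real amino-acid composition bias,
indel evolution, splice isoforms, and real PRD sequence space — the
reference consensi are synthetic stand-ins, so passing tests demonstrate
the pipeline's mechanics (detection, classification logic, curation, tree
support), not database-scale sensitivity on real proteins.  Real reference
PRD alignments can be dropped in wherever an `AlignmentMatrix` is accepted.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's own
benchmark conditions: 30–54 synthetic records per experiment, 100 bootstrap
replicates (the published replicate count), oracle sweeps of 200 random
sequences for the scanner, 100 random alignments (≤15×60) for the block
filter, and 50 random trees (≤12 leaves) for NJ topology recovery.  The
dataset-wide published counts (216 candidate sequences, 65–71 curated PRDs
on 108–121 positions) depend on database snapshots and are documented but
not asserted.  Ties in greedy hit selection resolve by score then position;
all RNG flows from `numpy.random.default_rng` seeds, with the bootstrap
stage offset by +1000 from the top-level seed so stage subsets reproduce.

## Known limitations

* Architecture calls degrade gracefully but noticeably above ~3–5% point
  divergence from the motif consensus, because short motifs are matched
  exactly; this matches the intent that borderline sequences fall back to
  indeterminate `Pax` rather than to a wrong family.
* The PoxNeuro junction motif is matched exactly (7 literals), so heavily
  diverged junctions demote PoxNeuro to `Pax`.
* No profile-HMM insert/delete states; a PRD with internal indels larger
  than the junction allowance will be reported as incomplete halves.
* eyg is flag-only by design; confirming it requires tree context and
  manual review.
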