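# Methods

This note documents the models, parameters and numerical choices behind
`seqcurate`, in the spirit of the methods documentation of mature scientific
packages: what each stage assumes, which knobs matter, and what a green test
does and does not establish.

## The curation problem

A single-locus reference set (the motivating case is vertebrate
mitochondrial cytochrome-b, ~1,140 nt, in amphibians) assembled from a
public repository contains several distinct error classes:

- **misidentified records** — the sequence is genuine but carries the wrong
  species (sometimes genus) label;
- **backward reads** — submitted as the reverse complement;
- **RefSeq duplicates** — `NC_` re-releases of a sequence already present
  under its original accession;
- **open nomenclature** — cf. / aff. / sp. / ssp. names that are not
  complete binomials and cannot be assessed at species rank;
- **embedded loci** — mitogenome-scale records that contain the target
  locus;
- **technical artifacts** — terminal ambiguity runs, vector padding,
  frame-breaking indels from sequencing error.

The pipeline repairs what is mechanically repairable (orientation,
extraction, padding, frame), removes what is redundant (duplicates), and
flags what needs human judgment (divergence conflicts, uncertain names)
with the evidence attached. It never auto-assigns a verdict: deciding
whether a flagged sequence reflects misidentification, contamination,
hybridization/introgression or a submission error requires the source
literature.

## Divergence model and threshold

The only distance used is the uncorrected proportion of differing sites
(p-distance) under **pairwise deletion**: a site contributes to a pair only
when both characters are plain A/C/G/T; gaps, N and IUPAC ambiguity codes
are excluded per pair. No substitution-model correction is applied — at the
few-percent divergences that matter for the threshold rule, corrections are
negligible relative to labeling noise, and the uncorrected value is what the
3% convention was calibrated on.

Two complementary rules share one threshold `t` (default 0.03, a
conservative barcoding-gap value for amphibian Cytb; re-estimate it for
other loci/taxa):

- **intraspecific**: conspecific sequences are accepted at `d ≤ t`, flagged
  above. The flagging unit is the single-linkage cluster at `t`: if the
  conspecific set splits, all members outside the largest cluster are
  flagged (a lone outlier is the degenerate case). Equal-size ties keep the
  cluster containing the lexicographically smallest label — a pure
  convention, recorded on every flag, because no automatic rule can say
  which of two equal divergent clusters is "right".
- **intrageneric**: heterospecific pairs within a genus are accepted at
  `d > t` and flagged at `d ≤ t` (suspiciously similar across species);
  both members are reported with their closest offending partner.

Distances on fewer than `min_overlap` comparable sites (default 100) are
*missing*: they neither accept nor flag, and the affected sequences are
listed separately ("insufficient_overlap"). Thresholds are compared on
exact values; percentages in reports are rendered to two decimals for
humans only.

**Monotonicity.** The intrageneric flag set grows monotonically (by set
inclusion) as `t` grows. For the intraspecific rule the flagged *count*
`n − |largest cluster|` is provably monotone non-increasing in `t`, but the
flagged *set* is not monotone in adversarial geometries (two small clusters
can merge and overtake the previous majority). Tests therefore assert count
monotonicity for the intraspecific rule and set monotonicity for the
intrageneric rule.

## Alignment engine

All pairwise alignment goes through Biopython's `PairwiseAligner` with one
scoring scheme: match +1, mismatch −1, a gap of length *k* costs
`gap_open + k·gap_extend` = 4 + *k*, and ambiguity codes score 0 against
anything (legitimate ambiguity calls are never penalized). Two modes are
used:

- **Mapping (local / Smith–Waterman).** Placing a record on the reference
  must be able to shave unalignable flanks — vector padding, genome context
  beyond the locus — off *both* sequences. Classical semi-global (free
  end-gap) alignment cannot do that: it only ever skips a prefix/suffix of
  one sequence, so it would align padding against the reference rather than
  drop it. Local alignment with the same scores implements the intended
  behavior. Orientation is the argmax of the two strand scores; exact ties
  or mappings below the identity floor (default 50% over the aligned
  reference span) or shorter than `min_length` (default 100 nt) are
  "undetermined" and reported as mapping failures.
- **MSA (semi-global).** Within a species, end columns must stay aligned,
  so the center-star aligner uses global alignment with free end gaps.

**Gapless fast path.** Most repository records differ from their reference
by substitutions only. A k-mer (k = 12) diagonal vote locates the candidate
offset; along that diagonal the best gapless local alignment is the
maximum-sum run of per-site scores (for semi-global, the full overlap). The
shortcut is accepted *only* when its score equals the full DP optimum, so
it is exact, and it removes the need for path reconstruction in the common
case. Records longer than twice the reference (mitogenomes) are first
reduced to a seeded candidate window (±200 nt) before DP; tests verify the
windowed result equals full-sequence DP. Both engine modes are verified
against independent pure-Python Gotoh / Smith–Waterman implementations.

Coordinates are 0-based half-open on the reference, forward strand.

## Multiple alignment and gap resolution

The per-species MSA is deterministic center-star: the longest sequence is
the center, every other sequence is aligned to it, and rows are merged on
center coordinates (insertions relative to the center get their own
columns; row order is input order). For two sequences this reduces to the
optimal pairwise alignment. No external aligner is invoked anywhere in the
tested code paths.

For a protein-coding locus, an internal gap run whose length is not a
multiple of 3 breaks the reading frame and is treated as a sequencing
artifact, not biology: each such gapped position is filled with the column
consensus base when all other rows' non-gap characters agree there, and
with `N` when they disagree (or the column is otherwise empty). Runs of
codon length (3, 6, 9, …) are genuine in-frame indels and are left alone,
as are terminal gaps. The strict variant (`strict_three`) instead fills
every run of length ≠ 3, for users who read the rule literally; the default
follows the reading-frame rationale, under which a length-6 codon deletion
is routine biology. Consensus is computed from the original columns
(simultaneous update), which makes the operation idempotent and guarantees
it never alters a non-gap character.

Leading/trailing runs of non-ACGT characters become terminal gaps (all
IUPAC ambiguity codes are trimmed, not just N); internal ambiguities are
kept and simply drop out of distances via pairwise deletion.

## Cross-species comparison

Within-species distances are computed on the curated species alignment.
Cross-species distances within a genus are computed on reference-coordinate
projections of the mapped sequences: each record contributes the character
aligned to every reference position in its span. This avoids genus-level
re-alignment (deterministic, no re-alignment artifacts) at the cost of
ignoring conspecific-only insertion columns — immaterial for p-distances,
since projected gaps are excluded pairwise anyway. The projections are
taken before consensus-filling; filled bases equal the column consensus and
would not change any distance materially, and re-projecting edited rows
would require tracking per-row edits through the MSA for no benefit.

## Coverage and summaries

Per reference position, coverage counts sequences (and distinct species)
contributing a plain base there. The "best region" of width *w* maximizes
the *minimum* species coverage across the window — a window is only usable
end-to-end — tie-broken by minimum sequence coverage, then leftmost start,
via exhaustive scan. Quantiles (median, 25th/75th) use linear interpolation
between order statistics (`numpy.percentile` default), stated here because
"interquartile range" admits several conventions.

## Synthetic data: the stated world

The generator emulates a repository snapshot with known ground truth. Each
species ancestor derives from the reference by independent per-site
substitution at `inter_div` (default 8%); each conspecific sequence derives
from its ancestor at `intra_div` (default 1%); the alternative base is
uniform. Expected conspecific divergence is therefore analytic,
`2q(1−q) + (2/3)q²` ≈ 2% at q = 1%, comfortably below the 3% threshold,
while heterospecific divergence ≈ 14.8% sits far above it — the benchmark
separation under which planted-error recovery must be perfect. Defaults (10
genera × 3 species × 8 sequences, 1,140 nt locus) are the benchmark world.

Planted misidentifications relabel a record to a species in a *different*
genus by default: a within-genus mislabel necessarily also flags its
nearest innocent partner under the intrageneric rule (both members of a
too-similar heterospecific pair are suspects), so perfect precision is only
a meaningful target for cross-genus swaps; within-genus swaps are available
(`misid_cross_genus=False`) and unit-tested for the both-members behavior.

What the generator does **not** emulate: phylogenetic structure (no
coalescent, no rate heterogeneity, no shared polymorphism), indel processes
beyond single planted deletions, length variation among records, sequencing
quality gradients, or real taxonomy. A green planted-recovery test
establishes that the machinery is correct under clean separation — not that
real data, where intra/inter-specific divergences overlap, will be flagged
with perfect precision.

## Determinism

One seeded generator instance drives all synthetic draws; every pipeline
iteration is over sorted keys; reports carry no timestamps; ties everywhere
break lexicographically. Two runs on identical inputs and configuration are
byte-identical, which is asserted in the test suite.

## Known limitations

- RefSeq deduplication requires *identical* sequences (after case folding
  and terminal-N stripping); an `NC_` record trimmed differently from its
  source submission is retained as a distinct record.
- The identity floor (50%) and minimum mappable length (100 nt) for
  accepting a mapping are conventions; no published value exists for the
  GUI mapping step they replace.
- Single-sequence species cannot be assessed by the intraspecific rule and
  are reported "unassessable_single" rather than silently accepted.
- The organism-string parser resolves trinomials vs definition text
  heuristically (a third lowercase token is a subspecies only when final);
  records failing the heuristic are noted, never silently altered.
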