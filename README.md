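# seqcurate

Reproducible curation of single-locus nucleotide records from public
sequence repositories.

Public repositories such as GenBank accumulate records whose taxonomic
labels, orientation, or composition are wrong: misidentified vouchers,
contaminated extractions, backward-read submissions, RefSeq duplicates, and
open-nomenclature names (cf., aff., sp., ssp.). For groups like amphibians —
where mitochondrial cytochrome-b (Cytb, ~1,140 nt) is the workhorse marker —
these errors contaminate every downstream phylogenetic, barcoding and
conservation analysis. `seqcurate` implements an automated, fully
deterministic curation pipeline for such a marker: everything a curator
would do before the final literature check, which remains a human step.

## What the pipeline does

1. **records** — parse FASTA (+ optional metadata TSV), normalize names to
   `Genus_epithet_ACCESSION`, drop RefSeq (`NC_`) records that duplicate a
   conspecific sequence, apply a user-supplied synonymy table, and split off
   records without a complete binomial into an uncertain-taxonomy report.
2. **refmap** — align each record against a reference locus in both
   orientations (local Smith–Waterman, match +1 / mismatch −1 / gap of
   length *k* costs 4 + *k*, ambiguity codes neutral), reverse-complement
   backward submissions, and extract the locus span — including from
   genome-scale records, which are pre-screened with a k-mer seed step.
3. **msa** — deterministic center-star multiple alignment per species, then
   frame-aware gap resolution (internal gap runs whose length is not a
   multiple of 3 are filled from the column consensus where the column is
   uniform, replaced by `N` where it is not) and trimming of ambiguous ends.
4. **divergence** — uncorrected pairwise divergence (p-distance) with
   pairwise deletion: for aligned sequences *x*, *y*,
   `d = #{i : x_i ≠ y_i} / n` over the *n* sites where both characters are
   plain A/C/G/T; distances on fewer than `min_overlap` comparable sites are
   reported missing.
5. **curation** — the two-sided 3% threshold rule: conspecific sequences are
   accepted at `d ≤ t` and flagged above (single-linkage clustering at *t*;
   members outside the largest cluster are the outliers), while
   heterospecific pairs within a genus are accepted at `d > t` and flagged
   at `d ≤ t`. The conflict report carries the evidence (nearest partner,
   divergence, comparable sites) and empty verdict/rationale/reference
   columns for the human literature check.
6. **coverage_summary** — per-position sequence and species coverage on the
   reference, the fixed-width window maximizing the coverage minimum
   (species first, then sequences, then leftmost), and summary statistics
   (sequences/species, species/genus, species/family) with medians and
   interquartile ranges.

A seeded synthetic-data generator (`seqcurate.simulate`) emits
repository-like record sets with planted errors in every class plus a truth
table, so the whole pipeline is testable offline.

## Worked example

```bash
seqcurate simulate --seed 4 --outdir fixture \
    --genera 5 --species-per-genus 3 --seqs-per-species 6 \
    --plant misidentified=4 --plant revcomp=3 \
    --plant refseq_duplicate=2 --plant non_binomial=2
seqcurate curate --input fixture/records.fasta \
    --metadata fixture/metadata.tsv \
    --reference fixture/reference.fasta --outdir out
seqcurate summarize --fasta out/curated.fasta --out summary.tsv
```

prints

```
wrote 92 records to fixture/records.fasta (reference fixture/reference.fasta, truth fixture/truth.tsv)
curated 84 of 92 records (4 flagged, 2 uncertain, 2 duplicates, 0 unmappable) -> out
seqs_per_species: median 6 [5, 6]
species_per_genus: median 3 [3, 3]
```

92 records went in (90 simulated + 2 planted RefSeq twins). The pipeline
dropped the 2 twins, routed the 2 open-nomenclature names to
`uncertain_taxonomy.tsv`, silently repaired the 3 backward reads, and
flagged exactly the 4 planted cross-genus misidentifications — e.g. the
first report row

```
SYN000068  Genaa specab  intraspecific_divergent  Genaa_specab_SYN000011  16.84  1140  3.00
```

says sequence SYN000068, labeled *Genaa specab*, sits 16.84% from its
nearest conspecific over 1,140 comparable sites — far beyond the 3%
threshold — so it is excluded from `curated.fasta` pending review. Every
input record is accounted for in `manifest.json`:
`records_in == curated_out + flagged + dropped_duplicates + uncertain +
unmappable`.

The library mirrors the CLI: `parse_records`, `deduplicate`,
`apply_taxonomy`, `RefMapper.orient`, `align_species`, `resolve_gaps`,
`p_distance`, `genus_matrix`, `flag_intraspecific`, `flag_intrageneric`,
`coverage_profile`, `best_region`, `summarize`, `run_pipeline`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the benchmark synthetic fixture from the given seed (10 genera ×
3 species × 8 sequences at 1% conspecific / 8% heterospecific divergence,
with errors planted in every class), runs the complete pipeline on it,
verifies that the run manifest reconciles, and writes the results JSON.

## Limitations

- The 3% threshold is a conservative, marker- and clade-specific value; it
  must be re-estimated for other loci or taxa.
- Final verdicts (misidentification vs contamination vs hybridization vs
  submission error) require literature and cannot be automated; the tool
  produces the candidate list and the evidence, not the verdicts.
- No network access: repository retrieval is out of scope; inputs are files.

See `docs/methods.md` for the model, parameter and design details.
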