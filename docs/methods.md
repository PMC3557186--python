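# Methods

## Problem and scope

`dupfate` analyzes the fate of gene duplicates in a family of paralogs and
orthologs: which copies remain intact, which have decayed into pseudogenes,
and what molecular lesions — indels, premature termination codons (PTCs),
degraded splice motifs — drove the decay. Every analysis stage consumes the
same unit, a `GeneModel` (sequence plus ordered exon intervals), and every
stage is validated against a simulator that plants known events and emits a
machine-readable truth table.

## Coordinates and formats

All arithmetic is done in 0-based half-open coordinates; every file and
report uses 1-based inclusive coordinates, matching how positions are
written in the comparative-genomics literature (e.g. "position 215–218").
Inputs are FASTA plus either a GFF3 subset (`exon` features with `gene_id`,
`species`, `paralog` attributes) or a 6-column TSV
(`gene_id, species, paralog, exon_index, start, end`); the TSV dialect
round-trips bit-exactly. Reverse-strand GFF3 features are normalized to the
coding strand at load. Lowercase and `U` are normalized to uppercase `T`.

## Pairwise alignment

The aligner is a Gotoh affine-gap global aligner. A gap of length *L* costs
`gap_open + gap_extend·L`; nucleotide defaults are match +5, mismatch −4,
gap_open 10, gap_extend 0.5 (conventional DNA scoring), protein defaults
gap_open 11 / extend 1. IUPAC ambiguity symbols score as mismatches unless
literally identical (conservative). The traceback is deterministic with the
fixed tie-break order substitution → gap-in-b → gap-in-a, so reruns are
byte-identical. The recurrences are vectorized row-wise in numpy; the
horizontal gap state uses a prefix-max transform (valid because a gap
reopening is never strictly better than extension when `gap_open ≥ 0`).

Multiple alignments are *consumed* (aligned FASTA); `star_msa` is a
center-star merge of pairwise alignments provided as a convenience for
callers without a precomputed MSA. It is exact for low-divergence families
(the regime the simulator's validation uses) but is not a general-purpose
MSA heuristic.

## Indel mapping and canonical placement

`map_indels` extracts deletions (row-gap runs over reference-bearing
columns) and insertions (row residues inside reference-gap blocks) relative
to a declared reference row. Deletion runs are projected onto
reference-bearing columns so that another taxon's insertion interleaved in
the alignment does not split one deletion into two. Because an indel
bounded by repeated sequence has several score-equivalent placements, every
event — and every planted truth record in the simulator — is
left-normalized to its leftmost equivalent placement (the same convention
VCF uses). This makes planted and recovered coordinates comparable exactly
rather than "up to a shift". Frame effect is `in-frame` iff the event is
coding and `length mod 3 = 0`. Terminal gap runs are treated as unsequenced
ends (missing data), not indels, unless explicitly requested. With no
coding mask the whole alignment is treated as coding (the cDNA case).

## Gene-fate calling

Translation uses the standard genetic code; degenerate codons translate to
`X` unless every resolution agrees. The fate call from the annotated CDS
start (or first ATG):

* **INTACT** — the first in-frame stop yields an ORF covering at least 90%
  of the reference protein length (configurable `min_fraction`), or at
  least 100 codons when no reference is given. The completeness threshold
  is judged against orthologs because absolute ORF length is meaningless
  across families.
* **RESCUED_ALT_START** — the annotated frame fails but the nearest
  upstream in-frame ATG (within 90 nt, same exon by default) reaches a
  terminal stop at the expected span. This models the documented case of a
  frameshifted start rescued by an alternative initiator.
* **PSEUDOGENE** — otherwise, with stop-codon evidence; stops before the
  expected-span codon are reported as premature.
* **NO_TERMINATOR** — no in-frame stop at all.

A consequence worth knowing: a PTC planted within the last ~10% of the
coding region is *not* premature under the 90% rule and the gene is called
INTACT. The cleavage motif (default furin/PC consensus `R-X-[KR]-R`, the
field's standard consensus; configurable) is located on the translated
protein and reported, with all matches available in detail mode.

## Motif auditing

A subject symbol matches a degenerate pattern symbol iff the subject's
possible bases are a subset of the pattern's; overlapping occurrences are
counted (step 1) because no exclusion rule is standard. Splice-site audits
evaluate the last 3 exonic + first 6 intronic nt (donor) and last 3
intronic + first exonic nt (acceptor) against *both* donor consensus
dialects in circulation (`MAG/GTRAGT` and `RAG/GTRAGT`) plus acceptor
`CAG/G`, reporting agreement per dialect instead of silently choosing one;
`critical_intact` isolates the near-invariant GT / AG dinucleotides.
Branch points are `TNCTRAY` hits per intron with intron-relative,
gene-relative and distance-to-3'-splice-site coordinates; introns without a
hit are reported as not-found. YCAY counts are per exon/intron with
unsequenced features marked NA and excluded from totals.

## Conservation statistics

Identity uses pairwise deletion (columns with a gap in either row are not
counted) by default, which maximizes usable signal per pair; group means
are rounded half-up to integer percent for comparison with the
"N% identical" convention. Diagnostic residues are columns uniform within
one clade and absent outside it; gap columns are skipped. The per-taxon
unique-position count implements the strict one-row-differs rule.

## NG86 dN/dS screen

Synonymous site counts per codon are the fraction of the nine one-step
mutants preserving the amino acid (mutations to stops count as
nonsynonymous). Differences in multi-substitution codons are averaged over
all orderings of single steps, excluding orderings through a stop codon
(all orderings are used if every one is blocked). Sites are averaged over
both sequences; proportions are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − (4/3)p)`, with `p ≥ 3/4` flagged as saturation and
`dS = 0` flagged as omega-undefined. Gap-containing codon columns are
removed pairwise and counted; a shared terminal stop codon is trimmed, an
internal stop is an error (surfaced as a flagged row in the pairwise
screen, not dropped). Expect NG86 omega *below* 1 for neutrally evolving
pairs simulated with transition bias: the counting method does not correct
site counts for κ > 1, so transitions at third positions inflate dS — a
known property of the estimator, not a bug.

## Simulator

The simulator is the package's validation instrument and defines its study
conditions. The ancestral gene has three exons (defaults 370/371/381 nt,
the scale of the motivating family), donor boundaries `…AAG | GTAAGT`
(exonic `AAG` satisfies both donor dialects), acceptors `…CAG | G`, one
`TTCTAAC` branch motif per intron, an ORF running the full mRNA from ATG to
a terminal TAA with no internal stops, and an `RSKR` cleavage motif at
~63% of the protein. Introns default to 350–950 nt.

Two duplication rounds produce paralogs 1a/1b/2a/2b; each paralog ancestor
then evolves along a balanced species tree (6 species by default, or a
user-supplied newick). Substitution is per-site, single-hit: each site
mutates with probability equal to the branch length (default 0.01
substitutions/site per branch) and a mutated site becomes its transition
partner with weight κ (default 2) against 1 per transversion. There is no
rate heterogeneity and no selection — this is deliberately the neutral
null against which the detectors are validated, which also means ambient
nonsense mutations arise at realistic rates in long runs.

Planted events, each recorded once in the truth table:

* **indels** — per-gene probability 0.3, lengths drawn from
  {1, 4, 5, 7, 37, 48, 51} (the length spectrum of observed duplicate-gene
  decay; 37 is the canonical frameshifter), 25% insertions; exonic, kept
  ≥10 nt from exon edges; coordinates left-normalized.
* **PTCs** — per-gene probability 0.25; a codon is overwritten with TAA,
  kept clear of exonic boundary contexts (so a PTC never masquerades as
  splice damage) and of the gene's own indel footprint (±15 nt) so each
  event is independently recoverable from an alignment.
* **splice degradation** — per-boundary probability 0.25; the critical
  dinucleotide is broken (GT→GC donors, AG→AC acceptors).
* **diagnostic residues** — 2 per paralog group planted uniformly in a
  fixed clade (first half of the species by default), never creating a
  stop codon.

Random streams are per-gene and per-event-type substreams of the master
seed (SeedSequence keyed by CRC32 of stable tags), so enabling one event
type never perturbs another and a fixed seed gives byte-identical bundles.

What the simulator does *not* emulate: rate heterogeneity, selection,
codon-usage bias, demography, hybridization, sequencing error, and real
alignment ambiguity at high divergence. Passing recovery tests therefore
demonstrates correctness of the detectors' logic and coordinate handling,
not robustness to every property of real data.

## Validation problem sizes

The replicate-heavy recovery checks run on a compact configuration
(4 species × 4 paralogs, exons 90/93/96 nt, introns 80–120 nt,
substitution rate 0, all event types active) — 100 seeded replicates in the
test suite, 25 in the acceptance script — chosen so exhaustive replication
stays fast while exercising the identical event machinery and detectors as
the full scale. Single-family checks and the conservation/omega summaries
in the acceptance script run at the full default scale.

## Pipeline and reports

The CLI (`dupfate simulate | structure-map | pseudogene-call |
splice-audit | motif-count | identity | dnds | pipeline`) groups genes by
paralog label, picks each group's reference (a bundled `REF_*` gene when
present, else the first gene), star-aligns the group around it, and runs
every stage. Reports are TSV with `#` metadata lines and NA for missing
values, written atomically; a `manifest.json` records the tool version,
parameters and SHA-256 input digests. Reports are byte-identical across
reruns — only the manifest carries a timestamp. The dN/dS screen aligns
CDS regions within each group; pairs involving frameshifted pseudogenes
surface as flagged error rows rather than numbers.

## Known limitations

* `star_msa` degrades for divergent sequences; supply a real MSA for
  anything beyond closely related orthologs.
* Insertion-vs-deletion polarity is reference-relative only; no ancestral
  state reconstruction.
* The NG86 screen is not a substitute for ML codon models; it provides
  screen-level omega per pair only, with the κ-bias noted above.
* Multi-frameshift tracking is relative to the declared reference frame
  only.
* Selenocysteine and non-standard genetic codes are unsupported.
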