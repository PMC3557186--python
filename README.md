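# dupfate

Analysis toolkit for the fate of duplicated genes. After a whole-genome
duplication, surplus gene copies decay along characteristic routes — indels
that shift the reading frame, premature termination codons (PTCs), and
degraded splice-site motifs that block transcript processing — while
retained copies stay conserved. `dupfate` implements the comparative
analyses used to characterize such a family (the motivating case is a
four-paralog salmonid-like family with three-exon genes), end to end:

* **gene_models** — validated gene structures (sequence + ordered exon
  intervals), splicing, FASTA/GFF3/TSV ingestion. Coordinates are 0-based
  half-open internally and 1-based inclusive in every file and report.
* **aligner** — deterministic affine-gap (Gotoh) global alignment
  (gap of length *L* costs `gap_open + gap_extend·L`; defaults +5/−4/10/0.5),
  percent identity under explicit gap policies, aligned-FASTA I/O, and a
  center-star MSA convenience.
* **structure_compare** — indel events relative to a declared reference,
  left-normalized (VCF-style) for reproducible coordinates, classified as
  in-frame vs frameshift (`length mod 3`), grouped into shared missing
  regions across taxa.
* **orf_analysis** — gene-fate calls: `INTACT`, `PSEUDOGENE`,
  `RESCUED_ALT_START` (an upstream in-frame ATG restores a complete ORF) or
  `NO_TERMINATOR`, plus furin/PC cleavage-motif location (`R-X-[KR]-R`).
* **motif_scan** — IUPAC degenerate scanning: splice-site audits against
  both donor consensus dialects (`MAG/GTRAGT` and `RAG/GTRAGT`) and the
  acceptor `CAG/G`; branch-point search (`TNCTRAY`) with distance to the 3'
  splice site; YCAY counts per exon/intron.
* **conservation** — identity matrices (pairwise deletion), rounded group
  means, clade-diagnostic residues, per-taxon unique positions.
* **dnds** — Nei–Gojobori (1986) counting dN/dS with pathway averaging and
  Jukes–Cantor correction; a screen, not an ML model.
* **synthetic_data** — a gene-family simulator with machine-readable truth:
  ancestral gene with pristine boundaries and an open ORF, two rounds of
  duplication, K80-style substitutions along a species tree, and planted
  indels/PTCs/splice degradations/diagnostic residues.

## Worked example

Simulate a family and run the whole pipeline from the shell:

```sh
dupfate simulate --seed 5 --out-dir bundle
dupfate pipeline --fasta bundle/genes.fasta --features bundle/features.tsv \
    --out-dir reports
```

`reports/` then holds eight TSV reports plus a `manifest.json`. The same
thing from Python, reading one gene's fate:

```python
>>> from dupfate.synthetic_data import SimConfig, simulate_family
>>> from dupfate.gene_models import splice
>>> from dupfate.orf_analysis import classify_status
>>> from dupfate.dnds import ng86
>>> bundle = simulate_family(SimConfig(seed=1))
>>> gene = bundle.genes[1]   # sp02_1a
>>> report = classify_status(splice(gene), reference=bundle.references["1a"])
>>> report.status, report.premature_stops[:1]
('PSEUDOGENE', ((179, 535),))
>>> r = ng86("AAATTTGGGCCC", "AAATTCGGGCCC")
>>> round(r.pS, 3), round(r.dS, 4), r.dN
(0.375, 0.5199, 0.0)
```

The fate call says this simulated paralog carries an in-frame stop at codon
179 (mRNA position 535) — a pseudogene. The NG86 pair has one synonymous
difference over 8/3 synonymous sites (pS = 0.375), a Jukes–Cantor-corrected
dS of 0.5199 and dN = 0.

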