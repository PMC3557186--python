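"""Synthetic gene families with machine-readable truth.

Emulates a salmonid-like duplicated gene family: an ancestral three-exon gene
with pristine splice boundaries (MAG|GTAAGT donors, CAG|G acceptors), a
branch-point motif planted in each intron, an open reading frame ending in a
terminal stop and carrying a furin/PC cleavage motif (R-X-[KR]-R). The
ancestor is duplicated twice (paralogs 1a/1b/2a/2b by default), evolved along
a species tree under a K80-style per-site substitution process, and then
disrupted with planted events — indels (including frameshifting lengths),
premature termination codons, degraded splice boundaries and clade-diagnostic
substitutions — each of which is recorded as a :class:`TruthRecord`.

The truth table is the oracle against which every analysis stage is
validated. Event coordinates are recorded in the pre-edit (reference) frame
for indels and in post-edit mRNA codon units for PTCs; see each planting
function.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import dendropy
import numpy as np

from ._seq import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, TRANSITION
from .gene_models import GeneModel, splice, write_fasta, write_features

CLEAVAGE_CODONS = ("CGT", "AGT", "AAG", "CGT")  # -> R S K R, matches RX[KR]R
DONOR_INTRONIC = "GTAAGT"
ACCEPTOR_INTRONIC = "CAG"
BRANCH_MOTIF = "TTCTAAC"  # one concrete TNCTRAY instance

_BASES = ("A", "C", "G", "T")
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


class SimConfigError(ValueError):
    """Raised before any output when a configuration is inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated family.

    Defaults mirror the salmonid myostatin scenario: four paralogs from two
    rounds of duplication, three exons at the 370/371/381 nt scale, introns
    in the few-hundred-nt range, low per-branch substitution rates, and an
    indel length mixture containing the frameshifting lengths observed in
    real duplicate-gene decay (1, 4, 5, 7, 37 bp) alongside in-frame ones
    (48, 51 bp).
    """

    seed: int = 0
    n_species: int = 6
    species_tree: str | None = None  # newick; default balanced topology
    paralogs: int = 4
    exon_lengths: tuple[int, ...] = (370, 371, 381)
    intron_length_range: tuple[int, int] = (350, 950)
    branch_rate: float = 0.01  # expected substitutions/site per unit branch
    kappa: float = 2.0
    indel_prob: float = 0.3  # per gene
    indel_lengths: tuple[int, ...] = (1, 4, 5, 7, 37, 48, 51)
    insertion_fraction: float = 0.25
    splice_degrade_prob: float = 0.25  # per boundary
    ptc_prob: float = 0.25  # per gene
    diagnostic_sites: int = 2  # per paralog group, planted in a fixed clade
    diagnostic_clade: tuple[str, ...] | None = None  # default: first half

    def validate(self) -> None:
        if self.n_species < 2:
            raise SimConfigError("n_species must be >= 2")
        if self.paralogs < 1:
            raise SimConfigError("paralogs must be >= 1")
        if not self.exon_lengths or any(e <= 0 for e in self.exon_lengths):
            raise SimConfigError("exon lengths must be positive")
        if min(self.exon_lengths) < 24:
            raise SimConfigError("exons must be >= 24 nt to hold boundary contexts")
        if sum(self.exon_lengths) % 3:
            raise SimConfigError("total exon length must be a multiple of 3")
        lo, hi = self.intron_length_range
        if not (20 <= lo <= hi):
            raise SimConfigError("intron length range must satisfy 20 <= lo <= hi")
        for name in ("branch_rate", "kappa", "indel_prob",
                     "insertion_fraction", "splice_degrade_prob", "ptc_prob"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if any(l <= 0 for l in self.indel_lengths):
            raise SimConfigError("indel lengths must be positive")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(f"sp{i:02d}" for i in range(1, self.n_species + 1))

    @property
    def paralog_names(self) -> tuple[str, ...]:
        base = ["1a", "1b", "2a", "2b"]
        names = base[: self.paralogs]
        names += [f"x{i}" for i in range(5, self.paralogs + 1)]
        return tuple(names)


@dataclass(frozen=True)
class TruthRecord:
    event: str  # indel | ptc | splice_degradation | diagnostic
    gene_id: str
    paralog: str
    kind: str = ""  # deletion | insertion (indels only)
    feature: str = ""  # exon2, intron1_donor, ...
    start: int = 0  # 1-based gene coordinates, pre-edit frame
    end: int = 0
    length: int = 0
    codon_index: int = 0  # 1-based (PTC only)
    detail: str = ""
    carriers: str = ""  # comma-joined species (shared/diagnostic events)


TRUTH_COLUMNS = (
    "event", "gene_id", "paralog", "kind", "feature", "start", "end",
    "length", "codon_index", "detail", "carriers",
)


def _rng(seed: int, *tags) -> np.random.Generator:
    ent = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(t).encode()) for t in tags
    ]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(ent)))


# ---------------------------------------------------------------------------
# Substitution process
# ---------------------------------------------------------------------------


def mutate(
    seq: str,
    branch_length: float,
    kappa: float = 2.0,
    rng: np.random.Generator | int = 0,
) -> str:
    """Per-site substitution: each site mutates with probability equal to the
    branch length; a mutated site becomes its transition partner with weight
    kappa against weight 1 for each transversion (single-hit K80 sampling).
    Length is always preserved.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = _rng(int(rng), "mutate")
    if branch_length == 0 or not seq:
        return seq
    chars = list(seq)
    hit = np.flatnonzero(rng.random(len(chars)) < branch_length)
    if hit.size == 0:
        return seq
    p_ts = kappa / (kappa + 2.0)
    is_ts = rng.random(hit.size) < p_ts
    which_tv = rng.integers(0, 2, size=hit.size)
    for k, i in enumerate(hit):
        base = chars[i]
        if base not in TRANSITION:  # ambiguity symbols are left untouched
            continue
        chars[i] = TRANSITION[base] if is_ts[k] else _TRANSVERSIONS[base][which_tv[k]]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------


def build_ancestor(config: SimConfig) -> GeneModel:
    """Ancestral gene: open ORF, pristine boundaries, planted branch points."""
    config.validate()
    rng = _rng(config.seed, "ancestor")
    exon_lengths = config.exon_lengths
    mrna_len = sum(exon_lengths)
    n_codons = mrna_len // 3

    forced: dict[int, str] = {}

    def force(pos: int, ch: str, what: str) -> None:
        if forced.get(pos, ch) != ch:
            raise SimConfigError(
                f"conflicting sequence constraints at mRNA position {pos} ({what})"
            )
        forced[pos] = ch

    # Exonic boundary contexts: donor exon ends ...AAG (satisfies both the
    # MAG and RAG consensus dialects), acceptor exon starts G.
    cum = 0
    for length in exon_lengths[:-1]:
        cum += length
        for k, ch in enumerate("AAG"):
            force(cum - 3 + k, ch, "donor exonic context")
        force(cum, "G", "acceptor exonic context")

    # Cleavage motif, shifted codon-wise if it collides with a boundary.
    cc = int(0.63 * n_codons)
    motif = "".join(CLEAVAGE_CODONS)
    placed = False
    for shift in range(n_codons):
        for sign in (1, -1):
            start_codon = cc + sign * shift
            if not (1 <= start_codon < n_codons - len(CLEAVAGE_CODONS) - 1):
                continue
            p0 = 3 * start_codon
            if all(forced.get(p0 + k, motif[k]) == motif[k] for k in range(len(motif))):
                for k in range(len(motif)):
                    force(p0 + k, motif[k], "cleavage motif")
                placed = True
                break
        if placed:
            break
    if not placed:
        raise SimConfigError("could not place the cleavage motif")

    codons: list[str] = []
    for ci in range(n_codons):
        want = [forced.get(3 * ci + k) for k in range(3)]
        if ci == 0:
            codon = "ATG"
        elif ci == n_codons - 1:
            codon = "TAA"
        else:
            pool = [
                c for c in SENSE_CODONS
                if all(w is None or c[k] == w for k, w in enumerate(want))
            ]
            if not pool:
                raise SimConfigError(f"no sense codon satisfies constraints at codon {ci}")
            codon = pool[rng.integers(0, len(pool))]
        for k in range(3):
            if want[k] is not None and codon[k] != want[k]:
                raise SimConfigError(f"constraint clash at codon {ci}")
        codons.append(codon)
    mrna = "".join(codons)

    lo, hi = config.intron_length_range
    introns: list[str] = []
    for _ in range(len(exon_lengths) - 1):
        length = int(rng.integers(lo, hi + 1))
        body = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        body = DONOR_INTRONIC + body[6:-3] + ACCEPTOR_INTRONIC
        bp_pos = min(max(6, length - 145), length - 3 - len(BRANCH_MOTIF))
        body = body[:bp_pos] + BRANCH_MOTIF + body[bp_pos + len(BRANCH_MOTIF):]
        introns.append(body)

    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    moff = 0
    goff = 0
    for i, length in enumerate(exon_lengths):
        pieces.append(mrna[moff : moff + length])
        exons.append((goff, goff + length))
        goff += length
        moff += length
        if i < len(introns):
            pieces.append(introns[i])
            goff += len(introns[i])
    return GeneModel(
        gene_id="ANC",
        species="ancestor",
        paralog_label="other",
        sequence="".join(pieces),
        exons=tuple(exons),
        annotated_cds_start=0,
    )


# ---------------------------------------------------------------------------
# Event planting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndelSpec:
    kind: str  # "deletion" | "insertion"
    exon: int  # 1-based exon index
    offset: int  # 0-based offset within the exon
    length: int
    insert_seq: str | None = None
    allow_boundary: bool = False


def plant_indel(
    gene: GeneModel, spec: IndelSpec, rng: np.random.Generator | int = 0
) -> tuple[GeneModel, TruthRecord]:
    """Apply one exonic indel; exon intervals are shifted consistently.

    Truth coordinates are 1-based positions in the *pre-edit* gene (the
    reference frame shared with an unedited ortholog).
    """
    if isinstance(rng, (int, np.integer)):
        rng = _rng(int(rng), "indel")
    if not 1 <= spec.exon <= gene.n_exons:
        raise ValueError(f"exon {spec.exon} out of range")
    s, e = gene.exons[spec.exon - 1]
    pos = s + spec.offset
    from .structure_compare import left_normalize_deletion, left_normalize_insertion

    if spec.kind == "deletion":
        if pos < s or pos + spec.length > e:
            if not spec.allow_boundary:
                raise ValueError("deletion spans a feature boundary")
        new_seq = gene.sequence[:pos] + gene.sequence[pos + spec.length :]
        delta = -spec.length
        # truth coordinates: leftmost equivalent placement (matches map_indels)
        start = left_normalize_deletion(gene.sequence, pos + 1, spec.length)
        end = start + spec.length - 1
        detail = gene.sequence[start - 1 : end]
    elif spec.kind == "insertion":
        if not (s < pos < e) and not spec.allow_boundary:
            raise ValueError("insertion point not strictly inside the exon")
        ins = spec.insert_seq or "".join(
            _BASES[i] for i in rng.integers(0, 4, size=spec.length)
        )
        if len(ins) != spec.length:
            raise ValueError("insert_seq length != spec.length")
        new_seq = gene.sequence[:pos] + ins + gene.sequence[pos:]
        delta = spec.length
        flank, ins_norm = left_normalize_insertion(gene.sequence, pos, ins)
        detail = ins_norm
        start = end = flank  # flanking reference position
    else:
        raise ValueError(f"bad indel kind {spec.kind!r}")

    new_exons = []
    for i, (xs, xe) in enumerate(gene.exons, start=1):
        if i < spec.exon:
            new_exons.append((xs, xe))
        elif i == spec.exon:
            new_exons.append((xs, xe + delta))
        else:
            new_exons.append((xs + delta, xe + delta))
    edited = replace(gene, sequence=new_seq, exons=tuple(new_exons))
    truth = TruthRecord(
        event="indel",
        gene_id=gene.gene_id,
        paralog=gene.paralog_label,
        kind=spec.kind,
        feature=f"exon{spec.exon}",
        start=start,
        end=end,
        length=spec.length,
        detail=detail,
        carriers=gene.species,
    )
    return edited, truth


def plant_ptc(gene: GeneModel, codon_index: int) -> tuple[GeneModel, TruthRecord]:
    """Overwrite one mRNA codon with TAA (1-based codon index in the frame of
    the annotated CDS start of the *current* gene)."""
    spliced = splice(gene)
    start0 = gene.annotated_cds_start or 0
    mpos = start0 + 3 * (codon_index - 1)
    if mpos + 3 > len(spliced.mrna):
        raise ValueError(f"codon {codon_index} beyond mRNA")
    chars = list(gene.sequence)
    gpositions = [spliced.mrna_to_gene(mpos + k) for k in range(3)]
    old = "".join(chars[p] for p in gpositions)
    for p, ch in zip(gpositions, "TAA"):
        chars[p] = ch
    edited = replace(gene, sequence="".join(chars))
    truth = TruthRecord(
        event="ptc",
        gene_id=gene.gene_id,
        paralog=gene.paralog_label,
        feature=f"exon{spliced.exon_of_mrna_pos(mpos)}",
        start=gpositions[0] + 1,
        end=gpositions[-1] + 1,
        length=3,
        codon_index=codon_index,
        detail=f"{old}>TAA",
        carriers=gene.species,
    )
    return edited, truth


def degrade_splice_site(
    gene: GeneModel, intron_index: int, site: str
) -> tuple[GeneModel, TruthRecord]:
    """Break the critical dinucleotide of one boundary (GT->GC / AG->AC)."""
    if site not in {"donor", "acceptor"}:
        raise ValueError(f"bad site {site!r}")
    if not 1 <= intron_index <= len(gene.introns):
        raise ValueError(f"intron {intron_index} out of range")
    s, e = gene.introns[intron_index - 1]
    chars = list(gene.sequence)
    if site == "donor":
        pos = s + 1  # the T of GT
        old, new = chars[pos], "C"
    else:
        pos = e - 1  # the G of AG
        old, new = chars[pos], "C"
    chars[pos] = new
    edited = replace(gene, sequence="".join(chars))
    truth = TruthRecord(
        event="splice_degradation",
        gene_id=gene.gene_id,
        paralog=gene.paralog_label,
        feature=f"intron{intron_index}_{site}",
        start=pos + 1,
        end=pos + 1,
        length=1,
        detail=f"{old}>{new}",
        carriers=gene.species,
    )
    return edited, truth


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimBundle:
    config: SimConfig
    references: dict[str, GeneModel]  # paralog name -> pristine reference gene
    genes: list[GeneModel]
    truth: list[TruthRecord]

    def all_genes(self) -> list[GeneModel]:
        return [*self.references.values(), *self.genes]


def _default_tree_newick(species: tuple[str, ...]) -> str:
    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{species[lo]}:1"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):1"

    if len(species) == 1:
        return f"({species[0]}:1);"
    mid = len(species) // 2
    return f"({build(0, mid)},{build(mid, len(species))});"


def _evolve_along_tree(
    tree: dendropy.Tree,
    root_seq: str,
    rate: float,
    kappa: float,
    seed: int,
    pname: str,
) -> dict[str, str]:
    seqs: dict[str, str] = {}

    def clade_key(node) -> str:
        return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))

    def rec(node, seq: str) -> None:
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 1.0
            cseq = mutate(
                seq, rate * bl, kappa, _rng(seed, "subs", pname, clade_key(child))
            )
            if child.is_leaf():
                seqs[child.taxon.label] = cseq
            else:
                rec(child, cseq)

    rec(tree.seed_node, root_seq)
    return seqs


def simulate_family(
    config: SimConfig, out_dir: str | Path | None = None
) -> SimBundle:
    """Simulate one family; optionally write the FASTA/TSV/truth bundle.

    Fixed seed implies byte-identical output. The per-gene and per-event-type
    random streams are independent substreams of the master seed, so enabling
    one event type does not perturb the others.
    """
    config.validate()
    ancestor = build_ancestor(config)

    newick = config.species_tree or _default_tree_newick(config.species)
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    leaf_labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if config.species_tree is None and leaf_labels != sorted(config.species):
        raise AssertionError("default tree does not cover all species")

    rate, kappa = config.branch_rate, config.kappa
    # Two rounds of duplication: root -> {1,2} -> {1a,1b,2a,2b,...}.
    group_seq = {
        g: mutate(ancestor.sequence, rate, kappa, _rng(config.seed, "dup", g))
        for g in ("1", "2")
    }
    references: dict[str, GeneModel] = {}
    leaves: list[GeneModel] = []
    truth: list[TruthRecord] = []

    species_list = tuple(leaf_labels if config.species_tree else config.species)
    diag_clade = config.diagnostic_clade or species_list[: len(species_list) // 2]

    for pname in config.paralog_names:
        parent = group_seq.get(pname[0], ancestor.sequence)
        anc_seq = mutate(parent, rate, kappa, _rng(config.seed, "dup", pname))
        label = pname if pname in {"1a", "1b", "2a", "2b"} else "other"
        ref = replace(
            ancestor,
            gene_id=f"REF_{pname}",
            species="reference",
            paralog_label=label,
            sequence=anc_seq,
        )
        references[pname] = ref
        leaf_seqs = _evolve_along_tree(tree, anc_seq, rate, kappa, config.seed, pname)

        # Clade-diagnostic substitutions: same exonic position, same new base,
        # applied to every clade member; coordinates in the reference frame.
        diag_edits: list[tuple[int, str]] = []
        if config.diagnostic_sites and len(diag_clade) >= 1:
            drng = _rng(config.seed, "diag", pname)
            spliced_ref = splice(ref)
            for _ in range(config.diagnostic_sites):
                for _attempt in range(100):
                    exon_i = int(drng.integers(0, ref.n_exons))
                    xs, xe = ref.exons[exon_i]
                    if xe - xs <= 20:
                        continue
                    gpos = int(drng.integers(xs + 10, xe - 10))
                    old = ref.sequence[gpos]
                    cands = [b for b in _BASES if b != old]
                    drng.shuffle(cands)
                    pick = _diag_base(spliced_ref, gpos, cands)
                    if pick is None:
                        continue
                    diag_edits.append((gpos, pick))
                    truth.append(
                        TruthRecord(
                            event="diagnostic",
                            gene_id=f"*_{pname}",
                            paralog=label,
                            feature=f"exon{exon_i + 1}",
                            start=gpos + 1,
                            end=gpos + 1,
                            length=1,
                            detail=f"{old}>{pick}",
                            carriers=",".join(diag_clade),
                        )
                    )
                    break

        for sp in species_list:
            seq = leaf_seqs[sp]
            if sp in diag_clade:
                chars = list(seq)
                for gpos, base in diag_edits:
                    chars[gpos] = base
                seq = "".join(chars)
            gene = replace(
                ancestor,
                gene_id=f"{sp}_{pname}",
                species=sp,
                paralog_label=label,
                sequence=seq,
            )

            grng = _rng(config.seed, "events", pname, sp)
            # splice degradation per boundary
            for ii in range(1, gene.n_exons):
                for site in ("donor", "acceptor"):
                    if grng.random() < config.splice_degrade_prob:
                        gene, rec = degrade_splice_site(gene, ii, site)
                        truth.append(rec)
            # at most one indel per gene
            indel_guard: tuple[int, int] | None = None
            if grng.random() < config.indel_prob:
                kind = (
                    "insertion"
                    if grng.random() < config.insertion_fraction
                    else "deletion"
                )
                length = int(
                    config.indel_lengths[grng.integers(0, len(config.indel_lengths))]
                )
                exon_i = int(grng.integers(0, gene.n_exons)) + 1
                xs, xe = gene.exons[exon_i - 1]
                room = (xe - xs) - 20 - (length if kind == "deletion" else 0)
                if room > 0:
                    offset = 10 + int(grng.integers(0, room))
                    gene, rec = plant_indel(
                        gene,
                        IndelSpec(kind=kind, exon=exon_i, offset=offset, length=length),
                        grng,
                    )
                    truth.append(rec)
                    gpos = gene.exons[exon_i - 1][0] + offset
                    span = length if kind == "insertion" else 0
                    # events in one gene are kept apart so each is
                    # independently recoverable from an alignment
                    indel_guard = (gpos - 15, gpos + span + 15)
            # premature termination codon, kept clear of the exonic
            # boundary contexts (so it never masquerades as splice damage)
            # and of the gene's indel footprint
            if grng.random() < config.ptc_prob:
                spl = splice(gene)
                n_codons = len(spl.mrna) // 3
                blocked = _boundary_mrna_positions(gene)
                for _attempt in range(50):
                    ci = 10 + int(grng.integers(0, max(1, n_codons - 20)))
                    mpos = 3 * (ci - 1)
                    if blocked & set(range(mpos, mpos + 3)):
                        continue
                    gpos3 = [spl.mrna_to_gene(mpos + k) for k in range(3)]
                    if indel_guard is not None and any(
                        indel_guard[0] <= p <= indel_guard[1] for p in gpos3
                    ):
                        continue
                    gene, rec = plant_ptc(gene, ci)
                    truth.append(rec)
                    break
            leaves.append(gene)

    bundle = SimBundle(
        config=config, references=references, genes=leaves, truth=truth
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _boundary_mrna_positions(gene: GeneModel) -> set[int]:
    """0-based mRNA positions forming exonic splice contexts (MAG / G)."""
    blocked: set[int] = set()
    cum = 0
    for s, e in gene.exons[:-1]:
        cum += e - s
        blocked.update(range(cum - 3, cum + 1))
    return blocked


def _diag_base(spliced_ref, gpos: int, candidates: list[str]) -> str | None:
    """First candidate base that does not create an in-frame stop codon."""
    mpos = spliced_ref.gene_to_mrna(gpos)
    if mpos is None:
        return None
    start0 = spliced_ref.gene.annotated_cds_start or 0
    if mpos < start0:
        return candidates[0]
    ci = (mpos - start0) // 3
    c0 = start0 + 3 * ci
    codon = spliced_ref.mrna[c0 : c0 + 3]
    if len(codon) < 3:
        return candidates[0]
    k = mpos - c0
    for b in candidates:
        mutant = codon[:k] + b + codon[k + 1 :]
        if mutant not in STOP_CODONS:
            return b
    return None


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = bundle.all_genes()
    paths = {
        "fasta": out / "genes.fasta",
        "features": out / "features.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.txt",
    }
    write_fasta(genes, paths["fasta"])
    write_features(genes, paths["features"])
    lines = ["\t".join(TRUTH_COLUMNS)]
    for t in bundle.truth:
        lines.append(
            "\t".join(
                str(getattr(t, c)) for c in TRUTH_COLUMNS
            )
        )
    paths["truth"].write_text("\n".join(lines) + "\n")
    cfg = bundle.config
    cfg_lines = [
        f"{k} = {getattr(cfg, k)}"
        for k in (
            "seed", "n_species", "species_tree", "paralogs", "exon_lengths",
            "intron_length_range", "branch_rate", "kappa", "indel_prob",
            "indel_lengths", "insertion_fraction", "splice_degrade_prob",
            "ptc_prob", "diagnostic_sites", "diagnostic_clade",
        )
    ]
    paths["config"].write_text("\n".join(cfg_lines) + "\n")
    return paths


def read_truth(path: str | Path) -> list[TruthRecord]:
    records = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        f = line.split("\t")
        records.append(
            TruthRecord(
                event=f[0], gene_id=f[1], paralog=f[2], kind=f[3], feature=f[4],
                start=int(f[5]), end=int(f[6]), length=int(f[7]),
                codon_index=int(f[8]), detail=f[9],
                carriers=f[10] if len(f) > 10 else "",
            )
        )
    return records
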