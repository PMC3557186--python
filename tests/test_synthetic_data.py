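"""Simulator contracts: determinism, event planting, truth consistency."""

import numpy as np
import pytest

from dupfate.gene_models import splice
from dupfate.motif_scan import audit_splice_sites, find_branch_points
from dupfate.orf_analysis import INTACT, classify_status, scan_stops
from dupfate.structure_compare import map_indels, shared_missing_regions
from dupfate.aligner import star_msa
from dupfate.synthetic_data import (
    IndelSpec,
    SimConfig,
    SimConfigError,
    build_ancestor,
    degrade_splice_site,
    mutate,
    plant_indel,
    plant_ptc,
    simulate_family,
)

from conftest import compact_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_species=1),
            dict(exon_lengths=(0, 30, 30)),
            dict(exon_lengths=(30, 31, 30)),  # sum not a multiple of 3
            dict(intron_length_range=(5, 4)),
            dict(branch_rate=-1.0),
            dict(indel_lengths=(0,)),
        ],
    )
    def test_inconsistent_config_rejected_before_output(self, kwargs):
        with pytest.raises(SimConfigError):
            simulate_family(SimConfig(**kwargs))


class TestAncestor:
    def test_ancestor_is_intact_with_pristine_boundaries(self):
        anc = build_ancestor(SimConfig(seed=0, exon_lengths=(90, 93, 96),
                                       intron_length_range=(60, 90)))
        sp = splice(anc)
        rep = classify_status(sp, reference=anc)
        assert rep.status == INTACT
        assert rep.cleavage_site is not None
        for a in audit_splice_sites(sp):
            assert a.critical_intact
            assert all(c.overall_intact for c in a.per_consensus)
        bp = find_branch_points(sp)
        assert all(bp[i] for i in bp)  # a branch motif planted in every intron


class TestMutate:
    def test_zero_branch_length_is_identity(self):
        assert mutate("ACGTACGT", 0.0, rng=1) == "ACGTACGT"

    def test_fixed_seed_reproducible(self):
        s = "ACGT" * 500
        assert mutate(s, 0.1, rng=42) == mutate(s, 0.1, rng=42)

    def test_length_preserved(self):
        s = "ACGT" * 250
        assert len(mutate(s, 0.5, rng=3)) == len(s)

    def test_substitution_count_within_binomial_band(self):
        # p=0.05 over 10 kb: central 99% interval of Binomial(10000, 0.05)
        s = "A" * 10_000
        out = mutate(s, 0.05, rng=11)
        n = sum(1 for x, y in zip(s, out) if x != y)
        assert 445 <= n <= 557

    def test_large_branch_length_approaches_uniform_composition(self):
        s = "A" * 10_000
        out = mutate(s, 1.0, kappa=1.0, rng=5)
        freqs = {b: out.count(b) / len(out) for b in "ACGT"}
        # single-hit model at p=1: every site substituted away from A
        assert freqs["A"] < 0.01
        assert all(0.25 <= freqs[b] <= 0.42 for b in "CGT")


class TestPlanting:
    def _anc(self, seed=0):
        return build_ancestor(SimConfig(seed=seed, exon_lengths=(90, 93, 96),
                                        intron_length_range=(60, 90)))

    def test_deletion_spanning_boundary_rejected(self):
        anc = self._anc()
        with pytest.raises(ValueError, match="boundary"):
            plant_indel(anc, IndelSpec(kind="deletion", exon=1, offset=85, length=20))

    def test_degraded_donor_flags_exactly_that_boundary(self):
        anc = self._anc()
        edited, truth = degrade_splice_site(anc, 1, "donor")
        audits = {a.boundary_id: a for a in audit_splice_sites(splice(edited))}
        assert truth.feature == "intron1_donor"
        assert not audits["intron1_donor"].critical_intact
        assert audits["intron2_donor"].critical_intact
        assert audits["intron1_acceptor"].critical_intact

    def test_planted_stop_found_at_truth_codon(self):
        anc = self._anc()
        edited, truth = plant_ptc(anc, 40)
        stops = scan_stops(splice(edited).mrna, 1)
        assert (truth.codon_index, 3 * 39 + 1) in stops

    def test_shared_deletion_grouped_across_taxa(self):
        cfg = compact_config(seed=2, indel_prob=0.0, splice_degrade_prob=0.0,
                             ptc_prob=0.0, n_species=6, paralogs=1)
        bundle = simulate_family(cfg)
        ref = bundle.references["1a"]
        spec = IndelSpec(kind="deletion", exon=2, offset=20, length=51)
        edited = {}
        carriers = [g for g in bundle.genes[:4]]
        keep = bundle.genes[4:]
        for g in carriers:
            e, _ = plant_indel(g, spec)
            edited[e.gene_id] = e
        seqs = {ref.gene_id: ref.sequence}
        seqs.update({g.gene_id: g.sequence for g in keep})
        seqs.update({g.gene_id: g.sequence for g in edited.values()})
        msa = star_msa(seqs, center_id=ref.gene_id)
        events = map_indels(msa, ref.gene_id)
        report = shared_missing_regions(events, min_carriers=2,
                                        all_taxa=list(seqs))
        assert len(report) == 1
        assert report.iloc[0]["n_carriers"] == 4
        assert report.iloc[0]["length"] == 51


class TestSimulateFamily:
    def test_rate_zero_no_events_all_leaves_identical_and_intact(self):
        cfg = compact_config(seed=7, indel_prob=0.0, splice_degrade_prob=0.0,
                             ptc_prob=0.0)
        bundle = simulate_family(cfg)
        assert bundle.truth == []
        for g in bundle.genes:
            pname = g.gene_id.split("_")[1]
            assert g.sequence == bundle.references[pname].sequence
            rep = classify_status(splice(g), reference=bundle.references[pname])
            assert rep.status == INTACT
            for a in audit_splice_sites(splice(g)):
                assert all(c.overall_intact for c in a.per_consensus)

    def test_fixed_seed_bundles_are_byte_identical(self, tmp_path):
        cfg = compact_config(seed=3)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        simulate_family(cfg, out_dir=d1)
        simulate_family(cfg, out_dir=d2)
        for name in ("genes.fasta", "features.tsv", "truth.tsv", "config.txt"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        b1 = simulate_family(compact_config(seed=1, branch_rate=0.01))
        b2 = simulate_family(compact_config(seed=2, branch_rate=0.01))
        assert b1.genes[0].sequence != b2.genes[0].sequence

    def test_truth_coordinates_valid_in_emitted_models(self):
        bundle = simulate_family(compact_config(seed=11))
        by_id = {g.gene_id: g for g in bundle.genes}
        for t in bundle.truth:
            if t.event == "splice_degradation":
                g = by_id[t.gene_id]
                assert 1 <= t.start <= len(g.sequence)
            elif t.event == "ptc":
                g = by_id[t.gene_id]
                mrna = splice(g).mrna
                assert mrna[3 * (t.codon_index - 1) : 3 * t.codon_index + 2][:3] == "TAA"

    def test_single_planted_frameshift_deletion_detected_end_to_end(self):
        cfg = compact_config(seed=13, indel_prob=0.0, splice_degrade_prob=0.0,
                             ptc_prob=0.0, paralogs=1)
        bundle = simulate_family(cfg)
        ref = bundle.references["1a"]
        victim, rest = bundle.genes[0], bundle.genes[1:]
        edited, truth = plant_indel(
            victim, IndelSpec(kind="deletion", exon=1, offset=20, length=37)
        )
        seqs = {ref.gene_id: ref.sequence, edited.gene_id: edited.sequence}
        seqs.update({g.gene_id: g.sequence for g in rest})
        msa = star_msa(seqs, center_id=ref.gene_id)
        events = map_indels(
            msa, ref.gene_id, coding_mask=[(s + 1, e) for s, e in ref.exons]
        )
        (ev,) = events
        assert ev.frame_effect == "frameshift"
        assert ev.ref_interval == (truth.start, truth.end)
        rep = classify_status(splice(edited), reference=ref)
        assert rep.status == "PSEUDOGENE"
        for g in rest:
            assert classify_status(splice(g), reference=ref).status == INTACT
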