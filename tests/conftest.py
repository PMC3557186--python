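"""Shared fixtures: tiny hand-built gene models and compact simulations."""

import pytest

from dupfate.gene_models import GeneModel
from dupfate.synthetic_data import SimConfig


def toy_gene(
    gene_id: str = "g1",
    sequence: str = "ATGAAAGGTTTTTTCCCAAATAAGGG",
    exons=((0, 9), (15, 24)),
    **kwargs,
) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        species=kwargs.pop("species", "spX"),
        paralog_label=kwargs.pop("paralog_label", "other"),
        sequence=sequence,
        exons=exons,
        **kwargs,
    )


def compact_config(seed: int = 0, **overrides) -> SimConfig:
    """Small, fast study conditions used for exhaustive replicate checks."""
    base = dict(
        seed=seed,
        n_species=4,
        paralogs=4,
        exon_lengths=(90, 93, 96),
        intron_length_range=(80, 120),
        branch_rate=0.0,
        indel_prob=0.5,
        splice_degrade_prob=0.25,
        ptc_prob=0.3,
        diagnostic_sites=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def three_exon_gene() -> GeneModel:
    # 30 nt, exons at 1-6, 13-18, 25-30 in 1-based inclusive coordinates
    return GeneModel(
        gene_id="toy3",
        species="spX",
        paralog_label="1a",
        sequence="ATGAAAGTAAGTCAGTTTGTACAGTGATAA",
        exons=((0, 6), (12, 18), (24, 30)),
        annotated_cds_start=0,
    )
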