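"""Shared fixtures: toy references, a small simulated louse-style dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mthet import (
    GeneAnnotation,
    HeteroplasmyModel,
    ReferenceSequence,
    ReferenceSet,
    choose_planted_sites,
    generate_reference,
    louse_preset,
    simulate_pileup,
)


@pytest.fixture(scope="session")
def toy_reference() -> ReferenceSet:
    """Two tiny chromosomes with known homopolymer context.

    chr1 (linear, 40 bp) carries a run of four As at positions 11-14, so
    position 15 is a homopolymer-adjacent hotspot; chr2 is circular.
    """
    chr1 = "GCTAGCTAGC" + "AAAA" + "CGTACGTAGC" + "TTTTTTTTTT" + "GCGCGC"
    chr2 = "ACGTACGTACGTACGTACGT"
    return ReferenceSet(
        [
            ReferenceSequence("chr1", chr1, topology="linear"),
            ReferenceSequence("chr2", chr2, topology="circular"),
        ]
    )


@pytest.fixture(scope="session")
def protein_gene_reference() -> tuple[ReferenceSet, list[GeneAnnotation]]:
    """One chromosome with a plus-strand and a minus-strand protein gene.

    plusgene: positions 11-28 = ATG GGA CTA GAA TCA TTC (6 codons).
    minusgene: positions 41-58 hold the reverse complement of the same
    coding sequence, so both genes translate identically.
    """
    coding = "ATGGGACTAGAATCATTC"
    rc = coding[::-1].translate(str.maketrans("ACGT", "TGCA"))
    seq = "GCGCGCGCGC" + coding + "GCGCGCGCGCGC" + rc + "GCGCGCGC"
    ref = ReferenceSet([ReferenceSequence("mc1", seq, topology="circular")])
    anns = [
        GeneAnnotation("plusgene", "mc1", 11, 28, "+", "protein", 0, 5),
        GeneAnnotation("minusgene", "mc1", 41, 58, "-", "protein", 0, 5),
    ]
    assert seq[10:28] == coding and seq[40:58] == rc
    return ref, anns


@pytest.fixture(scope="session")
def louse_run():
    """A small fragmented-genome simulation with planted heteroplasmy, fitted.

    Three 3-4 kb circular minichromosomes at 2,000x, 30 sites planted at 5%
    frequency inside genes; returns (reference, annotations, pileup, truth,
    results).
    """
    cfg = louse_preset(seed=7, n_chroms=3, depth=2000.0)
    rng = np.random.default_rng(7)
    reference, annotations = generate_reference(cfg, rng)
    planted = choose_planted_sites(
        reference, 30, 0.05, rng, annotations=annotations
    )
    table, truth = simulate_pileup(reference, cfg, rng, planted_sites=planted)
    model = HeteroplasmyModel(
        table, reference, sample="sim1", annotations=annotations
    )
    return reference, annotations, table, truth, model.fit()
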