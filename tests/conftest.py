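from __future__ import annotations

import numpy as np
import pytest

from flnc_collapse.models import (
    GeneModel,
    ReferenceAnnotation,
    TranscriptModel,
)
from flnc_collapse import synthetic_data as sim


def make_tx(id, exons, strand="+", chrom="chr1"):
    return TranscriptModel(id=id, chrom=chrom, strand=strand, exons=tuple(exons))


@pytest.fixture
def toy_annotation() -> ReferenceAnnotation:
    """Two multi-exon genes on chr1 (+/-) and one on chr2."""
    g1 = GeneModel(
        id="geneA",
        chrom="chr1",
        strand="+",
        isoforms=(
            make_tx("geneA.t1", [(1000, 1200), (2000, 2200), (3000, 3300)]),
            make_tx("geneA.t2", [(1000, 1200), (3000, 3300)]),
        ),
    )
    g2 = GeneModel(
        id="geneB",
        chrom="chr1",
        strand="-",
        isoforms=(
            make_tx("geneB.t1", [(50_000, 50_400), (52_000, 52_500)], strand="-"),
        ),
    )
    g3 = GeneModel(
        id="geneC",
        chrom="chr2",
        strand="+",
        isoforms=(
            make_tx(
                "geneC.t1",
                [(5_000, 5_300), (6_000, 6_200), (7_000, 7_400)],
                chrom="chr2",
            ),
        ),
    )
    return ReferenceAnnotation(genes=(g1, g2, g3))


@pytest.fixture(scope="session")
def sim_annotation() -> ReferenceAnnotation:
    return sim.simulate_annotation(
        n_genes=40, exons_per_isoform=(2, 6), isoforms_per_gene=(1, 3), seed=7
    )
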