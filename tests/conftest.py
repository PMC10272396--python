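"""Shared fixtures: direct construction of small annotated genomes.

``build_genome`` assembles an AnnotatedGenome from explicit GH/transporter
ordinals by synthesizing one representative domain hit per class and running
the real annotation path, so every test exercises the same classification
code as production inputs.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pytest

from ghsynteny.annotation_io import (
    CIRCULAR,
    DomainHit,
    GeneRecord,
    Replicon,
    annotate,
    default_family_map,
)
from ghsynteny.synthetic_data import CLASS_ACCESSIONS


def build_genome(
    n_pegs: int,
    gh: Sequence[int] = (),
    strands: Optional[Mapping[int, str]] = None,
    topology: str = CIRCULAR,
    tr: Optional[Mapping[str, Sequence[int]]] = None,
    genome_id: str = "test",
    replicon_id: str = "chr",
):
    """Genome with GH genes at ``gh`` ordinals and transporters per ``tr``.

    ``strands`` maps ordinal -> "+"/"-" (default all forward).  A single
    ordinal may appear both in ``gh`` and a transporter class, producing a
    dual-annotated gene.
    """
    strands = strands or {}
    genes = tuple(
        GeneRecord(genome_id, replicon_id, o, strands.get(o, "+"), f"{genome_id}_p{o}")
        for o in range(1, n_pegs + 1)
    )
    replicon = Replicon(replicon_id, topology, genes)
    hits = [
        DomainHit(f"{genome_id}_p{o}", CLASS_ACCESSIONS["GH"], 100.0, (1, 300))
        for o in gh
    ]
    for tr_class, ordinals in (tr or {}).items():
        hits.extend(
            DomainHit(f"{genome_id}_p{o}", CLASS_ACCESSIONS[tr_class], 100.0, (1, 300))
            for o in ordinals
        )
    return annotate([replicon], hits, default_family_map(), genome_id=genome_id)


@pytest.fixture
def genome_builder():
    return build_genome
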