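"""GH:transporter colocalization (GH:TR clusters).

A GH gene is colocalized with a transporter class (MFS, ABC, PTS, or SUS)
when a gene of that class lies within a PEG-distance threshold (default 10)
on the same replicon.  Association is scored per GH gene -- the unit behind
"fraction of GH genes colocalized with at least one transporter" -- and per
class, recording the nearest transporter of each class.  Strand plays no
role; a gene that is both GH and transporter never partners itself.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .annotation_io import (
    CIRCULAR,
    GH,
    TRANSPORTER_CLASSES,
    AnnotatedGenome,
    GeneRecord,
)

__all__ = [
    "DEFAULT_COLOC_THRESHOLD",
    "GHTRAssociation",
    "ColocalizationSummary",
    "gh_tr_associations",
    "colocalization_summary",
    "write_colocalization_table",
]

DEFAULT_COLOC_THRESHOLD = 10


@dataclass(frozen=True)
class GHTRAssociation:
    """Nearest transporter of each class within the threshold, for one GH gene."""

    gene: GeneRecord
    partners: dict[str, tuple[str, int]]  # class -> (partner gene_id, PEG distance)

    @property
    def isolated(self) -> bool:
        return not self.partners

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self.partners)

    def distance(self, tr_class: str) -> Optional[int]:
        pair = self.partners.get(tr_class)
        return pair[1] if pair else None


@dataclass(frozen=True)
class ColocalizationSummary:
    """Genome-level GH:TR association summary at one threshold."""

    genome_id: str
    threshold: int
    n_gh: int
    n_colocalized: int
    per_class_counts: dict[str, int]  # GH genes associated with each class
    n_multi_class: int  # GH genes associated with > 1 class

    @property
    def colocalized_fraction(self) -> float:
        return self.n_colocalized / self.n_gh

    @property
    def classes_present(self) -> frozenset[str]:
        return frozenset(c for c, n in self.per_class_counts.items() if n > 0)


def _nearest_partner(
    gene: GeneRecord,
    members: list[GeneRecord],
    n_pegs: int,
    circular: bool,
) -> Optional[tuple[str, int]]:
    """Nearest member to ``gene`` (excluding itself); ties prefer upstream."""
    best: Optional[tuple[str, int]] = None
    for member in members:
        if member.gene_id == gene.gene_id:
            continue
        delta = abs(member.ordinal - gene.ordinal)
        dist = min(delta, n_pegs - delta) if circular else delta
        upstream = (gene.ordinal - member.ordinal) % n_pegs == dist if circular else (
            member.ordinal < gene.ordinal
        )
        if best is None or dist < best[1] or (dist == best[1] and upstream and not best[2]):
            best = (member.gene_id, dist, upstream)
    return (best[0], best[1]) if best else None


def gh_tr_associations(
    genome: AnnotatedGenome, threshold: int = DEFAULT_COLOC_THRESHOLD
) -> list[GHTRAssociation]:
    """Per GH gene, the nearest transporter of each class within the threshold."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    associations = []
    for replicon in genome.replicons:
        circular = replicon.topology == CIRCULAR
        gh_genes = genome.class_members(replicon.replicon_id, GH)
        tr_members = {
            cls: genome.class_members(replicon.replicon_id, cls)
            for cls in TRANSPORTER_CLASSES
        }
        for gene in gh_genes:
            partners: dict[str, tuple[str, int]] = {}
            for cls, members in tr_members.items():
                found = _nearest_partner(gene, members, replicon.n_pegs, circular)
                if found is not None and found[1] <= threshold:
                    partners[cls] = found
            associations.append(GHTRAssociation(gene, partners))
    return associations


def colocalization_summary(
    genome: AnnotatedGenome, threshold: int = DEFAULT_COLOC_THRESHOLD
) -> ColocalizationSummary:
    """Fraction of GH genes with >= 1 transporter partner, plus per-class counts."""
    if genome.n_gh == 0:
        raise ValueError(f"no GH genes in genome {genome.genome_id}")
    associations = gh_tr_associations(genome, threshold)
    per_class = {cls: 0 for cls in TRANSPORTER_CLASSES}
    n_coloc = 0
    n_multi = 0
    for assoc in associations:
        if not assoc.isolated:
            n_coloc += 1
        if len(assoc.partners) > 1:
            n_multi += 1
        for cls in assoc.partners:
            per_class[cls] += 1
    return ColocalizationSummary(
        genome.genome_id, threshold, len(associations), n_coloc, per_class, n_multi
    )


def write_colocalization_table(
    genome: AnnotatedGenome, path: str | Path, threshold: int = DEFAULT_COLOC_THRESHOLD
) -> None:
    """Per-GH-gene TSV of class-wise nearest-transporter distances."""
    associations = gh_tr_associations(genome, threshold)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "gh_gene_id",
                "replicon_id",
                "mfs_dist",
                "abc_dist",
                "pts_dist",
                "sus_dist",
                "isolated",
            ]
        )
        for assoc in associations:
            row = [assoc.gene.gene_id, assoc.gene.replicon_id]
            for cls in ("TR_MFS", "TR_ABC", "TR_PTS", "TR_SUS"):
                dist = assoc.distance(cls)
                row.append("NA" if dist is None else dist)
            row.append(str(assoc.isolated).lower())
            writer.writerow(row)
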