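"""Synteny scores, SSc histograms, and GH-gene clusters.

The synteny score (SSc) of a gene of interest is the shortest distance,
counted in protein-encoding genes (PEGs) upstream or downstream, to the next
gene of the same class on the same replicon.  Contiguous genes have SSc = 1.
A gene is called *clustered* when its SSc is at or below a threshold
(default 5); clusters are maximal chains of same-class genes in which every
consecutive gap stays within the threshold.

Distances never cross replicon boundaries.  On circular replicons they wrap
across the origin; on linear ones they do not, and a replicon carrying a
single gene of the class leaves that gene's SSc undefined.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation_io import GH, CIRCULAR, AnnotatedGenome, GeneRecord

__all__ = [
    "DEFAULT_CLUSTER_THRESHOLD",
    "DEFAULT_S_MAX",
    "SyntenyProfile",
    "ClusterRecord",
    "ssc_from_positions",
    "cluster_indices_from_positions",
    "synteny_scores",
    "find_clusters",
    "clustered_fraction",
    "write_synteny_table",
]

DEFAULT_CLUSTER_THRESHOLD = 5
DEFAULT_S_MAX = 20


# ---------------------------------------------------------------------------
# Position-level primitives (shared with the randomization null models)
# ---------------------------------------------------------------------------


def ssc_from_positions(positions: np.ndarray, n_pegs: int, circular: bool) -> np.ndarray:
    """Per-gene SSc for sorted 1-based ordinals on one replicon.

    Returns a float array aligned with ``positions``; undefined scores
    (single member, or any member count < 2) are NaN.
    """
    positions = np.asarray(positions)
    m = positions.size
    if m == 0:
        return np.empty(0)
    if m == 1:
        return np.full(1, np.nan)
    gaps = np.diff(positions).astype(float)
    if circular:
        wrap = float(n_pegs - positions[-1] + positions[0])
        # gap_before[i] pairs gene i with its predecessor, gap_after[i] with
        # its successor; the wrap gap closes the circle.
        gap_before = np.concatenate(([wrap], gaps))
        gap_after = np.concatenate((gaps, [wrap]))
        return np.minimum(gap_before, gap_after)
    gap_before = np.concatenate(([np.inf], gaps))
    gap_after = np.concatenate((gaps, [np.inf]))
    return np.minimum(gap_before, gap_after)


def cluster_indices_from_positions(
    positions: np.ndarray, n_pegs: int, circular: bool, threshold: int
) -> list[list[int]]:
    """Group indices of sorted ordinals into maximal chains with gaps <= threshold.

    On a circular replicon the wrap gap may join the last chain to the first;
    if every gap (including the wrap) is within the threshold, a single
    cluster holds all members.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    positions = np.asarray(positions)
    m = positions.size
    if m == 0:
        return []
    if m == 1:
        return [[0]]
    gaps = np.diff(positions)
    chains: list[list[int]] = [[0]]
    for i in range(1, m):
        if gaps[i - 1] <= threshold:
            chains[-1].append(i)
        else:
            chains.append([i])
    if circular:
        wrap = n_pegs - positions[-1] + positions[0]
        if wrap <= threshold and len(chains) > 1:
            chains[0] = chains.pop() + chains[0]
        elif wrap <= threshold and len(chains) == 1 and gaps.max(initial=0) <= threshold:
            pass  # fully connected circle: single cluster already
    return chains


# ---------------------------------------------------------------------------
# Genome-level API
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntenyProfile:
    """Per-gene SSc values plus the N_SSc / F_SSc histograms.

    ``n_ssc[s-1]`` counts genes with SSc exactly ``s`` for s = 1..s_max;
    ``f_ssc`` divides by the total number of class genes.  Genes with
    SSc > s_max or with undefined SSc are tallied separately so the parts
    always sum to ``n_genes``.
    """

    gene_class: str
    genes: tuple[GeneRecord, ...]
    ssc: tuple[Optional[int], ...]
    s_max: int

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.ssc):
            raise ValueError("genes and ssc must align")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_undefined(self) -> int:
        return sum(1 for s in self.ssc if s is None)

    @property
    def n_beyond(self) -> int:
        return sum(1 for s in self.ssc if s is not None and s > self.s_max)

    @property
    def n_ssc(self) -> np.ndarray:
        counts = np.zeros(self.s_max, dtype=int)
        for s in self.ssc:
            if s is not None and 1 <= s <= self.s_max:
                counts[s - 1] += 1
        return counts

    @property
    def f_ssc(self) -> np.ndarray:
        if self.n_genes == 0:
            return np.zeros(self.s_max)
        return self.n_ssc / self.n_genes

    def mean_ssc(self) -> float:
        """Mean of the defined SSc values (NaN when none are defined)."""
        defined = [s for s in self.ssc if s is not None]
        return float(np.mean(defined)) if defined else float("nan")

    def fraction_at_most(self, threshold: int) -> float:
        """Fraction of class genes with defined SSc <= threshold."""
        if self.n_genes == 0:
            raise ValueError("no genes in profile")
        return sum(1 for s in self.ssc if s is not None and s <= threshold) / self.n_genes


@dataclass(frozen=True)
class ClusterRecord:
    """A maximal chain of same-class genes with all consecutive gaps <= threshold."""

    replicon_id: str
    genes: tuple[GeneRecord, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("cluster must have >= 1 member")
        if len(self.gaps) != len(self.genes) - 1:
            raise ValueError("gaps must pair sequential members")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def span(self) -> int:
        """PEGs covered from first to last member along the chain."""
        return int(sum(self.gaps)) + 1

    @property
    def codirectional_pairs(self) -> int:
        return sum(
            1
            for a, b in zip(self.genes, self.genes[1:])
            if a.strand == b.strand
        )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)


def synteny_scores(
    genome: AnnotatedGenome, gene_class: str = GH, s_max: int = DEFAULT_S_MAX
) -> SyntenyProfile:
    """Compute per-gene SSc for all genes of a class, replicon by replicon."""
    genes: list[GeneRecord] = []
    sscs: list[Optional[int]] = []
    for replicon in genome.replicons:
        members = genome.class_members(replicon.replicon_id, gene_class)
        positions = np.array([g.ordinal for g in members], dtype=int)
        values = ssc_from_positions(
            positions, replicon.n_pegs, replicon.topology == CIRCULAR
        )
        genes.extend(members)
        sscs.extend(None if np.isnan(v) else int(v) for v in values)
    return SyntenyProfile(gene_class, tuple(genes), tuple(sscs), s_max)


def find_clusters(
    genome: AnnotatedGenome,
    threshold: int = DEFAULT_CLUSTER_THRESHOLD,
    gene_class: str = GH,
) -> list[ClusterRecord]:
    """Maximal same-class gene chains with every consecutive gap <= threshold.

    Singleton genes are returned as size-1 clusters.  On circular replicons a
    chain may wrap across the origin, in which case members are listed in
    chain order (crossing the origin once).
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    clusters: list[ClusterRecord] = []
    for replicon in genome.replicons:
        members = genome.class_members(replicon.replicon_id, gene_class)
        if not members:
            continue
        positions = np.array([g.ordinal for g in members], dtype=int)
        circular = replicon.topology == CIRCULAR
        for chain in cluster_indices_from_positions(
            positions, replicon.n_pegs, circular, threshold
        ):
            chain_genes = tuple(members[i] for i in chain)
            gaps = []
            for a, b in zip(chain_genes, chain_genes[1:]):
                d = b.ordinal - a.ordinal
                if d <= 0:  # wrapped pair
                    d += replicon.n_pegs
                gaps.append(d)
            clusters.append(ClusterRecord(replicon.replicon_id, chain_genes, tuple(gaps)))
    return clusters


def clustered_fraction(
    genome: AnnotatedGenome,
    threshold: int = DEFAULT_CLUSTER_THRESHOLD,
    gene_class: str = GH,
) -> float:
    """Fraction of class genes with defined SSc <= threshold.

    Genes with undefined SSc (sole member of their replicon) count as
    unclustered.  Raises if the genome carries no genes of the class.
    """
    profile = synteny_scores(genome, gene_class)
    if profile.n_genes == 0:
        raise ValueError(f"no {gene_class} genes in genome {genome.genome_id}")
    return profile.fraction_at_most(threshold)


def write_synteny_table(
    genome: AnnotatedGenome,
    path: str | Path,
    threshold: int = DEFAULT_CLUSTER_THRESHOLD,
    gene_class: str = GH,
) -> None:
    """Per-gene TSV: gene_id, replicon_id, ordinal, strand, SSc, cluster_id, cluster_size."""
    profile = synteny_scores(genome, gene_class)
    clusters = find_clusters(genome, threshold, gene_class)
    membership: dict[str, tuple[int, int]] = {}
    for idx, cluster in enumerate(clusters, 1):
        for gid in cluster.gene_ids:
            membership[gid] = (idx, cluster.size)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene_id", "replicon_id", "ordinal", "strand", "SSc", "cluster_id", "cluster_size"]
        )
        for gene, ssc in zip(profile.genes, profile.ssc):
            cid, csize = membership.get(gene.gene_id, ("NA", "NA"))
            writer.writerow(
                [
                    gene.gene_id,
                    gene.replicon_id,
                    gene.ordinal,
                    gene.strand,
                    "NA" if ssc is None else ssc,
                    cid,
                    csize,
                ]
            )
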