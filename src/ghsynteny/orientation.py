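"""Strand codirectionality of sequential same-class gene pairs.

Two sequential genes are codirectional when they lie on the same coding
strand, a prerequisite for transcriptional read-through and operon formation.
Without selection on orientation, each sequential pair is codirectional with
probability 1/2, so the observed codirectional count among n pairs is
compared with Binomial(n, 1/2) by an exact two-sided test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .annotation_io import GH, CIRCULAR, AnnotatedGenome, GeneRecord
from .synteny_core import DEFAULT_CLUSTER_THRESHOLD

__all__ = [
    "SequentialPair",
    "PairSet",
    "sequential_pairs",
    "codirectional_fraction",
    "binomial_codirectionality_test",
]


@dataclass(frozen=True)
class SequentialPair:
    gene_a: GeneRecord
    gene_b: GeneRecord
    gap: int  # PEG distance from a to b along the replicon; the pair's SSc

    @property
    def codirectional(self) -> bool:
        return self.gene_a.strand == self.gene_b.strand


@dataclass(frozen=True)
class PairSet:
    """Sequential same-class pairs, optionally restricted to clustered ones.

    On a circular replicon with >= 2 class members the wrap pair (last member
    back to the first) is included, so the replicon contributes as many pairs
    as members; a linear replicon contributes members - 1.
    """

    pairs: tuple[SequentialPair, ...]
    restriction: str  # "all" or "clustered"
    threshold: Optional[int] = None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_codirectional(self) -> int:
        return sum(1 for p in self.pairs if p.codirectional)


def sequential_pairs(
    genome: AnnotatedGenome,
    restriction: str = "all",
    threshold: int = DEFAULT_CLUSTER_THRESHOLD,
    gene_class: str = GH,
) -> PairSet:
    """All sequential same-class pairs, or only those with gap <= threshold.

    The gap between sequential members is exactly the pair's SSc, so the
    "clustered" restriction keeps the pairs inside SSc <= threshold clusters.
    """
    if restriction not in ("all", "clustered"):
        raise ValueError(f"unknown restriction {restriction!r}")
    pairs: list[SequentialPair] = []
    for replicon in genome.replicons:
        members = genome.class_members(replicon.replicon_id, gene_class)
        if len(members) < 2:
            continue
        sequential = list(zip(members, members[1:], strict=False))
        if replicon.topology == CIRCULAR:
            sequential.append((members[-1], members[0]))
        for a, b in sequential:
            gap = b.ordinal - a.ordinal
            if gap <= 0:
                gap += replicon.n_pegs
            pairs.append(SequentialPair(a, b, gap))
    if restriction == "clustered":
        pairs = [p for p in pairs if p.gap <= threshold]
    return PairSet(
        tuple(pairs), restriction, threshold if restriction == "clustered" else None
    )


def codirectional_fraction(pairs: PairSet) -> float:
    """Fraction of sequential pairs sharing the coding strand."""
    if len(pairs) == 0:
        raise ValueError("no pairs")
    return pairs.n_codirectional / len(pairs)


def binomial_codirectionality_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (equal-tail doubling, capped at 1).

    ``k`` codirectional pairs out of ``n`` sequential pairs are tested
    against Binomial(n, p0): p = 2 * min(P[X <= k], P[X >= k]).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))
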