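"""Randomized-genome null models for GH-gene clustering statistics.

The null hypothesis throughout is uniform placement: the observed number of
GH genes is scattered uniformly at random (without replacement) over the
observed number of PEG slots, and every synteny statistic is recomputed on
each randomized genome.  Nulls matched to a real genome preserve its
replicon partition (each replicon keeps its own PEG and GH-gene counts).

For the count of contiguous genes (SSc = 1) the null expectation also has a
hypergeometric closed form, used as an independent cross-check of the
Monte-Carlo machinery: conditional on one gene's position, its flanking
slots are occupied by the remaining genes hypergeometrically, so on a
circular replicon

    E[#SSc=1] = g * (1 - (N-g)(N-g-1) / ((N-1)(N-2)))

for g genes among N slots, with end positions handled separately on linear
replicons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .annotation_io import CIRCULAR, LINEAR, TOPOLOGIES, AnnotatedGenome, GH
from .synteny_core import DEFAULT_S_MAX, ssc_from_positions

__all__ = [
    "NullSpec",
    "NullDistribution",
    "StatResult",
    "randomize_placement",
    "simulate_null",
    "expected_adjacent_count",
    "matched_null",
    "empirical_p",
    "normality_summary",
]

DEFAULT_ITERATIONS = 5000
DEFAULT_THRESHOLDS = (1, 5, 10)


@dataclass(frozen=True)
class NullSpec:
    """Conditions for one batch of genome randomizations."""

    n_pegs: int
    n_gh: int
    topology: str = CIRCULAR
    iterations: int = DEFAULT_ITERATIONS
    seed: int = 0
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    s_max: int = DEFAULT_S_MAX

    def __post_init__(self) -> None:
        if not 1 <= self.n_gh <= self.n_pegs:
            raise ValueError(
                f"need 1 <= n_gh <= n_pegs, got n_gh={self.n_gh}, n_pegs={self.n_pegs}"
            )
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class StatResult:
    """A named statistic, optionally with a p-value."""

    name: str
    value: float
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


class NullDistribution:
    """Per-iteration statistics from a batch of genome randomizations.

    ``stats`` maps a statistic name ("mean_ssc", "adjacent_count",
    "clustered_fraction_<t>") to its per-iteration values; ``n_ssc`` holds
    the full SSc histogram per iteration (iterations x s_max).
    """

    def __init__(
        self,
        spec_echo: dict,
        stat_values: dict[str, np.ndarray],
        n_ssc: Optional[np.ndarray] = None,
    ):
        iterations = spec_echo["iterations"]
        for name, values in stat_values.items():
            if len(values) != iterations:
                raise ValueError(f"{name}: expected {iterations} values")
        self.spec_echo = dict(spec_echo)
        self.stats = {k: np.asarray(v, dtype=float) for k, v in stat_values.items()}
        self.n_ssc = None if n_ssc is None else np.asarray(n_ssc)

    @property
    def iterations(self) -> int:
        return self.spec_echo["iterations"]

    def values(self, statistic: Optional[str] = None) -> np.ndarray:
        if statistic is None:
            if len(self.stats) != 1:
                raise ValueError(
                    f"statistic must be named; available: {sorted(self.stats)}"
                )
            statistic = next(iter(self.stats))
        return self.stats[statistic]

    def summary(self, statistic: Optional[str] = None) -> dict[str, float]:
        v = self.values(statistic)
        q = np.nanquantile(v, [0.025, 0.5, 0.975])
        return {
            "mean": float(np.nanmean(v)),
            "sd": float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0,
            "q2.5": float(q[0]),
            "median": float(q[1]),
            "q97.5": float(q[2]),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": self.spec_echo,
            "values": {k: v.tolist() for k, v in self.stats.items()},
            "summaries": {k: self.summary(k) for k in self.stats},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def randomize_placement(n_pegs: int, n_gh: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n_gh distinct 1-based ordinals uniformly from 1..n_pegs (sorted)."""
    if not 1 <= n_gh <= n_pegs:
        raise ValueError(f"need 1 <= n_gh <= n_pegs, got {n_gh} > {n_pegs}")
    positions = rng.choice(n_pegs, size=n_gh, replace=False)
    positions.sort()
    return positions + 1


def _iteration_stats(
    replicon_specs: Sequence[tuple[int, int, bool]],
    iterations: int,
    rng: np.random.Generator,
    thresholds: Sequence[int],
    s_max: int,
):
    """Shared Monte-Carlo core for simulate_null and matched_null."""
    total_gh = sum(g for _, g, _ in replicon_specs)
    mean_ssc = np.empty(iterations)
    adjacent = np.zeros(iterations)
    n_ssc = np.zeros((iterations, s_max), dtype=np.int64)
    clustered = {t: np.zeros(iterations) for t in thresholds}
    for i in range(iterations):
        all_ssc: list[np.ndarray] = []
        for n_pegs, n_gh, circular in replicon_specs:
            if n_gh == 0:
                continue
            positions = randomize_placement(n_pegs, n_gh, rng)
            all_ssc.append(ssc_from_positions(positions, n_pegs, circular))
        ssc = np.concatenate(all_ssc) if all_ssc else np.empty(0)
        defined = ssc[np.isfinite(ssc)]
        mean_ssc[i] = defined.mean() if defined.size else np.nan
        if defined.size:
            ints = defined.astype(np.int64)
            adjacent[i] = np.count_nonzero(ints == 1)
            binned = ints[ints <= s_max]
            if binned.size:
                n_ssc[i] = np.bincount(binned, minlength=s_max + 1)[1:]
            for t in thresholds:
                clustered[t][i] = np.count_nonzero(ints <= t) / total_gh
    stat_values = {"mean_ssc": mean_ssc, "adjacent_count": adjacent}
    for t in thresholds:
        stat_values[f"clustered_fraction_{t}"] = clustered[t]
    return stat_values, n_ssc


def simulate_null(spec: NullSpec) -> NullDistribution:
    """Monte-Carlo null distribution of synteny statistics under uniform placement."""
    rng = np.random.default_rng(spec.seed)
    stat_values, n_ssc = _iteration_stats(
        [(spec.n_pegs, spec.n_gh, spec.topology == CIRCULAR)],
        spec.iterations,
        rng,
        spec.thresholds,
        spec.s_max,
    )
    echo = {
        "n_pegs": spec.n_pegs,
        "n_gh": spec.n_gh,
        "topology": spec.topology,
        "iterations": spec.iterations,
        "seed": spec.seed,
        "thresholds": list(spec.thresholds),
        "s_max": spec.s_max,
    }
    return NullDistribution(echo, stat_values, n_ssc)


def expected_adjacent_count(n_pegs: int, n_gh: int, topology: str = CIRCULAR) -> float:
    """Exact E[#genes with SSc = 1] under uniform placement (closed form).

    Conditional on a focal gene's slot, the other g-1 genes occupy the
    remaining N-1 slots uniformly, so the probability that both flanking
    slots are free is (N-g)(N-g-1)/((N-1)(N-2)); summing the complement over
    genes gives the expectation.  Linear replicons treat the two end slots,
    which have a single neighbor, separately.
    """
    n, g = n_pegs, n_gh
    if g < 2:
        raise ValueError("need at least 2 genes for adjacency")
    if g > n:
        raise ValueError("n_gh cannot exceed n_pegs")
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    if n == 2:
        return 2.0  # both slots occupied and mutually adjacent
    p_both_free = (n - g) * (n - g - 1) / ((n - 1) * (n - 2))
    if topology == CIRCULAR:
        return g * (1.0 - p_both_free)
    p_one_free = (n - g) / (n - 1)  # single neighbor of an end slot
    # A focal gene sits in a uniformly chosen slot: 2 of n slots are ends.
    return g * ((2 / n) * (1.0 - p_one_free) + ((n - 2) / n) * (1.0 - p_both_free))


def matched_null(
    genome: AnnotatedGenome,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    s_max: int = DEFAULT_S_MAX,
    gene_class: str = GH,
) -> NullDistribution:
    """Null matched to a real genome: same replicon sizes and per-replicon gene counts."""
    replicon_specs = []
    total = 0
    for replicon in genome.replicons:
        n_class = len(genome.class_members(replicon.replicon_id, gene_class))
        total += n_class
        replicon_specs.append((replicon.n_pegs, n_class, replicon.topology == CIRCULAR))
    if total < 2:
        raise ValueError(
            f"genome {genome.genome_id} has {total} {gene_class} gene(s); need >= 2"
        )
    rng = np.random.default_rng(seed)
    stat_values, n_ssc = _iteration_stats(
        replicon_specs, iterations, rng, tuple(thresholds), s_max
    )
    echo = {
        "genome_id": genome.genome_id,
        "replicons": [
            {"n_pegs": n, "n_class": g, "topology": CIRCULAR if c else LINEAR}
            for n, g, c in replicon_specs
        ],
        "iterations": iterations,
        "seed": seed,
        "thresholds": list(thresholds),
        "s_max": s_max,
    }
    return NullDistribution(echo, stat_values, n_ssc)


def empirical_p(
    observed: float,
    null: NullDistribution,
    side: str = "greater",
    statistic: Optional[str] = None,
) -> float:
    """Add-one empirical p-value: (1 + #null at least as extreme) / (1 + iterations)."""
    if side not in ("greater", "less"):
        raise ValueError(f"side must be 'greater' or 'less', got {side!r}")
    values = null.values(statistic)
    if len(values) == 0:
        raise ValueError("empty null distribution")
    if side == "greater":
        extreme = np.count_nonzero(values >= observed)
    else:
        extreme = np.count_nonzero(values <= observed)
    return (1 + int(extreme)) / (1 + len(values))


def normality_summary(
    values: Sequence[float], seed: int = 0, max_n: int = 5000
) -> StatResult:
    """Shapiro-Wilk normality test of a statistic's sampling distribution.

    Samples larger than ``max_n`` are subsampled without replacement (seeded)
    before testing, since the test's p-value is unreliable for huge n.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise ValueError("need at least 3 finite values")
    if np.ptp(arr) == 0:
        raise ValueError("zero variance: all values identical")
    if arr.size > max_n:
        rng = np.random.default_rng(seed)
        arr = rng.choice(arr, size=max_n, replace=False)
    w, p = stats.shapiro(arr)
    return StatResult("shapiro_wilk", float(w), float(p))
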