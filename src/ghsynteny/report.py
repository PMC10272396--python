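"""Per-genome summaries, pipeline orchestration, and genome maps.

``summarize_genome`` gathers every statistic the upstream modules compute --
GH-gene frequency, clustered counts/fractions at SSc thresholds 1, 5 and 10,
strand codirectionality, transporter colocalization, and (optionally) a
matched randomization null -- into one record.  ``run_pipeline`` applies it
over a configured set of genomes and writes per-genome and cohort tables;
``render_genome_map`` draws the GH-gene track of a genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from . import annotation_io, colocalization, lineage_stats, null_models, orientation, synteny_core
from .annotation_io import GH, TRANSPORTER_CLASSES, AnnotatedGenome

__all__ = [
    "GenomeSummary",
    "PipelineResult",
    "format_percent",
    "summarize_genome",
    "run_pipeline",
    "render_genome_map",
]

REPORT_THRESHOLDS = (1, 5, 10)


def format_percent(fraction: float) -> str:
    """Report a fraction as a percentage truncated to one decimal (e.g. "2.2%").

    Truncation (not rounding) matches the reporting convention of the
    worked summaries this package reproduces; the full-precision value is
    always kept alongside the display string.
    """
    if math.isnan(fraction):
        return "NA"
    return f"{math.floor(fraction * 1000 + 1e-9) / 10:.1f}%"


@dataclass(frozen=True)
class GenomeSummary:
    """All per-genome statistics in one record."""

    genome_id: str
    n_pegs: int
    n_gh: int
    f_gh: float  # percent, full precision
    n_clustered: dict[int, int]  # threshold -> count of GH genes with SSc <= t
    f_clustered: dict[int, float]  # threshold -> fraction
    n_pairs_all: int
    n_pairs_clustered: int
    f_codir_all: Optional[float]
    f_codir_clustered: Optional[float]
    binom_p: Optional[float]
    colocalized_fraction: Optional[float]
    per_class_counts: dict[str, int]
    n_tr: dict[str, int]
    null_median_clustered: Optional[float] = None
    null_empirical_p: Optional[float] = None

    @property
    def f_gh_display(self) -> str:
        return format_percent(self.f_gh / 100.0)

    def to_row(self) -> dict:
        """Flat dict for the cohort table."""
        row = {
            "genome_id": self.genome_id,
            "n_pegs": self.n_pegs,
            "n_gh": self.n_gh,
            "f_gh": self.f_gh,
            "f_gh_display": self.f_gh_display,
        }
        for t in sorted(self.n_clustered):
            row[f"n_clustered_{t}"] = self.n_clustered[t]
            row[f"f_clustered_{t}"] = self.f_clustered[t]
        row["n_clustered"] = self.n_clustered.get(5)
        row["f_clustered"] = self.f_clustered.get(5)
        row.update(
            n_pairs_all=self.n_pairs_all,
            n_pairs_clustered=self.n_pairs_clustered,
            f_codir_all=self.f_codir_all,
            f_codir_clustered=self.f_codir_clustered,
            binom_p=self.binom_p,
            colocalized_fraction=self.colocalized_fraction,
        )
        for cls in TRANSPORTER_CLASSES:
            row[f"n_{cls.lower()}"] = self.n_tr.get(cls, 0)
            row[f"n_gh_with_{cls.lower()}"] = self.per_class_counts.get(cls, 0)
        row["null_median_clustered"] = self.null_median_clustered
        row["null_empirical_p"] = self.null_empirical_p
        return row


def summarize_genome(
    genome: AnnotatedGenome,
    thresholds: Sequence[int] = REPORT_THRESHOLDS,
    cluster_threshold: int = synteny_core.DEFAULT_CLUSTER_THRESHOLD,
    coloc_threshold: int = colocalization.DEFAULT_COLOC_THRESHOLD,
    null_iterations: int = 0,
    seed: int = 0,
) -> GenomeSummary:
    """Compute the full per-genome statistics record.

    With ``null_iterations > 0`` and >= 2 GH genes, a matched randomization
    null of the clustered fraction (at ``cluster_threshold``) is added:
    its median and the add-one empirical p of the observed fraction.
    """
    if genome.n_pegs == 0:
        raise ValueError(f"genome {genome.genome_id} has no PEGs")
    f_gh = 100.0 * genome.n_gh / genome.n_pegs
    n_clustered: dict[int, int] = {}
    f_clustered: dict[int, float] = {}
    if genome.n_gh > 0:
        profile = synteny_core.synteny_scores(genome, GH)
        for t in thresholds:
            frac = profile.fraction_at_most(t)
            f_clustered[t] = frac
            n_clustered[t] = round(frac * genome.n_gh)
    else:
        for t in thresholds:
            n_clustered[t] = 0
            f_clustered[t] = float("nan")

    pairs_all = orientation.sequential_pairs(genome, "all", gene_class=GH)
    pairs_clustered = orientation.sequential_pairs(
        genome, "clustered", threshold=cluster_threshold, gene_class=GH
    )
    f_codir_all = (
        orientation.codirectional_fraction(pairs_all) if len(pairs_all) else None
    )
    f_codir_clustered = (
        orientation.codirectional_fraction(pairs_clustered)
        if len(pairs_clustered)
        else None
    )
    binom_p = (
        orientation.binomial_codirectionality_test(
            pairs_clustered.n_codirectional, len(pairs_clustered)
        )
        if len(pairs_clustered)
        else None
    )

    if genome.n_gh > 0:
        coloc = colocalization.colocalization_summary(genome, coloc_threshold)
        coloc_fraction: Optional[float] = coloc.colocalized_fraction
        per_class = dict(coloc.per_class_counts)
    else:
        coloc_fraction = None
        per_class = {cls: 0 for cls in TRANSPORTER_CLASSES}

    null_median = None
    null_p = None
    if null_iterations > 0 and genome.n_gh >= 2:
        null = null_models.matched_null(
            genome, iterations=null_iterations, seed=seed,
            thresholds=(cluster_threshold,),
        )
        stat = f"clustered_fraction_{cluster_threshold}"
        null_median = null.summary(stat)["median"]
        null_p = null_models.empirical_p(
            f_clustered[cluster_threshold], null, side="greater", statistic=stat
        )

    return GenomeSummary(
        genome_id=genome.genome_id,
        n_pegs=genome.n_pegs,
        n_gh=genome.n_gh,
        f_gh=f_gh,
        n_clustered=n_clustered,
        f_clustered=f_clustered,
        n_pairs_all=len(pairs_all),
        n_pairs_clustered=len(pairs_clustered),
        f_codir_all=f_codir_all,
        f_codir_clustered=f_codir_clustered,
        binom_p=binom_p,
        colocalized_fraction=coloc_fraction,
        per_class_counts=per_class,
        n_tr=dict(genome.n_tr),
        null_median_clustered=null_median,
        null_empirical_p=null_p,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    out_dir: Path
    summaries: list[GenomeSummary] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)  # (genome_id, message)

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_config(config: Union[str, Path, Mapping]) -> dict:
    if isinstance(config, (str, Path)):
        loaded = yaml.safe_load(Path(config).read_text())
        if not isinstance(loaded, Mapping):
            raise ValueError(f"{config}: pipeline config must be a mapping")
        return dict(loaded)
    return dict(config)


def run_pipeline(config: Union[str, Path, Mapping]) -> PipelineResult:
    """Run annotation -> synteny -> orientation -> colocalization over a cohort.

    Config keys: ``out_dir``; ``genomes`` (list of mappings with ``features``
    and ``hits`` paths, their dialects, optional ``genome_id``, ``topology``
    and taxonomy/environment labels); optional ``family_map`` path;
    ``cluster_threshold`` (default 5), ``coloc_threshold`` (default 10),
    ``min_score`` (default 25), ``null_iterations`` (default 0), ``seed``.

    All input paths are verified before any computation.  A genome that
    fails mid-run is logged and skipped; the result records the failures.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg["out_dir"])
    genome_cfgs = cfg.get("genomes", [])
    if not genome_cfgs:
        raise ValueError("config lists no genomes")
    missing = []
    for gc in genome_cfgs:
        for key in ("features", "hits"):
            if key not in gc:
                raise ValueError(f"genome config missing {key!r}: {gc}")
            if not Path(gc[key]).exists():
                missing.append(str(gc[key]))
    if cfg.get("family_map") and not Path(cfg["family_map"]).exists():
        missing.append(str(cfg["family_map"]))
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")

    cluster_threshold = int(cfg.get("cluster_threshold", synteny_core.DEFAULT_CLUSTER_THRESHOLD))
    coloc_threshold = int(cfg.get("coloc_threshold", colocalization.DEFAULT_COLOC_THRESHOLD))
    min_score = float(cfg.get("min_score", 25.0))
    null_iterations = int(cfg.get("null_iterations", 0))
    seed = int(cfg.get("seed", 0))
    family_map = (
        annotation_io.load_family_map(cfg["family_map"])
        if cfg.get("family_map")
        else annotation_io.default_family_map()
    )

    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"seed\t{seed}",
        f"cluster_threshold\t{cluster_threshold}",
        f"coloc_threshold\t{coloc_threshold}",
        f"min_score\t{min_score}",
        f"null_iterations\t{null_iterations}",
    ]
    result = PipelineResult(out_dir=out_dir)
    rows = []
    for index, gc in enumerate(genome_cfgs):
        gid = gc.get("genome_id") or Path(gc["features"]).stem.replace(".features", "")
        try:
            genome_id, replicons = annotation_io.read_feature_table(
                gc["features"],
                dialect=gc.get("features_dialect", "tsv"),
                genome_id=gc.get("genome_id"),
                default_topology=gc.get("topology", annotation_io.CIRCULAR),
            )
            hits = annotation_io.read_domain_hits(
                gc["hits"], dialect=gc.get("hits_dialect", "tsv"), min_score=min_score
            )
            genome = annotation_io.annotate(
                replicons, hits, family_map, genome_id=genome_id, strict=False
            )
            for replicon in genome.replicons:
                log_lines.append(
                    f"topology\t{genome.genome_id}\t{replicon.replicon_id}\t{replicon.topology}"
                )
            summary = summarize_genome(
                genome,
                cluster_threshold=cluster_threshold,
                coloc_threshold=coloc_threshold,
                null_iterations=null_iterations,
                seed=seed + index,
            )
            if genome.n_gh:
                synteny_core.write_synteny_table(
                    genome, out_dir / f"{genome.genome_id}.synteny.tsv", cluster_threshold
                )
                colocalization.write_colocalization_table(
                    genome, out_dir / f"{genome.genome_id}.coloc.tsv", coloc_threshold
                )
            if null_iterations > 0 and genome.n_gh >= 2:
                null = null_models.matched_null(
                    genome, iterations=null_iterations, seed=seed + index
                )
                null.to_json(out_dir / f"{genome.genome_id}.null.json")
            result.summaries.append(summary)
            row = summary.to_row()
            for label in ("phylum", "genus", "environment"):
                row[label] = gc.get(label, "NA")
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            result.failures.append((gid, str(exc)))
            log_lines.append(f"error\t{gid}\t{exc}")
    if rows:
        cohort = pd.DataFrame(rows)
        lineage_stats.write_cohort(cohort, out_dir / "cohort.tsv")
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return result


# ---------------------------------------------------------------------------
# Genome maps
# ---------------------------------------------------------------------------


def render_genome_map(
    genome: AnnotatedGenome,
    path: str | Path,
    coloc_threshold: int = colocalization.DEFAULT_COLOC_THRESHOLD,
) -> Path:
    """Draw one horizontal track per replicon: GH genes colored by strand,
    transporters in gray, and GH:TR associations as connecting stems."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_tracks = max(1, len(genome.replicons))
    fig, axes = plt.subplots(
        n_tracks, 1, figsize=(10, 1.8 * n_tracks), squeeze=False
    )
    associations = (
        colocalization.gh_tr_associations(genome, coloc_threshold)
        if genome.n_gh
        else []
    )
    partner_ids = {
        pid for assoc in associations for pid, _ in assoc.partners.values()
    }
    assoc_gh = {a.gene.gene_id for a in associations if not a.isolated}
    for ax, replicon in zip(axes.ravel(), genome.replicons or [None]):
        if replicon is None:
            ax.set_axis_off()
            continue
        ax.hlines(0, 1, replicon.n_pegs, color="0.8", lw=2, zorder=1)
        for gene in replicon.genes:
            ann = genome.annotation(gene.gene_id)
            if ann.is_gh:
                y = 1.0 if gene.strand == "+" else -1.0
                ax.vlines(gene.ordinal, 0, y, color="tab:orange", lw=1.5, zorder=3)
                if gene.gene_id in assoc_gh:
                    ax.plot(gene.ordinal, y, "v" if y < 0 else "^",
                            color="tab:red", ms=4, zorder=4)
            elif ann.is_transporter or gene.gene_id in partner_ids:
                ax.vlines(gene.ordinal, -0.5, 0.5, color="0.5", lw=1.0, zorder=2)
        ax.set_xlim(0, replicon.n_pegs + 1)
        ax.set_ylim(-1.4, 1.4)
        ax.set_yticks([])
        ax.set_xlabel("PEG ordinal")
        ax.set_title(f"{genome.genome_id} / {replicon.replicon_id} ({replicon.topology})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
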