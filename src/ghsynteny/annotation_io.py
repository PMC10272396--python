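"""Gene feature tables, protein-domain hits, and GH/transporter classification.

The analyses in this package work on gene *order*, not nucleotide coordinates:
each protein-encoding gene (PEG) is reduced to its ordinal rank along its
replicon plus its coding strand.  This module reads the two inputs every
downstream step depends on -- an ordered gene feature table (GFF3 or TSV) and
a protein-domain hit table (hmmscan ``--domtblout`` or TSV) -- and classifies
each gene into glycoside hydrolase (GH) and sugar-transporter classes through
a configurable accession-to-family map.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "GH",
    "TR_MFS",
    "TR_ABC",
    "TR_PTS",
    "TR_SUS",
    "OTHER",
    "TRANSPORTER_CLASSES",
    "FUNCTIONAL_CLASSES",
    "AnnotationError",
    "FamilyMap",
    "DomainHit",
    "GeneRecord",
    "Replicon",
    "GeneAnnotation",
    "AnnotatedGenome",
    "default_family_map",
    "load_family_map",
    "read_feature_table",
    "read_domain_hits",
    "annotate",
    "write_feature_table",
    "write_domain_hits",
]

# ---------------------------------------------------------------------------
# Functional classes
# ---------------------------------------------------------------------------

GH = "GH"
TR_MFS = "TR_MFS"
TR_ABC = "TR_ABC"
TR_PTS = "TR_PTS"
TR_SUS = "TR_SUS"
OTHER = "OTHER"

TRANSPORTER_CLASSES = (TR_MFS, TR_ABC, TR_PTS, TR_SUS)
FUNCTIONAL_CLASSES = (GH,) + TRANSPORTER_CLASSES + (OTHER,)

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

CIRCULAR = "circular"
LINEAR = "linear"
TOPOLOGIES = (CIRCULAR, LINEAR)


class AnnotationError(ValueError):
    """Raised for malformed inputs or inconsistent annotations."""


def strip_accession_version(accession: str) -> str:
    """Normalize a Pfam-style accession by removing a trailing ``.NN`` version."""
    head, sep, tail = accession.partition(".")
    return head if sep and tail.isdigit() else accession


# ---------------------------------------------------------------------------
# Family map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyEntry:
    accession: str
    family_label: str
    functional_class: str

    def __post_init__(self) -> None:
        if not self.family_label:
            raise AnnotationError(f"{self.accession}: empty family_label")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise AnnotationError(
                f"{self.accession}: unknown functional class "
                f"{self.functional_class!r}; expected one of {FUNCTIONAL_CLASSES}"
            )


class FamilyMap:
    """Accession -> (family label, functional class) lookup table.

    Accessions are stored version-stripped; queries are normalized the same
    way, so ``PF00128.15`` and ``PF00128`` resolve identically.
    """

    def __init__(self, entries: Iterable[FamilyEntry]):
        self._entries: dict[str, FamilyEntry] = {}
        for entry in entries:
            acc = strip_accession_version(entry.accession)
            if acc in self._entries:
                raise AnnotationError(f"duplicate accession {acc!r} in family map")
            self._entries[acc] = FamilyEntry(acc, entry.family_label, entry.functional_class)

    def __contains__(self, accession: str) -> bool:
        return strip_accession_version(accession) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, accession: str) -> Optional[FamilyEntry]:
        return self._entries.get(strip_accession_version(accession))

    def family(self, accession: str) -> Optional[str]:
        entry = self.get(accession)
        return entry.family_label if entry else None

    def functional_class(self, accession: str) -> str:
        """Class of an accession; unmapped accessions are OTHER."""
        entry = self.get(accession)
        return entry.functional_class if entry else OTHER

    def entries(self) -> Sequence[FamilyEntry]:
        return tuple(self._entries.values())

    def updated(self, entries: Iterable[FamilyEntry]) -> "FamilyMap":
        """New map with ``entries`` overriding or extending this one."""
        merged = dict(self._entries)
        seen: set[str] = set()
        for entry in entries:
            acc = strip_accession_version(entry.accession)
            if acc in seen:
                raise AnnotationError(f"duplicate accession {acc!r} in family map")
            seen.add(acc)
            merged[acc] = FamilyEntry(acc, entry.family_label, entry.functional_class)
        return FamilyMap(merged.values())


#: Built-in defaults.  GH entries are the ten most common GH domains in
#: bacterial genomes; the four TR_SUS entries are the TonB-dependent
#: transporter (SusC-like) barrel, plug, NTE and STN domains.  The MFS, ABC
#: and PTS entries are provisional single-domain placeholders (the canonical
#: Pfam domain of each transporter superfamily) and are expected to be
#: extended via a user-supplied map for real annotation work.
_DEFAULT_ENTRIES = [
    FamilyEntry("PF00128", "GH13", GH),
    FamilyEntry("PF00232", "GH1", GH),
    FamilyEntry("PF00933", "GH3", GH),
    FamilyEntry("PF00150", "GH5", GH),
    FamilyEntry("PF01270", "GH8", GH),
    FamilyEntry("PF01341", "GH6", GH),
    FamilyEntry("PF00331", "GH10", GH),
    FamilyEntry("PF00457", "GH11", GH),
    FamilyEntry("PF00704", "GH18", GH),
    FamilyEntry("PF00182", "GH19", GH),
    FamilyEntry("PF00593", "TBDT_barrel", TR_SUS),
    FamilyEntry("PF07715", "TBDT_plug", TR_SUS),
    FamilyEntry("PF13715", "TBDT_NTE", TR_SUS),
    FamilyEntry("PF07660", "TBDT_STN", TR_SUS),
    FamilyEntry("PF07690", "MFS_1", TR_MFS),
    FamilyEntry("PF00005", "ABC_tran", TR_ABC),
    FamilyEntry("PF02378", "PTS_EIIC", TR_PTS),
    FamilyEntry("PF00358", "PTS_EIIA", TR_PTS),
]


def default_family_map() -> FamilyMap:
    """The built-in accession map (see ``_DEFAULT_ENTRIES``)."""
    return FamilyMap(_DEFAULT_ENTRIES)


def load_family_map(path: str | Path, include_defaults: bool = True) -> FamilyMap:
    """Load a family map from YAML or TSV.

    YAML holds a list of ``{accession, family_label, functional_class}``
    mappings (or a top-level ``families:`` key with that list).  TSV needs a
    header with those three column names.  File entries override the built-in
    defaults unless ``include_defaults`` is false.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        entries = _family_entries_from_yaml(path)
    else:
        entries = _family_entries_from_tsv(path)
    if include_defaults:
        return default_family_map().updated(entries)
    return FamilyMap(entries)


def _family_entries_from_yaml(path: Path) -> list[FamilyEntry]:
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise AnnotationError(f"{path}: malformed YAML family map: {exc}") from exc
    if isinstance(data, Mapping) and "families" in data:
        data = data["families"]
    if data is None:
        return []
    if not isinstance(data, list):
        raise AnnotationError(f"{path}: expected a list of family entries")
    entries = []
    for i, row in enumerate(data, 1):
        if not isinstance(row, Mapping):
            raise AnnotationError(f"{path}: entry {i} is not a mapping")
        try:
            entries.append(
                FamilyEntry(
                    str(row["accession"]),
                    str(row["family_label"]),
                    str(row["functional_class"]),
                )
            )
        except KeyError as exc:
            raise AnnotationError(f"{path}: entry {i} missing key {exc}") from exc
    return entries


def _family_entries_from_tsv(path: Path) -> list[FamilyEntry]:
    entries = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"accession", "family_label", "functional_class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise AnnotationError(
                f"{path}: family-map TSV must have columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, 2):
            try:
                entries.append(
                    FamilyEntry(
                        row["accession"], row["family_label"], row["functional_class"]
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
    return entries


# ---------------------------------------------------------------------------
# Gene records and domain hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One protein-encoding gene, positioned by ordinal rank on its replicon."""

    genome_id: str
    replicon_id: str
    ordinal: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise AnnotationError(f"{self.gene_id}: ordinal must be >= 1")
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"{self.gene_id}: unknown strand symbol {self.strand!r}"
            )


@dataclass(frozen=True)
class Replicon:
    """An ordered list of genes on one chromosome or plasmid."""

    replicon_id: str
    topology: str
    genes: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise AnnotationError(f"unknown topology {self.topology!r}")
        ordinals = [g.ordinal for g in self.genes]
        if ordinals != list(range(1, len(ordinals) + 1)):
            dupes = {o for o in ordinals if ordinals.count(o) > 1}
            if dupes:
                raise AnnotationError(
                    f"{self.replicon_id}: duplicate ordinal {sorted(dupes)[0]}"
                )
            raise AnnotationError(
                f"{self.replicon_id}: ordinals must be consecutive from 1"
            )

    @property
    def n_pegs(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class DomainHit:
    """One profile match on one protein."""

    gene_id: str
    accession: str
    score: float
    region: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.score):
            raise AnnotationError(f"{self.gene_id}: non-finite score")
        if self.region is not None and self.region[0] > self.region[1]:
            raise AnnotationError(f"{self.gene_id}: region start > end")


# ---------------------------------------------------------------------------
# Feature-table input
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ["genome_id", "replicon_id", "ordinal", "strand", "gene_id", "topology"]


def read_feature_table(
    path: str | Path,
    dialect: str = "tsv",
    genome_id: Optional[str] = None,
    default_topology: str = CIRCULAR,
) -> tuple[str, list[Replicon]]:
    """Read an ordered gene table; returns ``(genome_id, replicons)``.

    ``dialect`` is ``"tsv"`` (explicit ordinals and topology, header
    ``genome_id  replicon_id  ordinal  strand  gene_id  topology``) or
    ``"gff3"`` (CDS features only; ordinals are assigned by coordinate order
    per seqid; topology comes from ``default_topology`` since GFF3 does not
    carry it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_feature_tsv(path)
    if dialect == "gff3":
        return _read_feature_gff3(path, genome_id, default_topology)
    raise AnnotationError(f"unknown feature dialect {dialect!r}")


def _read_feature_tsv(path: Path) -> tuple[str, list[Replicon]]:
    rows: dict[str, list[tuple[int, str, str, str]]] = {}
    topologies: dict[str, str] = {}
    genome_ids: set[str] = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not set(_FEATURE_COLUMNS).issubset(reader.fieldnames):
            raise AnnotationError(
                f"{path}: feature TSV must have columns {_FEATURE_COLUMNS}"
            )
        for lineno, row in enumerate(reader, 2):
            try:
                ordinal = int(row["ordinal"])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: bad ordinal {row['ordinal']!r}"
                ) from exc
            rid = row["replicon_id"]
            genome_ids.add(row["genome_id"])
            topologies.setdefault(rid, row["topology"])
            rows.setdefault(rid, []).append(
                (ordinal, row["strand"], row["gene_id"], row["genome_id"])
            )
    if len(genome_ids) != 1:
        raise AnnotationError(f"{path}: expected exactly one genome_id, found {sorted(genome_ids)}")
    gid = genome_ids.pop()
    replicons = []
    for rid, recs in rows.items():
        recs.sort(key=lambda r: r[0])
        ordinals = [r[0] for r in recs]
        for o in ordinals:
            if ordinals.count(o) > 1:
                raise AnnotationError(f"{path}: {rid}: duplicate ordinal {o}")
        if ordinals != list(range(1, len(ordinals) + 1)):
            raise AnnotationError(f"{path}: {rid}: gapped ordinals (must run 1..n)")
        genes = tuple(
            GeneRecord(gid, rid, o, strand, gene_id)
            for o, strand, gene_id, _ in recs
        )
        replicons.append(Replicon(rid, topologies[rid], genes))
    return gid, replicons


def _read_feature_gff3(
    path: Path, genome_id: Optional[str], default_topology: str
) -> tuple[str, list[Replicon]]:
    import gffutils

    gid = genome_id or path.stem
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_replicon: dict[str, list] = {}
    for feature in db.features_of_type("CDS"):
        by_replicon.setdefault(feature.seqid, []).append(feature)
    replicons = []
    for rid in sorted(by_replicon):
        feats = sorted(by_replicon[rid], key=lambda f: (f.start, f.end))
        genes = []
        for ordinal, feat in enumerate(feats, 1):
            if feat.strand not in STRANDS:
                raise AnnotationError(
                    f"{path}: {feat.id}: unknown strand symbol {feat.strand!r}"
                )
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            genes.append(GeneRecord(gid, rid, ordinal, feat.strand, gene_id))
        replicons.append(Replicon(rid, default_topology, tuple(genes)))
    return gid, replicons


# ---------------------------------------------------------------------------
# Domain-hit input
# ---------------------------------------------------------------------------


def read_domain_hits(
    path: str | Path, dialect: str = "tsv", min_score: float = 25.0
) -> list[DomainHit]:
    """Read domain hits from hmmscan ``--domtblout`` or the TSV dialect.

    Accession versions are stripped and hits scoring below ``min_score`` bits
    are dropped.  The TSV dialect has header
    ``gene_id  accession  score  ali_from  ali_to``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if min_score < 0:
        raise AnnotationError(f"min_score must be >= 0, got {min_score}")
    if dialect == "domtblout":
        hits = _read_domtblout(path)
    elif dialect == "tsv":
        hits = _read_hits_tsv(path)
    else:
        raise AnnotationError(f"unknown hit dialect {dialect!r}")
    return [h for h in hits if h.score >= min_score]


def _read_domtblout(path: Path) -> list[DomainHit]:
    # hmmscan per-domain table: target (profile) name + accession in columns
    # 1-2, query (protein) name in column 4, per-domain bit score in column
    # 14, alignment coordinates in columns 18-19 (1-based).
    hits = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 19:
                raise AnnotationError(f"{path}: line {lineno}: too few columns")
            try:
                hits.append(
                    DomainHit(
                        gene_id=fields[3],
                        accession=strip_accession_version(fields[1]),
                        score=float(fields[13]),
                        region=(int(fields[17]), int(fields[18])),
                    )
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def _read_hits_tsv(path: Path) -> list[DomainHit]:
    hits = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"gene_id", "accession", "score"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise AnnotationError(
                f"{path}: hit TSV must have columns gene_id, accession, score"
                " (optionally ali_from, ali_to)"
            )
        for lineno, row in enumerate(reader, 2):
            try:
                region = None
                if row.get("ali_from") not in (None, "", "NA"):
                    region = (int(row["ali_from"]), int(row["ali_to"]))
                hits.append(
                    DomainHit(
                        gene_id=row["gene_id"],
                        accession=strip_accession_version(row["accession"]),
                        score=float(row["score"]),
                        region=region,
                    )
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """Class membership of one gene, derived from its domain hits."""

    is_gh: bool = False
    gh_families: frozenset[str] = frozenset()
    tr_classes: frozenset[str] = frozenset()

    @property
    def is_transporter(self) -> bool:
        return bool(self.tr_classes)


class AnnotatedGenome:
    """Ordered replicons plus per-gene GH / transporter annotation.

    A gene carrying both a GH-class and a transporter-class domain keeps both
    flags: it counts as a GH gene for synteny and as a transporter for other
    genes' colocalization (never for its own).
    """

    def __init__(
        self,
        genome_id: str,
        replicons: Sequence[Replicon],
        annotations: Mapping[str, GeneAnnotation],
        hits_by_gene: Optional[Mapping[str, Sequence[DomainHit]]] = None,
    ):
        ids = [r.replicon_id for r in replicons]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate replicon_id")
        self.genome_id = genome_id
        self.replicons: tuple[Replicon, ...] = tuple(replicons)
        self._by_id = {r.replicon_id: r for r in self.replicons}
        all_genes = {g.gene_id for r in self.replicons for g in r.genes}
        if len(all_genes) != sum(r.n_pegs for r in self.replicons):
            raise AnnotationError("duplicate gene_id across replicons")
        unknown = set(annotations) - all_genes
        if unknown:
            raise AnnotationError(f"annotation for unknown gene(s): {sorted(unknown)[:3]}")
        self.annotations = {
            g.gene_id: annotations.get(g.gene_id, GeneAnnotation())
            for r in self.replicons
            for g in r.genes
        }
        self.hits_by_gene = {k: tuple(v) for k, v in (hits_by_gene or {}).items()}
        # cached counts
        self.n_pegs = sum(r.n_pegs for r in self.replicons)
        self.n_gh = sum(1 for a in self.annotations.values() if a.is_gh)
        self.n_tr = {
            cls: sum(1 for a in self.annotations.values() if cls in a.tr_classes)
            for cls in TRANSPORTER_CLASSES
        }

    def replicon(self, replicon_id: str) -> Replicon:
        return self._by_id[replicon_id]

    def annotation(self, gene_id: str) -> GeneAnnotation:
        return self.annotations[gene_id]

    def in_class(self, gene: GeneRecord, gene_class: str) -> bool:
        ann = self.annotations[gene.gene_id]
        if gene_class == GH:
            return ann.is_gh
        return gene_class in ann.tr_classes

    def class_members(self, replicon_id: str, gene_class: str) -> list[GeneRecord]:
        """Genes of a class on one replicon, in ordinal order."""
        return [
            g for g in self._by_id[replicon_id].genes if self.in_class(g, gene_class)
        ]

    @property
    def f_gh(self) -> float:
        """Fraction of PEGs that are GH genes."""
        return self.n_gh / self.n_pegs if self.n_pegs else 0.0


def annotate(
    replicons: Sequence[Replicon],
    hits: Sequence[DomainHit],
    family_map: Optional[FamilyMap] = None,
    genome_id: Optional[str] = None,
    strict: bool = True,
) -> AnnotatedGenome:
    """Attach GH/transporter classes to genes from their domain hits.

    A gene is a GH gene iff at least one of its hits maps to a GH-class
    accession; its transporter classes are the set of TR_* classes among its
    hits.  In strict mode a hit naming an unknown gene is an error; otherwise
    such hits are ignored.
    """
    family_map = family_map or default_family_map()
    if genome_id is None:
        genome_id = replicons[0].genes[0].genome_id if replicons and replicons[0].genes else ""
    known = {g.gene_id for r in replicons for g in r.genes}
    hits_by_gene: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.gene_id not in known:
            if strict:
                raise AnnotationError(f"hit references unknown gene_id {hit.gene_id!r}")
            continue
        hits_by_gene.setdefault(hit.gene_id, []).append(hit)
    annotations: dict[str, GeneAnnotation] = {}
    for gene_id, gene_hits in hits_by_gene.items():
        families = set()
        tr_classes = set()
        for hit in gene_hits:
            cls = family_map.functional_class(hit.accession)
            if cls == GH:
                families.add(family_map.family(hit.accession))
            elif cls in TRANSPORTER_CLASSES:
                tr_classes.add(cls)
        annotations[gene_id] = GeneAnnotation(
            is_gh=bool(families),
            gh_families=frozenset(families),
            tr_classes=frozenset(tr_classes),
        )
    return AnnotatedGenome(genome_id, replicons, annotations, hits_by_gene)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_feature_table(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write the gene table in the TSV feature dialect (round-trippable)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_FEATURE_COLUMNS)
        for replicon in genome.replicons:
            for gene in replicon.genes:
                writer.writerow(
                    [
                        genome.genome_id,
                        replicon.replicon_id,
                        gene.ordinal,
                        gene.strand,
                        gene.gene_id,
                        replicon.topology,
                    ]
                )


def write_domain_hits(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write the hits used at annotation time in the TSV hit dialect."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "accession", "score", "ali_from", "ali_to"])
        for replicon in genome.replicons:
            for gene in replicon.genes:
                for hit in genome.hits_by_gene.get(gene.gene_id, ()):
                    ali_from = hit.region[0] if hit.region else "NA"
                    ali_to = hit.region[1] if hit.region else "NA"
                    writer.writerow(
                        [hit.gene_id, hit.accession, f"{hit.score:g}", ali_from, ali_to]
                    )
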