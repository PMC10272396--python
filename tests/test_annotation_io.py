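"""Feature/hit parsing and GH-transporter classification."""

import textwrap

import pytest

from ghsynteny import annotation_io as aio


# ---------------------------------------------------------------------------
# Family map
# ---------------------------------------------------------------------------


class TestFamilyMap:
    def test_default_map_classifies_known_accessions(self):
        fmap = aio.default_family_map()
        assert fmap.family("PF00128") == "GH13"
        assert fmap.functional_class("PF00128") == aio.GH
        assert fmap.functional_class("PF00593") == aio.TR_SUS
        assert fmap.functional_class("PF07715") == aio.TR_SUS

    def test_version_suffix_is_ignored_on_lookup(self):
        fmap = aio.default_family_map()
        assert fmap.family("PF00128.15") == "GH13"

    def test_unknown_accession_is_other(self):
        assert aio.default_family_map().functional_class("PF99999") == aio.OTHER

    def test_override_changes_class(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "accession\tfamily_label\tfunctional_class\nPF00128\tnot_gh\tOTHER\n"
        )
        fmap = aio.load_family_map(path)
        assert fmap.functional_class("PF00128") == aio.OTHER
        # defaults survive for non-overridden accessions
        assert fmap.functional_class("PF00232") == aio.GH

    def test_yaml_map_roundtrip(self, tmp_path):
        path = tmp_path / "map.yaml"
        path.write_text(
            textwrap.dedent(
                """
                families:
                  - accession: PF12345
                    family_label: GH99
                    functional_class: GH
                """
            )
        )
        fmap = aio.load_family_map(path)
        assert fmap.family("PF12345") == "GH99"
        assert len(fmap) == len(aio.default_family_map()) + 1

    def test_invalid_class_rejected(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "accession\tfamily_label\tfunctional_class\nPF1\tx\tTRANSPORTER\n"
        )
        with pytest.raises(aio.AnnotationError, match="functional class"):
            aio.load_family_map(path)

    def test_duplicate_accession_rejected(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "accession\tfamily_label\tfunctional_class\n"
            "PF1\tx\tGH\nPF1.3\ty\tGH\n"
        )
        with pytest.raises(aio.AnnotationError, match="duplicate accession"):
            aio.load_family_map(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            aio.load_family_map(tmp_path / "absent.tsv")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    contig1\tsrc\tgene\t100\t400\t.\t+\t.\tID=gene1
    contig1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=cds1
    contig1\tsrc\tCDS\t500\t800\t.\t+\t0\tID=cds2
    contig1\tsrc\tCDS\t900\t1200\t.\t-\t0\tID=cds3
    """
)


class TestFeatureTables:
    def test_gff3_cds_ordinals_by_coordinate(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(GFF3)
        gid, replicons = aio.read_feature_table(path, dialect="gff3", genome_id="G")
        assert gid == "G"
        (rep,) = replicons
        assert [g.ordinal for g in rep.genes] == [1, 2, 3]
        assert [g.strand for g in rep.genes] == ["+", "+", "-"]
        assert [g.gene_id for g in rep.genes] == ["cds1", "cds2", "cds3"]
        # non-CDS features are ignored
        assert rep.n_pegs == 3

    def test_tsv_roundtrip_matches_gff3(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(GFF3)
        _, from_gff = aio.read_feature_table(gff, dialect="gff3", genome_id="G")
        tsv = tmp_path / "g.tsv"
        header = "genome_id\treplicon_id\tordinal\tstrand\tgene_id\ttopology\n"
        rows = "".join(
            f"G\tcontig1\t{g.ordinal}\t{g.strand}\t{g.gene_id}\tcircular\n"
            for g in from_gff[0].genes
        )
        tsv.write_text(header + rows)
        _, from_tsv = aio.read_feature_table(tsv, dialect="tsv")
        assert from_tsv[0].genes == from_gff[0].genes

    def test_duplicate_ordinal_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "genome_id\treplicon_id\tordinal\tstrand\tgene_id\ttopology\n"
            "G\tc\t1\t+\ta\tcircular\nG\tc\t2\t+\tb\tcircular\nG\tc\t2\t-\tc\tcircular\n"
        )
        with pytest.raises(aio.AnnotationError, match="duplicate ordinal"):
            aio.read_feature_table(path)

    def test_gapped_ordinals_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "genome_id\treplicon_id\tordinal\tstrand\tgene_id\ttopology\n"
            "G\tc\t1\t+\ta\tcircular\nG\tc\t3\t+\tb\tcircular\n"
        )
        with pytest.raises(aio.AnnotationError, match="gapped"):
            aio.read_feature_table(path)

    def test_unknown_strand_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "genome_id\treplicon_id\tordinal\tstrand\tgene_id\ttopology\n"
            "G\tc\t1\t?\ta\tcircular\n"
        )
        with pytest.raises(aio.AnnotationError, match="strand"):
            aio.read_feature_table(path)


# ---------------------------------------------------------------------------
# Domain hits
# ---------------------------------------------------------------------------

DOMTBL_ROW = (
    "Alpha-amylase  PF00128.15  350  geneA  -  512  1.2e-50  170.0  0.1  1  1"
    "  2e-48  3.1e-45  160.0  0.1  5  340  10  350  8  355  0.98  amylase\n"
)


class TestDomainHits:
    def test_domtblout_row_parses_and_strips_version(self, tmp_path):
        path = tmp_path / "h.domtbl"
        path.write_text("# comment line\n" + DOMTBL_ROW)
        (hit,) = aio.read_domain_hits(path, dialect="domtblout")
        assert hit.gene_id == "geneA"
        assert hit.accession == "PF00128"
        assert hit.score == pytest.approx(160.0)
        assert hit.region == (10, 350)

    def test_min_score_filters(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(
            "gene_id\taccession\tscore\tali_from\tali_to\n"
            "a\tPF00128.15\t60\t1\t100\n"
            "b\tPF00128\t10\t1\t100\n"
        )
        hits = aio.read_domain_hits(path, min_score=25)
        assert [h.gene_id for h in hits] == ["a"]
        assert hits[0].accession == "PF00128"

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("gene_id\taccession\tscore\tali_from\tali_to\n")
        assert aio.read_domain_hits(path) == []

    def test_bad_row_reports_line_number(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(
            "gene_id\taccession\tscore\tali_from\tali_to\na\tPF1\tnot_a_number\t1\t2\n"
        )
        with pytest.raises(aio.AnnotationError, match="line 2"):
            aio.read_domain_hits(path)

    def test_negative_min_score_rejected(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("gene_id\taccession\tscore\tali_from\tali_to\n")
        with pytest.raises(aio.AnnotationError, match="min_score"):
            aio.read_domain_hits(path, min_score=-1)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _one_replicon(n=5, genome_id="G"):
    genes = tuple(
        aio.GeneRecord(genome_id, "c", o, "+", f"g{o}") for o in range(1, n + 1)
    )
    return [aio.Replicon("c", aio.CIRCULAR, genes)]


class TestAnnotate:
    def test_gh_hit_sets_family(self):
        genome = aio.annotate(
            _one_replicon(), [aio.DomainHit("g1", "PF00128", 60.0)]
        )
        ann = genome.annotation("g1")
        assert ann.is_gh and ann.gh_families == {"GH13"}
        assert genome.n_gh == 1

    def test_sus_domains_give_transporter_not_gh(self):
        genome = aio.annotate(
            _one_replicon(),
            [aio.DomainHit("g1", "PF00593", 60.0), aio.DomainHit("g1", "PF07715", 60.0)],
        )
        ann = genome.annotation("g1")
        assert not ann.is_gh
        assert ann.tr_classes == {aio.TR_SUS}

    def test_dual_gh_and_transporter_retained(self):
        genome = aio.annotate(
            _one_replicon(),
            [aio.DomainHit("g2", "PF00232", 60.0), aio.DomainHit("g2", "PF00593", 60.0)],
        )
        ann = genome.annotation("g2")
        assert ann.is_gh and aio.TR_SUS in ann.tr_classes
        assert genome.n_gh == 1 and genome.n_tr[aio.TR_SUS] == 1

    def test_strict_mode_rejects_unknown_gene(self):
        with pytest.raises(aio.AnnotationError, match="unknown gene_id"):
            aio.annotate(_one_replicon(), [aio.DomainHit("nope", "PF00128", 60.0)])
        genome = aio.annotate(
            _one_replicon(), [aio.DomainHit("nope", "PF00128", 60.0)], strict=False
        )
        assert genome.n_gh == 0

    def test_empty_hits_give_zero_counts(self):
        genome = aio.annotate(_one_replicon(), [])
        assert genome.n_gh == 0
        assert all(v == 0 for v in genome.n_tr.values())

    def test_annotation_independent_of_hit_order(self):
        hits = [
            aio.DomainHit("g1", "PF00128", 60.0),
            aio.DomainHit("g1", "PF00593", 60.0),
            aio.DomainHit("g3", "PF07690", 60.0),
        ]
        forward = aio.annotate(_one_replicon(), hits)
        backward = aio.annotate(_one_replicon(), list(reversed(hits)))
        assert forward.annotations == backward.annotations

    def test_cached_counts_match_recount(self):
        hits = [
            aio.DomainHit("g1", "PF00128", 60.0),
            aio.DomainHit("g2", "PF00933", 60.0),
            aio.DomainHit("g4", "PF00005", 60.0),
        ]
        genome = aio.annotate(_one_replicon(), hits)
        assert genome.n_gh == sum(a.is_gh for a in genome.annotations.values())
        assert genome.n_tr[aio.TR_ABC] == sum(
            aio.TR_ABC in a.tr_classes for a in genome.annotations.values()
        )

    def test_tsv_write_read_roundtrip(self, tmp_path):
        hits = [
            aio.DomainHit("g1", "PF00128", 60.0, (1, 100)),
            aio.DomainHit("g3", "PF00593", 45.5, (5, 200)),
        ]
        genome = aio.annotate(_one_replicon(), hits)
        fpath, hpath = tmp_path / "f.tsv", tmp_path / "h.tsv"
        aio.write_feature_table(genome, fpath)
        aio.write_domain_hits(genome, hpath)
        gid, replicons = aio.read_feature_table(fpath)
        reread = aio.annotate(
            replicons, aio.read_domain_hits(hpath), genome_id=gid
        )
        assert reread.genome_id == genome.genome_id
        assert reread.replicons == genome.replicons
        assert reread.annotations == genome.annotations
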