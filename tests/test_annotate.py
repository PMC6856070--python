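"""Six-class site annotation: rule geometry, priority, GFF3 round trip."""

import warnings

import pytest

from wttsapa import AnnotParams, AnnotationIndex, GeneModel, classify_all, classify_site, load_gff
from wttsapa.annotate import CONVENTIONAL, write_gff3
from tests.conftest import make_cluster

# toy + strand transcript: exons [1000,1200) and [1500,2000), tes = 1999
TOY = GeneModel("gA", "gA.t1", "chr1", "+", ((1000, 1200), (1500, 2000)))


@pytest.fixture(scope="module")
def toy_index():
    return AnnotationIndex([TOY], AnnotParams())


class TestClassRules:
    @pytest.mark.parametrize(
        "positions,strand,expected",
        [
            ({1100: 5}, "+", "Ex"),                 # inside first exon
            ({1300: 5}, "+", "In"),                 # inside the intron
            ({1999: 5}, "+", "Di"),                 # at the 3' terminus
            ({2500: 5}, "+", "Edi"),                # 501 nt downstream
            ({1190: 5, 1210: 2, 1229: 2}, "+", "Eex"),  # 30 nt into the intron
            ({1100: 5}, "-", "An"),                 # exonic, opposite strand
        ],
    )
    def test_rule_geometry(self, toy_index, positions, strand, expected):
        site = classify_site(make_cluster("chr1", strand, positions), toy_index)
        assert site.class_code == expected
        assert site.gene_id == "gA"
        assert site.conventional == (expected in CONVENTIONAL)

    def test_eex_needs_ten_intronic_bases(self, toy_index):
        # span [1195, 1205]: only 6 intronic bases -> not Eex; mixed span
        # falls through to the downstream check and ends unassignable
        site = classify_site(make_cluster("chr1", "+", {1195: 5, 1205: 2}), toy_index)
        assert site.class_code != "Eex"

    def test_no_gene_on_chrom_is_na(self, toy_index):
        site = classify_site(make_cluster("chr2", "+", {1100: 5}), toy_index)
        assert site.class_code == "NA"
        assert site.gene_id is None

    def test_beyond_edi_window_is_na(self, toy_index):
        site = classify_site(make_cluster("chr1", "+", {4500: 5}), toy_index)
        assert site.class_code == "NA"


class TestPriority:
    def test_di_beats_edi_within_tolerance(self, toy_index):
        # 10 nt downstream of the terminus is both Di-eligible and
        # Edi-eligible; Di wins
        site = classify_site(make_cluster("chr1", "+", {2009: 5}), toy_index)
        assert site.class_code == "Di"

    def test_di_beats_ex_in_last_exon(self, toy_index):
        site = classify_site(make_cluster("chr1", "+", {1980: 5}), toy_index)
        assert site.class_code == "Di"

    def test_di_never_reported_edi_with_multiple_transcripts(self):
        # second transcript ends 500 nt earlier; the site is at tx1's
        # terminus and downstream of tx2 -> must stay Di
        tx2 = GeneModel("gA", "gA.t2", "chr1", "+", ((1000, 1200), (1400, 1500)))
        index = AnnotationIndex([TOY, tx2], AnnotParams())
        site = classify_site(make_cluster("chr1", "+", {1999: 5}), index)
        assert site.class_code == "Di"
        assert site.transcript_id == "gA.t1"

    def test_nearest_tes_wins_among_equal_priority(self):
        a = GeneModel("gA", "tA", "chr1", "+", ((1000, 2000),))
        b = GeneModel("gB", "tB", "chr1", "+", ((900, 2100),))
        index = AnnotationIndex([a, b], AnnotParams())
        site = classify_site(make_cluster("chr1", "+", {1500: 5}), index)
        assert site.class_code == "Ex"
        assert site.transcript_id == "tA"  # tes 1999 nearer than 2099

    def test_antisense_requires_no_sense_assignment(self):
        minus = GeneModel("gB", "gB.t1", "chr1", "-", ((1050, 1150),))
        index = AnnotationIndex([TOY, minus], AnnotParams())
        # + site inside TOY exon AND inside gB exon: sense Ex wins
        site = classify_site(make_cluster("chr1", "+", {1100: 5}), index)
        assert site.class_code == "Ex"


MINUS = GeneModel("gM", "gM.t1", "chr1", "-", ((1000, 1200), (1500, 2000)))


class TestMinusStrand:
    @pytest.fixture()
    def index(self):
        return AnnotationIndex([MINUS], AnnotParams())

    @pytest.mark.parametrize(
        "positions,strand,expected",
        [
            ({1700: 5}, "-", "Ex"),
            ({1300: 5}, "-", "In"),
            ({1000: 5}, "-", "Di"),   # tes = min start on the minus strand
            ({700: 5}, "-", "Edi"),   # 300 nt downstream (leftward)
            ({1700: 5}, "+", "An"),
        ],
    )
    def test_mirror_geometry(self, index, positions, strand, expected):
        site = classify_site(make_cluster("chr1", strand, positions), index)
        assert site.class_code == expected


def reflect_gene(g: GeneModel, L: int) -> GeneModel:
    exons = tuple(sorted((L - b, L - a) for a, b in g.exons))
    return GeneModel(g.gene_id, g.transcript_id, g.chrom, "-" if g.strand == "+" else "+", exons)


def reflect_cluster(c, L: int):
    positions = {L - 1 - p: sum(per.values()) for p, per in c.positions_with_counts.items()}
    return make_cluster(c.chrom, "-" if c.strand == "+" else "+", positions)


def test_reflection_strand_symmetry(pipeline_result, sim_dataset, sim_params):
    """Mirroring all coordinates and flipping every strand preserves codes."""
    L = sim_params.chrom_length
    genes = [reflect_gene(g, L) for g in sim_dataset["genes"]]
    clusters = [reflect_cluster(c, L) for c in pipeline_result.clusters]
    flipped, _ = classify_all(clusters, genes)
    original = [s.class_code for s in pipeline_result.classified]
    assert [s.class_code for s in flipped] == original


def test_classify_all_recovers_planted_classes(pipeline_result, sim_dataset):
    truth_by_key = {
        (t.chrom, t.strand, t.position): t.true_class for t in sim_dataset["truth"]
    }
    for cluster, site in zip(pipeline_result.clusters, pipeline_result.classified):
        key = (cluster.chrom, cluster.strand, cluster.representative)
        assert site.class_code == truth_by_key[key]
    assert pipeline_result.class_tally["NA"] == 0


def test_every_cluster_gets_exactly_one_code(pipeline_result):
    codes = [s.class_code for s in pipeline_result.classified]
    assert len(codes) == len(pipeline_result.clusters)
    assert all(c in {"Ex", "Di", "Edi", "Eex", "In", "An", "NA"} for c in codes)


class TestGffIO:
    def test_coordinate_conversion(self, tmp_path):
        path = tmp_path / "one.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1001\t1200\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1001\t1200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tx\texon\t1001\t1200\t.\t+\t.\tID=e1;Parent=t1\n"
        )
        (gene,) = load_gff(path)
        assert gene.exons == ((1000, 1200),)

    def test_empty_gff_warns(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        with pytest.warns(UserWarning):
            assert load_gff(path) == []

    def test_orphan_exon_rejected(self, tmp_path):
        path = tmp_path / "orphan.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tx\texon\t1001\t1200\t.\t+\t.\tID=e1;Parent=ghost\n"
        )
        with pytest.raises(ValueError, match="parent"):
            load_gff(path)

    def test_round_trip_identity(self, tmp_path, sim_dataset):
        genes = sim_dataset["genes"]
        p1 = tmp_path / "a.gff3"
        write_gff3(genes, p1)
        loaded = load_gff(p1)
        p2 = tmp_path / "b.gff3"
        write_gff3(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
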