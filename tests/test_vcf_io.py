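"""I/O: PED pedigrees, annotated trio VCFs, classifier tables, detections."""
import numpy as np
import pytest

from trioprio import vcf_io
from trioprio.models import Detection, DetectionSet
from trioprio.vcf_io import ParseError

from .conftest import TRIO


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------


def write(path, text):
    path.write_text(text)
    return path


def test_read_ped_minimal_trio(tmp_path):
    ped = write(tmp_path / "t.ped", (
        "F1 FA1 0 0 1 1\n"
        "F1 MO1 0 0 2 1\n"
        "F1 P1 FA1 MO1 1 2\n"
    ))
    trios = vcf_io.read_ped(ped)
    assert len(trios) == 1
    t = trios[0]
    assert (t.proband_id, t.father_id, t.mother_id) == ("P1", "FA1", "MO1")
    assert t.proband_sex == "male"


def test_read_ped_unknown_sex_is_error(tmp_path):
    ped = write(tmp_path / "t.ped", (
        "F1 FA1 0 0 1 1\nF1 MO1 0 0 2 1\nF1 P1 FA1 MO1 0 2\n"
    ))
    with pytest.raises(ParseError, match="P1"):
        vcf_io.read_ped(ped)


def test_read_ped_missing_parent_excluded_with_warning(tmp_path, caplog):
    ped = write(tmp_path / "t.ped", (
        "F1 MO1 0 0 2 1\nF1 P1 FA1 MO1 1 2\n"
    ))
    with caplog.at_level("WARNING"):
        trios = vcf_io.read_ped(ped)
    assert trios == []
    assert "FA1" in caplog.text


def test_read_ped_malformed_line_names_line_number(tmp_path):
    ped = write(tmp_path / "t.ped", "F1 FA1 0 0 1\n")
    with pytest.raises(ParseError, match="line 1"):
        vcf_io.read_ped(ped)


def test_read_ped_cohort_of_220_trios(tmp_path):
    lines = []
    for i in range(1, 221):
        lines.append(f"F{i} FA{i} 0 0 1 1")
        lines.append(f"F{i} MO{i} 0 0 2 1")
        lines.append(f"F{i} P{i} FA{i} MO{i} {1 + i % 2} 2")
    ped = write(tmp_path / "big.ped", "\n".join(lines) + "\n")
    assert len(vcf_io.read_ped(ped)) == 220


# ---------------------------------------------------------------------------
# Trio VCF with CSQ annotations
# ---------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=248956422>
##FILTER=<ID=ExcessHet,Description="x">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from VEP. Format: Allele|Consequence|SYMBOL|gnomAD_AF|SIFT|PolyPhen|CADD_PHRED|REVEL|M-CAP|MPC|LoFtool">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tFA1\tMO1
"""


def test_read_trio_vcf_single_record_with_csq_scores(tmp_path):
    vcf = write(tmp_path / "t.vcf", VCF_HEADER + (
        "1\t1000\t.\tA\tG\t100\tPASS\t"
        "CSQ=G|missense_variant|GENEA|0.0001|deleterious(0.01)|0.98|25.1|0.8|0.1|2.5|0.1\t"
        "GT:DP:GQ\t0/1:60:99\t0/0:55:98\t0/0:52:97\n"
    ))
    records = list(vcf_io.read_trio_vcf(vcf, [TRIO]))
    assert len(records) == 1
    v = records[0]
    assert v.consequence == "missense_variant"
    assert v.gene == "GENEA"
    assert v.scores.sift == pytest.approx(0.01)
    assert v.scores.polyphen2 == pytest.approx(0.98)
    assert v.scores.mpc == pytest.approx(2.5)
    assert v.pop_af == pytest.approx(0.0001)
    assert v.call("P1").genotype == (0, 1)
    assert v.call("P1").depth == 60
    assert set(v.calls) == {"P1", "FA1", "MO1"}


def test_read_trio_vcf_multiallelic_emitted_with_two_alts(tmp_path):
    vcf = write(tmp_path / "t.vcf", VCF_HEADER + (
        "1\t1000\t.\tA\tG,T\t100\tPASS\t.\t"
        "GT:DP:GQ\t0/1:60:99\t0/0:55:98\t0/0:52:97\n"
    ))
    v = next(vcf_io.read_trio_vcf(vcf, [TRIO]))
    assert v.alts == ("G", "T")
    assert v.is_multiallelic


def test_read_trio_vcf_missing_dp_recorded_absent(tmp_path):
    vcf = write(tmp_path / "t.vcf", VCF_HEADER + (
        "1\t1000\t.\tA\tG\t100\tPASS\t.\t"
        "GT:GQ\t0/1:99\t0/0:98\t0/0:97\n"
    ))
    v = next(vcf_io.read_trio_vcf(vcf, [TRIO]))
    assert v.call("P1").depth is None
    assert v.call("P1").gq == 99


def test_read_trio_vcf_missing_sample_is_fatal(tmp_path):
    vcf = write(tmp_path / "t.vcf", VCF_HEADER.replace("MO1", "OTHER"))
    with pytest.raises(ParseError, match="MO1"):
        list(vcf_io.read_trio_vcf(vcf, [TRIO]))


def test_csq_picks_most_severe_transcript():
    parser = vcf_io.CsqParser(
        "Consequence annotations. Format: Allele|Consequence|SYMBOL|gnomAD_AF|SIFT"
    )
    ann = parser.parse(
        "G|intron_variant|GENEA||0.5,G|stop_gained&splice_region_variant|GENEA||0.2",
        alt="G",
    )
    assert ann.consequence == "stop_gained"
    assert ann.scores.sift == pytest.approx(0.2)


def test_chrom_prefix_normalized(tmp_path):
    vcf = write(
        tmp_path / "t.vcf",
        VCF_HEADER.replace("ID=1,", "ID=chr1,") + (
            "chr1\t1000\t.\tA\tG\t100\tPASS\t.\tGT:DP:GQ\t0/1:60:99\t0/0:55:98\t0/0:52:97\n"
        ),
    )
    v = next(vcf_io.read_trio_vcf(vcf, [TRIO]))
    assert v.chrom == "1"


# ---------------------------------------------------------------------------
# Classifier tables
# ---------------------------------------------------------------------------


def test_read_classification_table_direct_parse(tmp_path):
    t = write(tmp_path / "c.tsv",
              "chrom\tpos\tref\talt\tproband\tclassification\tcriteria\n"
              "1\t1000\tA\tG\tp1\tVUS\tPM2;PP3\n")
    (rec,) = vcf_io.read_classification_table(t, "InterVar")
    assert rec.variant_key == ("1", 1000, "A", "G")
    assert rec.criteria == frozenset({"PM2", "PP3"})
    assert rec.classification == "VUS"
    assert rec.tool == "InterVar"


def test_read_classification_table_long_form_label(tmp_path):
    t = write(tmp_path / "c.tsv",
              "chrom\tpos\tref\talt\tproband\tclassification\tcriteria\n"
              "1\t1000\tA\tG\tp1\tLikely pathogenic\tPS2;PM2\n")
    (rec,) = vcf_io.read_classification_table(t, "t")
    assert rec.classification == "LP"


def test_read_classification_table_unknown_tag_errors(tmp_path):
    t = write(tmp_path / "c.tsv",
              "chrom\tpos\tref\talt\tproband\tclassification\tcriteria\n"
              "1\t1000\tA\tG\tp1\tVUS\tPX9\n")
    with pytest.raises(ParseError, match="PX9"):
        vcf_io.read_classification_table(t, "t")


def test_criteria_vocabulary_has_28_tags():
    assert len(vcf_io.CRITERIA_VOCABULARY) == 28
    pathogenic = {t for t in vcf_io.CRITERIA_VOCABULARY if t[0] == "P"}
    benign = vcf_io.CRITERIA_VOCABULARY - pathogenic
    assert (len(pathogenic), len(benign)) == (16, 12)


# ---------------------------------------------------------------------------
# Detection TSV round trip
# ---------------------------------------------------------------------------


def random_detections(rng, n):
    members = set()
    while len(members) < n:
        members.add(Detection(
            variant_key=(str(rng.integers(1, 23)), int(rng.integers(1, 10**6)),
                         "A", "G"),
            proband_id=f"P{rng.integers(1, 50)}",
            gene=f"G{rng.integers(0, 100):06d}",
            inheritance=["de_novo", "autosomal_recessive", "x_linked_male"][rng.integers(0, 3)],
            consequence_group=["truncating", "missense", "other"][rng.integers(0, 3)],
            detection_class=["lgd_truncating", "lgd_missense", "acmg_lp_p"][rng.integers(0, 3)],
        ))
    return DetectionSet.from_iterable("toolX", members)


def test_write_detections_empty_set_header_only(tmp_path):
    path = tmp_path / "d.tsv"
    vcf_io.write_detections(DetectionSet.from_iterable("t", []), path)
    assert path.read_text().count("\n") == 1


def test_write_detections_sorted_and_deterministic(tmp_path):
    rng = np.random.default_rng(3)
    ds = random_detections(rng, 30)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    vcf_io.write_detections(ds, p1)
    vcf_io.write_detections(ds, p2)
    assert p1.read_bytes() == p2.read_bytes()
    rows = p1.read_text().splitlines()[1:]
    keys = [(r.split("\t")[0], int(r.split("\t")[1]), r.split("\t")[4]) for r in rows]
    from trioprio.models import chrom_sort_key
    assert keys == sorted(keys, key=lambda k: (chrom_sort_key(k[0]), k[1], k[2]))


def test_detections_round_trip_random_sets(tmp_path):
    rng = np.random.default_rng(7)
    for i in range(5):
        ds = random_detections(rng, 100)
        path = tmp_path / f"d{i}.tsv"
        vcf_io.write_detections(ds, path)
        back = vcf_io.read_detections(path)
        assert back.members == ds.members
        assert back.tool == ds.tool


def test_gene_list_round_trip(tmp_path, small_cohort):
    genes = vcf_io.read_gene_list(small_cohort.gene_list_path)
    assert len(genes.symbols) == small_cohort.config.gene_list_size
    assert set(genes.scores.values()) <= {1, 2, 3}
    out = tmp_path / "g.tsv"
    vcf_io.write_gene_list(genes, out)
    assert vcf_io.read_gene_list(out) == genes


def test_variant_table_round_trip(small_cohort):
    trios = vcf_io.read_ped(small_cohort.ped_path)
    ann = vcf_io.read_annotation_table(small_cohort.annotations_path)
    originals = [
        v for v in vcf_io.read_trio_vcf(small_cohort.vcf_path, trios, ann)
        if v.call(v.trio.proband_id).n_alt > 0
    ][:50]
    import io, tempfile, os
    fd, path = tempfile.mkstemp(suffix=".tsv")
    os.close(fd)
    try:
        vcf_io.write_variant_table(originals, path)
        back = list(vcf_io.read_variant_table(path, trios))
    finally:
        os.unlink(path)
    assert len(back) == len(originals)
    for a, b in zip(originals, back):
        assert a.key == b.key
        assert a.gene == b.gene
        assert a.consequence == b.consequence
        assert {s: c.genotype for s, c in a.calls.items()} == {
            s: c.genotype for s, c in b.calls.items()
        }
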