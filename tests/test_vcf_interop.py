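"""VCF reading, cohort assembly and report writing."""

import io

import pytest

from varbin import (
    GenotypeLikelihoods,
    ReportRow,
    VariantKey,
    VcfConfigError,
    VcfParseError,
    assemble_cohort,
    emit_forced_call_settings,
    read_forced_calls,
    write_report,
)

from conftest import make_obs

HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def vcf_file(tmp_path, body, header=HEADER, name="test.vcf"):
    path = tmp_path / name
    path.write_text(header + body)
    return str(path)


def test_simple_record_maps_fields(tmp_path):
    path = vcf_file(
        tmp_path, "1\t100\t.\tA\tG\t50\t.\tQD=12.5;MQ=60\tGT:PL:DP\t0/1:120,0,200:40\n"
    )
    (obs,) = read_forced_calls(path)
    assert obs.key == VariantKey("1", 100, "A", "G")
    assert obs.pl == GenotypeLikelihoods(120, 0, 200)
    assert obs.dp == 40
    assert obs.is_indel is False
    assert obs.info.qd == pytest.approx(12.5)
    assert obs.info.mq == pytest.approx(60.0)
    assert obs.info.fs is None
    assert obs.sample_id == "S1"


def test_indel_flag_from_allele_lengths(tmp_path):
    path = vcf_file(
        tmp_path, "1\t100\t.\tA\tAG\t50\t.\t.\tGT:PL:DP\t0/1:90,0,150:30\n"
    )
    (obs,) = read_forced_calls(path)
    assert obs.is_indel is True


def test_multiallelic_decomposition_subtriples(tmp_path):
    # Diploid PL ordering for ALTs (G, T): AA,AG,GG,AT,GT,TT = a,b,c,d,e,f.
    # ALT G takes (a, b, c); ALT T takes (a, d, f).
    path = vcf_file(
        tmp_path,
        "1\t100\t.\tA\tG,T\t50\t.\t.\tGT:PL:DP\t1/2:10,20,30,40,50,60:25\n",
    )
    obs_g, obs_t = read_forced_calls(path)
    assert obs_g.key.alt == "G" and obs_g.pl == GenotypeLikelihoods(10, 20, 30)
    assert obs_t.key.alt == "T" and obs_t.pl == GenotypeLikelihoods(10, 40, 60)
    assert obs_g.dp == obs_t.dp == 25


def test_missing_pl_value_is_unusable(tmp_path):
    path = vcf_file(tmp_path, "1\t100\t.\tA\tG\t50\t.\t.\tGT:DP\t0/1:40\n")
    (obs,) = read_forced_calls(path)
    assert obs.pl is None and obs.dp == 40
    assert not obs.usable


def test_missing_dp_value_is_unusable(tmp_path):
    path = vcf_file(tmp_path, "1\t100\t.\tA\tG\t50\t.\t.\tGT:PL\t0/1:120,0,200\n")
    (obs,) = read_forced_calls(path)
    assert obs.dp is None
    assert not obs.usable


def test_header_without_pl_is_config_error(tmp_path):
    header = HEADER.replace(
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="x">\n', ""
    )
    path = vcf_file(tmp_path, "1\t100\t.\tA\tG\t50\t.\t.\tGT:DP\t0/1:40\n", header)
    with pytest.raises(VcfConfigError, match="PL"):
        read_forced_calls(path)


def test_malformed_record_names_position(tmp_path):
    path = vcf_file(tmp_path, "1\tnot_a_pos\t.\tA\tG\t50\t.\t.\tGT:PL:DP\t0/1:1,0,1:5\n")
    with pytest.raises((VcfParseError, VcfConfigError)):
        read_forced_calls(path)


def test_unknown_sample_rejected(tmp_path):
    path = vcf_file(tmp_path, "1\t100\t.\tA\tG\t50\t.\t.\tGT:PL:DP\t0/1:1,0,1:5\n")
    with pytest.raises(VcfConfigError, match="nope"):
        read_forced_calls(path, sample_id="nope")


def test_variant_key_validation():
    with pytest.raises(ValueError):
        VariantKey("1", 0, "A", "G")
    with pytest.raises(ValueError):
        VariantKey("1", 10, "A", "A")
    with pytest.raises(ValueError):
        VariantKey("1", 10, "a", "G")
    with pytest.raises(ValueError):
        VariantKey("1", 10, "A", "")


def keys(n):
    return [VariantKey("1", 100 + i, "A", "G") for i in range(n)]


def test_assemble_cohort_full_coverage():
    k = keys(3)
    proband = [make_obs(sample_id="p", key=key) for key in k]
    bg1 = [make_obs(sample_id="b1", key=key) for key in k]
    bg2 = [make_obs(sample_id="b2", key=key) for key in k]
    cohort = assemble_cohort(proband, [], [bg1, bg2])
    assert cohort.site_list == k
    assert all(not missing for missing in cohort.missing_sites.values())
    assert cohort.proband_id == "p"


def test_assemble_cohort_records_missing_background_site():
    k = keys(3)
    proband = [make_obs(sample_id="p", key=key) for key in k]
    bg = [make_obs(sample_id="b", key=key) for key in k if key != k[1]]
    cohort = assemble_cohort(proband, [], [bg])
    assert cohort.missing_sites["b"] == [k[1]]
    assert k[1] in cohort.site_list  # site retained
    assert cohort.get("b", k[1]) is None


def test_assemble_cohort_duplicate_sample_id_rejected():
    k = keys(1)
    proband = [make_obs(sample_id="p", key=k[0])]
    dup = [make_obs(sample_id="p", key=k[0])]
    with pytest.raises(VcfConfigError, match="duplicate"):
        assemble_cohort(proband, [], [dup])


def test_assemble_cohort_requires_backgrounds():
    with pytest.raises(VcfConfigError):
        assemble_cohort([make_obs(sample_id="p")], [], [])


def test_assemble_cohort_drops_non_proband_sites_with_warning():
    k = keys(2)
    proband = [make_obs(sample_id="p", key=k[0])]
    bg = [make_obs(sample_id="b", key=key) for key in k]
    with pytest.warns(UserWarning, match="absent from proband"):
        cohort = assemble_cohort(proband, [], [bg])
    assert cohort.site_list == [k[0]]


def row(key, plrd=3.14159265):
    return ReportRow(
        key=key,
        proband_plrd=plrd,
        bg_median=-3.0,
        bg_iqd=0.25,
        bg_n_wildtype=18,
        bg_n_variant=2,
        bin_label="Bin1",
        flags=("LOW_DEPTH",),
    )


def test_write_report_header_only():
    sink = io.StringIO()
    assert write_report([], sink) == 0
    lines = sink.getvalue().splitlines()
    assert len(lines) == 1
    assert lines[0].startswith("chrom\tpos\tref\talt\tproband_plrd")


def test_write_report_row_count_and_format():
    k = keys(3)
    sink = io.StringIO()
    assert write_report([row(key) for key in k], sink) == 3
    lines = sink.getvalue().splitlines()
    assert len(lines) == 4
    fields = lines[1].split("\t")
    assert fields[:4] == ["1", "100", "A", "G"]
    assert fields[4] == "3.14159"  # six significant digits
    assert fields[10] == "LOW_DEPTH"


def test_write_report_deterministic():
    rows = [row(k) for k in keys(5)]
    a, b = io.StringIO(), io.StringIO()
    write_report(rows, a)
    write_report(rows, b)
    assert a.getvalue() == b.getvalue()


def test_write_report_none_as_na():
    k = keys(1)[0]
    sink = io.StringIO()
    write_report(
        [
            ReportRow(
                key=k,
                proband_plrd=None,
                bg_median=None,
                bg_iqd=None,
                bg_n_wildtype=0,
                bg_n_variant=0,
                bin_label="Unclassifiable",
                flags=(),
            )
        ],
        sink,
    )
    fields = sink.getvalue().splitlines()[1].split("\t")
    assert fields[4] == fields[5] == fields[6] == "NA"
    assert fields[10] == "."


@pytest.mark.parametrize(
    "needle",
    [
        "min_base_quality_score 17",
        "EMIT_ALL_SITES",
        "max_deletion_fraction 1.0",
        "GENOTYPE_GIVEN_ALLELES",
        "stand_call_conf 0.0",
        "stand_emit_conf 0.0",
        "genotype_likelihoods_model BOTH",
    ],
)
def test_forced_call_settings_text(needle):
    assert needle in emit_forced_call_settings()


def test_simulated_vcf_round_trip(sim_cohort):
    """Parsing a simulated VCF recovers PL, DP and INFO as written.

    The text lines themselves are the independent oracle: PL/DP must match
    exactly, INFO floats to VCF float precision.
    """
    path = sim_cohort.background_paths[0]
    obs_list = read_forced_calls(path)
    data_lines = [
        line for line in open(path).read().splitlines() if not line.startswith("#")
    ]
    assert len(obs_list) == len(data_lines)
    for obs, line in zip(obs_list, data_lines):
        cols = line.split("\t")
        assert obs.key.chrom == cols[0] and obs.key.pos == int(cols[1])
        gt, pl_str, dp_str = cols[9].split(":")
        expected_pl = tuple(float(x) for x in pl_str.split(","))
        assert (obs.pl.pl_aa, obs.pl.pl_ab, obs.pl.pl_bb) == expected_pl
        assert obs.dp == int(dp_str)
        info = dict(kv.split("=") for kv in cols[7].split(";"))
        assert obs.info.qd == pytest.approx(float(info["QD"]), abs=1e-4)
        assert obs.info.fs == pytest.approx(float(info["FS"]), abs=1e-4)
        assert obs.info.read_pos_rank_sum == pytest.approx(
            float(info["ReadPosRankSum"]), abs=1e-4
        )
        assert obs.vcf_filter == cols[6]
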