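import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix, make_panel
from signburden.catalog import RiskVariant
from signburden.genotypes import (
    OrientationMode,
    read_panel,
    read_vcf,
    resolve_orientation,
    subset_samples,
)

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class TestResolveOrientation:
    @pytest.mark.parametrize(
        "risk,other,ref,alt,mode,palindrome",
        [
            ("G", "A", "A", "G", OrientationMode.RISK_IS_ALT, False),
            ("T", "C", "A", "G", OrientationMode.FLIP_RISK_IS_REF, False),
            ("A", "T", "A", "T", OrientationMode.RISK_IS_REF, True),
            ("C", "G", "A", "G", OrientationMode.UNRESOLVED, True),
        ],
    )
    def test_reference_cases(self, risk, other, ref, alt, mode, palindrome):
        o = resolve_orientation(risk, other, ref, alt)
        assert o.mode is mode
        assert o.ambiguous_palindrome is palindrome

    def test_exhaustive_pairings_resolve_iff_alleles_correspond(self):
        # Over all ordered base pairs: resolution happens exactly when the
        # catalog pair equals the VCF pair as a set, directly or after
        # reverse-complementing both alleles.
        pairs = [(a, b) for a, b in itertools.product("ACGT", repeat=2) if a != b]
        for (risk, other), (ref, alt) in itertools.product(pairs, pairs):
            o = resolve_orientation(risk, other, ref, alt)
            direct = {risk, other} == {ref, alt}
            flipped = {COMP[risk], COMP[other]} == {ref, alt}
            assert o.resolved == (direct or flipped)

    def test_identity_round_trip_never_unresolved(self):
        for risk, other in [(a, b) for a, b in itertools.product("ACGT", repeat=2) if a != b]:
            o = resolve_orientation(risk, other, risk, other)
            assert o.mode is OrientationMode.RISK_IS_REF

    def test_unknown_other_allele_matches_on_risk_alone(self):
        assert resolve_orientation("G", None, "A", "G").mode is OrientationMode.RISK_IS_ALT
        assert resolve_orientation("T", None, "A", "G").mode is OrientationMode.FLIP_RISK_IS_REF


class TestReadPanel:
    def test_small_fixture(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text(
            "sample\tpop\tsuper_pop\nN1\tYRI\tAFR\nN2\tYRI\tAFR\nN3\tCEU\tEUR\nN4\tCEU\tEUR\n"
        )
        panel = read_panel(p)
        assert len(panel) == 4
        assert sorted(panel.group_of("super_pop").unique()) == ["AFR", "EUR"]

    def test_duplicate_sample_errors_naming_it(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("sample\tpop\tsuper_pop\nN1\tYRI\tAFR\nN1\tYRI\tAFR\n")
        with pytest.raises(ValueError, match="N1"):
            read_panel(p)

    def test_unknown_column_warns_but_parses(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("sample\tpop\tsuper_pop\tgender\tweird\nN1\tYRI\tAFR\tfemale\tx\n")
        with pytest.warns(UserWarning, match="weird"):
            panel = read_panel(p)
        assert panel.samples == ["N1"]

    def test_generator_round_trip_group_sizes(self, sim_neutral):
        panel = read_panel(sim_neutral.panel_path)
        sizes = panel.table.groupby("super_pop").size()
        assert sizes["GRPA"] == sizes["GRPB"] == 120

    def test_inconsistent_pop_mapping_rejected(self):
        with pytest.raises(ValueError, match="super-population"):
            make_panel([("a", "YRI", "AFR"), ("b", "YRI", "EUR")])


def _toy_vcf(tmp_path):
    """5 catalog variants vs a hand-written VCF; expected matrix built by hand."""
    cat = [
        RiskVariant("rs1", "1", 100, "G", "A", "T", 1e-9),  # risk_is_alt, GT
        RiskVariant("rs2", "1", 200, "T", "C", "T", 1e-9),  # risk_is_ref, DS -> 2-d
        RiskVariant("rs3", "2", 300, "T", "C", "T", 1e-9),  # strand flip -> 2-d
        RiskVariant("rs4", "2", 400, "A", "C", "T", 1e-9),  # multi-allelic -> skip
        RiskVariant("rs5", "2", 500, "C", "G", "T", 1e-9),  # unresolved vs A/G
        RiskVariant("rs6", "3", 600, "A", "G", "T", 1e-9),  # absent from VCF
    ]
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\tS2\tS3\tS4\tS5\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\t0/1\t0/0\n"
        "1\t200\trs2\tT\tC\t.\tPASS\t.\tGT:DS\t0/1:1.7\t0/0:0.0\t1/1:2.0\t0/0:0.5\t0/1:1.0\t0/1:0.2\n"
        "2\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1\t0/1\t0/1\t0/1\n"
        "2\t400\trs4\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\n"
        "2\t500\trs5\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\n"
    )
    # rs2: REF=T ALT=C, risk=T -> risk_is_ref; DS preferred -> dosage = 2 - DS
    # rs3: REF=G ALT=A, risk=T other=C -> comp(T)=A comp(C)=G -> flip, risk is ALT -> d
    expected = {
        "rs1": [0, 1, 2, np.nan, 1, 0],
        "rs2": [0.3, 2.0, 0.0, 1.5, 1.0, 1.8],
        "rs3": [1, 1, 1, 1, 1, 1],
    }
    return cat, vcf, expected


class TestReadVcf:
    def test_hand_built_matrix(self, tmp_path):
        cat, vcf, expected = _toy_vcf(tmp_path)
        panel = make_panel([(f"S{i}", "YRI", "AFR") for i in range(6)])
        matrix, report = read_vcf(vcf, cat, panel)
        assert matrix.variants == ["rs1", "rs2", "rs3"]
        for vid, exp in expected.items():
            np.testing.assert_allclose(matrix.column(vid), exp, atol=1e-6, equal_nan=True)
        assert matrix.source == ["GT", "DS", "GT"]
        status = {m.variant_id: m.status for m in report}
        assert status == {
            "rs1": "matched", "rs2": "matched", "rs3": "matched",
            "rs4": "skipped", "rs5": "skipped", "rs6": "missing",
        }

    def test_disjoint_panel_errors(self, tmp_path):
        cat, vcf, _ = _toy_vcf(tmp_path)
        panel = make_panel([("ZZ1", "YRI", "AFR")])
        with pytest.raises(ValueError, match="disjoint"):
            read_vcf(vcf, cat, panel)

    def test_risk_plus_other_dosages_sum_to_two(self, tmp_path):
        # For hard calls, scoring the declared risk allele and its partner
        # must partition the two chromosomes.
        cat, vcf, _ = _toy_vcf(tmp_path)
        swapped = [
            RiskVariant(v.variant_id, v.chromosome, v.position, v.other_allele,
                        v.risk_allele, v.trait, v.assoc_p)
            for v in cat[:1]
        ]
        m1, _ = read_vcf(vcf, cat[:1], None)
        m2, _ = read_vcf(vcf, swapped, None)
        np.testing.assert_allclose(m1.column("rs1") + m2.column("rs1"),
                                   [2, 2, 2, np.nan, 2, 2], equal_nan=True)

    def test_record_order_does_not_matter(self, tmp_path, sim_neutral):
        from signburden.catalog import load_catalog

        cat, _ = load_catalog(sim_neutral.catalog_path)
        lines = sim_neutral.vcf_path.read_text().splitlines(keepends=True)
        header = [l for l in lines if l.startswith("#")]
        body = [l for l in lines if not l.startswith("#")]
        shuffled = tmp_path / "shuffled.vcf"
        shuffled.write_text("".join(header + body[::-1]))
        m1, _ = read_vcf(sim_neutral.vcf_path, cat, None)
        m2, _ = read_vcf(shuffled, cat, None)
        assert m1.variants == m2.variants  # fixed to catalog order
        np.testing.assert_array_equal(m1.dosage, m2.dosage)


class TestSubsetSamples:
    @pytest.fixture()
    def seven_pop_panel(self):
        pops = ["YRI", "LWK", "GWD", "MSL", "ESN", "ACB", "ASW"]
        rows = [(f"{p}{i}", p, "AFR") for p in pops for i in range(2)]
        rows += [("CEU0", "CEU", "EUR"), ("CEU1", "CEU", "EUR")]
        return make_panel(rows)

    def test_continental_africa_exclusion_keeps_five_populations(self, seven_pop_panel):
        matrix = make_matrix(np.zeros((16, 2)), samples=seven_pop_panel.samples)
        sub = subset_samples(matrix, seven_pop_panel, ["AFR"], exclude=["ACB", "ASW"])
        kept_pops = set(seven_pop_panel.group_of("population")[sub.samples])
        assert kept_pops == {"YRI", "LWK", "GWD", "MSL", "ESN"}
        assert sub.n_samples == 10

    def test_empty_exclude_is_identity_on_group(self, seven_pop_panel):
        matrix = make_matrix(np.zeros((16, 2)), samples=seven_pop_panel.samples)
        sub = subset_samples(matrix, seven_pop_panel, ["AFR"])
        assert sub.n_samples == 14

    def test_count_matches_direct_filter(self, sim_neutral):
        from signburden.catalog import load_catalog

        panel = read_panel(sim_neutral.panel_path)
        cat, _ = load_catalog(sim_neutral.catalog_path)
        matrix, _ = read_vcf(sim_neutral.vcf_path, cat, panel)
        sub = subset_samples(matrix, panel, ["GRPA"])
        direct = (panel.table["super_pop"] == "GRPA").sum()
        assert sub.n_samples == direct

    def test_unknown_group_and_empty_result_error(self, seven_pop_panel):
        matrix = make_matrix(np.zeros((16, 2)), samples=seven_pop_panel.samples)
        with pytest.raises(ValueError, match="unknown"):
            subset_samples(matrix, seven_pop_panel, ["NOPE"])
        with pytest.raises(ValueError, match="no samples"):
            subset_samples(matrix, seven_pop_panel, ["EUR"], exclude=["CEU"])
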