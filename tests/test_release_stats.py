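import numpy as np
import pytest

from milkpep import (
    ACTIVITY_ACE,
    ACTIVITY_DPP4,
    GeneratorConfig,
    PeptideActivityRecord,
    ProteinRecord,
    gen_activity_table,
    gen_proteins,
    occurrences,
    profile_report,
    release_profile,
)

from oracles import oracle_release_stats


@pytest.fixture
def afvaw():
    return ProteinRecord(accession="X", sequence="AFVAW")


@pytest.fixture
def afvaw_table():
    return [
        PeptideActivityRecord("AF", ACTIVITY_ACE, 10.0),
        PeptideActivityRecord("VA", ACTIVITY_ACE, 2.0),
    ]


class TestOccurrences:
    def test_positions_and_count(self, afvaw, afvaw_table):
        occ = occurrences(afvaw, afvaw_table, ACTIVITY_ACE)
        assert [(pos, rec.sequence) for pos, rec in occ] == [(1, "AF"), (3, "VA")]

    def test_overlaps_counted(self):
        protein = ProteinRecord(accession="X", sequence="AAA")
        table = [PeptideActivityRecord("AA", ACTIVITY_ACE, None)]
        assert len(occurrences(protein, table, ACTIVITY_ACE)) == 2

    def test_unlisted_activity_is_empty(self, afvaw, afvaw_table):
        assert occurrences(afvaw, afvaw_table, ACTIVITY_DPP4) == []


class TestReleaseProfile:
    def test_worked_example(self, afvaw, afvaw_table, enzymes):
        # chymotrypsin cuts AFVAW after F and (terminal) W -> [AF, VAW]
        profile = release_profile(afvaw, [enzymes["chymotrypsin"]], afvaw_table, ACTIVITY_ACE)
        assert (profile.a, profile.d) == (2, 1)
        assert profile.A == pytest.approx(0.4)
        assert profile.A_E == pytest.approx(0.2)
        assert profile.W == pytest.approx(0.5)
        assert profile.B == pytest.approx(0.12)
        assert profile.B_E == pytest.approx(0.02)
        assert profile.V == pytest.approx(1 / 6)

    def test_missing_ic50_excluded_from_b_only(self, afvaw, enzymes):
        table = [
            PeptideActivityRecord("AF", ACTIVITY_ACE, None),  # counted in a/d only
            PeptideActivityRecord("VA", ACTIVITY_ACE, 2.0),
        ]
        profile = release_profile(afvaw, [enzymes["chymotrypsin"]], table, ACTIVITY_ACE)
        assert (profile.a, profile.d) == (2, 1)
        assert profile.B == pytest.approx(0.5 / 5)
        assert profile.B_E == 0.0

    def test_empty_table_leaves_ratios_undefined(self, afvaw, enzymes):
        profile = release_profile(afvaw, [enzymes["chymotrypsin"]], [], ACTIVITY_ACE)
        assert (profile.a, profile.d) == (0, 0)
        assert profile.A == profile.A_E == profile.B == profile.B_E == 0.0
        assert profile.W is None and profile.V is None

    def test_full_fragmentation_releases_nothing(self, afvaw, afvaw_table):
        from milkpep import CleavageRule, EnzymeSpec
        cut_all = EnzymeSpec(
            id="all", name="", ec_number="",
            rules=(CleavageRule(frozenset("ACDEFGHIKLMNPQRSTVWY")),),
        )
        profile = release_profile(afvaw, [cut_all], afvaw_table, ACTIVITY_ACE)
        assert profile.d == 0 and profile.A_E == 0.0

    def test_agrees_with_bruteforce_oracle(self, all_enzymes):
        rng = np.random.default_rng(11)
        for trial in range(60):
            config = GeneratorConfig(seed=int(rng.integers(2**31)), n_proteins=1,
                                     protein_length=(20, 120))
            (protein,) = gen_proteins(config)
            table = gen_activity_table(config, [protein])
            for activity in (ACTIVITY_ACE, ACTIVITY_DPP4):
                got = release_profile(protein, all_enzymes, table, activity)
                expected = oracle_release_stats(protein.sequence, all_enzymes, table, activity)
                assert got.a == expected["a"] and got.d == expected["d"]
                assert got.A == pytest.approx(expected["A"], abs=1e-12)
                assert got.A_E == pytest.approx(expected["A_E"], abs=1e-12)
                assert got.B == pytest.approx(expected["B"], abs=1e-12)
                assert got.B_E == pytest.approx(expected["B_E"], abs=1e-12)

    def test_invariants_on_synthetic_instances(self, all_enzymes):
        for seed in range(30):
            config = GeneratorConfig(seed=seed, n_proteins=2)
            proteins = gen_proteins(config)
            table = gen_activity_table(config, proteins)
            for protein in proteins:
                p = release_profile(protein, all_enzymes, table, ACTIVITY_ACE)
                assert 0 <= p.A_E <= p.A
                assert 0 <= p.B_E <= p.B or (p.B == 0 and p.B_E == 0)
                # A*N and A_E*N are exact integers
                assert abs(p.A * p.N - round(p.A * p.N)) < 1e-9
                assert abs(p.A_E * p.N - round(p.A_E * p.N)) < 1e-9
                if p.W is not None:
                    assert 0 <= p.W <= 1
                if p.V is not None:
                    assert 0 <= p.V <= 1

    def test_monotone_in_knowledge_table(self, all_enzymes):
        config = GeneratorConfig(seed=5, n_proteins=1)
        (protein,) = gen_proteins(config)
        table = gen_activity_table(config, [protein])
        previous = (0, 0)
        for k in range(0, len(table) + 1, 10):
            p = release_profile(protein, all_enzymes, table[:k], ACTIVITY_ACE)
            assert p.a >= previous[0] and p.d >= previous[1]
            previous = (p.a, p.d)


class TestProfileReport:
    def test_cartesian_rows_and_rounding(self, all_enzymes):
        proteins = [
            ProteinRecord(accession="P1", sequence="AFVAW"),
            ProteinRecord(accession="P2", sequence="PKPK"),
        ]
        table = [
            PeptideActivityRecord("AF", ACTIVITY_ACE, 10.0),
            PeptideActivityRecord("VA", ACTIVITY_ACE, 2.0),
        ]
        report = profile_report(proteins, all_enzymes, table,
                                [ACTIVITY_ACE, ACTIVITY_DPP4])
        assert len(report) == 4
        row = report[(report.protein == "P1") & (report.activity == ACTIVITY_ACE)].iloc[0]
        # 1/6 displayed at 4 decimals
        assert row.V == pytest.approx(0.1667)
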