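import numpy as np
import pytest

from milkpep import (
    ACTIVITY_ACE,
    ACTIVITY_DPP4,
    GeneratorConfig,
    PeptideActivityRecord,
    PresenceMatrix,
    ProteinRecord,
    Spectrum,
    attribute_sources,
    autolysis_screen,
    gen_spectrum,
    identify,
    load_identified_peptides,
    mz_MH,
    summarize,
    theoretical_spectrum,
)

ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")


class TestIdentify:
    def test_noiseless_self_match_scores_one(self):
        spectrum = theoretical_spectrum("PK")
        result = identify(spectrum, ["PK", "PA", "VY"])
        assert result.candidate_sequences == ("PK",)
        assert result.score == 1.0
        assert result.matched_peaks == result.total_candidate_ions

    def test_composition_isomers_reported_together(self):
        # PL and IP share residue composition (I/L collapsed) and precursor;
        # they co-elute and are never resolved to a single sequence
        result = identify(theoretical_spectrum("PL"), ["PL", "IP", "VY"])
        assert set(result.candidate_sequences) == {"PL", "IP"}

    def test_leucine_isoleucine_tie(self):
        result = identify(theoretical_spectrum("LK"), ["LK", "IK"])
        assert set(result.candidate_sequences) == {"LK", "IK"}

    def test_precursor_filter_rejects_everything(self):
        spectrum = theoretical_spectrum("PK")
        result = identify(spectrum, ["VY"])  # precursor 244.17 vs 281.15
        assert not result.identified
        assert "precursor" in result.reason

    def test_min_matched_rejects_sparse_matches(self):
        rng = np.random.default_rng(0)
        pre = mz_MH("PK")
        peaks = tuple((float(x), 1.0) for x in rng.uniform(50, pre, 30))
        spectrum = Spectrum(peaks=peaks, precursor_mz=pre, label="decoy")
        result = identify(spectrum, ["PK"], min_matched=10)
        assert not result.identified

    def test_jittered_recovery_with_decoys(self):
        """Seeded jittered spectra recover the generating isomer set."""
        rng = np.random.default_rng(99)
        hits = 0
        trials = 50
        for trial in range(trials):
            true = "".join(rng.choice(ALPHABET, 2))
            decoys = ["".join(rng.choice(ALPHABET, 2)) for _ in range(50)]
            candidates = list(dict.fromkeys([true] + decoys))
            spectrum = gen_spectrum(true, GeneratorConfig(seed=trial))
            result = identify(spectrum, candidates)
            if true in result.candidate_sequences:
                hits += 1
        assert hits / trials >= 0.95

    def test_tolerances_must_be_positive(self):
        with pytest.raises(ValueError):
            identify(theoretical_spectrum("PK"), ["PK"], mz_tol=0.0)


class TestAttributeSources:
    PROTEINS = [
        ProteinRecord(accession="P1", sequence="VPLGYK"),
        ProteinRecord(accession="P2", sequence="AAVPL"),   # C-terminal hit
        ProteinRecord(accession="P3", sequence="GYKAAA"),
    ]

    def test_all_containing_proteins_listed_in_order(self):
        assert attribute_sources("VPL", self.PROTEINS) == ["P1", "P2"]

    def test_boundaries_detected(self):
        assert attribute_sources("GYK", self.PROTEINS) == ["P1", "P3"]

    def test_absent_peptide_gives_empty_list(self):
        assert attribute_sources("WWW", self.PROTEINS) == []

    def test_stable_under_reordering(self):
        reordered = list(reversed(self.PROTEINS))
        assert set(attribute_sources("VPL", reordered)) == {"P1", "P2"}


class TestAutolysisScreen:
    ENZYMES = [
        ProteinRecord(accession="E1", sequence="MKTFIVGGYTCGA"),
        ProteinRecord(accession="E2", sequence="AAPWAA"),
    ]

    def test_partition_by_enzyme_occurrence(self):
        result = autolysis_screen(["GG", "PW", "VY"], self.ENZYMES)
        assert result.enzyme_possible == ("GG", "PW")
        assert result.milk_only == ("VY",)

    def test_empty_peptide_list(self):
        result = autolysis_screen([], self.ENZYMES)
        assert result.enzyme_possible == () and result.milk_only == ()

    def test_requires_enzyme_sequences(self):
        with pytest.raises(ValueError):
            autolysis_screen(["GG"], [])


class TestSummarize:
    def test_fixture_counts(self):
        matrix = PresenceMatrix.from_identified(load_identified_peptides())
        counts = summarize(matrix)
        assert counts.total_peptides == 36
        # per-sample presences implied by the packaged table rows
        assert counts.per_sample == {
            "MCC-0": 2, "MCC-D": 30, "MBP-0": 4, "MBP-D": 30, "SPC-0": 1, "SPC-D": 27,
        }
        assert counts.common_duodenal == 23

    def test_activity_counts_allow_multiple_classes(self):
        matrix = PresenceMatrix.from_identified(load_identified_peptides())
        table = [
            PeptideActivityRecord("VY", ACTIVITY_ACE, 7.1),
            PeptideActivityRecord("VY", ACTIVITY_DPP4, None),
            PeptideActivityRecord("PK", ACTIVITY_DPP4, None),
        ]
        counts = summarize(matrix, table)
        assert counts.activities_per_sample["MCC-D"][ACTIVITY_ACE] == 1
        assert counts.activities_per_sample["MCC-D"][ACTIVITY_DPP4] == 2

    def test_empty_matrix(self):
        import pandas as pd
        from milkpep import SAMPLE_LABELS
        matrix = PresenceMatrix(pd.DataFrame(columns=list(SAMPLE_LABELS), dtype=float))
        counts = summarize(matrix)
        assert counts.total_peptides == 0
        assert counts.common_duodenal == 0
        assert all(v == 0 for v in counts.per_sample.values())

    def test_round_trip_via_tsv(self, tmp_path):
        matrix = PresenceMatrix.from_identified(load_identified_peptides())
        path = tmp_path / "matrix.tsv"
        matrix.table.to_csv(path, sep="\t")
        again = PresenceMatrix.from_tsv(path)
        assert summarize(again) == summarize(matrix)
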