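"""Peptide mapping, flank windows, logo information content, ladders,
coverage and group-uniqueness censuses."""

import numpy as np
import pandas as pd
import pytest

from cystomics import (
    PeptideRecord, ProteaseProfile, ProteinDB, QuantMatrix, build_logo,
    collect_flank_windows, coverage_map, detect_ladders, extract_flanks,
    generate_proteome, group_uniqueness, logo_divergence, map_peptides,
    simulate_digestion, tryptic_profile, chymotryptic_profile,
)
from cystomics.degradome import MAX_BITS, FlankWindow


class TestMapping:
    def test_substring_position(self):
        db = ProteinDB({"P1": "MKWVTFISLLF"})
        recs, unmapped = map_peptides(["VTFISL"], db)
        assert recs[0].matches == [("P1", 4, 9)]
        assert unmapped == []

    def test_repeated_occurrence_recorded_twice(self):
        db = ProteinDB({"P1": "AGAGA"})
        recs, _ = map_peptides(["AGA"], db)
        assert recs[0].matches == [("P1", 1, 3), ("P1", 3, 5)]

    def test_unmatched_reported(self):
        db = ProteinDB({"P1": "MKWV"})
        recs, unmapped = map_peptides(["AAAA"], db)
        assert recs[0].matches == [] and unmapped == ["AAAA"]

    def test_multiple_proteins(self):
        db = ProteinDB({"P1": "AAKW", "P2": "CAKW"})
        recs, _ = map_peptides(["AKW"], db)
        assert {m[0] for m in recs[0].matches} == {"P1", "P2"}


class TestFlanks:
    # protein positions:   1234567890
    DB = ProteinDB({"P1": "ACDEFGHIKL"})

    def test_interior_peptide_windows(self):
        rec = PeptideRecord("p", "EFG", [("P1", 4, 6)])
        (n_win, c_win), = extract_flanks(rec, self.DB)
        assert n_win.residues == ("-", "A", "C", "D", "E", "F", "G", "H")
        assert c_win.residues == ("D", "E", "F", "G", "H", "I", "K", "L")

    def test_protein_start_gives_all_gap_upstream(self):
        rec = PeptideRecord("p", "ACDE", [("P1", 1, 4)])
        (n_win, _), = extract_flanks(rec, self.DB)
        assert n_win.residues[:4] == ("-", "-", "-", "-")
        assert n_win.residues[4:] == ("A", "C", "D", "E")

    def test_protein_end_gives_all_gap_downstream(self):
        rec = PeptideRecord("p", "HIKL", [("P1", 7, 10)])
        (_, c_win), = extract_flanks(rec, self.DB)
        assert c_win.residues[4:] == ("-", "-", "-", "-")
        assert c_win.residues[:4] == ("H", "I", "K", "L")  # P1 = last residue

    def test_p1_is_residue_before_peptide_start(self):
        rec = PeptideRecord("p", "FGH", [("P1", 5, 7)])
        (n_win, _), = extract_flanks(rec, self.DB)
        assert n_win.residues[3] == "E"   # P1
        assert n_win.residues[4] == "F"   # P1'


def windows_from_strings(strings):
    return [
        FlankWindow("N", tuple(s), ("p", "X", 0)) for s in strings
    ]


class TestLogo:
    def test_uniform_position_zero_bits(self):
        from cystomics.io import CANONICAL_AA
        wins = windows_from_strings([aa * 8 for aa in CANONICAL_AA])
        logo = build_logo(wins)
        assert logo.info_bits.max() == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_position_max_bits(self):
        wins = windows_from_strings(["KKKKKKKK"] * 5)
        logo = build_logo(wins)
        assert logo.info_bits["P1"] == pytest.approx(MAX_BITS)

    def test_half_half_position(self):
        wins = windows_from_strings(["KKKKKKKK", "RRRRRRRR"])
        logo = build_logo(wins)
        assert logo.info_bits["P1"] == pytest.approx(MAX_BITS - 1.0)

    def test_gaps_excluded_from_normalization(self):
        wins = windows_from_strings(["----KKKK", "KKKKKKKK"])
        logo = build_logo(wins)
        assert logo.freqs.loc["P4", "K"] == pytest.approx(1.0)
        assert logo.counts.loc["P4"].sum() == 1

    def test_abundance_weighting(self):
        wins = [
            FlankWindow("N", tuple("KKKKKKKK"), ("hi", "X", 0)),
            FlankWindow("N", tuple("RRRRRRRR"), ("lo", "X", 0)),
        ]
        logo = build_logo(wins, weights={"hi": 3.0, "lo": 1.0})
        assert logo.freqs.loc["P1", "K"] == pytest.approx(0.75)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_logo([])

    def test_tryptic_digestion_recovers_p1_specificity(self):
        """K/R-specific digestion: the N-terminal-window logo must put its
        information at P1 (argmax K or R, > 1 bit) and essentially nowhere
        else (< 0.3 bits)."""
        db = generate_proteome(40, (200, 300), seed=10)
        peps, events = simulate_digestion(db, tryptic_profile(), seed=10)
        assert len(events) >= 500
        # internal cleavages only: peptides whose N-terminus is a real cut
        recs = [p for p in peps if p.matches[0][1] > 1]
        n_win, _ = collect_flank_windows(recs, db)
        logo = build_logo(n_win)
        assert logo.info_bits["P1"] > 1.0
        assert logo.freqs.loc["P1"].idxmax() in {"K", "R"}
        others = logo.info_bits.drop("P1")
        assert others.max() < 0.3

    def test_distinct_specificities_diverge_most_at_p1(self):
        db = generate_proteome(30, (200, 300), seed=11)
        peps_a, _ = simulate_digestion(db, tryptic_profile(), seed=11)
        peps_b, _ = simulate_digestion(db, chymotryptic_profile(), seed=12)
        wa, _ = collect_flank_windows([p for p in peps_a if p.matches[0][1] > 1], db)
        wb, _ = collect_flank_windows([p for p in peps_b if p.matches[0][1] > 1], db)
        div = logo_divergence(build_logo(wa), build_logo(wb))
        assert div.idxmax() == "P1"


class TestLadders:
    def rec(self, pid, start, end):
        seq = "ACDEFGHIKLMNPQRSTVWY"[: end - start + 1]
        return PeptideRecord(pid, seq, [("P1", start, end)])

    def test_c_trimmed_series_forms_n_anchored_ladder(self):
        recs = [self.rec("a", 1, 8), self.rec("b", 1, 7), self.rec("c", 1, 6)]
        (ladder,) = detect_ladders(recs, min_rungs=3)
        assert ladder.shared_terminus == "N" and ladder.coordinate == 1
        assert ladder.members == ["a", "b", "c"]
        assert ladder.steps == [1, 1]

    def test_n_trimmed_series_forms_c_anchored_ladder(self):
        recs = [self.rec("a", 1, 8), self.rec("b", 2, 8), self.rec("c", 3, 8)]
        (ladder,) = detect_ladders(recs, min_rungs=3)
        assert ladder.shared_terminus == "C" and ladder.coordinate == 8

    def test_min_rungs_unmet_gives_nothing(self):
        recs = [self.rec("a", 1, 8), self.rec("b", 3, 6)]
        assert detect_ladders(recs, min_rungs=3) == []

    def test_members_are_anchored_substrings_of_longest(self):
        db = generate_proteome(10, (150, 250), seed=6)
        prof = ProteaseProfile(
            "lad", {"K": 1.0, "R": 1.0}, cleavage_probability=0.9,
            trim_prob_n=1.0, trim_prob_c=1.0, trim_max=4,
        )
        peps, _ = simulate_digestion(db, prof, seed=6)
        by_id = {p.peptide_id: p for p in peps}
        ladders = detect_ladders(peps, min_rungs=3)
        assert ladders, "trimming at probability 1 must create ladders"
        for lad in ladders:
            longest = by_id[lad.members[0]].sequence
            for pid in lad.members[1:]:
                seq = by_id[pid].sequence
                if lad.shared_terminus == "N":
                    assert longest.startswith(seq)
                else:
                    assert longest.endswith(seq)
            assert lad.lengths == sorted(lad.lengths, reverse=True)


class TestCoverage:
    DB = ProteinDB({"P1": "ACDEFGHIKL"})

    def test_no_peptides_all_zero(self):
        assert coverage_map([], self.DB, "P1").tolist() == [0] * 10

    def test_single_peptide(self):
        recs = [PeptideRecord("p", "EFG", [("P1", 4, 6)])]
        assert coverage_map(recs, self.DB, "P1").tolist() == [0, 0, 0, 1, 1, 1, 0, 0, 0, 0]

    def test_overlap_counts_stack(self):
        recs = [
            PeptideRecord("p1", "ACDEF", [("P1", 1, 5)]),
            PeptideRecord("p2", "EFGHI", [("P1", 4, 8)]),
        ]
        cov = coverage_map(recs, self.DB, "P1")
        assert cov[3] == 2 and cov[4] == 2 and cov[0] == 1

    def test_unknown_accession(self):
        with pytest.raises(KeyError):
            coverage_map([], self.DB, "nope")


class TestUniqueness:
    def _setup(self, patterns, groups=("A", "B")):
        """patterns: feature -> set of groups the feature is detected in."""
        samples = pd.DataFrame(
            {"group": [g for g in groups for _ in range(2)]},
            index=[f"{g}{i}" for g in groups for i in range(2)],
        )
        data = pd.DataFrame(
            np.nan, index=list(patterns), columns=samples.index, dtype=float
        )
        for f, gs in patterns.items():
            for g in gs:
                data.loc[f, f"{g}0"] = 10.0
        return QuantMatrix(data, "log2"), samples

    def test_enumerated_venn(self):
        m, samples = self._setup({"f1": {"A"}, "f2": {"B"}, "f3": {"A", "B"}})
        rep = group_uniqueness(m, samples)
        assert rep.unique == {"A": 1, "B": 1}
        assert rep.shared_all == 1
        assert rep.venn == {
            frozenset({"A"}): 1, frozenset({"B"}): 1, frozenset({"A", "B"}): 1,
        }

    def test_venn_partition_sums_to_detected_union(self):
        rng = np.random.default_rng(0)
        patterns = {
            f"f{i}": {g for g in "ABC" if rng.random() < 0.5} for i in range(60)
        }
        patterns = {f: gs for f, gs in patterns.items() if gs}
        m, samples = self._setup(patterns, groups=("A", "B", "C"))
        rep = group_uniqueness(m, samples)
        assert sum(rep.venn.values()) == len(patterns)

    def test_unc_excluded_by_default(self):
        samples = pd.DataFrame(
            {"group": ["A", "A", "UNC"]}, index=["a0", "a1", "u0"]
        )
        data = pd.DataFrame(
            {"a0": [np.nan], "a1": [np.nan], "u0": [5.0]}, index=["f1"], dtype=float
        )
        rep = group_uniqueness(QuantMatrix(data, "log2"), samples)
        assert rep.detected == {"A": 0}

    def test_protein_level_census(self):
        m, samples = self._setup({"f1": {"A"}, "f2": {"A"}, "f3": {"B"}})
        rep = group_uniqueness(
            m, samples, feature_to_protein={"f1": "P", "f2": "P", "f3": "Q"}
        )
        assert rep.detected_proteins == {"A": 1, "B": 1}
        assert rep.unique_proteins == {"A": 1, "B": 1}
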