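import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from puf3regulon.io import SpeciesDataset
from puf3regulon.motif import (
    MatchList,
    WindowCounts,
    call_targets,
    compile_profile,
    count_in_windows,
    scan_dataset,
    scan_sequence,
)

from conftest import random_sequences


def regex_starts(seq, profile):
    """Independent oracle: overlapping character-class regex search."""
    pattern = "".join("[" + "".join(sorted(s)) + "]" for s in profile.positions)
    return [m.start() for m in re.finditer(f"(?=({pattern}))", seq)]


class TestCompileProfile:
    def test_default_has_flexible_fifth_position(self, default_profile):
        assert [len(s) for s in default_profile.positions] == [1, 1, 1, 1, 4, 1, 1, 1]
        assert default_profile.positions[4] == frozenset("ACGT")
        assert default_profile.positions[0] == frozenset("T")

    def test_all_singleton_profile_allowed(self):
        prof = compile_profile("AAAAAAAA")
        assert all(s == frozenset("A") for s in prof.positions)

    @pytest.mark.parametrize("bad", ["TGTANAT", "TGTANATAA", "TGTAXATA", ""])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            compile_profile(bad)

    def test_admitted_words_default(self, default_profile):
        words = default_profile.admitted_words()
        assert len(words) == 4
        assert "TGTAAATA" in words and "TGTACATA" in words

    def test_match_probability_closed_form(self, default_profile):
        # six fixed A/T sites at (1-gc)/2, one fixed G site at gc/2, and a
        # free fifth site: p = ((1-gc)/2)^6 * gc/2
        for gc in (0.38, 0.6):
            expected = ((1 - gc) / 2) ** 6 * (gc / 2)
            assert default_profile.match_probability(gc) == pytest.approx(expected)
        assert default_profile.match_probability(0.0) == 0.0  # G site impossible


class TestScanSequence:
    def test_single_match_at_origin(self, default_profile):
        assert scan_sequence("TGTAAATA", default_profile) == [0]

    def test_no_match(self, default_profile):
        assert scan_sequence("CCCCCCCC", default_profile) == []

    def test_two_adjacent_matches(self, default_profile):
        assert scan_sequence("TGTAAATATGTACATA", default_profile) == [0, 8]

    def test_n_in_sequence_matches_nothing(self, default_profile):
        assert scan_sequence("TGTANATA", default_profile) == []

    def test_short_and_empty_sequences(self, default_profile):
        assert scan_sequence("", default_profile) == []
        assert scan_sequence("TGTAAAT", default_profile) == []

    def test_overlapping_matches_all_reported(self):
        prof = compile_profile("ANNNNNNA")
        seq = "A" * 12
        assert scan_sequence(seq, prof) == list(range(5))

    def test_sense_strand_only(self, default_profile):
        # reverse complement of a motif-bearing sequence: the element is read
        # on the mRNA, so the complement must not be reported as a match
        seq = "TGTAAATA" + "C" * 8
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert scan_sequence(seq, default_profile) == [0]
        assert scan_sequence(rc, default_profile) == []

    @pytest.mark.parametrize("gc", [0.2, 0.4, 0.6])
    def test_equals_regex_oracle_on_random_sequences(self, default_profile, gc):
        for seq in random_sequences(gc, 60, 1000, seed=int(gc * 100)):
            assert scan_sequence(seq, default_profile) == regex_starts(seq, default_profile)

    def test_scan_dataset_matches_per_sequence_scan(self, default_profile, make_dataset):
        seqs = random_sequences(0.3, 25, 400, seed=7)
        ds = make_dataset(seqs)
        matches = scan_dataset(ds, default_profile)
        for gene, seq in ds.downstream.items():
            assert matches[gene].starts == scan_sequence(seq, default_profile)


class TestCountInWindows:
    def test_two_matches_in_first_window_are_independent_events(self):
        wc = count_in_windows({"g": [0, 8]}, {"g": 1000})
        assert wc.counts[0] == 2
        assert wc.counts[1:].sum() == 0

    def test_no_genes_gives_all_zero(self):
        wc = count_in_windows({}, {})
        assert wc.counts.sum() == 0 and wc.eligible_positions.sum() == 0

    def test_window_assignment_by_start_at_boundary(self):
        wc = count_in_windows({"g": [49, 50]}, {"g": 1000})
        assert wc.counts[0] == 1 and wc.counts[1] == 1

    def test_eligible_positions_full_length_gene(self):
        wc = count_in_windows({"g": []}, {"g": 1000})
        # 993 valid starts: 50 per window except 43 in the last
        assert wc.eligible_positions[:-1].tolist() == [50] * 19
        assert wc.eligible_positions[-1] == 43
        assert wc.eligible_positions.sum() == 993

    def test_eligible_positions_short_gene(self):
        wc = count_in_windows({"g": []}, {"g": 60})
        # valid starts 0..52: 50 in window 0, 3 in window 1
        assert wc.eligible_positions[0] == 50
        assert wc.eligible_positions[1] == 3
        assert wc.eligible_positions[2:].sum() == 0

    def test_counts_conservation_property(self, default_profile, make_dataset):
        seqs = random_sequences(0.25, 40, 1000, seed=3)
        ds = make_dataset(seqs)
        matches = scan_dataset(ds, default_profile)
        lengths = {g: len(ds.downstream[g]) for g in matches}
        wc = count_in_windows(matches, lengths)
        total = sum(len(m.starts) for m in matches.values())
        assert wc.counts.sum() == total
        assert np.all(wc.eligible_positions >= wc.counts)

    def test_invalid_window_size_rejected(self):
        with pytest.raises(ValueError):
            count_in_windows({}, {}, window_size=0)
        with pytest.raises(ValueError):
            count_in_windows({}, {}, window_size=300, region_length=1000)

    def test_corrupt_counts_rejected(self):
        with pytest.raises(ValueError, match="eligible"):
            WindowCounts(window_size=50, region_length=100,
                         counts=[5, 0], eligible_positions=[1, 0], n_genes=1)


class TestCallTargets:
    def _dataset(self, seq):
        return SpeciesDataset(species_id="s", downstream={"g": seq})

    def test_match_ending_exactly_at_cutoff_is_target(self, default_profile):
        seq = "C" * 242 + "TGTAAATA" + "C" * 750  # start 242, ends at base 250
        targets = call_targets(self._dataset(seq), default_profile)
        assert targets.targets == {"g"}

    def test_match_one_base_past_cutoff_is_not_target(self, default_profile):
        seq = "C" * 243 + "TGTAAATA" + "C" * 749
        targets = call_targets(self._dataset(seq), default_profile)
        assert targets.targets == set()

    def test_no_match_not_target(self, default_profile):
        targets = call_targets(self._dataset("C" * 1000), default_profile)
        assert targets.targets == set()

    def test_matches_agree_with_cutoff_rule(self, default_profile, make_dataset):
        seqs = random_sequences(0.2, 80, 1000, seed=11)
        ds = make_dataset(seqs)
        targets = call_targets(ds, default_profile, utr_cutoff=250)
        matches = scan_dataset(ds, default_profile)
        expected = {g for g, m in matches.items() if any(s <= 242 for s in m.starts)}
        assert targets.targets == expected


class TestScannerProperties:
    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(seq=st.text(alphabet="ACGTN", min_size=0, max_size=120))
    def test_scan_always_equals_regex_oracle(self, default_profile, seq):
        assert scan_sequence(seq, default_profile) == regex_starts(seq, default_profile)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        starts=st.lists(st.integers(min_value=0, max_value=1100), unique=True),
        length=st.integers(min_value=8, max_value=1000),
    )
    def test_window_counts_conserve_in_region_matches(self, starts, length):
        starts = sorted(s for s in starts if s + 8 <= length)
        wc = count_in_windows({"g": starts}, {"g": length})
        assert wc.counts.sum() == sum(s < 1000 for s in starts)
        assert np.all(wc.eligible_positions >= 0)


class TestMatchList:
    def test_rejects_unsorted_starts(self):
        with pytest.raises(ValueError):
            MatchList(gene_id="g", starts=[5, 3])
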