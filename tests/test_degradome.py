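"""Degradome tests: tag mapping, duplex scoring, T-plot categorization
(against a brute-force classifier) and target validation."""

import numpy as np
import pytest

from memomir.degradome import (
    DegradomeProfile,
    categorize_site,
    cleavage_position,
    find_candidate_sites,
    map_tags,
    score_duplex,
    validate_targets,
)
from memomir.errors import ConfigurationError, InputError
from memomir.seqio import revcomp, write_fastq

MIR = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def _profile(counts):
    arr = np.array(counts, dtype=np.int64)
    return DegradomeProfile("t1", len(arr), arr)


class TestMapTags:
    def _write(self, tmp_path, reads):
        p = tmp_path / "deg.fastq"
        write_fastq(p, [(f"r{i}", s, "I" * len(s)) for i, s in enumerate(reads)])
        return p

    def test_exact_match_increments_position(self, tmp_path):
        rng = np.random.default_rng(1)
        tx = {"t1": "".join("ACGT"[i] for i in rng.integers(0, 4, 200))}
        tag = tx["t1"][99:120]
        profiles, stats = map_tags(self._write(tmp_path, [tag]), tx)
        assert profiles["t1"].counts[99] == 1
        assert stats["mapped"] == 1

    def test_multimapper_counts_once_per_locus(self, tmp_path):
        core = "ACGTGGCATTGCAATGCCAGGTAC"
        tx = {"t1": "AAAA" + core + "CCCC", "t2": "GGGG" + core + "TTTT"}
        profiles, _ = map_tags(self._write(tmp_path, [core[:21]]), tx)
        assert profiles["t1"].counts[4] == 1 and profiles["t2"].counts[4] == 1

    def test_unmapped_counted(self, tmp_path):
        tx = {"t1": "A" * 100}
        _p, stats = map_tags(self._write(tmp_path, ["CGCGCGCGCGCGCGCGCGCGC"]), tx)
        assert stats["unmapped"] == 1 and stats["mapped"] == 0

    def test_empty_transcriptome_is_configuration_error(self, tmp_path):
        with pytest.raises(ConfigurationError):
            map_tags(self._write(tmp_path, ["ACGT" * 6]), {})


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        assert score_duplex(MIR, revcomp(MIR)) == 0.0

    def test_gu_wobble_at_position_five_doubled(self):
        # miRNA position 5 faces site position L-5; make it a G:U wobble
        mir = MIR[:4] + "G" + MIR[5:]
        site = list(revcomp(mir))
        site[len(mir) - 5] = "T"  # G opposite U(T) instead of C
        assert score_duplex(mir, "".join(site)) == 1.0

    def test_mismatch_outside_seed_region(self):
        site = list(revcomp(MIR))
        m20 = MIR[19]
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[m20]
        bad = next(b for b in "ACGT" if b != comp and (m20, b) not in
                   (("G", "T"), ("T", "G")))
        site[len(MIR) - 20] = bad
        assert score_duplex(MIR, "".join(site)) == 1.0

    def test_length_mismatch_is_input_error(self):
        with pytest.raises(InputError):
            score_duplex(MIR, "ACGT")


class TestFindCandidateSites:
    def test_planted_site_coordinates(self):
        rng = np.random.default_rng(7)
        tx = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        tx = tx[:490] + revcomp(MIR) + tx[490 + 21:]
        sites = find_candidate_sites(MIR, tx, score_max=4.0)
        assert (491, 502, 0.0) in sites
        assert cleavage_position(491, 21) == 491 + (21 - 10)

    def test_no_qualifying_window(self):
        assert find_candidate_sites(MIR, "A" * 100, score_max=4.0) == []

    def test_adjacent_windows_both_reported(self):
        # site duplicated back to back -> two qualifying windows
        tx = "CCCC" + revcomp(MIR) + revcomp(MIR) + "CCCC"
        sites = find_candidate_sites(MIR, tx, score_max=4.0)
        starts = [s for s, _c, sc in sites if sc == 0.0]
        assert starts == [5, 26]


class TestCategorizeSite:
    def test_hand_example(self):
        prof = _profile([10, 4, 1, 0])
        assert categorize_site(prof, 1) == 0
        assert categorize_site(prof, 2) == 3  # mean over covered = 5, 4 <= 5
        assert categorize_site(prof, 3) == 4
        assert categorize_site(prof, 4) is None

    def test_tied_maximum(self):
        prof = _profile([5, 5, 1])
        assert categorize_site(prof, 1) == 1
        assert categorize_site(prof, 2) == 1

    def test_single_read_position(self):
        assert categorize_site(_profile([0, 1, 0]), 2) == 4

    def test_category_two(self):
        prof = _profile([10, 6, 1, 1, 1, 1])  # mean over covered ~ 3.33
        assert categorize_site(prof, 2) == 2

    def test_out_of_range_is_input_error(self):
        with pytest.raises(InputError):
            categorize_site(_profile([1]), 5)

    def test_matches_brute_force_classifier(self):
        """Exhaustive/exclusive assignment vs an independent literal
        re-implementation on 1,000 random profiles."""

        def brute(counts, pos):
            # literal rules, maximum checks taking precedence over the
            # mean comparison (they overlap when all covered counts tie)
            c = counts[pos]
            if c == 0:
                return None
            covered = [x for x in counts if x > 0]
            M, mu = max(covered), sum(covered) / len(covered)
            if c == 1:
                return 4
            if c == M and counts.count(M) == 1:
                return 0
            if c == M:
                return 1
            if c > mu:
                return 2
            return 3

        rng = np.random.default_rng(2024)
        for _ in range(1000):
            counts = rng.choice([0, 0, 1, 1, 2, 3, 5, 9], size=8).tolist()
            prof = _profile(counts)
            pos = int(rng.integers(1, 9))
            assert categorize_site(prof, pos) == brute(counts, pos - 1)


class TestValidateTargets:
    def _setup(self):
        rng = np.random.default_rng(3)
        tx = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        tx = tx[:99] + revcomp(MIR) + tx[99 + 21:]
        cleave = 100 + 21 - 10
        counts = np.zeros(300, dtype=np.int64)
        counts[cleave - 1] = 6
        counts[10] = 1
        counts[200] = 1
        profiles = {"t1": DegradomeProfile("t1", 300, counts)}
        return {"t1": tx}, profiles, cleave

    def test_planted_signal_yields_single_hit(self):
        tx, profiles, cleave = self._setup()
        hits = validate_targets({"mir1": MIR}, profiles, tx)
        assert len(hits) == 1
        h = hits[0]
        assert (h.transcript_id, h.cleavage_pos, h.category) == ("t1", cleave, 0)
        assert h.reads_at_site == 6 and h.duplex_score == 0.0

    def test_background_only_profile_no_hits(self):
        tx, profiles, _ = self._setup()
        profiles["t1"].counts[:] = 0
        profiles["t1"].counts[[10, 50, 90]] = 1
        assert validate_targets({"mir1": MIR}, profiles, tx) == []

    def test_category_above_threshold_excluded(self):
        tx, profiles, cleave = self._setup()
        # make the planted position a non-peak (category 3)
        profiles["t1"].counts[250] = 50
        profiles["t1"].counts[251] = 50
        profiles["t1"].counts[cleave - 1] = 2
        hits = validate_targets({"mir1": MIR}, profiles, tx, category_max=2)
        assert hits == []
        hits3 = validate_targets({"mir1": MIR}, profiles, tx, category_max=3)
        assert len(hits3) == 1 and hits3[0].category == 3

    @pytest.mark.parametrize("score_max,category_max", [(0.0, 0), (2.0, 1), (4.0, 2)])
    def test_filter_monotonicity(self, score_max, category_max):
        tx, profiles, _ = self._setup()
        strict = validate_targets({"mir1": MIR}, profiles, tx,
                                  score_max=score_max, category_max=category_max)
        loose = validate_targets({"mir1": MIR}, profiles, tx,
                                 score_max=4.0, category_max=2)
        strict_keys = {(h.mirna_id, h.transcript_id, h.cleavage_pos) for h in strict}
        loose_keys = {(h.mirna_id, h.transcript_id, h.cleavage_pos) for h in loose}
        assert strict_keys <= loose_keys

    def test_position_first_equals_sliding_route(self):
        """validate_targets (position-first) agrees with filtering the
        find_candidate_sites sliding scan."""
        tx, profiles, _ = self._setup()
        hits = validate_targets({"mir1": MIR}, profiles, tx)
        slide = []
        for start, cleave, score in find_candidate_sites(MIR, tx["t1"], 4.0):
            if not 1 <= cleave <= 300:
                continue
            cat = categorize_site(profiles["t1"], cleave)
            if cat is not None and cat <= 2 and profiles["t1"].counts[cleave - 1] > 1:
                slide.append(("mir1", "t1", cleave, score, cat))
        assert [(h.mirna_id, h.transcript_id, h.cleavage_pos, h.duplex_score,
                 h.category) for h in hits] == slide
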