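"""Catalog tests: Nussinov folding against brute-force enumeration, hairpin
criteria, classification cascade and variant naming."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memomir.catalog import (
    ReferenceIndex,
    apply_variant,
    base_composition,
    classify_tag,
    match_mature,
    name_variant,
    nussinov_pairs,
    predict_hairpin,
)
from memomir.errors import InputError
from memomir.seqio import revcomp

# ---------------------------------------------------------------------------
# Nussinov folding
# ---------------------------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def brute_force_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Independent oracle: enumerate every nested secondary structure."""

    def rec(positions: tuple[int, ...]) -> int:
        if len(positions) < 2:
            return 0
        i, rest = positions[0], positions[1:]
        best = rec(rest)  # i unpaired
        for idx, j in enumerate(rest):
            if j - i <= min_loop:
                continue
            if (seq[i], seq[j]) in _PAIRS:
                inside = tuple(q for q in rest[:idx] if i < q < j)
                outside = tuple(q for q in rest[idx + 1:])
                best = max(best, 1 + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(len(seq))))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=0, max_size=12))
def test_nussinov_matches_brute_force(seq):
    pairs = nussinov_pairs(seq)
    assert len(pairs) == brute_force_max_pairs(seq)
    for i, j in pairs:
        assert (seq[i], seq[j]) in _PAIRS
        assert j - i > 3


def test_nussinov_structure_is_nested():
    seq = "GGGGCCAAAACCCCGGTTTT"
    pairs = nussinov_pairs(seq)
    for (i, j), (k, l) in itertools.combinations(pairs, 2):
        # nested or disjoint, never crossing
        assert not (i < k < j < l or k < i < l < j)


# ---------------------------------------------------------------------------
# Hairpin prediction
# ---------------------------------------------------------------------------


class TestPredictHairpin:
    def test_perfect_inverted_repeat_passes(self):
        mature = "ACGTTGCAACGGTACGATCGA"
        window = mature + "TTCA" + revcomp(mature)
        hp = predict_hairpin(window, (0, len(mature)))
        assert hp.passed
        assert hp.paired_fraction_of_mature == 1.0
        assert hp.arm == "5p"
        assert hp.loop_length >= 3

    def test_mature_on_3p_arm(self):
        mature = "ACGTTGCAACGGTACGATCGA"
        window = revcomp(mature) + "TTCA" + mature
        hp = predict_hairpin(window, (len(mature) + 4, len(window)))
        assert hp.passed and hp.arm == "3p"

    def test_homopolymer_fails(self):
        hp = predict_hairpin("A" * 60, (0, 21))
        assert not hp.passed and hp.paired_fraction_of_mature == 0.0

    def test_mature_straddling_loop_fails(self):
        stem = "ACGTTGCAACGGTACGATCGA"
        window = stem + "TTCA" + revcomp(stem)
        # span covering the loop: bases pair across the mature itself
        span = (len(stem) - 5, len(stem) + 9)
        hp = predict_hairpin(window, span)
        assert not hp.passed

    def test_span_outside_window_is_input_error(self):
        with pytest.raises(InputError):
            predict_hairpin("ACGT" * 10, (30, 50))


# ---------------------------------------------------------------------------
# Variant naming
# ---------------------------------------------------------------------------

MATURE = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


class TestNameVariant:
    def test_identical_keeps_reference_name(self):
        assert name_variant(MATURE, MATURE, "tae-miR164a-5p") == "tae-miR164a-5p"

    def test_five_prime_trim_two(self):
        assert name_variant(MATURE[2:], MATURE, "tae-miR531") == "tae-miR531_L-2"

    def test_three_prime_trim_one(self):
        assert name_variant(MATURE[:-1], MATURE, "tae-miR408") == "tae-miR408_R-1"

    def test_single_substitution_at_21(self):
        mature = MATURE[:20] + "G"
        tag = MATURE[:20] + "A"
        assert name_variant(tag, mature, "tae-MIR9676-p3") == "tae-MIR9676-p3_1ss21GA"

    def test_combined_trim_and_substitution(self):
        tag = MATURE[1:]
        tag = tag[:5] + ("C" if tag[5] != "C" else "G") + tag[6:]
        name = name_variant(tag, MATURE, "tae-miR167a-3p")
        assert name.startswith("tae-miR167a-3p_L-1_1ss6")

    def test_unalignable_returns_none(self):
        assert name_variant("A" * 10, MATURE, "x") is None

    @pytest.mark.parametrize(
        "tag",
        [MATURE, MATURE[2:], MATURE[:-2], MATURE[1:-1],
         MATURE[:10] + "A" + MATURE[11:] if MATURE[10] != "A" else MATURE[:10] + "C" + MATURE[11:]],
    )
    def test_round_trip_trims_and_substitutions(self, tag):
        name = name_variant(tag, MATURE, "ref")
        suffix = name[len("ref"):]
        assert apply_variant(MATURE, suffix) == tag

    def test_extension_round_trip_needs_context(self):
        tag = "GG" + MATURE
        m = match_mature(tag, MATURE)
        assert m is not None and m.d5 == 2
        name = name_variant(tag, MATURE, "ref")
        assert name == "ref_L+2"
        assert apply_variant(MATURE, "_L+2", context=("AAGG", "")) == tag
        with pytest.raises(InputError):
            apply_variant(MATURE, "_L+2")


# ---------------------------------------------------------------------------
# Classification cascade
# ---------------------------------------------------------------------------


def test_classification_recovers_planted_groups(small_run, small_truth):
    _report, out = small_run
    import pandas as pd

    cat = pd.read_csv(out / "catalog.tsv", sep="\t", index_col=0)
    merged = small_truth.mirnas.merge(
        cat.reset_index()[["id", "seq", "group"]], on="seq", suffixes=("_truth", "")
    )
    assert len(merged) == len(small_truth.mirnas)
    assert (merged["gp"] == merged["group"]).all()
    assert (merged["id_truth"] == merged["id"]).all()


def test_unassigned_tag(small_reference):
    index = ReferenceIndex(
        small_reference.wheat_mature, small_reference.wheat_precursor,
        small_reference.other_mature, small_reference.genome_windows,
    )
    # random tag matching nothing -> unassigned
    assert classify_tag("ATCGGCTAGCTAGGATCCAAT", index) is None


def test_gp2_split_follows_hairpin(small_reference, small_truth):
    index = ReferenceIndex(
        small_reference.wheat_mature, small_reference.wheat_precursor,
        small_reference.other_mature, small_reference.genome_windows,
    )
    truth = small_truth.mirnas
    for gp in ("gp2a", "gp2b", "gp3", "gp4", "gp1b"):
        for seq in truth.loc[truth["gp"] == gp, "seq"]:
            entry = classify_tag(seq, index)
            assert entry is not None and entry.group == gp, (gp, seq)


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------


def test_base_composition_frequencies():
    import pandas as pd

    tags = pd.DataFrame(
        {"L1": [1, 1]},
        index=pd.Index(["T" + "A" * 17, "A" * 18], name="seq"),
    )
    table = base_composition(tags)
    row = table[(table["length"] == 18) & (table["position"] == 1)].iloc[0]
    assert row["U"] == pytest.approx(0.5) and row["A"] == pytest.approx(0.5)
    sums = table[["A", "C", "G", "U"]].sum(axis=1)
    assert (abs(sums - 1) < 1e-12).all()
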