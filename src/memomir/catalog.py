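"""miRNA cataloguing: hairpin prediction, tag classification, variant naming.

Tags are assigned to six classes following the ACGT101-style convention:

* gp1a  known miRNA: matches a wheat mature (<=2 substitutions and/or <=2-nt
        end trimming/extension) and maps within its wheat precursor;
* gp1b  wheat-precursor variant: maps within a wheat precursor but not to an
        annotated mature (opposite arm / shifted);
* gp2a  conserved: matches a non-wheat mature and maps to a genome window
        that folds into a hairpin;
* gp2b  conserved, hairpin fails at the genomic locus;
* gp3   conserved, no genomic locus;
* gp4   novel: no miRBase-style match, genomic hairpin present.

Folding uses Nussinov maximum base-pairing (AU/GC/GU pairs, minimum loop 3)
rather than free-energy minimization: it is dependency-free and fully
deterministic; an energy-based backend can be substituted where needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .simulate import novel_id  # shared so synthetic ground truth can predict ids

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_CAN_PAIR = np.zeros((4, 4), dtype=np.int16)
for a, b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:  # AU, GC, GU
    _CAN_PAIR[a, b] = 1

MIN_LOOP = 3


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_ENC[c] for c in seq.upper()), dtype=np.int64)
    except KeyError as exc:
        raise InputError(f"non-nucleotide character in sequence: {exc}") from exc


@dataclass
class HairpinResult:
    passed: bool
    paired_fraction_of_mature: float
    loop_length: int
    arm: str            # "5p", "3p" or "" when undetermined
    structure: str      # dot-bracket
    pairs: list[tuple[int, int]] = field(default_factory=list, repr=False)


def nussinov_pairs(seq: str, min_loop: int = MIN_LOOP) -> list[tuple[int, int]]:
    """Maximum base-pairing structure (Nussinov recursion), 0-based pairs.

    Diagonal-vectorized DP; traceback prefers closing the outer pair, which
    recovers the rod-like stem of a perfect inverted repeat.
    """
    n = len(seq)
    if n == 0:
        return []
    s = _encode(seq)
    pairable = _CAN_PAIR[s[:, None], s[None, :]]
    dp = np.zeros((n, n), dtype=np.int16)
    for l in range(min_loop + 1, n):
        i = np.arange(0, n - l)
        j = i + l
        best = np.maximum(dp[i + 1, j], dp[i, j - 1])
        best = np.maximum(best, dp[i + 1, j - 1] + pairable[i, j])
        for d in range(1, l):
            np.maximum(best, dp[i, i + d] + dp[i + d + 1, j], out=best)
        dp[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or dp[i, j] == 0:
            continue
        if pairable[i, j] and dp[i, j] == dp[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
        elif dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if dp[i, k] + dp[k + 1, j] == dp[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return sorted(pairs)


def predict_hairpin(window: str, mature_span: tuple[int, int]) -> HairpinResult:
    """Fold ``window`` and decide whether it hosts ``mature_span`` as a miRNA
    hairpin.

    ``mature_span`` is a half-open 0-based interval within the window.  The
    prediction passes iff the mature lies entirely on one arm (no base pair
    internal to the mature; all partners on one side), >=60% of mature bases
    are paired, the hairpin loop is >=3 nt, and >=45% of window bases are
    paired.
    """
    lo, hi = mature_span
    n = len(window)
    if not (0 <= lo < hi <= n):
        raise InputError(f"mature span {mature_span} outside window of length {n}")
    if n > 300:
        raise InputError("window longer than 300 nt")

    pairs = nussinov_pairs(window)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    structure = ["."] * n
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"

    loop_length = min((j - i - 1 for i, j in pairs), default=0)

    mature_positions = range(lo, hi)
    partners = [partner[i] for i in mature_positions if i in partner]
    paired_fraction = len(partners) / (hi - lo)
    window_fraction = 2 * len(pairs) / n if n else 0.0

    internal = any(lo <= q < hi for q in partners)
    arm = ""
    if partners and not internal:
        if all(q >= hi for q in partners):
            arm = "5p"
        elif all(q < lo for q in partners):
            arm = "3p"

    passed = (
        arm != ""
        and paired_fraction >= 0.6
        and loop_length >= MIN_LOOP
        and window_fraction >= 0.45
    )
    return HairpinResult(
        passed, paired_fraction, loop_length, arm, "".join(structure), pairs
    )


# ---------------------------------------------------------------------------
# Fuzzy matching of a tag to a reference mature and variant naming
# ---------------------------------------------------------------------------

MAX_SUB = 2
MAX_SHIFT = 2


@dataclass
class MatureMatch:
    d5: int              # tag 5' start minus mature start (+: extension)
    d3: int              # tag 3' end minus mature end (+: extension)
    substitutions: list[tuple[int, str, str]]  # (1-based tag pos, ref, tag)

    @property
    def cost(self) -> tuple[int, int]:
        return (len(self.substitutions), abs(self.d5) + abs(self.d3))


def match_mature(tag: str, mature: str) -> MatureMatch | None:
    """Best alignment of ``tag`` against ``mature`` allowing <=2 substitutions
    and <=2-nt trimming/extension at either end; None when no alignment fits.

    ``d5`` is negative for 5' trimming relative to the mature, positive for
    extension (bases the suffix grammar cannot spell; they come from the
    precursor context).  Substitution positions are 1-based on the tag.
    """
    if abs(len(tag) - len(mature)) > MAX_SHIFT * 2:
        return None
    best: MatureMatch | None = None
    for d5 in range(-MAX_SHIFT, MAX_SHIFT + 1):
        # tag position k corresponds to mature position k - d5... using
        # convention: d5 = (mature start index of tag start); trimming -> tag
        # starts inside the mature (offset +), extension -> before it.
        d3 = (len(tag) - len(mature)) - d5
        if abs(d3) > MAX_SHIFT:
            continue
        subs: list[tuple[int, str, str]] = []
        ok = True
        for k in range(len(tag)):
            m_idx = k - d5
            if m_idx < 0 or m_idx >= len(mature):
                continue  # extension base, not comparable
            if tag[k] != mature[m_idx]:
                subs.append((k + 1, mature[m_idx], tag[k]))
                if len(subs) > MAX_SUB:
                    ok = False
                    break
        if not ok:
            continue
        cand = MatureMatch(d5=d5, d3=d3, substitutions=subs)
        if best is None or cand.cost < best.cost:
            best = cand
    return best


def name_variant(tag: str, mature: str, ref_name: str) -> str | None:
    """ACGT101-style variant id: reference name plus an ``_L±k`` / ``_R±k`` /
    ``_nss<pos><ref><obs>`` suffix; None when the tag cannot be aligned."""
    m = match_mature(tag, mature)
    if m is None:
        return None
    parts = [ref_name]
    if m.d5 != 0:
        parts.append(f"L{m.d5:+d}")
    if m.d3 != 0:
        parts.append(f"R{m.d3:+d}")
    if m.substitutions:
        ss = "".join(f"{pos}{ref}{obs}" for pos, ref, obs in m.substitutions)
        parts.append(f"{len(m.substitutions)}ss{ss}")
    return "_".join(parts)


_SUFFIX_RE = re.compile(r"_(L[+-]\d+|R[+-]\d+|\d+ss(?:\d+[ACGTU]{2})+)")


def apply_variant(mature: str, suffix: str, context: tuple[str, str] = ("", "")) -> str:
    """Re-apply a variant suffix to a reference mature, regenerating the tag.

    ``context`` supplies the 5'/3' flanking precursor bases consumed by
    extensions; trims and substitutions need no context.
    """
    tag = mature
    left_ctx, right_ctx = context
    for op in _SUFFIX_RE.findall("_" + suffix if not suffix.startswith("_") else suffix):
        if op.startswith("L"):
            k = int(op[1:])
            if k < 0:
                tag = tag[-k:]
            elif k > 0:
                if len(left_ctx) < k:
                    raise InputError("5' extension requires precursor context")
                tag = left_ctx[-k:] + tag
        elif op.startswith("R"):
            k = int(op[1:])
            if k < 0:
                tag = tag[:k]
            elif k > 0:
                if len(right_ctx) < k:
                    raise InputError("3' extension requires precursor context")
                tag = tag + right_ctx[:k]
        else:
            body = op.split("ss", 1)[1]
            for pos, ref, obs in re.findall(r"(\d+)([ACGTU])([ACGTU])", body):
                p = int(pos) - 1
                chars = list(tag)
                chars[p] = obs
                tag = "".join(chars)
    return tag


# ---------------------------------------------------------------------------
# Classification cascade
# ---------------------------------------------------------------------------


@dataclass
class MiRNAEntry:
    id: str
    seq: str
    group: str
    precursor_id: str | None
    counts: pd.Series | None = None


def _fuzzy_substring(tag: str, text: str, max_mismatch: int = MAX_SUB) -> int | None:
    """Leftmost start of an occurrence of ``tag`` in ``text`` with up to
    ``max_mismatch`` substitutions; exact search fast path first."""
    pos = text.find(tag)
    if pos >= 0:
        return pos
    if max_mismatch == 0:
        return None
    n, m = len(text), len(tag)
    for start in range(0, n - m + 1):
        mm = 0
        for a, b in zip(tag, text[start:start + m]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return start
    return None


class ReferenceIndex:
    """Pre-indexed references for classification."""

    def __init__(
        self,
        wheat_mature: dict[str, str],
        wheat_precursor: dict[str, str],
        other_mature: dict[str, str],
        genome_windows: dict[str, str],
        mature_precursor: dict[str, str] | None = None,
    ):
        if not wheat_mature and not other_mature:
            raise ConfigurationError("no mature miRNA references supplied")
        self.wheat_mature = wheat_mature
        self.wheat_precursor = wheat_precursor
        self.other_mature = other_mature
        self.genome_windows = genome_windows
        self.wheat_by_seq = {s: n for n, s in wheat_mature.items()}
        self.other_by_seq = {s: n for n, s in other_mature.items()}
        # mature name -> precursor name; default pairing by shared numeric stem
        if mature_precursor is None:
            mature_precursor = {}
            for mname in wheat_mature:
                stem = re.sub(r"^(\w+)-miR", r"\1-MIR", mname)
                stem = re.sub(r"(-[35]p)?$", "", stem, count=1)
                if stem in wheat_precursor:
                    mature_precursor[mname] = stem
        self.mature_precursor = mature_precursor

    def find_wheat_mature(self, tag: str) -> tuple[str, MatureMatch] | None:
        if tag in self.wheat_by_seq:
            name = self.wheat_by_seq[tag]
            return name, MatureMatch(0, 0, [])
        best = None
        for name, mat in self.wheat_mature.items():
            m = match_mature(tag, mat)
            if m is not None and (best is None or m.cost < best[1].cost):
                best = (name, m)
        return best

    def find_other_mature(self, tag: str) -> tuple[str, MatureMatch] | None:
        if tag in self.other_by_seq:
            return self.other_by_seq[tag], MatureMatch(0, 0, [])
        best = None
        for name, mat in self.other_mature.items():
            m = match_mature(tag, mat)
            if m is not None and (best is None or m.cost < best[1].cost):
                best = (name, m)
        return best

    def find_precursor(self, tag: str) -> tuple[str, int] | None:
        # exact mapping (the original pipeline maps reads with bowtie); the
        # tolerant comparison against the annotated mature happens upstream
        for name, seq in self.wheat_precursor.items():
            pos = seq.find(tag)
            if pos >= 0:
                return name, pos
        return None

    def find_genome(self, tag: str) -> tuple[str, int] | None:
        for name, seq in self.genome_windows.items():
            pos = seq.find(tag)
            if pos >= 0:
                return name, pos
        return None


def _arm_of(pos: int, tag_len: int, total_len: int) -> str:
    center = pos + tag_len / 2
    return "5p" if center < total_len / 2 else "3p"


def classify_tag(tag: str, index: ReferenceIndex) -> MiRNAEntry | None:
    """Assign one tag to gp1a/gp1b/gp2a/gp2b/gp3/gp4 or None (unassigned)."""
    if not 18 <= len(tag) <= 25:
        return None

    wheat = index.find_wheat_mature(tag)
    if wheat is not None:
        name, m = wheat
        prec = index.mature_precursor.get(name)
        if prec is not None and _fuzzy_substring(tag, index.wheat_precursor[prec]) is not None:
            vid = name if m.cost == (0, 0) else name_variant(tag, index.wheat_mature[name], name)
            return MiRNAEntry(vid, tag, "gp1a", prec)

    prec_hit = index.find_precursor(tag)
    if prec_hit is not None:
        pname, pos = prec_hit
        arm = _arm_of(pos, len(tag), len(index.wheat_precursor[pname]))
        return MiRNAEntry(f"{pname}-p{arm[0]}", tag, "gp1b", pname)

    other = index.find_other_mature(tag)
    if other is not None:
        name, m = other
        vid = name if m.cost == (0, 0) else name_variant(tag, index.other_mature[name], name)
        gen = index.find_genome(tag)
        if gen is None:
            return MiRNAEntry(vid, tag, "gp3", None)
        wname, pos = gen
        window = index.genome_windows[wname]
        hp = predict_hairpin(window, (pos, pos + len(tag)))
        group = "gp2a" if hp.passed else "gp2b"
        return MiRNAEntry(vid, tag, group, wname if hp.passed else None)

    gen = index.find_genome(tag)
    if gen is not None:
        wname, pos = gen
        window = index.genome_windows[wname]
        hp = predict_hairpin(window, (pos, pos + len(tag)))
        if hp.passed:
            return MiRNAEntry(novel_id(hp.arm, tag), tag, "gp4", wname)
    return None


def build_catalog(tags: pd.DataFrame, index: ReferenceIndex) -> pd.DataFrame:
    """Classify every tag of a (seq x library) count table.

    Returns a catalog table indexed by miRNA id with columns ``seq``, ``group``,
    ``precursor`` and the per-library counts.  Unassigned tags are dropped.
    """
    rows = []
    for seq, counts in tags.iterrows():
        entry = classify_tag(str(seq), index)
        if entry is None:
            continue
        rows.append({"id": entry.id, "seq": entry.seq, "group": entry.group,
                     "precursor": entry.precursor_id or "", **counts.to_dict()})
    if not rows:
        return pd.DataFrame(columns=["seq", "group", "precursor"])
    df = pd.DataFrame(rows).set_index("id")
    return df


def base_composition(tags: pd.DataFrame) -> pd.DataFrame:
    """Per-length, per-position nucleotide frequencies weighted by total count.

    Returns a long-form table (length, position, A, C, G, U) where the four
    frequencies sum to 1 for every covered (length, position).
    """
    lib_cols = [c for c in tags.columns if c not in ("seq",)]
    weights = tags[lib_cols].sum(axis=1) if lib_cols else pd.Series(1, index=tags.index)
    rows = []
    for length in range(18, 26):
        sel = [s for s in tags.index if len(s) == length]
        if not sel:
            continue
        w = weights.loc[sel].to_numpy(dtype=float)
        if w.sum() == 0:
            w = np.ones(len(sel))
        for pos in range(length):
            freq = {b: 0.0 for b in "ACGU"}
            for s, wi in zip(sel, w):
                base = s[pos].replace("T", "U")
                freq[base] += wi
            total = sum(freq.values())
            rows.append({"length": length, "position": pos + 1,
                         **{b: v / total for b, v in freq.items()}})
    return pd.DataFrame(rows)
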