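"""Degradome (PARE) target validation.

Degradome tags are 5' ends of uncapped transcripts; a miRNA-guided cleavage
leaves a pileup of tag 5' ends at the transcript base paired to miRNA
nucleotide 10.  Per-transcript position profiles are classified into T-plot
categories:

* 0: count > 1, the unique maximum of the transcript;
* 1: count > 1, tied maximum (>= 2 positions);
* 2: 1 < count < max and count > mean over covered positions;
* 3: 1 < count <= mean;
* 4: count == 1.

Duplex scoring is the classic plant-target penalty scheme: match 0, G:U
wobble 0.5, mismatch 1.0, penalties doubled opposite miRNA positions 2-13,
ungapped, with a default cutoff of 4.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .seqio import read_fastq

MATCH_LEN = 20           # leading bases used for exact transcript mapping
SEED_DOUBLE = (2, 13)    # miRNA positions (1-based) with doubled penalty
DEFAULT_SCORE_MAX = 4.0
DEFAULT_CATEGORY_MAX = 2


@dataclass
class DegradomeProfile:
    transcript_id: str
    length: int
    counts: np.ndarray  # 1-based positions stored at index pos-1

    def covered(self) -> np.ndarray:
        return np.flatnonzero(self.counts > 0) + 1


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    cleavage_pos: int
    duplex_score: float
    category: int
    reads_at_site: int
    library: str = ""


def map_tags(
    fastq_path: str | Path,
    transcripts: dict[str, str],
    min_tag_len: int = 18,
) -> tuple[dict[str, DegradomeProfile], dict[str, int]]:
    """Build per-transcript 5'-end profiles from a degradome FASTQ.

    A tag is assigned to every transcript position where its first 20 nt
    match exactly (sense strand); multi-mapping tags count once per locus.
    """
    if not transcripts:
        raise ConfigurationError("empty transcriptome")
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        for i in range(0, len(seq) - MATCH_LEN + 1):
            index.setdefault(seq[i: i + MATCH_LEN], []).append((tid, i + 1))
    profiles = {
        tid: DegradomeProfile(tid, len(seq), np.zeros(len(seq), dtype=np.int64))
        for tid, seq in transcripts.items()
    }
    stats = {"tags": 0, "mapped": 0, "unmapped": 0, "too_short": 0}
    for _title, seq, _qual in read_fastq(fastq_path):
        stats["tags"] += 1
        if len(seq) < max(min_tag_len, MATCH_LEN):
            stats["too_short"] += 1
            continue
        hits = index.get(seq[:MATCH_LEN].upper())
        if not hits:
            stats["unmapped"] += 1
            continue
        stats["mapped"] += 1
        for tid, pos in hits:
            profiles[tid].counts[pos - 1] += 1
    return profiles, stats


_PENALTY_CACHE: dict[tuple[str, str], float] = {}


def _pair_penalty(mirna_base: str, target_base: str) -> float:
    """Penalty for one miRNA base opposite one target base (antiparallel):
    0 for Watson-Crick, 0.5 for G:U wobble, 1.0 otherwise."""
    key = (mirna_base, target_base)
    if key in _PENALTY_CACHE:
        return _PENALTY_CACHE[key]
    m = mirna_base.upper().replace("U", "T")
    t = target_base.upper().replace("U", "T")
    wc = {"A": "T", "T": "A", "G": "C", "C": "G"}
    if wc.get(m) == t:
        p = 0.0
    elif (m, t) in (("G", "T"), ("T", "G")):
        p = 0.5
    else:
        p = 1.0
    _PENALTY_CACHE[key] = p
    return p


def score_duplex(mirna: str, site: str) -> float:
    """Penalty score of an ungapped miRNA:target duplex.

    ``site`` is the target subsequence 5'->3'; the miRNA pairs antiparallel,
    so miRNA position i (1-based from its 5' end) faces site position
    len - i + 1.  Penalties are doubled at miRNA positions 2-13.
    """
    if len(mirna) != len(site):
        raise InputError("site length must equal miRNA length (ungapped mode)")
    L = len(mirna)
    score = 0.0
    for i in range(1, L + 1):
        p = _pair_penalty(mirna[i - 1], site[L - i])
        if SEED_DOUBLE[0] <= i <= SEED_DOUBLE[1]:
            p *= 2
        score += p
    return score


def cleavage_position(site_start: int, mirna_len: int) -> int:
    """Transcript position (1-based) paired to miRNA nucleotide 10 for a site
    starting at 1-based ``site_start``."""
    return site_start + (mirna_len - 10)


def find_candidate_sites(
    mirna: str, transcript: str, score_max: float = DEFAULT_SCORE_MAX
) -> list[tuple[int, int, float]]:
    """Slide an ungapped window over the transcript; return
    (site_start, cleavage_pos, score) for windows scoring <= score_max."""
    L = len(mirna)
    if len(transcript) < L:
        return []
    out = []
    for start in range(1, len(transcript) - L + 2):
        site = transcript[start - 1: start - 1 + L]
        s = score_duplex(mirna, site)
        if s <= score_max:
            out.append((start, cleavage_position(start, L), s))
    return out


def categorize_site(profile: DegradomeProfile, pos: int) -> int | None:
    """T-plot category of one 1-based position; None when uncovered."""
    if not 1 <= pos <= profile.length:
        raise InputError(f"position {pos} outside transcript of length {profile.length}")
    c = int(profile.counts[pos - 1])
    if c == 0:
        return None
    if c == 1:
        return 4
    covered = profile.counts[profile.counts > 0]
    m = int(covered.max())
    mu = float(covered.mean())
    if c == m:
        return 0 if int((profile.counts == m).sum()) == 1 else 1
    if c > mu:
        return 2
    return 3


def validate_targets(
    mirnas: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    transcripts: dict[str, str],
    score_max: float = DEFAULT_SCORE_MAX,
    category_max: int = DEFAULT_CATEGORY_MAX,
    library: str = "",
) -> list[TargetHit]:
    """Cleavage-validated targets of a set of candidate miRNAs.

    Keeps (miRNA, transcript, site) combinations whose cleavage position has
    more than one degradome read and a T-plot category <= ``category_max``,
    and whose duplex scores <= ``score_max``.  Implemented position-first
    (equivalent to filtering find_candidate_sites output, because every kept
    hit must sit on a covered position with count > 1).
    """
    hits: list[TargetHit] = []
    for tid, profile in profiles.items():
        seq = transcripts.get(tid)
        if seq is None:
            continue
        cand_pos = [
            int(p) for p in profile.covered()
            if profile.counts[p - 1] > 1
        ]
        if not cand_pos:
            continue
        cats = {p: categorize_site(profile, p) for p in cand_pos}
        for mid, mseq in mirnas.items():
            L = len(mseq)
            for p in cand_pos:
                cat = cats[p]
                if cat is None or cat > category_max:
                    continue
                start = p - (L - 10)
                if start < 1 or start + L - 1 > len(seq):
                    continue
                site = seq[start - 1: start - 1 + L]
                s = score_duplex(mseq, site)
                if s <= score_max:
                    hits.append(
                        TargetHit(mid, tid, p, s, cat,
                                  int(profile.counts[p - 1]), library)
                    )
    return hits


def hits_table(hits: list[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [h.__dict__ for h in hits],
        columns=["mirna_id", "transcript_id", "cleavage_pos", "duplex_score",
                 "category", "reads_at_site", "library"],
    )


def summarize_hits(hits: list[TargetHit]) -> dict:
    mirnas = {h.mirna_id for h in hits}
    transcripts = {h.transcript_id for h in hits}
    return {
        "validated_mirnas": len(mirnas),
        "validated_transcripts": len(transcripts),
        "hits": len(hits),
        "mirna_ids": mirnas,
        "transcript_ids": transcripts,
    }
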