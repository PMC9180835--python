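"""Small-RNA read preprocessing: adapter/UMI extraction, PCR deduplication,
tag collapsing and contaminant filtering.

The read layout is insert + 3' adapter + UMI (padded to a fixed read length).
A read is rejected when its raw length falls outside the 30-80 nt gate, its
mean Phred quality is below 20, the adapter is missing, or the insert is
empty.  PCR duplicates are molecules identical in (insert, UMI); the
duplication ratio is ``1 - unique/total``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError
from .seqio import read_fastq

RAW_MIN, RAW_MAX = 30, 80
TAG_MIN, TAG_MAX = 18, 25
MIN_MEAN_QUALITY = 20.0
LOW_COMPLEXITY_FRACTION = 0.8


@dataclass
class Molecule:
    insert: str
    umi: str


@dataclass
class PreprocessStats:
    raw_reads: int = 0
    length_pass: int = 0
    quality_pass: int = 0
    adapter_found: int = 0
    molecules: int = 0
    unique_molecules: int = 0
    duplication_ratio: float = 0.0
    contaminant_removed: dict = field(default_factory=dict)
    valid_tags: int = 0

    def as_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k != "contaminant_removed"}
        for cls, n in self.contaminant_removed.items():
            row[f"removed_{cls}"] = n
        return row


def _mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)


def _find_adapter(seq: str, adapter: str) -> int:
    """Leftmost adapter occurrence: one mismatch allowed in the first 8
    adapter bases, further adapter bases present in the read must match
    (a tail truncated by the read end is accepted)."""
    exact = seq.find(adapter)
    limit = exact if exact >= 0 else len(seq) - min(8, len(adapter)) + 1
    head = adapter[:8]
    rest = adapter[8:]
    for start in range(0, limit):
        mm = 0
        ok = True
        for k, hc in enumerate(head):
            if start + k >= len(seq) or seq[start + k] != hc:
                mm += 1
                if mm > 1:
                    ok = False
                    break
        if not ok:
            continue
        got = seq[start + 8: start + 8 + len(rest)]
        if got == rest[: len(got)]:
            return start
    return exact


def trim_and_extract(
    seq: str, qual: str, adapter: str, umi_len: int
) -> tuple[Molecule | None, str]:
    """Extract (insert, UMI) from one read; returns (None, reason) on
    rejection with reason in {'length', 'quality', 'no_adapter', 'empty_insert',
    'no_umi'}."""
    if not adapter:
        raise ConfigurationError("adapter sequence must be non-empty")
    if not RAW_MIN <= len(seq) <= RAW_MAX:
        return None, "length"
    if _mean_quality(qual) < MIN_MEAN_QUALITY:
        return None, "quality"
    pos = _find_adapter(seq, adapter)
    if pos < 0:
        return None, "no_adapter"
    if pos == 0:
        return None, "empty_insert"
    umi = seq[pos + len(adapter): pos + len(adapter) + umi_len]
    if len(umi) < umi_len:
        return None, "no_umi"
    return Molecule(insert=seq[:pos].upper(), umi=umi.upper()), "ok"


def dedup_umi(molecules: list[Molecule]) -> tuple[list[Molecule], float]:
    """Collapse molecules identical in (insert, UMI); ratio = 1 - unique/total."""
    total = len(molecules)
    seen: dict[tuple[str, str], Molecule] = {}
    for m in molecules:
        seen.setdefault((m.insert, m.umi), m)
    unique = list(seen.values())
    ratio = 0.0 if total == 0 else 1.0 - len(unique) / total
    return unique, ratio


def collapse_tags(unique_by_library: dict[str, list[Molecule]]) -> pd.DataFrame:
    """One row per distinct insert, one count column per library (zeros where
    a tag is absent); the column sum equals that library's unique molecules."""
    counters = {lib: Counter(m.insert for m in mols)
                for lib, mols in unique_by_library.items()}
    tags = sorted(set().union(*[set(c) for c in counters.values()] or [set()]))
    df = pd.DataFrame(
        {lib: [c.get(t, 0) for t in tags] for lib, c in counters.items()},
        index=pd.Index(tags, name="seq"), dtype=int,
    )
    return df


def is_low_complexity(tag: str) -> bool:
    if not tag:
        return True
    counts = Counter(tag)
    return counts.most_common(1)[0][1] / len(tag) > LOW_COMPLEXITY_FRACTION


def filter_contaminants(
    tags: pd.DataFrame,
    contaminants: dict[str, dict[str, str]],
    mrna: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Remove contaminant / junk tags and restrict to the 18-25 nt miRNA range.

    A tag is removed when it is an exact full-length substring of any
    contaminant record (class recorded), or is low-complexity (one base above
    80%).  Clean tags outside 18-25 nt are excluded from the miRNA set but
    reported separately.  Returns (clean, removed, removed_counts_by_class).
    """
    if not contaminants and not mrna:
        raise ConfigurationError("no contaminant references supplied")
    classes = dict(contaminants)
    if mrna:
        classes = {**classes, "mRNA": mrna}
    removed_class: dict[str, str] = {}
    for tag in tags.index:
        t = str(tag)
        for cls, records in classes.items():
            if any(t in seq for seq in records.values()):
                removed_class[t] = cls
                break
        else:
            if is_low_complexity(t):
                removed_class[t] = "low_complexity"
            elif not TAG_MIN <= len(t) <= TAG_MAX:
                removed_class[t] = "length"
    removed_mask = tags.index.isin(removed_class)
    removed = tags.loc[removed_mask].copy()
    removed["class"] = [removed_class[str(t)] for t in removed.index]
    clean = tags.loc[~removed_mask]
    by_class = Counter(removed_class.values())
    return clean, removed, dict(by_class)


def preprocess_library(
    path: str | Path, adapter: str, umi_len: int
) -> tuple[list[Molecule], PreprocessStats]:
    """Run trim + dedup for one FASTQ library."""
    stats = PreprocessStats()
    molecules: list[Molecule] = []
    for _title, seq, qual in read_fastq(path):
        stats.raw_reads += 1
        mol, reason = trim_and_extract(seq, qual, adapter, umi_len)
        if reason != "length":
            stats.length_pass += 1
            if reason != "quality":
                stats.quality_pass += 1
        if mol is not None:
            stats.adapter_found += 1
            molecules.append(mol)
    stats.molecules = len(molecules)
    unique, ratio = dedup_umi(molecules)
    stats.unique_molecules = len(unique)
    stats.duplication_ratio = ratio
    return unique, stats


def preprocess_libraries(
    paths: dict[str, str | Path],
    adapter: str,
    umi_len: int,
    contaminants: dict[str, dict[str, str]],
    mrna: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full preprocessing over a set of libraries.

    Returns (clean_tags, removed_tags, stats_table); clean tags are the
    18-25 nt UMI-deduplicated unique-tag counts per library.
    """
    unique_by_library = {}
    stats_rows = {}
    for lib, path in paths.items():
        unique, stats = preprocess_library(path, adapter, umi_len)
        unique_by_library[lib] = unique
        stats_rows[lib] = stats
    tags = collapse_tags(unique_by_library)
    clean, removed, by_class = filter_contaminants(tags, contaminants, mrna)
    for lib, stats in stats_rows.items():
        stats.contaminant_removed = {
            cls: int(removed.loc[removed["class"] == cls, lib].sum())
            for cls in by_class
        }
        stats.valid_tags = int((clean[lib] > 0).sum())
    stats_df = pd.DataFrame(
        {lib: s.as_row() for lib, s in stats_rows.items()}
    ).T.fillna(0)
    return clean, removed, stats_df
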