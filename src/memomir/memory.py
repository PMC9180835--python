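"""Drought-memory candidate selection from per-contrast DE results.

The selection logic: miRNAs DE in the primed group (DM vs CG union over the
post-stress timepoints) but not in the unprimed group (DD vs CG union) are
memory-specific; shared miRNAs that are additionally DE between DM and DD are
"rescued" back into the candidate set.  candidates = specific ∪ rescue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError


@dataclass
class MemoryCallSet:
    dm_union: set[str]
    dd_union: set[str]
    shared: set[str]
    specific: set[str]
    rescue: set[str]
    candidates: set[str]
    baseline: set[str] = field(default_factory=set)
    baseline_up: set[str] = field(default_factory=set)
    baseline_down: set[str] = field(default_factory=set)

    def validate(self) -> None:
        assert self.shared == self.dm_union & self.dd_union
        assert self.specific == self.dm_union - self.shared
        assert self.rescue <= self.shared
        assert self.candidates == self.specific | self.rescue
        assert not (self.specific & self.rescue)

    def cardinalities(self) -> dict[str, int]:
        return {
            "dm_union": len(self.dm_union),
            "dd_union": len(self.dd_union),
            "shared": len(self.shared),
            "specific": len(self.specific),
            "rescue": len(self.rescue),
            "candidates": len(self.candidates),
            "baseline": len(self.baseline),
            "baseline_up": len(self.baseline_up),
            "baseline_down": len(self.baseline_down),
        }


def union_de(comparisons: list[pd.DataFrame], alpha: float = 0.05) -> set[str]:
    """ids significant (p < alpha) in at least one comparison table."""
    if not comparisons:
        raise InputError("need at least one DE comparison")
    out: set[str] = set()
    for comp in comparisons:
        out |= set(comp.index[comp["p"] < alpha])
    return out


def select_memory_candidates(
    dm_union: set[str], dd_union: set[str], dm_vs_dd_union: set[str]
) -> MemoryCallSet:
    """Apply the memory-selection set algebra.

    specific = dm_union \\ dd_union; rescue = (dm_union ∩ dd_union) ∩
    dm_vs_dd_union; candidates = specific ∪ rescue.
    """
    shared = set(dm_union) & set(dd_union)
    specific = set(dm_union) - shared
    rescue = shared & set(dm_vs_dd_union)
    return MemoryCallSet(
        dm_union=set(dm_union),
        dd_union=set(dd_union),
        shared=shared,
        specific=specific,
        rescue=rescue,
        candidates=specific | rescue,
    )


def baseline_de(
    matrix: pd.DataFrame,
    cg_libs: list[str],
    dm_libs: list[str],
    alpha: float = 0.05,
) -> tuple[set[str], set[str], set[str]]:
    """Baseline (pre-stress) DE of DM against CG with an up/down partition.

    Returns (significant, up, down)."""
    from .expression import de_pairwise

    missing = [c for c in cg_libs + dm_libs if c not in matrix.columns]
    if missing:
        raise InputError(f"libraries missing from matrix: {missing}")
    comp = de_pairwise(matrix, cg_libs, dm_libs, alpha=alpha)
    sig = comp[comp["significant"]]
    up = set(sig.index[sig["direction"] == "up"])
    down = set(sig.index[sig["direction"] == "down"])
    return set(sig.index), up, down


def venn_summary(calls: MemoryCallSet) -> pd.DataFrame:
    """Two-set Venn cells for the DM/DD union overlap."""
    return pd.DataFrame(
        [
            {"cell": "DM_only", "count": len(calls.specific)},
            {"cell": "shared", "count": len(calls.shared)},
            {"cell": "DD_only", "count": len(calls.dd_union - calls.shared)},
            {"cell": "rescue", "count": len(calls.rescue)},
            {"cell": "candidates", "count": len(calls.candidates)},
        ]
    )
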