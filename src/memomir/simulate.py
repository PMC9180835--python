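"""Synthetic study generator for the drought-memory sRNA + degradome design.

Emulates a three-group (CG control, DD direct drought, DM drought memory) by
four-timepoint (0/1/6/12 h) by three-replicate small-RNA experiment (33
libraries) plus three pooled degradome libraries, with a planted differential
structure: a baseline DE set (DM_0h vs CG_0h, with an up/down split), DM- and
DD-responsive union sets over the post-stress timepoints, a shared subset, a
"rescue" subset that is additionally DE between DM and DD, and a set of
degradome-validated miRNA-target pairs.

Acceptance noise mode
---------------------
In ``noise_mode="acceptance"`` counts are fully deterministic and every
library's total miRNA count is balanced to the same constant.  Per-million
normalization is then the same scale factor in every library, so null miRNAs
stay *exactly* flat and differential-expression recovery of the planted sets
is exact (the zero-variance degenerate t-test rules apply).  Balance is
achieved by giving each group x timepoint library class mostly down-regulated
planted effects plus one class-exclusive up-regulated "absorber" member whose
count soaks up the integer residual (its fold is therefore >= effect_fold).

``noise_mode="realistic"`` draws gamma-Poisson (negative binomial) counts
around the same means; set recovery is then only approximate.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .seqio import revcomp, write_fasta, write_fastq

GROUPS = ("CG", "DD", "DM")
TIMEPOINTS = (0, 1, 6, 12)
POST_TIMEPOINTS = (1, 6, 12)

# TruSeq-small-RNA-like 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

HAIRPIN_LOOP = "TTCAATTA"  # low self-pairing loop used in planted precursors

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


@dataclass(frozen=True)
class PlantedSets:
    """Cardinalities of the planted differential structure."""

    baseline_up: int = 8
    baseline_down: int = 5
    dm_union: int = 18
    dd_union: int = 15
    shared: int = 6
    rescue: int = 2
    validated_mirnas: int = 5
    validated_targets: int = 12
    baseline_validated_overlap: int = 2

    @property
    def baseline(self) -> int:
        return self.baseline_up + self.baseline_down

    @property
    def specific(self) -> int:
        return self.dm_union - self.shared

    @property
    def candidates(self) -> int:
        return self.specific + self.rescue


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of a synthetic scenario.

    ``n_null`` is derived (miRNAs belonging to no planted set) and validated
    against the layout rather than supplied independently.
    """

    name: str = "small"
    n_mirnas: int = 60
    n_transcripts: int = 20
    planted_sets: PlantedSets = field(default_factory=PlantedSets)
    group_sizes: int = 3
    effect_fold: float = 4.0
    noise_mode: str = "acceptance"
    cv: float = 0.05
    seed: int = 12061

    base_count: int = 12          # per-library molecules of an unaffected miRNA
    duplication_rate: float = 0.2  # PCR duplicate fraction of final reads
    umi_len: int = 12
    read_len: int = 60
    adapter: str = DEFAULT_ADAPTER
    transcript_len: int = 300
    degradome_signal_reads: int = 7
    degradome_background_sites: int = 8
    # non-gp1a class sizes; remaining miRNAs are gp1a
    class_counts: dict = field(
        default_factory=lambda: {"gp1b": 4, "gp2a": 4, "gp2b": 4, "gp3": 4, "gp4": 4}
    )

    # ---- derived layout (contiguous index blocks over 0..n_mirnas) ----
    @property
    def _blocks(self) -> dict[str, range]:
        p = self.planted_sets
        shared = range(0, p.shared)
        rescue = range(0, p.rescue)
        specific = range(p.shared, p.dm_union)
        dd_only = range(p.dm_union, p.dm_union + p.dd_union - p.shared)
        validated = range(p.shared, p.shared + p.validated_mirnas)
        b_start = p.shared + p.validated_mirnas - p.baseline_validated_overlap
        baseline = range(b_start, b_start + p.baseline)
        return {
            "shared": shared,
            "rescue": rescue,
            "specific": specific,
            "dd_only": dd_only,
            "validated": validated,
            "baseline": baseline,
        }

    @property
    def n_null(self) -> int:
        b = self._blocks
        involved = set()
        for r in b.values():
            involved.update(r)
        return self.n_mirnas - len(involved)

    def validate(self) -> None:
        p = self.planted_sets
        if self.n_mirnas < 1:
            raise ConfigurationError("n_mirnas must be >= 1")
        if self.base_count % 4 != 0 or self.base_count < 4:
            raise ConfigurationError("base_count must be a positive multiple of 4")
        if self.noise_mode not in ("acceptance", "realistic"):
            raise ConfigurationError(f"unknown noise_mode {self.noise_mode!r}")
        if not 0 <= self.duplication_rate < 1:
            raise ConfigurationError("duplication_rate must be in [0, 1)")
        if p.shared > min(p.dm_union, p.dd_union):
            raise ConfigurationError("shared set exceeds the DM/DD unions")
        if p.rescue > p.shared:
            raise ConfigurationError("rescue set must be a subset of shared")
        if p.validated_mirnas > p.specific:
            raise ConfigurationError(
                "validated miRNAs must fit inside the DM-specific set"
            )
        if p.baseline_validated_overlap > min(p.validated_mirnas, p.baseline):
            raise ConfigurationError("baseline/validated overlap too large")
        if p.baseline_up > 0 and p.baseline_down == 0:
            raise ConfigurationError(
                "baseline needs down-regulated members to balance library totals"
            )
        if p.baseline_down > 0 and p.baseline_up == 0:
            raise ConfigurationError(
                "baseline needs up-regulated members to balance library totals"
            )
        if p.rescue > 0 and self.base_count // 4 < 2:
            raise ConfigurationError(
                "base_count too small to distinguish rescue members between DM and DD"
            )
        b = self._blocks
        end = max((r.stop for r in b.values()), default=0)
        if end > self.n_mirnas:
            raise ConfigurationError(
                f"planted sets need {end} miRNAs but n_mirnas={self.n_mirnas}"
            )
        if p.validated_targets > self.n_transcripts:
            raise ConfigurationError("validated_targets exceeds n_transcripts")
        if p.validated_mirnas > 0 and p.validated_targets < p.validated_mirnas:
            raise ConfigurationError("need at least one target per validated miRNA")
        n_special = sum(self.class_counts.values())
        if n_special > self.n_mirnas:
            raise ConfigurationError("class_counts exceed n_mirnas")
        for cls in self.class_counts:
            if cls not in ("gp1b", "gp2a", "gp2b", "gp3", "gp4"):
                raise ConfigurationError(f"unknown miRNA class {cls!r}")

    @property
    def libraries(self) -> list[str]:
        return [
            f"{g}_{t}h_r{r + 1}"
            for g in GROUPS
            for t in TIMEPOINTS
            for r in range(self.group_sizes)
        ]

    def group_libs(self, group: str, timepoint: int) -> list[str]:
        return [f"{group}_{timepoint}h_r{r + 1}" for r in range(self.group_sizes)]


def cs_memory_scenario() -> ScenarioConfig:
    """Preset 'cs-memory-v1': planted cardinalities of the Chinese Spring
    drought-memory study design (198 baseline DE with 75 down, 243 DM-
    responsive, 228 DD-responsive, 57 shared, 9 rescue, 64 validated miRNAs
    with 445 target transcripts, 19 baseline-validated overlap)."""
    return ScenarioConfig(
        name="cs-memory-v1",
        n_mirnas=500,
        n_transcripts=500,
        planted_sets=PlantedSets(
            baseline_up=123,
            baseline_down=75,
            dm_union=243,
            dd_union=228,
            shared=57,
            rescue=9,
            validated_mirnas=64,
            validated_targets=445,
            baseline_validated_overlap=19,
        ),
        class_counts={"gp1b": 30, "gp2a": 30, "gp2b": 30, "gp3": 30, "gp4": 30},
        seed=20220525,
    )


PRESETS = {"cs-memory-v1": cs_memory_scenario}


def novel_id(arm: str, seq: str) -> str:
    """Deterministic id for a novel (gp4) miRNA, 'PC-5p-<serial>' style."""
    return f"PC-{arm}-{zlib.crc32(seq.encode()) % 100000}"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _umi(index: int, umi_len: int) -> str:
    digits = []
    for _ in range(umi_len):
        digits.append("ACGT"[index % 4])
        index //= 4
    return "".join(digits)


# ---------------------------------------------------------------------------
# Scenario layout: per-miRNA identity, class, set membership and counts
# ---------------------------------------------------------------------------


@dataclass
class _MirnaPlan:
    index: int
    mid: str              # catalog id the pipeline will assign
    seq: str              # mature / tag sequence (DNA alphabet)
    gp: str               # gp1a / gp1b / gp2a / gp2b / gp3 / gp4
    base: int             # per-library count without planted effect
    ref_name: str = ""    # wheat or other-species reference entry name
    precursor_id: str = ""


def _build_plans(config: ScenarioConfig) -> list[_MirnaPlan]:
    rng = np.random.default_rng(config.seed)
    n = config.n_mirnas
    classes = ["gp1a"] * n
    special: list[str] = []
    for cls, cnt in config.class_counts.items():
        special.extend([cls] * cnt)
    idx = rng.permutation(n)[: len(special)]
    for i, cls in zip(idx, special):
        classes[i] = cls

    seen: set[str] = set()

    def fresh(length: int) -> str:
        while True:
            s = _random_seq(rng, length)
            if s not in seen and revcomp(s) not in seen:
                seen.add(s)
                return s

    plans: list[_MirnaPlan] = []
    for i in range(n):
        gp = classes[i]
        length = int(rng.integers(20, 25))
        if gp == "gp1a":
            seq = fresh(length)
            plans.append(
                _MirnaPlan(i, f"tae-miR{1000 + i}", seq, gp, 0,
                           ref_name=f"tae-miR{1000 + i}",
                           precursor_id=f"tae-MIR{1000 + i}")
            )
        elif gp == "gp1b":
            # annotated mature on the 5p arm; the observed tag is the 3p arm
            annotated = fresh(length)
            seq = revcomp(annotated)
            seen.add(seq)
            plans.append(
                _MirnaPlan(i, f"tae-MIR{1000 + i}-p3", seq, gp, 0,
                           ref_name=f"tae-miR{1000 + i}-5p",
                           precursor_id=f"tae-MIR{1000 + i}")
            )
        elif gp in ("gp2a", "gp2b", "gp3"):
            seq = fresh(length)
            plans.append(
                _MirnaPlan(i, f"osa-miR{2000 + i}", seq, gp, 0,
                           ref_name=f"osa-miR{2000 + i}")
            )
        else:  # gp4
            seq = fresh(length)
            plans.append(_MirnaPlan(i, novel_id("5p", seq), seq, gp, 0))
    return plans


def _allocate_timepoints(rng: np.random.Generator, members: list[int]) -> dict[int, int]:
    """Assign each member one post-stress timepoint, balanced round-robin
    after a seeded shuffle (the per-timepoint split is not itself planted)."""
    order = list(members)
    rng.shuffle(order)
    return {m: POST_TIMEPOINTS[i % 3] for i, m in enumerate(order)}


def expected_count_matrix(config: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    """Expected unique-molecule counts per miRNA per library, plus the layout
    (id sets, timepoint allocation) used to generate them."""
    config.validate()
    p = config.planted_sets
    blocks = config._blocks
    plans = _build_plans(config)
    rng = np.random.default_rng(config.seed + 1)

    baseline = list(blocks["baseline"])
    baseline_up = baseline[: p.baseline_up]
    baseline_down = baseline[p.baseline_up:]
    shared = list(blocks["shared"])
    rescue = list(blocks["rescue"])
    shared_nonrescue = shared[p.rescue:]
    specific = list(blocks["specific"])
    dd_only = list(blocks["dd_only"])

    bases = np.full(config.n_mirnas, config.base_count, dtype=np.int64)
    fold = int(config.effect_fold)

    tp_specific = _allocate_timepoints(rng, specific)
    tp_dd_only = _allocate_timepoints(rng, dd_only)
    tp_shared = _allocate_timepoints(rng, shared_nonrescue)
    tp_rescue = _allocate_timepoints(rng, rescue)

    # One up-regulated "absorber" per union library class soaks up the
    # integer balance residual; give it a small base so little down-capacity
    # is needed.  Members destined for large baseline-down bases are excluded.
    bdown_set = set(baseline_down)
    absorbers: dict[tuple[str, int], int] = {}
    for t in POST_TIMEPOINTS:
        for group, members, tp in (("DM", specific, tp_specific),
                                   ("DD", dd_only, tp_dd_only)):
            flex = [m for m in members if tp[m] == t]
            pick = next((m for m in flex if m not in bdown_set), None)
            if pick is None and flex:
                pick = flex[0]
            if pick is not None:
                absorbers[(group, t)] = pick
                if pick not in bdown_set:
                    bases[pick] = 4

    if baseline_down:
        # enough down-capacity at 0 h to balance the planted number of ups
        need = 4 * int(bases[baseline_up].sum())
        per = -(-need // len(baseline_down))  # ceil
        bases[baseline_down] = 4 * (-(-per // 4))

    libs = config.libraries
    counts = pd.DataFrame(
        np.tile(bases[:, None], (1, len(libs))), columns=libs,
        index=[pl.mid for pl in plans], dtype=np.int64,
    )

    def apply_class(group: str, t: int, ups: list[int], downs: list[int],
                    fixed: list[tuple[int, int]]) -> None:
        """Set counts for one group x timepoint library class, balancing the
        total to the all-base constant. ups[0] absorbs the residual."""
        cols = config.group_libs(group, t)
        vals: dict[int, int] = {}
        for m, c in fixed:
            vals[m] = c
        for m in downs:
            vals[m] = int(bases[m]) // fold
        for m in ups:
            vals[m] = int(bases[m]) * fold
        net = sum(c - int(bases[m]) for m, c in vals.items())
        if net < 0:
            if not ups:
                raise ConfigurationError(
                    f"library class {group}_{t}h has no up-regulated member to "
                    "absorb the balance residual"
                )
            vals[ups[0]] += -net
        elif net > 0:
            for m in downs:
                take = min(net, vals[m] - 1)
                vals[m] -= take
                net -= take
                if net == 0:
                    break
            if net > 0:
                raise ConfigurationError(
                    f"cannot balance library class {group}_{t}h; add more "
                    "down-capacity (bigger sets or base_count)"
                )
        rows = [plans[m].mid for m in vals]
        counts.loc[rows, cols] = np.array(list(vals.values()))[:, None]

    # baseline class: DM_0h vs CG_0h with the printed up/down split
    if baseline:
        apply_class("DM", 0, baseline_up, baseline_down, [])

    for t in POST_TIMEPOINTS:
        spec_t = [m for m in specific if tp_specific[m] == t]
        ddo_t = [m for m in dd_only if tp_dd_only[m] == t]
        shr_t = [m for m in shared_nonrescue if tp_shared[m] == t]
        res_t = [m for m in rescue if tp_rescue[m] == t]
        # shared non-rescue: identical down effect in DM and DD (never DM-vs-DD DE)
        shr_fixed = [(m, int(bases[m]) // fold) for m in shr_t]
        # rescue: down in both groups but at different depths, so it is DE in
        # DM-vs-CG, DD-vs-CG and DM-vs-DD (noiseless counts: any difference is
        # exact); down effects keep the per-library balance tractable
        dm_fixed = shr_fixed + [(m, int(bases[m]) // fold) for m in res_t]
        dd_fixed = shr_fixed + [(m, 1) for m in res_t]
        for group, flex, fixed in (("DM", spec_t, dm_fixed),
                                   ("DD", ddo_t, dd_fixed)):
            if not flex and not fixed:
                continue
            ab = absorbers.get((group, t))
            ups = [ab] if ab is not None else []
            downs = [m for m in flex if m != ab]
            apply_class(group, t, ups, downs, fixed)

    if config.noise_mode == "realistic":
        noise_rng = np.random.default_rng(config.seed + 2)
        mean = counts.to_numpy().astype(float)
        shape = 1.0 / max(config.cv, 1e-6) ** 2
        lam = mean * noise_rng.gamma(shape, 1.0 / shape, size=mean.shape)
        counts = pd.DataFrame(
            noise_rng.poisson(lam), index=counts.index, columns=counts.columns
        )

    ids = [pl.mid for pl in plans]

    def id_set(members) -> set[str]:
        return {ids[m] for m in members}

    layout = {
        "plans": plans,
        "sets": {
            "dm_union": id_set(shared + specific),
            "dd_union": id_set(shared + dd_only),
            "shared": id_set(shared),
            "rescue": id_set(rescue),
            "specific": id_set(specific),
            "candidates": id_set(specific + rescue),
            "baseline": id_set(baseline),
            "baseline_up": id_set(baseline_up),
            "baseline_down": id_set(baseline_down),
            "validated_mirnas": id_set(blocks["validated"]),
        },
        "timepoints": {
            "specific": tp_specific, "dd_only": tp_dd_only,
            "shared": tp_shared, "rescue": tp_rescue,
        },
    }
    return counts, layout


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------


@dataclass
class ReferenceBundle:
    wheat_mature: dict[str, str]
    wheat_precursor: dict[str, str]
    other_mature: dict[str, str]
    transcripts: dict[str, str]
    genome_windows: dict[str, str]
    contaminants: dict[str, dict[str, str]]   # class -> {name: seq}
    mrna: dict[str, str]
    annotation: pd.DataFrame                  # gene, term, label, namespace

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for key, recs in [
            ("mature", self.wheat_mature),
            ("precursor", self.wheat_precursor),
            ("other_mature", self.other_mature),
            ("transcripts", self.transcripts),
            ("genome_windows", self.genome_windows),
            ("mrna", self.mrna),
        ]:
            paths[key] = outdir / f"{key}.fa"
            write_fasta(paths[key], recs.items())
        flat = [
            (f"{cls}|{name}", seq)
            for cls, recs in self.contaminants.items()
            for name, seq in recs.items()
        ]
        paths["contaminants"] = outdir / "contaminants.fa"
        write_fasta(paths["contaminants"], flat)
        paths["annotation"] = outdir / "annotation.tsv"
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        return paths


def _hairpin(seq: str) -> str:
    return seq + HAIRPIN_LOOP + revcomp(seq)


def _target_allocation(config: ScenarioConfig) -> list[int]:
    """Number of target transcripts per validated miRNA (sums to the planted
    total; e.g. 61 x 7 + 3 x 6 = 445 for the cs-memory-v1 preset)."""
    p = config.planted_sets
    v = p.validated_mirnas
    if v == 0:
        return []
    q, r = divmod(p.validated_targets, v)
    return [q + 1] * r + [q] * (v - r)


def make_reference(config: ScenarioConfig) -> ReferenceBundle:
    """Build the reference FASTA bundle for a scenario.

    Every mature miRNA is embedded in one arm of a precursor/window that folds
    into a perfect-stem hairpin (except gp2b decoy windows, built with poly-A
    flanks so folding fails); every validated target transcript carries a site
    exactly complementary to its miRNA.
    """
    config.validate()
    counts, layout = expected_count_matrix(config)
    plans: list[_MirnaPlan] = layout["plans"]
    rng = np.random.default_rng(config.seed + 3)

    wheat_mature: dict[str, str] = {}
    wheat_precursor: dict[str, str] = {}
    other_mature: dict[str, str] = {}
    genome_windows: dict[str, str] = {}

    for pl in plans:
        if pl.gp == "gp1a":
            wheat_mature[pl.ref_name] = pl.seq
            wheat_precursor[pl.precursor_id] = _hairpin(pl.seq)
        elif pl.gp == "gp1b":
            annotated = revcomp(pl.seq)
            wheat_mature[pl.ref_name] = annotated
            wheat_precursor[pl.precursor_id] = _hairpin(annotated)
        elif pl.gp == "gp2a":
            other_mature[pl.ref_name] = pl.seq
            genome_windows[f"window_{pl.index}"] = _hairpin(pl.seq)
        elif pl.gp == "gp2b":
            other_mature[pl.ref_name] = pl.seq
            genome_windows[f"window_{pl.index}"] = "A" * 30 + pl.seq + "A" * 30
        elif pl.gp == "gp3":
            other_mature[pl.ref_name] = pl.seq
        else:  # gp4: genome hairpin, no miRBase entry
            genome_windows[f"window_{pl.index}"] = _hairpin(pl.seq)

    # transcripts; validated targets carry a perfectly complementary site
    validated_ids = sorted(layout["sets"]["validated_mirnas"])
    by_id = {pl.mid: pl for pl in plans}
    alloc = _target_allocation(config)
    transcripts: dict[str, str] = {}
    pairs: list[dict] = []
    serial = 0
    for mid, n_targets in zip(validated_ids, alloc):
        mir = by_id[mid].seq
        L = len(mir)
        for _ in range(n_targets):
            tid = f"transcript_{serial:04d}"
            serial += 1
            seq = _random_seq(rng, config.transcript_len)
            start = int(rng.integers(50, config.transcript_len - L - 30))
            seq = seq[: start - 1] + revcomp(mir) + seq[start - 1 + L:]
            transcripts[tid] = seq
            pairs.append(
                {"mirna_id": mid, "transcript_id": tid,
                 "cleavage_pos": start + L - 10}
            )
    while serial < config.n_transcripts:
        transcripts[f"transcript_{serial:04d}"] = _random_seq(
            rng, config.transcript_len
        )
        serial += 1

    contaminants = {
        cls: {f"{cls}_decoy_{k}": _random_seq(rng, 200) for k in range(2)}
        for cls in CONTAMINANT_CLASSES
    }
    mrna = {f"mRNA_decoy_{k}": _random_seq(rng, 300) for k in range(3)}

    annotation = _make_annotation(config, rng, pairs, transcripts)

    bundle = ReferenceBundle(
        wheat_mature, wheat_precursor, other_mature, transcripts,
        genome_windows, contaminants, mrna, annotation,
    )
    bundle._pairs = pairs  # stashed for the ground truth
    return bundle


def _make_annotation(config, rng, pairs, transcripts) -> pd.DataFrame:
    """Toy GO/KEGG-style annotation: one term enriched among validated
    targets plus scattered background terms."""
    genes = sorted(transcripts)
    target_genes = sorted({p["transcript_id"] for p in pairs})
    rows = []
    n_hit = max(1, int(0.6 * len(target_genes))) if target_genes else 0
    for g in target_genes[:n_hit]:
        rows.append((g, "GO:0006355",
                     "regulation of transcription, DNA-templated", "BP"))
    background_terms = [
        ("GO:0003677", "DNA binding", "MF"),
        ("GO:0005634", "nucleus", "CC"),
        ("ko00360", "Phenylalanine metabolism", "pathway"),
        ("ko00940", "Phenylpropanoid biosynthesis", "pathway"),
    ]
    for g in genes:
        for term, label, ns in background_terms:
            if rng.random() < 0.15:
                rows.append((g, term, label, ns))
    # make sure every gene used in enrichment has at least one annotation
    annotated = {r[0] for r in rows}
    for g in genes:
        if g not in annotated:
            rows.append((g, "GO:0008150", "biological_process", "BP"))
    return pd.DataFrame(rows, columns=["gene", "term", "label", "namespace"])


# ---------------------------------------------------------------------------
# Ground truth + FASTQ emission
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted truth: per-miRNA memberships, expected counts, degradome pairs."""

    mirnas: pd.DataFrame          # id, seq, gp, per-set flags
    expected_counts: pd.DataFrame  # id x library, unique molecules
    sets: dict[str, set[str]]
    pairs: pd.DataFrame           # mirna_id, transcript_id, cleavage_pos

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.mirnas.to_csv(outdir / "truth_mirnas.tsv", sep="\t", index=False)
        self.expected_counts.to_csv(outdir / "truth_counts.tsv", sep="\t")
        self.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
        with open(outdir / "truth_sets.json", "w") as fh:
            json.dump({k: sorted(v) for k, v in self.sets.items()}, fh, indent=1)


def build_ground_truth(config: ScenarioConfig, ref: ReferenceBundle) -> GroundTruth:
    counts, layout = expected_count_matrix(config)
    plans: list[_MirnaPlan] = layout["plans"]
    sets = layout["sets"]
    rows = []
    for pl in plans:
        row = {"id": pl.mid, "seq": pl.seq, "gp": pl.gp}
        for name, members in sets.items():
            row[name] = pl.mid in members
        rows.append(row)
    pairs = pd.DataFrame(
        getattr(ref, "_pairs", []),
        columns=["mirna_id", "transcript_id", "cleavage_pos"],
    )
    return GroundTruth(pd.DataFrame(rows), counts, sets, pairs)


def make_srna_libraries(
    ref: ReferenceBundle, config: ScenarioConfig, outdir: str | Path
) -> tuple[list[Path], GroundTruth]:
    """Write the 3 x 4 x replicates small-RNA FASTQ libraries.

    Read layout: insert + 3' adapter + UMI, padded with A to ``read_len``.
    PCR duplicates (same insert + UMI) are injected at ``duplication_rate`` of
    the final read count; a handful of contaminant / junk / low-quality /
    adapter-less reads exercise every preprocessing rejection path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_ground_truth(config, ref)
    counts = truth.expected_counts
    seq_of = dict(zip(truth.mirnas["id"], truth.mirnas["seq"]))
    qual_hi = "I" * config.read_len
    paths = []

    contaminant_inserts = []
    for cls in CONTAMINANT_CLASSES:
        rec = next(iter(ref.contaminants[cls].values()))
        contaminant_inserts.append((cls, rec[40:61]))  # 21-nt exact substring
    mrna_rec = next(iter(ref.mrna.values()))
    contaminant_inserts.append(("mRNA", mrna_rec[100:121]))

    for li, lib in enumerate(config.libraries):
        rng = np.random.default_rng(config.seed + 100 + li)
        reads: list[tuple[str, str, str]] = []

        def emit(insert: str, umi_index: int, qual: str | None = None,
                 tag: str = "m") -> None:
            umi = _umi(umi_index, config.umi_len)
            seq = insert + config.adapter + umi
            seq = seq[: config.read_len].ljust(config.read_len, "A")
            reads.append(
                (f"{lib}:{tag}:{len(reads)}", seq, qual or qual_hi)
            )

        molecules: list[tuple[str, int]] = []
        for mid in counts.index:
            c = int(counts.at[mid, lib])
            ins = seq_of[mid]
            molecules.extend((ins, k) for k in range(c))
        for k, (cls, ins) in enumerate(contaminant_inserts):
            for j in range(4):
                molecules.append((ins, j))
        for j in range(3):
            molecules.append(("A" * 21, j))          # low complexity junk
        for j in range(2):
            molecules.append((_random_seq(rng, 26), j))  # too long for miRNA set

        m = len(molecules)
        d = int(round(m * config.duplication_rate / (1 - config.duplication_rate)))
        dup_idx = rng.integers(0, m, size=d) if d else []

        for ins, k in molecules:
            emit(ins, k)
        for i in dup_idx:
            ins, k = molecules[int(i)]
            emit(ins, k, tag="dup")
        # rejection-path reads: low quality, adapter-less, out of length gate
        emit(_random_seq(rng, 21), 0, qual="#" * config.read_len, tag="lowq")
        reads.append((f"{lib}:noadapter:{len(reads)}",
                      _random_seq(rng, config.read_len), qual_hi))
        reads.append((f"{lib}:short:{len(reads)}",
                      _random_seq(rng, 25), "I" * 25))

        path = outdir / f"{lib}.fastq"
        write_fastq(path, reads)
        paths.append(path)
    return paths, truth


def make_degradome_libraries(
    ref: ReferenceBundle, config: ScenarioConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write one pooled degradome FASTQ per group.

    The DM library carries the planted cleavage signals: for every planted
    (miRNA, transcript, position) pair, ``degradome_signal_reads`` tags whose
    5' end sits exactly at the cleavage position (category-0 signal).  All
    libraries carry count-1 background tags scattered across every transcript.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_ground_truth(config, ref)
    tag_len = 21
    paths: dict[str, Path] = {}
    # keep background tags clear of planted complementary sites so no
    # accidental pileup can pass duplex scoring
    seq_of = dict(zip(truth.mirnas["id"], truth.mirnas["seq"]))
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for r in truth.pairs.itertuples():
        L = len(seq_of[r.mirna_id])
        site_start = int(r.cleavage_pos) - L + 10
        forbidden.setdefault(r.transcript_id, []).append(
            (site_start - tag_len, site_start + L)
        )

    def clear(tid: str, pos: int) -> bool:
        return all(not (lo <= pos <= hi) for lo, hi in forbidden.get(tid, ()))

    for group in GROUPS:
        reads = []
        if group == "DM":
            for r in truth.pairs.itertuples():
                seq = ref.transcripts[r.transcript_id]
                pos = int(r.cleavage_pos)
                frag = seq[pos - 1: pos - 1 + tag_len]
                for j in range(config.degradome_signal_reads):
                    reads.append(
                        (f"DM:sig:{r.transcript_id}:{pos}:{j}", frag, "I" * len(frag))
                    )
        step = max(
            1,
            (config.transcript_len - tag_len) // max(config.degradome_background_sites, 1),
        )
        for tid, seq in ref.transcripts.items():
            pos = 2
            placed = 0
            while placed < config.degradome_background_sites and pos + tag_len <= len(seq):
                if clear(tid, pos):
                    frag = seq[pos - 1: pos - 1 + tag_len]
                    reads.append((f"{group}:bg:{tid}:{pos}", frag, "I" * len(frag)))
                    placed += 1
                pos += step
        path = outdir / f"degradome_{group}.fastq"
        write_fastq(path, reads)
        paths[group] = path
    return paths, truth


def config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    if "planted_sets" in d and isinstance(d["planted_sets"], dict):
        d["planted_sets"] = PlantedSets(**d["planted_sets"])
    return ScenarioConfig(**d)
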