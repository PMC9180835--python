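"""End-to-end orchestration: simulate -> preprocess -> catalog -> expression
-> memory selection -> degradome validation -> enrichment, with per-stage
TSV outputs and a machine-readable JSON run report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import simulate
from .catalog import ReferenceIndex, base_composition, build_catalog
from .degradome import (
    DEFAULT_CATEGORY_MAX,
    DEFAULT_SCORE_MAX,
    hits_table,
    map_tags,
    summarize_hits,
    validate_targets,
)
from .enrichment import AnnotationMap, association_table, hypergeom_enrich
from .errors import ConfigurationError
from .expression import bin_expression, de_pairwise, normalize
from .memory import MemoryCallSet, baseline_de, select_memory_candidates, union_de, venn_summary
from .preprocess import preprocess_libraries
from .simulate import POST_TIMEPOINTS, ScenarioConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig
    outdir: Path
    alpha: float = 0.05
    score_max: float = DEFAULT_SCORE_MAX
    category_max: int = DEFAULT_CATEGORY_MAX
    degradome_library: str = "DM"

    @classmethod
    def from_preset(cls, preset: str, outdir: str | Path, seed: int | None = None,
                    **kw) -> "PipelineConfig":
        if preset not in simulate.PRESETS:
            raise ConfigurationError(
                f"unknown preset {preset!r}; available: {sorted(simulate.PRESETS)}"
            )
        scenario = simulate.PRESETS[preset]()
        if seed is not None:
            scenario = dataclasses.replace(scenario, seed=seed)
        return cls(scenario=scenario, outdir=Path(outdir), **kw)

    def hash(self) -> str:
        payload = json.dumps(
            {
                "scenario": simulate.config_to_dict(self.scenario),
                "alpha": self.alpha,
                "score_max": self.score_max,
                "category_max": self.category_max,
                "degradome_library": self.degradome_library,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    preprocess: dict
    catalog_groups: dict
    de_counts: dict
    memory: dict
    degradome: dict
    enrichment: dict

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        m = self.memory
        assert m["candidates"] == m["specific"] + m["rescue"]
        assert m["shared"] == m["dm_union"] + m["dd_union"] - m["union_total"]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order, writing stage outputs under ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.scenario
    sc.validate()

    log.info("stage 1/7: simulate scenario %s (seed %d)", sc.name, sc.seed)
    ref = simulate.make_reference(sc)
    ref.write(out / "reference")
    srna_paths, truth = simulate.make_srna_libraries(ref, sc, out / "srna")
    deg_paths, _ = simulate.make_degradome_libraries(ref, sc, out / "degradome")
    truth.write(out / "truth")

    log.info("stage 2/7: preprocess %d libraries", len(srna_paths))
    lib_paths = {p.stem: p for p in srna_paths}
    tags, removed, stats = preprocess_libraries(
        lib_paths, sc.adapter, sc.umi_len, ref.contaminants, ref.mrna
    )
    tags.to_csv(out / "tags.tsv", sep="\t")
    stats.to_csv(out / "preprocess_stats.tsv", sep="\t")

    log.info("stage 3/7: catalog %d unique tags", len(tags))
    index = ReferenceIndex(
        ref.wheat_mature, ref.wheat_precursor, ref.other_mature, ref.genome_windows
    )
    catalog = build_catalog(tags, index)
    catalog.to_csv(out / "catalog.tsv", sep="\t")
    base_composition(tags).to_csv(out / "base_composition.tsv", sep="\t", index=False)

    lib_cols = [c for c in catalog.columns if c not in ("seq", "group", "precursor")]
    counts = catalog[lib_cols]
    norm = normalize(counts)
    norm.to_csv(out / "normalized.tsv", sep="\t")

    log.info("stage 4/7: differential expression")
    de_counts = {}
    dm_comps, dd_comps, dmdd_comps = [], [], []
    for t in POST_TIMEPOINTS:
        cg = sc.group_libs("CG", t)
        dd = sc.group_libs("DD", t)
        dm = sc.group_libs("DM", t)
        c_dm = de_pairwise(norm, cg, dm, alpha=config.alpha)
        c_dd = de_pairwise(norm, cg, dd, alpha=config.alpha)
        c_dmdd = de_pairwise(norm, dd, dm, alpha=config.alpha)
        for name, comp in [(f"DM_{t}h_vs_CG_{t}h", c_dm),
                           (f"DD_{t}h_vs_CG_{t}h", c_dd),
                           (f"DM_{t}h_vs_DD_{t}h", c_dmdd)]:
            comp.to_csv(out / f"de_{name}.tsv", sep="\t")
            de_counts[name] = int(comp["significant"].sum())
        dm_comps.append(c_dm)
        dd_comps.append(c_dd)
        dmdd_comps.append(c_dmdd)

    log.info("stage 5/7: memory-candidate selection")
    dm_union = union_de(dm_comps, alpha=config.alpha)
    dd_union = union_de(dd_comps, alpha=config.alpha)
    dmdd_union = union_de(dmdd_comps, alpha=config.alpha)
    calls = select_memory_candidates(dm_union, dd_union, dmdd_union)
    base_sig, base_up, base_down = baseline_de(
        norm, sc.group_libs("CG", 0), sc.group_libs("DM", 0), alpha=config.alpha
    )
    calls = MemoryCallSet(
        **{**calls.__dict__, "baseline": base_sig,
           "baseline_up": base_up, "baseline_down": base_down}
    )
    calls.validate()
    with open(out / "memory_sets.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in calls.__dict__.items()}, fh, indent=1)
    venn_summary(calls).to_csv(out / "venn_summary.tsv", sep="\t", index=False)

    log.info("stage 6/7: degradome validation (%s library)", config.degradome_library)
    profiles, map_stats = map_tags(
        deg_paths[config.degradome_library], ref.transcripts
    )
    cand_seq = {
        mid: str(catalog.at[mid, "seq"]) for mid in sorted(calls.candidates)
        if mid in catalog.index
    }
    hits = validate_targets(
        cand_seq, profiles, ref.transcripts,
        score_max=config.score_max, category_max=config.category_max,
        library=config.degradome_library,
    )
    hits_table(hits).to_csv(out / "target_hits.tsv", sep="\t", index=False)
    hit_summary = summarize_hits(hits)
    validated_ids = hit_summary.pop("mirna_ids")
    target_ids = hit_summary.pop("transcript_ids")
    hit_summary["baseline_validated_overlap"] = len(validated_ids & base_sig)

    # expression-level bins of validated miRNAs
    mean_abund = norm.mean(axis=1)
    dataset_mean = float(mean_abund.mean())
    bins = {"high": 0, "medium": 0, "low": 0}
    for mid in validated_ids:
        bins[bin_expression(float(mean_abund.get(mid, 0.0)), dataset_mean)] += 1
    hit_summary["validated_bins"] = bins

    log.info("stage 7/7: enrichment of %d target genes", len(target_ids))
    annotation = AnnotationMap.from_table(ref.annotation)
    if target_ids:
        enrich = hypergeom_enrich(
            set(target_ids) & annotation.population, annotation, alpha=config.alpha
        )
    else:
        enrich = pd.DataFrame(
            columns=["term", "label", "namespace", "k", "n", "K", "N", "p",
                     "significant"]
        )
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    edges = association_table(calls.candidates, hits, enrich, annotation)
    edges.to_csv(out / "association_edges.tsv", sep="\t", index=False)

    memory_card = calls.cardinalities()
    memory_card["union_total"] = len(dm_union | dd_union)
    report = RunReport(
        config_hash=config.hash(),
        seed=sc.seed,
        preprocess={
            "raw_reads": int(stats["raw_reads"].sum()),
            "molecules": int(stats["molecules"].sum()),
            "unique_molecules": int(stats["unique_molecules"].sum()),
            "mean_duplication_ratio": float(stats["duplication_ratio"].mean()),
            "valid_tag_rows": int(len(tags)),
        },
        catalog_groups={
            g: int(n) for g, n in catalog["group"].value_counts().items()
        },
        de_counts=de_counts,
        memory=memory_card,
        degradome={**hit_summary, "mapping": map_stats},
        enrichment={
            "terms_tested": int(len(enrich)),
            "significant_terms": int(enrich["significant"].sum()) if len(enrich) else 0,
        },
    )
    report.validate()
    report.write(out / "report.json")
    return report
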