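"""End-to-end pipeline: enrichment -> media cover -> comparisons -> targeted.

Runs every analysis stage over one table + metadata pair (or a self-contained
simulated demo), collecting a JSON-serializable report bundle plus per-donor
TSVs.  Reruns with an identical configuration are byte-identical; every
output carries the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import community_compare, enrichment, media_cover, synthetic, targeted_isolation
from .io_formats import (
    AnalysisConfig,
    ConditionSpec,
    OtuTable,
    SampleMetadata,
    read_fasta,
    read_metadata,
    read_otu_table,
    write_metadata,
    write_otu_table,
)

__all__ = ["RunConfig", "run_full_pipeline", "render_summary"]

# demo-mode simulation scale: 2 donors x 10 media x 2 atmospheres keeps the
# self-contained demo under a few seconds while exercising every stage
_DEMO = dict(n_donors=2, n_otus=200, n_media=10, independent_depth=50_000, plate_depth=20_000)


@dataclass
class RunConfig:
    table_path: str | None = None
    metadata_path: str | None = None
    isolates_path: str | None = None
    references_path: str | None = None
    out_dir: str = "cultenrich_out"
    taxon: str | None = None
    cover_threshold: float = 0.001
    demo: bool = False
    seed: int = 0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are — leave it out
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _validate_inputs(config: RunConfig) -> None:
    if config.demo:
        return
    for label, p in (
        ("table", config.table_path),
        ("metadata", config.metadata_path),
    ):
        if p is None:
            raise FileNotFoundError(f"{label} path is required outside demo mode")
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} path does not exist: {p}")
    for label, p in (
        ("isolates", config.isolates_path),
        ("references", config.references_path),
    ):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{label} path does not exist: {p}")


def _demo_inputs(config: RunConfig):
    conditions = synthetic.default_conditions(n_media=_DEMO["n_media"])
    table, metadata, truths = synthetic.simulate_study(
        n_donors=_DEMO["n_donors"],
        n_otus=_DEMO["n_otus"],
        conditions=conditions,
        independent_depth=_DEMO["independent_depth"],
        plate_depth=_DEMO["plate_depth"],
        seed=config.seed,
    )
    # frozen replicate of donor D1's plates for the storage stage
    rng = np.random.default_rng(config.seed + 1)
    frozen_matrix = synthetic.apply_perturbation(
        truths["D1"].culturability,
        synthetic.PerturbationSpec("frozen", 0.4, int(rng.integers(2**31))),
    )
    frozen_exp = synthetic.build_experiment(
        truths["D1"].community,
        frozen_matrix,
        donor="D1",
        plate_depth=_DEMO["plate_depth"],
        seed=int(rng.integers(2**31)),
        storage="frozen",
        include_independent=False,
        taxonomy=table.taxonomy,
    )
    table = OtuTable.concat([table, frozen_exp.table])
    metadata = metadata + frozen_exp.metadata
    # isolates for the novelty screen: a mix of near-identical and divergent
    refs = synthetic.generate_reference_sequences(5, 150, config.seed + 7)
    isolates = [
        (i, s)
        for i, s, _, _ in synthetic.generate_isolate_sequences(refs, 6, 0.01, config.seed + 8)
    ] + [
        (i, s)
        for i, s, _, _ in synthetic.generate_isolate_sequences(
            refs, 4, 0.05, config.seed + 9, prefix="nov"
        )
    ]
    return table, metadata, isolates, refs


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``."""
    _validate_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    if config.demo:
        table, metadata, isolates, references = _demo_inputs(config)
        write_otu_table(table, out_dir / "simulated_table.tsv")
        write_metadata(metadata, out_dir / "simulated_metadata.tsv")
        taxon = config.taxon or "Lachnospiraceae"
    else:
        table = read_otu_table(config.table_path)
        metadata = read_metadata(config.metadata_path)
        isolates = read_fasta(config.isolates_path) if config.isolates_path else None
        references = read_fasta(config.references_path) if config.references_path else None
        taxon = config.taxon

    cfg = config.analysis
    donors = sorted(
        {m.donor for m in metadata if m.role == "culture_independent"}
    )
    report: dict = {"config_hash": chash, "seed": config.seed, "donors": donors}

    # ---- enrichment -----------------------------------------------------
    try:
        per_donor: dict[str, dict] = {}
        all_calls: dict[str, list[enrichment.CulturedCall]] = {}
        pooled_cultured: set[str] = set()
        pooled_independent: set[str] = set()
        for donor in donors:
            calls = enrichment.call_cultured(table, metadata, cfg, donor)
            all_calls[donor] = calls
            fecal = next(
                m for m in metadata if m.donor == donor and m.role == "culture_independent"
            )
            ind = table.counts_for(fecal.sample_id)
            curve = enrichment.recovery_curve(
                ind, calls, [0.0, *cfg.abundance_thresholds]
            )
            part = enrichment.partition_otus(ind, calls)
            pooled_cultured |= set(part.culture_only) | set(part.both)
            pooled_independent |= set(part.both) | set(part.independent_only)
            per_donor[donor] = {
                "fecal_sample": fecal.sample_id,
                "recovery": {
                    "thresholds": curve.thresholds,
                    "proportion_cultured": curve.proportion_cultured,
                    "n_otus": curve.n_otus_at_threshold,
                },
                "partition_sizes": [
                    len(part.culture_only),
                    len(part.both),
                    len(part.independent_only),
                ],
                "partition_percentages": list(part.percentages),
            }
            rows = [
                {
                    "otu_id": c.otu_id,
                    "cultured": c.cultured,
                    "n_supporting_conditions": len(c.supporting_conditions),
                    "max_plate_relabund": c.max_plate_relabund,
                }
                for c in calls
            ]
            df = pd.DataFrame(rows)
            with open(out_dir / f"calls_{donor}.tsv", "w", encoding="utf-8") as fh:
                fh.write(f"# config_hash={chash} seed={config.seed}\n")
                df.to_csv(fh, sep="\t", index=False)
        pooled = enrichment.partition_from_sets(pooled_cultured, pooled_independent)
        report["enrichment"] = {
            "per_donor": per_donor,
            "pooled_partition_sizes": [
                len(pooled.culture_only),
                len(pooled.both),
                len(pooled.independent_only),
            ],
            "pooled_partition_percentages": list(pooled.percentages),
        }
    except Exception as exc:
        raise RuntimeError(f"enrich stage failed: {exc}") from exc

    # ---- media cover ----------------------------------------------------
    try:
        covers: dict[str, media_cover.CoverResult] = {}
        cover_report: dict[str, dict] = {}
        for donor in donors:
            inst = media_cover.build_cover_instance(
                table, metadata, all_calls[donor], cfg, donor, config.cover_threshold
            )
            greedy = media_cover.greedy_cover(inst) if inst.targets else media_cover.CoverResult(
                (), "greedy", frozenset(), False
            )
            entry = {
                "n_targets": len(inst.targets),
                "greedy_size": len(greedy.selected),
                "greedy_selected": [f"{c.medium}:{c.atmosphere}" for c in greedy.selected],
            }
            if len(inst.condition_sets) <= 30:
                exact = media_cover.exact_cover(inst)
                entry["exact_size"] = len(exact.selected)
                entry["exact_selected"] = [
                    f"{c.medium}:{c.atmosphere}" for c in exact.selected
                ]
            covers[donor] = greedy
            cover_report[donor] = entry
        _, union_n = media_cover.cross_donor_union(covers)
        _, union_anaerobic = media_cover.cross_donor_union(covers, atmosphere="anaerobic")
        report["cover"] = {
            "per_donor": cover_report,
            "union_size": union_n,
            "union_size_anaerobic": union_anaerobic,
            "threshold": config.cover_threshold,
        }
    except Exception as exc:
        raise RuntimeError(f"cover stage failed: {exc}") from exc

    # ---- community comparison -------------------------------------------
    try:
        nonzero = [s for s, t in zip(table.sample_ids, table.sample_totals()) if t > 0]
        dm = community_compare.dissimilarity_matrix(table, nonzero)
        with open(out_dir / "bray_curtis_matrix.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# config_hash={chash} seed={config.seed}\n")
            dm.to_frame().to_csv(fh, sep="\t")
        compare_report: dict = {}
        for donor in donors:
            ranking = community_compare.plate_vs_fecal_ranking(table, metadata, donor)
            compare_report[donor] = {
                "most_similar": f"{ranking[0][0].medium}:{ranking[0][0].atmosphere}",
                "most_similar_bc": ranking[0][1],
                "most_different": f"{ranking[-1][0].medium}:{ranking[-1][0].atmosphere}",
                "most_different_bc": ranking[-1][1],
            }
        storage_pairs: list[dict] = []
        frozen_conds = {
            (m.donor, m.condition)
            for m in metadata
            if m.role == "plate_pool" and m.storage == "frozen"
        }
        for donor, cond in sorted(frozen_conds, key=lambda e: (e[0], e[1].medium, e[1].atmosphere)):
            try:
                eff = community_compare.storage_effect(table, metadata, donor, cond)
            except ValueError:
                continue
            storage_pairs.append(
                {
                    "donor": donor,
                    "condition": f"{cond.medium}:{cond.atmosphere}",
                    "bc_fresh_frozen": eff.bc_fresh_frozen,
                    "bc_fresh_aerobic": eff.bc_fresh_aerobic,
                }
            )
        report["compare"] = {
            "plate_vs_fecal": compare_report,
            "storage": storage_pairs,
        }
    except Exception as exc:
        raise RuntimeError(f"compare stage failed: {exc}") from exc

    # ---- targeted isolation (optional) ----------------------------------
    targeted: dict = {}
    try:
        if taxon and table.taxonomy:
            rec = targeted_isolation.media_rank_for_taxon(table, metadata, taxon)
            targeted["media_recommendation"] = {
                "taxon": rec.taxon,
                "top": [
                    {"condition": f"{c.medium}:{c.atmosphere}", "relabund": v}
                    for c, v in rec.ranked[:5]
                ],
            }
        if isolates and references:
            reports = targeted_isolation.classify_isolates(isolates, references, cfg)
            targeted["isolates"] = {
                "n": len(reports),
                "n_novel": sum(r.novel for r in reports),
                "threshold": cfg.identity_threshold,
            }
            rows = [
                {
                    "isolate_id": r.isolate_id,
                    "best_reference_id": r.best_reference_id,
                    "identity": r.identity,
                    "novel": r.novel,
                    "alignment_length": r.alignment_length,
                }
                for r in reports
            ]
            with open(out_dir / "isolate_screen.tsv", "w", encoding="utf-8") as fh:
                fh.write(f"# config_hash={chash} seed={config.seed}\n")
                pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"targeted stage failed: {exc}") from exc
    if targeted:
        report["targeted"] = targeted

    (out_dir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, default=float) + "\n", encoding="utf-8"
    )
    return report


def render_summary(report: dict) -> str:
    """Human-readable digest of a report bundle."""
    missing = [k for k in ("enrichment", "cover", "compare") if k not in report]
    if missing:
        raise ValueError(f"incomplete report bundle, missing sections: {missing}")
    lines = [f"cultenrich run {report['config_hash']} (seed {report['seed']})", ""]
    lines.append("Proportion of culture-independent OTUs cultured:")
    for donor, entry in report["enrichment"]["per_donor"].items():
        rec = entry["recovery"]
        parts = [
            f"{100 * t:g}%: {100 * p:.0f}% (n={n})" if t > 0 else f"all: {100 * p:.0f}% (n={n})"
            for t, p, n in zip(rec["thresholds"], rec["proportion_cultured"], rec["n_otus"])
        ]
        lines.append(f"  {donor}: " + "; ".join(parts))
    pp = report["enrichment"]["pooled_partition_percentages"]
    ps = report["enrichment"]["pooled_partition_sizes"]
    lines.append(
        f"Detection partition (culture-only / both / independent-only): "
        f"{ps[0]} / {ps[1]} / {ps[2]} OTUs = {pp[0]} % / {pp[1]} % / {pp[2]} %"
    )
    lines.append("")
    lines.append("Minimal media sets (threshold "
                 f"{100 * report['cover']['threshold']:g}%):")
    for donor, entry in report["cover"]["per_donor"].items():
        extra = f", exact {entry['exact_size']}" if "exact_size" in entry else ""
        lines.append(
            f"  {donor}: {entry['n_targets']} targets, greedy {entry['greedy_size']}{extra}"
        )
    lines.append(
        f"  union across donors: {report['cover']['union_size']} conditions "
        f"({report['cover']['union_size_anaerobic']} anaerobic)"
    )
    lines.append("")
    lines.append("Plate vs fecal similarity (Bray-Curtis):")
    for donor, entry in report["compare"]["plate_vs_fecal"].items():
        lines.append(
            f"  {donor}: most similar {entry['most_similar']} "
            f"(BC={entry['most_similar_bc']:.2f}); most different "
            f"{entry['most_different']} (BC={entry['most_different_bc']:.2f})"
        )
    if report["compare"]["storage"]:
        vals = [e["bc_fresh_frozen"] for e in report["compare"]["storage"]]
        lines.append(
            f"  fresh-vs-frozen BC over {len(vals)} matched conditions: "
            f"mean {np.mean(vals):.2f} (range {min(vals):.2f}-{max(vals):.2f})"
        )
    if "targeted" in report:
        lines.append("")
        t = report["targeted"]
        if "media_recommendation" in t:
            top = t["media_recommendation"]["top"][0]
            lines.append(
                f"Top medium for {t['media_recommendation']['taxon']}: "
                f"{top['condition']} ({100 * top['relabund']:.0f}% of plate reads)"
            )
        if "isolates" in t:
            lines.append(
                f"Isolate screen: {t['isolates']['n_novel']} of {t['isolates']['n']} "
                f"below {100 * t['isolates']['threshold']:g}% identity (putatively novel)"
            )
    else:
        lines.append("")
        lines.append("Targeted-isolation section omitted (no taxonomy/isolates provided).")
    return "\n".join(lines) + "\n"
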