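"""End-to-end orchestration: simulate (or ingest) → quantify → metagene →
driver classification → gene-set shifts → microRNA analysis.

Every run is a pure function of the configuration and its seed: the
manifest records a hash of the canonical configuration, and identical
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import metagene as mg
from .drivers import (
    classify_drivers,
    contribution_ratio,
    fold_changes,
    fold_changes_by_replicate,
    summarize_driver_classes,
)
from .errors import InvalidConfigError
from .mirna import (
    collapse_families,
    cross_tissue_target_shift,
    site_density_vs_fc,
    stronger_repression_fraction,
    target_repression_within_tissue,
)
from .quantify import (
    ExpressionSet,
    filter_detected,
    hierarchical_cluster,
    rpkm,
    sample_correlation,
    translational_efficiency,
)
from .setshift import benjamini_hochberg, set_shift_test
from .simulate import (
    PauseParams,
    SimConfig,
    family_table,
    generate_annotation,
    generate_truth,
    simulate_counts,
    simulate_footprint_positions,
)

__all__ = ["RunConfig", "run_pipeline", "report"]

METRIC_COLUMNS = {"RNA": "log2_rna_fc", "RPF": "log2_rpf_fc", "Eff": "log2_eff_fc"}


@dataclass
class ContrastSpec:
    condition_a: str
    condition_b: str
    rpf_fold: float = 4.0


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulation mode or file inputs)."""

    outdir: str
    seed: int = 0
    min_reads: int = 10
    pseudocount: float = 0.5
    contrasts: dict = field(default_factory=dict)  # name -> ContrastSpec
    sim: SimConfig | None = None
    inputs: dict | None = None  # counts / annotation / targets / positions paths
    metagene_genes: int = 100
    metagene_reads: int = 1000
    mirna_min_targets: int = 10

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        contrasts = {
            name: ContrastSpec(spec["a"], spec["b"], float(spec.get("rpf_fold", 4.0)))
            for name, spec in raw.get("contrasts", {}).items()
        }
        sim = None
        if "simulate" in raw:
            sim_kw = dict(raw["simulate"])
            if contrasts:
                sim_kw.setdefault(
                    "contrasts",
                    {n: (c.condition_a, c.condition_b) for n, c in contrasts.items()},
                )
            sim = SimConfig(**sim_kw)
        cfg = cls(
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            min_reads=int(raw.get("min_reads", 10)),
            pseudocount=float(raw.get("pseudocount", 0.5)),
            contrasts=contrasts,
            sim=sim,
            inputs=raw.get("inputs"),
            metagene_genes=int(raw.get("metagene_genes", 100)),
            metagene_reads=int(raw.get("metagene_reads", 1000)),
            mirna_min_targets=int(raw.get("mirna_min_targets", 10)),
        )
        if sim is not None:
            cfg.sim = sim.with_(seed=cfg.seed)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> dict:
        out = {
            "seed": self.seed,
            "min_reads": self.min_reads,
            "pseudocount": self.pseudocount,
            "contrasts": {
                n: [c.condition_a, c.condition_b, c.rpf_fold]
                for n, c in sorted(self.contrasts.items())
            },
            "metagene_genes": self.metagene_genes,
            "metagene_reads": self.metagene_reads,
            "mirna_min_targets": self.mirna_min_targets,
            "inputs": self.inputs,
        }
        if self.sim is not None:
            sim = {}
            for k, v in sorted(vars(self.sim).items()):
                if isinstance(v, dict):
                    v = {kk: (list(vv) if isinstance(vv, (tuple, list)) else
                              ({k2: v2 for k2, v2 in vv.items()} if isinstance(vv, dict) else vv))
                         for kk, vv in sorted(v.items())}
                elif isinstance(v, tuple):
                    v = list(v)
                sim[k] = v
            out["sim"] = sim
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate(config: RunConfig, conditions) -> None:
    if not config.contrasts:
        raise InvalidConfigError("no contrasts configured")
    for name, spec in config.contrasts.items():
        for cond in (spec.condition_a, spec.condition_b):
            if cond not in conditions:
                raise InvalidConfigError(
                    f"contrast {name!r} references condition {cond!r} absent from the data"
                )
        if spec.rpf_fold <= 1:
            raise InvalidConfigError(f"contrast {name!r}: rpf_fold must be > 1")
    if config.min_reads < 0:
        raise InvalidConfigError("min_reads must be >= 0")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _mean_by_condition(es: ExpressionSet, assay: str, condition: str) -> pd.Series:
    return es.data[es.columns_for(assay=assay, condition=condition)].mean(axis=1)


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Execute every stage and return the output manifest (also written to
    ``manifest.json`` in the output directory)."""

    def say(msg):
        if log is not None:
            log(msg)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "files": {},
    }

    def record(stage, name, path: Path):
        manifest["files"][name] = str(path.relative_to(outdir))
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)

    t0 = time.time()
    # ---- stage: inputs ---------------------------------------------------
    truth = None
    if config.sim is not None:
        sim = config.sim
        sim.validate()
        _validate(config, sim.conditions)
        genes = generate_annotation(sim)
        truth = generate_truth(genes, sim)
        counts = simulate_counts(truth, genes, sim)
        targets = family_table(genes)
        tio.write_annotation(genes, outdir / "annotation.tsv")
        counts.to_tsv(outdir / "counts.tsv")
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if not targets.empty:
            tio.write_targets(targets, outdir / "targets.tsv")
            record("inputs", "targets", outdir / "targets.tsv")
        record("inputs", "annotation", outdir / "annotation.tsv")
        record("inputs", "counts", outdir / "counts.tsv")
        record("inputs", "truth", outdir / "truth.tsv")
    elif config.inputs:
        ann_path = config.inputs["annotation"]
        genes = (
            tio.read_annotation_gtf(ann_path)
            if str(ann_path).endswith((".gtf", ".gff"))
            else tio.read_annotation(ann_path)
        )
        counts = ExpressionSet.from_tsv(config.inputs["counts"])
        _validate(config, set(counts.samples["condition"]))
        targets = (
            tio.read_targets(config.inputs["targets"])
            if config.inputs.get("targets")
            else pd.DataFrame(columns=["family_id", "gene_id", "n_sites"])
        )
    else:
        raise InvalidConfigError("config needs either a 'simulate' block or 'inputs'")
    say(f"[inputs] {len(genes)} genes, {counts.data.shape[1]} samples ({time.time()-t0:.1f}s)")

    # ---- stage: quantify -------------------------------------------------
    t = time.time()
    detected = filter_detected(counts, min_reads=config.min_reads)
    sub = counts.subset_genes(detected)
    rpkm_es = rpkm(sub, genes)
    eff = translational_efficiency(rpkm_es.for_assay("RPF"), rpkm_es.for_assay("RNA"))
    corr = sample_correlation(counts)
    tree = hierarchical_cluster(corr)
    rpkm_es.to_tsv(outdir / "rpkm.tsv")
    eff.to_tsv(outdir / "eff.tsv")
    corr.rename_axis("sample").to_csv(outdir / "sample_correlation.tsv", sep="\t")
    _write_json(tree.to_dict(), outdir / "clustering.json")
    for name in ("rpkm", "eff", "sample_correlation", "clustering"):
        suffix = "json" if name == "clustering" else "tsv"
        record("quantify", name, outdir / f"{name}.{suffix}")
    say(f"[quantify] {len(detected)}/{len(genes)} genes detected ({time.time()-t:.1f}s)")

    # ---- stage: metagene -------------------------------------------------
    t = time.time()
    mg_genes = genes[: config.metagene_genes]
    psite_rows = []
    for i, g in enumerate(mg_genes):
        pc = simulate_footprint_positions(
            g, config.metagene_reads, PauseParams(), seed=config.seed * 100003 + i
        )
        psite_rows.append(mg.psite_shift(pc))
    if psite_rows:
        tio.write_positional_counts(psite_rows, outdir / "psites.tsv")
        record("metagene", "psites", outdir / "psites.tsv")
        profiles = {}
        for align in ("start", "stop"):
            prof = mg.metagene_profile(psite_rows, mg_genes, align_at=align)
            frame = pd.DataFrame(
                {"offset": prof.offsets, "density": prof.density, "n_genes": prof.n_genes_per_offset}
            )
            frame.to_csv(outdir / f"metagene_{align}.tsv", sep="\t", index=False)
            record("metagene", f"metagene_{align}", outdir / f"metagene_{align}.tsv")
            profiles[align] = prof.peak_offset()
        per = mg.periodicity_score(psite_rows, mg_genes)
        _write_json(
            {
                "frame_fractions": [round(f, 4) for f in per.frame_fractions],
                "score": round(per.score, 4),
                "chi2_p": per.p_value,
                "n_psites": per.n_psites,
                "peak_offsets": profiles,
            },
            outdir / "periodicity.json",
        )
        record("metagene", "periodicity", outdir / "periodicity.json")
    say(f"[metagene] {len(mg_genes)} genes profiled ({time.time()-t:.1f}s)")

    # ---- stage: classify -------------------------------------------------
    t = time.time()
    fc_tables = {}
    driver_summary = {}
    for name, spec in config.contrasts.items():
        # detection restricted to the contrast's own comparison set: genes
        # undetectable only in unrelated conditions still enter this contrast
        pair = [spec.condition_a, spec.condition_b]
        detected_pair = filter_detected(counts, min_reads=config.min_reads, conditions=pair)
        rpkm_pair = rpkm(counts.subset_genes(detected_pair), genes)
        fc = fold_changes(
            rpkm_pair, spec.condition_a, spec.condition_b, config.pseudocount, contrast=name
        )
        fc_tables[name] = fc
        assignments = classify_drivers(fc, rpf_fold_threshold=spec.rpf_fold)
        merged = fc.data.join(assignments, how="left")
        merged.rename_axis("gene_id").to_csv(outdir / f"assignments_{name}.tsv", sep="\t")
        record("classify", f"assignments_{name}", outdir / f"assignments_{name}.tsv")
        summary = summarize_driver_classes(assignments)
        reps = fold_changes_by_replicate(
            rpkm_pair, spec.condition_a, spec.condition_b, config.pseudocount, contrast=name
        )
        if len(reps) >= 2:
            est = contribution_ratio(reps[0], reps[1])
            summary["contribution"] = {
                "r_rna": round(est.r_rna, 4),
                "r_eff": round(est.r_eff, 4),
                "r_rep": round(est.r_rep, 4),
                "eff_contribution_pct": None
                if est.eff_contribution_pct is None
                else round(est.eff_contribution_pct, 1),
            }
        driver_summary[name] = summary
    _write_json(driver_summary, outdir / "driver_summary.json")
    record("classify", "driver_summary", outdir / "driver_summary.json")
    say(f"[classify] {len(fc_tables)} contrasts ({time.time()-t:.1f}s)")

    # ---- stage: set shifts -----------------------------------------------
    t = time.time()
    categories = sorted({c for g in genes for c in g.categories})
    cat_members = {c: {g.gene_id for g in genes if c in g.categories} for c in categories}
    shift_rows = []
    for cname, fc in fc_tables.items():
        for cat in categories:
            members = cat_members[cat] & set(fc.data.index)
            if not members:
                continue
            for metric, col in METRIC_COLUMNS.items():
                ks = set_shift_test(fc.data[col], members, background_mode="all_other_genes")
                shift_rows.append(
                    (cname, cat, metric, len(members), ks.d_statistic, ks.p_value,
                     ks.shift_direction, "all_other_genes")
                )
    shifts = pd.DataFrame(
        shift_rows,
        columns=["contrast", "category", "metric", "n_set", "ks_d", "ks_p",
                 "direction", "background"],
    )
    if not shifts.empty:
        shifts["fdr"] = benjamini_hochberg(shifts["ks_p"])
    shifts.to_csv(outdir / "shifts.tsv", sep="\t", index=False)
    record("setshift", "shifts", outdir / "shifts.tsv")
    say(f"[setshift] {len(shift_rows)} tests ({time.time()-t:.1f}s)")

    # ---- stage: mirna ----------------------------------------------------
    t = time.time()
    mirna_summary: dict = {"n_families": 0}
    if not targets.empty:
        families = collapse_families(targets)
        mirna_summary["n_families"] = len(families)
        tissues = [c for c in ("BAT", "WAT") if c in rpkm_es.conditions]
        within_rows = []
        within_records: dict = {}
        for tissue in tissues:
            metric_values = {
                "RPF": _mean_by_condition(rpkm_es, "RPF", tissue),
                "RNA": _mean_by_condition(rpkm_es, "RNA", tissue),
                "Eff": eff.data[eff.columns_for(tissue)].mean(axis=1),
            }
            for metric, values in metric_values.items():
                recs = [
                    target_repression_within_tissue(
                        values, fam, metric=metric, label=tissue,
                        min_targets=config.mirna_min_targets,
                    )
                    for fam in families
                ]
                within_records[(tissue, metric)] = recs
                within_rows += [
                    (r.family_id, tissue, metric, r.n_targets, r.ratio, r.ks_p,
                     r.direction, r.repressed, r.skipped)
                    for r in recs
                ]
        if within_rows:
            pd.DataFrame(
                within_rows,
                columns=["family_id", "tissue", "metric", "n_targets", "ratio",
                         "ks_p", "direction", "repressed", "skipped"],
            ).to_csv(outdir / "mirna_within.tsv", sep="\t", index=False)
            record("mirna", "mirna_within", outdir / "mirna_within.tsv")
        if len(tissues) == 2:
            eligible = [
                r.family_id
                for r in within_records[("BAT", "RPF")] + within_records[("WAT", "RPF")]
                if r.repressed
            ]
            for metric in ("RPF", "RNA", "Eff"):
                frac = stronger_repression_fraction(
                    within_records[("BAT", metric)],
                    within_records[("WAT", metric)],
                    eligible_families=eligible,
                    metric=metric,
                )
                mirna_summary[f"stronger_in_BAT_{metric}"] = {
                    "fraction": None if frac.empty else round(frac.fraction, 4),
                    "n_eligible": frac.n_eligible,
                    "n_ties": frac.n_ties,
                }
        tissue_contrast = next(
            (
                n
                for n, s in config.contrasts.items()
                if {s.condition_a, s.condition_b} == {"BAT", "WAT"}
            ),
            None,
        )
        if tissue_contrast is not None:
            fc = fc_tables[tissue_contrast]
            cross_rows = []
            for metric in ("RPF", "RNA", "Eff"):
                for fam in families:
                    r = cross_tissue_target_shift(
                        fc, fam, metric=metric, min_targets=config.mirna_min_targets
                    )
                    cross_rows.append(
                        (r.family_id, metric, r.n_targets, r.ratio, r.ks_p,
                         r.direction, r.repressed, r.skipped)
                    )
            pd.DataFrame(
                cross_rows,
                columns=["family_id", "metric", "n_targets", "ratio", "ks_p",
                         "direction", "repressed", "skipped"],
            ).to_csv(outdir / "mirna_cross.tsv", sep="\t", index=False)
            record("mirna", "mirna_cross", outdir / "mirna_cross.tsv")
            site_totals = pd.Series(
                {g.gene_id: g.total_sites for g in genes}, name="sites"
            )
            density = {}
            for metric, col in METRIC_COLUMNS.items():
                fit = site_density_vs_fc(fc.data[col], site_totals)
                density[metric] = {"slope": round(fit.slope, 5), "slope_p": fit.slope_p}
            mirna_summary["site_density"] = density
    _write_json(mirna_summary, outdir / "mirna_summary.json")
    record("mirna", "mirna_summary", outdir / "mirna_summary.json")
    say(f"[mirna] {mirna_summary['n_families']} families ({time.time()-t:.1f}s)")

    manifest["runtime_s"] = round(time.time() - t0, 2)
    _write_json(manifest, outdir / "manifest.json")
    report_text = report(manifest, outdir)
    (outdir / "report.md").write_text(report_text)
    return manifest


def report(manifest: dict, outdir) -> str:
    """Human-readable markdown summary regenerated from a saved manifest."""
    outdir = Path(outdir)
    lines = [
        "# Pipeline report",
        "",
        f"- config hash: `{manifest['config_hash']}`",
        f"- seed: {manifest['seed']}",
        "",
    ]
    missing = [n for n, p in manifest["files"].items() if not (outdir / p).exists()]
    if missing:
        lines.append(f"**Warning: partial manifest — missing outputs: {missing}**")
    summary_path = outdir / manifest["files"].get("driver_summary", "driver_summary.json")
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        for contrast, block in sorted(summary.items()):
            lines.append(f"## Driver classes — {contrast}")
            if block.get("empty"):
                lines.append("no genes passed threshold")
                lines.append("")
                continue
            lines.append(f"total classified: {block['total']}")
            for cat in ("translation_driven", "synergistic", "rna_driven"):
                lines.append(f"- {cat}: {block[cat]['count']} ({block[cat]['pct']}%)")
            contrib = block.get("contribution")
            if contrib and contrib.get("eff_contribution_pct") is not None:
                lines.append(
                    f"- Eff contribution (ratio-of-correlations): {contrib['eff_contribution_pct']}%"
                )
            lines.append("")
    shifts_path = outdir / manifest["files"].get("shifts", "shifts.tsv")
    if shifts_path.exists():
        shifts = pd.read_csv(shifts_path, sep="\t")
        if not shifts.empty:
            lines.append("## Gene-set shifts (KS)")
            sig = shifts[shifts["ks_p"] < 0.05]
            lines.append(
                f"{len(sig)}/{len(shifts)} set-metric-contrast combinations shifted at p < 0.05"
            )
            lines.append("")
    mirna_path = outdir / manifest["files"].get("mirna_summary", "mirna_summary.json")
    if mirna_path.exists():
        msum = json.loads(mirna_path.read_text())
        lines.append("## microRNA repression")
        lines.append(f"families analysed: {msum.get('n_families', 0)}")
        for metric in ("RPF", "RNA", "Eff"):
            block = msum.get(f"stronger_in_BAT_{metric}")
            if block and block.get("fraction") is not None:
                lines.append(
                    f"- stronger repression in BAT ({metric}): "
                    f"{100 * block['fraction']:.1f}% of {block['n_eligible']} eligible families"
                )
        lines.append("")
    return "\n".join(lines) + "\n"
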