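"""End-to-end orchestration: simulate -> call -> merge -> diff -> annotate
-> SD association -> heatmap, under one config and one global seed.

The global seed is expanded into per-stage child seeds through
:func:`cnvpop.simulate.child_rng` (CRC32-keyed seed sequences), so any
stage reruns standalone with the same stream. Each stage logs one
structured line with its input/output row counts — the attrition of calls
through the filters is the main thing a reader wants to see — and the run
manifest records the config snapshot plus a checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .caller import call_sample
from .cnvr import build_cn_matrix, merge_calls
from .annotate import enrich, enrichment_frame, genes_in_cnvrs
from .genome import ConfigurationError
from .popdiff import results_frame, select_differentiated
from .profile import profile_region, render_heatmap
from .sd import IntervalSet, permutation_test
from .simulate import (
    SimConfig,
    child_rng,
    simulate_cohort,
    synthesize_gene_models,
    synthesize_sd_intervals,
)

log = logging.getLogger("cnvpop")


@dataclass
class PipelineConfig:
    """Schema of the YAML pipeline config (all stages, flat defaults)."""

    outdir: str = "cnvpop_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    call: dict = field(default_factory=dict)
    merge: dict = field(default_factory=dict)
    diff: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    sdassoc: dict = field(default_factory=dict)
    heatmap: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def demo_config(outdir: str, seed: int = 17) -> PipelineConfig:
    """Small bundled demo: 2 populations x 5 samples, 6 Mb, 30 events."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        simulate={
            "n_samples": {"wild": 5, "domestic": 5},
            "scaffolds": [["scaffold1", 2_000_000], ["scaffold2", 2_000_000],
                          ["scaffold3", 2_000_000]],
            "n_neutral_events": 24,
            "n_differentiated_events": 6,
            "n_repeat_regions": 4,
        },
        merge={"min_support": 2},
        sdassoc={"n_perm": 99, "flank": 0, "min_len": 3000},
        heatmap={"window_size": 1000},
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; halt on the first stage error; return the manifest."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "artifact": "cnvpop 0.1.0",
        "config": asdict(config),
        "stages": {},
        "checksums": {},
    }

    def finish_stage(name: str, files: list[Path], **counts) -> None:
        manifest["stages"][name] = counts
        for f in files:
            manifest["checksums"][str(f.relative_to(outdir))] = _sha256(f)
        log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))

    # ---------------------------------------------------------- simulate
    sim = SimConfig(seed=config.seed, **config.simulate)
    layout, truth, table, tracks = simulate_cohort(sim)
    files = []
    cio.write_layout(layout, outdir / "layout.json")
    cio.write_truth(truth, outdir / "truth.bed", outdir / "truth.json")
    cio.write_sample_table(table, outdir / "samples.tsv")
    files += [outdir / "layout.json", outdir / "truth.bed", outdir / "truth.json",
              outdir / "samples.tsv"]
    depth_dir = outdir / "depth"
    depth_dir.mkdir(exist_ok=True)
    for sample, track in tracks.items():
        p = depth_dir / f"{sample}.depth.tsv"
        cio.write_depth_tsv(track, p)
        files.append(p)
    finish_stage("simulate", files, n_samples=len(tracks), n_truth_events=len(truth),
                 n_bins=layout.total_bins)

    # -------------------------------------------------------------- call
    call_kw = dict(config.call)
    all_calls = []
    stats = {}
    corrected = {}
    for sample, track in tracks.items():
        calls, gstats = call_sample(track, layout, **call_kw)
        # keep the corrected track for the CN matrix / heatmap stages
        from .depth import gc_correct

        corrected[sample] = gc_correct(track, layout)
        stats[sample] = gstats
        all_calls.extend(calls)
    calls_path = outdir / "cnv_calls.tsv"
    cio.write_calls(all_calls, calls_path, outdir / "cnv_calls.bed")
    finish_stage("call", [calls_path, outdir / "cnv_calls.bed"],
                 n_calls=len(all_calls),
                 n_gain=sum(c.kind == "gain" for c in all_calls),
                 n_loss=sum(c.kind == "loss" for c in all_calls))

    # ------------------------------------------------------------- merge
    cnvrs = merge_calls(all_calls, **{"min_support": 4, **config.merge})
    cio.write_cnvrs(cnvrs, outdir / "cnvrs.tsv", outdir / "cnvrs.bed")
    matrix = build_cn_matrix(cnvrs, corrected, stats, layout)
    matrix.to_csv(outdir / "cn_matrix.tsv", sep="\t")
    finish_stage("merge", [outdir / "cnvrs.tsv", outdir / "cnvrs.bed",
                           outdir / "cn_matrix.tsv"],
                 n_cnvrs=len(cnvrs),
                 total_bp=sum(r.length for r in cnvrs))

    # -------------------------------------------------------------- diff
    diff_kw = dict(config.diff)
    group_col = diff_kw.pop("group_column", "population")
    assignment = table.set_index("sample")[group_col]
    results = select_differentiated(matrix, assignment, **diff_kw) if len(cnvrs) else []
    rframe = results_frame(results)
    rframe.to_csv(outdir / "vst.tsv", sep="\t", index=False)
    finish_stage("diff", [outdir / "vst.tsv"],
                 n_tested=len(results),
                 n_selected=int(rframe["selected"].sum()) if len(rframe) else 0)

    # ---------------------------------------------------------- annotate
    ann_kw = dict(config.annotate)
    gff = ann_kw.pop("gene_models_gff3", None)
    if gff:
        genes = cio.read_gene_models_gff3(gff)
    else:
        term_pool = [f"TERM:{i:04d}" for i in range(20)]
        gene_df = synthesize_gene_models(
            layout,
            n_genes=int(ann_kw.pop("n_genes", 300)),
            term_pool=term_pool,
            seed=int(child_rng(config.seed, "genes").integers(2**31)),
        )
        cio.write_gene_models_gff3(gene_df, outdir / "genes.gff3")
        genes = cio.read_gene_models_gff3(outdir / "genes.gff3")
    hits = genes_in_cnvrs(genes, cnvrs)
    hits.to_csv(outdir / "cnvr_genes.tsv", sep="\t", index=False)
    term_map = {g.gene_id: set(g.terms) for g in genes}
    study = set(hits["gene_id"])
    rows = enrich(study, {g.gene_id for g in genes}, term_map) if study else []
    enrichment_frame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    finish_stage("annotate", [outdir / "cnvr_genes.tsv", outdir / "enrichment.tsv"],
                 n_genes=len(genes), n_cnvr_genes=len(hits),
                 n_terms_tested=len(rows))

    # ----------------------------------------------------------- sdassoc
    sd_kw = dict(config.sdassoc)
    sd_bed = sd_kw.pop("sd_bed", None)
    if sd_bed:
        sd_df = cio.read_bed(sd_bed)
    else:
        sd_df = synthesize_sd_intervals(
            layout,
            n_intervals=int(sd_kw.pop("n_sds", 120)),
            near=[(r.scaffold, r.start, r.end) for r in cnvrs],
            near_fraction=0.4,
            seed=int(child_rng(config.seed, "sds").integers(2**31)),
        )
        cio.write_bed(sd_df.itertuples(index=False), outdir / "sds.bed")
    sd_set = IntervalSet([(r.scaffold, int(r.start), int(r.end))
                          for r in sd_df.itertuples(index=False)])
    cnvr_set = IntervalSet([(r.scaffold, r.start, r.end) for r in cnvrs])
    perm_seed = int(child_rng(config.seed, "sdassoc").integers(2**31))
    perm = permutation_test(cnvr_set, sd_set, layout, seed=perm_seed, **sd_kw)
    sd_report = {
        "observed_fraction": perm.observed,
        "null_mean": perm.null_mean,
        "null_sd": perm.null_sd,
        "n_perm": perm.n_perm,
        "p_value": perm.p_value,
    }
    (outdir / "sd_association.json").write_text(json.dumps(sd_report, indent=1))
    finish_stage("sdassoc", [outdir / "sd_association.json"], **{
        "observed_pct": round(100 * perm.observed, 1), "p": perm.p_value})

    # ----------------------------------------------------------- heatmap
    hm_kw = dict(config.heatmap)
    window = int(hm_kw.pop("window_size", 5000))
    region = hm_kw.pop("region", None)
    if region is None and len(rframe):
        top = rframe.iloc[0]["cnvr_id"]
        r = next(r for r in cnvrs if r.id == top)
        margin = 5 * window
        region = (r.scaffold, max(0, r.start - margin),
                  min(layout.length(r.scaffold), r.end + margin))
    if region is not None:
        scaffold, start, end = region
        prof = profile_region(corrected, stats, layout, scaffold, int(start), int(end),
                              window_size=window)
        prof.to_frame().to_csv(outdir / "heatmap.tsv", sep="\t", index=False)
        render_heatmap(prof, str(outdir / "heatmap.png"),
                       groups=table.set_index("sample")[group_col])
        finish_stage("heatmap", [outdir / "heatmap.tsv"],
                     region=f"{scaffold}:{start}-{end}", n_windows=prof.ratios.shape[1])

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
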