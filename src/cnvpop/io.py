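"""File formats: depth TSV, BED, GFF3, sample tables, matrices, manifests.

All on-disk coordinates follow the conventions of the format: BED and the
internal TSVs are 0-based half-open; GFF3 is 1-based inclusive and is
converted on read/write. Everything in memory is 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .caller import CNVCall
from .cnvr import CNVR
from .depth import BinnedDepthTrack
from .genome import GenomeLayout
from .simulate import TruthEvent

# ---------------------------------------------------------------- depth TSV


def write_depth_tsv(track: BinnedDepthTrack, path: str | Path) -> None:
    """5-column depth track: sample, scaffold, bin_start, depth, q0_frac."""
    frames = []
    for scaffold in track.scaffolds:
        n = track.raw_depth[scaffold].size
        frames.append(
            pd.DataFrame(
                {
                    "sample": track.sample_id,
                    "scaffold": scaffold,
                    "bin_start": np.arange(n, dtype=np.int64) * track.bin_size,
                    "depth": track.raw_depth[scaffold],
                    "q0_frac": track.q0_frac[scaffold],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str | Path, bin_size: int = 500) -> BinnedDepthTrack:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "scaffold", "bin_start", "depth", "q0_frac"}
    if not required.issubset(df.columns):
        raise ValueError(f"depth TSV missing columns {sorted(required - set(df.columns))}")
    samples = df["sample"].unique()
    if samples.size != 1:
        raise ValueError(f"expected a single-sample depth TSV, found {samples.tolist()}")
    raw: dict[str, np.ndarray] = {}
    q0: dict[str, np.ndarray] = {}
    for scaffold, sub in df.groupby("scaffold", sort=False):
        sub = sub.sort_values("bin_start")
        starts = sub["bin_start"].to_numpy()
        if starts.size > 1 and not np.all(np.diff(starts) == bin_size):
            raise ValueError(f"non-uniform bin grid on {scaffold!r}")
        raw[str(scaffold)] = sub["depth"].to_numpy(dtype=float)
        q0[str(scaffold)] = sub["q0_frac"].to_numpy(dtype=float)
    return BinnedDepthTrack(
        sample_id=str(samples[0]), bin_size=bin_size, raw_depth=raw, q0_frac=q0
    )


# ---------------------------------------------------------------------- BED


def write_bed(intervals, path: str | Path) -> None:
    """Minimal BED writer: iterable of (scaffold, start, end[, name[, score]])."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED reader returning scaffold/start/end (+name/score when present)."""
    names = ["scaffold", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ------------------------------------------------------------------ truth


def write_truth(truth: list[TruthEvent], bed_path: str | Path, json_path: str | Path) -> None:
    """Truth events as BED (coords + kind) with a JSON sidecar (CN maps)."""
    write_bed(
        [(e.scaffold, e.start, e.end, e.kind) for e in truth],
        bed_path,
    )
    payload = [
        {
            "scaffold": e.scaffold,
            "start": e.start,
            "end": e.end,
            "kind": e.kind,
            "cn_by_sample": e.cn_by_sample,
            "pop_freq": e.pop_freq,
        }
        for e in truth
    ]
    Path(json_path).write_text(json.dumps(payload, indent=1))


def read_truth(json_path: str | Path) -> list[TruthEvent]:
    payload = json.loads(Path(json_path).read_text())
    return [TruthEvent(**item) for item in payload]


# ------------------------------------------------------------------- calls


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample_id for c in calls],
            "scaffold": [c.scaffold for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "kind": [c.kind for c in calls],
            "cn": [c.cn for c in calls],
            "p_value": [c.p_value for c in calls],
            "q0_frac": [c.q0_frac for c in calls],
        }
    )


def write_calls(calls: list[CNVCall], tsv_path: str | Path, bed_path: str | Path | None = None):
    calls_to_frame(calls).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        write_bed(
            [
                (c.scaffold, c.start, c.end, c.kind, int(round(100 * c.cn)))
                for c in calls
            ],
            bed_path,
        )


def read_calls(tsv_path: str | Path) -> list[CNVCall]:
    df = pd.read_csv(tsv_path, sep="\t")
    return [
        CNVCall(
            sample_id=str(r["sample"]),
            scaffold=str(r["scaffold"]),
            start=int(r["start"]),
            end=int(r["end"]),
            kind=str(r["kind"]),
            cn=float(r["cn"]),
            p_value=float(r["p_value"]),
            q0_frac=float(r["q0_frac"]),
        )
        for _, r in df.iterrows()
    ]


# ------------------------------------------------------------------- CNVRs


def cnvrs_to_frame(cnvrs: list[CNVR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in cnvrs],
            "scaffold": [r.scaffold for r in cnvrs],
            "start": [r.start for r in cnvrs],
            "end": [r.end for r in cnvrs],
            "type": [r.type for r in cnvrs],
            "support": [r.support for r in cnvrs],
        }
    )


def write_cnvrs(cnvrs: list[CNVR], tsv_path: str | Path, bed_path: str | Path | None = None):
    cnvrs_to_frame(cnvrs).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        write_bed(
            [(r.scaffold, r.start, r.end, f"{r.id}:{r.type}", r.support) for r in cnvrs],
            bed_path,
        )


def read_cnvrs(tsv_path: str | Path) -> list[CNVR]:
    df = pd.read_csv(tsv_path, sep="\t")
    return [
        CNVR(
            id=str(r["id"]),
            scaffold=str(r["scaffold"]),
            start=int(r["start"]),
            end=int(r["end"]),
            type=str(r["type"]),
            support=int(r["support"]),
        )
        for _, r in df.iterrows()
    ]


# -------------------------------------------------------------------- GFF3


def write_gene_models_gff3(genes: pd.DataFrame | list[GeneModel], path: str | Path) -> None:
    """Gene models to GFF3 (1-based inclusive on disk)."""
    if isinstance(genes, pd.DataFrame):
        genes = [
            GeneModel(
                gene_id=str(r["gene_id"]),
                scaffold=str(r["scaffold"]),
                start=int(r["start"]),
                end=int(r["end"]),
                terms=tuple(t for t in str(r.get("terms", "") or "").split(",") if t),
            )
            for _, r in genes.iterrows()
        ]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.terms:
                attrs += f";Ontology_term={','.join(g.terms)}"
            fh.write(
                f"{g.scaffold}\tcnvpop\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )


def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Gene features from GFF3, converted to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        terms = tuple(feat.attributes.get("Ontology_term", []))
        genes.append(
            GeneModel(
                gene_id=feat.id,
                scaffold=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                terms=terms,
            )
        )
    return genes


# ------------------------------------------------------------- sample table


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("sample table needs a 'sample' column")
    return df


# ----------------------------------------------------------------- layout


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    """Layout as JSON: scaffolds, bin size and per-bin GC."""
    payload = {
        "scaffolds": [[n, length] for n, length in layout.scaffolds],
        "bin_size": layout.bin_size,
        "gc": {s: np.round(arr, 5).tolist() for s, arr in layout.gc.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_layout(path: str | Path) -> GenomeLayout:
    payload = json.loads(Path(path).read_text())
    return GenomeLayout(
        scaffolds=[(n, int(length)) for n, length in payload["scaffolds"]],
        bin_size=int(payload["bin_size"]),
        gc={s: np.asarray(v, dtype=float) for s, v in payload.get("gc", {}).items()},
    )


# ----------------------------------------------------- SAM/BAM depth helper


def depth_from_alignments(
    path: str | Path,
    layout: GenomeLayout,
    sample_id: str,
    min_mapq_unique: int = 1,
) -> BinnedDepthTrack:
    """Binned depth from a coordinate-sorted SAM/BAM of aligned reads.

    Helper for real data: alignment itself is an external step (e.g.
    BWA-MEM). Each read is counted once, in the bin of its leftmost
    aligned base; reads with MAPQ below ``min_mapq_unique`` count toward
    the multi-mapping (q0) fraction of their bin.
    """
    import pysam

    raw = {s: np.zeros(layout.n_bins(s)) for s in layout.scaffold_names}
    multi = {s: np.zeros(layout.n_bins(s)) for s in layout.scaffold_names}
    with pysam.AlignmentFile(str(path)) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            scaffold = read.reference_name
            if scaffold not in raw:
                continue
            b = min(read.reference_start // layout.bin_size, layout.n_bins(scaffold) - 1)
            raw[scaffold][b] += 1
            if read.mapping_quality < min_mapq_unique:
                multi[scaffold][b] += 1
    q0 = {
        s: np.divide(multi[s], raw[s], out=np.zeros_like(raw[s]), where=raw[s] > 0)
        for s in raw
    }
    return BinnedDepthTrack(
        sample_id=sample_id, bin_size=layout.bin_size, raw_depth=raw, q0_frac=q0
    )


# -------------------------------------------------------------------- qPCR


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """qPCR Ct table: sample, target, ct_target, ct_ref (+optional replicate)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "ct_target", "ct_ref"}
    if not required.issubset(df.columns):
        raise ValueError(f"qPCR table missing columns {sorted(required - set(df.columns))}")
    return df
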