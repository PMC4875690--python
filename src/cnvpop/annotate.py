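"""Gene content of CNVRs and functional-term enrichment.

A gene is assigned to the CNVR set when more than half of its length lies
inside the union of all CNVRs (the >50% rule — about the gene, not any
single region). Enrichment of functional terms among those genes is the
upper-tail hypergeometric test against a gene background, with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneModel:
    """A gene interval (0-based half-open) with optional functional terms."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    terms: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EnrichmentRow:
    term_id: str
    k: int  # study genes with the term
    n: int  # study-set size
    K: int  # background genes with the term
    N: int  # background size
    p: float
    p_adj: float = float("nan")
    significant: bool = False


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def genes_in_cnvrs(
    genes: list[GeneModel],
    cnvrs,
    min_fraction: float = 0.5,
    known_scaffolds: set[str] | None = None,
) -> pd.DataFrame:
    """Genes whose length is covered > ``min_fraction`` by the CNVR union.

    ``cnvrs`` is any iterable of objects with scaffold/start/end (CNVR
    dataclasses or BED-like rows). Returns columns gene_id, cnvr_ids
    (comma-joined ids of intersecting regions, when available) and
    covered_fraction, strictly above the threshold.
    """
    by_scaffold: dict[str, list[tuple[int, int, str]]] = {}
    for r in cnvrs:
        rid = getattr(r, "id", "")
        by_scaffold.setdefault(r.scaffold, []).append((r.start, r.end, rid))
    union = {s: _union_intervals([(a, b) for a, b, _ in iv]) for s, iv in by_scaffold.items()}
    records = []
    for gene in genes:
        if known_scaffolds is not None and gene.scaffold not in known_scaffolds:
            raise KeyError(f"gene {gene.gene_id} on unknown scaffold {gene.scaffold!r}")
        pieces = union.get(gene.scaffold, [])
        covered = sum(
            max(0, min(gene.end, b) - max(gene.start, a)) for a, b in pieces
        )
        fraction = covered / gene.length
        if fraction > min_fraction:
            hit_ids = [
                rid
                for a, b, rid in by_scaffold.get(gene.scaffold, [])
                if a < gene.end and gene.start < b and rid
            ]
            records.append((gene.gene_id, ",".join(hit_ids), fraction))
    return pd.DataFrame(records, columns=["gene_id", "cnvr_ids", "covered_fraction"])


def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    study_genes: set[str],
    background_genes: set[str],
    term_map: dict[str, set[str] | tuple[str, ...] | list[str]],
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Term enrichment of a study gene set against a background.

    Upper-tail hypergeometric p per term, BH-adjusted across all tested
    terms; terms absent from the background are skipped. Rows come back
    sorted by adjusted then raw p.
    """
    if not background_genes:
        raise ValueError("empty background")
    extra = study_genes - background_genes
    if extra:
        raise ValueError(f"study genes not in background: {sorted(extra)[:5]}")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in background_genes:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N = len(background_genes)
    n = len(study_genes)
    rows = []
    for term, members in sorted(term_genes.items()):
        K = len(members)
        if K == 0:
            continue
        k = len(members & study_genes)
        rows.append(EnrichmentRow(term_id=term, k=k, n=n, K=K, N=N, p=hypergeom_upper(k, N, K, n)))
    if rows:
        _, p_adj, _, _ = multipletests([r.p for r in rows], method="fdr_bh")
        for r, adj in zip(rows, p_adj):
            r.p_adj = float(adj)
            r.significant = r.p_adj < alpha
    rows.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "k": [r.k for r in rows],
            "n": [r.n for r in rows],
            "K": [r.K for r in rows],
            "N": [r.N for r in rows],
            "p": [r.p for r in rows],
            "p_adj": [r.p_adj for r in rows],
            "significant": [r.significant for r in rows],
        }
    )
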