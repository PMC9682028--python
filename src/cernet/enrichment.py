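"""Hypergeometric gene-set enrichment and pathway crosstalk.

Network mRNAs are tested against a gene-set collection (GMT-style, e.g.
KEGG pathways) with the one-sided hypergeometric test, Benjamini-Hochberg
corrected. Enriched pathways from two conditions are compared, and a
crosstalk graph connects every pair of selected pathways sharing at least
one gene, highlighting heavily overlapping pairs (> 20 shared genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: edges sharing strictly more genes than this are flagged as heavy crosstalk
DEFAULT_HIGHLIGHT_MIN_SHARED = 20
DEFAULT_Q_MAX = 0.05


@dataclass(frozen=True)
class GeneSetCollection:
    """pathway_id -> (pathway_name, gene id set)."""

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {pid!r} is empty")

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set id, description, then tab-separated genes."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs id, description and >= 1 gene")
            pid, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if pid in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene-set id {pid!r}")
            sets[pid] = (desc, frozenset(genes))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in collection:
            genes = sorted(collection.genes(pid))
            fh.write("\t".join([pid, collection.name(pid), *genes]) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    overlap_count: int
    query_size: int
    set_size: int
    universe_size: int
    p_value: float
    q_value: float


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    if len(p_values) == 0:
        return []
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {p}")
    _, q, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(v) for v in q]


def hypergeometric_enrichment(
    query: frozenset[str] | set[str],
    collection: GeneSetCollection,
    universe: frozenset[str] | set[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of ``query`` in each gene set.

    p = P(X >= overlap) drawing ``|query|`` genes from ``|universe|`` with
    ``|set ∩ universe|`` successes. Query genes outside the universe and set
    genes outside the universe are dropped with a warning. Results are sorted
    by p-value (ties by pathway id) and BH-adjusted.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    universe = frozenset(universe)
    stray = frozenset(query) - universe
    if stray:
        log.warning("dropping %d query ids outside the universe", len(stray))
    query = frozenset(query) & universe
    if not query:
        raise ValueError("no query genes remain inside the universe")

    rows: list[EnrichmentResult] = []
    n_u, n_q = len(universe), len(query)
    for pid in collection:
        genes = collection.genes(pid)
        if genes - universe:
            log.warning(
                "gene set %s: dropping %d genes outside the universe", pid, len(genes - universe)
            )
        genes = genes & universe
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, n_u, len(genes), n_q))
        rows.append(
            EnrichmentResult(
                pathway_id=pid,
                pathway_name=collection.name(pid),
                overlap_count=k,
                query_size=n_q,
                set_size=len(genes),
                universe_size=n_u,
                p_value=min(p, 1.0),
                q_value=float("nan"),
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.pathway_id))
    qs = bh_adjust([r.p_value for r in rows])
    return [
        EnrichmentResult(**{**r.__dict__, "q_value": q}) for r, q in zip(rows, qs)
    ]


@dataclass(frozen=True)
class CrosstalkEdge:
    pathway_a: str
    pathway_b: str
    n_shared_genes: int
    highlight: bool


@dataclass(frozen=True)
class CrosstalkNetwork:
    """Pathway graph: edge iff >= 1 shared gene; highlight iff > threshold."""

    nodes: Mapping[str, str]  # pathway_id -> origin label
    edges: tuple[CrosstalkEdge, ...]


def crosstalk_network(
    selected: Mapping[str, str],
    collection: GeneSetCollection,
    highlight_min_shared: int = DEFAULT_HIGHLIGHT_MIN_SHARED,
) -> CrosstalkNetwork:
    """Crosstalk graph over ``selected`` pathways (id -> origin label).

    Unordered pathway pairs sharing at least one gene are connected; the
    edge weight is the shared-gene count and the highlight flag marks
    weights strictly greater than ``highlight_min_shared``.
    """
    unknown = [pid for pid in selected if pid not in collection.sets]
    if unknown:
        raise KeyError(f"unknown pathway id(s): {unknown}")
    ids = sorted(selected)
    edges: list[CrosstalkEdge] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            n = len(collection.genes(a) & collection.genes(b))
            if n >= 1:
                edges.append(
                    CrosstalkEdge(
                        pathway_a=a,
                        pathway_b=b,
                        n_shared_genes=n,
                        highlight=n > highlight_min_shared,
                    )
                )
    return CrosstalkNetwork(nodes=dict(selected), edges=tuple(edges))


def compare_state_functions(
    res_a: Sequence[EnrichmentResult],
    res_b: Sequence[EnrichmentResult],
    q_max: float = DEFAULT_Q_MAX,
    label_a: str = "A",
    label_b: str = "B",
) -> dict[str, str]:
    """Label pathways significant in either condition as A-specific,
    B-specific or shared (q <= q_max per condition)."""
    sig_a = {r.pathway_id for r in res_a if r.q_value <= q_max}
    sig_b = {r.pathway_id for r in res_b if r.q_value <= q_max}
    out: dict[str, str] = {}
    for pid in sorted(sig_a | sig_b):
        if pid in sig_a and pid in sig_b:
            out[pid] = "shared"
        elif pid in sig_a:
            out[pid] = f"{label_a}-specific"
        else:
            out[pid] = f"{label_b}-specific"
    return out
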