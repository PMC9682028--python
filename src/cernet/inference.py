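"""Candidate sponge pairs and condition-specific ceRNA networks.

A lncRNA L and an mRNA M become a candidate competitive pair when they are
targeted by more than 3 common miRNAs (i.e. at least 4). For each candidate
the Spearman rank correlation of the two expression profiles is computed
separately per condition on that condition's samples only; a candidate
enters the network of a condition when its correlation there reaches the
cutoff (0.9 by default — only strong positive co-expression qualifies, which
is what sponge competition predicts: more lncRNA, less free miRNA, more mRNA).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import (
    LNCRNA,
    MRNA,
    CandidatePair,
    CeRNANetwork,
    ExpressionMatrix,
    InteractionTable,
    NetworkEdge,
)

log = logging.getLogger(__name__)

#: default shared-miRNA rule: "more than 3" common miRNAs
DEFAULT_MIN_SHARED = 4
#: default correlation cutoff for a competitive regulatory pair
DEFAULT_RHO_MIN = 0.9
#: absolute guard so a correlation of exactly rho_min computed as
#: Pearson-of-ranks is not excluded by floating-point roundoff
_RHO_EPS = 1e-9


def candidate_pairs(
    lnc_table: InteractionTable,
    mrna_table: InteractionTable,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> list[CandidatePair]:
    """Enumerate (lncRNA, mRNA) pairs sharing at least ``min_shared`` miRNAs.

    The overlap significance ``p_shared`` is the hypergeometric upper tail
    P(X >= k) of drawing ``|targets(L)|`` miRNAs from the universe of all
    miRNA ids observed in either table, where ``|targets(M)|`` of them are
    "successes". It is reported, not used as a filter.
    """
    if min_shared < 1:
        raise ValueError(f"min_shared must be >= 1, got {min_shared}")
    if not lnc_table.edges or not mrna_table.edges:
        log.warning("empty interaction table: no candidate pairs")
        return []

    universe = lnc_table.mirnas | mrna_table.mirnas
    n_universe = len(universe)
    lnc_targets = lnc_table.target_map()
    mrna_targets = mrna_table.target_map()

    out: list[CandidatePair] = []
    for lnc in sorted(lnc_targets):
        t_l = lnc_targets[lnc]
        for mrna in sorted(mrna_targets):
            t_m = mrna_targets[mrna]
            shared = t_l & t_m
            if len(shared) < min_shared:
                continue
            p = float(stats.hypergeom.sf(len(shared) - 1, n_universe, len(t_m), len(t_l)))
            out.append(
                CandidatePair(
                    lncrna=lnc,
                    mrna=mrna,
                    shared_mirnas=shared,
                    shared_count=len(shared),
                    p_shared=min(p, 1.0),
                )
            )
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks on ties).

    Returns NaN when either vector is constant — an undefined correlation
    must never silently pass or fail a cutoff downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 4:
        raise ValueError(f"need >= 4 observations for a stable rank correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def build_state_network(
    candidates: Sequence[CandidatePair],
    expr: ExpressionMatrix,
    state: str,
    rho_min: float = DEFAULT_RHO_MIN,
) -> CeRNANetwork:
    """Keep the candidates whose within-state Spearman rho reaches ``rho_min``.

    Candidates whose transcripts are absent from the matrix are skipped (count
    logged); candidates with a constant profile (undefined rho) are excluded.
    """
    samples = expr.samples_in(state)
    if not samples:
        raise ValueError(f"state {state!r} has no samples in the expression matrix")
    if len(samples) < 4:
        raise ValueError(f"state {state!r} has {len(samples)} samples; need >= 4")

    values = expr.values[samples]
    present = set(expr.values.index)
    edges: dict[tuple[str, str], NetworkEdge] = {}
    n_skipped = 0
    for cand in candidates:
        if cand.lncrna not in present or cand.mrna not in present:
            n_skipped += 1
            continue
        rho = spearman_rho(values.loc[cand.lncrna].to_numpy(), values.loc[cand.mrna].to_numpy())
        if math.isnan(rho) or rho < rho_min - _RHO_EPS:
            continue
        edges[(cand.lncrna, cand.mrna)] = NetworkEdge(
            lncrna=cand.lncrna,
            mrna=cand.mrna,
            rho=rho,
            shared_count=cand.shared_count,
            shared_mirnas=cand.shared_mirnas,
        )
    if n_skipped:
        log.info("state %s: skipped %d candidates absent from expression", state, n_skipped)
    return CeRNANetwork(state=state, edges=edges)


def degree_table(net: CeRNANetwork, side: str) -> list[tuple[str, int]]:
    """Node degrees on one side, ranked descending (ties lexicographic)."""
    if side not in (LNCRNA, MRNA):
        raise ValueError(f"side must be {LNCRNA!r} or {MRNA!r}")
    idx = 0 if side == LNCRNA else 1
    counts: dict[str, int] = {}
    for pair in net.edges:
        counts[pair[idx]] = counts.get(pair[idx], 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def extract_axes(
    net: CeRNANetwork,
    lnc_table: InteractionTable,
    mrna_table: InteractionTable,
    lncrna: str,
) -> list[tuple[str, str, str]]:
    """Enumerate lncRNA -> miRNA -> mRNA regulation cascades for one lncRNA.

    For every network edge (lncrna, M) each miRNA of the edge's shared set
    yields one (lncRNA, miRNA, mRNA) triple. The interaction tables are
    accepted so a caller can restrict the shared set recorded on edges built
    elsewhere; edges already carry their shared miRNAs, which are the
    intersection of the two tables' target sets.
    """
    if lncrna not in net.lncrnas:
        log.warning("lncRNA %s has no edges in the %s network", lncrna, net.state)
        return []
    triples: list[tuple[str, str, str]] = []
    for (l, m), edge in sorted(net.edges.items()):
        if l != lncrna:
            continue
        shared = edge.shared_mirnas or (lnc_table.targets_of(l) & mrna_table.targets_of(m))
        for mir in sorted(shared):
            triples.append((l, mir, m))
    return triples
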