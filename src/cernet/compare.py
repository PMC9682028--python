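"""Comparison of condition-specific ceRNA networks.

Quantifies how much two state networks share — lncRNA nodes, mRNA nodes and
(lncRNA, mRNA) edges — via Jaccard indices, extracts the shared-edge
subnetwork, reports the differentially-expressed fraction of network nodes,
and partitions a single lncRNA's regulatory neighborhood into state-specific
and shared targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .containers import LNCRNA, MRNA, CeRNANetwork, ExpressionMatrix

log = logging.getLogger(__name__)


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|a ∩ b| / |a ∪ b|; NaN (with a warning) when both sets are empty."""
    union = len(a | b)
    if union == 0:
        log.warning("jaccard of two empty sets is undefined")
        return float("nan")
    return len(a & b) / union


def percent_1dp(fraction: float) -> float:
    """Fraction as a percentage truncated (not rounded) to one decimal.

    Truncation is this package's reporting convention for sharing
    percentages: 197/296 prints as 66.5, 230/5163 as 4.4.
    """
    if math.isnan(fraction):
        return float("nan")
    return math.floor(fraction * 1000.0 + 1e-9) / 10.0


@dataclass(frozen=True)
class SharingRow:
    """Sharing counts for one entity class (lncRNA / mRNA / edge)."""

    count_a: int
    count_b: int
    count_shared: int
    jaccard: float

    @property
    def percent_shared(self) -> float:
        return percent_1dp(self.jaccard)


@dataclass(frozen=True)
class SharingSummary:
    lncrna: SharingRow
    mrna: SharingRow
    edge: SharingRow

    def as_dict(self) -> dict:
        out = {}
        for name in ("lncrna", "mrna", "edge"):
            row: SharingRow = getattr(self, name)
            out[name] = {
                "count_a": row.count_a,
                "count_b": row.count_b,
                "count_shared": row.count_shared,
                "jaccard": row.jaccard,
                "percent_shared": row.percent_shared,
            }
        return out


@dataclass(frozen=True)
class NeighborhoodDiff:
    """Partition of a lncRNA's mRNA targets across two networks."""

    lncrna: str
    targets_a_only: frozenset[str]
    targets_b_only: frozenset[str]
    targets_both: frozenset[str]


def _row(a: frozenset, b: frozenset) -> SharingRow:
    return SharingRow(
        count_a=len(a), count_b=len(b), count_shared=len(a & b), jaccard=jaccard(a, b)
    )


def compare_networks(net_a: CeRNANetwork, net_b: CeRNANetwork) -> SharingSummary:
    """Node and edge sharing between two state networks.

    Edge identity is the ordered (lncrna, mrna) id pair; correlation values
    are annotations, not identity.
    """
    return SharingSummary(
        lncrna=_row(net_a.lncrnas, net_b.lncrnas),
        mrna=_row(net_a.mrnas, net_b.mrnas),
        edge=_row(net_a.edge_ids, net_b.edge_ids),
    )


def shared_subnetwork(
    net_a: CeRNANetwork, net_b: CeRNANetwork
) -> list[tuple[str, str, float, float]]:
    """Edges present in both networks as (lncrna, mrna, rho_a, rho_b)."""
    shared = net_a.edge_ids & net_b.edge_ids
    return [
        (l, m, net_a.edges[(l, m)].rho, net_b.edges[(l, m)].rho) for l, m in sorted(shared)
    ]


def de_fraction(net: CeRNANetwork, expr: ExpressionMatrix, side: str) -> float:
    """Fraction of the network's nodes on one side flagged as DE.

    DE flags are inputs carried by the expression matrix; NaN (with a
    warning) when the side has no nodes.
    """
    if side == LNCRNA:
        nodes = net.lncrnas
    elif side == MRNA:
        nodes = net.mrnas
    else:
        raise ValueError(f"side must be {LNCRNA!r} or {MRNA!r}")
    if not nodes:
        log.warning("de_fraction undefined: %s network has no %s nodes", net.state, side)
        return float("nan")
    flagged = sum(1 for n in nodes if expr.de_flag.get(n, False))
    return flagged / len(nodes)


def neighborhood_diff(
    lncrna: str, net_a: CeRNANetwork, net_b: CeRNANetwork
) -> NeighborhoodDiff:
    """Split a lncRNA's targets into A-only / B-only / both."""
    in_a, in_b = lncrna in net_a.lncrnas, lncrna in net_b.lncrnas
    if not in_a and not in_b:
        raise ValueError(f"lncRNA {lncrna!r} is absent from both networks")
    ngb_a = net_a.neighbors_of(lncrna)
    ngb_b = net_b.neighbors_of(lncrna)
    return NeighborhoodDiff(
        lncrna=lncrna,
        targets_a_only=ngb_a - ngb_b,
        targets_b_only=ngb_b - ngb_a,
        targets_both=ngb_a & ngb_b,
    )
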