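"""Core in-memory containers shared across the pipeline.

The pipeline works on three kinds of objects: bipartite regulator-miRNA
interaction tables (one for lncRNAs, one for mRNAs), expression matrices
with a sample-to-condition map, and state-labeled ceRNA networks whose
edges carry the Spearman correlation that admitted them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

LNCRNA = "lncRNA"
MRNA = "mRNA"
MIRNA = "miRNA"

SIDES = (LNCRNA, MRNA)


@dataclass(frozen=True)
class InteractionTable:
    """A bipartite edge set between regulators (lncRNAs or mRNAs) and miRNAs.

    Edges are (regulator_id, mirna_id) pairs; ids are opaque, case-sensitive
    strings. ``side`` records which transcript class the regulators belong to.
    """

    side: str
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        for reg, mir in self.edges:
            if not reg or not mir:
                raise ValueError("interaction ids must be non-empty strings")

    @property
    def regulators(self) -> frozenset[str]:
        return frozenset(reg for reg, _ in self.edges)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(mir for _, mir in self.edges)

    def targets_of(self, regulator: str) -> frozenset[str]:
        """miRNAs interacting with ``regulator`` (empty set if unknown)."""
        return frozenset(mir for reg, mir in self.edges if reg == regulator)

    def target_map(self) -> dict[str, frozenset[str]]:
        """regulator -> set of interacting miRNAs, for all regulators."""
        out: dict[str, set[str]] = {}
        for reg, mir in self.edges:
            out.setdefault(reg, set()).add(mir)
        return {reg: frozenset(mirs) for reg, mirs in out.items()}

    @classmethod
    def from_pairs(cls, side: str, pairs: Iterable[tuple[str, str]]) -> "InteractionTable":
        return cls(side=side, edges=frozenset(pairs))


@dataclass
class ExpressionMatrix:
    """Transcripts-by-samples expression with condition labels and DE flags.

    ``values`` holds nonnegative expression (rows = transcripts, columns =
    samples); only within-state ranks matter downstream, so the scale is
    arbitrary. ``state_of`` maps every sample to its condition label,
    ``transcript_kind`` maps transcripts to lncRNA/mRNA/miRNA, and ``de_flag``
    marks transcripts called differentially expressed (an input here, not a
    computation).
    """

    values: pd.DataFrame
    state_of: dict[str, str]
    transcript_kind: dict[str, str] = field(default_factory=dict)
    de_flag: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate transcript ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.state_of]
        if missing:
            raise ValueError(f"samples without a state label: {missing}")

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def states(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.state_of[s], None)
        return list(seen)

    def samples_in(self, state: str) -> list[str]:
        return [s for s in self.values.columns if self.state_of[s] == state]

    def state_values(self, transcript: str, state: str) -> pd.Series:
        return self.values.loc[transcript, self.samples_in(state)]


@dataclass(frozen=True)
class CandidatePair:
    """A (lncRNA, mRNA) pair sharing enough miRNAs to be a sponge candidate.

    ``p_shared`` is the hypergeometric upper tail P(X >= shared_count) for the
    overlap between the two target sets in the observed miRNA universe.
    """

    lncrna: str
    mrna: str
    shared_mirnas: frozenset[str]
    shared_count: int
    p_shared: float

    def __post_init__(self) -> None:
        if self.shared_count != len(self.shared_mirnas):
            raise ValueError("shared_count must equal |shared_mirnas|")
        if not (0.0 < self.p_shared <= 1.0) and not math.isnan(self.p_shared):
            raise ValueError(f"p_shared out of (0, 1]: {self.p_shared}")


@dataclass(frozen=True)
class NetworkEdge:
    """A competitive-regulation edge with its admitting correlation."""

    lncrna: str
    mrna: str
    rho: float
    shared_count: int
    shared_mirnas: frozenset[str] = frozenset()


@dataclass
class CeRNANetwork:
    """State-labeled bipartite lncRNA-mRNA competitive-regulation network."""

    state: str
    edges: dict[tuple[str, str], NetworkEdge] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lnc, mr = self.lncrnas, self.mrnas
        overlap = lnc & mr
        if overlap:
            raise ValueError(f"ids appear on both sides of the bipartite network: {sorted(overlap)}")

    @property
    def lncrnas(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.edges)

    @property
    def mrnas(self) -> frozenset[str]:
        return frozenset(m for _, m in self.edges)

    @property
    def edge_ids(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors_of(self, lncrna: str) -> frozenset[str]:
        return frozenset(m for (l, m) in self.edges if l == lncrna)


@dataclass(frozen=True)
class RiskModel:
    """Linear miRNA risk score: S = intercept + sum_i beta_i * x_i.

    ``provenance`` records whether the coefficients were fitted from a panel
    or loaded from a coefficient file.
    """

    coefficients: Mapping[str, float]
    intercept: float = 0.0
    provenance: str = "loaded"

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise ValueError("risk model needs at least one coefficient")
        if self.provenance not in ("fitted", "loaded"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def mirnas(self) -> list[str]:
        return list(self.coefficients)
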