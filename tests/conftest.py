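import numpy as np
import pandas as pd
import pytest

from cernet import (
    CeRNANetwork,
    ExpressionMatrix,
    InteractionTable,
    NetworkEdge,
    SimulationConfig,
)
from cernet.containers import LNCRNA, MRNA


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_lncrna=30,
        n_mrna=30,
        n_mirna=40,
        n_samples_per_state=5,
        n_planted_pairs=5,
        shared_mirna_min=4,
        rho_target=0.98,
        background_density=0.1,
        de_fraction=0.2,
        effect_size=5.0,
        seed=42,
    )


def make_network(state: str, edges: list[tuple[str, str, float]]) -> CeRNANetwork:
    return CeRNANetwork(
        state=state,
        edges={
            (l, m): NetworkEdge(lncrna=l, mrna=m, rho=r, shared_count=4)
            for l, m, r in edges
        },
    )


def make_expression(values: dict[str, list[float]], states: list[str],
                    de: dict[str, bool] | None = None) -> ExpressionMatrix:
    """Tiny expression matrix; ``values`` maps transcript -> per-sample row."""
    n = len(next(iter(values.values())))
    samples = [f"s{i}" for i in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=samples).T,
        state_of=dict(zip(samples, states)),
        de_flag=de or {},
    )


@pytest.fixture
def toy_tables() -> tuple[InteractionTable, InteractionTable]:
    lnc = InteractionTable.from_pairs(
        LNCRNA,
        [("L1", f"m{i}") for i in range(1, 6)] + [("L2", "m1"), ("L2", "m9")],
    )
    mrna = InteractionTable.from_pairs(
        MRNA,
        [("G1", f"m{i}") for i in range(1, 5)] + [("G2", "m9")],
    )
    return lnc, mrna


def brute_force_candidates(lnc: InteractionTable, mrna: InteractionTable, min_shared: int):
    """Independent oracle: exhaustive set intersection over the raw tables."""
    out = {}
    for l in lnc.regulators:
        for g in mrna.regulators:
            shared = lnc.targets_of(l) & mrna.targets_of(g)
            if len(shared) >= min_shared:
                out[(l, g)] = shared
    return out
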