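"""Synthetic data generator with planted ceRNA structure.

Emulates the study design the pipeline targets: two regulator-miRNA
interaction tables, a two-condition expression matrix (a handful of samples
per condition, as in a 5 + 5 islet-exosome experiment), differential-
expression flags, and a labeled miRNA panel for biomarker evaluation.

Planted (lncRNA, mRNA) pairs share at least ``shared_mirna_min`` miRNAs by
construction and are strongly rank-correlated in exactly one condition, so
downstream inference has a known ground truth to recover.

Correlation planting
--------------------
Within a planted pair's active condition, the lncRNA takes a latent draw
``z`` and the mRNA copies ``z`` per sample with probability ``rho_target``,
otherwise takes a fresh independent draw. This is a shared-latent-factor
mixture copula whose population Spearman correlation equals ``rho_target``
exactly, while keeping per-sample rank agreement high enough that strong
plants remain detectable at very small sample sizes (a pure bivariate
Gaussian with the same asymptotic Spearman scrambles small-sample ranks far
more often). Latents are pushed through ``exp`` so emitted values are
positive; rank statistics are invariant to that transform.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import LNCRNA, MIRNA, MRNA, ExpressionMatrix, InteractionTable

STATE_CONTROL = "control"
STATE_CYTOKINES = "cytokines"
STATES = (STATE_CONTROL, STATE_CYTOKINES)

#: latent-scale mean shift applied to DE-flagged transcripts in the
#: cytokines condition (in units of the latent SD)
DE_SHIFT = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror a small two-condition exosome experiment: 5 samples per
    condition, sparse CLIP-style target tables (each regulator interacts
    with ~5% of a 100-miRNA universe), and planted sponge pairs sharing at
    least 4 miRNAs.
    """

    n_lncrna: int = 120
    n_mrna: int = 120
    n_mirna: int = 100
    n_samples_per_state: int = 5
    n_planted_pairs: int = 20
    shared_mirna_min: int = 4
    rho_target: float = 0.98
    background_density: float = 0.05
    de_fraction: float = 0.1
    effect_size: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lncrna", "n_mrna", "n_mirna", "n_samples_per_state"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_planted_pairs < 0 or self.shared_mirna_min < 0:
            raise ValueError("counts must be nonnegative")
        if not (0.0 < self.rho_target <= 1.0):
            raise ValueError("rho_target must be in (0, 1]")
        for name in ("background_density", "de_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.shared_mirna_min > self.n_mirna:
            raise ValueError(
                f"cannot plant {self.shared_mirna_min} shared miRNAs with only "
                f"{self.n_mirna} miRNAs"
            )
        if self.n_planted_pairs > min(self.n_lncrna, self.n_mrna):
            raise ValueError("more planted pairs than available transcripts")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-output-table substream of the master seed."""
        key = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for downstream scoring."""

    planted_pairs: frozenset[tuple[str, str, str]] = frozenset()
    de_transcripts: frozenset[str] = frozenset()
    panel_effect_mirnas: frozenset[str] = frozenset()


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}-{i:04d}" for i in range(1, n + 1)]


def lncrna_ids(config: SimulationConfig) -> list[str]:
    return _ids("lnc", config.n_lncrna)


def mrna_ids(config: SimulationConfig) -> list[str]:
    return _ids("gene", config.n_mrna)


def mirna_ids(config: SimulationConfig) -> list[str]:
    return _ids("mir", config.n_mirna)


def generate_interactions(
    config: SimulationConfig,
) -> tuple[InteractionTable, InteractionTable, GroundTruth]:
    """Draw the two bipartite target tables with planted sponge pairs.

    Planted pairs are disjoint in both lncRNAs and mRNAs; each receives
    ``shared_mirna_min`` common miRNAs wired into both tables and a state
    label (alternating between the two conditions). Background edges are
    independent Bernoulli(``background_density``) draws. DE transcripts are
    also selected here (a ``de_fraction`` subset of all transcripts) so the
    full ground truth is fixed by the interaction stream.
    """
    rng = config.rng("interactions")
    lncs, genes, mirs = lncrna_ids(config), mrna_ids(config), mirna_ids(config)

    planted_lncs = rng.choice(lncs, size=config.n_planted_pairs, replace=False)
    planted_genes = rng.choice(genes, size=config.n_planted_pairs, replace=False)

    lnc_edges: set[tuple[str, str]] = set()
    mrna_edges: set[tuple[str, str]] = set()
    planted: set[tuple[str, str, str]] = set()
    for i, (lnc, gene) in enumerate(zip(planted_lncs, planted_genes)):
        shared = rng.choice(mirs, size=config.shared_mirna_min, replace=False)
        state = STATES[i % 2]
        planted.add((str(lnc), str(gene), state))
        for mir in shared:
            lnc_edges.add((str(lnc), str(mir)))
            mrna_edges.add((str(gene), str(mir)))

    if config.background_density > 0:
        lnc_mask = rng.random((config.n_lncrna, config.n_mirna)) < config.background_density
        gene_mask = rng.random((config.n_mrna, config.n_mirna)) < config.background_density
        for i, j in zip(*np.nonzero(lnc_mask)):
            lnc_edges.add((lncs[i], mirs[j]))
        for i, j in zip(*np.nonzero(gene_mask)):
            mrna_edges.add((genes[i], mirs[j]))

    n_de = int(round(config.de_fraction * (config.n_lncrna + config.n_mrna)))
    de = rng.choice(np.array(lncs + genes), size=n_de, replace=False) if n_de else []

    truth = GroundTruth(
        planted_pairs=frozenset(planted),
        de_transcripts=frozenset(str(t) for t in de),
    )
    lnc_table = InteractionTable(side=LNCRNA, edges=frozenset(lnc_edges))
    mrna_table = InteractionTable(side=MRNA, edges=frozenset(mrna_edges))
    return lnc_table, mrna_table, truth


def generate_expression(config: SimulationConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Two-condition expression with planted within-state rank correlation.

    Non-planted transcripts are independent lognormal noise. For each
    planted pair, within its active state the mRNA copies the lncRNA latent
    per sample with probability ``rho_target`` (see module docstring). DE
    transcripts get a +``DE_SHIFT`` latent mean shift in the cytokines
    condition; a constant within-state shift never alters within-state ranks.
    """
    if config.n_samples_per_state < 4:
        raise ValueError(
            "need >= 4 samples per state for stable rank correlation, got "
            f"{config.n_samples_per_state}"
        )
    rng = config.rng("expression")
    n = config.n_samples_per_state
    samples = [f"ctrl_{i+1}" for i in range(n)] + [f"cyto_{i+1}" for i in range(n)]
    state_of = {s: (STATE_CONTROL if s.startswith("ctrl") else STATE_CYTOKINES) for s in samples}

    lncs, genes = lncrna_ids(config), mrna_ids(config)
    transcripts = lncs + genes
    latent = pd.DataFrame(
        rng.standard_normal((len(transcripts), 2 * n)), index=transcripts, columns=samples
    )

    state_cols = {st: [s for s in samples if state_of[s] == st] for st in STATES}
    for lnc, gene, state in sorted(truth.planted_pairs):
        cols = state_cols[state]
        z = rng.standard_normal(n)
        copy = rng.random(n) < config.rho_target
        noise = rng.standard_normal(n)
        latent.loc[lnc, cols] = z
        latent.loc[gene, cols] = np.where(copy, z, noise)

    for t in sorted(truth.de_transcripts):
        latent.loc[t, state_cols[STATE_CYTOKINES]] += DE_SHIFT

    kinds = {t: LNCRNA for t in lncs}
    kinds.update({t: MRNA for t in genes})
    return ExpressionMatrix(
        values=np.exp(latent),
        state_of=state_of,
        transcript_kind=kinds,
        de_flag={t: (t in truth.de_transcripts) for t in transcripts},
    )


def generate_mirna_panel(
    config: SimulationConfig,
    effect_direction: Mapping[str, float] | None = None,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Labeled miRNA panel for biomarker fitting and validation.

    Two balanced groups of ``n_samples_per_state`` samples (labels 0/1).
    Effect miRNAs differ between groups by ``effect_size`` on the latent
    (log) scale, in the direction given by ``effect_direction`` (a map
    miRNA -> sign/scale multiplier). By default a ``de_fraction`` subset of
    the generator's own miRNA ids gets a positive shift; passing an explicit
    map reproduces e.g. a coefficient-sign-consistent panel where negative-
    coefficient miRNAs are lower in cases. Non-effect miRNAs are
    exchangeable between groups.
    """
    rng = config.rng("panel")
    n = config.n_samples_per_state
    samples = [f"s{i+1:03d}" for i in range(2 * n)]
    labels = pd.Series([0] * n + [1] * n, index=samples, name="label")

    if effect_direction is None:
        mirs = mirna_ids(config)
        n_eff = max(1, int(round(config.de_fraction * config.n_mirna)))
        chosen = rng.choice(mirs, size=n_eff, replace=False)
        effect_direction = {str(m): 1.0 for m in chosen}
        features = mirs
    else:
        features = list(effect_direction)

    latent = pd.DataFrame(
        rng.standard_normal((len(features), 2 * n)), index=list(features), columns=samples
    )
    case_cols = [s for s in samples if labels[s] == 1]
    for mir, direction in effect_direction.items():
        if direction != 0.0:
            latent.loc[mir, case_cols] += direction * config.effect_size

    kinds = {m: MIRNA for m in features}
    expr = ExpressionMatrix(
        values=np.exp(latent),
        state_of={s: ("case" if labels[s] else "ctrl") for s in samples},
        transcript_kind=kinds,
    )
    truth = GroundTruth(
        panel_effect_mirnas=frozenset(m for m, d in effect_direction.items() if d != 0.0)
    )
    return expr, labels, truth
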