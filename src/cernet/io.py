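"""TSV/JSON readers and writers plus the end-to-end pipeline driver.

All tabular artifacts are tab-separated text (Cytoscape-importable edge
lists included); ids are case-sensitive and never altered. Every domain
type that is serialized round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarker as bm
from . import compare as cmp
from . import enrichment as enr
from . import inference as inf
from .containers import (
    LNCRNA,
    MRNA,
    CandidatePair,
    CeRNANetwork,
    ExpressionMatrix,
    InteractionTable,
    NetworkEdge,
)
from .simulate import GroundTruth

log = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "lncrna", "mirna", "mrna", "gene", "target", "regulator",
    "regulator_id", "mirna_id", "lncrna_id", "mrna_id", "gene_id",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


# ---------------------------------------------------------------- interactions

def read_interaction_table(path, side: str) -> InteractionTable:
    """2+ column TSV of (regulator_id, mirna_id); header auto-detected."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{ln}: expected 'regulator<TAB>mirna'")
            if ln == 1 and {fields[0].strip().lower(), fields[1].strip().lower()} & _HEADER_TOKENS:
                continue
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ValueError(f"{path}: empty interaction table")
    n_dup = len(pairs) - len(set(pairs))
    if n_dup:
        log.info("%s: dropped %d duplicate edge(s)", path, n_dup)
    log.info("%s: %d rows, %d unique edges", path, len(pairs), len(set(pairs)))
    return InteractionTable(side=side, edges=frozenset(pairs))


def write_interaction_table(table: InteractionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator_id\tmirna_id\n")
        for reg, mir in sorted(table.edges):
            fh.write(f"{reg}\t{mir}\n")


# ----------------------------------------------------------------- expression

def read_expression(path, state_map_path, annotations_path=None) -> ExpressionMatrix:
    """Expression TSV (first column transcript id, header = sample ids),
    a 2-column sample→state map, and optional per-transcript annotations
    (transcript_id, kind, de_flag)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate transcript ids {dups}")
    state_map = _read_two_column_map(state_map_path)
    missing = [s for s in values.columns if s not in state_map]
    if missing:
        raise ValueError(f"{state_map_path}: samples missing a state: {missing}")
    kinds: dict[str, str] = {}
    de: dict[str, bool] = {}
    if annotations_path is not None:
        annot = pd.read_csv(annotations_path, sep="\t", dtype=str)
        for _, row in annot.iterrows():
            kinds[row["transcript_id"]] = row["kind"]
            de[row["transcript_id"]] = row["de_flag"].lower() in ("1", "true")
    return ExpressionMatrix(
        values=values.astype(float),
        state_of={s: state_map[s] for s in values.columns},
        transcript_kind=kinds,
        de_flag=de,
    )


def write_expression(expr: ExpressionMatrix, path, state_map_path, annotations_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="transcript_id")
    with open(state_map_path, "w") as fh:
        fh.write("sample_id\tstate\n")
        for s in expr.samples:
            fh.write(f"{s}\t{expr.state_of[s]}\n")
    if annotations_path is not None:
        with open(annotations_path, "w") as fh:
            fh.write("transcript_id\tkind\tde_flag\n")
            for t in expr.transcripts:
                kind = expr.transcript_kind.get(t, "")
                flag = str(expr.de_flag.get(t, False)).lower()
                fh.write(f"{t}\t{kind}\t{flag}\n")


def _read_two_column_map(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
            if ln == 1 and fields[0].strip().lower() in ("sample_id", "sample"):
                continue
            out[fields[0].strip()] = fields[1].strip()
    return out


def read_labels(path) -> pd.Series:
    """2-column TSV sample_id → 0/1 label."""
    raw = _read_two_column_map(path)
    return pd.Series({k: int(v) for k, v in raw.items()}, name="label")


def write_labels(labels: pd.Series, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s, v in labels.items():
            fh.write(f"{s}\t{int(v)}\n")


# ------------------------------------------------------------ candidates/nets

def write_candidates(cands: list[CandidatePair], path) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna\tmrna\tshared_count\tshared_mirnas\tp_shared\n")
        for c in cands:
            fh.write(
                f"{c.lncrna}\t{c.mrna}\t{c.shared_count}\t"
                f"{';'.join(sorted(c.shared_mirnas))}\t{c.p_shared!r}\n"
            )


def read_candidates(path) -> list[CandidatePair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        shared = frozenset(r["shared_mirnas"].split(";")) if r["shared_mirnas"] else frozenset()
        out.append(
            CandidatePair(
                lncrna=r["lncrna"],
                mrna=r["mrna"],
                shared_mirnas=shared,
                shared_count=int(r["shared_count"]),
                p_shared=float(r["p_shared"]),
            )
        )
    return out


def write_network(net: CeRNANetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna\tmrna\trho\tshared_count\tshared_mirnas\tstate\n")
        for (l, m), e in sorted(net.edges.items()):
            fh.write(
                f"{l}\t{m}\t{e.rho!r}\t{e.shared_count}\t"
                f"{';'.join(sorted(e.shared_mirnas))}\t{net.state}\n"
            )


def read_network(path) -> CeRNANetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty network file (state unknown)")
    states = df["state"].unique().tolist()
    if len(states) != 1:
        raise ValueError(f"{path}: expected one state, found {states}")
    edges: dict[tuple[str, str], NetworkEdge] = {}
    for _, r in df.iterrows():
        shared = frozenset(r["shared_mirnas"].split(";")) if isinstance(r["shared_mirnas"], str) and r["shared_mirnas"] else frozenset()
        edges[(r["lncrna"], r["mrna"])] = NetworkEdge(
            lncrna=r["lncrna"],
            mrna=r["mrna"],
            rho=float(r["rho"]),
            shared_count=int(r["shared_count"]),
            shared_mirnas=shared,
        )
    return CeRNANetwork(state=states[0], edges=edges)


def write_degree_table(rows: list[tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tdegree\n")
        for node, deg in rows:
            fh.write(f"{node}\t{deg}\n")


# ------------------------------------------------------- comparison/enrichment

def write_sharing_summary(summary: cmp.SharingSummary, json_path, tsv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2)
        fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("entity\tcount_a\tcount_b\tcount_shared\tjaccard\tpercent_shared\n")
            for name, row in summary.as_dict().items():
                fh.write(
                    f"{name}\t{row['count_a']}\t{row['count_b']}\t{row['count_shared']}\t"
                    f"{row['jaccard']}\t{row['percent_shared']}\n"
                )


def write_neighborhood(diff: cmp.NeighborhoodDiff, path) -> None:
    with open(path, "w") as fh:
        fh.write("mrna\tmembership\n")
        for m in sorted(diff.targets_a_only):
            fh.write(f"{m}\tA-only\n")
        for m in sorted(diff.targets_b_only):
            fh.write(f"{m}\tB-only\n")
        for m in sorted(diff.targets_both):
            fh.write(f"{m}\tboth\n")


def write_enrichment(results: list[enr.EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pathway_id\tpathway_name\toverlap_count\tquery_size\tset_size\t"
            "universe_size\tp_value\tq_value\n"
        )
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.pathway_name}\t{r.overlap_count}\t{r.query_size}\t"
                f"{r.set_size}\t{r.universe_size}\t{r.p_value!r}\t{r.q_value!r}\n"
            )


def write_crosstalk(net: enr.CrosstalkNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_a\tpathway_b\tn_shared_genes\thighlight\n")
        for e in net.edges:
            fh.write(f"{e.pathway_a}\t{e.pathway_b}\t{e.n_shared_genes}\t{str(e.highlight).lower()}\n")


def write_scores(scores: pd.Series, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trisk_score\n")
        for s, v in scores.items():
            fh.write(f"{s}\t{v!r}\n")


def write_roc(roc: bm.ROCResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in roc.curve:
            fh.write(f"{fpr!r},{tpr!r}\n")


# ---------------------------------------------------------------- ground truth

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_pairs": sorted(list(p) for p in truth.planted_pairs),
        "de_transcripts": sorted(truth.de_transcripts),
        "panel_effect_mirnas": sorted(truth.panel_effect_mirnas),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        planted_pairs=frozenset(tuple(p) for p in payload["planted_pairs"]),
        de_transcripts=frozenset(payload["de_transcripts"]),
        panel_effect_mirnas=frozenset(payload["panel_effect_mirnas"]),
    )


# -------------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    """Paths and thresholds for an end-to-end run."""

    lnc_interactions: str
    mrna_interactions: str
    expression: str
    state_map: str
    outdir: str
    annotations: str | None = None
    gmt: str | None = None
    panel: str | None = None
    panel_state_map: str | None = None
    panel_labels: str | None = None
    coefficients: str | None = None
    min_shared: int = inf.DEFAULT_MIN_SHARED
    rho_min: float = inf.DEFAULT_RHO_MIN
    q_max: float = enr.DEFAULT_Q_MAX
    crosstalk_highlight: int = enr.DEFAULT_HIGHLIGHT_MIN_SHARED
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")
        if not (-1.0 <= self.rho_min <= 1.0):
            raise ValueError("rho_min must be in [-1, 1]")
        if not (0.0 < self.q_max <= 1.0):
            raise ValueError("q_max must be in (0, 1]")
        if self.crosstalk_highlight < 0:
            raise ValueError("crosstalk_highlight must be >= 0")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


def run_pipeline(config: PipelineConfig) -> dict:
    """Candidate pairing → per-state networks → comparison → enrichment and
    crosstalk → biomarker evaluation; writes all artifacts under
    ``config.outdir`` plus a JSON ``report.json`` of the headline counts.
    Deterministic given identical inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config)}

    lnc_table, mrna_table, expr = _load_inputs(config)

    cands = _run_candidates(config, lnc_table, mrna_table, outdir, report)
    nets = _run_networks(config, cands, expr, outdir, report)
    if len(nets) >= 2:
        _run_comparison(nets, expr, outdir, report)
    if config.gmt is not None:
        _run_enrichment(config, nets, mrna_table, outdir, report)
    if config.panel is not None and config.panel_labels is not None:
        _run_biomarker(config, outdir, report)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


@_stage("load-inputs")
def _load_inputs(config: PipelineConfig):
    lnc_table = read_interaction_table(config.lnc_interactions, side=LNCRNA)
    mrna_table = read_interaction_table(config.mrna_interactions, side=MRNA)
    expr = read_expression(config.expression, config.state_map, config.annotations)
    return lnc_table, mrna_table, expr


@_stage("candidate-pairs")
def _run_candidates(config, lnc_table, mrna_table, outdir, report):
    cands = inf.candidate_pairs(lnc_table, mrna_table, min_shared=config.min_shared)
    write_candidates(cands, outdir / "candidates.tsv")
    report["candidates"] = {"count": len(cands)}
    return cands


@_stage("state-networks")
def _run_networks(config, cands, expr, outdir, report):
    nets: dict[str, CeRNANetwork] = {}
    report["networks"] = {}
    for state in expr.states:
        net = inf.build_state_network(cands, expr, state, rho_min=config.rho_min)
        nets[state] = net
        write_network(net, outdir / f"network_{state}.tsv")
        for side, tag in ((LNCRNA, "lncrna"), (MRNA, "mrna")):
            write_degree_table(
                inf.degree_table(net, side), outdir / f"degree_{tag}_{state}.tsv"
            )
        report["networks"][state] = {
            "n_edges": net.n_edges(),
            "n_lncrnas": len(net.lncrnas),
            "n_mrnas": len(net.mrnas),
        }
    return nets


@_stage("network-comparison")
def _run_comparison(nets, expr, outdir, report):
    (state_a, net_a), (state_b, net_b) = list(nets.items())[:2]
    summary = cmp.compare_networks(net_a, net_b)
    write_sharing_summary(summary, outdir / "sharing.json", outdir / "sharing.tsv")
    shared = cmp.shared_subnetwork(net_a, net_b)
    with open(outdir / "shared_subnetwork.tsv", "w") as fh:
        fh.write("lncrna\tmrna\trho_a\trho_b\n")
        for l, m, ra, rb in shared:
            fh.write(f"{l}\t{m}\t{ra!r}\t{rb!r}\n")
    de = {}
    for state, net in ((state_a, net_a), (state_b, net_b)):
        de[state] = {
            "lncrna": _nan_to_none(cmp.de_fraction(net, expr, LNCRNA)),
            "mrna": _nan_to_none(cmp.de_fraction(net, expr, MRNA)),
        }
    report["comparison"] = {
        "states": [state_a, state_b],
        "sharing": summary.as_dict(),
        "n_shared_edges": len(shared),
        "de_fractions": de,
    }


@_stage("enrichment")
def _run_enrichment(config, nets, mrna_table, outdir, report):
    collection = enr.read_gmt(config.gmt)
    universe = frozenset(mrna_table.regulators)
    results: dict[str, list[enr.EnrichmentResult]] = {}
    for state, net in nets.items():
        if not net.mrnas:
            log.warning("state %s: empty mRNA set, skipping enrichment", state)
            continue
        res = enr.hypergeometric_enrichment(net.mrnas, collection, universe)
        results[state] = res
        write_enrichment(res, outdir / f"enrichment_{state}.tsv")
    report["enrichment"] = {
        state: {"n_significant": sum(1 for r in res if r.q_value <= config.q_max)}
        for state, res in results.items()
    }
    if len(results) >= 2:
        (sa, ra), (sb, rb) = list(results.items())[:2]
        labels = enr.compare_state_functions(ra, rb, q_max=config.q_max, label_a=sa, label_b=sb)
        crosstalk = enr.crosstalk_network(
            labels, collection, highlight_min_shared=config.crosstalk_highlight
        )
        write_crosstalk(crosstalk, outdir / "crosstalk.tsv")
        report["crosstalk"] = {
            "n_pathways": len(labels),
            "n_edges": len(crosstalk.edges),
            "n_highlighted": sum(1 for e in crosstalk.edges if e.highlight),
        }


@_stage("biomarker")
def _run_biomarker(config, outdir, report):
    panel = read_expression(config.panel, config.panel_state_map or config.state_map)
    labels = read_labels(config.panel_labels)
    labels = labels.reindex(panel.samples)
    if labels.isna().any():
        raise ValueError("panel samples missing from the label file")
    if config.coefficients is not None:
        model = bm.load_coefficients(config.coefficients)
    else:
        model = bm.fit_risk_model(panel, labels.to_numpy())
    write_coefficients_path = outdir / "risk_coefficients.tsv"
    bm.write_coefficients(model, write_coefficients_path)
    roc, used = bm.evaluate_on_validation(model, panel, labels.to_numpy())
    scores, _ = bm.score_panel(model, panel)
    write_scores(scores, outdir / "risk_scores.tsv")
    write_roc(roc, outdir / "roc_points.csv")
    report["biomarker"] = {
        "provenance": model.provenance,
        "n_model_features": len(model.coefficients),
        "n_used_features": len(used),
        "auc": roc.auc,
    }


def _nan_to_none(x: float):
    return None if isinstance(x, float) and np.isnan(x) else x
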