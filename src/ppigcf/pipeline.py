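"""End-to-end orchestration of the four filter layers.

The flow per group is: GO grouping -> interaction network (RD1) ->
correlation filter (RD2) -> information-content selection (FRD); the
per-group FRD sets are merged into the final reduced matrix. Each layer is
also exposed as a standalone stage over a serialisable state dict, so the
CLI stage subcommands compose to exactly the same result as a monolithic
run. The filter itself has no stochastic step: the configured seed only
matters for simulation and cross-validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import ExpressionMatrix, GOAnnotationSet, StageResult
from .corr_filter import run_correlation_stage
from .errors import StageInputMissingError
from .grouping import build_groups
from .infocontent import (
    DEFAULT_GOA_TABLE,
    build_ic_table,
    ic_threshold,
    load_goa_table,
    select_significant,
)
from .io import write_stage_outputs
from .network import build_network, eliminate_isolated, weight_matrix

log = logging.getLogger(__name__)


@dataclass
class PipelineState:
    """Serialisable intermediate state passed between stages."""

    groups: dict[str, list[str]] = field(default_factory=dict)
    eliminated: dict[str, str] = field(default_factory=dict)
    rd1: dict[str, list[str]] = field(default_factory=dict)
    rd2: dict[str, list[str]] = field(default_factory=dict)
    rd2_edges: dict[str, list[list[str]]] = field(default_factory=dict)
    frd: dict[str, list[str]] = field(default_factory=dict)
    ic_scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {
            "groups": self.groups,
            "eliminated": self.eliminated,
            "rd1": self.rd1,
            "rd2": self.rd2,
            "rd2_edges": self.rd2_edges,
            "frd": self.frd,
            "ic_scores": self.ic_scores,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "PipelineState":
        path = Path(path)
        if not path.exists():
            raise StageInputMissingError(f"state file {path} not found")
        with open(path) as fh:
            return cls(**json.load(fh))


def stage_group(
    em: ExpressionMatrix, annos: GOAnnotationSet, cfg: PipelineConfig,
    state: PipelineState,
) -> PipelineState:
    groups, eliminated = build_groups(em, annos, cfg.target_terms)
    state.groups = {
        g.group_term: list(g.members) for g in groups
    }
    state.eliminated = dict(eliminated)
    return state


def stage_ppi(
    em: ExpressionMatrix, annos: GOAnnotationSet, cfg: PipelineConfig,
    state: PipelineState,
) -> PipelineState:
    if not state.groups:
        raise StageInputMissingError("grouping stage has not run")
    from .grouping import GOGroup, compute_term_ic, group_similarity

    if not annos.term_ic:
        annos.term_ic = compute_term_ic(annos)
    for term, members in state.groups.items():
        if len(members) < cfg.group_min_size:
            # too small to form any edge; everything is isolated
            for g in members:
                state.eliminated[g] = "ISOLATED"
            state.rd1[term] = []
            continue
        grp = GOGroup(group_term=term, members=list(members))
        sim = group_similarity(grp, annos)
        W = weight_matrix(em.subset(members), sim)
        net = build_network(W, cfg.tau_ppi, term, list(members))
        res = eliminate_isolated(net)
        state.rd1[term] = sorted(res.kept)
        state.eliminated.update(res.eliminated)
    return state


def stage_corr(
    em: ExpressionMatrix, cfg: PipelineConfig, state: PipelineState
) -> PipelineState:
    if not state.rd1:
        raise StageInputMissingError("network stage has not run")
    for term, kept in state.rd1.items():
        if not kept:
            state.rd2[term] = []
            state.rd2_edges[term] = []
            continue
        res, _tables, surv = run_correlation_stage(
            em.subset(kept),
            policy=cfg.negative_pcc_policy,
            theta_R=cfg.theta_R,
            theta_L=cfg.theta_L,
            theta_S=cfg.theta_S,
            sem_offset=cfg.sem_offset,
        )
        state.rd2[term] = sorted(res.kept)
        state.eliminated.update(res.eliminated)
        edges: list[list[str]] = []
        if surv is not None:
            genes = _tables.genes
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    if surv[i, j] and genes[i] in res.kept \
                            and genes[j] in res.kept:
                        edges.append(sorted([genes[i], genes[j]]))
        state.rd2_edges[term] = sorted(edges)
    return state


def stage_ic(
    annos: GOAnnotationSet, cfg: PipelineConfig, state: PipelineState
) -> PipelineState:
    if not state.rd2:
        raise StageInputMissingError("correlation stage has not run")
    goa = (
        load_goa_table(cfg.goa_table)
        if cfg.goa_table
        else DEFAULT_GOA_TABLE
    )
    delta = ic_threshold(goa) if cfg.delta == "auto" else float(cfg.delta)
    for term, kept in state.rd2.items():
        if not kept:
            state.frd[term] = []
            continue
        graph = nx.Graph()
        graph.add_nodes_from(kept)
        graph.add_edges_from(state.rd2_edges.get(term, []))
        ic_table = build_ic_table(
            kept, graph, annos, lambda_=cfg.lambda_, delta=delta,
            goa_table=goa, score_mode=cfg.score_mode,
        )
        res = select_significant(ic_table)
        state.frd[term] = sorted(res.kept)
        state.eliminated.update(res.eliminated)
        state.ic_scores[term] = {
            g: float(ic_table.table.loc[g, "score"]) for g in kept
        }
    return state


@dataclass
class PipelineResult:
    reduced: ExpressionMatrix
    state: PipelineState
    report: dict


def _stage_counts(state: PipelineState) -> dict:
    per_group = {}
    for term, members in state.groups.items():
        per_group[term] = {
            "grouped": len(members),
            "rd1": len(state.rd1.get(term, [])),
            "rd2": len(state.rd2.get(term, [])),
            "frd": len(state.frd.get(term, [])),
        }
    return per_group


def run(
    em: ExpressionMatrix,
    annos: GOAnnotationSet,
    cfg: PipelineConfig | None = None,
    outdir=None,
) -> PipelineResult:
    """Execute all four stages and merge the per-group FRD sets.

    When ``outdir`` is given the per-stage gene tables, reduced matrices and
    the JSON run report are written there. Completes (with a warning) even
    when the final set is empty.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    em.validate()
    state = PipelineState()
    state = stage_group(em, annos, cfg, state)
    state = stage_ppi(em, annos, cfg, state)
    state = stage_corr(em, cfg, state)
    state = stage_ic(annos, cfg, state)

    frd_genes = sorted(set().union(*state.frd.values())) if state.frd else []
    kept_order = [g for g in em.genes if g in set(frd_genes)]
    reduced = em.subset(kept_order)
    if not kept_order:
        log.warning("final reduced gene set is empty")

    histogram: dict[str, int] = {}
    for reason in state.eliminated.values():
        histogram[reason] = histogram.get(reason, 0) + 1
    report = {
        "software": {"name": "ppigcf", "version": __version__},
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_input_genes": em.n_genes,
        "n_samples": em.n_samples,
        "per_group": _stage_counts(state),
        "overall": {
            "grouped": sum(len(m) for m in state.groups.values()),
            "rd1": sum(len(m) for m in state.rd1.values()),
            "rd2": sum(len(m) for m in state.rd2.values()),
            "frd": len(kept_order),
        },
        "eliminated_by_reason": histogram,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for stage_name, kept_map in (
            ("RD1", state.rd1), ("RD2", state.rd2), ("FRD", state.frd)
        ):
            kept = set().union(*kept_map.values()) if kept_map else set()
            universe = set().union(*state.groups.values()) | set(
                state.eliminated
            )
            res = StageResult(
                stage=stage_name,
                kept=kept,
                eliminated={
                    g: r for g, r in state.eliminated.items()
                    if g not in kept
                },
            )
            # stage results are cumulative over the full input gene set
            assert res.input_genes == universe
            write_stage_outputs(res, em, outdir)
        state.save(outdir / "state.json")
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return PipelineResult(reduced=reduced, state=state, report=report)
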