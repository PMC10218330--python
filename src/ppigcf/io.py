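"""Readers and writers for every external format the pipeline touches.

Expression matrices are genes-in-rows TSV/CSV; labels a two-column TSV;
annotations GAF 2.x or a three-column TSV; the term hierarchy a three-column
TSV edge list. All reports are UTF-8 JSON with sorted keys.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GOAnnotationSet, StageResult
from .errors import (
    BadAspectError,
    BadGoIdError,
    CycleDetectedError,
    DuplicateGeneError,
    IOFailureError,
    MalformedTableError,
    MissingRootError,
    NonNumericCellError,
    NotTwoClassesError,
)

log = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")
ASPECT_MAP = {"P": "BP", "C": "CC", "F": "MF", "BP": "BP", "CC": "CC", "MF": "MF"}

#: decimal text round-trips float64 exactly at 17 significant digits
FLOAT_FMT = "%.17g"


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    return "csv" if path.suffix.lower() == ".csv" else "tsv"


def read_expression(
    path, dialect: str | None = None, impute: str | None = None
) -> ExpressionMatrix:
    """Load a genes-in-rows expression table.

    First column holds gene symbols, the header row sample IDs. Missing
    values are rejected unless ``impute='median'`` (per-gene median fill).
    """
    path = Path(path)
    sep = "\t" if _dialect_for(path, dialect) == "tsv" else ","
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise MalformedTableError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MalformedTableError(
                f"{path}: line {i} has {len(row)} fields, expected {width}"
            )
    genes = [row[0] for row in rows[1:]]
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise DuplicateGeneError(f"{path}: gene {g!r} appears twice")
        seen.add(g)
    samples = header[1:]
    data = np.empty((len(genes), len(samples)))
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            if cell in ("", "NA", "NaN", "nan"):
                data[i, j] = np.nan
                continue
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise NonNumericCellError(
                    f"{path}: non-numeric cell {cell!r} at gene "
                    f"{genes[i]!r}, sample {samples[j]!r}"
                ) from None
    values = pd.DataFrame(data, index=genes, columns=samples)
    if values.isna().to_numpy().any():
        if impute == "median":
            values = values.apply(lambda r: r.fillna(r.median()), axis=1)
            log.info("imputed missing values with per-gene medians")
        else:
            raise NonNumericCellError(f"{path}: missing values present")
    if not np.isfinite(values.to_numpy()).all():
        raise NonNumericCellError(f"{path}: non-finite values present")
    em = ExpressionMatrix(values)
    em.validate()
    return em


def read_labels(path) -> pd.Series:
    """Load a two-column (sample ID, label) TSV with exactly two classes."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r]
    pairs = []
    for i, row in enumerate(rows, start=1):
        if i == 1 and [c.lower() for c in row[:2]] == ["sample", "label"]:
            continue
        if len(row) != 2:
            raise MalformedTableError(f"{path}: line {i} is not two columns")
        pairs.append(row)
    labels = pd.Series(
        {s: lab for s, lab in pairs}, name="label", dtype="object"
    )
    if labels.nunique() != 2:
        raise NotTwoClassesError(
            f"{path}: found {labels.nunique()} distinct labels, expected 2"
        )
    return labels


def read_annotations(path, format: str | None = None) -> GOAnnotationSet:
    """Load gene -> GO-term annotations from GAF 2.x or a 3-column TSV.

    GAF columns used: 2 (symbol), 5 (GO ID), 9 (aspect); comment lines start
    with ``!``. Duplicate (gene, term) pairs collapse to one entry.
    """
    path = Path(path)
    if format is None:
        format = "gaf" if path.suffix.lower() == ".gaf" else "tsv"
    annos = GOAnnotationSet()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if format == "gaf":
                if len(fields) < 9:
                    raise MalformedTableError(
                        f"{path}: GAF line {i} has {len(fields)} columns"
                    )
                gene, go_id, aspect = fields[1], fields[4], fields[8]
            else:
                if i == 1 and fields[0].lower() in ("gene", "symbol"):
                    continue
                if len(fields) != 3:
                    raise MalformedTableError(
                        f"{path}: line {i} is not three columns"
                    )
                gene, go_id, aspect = fields
            if not GO_ID_RE.match(go_id):
                raise BadGoIdError(f"{path}: line {i}: bad GO ID {go_id!r}")
            if aspect not in ASPECT_MAP:
                raise BadAspectError(f"{path}: line {i}: aspect {aspect!r}")
            annos.annotations.setdefault(gene, set()).add(go_id)
            annos.aspects[(gene, go_id)] = ASPECT_MAP[aspect]
    return annos


def read_ontology(path) -> GOAnnotationSet:
    """Load the term hierarchy from a (term, parent, namespace) edge list.

    Roots have an empty parent field. Depth is the shortest-path distance to
    the namespace root; ``n_descendants`` counts distinct terms reachable
    downward, excluding the term itself.
    """
    path = Path(path)
    hier = nx.DiGraph()  # edges child -> parent
    namespace: dict[str, str] = {}
    roots: dict[str, str] = {}  # namespace -> root term
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if i == 1 and row[0].lower() == "term":
                continue
            if len(row) != 3:
                raise MalformedTableError(f"{path}: line {i} is not 3 columns")
            term, parent, ns = row
            if not GO_ID_RE.match(term):
                raise BadGoIdError(f"{path}: line {i}: bad GO ID {term!r}")
            hier.add_node(term)
            namespace[term] = ns
            if parent == "":
                roots[ns] = term
            else:
                if not GO_ID_RE.match(parent):
                    raise BadGoIdError(
                        f"{path}: line {i}: bad GO ID {parent!r}"
                    )
                hier.add_edge(term, parent)
                namespace.setdefault(parent, ns)
    if not nx.is_directed_acyclic_graph(hier):
        cycle = nx.find_cycle(hier)
        raise CycleDetectedError(f"{path}: hierarchy cycle {cycle}")
    depth: dict[str, int] = {}
    for ns in sorted({namespace[t] for t in hier.nodes}):
        root = roots.get(ns)
        if root is None:
            raise MissingRootError(f"{path}: namespace {ns!r} has no root")
        # rootward edges: depth(t) = shortest child->parent path to the root
        lengths = nx.shortest_path_length(hier.reverse(copy=False), root)
        for t, d in lengths.items():
            if namespace[t] == ns:
                depth[t] = d
    undepthed = set(hier.nodes) - set(depth)
    if undepthed:
        raise MissingRootError(
            f"{path}: {len(undepthed)} term(s) unreachable from their root"
        )
    n_desc = {t: len(nx.ancestors(hier, t)) for t in hier.nodes}
    return GOAnnotationSet(
        hierarchy=hier, namespace=namespace, depth=depth, n_descendants=n_desc
    )


def load_annotation_set(annotations_path, ontology_path) -> GOAnnotationSet:
    """Read annotations and hierarchy and merge them into one set.

    Annotated terms absent from the hierarchy are flagged as orphans (kept in
    the annotations, reported, never used for depth-based scores).
    """
    onto = read_ontology(ontology_path)
    annos = read_annotations(annotations_path)
    merged = onto.merge_annotations(annos)
    if merged.orphans:
        log.warning("%d annotated term(s) missing from the hierarchy",
                    len(merged.orphans))
    return merged


def write_expression(em: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(["gene"] + em.samples)
        for g, row in zip(em.genes, em.values.to_numpy()):
            w.writerow([g] + [FLOAT_FMT % v for v in row])


def write_labels(labels: pd.Series, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "label"])
        for s, lab in labels.items():
            w.writerow([s, lab])


def write_stage_outputs(
    result: StageResult, matrix: ExpressionMatrix, outdir
) -> dict:
    """Write the reduced matrix, the per-gene decision table and a JSON report.

    Returns the report dict (also written to ``<stage>_report.json``).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        missing = result.kept - set(matrix.genes)
        if missing:
            raise IOFailureError(f"kept genes absent from matrix: {missing}")
        stage = result.stage.lower()
        kept_order = [g for g in matrix.genes if g in result.kept]
        write_expression(matrix.subset(kept_order),
                         outdir / f"{stage}_expression.tsv")
        with open(outdir / f"{stage}_genes.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            score_cols = (list(result.scores.columns)
                          if result.scores is not None else [])
            w.writerow(["gene", "status", "reason"] + score_cols)
            for g in sorted(result.input_genes):
                status = "kept" if g in result.kept else "eliminated"
                reason = result.eliminated.get(g, "")
                scores = []
                if result.scores is not None and g in result.scores.index:
                    scores = [
                        "" if pd.isna(v) else FLOAT_FMT % v
                        for v in result.scores.loc[g]
                    ]
                elif score_cols:
                    scores = [""] * len(score_cols)
                w.writerow([g, status, reason] + scores)
        reasons: dict[str, int] = {}
        for reason in result.eliminated.values():
            reasons[reason] = reasons.get(reason, 0) + 1
        report = {
            "stage": result.stage,
            "n_input": len(result.input_genes),
            "n_kept": len(result.kept),
            "n_eliminated": len(result.eliminated),
            "eliminated_by_reason": reasons,
        }
        with open(outdir / f"{stage}_report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
            fh.write("\n")
        return report
    except OSError as exc:
        raise IOFailureError(str(exc)) from exc
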