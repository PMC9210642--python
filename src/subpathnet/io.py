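"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and annotations travel as TSV, interaction networks as
SIF-like 3-column TSV (and GraphML via networkx), gene sets as GMT, survival
tables as CSV, models and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .netprop import InteractionNetwork
from .prognosis import LassoModel, SurvivalCohort
from .subpathway import Subpathway, SubpathwayCollection
from .synthetic_data import GeneExpressionStudy

__all__ = [
    "write_expression", "read_expression",
    "write_annotations", "read_annotations",
    "write_study", "read_study",
    "write_network_sif", "read_network_sif", "write_graphml",
    "parse_gmt", "format_gmt", "write_gmt", "read_gmt",
    "collection_to_gmt", "collection_from_gmt",
    "write_survival", "read_survival",
    "write_model", "read_model",
]


def write_expression(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample")


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_study(study: GeneExpressionStudy, directory, stem: str | None = None) -> tuple[Path, Path]:
    """Write a study as <stem>.expr.tsv + <stem>.annotations.tsv; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or study.dataset_id
    expr_path = directory / f"{stem}.expr.tsv"
    ann_path = directory / f"{stem}.annotations.tsv"
    write_expression(study.values, expr_path)
    ann = study.sample_annotations.copy()
    ann["scale_tag"] = study.scale_tag
    write_annotations(ann, ann_path)
    return expr_path, ann_path


def read_study(expr_path, ann_path, dataset_id: str | None = None) -> GeneExpressionStudy:
    values = read_expression(expr_path)
    ann = read_annotations(ann_path)
    scale = "count"
    if "scale_tag" in ann.columns:
        tags = set(ann["scale_tag"])
        if len(tags) != 1:
            raise InvalidArgumentError(f"inconsistent scale tags {tags}")
        scale = tags.pop()
        ann = ann.drop(columns=["scale_tag"])
    if dataset_id is None:
        dataset_id = str(ann["batch"].iloc[0]) if "batch" in ann.columns else Path(expr_path).stem
    return GeneExpressionStudy(dataset_id=dataset_id, values=values,
                               scale_tag=scale, sample_annotations=ann)


def write_network_sif(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tevidence_count\n")
        for a, b, count in network.edge_triples():
            fh.write(f"{a}\t{b}\t{count}\n")


def read_network_sif(path) -> InteractionNetwork:
    frame = pd.read_csv(path, sep="\t")
    triples = list(frame.itertuples(index=False, name=None))
    return InteractionNetwork.from_edges(triples)


def write_graphml(graph_or_network, path) -> None:
    if isinstance(graph_or_network, nx.Graph):
        graph = graph_or_network
    else:
        graph = getattr(graph_or_network, "graph", graph_or_network)
    if any(not isinstance(n, str) for n in graph.nodes):
        graph = nx.relabel_nodes(graph, {n: "|".join(map(str, n)) if isinstance(n, tuple) else str(n)
                                         for n in graph.nodes})
    nx.write_graphml(graph, path)


# --- GMT -------------------------------------------------------------------


def parse_gmt(text: str) -> dict[str, tuple[str, list[str]]]:
    """GMT text -> {set id: (description, member list)}."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InvalidArgumentError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = (parts[1], [p for p in parts[2:] if p])
    return sets


def format_gmt(sets: Mapping[str, tuple[str, Iterable[str]]]) -> str:
    lines = []
    for set_id, (description, members) in sets.items():
        lines.append("\t".join([set_id, description, *sorted(members)]))
    return "\n".join(lines) + "\n"


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    Path(path).write_text(format_gmt(sets))


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    return parse_gmt(Path(path).read_text())


def collection_to_gmt(collection: SubpathwayCollection, path) -> None:
    """Subpathways as GMT; parent pathway and class ride in the description."""
    sets = {
        e.subpathway_id: (f"parent={e.parent_pathway_id};class={e.class_label}", e.members)
        for e in collection
    }
    write_gmt(sets, path)


def collection_from_gmt(path) -> SubpathwayCollection:
    entries = []
    for set_id, (description, members) in read_gmt(path).items():
        parent, class_label = set_id, "unknown"
        for token in description.split(";"):
            if token.startswith("parent="):
                parent = token[len("parent="):]
            elif token.startswith("class="):
                class_label = token[len("class="):]
        entries.append(Subpathway(subpathway_id=set_id, parent_pathway_id=parent,
                                  class_label=class_label, members=frozenset(members)))
    return SubpathwayCollection(entries)


# --- survival / model ------------------------------------------------------


def write_survival(cohort: SurvivalCohort, path) -> None:
    cohort.data.to_csv(path, index_label="sample")


def read_survival(path) -> SurvivalCohort:
    return SurvivalCohort(pd.read_csv(path, index_col="sample"))


def write_model(model: LassoModel, path) -> None:
    payload = {
        "coefficients": model.coefficients,
        "lambda_grid": list(map(float, model.lambda_grid)),
        "selected_lambda": model.selected_lambda,
        "cv_deviance": list(map(float, model.cv_deviance)),
        "training_median": model.training_median,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path) -> LassoModel:
    obj = json.loads(Path(path).read_text())
    return LassoModel(
        coefficients=obj["coefficients"],
        lambda_grid=np.asarray(obj["lambda_grid"]),
        selected_lambda=obj["selected_lambda"],
        cv_deviance=np.asarray(obj["cv_deviance"]),
        training_median=obj.get("training_median"),
        metadata=obj.get("metadata", {}),
    )
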