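"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8, tab-delimited with a header row; missing values are
empty fields ("." is rejected as ambiguous).  Matrices carry the feature id
in column 1.  GMT is the usual tab-separated gene-set format (name,
description, members).  Networks are two-column undirected edge lists with
deduplicated unordered pairs and no self-loops.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Set

import networkx as nx
import numpy as np
import pandas as pd

from .synthcohort import FeatureMatrix


class FormatError(ValueError):
    pass


def _check_nonempty(path, df_or_lines):
    if len(df_or_lines) == 0:
        raise FormatError(f"{path}: no records")


def read_pheno(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "family_id": str})
    _check_nonempty(path, df)
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'subject_id'")
    obj_cols = df.select_dtypes(include="object")
    if (obj_cols == ".").any().any():
        bad = (obj_cols == ".").any()
        col = bad.index[bad][0]
        row = int(np.flatnonzero((obj_cols[col] == ".").to_numpy())[0]) + 2
        raise FormatError(f"{path}:{row}: '.' is not a valid missing marker (use empty field)")
    return df


def write_pheno(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_matrix(path, gene_map: pd.Series | None = None) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_nonempty(path, df)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if gene_map is None:
        gene_map = pd.Series(df.index, index=df.index, name="gene")
    return FeatureMatrix(values=df, gene_map=gene_map)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_cpg_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "gene_symbol": str})
    _check_nonempty(path, df)
    for col in ("cpg_id", "gene_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def write_cpg_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> Dict[str, Set[str]]:
    sets: Dict[str, Set[str]] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    _check_nonempty(path, lines)
    for i, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: GMT line needs >= 2 tab-separated fields")
        name = parts[0]
        if name in sets:
            raise FormatError(f"{path}:{i}: duplicate set name {name!r}")
        sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Dict[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_edge_list(path) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8", newline=None) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    _check_nonempty(path, lines)
    start = 0
    if lines[0].split("\t")[:2] in (["gene_a", "gene_b"], ["node_a", "node_b"]):
        start = 1
    for i, line in enumerate(lines[start:], start=start + 1):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}:{i}: edge line needs two tab-separated node names")
        a, b = parts[0], parts[1]
        if a == b:
            continue  # self-loops dropped
        g.add_edge(a, b)
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path) -> list:
    with open(path, encoding="utf-8", newline=None) as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    _check_nonempty(path, genes)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_truth(truth, path) -> None:
    """Ground-truth table for test oracles (gene, effect, mediated flag)."""
    rows = [
        {
            "gene": g,
            "effect": truth.true_effects[g],
            "mediated": int(g in truth.mediated_gene_ids),
            "mediator_cpg": truth.mediator_cpg.get(g, ""),
        }
        for g in sorted(truth.true_effects)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
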