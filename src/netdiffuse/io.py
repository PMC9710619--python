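"""Tab-separated readers and writers for the pipeline's file formats.

All formats are plain TSV: a genes × samples expression matrix (first
column = gene symbol), a 3-column interaction list
``gene_a<TAB>gene_b<TAB>confidence``, one-symbol-per-line gene lists with
``#`` comments, a 3-column TF→target weight table and a sample metadata
table.  Floats are written with 17 significant digits (shortest exact double
representation) so write→read round-trips are exact; missing t50 entries
are stored as the literal token ``NA``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import ExpressionMatrix, T50Matrix
from .network import InteractionRecord
from .stats import validate_metadata

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"
NA_TOKEN = "NA"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV; duplicate gene rows are averaged."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.index.isna().any() or frame.columns.isna().any():
        raise ValueError(f"{path}: empty gene or sample identifiers")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    if frame.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids {frame.columns[frame.columns.duplicated()].tolist()}")
    if frame.index.has_duplicates:
        n_dup = int(frame.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene rows collapsed by mean", path, n_dup)
        frame = frame.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(frame)


def read_edges(path: str | Path, header: bool = False) -> list[InteractionRecord]:
    """Read a 3-column interaction TSV (gene_a, gene_b, confidence)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            a, b, conf = parts
            try:
                conf_f = float(conf)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric confidence {conf!r}")
            records.append(InteractionRecord(a.strip(), b.strip(), conf_f))
    return records


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; ``#`` comments and blank lines ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                genes.add(token)
    return genes


def read_grn(path: str | Path) -> pd.DataFrame:
    """Read a 3-column TF→target weight TSV with header tf/target/weight."""
    frame = pd.read_csv(path, sep="\t")
    required = {"tf", "target", "weight"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: GRN table needs columns {sorted(required)}")
    return frame


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(frame)


def write_matrix(expr: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write a genes × samples matrix as TSV (10 significant digits)."""
    frame = expr.values if isinstance(expr, ExpressionMatrix) else expr
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")


def write_table(table: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Generic TSV writer for result tables; NaN becomes the NA token."""
    table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA_TOKEN,
                 index_label=index_label)


def write_t50(t50: T50Matrix, path: str | Path) -> None:
    """Write the t50 matrix with ``receptor|tf`` column names and NA sentinels."""
    flat = t50.values.copy()
    flat.columns = [f"{r}|{t}" for r, t in flat.columns]
    flat.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA_TOKEN,
                index_label="sample")


def read_t50(path: str | Path, alpha: float = float("nan"), horizon: int = 2000) -> T50Matrix:
    """Read a t50 TSV written by :func:`write_t50`."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                        float_precision="round_trip")
    pairs = [tuple(c.split("|", 1)) for c in frame.columns]
    frame.columns = pd.MultiIndex.from_tuples(pairs, names=["receptor", "tf"])
    return T50Matrix(values=frame.astype(float), alpha=alpha, horizon=horizon)


def write_network(network, node_path: str | Path, edge_path: str | Path) -> None:
    """Write node (gene, roles) and edge TSVs for an assembled network."""
    with open(node_path, "w") as fh:
        fh.write("gene\troles\n")
        for gene in network.nodes:
            fh.write(f"{gene}\t{','.join(sorted(network.roles_of(gene)))}\n")
    with open(edge_path, "w") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for a, b in network.edges():
            conf = network.graph.edges[a, b].get("confidence", "")
            fh.write(f"{a}\t{b}\t{conf}\n")


def write_graphml(network, path: str | Path) -> None:
    """GraphML export for inspection in Cytoscape/Gephi."""
    import networkx as nx

    g = network.graph.copy()
    for gene in g.nodes():
        g.nodes[gene]["roles"] = ",".join(sorted(g.nodes[gene]["roles"]))
    nx.write_graphml(g, path)
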