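"""Readers and writers for the plain-text formats the package touches.

Expression TSV/CSV (genes × samples, gzip-transparent), weighted
edge-list TSV, labelled square-matrix TSV, GMT gene-set collections, and
TSV/JSON result tables.  Floats in TSV output use 6 significant digits;
JSON keeps full precision.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compare import EnrichmentResult, GeneSetCollection, enrichment_table
from .contrast import ContrastResult, PeelTrace
from .graphs import WeightedNetwork

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


def _sep_for(path: Path, text: str | None = None) -> str:
    name = path.name.removesuffix(".gz")
    if name.endswith(".csv"):
        return ","
    if name.endswith((".tsv", ".txt")):
        return "\t"
    if text and "\t" not in text.splitlines()[0] and "," in text.splitlines()[0]:
        return ","
    return "\t"


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# -- expression matrices -----------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples expression table (first column = gene label).

    Non-numeric cells raise an error naming the offending gene/sample;
    empty cells and NA tokens become missing values.  Duplicate gene
    labels are collapsed to the row with the highest mean expression
    (logged), mirroring the most-expressed-probe convention.  Values must
    be non-negative.
    """
    path = Path(path)
    with _open_text(path) as fh:
        head = fh.readline()
    if not head.strip():
        raise ValueError(f"{path}: empty expression file")
    df = pd.read_csv(path, sep=_sep_for(path, head), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression file")
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"{path}: non-numeric value {df.loc[gene, sample]!r} at gene {gene!r}, "
            f"sample {sample!r}"
        )
    df = numeric.astype(np.float64)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        means = df.mean(axis=1)
        df = (
            df.assign(_mean=means)
            .sort_values("_mean", ascending=False, kind="stable")
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        df = df.loc[sorted(df.index)]
        logger.warning("collapsed %d duplicate gene labels (kept highest-mean row)", n_dup)
    if (df < 0).any().any():
        gene = df.index[(df < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative expression value at gene {gene!r}")
    return df


def write_expression(x: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    x.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT, index_label="gene")


# -- networks ----------------------------------------------------------------


def read_network(path: str | Path, kind: str = "edge_list") -> WeightedNetwork:
    """Load a network from an edge-list or labelled square-matrix TSV.

    Edge lists have columns node1/node2[/weight]; a missing weight column
    (PPI convention) means weight 1.  Duplicate and reciprocal rows are
    collapsed to the maximum weight with a warning.  Matrices must be
    symmetric within tolerance; the diagonal is zeroed.
    """
    path = Path(path)
    if kind == "edge_list":
        return _read_edge_list(path)
    if kind == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown network format {kind!r}")


def _read_edge_list(path: Path) -> WeightedNetwork:
    with _open_text(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty network file")
    sep = _sep_for(path, first)
    cells = first.rstrip("\n").split(sep)
    has_header = cells[0].lower() in ("node1", "source", "from", "gene1", "protein1")
    if not has_header and len(cells) >= 3:
        try:
            float(cells[2])
        except ValueError:
            has_header = True
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if df.shape[1] not in (2, 3):
        raise ValueError(f"{path}: edge list must have 2 or 3 columns, found {df.shape[1]}")
    rows = df.itertuples(index=False, name=None)
    return WeightedNetwork.from_edges(rows)


def _read_matrix(path: Path) -> WeightedNetwork:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix row and column labels differ")
    w = df.values.astype(float)
    if not np.allclose(w, w.T, atol=1e-8, rtol=0.0):
        raise ValueError(f"{path}: matrix is asymmetric beyond tolerance")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(list(df.index), w)


def write_network(
    net: WeightedNetwork, path: str | Path, kind: str = "edge_list"
) -> None:
    """Write a network as an edge list (nonzero pairs) or full matrix."""
    path = Path(path)
    if kind == "edge_list":
        with open(path, "w") as fh:
            fh.write("node1\tnode2\tweight\n")
            for u, v, w in net.iter_edges(nonzero_only=True):
                fh.write(f"{u}\t{v}\t{_FLOAT_FMT % w}\n")
    elif kind == "matrix":
        df = pd.DataFrame(net.weights, index=list(net.nodes), columns=list(net.nodes))
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="")
    else:
        raise ValueError(f"unknown network format {kind!r}")


# -- gene sets ---------------------------------------------------------------


def read_gmt(
    path: str | Path, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file: set name, description, tab-separated members.

    Without an explicit universe, the union of all sets is used.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection.from_dict(sets, universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_node_set(path: str | Path) -> frozenset[str]:
    """One node label per line; blank lines and '#' comments ignored."""
    with _open_text(Path(path)) as fh:
        nodes = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    if not nodes:
        raise ValueError(f"{path}: no node labels found")
    return frozenset(nodes)


# -- contrast results --------------------------------------------------------


def write_contrast_results(
    results: Sequence[ContrastResult],
    path: str | Path,
    traces: Sequence[PeelTrace] | None = None,
) -> None:
    """TSV of ranked contrast subgraphs, plus a JSON twin with trace summaries."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("rank\tdirection\tC\tobjective\tsize\tnodes\n")
        for r in results:
            fh.write(
                f"{r.rank}\t{r.direction}\t{_FLOAT_FMT % r.c_value}\t"
                f"{_FLOAT_FMT % r.objective}\t{r.size}\t{','.join(r.sorted_nodes())}\n"
            )
    payload = {
        "results": [
            {
                "rank": r.rank, "direction": r.direction, "c_value": r.c_value,
                "objective": r.objective, "size": r.size, "nodes": list(r.sorted_nodes()),
            }
            for r in results
        ]
    }
    if traces is not None:
        payload["traces"] = [
            {
                "c_value": t.c_value, "argmax_index": t.argmax_index,
                "n_candidates": t.n_candidates, "objectives": list(t.objectives),
            }
            for t in traces
        ]
    Path(str(path) + ".json").write_text(json.dumps(payload, indent=1))


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    enrichment_table(results).to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)
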