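"""End-to-end workflow: build networks, mine contrasts, run statistics.

A :class:`RunConfig` (constructible from a YAML file whose keys mirror
the CLI flags) drives one comparison: per condition either a prebuilt
network file or an expression matrix to turn into a coexpression
network, then ranked contrast subgraphs in one or both directions,
degree-distribution tests, optional overlap statistics against reference
node sets, and optional GMT enrichment.  Every run writes a provenance
record (config echo, package version, input checksums) so outputs are
traceable; the computation itself is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .coexpression import CoexpressionParams, build_network
from .compare import degree_distribution_test, enrich, fisher_overlap, jaccard_index
from .contrast import PeelParams, difference_graph, top_k_peel
from .graphs import WeightedNetwork
from .io import (
    read_expression,
    read_gmt,
    read_network,
    read_node_set,
    write_contrast_results,
    write_enrichment,
    write_network,
)

logger = logging.getLogger(__name__)

_DIRECTIONS = {"ab": ("A_over_B",), "ba": ("B_over_A",), "both": ("A_over_B", "B_over_A")}


@dataclass
class RunConfig:
    """One pipeline run.  Paths may be expression tables or networks."""

    out_dir: str
    expression_a: str | None = None
    expression_b: str | None = None
    network_a: str | None = None
    network_b: str | None = None
    network_kind: str = "edge_list"
    direction: str = "both"
    gmt: str | None = None
    reference_set_a: str | None = None
    reference_set_b: str | None = None
    write_networks: bool = False
    fdr_threshold: float = 0.05
    seed: int = 0
    log_level: str = "INFO"
    coexpression: CoexpressionParams = field(default_factory=CoexpressionParams)
    peel: PeelParams = field(default_factory=PeelParams)

    def __post_init__(self) -> None:
        for cond in "ab":
            expr = getattr(self, f"expression_{cond}")
            net = getattr(self, f"network_{cond}")
            if (expr is None) == (net is None):
                raise ValueError(
                    f"condition {cond.upper()}: provide exactly one of an expression "
                    "matrix or a network file"
                )
        if self.direction not in _DIRECTIONS:
            raise ValueError("direction must be one of ab, ba, both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        coex = CoexpressionParams(**raw.pop("coexpression", {}))
        peel_kwargs = dict(raw.pop("peel", {}))
        if "c_grid" in peel_kwargs:
            peel_kwargs["c_grid"] = tuple(peel_kwargs["c_grid"])
        peel = PeelParams(**peel_kwargs)
        return cls(coexpression=coex, peel=peel, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coexpression"] = asdict(self.coexpression)
        d["peel"] = asdict(self.peel)
        d["peel"]["c_grid"] = list(self.peel.c_grid)
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_condition(config: RunConfig, cond: str) -> tuple[WeightedNetwork, str]:
    expr_path = getattr(config, f"expression_{cond}")
    net_path = getattr(config, f"network_{cond}")
    if expr_path is not None:
        x = read_expression(expr_path)
        net = build_network(x, config.coexpression)
        return net, expr_path
    return read_network(net_path, kind=config.network_kind), net_path


def run_pipeline(config: RunConfig) -> dict:
    """Execute one comparison; returns the artifact bundle as a dict.

    Stages: load/build the two networks → contrast subgraphs per
    requested direction → degree-distribution test on each rank-1 set →
    overlap statistics against optional reference sets → enrichment
    against an optional GMT.  A missing GMT or reference set merely skips
    that stage.  Any stage failure raises with a stage-named message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out_dir)}

    def _stage(name: str):
        logger.info("pipeline stage: %s", name)

    _stage("load networks")
    try:
        net_a, path_a = _load_condition(config, "a")
        net_b, path_b = _load_condition(config, "b")
    except Exception as exc:  # re-raise with stage context
        raise RuntimeError(f"[load networks] {exc}") from exc
    logger.info(
        "networks loaded: A has %d nodes, B has %d nodes, %d shared",
        net_a.n_nodes, net_b.n_nodes, len(set(net_a.nodes) & set(net_b.nodes)),
    )
    if config.write_networks:
        write_network(net_a, out_dir / "network_a.tsv")
        write_network(net_b, out_dir / "network_b.tsv")

    _stage("contrast mining")
    try:
        diff = difference_graph(net_a, net_b)
        contrasts: dict[str, list] = {}
        for direction in _DIRECTIONS[config.direction]:
            g = diff if direction == "A_over_B" else diff.negated()
            results = top_k_peel(g, config.peel, direction=direction)
            contrasts[direction] = results
            tag = "ab" if direction == "A_over_B" else "ba"
            write_contrast_results(results, out_dir / f"contrast_{tag}.tsv")
    except Exception as exc:
        raise RuntimeError(f"[contrast mining] {exc}") from exc
    bundle["contrasts"] = contrasts

    _stage("degree statistics")
    degree_reports = {}
    for direction, results in contrasts.items():
        if not results:
            logger.info("no contrast subgraph found for %s; degree test skipped", direction)
            continue
        top = results[0]
        da, db, u, p = degree_distribution_test(top.node_set, net_a, net_b)
        tag = "ab" if direction == "A_over_B" else "ba"
        report = {
            "direction": direction,
            "nodes": sorted(top.node_set),
            "degrees_a": {k: float(v) for k, v in da.items()},
            "degrees_b": {k: float(v) for k, v in db.items()},
            "u_statistic": u,
            "p_value": p,
        }
        (out_dir / f"degree_test_{tag}.json").write_text(json.dumps(report, indent=1))
        degree_reports[direction] = report
    bundle["degree_tests"] = degree_reports

    _stage("overlap statistics")
    universe = frozenset(diff.nodes)
    overlaps = {}
    for cond, direction in (("a", "A_over_B"), ("b", "B_over_A")):
        ref_path = getattr(config, f"reference_set_{cond}")
        if ref_path is None or direction not in contrasts or not contrasts[direction]:
            continue
        ref = read_node_set(ref_path) & universe
        found = contrasts[direction][0].node_set
        odds, p, expected = fisher_overlap(found, ref, universe)
        overlaps[direction] = {
            "jaccard": jaccard_index(found, ref),
            "observed_overlap": len(found & ref),
            "expected_overlap": expected,
            "odds_ratio": odds,
            "p_value": p,
        }
    if overlaps:
        (out_dir / "overlap_stats.json").write_text(json.dumps(overlaps, indent=1))
    bundle["overlaps"] = overlaps

    _stage("enrichment")
    if config.gmt is None:
        logger.info("no GMT provided; enrichment skipped")
    else:
        collection = read_gmt(config.gmt, universe=universe)
        for direction, results in contrasts.items():
            if not results:
                continue
            tag = "ab" if direction == "A_over_B" else "ba"
            try:
                _, full = enrich(
                    results[0].node_set, collection, fdr_threshold=config.fdr_threshold
                )
            except ValueError as exc:
                logger.warning("enrichment skipped for %s: %s", direction, exc)
                continue
            write_enrichment(full, out_dir / f"enrichment_{tag}.tsv")

    _stage("provenance")
    inputs = {
        p: _sha256(p)
        for p in (path_a, path_b, config.gmt, config.reference_set_a, config.reference_set_b)
        if p is not None
    }
    provenance = {
        "tool": "contrastnet",
        "version": __version__,
        "config": config.to_dict(),
        "input_sha256": inputs,
        "n_shared_nodes": len(universe),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    bundle["provenance"] = provenance
    return bundle
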