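"""Synthetic fixtures: planted differential modules and expression blocks.

Two generators make the whole pipeline testable without external data:

* :func:`planted_contrast_pair` draws a pair of networks on the same
  nodes in which a chosen module is wired densely in condition A and
  sparsely in condition B, against a uniform background — the ground
  truth a contrast-subgraph miner should recover.
* :func:`planted_expression_pair` draws two-condition expression
  matrices with condition-specific co-regulated gene blocks driven by a
  shared latent factor, then exponentiates to abundance-like positive
  values so the log/filter preprocessing path is exercised.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
instance seeded from the spec, so outputs are reproducible bit-for-bit
for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np
import pandas as pd

from .compare import jaccard_index
from .graphs import ContrastResult, WeightedNetwork

#: Beta(a, b) weight draws for weighted mode: module pairs vs background
_MODULE_BETA = (6.0, 2.0)
_BACKGROUND_BETA = (2.0, 2.0)

#: log2 abundance baseline of the expression generator (values ≈ 2**5)
_BASE_LOG2 = 5.0


def _labels(prefix: str, n: int) -> list[str]:
    width = max(1, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


@dataclass(frozen=True)
class PlantedGraphSpec:
    """A planted differential module in a pair of random networks.

    ``module`` is either the number of module nodes to sample or an
    explicit collection of node labels.  Within-module pairs get an edge
    with probability ``p_in_a`` in network A and ``p_in_b`` in network B;
    every other pair gets probability ``p_background`` in both,
    independently.  In weighted mode present edges carry Beta-distributed
    weights whose mean is higher for module pairs.
    """

    n_nodes: int
    module: int | frozenset[str]
    p_in_a: float
    p_in_b: float
    p_background: float
    seed: int
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        for name in ("p_in_a", "p_in_b", "p_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if isinstance(self.module, int) and not 1 <= self.module <= self.n_nodes:
            raise ValueError("module size must be between 1 and n_nodes")


@dataclass(frozen=True)
class PlantedModule:
    """One co-regulated gene block of the expression generator."""

    genes: int | frozenset[str]
    loading: float
    active_in: str  # "A", "B" or "both"

    def __post_init__(self) -> None:
        if not 0.0 < self.loading <= 1.0:
            raise ValueError("loading must be in (0, 1]")
        if self.active_in not in ("A", "B", "both"):
            raise ValueError(f"active_in must be A, B or both, got {self.active_in!r}")


@dataclass(frozen=True)
class PlantedExpressionSpec:
    """Two-condition expression matrices with latent-factor gene blocks."""

    n_genes: int
    n_samples_a: int
    n_samples_b: int
    modules: tuple[PlantedModule, ...]
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_genes < 2 or self.n_samples_a < 3 or self.n_samples_b < 3:
            raise ValueError("need >= 2 genes and >= 3 samples per condition")


def planted_contrast_pair(
    spec: PlantedGraphSpec,
) -> tuple[WeightedNetwork, WeightedNetwork, frozenset[str]]:
    """Draw the (A, B, planted module) triple described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    nodes = _labels("n", spec.n_nodes)
    if isinstance(spec.module, int):
        chosen = rng.choice(spec.n_nodes, size=spec.module, replace=False)
        module = frozenset(nodes[i] for i in chosen)
    else:
        module = frozenset(map(str, spec.module))
        extra = module - set(nodes)
        if extra:
            raise ValueError(f"module nodes not in graph: {sorted(extra)[:5]}")
    mod_idx = np.zeros(spec.n_nodes, dtype=bool)
    mod_idx[[nodes.index(n) for n in module]] = True

    iu, ju = np.triu_indices(spec.n_nodes, k=1)
    in_module = mod_idx[iu] & mod_idx[ju]
    pa = np.where(in_module, spec.p_in_a, spec.p_background)
    pb = np.where(in_module, spec.p_in_b, spec.p_background)
    present_a = rng.random(iu.size) < pa
    present_b = rng.random(iu.size) < pb
    if spec.weighted:
        wm = rng.beta(*_MODULE_BETA, size=iu.size)
        wb = rng.beta(*_BACKGROUND_BETA, size=iu.size)
        base = np.where(in_module, wm, wb)
        vals_a = np.where(present_a, base, 0.0)
        # independent magnitudes for B, same pair-type means
        wm2 = rng.beta(*_MODULE_BETA, size=iu.size)
        wb2 = rng.beta(*_BACKGROUND_BETA, size=iu.size)
        vals_b = np.where(present_b, np.where(in_module, wm2, wb2), 0.0)
    else:
        vals_a = present_a.astype(float)
        vals_b = present_b.astype(float)

    def _assemble(vals: np.ndarray) -> WeightedNetwork:
        w = np.zeros((spec.n_nodes, spec.n_nodes))
        w[iu, ju] = vals
        w += w.T
        return WeightedNetwork(nodes, w, _trusted=True)

    return _assemble(vals_a), _assemble(vals_b), module


def planted_expression_pair(
    spec: PlantedExpressionSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, frozenset[str]]]:
    """Draw (expression A, expression B, planted module sets).

    Module genes follow loading·latent + N(0, noise_sd²) on the log2
    scale, with an independent standard-normal latent factor per sample;
    all other genes are pure noise.  Values are 2**(z + 5), i.e.
    log-normal-like abundances centred near 32 so the default
    low-expression filter passes unperturbed genes.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _labels("g", spec.n_genes)
    available = list(range(spec.n_genes))
    planted: dict[str, frozenset[str]] = {}
    rows: list[np.ndarray] = []
    for i, mod in enumerate(spec.modules, start=1):
        if isinstance(mod.genes, int):
            if mod.genes > len(available):
                raise ValueError("not enough unassigned genes for all modules")
            pick = rng.choice(len(available), size=mod.genes, replace=False)
            idx = np.array(sorted(available[j] for j in pick), dtype=int)
            available = [g for g in available if g not in set(idx.tolist())]
        else:
            members = sorted(map(str, mod.genes))
            extra = set(members) - set(genes)
            if extra:
                raise ValueError(f"module genes outside the universe: {sorted(extra)[:5]}")
            idx = np.array([genes.index(g) for g in members], dtype=int)
        planted[f"m{i}"] = frozenset(genes[j] for j in idx)
        rows.append(idx)

    def _condition(label: str, n_samples: int) -> pd.DataFrame:
        z = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
        for mod, idx in zip(spec.modules, rows):
            if mod.active_in in (label, "both"):
                latent = rng.normal(0.0, 1.0, size=n_samples)
                z[idx] += mod.loading * latent
        values = 2.0 ** (z + _BASE_LOG2)
        samples = _labels(label, n_samples)
        return pd.DataFrame(values, index=genes, columns=samples)

    return _condition("A", spec.n_samples_a), _condition("B", spec.n_samples_b), planted


def recovery_score(found: ContrastResult | Collection[str], planted: Collection[str]) -> float:
    """Jaccard index between a mined node set and the planted module."""
    node_set = found.node_set if isinstance(found, ContrastResult) else found
    return jaccard_index(node_set, planted)
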