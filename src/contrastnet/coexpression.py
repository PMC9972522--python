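"""WGCNA-style weighted coexpression networks from expression matrices.

The pipeline mirrors common practice for bulk transcriptomic/proteomic
coexpression analysis: genes expressed below a threshold in too many
samples are discarded, values are log transformed with a pseudocount, a
gene×gene association matrix is computed (Spearman correlation, or the
ρ proportionality coefficient for compositional data), and associations
are soft-thresholded into weights w = (0.5·(1 + ρ))^β.  No hard cutoff is
applied: the resulting network is complete, with weights in [0, 1] and
negative associations pushed toward 0 (the unsigned convention).

Expression matrices are plain :class:`pandas.DataFrame` objects with
gene labels as the index and sample labels as columns; values are
non-negative abundances (FPKM/TPM/protein intensity), NaN = missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graphs import ATOL, WeightedNetwork

logger = logging.getLogger(__name__)

ExpressionMatrix = pd.DataFrame

#: genes with more than this fraction of missing values are dropped
MAX_MISSING_FRACTION = 0.2


@dataclass(frozen=True)
class CoexpressionParams:
    """Parameters of the network build.

    filter_threshold / filter_max_low: a gene is discarded when its value
    is below ``filter_threshold`` in more than ``filter_max_low`` samples
    (an absolute count; ``filter_max_frac`` switches to a fraction of the
    sample size).  ``log_offset`` is the pseudocount of the log2
    transform; ``beta`` the soft-threshold exponent; ``measure`` selects
    the association.
    """

    filter_threshold: float = 1.0
    filter_max_low: int = 50
    filter_max_frac: float | None = None
    log_offset: float = 1.0
    beta: float = 12.0
    measure: Literal["spearman", "proportionality"] = "spearman"
    preprocess: bool = True

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be > 0")
        if self.measure not in ("spearman", "proportionality"):
            raise ValueError(f"unknown association measure {self.measure!r}")
        if self.filter_max_frac is not None and not 0 <= self.filter_max_frac <= 1:
            raise ValueError("filter_max_frac must be in [0, 1]")

    def max_low_count(self, n_samples: int) -> int:
        if self.filter_max_frac is not None:
            return int(np.floor(self.filter_max_frac * n_samples))
        return self.filter_max_low


def filter_low_expression(
    x: ExpressionMatrix, threshold: float = 1.0, max_low: int = 50
) -> ExpressionMatrix:
    """Drop genes with value < ``threshold`` in more than ``max_low`` samples.

    The rule is strict: a gene low in exactly ``max_low`` samples is
    retained.  Missing values do not count as low.  Gene order is
    preserved; samples are untouched.
    """
    low_counts = (x < threshold).sum(axis=1)
    keep = low_counts <= max_low
    if not keep.any():
        raise ValueError(
            "expression filter removed every gene; review filter_threshold/"
            "filter_max_low for this dataset"
        )
    removed = int((~keep).sum())
    if removed:
        logger.info("expression filter removed %d of %d genes", removed, len(keep))
    return x.loc[keep]


def log_transform(x: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset); with offset 1 a zero abundance maps to 0."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if (x < 0).any().any():
        raise ValueError("expression values must be non-negative before log transform")
    return np.log2(x + offset)


def _drop_missing_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    frac = x.isna().mean(axis=1)
    bad = frac > MAX_MISSING_FRACTION
    if bad.any():
        logger.warning(
            "dropping %d genes with > %.0f%% missing values",
            int(bad.sum()), 100 * MAX_MISSING_FRACTION,
        )
        x = x.loc[~bad]
    return x


def spearman_matrix(x: ExpressionMatrix) -> pd.DataFrame:
    """Gene×gene Spearman correlation across samples.

    Ties get average ranks; missing values are handled pairwise-complete.
    Genes with zero rank variance get correlation 0 to every other gene
    (with a logged warning) and 1 on the diagonal.
    """
    if x.shape[1] < 3:
        raise ValueError("at least 3 samples are required for correlation")
    if x.shape[0] < 2:
        raise ValueError("at least 2 genes are required for correlation")
    if x.isna().any().any():
        corr = x.T.corr(method="spearman", min_periods=3)
        corr = corr.astype(float)
        flat = corr.values
    else:
        ranks = rankdata(x.values, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            flat = np.corrcoef(ranks)
        corr = pd.DataFrame(flat, index=x.index, columns=x.index)
    n_bad = int(np.isnan(np.asarray(flat)).any(axis=1).sum())
    if n_bad:
        logger.warning(
            "%d genes with zero rank variance (or too few paired samples); "
            "their correlations are set to 0", n_bad,
        )
    out = corr.fillna(0.0)
    np.fill_diagonal(out.values, 1.0)
    np.clip(out.values, -1.0, 1.0, out=out.values)
    return out


def proportionality_matrix(
    x: ExpressionMatrix, log_offset: float = 1.0
) -> pd.DataFrame:
    """Gene×gene ρ proportionality on clr-transformed abundances.

    Each sample is log2(value + offset) centred by its per-sample mean
    over genes (centred log-ratio).  For clr vectors a_i,
    ρ(i, j) = 1 − var(a_i − a_j)/(var a_i + var a_j) = 2·cov(a_i, a_j) /
    (var a_i + var a_j), which lies in [−1, 1].  Genes with zero clr
    variance get 0 with a logged warning.
    """
    if x.shape[1] < 3:
        raise ValueError("at least 3 samples are required for proportionality")
    if x.isna().any().any():
        raise ValueError("proportionality requires a complete matrix (no NaN)")
    vals = x.values + log_offset
    if (vals <= 0).any():
        raise ValueError("values must be strictly positive after adding log_offset")
    a = np.log2(vals)
    a = a - a.mean(axis=0, keepdims=True)  # clr: centre per sample over genes
    cov = np.cov(a, ddof=1)
    var = np.diagonal(cov).copy()
    zero = var <= 0
    if zero.any():
        logger.warning("%d genes with zero clr variance; proportionality set to 0", int(zero.sum()))
        var[zero] = 1.0  # placeholder; rows zeroed below
    denom = var[:, None] + var[None, :]
    rho = 2.0 * cov / denom
    rho[zero, :] = 0.0
    rho[:, zero] = 0.0
    np.fill_diagonal(rho, 1.0)
    np.clip(rho, -1.0, 1.0, out=rho)
    return pd.DataFrame(rho, index=x.index, columns=x.index)


def soft_threshold(assoc: pd.DataFrame, beta: float = 12.0) -> WeightedNetwork:
    """Soft-threshold associations into edge weights (0.5·(1 + ρ))^β.

    ρ = 1 maps to 1, ρ = −1 to 0, ρ = 0 to 0.5^β; the diagonal is forced
    to 0 (no self-loops).  The network is complete — small correlations
    are suppressed smoothly rather than cut.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    vals = np.asarray(assoc.values, dtype=float)
    if np.nanmin(vals) < -1 - 1e-6 or np.nanmax(vals) > 1 + 1e-6:
        raise ValueError("association values must lie in [-1, 1]")
    w = (0.5 * (1.0 + np.clip(vals, -1.0, 1.0))) ** beta
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(list(assoc.index), w, meta={"beta": beta})


def build_network(
    x: ExpressionMatrix, params: CoexpressionParams | None = None
) -> WeightedNetwork:
    """Full coexpression build: filter → log → association → soft threshold.

    With ``preprocess=False`` the low-expression filter and log transform
    are skipped (for data already normalised upstream).  The Spearman
    path log transforms for reproducible intermediates even though ranks
    are invariant to it; the proportionality path applies its own clr
    log-ratio transform to the (offset) raw abundances.
    """
    params = params or CoexpressionParams()
    if (x < 0).any().any():
        raise ValueError("expression values must be non-negative")
    x = _drop_missing_genes(x)
    if params.preprocess:
        x = filter_low_expression(
            x, params.filter_threshold, params.max_low_count(x.shape[1])
        )
    if params.measure == "spearman":
        y = log_transform(x, params.log_offset) if params.preprocess else x
        assoc = spearman_matrix(y)
    else:
        assoc = proportionality_matrix(x, params.log_offset)
    net = soft_threshold(assoc, params.beta)
    net.meta.update(
        measure=params.measure,
        beta=params.beta,
        preprocess=params.preprocess,
        n_samples=int(x.shape[1]),
    )
    return net
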