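"""Global differential co-expression (DCE) network construction.

For each condition a Spearman correlation matrix is computed over that
condition's samples; each coefficient is mapped through the Fisher
z-transformation and the per-pair difference is standardized into a z-score

    z = (z_r2 - z_r1) / sqrt(c/(n2 - 3) + c/(n1 - 3))

where ``c`` corrects the asymptotic variance of the transformed coefficient:
c = 1.06 for Spearman rank correlations and c = 1 for Pearson.  The
resulting symmetric matrix Z is the global DCE network; z > 0 means the
pair is more strongly (positively) correlated in condition 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from cosinet.io import ConditionDesign, ExpressionMatrix

logger = logging.getLogger("cosinet")

#: variance-correction constant of the two-sample z-test on transformed
#: correlation coefficients, by correlation type
C_CONSTANTS = {"spearman": 1.06, "pearson": 1.0}

DEFAULT_CLAMP_EPS = 1e-7


@dataclass
class CorrelationMatrix:
    """Per-condition gene-gene correlation matrix.

    ``constant_genes`` lists genes with zero variance across the condition's
    samples; their correlations are set to 0 against every partner (there is
    no rank information to correlate) and downstream stages treat them as
    carrying no rewiring evidence.
    """

    r: np.ndarray
    n_samples: int
    condition: str
    gene_ids: list[str]
    method: str = "spearman"
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.gene_ids),) * 2:
            raise ValueError("correlation matrix shape does not match gene ids")
        if self.n_samples < 4:
            raise ValueError("correlation requires at least 4 samples")


@dataclass
class DCEMatrix:
    """Symmetric matrix of rewiring z-scores (the global DCE network)."""

    z: np.ndarray
    gene_ids: list[str]
    n1: int
    n2: int
    c: float
    method: str = "spearman"
    condition1: str = "1"
    condition2: str = "2"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.gene_ids),) * 2:
            raise ValueError("z matrix shape does not match gene ids")
        if not np.isfinite(self.z).all():
            raise ValueError("z matrix contains non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]


def filter_genes(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    min_samples: int = 20,
    floor: float = 0.0,
) -> ExpressionMatrix:
    """Drop genes not expressed above ``floor`` in ``min_samples`` samples
    of *both* conditions.

    Correlations estimated from genes detected in only a handful of samples
    are dominated by ties at the floor; this condition-aware filter removes
    them before network construction.  ``floor`` defaults to 0 on the stored
    values; on a log2(FPKM + 0.1) matrix, "zero expression" corresponds to
    log2(0.1) and the floor should be set accordingly.
    """
    design.validate_against(expr)
    keep = np.ones(expr.n_genes, dtype=bool)
    for samples in (design.samples1, design.samples2):
        idx = [expr.sample_index(s) for s in samples]
        n_expressed = (expr.values[:, idx] > floor).sum(axis=1)
        keep &= n_expressed >= min_samples
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "gene filter removed %d of %d genes (expressed > %g in < %d samples "
            "of at least one condition)",
            removed,
            expr.n_genes,
            floor,
            min_samples,
        )
    kept_genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    if not kept_genes:
        raise ValueError("gene filter removed every gene; lower min_samples or floor")
    return expr.subset_genes(kept_genes)


def _correlation(
    values: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """Gene x gene correlation of a genes x samples block.

    Returns the matrix and a boolean mask of constant genes.  Spearman uses
    average (fractional) ranks, i.e. rank-then-Pearson.
    """
    if method == "spearman":
        data = rankdata(values, axis=1)
    elif method == "pearson":
        data = values
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    sd = data.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.asarray(r, dtype=float)
    # constant genes: no rank information, r = 0 against all partners
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return r, constant


def spearman_matrix(
    expr: ExpressionMatrix,
    sample_subset: Sequence[str],
    condition: str = "",
    method: str = "spearman",
) -> CorrelationMatrix:
    """Correlation matrix over one condition's samples (Spearman by default)."""
    if len(sample_subset) < 4:
        raise ValueError(
            f"correlation needs >= 4 samples, got {len(sample_subset)}"
        )
    idx = [expr.sample_index(s) for s in sample_subset]
    r, constant = _correlation(expr.values[:, idx], method)
    constant_genes = [g for g, c in zip(expr.gene_ids, constant) if c]
    if constant_genes:
        logger.warning(
            "%d gene(s) constant across the %s samples; their correlations set to 0: %s",
            len(constant_genes),
            condition or "subset",
            constant_genes[:5],
        )
    return CorrelationMatrix(
        r=r,
        n_samples=len(sample_subset),
        condition=condition,
        gene_ids=list(expr.gene_ids),
        method=method,
        constant_genes=constant_genes,
    )


def fisher_z(r, clamp_eps: float = DEFAULT_CLAMP_EPS):
    """Fisher z-transformation ``arctanh(r)`` with clamping near |r| = 1.

    Perfect correlations occur with small sample sizes and would map to
    infinity; |r| is clamped to ``1 - clamp_eps`` first, which keeps the
    transform finite and direction-preserving.  Odd function of ``r``.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlation coefficient outside [-1, 1]")
    clamped = np.clip(arr, -1.0 + clamp_eps, 1.0 - clamp_eps)
    out = np.arctanh(clamped)
    return out if arr.ndim else float(out)


def dce_zscore_matrix(
    corr1: CorrelationMatrix,
    corr2: CorrelationMatrix,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> DCEMatrix:
    """Standardized difference of Fisher-transformed correlations.

    Positive z means the pair is more positively correlated in the condition
    of ``corr2``.  The diagonal is fixed at 0: self-co-expression is not an
    edge and would otherwise dominate the centrality computation.
    """
    if corr1.gene_ids != corr2.gene_ids:
        raise ValueError("correlation matrices cover different gene ids")
    if corr1.method != corr2.method:
        raise ValueError("correlation matrices use different methods")
    if min(corr1.n_samples, corr2.n_samples) <= 3:
        raise ValueError("z-test requires more than 3 samples per condition")
    c = C_CONSTANTS[corr1.method]
    z1 = fisher_z(corr1.r, clamp_eps)
    z2 = fisher_z(corr2.r, clamp_eps)
    denom = np.sqrt(c / (corr2.n_samples - 3) + c / (corr1.n_samples - 3))
    z = (z2 - z1) / denom
    np.fill_diagonal(z, 0.0)
    return DCEMatrix(
        z=z,
        gene_ids=list(corr1.gene_ids),
        n1=corr1.n_samples,
        n2=corr2.n_samples,
        c=c,
        method=corr1.method,
        condition1=corr1.condition,
        condition2=corr2.condition,
    )


def build_dce_network(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    method: str = "spearman",
    min_samples: int = 20,
    floor: float = 0.0,
) -> tuple[DCEMatrix, CorrelationMatrix, CorrelationMatrix, ExpressionMatrix]:
    """Convenience wrapper: filter genes, correlate per condition, z-score."""
    filtered = filter_genes(expr, design, min_samples=min_samples, floor=floor)
    corr1 = spearman_matrix(filtered, design.samples1, design.condition1, method)
    corr2 = spearman_matrix(filtered, design.samples2, design.condition2, method)
    return dce_zscore_matrix(corr1, corr2), corr1, corr2, filtered
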