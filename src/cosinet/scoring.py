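"""Single-sample rewiring scores over a DCE sub-network.

For a gene pair (x, y) and a sample k, local statistical dependence in a
reference condition is estimated from the frequencies of that condition's
samples inside three boxes drawn around k in the (x, y) scatter plot: a
band of gene-x values near x_k, a band of gene-y values near y_k, and their
intersection.  With n_x, n_y, n_xy the counts and n the condition's sample
count,

    rho = max{ n_xy/n - (n_x/n) * (n_y/n), 0 }

is 0 when the genes are independent at k's position and positive when they
are locally dependent; a negative raw value marks k as an outlier of the
condition's co-expression cloud and is floored at 0.  No further
normalization of rho is applied anywhere.

Each box spans a fixed proportion ``b`` (default 0.1) of the gene's
expression range in that condition, centred on the sample's value with
closed boundaries; the range can be trimmed to the central ``q`` quantile
mass to blunt extreme values.  Every sample is projected onto *both*
conditions regardless of its own membership, giving

    delta = 100 * (rho_cond2 - rho_cond1)

per pair, and the sample's score aggregates over the sub-network's edges:

    CS(k) = (1 / n_edges) * sum over edges |z_xy| * delta_xy(k)

Negative CS means the sample's co-expression resembles condition 1,
positive means condition 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cosinet.io import ConditionDesign, ExpressionMatrix
from cosinet.subnetwork import Subnetwork

logger = logging.getLogger("cosinet")


class DegenerateGeneError(ValueError):
    """A gene's (trimmed) expression range is zero in a condition."""


@dataclass(frozen=True)
class BoxParams:
    """Box geometry: width proportion ``b`` and quantile trim mass ``q``.

    ``b`` is the box width as a proportion of the per-condition, per-gene
    expression range (default 0.1: 10% of the range, half on either side of
    the sample's value).  ``q`` is the central quantile mass used to define
    that range (default 1: full range); counts always use all condition
    samples, only the box *size* is affected by trimming.
    """

    b: float = 0.1
    q: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.b <= 1:
            raise ValueError(f"box proportion b must be in (0, 1], got {self.b}")
        if not 0 < self.q <= 1:
            raise ValueError(f"quantile mass q must be in (0, 1], got {self.q}")


@dataclass
class PairStatistics:
    """Per-sample, per-pair audit record of the box statistics."""

    sample_id: str
    gene_x: str
    gene_y: str
    rho1: float
    rho2: float
    delta: float
    z: float
    n_x1: int = 0
    n_y1: int = 0
    n_xy1: int = 0
    n_x2: int = 0
    n_y2: int = 0
    n_xy2: int = 0
    excluded: bool = False


@dataclass
class ScoreTable:
    """Per-sample scores plus optional per-pair audit statistics."""

    scores: pd.DataFrame  # sample_id, condition, cosinet_score, n_pairs_used
    condition1: str
    condition2: str
    pair_stats: pd.DataFrame | None = None
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def score_of(self, sample_id: str) -> float:
        row = self.scores.loc[self.scores["sample_id"] == sample_id, "cosinet_score"]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in score table")
        return float(row.iloc[0])


def _trimmed_width(values: np.ndarray, q: float) -> float:
    """Width of the central-q-quantile expression range."""
    lo_p = (1.0 - q) / 2.0
    lo, hi = np.quantile(values, [lo_p, 1.0 - lo_p])
    return float(hi - lo)


def box_counts(
    expr_x: np.ndarray,
    expr_y: np.ndarray,
    xk: float,
    yk: float,
    params: BoxParams = BoxParams(),
) -> tuple[int, int, int, int]:
    """Counts (n_x, n_y, n_xy, n) of one condition's samples in the three
    boxes around (xk, yk).

    ``expr_x``/``expr_y`` are the condition's values for the two genes (the
    designated sample's own values included only when it belongs to the
    condition).  Boundaries are closed: a value exactly half a box-width
    from the sample's value counts as inside, which keeps counts stable
    under exact ties.
    """
    expr_x = np.asarray(expr_x, dtype=float)
    expr_y = np.asarray(expr_y, dtype=float)
    if expr_x.shape != expr_y.shape or expr_x.ndim != 1:
        raise ValueError("expr_x and expr_y must be 1-D and equal length")
    n = len(expr_x)
    if n == 0:
        raise ValueError("condition has no samples")
    w_x = params.b * _trimmed_width(expr_x, params.q)
    w_y = params.b * _trimmed_width(expr_y, params.q)
    if w_x == 0 or w_y == 0:
        raise DegenerateGeneError(
            "zero trimmed expression range; pair cannot be box-scored"
        )
    in_x = np.abs(expr_x - xk) <= w_x / 2
    in_y = np.abs(expr_y - yk) <= w_y / 2
    return int(in_x.sum()), int(in_y.sum()), int((in_x & in_y).sum()), n


def rho(n_x: int, n_y: int, n_xy: int, n: int) -> float:
    """Local dependence statistic from the three box counts (floored at 0)."""
    if n <= 0:
        raise ValueError("condition sample count must be positive")
    if not (0 <= n_xy <= min(n_x, n_y) <= n):
        raise ValueError(
            f"inconsistent box counts: n_x={n_x}, n_y={n_y}, n_xy={n_xy}, n={n}"
        )
    return max(n_xy / n - (n_x / n) * (n_y / n), 0.0)


def _condition_values(
    expr: ExpressionMatrix, design: ConditionDesign, gene: str
) -> tuple[np.ndarray, np.ndarray]:
    gi = expr.gene_index(gene)
    idx1 = [expr.sample_index(s) for s in design.samples1]
    idx2 = [expr.sample_index(s) for s in design.samples2]
    return expr.values[gi, idx1], expr.values[gi, idx2]


def pair_delta(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    sample_id: str,
    gene_x: str,
    gene_y: str,
    params: BoxParams = BoxParams(),
    z: float = float("nan"),
) -> PairStatistics:
    """Per-pair rewiring direction delta for one sample.

    The sample is projected onto both conditions whether or not it belongs
    to either; a pair with a degenerate (zero-range) gene in either
    condition is marked ``excluded`` and contributes nothing downstream.
    """
    xk = float(expr.values[expr.gene_index(gene_x), expr.sample_index(sample_id)])
    yk = float(expr.values[expr.gene_index(gene_y), expr.sample_index(sample_id)])
    x1, x2 = _condition_values(expr, design, gene_x)
    y1, y2 = _condition_values(expr, design, gene_y)
    try:
        n_x1, n_y1, n_xy1, n1 = box_counts(x1, y1, xk, yk, params)
        n_x2, n_y2, n_xy2, n2 = box_counts(x2, y2, xk, yk, params)
    except DegenerateGeneError:
        logger.warning(
            "pair (%s, %s) excluded: zero trimmed expression range in a condition",
            gene_x,
            gene_y,
        )
        return PairStatistics(
            sample_id=sample_id, gene_x=gene_x, gene_y=gene_y,
            rho1=float("nan"), rho2=float("nan"), delta=float("nan"),
            z=z, excluded=True,
        )
    rho1 = rho(n_x1, n_y1, n_xy1, n1)
    rho2 = rho(n_x2, n_y2, n_xy2, n2)
    return PairStatistics(
        sample_id=sample_id, gene_x=gene_x, gene_y=gene_y,
        rho1=rho1, rho2=rho2, delta=100.0 * (rho2 - rho1), z=z,
        n_x1=n_x1, n_y1=n_y1, n_xy1=n_xy1,
        n_x2=n_x2, n_y2=n_y2, n_xy2=n_xy2,
    )


def _usable_edges(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    sub: Subnetwork,
    params: BoxParams,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split edges into usable and degenerate-excluded, once per network."""
    degenerate: set[str] = set()
    for gene in sub.genes:
        for vals in _condition_values(expr, design, gene):
            if params.b * _trimmed_width(vals, params.q) == 0:
                degenerate.add(gene)
                break
    usable = [e for e in sub.edges if e[0] not in degenerate and e[1] not in degenerate]
    excluded = [e for e in sub.edges if e not in usable]
    if excluded:
        logger.warning(
            "%d of %d sub-network pair(s) excluded (degenerate gene range)",
            len(excluded),
            len(sub.edges),
        )
    return usable, excluded


def cosinet_score(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    sub: Subnetwork,
    sample_id: str,
    params: BoxParams = BoxParams(),
    weighted_mean: bool = False,
) -> float:
    """Score one sample over the sub-network's edges.

    ``weighted_mean=True`` divides by the sum of |z| instead of the edge
    count, turning the aggregate into a proper |z|-weighted mean of delta;
    the default divides by the edge count.
    """
    design.validate_against(expr)
    usable, _ = _usable_edges(expr, design, sub, params)
    if not usable:
        raise ValueError(
            f"no usable sub-network pair for sample {sample_id!r} "
            "(all pairs degenerate or none present)"
        )
    total = 0.0
    weight = 0.0
    for x, y in usable:
        z = sub.edge_z(x, y)
        stats = pair_delta(expr, design, sample_id, x, y, params, z=z)
        total += abs(z) * stats.delta
        weight += abs(z)
    return total / (weight if weighted_mean else len(usable))


def score_all_samples(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    sub: Subnetwork,
    params: BoxParams = BoxParams(),
    samples: list[str] | None = None,
    per_pair: bool = False,
    weighted_mean: bool = False,
) -> ScoreTable:
    """Score every requested sample (default: all, including unclassified).

    The box counting is vectorized across samples and condition members but
    is count-for-count identical to :func:`box_counts`; per-sample scores
    equal :func:`cosinet_score` exactly.
    """
    design.validate_against(expr)
    if samples is None:
        samples = list(expr.sample_ids)
    for s in samples:
        expr.sample_index(s)

    usable, excluded = _usable_edges(expr, design, sub, params)
    if not usable:
        raise ValueError("no usable sub-network pair after degenerate exclusions")

    genes = sorted({g for e in usable for g in e})
    gene_pos = {g: i for i, g in enumerate(genes)}
    target_idx = [expr.sample_index(s) for s in samples]
    gene_idx = [expr.gene_index(g) for g in genes]
    targets = expr.values[np.ix_(gene_idx, target_idx)]  # genes x targets

    n_k = len(samples)
    cond_data = []
    for cond_samples in (design.samples1, design.samples2):
        idx = [expr.sample_index(s) for s in cond_samples]
        vals = expr.values[np.ix_(gene_idx, idx)]  # genes x members
        widths = np.array([params.b * _trimmed_width(vals[g], params.q) for g in range(len(genes))])
        # membership[g, k, m]: member m inside gene-g box of target k
        membership = (
            np.abs(vals[:, None, :] - targets[:, :, None]) <= widths[:, None, None] / 2
        )
        cond_data.append((membership, membership.sum(axis=2), len(cond_samples)))

    zero = np.zeros(n_k)
    abs_z_sum = 0.0
    cs = np.zeros(n_k)
    records: list[PairStatistics] = []
    deltas_by_edge = {}
    for x, y in usable:
        gx, gy = gene_pos[x], gene_pos[y]
        rhos = []
        counts = []
        for membership, n_in_box, n_cond in cond_data:
            n_xy = (membership[gx] & membership[gy]).sum(axis=1)
            n_x = n_in_box[gx]
            n_y = n_in_box[gy]
            r = np.maximum(n_xy / n_cond - (n_x / n_cond) * (n_y / n_cond), zero)
            rhos.append(r)
            counts.append((n_x, n_y, n_xy))
        delta = 100.0 * (rhos[1] - rhos[0])
        z = sub.edge_z(x, y)
        cs += np.abs(z) * delta
        abs_z_sum += abs(z)
        deltas_by_edge[(x, y)] = delta
        if per_pair:
            (nx1, ny1, nxy1), (nx2, ny2, nxy2) = counts
            for k, s in enumerate(samples):
                records.append(
                    PairStatistics(
                        sample_id=s, gene_x=x, gene_y=y,
                        rho1=float(rhos[0][k]), rho2=float(rhos[1][k]),
                        delta=float(delta[k]), z=z,
                        n_x1=int(nx1[k]), n_y1=int(ny1[k]), n_xy1=int(nxy1[k]),
                        n_x2=int(nx2[k]), n_y2=int(ny2[k]), n_xy2=int(nxy2[k]),
                    )
                )
    cs = cs / (abs_z_sum if weighted_mean else len(usable))

    frame = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": [design.condition_of(s) or "NA" for s in samples],
            "cosinet_score": cs,
            "n_pairs_used": len(usable),
        }
    )
    pair_frame = pd.DataFrame([r.__dict__ for r in records]) if per_pair else None
    return ScoreTable(
        scores=frame,
        condition1=design.condition1,
        condition2=design.condition2,
        pair_stats=pair_frame,
        excluded_pairs=excluded,
    )
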