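"""Function-specific DCE sub-networks.

The leading-edge genes G of an enriched set are the nodes; the edges are
the unordered gene pairs of G whose rewiring z-score satisfies |z| >= t,
filtering out pairs with little change in co-expression.  The per-condition
correlations of each edge are kept for reporting.  t = 3 by default — a
conventional "strong change" two-sided z cutoff (normal tail ~ 0.0027) —
and is a first-class knob: case studies should sweep it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cosinet.dce import CorrelationMatrix, DCEMatrix
from cosinet.io import write_matrix, write_table

logger = logging.getLogger("cosinet")


@dataclass
class Subnetwork:
    """Leading-edge genes plus their strongly rewired pairs."""

    genes: list[str]
    z_sub: np.ndarray
    t: float
    edges: list[tuple[str, str]]
    r1_sub: np.ndarray | None = None
    r2_sub: np.ndarray | None = None
    condition1: str = "1"
    condition2: str = "2"

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}
        for x, y in self.edges:
            if x == y:
                raise ValueError(f"self-edge on {x!r}")
            if abs(self.z_sub[self._index[x], self._index[y]]) < self.t:
                raise ValueError(f"edge ({x}, {y}) below threshold t={self.t}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_z(self, x: str, y: str) -> float:
        return float(self.z_sub[self._index[x], self._index[y]])


def build_subnetwork(
    Z: DCEMatrix,
    core_genes: list[str],
    t: float = 3.0,
    corr1: CorrelationMatrix | None = None,
    corr2: CorrelationMatrix | None = None,
) -> Subnetwork:
    """Threshold the z submatrix over the leading-edge genes.

    ``core_genes`` order is preserved for genes present in the DCE matrix;
    pairs are unordered and the (zero) diagonal is never an edge.  Edges are
    enumerated in (i, j) upper-triangle order of the preserved gene order.
    """
    if t < 0:
        raise ValueError("threshold t must be nonnegative")
    genes = [g for g in core_genes if g in Z._gene_index]
    if not genes:
        raise ValueError("no core gene is present in the DCE matrix")
    dropped = len(core_genes) - len(genes)
    if dropped:
        logger.warning("%d core gene(s) absent from the DCE matrix", dropped)
    idx = [Z.gene_index(g) for g in genes]
    z_sub = Z.z[np.ix_(idx, idx)]

    def _sub(corr: CorrelationMatrix | None) -> np.ndarray | None:
        if corr is None:
            return None
        if corr.gene_ids != Z.gene_ids:
            raise ValueError("correlation matrix gene ids differ from DCE matrix")
        return corr.r[np.ix_(idx, idx)]

    edges = [
        (genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
        if abs(z_sub[i, j]) >= t
    ]
    if len(genes) < 2 or not edges:
        logger.warning(
            "sub-network has %d gene(s) and %d edge(s) at t=%g",
            len(genes), len(edges), t,
        )
    return Subnetwork(
        genes=genes,
        z_sub=z_sub,
        t=t,
        edges=edges,
        r1_sub=_sub(corr1),
        r2_sub=_sub(corr2),
        condition1=Z.condition1,
        condition2=Z.condition2,
    )


def subnetwork_edge_table(sub: Subnetwork) -> pd.DataFrame:
    """Edge list with z and both per-condition correlations."""
    rows = []
    for x, y in sub.edges:
        i, j = sub._index[x], sub._index[y]
        rows.append(
            {
                "gene_x": x,
                "gene_y": y,
                "z": sub.z_sub[i, j],
                "r_cond1": sub.r1_sub[i, j] if sub.r1_sub is not None else np.nan,
                "r_cond2": sub.r2_sub[i, j] if sub.r2_sub is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["gene_x", "gene_y", "z", "r_cond1", "r_cond2"])


def export_subnetwork(
    sub: Subnetwork,
    edges_path: str | Path,
    matrix_path: str | Path | None = None,
    header_lines: list[str] | None = None,
) -> None:
    """Write the edge list and (optionally) the dense z submatrix."""
    write_table(subnetwork_edge_table(sub), edges_path, header_lines=header_lines)
    if matrix_path is not None:
        write_matrix(sub.z_sub, sub.genes, matrix_path, header_lines=header_lines)
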