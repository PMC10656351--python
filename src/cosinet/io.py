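"""Input/output for every external artifact of the pipeline.

Expression matrices are genes x samples text tables (TSV or CSV, header row
of sample ids, first column gene ids), condition designs are two-column
TSVs, and gene sets use the GMT format.  Output tables carry optional
``#``-prefixed provenance headers which every reader skips.

Gene symbols are matched across artifacts by exact, case-sensitive string
identity: silent case-folding hides annotation mismatches, so overlap sizes
are logged instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cosinet")

#: significant digits used for every numeric artifact; round-trips are
#: lossless at this precision for float64 values of typical magnitude
FLOAT_FORMAT = "%.12g"


class CosinetError(Exception):
    """Base class for user-facing errors."""


class ParseError(CosinetError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (log-scale) expression values.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``.
    gene_ids, sample_ids
        Ordered, duplicate-free identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(self.values[idx], list(genes), list(self.sample_ids))

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in samples]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


@dataclass
class ConditionDesign:
    """Assignment of samples to exactly two conditions.

    ``condition1`` is the reference whose resemblance yields *negative*
    scores downstream; ``condition2`` yields positive scores.  Samples
    absent from ``assignment`` are unclassified: they are still scored by
    projection but contribute to neither condition's statistics.
    """

    assignment: dict[str, str]
    condition1: str
    condition2: str
    min_per_condition: int = 4

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        extra = labels - {self.condition1, self.condition2}
        if extra:
            raise ValueError(f"assignment contains unknown condition labels: {sorted(extra)}")
        if self.condition1 == self.condition2:
            raise ValueError("condition labels must differ")
        for cond in (self.condition1, self.condition2):
            n = sum(1 for v in self.assignment.values() if v == cond)
            if n < self.min_per_condition:
                raise ValueError(
                    f"condition {cond!r} has {n} samples; "
                    f"at least {self.min_per_condition} are required for correlation"
                )

    def samples_of(self, condition: str) -> list[str]:
        """Samples assigned to ``condition``, in assignment order."""
        return [s for s, c in self.assignment.items() if c == condition]

    @property
    def samples1(self) -> list[str]:
        return self.samples_of(self.condition1)

    @property
    def samples2(self) -> list[str]:
        return self.samples_of(self.condition2)

    def condition_of(self, sample: str) -> str | None:
        return self.assignment.get(sample)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in self.assignment if s not in expr._sample_index]
        if missing:
            raise ValueError(
                f"{len(missing)} design sample(s) absent from expression matrix, "
                f"e.g. {missing[:5]}"
            )

    def swapped(self) -> "ConditionDesign":
        """The same design with the two condition labels exchanged."""
        return ConditionDesign(
            dict(self.assignment), self.condition2, self.condition1, self.min_per_condition
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB hallmark collections)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source_description: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            # dedup preserving first occurrence
            self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _detect_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    na_policy: str = "error",
) -> ExpressionMatrix:
    """Load a genes x samples expression table.

    The first row holds sample ids, the first column gene ids.  Duplicate
    gene rows are resolved by keeping the row with the highest mean (a
    warning is logged); duplicate sample ids are fatal.  ``na_policy``
    is ``"error"`` (reject missing/non-numeric cells, naming the offender)
    or ``"drop"`` (drop gene rows containing missing values).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path, delimiter)
    # pandas silently renames duplicate columns, so check the raw header first
    with open(path) as fh:
        header = next(
            (line for line in fh if line.strip() and not line.startswith("#")), ""
        )
    sample_cols = [c for c in header.rstrip("\n").split(sep)[1:] if c]
    dup_samples = sorted({c for c in sample_cols if sample_cols.count(c) > 1})
    if dup_samples:
        raise ParseError(f"duplicate sample id(s) in {path.name}: {dup_samples}")
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {frame.iat[gi, si]!r} at gene {frame.index[gi]!r}, "
            f"sample {frame.columns[si]!r} in {path.name}"
        )
    if numeric.isna().to_numpy().any():
        if na_policy == "drop":
            before = len(numeric)
            numeric = numeric.dropna(axis=0)
            logger.warning(
                "dropped %d gene row(s) with missing values", before - len(numeric)
            )
        else:
            gi, si = np.argwhere(numeric.isna().to_numpy())[0]
            raise ParseError(
                f"missing value at gene {numeric.index[gi]!r}, "
                f"sample {numeric.columns[si]!r} in {path.name}"
            )

    if numeric.index.duplicated().any():
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        logger.warning(
            "duplicate gene id(s) %s: keeping the row with the highest mean", dups
        )
        means = numeric.mean(axis=1).to_numpy()
        keep = np.ones(len(numeric), dtype=bool)
        for g in dups:
            pos = np.flatnonzero(numeric.index == g)
            keep[pos] = False
            keep[pos[np.argmax(means[pos])]] = True
        numeric = numeric.loc[keep]

    return ExpressionMatrix.from_frame(numeric)


def read_design(
    path: str | Path,
    condition1: str | None = None,
    condition2: str | None = None,
    delimiter: str | None = None,
) -> ConditionDesign:
    """Load a two-column sample/condition design file.

    ``#``-prefixed comment lines are ignored.  Exactly two condition labels
    must occur; unless given explicitly, ``condition1`` and ``condition2``
    are taken in order of first appearance.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    assignment: dict[str, str] = {}
    order: list[str] = []
    first_data = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}")
            sample, cond = fields[0].strip(), fields[1].strip()
            if first_data:
                first_data = False
                if {sample.lower(), cond.lower()} & {"sample", "sample_id", "condition"}:
                    continue  # optional header row
            if sample in assignment:
                raise ParseError(f"{path.name}:{lineno}: duplicate sample id {sample!r}")
            assignment[sample] = cond
            if cond not in order:
                order.append(cond)
    if len(order) != 2:
        raise ParseError(
            f"{path.name}: expected exactly 2 condition labels, found {len(order)}: {order}"
        )
    c1 = condition1 if condition1 is not None else order[0]
    c2 = condition2 if condition2 is not None else order[1]
    if {c1, c2} != set(order):
        raise ValueError(
            f"requested conditions ({c1!r}, {c2!r}) do not match labels in file: {order}"
        )
    return ConditionDesign(assignment, c1, c2)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, genes, tab-separated)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if name in sets:
                raise ParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path.name)
    return GeneSetCollection(sets, descriptions, source_description=str(path))


def read_matrix(path: str | Path, delimiter: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Read a square gene x gene matrix written by :func:`write_matrix`."""
    sep = _detect_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise ParseError(f"{Path(path).name}: matrix row and column ids differ")
    return frame.to_numpy(dtype=float), list(frame.index)


def read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    sep = _detect_delimiter(path, delimiter)
    return pd.read_csv(path, sep=sep, comment="#")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; '#' comments and blanks ignored."""
    genes: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return list(dict.fromkeys(genes))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_header(fh, header_lines: Iterable[str] | None) -> None:
    for line in header_lines or ():
        fh.write(f"# {line}\n")


def write_matrix(
    matrix: np.ndarray,
    gene_ids: Sequence[str],
    path: str | Path,
    delimiter: str | None = None,
    header_lines: Iterable[str] | None = None,
) -> None:
    """Write a square gene x gene matrix with full-precision values."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(gene_ids), len(gene_ids)):
        raise ValueError("matrix dimensions do not match gene ids")
    sep = _detect_delimiter(path, delimiter)
    frame = pd.DataFrame(matrix, index=list(gene_ids), columns=list(gene_ids))
    with open(path, "w") as fh:
        _write_header(fh, header_lines)
        frame.to_csv(fh, sep=sep, float_format=FLOAT_FORMAT)


def write_table(
    rows: pd.DataFrame | Mapping[str, Sequence],
    path: str | Path,
    delimiter: str | None = None,
    header_lines: Iterable[str] | None = None,
) -> None:
    """Write a tabular artifact (scores, rankings, enrichment, edge lists)."""
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    sep = _detect_delimiter(path, delimiter)
    with open(path, "w") as fh:
        _write_header(fh, header_lines)
        frame.to_csv(fh, sep=sep, index=False, float_format=FLOAT_FORMAT)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    delimiter: str | None = None,
    header_lines: Iterable[str] | None = None,
) -> None:
    sep = _detect_delimiter(path, delimiter)
    with open(path, "w") as fh:
        _write_header(fh, header_lines)
        expr.to_frame().to_csv(fh, sep=sep, float_format=FLOAT_FORMAT)


def write_design(design: ConditionDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for sample, cond in design.assignment.items():
            fh.write(f"{sample}\t{cond}\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
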