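"""Data containers and delimited-text IO.

The package works on a samples x features numeric matrix (``GeneMatrix``)
and a numeric phenotype vector (``Phenotype``).  Files are plain delimited
text: the matrix has a header row of feature identifiers and a first column
of sample identifiers; the phenotype file holds one value per sample, with
an optional single name header line.

Feature columns containing missing-value tokens are dropped at load time
(the count is logged), mirroring the usual pre-filter applied to expression
or SNP matrices before wrapper selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, EmptyMatrixError, MatrixParseError

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("NA", "")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class GeneMatrix:
    """A samples x features numeric matrix with identifier metadata.

    ``values`` is the ``X`` of every formula in the package: rows are
    samples, columns are features, and column ``i`` corresponds to bit ``i``
    of a selection individual.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("GeneMatrix values must be 2-dimensional")
        n, q = self.values.shape
        if len(self.feature_ids) != q:
            raise ConfigError(
                f"{len(self.feature_ids)} feature ids for {q} columns"
            )
        if len(self.sample_ids) != n:
            raise ConfigError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.feature_ids)) != q:
            raise ConfigError("duplicate feature ids")
        if len(set(self.sample_ids)) != n:
            raise ConfigError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("GeneMatrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def subset_samples(self, rows: np.ndarray) -> "GeneMatrix":
        rows = np.asarray(rows, dtype=int)
        return GeneMatrix(
            self.values[rows],
            list(self.feature_ids),
            [self.sample_ids[i] for i in rows],
        )


@dataclass
class Phenotype:
    """A numeric response vector with a trait label."""

    values: np.ndarray
    name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("Phenotype contains non-finite entries")

    def __len__(self) -> int:
        return self.values.size

    def subset(self, rows: np.ndarray) -> "Phenotype":
        return Phenotype(self.values[np.asarray(rows, dtype=int)], self.name)


@dataclass
class SplitSpec:
    """Train/test split protocol: ``n_train`` samples for training.

    ``shuffle=True`` draws a seeded random partition; ``shuffle=False``
    takes the first ``n_train`` rows in file order.
    """

    n_train: int
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.n_train < 1:
            raise ConfigError("n_train must be positive")


def load_matrix(
    path: str | Path,
    delimiter: str | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> GeneMatrix:
    """Read a delimited matrix file, dropping features with missing values.

    The first row must hold feature identifiers and the first column sample
    identifiers.  Any column containing one of ``missing_tokens`` (or a
    non-parseable numeric cell treated as missing is NOT allowed — it raises)
    is removed; the number of dropped columns is logged.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            keep_default_na=False,
            na_values=list(missing_tokens),
            dtype=str,
        )
    except pd.errors.ParserError as exc:  # message names the offending line
        raise MatrixParseError(f"{path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # cells that are NaN in `numeric` but not flagged missing in `df` are
    # malformed rather than missing
    malformed = numeric.isna() & df.notna()
    if malformed.to_numpy().any():
        row, col = np.argwhere(malformed.to_numpy())[0]
        raise MatrixParseError(
            f"{path}: non-numeric value {df.iat[row, col]!r} at "
            f"sample {df.index[row]!r}, feature {df.columns[col]!r}"
        )
    keep = ~numeric.isna().any(axis=0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d feature(s) containing missing values", n_dropped)
    numeric = numeric.loc[:, keep]
    if numeric.shape[1] == 0:
        raise EmptyMatrixError(f"{path}: no features remain after filtering")
    return GeneMatrix(
        numeric.to_numpy(dtype=float),
        [str(c) for c in numeric.columns],
        [str(i) for i in numeric.index],
    )


def write_matrix(
    matrix: GeneMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    matrix.to_frame().to_csv(path, sep=sep, index_label="sample")


def load_phenotype(path: str | Path, name: str | None = None) -> Phenotype:
    """Read a one-value-per-line phenotype file.

    A non-numeric first line is taken as the trait name.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    header = None
    if lines:
        try:
            float(lines[0])
        except ValueError:
            header = lines[0]
            lines = lines[1:]
    try:
        values = np.array([float(ln) for ln in lines])
    except ValueError as exc:
        raise MatrixParseError(f"{path}: non-numeric phenotype value") from exc
    return Phenotype(values, name or header or path.stem)


def write_phenotype(phenotype: Phenotype, path: str | Path) -> None:
    path = Path(path)
    body = "\n".join(repr(float(v)) for v in phenotype.values)
    path.write_text(f"{phenotype.name}\n{body}\n")


def train_test_split(
    X: GeneMatrix, y: Phenotype, spec: SplitSpec
) -> tuple[GeneMatrix, Phenotype, GeneMatrix, Phenotype]:
    """Partition samples into a training and a test set.

    Deterministic for a fixed seed; the two index sets are disjoint and
    exhaustive.
    """
    n = X.n_samples
    if len(y) != n:
        raise ConfigError("phenotype length does not match matrix rows")
    if spec.n_train >= n:
        raise ConfigError(f"n_train={spec.n_train} must be < n={n}")
    order = np.arange(n)
    if spec.shuffle:
        order = np.random.default_rng(spec.seed).permutation(n)
    train_rows, test_rows = order[: spec.n_train], order[spec.n_train :]
    return (
        X.subset_samples(train_rows),
        y.subset(train_rows),
        X.subset_samples(test_rows),
        y.subset(test_rows),
    )
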