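"""Expression matrices: reading, validation, imputation and synthesis.

The search substrate is a real-valued n×m matrix of expression levels with
gene labels on rows and condition labels on columns.  Missing entries are
carried as NaN until :func:`impute_missing` replaces them with uniform draws,
mirroring the common microarray preprocessing of filling holes with random
values from the data range.  A synthetic generator plants coherent biclusters
into random background so the optimizer can be validated offline against a
known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MatrixParseError, ParameterError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "PlantedBicluster",
    "read_matrix",
    "write_matrix",
    "impute_missing",
    "generate_synthetic",
    "write_truth",
    "read_truth",
    "YEAST_IMPUTE_RANGE",
    "HUMAN_IMPUTE_RANGE",
]

# Imputation presets for the two microarray scales this package emulates:
# yeast cell-cycle style data (integer values 0-600) and human B-cell style
# data (values -750..650).
YEAST_IMPUTE_RANGE = (0.0, 800.0)
HUMAN_IMPUTE_RANGE = (-800.0, 800.0)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A labelled n×m expression matrix; NaN entries mark missing values."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        object.__setattr__(self, "condition_ids", tuple(map(str, self.condition_ids)))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        n, m = values.shape
        if n < 2 or m < 2:
            raise ValidationError(f"matrix must be at least 2×2, got {n}×{m}")
        if len(self.gene_ids) != n:
            raise ValidationError("gene_ids length does not match row count")
        if len(self.condition_ids) != m:
            raise ValidationError("condition_ids length does not match column count")
        if len(set(self.gene_ids)) != n:
            raise ValidationError("gene ids are not unique")
        if len(set(self.condition_ids)) != m:
            raise ValidationError("condition ids are not unique")
        if np.isinf(values).any():
            raise ValidationError("expression values must be finite or NaN (missing)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean n×m mask of cells still flagged as missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.condition_ids)
        )


@dataclass(frozen=True)
class PlantedBicluster:
    """Ground truth for a synthetic plant: which cells, which pattern, how noisy.

    pattern is one of:

    ``constant``
        every cell is ``mu`` plus noise (flat — zero residue, zero row variance);
    ``shifted``
        every gene follows the same condition profile, ``mu + b_j`` plus noise
        (zero residue, positive row variance);
    ``additive``
        shared profile plus a per-gene offset, ``mu + a_i + b_j`` plus noise
        (zero residue, positive row variance, rows at distinct levels).

    Profile/offset amplitudes ``a_i, b_j`` are drawn uniformly from
    [-amplitude, amplitude] when the matrix is generated.
    """

    gene_indices: tuple[int, ...]
    condition_indices: tuple[int, ...]
    pattern: str = "additive"
    noise_sd: float = 0.0
    mu: float = 0.0
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        genes = tuple(int(i) for i in self.gene_indices)
        conds = tuple(int(j) for j in self.condition_indices)
        object.__setattr__(self, "gene_indices", genes)
        object.__setattr__(self, "condition_indices", conds)
        if len(genes) < 2 or len(conds) < 2:
            raise ValidationError("a planted bicluster needs at least 2 genes and 2 conditions")
        if len(set(genes)) != len(genes) or len(set(conds)) != len(conds):
            raise ValidationError("planted indices must be duplicate-free")
        if min(genes) < 0 or min(conds) < 0:
            raise ValidationError("planted indices must be non-negative")
        if self.pattern not in ("constant", "additive", "shifted"):
            raise ParameterError(f"unknown plant pattern {self.pattern!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def read_matrix(path: str | Path, missing_sentinel: str | None = None) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First row: condition headers (the leading corner cell is ignored).
    First column: gene identifiers.  Cells equal to *missing_sentinel* are
    flagged missing (NaN); any other non-numeric token is a parse error.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise MatrixParseError(f"{path}: expected a header row and at least one data row")
    rows = [ln.split("\t") for ln in lines]
    header = rows[0]
    # Tolerate both a labelled and an absent corner cell in the header.
    body_width = len(rows[1])
    if len(header) == body_width:
        condition_ids = header[1:]
    elif len(header) == body_width - 1:
        condition_ids = header
    else:
        raise MatrixParseError(f"{path}: header width does not match data rows")
    gene_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(condition_ids)), dtype=float)
    for r, fields in enumerate(rows[1:], start=1):
        if len(fields) != body_width:
            raise MatrixParseError(
                f"{path}: row {r + 1} has {len(fields)} fields, expected {body_width}"
            )
        gene_ids.append(fields[0])
        for c, tok in enumerate(fields[1:]):
            tok = tok.strip()
            if missing_sentinel is not None and tok == missing_sentinel:
                data[r - 1, c] = np.nan
            else:
                try:
                    data[r - 1, c] = float(tok)
                except ValueError as exc:
                    raise MatrixParseError(
                        f"{path}: non-numeric value {tok!r} at row {r + 1}, column {c + 2}"
                    ) from exc
    return ExpressionMatrix(data, tuple(gene_ids), tuple(condition_ids))


def write_matrix(matrix: ExpressionMatrix, path: str | Path,
                 missing_sentinel: str = "NA") -> None:
    """Write the matrix as TSV; missing cells are emitted as *missing_sentinel*."""
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", na_rep=missing_sentinel)


def impute_missing(matrix: ExpressionMatrix, low: float, high: float,
                   seed: int | np.random.Generator) -> ExpressionMatrix:
    """Replace every missing cell by an independent uniform draw on [low, high].

    Non-missing cells are untouched; a matrix with no missing cells is returned
    unchanged.  The draw order is row-major, so results are reproducible under
    a fixed seed.
    """
    if not low < high:
        raise ParameterError(f"imputation range requires low < high, got [{low}, {high}]")
    mask = matrix.missing_mask
    if not mask.any():
        return matrix
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = matrix.values.copy()
    values[mask] = rng.uniform(low, high, size=int(mask.sum()))
    return replace(matrix, values=values)


def _draw_background(spec, n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Background distribution spec: ("normal", mu, sd) or ("uniform", lo, hi)."""
    kind, *params = spec
    if kind == "normal":
        mu, sd = params
        if sd < 0:
            raise ParameterError("background sd must be >= 0")
        return rng.normal(mu, sd, size=(n, m))
    if kind == "uniform":
        lo, hi = params
        if not lo < hi:
            raise ParameterError("background uniform range requires lo < hi")
        return rng.uniform(lo, hi, size=(n, m))
    raise ParameterError(f"unknown background distribution {kind!r}")


def generate_synthetic(
    n: int,
    m: int,
    background=("normal", 0.0, 1.0),
    plants: Sequence[PlantedBicluster] = (),
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionMatrix, list[PlantedBicluster]]:
    """Generate an n×m matrix of i.i.d. background with coherent plants on top.

    Each plant overwrites its cells with its pattern (see
    :class:`PlantedBicluster`) plus Normal(0, noise_sd) noise; overlapping
    plants are resolved last-writer-wins.  Deterministic for a fixed seed.
    """
    if n < 2 or m < 2:
        raise ParameterError("synthetic matrix must be at least 2×2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = _draw_background(background, n, m, rng)
    for plant in plants:
        g = np.asarray(plant.gene_indices)
        c = np.asarray(plant.condition_indices)
        if g.max() >= n or c.max() >= m:
            raise ParameterError(
                f"plant {plant.pattern} ({len(g)}×{len(c)}) exceeds matrix bounds {n}×{m}"
            )
        block = np.full((len(g), len(c)), plant.mu)
        if plant.pattern in ("shifted", "additive"):
            b = rng.uniform(-plant.amplitude, plant.amplitude, size=len(c))
            block += b[None, :]
        if plant.pattern == "additive":
            a = rng.uniform(-plant.amplitude, plant.amplitude, size=len(g))
            block += a[:, None]
        if plant.noise_sd > 0:
            block += rng.normal(0.0, plant.noise_sd, size=block.shape)
        values[np.ix_(g, c)] = block
    gene_ids = tuple(f"G{i}" for i in range(n))
    condition_ids = tuple(f"C{j}" for j in range(m))
    return ExpressionMatrix(values, gene_ids, condition_ids), list(plants)


def write_truth(plants: Sequence[PlantedBicluster], path: str | Path) -> None:
    """Write planted ground truth as a JSON sidecar next to a synthetic matrix."""
    records = [
        {
            "gene_indices": list(p.gene_indices),
            "condition_indices": list(p.condition_indices),
            "pattern": p.pattern,
            "noise_sd": p.noise_sd,
            "mu": p.mu,
            "amplitude": p.amplitude,
        }
        for p in plants
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_truth(path: str | Path) -> list[PlantedBicluster]:
    records = json.loads(Path(path).read_text())
    return [
        PlantedBicluster(
            gene_indices=tuple(r["gene_indices"]),
            condition_indices=tuple(r["condition_indices"]),
            pattern=r.get("pattern", "additive"),
            noise_sd=r.get("noise_sd", 0.0),
            mu=r.get("mu", 0.0),
            amplitude=r.get("amplitude", 2.0),
        )
        for r in records
    ]
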