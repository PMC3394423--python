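"""Bicluster mathematics: encoding, residue scores and the three objectives.

A bicluster is a submatrix B = g×c of the expression matrix D.  Its quality
is judged by the mean squared residue (MSR) — the average squared deviation
of each cell from the additive model row-mean + column-mean − overall-mean —
and by the row variance (RVAR), which separates trivially flat biclusters
from ones whose genes actually fluctuate together.  The optimizer minimizes
three objectives simultaneously:

    f1 = n·m / Size(B)      (prefer large biclusters; f1 = 1 for the full matrix)
    f2 = MSR(B) / δ         (prefer coherent biclusters; δ is the MSR budget)
    f3 = 1 / RVAR(B)        (prefer non-flat biclusters)

Objective vectors are plain float arrays of length 3 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateBiclusterError, EncodingError, ParameterError, ValidationError
from .expression import ExpressionMatrix

__all__ = [
    "Bicluster",
    "encode",
    "decode",
    "dimension_means",
    "msr",
    "row_variance",
    "fitness",
    "RVAR_PENALTY",
]

# f3 = 1/RVAR is undefined for perfectly flat biclusters; they are ranked
# worst on f3 with a large finite penalty so dominance stays well-defined.
RVAR_PENALTY = 1e12


@dataclass(frozen=True)
class Bicluster:
    """An ordered, duplicate-free gene index set × condition index set."""

    gene_indices: tuple[int, ...]
    condition_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        genes = tuple(int(i) for i in self.gene_indices)
        conds = tuple(int(j) for j in self.condition_indices)
        object.__setattr__(self, "gene_indices", genes)
        object.__setattr__(self, "condition_indices", conds)
        if len(set(genes)) != len(genes) or len(set(conds)) != len(conds):
            raise ValidationError("bicluster indices must be duplicate-free")
        if any(i < 0 for i in genes) or any(j < 0 for j in conds):
            raise ValidationError("bicluster indices must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_indices)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_indices)

    @property
    def size(self) -> int:
        """Size(g, c) = |g|·|c|, the number of cells."""
        return self.n_genes * self.n_conditions

    def submatrix(self, matrix: ExpressionMatrix) -> np.ndarray:
        self._check_in_range(matrix.n, matrix.m)
        return matrix.values[np.ix_(self.gene_indices, self.condition_indices)]

    def _check_in_range(self, n: int, m: int) -> None:
        if self.gene_indices and max(self.gene_indices) >= n:
            raise ValidationError("gene index out of range")
        if self.condition_indices and max(self.condition_indices) >= m:
            raise ValidationError("condition index out of range")


def decode(bits: np.ndarray, n: int, m: int) -> Bicluster:
    """Decode a binary vector of length n+m into a bicluster.

    The first n bits select genes, the last m bits select conditions; a set
    bit means the gene/condition belongs to the bicluster.
    """
    bits = np.asarray(bits)
    if bits.shape != (n + m,):
        raise EncodingError(f"expected a flat vector of length {n + m}, got shape {bits.shape}")
    on = bits != 0
    genes = tuple(int(i) for i in np.flatnonzero(on[:n]))
    conds = tuple(int(j) for j in np.flatnonzero(on[n:]))
    return Bicluster(genes, conds)


def encode(bicluster: Bicluster, n: int, m: int) -> np.ndarray:
    """Inverse of :func:`decode`: bicluster → binary vector of length n+m."""
    bicluster._check_in_range(n, m)
    bits = np.zeros(n + m, dtype=np.uint8)
    bits[list(bicluster.gene_indices)] = 1
    bits[[n + j for j in bicluster.condition_indices]] = 1
    return bits


def _selected(matrix: ExpressionMatrix, bicluster: Bicluster) -> np.ndarray:
    if bicluster.n_genes == 0 or bicluster.n_conditions == 0:
        raise DegenerateBiclusterError("bicluster has an empty gene or condition set")
    return bicluster.submatrix(matrix)


def dimension_means(matrix: ExpressionMatrix, bicluster: Bicluster):
    """Per-gene means d_ic, per-condition means d_gj and the overall mean d_gc."""
    sub = _selected(matrix, bicluster)
    return sub.mean(axis=1), sub.mean(axis=0), float(sub.mean())


def msr(matrix: ExpressionMatrix, bicluster: Bicluster) -> float:
    """Mean squared residue of B: mean over cells of (d_ij − d_ic − d_gj + d_gc)².

    Zero for any perfectly additive pattern d_ij = a_i + b_j, and for any
    single-gene or single-condition bicluster (the residue cancels exactly).
    Uses population (divide-by-count) normalization.
    """
    sub = _selected(matrix, bicluster)
    residue = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
    return float(np.mean(residue**2))


def row_variance(matrix: ExpressionMatrix, bicluster: Bicluster) -> float:
    """RVAR(g,c): mean over cells of (d_ij − d_ic)², the gene-dimensional variance."""
    sub = _selected(matrix, bicluster)
    return float(np.mean((sub - sub.mean(axis=1, keepdims=True)) ** 2))


def fitness(matrix: ExpressionMatrix, bicluster: Bicluster, delta: float,
            rvar_penalty: float = RVAR_PENALTY) -> np.ndarray:
    """The minimized objective vector (f1, f2, f3) for one bicluster.

    f3 falls back to *rvar_penalty* when RVAR = 0 (flat bicluster).
    """
    if delta <= 0:
        raise ParameterError(f"delta must be > 0, got {delta}")
    sub = _selected(matrix, bicluster)
    row_means = sub.mean(axis=1, keepdims=True)
    overall = sub.mean()
    residue = sub - row_means - sub.mean(axis=0, keepdims=True) + overall
    msr_value = np.mean(residue**2)
    rvar_value = np.mean((sub - row_means) ** 2)
    f1 = matrix.n * matrix.m / bicluster.size
    f2 = msr_value / delta
    f3 = 1.0 / rvar_value if rvar_value > 0 else rvar_penalty
    return np.array([f1, f2, f3], dtype=float)
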