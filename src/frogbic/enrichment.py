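"""Post-hoc scoring: enrichment p-values, recovery metrics and coverage.

Enrichment follows the classic hypergeometric over-representation test: the
probability of seeing at least k genes of a functional category of size
m_cat inside a bicluster of n genes drawn from a genome of g genes,

    p = 1 − Σ_{i=0}^{k−1} C(m_cat, i)·C(g−m_cat, n−i) / C(g, n).

Recovery metrics (Jaccard overlap with planted biclusters) and coverage
fractions validate the optimizer on synthetic ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bicluster import Bicluster
from .errors import ParameterError, ValidationError
from .expression import PlantedBicluster

__all__ = [
    "EnrichmentInput",
    "hypergeometric_pvalue",
    "read_gmt",
    "enrich_bicluster",
    "recovery_score",
    "coverage_stats",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one category/bicluster pair.

    k: category genes inside the bicluster; n: bicluster gene count;
    m_cat: category genes in the genome; g: genome gene count.
    """

    k: int
    n: int
    m_cat: int
    g: int

    def __post_init__(self) -> None:
        if self.g <= 0 or self.n <= 0:
            raise ParameterError("genome and bicluster gene counts must be > 0")
        if self.k < 0 or self.m_cat < 0:
            raise ParameterError("k and m_cat must be >= 0")
        if self.n > self.g or self.m_cat > self.g:
            raise ParameterError("bicluster/category cannot exceed the genome")
        if self.k > min(self.n, self.m_cat):
            raise ParameterError("k cannot exceed min(n, m_cat)")


def hypergeometric_pvalue(inp: EnrichmentInput) -> float:
    """Upper-tail probability P(X ≥ k) for X ~ Hypergeom(g, m_cat, n).

    Computed with the survival function of the hypergeometric distribution
    (log-space internally), so it stays stable at genome scale; k = 0
    returns exactly 1.
    """
    if inp.k == 0:
        return 1.0
    return float(stats.hypergeom.sf(inp.k - 1, inp.g, inp.m_cat, inp.n))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT dialect: name TAB description TAB gene ids..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = {gene for gene in fields[2:] if gene}
    if not sets:
        raise ValidationError(f"{path}: empty gene-set file")
    return sets


def enrich_bicluster(
    bicluster: Bicluster,
    gene_ids: Sequence[str],
    gene_sets: Mapping[str, set[str]],
    genome_size: int,
) -> pd.DataFrame:
    """Enrichment table for one bicluster: one row per gene set, ascending p.

    Bicluster gene ids not present in any set are counted and logged, never
    raised.  A Bonferroni-adjusted column is included alongside the raw
    p-values as a labelled extension.
    """
    if not gene_sets:
        raise ValidationError("no gene sets supplied")
    members = {gene_ids[i] for i in bicluster.gene_indices}
    known = set().union(*gene_sets.values())
    unknown = len(members - known)
    if unknown:
        logger.info("%d bicluster gene id(s) absent from every gene set", unknown)
    n = len(members)
    rows = []
    for name, genes in gene_sets.items():
        k = len(members & genes)
        inp = EnrichmentInput(k=k, n=n, m_cat=len(genes), g=genome_size)
        rows.append({"set": name, "k": k, "n": n, "m_cat": len(genes),
                     "g": genome_size, "p": hypergeometric_pvalue(inp)})
    table = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    table["p_bonferroni"] = np.minimum(1.0, table["p"] * len(gene_sets))
    return table


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def recovery_score(found: Sequence[Bicluster],
                   truth: Sequence[PlantedBicluster]) -> pd.DataFrame:
    """Best Jaccard overlap of each plant with any found bicluster.

    One row per plant: gene_jaccard and condition_jaccard are maxima over
    found biclusters of the index-set overlaps; cell_jaccard is the maximum
    overlap of the full cell sets.  All zeros when nothing was found.
    """
    rows = []
    for plant in truth:
        tg, tc = set(plant.gene_indices), set(plant.condition_indices)
        tcells = {(i, j) for i in tg for j in tc}
        best_g = best_c = best_cell = 0.0
        for b in found:
            fg, fc = set(b.gene_indices), set(b.condition_indices)
            best_g = max(best_g, _jaccard(fg, tg))
            best_c = max(best_c, _jaccard(fc, tc))
            best_cell = max(best_cell, _jaccard({(i, j) for i in fg for j in fc}, tcells))
        rows.append({"gene_jaccard": best_g, "condition_jaccard": best_c,
                     "cell_jaccard": best_cell})
    return pd.DataFrame(rows, columns=["gene_jaccard", "condition_jaccard", "cell_jaccard"])


def coverage_stats(found: Sequence[Bicluster], n: int, m: int) -> tuple[float, float, float]:
    """Union coverage of the matrix: (gene fraction, condition fraction, cell fraction).

    Cells are counted once no matter how many biclusters contain them.
    """
    genes: set[int] = set()
    conds: set[int] = set()
    cells = np.zeros((n, m), dtype=bool)
    for b in found:
        genes.update(b.gene_indices)
        conds.update(b.condition_indices)
        cells[np.ix_(b.gene_indices, b.condition_indices)] = True
    return len(genes) / n, len(conds) / m, float(cells.sum()) / (n * m)
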