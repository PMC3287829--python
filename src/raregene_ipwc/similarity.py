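"""Inverse-probability weighted similarity scores and the bounded distance
transform.

The allelic score for observing alleles ``x`` and ``y`` in two random
individuals is

    score(x, y) = 1{x = y} / p_x - 1,

where ``p_a = p`` (the minor allele frequency) and ``p_A = 1 - p``. A match
on the rare allele a thus earns ``1/p - 1`` (large), a match on the common
allele earns ``p/(1-p)`` (small), and any mismatch costs 1. Drawing the two
alleles independently at frequencies (p, 1-p) gives the score expectation 0.

The genotypic score between two individuals at one SNP is half the sum of
the allelic scores over the four cross-pairs of their alleles, so e.g.
genotype aa against aA contributes exactly one (a, a) match and one (a, A)
mismatch. Under Hardy-Weinberg genotype frequencies for two independent
individuals, the genotypic score also has expectation 0.

Gene-level similarity sums the per-SNP genotypic scores over the SNPs of the
gene, and is converted to a dissimilarity with

    d(i, j) = exp(-sim(i, j) / a),   a = max(1, max_{i<j} |sim(i, j)| / 20),

so every off-diagonal distance lies in [e^-20, e^20].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .datamodel import GenotypeMatrix

__all__ = [
    "allelic_score",
    "AlleleScoreTable",
    "genotype_score",
    "genotype_score_table",
    "GenotypeScoreTable",
    "hwe_expected_score",
    "SimilarityMatrix",
    "DistanceMatrix",
    "gene_similarity",
    "similarity_to_distance",
    "DISTANCE_LOG_BOUND",
]

#: the distance transform is normalized so |log d| <= this bound (d <= e^20)
DISTANCE_LOG_BOUND = 20.0


def _check_p(p: float) -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(f"allele frequency p={p} must lie strictly in (0, 1)")
    if p > 0.5 + 1e-12:
        raise ValueError(f"p={p} is not a minor allele frequency (p <= 0.5)")


def allelic_score(x: str, y: str, p: float) -> float:
    """Inverse-probability similarity of two alleles ('a' minor, 'A' major)."""
    _check_p(p)
    if x not in ("a", "A") or y not in ("a", "A"):
        raise ValueError("alleles must be 'a' (minor) or 'A' (major)")
    if x != y:
        return -1.0
    p_x = p if x == "a" else 1.0 - p
    return 1.0 / p_x - 1.0


@dataclass
class AlleleScoreTable:
    """The 2x2 allelic score table at minor allele frequency ``p``."""

    p: float
    scores: Dict[Tuple[str, str], float] = field(init=False)

    def __post_init__(self) -> None:
        _check_p(self.p)
        self.scores = {
            (x, y): allelic_score(x, y, self.p)
            for x in ("a", "A")
            for y in ("a", "A")
        }

    def expectation(self) -> float:
        """Closed-form score mean under independent allele draws."""
        freqs = {"a": self.p, "A": 1.0 - self.p}
        return sum(
            freqs[x] * freqs[y] * s for (x, y), s in self.scores.items()
        )


def genotype_score(g1: int, g2: int, p: float) -> float:
    """Similarity of two genotypes given as minor-allele dosages in {0,1,2}.

    Half the sum of allelic scores over the four allele cross-pairs, so that
    (aa, aA) reduces to one (a, a) match plus one (a, A) mismatch.
    """
    _check_p(p)
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ValueError("genotypes must be dosages in {0, 1, 2}")
    alleles = {0: ("A", "A"), 1: ("a", "A"), 2: ("a", "a")}
    total = sum(
        allelic_score(x, y, p) for x in alleles[g1] for y in alleles[g2]
    )
    return 0.5 * total


def genotype_score_table(p: float) -> np.ndarray:
    """3x3 genotypic score table indexed by dosage (0, 1, 2)."""
    return np.array(
        [[genotype_score(i, j, p) for j in (0, 1, 2)] for i in (0, 1, 2)]
    )


def hwe_genotype_frequencies(p: float) -> np.ndarray:
    """Hardy-Weinberg frequencies of dosages (0, 1, 2)."""
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def hwe_expected_score(p: float) -> float:
    """Closed-form mean of the genotypic score for two independent
    individuals under Hardy-Weinberg equilibrium (identically 0)."""
    f = hwe_genotype_frequencies(p)
    t = genotype_score_table(p)
    return float(f @ t @ f)


@dataclass
class GenotypeScoreTable:
    """The symmetric 3x3 genotypic score table at frequency ``p``."""

    p: float
    table: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        _check_p(self.p)
        self.table = genotype_score_table(self.p)

    def expectation(self) -> float:
        return hwe_expected_score(self.p)


@dataclass
class SimilarityMatrix:
    """Per-gene pairwise individual similarity (sum of per-SNP scores)."""

    gene: str
    values: np.ndarray
    snp_columns_used: List[int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DistanceMatrix:
    """Bounded monotone-decreasing transform of a similarity matrix."""

    gene: str
    values: np.ndarray
    normalizer: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def gene_similarity(
    genotypes: GenotypeMatrix, gene_columns: Sequence[int], gene: str = ""
) -> SimilarityMatrix:
    """Pairwise similarity over the SNPs of one gene.

    sim(i, j) = sum over gene SNPs k of the genotypic score of
    (dosage_ik, dosage_jk) at the column's sample MAF. The diagonal holds
    self-similarity (later ignored by the distance transform).
    """
    cols = list(gene_columns)
    if not cols:
        raise ValueError("gene_columns must be nonempty")
    n = genotypes.n_individuals
    sim = np.zeros((n, n))
    mafs = genotypes.mafs()
    for k in cols:
        p = float(mafs[k])
        if p <= 0.0:
            raise ValueError(
                f"column {k} is monomorphic (MAF=0); similarity undefined"
            )
        table = genotype_score_table(p)
        g = genotypes.dosages[:, k].astype(np.intp)
        sim += table[g][:, g]
    return SimilarityMatrix(gene=gene, values=sim, snp_columns_used=cols)


def similarity_to_distance(sim: SimilarityMatrix) -> DistanceMatrix:
    """Map similarity to a bounded dissimilarity, d = exp(-sim / a).

    The normalizer a = max(1, max off-diagonal |sim| / 20) guarantees every
    off-diagonal distance lies in [e^-20, e^20]; the floor at 1 avoids
    amplifying near-zero similarities. The diagonal is forced to 0.
    """
    n = sim.n
    if n < 2:
        raise ValueError("need at least 2 individuals")
    off = ~np.eye(n, dtype=bool)
    max_abs = float(np.abs(sim.values[off]).max())
    a = max(1.0, max_abs / DISTANCE_LOG_BOUND)
    d = np.exp(-sim.values / a)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(gene=sim.gene, values=d, normalizer=a)


def write_distance_matrix(dist: DistanceMatrix, path, individual_ids=None) -> None:
    """Square TSV of the per-gene distances (for external clustering tools)."""
    import pandas as pd

    ids = individual_ids or [str(i) for i in range(dist.n)]
    pd.DataFrame(dist.values, index=ids, columns=ids).to_csv(path, sep="\t")
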