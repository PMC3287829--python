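"""Shared domain types: SNP records, genotype matrices, gene indexes,
traits, and replicated phenotype sets.

Conventions
-----------
* Genotypes are stored as minor-allele dosages in {0, 1, 2}; the minor
  allele is determined from the data (folded so MAF <= 0.5).
* Missing genotypes are not allowed anywhere: inputs must be complete.
* ``maf`` on a :class:`SnpRecord` is the folded minor allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd

QUANTITATIVE = "quantitative"
DICHOTOMOUS = "dichotomous"

#: trait names of a GAW17-style phenotype table
TRAIT_NAMES = ("Q1", "Q2", "Q4", "Affected")


@dataclass
class SnpRecord:
    """Per-SNP metadata.

    ``synonymous`` may be ``None`` when the annotation does not say; such
    SNPs are treated as not-nonsynonymous by the nonsynonymous-only filter.
    """

    snp_id: str
    gene: str = ""
    chromosome: str = ""
    synonymous: Optional[bool] = None
    maf: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(
                f"MAF of {self.snp_id} is {self.maf}; the minor allele "
                "frequency must lie in [0, 0.5]"
            )


class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix with aligned metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` integer array with entries in {0, 1, 2}
        counting copies of the minor allele. No missing values.
    individual_ids
        Unique identifier per row.
    snps
        One :class:`SnpRecord` per column. If a record's ``maf`` is 0 it is
        filled in from the dosage column.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        individual_ids: Sequence[str],
        snps: Sequence[SnpRecord],
    ) -> None:
        dosages = np.asarray(dosages)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if not np.issubdtype(dosages.dtype, np.integer):
            if not np.all(np.equal(np.mod(dosages, 1), 0)):
                raise ValueError("dosages must be integers in {0, 1, 2}")
            dosages = dosages.astype(np.int8)
        if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
            bad = np.unique(dosages[(dosages < 0) | (dosages > 2)])
            raise ValueError(f"dosage entries outside {{0,1,2}}: {bad.tolist()}")
        n, m = dosages.shape
        if len(individual_ids) != n:
            raise ValueError("individual_ids length does not match rows")
        if len(snps) != m:
            raise ValueError("snps length does not match columns")
        ids = list(map(str, individual_ids))
        if len(set(ids)) != n:
            raise ValueError("individual ids must be unique")
        snp_ids = [s.snp_id for s in snps]
        if len(set(snp_ids)) != m:
            raise ValueError("snp ids must be unique")

        self.dosages = dosages.astype(np.int8, copy=False)
        self.individual_ids: List[str] = ids
        self.snps: List[SnpRecord] = list(snps)

        observed = self.column_mafs()
        tol = 1.0 / (2 * n) if n else 0.0
        for rec, obs in zip(self.snps, observed):
            if rec.maf == 0.0:
                rec.maf = float(obs)
            elif abs(rec.maf - obs) > tol + 1e-9:
                raise ValueError(
                    f"stated MAF {rec.maf} of {rec.snp_id} disagrees with the "
                    f"dosage-derived MAF {obs:.6g} by more than 1/(2n)"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> List[str]:
        return [s.snp_id for s in self.snps]

    def column_mafs(self) -> np.ndarray:
        """Minor-allele frequency of every column, computed from dosages."""
        n = self.n_individuals
        if n == 0:
            return np.zeros(self.n_snps)
        freq = self.dosages.sum(axis=0) / (2.0 * n)
        return np.minimum(freq, 1.0 - freq)

    def mafs(self) -> np.ndarray:
        return np.array([s.maf for s in self.snps])

    def column(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None


@dataclass
class GeneIndex:
    """Mapping gene -> ordered genotype-matrix column indices.

    Empty genes are never stored and a column belongs to at most one gene.
    """

    groups: Dict[str, List[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: Dict[int, str] = {}
        for gene, cols in self.groups.items():
            if not cols:
                raise ValueError(f"gene {gene!r} has no columns")
            for c in cols:
                if c in seen:
                    raise ValueError(
                        f"column {c} assigned to both {seen[c]!r} and {gene!r}"
                    )
                seen[c] = gene

    def __contains__(self, gene: str) -> bool:
        return gene in self.groups

    def __getitem__(self, gene: str) -> List[int]:
        return self.groups[gene]

    def __iter__(self) -> Iterator[str]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def genes(self) -> List[str]:
        return list(self.groups)


def build_gene_index(
    snps: Sequence[SnpRecord],
    drop_monomorphic: bool = True,
) -> GeneIndex:
    """Group genotype columns by gene, preserving column order.

    SNPs with an empty gene field are excluded with a warning; monomorphic
    SNPs (MAF = 0) carry no similarity information (the inverse-probability
    score is undefined at p = 0) and are dropped when ``drop_monomorphic``.
    """
    groups: Dict[str, List[int]] = {}
    for idx, rec in enumerate(snps):
        if not rec.gene:
            warnings.warn(f"SNP {rec.snp_id} has no gene; excluded from index")
            continue
        if drop_monomorphic and rec.maf == 0.0:
            warnings.warn(f"SNP {rec.snp_id} is monomorphic (MAF=0); dropped")
            continue
        groups.setdefault(rec.gene, []).append(idx)
    return GeneIndex(groups)


@dataclass
class TraitVector:
    """A single phenotype over the n individuals."""

    values: np.ndarray
    kind: str
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trait values must be 1-D")
        if self.kind not in (QUANTITATIVE, DICHOTOMOUS):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == DICHOTOMOUS:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, [0.0, 1.0])):
                raise ValueError(
                    f"dichotomous trait {self.name!r} has values outside "
                    f"{{0,1}}: {uniq.tolist()}"
                )

    def __len__(self) -> int:
        return self.values.shape[0]


class PhenotypeReplicateSet:
    """Ordered phenotype replicates over one fixed set of individuals.

    Each replicate is a DataFrame indexed by individual id with columns
    Q1, Q2, Q4 (quantitative) and Affected (0/1).
    """

    def __init__(self, replicates: Sequence[pd.DataFrame]) -> None:
        if not len(replicates):
            raise ValueError("at least one replicate is required")
        reps = []
        ref_index = None
        for i, df in enumerate(replicates):
            missing = [c for c in TRAIT_NAMES if c not in df.columns]
            if missing:
                raise ValueError(f"replicate {i} lacks columns {missing}")
            aff = df["Affected"].to_numpy(dtype=float)
            if not np.all(np.isin(np.unique(aff), [0.0, 1.0])):
                raise ValueError(
                    f"replicate {i}: Affected must be 0/1, got "
                    f"{sorted(set(aff.tolist()))}"
                )
            if ref_index is None:
                ref_index = df.index
            elif not df.index.equals(ref_index):
                raise ValueError(
                    f"replicate {i} individuals differ from replicate 0"
                )
            reps.append(df[list(TRAIT_NAMES)].copy())
        self.replicates: List[pd.DataFrame] = reps
        self.individual_ids: List[str] = [str(x) for x in ref_index]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def trait(self, replicate: int, name: str) -> TraitVector:
        kind = DICHOTOMOUS if name == "Affected" else QUANTITATIVE
        values = self.replicates[replicate][name].to_numpy(dtype=float)
        return TraitVector(values=values, kind=kind, name=name)

    def aligned_to(self, genotypes: GenotypeMatrix) -> "PhenotypeReplicateSet":
        """Reorder every replicate to the genotype matrix's individuals.

        Raises with the symmetric difference when the id sets disagree.
        """
        geno = set(genotypes.individual_ids)
        pheno = set(self.individual_ids)
        if geno != pheno:
            only_geno = sorted(geno - pheno)
            only_pheno = sorted(pheno - geno)
            raise ValueError(
                "individuals differ between genotypes and phenotypes; "
                f"genotypes-only={only_geno[:5]} phenotypes-only={only_pheno[:5]}"
            )
        order = genotypes.individual_ids
        return PhenotypeReplicateSet([df.loc[order] for df in self.replicates])
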