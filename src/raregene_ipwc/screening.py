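"""End-to-end gene screen across traits, partition sizes, SNP filters, and
phenotype replicates.

For every gene the pipeline is: filter SNPs (all, or nonsynonymous only)
-> inverse-probability similarity -> bounded distance -> Ward tree -> cuts
at each requested partition size -> association tests. Across replicates,
each gene's selections (Bonferroni-significant for ANOVA / chi-square, or
in the top fraction by the partition-retention I) are counted per partition
size, and the average count across the partition-size sweep ranks genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .association import (
    SelectionRule,
    TestResult,
    anova_test,
    apply_selection,
    chisq_test,
    partition_retention_i,
)
from .datamodel import (
    DICHOTOMOUS,
    GeneIndex,
    GenotypeMatrix,
    PhenotypeReplicateSet,
    TraitVector,
    build_gene_index,
)
from .partitioning import Partition, cut_tree, ward_tree
from .similarity import gene_similarity, similarity_to_distance
from .simulator import SimulationModel, TruthTable, build_truth_table

__all__ = [
    "ScreenConfig",
    "GeneTraitCount",
    "GeneEffectSize",
    "ScreenResults",
    "screen_gene",
    "screen_all",
    "gene_effect_sizes",
    "power_curve",
    "write_results_tsv",
    "write_counts_tsv",
]

DEFAULT_KS = (5, 6, 7, 8, 9, 10)
ALL_METHODS = ("anova", "chisq", "partition_retention")


def _default_selection() -> Dict[str, SelectionRule]:
    return {
        "anova": SelectionRule("bonferroni", alpha=0.05),
        "chisq": SelectionRule("bonferroni", alpha=0.05),
        "partition_retention": SelectionRule("top_fraction", fraction=0.001),
    }


@dataclass
class ScreenConfig:
    """Configuration of one screen run."""

    ks: Tuple[int, ...] = DEFAULT_KS
    snp_filter: str = "all"
    methods: Tuple[str, ...] = ALL_METHODS
    traits: Tuple[str, ...] = ("Q1", "Q2", "Q4", "Affected")
    selection: Dict[str, SelectionRule] = field(default_factory=_default_selection)
    ward_dialect: str = "ward.D"
    seed: int = 0
    aggregation: str = "per_k"

    def __post_init__(self) -> None:
        if self.snp_filter not in ("all", "nonsynonymous_only"):
            raise ValueError(f"unknown snp_filter {self.snp_filter!r}")
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.aggregation not in ("per_k", "best_k"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if any(k < 2 for k in self.ks):
            raise ValueError("partition sizes must be >= 2")

    def methods_for(self, trait_kind: str) -> List[str]:
        """chi-square applies only to dichotomous traits."""
        return [
            m
            for m in self.methods
            if not (m == "chisq" and trait_kind != DICHOTOMOUS)
        ]


@dataclass
class GeneTraitCount:
    """Selection counts of one (gene, trait, method) across replicates."""

    gene: str
    trait: str
    method: str
    counts: Dict[int, int]

    @property
    def average_count(self) -> float:
        return float(np.mean(list(self.counts.values())))


@dataclass
class GeneEffectSize:
    """Gene-wise total effect: sum over SNPs of MAF_i x beta_i."""

    gene: str
    total_effect: float


@dataclass
class ScreenResults:
    counts: List[GeneTraitCount]
    n_replicates: int
    genes: List[str]
    skipped_genes: List[str]

    def top_genes(
        self, trait: str, method: str, n: int = 10
    ) -> List[Tuple[str, float]]:
        """Genes ranked by average selection count (ties by gene id)."""
        rows = [
            (c.gene, c.average_count)
            for c in self.counts
            if c.trait == trait and c.method == method
        ]
        rows.sort(key=lambda t: (-t[1], t[0]))
        return rows[:n]


def _filter_columns(
    genotypes: GenotypeMatrix, columns: Sequence[int], snp_filter: str
) -> List[int]:
    if snp_filter == "all":
        return list(columns)
    # nonsynonymous only: an absent flag is treated as not nonsynonymous
    return [c for c in columns if genotypes.snps[c].synonymous is False]


def _gene_partitions(
    genotypes: GenotypeMatrix,
    gene: str,
    columns: Sequence[int],
    config: ScreenConfig,
) -> Tuple[List[Tuple[int, Partition]], bool]:
    """(requested k, Partition) pairs for each k, from one Ward tree.

    When the gene offers fewer distinct genotype profiles than k, the cut
    is capped at the number of distinct profiles (recorded by the returned
    flag) but stays associated with the requested k, so the gene keeps one
    entry per screen family; sizes capped below 2 produce no partition.
    """
    sub = genotypes.dosages[:, list(columns)]
    n_profiles = np.unique(sub, axis=0).shape[0]
    sim = gene_similarity(genotypes, columns, gene=gene)
    dist = similarity_to_distance(sim)
    tree = ward_tree(dist, dialect=config.ward_dialect)
    parts: List[Tuple[int, Partition]] = []
    capped = False
    for k in config.ks:
        k_eff = min(k, n_profiles)
        if k_eff < k:
            capped = True
        if k_eff < 2:
            continue
        parts.append((k, cut_tree(tree, k_eff)))
    return parts, capped


def screen_gene(
    genotypes: GenotypeMatrix,
    gene: str,
    traits: Sequence[TraitVector],
    config: ScreenConfig,
    gene_index: Optional[GeneIndex] = None,
) -> List[TestResult]:
    """All association tests for one gene: (trait, method, k) combinations."""
    if gene_index is None:
        gene_index = build_gene_index(genotypes.snps)
    if gene not in gene_index:
        raise KeyError(f"gene {gene!r} not in the gene index")
    columns = _filter_columns(genotypes, gene_index[gene], config.snp_filter)
    if not columns:
        return []
    parts, capped = _gene_partitions(genotypes, gene, columns, config)
    results: List[TestResult] = []
    for y in traits:
        for method in config.methods_for(y.kind):
            for _, part in parts:
                res = _run_test(method, y, part)
                res.gene = gene
                if capped:
                    res.flags.add("k_capped")
                results.append(res)
    return results


def _run_test(method: str, y: TraitVector, part: Partition) -> TestResult:
    if method == "anova":
        res = anova_test(y, part)
    elif method == "chisq":
        res = chisq_test(y, part)
    elif method == "partition_retention":
        pr = partition_retention_i(y, part)
        res = TestResult(
            "partition_retention", pr.i_score, None, trait=y.name, k=part.k,
            flags={"degenerate"} if pr.degenerate else set(),
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown method {method!r}")
    res.trait, res.k = y.name, part.k
    return res


def screen_all(
    genotypes: GenotypeMatrix,
    phenos: PhenotypeReplicateSet,
    config: ScreenConfig,
    gene_index: Optional[GeneIndex] = None,
) -> ScreenResults:
    """Run the full screen over genes and replicates and count selections.

    For every replicate and every (trait, method, k), each gene's test is
    computed and selection applied across genes (Bonferroni with n_tests =
    number of genes in that screen, or top-fraction on the statistic);
    counts accumulate per (gene, trait, method, k) over replicates.
    """
    if gene_index is None:
        gene_index = build_gene_index(genotypes.snps)
    if phenos.n_individuals != genotypes.n_individuals:
        raise ValueError("phenotypes and genotypes cover different cohorts")

    # partitions depend only on the fixed genotypes: compute once per gene
    partitions: Dict[str, List[Tuple[int, Partition]]] = {}
    skipped: List[str] = []
    for gene in sorted(gene_index.genes):
        columns = _filter_columns(genotypes, gene_index[gene], config.snp_filter)
        if not columns:
            skipped.append(gene)
            continue
        parts, _ = _gene_partitions(genotypes, gene, columns, config)
        if parts:
            partitions[gene] = parts
        else:
            skipped.append(gene)
    genes = sorted(partitions)

    counters: Dict[Tuple[str, str, str], Dict[int, int]] = {}
    for rep in range(phenos.n_replicates):
        for trait_name in config.traits:
            y = phenos.trait(rep, trait_name)
            for method in config.methods_for(y.kind):
                rule = config.selection[method]
                per_k: Dict[int, List[TestResult]] = {}
                for gene in genes:
                    for k_req, part in partitions[gene]:
                        res = _run_test(method, y, part)
                        res.gene = gene
                        per_k.setdefault(k_req, []).append(res)
                if config.aggregation == "per_k":
                    for k, results in per_k.items():
                        chosen = apply_selection(results, rule)
                        for g in chosen:
                            counters.setdefault(
                                (g, trait_name, method), {}
                            ).setdefault(k, 0)
                            counters[(g, trait_name, method)][k] += 1
                else:  # best_k: judge each gene at its most significant k
                    best: Dict[str, Tuple[int, TestResult]] = {}
                    for k_req, results in per_k.items():
                        for res in results:
                            cur = best.get(res.gene)
                            if cur is None or _more_significant(res, cur[1]):
                                best[res.gene] = (k_req, res)
                    chosen = apply_selection(
                        [res for _, res in best.values()], rule
                    )
                    for g in chosen:
                        k = best[g][0]
                        counters.setdefault(
                            (g, trait_name, method), {}
                        ).setdefault(k, 0)
                        counters[(g, trait_name, method)][k] += 1

    counts: List[GeneTraitCount] = []
    for gene in genes:
        for trait_name in config.traits:
            kind = DICHOTOMOUS if trait_name == "Affected" else "quantitative"
            for method in config.methods_for(kind):
                raw = counters.get((gene, trait_name, method), {})
                full = {k: raw.get(k, 0) for k in config.ks}
                counts.append(GeneTraitCount(gene, trait_name, method, full))
    return ScreenResults(
        counts=counts,
        n_replicates=phenos.n_replicates,
        genes=genes,
        skipped_genes=skipped,
    )


def _more_significant(a: TestResult, b: TestResult) -> bool:
    if a.p_value is not None and b.p_value is not None:
        return a.p_value < b.p_value
    return a.statistic > b.statistic


def gene_effect_sizes(
    model: Union[SimulationModel, TruthTable],
    genotypes: GenotypeMatrix,
    trait: str = "Q1",
) -> List[GeneEffectSize]:
    """Gene-wise total effect sizes sum_i MAF_i x beta_i for one trait.

    beta is 0 for noncausal SNPs, so genes without causal SNPs have total
    effect 0. MAFs are the sample MAFs of the genotype matrix.
    """
    truth = (
        model
        if isinstance(model, TruthTable)
        else build_truth_table(genotypes, model)
    )
    effects = truth.gene_effects.get(trait, {})
    genes = sorted({s.gene for s in genotypes.snps if s.gene})
    return [GeneEffectSize(g, float(effects.get(g, 0.0))) for g in genes]


def power_curve(
    counts: Iterable[GeneTraitCount],
    effects: Iterable[GeneEffectSize],
    n_replicates: int,
) -> pd.DataFrame:
    """Detection frequency (average count / replicates) against effect size.

    Returns a DataFrame (gene, effect, detection_frequency) sorted by
    effect then gene.
    """
    eff = {e.gene: e.total_effect for e in effects}
    rows = []
    for c in counts:
        if c.gene not in eff:
            raise KeyError(f"no effect size for gene {c.gene!r}")
        rows.append(
            {
                "gene": c.gene,
                "effect": eff[c.gene],
                "detection_frequency": c.average_count / n_replicates,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "effect", "detection_frequency"])
    return df.sort_values(["effect", "gene"], kind="mergesort").reset_index(
        drop=True
    )


def write_results_tsv(results: Iterable[TestResult], path: Union[str, Path]) -> None:
    """Long-format results table: gene, trait, method, k, statistic, p, selected."""
    rows = [
        {
            "gene": r.gene,
            "trait": r.trait,
            "method": r.method,
            "k": r.k,
            "statistic": f"{r.statistic:.10g}",
            "p_value": "" if r.p_value is None else f"{r.p_value:.10g}",
            "selected": "" if r.selected is None else str(bool(r.selected)),
            "flags": ",".join(sorted(r.flags)),
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["gene", "trait", "method", "k", "statistic", "p_value",
                 "selected", "flags"],
    ).to_csv(path, sep="\t", index=False)


def write_counts_tsv(screen: ScreenResults, path: Union[str, Path]) -> None:
    rows = []
    for c in screen.counts:
        row = {"gene": c.gene, "trait": c.trait, "method": c.method}
        for k in sorted(c.counts):
            row[f"count_k{k}"] = c.counts[k]
        row["average_count"] = f"{c.average_count:.10g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
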