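# raregene-ipwc

Gene-based association screening for genes carrying multiple, potentially
rare variants, by **inverse-probability weighted clustering**.

Single-SNP association tests lose essentially all power once the minor
allele frequency (MAF) drops below ~1%, so rare-variant analysis groups
SNPs by gene and collapses their genotypes before testing. Instead of a
univariate burden score, this package collapses a gene's multi-SNP
genotypes into a **partition of the individuals**: pairwise genotype
similarity is scored with inverse-probability weights — a match on an
allele of frequency *p* scores 1/*p* − 1, so sharing a rare allele counts
far more than sharing a common one, and the score has mean 0 under random
pairing — summed over the gene's SNPs, converted to a bounded distance
d = exp(−sim/a) with a = max(1, max|sim|/20), and clustered with Ward's
method. The tree is cut into K = 5…10 groups, and partition–trait
association is tested with one-way ANOVA, the chi-square test of
independence (dichotomous traits), and the partition-retention influence
statistic

    I = Σᵢ nᵢ² (ȳᵢ − ȳ)² / (n s²),

which under the null converges to a weighted sum of 1-df chi-squares with
mean 1, tolerates sparse partitions better than chi-square, and applies to
quantitative and 0/1 traits alike. Genes are selected per screen by
Bonferroni (ANOVA, chi-square) or by taking the top 0.1% by I, and
selections are counted across phenotype replicates and averaged over the
partition-size sweep to rank genes. A Fisher exact test for 2×c tables is
included for diagnosing partition–SNP cross tables, and a synthetic
mini-exome simulator (697 individuals, 209 cases/488 controls, 74% rare
SNPs, replicated phenotypes with known per-SNP effects β) makes the whole
screen exercisable with no external data.

Intended users: statistical geneticists benchmarking rare-variant
collapsing strategies, and anyone who wants a partition-based alternative
to burden/kernel tests on complete biallelic dosage data.

## Worked example

Simulate a 50-gene exome, plant a causal SNP (gene-wise total effect
Σ MAF·β = 0.35 on trait Q1), and screen:

```python
from dataclasses import replace
from raregene_ipwc import (
    ScreenConfig, SimulationModel, simulate_genotypes, simulate_phenotypes,
    screen_all, gene_effect_sizes, power_curve,
)
from raregene_ipwc.datamodel import build_gene_index

model = SimulationModel(n_genes=50, n_replicates=20, seed=1)
exome = simulate_genotypes(model)
index = build_gene_index(exome.snps)
mafs = exome.mafs()
col = max(index["G0007"], key=lambda c: mafs[c])
model = replace(model, causal_betas={"Q1": {exome.snp_ids[col]: 0.35 / mafs[col]}})
phenos, truth = simulate_phenotypes(exome, model)

config = ScreenConfig(methods=("anova", "partition_retention"), traits=("Q1",))
result = screen_all(exome, phenos, config)
for gene, avg in result.top_genes("Q1", "anova", n=3):
    print(f"{gene}  average count {avg:.2f} / {result.n_replicates}")

effects = gene_effect_sizes(truth, exome, "Q1")
curve = power_curve([c for c in result.counts if c.method == "anova"],
                    effects, result.n_replicates)
print(curve.tail(3).to_string(index=False))
```

Output:

```
G0007  average count 20.00 / 20
G0040  average count 1.00 / 20
G0037  average count 0.33 / 20
 gene  effect  detection_frequency
G0049    0.00                  0.0
G0050    0.00                  0.0
G0007    0.35                  1.0
```

The causal gene G0007 is Bonferroni-significant in all 20 of 20 phenotype
replicates at every partition size (average count 20, detection frequency
1.0), while null genes are selected only sporadically. G0040's average
count of 1.00 illustrates a *consistent* false positive: genotypes are
fixed across replicates, so a chance correlation between one gene's
partition and a causal SNP recurs in every replicate — the package's
Fisher 2×c diagnostic (`fisher_exact_rxc`) is provided to probe exactly
this situation.

The same screen is available from the shell:

```sh
raregene-ipwc simulate --config sim.yaml --out data/
raregene-ipwc screen --genotypes data/genotypes.tsv \
    --annotation data/annotation.tsv --phenotypes data/phenotypes \
    --ks 5:10 --filter all --methods anova,chisq,pr \
    --select bonferroni:0.05,top:0.001 --seed 1 --out results/
```

writing `results.tsv`, `counts.tsv`, `top_genes.tsv`, and a `run.log`.

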