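"""Readers and writers for genotype, SNP-annotation, and phenotype files.

Supported genotype formats:

* VCF v4.x, biallelic sites with a GT field (read through cyvcf2). Optional
  INFO keys ``GENE`` and ``SYN`` carry gene affiliation and the
  synonymous flag so a VCF can round-trip annotations.
* A plain dosage matrix TSV: header row of SNP ids, first column of
  individual ids, entries in {0, 1, 2}.

Dosages always count the *minor* allele: a column whose alternate-allele
frequency exceeds 0.5 is folded (dosage -> 2 - dosage) at load. Missing
genotypes are a hard error; inputs must be complete.
"""

from __future__ import annotations

import glob as _glob
import warnings
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import (
    GeneIndex,
    GenotypeMatrix,
    PhenotypeReplicateSet,
    SnpRecord,
    TRAIT_NAMES,
    build_gene_index,
)

PathLike = Union[str, Path]


def _fold_minor(dosages: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Fold alternate-allele dosages to minor-allele dosages column-wise.

    Ties at frequency exactly 0.5 keep the file's alternate allele as the
    minor allele. Returns (folded dosages, boolean fold mask).
    """
    n = dosages.shape[0]
    freq = dosages.sum(axis=0) / (2.0 * n)
    flip = freq > 0.5
    folded = dosages.copy()
    folded[:, flip] = 2 - folded[:, flip]
    return folded, flip


def read_genotypes(path: PathLike, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or dosage-matrix TSV.

    ``format`` is one of ``vcf``, ``matrix-tsv``, or ``auto`` (by suffix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "auto":
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "matrix-tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix-tsv":
        return _read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_matrix_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing genotype entries are not allowed")
    raw = df.to_numpy()
    if not np.all(np.isin(raw, [0, 1, 2])):
        bad = sorted(set(np.asarray(raw).ravel().tolist()) - {0, 1, 2})
        raise ValueError(f"{path}: non-{{0,1,2}} dosage entries {bad[:5]}")
    dosages, _ = _fold_minor(raw.astype(np.int8))
    snps = [SnpRecord(snp_id=str(c)) for c in df.columns]
    return GenotypeMatrix(dosages, [str(i) for i in df.index], snps)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    dosage_cols: List[np.ndarray] = []
    snps: List[SnpRecord] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: multiallelic record at {var.CHROM}:{var.POS} "
                "(biallelic sites only)"
            )
        col = np.empty(len(individual_ids), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                raise ValueError(
                    f"{path}: missing genotype at {var.CHROM}:{var.POS} "
                    f"sample {individual_ids[i]} (imputation is out of scope)"
                )
            col[i] = sum(alleles)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        gene = var.INFO.get("GENE") or ""
        syn_raw = var.INFO.get("SYN")
        synonymous = None if syn_raw in (None, "NA") else bool(int(syn_raw))
        snps.append(
            SnpRecord(snp_id=str(snp_id), gene=str(gene),
                      chromosome=str(var.CHROM), synonymous=synonymous)
        )
        dosage_cols.append(col)
    vcf.close()
    if not dosage_cols:
        raise ValueError(f"{path}: VCF contains no variant records")
    dosages, _ = _fold_minor(np.stack(dosage_cols, axis=1))
    return GenotypeMatrix(dosages, individual_ids, snps)


def write_genotypes(
    genotypes: GenotypeMatrix, path: PathLike, format: str = "auto"
) -> None:
    """Write a genotype matrix as dosage TSV or minimal VCF."""
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix == ".vcf" else "matrix-tsv"
    if format == "matrix-tsv":
        df = pd.DataFrame(
            genotypes.dosages,
            index=pd.Index(genotypes.individual_ids, name="individual_id"),
            columns=genotypes.snp_ids,
        )
        df.to_csv(path, sep="\t")
        return
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write(
            '##INFO=<ID=SYN,Number=1,Type=Integer,'
            'Description="1 if synonymous, 0 if nonsynonymous">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for k, rec in enumerate(genotypes.snps):
            chrom = rec.chromosome or "1"
            info = []
            if rec.gene:
                info.append(f"GENE={rec.gene}")
            if rec.synonymous is not None:
                info.append(f"SYN={int(rec.synonymous)}")
            info_s = ";".join(info) if info else "."
            calls = "\t".join(gt_code[int(d)] for d in genotypes.dosages[:, k])
            fh.write(
                f"{chrom}\t{k + 1}\t{rec.snp_id}\tA\tT\t.\tPASS\t{info_s}\tGT\t{calls}\n"
            )


def read_snp_annotation(
    path: PathLike, genotypes: Optional[GenotypeMatrix] = None
) -> Tuple[List[SnpRecord], GeneIndex]:
    """Read the SNP annotation TSV (snp_id, gene, chromosome, synonymous).

    When ``genotypes`` is given, annotations are applied in place to the
    matching genotype columns, annotation rows for SNPs absent from the
    matrix are reported and dropped, and the returned :class:`GeneIndex`
    maps genes to genotype-matrix column indices (monomorphic columns
    excluded). Without ``genotypes``, the index is over annotation row order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "gene", "chromosome", "synonymous"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {missing}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"{path}: duplicate snp_id {dup[:5]}")

    def parse_syn(v: object) -> Optional[bool]:
        s = str(v).strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        if s in ("na", "nan", "", "none", "."):
            return None
        raise ValueError(f"unparseable synonymous flag {v!r}")

    records: List[SnpRecord] = []
    for _, row in df.iterrows():
        gene = "" if pd.isna(row["gene"]) else str(row["gene"]).strip()
        records.append(
            SnpRecord(
                snp_id=str(row["snp_id"]),
                gene=gene,
                chromosome="" if pd.isna(row["chromosome"]) else str(row["chromosome"]),
                synonymous=parse_syn(row["synonymous"]),
            )
        )

    if genotypes is None:
        # no genotypes: MAFs unknown, so nothing can be called monomorphic
        return records, build_gene_index(records, drop_monomorphic=False)

    by_id = {r.snp_id: r for r in records}
    dropped = [r.snp_id for r in records if r.snp_id not in set(genotypes.snp_ids)]
    if dropped:
        warnings.warn(
            f"{len(dropped)} annotated SNPs absent from genotypes, dropped: "
            f"{dropped[:5]}"
        )
    kept: List[SnpRecord] = []
    for col_rec in genotypes.snps:
        ann = by_id.get(col_rec.snp_id)
        if ann is not None:
            col_rec.gene = ann.gene
            col_rec.chromosome = ann.chromosome or col_rec.chromosome
            col_rec.synonymous = ann.synonymous
        kept.append(col_rec)
    return [r for r in records if r.snp_id not in set(dropped)], build_gene_index(kept)


def write_snp_annotation(snps: Sequence[SnpRecord], path: PathLike) -> None:
    rows = [
        {
            "snp_id": s.snp_id,
            "gene": s.gene,
            "chromosome": s.chromosome,
            "synonymous": "NA" if s.synonymous is None else str(bool(s.synonymous)),
        }
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_phenotype_file(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: phenotype file lacks individual_id column")
    missing = [c for c in TRAIT_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype file lacks columns {missing}")
    df = df.set_index(df["individual_id"].astype(str))[list(TRAIT_NAMES)]
    return df


def read_phenotypes(
    paths: Union[PathLike, Iterable[PathLike]],
    genotypes: Optional[GenotypeMatrix] = None,
) -> PhenotypeReplicateSet:
    """Read one or many phenotype replicate TSVs.

    ``paths`` may be a single file, a glob pattern, or an iterable of files;
    glob matches are sorted so replicate order follows filename order. With
    ``genotypes`` given, individuals are aligned to the genotype matrix.
    """
    if isinstance(paths, (str, Path)):
        p = str(paths)
        files = sorted(_glob.glob(p)) if any(ch in p for ch in "*?[") else [p]
    else:
        files = [str(p) for p in paths]
    if not files:
        raise FileNotFoundError(f"no phenotype files match {paths!r}")
    reps = [_read_phenotype_file(Path(f)) for f in files]
    pheno = PhenotypeReplicateSet(reps)
    if genotypes is not None:
        pheno = pheno.aligned_to(genotypes)
    return pheno


def write_phenotypes(
    phenos: PhenotypeReplicateSet, out_dir: PathLike, stem: str = "pheno"
) -> List[Path]:
    """Write one TSV per replicate as ``<stem>_rep<idx>.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(phenos.n_replicates)))
    paths = []
    for i, df in enumerate(phenos.replicates, start=1):
        out = out_dir / f"{stem}_rep{i:0{width}d}.tsv"
        full = df.copy()
        full.insert(0, "individual_id", phenos.individual_ids)
        full["Affected"] = full["Affected"].astype(int)
        full.to_csv(out, sep="\t", index=False, float_format="%.10g")
        paths.append(out)
    return paths
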