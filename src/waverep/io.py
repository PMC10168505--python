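"""Plain-text I/O: curve matrices, dosage tables, VCF (DS field), summary
statistics, loci BED, and encodings."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import AssocResult, Locus
from .synthetic import GenotypeMatrix


def write_curves_tsv(path: str, curves: np.ndarray,
                     ids: list[str] | None = None) -> None:
    """One row per individual, one column per sample."""
    x = np.asarray(curves, dtype=float)
    df = pd.DataFrame(x)
    df.insert(0, "individual_id", ids if ids is not None
              else [f"I{i}" for i in range(len(x))])
    df.to_csv(path, sep="\t", index=False)


def read_curves_tsv(path: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    ids = df["individual_id"].astype(str).tolist()
    return df.drop(columns="individual_id").to_numpy(dtype=float), ids


def write_genotypes_tsv(dosage_path: str, variants_path: str,
                        G: GenotypeMatrix) -> None:
    """Dosage table (individual x variant, variant-id header) plus a
    variant metadata table (ID, CHR, POS, MAF)."""
    pd.DataFrame(G.dosages, columns=G.variant_ids).to_csv(
        dosage_path, sep="\t", index=False)
    pd.DataFrame({"ID": G.variant_ids, "CHR": G.chromosome,
                  "POS": G.position_bp, "MAF": G.maf}).to_csv(
        variants_path, sep="\t", index=False)


def read_genotypes_tsv(dosage_path: str, variants_path: str) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t")
    meta = pd.read_csv(variants_path, sep="\t")
    if list(dos.columns) != meta["ID"].astype(str).tolist():
        raise ValueError("dosage header and variant table IDs disagree")
    return GenotypeMatrix(dosages=dos.to_numpy(dtype=float),
                          variant_ids=list(dos.columns),
                          chromosome=meta["CHR"].to_numpy(dtype=np.int64),
                          position_bp=meta["POS"].to_numpy(dtype=np.int64),
                          maf=meta["MAF"].to_numpy(dtype=float))


def write_vcf(path: str, G: GenotypeMatrix,
              sample_ids: list[str] | None = None) -> None:
    """Uncompressed VCF with per-sample dosages in the DS FORMAT field.

    Alleles are synthetic (REF=A, ALT=C); genotypes are emitted as hard
    calls from rounded dosage alongside DS.
    """
    n = G.n_individuals
    samples = sample_ids or [f"I{i}" for i in range(n)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Dosage">\n')
        for chrom in sorted(set(G.chromosome.tolist())):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(G.n_variants):
            ds = G.dosages[:, j]
            calls = np.clip(np.round(ds), 0, 2).astype(int)
            fields = [f"{gt_map[c]}:{d:.3f}" for c, d in zip(calls, ds)]
            fh.write(f"{G.chromosome[j]}\t{G.position_bp[j]}\t"
                     f"{G.variant_ids[j]}\tA\tC\t.\t.\t.\tGT:DS\t"
                     + "\t".join(fields) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read dosages from the DS field (falling back to GT allele counts)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    rows, ids, chroms, poss = [], [], [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is not None:
            rows.append(np.asarray(ds, dtype=float).ravel())
        else:
            gts = np.asarray(var.genotypes)[:, :2]
            rows.append(gts.sum(axis=1).astype(float))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(int(var.CHROM))
        poss.append(var.POS)
    vcf.close()
    dosages = np.column_stack(rows) if rows else np.empty((0, 0))
    af = dosages.mean(axis=0) / 2 if dosages.size else np.empty(0)
    return GenotypeMatrix(dosages=dosages, variant_ids=ids,
                          chromosome=np.asarray(chroms, dtype=np.int64),
                          position_bp=np.asarray(poss, dtype=np.int64),
                          maf=np.minimum(af, 1 - af))


def write_summary_stats(path: str, assoc: AssocResult) -> None:
    """GWAS-catalog-compatible columns: CHR POS ID A1 A2 BETA SE P N."""
    t = assoc.table
    out = pd.DataFrame({"CHR": t["CHR"], "POS": t["POS"], "ID": t["ID"],
                        "A1": "C", "A2": "A", "BETA": t["BETA"],
                        "SE": t["SE"], "P": t["P"], "N": assoc.n_used})
    out.to_csv(path, sep="\t", index=False)


def write_loci_bed(path: str, loci: list[Locus]) -> None:
    """BED is 0-based half-open: start = start_bp - 1, end = end_bp."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chromosome}\t{loc.start_bp - 1}\t{loc.end_bp}\t"
                     f"{loc.lead_variant_id}\t{loc.lead_p:.3g}\n")


def write_encodings_tsv(path: str, values: np.ndarray,
                        ids: list[str] | None = None,
                        prefix: str = "coord") -> None:
    x = np.asarray(values, dtype=float)
    df = pd.DataFrame(x, columns=[f"{prefix}{j + 1}" for j in range(x.shape[1])])
    df.insert(0, "individual_id", ids if ids is not None
              else [f"I{i}" for i in range(len(x))])
    df.to_csv(path, sep="\t", index=False)
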