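"""Plain-text genotype and sidecar I/O.

Genotypes travel either as a VCF with GT fields (readable by any variant
toolchain) or as a plain TSV dosage matrix; the simulation ground truth is
serialized as a YAML sidecar for reproducibility audits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .simulate import GroundTruth, LDPanel

__all__ = ["write_vcf", "read_vcf_dosages", "write_dosage_tsv", "read_dosage_tsv",
           "write_ground_truth", "read_ground_truth"]

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, genotypes: np.ndarray, panel: LDPanel, sample_ids=None) -> None:
    """Write dosages as a minimal VCFv4.2 with GT genotypes.

    The panel's effect allele (the one the dosage counts) is written as ALT,
    so ``ALT dosage == stored dosage``.
    """
    n, m = genotypes.shape
    if sample_ids is None:
        sample_ids = [f"id{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j in range(m):
            gts = "\t".join(_GT_CODES[int(g)] for g in genotypes[:, j])
            fh.write(f"{panel.chrom}\t{panel.positions[j]}\trs{j + 1}\tG\tA\t.\t.\t.\tGT\t"
                     + gts + "\n")


def read_vcf_dosages(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read ALT-allele dosages from a VCF (cyvcf2 when importable, else a
    plain-text fallback for the minimal dialect written here).

    Returns ``(dosages (n, m) int8, variants DataFrame[SNP, CHR, BP, REF, ALT])``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    rows, dosage_cols = [], []
    if VCF is not None:
        vcf = VCF(str(path), gts012=True)
        for var in vcf:
            rows.append({"SNP": var.ID, "CHR": var.CHROM, "BP": var.POS,
                         "REF": var.REF, "ALT": var.ALT[0]})
            dosage_cols.append(var.gt_types.copy())
        vcf.close()
    else:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                rows.append({"SNP": parts[2], "CHR": parts[0], "BP": int(parts[1]),
                             "REF": parts[3], "ALT": parts[4]})
                dosage_cols.append([sum(int(a) for a in gt.replace("|", "/").split("/"))
                                    for gt in parts[9:]])
    variants = pd.DataFrame(rows)
    dosages = np.asarray(dosage_cols, dtype=np.int8).T
    return dosages, variants


def write_dosage_tsv(path, genotypes: np.ndarray, snp_ids, sample_ids=None) -> None:
    n = genotypes.shape[0]
    if sample_ids is None:
        sample_ids = [f"id{i + 1}" for i in range(n)]
    df = pd.DataFrame(genotypes, columns=list(snp_ids))
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> tuple[np.ndarray, list, list]:
    df = pd.read_csv(path, sep="\t")
    sample_ids = df["sample_id"].tolist()
    snp_ids = [c for c in df.columns if c != "sample_id"]
    return df[snp_ids].to_numpy(dtype=np.int8), snp_ids, sample_ids


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Structured sidecar with the generating values (matrices as lists)."""
    payload = {
        "S_true": truth.S_true.tolist(),
        "Lambda": truth.Lambda.tolist(),
        "Psi": truth.Psi.tolist(),
        "Phi": truth.Phi.tolist(),
        "h2": truth.h2.tolist(),
        "realized_h2": truth.realized_h2.tolist(),
        "overlap_n": truth.overlap_n.tolist(),
        "expected_cross_intercept": truth.expected_cross_intercept.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {k: np.asarray(v) for k, v in payload.items()}
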