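"""Reading and writing the pipeline's plain-text tables.

All artifacts are tab-separated tables with ``#``-prefixed header comments
(seed, stage parameters), plus an optional minimal VCF export of validation
genotypes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import ANTIBODIES
from .simulate import snp_columns


def write_table(
    df: pd.DataFrame, path: str | Path, comments: Mapping[str, object] | None = None
) -> Path:
    """Write a TSV with ``# key: value`` header comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_table_comments(path: str | Path) -> dict[str, str]:
    """Parse the ``# key: value`` header comments of a table."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, value = line[1:].split(":", 1)
                out[key.strip()] = value.strip()
    return out


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    stage: str,
    seed: int | None,
    parameters: Mapping[str, object],
    inputs: Mapping[str, str | Path],
    outputs: Mapping[str, str | Path],
) -> Path:
    """Machine-readable run manifest with input/output checksums.

    Deliberately timestamp-free so identical configurations produce
    byte-identical manifests.
    """
    path = Path(path)
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": dict(parameters),
        "inputs": {k: sha256_file(v) for k, v in inputs.items()},
        "outputs": {k: sha256_file(v) for k, v in outputs.items()},
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_vcf(subjects: pd.DataFrame, path: str | Path) -> Path:
    """Minimal VCF 4.2 export of subject genotypes (GT field only).

    Simulated SNPs carry placeholder coordinates (chromosome 1, evenly
    spaced positions) and generic REF/ALT alleles; the export exists for
    interoperability, not for coordinate-based analyses.
    """
    path = Path(path)
    snps = snp_columns(subjects)
    samples = subjects["subject"].tolist()
    geno = subjects.set_index("subject")[snps]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolgwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i, snp in enumerate(snps, start=1):
            calls = [
                code.get(g, "./.") if pd.notna(g) else "./."
                for g in geno[snp]
            ]
            fh.write(
                f"1\t{i * 1000}\t{snp}\tA\tB\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
    return path


def read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    """Read GT calls from a VCF into a subject x SNP minor-allele-count table."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = vcf.samples
    data: dict[str, list[float]] = {}
    for variant in vcf:
        counts = []
        for gt in variant.genotypes:
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                counts.append(float("nan"))
            else:
                counts.append(float(sum(alleles)))
        data[variant.ID] = counts
    return pd.DataFrame(data, index=pd.Index(samples, name="subject"))


def merge_vcf_phenotypes(
    vcf_path: str | Path, phenotype_table: pd.DataFrame
) -> pd.DataFrame:
    """Join VCF genotypes to a phenotype table on the subject id column."""
    geno = read_vcf_genotypes(vcf_path)
    merged = phenotype_table.merge(
        geno, left_on="subject", right_index=True, how="inner"
    )
    return merged


def subject_table_columns(subjects: pd.DataFrame) -> list[str]:
    """Canonical column order for subject TSVs."""
    meta = [
        c
        for c in (
            "subject", "ancestry", "role", "group", "ifn_score", "age",
            *[f"ab_{a}" for a in ANTIBODIES],
        )
        if c in subjects.columns
    ]
    return meta + snp_columns(subjects)
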