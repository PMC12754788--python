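"""Readers and writers for genotype, phenotype, and summary-statistic files.

Genotype dosages travel as TSV (samples x variants, header = variant ids,
with a ``#positions:`` comment line) or VCF (biallelic records with GT;
dosage = ALT allele count). Phenotypes are TSV with columns sample_id,
value, lod: a single LOD per trait is enforced at read time, and the
boundary convention is that value <= LOD means censored (substituted data
sit exactly at the LOD). Summary statistics round-trip with a provenance
header recording transform policy, clump parameters, and seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pipeline import ClumpParams
from .simulate import CensoredPhenotype, GenotypeMatrix

logger = logging.getLogger("tobitgwas")

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "read_phenotype",
    "write_phenotype",
    "write_sumstats",
    "read_sumstats",
]


def read_genotypes(path: str, fmt: str | None = None) -> GenotypeMatrix:
    """Read a dosage matrix from TSV or VCF (inferred from the suffix)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    positions = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#positions:"):
            positions = np.array(
                [int(x) for x in first.split(":", 1)[1].split()], dtype=np.int64
            )
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    try:
        dosages = df.to_numpy(dtype=np.int8)
    except ValueError as exc:
        raise ValueError(f"non-integer dosage in {path}: {exc}") from exc
    if positions is None:
        positions = np.arange(1, df.shape[1] + 1, dtype=np.int64)
    return GenotypeMatrix(dosages, list(df.columns), positions)


def write_genotypes_tsv(
    gm: GenotypeMatrix, path: str, sample_ids: list[str] | None = None
) -> None:
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(gm.n_samples)]
    df = pd.DataFrame(gm.dosages, index=sample_ids, columns=gm.variant_ids)
    df.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write("#positions: " + " ".join(str(p) for p in gm.positions) + "\n")
        df.to_csv(fh, sep="\t")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids, positions, columns = [], [], []
    n_multi = n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        dosage = np.where(gt == 3, 2, np.where(gt == 1, 1, 0)).astype(float)
        missing = gt == 2
        if missing.any():
            n_missing += int(missing.sum())
            fill = int(round(dosage[~missing].mean())) if (~missing).any() else 0
            dosage[missing] = fill
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        columns.append(dosage.astype(np.int8))
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    if n_missing:
        logger.info("imputed %d missing genotypes in %s", n_missing, path)
    if not columns:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypeMatrix(
        np.column_stack(columns), ids, np.asarray(positions, dtype=np.int64)
    )


def write_vcf(
    gm: GenotypeMatrix,
    path: str,
    sample_ids: list[str] | None = None,
    chrom: str = "1",
) -> None:
    """Minimal biallelic VCF with GT derived from the dosage (0/0, 0/1, 1/1)."""
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(gm.n_samples)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j in range(gm.n_variants):
            gts = "\t".join(gt_map[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{chrom}\t{gm.positions[j]}\t{gm.variant_ids[j]}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_phenotype(path: str) -> CensoredPhenotype:
    """Read sample_id/value/lod TSV; value <= LOD is treated as censored."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "value", "lod"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    n_na = int(df["value"].isna().sum())
    if n_na:
        logger.info("dropped %d rows with missing values from %s", n_na, path)
        df = df.dropna(subset=["value"])
    values = pd.to_numeric(df["value"], errors="raise").to_numpy(dtype=float)
    lods = pd.to_numeric(df["lod"], errors="raise").to_numpy(dtype=float)
    if np.unique(lods).size != 1:
        raise ValueError(
            "per-row LODs differ; a single LOD per trait is required "
            "(batch-varying LODs should be analyzed per batch)"
        )
    lod = float(lods[0])
    is_censored = values <= lod
    if is_censored.all():
        raise ValueError("all phenotype values at or below the LOD")
    return CensoredPhenotype(np.maximum(values, lod), lod, is_censored)


def write_phenotype(
    ph: CensoredPhenotype, path: str, sample_ids: list[str] | None = None
) -> None:
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(ph.n)]
    pd.DataFrame(
        {
            "sample_id": sample_ids,
            "value": ph.observed,
            "lod": ph.lod,
            "is_censored": ph.is_censored.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


_SUMSTAT_FLOAT_FMT = {
    "beta": "%.6g", "se": "%.6g", "refined_beta": "%.6g", "refined_se": "%.6g",
    "p_value": "%.4e", "refined_p": "%.4e",
}


def write_sumstats(
    table: pd.DataFrame, path: str, provenance: dict | None = None
) -> None:
    """Write the GWAS table as TSV with '# key=value' provenance header lines."""
    if table.empty:
        raise ValueError("refusing to write an empty summary-statistics table")
    out = table.copy()
    for col, fmt in _SUMSTAT_FLOAT_FMT.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v, f=fmt: "NA" if pd.isna(v) else f % v
            )
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_sumstats(path: str) -> pd.DataFrame:
    """Read a summary-statistics TSV; provenance lines land in ``df.attrs``."""
    provenance = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("# "):
            key, _, val = line[2:].strip().partition("=")
            provenance[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    df.attrs["provenance"] = provenance
    return df


def default_provenance(
    model: str,
    ties_policy: str,
    int_offset: float,
    seed: int | None = None,
    clump_params: ClumpParams | None = None,
) -> dict:
    from . import __version__

    prov = {
        "tool": f"tobitgwas {__version__}",
        "model": model,
        "transform_policy": ties_policy,
        "int_offset": int_offset,
    }
    if seed is not None:
        prov["seed"] = seed
    if clump_params is not None:
        prov.update(
            p1=clump_params.p1, p2=clump_params.p2,
            r2=clump_params.r2, window_kb=clump_params.window_kb,
        )
    return prov
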