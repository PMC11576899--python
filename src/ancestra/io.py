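"""File input/output: VCF genotypes, BED intervals, TSV tables."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenomicIntervalSet, GenotypeMatrix

logger = logging.getLogger("ancestra")

__all__ = [
    "read_genotype_vcf",
    "write_genotype_vcf",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_table",
    "write_results",
]


def read_genotype_vcf(path, sample_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a GenotypeMatrix.

    GT fields become dosages {0, 1, 2}; missing calls become the missing
    code. Multiallelic records are skipped with a logged count. Sample
    metadata (indexed by sample id, e.g. a ``group`` column) is joined by id.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, recs = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dosage = np.select(
            [gts == 0, gts == 1, gts == 3], [0, 1, 2], default=MISSING
        ).astype(np.int8)
        rows.append(dosage)
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic records in %s", n_skipped, path)
    variants = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.stack(rows, axis=1) if rows else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    if sample_meta is not None:
        missing_ids = [s for s in sample_ids if s not in sample_meta.index]
        if missing_ids:
            raise ValueError(f"sample metadata missing ids: {missing_ids}")
        samples = samples.join(sample_meta)
    return GenotypeMatrix(dosage=dosage, variants=variants, samples=samples)


def write_genotype_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF (via pysam)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "ancestra")
    header.formats.add("GT", 1, "String", "Genotype")
    for chrom, sub in matrix.variants.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(sub["pos"].max()) + 1)
    for sid in matrix.sample_ids:
        header.add_sample(str(sid))
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, row in enumerate(matrix.variants.itertuples()):
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            for i, sid in enumerate(matrix.sample_ids):
                rec.samples[str(sid)]["GT"] = gt_of[int(matrix.dosage[i, j])]
            out.write(rec)


def read_intervals_bed(path, label: str | None = None) -> GenomicIntervalSet:
    """Read a 3+ column BED file into a sorted, merged interval set."""
    recs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected at least 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            recs.append((chrom, start, end))
    return GenomicIntervalSet(
        intervals=pd.DataFrame(recs, columns=["chrom", "start", "end"]), label=label
    )


def write_intervals_bed(regions: GenomicIntervalSet, path) -> None:
    regions.intervals.to_csv(path, sep="\t", header=False, index=False)


def write_results(table: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a results table as headered TSV with NaN encoded as NA."""
    if table.shape[1] == 0:
        raise ValueError("refusing to write a table with no columns")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=float_format)


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results` (NA parsed as missing)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
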