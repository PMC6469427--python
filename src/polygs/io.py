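"""Readers and writers for genotype, pedigree and phenotype tables.

CSV dialect: genotype tables have one row per individual (first column
the individual id) and one column per marker; missing entries are empty
or NA.  Marker metadata travels in a sidecar CSV with columns
``marker, scaffold, position, probe``.  Pedigrees are three-column CSVs
(``id, sire, dam``; 0 or empty = unknown parent).  Phenotypes are tidy:
``genotype, year, row, column, trait, value``.

VCF input uses cyvcf2 when available: GT fields give the
alternative-allele dosage, AD fields the (alt, ref) read counts.
A minimal VCF 4.2 writer is provided for simulated populations.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotypes import GenotypeData, GenotypeError
from .pedigree import Pedigree
from .simulate import ReadCountMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes_csv",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "write_vcf",
]


def _read_marker_sidecar(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame = frame.set_index(frame.columns[0])
    frame.index = frame.index.astype(str)
    return frame


def read_genotypes(
    path,
    format: str = "csv",
    ploidy: int | str = 4,
    markers_path=None,
) -> GenotypeData:
    """Load a genotype table from CSV or VCF.

    ``ploidy`` selects the parameterization of a CSV table: 2 or 4 for
    integer dosages, ``"ratio"`` for continuous values.  VCF input
    always yields tetraploid-coded dosages plus read counts when AD is
    present; non-biallelic records are kept but flagged
    ``biallelic=False`` so the marker filters can drop them.
    """
    if format == "csv":
        return _read_genotypes_csv(path, ploidy, markers_path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_csv(path, ploidy, markers_path) -> GenotypeData:
    if os.path.getsize(path) == 0:
        raise GenotypeError(f"empty genotype file: {path}")
    try:
        frame = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise GenotypeError(f"empty genotype file: {path}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise GenotypeError(f"genotype file has no data rows/columns: {path}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        for j, col in enumerate(frame.columns):
            bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad.argmax()]
                raise GenotypeError(
                    f"unparseable genotype entry at individual {row!r}, "
                    f"marker {col!r}"
                ) from exc
        raise
    markers = (
        _read_marker_sidecar(markers_path)
        if markers_path is not None
        else pd.DataFrame(index=[str(c) for c in frame.columns])
    )
    markers = markers.reindex([str(c) for c in frame.columns])
    if ploidy == "ratio":
        return GenotypeData(
            individuals=[str(i) for i in frame.index],
            markers=markers,
            ratio=values,
            ploidy_code="ratio",
        )
    return GenotypeData(
        individuals=[str(i) for i in frame.index],
        markers=markers,
        dosage=values,
        ploidy_code=int(ploidy),
    )


def _read_genotypes_vcf(path) -> GenotypeData:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF input requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    names, scaffolds, positions, biallelic = [], [], [], []
    dosage_cols, alt_cols, ref_cols = [], [], []
    for var in vcf:
        names.append(var.ID or f"{var.CHROM}_{var.POS}")
        scaffolds.append(var.CHROM)
        positions.append(var.POS)
        biallelic.append(len(var.ALT) == 1)
        gts = var.genotype.array()  # samples x (alleles..., phased flag)
        alleles = gts[:, :-1].astype(float)
        alleles[alleles < 0] = np.nan
        dosage_cols.append(np.nansum(alleles > 0, axis=1).astype(float)
                           * np.where(np.isnan(alleles).all(axis=1), np.nan, 1.0))
        ad = var.format("AD")
        if ad is not None:
            # AD carries (alt, ref) in this pipeline's convention
            ad = ad.astype(float)
            ad[ad < 0] = 0
            alt_cols.append(ad[:, 0])
            ref_cols.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples)))
        else:
            alt_cols.append(np.zeros(len(samples)))
            ref_cols.append(np.zeros(len(samples)))
    if not names:
        raise GenotypeError(f"no variant records in VCF: {path}")
    markers = pd.DataFrame(
        {"scaffold": scaffolds, "position": positions, "biallelic": biallelic},
        index=names,
    )
    reads = ReadCountMatrix(
        alt=np.column_stack(alt_cols).astype(int),
        ref=np.column_stack(ref_cols).astype(int),
    )
    return GenotypeData(
        individuals=samples,
        markers=markers,
        dosage=np.column_stack(dosage_cols),
        reads=reads,
        ploidy_code=4,
    )


def write_genotypes_csv(data: GenotypeData, path, markers_path=None) -> None:
    mat = data.values
    frame = pd.DataFrame(mat, index=data.individuals, columns=data.markers.index)
    if data.ploidy_code != "ratio":
        frame = frame.astype("Int64")  # keeps NaN, writes integers
    frame.to_csv(path, index_label="individual")
    if markers_path is not None:
        data.markers.to_csv(markers_path, index_label="marker")


def write_vcf(data: GenotypeData, path) -> None:
    """Minimal VCF 4.2 with GT (tetraploid) and AD (alt,ref) per sample."""
    if data.dosage is None or data.reads is None:
        raise GenotypeError("VCF output needs tetraploid dosages and read counts")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (alt,ref)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.individuals)
            + "\n"
        )
        for j, (name, meta) in enumerate(data.markers.iterrows()):
            fields = [
                str(meta.get("scaffold", "scaffold_0")),
                str(int(meta.get("position", j + 1) or j + 1)),
                str(name),
                "A",
                "B",
                ".",
                "PASS",
                ".",
                "GT:AD",
            ]
            for i in range(data.n_individuals):
                d = data.dosage[i, j]
                if np.isnan(d):
                    gt = "./././."
                else:
                    d = int(d)
                    gt = "/".join(["1"] * d + ["0"] * (4 - d))
                ad = f"{int(data.reads.alt[i, j])},{int(data.reads.ref[i, j])}"
                fields.append(f"{gt}:{ad}")
            fh.write("\t".join(fields) + "\n")


def read_pedigree_csv(path, ploidy: int = 4) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path, dtype=str), ploidy=ploidy)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"genotype", "year", "row", "column", "trait", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    frame["genotype"] = frame["genotype"].astype(str)
    return frame


def write_phenotypes_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
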