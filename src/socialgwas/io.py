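"""Readers and writers for the package's tabular interfaces.

Phenotype, covariate and cage tables are UTF-8 CSV with a header row;
``individual_id`` is the join key everywhere. Genotypes travel as a TSV
dosage matrix (variants in rows: chrom, pos, ref, alt, then one column
per individual) or HDF5; a minimal PLINK .bed/.bim/.fam hard-call reader
is included. GRMs round-trip as square TSV with an individual-id header
or HDF5. All analysis outputs are TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeSet

__all__ = [
    "read_phenotypes",
    "read_covariates",
    "read_cage_assignments",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_hdf5",
    "write_genotypes_hdf5",
    "read_plink",
    "read_grm_tsv",
    "write_grm_tsv",
    "read_grm_hdf5",
    "write_grm_hdf5",
]


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: individual_id plus one column per phenotype."""
    df = pd.read_csv(path)
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: missing individual_id column")
    return df.set_index("individual_id")


def read_covariates(path) -> pd.DataFrame:
    """Covariate table; sex (0/1) is expected among the columns."""
    df = pd.read_csv(path)
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: missing individual_id column")
    return df.set_index("individual_id")


def read_cage_assignments(path) -> pd.DataFrame:
    """Cage assignments: individual_id, cage_id, optional timepoint."""
    df = pd.read_csv(path)
    for col in ("individual_id", "cage_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing {col} column")
    return df


# ---------------------------------------------------------------------------
# genotypes

_VARIANT_COLS = ["chrom", "pos", "ref", "alt"]


def read_genotypes_tsv(path) -> GenotypeSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _VARIANT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing variant columns {missing}")
    ids = [c for c in df.columns if c not in _VARIANT_COLS]
    dosages = df[ids].to_numpy(dtype=float).T  # individuals x variants
    return GenotypeSet(dosages, df[_VARIANT_COLS].copy(), np.array(ids))


def write_genotypes_tsv(genotypes: GenotypeSet, path):
    out = genotypes.variant_map.copy()
    for i, iid in enumerate(genotypes.individual_ids):
        out[str(iid)] = genotypes.dosages[i]
    out.to_csv(path, sep="\t", index=False)


def write_genotypes_hdf5(genotypes: GenotypeSet, path):
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("dosages", data=genotypes.dosages)
        fh.create_dataset(
            "individual_ids",
            data=np.asarray(genotypes.individual_ids, dtype="S"),
        )
        for col in _VARIANT_COLS:
            data = genotypes.variant_map[col].to_numpy()
            if data.dtype == object or data.dtype.kind == "U":
                data = data.astype("S")
            fh.create_dataset(f"variants/{col}", data=data)


def read_genotypes_hdf5(path) -> GenotypeSet:
    import h5py

    with h5py.File(path, "r") as fh:
        dosages = fh["dosages"][()]
        ids = fh["individual_ids"][()].astype(str)
        vm = {}
        for col in _VARIANT_COLS:
            data = fh[f"variants/{col}"][()]
            vm[col] = data.astype(str) if data.dtype.kind == "S" else data
    return GenotypeSet(dosages, pd.DataFrame(vm), ids)


def read_plink(prefix, missing: str = "mean") -> GenotypeSet:
    """Minimal PLINK1 .bed/.bim/.fam reader (SNP-major hard calls).

    Dosages count the A1 allele (the .bim's fifth column). Missing calls
    are replaced by the variant mean ("mean") or left as NaN ("nan").
    """
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    n, p = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != b"\x6c\x1b\x01":
            raise ValueError(f"{prefix}.bed: not a SNP-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_variant = (n + 3) // 4
    raw = raw.reshape(p, bytes_per_variant)
    # unpack 2-bit codes, sample-major within each variant
    codes = np.zeros((p, bytes_per_variant * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    dosage = np.choose(codes, [2.0, np.nan, 1.0, 0.0]).T  # n x p
    if missing == "mean":
        means = np.nanmean(dosage, axis=0)
        idx = np.where(np.isnan(dosage))
        dosage[idx] = means[idx[1]]
    vm = pd.DataFrame(
        {"chrom": bim["chrom"], "pos": bim["pos"], "ref": bim["a2"], "alt": bim["a1"]}
    )
    ids = fam[1].astype(str).to_numpy()
    return GenotypeSet(dosage, vm, ids)


# ---------------------------------------------------------------------------
# GRM


def write_grm_tsv(A: np.ndarray, individual_ids, path):
    pd.DataFrame(A, columns=list(individual_ids)).to_csv(
        path, sep="\t", index=False
    )


def read_grm_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), np.array(df.columns)


def write_grm_hdf5(A: np.ndarray, individual_ids, path):
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("grm", data=A)
        fh.create_dataset(
            "individual_ids", data=np.asarray(individual_ids, dtype="S")
        )


def read_grm_hdf5(path):
    import h5py

    with h5py.File(path, "r") as fh:
        return fh["grm"][()], fh["individual_ids"][()].astype(str)
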