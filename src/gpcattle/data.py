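"""Core genotype/phenotype containers and standard-format readers/writers.

Genotypes are held as 0/1/2 counted-allele dosages in a masked array (the
mask marks missing calls — no magic sentinel values in the data itself).
Supported on-disk dialects are the PLINK RAW additive text format and a
minimal VCF 4.x with GT fields only; phenotypes travel as a delimited table
with ``id, gender, farm, year, age`` plus one column per trait.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "write_plink_raw",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "align_samples",
]

#: columns every phenotype file must carry besides the trait columns
PHENO_FIXED_COLUMNS = ("id", "gender", "farm", "year", "age")


@dataclass
class GenotypeMatrix:
    """N x M counted-allele dosage matrix with sample and marker metadata.

    ``dosages`` is a :class:`numpy.ma.MaskedArray`; masked entries are
    missing calls.  Non-missing entries are 0, 1 or 2 copies of the counted
    allele (real-valued after mean imputation).
    """

    dosages: np.ma.MaskedArray
    sample_ids: np.ndarray
    marker_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.ma.masked_array(self.dosages, copy=False)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x markers) array")
        n, m = self.dosages.shape
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.counted_allele = np.asarray(self.counted_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        for name, arr in [
            ("marker_ids", self.marker_ids),
            ("chromosome", self.chromosome),
            ("position", self.position),
            ("counted_allele", self.counted_allele),
            ("other_allele", self.other_allele),
        ]:
            if len(arr) != m:
                raise ValueError(f"{name} has {len(arr)} entries for {m} markers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker_ids")
        if (self.position < 0).any():
            raise ValueError("positions must be nonnegative")
        # positions nondecreasing within each chromosome
        for chrom in pd.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if len(pos) > 1 and (np.diff(pos) < 0).any():
                raise ValueError(f"positions not sorted within chromosome {chrom}")
        valid = self.dosages.compressed()
        if valid.size and (np.nanmin(valid) < 0 or np.nanmax(valid) > 2):
            raise ValueError("dosages outside [0, 2]")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_complete(self) -> bool:
        return not np.ma.is_masked(self.dosages) or not self.dosages.mask.any()

    def values(self) -> np.ndarray:
        """Plain float array of dosages; requires a complete matrix."""
        if not self.is_complete:
            raise ValueError("matrix has missing calls; impute first")
        return np.asarray(self.dosages.filled(0.0), dtype=np.float64)

    # -- subsetting ------------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[index, :],
            sample_ids=self.sample_ids[index],
        )

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[:, index],
            marker_ids=self.marker_ids[index],
            chromosome=self.chromosome[index],
            position=self.position[index],
            counted_allele=self.counted_allele[index],
            other_allele=self.other_allele[index],
        )


@dataclass
class PhenotypeTable:
    """One row per animal: trait values plus fixed-effect factors and the
    slaughter-age covariate.  Missing trait cells are NaN."""

    df: pd.DataFrame
    trait_names: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = self.df
        for col in PHENO_FIXED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"phenotype table missing required column {col!r}")
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id {dup.iloc[0]!r}")
        df = df.copy()
        for col in ("id", "gender", "farm", "year"):
            df[col] = df[col].astype(str)
        if not self.trait_names:
            self.trait_names = tuple(
                c for c in df.columns if c not in PHENO_FIXED_COLUMNS
            )
        for t in self.trait_names:
            if not pd.api.types.is_numeric_dtype(df[t]):
                raise ValueError(f"trait column {t!r} is not numeric")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["id"].to_numpy(dtype=object)

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def trait(self, name: str) -> np.ndarray:
        if name not in self.trait_names:
            raise KeyError(f"unknown trait {name!r}")
        return self.df[name].to_numpy(dtype=float)

    def take(self, index: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(self.df.iloc[index].reset_index(drop=True),
                              self.trait_names)


# ---------------------------------------------------------------------------
# PLINK RAW
# ---------------------------------------------------------------------------

_RAW_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_plink_raw(geno: GenotypeMatrix, path) -> None:
    """Write in the PLINK ``--recode A`` additive text dialect.

    Marker columns are named ``<marker_id>_<counted_allele>``; missing
    dosages become ``NA``.  Integer dosages are written without decimals.
    """
    with open(path, "w") as fh:
        cols = [f"{m}_{a}" for m, a in zip(geno.marker_ids, geno.counted_allele)]
        fh.write(" ".join(_RAW_LEAD + cols) + "\n")
        dos = geno.dosages
        for i, sid in enumerate(geno.sample_ids):
            row = dos[i]
            cells = [
                "NA" if row.mask is not np.ma.nomask and np.ma.is_masked(row[j])
                else _fmt_dosage(row[j])
                for j in range(len(row))
            ]
            fh.write(" ".join([str(sid), str(sid), "0", "0", "0", "-9"] + cells))
            fh.write("\n")


def _fmt_dosage(x) -> str:
    x = float(x)
    return str(int(x)) if x == int(x) else repr(x)


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    if list(df.columns[:6]) != _RAW_LEAD:
        raise ValueError(
            f"{path}: line 1: not a PLINK RAW header (expected {' '.join(_RAW_LEAD)} ...)"
        )
    marker_cols = list(df.columns[6:])
    marker_ids, counted = [], []
    for c in marker_cols:
        if "_" not in c:
            raise ValueError(f"{path}: marker column {c!r} lacks an _allele suffix")
        mid, allele = c.rsplit("_", 1)
        marker_ids.append(mid)
        counted.append(allele)
    dos = df[marker_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: line {i + 2}: dosage {dos[i, j]!r} for marker "
            f"{marker_ids[j]!r} not in {{0,1,2,NA}}"
        )
    m = len(marker_ids)
    return GenotypeMatrix(
        dosages=np.ma.masked_invalid(dos),
        sample_ids=df["IID"].astype(str).to_numpy(dtype=object),
        marker_ids=np.array(marker_ids, dtype=object),
        chromosome=np.array(["1"] * m, dtype=object),
        position=np.arange(1, m + 1),
        counted_allele=np.array(counted, dtype=object),
        other_allele=np.array(["0"] * m, dtype=object),
    )


# ---------------------------------------------------------------------------
# minimal VCF (GT only)
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT only; the counted allele is written as ALT so
    dosages round-trip as alternate-allele counts."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.chromosome):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in geno.sample_ids) + "\n")
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        dos = geno.dosages
        for j in range(geno.n_markers):
            ref = geno.other_allele[j] if geno.other_allele[j] in "ACGT" else "A"
            alt = geno.counted_allele[j] if geno.counted_allele[j] in "ACGT" else "G"
            if ref == alt:
                ref = "A" if alt != "A" else "C"
            col = dos[:, j]
            gts = [
                "./." if np.ma.is_masked(col[i]) else gt_of[float(col[i])]
                for i in range(geno.n_samples)
            ]
            fh.write(
                f"{geno.chromosome[j]}\t{geno.position[j]}\t{geno.marker_ids[j]}"
                f"\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    rows, mids, chroms, poss, refs, alts = [], [], [], [], [], []
    for k, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise ValueError(
                f"{path}: record {k + 1} ({v.CHROM}:{v.POS}): not biallelic"
            )
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(v.gt_types)
        dos = np.empty(len(gt), dtype=float)
        dos[gt == 0] = 0.0
        dos[gt == 1] = 1.0
        dos[gt == 3] = 2.0
        dos[gt == 2] = np.nan
        rows.append(dos)
        mids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if not rows:
        raise ValueError(f"{path}: no variant records")
    dosages = np.ma.masked_invalid(np.array(rows).T)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=samples,
        marker_ids=np.array(mids, dtype=object),
        chromosome=np.array(chroms, dtype=object),
        position=np.array(poss),
        counted_allele=np.array(alts, dtype=object),
        other_allele=np.array(refs, dtype=object),
    )


def read_genotypes(path, format: str = "plink_raw") -> GenotypeMatrix:
    """Read genotypes from ``plink_raw`` or ``vcf`` files as counted-allele
    dosages (ALT-allele counts for VCF)."""
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep=None, engine="python")
    for col in PHENO_FIXED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["id"] = df["id"].astype(str)
    trait_cols = [c for c in df.columns if c not in PHENO_FIXED_COLUMNS]
    for c in trait_cols + ["age"]:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {c!r} is not numeric: {exc}") from exc
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_samples(geno: GenotypeMatrix, pheno: PhenotypeTable):
    """Restrict both sides to the shared sample ids, in genotype order."""
    gset = {str(s) for s in geno.sample_ids}
    pset = {str(s) for s in pheno.sample_ids}
    shared = gset & pset
    if not shared:
        raise ValueError("no sample ids shared between genotypes and phenotypes")
    gidx = np.array([i for i, s in enumerate(geno.sample_ids) if str(s) in shared])
    order = [str(geno.sample_ids[i]) for i in gidx]
    prank = {str(s): i for i, s in enumerate(pheno.sample_ids)}
    pidx = np.array([prank[s] for s in order])
    log.info(
        "align_samples: kept %d ids (dropped %d genotype-only, %d phenotype-only)",
        len(shared), len(gset) - len(shared), len(pset) - len(shared),
    )
    return geno.take_samples(gidx), pheno.take(pidx)
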