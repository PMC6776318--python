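"""Readers and writers for standard formats (VCF genotypes, TSV tables).

Genotypes come in as a region of a VCF (biallelic records only; the
alternate-allele dosage is folded to the minor allele, missing genotypes
are mean-imputed to twice the sample MAF).  Counts and covariates are
plain TSV; results and power tables go out as TSV that round-trips to
full float precision.  Sample alignment between genotypes and counts is
always by sample id, never by column position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import EmptyRegionError
from .results import ResultsRecord, TestResult, results_to_frame
from .simdata import CountData, GenotypeMatrix

#: reserved row id for per-sample library sizes in a counts table
LIBRARY_SIZE_ROW = "library_size"


@dataclass(frozen=True)
class RegionQuery:
    """A 1-based inclusive genomic interval ``contig:start-end``."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.start > self.end:
            raise ValueError("require start <= end")

    @classmethod
    def parse(cls, text: str) -> "RegionQuery":
        m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", text.strip())
        if not m:
            raise ValueError(f"cannot parse region {text!r}; expected contig:start-end")
        return cls(contig=m.group(1), start=int(m.group(2)), end=int(m.group(3)))

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


def read_genotypes_vcf(
    path: Union[str, Path],
    region: Optional[RegionQuery] = None,
    maf_max: float = 0.05,
) -> GenotypeMatrix:
    """Read a dosage matrix for one region from a VCF.

    Multiallelic records are skipped with a warning.  Dosage is the count
    of alternate alleles, folded so the minor allele is counted when the
    alternate frequency exceeds 0.5.  Missing genotypes are imputed to
    twice the sample MAF of the site (mean imputation).  Sites with sample
    MAF strictly above ``maf_max`` are removed; an empty result raises
    :class:`EmptyRegionError`.
    """
    if isinstance(region, str):
        region = RegionQuery.parse(region)
    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    dosage_cols: List[np.ndarray] = []
    ids: List[str] = []
    positions: List[int] = []
    mafs: List[float] = []
    for v in vcf:
        if region is not None and not (
            v.CHROM == region.contig and region.start <= v.POS <= region.end
        ):
            continue
        if len(v.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record {v.CHROM}:{v.POS}", stacklevel=2
            )
            continue
        dos = np.empty(len(samples))
        for i, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1] if a is not None]
            if any(a < 0 for a in alleles) or not alleles:
                dos[i] = np.nan
            else:
                dos[i] = sum(1 for a in alleles if a >= 1)
        observed = dos[~np.isnan(dos)]
        if observed.size == 0:
            warnings.warn(f"all genotypes missing at {v.CHROM}:{v.POS}; skipped", stacklevel=2)
            continue
        alt_freq = observed.mean() / 2.0
        if alt_freq > 0.5:
            dos = 2.0 - dos
            alt_freq = 1.0 - alt_freq
        dos = np.where(np.isnan(dos), 2.0 * alt_freq, dos)
        dosage_cols.append(dos)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        positions.append(v.POS)
        mafs.append(alt_freq)
    vcf.close()
    if not dosage_cols:
        raise EmptyRegionError(f"no usable variants in region {region}")
    D = np.column_stack(dosage_cols)
    maf_sample = D.mean(axis=0) / 2.0
    maf_sample = np.minimum(maf_sample, 1.0 - maf_sample)
    keep = np.flatnonzero(maf_sample <= maf_max)
    if keep.size == 0:
        raise EmptyRegionError(
            f"no variants with sample MAF <= {maf_max} in region {region}"
        )
    D = D[:, keep]
    p = D.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=D,
        site_id=np.asarray(ids)[keep],
        position=np.asarray(positions, dtype=np.int64)[keep],
        freq_pool=np.maximum(np.asarray(mafs)[keep], 1e-12),
        maf_sample=np.minimum(p, 1.0 - p),
        causal=np.zeros(keep.size, dtype=bool),
        samples=samples,
    )


def read_counts_table(
    path: Union[str, Path],
    gene: str,
    samples: Optional[Sequence[str]] = None,
) -> CountData:
    """Read one gene's counts from a gene-by-sample TSV.

    The header row carries sample ids; a reserved row id
    ``"library_size"`` is recognized as per-sample library sizes.  When
    ``samples`` is given (typically the VCF sample order), columns are
    re-aligned to that order by id; a mismatch raises.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if gene not in df.index:
        raise KeyError(f"gene {gene!r} not present in {path}")
    if samples is not None:
        missing = [s for s in samples if s not in df.columns]
        if missing:
            raise ValueError(f"samples absent from counts table: {missing}")
        df = df.loc[:, list(samples)]
    row = df.loc[gene].to_numpy(dtype=float)
    if np.any(row < 0) or not np.allclose(row, np.round(row)):
        raise ValueError(f"counts for gene {gene!r} must be non-negative integers")
    k = None
    if LIBRARY_SIZE_ROW in df.index:
        k = df.loc[LIBRARY_SIZE_ROW].to_numpy(dtype=float)
        k = k.astype(np.int64)
    return CountData(t=row.astype(np.int64), k=k)


def read_covariates(
    path: Union[str, Path], samples: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Read a sample-by-covariate TSV (first column: sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if samples is not None:
        missing = [s for s in samples if s not in df.index]
        if missing:
            raise ValueError(f"samples absent from covariate table: {missing}")
        df = df.loc[list(samples)]
    return df.to_numpy(dtype=float)


def write_results(
    path: Union[str, Path],
    records: Union[pd.DataFrame, Sequence[Union[TestResult, ResultsRecord]]],
) -> Path:
    """Write test results or a power table as TSV (deterministic columns).

    Floats are written with full repr precision so a read-back reproduces
    the values exactly.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        if df.empty:
            raise ValueError("no records to write")
    else:
        df = results_to_frame(records)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_genotypes_vcf(
    path: Union[str, Path],
    G: GenotypeMatrix,
    contig: str = "1",
) -> Path:
    """Export a (simulated) integer-dosage genotype matrix as a minimal VCF.

    GT-only records, one contig; dosage 0/1/2 becomes 0/0, 0/1, 1/1.
    Fractional (imputed) dosages are not representable and raise.
    """
    D = G.dosages
    if not np.allclose(D, np.round(D)):
        raise ValueError("cannot export fractional dosages to VCF")
    D = D.astype(int)
    n = G.n_subjects
    names = list(G.samples) if G.samples is not None else [f"S{i:05d}" for i in range(n)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={int(max(G.position)) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for j in range(G.n_variants):
            gts = "\t".join(gt_map[int(D[i, j])] for i in range(n))
            fh.write(
                f"{contig}\t{int(G.position[j])}\t{G.site_id[j]}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def write_counts_table(
    path: Union[str, Path],
    counts: CountData,
    gene: str = "simulated_gene",
    samples: Optional[Sequence[str]] = None,
) -> Path:
    """Write a one-gene counts TSV in the format read_counts_table expects."""
    names = list(samples) if samples is not None else [f"S{i:05d}" for i in range(counts.n)]
    rows = {gene: counts.t}
    if counts.k is not None:
        rows[LIBRARY_SIZE_ROW] = counts.k
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "gene"
    path = Path(path)
    df.to_csv(path, sep="\t")
    return path


def read_config(path: Union[str, Path]) -> dict:
    """Parse a flat key=value configuration file.

    Values are parsed as int, float, comma-separated lists thereof, or
    left as strings.  Lines starting with '#' are ignored.
    """
    cfg: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"cannot parse config line {line!r}")
        key, _, raw = line.partition("=")
        cfg[key.strip()] = _parse_config_value(raw.strip())
    return cfg


def _parse_scalar(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def _parse_config_value(raw: str):
    if "," in raw:
        return tuple(_parse_scalar(part.strip()) for part in raw.split(",") if part.strip())
    return _parse_scalar(raw)
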