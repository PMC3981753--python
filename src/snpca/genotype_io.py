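"""PLINK 1 binary fileset I/O and whitespace-delimited text output of PCA results.

The PLINK 1 binary layout stores one variant after another (SNP-major mode):
for each variant, genotypes of all samples are packed two bits apiece into
``ceil(n/4)`` bytes, least-significant bit pair first. The 2-bit codes are

====  ==============================
code  meaning
====  ==============================
00    homozygous A1 (dosage 2)
01    missing
10    heterozygous (dosage 1)
11    homozygous A2 (dosage 0)
====  ==============================

Dosage counts the A1 allele (PLINK's first-listed, conventionally minor
allele); flipping the counted allele only flips eigenvector signs, which are
arbitrary. Missing genotypes are coded with the sentinel :data:`MISSING`.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "Variant",
    "GenotypeMatrix",
    "BedFormatError",
    "TextFormatError",
    "read_bed",
    "read_bim",
    "read_fam",
    "read_plink",
    "write_pca_outputs",
]

#: Sentinel for a missing genotype in dosage matrices (distinct from {0,1,2}).
MISSING: int = -1

_BED_MAGIC = b"\x6c\x1b"
_MODE_SNP_MAJOR = 0x01
_MODE_IND_MAJOR = 0x00

# 2-bit code -> dosage. Index by code 0..3.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)

# byte -> 4 dosages, LSB pair first; built once at import.
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _j in range(4):
        _BYTE_LUT[_b, _j] = _CODE_TO_DOSAGE[(_b >> (2 * _j)) & 0b11]
del _b, _j


class BedFormatError(ValueError):
    """Raised for malformed PLINK .bed content."""


class TextFormatError(ValueError):
    """Raised for malformed .bim/.fam text files."""


class Variant(NamedTuple):
    chrom: str
    id: str
    pos: int
    allele1: str
    allele2: str


@dataclass
class GenotypeMatrix:
    """n samples x p SNPs of allele-dosage codes with metadata.

    ``dosages[i, j]`` is the A1-allele count of sample i at SNP j, one of
    {0, 1, 2, MISSING}.
    """

    dosages: np.ndarray
    sample_ids: list[tuple[str, str]]
    variants: list[Variant]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, p = self.dosages.shape
        if n < 1 or p < 1:
            raise ValueError(f"need at least one sample and one variant, got {n} x {p}")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variants) != p:
            raise ValueError(f"{len(self.variants)} variant records for {p} columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


def bytes_per_variant(n_samples: int) -> int:
    return math.ceil(n_samples / 4)


def read_bed(
    bed_path: str | os.PathLike,
    n_samples: int,
    n_variants: int,
    chunk_variants: int | None = None,
) -> np.ndarray:
    """Decode a SNP-major PLINK .bed file into an (n_samples, n_variants) dosage block.

    Parameters
    ----------
    bed_path : path to the .bed file.
    n_samples, n_variants : dimensions, normally taken from the .fam/.bim files.
    chunk_variants : decode this many variants at a time (None = whole file).
        Output is identical either way; chunking bounds peak decode memory.

    Returns
    -------
    int8 array of shape (n_samples, n_variants) with values in {0,1,2,MISSING}.
    """
    bpv = bytes_per_variant(n_samples)
    expected = 3 + n_variants * bpv
    actual = os.path.getsize(bed_path)
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != _BED_MAGIC:
            raise BedFormatError(f"{bed_path}: not a BED file (bad magic bytes)")
        mode = header[2]
        if mode == _MODE_IND_MAJOR:
            raise BedFormatError(f"{bed_path}: individual-major BED unsupported")
        if mode != _MODE_SNP_MAJOR:
            raise BedFormatError(f"{bed_path}: unknown BED mode byte 0x{mode:02x}")
        if actual != expected:
            raise BedFormatError(
                f"{bed_path}: size mismatch, expected {expected} bytes "
                f"({n_samples} samples x {n_variants} variants) but file has {actual}"
            )
        out = np.empty((n_samples, n_variants), dtype=np.int8)
        step = n_variants if chunk_variants is None else max(1, int(chunk_variants))
        for start in range(0, n_variants, step):
            count = min(step, n_variants - start)
            raw = np.frombuffer(fh.read(count * bpv), dtype=np.uint8)
            # (count, bpv) bytes -> (count, 4*bpv) dosages; padding columns dropped
            block = _BYTE_LUT[raw.reshape(count, bpv)].reshape(count, 4 * bpv)
            out[:, start : start + count] = block[:, :n_samples].T
    return out


def _read_table(path: str | os.PathLike, what: str) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:  # blank lines (incl. trailing) ignored
                continue
            if len(fields) != 6:
                raise TextFormatError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(fields)}"
                )
            rows.append(fields)
    if not rows:
        raise TextFormatError(f"{path}: no {what}")
    return rows


def read_bim(path: str | os.PathLike) -> list[Variant]:
    """Parse a 6-column .bim file (chrom, id, cM, pos, allele1, allele2)."""
    return [
        Variant(chrom=f[0], id=f[1], pos=int(f[3]), allele1=f[4], allele2=f[5])
        for f in _read_table(path, "variants")
    ]


def read_fam(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Parse a 6-column .fam file, returning (family_id, individual_id) pairs."""
    return [(f[0], f[1]) for f in _read_table(path, "samples")]


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a complete .bed/.bim/.fam fileset given the shared path prefix."""
    prefix = os.fspath(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"{prefix + ext}: file not found")
    samples = read_fam(prefix + ".fam")
    variants = read_bim(prefix + ".bim")
    dosages = read_bed(prefix + ".bed", len(samples), len(variants))
    return GenotypeMatrix(dosages=dosages, sample_ids=samples, variants=variants)


def _format_matrix(m: np.ndarray) -> list[str]:
    return [" ".join(f"{v:.6g}" for v in row) for row in np.atleast_2d(m)]


def write_pca_outputs(result, prefix: str | os.PathLike) -> None:
    """Write eigenvalues, eigenvectors and PCs as whitespace-delimited text.

    Three files are produced: ``<prefix>.eigenvalues`` (k lines),
    ``<prefix>.eigenvectors`` (n x k, bare numeric, smartpca-style) and
    ``<prefix>.pcs`` (header row, then FID IID followed by the k weighted
    PCs). Values carry 6 significant digits. All files are written to
    temporaries and renamed into place, so a failure leaves no partial set.
    """
    prefix = os.fspath(prefix)
    k = len(result.eigenvalues)
    ids = result.sample_ids
    if ids is None:
        ids = [("0", f"sample{i + 1}") for i in range(result.pcs_P.shape[0])]

    header = "FID IID " + " ".join(f"PC{j + 1}" for j in range(k))
    pcs_lines = [header] + [
        f"{fid} {iid} " + " ".join(f"{v:.6g}" for v in row)
        for (fid, iid), row in zip(ids, result.pcs_P)
    ]
    contents = {
        prefix + ".eigenvalues": [f"{v:.6g}" for v in result.eigenvalues],
        prefix + ".eigenvectors": _format_matrix(result.eigenvectors_U),
        prefix + ".pcs": pcs_lines,
    }
    outdir = os.path.dirname(prefix) or "."
    tmp_paths: dict[str, str] = {}
    try:
        for path, lines in contents.items():
            fd, tmp = tempfile.mkstemp(dir=outdir, prefix=".snpca-")
            tmp_paths[path] = tmp
            with os.fdopen(fd, "w") as fh:
                fh.write("\n".join(lines) + "\n")
        for path, tmp in tmp_paths.items():
            os.replace(tmp, path)
            tmp_paths[path] = ""
    finally:
        for tmp in tmp_paths.values():
            if tmp and os.path.exists(tmp):
                os.unlink(tmp)
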