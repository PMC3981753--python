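"""Structured genotype simulation under the Balding-Nichols island model.

Gives every pipeline stage a dataset with known population labels. For each
SNP an ancestral allele frequency pi is drawn uniformly from ``maf_range``;
each island population then draws its own frequency from

    Beta(pi (1 - F) / F,  (1 - pi)(1 - F) / F)

whose mean is pi and variance pi (1 - pi) F, with F the fixation index
(Fst) controlling divergence. Individual dosages are Binomial(2, population
frequency). SNPs are independent, emulating LD-pruned input — the form PCA
pipelines expect after thinning markers by linkage disequilibrium.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    Variant,
    _BED_MAGIC,
    _MODE_SNP_MAJOR,
    bytes_per_variant,
)

__all__ = ["SyntheticSpec", "simulate_genotypes", "write_plink_fixture", "encode_bed"]

# dosage -> 2-bit BED code; index -1 (the missing sentinel) lands on code 01
_DOSAGE_TO_CODE = np.array([3, 2, 0, 1], dtype=np.uint8)


@dataclass
class SyntheticSpec:
    """Study design for one simulated dataset.

    pop_sizes : individuals per island population.
    n_snps : number of independent SNPs.
    fst : divergence parameter in (0, 1); 0.1 gives continental-scale
        separation, 0.001-0.01 within-continent structure.
    maf_range : bounds of the uniform ancestral-frequency draw.
    missing_rate : independent per-entry missingness probability.
    seed : generator seed; the whole draw is deterministic given the spec.
    """

    pop_sizes: list[int] = field(default_factory=lambda: [100, 100, 100])
    n_snps: int = 5000
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.pop_sizes = [int(s) for s in self.pop_sizes]
        if any(s < 1 for s in self.pop_sizes) or sum(self.pop_sizes) < 2:
            raise ValueError("pop_sizes must be positive and sum to >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        low, high = self.maf_range
        if not 0.0 <= low < high <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= low < high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def simulate_genotypes(spec: SyntheticSpec) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw a genotype matrix plus per-sample population labels.

    Returns
    -------
    (GenotypeMatrix, labels) where ``labels[i]`` is the population name
    ("POP1", ...) of sample i; the same label is stored as the sample's
    family id.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_snps
    pi = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=p)
    f = spec.fst
    alpha = pi * (1.0 - f) / f
    beta = (1.0 - pi) * (1.0 - f) / f

    blocks, labels = [], []
    for ipop, size in enumerate(spec.pop_sizes):
        pop_freq = rng.beta(alpha, beta)
        blocks.append(rng.binomial(2, pop_freq, size=(size, p)).astype(np.int8))
        labels.extend([f"POP{ipop + 1}"] * size)
    dosages = np.vstack(blocks)
    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = MISSING

    labels = np.array(labels)
    sample_ids = [(lab, f"I{i + 1}") for i, lab in enumerate(labels)]
    variants = [Variant("1", f"snp{j + 1}", j + 1, "A", "B") for j in range(p)]
    return GenotypeMatrix(dosages, sample_ids, variants), labels


def encode_bed(dosages: np.ndarray) -> bytes:
    """Pack an (n, p) dosage block into SNP-major PLINK .bed bytes.

    Inverse of the decoder; used to write simulated filesets and to
    round-trip-test the reader. Padding bit pairs in each variant's final
    byte are zero.
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    bpv = bytes_per_variant(n)
    codes = _DOSAGE_TO_CODE[dosages.T]  # (p, n), sentinel -1 wraps to index 3
    padded = np.zeros((p, 4 * bpv), dtype=np.uint8)
    padded[:, :n] = codes
    quads = padded.reshape(p, bpv, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    return _BED_MAGIC + bytes([_MODE_SNP_MAJOR]) + packed.tobytes()


def write_plink_fixture(
    g: GenotypeMatrix, labels=None, prefix: str | os.PathLike = "synthetic"
) -> None:
    """Write a conformant .bed/.bim/.fam fileset for a genotype matrix.

    ``labels`` (population per sample) override the family-id column of the
    .fam file so downstream plots/tests can recover the truth; by default
    the matrix's own sample ids are used.
    """
    prefix = os.fspath(prefix)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(encode_bed(g.dosages))
    with open(prefix + ".bim", "w") as fh:
        for v in g.variants:
            fh.write(f"{v.chrom} {v.id} 0 {v.pos} {v.allele1} {v.allele2}\n")
    with open(prefix + ".fam", "w") as fh:
        for i, (fid, iid) in enumerate(g.sample_ids):
            fam = labels[i] if labels is not None else fid
            fh.write(f"{fam} {iid} 0 0 0 -9\n")
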