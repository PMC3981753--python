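"""Dosage standardization for genotype PCA.

PCA of SNP data operates on a real-valued matrix derived from the integer
dosages. The default ("binom") follows the smartpca convention: each SNP
column j is centered by its observed mean mu_j and divided by
sqrt(q_j (1 - q_j)), the standard deviation (up to a constant) of a
Binomial(2, q_j) draw, where

    q_j = (1 + sum_i x_ij) / (2 + 2 n_obs,j)

is the posterior-mean allele-frequency estimate with a pseudocount of one
allele of each kind; n_obs,j counts the non-missing entries. The pseudocount
keeps q_j strictly inside (0, 1), so monomorphic SNPs still get a positive
scale. Missing dosages are mean-imputed before centering, hence contribute
exactly zero afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["MODES", "StandardizedMatrix", "standardize_columns", "standardize_rows"]

MODES = ("binom", "center", "none")


@dataclass
class StandardizedMatrix:
    """Real-valued n x p matrix ready for decomposition.

    Carries the per-column mean and scale actually applied, so the transform
    can be replayed on held-out samples.
    """

    values: np.ndarray
    col_means: np.ndarray
    col_scales: np.ndarray
    mode: str


def _as_dosage_array(g) -> np.ndarray:
    if isinstance(g, GenotypeMatrix):
        return g.dosages
    return np.asarray(g)


def _variant_name(g, j: int) -> str:
    if isinstance(g, GenotypeMatrix):
        return g.variants[j].id
    return f"column {j}"


def standardize_columns(g, mode: str = "binom") -> StandardizedMatrix:
    """Standardize each SNP column of a genotype matrix.

    Parameters
    ----------
    g : GenotypeMatrix or integer array with :data:`MISSING` sentinels.
    mode : "binom" (center then binomial scale), "center" (center only) or
        "none" (dosages cast to float, untouched).

    Raises
    ------
    ValueError
        If a column has no observed (non-missing) dosages, naming the SNP.
    """
    if mode not in MODES:
        raise ValueError(f"unknown standardization mode {mode!r}")
    dosages = _as_dosage_array(g)
    if dosages.shape[0] < 2 and mode != "none":
        raise ValueError("standardization needs at least 2 samples")
    x = dosages.astype(np.float64)
    observed = dosages != MISSING
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"SNP {_variant_name(g, j)!r}: all genotypes missing")

    sums = np.where(observed, x, 0.0).sum(axis=0)
    means = sums / n_obs
    p = x.shape[1]
    if mode == "none":
        return StandardizedMatrix(x, means, np.ones(p), mode)

    x = np.where(observed, x, means)  # mean-impute -> exact 0 after centering
    x -= means
    scales = np.ones(p)
    if mode == "binom":
        q = (1.0 + sums) / (2.0 + 2.0 * n_obs)
        var = q * (1.0 - q)
        degenerate = var <= 0.0  # unreachable with the pseudocount; guard anyway
        if degenerate.any():
            names = [_variant_name(g, j) for j in np.flatnonzero(degenerate)[:5]]
            warnings.warn(
                f"{int(degenerate.sum())} SNP(s) with degenerate allele frequency "
                f"(e.g. {names}); their columns were zero-filled",
                stacklevel=2,
            )
            var = np.where(degenerate, 1.0, var)
        scales = np.sqrt(var)
        x /= scales
        if degenerate.any():
            x[:, degenerate] = 0.0
    return StandardizedMatrix(x, means, scales, mode)


def standardize_rows(g, mode: str = "binom") -> StandardizedMatrix:
    """Standardize rows instead of columns (the transposed-data orientation).

    Defined as :func:`standardize_columns` applied to the transpose; the
    returned values are transposed back so shape matches the input, and
    ``col_means``/``col_scales`` describe the rows of the input.
    """
    dosages = _as_dosage_array(g)
    res = standardize_columns(dosages.T, mode)
    return StandardizedMatrix(res.values.T, res.col_means, res.col_scales, mode)
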