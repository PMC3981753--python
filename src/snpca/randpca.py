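"""Randomized top-k PCA of standardized genotype matrices.

The decomposition targets the sample covariance of the standardized n x p
matrix X. Rather than a full eigendecomposition of the n x n Gram matrix
S = X X^T (or p x p X^T X), a randomized subspace iteration sketches the
dominant eigenspace:

1. draw an iid standard-normal matrix R of size n x (k + l);
2. Y <- S R, normalize each column by its l2 norm, Q <- orthonormal factor
   of QR(Y);
3. repeat ``maxiter`` times: Y <- S Q, column-normalize, Q <- QR(Y);
4. form the small (k+l) x (k+l) matrix B = Q^T S Q, symmetrized;
5. eigendecompose B and map the eigenvectors back through Q.

The l "extra" dimensions absorb approximation error and are discarded; with
a handful of power iterations the top-k eigenpairs match the exact
decomposition to near machine precision for spectra with any decay, at a
cost dominated by k+l matrix-vector products per iteration instead of a
dense n x n factorization.

When n > p the same algorithm runs on the p x p Gram matrix instead (the
"transpose trick"): its eigenvectors are the SNP loadings V, the principal
components are P = X V, and the sample eigenvectors are recovered by
column-normalizing P. Nonzero eigenvalues of the two Gram matrices are
identical, so results agree up to eigenvector sign.

Reported eigenvalues are on the scaled-covariance convention
lambda / (p - 1); the weighted principal components satisfy
P_j = U_j * sqrt(lambda_j) with lambda_j the *unscaled* Gram eigenvalue,
i.e. P = U Sigma with Sigma the singular values of X.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .genotype_io import GenotypeMatrix
from .standardize import MODES, StandardizedMatrix, standardize_columns

__all__ = [
    "RandPCAConfig",
    "PCAResult",
    "rand_eigen",
    "choose_orientation",
    "randomized_pca",
    "exact_pca",
    "decompose_standardized",
    "exact_standardized",
]

#: Total sketch dimension k + extra used when ``extra`` is left unset,
#: capped by the smaller matrix dimension. Ample for the first ~10 PCs.
DEFAULT_TOTAL_DIM = 200


@dataclass
class RandPCAConfig:
    """Settings for :func:`randomized_pca`.

    k : number of eigenpairs/PCs wanted.
    extra : auxiliary sketch dimensions l, discarded after the solve.
        None resolves to min(DEFAULT_TOTAL_DIM, min(n, p)) - k at run time.
    maxiter : fixed number of power iterations (no convergence test, so
        runtime is deterministic).
    seed : RNG seed; identical seed + config + input gives bit-identical
        output.
    stand : standardization mode, one of "binom", "center", "none".
    orientation : "auto" picks the smaller Gram matrix; "columns"/"rows"
        force working in sample space (X X^T) / SNP space (X^T X).
    """

    k: int = 10
    extra: Optional[int] = None
    maxiter: int = 10
    seed: int = 0
    stand: str = "binom"
    orientation: str = "auto"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.extra is not None and self.extra < 0:
            raise ValueError("extra must be >= 0")
        if self.maxiter < 0:
            raise ValueError("maxiter must be >= 0")
        if self.stand not in MODES:
            raise ValueError(f"unknown standardization mode {self.stand!r}")
        if self.orientation not in ("auto", "rows", "columns"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def resolved_extra(self, n: int, p: int) -> int:
        if self.extra is not None:
            return self.extra
        return max(0, min(DEFAULT_TOTAL_DIM, min(n, p)) - self.k)


@dataclass
class PCAResult:
    """Top-k eigenpairs and principal components.

    eigenvalues : non-increasing, on the covariance scale lambda/(p-1).
    eigenvectors_U : n x k, orthonormal columns (sample-space eigenvectors).
    pcs_P : n x k weighted PCs, P = U Sigma.
    loadings_V : p x k SNP loadings, or None.
    orientation_used : which Gram matrix the solve ran on.
    sample_ids : (FID, IID) pairs carried through from the input, if known.
    """

    eigenvalues: np.ndarray
    eigenvectors_U: np.ndarray
    pcs_P: np.ndarray
    loadings_V: Optional[np.ndarray]
    orientation_used: str
    sample_ids: Optional[list[tuple[str, str]]] = None

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


def choose_orientation(n: int, p: int, policy: str = "auto") -> str:
    """Pick the Gram matrix to decompose: "columns" = X X^T, "rows" = X^T X.

    Auto policy works in sample space when n <= p (ties included), else in
    SNP space, so the dense object is always min(n, p)-sized.
    """
    if policy in ("rows", "columns"):
        return policy
    if policy != "auto":
        raise ValueError(f"unknown orientation policy {policy!r}")
    return "columns" if n <= p else "rows"


def _normalize_columns(y: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(y, axis=0)
    return y / np.where(norms > 0, norms, 1.0)


def rand_eigen(
    s_apply: Callable[[np.ndarray], np.ndarray],
    n: int,
    k: int,
    extra: int,
    maxiter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomized eigendecomposition of a symmetric PSD operator.

    Parameters
    ----------
    s_apply : maps an (n, m) block to S @ block for the implicit symmetric
        positive-semidefinite S.
    n : operator dimension.
    k, extra : sketch is k + extra columns wide.
    maxiter : number of power iterations after the initial sketch.
    rng : seeded generator supplying the Gaussian sketch.

    Returns
    -------
    (eigenvalues, eigenvectors) of the k + extra leading eigenpairs,
    eigenvalues sorted non-increasing, eigenvectors as columns.
    """
    m = k + extra
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= k+extra <= n, got k+extra={m}, n={n}")

    def _apply(block: np.ndarray, stage: str) -> np.ndarray:
        y = s_apply(block)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite values at {stage}")
        return y

    q = rng.standard_normal((n, m))
    y = _apply(q, "initial sketch")
    q, _ = np.linalg.qr(_normalize_columns(y))
    for it in range(maxiter):
        y = _apply(q, f"power iteration {it + 1}")
        q, _ = np.linalg.qr(_normalize_columns(y))
    b = q.T @ _apply(q, "projection")
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    return evals[order], q @ evecs[:, order]


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Per-column sign flips making the largest-magnitude entry positive.

    Eigenvectors are defined only up to sign; this deterministic convention
    (ties broken by earliest index, as argmax does) makes outputs
    reproducible across runs and orientations.
    """
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def _clamp_eigenvalues(lam: np.ndarray) -> np.ndarray:
    # tiny float-negative eigenvalues of a PSD operator are rounded to 0
    top = lam[0] if len(lam) and lam[0] > 0 else 1.0
    if lam.min(initial=0.0) < -1e-9 * top:
        raise FloatingPointError("operator produced significantly negative eigenvalues")
    return np.maximum(lam, 0.0)


def _assemble(
    x: np.ndarray,
    lam_gram: np.ndarray,
    u: np.ndarray,
    v: Optional[np.ndarray],
    orientation: str,
    sample_ids,
) -> PCAResult:
    n, p = x.shape
    lam_gram = _clamp_eigenvalues(lam_gram)
    sigma = np.sqrt(lam_gram)
    if orientation == "rows":
        pcs = x @ v
        norms = np.linalg.norm(pcs, axis=0)
        u = pcs / np.where(norms > 0, norms, 1.0)
    else:
        pcs = u * sigma
        if v is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(sigma > 0, (x.T @ u) / np.where(sigma > 0, sigma, 1.0), 0.0)
    signs = _fix_signs(u)
    return PCAResult(
        eigenvalues=lam_gram / max(p - 1, 1),
        eigenvectors_U=u * signs,
        pcs_P=pcs * signs,
        loadings_V=None if v is None else v * signs,
        orientation_used=orientation,
        sample_ids=sample_ids,
    )


def decompose_standardized(
    x: np.ndarray, cfg: RandPCAConfig, sample_ids=None
) -> PCAResult:
    """Randomized top-k PCA of an already-standardized real matrix."""
    x = np.asarray(x, dtype=np.float64)
    n, p = x.shape
    extra = cfg.resolved_extra(n, p)
    if cfg.k + extra > min(n, p):
        raise ValueError(
            f"k + extra = {cfg.k + extra} exceeds min(n, p) = {min(n, p)}"
        )
    orientation = choose_orientation(n, p, cfg.orientation)
    rng = np.random.default_rng(cfg.seed)
    if orientation == "columns":
        lam, vecs = rand_eigen(lambda b: x @ (x.T @ b), n, cfg.k, extra, cfg.maxiter, rng)
        return _assemble(x, lam[: cfg.k], vecs[:, : cfg.k], None, orientation, sample_ids)
    lam, vecs = rand_eigen(lambda b: x.T @ (x @ b), p, cfg.k, extra, cfg.maxiter, rng)
    return _assemble(x, lam[: cfg.k], None, vecs[:, : cfg.k], orientation, sample_ids)


def randomized_pca(g: GenotypeMatrix, cfg: RandPCAConfig) -> PCAResult:
    """Standardize a genotype matrix and run the randomized decomposition."""
    std = standardize_columns(g, cfg.stand)
    ids = g.sample_ids if isinstance(g, GenotypeMatrix) else None
    return decompose_standardized(std.values, cfg, sample_ids=ids)


def exact_standardized(
    x: np.ndarray,
    k: int,
    method: str = "svd",
    orientation: str = "auto",
    sample_ids=None,
) -> PCAResult:
    """Exact top-k PCA of a standardized matrix, by full SVD or by dense
    eigendecomposition of the (smaller) Gram matrix. The two methods agree
    to floating-point accuracy and share output conventions with
    :func:`decompose_standardized`; this is the oracle the randomized path
    is validated against.
    """
    x = np.asarray(x, dtype=np.float64)
    n, p = x.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"need 1 <= k <= min(n, p), got k={k}")
    orient = choose_orientation(n, p, orientation)
    if method == "svd":
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        lam = s[:k] ** 2
        if orient == "rows":
            return _assemble(x, lam, None, vt[:k].T, orient, sample_ids)
        return _assemble(x, lam, u[:, :k], vt[:k].T, orient, sample_ids)
    if method != "eigen":
        raise ValueError(f"unknown method {method!r}")
    if orient == "columns":
        lam, vecs = np.linalg.eigh(x @ x.T)
        order = np.argsort(lam)[::-1][:k]
        return _assemble(x, lam[order], vecs[:, order], None, orient, sample_ids)
    lam, vecs = np.linalg.eigh(x.T @ x)
    order = np.argsort(lam)[::-1][:k]
    return _assemble(x, lam[order], None, vecs[:, order], orient, sample_ids)


def exact_pca(
    g: GenotypeMatrix,
    k: int = 10,
    stand: str = "binom",
    method: str = "svd",
    orientation: str = "auto",
) -> PCAResult:
    """Exact full-decomposition PCA of a genotype matrix (oracle path)."""
    std = standardize_columns(g, stand)
    ids = g.sample_ids if isinstance(g, GenotypeMatrix) else None
    return exact_standardized(std.values, k, method, orientation, sample_ids=ids)
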