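# Methods

## Problem and data model

`snpca` extracts the top-k eigenpairs and principal components of a
standardized genotype matrix X (n samples × p SNPs of allele dosages
0/1/2, with a missing sentinel). The intended input is LD-pruned SNP data:
the solver assumes nothing about linkage, but principal components of
unpruned data are distorted by local LD, so pruning to ~10k–50k markers
with external tooling is the expected preprocessing, as in standard
population-structure pipelines.

## Standardization

Three per-SNP modes, selected by `--standx` / `RandPCAConfig.stand`:

- `binom` (default): center by the observed mean μ_j, divide by
  sqrt(q_j(1−q_j)) with q_j = (1 + Σx)/(2 + 2n_j), the posterior-mean
  allele-frequency estimate with one pseudo-observation of each allele.
  This is the smartpca-compatible scaling: the divisor is proportional to
  the standard deviation of a Binomial(2, q) dosage, up-weighting rare
  variants. The literature leaves the proportionality constant
  unspecified (sqrt(q(1−q)) vs sqrt(2q(1−q))); we fix sqrt(q(1−q)). The
  constant rescales all eigenvalues uniformly and leaves eigenvectors and
  PC directions unchanged, so nothing downstream depends on the choice.
- `center`: mean-centering only (classical prcomp-style PCA).
- `none`: raw dosages as floats, for callers who standardize themselves.

Missing dosages are mean-imputed per SNP before centering, so they
contribute exactly zero afterwards and leave the covariance unbiased in
expectation; μ_j and q_j are computed over observed entries only. A SNP
with no observed genotypes is an error (it has no estimable frequency). The
pseudocount keeps q strictly inside (0,1), so a zero scale is impossible
for valid input; a defensive guard still zero-fills and warns rather than
aborting if it is ever hit.

Row standardization (`standardize_rows`) is defined as column
standardization of the transpose and exists for workflows that store the
data SNP-major; the solver itself always standardizes columns and handles
the n > p case through the Gram-operator choice below, which is
mathematically the same transposition shortcut.

## Randomized eigendecomposition

The solver targets the symmetric PSD Gram operator S (either X Xᵀ, n × n,
or Xᵀ X, p × p) without forming it densely; every access is two thin
matrix products. With sketch width m = k + l:

1. R ← n × m iid N(0,1) from one seeded `numpy` Generator;
2. Y ← S R; divide each column of Y by its ℓ2 norm; Q ← Q-factor of QR(Y);
3. repeat `maxiter` times: Y ← S Q, column-normalize, Q ← QR(Y);
4. B ← Qᵀ S Q, symmetrized as (B + Bᵀ)/2 to scrub round-off asymmetry;
5. eigendecompose B (dense `eigh`), sort descending, map back through Q.

The column normalization guards against overflow/underflow under repeated
application of S; QR provides the actual re-orthonormalization. The
iteration count is fixed — no convergence test — so runtime is
deterministic and accuracy is certified by the oracle test suite instead.
Power iteration sharpens the spectral separation as (λ_m/λ_k)^(2·maxiter),
so for spectra with any decay the defaults reach near machine precision on
the leading eigenpairs; for perfectly flat spectra (iid noise with no
structure) the leading subspace is ill-defined and no subspace method, nor
the data, distinguishes the components.

Defaults: k = 10 (the usual number of ancestry covariates), maxiter = 10,
and l chosen so the sketch totals min(200, min(n,p)) columns — generous for
10 PCs while keeping B trivially small. All are overridable; `extra` given
explicitly is used as-is.

### Orientation dispatch

`auto` works on X Xᵀ when n ≤ p (ties to sample space) and on Xᵀ X
otherwise, so the sketch always lives in the smaller dimension. The two
Gram matrices share their nonzero eigenvalues; in SNP space the recovered
eigenvectors are the loadings V, the PCs are P = X V, and U is P with
columns normalized. Both orientations can be forced for testing, and agree
up to floating point (exactly, when the sketch spans the small dimension;
to solver accuracy otherwise).

### Output conventions

- Eigenvalues are reported on the scaled-covariance convention Λ/(p−1),
  matching the unbiased-covariance/prcomp convention; the scale factor is
  applied once at the end, never to the matrix. For the degenerate p = 1
  the divisor is taken as 1.
- Both the weighted PCs P = U Σ and the bare orthonormal U are emitted,
  since downstream tools disagree on which to call "the PCs"; the scale
  difference has no bearing on interpretation.
- Sign convention: each eigenvector is flipped so its largest-magnitude
  entry is positive (ties broken by earliest index). Eigenvectors are
  defined only up to sign; fixing one makes outputs bit-reproducible
  across runs, methods and orientations.
- Tiny negative eigenvalues from round-off (above −1e-9 × λ₁) are clamped
  to zero; anything more negative raises, since the operator must be PSD.
- The Gaussian draw comes from a single seeded generator in a fixed order,
  so identical seed + config + input gives bit-identical output.

## Exact oracle

`exact_pca` computes the same quantities by full SVD or by dense
eigendecomposition of the (smaller) Gram matrix. The two routes are
mathematically identical (σ² = λ) and are tested against each other and
against scikit-learn's exact PCA (converting between its 1/(n−1) and our
1/(p−1) variance conventions). The randomized path is validated against
this oracle, never against itself.

## PLINK I/O

The reader decodes SNP-major PLINK 1 `.bed` files (magic `0x6C 0x1B`, mode
`0x01`): per variant, ceil(n/4) bytes, two bits per genotype unpacked from
the least-significant pair upward, codes 00→2, 01→missing, 10→1, 11→0,
with pad bits ignored. Decoding is a 256×4 table lookup, optionally
chunked by variants to bound memory; chunked and whole-file reads are
bit-identical. Individual-major files, truncations and bad magic are
distinct errors. Dosage counts the A1 (first-listed) allele; flipping the
counted allele only flips eigenvector signs. `.bim`/`.fam` are parsed as
whitespace-delimited 6-column text with line-numbered errors; blank lines
are ignored. A BED *encoder* exists in the simulation module for writing
synthetic filesets and round-trip testing; it is not a supported user
path for real data.

Outputs are whitespace-delimited text at 6 significant digits:
`<prefix>.eigenvalues` (k lines), `<prefix>.eigenvectors` (bare n × k, for
smartpca-style consumers) and `<prefix>.pcs` (header row, FID IID + k
weighted PCs, joinable to phenotype tables). All files are written to
temporaries and renamed into place, so an interrupted run leaves no
partial set. A JSON manifest records the resolved configuration, input
sizes, orientation used and wall time.

## Synthetic data generator

`simulate_genotypes` draws from the Balding–Nichols island model: per SNP
an ancestral frequency π ~ Uniform(maf_range), per population a frequency
from Beta(π(1−F)/F, (1−π)(1−F)/F) — mean π, variance π(1−π)F — and per
individual a Binomial(2, pop-frequency) dosage, with optional independent
missingness. Defaults (3 × 100 samples, 5,000 SNPs, F = 0.1,
maf ∈ [0.05, 0.5], no missingness) give a dataset whose two leading
components cleanly separate the three populations, the qualitative
structure continental-scale human panels show on PC1/PC2; discrete islands
were chosen over continuous-admixture models precisely because cluster
recovery is then crisply assertable (silhouette against true labels).

What the generator deliberately omits — and what passing tests therefore
do not certify: linkage disequilibrium (SNPs are independent, emulating
post-pruning data; the solver's accuracy on *unpruned* data is a data
question, not an algorithmic one), admixture gradients and relatedness,
genotyping batch effects, and case/control ascertainment. The concordance
and recovery results certify the solver and codec, not any robustness of
PCA itself to those real-data features.

## Problem sizes in the shipped checks

The acceptance computation uses the 3 × 100 × 5,000 design above: large
enough that the structured eigenvalues dominate the noise bulk by an order
of magnitude, small enough that the exact oracle is instant. Oracle
equivalence is checked on random matrices with geometrically decaying
spectra (n, p ≤ 300, ratio 0.8–0.92): decaying spectra are the regime
where per-component comparisons are well-posed; near-degenerate bulk
eigenvalues of genotype noise differ between any two solvers in ways that
are irrelevant to (and invisible in) the retained top components.

## Known limitations

- Single-threaded and in-memory: X is held densely as float64, so ~16 GB
  of genotypes is a practical ceiling; streaming/out-of-core covariance is
  not implemented.
- No LD pruning, QC or frequency filtering: those belong to upstream
  tooling.
- No whitening/de-correlation transform, no sparse PCA, no PLINK 2
  `.pgen`/VCF input.
- Fixed iteration count means a pathological spectrum (near-flat with
  meaningful structure just below the sketch width) can under-resolve
  trailing retained components; raising `--nextra`/`--maxiter` is the
  remedy and costs linearly.
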