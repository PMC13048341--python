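# Methods

## Decomposition algorithms

**Exact path.** `exact_svd` computes the full thin SVD of the prepared
matrix through the backend (LAPACK `gesdd` on the reference backend) and
truncates afterwards. It never uses the sketch, so its leading triplets
are exact up to LAPACK accuracy; it serves as the reference for every
validation metric. All decomposition arithmetic is float64.

**Randomized path.** `randomized_svd` implements Gaussian range
sketching with subspace (power) iteration. For an n × p matrix M and
target rank k:

1. draw Ω ∈ R^{p×(k+ℓ)} from the backend's seeded standard-normal
   sampler (oversampling ℓ, default 10);
2. Y = MΩ; Q ← thin-QR(Y);
3. for each of q power iterations (default 2):
   Z ← thin-QR(MᵀQ); Q ← thin-QR(MZ) — re-orthonormalizing at *every*
   half-step, the numerically stable form of subspace iteration (raw
   (MMᵀ)^q multiplication squares the condition number each pass and
   underflows small singular directions);
4. B = QᵀM; exact SVD of the (k+ℓ) × p matrix B; U = Q·U_B; truncate
   to k.

The projected singular values can never exceed the true ones
(Rayleigh–Ritz), which the tests assert as `S̃_i ≤ S_i + 1e-8`.

Defaults ℓ = 10, q = 2 are standard practice for this family of
sketching algorithms: ℓ = 10 makes the subspace-capture failure
probability negligible, and q = 2 suffices when a matrix has a decaying
leading spectrum over a noise bulk, which prepared expression matrices
do. Both are overridable everywhere (API, CLI, config file).

**Sign convention.** Singular-vector signs are arbitrary. Every
decomposition flips each (U column, Vt row) pair so the
largest-magnitude entry of the U column is positive; `align_signs`
additionally aligns a candidate to a reference by the sign of the U
column dot products before any vector-wise comparison. Without a
convention, CCC of PC scores would be meaningless.

**Ties.** Order among numerically equal singular values is whatever the
backend's small SVD returns; comparisons in degenerate cases must be
made on subspaces, not individual vectors.

## Matrix preparation

Transformations apply in the fixed order
**transpose → log(x + pseudocount) → center → scale**:

* Orientation: single-cell matrices normally arrive features × samples
  (genes × cells); `prep_matrix` transposes them to samples × features.
  With `orientation="auto"` the longer axis is taken as samples (cells
  vastly outnumber genes in practice); an undeclared square matrix is an
  error rather than a guess.
* Log transform: `log_base` 2 or e, pseudocount default 1 (counts
  contain zeros; log2(x+1) is the standard variance-stabilizing choice
  for count data).
* Centering/scaling: column mean subtraction and division by the sample
  standard deviation (n−1 denominator, the R convention). Zero-variance
  features cannot be scaled; the default policy drops them with a
  warning and records them in provenance (`keep_zero` and `error` are
  available).

Provenance (orientation, bases, pseudocount, dropped features, and the
per-column means/sds when centering or scaling was applied) is stored on
the `PreparedMatrix` and written to `prep.json` by the pipeline.

## Validation metrics

* **SSE ratio** = ‖M − Û_k‖²_F / ‖M − M_k‖²_F with M_k the exact rank-k
  truncation. Eckart–Young guarantees the ratio ≥ 1; 1 means the
  candidate captured the same variance as the optimal truncation.
  Degenerate guard: when the reference SSE is below roundoff —
  den < (1e-13·‖M‖_F)², i.e. the matrix is effectively rank ≤ k — the
  ratio is undefined and an error is raised (an absolute cutoff would
  never fire, since a floating-point decomposition of an exactly
  low-rank matrix still leaves a ~1e-30 residual).
* **Frobenius errors**: absolute ‖M − reconstruction‖_F and relative
  (divided by ‖M‖_F by default; a centered-sum-of-squares divisor is
  available and the divisor used is recorded in the report).
* **CCC** uses Lin's original population-moment (1/n) estimators. The
  sample-moment variant differs only in the weight of the mean-shift
  term; only the canonical definition is offered.
* Reported tables round half-to-even to 6 decimals (SSE ratio) and 4
  decimals (CCC) at presentation time only; JSON keeps full precision.

## Synthetic data

**`make_lowrank(n, m, spectrum, noise_sd, seed)`** builds
U·diag(spectrum)·Vᵀ + noise_sd·G with orthonormal factors from QR of
seeded Gaussians (sign convention applied, so planted factors compare
directly to estimates) and i.i.d. standard-normal G. Note the noise
perturbs the *spectrum* by roughly its operator norm
noise_sd·(√n + √m), not by noise_sd: planted values below that scale
are inflated toward the noise bulk edge (observed value ≈
√(σ² + noise_sd²(n+m))) in the matrix itself, so no decomposition
method can recover them accurately — a property of the construction,
not of the solver.

**`make_counts(n_cells, n_genes, n_programs, mean_depth, dispersion,
seed)`** emulates a single-cell / spatial expression count matrix:
a rank-`n_programs` log-rate matrix from Gaussian factors with program
strengths decaying as j^{−1/2} and total log-rate sd 2 (a few
fold-changes between cell populations), softplus link, per-gene
baselines, columns scaled so the expected depth per cell is
`mean_depth`, and Gamma–Poisson (negative binomial) sampling with shape
`dispersion` (variance μ + μ²/dispersion; Poisson in the large-
dispersion limit). Defaults (depth 300, dispersion 2) sit in the range
typical of imaging-based spatial panels. After log2/center/scale
preparation this reproduces the spectral shape of real expression
matrices — leading components carrying several percent of variance each
above a flat sampling-noise bulk — which is what makes it a meaningful
stand-in for decomposition benchmarks.

What the fixtures do **not** emulate: batch effects, spatial
autocorrelation, gene–gene correlation beyond the low-rank programs,
zero inflation beyond NB sampling, and cell-type label structure.
Passing tests demonstrate numerical correctness of the decompositions
and metrics on realistic spectra; they do not certify biological
conclusions drawn from any particular dataset.

## Benchmark problem sizes

The package's standing accuracy benchmark (tests and
`scripts/acceptance.py`) uses a 20,000-cell × 500-gene synthetic counts
matrix at k = 100 — the same protocol shape as full-scale spatial
datasets (tall and thin, k well beyond the informative rank) at a size
where the exact reference decomposition is cheap to recompute. One
consequence of desk scale is a wider relative noise bulk (bulk width
scales with √(p/n)), so the randomized path's SSE excess over optimal
is a few percent here versus a few tenths of a percent on 200k-cell
data; the PC-score concordances (CCC 1.0000 to four decimals) and the
machine-precision exact reconstruction transfer across scales.

## Backends

The numeric contract is matmul, thin QR, full SVD of small dense
matrices, and the seeded Gaussian sampler. Every backend must draw from
numpy's `default_rng(seed)` stream, so randomized results are
bit-reproducible per (backend, seed). The reference backend is pure
NumPy and always present; a torch backend registers itself lazily when
torch is importable and accepts `device="gpu"` only if CUDA is actually
available — a GPU request on a CPU-only host is an error, never a
silent fallback. The reference backend delegates threading to NumPy's
BLAS and reports an effective thread count of 1 (the only count it can
guarantee).

## Known limitations

* Sparse matrices are densified before decomposition; sparse-aware
  sketching is out of scope.
* The randomized path's tail singular values (deep in a flat noise
  bulk) are biased slightly low; increase `power_iters` or `oversample`
  if the tail matters.
* No out-of-core path: the prepared matrix must fit in memory in
  float64.
* CCC confidence intervals and inferential statistics are not provided.
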