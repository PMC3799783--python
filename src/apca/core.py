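"""Asymmetric PCA: class-weighted covariance decomposition of expression data.

The method targets two-class designs with unbalanced group sizes
(n controls, d cases, n >> d is common). Standard PCA builds the total
covariance, which implicitly weights each class-conditional covariance
by its sample fraction, so the minority class contributes little. APCA
instead eigendecomposes

    C = a * C_n + (1 - a) * C_d + b * C_B,   0 < a < 1, b >= 0,

where C_n and C_d are the class-conditional covariances of control and
case samples, C_B is the between-class (class-mean scatter) matrix, and
the weights are free parameters. A large b forces the leading
eigenvector to absorb the class-mean difference together with the
shared genome-wide profile, so the *second* eigenvector — the
discriminant component — captures the dominant within-class contrast
between the groups; its gene-space coefficients are the per-probe
scores used for differential-expression calling.

Because the number of probes m vastly exceeds the number of samples l,
all eigenproblems are solved in the l-dimensional sample space via the
Gram matrix X'X (the snapshot trick) and results are back-projected to
gene space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, AnnotationMap, ExpressionMatrix

#: Relative eigenvalue cutoff below which Gram directions are treated as null.
DEFAULT_RANK_TOL = 1e-10

#: Basis conventions for the back-projection matrix (see :func:`gram_project`).
BASIS_MODES = ("orthonormal", "raw")


@dataclass
class APCAParams:
    """Weights of the asymmetric covariance combination.

    ``a`` multiplies the control-class covariance (so ``1 - a`` weights
    the case class; a < 0.5 emphasises the minority case class), and
    ``b`` the between-class matrix. ``n_components`` limits how many
    eigenpairs are retained (None keeps all).
    """

    a: float = 0.3
    b: float = 20.0
    n_components: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.a < 1:
            raise ValueError(f"a must lie in (0, 1), got {self.a}")
        if self.b < 0:
            raise ValueError(f"b must be non-negative, got {self.b}")


@dataclass
class EigenResult:
    """Eigendecomposition of the weighted covariance, sorted descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are eigenvectors
    proportions: np.ndarray
    cumulative: np.ndarray


@dataclass
class APCADecomposition:
    """All intermediate and final quantities of one APCA run."""

    basis: np.ndarray          # m x r back-projection basis
    projected: np.ndarray      # r x l sample coordinates
    gram_eigenvalues: np.ndarray
    class_covs: tuple[np.ndarray, np.ndarray, np.ndarray]  # (C_n, C_d, C_B)
    weighted: np.ndarray       # r x r combined matrix C
    eigen: EigenResult
    pc_gene: np.ndarray        # m x k gene-space components (sign-fixed)
    factor_loadings: np.ndarray  # l x k sample-PC correlations
    params: APCAParams
    mode: str
    probe_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    labels: list[str] | None = None

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.eigen.eigenvalues

    @property
    def proportions(self) -> np.ndarray:
        return self.eigen.proportions

    @property
    def cumulative(self) -> np.ndarray:
        return self.eigen.cumulative

    def summary(self) -> pd.DataFrame:
        """Eigenvalue / proportion / cumulative table, one row per PC."""
        return pd.DataFrame({
            "pc": np.arange(1, len(self.eigenvalues) + 1),
            "eigenvalue": self.eigenvalues,
            "proportion": self.proportions,
            "cumulative": self.cumulative,
        })


def gram_project(x: ExpressionMatrix | np.ndarray,
                 tol: float = DEFAULT_RANK_TOL,
                 mode: str = "orthonormal") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project the m x l matrix X into sample space via the Gram trick.

    The Gram matrix S = X'X shares its nonzero eigenvalues with the
    m x m scatter XX'; left directions are recovered as X @ EIV_S.
    Directions whose Gram eigenvalue is <= ``tol`` times the largest are
    dropped as numerically null.

    ``mode`` selects the back-projection convention:

    * ``"orthonormal"`` — columns normalised to unit length, giving an
      orthonormal basis (each column divided by sqrt(eigenvalue));
      required for the exact equivalence with full-space PCA.
    * ``"raw"`` — the unnormalised product X @ EIV_S, whose columns
      scale with the data; downstream gene scores then live on the
      intensity scale of the input rather than on a unit sphere.

    Returns ``(basis, projected, gram_eigenvalues)`` with basis m x r,
    projected = basis' X of size r x l, and the r retained eigenvalues.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    m, l = values.shape
    if m < l:
        raise ValueError(f"expected m >= l (probes >= samples), got {m} x {l}")
    if mode not in BASIS_MODES:
        raise ValueError(f"mode must be one of {BASIS_MODES}, got {mode!r}")
    gram = values.T @ values
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(-evals, kind="stable")
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValueError("zero matrix: no nonzero eigenvalues")
    keep = evals > tol * evals[0]
    evals, evecs = evals[keep], evecs[:, keep]
    basis = values @ evecs
    if mode == "orthonormal":
        basis = basis / np.sqrt(evals)
    projected = basis.T @ values
    return basis, projected, evals


def _class_indices(labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels)
    ctrl = np.flatnonzero(lab == CONTROL)
    case = np.flatnonzero(lab == CASE)
    if len(ctrl) == 0 or len(case) == 0:
        raise ValueError("both classes must have at least one sample")
    return ctrl, case


def class_stats(projected: np.ndarray,
                labels: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-conditional and between-class covariance matrices.

    With n controls, d cases and l = n + d samples in the projected
    coordinates, returns

    * ``C_n`` = (1/n) Y_n Y_n' — covariance of centred control samples,
    * ``C_d`` = (1/d) Y_d Y_d' — covariance of centred case samples,
    * ``C_B`` = (1/l) [n (M_n - M)(M_n - M)' + d (M_d - M)(M_d - M)'] —
      between-class scatter of the class means about the global mean.

    Divisors are the class sizes themselves (maximum-likelihood form),
    not n - 1.
    """
    projected = np.asarray(projected, float)
    ctrl, case = _class_indices(labels)
    l = projected.shape[1]
    if l != len(labels):
        raise ValueError("labels length must match sample count")
    xn, xd = projected[:, ctrl], projected[:, case]
    n, d = xn.shape[1], xd.shape[1]
    m_n = xn.mean(axis=1, keepdims=True)
    m_d = xd.mean(axis=1, keepdims=True)
    m_all = projected.mean(axis=1, keepdims=True)
    yn, yd = xn - m_n, xd - m_d
    c_n = (yn @ yn.T) / n
    c_d = (yd @ yd.T) / d
    dn, dd = m_n - m_all, m_d - m_all
    c_b = (n * (dn @ dn.T) + d * (dd @ dd.T)) / l
    return c_n, c_d, c_b


def weighted_covariance(c_n: np.ndarray, c_d: np.ndarray, c_b: np.ndarray,
                        params: APCAParams) -> np.ndarray:
    """Combine the three matrices: C = a*C_n + (1-a)*C_d + b*C_B.

    With a = n/l and b = 1 this reproduces the total covariance of the
    samples about the global mean, i.e. standard PCA.
    """
    c_n, c_d, c_b = (np.asarray(c, float) for c in (c_n, c_d, c_b))
    if not (c_n.shape == c_d.shape == c_b.shape):
        raise ValueError("covariance matrices must be conformable")
    return params.a * c_n + (1.0 - params.a) * c_d + params.b * c_b


def decompose(c: np.ndarray, n_components: int | None = None) -> EigenResult:
    """Eigendecompose a symmetric matrix; proportions = eigenvalue / trace.

    Eigenpairs are sorted by descending eigenvalue; exact ties keep
    their index order. Cumulative proportions are non-decreasing and end
    at 1 (over the full spectrum).
    """
    c = np.asarray(c, float)
    if not np.isfinite(c).all():
        raise ValueError("matrix contains non-finite entries")
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(-evals, kind="stable")
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("matrix has non-positive trace; no variance to apportion")
    proportions = evals / total
    cumulative = np.cumsum(proportions)
    if n_components is not None:
        evals = evals[:n_components]
        evecs = evecs[:, :n_components]
        proportions = proportions[:n_components]
        cumulative = cumulative[:n_components]
    return EigenResult(evals, evecs, proportions, cumulative)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Orient a vector so its maximum-|entry| coefficient is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def gene_scores(basis: np.ndarray, eigenvectors: np.ndarray, k: int = 2) -> np.ndarray:
    """Back-project the k-th eigenvector (1-based) to gene space.

    The resulting length-m vector holds one signed score per probe; the
    sign is fixed so the entry of maximum absolute value is positive
    (eigenvector signs are otherwise arbitrary).
    """
    r = eigenvectors.shape[1]
    if not 1 <= k <= r:
        raise ValueError(f"PC index k={k} out of range 1..{r}")
    return _fix_sign(basis @ eigenvectors[:, k - 1])


def score_table(scores: np.ndarray, probe_ids: list[str],
                annotation: AnnotationMap | None = None) -> pd.DataFrame:
    """Assemble the per-probe score table (probe_id, gene_symbol, score)."""
    if len(scores) != len(probe_ids):
        raise ValueError("one score per probe required")
    symbols = [annotation.symbol(p) if annotation else None for p in probe_ids]
    return pd.DataFrame({
        "probe_id": probe_ids,
        "gene_symbol": symbols,
        "score": np.asarray(scores, float),
    })


def factor_loadings(x: ExpressionMatrix | np.ndarray, pc_gene: np.ndarray) -> np.ndarray:
    """Pearson correlation of each sample column with a gene-space PC.

    The loading of sample j is corr(X[:, j], pc_gene), always in
    [-1, 1]. A zero-variance sample column has no defined correlation
    and raises ``ValueError`` naming the sample.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    ids = x.sample_ids if isinstance(x, ExpressionMatrix) else list(range(values.shape[1]))
    pc = np.asarray(pc_gene, float)
    if pc.shape[0] != values.shape[0]:
        raise ValueError("pc_gene length must equal the number of probes")
    pc_c = pc - pc.mean()
    pc_norm = np.linalg.norm(pc_c)
    if pc_norm == 0:
        raise ValueError("gene-space PC has zero variance")
    cols = values - values.mean(axis=0, keepdims=True)
    col_norms = np.linalg.norm(cols, axis=0)
    zero = np.flatnonzero(col_norms == 0)
    if zero.size:
        raise ValueError(f"zero-variance sample column(s): {[ids[j] for j in zero]}")
    return (cols.T @ pc_c) / (col_norms * pc_norm)


def apca(x: ExpressionMatrix, params: APCAParams | None = None,
         mode: str = "orthonormal", tol: float = DEFAULT_RANK_TOL) -> APCADecomposition:
    """Run the full asymmetric-PCA decomposition on a labelled matrix.

    Phases: Gram-trick projection to sample space, class-conditional and
    between-class covariance construction, asymmetric weighting,
    eigendecomposition, and back-projection of every retained component
    to gene space (with the positive-maximum sign convention) together
    with per-sample factor loadings.
    """
    params = params or APCAParams()
    x._require_labels()
    basis, projected, gram_evals = gram_project(x, tol=tol, mode=mode)
    c_n, c_d, c_b = class_stats(projected, x.labels)
    weighted = weighted_covariance(c_n, c_d, c_b, params)
    eigen = decompose(weighted, params.n_components)
    pc_gene = basis @ eigen.eigenvectors
    for j in range(pc_gene.shape[1]):
        i = int(np.argmax(np.abs(pc_gene[:, j])))
        if pc_gene[i, j] < 0:  # keep eigenvector and back-projection in sync
            pc_gene[:, j] *= -1
            eigen.eigenvectors[:, j] *= -1
    fls = np.column_stack([
        factor_loadings(x, pc_gene[:, j]) for j in range(pc_gene.shape[1])
    ])
    return APCADecomposition(
        basis=basis, projected=projected, gram_eigenvalues=gram_evals,
        class_covs=(c_n, c_d, c_b), weighted=weighted, eigen=eigen,
        pc_gene=pc_gene, factor_loadings=fls, params=params, mode=mode,
        probe_ids=list(x.probe_ids), sample_ids=list(x.sample_ids),
        labels=list(x.labels),
    )


def pca_baseline(x: ExpressionMatrix, mode: str = "orthonormal",
                 tol: float = DEFAULT_RANK_TOL) -> APCADecomposition:
    """Standard PCA expressed in the same weighted-covariance framework.

    Uses a = n/l and b = 1, which makes the combined matrix equal the
    total covariance of the projected samples about their global mean —
    the class-conditional covariances are weighted by their sample
    fractions, which is exactly what lets a majority class dominate.
    """
    x._require_labels()
    n, l = x.n_controls, x.n_samples
    return apca(x, APCAParams(a=n / l, b=1.0), mode=mode, tol=tol)
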