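"""Nuisance regressor construction, orthogonalisation and removal.

Nuisance regression removes non-neural signal models from voxel time
courses by ordinary least squares.  Four regressor blocks are supported:

* ``detr`` — constant, linear, quadratic trends on a time axis normalised
  to [-1, 1] (well conditioned by construction);
* ``wm`` / ``csf`` — the spatial-mean time course plus the first five
  temporal principal components of the voxel time courses inside an eroded
  tissue mask (six regressors per tissue, a CompCor-style basis);
* ``rp`` — the six realignment parameters from motion correction, passed
  through unchanged;
* ``expl`` — data-driven "exploratory" slow trends obtained from a
  lag-one canonical correlation analysis of dimension-reduced non-grey
  time courses, ranked by autocorrelation.

All non-trend blocks are orthogonalised against the polynomial trends with
a QR decomposition before regression, so that low-order drifts are carried
exclusively by the trend basis.  Exploratory trends are the exception:
they enter the design as estimated, and no other block is orthogonalised
against them.

Phase-randomised surrogate regressors — same amplitude spectra and
inter-regressor correlations, random Fourier phases — serve as a negative
control for the number-of-regressors effect.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "RegressorBlock",
    "DesignMatrix",
    "TissueExtraction",
    "polynomial_block",
    "extract_tissue_timecourses",
    "pca_block",
    "rp_block",
    "orthogonalise",
    "build_design",
    "regress_out",
    "unitary_dft_matrix",
    "regress_fourier",
    "phase_randomise",
    "exploratory_trends",
]

BLOCK_NAMES = ("detr", "wm", "csf", "rp", "expl")


@dataclasses.dataclass
class RegressorBlock:
    """A named set of nuisance regressors, one column per time course."""

    name: str
    columns: np.ndarray  # (N, k)

    def __post_init__(self) -> None:
        if self.name not in BLOCK_NAMES:
            raise ValueError(f"unknown block name {self.name!r}")
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.ndim != 2 or self.columns.shape[1] < 1:
            raise ValueError("block columns must form an N x k matrix, k >= 1")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError(f"block {self.name!r} contains non-finite values")
        norms = np.linalg.norm(self.columns, axis=0)
        if np.any(norms == 0):
            raise ValueError(f"block {self.name!r} has an identically zero column")

    @property
    def n_regressors(self) -> int:
        return self.columns.shape[1]


@dataclasses.dataclass
class DesignMatrix:
    """An assembled N x p design with per-column provenance labels."""

    X: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if p >= n:
            raise ValueError(f"design has p={p} columns for only N={n} samples")
        if len(self.labels) != p:
            raise ValueError("one provenance label required per column")

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]


@dataclasses.dataclass
class TissueExtraction:
    """Voxel time courses surviving tissue-mask thresholding and erosion."""

    mask: np.ndarray  # boolean 3-D
    threshold: float
    erosion_voxels: int
    timecourses: np.ndarray  # (N, V)


def normalised_time_axis(n_timepoints: int) -> np.ndarray:
    """Time axis spanning [-1, 1] in ``n_timepoints`` equal steps."""
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    return np.linspace(-1.0, 1.0, n_timepoints)


def polynomial_block(n_timepoints: int) -> RegressorBlock:
    """Constant, linear and quadratic trend regressors.

    The time axis is normalised to [-1, 1] so the three columns are far
    from collinear regardless of run length.
    """
    if n_timepoints < 4:
        raise ValueError("need at least 4 time points for a quadratic trend")
    t = normalised_time_axis(n_timepoints)
    cols = np.column_stack([np.ones_like(t), t, t**2])
    return RegressorBlock("detr", cols)


def extract_tissue_timecourses(
    bold: np.ndarray,
    prob_map: np.ndarray,
    threshold: float = 0.9,
    erosion_voxels: int = 1,
) -> TissueExtraction:
    """Threshold and erode a tissue probability map, extract time courses.

    The binary mask is ``prob_map >= threshold`` eroded ``erosion_voxels``
    times with the 6-connected structuring element; erosion guards against
    partial-volume contamination from neighbouring grey matter.
    """
    bold = np.asarray(bold, dtype=float)
    prob = np.asarray(prob_map, dtype=float)
    if bold.ndim != 4 or prob.shape != bold.shape[:3]:
        raise ValueError("prob_map must match the spatial dims of bold")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = prob >= threshold
    if erosion_voxels > 0 and mask.any():
        mask = ndimage.binary_erosion(mask, iterations=erosion_voxels)
    if not mask.any():
        raise ValueError(
            f"tissue mask empty after threshold={threshold}, "
            f"erosion={erosion_voxels} voxels"
        )
    tcs = bold[mask].T  # (N, V)
    return TissueExtraction(mask, threshold, erosion_voxels, tcs)


def pca_block(
    timecourses: np.ndarray, name: str = "wm", n_components: int = 5
) -> RegressorBlock:
    """Mean time course plus the first temporal principal components.

    The input is an N x V matrix of voxel time courses.  Each voxel is
    demeaned and the temporal PCs (left singular vectors scaled by their
    singular values, so amplitude reflects explained variance) are taken
    in descending explained-variance order.  Together with the spatial
    mean this yields ``n_components + 1`` regressors.

    PCA operates on the covariance of the demeaned data, not the
    correlation: voxels with larger fluctuations contribute more, which is
    intended since the components are meant to capture the dominant shared
    noise processes.
    """
    tcs = np.asarray(timecourses, dtype=float)
    if tcs.ndim != 2:
        raise ValueError("timecourses must be an N x V matrix")
    n, v = tcs.shape
    if v < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} voxels for {n_components} "
            f"components, got {v}"
        )
    mean_tc = tcs.mean(axis=1)
    demeaned = tcs - tcs.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(demeaned, full_matrices=False)
    pcs = u[:, :n_components] * s[:n_components]
    return RegressorBlock(name, np.column_stack([mean_tc, pcs]))


def rp_block(realignment_params: np.ndarray) -> RegressorBlock:
    """The six realignment parameters as regressors, unmodified.

    No temporal derivatives or squared expansions are added; collinearity
    with the constant trend (e.g. a parameter that never moves) is handled
    downstream by the orthogonalisation step.
    """
    rp = np.asarray(realignment_params, dtype=float)
    if rp.ndim != 2 or rp.shape[1] != 6:
        raise ValueError(
            f"realignment parameters must have exactly 6 columns, got shape {rp.shape}"
        )
    return RegressorBlock("rp", rp)


def orthogonalise(
    blocks: list[RegressorBlock],
    reference: RegressorBlock,
    tol: float = 1e-10,
) -> list[RegressorBlock]:
    """Orthogonalise every block against the polynomial trend basis.

    Uses the thin QR decomposition of the reference columns; each
    non-trend column has its projection onto the trend span subtracted, so
    the span of reference plus blocks is unchanged.  Columns lying
    entirely inside the trend span are dropped with a logged warning.
    Blocks named ``detr`` or ``expl`` pass through untouched (exploratory
    trends are used exactly as estimated).
    """
    q, _ = np.linalg.qr(reference.columns)
    out: list[RegressorBlock] = []
    for block in blocks:
        if block.name in ("detr", "expl"):
            out.append(block)
            continue
        cols = block.columns - q @ (q.T @ block.columns)
        orig_norms = np.linalg.norm(block.columns, axis=0)
        new_norms = np.linalg.norm(cols, axis=0)
        keep = new_norms > tol * np.maximum(orig_norms, 1.0)
        if not np.all(keep):
            dropped = np.flatnonzero(~keep)
            logger.warning(
                "block %r: dropping column(s) %s lying in the polynomial span",
                block.name,
                dropped.tolist(),
            )
            warnings.warn(
                f"block {block.name!r}: column(s) {dropped.tolist()} lie in the "
                "polynomial trend span and were dropped",
                stacklevel=2,
            )
        if keep.any():
            out.append(RegressorBlock(block.name, cols[:, keep]))
    return out


def build_design(blocks: list[RegressorBlock]) -> DesignMatrix:
    """Assemble blocks into a design matrix with provenance labels.

    Block order is preserved as given (callers use the stable order detr,
    expl, wm, csf, rp); labels are ``<block>_<index>``.
    """
    if not blocks:
        raise ValueError("cannot build a design from zero blocks")
    cols = np.column_stack([b.columns for b in blocks])
    labels = [f"{b.name}_{i}" for b in blocks for i in range(b.n_regressors)]
    return DesignMatrix(cols, labels)


def _check_full_rank(X: np.ndarray, labels: list[str] | None = None) -> None:
    n, p = X.shape
    # normalise columns first so the rank decision is scale-invariant
    # (designs mix units: baselines ~100, rotations ~1e-3)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0).tolist()
        names = [labels[i] for i in bad] if labels else bad
        raise np.linalg.LinAlgError(f"design matrix has zero columns: {names}")
    Xn = X / norms
    rank = np.linalg.matrix_rank(Xn)
    if rank < p:
        # identify offending columns via the pivoted QR diagonal
        _, r = np.linalg.qr(Xn)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0)).tolist()
        names = [labels[i] for i in bad] if labels else bad
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < p {p}); "
            f"dependent columns: {names}"
        )


def regress_out(y: np.ndarray, design: DesignMatrix | np.ndarray) -> np.ndarray:
    """Least-squares removal of the design from one or many time courses.

    Returns ``y - X (X'X)^-1 X' y`` computed through a QR-based solver
    (``numpy.linalg.lstsq``) for numerical conditioning.  ``y`` may be a
    single time course of length N or an N x V matrix; residuals are
    orthogonal to every design column.
    """
    if isinstance(design, DesignMatrix):
        X, labels = design.X, design.labels
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        labels = None
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"y has {Y.shape[0]} rows but design has {X.shape[0]}")
    if X.shape[1] >= X.shape[0]:
        raise ValueError("design must have fewer columns than time points")
    _check_full_rank(X, labels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid[:, 0] if squeeze else resid


def unitary_dft_matrix(n: int) -> np.ndarray:
    """The unitary DFT matrix U with ``U^-1 = U^H`` (F / sqrt(N))."""
    k = np.arange(n)
    F = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return F / np.sqrt(n)


def regress_fourier(Y: np.ndarray, X_fourier: np.ndarray) -> np.ndarray:
    """Residual spectrum of complex least squares in the Fourier domain.

    Given ``Y = U y`` and ``X_fourier = U x`` for the unitary DFT matrix
    U, returns ``(I - X (X^H X)^-1 X^H) Y``.  Because U is unitary, the
    inverse transform of the result equals the time-domain residual of
    ``regress_out`` — nuisance regression is a linear transformation of
    the Fourier components that mixes frequencies according to the
    regressors' spectra.
    """
    Y = np.asarray(Y, dtype=complex)
    X = np.atleast_2d(np.asarray(X_fourier, dtype=complex))
    squeeze = Y.ndim == 1
    Ymat = Y[:, None] if squeeze else Y
    if Ymat.shape[0] != X.shape[0]:
        raise ValueError("Y and X_fourier must have the same number of rows")
    gram = X.conj().T @ X
    if np.linalg.matrix_rank(gram) < X.shape[1]:
        raise np.linalg.LinAlgError("Fourier-domain design is rank deficient")
    beta = np.linalg.solve(gram, X.conj().T @ Ymat)
    resid = Ymat - X @ beta
    return resid[:, 0] if squeeze else resid


def phase_randomise(
    blocks: list[RegressorBlock],
    rng: np.random.Generator,
    n_repetitions: int = 25,
) -> list[list[RegressorBlock]]:
    """Phase-randomised surrogate regressor sets.

    For each repetition one random phase vector is drawn and applied to
    the Fourier transform of *every* regressor of every block, followed by
    an inverse FFT.  Sharing the phases within a repetition preserves all
    cross-spectra, hence the full inter-regressor correlation structure,
    while destroying any temporal alignment with the data.  Phases are
    applied with Hermitian symmetry — the DC bin and, for even N, the
    Nyquist bin stay real — so surrogates are exactly real-valued and
    amplitude spectra are preserved bin by bin.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if not blocks:
        return [[] for _ in range(n_repetitions)]
    n = blocks[0].columns.shape[0]
    n_rfft = n // 2 + 1
    surrogate_sets: list[list[RegressorBlock]] = []
    for _ in range(n_repetitions):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_rfft)
        phases[0] = 0.0
        if n % 2 == 0:
            phases[-1] = 0.0
        rotation = np.exp(1j * phases)
        rep: list[RegressorBlock] = []
        for block in blocks:
            spec = np.fft.rfft(block.columns, axis=0)
            surr = np.fft.irfft(spec * rotation[:, None], n=n, axis=0)
            rep.append(RegressorBlock(block.name, surr))
        surrogate_sets.append(rep)
    return surrogate_sets


def _classical_cca(
    A: np.ndarray, B: np.ndarray, reg: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlation analysis via whitened cross-covariance SVD.

    Returns (correlations, weights_a, weights_b), correlations descending.
    A small ridge keeps the within-set covariances invertible.
    """
    A = A - A.mean(axis=0, keepdims=True)
    B = B - B.mean(axis=0, keepdims=True)
    n = A.shape[0]
    Saa = A.T @ A / (n - 1) + reg * np.eye(A.shape[1])
    Sbb = B.T @ B / (n - 1) + reg * np.eye(B.shape[1])
    Sab = A.T @ B / (n - 1)

    def inv_sqrt(S: np.ndarray) -> np.ndarray:
        w, v = np.linalg.eigh(S)
        w = np.clip(w, reg, None)
        return v @ np.diag(1.0 / np.sqrt(w)) @ v.T

    Wa, Wb = inv_sqrt(Saa), inv_sqrt(Sbb)
    u, s, vt = np.linalg.svd(Wa @ Sab @ Wb)
    return np.clip(s, 0.0, 1.0), Wa @ u, Wb @ vt.T


def exploratory_trends(
    non_gm_timecourses: np.ndarray,
    n_trends: int = 4,
    reduction_fraction: float = 0.05,
) -> RegressorBlock:
    """Estimate data-driven slow-trend regressors from non-grey time courses.

    Procedure: (1) demean each voxel time course; (2) reduce to
    ``d = ceil(reduction_fraction * N)`` temporal principal components;
    (3) run a canonical correlation analysis between the reduced series at
    times 1..N-1 and its lag-one shifted version at times 2..N; (4) form
    each canonical variate over the full N time points by projecting the
    reduced data onto the first-set canonical weights; (5) rank variates
    by their empirical lag-one autocorrelation, descending (the canonical
    correlation order breaks ties), and return the top ``n_trends``.

    High-autocorrelation variates are smooth, slowly varying time courses
    that explain low-frequency drifts without imposing a fixed functional
    form.  The inputs must contain no grey-matter voxels, otherwise signal
    of interest would be regressed out.
    """
    tcs = np.asarray(non_gm_timecourses, dtype=float)
    if tcs.ndim != 2:
        raise ValueError("non_gm_timecourses must be an N x V matrix")
    n, v = tcs.shape
    d = int(np.ceil(reduction_fraction * n))
    if d < n_trends:
        raise ValueError(
            f"dimensionality d=ceil({reduction_fraction}*{n})={d} is below "
            f"n_trends={n_trends}; use a longer series or fewer trends"
        )
    if v <= d:
        raise ValueError(f"need more than d={d} voxels, got {v}")
    demeaned = tcs - tcs.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(demeaned, full_matrices=False)
    scores = u[:, :d] * s[:d]  # (N, d) reduced representation
    corrs, wa, _ = _classical_cca(scores[:-1], scores[1:])
    centred = scores - scores.mean(axis=0, keepdims=True)
    variates = centred @ wa  # (N, d), full-length reconstruction
    lag1 = np.array(
        [
            np.corrcoef(variates[:-1, j], variates[1:, j])[0, 1]
            for j in range(variates.shape[1])
        ]
    )
    # stable sort on -autocorrelation keeps canonical order among ties
    order = np.argsort(-lag1, kind="stable")
    top = variates[:, order[:n_trends]]
    return RegressorBlock("expl", top)
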