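"""Gaussian-kernel linear discriminant analysis (GK-LDA).

Fisher's discriminant seeks directions R maximizing the ratio of
between-class to within-class scatter,

    V(R) = tr(R' B R) / tr(R' W R),

with B = sum_m s_m (mu_m - mu)(mu_m - mu)'  and
W = sum_m sum_{n in class m} (x_n - mu_m)(x_n - mu_m)'.

The directions solve the generalized eigenproblem B r = lambda (W + eps I) r;
the top c-1 eigenvectors (c = number of classes) span the discriminant
subspace.  The ridge eps guards against the small-sample-size singularity of
W when samples are few relative to dimensionality.

Two modes:

* **linear** — scatter matrices on the raw features (classical LDA); used
  both directly and as the oracle-comparable baseline.
* **kernel** — the kernel Fisher discriminant: each sample is represented by
  its row of the *centred* Gaussian kernel matrix
  K(i, j) = exp(-gamma ||x_i - x_j||^2) (centring takes the feature-space
  scatter about the feature-space mean) and the same scatter machinery runs
  in that L-dimensional space.  Projection of new data evaluates the kernel
  against the training rows, applies the stored centring, then the dual
  coefficients.  ``gamma="median-heuristic"`` sets
  gamma = 1 / (2 median^2) of the pairwise training distances.

A single kernel width is used for all pairs; eigenvector signs are fixed by
making each vector's largest-magnitude component positive so repeated fits
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.linalg

from .errors import NumericalError, ValidationError
from .preprocess import FeatureMatrix

__all__ = [
    "ScatterPair",
    "KernelMatrix",
    "ProjectionBasis",
    "class_statistics",
    "scatter_matrices",
    "gaussian_kernel_matrix",
    "solve_discriminant",
    "project",
    "fisher_criterion",
    "GaussianKernelLDA",
    "DiscriminantResults",
]


@dataclass(frozen=True)
class ScatterPair:
    """Between- and within-class scatter with the statistics behind them."""

    between: np.ndarray
    within: np.ndarray
    class_means: dict[int, np.ndarray]
    grand_mean: np.ndarray
    class_sizes: dict[int, int]

    @property
    def class_count(self) -> int:
        return len(self.class_sizes)

    @property
    def total_count(self) -> int:
        return sum(self.class_sizes.values())


@dataclass(frozen=True)
class KernelMatrix:
    """Gaussian kernel Gram matrix with the width used to build it."""

    values: np.ndarray
    gamma: float


@dataclass(frozen=True)
class ProjectionBasis:
    """Solved discriminant directions (or dual coefficients in kernel mode)."""

    vectors: np.ndarray  # (P, k) columns R_m — or (L, k) dual coefs
    eigenvalues: np.ndarray  # (k,) nonincreasing
    n_components: int
    regularization: float
    mode: Literal["linear", "kernel"]
    gamma: float | None = None  # kernel width (kernel mode)
    training_data: np.ndarray | None = None  # kernel mode: rows to kernel against
    # kernel-centering statistics of the training Gram matrix
    k_fit_rows: np.ndarray | None = None
    k_fit_all: float | None = None


def _split_classes(X: np.ndarray, y: np.ndarray) -> dict[int, np.ndarray]:
    classes = np.unique(y)
    groups = {int(c): X[y == c] for c in classes}
    for c, g in groups.items():
        if len(g) == 0:  # pragma: no cover - unique() precludes this
            raise ValidationError(f"class {c} has no rows")
    return groups


def class_statistics(
    X: np.ndarray, y: np.ndarray
) -> tuple[dict[int, np.ndarray], np.ndarray, dict[int, int]]:
    """Per-class means, grand mean, and class sizes."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ValidationError("label vector length != row count")
    groups = _split_classes(X, np.asarray(y))
    class_means = {c: g.mean(axis=0) for c, g in groups.items()}
    class_sizes = {c: len(g) for c, g in groups.items()}
    grand_mean = X.mean(axis=0)
    return class_means, grand_mean, class_sizes


def scatter_matrices(X: np.ndarray, y: np.ndarray) -> ScatterPair:
    """Size-weighted between-class and pooled within-class scatter."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    class_means, grand_mean, class_sizes = class_statistics(X, y)
    if len(class_sizes) < 2:
        raise ValidationError("scatter matrices need at least 2 classes")
    P = X.shape[1]
    between = np.zeros((P, P))
    within = np.zeros((P, P))
    y = np.asarray(y)
    for c, mu in class_means.items():
        d = (mu - grand_mean)[:, None]
        between += class_sizes[c] * (d @ d.T)
        centered = X[y == c] - mu
        within += centered.T @ centered
    return ScatterPair(between, within, class_means, grand_mean, class_sizes)


def gaussian_kernel_matrix(
    X: np.ndarray, gamma: float | str = "median-heuristic"
) -> KernelMatrix:
    """Gram matrix K_ij = exp(-gamma ||x_i - x_j||^2).

    The median heuristic chooses gamma = 1 / (2 m^2) with m the median
    pairwise Euclidean distance (over distinct pairs).
    """
    X = np.asarray(X, dtype=float)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    if gamma == "median-heuristic":
        iu = np.triu_indices(len(X), k=1)
        med = float(np.median(np.sqrt(sq[iu]))) if len(iu[0]) else 1.0
        gamma = 1.0 / (2.0 * med * med) if med > 0 else 1.0
    gamma = float(gamma)
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    return KernelMatrix(np.exp(-gamma * sq), gamma)


def _kernel_cross(
    X_new: np.ndarray, X_train: np.ndarray, gamma: float
) -> np.ndarray:
    sq = ((X_new[:, None, :] - X_train[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-gamma * sq)


def default_regularization(within: np.ndarray) -> float:
    """Ridge scale eps = 1e-6 * tr(W) / P (0 if W is exactly zero)."""
    P = within.shape[0]
    return 1e-6 * float(np.trace(within)) / P


def solve_discriminant(
    X: np.ndarray,
    y: np.ndarray,
    *,
    mode: Literal["linear", "kernel"] = "linear",
    gamma: float | str = "median-heuristic",
    regularization: float | None = None,
    n_components: int | None = None,
) -> ProjectionBasis:
    """Solve B r = lambda (W + eps I) r and keep the top c-1 eigenpairs."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    k_fit_rows: np.ndarray | None = None
    k_fit_all: float | None = None
    if mode == "kernel":
        km = gaussian_kernel_matrix(X, gamma)
        # centre the Gram matrix so feature-space scatter is taken about the
        # feature-space mean (canonical kernel Fisher discriminant)
        k_fit_rows = km.values.mean(axis=0)
        k_fit_all = float(km.values.mean())
        data = (
            km.values
            - k_fit_rows[None, :]
            - km.values.mean(axis=1)[:, None]
            + k_fit_all
        )
        used_gamma: float | None = km.gamma
        training = X
    else:
        data = X
        used_gamma = None
        training = None

    pair = scatter_matrices(data, y)
    if regularization is None:
        regularization = default_regularization(pair.within)
    if regularization < 0:
        raise ValidationError("regularization must be >= 0")
    W_reg = pair.within + regularization * np.eye(pair.within.shape[0])

    try:
        eigvals, eigvecs = scipy.linalg.eigh(pair.between, W_reg)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"generalized eigensolver failed: {exc}") from exc
    if not np.all(np.isfinite(eigvals)):
        raise NumericalError("non-finite generalized eigenvalues")

    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    c = pair.class_count
    k = c - 1 if n_components is None else n_components
    k = min(k, eigvecs.shape[1])
    vectors = eigvecs[:, :k].copy()
    # deterministic sign: largest-magnitude component positive
    for j in range(k):
        i = int(np.argmax(np.abs(vectors[:, j])))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]

    return ProjectionBasis(
        vectors=vectors,
        eigenvalues=eigvals[:k].copy(),
        n_components=k,
        regularization=float(regularization),
        mode=mode,
        gamma=used_gamma,
        training_data=training,
        k_fit_rows=k_fit_rows,
        k_fit_all=k_fit_all,
    )


def project(X: np.ndarray, basis: ProjectionBasis) -> np.ndarray:
    """Project rows onto the discriminant subspace (L x (c-1) scores)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if basis.mode == "kernel":
        assert basis.training_data is not None and basis.gamma is not None
        if X.shape[1] != basis.training_data.shape[1]:
            raise ValidationError("feature dimension mismatch with basis")
        K = _kernel_cross(X, basis.training_data, basis.gamma)
        if basis.k_fit_rows is not None:
            assert basis.k_fit_all is not None
            K = (
                K
                - basis.k_fit_rows[None, :]
                - K.mean(axis=1)[:, None]
                + basis.k_fit_all
            )
        return K @ basis.vectors
    if X.shape[1] != basis.vectors.shape[0]:
        raise ValidationError("feature dimension mismatch with basis")
    return X @ basis.vectors


def fisher_criterion(
    X: np.ndarray, y: np.ndarray, vectors: np.ndarray
) -> float:
    """tr(R' B R) / tr(R' W R) for a candidate basis R on raw features."""
    pair = scatter_matrices(X, y)
    num = float(np.trace(vectors.T @ pair.between @ vectors))
    den = float(np.trace(vectors.T @ pair.within @ vectors))
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return num / den


# -- model / results objects ------------------------------------------------


class GaussianKernelLDA:
    """Discriminant-reduction model over a labelled feature matrix.

    Parameters
    ----------
    mode : "linear" or "kernel"
    gamma : kernel width, or "median-heuristic" (kernel mode only)
    regularization : ridge added to the within-class scatter; default
        1e-6 tr(W)/P
    n_components : retained discriminant directions; default c - 1
    """

    def __init__(
        self,
        mode: Literal["linear", "kernel"] = "kernel",
        gamma: float | str = "median-heuristic",
        regularization: float | None = None,
        n_components: int | None = None,
    ) -> None:
        self.mode = mode
        self.gamma = gamma
        self.regularization = regularization
        self.n_components = n_components

    @classmethod
    def from_feature_matrix(cls, matrix: FeatureMatrix, **kwargs):
        model = cls(**kwargs)
        return model.fit(matrix.values, matrix.labels)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DiscriminantResults":
        basis = solve_discriminant(
            X,
            y,
            mode=self.mode,
            gamma=self.gamma,
            regularization=self.regularization,
            n_components=self.n_components,
        )
        scores = project(np.asarray(X, dtype=float), basis)
        return DiscriminantResults(self, basis, np.asarray(y), scores)


@dataclass
class DiscriminantResults:
    """Fitted discriminant basis plus training scores and diagnostics."""

    model: GaussianKernelLDA
    basis: ProjectionBasis
    labels: np.ndarray
    training_scores: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return project(X, self.basis)

    def summary(self) -> str:
        b = self.basis
        lines = [
            "Gaussian-Kernel LDA results",
            "===========================",
            f"mode:            {b.mode}",
            f"components:      {b.n_components}",
            f"regularization:  {b.regularization:.3e}",
        ]
        if b.gamma is not None:
            lines.append(f"kernel gamma:    {b.gamma:.6g}")
        lines.append(
            "eigenvalues:     "
            + ", ".join(f"{v:.6g}" for v in b.eigenvalues)
        )
        return "\n".join(lines)

    # -- persistence (text) -------------------------------------------------

    def save_basis(self, path: str | Path) -> None:
        save_basis(self.basis, path)


def save_basis(basis: ProjectionBasis, path: str | Path) -> None:
    """Persist a basis as a text file with a metadata header."""
    lines = [
        f"mode\t{basis.mode}",
        f"n_components\t{basis.n_components}",
        f"regularization\t{basis.regularization!r}",
        f"gamma\t{'' if basis.gamma is None else repr(basis.gamma)}",
        "eigenvalues\t" + " ".join(repr(float(v)) for v in basis.eigenvalues),
        f"vectors\t{basis.vectors.shape[0]}\t{basis.vectors.shape[1]}",
    ]
    for row in basis.vectors:
        lines.append(" ".join(repr(float(v)) for v in row))
    if basis.training_data is not None:
        lines.append(
            f"training\t{basis.training_data.shape[0]}\t"
            f"{basis.training_data.shape[1]}"
        )
        for row in basis.training_data:
            lines.append(" ".join(repr(float(v)) for v in row))
    if basis.k_fit_rows is not None:
        lines.append(f"centering\t{basis.k_fit_all!r}")
        lines.append(" ".join(repr(float(v)) for v in basis.k_fit_rows))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_basis(path: str | Path) -> ProjectionBasis:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    it = iter(lines)
    meta: dict[str, str] = {}
    for _ in range(5):
        key, _, value = next(it).partition("\t")
        meta[key] = value
    tag, rows, cols = next(it).split("\t")
    if tag != "vectors":
        raise ValidationError("malformed basis file")
    vectors = np.array(
        [[float(v) for v in next(it).split()] for _ in range(int(rows))]
    ).reshape(int(rows), int(cols))
    training = None
    k_fit_rows = None
    k_fit_all = None
    remaining = list(it)
    if remaining and remaining[0].startswith("training\t"):
        _, trows, tcols = remaining[0].split("\t")
        training = np.array(
            [[float(v) for v in ln.split()] for ln in remaining[1 : 1 + int(trows)]]
        ).reshape(int(trows), int(tcols))
        remaining = remaining[1 + int(trows) :]
    if remaining and remaining[0].startswith("centering\t"):
        k_fit_all = float(remaining[0].split("\t")[1])
        k_fit_rows = np.array([float(v) for v in remaining[1].split()])
    return ProjectionBasis(
        vectors=vectors,
        eigenvalues=np.array([float(v) for v in meta["eigenvalues"].split()]),
        n_components=int(meta["n_components"]),
        regularization=float(meta["regularization"]),
        mode=meta["mode"],  # type: ignore[arg-type]
        gamma=float(meta["gamma"]) if meta["gamma"] else None,
        training_data=training,
        k_fit_rows=k_fit_rows,
        k_fit_all=k_fit_all,
    )
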