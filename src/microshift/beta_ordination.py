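"""Bray–Curtis dissimilarity and classical PCoA, built from first principles.

PCoA (classical metric multidimensional scaling) double-centers the squared
dissimilarity matrix, B = −½ J D∘D J with J = I − 11ᵀ/n, and
eigendecomposes B. Axis k is the eigenvector scaled by √λ_k, so Euclidean
distances among coordinates reproduce a Euclidean-embeddable D exactly.

Bray–Curtis is a semimetric (non-Euclidean), so B generally has negative
eigenvalues. Default policy: retain positive axes only and record the
negative-eigenvalue mass fraction; Lingoes and Cailliez additive-constant
corrections are available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError, ValidationError
from .diversity import RelativeAbundanceTable, to_relative
from .tables_io import GenusCountTable

EIG_TOL = 1e-10


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("dissimilarity matrix must be square over sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValidationError("dissimilarity matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValidationError("dissimilarities must be non-negative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA/PCA embedding. ``coordinates[:, k]`` is axis k+1, scaled by
    √eigenvalue (PCoA) or the singular value (PCA); columns are centered."""

    sample_ids: list[str]
    coordinates: np.ndarray          # samples × retained axes
    eigenvalues: np.ndarray          # retained, descending, non-negative
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int = 0
    negative_eigenvalue_mass: float = 0.0
    correction_applied: str = "none"
    method: str = "pcoa"

    def axis(self, k: int) -> np.ndarray:
        return self.coordinates[:, k]


def bray_curtis(data: RelativeAbundanceTable | GenusCountTable) -> DissimilarityMatrix:
    """Pairwise Bray–Curtis: BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ).

    Counts are converted to relative abundances first, so the statistic
    compares compositions, not library sizes.
    """
    if isinstance(data, GenusCountTable):
        data = to_relative(data)
    X = data.fractions
    if X.shape[0] < 2:
        raise ValidationError("Bray–Curtis needs at least 2 samples")
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    tot = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        D = np.where(tot > 0, diff / tot, 0.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry against float noise
    return DissimilarityMatrix(list(data.sample_ids), D)


def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    return (B + B.T) / 2.0


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| element positive."""
    V = V.copy()
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return V


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest c such that D + c (off-diagonal) is Euclidean-embeddable:
    largest real eigenvalue of the 2n × 2n Cailliez companion matrix."""
    n = D.shape[0]
    d1 = _gower_center(D ** 2)
    d2 = _gower_center(D)  # note: −½ J D J (not squared)
    top = np.hstack([np.zeros((n, n)), 2.0 * d1])
    bot = np.hstack([-np.eye(n), -4.0 * d2])
    ev = np.linalg.eigvals(np.vstack([top, bot]))
    real = ev.real[np.abs(ev.imag) < 1e-8]
    return float(max(real.max(), 0.0))


def pcoa(D: DissimilarityMatrix, n_axes: int | None = None,
         correction: str = "none") -> OrdinationResult:
    """Classical principal-coordinates analysis of a dissimilarity matrix.

    ``correction`` ∈ {"none", "lingoes", "cailliez"} handles negative
    eigenvalues; with "none" they are dropped (a warning reports their mass
    fraction). ``proportion_explained`` uses Σ|λ| as denominator so the
    retained proportions always sum to ≤ 1.
    """
    n = D.n
    if n < 2:
        raise ParameterError("PCoA needs at least 2 samples")
    if n_axes is not None and (n_axes < 1 or n_axes > n - 1):
        raise ParameterError(f"n_axes must be in [1, {n - 1}]")
    if correction not in ("none", "lingoes", "cailliez"):
        raise ParameterError(f"unknown correction {correction!r}")

    values = D.values
    B = _gower_center(values ** 2)
    lam, V = np.linalg.eigh(B)
    lam, V = lam[::-1], V[:, ::-1]

    applied = "none"
    if correction != "none" and lam.min() < -EIG_TOL:
        if correction == "lingoes":
            c = -lam.min()
            D2 = values ** 2 + 2.0 * c
            np.fill_diagonal(D2, 0.0)
        else:
            c = _cailliez_constant(values)
            Dc = values + c
            np.fill_diagonal(Dc, 0.0)
            D2 = Dc ** 2
        B = _gower_center(D2)
        lam, V = np.linalg.eigh(B)
        lam, V = lam[::-1], V[:, ::-1]
        applied = correction

    scale = max(np.abs(lam).max(), 1.0)
    pos = lam > EIG_TOL * scale
    neg = lam < -EIG_TOL * scale
    n_neg = int(neg.sum())
    neg_mass = float(np.abs(lam[neg]).sum() / np.abs(lam).sum()) if n_neg else 0.0
    if not pos.any():
        raise DegenerateInputError("all PCoA eigenvalues are non-positive")
    if n_neg and applied == "none":
        warnings.warn(
            f"PCoA dropped {n_neg} negative eigenvalues "
            f"({neg_mass:.1%} of eigenvalue mass); Bray–Curtis is non-Euclidean",
            stacklevel=2)

    lam_pos, V_pos = lam[pos], V[:, pos]
    denom = np.abs(lam).sum()
    prop = lam_pos / denom
    coords = _fix_signs(V_pos) * np.sqrt(lam_pos)
    coords = coords - coords.mean(axis=0)  # exact centering against float drift
    if n_axes is not None:
        k = min(n_axes, coords.shape[1])
        coords, lam_pos, prop = coords[:, :k], lam_pos[:k], prop[:k]
    return OrdinationResult(
        sample_ids=list(D.sample_ids), coordinates=coords,
        eigenvalues=lam_pos, proportion_explained=prop,
        n_negative_eigenvalues=n_neg, negative_eigenvalue_mass=neg_mass,
        correction_applied=applied, method="pcoa")


def pca_relabund(rel: RelativeAbundanceTable, n_axes: int | None = None
                 ) -> OrdinationResult:
    """PCA of column-centered relative abundances (scores = U·S).

    Fidelity mode for toolchains that run a principal-component routine on
    the abundance table instead of a true distance-based PCoA.
    """
    X = rel.fractions
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scale = max(s.max(), 1.0)
    keep = s > 1e-12 * scale
    U, s = U[:, keep], s[keep]
    # sign convention applied to the score columns
    scores = _fix_signs(U) * s
    ssq = s ** 2
    prop = ssq / ssq.sum()
    if n_axes is not None:
        if n_axes < 1:
            raise ParameterError("n_axes must be ≥ 1")
        k = min(n_axes, scores.shape[1])
        scores, ssq, prop = scores[:, :k], ssq[:k], prop[:k]
    scores = scores - scores.mean(axis=0)
    return OrdinationResult(
        sample_ids=list(rel.sample_ids), coordinates=scores,
        eigenvalues=ssq, proportion_explained=prop, method="pca")
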