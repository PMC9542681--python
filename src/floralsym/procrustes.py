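"""Procrustes superimposition and bilateral object-symmetry decomposition.

Shapes are superimposed by partial generalized Procrustes analysis
(translation to zero centroid, scaling to unit centroid size, least-squares
rotation to an iteratively re-estimated consensus) and projected
orthogonally onto the tangent space at the consensus, where all downstream
linear statistics operate.

For organs with internal bilateral symmetry, variation is split into a
symmetric and an asymmetric component by jointly superimposing each
configuration with a reflected-and-relabeled copy of itself: the symmetric
component is the average of the aligned original and its aligned mirror
image, the asymmetric component is the remainder. By construction the two
components add back to the aligned original exactly, and the asymmetric
component changes sign under reflection-and-relabeling while the symmetric
component is invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration, PairingScheme

__all__ = [
    "centroid_size",
    "gpa",
    "GPAResult",
    "AlignedShape",
    "reflect_relabel",
    "object_symmetry_decompose",
    "SymmetryDecomposition",
    "ObjectSymmetryResult",
    "procrustes_distance",
]


def _coords(shape) -> np.ndarray:
    if isinstance(shape, LandmarkConfiguration):
        return np.asarray(shape.coords, dtype=float)
    return np.asarray(shape, dtype=float)


def centroid_size(shape) -> float:
    """Centroid size: root summed squared landmark-to-centroid distances.

    Accepts a :class:`LandmarkConfiguration` or a (k, 2) array; returns the
    size in the units of the coordinates (millimeters for real data).
    """
    X = _coords(shape)
    if len(X) < 2:
        raise ValueError("centroid size requires at least 2 landmarks")
    return float(np.sqrt(((X - X.mean(axis=0)) ** 2).sum()))


def _preshape(X: np.ndarray, label: str = "configuration") -> np.ndarray:
    """Center a configuration and scale it to unit centroid size."""
    Xc = X - X.mean(axis=0)
    size = np.sqrt((Xc**2).sum())
    if size == 0.0:
        raise ValueError(f"degenerate {label}: all landmarks coincide")
    return Xc / size


def _rotate_to(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Optimally rotate centered configurations onto a target.

    ``X`` may be (k, 2) or a stack (n, k, 2); the least-squares rotation is
    computed per configuration (2D closed form via atan2).
    """
    single = X.ndim == 2
    Xs = X[None] if single else X
    dot = np.einsum("nki,ki->n", Xs, C)
    cross = np.einsum("nk,k->n", Xs[..., 0], C[:, 1]) - np.einsum(
        "nk,k->n", Xs[..., 1], C[:, 0]
    )
    theta = np.arctan2(cross, dot)
    cos, sin = np.cos(theta), np.sin(theta)
    # rotation matrix [[cos, -sin], [sin, cos]] applied to row vectors (x, y)
    out = np.empty_like(Xs)
    out[..., 0] = cos[:, None] * Xs[..., 0] - sin[:, None] * Xs[..., 1]
    out[..., 1] = sin[:, None] * Xs[..., 0] + cos[:, None] * Xs[..., 1]
    return out[0] if single else out


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations.

    Both are reduced to preshapes (centered, unit size) and optimally
    rotated; the distance is the Euclidean norm of the residual.
    """
    A = _preshape(_coords(a))
    B = _preshape(_coords(b))
    return float(np.linalg.norm(_rotate_to(A, B) - B))


@dataclass
class AlignedShape:
    """One superimposed organ: tangent-space coordinates and size."""

    organ_id: str | None
    tangent_vector: np.ndarray  # (2k,)
    centroid_size: float


@dataclass
class GPAResult:
    """Output of generalized Procrustes analysis."""

    aligned: np.ndarray  # (n, k, 2) superimposed preshapes
    consensus: np.ndarray  # (k, 2), centered, unit centroid size
    tangent: np.ndarray  # (n, 2k) tangent-space coordinates
    centroid_sizes: np.ndarray  # (n,) sizes of the input configurations (mm)
    n_iterations: int

    @property
    def shapes(self) -> list[AlignedShape]:
        return [
            AlignedShape(None, t, s)
            for t, s in zip(self.tangent, self.centroid_sizes)
        ]


def _tangent_project(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent space at the consensus."""
    c = consensus.ravel()
    c = c / np.linalg.norm(c)
    V = aligned.reshape(len(aligned), -1)
    return V - np.outer(V @ c, c)


def gpa(shapes, tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Partial generalized Procrustes superimposition.

    Parameters
    ----------
    shapes : sequence of LandmarkConfiguration or (n, k, 2) array
        At least two configurations with equal landmark counts.
    tol : float
        Convergence threshold on the change of the consensus between
        iterations.
    max_iter : int
        Iteration cap; exceeding it raises with diagnostics.
    """
    X = np.stack([_coords(s) for s in shapes]).astype(float)
    if len(X) < 2:
        raise ValueError("GPA requires at least 2 configurations")
    sizes = np.array([centroid_size(x) for x in X])
    P = np.stack([_preshape(x, f"configuration {i}") for i, x in enumerate(X)])

    consensus = P[0]
    aligned = P
    change = np.inf
    for iteration in range(1, max_iter + 1):
        aligned = _rotate_to(P, consensus)
        mean = aligned.mean(axis=0)
        new = _preshape(mean, "consensus")
        change = np.linalg.norm(new - consensus)
        consensus = new
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus change {change:.3e})"
        )
    aligned = _rotate_to(P, consensus)
    tangent = _tangent_project(aligned, consensus)
    return GPAResult(aligned, consensus, tangent, sizes, iteration)


def reflect_relabel(shape, pairing: PairingScheme):
    """Reflect a configuration about the y-axis and swap paired labels.

    The reflection axis is the coordinate y-axis before relabeling; after
    Procrustes superimposition the choice of axis is immaterial. Applying
    the operation twice returns the original configuration. Returns the
    same type as the input (array or :class:`LandmarkConfiguration`).
    """
    X = _coords(shape)
    if len(X) != pairing.k:
        raise ValueError(
            f"pairing scheme for k={pairing.k} does not match configuration "
            f"with k={len(X)}"
        )
    out = X.copy()
    out[:, 0] = -out[:, 0]
    out = out[pairing.permutation()]
    if isinstance(shape, LandmarkConfiguration):
        return LandmarkConfiguration(
            organ_id=shape.organ_id,
            flower_id=shape.flower_id,
            organ_type=shape.organ_type,
            coords=out,
            compass_orientation=shape.compass_orientation,
        )
    return out


@dataclass
class SymmetryDecomposition:
    """Symmetric/asymmetric split of one organ's tangent-space shape."""

    organ_id: str | None
    symmetric: np.ndarray  # (2k,)
    asymmetric: np.ndarray  # (2k,)

    @property
    def total(self) -> np.ndarray:
        return self.symmetric + self.asymmetric


@dataclass
class ObjectSymmetryResult:
    """Joint-superimposition decomposition of a sample of organs."""

    decompositions: list[SymmetryDecomposition]
    consensus: np.ndarray  # (k, 2), symmetric under reflect-and-relabel
    centroid_sizes: np.ndarray
    n_iterations: int

    @property
    def symmetric(self) -> np.ndarray:
        """(n, 2k) matrix of symmetric components."""
        return np.stack([d.symmetric for d in self.decompositions])

    @property
    def asymmetric(self) -> np.ndarray:
        """(n, 2k) matrix of asymmetric components."""
        return np.stack([d.asymmetric for d in self.decompositions])

    @property
    def tangent(self) -> np.ndarray:
        """(n, 2k) aligned original tangent vectors (symmetric + asymmetric)."""
        return self.symmetric + self.asymmetric


def _rot(X: np.ndarray, theta: float) -> np.ndarray:
    cos, sin = np.cos(theta), np.sin(theta)
    return np.stack(
        [cos * X[:, 0] - sin * X[:, 1], sin * X[:, 0] + cos * X[:, 1]], axis=1
    )


def _symmetrize(C: np.ndarray, pairing: PairingScheme) -> np.ndarray:
    """Average a consensus with its aligned mirror copy, in mirror pose.

    The result is exactly invariant under reflect-and-relabel: after
    averaging, the consensus is rotated so that its symmetry axis
    coincides with the coordinate y-axis.
    """
    M = _preshape(reflect_relabel(C, pairing))
    S = _preshape((C + _rotate_to(M, C)) / 2.0, "consensus")
    # rotate by -phi/2, where phi optimally aligns the mirror copy onto S
    M = reflect_relabel(S, pairing)
    phi = np.arctan2(
        float(M[:, 0] @ S[:, 1] - M[:, 1] @ S[:, 0]), float((M * S).sum())
    )
    return _rot(S, -phi / 2.0)


def object_symmetry_decompose(
    shapes,
    pairing: PairingScheme,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ObjectSymmetryResult:
    """Decompose shape variation under bilateral object symmetry.

    Runs a joint partial GPA over the original configurations and their
    reflected-and-relabeled copies, with the consensus symmetrized at every
    iteration so that it is exactly invariant under reflection-and-
    relabeling. In tangent space at that consensus, each organ's symmetric
    component is the mean of its aligned original and aligned mirror copy,
    and the asymmetric component is the aligned original minus the
    symmetric component (half the original-vs-mirror difference).
    """
    configs = list(shapes)
    if len(configs) < 2:
        raise ValueError("object-symmetry decomposition requires >= 2 configurations")
    organ_ids = [
        s.organ_id if isinstance(s, LandmarkConfiguration) else None for s in configs
    ]
    X = np.stack([_coords(s) for s in configs]).astype(float)
    sizes = np.array([centroid_size(x) for x in X])
    P = np.stack([_preshape(x, f"configuration {i}") for i, x in enumerate(X)])
    Q = np.stack([_preshape(reflect_relabel(p, pairing)) for p in P])
    both = np.concatenate([P, Q])

    consensus = _symmetrize(P[0], pairing)
    change = np.inf
    for iteration in range(1, max_iter + 1):
        aligned = _rotate_to(both, consensus)
        new = _symmetrize(_preshape(aligned.mean(axis=0), "consensus"), pairing)
        change = np.linalg.norm(new - consensus)
        consensus = new
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"joint GPA did not converge in {max_iter} iterations "
            f"(last consensus change {change:.3e})"
        )
    aligned = _rotate_to(both, consensus)
    tangent = _tangent_project(aligned, consensus)
    n = len(P)
    t_orig, t_refl = tangent[:n], tangent[n:]
    symmetric = (t_orig + t_refl) / 2.0
    asymmetric = t_orig - symmetric
    decomps = [
        SymmetryDecomposition(organ_ids[i], symmetric[i], asymmetric[i])
        for i in range(n)
    ]
    return ObjectSymmetryResult(decomps, consensus, sizes, iteration)


def reflect_relabel_tangent(
    vectors: np.ndarray, pairing: PairingScheme
) -> np.ndarray:
    """Apply reflection-and-relabeling to tangent vectors.

    Valid at a consensus that is itself symmetric (the joint-GPA
    consensus): negates x-components and permutes paired landmarks.
    ``vectors`` is (..., 2k) in landmark-major x,y order.
    """
    V = np.asarray(vectors, dtype=float)
    shape = V.shape
    V = V.reshape(-1, pairing.k, 2).copy()
    V[..., 0] = -V[..., 0]
    V = V[:, pairing.permutation()]
    return V.reshape(shape)
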