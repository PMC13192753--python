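"""Global concordance between ordinations: PCoA plus a Procrustes
permutation test.

Both configurations are centered and scaled to unit total sum of squares
before the rotation is fitted (symmetric Procrustes), so the concordance
statistic rho = sum of singular values of the cross-product is independent
of argument order and lies in [0, 1]; the residual m12^2 = 1 - rho^2.
Significance comes from permuting whole rows (sample relabeling) of the
second configuration and refitting, with the add-one permutation p-value
p = (#{permuted rho >= observed} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

from .containers import Ordination

__all__ = ["ProcrustesResult", "pcoa", "procrustes_fit", "procrustes_permutation_test"]

logger = logging.getLogger(__name__)


@dataclass
class ProcrustesResult:
    rho: float
    m12_squared: float
    rotation: np.ndarray
    p_value: float | None = None
    n_permutations: int | None = None

    def __post_init__(self):
        if not np.isclose(self.rho, np.sqrt(max(1.0 - self.m12_squared, 0.0)),
                          atol=1e-9):
            raise ValueError("rho and m12_squared are inconsistent")


def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis by double centering and
    eigendecomposition; only positive-eigenvalue axes are retained."""
    if not isinstance(d, DistanceMatrix):
        d = DistanceMatrix(np.asarray(d))  # validates symmetry / zero diagonal
    D2 = d.data ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = np.abs(eigvals).max() if n else 0.0
    tol = scale * n * np.finfo(float).eps * 1e2
    neg = eigvals[eigvals < -tol]
    if neg.size:
        share = -neg.sum() / np.abs(eigvals).sum()
        logger.warning("dropping %d negative eigenvalues (%.2g of total magnitude)",
                       neg.size, share)
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])[None, :]
    pos_sum = eigvals[keep].sum()
    prop = eigvals[keep] / pos_sum if pos_sum > 0 else eigvals[keep]
    return Ordination(sample_ids=list(d.ids), coordinates=coords,
                      eigenvalues=eigvals[keep], proportion_explained=prop)


def _normalized_coords(a: Ordination, b: Ordination) -> tuple[np.ndarray, np.ndarray]:
    if a.sample_ids != b.sample_ids:
        if set(a.sample_ids) != set(b.sample_ids):
            raise ValueError("ordinations must cover the same samples")
        order = [b.sample_ids.index(s) for s in a.sample_ids]
        b = Ordination(sample_ids=a.sample_ids, coordinates=b.coordinates[order])
    n = len(a.sample_ids)
    if n < 3:
        raise ValueError("Procrustes needs at least 3 shared samples")
    width = max(a.n_axes, b.n_axes)

    def prep(coords):
        X = np.zeros((n, width))
        X[:, :coords.shape[1]] = coords
        X = X - X.mean(axis=0, keepdims=True)
        ss = np.sqrt((X ** 2).sum())
        if ss == 0:
            raise ValueError("degenerate ordination: all points coincide")
        return X / ss

    return prep(a.coordinates), prep(b.coordinates)


def procrustes_fit(a: Ordination, b: Ordination) -> ProcrustesResult:
    """Symmetric Procrustes superimposition of two ordinations."""
    A, B = _normalized_coords(a, b)
    U, s, Vt = np.linalg.svd(A.T @ B)
    rho = float(min(s.sum(), 1.0))
    return ProcrustesResult(rho=rho, m12_squared=1.0 - rho ** 2,
                            rotation=(U @ Vt).T)


def procrustes_permutation_test(
    a: Ordination,
    b: Ordination,
    n_perm: int = 99_999,
    seed=None,
    batch: int = 2000,
) -> ProcrustesResult:
    """Procrustes concordance with a row-permutation null.

    Rows of ``b`` are relabeled ``n_perm`` times; each permutation refits the
    superimposition and the p-value is (#{perm rho >= observed} + 1) /
    (n_perm + 1), so the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    A, B = _normalized_coords(a, b)
    obs = procrustes_fit(a, b)
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    n_ge = 0
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(m)])
        Bp = B[perms]  # (m, n, k)
        M = np.einsum("ni,mnj->mij", A, Bp)
        s = np.linalg.svd(M, compute_uv=False)
        n_ge += int((s.sum(axis=1) >= obs.rho - 1e-12).sum())
        done += m
    p = (n_ge + 1) / (n_perm + 1)
    return ProcrustesResult(rho=obs.rho, m12_squared=obs.m12_squared,
                            rotation=obs.rotation, p_value=p,
                            n_permutations=n_perm)
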