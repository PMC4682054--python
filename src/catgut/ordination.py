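"""Jensen–Shannon divergence distances and classical-scaling PCoA.

Between-sample distances are the raw Jensen–Shannon divergence (natural
log, range [0, ln 2]) of relative-abundance vectors; ordination is
classical scaling (principal coordinates analysis): eigendecomposition
of the double-centred matrix -D²/2.  Raw JSD is not guaranteed metric,
so negative eigenvalues can occur; they are reported, never hidden or
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "jsd",
    "jsd_matrix",
    "pcoa",
    "pathway_weighted_ordination",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample-by-sample distances with zero diagonal."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("negative distances")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class Ordination:
    """PCoA coordinates with eigenvalues and per-axis variance shares."""

    coordinates: pd.DataFrame          # samples x axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # over positive eigenvalues only


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    nz = p > 0
    # q >= p/2 wherever p > 0 by construction of the mixture, so a zero
    # q can only arise from denormal underflow; clamp before dividing
    q_safe = np.maximum(q[nz], np.finfo(float).tiny)
    return float((p[nz] * np.log(p[nz] / q_safe)).sum())


def jsd(p, q) -> float:
    """Jensen–Shannon divergence (nats) between two composition vectors.

    JSD = KL(p||m)/2 + KL(q||m)/2 with m = (p+q)/2, natural log and the
    convention 0 ln 0 = 0 (no pseudocounts).  Inputs are renormalised to
    sum 1.  Bounded by ln 2.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must share one feature space")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative proportions")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("all-zero composition")
    p = p / p.sum()
    q = q / q.sum()
    m = (p + q) / 2.0
    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def jsd_matrix(t: FeatureTable) -> DistanceMatrix:
    """Pairwise raw JSD between sample columns of a proportions table."""
    if t.n_samples < 2:
        raise ValueError("need >= 2 samples")
    X = t.data.to_numpy(dtype=float)
    X = X / X.sum(axis=0, keepdims=True)
    n = X.shape[1]
    D = np.zeros((n, n))
    # entropy identity: JSD(p,q) = H(m) - (H(p)+H(q))/2, vectorised
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(X > 0, X * np.log(X), 0.0)
    H = -plogp.sum(axis=0)
    for i in range(n):
        M = (X[:, i][:, None] + X[:, i + 1:]) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            mlogm = np.where(M > 0, M * np.log(M), 0.0)
        Hm = -mlogm.sum(axis=0)
        d = Hm - (H[i] + H[i + 1:]) / 2.0
        D[i, i + 1:] = np.clip(d, 0.0, np.log(2.0))
    D = D + D.T
    return DistanceMatrix(t.sample_ids, D)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical scaling of a distance matrix.

    Eigendecomposition of B = -J D² J / 2 (J the centring matrix).
    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; axes with non-positive eigenvalues get zero coordinates.
    Variance shares are computed over positive eigenvalues only, and
    negative eigenvalues (possible: raw JSD need not be Euclidean) are
    kept in ``eigenvalues``.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_axes = min(n_axes, n)
    coords = np.zeros((n, n_axes))
    for k in range(n_axes):
        if evals[k] > 0:
            coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
    pos = evals[evals > 0]
    prop = pos / pos.sum() if pos.size else np.array([])
    cframe = pd.DataFrame(coords, index=d.sample_ids,
                          columns=[f"PCo{k + 1}" for k in range(n_axes)])
    return Ordination(cframe, evals, prop)


def pathway_weighted_ordination(
    ordn: Ordination,
    pathway_abundance: pd.Series,
    size_range: tuple[float, float] = (10.0, 200.0),
) -> pd.DataFrame:
    """Scatter specification with point sizes scaled by pathway abundance.

    Coordinates are taken unchanged from ``ordn``; sizes are linearly
    rescaled into ``size_range``.  Constant abundance gives equal
    mid-range sizes; a zero abundance gets the minimum size rather than
    being dropped.
    """
    ab = pathway_abundance.reindex(ordn.coordinates.index)
    if ab.isna().any():
        missing = ab.index[ab.isna()][0]
        raise ValueError(f"no pathway abundance for sample {missing!r}")
    lo, hi = size_range
    span = ab.max() - ab.min()
    if span == 0:
        sizes = pd.Series((lo + hi) / 2.0, index=ab.index)
    else:
        sizes = lo + (ab - ab.min()) / span * (hi - lo)
    out = ordn.coordinates.iloc[:, :2].copy()
    out["size"] = sizes
    out["abundance"] = ab
    return out
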