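"""Multivariate source analysis for site-by-PEM concentration matrices.

Workflow mirrors standard geochemical source apportionment: z-score
standardisation, sampling-adequacy diagnostics (overall KMO from the
anti-image partial correlations, Bartlett's sphericity test), principal
component extraction from the correlation matrix with the eigenvalue-1
retention rule, varimax rotation with Kaiser normalisation, and
average-linkage (UPGMA, between-groups) hierarchical clustering of sites
or of variables with merge heights rescaled to (D_link / D_max) × 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sample standard deviation 1)."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to standardize")
    if matrix.isna().any().any():
        raise ValueError("matrix holds missing cells; resolve censoring first")
    sd = matrix.std(ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    return (matrix - matrix.mean()) / sd


def kmo_bartlett(matrix: pd.DataFrame) -> tuple[float, float, float]:
    """Overall KMO measure and Bartlett's sphericity test.

    KMO = Σr² / (Σr² + Σq²) over off-diagonal correlations r and
    anti-image partial correlations q; Bartlett's statistic is
    −(n−1−(2p+5)/6)·ln|R| on p(p−1)/2 degrees of freedom.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError(
            "singular correlation matrix; remove collinear variables"
        )
    try:
        R_inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular correlation matrix; remove collinear variables"
        ) from exc
    d = np.sqrt(np.outer(np.diag(R_inv), np.diag(R_inv)))
    partial = -R_inv / d
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    kmo = r2 / (r2 + q2) if r2 + q2 > 0 else float("nan")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    p_value = float(stats.chi2.sf(chi2, df))
    return float(kmo), float(chi2), p_value


@dataclass
class FactorModel:
    """Varimax-rotated principal-component solution."""

    variables: list[str]
    loadings: pd.DataFrame          # variables × retained factors
    eigenvalues: np.ndarray         # all p eigenvalues, descending
    variance_pct: list[float]       # per retained (rotated) factor
    cumulative_pct: list[float]
    kmo: float
    bartlett_stat: float
    bartlett_p: float
    strength_labels: dict[tuple[str, str], str]

    def display_loadings(self, blank_below: float = 0.3) -> pd.DataFrame:
        """Sparse loading table: magnitudes below the cutoff blanked."""
        shown = self.loadings.round(3).astype(object)
        shown[self.loadings.abs() < blank_below] = ""
        return shown


def _strength(loading: float) -> str:
    a = abs(loading)
    if a > 0.75:
        return "strong"
    if a >= 0.50:
        return "moderate"
    return "weak"


def _varimax(L: np.ndarray, tol: float = 1e-6, max_iter: int = 100,
             kaiser: bool = True) -> np.ndarray:
    """Varimax rotation (optionally Kaiser-normalised) of a loading matrix."""
    L = L.copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.ones(p)
    if kaiser:
        h = np.sqrt(np.sum(L ** 2, axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        B = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (B ** 3 - B @ np.diag(np.sum(B ** 2, axis=0)) / p)
        )
        R = u @ vt
        var_new = np.sum(s)
        if var_new - var_old < tol * var_new:
            break
        var_old = var_new
    out = (L @ R)
    if kaiser:
        out = out * h[:, None]
    return out


def pca_varimax(
    z: pd.DataFrame,
    eigenvalue_min: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> FactorModel:
    """PCA on the correlation matrix, eigenvalue-1 retention, varimax.

    Input should be a standardized site × variable matrix.  Loadings are
    eigenvectors scaled by √eigenvalue; rotation preserves per-variable
    communality.  Each retained factor is signed so that its
    largest-magnitude loading is positive, making tables deterministic.
    """
    X = np.asarray(z, dtype=float)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    k = int(np.sum(eigval > eigenvalue_min))
    if k == 0:
        raise ValueError(
            f"no eigenvalue exceeds {eigenvalue_min}; spectrum = "
            f"{np.round(eigval, 4).tolist()}"
        )
    raw = eigvec[:, :k] * np.sqrt(eigval[:k])
    rotated = _varimax(raw, tol=tol, max_iter=max_iter)
    # deterministic sign: largest |loading| per factor made positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(rotated[:, j])))
        if rotated[i_max, j] < 0:
            rotated[:, j] = -rotated[:, j]
    # order rotated factors by explained variance (sum of squared loadings)
    ssl = np.sum(rotated ** 2, axis=0)
    fac_order = np.argsort(ssl)[::-1]
    rotated = rotated[:, fac_order]
    ssl = ssl[fac_order]
    names = [f"Factor {j + 1}" for j in range(k)]
    loadings = pd.DataFrame(rotated, index=list(z.columns), columns=names)
    variance_pct = (100.0 * ssl / p).tolist()
    cumulative = np.cumsum(variance_pct).tolist()
    try:
        kmo, chi2, p_value = kmo_bartlett(z)
    except ValueError:
        # perfectly collinear inputs: the component solution is still
        # well defined, the adequacy diagnostics are not
        kmo = chi2 = p_value = float("nan")
    labels = {
        (var, fac): _strength(loadings.loc[var, fac])
        for var in loadings.index
        for fac in names
    }
    return FactorModel(
        variables=list(z.columns),
        loadings=loadings,
        eigenvalues=eigval,
        variance_pct=variance_pct,
        cumulative_pct=cumulative,
        kmo=kmo,
        bartlett_stat=chi2,
        bartlett_p=p_value,
        strength_labels=labels,
    )


@dataclass
class ClusterTree:
    """Average-linkage dendrogram with rescaled merge heights."""

    items: list[str]
    merges: list[tuple[int, int, float]]   # scipy-style child ids + raw height
    rescaled_heights: list[float]          # (D_link / D_max) × 100
    _linkage: np.ndarray

    def cut(self, rescaled_threshold: float) -> dict[str, int]:
        """Flat clusters from cutting at a rescaled-height threshold."""
        d_max = self._linkage[:, 2].max()
        raw = rescaled_threshold / 100.0 * d_max
        flat = fcluster(self._linkage, t=raw, criterion="distance")
        return dict(zip(self.items, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from raw merge heights."""
        n = len(self.items)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.items[i] for i in range(n)}
        for idx, (a, b, h) in enumerate(self.merges):
            node_id = n + idx
            la = h - heights[a]
            lb = h - heights[b]
            nodes[node_id] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
            heights[node_id] = h
        return nodes[n + len(self.merges) - 1] + ";"


def cluster(matrix: pd.DataFrame, orientation: str = "sites",
            metric: str = "sqeuclidean") -> ClusterTree:
    """UPGMA (between-groups average linkage) hierarchical clustering.

    ``orientation="sites"`` clusters rows; ``"variables"`` clusters
    columns.  Features should be standardized beforehand.  The default
    dissimilarity is squared Euclidean distance — the convention of the
    statistical packages this analysis is usually run in, under which the
    rescaled (D_link/D_max)×100 dendrogram heights match reported
    contaminated-site separations; pass ``metric="euclidean"`` for plain
    Euclidean distance.
    """
    if orientation == "variables":
        matrix = matrix.T
    elif orientation != "sites":
        raise ValueError("orientation must be 'sites' or 'variables'")
    if len(matrix) < 2:
        raise ValueError("need at least 2 items to cluster")
    items = [str(i) for i in matrix.index]
    Z = linkage(pdist(np.asarray(matrix, dtype=float), metric=metric),
                method="average")
    d_max = Z[:, 2].max()
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    if d_max == 0:  # all items coincide
        rescaled = [0.0 for _ in merges]
    else:
        rescaled = [100.0 * h / d_max for _, _, h in merges]
    return ClusterTree(items=items, merges=merges,
                       rescaled_heights=rescaled, _linkage=Z)
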