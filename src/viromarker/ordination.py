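"""Ordination and environmental association.

Square-root transformed abundances are compared between samples with
Bray--Curtis dissimilarity and embedded in two dimensions by non-metric MDS
(SMACOF majorization alternating with monotone regression on the
dissimilarity ranks, Kruskal stress-1, primary treatment of ties, multiple
seeded restarts).  Environmental covariates are screened with Pearson
correlations against both the ordination axes and the type-aggregated
abundance rows, ranked by the strongest absolute correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "OrdinationResult",
    "sqrt_transform",
    "bray_curtis",
    "nmds",
    "env_correlation",
]


def sqrt_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Element-wise square root; rejects negative values."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("abundance matrix contains negative values")
    return np.sqrt(matrix)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray--Curtis dissimilarity (samples are columns).

    BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i); a pair of all-zero samples is
    defined to have dissimilarity 0.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # all-zero pairs
    return pd.DataFrame(squareform(d), index=matrix.columns, columns=matrix.columns)


@dataclass
class OrdinationResult:
    coords: pd.DataFrame  # samples x axes
    stress: float  # Kruskal stress-1 of the best restart
    n_restarts: int
    seed: int
    stress_history: list[float] = field(default_factory=list)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _classical_init(D: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) scaling as a warm start."""
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)


def _nmds_single(
    delta: np.ndarray,
    X0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    n = X0.shape[0]
    order = np.lexsort((np.arange(len(delta)), delta))  # primary ties: stable
    iso = IsotonicRegression(increasing=True)
    xs = np.arange(len(delta), dtype=float)
    X = X0.copy()
    history: list[float] = []
    best_X, best_stress = X, np.inf
    for _ in range(max_iter):
        d = pdist(X)
        if np.all(d == 0):
            break
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(xs, d[order])
        # scale disparities to the configuration's length so stress is comparable
        ssum = float(np.sum(dhat**2))
        if ssum > 0:
            dhat = dhat * np.sqrt(np.sum(d**2) / ssum)
        stress = _stress1(d, dhat)
        if history and stress > history[-1]:
            break  # keep the best configuration seen; trace stays monotone
        history.append(stress)
        if stress < best_stress:
            best_stress, best_X = stress, X.copy()
        if len(history) >= 2 and history[-2] - history[-1] < tol:
            break
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
    return best_X, best_stress, history


def nmds(
    dissimilarity: pd.DataFrame,
    dims: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of several restarts.

    The first restart is warm-started from classical scaling; the rest are
    random configurations from the seeded generator.
    """
    D = dissimilarity.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    np.fill_diagonal(D, 0.0)
    delta = squareform(D, checks=False)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for r in range(max(1, restarts)):
        X0 = (
            _classical_init(D, dims)
            if r == 0
            else rng.standard_normal((D.shape[0], dims))
        )
        X, stress, history = _nmds_single(delta, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history)
    X, stress, history = best
    coords = pd.DataFrame(
        X,
        index=dissimilarity.index,
        columns=[f"axis{i + 1}" for i in range(dims)],
    )
    return OrdinationResult(
        coords=coords,
        stress=stress,
        n_restarts=max(1, restarts),
        seed=seed,
        stress_history=history,
    )


def env_correlation(
    env: pd.DataFrame,
    axes: pd.DataFrame | None = None,
    type_matrix: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson r of each environmental variable against ordination axes and
    type-aggregated abundance rows, ranked by max |r| per variable.

    Samples are matched on index; missing samples are dropped pairwise.
    Zero-variance variables are reported with r = NaN.
    """
    targets: list[tuple[str, pd.Series]] = []
    if axes is not None:
        for col in axes.columns:
            targets.append((f"ordination:{col}", axes[col]))
    if type_matrix is not None:
        for cat in type_matrix.index:
            targets.append((f"type:{cat}", type_matrix.loc[cat]))
    if not targets:
        raise ValueError("need ordination axes and/or a type matrix")
    rows = []
    for var in env.columns:
        for tname, tseries in targets:
            joined = pd.concat([env[var], tseries], axis=1, join="inner").dropna()
            if len(joined) < 3:
                raise ValueError(
                    f"fewer than 3 shared samples between env '{var}' and {tname}"
                )
            x, y = joined.iloc[:, 0], joined.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                r = np.nan
            else:
                r = pearsonr(x, y)[0]
            rows.append({"variable": var, "target": tname, "r": r, "n": len(joined)})
    table = pd.DataFrame(rows)
    strength = table.groupby("variable")["r"].apply(
        lambda s: np.nanmax(np.abs(s)) if s.notna().any() else np.nan
    )
    table["max_abs_r"] = table["variable"].map(strength)
    table = table.sort_values(
        ["max_abs_r", "variable"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    table["rank"] = table["max_abs_r"].rank(ascending=False, method="dense")
    return table
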