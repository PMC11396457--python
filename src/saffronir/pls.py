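"""NIPALS partial least squares regression (PLS1) and latent-variable selection.

One model per quality index (PLS1): the spectra matrix X (samples x
wavelengths) and a single response y (% units) are decomposed into shared
latent components by NIPALS deflation. The regression vector b satisfies
yhat = (X - x_mean) @ b + y_mean, so predictions are affine in the spectrum.

Latent-variable count is chosen by seeded k-fold cross-validation: the
candidate count minimising SECV wins, with ties broken toward the smaller
(more parsimonious) count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "PLSModel",
    "LVSelectionResult",
    "pls_fit",
    "pls_predict",
    "fitted_values",
    "select_components",
    "cross_val_predictions",
]

_TOL = 1e-12
_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 decomposition.

    Attributes
    ----------
    x_weights, x_loadings : (p, k) arrays W and P
    y_loadings : (k,) array q
    scores : (n, k) training score matrix T (mutually orthogonal columns)
    coefficients : (p,) regression vector over wavelengths
    x_mean, y_mean : centering statistics of the training data
    metadata : free-form training context (pipeline name, grid, index)
    """

    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coefficients: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)

    def coefficient_path(self) -> np.ndarray:
        """(p, k) matrix whose column j is the regression vector using j+1 LVs.

        Exploits the upper-triangular structure of P'W: the rotation matrix
        R = W (P'W)^-1 for the full model restricts to leading columns for
        truncated models.
        """
        PtW = self.x_loadings.T @ self.x_weights
        R = np.linalg.solve(PtW.T, self.x_weights.T).T
        return np.cumsum(R * self.y_loadings, axis=1)

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "n_components": self.n_components,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "coefficients": self.coefficients.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PLSModel":
        return cls(
            n_components=int(d["n_components"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            metadata=d.get("metadata", {}),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class LVSelectionResult:
    """SECV per candidate component count and the chosen count."""

    candidates: tuple[int, ...]
    secv: tuple[float, ...]
    chosen: int

    @property
    def chosen_secv(self) -> float:
        return self.secv[self.candidates.index(self.chosen)]


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    metadata: dict[str, Any] | None = None,
) -> PLSModel:
    """Fit PLS1 by NIPALS deflation.

    X and y are centred internally with their own means (idempotent on
    pre-centred data). For a single response the NIPALS inner loop converges
    in one pass per component; the loop is retained with tolerance ``1e-12``
    for numerical robustness.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("PLS needs at least 2 samples")
    if y.shape[0] != n:
        raise ValueError(f"y has {y.shape[0]} entries for {n} spectra")
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for a {n}x{p} problem"
        )
    if np.std(y) == 0:
        raise ValueError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    k_eff = n_components
    for k in range(n_components):
        # NIPALS inner loop: w <- Xc'u / |Xc'u|, t <- Xc w, u <- yc.
        # With a single response u is yc itself, so the loop is stationary
        # after one pass; iterate only to guard against pathological inputs.
        w = Xc.T @ yc
        for _ in range(_MAX_ITER):
            norm = np.linalg.norm(w)
            if norm < _TOL:
                break
            w_new = Xc.T @ yc
            if np.linalg.norm(w_new - w) <= _TOL * norm:
                w = w_new
                break
            w = w_new
        norm = np.linalg.norm(w)
        if norm < _TOL:
            k_eff = k
            break
        w = w / norm
        t = Xc @ w
        tt = t @ t
        if tt < _TOL:
            k_eff = k
            break
        p_k = Xc.T @ t / tt
        q_k = yc @ t / tt
        W[:, k], P[:, k], T[:, k], q[k] = w, p_k, t, q_k
        Xc = Xc - np.outer(t, p_k)
        yc = yc - q_k * t
    if k_eff == 0:
        raise ValueError("X has no variance after centering; cannot fit PLS")
    W, P, T, q = W[:, :k_eff], P[:, :k_eff], T[:, :k_eff], q[:k_eff]

    PtW = P.T @ W
    coef = W @ np.linalg.solve(PtW, q)
    return PLSModel(
        n_components=k_eff,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=coef,
        x_mean=x_mean,
        y_mean=y_mean,
        metadata=metadata or {},
    )


def pls_predict(m: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict index values: yhat = (X - x_mean) @ b + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.x_mean.shape[0]:
        raise ValueError(
            f"model expects {m.x_mean.shape[0]} wavelengths, got {X.shape[1]}"
        )
    return (X - m.x_mean) @ m.coefficients + m.y_mean


def fitted_values(m: PLSModel) -> np.ndarray:
    """Training-set fitted values, reconstructed from scores and y-loadings."""
    return m.scores @ m.y_loadings + m.y_mean


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 8,
    max_components: int | None = None,
    seed: int = 0,
) -> LVSelectionResult:
    """Choose the LV count minimising k-fold cross-validated SECV.

    Folds are a seeded random partition into ``k_folds`` near-equal groups.
    For each fold one model with the maximal candidate count is fitted and
    truncated-model predictions are read off its coefficient path, so the
    whole SECV curve costs a single fit per fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError(f"k_folds={k_folds} exceeds the {n} samples")
    min_train = n - int(np.ceil(n / k_folds))
    cap = min(min_train - 1, p)
    if max_components is None:
        max_components = min(20, cap)
    max_components = min(max_components, cap)
    if max_components < 1:
        raise ValueError("no admissible component count for this fold geometry")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)

    cv_pred = np.empty((n, max_components))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        m = pls_fit(X[mask], y[mask], max_components)
        path = m.coefficient_path()  # (p, k_eff)
        Xv = X[fold] - m.x_mean
        preds = Xv @ path + m.y_mean  # (n_val, k_eff)
        if path.shape[1] < max_components:  # rank-deficient fold: pad with last
            pad = np.repeat(preds[:, -1:], max_components - path.shape[1], axis=1)
            preds = np.hstack([preds, pad])
        cv_pred[fold] = preds

    secv = np.sqrt(np.mean((y[:, None] - cv_pred) ** 2, axis=0))
    chosen = int(np.argmin(secv)) + 1  # argmin returns the first (smallest) count
    return LVSelectionResult(
        candidates=tuple(range(1, max_components + 1)),
        secv=tuple(float(v) for v in secv),
        chosen=chosen,
    )


def cross_val_predictions(
    X: np.ndarray, y: np.ndarray, n_components: int, k_folds: int = 8, seed: int = 0
) -> np.ndarray:
    """Out-of-fold predictions at a fixed component count (for SECV reporting)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if k_folds > n:
        raise ValueError(f"k_folds={k_folds} exceeds the {n} samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    out = np.empty(n)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        k = min(n_components, min(mask.sum() - 1, X.shape[1]))
        m = pls_fit(X[mask], y[mask], k)
        out[fold] = pls_predict(m, X[fold])
    return out
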