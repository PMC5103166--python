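"""Latent-variable regression core: PCA for calibration-sample selection,
single-response PLS (PLS1) for calibration, and leave-one-out PRESS for
choosing the number of latent factors.

PLS1 is the classical NIPALS scheme with X-deflation per factor.  For a
single response the weight vector of each factor is obtained directly as the
normalised covariance direction X'y, so the algorithm is deterministic —
no randomised initialisation, no iteration needed.

Leave-one-out cross-validation refits *everything* inside each fold: the MSC
reference, the derivative/window pipeline and the centering are all
recomputed on the n-1 retained samples, so the PRESS curve and SECV carry no
information leaked from the held-out sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as scipy_f

from .io import SpectraSet, WavenumberGrid
from .preprocess import MSCReference, PreprocessConfig, preprocess

__all__ = [
    "PCAModel",
    "PLSModel",
    "PressCurve",
    "pca_fit",
    "pls_fit",
    "pls_predict",
    "loo_press",
    "select_factors",
    "save_model",
    "load_model",
]


@dataclass
class PCAModel:
    """Column-mean-centered principal component decomposition.

    Loadings are orthonormal rows (component x variable); scores are the
    centered data projected on them.  Sign convention: each loading's
    largest-magnitude element is positive.
    """

    center: np.ndarray
    loadings: np.ndarray          # n_components x p, orthonormal rows
    scores: np.ndarray            # n x n_components
    explained_variance_ratio: np.ndarray

    def score(self, k: int) -> np.ndarray:
        """1-based component scores (PC1 = score(1))."""
        return self.scores[:, k - 1]


def pca_fit(spectra: SpectraSet | np.ndarray, n_components: int) -> PCAModel:
    """PCA of the absorbance matrix via SVD of the centered data."""
    X = spectra.absorbance if isinstance(spectra, SpectraSet) else np.asarray(spectra, float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components must be <= min(n-1, p) = {min(n - 1, p)}")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n_components]
    # fix sign so the largest-|.| element of each loading is positive
    signs = np.sign(V[np.arange(n_components), np.abs(V).argmax(axis=1)])
    signs[signs == 0] = 1.0
    V = V * signs[:, None]
    scores = Xc @ V.T
    total_var = float((Xc**2).sum())
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAModel(center, V, scores, evr)


@dataclass
class PLSModel:
    """Fitted PLS1 regression with its preprocessing provenance.

    ``coef`` maps centered preprocessed spectra to centered response:
    ``y_hat = (x - x_center) @ coef + y_center``.
    """

    x_center: np.ndarray
    y_center: float
    weights: np.ndarray        # p x k
    x_loadings: np.ndarray     # p x k
    y_loadings: np.ndarray     # k
    coef: np.ndarray           # p
    n_factors: int
    preprocess_config: PreprocessConfig | None = None
    msc_ref: MSCReference | None = None
    training_ids: list[str] | None = None
    component: str | None = None

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict from an already-preprocessed matrix."""
        return (np.asarray(X, float) - self.x_center) @ self.coef + self.y_center


def _pls1_core(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """NIPALS PLS1 on centered data.  Returns W, P, q, and per-factor coefs."""
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    Xd = Xc.copy()
    yd = yc.copy()
    for k in range(n_factors):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise ValueError(
                f"factor {k + 1}: no covariance left — n_factors exceeds the rank "
                "of the (X, y) relationship"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            raise ValueError(f"factor {k + 1}: degenerate score vector")
        pvec = Xd.T @ t / tt
        qk = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd = yd - qk * t
        W[:, k], P[:, k], q[k] = w, pvec, qk
    return W, P, q


def _coef_from_wpq(W, P, q) -> np.ndarray:
    """Regression vector B = W (P'W)^-1 q."""
    return W @ np.linalg.solve(P.T @ W, q)


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    *,
    preprocess_config: PreprocessConfig | None = None,
    msc_ref: MSCReference | None = None,
    training_ids=None,
    component: str | None = None,
) -> PLSModel:
    """Fit PLS1 on a preprocessed matrix X and reference vector y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PLS calibration needs at least 3 samples")
    if not (1 <= n_factors <= min(n - 1, p)):
        raise ValueError(f"n_factors must be in [1, {min(n - 1, p)}]")
    if np.std(y) == 0:
        raise ValueError("zero-variance reference values")
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    W, P, q = _pls1_core(X - x_center, y - y_center, n_factors)
    coef = _coef_from_wpq(W, P, q)
    return PLSModel(
        x_center, y_center, W, P, q, coef, n_factors,
        preprocess_config, msc_ref, list(training_ids) if training_ids is not None else None,
        component,
    )


def pls_predict(model: PLSModel, spectra: SpectraSet) -> np.ndarray:
    """Predict concentrations (%) for raw spectra.

    Applies the model's stored preprocessing — in particular the *stored* MSC
    reference, never one refit on the incoming batch — then the centered
    linear prediction.  Pure function of (model, input).
    """
    if model.preprocess_config is None:
        X = spectra.absorbance
        if X.shape[1] != model.coef.size:
            raise ValueError("grid size does not match model coefficient length")
    else:
        cfg = model.preprocess_config
        if cfg.msc:
            if model.msc_ref is None:
                raise ValueError("model has MSC enabled but stores no reference")
            if not np.array_equal(
                model.msc_ref.grid.values, spectra.grid.values
            ):
                raise ValueError("input grid incompatible with stored MSC reference")
        pp, _ = preprocess(spectra, cfg, msc_ref=model.msc_ref)
        X = pp.absorbance
        if X.shape[1] != model.coef.size:
            raise ValueError("preprocessed grid does not match model coefficients")
    return model.predict_matrix(X)


@dataclass
class PressCurve:
    """PRESS(k) for k = 1..K plus the per-k leave-one-out residuals."""

    press: np.ndarray                # K
    loo_residuals: np.ndarray        # n x K, residual = y_true - y_loo_pred

    def __post_init__(self):
        if np.any(self.press < 0):
            raise ValueError("PRESS values must be >= 0")


def loo_press(
    spectra: SpectraSet,
    y: np.ndarray,
    max_factors: int,
    config: PreprocessConfig | None = None,
) -> PressCurve:
    """Leave-one-out PRESS curve with fold-internal preprocessing refits.

    For each held-out sample the MSC reference and centering are refit on the
    remaining n-1 spectra, PLS models with 1..max_factors factors are fit,
    and the held-out spectrum is predicted after the fold's own
    preprocessing.  PRESS(k) = sum of squared held-out errors at k factors.
    """
    y = np.asarray(y, float)
    n = spectra.n_samples
    if n < 4:
        raise ValueError("leave-one-out PRESS needs n >= 4")
    if max_factors > n - 2:
        raise ValueError("max_factors must be <= n - 2")
    resid = np.zeros((n, max_factors))
    ids = spectra.sample_ids
    for i in range(n):
        keep = [s for j, s in enumerate(ids) if j != i]
        train = spectra.subset(keep)
        ytr = np.delete(y, i)
        if config is not None:
            tr_pp, ref = preprocess(train, config)
            held = SpectraSet(spectra.grid, spectra.absorbance[[i]], [ids[i]])
            held_pp, _ = preprocess(held, config, msc_ref=ref)
            Xtr, xh = tr_pp.absorbance, held_pp.absorbance[0]
        else:
            Xtr, xh = train.absorbance, spectra.absorbance[i]
        xc = Xtr.mean(axis=0)
        yc = float(ytr.mean())
        W, P, q = _pls1_core(Xtr - xc, ytr - yc, max_factors)
        for k in range(1, max_factors + 1):
            coef = _coef_from_wpq(W[:, :k], P[:, :k], q[:k])
            pred = float((xh - xc) @ coef) + yc
            resid[i, k - 1] = y[i] - pred
    return PressCurve((resid**2).sum(axis=0), resid)


def select_factors(
    curve: PressCurve, method: str = "f_test", alpha: float = 0.25
) -> int:
    """Optimal factor count from the PRESS curve.

    ``f_test`` (default): the parsimonious Haaland--Thomas rule — the
    smallest k whose PRESS is not significantly larger than the curve's
    minimum by an F-ratio test at level ``alpha``.  A raw PRESS curve is
    noisy once it flattens, so the literal global minimum tends to inflate
    the factor count by chasing sub-percent fluctuations; the F-rule keeps
    only factors that demonstrably reduce cross-validated error.

    ``global_min``: the literal minimum of the curve, ties broken toward
    smaller k.
    """
    press = curve.press
    if press.size == 0:
        raise ValueError("empty PRESS curve")
    k_min = int(np.argmin(press))  # argmin takes the smaller k on exact ties
    if method == "global_min":
        return k_min + 1
    if method != "f_test":
        raise ValueError(f"unknown selection method {method!r}")
    n = curve.loo_residuals.shape[0]
    crit = scipy_f.ppf(1.0 - alpha, n, n)
    ratios = press / press[k_min] if press[k_min] > 0 else np.where(press > 0, np.inf, 1.0)
    return int(np.argmax(ratios <= crit)) + 1


# ---------------------------------------------------------------------------
# model serialization (JSON, so archives stay text and diffable)

def save_model(model: PLSModel, path) -> None:
    d = {
        "format": "nirseed-pls/1",
        "component": model.component,
        "n_factors": model.n_factors,
        "x_center": model.x_center.tolist(),
        "y_center": model.y_center,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "training_ids": model.training_ids,
        "preprocess": model.preprocess_config.to_dict()
        if model.preprocess_config
        else None,
        "msc_ref": {
            "grid": model.msc_ref.grid.values.tolist(),
            "resolution": model.msc_ref.grid.resolution,
            "mean_spectrum": model.msc_ref.mean_spectrum.tolist(),
        }
        if model.msc_ref
        else None,
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def load_model(path) -> PLSModel:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "nirseed-pls/1":
        raise ValueError("not a nirseed PLS model archive")
    ref = None
    if d["msc_ref"] is not None:
        ref = MSCReference(
            WavenumberGrid(np.array(d["msc_ref"]["grid"]), d["msc_ref"]["resolution"]),
            np.array(d["msc_ref"]["mean_spectrum"]),
        )
    cfg = PreprocessConfig.from_dict(d["preprocess"]) if d["preprocess"] else None
    return PLSModel(
        np.array(d["x_center"]),
        float(d["y_center"]),
        np.array(d["weights"]),
        np.array(d["x_loadings"]),
        np.array(d["y_loadings"]),
        np.array(d["coef"]),
        int(d["n_factors"]),
        cfg,
        ref,
        d["training_ids"],
        d["component"],
    )
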