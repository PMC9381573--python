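"""The three reported classifier families: QDA, KNN, RBF-kernel SVM.

Each family exposes ``fit`` returning a :class:`TrainedModel` whose
``decision_score`` is a continuous, positively-oriented score (higher =
more positive-class) and whose ``predict`` is its sign.  Labels are
+1 / -1 throughout.

QDA and KNN are implemented directly from their defining formulas; the
SVM dual solve is delegated to scikit-learn's SMO solver, but the dual
solution (support vectors, ``alpha_i y_i``, bias, gamma) is extracted
and the decision function recomputed from it in-package, so models
serialize losslessly and dual feasibility is checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .preprocess import ScalingParams

FAMILIES = ("QDA", "KNN", "SVM")


@dataclass(frozen=True)
class ModelConfig:
    """One classifier configuration; only the named family's knobs apply.

    * QDA — ``qda_reg``: covariance shrinkage weight in [0, 1] toward a
      spherical target ``tr(S)/N_f * I`` (the family's single optimized
      hyperparameter; required for invertibility at n ~ 20, p = 7).
    * KNN — ``knn_k``: odd neighbor count (odd avoids vote ties).
    * SVM — ``svm_C`` margin penalty and ``svm_gamma_scale`` s in
      ``gamma = s / (N_f * var(X))`` with var(X) the overall variance of
      the scaled training matrix.
    """

    family: str
    qda_reg: float = 0.1
    knn_k: int = 5
    svm_C: float = 1.0
    svm_gamma_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family == "QDA" and not 0.0 <= self.qda_reg <= 1.0:
            raise ValueError(f"qda_reg must lie in [0, 1], got {self.qda_reg}")
        if self.family == "KNN":
            if self.knn_k < 1 or self.knn_k % 2 == 0:
                raise ValueError(f"knn_k must be a positive odd integer, got {self.knn_k}")
        if self.family == "SVM":
            if self.svm_C <= 0:
                raise ValueError(f"svm_C must be positive, got {self.svm_C}")
            if self.svm_gamma_scale <= 0:
                raise ValueError(f"svm_gamma_scale must be positive, got {self.svm_gamma_scale}")

    def complexity_key(self) -> float:
        """Sort key for 'prefer the simpler model' tie-breaking.

        Lower is simpler: lowest k (KNN), highest shrinkage (QDA),
        smallest gamma multiplier s (SVM).
        """
        if self.family == "KNN":
            return float(self.knn_k)
        if self.family == "QDA":
            return -float(self.qda_reg)
        return float(self.svm_gamma_scale)


#: Default hyperparameter grids per family (config-exposed; the study's
#: exact grids are not public).  SVM sweeps s at fixed C = 1.
DEFAULT_GRIDS: dict[str, tuple[ModelConfig, ...]] = {
    "QDA": tuple(ModelConfig("QDA", qda_reg=r) for r in (0.0, 1e-3, 1e-2, 0.1, 0.3, 0.5)),
    "KNN": tuple(ModelConfig("KNN", knn_k=k) for k in (1, 3, 5, 7, 9, 11)),
    "SVM": tuple(ModelConfig("SVM", svm_C=1.0, svm_gamma_scale=s) for s in (0.1, 0.5, 1.0, 2.0, 10.0)),
}

#: Single default configuration per family (used when no grid search is requested).
DEFAULT_CONFIGS: dict[str, ModelConfig] = {
    "QDA": ModelConfig("QDA", qda_reg=0.1),
    "KNN": ModelConfig("KNN", knn_k=5),
    "SVM": ModelConfig("SVM", svm_C=1.0, svm_gamma_scale=1.0),
}


@dataclass
class TrainedModel:
    """Fitted parameters of one classifier plus its scaling and feature mask."""

    family: str
    config: ModelConfig
    retained_features: tuple[str, ...]
    params: dict[str, Any]
    scaling: ScalingParams | None = None

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _SCORERS[self.family](self.params, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_score(X)
        return np.where(s >= 0, 1, -1)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def enc(v):
            if isinstance(v, np.ndarray):
                return {"__array__": v.tolist()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        d: dict[str, Any] = {
            "family": self.family,
            "config": self.config.__dict__,
            "retained_features": list(self.retained_features),
            "params": {k: enc(v) for k, v in self.params.items()},
        }
        if self.scaling is not None:
            d["scaling"] = {
                "features": list(self.scaling.features),
                "location": self.scaling.location.tolist(),
                "scale": self.scaling.scale.tolist(),
            }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrainedModel":
        def dec(v):
            if isinstance(v, dict) and "__array__" in v:
                return np.asarray(v["__array__"], dtype=float)
            return v

        scaling = None
        if "scaling" in d:
            s = d["scaling"]
            scaling = ScalingParams(
                features=tuple(s["features"]),
                location=np.asarray(s["location"], dtype=float),
                scale=np.asarray(s["scale"], dtype=float),
            )
        return cls(
            family=d["family"],
            config=ModelConfig(**d["config"]),
            retained_features=tuple(d["retained_features"]),
            params={k: dec(v) for k, v in d["params"].items()},
            scaling=scaling,
        )

    @classmethod
    def from_json(cls, source) -> "TrainedModel":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError(f"X must be 2-D with one row per label; got {X.shape} vs {len(y)}")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError(f"labels must be +/-1, got {sorted(set(y.tolist()))}")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present in the training set")
    return X, y


# ----------------------------------------------------------------------
# QDA
# ----------------------------------------------------------------------

def qda_fit(
    X: np.ndarray,
    y: np.ndarray,
    reg: float = 0.1,
    retained_features: Sequence[str] = (),
    scaling: ScalingParams | None = None,
) -> TrainedModel:
    """Quadratic discriminant analysis with spherical covariance shrinkage.

    Per class k: prior ``pi_k = n_k / n``, mean ``mu_k``, covariance
    ``Sigma_k = (1 - reg) S_k + reg (tr(S_k)/N_f) I`` with ``S_k`` the
    class sample covariance (ddof=1).  Discriminant
    ``g_k(x) = -1/2 ln|Sigma_k| - 1/2 (x-mu_k)' Sigma_k^-1 (x-mu_k) + ln pi_k``;
    the decision score is ``g_pos - g_neg``.
    """
    X, y = _check_xy(X, y)
    p = X.shape[1]
    params: dict[str, Any] = {}
    for label, tag in ((1, "pos"), (-1, "neg")):
        Xc = X[y == label]
        if len(Xc) < 2:
            raise ValueError(f"class {label:+d} needs >= 2 training records, got {len(Xc)}")
        mu = Xc.mean(axis=0)
        S = np.atleast_2d(np.cov(Xc, rowvar=False, ddof=1))
        Sigma = (1.0 - reg) * S + reg * (np.trace(S) / p) * np.eye(p)
        try:
            chol = np.linalg.cholesky(Sigma)
            prec = np.linalg.inv(Sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"class {label:+d} covariance is singular"
                + ("; use reg > 0 (shrinkage) to regularize" if reg == 0 else "")
            ) from exc
        logdet = float(2.0 * np.log(np.diag(chol)).sum())
        if not np.isfinite(logdet) or not np.isfinite(prec).all():
            raise ValueError(
                f"class {label:+d} covariance is singular"
                + ("; use reg > 0 (shrinkage) to regularize" if reg == 0 else "")
            )
        params[f"mu_{tag}"] = mu
        params[f"prec_{tag}"] = prec
        params[f"logdet_{tag}"] = logdet
        params[f"logprior_{tag}"] = float(np.log(len(Xc) / len(X)))
    return TrainedModel(
        family="QDA",
        config=ModelConfig("QDA", qda_reg=reg),
        retained_features=tuple(retained_features),
        params=params,
        scaling=scaling,
    )


def _qda_score(params: dict[str, Any], X: np.ndarray) -> np.ndarray:
    def g(tag):
        d = X - params[f"mu_{tag}"]
        quad = np.einsum("ij,jk,ik->i", d, params[f"prec_{tag}"], d)
        return -0.5 * params[f"logdet_{tag}"] - 0.5 * quad + params[f"logprior_{tag}"]

    return g("pos") - g("neg")


# ----------------------------------------------------------------------
# KNN
# ----------------------------------------------------------------------

def knn_fit(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    retained_features: Sequence[str] = (),
    scaling: ScalingParams | None = None,
) -> TrainedModel:
    """K-nearest neighbors over the scaled training matrix.

    Score = (positive votes - negative votes) / k in [-1, 1]; distance
    ties break toward the lowest training-record index.
    """
    X, y = _check_xy(X, y)
    if k > len(X):
        raise ValueError(f"k={k} exceeds training size {len(X)}")
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    return TrainedModel(
        family="KNN",
        config=ModelConfig("KNN", knn_k=k),
        retained_features=tuple(retained_features),
        params={"X": X.copy(), "y": y.copy(), "k": int(k)},
        scaling=scaling,
    )


def _knn_score(params: dict[str, Any], Xq: np.ndarray) -> np.ndarray:
    Xt, yt, k = params["X"], np.asarray(params["y"], dtype=int), int(params["k"])
    d = cdist(Xq, Xt)
    n = Xt.shape[0]
    order = np.lexsort((np.broadcast_to(np.arange(n), d.shape), d), axis=1)[:, :k]
    votes = yt[order].sum(axis=1)
    return votes / k


def knn_score(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    return model.decision_score(x)


# ----------------------------------------------------------------------
# SVM (RBF kernel)
# ----------------------------------------------------------------------

def svm_gamma(X: np.ndarray, scale: float = 1.0) -> float:
    """``gamma = s / (N_f * var(X))`` with var(X) the overall variance."""
    X = np.asarray(X, dtype=float)
    var = float(X.var())
    if var <= 0:
        raise ValueError("training matrix has zero overall variance; gamma undefined")
    return float(scale) / (X.shape[1] * var)


def svm_fit(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    gamma: float | None = None,
    gamma_scale: float = 1.0,
    retained_features: Sequence[str] = (),
    scaling: ScalingParams | None = None,
    tol: float = 1e-6,
) -> TrainedModel:
    """Soft-margin RBF SVM; returns the dual solution explicitly.

    ``gamma`` defaults to ``gamma_scale / (N_f * var(X))``.  The stored
    parameters are the support vectors, their dual weights
    ``alpha_i y_i`` (bounded by C), the bias and gamma; the decision
    function ``f(x) = sum_i alpha_i y_i K(x_i, x) + b`` is evaluated
    from these stored arrays.
    """
    X, y = _check_xy(X, y)
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if gamma is None:
        gamma = svm_gamma(X, gamma_scale)
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    clf = SVC(C=C, kernel="rbf", gamma=gamma, tol=tol, max_iter=200_000)
    clf.fit(X, y)
    if clf.fit_status_ != 0 or (clf.n_iter_ >= 200_000).any():
        raise RuntimeError(
            f"SVM dual solve did not converge (fit_status={clf.fit_status_}, "
            f"n_iter={clf.n_iter_}, C={C}, gamma={gamma}, n={len(X)})"
        )
    dual = clf.dual_coef_[0]  # alpha_i * y_i, ordered like support_vectors_
    if np.any(np.abs(dual) > C * (1 + 1e-6)):
        raise RuntimeError("dual coefficients violate the box constraint |alpha_i| <= C")
    return TrainedModel(
        family="SVM",
        config=ModelConfig("SVM", svm_C=C, svm_gamma_scale=gamma_scale),
        retained_features=tuple(retained_features),
        params={
            "support_vectors": clf.support_vectors_.copy(),
            "dual_coef": dual.copy(),
            "bias": float(clf.intercept_[0]),
            "gamma": float(gamma),
            "C": float(C),
        },
        scaling=scaling,
    )


def _svm_score(params: dict[str, Any], Xq: np.ndarray) -> np.ndarray:
    K = np.exp(-params["gamma"] * cdist(Xq, params["support_vectors"], "sqeuclidean"))
    return K @ params["dual_coef"] + params["bias"]


def svm_score(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    return model.decision_score(x)


_SCORERS = {"QDA": _qda_score, "KNN": _knn_score, "SVM": _svm_score}


def fit_classifier(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    retained_features: Sequence[str] = (),
    scaling: ScalingParams | None = None,
) -> TrainedModel:
    """Dispatch a fit to the family named in ``config``."""
    if config.family == "QDA":
        return qda_fit(X, y, reg=config.qda_reg, retained_features=retained_features, scaling=scaling)
    if config.family == "KNN":
        k = config.knn_k
        return knn_fit(X, y, k=k, retained_features=retained_features, scaling=scaling)
    return svm_fit(
        X, y, C=config.svm_C, gamma_scale=config.svm_gamma_scale,
        retained_features=retained_features, scaling=scaling,
    )
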