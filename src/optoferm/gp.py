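"""Gaussian-process surrogates of the kinetic parameters.

Each kinetic parameter is modeled as an independent multi-input
single-output GP over the two experimental features — light intensity I
(μmol m⁻² s⁻¹) and EL222 copy number n — with a Matérn-5/2 kernel and
one length scale per feature (automatic relevance determination).
Hyperparameters (signal variance, two length scales, noise variance) are
set by maximizing the log marginal likelihood from multiple restarts;
prediction returns the posterior mean and variance at a test condition.

Numerical conventions
---------------------
* Features are scaled to comparable magnitudes (I by the maximum design
  intensity 70, n by the maximum design copy number 8) so the ARD length
  scales live on similar scales.
* Labels are standardized (zero mean, unit variance) before fitting and
  predictions are un-standardized; the GP prior mean is zero in the
  scaled space.  With a raw zero-mean prior, predictions of strictly
  positive parameters would revert toward 0 away from data; raw-label
  mode is retained behind ``standardize_labels=False``.
* The predictive variance reported is that of the latent function
  (measurement noise excluded) unless ``include_noise`` is passed.
* Cholesky factorizations climb a jitter ladder 1e-10 -> 1e-6 before
  giving up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize

from .calibration import GPTrainingSet
from .model import Condition, KineticParams, PARAM_NAMES

__all__ = [
    "GPHyperparams",
    "GPPosterior",
    "GaussianProcess",
    "ParameterSurrogate",
    "matern52",
    "kernel_matrix",
    "log_marginal_likelihood",
]

#: Feature scaling divisors: (max design intensity, max design copy number).
FEATURE_SCALE = np.array([70.0, 8.0])

#: Scaling divisors when the intensity axis is log-compressed.
LOG_FEATURE_SCALE = np.array([np.log1p(70.0), 8.0])

#: Jitter ladder tried on Cholesky failure.
JITTERS = (0.0, 1e-10, 1e-8, 1e-6)

#: Box for hyperparameter search, in scaled units (applied to each of
#: signal variance, both length scales, noise variance).
HYPER_BOX = (1e-4, 1e4)


@dataclass(frozen=True)
class GPHyperparams:
    """Kernel hyperparameters: signal variance σf², ARD length scales l
    (one per feature, in scaled feature units) and noise variance σn²."""

    signal_variance: float
    length_scales: tuple[float, float]
    noise_variance: float

    def __post_init__(self):
        vals = (self.signal_variance, *self.length_scales, self.noise_variance)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError(f"hyperparameters must be strictly positive, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.signal_variance, *self.length_scales, self.noise_variance])

    @classmethod
    def from_array(cls, a) -> "GPHyperparams":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), (float(a[1]), float(a[2])), float(a[3]))


@dataclass(frozen=True)
class GPPosterior:
    """Posterior mean and variance of one parameter at a test condition."""

    mean: float
    variance: float

    def __post_init__(self):
        if self.variance < -1e-12:
            raise ValueError(f"posterior variance is negative: {self.variance}")
        object.__setattr__(self, "variance", max(self.variance, 0.0))


def matern52(v_i: np.ndarray, v_j: np.ndarray, hyper: GPHyperparams) -> float:
    """Matérn-5/2 covariance between two feature vectors.

    κ = σf²·(1 + √5 r + (5/3) r²)·exp(−√5 r) with the ARD distance
    r² = Σ_d ((v_i,d − v_j,d)/l_d)².  Symmetric, bounded by σf².
    """
    diff = (np.asarray(v_i, float) - np.asarray(v_j, float)) / np.asarray(hyper.length_scales)
    r = float(np.sqrt(np.sum(diff**2)))
    s = np.sqrt(5.0) * r
    return hyper.signal_variance * (1.0 + s + s**2 / 3.0) * np.exp(-s)


def kernel_matrix(V: np.ndarray, hyper: GPHyperparams, V2: np.ndarray | None = None) -> np.ndarray:
    """Matérn-5/2 Gram matrix for features stored column-wise (d x n)."""
    A = np.asarray(V, float).T / np.asarray(hyper.length_scales)  # (n, d)
    B = A if V2 is None else np.asarray(V2, float).T / np.asarray(hyper.length_scales)
    d2 = np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :] - 2.0 * A @ B.T
    s = np.sqrt(5.0 * np.clip(d2, 0.0, None))
    return hyper.signal_variance * (1.0 + s + s**2 / 3.0) * np.exp(-s)


def _chol_with_jitter(K: np.ndarray) -> np.ndarray:
    scale = float(np.trace(K)) / K.shape[0] or 1.0
    for jit in JITTERS:
        try:
            return cholesky(K + jit * scale * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("kernel matrix not positive definite after max jitter")


def log_marginal_likelihood(V: np.ndarray, y: np.ndarray, hyper: GPHyperparams) -> float:
    """log p(y | V, ρ) of the zero-mean GP, computed via Cholesky.

    −½ yᵀ(K+σn²I)⁻¹y − ½ log det(K+σn²I) − (n/2) log 2π.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    K = kernel_matrix(V, hyper) + hyper.noise_variance * np.eye(n)
    L = _chol_with_jitter(K)
    a = cho_solve((L, True), y)
    return float(-0.5 * y @ a - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi))


class GaussianProcess:
    """Zero-prior-mean GP regressor with Matérn-5/2 ARD kernel.

    Parameters
    ----------
    feature_scale:
        Per-feature divisors applied to inputs before the kernel.
    standardize_labels:
        Standardize labels to zero mean / unit variance before fitting
        (default); the zero prior mean then sits at the label mean.
    log_labels:
        Model log(y) instead of y (labels must be strictly positive).
        Suited to kinetic parameters, which vary multiplicatively and
        whose fitted values can scatter over orders of magnitude at
        weakly identifying conditions; predictions return the posterior
        median exp(m) with a delta-method variance m''^2 * var.
    log_intensity:
        Compress the intensity feature with log1p before scaling.  Light
        dose-response is steep at low intensity (Hill-type activation)
        and flat at high intensity; a stationary kernel on a linear axis
        cannot have both, while on the log axis one length scale fits.
    """

    def __init__(
        self,
        feature_scale: np.ndarray | None = None,
        standardize_labels: bool = True,
        log_labels: bool = False,
        log_intensity: bool = False,
    ):
        if feature_scale is not None:
            self.feature_scale = np.asarray(feature_scale, float)
        else:
            self.feature_scale = (LOG_FEATURE_SCALE if log_intensity else FEATURE_SCALE).copy()
        self.standardize_labels = standardize_labels
        self.log_labels = log_labels
        self.log_intensity = log_intensity
        self.intensity_hull: tuple[float, float] | None = None  # raw units
        self.hyper: GPHyperparams | None = None
        self._V = None  # scaled features (d, n)
        self._y = None  # scaled labels (n,)
        self._label_mean = 0.0
        self._label_std = 1.0
        self._L = None
        self._alpha = None

    # -- scaling ----------------------------------------------------------
    def _scale_features(self, V: np.ndarray) -> np.ndarray:
        V = np.asarray(V, float).copy()
        if self.log_intensity:
            V[0] = np.log1p(V[0])
        return V / self.feature_scale[:, None]

    def _prepare_labels(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, float).ravel()
        if self.log_labels:
            if np.any(y <= 0):
                raise ValueError("log_labels requires strictly positive labels")
            y = np.log(y)
        self._label_mean = float(np.mean(y)) if self.standardize_labels else 0.0
        std = float(np.std(y))
        self._label_std = std if (self.standardize_labels and std > 0) else 1.0
        return (y - self._label_mean) / self._label_std

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        V: np.ndarray,
        y: np.ndarray,
        *,
        restarts: int = 8,
        seed: int = 0,
    ) -> "GaussianProcess":
        """Fit hyperparameters by multi-start maximization of the log
        marginal likelihood (L-BFGS-B in log-hyperparameter space)."""
        V = np.asarray(V, float)
        y = np.asarray(y, float).ravel()
        if V.ndim != 2:
            raise ValueError("V must be 2-D (features x points)")
        if y.size != V.shape[1]:
            raise ValueError("label count must match feature columns")
        if y.size < 2:
            raise ValueError("need at least 2 training points")

        ys = self._prepare_labels(y)
        Vs = self._scale_features(V)
        self.intensity_hull = (float(V[0].min()), float(V[0].max()))

        lo, hi = np.log(HYPER_BOX[0]), np.log(HYPER_BOX[1])
        bounds = [(lo, hi)] * 4
        var_y = max(float(np.var(ys)), 1e-8)

        def neg_lml(log_h: np.ndarray) -> float:
            try:
                h = GPHyperparams.from_array(np.exp(log_h))
                return -log_marginal_likelihood(Vs, ys, h)
            except (np.linalg.LinAlgError, ValueError, FloatingPointError):
                return 1e25

        rng = np.random.default_rng(seed)
        starts = [np.log([var_y, 0.5, 0.5, 0.1 * var_y])]
        for _ in range(max(restarts - 1, 0)):
            starts.append(rng.uniform(np.log(1e-2), np.log(1e2), size=4))

        best = None
        for x0 in starts:
            res = minimize(neg_lml, x0, method="L-BFGS-B", bounds=bounds)
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError("all hyperparameter restarts failed")

        self.hyper = GPHyperparams.from_array(np.exp(best.x))
        self._V, self._y = Vs, ys
        K = kernel_matrix(Vs, self.hyper) + self.hyper.noise_variance * np.eye(ys.size)
        self._L = _chol_with_jitter(K)
        self._alpha = cho_solve((self._L, True), ys)
        return self

    def set_hyperparams(self, V: np.ndarray, y: np.ndarray, hyper: GPHyperparams) -> "GaussianProcess":
        """Condition on data with fixed hyperparameters (no optimization)."""
        V = np.asarray(V, float)
        self._y = self._prepare_labels(y)
        self._V = self._scale_features(V)
        self.intensity_hull = (float(V[0].min()), float(V[0].max()))
        self.hyper = hyper
        K = kernel_matrix(self._V, hyper) + hyper.noise_variance * np.eye(self._y.size)
        self._L = _chol_with_jitter(K)
        self._alpha = cho_solve((self._L, True), self._y)
        return self

    def log_marginal_likelihood(self) -> float:
        self._require_fit()
        return log_marginal_likelihood(self._V, self._y, self.hyper)

    # -- prediction -------------------------------------------------------
    def predict(self, v_star: np.ndarray, *, include_noise: bool = False) -> GPPosterior:
        """Posterior mean and variance at one test feature vector.

        Variance is that of the latent function; pass ``include_noise``
        to add the learned noise variance (a new-observation predictive
        variance).  Returned in original label units.
        """
        self._require_fit()
        v = self._scale_features(np.asarray(v_star, float).reshape(2, 1))
        k_star = kernel_matrix(self._V, self.hyper, v).ravel()  # (n,)
        mean_s = float(k_star @ self._alpha)
        w = cho_solve((self._L, True), k_star)
        var_s = float(self.hyper.signal_variance - k_star @ w)
        if include_noise:
            var_s += self.hyper.noise_variance
        var_s = max(var_s, 0.0)
        mean_lab = mean_s * self._label_std + self._label_mean
        var_lab = var_s * self._label_std**2
        if self.log_labels:
            mean = float(np.exp(mean_lab))  # posterior median of the parameter
            return GPPosterior(mean=mean, variance=var_lab * mean**2)
        return GPPosterior(mean=mean_lab, variance=var_lab)

    def _require_fit(self):
        if self.hyper is None or self._alpha is None:
            raise RuntimeError("GaussianProcess is not fitted")

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        self._require_fit()
        return {
            "feature_scale": self.feature_scale.tolist(),
            "standardize_labels": self.standardize_labels,
            "log_labels": self.log_labels,
            "log_intensity": self.log_intensity,
            "intensity_hull": list(self.intensity_hull) if self.intensity_hull else None,
            "label_mean": self._label_mean,
            "label_std": self._label_std,
            "V_scaled": self._V.tolist(),
            "y_scaled": self._y.tolist(),
            "hyperparams": {
                "signal_variance": self.hyper.signal_variance,
                "length_scales": list(self.hyper.length_scales),
                "noise_variance": self.hyper.noise_variance,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianProcess":
        gp = cls(
            feature_scale=np.asarray(d["feature_scale"], float),
            standardize_labels=bool(d["standardize_labels"]),
            log_labels=bool(d.get("log_labels", False)),
            log_intensity=bool(d.get("log_intensity", False)),
        )
        hull = d.get("intensity_hull")
        gp.intensity_hull = tuple(hull) if hull else None
        gp._label_mean = float(d["label_mean"])
        gp._label_std = float(d["label_std"])
        gp._V = np.asarray(d["V_scaled"], float)
        gp._y = np.asarray(d["y_scaled"], float)
        h = d["hyperparams"]
        gp.hyper = GPHyperparams(
            float(h["signal_variance"]),
            tuple(float(v) for v in h["length_scales"]),
            float(h["noise_variance"]),
        )
        K = kernel_matrix(gp._V, gp.hyper) + gp.hyper.noise_variance * np.eye(gp._y.size)
        gp._L = _chol_with_jitter(K)
        gp._alpha = cho_solve((gp._L, True), gp._y)
        return gp


class ParameterSurrogate:
    """Six independent GPs mapping (light intensity, copy number) to the
    six kinetic parameters; the surrogate half of the hybrid model.

    All six GPs must be trained on the same feature matrix.  Predicted
    means below a parameter's positivity floor are clamped to the lower
    bound of its default search box with a warning: the zero-mean prior
    can otherwise pull weakly constrained parameters non-positive off the
    training hull.
    """

    #: positivity floors (lower bounds of the calibration search boxes)
    FLOORS = {
        "mu_max": 0.01, "k_g": 1e-3, "alpha": 1.0,
        "beta": 1e-3, "d_p": 1e-4, "y_gb": 0.1,
    }

    def __init__(self, models: dict[str, GaussianProcess]):
        missing = set(PARAM_NAMES) - set(models)
        if missing:
            raise ValueError(f"missing GP models for parameters: {sorted(missing)}")
        ref = models[PARAM_NAMES[0]]
        ref._require_fit()
        for name in PARAM_NAMES:
            m = models[name]
            m._require_fit()
            if m._V.shape != ref._V.shape or not np.allclose(m._V, ref._V):
                raise ValueError("all six GPs must be trained on the same feature matrix V")
        self.models = models

    @classmethod
    def train(
        cls,
        training_sets: dict[str, GPTrainingSet],
        *,
        restarts: int = 8,
        seed: int = 0,
        standardize_labels: bool = True,
        log_labels: bool = True,
        log_intensity: bool = True,
    ) -> "ParameterSurrogate":
        """Train all six GPs.  By default labels are modeled in log space
        (kinetic parameters are positive and scatter multiplicatively,
        and the occasional wildly off per-condition fit at a weakly
        identifying condition would dominate a raw-scale GP) and the
        intensity feature is log-compressed (dose-response is steep at
        low light, flat at high light)."""
        models = {}
        for i, name in enumerate(PARAM_NAMES):
            ts = training_sets[name]
            gp = GaussianProcess(standardize_labels=standardize_labels,
                                 log_labels=log_labels, log_intensity=log_intensity)
            gp.fit(ts.V, ts.L, restarts=restarts, seed=seed + i)
            models[name] = gp
        return cls(models)

    def predict_params(
        self, condition: Condition
    ) -> tuple[KineticParams, dict[str, float]]:
        """Posterior-mean kinetic parameters (and per-parameter posterior
        variances) at a condition.  Non-integer copy numbers are allowed
        upstream (the GP maps R² -> R) but conditions store integers."""
        import warnings

        v = np.array([condition.light_intensity, condition.copy_number], float)
        values, variances = {}, {}
        for name in PARAM_NAMES:
            post = self.models[name].predict(v)
            mean = post.mean
            if mean <= 0:
                warnings.warn(
                    f"GP mean for {name} at {condition} is non-positive "
                    f"({mean:.3g}); flooring at {self.FLOORS[name]}",
                    stacklevel=2,
                )
                mean = self.FLOORS[name]
            values[name] = mean
            variances[name] = post.variance
        return KineticParams(**values), variances

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {name: self.models[name].to_dict() for name in PARAM_NAMES}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSurrogate":
        payload = json.loads(Path(path).read_text())
        return cls({name: GaussianProcess.from_dict(d) for name, d in payload.items()})
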