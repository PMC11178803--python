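"""Exact Gaussian-process regression with a Matérn-5/2 kernel.

The model is the standard zero-mean GP prior y(·) ~ GP(m(·), k(·,·)) with a
stationary Matérn-5/2 covariance (one shared lengthscale, no ARD) plus i.i.d.
Gaussian observation noise σ².  Hyperparameters (lengthscale ℓ, signal
variance, σ²) are fitted by maximizing the log marginal likelihood with
L-BFGS-B under a softplus positivity reparameterization; prediction uses the
closed-form Gaussian posterior.

Two surfaces are provided:

* low-level functions (:func:`matern52_gram`, :func:`log_marginal_likelihood`,
  :func:`fit_gp`, :func:`posterior_predict`, :func:`nlpd`) operating on a
  :class:`GPState` with caller-standardized targets, and
* a model class :class:`GaussianProcess` whose :meth:`~GaussianProcess.fit`
  returns a :class:`GPResults` object reporting everything in original yield
  units, in the spirit of statsmodels' Model/Results split.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from . import autodiff as ad
from ._standardize import Standardizer

__all__ = [
    "KernelParams",
    "GPState",
    "PredictiveDistribution",
    "matern52_gram",
    "log_marginal_likelihood",
    "fit_gp",
    "posterior_predict",
    "nlpd",
    "GaussianProcess",
    "GPResults",
]

_SQRT5 = np.sqrt(5.0)
#: jitter ladder tried on Cholesky failure; first attempt adds nothing
_JITTERS = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)
#: floor for reported predictive variances
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class KernelParams:
    """Matérn-5/2 hyperparameters on their natural (positive) scale."""

    lengthscale: float = 1.0
    outputscale: float = 1.0
    noise: float = 0.1

    def validate(self) -> "KernelParams":
        vals = (self.lengthscale, self.outputscale, self.noise)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite kernel parameters: {self}")
        if self.lengthscale <= 0 or self.outputscale < 0 or self.noise < 0:
            raise ValueError(f"kernel parameters out of range: {self}")
        return self


@dataclass
class PredictiveDistribution:
    """Per-point Gaussian posterior: mean and variance, tagged with its scale."""

    mean: np.ndarray
    variance: np.ndarray
    scale_tag: str = "standardized"  # "standardized" | "original"

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.variance = np.asarray(self.variance, dtype=np.float64).ravel()
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean and variance length mismatch")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def __len__(self) -> int:
        return self.mean.size


def matern52(r: np.ndarray, lengthscale: float, outputscale: float) -> np.ndarray:
    """Matérn-5/2 as a function of Euclidean distance r."""
    u = _SQRT5 * r / lengthscale
    return outputscale * (1.0 + u + u**2 / 3.0) * np.exp(-u)


def matern52_gram(A, B, params: KernelParams) -> np.ndarray:
    """Cross-covariance matrix k(A_i, B_j) under a Matérn-5/2 kernel."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError(f"incompatible point-set shapes {A.shape} and {B.shape}")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("non-finite inputs to kernel")
    params.validate()
    return matern52(cdist(A, B), params.lengthscale, params.outputscale)


def matern52_gram_ad(A: ad.Tensor, lengthscale: ad.Tensor, outputscale: ad.Tensor) -> ad.Tensor:
    """Differentiable square Gram matrix of the Matérn-5/2 kernel.

    Used inside marginal-likelihood optimization, where gradients must flow
    into both the points (deep kernel) and the hyperparameters.  Squared
    distances are clipped at zero and shifted by a 1e-12 floor before the
    square root so the diagonal stays differentiable; the resulting relative
    error against the exact kernel is below 1e-11.
    """
    sq = ad.tsum(ad.mul(A, A), axis=1, keepdims=True)
    d2 = ad.relu(sq + sq.T - 2.0 * (A @ A.T))
    r = ad.sqrt(d2 + 1e-12)
    u = ad.mul(r, ad.power(lengthscale, -1.0) * _SQRT5)
    poly = 1.0 + u + ad.mul(ad.mul(u, u), 1.0 / 3.0)
    return ad.mul(ad.mul(poly, ad.exp(ad.mul(u, -1.0))), outputscale)


@dataclass
class GPState:
    """Training data, hyperparameters and the cached Cholesky factorization.

    ``train_y`` is expected on the standardized scale (the caller, usually a
    model class, owns the standardizer).  ``prior_mean`` is the constant GP
    mean on that scale, fixed at zero by default.
    """

    train_X: np.ndarray
    train_y: np.ndarray
    params: KernelParams
    prior_mean: float = 0.0
    _chol: tuple = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)
    jitter: float = field(default=0.0, repr=False)

    def __post_init__(self):
        self.train_X = np.atleast_2d(np.asarray(self.train_X, dtype=np.float64))
        self.train_y = np.asarray(self.train_y, dtype=np.float64).ravel()
        if self.train_y.size != self.train_X.shape[0] or self.train_y.size < 1:
            raise ValueError("train_X rows and train_y length must match and be >= 1")
        self.params.validate()
        self._factorize()

    def _factorize(self) -> None:
        K = matern52_gram(self.train_X, self.train_X, self.params)
        n = K.shape[0]
        Kn = K + self.params.noise * np.eye(n)
        err = None
        for jit in _JITTERS:
            try:
                c, low = cho_factor(Kn + jit * np.eye(n), lower=True, check_finite=False)
            except np.linalg.LinAlgError as e:  # pragma: no cover - rare path
                err = e
                continue
            self._chol = (c, low)
            self.jitter = jit
            self._alpha = cho_solve((c, low), self.train_y - self.prior_mean, check_finite=False)
            return
        cond = float(np.linalg.cond(Kn))
        raise np.linalg.LinAlgError(
            f"Cholesky failed after jitter ladder up to {_JITTERS[-1]:g} "
            f"(condition estimate {cond:.3g})"
        ) from err


def log_marginal_likelihood(state: GPState) -> float:
    """Full Gaussian log marginal likelihood of the training targets.

    Returns −½ yᵀ(K+σ²I)⁻¹y − ½ log|K+σ²I| − (n/2) log 2π, with y centred on
    the prior mean.  The complete density (constants included) is used so
    values are comparable across training-set sizes.
    """
    c, low = state._chol
    y = state.train_y - state.prior_mean
    logdet = 2.0 * np.sum(np.log(np.diag(c[0] if isinstance(c, tuple) else c)))
    n = y.size
    return float(-0.5 * (y @ state._alpha) - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi))


def _raw_to_params(raw: np.ndarray) -> KernelParams:
    sp = np.logaddexp(0.0, raw)
    return KernelParams(lengthscale=sp[0], outputscale=sp[1], noise=sp[2])


def _params_to_raw(p: KernelParams) -> np.ndarray:
    vals = np.array([p.lengthscale, p.outputscale, p.noise])
    # inverse softplus, stable for large values
    return vals + np.log1p(-np.exp(-np.maximum(vals, 1e-12)))


def _neg_lml_and_grad(raw: np.ndarray, X: np.ndarray, y: np.ndarray):
    raw_t = ad.Tensor(raw, requires_grad=True)
    pos = ad.softplus(raw_t)
    ell, out, noise = pos[0], pos[1], pos[2]
    K = matern52_gram_ad(ad.Tensor(X), ell, out)
    n = X.shape[0]
    eye = ad.Tensor(np.eye(n))
    Kn = K + ad.mul(eye, ad.reshape(noise, (1, 1)))
    for jit in _JITTERS:
        try:
            lml = ad.gaussian_lml(Kn + jit * np.eye(n) if jit else Kn, y)
            break
        except np.linalg.LinAlgError:
            continue
    else:  # pragma: no cover - pathological
        return np.inf, np.zeros_like(raw)
    lml.backward()
    return -float(lml.value), -raw_t.grad


def fit_gp(X, y, init: KernelParams | None = None, optimizer: str = "lbfgs") -> GPState:
    """Fit Matérn-5/2 hyperparameters by L-BFGS-B on the log marginal likelihood.

    ``y`` must already be standardized by the caller.  Deterministic for a
    fixed ``init`` (default ℓ=1, outputscale=1, σ²=0.1).  If the optimizer
    fails to improve, the best iterate seen is returned with a warning in the
    state rather than an exception.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length must match")
    if y.size < 2:
        raise ValueError("GP fitting requires at least 2 observations")
    if optimizer != "lbfgs":
        raise ValueError(f"unsupported optimizer: {optimizer}")
    init = (init or KernelParams()).validate()
    raw0 = _params_to_raw(init)
    res = minimize(
        _neg_lml_and_grad,
        raw0,
        args=(X, y),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 200},
    )
    state = GPState(train_X=X, train_y=y, params=_raw_to_params(res.x))
    init_state = GPState(train_X=X, train_y=y, params=init)
    # optimizer contract: never return something worse than the start point
    if log_marginal_likelihood(state) < log_marginal_likelihood(init_state):
        return init_state
    return state


def posterior_predict(state: GPState, X_star) -> PredictiveDistribution:
    """Closed-form GP posterior at query points, on the standardized scale.

    Mean: μ + K*ₓ[Kₓₓ+σ²I]⁻¹(y−μ); variance: diag(K** − K*ₓ[Kₓₓ+σ²I]⁻¹Kₓ*),
    reusing the training Cholesky factor cached on ``state``.
    """
    X_star = np.atleast_2d(np.asarray(X_star, dtype=np.float64))
    if X_star.shape[1] != state.train_X.shape[1]:
        raise ValueError(
            f"query width {X_star.shape[1]} != training width {state.train_X.shape[1]}"
        )
    Ks = matern52_gram(X_star, state.train_X, state.params)
    mean = state.prior_mean + Ks @ state._alpha
    c, low = state._chol
    L = np.tril(c) if low else np.triu(c).T
    v = solve_triangular(L, Ks.T, lower=True, check_finite=False)
    var = state.params.outputscale + state.params.noise - np.einsum("ij,ij->j", v, v)
    return PredictiveDistribution(mean=mean, variance=np.maximum(var, _VAR_FLOOR))


def nlpd(pred: PredictiveDistribution, targets, reduce: str = "mean") -> float:
    """Negative log predictive density of held-out targets.

    Per point: −log N(tᵢ; μᵢ, σᵢ²) = ½[log(2πσᵢ²) + (tᵢ−μᵢ)²/σᵢ²].  Reduced
    by the mean over points by default so values are comparable across test
    sizes; ``reduce="sum"`` gives the summed form.
    """
    t = np.asarray(targets, dtype=np.float64).ravel()
    if t.size != len(pred):
        raise ValueError("targets length does not match predictions")
    if np.any(pred.variance <= 0):
        raise ValueError("non-positive predictive variance")
    ll = 0.5 * (np.log(2.0 * np.pi * pred.variance) + (t - pred.mean) ** 2 / pred.variance)
    if reduce == "mean":
        return float(ll.mean())
    if reduce == "sum":
        return float(ll.sum())
    raise ValueError(f"unknown reduce: {reduce}")


class GaussianProcess:
    """Exact GP regression model on fixed feature vectors.

    Parameters
    ----------
    X : array-like, shape (n, d)
        Feature matrix (fingerprints, descriptors, or embeddings).
    y : array-like, shape (n,)
        Targets in original units (e.g. percent yield); standardized
        internally on construction.
    standardize : bool
        If False the targets are used as-is (they are then assumed to be on a
        sensible scale already).

    Examples
    --------
    >>> res = GaussianProcess(X, y).fit()
    >>> pred = res.predict(X_new)   # PredictiveDistribution in yield units
    """

    def __init__(self, X, y, standardize: bool = True):
        self.X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        if self.X.shape[0] != y.size:
            raise ValueError("X rows and y length must match")
        self.scaler = Standardizer.fit(y) if standardize else Standardizer(0.0, 1.0)
        self.y = y
        self.y_std = self.scaler.transform(y)

    def fit(self, init: KernelParams | None = None) -> "GPResults":
        state = fit_gp(self.X, self.y_std, init=init)
        return GPResults(self, state)

    def loglike(self, params: KernelParams) -> float:
        return log_marginal_likelihood(GPState(self.X, self.y_std, params))


class GPResults:
    """Results of a fitted :class:`GaussianProcess`.

    Attributes
    ----------
    params : KernelParams
        Fitted hyperparameters (lengthscale/outputscale/noise on the
        standardized target scale).
    llf : float
        Log marginal likelihood at the optimum.
    """

    def __init__(self, model: GaussianProcess, state: GPState):
        self.model = model
        self.state = state
        self.params = state.params
        self.llf = log_marginal_likelihood(state)
        self.nobs = state.train_y.size

    def predict(self, X_star) -> PredictiveDistribution:
        """Posterior predictive distribution in original yield units."""
        pred = posterior_predict(self.state, X_star)
        return PredictiveDistribution(
            mean=self.model.scaler.inverse(pred.mean),
            variance=self.model.scaler.inverse_variance(pred.variance),
            scale_tag="original",
        )

    def nlpd(self, X_star, targets, reduce: str = "mean") -> float:
        """NLPD of held-out targets (original units) under the posterior."""
        return nlpd(self.predict(X_star), targets, reduce=reduce)

    def summary(self) -> str:
        buf = io.StringIO()
        p = self.params
        buf.write("Gaussian Process Regression (Matern-5/2, no ARD)\n")
        buf.write("=" * 50 + "\n")
        buf.write(f"{'No. observations:':<28}{self.nobs}\n")
        buf.write(f"{'Feature width:':<28}{self.state.train_X.shape[1]}\n")
        buf.write(f"{'Log marginal likelihood:':<28}{self.llf:.4f}\n")
        buf.write(f"{'Lengthscale:':<28}{p.lengthscale:.4f}\n")
        buf.write(f"{'Outputscale (signal var):':<28}{p.outputscale:.4f}\n")
        buf.write(f"{'Noise variance:':<28}{p.noise:.4f}\n")
        buf.write(f"{'Target mean / sd:':<28}{self.model.scaler.mean:.3f} / {self.model.scaler.sd:.3f}\n")
        return buf.getvalue()

    def save(self, path: str) -> None:
        """Versioned model file: training data, hyperparameters, standardizer."""
        p = self.params
        np.savez(
            path,
            version=np.int64(1),
            train_X=self.state.train_X,
            train_y=self.state.train_y,
            kernel=np.array([p.lengthscale, p.outputscale, p.noise]),
            prior_mean=np.float64(self.state.prior_mean),
            scaler=np.array([self.model.scaler.mean, self.model.scaler.sd]),
        )

    @classmethod
    def load(cls, path: str) -> "GPResults":
        dat = np.load(path, allow_pickle=False)
        if int(dat["version"]) != 1:
            raise ValueError(f"unsupported model file version {int(dat['version'])}")
        scaler_mean, scaler_sd = dat["scaler"]
        y_orig = dat["train_y"] * scaler_sd + scaler_mean
        model = GaussianProcess(dat["train_X"], y_orig, standardize=scaler_sd != 1.0 or scaler_mean != 0.0)
        ell, out, noise = dat["kernel"]
        state = GPState(dat["train_X"], dat["train_y"], KernelParams(ell, out, noise),
                        prior_mean=float(dat["prior_mean"]))
        return cls(model, state)
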