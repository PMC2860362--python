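"""Gaussian mixtures under mclust-style covariance constraints, with BIC selection.

Model-based clustering describes the rows of a data matrix as draws from a
finite mixture of multivariate normals.  The covariance families constrain
shape and volume of the components:

======  ==============================================  cov. parameters
EII     spherical, equal volume across components       1
VII     spherical, volume varies per component          k
EEI     diagonal, equal across components               d
VVI     diagonal, varies per component                  k·d
VVV     full covariance, varies per component           k·d(d+1)/2
======  ==============================================  cov. parameters

The number of clusters and the family are chosen jointly by the Bayesian
Information Criterion in the larger-is-better convention
``BIC = 2·logL − n_params·log(n)``.

The EM here is seeded by kmeans++ with multiple restarts; component labels in
:class:`ConstrainedGaussianMixture` follow the sklearn 0-based convention,
while the :class:`MixtureFit` record uses 1-based labels matching subclass
indices downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "MODEL_CODES",
    "DegenerateFitError",
    "MixtureFit",
    "ConstrainedGaussianMixture",
    "MixtureModelSelector",
    "fit_gmm",
    "bic_score",
    "select_model",
    "n_mixture_params",
]

MODEL_CODES = ("EII", "VII", "EEI", "VVI", "VVV")

DEFAULT_FAMILIES = MODEL_CODES


class DegenerateFitError(RuntimeError):
    """The EM collapsed (empty component, identical rows, non-finite likelihood)."""


def n_mixture_params(model_code: str, k: int, d: int) -> int:
    """Free-parameter count: (k−1) weights + k·d means + covariance parameters."""
    cov = {
        "EII": 1,
        "VII": k,
        "EEI": d,
        "VVI": k * d,
        "VVV": k * d * (d + 1) // 2,
    }[model_code]
    return (k - 1) + k * d + cov


def bic_score(log_likelihood: float, n_params: int, n: int) -> float:
    """BIC in the larger-is-better convention: 2·logL − n_params·log(n)."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return 2.0 * log_likelihood - n_params * np.log(n)


@dataclass
class MixtureFit:
    """One fitted constrained Gaussian mixture (hard assignments are 1-based)."""

    model_code: str
    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # (k, d, d), the constraint already applied
    log_likelihood: float
    n_params: int
    bic: float
    assignments: np.ndarray  # labels in 1..k
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    def volumes(self) -> np.ndarray:
        """Per-component generalized variance det(Σ)^(1/d) — the cluster-volume diagnostic."""
        d = self.means.shape[1]
        signs, logdets = np.linalg.slogdet(self.covariances)
        return np.exp(logdets / d) * signs


def _diag_log_density(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, k) log N(x | μ_j, diag v_j); GEMM form of the quadratic, no (n,k,d) temporary."""
    d = X.shape[1]
    inv = 1.0 / variances  # (k, d)
    logdet = np.log(variances).sum(axis=1)  # (k,)
    quad = (X**2) @ inv.T - 2.0 * (X @ (means * inv).T) + (means**2 * inv).sum(axis=1)[None, :]
    return -0.5 * (d * np.log(2 * np.pi) + logdet[None, :] + quad)


def _full_log_density(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    n, k = X.shape[0], means.shape[0]
    out = np.empty((n, k))
    for j in range(k):
        try:
            chol = np.linalg.cholesky(covs[j])
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError(f"singular covariance in component {j + 1}") from exc
        diff = X - means[j]
        sol = np.linalg.solve(chol, diff.T)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, j] = -0.5 * (d * np.log(2 * np.pi) + logdet + (sol**2).sum(axis=0))
    return out


def _m_step(X, R, model_code, reg):
    """Weighted ML estimates under the covariance constraint.

    Returns (weights, means, variances-or-covs) where diagonal families yield a
    (k, d) variance array and VVV a (k, d, d) covariance stack.
    """
    n, d = X.shape
    nk = R.sum(axis=0)
    if np.any(nk < 1e-10):
        raise DegenerateFitError("empty mixture component")
    weights = nk / n
    means = (R.T @ X) / nk[:, None]
    if model_code == "VVV":
        covs = np.empty((len(nk), d, d))
        for j in range(len(nk)):
            diff = X - means[j]
            covs[j] = (diff * R[:, j : j + 1]).T @ diff / nk[j]
        covs[:, np.arange(d), np.arange(d)] = np.maximum(covs[:, np.arange(d), np.arange(d)], reg)
        return weights, means, covs
    # per-component weighted SSQ about the component mean, (k, d):
    # Σ_i r_ij (x_i − μ_j)² = Σ_i r_ij x_i² − n_j μ_j²
    S = np.maximum(R.T @ (X**2) - nk[:, None] * means**2, 0.0)
    if model_code == "EII":
        lam = S.sum() / (n * d)
        var = np.full((len(nk), d), lam)
    elif model_code == "VII":
        var = np.repeat((S.sum(axis=1) / (nk * d))[:, None], d, axis=1)
    elif model_code == "EEI":
        var = np.repeat((S.sum(axis=0) / n)[None, :], len(nk), axis=0)
    elif model_code == "VVI":
        var = S / nk[:, None]
    else:
        raise ValueError(f"unknown model_code {model_code!r}")
    return weights, means, np.maximum(var, reg)


class ConstrainedGaussianMixture(BaseEstimator):
    """EM for one (family, k) candidate.

    Parameters
    ----------
    n_components : number of mixture components k ≥ 1.
    model_code : one of ``EII, VII, EEI, VVI, VVV``.
    random_state : seed for the kmeans++ initializations.
    n_init : number of kmeans++ restarts; the best final log-likelihood wins.
    reg : floor applied to covariance diagonals; ``None`` → 1e-6 of the mean
        column variance of the training data.

    Attributes (after ``fit``)
    --------------------------
    ``weights_, means_, covariances_`` (dense k×d×d), ``labels_`` (0-based MAP
    labels), ``log_likelihood_, n_params_, bic_, converged_, loglik_trace_``.
    """

    def __init__(
        self,
        n_components: int = 1,
        model_code: str = "VVV",
        random_state: int = 0,
        max_iter: int = 500,
        tol: float = 1e-8,
        reg: float | None = None,
        n_init: int = 5,
    ):
        self.n_components = n_components
        self.model_code = model_code
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.reg = reg
        self.n_init = n_init

    # -- internals ---------------------------------------------------------

    def _log_density(self, X, means, cov_param):
        if self.model_code == "VVV":
            return _full_log_density(X, means, cov_param)
        return _diag_log_density(X, means, cov_param)

    @staticmethod
    def _check_floor(cov, reg):
        """Reject singular fits: a covariance at or below the regularization
        floor means a component collapsed onto coincident points, or a full
        covariance was estimated from fewer points than dimensions — an
        unbounded-likelihood artifact, not a cluster."""
        if cov.ndim == 3:
            mineig = np.linalg.eigvalsh(cov)[:, 0]
        else:
            mineig = cov.min(axis=1)
        if np.any(mineig <= reg * (1.0 + 1e-9)):
            raise DegenerateFitError(
                "component covariance collapsed to the regularization floor"
            )

    def _em_run(self, X, R0, reg):
        weights, means, cov = _m_step(X, R0, self.model_code, reg)
        trace: list[float] = []
        prev = -np.inf
        converged = False
        for it in range(self.max_iter):
            log_dens = self._log_density(X, means, cov) + np.log(weights)[None, :]
            m = log_dens.max(axis=1)
            row_ll = m + np.log(np.exp(log_dens - m[:, None]).sum(axis=1))
            ll = float(row_ll.sum())
            if not np.isfinite(ll):
                raise DegenerateFitError("non-finite log-likelihood")
            trace.append(ll)
            if abs(ll - prev) <= self.tol * (1.0 + abs(ll)):
                converged = True
                break
            prev = ll
            R = np.exp(log_dens - row_ll[:, None])
            weights, means, cov = _m_step(X, R, self.model_code, reg)
            if it % 10 == 9 and (self.n_components > 1 or self.model_code == "VVV"):
                self._check_floor(cov, reg)  # abort collapsing runs early
        # k=1 diagonal fits are closed-form and bounded even for zero-variance
        # classes (identical profiles), so only multi-component fits and full
        # covariances (rank-deficient when a component has ≤ d points) are
        # screened for collapse
        if self.n_components > 1 or self.model_code == "VVV":
            self._check_floor(cov, reg)
        return ll, trace, converged, weights, means, cov

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n rows × d columns)")
        n, d = X.shape
        k = self.n_components
        if self.model_code not in MODEL_CODES:
            raise ValueError(f"unknown model_code {self.model_code!r}")
        if k < 1:
            raise ValueError("n_components must be ≥ 1")
        if n < k:
            raise ValueError(f"cannot fit {k} components to {n} rows")
        col_var = X.var(axis=0).mean()
        if k > 1 and col_var == 0.0:
            raise DegenerateFitError("all rows identical; k > 1 is degenerate")
        reg = self.reg if self.reg is not None else max(1e-6 * col_var, 1e-12)

        best = None
        failures: list[str] = []
        n_starts = 1 if k == 1 else self.n_init
        for start in range(n_starts):
            if k == 1:
                R0 = np.ones((n, 1))
            else:
                ss = np.random.SeedSequence([int(self.random_state), k, start])
                km_seed = int(ss.generate_state(1)[0] % (2**31))
                centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=km_seed)
                d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
                hard = d2.argmin(axis=1)
                if len(np.unique(hard)) < k:
                    failures.append(f"restart {start}: empty initial component")
                    continue
                R0 = np.zeros((n, k))
                R0[np.arange(n), hard] = 1.0
            try:
                result = self._em_run(X, R0, reg)
            except DegenerateFitError as exc:
                failures.append(f"restart {start}: {exc}")
                continue
            ll_r, _, _, weights_r, means_r, cov_r = result
            labels_r = (
                self._log_density(X, means_r, cov_r) + np.log(weights_r)[None, :]
            ).argmax(axis=1)
            # a Gaussian component needs ≥ 2 observations for its variance to
            # be identifiable; near-singleton solutions are spurious optima
            # (they shrink pooled variances without bound in high dimension)
            if k > 1 and np.bincount(labels_r, minlength=k).min() < 2:
                failures.append(f"restart {start}: component with fewer than 2 members")
                continue
            if best is None or result[0] > best[0]:
                best = result
                best_labels = labels_r
        if best is None:
            raise DegenerateFitError(
                f"{self.model_code} k={k}: every EM restart degenerated ({'; '.join(failures)})"
            )
        ll, trace, converged, weights, means, cov = best
        labels = best_labels

        self.weights_ = weights
        self.means_ = means
        if self.model_code == "VVV":
            self.covariances_ = cov
        else:
            self.covariances_ = np.stack([np.diag(v) for v in cov])
        self.labels_ = labels
        self.log_likelihood_ = ll
        self.n_params_ = n_mixture_params(self.model_code, k, d)
        self.bic_ = bic_score(ll, self.n_params_, n)
        self.converged_ = converged
        self.loglik_trace_ = trace
        self.reg_ = reg
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.model_code == "VVV":
            log_dens = _full_log_density(X, self.means_, self.covariances_)
        else:
            variances = np.stack([np.diag(c) for c in self.covariances_])
            log_dens = _diag_log_density(X, self.means_, variances)
        return (log_dens + np.log(self.weights_)[None, :]).argmax(axis=1)

    def to_fit(self) -> MixtureFit:
        return MixtureFit(
            model_code=self.model_code,
            k=self.n_components,
            weights=self.weights_,
            means=self.means_,
            covariances=self.covariances_,
            log_likelihood=self.log_likelihood_,
            n_params=self.n_params_,
            bic=self.bic_,
            assignments=self.labels_ + 1,
            converged=self.converged_,
            loglik_trace=self.loglik_trace_,
        )


class MixtureModelSelector(BaseEstimator):
    """Grid search over covariance families × k with BIC selection.

    Candidates run over k = 1..min(k_max, n) and the listed families, skipping
    (family, k) combinations that cannot be estimated on small classes: k > 1
    with n < k + 1, or n·d ≤ n_params.  Ties in BIC go to the smaller k, then
    to the earlier family in ``families``.
    """

    def __init__(
        self,
        k_max: int = 8,
        families: tuple[str, ...] = DEFAULT_FAMILIES,
        random_state: int = 0,
        max_iter: int = 500,
        tol: float = 1e-8,
        reg: float | None = None,
        n_init: int = 5,
    ):
        self.k_max = k_max
        self.families = families
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.reg = reg
        self.n_init = n_init

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least 2 rows to select a model")
        best: ConstrainedGaussianMixture | None = None
        attempted: list[tuple[str, int, float]] = []
        failures: list[str] = []
        for k in range(1, min(self.k_max, n) + 1):
            for fam in self.families:
                if k > 1 and n < k + 1:
                    continue
                if n * d <= n_mixture_params(fam, k, d):
                    continue
                est = ConstrainedGaussianMixture(
                    n_components=k,
                    model_code=fam,
                    random_state=self.random_state,
                    max_iter=self.max_iter,
                    tol=self.tol,
                    reg=self.reg,
                    n_init=self.n_init,
                )
                try:
                    est.fit(X)
                except (DegenerateFitError, np.linalg.LinAlgError) as exc:
                    failures.append(f"{fam} k={k}: {exc}")
                    continue
                attempted.append((fam, k, est.bic_))
                if best is None or est.bic_ > best.bic_:
                    best = est
        if best is None:
            raise DegenerateFitError(
                "no mixture candidate could be fitted: " + "; ".join(failures)
            )
        self.best_ = best
        self.candidates_ = attempted
        self.failures_ = failures
        self.labels_ = best.labels_
        self.bic_ = best.bic_
        return self

    def predict(self, X):
        return self.best_.predict(X)


def fit_gmm(
    data: np.ndarray,
    k: int,
    model_code: str = "VVV",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    reg: float | None = None,
) -> MixtureFit:
    """Fit one constrained Gaussian mixture and return its :class:`MixtureFit`."""
    est = ConstrainedGaussianMixture(
        n_components=k, model_code=model_code, random_state=seed,
        max_iter=max_iter, tol=tol, reg=reg,
    )
    return est.fit(np.asarray(data, dtype=float)).to_fit()


def select_model(
    data: np.ndarray,
    k_max: int = 8,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    reg: float | None = None,
) -> MixtureFit:
    """Best-BIC mixture over families × k ∈ 1..min(k_max, n)."""
    sel = MixtureModelSelector(
        k_max=k_max, families=families, random_state=seed,
        max_iter=max_iter, tol=tol, reg=reg,
    )
    return sel.fit(np.asarray(data, dtype=float)).best_.to_fit()
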