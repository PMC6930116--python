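"""Conditional Gaussian-mixture model of pre-bout to post-bout transforms.

The pre/post bout coordinate transforms of pursuing fish are
multivariate, heteroskedastic and potentially multi-modal.  A finite
Gaussian mixture over the joint (pre, post) vector, with the number of
components selected by an information criterion, captures all three
properties while keeping the conditional simulation exact: conditioning
a Gaussian mixture on the pre-bout block is closed-form Gaussian
algebra (component responsibilities re-weighted by the pre-marginal
likelihood, per-component conditional mean and covariance).  The fitted
model slots into the stochastic recursion
(:func:`pursuit3d.recursion.mixture_recursion`) as the generative arm.

The EM engine is scikit-learn's ``GaussianMixture``; fitting runs it
one iteration at a time so the log-likelihood trace is recorded (EM
guarantees it is non-decreasing, which tests assert).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = ["TransformSample", "MixtureTransform", "recover_noise_law"]


class TransformSample:
    """One pre-bout -> post-bout coordinate pair."""

    __slots__ = ("pre", "post")

    def __init__(self, pre, post):
        self.pre = np.asarray(pre, dtype=float)
        self.post = np.asarray(post, dtype=float)
        if self.pre.shape != self.post.shape:
            raise ValueError("pre and post must have the same dimension")

    def as_row(self) -> np.ndarray:
        return np.concatenate([self.pre, self.post])


def _as_matrix(samples) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        X = samples
    elif len(samples) and isinstance(samples[0], TransformSample):
        X = np.array([s.as_row() for s in samples])
    else:
        X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[1] % 2:
        raise ValueError("samples must be (n, 2*d): pre columns then post")
    return X


class MixtureTransform(BaseEstimator):
    """Joint Gaussian mixture over (pre, post) with exact conditioning.

    Parameters
    ----------
    k_range : sequence of int
        Candidate component counts; the best by ``criterion`` wins.
    n_restarts : int
        Independent EM initialisations per K (best final likelihood kept).
    criterion : {"bic", "aic"}
        Model-selection score.
    reg_covar : float
        Ridge added to covariance diagonals (degenerate-covariance guard).
    nonneg_post_dims : sequence of int or None
        Post-coordinate indices clamped at >= 0 when sampling (e.g. the
        distance coordinate).

    Attributes (after fit)
    ----------------------
    k_ : selected number of components
    weights_, means_, covariances_ : mixture parameters over 2*d dims
    pre_dim_ : d, the dimension of the pre block
    scores_ : dict K -> information-criterion value
    loglik_trace_ : per-iteration mean log-likelihood of the winning fit
    """

    def __init__(self, k_range: Sequence[int] = (1, 2, 3, 4, 5),
                 n_restarts: int = 3, max_iter: int = 200, tol: float = 1e-4,
                 reg_covar: float = 1e-6, criterion: str = "bic",
                 nonneg_post_dims: Optional[Sequence[int]] = None,
                 random_state: Optional[int] = None):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.reg_covar = reg_covar
        self.criterion = criterion
        self.nonneg_post_dims = nonneg_post_dims
        self.random_state = random_state

    def _fit_one(self, X, k, seed):
        """EM with warm restarts one iteration at a time, tracing the LL."""
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             reg_covar=self.reg_covar, max_iter=1,
                             warm_start=True, random_state=seed, n_init=1)
        trace = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for _ in range(self.max_iter):
                gm.fit(X)
                trace.append(gm.score(X))
                if len(trace) > 1 and abs(trace[-1] - trace[-2]) < self.tol:
                    break
        return gm, trace

    def fit(self, X, y=None):
        """Fit on (n, 2*d) rows of [pre, post] or a list of TransformSample."""
        X = _as_matrix(X)
        k_max = max(self.k_range)
        if len(X) < 10 * k_max:
            raise ValueError(f"need >= {10 * k_max} samples for k_range up to "
                             f"{k_max}, got {len(X)}")
        ss = np.random.SeedSequence(self.random_state)
        scores = {}
        best = None
        for k in self.k_range:
            cand = None
            for child in ss.spawn(self.n_restarts):
                seed = int(child.generate_state(1)[0] % 2**31)
                gm, trace = self._fit_one(X, k, seed)
                if cand is None or trace[-1] > cand[1][-1]:
                    cand = (gm, trace)
            gm, trace = cand
            score = gm.bic(X) if self.criterion == "bic" else gm.aic(X)
            scores[k] = float(score)
            if best is None or score < best[0]:
                best = (score, k, gm, trace)
        _, self.k_, gm, self.loglik_trace_ = best
        self.scores_ = scores
        self.weights_ = gm.weights_
        self.means_ = gm.means_
        self.covariances_ = gm.covariances_
        self.pre_dim_ = X.shape[1] // 2
        return self

    # -- conditional algebra -------------------------------------------------

    def _conditional_components(self, pre):
        """Re-weighted weights plus per-component conditional (mean, cov)."""
        check_is_fitted(self, "weights_")
        pre = np.asarray(pre, dtype=float).ravel()
        d = self.pre_dim_
        if pre.shape != (d,):
            raise ValueError(f"pre must have dimension {d}")
        log_w = np.log(self.weights_)
        cond_means, cond_covs = [], []
        for k in range(len(self.weights_)):
            mu_p = self.means_[k, :d]
            mu_q = self.means_[k, d:]
            S = self.covariances_[k]
            Spp, Spq = S[:d, :d], S[:d, d:]
            Sqp, Sqq = S[d:, :d], S[d:, d:]
            # responsibility: weight times pre-marginal density
            sign, logdet = np.linalg.slogdet(Spp)
            diff = pre - mu_p
            sol = np.linalg.solve(Spp, diff)
            log_w[k] += -0.5 * (d * np.log(2 * np.pi) + logdet + diff @ sol)
            gain = Sqp @ np.linalg.inv(Spp)
            cond_means.append(mu_q + gain @ diff)
            cond_covs.append(Sqq - gain @ Spq)
        w = np.exp(log_w - log_w.max())
        return w / w.sum(), cond_means, cond_covs

    def conditional_sample(self, pre, n: int,
                           rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Draw ``n`` post vectors from p(post | pre); exact, no rejection."""
        rng = np.random.default_rng(rng)
        w, means, covs = self._conditional_components(pre)
        comps = rng.choice(len(w), size=n, p=w)
        out = np.empty((n, self.pre_dim_))
        for k in np.unique(comps):
            idx = comps == k
            out[idx] = rng.multivariate_normal(means[k], covs[k],
                                               size=int(idx.sum()),
                                               method="cholesky")
        if self.nonneg_post_dims:
            for j in self.nonneg_post_dims:
                out[:, j] = np.maximum(out[:, j], 0.0)
        return out

    def sample_joint(self, n: int,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Draw ``n`` joint (pre, post) rows from the fitted mixture."""
        check_is_fitted(self, "weights_")
        rng = np.random.default_rng(rng)
        comps = rng.choice(len(self.weights_), size=n, p=self.weights_)
        out = np.empty((n, 2 * self.pre_dim_))
        for k in np.unique(comps):
            idx = comps == k
            out[idx] = rng.multivariate_normal(self.means_[k],
                                               self.covariances_[k],
                                               size=int(idx.sum()))
        return out


def recover_noise_law(model: MixtureTransform, grid, n_per: int = 2000,
                      rng: Optional[np.random.Generator] = None,
                      reference: Optional[np.ndarray] = None):
    """Estimate the graded-noise law sd(pre) = slope*pre + intercept.

    For each coordinate, the conditional sd of the post coordinate is
    estimated from ``n_per`` samples at each grid value (the other pre
    coordinates held at ``reference``, default the mixture mean), and a
    straight line is fit to sd versus pre value.

    Returns a list of (slope, intercept, se_slope) per coordinate.
    """
    check_is_fitted(model, "weights_")
    rng = np.random.default_rng(rng)
    d = model.pre_dim_
    grid = np.asarray(grid, dtype=float)
    if reference is None:
        reference = (model.weights_ @ model.means_)[:d]
    laws = []
    for i in range(d):
        sds = []
        for value in grid:
            pre = np.array(reference, dtype=float)
            pre[i] = value
            draws = model.conditional_sample(pre, n_per, rng)
            sds.append(np.std(draws[:, i], ddof=1))
        sds = np.asarray(sds)
        A = np.vstack([grid, np.ones_like(grid)]).T
        (slope, intercept), res, *_ = np.linalg.lstsq(A, sds, rcond=None)
        dof = max(len(grid) - 2, 1)
        s2 = (res[0] / dof) if len(res) else float(
            np.sum((sds - A @ [slope, intercept]) ** 2) / dof)
        se_slope = float(np.sqrt(s2 / np.sum((grid - grid.mean()) ** 2)))
        laws.append((float(slope), float(intercept), se_slope))
    return laws
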