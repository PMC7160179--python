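"""Multi-optima Ornstein-Uhlenbeck allometric regression likelihood.

The response (log dominant frequency) follows an OU process with a single
global selection strength alpha and diffusion variance sigma2, but with
regime-specific optima.  The optimum of regime k is itself a linear function
of log body size, theta_k + beta_k * x, so both intercepts and allometric
slopes may shift between regimes; they enter the tip expectation through the
same Hansen exponential weights.  Calling-site dummy and size-by-site
interaction coefficients (model forms "b" and "c") are global, non-shifting
effects.  The root state is fixed at the root-regime optimum, which yields a
proper Brownian-motion limit as alpha -> 0.

Tip expectation:  E[y_i] = sum_k W_ik (theta_k + beta_k x_i)
                           + d_i' beta_site + (x_i d_i)' beta_inter
Tip covariance:   V_ij = sigma2/(2 alpha) e^{-alpha(T_i+T_j-2 s_ij)}
                         (1 - e^{-2 alpha s_ij}),  plus ME variance on the
diagonal, where s_ij is the depth of the most recent common ancestor.  The
analytic BM limit sigma2 * s_ij is used below ALPHA_BM_THRESHOLD.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg

from .regimes import RegimePainting, ShiftConfig, paint
from .traits import TraitTable
from .tree import Phylogeny

ALPHA_BM_THRESHOLD = 1e-8

MODEL_FORMS = ("a", "b", "c")  # a: size; b: + site; c: + site + size:site


class LikelihoodError(ValueError):
    pass


@dataclasses.dataclass
class RegimeParams:
    """Parameters of the multi-optima OU regression.

    ``theta`` and ``beta_size`` have one entry per regime (root regime
    first); ``alpha`` (per time unit) and ``sigma2`` (trait^2 per time unit)
    are global, as are the optional site and interaction coefficients
    (ordered aquatic, arboreal; terrestrial is the reference).
    """

    theta: np.ndarray
    beta_size: np.ndarray
    alpha: float
    sigma2: float
    beta_site: np.ndarray | None = None
    beta_inter: np.ndarray | None = None

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.beta_size = np.atleast_1d(np.asarray(self.beta_size, dtype=float))
        if self.theta.shape != self.beta_size.shape:
            raise LikelihoodError("theta and beta_size must have equal length (K+1)")
        if self.alpha < 0:
            raise LikelihoodError("alpha must be >= 0")
        if self.sigma2 <= 0:
            raise LikelihoodError("sigma2 must be > 0")
        for name in ("beta_site", "beta_inter"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.atleast_1d(np.asarray(v, dtype=float)))

    @property
    def n_regimes(self) -> int:
        return self.theta.shape[0]

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "beta_size": self.beta_size.tolist(),
            "alpha": self.alpha,
            "sigma2": self.sigma2,
            "beta_site": None if self.beta_site is None else self.beta_site.tolist(),
            "beta_inter": None if self.beta_inter is None else self.beta_inter.tolist(),
        }


def validate_form(form: str) -> str:
    if form not in MODEL_FORMS:
        raise LikelihoodError(f"model form must be one of {MODEL_FORMS}, got {form!r}")
    return form


def hansen_weights(tree: Phylogeny, painting: RegimePainting, alpha: float) -> np.ndarray:
    """Hansen regime weight matrix W (n_tips x n_regimes); rows sum to 1.

    For tip i with depth T_i, a lineage segment of regime k spanning
    [t0, t1] contributes e^{-alpha (T_i - t1)} - e^{-alpha (T_i - t0)}; the
    residual weight e^{-alpha T_i} (the pull of the fixed root state) goes to
    the root regime.  At alpha ~ 0 all weight sits on the root regime.
    """
    if alpha < 0:
        raise LikelihoodError("alpha must be >= 0")
    n = tree.n_tips
    W = np.zeros((n, painting.n_regimes))
    if alpha < ALPHA_BM_THRESHOLD:
        W[:, 0] = 1.0
        return W
    for i, segs in enumerate(painting.segments):
        T = tree.tip_depths[i]
        for (r, t0, t1) in segs:
            W[i, r] += np.exp(-alpha * (T - t1)) - np.exp(-alpha * (T - t0))
        W[i, 0] += np.exp(-alpha * T)
    return W


def fast_hansen_weights(tip_depths: np.ndarray, shift_masks: np.ndarray,
                        shift_times: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized Hansen weights from per-shift tip masks and shift times.

    ``shift_masks`` is (K, n_tips) boolean (tip descends from the shift
    branch); ``shift_times`` the absolute shift times in canonical shift
    order (column k+1 of the result is the regime created by shift k).
    Must agree with :func:`hansen_weights`; the painting-based version is the
    reference implementation, this one is the sampler's hot path.
    """
    n = tip_depths.shape[0]
    K = shift_times.shape[0]
    if K == 0:
        return np.ones((n, 1))
    W = np.zeros((n, K + 1))
    if alpha < ALPHA_BM_THRESHOLD:
        W[:, 0] = 1.0
        return W
    if K == 1:
        m = shift_masks[0]
        W[m, 1] = 1.0 - np.exp(-alpha * (tip_depths[m] - shift_times[0]))
        W[:, 0] = 1.0 - W[:, 1]
        return W
    T = tip_depths[:, None]
    M = np.where(shift_masks.T, shift_times[None, :], np.inf)  # (n, K)
    order = np.argsort(M, axis=1)
    Ms = np.take_along_axis(M, order, axis=1)
    finite = np.isfinite(Ms)
    m = finite.sum(axis=1)
    E = np.where(finite, np.exp(-alpha * (T - np.where(finite, Ms, T))), 0.0)
    E_next = np.zeros_like(E)
    E_next[:, :-1] = E[:, 1:]
    rows = np.flatnonzero(m > 0)
    E_next[rows, m[rows] - 1] = 1.0
    w_sorted = np.where(finite, E_next - E, 0.0)
    Wk = np.zeros((n, K))
    np.put_along_axis(Wk, order, w_sorted, axis=1)
    W[:, 1:] = Wk
    W[:, 0] = np.where(m > 0, E[:, 0], 1.0)
    return W


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float,
                  me: np.ndarray | None = None) -> np.ndarray:
    """OU tip covariance with measurement-error variance on the diagonal."""
    if sigma2 <= 0:
        raise LikelihoodError("sigma2 must be > 0")
    S = tree.shared_depths()
    T = tree.tip_depths
    if alpha < ALPHA_BM_THRESHOLD:
        V = sigma2 * S.copy()
    else:
        V = (sigma2 / (2.0 * alpha)
             * np.exp(-alpha * (T[:, None] + T[None, :] - 2.0 * S))
             * (1.0 - np.exp(-2.0 * alpha * S)))
    if me is not None:
        V = V + np.diag(np.asarray(me, dtype=float))
    return V


def model_mean(W: np.ndarray, params: RegimeParams, log_size: np.ndarray,
               dummies: np.ndarray, form: str) -> np.ndarray:
    """Tip expectations under the given model form."""
    validate_form(form)
    mu = W @ params.theta + (W @ params.beta_size) * log_size
    if form in ("b", "c"):
        if params.beta_site is None:
            raise LikelihoodError(f"model {form!r} requires beta_site")
        mu = mu + dummies @ params.beta_site
    if form == "c":
        if params.beta_inter is None:
            raise LikelihoodError("model 'c' requires beta_inter")
        mu = mu + (log_size[:, None] * dummies) @ params.beta_inter
    return mu


def mvn_loglik(y: np.ndarray, mean: np.ndarray, V: np.ndarray) -> float:
    """Multivariate-normal log density via a dense triangular factorization."""
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        smallest = float(np.linalg.eigvalsh(V)[0])
        raise LikelihoodError(
            f"covariance not positive definite (smallest eigenvalue {smallest:.3e})"
        ) from exc
    r = y - mean
    quad = float(r @ linalg.cho_solve(cho, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    n = y.shape[0]
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def loglik(tree: Phylogeny, table: TraitTable, form: str,
           config: ShiftConfig, params: RegimeParams) -> float:
    """Exact log-likelihood (nats) of the trait table under the model."""
    validate_form(form)
    if params.n_regimes != config.k + 1:
        raise LikelihoodError(
            f"params have {params.n_regimes} regimes but config defines {config.k + 1}"
        )
    painting = paint(tree, config)
    W = hansen_weights(tree, painting, params.alpha)
    V = ou_covariance(tree, params.alpha, params.sigma2, table.me_filled())
    mu = model_mean(W, params, table.log_size, table.site_dummies(), form)
    return mvn_loglik(table.log_df, mu, V)
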