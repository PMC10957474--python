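"""Conjugate Bayesian multivariate regression on alr-transformed proportions.

The observation model is a logistic-normal regression: with eta the
(D-1) x N matrix of alr-transformed relative abundances and X the Q x N
design matrix,

    eta_j ~ N(Lambda X_j, Sigma)
    Lambda ~ MatrixNormal(Theta, Sigma, Gamma)
    Sigma ~ InverseWishart(Xi, nu)

Because eta is observed directly (the proportion-only case: abundances are
zero-replaced and alr-transformed deterministically, with no count layer),
the posterior is available in closed form as a matrix-normal
inverse-Wishart, and posterior draws of (Lambda, Sigma) are exact — no
MCMC is needed.  Draws can be mapped to clr coordinates, where summaries
are invariant to the alr reference used for fitting.

Default prior: Theta = 0, Gamma = I_Q, nu = D + 2 and Xi = (nu - D) I, so
the prior mean of Sigma is the identity on the alr scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PriorSpec",
    "PosteriorModel",
    "PosteriorDraws",
    "default_prior",
    "fit_conjugate",
    "sample_posterior",
    "draws_to_clr",
    "save_draws",
    "load_draws",
]


def _check_spd(M: np.ndarray, name: str) -> None:
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive-definite") from exc


@dataclass
class PriorSpec:
    """Matrix-normal inverse-Wishart prior for (Lambda, Sigma)."""

    Theta: np.ndarray  # (D-1) x Q prior mean of Lambda
    Gamma: np.ndarray  # Q x Q column (covariate) covariance
    Xi: np.ndarray  # (D-1) x (D-1) inverse-Wishart scale
    nu: float  # inverse-Wishart degrees of freedom

    def validate(self) -> None:
        dm1, q = self.Theta.shape
        if self.Gamma.shape != (q, q):
            raise ValueError("Gamma shape incompatible with Theta")
        if self.Xi.shape != (dm1, dm1):
            raise ValueError("Xi shape incompatible with Theta")
        _check_spd(self.Gamma, "Gamma")
        _check_spd(self.Xi, "Xi")
        if self.nu <= dm1 + 1:
            raise ValueError(f"nu must exceed (D-1)+1 = {dm1 + 1} for a finite prior mean")


def default_prior(D: int, Q: int) -> PriorSpec:
    """Weakly-informative default: Theta=0, Gamma=I, nu=D+2, Xi=(nu-D) I."""
    nu = D + 2
    return PriorSpec(
        Theta=np.zeros((D - 1, Q)),
        Gamma=np.eye(Q),
        Xi=(nu - D) * np.eye(D - 1),
        nu=float(nu),
    )


@dataclass
class PosteriorModel:
    Theta_post: np.ndarray
    Gamma_post: np.ndarray
    Xi_post: np.ndarray
    nu_post: float
    eta: np.ndarray
    term_names: list[str] | None = None

    @property
    def D(self) -> int:
        return self.Theta_post.shape[0] + 1

    @property
    def Q(self) -> int:
        return self.Theta_post.shape[1]


@dataclass
class PosteriorDraws:
    Lambda: np.ndarray  # S x rows x Q
    Sigma: np.ndarray  # S x (D-1) x (D-1)
    system: str  # "alr" or "clr"
    seed: int | None = None
    term_names: list[str] | None = None

    @property
    def S(self) -> int:
        return self.Lambda.shape[0]


def fit_conjugate(eta: np.ndarray, X: np.ndarray, prior: PriorSpec, term_names=None) -> PosteriorModel:
    """Exact conjugate update of the matrix-normal inverse-Wishart prior.

    Gamma_post = (X X' + Gamma^-1)^-1
    Theta_post = (eta X' + Theta Gamma^-1) Gamma_post
    nu_post    = nu + N
    Xi_post    = Xi + R R' + (Theta_post - Theta) Gamma^-1 (Theta_post - Theta)'
                 with R = eta - Theta_post X
    """
    eta = np.asarray(eta, dtype=float)
    X = np.asarray(X, dtype=float)
    if eta.ndim != 2 or X.ndim != 2:
        raise ValueError("eta and X must be 2-D")
    if eta.shape[1] != X.shape[1]:
        raise ValueError(f"eta has {eta.shape[1]} samples but X has {X.shape[1]}")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta contains non-finite values")
    prior.validate()
    if prior.Theta.shape != (eta.shape[0], X.shape[0]):
        raise ValueError("prior Theta shape must be (D-1) x Q")

    N = X.shape[1]
    Gamma_inv = np.linalg.inv(prior.Gamma)
    Gamma_post = np.linalg.inv(X @ X.T + Gamma_inv)
    Gamma_post = (Gamma_post + Gamma_post.T) / 2
    Theta_post = (eta @ X.T + prior.Theta @ Gamma_inv) @ Gamma_post
    R = eta - Theta_post @ X
    Dth = Theta_post - prior.Theta
    Xi_post = prior.Xi + R @ R.T + Dth @ Gamma_inv @ Dth.T
    Xi_post = (Xi_post + Xi_post.T) / 2
    return PosteriorModel(
        Theta_post=Theta_post,
        Gamma_post=Gamma_post,
        Xi_post=Xi_post,
        nu_post=prior.nu + N,
        eta=eta,
        term_names=list(term_names) if term_names is not None else None,
    )


def sample_posterior(post: PosteriorModel, S: int = 2000, seed: int | None = None) -> PosteriorDraws:
    """Exact posterior draws of (Sigma, Lambda | Sigma).

    Sigma ~ InverseWishart(Xi_post, nu_post); Lambda | Sigma ~
    MatrixNormal(Theta_post, Sigma, Gamma_post) via A Z B' with A, B the
    Cholesky factors of Sigma and Gamma_post.  Reproducible for fixed seed.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    dm1 = post.Theta_post.shape[0]
    if post.nu_post <= dm1 - 1:
        raise ValueError("nu_post too small for the inverse-Wishart dimension")
    rng = np.random.default_rng(seed)
    Sigma = stats.invwishart.rvs(df=post.nu_post, scale=post.Xi_post, size=S, random_state=rng)
    Sigma = np.asarray(Sigma).reshape(S, dm1, dm1)
    B = np.linalg.cholesky(post.Gamma_post)
    A = np.linalg.cholesky(Sigma)  # batched
    Z = rng.standard_normal((S, dm1, post.Q))
    Lambda = post.Theta_post[None] + A @ Z @ B.T
    return PosteriorDraws(Lambda=Lambda, Sigma=Sigma, system="alr", seed=seed, term_names=post.term_names)


def draws_to_clr(draws: PosteriorDraws, ref: int = -1) -> PosteriorDraws:
    """Re-express coefficient draws in clr coordinates (zero column sums)."""
    if draws.system == "clr":
        return draws
    S, dm1, Q = draws.Lambda.shape
    D = dm1 + 1
    ref = ref % D
    full = np.insert(draws.Lambda, ref, 0.0, axis=1)
    full = full - full.mean(axis=1, keepdims=True)
    return PosteriorDraws(Lambda=full, Sigma=draws.Sigma, system="clr", seed=draws.seed, term_names=draws.term_names)


def save_draws(draws: PosteriorDraws, prefix) -> None:
    """Persist draws as an .npz archive plus a JSON manifest."""
    np.savez_compressed(f"{prefix}.npz", Lambda=draws.Lambda, Sigma=draws.Sigma)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(
            {"system": draws.system, "seed": draws.seed, "term_names": draws.term_names, "S": draws.S},
            fh,
            indent=1,
        )


def load_draws(prefix) -> PosteriorDraws:
    arr = np.load(f"{prefix}.npz")
    with open(f"{prefix}.json") as fh:
        man = json.load(fh)
    return PosteriorDraws(
        Lambda=arr["Lambda"],
        Sigma=arr["Sigma"],
        system=man["system"],
        seed=man["seed"],
        term_names=man["term_names"],
    )
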