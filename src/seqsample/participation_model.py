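"""Bayesian logistic models for participation probabilities.

The participation probability of an invited individual is
``p(s=1 | b=1, z) = invlogit(alpha + f(z, beta))``.  Three linear-predictor
maps are supported:

``intercept_only``
    invlogit(alpha): a single shared participation probability (the
    deliberately misspecified robustness variant).
``linear``
    invlogit(alpha + z' beta).
``group``
    invlogit(beta_g) for the individual's group g -- per-group coefficients
    and no shared intercept.

Coefficients carry independent normal priors (default mean 0, variance 100,
i.e. effectively flat).  The posterior over (alpha, beta) given the records
of all responded invitees is approximated by a Laplace fit (posterior mode
plus inverse curvature); an MCMC backend (emcee) is available as a
cross-check.  The participation-probability estimate phi_hat is the
posterior-predictive mean of invlogit(eta), computed by one-dimensional
Gauss--Hermite quadrature over the (normal) linear predictor; a plug-in
variant evaluates invlogit at the posterior mode instead.

With zero responders the posterior equals the prior, and by symmetry of the
predictive integral phi_hat = 0.5 for every individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .population_io import Population

__all__ = [
    "ParticipationModel",
    "FixedParticipationModel",
    "Responders",
    "participation_probability",
    "fit_posterior",
    "predict_phi",
]

_PHI_EPS = 1e-12


def participation_probability(z, alpha: float, beta=None) -> np.ndarray | float:
    """invlogit(alpha + z' beta); strictly inside (0, 1)."""
    z = np.asarray(z, dtype=float)
    eta = alpha if beta is None else alpha + z @ np.asarray(beta, dtype=float)
    return np.clip(expit(eta), _PHI_EPS, 1.0 - _PHI_EPS)


@dataclass
class Responders:
    """Records (s, z-row) of invited individuals whose response is observed."""

    X: np.ndarray  # (m_i, p) design rows
    s: np.ndarray  # (m_i,) participation indicators

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.s = np.asarray(self.s, dtype=float)
        if self.s.ndim != 1 or self.X.shape[0] != self.s.shape[0]:
            raise ValueError("design rows and outcomes must align")
        if not np.isin(self.s, (0.0, 1.0)).all():
            raise ValueError("participation indicators must be 0/1")

    @property
    def count(self) -> int:
        return int(self.s.shape[0])


class ParticipationModel:
    """Laplace-approximated Bayesian logistic participation model.

    Parameters
    ----------
    kind : {"intercept_only", "linear", "group"}
        Linear-predictor map (see module docstring).
    d_z : int
        Number of covariates (``linear`` kind).
    n_groups : int
        Number of group levels (``group`` kind).
    prior_mean, prior_var : float or array
        Independent normal prior per coefficient.
    backend : {"laplace", "mcmc"}
        Posterior approximation. MCMC (emcee) is a slow cross-check backend.
    quadrature_nodes : int
        Gauss--Hermite nodes for the posterior-predictive integral.
    phi_method : {"predictive", "plugin"}
        Default phi_hat flavor.
    """

    def __init__(
        self,
        kind: str = "linear",
        d_z: int | None = None,
        n_groups: int | None = None,
        prior_mean: float | np.ndarray = 0.0,
        prior_var: float | np.ndarray = 100.0,
        backend: str = "laplace",
        quadrature_nodes: int = 40,
        phi_method: str = "predictive",
    ):
        if kind not in {"intercept_only", "linear", "group"}:
            raise ValueError(f"unknown model kind {kind!r}")
        if kind == "linear" and not d_z:
            raise ValueError("linear model needs d_z")
        if kind == "group" and not n_groups:
            raise ValueError("group model needs n_groups")
        if backend not in {"laplace", "mcmc"}:
            raise ValueError(f"unknown backend {backend!r}")
        if phi_method not in {"predictive", "plugin"}:
            raise ValueError(f"unknown phi method {phi_method!r}")
        self.kind = kind
        self.d_z = d_z or 0
        self.n_groups = n_groups or 0
        self.p = {"intercept_only": 1, "linear": 1 + self.d_z, "group": self.n_groups}[kind]
        self.prior_mean = np.broadcast_to(np.asarray(prior_mean, float), (self.p,)).copy()
        self.prior_var = np.broadcast_to(np.asarray(prior_var, float), (self.p,)).copy()
        if (self.prior_var <= 0).any():
            raise ValueError("prior variances must be positive")
        self.backend = backend
        self.phi_method = phi_method
        nodes, weights = np.polynomial.hermite.hermgauss(quadrature_nodes)
        self._gh_nodes = nodes * np.sqrt(2.0)
        self._gh_weights = weights / np.sqrt(np.pi)
        # posterior starts at the prior
        self.post_mean = self.prior_mean.copy()
        self.post_cov = np.diag(self.prior_var)
        self.n_responders = 0
        self.version = 0  # bumped on every refit (phi_hat cache invalidation)
        self._mcmc_draws: np.ndarray | None = None

    # -- design -------------------------------------------------------------
    def design_matrix(self, pop: Population) -> np.ndarray:
        """Per-individual design rows mapping coefficients to linear predictors."""
        n = pop.n
        if self.kind == "intercept_only":
            return np.ones((n, 1))
        if self.kind == "linear":
            if pop.z is None or pop.d_z != self.d_z:
                raise ValueError("population z does not match model dimension")
            return np.column_stack([np.ones(n), pop.z])
        if pop.group is None:
            raise ValueError("group model needs group labels")
        X = np.zeros((n, self.n_groups))
        X[np.arange(n), pop.group - 1] = 1.0
        return X

    # -- posterior fit --------------------------------------------------------
    def fit(self, responders: Responders) -> "ParticipationModel":
        """Update the posterior approximation from responder records (in place)."""
        if responders.count == 0:
            self.post_mean = self.prior_mean.copy()
            self.post_cov = np.diag(self.prior_var)
            self.n_responders = 0
            self.version += 1
            return self
        if responders.X.shape[1] != self.p:
            raise ValueError("responder design width does not match model")
        if self.kind in ("intercept_only", "group"):
            # one-hot designs: the posterior factorizes over coefficients and
            # depends on the data only through per-cell (trials, successes)
            trials = responders.X.sum(axis=0)
            succ = responders.X.T @ responders.s
            theta, cov = self._laplace_diag(trials, succ)
        else:
            theta, cov = self._laplace(responders.X, responders.s)
        self.post_mean, self.post_cov = theta, cov
        self.n_responders = responders.count
        self.version += 1
        if self.backend == "mcmc":
            self._mcmc_draws = self._run_mcmc(responders.X, responders.s)
        return self

    def _laplace_diag(self, trials, succ, tol: float = 1e-10, max_iter: int = 200):
        """Coordinate-wise Laplace fit for one-hot designs (exact factorization)."""
        prior_prec = 1.0 / self.prior_var
        theta = self.post_mean.copy()
        for _ in range(max_iter):
            p = expit(theta)
            grad = trials * p - succ + (theta - self.prior_mean) * prior_prec
            if np.max(np.abs(grad)) < tol * max(1.0, trials.sum()):
                break
            h = trials * p * (1.0 - p) + prior_prec
            # damp steps: Newton on the flat logistic tails can overshoot
            theta -= np.clip(grad / h, -4.0, 4.0)
        p = expit(theta)
        h = trials * p * (1.0 - p) + prior_prec
        return theta, np.diag(1.0 / h)

    def _neg_log_post(self, theta, X, s):
        eta = X @ theta
        # softplus, stable
        ll = np.sum(np.logaddexp(0.0, eta) - s * eta)
        dev = theta - self.prior_mean
        return ll + 0.5 * np.sum(dev * dev / self.prior_var)

    def _laplace(self, X, s, tol: float = 1e-6, max_iter: int = 100):
        # tol is per observation: a gradient below tol*m moves the mode by
        # O(tol) and phi_hat by far less, ample for invitation decisions
        prior_prec = 1.0 / self.prior_var
        gtol = tol * max(1.0, len(s))
        theta = self.post_mean.copy()  # warm start from the previous refit
        f = self._neg_log_post(theta, X, s)
        for _ in range(max_iter):
            p = expit(X @ theta)
            grad = X.T @ (p - s) + (theta - self.prior_mean) * prior_prec
            if np.max(np.abs(grad)) < gtol:
                break
            W = p * (1.0 - p)
            H = (X * W[:, None]).T @ X
            H[np.diag_indices_from(H)] += prior_prec
            step = np.linalg.solve(H, grad)
            # Newton decrement: stop once the attainable decrease is below
            # float resolution of the objective
            if 0.5 * float(grad @ step) < 1e-13 * (1.0 + abs(f)):
                break
            # backtracking keeps the Newton iteration globally convergent
            t = 1.0
            for _ in range(30):
                cand = theta - t * step
                f_cand = self._neg_log_post(cand, X, s)
                if f_cand <= f:
                    theta, f = cand, f_cand
                    break
                t *= 0.5
            else:  # objective no longer representably decreasable
                break
        p = expit(X @ theta)
        grad = X.T @ (p - s) + (theta - self.prior_mean) * prior_prec
        if np.max(np.abs(grad)) > 100.0 * gtol:
            raise RuntimeError(
                f"Laplace fit did not converge: |grad|={np.max(np.abs(grad)):.2e}, "
                f"m={len(s)}, p={self.p}"
            )
        W = p * (1.0 - p)
        H = (X * W[:, None]).T @ X
        H[np.diag_indices_from(H)] += prior_prec
        cov = np.linalg.inv(H)
        return theta, 0.5 * (cov + cov.T)

    def _run_mcmc(self, X, s, n_walkers=None, n_steps=1500, burn=500, seed=0):
        import emcee

        n_walkers = n_walkers or max(2 * self.p + 2, 8)
        rng = np.random.default_rng(seed)
        start = self.post_mean + rng.standard_normal((n_walkers, self.p)) @ np.linalg.cholesky(
            self.post_cov + 1e-12 * np.eye(self.p)
        ).T * 0.5
        sampler = emcee.EnsembleSampler(
            n_walkers, self.p, lambda th: -self._neg_log_post(th, X, s)
        )
        sampler.random_state = np.random.RandomState(seed).get_state()
        sampler.run_mcmc(start, n_steps, progress=False)
        return sampler.get_chain(discard=burn, flat=True)

    # -- prediction -----------------------------------------------------------
    def phi_from_design(self, X: np.ndarray, method: str | None = None) -> np.ndarray:
        """phi_hat for arbitrary design rows under the current posterior."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        method = method or self.phi_method
        if self.backend == "mcmc" and self._mcmc_draws is not None and method == "predictive":
            phi = expit(X @ self._mcmc_draws.T).mean(axis=1)
            return np.clip(phi, _PHI_EPS, 1.0 - _PHI_EPS)
        mu = X @ self.post_mean
        if method == "plugin":
            return np.clip(expit(mu), _PHI_EPS, 1.0 - _PHI_EPS)
        var = ((X @ self.post_cov) * X).sum(axis=1)
        sd = np.sqrt(np.maximum(var, 0.0))
        eta = mu[:, None] + sd[:, None] * self._gh_nodes[None, :]
        phi = expit(eta) @ self._gh_weights
        return np.clip(phi, _PHI_EPS, 1.0 - _PHI_EPS)

    def predict_phi(self, pop: Population, method: str | None = None) -> np.ndarray:
        """Posterior-predictive (or plug-in) participation probability per individual."""
        return self.phi_from_design(self.design_matrix(pop), method=method)


class FixedParticipationModel:
    """Known participation probabilities: no fitting, phi_hat == phi.

    Used when the willingness to participate is known a priori, and as the
    reference model in exactness/reduction experiments.
    """

    def __init__(self, phi: float | np.ndarray):
        self.phi = np.asarray(phi, dtype=float)
        if ((self.phi <= 0) | (self.phi > 1)).any():
            raise ValueError("phi must lie in (0, 1]")
        self.n_responders = 0
        self.version = 0

    def design_matrix(self, pop: Population) -> np.ndarray:
        phi = np.broadcast_to(self.phi, (pop.n,))
        return phi[:, None]

    def fit(self, responders: Responders) -> "FixedParticipationModel":
        return self

    def phi_from_design(self, X: np.ndarray, method: str | None = None) -> np.ndarray:
        return np.asarray(X)[:, 0]

    def predict_phi(self, pop: Population, method: str | None = None) -> np.ndarray:
        return np.broadcast_to(self.phi, (pop.n,)).copy()


# -- functional convenience surface --------------------------------------------


def fit_posterior(model: ParticipationModel, responders: Responders) -> ParticipationModel:
    """Refit the posterior on responder records; returns the updated model."""
    return model.fit(responders)


def predict_phi(model, pop: Population, method: str | None = None) -> np.ndarray:
    """phi_hat for every individual in the population."""
    return model.predict_phi(pop, method=method)
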