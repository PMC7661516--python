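"""Small adaptive MCMC building blocks shared by the hierarchical models.

Two proposal families cover everything the package fits:

* :class:`AdaptiveMVN` — Haario-style adaptive random-walk Metropolis for a
  low-dimensional parameter block (fixed effects, hyperparameters, whitened
  latent states).  The proposal covariance tracks the running empirical
  covariance of the chain and a global scale is tuned by Robbins–Monro
  toward a target acceptance rate.
* preconditioned Crank–Nicolson (:func:`pcn_propose`) — for a latent
  Gaussian field with known prior covariance; the acceptance ratio then
  involves only the likelihood, which keeps field updates cheap and exact.

All samplers draw exclusively from an explicit ``numpy`` Generator, so runs
are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np


class AdaptiveMVN:
    """Adaptive multivariate normal random-walk proposal.

    Starts from an isotropic proposal and, after ``adapt_start`` updates,
    mixes in the running empirical covariance of the visited states
    (2.38^2/d scaling).  A log-scale factor is adapted toward
    ``target_accept`` with a decaying Robbins–Monro step, frozen after
    warmup so the post-warmup chain is a valid Markov chain.
    """

    def __init__(self, dim: int, init_scale: float = 0.1,
                 target_accept: float | None = None, adapt_start: int = 100):
        self.dim = dim
        self.log_scale = np.log(init_scale)
        self.target = target_accept if target_accept is not None else \
            (0.44 if dim == 1 else 0.234)
        self.adapt_start = adapt_start
        self._n = 0
        self._mean = np.zeros(dim)
        self._m2 = np.eye(dim) * 1e-6
        self._chol = np.eye(dim)
        self.frozen = False

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        step = self._chol @ rng.standard_normal(self.dim)
        return x + np.exp(self.log_scale) * step

    def update(self, x: np.ndarray, accept_prob: float) -> None:
        if self.frozen:
            return
        self._n += 1
        delta = x - self._mean
        self._mean += delta / self._n
        self._m2 += np.outer(delta, x - self._mean)
        if not np.isfinite(accept_prob):
            accept_prob = 0.0
        gamma = min(0.5, 5.0 / max(self._n, 1))
        self.log_scale += gamma * (min(accept_prob, 1.0) - self.target)
        if self._n >= self.adapt_start and self._n % 50 == 0:
            cov = self._m2 / max(self._n - 1, 1)
            cov = (2.38 ** 2 / self.dim) * cov + 1e-9 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def freeze(self) -> None:
        self.frozen = True


class AdaptiveScalar(AdaptiveMVN):
    """Scalar adaptive random-walk proposal (0.44 target acceptance)."""

    def __init__(self, init_scale: float = 0.2):
        super().__init__(1, init_scale=init_scale, target_accept=0.44)

    def propose_scalar(self, x: float, rng: np.random.Generator) -> float:
        return float(x + np.exp(self.log_scale) * self._chol[0, 0]
                     * rng.standard_normal())

    def update_scalar(self, x: float, accept_prob: float) -> None:
        self.update(np.array([x]), accept_prob)


def metropolis_accept(log_ratio: float, rng: np.random.Generator) -> bool:
    if log_ratio >= 0:
        return True
    return np.log(rng.random()) < log_ratio


def pcn_propose(w: np.ndarray, chol: np.ndarray, beta: float,
                rng: np.random.Generator) -> np.ndarray:
    """Preconditioned Crank–Nicolson proposal for a centred Gaussian prior.

    ``w' = sqrt(1 - beta^2) w + beta L xi`` with ``xi ~ N(0, I)`` and
    ``L L' = prior covariance``; the prior cancels in the acceptance ratio.
    """
    xi = chol @ rng.standard_normal(len(w))
    return np.sqrt(1.0 - beta ** 2) * w + beta * xi


class RmScale:
    """Robbins–Monro tuned step size for vectorised coordinate updates."""

    def __init__(self, scale: float = 0.3, target: float = 0.44):
        self.scale = scale
        self.target = target
        self._n = 0
        self.frozen = False

    def update(self, accept_prob: float) -> None:
        if self.frozen:
            return
        self._n += 1
        gamma = min(0.5, 5.0 / self._n)
        self.scale = float(np.clip(
            np.exp(np.log(self.scale)
                   + gamma * (min(accept_prob, 1.0) - self.target)),
            1e-5, 50.0))

    def freeze(self) -> None:
        self.frozen = True


class PcnScale:
    """Robbins–Monro adaptation of the pCN step size toward 25% acceptance."""

    def __init__(self, beta: float = 0.2, target: float = 0.25):
        self.beta = beta
        self.target = target
        self._n = 0
        self.frozen = False

    def update(self, accept_prob: float) -> None:
        if self.frozen:
            return
        self._n += 1
        gamma = min(0.5, 5.0 / self._n)
        log_b = np.log(self.beta) + gamma * (min(accept_prob, 1.0) - self.target)
        self.beta = float(np.clip(np.exp(log_b), 1e-4, 0.999))


def run_adaptive_metropolis(logpost, x0: np.ndarray, n_warmup: int,
                            n_samples: int, rng: np.random.Generator,
                            thin: int = 1, init_scale: float = 0.1):
    """Generic adaptive Metropolis chain over a flat parameter vector.

    Returns ``(draws, logposts, accept_rate)`` where ``draws`` has shape
    ``(n_samples // thin, dim)``.  Adaptation stops at the end of warmup.
    """
    x = np.asarray(x0, dtype=float).copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the initial state")
    prop = AdaptiveMVN(len(x), init_scale=init_scale)
    kept = []
    kept_lp = []
    accepts = 0
    total = n_warmup + n_samples
    for it in range(total):
        if it == n_warmup:
            prop.freeze()
        x_new = prop.propose(x, rng)
        lp_new = logpost(x_new)
        log_ratio = lp_new - lp
        a = float(np.exp(min(log_ratio, 0.0))) if np.isfinite(log_ratio) else 0.0
        if np.isfinite(lp_new) and metropolis_accept(log_ratio, rng):
            x, lp = x_new, lp_new
            if it >= n_warmup:
                accepts += 1
        prop.update(x, a)
        if it >= n_warmup and (it - n_warmup) % thin == 0:
            kept.append(x.copy())
            kept_lp.append(lp)
    rate = accepts / max(n_samples, 1)
    return np.asarray(kept), np.asarray(kept_lp), rate


def summarise_draws(draws: np.ndarray, names: list[str]) -> "pd.DataFrame":
    """Posterior summary table: mean, sd and central 95% interval."""
    import pandas as pd

    draws = np.atleast_2d(draws)
    q = np.quantile(draws, [0.025, 0.975], axis=0)
    return pd.DataFrame({
        "term": names,
        "mean": draws.mean(axis=0),
        "sd": draws.std(axis=0, ddof=1),
        "q2.5": q[0],
        "q97.5": q[1],
    })
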