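"""Adaptive random-walk building blocks for the package's Gibbs samplers.

Both hierarchical fits in this package (the LBA and the ordered-beta rating
model) use blocked Metropolis-within-Gibbs: conditionally independent
parameter blocks are updated in parallel with Gaussian random-walk
proposals whose per-block scales adapt during warmup (Robbins-Monro on the
acceptance rate, proposal shape from running moments), while conjugate
blocks are drawn exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AdaptiveBlock", "metropolis_accept"]


class AdaptiveBlock:
    """Adaptive random-walk proposal for ``n`` parallel blocks of ``dim``
    coordinates.

    During warmup the per-block proposal scale follows Robbins-Monro
    adaptation toward a target acceptance rate, and the proposal shape
    tracks the running posterior spread (Welford): per-coordinate standard
    deviations by default, or the full per-block covariance Cholesky when
    ``full_cov=True`` (worthwhile for small, strongly correlated blocks).
    After ``freeze()`` the proposal is fixed, keeping the chain Markovian
    during sampling.
    """

    def __init__(self, n: int, dim: int, init_scale: float = 0.1,
                 target_accept: float = 0.35, full_cov: bool = False):
        self.n = n
        self.dim = dim
        self.log_scale = np.full(n, np.log(init_scale))
        self.target = target_accept
        self.full_cov = full_cov and dim > 1
        self._count = 0
        self._mean = np.zeros((n, dim))
        self._m2 = (
            np.zeros((n, dim, dim)) if self.full_cov else np.zeros((n, dim))
        )
        self._frozen = False
        self._sd = np.ones((n, dim))
        self._chol = np.broadcast_to(np.eye(dim), (n, dim, dim)).copy()
        self.n_proposed = 0
        self.n_accepted = 0

    def track(self, accepted: np.ndarray) -> None:
        """Record acceptance statistics (warmup and sampling alike)."""
        accepted = np.asarray(accepted)
        self.n_proposed += accepted.size
        self.n_accepted += int(accepted.sum())

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else float("nan")

    def observe(self, x: np.ndarray) -> None:
        """Update running moments with the current state (warmup only)."""
        if self._frozen:
            return
        self._count += 1
        delta = x - self._mean
        self._mean += delta / self._count
        if self.full_cov:
            self._m2 += np.einsum("ni,nj->nij", delta, x - self._mean)
            if self._count > 2 * self.dim + 5:
                cov = self._m2 / (self._count - 1)
                jitter = 1e-10 + 1e-6 * np.einsum("nii->n", cov) / self.dim
                cov = cov + jitter[:, None, None] * np.eye(self.dim)
                try:
                    self._chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        else:
            self._m2 += delta * (x - self._mean)
            if self._count > 10:
                var = self._m2 / (self._count - 1)
                self._sd = np.sqrt(np.clip(var, 1e-12, None))

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(x.shape)
        if self.full_cov:
            step = np.einsum("nij,nj->ni", self._chol, z)
        else:
            step = z * self._sd
        return x + np.exp(self.log_scale)[:, None] * step

    def adapt(self, accepted: np.ndarray) -> None:
        """Robbins-Monro step on the per-block log proposal scale."""
        if self._frozen:
            return
        self._adapt_t = getattr(self, "_adapt_t", 0) + 1
        gamma = 1.0 / self._adapt_t**0.6
        self.log_scale += gamma * (accepted.astype(float) - self.target)
        self.log_scale = np.clip(self.log_scale, -10.0, 3.0)

    def reset_moments(self) -> None:
        """Drop accumulated moments (used mid-warmup to discard the
        initial transient from the proposal-spread estimate)."""
        self._count = 0
        self._mean[:] = 0.0
        self._m2[:] = 0.0

    def freeze(self) -> None:
        self._frozen = True


def metropolis_accept(logp_new: np.ndarray, logp_old: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorised Metropolis accept decision; -inf proposals never accept."""
    logp_new = np.asarray(logp_new, dtype=float)
    logp_old = np.asarray(logp_old, dtype=float)
    logr = logp_new - logp_old
    with np.errstate(invalid="ignore"):
        accept = np.log(rng.random(logr.shape)) < logr
    return accept & np.isfinite(logp_new)
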