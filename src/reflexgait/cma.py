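"""Covariance matrix adaptation evolution strategy (CMA-ES).

Standard (mu/mu_w, lambda) CMA-ES with rank-one and rank-mu covariance
updates, cumulative step-size adaptation and log-linear recombination
weights, following the canonical published update rules.  Only lambda, mu
and the initial step size are exposed as tuning knobs; every other constant
takes its standard default.

Candidates are sampled as Y ~ N(m, sigma^2 C).  Non-finite objective values
are ranked worst.  Sampling is driven by an externally supplied generator so
seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CmaState", "CmaEs"]


@dataclass
class CmaState:
    """Search-distribution state of CMA-ES at one generation."""

    cma_mean: np.ndarray
    sigma: float
    C: np.ndarray
    p_sigma: np.ndarray
    p_C: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("C must be symmetric")


class CmaEs:
    """Ask/tell CMA-ES optimizer.

    Parameters
    ----------
    x0 : initial mean.
    sigma0 : initial step size.
    lam : population size per generation.
    mu : number of parents used in recombination.
    bounds : optional (lower, upper) arrays; samples are clipped into the box.
    """

    def __init__(
        self,
        x0: np.ndarray,
        sigma0: float = 0.1,
        lam: int = 20,
        mu: int = 7,
        bounds: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        x0 = np.asarray(x0, dtype=float)
        n = len(x0)
        if sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if not 1 <= mu <= lam:
            raise ValueError("need 1 <= mu <= lambda")
        self.n = n
        self.lam = lam
        self.mu = mu
        self.sigma0 = sigma0
        self.bounds = bounds

        # log-linear recombination weights
        w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
        self.weights = w / w.sum()
        self.mu_eff = 1.0 / np.sum(self.weights**2)

        # standard strategy constants
        self.c_sigma = (self.mu_eff + 2) / (n + self.mu_eff + 5)
        self.d_sigma = (
            1
            + 2 * max(0.0, np.sqrt((self.mu_eff - 1) / (n + 1)) - 1)
            + self.c_sigma
        )
        self.c_c = (4 + self.mu_eff / n) / (n + 4 + 2 * self.mu_eff / n)
        self.c_1 = 2 / ((n + 1.3) ** 2 + self.mu_eff)
        self.c_mu = min(
            1 - self.c_1,
            2 * (self.mu_eff - 2 + 1 / self.mu_eff) / ((n + 2) ** 2 + self.mu_eff),
        )
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

        self.state = CmaState(
            cma_mean=x0.copy(),
            sigma=sigma0,
            C=np.eye(n),
            p_sigma=np.zeros(n),
            p_C=np.zeros(n),
        )
        self._refresh_decomposition()
        self._last_z: np.ndarray | None = None

    # -- internals ---------------------------------------------------------
    def _refresh_decomposition(self) -> None:
        C = (self.state.C + self.state.C.T) / 2.0
        eigvals, eigvecs = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-20)
        self._B = eigvecs
        self._D = np.sqrt(eigvals)
        self.state.C = C

    # -- public API --------------------------------------------------------
    def ask(self, rng: np.random.Generator) -> np.ndarray:
        """Sample lambda candidates from N(m, sigma^2 C); shape (lam, n)."""
        z = rng.standard_normal((self.lam, self.n))
        y = z * self._D @ self._B.T  # y_k = B D z_k
        x = self.state.cma_mean + self.state.sigma * y
        if self.bounds is not None:
            lo, hi = self.bounds
            x = np.clip(x, lo, hi)
            # keep y consistent with clipped x for the updates
            y = (x - self.state.cma_mean) / self.state.sigma
        self._last_y = y
        return x

    def tell(self, candidates: np.ndarray, objectives: np.ndarray) -> CmaState:
        """Rank-mu update of mean, step size, covariance and paths."""
        s = self.state
        f = np.asarray(objectives, dtype=float).copy()
        f[~np.isfinite(f)] = np.inf  # non-finite -> worst rank
        order = np.argsort(f, kind="stable")
        y = (np.asarray(candidates, dtype=float) - s.cma_mean) / s.sigma
        y_sel = y[order[: self.mu]]
        y_w = self.weights @ y_sel

        mean_new = s.cma_mean + s.sigma * y_w

        # step-size path in the isotropic coordinate system
        C_inv_half = self._B @ np.diag(1.0 / self._D) @ self._B.T
        p_sigma = (1 - self.c_sigma) * s.p_sigma + np.sqrt(
            self.c_sigma * (2 - self.c_sigma) * self.mu_eff
        ) * (C_inv_half @ y_w)
        h_sigma = float(
            np.linalg.norm(p_sigma)
            / np.sqrt(1 - (1 - self.c_sigma) ** (2 * (s.generation + 1)))
            < (1.4 + 2 / (self.n + 1)) * self.chi_n
        )
        p_C = (1 - self.c_c) * s.p_C + h_sigma * np.sqrt(
            self.c_c * (2 - self.c_c) * self.mu_eff
        ) * y_w

        rank_one = np.outer(p_C, p_C)
        rank_mu = (y_sel * self.weights[:, None]).T @ y_sel
        delta_h = (1 - h_sigma) * self.c_c * (2 - self.c_c)
        C_new = (
            (1 - self.c_1 - self.c_mu) * s.C
            + self.c_1 * (rank_one + delta_h * s.C)
            + self.c_mu * rank_mu
        )
        sigma_new = s.sigma * np.exp(
            (self.c_sigma / self.d_sigma)
            * (np.linalg.norm(p_sigma) / self.chi_n - 1)
        )

        self.state = CmaState(
            cma_mean=mean_new,
            sigma=float(sigma_new),
            C=C_new,
            p_sigma=p_sigma,
            p_C=p_C,
            generation=s.generation + 1,
        )
        self._refresh_decomposition()
        return self.state

    def reset_for_new_velocity(self, sigma0: float | None = None) -> CmaState:
        """Reset step size to sigma0 and empty both evolution paths.

        The mean and covariance are retained so search continues from the
        previous velocity's optimum neighbourhood.
        """
        s = self.state
        self.state = CmaState(
            cma_mean=s.cma_mean.copy(),
            sigma=self.sigma0 if sigma0 is None else sigma0,
            C=s.C.copy(),
            p_sigma=np.zeros(self.n),
            p_C=np.zeros(self.n),
            generation=s.generation,
        )
        self._refresh_decomposition()
        return self.state
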