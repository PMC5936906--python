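"""Amino-acid substitution models and discrete-gamma rate heterogeneity.

A :class:`SubstitutionModel` bundles a symmetric exchangeability matrix with
equilibrium frequencies into a time-reversible rate matrix Q, normalised so a
branch length of 1 means one expected substitution per site.  Transition
probabilities P(t) = exp(Qt) come from a single symmetric eigendecomposition,
so repeated evaluations (bootstraps, rate grids) are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import AMINO_ACIDS

__all__ = ["SubstitutionModel", "GammaRates", "lg_model", "poisson_model", "discrete_gamma_rates"]

_NORM_TOL = 1e-10


class SubstitutionModel:
    """Time-reversible 20-state model: Q_ij = s_ij * pi_j, mean rate 1.

    Parameters
    ----------
    exchangeabilities : (20, 20) symmetric, non-negative, zero diagonal.
    frequencies : (20,) positive, summing to 1.
    p_inv : proportion of invariable sites in [0, 1); only consulted by
        likelihood code that models an invariant class, not by Q itself.
    """

    def __init__(self, exchangeabilities, frequencies, p_inv: float = 0.0, name: str = "custom"):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (20, 20):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must be positive and sum to 1")
        if not 0.0 <= p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        pi = pi / pi.sum()

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))  # expected substitutions per unit time
        if mu <= 0:
            raise ValueError("degenerate model: zero total substitution rate")
        Q /= mu

        self.name = name
        self.exchangeabilities = S
        self.frequencies = pi
        self.p_inv = float(p_inv)
        self.rate_matrix = Q

        # Symmetrised eigendecomposition: B = D^(1/2) Q D^(-1/2) is symmetric
        # for reversible Q, giving real eigenvalues and a stable P(t).
        sqrt_pi = np.sqrt(pi)
        B = sqrt_pi[:, None] * Q / sqrt_pi[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigenvalues = w
        self._left = U.T * sqrt_pi[None, :]
        self._right = U / sqrt_pi[:, None]

        norm = -np.dot(pi, np.diag(Q))
        if abs(norm - 1.0) > _NORM_TOL:
            raise ValueError(f"rate-matrix normalisation off by {abs(norm - 1.0):.2e}")

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0 or not np.isfinite(t):
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        P = (self._right * np.exp(self._eigenvalues * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def __repr__(self) -> str:
        return f"SubstitutionModel({self.name}, p_inv={self.p_inv})"


def _load_lg():
    text = resources.files("fslb").joinpath("data/lg.tsv").read_text()
    S = np.zeros((20, 20))
    freqs = None
    order = None
    for line in text.strip().splitlines():
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "#aa":
            order = parts[1:]
        elif parts[0] == "#freq":
            freqs = np.array([float(x) for x in parts[1:]])
        else:
            i = order.index(parts[0])
            S[i] = [float(x) for x in parts[1:]]
    perm = [order.index(a) for a in AMINO_ACIDS]
    S = S[np.ix_(perm, perm)]
    freqs = freqs[perm]
    return S, freqs


def lg_model(p_inv: float = 0.0) -> SubstitutionModel:
    """The LG amino-acid model (empirical exchangeabilities + frequencies)."""
    S, freqs = _load_lg()
    return SubstitutionModel(S, freqs, p_inv=p_inv, name="LG")


def poisson_model() -> SubstitutionModel:
    """Equal-frequency, equal-exchangeability 20-state model."""
    S = np.ones((20, 20))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel(S, np.full(20, 0.05), name="Poisson")


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (category means).

    The continuous Gamma(alpha, mean 1) is cut at its C-quantiles and each
    category is represented by its conditional mean, so the category mean
    rate is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    C = n_categories
    if C == 1:
        return np.ones(1)
    cuts = gamma_dist.ppf(np.arange(1, C) / C, a=alpha, scale=1.0 / alpha)
    # E[X ; X <= x] for X ~ Gamma(alpha, rate alpha) is P(alpha+1, alpha*x).
    partial = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * cuts), [1.0]])
    return C * np.diff(partial)


@dataclass(frozen=True)
class GammaRates:
    """Discrete-gamma among-site rate variation: shape alpha, C categories."""

    alpha: float
    n_categories: int = 4
    rates: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "rates", discrete_gamma_rates(self.alpha, self.n_categories))

    @property
    def prior_mean(self) -> float:
        return float(np.mean(self.rates))
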