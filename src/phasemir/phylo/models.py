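"""Substitution models: GTR (4-state), doublet (16-state), discrete gamma.

The doublet model treats a base-paired column pair as a single 16-state
character; only one position of a doublet may change per instantaneous
event, with rate equal to the GTR exchangeability of the changed
nucleotide pair times the stationary frequency of the target doublet.
Both rate matrices are scaled to one expected substitution per unit branch
length at stationarity, and rate heterogeneity uses equal-probability
discrete-gamma categories (mean-of-bin rates, mean exactly 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaincinv

NUC = "ACGU"
# exchangeability order: AC, AG, AU, CG, CU, GU
EXCH_INDEX = {(0, 1): 0, (0, 2): 1, (0, 3): 2, (1, 2): 3, (1, 3): 4, (2, 3): 5}
DOUBLETS = [a + b for a in NUC for b in NUC]


def _exch(rates: np.ndarray, a: int, b: int) -> float:
    return rates[EXCH_INDEX[(a, b) if a < b else (b, a)]]


def _validate_simplex(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0) or abs(v.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must be a positive simplex summing to 1")
    return v


def gtr_rate_matrix(exchangeabilities, base_freqs) -> np.ndarray:
    """4x4 GTR rate matrix, reversible, scaled to unit mean rate."""
    r = np.asarray(exchangeabilities, dtype=float)
    if r.shape != (6,) or np.any(r <= 0):
        raise ValueError("need 6 positive exchangeabilities")
    pi = _validate_simplex(base_freqs, "base_freqs")
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = _exch(r, i, j) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


def doublet_rate_matrix(exchangeabilities, doublet_freqs) -> np.ndarray:
    """16x16 doublet rate matrix: single-position changes only.

    rate(xy -> x'y) = exch(x, x') * pi16(x'y) (and symmetrically for the
    second position); simultaneous two-position changes have rate zero.
    Scaled to unit mean rate; time-reversible by construction.
    """
    r = np.asarray(exchangeabilities, dtype=float)
    pi = _validate_simplex(doublet_freqs, "doublet_freqs")
    Q = np.zeros((16, 16))
    for i in range(16):
        a, b = divmod(i, 4)
        for j in range(16):
            if i == j:
                continue
            c, d = divmod(j, 4)
            if a != c and b != d:
                continue
            changed = (a, c) if a != c else (b, d)
            Q[i, j] = _exch(r, *changed) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


def discrete_gamma(alpha: float, k: int = 4, method: str = "mean") -> np.ndarray:
    """K equal-probability gamma rate categories with mean exactly 1.

    ``mean`` uses the mean-of-bin rate (the conditional expectation of a
    Gamma(alpha, rate alpha) variable within each quantile bin); ``median``
    the bin median renormalized to mean 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    # X ~ Gamma(alpha, rate alpha): CDF(x) = gammainc(alpha, alpha x)
    if method == "median":
        qs = (np.arange(k) + 0.5) / k
        rates = gammaincinv(alpha, qs) / alpha
        return rates / rates.mean()
    cuts = np.concatenate([[0.0], gammaincinv(alpha, np.arange(1, k) / k), [np.inf]])
    upper = gammainc(alpha + 1.0, cuts[1:])
    lower = gammainc(alpha + 1.0, cuts[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstitutionModel:
    """Partitioned GTR + doublet model with discrete-gamma heterogeneity."""

    gtr_exchangeabilities: tuple = (1.0,) * 6
    base_freqs: tuple = (0.25,) * 4
    doublet_freqs: tuple = (1 / 16,) * 16
    gamma_shape: float = 1.0
    n_rate_categories: int = 4

    def __post_init__(self):
        _validate_simplex(np.asarray(self.base_freqs), "base_freqs")
        _validate_simplex(np.asarray(self.doublet_freqs), "doublet_freqs")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    def gtr_matrix(self) -> np.ndarray:
        return gtr_rate_matrix(np.asarray(self.gtr_exchangeabilities), np.asarray(self.base_freqs))

    def doublet_matrix(self) -> np.ndarray:
        return doublet_rate_matrix(np.asarray(self.gtr_exchangeabilities), np.asarray(self.doublet_freqs))

    def gamma_rates(self) -> np.ndarray:
        return discrete_gamma(self.gamma_shape, self.n_rate_categories)


def reversible_eigen(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible rate matrix via symmetrization.

    Returns (V, lam, Vinv) with Q = V diag(lam) Vinv; P(t) = V e^{lam t} Vinv.
    """
    sq = np.sqrt(pi)
    B = (sq[:, None] * Q) / sq[None, :]
    B = 0.5 * (B + B.T)  # clean numerical asymmetry
    lam, U = np.linalg.eigh(B)
    V = U / sq[:, None]
    Vinv = U.T * sq[None, :]
    return V, lam, Vinv


def transition_matrices(V, lam, Vinv, lengths: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """P matrices for every (edge, category): shape (nedge, ncat, S, S)."""
    t = np.asarray(lengths, dtype=float)[:, None, None] * np.asarray(rates)[None, :, None]
    e = np.exp(lam[None, None, :] * t)  # (nedge, ncat, S)
    P = np.matmul(V[None, None] * e[:, :, None, :], Vinv)
    np.clip(P, 0.0, None, out=P)
    return P
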