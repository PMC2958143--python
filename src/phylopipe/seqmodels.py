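"""Nucleotide substitution models (JC, K80, HKY, GTR, +I, +G) and the
symmetric Mk model for discrete morphological characters.

Rate matrices are reversible and scaled so that the expected substitution
rate at stationarity equals 1; branch lengths are therefore in expected
substitutions per site. Transition-probability matrices come from the
symmetrized eigendecomposition, computed once per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
FAMILIES = ("JC", "K80", "HKY", "GTR")

# GTR exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def discrete_gamma_rates(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Mean rates of `n_cat` equal-probability categories of Gamma(alpha, mean 1).

    Category representative = conditional mean within the quantile bin
    (Yang's discrete-gamma construction).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    cuts = gamma_dist.ppf(np.linspace(0, 1, n_cat + 1), a=alpha, scale=1.0 / alpha)
    # E[X | a < X < b] for Gamma(alpha, 1/alpha) via regularized incomplete gamma
    upper = gammainc(alpha + 1, cuts[1:] * alpha)
    lower = gammainc(alpha + 1, cuts[:-1] * alpha)
    rates = (upper - lower) * n_cat  # mean within bin, bins have prob 1/n_cat
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible nucleotide model with optional invariant-sites and
    discrete-gamma rate heterogeneity.

    Parameters
    ----------
    family : one of JC, K80, HKY, GTR
    freqs : stationary base frequencies (ACGT), must sum to 1
    kappa : transition/transversion rate ratio (K80/HKY)
    rates : six GTR exchangeabilities (AC, AG, AT, CG, CT, GT)
    p_inv : proportion of invariant sites in [0, 1)
    alpha : gamma shape; None disables +G
    n_cat : number of discrete gamma categories
    """

    family: str = "JC"
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa: float = 2.0
    rates: Optional[np.ndarray] = None
    p_inv: float = 0.0
    alpha: Optional[float] = None
    n_cat: int = 4

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or np.any(self.freqs < 0):
            raise ValueError("freqs must be 4 non-negative reals")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("freqs must sum to 1")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0,1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.family in ("JC", "K80"):
            self.freqs = np.full(4, 0.25)
        if self.family == "GTR":
            if self.rates is None:
                self.rates = np.ones(6)
            self.rates = np.asarray(self.rates, dtype=float)
            if self.rates.shape != (6,) or np.any(self.rates <= 0):
                raise ValueError("GTR needs 6 positive exchangeabilities")
        self._decompose()

    # ------------------------------------------------------------------
    def q_matrix(self) -> np.ndarray:
        """Scaled rate matrix (rows sum to 0, mean rate 1 at stationarity)."""
        pi = self.freqs
        R = np.zeros((4, 4))
        if self.family == "GTR":
            for r, (i, j) in zip(self.rates, _PAIRS):
                R[i, j] = R[j, i] = r
        else:
            k = 1.0 if self.family == "JC" else self.kappa
            for (i, j) in _PAIRS:
                R[i, j] = R[j, i] = k if (i, j) in _TRANSITIONS else 1.0
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        return Q / mu

    def _decompose(self):
        Q = self.q_matrix()
        pi = self.freqs
        pos = pi > 0
        if not np.all(pos):
            raise ValueError("zero stationary frequencies unsupported")
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]
        S = (S + S.T) / 2.0  # reversible => symmetric; average off rounding
        w, U = np.linalg.eigh(S)
        self._eigval = w
        self._left = U / d[:, None] * 1.0  # D^-1/2 U
        self._right = (U * d[:, None]).T   # U^T D^1/2

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); `t` in expected substitutions/site."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    # ------------------------------------------------------------------
    def site_rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the +I/+G site-rate mixture.

        Gamma-category rates are rescaled by 1/(1-p_inv) so the model-wide
        mean rate stays 1 and branch lengths keep their unit.
        """
        if self.alpha is not None:
            g = discrete_gamma_rates(self.alpha, self.n_cat)
        else:
            g = np.array([1.0])
        w = np.full(g.size, 1.0 / g.size)
        if self.p_inv > 0:
            g = g / (1.0 - self.p_inv)
            return (np.concatenate(([0.0], g)),
                    np.concatenate(([self.p_inv], w * (1.0 - self.p_inv))))
        return g, w

    def n_free_parameters(self) -> int:
        k = {"JC": 0, "K80": 1, "HKY": 1 + 3, "GTR": 5 + 3}[self.family]
        if self.p_inv > 0 or getattr(self, "_fit_pinv", False):
            k += 1
        if self.alpha is not None:
            k += 1
        return k

    def label(self) -> str:
        s = self.family
        if self.p_inv > 0 or getattr(self, "_fit_pinv", False):
            s += "+I"
        if self.alpha is not None:
            s += "+G"
        return s


# ----------------------------------------------------------------------
# symmetric Mk model (discrete morphological characters)
# ----------------------------------------------------------------------
def mk_transition_matrix(k: int, rate: float, t: float) -> np.ndarray:
    """P(t) for the symmetric k-state Mk model, closed form.

    `rate` is the total leaving rate per unit branch length; each of the
    k-1 alternative states is reached at rate/(k-1).
    """
    if k < 2:
        raise ValueError("Mk needs >= 2 states")
    if rate < 0 or t < 0:
        raise ValueError("rate and t must be non-negative")
    e = np.exp(-rate * t * k / (k - 1))
    p_same = 1.0 / k + (k - 1.0) / k * e
    p_diff = 1.0 / k - 1.0 / k * e
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, p_same)
    return P
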