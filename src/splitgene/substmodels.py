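"""Empirical amino-acid substitution models.

A model is a reversible CTMC on the 20 amino acids given by exchangeabilities
``S`` and equilibrium frequencies ``pi``: ``Q[i,j] = S[i,j]*pi[j]`` off the
diagonal, rows summing to zero, scaled so the mean substitution rate is one
(branch lengths are then expected substitutions per site).  Transition
matrices exp(Qt) are produced from a precomputed symmetric eigendecomposition,
so each evaluation is three 20x20 products.

The default model is LG; a uniform-rate Poisson model is provided for
testing.  An optional discrete-Gamma rate mixture (equal-weight categories at
quantile medians) models among-site rate heterogeneity.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
from scipy.stats import gamma as _gamma_dist

N_STATES = 20


class SubstModel:
    """Reversible amino-acid substitution model with optional Gamma rates."""

    def __init__(self, name: str, Q: np.ndarray, pi: np.ndarray,
                 rates: np.ndarray | None = None):
        pi = np.asarray(pi, dtype=float)
        Q = np.asarray(Q, dtype=float)
        if Q.shape != (N_STATES, N_STATES):
            raise ValueError("Q must be 20x20")
        if not np.all(pi > 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be positive and sum to 1")
        if np.abs(Q.sum(axis=1)).max() > 1e-8:
            raise ValueError("Q rows must sum to 0")
        self.name = name
        self.Q = Q
        self.pi = pi
        self.rates = np.ones(1) if rates is None else np.asarray(rates, float)
        # symmetric decomposition: B = D^{1/2} Q D^{-1/2} is symmetric for
        # reversible Q; eigh gives orthonormal V, and
        # exp(Qt) = D^{-1/2} V exp(L t) V^T D^{1/2}
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        lam, V = np.linalg.eigh(B)
        self._lam = lam
        self._U = V / sq[:, None]          # D^{-1/2} V
        self._Uinv = V.T * sq[None, :]     # V^T D^{1/2}

    @property
    def n_rates(self) -> int:
        return len(self.rates)

    def with_gamma(self, ncat: int = 4, alpha: float = 1.0) -> "SubstModel":
        """Equal-weight discrete-Gamma rate categories (category medians,
        rescaled to mean one)."""
        qs = (np.arange(ncat) + 0.5) / ncat
        rates = _gamma_dist.ppf(qs, a=alpha, scale=1.0 / alpha)
        rates = rates / rates.mean()
        return SubstModel(f"{self.name}+G{ncat}", self.Q, self.pi, rates)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * rate * t); rows sum to one."""
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        e = np.exp(self._lam * (rate * t))
        P = (self._U * e) @ self._Uinv
        np.clip(P, 1e-300, None, out=P)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stacked P(t) per rate category, shape (n_rates, 20, 20)."""
        e = np.exp(self._lam[None, :] * (self.rates[:, None] * t))
        P = (self._U[None, :, :] * e[:, None, :]) @ self._Uinv
        np.clip(P, 1e-300, None, out=P)
        return P

    @classmethod
    def from_exchangeabilities(cls, name: str, S: np.ndarray, pi: np.ndarray
                               ) -> "SubstModel":
        S = np.asarray(S, dtype=float)
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(pi * np.diag(Q)).sum()
        Q /= mean_rate
        return cls(name, Q, pi)


def _load_paml_style(text: str, name: str) -> SubstModel:
    rows: list[list[float]] = []
    freqs: list[float] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("order"):
            continue
        if line.startswith("freqs"):
            freqs = [float(x) for x in line.split()[1:]]
        else:
            rows.append([float(x) for x in line.split()])
    if len(rows) != N_STATES - 1 or len(freqs) != N_STATES:
        raise ValueError(f"malformed model file for {name}")
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(rows, start=1):
        for j, v in enumerate(row):
            S[i, j] = S[j, i] = v
    return SubstModel.from_exchangeabilities(name, S, np.array(freqs))


def load_lg() -> SubstModel:
    """The LG model (Le & Gascuel 2008), the engine default."""
    text = resources.files("splitgene.data").joinpath("lg.txt").read_text()
    return _load_paml_style(text, "LG")


def poisson_model() -> SubstModel:
    """Uniform exchangeabilities and frequencies; handy as a test oracle."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return SubstModel.from_exchangeabilities("Poisson", S, pi)


def get_model(name: str) -> SubstModel:
    base, _, suffix = name.partition("+")
    if base.upper() == "LG":
        m = load_lg()
    elif base.lower() == "poisson":
        m = poisson_model()
    else:
        raise ValueError(f"unknown model {name!r}")
    if suffix:
        if not suffix.upper().startswith("G"):
            raise ValueError(f"unknown model suffix {suffix!r}")
        ncat = int(suffix[1:] or 4)
        m = m.with_gamma(ncat=ncat)
    return m
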