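"""The GTR+Gamma+I nucleotide substitution model.

A general time-reversible rate matrix ``Q_ij = s_ij * pi_j`` (i != j) built
from six exchangeabilities ``s`` (order AC, AG, AT, CG, CT, GT; GT is the
reference and fixed to 1) and a stationary distribution ``pi``, combined
with discrete-gamma among-site rate variation (shape ``alpha``, ``n_cat``
equiprobable categories, category rates = conditional bin means) and a
proportion ``p_inv`` of invariant sites modelled as an extra rate-0
category.

Scaling conventions
-------------------
``Q`` is rescaled so the expected substitution rate at stationarity is 1,
and the full set of category rates (including the rate-0 invariant class)
has weighted mean 1.  Branch lengths are then expected substitutions per
site.

Transition probabilities use the symmetric eigendecomposition of
``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which is exact for reversible Q and
stable for the long/short branch extremes the scans encounter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaincinv, gammainc

__all__ = [
    "GTRGIParams",
    "RateMatrix",
    "RateCategories",
    "build_rate_matrix",
    "transition_probs",
    "gamma_rates",
    "JC69",
]

_EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class GTRGIParams:
    """Parameters of the GTR+Gamma+I model.

    exchangeabilities : 6 nonnegative reals in order AC, AG, AT, CG, CT, GT
        (GT is the reference rate, fixed to 1).
    freqs : 4 positive stationary frequencies (A, C, G, T) summing to 1.
    alpha : gamma shape of among-site rate variation (> 0).
    p_inv : proportion of invariant sites, in [0, 1).
    n_cat : number of discrete gamma categories (>= 1).
    """

    exchangeabilities: tuple = (1.0,) * 6
    freqs: tuple = (0.25,) * 4
    alpha: float = 1.0
    p_inv: float = 0.0
    n_cat: int = 4

    def __post_init__(self):
        ex = tuple(float(x) for x in self.exchangeabilities)
        fr = tuple(float(x) for x in self.freqs)
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "freqs", fr)
        if len(ex) != 6:
            raise ValueError("six exchangeabilities required (AC AG AT CG CT GT)")
        if any(x < 0 for x in ex):
            raise ValueError("exchangeabilities must be nonnegative")
        if abs(ex[5] - 1.0) > 1e-12:
            raise ValueError("GT exchangeability is the reference and must be 1")
        if len(fr) != 4 or any(f <= 0 for f in fr):
            raise ValueError("four positive base frequencies required")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if not self.alpha > 0:
            raise ValueError("gamma shape alpha must be > 0")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        if self.n_cat < 1:
            raise ValueError("n_cat must be >= 1")

    def with_(self, **kwargs) -> "GTRGIParams":
        return replace(self, **kwargs)

    # Flat key=value serialization (text config block).
    def to_config(self) -> str:
        lines = [
            f"exch_{name.lower()} = {v!r}"
            for name, v in zip(_EXCH_ORDER, self.exchangeabilities)
        ]
        for base, f in zip("acgt", self.freqs):
            lines.append(f"freq_{base} = {f!r}")
        lines += [
            f"alpha = {self.alpha!r}",
            f"p_inv = {self.p_inv!r}",
            f"n_cat = {self.n_cat}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "GTRGIParams":
        kv = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        ex = tuple(float(kv[f"exch_{n.lower()}"]) for n in _EXCH_ORDER)
        fr = tuple(float(kv[f"freq_{b}"]) for b in "acgt")
        return cls(
            exchangeabilities=ex,
            freqs=fr,
            alpha=float(kv["alpha"]),
            p_inv=float(kv["p_inv"]),
            n_cat=int(kv["n_cat"]),
        )


JC69 = GTRGIParams(n_cat=1)


@dataclass
class RateMatrix:
    """Scaled GTR rate matrix with its spectral decomposition.

    ``Q`` has rows summing to zero, off-diagonals >= 0, satisfies
    stationarity (``pi Q = 0``) and detailed balance
    (``pi_i Q_ij == pi_j Q_ji``), and is scaled so
    ``-sum_i pi_i Q_ii == 1``.
    """

    Q: np.ndarray
    freqs: np.ndarray
    eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.eigvals is None:
            pi = self.freqs
            sq = np.sqrt(pi)
            B = (self.Q / sq[None, :]) * sq[:, None]  # diag(sqrt(pi)) Q diag(1/sqrt(pi))
            B = 0.5 * (B + B.T)  # symmetric for reversible Q; kill roundoff
            w, U = np.linalg.eigh(B)
            self.eigvals = w
            self._right = U / sq[:, None]      # diag(1/sqrt(pi)) U
            self._left = (U * sq[:, None]).T   # U^T diag(sqrt(pi))


def build_rate_matrix(params: GTRGIParams) -> RateMatrix:
    """Build the scaled GTR rate matrix from model parameters."""
    pi = np.asarray(params.freqs, dtype=float)
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(params.exchangeabilities, _PAIRS):
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (all exchangeabilities zero?)")
    return RateMatrix(Q=Q / mu, freqs=pi)


def transition_probs(rm: RateMatrix, t: float, rate: float = 1.0) -> np.ndarray:
    """Transition probability matrix ``P = exp(Q * t * rate)``."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    d = np.exp(rm.eigvals * (t * rate))
    P = (rm._right * d[None, :]) @ rm._left
    np.clip(P, 0.0, 1.0, out=P)
    return P


def transition_probs_many(rm: RateMatrix, lengths: np.ndarray) -> np.ndarray:
    """Stack of P(t) for an array of effective lengths ``t*rate``.

    Returns an array of shape ``(len(lengths), 4, 4)``; used by the
    likelihood engine to build per-edge, per-category matrices in one call.
    """
    lengths = np.asarray(lengths, dtype=float)
    d = np.exp(np.multiply.outer(lengths, rm.eigvals))  # (n, 4)
    P = (rm._right[None, :, :] * d[:, None, :]) @ rm._left
    np.clip(P, 0.0, 1.0, out=P)
    return P


@dataclass(frozen=True)
class RateCategories:
    """Discrete site-rate classes: rates and weights, overall mean rate 1.

    When ``p_inv > 0`` the first class is the invariant one (rate 0, weight
    ``p_inv``); the gamma classes share weight ``(1 - p_inv) / n_cat`` and
    are rescaled so the weighted mean over *all* classes is exactly 1.
    """

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


def gamma_rates(alpha: float, n_cat: int, p_inv: float = 0.0) -> RateCategories:
    """Discrete-gamma + invariant rate classes.

    Gamma(alpha, alpha) is cut into ``n_cat`` equiprobable bins and each
    class rate is the conditional mean within its bin (the mean-of-bins
    discretization), then rescaled for unit overall mean including the
    invariant class.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if n_cat < 1:
        raise ValueError("n_cat must be >= 1")
    if not 0.0 <= p_inv < 1.0:
        raise ValueError("p_inv must be in [0, 1)")
    if n_cat == 1:
        rates = np.array([1.0])
    else:
        # Bin edges at equiprobable quantiles of Gamma(shape=a, rate=a).
        probs = np.arange(1, n_cat) / n_cat
        edges = np.concatenate([[0.0], gammaincinv(alpha, probs) / alpha, [np.inf]])
        # E[X ; a<X<b] for Gamma(a, a) (mean 1) = F_{a+1}(b) - F_{a+1}(a).
        upper = gammainc(alpha + 1.0, alpha * edges[1:])
        upper[-1] = 1.0
        lower = gammainc(alpha + 1.0, alpha * edges[:-1])
        rates = n_cat * (upper - lower)
        rates /= rates.mean()  # exact unit mean among gamma classes
    if p_inv > 0.0:
        rates = np.concatenate([[0.0], rates / (1.0 - p_inv)])
        weights = np.concatenate(
            [[p_inv], np.full(n_cat, (1.0 - p_inv) / n_cat)]
        )
    else:
        weights = np.full(n_cat, 1.0 / n_cat)
    return RateCategories(rates=rates, weights=weights)
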