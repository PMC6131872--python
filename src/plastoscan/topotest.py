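"""Alternative-topology tests on stored site log-likelihoods.

RELL (resampling estimated log-likelihoods) bootstrap machinery, the
Shimodaira-Hasegawa (SH) test, and the multiscale-bootstrap Approximately
Unbiased (AU) test.  All tests operate on per-site lnL profiles computed
once per topology; bootstrap replicates re-sum stored values without
refitting, which is what makes many-replicate testing cheap.

Implementation notes
--------------------
* Replicates are drawn as multinomial counts over the unique joint site
  patterns of the stacked profiles, so a 10,000-replicate RELL on a 130 kb
  alignment is a handful of matrix products.
* SH: per-topology centered replicate lnL; the null distribution of the
  test statistic is the centered max-difference, compared with the observed
  delta = lnL(best) - lnL(topology).
* AU: replicates at scales r (resampling ceil(r*L) columns), per-scale
  never-best frequencies converted to normal quantiles z(r), weighted
  least-squares fit of z = d*sqrt(r) + c/sqrt(r), and p = 1 - Phi(d - c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .treelik import SiteLikelihoodProfile

__all__ = [
    "TopologySet",
    "TestResult",
    "rell_replicates",
    "sh_test",
    "au_test",
]

DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


@dataclass
class TopologySet:
    """Site-likelihood profiles of >= 2 topologies on one alignment."""

    profiles: list[SiteLikelihoodProfile]

    def __post_init__(self):
        if len(self.profiles) < 2:
            raise ValueError("at least two topologies required")
        lengths = {len(p) for p in self.profiles}
        if len(lengths) > 1:
            raise ValueError("profiles have unequal lengths")

    @property
    def ids(self) -> list[str]:
        return [
            p.topology_id or f"T{i + 1}" for i, p in enumerate(self.profiles)
        ]

    @property
    def n_sites(self) -> int:
        return len(self.profiles[0])

    def matrix(self) -> np.ndarray:
        """(n_topologies, L) site-lnL matrix."""
        return np.stack([p.site_lnl for p in self.profiles])

    def totals(self) -> np.ndarray:
        return self.matrix().sum(axis=1)

    def compressed(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique joint site patterns: (values (m, k), counts (m,))."""
        M = np.ascontiguousarray(self.matrix().T)
        view = M.view([("", M.dtype)] * M.shape[1]).ravel()
        _, first, counts = np.unique(view, return_index=True, return_counts=True)
        return M[first], counts.astype(float)


@dataclass
class TestResult:
    """Per-topology outcome of a topology test."""

    topology_id: str
    lnl: float
    delta: float
    p_value: float
    n_replicates: int
    seed: int
    flag: str = ""


def _rell_totals(
    values: np.ndarray,
    counts: np.ndarray,
    n_draw: int,
    n_replicates: int,
    rng: np.random.Generator,
    batch: int = 2000,
) -> np.ndarray:
    """(n_replicates, k) replicate totals from multinomial pattern counts."""
    p = counts / counts.sum()
    out = np.empty((n_replicates, values.shape[1]))
    done = 0
    while done < n_replicates:
        b = min(batch, n_replicates - done)
        draws = rng.multinomial(n_draw, p, size=b).astype(float)
        out[done : done + b] = draws @ values
        done += b
    return out


def rell_replicates(
    topologies: TopologySet, n: int, seed: int
) -> np.ndarray:
    """RELL bootstrap: per-replicate total lnL per topology, ``(n, k)``.

    Columns are resampled uniformly with replacement; stored site lnL
    values are re-summed without refitting.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values, counts = topologies.compressed()
    rng = np.random.default_rng(seed)
    return _rell_totals(values, counts, topologies.n_sites, n, rng)


def sh_test(
    topologies: TopologySet, n: int = 10000, seed: int = 0
) -> list[TestResult]:
    """Shimodaira-Hasegawa test of every topology against the best one."""
    totals = topologies.totals()
    best = totals.max()
    deltas = best - totals
    reps = rell_replicates(topologies, n, seed)
    centered = reps - reps.mean(axis=0, keepdims=True)
    rep_delta = centered.max(axis=1, keepdims=True) - centered  # (n, k)
    results = []
    for i, tid in enumerate(topologies.ids):
        p = float((rep_delta[:, i] >= deltas[i]).mean())
        results.append(
            TestResult(
                topology_id=tid,
                lnl=float(totals[i]),
                delta=float(deltas[i]),
                p_value=p,
                n_replicates=n,
                seed=seed,
            )
        )
    return results


def au_test(
    topologies: TopologySet,
    scales=DEFAULT_AU_SCALES,
    n_per_scale: int = 5000,
    seed: int = 0,
) -> list[TestResult]:
    """Approximately Unbiased test via the multiscale bootstrap.

    For each scale ``r`` the alignment is resampled to ``ceil(r*L)``
    columns; the frequency with which each topology fails to be the maximum
    gives a z-value; the signed-distance / curvature decomposition
    ``z(r) = d*sqrt(r) + c/sqrt(r)`` is fit by weighted least squares and
    ``p = 1 - Phi(d - c)``.
    """
    values, counts = topologies.compressed()
    totals = topologies.totals()
    best = totals.max()
    deltas = best - totals
    L = topologies.n_sites
    k = values.shape[1]
    scales = np.asarray(scales, dtype=float)
    rng = np.random.default_rng(seed)
    # never-best counts per scale per topology
    notbest = np.zeros((len(scales), k))
    for si, r in enumerate(scales):
        n_draw = int(np.ceil(r * L))
        reps = _rell_totals(values, counts, n_draw, n_per_scale, rng)
        is_best = reps >= reps.max(axis=1, keepdims=True) - 1e-12
        notbest[si] = n_per_scale - is_best.sum(axis=0)

    results = []
    sqrt_r = np.sqrt(scales)
    X = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    for i, tid in enumerate(topologies.ids):
        c_i = notbest[:, i]
        flag = ""
        if np.all(c_i == 0) or np.all(c_i == n_per_scale):
            # degenerate: topology always (or never) the ML choice
            p = 1.0 if np.all(c_i == 0) else 0.0
            flag = "degenerate"
        else:
            f = np.clip(c_i / n_per_scale, 0.5 / n_per_scale,
                        1.0 - 0.5 / n_per_scale)
            z = norm.ppf(f)
            # delta-method weights for the probit of a binomial frequency
            w = n_per_scale * norm.pdf(z) ** 2 / (f * (1.0 - f))
            W = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
            d, c = coef
            p = float(1.0 - norm.cdf(d - c))
        results.append(
            TestResult(
                topology_id=tid,
                lnl=float(totals[i]),
                delta=float(deltas[i]),
                p_value=p,
                n_replicates=int(n_per_scale * len(scales)),
                seed=seed,
                flag=flag,
            )
        )
    return results


def results_to_tsv(sh: list[TestResult], au: list[TestResult] | None = None) -> str:
    """Combined result table (one row per topology)."""
    au_by_id = {r.topology_id: r for r in au} if au else {}
    lines = ["topology\tlnL\tdelta\tp_SH\tp_AU\tn\tseed"]
    for r in sh:
        a = au_by_id.get(r.topology_id)
        p_au = f"{a.p_value:.6g}" if a else "NA"
        lines.append(
            f"{r.topology_id}\t{r.lnl:.4f}\t{r.delta:.4f}\t"
            f"{r.p_value:.6g}\t{p_au}\t{r.n_replicates}\t{r.seed}"
        )
    return "\n".join(lines) + "\n"
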