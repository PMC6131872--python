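"""Phylogenetic likelihood on fixed topologies.

Newick I/O, Felsenstein pruning for per-site log-likelihoods under
GTR+Gamma+I, and optimization of branch lengths and model parameters on a
fixed topology.  Trees have unrooted semantics (stored with an arbitrary
root); for the reversible models used here the likelihood is invariant to
the rooting (the pulley principle), which the test-suite asserts.

The engine compresses the alignment to unique site patterns, evaluates the
pruning recursion vectorized over patterns and rate categories, and applies
per-node rescaling with log-scale accumulators so ~130 kb x 21-taxon data
cannot underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment, STATE_MASK
from .substmodel import (
    GTRGIParams,
    build_rate_matrix,
    gamma_rates,
    transition_probs_many,
)

__all__ = [
    "PhyloTree",
    "SiteLikelihoodProfile",
    "parse_newick",
    "write_newick",
    "site_loglik",
    "fit_on_topology",
    "bootstrap_columns",
    "empirical_frequencies",
    "constant_fraction",
    "LikelihoodEngine",
]

MIN_BRANCH_LENGTH = 1e-8  # floor during optimization; avoids log(0) scaling


@dataclass
class _Node:
    parent: int | None
    children: list[int]
    length: float
    label: str | None


class PhyloTree:
    """Tree with branch lengths and unique leaf labels.

    Stored rooted at an arbitrary node purely for traversal; all
    likelihood computations treat it as unrooted.
    """

    def __init__(self, nodes: list[_Node], root: int, lengths_present: bool = True):
        self.nodes = nodes
        self.root = root
        self.lengths_present = lengths_present
        labels = [n.label for n in nodes if not n.children]
        if any(lab is None or lab == "" for lab in labels):
            raise ValueError("tree contains an unlabeled leaf")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        nodes: list[_Node] = []
        index = {}
        any_length = False
        for nd in dtree.preorder_node_iter():
            parent = index[id(nd.parent_node)] if nd.parent_node else None
            label = nd.taxon.label if nd.taxon else (nd.label or None)
            if nd.edge.length is not None:
                any_length = True
            nodes.append(_Node(parent, [], float(nd.edge.length or 0.0), label))
            index[id(nd)] = len(nodes) - 1
            if parent is not None:
                nodes[parent].children.append(len(nodes) - 1)
        return cls(nodes, 0, lengths_present=any_length)

    # -- basic accessors --------------------------------------------------
    @property
    def leaf_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if not n.children]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.nodes[i].label for i in self.leaf_indices]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.nodes[i].children)
        return order[::-1]

    def edge_nodes(self) -> list[int]:
        """Indices of non-root nodes; each owns the edge to its parent."""
        return [i for i in range(len(self.nodes)) if i != self.root]

    def branch_lengths(self) -> np.ndarray:
        return np.array([self.nodes[i].length for i in self.edge_nodes()])

    def set_branch_lengths(self, lengths) -> None:
        for i, v in zip(self.edge_nodes(), lengths):
            self.nodes[i].length = float(v)

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def copy(self) -> "PhyloTree":
        nodes = [
            _Node(n.parent, list(n.children), n.length, n.label)
            for n in self.nodes
        ]
        return PhyloTree(nodes, self.root, self.lengths_present)

    # -- Newick output ----------------------------------------------------
    def to_newick(self, lengths: bool | None = None) -> str:
        if lengths is None:
            lengths = self.lengths_present

        def fmt(i: int) -> str:
            n = self.nodes[i]
            if n.children:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.label:
                    s += n.label
            else:
                s = n.label or ""
            if lengths and i != self.root:
                s += f":{n.length:.10g}"
            return s

        return fmt(self.root) + ";"

    # -- rerooting --------------------------------------------------------
    def rerooted(self, node: int) -> "PhyloTree":
        """Same unrooted tree, traversal-rooted at ``node``.

        Rooting at a leaf would drop its observed state from the pruning
        recursion, so a leaf target is normalized to its neighbor.
        """
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(self.nodes))}
        for i in self.edge_nodes():
            p = self.nodes[i].parent
            adj[i].append((p, self.nodes[i].length))
            adj[p].append((i, self.nodes[i].length))
        if len(adj[node]) == 1:
            node = adj[node][0][0]
        nodes = [
            _Node(None, [], 0.0, n.label if not n.children else n.label)
            for n in self.nodes
        ]
        seen = {node}
        stack = [node]
        while stack:
            i = stack.pop()
            for j, ln in adj[i]:
                if j in seen:
                    continue
                seen.add(j)
                nodes[j].parent = i
                nodes[j].length = ln
                nodes[i].children.append(j)
                stack.append(j)
        return PhyloTree(nodes, node, self.lengths_present)

    def __repr__(self) -> str:
        return f"PhyloTree({self.n_leaves} leaves, root={self.root})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths optional, defaulting to 0)."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


@dataclass
class SiteLikelihoodProfile:
    """Per-site natural-log likelihoods for one (topology, model) pair."""

    site_lnl: np.ndarray
    topology_id: str = ""

    @property
    def total(self) -> float:
        return float(self.site_lnl.sum())

    def __len__(self) -> int:
        return len(self.site_lnl)


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Pattern-compressed pruning likelihood for one alignment + topology.

    Branch lengths and model parameters are arguments of :meth:`loglik`, so
    one engine serves a whole optimization run.
    """

    def __init__(self, aln: Alignment, tree: PhyloTree):
        missing = [t for t in tree.leaf_labels if t not in aln.taxa]
        if missing:
            raise ValueError(
                f"taxa in tree but missing from alignment: {', '.join(missing)}"
            )
        self.tree = tree
        self.leaf_order = tree.leaf_indices
        rows = np.stack([aln.row(tree.nodes[i].label) for i in self.leaf_order])
        # unique site patterns (columns of the leaf-row submatrix)
        cols = np.ascontiguousarray(rows.T)
        view = cols.view([("", cols.dtype)] * cols.shape[1]).ravel()
        _, first, inverse, counts = np.unique(
            view, return_index=True, return_inverse=True, return_counts=True
        )
        self.patterns = cols[first].T            # (n_leaves, n_pat)
        self.pattern_index = inverse             # (L,)
        self.counts = counts.astype(float)
        self.n_sites = cols.shape[0]
        self.leaf_partials = STATE_MASK[self.patterns]  # (n_leaves, n_pat, 4)
        self._postorder = tree.postorder()
        self._edge_nodes = tree.edge_nodes()
        self._edge_pos = {n: k for k, n in enumerate(self._edge_nodes)}
        self._leaf_pos = {n: k for k, n in enumerate(self.leaf_order)}

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def loglik(
        self,
        params: GTRGIParams,
        lengths: np.ndarray | None = None,
        per_site: bool = False,
    ):
        """Total lnL, and optionally the per-site lnL vector."""
        if lengths is None:
            lengths = self.tree.branch_lengths()
        lengths = np.maximum(np.asarray(lengths, dtype=float), 0.0)
        # cache the spectral decomposition and rate classes per parameter set
        # (branch-length sweeps evaluate thousands of times per model)
        cached = getattr(self, "_model_cache", None)
        if cached is not None and cached[0] is params:
            rm, cats = cached[1], cached[2]
        else:
            rm = build_rate_matrix(params)
            cats = gamma_rates(params.alpha, params.n_cat, params.p_inv)
            self._model_cache = (params, rm, cats)
        ncat = len(cats.rates)
        # per-edge, per-category transition matrices in one spectral call
        eff = np.multiply.outer(lengths, cats.rates).ravel()
        P = transition_probs_many(rm, eff).reshape(len(lengths), ncat, 4, 4)

        npat = self.n_patterns
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        # per-pattern rescaling every few internal nodes: each unscaled edge
        # can shrink partials by ~1e-12 at worst, so a handful of levels is
        # safe and the (ncat, npat, 4) max reduction is the hot spot
        n_internal = 0
        for node in self._postorder:
            children = self.tree.nodes[node].children
            if not children:
                continue
            acc = None
            for c in children:
                Pt = P[self._edge_pos[c]].transpose(0, 2, 1)  # (ncat, 4, 4)
                if self.tree.nodes[c].children:
                    msg = partial.pop(c) @ Pt       # (ncat, npat, 4)
                else:
                    leaf = self.leaf_partials[self._leaf_pos[c]]
                    msg = leaf[None, :, :] @ Pt
                acc = msg if acc is None else acc * msg
            n_internal += 1
            if n_internal % 4 == 0:
                m = acc.max(axis=2).max(axis=0)
                nz = m > 0
                np.divide(acc, m[None, :, None], out=acc,
                          where=m[None, :, None] > 0)
                logscale[nz] += np.log(m[nz])
            partial[node] = acc
        root_partial = partial[self.tree.root]      # (ncat, npat, 4)
        site_l = cats.weights @ (root_partial @ rm.freqs)
        with np.errstate(divide="ignore"):
            pat_lnl = np.log(site_l) + logscale
        total = float(self.counts @ pat_lnl)
        if per_site:
            return total, pat_lnl[self.pattern_index]
        return total


def empirical_frequencies(aln: Alignment, pseudocount: float = 1.0) -> tuple:
    """Base frequencies from pure A/C/G/T counts (gaps/ambiguity ignored)."""
    counts = np.array(
        [(aln.data == code).sum() for code in range(4)], dtype=float
    )
    counts += pseudocount
    f = counts / counts.sum()
    f = f / f.sum()
    return tuple(f.tolist())


def constant_fraction(aln: Alignment) -> float:
    """Fraction of columns compatible with a single state in every row."""
    masks = STATE_MASK[aln.data]           # (n_taxa, L, 4)
    compat = masks.prod(axis=0)            # (L, 4)
    return float((compat.max(axis=1) > 0).mean())


def site_loglik(
    aln: Alignment,
    tree: PhyloTree,
    model: GTRGIParams,
    topology_id: str = "",
) -> SiteLikelihoodProfile:
    """Per-site log-likelihoods by Felsenstein pruning under GTR+Gamma+I."""
    engine = LikelihoodEngine(aln, tree)
    _, site = engine.loglik(model, per_site=True)
    return SiteLikelihoodProfile(site_lnl=site, topology_id=topology_id)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    tree: PhyloTree
    params: GTRGIParams
    profile: SiteLikelihoodProfile
    lnl: float
    converged: bool
    n_cycles: int = 0


def fit_on_topology(
    aln: Alignment,
    topology: PhyloTree,
    model0: GTRGIParams | None = None,
    free: tuple = ("brlen", "alpha", "p_inv"),
    topology_id: str = "",
    max_cycles: int = 8,
    tol: float = 1e-4,
    max_brlen: float = 5.0,
) -> FitResult:
    """Fit branch lengths and selected model parameters on a fixed topology.

    ``free`` may contain ``brlen``, ``alpha``, ``p_inv``, ``exch`` and
    ``freqs``; frequencies default to empirical counts when not free.
    Branch lengths use coordinate-wise Brent; model parameters a
    derivative-free simplex in log/logit space; the two alternate until the
    total lnL improves by less than ``tol`` over a full cycle.
    """
    if "brlen" not in free:
        raise ValueError("at least branch lengths must be free")
    tree = topology.copy()
    engine = LikelihoodEngine(aln, tree)

    if model0 is None:
        model0 = GTRGIParams(alpha=1.0, p_inv=0.0, n_cat=4)
    params = model0
    if "freqs" not in free:
        params = params.with_(freqs=empirical_frequencies(aln))

    # bound p_inv away from the Gamma+I identifiability ridge
    pinv_max = 0.99 * constant_fraction(aln)
    if "p_inv" in free and pinv_max > 1e-6:
        start = min(max(params.p_inv, 0.25 * pinv_max), 0.9 * pinv_max)
        params = params.with_(p_inv=start)
    elif "p_inv" in free:
        free = tuple(f for f in free if f != "p_inv")

    lengths = tree.branch_lengths()
    if not tree.lengths_present or np.all(lengths <= 0):
        lengths = np.full(len(lengths), 0.05)
    lengths = np.clip(lengths, MIN_BRANCH_LENGTH, max_brlen)

    def model_from_vec(x: np.ndarray) -> GTRGIParams:
        kw = {}
        i = 0
        if "alpha" in free:
            kw["alpha"] = float(np.exp(np.clip(x[i], -6, 6)))
            i += 1
        if "p_inv" in free:
            kw["p_inv"] = float(pinv_max / (1.0 + np.exp(-np.clip(x[i], -30, 30))))
            i += 1
        if "exch" in free:
            ex = np.exp(np.clip(x[i : i + 5], -8, 8))
            kw["exchangeabilities"] = tuple(ex.tolist()) + (1.0,)
            i += 5
        if "freqs" in free:
            w = np.exp(np.clip(x[i : i + 3], -8, 8))
            f = np.concatenate([w, [1.0]])
            f = f / f.sum()
            kw["freqs"] = tuple(f.tolist())
            i += 3
        return params.with_(**kw)

    def vec_from_model(p: GTRGIParams) -> np.ndarray:
        x = []
        if "alpha" in free:
            x.append(np.log(p.alpha))
        if "p_inv" in free:
            q = min(max(p.p_inv / pinv_max, 1e-6), 1 - 1e-6)
            x.append(np.log(q / (1 - q)))
        if "exch" in free:
            x.extend(np.log(np.maximum(p.exchangeabilities[:5], 1e-8)))
        if "freqs" in free:
            f = np.asarray(p.freqs)
            x.extend(np.log(f[:3] / f[3]))
        return np.array(x)

    model_free = any(f in free for f in ("alpha", "p_inv", "exch", "freqs"))
    lnl = engine.loglik(params, lengths)
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        lnl_start = lnl
        # --- branch length sweep (Brent per edge, log scale) ---
        for k in range(len(lengths)):
            def obj(u: float, k=k) -> float:
                ls = lengths.copy()
                ls[k] = np.exp(u)
                return -engine.loglik(params, ls)

            # bracket centered on the current value: a global [floor, max]
            # bracket can strand Brent in the flat saturated tail
            u0 = np.log(max(lengths[k], MIN_BRANCH_LENGTH))
            lo_u, hi_u = np.log(MIN_BRANCH_LENGTH), np.log(max_brlen)
            a, b = max(u0 - 3.0, lo_u), min(u0 + 3.0, hi_u)
            for _ in range(4):
                res = minimize_scalar(
                    obj, bounds=(a, b), method="bounded",
                    options={"xatol": 1e-4, "maxiter": 30},
                )
                at_edge = res.x - a < 2e-4 and a > lo_u
                at_hi = b - res.x < 2e-4 and b < hi_u
                if at_edge:
                    a = max(a - 3.0, lo_u)
                elif at_hi:
                    b = min(b + 3.0, hi_u)
                else:
                    break
            if -res.fun > lnl:
                lengths[k] = float(np.exp(res.x))
                lnl = -res.fun
        # --- model parameters ---
        if model_free:
            if cycle == 1 and ("alpha" in free or "p_inv" in free):
                # Coarse (alpha, p_inv) grid start: the Gamma+I likelihood
                # has a long flat ridge and a cold simplex start can strand
                # the fit far from the crest.
                alphas = (0.2, 0.4, 0.7, 1.2, 2.5) if "alpha" in free \
                    else (params.alpha,)
                pinvs = (
                    tuple(q * pinv_max for q in (0.05, 0.3, 0.6, 0.9))
                    if "p_inv" in free else (params.p_inv,)
                )
                for a in alphas:
                    for pv in pinvs:
                        cand = params.with_(alpha=a, p_inv=pv)
                        val = engine.loglik(cand, lengths)
                        if val > lnl:
                            params, lnl = cand, val

            # Joint simplex over the model parameters plus one log tree-scale
            # coordinate: alpha, p_inv and the overall branch scale are
            # strongly coupled along the Gamma+I ridge, and without the
            # scale coordinate the alternation crawls and stalls on it.
            x0 = np.concatenate([vec_from_model(params), [0.0]])

            def mobj(x: np.ndarray) -> float:
                s = np.exp(np.clip(x[-1], -2.0, 2.0))
                return -engine.loglik(model_from_vec(x[:-1]), lengths * s)

            res = minimize(
                mobj,
                x0,
                method="Nelder-Mead",
                options={
                    "maxfev": 150 + 80 * len(x0),
                    "xatol": 1e-3,
                    "fatol": 1e-5,
                    "adaptive": len(x0) > 3,
                },
            )
            if -res.fun > lnl:
                params = model_from_vec(res.x[:-1])
                lengths = lengths * np.exp(np.clip(res.x[-1], -2.0, 2.0))
                lnl = -res.fun
        if lnl - lnl_start < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fit_on_topology: no convergence after {cycle} cycles "
            f"(last improvement {lnl - lnl_start:.3g}); returning best-so-far",
            RuntimeWarning,
        )
    tree.set_branch_lengths(lengths)
    tree.lengths_present = True
    total, site = engine.loglik(params, lengths, per_site=True)
    profile = SiteLikelihoodProfile(site_lnl=site, topology_id=topology_id)
    return FitResult(tree=tree, params=params, profile=profile, lnl=total,
                     converged=converged, n_cycles=cycle)


def bootstrap_columns(aln, n_replicates: int, seed: int) -> np.ndarray:
    """Uniform with-replacement column resamples, ``(n_replicates, L)``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    L = aln if isinstance(aln, (int, np.integer)) else aln.n_columns
    rng = np.random.default_rng(seed)
    return rng.integers(0, L, size=(n_replicates, L))


def write_site_lnl_tsv(path, coords, profiles: list[SiteLikelihoodProfile]) -> None:
    """Site-likelihood table: site, coordinate, then one lnL column per topology."""
    import pandas as pd

    cols = {"site": np.arange(1, len(coords) + 1), "coordinate": coords}
    for p in profiles:
        cols[f"lnL_{p.topology_id or 'topology'}"] = p.site_lnl
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")
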