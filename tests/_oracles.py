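"""Independent oracles for the likelihood machinery.

Deliberately avoids the package's spectral transition-probability code:
P(t) comes from ``scipy.linalg.expm`` on a directly assembled Q, gamma bin
means from numerical quadrature of the gamma density, and site likelihoods
from exhaustive enumeration over internal-node state assignments.
"""

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from plastoscan.alignment import STATE_MASK

_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def oracle_rate_matrix(params):
    pi = np.asarray(params.freqs)
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(params.exchangeabilities, _PAIRS):
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / (-(pi * np.diag(Q)).sum())


def oracle_gamma_rates(alpha, n_cat, p_inv=0.0):
    """Bin means of Gamma(alpha, alpha) by quadrature, then +I rescaling."""
    if n_cat == 1:
        rates = np.array([1.0])
    else:
        edges = gamma_dist.ppf(
            np.linspace(0, 1, n_cat + 1), a=alpha, scale=1.0 / alpha
        )
        edges[0], edges[-1] = 0.0, np.inf
        pdf = lambda x: gamma_dist.pdf(x, a=alpha, scale=1.0 / alpha)
        rates = np.array(
            [
                quad(lambda x: x * pdf(x), edges[k], edges[k + 1], limit=200)[0]
                * n_cat
                for k in range(n_cat)
            ]
        )
        rates /= rates.mean()
    if p_inv > 0:
        rates = np.concatenate([[0.0], rates / (1.0 - p_inv)])
        weights = np.concatenate([[p_inv], np.full(n_cat, (1 - p_inv) / n_cat)])
    else:
        weights = np.full(n_cat, 1.0 / n_cat)
    return rates, weights


def oracle_site_loglik(aln, tree, params):
    """Per-site lnL by brute-force enumeration over internal states."""
    Q = oracle_rate_matrix(params)
    pi = np.asarray(params.freqs)
    rates, weights = oracle_gamma_rates(params.alpha, params.n_cat, params.p_inv)
    nodes = tree.nodes
    internal = [i for i, n in enumerate(nodes) if n.children]
    leaves = tree.leaf_indices
    P = {
        i: [expm(Q * nodes[i].length * r) for r in rates]
        for i in range(len(nodes))
        if i != tree.root
    }
    out = np.zeros(aln.n_columns)
    rows = {i: aln.row(nodes[i].label) for i in leaves}
    for site in range(aln.n_columns):
        total = 0.0
        for ci, (r, w) in enumerate(zip(rates, weights)):
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = dict(zip(internal, assign))
                pr = pi[st[tree.root]]
                for i in range(len(nodes)):
                    if i == tree.root:
                        continue
                    parent_state = st[nodes[i].parent]
                    if i in st:
                        pr *= P[i][ci][parent_state, st[i]]
                    else:
                        mask = STATE_MASK[rows[i][site]]
                        pr *= float(P[i][ci][parent_state] @ mask)
                    if pr == 0.0:
                        break
                acc += pr
            total += w * acc
        out[site] = np.log(total)
    return out


def all_small_topologies(rng, max_leaves=5):
    """All unrooted shapes with 3-5 leaves, with random branch lengths.

    1 three-leaf + 3 four-leaf + 15 five-leaf = 19 topologies; the
    five-leaf set is built by attaching the fifth leaf to each edge of each
    four-leaf shape.
    """
    def bl():
        return f"{rng.uniform(0.02, 0.6):.4f}"

    trees = [f"(A:{bl()},B:{bl()},C:{bl()});"]
    quartets = [
        "((A,B),(C,D))", "((A,C),(B,D))", "((A,D),(B,C))",
    ]
    for q in quartets:
        trees.append(_with_lengths(q, bl))
        # attach E to each of the 5 edges of the quartet shape
        inner = q[1:-1]  # strip outer parens
        left, right = _split_top(inner)
        l1, l2 = _split_top(left[1:-1])
        r1, r2 = _split_top(right[1:-1])
        a, b, c, d = l1, l2, r1, r2
        forms = [
            f"((({a},E),{b}),({c},{d}))",
            f"(({a},({b},E)),({c},{d}))",
            f"(({a},{b}),(({c},E),{d}))",
            f"(({a},{b}),({c},({d},E)))",
            f"((({a},{b}),E),({c},{d}))",
        ]
        trees.extend(_with_lengths(f, bl) for f in forms)
    return trees


def _split_top(s):
    depth = 0
    for i, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "," and depth == 0:
            return s[:i], s[i + 1:]
    raise ValueError(s)


def _with_lengths(shape, bl):
    out = []
    for ch in shape:
        out.append(ch)
        if ch.isalpha() or ch == ")":
            out.append(f":{bl()}")
    return "".join(out).replace("):", "):") + ";"
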