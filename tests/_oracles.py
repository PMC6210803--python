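"""Independent oracle implementations shared by the test modules.

These are deliberately written against the *semantics* (recursive tree walk,
exhaustive enumeration) rather than reusing the package's vectorized code
paths, so they can serve as cross-checks.
"""

import itertools

import numpy as np
from scipy import stats

from kfgep.gep.genome import ARITY, N_FUNCTIONS

ADD, SUB, MUL, DIV, SIN, COS, SQRT, SQ, INV, EXP = range(10)


def oracle_tree(gene):
    """Breadth-first Karva tree construction (queue-based)."""
    nodes = []
    demand = 1
    i = 0
    while i < demand:
        sym = int(gene[i])
        nodes.append(sym)
        demand += int(ARITY[sym])
        i += 1
    children = {}
    nxt = 1
    for idx, sym in enumerate(nodes):
        kids = []
        for _ in range(int(ARITY[sym])):
            kids.append(nxt)
            nxt += 1
        children[idx] = kids
    return nodes, children


def oracle_eval_node(nodes, children, idx, row):
    sym = nodes[idx]
    if sym >= N_FUNCTIONS:
        return np.float64(row[sym - N_FUNCTIONS])
    kids = [oracle_eval_node(nodes, children, k, row) for k in children[idx]]
    with np.errstate(over="ignore", divide="ignore"):
        if sym == ADD:
            return kids[0] + kids[1]
        if sym == SUB:
            return kids[0] - kids[1]
        if sym == MUL:
            return np.clip(kids[0] * kids[1], -1e30, 1e30)
        if sym == DIV:
            if kids[1] == 0:
                return np.float64(1.0)
            return np.clip(kids[0] / kids[1], -1e30, 1e30)
        if sym == SIN:
            return np.sin(kids[0])
        if sym == COS:
            return np.cos(kids[0])
        if sym == SQRT:
            return np.sqrt(np.abs(kids[0]))
        if sym == SQ:
            return np.clip(kids[0] * kids[0], -1e30, 1e30)
        if sym == INV:
            if kids[0] == 0:
                return np.float64(1.0)
            return np.clip(1.0 / kids[0], -1e30, 1e30)
        if sym == EXP:
            return np.exp(min(kids[0], np.float64(50.0)))
    raise AssertionError(sym)


def oracle_evaluate_chromosome(chrom, X, head_length):
    out = np.zeros(X.shape[0])
    for g in chrom:
        nodes, children = oracle_tree(g)
        for r in range(X.shape[0]):
            out[r] += oracle_eval_node(nodes, children, 0, X[r])
    return out


def brute_force_signed_rank_p(d, alternative="greater"):
    """Exhaustive 2^n enumeration of sign assignments for the Wilcoxon null."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=d.size)
        ]
    )
    if alternative == "greater":
        return np.mean(ws >= w_obs - 1e-12)
    return np.mean(ws <= w_obs + 1e-12)
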