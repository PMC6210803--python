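"""Karva genomes: encoding, validity, breadth-first decoding, evaluation.

A gene is a fixed-length string of symbol codes.  The first ``head_length``
positions (the head) may hold functions or terminals; the remaining tail
holds terminals only, which guarantees that the breadth-first ("Karva")
decoding of any gene terminates inside the gene.  A chromosome is a stack of
genes whose decoded expression trees are linked by addition.

Symbols are encoded as small integers: codes ``0..9`` are the functions
``+ - * / sin cos sqrt sq inv exp`` (arities 2,2,2,2,1,1,1,1,1,1) and codes
``10..16`` are the terminals ``T1..T7``.

All operators are *protected* so that every chromosome evaluates to a finite
number for any finite input:

* ``x / 0 -> 1`` and ``inv(0) -> 1``
* ``sqrt(x) -> sqrt(|x|)``
* ``exp(x) -> exp(min(x, 50))``
* products and squares saturate at ``+/- 1e30``
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .config import MAX_ARITY, tail_length

# --- symbol table -----------------------------------------------------------

FUNCTION_NAMES: Tuple[str, ...] = (
    "+", "-", "*", "/", "sin", "cos", "sqrt", "sq", "inv", "exp",
)
N_FUNCTIONS = len(FUNCTION_NAMES)
N_TERMINALS = 7
TERMINAL_NAMES: Tuple[str, ...] = tuple(f"T{i}" for i in range(1, N_TERMINALS + 1))
SYMBOL_NAMES: Tuple[str, ...] = FUNCTION_NAMES + TERMINAL_NAMES
N_SYMBOLS = len(SYMBOL_NAMES)

FUNCTION_CODES = np.arange(N_FUNCTIONS)
TERMINAL_CODES = np.arange(N_FUNCTIONS, N_SYMBOLS)

#: arity per symbol code (terminals have arity 0)
ARITY = np.array([2, 2, 2, 2, 1, 1, 1, 1, 1, 1] + [0] * N_TERMINALS, dtype=np.int64)

_ADD, _SUB, _MUL, _DIV, _SIN, _COS, _SQRT, _SQ, _INV, _EXP = range(N_FUNCTIONS)

SATURATION = 1e30
EXP_CLAMP = 50.0


# --- protected primitive operations ----------------------------------------

def p_mul(a, b):
    with np.errstate(over="ignore"):
        return np.clip(a * b, -SATURATION, SATURATION)


def p_div(a, b):
    b = np.asarray(b, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        out = np.divide(a, b, out=np.ones_like(b, dtype=float), where=b != 0)
        return np.clip(out, -SATURATION, SATURATION)


def p_inv(a):
    a = np.asarray(a, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        out = np.divide(1.0, a, out=np.ones_like(a, dtype=float), where=a != 0)
        return np.clip(out, -SATURATION, SATURATION)


def p_sqrt(a):
    return np.sqrt(np.abs(a))


def p_sq(a):
    a = np.asarray(a, dtype=float)
    with np.errstate(over="ignore"):
        return np.clip(a * a, -SATURATION, SATURATION)


def p_exp(a):
    return np.exp(np.minimum(a, EXP_CLAMP))


#: namespace in which exported infix formula strings can be ``eval``-ed
FORMULA_NAMESPACE: Dict[str, object] = {
    "pdiv": p_div,
    "pinv": p_inv,
    "psqrt": p_sqrt,
    "sq": p_sq,
    "pexp": p_exp,
    "sin": np.sin,
    "cos": np.cos,
    "pmul": p_mul,
    "__builtins__": {},
}


# --- validity and construction ----------------------------------------------

def is_valid_gene(gene: np.ndarray, head_length: int) -> bool:
    """Tail validity: every symbol is in range and the tail holds terminals only."""
    gene = np.asarray(gene)
    if gene.ndim != 1 or gene.shape[0] != head_length + tail_length(head_length):
        return False
    if gene.min() < 0 or gene.max() >= N_SYMBOLS:
        return False
    return bool((gene[head_length:] >= N_FUNCTIONS).all())


def is_valid_chromosome(chrom: np.ndarray, head_length: int) -> bool:
    chrom = np.asarray(chrom)
    if chrom.ndim != 2:
        return False
    return all(is_valid_gene(g, head_length) for g in chrom)


def random_chromosome(rng: np.random.Generator, n_genes: int, head_length: int) -> np.ndarray:
    """Uniform random valid chromosome: head over all symbols, tail over terminals."""
    t = tail_length(head_length)
    head = rng.integers(0, N_SYMBOLS, size=(n_genes, head_length))
    tail = rng.integers(N_FUNCTIONS, N_SYMBOLS, size=(n_genes, t))
    return np.concatenate([head, tail], axis=1).astype(np.int8)


def random_population(
    rng: np.random.Generator, population_size: int, n_genes: int, head_length: int
) -> np.ndarray:
    return np.stack(
        [random_chromosome(rng, n_genes, head_length) for _ in range(population_size)]
    )


# --- Karva decoding ----------------------------------------------------------

def coding_length(gene: np.ndarray) -> int:
    """Length of the coding region (breadth-first open-reading-frame scan)."""
    total = 1
    i = 0
    g = np.asarray(gene)
    while i < total:
        total += int(ARITY[g[i]])
        i += 1
    return total


def compile_gene(gene: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode a gene into a breadth-first node table.

    Returns ``(codes, left, right)`` over the coding region only; node ``i``'s
    children (where present) are at strictly larger indices, so the tree can
    be evaluated by one backward sweep.
    """
    n = coding_length(gene)
    codes = np.asarray(gene[:n], dtype=np.int64)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    nxt = 1
    for i in range(n):
        a = int(ARITY[codes[i]])
        if a >= 1:
            left[i] = nxt
            nxt += 1
        if a == 2:
            right[i] = nxt
            nxt += 1
    if nxt != n:  # unreachable for tail-valid genes
        raise ValueError("malformed gene: coding region does not close")
    return codes, left, right


def _eval_nodes(codes, left, right, X: np.ndarray) -> np.ndarray:
    n = len(codes)
    vals: List[np.ndarray] = [None] * n  # type: ignore[list-item]
    for i in range(n - 1, -1, -1):
        c = codes[i]
        if c >= N_FUNCTIONS:
            vals[i] = X[:, c - N_FUNCTIONS]
        elif c == _ADD:
            vals[i] = vals[left[i]] + vals[right[i]]
        elif c == _SUB:
            vals[i] = vals[left[i]] - vals[right[i]]
        elif c == _MUL:
            vals[i] = p_mul(vals[left[i]], vals[right[i]])
        elif c == _DIV:
            vals[i] = p_div(vals[left[i]], vals[right[i]])
        elif c == _SIN:
            vals[i] = np.sin(vals[left[i]])
        elif c == _COS:
            vals[i] = np.cos(vals[left[i]])
        elif c == _SQRT:
            vals[i] = p_sqrt(vals[left[i]])
        elif c == _SQ:
            vals[i] = p_sq(vals[left[i]])
        elif c == _INV:
            vals[i] = p_inv(vals[left[i]])
        elif c == _EXP:
            vals[i] = p_exp(vals[left[i]])
        else:  # pragma: no cover
            raise ValueError(f"unknown symbol code {c}")
    return np.asarray(vals[0], dtype=float)


def evaluate_gene(
    gene: np.ndarray,
    X: np.ndarray,
    head_length: int,
    cache: Dict[bytes, np.ndarray] | None = None,
) -> np.ndarray:
    """Evaluate one gene on a feature matrix ``X`` of shape (n, 7).

    ``cache`` (optional) memoizes by coding region, so genomes that differ
    only in non-coding symbols share one evaluation.
    """
    if not is_valid_gene(gene, head_length):
        raise ValueError("invalid gene: function symbol in tail or bad code")
    n = coding_length(gene)
    key = None
    if cache is not None:
        key = np.asarray(gene[:n], dtype=np.int8).tobytes()
        hit = cache.get(key)
        if hit is not None:
            return hit
    codes, left, right = compile_gene(gene)
    out = _eval_nodes(codes, left, right, X)
    out = np.broadcast_to(out, (X.shape[0],)).astype(float, copy=False)
    if cache is not None:
        cache[key] = out
    return out


def evaluate_chromosome(
    chrom: np.ndarray,
    X: np.ndarray,
    head_length: int,
    cache: Dict[bytes, np.ndarray] | None = None,
) -> np.ndarray:
    """Addition-linked chromosome value on each row of ``X`` (n rows, 7 columns)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != N_TERMINALS:
        raise ValueError(f"feature input must have {N_TERMINALS} columns, got {X.shape[1]}")
    if not np.isfinite(X).all():
        raise ValueError("feature input contains non-finite values")
    total = np.zeros(X.shape[0], dtype=float)
    for gene in np.asarray(chrom):
        total = total + evaluate_gene(gene, X, head_length, cache)
    return total


# --- rendering ---------------------------------------------------------------

_INFIX = {_ADD: "+", _SUB: "-"}


def _node_to_infix(codes, left, right, i: int) -> str:
    c = codes[i]
    if c >= N_FUNCTIONS:
        return SYMBOL_NAMES[c]
    if c in _INFIX:
        return f"({_node_to_infix(codes, left, right, left[i])} {_INFIX[c]} " \
               f"{_node_to_infix(codes, left, right, right[i])})"
    if c == _MUL:
        return (f"pmul({_node_to_infix(codes, left, right, left[i])}, "
                f"{_node_to_infix(codes, left, right, right[i])})")
    if c == _DIV:
        return (f"pdiv({_node_to_infix(codes, left, right, left[i])}, "
                f"{_node_to_infix(codes, left, right, right[i])})")
    name = {_SIN: "sin", _COS: "cos", _SQRT: "psqrt", _SQ: "sq",
            _INV: "pinv", _EXP: "pexp"}[c]
    return f"{name}({_node_to_infix(codes, left, right, left[i])})"


def gene_to_infix(gene: np.ndarray, head_length: int) -> str:
    """Human-readable infix rendering of one gene's coding region."""
    if not is_valid_gene(gene, head_length):
        raise ValueError("invalid gene")
    codes, left, right = compile_gene(gene)
    return _node_to_infix(codes, left, right, 0)


def chromosome_to_infix(chrom: np.ndarray, head_length: int) -> str:
    """Addition-linked formula string; evaluable in ``FORMULA_NAMESPACE``."""
    return " + ".join(gene_to_infix(g, head_length) for g in np.asarray(chrom))
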