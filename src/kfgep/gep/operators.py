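"""The seven genetic operators, each preserving head/tail validity.

Applied in a fixed, documented order so that runs are bit-reproducible:
point mutation, head inversion, IS transposition, RIS transposition, gene
transposition, then one-point, two-point and whole-gene recombination on
randomly paired parents.  Transposon lengths are drawn uniformly from
{1, 2, 3}.
"""

from __future__ import annotations

import numpy as np

from .config import GepConfig
from .genome import N_FUNCTIONS, N_SYMBOLS


def mutate(pop: np.ndarray, rate: float, head_length: int, rng: np.random.Generator) -> None:
    """Point mutation in place: each symbol flips with probability ``rate``.

    Head symbols move uniformly to any *other* symbol; tail symbols to any
    other terminal, so validity is preserved by construction.
    """
    if rate <= 0:
        return
    P, G, L = pop.shape
    mask = rng.random(pop.shape) < rate
    if not mask.any():
        return
    shift_head = rng.integers(1, N_SYMBOLS, size=pop.shape)
    shift_tail = rng.integers(1, 7, size=pop.shape)  # 7 terminals -> shift in 1..6
    head_mask = np.zeros(L, dtype=bool)
    head_mask[:head_length] = True
    hm = mask & head_mask[None, None, :]
    tm = mask & ~head_mask[None, None, :]
    pop[hm] = (pop[hm] + shift_head[hm]) % N_SYMBOLS
    t = pop[tm] - N_FUNCTIONS
    pop[tm] = (t + shift_tail[tm]) % 7 + N_FUNCTIONS


def invert(pop: np.ndarray, rate: float, head_length: int, rng: np.random.Generator) -> None:
    """Head-segment inversion: reverse a random slice of one gene's head."""
    P = pop.shape[0]
    hits = np.flatnonzero(rng.random(P) < rate)
    for c in hits:
        g = int(rng.integers(pop.shape[1]))
        if head_length < 2:
            continue
        i, j = np.sort(rng.choice(head_length, size=2, replace=False))
        pop[c, g, i : j + 1] = pop[c, g, i : j + 1][::-1]


def _transposon_length(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 4))


def is_transpose(pop: np.ndarray, rate: float, head_length: int, rng: np.random.Generator) -> None:
    """Insertion-sequence transposition: copy a random chromosome segment into a
    non-root head position of a random gene, shifting the head right and
    truncating at the head boundary (tail untouched)."""
    P, G, L = pop.shape
    hits = np.flatnonzero(rng.random(P) < rate)
    for c in hits:
        if head_length < 2:
            continue
        ln = _transposon_length(rng)
        src_gene = int(rng.integers(G))
        start = int(rng.integers(0, L - ln + 1))
        seg = pop[c, src_gene, start : start + ln].copy()
        tgt = int(rng.integers(G))
        pos = int(rng.integers(1, head_length))
        head = pop[c, tgt, :head_length]
        new_head = np.concatenate([head[:pos], seg, head[pos:]])[:head_length]
        pop[c, tgt, :head_length] = new_head


def ris_transpose(pop: np.ndarray, rate: float, head_length: int, rng: np.random.Generator) -> None:
    """Root insertion-sequence transposition: a function-started head segment
    is copied to the root of its gene; no-op if the scan finds no function."""
    P, G, L = pop.shape
    hits = np.flatnonzero(rng.random(P) < rate)
    for c in hits:
        g = int(rng.integers(G))
        scan = int(rng.integers(head_length))
        head = pop[c, g, :head_length]
        fpos = -1
        for k in range(scan, head_length):
            if head[k] < N_FUNCTIONS:
                fpos = k
                break
        if fpos < 0:
            continue
        ln = _transposon_length(rng)
        seg = pop[c, g, fpos : min(fpos + ln, head_length)].copy()
        new_head = np.concatenate([seg, head])[:head_length]
        pop[c, g, :head_length] = new_head


def gene_transpose(pop: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Move a randomly chosen non-first gene to the front of the chromosome."""
    P, G, _ = pop.shape
    if G < 2:
        return
    hits = np.flatnonzero(rng.random(P) < rate)
    for c in hits:
        g = int(rng.integers(1, G))
        moved = pop[c, g].copy()
        pop[c, 1 : g + 1] = pop[c, 0:g]
        pop[c, 0] = moved


def _pairs(P: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.permutation(P)
    n = P // 2
    return idx[: 2 * n].reshape(n, 2)


def one_point_recombine(pop: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    P, G, L = pop.shape
    for a, b in _pairs(P, rng):
        if rng.random() >= rate:
            continue
        q = int(rng.integers(1, G * L))
        fa, fb = pop[a].reshape(-1), pop[b].reshape(-1)
        fa[q:], fb[q:] = fb[q:].copy(), fa[q:].copy()


def two_point_recombine(pop: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    P, G, L = pop.shape
    for a, b in _pairs(P, rng):
        if rng.random() >= rate:
            continue
        q1, q2 = np.sort(rng.choice(G * L, size=2, replace=False))
        fa, fb = pop[a].reshape(-1), pop[b].reshape(-1)
        fa[q1:q2], fb[q1:q2] = fb[q1:q2].copy(), fa[q1:q2].copy()


def gene_recombine(pop: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    P, G, L = pop.shape
    for a, b in _pairs(P, rng):
        if rng.random() >= rate:
            continue
        g = int(rng.integers(G))
        pop[a, g], pop[b, g] = pop[b, g].copy(), pop[a, g].copy()


def apply_operators(pop: np.ndarray, config: GepConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply all seven operators (in the documented order) to a population.

    ``pop`` has shape (P, n_genes, gene_length); a modified copy is returned.

    All configured rates are *per genome symbol*.  Point mutation applies
    them directly, symbol by symbol.  The structural operators (inversion,
    the three transpositions, the three recombinations) act once per
    chromosome or per mating pair, so their per-symbol rates are converted
    to per-event probabilities ``min(1, rate * chromosome_length)`` —
    e.g. a 0.00546 inversion rate on a 186-symbol chromosome means about one
    inversion per chromosome per generation.
    """
    pop = np.array(pop, copy=True)
    h = config.head_length
    chrom_len = pop.shape[1] * pop.shape[2]

    def per_chrom(rate: float) -> float:
        return min(1.0, rate * chrom_len)

    mutate(pop, config.mutation_rate, h, rng)
    invert(pop, per_chrom(config.inversion_rate), h, rng)
    is_transpose(pop, per_chrom(config.is_rate), h, rng)
    ris_transpose(pop, per_chrom(config.ris_rate), h, rng)
    gene_transpose(pop, per_chrom(config.gene_transposition_rate), rng)
    one_point_recombine(pop, per_chrom(config.one_point_rate), rng)
    two_point_recombine(pop, per_chrom(config.two_point_rate), rng)
    gene_recombine(pop, per_chrom(config.gene_recombination_rate), rng)
    return pop
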