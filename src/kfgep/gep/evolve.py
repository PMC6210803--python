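"""The GEP evolutionary loop: roulette selection, one-elite preservation,
RMSE fitness, and early stopping on a stalled best score.

One :class:`numpy.random.Generator` seeded from the config drives the whole
run.  Draw order per generation: selection indices first, then the genetic
operators in the order documented in :mod:`kfgep.gep.operators` — so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .config import GepConfig
from .genome import (
    FORMULA_NAMESPACE,
    N_TERMINALS,
    evaluate_chromosome,
    evaluate_gene,
    gene_to_infix,
    random_population,
)
from .operators import apply_operators


def fitness_from_rmse(rmse, scale: float = 1000.0):
    """Selection fitness M/(1 + RMSE): strictly decreasing in RMSE, equal to
    M for a perfect fit."""
    return scale / (1.0 + np.asarray(rmse, dtype=float))


def chromosome_fitness(
    chrom: np.ndarray,
    features: np.ndarray,
    target: np.ndarray,
    head_length: int = 15,
    scale: float = 1000.0,
) -> float:
    """Fitness of one chromosome on data: M/(1 + RMSE) of its plain
    addition-linked prediction against ``target``."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.shape[0] != y.shape[0] or y.size == 0:
        raise ValueError("features and target must have matching nonzero length")
    pred = evaluate_chromosome(chrom, X, head_length)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return float(fitness_from_rmse(rmse, scale))


def affine_calibration(pred: np.ndarray, target: np.ndarray) -> Tuple[float, float]:
    """Closed-form least-squares (slope, intercept) mapping ``pred`` onto
    ``target``; slope 0 (constant model) when ``pred`` is degenerate."""
    pm = pred.mean()
    tm = target.mean()
    dp = pred - pm
    var = float(dp @ dp)
    if not np.isfinite(var) or var <= 1e-300 * pred.size:
        return 0.0, float(tm)
    slope = float(dp @ (target - tm)) / var
    if not np.isfinite(slope):
        return 0.0, float(tm)
    return slope, float(tm - slope * pm)


def weighted_linking(gene_values: np.ndarray, target: np.ndarray):
    """Least-squares linking coefficients for one chromosome.

    ``gene_values`` has one column per gene.  Returns ``(weights, intercept,
    rmse)`` minimizing ``||target - (gene_values @ weights + intercept)||``.
    Degenerate (constant or saturated) gene columns simply receive weight ~0
    via the minimum-norm solution, so no explicit zero-gene cancellation is
    ever required of the evolutionary search.
    """
    n, g = gene_values.shape
    # guard against saturated columns destroying the normal equations
    cols = np.where(np.isfinite(gene_values).all(axis=0), 1.0, 0.0)
    G = gene_values * cols
    scale = np.max(np.abs(G), axis=0)
    big = scale > 1e12
    if big.any():  # saturated genes carry no usable signal
        G = G.copy()
        G[:, big] = 0.0
    M = np.column_stack([G, np.ones(n)])
    coef, _, _, _ = np.linalg.lstsq(M, target, rcond=None)
    resid = target - M @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    if not np.isfinite(rmse):
        return np.zeros(g), float(target.mean()), float(target.std())
    return coef[:g], float(coef[g]), rmse


@dataclass
class GepModel:
    """A trained symbolic-regression model: genotype plus evaluable phenotype.

    The phenotype links the decoded genes additively with calibrated
    coefficients: ``sum_g weight_g * gene_g(T) + intercept``.  With
    ``linear_scaling=False`` the weights are all 1 and the intercept 0
    (plain addition linking).
    """

    genes: np.ndarray  # (n_genes, gene_length) int8
    head_length: int
    formula: str
    training_rmse: float
    gene_weights: np.ndarray | None = None
    intercept: float = 0.0
    config: GepConfig | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.gene_weights is None:
            self.gene_weights = np.ones(self.genes.shape[0])
        self.gene_weights = np.asarray(self.gene_weights, dtype=float)

    def _gene_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cache: Dict[bytes, np.ndarray] = {}
        cols = [
            evaluate_gene(g, X, self.head_length, cache=cache) for g in self.genes
        ]
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the model on rows of a (n, 7) feature matrix.

        Accumulates gene by gene in formula order so that the exported
        formula string reproduces the prediction bit for bit.
        """
        G = self._gene_values(X)
        acc = self.gene_weights[0] * G[:, 0]
        for j in range(1, G.shape[1]):
            acc = acc + self.gene_weights[j] * G[:, j]
        return acc + self.intercept

    def predict_formula(self, X: np.ndarray) -> np.ndarray:
        """Evaluate by re-parsing the exported formula string (round-trip check)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        env = {f"T{i + 1}": X[:, i] for i in range(N_TERMINALS)}
        out = eval(self.formula, dict(FORMULA_NAMESPACE), env)  # noqa: S307
        return np.broadcast_to(np.asarray(out, dtype=float), (X.shape[0],)).copy()

    def to_dict(self) -> dict:
        return {
            "genes": self.genes.tolist(),
            "head_length": int(self.head_length),
            "formula": self.formula,
            "training_rmse": float(self.training_rmse),
            "gene_weights": [float(w) for w in self.gene_weights],
            "intercept": float(self.intercept),
            "config": self.config.to_dict() if self.config is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GepModel":
        cfg = GepConfig.from_dict(d["config"]) if d.get("config") else None
        return cls(
            genes=np.asarray(d["genes"], dtype=np.int8),
            head_length=int(d["head_length"]),
            formula=d["formula"],
            training_rmse=float(d["training_rmse"]),
            gene_weights=d.get("gene_weights"),
            intercept=float(d.get("intercept", 0.0)),
            config=cfg,
        )


def _population_rmse(
    pop: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    head_length: int,
    gene_cache: Dict[bytes, np.ndarray],
    chrom_cache: Dict[bytes, float],
    linear_scaling: bool = False,
) -> np.ndarray:
    out = np.empty(pop.shape[0], dtype=float)
    for i, chrom in enumerate(pop):
        key = chrom.tobytes()
        hit = chrom_cache.get(key)
        if hit is not None:
            out[i] = hit
            continue
        if linear_scaling:
            G = np.column_stack(
                [evaluate_gene(g, X, head_length, cache=gene_cache) for g in chrom]
            )
            _, _, rmse = weighted_linking(G, y)
        else:
            pred = evaluate_chromosome(chrom, X, head_length, cache=gene_cache)
            with np.errstate(over="ignore"):
                rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        if not np.isfinite(rmse):  # enormous saturated predictions can overflow
            rmse = float(np.finfo(float).max / 4)
        chrom_cache[key] = rmse
        out[i] = rmse
    return out


def run_gep(
    features: np.ndarray,
    target: np.ndarray,
    config: GepConfig | None = None,
) -> Tuple[GepModel, np.ndarray]:
    """Evolve a symbolic model of ``target`` as a function of 7 RMS features.

    Parameters
    ----------
    features : (n, 7) array
        Training feature matrix (terminals T1..T7, one row per window).
    target : (n,) array
        Coordinate increments to model.
    config : GepConfig
        Engine configuration; defaults mirror the published setup.

    Returns
    -------
    (model, residuals)
        The best-ever model and its training residuals ``target - model(features)``.
    """
    config = config or GepConfig()
    config.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != N_TERMINALS:
        raise ValueError(f"features must be (n, {N_TERMINALS}), got {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"features rows ({X.shape[0]}) != target length ({y.shape[0]})")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")

    rng = np.random.default_rng(config.rng_seed)
    P = config.population_size
    pop = random_population(rng, P, config.n_genes, config.head_length)

    gene_cache: Dict[bytes, np.ndarray] = {}
    chrom_cache: Dict[bytes, float] = {}

    best_genes = None
    best_rmse = np.inf
    last_improvement_gen = 0
    history = []  # best-ever RMSE per generation (monotone non-increasing)

    for gen in range(config.n_generations):
        rmse = _population_rmse(
            pop, X, y, config.head_length, gene_cache, chrom_cache,
            linear_scaling=config.linear_scaling,
        )
        gen_best = int(np.argmin(rmse))
        if rmse[gen_best] < best_rmse - config.early_stop_tol:
            last_improvement_gen = gen
        if rmse[gen_best] < best_rmse:
            best_rmse = float(rmse[gen_best])
            best_genes = pop[gen_best].copy()
        history.append(best_rmse)
        if gen - last_improvement_gen >= config.early_stop_patience:
            break
        if gen == config.n_generations - 1:
            break
        # selection: keep the generation's best untouched, sample the rest
        fit = fitness_from_rmse(rmse, config.fitness_scale)
        if config.selection == "windowed":
            # roulette on fitness above the population minimum; the epsilon
            # keeps the wheel defined when all fitnesses coincide
            w = (fit - fit.min() + 1e-12 * (1.0 + fit.max())) ** config.selection_power
            chosen = rng.choice(P, size=P - 1, replace=True, p=w / w.sum())
        elif config.selection == "roulette":
            probs = fit / fit.sum()
            chosen = rng.choice(P, size=P - 1, replace=True, p=probs)
        else:  # tournament, size 2
            cand = rng.integers(0, P, size=(P - 1, 2))
            better = fit[cand[:, 0]] >= fit[cand[:, 1]]
            chosen = np.where(better, cand[:, 0], cand[:, 1])
        offspring = apply_operators(pop[chosen], config, rng)
        pop = np.concatenate([pop[gen_best][None], offspring], axis=0)
        if len(gene_cache) > 50_000:
            gene_cache.clear()
        if len(chrom_cache) > 50_000:
            chrom_cache.clear()

    assert best_genes is not None
    if config.linear_scaling:
        G = np.column_stack(
            [evaluate_gene(g, X, config.head_length, cache=gene_cache)
             for g in best_genes]
        )
        weights, intercept, _ = weighted_linking(G, y)
    else:
        weights = np.ones(best_genes.shape[0])
        intercept = 0.0
    formula = " + ".join(
        f"{float(w)!r}*({gene_to_infix(g, config.head_length)})"
        for w, g in zip(weights, best_genes)
    ) + f" + {float(intercept)!r}"
    model = GepModel(
        genes=best_genes,
        head_length=config.head_length,
        formula=formula,
        training_rmse=best_rmse,
        gene_weights=weights,
        intercept=intercept,
        config=config,
    )
    model.rmse_history = history  # per-generation best-ever trajectory
    residuals = y - model.predict(X)
    return model, residuals
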