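"""Run configuration for the GEP engine.

Defaults follow the published training configuration of the decoder this
package implements: 200 chromosomes of 6 genes, head length 15 (hence gene
length 31 for a max-arity-2 function set), addition linking, RMSE fitness,
and the per-operator rates listed below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

#: Function set available in gene heads (fixed; terminals are T1..T7).
DEFAULT_FUNCTIONS: Tuple[str, ...] = (
    "+", "-", "*", "/", "sin", "cos", "sqrt", "sq", "inv", "exp",
)

MAX_ARITY = 2


def tail_length(head_length: int, max_arity: int = MAX_ARITY) -> int:
    """Karva tail length t = h*(a-1) + 1 guaranteeing every head decodes."""
    return head_length * (max_arity - 1) + 1


@dataclass
class GepConfig:
    """Hyper-parameters of one GEP run.

    Rates are probabilities: ``mutation_rate`` applies per genome symbol,
    inversion/transposition rates per chromosome per generation, and the
    recombination rates per mating pair.
    """

    population_size: int = 200
    n_genes: int = 6
    head_length: int = 15
    n_terminals: int = 7
    n_generations: int = 200
    mutation_rate: float = 0.00138
    inversion_rate: float = 0.00546
    is_rate: float = 0.00546
    ris_rate: float = 0.00546
    gene_transposition_rate: float = 0.00546
    one_point_rate: float = 0.00277
    two_point_rate: float = 0.00277
    gene_recombination_rate: float = 0.00277
    fitness_scale: float = 1000.0  # selection fitness = scale / (1 + RMSE)
    selection: str = "windowed"  # "windowed" | "roulette" | "tournament"
    selection_power: float = 3.0  # exponent on the windowed roulette weights
    linear_scaling: bool = True  # affine output calibration inside the fitness
    early_stop_patience: int = 50
    early_stop_tol: float = 1e-8
    rng_seed: int = 0
    function_set: Tuple[str, ...] = field(default=DEFAULT_FUNCTIONS)

    @property
    def tail_length(self) -> int:
        return tail_length(self.head_length)

    @property
    def gene_length(self) -> int:
        return self.head_length + self.tail_length

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_genes < 1 or self.head_length < 1:
            raise ValueError("n_genes and head_length must be positive")
        if self.n_terminals < 1:
            raise ValueError("n_terminals must be positive")
        if self.n_generations < 1:
            raise ValueError("n_generations must be positive")
        for name in (
            "mutation_rate", "inversion_rate", "is_rate", "ris_rate",
            "gene_transposition_rate", "one_point_rate", "two_point_rate",
            "gene_recombination_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if self.selection not in ("windowed", "roulette", "tournament"):
            raise ValueError(f"unknown selection scheme {self.selection!r}")
        if tuple(self.function_set) != DEFAULT_FUNCTIONS:
            raise ValueError(
                "the function set is fixed to "
                f"{DEFAULT_FUNCTIONS}; got {self.function_set}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["function_set"] = list(self.function_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GepConfig":
        d = dict(d)
        if "function_set" in d:
            d["function_set"] = tuple(d["function_set"])
        return cls(**d)
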