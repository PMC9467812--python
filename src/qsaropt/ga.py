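"""Binary-coded genetic algorithm over the normalized descriptor box [0, 1]^d.

Each decision variable (gene) is a 20-bit unsigned integer decoded to
``value / (2^20 - 1)``, so every candidate satisfies the box constraint by
construction.  Part of the initial population is seeded by encoding rows of
the (normalized) training corpus; the rest is random bit strings.  Each
generation evaluates fitness in one batched surrogate call, selects parents
by roulette (fitness-proportionate) sampling, applies single-point crossover
and independent per-bit mutation, and carries the elite through unchanged —
making the best-so-far trace monotone non-decreasing.

Defaults follow the published solver configuration: population 2000,
500 generations, 224 genes of 20 bits, crossover rate 0.6, mutation rate 0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd


@dataclass
class GAConfig:
    population_size: int = 2000
    generations: int = 500
    n_genes: int = 224
    bits_per_gene: int = 20
    crossover_rate: float = 0.6
    mutation_rate: float = 0.1
    mutation_mode: str = "per_gene"  # or "per_bit"
    elite_count: int = 1
    seeded_fraction: float | None = None  # None: seed min(data rows, population)
    seed: int = 0

    def validate(self) -> None:
        if min(self.population_size, self.generations + 1, self.n_genes, self.bits_per_gene) <= 0:
            raise ValueError("counts must be positive (generations may be 0)")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.mutation_mode not in ("per_gene", "per_bit"):
            raise ValueError("mutation_mode must be 'per_gene' or 'per_bit'")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite count must be smaller than the population")
        if self.seeded_fraction is not None and not 0 <= self.seeded_fraction <= 1:
            raise ValueError("seeded_fraction must lie in [0, 1]")

    @property
    def n_bits(self) -> int:
        return self.n_genes * self.bits_per_gene


@dataclass
class OptimizationResult:
    best_vector: np.ndarray  # normalized units
    best_fitness: float
    trace: list[float]  # best-so-far fitness per generation
    config: GAConfig
    best_vector_real: np.ndarray | None = None
    feature_names: list[str] | None = None
    feasibility: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "best_fitness": self.best_fitness,
            "best_vector": self.best_vector.tolist(),
            "best_vector_real": None
            if self.best_vector_real is None
            else self.best_vector_real.tolist(),
            "feature_names": self.feature_names,
            "trace": self.trace,
            "config": asdict(self.config),
            "feasibility": self.feasibility,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def candidate_table(self) -> pd.DataFrame:
        """Report-shaped table: descriptor, normalized value, real value."""
        names = self.feature_names or [f"x{i + 1}" for i in range(self.best_vector.size)]
        real = self.best_vector_real if self.best_vector_real is not None else [np.nan] * len(names)
        return pd.DataFrame(
            {"descriptor": names, "normalized": self.best_vector, "real": real}
        )


# -- encoding ---------------------------------------------------------------

def encode(x: np.ndarray, bits: int) -> np.ndarray:
    """[0, 1]^d vector -> flat bit string (MSB first per gene)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any() or (x > 1).any():
        raise ValueError("coordinates must lie in [0, 1]")
    levels = (1 << bits) - 1
    ints = np.rint(x * levels).astype(np.int64)
    shifts = np.arange(bits - 1, -1, -1)
    return ((ints[:, None] >> shifts[None, :]) & 1).astype(np.uint8).reshape(-1)


def decode(chromosome: np.ndarray, bits: int) -> np.ndarray:
    """Flat bit string -> [0, 1]^d via integer / (2^bits - 1)."""
    c = np.asarray(chromosome, dtype=np.uint8)
    if c.ndim == 1:
        return decode(c[None, :], bits)[0]
    if c.shape[-1] % bits:
        raise ValueError(f"bit-string length {c.shape[-1]} is not a multiple of {bits}")
    genes = c.reshape(c.shape[0], -1, bits)
    weights = (1 << np.arange(bits - 1, -1, -1)).astype(np.float64)
    return genes @ weights / ((1 << bits) - 1)


# -- operators --------------------------------------------------------------

def init_population(
    data: pd.DataFrame | np.ndarray | None, cfg: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """(population, n_bits) uint8 array; part data-seeded, part random."""
    pop = np.empty((cfg.population_size, cfg.n_bits), dtype=np.uint8)
    rows = None
    if data is not None:
        rows = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
        if rows.shape[1] != cfg.n_genes:
            raise ValueError(f"data has {rows.shape[1]} variables, config expects {cfg.n_genes}")
    if cfg.seeded_fraction is None:
        n_seeded = 0 if rows is None else min(len(rows), cfg.population_size)
    else:
        n_seeded = int(round(cfg.seeded_fraction * cfg.population_size))
        if n_seeded and rows is None:
            raise ValueError("cannot seed the population without data")
    if n_seeded:
        picks = (
            rng.choice(len(rows), size=n_seeded, replace=False)
            if n_seeded <= len(rows)
            else rng.integers(0, len(rows), size=n_seeded)
        )
        for i, r in enumerate(picks):
            pop[i] = encode(np.clip(rows[r], 0.0, 1.0), cfg.bits_per_gene)
    if n_seeded < cfg.population_size:
        pop[n_seeded:] = rng.integers(
            0, 2, size=(cfg.population_size - n_seeded, cfg.n_bits), dtype=np.uint8
        )
    return pop


def roulette_select(
    fitnesses: np.ndarray, n_parents: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-proportionate parent indices; uniform fallback at zero total."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("empty population")
    if (f < 0).any():
        raise ValueError("roulette selection requires nonnegative fitness")
    total = f.sum()
    p = np.full(f.size, 1.0 / f.size) if total == 0 else f / total
    return rng.choice(f.size, size=n_parents, p=p)


def crossover(
    a: np.ndarray, b: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover with probability ``rate``; else parent copies."""
    if a.shape != b.shape:
        raise ValueError("parent length mismatch")
    if rng.uniform() >= rate:
        return a.copy(), b.copy()
    cut = rng.integers(1, a.size)
    return (
        np.concatenate([a[:cut], b[cut:]]),
        np.concatenate([b[:cut], a[cut:]]),
    )


def mutate(
    c: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    mode: str = "per_bit",
    bits_per_gene: int | None = None,
) -> np.ndarray:
    """Bit-flip mutation.

    ``per_bit``: every bit flips independently with probability ``rate``.
    ``per_gene``: each gene mutates with probability ``rate``; a mutated gene
    has one uniformly chosen bit flipped.  The per-gene reading keeps children
    near their parents (a 20-bit gene moves by ~5% of its range on average),
    which matches a solver whose optimum ends just above the corpus maximum;
    flipping 10% of *all* bits would amount to a random restart every child.
    """
    if rate == 0:
        return c.copy()
    if mode == "per_bit":
        flips = rng.uniform(size=c.shape) < rate
        return np.where(flips, 1 - c, c).astype(np.uint8)
    if mode != "per_gene":
        raise ValueError(f"unknown mutation mode {mode!r}")
    if not bits_per_gene or c.size % bits_per_gene:
        raise ValueError("per-gene mutation needs a bits_per_gene dividing the string")
    out = c.copy()
    n_genes = c.size // bits_per_gene
    hit = rng.uniform(size=n_genes) < rate
    for g in np.nonzero(hit)[0]:
        pos = g * bits_per_gene + rng.integers(bits_per_gene)
        out[pos] ^= 1
    return out


# -- driver -----------------------------------------------------------------

def run_ga(
    fitness_fn: Callable[[np.ndarray], np.ndarray],
    data: pd.DataFrame | np.ndarray | None,
    cfg: GAConfig,
) -> OptimizationResult:
    """Generational GA loop: evaluate, select, cross, mutate, keep the elite.

    ``fitness_fn`` maps a (n, n_genes) matrix of decoded candidates to a
    nonnegative fitness vector in one batched call.  Fitness values are
    cached per genotype, so surviving chromosomes are not re-scored.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 23)))
    pop = init_population(data, cfg, rng)
    cache: dict[bytes, float] = {}

    def evaluate(population: np.ndarray) -> np.ndarray:
        keys = [row.tobytes() for row in population]
        fresh = [i for i, k in enumerate(keys) if k not in cache]
        if fresh:
            vals = np.asarray(fitness_fn(decode(population[fresh], cfg.bits_per_gene)), dtype=float)
            if not np.isfinite(vals).all():
                bad = decode(population[fresh][int(np.argmax(~np.isfinite(vals)))], cfg.bits_per_gene)
                raise FloatingPointError(f"non-finite fitness at candidate {bad}")
            for i, v in zip(fresh, vals):
                cache[keys[i]] = float(v)
        return np.array([cache[k] for k in keys])

    fit = evaluate(pop)
    best_idx = int(np.argmax(fit))
    best_bits, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    trace: list[float] = []

    for _ in range(cfg.generations):
        n_children = cfg.population_size - cfg.elite_count
        parents = roulette_select(fit, 2 * ((n_children + 1) // 2), rng)
        children = []
        for i in range(0, parents.size, 2):
            c1, c2 = crossover(pop[parents[i]], pop[parents[i + 1]], cfg.crossover_rate, rng)
            for child in (c1, c2):
                children.append(
                    mutate(child, cfg.mutation_rate, rng, cfg.mutation_mode, cfg.bits_per_gene)
                )
        new_pop = np.array(children[:n_children], dtype=np.uint8)
        if cfg.elite_count:
            elite = pop[np.argsort(fit)[::-1][: cfg.elite_count]]
            new_pop = np.vstack([elite, new_pop])
        pop = new_pop
        cache.clear()  # cache lives within a generation; keeps memory flat
        fit = evaluate(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_bits = pop[gen_best].copy()
        trace.append(best_fit)

    return OptimizationResult(
        best_vector=decode(best_bits, cfg.bits_per_gene),
        best_fitness=best_fit,
        trace=trace,
        config=cfg,
    )
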