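"""Gene Expression Programming (GEP) engine.

GEP evolves computer programs encoded as fixed-length linear genomes in
Karva notation.  Each gene is a string of ``h`` head symbols (functions or
terminals) followed by ``t = h*(a_max - 1) + 1`` tail symbols (terminals
only), where ``a_max`` is the maximum function arity.  This head/tail rule
gives *closure*: any gene decodes to a valid expression tree by level-order
(breadth-first) reading — symbol 0 is the root and each function node
consumes the next unread symbols as its children.  Symbols past the end of
the coding region are silently non-coding, which lets blind genetic
operators rearrange genomes freely without ever producing an invalid
program.

A chromosome holds several genes (default three) whose sub-trees are
combined by an associative linking function (addition here).  Fitness of a
candidate on ``m`` fitness cases with outputs ``F_ij`` and targets ``T_j``
is::

    fitness_i = 1000 / (MSE_i + 1),   MSE_i = (1/m) * sum_j (F_ij - T_j)^2

so a perfect fit scores exactly 1000.  Evolution is roulette-wheel
selection with single-individual elitism plus the eight canonical
operators: point mutation, head-segment inversion, IS/RIS/gene
transposition, and one-point/two-point/whole-gene recombination.  It stops
when the best fitness reaches 1000 or the generation budget runs out.

Arithmetic is protected to preserve closure: ``sqrt`` acts on ``|x|``,
``exp`` clips its argument to [-50, 50], and division by a near-zero
denominator yields a non-finite sentinel.  A chromosome producing any
non-finite output on any fitness case receives fitness 0 rather than a
substitute value, which penalizes fragile programs without biasing the
search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io import ParameterError

__all__ = [
    "SymbolSet",
    "Gene",
    "Chromosome",
    "GEPConfig",
    "FitnessReport",
    "default_symbol_set",
    "tail_length",
    "random_gene",
    "random_chromosome",
    "decode",
    "evaluate_gene",
    "evaluate",
    "fitness",
    "mutate",
    "invert",
    "is_transpose",
    "ris_transpose",
    "gene_transpose",
    "one_point_recombine",
    "two_point_recombine",
    "gene_recombine",
    "evolve",
    "predict_binary",
    "save_chromosome",
    "load_chromosome",
]

_DIV_EPS = 1e-12
_EXP_CLIP = 50.0


def _p_div(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Protected division: near-zero denominators yield NaN sentinels."""
    with np.errstate(all="ignore"):
        return np.where(np.abs(b) < _DIV_EPS, np.nan, a / np.where(b == 0, 1.0, b))


def _p_sqrt(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.abs(a))


def _p_exp(a: np.ndarray) -> np.ndarray:
    with np.errstate(all="ignore"):
        return np.exp(np.clip(a, -_EXP_CLIP, _EXP_CLIP))


def _add(a, b):
    with np.errstate(all="ignore"):
        return a + b


def _sub(a, b):
    with np.errstate(all="ignore"):
        return a - b


def _mul(a, b):
    with np.errstate(all="ignore"):
        return a * b


def _sin(a):
    return np.sin(a)


def _cos(a):
    return np.cos(a)


#: Registry of every function symbol the engine knows: symbol -> (arity, impl).
FUNCTION_REGISTRY: dict[str, tuple[int, Callable]] = {
    "+": (2, _add),
    "-": (2, _sub),
    "*": (2, _mul),
    "/": (2, _p_div),
    "sin": (1, _sin),
    "cos": (1, _cos),
    "sqrt": (1, _p_sqrt),
    "exp": (1, _p_exp),
}


@dataclass(frozen=True)
class SymbolSet:
    """Function and terminal alphabets shared by all genes of a run."""

    functions: tuple[str, ...]
    terminals: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "functions", tuple(self.functions))
        object.__setattr__(self, "terminals", tuple(self.terminals))
        for f in self.functions:
            if f not in FUNCTION_REGISTRY:
                raise ParameterError(f"unknown function symbol {f!r}")
        all_syms = self.functions + self.terminals
        if len(set(all_syms)) != len(all_syms):
            raise ParameterError("function/terminal symbols must be unique")
        if not self.terminals:
            raise ParameterError("need at least one terminal")
        if not self.functions:
            raise ParameterError("need at least one function")

    @property
    def a_max(self) -> int:
        return max(FUNCTION_REGISTRY[f][0] for f in self.functions)

    def arity(self, symbol: str) -> int:
        if symbol in FUNCTION_REGISTRY and symbol in self.functions:
            return FUNCTION_REGISTRY[symbol][0]
        return 0

    @property
    def head_alphabet(self) -> tuple[str, ...]:
        return self.functions + self.terminals

    def terminal_index(self, symbol: str) -> int:
        return self.terminals.index(symbol)


def default_symbol_set(n_terminals: int = 12) -> SymbolSet:
    """The standard alphabet: {+, -, *, /, sin, cos, sqrt, exp} over
    terminals ``x1 .. xN`` (default twelve, one per principal component)."""
    if n_terminals < 1:
        raise ParameterError("need at least one terminal")
    return SymbolSet(
        functions=("+", "-", "*", "/", "sin", "cos", "sqrt", "exp"),
        terminals=tuple(f"x{i + 1}" for i in range(n_terminals)),
    )


def tail_length(h: int, a_max: int) -> int:
    """Karva gene-validity rule: ``t = h*(a_max - 1) + 1``.

    A head of ``h`` function slots of maximum arity ``a_max`` can demand at
    most that many terminals, so this tail always completes the tree.
    """
    if h < 1 or a_max < 1:
        raise ParameterError("h and a_max must be >= 1")
    return h * (a_max - 1) + 1


@dataclass(frozen=True)
class Gene:
    """One fixed-length Karva genome segment: ``h`` head + ``t`` tail symbols."""

    symbols: tuple[str, ...]
    h: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def head(self) -> tuple[str, ...]:
        return self.symbols[: self.h]

    @property
    def tail(self) -> tuple[str, ...]:
        return self.symbols[self.h :]

    def is_valid(self, sset: SymbolSet) -> bool:
        if len(self.symbols) != self.h + tail_length(self.h, sset.a_max):
            return False
        head_ok = all(s in sset.head_alphabet for s in self.head)
        tail_ok = all(s in sset.terminals for s in self.tail)
        return head_ok and tail_ok


@dataclass(frozen=True)
class Chromosome:
    """Multigenic genome; sub-trees are linked by addition."""

    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ParameterError("chromosome needs at least one gene")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def is_valid(self, sset: SymbolSet) -> bool:
        return all(g.is_valid(sset) for g in self.genes)

    def flat_symbols(self) -> list[str]:
        out: list[str] = []
        for g in self.genes:
            out.extend(g.symbols)
        return out


def _chromosome_from_flat(flat: Sequence[str], template: Chromosome) -> Chromosome:
    genes = []
    pos = 0
    for g in template.genes:
        n = len(g.symbols)
        genes.append(Gene(symbols=tuple(flat[pos : pos + n]), h=g.h))
        pos += n
    return Chromosome(genes=tuple(genes))


@dataclass
class GEPConfig:
    """Evolution hyperparameters (canonical defaults of the method)."""

    population_size: int = 50
    h: int = 15
    n_genes: int = 3
    max_generations: int = 2000
    mutation_rate: float = 0.044
    inversion_rate: float = 0.05
    is_rate: float = 0.05
    ris_rate: float = 0.05
    gene_transposition_rate: float = 0.05
    one_point_rate: float = 0.2
    two_point_rate: float = 0.2
    gene_recombination_rate: float = 0.05
    rounding_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ParameterError("population_size must be >= 2")
        if self.h < 1 or self.n_genes < 1 or self.max_generations < 0:
            raise ParameterError("h, n_genes must be >= 1 and max_generations >= 0")
        for name in (
            "mutation_rate",
            "inversion_rate",
            "is_rate",
            "ris_rate",
            "gene_transposition_rate",
            "one_point_rate",
            "two_point_rate",
            "gene_recombination_rate",
        ):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {r}")


# ---------------------------------------------------------------------------
# Initialization


def random_gene(sset: SymbolSet, h: int, rng: np.random.Generator) -> Gene:
    """Uniform random gene: head over functions+terminals, tail over terminals."""
    t = tail_length(h, sset.a_max)
    head = rng.choice(len(sset.head_alphabet), size=h)
    tail = rng.choice(len(sset.terminals), size=t)
    symbols = tuple(sset.head_alphabet[i] for i in head) + tuple(
        sset.terminals[i] for i in tail
    )
    return Gene(symbols=symbols, h=h)


def random_chromosome(sset: SymbolSet, cfg: GEPConfig, rng: np.random.Generator) -> Chromosome:
    return Chromosome(genes=tuple(random_gene(sset, cfg.h, rng) for _ in range(cfg.n_genes)))


# ---------------------------------------------------------------------------
# Decoding and evaluation

# Decoded-program cache: gene symbol tuples recur heavily across a
# converging population, and decoding is pure.
_DECODE_CACHE: dict[tuple, list[tuple[str, tuple[int, ...]]]] = {}
_DECODE_CACHE_MAX = 50_000


def decode(gene: Gene, sset: SymbolSet) -> list[tuple[str, tuple[int, ...]]]:
    """Level-order Karva decoding of a gene's coding region.

    Returns the expression tree as a list of ``(symbol, child_indices)``
    nodes in breadth-first order; node 0 is the root and children of node
    ``i`` are the next unread symbol positions, queue order.  Trailing
    non-coding symbols are ignored.
    """
    key = gene.symbols
    cached = _DECODE_CACHE.get(key)
    if cached is not None:
        return cached
    symbols = gene.symbols
    nodes: list[tuple[str, tuple[int, ...]]] = []
    n_assigned = 1
    pos = 0
    while pos < n_assigned:
        sym = symbols[pos]
        ar = sset.arity(sym)
        children = tuple(range(n_assigned, n_assigned + ar))
        nodes.append((sym, children))
        n_assigned += ar
        pos += 1
    if len(_DECODE_CACHE) >= _DECODE_CACHE_MAX:
        _DECODE_CACHE.clear()
    _DECODE_CACHE[key] = nodes
    return nodes


def evaluate_gene(gene: Gene, sset: SymbolSet, X: np.ndarray) -> np.ndarray:
    """Evaluate one gene's tree on an ``(m, n_terminals)`` input matrix.

    Returns an ``(m,)`` output vector; non-finite values mark protected-
    arithmetic sentinels and propagate to the caller unchanged.
    """
    nodes = decode(gene, sset)
    vals: list[np.ndarray | None] = [None] * len(nodes)
    for i in range(len(nodes) - 1, -1, -1):
        sym, children = nodes[i]
        if not children:
            vals[i] = X[:, sset.terminal_index(sym)]
        else:
            impl = FUNCTION_REGISTRY[sym][1]
            vals[i] = impl(*(vals[c] for c in children))
    return np.asarray(vals[0], dtype=float)


def evaluate(chromosome: Chromosome, sset: SymbolSet, x: np.ndarray) -> np.ndarray | float:
    """Chromosome output: addition-linked sum of its genes' tree outputs.

    ``x`` may be one input vector of length ``n_terminals`` (returns a
    scalar) or a matrix of fitness cases (returns a vector).  Non-finite
    outputs are returned as-is; callers decide how to penalize them.
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    X = arr[None, :] if single else arr
    if X.shape[1] != len(sset.terminals):
        raise ParameterError(
            f"input has {X.shape[1]} variables, symbol set has {len(sset.terminals)} terminals"
        )
    with np.errstate(all="ignore"):
        total = evaluate_gene(chromosome.genes[0], sset, X).copy()
        for g in chromosome.genes[1:]:
            total += evaluate_gene(g, sset, X)
    return float(total[0]) if single else total


@dataclass(frozen=True)
class FitnessReport:
    """Fitness and its underlying mean squared error over ``m`` cases."""

    fitness: float
    mse: float
    m: int


def fitness(
    chromosome: Chromosome,
    sset: SymbolSet,
    X: np.ndarray,
    T: np.ndarray,
) -> FitnessReport:
    """Fitness ``1000 / (MSE + 1)`` over the fitness cases ``(X, T)``.

    A perfect fit (all outputs equal to targets) scores exactly 1000; any
    non-finite output on any case scores 0.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ParameterError("need at least one fitness case")
    if T.shape[0] != X.shape[0]:
        raise ParameterError("X and T must have equal numbers of cases")
    out = evaluate(chromosome, sset, X)
    if not np.all(np.isfinite(out)):
        return FitnessReport(fitness=0.0, mse=float("inf"), m=X.shape[0])
    mse = float(np.mean((out - T) ** 2))
    return FitnessReport(fitness=1000.0 / (mse + 1.0), mse=mse, m=X.shape[0])


# ---------------------------------------------------------------------------
# Genetic operators.  All are population-level, preserve the head/tail
# symbol domains (closure), and draw every random decision from the given
# generator so evolution is bit-reproducible under a fixed seed.

_TRANSPOSON_LENGTHS = (1, 2, 3)


def mutate(
    pop: list[Chromosome], rate: float, sset: SymbolSet, rng: np.random.Generator
) -> list[Chromosome]:
    """Point mutation: each symbol flips with probability ``rate`` to a
    *different* symbol of its domain (head: functions+terminals; tail:
    terminals only)."""
    if rate == 0.0:
        return list(pop)
    head_alpha = sset.head_alphabet
    term_alpha = sset.terminals
    out = []
    for c in pop:
        genes = []
        changed = False
        for g in c.genes:
            mask = rng.random(len(g.symbols)) < rate
            if not mask.any():
                genes.append(g)
                continue
            syms = list(g.symbols)
            for pos in np.flatnonzero(mask):
                domain = head_alpha if pos < g.h else term_alpha
                options = [s for s in domain if s != syms[pos]]
                if options:
                    syms[pos] = options[int(rng.integers(len(options)))]
                    changed = True
            genes.append(Gene(symbols=tuple(syms), h=g.h))
        out.append(Chromosome(genes=tuple(genes)) if changed else c)
    return out


def invert(
    pop: list[Chromosome], rate: float, rng: np.random.Generator
) -> list[Chromosome]:
    """Head inversion: with probability ``rate`` per chromosome, reverse a
    random segment of one gene's head."""
    out = []
    for c in pop:
        if rng.random() >= rate:
            out.append(c)
            continue
        gi = int(rng.integers(c.n_genes))
        g = c.genes[gi]
        if g.h < 2:
            out.append(c)
            continue
        start = int(rng.integers(0, g.h - 1))
        end = int(rng.integers(start + 1, g.h))  # inclusive
        syms = list(g.symbols)
        syms[start : end + 1] = syms[start : end + 1][::-1]
        genes = list(c.genes)
        genes[gi] = Gene(symbols=tuple(syms), h=g.h)
        out.append(Chromosome(genes=tuple(genes)))
    return out


def _insert_into_head(g: Gene, transposon: Sequence[str], site: int) -> Gene:
    head = list(g.head)
    new_head = head[:site] + list(transposon) + head[site:]
    return Gene(symbols=tuple(new_head[: g.h]) + g.tail, h=g.h)


def is_transpose(
    pop: list[Chromosome], rate: float, rng: np.random.Generator
) -> list[Chromosome]:
    """Insertion-sequence transposition: a short random transposon (from
    anywhere in the chromosome) is copied into a non-root head position;
    downstream head symbols shift and the head is re-truncated to ``h``."""
    out = []
    for c in pop:
        if rng.random() >= rate:
            out.append(c)
            continue
        flat = c.flat_symbols()
        pos = int(rng.integers(len(flat)))
        length = int(rng.choice(_TRANSPOSON_LENGTHS))
        transposon = flat[pos : pos + length]
        gi = int(rng.integers(c.n_genes))
        g = c.genes[gi]
        if g.h < 2:
            out.append(c)
            continue
        site = int(rng.integers(1, g.h))  # never the root
        genes = list(c.genes)
        genes[gi] = _insert_into_head(g, transposon, site)
        out.append(Chromosome(genes=tuple(genes)))
    return out


def ris_transpose(
    pop: list[Chromosome], rate: float, sset: SymbolSet, rng: np.random.Generator
) -> list[Chromosome]:
    """Root-insertion-sequence transposition: scan one gene's head from a
    random point for a function symbol; the transposon starting there is
    inserted at the gene root.  No function found -> no change."""
    out = []
    for c in pop:
        if rng.random() >= rate:
            out.append(c)
            continue
        gi = int(rng.integers(c.n_genes))
        g = c.genes[gi]
        start = int(rng.integers(g.h))
        fpos = next(
            (p for p in range(start, g.h) if sset.arity(g.symbols[p]) > 0), None
        )
        if fpos is None:
            out.append(c)
            continue
        length = int(rng.choice(_TRANSPOSON_LENGTHS))
        transposon = list(g.symbols[fpos : fpos + length])
        genes = list(c.genes)
        genes[gi] = _insert_into_head(g, transposon, 0)
        out.append(Chromosome(genes=tuple(genes)))
    return out


def gene_transpose(
    pop: list[Chromosome], rate: float, rng: np.random.Generator
) -> list[Chromosome]:
    """Whole-gene transposition: a random non-first gene moves to the front
    (order matters only for readability — linking is associative)."""
    out = []
    for c in pop:
        if c.n_genes < 2 or rng.random() >= rate:
            out.append(c)
            continue
        gi = int(rng.integers(1, c.n_genes))
        genes = list(c.genes)
        moved = genes.pop(gi)
        out.append(Chromosome(genes=tuple([moved] + genes)))
    return out


def _paired(pop: list[Chromosome]) -> list[tuple[int, int]]:
    return [(i, i + 1) for i in range(0, len(pop) - 1, 2)]


def one_point_recombine(
    pop: list[Chromosome], rate: float, rng: np.random.Generator
) -> list[Chromosome]:
    """One-point recombination over the flattened chromosome string."""
    out = list(pop)
    for i, j in _paired(pop):
        if rng.random() >= rate:
            continue
        a, b = out[i].flat_symbols(), out[j].flat_symbols()
        point = int(rng.integers(1, len(a)))
        a2 = a[:point] + b[point:]
        b2 = b[:point] + a[point:]
        out[i] = _chromosome_from_flat(a2, pop[i])
        out[j] = _chromosome_from_flat(b2, pop[j])
    return out


def two_point_recombine(
    pop: list[Chromosome], rate: float, rng: np.random.Generator
) -> list[Chromosome]:
    """Two-point recombination: the segment between two cut points is
    exchanged between the paired parents."""
    out = list(pop)
    for i, j in _paired(pop):
        if rng.random() >= rate:
            continue
        a, b = out[i].flat_symbols(), out[j].flat_symbols()
        p1, p2 = sorted(rng.choice(np.arange(1, len(a)), size=2, replace=False).tolist())
        a2 = a[:p1] + b[p1:p2] + a[p2:]
        b2 = b[:p1] + a[p1:p2] + b[p2:]
        out[i] = _chromosome_from_flat(a2, pop[i])
        out[j] = _chromosome_from_flat(b2, pop[j])
    return out


def gene_recombine(
    pop: list[Chromosome], rate: float, rng: np.random.Generator
) -> list[Chromosome]:
    """Whole-gene recombination: one aligned gene swaps between parents."""
    out = list(pop)
    for i, j in _paired(pop):
        if rng.random() >= rate:
            continue
        gi = int(rng.integers(out[i].n_genes))
        ga, gb = list(out[i].genes), list(out[j].genes)
        ga[gi], gb[gi] = gb[gi], ga[gi]
        out[i] = Chromosome(genes=tuple(ga))
        out[j] = Chromosome(genes=tuple(gb))
    return out


# ---------------------------------------------------------------------------
# Evolution loop


def _select(
    pop: list[Chromosome], fits: np.ndarray, rng: np.random.Generator
) -> list[Chromosome]:
    """Roulette-wheel (fitness-proportional) selection with replacement.
    An all-zero-fitness population falls back to uniform selection."""
    total = fits.sum()
    if total <= 0:
        probs = None
    else:
        probs = fits / total
    idx = rng.choice(len(pop), size=len(pop), replace=True, p=probs)
    return [pop[i] for i in idx]


def evolve(
    X: np.ndarray,
    T: np.ndarray,
    sset: SymbolSet,
    cfg: GEPConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Chromosome, FitnessReport, dict[str, list[float]]]:
    """Evolve a chromosome that maps fitness-case inputs to targets.

    Returns the best individual ever seen (elitism makes best-so-far
    fitness non-decreasing), its fitness report, and a history of best and
    mean population fitness per generation.  Terminates when fitness
    reaches the 1000 maximum or after ``max_generations`` breeding steps.
    """
    cfg = cfg or GEPConfig()
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ParameterError("need a non-empty (m, n_terminals) fitness-case matrix")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    gene_out: dict[tuple, np.ndarray] = {}

    def chrom_fitness(c: Chromosome) -> tuple[float, float]:
        with np.errstate(all="ignore"):
            total = None
            for g in c.genes:
                out = gene_out.get(g.symbols)
                if out is None:
                    out = evaluate_gene(g, sset, X)
                    if len(gene_out) > 100_000:
                        gene_out.clear()
                    gene_out[g.symbols] = out
                total = out.copy() if total is None else total + out
        if not np.all(np.isfinite(total)):
            return 0.0, float("inf")
        mse = float(np.mean((total - T) ** 2))
        return 1000.0 / (mse + 1.0), mse

    pop = [random_chromosome(sset, cfg, rng) for _ in range(cfg.population_size)]
    best: Chromosome | None = None
    best_fit = -1.0
    best_mse = float("inf")
    history: dict[str, list[float]] = {"best": [], "mean": []}

    for gen in range(cfg.max_generations + 1):
        stats = [chrom_fitness(c) for c in pop]
        fits = np.array([s[0] for s in stats])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mse = stats[gen_best][1]
            best = pop[gen_best]
        history["best"].append(best_fit)
        history["mean"].append(float(fits.mean()))
        if best_mse == 0.0 or gen == cfg.max_generations:
            break
        pop = _select(pop, fits, rng)
        pop = mutate(pop, cfg.mutation_rate, sset, rng)
        pop = invert(pop, cfg.inversion_rate, rng)
        pop = is_transpose(pop, cfg.is_rate, rng)
        pop = ris_transpose(pop, cfg.ris_rate, sset, rng)
        pop = gene_transpose(pop, cfg.gene_transposition_rate, rng)
        pop = one_point_recombine(pop, cfg.one_point_rate, rng)
        pop = two_point_recombine(pop, cfg.two_point_rate, rng)
        pop = gene_recombine(pop, cfg.gene_recombination_rate, rng)
        pop[0] = best  # elitism: the best individual survives unchanged

    assert best is not None
    report = FitnessReport(fitness=best_fit, mse=best_mse, m=X.shape[0])
    return best, report, history


def predict_binary(
    chromosome: Chromosome,
    sset: SymbolSet,
    x: np.ndarray,
    rounding_threshold: float = 0.5,
) -> bool | np.ndarray:
    """Binary decision: output at or above the rounding threshold is
    positive.  A threshold of 0 reproduces the strict sign rule
    ``GEP(x) > 0 -> positive``; non-finite outputs are negative.
    """
    out = evaluate(chromosome, sset, x)
    if np.isscalar(out):
        return bool(np.isfinite(out) and out >= rounding_threshold)
    out = np.asarray(out)
    return np.isfinite(out) & (out >= rounding_threshold)


# ---------------------------------------------------------------------------
# Serialization: human-readable K-expression model files


def chromosome_to_dict(c: Chromosome, sset: SymbolSet) -> dict:
    return {
        "format": "emgsketch-gep-chromosome",
        "linking": "+",
        "functions": list(sset.functions),
        "terminals": list(sset.terminals),
        "h": c.genes[0].h,
        "genes": [" ".join(g.symbols) for g in c.genes],
    }


def chromosome_from_dict(payload: dict) -> tuple[Chromosome, SymbolSet]:
    sset = SymbolSet(
        functions=tuple(payload["functions"]), terminals=tuple(payload["terminals"])
    )
    h = int(payload["h"])
    genes = tuple(Gene(symbols=tuple(s.split()), h=h) for s in payload["genes"])
    c = Chromosome(genes=genes)
    if not c.is_valid(sset):
        raise ParameterError("serialized chromosome violates Karva head/tail rules")
    return c, sset


def save_chromosome(c: Chromosome, sset: SymbolSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(chromosome_to_dict(c, sset), indent=1))


def load_chromosome(path: str | Path) -> tuple[Chromosome, SymbolSet]:
    return chromosome_from_dict(json.loads(Path(path).read_text()))
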