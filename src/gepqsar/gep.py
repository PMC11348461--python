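"""Gene expression programming (GEP) symbolic regression over descriptor terminals.

GEP evolves fixed-length linear chromosomes written in Karva notation.
Each gene is a string of ``head_length`` symbols drawn from functions and
terminals followed by a tail of ``head_length + 1`` terminal-only symbols
(for binary operators), which makes every gene decodable into a valid
expression tree by breadth-first (level-order) filling.  Multigenic
chromosomes are joined by a linking operator.  The function set is the
four arithmetic operators {+, −, *, /}; terminals are named descriptors.

Fitness is ``1000 / (1 + RMSE)`` on the training data, with fitness 0 for
any individual whose expression divides by a near-zero quantity or
produces a non-finite value on any training row.  Selection is
fitness-proportionate roulette with elitism; variation is point mutation,
one- and two-point recombination, and head-segment inversion — each of
which preserves chromosome validity by construction.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from gepqsar.dataset import DescriptorTable
from gepqsar.errors import ConfigError, FormatError, ValidationError

__all__ = [
    "FUNCTIONS",
    "GepConfig",
    "Chromosome",
    "ExpressionTree",
    "EvolutionResult",
    "tail_length",
    "random_chromosome",
    "express",
    "evaluate",
    "evaluate_matrix",
    "fitness",
    "select_parents",
    "mutate",
    "recombine",
    "invert",
    "evolve",
    "predict",
    "to_infix",
    "chromosome_to_text",
    "chromosome_from_text",
]

#: The operational function set; all binary.
FUNCTIONS: tuple[str, ...] = ("+", "-", "*", "/")
_MAX_ARITY = 2
#: Divisors smaller than this in magnitude invalidate the individual.
DIV_GUARD = 1e-12
#: An individual at this fitness has (numerically) zero training RMSE.
PERFECT_FITNESS = 1000.0

#: A decoded node: either a terminal name or (operator, left, right).
Node = Union[str, tuple]


def tail_length(head_length: int) -> int:
    """Tail length ``h·(a − 1) + 1`` for maximum arity a = 2."""
    if head_length < 1:
        raise ConfigError(f"head_length must be >= 1, got {head_length}")
    return head_length * (_MAX_ARITY - 1) + 1


@dataclass(frozen=True)
class GepConfig:
    """All control parameters of an evolutionary run.

    Defaults are conventional GEP settings for small regression problems;
    every field can be overridden.  ``terminal_set`` must name columns of
    the training descriptor table.
    """

    terminal_set: tuple[str, ...]
    head_length: int = 7
    n_genes: int = 3
    population_size: int = 100
    n_generations: int = 500
    p_mutation: float = 0.044
    p_inversion: float = 0.1
    p_recombination_1pt: float = 0.3
    p_recombination_2pt: float = 0.3
    elitism: int = 1
    linking_function: str = "+"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "terminal_set", tuple(self.terminal_set))
        if not self.terminal_set:
            raise ConfigError("terminal_set must not be empty")
        if self.head_length < 1:
            raise ConfigError("head_length must be >= 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if not 1 <= self.elitism < self.population_size:
            raise ConfigError("need 1 <= elitism < population_size")
        if self.linking_function not in ("+", "*"):
            raise ConfigError("linking_function must be '+' or '*'")
        for name in ("p_mutation", "p_inversion", "p_recombination_1pt", "p_recombination_2pt"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        overlap = set(self.terminal_set) & set(FUNCTIONS)
        if overlap:
            raise ConfigError(f"terminal names collide with operators: {sorted(overlap)}")

    @property
    def gene_length(self) -> int:
        return self.head_length + tail_length(self.head_length)


@dataclass(frozen=True)
class Chromosome:
    """A Karva-encoded genotype: ``n_genes`` symbol strings of equal length."""

    genes: tuple[tuple[str, ...], ...]
    head_length: int

    def __post_init__(self) -> None:
        t = tail_length(self.head_length)
        for g, gene in enumerate(self.genes):
            if len(gene) != self.head_length + t:
                raise ValidationError(
                    f"gene {g} has length {len(gene)}, expected {self.head_length + t}"
                )

    def validate(self, terminals: Sequence[str]) -> None:
        """Check the head/tail alphabet rule (tail = terminals only)."""
        tset = set(terminals)
        for g, gene in enumerate(self.genes):
            for i, sym in enumerate(gene):
                in_head = i < self.head_length
                if sym in FUNCTIONS:
                    if not in_head:
                        raise ValidationError(f"function {sym!r} in tail of gene {g}")
                elif sym not in tset:
                    raise ValidationError(f"unknown symbol {sym!r} in gene {g}")


@dataclass(frozen=True)
class ExpressionTree:
    """The decoded phenotype: one sub-tree per gene, joined by the linker."""

    gene_trees: tuple[Node, ...]
    linking_function: str

    def terminals(self) -> set[str]:
        out: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                walk(node[1])
                walk(node[2])

        for t in self.gene_trees:
            walk(t)
        return out


@dataclass
class EvolutionResult:
    """Outcome of one seeded run."""

    best: Chromosome
    best_tree: ExpressionTree
    best_fitness: float
    best_fitness_per_generation: np.ndarray
    mean_fitness_per_generation: np.ndarray
    train_predictions: np.ndarray
    config: GepConfig


# ---------------------------------------------------------------------------
# genotype → phenotype


def _decode_gene(symbols: Sequence[str]) -> Node:
    """Breadth-first K-expression decoding; trailing unused symbols ignored."""
    first = symbols[0]
    if first not in FUNCTIONS:
        return first
    root = [first, None, None]
    queue: deque[list] = deque([root])
    i = 1
    while queue:
        node = queue.popleft()
        for slot in (1, 2):
            sym = symbols[i]
            i += 1
            if sym in FUNCTIONS:
                child = [sym, None, None]
                queue.append(child)
            else:
                child = sym
            node[slot] = child

    def freeze(node) -> Node:
        if isinstance(node, str):
            return node
        return (node[0], freeze(node[1]), freeze(node[2]))

    return freeze(root)


def express(chromosome: Chromosome, linking_function: str = "+",
            terminals: Sequence[str] | None = None) -> ExpressionTree:
    """Decode a chromosome into its expression tree.

    When ``terminals`` is given the chromosome is validity-checked first
    (functions confined to gene heads).
    """
    if terminals is not None:
        chromosome.validate(terminals)
    return ExpressionTree(
        gene_trees=tuple(_decode_gene(g) for g in chromosome.genes),
        linking_function=linking_function,
    )


# ---------------------------------------------------------------------------
# evaluation


def _eval_node(node: Node, columns: Mapping[str, np.ndarray], invalid: np.ndarray) -> np.ndarray:
    if isinstance(node, str):
        try:
            return np.asarray(columns[node], dtype=float)
        except KeyError:
            raise ValidationError(f"terminal {node!r} missing from input") from None
    op, left, right = node
    a = _eval_node(left, columns, invalid)
    b = _eval_node(right, columns, invalid)
    if op == "+":
        out = a + b
    elif op == "-":
        out = a - b
    elif op == "*":
        out = a * b
    else:
        guard = np.abs(b) < DIV_GUARD
        invalid |= guard
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            out = np.where(guard, 0.0, a) / np.where(guard, 1.0, b)
    invalid |= ~np.isfinite(out)
    return np.where(np.isfinite(out), out, 0.0)


def evaluate_matrix(tree: ExpressionTree, columns: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a tree over column vectors.

    Returns ``(values, invalid)``: rows flagged invalid hit a guarded
    division (|divisor| < 1e-12) or a non-finite intermediate.
    """
    first = next(iter(columns.values()))
    n = np.asarray(first).shape[0]
    invalid = np.zeros(n, dtype=bool)
    total: np.ndarray | None = None
    for gt in tree.gene_trees:
        val = _eval_node(gt, columns, invalid)
        if total is None:
            total = val
        elif tree.linking_function == "+":
            total = total + val
        else:
            total = total * val
        invalid |= ~np.isfinite(total)
        total = np.where(np.isfinite(total), total, 0.0)
    assert total is not None
    return total, invalid


def evaluate(tree: ExpressionTree, row: Mapping[str, float]) -> float | None:
    """Evaluate a tree on one compound; ``None`` marks an invalid evaluation."""
    cols = {k: np.asarray([v], dtype=float) for k, v in row.items()}
    missing = tree.terminals() - set(cols)
    if missing:
        raise ValidationError(f"terminals missing from row: {sorted(missing)}")
    val, invalid = evaluate_matrix(tree, cols)
    return None if invalid[0] else float(val[0])


def _columns_of(X: DescriptorTable | Mapping[str, np.ndarray], terminals: Sequence[str]) -> dict[str, np.ndarray]:
    if isinstance(X, DescriptorTable):
        missing = set(terminals) - set(X.descriptor_names)
        if missing:
            raise ValidationError(f"terminals missing from table: {sorted(missing)}")
        return {t: X.column(t) for t in terminals}
    missing = set(terminals) - set(X)
    if missing:
        raise ValidationError(f"terminals missing from input: {sorted(missing)}")
    return {t: np.asarray(X[t], dtype=float) for t in terminals}


def fitness(
    chromosome: Chromosome,
    X: DescriptorTable | Mapping[str, np.ndarray],
    y: np.ndarray,
    linking_function: str = "+",
    terminal_set: Sequence[str] | None = None,
) -> float:
    """``1000 / (1 + RMSE)`` on the training data; 0 if any row is invalid."""
    tree = express(chromosome, linking_function)
    terms = sorted(tree.terminals()) if terminal_set is None else list(terminal_set)
    cols = _columns_of(X, terms)
    y = np.asarray(y, dtype=float)
    pred, invalid = evaluate_matrix(tree, cols)
    if invalid.any():
        return 0.0
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return PERFECT_FITNESS / (1.0 + rmse)


# ---------------------------------------------------------------------------
# genetic operators


def random_chromosome(config: GepConfig, rng: np.random.Generator) -> Chromosome:
    """A uniformly random valid chromosome."""
    head_alphabet = list(FUNCTIONS) + list(config.terminal_set)
    tail_alphabet = list(config.terminal_set)
    t = tail_length(config.head_length)
    genes = []
    for _ in range(config.n_genes):
        head = [head_alphabet[i] for i in rng.integers(0, len(head_alphabet), config.head_length)]
        tail = [tail_alphabet[i] for i in rng.integers(0, len(tail_alphabet), t)]
        genes.append(tuple(head + tail))
    return Chromosome(genes=tuple(genes), head_length=config.head_length)


def select_parents(
    population: Sequence[Chromosome],
    fitnesses: Sequence[float],
    n_parents: int,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Fitness-proportionate (roulette) sampling with replacement."""
    f = np.asarray(fitnesses, dtype=float)
    total = f.sum()
    if total <= 0.0:
        warnings.warn("all fitnesses are zero: falling back to uniform selection", stacklevel=2)
        idx = rng.integers(0, len(population), n_parents)
    else:
        idx = rng.choice(len(population), size=n_parents, replace=True, p=f / total)
    return [population[i] for i in idx]


def mutate(
    chromosome: Chromosome,
    p_mutation: float,
    rng: np.random.Generator,
    terminal_set: Sequence[str],
) -> Chromosome:
    """Point mutation: each symbol independently resampled with probability p.

    Head positions draw from functions ∪ terminals, tail positions from
    terminals only, so validity is preserved by construction.
    """
    head_alphabet = list(FUNCTIONS) + list(terminal_set)
    tail_alphabet = list(terminal_set)
    h = chromosome.head_length
    genes = []
    for gene in chromosome.genes:
        hits = rng.random(len(gene)) < p_mutation
        # draw replacements unconditionally so the rng stream does not
        # depend on which positions mutate
        head_draw = rng.integers(0, len(head_alphabet), len(gene))
        tail_draw = rng.integers(0, len(tail_alphabet), len(gene))
        new = list(gene)
        for i in np.nonzero(hits)[0]:
            new[i] = head_alphabet[head_draw[i]] if i < h else tail_alphabet[tail_draw[i]]
        genes.append(tuple(new))
    return Chromosome(genes=tuple(genes), head_length=h)


def _flatten(ch: Chromosome) -> list[str]:
    return [s for gene in ch.genes for s in gene]


def _unflatten(symbols: Sequence[str], template: Chromosome) -> Chromosome:
    L = len(template.genes[0])
    genes = tuple(tuple(symbols[g * L : (g + 1) * L]) for g in range(len(template.genes)))
    return Chromosome(genes=genes, head_length=template.head_length)


def recombine(
    parent_a: Chromosome,
    parent_b: Chromosome,
    mode: str,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome]:
    """One- or two-point crossover over the concatenated chromosome.

    Head/tail alphabets align positionally across equal-shape parents, so
    any cut point yields valid children.
    """
    if parent_a.head_length != parent_b.head_length or len(parent_a.genes) != len(parent_b.genes):
        raise ValidationError("recombination requires equal-shape parents")
    a, b = _flatten(parent_a), _flatten(parent_b)
    L = len(a)
    if mode == "one-point":
        cut = int(rng.integers(1, L))
        ca = a[:cut] + b[cut:]
        cb = b[:cut] + a[cut:]
    elif mode == "two-point":
        i, j = sorted(rng.choice(L + 1, size=2, replace=False).tolist())
        ca = a[:i] + b[i:j] + a[j:]
        cb = b[:i] + a[i:j] + b[j:]
    else:
        raise ConfigError(f"unknown recombination mode {mode!r}")
    return _unflatten(ca, parent_a), _unflatten(cb, parent_b)


def invert(chromosome: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Reverse a random contiguous segment within one gene's head."""
    h = chromosome.head_length
    if h < 2:
        return chromosome
    g = int(rng.integers(0, len(chromosome.genes)))
    i, j = sorted(rng.integers(0, h, size=2).tolist())
    gene = list(chromosome.genes[g])
    gene[i : j + 1] = gene[i : j + 1][::-1]
    genes = list(chromosome.genes)
    genes[g] = tuple(gene)
    return Chromosome(genes=tuple(genes), head_length=h)


# ---------------------------------------------------------------------------
# the evolutionary loop


def evolve(
    config: GepConfig,
    X: DescriptorTable | Mapping[str, np.ndarray],
    y: np.ndarray,
) -> EvolutionResult:
    """Run a seeded, fully reproducible evolutionary search.

    Generational replacement with elitism: the ``elitism`` fittest
    individuals are copied unchanged, the rest of the next generation is
    produced by roulette selection followed by mutation, inversion, and
    one-/two-point recombination.  Terminates after ``n_generations`` or
    as soon as a numerically perfect individual (RMSE ≈ 0) appears.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValidationError("empty training data")
    cols = _columns_of(X, config.terminal_set)
    rng = np.random.default_rng(config.seed)

    def fit_of(ch: Chromosome) -> float:
        tree = express(ch, config.linking_function)
        pred, invalid = evaluate_matrix(tree, cols)
        if invalid.any():
            return 0.0
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        return PERFECT_FITNESS / (1.0 + rmse)

    population = [random_chromosome(config, rng) for _ in range(config.population_size)]
    best_hist: list[float] = []
    mean_hist: list[float] = []
    best_ch: Chromosome | None = None
    best_fit = -np.inf

    for _generation in range(config.n_generations):
        fits = np.array([fit_of(ch) for ch in population])
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_ch = population[gen_best]
        best_hist.append(best_fit)
        mean_hist.append(float(fits.mean()))
        if best_fit >= PERFECT_FITNESS - 1e-9:
            break

        elite_idx = np.argsort(-fits, kind="stable")[: config.elitism]
        elites = [population[i] for i in elite_idx]
        n_offspring = config.population_size - config.elitism
        parents = select_parents(population, fits, n_offspring, rng)
        offspring = [
            mutate(p, config.p_mutation, rng, config.terminal_set) for p in parents
        ]
        offspring = [
            invert(ch, rng) if rng.random() < config.p_inversion else ch
            for ch in offspring
        ]
        for i in range(0, n_offspring - 1, 2):
            if rng.random() < config.p_recombination_1pt:
                offspring[i], offspring[i + 1] = recombine(
                    offspring[i], offspring[i + 1], "one-point", rng
                )
            if rng.random() < config.p_recombination_2pt:
                offspring[i], offspring[i + 1] = recombine(
                    offspring[i], offspring[i + 1], "two-point", rng
                )
        population = elites + offspring

    assert best_ch is not None
    best_tree = express(best_ch, config.linking_function)
    train_pred, invalid = evaluate_matrix(best_tree, cols)
    train_pred = np.where(invalid, np.nan, train_pred)
    return EvolutionResult(
        best=best_ch,
        best_tree=best_tree,
        best_fitness=best_fit,
        best_fitness_per_generation=np.asarray(best_hist),
        mean_fitness_per_generation=np.asarray(mean_hist),
        train_predictions=train_pred,
        config=config,
    )


def predict(result: EvolutionResult, X: DescriptorTable | Mapping[str, np.ndarray]) -> np.ndarray:
    """Evaluate the best tree per row; invalid rows become NaN with a warning."""
    cols = _columns_of(X, result.config.terminal_set)
    pred, invalid = evaluate_matrix(result.best_tree, cols)
    if invalid.any():
        rows = np.nonzero(invalid)[0].tolist()
        warnings.warn(f"invalid model evaluation on rows {rows}", stacklevel=2)
    return np.where(invalid, np.nan, pred)


# ---------------------------------------------------------------------------
# rendering and serialization


def to_infix(tree: ExpressionTree | Node) -> str:
    """Render a tree (or node) as plain infix text."""

    def render(node: Node) -> str:
        if isinstance(node, str):
            return node
        op, left, right = node
        return f"({render(left)} {op} {render(right)})"

    if isinstance(tree, ExpressionTree):
        parts = [render(t) for t in tree.gene_trees]
        return f" {tree.linking_function} ".join(parts)
    return render(tree)


def chromosome_to_text(chromosome: Chromosome) -> str:
    """Serialize the raw gene strings (space-separated symbols, one gene per line)."""
    lines = [f"head_length={chromosome.head_length}"]
    lines += [" ".join(gene) for gene in chromosome.genes]
    return "\n".join(lines)


def chromosome_from_text(text: str) -> Chromosome:
    """Inverse of :func:`chromosome_to_text`."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("head_length="):
        raise FormatError("chromosome text must start with 'head_length=<int>'")
    h = int(lines[0].split("=", 1)[1])
    genes = tuple(tuple(ln.split()) for ln in lines[1:])
    if not genes:
        raise FormatError("chromosome text contains no genes")
    return Chromosome(genes=genes, head_length=h)
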