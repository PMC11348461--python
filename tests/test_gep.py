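import math

import numpy as np
import pytest

from gepqsar.errors import ConfigError, ValidationError
from gepqsar.gep import (
    FUNCTIONS,
    Chromosome,
    GepConfig,
    chromosome_from_text,
    chromosome_to_text,
    evaluate,
    evolve,
    express,
    fitness,
    invert,
    mutate,
    predict,
    random_chromosome,
    recombine,
    select_parents,
    tail_length,
    to_infix,
)

TERMINALS = ("a", "b", "c")


def oracle_decode(symbols):
    """Independent level-partition decoder for a K-expression prefix."""
    levels = [[symbols[0]]]
    i = 1
    while True:
        need = sum(2 for s in levels[-1] if s in FUNCTIONS)
        if need == 0:
            break
        levels.append(list(symbols[i : i + need]))
        i += need

    def build(lvl, j):
        s = levels[lvl][j]
        if s not in FUNCTIONS:
            return s
        nf = sum(1 for t in levels[lvl][:j] if t in FUNCTIONS)
        return (s, build(lvl + 1, 2 * nf), build(lvl + 1, 2 * nf + 1))

    return build(0, 0)


def oracle_eval(node, row):
    """Independent recursive scalar evaluator with the same division guard."""
    if isinstance(node, str):
        return float(row[node])
    op, l, r = node
    a, b = oracle_eval(l, row), oracle_eval(r, row)
    if a is None or b is None:
        return None
    if op == "+":
        out = a + b
    elif op == "-":
        out = a - b
    elif op == "*":
        out = a * b
    else:
        if abs(b) < 1e-12:
            return None
        out = a / b
    return out if math.isfinite(out) else None


def make_config(**kw):
    kw.setdefault("terminal_set", TERMINALS)
    return GepConfig(**kw)


class TestEncoding:
    @pytest.mark.parametrize("h, t", [(7, 8), (1, 2), (10, 11)])
    def test_tail_length(self, h, t):
        assert tail_length(h) == t

    def test_hand_decoded_gene(self):
        # head "+*a", tail "bbaa": level-order fill gives (b*b) + a
        ch = Chromosome(genes=(("+", "*", "a", "b", "b", "a", "a"),), head_length=3)
        tree = express(ch)
        assert to_infix(tree) == "((b * b) + a)"
        assert evaluate(tree, {"a": 1.0, "b": 2.0}) == 5.0

    def test_root_terminal_gene(self):
        ch = Chromosome(genes=(("a", "+", "b", "b", "c", "a", "a"),), head_length=3)
        assert to_infix(express(ch)) == "a"

    def test_function_in_tail_rejected(self):
        ch = Chromosome(genes=(("a", "b", "b", "+", "a", "a", "b"),), head_length=3)
        with pytest.raises(ValidationError, match="tail"):
            express(ch, terminals=TERMINALS)

    def test_decoding_matches_recursive_oracle_on_500_genes(self):
        rng = np.random.default_rng(7)
        cfg = make_config(head_length=5, n_genes=1)
        for _ in range(500):
            ch = random_chromosome(cfg, rng)
            assert express(ch).gene_trees[0] == oracle_decode(ch.genes[0])

    def test_serialization_round_trip(self, rng):
        ch = random_chromosome(make_config(), rng)
        assert chromosome_from_text(chromosome_to_text(ch)) == ch


class TestEvaluation:
    def test_division_by_zero_marks_invalid(self):
        ch = Chromosome(genes=(("/", "a", "b", "c", "a"),), head_length=2)
        assert evaluate(express(ch), {"a": 1.0, "b": 0.0, "c": 1.0}) is None

    def test_missing_terminal_errors(self):
        ch = Chromosome(genes=(("+", "a", "b", "c", "a"),), head_length=2)
        with pytest.raises(ValidationError, match="missing"):
            evaluate(express(ch), {"a": 1.0})

    def test_matches_recursive_oracle_on_200_random_trees(self):
        rng = np.random.default_rng(11)
        cfg = make_config(head_length=4, n_genes=1)
        checked = 0
        for _ in range(200):
            ch = random_chromosome(cfg, rng)
            tree = express(ch)
            row = {t: float(v) for t, v in zip(TERMINALS, rng.normal(0, 2, 3))}
            got = evaluate(tree, row)
            want = oracle_eval(tree.gene_trees[0], row)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, rel=1e-12)
                checked += 1
        assert checked > 100  # the vast majority of draws are valid


class TestFitness:
    def _identity_chromosome(self):
        return Chromosome(genes=(("a", "a", "a"),), head_length=1)

    def test_perfect_predictions(self):
        X = {"a": np.array([1.0, 2.0, 3.0])}
        assert fitness(self._identity_chromosome(), X, X["a"]) == 1000.0

    def test_invalid_row_zeroes_fitness(self):
        ch = Chromosome(genes=(("/", "a", "b", "a", "b"),), head_length=2)
        X = {"a": np.array([1.0, 1.0]), "b": np.array([1.0, 0.0])}
        assert fitness(ch, X, np.zeros(2)) == 0.0

    def test_rmse_formula(self):
        X = {"a": np.array([1.0, 2.0, 3.0])}
        y = np.array([1.0, 2.0, 5.0])
        rmse = math.sqrt(4.0 / 3.0)
        assert fitness(self._identity_chromosome(), X, y) == pytest.approx(1000.0 / (1.0 + rmse))


class TestSelection:
    def test_equal_fitness_uniform_within_3_sigma(self, rng):
        pop = [Chromosome(genes=((f"t{i}", f"t{i}", f"t{i}"),), head_length=1) for i in range(5)]
        draws = 10**5
        parents = select_parents(pop, [1.0] * 5, draws, rng)
        counts = np.array([sum(p is ind for p in parents) for ind in pop])
        expected = draws / 5
        sigma = math.sqrt(draws * 0.2 * 0.8)
        assert np.all(np.abs(counts - expected) < 3 * sigma)

    def test_degenerate_roulette(self, rng):
        pop = [Chromosome(genes=((t, t, t),), head_length=1) for t in ("a", "b")]
        parents = select_parents(pop, [5.0, 0.0], 50, rng)
        assert all(p is pop[0] for p in parents)

    def test_all_zero_falls_back_uniform_with_warning(self, rng):
        pop = [Chromosome(genes=((t, t, t),), head_length=1) for t in ("a", "b")]
        with pytest.warns(UserWarning, match="uniform"):
            parents = select_parents(pop, [0.0, 0.0], 10, rng)
        assert len(parents) == 10


class TestOperators:
    def test_mutation_p0_identity(self, rng):
        ch = random_chromosome(make_config(), rng)
        assert mutate(ch, 0.0, rng, TERMINALS) == ch

    def test_mutation_p1_tail_all_terminals(self, rng):
        cfg = make_config()
        ch = random_chromosome(cfg, rng)
        out = mutate(ch, 1.0, rng, TERMINALS)
        for gene in out.genes:
            assert all(s in TERMINALS for s in gene[cfg.head_length :])

    def test_mutation_validity_audit_1000(self):
        rng = np.random.default_rng(13)
        cfg = make_config()
        for _ in range(1000):
            out = mutate(random_chromosome(cfg, rng), 0.2, rng, TERMINALS)
            out.validate(TERMINALS)

    def test_recombination_identical_parents(self, rng):
        ch = random_chromosome(make_config(), rng)
        ca, cb = recombine(ch, ch, "one-point", rng)
        assert ca == ch and cb == ch

    def test_recombination_positionwise_conservation(self, rng):
        cfg = make_config()
        a, b = random_chromosome(cfg, rng), random_chromosome(cfg, rng)
        for mode in ("one-point", "two-point"):
            ca, cb = recombine(a, b, mode, rng)
            fa = [s for g in a.genes for s in g]
            fb = [s for g in b.genes for s in g]
            fca = [s for g in ca.genes for s in g]
            fcb = [s for g in cb.genes for s in g]
            for i in range(len(fa)):
                assert sorted([fa[i], fb[i]]) == sorted([fca[i], fcb[i]])

    def test_recombination_validity_audit_1000(self):
        rng = np.random.default_rng(17)
        cfg = make_config()
        for i in range(500):
            a, b = random_chromosome(cfg, rng), random_chromosome(cfg, rng)
            mode = "one-point" if i % 2 else "two-point"
            ca, cb = recombine(a, b, mode, rng)
            ca.validate(TERMINALS)
            cb.validate(TERMINALS)

    def test_recombination_shape_mismatch(self, rng):
        a = random_chromosome(make_config(head_length=3), rng)
        b = random_chromosome(make_config(head_length=4), rng)
        with pytest.raises(ValidationError, match="equal-shape"):
            recombine(a, b, "one-point", rng)

    def test_inversion_reverses_within_head_only(self):
        cfg = make_config(head_length=3, n_genes=1)
        base = Chromosome(genes=(("+", "-", "*", "a", "b", "c", "a"),), head_length=3)
        seen_full_reversal = seen_identity = False
        for seed in range(60):
            out = invert(base, np.random.default_rng(seed))
            assert out.genes[0][3:] == base.genes[0][3:]  # tail untouched
            out.validate(TERMINALS)
            if out.genes[0][:3] == ("*", "-", "+"):
                seen_full_reversal = True
            if out == base:
                seen_identity = True  # single-symbol segment
        assert seen_full_reversal and seen_identity

    def test_inversion_validity_audit_1000(self):
        rng = np.random.default_rng(19)
        cfg = make_config()
        for _ in range(1000):
            out = invert(random_chromosome(cfg, rng), rng)
            out.validate(TERMINALS)


class TestEvolve:
    def _data(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        X = {t: rng.standard_normal(n) for t in TERMINALS}
        y = X["a"] + X["b"] * X["c"]
        return X, y

    def test_bitwise_determinism(self):
        X, y = self._data()
        cfg = make_config(n_generations=30, population_size=30, seed=42)
        r1, r2 = evolve(cfg, X, y), evolve(cfg, X, y)
        assert r1.best == r2.best
        np.testing.assert_array_equal(
            r1.best_fitness_per_generation, r2.best_fitness_per_generation
        )
        np.testing.assert_array_equal(r1.train_predictions, r2.train_predictions)

    def test_best_fitness_monotone_with_elitism(self):
        X, y = self._data()
        for seed in range(5):
            cfg = make_config(n_generations=40, population_size=30, seed=seed)
            hist = evolve(cfg, X, y).best_fitness_per_generation
            assert np.all(np.diff(hist) >= 0)

    def test_early_termination_on_perfect_fit(self):
        rng = np.random.default_rng(1)
        X = {t: rng.standard_normal(20) for t in TERMINALS}
        cfg = make_config(n_generations=500, population_size=50, seed=3)
        res = evolve(cfg, X, X["a"])  # the bare terminal is discoverable quickly
        assert res.best_fitness == pytest.approx(1000.0)
        assert len(res.best_fitness_per_generation) < 500

    def test_empty_terminal_set_rejected(self):
        with pytest.raises(ConfigError, match="terminal_set"):
            make_config(terminal_set=())


class TestPredict:
    def test_train_predictions_consistency_and_shape(self):
        rng = np.random.default_rng(2)
        X = {t: rng.standard_normal(25) for t in TERMINALS}
        y = X["a"] * X["b"]
        cfg = make_config(n_generations=20, population_size=30, seed=9)
        res = evolve(cfg, X, y)
        np.testing.assert_allclose(predict(res, X), res.train_predictions)
        one = {t: v[:1] for t, v in X.items()}
        assert predict(res, one).shape == (1,)

    def test_missing_terminal_column_errors(self):
        rng = np.random.default_rng(2)
        X = {t: rng.standard_normal(10) for t in TERMINALS}
        cfg = make_config(n_generations=5, population_size=10, seed=0)
        res = evolve(cfg, X, X["a"])
        with pytest.raises(ValidationError, match="missing"):
            predict(res, {"a": X["a"]})
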