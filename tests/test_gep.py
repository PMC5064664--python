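"""GEP engine: Karva decoding vs. an independent oracle, closure, fitness,
operators, and the evolution loop."""

import numpy as np
import pytest

from emgsketch import gep
from emgsketch.gep import (
    Chromosome,
    Gene,
    GEPConfig,
    SymbolSet,
    default_symbol_set,
    tail_length,
)
from emgsketch.io import ParameterError

# ---------------------------------------------------------------------------
# Independent oracle: explicit queue-simulation tree builder + recursive
# evaluation with the same protected primitives.  Kept deliberately separate
# from the implementation's level-order index bookkeeping.

_ARITY = {"+": 2, "-": 2, "*": 2, "/": 2, "sin": 1, "cos": 1, "sqrt": 1, "exp": 1}


def oracle_tree(symbols):
    root = {"sym": symbols[0], "children": []}
    queue = [root]
    pos = 1
    while queue:
        node = queue.pop(0)
        for _ in range(_ARITY.get(node["sym"], 0)):
            child = {"sym": symbols[pos], "children": []}
            pos += 1
            node["children"].append(child)
            queue.append(child)
    return root


def oracle_eval(node, env):
    sym = node["sym"]
    if not node["children"]:
        return np.float64(env[sym])
    vals = [oracle_eval(c, env) for c in node["children"]]
    with np.errstate(all="ignore"):
        if sym == "+":
            return vals[0] + vals[1]
        if sym == "-":
            return vals[0] - vals[1]
        if sym == "*":
            return vals[0] * vals[1]
        if sym == "/":
            if abs(vals[1]) < 1e-12:
                return np.float64("nan")
            return vals[0] / vals[1]
        if sym == "sin":
            return np.sin(vals[0])
        if sym == "cos":
            return np.cos(vals[0])
        if sym == "sqrt":
            return np.sqrt(np.abs(vals[0]))
        if sym == "exp":
            return np.exp(np.clip(vals[0], -50.0, 50.0))
    raise AssertionError(sym)


def _abc_sset():
    return SymbolSet(functions=("+", "-", "*", "/", "sin", "cos", "sqrt", "exp"),
                     terminals=("a", "b", "c"))


class TestTailLength:
    @pytest.mark.parametrize("h, a_max, expected", [(15, 2, 16), (1, 2, 2), (5, 1, 1)])
    def test_karva_rule(self, h, a_max, expected):
        assert tail_length(h, a_max) == expected

    def test_default_symbol_set_gene_length(self):
        sset = default_symbol_set(12)
        assert sset.a_max == 2
        assert tail_length(15, sset.a_max) == 16  # 31-symbol genes


class TestDecode:
    def _gene_from_kexpr(self, kexpr, h, sset):
        # pad the tail with the first terminal to a syntactically full gene
        t = tail_length(h, sset.a_max)
        syms = list(kexpr) + [sset.terminals[0]] * (h + t - len(kexpr))
        return Gene(symbols=tuple(syms), h=h)

    def test_known_kexpression(self):
        # "*+abc": root *, children (+, a); + has children (b, c)
        sset = _abc_sset()
        g = self._gene_from_kexpr(["*", "+", "a", "b", "c"], h=4, sset=sset)
        out = gep.evaluate_gene(g, sset, np.array([[2.0, 3.0, 4.0]]))
        assert out[0] == (3.0 + 4.0) * 2.0 == 14.0

    def test_two_symbol_addition(self):
        sset = _abc_sset()
        g = self._gene_from_kexpr(["+", "a", "b"], h=2, sset=sset)
        out = gep.evaluate_gene(g, sset, np.array([[1.0, 1.0, 0.0]]))
        assert out[0] == 2.0

    def test_terminal_root_is_identity(self):
        sset = _abc_sset()
        g = self._gene_from_kexpr(["c"], h=3, sset=sset)
        X = np.array([[1.0, 2.0, 7.5]])
        assert gep.evaluate_gene(g, sset, X)[0] == 7.5

    def test_decode_ignores_noncoding_tail(self):
        sset = _abc_sset()
        g = self._gene_from_kexpr(["a"], h=2, sset=sset)
        nodes = gep.decode(g, sset)
        assert len(nodes) == 1 and nodes[0][0] == "a"


class TestOracleEquivalence:
    def test_evaluate_matches_queue_simulation_oracle(self):
        """500 random small chromosomes agree exactly with the brute-force
        tree oracle (NaN sentinels compared as equal)."""
        rng = np.random.default_rng(42)
        sset = default_symbol_set(3)
        cfg = GEPConfig(h=4, n_genes=3)
        for _ in range(500):
            c = gep.random_chromosome(sset, cfg, rng)
            x = rng.uniform(-3, 3, size=3)
            env = dict(zip(sset.terminals, x))
            expected = np.float64(0.0)
            for g in c.genes:
                expected = expected + oracle_eval(oracle_tree(list(g.symbols)), env)
            got = gep.evaluate(c, sset, x)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == expected


class TestClosure:
    def test_random_genes_always_valid(self):
        sset = default_symbol_set(4)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            assert gep.random_gene(sset, 6, rng).is_valid(sset)

    def test_gene_length_contract(self):
        sset = default_symbol_set(2)
        g = gep.random_gene(sset, 1, np.random.default_rng(1))
        assert len(g) == 3  # h=1, a_max=2 -> tail 2

    def test_fixed_seed_reproducible_gene(self):
        sset = default_symbol_set(4)
        g1 = gep.random_gene(sset, 6, np.random.default_rng(5))
        g2 = gep.random_gene(sset, 6, np.random.default_rng(5))
        assert g1 == g2

    def test_operators_preserve_closure(self):
        """A few thousand random operator applications never break the
        head/tail domain rules (the full-size fuzz lives in acceptance)."""
        sset = default_symbol_set(4)
        cfg = GEPConfig(h=5, n_genes=3)
        rng = np.random.default_rng(7)
        pop = [gep.random_chromosome(sset, cfg, rng) for _ in range(20)]
        for _ in range(50):
            pop = gep.mutate(pop, 0.1, sset, rng)
            pop = gep.invert(pop, 0.5, rng)
            pop = gep.is_transpose(pop, 0.5, rng)
            pop = gep.ris_transpose(pop, 0.5, sset, rng)
            pop = gep.gene_transpose(pop, 0.5, rng)
            pop = gep.one_point_recombine(pop, 0.5, rng)
            pop = gep.two_point_recombine(pop, 0.5, rng)
            pop = gep.gene_recombine(pop, 0.5, rng)
            for c in pop:
                assert c.is_valid(sset)


class TestFitness:
    def _identity_chromosome(self, sset):
        # x1 + (x1 - x1) + (x1 - x1) == x1 exactly
        h, t = 2, tail_length(2, sset.a_max)
        x1 = sset.terminals[0]
        ident = Gene(symbols=(x1,) + (x1,) * (h + t - 1), h=h)
        zero = Gene(symbols=("-",) + (x1,) * (h + t - 1), h=h)
        return Chromosome(genes=(ident, zero, zero))

    def test_perfect_fit_scores_1000(self):
        sset = default_symbol_set(1)
        c = self._identity_chromosome(sset)
        X = np.linspace(-2, 2, 7)[:, None]
        rep = gep.fitness(c, sset, X, X[:, 0])
        assert rep.fitness == 1000.0 and rep.mse == 0.0

    def test_unit_mse_scores_500(self):
        sset = default_symbol_set(1)
        c = self._identity_chromosome(sset)
        X = np.linspace(-2, 2, 7)[:, None]
        rep = gep.fitness(c, sset, X, X[:, 0] + 1.0)
        assert rep.fitness == pytest.approx(500.0)

    def test_fitness_strictly_decreasing_in_mse(self):
        sset = default_symbol_set(1)
        c = self._identity_chromosome(sset)
        X = np.linspace(-2, 2, 7)[:, None]
        fits = [
            gep.fitness(c, sset, X, X[:, 0] + off).fitness for off in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(fits, fits[1:]))

    def test_fitness_bounds_on_random_chromosomes(self):
        sset = default_symbol_set(3)
        cfg = GEPConfig(h=6)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        T = rng.normal(size=20)
        for _ in range(300):
            c = gep.random_chromosome(sset, cfg, rng)
            rep = gep.fitness(c, sset, X, T)
            assert 0.0 <= rep.fitness <= 1000.0

    def test_division_by_zero_chromosome_gets_zero_fitness(self):
        sset = default_symbol_set(1)
        x1 = sset.terminals[0]
        h = 3
        t = tail_length(h, 2)
        # tree: x1 / (x1 - x1)
        g = Gene(symbols=("/", x1, "-") + (x1,) * (h + t - 3), h=h)
        c = Chromosome(genes=(g,))
        rep = gep.fitness(c, sset, np.array([[1.0], [2.0]]), np.zeros(2))
        assert rep.fitness == 0.0 and rep.mse == float("inf")

    def test_empty_cases_rejected(self):
        sset = default_symbol_set(1)
        c = self._identity_chromosome(sset)
        with pytest.raises(ParameterError):
            gep.fitness(c, sset, np.empty((0, 1)), np.empty(0))


class TestOperators:
    def _pop(self, rng, n=30, h=7):
        sset = default_symbol_set(4)
        cfg = GEPConfig(h=h, n_genes=3)
        return sset, [gep.random_chromosome(sset, cfg, rng) for _ in range(n)]

    def test_zero_rates_leave_population_unchanged(self):
        rng = np.random.default_rng(0)
        sset, pop = self._pop(rng)
        out = pop
        out = gep.mutate(out, 0.0, sset, rng)
        out = gep.invert(out, 0.0, rng)
        out = gep.is_transpose(out, 0.0, rng)
        out = gep.ris_transpose(out, 0.0, sset, rng)
        out = gep.gene_transpose(out, 0.0, rng)
        out = gep.one_point_recombine(out, 0.0, rng)
        out = gep.two_point_recombine(out, 0.0, rng)
        out = gep.gene_recombine(out, 0.0, rng)
        assert out == pop

    def test_mutation_flip_rate_matches_binomial(self):
        """Expected flips = rate x positions; Monte-Carlo count within 4
        sigma of the binomial."""
        rate = 0.044
        rng = np.random.default_rng(123)
        sset, pop = self._pop(rng, n=50, h=7)
        gene_len = 7 + tail_length(7, 2)
        n_positions = 0
        flips = 0
        for _ in range(20):
            mutated = gep.mutate(pop, rate, sset, rng)
            for before, after in zip(pop, mutated):
                for gb, ga in zip(before.genes, after.genes):
                    flips += sum(sb != sa for sb, sa in zip(gb.symbols, ga.symbols))
                    n_positions += gene_len
        mean = rate * n_positions
        sigma = np.sqrt(n_positions * rate * (1 - rate))
        assert abs(flips - mean) < 4 * sigma

    def test_gene_transpose_moves_whole_gene_to_front(self):
        rng = np.random.default_rng(9)
        sset, pop = self._pop(rng, n=10)
        out = gep.gene_transpose(pop, 1.0, rng)
        for before, after in zip(pop, out):
            assert sorted(map(hash, before.genes)) == sorted(map(hash, after.genes))

    def test_recombination_conserves_symbol_multiset_across_pair(self):
        rng = np.random.default_rng(11)
        sset, pop = self._pop(rng, n=10)
        for op in (gep.one_point_recombine, gep.two_point_recombine, gep.gene_recombine):
            out = op(pop, 1.0, rng)
            for i in range(0, 10, 2):
                before = sorted(pop[i].flat_symbols() + pop[i + 1].flat_symbols())
                after = sorted(out[i].flat_symbols() + out[i + 1].flat_symbols())
                assert before == after


class TestEvolve:
    def _identity_cases(self):
        rng = np.random.default_rng(77)
        X = rng.uniform(-1, 1, size=(10, 1))
        return X, X[:, 0]

    def test_zero_generations_returns_initial_best(self):
        X, T = self._identity_cases()
        sset = default_symbol_set(1)
        cfg = GEPConfig(max_generations=0, seed=4)
        best, rep, hist = gep.evolve(X, T, sset, cfg)
        assert len(hist["best"]) == 1
        assert rep.fitness == hist["best"][0]

    def test_best_fitness_monotone_under_elitism(self):
        X, T = self._identity_cases()
        sset = default_symbol_set(1)
        cfg = GEPConfig(max_generations=60, seed=1)
        _, _, hist = gep.evolve(X, T, sset, cfg)
        b = hist["best"]
        assert all(x <= y for x, y in zip(b, b[1:]))

    def test_fixed_seed_identical_trajectory(self):
        X, T = self._identity_cases()
        sset = default_symbol_set(1)
        cfg = GEPConfig(max_generations=40, seed=2)
        b1, r1, h1 = gep.evolve(X, T, sset, cfg)
        b2, r2, h2 = gep.evolve(X, T, sset, cfg)
        assert b1 == b2 and r1 == r2 and h1 == h2

    def test_identity_target_often_solved(self):
        # the heavier 20-seed convergence check lives in the acceptance suite
        X, T = self._identity_cases()
        sset = default_symbol_set(1)
        wins = 0
        for seed in range(3):
            _, rep, _ = gep.evolve(X, T, sset, GEPConfig(max_generations=400, seed=seed))
            wins += rep.fitness == 1000.0
        assert wins >= 2

    def test_empty_cases_rejected(self):
        sset = default_symbol_set(1)
        with pytest.raises(ParameterError):
            gep.evolve(np.empty((0, 1)), np.empty(0), sset, GEPConfig(max_generations=1))


class TestPredictBinary:
    def _constant_free_chromosome(self, sset):
        x1 = sset.terminals[0]
        h, t = 1, tail_length(1, 2)
        return Chromosome(genes=(Gene(symbols=(x1,) * (h + t), h=h),))

    def test_threshold_rules(self):
        sset = default_symbol_set(1)
        c = self._constant_free_chromosome(sset)  # output == x1
        assert gep.predict_binary(c, sset, np.array([0.7]), 0.5) is True
        assert gep.predict_binary(c, sset, np.array([0.5]), 0.5) is True  # >= rule
        assert gep.predict_binary(c, sset, np.array([0.4]), 0.5) is False
        # threshold 0 reproduces the strict sign rule
        assert gep.predict_binary(c, sset, np.array([0.1]), 0.0) is True

    def test_nonfinite_output_is_negative(self):
        sset = default_symbol_set(1)
        x1 = sset.terminals[0]
        h, t = 3, tail_length(3, 2)
        g = Gene(symbols=("/", x1, "-") + (x1,) * (h + t - 3), h=h)
        c = Chromosome(genes=(g,))
        assert gep.predict_binary(c, sset, np.array([1.0]), 0.5) is False


class TestSerialization:
    def test_round_trip(self, tmp_path):
        sset = default_symbol_set(4)
        rng = np.random.default_rng(6)
        c = gep.random_chromosome(sset, GEPConfig(h=5), rng)
        path = tmp_path / "model.gep.json"
        gep.save_chromosome(c, sset, path)
        c2, sset2 = gep.load_chromosome(path)
        assert c2 == c and sset2 == sset
        X = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(
            np.asarray(gep.evaluate(c, sset, X)), np.asarray(gep.evaluate(c2, sset2, X))
        )

    def test_corrupted_gene_rejected(self, tmp_path):
        sset = default_symbol_set(2)
        payload = gep.chromosome_to_dict(
            gep.random_chromosome(sset, GEPConfig(h=3), np.random.default_rng(0)), sset
        )
        payload["genes"][0] = "+ + + + + + + + +"  # functions in the tail
        with pytest.raises(ParameterError):
            gep.chromosome_from_dict(payload)
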