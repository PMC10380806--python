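import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chalkmir.diffexpr import (
    _cond_loglik,
    _fit_nb_glm,
    _nb_loglik,
    _pseudo_counts,
    bh_adjust,
    compare_sets,
    estimate_common_dispersion,
    exact_test,
    exact_test_feature,
    interaction_test,
)


def nb_counts(rng, mu, phi, size):
    if phi <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def oracle_exact_p(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Independent enumeration via scipy's NB pmf (p parameter cancels)."""
    t = s_a + s_b
    if phi <= 0:
        probs = stats.binom.pmf(np.arange(t + 1), t, n_a / (n_a + n_b))
    else:
        r = 1.0 / phi
        a = np.arange(t + 1)
        probs = stats.nbinom.pmf(a, n_a * r, 0.5) * stats.nbinom.pmf(t - a, n_b * r, 0.5)
        probs = probs / probs.sum()
    return float(probs[probs <= probs[s_a] * (1 + 1e-9)].sum())


class TestDispersion:
    def test_poisson_data_near_zero(self, rng):
        counts = nb_counts(rng, 100.0, 0.0, size=(2000, 6))
        groups = ["A"] * 3 + ["B"] * 3
        sizes = np.full(6, 1e6)
        est = estimate_common_dispersion(counts, groups, sizes)
        assert est.phi < 0.02

    def test_nb_recovery(self, rng):
        counts = nb_counts(rng, 100.0, 0.2, size=(2000, 6))
        groups = ["A"] * 3 + ["B"] * 3
        sizes = np.full(6, 1e6)
        est = estimate_common_dispersion(counts, groups, sizes)
        assert 0.15 <= est.phi <= 0.25

    def test_grid_oracle(self, rng):
        counts = nb_counts(rng, 50.0, 0.15, size=(300, 6))
        groups = np.array(["A"] * 3 + ["B"] * 3)
        sizes = np.full(6, 1e6)
        est = estimate_common_dispersion(counts, groups, sizes)
        # 500-point grid search as the independent optimiser
        pseudo = _pseudo_counts(np.asarray(counts, float), sizes)
        masks = [groups == "A", groups == "B"]
        grid = np.exp(np.linspace(np.log(1e-6), np.log(10), 500))
        lls = [_cond_loglik(pseudo, masks, phi) for phi in grid]
        best = grid[int(np.argmax(lls))]
        step = np.log(grid[1]) - np.log(grid[0])
        assert abs(np.log(est.phi) - np.log(best)) <= step

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            est = estimate_common_dispersion(
                np.zeros((5, 4)), ["A", "A", "B", "B"], np.full(4, 1e6)
            )
        assert est.phi == 0.0


class TestExactTest:
    def test_null_identity(self):
        y = np.array([10.0, 20.0, 30.0])
        sizes = np.full(3, 1e6)
        lfc, p = exact_test_feature(y, y, 0.1, sizes, sizes)
        assert lfc == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        ya = nb_counts(rng, 80.0, 0.1, 3).astype(float)
        yb = nb_counts(rng, 160.0, 0.1, 3).astype(float)
        sizes = np.full(3, 1e6)
        lfc1, p1 = exact_test_feature(ya, yb, 0.1, sizes, sizes)
        lfc2, p2 = exact_test_feature(yb, ya, 0.1, sizes, sizes)
        assert lfc1 == pytest.approx(-lfc2)
        assert p1 == pytest.approx(p2)

    def test_matches_enumeration_oracle_small_totals(self, rng):
        sizes = np.full(3, 1e6)
        for _ in range(200):
            ya = rng.integers(0, 8, size=3).astype(float)
            yb = rng.integers(0, 8, size=3).astype(float)
            if ya.sum() + yb.sum() == 0 or ya.sum() + yb.sum() > 60:
                continue
            phi = float(rng.choice([0.0, 0.05, 0.1, 0.5]))
            _, p = exact_test_feature(ya, yb, phi, sizes, sizes)
            expected = oracle_exact_p(int(ya.sum()), int(yb.sum()), 3, 3, phi)
            assert p == pytest.approx(expected, rel=1e-8), (ya, yb, phi)

    def test_direction_recovery_4fold(self, rng):
        sizes = np.full(3, 1e6)
        hits = 0
        n = 300
        for _ in range(n):
            ya = nb_counts(rng, 100.0, 0.1, 3).astype(float)
            yb = nb_counts(rng, 400.0, 0.1, 3).astype(float)
            lfc, p = exact_test_feature(ya, yb, 0.1, sizes, sizes)
            if p < 0.05 and lfc > 0:
                hits += 1
        assert hits / n >= 0.95

    def test_unequal_library_sizes_normalised(self, rng):
        # same underlying expression, one library twice as deep: not DE
        rate = 100.0
        ya = np.array([rng.poisson(rate) for _ in range(3)], float)
        yb = np.array([rng.poisson(2 * rate) for _ in range(3)], float)
        sizes_a = np.full(3, 1e6)
        sizes_b = np.full(3, 2e6)
        lfc, p = exact_test_feature(ya, yb, 0.0, sizes_a, sizes_b)
        assert abs(lfc) < 0.5

    def test_table_interface(self, rng):
        counts = pd.DataFrame(
            nb_counts(rng, 100.0, 0.1, size=(20, 6)),
            index=[f"m{i}" for i in range(20)],
            columns=[f"l{j}" for j in range(6)],
        )
        sizes = pd.Series(np.full(6, 1e6), index=counts.columns)
        groups = ["CDT"] * 3 + ["HDT"] * 3
        table = exact_test(counts, groups, "CDT", "HDT", 0.1, sizes)
        assert set(table.columns) >= {"log2fc", "p_value", "p_adj", "direction"}
        assert table.attrs["contrast"] == "HDT_vs_CDT"
        for _, row in table.iterrows():
            if row.direction == "up":
                assert row.p_value < 0.05 and row.log2fc > 0
            elif row.direction == "down":
                assert row.p_value < 0.05 and row.log2fc < 0

    def test_both_groups_zero(self):
        sizes = np.full(3, 1e6)
        lfc, p = exact_test_feature(np.zeros(3), np.zeros(3), 0.1, sizes, sizes)
        assert (lfc, p) == (0.0, 1.0)


class TestBhAdjust:
    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestInteraction:
    @staticmethod
    def _design(n_rep=3):
        genotype = ["Cyp"] * (2 * n_rep) + ["Lagr"] * (2 * n_rep)
        condition = (["CDT"] * n_rep + ["HDT"] * n_rep) * 2
        return np.array(genotype), np.array(condition)

    def test_grid_oracle_tiny_case(self):
        # 2x2 with 2 reps; compare the fitted interaction coefficient with a
        # brute-force likelihood maximisation over a 4-D parameter grid
        genotype = np.array(["A", "A", "A", "A", "B", "B", "B", "B"])
        condition = np.array(["c", "c", "t", "t", "c", "c", "t", "t"])
        y = np.array([50, 60, 100, 110, 40, 50, 45, 55], float)
        phi = 0.1
        sizes = pd.Series(np.full(8, 1e6), index=[f"l{i}" for i in range(8)])
        counts = pd.DataFrame([y], index=["m1"], columns=sizes.index)
        table = interaction_test(counts, genotype, condition, phi, sizes)
        beta3_hat = table.loc["m1", "log2fc"] * np.log(2)

        g = (genotype == "B").astype(float)
        c = (condition == "t").astype(float)
        X = np.column_stack([np.ones(8), g, c, g * c])
        offset = np.log(np.full(8, 1e6))

        def ll(beta):
            mu = np.exp(X @ beta + offset)
            return _nb_loglik(y, mu, phi)

        beta_hat, ll_hat, _ = _fit_nb_glm(y, X, offset, phi)
        span = 0.4
        grids = [np.linspace(b - span, b + span, 13) for b in beta_hat]
        best, best_ll = None, -np.inf
        for b0 in grids[0]:
            for b1 in grids[1]:
                for b2 in grids[2]:
                    for b3 in grids[3]:
                        v = ll(np.array([b0, b1, b2, b3]))
                        if v > best_ll:
                            best_ll, best = v, (b0, b1, b2, b3)
        step = grids[3][1] - grids[3][0]
        assert ll_hat >= best_ll - 1e-6  # IRLS at least as good as the grid
        assert abs(beta3_hat - best[3]) <= step

    def test_null_rejection_rate(self, rng):
        genotype, condition = self._design()
        sizes = pd.Series(np.full(12, 1e6), index=[f"l{i}" for i in range(12)])
        mu = np.where(condition == "HDT", 200.0, 100.0) * np.where(
            genotype == "Cyp", 1.0, 1.5
        )
        n = 800
        counts = pd.DataFrame(
            [nb_counts(rng, mu, 0.1, 12) for _ in range(n)],
            index=[f"m{i}" for i in range(n)],
            columns=sizes.index,
        )
        table = interaction_test(counts, genotype, condition, 0.1, sizes)
        rate = float((table.p_value < 0.05).mean())
        assert 0.02 <= rate <= 0.08

    def test_power_planted_interaction(self, rng):
        genotype, condition = self._design()
        sizes = pd.Series(np.full(12, 1e6), index=[f"l{i}" for i in range(12)])
        fold = np.where(
            (genotype == "Cyp") & (condition == "HDT"), 4.0,
            np.where(condition == "HDT", 1.0, 1.0),
        )
        mu = 150.0 * fold
        n = 200
        counts = pd.DataFrame(
            [nb_counts(rng, mu, 0.1, 12) for _ in range(n)],
            index=[f"m{i}" for i in range(n)],
            columns=sizes.index,
        )
        table = interaction_test(counts, genotype, condition, 0.1, sizes)
        assert float((table.p_value < 0.05).mean()) >= 0.95

    def test_requires_2x2(self):
        sizes = pd.Series(np.full(4, 1e6), index=[f"l{i}" for i in range(4)])
        counts = pd.DataFrame([[1, 2, 3, 4]], index=["m"], columns=sizes.index)
        with pytest.raises(ValueError, match="2 genotypes"):
            interaction_test(counts, ["A"] * 4, ["c", "c", "t", "t"], 0.1, sizes)

    def test_all_zero_row(self):
        genotype, condition = self._design()
        sizes = pd.Series(np.full(12, 1e6), index=[f"l{i}" for i in range(12)])
        counts = pd.DataFrame(
            np.zeros((1, 12)), index=["m0"], columns=sizes.index
        )
        table = interaction_test(counts, genotype, condition, 0.1, sizes)
        assert table.loc["m0", "p_value"] == 1.0


def _de_table(universe, up=(), down=()):
    direction = ["up" if m in up else "down" if m in down else "ns" for m in universe]
    return pd.DataFrame({"direction": direction}, index=list(universe))


class TestCompareSets:
    UNIVERSE = [f"mir{i}" for i in range(10)]

    def test_shared_up_of_size_two(self):
        tables = {
            g: _de_table(self.UNIVERSE, up=["mir0", "mir1", f"mir{i + 2}"])
            for i, g in enumerate(["Beng", "Cyp", "KB", "Lagr", "NB"])
        }
        comp = compare_sets(tables)
        assert comp.shared_up == {"mir0", "mir1"}
        assert comp.shared_down == set()

    def test_empty_table_empties_shared(self):
        tables = {
            "A": _de_table(self.UNIVERSE, up=["mir0"]),
            "B": _de_table(self.UNIVERSE),
        }
        comp = compare_sets(tables)
        assert comp.shared_up == set()

    def test_group_exclusive(self):
        # mir5 up in both high-chalk genotypes, in no low-chalk one
        tables = {
            "Cyp": _de_table(self.UNIVERSE, up=["mir1"]),
            "Beng": _de_table(self.UNIVERSE, up=["mir1"]),
            "Lagr": _de_table(self.UNIVERSE, up=["mir5"]),
            "NB": _de_table(self.UNIVERSE, up=["mir5"]),
        }
        comp = compare_sets(
            tables, low_group=["Cyp", "Beng"], high_group=["Lagr", "NB"]
        )
        assert comp.group_exclusive["high_up"] == {"mir5"}
        assert comp.group_exclusive["low_up"] == {"mir1"}
        assert comp.group_exclusive["high_down"] == set()

    def test_genotype_specific(self):
        tables = {
            "A": _de_table(self.UNIVERSE, up=["mir0", "mir2"]),
            "B": _de_table(self.UNIVERSE, up=["mir0"], down=["mir3"]),
        }
        comp = compare_sets(tables)
        assert comp.genotype_specific["A_up"] == {"mir2"}
        assert comp.genotype_specific["B_down"] == {"mir3"}
        assert comp.genotype_specific["B_up"] == set()

    def test_mismatched_universe_warns(self):
        tables = {
            "A": _de_table(self.UNIVERSE, up=["mir0"]),
            "B": _de_table(self.UNIVERSE[:5], up=["mir0"]),
        }
        with pytest.warns(UserWarning, match="universes"):
            comp = compare_sets(tables)
        assert set(comp.membership.index) == set(self.UNIVERSE[:5])

    def test_counts_match_membership_brute_force(self, rng):
        genotypes = ["Beng", "Cyp", "KB", "Lagr", "NB"]
        dirs = np.array(["up", "down", "ns"])
        tables = {}
        for g in genotypes:
            choice = dirs[rng.integers(0, 3, size=len(self.UNIVERSE))]
            tables[g] = pd.DataFrame({"direction": choice}, index=self.UNIVERSE)
        comp = compare_sets(tables, low_group=["Cyp", "KB"], high_group=["Lagr", "NB"])
        # brute force over the membership matrix
        M = comp.membership
        for direction, shared in (("up", comp.shared_up), ("down", comp.shared_down)):
            expect = {m for m in M.index if all(M.loc[m, g] == direction for g in genotypes)}
            assert shared == expect
        for g in genotypes:
            for direction in ("up", "down"):
                expect = {
                    m
                    for m in M.index
                    if M.loc[m, g] == direction
                    and all(M.loc[m, h] != direction for h in genotypes if h != g)
                }
                assert comp.genotype_specific[f"{g}_{direction}"] == expect
        for label, members, other in (
            ("low", ["Cyp", "KB"], ["Lagr", "NB"]),
            ("high", ["Lagr", "NB"], ["Cyp", "KB"]),
        ):
            for direction in ("up", "down"):
                expect = {
                    m
                    for m in M.index
                    if all(M.loc[m, g] == direction for g in members)
                    and all(M.loc[m, h] != direction for h in other)
                }
                assert comp.group_exclusive[f"{label}_{direction}"] == expect
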