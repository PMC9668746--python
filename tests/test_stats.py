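"""Territory statistics: assignment, DE, BH, GLMM enrichment, Fisher exact."""

from fractions import Fraction
from itertools import product
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import clonemapper as cm
from clonemapper.io import CellTable, ValidationError
from clonemapper.postprocess import DominantCloneField
from clonemapper.stats import (
    MASKED,
    assign_cells,
    benjamini_hochberg,
    celltype_glmm,
    differential_expression,
    fisher_exact_rxc,
    histology_association,
)


def _field(labels, nx, ny):
    grid = cm.make_grid((0, 0, 100.0 * nx, 100.0 * ny), tile_size=100.0)
    labels = np.asarray(labels, dtype=object)
    reason = np.where(labels == "", "low_ccf", "").astype(object)
    return DominantCloneField(grid, labels, reason, np.zeros(len(labels), bool))


class TestAssignCells:
    def test_labels_and_masking(self):
        field = _field(["c1", "", "c2"], nx=3, ny=1)
        cells = CellTable(
            pd.DataFrame({"x": [50.0, 150.0, 250.0, 999.0], "y": [50.0] * 4})
        )
        out = assign_cells(cells, field)
        assert list(out.labels) == ["c1", MASKED, "c2", MASKED]
        assert list(out.cells_in("c1")) == [0]

    def test_counts_partition_cells(self):
        rng = np.random.default_rng(0)
        field = _field(["c1", "c2", "", "c1"], nx=2, ny=2)
        cells = CellTable(
            pd.DataFrame(
                {"x": rng.uniform(0, 200, 300), "y": rng.uniform(0, 200, 300)}
            )
        )
        out = assign_cells(cells, field)
        n = sum(len(out.cells_in(l)) for l in ("c1", "c2", MASKED))
        assert n == 300


class TestDifferentialExpression:
    def _cells_with_counts(self, rng, n_a=80, n_b=80, enriched_factor=3.0):
        n = n_a + n_b
        genes = [f"g{i}" for i in range(6)]
        base = rng.uniform(2, 6, len(genes))
        counts = np.empty((n, len(genes)), dtype=int)
        for i in range(n):
            mu = base.copy()
            if i < n_a:
                mu[0] *= enriched_factor
            counts[i] = rng.poisson(mu)
        cells = CellTable(
            pd.DataFrame({"x": np.zeros(n), "y": np.zeros(n)}),
            gene_counts=pd.DataFrame(counts, columns=genes),
        )
        labels = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
        assignment = cm.stats.TerritoryAssignment(labels, np.zeros(n, int))
        return cells, assignment

    def test_detects_enriched_gene(self):
        rng = np.random.default_rng(1)
        cells, assignment = self._cells_with_counts(rng)
        res = differential_expression(cells, assignment, "A", "B")
        assert bool(res.loc["g0", "significant"])
        assert res.loc["g0", "fold_change"] > 1.5
        # the spiked gene is the clearest hit; per-cell normalization pushes
        # the remaining genes the other way but never past it
        assert res["log2_fc"].abs().idxmax() == "g0"
        assert (res.drop(index="g0")["log2_fc"].abs()
                < res.loc["g0", "log2_fc"]).all()

    def test_symmetric_rule_catches_depletion(self):
        rng = np.random.default_rng(2)
        cells, assignment = self._cells_with_counts(rng, enriched_factor=1 / 4)
        res = differential_expression(cells, assignment, "A", "B")
        assert bool(res.loc["g0", "significant"])
        assert res.loc["g0", "fold_change"] < 1 / 1.5

    def test_group_size_guard_names_sizes(self):
        rng = np.random.default_rng(3)
        cells, assignment = self._cells_with_counts(rng, n_a=5, n_b=80)
        with pytest.raises(ValidationError, match="A: 5"):
            differential_expression(cells, assignment, "A", "B")

    def test_requires_gene_counts(self):
        cells = CellTable(pd.DataFrame({"x": [0.0], "y": [0.0]}))
        assignment = cm.stats.TerritoryAssignment(
            np.array(["A"], object), np.zeros(1, int)
        )
        with pytest.raises(ValidationError, match="gene counts"):
            differential_expression(cells, assignment, "A", "B")


class TestBenjaminiHochberg:
    @staticmethod
    def _bh_reference(p):
        """Textbook BH: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate(
            (m * p[order] / (np.arange(m) + 1))[::-1]
        )[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=25))
    def test_matches_textbook_definition(self, pvals):
        np.testing.assert_allclose(
            benjamini_hochberg(np.array(pvals)), self._bh_reference(pvals),
            rtol=1e-12, atol=1e-15,
        )

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 40)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()


class TestGLMM:
    def _dataset(self, rng, n_regions=20, beta=np.log(2.0), total_n=400):
        frac = pd.DataFrame(
            {"cloneA": rng.uniform(0, 1, n_regions)},
            index=[f"r{i}" for i in range(n_regions)],
        )
        total = pd.Series(total_n, index=frac.index)
        mu = total * 0.05 * np.exp(beta * frac["cloneA"])
        counts = pd.DataFrame(
            {"myeloid": rng.poisson(mu)}, index=frac.index
        )
        return counts, frac, total

    def test_recovers_enrichment_direction(self):
        rng = np.random.default_rng(0)
        counts, frac, total = self._dataset(rng, beta=np.log(3.0), total_n=800)
        res = celltype_glmm(counts, frac, total, seed=0)
        row = res.summary.loc[("myeloid", "cloneA")]
        assert row["beta_mean"] > 0
        assert row["ci_lo"] > 0
        assert row["converged"]

    def test_null_is_not_significant(self):
        rng = np.random.default_rng(1)
        counts, frac, total = self._dataset(rng, beta=0.0)
        res = celltype_glmm(counts, frac, total, seed=0)
        row = res.summary.loc[("myeloid", "cloneA")]
        assert row["ci_lo"] < 0 < row["ci_hi"]

    def test_input_validation(self):
        rng = np.random.default_rng(2)
        counts, frac, total = self._dataset(rng, n_regions=4)
        with pytest.raises(ValidationError, match="5 regions"):
            celltype_glmm(counts, frac, total)
        counts, frac, total = self._dataset(rng)
        frac.iloc[0, 0] = 1.3
        with pytest.raises(ValidationError, match="\\[0, 1\\]"):
            celltype_glmm(counts, frac, total)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        counts, frac, total = self._dataset(rng, n_regions=8)
        a = celltype_glmm(counts, frac, total, seed=5, n_steps=400, burn=100)
        b = celltype_glmm(counts, frac, total, seed=5, n_steps=400, burn=100)
        pd.testing.assert_frame_equal(a.summary, b.summary)


def _fisher_oracle(table):
    """Exact two-sided Fisher p via Fraction arithmetic (independent oracle)."""
    table = np.asarray(table, int)
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = int(table.sum())

    def prob(t):
        num = 1
        for r in rows:
            num *= factorial(int(r))
        for c in cols:
            num *= factorial(int(c))
        den = factorial(n)
        for v in t.ravel():
            den *= factorial(int(v))
        return Fraction(num, den)

    p_obs = prob(table)
    total = Fraction(0)
    n_r, n_c = table.shape

    def tables(i, remaining):
        if i == n_r - 1:
            if (remaining >= 0).all():
                yield remaining[None, :]
            return
        target = int(rows[i])
        for combo in product(*[range(min(target, int(remaining[j])) + 1)
                               for j in range(n_c - 1)]):
            last = target - sum(combo)
            if last < 0 or last > remaining[-1]:
                continue
            row = np.array(list(combo) + [last])
            for rest in tables(i + 1, remaining - row):
                yield np.vstack([row, rest])

    for t in tables(0, cols.copy()):
        if prob(t) <= p_obs:
            total += prob(t)
    return float(total)


class TestFisherExact:
    def test_two_by_two_textbook_value(self):
        # [[3,0],[0,3]]: only the two perfectly separated tables are as
        # extreme; p = 2 / C(6,3) = 0.1
        assert fisher_exact_rxc(np.array([[3, 0], [0, 3]])) == pytest.approx(0.1)

    def test_two_by_two_matches_scipy(self):
        rng = np.random.default_rng(0)
        from scipy import stats as sps

        for _ in range(10):
            t = rng.integers(0, 8, size=(2, 2))
            assert fisher_exact_rxc(t) == pytest.approx(
                sps.fisher_exact(t)[1], rel=1e-9
            )

    @pytest.mark.parametrize(
        "table",
        [
            [[4, 1, 0], [0, 2, 5]],
            [[2, 2, 2], [3, 0, 1], [0, 4, 0]],
            [[6, 0], [1, 3], [0, 4]],
        ],
    )
    def test_rxc_enumeration_matches_fraction_oracle(self, table):
        assert fisher_exact_rxc(np.array(table)) == pytest.approx(
            _fisher_oracle(table), rel=1e-9
        )

    def test_monte_carlo_fallback_close_to_exact(self):
        table = np.array([[4, 1, 0], [0, 2, 5]])
        exact = fisher_exact_rxc(table)
        mc = fisher_exact_rxc(table, max_enumeration=1, n_mc=40_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_independence_gives_large_p(self):
        table = np.array([[5, 5, 5], [5, 5, 5]])
        assert fisher_exact_rxc(table) == pytest.approx(1.0, abs=1e-9)


class TestHistologyAssociation:
    def _table(self):
        # clone A regions are ductal, clone B lobular; 'grade' is balanced
        rows = []
        for i in range(7):
            rows.append({"dominant_clone": "A", "hist": "DCIS",
                         "grade": ["low", "high"][i % 2], "fixed": "x"})
        for i in range(7):
            rows.append({"dominant_clone": "B", "hist": "invasive",
                         "grade": ["low", "high"][i % 2], "fixed": "x"})
        return pd.DataFrame(rows, index=[f"r{i}" for i in range(14)])

    def test_association_and_bonferroni(self):
        out = histology_association(self._table())
        # two testable features -> Bonferroni factor 2
        assert out.loc["hist", "p_bonferroni"] == pytest.approx(
            min(out.loc["hist", "p"] * 2, 1.0)
        )
        assert out.loc["hist", "p_bonferroni"] < 0.01
        assert out.loc["grade", "p"] > 0.5

    def test_single_category_skipped_with_note(self):
        out = histology_association(self._table())
        assert np.isnan(out.loc["fixed", "p"])
        assert "skipped" in out.loc["fixed", "note"]

    def test_requires_two_clones(self):
        tab = self._table()
        tab["dominant_clone"] = "A"
        with pytest.raises(ValidationError, match="clones"):
            histology_association(tab)
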