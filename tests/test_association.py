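"""Bayesian correlation screening, MPE gate, and paired position tests."""

import numpy as np
import pandas as pd
import pytest

from cardioresp.association import (
    bayes_correlation,
    correlation_matrix,
    position_tests,
)
from cardioresp.synthetic import SCMSpec, generate_scm_table
from cardioresp.types import ParameterTable


class TestBayesCorrelation:
    def test_identity_pair(self):
        x = np.arange(20, dtype=float)
        res = bayes_correlation(x, x.copy())
        assert res.cor == pytest.approx(1.0)
        assert res.mpe > 0.999
        assert res.significant

    def test_negative_scaling(self):
        x = np.linspace(-1, 1, 30) + np.sin(np.arange(30))
        res = bayes_correlation(x, -2.0 * x)
        assert res.cor == pytest.approx(-1.0)

    def test_point_estimate_equals_pearson(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=40)
            y = rng.normal(size=40) + 0.3 * x
            r = np.corrcoef(x, y)[0, 1]
            assert abs(bayes_correlation(x, y).cor - r) < 1e-10

    def test_affine_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        base = bayes_correlation(x, y)
        flipped = bayes_correlation(3.0 - 2.0 * x, 5.0 + 4.0 * y)
        assert flipped.cor == pytest.approx(-base.cor, abs=1e-12)
        assert flipped.mpe == pytest.approx(base.mpe, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bayes_correlation(np.ones(20), np.arange(20.0))
        with pytest.raises(ValueError):
            bayes_correlation(np.arange(20.0), np.arange(21.0))
        with pytest.raises(ValueError):
            bayes_correlation(np.arange(5.0), np.arange(5.0))

    def test_null_mpe_exceedance_near_twenty_percent(self):
        # MPE > 0.9 under beta = 0 is equivalent to two-sided p < 0.2
        rng = np.random.default_rng(0)
        exceed = sum(
            bayes_correlation(rng.normal(size=100), rng.normal(size=100)).mpe > 0.9
            for _ in range(200)
        )
        assert 0.10 <= exceed / 200 <= 0.30


class TestCorrelationMatrix:
    def test_null_table_mostly_masked(self):
        spec = SCMSpec(node_names=tuple("ABCDE"), edges=(), n=100, seed=13)
        table, _ = generate_scm_table(spec)
        result = correlation_matrix(table)
        frame = result.to_frame(masked=True)
        n_cells = len(table.columns) * (len(table.columns) - 1)
        assert frame.isna().to_numpy().sum() >= 0.6 * n_cells + len(table.columns)

    def test_perfect_pair_single_cell(self):
        x = np.random.default_rng(2).normal(size=30)
        table = ParameterTable(pd.DataFrame({"a": x, "b": 2 * x}))
        result = correlation_matrix(table)
        res = result.results[frozenset(("a", "b"))]
        assert res.cor == pytest.approx(1.0)
        assert res.significant

    def test_degenerate_column_masked_with_reason(self):
        rng = np.random.default_rng(3)
        table = ParameterTable(pd.DataFrame({
            "a": rng.normal(size=20), "b": np.ones(20),
        }))
        result = correlation_matrix(table)
        assert frozenset(("a", "b")) in result.masked_reasons


class TestPositionTests:
    def _tables(self, n=30, seed=0, shift=0.0, noise=1.0):
        rng = np.random.default_rng(seed)
        base = rng.normal(60, 5, size=n)
        supine = ParameterTable(
            pd.DataFrame({"HR": base}, index=[f"S{i}" for i in range(n)]),
            position="supine",
        )
        standing = ParameterTable(
            pd.DataFrame(
                {"HR": base + shift + rng.normal(0, noise, n)},
                index=[f"S{i}" for i in range(n)],
            ),
            position="standing",
        )
        return supine, standing

    def test_constant_shift_detected(self):
        supine, standing = self._tables(shift=10.0, noise=0.5)
        (res,) = position_tests(supine, standing)
        assert res.p_value < 1e-3

    def test_identical_tables_degenerate(self):
        supine, standing = self._tables(shift=0.0, noise=0.0)
        (res,) = position_tests(supine, standing)
        assert res.test_used == "degenerate"
        assert res.p_value == 1.0

    def test_null_pvalues_roughly_uniform(self):
        ps = []
        for seed in range(40):
            supine, standing = self._tables(n=50, seed=seed, shift=0.0, noise=1.0)
            ps.append(position_tests(supine, standing)[0].p_value)
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.15
        assert ps.mean() == pytest.approx(0.5, abs=0.2)

    def test_too_few_pairs(self):
        supine, standing = self._tables(n=2)
        with pytest.raises(ValueError):
            position_tests(supine, standing)
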