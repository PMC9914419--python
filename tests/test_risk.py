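import numpy as np
import pandas as pd
import pytest

import leriscape as L
from leriscape.risk import ClassificationScheme, RISK_LEVELS
from oracles import brute_force_leri, exhaustive_jenks


def _long(cell_rows):
    """Build (metrics, F) long frames from {cell: [(code, E, F, area), ...]}."""
    m_rows, f_rows = [], []
    for cid, rows in cell_rows.items():
        for code, e, f, a in rows:
            m_rows.append({"cell_id": cid, "class_code": code, "area_km2": a, "E": e})
            f_rows.append({"cell_id": cid, "class_code": code, "F": f})
    return pd.DataFrame(m_rows), pd.DataFrame(f_rows)


class TestLeri:
    def test_single_class_identity(self):
        m, f = _long({0: [(1, 1.0, 1.0, 400.0)]})
        assert L.leri(m, f)[0] == pytest.approx(1.0)

    def test_weighted_mean_of_two_classes(self):
        m, f = _long({0: [(1, 1.0, 2.0, 200.0), (5, 2.0, 2.0, 200.0)]})
        assert L.leri(m, f)[0] == pytest.approx(3.0)

    def test_zero_disturbance_gives_zero(self):
        m, f = _long({0: [(1, 0.0, 4.0, 100.0), (2, 0.0, 2.0, 300.0)]})
        assert L.leri(m, f)[0] == 0.0

    def test_bounded_by_max_EF(self):
        rng = np.random.default_rng(0)
        rows = {0: [(c, rng.random() * 2, rng.random() * 6, rng.random() + 0.1)
                    for c in range(1, 7)]}
        m, f = _long(rows)
        assert L.leri(m, f)[0] <= max(e * fv for _, e, fv, _ in rows[0]) + 1e-12

    def test_matches_brute_force_on_random_toy_cells(self):
        rng = np.random.default_rng(11)
        rows = {}
        for cid in range(50):
            rows[cid] = [
                (c, rng.random() * 3, rng.random() * 6, rng.random() * 100 + 1)
                for c in rng.choice(range(1, 7), size=rng.integers(1, 7), replace=False)
            ]
        m, f = _long(rows)
        result = L.leri(m, f)
        for cid, triples in rows.items():
            expected = brute_force_leri((e, fv, a) for _, e, fv, a in triples)
            assert result[cid] == pytest.approx(expected)

    def test_closed_form_limit_uniform_cell(self, grid):
        """With MN ≡ 1 and one class filling each cell, LERI = E · EV."""
        from conftest import toy_raster

        lc = toy_raster(np.full((100, 100), 3))  # all grassland
        metrics = L.compute_cell_metrics(grid, lc)
        mn = pd.Series(1.0, index=grid.cell_ids)
        f = L.vulnerability_index(L.VulnerabilityConfig(), mn)
        result = L.leri(metrics, f)
        e_grass = metrics.set_index(["cell_id", "class_code"])["E"]
        for cid in grid.cell_ids:
            assert result[cid] == pytest.approx(e_grass[(cid, 3)] * 3.0)


class TestClassify:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.5999, "low"),
            (0.60, "medium-low"),
            (1.3443, "medium"),
            (1.72, "medium-high"),
            (2.3999, "medium-high"),
            (2.40, "high"),
            (10.0, "high"),
        ],
    )
    def test_fixed_break_boundaries(self, value, label):
        assert L.classify(value) == label

    def test_published_yearly_means_are_medium(self):
        means = [1.3443, 1.3275, 1.3142, 1.3107, 1.2180]
        assert list(L.classify(means)) == ["medium"] * 5

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            L.classify(-0.1)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            ClassificationScheme(breaks=(1.0, 0.5, 2.0, 3.0)).validate()


class TestJenksBreaks:
    def test_two_obvious_clusters(self):
        scheme = L.jenks_breaks([1, 2, 3, 10, 11, 12], 2)
        labels = L.classify(np.array([1, 2, 3, 10, 11, 12], float), scheme)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            L.jenks_breaks([2.0] * 10, 2)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_partition_oracle(self, k):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n = int(rng.integers(k + 1, 21))
            x = np.round(rng.random(n) * 10, 3)
            if np.unique(x).size < k:
                continue
            scheme = L.jenks_breaks(x, k)
            labels = L.classify(np.sort(x), scheme)
            groups = {}
            for v, lab in zip(np.sort(x), labels):
                groups.setdefault(lab, []).append(v)
            cost = sum(
                np.sum((np.array(g) - np.mean(g)) ** 2) for g in groups.values()
            )
            best_cost, _ = exhaustive_jenks(x, k)
            assert cost == pytest.approx(best_cost, abs=1e-9)


class TestTemporalStats:
    def test_rrc_direct_values(self):
        assert L.risk_rate_of_change(1.0, 0.8, 5) == pytest.approx(-4.0)
        assert L.risk_rate_of_change(1.3, 1.3, 5) == 0.0
        assert L.risk_rate_of_change(1.0, 2.0, 1) == pytest.approx(100.0)

    def test_rrc_undefined_for_zero_start(self):
        out = L.risk_rate_of_change(pd.Series([0.0, 1.0]), pd.Series([1.0, 1.0]), 5)
        assert np.isnan(out.iloc[0]) and out.iloc[1] == 0.0

    def test_rrc_invalid_span(self):
        with pytest.raises(ValueError):
            L.risk_rate_of_change(1.0, 1.0, 0)

    def test_cv_constant_series_is_zero(self):
        panel = pd.DataFrame([[1.3, 1.3, 1.3]])
        assert L.coefficient_of_variation(panel).iloc[0] == 0.0

    def test_cv_hand_computed_sample_sd(self):
        panel = pd.DataFrame([[1.0, 1.0, 1.0, 1.0, 2.0]])
        expected = np.sqrt(0.2) / 1.2
        assert L.coefficient_of_variation(panel).iloc[0] == pytest.approx(expected)

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(9)
        panel = pd.DataFrame(rng.random((20, 5)) + 0.5)
        cv = L.coefficient_of_variation(panel)
        assert np.allclose(L.coefficient_of_variation(panel * 3.7), cv)

    def test_cv_needs_two_points(self):
        with pytest.raises(ValueError):
            L.coefficient_of_variation(pd.DataFrame([[1.0]]))


def test_relabeling_invariance_of_leri():
    """Swapping two class codes (with matched EV swap) leaves LERI unchanged."""
    rng = np.random.default_rng(13)
    m, f = [], []
    for cid in range(10):
        for code in (1, 2):
            e, a = rng.random(), rng.random() * 50 + 1
            m.append({"cell_id": cid, "class_code": code, "area_km2": a, "E": e})
            f.append({"cell_id": cid, "class_code": code, "F": (4.0 if code == 1 else 2.0)})
    m, f = pd.DataFrame(m), pd.DataFrame(f)
    base = L.leri(m, f)
    swap = {1: 2, 2: 1}
    m2 = m.assign(class_code=m.class_code.map(swap))
    f2 = f.assign(class_code=f.class_code.map(swap))
    assert np.allclose(L.leri(m2, f2), base)
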