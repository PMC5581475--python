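import math

import numpy as np
import pytest

from contactrank.evaluation import (
    aggregate_report,
    evaluate_target,
    k_from_L,
    paired_t_test,
    precision_at_k,
    scatter_report,
)
from contactrank.geometry import (
    ProteinRecord,
    RangeClass,
    contact_map,
    enumerate_pairs,
)
from contactrank.io_formats import PredictionList
from contactrank.synthetic import generate_structure


class TestKFromL:
    @pytest.mark.parametrize("L,metric,expected", [
        (100, "L5", 20),
        (100, "L10", 10),
        (47, "L10", 4),     # floor
        (47, "L5", 9),      # floor
        (9, "L10", 1),      # clamp: floor gives 0
        (4, "L5", 1),       # clamp
        (300, "top5", 5),
        (1, "top5", 5),
    ])
    def test_values(self, L, metric, expected):
        assert k_from_L(L, metric) == expected

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            k_from_L(0, "L5")
        with pytest.raises(ValueError):
            k_from_L(10, "L7")


def _oracle_setup(L=40, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 18, size=(L, 3))
    record = ProteinRecord(id="t", sequence="A" * L, coords=coords)
    return record, contact_map(record)


class TestPrecisionAtK:
    def test_13_of_20(self):
        record, cmap = _oracle_setup()
        pairs = enumerate_pairs(40, RangeClass.SHORT)
        labels = [bool(cmap.contacts[i - 1, j - 1]) for i, j in pairs]
        # order predictions so exactly 13 of the top 20 are contacts
        pos = [p for p, l in zip(pairs, labels) if l][:13]
        neg = [p for p, l in zip(pairs, labels) if not l][:7]
        if len(pos) < 13:  # regenerate with denser structure if unlucky
            pytest.skip("fixture lacks 13 short-range contacts")
        chosen = pos + neg
        records = [(i, j, 1.0 - 0.01 * k) for k, (i, j) in enumerate(chosen)]
        plist = PredictionList("t", records=records)
        assert precision_at_k(plist, cmap, RangeClass.SHORT, 20) == pytest.approx(65.0)

    def test_oracle_predictions_score_100(self):
        record, cmap = generate_structure(60, 1)
        for rc in (RangeClass.SHORT, RangeClass.MEDIUM, RangeClass.LONG):
            pairs = [
                (i, j) for i, j in enumerate_pairs(60, rc)
                if cmap.contacts[i - 1, j - 1]
            ]
            if not pairs:
                continue
            plist = PredictionList("t", records=[(i, j, 1.0) for i, j in pairs])
            k = min(5, len(pairs))
            assert precision_at_k(plist, cmap, rc, k) == 100.0

    def test_3_of_top5(self):
        record, cmap = _oracle_setup(seed=3)
        pairs = enumerate_pairs(40, RangeClass.MEDIUM)
        labels = [bool(cmap.contacts[i - 1, j - 1]) for i, j in pairs]
        pos = [p for p, l in zip(pairs, labels) if l][:3]
        neg = [p for p, l in zip(pairs, labels) if not l][:2]
        if len(pos) < 3:
            pytest.skip("fixture lacks 3 medium-range contacts")
        records = [(i, j, 1.0 - 0.01 * k) for k, (i, j) in enumerate(pos + neg)]
        assert precision_at_k(PredictionList("t", records=records),
                              cmap, RangeClass.MEDIUM, 5) == pytest.approx(60.0)

    def test_short_list_uses_taken_count(self):
        record, cmap = _oracle_setup()
        pairs = enumerate_pairs(40, RangeClass.LONG)
        i, j = pairs[0]
        plist = PredictionList("t", records=[(i, j, 0.9)])
        expected = 100.0 * int(cmap.contacts[i - 1, j - 1])
        assert precision_at_k(plist, cmap, RangeClass.LONG, 20) == expected

    def test_undefined_labels_excluded(self):
        coords = np.full((40, 3), np.nan)
        coords[0] = [0, 0, 0]
        coords[29] = [3, 0, 0]
        record = ProteinRecord(id="t", sequence="A" * 40, coords=coords)
        cmap = contact_map(record)
        plist = PredictionList(
            "t", records=[(1, 30, 0.9), (2, 31, 0.8)]  # second pair undefined
        )
        assert precision_at_k(plist, cmap, RangeClass.LONG, 2) == 100.0

    def test_no_defined_labels_returns_none(self):
        coords = np.full((40, 3), np.nan)
        coords[0] = [0, 0, 0]
        coords[1] = [3.8, 0, 0]
        record = ProteinRecord(id="t", sequence="A" * 40, coords=coords)
        cmap = contact_map(record)
        plist = PredictionList("t", records=[(5, 35, 0.9)])
        with pytest.warns(UserWarning):
            assert precision_at_k(plist, cmap, RangeClass.LONG, 1) is None

    def test_monotone_improvement(self):
        # replacing a false positive in the top-k with a true contact never
        # lowers precision
        record, cmap = _oracle_setup(seed=5)
        pairs = enumerate_pairs(40, RangeClass.SHORT)
        labels = {p: bool(cmap.contacts[p[0] - 1, p[1] - 1]) for p in pairs}
        pos = [p for p in pairs if labels[p]]
        neg = [p for p in pairs if not labels[p]]
        if not pos or len(neg) < 5:
            pytest.skip("fixture imbalance")
        base = neg[:5]
        better = [pos[0]] + neg[1:5]
        p_base = precision_at_k(
            PredictionList("t", records=[(i, j, 0.9) for i, j in base]),
            cmap, RangeClass.SHORT, 5)
        p_better = precision_at_k(
            PredictionList("t", records=[(i, j, 0.9) for i, j in better]),
            cmap, RangeClass.SHORT, 5)
        assert p_better >= p_base


class TestPairedTTest:
    def test_identical_vectors(self):
        a = np.array([50.0, 60.0, 70.0])
        assert paired_t_test(a, a.copy()) == 1.0

    def test_constant_shift_zero_noise(self):
        a = np.array([50.0, 60.0, 70.0, 80.0])
        assert paired_t_test(a, a + 5.0) == 0.0

    def test_matches_hand_computed_statistic(self):
        # 5-target fixture; oracle: t = dbar / (s_d / sqrt(n)), two-sided p
        # from the t distribution with n-1 dof, computed by hand below
        a = np.array([60.0, 55.0, 70.0, 40.0, 65.0])
        b = np.array([50.0, 52.0, 61.0, 43.0, 58.0])
        d = a - b                              # [10, 3, 9, -3, 7]
        dbar = d.mean()                        # 5.2
        s_d = math.sqrt(((d - dbar) ** 2).sum() / 4)
        t = dbar / (s_d / math.sqrt(5))
        from scipy.stats import t as tdist
        p_oracle = 2 * tdist.sf(abs(t), df=4)
        assert paired_t_test(a, b) == pytest.approx(p_oracle, abs=1e-12)

    def test_shape_and_n_guards(self):
        with pytest.raises(ValueError):
            paired_t_test(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            paired_t_test(np.ones(1), np.ones(1))


class TestScatterReport:
    def test_equal_methods_all_diagonal(self):
        a = {"t1": 50.0, "t2": 60.0}
        df = scatter_report(a, dict(a))
        assert (df["side"] == "diagonal").all()

    def test_one_target_better(self):
        a = {"t1": 50.0, "t2": 60.0}
        b = {"t1": 50.0, "t2": 55.0}
        df = scatter_report(a, b)
        assert (df["side"] == "below").sum() == 1

    def test_partition(self):
        rng = np.random.default_rng(0)
        a = {f"t{k}": float(rng.uniform(0, 100)) for k in range(10)}
        b = {f"t{k}": float(rng.uniform(0, 100)) for k in range(10)}
        df = scatter_report(a, b)
        counts = df["side"].value_counts()
        assert counts.sum() == 10

    def test_disjoint_raises(self):
        with pytest.raises(ValueError):
            scatter_report({"a": 1.0}, {"b": 2.0})


class TestAggregation:
    def test_macro_mean(self):
        record, cmap = generate_structure(60, 2)
        evals = []
        for tid in ("A", "B"):
            per_range = {}
            for rc in (RangeClass.SHORT, RangeClass.MEDIUM, RangeClass.LONG):
                pairs = enumerate_pairs(60, rc)
                recs = [(i, j, 0.5) for i, j in pairs[:10]]
                per_range[rc] = PredictionList(tid, records=recs)
            evals.append(evaluate_target(per_range, cmap, 60))
        df = aggregate_report(evals)
        mean_rows = df[df["target"] == "MEAN"]
        assert len(mean_rows) == 9  # 3 ranges x 3 metrics
        for _, row in mean_rows.iterrows():
            cell = df[(df["target"] != "MEAN") & (df["range"] == row["range"])
                      & (df["metric"] == row["metric"])]["precision"]
            assert row["precision"] == pytest.approx(cell.mean())

    def test_report_row_count(self):
        record, cmap = generate_structure(60, 2)
        per_range = {
            rc: PredictionList(
                "A", records=[(i, j, 0.5) for i, j in enumerate_pairs(60, rc)[:5]]
            )
            for rc in (RangeClass.SHORT, RangeClass.MEDIUM, RangeClass.LONG)
        }
        df = aggregate_report([evaluate_target(per_range, cmap, 60)])
        assert len(df) == 1 * 9 + 9  # per-target cells + MEAN rows
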