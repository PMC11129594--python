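"""Hot/cold typing, immune ITH, and immunoediting scores."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spatialevo import immune as IM
from spatialevo.simdata import CELL_TYPES, generate_cell_fractions


def cells_frame(vectors, patients=None, regions=None):
    df = pd.DataFrame(vectors, columns=CELL_TYPES)
    n = len(df)
    df.insert(0, "patient", patients or [f"P{i}" for i in range(n)])
    df.insert(1, "region", regions or ["T5"] * n)
    return df


class TestHotCold:
    def test_two_region_cd8_defines_hot(self):
        base = np.full(len(CELL_TYPES), 1.0 / len(CELL_TYPES))
        hot = base.copy(); hot[0] = 0.30
        cold = base.copy(); cold[0] = 0.02
        hot /= hot.sum(); cold /= cold.sum()
        cells = cells_frame([hot, cold], patients=["P1", "P1"], regions=["T1", "T3"])
        labels = IM.cluster_hot_cold(cells)
        assert labels[("P1", "T1")] == "hot"
        assert labels[("P1", "T3")] == "cold"

    def test_generative_recovery(self, rng):
        profiles = ["hot"] * 60 + ["cold"] * 60
        cells = generate_cell_fractions(profiles, concentration=200, seed=rng)
        cells.insert(0, "patient", [f"P{i}" for i in range(120)])
        cells.insert(1, "region", ["T5"] * 120)
        labels = IM.cluster_hot_cold(cells)
        agreement = (labels.to_numpy() == np.array(profiles)).mean()
        assert agreement >= 0.95

    def test_degenerate_identical_rows(self):
        v = np.full(len(CELL_TYPES), 1.0 / len(CELL_TYPES))
        cells = cells_frame([v, v, v])
        with pytest.raises(ValueError):
            IM.cluster_hot_cold(cells)

    def test_order_invariance(self, rng):
        profiles = ["hot"] * 20 + ["cold"] * 20
        cells = generate_cell_fractions(profiles, concentration=200, seed=rng)
        cells.insert(0, "patient", [f"P{i}" for i in range(40)])
        cells.insert(1, "region", ["T5"] * 40)
        l1 = IM.cluster_hot_cold(cells)
        perm = rng.permutation(40)
        l2 = IM.cluster_hot_cold(cells.iloc[perm].reset_index(drop=True))
        for key in l1.index:
            assert l1[key] == l2[key]


class TestPatientTyping:
    @pytest.mark.parametrize("combo", list(itertools.product(["hot", "cold"], repeat=3)))
    def test_all_label_combinations(self, combo):
        labels = pd.Series(
            list(combo),
            index=pd.MultiIndex.from_tuples([("P1", f"T{i+1}") for i in range(3)]),
        )
        res = IM.patient_immune_type(labels)
        expected = ("hot" if set(combo) == {"hot"}
                    else "cold" if set(combo) == {"cold"} else "het")
        assert res.patient_types["P1"] == expected

    def test_single_region_undetermined(self):
        labels = pd.Series(["hot"], index=pd.MultiIndex.from_tuples([("P1", "T5")]))
        assert IM.patient_immune_type(labels).patient_types["P1"] == "undetermined"

    def test_iith_zero_for_identical_vectors(self):
        v = np.full(len(CELL_TYPES), 1.0 / len(CELL_TYPES))
        cells = cells_frame([v, v], patients=["P1", "P1"], regions=["T1", "T5"])
        labels = pd.Series(
            ["hot", "hot"],
            index=pd.MultiIndex.from_tuples([("P1", "T1"), ("P1", "T5")]),
        )
        res = IM.patient_immune_type(labels, cells)
        assert res.iith["P1"] == 0.0

    def test_iith_bounded_for_simplex_rows(self, rng):
        vecs = rng.dirichlet(np.ones(len(CELL_TYPES)), size=6)
        cells = cells_frame(list(vecs), patients=["P1"] * 6,
                            regions=[f"T{i+1}" for i in range(5)] + ["LN1"])
        labels = pd.Series(["hot"] * 6, index=pd.MultiIndex.from_frame(
            cells[["patient", "region"]]))
        res = IM.patient_immune_type(labels, cells)
        assert 0.0 <= res.iith["P1"] <= 2.0


def muts_frame(n_neo, n_total, context="C>T"):
    return pd.DataFrame({
        "neoantigen_flag": [True] * n_neo + [False] * (n_total - n_neo),
        "context": [context] * n_total,
        "consequence": ["nonsyn"] * n_total,
    })


class TestIMScore:
    def test_arithmetic(self):
        res = IM.im_score(muts_frame(5, 50), {"*": 0.2})
        assert res.im_score == pytest.approx(0.5)
        assert res.observed_rate == pytest.approx(0.1)

    def test_equal_rates_give_one(self):
        res = IM.im_score(muts_frame(10, 50), {"*": 0.2})
        assert res.im_score == pytest.approx(1.0)

    def test_duplication_invariance(self):
        a = IM.im_score(muts_frame(4, 40), {"*": 0.1})
        b = IM.im_score(pd.concat([muts_frame(4, 40)] * 3), {"*": 0.1})
        assert a.im_score == pytest.approx(b.im_score)

    def test_context_weighting(self):
        df = pd.concat([muts_frame(2, 10, "C>T"), muts_frame(4, 30, "T>C")])
        rates = {"C>T": 0.3, "T>C": 0.1}
        res = IM.im_score(df, rates)
        # expected rate = 0.25*0.3 + 0.75*0.1
        assert res.expected_rate == pytest.approx(0.25 * 0.3 + 0.75 * 0.1)

    def test_flat_table_reduces_to_rate_ratio(self):
        res = IM.im_score(muts_frame(7, 70), IM.flat_rate_table(0.35))
        assert res.im_score == pytest.approx((7 / 70) / 0.35)

    def test_low_confidence_below_minimum(self):
        res = IM.im_score(muts_frame(1, 5), {"*": 0.2})
        assert res.low_confidence

    def test_zero_expected_rate_rejected(self):
        with pytest.raises(ValueError):
            IM.im_score(muts_frame(1, 20), {"*": 0.0})


class TestIMByClade:
    def test_identical_groups_p_near_one(self):
        clades = {f"c{i}": muts_frame(3, 30) for i in range(8)}
        regions = {f"c{i}": {"T1", "T5"} if i < 4 else {"T3", "T5"} for i in range(8)}
        _, _, p = IM.im_by_clade(clades, regions, {"*": 0.1})
        assert p > 0.5

    def test_constructed_separation(self):
        clades = {}
        regions = {}
        for i in range(10):
            clades[f"t1_{i}"] = muts_frame(5 + (i % 2), 100)   # IM ~ 0.5
            regions[f"t1_{i}"] = {"T1", "T5"}
            clades[f"o_{i}"] = muts_frame(10 + (i % 2), 100)   # IM ~ 1.0
            regions[f"o_{i}"] = {"T3", "T5"}
        _, _, p = IM.im_by_clade(clades, regions, {"*": 0.1}, alternative="less")
        assert p < 0.01

    def test_small_clades_excluded(self):
        clades = {"small": muts_frame(1, 3), "big": muts_frame(5, 50)}
        regions = {"small": {"T1", "T5"}, "big": {"T3", "T5"}}
        table, stat, p = IM.im_by_clade(clades, regions, {"*": 0.1})
        assert bool(table.set_index("clade").loc["small", "excluded"])
        assert np.isnan(p)  # fewer than two usable clades per group


class TestIMStatus:
    def test_bimodal_recovery(self, rng):
        low = np.exp(rng.normal(-0.7, 0.15, 50))
        high = np.exp(rng.normal(0.1, 0.15, 50))
        scores = {f"L{i}": v for i, v in enumerate(low)}
        scores.update({f"H{i}": v for i, v in enumerate(high)})
        labels, info = IM.im_status_threshold(scores, seed=0)
        assert info["bimodal"] == 1.0
        correct = (labels[[f"L{i}" for i in range(50)]] == "strong").mean()
        correct2 = (labels[[f"H{i}" for i in range(50)]] == "weak").mean()
        assert correct >= 0.9 and correct2 >= 0.9

    def test_unimodal_fallback_all_weak(self):
        scores = {f"P{i}": 1.0 for i in range(20)}
        labels, info = IM.im_status_threshold(scores, seed=0)
        assert info["bimodal"] == 0.0
        assert (labels == "weak").all()

    def test_deterministic(self, rng):
        scores = {f"P{i}": float(v) for i, v in enumerate(np.exp(rng.normal(0, 0.5, 30)))}
        l1, _ = IM.im_status_threshold(scores, seed=4)
        l2, _ = IM.im_status_threshold(scores, seed=4)
        assert (l1 == l2).all()

    def test_nonpositive_excluded(self, rng):
        scores = {f"P{i}": float(v) for i, v in enumerate(np.exp(rng.normal(0, 0.3, 15)))}
        scores["bad"] = 0.0
        labels, info = IM.im_status_threshold(scores, seed=0)
        assert "bad" not in labels.index
        assert info["n_excluded"] == 1.0
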