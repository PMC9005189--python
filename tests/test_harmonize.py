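import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from couplemap.harmonize import (aggregate_to_family, evaluate_protocols,
                                 gproteinwise_r2, harmonize, log_emax_ec50,
                                 mean_similarity, minmax_normalize_emax,
                                 receptorwise_r2, similarity)
from couplemap.qc_filter import apply_sd_cutoff

from conftest import make_measurements


def _harmonized(rows, k=0.0):
    return harmonize(apply_sd_cutoff(make_measurements(rows), k))


class TestMinMax:
    def test_maximum_maps_to_one(self):
        rows = [{"receptor": f"R{i}", "gprotein": "G15", "basal_mean": 0.0,
                 "emax": e} for i, e in enumerate((20.0, 50.0, 100.0))]
        out = minmax_normalize_emax(apply_sd_cutoff(make_measurements(rows), 0))
        assert sorted(out["emax_frac"]) == pytest.approx([0.2, 0.5, 1.0])

    def test_single_coupler_gets_one(self):
        out = _harmonized([{"receptor": "R", "gprotein": "Gq",
                            "basal_mean": 10.0, "emax": 60.0}])
        assert out["emax_frac"].iloc[0] == 1.0

    def test_normalization_is_per_gprotein_and_basal_subtracted(self):
        rows = [
            {"receptor": "R1", "gprotein": "Gs", "basal_mean": 10.0,
             "emax": 110.0},
            {"receptor": "R2", "gprotein": "Gs", "basal_mean": 10.0,
             "emax": 60.0},
            {"receptor": "R1", "gprotein": "G15", "basal_mean": 10.0,
             "emax": 1010.0},
        ]
        out = minmax_normalize_emax(apply_sd_cutoff(make_measurements(rows), 0))
        by = out.set_index(["receptor", "gprotein"])["emax_frac"]
        assert by[("R1", "Gs")] == 1.0
        assert by[("R2", "Gs")] == pytest.approx(0.5)
        assert by[("R1", "G15")] == 1.0  # separate window

    def test_noncouplers_stay_nan(self):
        rows = [{"receptor": "R1", "gprotein": "Gs", "emax": 80.0},
                {"receptor": "R2", "gprotein": "Gs", "emax": 11.0}]
        out = minmax_normalize_emax(apply_sd_cutoff(make_measurements(rows),
                                                    1.4))
        by = out.set_index("receptor")["emax_frac"]
        assert np.isnan(by["R2"]) and not np.isnan(by["R1"])

    @given(st.lists(st.floats(1.0, 1e4), min_size=2, max_size=12,
                    unique=True))
    @settings(max_examples=40, deadline=None)
    def test_rank_order_preserved(self, responses):
        rows = [{"receptor": f"R{i}", "gprotein": "Gq", "basal_mean": 0.0,
                 "emax": e} for i, e in enumerate(responses)]
        out = minmax_normalize_emax(apply_sd_cutoff(make_measurements(rows), 0))
        assert (out["emax_frac"].rank() == out["emax"].rank()).all()


class TestLogEmaxEC50:
    @pytest.mark.parametrize("frac,pec50,expected", [
        (1.0, 7.0, 7.0),
        (0.5, 8.0, 7.69897),
        (0.1, 5.0, 4.0),
    ])
    def test_known_values(self, frac, pec50, expected):
        assert log_emax_ec50(frac, pec50) == pytest.approx(expected, abs=1e-5)

    def test_zero_fraction_undefined(self):
        with pytest.raises(ValueError):
            log_emax_ec50(0.0, 7.0)

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0),
           st.floats(4.0, 10.0), st.floats(4.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_both_arguments(self, f1, f2, p1, p2):
        if abs(f1 - f2) > 1e-6:
            lo, hi = sorted((f1, f2))
            assert log_emax_ec50(lo, p1) < log_emax_ec50(hi, p1)
        if abs(p1 - p2) > 1e-6:
            lo, hi = sorted((p1, p2))
            assert log_emax_ec50(f1, lo) < log_emax_ec50(f1, hi)

    def test_bounded_by_pec50(self):
        vals = np.linspace(0.05, 1.0, 20)
        out = log_emax_ec50(vals, 7.0)
        assert (out <= 7.0 + 1e-12).all()
        assert out[-1] == pytest.approx(7.0)


class TestFamilyAggregation:
    def _harm(self):
        rows = [
            {"receptor": "R", "gprotein": "Gi1", "pec50": 7.2, "emax": 110.0,
             "basal_mean": 10.0},
            {"receptor": "R", "gprotein": "Gi2", "pec50": 6.8, "emax": 110.0,
             "basal_mean": 10.0},
            {"receptor": "R", "gprotein": "GoA", "pec50": 5.0, "emax": 110.0,
             "basal_mean": 10.0},
            {"receptor": "R", "gprotein": "Gz", "pec50": np.nan,
             "emax": np.nan, "curve_status": "no_activity"},
        ]
        return _harmonized(rows)

    def test_max_rule_takes_strongest_member(self):
        fam = aggregate_to_family(self._harm(), rule="max")
        gio = fam[fam["family"] == "Gi/o"].iloc[0]
        assert gio["coupler"]
        assert gio["log_emax_ec50"] == pytest.approx(7.2)
        assert gio["pec50"] == pytest.approx(7.2)  # argmax member's pEC50

    def test_mean_rule_lies_between_members(self):
        harm = self._harm()
        fam = aggregate_to_family(harm, rule="mean")
        gio = fam[fam["family"] == "Gi/o"].iloc[0]
        member_vals = harm["log_emax_ec50"].dropna()
        assert member_vals.min() <= gio["log_emax_ec50"] <= member_vals.max()

    def test_max_dominates_every_member(self):
        harm = self._harm()
        fam = aggregate_to_family(harm, rule="max")
        gio = fam[fam["family"] == "Gi/o"].iloc[0]
        assert (harm["log_emax_ec50"].dropna() <= gio["log_emax_ec50"]).all()

    def test_all_noncoupler_family_is_noncoupler(self):
        rows = [{"receptor": "R", "gprotein": g, "emax": 10.5}
                for g in ("Gi1", "Gi2")]
        fam = aggregate_to_family(_harmonized(rows, k=1.4))
        assert not fam["coupler"].any()

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            aggregate_to_family(self._harm(), rule="median")


class TestSimilarity:
    def test_known_values(self):
        assert similarity(2.0, 4.0) == 0.5
        assert similarity(3.0, 3.0) == 1.0

    @given(st.floats(0.01, 1e3), st.floats(0.01, 1e3), st.floats(0.01, 1e3))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_scale_invariant_bounded(self, x, y, c):
        s = similarity(x, y)
        assert 0.0 < s <= 1.0
        assert s == similarity(y, x)
        assert similarity(c * x, c * y) == pytest.approx(s, rel=1e-9)
        if s == 1.0:
            assert x == pytest.approx(y)

    def test_nonpositive_pairs_skipped_from_mean(self):
        assert mean_similarity([2.0, -1.0], [4.0, 5.0]) == pytest.approx(0.5)
        assert math.isnan(mean_similarity([-1.0], [2.0]))


class TestR2:
    def test_proportional_profiles_give_unity(self):
        paired = pd.DataFrame({
            "receptor": ["R"] * 4, "unit": list("ABCD"),
            "value_a": [1.0, 2.0, 3.0, 4.0], "value_b": [2.0, 4.0, 6.0, 8.0]})
        assert receptorwise_r2(paired) == pytest.approx(1.0)

    def test_three_point_toy_matches_closed_form_pearson(self):
        xa = np.array([1.0, 2.0, 10.0])
        xb = np.array([1.5, 1.9, 4.0])
        # independent closed-form oracle
        cov = np.mean((xa - xa.mean()) * (xb - xb.mean()))
        r = cov / (xa.std() * xb.std())
        paired = pd.DataFrame({"receptor": "R", "unit": list("ABC"),
                               "value_a": xa, "value_b": xb})
        assert receptorwise_r2(paired) == pytest.approx(r * r, abs=1e-12)

    def test_receptors_below_three_points_skipped(self):
        paired = pd.DataFrame({
            "receptor": ["R1"] * 3 + ["R2"] * 2,
            "unit": list("ABC") + list("AB"),
            "value_a": [1, 2, 3, 5, 6], "value_b": [1, 2, 3.1, 9, 1]})
        # R2 has only two points: result depends on R1 alone
        solo = paired[paired["receptor"] == "R1"]
        assert receptorwise_r2(paired) == receptorwise_r2(solo)

    def test_gproteinwise_groups_by_unit(self):
        paired = pd.DataFrame({
            "receptor": list("PQRS"), "unit": ["A"] * 4,
            "value_a": [1.0, 2.0, 3.0, 4.0], "value_b": [1.1, 2.2, 2.9, 4.1]})
        assert 0.9 < gproteinwise_r2(paired) <= 1.0


class TestProtocolEvaluation:
    def test_identical_sources_score_unity_everywhere(self):
        rows = [{"receptor": f"R{i}", "gprotein": g, "basal_mean": 10.0,
                 "emax": 20.0 + 17.0 * ((i * 3 + j) % 5),
                 "pec50": 5.0 + 0.5 * ((i + j) % 4)}
                for i in range(8) for j, g in enumerate(
                    ("Gs", "Gi1", "Gq", "G12", "G15"))]
        a = _harmonized([dict(r, source="a") for r in rows])
        b = _harmonized([dict(r, source="b") for r in rows])
        table = evaluate_protocols(a, b)
        assert set(table["scheme"]) == {"raw_emax", "minmax_emax",
                                        "double_norm_emax", "pec50",
                                        "log_emax_ec50"}
        assert np.allclose(table["mean_similarity"].dropna(), 1.0)
        assert np.allclose(table["mean_r2_receptorwise"].dropna(), 1.0)
        assert table.loc[table["selected"], "scheme"].eq("log_emax_ec50").all()

    def test_family_aggregation_variants_present(self):
        rows = [{"receptor": f"R{i}", "gprotein": g, "basal_mean": 10.0,
                 "emax": 30.0 + 10.0 * j, "pec50": 6.0 + 0.2 * i}
                for i in range(4) for j, g in enumerate(("Gi1", "Gi2", "Gq"))]
        a = _harmonized([dict(r, source="a") for r in rows])
        b = _harmonized([dict(r, source="b") for r in rows])
        table = evaluate_protocols(a, b)
        assert {"family_max", "family_mean"} <= set(table["level"])
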