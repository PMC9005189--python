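import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from couplemap.coupling_map import (ANNOTATION_SOURCE, build_unified_map,
                                    classify, evidence_patterns,
                                    find_contradicted_annotations, find_novel,
                                    unique_missing_summary)

from conftest import grid

QUANT = ("bouvier", "inoue")


class TestClassify:
    def test_dual_quantitative_unannotated_is_supported_novel(self):
        # e.g. a histamine-receptor Gs coupling seen by both screens but
        # absent from the literature annotation
        labels = classify({"bouvier", "inoue", "gtp"}, {"bouvier", "inoue"},
                          QUANT)
        assert {"supported", "novel"} <= labels
        assert "proposed" not in labels

    def test_annotated_but_rejected_by_both_screens(self):
        # alpha2C-adrenoceptor Gs pattern: literature coupling, both
        # quantitative screens tested and found nothing
        labels = classify({"bouvier", "inoue", "gtp"}, {"gtp"}, QUANT)
        assert labels == {"unique:gtp", "missing:bouvier", "missing:inoue"}

    def test_single_screen_untested_elsewhere_is_proposed(self):
        labels = classify({"bouvier"}, {"bouvier"}, QUANT)
        assert labels == {"proposed"}

    def test_annotation_only_receptor_is_supported(self):
        labels = classify({"gtp"}, {"gtp"}, QUANT)
        assert labels == {"supported"}

    def test_one_screen_plus_annotation_is_supported(self):
        labels = classify({"bouvier", "gtp"}, {"bouvier", "gtp"}, QUANT)
        assert "supported" in labels
        assert "novel" not in labels

    def test_coupler_must_be_tested(self):
        with pytest.raises(ValueError):
            classify({"bouvier"}, {"inoue"}, QUANT)

    @given(st.sets(st.sampled_from(["bouvier", "inoue", "gtp"])),
           st.sets(st.sampled_from(["bouvier", "inoue", "gtp"])))
    @settings(max_examples=200, deadline=None)
    def test_label_consistency_invariants(self, tested, couplers):
        couplers &= tested
        labels = classify(tested, couplers, QUANT)
        if "novel" in labels:
            assert "supported" in labels
        if "proposed" in labels:
            assert "supported" not in labels
        for s in ("bouvier", "inoue", "gtp"):
            assert not ({f"unique:{s}", f"missing:{s}"} <= labels)


class TestBuildMap:
    def _grids(self):
        receptors = ["R1", "R2"]
        units = ["Gs", "Gq"]
        cg = {
            "bouvier": grid([[1, 1], [0, None]], receptors, units),
            "inoue": grid([[1, 0], [1, None]], receptors, units),
        }
        vg = {
            "bouvier": pd.DataFrame([[7.0, 6.0], [np.nan, np.nan]],
                                    index=receptors, columns=units),
            "inoue": pd.DataFrame([[8.0, np.nan], [5.0, np.nan]],
                                  index=receptors, columns=units),
        }
        ann = pd.DataFrame({"receptor": ["R2", "R9"],
                            "family": ["Gq/11", "Gs"],
                            "rank": ["primary", "primary"]})
        return cg, vg, ann

    def test_dual_source_value_is_the_mean(self):
        cg, vg, ann = self._grids()
        map_df, _ = build_unified_map(cg, vg, ann)
        r1gs = map_df[(map_df["receptor"] == "R1")
                      & (map_df["gprotein"] == "Gs")]
        assert r1gs["map_value"].iloc[0] == pytest.approx(7.5)
        assert r1gs["support_count"].iloc[0] == 2

    def test_single_source_value_never_averaged_with_zero(self):
        cg, vg, ann = self._grids()
        # R2-Gs: inoue couples (5.0), bouvier tested and found nothing,
        # annotation covers Gs for R9 only -> R2-Gs unsupported, not in map
        map_df, patterns = build_unified_map(cg, vg, ann)
        cell = patterns[(patterns["receptor"] == "R2")
                        & (patterns["gprotein"] == "Gs")].iloc[0]
        assert "missing:bouvier" in cell["labels"]
        assert not ((map_df["receptor"] == "R2")
                    & (map_df["gprotein"] == "Gs")).any()

    def test_annotation_only_receptor_gets_family_entry(self):
        cg, vg, ann = self._grids()
        map_df, _ = build_unified_map(cg, vg, ann)
        r9 = map_df[map_df["receptor"] == "R9"]
        assert len(r9) == 1
        assert r9["section"].iloc[0] == "annotation_only"
        assert np.isnan(r9["map_value"].iloc[0])

    def test_receptor_universe_partitions_cleanly(self):
        cg, vg, ann = self._grids()
        map_df, _ = build_unified_map(cg, vg, ann)
        quant = set(map_df.loc[map_df["section"] == "quantitative",
                               "receptor"])
        ann_only = set(map_df.loc[map_df["section"] == "annotation_only",
                                  "receptor"])
        assert quant & ann_only == set()
        assert quant | ann_only == set(map_df["receptor"])


class TestFindNovel:
    def _toy(self, ann_families):
        receptors = ["R1", "R2", "R3"]
        units = ["Gz", "Gq", "G13"]
        cg = {
            "bouvier": grid([[1, 1, 0], [0, 1, 1], [0, 0, 0]],
                            receptors, units),
            "inoue": grid([[1, 0, 0], [0, 1, 1], [1, 0, 0]],
                          receptors, units),
        }
        ann = pd.DataFrame({"receptor": [r for r, _ in ann_families],
                            "family": [f for _, f in ann_families],
                            "rank": ["primary"] * len(ann_families)})
        return cg, ann

    def test_matches_brute_force_set_comparison(self):
        cg, ann = self._toy([("R1", "Gi/o"), ("R2", "Gq/11")])
        patterns = evidence_patterns(cg, ann, subtypes=("Gz", "Gq", "G13"))
        result = find_novel(patterns)
        # brute force: coupler in both screens, family not annotated
        fam = {"Gz": "Gi/o", "Gq": "Gq/11", "G13": "G12/13"}
        annotated = set(map(tuple, ann[["receptor", "family"]].values))
        expected = set()
        for r in ("R1", "R2", "R3"):
            for u in ("Gz", "Gq", "G13"):
                both = all(cg[s].loc[r, u] == 1 for s in cg)
                if both and (r, fam[u]) not in annotated:
                    expected.add((r, u))
        assert set(result["couplings"]) == expected
        assert result["n_couplings"] == len(expected)

    def test_fully_annotated_truth_has_no_novelty(self):
        cg, ann = self._toy([("R1", "Gi/o"), ("R1", "Gq/11"),
                             ("R2", "Gq/11"), ("R2", "G12/13")])
        patterns = evidence_patterns(cg, ann, subtypes=("Gz", "Gq", "G13"))
        assert find_novel(patterns)["n_couplings"] == 0

    def test_single_novel_coupling_counted_once(self):
        cg, ann = self._toy([])
        patterns = evidence_patterns(cg, None, subtypes=("Gz", "Gq", "G13"))
        result = find_novel(patterns)
        assert result["n_receptors"] == 2   # R1 (Gz) and R2 (Gq, G13)
        assert result["n_couplings"] == 3
        assert result["family_tally"] == {"Gi/o": 1, "Gq/11": 1, "G12/13": 1}


class TestContradictedAnnotations:
    def test_requires_rejection_by_every_screen(self):
        receptors = ["A2C", "CB1"]
        units = ["Gs", "Golf"]
        subtypes = ("Gs",)
        cg = {
            "bouvier": grid([[0], [0]], receptors, ["Gs"]),
            "inoue": grid([[0], [1]], receptors, ["Gs"]),
        }
        ann = pd.DataFrame({"receptor": ["A2C", "CB1"],
                            "family": ["Gs", "Gs"],
                            "rank": ["secondary", "secondary"]})
        patterns = evidence_patterns(cg, ann, subtypes=subtypes)
        out = find_contradicted_annotations(patterns, ann)
        assert out == [("A2C", "Gs")]  # CB1 couples in one screen

    def test_empty_annotations_give_empty_list(self):
        cg = {"bouvier": grid([[0]], ["R"], ["Gs"])}
        patterns = evidence_patterns(cg, None, subtypes=("Gs",))
        assert find_contradicted_annotations(patterns, None) == []


class TestUniqueMissing:
    def test_identical_sources_have_no_unique_or_missing(self):
        g = grid([[1, 0], [0, 1]], ["R1", "R2"], ["Gs", "Gq"])
        patterns = evidence_patterns({"bouvier": g, "inoue": g.copy()}, None,
                                     subtypes=("Gs", "Gq"))
        out = unique_missing_summary(patterns, ["R1", "R2"])
        assert (out["unique_pct"] == 0).all()
        assert (out["missing_pct"] == 0).all()

    def test_percentages_count_over_full_common_set(self):
        a = grid([[1], [1], [0], [0]], list("PQRS"), ["G15"])
        b = grid([[0], [0], [0], [0]], list("PQRS"), ["G15"])
        patterns = evidence_patterns({"bouvier": a, "inoue": b}, None,
                                     subtypes=("G15",))
        out = unique_missing_summary(patterns, list("PQRS"))
        row = out[(out["source"] == "bouvier")
                  & (out["gprotein"] == "G15")].iloc[0]
        assert row["unique_pct"] == pytest.approx(50.0)
        miss = out[(out["source"] == "inoue")
                   & (out["gprotein"] == "G15")].iloc[0]
        assert miss["missing_pct"] == pytest.approx(-50.0)

    def test_empty_common_set_rejected(self):
        g = grid([[1]], ["R"], ["Gs"])
        patterns = evidence_patterns({"bouvier": g}, None, subtypes=("Gs",))
        with pytest.raises(ValueError):
            unique_missing_summary(patterns, [])
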