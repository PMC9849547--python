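"""Patch dissolving and quality classification."""
from __future__ import annotations

import dataclasses

import pytest
from shapely.geometry import Polygon, box

from urbanros import (
    BiotopeType,
    RNQ,
    classify_patch,
    classify_rnq,
    dissolve_ugs,
    rnq_area_table,
)
from urbanros.criteria import CriteriaMatrix, LabelCriteria
from urbanros.types import InputError, NoiseProfile, UndefinedShareError

from conftest import LOUD, MODERATE, QUIET, STEEP, make_polygon, square_ha


class TestDissolve:
    def test_touching_polygons_merge_additively(self):
        polys = [
            make_polygon("a", box(0, 0, 100, 100)),
            make_polygon("b", box(100, 0, 200, 100)),
        ]
        patches = dissolve_ugs(polys)
        assert len(patches) == 1
        assert patches[0].area_ha == pytest.approx(2.0)
        assert patches[0].component_ids == ("a", "b")

    def test_disjoint_polygons_stay_separate(self):
        polys = [
            make_polygon("a", box(0, 0, 100, 100)),
            make_polygon("b", box(300, 0, 400, 100)),
        ]
        assert len(dissolve_ugs(polys)) == 2

    def test_sealed_polygon_does_not_bridge_green_neighbours(self):
        polys = [
            make_polygon("a", box(0, 0, 100, 100)),
            make_polygon("s", box(100, 0, 200, 100), BiotopeType.SEALED_OTHER),
            make_polygon("b", box(200, 0, 300, 100)),
        ]
        patches = dissolve_ugs(polys)
        assert len(patches) == 2
        assert all("s" not in p.component_ids for p in patches)

    def test_invalid_geometry_reported_with_polygon_id(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(InputError, match="bad"):
            dissolve_ugs([make_polygon("bad", bowtie)])


class TestClassify:
    def test_quiet_steep_large_forest_gets_six_labels(self, matrix):
        poly = make_polygon("f", square_ha(30.0), BiotopeType.FOREST, QUIET, STEEP)
        patches = dissolve_ugs([poly])
        labels = classify_patch(patches[0], [poly], matrix)
        assert set(labels) == {
            RNQ.SERENE,
            RNQ.SPACIOUS,
            RNQ.WILD,
            RNQ.SOUGHING_OPENNESS,
            RNQ.SOUGHING_WILD,
            RNQ.LUSH,
        }

    def test_loud_small_flat_heath_is_common_only(self, matrix):
        poly = make_polygon("h", square_ha(0.6), BiotopeType.HEATH_GRASSLAND, LOUD)
        patches = dissolve_ugs([poly])
        assert set(classify_patch(patches[0], [poly], matrix)) == {RNQ.COMMON}

    def test_size_threshold_is_strict_at_exactly_25_ha(self, matrix):
        poly = make_polygon("f", square_ha(25.0), BiotopeType.FOREST, QUIET, STEEP)
        patches = dissolve_ugs([poly])
        labels = classify_patch(patches[0], [poly], matrix)
        assert RNQ.SPACIOUS not in labels
        assert RNQ.SOUGHING_OPENNESS not in labels
        assert RNQ.WILD in labels  # no size criterion

    def test_nature_reserve_flag_admits_culture_and_soughing_others(self, matrix):
        poly = make_polygon(
            "r", square_ha(2.0), BiotopeType.ARABLE_LAND, MODERATE, nature_reserve=True
        )
        patches = dissolve_ugs([poly])
        labels = classify_patch(patches[0], [poly], matrix)
        assert {RNQ.SOUGHING_OTHERS, RNQ.LUSH, RNQ.CULTURE} <= set(labels)

    def test_label_union_over_mixed_components(self, matrix):
        quiet_forest = make_polygon("a", box(0, 0, 100, 100), BiotopeType.FOREST, QUIET)
        loud_park = make_polygon(
            "b", box(100, 0, 200, 100), BiotopeType.URBAN_PARK, LOUD
        )
        patches = dissolve_ugs([quiet_forest, loud_park])
        labels = classify_patch(patches[0], [quiet_forest, loud_park], matrix)
        assert RNQ.SERENE in labels and RNQ.COMMON in labels
        # each label's qualifying area covers only its own component
        assert labels[RNQ.SERENE].area_ha == pytest.approx(1.0)
        assert labels[RNQ.COMMON].area_ha == pytest.approx(1.0)

    def test_qualifying_area_never_exceeds_patch_area(self, matrix, city):
        result = classify_rnq(city.biotopes, matrix)
        for pc in result.patches:
            for lq in pc.labels.values():
                assert lq.area_ha <= pc.patch.area_ha + 1e-9

    def test_component_order_does_not_matter(self, matrix, city):
        forward = classify_rnq(city.biotopes, matrix)
        backward = classify_rnq(list(reversed(city.biotopes)), matrix)
        fw = {
            frozenset(pc.patch.component_ids): (
                pc.label_set,
                {l: round(q.area_ha, 9) for l, q in pc.labels.items()},
            )
            for pc in forward.patches
        }
        bw = {
            frozenset(pc.patch.component_ids): (
                pc.label_set,
                {l: round(q.area_ha, 9) for l, q in pc.labels.items()},
            )
            for pc in backward.patches
        }
        assert fw == bw

    def test_relaxing_criteria_never_removes_labels(self, matrix, city):
        """Monotonicity: higher caps, lower size/slope thresholds only add labels."""
        relaxed_thresholds = dataclasses.replace(
            matrix.thresholds,
            quiet={s: v + 10 for s, v in matrix.thresholds.quiet.items()},
            moderate={s: v + 10 for s, v in matrix.thresholds.moderate.items()},
        )
        relaxed_labels = {
            label: dataclasses.replace(
                crit,
                min_size_ha=None if crit.min_size_ha is None else crit.min_size_ha / 2,
                min_slope_deg=None
                if crit.min_slope_deg is None
                else crit.min_slope_deg / 2,
            )
            for label, crit in matrix.labels.items()
        }
        relaxed = CriteriaMatrix(thresholds=relaxed_thresholds, labels=relaxed_labels)
        strict_result = classify_rnq(city.biotopes, matrix)
        relaxed_result = classify_rnq(city.biotopes, relaxed)
        relaxed_by_comp = {
            frozenset(pc.patch.component_ids): pc.label_set
            for pc in relaxed_result.patches
        }
        for pc in strict_result.patches:
            assert pc.label_set <= relaxed_by_comp[frozenset(pc.patch.component_ids)]

    def test_quiet_gated_qualifying_set_within_moderate_analogue(self, matrix, city):
        """With identical biotope/size/slope criteria, the quiet-gated label's
        qualifying components are a subset of its moderate analogue's."""
        result = classify_rnq(city.biotopes, matrix)
        serene = matrix.labels[RNQ.SERENE]
        for pc in result.patches:
            quiet_ids = set(
                pc.labels[RNQ.SERENE].component_ids if RNQ.SERENE in pc.labels else ()
            )
            moderate_crit = dataclasses.replace(
                serene, noise_level=matrix.labels[RNQ.SOUGHING_OTHERS].noise_level
            )
            moderate_matrix = CriteriaMatrix(
                thresholds=matrix.thresholds,
                labels={**matrix.labels, RNQ.SERENE: moderate_crit},
            )
            relabeled = classify_patch(pc.patch, pc.components, moderate_matrix)
            moderate_ids = set(
                relabeled[RNQ.SERENE].component_ids if RNQ.SERENE in relabeled else ()
            )
            assert quiet_ids <= moderate_ids


class TestAreaTable:
    def test_overlapping_labels_can_both_reach_full_share(self, matrix):
        poly = make_polygon(
            "p", square_ha(10.0), BiotopeType.URBAN_PARK, LOUD, nature_reserve=True
        )
        result = classify_rnq([poly], matrix)
        table = rnq_area_table(result).set_index("rnq")
        assert table.loc["Culture", "share_pct"] == pytest.approx(100.0)
        assert table.loc["Common", "share_pct"] == pytest.approx(100.0)

    def test_absent_label_reports_zero(self, matrix):
        poly = make_polygon("h", square_ha(1.0), BiotopeType.HEATH_GRASSLAND, LOUD)
        table = rnq_area_table(classify_rnq([poly], matrix)).set_index("rnq")
        assert table.loc["Serene", "area_ha"] == 0.0
        assert table.loc["Serene", "share_pct"] == 0.0

    def test_zero_total_area_is_an_error(self, matrix):
        from urbanros.rnq import RNQResult

        with pytest.raises(UndefinedShareError):
            rnq_area_table(RNQResult(patches=[], matrix=matrix))
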