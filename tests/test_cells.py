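"""Per-cell model application and growth-bin / trophic-strategy summaries."""
from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, strategies as st

from osmolimit.cells import (
    CellModelResult,
    DDA_RECLASSIFICATION,
    ImagedCellFeatures,
    annotate_cells,
    apply_model,
    assign_growth_bin,
    assign_strategy,
    bin_and_summarize,
    geometry_from_features,
    growth_bin_labels,
    limited_cell_strategy_summary,
)
from osmolimit.diffusion import NutrientField
from osmolimit.errors import DomainError
from osmolimit.track import Region, Station, UnderwayObservation

TS = datetime(2021, 2, 1, tzinfo=timezone.utc)


def features(major, minor, taxon="living>Bacillariophyceae", lat=-30.0, lon=55.0):
    return ImagedCellFeatures(
        object_id="obj1", timestamp=TS, latitude=lat, longitude=lon,
        major_axis=major, minor_axis=minor, taxon=taxon,
    )


def result(gr_n, strategy="osmotroph", taxon="x", region=Region.SUBTROPICAL, gr_p=1.0):
    return CellModelResult(
        object_id="o", taxon=taxon, functional_group="g", trophic_strategy=strategy,
        esd=10.0, aspect_ratio=1.0, din=100.0, gr_n=gr_n, gr_p=gr_p, region=region,
        growth_bin=assign_growth_bin(gr_n, (0.2, 0.6, 2.0)),
    )


class TestGeometry:
    def test_spherical_cell(self):
        g = geometry_from_features(features(10.0, 10.0))
        assert g.aspect_ratio == 1.0
        assert g.biovolume == pytest.approx(523.60, abs=0.01)
        assert g.esd == pytest.approx(10.0, rel=1e-12)

    def test_elongated_cell(self):
        g = geometry_from_features(features(20.0, 10.0))
        assert g.aspect_ratio == 2.0
        assert g.biovolume == pytest.approx(1047.20, abs=0.01)
        assert g.esd == pytest.approx(12.599, abs=1e-3)

    @given(
        major=st.floats(min_value=0.5, max_value=500.0),
        ratio=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_esd_never_exceeds_major_axis(self, major, ratio):
        g = geometry_from_features(features(major, major * ratio))
        assert g.esd <= major * (1 + 1e-12)

    def test_minor_exceeding_major_rejected(self):
        with pytest.raises(DomainError):
            features(5.0, 10.0)


class TestStrategyAssignment:
    @pytest.mark.parametrize(
        "taxon, strategy",
        [
            ("living>Dinoflagellata>Dinophyceae", "mixotroph"),
            ("living>Cyanobacteria>Trichodesmium", "diazotroph"),
            ("living>Bacillariophyta>Richelia association", "diazotroph"),
            ("living>Haptophyta>Prymnesiophyceae", "osmotroph"),
        ],
    )
    def test_default_map(self, taxon, strategy):
        assert assign_strategy(taxon) == strategy

    def test_dda_reclassification_targets(self):
        assert assign_strategy("x>Hemiaulus", DDA_RECLASSIFICATION) == "dda"
        assert assign_strategy("x>Chaetocerotaceae", DDA_RECLASSIFICATION) == "dda"


class TestApplyModel:
    @pytest.fixture
    def mini_track(self):
        stations = [
            Station(id="n", latitude=-29.0, longitude=55.0, temperature=25.0, salinity=35.0,
                    nutrients=NutrientField(ammonium=30.0, nitrite=2.0, nitrate=20.0, phosphate=70.0)),
            Station(id="s", latitude=-31.0, longitude=55.0, temperature=25.0, salinity=35.0,
                    nutrients=NutrientField(ammonium=30.0, nitrite=2.0, nitrate=20.0, phosphate=70.0)),
        ]
        underway = [
            UnderwayObservation(timestamp=TS, latitude=-30.0, longitude=55.0, sst=25.0, salinity=35.0)
        ]
        return stations, underway

    def test_zero_field_gives_zero_growth(self, mini_track):
        stations, underway = mini_track
        for s in stations:
            s.nutrients = NutrientField(ammonium=0.0, nitrite=0.0, nitrate=0.0, phosphate=0.0)
        cells = annotate_cells([features(10.0, 10.0)])
        results, dropped = apply_model(cells, stations, underway)
        assert dropped == 0 and results[0].gr_n == 0.0

    def test_identity_conservation(self, mini_track):
        stations, underway = mini_track
        cells = annotate_cells([features(10.0, 10.0), features(30.0, 6.0)])
        results, dropped = apply_model(cells, stations, underway)
        assert len(results) + dropped == len(cells)

    def test_unresolvable_cells_dropped_and_counted(self, mini_track):
        stations, underway = mini_track
        stations[0].nutrients = NutrientField(ammonium=1.0, nitrite=1.0, nitrate=None, phosphate=1.0)
        cells = annotate_cells([features(10.0, 10.0)])
        results, dropped = apply_model(cells, stations, underway)
        assert results == [] and dropped == 1

    def test_high_din_supports_fast_growth_up_to_50um(self, mini_track):
        # subantarctic-like field: DIN > 14 umol/L
        stations, underway = mini_track
        rich = NutrientField(ammonium=2000.0, nitrite=500.0, nitrate=14000.0, phosphate=1200.0)
        for s in stations:
            s.nutrients = rich
            s.temperature = 5.0
        underway = [
            UnderwayObservation(timestamp=TS, latitude=-30.0, longitude=55.0, sst=5.0, salinity=34.0)
        ]
        sizes = [5.0, 12.0, 25.0, 50.0]
        cells = annotate_cells([features(s, s) for s in sizes])
        results, _ = apply_model(cells, stations, underway)
        assert all(r.gr_n > 2.0 for r in results)
        assert all(r.region is Region.SUBANTARCTIC for r in results)

    def test_matches_direct_model_call(self, mini_track):
        from osmolimit.diffusion import n_based_max_growth
        from osmolimit.track import interpolate_nutrients

        stations, underway = mini_track
        cells = annotate_cells([features(24.0, 8.0)])
        results, _ = apply_model(cells, stations, underway)
        field = interpolate_nutrients((-30.0, 55.0), stations)
        direct = n_based_max_growth(
            cells[0].geometry, field, underway[0].seawater_state
        )
        assert results[0].gr_n == pytest.approx(direct, rel=1e-14)


class TestBinning:
    def test_labels_from_thresholds(self):
        assert growth_bin_labels([0.2, 0.6]) == ["[0, 0.2)", "[0.2, 0.6)", ">=0.6"]
        assert assign_growth_bin(0.0, [0.2, 0.6]) == "[0, 0.2)"
        assert assign_growth_bin(0.2, [0.2, 0.6]) == "[0.2, 0.6)"
        assert assign_growth_bin(5.0, [0.2, 0.6]) == ">=0.6"

    def test_single_cell_gets_proportion_one(self):
        table = bin_and_summarize([result(0.1)])
        assert len(table) == 1 and table["proportion"].iloc[0] == 1.0

    def test_hand_counted_fixture(self):
        # 10 cells, thresholds [0.2, 0.6]: 4 slow (3 diatom, 1 dino),
        # 3 mid (diatom), 3 fast (dino)
        rs = (
            [result(0.1, taxon="d") for _ in range(3)]
            + [result(0.15, taxon="o")]
            + [result(0.4, taxon="d") for _ in range(3)]
            + [result(1.0, taxon="o") for _ in range(3)]
        )
        for i, r in enumerate(rs):
            object.__setattr__(r, "functional_group", "diatom" if r.taxon == "d" else "dino")
        table = bin_and_summarize(rs, thresholds=[0.2, 0.6])
        assert int(table["n"].sum()) == 10
        slow = table[table["growth_bin"] == "[0, 0.2)"].set_index("functional_group")
        assert slow.loc["diatom", "n"] == 3 and slow.loc["dino", "n"] == 1
        assert slow.loc["diatom", "proportion"] == pytest.approx(0.75)

    def test_proportions_sum_to_one_per_stratum(self):
        rng = np.random.default_rng(5)
        rs = [
            result(float(g), region=Region(rng.choice(["subtropical", "subantarctic"])))
            for g in rng.gamma(1.0, 1.0, 60)
        ]
        table = bin_and_summarize(rs)
        sums = table.groupby(["region", "growth_bin"], observed=True)["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_empty_results_give_empty_table(self):
        assert bin_and_summarize([]).empty


class TestLimitedStrategySummary:
    def test_printed_count_scenario(self):
        # 993 diffusion-limited cells of which 202 diazotrophs and 340
        # mixotrophs -> 54.6% with an alternative strategy (55% to rounding)
        rs = (
            [result(0.1, "diazotroph") for _ in range(202)]
            + [result(0.1, "mixotroph") for _ in range(340)]
            + [result(0.1, "osmotroph") for _ in range(451)]
            + [result(1.5, "osmotroph") for _ in range(100)]  # not limited
        )
        s = limited_cell_strategy_summary(rs, threshold=0.2)
        assert s["n_limited"] == 993
        assert s["alternative_strategy_percent"] == pytest.approx(100 * 542 / 993, rel=1e-12)
        assert round(s["alternative_strategy_percent"]) == 55

    def test_toy_hand_count(self):
        rs = [result(0.1, "diazotroph")] + [result(0.1, "osmotroph") for _ in range(3)]
        s = limited_cell_strategy_summary(rs)
        assert s["alternative_strategy_percent"] == pytest.approx(25.0)

    def test_empty_limited_set_reports_absent(self):
        s = limited_cell_strategy_summary([result(1.0)])
        assert s["n_limited"] == 0 and s["alternative_strategy_percent"] is None

    def test_reclassification_monotonically_increases_share(self):
        rng = np.random.default_rng(8)
        taxa = ["hemiaulus sp", "chaetoceros", "haslea-like", "mastogloia", "other"]
        rs = [
            result(0.1, "osmotroph", taxon=str(rng.choice(taxa)))
            for _ in range(60)
        ] + [result(0.1, "mixotroph", taxon="dino") for _ in range(20)]
        base = limited_cell_strategy_summary(rs)["alternative_strategy_percent"]
        keys = list(DDA_RECLASSIFICATION)
        for k in range(len(keys) + 1):
            partial = {key: "dda" for key in keys[:k]}
            share = limited_cell_strategy_summary(rs, reclassification=partial)[
                "alternative_strategy_percent"
            ]
            assert share >= base - 1e-12
            base = share
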