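"""Priority zoning, overlay tables and comparison statistics."""

import numpy as np
import pytest

import reefplan as rp
from reefplan.solver import SelectionFrequency


def _freq(scores, n_runs=1000):
    scores = np.asarray(scores, dtype=float)
    return SelectionFrequency(
        pu_ids=np.arange(1, len(scores) + 1),
        counts=scores * n_runs / 1000.0,
        n_runs=n_runs,
    )


class TestClassifyPriorities:
    @pytest.mark.parametrize(
        "score,zone",
        [
            (1000, "core"),
            (800, "core"),
            (750, "core"),           # bottom of the closed core band
            (749.9, "utilization"),
            (500, "utilization"),
            (499.9, "sustainable_fisheries"),
            (250, "sustainable_fisheries"),
            (249.9, "other"),
            (1, "other"),
            (0, "nonpriority"),
        ],
    )
    def test_threshold_bands(self, score, zone):
        z = rp.classify_priorities(_freq([score]))
        assert z.labels[0] == zone

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            rp.classify_priorities(_freq([1200]))
        with pytest.raises(ValueError):
            rp.classify_priorities(_freq([-5]))

    def test_every_unit_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        z = rp.classify_priorities(_freq(rng.integers(0, 1001, size=500)))
        assert len(z.labels) == 500
        assert set(z.labels) <= set(rp.zoning.ZONES)


class TestZoneAreaTable:
    def test_all_zero_scores_put_everything_in_other(self, mini_seascape):
        _, tess, _ = mini_seascape
        z = rp.classify_priorities(_freq(np.zeros(len(tess))))
        table = rp.zone_area_table(z, tess).set_index("zone")
        assert table.loc["other", "area_ha"] == pytest.approx(tess.total_area_ha)
        for zone in ("core", "utilization", "sustainable_fisheries"):
            assert table.loc[zone, "area_ha"] == 0.0

    def test_partition_sums_to_total(self, mini_seascape):
        _, tess, _ = mini_seascape
        rng = np.random.default_rng(1)
        z = rp.classify_priorities(_freq(rng.integers(0, 1001, size=len(tess))))
        for merge in (True, False):
            table = rp.zone_area_table(z, tess, merge_nonpriority=merge)
            body = table[table.zone != "total"]
            assert body.area_ha.sum() == pytest.approx(
                tess.total_area_ha, abs=1e-6
            )
            assert body.pct_of_total.sum() == pytest.approx(100.0, abs=1e-9)

    def test_percentage_arithmetic_matches_printed_style(self):
        # a 12.33 ha core out of 544.03 ha is 2.27% of the region
        assert round(100.0 * 12.33 / 544.03, 2) == 2.27


class TestOverlay:
    def test_core_overlay_amounts_and_percentages(self, mini_seascape):
        _, tess, features = mini_seascape
        scores = np.zeros(len(tess))
        # make the PUs of the first feature core
        fid = features.features[0].id
        for pu in features.amounts[fid]:
            scores[pu - 1] = 900
        z = rp.classify_priorities(_freq(scores))
        overlay = rp.core_habitat_overlay(z, features).set_index("habitat")
        f0 = features.features[0]
        assert overlay.loc[f0.name, "core_ha"] == pytest.approx(f0.total_amount)
        assert overlay.loc[f0.name, "pct_of_habitat"] == pytest.approx(100.0)
        for f in features.features[1:]:
            assert overlay.loc[f.name, "core_ha"] == 0.0
        # bound: habitat in core never exceeds the habitat total
        assert (overlay.core_ha <= overlay.total_ha + 1e-9).all()

    def test_empty_core_gives_zero_percentages(self, mini_seascape):
        _, tess, features = mini_seascape
        z = rp.classify_priorities(_freq(np.zeros(len(tess))))
        overlay = rp.core_habitat_overlay(z, features)
        assert (overlay.pct_of_habitat == 0.0).all()


class TestComparisonStatistics:
    @pytest.mark.parametrize(
        "value,reference,expected",
        [
            (34.37, 12.33, 178.75),
            (19.53, 12.33, 58.39),
            (15.67, 20.05, -21.85),
            (7.0, 7.0, 0.0),
        ],
    )
    def test_impact_magnitude(self, value, reference, expected):
        assert round(rp.impact_magnitude(value, reference), 2) == expected

    def test_impact_magnitude_requires_positive_reference(self):
        with pytest.raises(ValueError):
            rp.impact_magnitude(10.0, 0.0)

    @pytest.mark.parametrize(
        "spu,cc,expected",
        [(577, 92418, 0.0062), (849, 161932, 0.0052), (0, 100, 0.0)],
    )
    def test_conservation_efficiency(self, spu, cc, expected):
        assert round(rp.conservation_efficiency(spu, cc), 4) == expected

    def test_efficiency_requires_positive_cost(self):
        with pytest.raises(ValueError):
            rp.conservation_efficiency(10, 0)


@pytest.fixture(scope="module")
def report(mini_seascape):
    _, tess, features = mini_seascape
    scens = rp.EV_SCENARIOS(
        blm=0.05, spf=100.0, n_runs=20, iterations_per_run=5000, rng_seed=21
    )
    return rp.scenario_report(tess, features, scens)


class TestScenarioReport:
    def test_identical_scenarios_give_zero_impacts(self, mini_seascape):
        _, tess, features = mini_seascape
        base = rp.ScenarioConfig(
            target_fraction=0.4, blm=0.05, spf=100.0, n_runs=5,
            iterations_per_run=2000, rng_seed=9,
        )
        twins = [base.replace(name="A"), base.replace(name="B")]
        rep = rp.scenario_report(tess, features, twins)
        zc = rep.zone_comparison
        assert (zc["A_ha"] == zc["B_ha"]).all()
        impacts = zc["B_impact_vs_A"].dropna()
        assert (impacts == 0.0).all()

    def test_core_zone_grows_with_target(self, report):
        zc = report.zone_comparison.set_index("zone")
        core = [zc.loc["core", f"{n}_ha"] for n in ("EV1", "EV2", "EV3")]
        assert core[0] <= core[1] <= core[2]

    def test_efficiency_column_consistent_with_spu_and_cc(self, report):
        ec = report.efficiency_comparison.set_index("metric")
        for name in ("EV1", "EV2", "EV3"):
            spu, cc = ec.loc["spu", name], ec.loc["conservation_cost", name]
            if cc > 0:
                assert ec.loc["efficiency", name] == round(
                    rp.conservation_efficiency(spu, cc), 4
                )

    def test_single_scenario_omits_impact_columns(self, mini_seascape):
        _, tess, features = mini_seascape
        sc = rp.ScenarioConfig(
            name="solo", target_fraction=0.4, blm=0.05, spf=100.0,
            n_runs=3, iterations_per_run=1000, rng_seed=2,
        )
        rep = rp.scenario_report(tess, features, [sc])
        assert not [c for c in rep.zone_comparison.columns if "impact" in c]

    def test_zone_tables_partition_total_area(self, report, mini_seascape):
        _, tess, _ = mini_seascape
        for oc in report.outcomes.values():
            body = oc.zone_table[oc.zone_table.zone != "total"]
            assert body.area_ha.sum() == pytest.approx(
                tess.total_area_ha, abs=1e-6
            )

    def test_csv_outputs_written(self, report, tmp_path):
        written = report.to_csvs(tmp_path)
        assert "zone_comparison" in written
        for path in written.values():
            assert (tmp_path / path.split("/")[-1]).exists()
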