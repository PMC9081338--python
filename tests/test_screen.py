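"""Screen QC rules, normalization, timepoint selection and ranking."""

import numpy as np
import pandas as pd
import pytest

from fucci_cycle.screen import (
    aggregate_wells,
    normalize_to_control,
    rank_hits,
    run_screen,
    select_timepoint,
    site_qc,
    summarize_treatments,
    treatment_qc,
)
from fucci_cycle.synthetic import default_plate_layout, generate_plate


def make_sites(counts, plate="P1", tp=24.0):
    """One site row per entry of ``counts`` = (n_red, n_yellow, n_green, n_blue)."""
    rows = []
    for i, (r, y, g, b) in enumerate(counts):
        rows.append(
            {
                "plate_id": plate,
                "well_id": f"B{(i % 10) + 2:02d}",
                "site_id": f"s{i + 1}",
                "timepoint_h": tp,
                "n_nuclei": r + y + g + b,
                "n_blue": b,
                "n_red": r,
                "n_yellow": y,
                "n_green": g,
            }
        )
    return pd.DataFrame(rows)


class TestSiteQC:
    def _group(self, values):
        rows = []
        for i, n in enumerate(values):
            rows.append(
                {
                    "plate_id": "P1",
                    "well_id": "B02",
                    "site_id": f"s{i}",
                    "timepoint_h": 24.0,
                    "n_nuclei": n,
                    "n_blue": 0,
                    "n_red": n,
                    "n_yellow": 0,
                    "n_green": 0,
                }
            )
        return pd.DataFrame(rows)

    def test_low_count_site_excluded_and_borderline_retained(self):
        """Group with mean 100 and SD 5: a site at 85 (< mean - 2 SD = 90)
        is excluded, a site at 95 is retained."""
        base = [100, 105, 95, 100, 100, 105, 95, 100]  # mean 100, sd 3.78
        values = base + [85]
        sites = self._group(values)
        mean, sd = np.mean(values), np.std(values, ddof=1)
        assert 85 < mean - 2 * sd < 95
        retained, log = site_qc(sites)
        assert 85 not in retained["n_nuclei"].values
        assert 95 in retained["n_nuclei"].values
        assert len(log) == 1 and log.iloc[0]["reason"] == "low_nucleus_count"

    def test_small_groups_skipped_with_warning(self, caplog):
        sites = self._group([100, 10])
        with caplog.at_level("WARNING"):
            retained, log = site_qc(sites)
        assert len(retained) == 2 and len(log) == 0
        assert "only 2 sites" in caplog.text

    def test_dropout_sites_detected_against_generator_truth(self):
        """On a 100-site plate-timepoint with 5% dropout at 10% of the mean,
        all dropout sites are excluded with at most one false exclusion."""
        spec = default_plate_layout(
            n_compounds=16,
            n_controls=4,
            site_dropout_prob=0.05,
            n_replicate_plates=1,
            timepoints_h=(24.0,),
        )
        sites, _, truth = generate_plate(spec, seed=17)
        assert len(sites) == 100
        retained, log = site_qc(sites)
        merged = log.merge(truth, on=["plate_id", "well_id", "site_id", "timepoint_h"])
        n_true_dropouts = int(truth["is_dropout"].sum())
        assert merged["is_dropout"].sum() == n_true_dropouts   # all caught
        assert (~merged["is_dropout"]).sum() <= 1              # <=1 false


class TestAggregation:
    def test_identical_sites_average_to_any_site(self):
        sites = make_sites([(80, 5, 15, 10)] * 5)
        sites["well_id"] = "B02"
        wells = aggregate_wells(sites)
        assert len(wells) == 1
        assert wells.iloc[0]["main_parameter_pct"] == pytest.approx(20.0)
        assert wells.iloc[0]["n_sites"] == 5

    def test_site_count_field_reflects_retained_sites(self):
        s1 = make_sites([(90, 0, 10, 0)])
        s5 = make_sites([(90, 0, 10, 0)] * 5)
        s5["well_id"] = "C02"
        wells = aggregate_wells(pd.concat([s1, s5], ignore_index=True))
        assert sorted(wells["n_sites"]) == [1, 5]

    def test_sum_and_mean_agree_on_homogeneous_sites(self):
        sites = make_sites([(80, 5, 15, 0)] * 4)
        sites["well_id"] = "B02"
        a = aggregate_wells(sites, site_combine="sum")
        b = aggregate_wells(sites, site_combine="mean")
        assert a.iloc[0]["main_parameter_pct"] == pytest.approx(
            b.iloc[0]["main_parameter_pct"]
        )

    def test_zero_fucci_positive_flagged(self):
        sites = make_sites([(0, 0, 0, 50)])
        wells = aggregate_wells(sites)
        assert "no_fucci_positive" in wells.iloc[0]["qc_flags"]
        assert np.isnan(wells.iloc[0]["main_parameter_pct"])


class TestNormalization:
    def _wells(self):
        return pd.DataFrame(
            {
                "plate_id": ["P1"] * 3,
                "well_id": ["B02", "B03", "B04"],
                "timepoint_h": [24.0] * 3,
                "main_parameter_pct": [10.0, 10.0, 15.0],
            }
        )

    def _pmap(self):
        return pd.DataFrame(
            {
                "well_id": ["B02", "B03", "B04"],
                "compound_id": ["CTRL", "CTRL", "C001"],
                "role": ["control", "control", "compound"],
            }
        )

    def test_percent_of_control(self):
        out = normalize_to_control(self._wells(), self._pmap())
        assert out.loc[out["well_id"] == "B04", "normalized_pct"].iloc[0] == pytest.approx(150.0)

    def test_control_wells_average_to_hundred(self):
        out = normalize_to_control(self._wells(), self._pmap())
        ctrl = out[out["role"] == "control"]["normalized_pct"]
        assert ctrl.mean() == pytest.approx(100.0)

    def test_renormalizing_controls_is_idempotent_at_hundred(self):
        out = normalize_to_control(self._wells(), self._pmap())
        again = out.drop(columns="normalized_pct").rename(
            columns={"main_parameter_pct": "old"}
        )
        again["main_parameter_pct"] = out["normalized_pct"]
        again = normalize_to_control(
            again[["plate_id", "well_id", "timepoint_h", "main_parameter_pct"]],
            self._pmap(),
        )
        ctrl = again[again["role"] == "control"]["normalized_pct"]
        assert ctrl.mean() == pytest.approx(100.0)

    def test_missing_controls_error_names_plate_and_timepoint(self):
        pmap = self._pmap()
        pmap["role"] = "compound"
        with pytest.raises(ValueError, match="P1.*24"):
            normalize_to_control(self._wells(), pmap)

    def test_null_plate_compounds_distribute_around_hundred(self):
        spec = default_plate_layout(n_compounds=40, n_controls=10, site_dropout_prob=0.0)
        sites, pmap, _ = generate_plate(spec, seed=23)
        res = run_screen(sites, pmap)
        comp = res["result"]
        comp = comp[(comp["role"] == "compound") & (comp["timepoint_h"] == 48.0)]
        assert comp["normalized_mean_pct"].mean() == pytest.approx(100.0, abs=5.0)


class TestTreatmentQC:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [
            (50.0, 30.0, "excluded"),   # 30 > 25
            (50.0, 10.0, "retained"),
            (200.0, 99.0, "retained"),  # 99 <= 100, boundary retains
        ],
    )
    def test_dispersion_rule(self, mean, sd, expected):
        result = pd.DataFrame(
            {
                "compound_id": ["C001"],
                "timepoint_h": [48.0],
                "role": ["compound"],
                "n_wells": [3],
                "normalized_mean_pct": [mean],
                "normalized_sd_pct": [sd],
            }
        )
        out, log = treatment_qc(result)
        assert out.iloc[0]["status"] == expected
        assert (len(log) == 1) == (expected == "excluded")

    def test_single_replicate_flagged_not_excluded(self):
        result = pd.DataFrame(
            {
                "compound_id": ["C001"],
                "timepoint_h": [48.0],
                "role": ["compound"],
                "n_wells": [1],
                "normalized_mean_pct": [50.0],
                "normalized_sd_pct": [np.nan],
            }
        )
        out, _ = treatment_qc(result)
        assert out.iloc[0]["status"] == "flagged"
        assert out.iloc[0]["reason"] == "single_replicate"


class TestTimepointSelection:
    def _wells(self, cvs):
        rows = []
        for tp, cv in cvs.items():
            # two control wells constructed to the requested CV around 100
            sd = cv  # mean 100 -> CV% == sd
            for i, v in enumerate([100 - sd / np.sqrt(2), 100 + sd / np.sqrt(2)]):
                rows.append(
                    {
                        "plate_id": "P1",
                        "well_id": f"B{i + 2:02d}",
                        "timepoint_h": tp,
                        "role": "control",
                        "normalized_pct": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_smallest_cv_timepoint_selected(self):
        """CVs of 13.1 / 12.1 / 28.0 % at 24 / 48 / 72 h select 48 h."""
        best, table = select_timepoint(self._wells({24.0: 13.1, 48.0: 12.1, 72.0: 28.0}))
        assert best == 48.0
        by_tp = table.set_index("timepoint_h")["control_cv_pct"]
        assert by_tp[24.0] == pytest.approx(13.1, rel=0.01)
        assert by_tp[72.0] == pytest.approx(28.0, rel=0.01)

    def test_tie_breaks_toward_earlier_timepoint(self):
        best, _ = select_timepoint(self._wells({48.0: 12.0, 24.0: 12.0}))
        assert best == 24.0

    def test_identical_controls_give_zero_cv(self):
        wells = self._wells({24.0: 0.0, 48.0: 5.0})
        best, table = select_timepoint(wells)
        assert best == 24.0
        assert table.set_index("timepoint_h")["control_cv_pct"][24.0] == pytest.approx(0.0)

    def test_requires_two_timepoints(self):
        with pytest.raises(ValueError):
            select_timepoint(self._wells({24.0: 5.0}))


class TestRanking:
    def _result(self, rows):
        return pd.DataFrame(
            [
                {
                    "compound_id": cid,
                    "timepoint_h": 48.0,
                    "role": "compound",
                    "n_wells": 3,
                    "normalized_mean_pct": m,
                    "normalized_sd_pct": s,
                    "status": "retained",
                    "reason": "",
                }
                for cid, m, s in rows
            ]
        )

    def test_descending_by_normalized_mean(self):
        res = self._result([("A", 150.0, 5.0), ("B", 250.0, 5.0), ("C", 90.0, 5.0)])
        ranked = rank_hits(res, 48.0)
        assert list(ranked["compound_id"]) == ["B", "A", "C"]

    def test_tie_breaks_by_lower_sd(self):
        res = self._result([("A", 150.0, 20.0), ("B", 150.0, 5.0)])
        ranked = rank_hits(res, 48.0)
        assert list(ranked["compound_id"]) == ["B", "A"]

    def test_pipeline_is_permutation_invariant(self):
        spec = default_plate_layout(
            n_compounds=10, n_controls=4, effects={"C003": 2.0}, n_replicate_plates=2
        )
        sites, pmap, _ = generate_plate(spec, seed=31)
        shuffled = sites.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = run_screen(sites, pmap)
        b = run_screen(shuffled, pmap)
        pd.testing.assert_frame_equal(a["ranked"], b["ranked"])
        assert a["selected_timepoint_h"] == b["selected_timepoint_h"]

    def test_effect_compound_appears_in_ranked_output(self):
        spec = default_plate_layout(n_compounds=10, n_controls=4, effects={"C005": 2.0})
        sites, pmap, _ = generate_plate(spec, seed=37)
        res = run_screen(sites, pmap)
        assert "C005" in set(res["ranked"]["compound_id"])

    def test_exclusions_carry_machine_readable_reasons(self):
        spec = default_plate_layout(n_compounds=10, n_controls=4, site_dropout_prob=0.2)
        sites, pmap, _ = generate_plate(spec, seed=41)
        res = run_screen(sites, pmap)
        assert len(res["site_exclusions"]) > 0
        assert (res["site_exclusions"]["reason"] == "low_nucleus_count").all()
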