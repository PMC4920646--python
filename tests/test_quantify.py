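"""Seizure quantification, normalization, overall effects and statistics."""

import numpy as np
import pandas as pd
import pytest

from swdkit.design import SessionDesign
from swdkit.io import Event, EventList
from swdkit.quantify import (
    cohort_metrics,
    epoch_metrics,
    normalize_metrics,
    overall_effect,
)
from swdkit.stats import (
    anova_two_way,
    dunnett_vs_vehicle,
    peak_freq_test,
    sidak_per_epoch,
)

DESIGN = SessionDesign()


class TestEpochMetrics:
    def test_single_event_within_epoch(self):
        table = epoch_metrics(EventList([Event(100.0, 130.0, "swd")]), DESIGN)
        row = table[table["epoch_index"] == 0].iloc[0]
        assert row["total_time_s"] == 30.0
        assert row["n_seizures"] == 1
        assert row["mean_duration_s"] == 30.0

    def test_edge_spanning_event_convention(self):
        # total time splits at the epoch edge; count and full duration go to
        # the start epoch
        table = epoch_metrics(EventList([Event(1190.0, 1230.0, "swd")]), DESIGN)
        e0 = table[table["epoch_index"] == 0].iloc[0]
        e1 = table[table["epoch_index"] == 1].iloc[0]
        assert e0["total_time_s"] == 10.0 and e1["total_time_s"] == 30.0
        assert e0["n_seizures"] == 1 and e1["n_seizures"] == 0
        assert e0["mean_duration_s"] == 40.0
        assert np.isnan(e1["mean_duration_s"])

    def test_no_events(self):
        table = epoch_metrics(EventList([]), DESIGN)
        assert (table["total_time_s"] == 0).all()
        assert (table["n_seizures"] == 0).all()
        assert table["mean_duration_s"].isna().all()

    def test_time_conservation_against_ground_truth(self, small_session, small_config):
        _, gt = small_session
        design = small_config.design
        table = epoch_metrics(gt, design)
        total = table["total_time_s"].sum()
        expect = sum(
            min(e.end_s, design.treatment_end_s) - max(e.start_s, design.control_start_s)
            for e in gt.with_label("swd")
        )
        assert total == pytest.approx(expect, abs=1e-6)


class TestNormalization:
    def _animal(self, animal, ctrl, trt):
        rows = []
        for i, v in zip(DESIGN.control_epochs, ctrl):
            rows.append({"animal": animal, "epoch_index": i, "total_time_s": v,
                         "n_seizures": 1, "mean_duration_s": v})
        for i, v in zip(DESIGN.treatment_epochs, trt):
            rows.append({"animal": animal, "epoch_index": i, "total_time_s": v,
                         "n_seizures": 1, "mean_duration_s": v})
        return pd.DataFrame(rows)

    def test_percent_of_control_arithmetic(self):
        tab = self._animal("a", [240.0, 260.0], [125.0] * 6)
        out = normalize_metrics(tab, DESIGN)
        trt = out[out["epoch_index"] >= 0]
        assert np.allclose(trt["total_time_s_pct_control"], 50.0)

    def test_vehicle_self_normalization_group_mean_100(self, rng):
        tabs = [
            self._animal(f"a{i}", rng.uniform(100, 300, 2), rng.uniform(100, 300, 6))
            for i in range(5)
        ]
        veh = pd.concat(tabs, ignore_index=True)
        out = normalize_metrics(veh, DESIGN, vehicle_table=veh)
        grp = out.groupby("epoch_index")["total_time_s_pct_vehicle"].mean()
        assert np.allclose(grp, 100.0)

    def test_zero_control_excluded(self):
        tab = self._animal("a", [0.0, 0.0], [50.0] * 6)
        out = normalize_metrics(tab, DESIGN)
        assert out["total_time_s_pct_control"].isna().all()

    def test_zero_seizure_epoch_missing_duration_propagates(self):
        events = EventList([Event(-2000.0, -1990.0, "swd"), Event(-800.0, -790.0, "swd")])
        tab = epoch_metrics(events, DESIGN)
        tab["animal"] = "a"
        out = normalize_metrics(tab, DESIGN)
        trt = out[out["epoch_index"] >= 0]
        assert trt["mean_duration_s_pct_control"].isna().all()
        assert (trt["total_time_s_pct_control"] == 0).all()


class TestOverallEffect:
    def test_animal_means_arithmetic(self):
        rows = []
        for animal, pct in (("a", 30.0), ("b", 32.0), ("c", 28.0)):
            for e in DESIGN.treatment_epochs:
                rows.append(
                    {"animal": animal, "epoch_index": e, "total_time_s_pct_vehicle": pct}
                )
        res = overall_effect(pd.DataFrame(rows), DESIGN, "total_time_s")
        assert res["percent_change"] == pytest.approx(70.0)
        assert res["direction"] == "decrease"
        assert res["sem"] == pytest.approx(np.std([30, 32, 28], ddof=1) / np.sqrt(3))

    def test_insufficient_animals(self):
        rows = [
            {"animal": "a", "epoch_index": e, "total_time_s_pct_vehicle": 50.0}
            for e in DESIGN.treatment_epochs
        ]
        res = overall_effect(pd.DataFrame(rows), DESIGN, "total_time_s")
        assert np.isnan(res["sem"]) and res["n"] == 1


def _null_cohort(rng, n_per_arm=6):
    """Metrics-level two-arm cohort with no drug effect."""
    from swdkit.presets import get_preset
    from swdkit.synth import SessionConfig, sample_seizure_intervals, sleep_intervals

    cfg = SessionConfig()
    bouts = sleep_intervals(cfg)
    tables = []
    for arm in ("vehicle", "sham"):
        evs = {}
        for i in range(n_per_arm):
            iv = sample_seizure_intervals(cfg.process, cfg.drug, cfg.design, rng, sleep=bouts)
            evs[f"{arm}{i}"] = EventList(
                [Event(s, s + d, "swd") for s, d in iv], validate=False
            )
        tab = cohort_metrics(evs, cfg.design)
        tab.insert(1, "dose_arm", arm)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


class TestStats:
    def test_anova_identical_groups_null(self, rng):
        # same values in both arms: drug F ~ 0, p ~ 1
        rows = []
        for arm in ("vehicle", "drug"):
            for a in range(4):
                for e in DESIGN.treatment_epochs:
                    rows.append(
                        {
                            "dose_arm": arm,
                            "animal": f"{arm}{a}",
                            "epoch_index": e,
                            "v": 100.0 + 10 * a + e,
                        }
                    )
        table = anova_two_way(pd.DataFrame(rows), "v")
        drug_row = table.loc["C(drug, Sum)"]
        assert drug_row["F"] == pytest.approx(0.0, abs=1e-9)
        assert drug_row["PR(>F)"] == pytest.approx(1.0)

    def test_anova_detects_large_drug_effect(self, rng):
        tab = _null_cohort(rng, n_per_arm=8)
        # inject a strong drug effect on the normalized values
        veh = tab[tab["dose_arm"] == "vehicle"]
        norm = normalize_metrics(tab, DESIGN, vehicle_table=veh)
        trt = norm[norm["epoch_index"] >= 0].copy()
        trt.loc[trt["dose_arm"] == "sham", "total_time_s_pct_vehicle"] *= 0.3
        res = anova_two_way(trt, "total_time_s_pct_vehicle")
        assert res.loc["C(drug, Sum)", "PR(>F)"] < 0.001

    def test_anova_power_for_large_drug_effect(self, rng):
        # ~70% suppression of seizure time, n=8/arm: drug main effect should
        # reach p < 0.001 in at least 95% of replicates (ground-truth level)
        from swdkit.presets import get_preset
        from swdkit.synth import SessionConfig, sample_seizure_intervals, sleep_intervals

        cfg = SessionConfig()
        bouts = sleep_intervals(cfg)
        drug_model = get_preset("tcb2_0.3", cfg)
        hits, reps = 0, 200
        for _ in range(reps):
            tables = []
            for arm, model in (("vehicle", cfg.drug), ("drug", drug_model)):
                evs = {}
                for i in range(8):
                    iv = sample_seizure_intervals(cfg.process, model, cfg.design, rng,
                                                  sleep=bouts)
                    evs[f"{arm}{i}"] = EventList(
                        [Event(s, s + d, "swd") for s, d in iv], validate=False
                    )
                tab = cohort_metrics(evs, cfg.design)
                tab.insert(1, "dose_arm", arm)
                tables.append(tab)
            both = pd.concat(tables, ignore_index=True)
            veh = both[both["dose_arm"] == "vehicle"]
            norm = normalize_metrics(both, DESIGN, vehicle_table=veh)
            trt = norm[norm["epoch_index"] >= 0]
            res = anova_two_way(trt, "total_time_s_pct_vehicle")
            if res.loc["C(drug, Sum)", "PR(>F)"] < 0.001:
                hits += 1
        assert hits / reps >= 0.95

    def test_dunnett_contrasts(self, rng):
        means = pd.DataFrame(
            {
                "dose_arm": ["vehicle"] * 6 + ["low"] * 6 + ["high"] * 6,
                "value": np.r_[
                    rng.normal(100, 5, 6), rng.normal(95, 5, 6), rng.normal(30, 5, 6)
                ],
            }
        )
        res = dunnett_vs_vehicle(means, value_col="value")
        res = res.set_index("dose_arm")
        assert res.loc["high", "pvalue"] < 0.001
        assert res.loc["low", "pvalue"] > 0.05

    def test_sidak_adjustment_monotone(self, rng):
        tab = _null_cohort(rng)
        veh = tab[tab["dose_arm"] == "vehicle"]
        norm = normalize_metrics(tab, DESIGN, vehicle_table=veh)
        trt = norm[norm["epoch_index"] >= 0]
        res = sidak_per_epoch(trt, "total_time_s_pct_vehicle", arm="sham")
        assert len(res) == 6
        ok = res.dropna(subset=["pvalue"])
        assert np.all(ok["pvalue_sidak"] >= ok["pvalue"] - 1e-12)
        assert np.all(ok["pvalue_sidak"] <= 1.0)

    def test_peak_freq_test_identical_samples(self):
        res = peak_freq_test([7.0, 7.1, 6.9], [7.0, 7.1, 6.9])
        assert res["pvalue"] == pytest.approx(1.0)

    def test_peak_freq_test_requires_two_per_arm(self):
        with pytest.raises(ValueError):
            peak_freq_test([7.0], [7.0, 7.2])

    def test_peak_freq_power_for_half_hertz_shift(self, rng):
        # arms at 7.1 vs 7.6 Hz with realistic animal-level spread:
        # significant at alpha=0.05 in >= 90% of replicates
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(7.1, 0.12, 8)
            b = rng.normal(7.6, 0.12, 7)
            if peak_freq_test(a, b)["pvalue"] < 0.05:
                hits += 1
        assert hits / reps >= 0.90
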