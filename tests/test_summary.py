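import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

import murisleep as ms
from murisleep.errors import ValidationError


def hyp_with_counts(n_light, light_nrem, n_dark, dark_nrem, epoch_s=10.0):
    """Hypnogram with exact per-phase NREM epoch counts (rest WAKE)."""
    stages = (
        ["N"] * light_nrem
        + ["W"] * (n_light - light_nrem)
        + ["N"] * dark_nrem
        + ["W"] * (n_dark - dark_nrem)
    )
    phase = ["L"] * n_light + ["D"] * n_dark
    return ms.Hypnogram(stages, epoch_s=epoch_s, phase=phase)


def fake_summary(value, metric="pct_nrem", window="H24"):
    table = pd.DataFrame({metric: [value]}, index=[window])
    return ms.SleepSummary(table=table)


class TestSummarize:
    def test_all_wake(self):
        s = ms.summarize(ms.Hypnogram(["W"] * 100))
        assert s.value("pct_wake") == 100.0
        assert s.value("n_nrem_bouts") == 0.0
        assert np.isnan(s.value("arousals_per_h_sleep"))
        assert np.isnan(s.value("mean_resume_latency_min"))

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        h = ms.Hypnogram(rng.choice(list("WNR"), size=997))
        s = ms.summarize(h)
        total = sum(s.value(f"pct_{k}") for k in ("wake", "nrem", "rem"))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_equal_windows_h24_is_phase_mean(self):
        h = hyp_with_counts(400, 211, 400, 97)
        s = ms.summarize(h)
        assert s.value("pct_nrem") == pytest.approx(
            (s.value("pct_nrem", "LIGHT") + s.value("pct_nrem", "DARK")) / 2
        )

    def test_truth_summary_matches_direct_tally(self, default_cfg):
        truth = ms.sample_hypnogram(default_cfg)
        s = ms.summarize(truth)
        assert s.value("pct_nrem") == pytest.approx(100 * np.mean(truth.stages == "N"))
        assert s.value("n_nrem_bouts") == len(
            [b for b in ms.segment_bouts(truth) if b.kind == "N"]
        )
        assert s.value("arousals_per_h_sleep") == pytest.approx(
            ms.arousal_frequency(truth, "H24")
        )

    def test_window_absent_warns_and_omits(self):
        h = ms.Hypnogram(["N"] * 500, phase=["L"] * 500)
        with pytest.warns(UserWarning):
            s = ms.summarize(h)
        assert "DARK" not in s.table.index
        with pytest.raises(ValidationError):
            s.value("pct_nrem", "DARK")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("WNR"), min_size=4, max_size=200), st.integers(1, 199))
    def test_h24_is_epoch_weighted_phase_mean(self, stages, split):
        split = min(split, len(stages) - 1)
        phase = ["L"] * split + ["D"] * (len(stages) - split)
        h = ms.Hypnogram(stages, phase=phase)
        s = ms.summarize(h)
        n = len(stages)
        weighted = (
            s.value("pct_nrem", "LIGHT") * split + s.value("pct_nrem", "DARK") * (n - split)
        ) / n
        assert s.value("pct_nrem") == pytest.approx(weighted)


class TestCompareGroups:
    def test_identical_groups(self):
        a = [fake_summary(v) for v in (3.0, 4.0, 5.0)]
        c = ms.compare_groups(a, a, "pct_nrem")
        assert c.t == 0.0
        assert c.p == 1.0

    def test_textbook_example(self):
        a = [fake_summary(v) for v in (1.0, 2.0, 3.0)]
        b = [fake_summary(v) for v in (4.0, 5.0, 6.0)]
        c = ms.compare_groups(a, b, "pct_nrem")
        assert c.df == 4
        assert c.t == pytest.approx(-3.6742346141747673, abs=1e-9)
        assert c.p == pytest.approx(0.021311641128756713, abs=1e-9)
        assert c.sem_a == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))

    def test_matches_reference_implementation(self):
        """Pooled t and p agree with scipy to 1e-10 on 100 random fixtures."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            na, nb = rng.integers(2, 12, size=2)
            x = rng.normal(0, 1 + rng.random(), size=na)
            y = rng.normal(rng.normal(), 1 + rng.random(), size=nb)
            c = ms.compare_groups(
                [fake_summary(v) for v in x], [fake_summary(v) for v in y], "pct_nrem"
            )
            ref = sstats.ttest_ind(x, y, equal_var=True)
            assert c.t == pytest.approx(float(ref.statistic), abs=1e-10)
            assert c.p == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_nan_animals_excluded_with_warning(self):
        a = [fake_summary(v) for v in (1.0, 2.0, np.nan, 3.0)]
        b = [fake_summary(v) for v in (4.0, 5.0, 6.0)]
        with pytest.warns(UserWarning):
            c = ms.compare_groups(a, b, "pct_nrem")
        assert c.n_a == 3

    def test_too_few_animals_rejected(self):
        a = [fake_summary(1.0), fake_summary(np.nan)]
        b = [fake_summary(2.0), fake_summary(3.0)]
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError):
                ms.compare_groups(a, b, "pct_nrem")


class TestReport:
    @pytest.fixture()
    def cohort_summaries(self, default_cfg):
        import dataclasses

        cfg = dataclasses.replace(default_cfg, hours=24)  # spans both phases
        cohort = ms.generate_cohort(
            3, cfg, dataclasses.replace(cfg, wake_bout_min=6.0), signals=False
        )
        groups = {}
        for lab in cohort:
            groups.setdefault(lab.group, []).append(ms.summarize(lab.truth))
        return groups

    def test_table_shape(self, cohort_summaries, tmp_path):
        summary_df, comp_df = ms.report(cohort_summaries, out_dir=tmp_path)
        assert len(summary_df) == len(ms.METRICS) * 3
        assert {"metric", "window", "A_mean", "A_sem", "B_mean"} <= set(summary_df.columns)
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "comparisons.csv").exists()

    def test_single_group_blank_p(self, cohort_summaries):
        _, comp = ms.report({"A": cohort_summaries["A"]})
        assert comp["p"].isna().all()

    def test_json_reproduces_tables(self, cohort_summaries, tmp_path):
        summary_df, _ = ms.report(cohort_summaries, out_dir=tmp_path)
        payload = json.loads((tmp_path / "animals.json").read_text())
        for _, row in summary_df.iterrows():
            g, m, w = "A", row["metric"], row["window"]
            vals = np.array(
                [a["metrics"][w][m] for a in payload[g]], dtype=float
            )
            vals = vals[~np.isnan(vals)]
            recomputed = vals.mean() if vals.size else np.nan
            if np.isnan(recomputed):
                assert np.isnan(row["A_mean"])
            else:
                assert recomputed == row["A_mean"]
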