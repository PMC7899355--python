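import logging

import numpy as np
import pandas as pd
import pytest

from corneatrace import (
    COHORT_MARGINALS,
    CorneaTraceError,
    FormatError,
    PopulationSpec,
    SamplingError,
    analyze_batch,
    read_casia_csv,
    sample_population,
    summarize,
    write_casia_csv,
)
from corneatrace.focus import CRITERIA

from .conftest import MEAN_EYE


def mean_eye_frame(n=1):
    return pd.DataFrame(
        [{"eye_id": f"m{k}", **{v: MEAN_EYE[v] for v in ("R_f", "Q_f", "R_b", "Q_b", "CCT", "PUP")}} for k in range(n)]
    )


class TestSampling:
    def test_deterministic_for_fixed_seed(self):
        a = sample_population(PopulationSpec(n=200, seed=11))
        b = sample_population(PopulationSpec(n=200, seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_bounds_respected(self):
        df = sample_population(PopulationSpec(n=5000, seed=2))
        for var, m in COHORT_MARGINALS.items():
            col = df["CCT"] * 1000.0 if var == "CCT_um" else df[var]
            assert col.min() >= m["min"]
            assert col.max() <= m["max"]

    def test_marginal_means_recovered(self):
        n = 10000
        df = sample_population(PopulationSpec(n=n, seed=5))
        for var, m in COHORT_MARGINALS.items():
            col = df["CCT"] * 1000.0 if var == "CCT_um" else df[var]
            assert abs(col.mean() - m["mean"]) < 3.0 * m["sd"] / np.sqrt(n)

    def test_cct_stored_in_mm(self):
        df = sample_population(PopulationSpec(n=100, seed=1))
        assert 0.3 < df["CCT"].mean() < 0.8

    def test_correlated_sampling(self):
        corr = np.eye(6)
        corr[0, 2] = corr[2, 0] = 0.6  # R_f with R_b
        df = sample_population(PopulationSpec(n=4000, seed=9, corr=corr))
        r = np.corrcoef(df["R_f"], df["R_b"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.08)

    def test_infeasible_truncation_raises(self):
        marg = {k: dict(v) for k, v in COHORT_MARGINALS.items()}
        marg["R_f"].update(min=7.7325, max=7.7335)  # ~0.1% acceptance window
        with pytest.raises(SamplingError):
            sample_population(PopulationSpec(n=50, seed=0, marginals=marg))

    def test_invalid_spec_rejected(self):
        marg = {k: dict(v) for k, v in COHORT_MARGINALS.items()}
        marg["PUP"]["sd"] = -1.0
        with pytest.raises(ValueError):
            PopulationSpec(n=10, marginals=marg)


class TestCsvIO:
    def test_write_read_round_trip(self, tmp_path):
        df = sample_population(PopulationSpec(n=25, seed=3))
        path = tmp_path / "eyes.csv"
        write_casia_csv(df, path)
        back = read_casia_csv(path)
        pd.testing.assert_frame_equal(
            back[df.columns], df, check_exact=False, rtol=0, atol=1e-12
        )

    def test_eccentricity_columns_converted(self, tmp_path):
        path = tmp_path / "ecc.csv"
        path.write_text(
            "eye_id,Rf_mm,ecc_f,Rb_mm,ecc_b,CCT_um,PUP_mm\n"
            "a,7.72,0.56,6.53,0.1,547,4.4\n"
        )
        df = read_casia_csv(path)
        assert df.loc[0, "Q_f"] == pytest.approx(-0.3136, abs=1e-9)
        assert df.loc[0, "Q_b"] == pytest.approx(-0.01, abs=1e-12)
        assert df.loc[0, "CCT"] == pytest.approx(0.547)

    def test_negative_radius_normalised_with_warning(self, tmp_path, caplog):
        path = tmp_path / "neg.csv"
        path.write_text(
            "eye_id,Rf_mm,Qf,Rb_mm,Qb,CCT_um,PUP_mm\na,7.72,-0.3,-6.530,-0.01,547,4.4\n"
        )
        with caplog.at_level(logging.WARNING, logger="corneatrace.population"):
            df = read_casia_csv(path)
        assert df.loc[0, "R_b"] == 6.530
        assert any("negative" in rec.message for rec in caplog.records)

    def test_incomplete_rows_dropped_and_counted(self, tmp_path):
        path = tmp_path / "gaps.csv"
        path.write_text(
            "eye_id,Rf_mm,Qf,Rb_mm,Qb,CCT_um,PUP_mm\n"
            "a,7.72,-0.3,6.53,-0.01,547,4.4\n"
            "b,7.80,,6.50,-0.02,550,4.2\n"
        )
        df = read_casia_csv(path)
        assert len(df) == 1
        assert df.attrs["n_dropped"] == 1

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("eye_id,Rf_mm\na,7.7\n")
        with pytest.raises(FormatError):
            read_casia_csv(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_casia_csv(path)


class TestSummarize:
    def test_quantiles_match_sort_oracle(self, rng):
        vals = pd.DataFrame({"x": rng.normal(0, 1, 101)})
        table = summarize(vals)
        xs = np.sort(vals["x"].to_numpy())
        for q in (0.005, 0.05, 0.95, 0.995):
            # linear interpolation between order statistics
            pos = q * (len(xs) - 1)
            lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            expected = xs[lo] * (1 - frac) + xs[min(lo + 1, len(xs) - 1)] * frac
            assert table.loc[f"Quantile {100 * q:g}%", "x"] == pytest.approx(expected, abs=1e-12)
        assert table.loc["Median", "x"] == pytest.approx(np.median(xs), abs=1e-12)


class TestBatch:
    def test_single_mean_cornea_reproduces_cohort_power(self):
        res = analyze_batch(mean_eye_frame(), fit_models=False)
        row = res.per_eye.iloc[0]
        assert row["CP_WF"] == pytest.approx(43.02, abs=0.2)
        for c in CRITERIA:
            assert row[f"CP_{c}"] * row[f"zF_{c}"] == pytest.approx(1336.0, abs=1e-6)
        assert row["zF_WF"] < row["zF_TSD"] < row["zF_RMS"] < row["zF_MA"]

    def test_mean_zero_mode_zeroes_deviation_means(self):
        eyes = sample_population(PopulationSpec(n=10, seed=4))
        res = analyze_batch(eyes, n_rays=201, nk_mode="mean_zero", fit_models=False)
        for c in CRITERIA:
            assert res.per_eye[f"dCP_{c}"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_order_independent(self):
        eyes = sample_population(PopulationSpec(n=6, seed=8))
        a = analyze_batch(eyes, n_rays=201, fit_models=False).per_eye
        b = analyze_batch(
            eyes.iloc[::-1].reset_index(drop=True), n_rays=201, fit_models=False
        ).per_eye
        merged = a.merge(b, on="eye_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["CP_MA_a"], merged["CP_MA_b"], atol=1e-12)

    def test_failing_eye_logged_with_reason(self):
        eyes = mean_eye_frame(2)
        eyes.loc[1, "PUP"] = 25.0  # far outside the surface extent
        res = analyze_batch(eyes, n_rays=201, fit_models=False)
        assert len(res.per_eye) == 1
        assert len(res.failures) == 1
        assert res.failures.iloc[0]["reason"] in ("miss", "extent")

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            analyze_batch(mean_eye_frame(0))

    def test_all_failed_rejected(self):
        eyes = mean_eye_frame(1)
        eyes.loc[0, "PUP"] = 25.0
        with pytest.raises(CorneaTraceError):
            analyze_batch(eyes, n_rays=201, fit_models=False)

    def test_summary_tables_present(self):
        eyes = sample_population(PopulationSpec(n=10, seed=6))
        res = analyze_batch(eyes, n_rays=201)
        assert set(res.summaries) == {"inputs", "focus", "sa_index", "deviation"}
        assert "Quantile 99.5%" in res.summaries["focus"].index
        assert set(res.keratometer_indices) == set(CRITERIA)
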