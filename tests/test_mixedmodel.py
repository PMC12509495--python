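"""Frame-level mixed model: design construction, fitting, contrast, meta-OLS."""

import numpy as np
import pandas as pd
import pytest

from cholinepipe import mixedmodel
from cholinepipe.mixedmodel import (
    assemble_frame_table,
    build_design_matrix,
    fit_lmm,
    novelty_contrast,
    ols_meta,
    sliding_lmm,
)
from conftest import make_records


def _block_indicator(rng, n, n_bouts, bout_len):
    out = np.zeros(n, int)
    bout_len = min(bout_len, max(1, n // 3))
    for _ in range(n_bouts):
        start = rng.integers(0, max(1, n - bout_len))
        out[start : start + bout_len] = 1
    return out


def make_table(rng, n_sessions=4, n_frames=6000, beta_speed=0.25, beta_groom=-0.75,
               beta_rear=0.15, contrast=0.0, noise_sd=0.3, rate=30.0):
    """Frame table drawn from the model's own data-generating process."""
    frames = []
    for s in range(n_sessions):
        phase = s % 2
        speed = np.abs(np.cumsum(rng.standard_normal(n_frames)) / 20) + 0.1
        log2speed = np.log2(np.maximum(speed, 1.0))
        grooming = _block_indicator(rng, n_frames, 6, 150)
        rearing = _block_indicator(rng, n_frames, 6, 100) * (1 - grooming)
        exp_stat = _block_indicator(rng, n_frames, 8, 120)
        exp_nonstat = _block_indicator(rng, n_frames, 8, 120) * (1 - exp_stat)
        y = (
            beta_speed * log2speed
            + beta_groom * grooming
            + beta_rear * rearing
            + 0.2 * exp_stat
            + (0.2 + contrast * phase) * exp_nonstat
            + rng.standard_normal(n_frames) * noise_sd
        )
        frames.append(
            pd.DataFrame(
                {
                    "dff_z": y,
                    "phase": phase,
                    "log2speed": log2speed,
                    "grooming": grooming,
                    "rearing": rearing,
                    "exp_stat": exp_stat,
                    "exp_nonstat": exp_nonstat,
                    "mouse_id": f"m{s % 2}",
                    "session_id": f"s{s}",
                    "oblom_key": f"m{s % 2}:1",
                    "t": np.arange(n_frames) / rate,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestAssembleFrameTable:
    def test_row_count_and_columns(self):
        records, _ = make_records(rep_seed=1, n_pairs=1, dur=120.0)
        table = assemble_frame_table(records)
        assert len(table) == 2 * 120 * 30
        for col in ("dff_z", "phase", "log2speed", "grooming", "rearing",
                    "exp_stat", "exp_nonstat", "mouse_id", "session_id"):
            assert col in table.columns
        assert not table.isna().any().any()
        # behavior indicators keep the ethogram's exclusivity
        assert (table["exp_stat"] + table["exp_nonstat"]).max() <= 1
        assert table.groupby("session_id")["phase"].nunique().max() == 1

    def test_rate_mismatch_raises(self):
        records, _ = make_records(rep_seed=1, n_pairs=1, dur=120.0)
        records[0]["dff"].rate = 25.0
        with pytest.raises(ValueError, match="rate"):
            assemble_frame_table(records)


class TestDesignMatrix:
    def test_matches_hand_built_columns(self, rng):
        table = make_table(rng, n_sessions=2, n_frames=10)
        X = build_design_matrix(table)
        hand = {
            "Intercept": np.ones(len(table)),
            "phase": table["phase"].to_numpy(float),
            "log2speed": table["log2speed"].to_numpy(),
            "exp_nonstat": table["exp_nonstat"].to_numpy(float),
            "exp_stat": table["exp_stat"].to_numpy(float),
            "rearing": table["rearing"].to_numpy(float),
            "grooming": table["grooming"].to_numpy(float),
            "phase:log2speed": (table["phase"] * table["log2speed"]).to_numpy(),
            "phase:exp_nonstat": (table["phase"] * table["exp_nonstat"]).to_numpy(float),
            "phase:exp_stat": (table["phase"] * table["exp_stat"]).to_numpy(float),
            "phase:rearing": (table["phase"] * table["rearing"]).to_numpy(float),
            "phase:grooming": (table["phase"] * table["grooming"]).to_numpy(float),
        }
        assert set(X.columns) == set(hand)
        for name, col in hand.items():
            assert np.allclose(X[name].to_numpy(), col), name


class TestFitLmm:
    def test_recovers_generating_coefficients(self, rng):
        table = make_table(rng, contrast=0.3)
        res = fit_lmm(table, random_spec="intercepts")
        fx = res.fixed
        assert fx.loc["log2speed", "estimate"] == pytest.approx(0.25, abs=0.05)
        assert fx.loc["grooming", "estimate"] == pytest.approx(-0.75, abs=0.1)
        assert fx.loc["rearing", "estimate"] == pytest.approx(0.15, abs=0.1)
        assert res.random_level == "intercepts"
        assert (fx["se_eff"] > 0).all()
        assert res.df_resid == len(table) - len(fx)

    def test_intercept_only_data_recovers_mean(self, rng):
        table = make_table(rng, beta_speed=0, beta_groom=0, beta_rear=0, noise_sd=0.2)
        session_effects = {f"s{i}": e for i, e in enumerate((0.3, -0.2, 0.1, -0.2))}
        offsets = table["session_id"].map(session_effects).to_numpy()
        table["dff_z"] = 1.5 + offsets + rng.standard_normal(len(table)) * 0.2
        res = fit_lmm(table, random_spec="intercepts", formula="dff_z ~ 1")
        assert res.fixed.loc["Intercept", "estimate"] == pytest.approx(1.5, abs=0.1)

    def test_rank_deficient_design_reports_aliased_columns(self, rng):
        table = make_table(rng, n_sessions=2, n_frames=500)
        table["exp_stat"] = table["exp_nonstat"]
        with pytest.raises(ValueError, match="aliased"):
            fit_lmm(table, random_spec="intercepts")

    def test_requires_two_mice_and_sessions(self, rng):
        table = make_table(rng, n_sessions=2, n_frames=200)
        solo = table[table["mouse_id"] == "m0"]
        with pytest.raises(ValueError, match="2 mice"):
            fit_lmm(solo, random_spec="intercepts")

    def test_fallback_ladder_records_level(self, rng):
        table = make_table(rng, n_sessions=4, n_frames=1500)
        res = fit_lmm(table, random_spec="diag")
        assert res.random_level in ("diag", "intercepts")


class TestNoveltyContrast:
    def test_equals_difference_of_interaction_estimates(self, rng):
        table = make_table(rng, contrast=0.3)
        res = fit_lmm(table, random_spec="intercepts")
        con = novelty_contrast(res)
        expected = (
            res.fixed.loc["phase:exp_nonstat", "estimate"]
            - res.fixed.loc["phase:exp_stat", "estimate"]
        )
        assert con.estimate == pytest.approx(expected, abs=1e-10)
        assert con.F >= 0 and con.df_num == 1

    def test_recovers_injected_contrast(self, rng):
        table = make_table(rng, contrast=0.3)
        con = novelty_contrast(fit_lmm(table, random_spec="intercepts"))
        assert con.estimate == pytest.approx(0.3, abs=0.12)
        assert con.p_eff < 0.05

    def test_symmetric_null_is_small(self, rng):
        table = make_table(rng, contrast=0.0)
        con = novelty_contrast(fit_lmm(table, random_spec="intercepts"))
        assert abs(con.estimate) < 0.12


class TestSlidingLmm:
    def test_stationary_effect_gives_flat_series(self, rng):
        table = make_table(rng, n_sessions=4, n_frames=9000, contrast=0.0, noise_sd=0.1)
        coefs = sliding_lmm(table, window=100.0, step=100.0)
        diffs = coefs["diff"].dropna()
        assert len(diffs) >= 4
        assert diffs.std() < 0.1

    def test_full_window_equals_global_fit(self, rng):
        table = make_table(rng, n_sessions=4, n_frames=3000, contrast=0.3)
        global_fit = fit_lmm(table, random_spec="intercepts")
        coefs = sliding_lmm(table, window=100.0, step=200.0)
        sample_diff = (
            global_fit.fixed.loc["exp_nonstat", "estimate"]
            - global_fit.fixed.loc["exp_stat", "estimate"]
        )
        got = coefs[(coefs["phase"] == 0)]["diff"].iloc[0]
        assert got == pytest.approx(sample_diff, abs=1e-6)

    def test_windows_without_exploration_are_skipped(self, rng):
        table = make_table(rng, n_sessions=4, n_frames=6000)
        # wipe exploration from the second half of each session
        late = table["t"] >= 100.0
        table.loc[late, ["exp_stat", "exp_nonstat"]] = 0
        coefs = sliding_lmm(table, window=100.0, step=100.0)
        assert coefs[coefs["window_start"] >= 100.0]["diff"].isna().all()


class TestOlsMeta:
    def test_constant_difference(self):
        df = pd.DataFrame(
            {
                "window_idx": list(range(5)) * 2,
                "phase": [0] * 5 + [1] * 5,
                "diff": [0.4] * 10,
            }
        )
        fit = ols_meta(df)
        assert fit.loc["Intercept", "estimate"] == pytest.approx(0.4)
        for term in ("phase", "window_idx", "phase:window_idx"):
            assert fit.loc[term, "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        df = pd.DataFrame(
            {
                "window_idx": list(range(6)) * 2,
                "phase": [0] * 6 + [1] * 6,
                "diff": rng.standard_normal(12),
            }
        )
        fit = ols_meta(df)
        X = np.column_stack(
            [
                np.ones(12),
                df["phase"],
                df["window_idx"],
                df["phase"] * df["window_idx"],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ df["diff"].to_numpy())
        got = fit.loc[["Intercept", "phase", "window_idx", "phase:window_idx"], "estimate"]
        assert np.allclose(got.to_numpy(), beta, atol=1e-10)

    def test_single_phase_raises(self):
        df = pd.DataFrame({"window_idx": range(5), "phase": [0] * 5, "diff": np.ones(5)})
        with pytest.raises(ValueError):
            ols_meta(df)
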