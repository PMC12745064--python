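import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from seqchains import (
    ReproductionEvent,
    TrigramModel,
    build_rt_table,
    filter_rts,
    freq_length_correlation,
    poisson_freq_length,
    rt_tp_association,
)
from seqchains.metrics import UnitInventory


def poisson_mle_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Direct maximization of the Poisson log-likelihood (independent of
    the IRLS path used by the implementation)."""

    def neg_ll(beta):
        eta = X @ beta
        return float(np.sum(np.exp(eta)) - np.sum(y * eta))

    res = optimize.minimize(neg_ll, np.zeros(X.shape[1]), method="BFGS",
                            options={"gtol": 1e-10})
    return res.x


class TestPoissonFreqLength:
    def test_slope_recovery(self):
        rng = np.random.default_rng(21)
        n = 2000
        lengths = rng.integers(2, 9, size=n)
        mu = np.exp(4.0 - 0.3 * lengths)
        freq = rng.poisson(mu)
        while np.any(freq < 1):  # unit frequencies are >= 1 by definition
            redo = freq < 1
            freq[redo] = rng.poisson(mu[redo])
        fit = poisson_freq_length(pd.DataFrame({"frequency": freq, "length": lengths}))
        assert -0.35 <= fit.params["length"] <= -0.25

    def test_null_slope_when_independent(self):
        rng = np.random.default_rng(8)
        n = 3000
        lengths = rng.integers(2, 9, size=n)
        freq = 1 + rng.poisson(3.0, size=n)
        fit = poisson_freq_length(pd.DataFrame({"frequency": freq, "length": lengths}))
        assert abs(fit.params["length"]) < 0.02
        assert abs(fit.tvalues["length"]) < 3

    def test_irls_matches_direct_likelihood_maximization(self):
        rng = np.random.default_rng(5)
        n = 200
        lengths = rng.integers(1, 10, size=n)
        freq = 1 + rng.poisson(np.exp(1.2 - 0.1 * lengths))
        df = pd.DataFrame({"frequency": freq, "length": lengths})
        fit = poisson_freq_length(df)
        X = np.column_stack([np.ones(n), lengths.astype(float)])
        oracle = poisson_mle_oracle(freq.astype(float), X)
        assert fit.params["const"] == pytest.approx(oracle[0], abs=1e-6)
        assert fit.params["length"] == pytest.approx(oracle[1], abs=1e-6)

    def test_interaction_formulas_have_expected_terms(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "frequency": 1 + rng.poisson(2.0, size=400),
                "length": rng.integers(2, 9, size=400),
                "generation": rng.integers(0, 10, size=400),
            }
        )
        fit = poisson_freq_length(df, formula="length_x_generation")
        assert set(fit.params) == {"const", "length", "generation", "length:generation"}
        df["is_produced"] = rng.integers(0, 2, size=400)
        fit = poisson_freq_length(df, formula="length_x_produced")
        assert set(fit.params) == {"const", "length", "is_produced", "length:is_produced"}

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            poisson_freq_length(pd.DataFrame({"frequency": [2, 3], "length": [3, 3]}))
        with pytest.raises(ValueError, match="positive"):
            poisson_freq_length(pd.DataFrame({"frequency": [0, 3], "length": [3, 4]}))


class TestFreqLengthCorrelation:
    def test_perfect_log_linear_relation(self):
        inv = UnitInventory({"R": 2**9, "RG": 2**8, "RGB": 2**7, "RGBY": 2**6})
        assert freq_length_correlation(inv) == pytest.approx(-1.0)

    def test_constant_frequencies_rejected(self):
        inv = UnitInventory({"R": 3, "RG": 3, "RGB": 3})
        with pytest.raises(ValueError, match="variance"):
            freq_length_correlation(inv)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(13)
        units = {f"{'R' * int(l)}{'G' * i}": int(f) for i, (l, f) in enumerate(
            zip(rng.integers(1, 6, 20), rng.integers(1, 50, 20))
        )}
        inv = UnitInventory(units)
        logf = np.log([float(v) for v in inv.freq.values()])
        lens = np.array([float(len(k)) for k in inv.freq])
        lc, fc = lens - lens.mean(), logf - logf.mean()
        expected = np.sum(lc * fc) / math.sqrt(np.sum(lc**2) * np.sum(fc**2))
        assert freq_length_correlation(inv) == pytest.approx(expected)


class TestFilterRts:
    @staticmethod
    def make_events(rt_lists):
        return [
            ReproductionEvent("c", 1, i, "RGBY", ("RGBY" * 5)[: len(rts)], rts)
            for i, rts in enumerate(rt_lists)
        ]

    def test_floor_drops_fast_keypresses(self):
        events = self.make_events([[50.0, 400, 400, 400]])
        out, report = filter_rts(events)
        assert report["dropped_floor"] == 1
        assert 50.0 not in out["rt_ms"].values

    def test_identical_rts_survive_sd_step(self):
        events = self.make_events([[400.0] * 4, [400.0] * 4])
        out, report = filter_rts(events)
        assert report["dropped_sd"] == 0
        assert report["n_kept"] == 8

    def test_hand_built_table_matches_manual_filtering(self):
        rts = [300.0, 320, 310, 305, 315, 290, 330, 310, 1500, 50]
        events = self.make_events([rts[:5], rts[5:]])
        out, report = filter_rts(events)
        # manual: 50 < 100 ms goes first; survivors' mean/sd then exclude 1500
        survivors = np.array(rts[:9])
        m, sd = survivors.mean(), survivors.std(ddof=1)
        manual_keep = [r for r in survivors if m - 2 * sd <= r <= m + 2 * sd]
        assert report["dropped_floor"] == 1
        assert sorted(out["rt_ms"]) == sorted(manual_keep)

    def test_single_keypress_participant_retained(self):
        events = [ReproductionEvent("c", 3, 0, "RGB", "R", [400.0])]
        out, report = filter_rts(events)
        assert report["n_kept"] == 1


class TestRtTpAssociation:
    @staticmethod
    def simulate_rt_rows(n_rows, tp_slope, seed=0):
        rng = np.random.default_rng(seed)
        tp = rng.uniform(0.05, 1.0, size=n_rows)
        position = rng.integers(3, 17, size=n_rows)
        generation = rng.integers(1, 11, size=n_rows)
        log_rt = (
            math.log(450.0) + tp_slope * tp - 0.01 * position
            + 0.0 * generation + rng.normal(0, 0.2, size=n_rows)
        )
        return pd.DataFrame(
            {"log_rt": log_rt, "tp": tp, "position": position,
             "generation": generation}
        )

    def test_recovers_generator_tp_slope(self):
        df = self.simulate_rt_rows(5000, tp_slope=-0.16, seed=3)
        fit = rt_tp_association(df)
        assert -0.20 <= fit.params["tp"] <= -0.12
        assert fit.params["position"] < 0

    def test_null_tp_slope(self):
        df = self.simulate_rt_rows(5000, tp_slope=0.0, seed=4)
        fit = rt_tp_association(df)
        assert abs(fit.params["tp"]) < 0.03

    def test_collinear_design_rejected(self):
        df = self.simulate_rt_rows(100, tp_slope=-0.1, seed=5)
        df["tp"] = 0.05 * df["position"]  # tp an exact function of position
        with pytest.raises(ValueError, match="rank"):
            rt_tp_association(df)

    def test_constant_generation_term_is_dropped(self):
        df = self.simulate_rt_rows(200, tp_slope=-0.1, seed=6)
        df["generation"] = 5
        fit = rt_tp_association(df)
        assert "generation" not in fit.params
        assert {"const", "tp", "position"} <= set(fit.params)

    def test_end_to_end_recovery_from_simulated_events(self, sim_chain):
        """The RT generator's TP slope is recovered from the agent's own
        keypress stream via the full filter + TP-attachment path."""
        chain, events_by_gen = sim_chain
        tables = []
        models = {g: TrigramModel.fit(chain[g - 1]) for g in events_by_gen}
        all_events = [ev for evs in events_by_gen.values() for ev in evs]
        table = build_rt_table(all_events, models)
        assert len(table) > 2000
        fit = rt_tp_association(table)
        true_slope = -0.16
        assert abs(fit.params["tp"] - true_slope) <= 0.25 * abs(true_slope)
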