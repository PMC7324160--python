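"""Global least-squares inference, bootstrap, time-constant fitting."""

import numpy as np
import pandas as pd
import pytest

from isnkit import (
    BlockerEfficacy,
    DoseResponseDataset,
    TimeConstants,
    bootstrap_fit,
    build_dataset_from_units,
    count_free_parameters,
    fit_global,
    fit_time_constants,
    fixed_point,
    rescale_params,
    residual_loss,
    simulate_dynamics,
)
from isnkit.inference import IdentifiabilityWarning, predict_rates

from conftest import make_noiseless_dataset

EPS = BlockerEfficacy(0.3, 0.3)


@pytest.fixture(scope="module")
def noiseless_ds(vgat_params):
    return make_noiseless_dataset(vgat_params, eps=EPS)


@pytest.fixture(scope="module")
def recovered(vgat_params, noiseless_ds):
    """One moderately sized global fit shared by the recovery assertions."""
    return fit_global(noiseless_ds, n_restarts=60, seed=123)


class TestResidualLoss:
    def test_zero_at_generating_truth(self, vgat_params, noiseless_ds):
        loss = residual_loss(vgat_params, {"s0": EPS, "s1": EPS}, noiseless_ds)
        assert loss == pytest.approx(0.0, abs=1e-18)

    def test_positive_away_from_truth(self, vgat_params, noiseless_ds):
        from dataclasses import replace

        off = replace(vgat_params, W_EE=vgat_params.W_EE + 1.0)
        assert residual_loss(off, {"s0": EPS, "s1": EPS}, noiseless_ds) > 0

    def test_singular_model_penalized_not_raised(self, noiseless_ds):
        from isnkit import TwoPopParams

        p = TwoPopParams(W_EE=2.0, W_EI=1.0, W_IE=1.0, W_II=0.0,
                         I_EX=5.0, I_IX=5.0, lam=1.0)
        assert p.determinant == 0
        loss = residual_loss(p, {"s0": EPS, "s1": EPS}, noiseless_ds)
        assert np.isfinite(loss) and loss > 1e4


class TestGlobalFit:
    def test_recovers_all_parameters_within_2pct(self, vgat_params, recovered):
        truth = {
            "W_EE": 2.56, "W_EI": 1.77, "W_IE": 8.54, "W_II": 7.11,
            "I_EX": 8.51, "I_IX": 34.16, "x0_E": 1.19, "x0_I": 8.65,
            "lam": 6.3,
        }
        got = recovered.as_series()
        for name, val in truth.items():
            assert got[name] == pytest.approx(val, rel=0.02), name
        for s in ("s0", "s1"):
            assert recovered.eps[s].eps_E == pytest.approx(0.3, rel=0.02)
            assert recovered.eps[s].eps_I == pytest.approx(0.3, rel=0.02)

    def test_sse_roundtrip_consistent(self, recovered, noiseless_ds):
        loss = residual_loss(recovered.params, recovered.eps, noiseless_ds)
        assert loss == pytest.approx(recovered.sse, rel=1e-6, abs=1e-12)

    def test_more_restarts_never_worse(self, noiseless_ds):
        a = fit_global(noiseless_ds, n_restarts=3, seed=9)
        b = fit_global(noiseless_ds, n_restarts=6, seed=9)
        assert b.sse <= a.sse + 1e-15

    def test_deterministic_given_seed(self, noiseless_ds):
        a = fit_global(noiseless_ds, n_restarts=3, seed=4)
        b = fit_global(noiseless_ds, n_restarts=3, seed=4)
        assert a.sse == b.sse
        assert a.params == b.params

    def test_single_phase_warns_identifiability(self, vgat_params):
        ds = make_noiseless_dataset(vgat_params, eps=EPS)
        single = DoseResponseDataset(
            ds.table[ds.table.phase == "intact"].reset_index(drop=True)
        )
        with pytest.warns(IdentifiabilityWarning):
            fit_global(single, n_restarts=2, seed=0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(pd.DataFrame())

    def test_rescaled_truth_recovered(self, vgat_params, noiseless_ds):
        """Generating from a rescaled truth yields identical intact-phase
        rates (the equilibrium invariance family) but distinct blocker-phase
        rates — and the fit recovers the rescaled parameters."""
        scaled = rescale_params(vgat_params, 1.5, 0.8)
        ds_scaled = make_noiseless_dataset(scaled, eps=EPS)
        intact_a = ds_scaled.table[ds_scaled.table.phase == "intact"]["rate"]
        intact_b = noiseless_ds.table[noiseless_ds.table.phase == "intact"]["rate"]
        assert intact_a.to_numpy() == pytest.approx(intact_b.to_numpy(),
                                                    abs=1e-9)
        # blocker phases break the degeneracy (different W_EE scaling)
        blocked_a = ds_scaled.table[ds_scaled.table.phase != "intact"]["rate"]
        blocked_b = noiseless_ds.table[noiseless_ds.table.phase != "intact"]["rate"]
        assert not np.allclose(blocked_a, blocked_b, atol=1e-3)
        assert residual_loss(scaled, {"s0": EPS, "s1": EPS}, ds_scaled) == \
            pytest.approx(0.0, abs=1e-15)
        fit = fit_global(ds_scaled, n_restarts=40, seed=77)
        assert fit.params.W_EE == pytest.approx(scaled.W_EE, rel=0.02)
        assert fit.params.lam == pytest.approx(scaled.lam, rel=0.02)


@pytest.fixture(scope="module")
def unit_rates(vgat_params):
    """Small noisy unit-level table with known truth."""
    rng = np.random.default_rng(42)
    L = np.linspace(0.0, 3.0, 8)
    rows = []
    for sess in ("s0", "s1"):
        for pop in ("E", "I"):
            for u in range(6):
                mult = rng.lognormal(0, 0.05)
                for phase in ("intact", "e_blocked", "ei_blocked"):
                    r = predict_rates(vgat_params, EPS, phase, L, pop)
                    for li, ri in zip(L, r):
                        rows.append(
                            dict(session=sess, unit_id=f"{sess}{pop}{u}",
                                 population=pop, phase=phase,
                                 intensity=li, rate=ri * mult)
                        )
    return pd.DataFrame(rows)


class TestBootstrap:
    def test_identity_resample_reproduces_global_fit(self, unit_rates):
        ds = build_dataset_from_units(unit_rates)
        direct = fit_global(ds, n_restarts=5, seed=0)
        boot = bootstrap_fit(unit_rates, n_boot=1, n_restarts_per_boot=5,
                             seed=0, identity_first=True)
        assert boot.samples[0].params.W_EE == pytest.approx(
            direct.params.W_EE, rel=1e-6
        )

    def test_median_near_truth_and_summaries_recomputable(self, unit_rates):
        boot = bootstrap_fit(unit_rates, n_boot=12, n_restarts_per_boot=6,
                             seed=1)
        table = boot.table()
        med = boot.summary.loc["W_EE", "median"]
        assert med == pytest.approx(np.median(table["W_EE"]))
        assert med == pytest.approx(2.56, rel=0.10)

    def test_interval_shrinks_with_more_units(self, vgat_params, unit_rates):
        rng = np.random.default_rng(3)
        big = []
        for rep in range(4):
            t = unit_rates.copy()
            t["unit_id"] = t["unit_id"] + f"_r{rep}"
            # fresh per-unit heterogeneity multipliers (constant per unit)
            mults = {u: rng.lognormal(0, 0.05) for u in t["unit_id"].unique()}
            t["rate"] *= t["unit_id"].map(mults)
            big.append(t)
        big = pd.concat(big, ignore_index=True)
        kw = dict(n_boot=8, n_restarts_per_boot=15, seed=7)

        def iqr(table):
            return np.subtract(*np.percentile(table["W_EE"], [75, 25]))

        w_small = iqr(bootstrap_fit(unit_rates, **kw).table())
        w_big = iqr(bootstrap_fit(big, **kw).table())
        assert w_big < w_small

    def test_too_few_resamples_rejected(self, unit_rates):
        with pytest.raises(ValueError):
            bootstrap_fit(unit_rates, n_boot=1)


class TestTimeConstants:
    def test_recovery_from_noiseless_step(self, vgat_params):
        taus = TimeConstants(7.8, 34.3)
        t, rE, rI, _ = simulate_dynamics(
            vgat_params, taus, 2.6, dt=0.5, T=600,
            init=fixed_point(vgat_params, 0.0).rates,
        )
        res = fit_time_constants(vgat_params, rE, rI, dt=0.5, L=2.6)
        assert res.identifiable
        assert res.taus.tau_I == pytest.approx(34.3, abs=0.5)
        assert res.taus.ratio == pytest.approx(4.4, abs=0.1)

    def test_flat_traces_flagged(self, vgat_params):
        fp = fixed_point(vgat_params, 0.0)
        n = 200
        with pytest.warns(UserWarning, match="no dynamics"):
            res = fit_time_constants(
                vgat_params, np.full(n, fp.r_E), np.full(n, fp.r_I),
                dt=0.5, L=0.0,
            )
        assert not res.identifiable


class TestParameterCount:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(), 11),  # canonical equilibrium, gains pinned
            (dict(gains_pinned=False), 13),  # before pinning gains
            (dict(equilibrium=False), 13),  # dynamics, gains pinned
            (dict(n_sessions=6), 21),  # per-session efficacy pairs
            (dict(blockers=False), 9),
            (dict(transfer="softplus"), 13),
        ],
    )
    def test_counts(self, kwargs, expected):
        assert count_free_parameters(**kwargs) == expected
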