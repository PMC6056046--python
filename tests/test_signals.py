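import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrseqopt.signals import (
    FLAIRParams,
    FSEParams,
    GREParams,
    MPRAGEParams,
    TimingError,
    ernst_angle,
    flair_null_ti,
    flair_signal,
    fse_signal,
    gre_signal,
    mprage_signal,
    mprage_terms,
    sequence_signal,
)
from mrseqopt.tissues import TissueRelaxation, get_tissue

from oracles import fse_steady_state_bloch, gre_steady_state, mprage_cycle_signal


# ---------------------------------------------------------------- FSE


class TestFse:
    def test_full_recovery_limit(self, tissues_pre):
        p = FSEParams(tr_ms=1e9, esp_ms=7.4, etl=1, te_eff_ms=0.0)
        assert fse_signal(p, tissues_pre["brain_parenchyma"]).s_over_m0 == pytest.approx(1.0)

    def test_zero_recovery_interval_rejected(self):
        # TR equal to the train duration leaves no recovery: invalid timing
        with pytest.raises(TimingError):
            FSEParams(tr_ms=111.0, esp_ms=7.4, etl=15, te_eff_ms=59.2)

    def test_parenchyma_t1_weighted_value(self, tissues_pre):
        """Frozen value from direct evaluation of the closed form."""
        p = FSEParams(tr_ms=500.0, esp_ms=7.4, etl=1, te_eff_ms=7.4)
        res = fse_signal(p, tissues_pre["brain_parenchyma"])
        assert res.s_over_m0 == pytest.approx(0.1488, abs=5e-5)

    def test_closed_form_matches_bloch_iteration(self, tissues_pre):
        """First-order approximation vs exact ideal-pulse recovery simulation."""
        for tr, etl in [(500.0, 1), (6000.0, 13), (9000.0, 3)]:
            p = FSEParams(tr_ms=tr, esp_ms=7.4, etl=etl, te_eff_ms=0.0)
            for t in tissues_pre.values():
                exact = fse_steady_state_bloch(tr, 7.4, etl, t.t1_ms)
                approx = fse_signal(p, t).m_over_m0
                assert approx == pytest.approx(exact, rel=0.02)

    def test_signal_increases_with_tr(self, tissues_pre):
        t = tissues_pre["tumor"]
        values = [
            fse_signal(FSEParams(tr, 7.4, 3, 14.8), t).s_over_m0
            for tr in (200.0, 500.0, 1000.0, 3000.0, 9000.0)
        ]
        assert np.all(np.diff(values) > 0)


# ---------------------------------------------------------------- FLAIR


class TestFlair:
    def test_full_recovery_limit(self, tissues_pre):
        p = FLAIRParams(tr_ms=1e9, esp_ms=7.4, etl=1, te_eff_ms=0.0, ti_ms=1e8)
        assert flair_signal(p, tissues_pre["csf"]).m_over_m0 == pytest.approx(1.0)

    def test_parenchyma_longitudinal_value(self, tissues_pre):
        p = FLAIRParams(tr_ms=8000.0, esp_ms=7.4, etl=1, te_eff_ms=7.4, ti_ms=1700.0)
        m = flair_signal(p, tissues_pre["brain_parenchyma"]).m_over_m0
        assert m == pytest.approx(0.0134, abs=1e-4)

    def test_longitudinal_term_changes_sign_around_value(self, tissues_pre):
        """Root-bracketing: the 1700 ms value sits between a negative and a
        positive longitudinal state for parenchyma at TR 8000."""
        t = tissues_pre["brain_parenchyma"]

        def m_at(ti):
            return flair_signal(FLAIRParams(8000.0, 7.4, 1, 0.0, ti), t).m_over_m0

        assert m_at(1500.0) < 0 < m_at(1900.0)

    def test_null_ti_closed_form_vs_bisection(self, tissues_pre):
        """The closed-form null TI agrees with bisection on the signal to 1e-6."""
        t = tissues_pre["csf"]
        lo, hi = 1.0, 8000.0 - 7.4 - 1.0

        def m_at(ti):
            return flair_signal(FLAIRParams(8000.0, 7.4, 1, 0.0, ti), t).m_over_m0

        for _ in range(60):
            mid = (lo + hi) / 2
            if m_at(lo) * m_at(mid) <= 0:
                hi = mid
            else:
                lo = mid
        ti_bisect = (lo + hi) / 2
        ti_closed = flair_null_ti(t, 8000.0, 1, 7.4)
        assert ti_closed == pytest.approx(ti_bisect, abs=1e-6)
        assert ti_closed == pytest.approx(2106.8, abs=0.5)

    def test_null_ti_substitution_nulls_the_signal(self, tissues_pre):
        for t in tissues_pre.values():
            ti = flair_null_ti(t, 9000.0, 3, 7.4)
            p = FLAIRParams(9000.0, 7.4, 3, 0.0, ti)
            assert abs(flair_signal(p, t).m_over_m0) < 1e-9

    def test_null_ti_vanishes_with_t1(self):
        tiny = TissueRelaxation("x", "pre", 1e-3, 1e-4, 1e-5)
        assert flair_null_ti(tiny, 8000.0, 1, 7.4) < 1e-2

    def test_timing_invariant(self):
        with pytest.raises(TimingError):
            FLAIRParams(tr_ms=2000.0, esp_ms=7.4, etl=3, te_eff_ms=14.8, ti_ms=1990.0)

    def test_signal_decreases_with_tr_at_fixed_ti(self, tissues_pre):
        """The longitudinal term 1 − 2e^(−TI/T1) + e^(−TD/T1) loses its
        pre-inversion recovery contribution as TR grows."""
        t = tissues_pre["csf"]
        values = [
            flair_signal(FLAIRParams(tr, 7.4, 1, 7.4, 1700.0), t).s_over_m0
            for tr in (3000.0, 6000.0, 10000.0, 20000.0)
        ]
        assert np.all(np.diff(values) < 0)


# ---------------------------------------------------------------- GRE


class TestGre:
    def test_zero_flip_angle_gives_zero_signal(self, tissues_pre):
        p = GREParams(tr_ms=275.0, te_ms=3.5, fa_deg=0.0)
        assert gre_signal(p, tissues_pre["tumor"]).s_over_m0 == 0.0

    def test_saturation_limit(self, tissues_pre):
        p = GREParams(tr_ms=1e9, te_ms=1e-9, fa_deg=90.0)
        assert gre_signal(p, tissues_pre["tumor"]).s_over_m0 == pytest.approx(1.0)

    def test_parenchyma_value(self, tissues_pre):
        p = GREParams(tr_ms=350.0, te_ms=3.5, fa_deg=60.0)
        res = gre_signal(p, tissues_pre["brain_parenchyma"])
        assert res.s_over_m0 == pytest.approx(0.1725, abs=5e-5)

    def test_closed_form_matches_fixed_point_iteration(self, tissues_post):
        for fa in (10.0, 40.0, 90.0, 150.0):
            p = GREParams(tr_ms=275.0, te_ms=3.5, fa_deg=fa)
            for t in tissues_post.values():
                assert gre_signal(p, t).m_over_m0 == pytest.approx(
                    gre_steady_state(275.0, fa, t.t1_ms), abs=1e-12
                )

    def test_flip_angle_out_of_range(self):
        with pytest.raises(ValueError, match="fa_deg"):
            GREParams(tr_ms=275.0, te_ms=3.5, fa_deg=190.0)

    def test_ernst_angle_limits_and_value(self):
        assert ernst_angle(1e9, 1000.0) == pytest.approx(90.0)
        assert ernst_angle(1e-6, 1000.0) == pytest.approx(0.0, abs=1e-2)
        assert ernst_angle(275.0, 1032.96) == pytest.approx(40.0, abs=0.05)

    def test_ernst_angle_is_unique_interior_maximizer(self, tissues_post):
        """Dense grid search over θ confirms the closed-form maximizer."""
        t = tissues_post["tumor"]
        grid = np.linspace(0.5, 90.0, 1800)
        signals = [
            gre_signal(GREParams(275.0, 3.5, fa), t).s_over_m0 for fa in grid
        ]
        best = grid[int(np.argmax(signals))]
        assert best == pytest.approx(ernst_angle(275.0, t.t1_ms), abs=0.1)


# ---------------------------------------------------------------- MP-RAGE


def _random_mprage(rng) -> tuple[MPRAGEParams, TissueRelaxation]:
    t1 = rng.uniform(300.0, 4000.0)
    t2s = rng.uniform(5.0, 100.0)
    tissue = TissueRelaxation("rand", "pre", t1, min(t1, t2s * 2), t2s)
    n = int(rng.integers(1, 257))
    esp = rng.uniform(1.0, 10.0)
    ti = rng.uniform(100.0, 3000.0)
    td = rng.uniform(0.0, 500.0)
    fa = rng.uniform(1.0, 90.0)
    params = MPRAGEParams(
        tr_ms=ti + n * esp + td, ti_ms=ti, n_readouts=n, fa_deg=fa,
        te_ms=rng.uniform(1.0, 5.0), td_ms=td, esp_ms=esp,
        readout_index=int(rng.integers(1, n + 1)),
    )
    return params, tissue


class TestMprage:
    def test_zero_flip_angle_gives_zero_signal(self, tissues_post):
        p = MPRAGEParams(tr_ms=1983.0, ti_ms=1700.0, n_readouts=128,
                         fa_deg=0.0, te_ms=2.3)
        assert mprage_signal(p, tissues_post["tumor"]).s_over_m0 == 0.0

    def test_first_readout_is_pure_inversion_recovery(self, tissues_post):
        """At n = 1 the geometric sum is empty: M1 = (1−γ) − γ·Meq/M0."""
        t = tissues_post["tumor"]
        p = MPRAGEParams(tr_ms=1983.0, ti_ms=1700.0, n_readouts=128,
                         fa_deg=10.0, te_ms=2.3, readout_index=1)
        terms = mprage_terms(p, t)
        expected = (1.0 - terms.gamma) - terms.gamma * terms.meq_over_m0
        assert mprage_signal(p, t).m_over_m0 == pytest.approx(expected, abs=1e-15)

    def test_timing_identity_enforced(self):
        with pytest.raises(TimingError, match="residual"):
            MPRAGEParams(tr_ms=2000.0, ti_ms=1700.0, n_readouts=128,
                         fa_deg=10.0, te_ms=2.3, esp_ms=2.0)

    def test_default_readout_is_center_of_train(self):
        p = MPRAGEParams(tr_ms=1983.0, ti_ms=1700.0, n_readouts=128,
                         fa_deg=10.0, te_ms=2.3)
        assert p.readout_index == 64

    def test_published_protocol_matches_cycle_oracle(self, tissues_post):
        t = tissues_post["tumor"]
        p = MPRAGEParams(tr_ms=1983.0, ti_ms=1700.0, n_readouts=128,
                         fa_deg=10.0, te_ms=2.3)
        assert mprage_signal(p, t).s_over_m0 == pytest.approx(
            mprage_cycle_signal(p, t), abs=1e-6
        )

    def test_closed_form_matches_cycle_oracle_on_random_parameters(self):
        """100 random valid parameter sets agree with the recursion to 1e-6."""
        rng = np.random.default_rng(20180723)
        for _ in range(100):
            p, t = _random_mprage(rng)
            closed = mprage_signal(p, t).s_over_m0
            simulated = mprage_cycle_signal(p, t)
            assert closed == pytest.approx(simulated, abs=1e-6)

    def test_terms_lie_in_unit_interval(self, tissues_pre):
        p = MPRAGEParams(tr_ms=1983.0, ti_ms=1700.0, n_readouts=128,
                         fa_deg=10.0, te_ms=2.3)
        for t in tissues_pre.values():
            terms = mprage_terms(p, t)
            for name in ("delta", "mu", "gamma", "phi", "rho"):
                assert 0.0 < getattr(terms, name) <= 1.0
            assert -1.0 <= terms.meq_over_m0 <= 1.0


# ---------------------------------------------------- shared properties


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    scale=st.floats(0.2, 5.0),
    tr=st.floats(300.0, 20000.0),
    ti_frac=st.floats(0.05, 0.6),
    fa=st.floats(1.0, 90.0),
)
def test_time_scale_invariance(scale, tr, ti_frac, fa):
    """Scaling all relaxation times and all sequence times by a common factor
    leaves every sequence's signal unchanged."""
    t = TissueRelaxation("x", "pre", 2000.0, 80.0, 40.0)
    ts = t.scaled(scale)
    ti = ti_frac * tr

    p_fse = FSEParams(tr, 7.4, 3, 14.8)
    p_fse_s = FSEParams(tr * scale, 7.4 * scale, 3, 14.8 * scale)
    assert fse_signal(p_fse, t).s_over_m0 == pytest.approx(
        fse_signal(p_fse_s, ts).s_over_m0, rel=1e-12
    )

    if ti + 3 * 7.4 < tr:
        p_fl = FLAIRParams(tr, 7.4, 3, 14.8, ti)
        p_fl_s = FLAIRParams(tr * scale, 7.4 * scale, 3, 14.8 * scale, ti * scale)
        assert flair_signal(p_fl, t).s_over_m0 == pytest.approx(
            flair_signal(p_fl_s, ts).s_over_m0, rel=1e-9, abs=1e-12
        )

    p_gre = GREParams(tr, 3.5, fa)
    p_gre_s = GREParams(tr * scale, 3.5 * scale, fa)
    assert gre_signal(p_gre, t).s_over_m0 == pytest.approx(
        gre_signal(p_gre_s, ts).s_over_m0, rel=1e-12
    )

    if ti + 128 * 2.5 < tr:
        p_mp = MPRAGEParams(tr_ms=ti + 128 * 2.5, ti_ms=ti, n_readouts=128,
                            fa_deg=fa, te_ms=2.3)
        p_mp_s = MPRAGEParams(tr_ms=(ti + 128 * 2.5) * scale, ti_ms=ti * scale,
                              n_readouts=128, fa_deg=fa, te_ms=2.3 * scale,
                              esp_ms=2.5 * scale)
        assert mprage_signal(p_mp, t).s_over_m0 == pytest.approx(
            mprage_signal(p_mp_s, ts).s_over_m0, rel=1e-9, abs=1e-12
        )


def test_transverse_decay_bounds_signal(tissues_pre):
    """|S| <= |M| whenever the decay factor is <= 1."""
    t = tissues_pre["csf"]
    for p in (
        FSEParams(7000.0, 7.4, 15, 59.2),
        FLAIRParams(9000.0, 7.4, 3, 14.8, 1700.0),
        MPRAGEParams(tr_ms=1983.0, ti_ms=1700.0, n_readouts=128, fa_deg=10.0, te_ms=2.3),
    ):
        res = sequence_signal(p, t)
        assert abs(res.s_over_m0) <= abs(res.m_over_m0) + 1e-15


def test_dispatch_rejects_unknown_type(tissues_pre):
    with pytest.raises(TypeError):
        sequence_signal(object(), tissues_pre["csf"])
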