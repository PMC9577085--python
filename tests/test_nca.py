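"""Non-compartmental analysis: trapezoid geometry, BLQ rules, pooling."""

import numpy as np
import pytest
import scipy.integrate

from nanopk.nca import ConcProfile, nca, pool_destructive, summarize_arm


def profile(times, conc, blq=None, **kw):
    kw.setdefault("subject_id", "s")
    kw.setdefault("matrix", "plasma")
    return ConcProfile(times=np.asarray(times, float),
                       concentrations=np.asarray(conc, float), blq=blq, **kw)


class TestTrapezoidGeometry:
    def test_constant_profile(self):
        res = nca(profile([0, 25, 50], [2.0, 2.0, 2.0]))
        assert res.auc_last == pytest.approx(100.0)
        assert res.mrt == pytest.approx(25.0)  # AUMC = c T^2/2
        assert res.cmax == 2.0 and res.tmax == 0.0

    def test_triangle_profile(self):
        tau, c = 30.0, 4.0
        res = nca(profile([0, tau, 2 * tau], [0, c, 0]))
        assert res.auc_last == pytest.approx(c * tau)
        assert res.tmax == tau
        assert res.tlast == 2 * tau

    def test_one_compartment_curve_matches_closed_form(self):
        A, ka, ke = 1.5, 0.05, 0.008
        tlast = 5.5 / ke  # well past 5 half-lives
        t = np.linspace(0, tlast, 4000)
        c = A * (np.exp(-ke * t) - np.exp(-ka * t))
        res = nca(profile(t, c))
        auc_inf = A * (1 / ke - 1 / ka)
        assert res.auc_last == pytest.approx(auc_inf, rel=0.01)
        # MRT oracle: numerical quadrature of t*C and C over [0, tlast]
        f = lambda x: A * (np.exp(-ke * x) - np.exp(-ka * x))
        num, _ = scipy.integrate.quad(lambda x: x * f(x), 0, tlast, limit=200)
        den, _ = scipy.integrate.quad(f, 0, tlast, limit=200)
        assert res.mrt == pytest.approx(num / den, rel=0.02)

    def test_earliest_time_wins_tmax_ties(self):
        res = nca(profile([0, 10, 20, 30], [0, 5, 5, 1]))
        assert res.tmax == 10.0

    def test_collinear_point_insertion_is_auc_neutral(self):
        base = nca(profile([0, 10, 30], [0.0, 2.0, 6.0]))
        dense = nca(profile([0, 10, 20, 30], [0.0, 2.0, 4.0, 6.0]))
        assert dense.auc_last == pytest.approx(base.auc_last)

    def test_auc_monotone_in_tlast(self):
        t = np.array([0, 10, 20, 40, 80, 160], float)
        c = np.array([0, 4, 3, 2, 1, 0.5])
        aucs = [nca(profile(t[:n], c[:n])).auc_last for n in range(2, 7)]
        assert all(b >= a for a, b in zip(aucs, aucs[1:]))

    def test_time_shift_adds_delta_to_mrt(self):
        t = np.array([0, 10, 20, 40, 80], float)
        c = np.array([0, 4, 3, 1.5, 0.2])
        delta = 25.0
        base = nca(profile(t, c))
        shifted = nca(profile(np.concatenate([[0.0], t + delta]),
                              np.concatenate([[0.0], c])))
        assert shifted.mrt == pytest.approx(base.mrt + delta)
        assert shifted.auc_last == pytest.approx(base.auc_last)


class TestBLQHandling:
    def test_leading_blq_is_zeroed(self):
        res = nca(profile([0, 5, 15], [0.3, 1.0, 0.5],
                          blq=[True, False, False]))
        # BLQ pre-dose point contributes 0, not 0.3
        assert res.auc_last == pytest.approx((0 + 1) / 2 * 5 + (1 + 0.5) / 2 * 10)

    def test_trailing_blq_shortens_tlast(self):
        res = nca(profile([0, 5, 15, 30], [0, 1.0, 0.5, 0.1],
                          blq=[False, False, False, True]))
        assert res.tlast == 15.0

    def test_embedded_blq_treated_as_zero(self):
        res = nca(profile([0, 5, 10, 15], [0, 1.0, 0.8, 0.6],
                          blq=[False, False, True, False]))
        assert res.auc_last == pytest.approx(0.5 * 5 * 1.0      # up
                                             + 0.5 * 5 * 1.0    # down to 0
                                             + 0.5 * 5 * 0.6)   # up to 0.6

    def test_all_blq_profile_rejected(self):
        with pytest.raises(ValueError, match="BLQ"):
            nca(profile([0, 5], [0.1, 0.1], blq=[True, True]))

    def test_missing_predose_assumed_zero(self):
        res = nca(profile([5, 10], [1.0, 1.0]))
        assert res.auc_last == pytest.approx(0.5 * 5 * 1.0 + 5.0)


class TestPooling:
    def test_pooled_means(self):
        pooled = pool_destructive([(30, [1.0, 3.0]), (60, [2.0, 2.0])])
        assert pooled.concentrations.tolist() == [2.0, 2.0]
        assert pooled.pooled_n.tolist() == [2, 2]
        assert pooled.pooled_sd[1] == 0.0

    def test_single_animal_per_time_is_identity(self):
        pooled = pool_destructive([(30, [1.7]), (60, [0.9])])
        assert pooled.concentrations.tolist() == [1.7, 0.9]

    def test_duplicate_time_groups_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pool_destructive([(30, [1.0]), (30, [2.0])])

    def test_pooled_auc_is_mean_of_subject_aucs_on_shared_schedule(self):
        rng = np.random.default_rng(5)
        t = np.array([30.0, 60.0, 120.0, 240.0])
        subj = rng.uniform(0.5, 2.0, size=(4, t.size))
        pooled = pool_destructive(list(zip(t, subj.T)))
        auc_pooled = nca(pooled).auc_last
        aucs = [nca(profile(t, row, matrix="brain")).auc_last for row in subj]
        assert auc_pooled == pytest.approx(np.mean(aucs))


class TestArmSummary:
    def test_identical_profiles_have_zero_sd(self):
        p = profile([0, 30, 60], [0, 2.0, 1.0])
        out = summarize_arm([p, profile([0, 30, 60], [0, 2.0, 1.0],
                                        subject_id="s2")])
        assert (out["sd"] == 0).all()
        assert out.loc["auc_last", "mean"] == pytest.approx(nca(p).auc_last)

    def test_tmax_reported_as_range(self):
        p1 = profile([0, 30, 45, 60], [0, 3.0, 2.0, 1.0], subject_id="a")
        p2 = profile([0, 30, 45, 60], [0, 2.0, 3.0, 1.0], subject_id="b")
        out = summarize_arm([p1, p2])
        assert out.loc["tmax", "display"] == "30-45"

    def test_mixed_matrices_rejected(self):
        with pytest.raises(ValueError, match="matrices"):
            summarize_arm([profile([0, 10], [0, 1]),
                           profile([0, 10], [0, 1], matrix="brain",
                                   subject_id="t")])
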