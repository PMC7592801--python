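"""Comparison statistics: percent change, phase averages, rmcorr, Bonferroni."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitmet import signals, stats, synthetic
from gaitmet.metabolics_muscle import MetabolicProfile
from gaitmet.stats import (ConditionSummary, bonferroni, compare_methods,
                           percent_change, percent_of, phase_average, rmcorr)


def brute_force_rmcorr(x, y, subject):
    """Independent ANCOVA oracle: subject dummies + common slope via lstsq."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    labels, inv = np.unique(subject, return_inverse=True)
    dummies = np.eye(len(labels))[inv]
    full = np.column_stack([dummies, x])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    ss_err = float(np.sum((y - full @ beta) ** 2))
    beta0, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    ss_red = float(np.sum((y - dummies @ beta0) ** 2))
    ss_x = ss_red - ss_err
    slope = beta[-1]
    denom = ss_x + ss_err
    r = 0.0 if denom == 0 else np.sign(slope) * np.sqrt(max(ss_x, 0.0) / denom)
    df = len(x) - len(labels) - 1
    from scipy.stats import f as fdist
    if abs(r) >= 1:
        p = 0.0
    elif ss_err == 0 or ss_x <= 0:
        p = 1.0
    else:
        p = float(fdist.sf(ss_x / (ss_err / df), 1, df))
    return r, p, slope, df


def _profile(total, grid=None):
    grid = np.linspace(0, 100, len(total)) if grid is None else grid
    return MetabolicProfile(stride_grid=grid, sources={"all": total},
                            components={}, total=np.asarray(total, float))


class TestPercentChange:
    def test_identity_and_doubling(self):
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(10.0, 5.0) == 100.0

    def test_downhill_magnitude(self):
        assert percent_change(0.83, 1.0) == pytest.approx(-17.0)

    def test_levels(self):
        assert percent_of(0.83, 1.0) == pytest.approx(83.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)


class TestPhaseAverage:
    def test_constant_profile_shares_equal_durations(self):
        prof = _profile(np.full(1001, 2.0))
        means, shares = phase_average(prof, signals.CANONICAL_PHASES)
        np.testing.assert_allclose(means["ds1"], 2.0)
        assert shares["ds1"] == pytest.approx(15.0, abs=0.2)
        assert shares["ss"] == pytest.approx(35.0, abs=0.2)
        assert shares["ds2"] == pytest.approx(15.0, abs=0.2)
        assert shares["swing"] == pytest.approx(35.0, abs=0.2)

    def test_swing_only_profile(self):
        grid = np.linspace(0, 100, 1001)
        total = np.where(grid >= 65.0, 1.0, 0.0)
        _, shares = phase_average(_profile(total), signals.CANONICAL_PHASES)
        assert shares["swing"] == pytest.approx(100.0)

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(0)
        _, shares = phase_average(_profile(rng.uniform(0, 2, 501)),
                                  signals.CANONICAL_PHASES)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 201)
        b = rng.uniform(0, 1, 201)
        m_ab, _ = phase_average(_profile(a + b), signals.CANONICAL_PHASES)
        m_a, _ = phase_average(_profile(a), signals.CANONICAL_PHASES)
        m_b, _ = phase_average(_profile(b), signals.CANONICAL_PHASES)
        for ph in m_ab:
            assert m_ab[ph] == pytest.approx(m_a[ph] + m_b[ph])


class TestRmcorr:
    def test_perfect_within_subject_line(self):
        x = np.tile(np.arange(4.0), 3)
        y = 2 * x + np.repeat([10.0, 20.0, 30.0], 4)
        res = rmcorr(x, y, np.repeat(list("abc"), 4))
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p == 0.0
        assert res.df == 12 - 3 - 1

    def test_constant_y_within_subjects(self):
        x = np.tile(np.arange(3.0), 3)
        y = np.repeat([1.0, 2.0, 3.0], 3)
        res = rmcorr(x, y, np.repeat(list("abc"), 3))
        assert res.r == 0.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for n_subj in (2, 3, 4):
            for n_cond in (3, 4):
                for _ in range(5):
                    subj = np.repeat(np.arange(n_subj), n_cond)
                    x = rng.integers(-5, 6, n_subj * n_cond).astype(float)
                    while True:  # need within-subject x variation
                        xc = x - np.repeat(
                            x.reshape(n_subj, n_cond).mean(1), n_cond)
                        if np.sum(xc**2) > 0:
                            break
                        x = rng.integers(-5, 6, n_subj * n_cond).astype(float)
                    y = rng.integers(-5, 6, n_subj * n_cond).astype(float)
                    res = rmcorr(x, y, subj)
                    r, p, slope, df = brute_force_rmcorr(x, y, subj)
                    assert res.r == pytest.approx(r, abs=1e-9)
                    assert res.p == pytest.approx(p, abs=1e-9)
                    assert res.slope == pytest.approx(slope, abs=1e-9)
                    assert res.df == df

    def test_single_subject_reduces_to_pearson(self):
        from scipy.stats import pearsonr
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = 0.7 * x + rng.normal(scale=0.3, size=10)
        res = rmcorr(x, y, np.zeros(10))
        r_p, p_p = pearsonr(x, y)
        assert res.r == pytest.approx(r_p)
        assert res.p == pytest.approx(p_p, rel=1e-6)

    @given(shift=st.floats(-50, 50))
    def test_invariant_to_per_subject_offsets(self, shift):
        rng = np.random.default_rng(3)
        subj = np.repeat([0, 1, 2], 4)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = rmcorr(x, y, subj)
        shifted = rmcorr(x + shift * (subj == 1), y - shift * (subj == 2), subj)
        assert shifted.r == pytest.approx(base.r, abs=1e-9)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            rmcorr([1, 2], [1, 2], ["a", "b"])


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni([0.01], m=5), [0.05])
        np.testing.assert_allclose(bonferroni([0.5], m=8), [1.0])

    def test_order_preserved(self):
        p = np.array([0.001, 0.02, 0.2])
        adj = bonferroni(p)
        assert np.all(np.diff(adj) >= 0)


def _summaries(rng, n_subj=4, noise=0.0):
    """A synthetic comparison design with a shared latent condition effect."""
    out = []
    for i in range(n_subj):
        pid = f"P{i}"
        for cond in synthetic.STUDY_CONDITIONS:
            latent = 3.0 * synthetic.metabolic_scale(cond) * (1 + 0.05 * i)
            for method in ("musculoskeletal", "jointspace", "calorimetry"):
                val = latent * (1 + noise * rng.normal())
                phases = {ph: val * f * (1 + noise * rng.normal())
                          for ph, f in zip(stats.PHASES, (0.6, 1.6, 1.0, 0.8))}
                out.append(ConditionSummary(participant=pid, condition=cond,
                                            method=method, stride_average=val,
                                            phase_averages=phases))
    return out


class TestCompareMethods:
    def test_self_comparison_perfect(self):
        rng = np.random.default_rng(0)
        report = compare_methods(_summaries(rng, noise=0.0))
        for family in ("grade", "shoe"):
            for method in ("musculoskeletal", "jointspace"):
                assert report["stride_average"][family][method]["rmcorr"].r \
                    == pytest.approx(1.0)
        for cond in report["phase_profiles"].values():
            assert cond["rmcorr"].r == pytest.approx(1.0)

    def test_correlation_decreases_with_noise(self):
        rs = []
        for noise in (0.01, 0.2):
            rng = np.random.default_rng(42)
            rep = compare_methods(_summaries(rng, n_subj=6, noise=noise))
            rs.append(rep["stride_average"]["grade"]["musculoskeletal"]["rmcorr"].r)
        assert rs[1] < rs[0]

    def test_significance_threshold_is_005(self):
        rng = np.random.default_rng(1)
        rep = compare_methods(_summaries(rng, noise=0.0))
        assert rep["alpha"] == 0.05
        fam = rep["stride_average"]["grade"]["musculoskeletal"]
        assert fam["significant"] == (fam["rmcorr"].p <= 0.05)

    def test_unmatched_design_rejected(self):
        rng = np.random.default_rng(2)
        summaries = _summaries(rng)[:-1]  # drop one calorimetry cell
        with pytest.raises(ValueError, match="unmatched"):
            compare_methods(summaries)
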