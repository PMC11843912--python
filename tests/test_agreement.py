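import itertools
import math

import numpy as np
import pandas as pd
import pytest

from courtbeat.agreement import (
    bland_altman,
    cv_percent_rms,
    icc_3_1,
    mann_whitney,
    match_events,
    agreement_report,
    report_table,
    spearman_rho,
    weighted_kappa,
)


class TestMatchEvents:
    def test_detection_rate_86_25(self):
        """69 of 80 reference events matched gives 86.25%."""
        ref = np.arange(80) * 3.0
        det = ref[:69] + 0.005
        m = match_events(det, ref, tol_s=0.020)
        assert (m.true_positives, m.false_negatives, m.false_positives) == (69, 11, 0)
        assert m.detection_rate_pct == pytest.approx(86.25)

    def test_greedy_smallest_error_first(self):
        """One detection between two references pairs with the closer one."""
        m = match_events([1.004], [1.0, 1.01], tol_s=0.020)
        assert m.true_positives == 1
        assert m.matched_pairs == ((1.0, 1.004),)

    def test_one_to_one(self):
        """Two detections near one reference: only one matches."""
        m = match_events([0.995, 1.005], [1.0], tol_s=0.020)
        assert m.true_positives == 1
        assert m.false_positives == 1

    def test_tolerance_boundary(self):
        # offsets chosen to be exactly representable in binary floating point
        inside = match_events([1.015625], [1.0], tol_s=0.020)
        outside = match_events([1.03125], [1.0], tol_s=0.020)
        assert inside.true_positives == 1
        assert outside.true_positives == 0

    def test_empty_reference_rate_nan(self):
        m = match_events([1.0], [], tol_s=0.020)
        assert math.isnan(m.detection_rate_pct)


class TestCvPercent:
    def test_hand_example(self):
        """Single pair (0.80, 0.82): CV% = 100*0.02/(0.81*sqrt(2))."""
        expect = 100 * 0.02 / (0.81 * np.sqrt(2))
        assert cv_percent_rms([(0.80, 0.82)]) == pytest.approx(expect)

    def test_identical_pairs_zero(self):
        assert cv_percent_rms([(0.5, 0.5), (0.7, 0.7)]) == 0.0

    def test_zero_mean_pair_excluded(self):
        with pytest.warns(UserWarning, match="zero-mean"):
            out = cv_percent_rms([(0.80, 0.82), (-0.1, 0.1)])
        assert out == pytest.approx(cv_percent_rms([(0.80, 0.82)]))


class TestIcc:
    def test_against_pingouin(self):
        """ICC(3,1) value and CI match pingouin's ICC3 row."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        subj = rng.uniform(0.4, 1.2, 15)
        ref = subj + rng.normal(0, 0.02, 15)
        sys = subj + rng.normal(0.01, 0.02, 15)
        icc, ci = icc_3_1(np.column_stack([ref, sys]))

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": ["ref", "sys"] * 15,
                "score": np.column_stack([ref, sys]).ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        # two-way consistency, single rater: labeled ICC3 or ICC(C,1)
        key = "ICC3" if "ICC3" in table.index else "ICC(C,1)"
        expect = table.loc[key]
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        assert icc == pytest.approx(float(expect["ICC"]), abs=1e-9)
        # pingouin rounds the CI to two decimals
        assert ci[0] == pytest.approx(expect[ci_col][0], abs=6e-3)
        assert ci[1] == pytest.approx(expect[ci_col][1], abs=6e-3)

    def test_perfect_agreement(self):
        vals = [0.5, 0.7, 0.9, 1.1]
        icc, _ = icc_3_1([(v, v) for v in vals])
        assert icc == pytest.approx(1.0)

    def test_zero_subject_variance_nan(self):
        with pytest.warns(UserWarning, match="zero subject variance"):
            icc, _ = icc_3_1([(0.5, 0.5)] * 4)
        assert math.isnan(icc)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            icc_3_1([(0.5, 0.5), (0.6, 0.6)])


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        pairs = [(v, v) for v in np.linspace(0.4, 1.2, 12)]
        kappa, se = weighted_kappa(pairs)
        assert kappa == pytest.approx(1.0)
        assert se >= 0

    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        pairs = np.column_stack(
            [rng.uniform(0.4, 1.2, 400), rng.uniform(0.4, 1.2, 400)]
        )
        kappa, _ = weighted_kappa(pairs)
        assert abs(kappa) < 0.15

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.4, 1.2, 20)
        pairs = np.column_stack([base, base + rng.normal(0, 0.05, 20)])
        k1, _ = weighted_kappa(pairs)
        k2, _ = weighted_kappa(pairs[:, ::-1])
        assert k1 == pytest.approx(k2, abs=1e-9)

    def test_single_bin_undefined(self):
        with pytest.warns(UserWarning, match="single occupied bin"):
            kappa, _ = weighted_kappa([(0.500, 0.501), (0.502, 0.503)])
        assert math.isnan(kappa)


class TestBlandAltman:
    def test_hand_formulas(self):
        pairs = [(0.80, 0.84), (0.70, 0.72), (0.90, 0.91), (0.60, 0.65)]
        d = np.array([0.04, 0.02, 0.01, 0.05])
        ba = bland_altman(pairs)
        assert ba.mean_diff == pytest.approx(d.mean())
        assert ba.sd_diff == pytest.approx(d.std(ddof=1))
        assert ba.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert ba.ci_mean[0] < ba.mean_diff < ba.ci_mean[1]
        assert ba.ci_loa_lower[0] < ba.loa_lower < ba.ci_loa_lower[1]

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([(0.8, 0.82)])


class TestSpearman:
    def test_monotone_is_plus_one(self):
        pairs = [(x, x**3) for x in (0.1, 0.4, 0.9, 1.3, 2.0)]
        rho, p = spearman_rho(pairs)
        assert rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        pairs = [(x, -x) for x in (0.1, 0.4, 0.9, 1.3)]
        rho, _ = spearman_rho(pairs)
        assert rho == pytest.approx(-1.0)

    def test_constant_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_rho([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])
        assert math.isnan(rho)


def brute_force_mannwhitney(a, b):
    """Exact U statistic and two-sided p by full enumeration (no ties)."""
    a, b = np.asarray(a), np.asarray(b)
    u_obs = sum(x > y for x in a for y in b)
    combined = np.concatenate([a, b])
    n = len(a)
    stats = []
    for idx in itertools.combinations(range(len(combined)), n):
        ga = combined[list(idx)]
        gb = np.delete(combined, list(idx))
        stats.append(sum(x > y for x in ga for y in gb))
    stats = np.array(stats)
    mean_u = len(a) * len(b) / 2
    p = np.mean(np.abs(stats - mean_u) >= abs(u_obs - mean_u))
    return u_obs, float(p)


class TestMannWhitney:
    def test_exact_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.uniform(0, 1, 5)
            b = rng.uniform(0.2, 1.2, 6)
            u, p = mann_whitney(a, b)
            u_bf, p_bf = brute_force_mannwhitney(a, b)
            assert u == pytest.approx(u_bf)
            assert p == pytest.approx(p_bf, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestReport:
    def _pairs(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0.5, 1.1, 20)
        return np.column_stack([base, base + rng.normal(0.005, 0.01, 20)])

    def test_report_keys_and_consistency(self):
        pairs = self._pairs()
        report = agreement_report(pairs)
        assert report["n"] == 20
        assert report["cv_percent_rms"] == pytest.approx(cv_percent_rms(pairs))
        assert report["icc_3_1"] == pytest.approx(icc_3_1(pairs)[0])
        assert report["weighted_kappa"] == pytest.approx(weighted_kappa(pairs)[0])

    def test_shift_invariance_of_association(self):
        """Shifting both series by a constant leaves rank statistics alone."""
        pairs = self._pairs()
        shifted = pairs + 5.0
        assert spearman_rho(pairs)[0] == pytest.approx(spearman_rho(shifted)[0])
        assert icc_3_1(pairs)[0] == pytest.approx(icc_3_1(shifted)[0])

    def test_report_table_single_row(self):
        table = report_table(agreement_report(self._pairs()))
        assert len(table) == 1
        assert "ICC(3,1)" in table.columns
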