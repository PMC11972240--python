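"""ROC curves, Youden thresholds, AUC confidence intervals, and the
maximum-likelihood combination of two curves."""

import numpy as np
import pytest

import foragekit as fk
from foragekit.roc import OperatingPoint, RocCurve, _combine_independence


def mann_whitney_auc(values, labels):
    """Independent oracle: explicit pair counting (ties get half credit),
    with 'leave' predicted above the threshold."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    leave = values[labels == "leave"]
    stay = values[labels == "stay"]
    wins = sum(
        1.0 if l > s else (0.5 if l == s else 0.0) for l in leave for s in stay
    )
    return wins / (len(leave) * len(stay))


def random_dataset(rng, n_max=30):
    n = int(rng.integers(4, n_max))
    values = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)  # ties likely
    labels = np.where(rng.random(n) < 0.5, "leave", "stay")
    if (labels == "leave").all() or (labels == "stay").all():
        labels[0] = "leave"
        labels[1] = "stay"
    return values, labels


class TestRocCurve:
    def test_perfect_separation_below_gives_auc_one(self):
        values = [0.1, 0.2, 0.3, 0.9, 1.0, 1.1]
        labels = ["leave"] * 3 + ["stay"] * 3
        assert fk.roc_curve(values, labels, "below").auc == pytest.approx(1.0)

    def test_hand_counted_four_pair_example(self):
        curve = fk.roc_curve([2, 3, 1, 2.5], ["leave", "leave", "stay", "stay"],
                             "above")
        assert curve.auc == pytest.approx(0.75)

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.2, "leave", "stay")
        assert fk.roc_curve(values, labels, "below").auc == pytest.approx(0.5,
                                                                          abs=0.04)

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            values, labels = random_dataset(rng)
            curve = fk.roc_curve(values, labels, "above")
            assert curve.auc == pytest.approx(
                mann_whitney_auc(values, labels), abs=1e-12
            )

    def test_auto_polarity_never_below_half(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            values, labels = random_dataset(rng)
            assert fk.roc_curve(values, labels, "auto").auc >= 0.5 - 1e-12

    def test_curve_endpoints_span_the_unit_square(self):
        values, labels = random_dataset(np.random.default_rng(5))
        curve = fk.roc_curve(values, labels, "below")
        first, last = curve.points[0], curve.points[-1]
        assert (first.sensitivity, first.specificity) == (0.0, 1.0)
        assert (last.sensitivity, last.specificity) == (1.0, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fk.roc_curve([1, 2, 3], ["stay", "stay", "stay"], "below")

    def test_monotone_transform_leaves_curve_invariant(self):
        rng = np.random.default_rng(33)
        values = rng.normal(size=300)
        labels = np.where(rng.random(300) < 0.3 * (1 + np.tanh(values)), "leave",
                          "stay")
        a = fk.roc_curve(values, labels, "above")
        b = fk.roc_curve(np.exp(values), labels, "above")
        assert b.auc == pytest.approx(a.auc, abs=1e-12)
        ya, yb = fk.youden_optimal(a), fk.youden_optimal(b)
        assert yb.j == pytest.approx(ya.j, abs=1e-12)
        assert yb.point.threshold == pytest.approx(
            np.exp(ya.point.threshold), rel=1e-3
        )


class TestAucTrapezoid:
    def test_perfect_point(self):
        assert fk.auc_trapezoid([OperatingPoint(1.0, 1.0)]) == pytest.approx(1.0)

    def test_chance_point(self):
        assert fk.auc_trapezoid([OperatingPoint(0.5, 0.5)]) == pytest.approx(0.5)

    def test_two_point_hand_sum(self):
        # FPR path 0 → 0.2 → 0.4 → 1: 0.08 + 0.17 + 0.57
        pts = [OperatingPoint(0.8, 0.8), OperatingPoint(0.9, 0.6)]
        assert fk.auc_trapezoid(pts) == pytest.approx(0.82)

    def test_matches_roc_curve_auc_on_own_points(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            values, labels = random_dataset(rng)
            curve = fk.roc_curve(values, labels, "below")
            assert fk.auc_trapezoid(curve.points) == pytest.approx(curve.auc,
                                                                   abs=1e-12)


class TestYouden:
    def _curve(self, pts):
        return RocCurve(points=pts, polarity="below", auc=0.5, n_leave=5, n_stay=5)

    def test_perfect_point_wins(self):
        res = fk.youden_optimal(
            self._curve([OperatingPoint(0.4, 0.9), OperatingPoint(1.0, 1.0)])
        )
        assert res.j == pytest.approx(1.0)
        assert res.point.sensitivity == 1.0

    def test_identity_line_ties_break_to_sensitive(self):
        pts = [OperatingPoint(s, 1 - s) for s in (0.0, 0.3, 0.7, 1.0)]
        res = fk.youden_optimal(self._curve(pts))
        assert res.j == pytest.approx(0.0)
        assert res.point.sensitivity == 1.0

    def test_direct_comparison(self):
        res = fk.youden_optimal(
            self._curve([OperatingPoint(0.9, 0.6), OperatingPoint(0.7, 0.75)])
        )
        assert res.point == OperatingPoint(0.9, 0.6)
        assert res.j == pytest.approx(0.5)


class TestDelongCI:
    def test_perfect_separation_zero_width(self):
        values = np.concatenate([np.zeros(200), np.ones(200) + 1])
        labels = ["stay"] * 200 + ["leave"] * 200
        auc, (lo, hi) = fk.delong_ci(values, labels)
        assert auc == 1.0
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_mirrors_interval(self):
        rng = np.random.default_rng(44)
        values = rng.normal(size=100)
        labels = np.where(rng.random(100) < 0.4, "leave", "stay")
        auc, (lo, hi) = fk.delong_ci(values, labels)
        swapped = np.where(labels == "leave", "stay", "leave")
        auc2, (lo2, hi2) = fk.delong_ci(values, swapped)
        assert auc2 == pytest.approx(1 - auc)
        assert lo2 == pytest.approx(1 - hi, abs=1e-12)
        assert hi2 == pytest.approx(1 - lo, abs=1e-12)

    def test_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(55)
        n = 200
        labels = np.where(rng.random(n) < 0.35, "leave", "stay")
        values = rng.normal(size=n) + 1.0 * (labels == "leave")
        auc, (lo, hi) = fk.delong_ci(values, labels)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            vl, ll = values[idx], labels[idx]
            if (ll == "leave").all() or (ll == "stay").all():
                continue
            boots.append(mann_whitney_auc(vl, ll))
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        assert lo == pytest.approx(blo, abs=0.02)
        assert hi == pytest.approx(bhi, abs=0.02)


class TestHanleyMcNeil:
    def test_plug_in_arithmetic_at_half(self):
        # A = 0.5 ⇒ Q1 = Q2 = 1/3; SE² = 0.0175 with 10 per class
        lo, hi = fk.hanley_mcneil_ci(0.5, 10, 10)
        se = np.sqrt(0.0175)
        z = 1.959963984540054
        assert lo == pytest.approx(0.5 - z * se, abs=1e-9)
        assert hi == pytest.approx(0.5 + z * se, abs=1e-9)

    def test_se_shrinks_with_more_leavers(self):
        from foragekit.roc import hanley_mcneil_se

        ses = [hanley_mcneil_se(0.7, n, 50) for n in (5, 20, 80, 320)]
        assert all(b < a for a, b in zip(ses, ses[1:]))


def single_point_curve(se, sp, thr=0.0, n=50):
    return RocCurve(
        points=[OperatingPoint(se, sp, thr)],
        polarity="below",
        auc=(se + sp) / 2,
        n_leave=n,
        n_stay=n,
        predictor="X",
    )


class TestCombineRocMl:
    def test_enumerated_or_and_points_at_eighty_percent(self):
        a = single_point_curve(0.8, 0.8)
        b = single_point_curve(0.8, 0.8)
        combined = fk.combine_roc_ml(a, b)
        achieved = {
            (round(p.sensitivity, 6), round(p.specificity, 6))
            for p in combined.points
        }
        assert (0.96, 0.64) in achieved  # OR rule
        assert (0.64, 0.96) in achieved  # AND rule

    @staticmethod
    def _useless(n_leave, n_stay, k=21):
        return RocCurve(
            points=[OperatingPoint(s, 1 - s, s) for s in np.linspace(0, 1, k)],
            polarity="below",
            auc=0.5,
            n_leave=n_leave,
            n_stay=n_stay,
            predictor="noise",
        )

    def test_useless_partner_adds_nothing_to_concave_curve(self):
        informative = single_point_curve(0.7, 0.9)
        combined = fk.combine_roc_ml(informative, self._useless(50, 50))
        assert combined.auc == pytest.approx(
            fk.auc_trapezoid(informative.points), abs=1e-9
        )

    def test_useless_partner_bounded_by_convex_hull(self):
        """Pairing with a chance-level test can only realize randomized
        mixtures of the informative curve's own operating points, so the
        combined AUC sits between the trapezoid AUC and the convex-hull
        AUC of the informative curve."""
        rng = np.random.default_rng(60)
        values = rng.normal(size=500)
        labels = np.where(rng.random(500) < 0.3 * (1 + np.tanh(values)), "leave",
                          "stay")
        informative = fk.roc_curve(values, labels, "above", "inf")
        combined = fk.combine_roc_ml(
            informative, self._useless(informative.n_leave, informative.n_stay)
        )
        pts = sorted(
            [(1 - p.specificity, p.sensitivity) for p in informative.points]
            + [(0.0, 0.0), (1.0, 1.0)]
        )
        hull = [pts[0]]
        for p in pts[1:]:  # upper convex chain in (fpr, sens)
            while len(hull) >= 2 and (
                (hull[-1][0] - hull[-2][0]) * (p[1] - hull[-2][1])
                - (hull[-1][1] - hull[-2][1]) * (p[0] - hull[-2][0])
            ) >= 0:
                hull.pop()
            hull.append(p)
        hull_auc = np.trapezoid([h[1] for h in hull], [h[0] for h in hull])
        assert informative.auc - 1e-9 <= combined.auc <= hull_auc + 1e-9

    def test_combined_dominates_both_parents(self):
        rng = np.random.default_rng(61)
        n = 1500
        leave = rng.random(n) < 0.3
        a = rng.normal(size=n) + 1.1 * leave
        b = rng.normal(size=n) + 0.9 * leave
        labels = np.where(leave, "leave", "stay")
        ca = fk.roc_curve(a, labels, "above", "A")
        cb = fk.roc_curve(b, labels, "above", "B")
        combined = fk.combine_roc_ml(ca, cb)
        assert combined.auc >= max(ca.auc, cb.auc) - 0.01
        assert combined.ci is not None and combined.ci[0] < combined.auc < combined.ci[1]

    def test_envelope_points_are_non_dominated(self):
        a = single_point_curve(0.7, 0.9, 1.0)
        b = single_point_curve(0.6, 0.8, 2.0)
        entries = _combine_independence(a, b, "A", "B", max_points=21)
        combined = fk.combine_roc_ml(a, b, max_points=21)
        for p in combined.points:
            for fpr, sens, _ in entries:
                strictly_better = (
                    fpr < (1 - p.specificity) - 1e-9 and sens > p.sensitivity + 1e-9
                )
                assert not strictly_better

    def test_empirical_mode_matches_data_level_rules(self):
        rng = np.random.default_rng(62)
        n = 400
        leave = rng.random(n) < 0.4
        a = rng.normal(size=n) - 1.0 * leave
        b = rng.normal(size=n) - 1.0 * leave
        labels = np.where(leave, "leave", "stay")
        ca = fk.roc_curve(a, labels, "below", "A")
        cb = fk.roc_curve(b, labels, "below", "B")
        combined = fk.combine_roc_ml(
            ca, cb, mode="empirical", values_a=a, values_b=b, labels=labels,
            max_points=61,
        )
        best = fk.youden_optimal_rule(combined)
        assert best.rule is not None
        # re-evaluate the printed rule directly on the data
        pa = a < best.rule.threshold_a
        pb = b < best.rule.threshold_b
        pred = pa & pb if best.rule.connective == "AND" else (
            pa | pb if best.rule.connective == "OR" else
            (pa if best.rule.connective == "A" else pb)
        )
        sens = (pred & leave).sum() / leave.sum()
        spec = (~pred & ~leave).sum() / (~leave).sum()
        assert sens == pytest.approx(best.rule.sensitivity, abs=1e-12)
        assert spec == pytest.approx(best.rule.specificity, abs=1e-12)

    def test_mismatched_decision_sets_rejected(self):
        a = single_point_curve(0.8, 0.8, n=50)
        b = single_point_curve(0.8, 0.8, n=60)
        with pytest.raises(ValueError):
            fk.combine_roc_ml(a, b)
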