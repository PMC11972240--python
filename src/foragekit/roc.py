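"""ROC analysis of stay/leave decisions.

The positive class throughout is *leave*: sensitivity is the proportion
of leaving decisions correctly predicted, specificity the proportion of
staying decisions correctly predicted.  A predictor's ROC curve sweeps a
threshold over its values (midpoints between adjacent distinct values,
plus ±∞ sentinels) and records the (sensitivity, specificity) pair at
each; the area under the curve (AUC) equals the Mann–Whitney concordance
probability.  The Youden index J = sensitivity + specificity − 1 picks
the optimal operating point.

Two curves built on the same decision set can be combined into a single
compound leaving criterion.  Under class-conditional independence, each
pair of operating points (one per predictor) induces four joint test
outcomes with known class-conditional probabilities; sweeping a
likelihood-ratio threshold over those outcomes generates every achievable
(sensitivity, specificity) point, whose upper-left Pareto envelope is the
combined curve.  Envelope points realized by thresholding both predictors
correspond to AND/OR compound rules such as ``composite < −0.1 OR RIAIR
< 0.5``.  Confidence intervals: DeLong for single empirical curves,
Hanley–McNeil for combined curves (which have no per-decision scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

LEAVE, STAY = "leave", "stay"


@dataclass(frozen=True)
class OperatingPoint:
    sensitivity: float
    specificity: float
    threshold: float | None = None
    rule: str | None = None


@dataclass
class CompoundRule:
    """AND/OR combination of two single-predictor threshold tests."""

    name_a: str
    threshold_a: float
    direction_a: str  # "below" | "above"
    name_b: str
    threshold_b: float
    direction_b: str
    connective: str  # "AND" | "OR" | "A" | "B"
    sensitivity: float
    specificity: float

    def __str__(self) -> str:
        def fmt(t):
            return f"{t:.4g}" if t is not None else "?"

        def vacuous(thr, direction):  # condition true for every value
            return thr is not None and (
                (direction == "below" and thr == math.inf)
                or (direction == "above" and thr == -math.inf)
            )

        def impossible(thr, direction):
            return thr is not None and (
                (direction == "below" and thr == -math.inf)
                or (direction == "above" and thr == math.inf)
            )

        opa = "<" if self.direction_a == "below" else ">"
        opb = "<" if self.direction_b == "below" else ">"
        a = f"{self.name_a} {opa} {fmt(self.threshold_a)}"
        b = f"{self.name_b} {opb} {fmt(self.threshold_b)}"
        if self.connective == "A":
            return a
        if self.connective == "B":
            return b
        if self.connective == "AND":
            if vacuous(self.threshold_a, self.direction_a):
                return b
            if vacuous(self.threshold_b, self.direction_b):
                return a
            if impossible(self.threshold_a, self.direction_a) or impossible(
                self.threshold_b, self.direction_b
            ):
                return "never"
        if self.connective == "OR":
            if impossible(self.threshold_a, self.direction_a):
                return b
            if impossible(self.threshold_b, self.direction_b):
                return a
            if vacuous(self.threshold_a, self.direction_a) or vacuous(
                self.threshold_b, self.direction_b
            ):
                return "always"
        return f"{a} {self.connective} {b}"


@dataclass
class RocCurve:
    points: list[OperatingPoint]
    polarity: str  # "below": leave predicted when value < threshold
    auc: float
    n_leave: int
    n_stay: int
    predictor: str = ""
    ci: tuple[float, float] | None = None
    ci_method: str = ""
    ci_level: float = 0.95
    rules: list[CompoundRule] = field(default_factory=list)


@dataclass(frozen=True)
class YoudenResult:
    j: float
    point: OperatingPoint
    rule: CompoundRule | None = None


def _as_leave_mask(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return arr == LEAVE
    return arr.astype(bool)


def roc_curve(
    values,
    labels,
    polarity: str = "auto",
    predictor: str = "",
) -> RocCurve:
    """Empirical ROC curve of one predictor against stay/leave labels.

    ``polarity="below"`` predicts *leave* when the value is below the
    threshold (the convention for the composite, best-r and RIAIR, all of
    which drop before leaving); ``"above"`` predicts leave above it (mean
    ITD, PAO, intersection rate); ``"auto"`` picks whichever direction
    gives AUC ≥ 0.5.  Thresholds are the midpoints between adjacent
    distinct sorted values plus ±∞ sentinels, so every achievable
    confusion table appears exactly once.
    """
    values = np.asarray(values, dtype=float)
    leave_mask = _as_leave_mask(labels)
    if len(values) != len(leave_mask):
        raise ValueError("values and labels length mismatch")
    n_leave = int(leave_mask.sum())
    n_stay = int(len(values) - n_leave)
    if n_leave == 0 or n_stay == 0:
        raise ValueError("both stay and leave decisions are required")

    if polarity == "auto":
        below = roc_curve(values, labels, "below", predictor)
        if below.auc >= 0.5:
            return below
        return roc_curve(values, labels, "above", predictor)
    if polarity not in ("below", "above"):
        raise ValueError(f"unknown polarity {polarity!r}")

    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    leave_sorted = np.sort(values[leave_mask])
    stay_sorted = np.sort(values[~leave_mask])
    below_leave = np.searchsorted(leave_sorted, thresholds, side="left")
    below_stay = np.searchsorted(stay_sorted, thresholds, side="left")
    if polarity == "below":
        sens = below_leave / n_leave
        spec = 1.0 - below_stay / n_stay
        order = np.arange(len(thresholds))
    else:
        sens = 1.0 - below_leave / n_leave
        spec = below_stay / n_stay
        order = np.arange(len(thresholds))[::-1]

    points = [
        OperatingPoint(float(sens[i]), float(spec[i]), float(thresholds[i]))
        for i in order
    ]
    auc = auc_trapezoid(points)
    return RocCurve(
        points=points,
        polarity=polarity,
        auc=auc,
        n_leave=n_leave,
        n_stay=n_stay,
        predictor=predictor,
    )


def auc_trapezoid(points) -> float:
    """Trapezoid-rule AUC over (sensitivity, specificity) points.

    Points are mapped into (false-positive rate, sensitivity) space,
    augmented with the corners (0, 0) and (1, 1), sorted, and integrated.
    """
    pts = [(1.0 - p.specificity, p.sensitivity) for p in points]
    pts += [(0.0, 0.0), (1.0, 1.0)]
    pts.sort()
    fpr = np.array([p[0] for p in pts])
    sens = np.array([p[1] for p in pts])
    return float(np.trapezoid(sens, fpr))


def youden_optimal(curve: RocCurve) -> YoudenResult:
    """Operating point maximizing J = sensitivity + specificity − 1.

    Ties (within float tolerance) are broken toward the more sensitive
    point, i.e. the rule that catches more leaving decisions.
    """
    if not curve.points:
        raise ValueError("empty ROC curve")
    best = max(
        curve.points,
        key=lambda p: (round(p.sensitivity + p.specificity, 12), p.sensitivity),
    )
    rule = None
    if curve.rules:
        for r in curve.rules:
            if (
                abs(r.sensitivity - best.sensitivity) < 1e-12
                and abs(r.specificity - best.specificity) < 1e-12
            ):
                rule = r
                break
    return YoudenResult(
        j=best.sensitivity + best.specificity - 1.0, point=best, rule=rule
    )


def youden_optimal_rule(curve: RocCurve) -> YoudenResult:
    """Youden-optimal point restricted to operating points realized by an
    explicit single/AND/OR rule (combined curves may contain envelope
    points achievable only by randomized likelihood-ratio tests; reports
    should quote a deterministic rule).  Falls back to
    :func:`youden_optimal` when the curve carries no rule annotations."""
    if not curve.rules:
        return youden_optimal(curve)
    best = max(
        curve.rules,
        key=lambda r: (round(r.sensitivity + r.specificity, 12), r.sensitivity),
    )
    return YoudenResult(
        j=best.sensitivity + best.specificity - 1.0,
        point=OperatingPoint(best.sensitivity, best.specificity, rule=str(best)),
        rule=best,
    )


def delong_ci(values, labels, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC and DeLong confidence interval for one empirical predictor.

    Uses placement values (midranks, so ties get half credit); the AUC
    returned is identical to the Mann–Whitney estimate.  Convention:
    higher value ⇒ leave, so callers with a "below" polarity should pass
    the negated predictor.
    """
    values = np.asarray(values, dtype=float)
    leave_mask = _as_leave_mask(labels)
    x = values[leave_mask]  # positive class
    y = values[~leave_mask]
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("DeLong CI needs at least 2 decisions per class")
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    v01 = (all_ranks[:m] - rx) / n  # placement of each leave among stays
    v10 = 1.0 - (all_ranks[m:] - ry) / m
    auc = float(v01.mean())
    var = v01.var(ddof=1) / m + v10.var(ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def hanley_mcneil_se(auc: float, n_leave: int, n_stay: int) -> float:
    """Hanley–McNeil standard error of an AUC from class counts alone."""
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1 - a)
        + (n_leave - 1) * (q1 - a * a)
        + (n_stay - 1) * (q2 - a * a)
    ) / (n_leave * n_stay)
    return math.sqrt(max(var, 0.0))


def hanley_mcneil_ci(
    auc: float, n_leave: int, n_stay: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation CI with the Hanley–McNeil SE, clipped to [0, 1].

    Suited to combined curves, where no per-decision score exists and the
    placement-based DeLong variance is unavailable.
    """
    if n_leave < 1 or n_stay < 1:
        raise ValueError("class counts must be positive")
    se = hanley_mcneil_se(auc, n_leave, n_stay)
    z = stats.norm.ppf(0.5 + level / 2)
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def _thin_points(points: list[OperatingPoint], max_points: int) -> list[OperatingPoint]:
    if len(points) <= max_points:
        return points
    idx = np.unique(np.linspace(0, len(points) - 1, max_points).round().astype(int))
    return [points[i] for i in idx]


def _pareto_envelope(entries):
    """Upper-left Pareto front over (fpr, sens, payload) entries."""
    entries = sorted(entries, key=lambda e: (e[0], -e[1]))
    front = []
    best_sens = -1.0
    for e in entries:
        if e[1] > best_sens + 1e-12:
            front.append(e)
            best_sens = e[1]
    return front


# joint outcomes: 0 = A+B+, 1 = A+B-, 2 = A-B+, 3 = A-B-.  Every union of
# outcomes that is expressible as a deterministic single/AND/OR rule over
# the two threshold tests (possibly with a direction flipped) maps to its
# (connective, flip_a, flip_b); XOR-type sets map to nothing.
_RULE_SETS = {
    frozenset({0}): ("AND", False, False),
    frozenset({1}): ("AND", False, True),
    frozenset({2}): ("AND", True, False),
    frozenset({3}): ("AND", True, True),
    frozenset({0, 1}): ("A", False, False),
    frozenset({2, 3}): ("A", True, False),
    frozenset({0, 2}): ("B", False, False),
    frozenset({1, 3}): ("B", False, True),
    frozenset({0, 1, 2}): ("OR", False, False),
    frozenset({0, 1, 3}): ("OR", False, True),
    frozenset({0, 2, 3}): ("OR", True, False),
    frozenset({1, 2, 3}): ("OR", True, True),
}

_FLIP = {"below": "above", "above": "below"}


def combine_roc_ml(
    curve_a: RocCurve,
    curve_b: RocCurve,
    mode: str = "independence",
    values_a=None,
    values_b=None,
    labels=None,
    max_points: int = 201,
    ci_level: float = 0.95,
) -> RocCurve:
    """Combine two ROC curves into one compound leaving criterion.

    ``mode="independence"`` is the maximum-likelihood construction: for
    every pair of operating points, the four joint outcomes (predict
    leave on both, on A only, on B only, on neither) have known
    class-conditional probabilities under conditional independence; the
    likelihood-ratio sweep over those outcomes yields all achievable
    (sensitivity, specificity) points, and the combined curve is their
    upper-left Pareto envelope.  ``mode="empirical"`` evaluates AND/OR
    rules directly on the raw predictor values over a threshold grid and
    takes the same envelope; it requires ``values_a``, ``values_b`` and
    ``labels`` and makes no independence assumption.

    Both curves must come from the same decision set.  AUC is computed by
    the trapezoid rule over the envelope; the CI is Hanley–McNeil.
    """
    if (curve_a.n_leave, curve_a.n_stay) != (curve_b.n_leave, curve_b.n_stay):
        raise ValueError("curves were not built on the same decision set")
    name_a = curve_a.predictor or "A"
    name_b = curve_b.predictor or "B"

    if mode == "independence":
        entries = _combine_independence(
            curve_a, curve_b, name_a, name_b, max_points
        )
    elif mode == "empirical":
        if values_a is None or values_b is None or labels is None:
            raise ValueError("empirical mode requires raw values and labels")
        entries = _combine_empirical(
            curve_a, curve_b, values_a, values_b, labels, name_a, name_b, max_points
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    front = _pareto_envelope(entries)
    points, rules = [], []
    for fpr, sens, rule in front:
        pt = OperatingPoint(
            sensitivity=sens, specificity=1.0 - fpr, rule=str(rule) if rule else None
        )
        points.append(pt)
        if rule is not None:
            rules.append(rule)
    auc = auc_trapezoid(points)
    ci = hanley_mcneil_ci(auc, curve_a.n_leave, curve_a.n_stay, ci_level)
    return RocCurve(
        points=points,
        polarity="compound",
        auc=auc,
        n_leave=curve_a.n_leave,
        n_stay=curve_a.n_stay,
        predictor=f"{name_a}+{name_b}",
        ci=ci,
        ci_method="hanley-mcneil",
        ci_level=ci_level,
        rules=rules,
    )


def _combine_independence(curve_a, curve_b, name_a, name_b, max_points):
    pts_a = _thin_points(curve_a.points, max_points)
    pts_b = _thin_points(curve_b.points, max_points)
    entries = []
    for pa in pts_a:
        se1, sp1 = pa.sensitivity, pa.specificity
        for pb in pts_b:
            se2, sp2 = pb.sensitivity, pb.specificity
            # joint outcomes: 0 = A+B+, 1 = A+B-, 2 = A-B+, 3 = A-B-
            p_pos = np.array(
                [se1 * se2, se1 * (1 - se2), (1 - se1) * se2, (1 - se1) * (1 - se2)]
            )
            p_neg = np.array(
                [(1 - sp1) * (1 - sp2), (1 - sp1) * sp2, sp1 * (1 - sp2), sp1 * sp2]
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                lr = np.where(p_neg > 0, p_pos / np.maximum(p_neg, 1e-300), np.inf)
                lr[(p_pos == 0) & (p_neg == 0)] = 0.0
            order = np.argsort(-lr, kind="stable")
            sens_cum = 0.0
            fpr_cum = 0.0
            taken: set[int] = set()
            for o in order:
                sens_cum += p_pos[o]
                fpr_cum += p_neg[o]
                taken.add(int(o))
                spec = _RULE_SETS.get(frozenset(taken))
                rule = None
                if spec is not None:
                    conn, flip_a, flip_b = spec
                    dir_a = curve_a.polarity
                    dir_b = curve_b.polarity
                    rule = CompoundRule(
                        name_a=name_a,
                        threshold_a=pa.threshold,
                        direction_a=_FLIP[dir_a] if flip_a else dir_a,
                        name_b=name_b,
                        threshold_b=pb.threshold,
                        direction_b=_FLIP[dir_b] if flip_b else dir_b,
                        connective=conn,
                        sensitivity=sens_cum,
                        specificity=1.0 - fpr_cum,
                    )
                entries.append((fpr_cum, sens_cum, rule))
    return entries


def _leave_prediction(values, threshold, polarity):
    values = np.asarray(values, dtype=float)
    if polarity == "below":
        return values < threshold
    return values > threshold


def _combine_empirical(
    curve_a, curve_b, values_a, values_b, labels, name_a, name_b, max_points
):
    leave_mask = _as_leave_mask(labels)
    n_leave = int(leave_mask.sum())
    n_stay = int(len(leave_mask) - n_leave)
    thr_a = [
        p.threshold for p in _thin_points(curve_a.points, max_points)
        if p.threshold is not None and np.isfinite(p.threshold)
    ]
    thr_b = [
        p.threshold for p in _thin_points(curve_b.points, max_points)
        if p.threshold is not None and np.isfinite(p.threshold)
    ]
    A = np.stack(
        [_leave_prediction(values_a, t, curve_a.polarity) for t in thr_a]
    ).astype(float)  # (P, n)
    B = np.stack(
        [_leave_prediction(values_b, t, curve_b.polarity) for t in thr_b]
    ).astype(float)
    Al, As = A[:, leave_mask], A[:, ~leave_mask]
    Bl, Bs = B[:, leave_mask], B[:, ~leave_mask]
    and_sens = (Al @ Bl.T) / n_leave  # (P, Q)
    and_fpr = (As @ Bs.T) / n_stay
    sens_a = Al.mean(axis=1)[:, None]
    fpr_a = As.mean(axis=1)[:, None]
    sens_b = Bl.mean(axis=1)[None, :]
    fpr_b = Bs.mean(axis=1)[None, :]
    or_sens = sens_a + sens_b - and_sens
    or_fpr = fpr_a + fpr_b - and_fpr
    entries = []
    for i, ta in enumerate(thr_a):
        for j, tb in enumerate(thr_b):
            for conn, s, f in (
                ("AND", and_sens[i, j], and_fpr[i, j]),
                ("OR", or_sens[i, j], or_fpr[i, j]),
            ):
                rule = CompoundRule(
                    name_a=name_a,
                    threshold_a=ta,
                    direction_a=curve_a.polarity,
                    name_b=name_b,
                    threshold_b=tb,
                    direction_b=curve_b.polarity,
                    connective=conn,
                    sensitivity=float(s),
                    specificity=1.0 - float(f),
                )
                entries.append((float(f), float(s), rule))
    # single-predictor points are achievable too
    for p in curve_a.points:
        entries.append((1.0 - p.specificity, p.sensitivity, None))
    for p in curve_b.points:
        entries.append((1.0 - p.specificity, p.sensitivity, None))
    return entries
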