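"""Composite organization variables via standardization and PCA.

The four organization indicators share most of their variance: a single
latent "search organization" dimension accounts for them well.  This
module (a) checks that one-dimensionality with Horn's parallel analysis
and a correlation-matrix PCA on end-of-trial indicator values (one row
per trial, to keep observations independent), and (b) builds composite
variables from the standardized trial-so-far indicator series:

    C_w = w_br·z_br − w_itd·z_itd − w_pao·z_pao − w_int·z_int

Mean ITD, PAO and the intersection rate enter negatively because lower
values mean higher organization; best-r enters positively.  The weights
are the magnitudes of the first principal component's loadings (the sign
structure is hard-coded above, so only magnitudes are used), or all 1 for
the unweighted composite C_u.

Standardization statistics are computed over all trial-so-far instances
of the analysis stratum, per the pipeline's declared population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INDICATORS = ["best_r", "mean_itd", "pao", "intersection_rate"]

#: Eq.-style sign each indicator carries in the composite sum.
COMPOSITE_SIGNS = {
    "best_r": +1.0,
    "mean_itd": -1.0,
    "pao": -1.0,
    "intersection_rate": -1.0,
}


@dataclass
class StandardizationStats:
    """Per-indicator mean/sd over a declared population of instances."""

    mean: dict[str, float]
    sd: dict[str, float]
    stratum: str = ""
    n_instances: int = 0

    @classmethod
    def fit(cls, table: pd.DataFrame, stratum: str = "") -> "StandardizationStats":
        """Moments over all (non-degenerate) trial-so-far instances."""
        clean = table[INDICATORS].dropna()
        mean, sd = {}, {}
        for col in INDICATORS:
            m = float(clean[col].mean())
            s = float(clean[col].std(ddof=1))
            if not np.isfinite(s) or s == 0.0:
                raise ValueError(
                    f"indicator {col!r} has zero variance in stratum {stratum!r}"
                )
            mean[col], sd[col] = m, s
        return cls(mean=mean, sd=sd, stratum=stratum, n_instances=len(clean))


def standardize(table: pd.DataFrame, stats: StandardizationStats) -> pd.DataFrame:
    """z-score the four indicator columns; other columns pass through."""
    out = table.copy()
    for col in INDICATORS:
        out["z_" + col] = (table[col] - stats.mean[col]) / stats.sd[col]
    return out


@dataclass
class PcaResult:
    """First-component summary of the 4×4 indicator correlation matrix."""

    eigenvalues: np.ndarray
    loadings: dict[str, float]  # eigenvector × sqrt(λ1), best_r oriented +
    variance_explained_pct: float
    n_trials: int
    adjusted_eigenvalues: np.ndarray | None = None
    n_retained: int | None = None


def _corr_eigen(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    corr = np.corrcoef(data, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pca_first_component(end_of_trial: pd.DataFrame) -> PcaResult:
    """Correlation-matrix PCA on end-of-trial indicator values.

    One row per trial.  Loadings are the first eigenvector scaled by
    √λ₁, oriented so the best-r loading is positive (the component's
    sign is otherwise arbitrary).  Variance explained is 100·λ₁/p.
    """
    data = end_of_trial[INDICATORS].dropna().to_numpy(dtype=float)
    if data.shape[0] < data.shape[1]:
        raise ValueError("need at least as many trials as indicators")
    if np.any(np.ptp(data, axis=0) == 0):
        const = [c for i, c in enumerate(INDICATORS) if np.ptp(data[:, i]) == 0]
        raise ValueError(f"constant indicator column(s): {const}")
    vals, vecs = _corr_eigen(data)
    v1 = vecs[:, 0]
    if v1[INDICATORS.index("best_r")] < 0:
        v1 = -v1
    loadings = dict(zip(INDICATORS, v1 * np.sqrt(vals[0])))
    return PcaResult(
        eigenvalues=vals,
        loadings={k: float(v) for k, v in loadings.items()},
        variance_explained_pct=float(100.0 * vals[0] / len(INDICATORS)),
        n_trials=data.shape[0],
    )


def parallel_analysis(
    end_of_trial: pd.DataFrame,
    reps: int = 500,
    seed: int = 0,
) -> PcaResult:
    """Horn's parallel analysis for component retention.

    Observed correlation-matrix eigenvalues are adjusted by subtracting
    the over-chance inflation measured on ``reps`` standard-normal
    datasets of identical shape: adjusted λ_k = λ_k − (mean random
    λ_k − 1).  Components with adjusted eigenvalue > 1 are retained.
    Deterministic given ``seed``.
    """
    data = end_of_trial[INDICATORS].dropna().to_numpy(dtype=float)
    n, p = data.shape
    if n < p:
        raise ValueError("need at least as many rows as columns")
    if reps < 100:
        raise ValueError("parallel analysis needs reps >= 100")
    result = pca_first_component(end_of_trial)
    rng = np.random.default_rng(seed)
    rand_vals = np.empty((reps, p))
    for r in range(reps):
        sim = rng.standard_normal((n, p))
        rand_vals[r] = _corr_eigen(sim)[0]
    adjusted = result.eigenvalues - (rand_vals.mean(axis=0) - 1.0)
    result.adjusted_eigenvalues = adjusted
    # sequential stopping: retain leading components while adjusted λ > 1
    retained = 0
    for lam in adjusted:
        if lam > 1.0:
            retained += 1
        else:
            break
    result.n_retained = retained
    return result


@dataclass
class CompositeWeights:
    """Non-negative weights for the four indicators."""

    weights: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in INDICATORS}
    )

    @classmethod
    def from_pca(cls, pca: PcaResult) -> "CompositeWeights":
        """Weights as magnitudes of the first-component loadings."""
        return cls(weights={k: abs(v) for k, v in pca.loadings.items()})

    @classmethod
    def unit(cls) -> "CompositeWeights":
        return cls()


def weighted_composite(z: dict | pd.Series, weights: CompositeWeights) -> float:
    """Signed weighted sum of z-scored indicators (higher = more organized)."""
    total = 0.0
    for key in INDICATORS:
        zval = z["z_" + key] if ("z_" + key) in z else z[key]
        if zval is None or not np.isfinite(zval):
            return float("nan")
        total += COMPOSITE_SIGNS[key] * weights.weights[key] * float(zval)
    return total


def unweighted_composite(z: dict | pd.Series) -> float:
    """Composite with unit weights: z_br − z_itd − z_pao − z_int."""
    return weighted_composite(z, CompositeWeights.unit())


def add_composites(
    z_table: pd.DataFrame, weights: CompositeWeights
) -> pd.DataFrame:
    """Vectorized composites over a standardized indicator table."""
    out = z_table.copy()
    w_sum = sum(
        COMPOSITE_SIGNS[k] * weights.weights[k] * z_table["z_" + k]
        for k in INDICATORS
    )
    u_sum = sum(COMPOSITE_SIGNS[k] * z_table["z_" + k] for k in INDICATORS)
    out["composite_weighted"] = w_sum
    out["composite_unweighted"] = u_sum
    return out
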