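"""Cohort statistics: porosity conversion, two-sample t-tests, LDA.

The study layer compares disk geometry and identified material
properties between the intact and degenerated groups with pooled
two-sample t-tests (reproducible directly from published mean (SD)
summaries), and asks how well the pair (E_NP, k) separates the two
groups with a two-group linear discriminant classifier evaluated by
resubstitution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "SummaryStat",
    "TTestResult",
    "LdaResult",
    "porosity_from_water_content",
    "t_test_from_summary",
    "t_test_from_raw",
    "lda_two_group",
]


@dataclass(frozen=True)
class SummaryStat:
    """mean (SD) summary of one scalar property in one group."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, group: str, values: Sequence[float]) -> "SummaryStat":
        v = np.asarray(values, dtype=float)
        return cls(group=group, n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_two_tailed: float
    pooled_se: float

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05


def porosity_from_water_content(
    water_mass_fraction: float,
    tissue_density: float,
    water_density: float = 1.0,
) -> float:
    """Volumetric porosity from gravimetric water content.

    A tissue of density rho_t (g/cm^3) containing a water mass fraction w
    holds a water volume fraction w * rho_t / rho_w (the mass of water per
    unit tissue volume divided by the density of water).  Standard tissue
    densities: anulus 1.06, nucleus 1.0 g/cm^3.
    """
    if not 0.0 <= water_mass_fraction < 1.0:
        raise ValueError(f"water_mass_fraction must be in [0, 1), got {water_mass_fraction}")
    if tissue_density <= 0 or water_density <= 0:
        raise ValueError("densities must be > 0")
    phi = water_mass_fraction * tissue_density / water_density
    if phi >= 1.0:
        raise ValueError(
            f"inconsistent inputs: computed porosity {phi:.3f} >= 1"
        )
    return phi


def t_test_from_summary(a: SummaryStat, b: SummaryStat) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test from mean (SD) summaries.

    Two-tailed p from the Student t distribution with n1 + n2 - 2 degrees
    of freedom; this is the test whose p-values the published group
    tables can be reproduced from.
    """
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        raise ValueError("undefined statistic: zero variance in both groups, equal means")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    pooled_se = float(np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n)))
    return TTestResult(
        t_statistic=float(t),
        degrees_of_freedom=df,
        p_two_tailed=float(p),
        pooled_se=pooled_se,
    )


def t_test_from_raw(
    a_values: Sequence[float], b_values: Sequence[float],
    a_group: str = "a", b_group: str = "b",
) -> TTestResult:
    """Companion entry point: pooled t-test from raw value vectors."""
    return t_test_from_summary(
        SummaryStat.from_values(a_group, a_values),
        SummaryStat.from_values(b_group, b_values),
    )


@dataclass(frozen=True)
class LdaResult:
    """Two-group Fisher discriminant on (E_NP, k)."""

    weights: np.ndarray          # discriminant direction in feature space
    threshold: float             # decision threshold on the projection
    groups: tuple[str, str]
    predicted: np.ndarray        # per-specimen predicted group labels
    rates: dict[str, float]      # per-group correct-classification rate, %

    @property
    def overall_rate(self) -> float:
        return float(np.mean(list(self.rates.values())))


def lda_two_group(
    features: np.ndarray, labels: Sequence[str]
) -> LdaResult:
    """Fisher two-group linear discriminant with resubstitution rates.

    Pooled within-group covariance, equal priors; classification is
    in-sample (resubstitution), matching a "k of n correctly classified"
    style of report.

    Parameters
    ----------
    features : (n, 2) array of (e_np, k) per specimen.
    labels : group label per specimen (exactly two distinct values).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    groups = tuple(sorted(set(y.tolist())))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    for g in groups:
        if (y == g).sum() < 2:
            raise ValueError(f"need >= 2 specimens in group {g!r}")

    # scale features to comparable magnitude (k ~ 1e-16) for numerical
    # stability; LDA classification is invariant to this rescaling
    scale = np.abs(X).mean(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale

    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    try:
        lda.fit(Xs, y)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError(f"degenerate features: {err}") from err
    pred = lda.predict(Xs)
    rates = {
        g: float(100.0 * np.mean(pred[y == g] == g)) for g in groups
    }
    w = (lda.coef_[0] / scale)
    thr = float(-lda.intercept_[0])
    return LdaResult(
        weights=w, threshold=thr, groups=groups, predicted=pred, rates=rates
    )
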