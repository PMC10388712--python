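"""Viability classification from the mean-phase distribution.

The per-grain mean phase is strongly bimodal: cytoplasm-filled viable
grains form a high-mean mode, aborted grains a low-mean mode. A
two-component 1D Gaussian mixture fitted to the mean-phase values yields
class statistics and an equal-posterior decision threshold; a Welch
two-sample t-test quantifies the class separation, and grains near the
threshold (the histogram overlap region, where stain-based calls are
least trustworthy) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .morphometry import PollenMeasurement
from .simulate import PollenClass

__all__ = [
    "ClassStats",
    "TestResult",
    "DegenerateFitError",
    "fit_two_classes",
    "ttest_classes",
    "flag_overlap",
    "classify_population",
]


class DegenerateFitError(RuntimeError):
    """The two-component mixture collapsed or lacked data."""


@dataclass(frozen=True)
class ClassStats:
    """Summary statistics of mean phase for one viability class."""

    label: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class TestResult:
    """Welch two-sample t-test result plus classification context."""

    t_statistic: float
    degrees_freedom: float
    p_value: float
    threshold: float | None = None
    n_overlap: int | None = None


def _mean_phases(measurements: Sequence[PollenMeasurement] | Sequence[float]) -> np.ndarray:
    vals = [m.mean_phase if isinstance(m, PollenMeasurement) else float(m) for m in measurements]
    return np.asarray(vals, dtype=float)


def _equal_posterior_threshold(
    means: np.ndarray, sds: np.ndarray, weights: np.ndarray
) -> float:
    """Point between the component means where the posteriors are equal.

    Solves w1 N(x|m1,s1) = w2 N(x|m2,s2), a quadratic in x; the root
    between the means is returned (the midpoint when the quadratic
    degenerates).
    """
    (m1, m2), (s1, s2), (w1, w2) = means, sds, weights
    lo, hi = sorted((m1, m2))
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)) + np.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            return 0.5 * (m1 + m2)
        root = -c / b
        return float(root) if lo < root < hi else 0.5 * (m1 + m2)
    disc = b**2 - 4 * a * c
    if disc < 0:
        return 0.5 * (m1 + m2)
    roots = ((-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a))
    inside = [r for r in roots if lo < r < hi]
    return float(inside[0]) if inside else 0.5 * (m1 + m2)


def fit_two_classes(
    measurements: Sequence[PollenMeasurement] | Sequence[float],
    random_state: int = 0,
) -> tuple[float, tuple[ClassStats, ClassStats]]:
    """Fit a two-component Gaussian mixture to the mean-phase values.

    Returns the equal-posterior threshold and (viable, nonviable) class
    statistics computed from the hard partition at the threshold; the
    higher-mean component is labeled viable. Raises ``DegenerateFitError``
    for < 4 points, identical data, or a collapsed component (weight
    below 0.02).
    """
    x = _mean_phases(measurements)
    if x.size < 4:
        raise DegenerateFitError("need at least 4 measurements for a two-class fit")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all mean-phase values identical; no two-class structure")
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        init_params="kmeans",
        n_init=5,
        random_state=random_state,
    )
    gmm.fit(x[:, None])
    if gmm.weights_.min() < 0.02:
        raise DegenerateFitError("mixture component collapsed (weight < 0.02)")
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    threshold = _equal_posterior_threshold(means, sds, gmm.weights_)
    hi = x[x > threshold]
    lo = x[x <= threshold]
    if hi.size < 1 or lo.size < 1:
        raise DegenerateFitError("threshold partitions all points into one class")

    def _stats(label: str, v: np.ndarray) -> ClassStats:
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return ClassStats(label=label, n=int(v.size), mean=float(v.mean()), sd=sd)

    return threshold, (_stats(PollenClass.VIABLE.value, hi), _stats(PollenClass.NONVIABLE.value, lo))


def ttest_classes(
    group_a: Sequence[float] | np.ndarray,
    group_b: Sequence[float] | np.ndarray,
) -> TestResult:
    """Welch two-sample t-test on two groups of mean-phase values.

    Uses the unequal-variance statistic with Welch–Satterthwaite degrees
    of freedom and a two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        df = float(a.size + b.size - 2)
    else:
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return TestResult(
        t_statistic=float(res.statistic),
        degrees_freedom=float(df),
        p_value=float(res.pvalue),
    )


def flag_overlap(
    measurements: Sequence[PollenMeasurement],
    threshold: float,
    band_halfwidth: float,
) -> list[PollenMeasurement]:
    """Annotate grains in the histogram overlap band around the threshold.

    Sets ``phase_label`` from the threshold, ``overlap_flag`` when
    ``|mean_phase - threshold| < band_halfwidth``, and
    ``discordant_flag`` when a stain label is present and disagrees with
    the phase label.
    """
    out: list[PollenMeasurement] = []
    for m in measurements:
        phase_label = (
            PollenClass.VIABLE.value if m.mean_phase > threshold else PollenClass.NONVIABLE.value
        )
        overlap = abs(m.mean_phase - threshold) < band_halfwidth
        discordant = m.stain_label is not None and m.stain_label != phase_label
        out.append(
            replace(
                m,
                phase_label=phase_label,
                overlap_flag=bool(overlap),
                discordant_flag=bool(discordant),
            )
        )
    return out


def classify_population(
    measurements: Sequence[PollenMeasurement],
    band_halfwidth: float | None = None,
    random_state: int = 0,
) -> tuple[list[PollenMeasurement], tuple[ClassStats, ClassStats], TestResult]:
    """Full viability analysis of a measured population.

    Fits the two-class mixture, flags the overlap band (default half-width
    half the pooled within-class sd), and runs the Welch t-test between
    the two phase-defined classes.
    """
    threshold, (stats_v, stats_nv) = fit_two_classes(measurements, random_state=random_state)
    if band_halfwidth is None:
        pooled = np.sqrt(
            (
                (stats_v.n - 1) * stats_v.sd**2 + (stats_nv.n - 1) * stats_nv.sd**2
            )
            / max(stats_v.n + stats_nv.n - 2, 1)
        )
        band_halfwidth = 0.5 * float(pooled)
    annotated = flag_overlap(measurements, threshold, band_halfwidth)
    x = _mean_phases(measurements)
    test = ttest_classes(x[x > threshold], x[x <= threshold])
    n_overlap = sum(m.overlap_flag for m in annotated)
    test = replace(test, threshold=threshold, n_overlap=int(n_overlap))
    return annotated, (stats_v, stats_nv), test
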