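"""Method-agreement statistics: Bland-Altman limits, repeatability, CCC.

Bland-Altman: bias = mean paired difference, 95 % limits of agreement
(LoA) = bias +/- 1.96*SD of differences; t-based CI for the bias and the
classic sqrt(3*SD^2/n) CI for each limit.  For repeated measurements of
a quantity assumed constant within subject, the SD of differences is
corrected with one-way ANOVA variance components (between-subject +
within-subject), which needs replicate (subject) labels.  The
coefficient of repeatability is 2*SD of test-retest differences.

Lin's concordance correlation coefficient (CCC) measures agreement with
the identity line, combining precision (Pearson r) and accuracy (scale
and location shift); its CI uses the z-transform variance of Lin (1989,
corrected 2000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["AgreementStats", "CCCResult", "bland_altman", "repeatability", "ccc"]


@dataclass
class AgreementStats:
    """Bland-Altman summary for one pairwise comparison."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple
    ci_loa_lower: tuple
    ci_loa_upper: tuple
    cor: Optional[float] = None          # coefficient of repeatability, 2*sd_diff
    repeated: bool = False


@dataclass
class CCCResult:
    estimate: float
    ci: tuple
    n: int


def _complete_pairs(x, y, subjects=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    subj = None
    if subjects is not None:
        subj = np.asarray(subjects)
        if subj.shape != x.shape:
            raise ValueError("subjects must match x and y in length")
        subj = subj[mask]
    return x[mask], y[mask], subj


def _replicate_corrected_sd(d: np.ndarray, subjects: np.ndarray) -> float:
    """SD of a single difference from one-way ANOVA components on d by subject.

    sd^2 = sigma_between^2 + sigma_within^2 with sigma_between estimated as
    (MSB - MSW)/m0 (m0 the effective replicate count), floored at zero.
    Subjects with a single observation contribute only to the between term.
    """
    labels, counts = np.unique(subjects, return_counts=True)
    k = labels.size
    n = d.size
    if k < 2 or n == k:
        return float(np.std(d, ddof=1))
    grand = d.mean()
    means = np.array([d[subjects == lab].mean() for lab in labels])
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(sum(np.sum((d[subjects == lab] - m) ** 2) for lab, m in zip(labels, means)))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    m0 = (n - np.sum(counts**2) / n) / (k - 1)
    sigma_b2 = max((msb - msw) / m0, 0.0)
    return float(np.sqrt(sigma_b2 + msw))


def bland_altman(
    x: Sequence[float],
    y: Sequence[float],
    repeated: bool = False,
    subjects: Optional[Sequence] = None,
    loa_z: float = 1.96,
    ci_level: float = 0.95,
) -> AgreementStats:
    """Bland-Altman bias and limits of agreement with 95 % CIs.

    Missing pairs (NaN in either series) are dropped; at least 3 complete
    pairs are required.  With ``repeated=True`` and ``subjects`` given,
    the SD of differences uses the replicate-pairs variance correction;
    ``repeated=True`` without labels falls back to the plain SD with a
    warning.
    """
    x, y, subj = _complete_pairs(x, y, subjects)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    d = x - y
    bias = float(d.mean())
    if repeated:
        if subj is None:
            warnings.warn(
                "repeated=True without subject labels: falling back to the plain SD "
                "of differences", stacklevel=2,
            )
            sd = float(np.std(d, ddof=1))
        else:
            sd = _replicate_corrected_sd(d, subj)
    else:
        sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance of differences: limits collapse to the bias",
                      stacklevel=2)
    loa_lower = bias - loa_z * sd
    loa_upper = bias + loa_z * sd
    t = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = np.sqrt(3.0 * sd**2 / n)
    return AgreementStats(
        n=int(n), bias=bias, sd_diff=sd,
        loa_lower=float(loa_lower), loa_upper=float(loa_upper),
        ci_bias=(bias - t * se_bias, bias + t * se_bias),
        ci_loa_lower=(loa_lower - t * se_loa, loa_lower + t * se_loa),
        ci_loa_upper=(loa_upper - t * se_loa, loa_upper + t * se_loa),
        repeated=bool(repeated),
    )


def repeatability(rep1: Sequence[float], rep2: Sequence[float],
                  subjects: Optional[Sequence] = None) -> AgreementStats:
    """Test-retest Bland-Altman plus the coefficient of repeatability (2*SD)."""
    out = bland_altman(rep1, rep2, repeated=True, subjects=subjects)
    out.cor = 2.0 * out.sd_diff
    return out


def ccc(x: Sequence[float], y: Sequence[float], ci_level: float = 0.95,
        n_boot: Optional[int] = None, seed: Optional[int] = None) -> CCCResult:
    """Lin's concordance correlation coefficient with a z-transform CI.

    Uses sample (n-denominator) moments: ccc = 2*s_xy / (s_x^2 + s_y^2 +
    (mean_x - mean_y)^2).  Set ``n_boot`` for a percentile-bootstrap CI
    instead of the analytic one.
    """
    x, y, _ = _complete_pairs(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("zero variance in x or y")
    est = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)

    if n_boot:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            xb, yb = x[idx[b]], y[idx[b]]
            mxb, myb = xb.mean(), yb.mean()
            sxb = np.mean((xb - mxb) ** 2)
            syb = np.mean((yb - myb) ** 2)
            denom = sxb + syb + (mxb - myb) ** 2
            boots[b] = 2.0 * np.mean((xb - mxb) * (yb - myb)) / denom if denom else np.nan
        lo, hi = np.nanquantile(boots, [0.5 - ci_level / 2.0, 0.5 + ci_level / 2.0])
        return CCCResult(estimate=float(est), ci=(float(lo), float(hi)), n=int(n))

    r = sxy / np.sqrt(sx2 * sy2)
    if abs(est) >= 1.0 - 1e-12 or abs(r) >= 1.0 - 1e-12 or n < 4:
        return CCCResult(estimate=float(est), ci=(float(est), float(est)), n=int(n))
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c2 = est**2
    var_z = (
        (1.0 - r**2) * c2 / ((1.0 - c2) * r**2)
        + 4.0 * est**3 * (1.0 - est) * u**2 / (r * (1.0 - c2) ** 2)
        - 2.0 * est**4 * u**4 / (r**2 * (1.0 - c2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(est)
    zq = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    lo, hi = np.tanh(z - zq * np.sqrt(var_z)), np.tanh(z + zq * np.sqrt(var_z))
    return CCCResult(estimate=float(est), ci=(float(lo), float(hi)), n=int(n))
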