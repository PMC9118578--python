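"""Per-sample aggregation and Welch's unequal-variance t-test.

Each droplet of germination medium is a sample; its germination estimate is
the arithmetic mean of the per-image percentages (images with no grains are
excluded and reported separately).  Groups of samples — medium recipes,
incubation times — are compared with Welch's t-test,

    t  = (m_a - m_b) / sqrt(s2_a/n_a + s2_b/n_b)
    df = (s2_a/n_a + s2_b/n_b)^2
         / [ (s2_a/n_a)^2/(n_a-1) + (s2_b/n_b)^2/(n_b-1) ]

with sample variances s2 computed with denominator n-1 and a two-sided
p-value from the t distribution with the Welch–Satterthwaite df (evaluated
through the regularized incomplete beta function).  Medians are reported
alongside means, as is conventional for skewed germination distributions.
No multiple-testing correction is applied; pairwise p-values are raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .corrections import CountResult


@dataclass(frozen=True)
class SampleResult:
    """Mean germination percentage over the images of one sample."""

    sample_id: str
    image_percents: tuple[float, ...]
    n_excluded: int  # images with no grains (undefined percent)

    @property
    def mean_percent(self) -> float:
        return float(np.mean(self.image_percents))

    @property
    def n_images(self) -> int:
        return len(self.image_percents)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    group_means: tuple[float, float]
    group_vars: tuple[float, float]
    group_ns: tuple[int, int]
    group_medians: tuple[float, float]


class EmptySampleError(ValueError):
    """Raised when a sample has no image with a defined percentage."""


class InsufficientDataError(ValueError):
    """Raised when a group has fewer than two observations."""


def summarize_sample(image_results: Sequence[CountResult], sample_id: str) -> SampleResult:
    """Average the defined per-image percentages of one sample.

    Images with no grains have an undefined percentage; they are dropped
    from the mean and tallied in ``n_excluded``.  A sample with no defined
    percentage at all raises :class:`EmptySampleError`.
    """
    defined = [r.percent_germination for r in image_results if not r.undefined]
    excluded = sum(1 for r in image_results if r.undefined)
    if not defined:
        raise EmptySampleError(f"sample {sample_id!r} has no image with a defined percentage")
    return SampleResult(sample_id=sample_id, image_percents=tuple(defined), n_excluded=excluded)


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    Requires at least two observations per group.  The degenerate case of
    two constant groups with equal means reports t = 0, p = 1.  The
    two-sided p-value comes from the Student-t CDF, computed via the
    regularized incomplete beta function.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InsufficientDataError(f"each group needs n >= 2, got n_a={na}, n_b={nb}")
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    medians = (float(np.median(a)), float(np.median(b)))

    se2 = va / na + vb / nb
    if se2 == 0.0:
        # Both groups constant: no sampling noise to test against.
        t = 0.0 if ma == mb else float(np.inf) * np.sign(ma - mb)
        p = 1.0 if ma == mb else 0.0
        df = float(na + nb - 2)
    else:
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = _two_sided_p(t, df)
    return WelchResult(
        t=float(t),
        df=float(df),
        p=float(p),
        group_means=(ma, mb),
        group_vars=(va, vb),
        group_ns=(na, nb),
        group_medians=medians,
    )


def _two_sided_p(t: float | np.ndarray, df: float | np.ndarray):
    """Two-sided tail probability of Student's t via the incomplete beta.

    P(|T| >= t) = I_{df/(df+t^2)}(df/2, 1/2), the standard identity.
    Vectorised; used both per-test and for bulk null simulation.
    """
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    x = df / (df + t**2)
    p = special.betainc(df / 2.0, 0.5, x)
    return p if p.ndim else float(p)


def welch_t_bulk(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch test over the last axis — one test per row.

    Returns (t, df, p) arrays; used for null-calibration simulations where
    thousands of group pairs are tested at once.
    """
    na, nb = a.shape[-1], b.shape[-1]
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va, vb = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df, _two_sided_p(t, df)
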