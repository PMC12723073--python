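"""Paired pre/post group statistics with Bonferroni control and effect sizes.

The design compares each graph parameter (CS, ClC, PL) between the
prestimulus and poststimulus windows within subjects, per frequency band:
18 tests for the active design (6 bands), 15 for the sham design (5 bands,
alpha excluded).  The t statistic is computed on (pre - post), so an increase
after the pulse appears as a negative t.  The default p value is one-tailed:
the printed (t, p) pairs of this literature are mutually consistent only
under that convention (|t| = 2.76 at df = 28 gives 0.0050 one-tailed,
0.0101 two-tailed); the tail is configurable and echoed in the output.

Cohen's d defaults to the pooled-SD convention
``|mean_post - mean_pre| / sqrt((sd_pre^2 + sd_post^2) / 2)``; the paired
(difference-SD) convention is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "p_from_t",
    "paired_t",
    "cohens_d",
    "bonferroni",
    "compare_windows",
    "ACTIVE_BANDS",
    "SHAM_BANDS",
    "PARAMETERS",
]

PARAMETERS = ("cs", "clc", "pl")
ACTIVE_BANDS = ("theta", "alpha", "beta1", "beta2", "gamma", "global")
SHAM_BANDS = ("theta", "beta1", "beta2", "gamma", "global")

#: thresholds as printed in the source literature, echoed for traceability
PRINTED_THRESHOLDS = {"active": 0.002, "sham": 0.003}


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    band: str
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    t: float
    df: int
    p: float
    d: float
    significant_bonferroni: bool


def p_from_t(t: float, df: int, tail: str = "one") -> float:
    """p value of an observed t statistic.

    ``tail='one'`` gives ``P(T >= |t|)`` under the Student t distribution
    with ``df`` degrees of freedom (the convention under which this
    literature's printed (t, p) pairs are consistent); ``'two'`` doubles it.
    """
    if tail == "one":
        return float(sps.t.sf(abs(t), df))
    if tail == "two":
        return float(2 * sps.t.sf(abs(t), df))
    raise ValueError("tail must be 'one' or 'two'")


def paired_t(pre, post, tail: str = "one") -> tuple[float, int, float]:
    """Paired-samples t test on the (pre - post) differences.

    Returns ``(t, df, p)`` with ``df = n - 1``.  ``tail='one'`` gives the
    directional p value ``P(T >= |t|)`` (0.5 at t = 0); ``tail='two'`` doubles
    it.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d vectors")
    n = pre.size
    if n < 3:
        raise ValueError("paired t test needs >= 3 subjects")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0 and diff.mean() != 0:
        raise ValueError("zero variance of nonzero differences")
    if sd == 0:
        t = 0.0
    else:
        t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    return float(t), df, p_from_t(t, df, tail)


def cohens_d(pre, post, kind: str = "pooled") -> float:
    """Effect size of the pre/post change.

    ``kind='pooled'``: absolute mean difference over the root-mean-square of
    the two SDs.  ``kind='paired'``: mean paired difference over the SD of the
    differences.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if kind == "pooled":
        denom = np.sqrt((pre.std(ddof=1) ** 2 + post.std(ddof=1) ** 2) / 2.0)
    elif kind == "paired":
        denom = (post - pre).std(ddof=1)
    else:
        raise ValueError("kind must be 'pooled' or 'paired'")
    if denom == 0:
        if post.mean() == pre.mean():
            return 0.0
        raise ValueError("zero spread: Cohen's d undefined")
    return float(abs(post.mean() - pre.mean()) / denom)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Exact corrected per-test threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def compare_windows(
    metrics: pd.DataFrame,
    design: str = "active",
    estimator: str | None = None,
    alpha: float = 0.05,
    tail: str = "one",
    d_kind: str = "pooled",
    parameters=PARAMETERS,
) -> pd.DataFrame:
    """Per (parameter, band) paired comparison of pre vs post metrics.

    ``metrics`` is the tidy table with columns ``subject, window, band,
    estimator, parameter, value`` (windows ``prestimulus``/``poststimulus``).
    Rows are ordered parameter-major (CS, ClC, PL) then band.  The returned
    frame carries the decision threshold and design metadata in ``attrs``.
    """
    if design == "active":
        bands = ACTIVE_BANDS
    elif design == "sham":
        bands = SHAM_BANDS
    else:
        raise ValueError("design must be 'active' or 'sham'")
    df = metrics
    if estimator is not None:
        df = df[df["estimator"] == estimator]
    n_tests = len(PARAMETERS) * len(bands)  # the design's test count
    threshold = bonferroni(alpha, n_tests)

    rows = []
    for parameter in parameters:
        for band in bands:
            sub = df[(df["parameter"] == parameter) & (df["band"] == band)]
            pre = sub[sub["window"] == "prestimulus"].set_index("subject")["value"]
            post = sub[sub["window"] == "poststimulus"].set_index("subject")["value"]
            missing = sorted(set(pre.index) ^ set(post.index))
            if missing or pre.empty:
                raise ValueError(
                    f"incomplete pre/post pairs for ({parameter}, {band}): "
                    f"unmatched subjects {missing}"
                )
            pre = pre.sort_index()
            post = post.reindex(pre.index)
            t, dof, p = paired_t(pre.values, post.values, tail=tail)
            rows.append(
                ComparisonResult(
                    parameter=parameter,
                    band=band,
                    mean_pre=float(pre.mean()),
                    sd_pre=float(pre.std(ddof=1)),
                    mean_post=float(post.mean()),
                    sd_post=float(post.std(ddof=1)),
                    t=t,
                    df=dof,
                    p=p,
                    d=cohens_d(pre.values, post.values, kind=d_kind),
                    significant_bonferroni=bool(p < threshold),
                )
            )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.attrs.update(
        design=design,
        n_tests=n_tests,
        alpha=alpha,
        bonferroni_threshold=threshold,
        printed_threshold=PRINTED_THRESHOLDS[design],
        tail=tail,
        d_kind=d_kind,
    )
    return out
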