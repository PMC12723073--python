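"""Cohort-level validation scenarios: direction-of-effect recovery and
null (sham-like) false-positive calibration.

These runners simulate a synthetic cohort, compute PLV connectivity,
reduce to graph metrics and run the paired pre/post statistics — the full
analysis chain on data with known ground truth.  They use desk-scale
analysis settings chosen for single-CPU runtimes (10 ms wavelet hop,
6 voices/octave scale grid; both are resolution knobs that do not change
band-averaged connectivity beyond the third decimal at these SNRs).

Clustering is evaluated with the degree-denominator convention here: the
strength-denominator variant is monotonically DEcreasing under any
broad increase of edge weights (uniform complete graph:
``ClC = (N-2)/((N-1)w - 1)``), so a joint "strength up, clustering up"
effect — the direction pattern these scenarios are built to recover — is
only well-posed under the degree reading.  See ``docs/methods.md``.
"""

from __future__ import annotations

import pandas as pd

from .connectivity import POSTSTIMULUS, PRESTIMULUS, AnalysisWindow, connectivity_suite
from .pipeline import metrics_table
from .stats import SHAM_BANDS, compare_windows
from .synthetic import SyntheticConfig, effect_config, generate_cohort, null_config
from .wavelet import WaveletParams, default_freq_grid

__all__ = [
    "MATCHED_WINDOWS",
    "desk_scale_params",
    "desk_scale_freqs",
    "cohort_stats",
    "effect_stats",
    "null_stats",
    "global_direction_recovered",
    "familywise_hit",
    "nominal_familywise_rate",
]


def desk_scale_params() -> WaveletParams:
    """Wavelet parameters for cohort-scale simulations (10 ms hop)."""
    return WaveletParams(hop_s=0.01)


def desk_scale_freqs():
    """Scale grid for cohort-scale simulations (6 voices/octave)."""
    return default_freq_grid(voices_per_octave=6)


#: matched-length window pair for null calibration: two non-overlapping
#: 300 ms windows, so pre and post are exchangeable under the null.  The
#: standard analysis windows (1000 ms pre vs 300 ms post) are NOT
#: exchangeable: the shorter window band-averages fewer COI cells, and the
#: nonlinear graph metrics (1/w path distances, geometric-mean triangles)
#: turn that extra weight variance into a systematic mean shift (PL biased
#: up, ClC down in the short window) that a paired test detects reliably.
MATCHED_WINDOWS = (
    AnalysisWindow("prestimulus", (-315.0, -15.0)),
    AnalysisWindow("poststimulus", (15.0, 315.0)),
)


def cohort_stats(
    config: SyntheticConfig,
    design: str,
    estimator: str = "plv",
    windows=(PRESTIMULUS, POSTSTIMULUS),
) -> pd.DataFrame:
    """Simulate one cohort and return its paired pre/post comparison table."""
    params = desk_scale_params()
    freqs = desk_scale_freqs()
    cohort = generate_cohort(config)
    matrices = {}
    for k, rec in enumerate(cohort):
        suite = connectivity_suite(
            rec,
            windows=windows,
            estimators=(estimator,),
            freqs_hz=freqs,
            params=params,
            subject=k,
        )
        for (wlabel, est, band), mat in suite.items():
            matrices[(k, wlabel, est, band)] = mat
    metrics = metrics_table(matrices, clc_denominator="degree")
    return compare_windows(metrics, design=design, estimator=estimator)


def effect_stats(seed: int) -> pd.DataFrame:
    """Comparison table for a cohort with increased post-stimulus coupling."""
    return cohort_stats(effect_config(seed=seed), design="active")


def null_stats(seed: int) -> pd.DataFrame:
    """Comparison table for a coupling-free (sham-like) cohort, compared on
    the matched-length (exchangeable) window pair."""
    return cohort_stats(
        null_config(seed=seed), design="sham", windows=MATCHED_WINDOWS
    )


def global_direction_recovered(table: pd.DataFrame) -> bool:
    """True iff the global band shows Bonferroni-significant CS up, ClC up
    and PL down (pre minus post: negative t for CS/ClC, positive for PL)."""
    g = table[table["band"] == "global"].set_index("parameter")
    return bool(
        g.loc["cs", "significant_bonferroni"]
        and g.loc["clc", "significant_bonferroni"]
        and g.loc["pl", "significant_bonferroni"]
        and g.loc["cs", "t"] < 0
        and g.loc["clc", "t"] < 0
        and g.loc["pl", "t"] > 0
    )


def familywise_hit(table: pd.DataFrame) -> bool:
    """True iff any comparison in the table is Bonferroni-significant."""
    return bool(table["significant_bonferroni"].any())


def nominal_familywise_rate(alpha: float = 0.05, n_tests: int = len(SHAM_BANDS) * 3):
    """Familywise false-positive rate of the implemented procedure under the
    null: each test fires when ``sf(|t|) < alpha / n_tests``, i.e. with
    probability ``2 * alpha / n_tests`` (strong effects of either sign)."""
    per_test = min(1.0, 2.0 * alpha / n_tests)
    return 1.0 - (1.0 - per_test) ** n_tests
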