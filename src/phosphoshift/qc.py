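"""Pre-analysis quality control.

Three checks gate a SILAC dataset before any ratio is trusted:

* **label incorporation** -- the fraction of each labeled channel's
  protein pool actually carrying the heavy lysine.  Incomplete
  incorporation leaves an unlabeled shadow of every peptide and biases
  ratios toward the light channel; channels below the threshold
  (default 0.94) are excluded wholesale.
* **mixing check** -- the channels are combined 1:1(:1) by protein
  mass, so the median per-analyte log2 ratio between any two channels
  should sit near zero; a systematic offset means a pipetting/mixing
  error rather than biology.
* **replicate correlation** -- Pearson correlation of log2 shift
  values between biological replicates.

QC never mutates the data: it annotates, and the caller decides what
to exclude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import MISSING, PipelineParams, is_missing

__all__ = [
    "IncorporationResult",
    "MixingResult",
    "CorrelationResult",
    "incorporation_fraction",
    "check_incorporation",
    "mixing_check",
    "replicate_correlation",
]

#: Minimum shared analytes for a meaningful mixing median.
MIN_MIXING_ANALYTES = 10


@dataclass(frozen=True)
class IncorporationResult:
    experiment: str
    channel: str
    fraction: float
    passed: bool


@dataclass(frozen=True)
class MixingResult:
    experiment: str
    channel_a: str
    channel_b: str
    median_log2: float
    n_analytes: int
    sufficient: bool
    #: None when sufficient is False (verdict undefined).
    passed: bool | None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_pairs: int
    #: False when either vector has zero variance (r undefined).
    defined: bool


def incorporation_fraction(labeled: float, unlabeled: float) -> float:
    """labeled / (labeled + unlabeled); missing when both are zero or
    either side is missing."""
    if is_missing(labeled) or is_missing(unlabeled):
        return MISSING
    total = labeled + unlabeled
    if total <= 0:
        return MISSING
    return labeled / total


def check_incorporation(
    qc_table: pd.DataFrame, params: PipelineParams | None = None
) -> list[IncorporationResult]:
    """Summarize a QC table of labeled/unlabeled intensity pairs.

    The table has columns ``experiment, channel, analyte,
    labeled_intensity, unlabeled_intensity``; the per-channel
    incorporation is the median of per-analyte fractions (robust to a
    few badly quantified peptides).  A channel passes iff its fraction
    is at or above ``incorporation_min``.
    """
    params = params or PipelineParams()
    results: list[IncorporationResult] = []
    for (experiment, channel), group in qc_table.groupby(
        ["experiment", "channel"], sort=True
    ):
        fractions = [
            incorporation_fraction(lab, unlab)
            for lab, unlab in zip(
                group["labeled_intensity"], group["unlabeled_intensity"]
            )
        ]
        fractions = [f for f in fractions if not is_missing(f)]
        fraction = float(np.median(fractions)) if fractions else MISSING
        passed = (not is_missing(fraction)
                  and fraction >= params.incorporation_min)
        results.append(
            IncorporationResult(str(experiment), str(channel),
                                fraction, passed)
        )
    return results


def mixing_check(
    intensities_a: Sequence[float],
    intensities_b: Sequence[float],
    experiment: str = "",
    channel_a: str = "",
    channel_b: str = "",
    params: PipelineParams | None = None,
) -> MixingResult:
    """Median log2(b/a) across analytes quantified in both channels.

    With fewer than 10 shared analytes the result is flagged
    insufficient and the pass/fail verdict left undefined.
    """
    params = params or PipelineParams()
    ratios = [
        math.log2(b / a)
        for a, b in zip(intensities_a, intensities_b)
        if not is_missing(a) and not is_missing(b) and a > 0 and b > 0
    ]
    n = len(ratios)
    if n < MIN_MIXING_ANALYTES:
        return MixingResult(experiment, channel_a, channel_b,
                            MISSING, n, sufficient=False, passed=None)
    median = float(np.median(ratios))
    return MixingResult(
        experiment, channel_a, channel_b, median, n,
        sufficient=True, passed=abs(median) <= params.mixing_tolerance,
    )


def replicate_correlation(
    values_rep1: Iterable[float], values_rep2: Iterable[float]
) -> CorrelationResult:
    """Pearson r between two replicates on their complete pairs.

    Pairs with any missing member are dropped; needs >= 3 complete
    pairs.  Zero variance in either vector makes r undefined (flagged,
    not raised).
    """
    pairs = [
        (a, b)
        for a, b in zip(values_rep1, values_rep2)
        if not is_missing(a) and not is_missing(b)
    ]
    n = len(pairs)
    if n < 3:
        raise ValueError(
            f"replicate correlation needs >= 3 complete pairs, got {n}"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(MISSING, n, defined=False)
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r, n, defined=True)
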