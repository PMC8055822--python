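"""The analytical core: differential-proteome calls and phosphosite
scenario classification.

**Proteome.**  Each protein gets a glucose->malate shift in both
strains; a protein is called differential on an axis when its shift
lies at or beyond ``mean +/- k*SD`` of that axis's distribution
(k = 2 by default, population SD).  The cutoff adapts to the dataset,
so adding a constant to every shift moves the cutoff with it.

**Phosphosites.**  For sites quantified in both strains in both
conditions, the delta statistic (knockout shift minus wild-type shift)
separates three scenarios:

* ``independent``    -- |delta| within the threshold: the kinase has no
  influence on the site's condition response;
* ``candidate_direct``   -- delta below -t: the shift is attenuated in the
  knockout, as expected for a site the kinase itself phosphorylates;
* ``candidate_indirect`` -- delta above +t: the shift is amplified, as
  when the kinase normally restrains another kinase.

Ties at exactly |delta| = t are called independent (strict
inequality), so the zero-threshold limit is well defined.  The
threshold is either ``sd_multiplier`` population SDs of the delta
distribution about its mean (default) or a fixed log2 value for small
fixtures.

Sites detected in the wild type in both conditions but *never* in the
knockout (zero detections in any channel or replicate) form the
``wt_only`` class -- presence/absence evidence too strong for a ratio,
and the strongest substrate candidates.  "Never detected" means
exactly that: zero detections, not low intensity.

The "candidate" prefix is deliberate: nothing here demonstrates an
enzymatic kinase-substrate relationship; the calls rank sites for
orthogonal validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .design import (
    Contrast,
    DeltaDeltaRecord,
    ExperimentDesign,
    MISSING,
    PipelineParams,
    is_missing,
    shift_ratio,
)
from .tables_io import PhosphoSiteQuant, ProteinQuant

logger = logging.getLogger(__name__)

__all__ = [
    "ProteomeCall",
    "SubstrateCall",
    "SCENARIOS",
    "protein_shifts",
    "proteome_differential",
    "site_delta_records",
    "classify_sites",
    "wt_only_sites",
    "classify_phosphoproteome",
]

SCENARIOS = ("independent", "candidate_direct", "candidate_indirect",
             "wt_only")


@dataclass(frozen=True)
class ProteomeCall:
    protein: str
    wt_shift: float
    ko_shift: float
    call: str  # up_in_ko | down_in_ko | up_in_wt | down_in_wt | unchanged
    cutoff_wt_low: float
    cutoff_wt_high: float
    cutoff_ko_low: float
    cutoff_ko_high: float


@dataclass(frozen=True)
class SubstrateCall:
    protein: str
    site: int
    residue: str
    wt_shift: float
    ko_shift: float  # missing for wt_only
    delta: float     # missing for wt_only
    scenario: str
    threshold_used: float


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------


def protein_shifts(
    records: Iterable[ProteinQuant],
    design: ExperimentDesign,
    contrast: Contrast | None = None,
) -> list[tuple[str, float, float]]:
    """Per-protein (wt_shift, ko_shift) pairs; missing where a strain's
    shift cannot be formed."""
    contrast = contrast or Contrast()
    out = []
    for rec in records:
        wt = shift_ratio(rec.intensities, design, contrast.wt_strain,
                         contrast.cond_to, contrast.cond_from)
        ko = shift_ratio(rec.intensities, design, contrast.ko_strain,
                         contrast.cond_to, contrast.cond_from)
        out.append((
            rec.protein,
            wt.value if wt else MISSING,
            ko.value if ko else MISSING,
        ))
    return out


def _axis_stats(values: np.ndarray) -> tuple[float, float]:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return MISSING, MISSING
    # Population SD: the cutoff describes the observed distribution,
    # not an estimate of a larger one.
    return float(finite.mean()), float(finite.std(ddof=0))


def proteome_differential(
    shifts: Sequence[tuple[str, float, float]],
    params: PipelineParams | None = None,
) -> list[ProteomeCall]:
    """Call proteins beyond mean +/- k*SD on either strain's shift axis.

    Needs >= 3 proteins with both shifts present so the SDs are
    defined.  An axis with zero SD yields no calls on that axis (with a
    warning).  A protein at or beyond the cutoff on exactly one axis is
    called for that axis; beyond on both, the axis with the larger
    standardized excursion wins.
    """
    params = params or PipelineParams()
    wt = np.array([s[1] for s in shifts], dtype=float)
    ko = np.array([s[2] for s in shifts], dtype=float)
    complete = np.isfinite(wt) & np.isfinite(ko)
    if complete.sum() < 3:
        raise ValueError(
            "proteome differential needs >= 3 proteins with both shifts"
        )
    k = params.sd_multiplier
    wt_mean, wt_sd = _axis_stats(wt)
    ko_mean, ko_sd = _axis_stats(ko)
    for axis, sd in (("wild-type", wt_sd), ("knockout", ko_sd)):
        if sd == 0:
            logger.warning("%s axis has zero SD; no calls on it", axis)

    calls = []
    for (protein, w, o) in shifts:
        wt_z = (w - wt_mean) / wt_sd if wt_sd and math.isfinite(w) else 0.0
        ko_z = (o - ko_mean) / ko_sd if ko_sd and math.isfinite(o) else 0.0
        wt_hit = abs(wt_z) >= k and wt_sd > 0
        ko_hit = abs(ko_z) >= k and ko_sd > 0
        if wt_hit and ko_hit:
            wt_hit = abs(wt_z) >= abs(ko_z)
            ko_hit = not wt_hit
        if ko_hit:
            call = "up_in_ko" if ko_z > 0 else "down_in_ko"
        elif wt_hit:
            call = "up_in_wt" if wt_z > 0 else "down_in_wt"
        else:
            call = "unchanged"
        calls.append(ProteomeCall(
            protein=protein, wt_shift=w, ko_shift=o, call=call,
            cutoff_wt_low=wt_mean - k * wt_sd,
            cutoff_wt_high=wt_mean + k * wt_sd,
            cutoff_ko_low=ko_mean - k * ko_sd,
            cutoff_ko_high=ko_mean + k * ko_sd,
        ))
    return calls


# ---------------------------------------------------------------------------
# phosphosites
# ---------------------------------------------------------------------------


def site_delta_records(
    records: Iterable[PhosphoSiteQuant],
    design: ExperimentDesign,
    contrast: Contrast | None = None,
) -> list[DeltaDeltaRecord]:
    """Delta records for every site whose shift is quantifiable in both
    strains; sites lacking either shift are silently omitted here (they
    are handled by the presence/absence path)."""
    contrast = contrast or Contrast()
    out = []
    for rec in records:
        wt = shift_ratio(rec.intensities, design, contrast.wt_strain,
                         contrast.cond_to, contrast.cond_from)
        ko = shift_ratio(rec.intensities, design, contrast.ko_strain,
                         contrast.cond_to, contrast.cond_from)
        if wt is None or ko is None:
            continue
        out.append(DeltaDeltaRecord.from_shifts(
            rec.protein, rec.position, rec.residue, wt, ko
        ))
    return out


def classify_sites(
    dd_records: Sequence[DeltaDeltaRecord],
    params: PipelineParams | None = None,
) -> list[SubstrateCall]:
    """Assign each quantified-in-both site one of the three ratio
    scenarios.

    In ``sd_based`` mode the threshold is sd_multiplier population SDs
    of the delta distribution about its mean, so "significant" means
    "an outlier relative to the dataset's own spread"; ``fixed`` mode
    uses ``dd_fixed_cutoff`` log2 units.
    """
    params = params or PipelineParams()
    bad = [r for r in dd_records if not math.isfinite(r.delta)]
    if bad:
        raise ValueError(
            "non-finite delta for "
            + ", ".join(f"{r.protein} {r.residue}{r.site}" for r in bad[:5])
        )
    if params.dd_cutoff_mode == "sd_based":
        if len(dd_records) < 3:
            raise ValueError(
                "sd_based thresholding needs >= 3 delta records; use "
                "dd_cutoff_mode='fixed' for small fixtures"
            )
        deltas = np.array([r.delta for r in dd_records])
        center = float(deltas.mean())
        threshold = params.sd_multiplier * float(deltas.std(ddof=0))
    else:
        center = 0.0
        threshold = params.dd_fixed_cutoff

    calls = []
    for rec in dd_records:
        excess = rec.delta - center
        if excess > threshold:
            scenario = "candidate_indirect"
        elif excess < -threshold:
            scenario = "candidate_direct"
        else:
            scenario = "independent"
        calls.append(SubstrateCall(
            protein=rec.protein, site=rec.site, residue=rec.residue,
            wt_shift=rec.wt_shift, ko_shift=rec.ko_shift, delta=rec.delta,
            scenario=scenario, threshold_used=threshold,
        ))
    return calls


def _detected_in_strain(
    rec: PhosphoSiteQuant, design: ExperimentDesign, strain: str,
    condition: str | None = None,
) -> bool:
    """Any non-missing intensity on a channel carrying this strain
    (optionally restricted to one condition), any experiment/replicate."""
    for exp in design.experiments:
        for channel, state in exp.channels.items():
            if state.strain != strain:
                continue
            if condition is not None and state.condition != condition:
                continue
            for rep in range(1, design.replicates + 1):
                if not is_missing(rec.intensity(exp.name, rep, channel)):
                    return True
    return False


def wt_only_sites(
    records: Iterable[PhosphoSiteQuant],
    design: ExperimentDesign,
    contrast: Contrast | None = None,
) -> list[SubstrateCall]:
    """Sites phosphorylated in the wild type in both conditions but
    with zero detections in the knockout, carrying their WT shift."""
    contrast = contrast or Contrast()
    calls = []
    for rec in records:
        if _detected_in_strain(rec, design, contrast.ko_strain):
            continue
        if not _detected_in_strain(rec, design, contrast.wt_strain,
                                   contrast.cond_from):
            continue
        if not _detected_in_strain(rec, design, contrast.wt_strain,
                                   contrast.cond_to):
            continue
        wt = shift_ratio(rec.intensities, design, contrast.wt_strain,
                         contrast.cond_to, contrast.cond_from)
        if wt is None:
            # detected in both conditions but never in the same replicate:
            # no within-run ratio exists, so no shift to report
            logger.warning(
                "site %s %s%d detected in both WT conditions but in "
                "disjoint replicates; skipped",
                rec.protein, rec.residue, rec.position,
            )
            continue
        calls.append(SubstrateCall(
            protein=rec.protein, site=rec.position, residue=rec.residue,
            wt_shift=wt.value, ko_shift=MISSING, delta=MISSING,
            scenario="wt_only", threshold_used=MISSING,
        ))
    return calls


def classify_phosphoproteome(
    records: Iterable[PhosphoSiteQuant],
    design: ExperimentDesign,
    contrast: Contrast | None = None,
    params: PipelineParams | None = None,
) -> tuple[list[SubstrateCall], list[SubstrateCall]]:
    """Full site pipeline: localization filter, then the ratio path for
    sites quantified in both strains and the presence/absence path for
    wild-type-only sites.

    Returns ``(quantified_calls, wt_only_calls)``; the two sets are
    disjoint by construction and together cover every localized site
    that is classifiable at all.
    """
    params = params or PipelineParams()
    contrast = contrast or Contrast()
    localized = [
        r for r in records if r.localization_prob >= params.localization_min
    ]
    dd = site_delta_records(localized, design, contrast)
    quantified = classify_sites(dd, params) if dd else []
    wt_only = wt_only_sites(localized, design, contrast)
    return quantified, wt_only
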