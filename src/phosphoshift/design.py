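"""SILAC experiment designs and the log-ratio algebra built on them.

A SILAC mix combines up to three metabolically labeled cultures
(light Lys0, medium Lys4, heavy Lys8) in one MS run, so per-analyte
channel intensities can be turned into ratios free of run-to-run
variation.  When several mixes share a *common reference channel* --
one (strain, condition) culture labeled identically in every mix --
every sample can be placed on a single ratio scale: any two channels
are comparable through the reference even if they never sat in the
same tube.

Two derived quantities drive the downstream analysis:

* the **shift ratio**: the log2 change of an analyte between two growth
  conditions within one strain (here glucose -> malate), averaged over
  biological replicates; and
* the **ratio of ratios** (*delta*): the knockout strain's shift minus
  the wild type's.  A delta near zero means the kinase has no influence
  on the site; a strongly negative delta marks a candidate direct
  substrate (the shift is attenuated or lost in the knockout); a
  strongly positive delta marks an indirect effect (the kinase normally
  restrains whichever kinase drives the site).

All ratios are log2 (the field convention for SILAC); the base is fixed
here, in one place, by :func:`log2_ratio`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CHANNELS",
    "CHANNEL_LETTERS",
    "LETTER_CHANNELS",
    "MISSING",
    "DesignError",
    "SampleState",
    "Experiment",
    "ExperimentDesign",
    "Contrast",
    "PipelineParams",
    "ShiftRatio",
    "DeltaDeltaRecord",
    "default_design",
    "is_missing",
    "log2_ratio",
    "shift_ratio",
    "delta_delta",
    "integrate_experiments",
]

#: The three lysine SILAC channels, in increasing mass order.
CHANNELS: tuple[str, ...] = ("Lys0", "Lys4", "Lys8")

#: Conventional single-letter channel names used in table headers.
CHANNEL_LETTERS: dict[str, str] = {"Lys0": "L", "Lys4": "M", "Lys8": "H"}
LETTER_CHANNELS: dict[str, str] = {v: k for k, v in CHANNEL_LETTERS.items()}

#: Canonical missing-value marker.  Missing intensities are never zero.
MISSING: float = float("nan")


def is_missing(value: object) -> bool:
    """True for None or NaN; intensities of zero are *not* missing (they
    are invalid and rejected upstream)."""
    if value is None:
        return True
    try:
        return math.isnan(float(value))  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return False


class DesignError(ValueError):
    """A request inconsistent with the experiment design."""


@dataclass(frozen=True, order=True)
class SampleState:
    """One biological sample: a strain grown under one condition."""

    strain: str
    condition: str

    def __post_init__(self) -> None:
        if not self.strain or not self.condition:
            raise DesignError("strain and condition must be non-empty")

    @classmethod
    def parse(cls, text: str) -> "SampleState":
        """Parse the ``strain:condition`` notation of design files."""
        strain, sep, condition = text.partition(":")
        if not sep:
            raise DesignError(
                f"expected 'strain:condition', got {text!r}"
            )
        return cls(strain.strip(), condition.strip())

    def __str__(self) -> str:
        return f"{self.strain}:{self.condition}"


@dataclass
class Experiment:
    """One SILAC mix: a mapping of channels to samples."""

    name: str
    channels: dict[str, SampleState]

    def __post_init__(self) -> None:
        for channel in self.channels:
            if channel not in CHANNELS:
                raise DesignError(
                    f"experiment {self.name!r}: unknown channel {channel!r} "
                    f"(expected one of {CHANNELS})"
                )
        states = list(self.channels.values())
        if len(set(states)) != len(states):
            raise DesignError(
                f"experiment {self.name!r}: a sample appears on two channels"
            )

    def channel_of(self, state: SampleState) -> str | None:
        for channel, s in self.channels.items():
            if s == state:
                return channel
        return None


@dataclass
class ExperimentDesign:
    """A set of SILAC experiments tied together by a common reference.

    The reference sample must be present on some channel of *every*
    experiment; it is what makes cross-experiment ratios well defined.
    """

    experiments: list[Experiment]
    reference: SampleState
    replicates: int = 2

    def __post_init__(self) -> None:
        if not self.experiments:
            raise DesignError("design needs at least one experiment")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")
        names = [e.name for e in self.experiments]
        if len(set(names)) != len(names):
            raise DesignError("experiment names must be unique")
        for exp in self.experiments:
            if exp.channel_of(self.reference) is None:
                raise DesignError(
                    f"reference sample {self.reference} missing from "
                    f"experiment {exp.name!r}"
                )

    # -- lookups ---------------------------------------------------------

    def experiment(self, name: str) -> Experiment:
        for exp in self.experiments:
            if exp.name == name:
                return exp
        raise DesignError(f"no experiment named {name!r}")

    def locate(self, state: SampleState) -> list[tuple[str, str]]:
        """All (experiment, channel) slots carrying ``state``."""
        return [
            (exp.name, chan)
            for exp in self.experiments
            if (chan := exp.channel_of(state)) is not None
        ]

    def coresident_pair(
        self, state_b: SampleState, state_a: SampleState
    ) -> tuple[str, str, str]:
        """Find an experiment holding both samples.

        Returns ``(experiment, channel_b, channel_a)`` for the first
        experiment (in design order) where both samples are mixed, so
        their ratio can be formed within a single MS run.
        """
        for exp in self.experiments:
            chan_b = exp.channel_of(state_b)
            chan_a = exp.channel_of(state_a)
            if chan_b is not None and chan_a is not None:
                return exp.name, chan_b, chan_a
        raise DesignError(
            f"samples {state_b} and {state_a} share no experiment"
        )

    def channel_slots(self) -> list[tuple[str, int, str]]:
        """All (experiment, replicate, channel) intensity slots, in the
        deterministic order used for table columns."""
        return [
            (exp.name, rep, chan)
            for exp in self.experiments
            for rep in range(1, self.replicates + 1)
            for chan in CHANNELS
            if chan in exp.channels
        ]

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_text(cls, text: str) -> "ExperimentDesign":
        """Parse the plain-text design format::

            reference = WT:glucose
            replicates = 2

            [exp1]
            Lys0 = WT:glucose
            Lys4 = WT:malate
        """
        reference: SampleState | None = None
        replicates = 1
        experiments: list[Experiment] = []
        current: Experiment | None = None
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = Experiment(name=line[1:-1].strip(), channels={})
                experiments.append(current)
                continue
            key, sep, value = (part.strip() for part in line.partition("="))
            if not sep:
                raise DesignError(f"line {lineno}: expected 'key = value'")
            if current is None:
                if key == "reference":
                    reference = SampleState.parse(value)
                elif key == "replicates":
                    replicates = int(value)
                else:
                    raise DesignError(f"line {lineno}: unknown key {key!r}")
            else:
                current.channels[key] = SampleState.parse(value)
        if reference is None:
            raise DesignError("design file declares no reference sample")
        # re-run per-experiment validation now channels are complete
        experiments = [Experiment(e.name, dict(e.channels)) for e in experiments]
        return cls(experiments=experiments, reference=reference,
                   replicates=replicates)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentDesign":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))

    def to_text(self) -> str:
        lines = [f"reference = {self.reference}",
                 f"replicates = {self.replicates}", ""]
        for exp in self.experiments:
            lines.append(f"[{exp.name}]")
            for chan in CHANNELS:
                if chan in exp.channels:
                    lines.append(f"{chan} = {exp.channels[chan]}")
            lines.append("")
        return "\n".join(lines)


@dataclass(frozen=True)
class Contrast:
    """Which strains and conditions the pipeline compares.

    The shift is ``cond_to`` over ``cond_from`` within each strain; the
    delta statistic is the knockout shift minus the wild-type shift.
    """

    wt_strain: str = "WT"
    ko_strain: str = "dYeaG"
    cond_from: str = "glucose"
    cond_to: str = "malate"

    def wt_pair(self) -> tuple[SampleState, SampleState]:
        return (SampleState(self.wt_strain, self.cond_to),
                SampleState(self.wt_strain, self.cond_from))

    def ko_pair(self) -> tuple[SampleState, SampleState]:
        return (SampleState(self.ko_strain, self.cond_to),
                SampleState(self.ko_strain, self.cond_from))


def default_design() -> ExperimentDesign:
    """The two-mix triple-SILAC layout of the glucose->malate study.

    Experiment 1 mixes wild type on glucose (Lys0, the common
    reference) with wild type shifted to malate (Lys4).  Experiment 2
    mixes the same reference with the kinase knockout on glucose (Lys4)
    and on malate (Lys8).  Biological duplicates.
    """
    wt_glu = SampleState("WT", "glucose")
    return ExperimentDesign(
        experiments=[
            Experiment("exp1", {"Lys0": wt_glu,
                                "Lys4": SampleState("WT", "malate")}),
            Experiment("exp2", {"Lys0": wt_glu,
                                "Lys4": SampleState("dYeaG", "glucose"),
                                "Lys8": SampleState("dYeaG", "malate")}),
        ],
        reference=wt_glu,
        replicates=2,
    )


@dataclass
class PipelineParams:
    """Tunable thresholds of the analysis.

    incorporation_min
        Minimum SILAC label incorporation accepted for a channel (0.94:
        below this, unlabeled carry-over distorts ratios).
    sd_multiplier
        Width of the differential cutoff in population SDs (2.0).
    localization_min
        Minimum phosphosite localization probability (0.75, the class-I
        convention).
    dd_cutoff_mode
        ``sd_based`` derives the delta threshold from the delta
        distribution itself (sd_multiplier x its SD); ``fixed`` uses
        ``dd_fixed_cutoff`` log2 units, for small fixtures.
    alpha
        Significance level for enrichment (0.05).
    mixing_tolerance
        Maximum |median log2 ratio| accepted by the 1:1 mixing check
        (0.5, i.e. 1.4-fold).
    """

    incorporation_min: float = 0.94
    sd_multiplier: float = 2.0
    localization_min: float = 0.75
    dd_cutoff_mode: str = "sd_based"
    dd_fixed_cutoff: float = 1.0
    alpha: float = 0.05
    mixing_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.incorporation_min <= 1.0:
            raise ValueError("incorporation_min must be in (0, 1]")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if not 0.0 <= self.localization_min <= 1.0:
            raise ValueError("localization_min must be in [0, 1]")
        if self.dd_cutoff_mode not in ("sd_based", "fixed"):
            raise ValueError("dd_cutoff_mode must be 'sd_based' or 'fixed'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mixing_tolerance < 0:
            raise ValueError("mixing_tolerance must be non-negative")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "PipelineParams":
        kwargs: dict[str, object] = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for key, value in mapping.items():
            if key not in fields:
                continue
            kwargs[key] = value if key == "dd_cutoff_mode" else float(value)
        return cls(**kwargs)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# ratio algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftRatio:
    """A strain's condition shift: mean per-replicate log2 ratio."""

    strain: str
    value: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not math.isfinite(self.value):
            raise ValueError("shift value must be finite")


@dataclass(frozen=True)
class DeltaDeltaRecord:
    """One phosphosite's ratio-of-ratios statistic.

    ``delta`` is always exactly ``ko_shift - wt_shift`` at full
    precision; any two-decimal rounding happens only at serialization.
    """

    protein: str
    site: int
    residue: str
    wt_shift: float
    ko_shift: float
    delta: float
    n_wt: int = 1
    n_ko: int = 1

    @classmethod
    def from_shifts(
        cls,
        protein: str,
        site: int,
        residue: str,
        wt: ShiftRatio,
        ko: ShiftRatio,
    ) -> "DeltaDeltaRecord":
        return cls(
            protein=protein,
            site=site,
            residue=residue,
            wt_shift=wt.value,
            ko_shift=ko.value,
            delta=delta_delta(wt, ko),
            n_wt=wt.n_replicates,
            n_ko=ko.n_replicates,
        )


def log2_ratio(numerator: float, denominator: float) -> float:
    """log2(numerator/denominator); missing (NaN) if either side is
    missing or non-positive.  Non-positive intensities signal a missing
    measurement, never raise."""
    if is_missing(numerator) or is_missing(denominator):
        return MISSING
    if numerator <= 0 or denominator <= 0:
        return MISSING
    return math.log2(numerator / denominator)


IntensityMap = Mapping[tuple[str, int, str], float]


def shift_ratio(
    intensities: IntensityMap,
    design: ExperimentDesign,
    strain: str,
    cond_b: str,
    cond_a: str,
) -> ShiftRatio | None:
    """Mean per-replicate log2(cond_b/cond_a) for one strain.

    Both conditions must sit in the same experiment (a design error
    otherwise); replicates where either channel is missing contribute
    nothing.  Returns None when no replicate has both channels.
    """
    exp, chan_b, chan_a = design.coresident_pair(
        SampleState(strain, cond_b), SampleState(strain, cond_a)
    )
    values = []
    for rep in range(1, design.replicates + 1):
        r = log2_ratio(
            intensities.get((exp, rep, chan_b), MISSING),
            intensities.get((exp, rep, chan_a), MISSING),
        )
        if not is_missing(r):
            values.append(r)
    if not values:
        return None
    return ShiftRatio(strain=strain, value=sum(values) / len(values),
                      n_replicates=len(values))


def delta_delta(wt: ShiftRatio | float, ko: ShiftRatio | float) -> float:
    """Knockout shift minus wild-type shift (a quotient of ratios,
    hence a difference on the log scale)."""
    wt_value = wt.value if isinstance(wt, ShiftRatio) else float(wt)
    ko_value = ko.value if isinstance(ko, ShiftRatio) else float(ko)
    if is_missing(wt_value) or is_missing(ko_value):
        return MISSING
    return ko_value - wt_value


def integrate_experiments(site_tables: Sequence[Iterable], design: ExperimentDesign) -> list:
    """Join per-experiment quantification tables on (protein, position,
    residue).

    Each input record needs ``key`` (the join key) and ``intensities``
    (slot -> value) attributes; the output carries one record per
    analyte with the union of all intensity slots.  Analytes absent
    from an experiment simply lack that experiment's slots (accessors
    report them as missing).  A duplicated (analyte, experiment,
    replicate, channel) slot is a hard error naming the key.
    """
    known = {exp.name for exp in design.experiments}
    merged: dict[tuple, object] = {}
    for table in site_tables:
        for record in table:
            for (exp, _rep, _chan) in record.intensities:
                if exp not in known:
                    raise DesignError(
                        f"record {record.key}: experiment {exp!r} not in design"
                    )
            existing = merged.get(record.key)
            if existing is None:
                merged[record.key] = replace(
                    record, intensities=dict(record.intensities)
                )
                continue
            overlap = set(existing.intensities) & set(record.intensities)
            if overlap:
                slot = sorted(overlap)[0]
                raise DesignError(
                    "duplicate quantification for analyte "
                    f"{record.key} at (experiment, replicate, channel) {slot}"
                )
            existing.intensities.update(record.intensities)
            loc = getattr(record, "localization_prob", None)
            if loc is not None and loc > getattr(existing, "localization_prob", loc):
                existing.localization_prob = loc
            if getattr(existing, "gene", None) is None and getattr(record, "gene", None):
                existing.gene = record.gene
    return list(merged.values())
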