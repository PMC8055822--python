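"""Readers and writers for the quantification-table dialect, GO
annotation (GAF 2.x) and result reports.

The quantification dialect is a deliberately minimal TSV contract: key
columns ``protein``, ``gene`` (optional), ``position``, ``residue``,
``localization_prob``, plus one intensity column per (channel,
experiment, replicate) named ``Intensity <L|M|H> <exp>_<rep>`` (L/M/H =
Lys0/Lys4/Lys8).  Missing intensities are empty cells or ``NA`` --
never zero.  A thin adapter maps the column names of genuine MaxQuant
``Phospho (STY)Sites.txt`` exports onto this dialect.

Log-ratio columns in reports are rounded to two decimals,
half-away-from-zero, at serialization only; in-memory values stay at
full precision.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, fields as dc_fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .design import (
    CHANNEL_LETTERS,
    LETTER_CHANNELS,
    MISSING,
    ExperimentDesign,
    is_missing,
)

logger = logging.getLogger(__name__)

RESIDUES = ("S", "T", "Y")

KEY_COLUMNS = ("protein", "position", "residue", "localization_prob")

INTENSITY_RE = re.compile(r"^Intensity ([LMH]) (.+)_(\d+)$")

#: GAF aspect codes -> the three GO ontologies.
GO_ASPECTS = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 0.005 -> 0.01, -0.005 -> -0.01)."""
    if is_missing(value):
        return MISSING
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum,
                                                      rounding=ROUND_HALF_UP))


def format_log2(value: float) -> str:
    """Two-decimal report formatting; empty string for missing."""
    if is_missing(value):
        return ""
    return f"{round_half_away(value, 2):.2f}"


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class PhosphoSiteQuant:
    """One phosphosite and its per-channel intensities.

    ``position`` is 1-based on the protein sequence; ``intensities``
    maps (experiment, replicate, channel) to a positive intensity, with
    absent slots meaning missing.
    """

    protein: str
    position: int
    residue: str
    gene: str | None = None
    localization_prob: float = 1.0
    intensities: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.protein}: position must be >= 1")
        if self.residue not in RESIDUES:
            raise ValueError(
                f"{self.protein} {self.position}: residue must be S, T or Y"
            )
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError("localization_prob must be in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.protein, self.position, self.residue)

    def intensity(self, experiment: str, replicate: int, channel: str) -> float:
        return self.intensities.get((experiment, replicate, channel), MISSING)


@dataclass
class ProteinQuant:
    """One protein's per-channel intensities (no site dimension)."""

    protein: str
    gene: str | None = None
    intensities: dict[tuple[str, int, str], float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str]:
        return (self.protein,)

    def intensity(self, experiment: str, replicate: int, channel: str) -> float:
        return self.intensities.get((experiment, replicate, channel), MISSING)


@dataclass
class GoAnnotation:
    """Gene -> {(GO term, category)} map from a GAF file."""

    by_gene: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    n_lines_skipped: int = 0

    def genes(self) -> set[str]:
        return set(self.by_gene)

    def terms(self, category: str | None = None) -> set[str]:
        return {
            term
            for annos in self.by_gene.values()
            for term, cat in annos
            if category is None or cat == category
        }

    def genes_for(self, term: str, category: str) -> set[str]:
        return {
            gene
            for gene, annos in self.by_gene.items()
            if (term, category) in annos
        }


@dataclass
class TableReadResult:
    """Records plus bookkeeping: every input row is either parsed or
    counted as rejected (rows_in == len(records) + n_rejected_rows)."""

    records: list
    n_rows: int = 0
    n_rejected_rows: int = 0
    n_unparsable_cells: int = 0


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------


def _intensity_columns(
    header: Sequence[str], design: ExperimentDesign
) -> dict[str, tuple[str, int, str]]:
    """Map intensity column names to (experiment, replicate, channel)."""
    known = {exp.name: exp for exp in design.experiments}
    slots: dict[str, tuple[str, int, str]] = {}
    for column in header:
        m = INTENSITY_RE.match(column)
        if not m:
            continue
        letter, exp, rep = m.groups()
        channel = LETTER_CHANNELS[letter]
        if exp not in known:
            raise ValueError(
                f"intensity column {column!r}: experiment {exp!r} "
                "is not in the design"
            )
        if channel not in known[exp].channels:
            raise ValueError(
                f"intensity column {column!r}: channel {channel} is not "
                f"mixed in experiment {exp!r}"
            )
        slots[column] = (exp, int(rep), channel)
    return slots


def _parse_intensity(cell: str | None) -> tuple[float, bool]:
    """Return (value, unparsable).  Empty / NA cells are missing but
    well formed; garbage and non-positive values are unparsable."""
    if cell is None:
        return MISSING, False
    text = cell.strip()
    if text == "" or text.upper() in ("NA", "NAN"):
        return MISSING, False
    try:
        value = float(text)
    except ValueError:
        return MISSING, True
    if not math.isfinite(value) or value <= 0:
        return MISSING, True
    return value, False


def read_site_table(
    path: str | Path, design: ExperimentDesign
) -> TableReadResult:
    """Read a phosphosite quantification table in the dialect above.

    Rows with a residue outside S/T/Y (or other invalid key fields) are
    rejected and counted; unparsable intensity cells become missing
    with a logged warning.  A missing key column is a hard error.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        missing_cols = [c for c in KEY_COLUMNS if c not in header]
        if missing_cols:
            raise ValueError(
                f"{path}: missing key column(s) {missing_cols}; expected "
                f"header with {list(KEY_COLUMNS)} plus "
                "'Intensity <L|M|H> <exp>_<rep>' columns"
            )
        slots = _intensity_columns(header, design)
        result = TableReadResult(records=[])
        for row in reader:
            result.n_rows += 1
            intensities: dict[tuple[str, int, str], float] = {}
            for column, slot in slots.items():
                value, bad = _parse_intensity(row.get(column))
                if bad:
                    result.n_unparsable_cells += 1
                    logger.warning(
                        "%s row %d: unparsable intensity %r in %s",
                        path, result.n_rows, row.get(column), column,
                    )
                if not is_missing(value):
                    intensities[slot] = value
            try:
                record = PhosphoSiteQuant(
                    protein=row["protein"].strip(),
                    gene=(row.get("gene") or "").strip() or None,
                    position=int(row["position"]),
                    residue=row["residue"].strip(),
                    localization_prob=float(row["localization_prob"]),
                    intensities=intensities,
                )
            except (ValueError, KeyError) as exc:
                result.n_rejected_rows += 1
                logger.warning("%s row %d rejected: %s", path,
                               result.n_rows, exc)
                continue
            result.records.append(record)
    return result


def read_protein_table(
    path: str | Path, design: ExperimentDesign
) -> TableReadResult:
    """Read a protein-level quantification table (``protein``, optional
    ``gene``, intensity columns as in the site dialect)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        if "protein" not in header:
            raise ValueError(f"{path}: missing key column 'protein'")
        slots = _intensity_columns(header, design)
        result = TableReadResult(records=[])
        for row in reader:
            result.n_rows += 1
            intensities = {}
            for column, slot in slots.items():
                value, bad = _parse_intensity(row.get(column))
                if bad:
                    result.n_unparsable_cells += 1
                if not is_missing(value):
                    intensities[slot] = value
            if not intensities:
                result.n_rejected_rows += 1
                logger.warning(
                    "%s row %d rejected: no quantified intensity",
                    path, result.n_rows,
                )
                continue
            result.records.append(
                ProteinQuant(
                    protein=row["protein"].strip(),
                    gene=(row.get("gene") or "").strip() or None,
                    intensities=intensities,
                )
            )
    return result


def _slot_column(slot: tuple[str, int, str]) -> str:
    exp, rep, channel = slot
    return f"Intensity {CHANNEL_LETTERS[channel]} {exp}_{rep}"


def write_site_table(
    records: Iterable[PhosphoSiteQuant],
    path: str | Path,
    design: ExperimentDesign,
) -> None:
    """Write phosphosite records back to the TSV dialect (full float
    precision; missing slots as empty cells)."""
    slots = design.channel_slots()
    columns = ["protein", "gene", "position", "residue",
               "localization_prob"] + [_slot_column(s) for s in slots]
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for rec in records:
            row = [rec.protein, rec.gene or "", rec.position, rec.residue,
                   f"{rec.localization_prob:g}"]
            for slot in slots:
                value = rec.intensities.get(slot, MISSING)
                row.append("" if is_missing(value) else f"{value:.10g}")
            writer.writerow(row)


def write_protein_table(
    records: Iterable[ProteinQuant],
    path: str | Path,
    design: ExperimentDesign,
) -> None:
    slots = design.channel_slots()
    columns = ["protein", "gene"] + [_slot_column(s) for s in slots]
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for rec in records:
            row = [rec.protein, rec.gene or ""]
            for slot in slots:
                value = rec.intensities.get(slot, MISSING)
                row.append("" if is_missing(value) else f"{value:.10g}")
            writer.writerow(row)


def maxquant_to_dialect(frame: pd.DataFrame) -> pd.DataFrame:
    """Rename genuine MaxQuant ``Phospho (STY)Sites.txt`` columns onto
    the dialect.

    Expects MaxQuant experiments to be named ``<exp>_<rep>`` so that
    ``Intensity L <exp>_<rep>`` columns carry replicate structure.
    Only the identity columns are renamed; intensity columns already
    match the dialect pattern.
    """
    renames = {
        "Protein": "protein",
        "Proteins": "protein",
        "Gene names": "gene",
        "Position": "position",
        "Amino acid": "residue",
        "Localization prob": "localization_prob",
    }
    present = {old: new for old, new in renames.items() if old in frame.columns}
    out = frame.rename(columns=present)
    keep = [c for c in out.columns
            if c in ("protein", "gene", "position", "residue",
                     "localization_prob") or INTENSITY_RE.match(c)]
    return out[keep]


# ---------------------------------------------------------------------------
# GAF
# ---------------------------------------------------------------------------


def read_gaf(path: str | Path) -> GoAnnotation:
    """Parse a GAF 2.x annotation file.

    Comment lines start with ``!``; data lines need >= 17 columns
    (shorter lines are skipped and counted).  Annotations are keyed by
    the DB object symbol (the gene symbol; falls back to the object
    identifier when the symbol is empty) and deduplicated.
    """
    annotation = GoAnnotation()
    with Path(path).open(encoding="utf-8") as handle:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            columns = line.rstrip("\n").split("\t")
            if len(columns) < 17:
                annotation.n_lines_skipped += 1
                continue
            symbol = columns[2].strip() or columns[1].strip()
            term = columns[4].strip()
            aspect = columns[8].strip()
            if not symbol or not term or aspect not in GO_ASPECTS:
                annotation.n_lines_skipped += 1
                continue
            annotation.by_gene.setdefault(symbol, set()).add(
                (term, GO_ASPECTS[aspect])
            )
    return annotation


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

#: Fields rendered at two decimals in reports.
_LOG2_FIELDS = {"wt_shift", "ko_shift", "delta", "median_log2",
                "cutoff_wt_low", "cutoff_wt_high", "cutoff_ko_low",
                "cutoff_ko_high", "threshold_used"}


def write_results(records: Sequence, path: str | Path) -> None:
    """Write a homogeneous list of result dataclasses as TSV.

    Column order follows the dataclass field order; log-ratio fields
    are rounded to two decimals half-away-from-zero.  An empty record
    list still produces a file, but only when the record type is known
    is a header possible -- so an empty list writes an empty header
    line's worth of nothing; prefer the typed writers below for
    header-only empties.
    """
    records = list(records)
    path = Path(path)
    if not records:
        path.write_text("", encoding="utf-8")
        return
    names = [f.name for f in dc_fields(records[0])]
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(names)
        for rec in records:
            row = []
            for name in names:
                value = getattr(rec, name)
                if name in _LOG2_FIELDS:
                    row.append(format_log2(value))
                elif isinstance(value, float):
                    row.append("" if is_missing(value) else f"{value:.6g}")
                elif value is None:
                    row.append("")
                else:
                    row.append(value)
            writer.writerow(row)


def write_typed_results(
    records: Sequence, path: str | Path, columns: Sequence[str]
) -> None:
    """Like :func:`write_results` but with an explicit column list, so
    an empty record set still yields a header-only file."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for rec in records:
            row = []
            for name in columns:
                value = getattr(rec, name)
                if name in _LOG2_FIELDS:
                    row.append(format_log2(value))
                elif isinstance(value, float):
                    row.append("" if is_missing(value) else f"{value:.6g}")
                elif value is None:
                    row.append("")
                else:
                    row.append(value)
            writer.writerow(row)


def read_delta_table(path: str | Path) -> pd.DataFrame:
    """Read back a delta report written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
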