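"""Synthetic triple-SILAC datasets with planted kinase effects.

The study this pipeline is built for deposited no raw data, so the
generator stands in for the instrument: it emits protein and
phosphosite quantification tables in the exact TSV dialect of
:mod:`phosphoshift.tables_io`, a label-incorporation QC table, and a
ground-truth table, all from one seeded random stream.

Generative model
----------------
* Two SILAC mixes sharing the wild-type/glucose Lys0 reference
  (:func:`phosphoshift.design.default_design`), biological duplicates.
* Per protein: a log-normal base abundance (log2 mean 20, SD 2,
  resembling orbitrap intensity scales) and a true glucose->malate
  expression shift ~ N(0, base_shift_sd); the knockout's shift adds a
  N(0, protein_strain_sd) strain effect.
* Per site: residue drawn S/T/Y with the observed phosphoproteome
  proportions (67.7 / 28.31 / 3.94 %, renormalized to sum to one); a
  true wild-type shift ~ N(0, base_shift_sd); a planted scenario --
  ``candidate_direct`` subtracts ``effect_log2`` from the knockout
  shift, ``candidate_indirect`` adds it, ``independent`` leaves the
  shifts equal, and ``wt_only`` deletes every knockout channel.
* Channel intensities are the base abundance times 2^(true shift),
  times per-cell log-normal noise 2^N(0, noise_sd); missingness is
  completely at random at ``missing_rate`` per cell.
* The QC table carries labeled/unlabeled intensity pairs whose
  fractions scatter tightly (SD 0.005) around the ``incorporation``
  parameter.

Draw order (fixed so determinism survives refactoring): protein
abundances, protein shifts, site->protein assignment, residues,
positions, scenarios, true site shifts, per-cell noise, missingness
mask, QC fractions.

The module also inverts *printed* result tables into noiseless input
fixtures: given published shift columns, it reconstructs channel
intensities that make the pipeline reproduce those shifts exactly --
the bundled reference tables from the E. coli YeaG kinase-knockout
glucose->malate study ship with the package for this purpose.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd

from .design import (
    Contrast,
    ExperimentDesign,
    default_design,
    is_missing,
)
from .tables_io import (
    PhosphoSiteQuant,
    ProteinQuant,
    write_protein_table,
    write_site_table,
)

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "invert_printed_table",
    "load_reference_shift_table",
    "load_reference_wt_only_table",
]

#: Published phosphoresidue proportions (S, T, Y); they print as
#: 67.7 / 28.31 / 3.94 % and sum to 0.9995, so they are renormalized.
_RAW_RESIDUE_PROBS = (0.677, 0.2831, 0.0394)
DEFAULT_RESIDUE_PROBS = tuple(
    p / sum(_RAW_RESIDUE_PROBS) for p in _RAW_RESIDUE_PROBS
)


@dataclass
class SyntheticParams:
    """Scenario parameters of the simulated study.

    Defaults emulate the study's scale: ~1772 quantified proteins with
    a mean of 127/1772 phosphosites per protein, biological duplicates,
    and planted effect classes roughly matching the published class
    sizes (one clearly attenuated site, several amplified ones, and
    ~12% presence/absence sites).
    """

    n_proteins: int = 1772
    sites_per_protein: float = 127 / 1772
    #: Exact total site count; overrides the Poisson draw when set.
    n_sites: int | None = None
    residue_probs: tuple[float, float, float] = DEFAULT_RESIDUE_PROBS
    frac_direct: float = 0.05
    frac_indirect: float = 0.10
    frac_wt_only: float = 0.12
    effect_log2: float = 2.0
    base_shift_sd: float = 1.0
    protein_strain_sd: float = 0.3
    noise_sd: float = 0.25
    missing_rate: float = 0.1
    incorporation: float = 0.98
    replicates: int = 2
    #: log2-scale location/spread of base abundances.
    abundance_log2_mean: float = 20.0
    abundance_log2_sd: float = 2.0
    n_qc_analytes: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.residue_probs) - 1.0) > 1e-9:
            raise ValueError("residue_probs must sum to 1 (within 1e-9)")
        planted = self.frac_direct + self.frac_indirect + self.frac_wt_only
        if planted > 1.0:
            raise ValueError("planted scenario fractions sum to more than 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth: per-site scenario and shifts, per-protein shifts."""

    sites: pd.DataFrame     # protein, position, residue, true_wt_shift,
                            # true_ko_shift, scenario
    proteins: pd.DataFrame  # protein, true_wt_shift, true_ko_shift


@dataclass
class SyntheticDataset:
    design: ExperimentDesign
    protein_records: list[ProteinQuant]
    site_records: list[PhosphoSiteQuant]
    qc_table: pd.DataFrame
    truth: GroundTruth

    def to_directory(self, path: str | Path) -> dict[str, Path]:
        """Write all tables (TSV) plus the design file; deterministic
        bytes for a given params+seed."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "design": out / "design.txt",
            "proteins": out / "proteins.tsv",
            "sites": out / "sites.tsv",
            "qc": out / "qc.tsv",
            "truth_sites": out / "truth_sites.tsv",
            "truth_proteins": out / "truth_proteins.tsv",
        }
        paths["design"].write_text(self.design.to_text(), encoding="utf-8")
        write_protein_table(self.protein_records, paths["proteins"],
                            self.design)
        write_site_table(self.site_records, paths["sites"], self.design)
        self.qc_table.to_csv(paths["qc"], sep="\t", index=False,
                             float_format="%.10g")
        self.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False,
                                float_format="%.10g")
        self.truth.proteins.to_csv(paths["truth_proteins"], sep="\t",
                                   index=False, float_format="%.10g")
        return paths


def _state_shift(
    state, contrast: Contrast, wt_shift: float, ko_shift: float
) -> float:
    """True log2 offset of a sample relative to the reference
    (wild type on the pre-shift carbon source)."""
    if state.condition == contrast.cond_from:
        return 0.0
    return wt_shift if state.strain == contrast.wt_strain else ko_shift


def generate(params: SyntheticParams | None = None) -> SyntheticDataset:
    """Simulate one complete triple-SILAC study.

    Same params (including seed) => identical records and, through
    :meth:`SyntheticDataset.to_directory`, byte-identical files.
    """
    params = params or SyntheticParams()
    design = default_design()
    design.replicates = params.replicates
    contrast = Contrast()
    rng = np.random.default_rng(params.seed)

    # --- proteins ---------------------------------------------------------
    n_prot = params.n_proteins
    names = [f"P{i + 1:05d}" for i in range(n_prot)]
    base_log2 = rng.normal(params.abundance_log2_mean,
                           params.abundance_log2_sd, n_prot)
    prot_wt = rng.normal(0.0, params.base_shift_sd, n_prot)
    prot_ko = prot_wt + rng.normal(0.0, params.protein_strain_sd, n_prot)

    # --- site placement ---------------------------------------------------
    if params.n_sites is not None:
        owners = rng.integers(0, n_prot, params.n_sites)
    else:
        counts = rng.poisson(params.sites_per_protein, n_prot)
        owners = np.repeat(np.arange(n_prot), counts)
    n_sites = len(owners)
    residues = rng.choice(np.array(["S", "T", "Y"]), size=n_sites,
                          p=np.array(params.residue_probs))
    # unique positions per protein: consecutive slots in a shuffled range
    positions = np.empty(n_sites, dtype=int)
    order = np.argsort(owners, kind="stable")
    rank_within = np.empty(n_sites, dtype=int)
    seen: dict[int, int] = {}
    for idx in order:
        seen[owners[idx]] = seen.get(owners[idx], 0) + 1
        rank_within[idx] = seen[owners[idx]]
    offsets = rng.integers(1, 20, n_sites)
    positions = rank_within * 25 + offsets  # distinct within a protein

    scenario_pool = np.array(
        ["candidate_direct", "candidate_indirect", "wt_only", "independent"]
    )
    probs = np.array([
        params.frac_direct, params.frac_indirect, params.frac_wt_only,
        1.0 - params.frac_direct - params.frac_indirect - params.frac_wt_only,
    ])
    scenarios = rng.choice(scenario_pool, size=n_sites, p=probs)

    site_wt = rng.normal(0.0, params.base_shift_sd, n_sites)
    effect = np.where(
        scenarios == "candidate_direct", -params.effect_log2,
        np.where(scenarios == "candidate_indirect", params.effect_log2, 0.0),
    )
    site_ko = site_wt + effect
    site_ko_truth = np.where(scenarios == "wt_only", np.nan, site_ko)
    site_base = base_log2[owners] + rng.normal(0.0, 1.0, n_sites)

    # --- intensity tables -------------------------------------------------
    slots = design.channel_slots()
    n_slots = len(slots)

    def build_cells(base, wt_sh, ko_sh, wt_only_mask):
        n_rows = len(base)
        noise = rng.normal(0.0, params.noise_sd, (n_rows, n_slots))
        drop = rng.random((n_rows, n_slots)) < params.missing_rate
        cells = np.empty((n_rows, n_slots))
        for j, (exp, _rep, chan) in enumerate(slots):
            state = design.experiment(exp).channels[chan]
            shift = np.array([
                _state_shift(state, contrast, w, k)
                for w, k in zip(wt_sh, ko_sh)
            ])
            cells[:, j] = 2.0 ** (base + shift + noise[:, j])
            if state.strain == contrast.ko_strain:
                cells[wt_only_mask, j] = np.nan
        cells[drop] = np.nan
        return cells

    prot_cells = build_cells(base_log2, prot_wt, prot_ko,
                             np.zeros(n_prot, dtype=bool))
    site_cells = build_cells(site_base, site_wt, site_ko,
                             scenarios == "wt_only")

    protein_records = []
    for i, name in enumerate(names):
        intensities = {
            slot: float(prot_cells[i, j])
            for j, slot in enumerate(slots)
            if not np.isnan(prot_cells[i, j])
        }
        if intensities:
            protein_records.append(ProteinQuant(protein=name,
                                                intensities=intensities))

    site_records = []
    for i in range(n_sites):
        intensities = {
            slot: float(site_cells[i, j])
            for j, slot in enumerate(slots)
            if not np.isnan(site_cells[i, j])
        }
        site_records.append(PhosphoSiteQuant(
            protein=names[owners[i]],
            position=int(positions[i]),
            residue=str(residues[i]),
            localization_prob=1.0,
            intensities=intensities,
        ))

    # --- QC table ---------------------------------------------------------
    qc_rows = []
    for exp in design.experiments:
        for channel in ("Lys4", "Lys8"):
            if channel not in exp.channels:
                continue
            totals = 2.0 ** rng.normal(params.abundance_log2_mean,
                                       params.abundance_log2_sd,
                                       params.n_qc_analytes)
            fracs = np.clip(
                rng.normal(params.incorporation, 0.005,
                           params.n_qc_analytes),
                0.0, 1.0,
            )
            for a in range(params.n_qc_analytes):
                qc_rows.append({
                    "experiment": exp.name,
                    "channel": channel,
                    "analyte": f"QC{a + 1:04d}",
                    "labeled_intensity": totals[a] * fracs[a],
                    "unlabeled_intensity": totals[a] * (1.0 - fracs[a]),
                })
    qc_table = pd.DataFrame(
        qc_rows, columns=["experiment", "channel", "analyte",
                          "labeled_intensity", "unlabeled_intensity"]
    )

    truth = GroundTruth(
        sites=pd.DataFrame({
            "protein": [names[o] for o in owners],
            "position": positions,
            "residue": residues,
            "true_wt_shift": site_wt,
            "true_ko_shift": site_ko_truth,
            "scenario": scenarios,
        }),
        proteins=pd.DataFrame({
            "protein": names,
            "true_wt_shift": prot_wt,
            "true_ko_shift": prot_ko,
        }),
    )
    return SyntheticDataset(
        design=design,
        protein_records=protein_records,
        site_records=site_records,
        qc_table=qc_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# printed-table inversion
# ---------------------------------------------------------------------------

_SITE_RE = re.compile(r"^([STY])(\d+)$")


def _parse_site(label: str) -> tuple[str, int]:
    m = _SITE_RE.match(label.strip())
    if not m:
        raise ValueError(f"site label {label!r} is not like 'S398'")
    return m.group(1), int(m.group(2))


def invert_printed_table(
    rows: pd.DataFrame,
    design: ExperimentDesign | None = None,
    contrast: Contrast | None = None,
    reference_intensity: float = 1000.0,
) -> list[PhosphoSiteQuant]:
    """Turn published shift columns back into noiseless channel
    intensities.

    ``rows`` needs columns ``protein``, ``site`` (e.g. ``Y55``) and
    ``wt_shift``; an optional ``ko_shift`` column, where missing, marks
    wild-type-only sites whose knockout channels are emitted as
    missing.  Reference-condition channels are pinned at
    ``reference_intensity`` and shifted-condition channels scaled by
    2^shift, in replicate 1 only, so the pipeline recovers the printed
    shifts exactly.
    """
    design = design or default_design()
    contrast = contrast or Contrast()
    records = []
    has_ko = "ko_shift" in rows.columns
    for row in rows.itertuples(index=False):
        residue, position = _parse_site(row.site)
        wt_shift = float(row.wt_shift)
        ko_shift = float(row.ko_shift) if has_ko else float("nan")
        intensities: dict[tuple[str, int, str], float] = {}
        for exp in design.experiments:
            for channel, state in exp.channels.items():
                if state.strain == contrast.ko_strain:
                    shift = ko_shift
                elif state.condition == contrast.cond_to:
                    shift = wt_shift
                else:
                    shift = 0.0
                if state.strain == contrast.ko_strain and is_missing(ko_shift):
                    continue  # wt-only row: no knockout channels at all
                if state.condition == contrast.cond_from:
                    shift = 0.0
                intensities[(exp.name, 1, channel)] = (
                    reference_intensity * 2.0 ** shift
                )
        records.append(PhosphoSiteQuant(
            protein=str(row.protein),
            position=position,
            residue=residue,
            localization_prob=1.0,
            intensities=intensities,
        ))
    return records


def _load_data_table(name: str) -> pd.DataFrame:
    with resources.files("phosphoshift.data").joinpath(name).open(
        encoding="utf-8"
    ) as handle:
        return pd.read_csv(handle, sep="\t")


def load_reference_shift_table() -> pd.DataFrame:
    """The published 36-site table of glucose->malate shifts quantified
    in both strains (columns protein, site, wt_shift, ko_shift, delta
    as printed)."""
    return _load_data_table("yeag_shift_table.tsv")


def load_reference_wt_only_table() -> pd.DataFrame:
    """The published 15-row table of sites phosphorylated in the wild
    type in both conditions but undetected in the knockout (columns
    function, protein, site, wt_shift)."""
    return _load_data_table("yeag_wt_only_table.tsv")
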