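"""Synthetic data generation for the quantification pipeline.

Everything the downstream stages consume can be generated here: a spiked
dilution-standard registry (a UPS-2-like ladder of 48 proteins spanning
0.5-50,000 fmol), technical-replicate intensity tables for calibration, a
five-group pregnancy cohort whose marker concentrations follow the published
group means +/- SD, and a peptide-level intensity table produced by a forward
model that is the exact inverse of the quantification path (so noiseless
round trips are identities).

Intensity response model
------------------------
A protein at final concentration C (fmol/uL) produces a normalized total
intensity

    I = 10**intercept * C**slope * eps,   eps ~ lognormal, E[eps] = 1

i.e. a straight line in log10-log10 space, which is the minimal model
consistent with a linear log-log calibration. Detection is subject to a
logistic dropout in log on-column amount.

All randomness flows from explicit seeds; identical configuration and seed
give byte-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue mass used to invent sequence lengths for synthetic proteins.
_MEAN_RESIDUE_MASS = 110.0

#: fmol of ladder stock per uL of working dilution (the 0.5-50,000 fmol
#: ladder reconstitutes to a 0.05-5,000 fmol/uL working solution).
WORKING_DILUTION = 10.0

#: Default injection volume (uL) mapping fmol/uL to on-column fmol.
INJECTION_UL = 2.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardProtein:
    """One protein of the spiked dilution standard."""

    protein_id: str
    amount_fmol: float
    mw_da: float
    length_aa: int

    def __post_init__(self) -> None:
        if self.amount_fmol <= 0:
            raise ValidationError(f"{self.protein_id}: amount_fmol must be > 0")
        if self.mw_da <= 0:
            raise ValidationError(f"{self.protein_id}: mw_da must be > 0")
        if self.length_aa <= 0:
            raise ValidationError(f"{self.protein_id}: length_aa must be > 0")


@dataclass(frozen=True)
class StandardRegistry:
    """The full spiked standard: proteins plus the total protein mass."""

    proteins: tuple[StandardProtein, ...]
    total_mass_ug: float

    def __post_init__(self) -> None:
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate protein_id in standard registry")

    def __len__(self) -> int:
        return len(self.proteins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [p.protein_id for p in self.proteins],
                "amount_fmol": [p.amount_fmol for p in self.proteins],
                "mw_da": [p.mw_da for p in self.proteins],
                "length_aa": [p.length_aa for p in self.proteins],
            }
        )

    @property
    def total_mass_check_ug(self) -> float:
        """Sum of amount_fmol * mw_da converted to micrograms."""
        return sum(p.amount_fmol * p.mw_da for p in self.proteins) * 1e-9


@dataclass(frozen=True)
class NoiseModel:
    """Noise and detection parameters shared by all generators.

    replicate_cv
        Relative SD of technical replicates (multiplicative lognormal).
    biological_cv
        Extra per-subject multiplicative noise applied in the forward model.
    dropout_midpoint_fmol
        On-column amount at 50% detection probability; 0 disables dropout.
    dropout_steepness
        Slope of the logistic dropout in log on-column amount.
    """

    replicate_cv: float = 0.10
    biological_cv: float = 0.10
    dropout_midpoint_fmol: float = 0.002
    dropout_steepness: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_cv < 0 or self.biological_cv < 0:
            raise ValidationError("noise CVs must be >= 0")
        if not np.isfinite(self.dropout_midpoint_fmol) or not np.isfinite(
            self.dropout_steepness
        ):
            raise ValidationError("dropout parameters must be finite")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, outcome label and marker distributions.

    ``marker_params`` maps marker name to (mean, sd) in that marker's
    printed unit (see :data:`MARKERS` for units).
    """

    group_id: str
    n: int
    df_positive: bool
    marker_params: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError(f"{self.group_id}: n must be > 0")
        for marker, (_, sd) in self.marker_params.items():
            if sd < 0:
                raise ValidationError(f"{self.group_id}/{marker}: sd must be >= 0")


@dataclass(frozen=True)
class CurveTruth:
    """Generating parameters of the intensity response line (log10-log10)."""

    slope: float = 1.0
    intercept: float = -6.0  # log10 normalized intensity at 1 fmol/uL

    @property
    def gain(self) -> float:
        return 10.0 ** self.intercept


@dataclass(frozen=True)
class MarkerInfo:
    """Physical constants and display unit for one plasma marker."""

    protein_id: str
    uniprot: str
    mw_da: float
    length_aa: int
    unit: str           # unit the printed concentrations use
    to_ng_ml: float     # multiply a value in `unit` by this to get ng/mL


# ---------------------------------------------------------------------------
# study defaults: the published cohort
# ---------------------------------------------------------------------------

#: Circulating-species molecular masses: monomer averages for CRP, CEACAM1
#: and CNDP1; assembled antibody masses for immunoglobulins (IgM as the
#: serum pentamer), since the printed mg/mL values refer to whole antibody.
MARKERS: dict[str, MarkerInfo] = {
    "CRP": MarkerInfo("CRP", "P02741", 25_039.0, 224, "ug/mL", 1e3),
    "CEACAM1": MarkerInfo("CEACAM1", "P13688", 57_560.0, 526, "ng/mL", 1.0),
    "CNDP1": MarkerInfo("CNDP1", "Q96KN2", 56_705.0, 507, "ng/mL", 1.0),
    "IGHG1": MarkerInfo("IGHG1", "P01857", 146_000.0, 1320, "mg/mL", 1e6),
    "IGHG2": MarkerInfo("IGHG2", "P01859", 146_000.0, 1320, "mg/mL", 1e6),
    "IGHG3": MarkerInfo("IGHG3", "P01860", 165_000.0, 1500, "mg/mL", 1e6),
    "IGHG4": MarkerInfo("IGHG4", "P01861", 146_000.0, 1320, "mg/mL", 1e6),
    "IGHM": MarkerInfo("IGHM", "P01871", 970_000.0, 8800, "mg/mL", 1e6),
    "IGHA1": MarkerInfo("IGHA1", "P01876", 160_000.0, 1450, "mg/mL", 1e6),
    "IGHA2": MarkerInfo("IGHA2", "P01877", 160_000.0, 1450, "mg/mL", 1e6),
}

#: Published per-group marker means +/- SD, in each marker's printed unit.
#: Keys G01/G02 = gestational diabetes (normal course / fetopathy),
#: G03/G04 = type 2 diabetes (normal course / fetopathy), G05 = control.
_GROUP_MARKER_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "G01": {
        "CRP": (2.04, 1.32), "CEACAM1": (291.62, 34.55), "CNDP1": (32.4, 5.23),
        "IGHG1": (8.84, 1.22), "IGHG2": (2.27, 0.41), "IGHG3": (2.06, 0.49),
        "IGHG4": (2.12, 0.42), "IGHM": (1.87, 0.31), "IGHA1": (1.42, 0.26),
        "IGHA2": (0.41, 0.08),
    },
    "G02": {
        "CRP": (5.29, 1.82), "CEACAM1": (113.18, 16.23), "CNDP1": (49.3, 5.18),
        "IGHG1": (7.81, 1.69), "IGHG2": (2.43, 0.37), "IGHG3": (2.12, 0.38),
        "IGHG4": (1.85, 0.36), "IGHM": (1.67, 0.20), "IGHA1": (1.98, 0.14),
        "IGHA2": (0.52, 0.04),
    },
    "G03": {
        "CRP": (2.84, 0.67), "CEACAM1": (311.17, 42.16), "CNDP1": (27.4, 2.63),
        "IGHG1": (8.26, 2.09), "IGHG2": (2.54, 0.31), "IGHG3": (1.87, 0.24),
        "IGHG4": (2.08, 0.49), "IGHM": (1.93, 0.26), "IGHA1": (1.39, 0.19),
        "IGHA2": (0.38, 0.07),
    },
    "G04": {
        "CRP": (4.21, 1.37), "CEACAM1": (81.09, 10.54), "CNDP1": (37.7, 3.34),
        "IGHG1": (7.65, 2.13), "IGHG2": (2.37, 0.22), "IGHG3": (2.05, 0.38),
        "IGHG4": (1.81, 0.41), "IGHM": (1.71, 0.17), "IGHA1": (1.55, 0.28),
        "IGHA2": (0.46, 0.07),
    },
    "G05": {
        "CRP": (1.97, 0.71), "CEACAM1": (515.6, 72.14), "CNDP1": (17.1, 4.31),
        "IGHG1": (7.07, 1.99), "IGHG2": (2.11, 0.14), "IGHG3": (1.93, 0.65),
        "IGHG4": (2.64, 0.98), "IGHM": (1.34, 0.12), "IGHA1": (1.31, 0.23),
        "IGHA2": (0.23, 0.09),
    },
}

_GROUP_SIZES = {"G01": 43, "G02": 37, "G03": 34, "G04": 29, "G05": 36}
DF_GROUPS = ("G02", "G04")

#: The five markers combined into the fetopathy panel.
PANEL_MARKERS = ("CEACAM1", "CNDP1", "CRP", "IGHG4", "IGHA2")

GROUP_DM_TYPE = {"G01": "GDM", "G02": "GDM", "G03": "T2DM", "G04": "T2DM",
                 "G05": "none"}

#: Fraction of gestational-diabetes patients managed with insulin (the rest
#: by dietary intervention); type 2 patients are all insulin-treated.
GDM_INSULIN_FRACTION = 0.27


def default_group_specs(
    markers: Sequence[str] | None = None,
) -> list[GroupSpec]:
    """The published five-group cohort as :class:`GroupSpec` objects."""
    markers = tuple(markers) if markers is not None else tuple(MARKERS)
    specs = []
    for gid, size in _GROUP_SIZES.items():
        params = {m: _GROUP_MARKER_TABLE[gid][m] for m in markers}
        specs.append(
            GroupSpec(gid, size, df_positive=gid in DF_GROUPS,
                      marker_params=params)
        )
    return specs


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------

_STAGE_KEYS = {"registry": 11, "calibration": 23, "cohort": 37, "forward": 53}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and relative SD cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _detection_probability(
    on_column_fmol: np.ndarray, noise: NoiseModel
) -> np.ndarray:
    if noise.dropout_midpoint_fmol <= 0:
        return np.ones_like(np.asarray(on_column_fmol, dtype=float))
    x = np.log(np.asarray(on_column_fmol, dtype=float)
               / noise.dropout_midpoint_fmol)
    return expit(noise.dropout_steepness * x)


# ---------------------------------------------------------------------------
# standards
# ---------------------------------------------------------------------------

def build_ups2_registry(
    n_tiers: int = 6,
    proteins_per_tier: int = 8,
    min_fmol: float = 0.5,
    max_fmol: float = 50_000.0,
    total_mass_ug: float = 10.6,
) -> StandardRegistry:
    """Build a dilution-standard registry as a geometric amount ladder.

    Amounts run from ``max_fmol`` down to ``min_fmol`` in ``n_tiers``
    geometric steps with ``proteins_per_tier`` proteins per tier (the
    commercial standard is 6 tiers x 8 proteins, 50,000 ... 0.5 fmol).
    Synthetic molecular masses are rescaled so the total protein mass,
    sum(amount_fmol * mw_da) * 1e-9 ug, equals ``total_mass_ug``.
    """
    if n_tiers < 2 or proteins_per_tier < 1:
        raise ValidationError("n_tiers must be >= 2 and proteins_per_tier >= 1")
    if min_fmol <= 0 or max_fmol <= 0 or min_fmol >= max_fmol:
        raise ValidationError("need 0 < min_fmol < max_fmol")
    if total_mass_ug <= 0:
        raise ValidationError("total_mass_ug must be > 0")

    ratio = (min_fmol / max_fmol) ** (1.0 / (n_tiers - 1))
    tier_amounts = max_fmol * ratio ** np.arange(n_tiers)
    tier_amounts[-1] = min_fmol  # exact endpoints

    # Deterministic spread of masses across a plasma-like 10-80 kDa range.
    n = n_tiers * proteins_per_tier
    base_mw = np.logspace(np.log10(10_000), np.log10(80_000), n)
    amounts = np.repeat(tier_amounts, proteins_per_tier)
    scale = total_mass_ug / (float(np.dot(amounts, base_mw)) * 1e-9)
    mw = base_mw * scale

    proteins = tuple(
        StandardProtein(
            protein_id=f"STD{idx + 1:03d}",
            amount_fmol=float(amounts[idx]),
            mw_da=float(mw[idx]),
            length_aa=max(1, int(round(mw[idx] / _MEAN_RESIDUE_MASS))),
        )
        for idx in range(n)
    )
    return StandardRegistry(proteins=proteins, total_mass_ug=total_mass_ug)


def simulate_calibration_replicates(
    registry: StandardRegistry,
    spike_ratio: float = 0.1,
    n_replicates: int = 6,
    noise: NoiseModel = NoiseModel(),
    truth: CurveTruth = CurveTruth(),
    injection_ul: float = INJECTION_UL,
) -> pd.DataFrame:
    """Simulate technical-replicate intensities of the spiked standard.

    The registry amounts are taken to a working dilution (amount /
    :data:`WORKING_DILUTION` fmol/uL) and spiked into the background matrix
    at ``spike_ratio``, giving a final nominal concentration per protein.
    Each replicate draws a lognormal multiplicative error with relative SD
    ``noise.replicate_cv``; detection follows the logistic dropout model in
    on-column amount. Only detected replicates appear as rows.

    Returns a tidy frame: protein_id, replicate, amount_fmol,
    nominal_conc_fmol_ul, intensity.
    """
    if not 0 < spike_ratio <= 1:
        raise ValidationError("spike_ratio must be in (0, 1]")
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    if len(registry) == 0:
        raise ValidationError("empty standard registry")

    rng = _rng(noise.seed, "calibration")
    rows = []
    for p in registry.proteins:
        conc = p.amount_fmol / WORKING_DILUTION * spike_ratio
        mean_intensity = truth.gain * conc ** truth.slope
        eps = _lognormal_factor(rng, noise.replicate_cv, n_replicates)
        p_detect = _detection_probability(
            np.array(conc * injection_ul), noise
        )
        detected = rng.random(n_replicates) < p_detect
        for r in range(n_replicates):
            if detected[r]:
                rows.append(
                    (p.protein_id, r + 1, p.amount_fmol, conc,
                     mean_intensity * eps[r])
                )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "replicate", "amount_fmol",
                 "nominal_conc_fmol_ul", "intensity"],
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    specs: Sequence[GroupSpec] | None = None,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Draw a subject-level cohort from per-group marker distributions.

    Each subject's marker concentration is a zero-truncated normal with the
    group's (mean, sd) in the marker's printed unit. Returns a frame indexed
    by sample_id with columns group, dm_type, df_status, treatment and one
    column per marker.
    """
    if specs is None:
        specs = default_group_specs()
    if not specs:
        raise ValidationError("no group specs given")
    marker_sets = {tuple(sorted(s.marker_params)) for s in specs}
    if len(marker_sets) != 1:
        raise ValidationError("marker_params keys differ across groups")
    markers = sorted(specs[0].marker_params)

    rng = _rng(noise.seed, "cohort")
    records = []
    for spec in specs:
        dm = GROUP_DM_TYPE.get(spec.group_id, "none")
        for i in range(spec.n):
            sample_id = f"{spec.group_id}_S{i + 1:03d}"
            if dm == "GDM":
                treatment = ("insulin"
                             if rng.random() < GDM_INSULIN_FRACTION
                             else "diet")
            elif dm == "T2DM":
                treatment = "insulin"
            else:
                treatment = "none"
            row = {
                "sample_id": sample_id,
                "group": spec.group_id,
                "dm_type": dm,
                "df_status": spec.df_positive,
                "treatment": treatment,
            }
            for m in markers:
                mean, sd = spec.marker_params[m]
                if sd == 0:
                    row[m] = mean
                else:
                    a = (0.0 - mean) / sd  # truncate at zero
                    row[m] = float(
                        truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                      random_state=rng)
                    )
            records.append(row)
    return pd.DataFrame.from_records(records).set_index("sample_id")


def manifest_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extract the sample manifest (labels only) from a cohort table."""
    return cohort[["group", "dm_type", "df_status", "treatment"]].reset_index()


# ---------------------------------------------------------------------------
# forward model to peptide intensities
# ---------------------------------------------------------------------------

def _peptide_rng(protein_id: str) -> np.random.Generator:
    # stable across processes: CRC32 of the id, not Python's salted hash
    return np.random.default_rng(zlib.crc32(protein_id.encode()) & 0x7FFFFFFF)


def default_peptide_map(
    markers: Sequence[str] | None = None, peptides_per_protein: int = 3
) -> dict[str, tuple[str, ...]]:
    """Deterministic synthetic proteotypic peptides for each marker."""
    markers = tuple(markers) if markers is not None else tuple(MARKERS)
    out: dict[str, tuple[str, ...]] = {}
    for pid in markers:
        rng = _peptide_rng(pid)
        peps = []
        for _ in range(peptides_per_protein):
            length = int(rng.integers(8, 15))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length)) + "K"
            peps.append(seq)
        out[pid] = tuple(peps)
    return out


BACKGROUND_ID = "BACKGROUND"
_BACKGROUND_PEPTIDE = "GASSPLENDIDK"

#: Scale from normalized-intensity fraction to expected spectral counts.
_SPC_PER_FRACTION = 1e5


def forward_model_intensities(
    cohort: pd.DataFrame,
    curve_truth: CurveTruth = CurveTruth(),
    peptide_map: Mapping[str, Sequence[str]] | None = None,
    noise: NoiseModel = NoiseModel(),
    markers: Mapping[str, MarkerInfo] | None = None,
    total_intensity: float = 1e9,
    injection_ul: float = INJECTION_UL,
) -> pd.DataFrame:
    """Generate a peptide intensity table whose quantification inverts to
    the cohort's concentrations.

    Per sample and marker the true concentration (converted to fmol/uL via
    the marker's molecular mass) is pushed through the generating response
    line to a normalized-intensity fraction, multiplied by per-subject
    lognormal noise (``biological_cv``), and distributed over the marker's
    proteotypic peptides. A single background protein absorbs the remaining
    intensity so the per-sample total is exactly ``total_intensity`` and
    normalization recovers the intended fractions. Spectral counts are
    proportional to intensity (for abundance-ranking tests).
    """
    markers = dict(markers) if markers is not None else MARKERS
    marker_cols = [c for c in cohort.columns
                   if c not in ("group", "dm_type", "df_status", "treatment")]
    if peptide_map is None:
        peptide_map = default_peptide_map(marker_cols)
    for m in marker_cols:
        if m not in peptide_map or len(peptide_map[m]) == 0:
            raise ValidationError(f"marker {m!r} missing from peptide_map")
        if m not in markers:
            raise ValidationError(f"marker {m!r} missing molecular-mass info")

    rng = _rng(noise.seed, "forward")
    rows = []
    for sample_id, subject in cohort.iterrows():
        marker_total = 0.0
        sample_rows = []
        for m in marker_cols:
            info = markers[m]
            conc_native = float(subject[m])
            if conc_native <= 0:
                continue  # absent marker: no peptide rows
            conc_ng_ml = conc_native * info.to_ng_ml
            conc_fmol_ul = conc_ng_ml / (info.mw_da * 1e-3)
            p_det = float(
                _detection_probability(
                    np.array(conc_fmol_ul * injection_ul), noise
                )
            )
            if rng.random() >= p_det:
                continue  # dropped out entirely in this sample
            frac = (
                curve_truth.gain
                * conc_fmol_ul ** curve_truth.slope
                * float(_lognormal_factor(rng, noise.biological_cv, ()))
            )
            protein_intensity = frac * total_intensity
            peptides = peptide_map[m]
            share = protein_intensity / len(peptides)
            for pep in peptides:
                spc = max(1, int(round(share / total_intensity
                                       * _SPC_PER_FRACTION)))
                sample_rows.append((sample_id, m, pep, share, spc))
            marker_total += protein_intensity
        background = total_intensity - marker_total
        if background <= 0:
            raise ValidationError(
                f"{sample_id}: marker intensities exceed the total budget; "
                "lower the response gain or raise total_intensity"
            )
        spc_bg = max(1, int(round(background / total_intensity
                                  * _SPC_PER_FRACTION)))
        sample_rows.append(
            (sample_id, BACKGROUND_ID, _BACKGROUND_PEPTIDE, background, spc_bg)
        )
        rows.extend(sample_rows)
    return pd.DataFrame(
        rows,
        columns=["sample_id", "protein_id", "peptide_seq", "intensity",
                 "spectral_count"],
    )


# ---------------------------------------------------------------------------
# detection-set bookkeeping generator
# ---------------------------------------------------------------------------

def build_detection_sets(
    n_shared: int,
    specific_counts: Mapping[str, int],
    prefix: str = "P",
) -> dict[str, set[str]]:
    """Construct per-group detected-protein sets with a prescribed overlap
    structure: ``n_shared`` proteins present in every group plus, for each
    group, ``specific_counts[g]`` proteins present only there.

    Used to exercise shared/group-specific set algebra at the published
    bookkeeping (321 shared; 56/37/10/34 group-specific).
    """
    if n_shared < 0 or any(v < 0 for v in specific_counts.values()):
        raise ValidationError("counts must be non-negative")
    shared = {f"{prefix}_SHARED{i:04d}" for i in range(n_shared)}
    sets = {}
    for g, k in specific_counts.items():
        sets[g] = shared | {f"{prefix}_{g}_{i:04d}" for i in range(k)}
    return sets
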