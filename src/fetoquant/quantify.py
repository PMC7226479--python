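"""From peptide observations to absolute protein concentrations.

Quantification uses normalized total intensity: per sample, a protein's
proteotypic (single-protein) peptide intensities are summed and divided by
the sample's total proteotypic intensity, so values sum to 1 per sample and
are directly comparable with the spiked-standard calibration points
(standards and samples pass through the same normalization). Absolute
concentration follows from inverting the calibration curve; mass units via
the molecular mass (1 fmol/uL of a 50 kDa protein = 50 ng/mL).

NSAF (spectral count / length, renormalized to sum 1) is computed separately
and used only for abundance ranking, never for concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import LogLogCalibration
from .errors import ComputationError, ValidationError

META_COLUMNS = ("group", "dm_type", "df_status", "treatment")


@dataclass
class ProteinQuant:
    """Per-sample, per-protein quantification record."""

    sample_id: str
    protein_id: str
    n_unique_peptides: int
    norm_intensity: float
    conc_fmol_ul: float | None
    conc_ng_ml: float | None
    flags: set[str] = field(default_factory=set)


def unique_peptides(
    observations: pd.DataFrame,
    peptide_to_proteins: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Restrict observations to proteotypic peptides.

    ``peptide_to_proteins`` maps each peptide sequence to the set of proteins
    it occurs in; only peptides mapping to exactly one protein are retained.
    An observed peptide absent from the map is an error.
    """
    keep = []
    for pep in observations["peptide_seq"].unique():
        if pep not in peptide_to_proteins:
            raise ValidationError(f"peptide not in mapping: {pep!r}")
        if len(peptide_to_proteins[pep]) == 1:
            keep.append(pep)
    return observations[observations["peptide_seq"].isin(keep)].reset_index(
        drop=True
    )


def peptide_map_to_protein_index(
    protein_to_peptides: Mapping[str, Sequence[str]],
) -> dict[str, tuple[str, ...]]:
    """Invert a protein -> peptides map into peptide -> proteins."""
    inv: dict[str, list[str]] = {}
    for prot, peps in protein_to_peptides.items():
        for pep in peps:
            inv.setdefault(pep, []).append(prot)
    return {pep: tuple(prots) for pep, prots in inv.items()}


def normalized_total_intensity(sample_obs: pd.DataFrame) -> pd.Series:
    """Per-protein normalized total intensity within one sample.

    norm_intensity(p) = sum of p's proteotypic-peptide intensities divided
    by the sample's total proteotypic intensity; sums to 1 over detected
    proteins.
    """
    totals = sample_obs.groupby("protein_id")["intensity"].sum()
    grand = float(totals.sum())
    if grand <= 0:
        raise ComputationError("sample has zero total intensity")
    return totals / grand


def nsaf(spectral_counts: pd.Series, lengths: Mapping[str, int]) -> pd.Series:
    """Normalized spectral abundance factor: (SpC/L) / sum(SpC/L)."""
    missing = [p for p in spectral_counts.index if p not in lengths]
    if missing:
        raise ValidationError(f"missing protein length(s): {missing}")
    saf = spectral_counts.astype(float) / pd.Series(
        {p: float(lengths[p]) for p in spectral_counts.index}
    )
    total = float(saf.sum())
    if total <= 0:
        raise ComputationError("all spectral counts are zero")
    return saf / total


def quantify_protein(
    curve: LogLogCalibration,
    norm_intensity: float,
    mw_da: float,
    sample_id: str = "",
    protein_id: str = "",
    n_unique_peptides: int = 0,
) -> ProteinQuant:
    """Map one normalized intensity to absolute concentration.

    conc_ng_ml = conc_fmol_ul * mw_da * 1e-3 (1 fmol/uL of a 50,000 Da
    protein is 50 ng/mL). Zero intensity yields an ``undetected`` record
    with no concentration.
    """
    if mw_da <= 0:
        raise ValidationError("molecular mass must be > 0")
    if norm_intensity <= 0:
        return ProteinQuant(sample_id, protein_id, n_unique_peptides,
                            0.0, None, None, {"undetected"})
    conc, flags = curve.predict(norm_intensity, return_flags=True)
    return ProteinQuant(
        sample_id, protein_id, n_unique_peptides,
        float(norm_intensity), float(conc), float(conc) * mw_da * 1e-3, flags,
    )


def quantify_samples(
    curve: LogLogCalibration,
    observations: pd.DataFrame,
    protein_to_peptides: Mapping[str, Sequence[str]],
    masses: Mapping[str, float],
    lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Quantify every (sample, protein) in a peptide table.

    Proteins without a molecular mass (e.g. the simulated background) get
    norm_intensity only. Returns a tidy frame with columns sample_id,
    protein_id, n_unique_peptides, norm_intensity, conc_fmol_ul, conc_ng_ml,
    nsaf, flags (semicolon-joined).
    """
    pep_index = peptide_map_to_protein_index(protein_to_peptides)
    obs = unique_peptides(observations, pep_index)
    rows = []
    for sample_id, sample_obs in obs.groupby("sample_id", sort=True):
        norm = normalized_total_intensity(sample_obs)
        npep = sample_obs.groupby("protein_id")["peptide_seq"].nunique()
        spc = sample_obs.groupby("protein_id")["spectral_count"].sum()
        nsaf_vals = (
            nsaf(spc, lengths) if lengths is not None else
            pd.Series(np.nan, index=spc.index)
        )
        for pid in norm.index:
            if pid in masses:
                q = quantify_protein(
                    curve, float(norm[pid]), masses[pid],
                    sample_id, pid, int(npep[pid]),
                )
            else:
                q = ProteinQuant(sample_id, pid, int(npep[pid]),
                                 float(norm[pid]), None, None, set())
            rows.append(
                {
                    "sample_id": q.sample_id,
                    "protein_id": q.protein_id,
                    "n_unique_peptides": q.n_unique_peptides,
                    "norm_intensity": q.norm_intensity,
                    "conc_fmol_ul": q.conc_fmol_ul,
                    "conc_ng_ml": q.conc_ng_ml,
                    "nsaf": float(nsaf_vals[pid]),
                    "flags": ";".join(sorted(q.flags)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frequency and set-membership filters
# ---------------------------------------------------------------------------

def frequency_filter(
    quant: pd.DataFrame,
    manifest: pd.DataFrame,
    threshold: float = 1.0,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Retain, per group, proteins detected in >= threshold of its samples.

    A protein counts as detected in a sample if it has a quantification row
    without the ``undetected`` flag. Returns (retained sets per group, tidy
    frequency records).
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    group_of = manifest.set_index("sample_id")["group"]
    detected = quant[~quant["flags"].str.contains("undetected", na=False)]
    det = detected.assign(group=detected["sample_id"].map(group_of))
    group_sizes = manifest.groupby("group")["sample_id"].nunique()

    records = []
    retained: dict[str, set[str]] = {g: set() for g in group_sizes.index}
    counts = det.groupby(["group", "protein_id"])["sample_id"].nunique()
    for (g, pid), k in counts.items():
        freq = k / group_sizes[g]
        records.append({"protein_id": pid, "group": g, "frequency": freq})
        if freq >= threshold:
            retained[g].add(pid)
    return retained, pd.DataFrame(records)


def group_specific_sets(
    retained: Mapping[str, set[str]],
) -> dict[str, object]:
    """Shared and group-specific protein sets.

    shared_all is the intersection over all groups; a group's specific set
    contains proteins retained there and nowhere else; pairwise gives
    intersection sizes for every group pair.
    """
    groups = sorted(retained)
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    shared_all = set.intersection(*(set(retained[g]) for g in groups))
    specific = {}
    for g in groups:
        others = set().union(*(retained[h] for h in groups if h != g))
        specific[g] = set(retained[g]) - others
    pairwise = {
        f"{a}&{b}": len(set(retained[a]) & set(retained[b]))
        for i, a in enumerate(groups)
        for b in groups[i + 1:]
    }
    return {
        "shared_all": shared_all,
        "specific": specific,
        "pairwise": pairwise,
        "counts": {
            "shared_all": len(shared_all),
            **{f"specific_{g}": len(specific[g]) for g in groups},
        },
    }
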