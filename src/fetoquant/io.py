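"""Readers and writers for the pipeline's tabular formats.

All tables are TSV with a header row, UTF-8, '.' decimal separator. Derived
results are JSON with a schema_version field, canonical key order and
repr-precision floats so reruns diff cleanly. Readers validate every row and
raise :class:`~fetoquant.errors.SchemaError` / ``ValidationError`` with the
offending column or row number; nothing is silently coerced.
"""

from __future__ import annotations

import json
import logging
import math
import re
from pathlib import Path
from typing import Any

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

PEPTIDE_SEQ_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

PEPTIDE_COLUMNS = ["sample_id", "protein_id", "peptide_seq", "intensity",
                   "spectral_count"]
MANIFEST_COLUMNS = ["sample_id", "group", "dm_type", "df_status", "treatment"]
STANDARDS_COLUMNS = ["protein_id", "amount_fmol", "mw_da", "length_aa"]

VALID_GROUPS = ("G01", "G02", "G03", "G04", "G05")
GROUP_DM = {"G01": "GDM", "G02": "GDM", "G03": "T2DM", "G04": "T2DM",
            "G05": "none"}
DF_GROUPS = ("G02", "G04")
VALID_TREATMENTS = ("insulin", "diet", "none")


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a peptide-level intensity table.

    Duplicate (sample, protein, peptide) rows are summed with a warning
    (fragmented search-engine exports are common). Returns a frame with
    columns sample_id, protein_id, peptide_seq, intensity, spectral_count.
    """
    df = _read_tsv(path, PEPTIDE_COLUMNS)
    if df.empty:
        logger.warning("%s: peptide table has a header but no rows", path)
        return df.assign(intensity=pd.Series(dtype=float),
                         spectral_count=pd.Series(dtype=int))
    try:
        df["intensity"] = df["intensity"].astype(float)
    except ValueError as e:
        raise ValidationError(f"{path}: non-numeric intensity: {e}") from e
    try:
        df["spectral_count"] = df["spectral_count"].astype(int)
    except ValueError as e:
        raise ValidationError(f"{path}: non-integer spectral_count: {e}") from e

    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.intensity < 0:
            raise ValidationError(
                f"{path}: row {i}: negative intensity {row.intensity}")
        if row.spectral_count < 0:
            raise ValidationError(
                f"{path}: row {i}: negative spectral_count {row.spectral_count}")
        if not PEPTIDE_SEQ_RE.match(str(row.peptide_seq)):
            raise ValidationError(
                f"{path}: row {i}: invalid peptide sequence "
                f"{row.peptide_seq!r}")

    key = ["sample_id", "protein_id", "peptide_seq"]
    if df.duplicated(key).any():
        n_dup = int(df.duplicated(key).sum())
        logger.warning("%s: summing %d duplicated peptide row(s)", path, n_dup)
        df = df.groupby(key, as_index=False, sort=False).agg(
            intensity=("intensity", "sum"),
            spectral_count=("spectral_count", "sum"),
        )
    return df.reset_index(drop=True)


def write_peptide_table(path: str | Path, df: pd.DataFrame) -> None:
    df[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest; enforce group/diabetes-type consistency."""
    df = _read_tsv(path, MANIFEST_COLUMNS)
    if df.empty:
        logger.warning("%s: manifest has a header but no rows", path)
        return df.assign(df_status=pd.Series(dtype=bool))
    seen: set[str] = set()
    statuses = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.sample_id in seen:
            raise ValidationError(
                f"{path}: row {i}: duplicate sample_id {row.sample_id!r}")
        seen.add(row.sample_id)
        if row.group not in VALID_GROUPS:
            raise ValidationError(
                f"{path}: row {i}: unknown group label {row.group!r}")
        if row.dm_type != GROUP_DM[row.group]:
            raise ValidationError(
                f"{path}: row {i}: group {row.group} implies dm_type "
                f"{GROUP_DM[row.group]!r}, got {row.dm_type!r}")
        status = str(row.df_status).strip().lower()
        if status not in ("true", "false"):
            raise ValidationError(
                f"{path}: row {i}: df_status must be true/false, "
                f"got {row.df_status!r}")
        status_bool = status == "true"
        if status_bool != (row.group in DF_GROUPS):
            raise ValidationError(
                f"{path}: row {i}: df_status {status_bool} inconsistent with "
                f"group {row.group} under the default labeling")
        if row.treatment not in VALID_TREATMENTS:
            raise ValidationError(
                f"{path}: row {i}: unknown treatment {row.treatment!r}")
        statuses.append(status_bool)
    df = df.copy()
    df["df_status"] = statuses
    return df.reset_index(drop=True)


def write_manifest(path: str | Path, df: pd.DataFrame) -> None:
    out = df[MANIFEST_COLUMNS].copy()
    out["df_status"] = out["df_status"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def read_standards(path: str | Path) -> pd.DataFrame:
    """Read a standards registry table (protein, amount, mass, length)."""
    df = _read_tsv(path, STANDARDS_COLUMNS)
    try:
        df["amount_fmol"] = df["amount_fmol"].astype(float)
        df["mw_da"] = df["mw_da"].astype(float)
        df["length_aa"] = df["length_aa"].astype(int)
    except ValueError as e:
        raise ValidationError(f"{path}: non-numeric standards field: {e}") from e
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.amount_fmol <= 0 or row.mw_da <= 0 or row.length_aa <= 0:
            raise ValidationError(
                f"{path}: row {i}: non-positive amount/mass/length")
    if df["protein_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate protein_id in standards")
    return df


def write_standards(path: str | Path, df: pd.DataFrame) -> None:
    df[STANDARDS_COLUMNS].to_csv(path, sep="\t", index=False)


def registry_from_fasta(path: str | Path, monoisotopic: bool = False):
    """Build (protein_id, mw_da, length_aa) rows from a FASTA file.

    Masses are average by default (monoisotopic selectable). Requires
    biopython.
    """
    from Bio import SeqIO
    from Bio.SeqUtils import molecular_weight

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        rows.append(
            {
                "protein_id": rec.id,
                "mw_da": molecular_weight(seq, seq_type="protein",
                                          monoisotopic=monoisotopic),
                "length_aa": len(seq),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# JSON results
# ---------------------------------------------------------------------------

def _sanitize(obj: Any) -> Any:
    """Recursively convert to JSON-safe types; NaN/inf become null."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        logger.warning("non-finite value serialized as null")
        return None
    return obj


def write_results(path: str | Path, results: dict[str, Any]) -> None:
    """Write a results dict as canonical JSON (sorted keys, schema version).

    Floats use Python repr (17 significant digits), so identical results
    produce byte-identical files.
    """
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(_sanitize(results))
    text = json.dumps(payload, sort_keys=True, indent=2, allow_nan=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_results(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))
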