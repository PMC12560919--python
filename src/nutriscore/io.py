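"""Reading, writing and validating composition tables.

Input tables are CSV/TSV with a header row, one row per animal (or per
group mean), required columns ``animal_id`` and ``sex``, and analyte
columns named by canonical key or any registered synonym ("Oleic" and
"C18:1 cis" are the same column).  Unknown columns survive as record
annotations rather than being dropped.

The module also exposes the packaged fixture tables: the sex-stratified
proximate, fatty-acid and amino-acid group statistics of an Aubrac
cattle Longissimus dorsi study (27 males, 22 females), which double as
the default parameter source for the synthetic cohort generator.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd

from .types import (
    AminoAcidProfile,
    AnimalRecord,
    CohortTable,
    FattyAcidProfile,
    ProximateComposition,
    ValidationError,
    canonical_amino_acid,
    canonical_fatty_acid,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_report",
    "load_fixture",
    "fixture_proximate",
    "fixture_fatty_acid_profile",
    "fixture_amino_acid_profile",
    "fixture_protein_pct",
    "fixture_cohort",
]

_PROXIMATE_COLS = {
    "water": "water_pct",
    "water_pct": "water_pct",
    "dry_matter": "dry_matter_pct",
    "dry matter": "dry_matter_pct",
    "dry_matter_pct": "dry_matter_pct",
    "protein": "protein_pct",
    "protein_pct": "protein_pct",
    "fat": "fat_pct",
    "total_fat": "fat_pct",
    "total fat": "fat_pct",
    "fat_pct": "fat_pct",
    "minerals": "minerals_pct",
    "ash": "minerals_pct",
    "minerals_pct": "minerals_pct",
}


def _classify_column(name: str) -> tuple[str, str] | None:
    """Return (block, canonical_name) for an analyte column, else None."""
    low = name.strip().lower()
    if low in _PROXIMATE_COLS:
        return "proximate", _PROXIMATE_COLS[low]
    try:
        return "fatty_acid", canonical_fatty_acid(name)
    except KeyError:
        pass
    try:
        return "amino_acid", canonical_amino_acid(name)
    except KeyError:
        pass
    return None


def read_cohort(path: str | Path, schema: str = "combined") -> CohortTable:
    """Read a per-animal (or group-mean) composition table.

    Parameters
    ----------
    path:
        CSV or TSV file (delimiter sniffed from the extension).
    schema:
        ``"proximate"``, ``"fatty_acid"``, ``"amino_acid"`` or
        ``"combined"``; restricts which analyte blocks are parsed.

    Raises
    ------
    ValidationError
        If the ``sex`` column is missing, any analyte value is negative
        (the offending row and column are named), or a FAME row sums
        above 101.
    """
    path = Path(path)
    if schema not in ("proximate", "fatty_acid", "amino_acid", "combined"):
        raise ValueError(f"unknown schema {schema!r}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]

    lower = {c.lower(): c for c in df.columns}
    if "sex" not in lower:
        raise ValidationError(f"{path}: required column 'sex' is missing")
    sex_col = lower["sex"]
    id_col = lower.get("animal_id")

    wanted = {
        "proximate": {"proximate"},
        "fatty_acid": {"fatty_acid"},
        "amino_acid": {"amino_acid"},
        "combined": {"proximate", "fatty_acid", "amino_acid"},
    }[schema]

    colmap: dict[str, tuple[str, str]] = {}
    extra_cols: list[str] = []
    for c in df.columns:
        if c in (sex_col, id_col):
            continue
        cls = _classify_column(c)
        if cls is not None and cls[0] in wanted:
            colmap[c] = cls
        else:
            extra_cols.append(c)

    records: list[AnimalRecord] = []
    for i, row in df.iterrows():
        animal_id = str(row[id_col]) if id_col else f"row{i + 1}"
        sex = str(row[sex_col]).strip().lower()
        prox: dict[str, float] = {}
        fa: dict[str, float] = {}
        aa: dict[str, float] = {}
        for col, (block, canon) in colmap.items():
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            raw = str(raw).strip()
            if raw == "" or raw.lower() == "nan":
                continue
            try:
                value = float(raw)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: row {animal_id!r}, column {col!r}: "
                    f"cannot parse {raw!r} as a number"
                ) from exc
            if value < 0:
                raise ValidationError(
                    f"{path}: row {animal_id!r}, column {col!r}: "
                    f"negative value {value}"
                )
            {"proximate": prox, "fatty_acid": fa, "amino_acid": aa}[block][
                canon
            ] = value

        if fa and sum(fa.values()) > 101.0:
            raise ValidationError(
                f"{path}: row {animal_id!r}: fatty acids sum to "
                f"{sum(fa.values()):.2f} > 101"
            )

        annotations = {
            c: row[c]
            for c in extra_cols
            if not (isinstance(row[c], float) and math.isnan(row[c]))
        }
        records.append(
            AnimalRecord(
                animal_id=animal_id,
                sex=sex,
                proximate=ProximateComposition(**prox) if prox else None,
                fatty_acids=FattyAcidProfile(fa) if fa else None,
                amino_acids=AminoAcidProfile(aa) if aa else None,
                annotations=annotations,
            )
        )
    return CohortTable(records, provenance=str(path))


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort back to wide CSV (inverse of :func:`read_cohort`)."""
    path = Path(path)
    rows = []
    for r in cohort:
        row: dict[str, Any] = {"animal_id": r.animal_id, "sex": r.sex}
        if r.proximate is not None:
            row.update(dataclasses.asdict(r.proximate))
        if r.fatty_acids is not None:
            row.update(r.fatty_acids.values)
        if r.amino_acids is not None:
            row.update(r.amino_acids.values)
        row.update(r.annotations)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    out: dict[str, Any] = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            key = f"{prefix}{k}"
            if isinstance(v, dict) or dataclasses.is_dataclass(v):
                out.update(_flatten(v, f"{key}."))
            else:
                out[key] = v
    else:
        out[prefix.rstrip(".") or "value"] = obj
    return out


def write_report(result: Any, path: str | Path, format: str = "json") -> Path:
    """Serialize a result object (any dataclass or mapping) to disk.

    JSON preserves full float precision; CSV flattens nested fields into
    dotted column names.  Either round-trips every numeric field to at
    least 6 significant digits.
    """
    path = Path(path)
    if format == "json":
        payload = (
            dataclasses.asdict(result)
            if dataclasses.is_dataclass(result) and not isinstance(result, type)
            else result
        )
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    elif format == "csv":
        flat = _flatten(result)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["field", "value"])
            for k, v in flat.items():
                w.writerow([k, repr(v) if isinstance(v, float) else v])
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name.

    Available: ``aubrac_table3`` (proximate), ``aubrac_table4``
    (fatty acids + printed indices), ``aubrac_table5`` (amino acids),
    ``aubrac_table6`` (protein-basis values, FAO/WHO reference patterns
    and printed quality scores).
    """
    ref = resources.files("nutriscore.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def fixture_proximate(sex: str) -> ProximateComposition:
    """Group-mean proximate composition for ``"male"`` or ``"female"``."""
    df = load_fixture("aubrac_table3").set_index("analyte")
    col = f"{sex}_mean"
    return ProximateComposition(
        water_pct=df.at["water", col],
        dry_matter_pct=df.at["dry_matter", col],
        protein_pct=df.at["protein", col],
        fat_pct=df.at["fat", col],
        minerals_pct=df.at["minerals", col],
    )


def fixture_protein_pct(how: str = "sex_mean") -> float:
    """Protein percentage used for protein-basis conversion.

    ``sex_mean`` (default) is the unweighted mean of the male and female
    group means — the convention under which the packaged protein-basis
    fixture values reproduce; ``weighted`` weights by the group sizes
    (27 males, 22 females).
    """
    df = load_fixture("aubrac_table3").set_index("analyte")
    m, f = df.at["protein", "male_mean"], df.at["protein", "female_mean"]
    if how == "sex_mean":
        return (m + f) / 2.0
    if how == "weighted":
        return (27 * m + 22 * f) / 49.0
    raise ValueError(f"unknown protein aggregation {how!r}")


def fixture_fatty_acid_profile(column: str) -> FattyAcidProfile:
    """Fatty-acid profile from a fixture column: male, female or overall."""
    df = load_fixture("aubrac_table4")
    acids = df[df["kind"] == "acid"]
    return FattyAcidProfile(
        dict(zip(acids["analyte"], acids[f"{column}_mean"].astype(float)))
    )


def fixture_amino_acid_profile(column: str) -> AminoAcidProfile:
    """Amino-acid profile (g/100 g meat) from a fixture column."""
    df = load_fixture("aubrac_table5")
    aas = df[df["kind"] == "amino_acid"]
    return AminoAcidProfile(
        dict(zip(aas["analyte"], aas[f"{column}_mean"].astype(float)))
    )


def fixture_cohort(schema: str = "combined") -> CohortTable:
    """Two group-mean pseudo-records (male, female) built from fixtures."""
    records = []
    for sex in ("male", "female"):
        records.append(
            AnimalRecord(
                animal_id=f"{sex}_group_mean",
                sex=sex,
                proximate=(
                    fixture_proximate(sex)
                    if schema in ("proximate", "combined")
                    else None
                ),
                fatty_acids=(
                    fixture_fatty_acid_profile(sex)
                    if schema in ("fatty_acid", "combined")
                    else None
                ),
                amino_acids=(
                    fixture_amino_acid_profile(sex)
                    if schema in ("amino_acid", "combined")
                    else None
                ),
            )
        )
    return CohortTable(records, provenance="group_mean")
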