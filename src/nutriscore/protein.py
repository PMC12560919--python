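"""Protein quality scoring against FAO/WHO reference amino-acid patterns.

The pipeline converts a hydrolysate amino-acid profile (g/100 g meat)
to protein basis (g/100 g protein, numerically g/16 g N under the 6.25
nitrogen factor), scores the eight essential amino-acid groups against
an age-group reference pattern, and condenses the scores into the
classical quality indices:

    CS(g)  = 100 · AA_meat(g) / AA_reference(g)        (chemical score)
    EAAI   = geometric mean of the eight CS             (Oser's index)
    BV     = 1.09 · EAAI − 11.7                         (biological value)
    NI     = EAAI · protein% / 100                      (nutritional index)

Three FAO/WHO patterns ship with the package — ``children``
(Standard 1), ``youth`` (Standard 2) and ``adults`` (Standard 3) —
each a requirement vector over the groups Ile, Leu, Lys, Met+Cys,
Phe+Tyr, Thr, Trp, Val in g/100 g protein.  Custom patterns (e.g. whole
egg) can be supplied as CSV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import load_fixture
from .types import (
    AminoAcidProfile,
    ESSENTIAL_GROUPS,
    ProximateComposition,
    ValidationError,
)

__all__ = [
    "ProteinBasisProfile",
    "ReferencePattern",
    "ProteinQualityResult",
    "to_protein_basis",
    "essential_groups",
    "chemical_score",
    "eaai",
    "biological_value",
    "nutritional_index",
    "evaluate_protein_quality",
    "reference_patterns",
    "load_pattern_csv",
]


@dataclass
class ProteinBasisProfile:
    """Amino acids in g/100 g protein plus the protein % used to convert."""

    values: dict[str, float]
    source_protein_pct: float

    def __post_init__(self) -> None:
        if not (0.0 < self.source_protein_pct <= 100.0):
            raise ValidationError(
                f"source_protein_pct must be in (0, 100], got "
                f"{self.source_protein_pct}"
            )
        for k, v in self.values.items():
            if v < 0:
                raise ValidationError(f"negative value for {k}: {v}")


@dataclass(frozen=True)
class ReferencePattern:
    """An essential-amino-acid requirement vector in g/100 g protein."""

    standard_name: str
    requirements: dict[str, float]
    total_eaa: float

    def __post_init__(self) -> None:
        if set(self.requirements) != set(ESSENTIAL_GROUPS):
            missing = set(ESSENTIAL_GROUPS) - set(self.requirements)
            extra = set(self.requirements) - set(ESSENTIAL_GROUPS)
            raise ValidationError(
                f"pattern {self.standard_name!r} must be keyed by the 8 "
                f"essential groups; missing={sorted(missing)} extra={sorted(extra)}"
            )
        for g, v in self.requirements.items():
            if v <= 0:
                raise ValidationError(
                    f"pattern {self.standard_name!r}: requirement for {g} "
                    f"must be positive, got {v}"
                )
        if abs(self.total_eaa - sum(self.requirements.values())) > 0.1:
            raise ValidationError(
                f"pattern {self.standard_name!r}: total_eaa {self.total_eaa} "
                f"disagrees with the summed requirements "
                f"{sum(self.requirements.values()):.2f}"
            )


@dataclass
class ProteinQualityResult:
    """Chemical scores and quality indices per reference standard."""

    basis: ProteinBasisProfile
    total_eaa: float
    chemical_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    eaai: dict[str, float] = field(default_factory=dict)
    bv: dict[str, float] = field(default_factory=dict)
    ni: dict[str, float] = field(default_factory=dict)
    limiting_aa: dict[str, str] = field(default_factory=dict)


def to_protein_basis(
    profile: AminoAcidProfile, protein_pct: float
) -> ProteinBasisProfile:
    """Convert g/100 g meat to g/100 g protein (= g/16 g N)."""
    if protein_pct <= 0:
        raise ValidationError(f"protein_pct must be positive, got {protein_pct}")
    if profile.basis != "per_100g_meat":
        raise ValidationError(
            f"profile already on basis {profile.basis!r}; expected per_100g_meat"
        )
    values = {k: 100.0 * v / protein_pct for k, v in profile.values.items()}
    return ProteinBasisProfile(values, source_protein_pct=protein_pct)


def essential_groups(basis: ProteinBasisProfile) -> dict[str, float]:
    """The eight scored groups; Met+Cys and Phe+Tyr formed by summation."""
    v = basis.values
    return {
        "isoleucine": v.get("isoleucine", 0.0),
        "leucine": v.get("leucine", 0.0),
        "lysine": v.get("lysine", 0.0),
        "met_cys": v.get("methionine", 0.0) + v.get("cystine_cysteine", 0.0),
        "phe_tyr": v.get("phenylalanine", 0.0) + v.get("tyrosine", 0.0),
        "threonine": v.get("threonine", 0.0),
        "tryptophan": v.get("tryptophan", 0.0),
        "valine": v.get("valine", 0.0),
    }


def chemical_score(
    basis: ProteinBasisProfile, pattern: ReferencePattern
) -> dict[str, float]:
    """Per-group chemical score in percent: 100 · meat / reference."""
    groups = essential_groups(basis)
    absent = [
        g
        for g in ESSENTIAL_GROUPS
        if groups[g] == 0.0
        and g
        not in ("met_cys", "phe_tyr")  # paired groups may legitimately sum from one member
        and g not in basis.values
    ]
    if absent:
        raise ValidationError(
            f"profile missing essential amino acids: {sorted(absent)}"
        )
    return {g: 100.0 * groups[g] / pattern.requirements[g] for g in ESSENTIAL_GROUPS}


def eaai(scores: dict[str, float]) -> float:
    """Essential amino acid index: geometric mean of the chemical scores.

    Computed in log space so extreme scores (tryptophan can exceed
    2000%) neither overflow nor lose precision.
    """
    if not scores:
        raise ValidationError("no chemical scores supplied")
    for g, s in scores.items():
        if s <= 0:
            raise ValidationError(
                f"geometric mean undefined: score for {g} is {s} (must be > 0)"
            )
    return math.exp(sum(math.log(s) for s in scores.values()) / len(scores))


def biological_value(eaai_pct: float) -> float:
    """Biological value, the affine transform 1.09·EAAI − 11.7."""
    if eaai_pct < 0:
        raise ValidationError(f"EAAI must be non-negative, got {eaai_pct}")
    bv = 1.09 * eaai_pct - 11.7
    if bv < 0:
        warnings.warn(f"biological value is negative ({bv:.2f})", stacklevel=2)
    return bv


def nutritional_index(eaai_pct: float, protein_pct: float) -> float:
    """Nutritional index: EAAI scaled by the food's protein percentage."""
    if not (0.0 < protein_pct <= 100.0):
        raise ValidationError(
            f"protein_pct must be in (0, 100], got {protein_pct}"
        )
    return eaai_pct * protein_pct / 100.0


def evaluate_protein_quality(
    profile: AminoAcidProfile,
    proximate: ProximateComposition | float,
    patterns: list[ReferencePattern] | None = None,
) -> ProteinQualityResult:
    """Full pipeline: basis conversion → CS → EAAI → BV → NI per pattern.

    ``proximate`` may be a full :class:`ProximateComposition` or a bare
    protein percentage.  Defaults to the three packaged FAO/WHO
    patterns.
    """
    protein_pct = (
        proximate.protein_pct
        if isinstance(proximate, ProximateComposition)
        else float(proximate)
    )
    if patterns is None:
        patterns = list(reference_patterns().values())
    basis = to_protein_basis(profile, protein_pct)
    result = ProteinQualityResult(
        basis=basis,
        total_eaa=sum(essential_groups(basis).values()),
    )
    for pat in patterns:
        cs = chemical_score(basis, pat)
        idx = eaai(cs)
        result.chemical_scores[pat.standard_name] = cs
        result.eaai[pat.standard_name] = idx
        result.bv[pat.standard_name] = biological_value(idx)
        result.ni[pat.standard_name] = nutritional_index(idx, protein_pct)
        result.limiting_aa[pat.standard_name] = min(cs, key=cs.get)
    return result


def reference_patterns() -> dict[str, ReferencePattern]:
    """The three packaged FAO/WHO age-group patterns."""
    df = load_fixture("aubrac_table6")
    basis = df[df["row_type"] == "basis"].set_index("group")
    out: dict[str, ReferencePattern] = {}
    for name in ("children", "youth", "adults"):
        req = {
            g: float(basis.at[g, name]) for g in ESSENTIAL_GROUPS
        }
        out[name] = ReferencePattern(
            standard_name=name,
            requirements=req,
            total_eaa=float(basis.at["eaa_total", name]),
        )
    return out


def load_pattern_csv(path: str | Path, name: str = "custom") -> ReferencePattern:
    """Load a custom pattern: CSV with columns group, requirement_g_per_100g_protein."""
    df = pd.read_csv(path)
    req = dict(
        zip(df["group"], df["requirement_g_per_100g_protein"].astype(float))
    )
    return ReferencePattern(
        standard_name=name, requirements=req, total_eaa=sum(req.values())
    )
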