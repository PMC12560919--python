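"""Domain types for compositional meat-quality data.

The data model mirrors what a targeted compositional study actually
produces: a proximate breakdown of the muscle (water / dry matter /
protein / fat / ash), a GC-MS FAME fatty-acid profile expressed as % of
total identified methyl esters, and a hydrolysate amino-acid profile in
g per 100 g meat.  Records are sex-stratified throughout because the
downstream analysis contrasts males and females.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "CANONICAL_FATTY_ACIDS",
    "CANONICAL_AMINO_ACIDS",
    "ESSENTIAL_GROUPS",
    "FattyAcidKey",
    "ProximateComposition",
    "FattyAcidProfile",
    "AminoAcidProfile",
    "AnimalRecord",
    "CohortTable",
    "ValidationError",
    "canonical_fatty_acid",
    "canonical_amino_acid",
]


class ValidationError(ValueError):
    """Raised when a composition record violates a hard invariant."""


# ---------------------------------------------------------------------------
# Canonical analyte naming
# ---------------------------------------------------------------------------

#: The 16 fatty acids of the standard FAME panel, geometry-resolved.
#: Keys are lipid shorthand with geometry because the health indices
#: treat oleic (C18:1 cis) and trans-vaccenic (C18:1 trans) differently.
CANONICAL_FATTY_ACIDS: tuple[str, ...] = (
    "C10:0",
    "C12:0",
    "C14:0",
    "C14:1",
    "C15:0",
    "C16:0",
    "C16:1",
    "C17:0",
    "C18:0",
    "C18:1 cis",
    "C18:1 trans",
    "C18:2 cis",
    "C18:2 trans",
    "C18:3 cis n3",
    "C20:0",
    "C20:1",
)

_FA_SYNONYMS: dict[str, str] = {
    "capric": "C10:0",
    "capric acid": "C10:0",
    "lauric": "C12:0",
    "lauric acid": "C12:0",
    "myristic": "C14:0",
    "myristic acid": "C14:0",
    "myristoleic": "C14:1",
    "myristoleic acid": "C14:1",
    "pentadecanoic": "C15:0",
    "pentadecanoic acid": "C15:0",
    "palmitic": "C16:0",
    "palmitic acid": "C16:0",
    "palmitoleic": "C16:1",
    "palmitoleic acid": "C16:1",
    "margaric": "C17:0",
    "margaric acid": "C17:0",
    "stearic": "C18:0",
    "stearic acid": "C18:0",
    "oleic": "C18:1 cis",
    "oleic acid": "C18:1 cis",
    "trans-vaccenic": "C18:1 trans",
    "trans vaccenic": "C18:1 trans",
    "vaccenic": "C18:1 trans",
    "linoleic": "C18:2 cis",
    "linoleic acid": "C18:2 cis",
    "alpha-linolenic": "C18:3 cis n3",
    "alpha linolenic": "C18:3 cis n3",
    "linolenic": "C18:3 cis n3",
    "arachidic": "C20:0",
    "arachidic acid": "C20:0",
    "eicosenoic": "C20:1",
    "eicosenoic acid": "C20:1",
    # bare-shorthand conveniences: an unqualified C18:1 / C18:2 means cis
    "c18:1": "C18:1 cis",
    "c18:2": "C18:2 cis",
    "c18:3": "C18:3 cis n3",
}


def canonical_fatty_acid(name: str) -> str:
    """Map a column label to its canonical geometry-resolved key.

    Handles the common dialects seen in composition tables:
    ``"Oleic"``, ``"C18:1:cis"``, ``"C18:3:cis:ω3"``, ``"c18_1_cis"`` all
    resolve to the same key.  Raises :class:`KeyError` for labels that are
    neither canonical nor a registered synonym.
    """
    s = name.strip().lower()
    s = s.replace("ω3", "n3").replace("w3", "n3").replace("n-3", "n3")
    s = s.replace("_", " ").replace(":cis", " cis").replace(":trans", " trans")
    s = s.replace(":n3", " n3").replace("  ", " ").strip()
    # "C18 1 cis" (underscore dialect) back to "C18:1 cis"
    s = re.sub(r"^c(\d+) (\d+)", r"c\1:\2", s)
    for cand in CANONICAL_FATTY_ACIDS:
        if s == cand.lower():
            return cand
    if s in _FA_SYNONYMS:
        return _FA_SYNONYMS[s]
    raise KeyError(f"unknown fatty acid name: {name!r}")


#: Amino acids of the hydrolysate panel (canonical snake_case keys).
CANONICAL_AMINO_ACIDS: tuple[str, ...] = (
    "aspartic_acid",
    "glutamic_acid",
    "alanine",
    "arginine",
    "cystine_cysteine",
    "phenylalanine",
    "glycine",
    "hydroxyproline",
    "isoleucine",
    "histidine",
    "leucine",
    "lysine",
    "methionine",
    "proline",
    "serine",
    "tyrosine",
    "threonine",
    "tryptophan",
    "valine",
)

_AA_SYNONYMS: dict[str, str] = {
    "asp": "aspartic_acid",
    "aspartate": "aspartic_acid",
    "glu": "glutamic_acid",
    "glutamate": "glutamic_acid",
    "ala": "alanine",
    "arg": "arginine",
    "cys": "cystine_cysteine",
    "cysteine": "cystine_cysteine",
    "cystine": "cystine_cysteine",
    "cystine + cysteine": "cystine_cysteine",
    "phe": "phenylalanine",
    "gly": "glycine",
    "hyp": "hydroxyproline",
    "ile": "isoleucine",
    "his": "histidine",
    "leu": "leucine",
    "lys": "lysine",
    "met": "methionine",
    "pro": "proline",
    "ser": "serine",
    "tyr": "tyrosine",
    "thr": "threonine",
    "trp": "tryptophan",
    "tryptophan (total)": "tryptophan",
    "val": "valine",
}


def canonical_amino_acid(name: str) -> str:
    """Resolve an amino-acid column label to its canonical key."""
    s = name.strip().lower().replace("-", " ")
    s_snake = s.replace(" ", "_")
    if s_snake in CANONICAL_AMINO_ACIDS:
        return s_snake
    if s in _AA_SYNONYMS:
        return _AA_SYNONYMS[s]
    raise KeyError(f"unknown amino acid name: {name!r}")


#: The eight essential amino-acid groups scored against reference
#: patterns; Met+Cys and Phe+Tyr are conventional paired groups.
ESSENTIAL_GROUPS: tuple[str, ...] = (
    "isoleucine",
    "leucine",
    "lysine",
    "met_cys",
    "phe_tyr",
    "threonine",
    "tryptophan",
    "valine",
)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FattyAcidKey:
    """A geometry- and omega-resolved fatty-acid identity.

    Parameters
    ----------
    carbon_chain:
        Lipid shorthand ``"C<carbons>:<double bonds>"``, e.g. ``"C18:1"``.
    geometry:
        ``"cis"``, ``"trans"`` or ``"unspecified"``.  Saturated acids
        (zero double bonds) must be ``"unspecified"``.
    omega_class:
        ``"n3"``, ``"n6"`` or ``"none"``.
    """

    carbon_chain: str
    geometry: str = "unspecified"
    omega_class: str = "none"

    def __post_init__(self) -> None:
        m = re.fullmatch(r"C(\d+):(\d+)", self.carbon_chain)
        if not m:
            raise ValidationError(
                f"carbon_chain must look like 'C18:1', got {self.carbon_chain!r}"
            )
        if self.geometry not in ("cis", "trans", "unspecified"):
            raise ValidationError(f"bad geometry {self.geometry!r}")
        if self.omega_class not in ("n3", "n6", "none"):
            raise ValidationError(f"bad omega_class {self.omega_class!r}")
        if int(m.group(2)) == 0 and (
            self.geometry != "unspecified" or self.omega_class != "none"
        ):
            raise ValidationError(
                f"saturated acid {self.carbon_chain} cannot carry geometry or omega class"
            )

    @property
    def double_bonds(self) -> int:
        return int(self.carbon_chain.split(":")[1])

    def canonical(self) -> str:
        parts = [self.carbon_chain]
        if self.geometry != "unspecified":
            parts.append(self.geometry)
        if self.omega_class != "none":
            parts.append(self.omega_class)
        return " ".join(parts)

    @classmethod
    def parse(cls, name: str) -> "FattyAcidKey":
        canon = canonical_fatty_acid(name)
        tokens = canon.split()
        chain = tokens[0]
        geometry = "unspecified"
        omega = "none"
        for t in tokens[1:]:
            if t in ("cis", "trans"):
                geometry = t
            elif t in ("n3", "n6"):
                omega = t
        return cls(chain, geometry, omega)


@dataclass(frozen=True)
class ProximateComposition:
    """Proximate breakdown of fresh muscle, all fields in percent."""

    water_pct: float
    dry_matter_pct: float
    protein_pct: float
    fat_pct: float
    minerals_pct: float

    #: tolerance on water + dry matter = 100, absorbing table rounding
    WATER_DM_TOL = 0.05

    def __post_init__(self) -> None:
        for f in (
            "water_pct",
            "dry_matter_pct",
            "protein_pct",
            "fat_pct",
            "minerals_pct",
        ):
            v = getattr(self, f)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{f}={v} outside [0, 100]")
        if abs(self.water_pct + self.dry_matter_pct - 100.0) > self.WATER_DM_TOL:
            raise ValidationError(
                f"water ({self.water_pct}) + dry matter ({self.dry_matter_pct}) "
                f"must equal 100 within {self.WATER_DM_TOL}"
            )
        solids = self.protein_pct + self.fat_pct + self.minerals_pct
        if solids > self.dry_matter_pct + 0.5:
            # soft constraint: independent analytical determinations can
            # overshoot the gravimetric dry matter; warn, don't reject
            warnings.warn(
                f"protein+fat+minerals ({solids:.2f}) exceeds dry matter "
                f"({self.dry_matter_pct:.2f}) + 0.5",
                stacklevel=2,
            )


@dataclass
class FattyAcidProfile:
    """Fatty-acid composition as percent of total identified FAME.

    Profiles may be partial (a subset of the panel); ``closed`` records
    whether the vector was renormalized to a fixed total.
    """

    values: dict[str, float]
    closed: bool = False

    SUM_TOL = 1.0

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for name, v in self.values.items():
            key = canonical_fatty_acid(name)
            if v < 0:
                raise ValidationError(f"negative value for {name}: {v}")
            if not math.isfinite(v):
                raise ValidationError(f"non-finite value for {name}: {v}")
            canon[key] = canon.get(key, 0.0) + float(v)
        if sum(canon.values()) > 100.0 + self.SUM_TOL:
            raise ValidationError(
                f"FAME percentages sum to {sum(canon.values()):.2f} > "
                f"{100 + self.SUM_TOL}"
            )
        self.values = canon

    def get(self, name: str, default: float = 0.0) -> float:
        return self.values.get(canonical_fatty_acid(name), default)

    def total(self) -> float:
        return sum(self.values.values())

    def scaled(self, k: float) -> "FattyAcidProfile":
        """Profile with every acid multiplied by ``k`` (k > 0)."""
        if k <= 0:
            raise ValidationError("scale factor must be positive")
        return FattyAcidProfile({n: v * k for n, v in self.values.items()})


@dataclass
class AminoAcidProfile:
    """Amino-acid contents, either per 100 g meat or per 100 g protein."""

    values: dict[str, float]
    basis: str = "per_100g_meat"

    #: sanity ceiling on total AA in g/100 g fresh meat
    MEAT_BASIS_SUM_MAX = 35.0

    def __post_init__(self) -> None:
        if self.basis not in ("per_100g_meat", "per_100g_protein"):
            raise ValidationError(f"bad basis {self.basis!r}")
        canon: dict[str, float] = {}
        for name, v in self.values.items():
            key = canonical_amino_acid(name)
            if v < 0:
                raise ValidationError(f"negative value for {name}: {v}")
            canon[key] = canon.get(key, 0.0) + float(v)
        if (
            self.basis == "per_100g_meat"
            and sum(canon.values()) > self.MEAT_BASIS_SUM_MAX
        ):
            # soft sanity bound: real muscle sits near 30 g/100 g, but
            # synthetic or reference-derived profiles may exceed it
            warnings.warn(
                f"amino acids sum to {sum(canon.values()):.2f} g/100 g meat, "
                f"above the {self.MEAT_BASIS_SUM_MAX} sanity bound",
                stacklevel=2,
            )
        self.values = canon

    def get(self, name: str, default: float = 0.0) -> float:
        return self.values.get(canonical_amino_acid(name), default)

    def total(self) -> float:
        return sum(self.values.values())


@dataclass
class AnimalRecord:
    """One animal (or one group-mean pseudo-record) with its composition blocks."""

    animal_id: str
    sex: str
    proximate: ProximateComposition | None = None
    fatty_acids: FattyAcidProfile | None = None
    amino_acids: AminoAcidProfile | None = None
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"record {self.animal_id!r}: sex must be 'male' or 'female', "
                f"got {self.sex!r}"
            )
        if (
            self.proximate is None
            and self.fatty_acids is None
            and self.amino_acids is None
        ):
            raise ValidationError(
                f"record {self.animal_id!r} carries no composition block"
            )


@dataclass
class CohortTable:
    """An ordered collection of animal records with unique identifiers."""

    records: list[AnimalRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.animal_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate animal_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[AnimalRecord]:
        return iter(self.records)

    def subset(self, sex: str) -> "CohortTable":
        return CohortTable(
            [r for r in self.records if r.sex == sex],
            provenance=f"{self.provenance}[{sex}]",
        )
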