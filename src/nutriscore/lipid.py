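"""Fatty-acid class sums and lipid health indices.

Classes follow the standard FAME panel groupings:

    SFA  = C10:0 + C12:0 + C14:0 + C15:0 + C16:0 + C17:0 + C18:0 + C20:0
    MUFA = C14:1 + C16:1 + C18:1 cis + C20:1
    PUFA = C18:2 cis + C18:3 cis n3
    UFA  = MUFA + PUFA
    TFA  = C18:1 trans + C18:2 trans

and the indices are the classical Ulbricht–Southgate atherogenic and
thrombogenic indices plus the Fernandez hypocholesterolemic/
hypercholesterolemic ratio:

    AI  = (C12:0 + C16:0 + 4·C14:0) / (MUFA + n6 + n3)
    TI  = (C14:0 + C16:0 + C18:0) / (0.5·MUFA + 0.5·n6 + 3·n3 + n3/n6)
    h/H = (C18:1 + PUFA) / (C12:0 + C14:0 + C16:0)

Two dialects are exposed.  ``conventional`` is the literature reading:
n6 = C18:2 cis only and the C18:1 of h/H is oleic.  ``as_published``
reverse-engineers the arithmetic of the source study's printed table:
n6 additionally includes C18:2 trans, and the C18:1 of the
hypocholesterolemic sum is trans-vaccenic — the only reading that
reproduces every printed n6, hFA and h/H cell.  ``as_published`` is the
default because the packaged fixtures exist to reproduce that table; it
is a reproduction dialect, not a nutritional recommendation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .types import CohortTable, FattyAcidProfile

__all__ = [
    "FattyAcidClassSummary",
    "LipidQualityIndices",
    "sum_fatty_acid_classes",
    "atherogenic_index",
    "thrombogenic_index",
    "hypo_hyper_ratio",
    "n6_n3_ratio",
    "lipid_quality",
    "cohort_lipid_quality",
]

SFA_ACIDS = ("C10:0", "C12:0", "C14:0", "C15:0", "C16:0", "C17:0", "C18:0", "C20:0")
MUFA_ACIDS = ("C14:1", "C16:1", "C18:1 cis", "C20:1")  # cis-only by convention
PUFA_ACIDS = ("C18:2 cis", "C18:3 cis n3")
TRANS_ACIDS = ("C18:1 trans", "C18:2 trans")
N3_ACIDS = ("C18:3 cis n3",)

DIALECTS = ("as_published", "conventional")


@dataclass(frozen=True)
class FattyAcidClassSummary:
    """Class sums (percent of total FAME) and the two headline ratios."""

    sfa: float
    mufa: float
    pufa: float
    ufa: float
    tfa: float
    n3: float
    n6: float
    ufa_sfa_ratio: float
    n6_n3_ratio: float


@dataclass(frozen=True)
class LipidQualityIndices:
    """Health indices of a fat: AI, TI and the h/H decomposition."""

    ai: float
    ti: float
    hfa: float
    h_fa: float
    h_over_H: float
    dialect: str


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")


def _warn_missing(profile: FattyAcidProfile) -> None:
    panel = set(SFA_ACIDS + MUFA_ACIDS + PUFA_ACIDS + TRANS_ACIDS)
    missing = sorted(panel - set(profile.values))
    if missing:
        warnings.warn(
            f"profile missing {len(missing)} panel acids (treated as 0): "
            + ", ".join(missing),
            stacklevel=3,
        )


def sum_fatty_acid_classes(
    profile: FattyAcidProfile, dialect: str = "as_published"
) -> FattyAcidClassSummary:
    """Sum the profile into SFA/MUFA/PUFA/UFA/TFA/n3/n6 classes.

    Missing panel acids contribute zero (with a warning) so that partial
    panels remain scoreable.  With SFA = 0 the UFA/SFA ratio is reported
    as ``+inf``; with n3 = 0 the n6/n3 ratio is ``+inf``.
    """
    _check_dialect(dialect)
    _warn_missing(profile)
    g = profile.get
    sfa = sum(g(a) for a in SFA_ACIDS)
    mufa = sum(g(a) for a in MUFA_ACIDS)
    pufa = sum(g(a) for a in PUFA_ACIDS)
    ufa = mufa + pufa
    tfa = sum(g(a) for a in TRANS_ACIDS)
    n3 = sum(g(a) for a in N3_ACIDS)
    n6 = g("C18:2 cis") + (g("C18:2 trans") if dialect == "as_published" else 0.0)
    if sfa > 0:
        ufa_sfa = ufa / sfa
    else:
        warnings.warn("SFA sum is 0; UFA/SFA reported as +inf", stacklevel=2)
        ufa_sfa = math.inf
    n6n3 = n6 / n3 if n3 > 0 else math.inf
    return FattyAcidClassSummary(
        sfa=sfa,
        mufa=mufa,
        pufa=pufa,
        ufa=ufa,
        tfa=tfa,
        n3=n3,
        n6=n6,
        ufa_sfa_ratio=ufa_sfa,
        n6_n3_ratio=n6n3,
    )


def atherogenic_index(
    profile: FattyAcidProfile, dialect: str = "as_published"
) -> float:
    """Atherogenic index: (C12:0 + C16:0 + 4·C14:0) / (MUFA + n6 + n3)."""
    s = sum_fatty_acid_classes(profile, dialect)
    denom = s.mufa + s.n6 + s.n3
    if denom <= 0:
        raise ZeroDivisionError(
            "atherogenic index undefined: no unsaturated fatty acids"
        )
    g = profile.get
    return (g("C12:0") + g("C16:0") + 4.0 * g("C14:0")) / denom


def thrombogenic_index(
    profile: FattyAcidProfile, dialect: str = "as_published"
) -> float:
    """Thrombogenic index.

    (C14:0 + C16:0 + C18:0) / (0.5·MUFA + 0.5·n6 + 3·n3 + n3/n6); the
    last denominator term makes n6 = 0 a domain error.
    """
    s = sum_fatty_acid_classes(profile, dialect)
    if s.n6 <= 0:
        raise ZeroDivisionError(
            "thrombogenic index undefined: n-6 sum is zero (n3/n6 term)"
        )
    denom = 0.5 * s.mufa + 0.5 * s.n6 + 3.0 * s.n3 + s.n3 / s.n6
    if denom <= 0:
        raise ZeroDivisionError("thrombogenic index undefined: zero denominator")
    g = profile.get
    return (g("C14:0") + g("C16:0") + g("C18:0")) / denom


def hypo_hyper_ratio(
    profile: FattyAcidProfile, dialect: str = "as_published"
) -> tuple[float, float, float]:
    """Hypocholesterolemic vs hypercholesterolemic fatty acids.

    Returns ``(HFA, hFA, h/H)`` where HFA = C12:0 + C14:0 + C16:0 and
    hFA = C18:1 + PUFA.  The C18:1 isomer is trans-vaccenic under the
    ``as_published`` dialect and oleic under ``conventional``.
    """
    _check_dialect(dialect)
    g = profile.get
    hfa = g("C12:0") + g("C14:0") + g("C16:0")
    if hfa <= 0:
        raise ZeroDivisionError("h/H undefined: no hypercholesterolemic acids")
    c181 = g("C18:1 trans") if dialect == "as_published" else g("C18:1 cis")
    h_fa = c181 + sum(g(a) for a in PUFA_ACIDS)
    return hfa, h_fa, h_fa / hfa


def n6_n3_ratio(
    source: FattyAcidClassSummary | CohortTable,
    mode: str = "mean_of_ratios",
    dialect: str = "as_published",
) -> float:
    """n-6 : n-3 ratio of a class summary or of a cohort.

    For a cohort, ``mean_of_ratios`` (default) averages the per-record
    ratios — the aggregation consistent with per-sample cohort means —
    while ``ratio_of_means`` divides the cohort-mean class sums.
    """
    if isinstance(source, FattyAcidClassSummary):
        if source.n3 <= 0:
            raise ZeroDivisionError("n6/n3 undefined: n-3 sum is zero")
        return source.n6 / source.n3
    if mode not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown mode {mode!r}")
    summaries = []
    for rec in source:
        if rec.fatty_acids is None:
            continue
        s = sum_fatty_acid_classes(rec.fatty_acids, dialect)
        if s.n3 <= 0:
            raise ZeroDivisionError(
                f"n6/n3 undefined for record {rec.animal_id!r}: n-3 sum is zero"
            )
        summaries.append(s)
    if not summaries:
        raise ValueError("cohort contains no fatty-acid profiles")
    if mode == "mean_of_ratios":
        return float(np.mean([s.n6 / s.n3 for s in summaries]))
    return float(np.mean([s.n6 for s in summaries]) / np.mean([s.n3 for s in summaries]))


def lipid_quality(
    profile: FattyAcidProfile, dialect: str = "as_published"
) -> LipidQualityIndices:
    """All health indices of one profile as a single result object."""
    hfa, h_fa, ratio = hypo_hyper_ratio(profile, dialect)
    return LipidQualityIndices(
        ai=atherogenic_index(profile, dialect),
        ti=thrombogenic_index(profile, dialect),
        hfa=hfa,
        h_fa=h_fa,
        h_over_H=ratio,
        dialect=dialect,
    )


def cohort_lipid_quality(
    cohort: CohortTable,
    dialect: str = "as_published",
    aggregate: str = "per_record",
) -> LipidQualityIndices:
    """Cohort-level indices.

    ``per_record`` (default) computes the indices on each record and
    averages them; ``mean_profile`` first averages the acid vectors and
    scores the mean profile.
    """
    profiles = [r.fatty_acids for r in cohort if r.fatty_acids is not None]
    if not profiles:
        raise ValueError("cohort contains no fatty-acid profiles")
    if aggregate == "mean_profile":
        acids = sorted({a for p in profiles for a in p.values})
        mean_vals = {
            a: float(np.mean([p.get(a) for p in profiles])) for a in acids
        }
        return lipid_quality(FattyAcidProfile(mean_vals), dialect)
    if aggregate != "per_record":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    per = [lipid_quality(p, dialect) for p in profiles]
    return LipidQualityIndices(
        ai=float(np.mean([x.ai for x in per])),
        ti=float(np.mean([x.ti for x in per])),
        hfa=float(np.mean([x.hfa for x in per])),
        h_fa=float(np.mean([x.h_fa for x in per])),
        h_over_H=float(np.mean([x.h_over_H for x in per])),
        dialect=dialect,
    )
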