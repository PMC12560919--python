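"""Sex-stratified descriptive statistics, two-group tests and PCA.

These are the reporting statistics that surround the core indices:
per-sex and overall mean ± SD summaries, a two-group one-way ANOVA
(equivalently the equal-variance t-test, F = t²) with the conventional
significance codes, amino-acid category aggregation, and a principal
component analysis on the correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import AminoAcidProfile, CohortTable, canonical_amino_acid

__all__ = [
    "GroupSummary",
    "SignificanceResult",
    "PcaResult",
    "AminoAcidCategoryScheme",
    "DEFAULT_CATEGORY_SCHEME",
    "cohort_frame",
    "describe",
    "compare_sexes",
    "significance_code",
    "aggregate_categories",
    "pca",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD of one variable within one group."""

    variable: str
    group: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class SignificanceResult:
    """p-value of a male/female contrast with its significance code."""

    variable: str
    p_value: float
    code: str


@dataclass
class PcaResult:
    """Scores, loadings and variance shares of a correlation-matrix PCA."""

    scores: pd.DataFrame  # records × components
    loadings: pd.DataFrame  # variables × components
    variance_explained: dict[str, float]  # component → percent


@dataclass(frozen=True)
class AminoAcidCategoryScheme:
    """Overlapping amino-acid categories used for grouping and PCA.

    The default follows the common sensory/nutritional convention:
    essential (eAA), flavour/umami-related (fAA: Asp, Glu),
    saccharinity/sweet-related (sAA: Gly, Ala, Ser, Thr, Pro) and
    fragrance-related aromatic (frAA: Phe, Tyr, Trp).  It is a
    documented convention, overridable in full.
    """

    membership: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for cat, members in self.membership.items():
            canon = tuple(canonical_amino_acid(m) for m in members)
            object.__setattr__(
                self,
                "membership",
                {**self.membership, cat: canon},
            )


DEFAULT_CATEGORY_SCHEME = AminoAcidCategoryScheme(
    membership={
        "eAA": (
            "isoleucine",
            "leucine",
            "lysine",
            "methionine",
            "phenylalanine",
            "threonine",
            "tryptophan",
            "valine",
            "histidine",
        ),
        "fAA": ("aspartic_acid", "glutamic_acid"),
        "sAA": ("glycine", "alanine", "serine", "threonine", "proline"),
        "frAA": ("phenylalanine", "tyrosine", "tryptophan"),
    }
)


def cohort_frame(cohort: CohortTable) -> pd.DataFrame:
    """Flatten a cohort into a records × variables DataFrame.

    Columns are canonical analyte names across all present blocks, plus
    ``animal_id`` and ``sex``.
    """
    rows = []
    for r in cohort:
        row: dict[str, object] = {"animal_id": r.animal_id, "sex": r.sex}
        if r.proximate is not None:
            row.update(
                water=r.proximate.water_pct,
                dry_matter=r.proximate.dry_matter_pct,
                protein=r.proximate.protein_pct,
                fat=r.proximate.fat_pct,
                minerals=r.proximate.minerals_pct,
            )
        if r.fatty_acids is not None:
            row.update(r.fatty_acids.values)
        if r.amino_acids is not None:
            row.update(r.amino_acids.values)
        rows.append(row)
    return pd.DataFrame(rows)


def describe(
    cohort: CohortTable, variables: list[str] | None = None
) -> list[GroupSummary]:
    """Per-sex and overall mean, SD (n−1 denominator) and n.

    A group of size one reports SD = 0 with a warning rather than NaN.
    """
    df = cohort_frame(cohort)
    if variables is None:
        variables = [c for c in df.columns if c not in ("animal_id", "sex")]
    unknown = [v for v in variables if v not in df.columns]
    if unknown:
        raise KeyError(f"unknown variables: {unknown}")
    out: list[GroupSummary] = []
    groups: list[tuple[str, pd.DataFrame]] = [
        (sex, df[df["sex"] == sex]) for sex in ("male", "female")
    ]
    groups.append(("overall", df))
    for var in variables:
        for name, sub in groups:
            vals = sub[var].dropna().astype(float)
            if len(vals) == 0:
                continue
            if len(vals) == 1:
                warnings.warn(
                    f"{var}/{name}: single record, SD reported as 0",
                    stacklevel=2,
                )
                sd = 0.0
            else:
                sd = float(vals.std(ddof=1))
            out.append(
                GroupSummary(
                    variable=var,
                    group=name,
                    mean=float(vals.mean()),
                    sd=sd,
                    n=int(len(vals)),
                )
            )
    return out


def significance_code(p: float) -> str:
    """Conventional significance coding of a p-value."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_sexes(
    cohort: CohortTable, variable: str, welch: bool = False
) -> SignificanceResult:
    """One-way two-group ANOVA of a variable between the sexes.

    Equal-variance by default (the two-group ANOVA, F = t²); Welch's
    unequal-variance test by flag.  Requires ≥ 2 records per sex.
    """
    df = cohort_frame(cohort)
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    m = df.loc[df["sex"] == "male", variable].dropna().astype(float)
    f = df.loc[df["sex"] == "female", variable].dropna().astype(float)
    for name, vals in (("male", m), ("female", f)):
        if len(vals) < 2:
            raise ValueError(
                f"group {name!r} has {len(vals)} records; need at least 2"
            )
    if welch:
        p = float(sps.ttest_ind(m, f, equal_var=False).pvalue)
    else:
        p = float(sps.f_oneway(m, f).pvalue)
    return SignificanceResult(
        variable=variable, p_value=p, code=significance_code(p)
    )


def aggregate_categories(
    profile: AminoAcidProfile,
    scheme: AminoAcidCategoryScheme = DEFAULT_CATEGORY_SCHEME,
) -> dict[str, float]:
    """Sum member amino acids per category; ``total_aa`` sums everything."""
    out = {
        cat: sum(profile.get(m) for m in members)
        for cat, members in scheme.membership.items()
    }
    out["total_aa"] = profile.total()
    return out


def pca(
    cohort: CohortTable | pd.DataFrame,
    variables: list[str],
    standardize: bool = True,
) -> PcaResult:
    """PCA via eigendecomposition of the correlation (or covariance) matrix.

    Requires ≥ 3 records, ≥ 2 variables and no missing values.  Sign
    convention: within each loading column the largest-magnitude entry
    is made positive.  Scores are the centered (standardized) data
    projected on the loadings.
    """
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    if len(variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    if len(df) < 3:
        raise ValueError(
            f"PCA needs at least 3 records, got {len(df)} "
            "(group-mean tables cannot be decomposed)"
        )
    X = df[variables].astype(float).to_numpy()
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        constant = [v for v, s in zip(variables, sd) if s == 0]
        if constant:
            raise ValueError(
                f"constant variables cannot be standardized: {constant}"
            )
        Xc = Xc / sd
        mat = np.corrcoef(X, rowvar=False)
    else:
        mat = np.cov(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    # sign convention: largest-magnitude loading per component positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"F{i + 1}" for i in range(len(eigval))]
    scores = Xc @ eigvec
    index = (
        df["animal_id"] if "animal_id" in df.columns else pd.RangeIndex(len(df))
    )
    total = eigval.sum()
    return PcaResult(
        scores=pd.DataFrame(scores, columns=comps, index=index),
        loadings=pd.DataFrame(eigvec, columns=comps, index=variables),
        variance_explained={
            c: float(100.0 * v / total) for c, v in zip(comps, eigval)
        },
    )
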