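"""Synthetic sex-stratified cohort generation.

The generator emulates the statistical structure a compositional study
reports: per-analyte group means ± SD for males and females.  Each
analyte is drawn independently per animal from a normal distribution
truncated below (at zero by default), because marginal moments are all
such a report gives — no inter-analyte covariance is available, so none
is imposed (an explicit correlation hook exists but defaults to
independence).

Three scenarios ship with the package, parameterized by the fixture
tables of the Aubrac Longissimus dorsi study: ``aubrac_table3``
(proximate), ``aubrac_table4`` (fatty acids) and ``aubrac_table5``
(amino acids), each with the study's default group sizes of 27 males
and 22 females.

Structural constraints honoured during generation:

* water and dry matter are complementary — dry matter is computed as
  100 − water, never drawn independently;
* a fatty-acid vector whose draw exceeds the 101% validity bound is
  redrawn in full (a <1% event under the packaged scenarios);
* with ``closure_total`` set, fatty-acid vectors are rescaled to that
  exact total after drawing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import truncnorm

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
    "AnalyteModel",
    "CohortScenario",
    "RecoveryRow",
    "generate",
    "recover_parameters",
    "load_scenario",
    "PACKAGED_SCENARIOS",
]

PACKAGED_SCENARIOS = ("aubrac_table3", "aubrac_table4", "aubrac_table5")

_PROXIMATE_ANALYTES = ("water", "dry_matter", "protein", "fat", "minerals")


def _block_of(analyte: str) -> str:
    if analyte in _PROXIMATE_ANALYTES:
        return "proximate"
    try:
        canonical_fatty_acid(analyte)
        return "fatty_acid"
    except KeyError:
        pass
    try:
        canonical_amino_acid(analyte)
        return "amino_acid"
    except KeyError:
        pass
    raise KeyError(f"cannot classify analyte {analyte!r}")


@dataclass(frozen=True)
class AnalyteModel:
    """Marginal model for one analyte in one sex: N(mean, sd) truncated below."""

    analyte: str
    group: str
    mean: float
    sd: float
    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("male", "female"):
            raise ValidationError(f"group must be male/female, got {self.group!r}")
        if self.sd < 0:
            raise ValidationError(f"{self.analyte}: sd must be ≥ 0, got {self.sd}")
        if self.mean < self.lower_bound:
            raise ValidationError(
                f"{self.analyte}/{self.group}: mean {self.mean} below "
                f"lower bound {self.lower_bound}"
            )

    def distribution(self):
        """The frozen scipy distribution actually sampled (or None if sd=0)."""
        if self.sd == 0:
            return None
        a = (self.lower_bound - self.mean) / self.sd
        return truncnorm(a=a, b=np.inf, loc=self.mean, scale=self.sd)

    @property
    def true_mean(self) -> float:
        """Mean of the truncated generating distribution."""
        d = self.distribution()
        return self.mean if d is None else float(d.mean())

    @property
    def true_sd(self) -> float:
        d = self.distribution()
        return 0.0 if d is None else float(d.std())


@dataclass
class CohortScenario:
    """A generation recipe: group sizes, per-analyte models, closure, seed."""

    n_male: int
    n_female: int
    models: list[AnalyteModel]
    closure_total: float | None = None
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.n_male + self.n_female < 1:
            raise ValidationError("scenario must generate at least one animal")
        seen = set()
        for m in self.models:
            key = (m.analyte, m.group)
            if key in seen:
                raise ValidationError(f"duplicate model for {key}")
            seen.add(key)

    def models_for(self, sex: str) -> list[AnalyteModel]:
        return [m for m in self.models if m.group == sex]


@dataclass(frozen=True)
class RecoveryRow:
    """Sample-vs-model comparison for one (analyte, sex) pair."""

    analyte: str
    group: str
    model_mean: float
    sample_mean: float
    z: float
    flagged: bool


def _draw_block(
    rng: np.random.Generator,
    models: list[AnalyteModel],
    n: int,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for m in models:
        d = m.distribution()
        if d is None:
            out[m.analyte] = np.full(n, m.mean)
        else:
            out[m.analyte] = d.rvs(size=n, random_state=rng)
    return out


def generate(scenario: CohortScenario) -> CohortTable:
    """Draw a cohort from a scenario; fixed seed gives identical output.

    Each analyte is an independent truncated-normal draw.  Water and dry
    matter are kept complementary (dry matter = 100 − water).  If
    ``closure_total`` is set every fatty-acid vector is rescaled to sum
    to it exactly; otherwise vectors breaching the 101% validity bound
    are redrawn.
    """
    rng = np.random.default_rng(scenario.seed)
    records: list[AnimalRecord] = []
    for sex, n in (("male", scenario.n_male), ("female", scenario.n_female)):
        if n == 0:
            continue
        models = scenario.models_for(sex)
        blocks: dict[str, list[AnalyteModel]] = {}
        for m in models:
            blocks.setdefault(_block_of(m.analyte), []).append(m)

        prox_draws = fa_draws = aa_draws = None
        if "proximate" in blocks:
            # dry matter is derived, not drawn
            mdl = [m for m in blocks["proximate"] if m.analyte != "dry_matter"]
            prox_draws = _draw_block(rng, mdl, n)
            if "water" in prox_draws:
                prox_draws["dry_matter"] = 100.0 - prox_draws["water"]
        if "fatty_acid" in blocks:
            fa_models = blocks["fatty_acid"]
            fa_draws = _draw_block(rng, fa_models, n)
            names = list(fa_draws)
            mat = np.column_stack([fa_draws[a] for a in names])
            if scenario.closure_total is not None:
                mat = mat / mat.sum(axis=1, keepdims=True) * scenario.closure_total
            else:
                # redraw rows that breach the FAME-sum validity bound
                for _ in range(1000):
                    bad = np.flatnonzero(mat.sum(axis=1) > 101.0)
                    if bad.size == 0:
                        break
                    redraw = _draw_block(rng, fa_models, bad.size)
                    mat[bad] = np.column_stack([redraw[a] for a in names])
                else:
                    raise ValidationError(
                        "could not draw fatty-acid vectors within the 101% bound"
                    )
            fa_draws = {a: mat[:, j] for j, a in enumerate(names)}
        if "amino_acid" in blocks:
            aa_draws = _draw_block(rng, blocks["amino_acid"], n)

        for i in range(n):
            records.append(
                AnimalRecord(
                    animal_id=f"{sex}_{i + 1:04d}",
                    sex=sex,
                    proximate=(
                        ProximateComposition(
                            water_pct=prox_draws["water"][i],
                            dry_matter_pct=prox_draws["dry_matter"][i],
                            protein_pct=prox_draws["protein"][i],
                            fat_pct=prox_draws["fat"][i],
                            minerals_pct=prox_draws["minerals"][i],
                        )
                        if prox_draws is not None
                        else None
                    ),
                    fatty_acids=(
                        FattyAcidProfile(
                            {a: float(v[i]) for a, v in fa_draws.items()},
                            closed=scenario.closure_total is not None,
                        )
                        if fa_draws is not None
                        else None
                    ),
                    amino_acids=(
                        AminoAcidProfile(
                            {a: float(v[i]) for a, v in aa_draws.items()}
                        )
                        if aa_draws is not None
                        else None
                    ),
                )
            )
    return CohortTable(records, provenance=f"synthetic:{scenario.name}:seed={scenario.seed}")


def recover_parameters(
    cohort: CohortTable, scenario: CohortScenario
) -> list[RecoveryRow]:
    """z-score each sample mean against its generating distribution.

    The reference is the mean and SD of the *truncated* normal actually
    sampled (for analytes with mean ≫ 0 this coincides with the nominal
    parameters; near the bound it does not).  |z| > 3 is flagged.
    """
    from .stats import cohort_frame

    df = cohort_frame(cohort)
    out: list[RecoveryRow] = []
    for m in scenario.models:
        sub = df[df["sex"] == m.group]
        col = (
            m.analyte
            if m.analyte in df.columns
            else _canonical_column(m.analyte)
        )
        vals = sub[col].dropna().astype(float)
        n = len(vals)
        sample_mean = float(vals.mean())
        true_mean, true_sd = m.true_mean, m.true_sd
        if true_sd == 0:
            z = 0.0 if np.isclose(sample_mean, true_mean) else np.inf
        else:
            z = (sample_mean - true_mean) / (true_sd / np.sqrt(n))
        out.append(
            RecoveryRow(
                analyte=m.analyte,
                group=m.group,
                model_mean=true_mean,
                sample_mean=sample_mean,
                z=float(z),
                flagged=abs(z) > 3,
            )
        )
    return out


def _canonical_column(analyte: str) -> str:
    block = _block_of(analyte)
    if block == "fatty_acid":
        return canonical_fatty_acid(analyte)
    if block == "amino_acid":
        return canonical_amino_acid(analyte)
    return analyte


def load_scenario(
    source: str | Path,
    n_male: int | None = None,
    n_female: int | None = None,
    seed: int = 0,
    closure_total: float | None = None,
) -> CohortScenario:
    """Load a scenario from a packaged name or a YAML file path.

    Packaged names: ``aubrac_table3``, ``aubrac_table4``,
    ``aubrac_table5``.  Counts, seed and closure can be overridden.
    """
    if isinstance(source, str) and source in PACKAGED_SCENARIOS:
        ref = resources.files("nutriscore.data").joinpath(f"{source}.yaml")
        with resources.as_file(ref) as p:
            payload = yaml.safe_load(p.read_text())
    else:
        payload = yaml.safe_load(Path(source).read_text())
    models = [
        AnalyteModel(
            analyte=row["analyte"],
            group=row["group"],
            mean=float(row["mean"]),
            sd=float(row["sd"]),
            lower_bound=float(row.get("lower_bound", 0.0)),
        )
        for row in payload["models"]
    ]
    return CohortScenario(
        n_male=n_male if n_male is not None else int(payload.get("n_male", 27)),
        n_female=(
            n_female if n_female is not None else int(payload.get("n_female", 22))
        ),
        models=models,
        closure_total=(
            closure_total
            if closure_total is not None
            else payload.get("closure_total")
        ),
        seed=seed,
        name=payload.get("name", str(source)),
    )
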