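"""Population specifications and virtual-subject sampling.

A population is described distributionally (demographics, height–weight
relationship, haematocrit, per-CYP hepatic abundance) and virtual subjects are
Monte-Carlo realizations of that description. A disease population is derived
from the healthy baseline by scaling enzyme abundances, resetting haematocrit
and recalibrating the height–weight model to disease BMI targets.

The height–weight relationship is the exponential model

    weight = exp(a + x0 * height)        [weight kg, height cm]

with a multiplicative log-normal residual (geometric SD ``residual_gsd``).
Per-subject covariates with a mean m and coefficient of variation CV are drawn
log-normally with the arithmetic mean preserved: sigma^2 = ln(1 + CV^2),
mu = ln m - sigma^2/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .pooling import CYP_ENZYMES, _canonical_enzyme

Sex = Literal["male", "female"]


class HeightWeightModel(BaseModel):
    """Exponential height–weight model weight = exp(a + x0*height)."""

    a: float
    x0: float
    residual_gsd: float = Field(default=1.1, ge=1.0)


class SexSpec(BaseModel):
    """Per-sex anthropometric and haematocrit distribution."""

    height_mean_cm: float = Field(gt=0)
    height_sd_cm: float = Field(ge=0)
    height_weight: HeightWeightModel
    target_bmi_mean: float = Field(gt=0)
    haematocrit_mean_pct: float = Field(gt=0, lt=100)
    haematocrit_cv: float = Field(ge=0)


class PopulationSpec(BaseModel):
    """Distributional description of a virtual population."""

    name: str
    age_range_years: tuple[float, float] = (20.0, 65.0)
    proportion_female: float = Field(default=0.5, ge=0.0, le=1.0)
    male: SexSpec
    female: SexSpec
    albumin_ratio: float = Field(default=1.0, gt=0)
    cyp_abundance_mean: Dict[str, float]  # pmol per mg microsomal protein
    cyp_abundance_cv: Dict[str, float]
    mppgl_mg_per_g: float = Field(gt=0)  # microsomal protein per g liver
    liver_mass_g: float = Field(gt=0)
    hepatic_blood_flow_l_per_h: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        lo, hi = self.age_range_years
        if not (0 < lo <= hi):
            raise ValueError(f"bad age range {self.age_range_years}")
        self.cyp_abundance_mean = {
            _canonical_enzyme(k): v for k, v in self.cyp_abundance_mean.items()
        }
        self.cyp_abundance_cv = {
            _canonical_enzyme(k): v for k, v in self.cyp_abundance_cv.items()
        }
        for enz, mean in self.cyp_abundance_mean.items():
            if mean <= 0:
                raise ValueError(f"{enz} abundance mean must be > 0")
            if enz not in self.cyp_abundance_cv:
                raise ValueError(f"missing abundance CV for {enz}")
        return self

    def sex_spec(self, sex: Sex) -> SexSpec:
        return self.male if sex == "male" else self.female


@dataclass(frozen=True)
class Subject:
    """One sampled virtual individual."""

    sex: str
    age_years: float
    height_cm: float
    weight_kg: float
    haematocrit_pct: float
    cyp_abundance: Dict[str, float]  # pmol/mg
    mppgl_mg_per_g: float
    liver_mass_g: float
    hepatic_blood_flow_l_per_h: float

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


def predict_weight(model: HeightWeightModel, height_cm: float) -> float:
    """Deterministic weight (kg) at a given height, before residual noise."""
    return math.exp(model.a + height_cm * model.x0)


def calibrate_height_weight(
    target_bmi_mean: float,
    x0: float,
    mean_height_cm: float,
    residual_gsd: float = 1.1,
) -> HeightWeightModel:
    """Solve the intercept ``a`` so the model hits a target BMI at mean height.

    predict_weight(mean_height) / (mean_height/100)^2 == target_bmi_mean
    gives a = ln(BMI * (h/100)^2) - x0*h.
    """
    if target_bmi_mean <= 0 or mean_height_cm <= 0:
        raise ValueError("BMI target and mean height must be > 0")
    a = math.log(target_bmi_mean * (mean_height_cm / 100.0) ** 2) - x0 * mean_height_cm
    return HeightWeightModel(a=a, x0=x0, residual_gsd=residual_gsd)


def build_mafld_spec(
    healthy: PopulationSpec,
    cyp_scalars: Dict[str, float],
    bmi_targets: Dict[str, float] | None = None,
    hct_fold: float | None = None,
    hct_targets: Dict[str, float] | None = None,
    name: str = "mafld",
    albumin_ratio: float | None = None,
) -> PopulationSpec:
    """Derive a disease population from the healthy baseline.

    Per-CYP abundance means are multiplied by ``cyp_scalars`` (a fold change
    per enzyme; every enzyme modelled in the baseline must have one).
    Haematocrit is either multiplied by ``hct_fold`` or set directly from
    ``hct_targets`` ({'male': %, 'female': %}); the height–weight model is
    recalibrated to ``bmi_targets`` per sex. Everything else is copied.
    """
    scalars = {_canonical_enzyme(k): v for k, v in cyp_scalars.items()}
    missing = set(healthy.cyp_abundance_mean) - set(scalars)
    if missing:
        raise ValueError(f"missing CYP scalars for {sorted(missing)}")
    if any(s <= 0 for s in scalars.values()):
        raise ValueError("CYP scalars must be > 0")
    if hct_fold is not None and hct_fold <= 0:
        raise ValueError("haematocrit fold must be > 0")

    spec = healthy.model_copy(deep=True)
    spec.name = name
    spec.cyp_abundance_mean = {
        enz: mean * scalars[enz] for enz, mean in healthy.cyp_abundance_mean.items()
    }
    if albumin_ratio is not None:
        spec.albumin_ratio = albumin_ratio
    for sex in ("male", "female"):
        sspec: SexSpec = getattr(spec, sex)
        if hct_targets is not None:
            sspec.haematocrit_mean_pct = hct_targets[sex]
        elif hct_fold is not None:
            sspec.haematocrit_mean_pct = sspec.haematocrit_mean_pct * hct_fold
        if bmi_targets is not None:
            sspec.target_bmi_mean = bmi_targets[sex]
            sspec.height_weight = calibrate_height_weight(
                bmi_targets[sex],
                sspec.height_weight.x0,
                sspec.height_mean_cm,
                sspec.height_weight.residual_gsd,
            )
    return spec


# ---------------------------------------------------------------------------
# Sampling

def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw preserving the arithmetic mean; cv=0 is deterministic."""
    if cv == 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n_sd: float = 3.0) -> float:
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sd * sd:
            return float(x)


def sample_subject(
    spec: PopulationSpec,
    rng: np.random.Generator,
    sex: Sex | None = None,
) -> Subject:
    """Draw one virtual subject from a population specification.

    ``sex`` may be forced by the caller (trial designs balance sexes
    deterministically); otherwise it is Bernoulli(proportion_female). Height
    is normal truncated at ±3 SD; weight is the height–weight prediction times
    a log-normal residual; haematocrit and CYP abundances are log-normal with
    the configured mean and CV.
    """
    if sex is None:
        sex = "female" if rng.random() < spec.proportion_female else "male"
    sspec = spec.sex_spec(sex)
    lo, hi = spec.age_range_years
    age = float(rng.uniform(lo, hi))
    height = _truncated_normal(rng, sspec.height_mean_cm, sspec.height_sd_cm)
    gsd = sspec.height_weight.residual_gsd
    residual = math.exp(rng.normal(0.0, math.log(gsd))) if gsd > 1.0 else 1.0
    weight = predict_weight(sspec.height_weight, height) * residual
    hct = _lognormal_mean_cv(rng, sspec.haematocrit_mean_pct, sspec.haematocrit_cv)
    abundances = {
        enz: _lognormal_mean_cv(rng, mean, spec.cyp_abundance_cv[enz])
        for enz, mean in spec.cyp_abundance_mean.items()
    }
    return Subject(
        sex=sex,
        age_years=age,
        height_cm=height,
        weight_kg=weight,
        haematocrit_pct=hct,
        cyp_abundance=abundances,
        mppgl_mg_per_g=spec.mppgl_mg_per_g,
        liver_mass_g=spec.liver_mass_g,
        hepatic_blood_flow_l_per_h=spec.hepatic_blood_flow_l_per_h,
    )


# ---------------------------------------------------------------------------
# YAML serialization

def spec_to_yaml(spec: PopulationSpec, path: str | Path) -> None:
    data = spec.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def spec_from_yaml(path: str | Path) -> PopulationSpec:
    data = yaml.safe_load(Path(path).read_text())
    return PopulationSpec.model_validate(data)
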