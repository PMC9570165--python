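"""Packaged reference tables, fixture profiles and synthetic study generation.

Everything the pipeline consumes is generated here without downloads:

* the published study-level in vitro CYP activity ratio table and its pooled
  validation comparators (in vitro activity arm and pre-clinical animal arm);
* the published virtual-trial exposure table (geometric-mean AUC/Cmax per
  population) used for ratio arithmetic and equivalence flagging;
* eight probe-substrate compound profiles with literature-typical PK
  parameters (the commercial platform's compound models are proprietary, so
  these are documented approximations — quantitative validation rests only on
  the printed tables, never on these fixtures);
* healthy and fatty-liver-disease population profiles;
* synthetic study-ratio tables with known truth for pooling
  parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .engine import CompoundProfile, DoseRegimen, compound_to_yaml
from .pooling import StudyRecord
from .population import (
    HeightWeightModel,
    PopulationSpec,
    SexSpec,
    build_mafld_spec,
    calibrate_height_weight,
    spec_to_yaml,
)

_DATA = files("mafld_pbpk") / "data"

COMPOUND_NAMES = (
    "caffeine",
    "clozapine",
    "s-warfarin",
    "rosiglitazone",
    "omeprazole",
    "dextromethorphan",
    "metoprolol",
    "midazolam",
)

# q12h probes; everything else is dosed q24h in multiple-dose trials
_Q12H = {"midazolam", "dextromethorphan"}

# ---------------------------------------------------------------------------
# Published study-level in vitro activity ratios (MAFLD model / healthy model)

_ACTIVITY_STUDIES = [
    # enzyme, probe reaction, ratio, citation key
    ("CYP1A2", "7-methoxyresorufin O-demethylation", 0.46, "B25"),
    ("CYP1A2", "Phenacetin O-deethylation", 0.58, "B26"),
    ("CYP2C9", "Diclofenac 4'-hydroxylation", 0.82, "B25"),
    ("CYP2C9", "Testosterone 16b-hydroxylation", 0.64, "B25"),
    ("CYP2C9", "Testosterone 16b-hydroxylation", 0.40, "B27"),
    ("CYP2C9", "Diclofenac 4'-hydroxylation", 1.53, "B26"),
    ("CYP2C9", "Tolbutamide 4-hydroxylation", 1.42, "B26"),
    ("CYP2C19", "Androstenedione", 0.46, "B25"),
    ("CYP2C19", "Testosterone 16b-hydroxylation", 0.40, "B27"),
    ("CYP2C19", "Androstenedione", 0.62, "B27"),
    ("CYP2C19", "Mephenytoin 4'-hydroxylation", 0.21, "B26"),
    ("CYP2D6", "Dextromethorphan O-demethylation", 0.68, "B26"),
    ("CYP3A4", "Midazolam 1'-hydroxylation", 0.45, "B28"),
    ("CYP3A4", "Testosterone 6b-hydroxylation", 0.55, "B25"),
    ("CYP3A4", "Testosterone 6b-hydroxylation", 0.57, "B25"),
    ("CYP3A4", "Testosterone 2b-hydroxylation", 0.41, "B25"),
    ("CYP3A4", "Testosterone 15b-hydroxylation", 0.55, "B27"),
    ("CYP3A4", "Testosterone 6b-hydroxylation", 0.44, "B27"),
    ("CYP3A4", "Testosterone 2b-hydroxylation", 0.43, "B27"),
    ("CYP3A4", "Testosterone 6b-hydroxylation", 0.46, "B29"),
    ("CYP3A4", "Midazolam 1'-hydroxylation", 0.41, "B28"),
    ("CYP3A4", "Midazolam 1'-hydroxylation", 0.61, "B30"),
]

# Published validation comparators: observed in vitro control/MAFLD activity
# ratio vs simulated probe AUC ratio, with the printed MFE column.
_INVITRO_VALIDATION = [
    ("CYP1A2", 1.93, 2.12, 1.10),
    ("CYP2C9", 1.04, 1.00, 1.04),
    ("CYP2C19", 2.38, 2.52, 1.06),
    ("CYP2D6", 1.46, 1.32, 1.11),
    ("CYP3A4", 2.03, 1.55, 1.31),
]

# Published animal-model PK ratios (MAFLD/healthy animals) vs simulated human
# ratios, with the printed MFE column and citation key.
_ANIMAL_STUDIES = [
    ("CYP1A2", "caffeine", "AUC", 2.90, 2.12, 1.37, "B9"),
    ("CYP1A2", "caffeine", "Cmax", 2.50, 1.14, 2.19, "B9"),
    ("CYP1A2", "clozapine", "AUC", 1.20, 1.81, 1.50, "B12"),
    ("CYP1A2", "clozapine", "Cmax", 0.69, 1.15, 1.66, "B12"),
    ("CYP2C9", "rosiglitazone", "AUC", 2.41, 1.16, 2.08, "B10"),
    ("CYP2C9", "rosiglitazone", "Cmax", 0.86, 0.982, 1.14, "B10"),
    ("CYP2C19", "omeprazole", "AUC", 11.1, 2.52, 4.40, "B9"),
    ("CYP2C19", "omeprazole", "Cmax", 6.50, 1.54, 4.23, "B9"),
    ("CYP2D6", "dextromethorphan", "AUC", 2.69, 1.32, 2.03, "B9"),
    ("CYP2D6", "dextromethorphan", "Cmax", 3.31, 1.20, 2.77, "B9"),
    ("CYP2D6", "metoprolol", "AUC", 2.28, 1.45, 1.57, "B11"),
    ("CYP2D6", "metoprolol", "Cmax", 1.41, 1.22, 1.16, "B11"),
    ("CYP3A4", "midazolam", "AUC", 1.55, 1.55, 1.00, "B9"),
    ("CYP3A4", "midazolam", "Cmax", 1.22, 1.11, 1.10, "B9"),
]

# Published virtual-trial geometric means (healthy vs disease) and printed
# ratios; suspect=1 marks the metoprolol healthy single-dose Cmax, whose
# printed value (1412) contradicts its own interval and is treated as a typo.
_EXPOSURE_TABLE = [
    # compound, enzyme, regimen, metric, healthy, mafld, printed_ratio, suspect
    ("caffeine", "CYP1A2", "single", "cmax", 3399, 3885, 1.14, 0),
    ("caffeine", "CYP1A2", "single", "auc", 23712, 50331, 2.12, 0),
    ("caffeine", "CYP1A2", "multiple", "cmax", 3597, 5568, 1.55, 0),
    ("caffeine", "CYP1A2", "multiple", "auc", 25130, 72715, 2.89, 0),
    ("clozapine", "CYP1A2", "single", "cmax", 54.4, 62.6, 1.15, 0),
    ("clozapine", "CYP1A2", "single", "auc", 436, 788, 1.81, 0),
    ("clozapine", "CYP1A2", "multiple", "cmax", 58.4, 81.3, 1.39, 0),
    ("clozapine", "CYP1A2", "multiple", "auc", 469, 1026, 2.19, 0),
    ("s-warfarin", "CYP2C9", "single", "cmax", 924, 866, 0.94, 0),
    ("s-warfarin", "CYP2C9", "single", "auc", 15458, 15500, 1.00, 0),
    ("s-warfarin", "CYP2C9", "multiple", "cmax", 1877, 1983, 1.06, 0),
    ("s-warfarin", "CYP2C9", "multiple", "auc", 31630, 35778, 1.13, 0),
    ("rosiglitazone", "CYP2C9", "single", "cmax", 245, 241, 0.98, 0),
    ("rosiglitazone", "CYP2C9", "single", "auc", 1152, 1331, 1.16, 0),
    ("rosiglitazone", "CYP2C9", "multiple", "cmax", 248, 247, 0.99, 0),
    ("rosiglitazone", "CYP2C9", "multiple", "auc", 1166, 1364, 1.17, 0),
    ("omeprazole", "CYP2C19", "single", "cmax", 153, 236, 1.54, 0),
    ("omeprazole", "CYP2C19", "single", "auc", 467, 1174, 2.52, 0),
    ("omeprazole", "CYP2C19", "multiple", "cmax", 191, 323, 1.70, 0),
    ("omeprazole", "CYP2C19", "multiple", "auc", 666, 2112, 3.17, 0),
    ("dextromethorphan", "CYP2D6", "single", "cmax", 4.25, 5.08, 1.20, 0),
    ("dextromethorphan", "CYP2D6", "single", "auc", 49.9, 66.0, 1.32, 0),
    ("dextromethorphan", "CYP2D6", "multiple", "cmax", 7.56, 10.1, 1.33, 0),
    ("dextromethorphan", "CYP2D6", "multiple", "auc", 63.6, 89.8, 1.41, 0),
    ("metoprolol", "CYP2D6", "single", "cmax", 1412, 172, 1.22, 1),
    ("metoprolol", "CYP2D6", "single", "auc", 841, 1223, 1.45, 0),
    ("metoprolol", "CYP2D6", "multiple", "cmax", 145, 180, 1.24, 0),
    ("metoprolol", "CYP2D6", "multiple", "auc", 863, 1276, 1.48, 0),
    ("midazolam", "CYP3A4", "single", "cmax", 18.7, 20.7, 1.11, 0),
    ("midazolam", "CYP3A4", "single", "auc", 54.7, 84.8, 1.55, 0),
    ("midazolam", "CYP3A4", "multiple", "cmax", 19.9, 23.4, 1.18, 0),
    ("midazolam", "CYP3A4", "multiple", "auc", 56.1, 89.7, 1.60, 0),
]

# ---------------------------------------------------------------------------
# Population defaults
#
# Healthy baseline abundances (pmol/mg microsomal protein) and a common 40%
# log-normal CV are literature-typical values for adult human liver; MPPGL,
# liver mass and hepatic blood flow are standard adult IVIVE scaling factors.

HEALTHY_CYP_ABUNDANCE = {
    "CYP1A2": 52.0,
    "CYP2C9": 73.0,
    "CYP2C19": 14.0,
    "CYP2D6": 8.0,
    "CYP3A4": 137.0,
}
HEALTHY_CYP_CV = {enz: 0.40 for enz in HEALTHY_CYP_ABUNDANCE}

# Disease/healthy abundance fold changes applied to the healthy baseline.
# CYP1A2 and CYP2C9 are the pooled abundance meta-analysis values (abundance
# reduced by 63% and 28%). The remaining three are CALIBRATED: chosen so the
# low-extraction single-enzyme identity 1/(fm*s + 1 - fm), with the fixture
# fm of the enzyme's dominant probe, reproduces that probe's published
# single-dose AUC ratio. They are not published values.
MAFLD_CYP_SCALARS = {
    "CYP1A2": 0.37,
    "CYP2C9": 0.72,
    "CYP2C19": 0.307,  # CALIBRATED from omeprazole 2.52, fm 0.87
    "CYP2D6": 0.715,  # CALIBRATED from dextromethorphan 1.32, fm 0.85
    "CYP3A4": 0.623,  # CALIBRATED from midazolam 1.55, fm 0.94
}

MAFLD_HCT_TARGETS = {"male": 48.2, "female": 42.6}  # = healthy x 1.12
MAFLD_BMI_TARGETS = {"male": 29.7, "female": 27.3}
HEALTHY_BMI_TARGETS = {"male": 24.4, "female": 23.5}
HEIGHT_WEIGHT_SLOPE = 0.012  # per cm, shared slope; intercept set by BMI target


def healthy_population_spec() -> PopulationSpec:
    """Healthy-volunteer baseline population."""

    def sex_spec(height_mean: float, height_sd: float, bmi: float, hct: float) -> SexSpec:
        return SexSpec(
            height_mean_cm=height_mean,
            height_sd_cm=height_sd,
            height_weight=calibrate_height_weight(bmi, HEIGHT_WEIGHT_SLOPE, height_mean),
            target_bmi_mean=bmi,
            haematocrit_mean_pct=hct,
            haematocrit_cv=0.05,
        )

    return PopulationSpec(
        name="healthy",
        age_range_years=(20.0, 65.0),
        proportion_female=0.5,
        male=sex_spec(176.0, 7.0, HEALTHY_BMI_TARGETS["male"], 43.0),
        female=sex_spec(163.0, 6.0, HEALTHY_BMI_TARGETS["female"], 38.0),
        cyp_abundance_mean=dict(HEALTHY_CYP_ABUNDANCE),
        cyp_abundance_cv=dict(HEALTHY_CYP_CV),
        mppgl_mg_per_g=40.0,
        liver_mass_g=1650.0,
        hepatic_blood_flow_l_per_h=90.0,
    )


def mafld_population_spec() -> PopulationSpec:
    """Disease population derived from the healthy baseline."""
    return build_mafld_spec(
        healthy_population_spec(),
        cyp_scalars=MAFLD_CYP_SCALARS,
        bmi_targets=MAFLD_BMI_TARGETS,
        hct_targets=MAFLD_HCT_TARGETS,
        name="mafld",
    )


# ---------------------------------------------------------------------------
# Compound fixture library
#
# Literature-typical oral PK parameters per probe. ``fm`` is the fraction of
# hepatic intrinsic clearance through each CYP; ``clint_total`` (uL/min/mg
# microsomal protein) sets a plausible whole-body clearance when scaled by
# MPPGL 40 mg/g and a 1650 g liver.

_COMPOUNDS: dict[str, dict] = {
    "caffeine": dict(
        dose_mg=150.0, ka_per_h=4.0, fa_fg=1.0, fu=0.65, bp_ratio=1.04,
        vss_l_per_kg=0.5, fm={"CYP1A2": 0.95}, clint_total=3.7, cl_renal=0.08,
    ),
    "clozapine": dict(
        dose_mg=12.5, ka_per_h=1.5, fa_fg=0.9, fu=0.05, bp_ratio=0.85,
        vss_l_per_kg=5.4, fm={"CYP1A2": 0.70, "CYP3A4": 0.15}, clint_total=190.0,
        cl_renal=0.0,
    ),
    "s-warfarin": dict(
        dose_mg=10.0, ka_per_h=1.0, fa_fg=1.0, fu=0.01, bp_ratio=0.55,
        vss_l_per_kg=0.14, fm={"CYP2C9": 0.91}, clint_total=2.8, cl_renal=0.0,
    ),
    "rosiglitazone": dict(
        dose_mg=4.0, ka_per_h=1.2, fa_fg=0.99, fu=0.002, bp_ratio=0.8,
        vss_l_per_kg=0.25, fm={"CYP2C9": 0.49}, clint_total=310.0, cl_renal=0.0,
    ),
    "omeprazole": dict(
        dose_mg=20.0, ka_per_h=2.0, fa_fg=0.9, fu=0.05, bp_ratio=0.6,
        vss_l_per_kg=0.3, fm={"CYP2C19": 0.87}, clint_total=135.0, cl_renal=0.0,
    ),
    "dextromethorphan": dict(
        dose_mg=30.0, ka_per_h=1.5, fa_fg=0.95, fu=0.35, bp_ratio=1.0,
        vss_l_per_kg=5.0, fm={"CYP2D6": 0.85}, clint_total=80.0, cl_renal=0.5,
    ),
    "metoprolol": dict(
        dose_mg=100.0, ka_per_h=2.0, fa_fg=0.95, fu=0.88, bp_ratio=1.1,
        vss_l_per_kg=4.0, fm={"CYP2D6": 0.78}, clint_total=57.0, cl_renal=6.0,
    ),
    "midazolam": dict(
        dose_mg=5.0, ka_per_h=6.0, fa_fg=0.55, fu=0.03, bp_ratio=0.66,
        vss_l_per_kg=1.0, fm={"CYP3A4": 0.94}, clint_total=215.0, cl_renal=0.0,
    ),
}


def compound_profile(name: str) -> CompoundProfile:
    """Build one fixture compound profile from the library parameters.

    The per-enzyme microsomal CLint is partitioned by fm against the healthy
    baseline abundances, so that in the *healthy* population each enzyme
    carries its nominal fraction of clearance; the non-CYP remainder goes to
    ``clint_other``.
    """
    if name not in _COMPOUNDS:
        raise KeyError(f"unknown compound {name!r}; have {sorted(_COMPOUNDS)}")
    p = _COMPOUNDS[name]
    total = p["clint_total"]
    fm = p["fm"]
    clint_per_pmol = {
        enz: round(frac * total / HEALTHY_CYP_ABUNDANCE[enz], 6) for enz, frac in fm.items()
    }
    return CompoundProfile(
        name=name,
        dose_mg=p["dose_mg"],
        ka_per_h=p["ka_per_h"],
        fa_fg=p["fa_fg"],
        fu=p["fu"],
        bp_ratio=p["bp_ratio"],
        vss_l_per_kg=p["vss_l_per_kg"],
        clint_per_pmol=clint_per_pmol,
        clint_other_ul_min_mg=round((1.0 - sum(fm.values())) * total, 6),
        cl_renal_l_per_h=p["cl_renal"],
    )


def compound_fm(name: str) -> dict[str, float]:
    """Nominal per-CYP fraction metabolized of a fixture compound."""
    return dict(_COMPOUNDS[name]["fm"])


def default_regimen(name: str, multiple: bool = False, observation_window_h: float = 24.0) -> DoseRegimen:
    """Single dose, or 10 doses q24h (q12h for the short-interval probes)."""
    interval = 12.0 if name in _Q12H else 24.0
    return DoseRegimen(
        dose_mg=_COMPOUNDS[name]["dose_mg"],
        interval_h=interval,
        n_doses=10 if multiple else 1,
        observation_window_h=observation_window_h,
    )


# ---------------------------------------------------------------------------
# Synthetic study-ratio tables with known truth

class SyntheticStudySpec(BaseModel):
    """Log-normal between-study heterogeneity around a known true ratio."""

    enzyme: str
    endpoint: str = "activity"
    true_ratio: float = Field(gt=0)
    n_studies: int = Field(ge=1)
    log_sd: float = Field(ge=0)
    seed: int = 0


def generate_study_table(spec: SyntheticStudySpec) -> list[StudyRecord]:
    """Draw n study records with ratio = true_ratio * exp(N(0, log_sd))."""
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.log_sd, size=spec.n_studies) if spec.log_sd > 0 else np.zeros(spec.n_studies)
    return [
        StudyRecord(
            enzyme=spec.enzyme,
            endpoint=spec.endpoint,
            ratio=float(spec.true_ratio * np.exp(z)),
            probe_reaction="synthetic",
            source_ref=f"synthetic-{i}",
        )
        for i, z in enumerate(noise)
    ]


# ---------------------------------------------------------------------------
# DataFrame builders and packaged-file loaders

def _activity_frame() -> pd.DataFrame:
    df = pd.DataFrame(_ACTIVITY_STUDIES, columns=["enzyme", "probe_reaction", "ratio", "source_ref"])
    df["endpoint"] = "activity"
    df["model_system"] = "human_microsomes"
    return df[["enzyme", "endpoint", "probe_reaction", "ratio", "source_ref", "model_system"]]


def _invitro_frame() -> pd.DataFrame:
    return pd.DataFrame(
        _INVITRO_VALIDATION,
        columns=["enzyme", "observed_ratio", "simulated_ratio", "printed_mfe"],
    )


def _animal_frame() -> pd.DataFrame:
    return pd.DataFrame(
        _ANIMAL_STUDIES,
        columns=["enzyme", "substrate", "parameter", "observed_ratio", "simulated_ratio", "printed_mfe", "source_ref"],
    )


def _exposure_frame() -> pd.DataFrame:
    return pd.DataFrame(
        _EXPOSURE_TABLE,
        columns=["compound", "enzyme", "regimen", "metric", "healthy", "mafld", "printed_ratio", "suspect"],
    )


def load_activity_studies() -> pd.DataFrame:
    """Study-level in vitro activity ratio table (packaged CSV)."""
    with (_DATA / "cyp_activity_studies.csv").open() as fh:
        return pd.read_csv(fh)


def activity_study_records() -> list[StudyRecord]:
    from .pooling import records_from_frame

    return records_from_frame(load_activity_studies())


def load_invitro_validation() -> pd.DataFrame:
    """Observed in vitro vs simulated ratio comparators per enzyme."""
    with (_DATA / "invitro_validation.csv").open() as fh:
        return pd.read_csv(fh)


def load_animal_studies() -> pd.DataFrame:
    """Observed animal-model vs simulated ratio comparators per substrate."""
    with (_DATA / "animal_pk_studies.csv").open() as fh:
        return pd.read_csv(fh)


def animal_study_records() -> list[StudyRecord]:
    return [
        StudyRecord(
            enzyme=row.enzyme,
            endpoint={"AUC": "in_vivo_AUC", "Cmax": "in_vivo_Cmax"}[row.parameter],
            probe_reaction=row.substrate,
            ratio=float(row.observed_ratio),
            source_ref=str(row.source_ref),
            model_system="animal",
        )
        for row in load_animal_studies().itertuples()
    ]


def load_exposure_table() -> pd.DataFrame:
    """Published virtual-trial geometric means and printed exposure ratios."""
    with (_DATA / "simulated_exposure.csv").open() as fh:
        return pd.read_csv(fh)


def load_compound(name: str) -> CompoundProfile:
    from .engine import CompoundProfile as CP
    import yaml

    with (_DATA / "compounds" / f"{name}.yaml").open() as fh:
        return CP.model_validate(yaml.safe_load(fh))


def load_population(name: str) -> PopulationSpec:
    import yaml

    with (_DATA / "populations" / f"{name}.yaml").open() as fh:
        return PopulationSpec.model_validate(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Fixture writer

def make_fixture_library(output_dir: str | Path) -> list[Path]:
    """Write every fixture file (CSV tables, compound YAMLs, population YAMLs).

    Deterministic: regenerating into the same directory yields byte-identical
    files. Returns the list of written paths.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "compounds").mkdir(exist_ok=True)
    (out / "populations").mkdir(exist_ok=True)
    written: list[Path] = []

    frames = {
        "cyp_activity_studies.csv": _activity_frame(),
        "invitro_validation.csv": _invitro_frame(),
        "animal_pk_studies.csv": _animal_frame(),
        "simulated_exposure.csv": _exposure_frame(),
    }
    for fname, df in frames.items():
        path = out / fname
        df.to_csv(path, index=False)
        written.append(path)

    for name in COMPOUND_NAMES:
        path = out / "compounds" / f"{name}.yaml"
        compound_to_yaml(compound_profile(name), path)
        written.append(path)

    for name, spec in (("healthy", healthy_population_spec()), ("mafld", mafld_population_spec())):
        path = out / "populations" / f"{name}.yaml"
        spec_to_yaml(spec, path)
        written.append(path)
    return written
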