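"""Model validation by mean fold error against observed comparators.

Simulated disease/healthy exposure ratios are compared with two orthogonal
observed arms: pooled in vitro CYP activity ratios (inverted to the
control/MAFLD orientation so that reduced activity reads as increased
exposure) and probe-substrate PK ratios from pre-clinical animal models. The
accuracy statistic is the absolute mean fold error

    MFE = max(simulated/observed, observed/simulated) >= 1

with MFE <= 2 classified as robust concordance and anything above as poor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Literal, Sequence

import pandas as pd

from .pooling import PooledEffect, StudyRecord, to_observed_activity_ratio

ROBUST_THRESHOLD = 2.0

Concordance = Literal["robust", "poor"]

# Default probe substrate per enzyme for the in vitro comparison arm.
PRIMARY_PROBE: Dict[str, str] = {
    "CYP1A2": "caffeine",
    "CYP2C9": "s-warfarin",
    "CYP2C19": "omeprazole",
    "CYP2D6": "dextromethorphan",
    "CYP3A4": "midazolam",
}


@dataclass(frozen=True)
class MFEResult:
    enzyme: str
    parameter: str  # AUC | Cmax | activity
    observed_ratio: float
    simulated_ratio: float
    mfe: float
    concordance: str
    substrate: str | None = None


def mfe(simulated_ratio: float, observed_ratio: float) -> float:
    """Absolute mean fold error: max(sim/obs, obs/sim), always >= 1."""
    if simulated_ratio <= 0 or observed_ratio <= 0:
        raise ValueError("ratios must be > 0")
    return max(simulated_ratio / observed_ratio, observed_ratio / simulated_ratio)


def classify_concordance(mfe_value: float) -> Concordance:
    """Within 2-fold (inclusive) is robust model performance; above is poor."""
    if mfe_value < 1.0:
        raise ValueError(f"an MFE is >= 1 by construction, got {mfe_value}")
    return "robust" if mfe_value <= ROBUST_THRESHOLD else "poor"


def _mfe_result(
    enzyme: str,
    parameter: str,
    observed: float,
    simulated: float,
    substrate: str | None = None,
) -> MFEResult:
    value = mfe(simulated, observed)
    return MFEResult(
        enzyme=enzyme,
        parameter=parameter,
        observed_ratio=observed,
        simulated_ratio=simulated,
        mfe=value,
        concordance=classify_concordance(value),
        substrate=substrate,
    )


def build_validation_tables(
    simulated: pd.DataFrame,
    observed_invitro: Sequence[PooledEffect] = (),
    observed_animal: Sequence[StudyRecord] = (),
    round_observed_first: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Assemble the in vitro and animal validation reports.

    ``simulated`` needs columns enzyme, substrate, parameter ('AUC'/'Cmax'),
    ratio — the disease/healthy geometric-mean ratios from virtual trials.
    The in vitro arm yields one row per enzyme (pooled activity inverted via
    :func:`to_observed_activity_ratio`, matched against the enzyme's primary
    probe AUC ratio). The animal arm yields one row per (substrate, parameter)
    plus per-enzyme arithmetic averages of the substrate AUC MFEs. Comparators
    without a matching simulated ratio are returned in the missing list.
    """
    required = {"enzyme", "substrate", "parameter", "ratio"}
    if not required.issubset(simulated.columns):
        raise ValueError(f"simulated frame needs columns {sorted(required)}")
    missing: list[str] = []

    invitro_rows: list[MFEResult] = []
    for effect in observed_invitro:
        probe = PRIMARY_PROBE.get(effect.enzyme)
        sel = simulated[
            (simulated.enzyme == effect.enzyme)
            & (simulated.parameter == "AUC")
            & ((simulated.substrate == probe) if probe else True)
        ]
        if sel.empty:
            sel = simulated[(simulated.enzyme == effect.enzyme) & (simulated.parameter == "AUC")]
        if sel.empty:
            missing.append(f"invitro:{effect.enzyme}")
            continue
        observed = to_observed_activity_ratio(effect, round_first=round_observed_first)
        invitro_rows.append(
            _mfe_result(effect.enzyme, "activity", observed, float(sel.iloc[0].ratio))
        )

    animal_rows: list[MFEResult] = []
    for rec in observed_animal:
        parameter = {"in_vivo_AUC": "AUC", "in_vivo_Cmax": "Cmax"}.get(rec.endpoint, rec.endpoint)
        substrate = rec.probe_reaction
        sel = simulated[
            (simulated.enzyme == rec.enzyme)
            & (simulated.substrate == substrate)
            & (simulated.parameter == parameter)
        ]
        if sel.empty:
            missing.append(f"animal:{rec.enzyme}:{substrate}:{parameter}")
            continue
        animal_rows.append(
            _mfe_result(rec.enzyme, parameter, rec.ratio, float(sel.iloc[0].ratio), substrate)
        )

    invitro_df = _results_frame(invitro_rows)
    animal_df = _results_frame(animal_rows)
    return invitro_df, animal_df, missing


def enzyme_average_mfe(animal_df: pd.DataFrame, parameter: str = "AUC") -> pd.Series:
    """Arithmetic mean of substrate-level MFEs per enzyme for one parameter."""
    sub = animal_df[animal_df.parameter == parameter]
    return sub.groupby("enzyme").mfe.mean()


def _results_frame(rows: Iterable[MFEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "enzyme": r.enzyme,
                "substrate": r.substrate,
                "parameter": r.parameter,
                "observed_ratio": r.observed_ratio,
                "simulated_ratio": r.simulated_ratio,
                "mfe": r.mfe,
                "concordance": r.concordance,
            }
            for r in rows
        ],
        columns=[
            "enzyme",
            "substrate",
            "parameter",
            "observed_ratio",
            "simulated_ratio",
            "mfe",
            "concordance",
        ],
    )
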