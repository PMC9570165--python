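"""Pooling of study-level MAFLD/control ratios for CYP abundance and activity.

Published studies report the effect of fatty liver disease on a CYP enzyme as
a ratio of the diseased to the healthy measurement (abundance in pmol/mg, or
probe-reaction activity). This module pools such ratios across studies into a
single proportional-difference effect per enzyme, and converts a pooled
activity ratio into the control/MAFLD orientation used as the observed
comparator in model validation.

No inverse-variance weighting is applied: each study contributes equally,
matching the unweighted pooling used to build the disease population profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

CYP_ENZYMES = ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4")

Endpoint = Literal["abundance", "activity", "in_vivo_AUC", "in_vivo_Cmax"]
ModelSystem = Literal["human_microsomes", "human_hepatocytes", "biopsy", "animal"]
PoolingMethod = Literal["arithmetic", "geometric"]

STUDY_COLUMNS = ["enzyme", "endpoint", "probe_reaction", "ratio", "source_ref", "model_system"]


def _canonical_enzyme(enzyme: str) -> str:
    """Accept '1A2' or 'CYP1A2' spellings; return the canonical 'CYP1A2'."""
    name = enzyme.upper()
    if not name.startswith("CYP"):
        name = "CYP" + name
    if name not in CYP_ENZYMES:
        raise ValueError(f"unknown CYP enzyme {enzyme!r}; expected one of {CYP_ENZYMES}")
    return name


@dataclass(frozen=True)
class StudyRecord:
    """One study's MAFLD/control ratio for a single enzyme and endpoint.

    ``ratio`` is dimensionless (diseased measurement over healthy control);
    values below 1 indicate reduced abundance/activity in disease.
    """

    enzyme: str
    endpoint: str
    ratio: float
    probe_reaction: str = ""
    source_ref: str = ""
    model_system: str = "human_microsomes"

    def __post_init__(self) -> None:
        object.__setattr__(self, "enzyme", _canonical_enzyme(self.enzyme))
        if not self.ratio > 0:
            raise ValueError(f"study ratio must be > 0, got {self.ratio}")


@dataclass(frozen=True)
class PooledEffect:
    """Pooled proportional difference for one enzyme and endpoint."""

    enzyme: str
    endpoint: str
    n_studies: int
    pooled_ratio: float
    ratio_min: float
    ratio_max: float
    method: str

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("a pooled effect needs at least one study")
        if not (self.ratio_min <= self.pooled_ratio <= self.ratio_max):
            raise ValueError(
                f"pooled ratio {self.pooled_ratio} outside study range "
                f"[{self.ratio_min}, {self.ratio_max}]"
            )


def pool_ratios(records: Sequence[StudyRecord], method: PoolingMethod = "arithmetic") -> PooledEffect:
    """Pool study ratios for one enzyme+endpoint into a single effect.

    ``arithmetic`` returns the plain mean of the ratios; ``geometric`` returns
    exp(mean(ln ratio)). The reported range is the min/max of the inputs.

    When the two methods disagree by more than 1% a warning is emitted: the
    source tables label their pooled column a geometric mean, yet the printed
    values are reproduced by the arithmetic mean, so the discrepancy is worth
    surfacing to the caller.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot pool an empty list of study records")
    if method not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown pooling method {method!r}")
    enzymes = {r.enzyme for r in records}
    endpoints = {r.endpoint for r in records}
    if len(enzymes) > 1:
        raise ValueError(f"records mix enzymes: {sorted(enzymes)}")
    if len(endpoints) > 1:
        raise ValueError(f"records mix endpoints: {sorted(endpoints)}")
    ratios = np.array([r.ratio for r in records], dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("all study ratios must be > 0")

    arith = float(ratios.mean())
    geo = float(np.exp(np.log(ratios).mean()))
    pooled = arith if method == "arithmetic" else geo
    # guard against a few ulp of roundoff pushing the mean past the extremes
    pooled = float(np.clip(pooled, ratios.min(), ratios.max()))
    if len(ratios) > 1 and abs(arith - geo) / geo > 0.01:
        warnings.warn(
            f"{records[0].enzyme} {records[0].endpoint}: arithmetic ({arith:.3f}) and "
            f"geometric ({geo:.3f}) pooled ratios differ by >1%; method={method}",
            stacklevel=2,
        )
    return PooledEffect(
        enzyme=records[0].enzyme,
        endpoint=records[0].endpoint,
        n_studies=len(ratios),
        pooled_ratio=pooled,
        ratio_min=float(ratios.min()),
        ratio_max=float(ratios.max()),
        method=method,
    )


def pool_table(
    records: Iterable[StudyRecord],
    method: PoolingMethod = "arithmetic",
    by_system: bool = False,
) -> list[PooledEffect]:
    """Pool a mixed table of study records, grouped by enzyme and endpoint.

    With ``by_system=True`` the pooling is additionally stratified by
    ``model_system`` (a sensitivity analysis: does the pooled effect depend on
    whether it was measured in microsomes, hepatocytes, biopsy or animals?).
    The stratified effects carry ``endpoint`` suffixed with ``@system``.
    """
    groups: dict[tuple, list[StudyRecord]] = {}
    for rec in records:
        key = (rec.enzyme, rec.endpoint, rec.model_system if by_system else None)
        groups.setdefault(key, []).append(rec)
    effects = []
    for (enzyme, endpoint, system), recs in sorted(groups.items()):
        eff = pool_ratios(recs, method=method)
        if system is not None:
            eff = PooledEffect(
                enzyme=eff.enzyme,
                endpoint=f"{endpoint}@{system}",
                n_studies=eff.n_studies,
                pooled_ratio=eff.pooled_ratio,
                ratio_min=eff.ratio_min,
                ratio_max=eff.ratio_max,
                method=eff.method,
            )
        effects.append(eff)
    return effects


def to_observed_activity_ratio(effect: PooledEffect, round_first: bool = False) -> float:
    """Reciprocal of a pooled MAFLD/control ratio: the control/MAFLD orientation.

    An activity *reduction* in disease (pooled ratio < 1) becomes a value > 1
    comparable to a disease/healthy exposure ratio — reduced metabolism means
    increased exposure. With ``round_first=True`` the pooled ratio is rounded
    to 2 decimals before inverting, matching published tables that invert the
    printed (2-decimal) pooled value.
    """
    pooled = effect.pooled_ratio
    if round_first:
        pooled = round(pooled, 2)
    if not pooled > 0:
        raise ValueError(f"pooled ratio must be > 0, got {pooled}")
    return 1.0 / pooled


# ---------------------------------------------------------------------------
# CSV I/O

def read_study_csv(path: str | Path) -> list[StudyRecord]:
    """Read study records from a CSV with the standard study columns."""
    df = pd.read_csv(path)
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study CSV {path} lacks columns: {sorted(missing)}")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[StudyRecord]:
    return [
        StudyRecord(
            enzyme=row.enzyme,
            endpoint=row.endpoint,
            probe_reaction=row.probe_reaction if isinstance(row.probe_reaction, str) else "",
            ratio=float(row.ratio),
            source_ref=str(row.source_ref),
            model_system=row.model_system,
        )
        for row in df.itertuples()
    ]


def effects_to_frame(effects: Sequence[PooledEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "enzyme": e.enzyme,
                "endpoint": e.endpoint,
                "n_studies": e.n_studies,
                "pooled_ratio": e.pooled_ratio,
                "ratio_min": e.ratio_min,
                "ratio_max": e.ratio_max,
                "method": e.method,
            }
            for e in effects
        ]
    )
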