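"""Hakanson ecological risk: per-PEM risk factor Er and their sum PERI.

Er_i = Tr_i × CF_i, where CF_i is the contamination factor of the *mean*
concentration (over at least five sampling points) relative to background,
and Tr_i is the element's toxic-response factor.  PERI = Σ Er_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core_data import QUANTIFIED_PEMS, SampleSet, ToxicResponseTable
from .quality_indices import BackgroundProfile, contamination_factor


def classify_er(value: float) -> str:
    if value < 40:
        return "low"
    if value < 80:
        return "moderate"
    if value < 160:
        return "considerable"
    if value < 320:
        return "high"
    return "extremely high"


def classify_peri(value: float) -> str:
    if value < 150:
        return "low"
    if value < 300:
        return "moderate"
    if value < 600:
        return "considerable"
    if value < 1200:
        return "high"
    return "extremely high"


@dataclass
class EcoRiskTable:
    """Mean concentrations, CF, Er per PEM, and the PERI aggregate."""

    mean_concentration: dict[str, float]
    cf: dict[str, float]
    er: dict[str, float]
    peri: float
    er_class: dict[str, str]
    peri_class: str
    background_used: BackgroundProfile


def mean_profile(
    samples: SampleSet,
    pems: Sequence[str] = QUANTIFIED_PEMS,
) -> dict[str, float]:
    """Per-PEM arithmetic mean concentration over a resolved sample set."""
    if len(samples) == 0:
        raise ValueError("cannot take a mean profile of an empty sample set")
    if len(samples) < 5:
        warnings.warn(
            "ecological risk calls for mean concentrations from at least "
            f"five sampling points; got {len(samples)}",
            stacklevel=2,
        )
    out: dict[str, float] = {}
    for pem in pems:
        values = [ws.resolved(pem, samples.censor_policy) for ws in samples]
        out[pem] = sum(values) / len(values)
    return out


def ecological_risk(
    means: Mapping[str, float],
    bg: BackgroundProfile,
    tr: ToxicResponseTable | None = None,
) -> EcoRiskTable:
    """Er = Tr × CF for each PEM in ``means``; missing Tr or Cb raises."""
    tr = tr or ToxicResponseTable()
    profile = contamination_factor(dict(means), bg)
    er = {pem: tr[pem] * cf for pem, cf in profile.cf.items()}
    total = sum(er.values())
    return EcoRiskTable(
        mean_concentration=dict(means),
        cf=dict(profile.cf),
        er=er,
        peri=total,
        er_class={pem: classify_er(v) for pem, v in er.items()},
        peri_class=classify_peri(total),
        background_used=bg,
    )


def peri(table: EcoRiskTable) -> tuple[float, str]:
    """PERI = Σ Er with its classification band."""
    if not table.er:
        raise ValueError("ecological risk table holds no Er values")
    value = sum(table.er.values())
    return value, classify_peri(value)


def risk_table(
    samples: SampleSet,
    bg: BackgroundProfile,
    tr: ToxicResponseTable | None = None,
    pems: Sequence[str] = QUANTIFIED_PEMS,
) -> pd.DataFrame:
    """Mean / Cb / CF / Tr / Er rows per PEM (PERI in ``df.attrs``)."""
    tr = tr or ToxicResponseTable()
    means = mean_profile(samples, pems)
    table = ecological_risk(means, bg, tr)
    df = pd.DataFrame(
        {
            "mean_concentration": table.mean_concentration,
            "Cb": {p: bg[p] for p in pems},
            "Cf": table.cf,
            "Tr": {p: tr[p] for p in pems},
            "Er": table.er,
            "Er_class": table.er_class,
        }
    ).loc[list(pems)]
    df.attrs["PERI"] = table.peri
    df.attrs["PERI_class"] = table.peri_class
    return df
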