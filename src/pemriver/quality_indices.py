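"""Water-quality indices: HEI, PLI/CF, weighted WQI and the CCME WQI.

Two families of index are implemented.  Regulatory-compliance indices
(HEI, WQI, CCME WQI) compare concentrations with maximum permissible
limits; baseline-deviation indices (contamination factor, PLI) compare
them with a background profile derived from uncontaminated reference
sites.  Each computation returns an :class:`IndexReport` carrying the
value, its per-parameter components and a classification band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core_data import (
    QUANTIFIED_PEMS,
    SampleSet,
    StandardsRegistry,
    WQIScheme,
    WaterSample,
    resolve_censored,
)

# ---------------------------------------------------------------------------
# Classification bands.  Bounds follow the printed inequalities of each
# index's source convention; where open/closed is printed inconsistently,
# left-closed intervals are used and noted in the docs.


def classify_hei(value: float) -> str:
    if value <= 40:
        return "low"
    if value <= 80:
        return "medium"
    return "high"


def classify_pli(value: float) -> str:
    if value < 1:
        return "none"
    if value < 2:
        return "moderate"
    if value < 5:
        return "severe"
    return "extreme"


def classify_wqi(value: float) -> str:
    if value < 50:
        return "excellent"
    if value < 100:
        return "good"
    if value < 200:
        return "poor"
    if value < 300:
        return "very poor"
    return "unsuitable"


def classify_ccme(value: float) -> str:
    if value > 95:
        return "excellent"
    if value >= 80:
        return "good"
    if value >= 65:
        return "fair"
    if value >= 45:
        return "marginal"
    return "poor"


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class IndexReport:
    """Universal output record: value + breakdown + classification."""

    index_name: str
    value: float
    components: dict[str, float]
    classification: str
    scope: str


@dataclass
class BackgroundProfile:
    """Per-PEM baseline concentrations Cb (µg/L) and their provenance."""

    cb: dict[str, float]
    derivation: str = ""

    def __getitem__(self, pem: str) -> float:
        try:
            return self.cb[pem]
        except KeyError:
            raise KeyError(f"background profile has no entry for {pem}") from None


@dataclass
class ContaminationProfile:
    """Contamination factors CF = C / Cb per PEM."""

    cf: dict[str, float]
    background_used: BackgroundProfile


@dataclass
class CCMEBreakdown:
    """Intermediate quantities of the CCME index (scope F1, frequency F2,
    amplitude F3 with its normalised sum of excursions)."""

    f1: float
    f2: float
    f3: float
    nse: float
    excursions: list[tuple[str, str, float]]
    n_parameters: int
    n_tests: int
    n_failed_parameters: int
    n_failed_tests: int


# ---------------------------------------------------------------------------
# Operations


def derive_background(
    s: SampleSet,
    reference_sites: Sequence[str] = ("NY-01", "NY-13"),
    policy: str = "half_dl",
    pems: Sequence[str] = QUANTIFIED_PEMS,
) -> BackgroundProfile:
    """Background Cb = arithmetic mean over reference sites, per PEM.

    Works on a raw or resolved set; raw sets are resolved with ``policy``
    first.  Under ``drop`` a PEM censored at every reference site raises.
    """
    if s.censor_policy == "raw":
        s = resolve_censored(s, policy)
    refs = []
    for site in reference_sites:
        refs.append(s.get(site))  # KeyError if absent
    cb: dict[str, float] = {}
    for pem in pems:
        values = [ws.concentrations[pem].resolved(s.censor_policy)
                  for ws in refs if pem in ws.concentrations]
        values = [v for v in values if v is not None]
        if not values:
            raise ValueError(
                f"background for {pem} undefined: all reference measurements "
                f"censored/dropped under policy {s.censor_policy!r}"
            )
        cb[pem] = sum(values) / len(values)
    return BackgroundProfile(
        cb=cb,
        derivation=f"mean of {list(reference_sites)} under {s.censor_policy}",
    )


def contamination_factor(
    concentrations: Mapping[str, float],
    bg: BackgroundProfile,
) -> ContaminationProfile:
    """Element-wise CF = C / Cb for resolved concentrations."""
    cf = {pem: c / bg[pem] for pem, c in concentrations.items()}
    return ContaminationProfile(cf=cf, background_used=bg)


def _resolved_map(
    sample: WaterSample, pems: Sequence[str], policy: str
) -> dict[str, float]:
    out = {}
    for pem in pems:
        if pem not in sample.concentrations:
            raise KeyError(
                f"{pem} missing at {sample.site_id} (dropped or never measured)"
            )
        m = sample.concentrations[pem]
        if m.censored:
            raise ValueError(
                f"{pem} at {sample.site_id} still censored; resolve first"
            )
        out[pem] = m.value  # type: ignore[assignment]
    return out


def hei(
    sample: WaterSample,
    limits: Mapping[str, float] | StandardsRegistry | None = None,
    pems: Sequence[str] = QUANTIFIED_PEMS,
) -> IndexReport:
    """Heavy metal Evaluation Index: HEI = Σ Cᵢ / MPLᵢ.

    ``limits`` maps PEM → maximum permissible limit (µg/L); by default the
    UNBS potable-water plan with the BC cobalt guideline.  Every requested
    PEM must have a limit — none is skipped silently.
    """
    plan = _as_plan(limits, pems)
    conc = _resolved_map(sample, pems, "resolved")
    components = {}
    for pem in pems:
        if pem not in plan:
            raise KeyError(f"no permissible limit for {pem} in the plan")
        components[pem] = conc[pem] / float(plan[pem])  # type: ignore[arg-type]
    value = sum(components.values())
    return IndexReport("HEI", value, components, classify_hei(value),
                       scope=f"{sample.site_id}: {list(pems)}")


def pli(
    sample: WaterSample,
    bg: BackgroundProfile,
    pems: Sequence[str] = QUANTIFIED_PEMS,
) -> IndexReport:
    """Pollution Load Index: geometric mean of the contamination factors.

    Computed in log space for numerical stability; any CF ≤ 0 raises.
    """
    conc = _resolved_map(sample, pems, "resolved")
    profile = contamination_factor(conc, bg)
    bad = [p for p, v in profile.cf.items() if v <= 0]
    if bad:
        raise ValueError(f"nonpositive contamination factor(s) for {bad}")
    value = math.exp(sum(math.log(v) for v in profile.cf.values())
                     / len(profile.cf))
    return IndexReport("PLI", value, dict(profile.cf), classify_pli(value),
                       scope=f"{sample.site_id}: {list(pems)}")


def wqi(sample: WaterSample, scheme: WQIScheme | None = None) -> IndexReport:
    """Weighted WQI = Σ Cᵢ·Wᵢ / (Sᵢ·ΣW) × 100 over pH and the PEMs.

    pH enters as a plain ratio against its upper objective.  When every
    parameter sits exactly at its standard the index is 100 regardless of
    the weights.
    """
    scheme = scheme or WQIScheme()
    wsum = scheme.weight_sum
    components = {}
    for param, weight in scheme.weights.items():
        if param == "pH":
            c = sample.pH
        else:
            c = _resolved_map(sample, (param,), "resolved")[param]
        try:
            s_i = scheme.s_values[param]
        except KeyError:
            raise KeyError(f"scheme has no standard S for {param}") from None
        components[param] = (c * weight) / (s_i * wsum) * 100.0
    value = sum(components.values())
    return IndexReport("WQI", value, components, classify_wqi(value),
                       scope=f"{sample.site_id}: {list(scheme.weights)}")


def _as_plan(
    limits: Mapping[str, float | tuple[float, float]] | StandardsRegistry | None,
    pems: Sequence[str],
    include_ph: bool = False,
) -> Mapping[str, float | tuple[float, float]]:
    if limits is None:
        limits = StandardsRegistry.default()
    if isinstance(limits, StandardsRegistry):
        return limits.plan(parameters=pems, include_ph=include_ph)
    return limits


def ccme_wqi(
    samples: SampleSet,
    objectives: Mapping[str, float | tuple[float, float]] | StandardsRegistry | None = None,
    parameters: Sequence[str] = ("pH",) + QUANTIFIED_PEMS,
) -> tuple[IndexReport, CCMEBreakdown]:
    """CCME WQI = 100 − √(F1² + F2² + F3²)/1.732 over a monitoring set.

    F1 (scope) is the percentage of parameters failing at least once, F2
    (frequency) the percentage of failed tests, and F3 the amplitude,
    an asymptotic transform of the normalised sum of excursions.  Upper-
    bound objectives use ``value/objective − 1``; a two-sided pH objective
    also penalises values below the lower bound with ``lower/value − 1``.
    The model minimum is four parameters sampled at least four times.
    """
    params = list(parameters)
    pems_only = [p for p in params if p != "pH"]
    plan = _as_plan(objectives, pems_only, include_ph="pH" in params)
    n_parameters = len(params)
    n_tests = n_parameters * len(samples)
    if n_parameters < 4 or len(samples) < 4:
        raise ValueError(
            "CCME WQI model minimum is 4 parameters sampled at least 4 "
            f"times; got {n_parameters} parameters × {len(samples)} samples"
        )
    excursions: list[tuple[str, str, float]] = []
    failed_parameters: set[str] = set()
    for ws in samples:
        for param in params:
            objective = plan[param]
            if param == "pH":
                lo, hi = objective  # type: ignore[misc]
                v = ws.pH
                if v > hi:
                    exc = v / hi - 1.0
                elif v < lo:
                    exc = lo / v - 1.0
                else:
                    continue
            else:
                v = _resolved_map(ws, (param,), "resolved")[param]
                limit = float(objective)  # type: ignore[arg-type]
                if v > limit:  # ties at the limit count as passed
                    exc = v / limit - 1.0
                else:
                    continue
            excursions.append((ws.site_id, param, exc))
            failed_parameters.add(param)
    n_failed_tests = len(excursions)
    f1 = 100.0 * len(failed_parameters) / n_parameters
    f2 = 100.0 * n_failed_tests / n_tests
    nse = sum(e for _, _, e in excursions) / n_tests
    f3 = 100.0 * nse / (nse + 1.0)
    value = 100.0 - math.sqrt(f1 ** 2 + f2 ** 2 + f3 ** 2) / 1.732
    value = max(value, 0.0)
    breakdown = CCMEBreakdown(
        f1=f1, f2=f2, f3=f3, nse=nse, excursions=excursions,
        n_parameters=n_parameters, n_tests=n_tests,
        n_failed_parameters=len(failed_parameters),
        n_failed_tests=n_failed_tests,
    )
    report = IndexReport(
        "CCME WQI", value, {"F1": f1, "F2": f2, "F3": f3},
        classify_ccme(value),
        scope=f"{len(samples)} samples × {n_parameters} parameters",
    )
    return report, breakdown


def exceedance_summary(
    samples: SampleSet,
    pem: str,
    threshold: float,
) -> tuple[int, float]:
    """Count and percentage of samples strictly exceeding ``threshold``."""
    values = [
        _resolved_map(ws, (pem,), "resolved")[pem] for ws in samples
    ]
    count = sum(1 for v in values if v > threshold)
    return count, 100.0 * count / len(values) if values else 0.0


def indices_table(
    samples: SampleSet,
    bg: BackgroundProfile,
    limits: Mapping[str, float] | StandardsRegistry | None = None,
    scheme: WQIScheme | None = None,
    pems: Sequence[str] = QUANTIFIED_PEMS,
) -> "pd.DataFrame":
    """Per-site HEI / PLI / WQI summary mirroring a monitoring report table."""
    import pandas as pd

    rows = []
    for ws in samples:
        rows.append({
            "site_id": ws.site_id,
            "distance_km": ws.distance_km,
            "HEI": hei(ws, limits, pems).value,
            "PLI": pli(ws, bg, pems).value,
            "WQI": wqi(ws, scheme).value,
        })
    return pd.DataFrame(rows).set_index("site_id")
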