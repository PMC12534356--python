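"""US-EPA style human health risk assessment for water-borne metal(loid)s.

Exposure doses are estimated for two pathways — ingestion of river water
(chronic daily dose, CDD) and dermal contact (dermally absorbed dose,
DAD) — and characterised as non-carcinogenic hazard (HQ per pathway and
PEM, HI aggregate) and excess lifetime cancer risk (ELCR per pathway, CR
total) for configurable cohorts (child / adult by default).

    CDD = C·IR·ED·EF / (AT·BW)
    DAD = C·Kp·ED·EF·ET·SA·CF_vol / (AT·BW),  CF_vol = 10⁻³ L/cm³

The volumetric factor converts the cm³ of water film implied by
Kp (cm/h) × SA (cm²) × ET (h) to litres so the dose comes out in
mg/kg-day; the governing equation is frequently printed without it.

Concentrations enter this module in µg/L (the package-wide unit) and are
converted to mg/L at the boundary.

Averaging time is an explicit per-scenario field.  By default both the
non-cancer and the cancer averaging times equal the exposure duration
(AT = ED × 365 days), i.e. cancer risk is averaged over the exposure
period rather than a fixed 70-year lifetime; this is what keeps the child
cohort's risk above the adult's (the child's IR/BW and SA·ET/BW ratios
are higher) and matches how this assessment is conventionally applied to
drinking-water scenarios in the mining-impact literature.  Set
``AT_cancer = 70 * 365`` on a scenario to recover the fixed-lifetime
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_data import WaterSample

UG_PER_L_TO_MG_PER_L = 1e-3
L_PER_CM3 = 1e-3  # volumetric conversion for the dermal dose

CARCINOGENS: tuple[str, ...] = ("As", "Ni", "Pb")


def classify_hq(value: float) -> str:
    if value < 1:
        return "negligible"
    if value < 10:
        return "moderately significant"
    return "highly significant"


def classify_hi(value: float) -> str:
    return "no harmful effect" if value < 1 else "potential harmful impact"


#: Default three-band cancer-risk rule; override via ``cr_bands=`` with any
#: ordered (upper_bound, label) list for finer gradations.
DEFAULT_CR_BANDS: tuple[tuple[float, str], ...] = (
    (1e-6, "negligible"),
    (1e-4, "acceptable"),
    (float("inf"), "unacceptable"),
)


def classify_cr(
    value: float,
    bands: Sequence[tuple[float, str]] = DEFAULT_CR_BANDS,
) -> str:
    for upper, label in bands:
        if value < upper:
            return label
    return bands[-1][1]


@dataclass(frozen=True)
class ExposureScenario:
    """Cohort exposure parameters.

    IR L/day, ED years, EF days/year, BW kg, ET hours/event, SA cm²;
    averaging times in days (``None`` → ED × 365 for both modes).
    """

    cohort: str
    IR: float
    ED: float
    EF: float
    BW: float
    ET: float
    SA: float
    AT_noncancer: float | None = None
    AT_cancer: float | None = None

    def __post_init__(self) -> None:
        for name in ("IR", "ED", "EF", "BW", "ET", "SA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def averaging_time(self, mode: str) -> float:
        if mode == "noncancer":
            at = self.AT_noncancer
        elif mode == "cancer":
            at = self.AT_cancer
        else:
            raise ValueError(f"mode must be noncancer|cancer, got {mode!r}")
        if at is None:
            at = self.ED * 365.0
        if at <= 0:
            raise ValueError("averaging time must be > 0")
        return at


#: US-EPA RAGS residential defaults (resident child 0–6 y, resident adult).
CHILD = ExposureScenario(cohort="child", IR=1.0, ED=6.0, EF=350.0,
                         BW=15.0, ET=1.0, SA=6600.0)
ADULT = ExposureScenario(cohort="adult", IR=2.0, ED=30.0, EF=350.0,
                         BW=70.0, ET=0.58, SA=18000.0)
DEFAULT_SCENARIOS: tuple[ExposureScenario, ...] = (CHILD, ADULT)


@dataclass(frozen=True)
class ToxicityRecord:
    """Per-PEM toxicology: Kp cm/h, RfD_ing mg/kg-day, ABS_g fraction,
    optional oral cancer slope factor (mg/kg-day)⁻¹."""

    Kp: float
    RfD_ing: float
    ABS_g: float
    CSF_oral: float | None = None

    def __post_init__(self) -> None:
        if self.Kp < 0:
            raise ValueError("Kp must be >= 0")
        if self.RfD_ing <= 0:
            raise ValueError("RfD_ing must be > 0")
        if not 0 < self.ABS_g <= 1:
            raise ValueError("ABS_g must lie in (0, 1]")

    @property
    def rfd_abs(self) -> float:
        """Absorbed-basis reference dose: RfD_ing × ABS_g."""
        return self.RfD_ing * self.ABS_g

    @property
    def csf_abs(self) -> float:
        """Absorbed-basis slope factor: CSF_oral / ABS_g."""
        if self.CSF_oral is None:
            raise ValueError("no oral cancer slope factor available")
        return self.CSF_oral / self.ABS_g


@dataclass
class ToxicityTable:
    """PEM → :class:`ToxicityRecord`; defaults seeded from US-EPA IRIS/RAGS
    residential values and the toxicology commonly used in water-risk
    studies.  Editable: pass your own mapping or use :meth:`updated`."""

    records: dict[str, ToxicityRecord] = field(default_factory=lambda: {
        "Al": ToxicityRecord(Kp=0.001, RfD_ing=1.0, ABS_g=1.0),
        "As": ToxicityRecord(Kp=0.001, RfD_ing=3.0e-4, ABS_g=1.0, CSF_oral=1.5),
        "Cd": ToxicityRecord(Kp=0.001, RfD_ing=5.0e-4, ABS_g=0.025),
        "Co": ToxicityRecord(Kp=0.0004, RfD_ing=3.0e-4, ABS_g=1.0),
        "Cr": ToxicityRecord(Kp=0.002, RfD_ing=3.0e-3, ABS_g=0.025),
        "Cu": ToxicityRecord(Kp=0.001, RfD_ing=4.0e-2, ABS_g=1.0),
        "Fe": ToxicityRecord(Kp=0.001, RfD_ing=0.7, ABS_g=1.0),
        "Mn": ToxicityRecord(Kp=0.001, RfD_ing=0.14, ABS_g=0.04),
        "Mo": ToxicityRecord(Kp=0.001, RfD_ing=5.0e-3, ABS_g=1.0),
        "Ni": ToxicityRecord(Kp=0.0002, RfD_ing=2.0e-2, ABS_g=0.04, CSF_oral=0.91),
        "Pb": ToxicityRecord(Kp=0.0001, RfD_ing=3.5e-3, ABS_g=1.0, CSF_oral=8.5e-3),
        "Zn": ToxicityRecord(Kp=0.0006, RfD_ing=0.3, ABS_g=1.0),
    })

    def __getitem__(self, pem: str) -> ToxicityRecord:
        try:
            return self.records[pem]
        except KeyError:
            raise KeyError(f"no toxicity record for {pem}") from None

    def __contains__(self, pem: str) -> bool:
        return pem in self.records

    def updated(self, **overrides: ToxicityRecord) -> "ToxicityTable":
        merged = dict(self.records)
        merged.update(overrides)
        return ToxicityTable(merged)


#: PEMs assessed for non-cancer hazard by default: the ten quantified in the
#: packaged dataset (Cd, Cr below detection there).
DEFAULT_HAZARD_PEMS: tuple[str, ...] = (
    "Al", "As", "Co", "Cu", "Fe", "Mn", "Mo", "Ni", "Pb", "Zn",
)


@dataclass
class RiskReport:
    """Per-site, per-cohort risk breakdown."""

    site_id: str
    cohort: str
    cdd: dict[str, float] = field(default_factory=dict)
    dad: dict[str, float] = field(default_factory=dict)
    hq_ing: dict[str, float] = field(default_factory=dict)
    hq_dermal: dict[str, float] = field(default_factory=dict)
    hq: dict[str, float] = field(default_factory=dict)
    hq_class: dict[str, str] = field(default_factory=dict)
    hi: float = 0.0
    hi_class: str = ""
    elcr_ing: dict[str, float] = field(default_factory=dict)
    elcr_dermal: dict[str, float] = field(default_factory=dict)
    cr: dict[str, float] = field(default_factory=dict)
    cr_class: dict[str, str] = field(default_factory=dict)
    cr_total: float = 0.0
    cr_total_class: str = ""
    skipped: list[str] = field(default_factory=list)


def chronic_daily_dose(
    c_mg_per_l: float,
    scenario: ExposureScenario,
    mode: str = "noncancer",
) -> float:
    """Ingestion dose in mg/kg-day from a concentration in mg/L."""
    if c_mg_per_l < 0:
        raise ValueError("concentration must be >= 0")
    at = scenario.averaging_time(mode)
    return (c_mg_per_l * scenario.IR * scenario.ED * scenario.EF) / (
        at * scenario.BW
    )


def dermally_absorbed_dose(
    c_mg_per_l: float,
    kp_cm_per_h: float,
    scenario: ExposureScenario,
    mode: str = "noncancer",
) -> float:
    """Dermal dose in mg/kg-day, with the explicit 10⁻³ L/cm³ conversion."""
    if c_mg_per_l < 0:
        raise ValueError("concentration must be >= 0")
    if kp_cm_per_h < 0:
        raise ValueError("Kp must be >= 0")
    at = scenario.averaging_time(mode)
    return (
        c_mg_per_l * kp_cm_per_h * scenario.ED * scenario.EF
        * scenario.ET * scenario.SA * L_PER_CM3
    ) / (at * scenario.BW)


def hazard_assessment(
    sample: WaterSample,
    scenario: ExposureScenario,
    tox: ToxicityTable | None = None,
    pems: Sequence[str] = DEFAULT_HAZARD_PEMS,
) -> RiskReport:
    """Non-carcinogenic hazard: HQ per pathway and PEM, HI aggregate.

    HQ_ing = CDD/RfD_ing; HQ_dermal = DAD/RfD_ABS with
    RfD_ABS = RfD_ing × ABS_g.  A PEM without a toxicity record is skipped
    and listed in ``report.skipped`` (never silently).
    """
    tox = tox or ToxicityTable()
    report = RiskReport(site_id=sample.site_id, cohort=scenario.cohort)
    for pem in pems:
        if pem not in tox:
            report.skipped.append(pem)
            continue
        rec = tox[pem]
        c = sample.resolved(pem, "half_dl") * UG_PER_L_TO_MG_PER_L
        cdd = chronic_daily_dose(c, scenario, "noncancer")
        dad = dermally_absorbed_dose(c, rec.Kp, scenario, "noncancer")
        report.cdd[pem] = cdd
        report.dad[pem] = dad
        report.hq_ing[pem] = cdd / rec.RfD_ing
        report.hq_dermal[pem] = dad / rec.rfd_abs
        report.hq[pem] = report.hq_ing[pem] + report.hq_dermal[pem]
        report.hq_class[pem] = classify_hq(report.hq[pem])
    report.hi = sum(report.hq.values())
    report.hi_class = classify_hi(report.hi)
    return report


def cancer_assessment(
    sample: WaterSample,
    scenario: ExposureScenario,
    tox: ToxicityTable | None = None,
    pems: Sequence[str] = CARCINOGENS,
    cr_bands: Sequence[tuple[float, str]] = DEFAULT_CR_BANDS,
) -> RiskReport:
    """Cancer risk: ELCR per pathway, CR per PEM and summed.

    ELCR_ing = CDD × CSF_oral; ELCR_dermal = DAD × CSF_ABS with
    CSF_ABS = CSF_oral / ABS_g.  Requesting a PEM without a slope factor
    raises (slope factors exist only for As, Ni, Pb here).
    """
    tox = tox or ToxicityTable()
    report = RiskReport(site_id=sample.site_id, cohort=scenario.cohort)
    for pem in pems:
        rec = tox[pem]
        if rec.CSF_oral is None:
            raise ValueError(f"no cancer slope factor available for {pem}")
        c = sample.resolved(pem, "half_dl") * UG_PER_L_TO_MG_PER_L
        cdd = chronic_daily_dose(c, scenario, "cancer")
        dad = dermally_absorbed_dose(c, rec.Kp, scenario, "cancer")
        report.cdd[pem] = cdd
        report.dad[pem] = dad
        report.elcr_ing[pem] = cdd * rec.CSF_oral
        report.elcr_dermal[pem] = dad * rec.csf_abs
        report.cr[pem] = report.elcr_ing[pem] + report.elcr_dermal[pem]
        report.cr_class[pem] = classify_cr(report.cr[pem], cr_bands)
    report.cr_total = sum(report.cr.values())
    report.cr_total_class = classify_cr(report.cr_total, cr_bands)
    return report


def risk_frame(
    samples: Iterable[WaterSample],
    scenarios: Sequence[ExposureScenario] = DEFAULT_SCENARIOS,
    tox: ToxicityTable | None = None,
    hazard_pems: Sequence[str] = DEFAULT_HAZARD_PEMS,
    cancer_pems: Sequence[str] = CARCINOGENS,
) -> "pd.DataFrame":
    """Long-format table (site × cohort × PEM × pathway) of doses and risks."""
    import pandas as pd

    tox = tox or ToxicityTable()
    rows = []
    for ws in samples:
        for sc in scenarios:
            hz = hazard_assessment(ws, sc, tox, hazard_pems)
            ca = cancer_assessment(ws, sc, tox, cancer_pems)
            for pem in hz.hq:
                rows.append({
                    "site_id": ws.site_id, "cohort": sc.cohort, "pem": pem,
                    "CDD": hz.cdd[pem], "DAD": hz.dad[pem],
                    "HQ_ing": hz.hq_ing[pem], "HQ_dermal": hz.hq_dermal[pem],
                    "HQ": hz.hq[pem], "HI": hz.hi,
                    "CR": ca.cr.get(pem), "CR_total": ca.cr_total,
                })
    return pd.DataFrame(rows)
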