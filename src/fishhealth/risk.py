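"""USEPA-style methylmercury exposure screening and consumption limits.

For a consumer eating fish with muscle total mercury T-Hg (ug/g wet weight):

    C    = 0.9 * T-Hg                  MeHg fraction of muscle T-Hg
    EDI  = C * MS / BW                 ug MeHg / kg body weight / day
    HQ   = EDI / RfD                   RfD = 0.1 ug/kg/day
    CRmw = 7 * RfD * BW / (C * MS)     allowed meals per week

with MS the meal size (g) and BW the body weight (kg). For the reference
adult (MS = 230 g, BW = 70 kg) the CRmw numerator is the familiar constant
49 = 0.1 * 70 * 7; the generalized form is used so non-adult scenarios scale
with their own body weight. Whole meals per week are floored, never rounded:
a CRmw below one meal means the stratum should not be eaten weekly at all.
HQ > 1 (strictly) flags potential non-cancer risk. For any T-Hg > 0 the
identity CRmw_raw * HQ = 7 holds exactly, since both derive from one EDI.
"""

from __future__ import annotations

import math

from .defaults import DEFAULT_CONSUMERS, DEFAULT_RFD, MEHG_FRACTION
from .errors import ValidationError
from .model import ConsumerProfile, FishSpecimen, RiskResult

#: Cap on meals/week reported when the mercury concentration is zero.
UNRESTRICTED_MEALS = 21


def mehg_concentration(thg_ugg: float) -> float:
    """Methylmercury concentration C = 0.9 * T-Hg (ug/g ww)."""
    if thg_ugg < 0:
        raise ValidationError("T-Hg concentration must be nonnegative")
    return MEHG_FRACTION * thg_ugg


def estimated_daily_intake(thg_ugg: float, profile: ConsumerProfile) -> float:
    """EDI = C * MS / BW in ug MeHg per kg body weight per day."""
    return mehg_concentration(thg_ugg) * profile.meal_size_g / profile.body_weight_kg


def hazard_quotient(edi_ugkgday: float, rfd: float = DEFAULT_RFD) -> float:
    """HQ = EDI / RfD; > 1 (strictly) signals potential non-cancer risk."""
    if rfd <= 0:
        raise ValidationError("RfD must be positive")
    if edi_ugkgday < 0:
        raise ValidationError("EDI must be nonnegative")
    return edi_ugkgday / rfd


def weekly_consumption_limit(
    thg_ugg: float, profile: ConsumerProfile, rfd: float = DEFAULT_RFD
) -> tuple[float, int, bool]:
    """Allowed meals/week: (raw value, floored whole meals, unrestricted flag).

    CRmw = 7 * RfD * BW / (C * MS); equals 49/(C * MS) for the reference
    adult. A zero concentration caps the result at ``UNRESTRICTED_MEALS``.
    """
    c = mehg_concentration(thg_ugg)
    if rfd <= 0:
        raise ValidationError("RfD must be positive")
    if c == 0:
        return float(UNRESTRICTED_MEALS), UNRESTRICTED_MEALS, True
    raw = 7.0 * rfd * profile.body_weight_kg / (c * profile.meal_size_g)
    if raw >= UNRESTRICTED_MEALS:
        return raw, UNRESTRICTED_MEALS, True
    return raw, math.floor(raw), False


def assess(
    species: str,
    season: str,
    thg_ugg: float,
    profile: ConsumerProfile,
    rfd: float = DEFAULT_RFD,
) -> RiskResult:
    """Full risk record for one stratum mean T-Hg and one consumer scenario."""
    edi = estimated_daily_intake(thg_ugg, profile)
    hq = hazard_quotient(edi, rfd)
    raw, meals, unrestricted = weekly_consumption_limit(thg_ugg, profile, rfd)
    return RiskResult(
        species=species, season=season, profile=profile.name,
        thg_ugg=thg_ugg, c_mehg_ugg=mehg_concentration(thg_ugg),
        edi_ugkgday=edi, hq=hq, crmw_raw=raw, crmw_meals=meals,
        unrestricted=unrestricted, verdict="risk" if hq > 1 else "minimal",
    )


def assess_cohort(
    specimens: list[FishSpecimen],
    profiles: list[ConsumerProfile] | None = None,
    rfd: float = DEFAULT_RFD,
) -> list[RiskResult]:
    """Risk table over species x season strata (stratum mean T-Hg) x scenario."""
    profiles = profiles or DEFAULT_CONSUMERS
    strata: dict[tuple[str, str], list[float]] = {}
    for s in specimens:
        if s.thg_ugg is not None:
            strata.setdefault((s.species, s.season.value), []).append(s.thg_ugg)
    results = []
    for (species, season), values in sorted(strata.items()):
        mean_thg = sum(values) / len(values)
        for profile in profiles:
            results.append(assess(species, season, mean_thg, profile, rfd))
    return results
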