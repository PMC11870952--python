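"""Fish condition indices.

Fulton's condition factor CF = 100 * W / L^3 (W in g, L in cm) measures the
robustness of a fish relative to cubic length growth; the hepatosomatic
index HSI = 100 * LW / W expresses liver weight as a percent of body weight.
Stratum summaries average per-fish indices (never the index of stratum
means — the two differ by a Jensen gap when length varies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .model import FishSpecimen, Season


def condition_factor(length_cm: float, weight_g: float) -> float:
    """Fulton condition factor, 100 * W / L^3 (units: 100 g/cm^3)."""
    if not (length_cm > 0) or not (weight_g > 0):
        raise ValidationError("condition factor requires positive length and weight")
    return 100.0 * weight_g / length_cm**3


def hepatosomatic_index(liver_weight_g: float | None, weight_g: float) -> float | None:
    """Liver weight as percent of body weight; None when liver unmeasured."""
    if liver_weight_g is None:
        return None
    if not (weight_g > 0):
        raise ValidationError("HSI requires positive body weight")
    if liver_weight_g < 0:
        raise ValidationError("liver weight must be nonnegative")
    if liver_weight_g > weight_g:
        raise ValidationError(
            f"liver weight {liver_weight_g} g exceeds body weight {weight_g} g"
        )
    return 100.0 * liver_weight_g / weight_g


@dataclass
class IndexSummary:
    species: str
    season: str
    n: int
    mean_cf: float
    se_cf: float
    mean_hsi: float | None
    se_hsi: float | None


def _mean_se(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n)


def summarize_indices(specimens: list[FishSpecimen]) -> list[IndexSummary]:
    """Per species x season mean +/- SE of per-fish CF and HSI."""
    strata: dict[tuple[str, Season], list[FishSpecimen]] = {}
    for s in specimens:
        strata.setdefault((s.species, s.season), []).append(s)
    out = []
    for (species, season), group in sorted(
        strata.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        cfs = [condition_factor(s.length_cm, s.weight_g) for s in group]
        hsis = [hepatosomatic_index(s.liver_weight_g, s.weight_g) for s in group]
        hsis = [h for h in hsis if h is not None]
        mean_cf, se_cf = _mean_se(cfs)
        if hsis:
            mean_hsi, se_hsi = _mean_se(hsis)
        else:
            mean_hsi = se_hsi = None
        out.append(IndexSummary(species, season.value, len(group),
                                mean_cf, se_cf, mean_hsi, se_hsi))
    return out
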