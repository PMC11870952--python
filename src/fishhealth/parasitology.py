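"""Quantitative parasitology: prevalence, mean abundance, mean intensity.

Conventions follow the standard ecological-parasitology definitions:
prevalence = infected / examined, mean abundance = parasites / examined,
mean intensity = parasites / infected (undefined when nothing is infected).
The identity abundance = prevalence * intensity holds exactly for every
emitted summary. Seasonal prevalence contrasts use the two-sided Fisher
exact test on the infected/uninfected 2x2 table.
"""

from __future__ import annotations

import logging

from scipy import stats

from .errors import InsufficientDataError
from .model import FishSpecimen, ParasitologySummary, StatTestResult

log = logging.getLogger(__name__)


def _summary(species: str, season: str,
             counts: list[int], ses: bool = True) -> ParasitologySummary:
    n = len(counts)
    infected = sum(1 for c in counts if c > 0)
    total = int(sum(counts))
    se = None
    if ses and n >= 2:
        mean = total / n
        var = sum((c - mean) ** 2 for c in counts) / (n - 1)
        se = (var / n) ** 0.5
    return ParasitologySummary(species, season, n, infected, total, se)


def summarize_parasitology(
    specimens: list[FishSpecimen],
    stratify_by: tuple[str, ...] = ("species", "season"),
) -> list[ParasitologySummary]:
    """One summary per stratum, plus seasonal and overall aggregates.

    ``stratify_by`` may contain "species" and/or "season"; the overall
    summary (species="overall", season="both") is always appended last.
    """
    if not specimens:
        raise InsufficientDataError("no specimens to summarize")
    strata: dict[tuple[str, str], list[int]] = {}
    for s in specimens:
        key = (
            s.species if "species" in stratify_by else "overall",
            s.season.value if "season" in stratify_by else "both",
        )
        strata.setdefault(key, []).append(s.parasite_count)
    out = [
        _summary(species, season, counts)
        for (species, season), counts in sorted(strata.items())
    ]
    if "season" in stratify_by and "species" in stratify_by:
        for season in sorted({s.season.value for s in specimens}):
            counts = [s.parasite_count for s in specimens
                      if s.season.value == season]
            out.append(_summary("overall", season, counts))
    out.append(_summary("overall", "both",
                        [s.parasite_count for s in specimens]))
    return out


def compare_prevalence(
    a: ParasitologySummary, b: ParasitologySummary, alpha: float = 0.05
) -> StatTestResult:
    """Two-sided Fisher exact test on the infected/uninfected 2x2 table."""
    table = [
        [a.n_infected, a.n_examined - a.n_infected],
        [b.n_infected, b.n_examined - b.n_infected],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return StatTestResult(
        test_name="fisher_exact",
        statistic=float(odds),
        p_value=float(p),
        alpha=alpha,
        decision_path=(
            f"2x2 table {table} ({a.species}/{a.season} vs {b.species}/{b.season})"
        ),
    )
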