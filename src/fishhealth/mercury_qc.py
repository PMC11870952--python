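"""Quality-control arithmetic for the mercury measurement stream.

Covers the four acceptance checks a direct mercury analyzer run is screened
against: limit of detection (3 x sd of method blanks), replicate precision
(RSD < 10%), calibration linearity (R^2 >= 0.999 when calibration points are
present), and certified-reference-material recovery (default acceptance band
90-110%). Samples below the LOD are flagged and substituted at LOD/2 — the
common ecotoxicology convention, configurable — in downstream summaries.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

log = logging.getLogger(__name__)


@dataclass
class QCRules:
    max_rsd_pct: float = 10.0
    min_calibration_r2: float = 0.999
    recovery_band_pct: tuple[float, float] = (90.0, 110.0)
    below_lod_fraction: float = 0.5  # substitute <LOD values at LOD * fraction


@dataclass
class QCReport:
    lod_ugg: float
    rsd_pct: dict[str, float]
    calibration_r2: float | None
    recovery_pct: float | None
    sample_values: dict[str, float]      # duplicate-averaged, <LOD substituted
    below_lod: list[str]
    flags: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.flags)


def detection_limit(blank_readings: list[float]) -> float:
    """LOD = 3 x sd (n-1 denominator) of method-blank readings."""
    if len(blank_readings) < 2:
        raise InsufficientDataError(
            "detection limit needs at least 2 blank readings"
        )
    return 3.0 * statistics.stdev(blank_readings)


def relative_sd_pct(replicates: list[float]) -> float:
    """Coefficient of variation between replicates, in percent."""
    if len(replicates) < 2:
        raise InsufficientDataError("RSD needs at least 2 replicates")
    mean = statistics.fmean(replicates)
    if mean == 0:
        return 0.0 if statistics.stdev(replicates) == 0 else float("inf")
    return 100.0 * statistics.stdev(replicates) / mean


def recovery_pct(measured: list[float], reference: float) -> float:
    """CRM recovery: 100 * mean(measured) / certified reference value."""
    if reference <= 0:
        raise InsufficientDataError("CRM reference value must be positive")
    return 100.0 * statistics.fmean(measured) / reference


def calibration_r2(nominal: list[float], measured: list[float]) -> float:
    """R^2 of the measured-vs-nominal linear fit over calibration points."""
    if len(nominal) < 3:
        raise InsufficientDataError("calibration R^2 needs >= 3 points")
    x, y = np.asarray(nominal, float), np.asarray(measured, float)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def qc_evaluate(run: pd.DataFrame, rules: QCRules | None = None) -> QCReport:
    """Evaluate a QC table (see ``io.read_qc_table`` for the layout)."""
    rules = rules or QCRules()
    flags: list[tuple[str, bool]] = []

    blanks = run.loc[run["kind"] == "blank", "value"].astype(float).tolist()
    lod = detection_limit(blanks)

    rsds: dict[str, float] = {}
    sample_values: dict[str, float] = {}
    below: list[str] = []
    samples = run[run["kind"] == "sample"]
    for sid, grp in samples.groupby("sample_id"):
        reps = grp["value"].astype(float).tolist()
        if len(reps) >= 2:
            rsds[str(sid)] = relative_sd_pct(reps)
        value = statistics.fmean(reps)  # duplicates averaged before use
        if value < lod:
            below.append(str(sid))
            value = lod * rules.below_lod_fraction
            log.info("sample %s below LOD %.4g; substituted at LOD*%.2f",
                     sid, lod, rules.below_lod_fraction)
        sample_values[str(sid)] = value
    # precision rule applies only above the LOD, where RSD is meaningful
    gated = {sid: v for sid, v in rsds.items() if sid not in below}
    if gated:
        flags.append((f"rsd<{rules.max_rsd_pct}%",
                      max(gated.values()) < rules.max_rsd_pct))

    cal = run[run["kind"] == "calibration"]
    r2 = None
    if len(cal) >= 3:
        r2 = calibration_r2(cal["reference"].astype(float).tolist(),
                            cal["value"].astype(float).tolist())
        flags.append((f"calibration_r2>={rules.min_calibration_r2}",
                      r2 >= rules.min_calibration_r2))

    crm = run[run["kind"] == "crm"]
    rec = None
    if len(crm):
        refs = crm["reference"].dropna().astype(float).unique()
        if len(refs) == 0:
            log.warning("CRM rows lack a reference value; recovery rule skipped")
        else:
            rec = recovery_pct(crm["value"].astype(float).tolist(), float(refs[0]))
            lo, hi = rules.recovery_band_pct
            flags.append((f"recovery in [{lo}%, {hi}%]", lo <= rec <= hi))

    return QCReport(lod_ugg=lod, rsd_pct=rsds, calibration_r2=r2,
                    recovery_pct=rec, sample_values=sample_values,
                    below_lod=below, flags=flags)
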