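"""ECG-derived analysis traits and per-trait exclusion rules.

Traits: QRS duration, Bazett heart-rate-corrected QT (QTc), PR interval, and
three voltage-duration products used as left-ventricular-hypertrophy (LVH)
proxies — Sokolow–Lyon (SL), Cornell (CV) and the 12-lead sum (12LS).
Amplitudes are in mm (1 mm = 0.1 mV at standard calibration), durations in
ms, so the products are in mm·ms, approximating the area under the QRS
complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "EcgRecord",
    "LEADS",
    "TRAITS",
    "GLOBAL_EXCLUSION_FLAGS",
    "DomainError",
    "MissingLeadError",
    "bazett_qtc",
    "sokolow_lyon_product",
    "cornell_product",
    "twelve_lead_sum_product",
    "derived_trait",
    "exclusion_reason",
    "apply_exclusions",
]

#: the 12 standard leads
LEADS = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")

TRAITS = ("QRS", "QT", "PR", "SL", "CV", "12LS")

#: flag exclusions applied to every trait, in reporting priority order
GLOBAL_EXCLUSION_FLAGS = (
    "atrial_fibrillation",
    "myocardial_infarction",
    "bundle_branch_block",
    "av_block",
    "pacemaker",
    "wpw",
    "pregnancy",
    "antiarrhythmic_or_digoxin",
)

_LVH_TRAITS = frozenset({"SL", "CV", "12LS"})
_QRS_RULE_TRAITS = frozenset({"QRS", "QT", "SL", "CV", "12LS"})


class DomainError(ValueError):
    """Input outside the physical domain (nonpositive duration/rate, ...)."""


class MissingLeadError(ValueError):
    """A lead amplitude needed by a voltage product is absent."""


@dataclass(frozen=True)
class EcgRecord:
    """One individual's measured ECG parameters.

    ``amp`` maps lead name to ``(R, S)`` amplitudes in mm, both as
    nonnegative magnitudes.  Missing leads are simply absent from the map.
    """

    id: str
    qrs_ms: float
    qt_ms: float
    pr_ms: float
    heart_rate_bpm: float
    qrs_axis_deg: float
    amp: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (
            ("qrs_ms", self.qrs_ms),
            ("qt_ms", self.qt_ms),
            ("pr_ms", self.pr_ms),
            ("heart_rate_bpm", self.heart_rate_bpm),
        ):
            if v is not None and not v > 0:
                raise DomainError(f"{name} must be positive, got {v}")
        if self.qrs_axis_deg is not None and not -180 <= self.qrs_axis_deg <= 180:
            raise DomainError(f"qrs_axis_deg out of [-180, 180]: {self.qrs_axis_deg}")
        for lead, (r, s) in self.amp.items():
            if r < 0 or s < 0:
                raise DomainError(f"negative amplitude on lead {lead}")

    def _rs(self, lead: str) -> tuple[float, float]:
        try:
            return self.amp[lead]
        except KeyError:
            raise MissingLeadError(f"record {self.id}: lead {lead} missing") from None


def bazett_qtc(qt_ms: float, heart_rate_bpm: float) -> float:
    """Heart-rate-corrected QT: ``QTc = QT / sqrt(RR)`` with RR in seconds."""
    if not qt_ms > 0 or not heart_rate_bpm > 0:
        raise DomainError("QT and heart rate must be positive")
    rr_s = 60.0 / heart_rate_bpm
    return qt_ms / math.sqrt(rr_s)


def sokolow_lyon_product(rec: EcgRecord) -> float:
    """(S in V1 + max of R in V5/V6) x QRS duration, mm·ms."""
    s_v1 = rec._rs("V1")[1]
    r_v5 = rec._rs("V5")[0]
    r_v6 = rec._rs("V6")[0]
    return (s_v1 + max(r_v5, r_v6)) * rec.qrs_ms


def cornell_product(rec: EcgRecord) -> float:
    """(R in aVL + S in V3) x QRS duration, mm·ms."""
    return (rec._rs("aVL")[0] + rec._rs("V3")[1]) * rec.qrs_ms


def twelve_lead_sum_product(rec: EcgRecord, mode: str = "amplitude") -> float:
    """Sum over the 12 leads of the R/S voltages, times QRS duration.

    ``mode="amplitude"`` (default) sums R + S magnitudes per lead (total QRS
    amplitude); ``mode="signed"`` sums R - S.
    """
    if mode not in {"amplitude", "signed"}:
        raise ValueError(f"unknown 12LS mode {mode!r}")
    total = 0.0
    for lead in LEADS:
        r, s = rec._rs(lead)
        total += (r + s) if mode == "amplitude" else (r - s)
    return total * rec.qrs_ms


def derived_trait(rec: EcgRecord, trait: str, mode_12ls: str = "amplitude") -> float:
    """Raw analysis value for one trait from one record."""
    if trait == "QRS":
        return rec.qrs_ms
    if trait == "QT":
        return bazett_qtc(rec.qt_ms, rec.heart_rate_bpm)
    if trait == "PR":
        return rec.pr_ms
    if trait == "SL":
        return sokolow_lyon_product(rec)
    if trait == "CV":
        return cornell_product(rec)
    if trait == "12LS":
        return twelve_lead_sum_product(rec, mode=mode_12ls)
    raise ValueError(f"unknown trait {trait!r}")


def exclusion_reason(rec: EcgRecord, trait: str) -> str | None:
    """First triggered exclusion reason for this record/trait, else None.

    Rules: clinical flags exclude from every trait; QRS > 120 ms excludes
    from QRS/QT and the LVH proxies (not PR); PR >= 320 or <= 80 ms excludes
    from PR only; QRS axis > 90 or < -30 degrees excludes from the LVH
    proxies only.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    for flag in GLOBAL_EXCLUSION_FLAGS:
        if rec.flags.get(flag, False):
            return flag
    if trait in _QRS_RULE_TRAITS and rec.qrs_ms > 120:
        return "qrs_gt_120ms"
    if trait == "PR" and (rec.pr_ms >= 320 or rec.pr_ms <= 80):
        return "pr_out_of_range"
    if trait in _LVH_TRAITS and (rec.qrs_axis_deg > 90 or rec.qrs_axis_deg < -30):
        return "axis_out_of_range"
    return None


def apply_exclusions(
    cohort: Iterable[EcgRecord], trait: str
) -> tuple[list[EcgRecord], list[tuple[EcgRecord, str]]]:
    """Partition a cohort into (kept, dropped-with-reason) for one trait."""
    kept: list[EcgRecord] = []
    dropped: list[tuple[EcgRecord, str]] = []
    for rec in cohort:
        reason = exclusion_reason(rec, trait)
        if reason is None:
            kept.append(rec)
        else:
            dropped.append((rec, reason))
    return kept, dropped
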