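"""Simplified 2014 Lugano response classification for lymphoma lesions.

Classifies a (virtual) patient as CR / PR / SD / PD from the history of lesion
diameters and the sum of product of diameters (SPD):

* CR  — SPD reduced by at least 50% from baseline AND the longest diameter is
        under 1.5 cm (for multiple lesions: every lesion under 1.5 cm);
* PR  — SPD reduced by at least 50% from baseline;
* PD  — SPD increased by at least 50% from baseline AND the longest diameter
        exceeds 1.5 cm AND it has grown from its nadir by at least 0.5 cm
        (when the diameter is under 2 cm) or 1.0 cm (otherwise); with several
        lesions, a new lesion or any single lesion meeting these conditions
        suffices;
* SD  — anything else.

Precedence is PD, then CR, then PR, then SD: PD references the nadir and must
dominate, while SD is defined residually. "At least 50%" is inclusive; the
1.5 cm diameter cuts are strict (< for CR, > for PD). Only this simplified
rule set is implemented — no PET five-point scale, bone marrow or spleen
criteria.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List


class ResponseClass(enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


#: ordinal coding used when response enters numeric analyses (best -> worst)
ORDINAL = {ResponseClass.CR: 0, ResponseClass.PR: 1,
           ResponseClass.SD: 2, ResponseClass.PD: 3}


def ordinal(c: ResponseClass) -> int:
    return ORDINAL[c]


@dataclass
class LesionRecord:
    """One lesion's longest diameter at baseline, nadir and evaluation (cm)."""

    baseline_d: float
    nadir_d: float
    current_d: float

    def validate(self) -> None:
        if min(self.baseline_d, self.nadir_d, self.current_d) < 0:
            raise ValueError("diameters must be >= 0")
        if self.nadir_d > self.baseline_d + 1e-12:
            raise ValueError("nadir diameter cannot exceed baseline")


@dataclass
class LesionHistory:
    """Per-patient lesion state used for classification."""

    baseline_spd: float
    current_spd: float
    lesions: List[LesionRecord] = field(default_factory=list)
    new_lesion: bool = False

    def validate(self) -> None:
        if self.baseline_spd < 0 or self.current_spd < 0:
            raise ValueError("SPD must be >= 0")
        if not self.lesions:
            raise ValueError("at least one lesion record required")
        for les in self.lesions:
            les.validate()


def _lesion_meets_pd(les: LesionRecord) -> bool:
    """Diameter conditions of PD for one lesion (the SPD condition is global)."""
    growth = les.current_d - les.nadir_d
    threshold = 0.5 if les.current_d < 2.0 else 1.0
    return les.current_d > 1.5 and growth >= threshold


def _classify(h: LesionHistory) -> ResponseClass:
    h.validate()
    if h.baseline_spd == 0:
        raise ValueError("baseline SPD must be > 0 (relative change undefined)")
    change = (h.current_spd - h.baseline_spd) / h.baseline_spd

    if h.new_lesion or (change >= 0.5 and any(map(_lesion_meets_pd, h.lesions))):
        return ResponseClass.PD
    if change <= -0.5 and all(les.current_d < 1.5 for les in h.lesions):
        return ResponseClass.CR
    if change <= -0.5:
        return ResponseClass.PR
    return ResponseClass.SD


def classify_single(h: LesionHistory) -> ResponseClass:
    """Classify a single-lesion patient."""
    if len(h.lesions) != 1:
        raise ValueError("classify_single requires exactly one lesion")
    return _classify(h)


def classify_multi(h: LesionHistory) -> ResponseClass:
    """Classify a multi-lesion patient (>= 2 lesions)."""
    if len(h.lesions) < 2:
        raise ValueError("classify_multi requires >= 2 lesions")
    return _classify(h)


def classify(h: LesionHistory) -> ResponseClass:
    """Dispatch to the single- or multi-lesion rule set."""
    return classify_single(h) if len(h.lesions) == 1 else classify_multi(h)
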