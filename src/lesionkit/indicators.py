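"""Tumor aggregation and dissemination indicators.

From per-lesion measurements and anatomical site annotations this module
derives the patient-level quantities used for prognosis in lymphoma imaging:

* TMTV — total metabolic tumor volume, the sum of lesion mesh volumes (mm^3);
* TTS — total tumor surface, the sum of lesion mesh surfaces (mm^2);
* TVSR — tumor volume-surface ratio TMTV/TTS (mm), higher = more aggregated;
* bulky disease — any mass with diameter > 5.0 cm (aggregation flag);
* extra stage — lesions on both sides of the diaphragm AND more than one
  distinct extranodal site (dissemination flag);
* the legacy IPI dissemination items (Ann Arbor stage III/IV, >1 extranodal
  site) for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from .mesh import LesionMetrics

__all__ = [
    "Side",
    "Compartment",
    "SiteAnnotation",
    "AnnotatedLesion",
    "BULKY_DIAMETER_MM",
    "compute_tmtv",
    "compute_tts",
    "compute_tvsr",
    "bulky_flag",
    "extra_stage_flag",
    "legacy_flags",
    "synergy_group",
]

#: bulky disease threshold: mass diameter strictly greater than 5.0 cm
BULKY_DIAMETER_MM = 50.0

_STAGES_3_4 = {"III", "IV", "3", "4"}
_STAGES_1_2 = {"I", "II", "1", "2"}


class Side(str, Enum):
    ABOVE = "above_diaphragm"
    BELOW = "below_diaphragm"


class Compartment(str, Enum):
    NODAL = "nodal"
    EXTRANODAL = "extranodal"


@dataclass(frozen=True)
class SiteAnnotation:
    """Anatomical site of one lesion: diaphragm side, nodal/extranodal
    compartment, and an opaque organ label used to count distinct
    extranodal sites (one organ with several lesions is one site)."""

    side: Side
    compartment: Compartment
    organ_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "compartment", Compartment(self.compartment))


@dataclass
class AnnotatedLesion:
    metrics: LesionMetrics
    site: SiteAnnotation | None = field(default=None)


def _sites(lesions: list[AnnotatedLesion]) -> list[SiteAnnotation]:
    out = []
    for i, les in enumerate(lesions):
        if les.site is None:
            raise ValueError(f"lesion {getattr(les.metrics, 'label', i)} has no site annotation")
        out.append(les.site)
    return out


def compute_tmtv(lesions: list[AnnotatedLesion]) -> float:
    """Total metabolic tumor volume: sum of per-lesion mesh volumes (mm^3)."""
    if not lesions:
        warnings.warn("empty lesion list: TMTV = 0 (no measurable disease)", stacklevel=2)
        return 0.0
    return float(sum(les.metrics.volume for les in lesions))


def compute_tts(lesions: list[AnnotatedLesion]) -> float:
    """Total tumor surface: sum of per-lesion mesh surfaces (mm^2)."""
    if not lesions:
        warnings.warn("empty lesion list: TTS = 0 (no measurable disease)", stacklevel=2)
        return 0.0
    return float(sum(les.metrics.surface for les in lesions))


def compute_tvsr(tmtv: float, tts: float) -> float:
    """Tumor volume-surface ratio TMTV/TTS in mm. Undefined when TTS = 0."""
    if tts <= 0:
        raise ValueError("TVSR undefined: TTS must be > 0")
    return tmtv / tts


def bulky_flag(lesions: list[AnnotatedLesion]) -> bool:
    """True iff any lesion's maximum diameter strictly exceeds 50.0 mm."""
    return any(les.metrics.max_diameter > BULKY_DIAMETER_MM for les in lesions)


def extra_stage_flag(lesions: list[AnnotatedLesion]) -> bool:
    """Dissemination flag: lesions above AND below the diaphragm, and more
    than one distinct extranodal organ involved."""
    if not lesions:
        return False
    sites = _sites(lesions)
    sides = {s.side for s in sites}
    organs = {s.organ_id for s in sites if s.compartment is Compartment.EXTRANODAL}
    return (Side.ABOVE in sides and Side.BELOW in sides) and len(organs) > 1


def legacy_flags(lesions: list[AnnotatedLesion], stage: str) -> tuple[bool, bool]:
    """IPI-style dissemination items: (stage III/IV, >1 extranodal site).

    Ann Arbor stage is a clinical annotation supplied as input, never derived
    from images here.
    """
    token = str(stage).strip().upper()
    if token in _STAGES_3_4:
        stage_3_4 = True
    elif token in _STAGES_1_2:
        stage_3_4 = False
    else:
        raise ValueError(f"unknown Ann Arbor stage {stage!r}; expected I-IV")
    organs = {
        s.organ_id for s in _sites(lesions) if s.compartment is Compartment.EXTRANODAL
    } if lesions else set()
    return stage_3_4, len(organs) > 1


def synergy_group(bulky: bool, extra_stage: bool) -> str:
    """Three-level ordinal grouping of the two flags: neither / either / both."""
    if bulky and extra_stage:
        return "both"
    if bulky or extra_stage:
        return "either"
    return "neither"
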