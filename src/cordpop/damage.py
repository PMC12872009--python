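"""Strain-threshold injury scoring at the epicenter.

Tissue-specific thresholds on minimum principal logarithmic strain (min
LEP, compressive = negative) classify elements as injured: gray matter
below -0.44 and white matter below -0.77 correspond to at least a 50%
probability of histological damage, applied here as hard cutoffs.  "Below"
is strictly more negative than the threshold; boundary equality is spared
(configurable via ``strict``).  Sparing per tissue is the volume-weighted
complement of the injured fraction:

    sparing% = 100 * (1 - sum EVOL_injured / sum EVOL_tissue)

over the epicenter slab.  Two lesion-topology summaries follow the
population analysis: whether the white-matter lesion reaches the
ipsilateral cord edge (lateral extension), and damaged volume per
anatomical region (ipsi/contra x dorsal/ventral, for gray horns and white
columns; quadrants split at the cord midline and the horizontal through
the canal center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GRAY, WHITE
from .surrogate import StrainField

__all__ = [
    "DamageThresholds", "DamageSummary", "classify_elements", "sparing",
    "lateral_extension", "contralateral_summary", "score_field",
    "REGIONS",
]

REGIONS = (
    "gm_central", "wm_midline",
    "gm_dorsal_horn_ipsi", "gm_dorsal_horn_contra",
    "gm_ventral_horn_ipsi", "gm_ventral_horn_contra",
    "wm_dorsal_columns_ipsi", "wm_dorsal_columns_contra",
    "wm_ventral_columns_ipsi", "wm_ventral_columns_contra",
)

#: Half-width (mm) of the midline band: gray matter there is the central
#: canal / commissure zone (gm_central), white matter the median septum /
#: fissure zone (wm_midline); horns and columns proper lie beyond it.
CENTRAL_HALFWIDTH = 0.6


@dataclass(frozen=True)
class DamageThresholds:
    """Injury thresholds on min LEP (negative, compressive)."""

    gray_threshold: float = -0.44
    white_threshold: float = -0.77
    #: strictly-more-negative-than-threshold convention (equality spared)
    strict: bool = True

    def __post_init__(self) -> None:
        if self.gray_threshold >= 0 or self.white_threshold >= 0:
            raise ValueError("injury thresholds must be negative strains")


@dataclass(frozen=True)
class DamageSummary:
    """Per-subject damage outcome at the epicenter."""

    gm_sparing_pct: float
    wm_sparing_pct: float
    lateral_extension: bool
    region_damage_mm3: dict[str, float]

    @property
    def region_flags(self) -> dict[str, bool]:
        return {k: v > 0 for k, v in self.region_damage_mm3.items()}


def classify_elements(field: StrainField,
                      th: DamageThresholds | None = None) -> np.ndarray:
    """Boolean injured flag per element.

    Gray elements are injured below the gray threshold, white below the
    white threshold; every other label is never injured.  Independent of
    element ordering.
    """
    th = th or DamageThresholds()
    label, lep = field.mesh.label, field.min_lep
    if th.strict:
        injured_gray = lep < th.gray_threshold
        injured_white = lep < th.white_threshold
    else:
        injured_gray = lep <= th.gray_threshold
        injured_white = lep <= th.white_threshold
    return ((label == GRAY) & injured_gray) | ((label == WHITE) & injured_white)


def sparing(field: StrainField, th: DamageThresholds | None = None,
            tissue: str = "white") -> float:
    """Percent spared volume of ``tissue`` ('gray' or 'white') at the
    epicenter; raises on zero tissue volume."""
    th = th or DamageThresholds()
    code = {"gray": GRAY, "white": WHITE}.get(tissue)
    if code is None:
        raise ValueError("tissue must be 'gray' or 'white'")
    mask = field.mesh.label == code
    total = field.mesh.evol[mask].sum()
    if total <= 0:
        raise ValueError(f"no {tissue}-matter volume at the epicenter")
    injured = classify_elements(field, th) & mask
    return float(100.0 * (1.0 - field.mesh.evol[injured].sum() / total))


def lateral_extension(field: StrainField,
                      th: DamageThresholds | None = None) -> bool:
    """True if the white-matter lesion reaches the ipsilateral cord edge.

    The lesion "reaches the edge" when some injured white element lies
    within one voxel of the ipsilateral-most extent of the white matter.
    """
    mesh = field.mesh
    white = mesh.label == WHITE
    if not white.any():
        return False
    x_ipsi = mesh.x * mesh.ipsi_sign
    edge = x_ipsi[white].max()
    injured = classify_elements(field, th) & white
    if not injured.any():
        return False
    return bool(x_ipsi[injured].max() >= edge - mesh.voxel_size)


def _region_codes(field: StrainField) -> dict[str, np.ndarray]:
    """Anatomical region masks: gray horns / white columns by quadrant
    (dorsal = y > 0, ipsilateral = impactor side of the midline)."""
    mesh = field.mesh
    x_ipsi = mesh.x * mesh.ipsi_sign
    dorsal = mesh.y > 0
    ipsi = x_ipsi > 0
    gray, white = mesh.label == GRAY, mesh.label == WHITE
    midline = np.abs(x_ipsi) <= CENTRAL_HALFWIDTH
    gray_horn = gray & ~midline
    wm_col = white & ~midline
    return {
        "gm_central": gray & midline,
        "wm_midline": white & midline,
        "gm_dorsal_horn_ipsi": gray_horn & dorsal & ipsi,
        "gm_dorsal_horn_contra": gray_horn & dorsal & ~ipsi,
        "gm_ventral_horn_ipsi": gray_horn & ~dorsal & ipsi,
        "gm_ventral_horn_contra": gray_horn & ~dorsal & ~ipsi,
        "wm_dorsal_columns_ipsi": wm_col & dorsal & ipsi,
        "wm_dorsal_columns_contra": wm_col & dorsal & ~ipsi,
        "wm_ventral_columns_ipsi": wm_col & ~dorsal & ipsi,
        "wm_ventral_columns_contra": wm_col & ~dorsal & ~ipsi,
    }


def contralateral_summary(field: StrainField,
                          th: DamageThresholds | None = None,
                          ) -> dict[str, float]:
    """Damaged volume (mm^3) per anatomical region.

    The regions partition the gray+white elements, so the region volumes
    sum to the total injured volume.
    """
    injured = classify_elements(field, th)
    evol = field.mesh.evol
    return {name: float(evol[mask & injured].sum())
            for name, mask in _region_codes(field).items()}


def score_field(field: StrainField,
                th: DamageThresholds | None = None) -> DamageSummary:
    """Full damage summary for one subject's strain field."""
    th = th or DamageThresholds()
    return DamageSummary(
        gm_sparing_pct=sparing(field, th, "gray"),
        wm_sparing_pct=sparing(field, th, "white"),
        lateral_extension=lateral_extension(field, th),
        region_damage_mm3=contralateral_summary(field, th),
    )
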