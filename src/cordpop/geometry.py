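"""Epicenter cross-section construction and voxelization.

Builds, for one digital subject, the labeled transverse cross-section at the
injury epicenter: white matter (cord ellipse minus a fixed gray-matter
butterfly template), a 150-um pia band outward of the cord, the CSF annulus,
a 350-um dura band inward of the canal, and the impactor footprint.  The
section is extruded conceptually into a thin epicenter slab so every element
carries a volume (EVOL, mm^3) for volume-weighted damage scoring.

Coordinate convention: x = mediolateral with positive toward the impactor
(ipsilateral) side, y = anterior-posterior with positive dorsal, origin at
the canal center.  Cord and canal are concentric ellipses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely import affinity

from .morphology import SubjectMorphology

__all__ = [
    "GeometryConfig",
    "CrossSection",
    "LabeledMesh",
    "Footprint",
    "GeometryError",
    "LABELS",
    "GRAY", "WHITE", "PIA", "CSF", "DURA", "OUTSIDE",
    "default_gray_template",
    "build_cross_section",
    "voxelize",
    "impactor_footprint",
]

# Integer tissue labels
GRAY, WHITE, PIA, CSF, DURA, OUTSIDE = 0, 1, 2, 3, 4, 5
LABELS = {GRAY: "gray", WHITE: "white", PIA: "pia", CSF: "csf",
          DURA: "dura", OUTSIDE: "outside"}

#: Gray-matter area as a fraction of the mean cord cross-section.  The
#: butterfly occupies a fixed absolute area for every subject (morphological
#: variation is carried by the white matter).
GRAY_AREA_FRACTION = 0.22
_MEAN_CORD_AREA = np.pi * (9.8 / 2) * (6.3 / 2)


class GeometryError(ValueError):
    """Cross-section construction failed (message names the subject)."""


def _ellipse(cx: float, cy: float, rx: float, ry: float,
             angle_deg: float = 0.0, quad_segs: int = 48) -> Polygon:
    e = shapely.Point(0.0, 0.0).buffer(1.0, quad_segs=quad_segs)
    e = affinity.scale(e, rx, ry, origin=(0, 0))
    if angle_deg:
        e = affinity.rotate(e, angle_deg, origin=(0, 0))
    return affinity.translate(e, cx, cy)


@lru_cache(maxsize=8)
def default_gray_template(target_area: float | None = None) -> Polygon:
    """Fixed butterfly gray-matter contour, centered on the cord center.

    The shape (central commissure band, two ventral horns, two slimmer
    dorsal horns) is a stylized primate cervical gray matter; its exact
    contour is a package design choice.  The union of construction ellipses
    is uniformly rescaled so the area equals ``target_area`` (default:
    GRAY_AREA_FRACTION of the mean cord area).  Exactly mirror-symmetric in
    x by construction.
    """
    if target_area is None:
        target_area = GRAY_AREA_FRACTION * _MEAN_CORD_AREA
    central = _ellipse(0.0, -0.15, 1.35, 0.52)
    ventral = _ellipse(1.05, -0.95, 0.78, 1.02, angle_deg=-14.0)
    dorsal = _ellipse(0.82, 0.88, 0.40, 1.00, angle_deg=-18.0)
    right = shapely.union_all([central, ventral, dorsal])
    left = affinity.scale(right, -1.0, 1.0, origin=(0, 0))
    base = right.union(left)
    s = float(np.sqrt(target_area / base.area))
    return affinity.scale(base, s, s, origin=(0, 0))


@dataclass(frozen=True)
class GeometryConfig:
    """Geometric constants of the contusion model.

    Units: thicknesses in um are stored in mm here; all lengths mm.
    """

    pia_thickness: float = 0.150
    dura_thickness: float = 0.350
    impactor_diameter: float = 5.0
    impactor_lateral_offset: float = 0.5   # toward ipsilateral (+x)
    slab_thickness: float = 1.0            # epicenter slab depth, mm
    voxel_size: float = 0.1
    gray_template: Polygon = field(default_factory=default_gray_template)
    #: Dorsal laminectomy window on the canal boundary (degrees of arc and
    #: angular offset of its center from the dorsal midline, toward the
    #: ipsilateral side).  The printed protocol does not give dimensions;
    #: these defaults are a documented guess and the window is metadata only.
    laminectomy_width_deg: float = 60.0
    laminectomy_offset_deg: float = 20.0

    def __post_init__(self) -> None:
        for name in ("pia_thickness", "dura_thickness", "impactor_diameter",
                     "slab_thickness", "voxel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CrossSection:
    """Analytic region description for one subject's epicenter section."""

    subject: SubjectMorphology
    cfg: GeometryConfig
    gray: Polygon
    white: Polygon
    pia: Polygon
    csf: Polygon
    dura: Polygon
    cord: Polygon
    canal: Polygon
    #: angular interval (deg, dorsal midline = 0, positive toward ipsi) of
    #: the laminectomy window on the canal boundary
    laminectomy_arc: tuple[float, float] = (0.0, 0.0)

    @property
    def ipsi_sign(self) -> float:
        return 1.0 if self.cfg.impactor_lateral_offset >= 0 else -1.0


@dataclass
class LabeledMesh:
    """Voxelized epicenter slab: per-element centroid, volume and label."""

    x: np.ndarray          # centroid mediolateral coordinate, mm
    y: np.ndarray          # centroid anterior-posterior coordinate, mm
    evol: np.ndarray       # element volume, mm^3
    label: np.ndarray      # integer tissue label (GRAY..DURA)
    voxel_size: float
    slab_thickness: float
    ipsi_sign: float
    cord_rx: float         # cord semi-axes, for surface-relative kernels
    cord_ry: float

    def volume(self, *labels: int) -> float:
        """Total element volume (mm^3) over the given tissue labels."""
        mask = np.isin(self.label, labels)
        return float(self.evol[mask].sum())

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class Footprint:
    """Mediolateral impactor-cord overlap at the epicenter (mm, ipsi=+x)."""

    center: float          # impactor center
    radius: float
    lo: float              # overlap interval clipped to the cord
    hi: float
    overhang_ipsi: bool    # impactor edge beyond the ipsilateral cord edge
    overhang_contra: bool
    overhang_fraction: float  # impactor width not backed by cord tissue

    @property
    def any_overhang(self) -> bool:
        return self.overhang_ipsi or self.overhang_contra


def build_cross_section(m: SubjectMorphology,
                        cfg: GeometryConfig | None = None) -> CrossSection:
    """Construct the analytic tissue regions for subject ``m``.

    White matter is the cord ellipse minus the fixed gray template; the pia
    occupies a band of ``pia_thickness`` outward of the cord, the dura a
    band of ``dura_thickness`` inward of the canal, and the CSF annulus is
    what remains between them (the band bookkeeping keeps the regions
    disjoint, so shells never overlap their neighbours).

    Raises :class:`GeometryError` if the gray template is not strictly
    inside the cord ellipse, or if the pia band leaves no CSF space.
    """
    cfg = cfg or GeometryConfig()
    rx_c, ry_c = m.scow / 2.0, m.scod / 2.0
    rx_k, ry_k = m.scw / 2.0, m.scd / 2.0
    cord = _ellipse(0, 0, rx_c, ry_c, quad_segs=96)
    canal = _ellipse(0, 0, rx_k, ry_k, quad_segs=96)
    gray = cfg.gray_template
    if not cord.contains(gray):
        raise GeometryError(
            f"subject {m.subject_id!r}: gray-matter template (extent "
            f"{gray.bounds}) is not strictly inside the cord ellipse "
            f"({m.scow} x {m.scod} mm)")
    white = cord.difference(gray)
    # shell bookkeeping: the pia band sits outward of the cord and the dura
    # band inward of the canal, with the pia clipped to the canal and given
    # priority where the bands would meet, so regions stay disjoint even
    # for near-contact (high-occlusion) cords
    cord_with_pia = cord.buffer(cfg.pia_thickness, quad_segs=48) \
                        .intersection(canal)
    pia = cord_with_pia.difference(cord)
    canal_inner = canal.buffer(-cfg.dura_thickness, quad_segs=48)
    dura = canal.difference(canal_inner).difference(cord_with_pia)
    csf = canal_inner.difference(cord_with_pia)
    if csf.is_empty:
        warnings.warn(
            f"subject {m.subject_id!r}: cord+pia fills the canal; the CSF "
            "region is empty at the epicenter", stacklevel=2)
    ipsi = 1.0 if cfg.impactor_lateral_offset >= 0 else -1.0
    half = cfg.laminectomy_width_deg / 2.0
    arc_center = ipsi * cfg.laminectomy_offset_deg
    return CrossSection(
        subject=m, cfg=cfg, gray=gray, white=white, pia=pia, csf=csf,
        dura=dura, cord=cord, canal=canal,
        laminectomy_arc=(arc_center - half, arc_center + half))


def voxelize(section: CrossSection,
             voxel_size: float | None = None) -> LabeledMesh:
    """Voxelize a cross-section into a :class:`LabeledMesh`.

    Elements are squares of side ``voxel_size`` extruded through the
    epicenter slab (EVOL = voxel_size^2 * slab_thickness); each element is
    labeled by a centroid-in-region test with priority gray > white > pia >
    csf > dura.  The centroid grid is symmetric about both axes so a
    mirrored subject voxelizes to the mirrored mesh.  Elements outside
    every tissue are dropped.

    Warns if ``voxel_size`` exceeds a shell thickness (that band may come
    out empty).
    """
    cfg = section.cfg
    h = float(voxel_size if voxel_size is not None else cfg.voxel_size)
    if h <= 0:
        raise ValueError("voxel_size must be > 0")
    if h > min(cfg.pia_thickness, cfg.dura_thickness):
        warnings.warn(
            f"voxel size {h} mm exceeds the thinnest shell "
            f"({min(cfg.pia_thickness, cfg.dura_thickness)} mm); that "
            "shell's band may contain no elements", stacklevel=2)
    rx, ry = section.subject.scw / 2.0, section.subject.scd / 2.0
    nx = int(np.ceil(2.0 * rx / h)) + 2
    ny = int(np.ceil(2.0 * ry / h)) + 2
    xs = (np.arange(nx) - (nx - 1) / 2.0) * h
    ys = (np.arange(ny) - (ny - 1) / 2.0) * h
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()

    def inside(poly: Polygon) -> np.ndarray:
        return shapely.contains_xy(poly, gx, gy)

    in_gray = inside(section.gray)
    in_cord = inside(section.cord)
    in_cord_pia = in_cord | inside(section.pia)
    in_inner = in_cord_pia | inside(section.csf)
    in_canal = in_inner | inside(section.dura)

    label = np.full(gx.shape, OUTSIDE, dtype=np.int8)
    label[in_canal] = DURA
    label[in_inner] = CSF
    label[in_cord_pia] = PIA
    label[in_cord] = WHITE
    label[in_gray] = GRAY

    keep = label != OUTSIDE
    evol = np.full(keep.sum(), h * h * cfg.slab_thickness)
    return LabeledMesh(
        x=gx[keep], y=gy[keep], evol=evol, label=label[keep],
        voxel_size=h, slab_thickness=cfg.slab_thickness,
        ipsi_sign=section.ipsi_sign,
        cord_rx=section.subject.scow / 2.0,
        cord_ry=section.subject.scod / 2.0)


def impactor_footprint(m: SubjectMorphology,
                       cfg: GeometryConfig | None = None) -> Footprint:
    """Mediolateral impactor-cord overlap interval at the epicenter.

    The impactor (diameter ``impactor_diameter``) is centered
    ``impactor_lateral_offset`` mm toward the ipsilateral side of the cord
    midline; the footprint is that interval clipped to the cord width, with
    flags when the impactor edge overhangs the cord laterally (inadequate
    tissue at the impactor edge, which permits lateral slippage).  The
    bevel is ignored in this planar analysis.
    """
    cfg = cfg or GeometryConfig()
    ipsi = 1.0 if cfg.impactor_lateral_offset >= 0 else -1.0
    # work in the ipsi-positive frame
    center = abs(cfg.impactor_lateral_offset)
    r = cfg.impactor_diameter / 2.0
    edge = m.scow / 2.0
    lo, hi = max(center - r, -edge), min(center + r, edge)
    over_ipsi = center + r > edge
    over_contra = center - r < -edge
    overlap = max(hi - lo, 0.0)
    frac = 1.0 - overlap / (2.0 * r)
    return Footprint(center=ipsi * center, radius=r,
                     lo=ipsi * lo if ipsi > 0 else -hi * 1.0,
                     hi=ipsi * hi if ipsi > 0 else -lo * 1.0,
                     overhang_ipsi=over_ipsi, overhang_contra=over_contra,
                     overhang_fraction=frac)
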