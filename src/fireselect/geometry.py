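"""Used/available delineation and ownership overlay.

The unit of observation is the *fire footprint*: one single-part burned
polygon. Multi-part mapped perimeters are split into independent footprints.
For each footprint the *used* area is the burned polygon and the *available*
area is the burned polygon plus a variable-width outside buffer whose area
equals the burned area, so burned and unburned land are sampled equally. A
footprint whose available area leaves the study boundary is excluded, since
ownership cannot be assigned outside it.

Interior rings (unburned islands inside a perimeter) are honoured as
unburned: by default their area counts neither as used nor as buffer and is
not part of the available area (``holes="excluded"``); the alternative
convention, treating hole interiors as available unburned land, is selected
with ``holes="available"``.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .io_formats import (
    M2_PER_HA,
    OTHER_CLASS,
    FirePerimeter,
    OwnershipLayer,
    StudyArea,
    VegetationLayer,
    logger,
)

__all__ = [
    "FireFootprint",
    "AvailableRegion",
    "ProportionTable",
    "GeometryError",
    "split_multipart",
    "delineate_available",
    "apply_exclusion",
    "overlay_proportions",
]

#: segments per quadrant for outward offsets (round joins)
BUFFER_QUAD_SEGS = 64


class GeometryError(RuntimeError):
    """Raised when the equal-area buffer width cannot be bracketed."""


@dataclass(frozen=True)
class FireFootprint:
    """One single-part burned polygon: the unit of observation."""

    footprint_id: str
    event_id: str
    year: int
    used_polygon: Polygon

    def __post_init__(self) -> None:
        if not self.used_polygon.is_valid or self.used_polygon.area <= 0:
            raise ValueError(f"{self.footprint_id}: used polygon invalid or empty")

    @property
    def used_area_ha(self) -> float:
        return self.used_polygon.area / M2_PER_HA


@dataclass(frozen=True)
class AvailableRegion:
    """A footprint's used polygon plus its equal-area outside buffer."""

    footprint_id: str
    used_polygon: Polygon
    buffer_polygon: BaseGeometry
    available_polygon: BaseGeometry
    buffer_width_m: float

    @property
    def used_area_ha(self) -> float:
        return self.used_polygon.area / M2_PER_HA

    @property
    def available_area_ha(self) -> float:
        return self.available_polygon.area / M2_PER_HA


@dataclass(frozen=True)
class ProportionTable:
    """Per-footprint used and available proportions by ownership class.

    ``rows`` maps owner_class -> (o, pi) with o the used proportion and pi
    the available proportion; classes with pi == 0 are omitted, so both
    columns sum to one over the listed classes.
    """

    footprint_id: str
    rows: tuple[tuple[str, float, float], ...]
    unburnable_available_fraction: float


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_multipart(perimeter: FirePerimeter) -> list[FireFootprint]:
    """Split a possibly multi-part perimeter into independent footprints.

    Each disjoint polygon becomes its own observation. Footprint ids append
    an ordinal suffix to the event id, ordered by descending area with ties
    broken by centroid x then y; zero-area parts are dropped with a warning.
    """
    geom = perimeter.geometry
    if isinstance(geom, Polygon):
        parts = [geom]
    elif isinstance(geom, MultiPolygon):
        parts = list(geom.geoms)
    else:
        raise TypeError(f"perimeter geometry must be polygonal, got {geom.geom_type}")

    kept = []
    for p in parts:
        if p.area <= 0.0:
            logger.warning("%s: dropping zero-area part", perimeter.event_id)
            continue
        kept.append(p)
    kept.sort(key=lambda p: (-p.area, p.centroid.x, p.centroid.y))
    return [
        FireFootprint(
            footprint_id=f"{perimeter.event_id}-{k + 1}",
            event_id=perimeter.event_id,
            year=perimeter.year,
            used_polygon=p,
        )
        for k, p in enumerate(kept)
    ]


# ---------------------------------------------------------------------------
# equal-area buffer
# ---------------------------------------------------------------------------


def _ring_at(used: Polygon, filled: Polygon, w: float, holes: str) -> BaseGeometry:
    """Outside buffer ring of width ``w`` (round joins)."""
    outer = used.buffer(w, quad_segs=BUFFER_QUAD_SEGS)
    if holes == "excluded":
        # hole interiors belong to neither used nor buffer
        return outer.difference(filled)
    return outer.difference(used)


def delineate_available(
    footprint: FireFootprint,
    tol: float = 1e-3,
    holes: str = "excluded",
) -> AvailableRegion:
    """Find the buffer width giving a buffer of the same area as the fire.

    The width ``w`` solves ``area(ring(w)) = used_area`` by bracketed
    root-finding (Brent) with ``tol`` the relative area tolerance. With
    ``holes="excluded"`` the ring excludes interior-hole area, so the buffer
    lies strictly outside the mapped perimeter envelope.
    """
    if holes not in ("excluded", "available"):
        raise ValueError("holes must be 'excluded' or 'available'")
    used = footprint.used_polygon
    a = used.area
    filled = Polygon(used.exterior)

    def f(w: float) -> float:
        return _ring_at(used, filled, w, holes).area - a

    # initial scale: ring area ≈ perimeter * w for small w
    minx, miny, maxx, maxy = used.bounds
    diag = ((maxx - minx) ** 2 + (maxy - miny) ** 2) ** 0.5
    w_hi = max(a / max(used.length, 1e-12), diag / 8, 1e-9)
    limit = 10.0 * diag
    while f(w_hi) < 0.0:
        w_hi *= 2.0
        if w_hi > limit:
            raise GeometryError(
                f"{footprint.footprint_id}: equal-area buffer width not "
                f"bracketed below 10x the bounding-box diagonal"
            )
    w = brentq(f, 0.0, w_hi, xtol=1e-9 * max(w_hi, 1.0), rtol=1e-12)
    ring = _ring_at(used, filled, w, holes)
    rel_err = abs(ring.area - a) / a
    if rel_err > tol:
        raise GeometryError(
            f"{footprint.footprint_id}: buffer area off by {rel_err:.2e} (> {tol})"
        )
    available = unary_union([used, ring])
    return AvailableRegion(
        footprint_id=footprint.footprint_id,
        used_polygon=used,
        buffer_polygon=ring,
        available_polygon=available,
        buffer_width_m=float(w),
    )


# ---------------------------------------------------------------------------
# study-area exclusion
# ---------------------------------------------------------------------------


def apply_exclusion(
    region: AvailableRegion, study: StudyArea, edge_tol: float = 1e-4
) -> bool:
    """True if the region is kept (available area inside the study boundary).

    Ownership cannot be assigned outside the study area, so a footprint whose
    available area extends beyond the boundary is excluded. ``edge_tol`` is
    the outside-area fraction treated as a floating-point sliver.
    """
    outside = region.available_polygon.difference(study.boundary).area
    return outside / region.available_polygon.area <= edge_tol


# ---------------------------------------------------------------------------
# overlay
# ---------------------------------------------------------------------------


def _class_areas(target: BaseGeometry, class_geoms: dict[str, BaseGeometry]) -> dict[str, float]:
    out: dict[str, float] = {}
    for cls_, geom in class_geoms.items():
        inter = target.intersection(geom)
        if not inter.is_empty and inter.area > 0.0:
            out[cls_] = inter.area
    return out


def overlay_proportions(
    region: AvailableRegion,
    ownership: OwnershipLayer,
    vegetation: VegetationLayer | None = None,
) -> ProportionTable:
    """Used and available ownership proportions for one footprint.

    ``o_i`` is the fraction of the burned area in ownership class *i* and
    ``pi_i`` the fraction of the available area in class *i*. Area uncovered
    by any parcel is assigned to ``other``. Classes absent from the available
    area are omitted, so each column sums to one. The unburnable fraction of
    the available area is reported alongside but does not reduce the
    ownership denominators.
    """
    used = region.used_polygon
    available = region.available_polygon
    a_used = used.area
    a_avail = available.area

    class_geoms = ownership.class_geometries()
    used_by = _class_areas(used, class_geoms)
    avail_by = _class_areas(available, class_geoms)

    gap_avail = a_avail - sum(avail_by.values())
    if gap_avail / a_avail > 1e-9:
        logger.warning(
            "%s: %.2f%% of available area uncovered by ownership; assigned to %r",
            region.footprint_id,
            100.0 * gap_avail / a_avail,
            OTHER_CLASS,
        )
        avail_by[OTHER_CLASS] = avail_by.get(OTHER_CLASS, 0.0) + gap_avail
        gap_used = a_used - sum(used_by.values())
        if gap_used > 0.0:
            used_by[OTHER_CLASS] = used_by.get(OTHER_CLASS, 0.0) + gap_used

    rows = tuple(
        (cls_, used_by.get(cls_, 0.0) / a_used, avail_by[cls_] / a_avail)
        for cls_ in sorted(avail_by)
    )

    unb_frac = 0.0
    if vegetation is not None:
        veg_geoms = vegetation.class_geometries()
        unb = veg_geoms.get("unburnable")
        if unb is not None:
            unb_frac = available.intersection(unb).area / a_avail

    return ProportionTable(
        footprint_id=region.footprint_id,
        rows=rows,
        unburnable_available_fraction=float(unb_frac),
    )
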