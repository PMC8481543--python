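"""Vector and tabular I/O, configuration and logging plumbing.

All spatial layers enter the pipeline through :func:`read_vector_layer` and all
result tables leave it through :func:`write_records`; no other module touches
files. Geometry is handled in a planar projected CRS with meter units; areas
are reported in hectares (1 ha = 10⁴ m²).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from shapely import make_valid
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "StudyArea",
    "OwnershipLayer",
    "VegetationLayer",
    "FirePerimeter",
    "SchemaError",
    "FormatError",
    "CRSError",
    "M2_PER_HA",
    "VEG_CLASSES",
    "OTHER_CLASS",
    "read_vector_layer",
    "write_vector_layer",
    "write_records",
    "load_config",
    "setup_logging",
]

logger = logging.getLogger("fireselect")

M2_PER_HA = 10_000.0
VEG_CLASSES = ("forest", "grass_shrub", "unburnable")
#: label implicitly assigned to area not covered by any ownership parcel
OTHER_CLASS = "other"

DEFAULT_CRS = "local-metric"

#: substrings that identify a geographic (degree-unit) CRS we cannot analyse
_GEOGRAPHIC_CRS_HINTS = ("4326", "crs84", "wgs84", "wgs 84", "longlat", "geographic")


class SchemaError(ValueError):
    """A required attribute column is missing from an input layer."""


class FormatError(ValueError):
    """The input file is not a format or geometry mix the pipeline accepts."""


class CRSError(ValueError):
    """Layers do not share a planar metric CRS."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyArea:
    """Analysis extent: a single valid polygon in planar meter coordinates."""

    boundary: Polygon
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.area <= 0:
            raise ValueError("study-area boundary must be valid with positive area")

    @property
    def area_ha(self) -> float:
        return self.boundary.area / M2_PER_HA


@dataclass(frozen=True)
class OwnershipLayer:
    """Pairwise non-overlapping parcels labelled with an ownership class.

    Area inside the study extent not covered by any parcel is implicitly
    ``other``: overlays assign uncovered area to that class.
    """

    parcels: tuple[tuple[BaseGeometry, str], ...]
    owner_classes: tuple[str, ...]
    crs_id: str = DEFAULT_CRS

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[BaseGeometry, str]],
        crs_id: str = DEFAULT_CRS,
        owner_classes: Sequence[str] | None = None,
    ) -> "OwnershipLayer":
        pairs = tuple((g, str(c)) for g, c in pairs)
        if owner_classes is None:
            seen: list[str] = []
            for _, c in pairs:
                if c not in seen:
                    seen.append(c)
            owner_classes = seen
        return cls(parcels=pairs, owner_classes=tuple(owner_classes), crs_id=crs_id)

    def class_geometries(self) -> dict[str, BaseGeometry]:
        """Parcels merged per ownership class."""
        from shapely.ops import unary_union

        out: dict[str, list[BaseGeometry]] = {}
        for geom, cls_ in self.parcels:
            out.setdefault(cls_, []).append(geom)
        return {c: unary_union(gs) for c, gs in out.items()}


@dataclass(frozen=True)
class VegetationLayer:
    """Non-overlapping patches labelled forest / grass_shrub / unburnable."""

    patches: tuple[tuple[BaseGeometry, str], ...]
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        bad = {c for _, c in self.patches} - set(VEG_CLASSES)
        if bad:
            raise ValueError(f"unknown vegetation classes: {sorted(bad)}")

    def class_geometries(self) -> dict[str, BaseGeometry]:
        from shapely.ops import unary_union

        out: dict[str, list[BaseGeometry]] = {}
        for geom, cls_ in self.patches:
            out.setdefault(cls_, []).append(geom)
        return {c: unary_union(gs) for c, gs in out.items()}


@dataclass(frozen=True)
class FirePerimeter:
    """A mapped fire perimeter, possibly multi-part, before splitting."""

    event_id: str
    year: int
    geometry: BaseGeometry  # Polygon or MultiPolygon
    crs_id: str = DEFAULT_CRS


# ---------------------------------------------------------------------------
# GeoJSON reading / writing
# ---------------------------------------------------------------------------

_REQUIRED_PROPS = {
    "fires": ("event_id", "year"),
    "ownership": ("owner_class",),
    "vegetation": ("veg_class",),
    "study_area": (),
}


def _check_crs(doc: Mapping, study_crs: str | None) -> str:
    """Extract and vet the document CRS string.

    Reprojection is out of scope: layers must already share a planar metric
    CRS, and an explicitly geographic CRS is rejected.
    """
    crs_id = DEFAULT_CRS
    crs = doc.get("crs")
    if isinstance(crs, Mapping):
        name = crs.get("properties", {}).get("name", "")
        if not isinstance(name, str) or not name:
            raise CRSError("unparseable crs member in GeoJSON document")
        crs_id = name
    if any(h in crs_id.lower() for h in _GEOGRAPHIC_CRS_HINTS):
        raise CRSError(
            f"layer CRS {crs_id!r} is geographic (degree units); "
            "analysis requires a planar projected CRS in meters"
        )
    if study_crs is not None and crs_id != DEFAULT_CRS and crs_id != study_crs:
        raise CRSError(f"layer CRS {crs_id!r} differs from study CRS {study_crs!r}")
    return crs_id


def _repair(geom: BaseGeometry, what: str) -> BaseGeometry | None:
    """Standard validity repair; reject features that stay invalid."""
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if fixed.is_valid and fixed.area > 0:
        # make_valid may return a collection; keep the polygonal part
        if fixed.geom_type == "GeometryCollection":
            polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            if not polys:
                logger.warning("rejected unrepairable feature in %s", what)
                return None
            from shapely.ops import unary_union

            fixed = unary_union(polys)
        logger.info("repaired invalid geometry in %s", what)
        return fixed
    logger.warning("rejected unrepairable feature in %s", what)
    return None


def _load_features(path: str | Path) -> tuple[dict, list[dict]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".gpkg", ".shp"):
        raise FormatError(
            f"{path.suffix} input is not supported in this build; "
            "convert the layer to GeoJSON"
        )
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - message pass-through
        raise FormatError(f"{path} is not parseable GeoJSON: {exc}") from exc
    if doc.get("type") == "FeatureCollection":
        feats = doc.get("features", [])
    elif doc.get("type") == "Feature":
        feats = [doc]
    else:
        raise FormatError(f"{path}: expected a GeoJSON Feature or FeatureCollection")
    return doc, feats


def read_vector_layer(
    path: str | Path,
    layer_kind: str,
    study_crs: str | None = None,
):
    """Read a GeoJSON layer into the matching domain type.

    Parameters
    ----------
    path:
        GeoJSON file (RFC 7946 structure; coordinates interpreted as planar
        meters in the study CRS).
    layer_kind:
        One of ``fires``, ``ownership``, ``vegetation``, ``study_area``.
    study_crs:
        CRS identifier the layer must match, if already known.

    Returns
    -------
    ``list[FirePerimeter]`` | :class:`OwnershipLayer` | :class:`VegetationLayer`
    | :class:`StudyArea`
    """
    if layer_kind not in _REQUIRED_PROPS:
        raise ValueError(f"unknown layer_kind {layer_kind!r}")
    doc, feats = _load_features(path)
    crs_id = _check_crs(doc, study_crs)

    required = _REQUIRED_PROPS[layer_kind]
    geoms: list[BaseGeometry] = []
    props: list[dict] = []
    for i, feat in enumerate(feats):
        p = feat.get("properties") or {}
        for col in required:
            if col not in p:
                raise SchemaError(
                    f"{path}: feature {i} of layer {layer_kind!r} lacks "
                    f"required attribute {col!r}"
                )
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise FormatError(
                f"{path}: mixed/non-areal geometry type {geom.geom_type!r} "
                f"in {layer_kind!r} layer"
            )
        geom = _repair(geom, f"{path}:{i}")
        if geom is None:
            continue
        geoms.append(geom)
        props.append(p)

    if layer_kind == "study_area":
        if not geoms:
            raise FormatError(f"{path}: study-area layer is empty")
        from shapely.ops import unary_union

        merged = unary_union(geoms)
        if merged.geom_type == "MultiPolygon":
            merged = max(merged.geoms, key=lambda g: g.area)
            logger.warning("multi-part study area: keeping the largest part")
        return StudyArea(boundary=merged, crs_id=crs_id)
    if layer_kind == "ownership":
        return OwnershipLayer.from_pairs(
            [(g, p["owner_class"]) for g, p in zip(geoms, props)], crs_id=crs_id
        )
    if layer_kind == "vegetation":
        return VegetationLayer(
            patches=tuple((g, p["veg_class"]) for g, p in zip(geoms, props)),
            crs_id=crs_id,
        )
    return [
        FirePerimeter(
            event_id=str(p["event_id"]), year=int(p["year"]), geometry=g, crs_id=crs_id
        )
        for g, p in zip(geoms, props)
    ]


def write_vector_layer(
    geometries: Iterable[BaseGeometry],
    properties: Iterable[Mapping] | None,
    path: str | Path,
    crs_id: str = DEFAULT_CRS,
) -> None:
    """Write polygons + attribute mappings as a GeoJSON FeatureCollection."""
    geometries = list(geometries)
    properties = list(properties) if properties is not None else [{}] * len(geometries)
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": dict(p)}
        for g, p in zip(geometries, properties)
    ]
    doc: dict = {"type": "FeatureCollection", "features": features}
    if crs_id != DEFAULT_CRS:
        doc["crs"] = {"type": "name", "properties": {"name": crs_id}}
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_records(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a result table to CSV with a stable column order and header.

    Accepts a DataFrame, a sequence of dataclasses, or a sequence of dicts.
    An empty input with a known schema yields a header-only file. Floats are
    serialized with full precision (well above 6 significant digits), so a
    read-back reproduces values within 1e-9.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and hasattr(rows[0], "__dataclass_fields__"):
            from dataclasses import asdict

            rows = [asdict(r) for r in rows]
        df = pd.DataFrame(rows, columns=columns if (columns and not rows) else None)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# config and logging
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_permutations": 50_000,
    "alpha": 0.05,
    "equal_area_tol": 1e-3,
    "edge_tol": 1e-4,
    "tie_tol": 1e-9,
    "display_min_n": 25,
    "holes": "excluded",  # or "available"
    "boundary_mode": "inclusive",  # 2:1 classification boundary
    "null_mode": "pairwise",  # or "fire"
}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Merge defaults <- YAML/JSON config file <- explicit overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        if loaded:
            if not isinstance(loaded, Mapping):
                raise FormatError(f"{path}: config must be a mapping")
            cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Timestamped logging to stderr, optionally duplicated to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("fireselect")
    root.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)
    root.setLevel(getattr(logging, level.upper()))
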