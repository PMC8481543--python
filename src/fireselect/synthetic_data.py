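"""Synthetic landscapes and fires with known, tunable ownership selectivity.

The generator builds an ownership mosaic (checkerboard, Voronoi, or
large-swath patterns), a three-class vegetation layer (forest, grass/shrub,
unburnable) and a set of fire footprints grown stochastically on a raster
lattice. Growth starts at a random burnable ignition cell and repeatedly
adds a frontier cell sampled with probability proportional to
``exp(beta(owner(cell)))``, never entering unburnable cells; ``beta = 0``
for every class makes growth blind to ownership, which is the
proportional-use null by construction, while a positive (negative) beta for
one class injects a known preference (avoidance) that downstream estimators
should recover.

Two evaluation routes consume the grown fires. The polygon route
(:func:`generate_fire_set`) polygonises each cell set into a
:class:`~fireselect.geometry.FireFootprint` for the exact geometric
pipeline. The lattice route (:func:`simulate_selectivity_dataset`) computes
used/available proportions directly by cell counting, with the equal-area
availability ring taken as the burned-cell-count nearest unburned cells by
Euclidean distance — the discrete analogue of the equal-area buffer — which
makes replicated power and type-I-error studies cheap. The two routes agree
in the small-cell limit and that agreement is itself under test.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from shapely import box as shp_box
from shapely import union_all
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

from .classification import _label
from .geometry import FireFootprint
from .io_formats import OwnershipLayer, StudyArea, VegetationLayer
from .selectivity import SelectivityRecord, jacobs_index

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "SyntheticTruth",
    "LandscapeLattice",
    "IgnitionRejected",
    "generate_landscape",
    "build_lattice",
    "rasterize_layers",
    "grow_fire",
    "generate_fire_set",
    "simulate_selectivity_dataset",
]

VEG_IDX = {"forest": 0, "grass_shrub": 1, "unburnable": 2}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class IgnitionRejected(RuntimeError):
    """Ignition fell on unburnable land; the caller should redraw."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``extent`` is the rectangular study area in meters; the lattice divides
    it into ``lattice_cells`` cells per side. Fire sizes (in cells) follow a
    log-normal law with parameters ``fire_size_mu``/``fire_size_sigma`` on
    the log scale — with the defaults (96 km extent, 512 cells, cell area
    3.52 ha, median e^4.956 ≈ 142 cells) the median fire is ≈ 500 ha, with
    the heavy right tail characteristic of fire-size data. ``bias`` maps
    ownership class names to the spread-preference log-weight beta.
    """

    extent: tuple[float, float] = (96_000.0, 96_000.0)
    mosaic_pattern: str = "voronoi"
    n_owner_classes: int = 8
    n_mosaic_seeds: int | None = None  # voronoi sites; default 32 per class
    mosaic_tiles: int = 8  # checkerboard tiles per side
    swaths_per_class: int = 2  # swath strips cycle through the classes
    veg_fractions: tuple[float, float, float] = (0.51, 0.31, 0.18)
    veg_tile_grid: int = 16  # vegetation tiles per side
    n_fires: int = 100
    fire_size_mu: float = 4.956  # log cells; median exp(mu)
    fire_size_sigma: float = 1.0
    bias: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    lattice_cells: int = 512
    periodic: bool = False  # toroidal lattice: no extent edge, no exclusions
    start_year: int = 1984
    n_years: int = 35

    def __post_init__(self) -> None:
        if self.n_owner_classes < 2:
            raise ConfigError("n_owner_classes must be at least 2")
        vf = self.veg_fractions
        if len(vf) != 3 or any(f < 0 for f in vf) or abs(sum(vf) - 1.0) > 1e-9:
            raise ConfigError("veg_fractions must be 3 non-negative values summing to 1")
        if self.n_fires < 1:
            raise ConfigError("n_fires must be >= 1")
        if self.fire_size_sigma <= 0:
            raise ConfigError("fire_size_sigma must be > 0")
        if self.mosaic_pattern not in ("checkerboard", "voronoi", "swaths"):
            raise ConfigError(f"unknown mosaic_pattern {self.mosaic_pattern!r}")
        # median fire must fit well inside the extent
        median_cells = math.exp(self.fire_size_mu)
        if median_cells > 0.25 * self.lattice_cells**2:
            raise ConfigError("extent/lattice too small for the requested fire sizes")

    @property
    def cell_size(self) -> float:
        return self.extent[0] / self.lattice_cells

    @property
    def owner_class_names(self) -> tuple[str, ...]:
        return tuple(f"owner_{i + 1:02d}" for i in range(self.n_owner_classes))

    def beta_array(self) -> np.ndarray:
        names = self.owner_class_names
        unknown = set(self.bias) - set(names)
        if unknown:
            raise ConfigError(f"bias refers to unknown classes: {sorted(unknown)}")
        return np.array([float(self.bias.get(c, 0.0)) for c in names])


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests."""

    bias: dict[str, float]
    ignition_cells: dict[str, tuple[int, int]]  # footprint_id -> (row, col)
    burned_cells: dict[str, np.ndarray]  # footprint_id -> flat cell indices


@dataclass(frozen=True)
class LandscapeLattice:
    """Rasterised landscape shared by growth and the lattice evaluation route."""

    owner_idx: np.ndarray  # (H, W) int16, index into class_names
    veg_idx: np.ndarray  # (H, W) int8, index into VEG_IDX
    cell_size: float
    class_names: tuple[str, ...]
    extent: tuple[float, float]

    @property
    def burnable(self) -> np.ndarray:
        return self.veg_idx != VEG_IDX["unburnable"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.owner_idx.shape


# ---------------------------------------------------------------------------
# mosaic construction (analytic raster + matching polygons)
# ---------------------------------------------------------------------------


def _mosaic_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))


def _voronoi_sites(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Site coordinates and their class assignment (every class present)."""
    rng = _mosaic_rng(config)
    n_sites = config.n_mosaic_seeds or 32 * config.n_owner_classes
    if n_sites < config.n_owner_classes:
        raise ConfigError("n_mosaic_seeds must be >= n_owner_classes")
    w, h = config.extent
    sites = rng.uniform((0.0, 0.0), (w, h), size=(n_sites, 2))
    classes = np.arange(n_sites) % config.n_owner_classes
    rng.shuffle(classes)
    return sites, classes


def _veg_tiles(config: SimulationConfig) -> np.ndarray:
    """(G, G) vegetation class index per coarse tile, matching veg_fractions."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    g = config.veg_tile_grid
    n = g * g
    n_forest = round(config.veg_fractions[0] * n)
    n_grass = round(config.veg_fractions[1] * n)
    order = rng.permutation(n)
    tiles = np.full(n, VEG_IDX["unburnable"], dtype=np.int8)
    tiles[order[:n_forest]] = VEG_IDX["forest"]
    tiles[order[n_forest : n_forest + n_grass]] = VEG_IDX["grass_shrub"]
    return tiles.reshape(g, g)


def _cell_centers(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    n = config.lattice_cells
    cs = config.cell_size
    xs = (np.arange(n) + 0.5) * cs
    ys = (np.arange(config.lattice_cells) + 0.5) * (config.extent[1] / n)
    return xs, ys


def build_lattice(config: SimulationConfig) -> LandscapeLattice:
    """Rasterise the configured mosaic analytically (no polygon overlay)."""
    n = config.lattice_cells
    xs, ys = _cell_centers(config)
    if config.mosaic_pattern == "checkerboard":
        k = config.mosaic_tiles
        ti = np.floor(xs / (config.extent[0] / k)).astype(int).clip(0, k - 1)
        tj = np.floor(ys / (config.extent[1] / k)).astype(int).clip(0, k - 1)
        owner = ((tj[:, None] + ti[None, :]) % config.n_owner_classes).astype(np.int16)
    elif config.mosaic_pattern == "swaths":
        n_strips = config.swaths_per_class * config.n_owner_classes
        strip = np.floor(xs / (config.extent[0] / n_strips)).astype(int)
        strip = strip.clip(0, n_strips - 1) % config.n_owner_classes
        owner = np.broadcast_to(strip[None, :].astype(np.int16), (n, n)).copy()
    else:  # voronoi: nearest site
        sites, classes = _voronoi_sites(config)
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        _, nearest = cKDTree(sites).query(pts)
        owner = classes[nearest].reshape(n, n).astype(np.int16)

    g = config.veg_tile_grid
    tiles = _veg_tiles(config)
    ti = np.floor(xs / (config.extent[0] / g)).astype(int).clip(0, g - 1)
    tj = np.floor(ys / (config.extent[1] / g)).astype(int).clip(0, g - 1)
    veg = tiles[np.ix_(tj, ti)]

    return LandscapeLattice(
        owner_idx=owner,
        veg_idx=veg.astype(np.int8),
        cell_size=config.cell_size,
        class_names=config.owner_class_names,
        extent=config.extent,
    )


def generate_landscape(
    config: SimulationConfig,
) -> tuple[StudyArea, OwnershipLayer, VegetationLayer]:
    """Polygon layers for the configured mosaic.

    The polygons are exact (tile boxes, Voronoi cells, strips), and
    :func:`build_lattice` rasterises the same mosaic analytically, so the
    vector and raster views agree up to cell-centre quantisation.
    """
    w, h = config.extent
    study = StudyArea(boundary=shp_box(0.0, 0.0, w, h))
    names = config.owner_class_names

    pairs: list[tuple[Polygon, str]] = []
    if config.mosaic_pattern == "checkerboard":
        k = config.mosaic_tiles
        tw, th = w / k, h / k
        for j in range(k):
            for i in range(k):
                cls = names[(i + j) % config.n_owner_classes]
                pairs.append((shp_box(i * tw, j * th, (i + 1) * tw, (j + 1) * th), cls))
    elif config.mosaic_pattern == "swaths":
        n_strips = config.swaths_per_class * config.n_owner_classes
        sw = w / n_strips
        for i in range(n_strips):
            cls = names[i % config.n_owner_classes]
            pairs.append((shp_box(i * sw, 0.0, (i + 1) * sw, h), cls))
    else:
        sites, classes = _voronoi_sites(config)
        pts = MultiPoint([Point(*s) for s in sites])
        regions = voronoi_diagram(pts, envelope=shp_box(0.0, 0.0, w, h))
        extent_box = shp_box(0.0, 0.0, w, h)
        for region in regions.geoms:
            clipped = region.intersection(extent_box)
            if clipped.is_empty or clipped.area <= 0:
                continue
            # match the region back to its generating site
            inside = [i for i, s in enumerate(sites) if region.covers(Point(*s))]
            if not inside:  # pragma: no cover - voronoi regions always cover a site
                continue
            pairs.append((clipped, names[classes[inside[0]]]))

    ownership = OwnershipLayer.from_pairs(pairs, owner_classes=names)

    g = config.veg_tile_grid
    tiles = _veg_tiles(config)
    tw, th = w / g, h / g
    by_class: dict[str, list[Polygon]] = {v: [] for v in VEG_IDX}
    inv = {v: k for k, v in VEG_IDX.items()}
    for j in range(g):
        for i in range(g):
            by_class[inv[int(tiles[j, i])]].append(
                shp_box(i * tw, j * th, (i + 1) * tw, (j + 1) * th)
            )
    patches = tuple(
        (union_all(boxes), veg_cls) for veg_cls, boxes in by_class.items() if boxes
    )
    vegetation = VegetationLayer(patches=patches)
    return study, ownership, vegetation


def rasterize_layers(
    ownership: OwnershipLayer,
    vegetation: VegetationLayer,
    study: StudyArea,
    n_cells: int = 256,
) -> LandscapeLattice:
    """Rasterise arbitrary polygon layers by cell-centre point lookup.

    Used to run the lattice route on landscapes that did not originate from
    :func:`build_lattice` (e.g. route-equivalence tests on hand-built
    layers).
    """
    import shapely

    minx, miny, maxx, maxy = study.boundary.bounds
    w, h = maxx - minx, maxy - miny
    cs = w / n_cells
    ny = max(1, round(h / cs))
    xs = minx + (np.arange(n_cells) + 0.5) * cs
    ys = miny + (np.arange(ny) + 0.5) * (h / ny)
    xx, yy = np.meshgrid(xs, ys)
    pts = shapely.points(xx.ravel(), yy.ravel())

    names = tuple(ownership.owner_classes)
    owner = np.full(pts.shape, -1, dtype=np.int16)
    cls_geoms = ownership.class_geometries()
    for ci, name in enumerate(names):
        geom = cls_geoms.get(name)
        if geom is None:
            continue
        owner[shapely.covers(geom, pts)] = ci

    veg = np.full(pts.shape, VEG_IDX["unburnable"], dtype=np.int8)
    for veg_cls, geom in vegetation.class_geometries().items():
        veg[shapely.covers(geom, pts)] = VEG_IDX[veg_cls]

    if (owner < 0).any():
        # uncovered cells: implicit "other"
        names = names + ("other",)
        owner[owner < 0] = len(names) - 1
    return LandscapeLattice(
        owner_idx=owner.reshape(ny, n_cells),
        veg_idx=veg.reshape(ny, n_cells),
        cell_size=cs,
        class_names=names,
        extent=(w, h),
    )


# ---------------------------------------------------------------------------
# fire growth
# ---------------------------------------------------------------------------


def grow_fire(
    lattice: LandscapeLattice,
    ignition: tuple[int, int],
    target_cells: int,
    beta: np.ndarray | Mapping[str, float] | None,
    rng: random.Random,
    periodic: bool = False,
) -> np.ndarray:
    """Grow one fire as a connected cell set; returns flat cell indices.

    Starting from the ignition cell, repeatedly sample a frontier cell
    (4-neighbourhood) with probability proportional to
    ``exp(beta[owner(cell)])`` — by rejection against the maximum weight —
    and add it, until ``target_cells`` cells have burned or the frontier is
    exhausted. Unburnable cells are never added. With ``periodic=True`` the
    lattice is a torus (neighbours wrap), giving translation-invariant
    growth with no extent-edge effects.
    """
    H, W = lattice.shape
    r0, c0 = ignition
    if not (0 <= r0 < H and 0 <= c0 < W):
        raise ValueError("ignition outside the lattice")
    burnable = lattice.burnable
    if not burnable[r0, c0]:
        raise IgnitionRejected(f"ignition cell {ignition} is unburnable")
    if target_cells < 1:
        raise ValueError("target_cells must be >= 1")

    if beta is None:
        weights = None
    else:
        if isinstance(beta, Mapping):
            beta = np.array([float(beta.get(c, 0.0)) for c in lattice.class_names])
        beta = np.asarray(beta, dtype=float)
        if np.all(beta == beta[0]):
            weights = None  # uniform: skip rejection entirely
        else:
            w = np.exp(beta - beta.max())
            weights = w.tolist()

    owner = lattice.owner_idx
    burned = np.zeros((H, W), dtype=bool)
    in_frontier = np.zeros((H, W), dtype=bool)
    burned[r0, c0] = True
    cells = [r0 * W + c0]
    frontier: list[int] = []

    if periodic:

        def push_neighbours(r: int, c: int) -> None:
            for rr, cc in (
                ((r - 1) % H, c),
                ((r + 1) % H, c),
                (r, (c - 1) % W),
                (r, (c + 1) % W),
            ):
                if burnable[rr, cc] and not burned[rr, cc] and not in_frontier[rr, cc]:
                    in_frontier[rr, cc] = True
                    frontier.append(rr * W + cc)

    else:

        def push_neighbours(r: int, c: int) -> None:
            if r > 0 and burnable[r - 1, c] and not burned[r - 1, c] and not in_frontier[r - 1, c]:
                in_frontier[r - 1, c] = True
                frontier.append((r - 1) * W + c)
            if r + 1 < H and burnable[r + 1, c] and not burned[r + 1, c] and not in_frontier[r + 1, c]:
                in_frontier[r + 1, c] = True
                frontier.append((r + 1) * W + c)
            if c > 0 and burnable[r, c - 1] and not burned[r, c - 1] and not in_frontier[r, c - 1]:
                in_frontier[r, c - 1] = True
                frontier.append(r * W + c - 1)
            if c + 1 < W and burnable[r, c + 1] and not burned[r, c + 1] and not in_frontier[r, c + 1]:
                in_frontier[r, c + 1] = True
                frontier.append(r * W + c + 1)

    push_neighbours(r0, c0)
    rand = rng.random
    randrange = rng.randrange
    owner_flat = owner.ravel()

    while len(cells) < target_cells and frontier:
        if weights is None:
            k = randrange(len(frontier))
        else:
            while True:  # rejection sampling against the max class weight
                k = randrange(len(frontier))
                if rand() < weights[owner_flat[frontier[k]]]:
                    break
        flat = frontier[k]
        frontier[k] = frontier[-1]
        frontier.pop()
        r, c = divmod(flat, W)
        in_frontier[r, c] = False
        burned[r, c] = True
        cells.append(flat)
        push_neighbours(r, c)

    return np.asarray(cells, dtype=np.int64)


def _fire_rng(seed: int, k: int) -> random.Random:
    # per-fire substream keyed by (seed, counter): fire k is reproducible
    # independent of generation order
    return random.Random(f"{seed}:{k}")


def _draw_fires(
    config: SimulationConfig, lattice: LandscapeLattice
) -> list[tuple[str, int, np.ndarray, tuple[int, int]]]:
    """Shared fire drawing: (footprint_id, year, flat cells, ignition)."""
    H, W = lattice.shape
    burnable_flat = np.flatnonzero(lattice.burnable.ravel())
    if burnable_flat.size == 0:
        raise ConfigError("landscape has no burnable cells")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    sizes = np.maximum(
        1, np.rint(rng.lognormal(config.fire_size_mu, config.fire_size_sigma, config.n_fires))
    ).astype(int)
    years = rng.integers(config.start_year, config.start_year + config.n_years, config.n_fires)
    out = []
    for k in range(config.n_fires):
        sub = _fire_rng(config.seed, k)
        # redraw ignition until burnable (burnable_flat guarantees it here;
        # kept as a loop for clarity with grow_fire's rejection contract)
        flat0 = int(burnable_flat[sub.randrange(burnable_flat.size)])
        ign = divmod(flat0, W)
        cells = grow_fire(
            lattice, ign, int(sizes[k]), config.beta_array(), sub,
            periodic=config.periodic,
        )
        out.append((f"SIM{k:05d}", int(years[k]), cells, ign))
    return out


def _cells_to_polygon(cells: np.ndarray, lattice: LandscapeLattice) -> Polygon:
    H, W = lattice.shape
    csx = lattice.extent[0] / W
    csy = lattice.extent[1] / H
    rr, cc = np.divmod(cells, W)
    boxes = shp_box(cc * csx, rr * csy, (cc + 1) * csx, (rr + 1) * csy)
    merged = union_all(boxes)
    if merged.geom_type != "Polygon":  # pragma: no cover - growth is 4-connected
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged


def generate_fire_set(
    config: SimulationConfig,
    lattice: LandscapeLattice | None = None,
) -> tuple[list[FireFootprint], SyntheticTruth]:
    """Grow ``n_fires`` footprints and polygonise them (polygon route).

    Synthetic fires are single-part by construction; multi-part splitting is
    exercised on hand-built fixtures instead.
    """
    if lattice is None:
        lattice = build_lattice(config)
    truth = SyntheticTruth(
        bias={c: float(config.bias.get(c, 0.0)) for c in config.owner_class_names},
        ignition_cells={},
        burned_cells={},
    )
    footprints = []
    for fid, year, cells, ign in _draw_fires(config, lattice):
        truth.ignition_cells[fid] = ign
        truth.burned_cells[fid] = cells
        footprints.append(
            FireFootprint(
                footprint_id=f"{fid}-1",
                event_id=fid,
                year=year,
                used_polygon=_cells_to_polygon(cells, lattice),
            )
        )
    return footprints, truth


# ---------------------------------------------------------------------------
# lattice evaluation route
# ---------------------------------------------------------------------------


def _equal_area_ring(
    burned_flat: np.ndarray,
    lattice: LandscapeLattice,
    periodic: bool = False,
    anchor: tuple[int, int] | None = None,
) -> np.ndarray | None:
    """The n nearest unburned cells to an n-cell fire, by Euclidean distance.

    Discrete analogue of the equal-area outside buffer. On a bounded
    lattice, returns None when the ring would leave it (the study-area
    exclusion rule: the available area extends beyond the extent, so
    ownership cannot be assigned and the footprint is excluded). On a
    periodic lattice coordinates are unwrapped around the ignition anchor
    and the ring never leaves the torus.
    """
    H, W = lattice.shape
    rr, cc = np.divmod(burned_flat, W)
    n = burned_flat.size
    margin = int(math.ceil(0.9 * math.sqrt(n))) + 3
    if periodic:
        if anchor is None:
            anchor = (int(rr[0]), int(cc[0]))
        # unwrap around the anchor: fires are connected and much smaller
        # than the torus, so centered offsets are unambiguous
        rr = (rr - anchor[0] + H // 2) % H - H // 2 + anchor[0]
        cc = (cc - anchor[1] + W // 2) % W - W // 2 + anchor[1]
    r_lo, r_hi = rr.min() - margin, rr.max() + margin + 1
    c_lo, c_hi = cc.min() - margin, cc.max() + margin + 1
    if not periodic and (r_lo < 0 or c_lo < 0 or r_hi > H or c_hi > W):
        return None  # available area would leave the study extent
    win = np.ones((r_hi - r_lo, c_hi - c_lo), dtype=bool)
    win[rr - r_lo, cc - c_lo] = False
    dist = distance_transform_edt(win)
    flat_local = np.flatnonzero(win.ravel())
    d = dist.ravel()[flat_local]
    order = np.argsort(d, kind="stable")[:n]
    if d[order[-1]] >= margin - 1:  # ring truncated by the crop window
        return None
    sel = flat_local[order]
    lr, lc = np.divmod(sel, c_hi - c_lo)
    out_r = lr + r_lo
    out_c = lc + c_lo
    if periodic:
        out_r %= H
        out_c %= W
    return out_r * W + out_c


def simulate_selectivity_dataset(
    config: SimulationConfig,
    lattice: LandscapeLattice | None = None,
) -> tuple[list[SelectivityRecord], SyntheticTruth]:
    """Full synthetic dataset evaluated on the lattice (cell counting).

    For each fire: the used proportion per ownership is the burned cell
    share, the available proportion the (burned + equal-count ring) share,
    the fire type the 2:1 dominance label on burned vegetation cells, and
    the Jacobs' index follows from (o, pi). Fires whose ring would leave the
    extent are excluded, mirroring the study-area exclusion rule.
    """
    if lattice is None:
        lattice = build_lattice(config)
    names = lattice.class_names
    n_classes = len(names)
    owner_flat = lattice.owner_idx.ravel()
    veg_flat = lattice.veg_idx.ravel()
    truth = SyntheticTruth(
        bias={c: float(config.bias.get(c, 0.0)) for c in config.owner_class_names},
        ignition_cells={},
        burned_cells={},
    )
    records: list[SelectivityRecord] = []
    for fid, _year, cells, ign in _draw_fires(config, lattice):
        truth.ignition_cells[fid] = ign
        truth.burned_cells[fid] = cells
        ring = _equal_area_ring(cells, lattice, periodic=config.periodic, anchor=ign)
        if ring is None:
            continue
        footprint_id = f"{fid}-1"
        veg_counts = np.bincount(veg_flat[cells], minlength=3)
        f_area, g_area = int(veg_counts[0]), int(veg_counts[1])
        if f_area + g_area == 0:
            continue  # unclassifiable: burned only unburnable-mapped land
        fire_type = _label(float(f_area), float(g_area), strict_boundary=False)

        used_counts = np.bincount(owner_flat[cells], minlength=n_classes)
        avail_counts = used_counts + np.bincount(owner_flat[ring], minlength=n_classes)
        n_used = cells.size
        n_avail = cells.size + ring.size
        for ci in np.flatnonzero(avail_counts):
            o = used_counts[ci] / n_used
            pi = avail_counts[ci] / n_avail
            records.append(
                SelectivityRecord(
                    footprint_id=footprint_id,
                    owner_class=names[ci],
                    fire_type=fire_type,
                    o=float(o),
                    pi=float(pi),
                    jacobs=jacobs_index(float(o), float(pi)),
                )
            )
    return records, truth
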