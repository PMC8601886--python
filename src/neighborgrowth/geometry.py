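"""Planar plot geometry: edge buffers, fold partitions, fold buffers.

All coordinates are local plot meters (ForestGEO gx/gy); geometry is
strictly planar Euclidean, no geodesy. Two distance conventions are used on
purpose and documented here once:

* the **edge-buffer flag** uses strict ``<`` — a stem exactly at distance
  ``dist`` from the plot edge still counts as interior/focal;
* **fold-buffer exclusion** (and competitor inclusion elsewhere) uses
  ``<=`` — a stem exactly at the buffer distance from a test block is
  excluded from training.

Both choices act on sets of measure zero and only matter for exact ties.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box, mapping, shape

from .errors import AssignmentError, DomainError, FoldLookupError, ValidationError

logger = logging.getLogger(__name__)


def _as_points(points) -> np.ndarray:
    """Coerce an (n,2) array, or a DataFrame with gx/gy columns, to floats."""
    if hasattr(points, "columns"):
        arr = np.column_stack(
            [np.asarray(points["gx"], float), np.asarray(points["gy"], float)]
        )
    else:
        arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError(f"points must be (n, 2), got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class StudyRegion:
    """The plot boundary as a simple polygon with positive area."""

    boundary: Polygon

    def __post_init__(self):
        if not isinstance(self.boundary, Polygon):
            raise ValidationError("boundary must be a shapely Polygon")
        if not self.boundary.is_valid or self.boundary.is_empty:
            raise ValidationError("boundary polygon must be simple and non-empty")
        if self.boundary.area <= 0:
            raise ValidationError("boundary polygon must have positive area")

    @classmethod
    def rectangle(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "StudyRegion":
        return cls(box(xmin, ymin, xmax, ymax))

    @property
    def area(self) -> float:
        return self.boundary.area

    def to_geojson(self) -> dict:
        return {"type": "Feature", "properties": {}, "geometry": mapping(self.boundary)}

    @classmethod
    def from_geojson(cls, obj: dict | str) -> "StudyRegion":
        if isinstance(obj, str):
            obj = json.loads(obj)
        if obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]
        geom = obj["geometry"] if obj.get("type") == "Feature" else obj
        return cls(shape(geom))


@dataclass
class FoldPartition:
    """Spatial cross-validation blocks: (fold_id >= 1, polygon) pairs.

    Blocks must be pairwise interior-disjoint and jointly cover the region
    (both within an area tolerance); fold ids need not be contiguous but must
    be positive integers.
    """

    blocks: list[tuple[int, Polygon]]
    region: StudyRegion
    tol: float = field(default=1e-6, repr=False)

    def __post_init__(self):
        if not self.blocks:
            raise ValidationError("partition needs at least one block")
        for fid, poly in self.blocks:
            if int(fid) != fid or fid < 1:
                raise ValidationError(f"fold_id must be an integer >= 1, got {fid!r}")
            if not isinstance(poly, Polygon) or poly.area <= 0:
                raise ValidationError(f"block {fid} must be a polygon of positive area")
        area_tol = self.tol * max(1.0, self.region.area)
        total = sum(p.area for _, p in self.blocks)
        union = shapely.unary_union([p for _, p in self.blocks])
        if abs(total - union.area) > area_tol:
            raise ValidationError("blocks overlap beyond tolerance")
        if abs(union.area - self.region.area) > area_tol or not union.covers(
            self.region.boundary.buffer(-self.tol)
        ):
            raise ValidationError("blocks do not cover the study region")
        self.blocks = sorted(((int(f), p) for f, p in self.blocks), key=lambda b: b[0])

    @property
    def fold_ids(self) -> list[int]:
        return sorted({fid for fid, _ in self.blocks})

    def fold_geometry(self, fold_id: int):
        polys = [p for fid, p in self.blocks if fid == fold_id]
        if not polys:
            raise FoldLookupError(f"fold_id {fold_id} not in partition {self.fold_ids}")
        return shapely.unary_union(polys)

    def to_geojson(self) -> dict:
        feats = [
            {"type": "Feature", "properties": {"fold_id": fid}, "geometry": mapping(p)}
            for fid, p in self.blocks
        ]
        feats.append(
            {
                "type": "Feature",
                "properties": {"role": "region"},
                "geometry": mapping(self.region.boundary),
            }
        )
        return {"type": "FeatureCollection", "features": feats}

    @classmethod
    def from_geojson(cls, obj: dict | str) -> "FoldPartition":
        if isinstance(obj, str):
            obj = json.loads(obj)
        blocks, region = [], None
        for feat in obj["features"]:
            props = feat.get("properties") or {}
            if props.get("role") == "region":
                region = StudyRegion(shape(feat["geometry"]))
            elif "fold_id" in props:
                blocks.append((int(props["fold_id"]), shape(feat["geometry"])))
        if region is None:
            region = StudyRegion(shapely.unary_union([p for _, p in blocks]))
        return cls(blocks=blocks, region=region)


def add_buffer_flag(points, region: StudyRegion, dist: float) -> np.ndarray:
    """Flag stems too close to the plot edge to be modeled as focal trees.

    True iff the point lies strictly within ``dist`` of the region boundary
    (or outside the region altogether — real census tables contain edge
    coordinates, so outside points are tolerated, flagged, and logged rather
    than rejected). Buffer stems serve only as competitors downstream.
    """
    if dist < 0:
        raise DomainError("buffer dist must be >= 0")
    arr = _as_points(points)
    pts = shapely.points(arr)
    inside = shapely.covers(region.boundary, pts)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("add_buffer_flag: %d points outside the study region "
                       "(flagged as buffer)", n_out)
    d = shapely.distance(region.boundary.boundary, pts)
    return (~inside) | (d < dist)


def make_rectangular_partition(region: StudyRegion, nx: int, ny: int) -> FoldPartition:
    """Tile an axis-aligned rectangular region into nx*ny equal blocks.

    Fold ids run row-major from 1, starting at the (xmin, ymin) corner.
    Stands in for external block-CV generators; arbitrary user polygons go
    through :class:`FoldPartition` directly.
    """
    if nx < 1 or ny < 1:
        raise DomainError("nx and ny must be >= 1")
    xmin, ymin, xmax, ymax = region.boundary.bounds
    rect = box(xmin, ymin, xmax, ymax)
    if region.boundary.symmetric_difference(rect).area > 1e-9 * max(1.0, rect.area):
        raise DomainError(
            "make_rectangular_partition requires an axis-aligned rectangle; "
            "build a FoldPartition from your own polygons instead"
        )
    dx, dy = (xmax - xmin) / nx, (ymax - ymin) / ny
    blocks = []
    for iy in range(ny):
        for ix in range(nx):
            fid = iy * nx + ix + 1
            blocks.append(
                (fid, box(xmin + ix * dx, ymin + iy * dy,
                          xmin + (ix + 1) * dx, ymin + (iy + 1) * dy))
            )
    return FoldPartition(blocks=blocks, region=region)


def assign_folds(points, partition: FoldPartition, tol: float = 1e-9) -> np.ndarray:
    """Assign each point the fold_id of the block containing it.

    Points on a shared block edge get the lowest adjacent fold_id (blocks are
    scanned in increasing fold_id order). Points covered by no block are
    snapped to the nearest block within ``tol`` meters; beyond that an
    :class:`AssignmentError` lists them.
    """
    arr = _as_points(points)
    pts = shapely.points(arr)
    fold = np.zeros(len(arr), dtype=int)
    for fid, poly in partition.blocks:  # sorted ascending: lowest id wins ties
        unset = fold == 0
        if not unset.any():
            break
        hit = shapely.covers(poly, pts[unset])
        idx = np.flatnonzero(unset)[hit]
        fold[idx] = fid
    unset = fold == 0
    if unset.any():
        for i in np.flatnonzero(unset):
            dists = [(shapely.distance(poly, pts[i]), fid) for fid, poly in partition.blocks]
            dmin, fid = min(dists)
            if dmin <= tol:
                fold[i] = fid
        still = fold == 0
        if still.any():
            bad = arr[still][:10].tolist()
            raise AssignmentError(f"points outside every block beyond tolerance: {bad}")
    return fold


def fold_buffer_mask(
    points, partition: FoldPartition, test_fold: int, dist: float
) -> np.ndarray:
    """Mask of points excluded from TRAINING when ``test_fold`` is the test set.

    True for points not in the interior of the test block whose distance to
    the test block is <= ``dist``; points inside the test block are always
    False (they are the test set, not buffered training data).
    """
    if dist < 0:
        raise DomainError("fold-buffer dist must be >= 0")
    block = partition.fold_geometry(test_fold)
    arr = _as_points(points)
    pts = shapely.points(arr)
    interior = shapely.contains_properly(block, pts)
    near = shapely.distance(block, pts) <= dist
    return (~interior) & near
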