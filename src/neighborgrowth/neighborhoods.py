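"""Focal-vs-competitor neighborhood construction.

A *focal* stem is an interior (non-buffer) stem with a valid growth
measurement and at least one neighbor within the competitive radius
``comp_dist``. Its *competitors* are **all** other stems within that radius
— including buffer stems and stems of any CV fold; that is the whole point
of the buffer region, whose trees act only as competitors. Radius
comparisons use ``<=`` on exact squared distances, so a neighbor exactly at
``comp_dist`` is included regardless of sqrt rounding.

Self-exclusion is by stem id only: other stems of the same multi-stem tree
do count as competitors, since conspecific competition is part of the model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DomainError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompetitorEntry:
    """One competitor stem as seen from a focal stem."""

    comp_id: str
    dist: float          # meters to the focal stem, 0 < dist <= comp_dist
    comp_group: str      # species / grouping label
    comp_x: float        # explanatory value (e.g. basal area, m^2)


@dataclass
class FocalRecord:
    """A focal stem plus its neighborhood.

    Competitor attributes are stored as parallel arrays (ids, distances,
    integer group codes into the global ``comp_levels``, explanatory values);
    ``competitors`` materializes them as :class:`CompetitorEntry` objects.
    ``comp_totals[k]`` is the per-group sum of ``comp_x`` — the x^comp
    covariates of the growth model.
    """

    focal_id: str
    focal_group: str
    dbh: float           # cm, earlier census
    growth: float        # cm / yr (the response)
    gx: float
    gy: float
    fold_id: int
    comp_ids: np.ndarray
    comp_dists: np.ndarray
    comp_group_codes: np.ndarray   # int codes into FocalTable.comp_levels
    comp_x: np.ndarray
    comp_totals: np.ndarray        # length K
    comp_levels: tuple = field(repr=False, default=())

    @property
    def competitors(self) -> list[CompetitorEntry]:
        return [
            CompetitorEntry(str(i), float(d), self.comp_levels[g], float(x))
            for i, d, g, x in zip(
                self.comp_ids, self.comp_dists, self.comp_group_codes, self.comp_x
            )
        ]

    @property
    def n_competitors(self) -> int:
        return len(self.comp_ids)


@dataclass
class FocalTable:
    """The focal-vs-competitor table plus the global level sets.

    ``comp_levels`` (and ``focal_levels``) are fixed from the full growth
    table, not per neighborhood, so design matrices are consistent across CV
    folds and permutation replicates.
    """

    records: list[FocalRecord]
    focal_levels: tuple
    comp_levels: tuple
    comp_dist: float
    comp_x_var: str = "basal_area"
    grouping: str = "group"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def growth(self) -> np.ndarray:
        return np.array([r.growth for r in self.records], dtype=float)

    @property
    def points(self) -> np.ndarray:
        return np.array([[r.gx, r.gy] for r in self.records], dtype=float)

    @property
    def fold_ids(self) -> np.ndarray:
        return np.array([r.fold_id for r in self.records], dtype=int)

    def subset(self, mask) -> "FocalTable":
        recs = [r for r, m in zip(self.records, mask) if m]
        return replace(self, records=recs)

    # --- serialization -------------------------------------------------
    def to_exploded_frame(self) -> pd.DataFrame:
        """One row per focal x competitor pair (the unnested view)."""
        rows = []
        for r in self.records:
            for i, d, g, x in zip(r.comp_ids, r.comp_dists, r.comp_group_codes, r.comp_x):
                rows.append(
                    (r.focal_id, r.focal_group, r.dbh, r.growth, r.gx, r.gy,
                     r.fold_id, str(i), float(d), self.comp_levels[g], float(x))
                )
        return pd.DataFrame(
            rows,
            columns=["focal_id", "focal_group", "dbh", "growth", "gx", "gy",
                     "fold_id", "comp_id", "dist", "comp_group", "comp_x"],
        )

    def to_json(self) -> str:
        doc = {
            "comp_dist": self.comp_dist,
            "comp_x_var": self.comp_x_var,
            "grouping": self.grouping,
            "focal_levels": list(self.focal_levels),
            "comp_levels": list(self.comp_levels),
            "records": [
                {
                    "focal_id": r.focal_id,
                    "focal_group": r.focal_group,
                    "dbh": r.dbh,
                    "growth": r.growth,
                    "gx": r.gx,
                    "gy": r.gy,
                    "fold_id": int(r.fold_id),
                    "comp_ids": [str(i) for i in r.comp_ids],
                    "comp_dists": [float(d) for d in r.comp_dists],
                    "comp_groups": [self.comp_levels[g] for g in r.comp_group_codes],
                    "comp_x": [float(x) for x in r.comp_x],
                }
                for r in self.records
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "FocalTable":
        doc = json.loads(text)
        comp_levels = tuple(doc["comp_levels"])
        code = {g: k for k, g in enumerate(comp_levels)}
        records = []
        for r in doc["records"]:
            codes = np.array([code[g] for g in r["comp_groups"]], dtype=int)
            x = np.asarray(r["comp_x"], dtype=float)
            records.append(
                FocalRecord(
                    focal_id=r["focal_id"], focal_group=r["focal_group"],
                    dbh=float(r["dbh"]), growth=float(r["growth"]),
                    gx=float(r["gx"]), gy=float(r["gy"]), fold_id=int(r["fold_id"]),
                    comp_ids=np.array(r["comp_ids"], dtype=object),
                    comp_dists=np.asarray(r["comp_dists"], dtype=float),
                    comp_group_codes=codes, comp_x=x,
                    comp_totals=np.bincount(codes, weights=x, minlength=len(comp_levels)),
                    comp_levels=comp_levels,
                )
            )
        return cls(
            records=records,
            focal_levels=tuple(doc["focal_levels"]),
            comp_levels=comp_levels,
            comp_dist=float(doc["comp_dist"]),
            comp_x_var=doc["comp_x_var"],
            grouping=doc["grouping"],
        )


def _group_levels(series: pd.Series) -> tuple:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return tuple(str(c) for c in series.cat.categories)
    return tuple(sorted(series.astype(str).unique()))


def neighbor_pairs(coords: np.ndarray, comp_dist: float) -> set[tuple[int, int]]:
    """Index pairs (i < j) at Euclidean distance <= comp_dist.

    A k-d tree proposes candidates with a slightly inflated radius; the final
    decision compares exact squared distances, avoiding sqrt-rounding ties.
    """
    tree = cKDTree(coords)
    cand = tree.query_pairs(r=comp_dist * (1.0 + 1e-9))
    r2 = comp_dist * comp_dist
    out = set()
    for i, j in cand:
        d2 = (coords[i, 0] - coords[j, 0]) ** 2 + (coords[i, 1] - coords[j, 1]) ** 2
        if d2 <= r2:
            out.add((i, j) if i < j else (j, i))
    return out


def create_focal_vs_comp(
    growth: pd.DataFrame,
    comp_dist: float,
    comp_x_var: str = "basal_area",
    grouping: str = "group",
    id_col: str = "stem_id",
    buffer_col: str = "buffer",
    fold_col: str = "fold_id",
) -> FocalTable:
    """Build the focal-vs-competitor table from an annotated growth table.

    ``growth`` must carry the buffer flag, fold id, a grouping label column
    and the numeric competitor explanatory column ``comp_x_var``. Competitor
    entries are sorted by comp_id within each neighborhood for determinism.
    """
    if comp_dist <= 0:
        raise DomainError("comp_dist must be > 0")
    for col in (comp_x_var, grouping, id_col, buffer_col, fold_col, "growth",
                "dbh1", "gx", "gy"):
        if col not in growth.columns:
            raise SchemaError(f"growth table lacks required column {col!r}")
    if not np.issubdtype(np.asarray(growth[comp_x_var]).dtype, np.number):
        raise SchemaError(f"comp_x_var column {comp_x_var!r} must be numeric")

    levels = _group_levels(growth[grouping])
    code_of = {g: k for k, g in enumerate(levels)}
    n = len(growth)
    coords = growth[["gx", "gy"]].to_numpy(float)
    ids = growth[id_col].astype(str).to_numpy()
    group_codes = np.array([code_of[str(g)] for g in growth[grouping]], dtype=int)
    comp_x = growth[comp_x_var].to_numpy(float)
    is_buffer = growth[buffer_col].to_numpy(bool)
    fold_ids = growth[fold_col].to_numpy(int)
    dbh1 = growth["dbh1"].to_numpy(float)
    resp = growth["growth"].to_numpy(float)

    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in neighbor_pairs(coords, comp_dist):
        neighbors[i].append(j)
        neighbors[j].append(i)

    K = len(levels)
    records = []
    for i in range(n):
        if is_buffer[i] or not np.isfinite(resp[i]) or not neighbors[i]:
            continue
        nbr = np.asarray(neighbors[i], dtype=int)
        order = np.argsort(ids[nbr], kind="stable")
        nbr = nbr[order]
        d = np.hypot(coords[nbr, 0] - coords[i, 0], coords[nbr, 1] - coords[i, 1])
        codes = group_codes[nbr]
        x = comp_x[nbr]
        records.append(
            FocalRecord(
                focal_id=str(ids[i]),
                focal_group=levels[group_codes[i]],
                dbh=float(dbh1[i]),
                growth=float(resp[i]),
                gx=float(coords[i, 0]),
                gy=float(coords[i, 1]),
                fold_id=int(fold_ids[i]),
                comp_ids=ids[nbr].astype(object),
                comp_dists=d,
                comp_group_codes=codes,
                comp_x=x,
                comp_totals=np.bincount(codes, weights=x, minlength=K),
                comp_levels=levels,
            )
        )
    if not records:
        warnings.warn("create_focal_vs_comp: empty focal set", stacklevel=2)
    logger.info("create_focal_vs_comp: %d focal records from %d growth records",
                len(records), n)
    return FocalTable(
        records=records,
        focal_levels=levels,
        comp_levels=levels,
        comp_dist=float(comp_dist),
        comp_x_var=comp_x_var,
        grouping=grouping,
    )


def aggregate_competition(record: FocalRecord, group_levels) -> np.ndarray:
    """Per-group sums of the competitor explanatory value, zeros for absent groups."""
    group_levels = tuple(group_levels)
    code = {g: k for k, g in enumerate(group_levels)}
    out = np.zeros(len(group_levels))
    for entry in record.competitors:
        if entry.comp_group not in code:
            raise IntegrityError(f"unknown competitor group {entry.comp_group!r}")
        out[code[entry.comp_group]] += entry.comp_x
    return out
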