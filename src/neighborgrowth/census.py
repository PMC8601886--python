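"""Census ingestion and per-stem growth.

Reads ForestGEO-style stem-census tables, computes annualized DBH growth
between two censuses, joins species attributes, and provides the basal-area
explanatory variable.

A census is represented as a :class:`pandas.DataFrame` with the canonical
columns

    stem_id (str), tree_id (str), sp (str), gx (m), gy (m),
    dbh (cm, NaN = not measured), date (datetime), codes (str, ';'-joined),
    alive (bool)

and a growth table adds ``dbh1``, ``dbh2``, ``growth`` (cm/yr) and carries
any extra numeric columns (basal area, biomass, ...) the user derives.
"""

from __future__ import annotations

import logging
import math
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, IntegrityError, JoinError, SchemaError

logger = logging.getLogger(__name__)

#: logical field -> description; these must be mapped by the schema
REQUIRED_FIELDS = ("stem_id", "sp", "gx", "gy", "dbh", "date")
OPTIONAL_FIELDS = ("tree_id", "codes", "status")

#: days per Julian year, the denominator used to annualize growth
DAYS_PER_YEAR = 365.25


def read_census(
    source: str | IO[str],
    schema: Mapping[str, str] | None = None,
    dbh_unit: str = "cm",
    date_format: str | None = None,
    alive_values: tuple[str, ...] = ("A", "alive", "AB", "AS"),
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read one stem census from delimited text into the canonical layout.

    Parameters
    ----------
    source
        Path or open text stream of a delimited table.
    schema
        Map of logical field name -> physical column name. Identity for any
        field not listed. Required logical fields: stem_id, sp, gx, gy, dbh,
        date. Optional: tree_id, codes, status.
    dbh_unit
        Unit DBH is recorded in, ``"mm"`` or ``"cm"``. Output is always cm
        (ForestGEO sites differ; e.g. some record millimeters).
    date_format
        Optional explicit ``strptime`` format for the date column;
        ISO-8601 is parsed by default.
    alive_values
        Status values interpreted as alive when a status column is mapped.
        Without a status column every stem is taken as alive.

    Returns
    -------
    DataFrame in the canonical census layout, DBH in centimeters. Rows with
    unparseable coordinates are dropped and counted in the log.
    """
    if dbh_unit not in ("mm", "cm"):
        raise DomainError(f"dbh_unit must be 'mm' or 'cm', got {dbh_unit!r}")
    schema = dict(schema or {})
    raw = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=True,
                      comment="#")

    colmap = {f: schema.get(f, f) for f in REQUIRED_FIELDS + OPTIONAL_FIELDS}
    missing = [f for f in REQUIRED_FIELDS if colmap[f] not in raw.columns]
    if missing:
        raise SchemaError(
            "census table is missing required field(s): "
            + ", ".join(f"{f} (column {colmap[f]!r})" for f in missing)
        )

    out = pd.DataFrame(
        {
            "stem_id": raw[colmap["stem_id"]].astype(str),
            "sp": raw[colmap["sp"]].astype(str),
            "gx": pd.to_numeric(raw[colmap["gx"]], errors="coerce"),
            "gy": pd.to_numeric(raw[colmap["gy"]], errors="coerce"),
            "dbh": pd.to_numeric(raw[colmap["dbh"]], errors="coerce"),
            "date": pd.to_datetime(
                raw[colmap["date"]], format=date_format, errors="coerce"
            ),
        }
    )
    out["tree_id"] = (
        raw[colmap["tree_id"]].astype(str)
        if colmap["tree_id"] in raw.columns
        else out["stem_id"]
    )
    out["codes"] = (
        raw[colmap["codes"]].fillna("").astype(str)
        if colmap["codes"] in raw.columns
        else ""
    )
    if colmap["status"] in raw.columns:
        out["alive"] = raw[colmap["status"]].isin(alive_values).to_numpy()
    else:
        out["alive"] = True

    if dbh_unit == "mm":
        out["dbh"] = out["dbh"] / 10.0

    bad_coords = out["gx"].isna() | out["gy"].isna() | ~np.isfinite(
        out["gx"].fillna(np.inf)
    ) | ~np.isfinite(out["gy"].fillna(np.inf))
    if bad_coords.any():
        logger.warning("read_census: rejected %d rows with unparseable coordinates",
                       int(bad_coords.sum()))
        out = out.loc[~bad_coords]

    dup = out["stem_id"].duplicated()
    if dup.any():
        dupes = out.loc[dup, "stem_id"].unique()[:10]
        raise IntegrityError(f"duplicate stem_id values in census: {list(dupes)}")
    return out.reset_index(drop=True)


def _has_resprout_code(codes: str) -> bool:
    # ForestGEO codes are ';'- or ','-separated tokens; "R" marks a resprout
    tokens = {t.strip() for t in str(codes).replace(",", ";").split(";")}
    return "R" in tokens


def compute_growth(
    census1: pd.DataFrame,
    census2: pd.DataFrame,
    id_field: str = "stem_id",
    nominal_interval: float | None = None,
    growth_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Annualized DBH growth for stems alive and measured at both censuses.

    Joins the two censuses on ``id_field``, keeps stems that are alive with a
    measured DBH in both, drops stems whose later-census codes contain the
    resprout code ``"R"``, and computes

        growth = (dbh2 - dbh1) / dt,   dt in years

    where dt comes from each stem's own pair of census dates
    (days / 365.25), falling back to ``nominal_interval`` (years) when either
    date is missing. Species is coerced to a categorical whose level set is
    the union of species seen in either census, so downstream design matrices
    are stable.

    Negative growth is kept by default (shrinkage and measurement error are
    real); pass ``growth_bounds=(lo, hi)`` to drop records outside a range.
    """
    for df, name in ((census1, "census1"), (census2, "census2")):
        if id_field not in df.columns:
            raise SchemaError(f"{name} lacks the id field {id_field!r}")

    sp_levels = sorted(set(census1["sp"].astype(str)) | set(census2["sp"].astype(str)))

    merged = census1.merge(
        census2, on=id_field, how="inner", suffixes=("1", "2"), validate="one_to_one"
    )
    n_matched = len(merged)

    dead = ~(merged["alive1"].astype(bool) & merged["alive2"].astype(bool))
    resprout = merged["codes2"].map(_has_resprout_code).astype(bool)
    missing_dbh = merged["dbh1"].isna() | merged["dbh2"].isna()
    keep = ~(dead | resprout | missing_dbh)
    logger.info(
        "compute_growth: %d matched, excluded %d dead, %d resprouts, %d missing dbh",
        n_matched, int(dead.sum()), int((resprout & ~dead).sum()),
        int((missing_dbh & ~dead & ~resprout).sum()),
    )
    kept = merged.loc[keep].copy()

    if nominal_interval is not None and nominal_interval <= 0:
        raise DomainError("nominal_interval must be positive (years)")

    have_dates = kept["date1"].notna() & kept["date2"].notna()
    dt = pd.Series(np.nan, index=kept.index, dtype=float)
    dt[have_dates] = (
        (kept.loc[have_dates, "date2"] - kept.loc[have_dates, "date1"]).dt.days
        / DAYS_PER_YEAR
    )
    if not have_dates.all():
        if nominal_interval is None:
            raise DataError(
                "stems with missing census dates and no nominal_interval fallback: "
                f"{list(kept.loc[~have_dates, id_field].head(10))}"
            )
        dt[~have_dates] = float(nominal_interval)

    nonpos = dt <= 0
    if nonpos.any():
        raise DataError(
            "non-positive inter-census interval for stem(s): "
            f"{list(kept.loc[nonpos, id_field].head(10))}"
        )

    out = pd.DataFrame(
        {
            id_field: kept[id_field].to_numpy(),
            "sp": pd.Categorical(kept["sp1"].astype(str), categories=sp_levels),
            "gx": kept["gx1"].to_numpy(float),
            "gy": kept["gy1"].to_numpy(float),
            "dbh1": kept["dbh1"].to_numpy(float),
            "dbh2": kept["dbh2"].to_numpy(float),
            "growth": (kept["dbh2"] - kept["dbh1"]).to_numpy(float) / dt.to_numpy(),
            "date1": kept["date1"].to_numpy(),
            "date2": kept["date2"].to_numpy(),
        }
    )
    if growth_bounds is not None:
        lo, hi = growth_bounds
        inside = (out["growth"] >= lo) & (out["growth"] <= hi)
        logger.info("compute_growth: dropped %d records outside growth bounds",
                    int((~inside).sum()))
        out = out.loc[inside]
    return out.reset_index(drop=True)


def basal_area(dbh):
    """Stem basal area in m^2 from DBH in cm: pi * (dbh/2)^2 / 10000."""
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr < 0):
        raise DomainError("dbh must be non-negative")
    out = math.pi * (arr / 2.0) ** 2 / 10000.0
    return float(out) if np.isscalar(dbh) or arr.ndim == 0 else out


def join_species(
    growth: pd.DataFrame,
    species: pd.DataFrame,
    grouping: str = "sp",
    fallback: str | None = None,
) -> pd.DataFrame:
    """Attach the categorical group label used as focal/competitor index.

    ``grouping="sp"`` uses the species code itself; any other value names a
    column of the species table (family, canopy position, ...). Species codes
    absent from the table raise unless a ``fallback`` group is configured.
    The result carries a ``group`` categorical column.
    """
    out = growth.copy()
    if grouping == "sp":
        out["group"] = pd.Categorical(out["sp"].astype(str))
        return out

    if "sp" not in species.columns:
        raise SchemaError("species table lacks an 'sp' column")
    if grouping not in species.columns:
        raise SchemaError(f"species table lacks the grouping column {grouping!r}")
    if species["sp"].duplicated().any():
        raise IntegrityError("species table has duplicate sp keys")

    lookup = species.set_index(species["sp"].astype(str))[grouping]
    labels = out["sp"].astype(str).map(lookup)
    unmatched = labels.isna()
    if unmatched.any():
        if fallback is None:
            codes = sorted(out.loc[unmatched, "sp"].astype(str).unique())
            raise JoinError(f"species codes missing from species table: {codes}")
        labels = labels.fillna(fallback)
    out["group"] = pd.Categorical(labels.astype(str))
    return out
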