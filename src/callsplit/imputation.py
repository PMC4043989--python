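"""Monte Carlo imputation of uncertain catch locations and dates.

Historical catch records come with five levels of location uncertainty:

* ``certain`` — exact position and date reported; used as is.
* ``inferred`` — position recovered with high confidence upstream (land
  stations, averages of adjacent same-day catches); used without
  uncertainty.
* ``soviet`` — original whaling logs pin the catch inside a small
  rectangle; locations are drawn uniformly within it.
* ``iwc_region`` — only the broad management rectangle is known; locations
  are drawn with replacement from reported catch positions of blue, fin,
  sei and common minke whales in the same region (the donor pool), which
  bakes the spatial pattern of whaling effort into the draws.
* ``partial`` — the expedition reported positions for other catches; the
  location is drawn from same-expedition-year donor positions in the
  catch's month.

Missing months are drawn from the month distribution of donor catches,
restricted to the expedition's operating period (any month if unknown).
One pass over the catch table produces a single realization of the
conflated catch series; repeated passes propagate catch uncertainty into
the final split.

The module also implements the allocation of unspecified-species catches
to blue whales from expedition-year species proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MonthWeights",
    "CatchRealization",
    "allocate_unspecified",
    "month_weights",
    "draw_realization",
    "infer_from_neighbours",
]

CATEGORIES = ("iwc_region", "partial", "inferred", "soviet", "certain")


# ---------------------------------------------------------------------------
# species allocation


def allocate_unspecified(expedition_year_table: pd.DataFrame,
                         japan_early_rate: float = 0.164,
                         max_window: int = 3) -> pd.Series:
    """Estimate how many unspecified-species catches were blue whales.

    ``expedition_year_table`` needs columns ``expedition_id, year, blue,
    other, unspecified`` and an optional boolean ``japan_early`` flag for
    coastal-Japan rows in the early no-species-reporting era. Three rules,
    in order of precedence per row:

    1. rows flagged ``japan_early`` use the fixed ``japan_early_rate``
       (default 16.4%, the share of blue whales in the first two years
       with species-level reporting);
    2. rows with species-identified catches in the same expedition-year
       use that year's blue proportion;
    3. rows with none use the blue proportion of adjacent years for the
       same expedition, widening the window year by year up to
       ``max_window``; if nothing is found the allocation is 0 with a
       warning.

    Returns the added blue-whale counts per row, rounded to the nearest
    integer (ties to even).
    """
    t = expedition_year_table
    for col in ("expedition_id", "year", "blue", "other", "unspecified"):
        if col not in t.columns:
            raise ValueError(f"missing column {col!r}")
    if (t[["blue", "other", "unspecified"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    japan = t["japan_early"] if "japan_early" in t.columns else \
        pd.Series(False, index=t.index)

    added = np.zeros(len(t))
    by_exp = {k: g for k, g in t.groupby("expedition_id")}
    for pos, (idx, row) in enumerate(t.iterrows()):
        unspec = row["unspecified"]
        if unspec == 0:
            continue
        if japan.loc[idx]:
            added[pos] = unspec * japan_early_rate
            continue
        specified = row["blue"] + row["other"]
        if specified > 0:
            added[pos] = unspec * row["blue"] / specified
            continue
        g = by_exp[row["expedition_id"]]
        rate = None
        for w in range(1, max_window + 1):
            near = g[(g["year"] - row["year"]).abs().between(1, w)]
            tot = (near["blue"] + near["other"]).sum()
            if tot > 0:
                rate = near["blue"].sum() / tot
                break
        if rate is None:
            warnings.warn(
                f"no species-identified catches within +/-{max_window} years "
                f"for expedition {row['expedition_id']} year {row['year']}; "
                "allocating 0", stacklevel=2)
            rate = 0.0
        added[pos] = unspec * rate
    # nearest integer, ties to even
    return pd.Series(np.rint(added).astype(int), index=t.index, name="added_blue")


# ---------------------------------------------------------------------------
# month weights


@dataclass(frozen=True)
class MonthWeights:
    """Probability over months 1-12; zero outside the allowed set."""

    w: tuple

    def __post_init__(self):
        if len(self.w) != 12:
            raise ValueError("need 12 weights")
        if any(x < 0 for x in self.w):
            raise ValueError("weights must be non-negative")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(np.arange(1, 13), p=np.asarray(self.w)))


def month_weights(donors: pd.DataFrame,
                  allowed_months=None) -> MonthWeights:
    """Month distribution of donor catches, restricted and renormalized.

    Weights are proportional to donor counts per month within
    ``allowed_months`` (default: all 12). If no donor falls in an allowed
    month the weights are uniform over the allowed months.
    """
    if allowed_months is None:
        allowed = set(range(1, 13))
    else:
        allowed = {int(m) for m in allowed_months}
    if not allowed:
        raise ValueError("allowed_months is empty")
    if not allowed <= set(range(1, 13)):
        raise ValueError("months must be in 1..12")
    counts = np.zeros(12)
    if len(donors):
        vc = donors["month"].value_counts()
        for m, c in vc.items():
            counts[int(m) - 1] = c
    mask = np.zeros(12)
    for m in allowed:
        mask[m - 1] = 1.0
    w = counts * mask
    if w.sum() == 0:
        w = mask
    return MonthWeights(tuple(w / w.sum()))


# ---------------------------------------------------------------------------
# realizations


@dataclass
class CatchRealization:
    """One Monte Carlo draw of (lon, lat, month) for every catch."""

    table: pd.DataFrame  # catch_id, lon_east, lat, month
    realization_seed: int

    def __len__(self):
        return len(self.table)


def _operating_months(row) -> set[int]:
    s, e = row.get("op_month_start"), row.get("op_month_end")
    if pd.isna(s) or pd.isna(e):
        return set(range(1, 13))
    s, e = int(s), int(e)
    if s <= e:
        return set(range(s, e + 1))
    return set(range(s, 13)) | set(range(1, e + 1))  # wraps over new year


def draw_realization(catches: pd.DataFrame, donors: pd.DataFrame,
                     rng_seed: int) -> CatchRealization:
    """Sample one realization of the conflated catch series.

    Known fields are never modified; only missing months and unconstrained
    coordinates are drawn. Partial records sample their month first (if
    missing), then a location conditional on it. Draws are vectorized per
    category so a realization of thousands of catches costs milliseconds.
    """
    rng = np.random.default_rng(rng_seed)
    n = len(catches)
    bad = ~catches["category"].isin(CATEGORIES)
    if bad.any():
        first = catches.loc[bad].iloc[0]
        raise ValueError(
            f"unknown category {first['category']!r} for {first['catch_id']}")

    cat = catches["category"].to_numpy()
    out_lon = np.full(n, np.nan)
    out_lat = np.full(n, np.nan)
    out_month = np.full(n, -1, dtype=int)

    # months first: keep known, draw the rest per operating-period group
    known = catches["month"].notna().to_numpy()
    out_month[known] = catches.loc[known, "month"].to_numpy(dtype=int)
    if (~known).any():
        missing = catches.loc[~known]
        s = missing.get("op_month_start", pd.Series(np.nan, missing.index))
        e = missing.get("op_month_end", pd.Series(np.nan, missing.index))
        keys_arr = np.where(s.isna() | e.isna(), 0,
                            s.fillna(0).astype(int) * 100
                            + e.fillna(0).astype(int))
        donor_stub = donors if len(donors) else pd.DataFrame(columns=["month"])
        drawn = np.empty(len(missing), dtype=int)
        for key in np.unique(keys_arr):
            sel = keys_arr == key
            if key == 0:
                allowed = range(1, 13)
            else:
                ks, ke = divmod(int(key), 100)
                allowed = (range(ks, ke + 1) if ks <= ke else
                           list(range(ks, 13)) + list(range(1, ke + 1)))
            w = np.asarray(month_weights(donor_stub, allowed).w)
            drawn[sel] = rng.choice(np.arange(1, 13), int(sel.sum()), p=w)
        out_month[~known] = drawn

    # fixed coordinates
    fixed = np.isin(cat, ("certain", "inferred"))
    if fixed.any():
        lon = catches.loc[fixed, "lon_east"].to_numpy(dtype=float)
        lat = catches.loc[fixed, "lat"].to_numpy(dtype=float)
        if np.isnan(lon).any() or np.isnan(lat).any():
            miss = catches.loc[fixed].loc[
                catches.loc[fixed, "lon_east"].isna()
                | catches.loc[fixed, "lat"].isna(), "catch_id"]
            raise ValueError(f"records require coordinates: "
                             f"{miss.head().tolist()}")
        out_lon[fixed], out_lat[fixed] = lon, lat

    # soviet rectangles: uniform draws
    sov = cat == "soviet"
    if sov.any():
        sub = catches.loc[sov]
        rect = sub[["rect_lat_min", "rect_lat_max",
                    "rect_lon_min", "rect_lon_max"]].to_numpy(dtype=float)
        if np.isnan(rect).any():
            miss = sub.loc[np.isnan(rect).any(axis=1), "catch_id"]
            raise ValueError(f"soviet records missing rects: "
                             f"{miss.head().tolist()}")
        out_lat[sov] = rng.uniform(rect[:, 0], rect[:, 1])
        out_lon[sov] = rng.uniform(rect[:, 2], rect[:, 3])

    donors_xy = donors[["lon_east", "lat"]].to_numpy() if len(donors) else None

    # IWC regions: resample donor positions within the region
    reg = cat == "iwc_region"
    if reg.any():
        by_region = ({k: donors_xy[v]
                      for k, v in donors.groupby("region_id").indices.items()}
                     if len(donors) else {})
        rids = catches.loc[reg, "region_id"].to_numpy()
        idx = np.flatnonzero(reg)
        for rid in pd.unique(rids):
            pool = by_region.get(rid)
            if pool is None or len(pool) == 0:
                bad_ids = catches.loc[reg].loc[rids == rid, "catch_id"]
                raise ValueError(f"no donors in region {rid!r} for catches "
                                 f"{bad_ids.head().tolist()}")
            sel = idx[rids == rid]
            j = rng.integers(0, len(pool), sel.size)
            out_lon[sel] = pool[j, 0]
            out_lat[sel] = pool[j, 1]

    # partial: same-expedition-year donors in the realized month
    par = cat == "partial"
    if par.any():
        by_exp_year = ({k: donors_xy[v] for k, v in donors.groupby(
                            ["expedition_id", "year", "month"]).indices.items()}
                       if len(donors) else {})
        by_exp_year_all = ({k: donors_xy[v] for k, v in donors.groupby(
                                ["expedition_id", "year"]).indices.items()}
                           if len(donors) else {})
        idx = np.flatnonzero(par)
        sub = catches.loc[par]
        groups = pd.DataFrame({
            "pos": idx,
            "expedition_id": sub["expedition_id"].to_numpy(),
            "year": sub["year"].to_numpy(),
            "month": out_month[idx],
            "catch_id": sub["catch_id"].to_numpy(),
        })
        fallbacks = []
        for (eid, yr, mo), g in groups.groupby(
                ["expedition_id", "year", "month"], sort=False):
            pool = by_exp_year.get((eid, yr, mo))
            if pool is None or len(pool) == 0:
                pool = by_exp_year_all.get((eid, yr))
                if pool is None or len(pool) == 0:
                    raise ValueError(
                        f"{g['catch_id'].iloc[0]}: no donors for expedition "
                        f"{eid!r} year {yr}")
                fallbacks.append((eid, yr, mo))
            pos = g["pos"].to_numpy()
            j = rng.integers(0, len(pool), pos.size)
            out_lon[pos] = pool[j, 0]
            out_lat[pos] = pool[j, 1]
        if fallbacks:
            warnings.warn(
                f"no expedition donors in the realized month for "
                f"{len(fallbacks)} expedition-month groups; fell back to "
                "all months", stacklevel=2)

    table = pd.DataFrame({
        "catch_id": catches["catch_id"].to_numpy(),
        "lon_east": out_lon, "lat": out_lat, "month": out_month,
    })
    return CatchRealization(table, int(rng_seed))


def infer_from_neighbours(neighbours: pd.DataFrame) -> tuple[float, float]:
    """Average the positions of adjacent same-day catches of other species.

    Data-preparation helper for the ``inferred`` category: the caller
    supplies the explicit neighbour positions and stores the mean location
    on the record, which is then treated as exact.
    """
    if len(neighbours) == 0:
        raise ValueError("no neighbour locations supplied")
    return (float(neighbours["lon_east"].mean()),
            float(neighbours["lat"].mean()))
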