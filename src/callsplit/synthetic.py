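"""Synthetic worlds with two acoustically distinct whale populations.

The generator builds a small North Pacific with known truth: two smooth
occurrence surfaces (an eastern population whose song is heard mostly in
the eastern basin, a western one mirrored), beta-binomial over-dispersion
in hourly call presence, whaling catches placed by an effort surface that
overlaps both populations, the five location-uncertainty categories found
in historical catch databases, donor pools of reported catch positions of
similar species (blue, fin, sei, common minke) for imputation, and
population-specific body lengths. Every downstream stage — occurrence model
fitting, catch imputation, the population split and the length validation —
can therefore be tested against known truth.

Defaults describe a plausible study system: ~60-70 station-months per call
type at 720 analyzed hours each, over-dispersion sigma around 0.3-0.5,
catches spanning 1905-1971 with category proportions 41/9/5/2/43
(region / partial / inferred / soviet / certain), and mean lengths of
22.0 m (eastern) vs 22.91 m (western) with 1 m spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "OccurrenceSurface",
    "DispersionField",
    "WorldConfig",
    "StationSpec",
    "default_stations",
    "DEFAULT_CATEGORY_MIX",
    "simulate_acoustic",
    "simulate_catches",
    "simulate_lengths",
    "simulate_world",
]

LON_RANGE = (140.0, 260.0)  # degrees east, dateline-contiguous
LAT_RANGE = (20.0, 62.0)

#: category proportions mirroring the historical record:
#: (iwc_region, partial, inferred, soviet, certain)
DEFAULT_CATEGORY_MIX = (0.41, 0.09, 0.05, 0.02, 0.43)

CATEGORIES = ("iwc_region", "partial", "inferred", "soviet", "certain")

#: fraction of records in each category whose month is unknown, mirroring
#: the uncertain-month shares of the historical uncertainty table
MONTH_MISSING = {"iwc_region": 1.0, "partial": 0.48, "inferred": 1.0,
                 "soviet": 0.48, "certain": 0.0}


def _scale_lon(lon):
    return (np.asarray(lon, dtype=float) - 200.0) / 40.0


def _scale_lat(lat):
    return (np.asarray(lat, dtype=float) - 41.0) / 14.0


@dataclass(frozen=True)
class OccurrenceSurface:
    """Logistic-quadratic occurrence surface with additive month offsets.

    ``mu(lon, lat, month) = expit(b0 + b1*x + b2*y + b3*x^2 + b4*y^2
    + b5*x*y + month_offsets[month-1])`` with x, y centred/scaled lon and
    lat. Smooth and low-order, hence representable by the fitting module's
    spline bases.
    """

    b0: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    month_offsets: tuple = tuple(np.zeros(12))

    def mu(self, lon, lat, month):
        x, y = _scale_lon(lon), _scale_lat(lat)
        month = np.asarray(month, dtype=int)
        off = np.asarray(self.month_offsets)[month - 1]
        eta = (self.b0 + self.b1 * x + self.b2 * y + self.b3 * x ** 2
               + self.b4 * y ** 2 + self.b5 * x * y + off)
        return expit(eta)


@dataclass(frozen=True)
class DispersionField:
    """Over-dispersion surface, log-quadratic in space with month offsets.

    ``sigma = floor + exp(c0 + c1*x + c2*y + c3*x^2 + c4*y^2 +
    month_offsets[m-1])`` with the same centred/scaled coordinates as the
    occurrence surfaces; ``floor`` guarantees a minimum dispersion level
    everywhere. The default is a constant sigma = 0.4.
    """

    c0: float = np.log(0.4)
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0
    month_offsets: tuple = tuple(np.zeros(12))
    floor: float = 0.0

    def sigma(self, lon, lat, month):
        x, y = _scale_lon(lon), _scale_lat(lat)
        month = np.asarray(month, dtype=int)
        off = np.asarray(self.month_offsets)[month - 1]
        return self.floor + np.exp(self.c0 + self.c1 * x + self.c2 * y
                                   + self.c3 * x ** 2 + self.c4 * y ** 2
                                   + off)


def _summer_offsets(amplitude=0.9, peak_month=8):
    m = np.arange(1, 13)
    return tuple(amplitude * np.cos(2 * np.pi * (m - peak_month) / 12.0))


@dataclass(frozen=True)
class WorldConfig:
    """Ground truth for one synthetic study system."""

    surface_east: OccurrenceSurface = OccurrenceSurface(
        -1.3, 1.5, 0.25, -0.45, -0.5, 0.0, _summer_offsets(0.9, 8))
    surface_west: OccurrenceSurface = OccurrenceSurface(
        -1.3, -1.5, 0.25, -0.45, -0.5, 0.0, _summer_offsets(0.9, 7))
    dispersion_field: DispersionField = DispersionField()
    length_mean_east: float = 22.0
    length_mean_west: float = 22.91
    length_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")

    def p_east(self, lon, lat, month, lam=1.0):
        """True probability a whale at (lon, lat, month) is eastern."""
        de = self.surface_east.mu(lon, lat, month)
        dw = self.surface_west.mu(lon, lat, month)
        return de / (de + lam * dw)


@dataclass(frozen=True)
class StationSpec:
    """One hydrophone: location, active months, analyzed hours per month."""

    station_id: str
    lon_east: float
    lat: float
    months_active: tuple
    hours_per_month: int = 720

    def __post_init__(self):
        if len(self.months_active) == 0:
            raise ValueError(f"station {self.station_id}: months_active empty")
        if self.hours_per_month < 1:
            raise ValueError(
                f"station {self.station_id}: hours_per_month must be >= 1")
        if any(m < 1 or m > 12 for m in self.months_active):
            raise ValueError(f"station {self.station_id}: months must be 1-12")


def default_stations(n_stations: int = 32, seed: int = 0,
                     hours_per_month: int = 720) -> list[StationSpec]:
    """Hydrophone network over the basin with realistic gaps.

    Stations are laid out on a jittered grid covering the study region;
    each is active for a contiguous run of months (some year-round, some
    seasonal) to emulate deployments of different durations and hardware
    outages.
    """
    rng = np.random.default_rng(seed)
    cols = int(np.ceil(np.sqrt(n_stations * 2)))
    rows = int(np.ceil(n_stations / cols))
    lon_g = np.linspace(LON_RANGE[0] + 5, LON_RANGE[1] - 5, cols)
    lat_g = np.linspace(LAT_RANGE[0] + 4, LAT_RANGE[1] - 4, rows)
    specs = []
    i = 0
    for la in lat_g:
        for lo in lon_g:
            if i >= n_stations:
                break
            lon = float(np.clip(lo + rng.normal(0, 3), *LON_RANGE))
            lat = float(np.clip(la + rng.normal(0, 2), *LAT_RANGE))
            n_active = int(rng.integers(6, 13))
            start = int(rng.integers(1, 13))
            months = tuple(sorted(((start - 1 + j) % 12) + 1
                                  for j in range(n_active)))
            specs.append(StationSpec(f"H{i:02d}", lon, lat, months,
                                     hours_per_month))
            i += 1
    return specs


def simulate_acoustic(world: WorldConfig, stations: list[StationSpec],
                      rng_seed: int) -> pd.DataFrame:
    """Draw hourly-presence counts for every station-month and call type.

    ``k_hours ~ BetaBinomial(n_hours, mu, sigma)`` sampled as a beta
    mixing probability followed by a binomial draw; ``sigma = 0`` falls
    back to a pure binomial.
    """
    if len(stations) == 0:
        raise ValueError("no stations supplied")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for spec in stations:
        for month in spec.months_active:
            for call_type, surf in (("east", world.surface_east),
                                    ("west", world.surface_west)):
                mu = float(surf.mu(spec.lon_east, spec.lat, month))
                sig = float(world.dispersion_field.sigma(
                    spec.lon_east, spec.lat, month))
                if not 0.0 < mu < 1.0 or not np.isfinite(mu):
                    raise ValueError(
                        f"invalid mu={mu} at (lon={spec.lon_east}, "
                        f"lat={spec.lat}, month={month})")
                if sig < 0 or not np.isfinite(sig):
                    raise ValueError(
                        f"invalid sigma={sig} at (lon={spec.lon_east}, "
                        f"lat={spec.lat}, month={month})")
                n = spec.hours_per_month
                if sig == 0.0:
                    k = int(rng.binomial(n, mu))
                else:
                    p = rng.beta(mu / sig, (1.0 - mu) / sig)
                    k = int(rng.binomial(n, p))
                rows.append((spec.station_id, spec.lon_east, spec.lat,
                             month, n, k, call_type))
    return pd.DataFrame(rows, columns=["station_id", "lon_east", "lat",
                                       "month", "n_hours", "k_hours",
                                       "call_type"])


# ---------------------------------------------------------------------------
# catches


def _region_grid():
    """Fixed partition of the basin into 6 large management rectangles."""
    lon_edges = np.linspace(*LON_RANGE, 4)
    lat_edges = np.linspace(*LAT_RANGE, 3)
    regions = {}
    rid = 0
    for i in range(3):
        for j in range(2):
            regions[f"R{rid}"] = (lat_edges[j], lat_edges[j + 1],
                                  lon_edges[i], lon_edges[i + 1])
            rid += 1
    return regions


def region_of(lon, lat):
    for rid, (la0, la1, lo0, lo1) in _region_grid().items():
        if la0 <= lat <= la1 and lo0 <= lon <= lo1:
            return rid
    return "R0"


def _effort_weights(world: WorldConfig, lon, lat, month):
    """Whaling effort: mixture of the two density surfaces plus a coastal
    bias bump along the northern rim (shore stations, Aleutian grounds)."""
    de = world.surface_east.mu(lon, lat, month)
    dw = world.surface_west.mu(lon, lat, month)
    coastal = 0.15 * np.exp(-0.5 * ((np.asarray(lat) - 55.0) / 6.0) ** 2)
    return de + dw + coastal


def _year_weights(years):
    # two eras of intense whaling: early century and the 1950s-60s
    y = np.asarray(years, dtype=float)
    early = np.exp(-0.5 * ((y - 1915) / 8.0) ** 2)
    late = 0.7 * np.exp(-0.5 * ((y - 1960) / 5.0) ** 2)
    w = early + late + 0.02
    return w / w.sum()


def simulate_catches(world: WorldConfig, n_catches: int,
                     category_mix: tuple = DEFAULT_CATEGORY_MIX,
                     rng_seed: int = 0):
    """Generate catches with known population labels plus a donor pool.

    Returns ``(catches, donors)``. The catches table carries both the
    observable view (fields masked according to the uncertainty category)
    and the ``true_*`` ground-truth columns used only for evaluation.
    Every constrained catch's true location is inside its constraint
    payload and has at least one matching donor, so imputation can recover
    truth in expectation.
    """
    mix = np.asarray(category_mix, dtype=float)
    if mix.size != 5:
        raise ValueError("category_mix must have 5 entries")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"category_mix sums to {mix.sum()}, expected 1")
    rng = np.random.default_rng(rng_seed)

    cols = ["catch_id", "year", "month", "lon_east", "lat", "category",
            "region_id", "rect_lat_min", "rect_lat_max", "rect_lon_min",
            "rect_lon_max", "expedition_id", "op_month_start", "op_month_end",
            "sex", "length_m", "maturity", "true_population",
            "true_lon_east", "true_lat", "true_month"]
    donor_cols = ["species", "lon_east", "lat", "month", "year",
                  "expedition_id", "region_id"]
    if n_catches == 0:
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=donor_cols)

    # place catches by rejection sampling from the effort surface
    lon = np.empty(n_catches)
    lat = np.empty(n_catches)
    month = np.empty(n_catches, dtype=int)
    filled = 0
    wmax = 2.2  # effort weight upper bound (mu sums <= 2 plus bias)
    month_season = np.exp(0.8 * np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12))
    month_season /= month_season.sum()
    while filled < n_catches:
        m = n_catches - filled
        clon = rng.uniform(*LON_RANGE, 2 * m + 16)
        clat = rng.uniform(*LAT_RANGE, 2 * m + 16)
        cmon = rng.choice(np.arange(1, 13), 2 * m + 16, p=month_season)
        w = _effort_weights(world, clon, clat, cmon)
        keep = rng.uniform(0, wmax, clon.size) < w
        take = min(int(keep.sum()), m)
        sel = np.flatnonzero(keep)[:take]
        lon[filled:filled + take] = clon[sel]
        lat[filled:filled + take] = clat[sel]
        month[filled:filled + take] = cmon[sel]
        filled += take

    years_all = np.arange(1905, 1972)
    year = rng.choice(years_all, n_catches, p=_year_weights(years_all))
    p_east = world.p_east(lon, lat, month)
    is_east = rng.uniform(size=n_catches) < p_east
    sex = rng.choice(["F", "M"], n_catches)
    category = rng.choice(CATEGORIES, n_catches, p=mix)

    # expeditions: groups of catches sharing a year and operating window
    n_exp = max(1, n_catches // 25)
    exp_ids = rng.integers(0, n_exp, n_catches)
    op_start = np.minimum(month, rng.integers(3, 6, n_catches))
    op_end = np.maximum(month, rng.integers(9, 12, n_catches))

    records = []
    donors = []
    regions = _region_grid()
    for i in range(n_catches):
        cat = category[i]
        rid = region_of(lon[i], lat[i])
        month_missing = rng.uniform() < MONTH_MISSING[cat]
        rec = {
            "catch_id": f"C{i:05d}", "year": int(year[i]),
            "month": np.nan if month_missing else int(month[i]),
            "lon_east": np.nan, "lat": np.nan, "category": cat,
            "region_id": "", "rect_lat_min": np.nan, "rect_lat_max": np.nan,
            "rect_lon_min": np.nan, "rect_lon_max": np.nan,
            "expedition_id": f"E{exp_ids[i]:03d}",
            "op_month_start": int(op_start[i]), "op_month_end": int(op_end[i]),
            "sex": sex[i], "length_m": np.nan, "maturity": "unknown",
            "true_population": "east" if is_east[i] else "west",
            "true_lon_east": float(lon[i]), "true_lat": float(lat[i]),
            "true_month": int(month[i]),
        }
        if cat in ("certain", "inferred"):
            rec["lon_east"], rec["lat"] = float(lon[i]), float(lat[i])
            if cat == "certain":
                rec["month"] = int(month[i])
        elif cat == "soviet":
            dla = rng.uniform(1.5, 4.0, 2)
            dlo = rng.uniform(3.0, 8.0, 2)
            rec["rect_lat_min"] = max(LAT_RANGE[0], lat[i] - dla[0])
            rec["rect_lat_max"] = min(LAT_RANGE[1], lat[i] + dla[1])
            rec["rect_lon_min"] = max(LON_RANGE[0], lon[i] - dlo[0])
            rec["rect_lon_max"] = min(LON_RANGE[1], lon[i] + dlo[1])
        elif cat == "iwc_region":
            rec["region_id"] = rid
            donors.append(("blue", float(lon[i]), float(lat[i]),
                           int(month[i]), int(year[i]),
                           rec["expedition_id"], rid))
        elif cat == "partial":
            # same-expedition donors: the true position in the true month,
            # plus nearby reported catches through the operating season
            donors.append((rng.choice(["fin", "sei", "minke"]),
                           float(lon[i]), float(lat[i]), int(month[i]),
                           int(year[i]), rec["expedition_id"], rid))
            for mo in range(int(op_start[i]), int(op_end[i]) + 1):
                jlon = float(np.clip(lon[i] + rng.normal(0, 2.5), *LON_RANGE))
                jlat = float(np.clip(lat[i] + rng.normal(0, 1.5), *LAT_RANGE))
                donors.append((rng.choice(["blue", "fin", "sei", "minke"]),
                               jlon, jlat, mo, int(year[i]),
                               rec["expedition_id"], region_of(jlon, jlat)))
        records.append(rec)

    # background donor pool: reported positions of the four species, drawn
    # from the same effort surface so month weights reflect the seasons
    n_bg = max(50, n_catches)
    bg_lon = rng.uniform(*LON_RANGE, n_bg)
    bg_lat = rng.uniform(*LAT_RANGE, n_bg)
    bg_mon = rng.choice(np.arange(1, 13), n_bg, p=month_season)
    bg_w = _effort_weights(world, bg_lon, bg_lat, bg_mon)
    bg_keep = rng.uniform(0, wmax, n_bg) < bg_w
    for lo, la, mo in zip(bg_lon[bg_keep], bg_lat[bg_keep], bg_mon[bg_keep]):
        donors.append((rng.choice(["blue", "fin", "sei", "minke"]),
                       float(lo), float(la), int(mo),
                       int(rng.choice(years_all)), f"E{rng.integers(n_exp):03d}",
                       region_of(lo, la)))

    catches = pd.DataFrame.from_records(records, columns=cols)
    donor_df = pd.DataFrame(donors, columns=donor_cols)
    return catches, donor_df


def simulate_lengths(catches: pd.DataFrame, world: WorldConfig,
                     rng_seed: int) -> pd.DataFrame:
    """Fill ``length_m`` with population-specific normal lengths.

    Mature females are flagged by a 21 m threshold, the working proxy for
    the sexual-maturity length of female blue whales.
    """
    if world.length_sd < 0:
        raise ValueError("length_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    out = catches.copy()
    means = np.where(out["true_population"] == "east",
                     world.length_mean_east, world.length_mean_west)
    out["length_m"] = rng.normal(means, world.length_sd)
    out["maturity"] = np.where(out["length_m"] >= 21.0, "mature", "immature")
    return out


def simulate_world(n_catches: int = 1000, n_stations: int = 32,
                   seed: int = 0, world: WorldConfig | None = None,
                   category_mix: tuple = DEFAULT_CATEGORY_MIX,
                   hours_per_month: int = 720):
    """One-call convenience: world, acoustic data, catches, donors.

    Returns ``(world, acoustic, catches, donors)`` with lengths filled.
    Seeds for the three stages are derived from ``seed`` so identical seeds
    reproduce identical tables.
    """
    world = world or WorldConfig(seed=seed)
    ss = np.random.SeedSequence(seed).spawn(3)
    stations = default_stations(n_stations, seed=seed,
                                hours_per_month=hours_per_month)
    acoustic = simulate_acoustic(world, stations,
                                 int(ss[0].generate_state(1)[0] % 2**31))
    catches, donors = simulate_catches(
        world, n_catches, category_mix,
        int(ss[1].generate_state(1)[0] % 2**31))
    catches = simulate_lengths(catches, world,
                               int(ss[2].generate_state(1)[0] % 2**31))
    return world, acoustic, catches, donors
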