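"""Synthetic landscapes, grazing schedules and GPS telemetry.

Everything downstream of this module is exercised against data generated
here from a *known* selection model, so parameter recovery and validation
statistics can be judged against ground truth.

The stated world mirrors a herded-flock conservation-grazing study in a
central-European forest-heath mosaic: 2-hourly GPS fixes from about a dozen
animals over about three years, three grazing sites (roughly 62, 22 and
102 ha) split into a northern and a southern group, one short (~25 day)
December grazing term in the first year and long June-September/October
terms in later years.

Deer are simulated as an independent weighted point process: each fix is
drawn from the animal's home polygon with probability proportional to
``exp(eta(x))``, where ``eta`` is the linear predictor of the true selection
model in that fix's treatment/time-of-day context.  This matches the
exchangeability assumption of the downstream use-availability design; serial
movement correlation is deliberately out of scope.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage, special

from .covariates import Scaler, distance_to_sites
from .design import CONT_BASIS, BINARY, FACTORS, INTERCEPT, ModelSpec, build_design
from .raster import Raster
from .solar import classify_times
from .temporal import GrazingSchedule, assign_site_group, assign_treatment, flag_biological_periods

FIX_INTERVAL = dt.timedelta(hours=2)

_COL_RE = re.compile(r"^([a-z0-9]+)(\[([a-z]+)\])?$")


def _column_to_term(name: str) -> str:
    """Map a design *column* name (levels in brackets) to its term."""
    parts = []
    for comp in name.split(":"):
        m = _COL_RE.match(comp)
        if not m:
            raise ValueError(f"unparseable coefficient name {name!r}")
        base, _, level = m.groups()
        if base in FACTORS:
            if level is None or level not in FACTORS[base][1]:
                raise ValueError(f"bad factor level in coefficient {name!r}")
        elif base in CONT_BASIS or base in BINARY:
            if level is not None:
                raise ValueError(f"coefficient {name!r}: {base} takes no level")
        else:
            raise ValueError(f"unknown coefficient component {base!r}")
        parts.append(base)
    return ":".join(parts)


@dataclass
class TrueModel:
    """Ground-truth selection model for the simulator.

    Parameters
    ----------
    coefficients : dict
        Design *column* name -> coefficient, e.g. ``{"dist": -0.6,
        "dist:treatment[ongoing]": 0.55}``.  Names use the same vocabulary as
        the fitted design matrices; factor levels in brackets.
    re_sd : float
        SD of the zero-mean Gaussian animal-level intercept (default 0.5).
    scaling : Scaler
        Reference centring/scaling under which the coefficients are
        expressed (continuous covariates enter as (v - mean)/sd).
    """

    coefficients: dict
    re_sd: float = 0.5
    scaling: Scaler = field(default_factory=Scaler)

    def __post_init__(self) -> None:
        for name, val in self.coefficients.items():
            if name != INTERCEPT:
                _column_to_term(name)
            if not np.isfinite(val):
                raise ValueError(f"non-finite coefficient {name!r}")

    def terms(self) -> list[str]:
        seen: list[str] = []
        for name in self.coefficients:
            if name == INTERCEPT:
                continue
            t = _column_to_term(name)
            if t not in seen:
                seen.append(t)
        return seen

    def spec(self) -> ModelSpec:
        return ModelSpec(self.terms(), response="__none__", group="__none__")

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        """Fixed-effect linear predictor for rows carrying scaled covariates
        (``*_s`` columns) and context columns (treatment/tod/calving/rut)."""
        cols = [INTERCEPT] + [c for c in self.coefficients if c != INTERCEPT]
        X, _, _ = build_design(df, self.spec(), columns=cols)
        beta = np.array([self.coefficients.get(c, 0.0) for c in cols])
        return X.to_numpy(dtype=float) @ beta


# ---------------------------------------------------------------------------
# landscape


def generate_landscape(extent_m, cell_m: float, seed: int,
                       smoothness: float = 250.0) -> tuple[Raster, Raster]:
    """Co-registered tree-cover (%) and NDVI rasters from smoothed noise.

    Gaussian-smoothed white noise, min-max rescaled into the legal range of
    each variable ([0, 100] for cover; [-0.2, 0.9] for spring NDVI).
    ``smoothness`` is the smoothing SD in meters and controls spatial
    autocorrelation.  Identical seeds give identical rasters.
    """
    xmin, ymin, xmax, ymax = extent_m
    if cell_m <= 0:
        raise ValueError("cell size must be positive")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    w, h = xmax - xmin, ymax - ymin
    if w < cell_m or h < cell_m:
        raise ValueError("extent smaller than one cell")
    ncols, nrows = w / cell_m, h / cell_m
    if abs(ncols - round(ncols)) > 1e-9 or abs(nrows - round(nrows)) > 1e-9:
        raise ValueError("extent must divide into whole cells")
    ncols, nrows = int(round(ncols)), int(round(nrows))

    ss = np.random.SeedSequence(seed)
    ranges = {"cover": (0.0, 100.0), "ndvi": (-0.2, 0.9)}
    out = []
    for child, (lo, hi) in zip(ss.spawn(2), ranges.values()):
        rng = np.random.default_rng(child)
        noise = rng.standard_normal((nrows, ncols))
        smooth = ndimage.gaussian_filter(noise, sigma=smoothness / cell_m,
                                         mode="reflect")
        span = smooth.max() - smooth.min()
        scaled = lo + (smooth - smooth.min()) / span * (hi - lo)
        out.append(Raster(scaled, xmin, ymin, cell_m))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# schedules


def generate_schedule(sites: dict, years, seed: int,
                      winter_years=(2016,), site_groups: dict | None = None
                      ) -> GrazingSchedule:
    """Dated grazing intervals emulating a herded-flock rotation.

    ``sites`` maps site_id -> polygon.  Unless ``site_groups`` is given, the
    northernmost site forms the ``north`` group and the remainder ``south``.
    Years in ``winter_years`` get one short December term (25 days, a single
    group); other years get a long summer term starting in the first half of
    June and ending late September or late October, alternating between the
    two groups in blocks of three to six weeks.  Intervals within each group
    are non-overlapping.
    """
    if not sites:
        raise ValueError("need at least one site polygon")
    for sid, poly in sites.items():
        if poly is None or poly.is_empty or poly.area <= 0:
            raise ValueError(f"degenerate site polygon {sid!r}")
    if site_groups is None:
        north_id = max(sites, key=lambda s: sites[s].centroid.y)
        site_groups = {sid: ("north" if sid == north_id else "south")
                       for sid in sites}
    groups = sorted(set(site_groups.values()))
    rng = np.random.default_rng(seed)
    rows = []
    for year in sorted(years):
        if year in winter_years:
            start = dt.date(year, 12, 1) + dt.timedelta(days=int(rng.integers(0, 6)))
            group = groups[int(rng.integers(len(groups)))]
            site = _pick_site(rng, site_groups, group)
            rows.append((site, group, start, start + dt.timedelta(days=24)))
        else:
            start = dt.date(year, 6, 1) + dt.timedelta(days=int(rng.integers(0, 15)))
            end_month = int(rng.choice([9, 10]))
            end = dt.date(year, end_month, 30 if end_month == 9 else 31)
            gi = int(rng.integers(len(groups)))
            block_start = start
            while block_start <= end:
                # one consecutive period per site group before the flock
                # moves on: six to nine weeks, long enough that both the
                # early (days 1-21) and ongoing (days 22-42) windows exist
                block_len = int(rng.integers(42, 64))
                block_end = min(end, block_start + dt.timedelta(days=block_len - 1))
                group = groups[gi % len(groups)]
                site = _pick_site(rng, site_groups, group)
                rows.append((site, group, block_start, block_end))
                block_start = block_end + dt.timedelta(days=1)
                gi += 1
    intervals = pd.DataFrame(rows, columns=["site_id", "group", "start", "end"])
    schedule = GrazingSchedule(intervals, dict(sites), dict(site_groups))
    schedule.validate()
    return schedule


def _pick_site(rng, site_groups, group):
    members = sorted(s for s, g in site_groups.items() if g == group)
    return members[int(rng.integers(len(members)))]


# ---------------------------------------------------------------------------
# telemetry


def simulate_deer(true_model: TrueModel, home_polygon, n_fixes: int,
                  schedule: GrazingSchedule, sex: str, seed: int, *,
                  cover: Raster, ndvi: Raster, animal_id: str = "deer01",
                  start: dt.datetime | None = None,
                  lat: float = 51.88, lon: float = 12.98,
                  utc_offset_hours: float = 1.0,
                  group: str | None = None) -> pd.DataFrame:
    """Simulate a 2-hourly GPS track from the true selection model.

    Each fix is an independent draw from the raster cells whose centers fall
    inside ``home_polygon``, weighted by ``exp(eta)`` with ``eta`` the true
    model's linear predictor in that fix's treatment/time-of-day context,
    then jittered uniformly within the chosen cell.  The animal-level
    intercept is drawn once from N(0, re_sd) -- it cancels from the
    within-home-range location distribution but is drawn to keep the
    generative story complete and the RNG stream well-defined.

    Returns a relocation table: animal_id, timestamp (UTC), x, y, sex,
    quality_ok.
    """
    if n_fixes < 1:
        raise ValueError("n_fixes must be >= 1")
    if not cover.same_grid(ndvi):
        raise ValueError("cover and NDVI rasters are not co-registered")
    rng = np.random.default_rng(seed)
    _animal_intercept = rng.normal(0.0, true_model.re_sd)

    # candidate cells: centers inside the home polygon
    cx, cy = cover.center_grid()
    inside = shapely.contains_xy(home_polygon, cx, cy)
    if not inside.any():
        raise ValueError("home polygon contains no raster cell centers")
    cx, cy = cx[inside], cy[inside]
    cells = pd.DataFrame({"x": cx, "y": cy})
    cells["cover"] = cover.extract(cx, cy)
    cells["ndvi"] = ndvi.extract(cx, cy)
    cells["dist_site"] = distance_to_sites(cells, schedule.site_polygons)
    for var in ("cover", "ndvi", "dist_site"):
        if var in true_model.scaling.means:
            cells[var + "_s"] = true_model.scaling.transform(cells[var], var)
        else:
            cells[var + "_s"] = cells[var]

    if group is None:
        group = assign_site_group(home_polygon, schedule)
        if group is None:
            raise ValueError("home polygon overlaps no grazing-site group")

    if start is None:
        first_year = int(min(schedule.intervals["start"]).year)
        start = dt.datetime(first_year, 1, 1, tzinfo=dt.timezone.utc)
    timestamps = pd.Series(
        pd.date_range(start, periods=n_fixes, freq=FIX_INTERVAL, tz="UTC")
    )
    treatment = assign_treatment(timestamps, schedule, group, utc_offset_hours)
    tod = pd.Series(classify_times(timestamps, lat, lon))
    flags = flag_biological_periods(timestamps, [sex] * n_fixes)

    ctx = pd.DataFrame({
        "treatment": treatment.values, "tod": tod.values,
        "calving": flags["calving"].astype(float).values,
        "rut": flags["rut"].astype(float).values,
    })
    x_out = np.empty(n_fixes)
    y_out = np.empty(n_fixes)
    half = cover.cell / 2.0
    for key, idx in ctx.groupby(["treatment", "tod", "calving", "rut"],
                                sort=True).groups.items():
        cdf = cells.copy()
        cdf["treatment"], cdf["tod"], cdf["calving"], cdf["rut"] = key
        eta = true_model.linear_predictor(cdf)
        if not np.any(np.isfinite(eta)):
            raise ValueError("all selection weights are zero/undefined")
        w = np.exp(eta - np.max(eta))
        p = w / w.sum()
        pick = rng.choice(len(cells), size=len(idx), p=p)
        jit = rng.uniform(-half, half, size=(len(idx), 2))
        x_out[idx] = cx[pick] + jit[:, 0]
        y_out[idx] = cy[pick] + jit[:, 1]

    return pd.DataFrame({
        "animal_id": animal_id, "timestamp": timestamps,
        "x": x_out, "y": y_out, "sex": sex, "quality_ok": True,
    })


def simulate_use_series(use_params: dict, schedule: GrazingSchedule,
                        timestamps, seed: int, *, group: str,
                        sex: str = "female", lat: float = 51.88,
                        lon: float = 12.98, utc_offset_hours: float = 1.0,
                        offset: float = 0.0) -> np.ndarray:
    """Independent Bernoulli in/out-of-site indicators for given timestamps.

    ``use_params`` is a coefficient map over the use-model vocabulary and
    must contain an ``(Intercept)``; the success probability at each
    timestamp is the inverse logit of the linear predictor in that
    timestamp's treatment/time-of-day context plus ``offset`` (e.g. an
    animal-level intercept).
    """
    if INTERCEPT not in use_params:
        raise ValueError("use_params must contain an (Intercept)")
    ts = pd.Series(pd.to_datetime(pd.Series(timestamps)))
    treatment = assign_treatment(ts, schedule, group, utc_offset_hours)
    if (treatment == "unassigned").any():
        raise ValueError("timestamp(s) outside schedule treatment coverage")
    tod = classify_times(ts, lat, lon)
    flags = flag_biological_periods(ts, [sex] * len(ts))
    df = pd.DataFrame({
        "treatment": treatment.values, "tod": tod,
        "calving": flags["calving"].astype(float).values,
        "rut": flags["rut"].astype(float).values,
        "cover_s": 0.0, "ndvi_s": 0.0, "dist_site_s": 0.0,
    })
    tm = TrueModel({k: v for k, v in use_params.items() if k != INTERCEPT},
                   re_sd=0.0)
    eta = tm.linear_predictor(df) + use_params[INTERCEPT] + offset
    p = special.expit(eta)
    rng = np.random.default_rng(seed)
    return (rng.random(len(p)) < p).astype(int)
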