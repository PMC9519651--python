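"""End-to-end pipeline: simulate -> label -> home range -> fit -> validate.

The pipeline is a set of composable library functions returning plain
objects; :func:`run_pipeline` chains them according to a YAML-style config
mapping and writes every artifact (CSV/GeoJSON/ASCII-grid/JSON manifest)
into a run directory.  Any stage failure is re-raised with the stage name.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from . import io as gio
from .covariates import Scaler, add_scaled_columns, attach_covariates, point_in_sites
from .design import INTERCEPT, ModelSpec, build_design
from .glmm import MixedLogit, aic_select, check_collinearity, r2_nakagawa
from .homerange import isopleth_polygon, kde_surface, sample_available
from .raster import Raster
from .rsf import build_rsf, predict_map, score_distance_profile
from .solar import classify_times
from .synthetic import TrueModel, generate_landscape, generate_schedule, simulate_deer
from .temporal import (GrazingSchedule, assign_season, assign_site_group,
                       assign_treatment, exclude_hunt_windows,
                       flag_biological_periods)
from .validation import kfold_cv, recovery_report

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# stated world defaults


def default_sim_config() -> dict:
    """The default simulated study system.

    An 8 x 8 km forest-heath mosaic at 20 m resolution; three grazing sites
    of about 62, 22 and 102 ha (one northern, two southern); grazing in
    2016-2018 with a short December term in 2016 and long summer terms
    otherwise; 12 collared animals (three quarters female) recording a fix
    every 2 hours for three years.
    """
    return {
        "extent": [0.0, 0.0, 10000.0, 12000.0],
        "cell_m": 20.0,
        "smoothness_m": 300.0,
        "years": [2016, 2017, 2018],
        "winter_years": [2016],
        # rectangles xmin, ymin, xmax, ymax; areas ~62 / 22 / 102 ha
        "sites": {
            "north": [4200.0, 8200.0, 5000.0, 8975.0],
            "south_small": [3800.0, 3800.0, 4270.0, 4270.0],
            "south_big": [4900.0, 2600.0, 5920.0, 3600.0],
        },
        "site_groups": {"north": "north", "south_small": "south",
                        "south_big": "south"},
        "n_animals": 12,
        "n_fixes": 13140,  # 3 years of 2-hourly fixes
        "female_fraction": 0.75,
        # generative support: a generous box around the home-range center;
        # the selection surface itself (distance decay) confines the animal,
        # so the realised home range has soft edges like a real one and the
        # kernel home range lies inside the true support
        "home_halfwidth_m": 3000.0,
        "home_jitter_m": 400.0,
        # distance enters the true model in fixed units of 600 m centred at
        # 900 m, so one coefficient unit spans a home range
        "dist_reference": {"mean": 900.0, "sd": 600.0},
        "true_model": {
            "re_sd": 0.5,
            "coefficients": {
                "cover": 0.4, "cover2": -0.3, "ndvi": 0.5,
                "dist": -0.6, "dist2": -0.5,
                "dist:treatment[early]": 0.3,
                "dist:treatment[ongoing]": 0.55,
                "dist:treatment[after]": 0.45,
            },
        },
    }


def default_analysis_config() -> dict:
    return {
        "ratio": 16,
        "bandwidth": "reference",
        "kde_cell_m": 20.0,
        "isopleth_level": 0.99,
        "alpha": 0.05,
        "quad_points": 15,
        "use_model": {
            "base_terms": ["treatment", "tod", "treatment:tod"],
            "optional_terms": ["rut", "calving"],
        },
        "rsf_candidates": {
            "full": ["cover", "cover2", "ndvi", "dist", "dist2",
                     "treatment", "dist:treatment"],
            "no_interaction": ["cover", "cover2", "ndvi", "dist", "dist2",
                               "treatment"],
        },
        "cv": {"k": 5, "n_bins": 10},
    }


def default_reference() -> dict:
    return {"lat": 51.88, "lon": 12.98, "utc_offset_hours": 1.0}


# ---------------------------------------------------------------------------
# stage: simulate


def simulate_world(sim_cfg: dict | None = None, seed: int = 0,
                   reference: dict | None = None) -> dict:
    """Generate landscape, schedule and telemetry from the true model.

    Returns a dict with cover/ndvi rasters, the schedule, the relocation
    table, the TrueModel (reference scaling filled in from the landscape)
    and per-animal metadata.
    """
    cfg = {**default_sim_config(), **(sim_cfg or {})}
    ref = {**default_reference(), **(reference or {})}
    ss = np.random.SeedSequence(seed)
    s_land, s_sched, s_animals, s_deer = (int(c.generate_state(1)[0] % (2**31))
                                          for c in ss.spawn(4))

    cover, ndvi = generate_landscape(cfg["extent"], cfg["cell_m"], s_land,
                                     cfg["smoothness_m"])
    sites = {sid: box(*bounds) for sid, bounds in cfg["sites"].items()}
    schedule = generate_schedule(sites, cfg["years"], s_sched,
                                 winter_years=tuple(cfg["winter_years"]),
                                 site_groups=cfg["site_groups"])

    # reference scaling: landscape-wide stats for the fields, fixed units
    # for distance (so the distance gradient spans one home range)
    scaling = Scaler(
        means={"cover": float(np.nanmean(cover.values)),
               "ndvi": float(np.nanmean(ndvi.values)),
               "dist_site": float(cfg["dist_reference"]["mean"])},
        sds={"cover": float(np.nanstd(cover.values, ddof=1)),
             "ndvi": float(np.nanstd(ndvi.values, ddof=1)),
             "dist_site": float(cfg["dist_reference"]["sd"])},
    )
    tm_cfg = cfg["true_model"]
    true_model = TrueModel(dict(tm_cfg["coefficients"]),
                           re_sd=float(tm_cfg.get("re_sd", 0.5)),
                           scaling=scaling)

    rng = np.random.default_rng(s_animals)
    n = int(cfg["n_animals"])
    n_female = int(round(cfg["female_fraction"] * n))
    sexes = ["female"] * n_female + ["male"] * (n - n_female)
    group_names = sorted(set(cfg["site_groups"].values()))
    site_by_group = {
        g: shapely.union_all([sites[s] for s, gg in cfg["site_groups"].items()
                              if gg == g])
        for g in group_names
    }
    animals = []
    xmin, ymin, xmax, ymax = cfg["extent"]
    hw = float(cfg["home_halfwidth_m"])
    jit = float(cfg["home_jitter_m"])
    for i in range(n):
        group = group_names[i % len(group_names)]
        c = site_by_group[group].centroid
        # home-range center jittered around the group's sites, kept in extent
        hx = float(np.clip(c.x + rng.uniform(-jit, jit), xmin + hw, xmax - hw))
        hy = float(np.clip(c.y + rng.uniform(-jit, jit), ymin + hw, ymax - hw))
        animals.append({"animal_id": f"deer{i + 1:02d}", "sex": sexes[i],
                        "group": group,
                        "home_polygon": box(hx - hw, hy - hw, hx + hw, hy + hw)})

    deer_seeds = np.random.SeedSequence(s_deer).spawn(n)
    start = dt.datetime(int(min(cfg["years"])), 1, 1, tzinfo=dt.timezone.utc)
    tracks = []
    for meta, child in zip(animals, deer_seeds):
        tracks.append(simulate_deer(
            true_model, meta["home_polygon"], int(cfg["n_fixes"]), schedule,
            meta["sex"], int(child.generate_state(1)[0] % (2**31)),
            cover=cover, ndvi=ndvi, animal_id=meta["animal_id"], start=start,
            lat=ref["lat"], lon=ref["lon"],
            utc_offset_hours=ref["utc_offset_hours"], group=meta["group"]))
    relocations = pd.concat(tracks, ignore_index=True)
    return {"cover": cover, "ndvi": ndvi, "sites": sites,
            "schedule": schedule, "relocations": relocations,
            "true_model": true_model, "animals": animals, "config": cfg}


# ---------------------------------------------------------------------------
# stage: prepare (label, home ranges, availability, covariates)


def prepare_data(relocations: pd.DataFrame, schedule: GrazingSchedule,
                 cover: Raster, ndvi: Raster, analysis_cfg: dict | None = None,
                 reference: dict | None = None, hunt_dates=(), seed: int = 0
                 ) -> dict:
    """Label fixes, build home ranges, sample availability, attach covariates.

    Returns a dict with the labelled used table, per-animal isopleths, the
    per-season RSF datasets (used + available, scaled) with their scalers,
    and per-stage record counts.
    """
    cfg = {**default_analysis_config(), **(analysis_cfg or {})}
    ref = {**default_reference(), **(reference or {})}
    counts = {"fixes_in": int(len(relocations))}

    df = relocations.copy()
    if "quality_ok" in df:
        df = df.loc[df["quality_ok"].astype(bool)].copy()
    counts["fixes_quality_ok"] = int(len(df))
    df = exclude_hunt_windows(df, hunt_dates, ref["utc_offset_hours"])
    counts["fixes_after_hunt_exclusion"] = int(len(df))

    # home ranges from ALL of an animal's fixes, independent of labelling
    isopleths, groups = {}, {}
    for animal, sub in df.groupby("animal_id", sort=True):
        surface = kde_surface(sub, bandwidth=cfg["bandwidth"],
                              cell_m=cfg["kde_cell_m"])
        iso = isopleth_polygon(surface, cfg["isopleth_level"])
        isopleths[animal] = iso
        groups[animal] = assign_site_group(iso.polygons, schedule)
    dropped = [a for a, g in groups.items() if g is None]
    if dropped:
        logger.warning("dropping %d animal(s) with no site overlap: %s",
                       len(dropped), dropped)
        df = df.loc[~df["animal_id"].isin(dropped)].copy()
    counts["animals"] = int(df["animal_id"].nunique())

    # temporal labels
    parts = []
    for animal, sub in df.groupby("animal_id", sort=True):
        sub = sub.copy()
        sub["treatment"] = assign_treatment(
            sub["timestamp"], schedule, groups[animal],
            ref["utc_offset_hours"]).to_numpy()
        parts.append(sub)
    df = pd.concat(parts, ignore_index=True)
    df["tod"] = classify_times(df["timestamp"], ref["lat"], ref["lon"])
    flags = flag_biological_periods(df["timestamp"], df["sex"])
    df["calving"] = flags["calving"].astype(float)
    df["rut"] = flags["rut"].astype(float)
    df["season"] = assign_season(df["timestamp"]).to_numpy()
    df["in_site"] = point_in_sites(df, schedule.site_polygons)

    labelled = df.loc[(df["treatment"] != "unassigned")
                      & (df["season"] != "excluded")].reset_index(drop=True)
    counts["fixes_labelled"] = int(len(labelled))
    counts["per_treatment"] = labelled["treatment"].value_counts().to_dict()

    # per-season RSF datasets: used + available, covariates, scaling
    rng = np.random.default_rng(seed)
    seasonal = {}
    for season in ("summer", "winter"):
        season_used = labelled.loc[labelled["season"] == season].copy()
        if season_used.empty:
            continue
        season_used["response"] = 1
        blocks = []
        n_outside = 0
        for animal, sub in season_used.groupby("animal_id", sort=True):
            # the use-availability contrast is defined over the availability
            # domain: used fixes outside the animal's own home-range
            # isopleth (about 1% by construction) are dropped
            inside = shapely.covers(
                isopleths[animal].polygons,
                shapely.points(sub["x"].to_numpy(), sub["y"].to_numpy()))
            n_outside += int((~inside).sum())
            sub = sub.loc[inside].reset_index(drop=True)
            sub["pair_id"] = np.arange(len(sub))
            avail = sample_available(
                isopleths[animal], sub, int(cfg["ratio"]),
                seed=int(rng.integers(2**31)),
                carry_cols=("animal_id", "timestamp", "sex", "treatment",
                            "tod", "season", "calving", "rut"))
            blocks.extend([sub, avail])
        data = pd.concat(blocks, ignore_index=True)
        data = attach_covariates(data, cover, ndvi, schedule.site_polygons)
        data = data.dropna(subset=["cover", "ndvi"]).reset_index(drop=True)
        scaler = Scaler.fit(data, ("cover", "ndvi", "dist_site"))
        data = add_scaled_columns(data, scaler)
        seasonal[season] = {"data": data, "scaler": scaler}
        counts[f"n_{season}"] = int(len(data))
        counts[f"used_outside_homerange_{season}"] = n_outside

    return {"labelled": labelled, "isopleths": isopleths, "groups": groups,
            "seasonal": seasonal, "counts": counts, "config": cfg}


# ---------------------------------------------------------------------------
# stage: fit


def fit_use_models(prepared: dict, quad_points: int | None = None) -> dict:
    """Seasonal in/out-of-site use models with AIC candidate selection."""
    cfg = prepared["config"]
    qp = int(quad_points or cfg["quad_points"])
    out = {}
    for season, bundle in prepared["seasonal"].items():
        used = bundle["data"].loc[bundle["data"]["response"] == 1].copy()
        used["use"] = used["in_site"].astype(float)
        if used["use"].nunique() < 2 or used["animal_id"].nunique() < 2:
            logger.warning("season %s: degenerate use response; skipped", season)
            continue
        base = list(cfg["use_model"]["base_terms"])
        optional = [t for t in cfg["use_model"]["optional_terms"]
                    if season == "summer"]
        candidates, names = [], []
        for mask in range(2 ** len(optional)):
            terms = base + [t for i, t in enumerate(optional) if mask >> i & 1]
            spec = ModelSpec(terms, response="use", group="animal_id")
            X, y, g = build_design(used, spec)
            X = _drop_void_columns(X)
            fit = MixedLogit(y, X, g).fit(quad_points=qp)
            candidates.append(fit)
            names.append("+".join(terms))
        if len(candidates) > 1:
            winner, table, decisive = aic_select(candidates, names)
        else:
            winner, table, decisive = candidates[0], None, True
        r2m, r2c = r2_nakagawa(winner)
        out[season] = {"fit": winner, "aic_table": table, "decisive": decisive,
                       "r2_marginal": r2m, "r2_conditional": r2c}
    return out


def _drop_void_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Drop non-varying design columns (e.g. a factor level absent from --
    or omnipresent in -- a seasonal subset, which would alias the
    intercept)."""
    def varies(c):
        v = X[c].to_numpy()
        return bool(np.any(v != v[0]))

    keep = [c for c in X.columns if c == INTERCEPT or varies(c)]
    term_map = X.attrs.get("term_map")
    X2 = X[keep]
    if term_map is not None:
        X2.attrs["term_map"] = {t: [c for c in cols if c in keep]
                                for t, cols in term_map.items()}
    return X2


def fit_rsf_models(prepared: dict, quad_points: int | None = None) -> dict:
    """Seasonal use-availability fits, AIC selection, RSF construction."""
    cfg = prepared["config"]
    qp = int(quad_points or cfg["quad_points"])
    out = {}
    for season, bundle in prepared["seasonal"].items():
        data, scaler = bundle["data"], bundle["scaler"]
        candidates, names, specs = [], [], []
        for name, terms in cfg["rsf_candidates"].items():
            spec = ModelSpec(list(terms), response="response",
                             group="animal_id")
            X, y, g = build_design(data, spec)
            X = _drop_void_columns(X)
            fit = MixedLogit(y, X, g).fit(quad_points=qp)
            candidates.append(fit)
            names.append(name)
            specs.append(spec)
        if len(candidates) > 1:
            winner, table, decisive = aic_select(candidates, names)
        else:
            winner, table, decisive = candidates[0], None, True
        spec = specs[candidates.index(winner)]
        corr, gvif = check_collinearity(
            winner.model.exog, winner.model.exog.attrs.get("term_map"))
        r2m, r2c = r2_nakagawa(winner)
        model = build_rsf(winner, scaler, alpha=float(cfg["alpha"]))
        out[season] = {"fit": winner, "spec": spec, "rsf": model,
                       "aic_table": table, "decisive": decisive,
                       "gvif": gvif, "r2_marginal": r2m, "r2_conditional": r2c}
    return out


def validate_rsf(prepared: dict, rsf_fits: dict, seed: int = 0,
                 quad_points: int | None = None) -> pd.DataFrame:
    """Five-fold random and animal-blocked cross-validation per season."""
    cfg = prepared["config"]
    qp = int(quad_points or cfg["quad_points"])
    tables = []
    for season, bundle in prepared["seasonal"].items():
        if season not in rsf_fits:
            continue
        data = bundle["data"]
        spec = rsf_fits[season]["spec"]
        for blocking in ("random", "by_animal"):
            try:
                t = kfold_cv(data, spec, k=int(cfg["cv"]["k"]),
                             blocking=blocking,
                             n_bins=int(cfg["cv"]["n_bins"]), seed=seed,
                             quad_points=qp)
            except ValueError as exc:
                logger.warning("CV skipped (%s, %s): %s", season, blocking,
                               exc)
                continue
            t["season"] = season
            tables.append(t)
    if not tables:
        raise ValueError("cross-validation infeasible for every season")
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: dict | str, out_dir=None) -> Path:
    """Execute the full pipeline from a config mapping (or YAML path).

    Writes relocations, schedules, coefficient tables, CV reports, scenario
    maps and a manifest into the run directory, which is returned.
    """
    if isinstance(config, (str, Path)):
        config = gio.load_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "grazerange_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "started": dt.datetime.now(dt.timezone.utc)
                .isoformat(), "stages": {}}
    ref = {**default_reference(), **config.get("reference", {})}

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = "ok"
        return result

    if "simulate" in config or "paths" not in config:
        world = stage("simulate", simulate_world, config.get("simulate"),
                      seed, ref)
        cover, ndvi = world["cover"], world["ndvi"]
        schedule = world["schedule"]
        relocations = world["relocations"]
        gio.write_relocations(relocations, out / "relocations.csv")
        schedule.to_csv(out / "schedule.csv")
        gio.write_sites_geojson(schedule.site_polygons, schedule.site_groups,
                                out / "sites.geojson")
        cover.write_ascii(out / "cover.asc")
        ndvi.write_ascii(out / "ndvi.asc")
        hunt_dates = ()
    else:
        def _read_inputs():
            paths = config["paths"]
            for key in ("relocations", "cover", "ndvi", "sites", "schedule"):
                if key not in paths:
                    raise KeyError(f"config paths missing key {key!r}")
            relocations = gio.read_relocations(paths["relocations"])
            cover = Raster.read_ascii(paths["cover"])
            ndvi = Raster.read_ascii(paths["ndvi"])
            sites, groups_ = gio.read_sites_geojson(paths["sites"])
            schedule = GrazingSchedule.from_csv(paths["schedule"], sites,
                                                groups_)
            hunts = (gio.read_hunt_dates(paths["hunts"])
                     if paths.get("hunts") else ())
            return relocations, cover, ndvi, schedule, hunts

        relocations, cover, ndvi, schedule, hunt_dates = stage(
            "read-inputs", _read_inputs)
        world = None

    prepared = stage("prepare", prepare_data, relocations, schedule, cover,
                     ndvi, config.get("analysis"), ref, hunt_dates, seed)
    manifest["counts"] = prepared["counts"]
    for animal, iso in prepared["isopleths"].items():
        gio.write_geojson_geometry(
            iso.polygons, out / f"homerange_{animal}.geojson",
            {"animal_id": animal, "level": iso.level,
             "contained_mass": iso.contained_mass})

    use_fits = stage("fit-use", fit_use_models, prepared)
    for season, res in use_fits.items():
        res["fit"].to_frame().to_csv(out / f"use_model_{season}.csv")
        manifest["stages"][f"use_model_{season}"] = {
            "aic": res["fit"].aic, "decisive": bool(res["decisive"]),
            "r2_marginal": res["r2_marginal"],
            "r2_conditional": res["r2_conditional"],
            "re_sd": res["fit"].re_sd}

    rsf_fits = stage("fit-rsf", fit_rsf_models, prepared)
    for season, res in rsf_fits.items():
        res["fit"].to_frame().to_csv(out / f"rsf_model_{season}.csv")
        res["rsf"].coefficients.to_csv(out / f"rsf_coefficients_{season}.csv",
                                       header=["estimate"])
        manifest["stages"][f"rsf_{season}"] = {
            "aic": res["fit"].aic, "decisive": bool(res["decisive"]),
            "n_retained": int(len(res["rsf"].coefficients)),
            "r2_marginal": res["r2_marginal"],
            "r2_conditional": res["r2_conditional"],
            "re_sd": res["fit"].re_sd}

    cv = stage("validate", validate_rsf, prepared, rsf_fits, seed)
    cv.to_csv(out / "cv_report.csv", index=False)
    manifest["cv_mean_rho"] = {
        f"{season}/{blocking}": float(sub["rho"].mean())
        for (season, blocking), sub in cv.groupby(["season", "blocking"])}

    scenarios = config.get("scenarios", {
        "before_day": {"treatment": "before", "tod": "day"},
        "ongoing_day": {"treatment": "ongoing", "tod": "day"},
    })
    for season, res in rsf_fits.items():
        profiles = score_distance_profile(
            res["rsf"], np.linspace(0.0, 4000.0, 81),
            {k: dict(v) for k, v in scenarios.items()})
        profiles.to_csv(out / f"score_profile_{season}.csv", index=False)
        for name, ctx in scenarios.items():
            m = predict_map(res["rsf"], cover, ndvi, schedule.site_polygons,
                            dict(ctx))
            m.write_ascii(out / f"rsf_map_{season}_{name}.asc")

    if world is not None:
        # ground truth available: append a recovery report per season
        for season, res in rsf_fits.items():
            rep = recovery_report(world["true_model"], res["fit"],
                                  prepared["seasonal"][season]["scaler"])
            rep.to_csv(out / f"recovery_{season}.csv", index=False)

    manifest["finished"] = dt.datetime.now(dt.timezone.utc).isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
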