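"""Pipeline stages tying the synthetic source, the two simulators and the
indicator suite together.

Each stage reads the outputs of its predecessors from a scenario
directory, runs the corresponding library operations, and writes tidy
CSV outputs plus a JSON manifest.  Stage order: synth -> derive ->
calibrate -> run (ss, pool) -> perturb -> compare/indicators.  Missing
predecessor outputs are fatal with the required stage named.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import derive, indicators as ind, pool, roster as ros, shipped, \
    sizespectrum as ss, synthetic as syn
from .config import RunManifest, wide_from_tidy, write_tidy

log = logging.getLogger(__name__)

FORCING_YEARS = list(range(2008, 2014))   # six-year forcing library
HINDCAST = (1900, 2014)                   # size-spectrum hindcast span
POOL_HINDCAST = (1959, 2014)              # pool-model hindcast span
BURN_IN = 35


def _dir(cfg, stage: str) -> Path:
    return Path(cfg["out_dir"]) / stage


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} is missing; run the {producer!r} stage first"
        )
    return path


def _seed(cfg, offset: int) -> int:
    return (int(cfg["seed"]) + offset) % (2**31 - 1)


# --------------------------------------------------------------------------
# stage: synth
# --------------------------------------------------------------------------

def stage_synth(cfg: dict, force: bool = False) -> Path:
    """Generate the synthetic source-ecosystem dataset."""
    out = _dir(cfg, "source")
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg, "synth")
    scfg = cfg.get("synthetic", {})

    roster = ros.build_reference_roster()
    traits = syn.gen_traits(roster, seed=_seed(cfg, 0))
    diet = syn.gen_diet_preferences(roster, seed=_seed(cfg, 1), traits=traits)
    overlap = syn.gen_overlap_tensor(roster, seed=_seed(cfg, 2))
    forcing = syn.gen_forcing_library(
        n_years=len(FORCING_YEARS), seed=_seed(cfg, 3), start_year=FORCING_YEARS[0]
    )

    # carrying capacities and catch patterns for the fished hindcast
    rng = np.random.default_rng(_seed(cfg, 4))
    consumers = roster[roster["taxon_class"].isin(["vertebrate", "invertebrate"])]
    k_median = float(scfg.get("k_median_tonnes", 2000.0))
    K = {
        g: float(np.exp(rng.normal(np.log(k_median), 0.7)))
        for g in consumers["group_id"]
    }
    fished = [g for g in consumers["group_id"] if rng.random() < 0.7]
    years = np.arange(HINDCAST[0], HINDCAST[1])
    pattern = {
        g: {
            "amplitude": 0.12 * K[g],
            "peak_year": int(rng.uniform(1965, 1995)),
            "width": 15.0,
            "start_year": int(rng.choice([1900, 1930, 1950, 1960])),
            "cv": 0.2,
        }
        for g in fished
    }
    catch = syn.gen_catch_history(list(consumers["group_id"]), years, pattern,
                                  seed=_seed(cfg, 5))

    zero_catch = catch * 0.0
    process_cv = float(scfg.get("process_cv", 0.1))
    unfished = syn.emulate_source_run(
        traits, diet, zero_catch, forcing, seed=_seed(cfg, 6),
        carrying_capacity=K, process_cv=process_cv,
    )
    fished_run = syn.emulate_source_run(
        traits, diet, catch, forcing, seed=_seed(cfg, 6),
        carrying_capacity=K, process_cv=process_cv,
    )

    # observation series: survey indices for every fished group, CPUE for a few
    obs_cv = float(scfg.get("obs_cv", 0.3))
    idx_rows = []
    survey_years = np.arange(1992, 2014, 2)
    for j, g in enumerate(fished):
        truth = fished_run.ssb[g].loc[fished_run.ssb.index.isin(survey_years)]
        obs = syn.gen_observation_series(truth, q=0.5, obs_cv=obs_cv,
                                         seed=_seed(cfg, 100 + j), kind="survey")
        obs["group"] = g
        idx_rows.append(obs)
    for j, g in enumerate(fished[:3]):
        truth = fished_run.ssb[g].loc[1990:]
        obs = syn.gen_observation_series(truth, q=1.2, obs_cv=obs_cv,
                                         seed=_seed(cfg, 200 + j), kind="cpue")
        obs["group"] = g
        idx_rows.append(obs)

    write_tidy(traits, out / "species_traits.csv")
    diet_long = diet.stack().rename("proportion").reset_index()
    write_tidy(diet_long[diet_long["proportion"] > 0], out / "diet_prefs.csv")
    write_tidy(overlap, out / "overlap.csv")
    write_tidy(
        catch.stack().rename("tonnes").reset_index().rename(columns={"level_1": "group"}),
        out / "catch.csv",
    )
    write_tidy(forcing, out / "forcing.csv")
    write_tidy(pd.concat(idx_rows, ignore_index=True), out / "index.csv")
    for name, run_ in (("unfished", unfished), ("fished", fished_run)):
        tidy = pd.concat(
            [
                run_.biomass.stack().rename("value").reset_index()
                .rename(columns={"level_1": "group"}).assign(variable="biomass"),
                run_.ssb.stack().rename("value").reset_index()
                .rename(columns={"level_1": "group"}).assign(variable="ssb"),
            ],
            ignore_index=True,
        )[["year", "group", "variable", "value"]]
        write_tidy(tidy, out / f"source_{name}.csv")
        diet_r = run_.diet.stack().rename("proportion").reset_index()
        diet_r.columns = ["predator", "prey", "proportion"]
        write_tidy(diet_r[diet_r["proportion"] > 0], out / f"source_{name}_diet.csv")
    for f in sorted(out.glob("*.csv")):
        man.add_output(f)
    man.write(out)
    return out


# --------------------------------------------------------------------------
# stage: derive
# --------------------------------------------------------------------------

def stage_derive(cfg: dict) -> Path:
    """Filter the roster and derive size-spectrum parameters and F series."""
    src = _dir(cfg, "source")
    out = _dir(cfg, "derived")
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg, "derive")
    traits = pd.read_csv(_require(src / "species_traits.csv", "synth"))
    diet_prefs = pd.read_csv(_require(src / "diet_prefs.csv", "synth"))
    overlap = pd.read_csv(_require(src / "overlap.csv", "synth"))
    catch = pd.read_csv(_require(src / "catch.csv", "synth"))
    source_fished = pd.read_csv(_require(src / "source_fished.csv", "synth"))

    roster = ros.build_reference_roster()
    dynamic = derive.filter_size_based_groups(roster)
    keep = set(dynamic["group_id"])

    links = diet_prefs[
        diet_prefs["predator"].isin(keep) & diet_prefs["prey"].isin(keep)
    ][["predator", "prey"]]
    bs = derive.derive_beta_sigma(traits, links)
    species = traits[traits["group_id"].isin(keep)].merge(bs, on="group_id",
                                                          how="left")
    # groups with no in-set prey links feed on the plankton resource:
    # wide planktivore kernel defaults
    species["beta"] = species["beta"].fillna(100.0)
    species["sigma"] = species["sigma"].fillna(1.3)

    theta = derive.derive_interaction_matrix(
        overlap[overlap["predator"].isin(keep) & overlap["prey"].isin(keep)]
    )

    biomass = wide_from_tidy(source_fished, "biomass")
    catch_w = catch.pivot(index="year", columns="group", values="tonnes")
    f_rows = []
    for g in sorted(keep & set(catch_w.columns)):
        f = derive.f_from_catch(catch_w[g], biomass[g].loc[catch_w.index])
        f_rows.append(pd.DataFrame({"year": f.index, "group": g, "f": f.to_numpy()}))
    f_series = pd.concat(f_rows, ignore_index=True)

    write_tidy(species, out / "species_params.csv")
    theta.to_csv(out / "theta.csv")
    write_tidy(f_series, out / "f_series.csv")
    write_tidy(dynamic, out / "dynamic_groups.csv")
    for f in sorted(out.glob("*.csv")):
        man.add_output(f)
    man.write(out)
    return out


# --------------------------------------------------------------------------
# stage: calibrate
# --------------------------------------------------------------------------

def stage_calibrate(cfg: dict) -> Path:
    """Calibrate R_max against source virgin biomasses; check stability."""
    der = _dir(cfg, "derived")
    src = _dir(cfg, "source")
    out = _dir(cfg, "calibrated")
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg, "calibrate")
    species = pd.read_csv(_require(der / "species_params.csv", "derive"))
    theta = pd.read_csv(_require(der / "theta.csv", "derive"), index_col=0)
    source_unfished = pd.read_csv(_require(src / "source_unfished.csv", "synth"))

    resource = ss.ResourceParams.reduced()
    sp = ss.default_physiology(species)
    model = ss.SSModel(sp, theta, resource=resource)
    biomass = wide_from_tidy(source_unfished, "biomass")
    targets = biomass.iloc[-30:].mean().loc[model.species["group_id"]]
    opts = cfg.get("species", {})
    rmax, report = derive.calibrate_rmax(
        model, targets,
        tol=float(opts.get("calibrate_tol", 0.05)),
        max_iter=int(opts.get("calibrate_max_iter", 25)),
    )

    # stability diagnostic: unfished burn-in + hindcast, per-group CV
    traj, _ = ss.run(model, years=HINDCAST[1] - HINDCAST[0] + 1,
                     burn_in=BURN_IN, start_year=HINDCAST[0])
    bio = wide_from_tidy(traj, "biomass")
    cv = bio.std(ddof=1) / bio.mean()

    model.species.to_csv(out / "calibrated_species.csv", index=False)
    theta.to_csv(out / "calibrated_theta.csv")
    rp = {
        "kappa": resource.kappa, "kappa_ref": resource.kappa_ref,
        "lam": resource.lam, "r0": resource.r0, "w_cut": resource.w_cut,
    }
    import yaml
    (out / "calibrated_resource.yaml").write_text(yaml.safe_dump(rp))
    summary = {
        "converged": bool(report["converged"]),
        "iterations": int(report["iterations"]),
        "pearson_log_biomass": float(report["pearson_log"]),
        "max_abs_residual": float(report["residuals"].abs().max()),
        "stability_max_cv": float(cv.max()),
        "stability_cv_by_group": {k: float(v) for k, v in cv.items()},
    }
    (out / "calibration_report.json").write_text(json.dumps(summary, indent=2))
    for f in sorted(out.iterdir()):
        man.add_output(f)
    man.write(out)
    return out


def load_scenario_ss_model(cfg: dict) -> ss.SSModel:
    """Scenario-local calibrated model if present, else the packaged one."""
    cal = _dir(cfg, "calibrated")
    if (cal / "calibrated_species.csv").exists():
        import yaml
        species = pd.read_csv(cal / "calibrated_species.csv")
        theta = pd.read_csv(cal / "calibrated_theta.csv", index_col=0)
        raw = yaml.safe_load((cal / "calibrated_resource.yaml").read_text())
        return ss.SSModel(species, theta, resource=ss.ResourceParams(**raw))
    return shipped.load_calibrated_model()


# --------------------------------------------------------------------------
# stage: run
# --------------------------------------------------------------------------

def stage_run(cfg: dict, which: str) -> Path:
    """Run one simulator ('ss' or 'pool') for the hindcast."""
    if which == "ss":
        return _run_ss(cfg)
    if which == "pool":
        return _run_pool(cfg)
    raise ValueError(f"unknown model {which!r}; expected 'ss' or 'pool'")


def _run_ss(cfg: dict) -> Path:
    der = _dir(cfg, "derived")
    out = _dir(cfg, "runs")
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg, "run_ss")
    try:
        model = load_scenario_ss_model(cfg)
    except FileNotFoundError as err:
        raise FileNotFoundError(
            "no calibrated configuration; run the 'calibrate' stage first"
        ) from err
    f_series = pd.read_csv(_require(der / "f_series.csv", "derive"))
    f_wide = f_series.pivot(index="year", columns="group", values="f")
    years = HINDCAST[1] - HINDCAST[0] + 1
    unfished, state_u = ss.run(model, years=years, burn_in=BURN_IN,
                               start_year=HINDCAST[0])
    fished, state_f = ss.run(model, years=years, burn_in=BURN_IN,
                             start_year=HINDCAST[0], f_schedule=f_wide)
    write_tidy(unfished, out / "ss_unfished.csv")
    write_tidy(fished, out / "ss_fished.csv")
    diet = model.realised_diet(state_u)
    diet_long = diet.stack().rename("proportion").reset_index()
    diet_long.columns = ["predator", "prey", "proportion"]
    write_tidy(diet_long[diet_long["proportion"] > 0], out / "ss_diet.csv")
    for f in ("ss_unfished.csv", "ss_fished.csv", "ss_diet.csv"):
        man.add_output(out / f)
    man.write(out)
    return out


def build_pool_inputs(cfg: dict):
    """Ecopath-style snapshot from the synthetic source outputs.

    B0 is the unfished source mean biomass, PB comes from literature M
    (consumers) or class defaults (pools), QB = PB / GE with GE = 0.3,
    DC is the source realised diet transposed to prey x predator, and Y0
    is the catch at the pool baseline year.  Diets are then iteratively
    scaled down on over-predated prey until every EE <= 1.
    """
    src = _dir(cfg, "source")
    traits = pd.read_csv(_require(src / "species_traits.csv", "synth"))
    diet_prefs = pd.read_csv(_require(src / "source_fished_diet.csv", "synth"))
    source_unfished = pd.read_csv(_require(src / "source_unfished.csv", "synth"))
    catch = pd.read_csv(_require(src / "catch.csv", "synth"))

    roster = ros.build_reference_roster()
    groups = roster["group_id"].tolist()
    b0 = wide_from_tidy(source_unfished, "biomass").mean()
    # producers and detrital pools: biomass scaled to support consumption
    class_pb = {"producer": 60.0, "bacteria_detritus": 30.0}
    m_lookup = dict(zip(traits["group_id"], traits["M_lit"]))
    rows = []
    ge = 0.3
    for _, r in roster.iterrows():
        g = r["group_id"]
        cls = r["taxon_class"]
        if cls in class_pb:
            pb, qb = class_pb[cls], np.nan
        else:
            m = m_lookup.get(g, 0.8)
            pb = max(2.0 * m, 0.3)       # production ~ twice M for balance headroom
            qb = pb / ge
        rows.append({"group": g, "B0": float(b0.get(g, np.nan)), "PB": pb,
                     "QB": qb, "Y0": 0.0})
    inputs = pd.DataFrame(rows)
    # basal pools have no source biomass trajectory: give them a stock large
    # enough to support their consumers
    basal = inputs["B0"].isna()
    inputs.loc[basal, "B0"] = 5.0 * float(np.nanmedian(inputs["B0"]))

    catch_w = catch.pivot(index="year", columns="group", values="tonnes")
    y0_year = POOL_HINDCAST[0]
    for i, row in inputs.iterrows():
        g = row["group"]
        if g in catch_w.columns and y0_year in catch_w.index:
            inputs.loc[i, "Y0"] = float(catch_w.loc[y0_year, g])

    dc = (
        diet_prefs.pivot(index="prey", columns="predator", values="proportion")
        .reindex(index=groups)
        .fillna(0.0)
    )
    # import share: a slice of each vertebrate diet taken outside the area
    import_frac = float(cfg.get("pool", {}).get("import_fraction", 0.1))
    verts = set(roster.loc[roster["taxon_class"] == "vertebrate", "group_id"])
    for pred in dc.columns:
        col = dc[pred]
        if col.sum() > 0:
            dc[pred] = col / col.sum()
            if pred in verts and import_frac > 0:
                dc[pred] = dc[pred] * (1.0 - import_frac)
                dc.loc[IMPORT_ROW, pred] = import_frac
    dc = dc.fillna(0.0)
    inputs, dc = rebalance_diets(inputs, dc)
    return inputs, dc


IMPORT_ROW = pool.IMPORT_ID


def rebalance_diets(inputs: pd.DataFrame, dc: pd.DataFrame, max_iter: int = 60):
    """Scale down diet shares of over-predated prey until every EE <= 1.

    The standard manual balancing move automated: each round, prey with
    EE > 1 have their diet contributions shrunk by the excess factor and
    the removed share moved to the IMPORT row (diet sourced outside the
    area), so total consumption demand on local pools actually falls.
    """
    import warnings as _w

    if IMPORT_ROW not in dc.index:
        dc.loc[IMPORT_ROW] = 0.0
    for _ in range(max_iter):
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            bal = pool.balance(inputs, dc)
        if not bal.unbalanced:
            return inputs, dc
        for g in bal.unbalanced:
            if g not in dc.index:
                continue
            factor = 0.9 / float(bal.ee[g])
            removed = dc.loc[g] * (1.0 - factor)
            dc.loc[g] *= factor
            dc.loc[IMPORT_ROW] += removed
    raise RuntimeError(f"diet rebalancing failed; still unbalanced: {bal.unbalanced}")


def _run_pool(cfg: dict) -> Path:
    src = _dir(cfg, "source")
    out = _dir(cfg, "runs")
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg, "run_pool")
    inputs, dc = build_pool_inputs(cfg)
    bal = pool.balance(inputs, dc)
    arena = pool.derive_arena_params(inputs, bal)
    years = POOL_HINDCAST[1] - POOL_HINDCAST[0] + 1

    catch = pd.read_csv(_require(src / "catch.csv", "synth"))
    source_fished = pd.read_csv(_require(src / "source_fished.csv", "synth"))
    catch_w = catch.pivot(index="year", columns="group", values="tonnes")
    bio_w = wide_from_tidy(source_fished, "biomass")
    f_cols = {}
    for g in catch_w.columns:
        if g in bio_w.columns:
            f_cols[g] = derive.f_from_catch(catch_w[g], bio_w[g].loc[catch_w.index])
    f_wide = pd.DataFrame(f_cols)

    baseline = pool.run_pool(inputs, dc, arena, f_series=None, years=years,
                             start_year=POOL_HINDCAST[0])
    fished = pool.run_pool(inputs, dc, arena, f_series=f_wide, years=years,
                           start_year=POOL_HINDCAST[0])
    write_tidy(pool.tidy_trajectories(baseline), out / "pool_baseline.csv")
    write_tidy(pool.tidy_trajectories(fished), out / "pool_fished.csv")
    diet = pool.realised_diet_pool(fished, inputs, dc)
    diet_long = diet.stack().rename("proportion").reset_index()
    diet_long.columns = ["prey", "predator", "proportion"]
    write_tidy(diet_long[diet_long["proportion"] > 0], out / "pool_diet.csv")
    write_tidy(inputs, out / "pool_inputs.csv")
    dc.to_csv(out / "pool_dc.csv")
    for f in ("pool_baseline.csv", "pool_fished.csv", "pool_diet.csv"):
        man.add_output(out / f)
    man.write(out)
    return out

# --------------------------------------------------------------------------
# stage: perturb (sensitivity and keystoneness experiments)
# --------------------------------------------------------------------------

def _pool_runner_factory(inputs, dc, arena, substeps=20):
    """Runner for the pool-model perturbation suite: adds extra natural
    mortality to named groups via the F channel and reports end biomass."""

    groups = inputs["group"].tolist()

    def runner(extra_m: dict, horizon: int) -> pd.Series:
        f = pd.DataFrame(
            {g: [extra_m.get(g, 0.0)] * horizon for g in groups},
            index=np.arange(2000, 2000 + horizon),
        )
        base_f = (inputs.set_index("group")["Y0"].fillna(0.0)
                  / inputs.set_index("group")["B0"])
        f = f.add(base_f, axis=1)
        res = pool.run_pool(inputs, dc, arena, f_series=f, years=horizon,
                            start_year=2000, substeps=substeps)
        return res.biomass.iloc[-1]

    return runner


def _ss_runner_factory(model, state0):
    """Runner for the size-spectrum perturbation suite: adds background
    mortality to one species and integrates from the calibrated state."""

    groups = model.species["group_id"].tolist()

    def runner(extra_m: dict, horizon: int) -> pd.Series:
        saved = model.mu_b.copy()
        try:
            for g, level in extra_m.items():
                model.mu_b[groups.index(g)] += level
            state = ss.CommunityState(N=state0.N.copy(), N_R=state0.N_R.copy(), t=0.0)
            for _ in range(int(horizon / 0.1)):
                state, _ = model.step(state, dt=0.1)
            return pd.Series(model.biomass(state), index=groups)
        finally:
            model.mu_b = saved

    return runner


def stage_perturb(cfg: dict) -> Path:
    """Initial-condition, forcing-year and keystoneness experiments."""
    src = _dir(cfg, "source")
    runs = _dir(cfg, "runs")
    out = _dir(cfg, "perturb")
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg, "perturb")
    exp = cfg.get("experiments", {})

    traits = pd.read_csv(_require(src / "species_traits.csv", "synth"))
    diet_prefs = pd.read_csv(_require(src / "diet_prefs.csv", "synth"))
    catch = pd.read_csv(_require(src / "catch.csv", "synth"))
    forcing = pd.read_csv(_require(src / "forcing.csv", "synth"))
    catch_w = catch.pivot(index="year", columns="group", values="tonnes")
    diet_w = diet_prefs.pivot(index="predator", columns="prey",
                              values="proportion").fillna(0.0)
    all_groups = sorted(set(diet_w.index) | set(diet_w.columns) | set(catch_w.columns))
    diet_w = diet_w.reindex(index=all_groups, columns=all_groups).fillna(0.0)

    rng_k = np.random.default_rng(_seed(cfg, 4))
    roster = ros.build_reference_roster()
    consumers = roster[roster["taxon_class"].isin(["vertebrate", "invertebrate"])]
    k_median = float(cfg.get("synthetic", {}).get("k_median_tonnes", 2000.0))
    K = pd.Series({g: float(np.exp(rng_k.normal(np.log(k_median), 0.7)))
                   for g in consumers["group_id"]})

    # 1) initial-condition perturbation of the source model (K multipliers)
    n_init = int(exp.get("n_init_runs", 20))
    init_cv = float(exp.get("init_cv", 0.1))
    k_sets = derive.perturb_initial_conditions(K, init_cv, n_init,
                                               seed=_seed(cfg, 30))
    ensemble = []
    for j, k_j in enumerate(k_sets):
        run_j = syn.emulate_source_run(
            traits, diet_w, catch_w, forcing, seed=_seed(cfg, 31),
            carrying_capacity=k_j.to_dict(),
        )
        ensemble.append(run_j.biomass)
    cv_init = ind.between_run_cv(ensemble, window=(2000, 2013))
    write_tidy(cv_init.rename("cv").reset_index().rename(columns={"index": "group"}),
               out / "cv_initial_conditions.csv")

    # 2) forcing-year bootstrap and repeat-year envelopes
    n_boot = int(exp.get("n_bootstrap_runs", 50))
    designs = ind.bootstrap_forcing_design(
        FORCING_YEARS, n_runs=n_boot, n_years=len(catch_w),
        burn_in_year=None, burn_in_len=0, seed=_seed(cfg, 40),
    )
    boot_ens = []
    for j, seq in enumerate(designs):
        run_j = syn.emulate_source_run(
            traits, diet_w, catch_w, forcing, seed=_seed(cfg, 41),
            carrying_capacity=K.to_dict(), year_sequence=seq,
        )
        boot_ens.append(run_j.biomass)
    cv_boot = ind.between_run_cv(boot_ens, window=(2000, 2013))
    write_tidy(cv_boot.rename("cv").reset_index().rename(columns={"index": "group"}),
               out / "cv_bootstrap_forcing.csv")

    repeat_runs = []
    for seq in ind.repeat_year_design(FORCING_YEARS, n_years=len(catch_w),
                                      burn_in_len=0):
        run_j = syn.emulate_source_run(
            traits, diet_w, catch_w, forcing, seed=_seed(cfg, 41),
            carrying_capacity=K.to_dict(), year_sequence=seq,
        )
        repeat_runs.append(run_j.biomass)
    cv_repeat = ind.between_run_cv(repeat_runs, window=(2000, 2013), reduce="p90")
    write_tidy(cv_repeat.rename("cv_p90").reset_index().rename(columns={"index": "group"}),
               out / "cv_repeat_year.csv")

    rep_year, rep_table = ind.representative_year(forcing)
    rep_table.reset_index().to_csv(out / "representative_year.csv", index=False)
    (out / "representative_year.json").write_text(
        json.dumps({"representative_year": int(rep_year)})
    )

    # 3) keystoneness: perturbation suites on both simulators
    levels = tuple(exp.get("mortality_levels", (0.1, 0.005)))
    horizon = int(exp.get("keystone_horizon", 50))

    inputs, dc = build_pool_inputs(cfg)
    bal = pool.balance(inputs, dc)
    arena = pool.derive_arena_params(inputs, bal)
    aged = roster.loc[roster["lifespan"].notna(), "group_id"].tolist()
    n_keystone = exp.get("n_keystone_groups")
    if n_keystone:
        aged = aged[: int(n_keystone)]
    pool_runner = _pool_runner_factory(inputs, dc, arena)
    impacts_pool = ind.run_perturbation_suite(pool_runner, aged, levels=levels,
                                              horizon=horizon)
    b_pool = inputs.set_index("group").loc[aged, "B0"]
    ks_pool = ind.keystoneness(impacts_pool.mean, b_pool)
    ks_pool.reset_index(names="group").to_csv(out / "keystone_pool.csv", index=False)

    model = load_scenario_ss_model(cfg)
    _, state0 = ss.equilibrium_biomass(model, t_max=80.0)
    all_ss_groups = model.species["group_id"].tolist()
    ss_groups = all_ss_groups[: int(n_keystone)] if n_keystone else all_ss_groups
    ss_runner = _ss_runner_factory(model, state0)
    impacts_ss = ind.run_perturbation_suite(ss_runner, ss_groups, levels=levels,
                                            horizon=horizon)
    b_ss = pd.Series(model.biomass(state0), index=all_ss_groups).loc[ss_groups]
    ks_ss = ind.keystoneness(impacts_ss.mean, b_ss)
    ks_ss.reset_index(names="group").to_csv(out / "keystone_ss.csv", index=False)

    shared = sorted(set(aged) & set(ss_groups))
    thirds = ind.classify_rank_thirds(
        ks_pool.loc[shared, "ks_rank"].rank(method="first"),
        ks_ss.loc[shared, "ks_rank"].rank(method="first"),
    )
    (out / "keystone_thirds.json").write_text(json.dumps(thirds))
    for f in sorted(out.iterdir()):
        man.add_output(f)
    man.write(out)
    return out


# --------------------------------------------------------------------------
# stage: compare / indicators
# --------------------------------------------------------------------------

PLANKTON_PREY = ("Resource", "Diatoms", "Pico-phytoplankton", "MicroZoo",
                 "MesoZoo", "Carniv Zoo", "Gelat Zoo")


def _diet_from_csv(path, index_col="predator", col="prey"):
    df = pd.read_csv(path)
    return df.pivot(index=index_col, columns=col, values="proportion").fillna(0.0)


def stage_compare(cfg: dict) -> Path:
    """Cross-model comparisons: diets, responses to fishing, skill."""
    src = _dir(cfg, "source")
    runs = _dir(cfg, "runs")
    out = _dir(cfg, "compare")
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg, "compare")

    source_diet = _diet_from_csv(_require(src / "source_fished_diet.csv", "synth"))
    pool_diet = _diet_from_csv(_require(runs / "pool_diet.csv", "run pool"),
                               index_col="prey", col="predator").T
    ss_diet = _diet_from_csv(_require(runs / "ss_diet.csv", "run ss"))

    diets = {"source": source_diet, "pool": pool_diet, "ss": ss_diet}
    rows = []
    names = sorted(diets)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            da, db = diets[na], diets[nb]
            for g in sorted(set(da.index) & set(db.index)):
                drop = PLANKTON_PREY if "ss" in (na, nb) else ()
                rho = ind.diet_spearman(da.loc[g], db.loc[g], drop_prey=drop)
                rows.append({"group": g, "pair": f"{na}_vs_{nb}", "spearman": rho})
    write_tidy(pd.DataFrame(rows), out / "diet_spearman.csv")

    source_fished = pd.read_csv(_require(src / "source_fished.csv", "synth"))
    trajs = {
        "source": wide_from_tidy(source_fished, "biomass"),
        "pool": wide_from_tidy(pd.read_csv(runs / "pool_fished.csv"), "biomass"),
        "ss": wide_from_tidy(pd.read_csv(runs / "ss_fished.csv"), "biomass"),
    }
    resp = ind.response_correlation_matrix(trajs)
    resp.reset_index(names="group").to_csv(out / "response_correlations.csv",
                                           index=False)

    # skill: source SSB against the synthetic survey/CPUE indices
    index_df = pd.read_csv(_require(src / "index.csv", "synth"))
    ssb = wide_from_tidy(source_fished, "ssb")
    skill_rows = []
    for (g, kind), sub in index_df.groupby(["group", "kind"]):
        if g not in ssb.columns:
            continue
        series = pd.Series(sub["value"].to_numpy(), index=sub["year"].to_numpy())
        r, _ = ind.skill_pearson(ssb[g], series)
        skill_rows.append({"group": g, "kind": kind, "pearson": r})
    write_tidy(pd.DataFrame(skill_rows), out / "skill.csv")
    for f in sorted(out.iterdir()):
        man.add_output(f)
    man.write(out)
    return out


def stage_indicators(cfg: dict) -> Path:
    """Trophic levels, prey-category summaries, diversity and diagnostics."""
    src = _dir(cfg, "source")
    runs = _dir(cfg, "runs")
    out = _dir(cfg, "indicators")
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg, "indicators")

    roster = ros.build_reference_roster()
    producers = set(roster.loc[roster["taxon_class"] == "producer", "group_id"])
    bacteria = {"Pelagic bacteria", "Sediment bacteria"}
    categories = ros.load_prey_categories()
    cat_map = dict(zip(categories["group_id"], categories["category"]))
    cat_map["Resource"] = "Phytoplankton"
    cat_map[pool.IMPORT_ID] = "Teleost"  # imported diet is fish taken elsewhere

    source_diet = _diet_from_csv(_require(src / "source_fished_diet.csv", "synth"))
    pool_diet = _diet_from_csv(_require(runs / "pool_diet.csv", "run pool"),
                               index_col="prey", col="predator").T
    ss_diet = _diet_from_csv(_require(runs / "ss_diet.csv", "run ss"))
    diets = {"source": source_diet, "pool": pool_diet, "ss": ss_diet}

    tl_rows, cat_rows = [], []
    tls = {}
    for name, diet in diets.items():
        if pool.IMPORT_ID in diet.columns:
            # diet taken outside the area carries no local trophic signal
            diet = diet.drop(columns=pool.IMPORT_ID)
            rs = diet.sum(axis=1)
            diet.loc[rs > 0] = diet.loc[rs > 0].div(rs[rs > 0], axis=0)
        tl = ind.trophic_levels(diet, producers | {"Resource"}, bacteria)
        tls[name] = tl
        for g, v in tl.items():
            tl_rows.append({"model": name, "group": g, "tl": float(v)})
        cats = ind.summarise_prey_categories(diet, cat_map)
        for g in cats.index:
            for c in cats.columns:
                if cats.loc[g, c] > 0:
                    cat_rows.append({"model": name, "predator": g, "category": c,
                                     "proportion": float(cats.loc[g, c])})
    write_tidy(pd.DataFrame(tl_rows), out / "trophic_levels.csv")
    write_tidy(pd.DataFrame(cat_rows), out / "diet_categories.csv")

    # Kempton's Q series per model under fishing, scaled to a common mean
    source_fished = pd.read_csv(_require(src / "source_fished.csv", "synth"))
    trajs = {
        "source": wide_from_tidy(source_fished, "biomass"),
        "pool": wide_from_tidy(pd.read_csv(runs / "pool_fished.csv"), "biomass"),
        "ss": wide_from_tidy(pd.read_csv(runs / "ss_fished.csv"), "biomass"),
    }
    q_series = {}
    for name, bio in trajs.items():
        tl = tls[name]
        qs = {}
        for year in bio.index:
            try:
                qs[year] = ind.kemptons_q(bio.loc[year], tl)
            except ValueError:
                continue
        if qs:
            q_series[name] = pd.Series(qs)
    scaled, ratios = ind.diversity_comparison(q_series, reference="source")
    scaled.reset_index(names="year").to_csv(out / "diversity_scaled.csv", index=False)
    ratios.reset_index(names="year").to_csv(out / "diversity_ratios.csv", index=False)

    # size diagnostics from the calibrated size-spectrum equilibrium
    model = load_scenario_ss_model(cfg)
    _, state = ss.equilibrium_biomass(model, t_max=80.0)
    diag_rows = []
    for i, r in model.species.iterrows():
        spec = (model.grid.w, state.N[i])
        l_p90 = ind.lmax_estimate(r["a_lw"], r["b_lw"], spectrum=spec, mode="p90")
        l_max = ind.lmax_estimate(r["a_lw"], r["b_lw"], spectrum=spec, mode="max")
        l_inf = float((r["w_inf_g"] / r["a_lw"]) ** (1.0 / r["b_lw"]))
        props = model.proportions_at_age(state, r["group_id"],
                                         max_age=int(2 / r["k_vb"]))
        m_hat, m_diff = ind.mortality_decay_check(props, r["M_lit"])
        diag_rows.append({"group": r["group_id"], "L_p90_cm": l_p90,
                          "L_max_cm": l_max, "L_inf_cm": l_inf,
                          "M_hat": m_hat, "M_minus_lit": m_diff})
    write_tidy(pd.DataFrame(diag_rows), out / "size_mortality_diagnostics.csv")
    for f in sorted(out.iterdir()):
        man.add_output(f)
    man.write(out)
    return out
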