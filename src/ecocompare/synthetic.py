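"""Synthetic source ecosystem: seeded stand-ins for a complex source model.

The comparison pipeline needs, from some "source" ecosystem model, a set
of annual biomass/SSB trajectories, realised diet matrices, spatial
overlap tensors, catch histories, environmental forcing years, and noisy
observation indices.  This module generates all of these from seeds with
the statistical structure the downstream analysis assumes: a logistic
surplus-production biomass model with AR(1) lognormal process noise and
productivity year effects, Dirichlet diet preferences over size-permitted
prey, and lognormal observation error.  Everything is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

OVERLAP_COMBOS = ("adult_adult", "adult_juvenile", "juvenile_juvenile")

# Trait scales by taxon class.  Asymptotic mass covaries with lifespan
# (w_inf ~ base * lifespan^1.5, jittered), the life-history invariant
# that keeps long-lived species large and fast-growing species small;
# vertebrates span small schooling fish through sharks, the
# age-structured invertebrates (cephalopods, shellfish) are smaller.
_TRAIT_RANGES = {
    "vertebrate": {"w_inf_base": 40.0, "w_inf": (2e2, 5e4), "a_lw": (0.005, 0.03)},
    "invertebrate": {"w_inf_base": 150.0, "w_inf": (5e0, 2e3), "a_lw": (0.01, 0.1)},
}


@dataclasses.dataclass
class SourceRunOutput:
    """Annual outputs of the emulated source-model run."""

    biomass: pd.DataFrame        # year x group, tonnes
    ssb: pd.DataFrame            # year x group, tonnes
    catch: pd.DataFrame          # year x group, tonnes actually removed
    diet: pd.DataFrame           # realised predator x prey proportions
    overlap: pd.DataFrame        # long-format overlap tensor snapshot
    n_catch_truncations: int     # years where catch exceeded available biomass


def _proxy_mass(row) -> float:
    """Typical individual mass used to order groups when no traits are given."""
    if row["taxon_class"] == "producer":
        return 1e-6
    if row["taxon_class"] == "bacteria_detritus":
        return 5e-7  # within the predation window of the smallest grazers
    lifespan = row.get("lifespan", np.nan)
    if np.isnan(lifespan):
        return 1e-2  # small benthos / zooplankton pools
    base = 1.0 if row["taxon_class"] == "invertebrate" else 50.0
    return base * float(lifespan) ** 1.5


def gen_traits(roster: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw life-history traits for every age-structured group.

    Asymptotic mass scales with lifespan^1.5 (log-jittered, clipped to
    per-taxon-class ranges) so that long-lived groups are also the large
    ones; the maturity mass is a fraction rho ~ U[0.05, 0.5] of the
    asymptotic mass; the von Bertalanffy rate and literature natural
    mortality scale inversely with lifespan (k ~ 3/lifespan,
    M ~ 5.4/lifespan, both jittered); the length-weight exponent is
    uniform on [2.5, 3.5].  Deterministic given the seed.
    """
    if roster.empty:
        raise ValueError("roster is empty")
    rng = np.random.default_rng(seed)
    rows = []
    aged = roster[roster["lifespan"].notna()]
    for _, r in aged.iterrows():
        ranges = _TRAIT_RANGES.get(r["taxon_class"], _TRAIT_RANGES["invertebrate"])
        lifespan = float(r["lifespan"])
        lo, hi = ranges["w_inf"]
        w_inf = np.clip(
            ranges["w_inf_base"] * lifespan**1.5 * np.exp(rng.uniform(-0.7, 0.7)),
            lo, hi,
        )
        rho = rng.uniform(0.05, 0.5)
        k_vb = np.clip(3.0 / lifespan * np.exp(rng.uniform(-0.3, 0.3)), 0.05, 2.0)
        lo_a, hi_a = ranges["a_lw"]
        a_lw = np.exp(rng.uniform(np.log(lo_a), np.log(hi_a)))
        b_lw = rng.uniform(2.5, 3.5)
        m_lit = 5.4 / lifespan * np.exp(rng.uniform(-0.2, 0.2))
        rows.append(
            {
                "group_id": r["group_id"],
                "w_inf_g": w_inf,
                "w_mat_g": rho * w_inf,
                "k_vb": k_vb,
                "a_lw": a_lw,
                "b_lw": b_lw,
                "M_lit": m_lit,
            }
        )
    return pd.DataFrame(rows)


def gen_diet_preferences(
    roster: pd.DataFrame, seed: int, traits: pd.DataFrame | None = None,
    concentration: float = 0.5, window: float = 1e-5,
) -> pd.DataFrame:
    """Dirichlet diet-preference rows for every consumer group.

    Permitted prey of a consumer are the groups within its predation
    mass window: smaller than half the predator's typical mass
    (asymptotic mass where traits are supplied, a class/lifespan proxy
    otherwise) but no more than a factor ``window`` below it.  The
    window keeps large predators off the producer base, giving the food
    web its chain structure; small grazing consumers reach the
    producers directly.  Producer and bacteria/detritus rows are all
    zero.  Rows of consumers sum to one.
    """
    producers = roster[roster["taxon_class"] == "producer"]
    if producers.empty:
        raise ValueError("roster has no producer group; a food web needs a base")
    rng = np.random.default_rng(seed)
    groups = roster["group_id"].tolist()
    mass = {}
    for _, r in roster.iterrows():
        gid = r["group_id"]
        if traits is not None and gid in set(traits["group_id"]):
            mass[gid] = float(traits.set_index("group_id").loc[gid, "w_inf_g"])
        else:
            mass[gid] = _proxy_mass(r)
    diet = pd.DataFrame(0.0, index=groups, columns=groups)
    consumers = roster[roster["taxon_class"].isin(["vertebrate", "invertebrate"])]
    for _, r in consumers.iterrows():
        pred = r["group_id"]
        prey = [
            g for g in groups
            if window * mass[pred] <= mass[g] < 0.5 * mass[pred] and g != pred
        ]
        if not prey:  # smallest consumers graze the producer base
            prey = producers["group_id"].tolist()
        draw = rng.dirichlet(np.full(len(prey), concentration))
        diet.loc[pred, prey] = draw
    diet.index.name = "predator"
    diet.columns.name = "prey"
    return diet


def gen_overlap_tensor(roster: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Spatial-overlap values in [0, 1] for each predator-prey pair.

    Three size combinations per pair (adult-adult, adult-juvenile,
    juvenile-juvenile); the juvenile-predator/adult-prey combination is
    absent by design.  A group overlaps itself completely (value 1).
    Returned in long format: predator, prey, combo, value.
    """
    rng = np.random.default_rng(seed)
    groups = roster["group_id"].tolist()
    rows = []
    for pred in groups:
        for prey in groups:
            for combo in OVERLAP_COMBOS:
                value = 1.0 if pred == prey else rng.beta(2.0, 2.0)
                rows.append({"predator": pred, "prey": prey, "combo": combo,
                             "value": value})
    return pd.DataFrame(rows)


def gen_catch_history(
    groups: list[str],
    years: np.ndarray,
    pattern: dict,
    seed: int,
) -> pd.DataFrame:
    """Ramp-peak-decline catch history with multiplicative lognormal noise.

    ``pattern`` maps each group to a dict with keys ``amplitude`` (peak
    tonnes), ``peak_year``, ``width`` (years, Gaussian half-width) and
    ``start_year`` (zero catch before it).  A single dict applies to all
    groups.  Noise CV is ``pattern['cv']`` (default 0.2).
    """
    years = np.asarray(years)
    if not np.all(np.diff(years) == 1):
        raise ValueError("years must be contiguous")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(0.0, index=years, columns=groups)
    out.index.name = "year"
    for g in groups:
        p = pattern if "amplitude" in pattern else pattern.get(g, {"amplitude": 0.0})
        amp = float(p.get("amplitude", 0.0))
        if amp < 0 or p.get("width", 1) <= 0:
            raise ValueError(f"negative/zero pattern parameters for {g}")
        peak = float(p.get("peak_year", years[len(years) // 2]))
        width = float(p.get("width", (years[-1] - years[0]) / 6))
        start = float(p.get("start_year", years[0]))
        cv = float(p.get("cv", 0.2))
        shape = amp * np.exp(-((years - peak) ** 2) / (2 * width**2))
        shape[years < start] = 0.0
        if cv > 0 and amp > 0:
            sig = np.sqrt(np.log(1 + cv**2))
            noise = rng.lognormal(-0.5 * sig**2, sig, len(years))
            shape = shape * noise
        out[g] = shape
    return out


def gen_forcing_library(
    n_years: int = 6,
    seed: int = 0,
    start_year: int = 2008,
    prod_cv: float = 0.15,
    temp_sd: float = 0.6,
) -> pd.DataFrame:
    """Monthly environmental forcing for a small library of years.

    Emulates a short reanalysis archive: for each year, 12 monthly
    temperature anomalies (seasonal cycle plus year effects, degrees C)
    and positive productivity multipliers (lognormal around 1).
    Long format: year, month, temp_anom, prod_mult.
    """
    if n_years < 1:
        raise ValueError("need at least one forcing year")
    rng = np.random.default_rng(seed)
    months = np.arange(1, 13)
    season = np.sin(2 * np.pi * (months - 2) / 12)
    rows = []
    for i in range(n_years):
        year = start_year + i
        year_temp = rng.normal(0.0, temp_sd)
        year_prod = rng.lognormal(-0.5 * prod_cv**2, prod_cv)
        for m, s in zip(months, season):
            rows.append(
                {
                    "year": year,
                    "month": int(m),
                    "temp_anom": year_temp + 0.8 * s + rng.normal(0, 0.15),
                    "prod_mult": float(
                        year_prod * np.exp(0.1 * s) * rng.lognormal(-0.5 * 0.05**2, 0.05)
                    ),
                }
            )
    return pd.DataFrame(rows)


def emulate_source_run(
    traits: pd.DataFrame,
    diets: pd.DataFrame,
    catch: pd.DataFrame,
    forcing: pd.DataFrame | None,
    seed: int,
    carrying_capacity: dict | float = 5000.0,
    growth_rate: dict | float | None = None,
    process_cv: float = 0.1,
    ar1_coef: float = 0.5,
    ssb_fraction: float = 0.5,
    year_sequence: list[int] | None = None,
) -> SourceRunOutput:
    """Emulated source-model run: logistic surplus production per group.

    Each group follows B[t+1] = (B[t] + r_t B[t](1 - B[t]/K) - C[t]) * e[t]
    where r_t is the intrinsic rate scaled by the forcing year's mean
    productivity multiplier and e[t] is AR(1) lognormal process noise
    (stationary CV ``process_cv``, autocorrelation ``ar1_coef``).
    Catch exceeding available biomass is truncated and counted.  SSB is
    a fixed fraction of biomass.  Realised diets are the preference rows
    renormalised over extant (non-floored) prey.
    """
    rng = np.random.default_rng(seed)
    groups = list(catch.columns)
    missing = set(groups) - set(diets.index)
    if missing:
        raise ValueError(f"groups present in catch but not in diets: {sorted(missing)}")
    years = np.asarray(catch.index)
    n_y, n_g = len(years), len(groups)

    def _per_group(value, default):
        if value is None:
            value = default
        if isinstance(value, dict):
            return np.array([value[g] for g in groups])
        return np.full(n_g, float(value))

    K = _per_group(carrying_capacity, 5000.0)
    # default intrinsic rate: twice the literature M where known, else 0.8
    m_lookup = dict(zip(traits["group_id"], traits["M_lit"])) if traits is not None else {}
    r0 = _per_group(growth_rate, None) if growth_rate is not None else np.array(
        [2.0 * m_lookup.get(g, 0.4) for g in groups]
    )
    r0 = np.clip(r0, 0.05, 1.8)

    if forcing is not None and len(forcing):
        prod_by_year = forcing.groupby("year")["prod_mult"].mean()
        if year_sequence is not None:
            # explicit forcing-year assignment (bootstrap / repeat designs);
            # shorter sequences are padded by cycling
            seq = [year_sequence[t % len(year_sequence)] for t in range(n_y)]
            year_mult = prod_by_year.loc[seq].to_numpy()
        else:
            f_years = prod_by_year.index.to_numpy()
            year_mult = prod_by_year.to_numpy()[(years - years[0]) % len(f_years)]
    else:
        year_mult = np.ones(n_y)

    sigma = np.sqrt(np.log(1 + process_cv**2))
    # stationary AR(1) in log space with marginal sd sigma
    innov_sd = sigma * np.sqrt(1 - ar1_coef**2)
    eps = np.zeros(n_g)
    if process_cv > 0:
        eps = rng.normal(0.0, sigma, n_g)

    floor = 1e-6 * K
    B = np.empty((n_y, n_g))
    C_real = np.empty((n_y, n_g))
    B_now = K.copy()
    n_trunc = 0
    for t in range(n_y):
        B[t] = B_now
        want = catch.iloc[t].to_numpy(dtype=float)
        avail = np.maximum(B_now - floor, 0.0)
        C_t = np.minimum(want, avail)
        if np.any(C_t < want - 1e-12):
            n_trunc += 1
            warnings.warn(
                f"catch truncated to available biomass in year {years[t]}",
                stacklevel=2,
            )
        C_real[t] = C_t
        surplus = r0 * year_mult[t] * B_now * (1.0 - B_now / K)
        B_next = B_now + surplus - C_t
        if process_cv > 0:
            eps = ar1_coef * eps + rng.normal(0.0, innov_sd, n_g)
            B_next = B_next * np.exp(eps - 0.5 * sigma**2)
        B_now = np.maximum(B_next, floor)

    biomass = pd.DataFrame(B, index=years, columns=groups)
    biomass.index.name = "year"
    catch_out = pd.DataFrame(C_real, index=years, columns=groups)
    catch_out.index.name = "year"

    # realised diets: preference rows renormalised over prey still extant
    mean_b = biomass.mean()
    extinct = set(mean_b[mean_b <= 2.0 * float(np.mean(floor))].index)
    diet = diets.copy()
    for prey in diet.columns:
        if prey in extinct:
            diet[prey] = 0.0
    rowsum = diet.sum(axis=1)
    live = rowsum > 0
    diet.loc[live] = diet.loc[live].div(rowsum[live], axis=0)

    return SourceRunOutput(
        biomass=biomass,
        ssb=ssb_fraction * biomass,
        catch=catch_out,
        diet=diet,
        overlap=pd.DataFrame(),
        n_catch_truncations=n_trunc,
    )


def gen_observation_series(
    truth: pd.Series,
    q: float,
    obs_cv: float,
    seed: int,
    kind: str = "survey",
) -> pd.DataFrame:
    """Noisy abundance index: index_t = q * truth_t * exp(eps - cv^2/2).

    eps ~ Normal(0, obs_cv^2), so E[index] = q * truth.  ``kind`` labels
    the series as a fishery-independent survey or a CPUE index.
    """
    if obs_cv < 0:
        raise ValueError("obs_cv must be non-negative")
    if (np.asarray(truth) <= 0).any():
        raise ValueError("truth must be positive")
    if kind not in ("survey", "cpue"):
        raise ValueError(f"unknown index kind: {kind}")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, obs_cv, len(truth)) if obs_cv > 0 else np.zeros(len(truth))
    value = q * np.asarray(truth, dtype=float) * np.exp(eps - 0.5 * obs_cv**2)
    return pd.DataFrame(
        {"year": np.asarray(truth.index), "value": value, "kind": kind,
         "obs_cv": obs_cv}
    )
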