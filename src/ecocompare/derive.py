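"""Turning source-model descriptions into simulator parameters.

The procedures here mirror how a size-based community model is
parameterised from a richer source model: selecting the groups that feed
in a size-based way, deriving the feeding-kernel parameters beta and
sigma from diet links and body masses, collapsing a spatial-overlap
tensor into a normalised interaction matrix, tuning the recruitment
ceilings R_max to match virgin biomasses, converting catch series to
fishing mortalities, shellfish greenweight-to-meatweight conversion, and
perturbing initial conditions for sensitivity ensembles.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import sizespectrum as ss

log = logging.getLogger(__name__)

#: Groups excluded from the size-based model: marine mammals, birds, and
#: the benthic/planktonic invertebrate pools that do not feed by size.
DEFAULT_EXCLUSIONS = (
    "Pinniped",          # fur seals
    "Seabird",
    "Benthic Carniv",
    "Benthic grazer",
    "Carniv Zoo",
    "Deposit feeder",
    "Dredge oysters",
    "Filter other",
    "Invert comm Herb",  # paua, kina
    "Invert comm Scav",  # rock lobster
    "Macrobenth other",
    "MesoZoo",
    "MicroZoo",
    "Mussels",
    "Scallops",
    "Surf clams",
)

#: Shellfish greenweight (shell-on) to meatweight conversion factors.
MEATWEIGHT_FACTORS = {
    "dredge oysters": 0.12,
    "mussels": 0.25,
    "surf clams": 0.18,
}


def filter_size_based_groups(
    roster: pd.DataFrame, exclusions: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Reduce a roster to the groups modelled dynamically by size.

    Keeps the vertebrate groups plus cephalopods (squid and octopus feed
    in a size-based way), then removes the exclusion list (defaulting to
    the mammals, birds and non-size-feeding invertebrates).  The count
    of retained groups is logged.
    """
    if exclusions is None:
        exclusions = DEFAULT_EXCLUSIONS
    known = set(roster["group_id"])
    unknown = set(exclusions) - known
    if unknown:
        raise ValueError(f"exclusion list names unknown groups: {sorted(unknown)}")
    eligible = roster[
        (roster["taxon_class"] == "vertebrate") | (roster["group_id"] == "Cephalopod")
    ]
    out = eligible[~eligible["group_id"].isin(exclusions)].reset_index(drop=True)
    if out.empty:
        warnings.warn("species filter removed every group", stacklevel=2)
    log.info("size-based filter retained %d dynamic species groups", len(out))
    return out


def derive_beta_sigma(
    traits: pd.DataFrame,
    diet_links: pd.DataFrame,
    sigma_min: float = 0.5,
) -> pd.DataFrame:
    """Feeding-kernel parameters from diet links and body masses.

    For each predator, adult mass ratios are w_inf,pred / (0.5 w_inf,prey)
    and juvenile ratios are w_mat,pred / (0.5 w_mat,prey) over its prey
    links (prey mass approximated as half the respective reference mass).
    beta is the mean of all ratios; sigma is log10 of their sample
    standard deviation.  Degenerate cases (fewer than two distinct
    ratios, or sigma <= 0 from a tight ratio spread) fall back to
    ``sigma_min`` with a warning.
    """
    t = traits.set_index("group_id")
    rows = []
    for pred, links in diet_links.groupby("predator"):
        if pred not in t.index:
            raise KeyError(f"predator {pred!r} missing from traits")
        prey_ids = [p for p in links["prey"] if p in t.index]
        if not prey_ids:
            raise ValueError(f"predator {pred!r} has no prey links with traits")
        adult = (t.loc[pred, "w_inf_g"] / (0.5 * t.loc[prey_ids, "w_inf_g"])).to_numpy()
        juv = (t.loc[pred, "w_mat_g"] / (0.5 * t.loc[prey_ids, "w_mat_g"])).to_numpy()
        ratios = np.concatenate([adult, juv])
        beta = float(np.mean(ratios))
        if len(np.unique(np.round(ratios, 12))) < 2:
            warnings.warn(
                f"{pred}: all mass ratios identical; sigma falls back to {sigma_min}",
                stacklevel=2,
            )
            sigma = sigma_min
        else:
            sigma = float(np.log10(np.std(ratios, ddof=1)))
            if sigma <= 0:
                warnings.warn(
                    f"{pred}: log10(sd of ratios) = {sigma:.3f} <= 0; "
                    f"using sigma_min = {sigma_min}",
                    stacklevel=2,
                )
                sigma = sigma_min
        rows.append({"group_id": pred, "beta": beta, "sigma": sigma})
    return pd.DataFrame(rows)


def derive_interaction_matrix(overlap: pd.DataFrame) -> pd.DataFrame:
    """Normalised interaction matrix from a spatial-overlap tensor.

    theta_ij is the mean of the three size-combination overlaps
    (adult-adult, adult-juvenile, juvenile-juvenile) for predator i on
    prey j, then the whole matrix is divided by its maximum so values
    span (0, 1].  An all-zero tensor is returned unnormalised with a
    warning.
    """
    if (overlap["value"] < 0).any() or (overlap["value"] > 1).any():
        raise ValueError("overlap values must lie in [0, 1]")
    mean = overlap.groupby(["predator", "prey"])["value"].mean().unstack()
    mean = mean.fillna(0.0)
    peak = mean.to_numpy().max()
    if peak == 0:
        warnings.warn("all-zero overlap tensor; interaction matrix left at zero",
                      stacklevel=2)
        return mean
    return mean / peak


def calibrate_rmax(
    model: ss.SSModel,
    targets: pd.Series,
    tol: float = 0.05,
    max_iter: int = 25,
    t_run: float = 60.0,
    t_first: float = 120.0,
    delta: float = 0.8,
    dt: float = 0.1,
    max_log_step: float = 2.0,
) -> tuple[pd.Series, dict]:
    """Tune per-species R_max so unfished equilibrium biomass hits targets.

    Iterative multiplicative update on the log scale,
    log R_max += delta (log B_target - log B_model), re-running the model
    to (quasi-)equilibrium between updates (warm-started).  Stops when
    every relative biomass error is below ``tol`` or after ``max_iter``
    iterations.  The report carries the Pearson correlation between log
    target and log achieved biomass and per-species residuals;
    non-convergence is reported, not fatal.
    """
    targets = targets.loc[model.species["group_id"]]
    if (targets <= 0).any():
        raise ValueError("target biomasses must be positive")
    if np.isnan(model.species["R_max"]).any():
        # neutral starting guess scaled by the resource
        model.species["R_max"] = (
            model.resource.kappa * model.species["w_inf_g"] ** -1.0
        )
    state = None
    achieved = None
    converged = False
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        horizon = t_first if it == 0 else t_run
        achieved, state = ss.equilibrium_biomass(model, t_max=horizon, dt=dt, state=state)
        achieved = achieved.clip(lower=1e-300)
        err = np.log(targets.to_numpy()) - np.log(achieved.to_numpy())
        if np.max(np.abs(np.exp(err) - 1.0)) < tol:
            converged = True
            break
        # bound the log-scale step so collapsed species (biomass ~ 0)
        # ramp R_max up gradually instead of overshooting to infinity
        step = np.clip(delta * err, -max_log_step, max_log_step)
        model.species["R_max"] = model.species["R_max"].to_numpy() * np.exp(step)
    log_t, log_a = np.log(targets.to_numpy()), np.log(achieved.to_numpy())
    pearson = float(stats.pearsonr(log_t, log_a)[0]) if len(log_t) > 2 else np.nan
    residuals = pd.Series(
        achieved.to_numpy() / targets.to_numpy() - 1.0, index=targets.index
    )
    if not converged:
        warnings.warn(
            "R_max calibration did not converge; worst residual "
            f"{residuals.abs().max():.2%} ({residuals.abs().idxmax()})",
            stacklevel=2,
        )
    report = {
        "converged": converged,
        "iterations": iterations,
        "pearson_log": pearson,
        "residuals": residuals,
        "achieved": achieved,
    }
    return model.species.set_index("group_id")["R_max"].copy(), report


def f_from_catch(
    catch: pd.Series,
    biomass: pd.Series,
    mode: str = "ratio",
    f_max: float = 2.0,
) -> pd.Series:
    """Fishing mortality from an annual catch and mean-biomass series.

    ``ratio`` mode gives F_t = C_t / B_t; ``baranov`` mode solves
    C = B (1 - exp(-F)) instead.  Catches at or above the biomass (which
    the ratio cannot represent) are capped at ``f_max`` with a warning.
    """
    catch, biomass = catch.align(biomass, join="inner")
    if (biomass <= 0).any():
        raise ValueError("biomass must be positive")
    if (catch < 0).any():
        raise ValueError("catch must be non-negative")
    ratio = catch / biomass
    if mode == "ratio":
        f = ratio
    elif mode == "baranov":
        inner = 1.0 - ratio
        f = pd.Series(
            np.where(inner > 0, -np.log(np.maximum(inner, 1e-300)), np.inf),
            index=ratio.index,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    over = ~np.isfinite(f) | (f > f_max)
    if mode == "ratio":
        over |= ratio > 1.0   # a rate cannot remove more than the stock
    if over.any():
        warnings.warn(
            f"{int(over.sum())} year(s) with catch >= biomass; F capped at {f_max}",
            stacklevel=2,
        )
        f = f.where(~over, f_max)
    return f


def meatweight_from_greenweight(tonnes: float, species: str) -> float:
    """Convert shell-on (greenweight) landings to meatweight tonnes."""
    if tonnes < 0:
        raise ValueError("landings cannot be negative")
    key = species.strip().lower()
    if key not in MEATWEIGHT_FACTORS:
        raise KeyError(
            f"no meatweight conversion for {species!r}; "
            f"known: {sorted(MEATWEIGHT_FACTORS)}"
        )
    return tonnes * MEATWEIGHT_FACTORS[key]


def perturb_initial_conditions(
    state: pd.Series | np.ndarray,
    cv: float,
    n_runs: int,
    seed: int,
) -> list:
    """Mean-preserving multiplicative lognormal perturbations of a state.

    Each run multiplies every element by exp(eps - s^2/2) with
    eps ~ Normal(0, s^2), s = sqrt(ln(1 + cv^2)), so the expected value
    is unchanged and the coefficient of variation across runs is ``cv``.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    base = np.asarray(state, dtype=float)
    s = np.sqrt(np.log(1.0 + cv**2))
    out = []
    for _ in range(n_runs):
        mult = np.exp(rng.normal(0.0, s, base.shape) - 0.5 * s**2) if cv > 0 else np.ones_like(base)
        pert = base * mult
        if isinstance(state, pd.Series):
            pert = pd.Series(pert, index=state.index)
        out.append(pert)
    return out
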