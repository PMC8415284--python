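"""Mass-balanced biomass-pool trophodynamics (Ecopath/Ecosim style).

A snapshot mass balance first solves, for every group, the ecotrophic
efficiency EE (the fraction of production consumed by predators or
caught) and the residual non-predation mortality M0.  Foraging-arena
consumption then drives the pools through time: only a vulnerable
fraction of each prey pool is exposed to each predator, giving
saturating predator functional responses and a baseline equilibrium that
reproduces the balanced snapshot exactly.

Conventions: the diet matrix DC has prey rows and predator columns, each
column summing to 1; a reserved prey id ``IMPORT`` represents diet taken
outside the modelled area.  Biomasses in t/km^2, rates in 1/yr.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

IMPORT_ID = "IMPORT"


@dataclasses.dataclass
class BalanceResult:
    ee: pd.Series            # ecotrophic efficiency per group
    m0: pd.Series            # non-predation mortality rate (1/yr)
    consumption: pd.DataFrame  # baseline Q0, prey x predator (t/km^2/yr)
    unbalanced: list         # groups with EE > 1


@dataclasses.dataclass
class ArenaParams:
    v: pd.DataFrame          # vulnerability exchange rate per link (1/yr)
    a: pd.DataFrame          # effective search rate per link


@dataclasses.dataclass
class PoolRunResult:
    biomass: pd.DataFrame     # year x group
    catch: pd.DataFrame       # year x group (t/km^2/yr removed)
    consumption: pd.DataFrame  # prey x predator, integrated over the run
    n_floor_events: int


def _check_inputs(inputs: pd.DataFrame, dc: pd.DataFrame) -> None:
    required = {"group", "B0", "PB", "QB", "Y0"}
    missing = required - set(inputs.columns)
    if missing:
        raise ValueError(f"ecopath inputs missing columns: {sorted(missing)}")
    groups = inputs["group"].tolist()
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group ids in ecopath inputs")
    consumers = inputs.loc[inputs["QB"].notna() & (inputs["QB"] > 0), "group"]
    for g in consumers:
        if g not in dc.columns:
            raise ValueError(f"consumer {g!r} has no diet column")
        col = dc[g]
        if abs(col.sum() - 1.0) > 1e-9:
            raise ValueError(f"diet column for {g!r} sums to {col.sum():.12f}, not 1")
    bad_prey = set(dc.index) - set(groups) - {IMPORT_ID}
    if bad_prey:
        raise ValueError(f"diet matrix names unknown prey: {sorted(bad_prey)}")


def growth_efficiency(inputs: pd.DataFrame) -> pd.Series:
    """GE = PB/QB for consumers (must lie in (0, 1)); NaN for producers."""
    ge = inputs.set_index("group").eval("PB / QB")
    consumers = ge.notna()
    if ((ge[consumers] <= 0) | (ge[consumers] >= 1)).any():
        bad = ge[consumers][(ge[consumers] <= 0) | (ge[consumers] >= 1)]
        raise ValueError(f"growth efficiency outside (0,1): {bad.to_dict()}")
    return ge


def balance(inputs: pd.DataFrame, dc: pd.DataFrame) -> BalanceResult:
    """Solve the mass balance B0 PB EE = sum_j Q0_ij + Y0 for every group.

    Q0_ij = B0_j QB_j DC_ij is the baseline consumption of prey i by
    predator j.  EE above 1 means more of a group is eaten and caught
    than it produces; those groups are reported in a structured
    ``unbalanced`` list rather than failing silently.
    """
    _check_inputs(inputs, dc)
    idx = inputs.set_index("group")
    groups = idx.index
    q0 = pd.DataFrame(0.0, index=groups, columns=groups)
    for pred in groups:
        qb = idx.loc[pred, "QB"]
        if pred in dc.columns and pd.notna(qb) and qb > 0:
            col = dc[pred].reindex(groups).fillna(0.0)
            q0[pred] = idx.loc[pred, "B0"] * qb * col
    predation = q0.sum(axis=1)
    production = idx["B0"] * idx["PB"]
    if (production <= 0).any():
        raise ValueError("every group needs positive B0 * PB")
    ee = (predation + idx["Y0"].fillna(0.0)) / production
    m0 = idx["PB"] * (1.0 - ee)
    unbalanced = ee[ee > 1.0 + 1e-12].index.tolist()
    if unbalanced:
        warnings.warn(
            "unbalanced groups (EE > 1): "
            + ", ".join(f"{g} (EE={ee[g]:.3f})" for g in unbalanced),
            stacklevel=2,
        )
    return BalanceResult(ee=ee, m0=m0, consumption=q0, unbalanced=unbalanced)


def derive_arena_params(
    inputs: pd.DataFrame,
    bal: BalanceResult,
    v_default: pd.DataFrame | float | None = None,
) -> ArenaParams:
    """Solve each link's search rate so baseline consumption is reproduced.

    Foraging-arena consumption of prey i by predator j is
    Q_ij = a v B_i B_j / (2 v + a B_j): prey exchange in and out of a
    vulnerable pool at rate v, and only that pool is searchable.  Given a
    vulnerability v_ij (default 2 Q0_ij / B0_i, mid-range mixed control),
    a_ij = 2 v Q0 / (B_j (v B_i - Q0)); the arena supremum v B_i must
    exceed Q0, otherwise the link is infeasible and reported fatally.
    """
    if bal.unbalanced:
        raise ValueError(f"cannot derive arena parameters while unbalanced: {bal.unbalanced}")
    idx = inputs.set_index("group")
    groups = idx.index
    q0 = bal.consumption
    b0 = idx["B0"]
    if v_default is None:
        v = 2.0 * q0.div(b0, axis=0)
    elif np.isscalar(v_default):
        v = pd.DataFrame(float(v_default), index=groups, columns=groups).where(q0 > 0, 0.0)
    else:
        v = v_default.reindex(index=groups, columns=groups).fillna(0.0)
    a = pd.DataFrame(0.0, index=groups, columns=groups)
    for prey in groups:
        for pred in groups:
            q = q0.loc[prey, pred]
            if q <= 0:
                continue
            vij = v.loc[prey, pred]
            sup = vij * b0[prey]
            if sup <= q * (1.0 + 1e-12):
                raise ValueError(
                    f"link {prey}->{pred}: baseline consumption {q:.4g} reaches the "
                    f"arena supremum v*B0 = {sup:.4g}; vulnerability too low"
                )
            a.loc[prey, pred] = 2.0 * vij * q / (b0[pred] * (sup - q))
    return ArenaParams(v=v, a=a)


def _consumption(B: np.ndarray, a: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Arena consumption matrix Q_ij at biomasses B (prey rows i)."""
    denom = 2.0 * v + a * B[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = a * v * np.outer(B, B) / denom
    q[a <= 0] = 0.0
    return q


def run_pool(
    inputs: pd.DataFrame,
    dc: pd.DataFrame,
    arena: ArenaParams,
    f_series: pd.DataFrame | None = None,
    years: int = 50,
    start_year: int = 1959,
    substeps: int = 100,
    floor: float = 1e-9,
) -> PoolRunResult:
    """Integrate the pools with annual reporting and RK4 sub-steps.

    dB_i/dt = production_i - predation_i - M0_i B_i - F_i(t) B_i, where
    consumer production is GE_i times total consumption (arena links plus
    import diet, the latter linear in predator biomass), and producer
    production saturates as 2 PB B0 B/(B + B0) so the baseline is an
    equilibrium.  ``f_series`` is year x group F (1/yr); missing years
    and groups use the baseline Y0/B0.  Negative biomasses are floored
    with a warning count.
    """
    bal = balance(inputs, dc)
    idx = inputs.set_index("group")
    groups = idx.index.tolist()
    n = len(groups)
    b0 = idx["B0"].to_numpy(dtype=float)
    pb = idx["PB"].to_numpy(dtype=float)
    qb = idx["QB"].fillna(0.0).to_numpy(dtype=float)
    is_consumer = qb > 0
    ge = np.where(is_consumer, pb / np.where(is_consumer, qb, 1.0), 0.0)
    m0 = bal.m0.to_numpy(dtype=float)
    f_base = (idx["Y0"].fillna(0.0) / idx["B0"]).to_numpy(dtype=float)
    a = arena.a.reindex(index=groups, columns=groups).fillna(0.0).to_numpy()
    v = arena.v.reindex(index=groups, columns=groups).fillna(0.0).to_numpy()
    # import diet: consumption per unit predator biomass
    if IMPORT_ID in dc.index:
        imp = dc.loc[IMPORT_ID].reindex(groups).fillna(0.0).to_numpy() * qb
    else:
        imp = np.zeros(n)

    floor_count = 0

    def rhs(B):
        q = _consumption(B, a, v)
        intake = q.sum(axis=0) + imp * B
        production = np.where(
            is_consumer, ge * intake, 2.0 * pb * b0 * B / (B + b0)
        )
        return production - q.sum(axis=1) - m0 * B - f_now * B, q

    dt = 1.0 / substeps
    B = b0.copy()
    years_idx = np.arange(start_year, start_year + years)
    bio = np.empty((years, n))
    catch = np.empty((years, n))
    q_accum = np.zeros((n, n))
    for yi, year in enumerate(years_idx):
        if f_series is not None and year in f_series.index:
            f_now = (
                f_series.loc[year].reindex(groups).astype(float)
                .fillna(pd.Series(f_base, index=groups)).to_numpy()
            )
        else:
            f_now = f_base
        catch_year = 0.0
        for _ in range(substeps):
            k1, q1 = rhs(B)
            k2, _ = rhs(np.maximum(B + 0.5 * dt * k1, floor))
            k3, _ = rhs(np.maximum(B + 0.5 * dt * k2, floor))
            k4, _ = rhs(np.maximum(B + dt * k3, floor))
            B_new = B + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if (B_new < floor).any():
                floor_count += int((B_new < floor).sum())
                B_new = np.maximum(B_new, floor)
            catch_year = catch_year + f_now * B * dt
            q_accum += q1 * dt
            B = B_new
        bio[yi] = B
        catch[yi] = catch_year
    if floor_count:
        warnings.warn(f"{floor_count} biomass floor event(s) during pool run",
                      stacklevel=2)
    biomass = pd.DataFrame(bio, index=years_idx, columns=groups)
    biomass.index.name = "year"
    catch_df = pd.DataFrame(catch, index=years_idx, columns=groups)
    catch_df.index.name = "year"
    consumption = pd.DataFrame(q_accum, index=groups, columns=groups)
    return PoolRunResult(
        biomass=biomass, catch=catch_df, consumption=consumption,
        n_floor_events=floor_count,
    )


def realised_diet_pool(result: PoolRunResult, inputs: pd.DataFrame,
                       dc: pd.DataFrame) -> pd.DataFrame:
    """Realised diet proportions from integrated consumption.

    Consumption per link is integrated over the reporting window and
    normalised per predator.  Import diet (taken outside the area) is
    included in the normalisation and reported in a separate ``IMPORT``
    row, so columns sum to 1 for every consumer.
    """
    groups = result.consumption.index.tolist()
    q = result.consumption.copy()
    if IMPORT_ID in dc.index:
        idx = inputs.set_index("group")
        qb = idx["QB"].fillna(0.0)
        imp_frac = dc.loc[IMPORT_ID].reindex(groups).fillna(0.0)
        # import consumption integrates qb * frac * B over time
        years = result.biomass.index
        imp_q = (result.biomass.mean() * qb * imp_frac) * len(years)
        q.loc[IMPORT_ID] = imp_q.reindex(groups).fillna(0.0)
    total = q.sum(axis=0)
    consumers = total > 0
    diet = q.copy()
    diet.loc[:, consumers] = q.loc[:, consumers].div(total[consumers], axis=1)
    diet.loc[:, ~consumers] = 0.0
    return diet


def tidy_trajectories(result: PoolRunResult) -> pd.DataFrame:
    """Long-format (year, group, variable, value) view of a pool run."""
    rows = []
    for var, frame in (("biomass", result.biomass), ("yield", result.catch)):
        melted = frame.reset_index().melt(id_vars="year", var_name="group",
                                          value_name="value")
        melted["variable"] = var
        rows.append(melted)
    return pd.concat(rows, ignore_index=True)[["year", "group", "variable", "value"]]
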