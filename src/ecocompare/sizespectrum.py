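"""Deterministic multispecies size-spectrum community model.

Tracks, for each species, an abundance density N_i(w) (individuals per
gram) over a logarithmic body-mass grid, plus a background resource
spectrum N_R(w).  Individuals feed on smaller individuals through a
lognormal mass-ratio kernel, grow with the energy they assimilate,
allocate an increasing share of it to reproduction as they mature, and
die of predation, background mortality, starvation and fishing.  Eggs
enter through a Beverton-Holt recruitment bottleneck.  The dynamics are
integrated with a semi-implicit upwind scheme that is unconditionally
positive.

Units: body mass in grams, time in years, biomass in tonnes (the density
scale is set by the resource coefficient kappa and is calibrated to
source-model biomasses through R_max).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ResourceParams:
    """Background resource spectrum: capacity kappa * w^-lam, semi-chemostat
    regeneration at rate r0 * w^(n-1), zero capacity above w_cut."""

    kappa: float = 0.7e4          # 70 % of the reference coefficient
    kappa_ref: float = 1.0e4      # reference (unreduced) coefficient
    lam: float = 2.05
    r0: float = 10.0
    w_cut: float = 10.0           # g; resource is plankton-sized

    @classmethod
    def reduced(cls, kappa_ref: float = 1.0e4, fraction: float = 0.70, **kw):
        """Resource capacity at a fraction (default 70 %) of a reference."""
        return cls(kappa=fraction * kappa_ref, kappa_ref=kappa_ref, **kw)


@dataclasses.dataclass
class GridParams:
    n_w: int = 130                # species grid points
    w_egg_min: float = 1e-3      # g
    w_max_margin: float = 1.1
    resource_decades: float = 8.0


@dataclasses.dataclass
class Exponents:
    n: float = 2.0 / 3.0          # intake
    p: float = 2.0 / 3.0          # metabolism (p = n keeps ks a pure fraction of h)
    q: float = 2.0 / 3.0          # search volume
    mat_steepness: float = 10.0   # maturity ogive steepness u


class SizeGrid:
    """Log-spaced mass grids: a species grid and a resource extension below it."""

    def __init__(self, w_infs, grid: GridParams | None = None):
        grid = grid or GridParams()
        if grid.n_w < 100:
            warnings.warn("fewer than 100 species grid points", stacklevel=2)
        w_lo = grid.w_egg_min
        w_hi = float(np.max(w_infs)) * grid.w_max_margin
        self.w = np.logspace(np.log10(w_lo), np.log10(w_hi), grid.n_w)
        step = np.log10(self.w[1] / self.w[0])
        n_res = int(np.ceil(grid.resource_decades / step))
        res = w_lo * 10 ** (-step * np.arange(n_res, 0, -1))
        self.w_full = np.concatenate([res, self.w])
        self.n_res = n_res
        # bin widths (forward differences, last bin extrapolated)
        self.dw = np.empty_like(self.w)
        self.dw[:-1] = np.diff(self.w)
        self.dw[-1] = self.dw[-2] * self.w[-1] / self.w[-2]
        self.dw_full = np.empty_like(self.w_full)
        self.dw_full[:-1] = np.diff(self.w_full)
        self.dw_full[-1] = self.dw_full[-2] * self.w_full[-1] / self.w_full[-2]


# --------------------------------------------------------------------------
# physiology
# --------------------------------------------------------------------------

def default_physiology(
    traits: pd.DataFrame,
    f0: float = 0.6,
    alpha: float = 0.6,
    fc: float = 0.0,
    exponents: Exponents | None = None,
    resource: ResourceParams | None = None,
) -> pd.DataFrame:
    """Derive the physiological rate coefficients h, gamma and ks.

    * ``h`` (max intake coefficient) is set so that growth at a constant
      feeding level ``f0`` reproduces the von Bertalanffy rate:
      h = 3 k_vb w_inf^(1/3) / (alpha f0), valid for intake exponent
      n = 2/3.
    * ``ks`` (metabolic coefficient) is the fraction ``fc`` (the critical
      feeding level) of the maximum assimilated intake: ks = fc alpha h.
    * ``gamma`` (search volume) is set so that a species embedded in the
      reference power-law spectrum kappa w^-lam experiences feeding level
      f0 at the 1 g reference mass.

    ``traits`` must carry w_inf_g, k_vb, beta and sigma per group.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie in (0, 1)")
    if not 0 <= fc < f0:
        raise ValueError("critical feeding level fc must lie in [0, f0)")
    ex = exponents or Exponents()
    res = resource or ResourceParams()
    out = traits.copy()
    h = 3.0 * out["k_vb"] * out["w_inf_g"] ** (1.0 / 3.0) / (alpha * f0)
    out["h"] = h
    out["ks"] = fc * alpha * h
    # encounter in a power-law spectrum kappa w^-lam:
    #   E(w) = gamma w^q kappa Phi w^(2-lam),
    #   Phi = sqrt(2 pi) sigma beta^(lam-2) exp((lam-2)^2 sigma^2 / 2)
    lam = res.lam
    phi_int = (
        np.sqrt(2.0 * np.pi)
        * out["sigma"]
        * out["beta"] ** (lam - 2.0)
        * np.exp((lam - 2.0) ** 2 * out["sigma"] ** 2 / 2.0)
    )
    w_ref = 1.0
    e_needed = f0 / (1.0 - f0) * h * w_ref**ex.n
    out["gamma"] = e_needed / (res.kappa * phi_int * w_ref ** (ex.q + 2.0 - lam))
    out["alpha"] = alpha
    out["f0"] = f0
    out["fc"] = fc
    return out


def feeding_kernel(beta, sigma, w_pred, w_prey):
    """Lognormal prey-preference weight in (0, 1].

    phi = exp(-[ln(beta w_prey / w_pred)]^2 / (2 sigma^2)); maximal (=1)
    when the prey is exactly a factor beta smaller than the predator.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("kernel width sigma must be positive")
    if np.any(np.asarray(w_pred) <= 0) or np.any(np.asarray(w_prey) <= 0):
        raise ValueError("masses must be positive")
    z = np.log(np.multiply.outer(1.0 / np.asarray(w_pred, dtype=float), np.asarray(w_prey, dtype=float)) * beta)
    return np.exp(-(z**2) / (2.0 * sigma**2))


def maturity_ogive(w, w_mat, w_inf, n=2.0 / 3.0, steepness=10.0):
    """Fraction of positive net energy allocated to reproduction.

    A smooth sigmoid in w/w_mat (0.5 at maturity) times (w/w_inf)^(1-n);
    the latter factor makes adult growth follow the von Bertalanffy
    form.  Capped at 1, and exactly 1 at or above w_inf.
    """
    w = np.asarray(w, dtype=float)
    sig = 1.0 / (1.0 + (w / w_mat) ** (-steepness))
    psi = sig * (w / w_inf) ** (1.0 - n)
    psi = np.minimum(psi, 1.0)
    psi[w >= w_inf] = 1.0
    return psi


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class SSModel:
    """A parameterised community: species table, interaction matrix,
    resource, grids and precomputed feeding kernels."""

    def __init__(
        self,
        species: pd.DataFrame,
        theta: pd.DataFrame | np.ndarray,
        resource: ResourceParams | None = None,
        grid: GridParams | None = None,
        exponents: Exponents | None = None,
        background_mortality: pd.Series | None = None,
        starvation_coef: float = 1.0,
        sigma_log_base: str = "ln",
    ):
        """``species`` needs columns group_id, w_inf_g, w_mat_g, k_vb, beta,
        sigma, h, gamma, ks, alpha, plus optional w_egg_g, R_max, erepro.

        ``sigma_log_base`` records how the kernel width was derived; the
        width is used directly as the natural-log kernel width either way
        (flagged because a log10-derived width is numerically narrower).
        """
        self.species = species.reset_index(drop=True).copy()
        ns = len(self.species)
        if "w_egg_g" not in self.species:
            self.species["w_egg_g"] = 1e-3
        if "erepro" not in self.species:
            self.species["erepro"] = 1.0
        if "R_max" not in self.species:
            self.species["R_max"] = np.nan
        if (self.species["beta"] <= 1).any():
            raise ValueError("beta must exceed 1 (predators eat smaller prey)")
        theta = (
            theta.loc[self.species["group_id"], self.species["group_id"]].to_numpy()
            if isinstance(theta, pd.DataFrame)
            else np.asarray(theta, dtype=float)
        )
        if theta.shape != (ns, ns) or theta.min() < 0 or theta.max() > 1:
            raise ValueError("theta must be species x species with entries in [0,1]")
        self.theta = theta
        self.resource = resource or ResourceParams()
        self.exponents = exponents or Exponents()
        self.grid = SizeGrid(self.species["w_inf_g"].to_numpy(), grid)
        self.sigma_log_base = sigma_log_base
        if background_mortality is None:
            # the shipped default: a small fraction of the growth rate
            background_mortality = 0.1 * self.species.set_index("group_id")["k_vb"]
        self.mu_b = background_mortality.loc[self.species["group_id"]].to_numpy()
        self.starvation_coef = starvation_coef

        g = self.grid
        ex = self.exponents
        self._w_n = g.w ** ex.n
        self._w_p = g.w ** ex.p
        self._w_q = g.w ** ex.q
        sl = slice(g.n_res, None)
        self._species_slice = sl
        # kernels: phi[i, a, k] over predator sizes a (species grid) and
        # prey sizes k (full grid); store the prey-mass-weighted version
        # for encounter and the raw version for predation mortality.
        beta = self.species["beta"].to_numpy()
        sigma = self.species["sigma"].to_numpy()
        z = np.log(np.multiply.outer(1.0 / g.w, g.w_full))  # ln(w_prey/w_pred)
        self._phi = np.exp(
            -((z[None, :, :] + np.log(beta)[:, None, None]) ** 2)
            / (2.0 * sigma[:, None, None] ** 2)
        )
        self._phi_wdw = self._phi * (g.w_full * g.dw_full)[None, None, :]
        self._psi = np.stack(
            [
                maturity_ogive(
                    g.w, r.w_mat_g, r.w_inf_g, n=ex.n, steepness=ex.mat_steepness
                )
                for r in self.species.itertuples()
            ]
        )
        self._above_winf = g.w[None, :] > self.species["w_inf_g"].to_numpy()[:, None]
        # index of the egg bin per species
        self._egg_idx = np.searchsorted(g.w, self.species["w_egg_g"].to_numpy())
        self.resource_capacity = np.where(
            g.w_full <= self.resource.w_cut,
            self.resource.kappa * g.w_full ** (-self.resource.lam),
            0.0,
        )
        self._res_rate = self.resource.r0 * g.w_full ** (ex.n - 1.0)

    # -- state ------------------------------------------------------------
    def initial_state(self, depletion: float = 0.01) -> "CommunityState":
        """Power-law initial spectra: resource at capacity, each species a
        truncated kappa-scaled power law carrying ``depletion`` of the
        resource-equivalent density."""
        g = self.grid
        ns = len(self.species)
        N = np.zeros((ns, len(g.w)))
        for i, r in enumerate(self.species.itertuples()):
            mask = (g.w >= r.w_egg_g) & (g.w <= r.w_inf_g)
            N[i, mask] = depletion * self.resource.kappa * g.w[mask] ** (-self.resource.lam)
        return CommunityState(N=N, N_R=self.resource_capacity.copy(), t=0.0)

    # -- rates ------------------------------------------------------------
    def encounter_and_feeding_level(self, state):
        """Encounter rate E_i(w) and Holling type-II feeding level f_i(w)."""
        g = self.grid
        ns = len(self.species)
        # community density on the full grid, weighted per predator by theta
        N_full = np.zeros((ns, len(g.w_full)))
        N_full[:, self._species_slice] = state.N
        prey = self.theta @ N_full  # (pred, full grid)
        prey += state.N_R[None, :]
        E = np.einsum("iak,ik->ia", self._phi_wdw, prey)
        E *= self.species["gamma"].to_numpy()[:, None] * self._w_q[None, :]
        intake_max = self.species["h"].to_numpy()[:, None] * self._w_n[None, :]
        f = E / (E + intake_max)
        return E, f

    def energetics(self, f):
        """Net energy, growth rate and reproductive flux density.

        e = alpha f h w^n - ks w^p; positive energy is split by the
        maturity ogive into growth (1 - psi) and reproduction (psi);
        negative energy gives zero growth and starvation mortality.
        """
        sp = self.species
        e = (
            sp["alpha"].to_numpy()[:, None] * f * sp["h"].to_numpy()[:, None] * self._w_n
            - sp["ks"].to_numpy()[:, None] * self._w_p
        )
        e_pos = np.maximum(e, 0.0)
        growth = e_pos * (1.0 - self._psi)
        growth[self._above_winf] = 0.0
        repro_density = e_pos * self._psi
        starvation = self.starvation_coef * np.maximum(-e, 0.0) / self.grid.w[None, :]
        return e, growth, repro_density, starvation

    def predation_pressure(self, state, f):
        """Unsatisfied predator search pressure on the full prey grid.

        P_i(w_prey) = integral (1 - f_i) gamma_i w^q phi_i N_i dw over
        predator sizes; species j then suffers sum_i theta_ij P_i and the
        resource suffers sum_i P_i.
        """
        weight = (
            (1.0 - f)
            * self.species["gamma"].to_numpy()[:, None]
            * self._w_q[None, :]
            * state.N
            * self.grid.dw[None, :]
        )
        return np.einsum("ia,iak->ik", weight, self._phi)

    def mortality(self, state, f, f_rate=None, starvation=None):
        """Total per-species mortality mu_i(w) and resource mortality."""
        P = self.predation_pressure(state, f)
        mu_pred = (self.theta.T @ P)[:, self._species_slice]
        mu = mu_pred + self.mu_b[:, None]
        if starvation is not None:
            mu = mu + starvation
        if f_rate is not None:
            sel = self.grid.w[None, :] >= self.species["w_mat_g"].to_numpy()[:, None]
            mu = mu + np.asarray(f_rate, dtype=float)[:, None] * sel
        mu_resource = P.sum(axis=0)
        return mu, mu_resource

    def recruitment(self, state, repro_density):
        """Beverton-Holt recruitment flux (individuals / yr) per species."""
        sp = self.species
        egg = sp["w_egg_g"].to_numpy()
        rp = (
            sp["erepro"].to_numpy()
            * np.sum(repro_density * state.N * self.grid.dw[None, :], axis=1)
            / (2.0 * egg)
        )
        rmax = sp["R_max"].to_numpy()
        if np.any(~np.isfinite(rmax)) or np.any(rmax <= 0):
            raise ValueError("R_max must be set and positive before running")
        return rmax * rp / (rp + rmax), rp

    # -- integration -------------------------------------------------------
    def step(self, state, dt=0.1, f_rate=None):
        """One semi-implicit upwind step of length dt (years).

        Implicit in mortality, upwind in growth: unconditionally positive.
        The resource relaxes exactly toward its capacity under the current
        predation pressure.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if not (np.all(np.isfinite(state.N)) and np.all(np.isfinite(state.N_R))):
            raise FloatingPointError(
                f"non-finite state at t={state.t:.3f}: "
                f"N range [{np.nanmin(state.N)}, {np.nanmax(state.N)}]"
            )
        _, f = self.encounter_and_feeding_level(state)
        _, growth, repro_density, starv = self.energetics(f)
        mu, mu_res = self.mortality(state, f, f_rate=f_rate, starvation=starv)
        R, _ = self.recruitment(state, repro_density)

        g_grid = self.grid
        dw = g_grid.dw
        N = state.N
        denom = 1.0 + dt * (growth / dw[None, :] + mu)
        N_new = np.empty_like(N)
        inflow = dt * growth[:, :-1] / dw[None, 1:]
        # egg bin: recruitment flux enters the first cell of each species
        src = N.copy()
        egg_cols = self._egg_idx
        src[np.arange(len(R)), egg_cols] += dt * R / dw[egg_cols]
        N_new[:, 0] = src[:, 0] / denom[:, 0]
        for a in range(1, N.shape[1]):
            N_new[:, a] = (src[:, a] + inflow[:, a - 1] * N_new[:, a - 1]) / denom[:, a]

        # resource: exact semi-chemostat relaxation
        rr = self._res_rate
        tot = rr + mu_res
        eq = np.where(tot > 0, rr * self.resource_capacity / np.maximum(tot, 1e-300), 0.0)
        N_R_new = eq + (state.N_R - eq) * np.exp(-tot * dt)

        yield_rate = None
        if f_rate is not None:
            sel = g_grid.w[None, :] >= self.species["w_mat_g"].to_numpy()[:, None]
            yield_rate = np.sum(
                np.asarray(f_rate)[:, None] * sel * N_new * g_grid.w[None, :] * dw[None, :],
                axis=1,
            )
        return CommunityState(N=N_new, N_R=N_R_new, t=state.t + dt), yield_rate

    # -- summaries ---------------------------------------------------------
    def realised_diet(self, state, resource_label: str = "Resource") -> pd.DataFrame:
        """Realised diet proportions by mass consumed, per predator.

        Actual intake f h w^n is apportioned across prey in proportion to
        their contribution to the encounter rate, then integrated over the
        predator's size range and normalised.  The background resource
        appears as its own prey column.
        """
        g = self.grid
        groups = self.species["group_id"].tolist()
        ns = len(groups)
        N_full = np.zeros((ns, len(g.w_full)))
        N_full[:, self._species_slice] = state.N
        # encounter contribution of each prey j (and the resource) per predator i
        enc_by_prey = np.einsum("iak,jk->ija", self._phi_wdw, N_full)
        enc_by_prey = enc_by_prey * self.theta[:, :, None]
        enc_res = np.einsum("iak,k->ia", self._phi_wdw, state.N_R)
        total = enc_by_prey.sum(axis=1) + enc_res
        # feeding level f = E/(E+h w^n); intake density = f h w^n N dw
        E = total * self.species["gamma"].to_numpy()[:, None] * self._w_q[None, :]
        f = E / (E + self.species["h"].to_numpy()[:, None] * self._w_n[None, :])
        weight = np.where(total > 0, f * self.species["h"].to_numpy()[:, None]
                          * self._w_n[None, :] / np.maximum(total, 1e-300), 0.0)
        weight = weight * state.N * g.dw[None, :]
        q_prey = np.einsum("ija,ia->ij", enc_by_prey, weight)
        q_res = np.einsum("ia,ia->i", enc_res, weight)
        diet = pd.DataFrame(q_prey, index=groups, columns=groups)
        diet[resource_label] = q_res
        tot = diet.sum(axis=1)
        live = tot > 0
        diet.loc[live] = diet.loc[live].div(tot[live], axis=0)
        diet.index.name = "predator"
        return diet

    def proportions_at_age(self, state, species_id: str, max_age: int | None = None):
        """Equilibrium proportions-at-age implied by the size spectrum.

        Ages are assigned to masses by integrating dt = dw / g(w) along
        the equilibrium growth curve; abundance is then binned by integer
        age.  Used for the exponential-decay natural-mortality check.
        """
        i = int(self.species.index[self.species["group_id"] == species_id][0])
        _, f = self.encounter_and_feeding_level(state)
        _, growth, _, _ = self.energetics(f)
        g = self.grid
        gg = growth[i]
        with np.errstate(divide="ignore"):
            dt_per_bin = np.where(gg > 0, g.dw / np.maximum(gg, 1e-300), np.inf)
        age = np.concatenate([[0.0], np.cumsum(dt_per_bin)[:-1]])
        numbers = state.N[i] * g.dw
        finite = np.isfinite(age) & (numbers > 0)
        if max_age is None:
            max_age = int(np.ceil(np.nanmax(age[finite]))) if finite.any() else 1
        bins = np.arange(0, max_age + 1)
        counts = np.zeros(len(bins))
        idx = np.clip(np.floor(age[finite]).astype(int), 0, max_age)
        np.add.at(counts, idx, numbers[finite])
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"no abundance for {species_id}")
        return pd.Series(counts / total, index=bins)

    def biomass(self, state):
        """Total biomass per species (same units as kappa; nominally tonnes)."""
        return np.sum(state.N * self.grid.w[None, :] * self.grid.dw[None, :], axis=1)

    def ssb(self, state):
        """Spawning-stock biomass: ogive-weighted biomass per species."""
        return np.sum(
            self._psi * state.N * self.grid.w[None, :] * self.grid.dw[None, :], axis=1
        )


@dataclasses.dataclass
class CommunityState:
    N: np.ndarray      # species x species-grid abundance density
    N_R: np.ndarray    # resource density on the full grid
    t: float


def run(
    model: SSModel,
    years: int,
    dt: float = 0.1,
    f_schedule: pd.DataFrame | None = None,
    state: CommunityState | None = None,
    burn_in: int = 0,
    start_year: int = 1900,
) -> tuple[pd.DataFrame, CommunityState]:
    """Integrate the community and report annual biomass, SSB and yield.

    ``f_schedule`` is year x group fishing mortality (1/yr), knife-edge
    above maturity; None means unfished.  A burn-in of ``burn_in`` years
    (not reported) precedes the ``years`` reported hindcast years
    labelled from ``start_year``.  Returns a tidy frame
    (year, group, variable, value) and the final state.
    """
    state = state or model.initial_state()
    groups = model.species["group_id"].tolist()
    steps_per_year = int(round(1.0 / dt))
    records = []
    zero_f = np.zeros(len(groups))
    for y in range(-burn_in, years):
        year_label = start_year + y
        if f_schedule is not None and year_label in f_schedule.index and y >= 0:
            f_rate = f_schedule.loc[year_label].reindex(groups).fillna(0.0).to_numpy()
        else:
            f_rate = zero_f
        annual_yield = np.zeros(len(groups))
        for _ in range(steps_per_year):
            state, y_rate = model.step(state, dt=dt, f_rate=f_rate)
            if y_rate is not None:
                annual_yield += y_rate * dt
        if y >= 0:
            b = model.biomass(state)
            s = model.ssb(state)
            for gi, g in enumerate(groups):
                records.append((year_label, g, "biomass", b[gi]))
                records.append((year_label, g, "ssb", s[gi]))
                records.append((year_label, g, "yield", annual_yield[gi]))
    traj = pd.DataFrame(records, columns=["year", "group", "variable", "value"])
    return traj, state


def equilibrium_biomass(model: SSModel, t_max: float = 100.0, dt: float = 0.1,
                        state: CommunityState | None = None):
    """Run unfished for t_max years and return final per-species biomass."""
    state = state or model.initial_state()
    for _ in range(int(round(t_max / dt))):
        state, _ = model.step(state, dt=dt)
    return pd.Series(model.biomass(state), index=model.species["group_id"]), state


def grow_at_feeding_level(species_row, ages, f_level=None):
    """Mass-at-age under a pinned feeding level (no community feedback).

    Integrates dw/dt = (alpha f h w^n - ks w^p)(1 - psi(w)) from the egg
    mass; used to check the von Bertalanffy closed-form limit.
    """
    from scipy.integrate import solve_ivp

    r = species_row
    f = r["f0"] if f_level is None else f_level
    n = 2.0 / 3.0

    def rhs(_t, w):
        w = max(w[0], 1e-12)
        e = r["alpha"] * f * r["h"] * w**n - r["ks"] * w**n
        psi = float(maturity_ogive(np.array([w]), r["w_mat_g"], r["w_inf_g"], n=n)[0])
        return [max(e, 0.0) * (1.0 - psi)]

    sol = solve_ivp(
        rhs, (0.0, float(np.max(ages))), [r.get("w_egg_g", 1e-3)],
        t_eval=np.asarray(ages, dtype=float), rtol=1e-8, atol=1e-12,
    )
    return sol.y[0]


def von_bertalanffy_mass(ages, w_inf, k_vb, t_anchor=0.0, w_anchor=None):
    """Closed-form von Bertalanffy mass-at-age, anchored so the curve
    passes through (t_anchor, w_anchor); w(t) = w_inf (1 - c e^(-k t))^3."""
    ages = np.asarray(ages, dtype=float)
    if w_anchor is None:
        c = 1.0
        t0 = 0.0
    else:
        c = 1.0 - (w_anchor / w_inf) ** (1.0 / 3.0)
        t0 = t_anchor
    frac = 1.0 - c * np.exp(-k_vb * (ages - t0))
    return w_inf * np.maximum(frac, 0.0) ** 3
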