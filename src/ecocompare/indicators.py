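"""Ecosystem indicators, sensitivity designs and model-comparison statistics.

Everything downstream of the simulators lives here: trophic levels
solved from diet matrices, prey-category diet summaries, the modified
Kempton's Q diversity index, keystoneness from perturbation experiments,
rank-third agreement between keystone orderings, Spearman diet
comparison with the zero-overlap convention, Pearson skill against
rescaled survey/CPUE indices, between-run CV envelopes, bootstrap and
repeat-year forcing designs, representative-year selection, pairwise
fishing-response correlations, diversity-series scaling, asymptotic
length diagnostics, and proportions-at-age mortality checks.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

BACTERIA_TL = 0.01  # nominal close-to-zero trophic level for bacteria groups


# --------------------------------------------------------------------------
# food-web indicators
# --------------------------------------------------------------------------

def trophic_levels(
    diet: pd.DataFrame,
    producers: set[str] | list[str],
    bacteria: set[str] | list[str] = (),
) -> pd.Series:
    """Trophic levels from a predator x prey diet-proportion matrix.

    Producers are pinned at TL 1, bacteria at the nominal 0.01, and every
    consumer i satisfies TL_i = 1 + sum_j D_ij TL_j (a linear solve).
    Groups appearing only as prey with no diet row are treated as
    producers.  A singular system (pathological cycling) is fatal with a
    diagnostic.
    """
    producers, bacteria = set(producers), set(bacteria)
    groups = list(dict.fromkeys(list(diet.index) + list(diet.columns)))
    d = diet.reindex(index=groups, columns=groups).fillna(0.0)
    pinned = {}
    for g in groups:
        if g in bacteria:
            pinned[g] = BACTERIA_TL
        elif g in producers or d.loc[g].sum() == 0:
            pinned[g] = 1.0
    unknown = [g for g in groups if g not in pinned]
    tl = pd.Series(index=groups, dtype=float)
    for g, v in pinned.items():
        tl[g] = v
    if unknown:
        p_cc = d.loc[unknown, unknown].to_numpy()
        rhs = 1.0 + d.loc[unknown, list(pinned)].to_numpy() @ np.array(
            [pinned[g] for g in pinned]
        )
        mat = np.eye(len(unknown)) - p_cc
        if abs(np.linalg.det(mat)) < 1e-12:
            raise np.linalg.LinAlgError(
                "singular trophic-level system; check for closed diet cycles among "
                + ", ".join(unknown)
            )
        tl[unknown] = np.linalg.solve(mat, rhs)
    return tl


def summarise_prey_categories(
    diet: pd.DataFrame, category_map: pd.DataFrame | dict
) -> pd.DataFrame:
    """Aggregate prey columns of a diet matrix into summary categories.

    Every prey must map to exactly one category; unmapped prey are fatal
    with the offenders listed.  Row sums are preserved.
    """
    if isinstance(category_map, pd.DataFrame):
        category_map = dict(zip(category_map["group_id"], category_map["category"]))
    unmapped = [p for p in diet.columns if p not in category_map]
    if unmapped:
        raise KeyError(f"prey groups without a category: {unmapped}")
    cats = pd.Series({p: category_map[p] for p in diet.columns})
    return diet.T.groupby(cats).sum().T


def kemptons_q(
    biomasses: pd.Series, tls: pd.Series, tl_min: float = 3.0
) -> float:
    """Modified Kempton's Q: interquartile slope of the ranked-biomass
    distribution of upper-trophic-level groups.

    Groups with TL >= tl_min are ranked by descending biomass and
    Q = 0.5 S / log10(B_rank(ceil(S/4)) / B_rank(floor(3S/4))).  Needs at
    least four qualifying groups; equal quartile biomasses make the index
    undefined (NaN, with a warning).
    """
    biomasses, tls = biomasses.align(tls, join="inner")
    keep = biomasses[tls >= tl_min]
    s = len(keep)
    if s < 4:
        raise ValueError(f"Kempton's Q needs >= 4 groups with TL >= {tl_min}; got {s}")
    ranked = np.sort(keep.to_numpy())[::-1]
    upper = ranked[int(np.ceil(0.25 * s)) - 1]
    lower = ranked[int(np.floor(0.75 * s)) - 1]
    if upper <= 0 or lower <= 0 or np.isclose(upper, lower):
        warnings.warn("Kempton's Q undefined: equal or non-positive quartile biomasses",
                      stacklevel=2)
        return float("nan")
    return 0.5 * s / np.log10(upper / lower)


# --------------------------------------------------------------------------
# keystoneness
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ImpactMatrix:
    """Relative biomass responses m_ij of group j to perturbing group i."""

    mean: pd.DataFrame                 # averaged over mortality levels
    per_level: dict                    # level -> matrix
    levels: tuple


def run_perturbation_suite(
    runner,
    groups: list[str],
    levels: tuple[float, ...] = (0.1, 0.005),
    horizon: int = 50,
) -> ImpactMatrix:
    """Press-perturbation impact matrix from repeated model runs.

    ``runner(extra_mortality: dict, horizon)`` must return end-state
    biomass as a Series over ``groups``.  Each group in turn receives
    added natural mortality at each level; the impact of i on j is the
    relative end-state biomass change (B_pert - B_base)/B_base, averaged
    over the levels.  One base run plus one run per (group, level).
    """
    base = runner({}, horizon)
    base = base.loc[groups]
    per_level = {}
    for level in levels:
        m = pd.DataFrame(0.0, index=groups, columns=groups)
        for g in groups:
            try:
                pert = runner({g: level}, horizon)
            except Exception as err:
                raise RuntimeError(
                    f"perturbation run failed for group {g!r} at level {level}"
                ) from err
            if level == 0:
                continue
            m.loc[g] = (pert.loc[groups] - base) / base
        per_level[level] = m
    mean = sum(per_level.values()) / len(per_level)
    return ImpactMatrix(mean=mean, per_level=per_level, levels=tuple(levels))


def keystoneness(impacts: pd.DataFrame, biomasses: pd.Series) -> pd.DataFrame:
    """Keystoneness: KS_i = log10(sqrt(sum_{j != i} m_ij^2) * drank_i).

    ``drank`` is the descending biomass rank (largest biomass gets rank
    1), so high KS flags groups with strong system-wide impact relative
    to their standing stock.  Rank 1 in ``ks_rank`` is the most
    influential; an all-zero impact row yields KS = -inf and is ranked
    last; ties break by group id.
    """
    if impacts.shape[0] != impacts.shape[1]:
        raise ValueError("impact matrix must be square")
    groups = list(impacts.index)
    biomasses = biomasses.loc[groups]
    if (biomasses <= 0).any():
        raise ValueError("biomasses must be positive")
    drank = biomasses.rank(ascending=False, method="first").astype(int)
    m = impacts.to_numpy().copy()
    np.fill_diagonal(m, 0.0)
    overall = np.sqrt((m**2).sum(axis=1))
    with np.errstate(divide="ignore"):
        ks = np.log10(overall * drank.to_numpy())
    table = pd.DataFrame({"ks": ks, "drank": drank.to_numpy()}, index=groups)
    # rank 1 = highest KS; -inf sentinels sort last; ties break by group id
    key = -np.nan_to_num(table["ks"].to_numpy(), neginf=-1e18)
    order = np.lexsort((np.asarray(groups, dtype=object), key))
    ranks = np.empty(len(groups), dtype=int)
    ranks[order] = np.arange(1, len(groups) + 1)
    table["ks_rank"] = ranks
    return table


def classify_rank_thirds(ranks_a: pd.Series, ranks_b: pd.Series) -> dict:
    """Agreement of two rankings at the coarse top/middle/bottom-third level.

    Ranks are split positionally into thirds (sizes as even as possible,
    earlier thirds taking the extra member when n is not divisible by 3;
    rank ties were already resolved upstream).  Returns counts of groups
    in the same third, in opposite thirds (top vs bottom), and other.
    """
    if set(ranks_a.index) != set(ranks_b.index):
        raise ValueError("rankings cover different group sets")
    n = len(ranks_a)
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), 3)]
    bounds = np.cumsum(sizes)

    def third(rank):
        return int(np.searchsorted(bounds, rank, side="left"))

    same = opposite = other = 0
    for g in ranks_a.index:
        ta, tb = third(ranks_a[g]), third(ranks_b[g])
        if ta == tb:
            same += 1
        elif abs(ta - tb) == 2:
            opposite += 1
        else:
            other += 1
    return {"same_third": same, "opposite_thirds": opposite, "other": other}


# --------------------------------------------------------------------------
# comparison statistics
# --------------------------------------------------------------------------

def diet_spearman(
    diet_a: pd.Series,
    diet_b: pd.Series,
    drop_prey: set[str] | list[str] = (),
) -> float:
    """Spearman rank correlation of two diets on a shared prey universe.

    Configured prey (e.g. plankton categories for size-spectrum diets)
    are dropped first; prey absent from both diets are removed; diets
    with no shared nonzero prey get the conventional value -1.
    """
    drop_prey = set(drop_prey)
    a = diet_a.drop(labels=[p for p in drop_prey if p in diet_a.index])
    b = diet_b.drop(labels=[p for p in drop_prey if p in diet_b.index])
    universe = sorted(set(a.index) | set(b.index))
    if not universe:
        raise ValueError("empty prey universe after drops")
    a = a.reindex(universe).fillna(0.0)
    b = b.reindex(universe).fillna(0.0)
    keep = (a > 0) | (b > 0)
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("both diets are empty after dropping shared-zero prey")
    if not ((a > 0) & (b > 0)).any():
        return -1.0
    if len(a) < 2:
        return 1.0  # single shared prey: degenerate full agreement
    rho = stats.spearmanr(a.to_numpy(), b.to_numpy()).statistic
    return float(rho)


def skill_pearson(
    model_series: pd.Series, index_series: pd.Series
) -> tuple[float, pd.Series]:
    """Pearson skill of a model series against an abundance index.

    The index is first rescaled multiplicatively to match the model
    series' mean over the overlapping years (indices are relative, not
    absolute), then Pearson r is computed on the overlap.  Fewer than
    three overlapping years is fatal; zero variance in either series
    gives NaN with a warning.
    """
    m, x = model_series.align(index_series, join="inner")
    if len(m) < 3:
        raise ValueError(f"need >= 3 overlapping years, got {len(m)}")
    if x.mean() == 0:
        raise ValueError("index series has zero mean; cannot rescale")
    rescaled = x * (m.mean() / x.mean())
    if np.isclose(m.std(), 0.0) or np.isclose(x.std(), 0.0):
        warnings.warn("zero variance in skill comparison; r undefined", stacklevel=2)
        return float("nan"), rescaled
    r = float(stats.pearsonr(m.to_numpy(), rescaled.to_numpy())[0])
    return r, rescaled


def make_skill_toy_series(
    r: float, n: int = 11, seed: int = 0, mean: float = 1000.0
) -> tuple[pd.Series, pd.Series]:
    """Construct a (model SSB, survey index) pair with exact Pearson r.

    The survey vector is built from the standardised model vector and an
    orthogonalised noise vector so its sample correlation with the model
    series is exactly ``r``; both series are shifted positive.  Used to
    regression-test the skill statistic against a reference correlation
    table.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=0)
    z = z - z.mean()
    z = z - (z @ x) / (x @ x) * x       # orthogonal to x
    z = z / np.sqrt((z**2).mean())
    y = r * x + np.sqrt(1.0 - r**2) * z
    years = np.arange(2000, 2000 + n)
    model = pd.Series(mean * (1.0 + 0.1 * x), index=years)
    survey = pd.Series(mean * (1.0 + 0.1 * y), index=years)
    return model, survey


def between_run_cv(
    ensemble: list[pd.DataFrame],
    window: tuple[int, int],
    reduce: str = "mean",
) -> pd.Series:
    """Between-run CV per group over a year window.

    For each year in the window the CV of biomass across runs is
    computed (sample sd over mean); the yearly CVs are then reduced over
    the window by their mean (default) or their 90th percentile
    (``reduce='p90'``, the upper-CI convention for repeat-year designs).
    """
    if len(ensemble) < 2:
        raise ValueError("need at least two runs for a between-run CV")
    lo, hi = window
    years = ensemble[0].index
    if lo < years.min() or hi > years.max():
        raise ValueError(f"window {window} outside trajectory span "
                         f"({years.min()}-{years.max()})")
    sel = [df.loc[lo:hi] for df in ensemble]
    stack = np.stack([df.to_numpy() for df in sel])  # run x year x group
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    if np.isnan(cv).any():
        warnings.warn("zero-mean cells in CV computation flagged as NaN", stacklevel=2)
    if reduce == "mean":
        reduced = np.nanmean(cv, axis=0)
    elif reduce == "p90":
        reduced = np.nanpercentile(cv, 90, axis=0)
    else:
        raise ValueError(f"unknown reduction {reduce!r}")
    return pd.Series(reduced, index=sel[0].columns)


# --------------------------------------------------------------------------
# forcing-year experiment designs
# --------------------------------------------------------------------------

def bootstrap_forcing_design(
    library_years: list[int],
    n_runs: int = 50,
    n_years: int = 115,
    burn_in_year: int | None = None,
    burn_in_len: int = 35,
    seed: int = 0,
) -> list[list[int]]:
    """Year sequences for the bootstrap forcing experiment.

    Each of ``n_runs`` sequences repeats the designated burn-in year for
    ``burn_in_len`` years, then draws ``n_years`` library years i.i.d.
    uniformly with replacement.  Deterministic under the seed.
    """
    if len(library_years) < 1:
        raise ValueError("empty forcing library")
    if len(library_years) == 1:
        warnings.warn("single-year forcing library: all bootstrap sequences identical",
                      stacklevel=2)
    if burn_in_year is None:
        burn_in_year = library_years[0]
    rng = np.random.default_rng(seed)
    designs = []
    for _ in range(n_runs):
        draws = rng.choice(library_years, size=n_years, replace=True)
        designs.append([burn_in_year] * burn_in_len + [int(y) for y in draws])
    return designs


def repeat_year_design(
    library_years: list[int], n_years: int = 115, burn_in_len: int = 35
) -> list[list[int]]:
    """One constant-forcing sequence per library year (plus burn-in)."""
    return [[y] * (burn_in_len + n_years) for y in library_years]


def representative_year(forcing: pd.DataFrame) -> tuple[int, pd.DataFrame]:
    """Pick the forcing year closest to the across-year mean seasonal cycle.

    For each year and each variable (temperature anomaly, productivity
    multiplier) the sum of squared monthly deviations from the
    across-year mean cycle is computed, along with the Pearson
    correlation against that mean cycle.  Per-variable SS values are
    min-max scaled and summed; the year with the lowest combined score
    wins (ties go to the earliest year with a warning).
    """
    years = sorted(forcing["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least two forcing years")
    variables = ["temp_anom", "prod_mult"]
    wide = {v: forcing.pivot(index="month", columns="year", values=v) for v in variables}
    rows = []
    for y in years:
        row = {"year": y}
        for v in variables:
            series = wide[v][y]
            mean_cycle = wide[v].mean(axis=1)
            row[f"ss_{v}"] = float(((series - mean_cycle) ** 2).sum())
            sd_s, sd_m = series.std(), mean_cycle.std()
            row[f"r_{v}"] = (
                float(stats.pearsonr(series, mean_cycle)[0])
                if sd_s > 0 and sd_m > 0
                else np.nan
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("year")
    combined = np.zeros(len(years))
    for v in variables:
        ss = table[f"ss_{v}"].to_numpy()
        rng_ = ss.max() - ss.min()
        combined += (ss - ss.min()) / rng_ if rng_ > 0 else np.zeros_like(ss)
    table["combined_ss"] = combined
    best = combined.min()
    winners = [y for y, c in zip(years, combined) if np.isclose(c, best)]
    if len(winners) > 1:
        warnings.warn(f"representative-year tie between {winners}; taking earliest",
                      stacklevel=2)
    return winners[0], table


# --------------------------------------------------------------------------
# cross-model comparison
# --------------------------------------------------------------------------

def response_correlation_matrix(
    trajectories: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Pairwise Pearson correlations of biomass responses per group.

    ``trajectories`` maps model name to a year x group biomass frame.
    For every model pair and every group present in both, Pearson r is
    computed over the overlapping years; groups absent from a model get
    NaN (e.g. invertebrates absent from a fish-only model).
    """
    names = sorted(trajectories)
    all_groups = sorted(set().union(*(t.columns for t in trajectories.values())))
    out = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            ta, tb = trajectories[na], trajectories[nb]
            col = {}
            years = ta.index.intersection(tb.index)
            for g in all_groups:
                if g not in ta.columns or g not in tb.columns or len(years) < 3:
                    col[g] = np.nan
                    continue
                a = ta.loc[years, g].to_numpy()
                b = tb.loc[years, g].to_numpy()
                if np.std(a) == 0 or np.std(b) == 0:
                    col[g] = np.nan
                else:
                    col[g] = float(stats.pearsonr(a, b)[0])
            out[f"{na}_vs_{nb}"] = col
    return pd.DataFrame(out).reindex(all_groups)


def diversity_comparison(
    q_series: dict[str, pd.Series], reference: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale diversity series to a common mean and form ratio series.

    Every model's Kempton's Q series is rescaled multiplicatively so its
    mean over the shared years equals the reference model's mean; the
    ratio of each alternative (scaled) series to the reference is
    returned alongside.  Zero-mean series are fatal.
    """
    if reference not in q_series:
        raise KeyError(f"reference model {reference!r} not in series")
    years = None
    for s in q_series.values():
        years = s.index if years is None else years.intersection(s.index)
    if years is None or len(years) == 0:
        raise ValueError("no overlapping years across diversity series")
    ref_mean = q_series[reference].loc[years].mean()
    scaled = {}
    for name, s in q_series.items():
        m = s.loc[years].mean()
        if m == 0:
            raise ValueError(f"diversity series {name!r} has zero mean")
        scaled[name] = s.loc[years] * (ref_mean / m)
    scaled_df = pd.DataFrame(scaled)
    ratios = pd.DataFrame(
        {name: scaled_df[name] / scaled_df[reference]
         for name in q_series if name != reference}
    )
    return scaled_df, ratios


# --------------------------------------------------------------------------
# calibration diagnostics
# --------------------------------------------------------------------------

def lmax_estimate(
    a_lw: float,
    b_lw: float,
    weights: np.ndarray | None = None,
    spectrum: tuple[np.ndarray, np.ndarray] | None = None,
    mode: str = "p90",
    abundance_threshold: float = 1e-6,
) -> float:
    """Asymptotic-length diagnostic in cm from weights or a size spectrum.

    ``p90`` mode takes the 90th percentile of a weight sample (abundance-
    weighted when a spectrum is given); ``max`` mode takes the largest
    mass whose density exceeds ``abundance_threshold`` times the peak
    density.  Lengths come from L = (w / a_lw)^(1/b_lw).
    """
    if spectrum is not None:
        w, dens = (np.asarray(x, dtype=float) for x in spectrum)
        if not (dens > 0).any():
            raise ValueError("empty spectrum")
        if mode == "max":
            peak = dens.max()
            w_star = w[dens > abundance_threshold * peak].max()
        elif mode == "p90":
            cdf = np.cumsum(dens * w * np.gradient(w))
            cdf /= cdf[-1]
            w_star = float(np.interp(0.9, cdf, w))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    else:
        if weights is None or len(weights) == 0:
            raise ValueError("empty weight sample")
        if mode not in ("p90", "max"):
            raise ValueError(f"unknown mode {mode!r}")
        w_arr = np.asarray(weights, dtype=float)
        w_star = float(np.percentile(w_arr, 90)) if mode == "p90" else w_arr.max()
    return float((w_star / a_lw) ** (1.0 / b_lw))


def mortality_decay_check(
    proportions: pd.Series | np.ndarray, m_lit: float
) -> tuple[float, float]:
    """Fit total mortality from proportions-at-age and compare to the
    literature value.

    Under constant mortality M, proportions-at-age decay as exp(-M age);
    M-hat is the negative least-squares slope of log proportion against
    age over the positive support (a warning notes truncation).  Returns
    (M-hat, M-hat minus m_lit).
    """
    p = np.asarray(proportions, dtype=float)
    ages = (
        np.asarray(proportions.index, dtype=float)
        if isinstance(proportions, pd.Series)
        else np.arange(len(p), dtype=float)
    )
    pos = p > 0
    if pos.sum() < 2:
        raise ValueError("need at least two positive proportions-at-age")
    if not pos.all():
        warnings.warn("zero proportions beyond age 0; fitting on positive support",
                      stacklevel=2)
    slope = np.polyfit(ages[pos], np.log(p[pos]), 1)[0]
    m_hat = float(-slope)
    return m_hat, m_hat - m_lit
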