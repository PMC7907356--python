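"""Evaluated quantities: trophic levels, ranks, lifetimes, SAR, ranges, similarity.

All analyses operate on run outputs (species table, extinction log,
occupancy snapshots, range trajectories); none of them mutates its input.

Conventions
-----------
* Trophic level: 1 + mean trophic level of a species' prey, resource at
  level 0; basal species (feeding on the resource only) sit at level 1.
  Strata are formed by rounding: "basal" = rounded TL 1, "higher" = > 1.
* Lifetime: extinction time minus origination time; species still alive at
  the end of a run are excluded, as their true lifetime is unknown.
* Range: number of occupied habitats; the time-averaged range is the time
  integral of the occupancy step function divided by the lifetime.
* Power-law exponents are estimated by least squares on logarithmically
  binned densities in log-log axes (a visual-slope methodology), with a
  configurable fitting window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .biomass_equilibrium import LocalWeb
from .evolution_engine import Snapshot, round_half_up
from .spatial_lattice import Lattice

__all__ = [
    "trophic_levels",
    "rank_abundance",
    "average_ranks",
    "lifetime_distribution",
    "species_area_relation",
    "similarity_decay",
    "range_size_distribution",
    "classify_range_shape",
    "hat_fractions",
    "extinction_cause_summary",
    "range_lifetime_curve",
    "biomass_ratio",
    "mean_richness",
    "compute_metrics",
]


# -- per-web quantities ----------------------------------------------------


def trophic_levels(web: LocalWeb) -> np.ndarray:
    """Trophic level of every species in the web (resource = 0).

    Solves ``TL_i = 1 + mean_j(TL_j)`` over each species' prey set
    (strength > 0, self-links excluded) as a linear system, which handles
    feeding loops.  Raises if a species has no prey at all — that cannot
    occur in a post-cascade web.
    """
    a = web.matrices.strength
    n = a.shape[0]
    if n == 0:
        return np.zeros(0)
    W = np.zeros((n, n))
    rhs = np.ones(n)
    for i in range(n):
        prey = [j for j in range(n) if j != i and a[i, j + 1] > 0]
        cnt = len(prey) + (1 if a[i, 0] > 0 else 0)
        if cnt == 0:
            raise ValueError(f"species {web.species_ids[i]} has no prey")
        for j in prey:
            W[i, j] = 1.0 / cnt
    return np.linalg.solve(np.eye(n) - W, rhs)


def rank_abundance(web: LocalWeb) -> dict[int, int]:
    """Abundance rank per species: rank 1 = most abundant; ties by smaller id."""
    order = sorted(
        range(len(web)), key=lambda k: (-web.biomasses[k], web.species_ids[k])
    )
    return {web.species_ids[k]: r + 1 for r, k in enumerate(order)}


def average_ranks(snapshot: Snapshot) -> pd.Series:
    """Mean abundance rank of each species over the habitats it occupies."""
    H, S = snapshot.biomass.shape
    rank_sum = np.zeros(S)
    occ = np.zeros(S, dtype=int)
    for h in range(H):
        b = snapshot.biomass[h]
        present = np.flatnonzero(b > 0)
        if present.size == 0:
            continue
        # descending biomass, ties by smaller species id (column order = id order)
        order = present[np.lexsort((snapshot.species_ids[present], -b[present]))]
        for r, col in enumerate(order, start=1):
            rank_sum[col] += r
            occ[col] += 1
    with np.errstate(invalid="ignore"):
        avg = rank_sum / occ
    return pd.Series(avg, index=snapshot.species_ids, name="average_rank")


# -- distribution fitting helpers -----------------------------------------


def log_binned_density(
    values: np.ndarray, bins_per_decade: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram on logarithmic bins, normalized to a probability density."""
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        return np.zeros(0), np.zeros(0)
    lo, hi = v.min(), v.max()
    if lo == hi:
        return np.array([lo]), np.array([np.inf])
    n_bins = max(3, int(np.ceil((np.log10(hi) - np.log10(lo)) * bins_per_decade)))
    edges = np.logspace(np.log10(lo), np.log10(hi) * (1 + 1e-12), n_bins + 1)
    counts, edges = np.histogram(v, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / (widths * v.size)
    return centers, density


def _loglog_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of log10(y) against log10(x)."""
    mask = (x > 0) & (y > 0) & np.isfinite(y)
    if mask.sum() < 2:
        return math.nan
    return float(np.polyfit(np.log10(x[mask]), np.log10(y[mask]), 1)[0])


@dataclass
class PowerLawFit:
    bin_centers: np.ndarray
    density: np.ndarray
    exponent: Optional[float]
    window: Optional[tuple[float, float]]


def lifetime_distribution(
    species: pd.DataFrame,
    established_only: bool = True,
    bins_per_decade: float = 8.0,
    fit_window: Optional[tuple[float, float]] = None,
) -> PowerLawFit:
    """Log-binned lifetime distribution with a fitted power-law exponent.

    Only extinct species enter (alive-at-end lifetimes are unknown); by
    default species that never established are excluded as well.  The
    exponent is the least-squares slope of log density vs log lifetime.
    When no window is given, the two decades ending at the longest
    observed lifetime are used: the short-lifetime side of the
    distribution is a separate regime (species that die before ever
    spreading, flattened further by the discreteness of the event clock),
    and the power law lives in the tail.  With fewer than 50 lifetimes,
    or degenerate support, the distribution is returned without a fit.
    """
    df = species[np.isfinite(species["t_ext"])]
    if established_only:
        df = df[df["established"]]
    lt = df["lifetime"].to_numpy()
    lt = lt[lt > 0]
    centers, density = log_binned_density(lt, bins_per_decade)
    if lt.size < 50 or centers.size < 3 or lt.min() == lt.max():
        return PowerLawFit(centers, density, None, None)
    if fit_window is None:
        fit_window = (lt.max() / 100.0, lt.max())
    sel = (centers >= fit_window[0]) & (centers <= fit_window[1])
    slope = _loglog_slope(centers[sel], density[sel])
    return PowerLawFit(centers, density, slope, fit_window)


# -- spatial analyses ------------------------------------------------------


def species_area_relation(
    snapshots: Sequence[Snapshot],
    lattice: Lattice,
    n_starts: int = 10,
    rng: Optional[np.random.Generator] = None,
    area_window: Optional[tuple[float, float]] = None,
    starts: Optional[Sequence[int]] = None,
) -> tuple[pd.DataFrame, float]:
    """Nested species-area curve and its mid-range log-log slope.

    For each snapshot and each of ``n_starts`` random start habitats
    (or the explicit ``starts`` list), counts distinct species in nested
    shells of increasing radius, then averages over starts and snapshots.
    The slope is fitted over areas in ``area_window`` (default [5, H/4]).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    H = lattice.n_habitats
    max_r = lattice.max_distance()
    # shell sizes are start-independent on a torus
    d0 = lattice.distance_matrix[0]
    areas = np.array([(d0 <= k).sum() for k in range(max_r + 1)])
    curves = []
    for snap in snapshots:
        P = snap.presence
        snap_starts = (
            np.asarray(starts) if starts is not None
            else rng.integers(0, H, size=n_starts)
        )
        counts = np.zeros(max_r + 1)
        for start in snap_starts:
            d = lattice.distance_matrix[start]
            for k in range(max_r + 1):
                counts[k] += P[d <= k].any(axis=0).sum()
        curves.append(counts / len(snap_starts))
    mean_S = np.mean(curves, axis=0)
    df = pd.DataFrame({"area": areas, "species": mean_S})
    if area_window is None:
        area_window = (5.0, H / 4.0)
        if ((areas >= 5.0) & (areas <= H / 4.0)).sum() < 2:
            area_window = (2.0, H / 2.0)  # tiny grids: too few shells mid-range
    sel = (areas >= area_window[0]) & (areas <= area_window[1])
    slope = _loglog_slope(areas[sel].astype(float), mean_S[sel])
    return df, slope


def _jaccard_matrix(P: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity between habitat rows of a presence matrix."""
    P = P.astype(float)
    inter = P @ P.T
    counts = P.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore"):
        jac = inter / union
    return jac  # NaN where both sets empty


def similarity_decay(
    snapshots: Sequence[Snapshot], lattice: Lattice
) -> pd.DataFrame:
    """Mean Jaccard similarity vs toroidal distance, basal and higher strata.

    For each snapshot, the Jaccard index is averaged over all habitat
    pairs at each distance, separately for the basal stratum (rounded
    per-habitat trophic level 1) and all other species; the per-snapshot
    means are then averaged over snapshots, with their standard deviation.
    """
    dmat = lattice.distance_matrix
    max_d = dmat.max()
    per_snap = {"basal": [], "higher": []}
    for snap in snapshots:
        pres = snap.presence
        tl_round = np.where(
            pres, np.floor(snap.trophic_level + 0.5).astype(int), -1
        )
        strata = {"basal": pres & (tl_round == 1), "higher": pres & (tl_round > 1)}
        for name, P in strata.items():
            jac = _jaccard_matrix(P)
            means = np.full(max_d + 1, np.nan)
            for dist in range(1, max_d + 1):
                iu, ju = np.nonzero(np.triu(dmat == dist))
                vals = jac[iu, ju]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    means[dist] = vals.mean()
            per_snap[name].append(means)
    rows = {"distance": np.arange(max_d + 1)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN distances
        for name, arrs in per_snap.items():
            stack = np.vstack(arrs)
            rows[f"jaccard_{name}"] = np.nanmean(stack, axis=0)
            rows[f"jaccard_{name}_std"] = np.nanstd(stack, axis=0)
    return pd.DataFrame(rows).iloc[1:].reset_index(drop=True)


def similarity_plateau(decay: pd.DataFrame, stratum: str, n_far: int = 3) -> float:
    """Mean similarity over the ``n_far`` largest distances (the plateau)."""
    col = f"jaccard_{stratum}"
    vals = decay[col].to_numpy()
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals[-n_far:]))


# -- range analyses --------------------------------------------------------


def _extinct_established(species: pd.DataFrame) -> pd.DataFrame:
    return species[np.isfinite(species["t_ext"]) & species["established"]]


def range_size_distribution(
    species: pd.DataFrame, bins_per_decade: float = 8.0
) -> dict[str, dict[str, PowerLawFit]]:
    """Normalized distributions of time-averaged and maximum range per stratum.

    Strata are basal (rounded origination TL 1) versus all other species;
    each distribution comes with the log-log slope of its log-binned
    density (fitted over the full positive support).
    """
    df = _extinct_established(species)
    tl_round = np.floor(df["origin_tl"] + 0.5)
    out: dict[str, dict[str, PowerLawFit]] = {}
    strata = (
        ("all", np.ones(len(df), dtype=bool)),
        ("basal", (tl_round == 1).to_numpy()),
        ("higher", (tl_round > 1).to_numpy()),
    )
    for name, sel in strata:
        sub = df[sel]
        out[name] = {}
        for kind, col in (("average", "avg_range"), ("maximum", "max_range")):
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals) & (vals > 0)]
            centers, density = log_binned_density(vals, bins_per_decade)
            slope = _loglog_slope(centers, density) if centers.size >= 3 else None
            out[name][kind] = PowerLawFit(centers, density, slope, None)
    return out


def classify_range_shape(
    trajectory: np.ndarray,
    n_habitats: int,
    smooth_frac: float = 0.05,
    prominence_frac: float = 0.10,
    n_samples: int = 200,
    min_range_frac: float = 0.5,
) -> str:
    """Classify a range trajectory as ``"hat"`` or ``"multi_peak"``.

    The event-driven step series is resampled on a uniform time grid,
    smoothed with a moving average window of ``smooth_frac`` of the
    lifetime, and local maxima with prominence of at least
    ``prominence_frac * max_range`` are counted: exactly one prominent
    maximum (including plateaus, e.g. residence at the full grid) is a
    hat.  Only species whose maximum range reached ``min_range_frac`` of
    the grid qualify; others are rejected.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[0] < 2:
        raise ValueError("trajectory must be a (k, 2) array of (time, range)")
    t, c = traj[:, 0], traj[:, 1]
    max_range = c.max()
    if max_range < min_range_frac * n_habitats:
        raise ValueError(
            f"trajectory peaked at {max_range:.0f} habitats, below the "
            f"{min_range_frac:.0%} of grid filter"
        )
    if t[-1] <= t[0]:
        return "hat"  # zero-duration trajectory: trivially unimodal
    grid = np.linspace(t[0], t[-1], n_samples)
    series = c[np.searchsorted(t, grid, side="right") - 1]
    win = max(1, int(round(smooth_frac * n_samples)))
    kernel = np.ones(win) / win
    smooth = np.convolve(series, kernel, mode="same")
    padded = np.concatenate(([-1.0], smooth, [-1.0]))
    peaks, _ = find_peaks(padded, prominence=prominence_frac * max_range)
    return "hat" if peaks.size <= 1 else "multi_peak"


def hat_fractions(
    species: pd.DataFrame,
    trajectories: dict[int, np.ndarray],
    n_habitats: int,
    min_range_frac: float = 0.5,
    smooth_frac: float = 0.05,
    prominence_frac: float = 0.10,
) -> pd.DataFrame:
    """Fraction of hat-shaped range trajectories per trophic stratum.

    Considers extinct, established species whose maximum range reached
    ``min_range_frac`` of the grid, binned by rounded origination trophic
    level.
    """
    df = _extinct_established(species)
    df = df[df["max_range"] >= min_range_frac * n_habitats]
    rows = []
    for _, row in df.iterrows():
        sid = int(row["species_id"])
        if sid not in trajectories:
            continue
        label = classify_range_shape(
            trajectories[sid],
            n_habitats,
            smooth_frac=smooth_frac,
            prominence_frac=prominence_frac,
            min_range_frac=min_range_frac,
        )
        rows.append((round_half_up(row["origin_tl"]), label))
    if not rows:
        return pd.DataFrame(columns=["trophic_level", "n", "hat_fraction"])
    tab = pd.DataFrame(rows, columns=["trophic_level", "shape"])
    out = (
        tab.groupby("trophic_level")["shape"]
        .agg(n="size", hat_fraction=lambda s: (s == "hat").mean())
        .reset_index()
    )
    return out


def range_lifetime_curve(
    species: pd.DataFrame,
    n_habitats: int,
    bin_width: float = 0.055,
    saturation_frac: float = 0.25,
    floor_range: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """Binned mean time-averaged range vs lifetime, with the growth-regime slope.

    Lifetimes are binned with width ``bin_width`` in log10; the log-log
    slope is fitted over bins whose mean range lies between
    ``floor_range`` and ``saturation_frac * H``.  The excluded ends are
    separate regimes: below the floor, short-lived species sit at the
    single-habitat minimum regardless of lifetime; above the cap the
    curve already bends toward the system-size plateau (on the torus a
    patch of H/4 habitats spans half the lattice diameter).
    """
    df = _extinct_established(species)
    lt = df["lifetime"].to_numpy(dtype=float)
    ar = df["avg_range"].to_numpy(dtype=float)
    ok = (lt > 0) & np.isfinite(ar) & (ar > 0)
    lt, ar = lt[ok], ar[ok]
    if lt.size == 0:
        return pd.DataFrame(columns=["lifetime", "mean_avg_range", "n"]), math.nan
    logs = np.log10(lt)
    start = np.floor(logs.min() / bin_width) * bin_width
    idx = np.floor((logs - start) / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        center = 10 ** (start + (b + 0.5) * bin_width)
        rows.append((center, ar[sel].mean(), int(sel.sum())))
    curve = pd.DataFrame(rows, columns=["lifetime", "mean_avg_range", "n"])
    unsat = curve[
        (curve["mean_avg_range"] < saturation_frac * n_habitats)
        & (curve["mean_avg_range"] >= floor_range)
    ]
    slope = _loglog_slope(
        unsat["lifetime"].to_numpy(), unsat["mean_avg_range"].to_numpy()
    )
    return curve, slope


# -- extinction causes -----------------------------------------------------


def extinction_cause_summary(extinctions: pd.DataFrame) -> pd.DataFrame:
    """Fractions of extinction causes per victim trophic level.

    Causes are the cross of trigger (local speciation vs immigration) and
    relation (same_level / level_below / level_above / secondary); victims
    are binned by their rounded trophic level at death.  Fractions sum to
    1 within each trophic level.
    """
    if extinctions.empty:
        raise ValueError("no extinction records")
    df = extinctions.copy()
    df["cause"] = df["trigger"].str.replace("local_speciation", "local") + ":" + df[
        "relation"
    ]
    tab = pd.crosstab(df["victim_tl"], df["cause"], normalize="index")
    tab.index.name = "trophic_level"
    return tab


# -- run-level summaries ---------------------------------------------------


def mean_richness(richness: pd.DataFrame, burn_in_frac: float = 0.5) -> float:
    """Time-averaged per-habitat species count after a burn-in fraction."""
    t_end = richness["time"].max()
    post = richness[richness["time"] >= burn_in_frac * t_end]
    return float(post["mean_richness"].mean())


def biomass_ratio(snapshots: Sequence[Snapshot], burn_in_frac: float = 0.5) -> float:
    """Median max/min biomass ratio within local communities (post-burn-in snapshots)."""
    if not snapshots:
        return math.nan
    t_end = max(s.time for s in snapshots)
    ratios = []
    for snap in snapshots:
        if snap.time < burn_in_frac * t_end:
            continue
        for h in range(snap.biomass.shape[0]):
            b = snap.biomass[h]
            b = b[b > 0]
            if b.size >= 2:
                ratios.append(b.max() / b.min())
    return float(np.median(ratios)) if ratios else math.nan


def _json_safe(x):
    if isinstance(x, float) and not math.isfinite(x):
        return None
    return x


def compute_metrics(outputs, sar_rng_seed: int = 0) -> dict:
    """Headline metrics of one run, JSON-serializable (used by the CLI)."""
    lattice = outputs.lattice
    H = lattice.n_habitats
    lt_fit = lifetime_distribution(outputs.species)
    sar_df, sar_slope = species_area_relation(
        outputs.snapshots, lattice, rng=np.random.default_rng(sar_rng_seed)
    )
    decay = similarity_decay(outputs.snapshots, lattice)
    rl_curve, rl_slope = range_lifetime_curve(outputs.species, H)
    rsd = range_size_distribution(outputs.species)
    metrics = {
        "mean_local_richness": mean_richness(outputs.richness),
        "lifetime_exponent": lt_fit.exponent,
        "sar_slope": sar_slope,
        "similarity_plateau_basal": similarity_plateau(decay, "basal"),
        "similarity_plateau_higher": similarity_plateau(decay, "higher"),
        "range_lifetime_slope": rl_slope,
        "biomass_ratio_median": biomass_ratio(outputs.snapshots),
        "rsd_slope_average_range": rsd["all"]["average"].exponent,
        "n_species_total": int(len(outputs.species)),
        "n_extinct_established": int(len(_extinct_established(outputs.species))),
    }
    if outputs.trajectories is not None:
        hats = hat_fractions(outputs.species, outputs.trajectories, H)
        metrics["hat_fractions"] = {
            int(r["trophic_level"]): float(r["hat_fraction"])
            for _, r in hats.iterrows()
        }
        metrics["hat_sample_sizes"] = {
            int(r["trophic_level"]): int(r["n"]) for _, r in hats.iterrows()
        }
    return {k: _json_safe(v) for k, v in metrics.items()}
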