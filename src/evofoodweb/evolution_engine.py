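"""The evolutionary event loop on the lattice metacommunity.

Two kinds of events act on the metacommunity: **speciation** (a randomly
chosen habitat picks a uniformly random resident as parent; the child's
traits are drawn from intervals around the parent's) and **dispersal** (a
source population is chosen with probability proportional to its local
biomass density, and the species is copied to a uniformly random one of
the four neighboring habitats).  The average speciation rate per habitat
is fixed at 1 and serves as the unit of time; each event is dispersal with
probability ``d / (1 + d)``, so on average ``d`` dispersal events fall
between consecutive speciation events.  The clock advances by ``1/H`` per
speciation event only, making "time" exactly "speciation events per
habitat".

After every insertion the affected habitat is re-equilibrated and the
extinction cascade applied; all removals of previously established
populations are recorded with their trigger (local speciation vs
immigration) and their trophic relation to the triggering species.

Child traits (natural logs throughout):

* ``m_child`` uniform in ``[m_parent - ln q, m_parent + ln q]``
* ``f_child`` uniform in ``[m_child - dm1, m_child - dm2]`` (independent of parent)
* ``s_child`` uniform in ``[s_min, s_max]``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from .spatial_lattice import Lattice
from .trophic_network import Resource, SpeciesTraits, build_matrices
from .biomass_equilibrium import LocalWeb, solve_equilibrium

__all__ = [
    "SimulationConfig",
    "SpeciesHistory",
    "MetacommunityState",
    "Snapshot",
    "RunOutputs",
    "initialize",
    "draw_event",
    "speciation_event",
    "dispersal_event",
    "classify_relation",
    "run",
]

TRIGGER_LOCAL = "local_speciation"
TRIGGER_IMMIGRATION = "immigration"

RELATIONS = ("same_level", "level_below", "level_above", "secondary")


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (used for trophic levels)."""
    return int(math.floor(x + 0.5))


@dataclass
class SimulationConfig:
    """All model parameters plus run controls.

    Defaults are the reference parameter set used throughout: transfer
    efficiency ``lambda = 0.65``, competition strength ``delta = 0.25``,
    resource amount ``R = 25`` per habitat, speciation width ``q = 5``
    (child body mass within a factor q of the parent), feeding-center
    offsets ``dm1 = 3, dm2 = 1``, feeding-width interval ``[0.5, 1]``,
    dispersal rate ``d = 10``, extinction threshold 1, and kernel cutoff
    constant 2.  ``steps`` counts speciation events per habitat.
    """

    efficiency: float = 0.65
    competition_delta: float = 0.25
    resource: float = 25.0
    speciation_width: float = 5.0
    dm1: float = 3.0
    dm2: float = 1.0
    s_min: float = 0.5
    s_max: float = 1.0
    dispersal_rate: float = 10.0
    width: int = 10
    height: int = 10
    steps: float = 1e5
    extinction_threshold: float = 1.0
    cutoff: float = 1.0
    seed: int = 0
    snapshots: int = 10
    founder_m: float = 2.0
    founder_f: float = 0.0
    founder_s: float = 0.75
    disperser_selection: str = "biomass"  # or "uniform"
    batch_removal: bool = False
    record_events: bool = True
    record_trajectories: bool = True

    def validate(self) -> None:
        if not 0 < self.efficiency < 1:
            raise ValueError("efficiency must be in (0, 1)")
        if not self.competition_delta > 0:
            raise ValueError("competition_delta must be positive")
        if not self.resource > 0:
            raise ValueError("resource must be positive")
        if not self.speciation_width > 1:
            raise ValueError("speciation_width must exceed 1")
        if not (self.dm1 > self.dm2 >= 1):
            raise ValueError("need dm1 > dm2 >= 1")
        if not (0 < self.s_min <= self.s_max):
            raise ValueError("need 0 < s_min <= s_max")
        if self.dispersal_rate < 0:
            raise ValueError("dispersal_rate must be >= 0")
        if self.width < 2 or self.height < 2:
            raise ValueError("lattice must be at least 2x2")
        if not self.steps > 0:
            raise ValueError("steps must be positive")
        if not self.extinction_threshold > 0:
            raise ValueError("extinction_threshold must be positive")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if self.snapshots < 1:
            raise ValueError("need at least one snapshot")
        if self.disperser_selection not in ("biomass", "uniform"):
            raise ValueError("disperser_selection must be 'biomass' or 'uniform'")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def lattice(self) -> Lattice:
        return Lattice(self.width, self.height)

    @property
    def resource_obj(self) -> Resource:
        return Resource(log_body_mass=0.0, amount_per_habitat=self.resource)


class SpeciesHistory:
    """Per-species bookkeeping: traits, origination/extinction, occupancy."""

    __slots__ = (
        "species_id",
        "parent_id",
        "m",
        "f",
        "s",
        "t_orig",
        "t_ext",
        "established",
        "origin_tl",
        "count",
        "max_range",
        "integral",
        "last_t",
        "trajectory",
    )

    def __init__(self, species_id, parent_id, m, f, s, t_orig, keep_traj):
        self.species_id = species_id
        self.parent_id = parent_id
        self.m = m
        self.f = f
        self.s = s
        self.t_orig = t_orig
        self.t_ext = math.nan
        self.established = False
        self.origin_tl = math.nan
        self.count = 0
        self.max_range = 0
        self.integral = 0.0  # time integral of the occupancy step function
        self.last_t = t_orig
        self.trajectory: Optional[list] = [] if keep_traj else None

    @property
    def traits(self) -> SpeciesTraits:
        return SpeciesTraits(self.m, self.f, self.s)

    def change_count(self, t: float, delta: int) -> None:
        self.integral += self.count * (t - self.last_t)
        self.last_t = t
        self.count += delta
        if self.count > self.max_range:
            self.max_range = self.count
        if self.trajectory is not None:
            self.trajectory.append((t, self.count))
        if self.count == 0:
            self.t_ext = t

    @property
    def lifetime(self) -> float:
        return self.t_ext - self.t_orig

    @property
    def avg_range(self) -> float:
        """Time-averaged occupied habitat count over the species' lifetime."""
        lt = self.lifetime
        return self.integral / lt if lt > 0 else math.nan


@dataclass
class Snapshot:
    """Occupancy, biomass and per-habitat trophic level at one time point."""

    time: float
    species_ids: np.ndarray  # (S,) global ids of species alive anywhere
    biomass: np.ndarray  # (H, S); 0 where absent
    trophic_level: np.ndarray  # (H, S); 0 where absent

    @property
    def presence(self) -> np.ndarray:
        return self.biomass > 0


class MetacommunityState:
    """Lattice of local webs plus the global species registry and clock."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.lattice = config.lattice
        H = self.lattice.n_habitats
        self.clock = 0.0
        self.next_id = 1
        self.registry: dict[int, SpeciesHistory] = {}
        self.ids: list[list[int]] = [[] for _ in range(H)]
        self.m: list[list[float]] = [[] for _ in range(H)]
        self.f: list[list[float]] = [[] for _ in range(H)]
        self.s: list[list[float]] = [[] for _ in range(H)]
        self.B: list[np.ndarray] = [np.zeros(0) for _ in range(H)]
        self.idset: list[set[int]] = [set() for _ in range(H)]
        self.total_B = np.zeros(H)
        self.extinction_log: list[tuple] = []
        self.event_log: list[tuple] = []
        self.n_speciation_events = 0
        self.n_dispersal_events = 0

    # -- views -------------------------------------------------------------

    @property
    def n_habitats(self) -> int:
        return self.lattice.n_habitats

    def alive_species(self) -> set[int]:
        alive: set[int] = set()
        for sset in self.idset:
            alive |= sset
        return alive

    def richness(self) -> np.ndarray:
        return np.array([len(ids) for ids in self.ids])

    def local_web(self, habitat: int) -> LocalWeb:
        """Materialize one habitat as a LocalWeb (reference representation)."""
        cfg = self.config
        traits = [
            SpeciesTraits(m, f, s)
            for m, f, s in zip(self.m[habitat], self.f[habitat], self.s[habitat])
        ]
        mats = build_matrices(traits, cfg.resource_obj, cfg.competition_delta, cfg.cutoff)
        return LocalWeb(
            species_ids=list(self.ids[habitat]),
            traits=traits,
            matrices=mats,
            biomasses=self.B[habitat].copy(),
            resource=cfg.resource_obj,
        )

    # -- core insertion ----------------------------------------------------

    def _insert_and_settle(
        self, habitat: int, sid: int, m: float, f: float, s: float, trigger: str
    ) -> str:
        """Insert a species, re-equilibrate, cascade, and record the outcome.

        Returns the event outcome: "established" or "failed".
        """
        cfg = self.config
        ids_h = self.ids[habitat]
        pre_n = len(ids_h)
        ids_h.append(sid)
        self.m[habitat].append(m)
        self.f[habitat].append(f)
        self.s[habitat].append(s)

        m_arr = np.asarray(self.m[habitat])
        f_arr = np.asarray(self.f[habitat])
        s_arr = np.asarray(self.s[habitat])
        id_arr = np.asarray(ids_h, dtype=np.int64)
        a = _kernel.strength_matrix_nb(m_arr, f_arr, s_arr, cfg.cutoff)
        B, active, removed_idx, removed_B, removed_round = _kernel.cascade_nb(
            a,
            id_arr,
            cfg.efficiency,
            cfg.competition_delta,
            cfg.resource,
            cfg.extinction_threshold,
            cfg.batch_removal,
        )

        new_tl = math.nan
        if removed_idx.size or trigger == TRIGGER_LOCAL:
            all_active = np.ones(pre_n + 1, dtype=bool)
            tl_post = _kernel.trophic_levels_nb(a, all_active)
            new_tl = float(tl_post[pre_n])
        if removed_idx.size:
            pre_active = np.ones(pre_n + 1, dtype=bool)
            pre_active[pre_n] = False
            tl_pre = _kernel.trophic_levels_nb(a, pre_active)

        t = self.clock
        newcomer_rec = self.registry[sid]
        if trigger == TRIGGER_LOCAL and math.isfinite(new_tl):
            newcomer_rec.origin_tl = new_tl

        for vic, vic_B, order in zip(removed_idx, removed_B, removed_round):
            vic = int(vic)
            order = int(order)
            vic_sid = ids_h[vic]
            if vic_sid == sid:
                continue  # failed newcomer: not an extinction of an established population
            vic_tl = float(tl_pre[vic])
            relation = classify_relation(new_tl, vic_tl, order)
            self.extinction_log.append(
                (t, vic_sid, habitat, trigger, relation, round_half_up(vic_tl))
            )
            rec = self.registry[vic_sid]
            self.idset[habitat].discard(vic_sid)
            rec.change_count(t, -1)

        survived = bool(active[pre_n])
        if survived:
            newcomer_rec.established = True
            self.idset[habitat].add(sid)
            newcomer_rec.change_count(t, +1)

        # compact the habitat arrays down to the survivors
        keep = np.flatnonzero(active)
        self.ids[habitat] = [ids_h[k] for k in keep]
        self.m[habitat] = [self.m[habitat][k] for k in keep]
        self.f[habitat] = [self.f[habitat][k] for k in keep]
        self.s[habitat] = [self.s[habitat][k] for k in keep]
        self.B[habitat] = B[keep]
        self.total_B[habitat] = self.B[habitat].sum()
        return "established" if survived else "failed"


def classify_relation(
    new_species_tl: float, extinct_species_tl: float, cascade_iteration: int
) -> str:
    """Trophic relation of an extinction to the event that triggered it.

    Secondary extinctions (cascade iteration >= 2) are labelled as such
    regardless of levels; otherwise the comparison of rounded trophic
    levels is expressed relative to the extinct species: a victim one
    level below the newcomer is ``level_below``.
    """
    if cascade_iteration >= 2:
        return "secondary"
    if not (math.isfinite(new_species_tl) and math.isfinite(extinct_species_tl)):
        return "same_level"
    new_r = round_half_up(new_species_tl)
    vic_r = round_half_up(extinct_species_tl)
    if vic_r == new_r:
        return "same_level"
    return "level_below" if vic_r < new_r else "level_above"


# -- public operations -----------------------------------------------------


def initialize(config: SimulationConfig) -> MetacommunityState:
    """Set up the lattice with the resource and one founder species everywhere.

    The same founder species (id 1) is placed on every habitat; it feeds on
    the resource and equilibrates to biomass R on each habitat.
    """
    state = MetacommunityState(config)
    founder = SpeciesHistory(
        species_id=1,
        parent_id=0,
        m=config.founder_m,
        f=config.founder_f,
        s=config.founder_s,
        t_orig=0.0,
        keep_traj=config.record_trajectories,
    )
    founder.established = True
    founder.origin_tl = 1.0
    state.registry[1] = founder
    state.next_id = 2
    H = state.n_habitats
    for h in range(H):
        state.ids[h] = [1]
        state.m[h] = [config.founder_m]
        state.f[h] = [config.founder_f]
        state.s[h] = [config.founder_s]
        web = state.local_web(h)
        state.B[h] = solve_equilibrium(web, config.efficiency)
        state.total_B[h] = state.B[h].sum()
        state.idset[h] = {1}
    founder.count = H
    founder.max_range = H
    if founder.trajectory is not None:
        founder.trajectory.append((0.0, H))
    return state


def draw_event(
    state: MetacommunityState, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """Draw the next event type: dispersal with probability d/(1+d)."""
    d = config.dispersal_rate
    return "dispersal" if rng.random() < d / (1.0 + d) else "speciation"


def speciation_event(
    state: MetacommunityState, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """One speciation event: uniform habitat, uniform parent, child traits drawn.

    The clock advances by 1/H.  Returns the outcome string.
    """
    H = state.n_habitats
    for _ in range(100 * H):
        h = int(rng.random() * H)
        if state.ids[h]:
            break
    else:
        raise RuntimeError("all habitats are empty; no parent available")
    pos = int(rng.random() * len(state.ids[h]))
    m_p = state.m[h][pos]
    parent_id = state.ids[h][pos]
    lnq = math.log(config.speciation_width)
    m_c = m_p + (2.0 * rng.random() - 1.0) * lnq
    f_c = m_c - config.dm1 + rng.random() * (config.dm1 - config.dm2)
    s_c = config.s_min + rng.random() * (config.s_max - config.s_min)

    state.n_speciation_events += 1
    state.clock = state.n_speciation_events / H

    sid = state.next_id
    state.next_id += 1
    state.registry[sid] = SpeciesHistory(
        sid, parent_id, m_c, f_c, s_c, state.clock, config.record_trajectories
    )
    outcome = state._insert_and_settle(h, sid, m_c, f_c, s_c, TRIGGER_LOCAL)
    if config.record_events:
        state.event_log.append((state.clock, "speciation", h, h, sid, outcome))
    return outcome


def dispersal_event(
    state: MetacommunityState, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """One dispersal event: a biomass-weighted source population spreads to a neighbor.

    If the species is already present on the target habitat nothing changes
    (the event is still consumed).  Otherwise the species is inserted, the
    target re-equilibrated, and the cascade applied; the immigrant itself
    may fail.
    """
    state.n_dispersal_events += 1
    total = state.total_B.sum()
    if total <= 0:
        return "no_source"
    if config.disperser_selection == "biomass":
        r = rng.random() * total
        cum = np.cumsum(state.total_B)
        h = int(np.searchsorted(cum, r, side="right"))
        h = min(h, state.n_habitats - 1)
        Bh = state.B[h]
        r2 = rng.random() * Bh.sum()
        pos = int(np.searchsorted(np.cumsum(Bh), r2, side="right"))
        pos = min(pos, len(Bh) - 1)
    else:  # uniform over populations
        sizes = np.array([len(ids) for ids in state.ids])
        npop = sizes.sum()
        if npop == 0:
            return "no_source"
        k = int(rng.random() * npop)
        h = int(np.searchsorted(np.cumsum(sizes), k, side="right"))
        pos = k - int(np.cumsum(sizes)[h - 1]) if h > 0 else k
    sid = state.ids[h][pos]
    target = int(state.lattice.neighbor_table[h, int(rng.random() * 4)])
    if sid in state.idset[target]:
        outcome = "already_present"
    else:
        outcome = state._insert_and_settle(
            target,
            sid,
            state.m[h][pos],
            state.f[h][pos],
            state.s[h][pos],
            TRIGGER_IMMIGRATION,
        )
    if config.record_events:
        state.event_log.append(
            (state.clock, "dispersal", h, target, sid, outcome)
        )
    return outcome


# -- full run --------------------------------------------------------------


@dataclass
class RunOutputs:
    """Everything a run produces, in memory."""

    config: SimulationConfig
    species: pd.DataFrame
    extinctions: pd.DataFrame
    richness: pd.DataFrame
    snapshots: list[Snapshot]
    events: Optional[pd.DataFrame]
    trajectories: Optional[dict[int, np.ndarray]]
    state: MetacommunityState = field(repr=False)

    @property
    def lattice(self) -> Lattice:
        return self.config.lattice


def take_snapshot(state: MetacommunityState) -> Snapshot:
    """Capture occupancy, biomass and per-habitat trophic levels."""
    cfg = state.config
    alive = sorted(state.alive_species())
    col = {sid: k for k, sid in enumerate(alive)}
    H = state.n_habitats
    S = len(alive)
    biomass = np.zeros((H, S))
    tl = np.zeros((H, S))
    for h in range(H):
        n = len(state.ids[h])
        if n == 0:
            continue
        a = _kernel.strength_matrix_nb(
            np.asarray(state.m[h]), np.asarray(state.f[h]), np.asarray(state.s[h]),
            cfg.cutoff,
        )
        tl_h = _kernel.trophic_levels_nb(a, np.ones(n, dtype=bool))
        for k, sid in enumerate(state.ids[h]):
            biomass[h, col[sid]] = state.B[h][k]
            tl[h, col[sid]] = tl_h[k]
    return Snapshot(
        time=state.clock,
        species_ids=np.asarray(alive, dtype=np.int64),
        biomass=biomass,
        trophic_level=tl,
    )


def _species_frame(state: MetacommunityState) -> pd.DataFrame:
    rows = []
    for sid, rec in state.registry.items():
        rows.append(
            (
                sid,
                rec.parent_id,
                rec.m,
                rec.f,
                rec.s,
                rec.t_orig,
                rec.t_ext,
                rec.established,
                rec.origin_tl,
                rec.max_range,
                rec.avg_range,
                rec.lifetime,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "parent_id",
            "m",
            "f",
            "s",
            "t_orig",
            "t_ext",
            "established",
            "origin_tl",
            "max_range",
            "avg_range",
            "lifetime",
        ],
    )


def run(config: SimulationConfig, progress: bool = False) -> RunOutputs:
    """Execute a full simulation: ``steps * H`` speciation events with dispersal.

    Snapshots of occupancy/biomass are taken after each ``1/snapshots``
    fraction of the simulation time; mean per-habitat richness is sampled
    once per time unit.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = initialize(config)
    H = state.n_habitats
    total = int(round(config.steps * H))
    snap_marks = [
        int(round(total * k / config.snapshots)) for k in range(1, config.snapshots + 1)
    ]
    snap_ptr = 0
    snapshots: list[Snapshot] = []
    rich_t = [0.0]
    rich_v = [float(np.mean(state.richness()))]
    p_disp = config.dispersal_rate / (1.0 + config.dispersal_rate)

    while state.n_speciation_events < total:
        if rng.random() < p_disp:
            dispersal_event(state, config, rng)
        else:
            speciation_event(state, config, rng)
            ns = state.n_speciation_events
            if ns % H == 0:
                rich_t.append(state.clock)
                rich_v.append(float(np.mean(state.richness())))
                if progress and (ns // H) % 100 == 0:
                    print(
                        f"t={state.clock:.0f}/{config.steps:.0f} "
                        f"richness={rich_v[-1]:.1f} species_total={state.next_id - 1}"
                    )
            while snap_ptr < len(snap_marks) and ns >= snap_marks[snap_ptr]:
                snapshots.append(take_snapshot(state))
                snap_ptr += 1

    extinctions = pd.DataFrame(
        state.extinction_log,
        columns=["time", "species_id", "habitat", "trigger", "relation", "victim_tl"],
    )
    events = None
    if config.record_events:
        events = pd.DataFrame(
            state.event_log,
            columns=["time", "event_type", "source_habitat", "target_habitat",
                     "species_id", "outcome"],
        )
    trajectories = None
    if config.record_trajectories:
        trajectories = {
            sid: np.asarray(rec.trajectory, dtype=float)
            for sid, rec in state.registry.items()
            if rec.trajectory
        }
    richness = pd.DataFrame({"time": rich_t, "mean_richness": rich_v})
    return RunOutputs(
        config=config,
        species=_species_frame(state),
        extinctions=extinctions,
        richness=richness,
        snapshots=snapshots,
        events=events,
        trajectories=trajectories,
        state=state,
    )
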