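"""Agent-based synthetic hive generator.

Emits per-second tracking tables with the statistical structure the
analysis pipeline assumes, plus ground-truth labels for every detector:

* two locomotor states — quiet agents take small correlated-random-walk
  steps, active agents large ones (the active/quiet kinetic-energy ratio
  plays the role of the burst-detector's rate ratio, and the contact
  count needed to activate plays the role of its level threshold);
* contact-induced activation: a quiet agent with at least
  ``activation_threshold`` active agents within ``contact_radius``
  becomes active with probability ``p_contact_activation`` per second,
  plus rare spontaneous activations; active agents revert after an
  exponentially distributed duration;
* scripted trips (literal removals from the table, re-inserted at the
  entrance), scripted waggle dancers (alternating ±(180°−δ) turns that
  satisfy the dance criteria by construction) and followers (held within
  600 px of their dancer, facing it);
* planned mass-activation events with planted "pioneer" groups that
  pre-activate a lead time before each event at an intermediate step
  scale.

This is a validation scaffold for the pipeline's recovery ability, not a
calibrated model of hive biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking_io import TrackingTable, TrialMetadata, from_dataframe, write_metadata, write_tracking

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ReturnEvent",
    "ScriptedDance",
    "ScriptedFollow",
    "ScriptedTrip",
    "PlannedBurst",
    "simulate",
    "preset_config",
    "emit_fixture_suite",
    "PRESETS",
]

QUIET, ACTIVE, TRIP = 0, 1, 2


@dataclass(frozen=True)
class ReturnEvent:
    """A group of agents away on a trip that returns (active) at ``time``."""

    time: int
    bees: tuple[int, ...]
    trip_duration: int = 120
    dance: bool = False
    return_active_duration: float = 60.0


@dataclass(frozen=True)
class ScriptedDance:
    bee: int
    start: int
    end: int


@dataclass(frozen=True)
class ScriptedFollow:
    follower: int
    dancer: int
    start: int
    end: int


@dataclass(frozen=True)
class ScriptedTrip:
    """Agent absent during seconds [absence_start, absence_end)."""

    bee: int
    absence_start: int
    absence_end: int


@dataclass(frozen=True)
class PlannedBurst:
    """Mass-activation event with a planted pioneer group.

    Pioneers move at ``sigma_pioneer`` from ``time − lead`` until
    ``time`` (pre-onset activity); at ``time`` a ``mass_fraction`` of the
    non-pioneer agents activates fully.
    """

    time: int
    pioneers: tuple[int, ...]
    lead: int = 60
    mass_fraction: float = 0.6


@dataclass
class SimConfig:
    n_bees: int = 100
    arena: tuple[float, float] = (6576.0, 4384.0)
    duration: int = 7200
    entrance_open_t: int = 600
    start_datetime: datetime = field(
        default_factory=lambda: datetime(2012, 7, 4, 6, 0, 0)
    )
    # locomotion (px/s step scales; radians turn noise)
    sigma_quiet: float = 3.0
    sigma_active: float = 40.0
    sigma_pioneer: float = 15.0
    turn_sigma_quiet: float = 0.25
    turn_sigma_active: float = 0.9
    heading_jitter: float = 0.05
    diurnal_amplitude: float = 0.0
    # activation dynamics
    contact_radius: float = 120.0
    p_contact_activation: float = 0.0
    p_spontaneous: float = 0.0
    active_duration_mean: float = 40.0
    activation_threshold: int = 1
    # geometry
    entrance: tuple[float, float] | None = None
    # scripts
    schedule: tuple[ReturnEvent, ...] = ()
    dances: tuple[ScriptedDance, ...] = ()
    follows: tuple[ScriptedFollow, ...] = ()
    trips: tuple[ScriptedTrip, ...] = ()
    planned_bursts: tuple[PlannedBurst, ...] = ()
    trial_id: str = "sim"

    def __post_init__(self) -> None:
        for p in (self.p_contact_activation, self.p_spontaneous):
            if not 0.0 <= p <= 1.0:
                raise ValueError("activation probabilities must lie in [0, 1]")
        if not (self.sigma_active > self.sigma_quiet > 0):
            raise ValueError("need sigma_active > sigma_quiet > 0")
        if self.planned_bursts:
            events = sorted(pb.time for pb in self.planned_bursts)
            min_space = 2 * max(pb.lead for pb in self.planned_bursts)
            for a, b in zip(events, events[1:]):
                if b - a < min_space:
                    raise ValueError(
                        f"planned bursts at {a} and {b} closer than 2x lead "
                        f"({min_space})"
                    )

    @property
    def metadata(self) -> TrialMetadata:
        return TrialMetadata(
            trial_id=self.trial_id,
            start_datetime=self.start_datetime,
            entrance_open_t=self.entrance_open_t,
            T_total=self.duration,
            arena_width=self.arena[0],
            arena_height=self.arena[1],
        )


@dataclass
class GroundTruth:
    """Per-second agent states plus every scripted/planted label."""

    states: np.ndarray                      # (n_bees, duration) int8
    planted: dict[int, tuple[int, ...]]     # event time -> pioneer indices
    planned_onsets: tuple[int, ...]
    dances: tuple[ScriptedDance, ...]
    follows: tuple[ScriptedFollow, ...]
    trips: tuple[tuple[int, int, int], ...]  # (bee, exit_t, entry_t) detector convention
    bee_ids: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        def rle(row: np.ndarray) -> list[list[int]]:
            out = []
            start = 0
            for i in range(1, len(row) + 1):
                if i == len(row) or row[i] != row[start]:
                    out.append([int(row[start]), int(start), int(i - start)])
                    start = i
            return out

        payload = {
            "bee_ids": list(self.bee_ids),
            "states_rle": [rle(r) for r in self.states],
            "planted": {str(k): list(v) for k, v in self.planted.items()},
            "planned_onsets": list(self.planned_onsets),
            "dances": [[int(d.bee), int(d.start), int(d.end)] for d in self.dances],
            "follows": [
                [int(f.follower), int(f.dancer), int(f.start), int(f.end)]
                for f in self.follows
            ],
            "trips": [[int(v) for v in t] for t in self.trips],
        }
        Path(path).write_text(json.dumps(payload))


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    pos = np.mod(pos - lo, 2 * span)
    pos = np.where(pos > span, 2 * span - pos, pos) + lo
    return pos


def simulate(config: SimConfig, seed: int | None = None) -> tuple[TrackingTable, GroundTruth]:
    """Run the agent model; returns the tracking table and ground truth."""
    rng = np.random.default_rng(seed)
    n = config.n_bees
    T = config.duration
    W, H = config.arena
    entrance = config.entrance or (0.02 * W, 0.5 * H)

    pos = np.column_stack((rng.uniform(0, W, n), rng.uniform(0, H, n)))
    theta = rng.uniform(-np.pi, np.pi, n)
    state = np.zeros(n, dtype=np.int8)
    deact_at = np.full(n, -1.0)       # second at which an active agent reverts
    pioneer_until = np.full(n, -1)    # planted pre-activation window end
    dance_sign = np.ones(n)

    # --- script lookup tables -------------------------------------------
    absent_until = np.full(n, -1)
    trip_rows = []
    absences: list[tuple[int, int, int]] = []  # (bee, a_start, a_end)
    for tr in config.trips:
        absences.append((tr.bee, tr.absence_start, tr.absence_end))
    for ev in config.schedule:
        a_start = ev.time - ev.trip_duration
        for bee in ev.bees:
            absences.append((bee, a_start, ev.time))
    absence_start_map: dict[int, list[tuple[int, int]]] = {}
    for bee, a, b in absences:
        absence_start_map.setdefault(a, []).append((bee, b))
        trip_rows.append((bee, a - 1, b))
    return_map: dict[int, list[tuple[int, float]]] = {}
    for ev in config.schedule:
        for bee in ev.bees:
            return_map.setdefault(ev.time, []).append((bee, ev.return_active_duration))

    dancing_now: dict[int, list[int]] = {}
    for d in config.dances:
        for tt in range(d.start, d.end + 1):
            dancing_now.setdefault(tt, []).append(d.bee)
    follow_now: dict[int, list[tuple[int, int]]] = {}
    for f in config.follows:
        for tt in range(f.start, f.end + 1):
            follow_now.setdefault(tt, []).append((f.follower, f.dancer))
    follow_offset = {
        (f.follower, f.dancer): (
            rng.uniform(150, 450) * np.array([np.cos(a), np.sin(a)])
        )
        for f in config.follows
        for a in (rng.uniform(-np.pi, np.pi),)
    }

    planted: dict[int, tuple[int, ...]] = {}
    pre_activate_map: dict[int, PlannedBurst] = {}
    mass_map: dict[int, PlannedBurst] = {}
    for pb in config.planned_bursts:
        planted[pb.time] = tuple(pb.pioneers)
        pre_activate_map[pb.time - pb.lead] = pb
        mass_map[pb.time] = pb

    states_gt = np.zeros((n, T), dtype=np.int8)
    rows_bee = []
    rows_t = []
    rows_xy = []
    rows_heading = []
    idx_all = np.arange(n)

    for t in range(T):
        # --- trips ------------------------------------------------------
        for bee, until in absence_start_map.get(t, ()):
            absent_until[bee] = until
            state[bee] = QUIET
        on_trip = absent_until > t
        for bee, dur in return_map.get(t, ()):
            pos[bee] = entrance + rng.normal(0, 20, 2)
            state[bee] = ACTIVE
            deact_at[bee] = t + rng.exponential(dur)
        # --- planted pioneer pre-activation / mass events ----------------
        if t in pre_activate_map:
            pb = pre_activate_map[t]
            for bee in pb.pioneers:
                pioneer_until[bee] = pb.time
        if t in mass_map:
            pb = mass_map[t]
            eligible = idx_all[~on_trip]
            eligible = eligible[~np.isin(eligible, pb.pioneers)]
            k = int(round(pb.mass_fraction * eligible.size))
            chosen = rng.choice(eligible, size=k, replace=False)
            state[chosen] = ACTIVE
            deact_at[chosen] = t + rng.exponential(
                config.active_duration_mean, size=k
            )
        pioneering = (pioneer_until > t) & ~on_trip
        # --- deactivation ------------------------------------------------
        expire = (state == ACTIVE) & (deact_at <= t)
        state[expire] = QUIET
        # --- activation --------------------------------------------------
        scripted = np.zeros(n, dtype=bool)
        dancers_t = dancing_now.get(t, [])
        follows_t = follow_now.get(t, [])
        scripted[dancers_t] = True
        for fol, _ in follows_t:
            scripted[fol] = True
        active_mask = (state == ACTIVE) & ~on_trip
        quiet_mask = (state == QUIET) & ~on_trip & ~scripted & ~pioneering
        if config.p_spontaneous > 0:
            spont = quiet_mask & (rng.random(n) < config.p_spontaneous)
        else:
            spont = np.zeros(n, dtype=bool)
        contact = np.zeros(n, dtype=bool)
        if config.p_contact_activation > 0 and active_mask.any():
            qi = idx_all[quiet_mask]
            if qi.size:
                ap = pos[active_mask]
                d2 = (
                    (pos[qi, 0][:, None] - ap[None, :, 0]) ** 2
                    + (pos[qi, 1][:, None] - ap[None, :, 1]) ** 2
                )
                n_near = (d2 <= config.contact_radius**2).sum(axis=1)
                hit = (n_near >= config.activation_threshold) & (
                    rng.random(qi.size) < config.p_contact_activation
                )
                contact[qi[hit]] = True
        newly = spont | contact
        if newly.any():
            state[newly] = ACTIVE
            deact_at[newly] = t + rng.exponential(
                config.active_duration_mean, size=int(newly.sum())
            )
        # --- movement ----------------------------------------------------
        active_mask = (state == ACTIVE) & ~on_trip
        mod = 1.0
        if config.diurnal_amplitude:
            mod = 1.0 + config.diurnal_amplitude * np.sin(
                2 * np.pi * t / 86400.0
            )
        sigma = np.full(n, config.sigma_quiet * mod)
        sigma[active_mask] = config.sigma_active * mod
        sigma[pioneering] = config.sigma_pioneer * mod
        turn = np.where(
            active_mask | pioneering,
            config.turn_sigma_active,
            config.turn_sigma_quiet,
        )
        theta_prev = theta.copy()
        theta = theta + rng.normal(0, 1, n) * turn
        step = np.abs(rng.normal(0, 1, n)) * sigma
        # scripted dancers: in-place alternating reversals; the turn is
        # kept in (152, 168) degrees so that heading jitter can neither
        # push it past 180 (flipping the cross-product sign) nor under 90
        for bee in dancers_t:
            dance_sign[bee] *= -1
            theta[bee] = theta_prev[bee] + dance_sign[bee] * (
                np.pi - np.deg2rad(20 + rng.uniform(-8, 8))
            )
            step[bee] = abs(rng.normal(0, 1.0))
        pos[:, 0] = _reflect(pos[:, 0] + step * np.cos(theta), 0, W)
        pos[:, 1] = _reflect(pos[:, 1] + step * np.sin(theta), 0, H)
        heading = theta + rng.normal(0, config.heading_jitter, n)
        # scripted followers: pinned near the dancer, facing it
        for fol, dancer in follows_t:
            target = pos[dancer] + follow_offset[(fol, dancer)]
            target[0] = np.clip(target[0], 0, W)
            target[1] = np.clip(target[1], 0, H)
            pos[fol] = target
            to_dancer = pos[dancer] - pos[fol]
            heading[fol] = np.arctan2(to_dancer[1], to_dancer[0]) + rng.uniform(
                -0.6, 0.6
            )
            theta[fol] = heading[fol]
        # --- record ------------------------------------------------------
        present = ~on_trip
        states_gt[:, t] = np.where(
            on_trip, TRIP, np.where(active_mask | pioneering, ACTIVE, QUIET)
        )
        pi = idx_all[present]
        rows_bee.append(pi)
        rows_t.append(np.full(pi.size, t, dtype=np.int64))
        rows_xy.append(pos[pi].copy())
        rows_heading.append(heading[pi].copy())

    bee_ids = tuple(f"B{i:03d}" for i in range(n))
    bee_idx = np.concatenate(rows_bee)
    df = pd.DataFrame(
        {
            "bee_id": np.array(bee_ids)[bee_idx],
            "t": np.concatenate(rows_t),
            "x": np.concatenate([xy[:, 0] for xy in rows_xy]),
            "y": np.concatenate([xy[:, 1] for xy in rows_xy]),
        }
    )
    h = np.concatenate(rows_heading)
    df["nx"] = np.cos(h)
    df["ny"] = np.sin(h)
    table = from_dataframe(df, config.metadata)
    gt = GroundTruth(
        states=states_gt,
        planted=planted,
        planned_onsets=tuple(sorted(planted)),
        dances=config.dances,
        follows=config.follows,
        trips=tuple((bee, a, b) for bee, a, b in trip_rows),
        bee_ids=bee_ids,
    )
    return table, gt


# ---------------------------------------------------------------------------
# presets


def _dance_script(rng: np.random.Generator, n: int, duration: int, n_dances: int):
    dances, follows = [], []
    times = np.linspace(400, duration - 400, n_dances).astype(int)
    for i, t0 in enumerate(times):
        t0 = int(t0)
        dancer = int(rng.integers(0, n))
        follower = (dancer + 1 + int(rng.integers(0, n - 1))) % n
        length = int(rng.integers(30, 60))
        dances.append(ScriptedDance(bee=dancer, start=t0, end=t0 + length))
        follows.append(
            ScriptedFollow(
                follower=follower, dancer=dancer,
                start=t0 + 2, end=t0 + length - 2,
            )
        )
    return tuple(dances), tuple(follows)


def preset_config(name: str, seed: int = 0) -> SimConfig:
    """Deterministic fixture presets (small hives, ≤ 2 simulated hours)."""
    rng = np.random.default_rng(seed)
    arena = (1600.0, 1100.0)  # fixture hives are dense, like a real comb face
    if name == "null":
        return SimConfig(
            n_bees=100, arena=arena, duration=7200, trial_id="null",
            p_contact_activation=0.0, p_spontaneous=0.0,
        )
    if name == "contact_cascade":
        # near-critical: pairs of coincident spontaneous activations ignite
        # hive-wide cascades that collapse once durations expire
        return SimConfig(
            n_bees=100, arena=arena, duration=7200, trial_id="contact_cascade",
            p_contact_activation=0.18, p_spontaneous=0.002,
            activation_threshold=2, contact_radius=120.0,
            active_duration_mean=20.0,
        )
    if name == "forager_driven":
        fp = tuple(range(15))
        schedule = []
        for i, t0 in enumerate(range(900, 7000, 320)):
            group = tuple(
                int(b) for b in rng.choice(fp, size=10, replace=False)
            )
            schedule.append(
                ReturnEvent(
                    time=t0, bees=group, trip_duration=120,
                    return_active_duration=50.0,
                )
            )
        # threshold-2 bistability: the clustered returners ignite a
        # hive-wide cascade that collapses before the next return event,
        # so non-forager activity is driven by forager returns with a lag
        return SimConfig(
            n_bees=100, arena=arena, duration=7200, trial_id="forager_driven",
            entrance_open_t=300,
            p_contact_activation=0.2, p_spontaneous=0.0003,
            activation_threshold=2, contact_radius=120.0,
            active_duration_mean=20.0,
            schedule=tuple(schedule),
        )
    if name == "dance_demo":
        n = 50
        dances, follows = _dance_script(rng, n, 7200, 12)
        busy = {d.bee for d in dances} | {f.follower for f in follows}
        free = [i for i in range(n) if i not in busy]
        trips = []
        for i, t0 in enumerate(range(900, 6200, 640)):
            bee = free[i % len(free)]
            trips.append(
                ScriptedTrip(
                    bee=bee, absence_start=t0,
                    absence_end=t0 + int(rng.integers(90, 400)),
                )
            )
        return SimConfig(
            n_bees=n, arena=arena, duration=7200, trial_id="dance_demo",
            entrance_open_t=600,
            dances=dances, follows=follows, trips=tuple(trips),
        )
    if name == "pioneer_recovery":
        events = []
        for t0 in range(350, 350 + 20 * 340, 340):
            pioneers = tuple(
                int(b) for b in rng.choice(100, size=20, replace=False)
            )
            events.append(
                PlannedBurst(time=t0, pioneers=pioneers, lead=60, mass_fraction=0.6)
            )
        return SimConfig(
            n_bees=100, arena=arena, duration=7200, trial_id="pioneer_recovery",
            p_contact_activation=0.0, p_spontaneous=0.0002,
            active_duration_mean=30.0,
            planned_bursts=tuple(events),
        )
    raise KeyError(f"unknown preset: {name!r}")


PRESETS = ("null", "contact_cascade", "forager_driven", "dance_demo", "pioneer_recovery")


def emit_fixture_suite(
    presets=PRESETS, outdir: str | Path = "fixtures", seed: int = 0
) -> dict[str, dict[str, Path]]:
    """Write tracking CSV + metadata YAML + ground-truth JSON per preset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in presets:
        config = preset_config(name, seed=seed)
        table, gt = simulate(config, seed=seed)
        paths = {
            "tracking": outdir / f"{name}_tracking.csv",
            "metadata": outdir / f"{name}_metadata.yaml",
            "ground_truth": outdir / f"{name}_ground_truth.json",
        }
        write_tracking(table, paths["tracking"])
        write_metadata(config.metadata, paths["metadata"])
        gt.to_json(paths["ground_truth"])
        written[name] = paths
    return written
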