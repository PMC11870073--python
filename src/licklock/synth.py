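"""Seeded generative model of a recording session with known ground truth.

The generator emulates the statistical structure of head-fixed mouse licking
and Purkinje-cell spiking so that every analysis stage can be validated by
parameter recovery:

* licking at ~6.25 Hz organised in bouts (Gamma inter-lick intervals, a
  geometric number of licks per bout, inter-bout gaps >= 0.5 s), with 2-D
  Gaussian tongue endpoints around the current port position and
  max-protrusion 16 ms after detection;
* simple spikes as an inhomogeneous Poisson process, von Mises phase-locked
  to the lick cycle inside bouts and at the flat base rate outside them
  (rhythmicity is confined to licking);
* sparse complex spikes (~1 Hz) with multiplicative 300 ms bumps at bout
  transitions and after lick-port movements, optional phase locking, and a
  >= 8 ms simple-spike pause enforced after every complex spike;
* closed-loop lick-port trials (3 mm rightward moves, 40 ms onset delay,
  50 ms travel, return after 750 ms, 750 ms refractory) with partial-then-
  full behavioural following, and optogenetic trials that bend and shorten
  the next protrusion.

One global seed is split into independent substreams per stream type and
per cell, so adding a cell never perturbs the behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.special import i0

from .core_io import (
    CellRecording,
    LickTrain,
    OptoTrial,
    PortTrial,
    Session,
    segment_bouts,
)
from .rhythm import build_phase_map

KAPPA_CAP = 20.0  # rate overflow guard for the von Mises factor


@dataclass
class BehaviourSpec:
    """Parameters of the behavioural (licking) model.

    Defaults emulate the study conditions: median lick frequency just above
    6 Hz (160 ms inter-lick interval), bouts of geometric size, inter-bout
    gaps of 2 s on average but never below the 0.5 s bout criterion, and a
    ~4.2 mm protrusion with sub-millimetre endpoint scatter.
    """

    lick_rate_mean: float = 6.25          # Hz, intra-bout
    ili_cv: float = 0.1                   # CV of intra-bout intervals
    bout_size_mean: float = 8.0           # licks per bout (geometric)
    interbout_mean: float = 2.0           # s, shifted so every gap >= 0.5 s
    endpoint_mean_x: float = 0.0          # mm, resting port position
    endpoint_mean_y: float = 4.2          # mm, typical protrusion extension
    endpoint_sd_x: float = 0.3            # mm
    endpoint_sd_y: float = 0.5            # mm
    maxprot_delay: float = 0.016          # s, detection -> max protrusion
    follow_gain: tuple = (0.5, 1.0, 1.0)  # port tracking by licks 1/2/3
    opto_bend: float = 0.5                # mm ipsiversive bend of lick 1
    opto_shorten: float = 0.3             # mm reduction of extension


@dataclass
class CellSpec:
    """Ground-truth coupling parameters of one synthetic Purkinje cell."""

    ss_base_rate: float = 60.0        # Hz
    ss_phase_pref: float = np.pi      # radians in [0, 2*pi)
    ss_kappa: float = 0.0             # von Mises concentration, 0 = no locking
    ss_bout_gain: float = 1.0         # multiplicative in-bout SS rate factor
    cs_base_rate: float = 1.0         # Hz
    cs_bout_start_gain: float = 0.0   # multiplicative bump, 300 ms at bout start
    cs_bout_end_gain: float = 0.0     # multiplicative bump, 300 ms at bout end
    cs_move_gain_right: float = 0.0   # bump after rightward port movements
    cs_move_gain_centre: float = 0.0  # bump after returns to centre
    cs_pause: float = 0.008           # s, SS silenced after each CS
    cs_lick_phase_pref: float = 0.0
    cs_lick_kappa: float = 0.0
    ss_endpoint_gain_hz_per_mm: float = 0.0  # SS-rate coupling to endpoint x
    grid_row: int = 1
    grid_col: int = 1
    region_tag: str = "medial"

    def __post_init__(self) -> None:
        if min(self.ss_base_rate, self.cs_base_rate) < 0:
            raise ValueError("rates must be >= 0")
        if min(self.ss_kappa, self.cs_lick_kappa) < 0:
            raise ValueError("kappa must be >= 0")
        if self.cs_pause < 0.008:
            raise ValueError("cs_pause must be >= 0.008 s")


@dataclass
class GroundTruth:
    """Every latent parameter of a generated session, for recovery tests."""

    behaviour: dict
    cells: dict              # cell_id -> CellSpec fields
    bout_first_indices: list
    bout_last_indices: list
    n_port_trials: int
    port_trials: list        # dicts mirroring PortTrial
    opto_trials: list
    opto_controls: list
    seed: int
    duration: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=float)


def reference_specs() -> dict:
    """Named reference cell phenotypes used throughout validation.

    Coupling strengths are fixed design choices producing effect sizes
    comparable to the recorded phenomena: clear phase locking, an
    unambiguous bout-transition complex-spike response, a decodable
    in-bout rate change, and a direction-selective movement response.
    """
    return {
        "phase_locked": CellSpec(ss_kappa=4.0, ss_phase_pref=np.pi / 2,
                                 cs_base_rate=0.0),
        "unlocked": CellSpec(ss_kappa=0.0, cs_base_rate=0.0),
        "bout_start_coder": CellSpec(cs_base_rate=1.0, cs_bout_start_gain=6.0),
        "cs_flat": CellSpec(cs_base_rate=1.0),
        "strong_decoder": CellSpec(ss_base_rate=50.0, ss_bout_gain=1.8,
                                   ss_kappa=2.0),
        "move_coder": CellSpec(cs_base_rate=1.0, cs_move_gain_right=6.0,
                               cs_move_gain_centre=1.0),
        "endpoint_coupled": CellSpec(ss_base_rate=60.0,
                                     ss_endpoint_gain_hz_per_mm=50.0),
    }


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def generate_licks(
    spec: BehaviourSpec,
    duration: float,
    seed_or_rng,
) -> LickTrain:
    """Generate a bout-structured lick train over ``[0, duration]``.

    Intra-bout intervals are i.i.d. Gamma with the specified mean and CV
    (degenerate at the mean when the CV is ~0), clipped to stay strictly
    below the 0.5 s bout criterion; inter-bout gaps are 0.5 s plus an
    exponential tail so bouts are exactly recoverable by segmentation.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(seed_or_rng)
    mean_ili = 1.0 / spec.lick_rate_mean
    times = []
    t = 0.5 + rng.exponential(max(spec.interbout_mean - 0.5, 1e-6))
    while t < duration - 0.1:
        size = int(rng.geometric(1.0 / spec.bout_size_mean))
        if spec.ili_cv <= 1e-9:
            ilis = np.full(max(size - 1, 0), mean_ili)
        else:
            shape = 1.0 / spec.ili_cv**2
            ilis = rng.gamma(shape, mean_ili / shape, size=max(size - 1, 0))
            ilis = np.clip(ilis, 0.02, 0.45)
        bout = t + np.concatenate(([0.0], np.cumsum(ilis)))
        bout = bout[bout < duration - 0.05]
        if bout.size == 0:
            break
        times.append(bout)
        t = bout[-1] + 0.5 + rng.exponential(max(spec.interbout_mean - 0.5, 1e-6))
    detect = np.concatenate(times) if times else np.empty(0)
    n = detect.size
    x = rng.normal(spec.endpoint_mean_x, spec.endpoint_sd_x, size=n)
    y = rng.normal(spec.endpoint_mean_y, spec.endpoint_sd_y, size=n)
    return LickTrain(
        detect_times=detect,
        session_duration=duration,
        endpoint_x=x,
        endpoint_y=y,
        max_protrusion_times=detect + spec.maxprot_delay,
    )


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _von_mises_factor(phi: np.ndarray, pref: float, kappa: float) -> np.ndarray:
    """exp(kappa*cos(phi - pref)) / I0(kappa): unit-mean phase modulation."""
    kappa = min(kappa, KAPPA_CAP)
    return np.exp(kappa * np.cos(phi - pref)) / i0(kappa)


def _thinned_poisson(
    rate_fn, envelope: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample an inhomogeneous Poisson process by thinning an exact envelope."""
    if envelope <= 0:
        return np.empty(0)
    n = rng.poisson(envelope * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n))
    if cand.size == 0:
        return cand
    accept = rng.uniform(0.0, envelope, size=cand.size) < rate_fn(cand)
    return cand[accept]


def generate_cell(
    spec: CellSpec,
    licks: LickTrain,
    trials: Optional[Sequence[PortTrial]] = None,
    seed_or_rng=None,
    cell_id: str = "cell",
    bump_width: float = 0.3,
) -> CellRecording:
    """Generate one cell's SS and CS trains coupled to the given behaviour.

    SS rate is ``ss_base_rate`` times the unit-mean von Mises factor of the
    lick phase inside bouts (flat outside), plus an optional endpoint-x
    coupling confined to the 75 ms before each max protrusion. CS rate is
    ``cs_base_rate`` modulated multiplicatively by 300 ms bumps centred on
    bout starts/ends and following port movements, and optionally
    phase-locked. All SS within ``cs_pause`` after a CS are deleted, which
    makes the >= 8 ms pause guarantee exact.
    """
    rng = _as_rng(seed_or_rng)
    duration = licks.session_duration
    bouts = segment_bouts(licks)
    pmap = build_phase_map(licks, bouts)
    mp = licks.maxprot()
    ex = licks.endpoint_x if licks.endpoint_x is not None else np.zeros(licks.n_licks)

    kappa = min(spec.ss_kappa, KAPPA_CAP)
    vm_peak = float(np.exp(kappa) / i0(kappa))
    g = spec.ss_endpoint_gain_hz_per_mm
    x_peak = float(np.nanmax(np.abs(ex))) if ex.size and g != 0 else 0.0

    def ss_rate(t: np.ndarray) -> np.ndarray:
        phi, valid = pmap.phase(t)
        r = np.full(t.shape, spec.ss_base_rate)
        if kappa > 0 and valid.any():
            r[valid] = spec.ss_base_rate * _von_mises_factor(
                phi[valid], spec.ss_phase_pref, kappa
            )
        if spec.ss_bout_gain != 1.0:
            r[valid] = r[valid] * spec.ss_bout_gain
        if g != 0.0 and mp.size:
            # extra drive proportional to the upcoming endpoint x, confined
            # to the late-protrusion window (-75..0 ms before max protrusion)
            idx = np.searchsorted(mp, t, side="left")
            hit = idx < mp.size
            close = np.zeros(t.shape, dtype=bool)
            close[hit] = (mp[idx[hit]] - t[hit]) <= 0.075
            add = np.zeros(t.shape)
            xi = np.nan_to_num(ex[idx[hit]], nan=0.0)
            add[hit] = np.where(close[hit], g * xi, 0.0)
            r = np.maximum(r + add, 0.0)
        return r

    ss_env = (
        spec.ss_base_rate * max(vm_peak, 1.0) * max(spec.ss_bout_gain, 1.0)
        + abs(g) * x_peak
    )
    ss = _thinned_poisson(ss_rate, ss_env, duration, rng)

    starts = np.array([b.start_time for b in bouts])
    ends = np.array([b.end_time for b in bouts])
    right_onsets = np.array(
        [tr.move_onset for tr in (trials or []) if tr.direction == "rightward"]
    )
    centre_onsets = np.array(
        [tr.move_onset for tr in (trials or []) if tr.direction == "centreward"]
    )
    ckappa = min(spec.cs_lick_kappa, KAPPA_CAP)
    cvm_peak = float(np.exp(ckappa) / i0(ckappa))

    def _bump(t: np.ndarray, centres: np.ndarray, gain: float,
              centred: bool) -> np.ndarray:
        out = np.ones(t.shape)
        if gain == 0.0 or centres.size == 0:
            return out
        half = bump_width / 2.0
        lo, hi = (-half, half) if centred else (0.0, bump_width)
        idx = np.searchsorted(centres, t)
        for shift in (0, -1):
            j = np.clip(idx + shift, 0, centres.size - 1)
            d = t - centres[j]
            out = np.where((d >= lo) & (d <= hi), 1.0 + gain, out)
        return out

    def cs_rate(t: np.ndarray) -> np.ndarray:
        r = np.full(t.shape, spec.cs_base_rate)
        r = r * _bump(t, starts, spec.cs_bout_start_gain, centred=True)
        r = r * _bump(t, ends, spec.cs_bout_end_gain, centred=True)
        r = r * _bump(t, right_onsets, spec.cs_move_gain_right, centred=False)
        r = r * _bump(t, centre_onsets, spec.cs_move_gain_centre, centred=False)
        if ckappa > 0:
            phi, valid = pmap.phase(t)
            f = np.ones(t.shape)
            f[valid] = _von_mises_factor(phi[valid], spec.cs_lick_phase_pref, ckappa)
            r = r * f
        return r

    cs_env = (
        spec.cs_base_rate
        * (1.0 + max(spec.cs_bout_start_gain, 0.0))
        * (1.0 + max(spec.cs_bout_end_gain, 0.0))
        * (1.0 + max(spec.cs_move_gain_right, 0.0))
        * (1.0 + max(spec.cs_move_gain_centre, 0.0))
        * max(cvm_peak, 1.0)
    )
    cs = _thinned_poisson(cs_rate, cs_env, duration, rng)

    # climbing-fibre pause: delete SS within cs_pause after each CS
    if cs.size and ss.size:
        keep = np.ones(ss.shape, dtype=bool)
        lo = np.searchsorted(ss, cs, side="right")
        hi = np.searchsorted(ss, cs + spec.cs_pause, side="right")
        for a, b in zip(lo, hi):
            keep[a:b] = False
        ss = ss[keep]

    return CellRecording(
        cell_id=cell_id,
        ss_times=ss,
        cs_times=cs,
        grid_row=spec.grid_row,
        grid_col=spec.grid_col,
        region_tag=spec.region_tag,
    )


# ---------------------------------------------------------------------------
# trials and full session
# ---------------------------------------------------------------------------

def _plan_port_trials(
    licks: LickTrain,
    n_trials: int,
    rng: np.random.Generator,
    displacement: float = 3.0,
    trigger_prob: float = 0.5,
    onset_delay: float = 0.040,
    hold: float = 0.750,
    refractory: float = 0.750,
) -> list[PortTrial]:
    """Closed-loop rightward/centreward trial plan over the lick train."""
    t = licks.detect_times
    trials: list[PortTrial] = []
    available = 0.0
    n_done = 0
    for i, ti in enumerate(t):
        if n_done >= n_trials:
            break
        if ti < available:
            continue
        if rng.uniform() < trigger_prob:
            onset = ti + onset_delay
            ret = onset + hold
            trials.append(PortTrial(i, onset, "rightward", displacement))
            trials.append(PortTrial(i, ret, "centreward", displacement))
            available = ret + refractory
            n_done += 1
    if n_done < n_trials:
        raise ValueError(
            f"over-subscribed trial plan: {n_trials} requested, "
            f"only {n_done} eligible triggers in the session"
        )
    return trials


def _apply_port_following(
    licks: LickTrain, trials: Sequence[PortTrial], spec: BehaviourSpec
) -> None:
    """Shift endpoint x means so licks track the port per follow_gain."""
    if not trials:
        return
    events = sorted(trials, key=lambda tr: tr.move_onset)
    ev_times = np.array([e.move_onset for e in events])
    targets = np.array(
        [e.displacement if e.direction == "rightward" else 0.0 for e in events]
    )
    t = licks.detect_times
    gains = spec.follow_gain
    for i, ti in enumerate(t):
        j = np.searchsorted(ev_times, ti, side="right") - 1
        if j < 0:
            continue
        prev = targets[j - 1] if j > 0 else 0.0
        # lick index after this event
        k = int(np.searchsorted(t, ev_times[j], side="right"))
        rank = i - k + 1
        if rank <= 0:
            mean = prev
        elif rank <= len(gains) and ti - ev_times[j] <= 0.75:
            # partial following for the first licks; adaptation completes
            # within the 750 ms hold even when few licks occur
            mean = prev + (targets[j] - prev) * gains[rank - 1]
        else:
            mean = targets[j]
        licks.endpoint_x[i] += mean


def _plan_opto(
    licks: LickTrain,
    plan: dict,
    rng: np.random.Generator,
) -> tuple[list[OptoTrial], list[int]]:
    """Choose trigger licks for stimulation and matched controls."""
    n_stim = int(plan.get("n_trials", 0))
    n_ctrl = int(plan.get("n_controls", n_stim))
    onset = float(plan.get("onset_offset", 0.010))
    dur = float(plan.get("duration", 0.160))
    fibre = str(plan.get("fibre", "right_medial"))
    t = licks.detect_times
    # eligible: licks with a successor within the bout (so "lick 1" exists)
    eligible = np.flatnonzero(
        (np.arange(t.size) < t.size - 1) & (np.diff(t, append=np.inf) < 0.5)
    )
    need = n_stim + n_ctrl
    if need > eligible.size:
        raise ValueError(
            f"over-subscribed opto plan: {need} triggers requested, "
            f"{eligible.size} eligible licks"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    stim = np.sort(chosen[:n_stim])
    ctrl = np.sort(chosen[n_stim:])
    return (
        [OptoTrial(int(i), onset, dur, fibre) for i in stim],
        [int(i) for i in ctrl],
    )


_FIBRE_BEND_SIGN = {
    "right_medial": 1.0,
    "left_medial": -1.0,
    "both": 0.0,
    "lateral": 0.4,  # lateral stimulation is markedly less effective
}


def _apply_opto_effects(
    licks: LickTrain, opto_trials: Sequence[OptoTrial], spec: BehaviourSpec
) -> None:
    """Bend and shorten the first protrusion after each stimulation onset."""
    t = licks.detect_times
    for tr in opto_trials:
        onset = t[tr.trigger_lick_index] + tr.onset_offset
        nxt = int(np.searchsorted(t, onset, side="right"))
        if nxt >= t.size:
            continue
        sign = _FIBRE_BEND_SIGN.get(tr.fibre, 0.0)
        licks.endpoint_x[nxt] += sign * spec.opto_bend
        licks.endpoint_y[nxt] -= spec.opto_shorten


def generate_session(
    behaviour: BehaviourSpec,
    cell_specs: Sequence[CellSpec],
    duration: float = 600.0,
    n_port_trials: int = 0,
    opto_plan: Optional[dict] = None,
    seed: int = 0,
) -> tuple[Session, GroundTruth]:
    """Compose a full synthetic session plus its ground-truth record.

    The master seed is split into independent substreams (behaviour, trial
    plan, opto plan, one per cell), so the behavioural realisation is
    invariant to the number of cells requested.
    """
    ss = np.random.SeedSequence(seed)
    keys = ss.spawn(4 + len(cell_specs))
    licks = generate_licks(behaviour, duration, np.random.default_rng(keys[0]))
    port_trials = (
        _plan_port_trials(licks, n_port_trials, np.random.default_rng(keys[1]))
        if n_port_trials
        else []
    )
    _apply_port_following(licks, port_trials, behaviour)
    opto_trials: list[OptoTrial] = []
    opto_controls: list[int] = []
    if opto_plan:
        opto_trials, opto_controls = _plan_opto(
            licks, opto_plan, np.random.default_rng(keys[2])
        )
        _apply_opto_effects(licks, opto_trials, behaviour)
    cells = [
        generate_cell(
            spec,
            licks,
            trials=port_trials,
            seed_or_rng=np.random.default_rng(keys[4 + i]),
            cell_id=f"cell{i:02d}",
        )
        for i, spec in enumerate(cell_specs)
    ]
    bouts = segment_bouts(licks)
    session = Session(
        licks=licks,
        cells=cells,
        port_trials=port_trials,
        opto_trials=opto_trials,
        opto_controls=opto_controls,
        metadata={"synthetic": True, "seed": seed},
    )
    truth = GroundTruth(
        behaviour=asdict(behaviour),
        cells={c.cell_id: asdict(s) for c, s in zip(cells, cell_specs)},
        bout_first_indices=[b.first_lick_index for b in bouts],
        bout_last_indices=[b.last_lick_index for b in bouts],
        n_port_trials=n_port_trials,
        port_trials=[asdict_trial(tr) for tr in port_trials],
        opto_trials=[
            {
                "trigger_lick_index": tr.trigger_lick_index,
                "onset_offset": tr.onset_offset,
                "duration": tr.duration,
                "fibre": tr.fibre,
            }
            for tr in opto_trials
        ],
        opto_controls=list(opto_controls),
        seed=seed,
        duration=duration,
    )
    return session, truth


def asdict_trial(tr: PortTrial) -> dict:
    return {
        "trigger_lick_index": tr.trigger_lick_index,
        "move_onset": tr.move_onset,
        "direction": tr.direction,
        "displacement": tr.displacement,
    }
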