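"""Moving lick-port and optogenetic trial analyses.

Licks around each port movement are indexed 0 (trigger) through 3; their
endpoint coordinates are normalized to the pre-movement position. Complex-
spike responses to target movements are Z-scored against the 500 ms
pre-bout baseline; simple-spike adaptation is read as the peak Z around
tongue protraction of licks 0..3, against a 750 ms pre-lick baseline.
Centreward (return) events are analysed with the same machinery as the
rightward onsets. Optogenetic effects are mean endpoint differences between
stimulated and matched control trials per lick index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import Bout, CellRecording, LickTrain, OptoTrial, PortTrial, segment_bouts
from .modulation import Z_THRESHOLD, compute_psth, zscore_psth

#: a lick is "baseline" when no movement affected the port for >= 300 ms
BASELINE_CLEAR_S = 0.300
#: CS move response baseline: 500 ms preceding bout starts
CS_MOVE_BASELINE = (-0.5, 0.0)
#: SS adaptation baseline: 750 ms preceding the licks of interest
SS_ADAPT_BASELINE = (-1.0, -0.25)
#: protraction window for SS peaks (relative to max protrusion)
PROTRACTION_WINDOW = (-0.075, 0.0)
#: CS analysis window after movement onset
CS_RESPONSE_WINDOW = (0.0, 0.300)
MAX_LICK_INDEX = 3


@dataclass
class TrialLicks:
    """Lick indices 0..3 for one movement event (None where truncated)."""

    trial: PortTrial
    lick_indices: list  # position k holds the lick index for lick k


@dataclass
class TrialLickSet:
    """Indexed trial licks plus the session's unperturbed baseline licks."""

    trials: list
    baseline_lick_indices: np.ndarray
    n_excluded: int  # trials with no subsequent lick before the next event


def index_trial_licks(
    trials: Sequence[PortTrial],
    licks: LickTrain,
    max_index: int = MAX_LICK_INDEX,
) -> TrialLickSet:
    """Assign licks 0..3 to each movement event.

    Lick k (k >= 1) is the k-th detection after ``move_onset`` and before
    the next movement event; lick 0 is the trigger. Trials truncated by the
    next event keep only the available indices; trials with no subsequent
    lick are excluded (counted). Baseline licks are those at least 300 ms
    clear of any port displacement interval.
    """
    t = licks.detect_times
    events = sorted(trials, key=lambda tr: tr.move_onset)
    ev_times = np.array([e.move_onset for e in events])
    out = []
    n_excluded = 0
    for j, ev in enumerate(events):
        nxt = ev_times[j + 1] if j + 1 < len(events) else np.inf
        first = int(np.searchsorted(t, ev.move_onset, side="right"))
        indices: list = [ev.trigger_lick_index]
        k = 0
        while k < max_index and first + k < t.size and t[first + k] < nxt:
            indices.append(first + k)
            k += 1
        while len(indices) < max_index + 1:
            indices.append(None)
        if k == 0:
            n_excluded += 1
            continue
        out.append(TrialLicks(trial=ev, lick_indices=indices))
    # port is displaced from each rightward onset until its return; a
    # baseline lick is >= 300 ms clear of every such interval
    blocked = np.zeros(t.shape, dtype=bool)
    rights = [e for e in events if e.direction == "rightward"]
    for e in rights:
        ret = next(
            (r.move_onset for r in events
             if r.direction == "centreward" and r.move_onset > e.move_onset),
            licks.session_duration,
        )
        blocked |= (t >= e.move_onset - 0.0) & (t <= ret + BASELINE_CLEAR_S)
    for e in events:  # clear margin around every movement event itself
        blocked |= np.abs(t - e.move_onset) <= BASELINE_CLEAR_S
    return TrialLickSet(
        trials=out,
        baseline_lick_indices=np.flatnonzero(~blocked),
        n_excluded=n_excluded,
    )


def normalize_trial_coordinates(
    trial_licks: TrialLickSet,
    licks: LickTrain,
    n_reference: int = 3,
) -> dict:
    """Endpoint coordinates relative to the pre-movement tongue position.

    Per trial, the mean endpoint of the reference licks (the up to
    ``n_reference`` licks immediately preceding the movement onset, within
    the same lick chain) is subtracted — for rightward onsets these are the
    trigger and earlier centred licks, for returns the licks tracking the
    displaced port. Returns ``{direction: {k: (n, 2) array of [dx, dy]}}``
    for k = 0..3. Normalization is idempotent on already-centred data.
    """
    if not licks.has_endpoints():
        raise ValueError("licks carry no endpoint coordinates")
    ex, ey = licks.endpoint_x, licks.endpoint_y
    t = licks.detect_times
    out: dict = {}
    for tl in trial_licks.trials:
        i0 = int(np.searchsorted(t, tl.trial.move_onset, side="right")) - 1
        if i0 < 0:
            continue
        refs = [i0]
        j = i0 - 1
        while j >= 0 and len(refs) < n_reference and t[j + 1] - t[j] < 0.5:
            refs.append(j)
            j -= 1
        refs = [r for r in refs if np.isfinite(ex[r])]
        if not refs:
            continue
        rx = float(np.mean(ex[refs]))
        ry = float(np.mean(ey[refs]))
        d = out.setdefault(tl.trial.direction, {k: [] for k in range(MAX_LICK_INDEX + 1)})
        for k, li in enumerate(tl.lick_indices):
            if li is None or not np.isfinite(ex[li]):
                continue
            d[k].append((ex[li] - rx, ey[li] - ry))
    return {
        direction: {k: np.array(v) if v else np.empty((0, 2)) for k, v in d.items()}
        for direction, d in out.items()
    }


@dataclass
class MoveResponse:
    """Complex-spike response to port movements in one direction."""

    direction: str
    peak_z: float
    responsive: bool
    n_trials: int
    z_defined: bool = True


def cs_move_response(
    cell: CellRecording,
    trials: Sequence[PortTrial],
    licks: LickTrain,
    direction: str,
    bouts: Optional[Sequence[Bout]] = None,
    min_trials: int = 20,
) -> MoveResponse:
    """CS PSTH aligned on movement onsets of one direction.

    Z-scored against the 500 ms baseline preceding bout starts; responsive
    means the peak Z within 300 ms after onset exceeds 3. The baseline SD
    is scaled by sqrt(n_bouts / n_trials) so that the noise yardstick
    matches the sampling noise of the trial-aligned PSTH (bin-rate variance
    is inversely proportional to the number of alignments).
    """
    onsets = np.array(
        [tr.move_onset for tr in trials if tr.direction == direction]
    )
    if onsets.size < min_trials:
        raise ValueError(f"{onsets.size} {direction} trials, need >= {min_trials}")
    if bouts is None:
        bouts = segment_bouts(licks)
    starts = np.array([b.start_time for b in bouts])
    base_psth = compute_psth(
        cell.cs_times, starts, window=CS_MOVE_BASELINE,
        valid_range=(0.0, licks.session_duration),
    )
    mu = float(base_psth.rate.mean())
    sd = float(base_psth.rate.std(ddof=0))
    psth = compute_psth(
        cell.cs_times, onsets, window=(-0.5, 0.5),
        valid_range=(0.0, licks.session_duration),
    )
    if sd <= 0:
        return MoveResponse(direction, np.nan, False, int(onsets.size), z_defined=False)
    sd = sd * np.sqrt(base_psth.n_align / psth.n_align)
    z = (psth.rate - mu) / sd
    sl = psth.window_slice((CS_RESPONSE_WINDOW[0], CS_RESPONSE_WINDOW[1] - 1e-9))
    peak = float(np.max(z[sl]))
    return MoveResponse(direction, peak, bool(peak > Z_THRESHOLD), int(onsets.size))


def cs_direction_selectivity(
    cell: CellRecording,
    trials: Sequence[PortTrial],
    licks: LickTrain,
    min_trials: int = 20,
) -> tuple[MoveResponse, MoveResponse, float]:
    """(rightward, centreward, selectivity = peak_z_right - peak_z_centre)."""
    right = cs_move_response(cell, trials, licks, "rightward", min_trials=min_trials)
    centre = cs_move_response(cell, trials, licks, "centreward", min_trials=min_trials)
    return right, centre, float(right.peak_z - centre.peak_z)


def ss_adaptation_peaks(
    cell: CellRecording,
    trial_licks: TrialLickSet,
    licks: LickTrain,
    min_trials: int = 10,
) -> dict:
    """Peak SS Z around tongue protraction per lick index and direction.

    PSTHs are aligned on max protrusion of lick k (k = 0..3) per direction,
    Z-scored against the 750 ms pre-lick baseline; the peak is taken in the
    -75..0 ms protraction window. Returns
    ``{direction: {k: peak_z or NaN}}``.
    """
    mp = licks.maxprot()
    out: dict = {}
    for direction in ("rightward", "centreward"):
        trs = [tl for tl in trial_licks.trials if tl.trial.direction == direction]
        peaks = {}
        for k in range(MAX_LICK_INDEX + 1):
            idx = [tl.lick_indices[k] for tl in trs if tl.lick_indices[k] is not None]
            if len(idx) < min_trials:
                peaks[k] = np.nan
                continue
            psth = compute_psth(
                cell.ss_times, mp[idx], window=(-1.0, 0.1),
                valid_range=(0.0, licks.session_duration),
            )
            psth = zscore_psth(psth, SS_ADAPT_BASELINE)
            if not psth.z_defined:
                peaks[k] = np.nan
                continue
            sl = psth.window_slice((PROTRACTION_WINDOW[0], PROTRACTION_WINDOW[1] - 1e-9))
            peaks[k] = float(np.max(psth.z[sl]))
        out[direction] = peaks
    return out


def opto_effect(
    licks: LickTrain,
    opto_trials: Sequence[OptoTrial],
    control_lick_indices: Sequence[int],
    max_index: int = MAX_LICK_INDEX,
) -> dict:
    """Mean endpoint differences (stim - control) per lick index and condition.

    Licks after each trigger are indexed 1..3 (lick 0 = trigger); controls
    are matched non-stimulated triggers. Results are keyed by
    (onset_offset, duration, fibre); positive dx = rightward.
    """
    if not licks.has_endpoints():
        raise ValueError("licks carry no endpoint coordinates")
    if not len(control_lick_indices):
        raise ValueError("no control licks")
    ex, ey = licks.endpoint_x, licks.endpoint_y
    n = licks.n_licks

    def _collect(trigger_indices: Sequence[int]) -> dict:
        coords = {k: [] for k in range(max_index + 1)}
        for i0 in trigger_indices:
            for k in range(max_index + 1):
                li = i0 + k
                if li >= n or not np.isfinite(ex[li]):
                    break
                if k > 0 and licks.detect_times[li] - licks.detect_times[li - 1] >= 0.5:
                    break  # bout ended
                coords[k].append((ex[li], ey[li]))
        return {k: np.array(v) if v else np.empty((0, 2)) for k, v in coords.items()}

    ctrl = _collect(control_lick_indices)
    out: dict = {}
    groups: dict = {}
    for tr in opto_trials:
        key = (tr.onset_offset, tr.duration, tr.fibre)
        groups.setdefault(key, []).append(tr.trigger_lick_index)
    for key, triggers in groups.items():
        stim = _collect(triggers)
        eff = {}
        for k in range(1, max_index + 1):
            if stim[k].size == 0 or ctrl[k].size == 0:
                eff[k] = {"dx": np.nan, "dy": np.nan, "n_stim": int(stim[k].shape[0])}
                continue
            eff[k] = {
                "dx": float(stim[k][:, 0].mean() - ctrl[k][:, 0].mean()),
                "dy": float(stim[k][:, 1].mean() - ctrl[k][:, 1].mean()),
                "n_stim": int(stim[k].shape[0]),
            }
        out[key] = eff
    return out
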