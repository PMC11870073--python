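"""Domain types, session container, bout segmentation and event-table I/O.

All times are seconds (floats) from session start; all coordinates are mm.
The x axis is lateral, positive toward the animal's right (ipsilateral to
right-hemisphere recordings); the y axis is the protrusion direction,
positive rostral; the origin is the resting spout position.

Event tables are plain UTF-8 CSV with mandatory header rows:

``licks.csv``
    ``t_detect_s, x_mm, y_mm, t_maxprot_s`` (last three optional / NaN-able)
``cells/<cell_id>.csv``
    ``t_s, kind`` with kind in {SS, CS}; a sidecar ``cells/<cell_id>.json``
    carries ``grid_row, grid_col, region_tag``
``port_trials.csv``
    ``trigger_lick_idx, move_onset_s, direction, displacement_mm``
``opto_trials.csv``
    ``trigger_lick_idx, onset_offset_s, duration_s, fibre`` (fibre
    ``control`` marks matched non-stimulated trigger licks)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: maximal tongue protrusion follows optical lick detection by ~16 ms
MAXPROT_DELAY_S = 0.016
#: inter-lick intervals below this gap belong to the same bout
BOUT_MAX_GAP_S = 0.5
#: minimal simple-spike pause after each complex spike (cell validity)
CS_PAUSE_S = 0.008
#: minimal number of analysable trials for a cell to be included
MIN_TRIALS = 20


class ValidationError(ValueError):
    """Raised when an input table or event list violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LickTrain:
    """Ordered lick detections with optional endpoint coordinates.

    Parameters
    ----------
    detect_times
        Strictly increasing detection times (s).
    endpoint_x, endpoint_y
        Tongue-tip coordinates at maximal protrusion (mm), one per lick,
        NaN where the video endpoint is missing.
    max_protrusion_times
        Times of maximal protrusion (s); derived as detection + 16 ms
        when absent.
    session_duration
        Length of the recording (s).
    """

    detect_times: np.ndarray
    session_duration: float
    endpoint_x: Optional[np.ndarray] = None
    endpoint_y: Optional[np.ndarray] = None
    max_protrusion_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.detect_times = np.asarray(self.detect_times, dtype=float)
        t = self.detect_times
        if t.size and np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValidationError(
                f"lick detect_times not strictly increasing at index {i}"
            )
        if t.size and (t[0] < 0 or t[-1] > self.session_duration):
            raise ValidationError("lick times outside [0, session_duration]")
        for name in ("endpoint_x", "endpoint_y", "max_protrusion_times"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != t.shape:
                    raise ValidationError(
                        f"{name} length {v.size} != number of licks {t.size}"
                    )
                setattr(self, name, v)

    @property
    def n_licks(self) -> int:
        return int(self.detect_times.size)

    def maxprot(self) -> np.ndarray:
        """Max-protrusion times, falling back to detection + 16 ms."""
        if self.max_protrusion_times is not None:
            out = self.max_protrusion_times.copy()
            bad = ~np.isfinite(out)
            out[bad] = self.detect_times[bad] + MAXPROT_DELAY_S
            return out
        return self.detect_times + MAXPROT_DELAY_S

    def has_endpoints(self) -> bool:
        return (
            self.endpoint_x is not None
            and self.endpoint_y is not None
            and bool(np.isfinite(self.endpoint_x).any())
        )


@dataclass
class CellRecording:
    """One Purkinje cell: simple-spike and complex-spike times plus location.

    ``grid_row`` (1-8) and ``grid_col`` (1-4) index the electrode entry point
    on the 8x4 recording grid; ``region_tag`` is ``medial`` or ``lateral``.
    """

    cell_id: str
    ss_times: np.ndarray
    cs_times: np.ndarray
    grid_row: int = 1
    grid_col: int = 1
    region_tag: str = "medial"

    def __post_init__(self) -> None:
        self.ss_times = np.asarray(self.ss_times, dtype=float)
        self.cs_times = np.asarray(self.cs_times, dtype=float)
        for name in ("ss_times", "cs_times"):
            t = getattr(self, name)
            if t.size and np.any(np.diff(t) <= 0):
                i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
                raise ValidationError(
                    f"{self.cell_id}: {name} not strictly increasing at index {i}"
                )
        if not 1 <= int(self.grid_row) <= 8:
            raise ValidationError(f"{self.cell_id}: grid_row {self.grid_row} outside 1-8")
        if not 1 <= int(self.grid_col) <= 4:
            raise ValidationError(f"{self.cell_id}: grid_col {self.grid_col} outside 1-4")


@dataclass(frozen=True)
class Bout:
    """A maximal run of licks whose inter-lick intervals stay below the gap."""

    first_lick_index: int
    last_lick_index: int
    start_time: float
    end_time: float

    @property
    def n_licks(self) -> int:
        return self.last_lick_index - self.first_lick_index + 1


@dataclass
class Session:
    """A full recording session: behaviour, cells and optional trial tables."""

    licks: LickTrain
    cells: list = field(default_factory=list)
    port_trials: list = field(default_factory=list)
    opto_trials: list = field(default_factory=list)
    opto_controls: list = field(default_factory=list)  # trigger lick indices
    metadata: dict = field(default_factory=dict)


@dataclass
class ValidityReport:
    """Outcome of the cell inclusion checks (reports, never raises)."""

    cell_id: str
    pause_ok: bool
    pause_offenders: np.ndarray  # CS times followed by an SS within 8 ms
    n_trials: int
    enough_trials: bool

    @property
    def passed(self) -> bool:
        return self.pause_ok and self.enough_trials


# ---------------------------------------------------------------------------
# bout segmentation
# ---------------------------------------------------------------------------

def segment_bouts(licks: LickTrain, max_gap: float = BOUT_MAX_GAP_S) -> list[Bout]:
    """Partition licks into bouts: runs with inter-lick intervals < ``max_gap``.

    A gap exactly equal to ``max_gap`` splits bouts (the within-bout rule is
    strictly "interval < 500 ms"). Single-lick bouts are permitted. Returns
    an empty list for an empty train.
    """
    t = licks.detect_times
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) >= max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))
    return [
        Bout(int(a), int(b), float(t[a]), float(t[b]))
        for a, b in zip(starts, ends)
    ]


def bout_epochs(bouts: Sequence[Bout]) -> np.ndarray:
    """(n, 2) array of [start_time, end_time] per bout."""
    if not bouts:
        return np.empty((0, 2))
    return np.array([[b.start_time, b.end_time] for b in bouts])


def in_bout_mask(times: np.ndarray, bouts: Sequence[Bout]) -> np.ndarray:
    """Boolean mask: which times fall inside any bout [start, end] interval."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for b in bouts:
        mask |= (times >= b.start_time) & (times <= b.end_time)
    return mask


# ---------------------------------------------------------------------------
# cell validity
# ---------------------------------------------------------------------------

def validate_cell(
    cell: CellRecording,
    n_trials: Optional[int] = None,
    min_trials: int = MIN_TRIALS,
    pause: float = CS_PAUSE_S,
) -> ValidityReport:
    """Check the complex-spike pause and trial-count inclusion criteria.

    A recording counts as a single Purkinje cell only if every complex spike
    is followed by >= 8 ms without simple spikes. ``n_trials`` is the number
    of analysable trials (licks, or perturbation trials when those are the
    unit of analysis); it must reach ``min_trials``.
    """
    ss, cs = cell.ss_times, cell.cs_times
    offenders = []
    if cs.size and ss.size:
        idx = np.searchsorted(ss, cs, side="right")
        ok = idx < ss.size
        gap = np.full(cs.shape, np.inf)
        gap[ok] = ss[idx[ok]] - cs[ok]
        offenders = cs[gap < pause]
    offenders = np.asarray(offenders, dtype=float)
    nt = int(n_trials) if n_trials is not None else 0
    return ValidityReport(
        cell_id=cell.cell_id,
        pause_ok=offenders.size == 0,
        pause_offenders=offenders,
        n_trials=nt,
        enough_trials=nt >= min_trials,
    )


# ---------------------------------------------------------------------------
# trial records (perturbation module consumes these)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PortTrial:
    """One lick-port movement event.

    ``rightward`` events are 3 mm displacements starting 40 ms after the
    trigger lick with 50 ms travel; the ``centreward`` event is the return
    to centre 750 ms later, recorded with ``move_onset`` at the return time.
    """

    trigger_lick_index: int
    move_onset: float
    direction: str  # rightward | centreward
    displacement: float = 3.0


@dataclass(frozen=True)
class OptoTrial:
    """One optogenetic stimulation trial (pulse timing relative to trigger lick)."""

    trigger_lick_index: int
    onset_offset: float  # 0.010 or 0.090 s after lick detection
    duration: float      # 0.080 or 0.160 s
    fibre: str           # right_medial | left_medial | lateral | both

    @property
    def pulse_onset_lick_relative(self) -> float:
        return self.onset_offset


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")


def _check_monotonic(values: np.ndarray, path: Path, column: str) -> None:
    bad = np.flatnonzero(np.diff(values) <= 0)
    if bad.size:
        # +2: header line plus 1-based data row of the second member of the pair
        raise ValidationError(
            f"{path}: column {column} not strictly increasing at line {int(bad[0]) + 3}"
        )


def write_session(session: Session, directory: str | Path) -> None:
    """Write a session to CSV/JSON event tables under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    licks = session.licks
    n = licks.n_licks
    nan = np.full(n, np.nan)
    pd.DataFrame(
        {
            "t_detect_s": licks.detect_times,
            "x_mm": licks.endpoint_x if licks.endpoint_x is not None else nan,
            "y_mm": licks.endpoint_y if licks.endpoint_y is not None else nan,
            "t_maxprot_s": (
                licks.max_protrusion_times
                if licks.max_protrusion_times is not None
                else nan
            ),
        }
    ).to_csv(d / "licks.csv", index=False, float_format="%.9f")
    (d / "session.json").write_text(
        json.dumps(
            {"session_duration": licks.session_duration, "metadata": session.metadata},
            indent=1,
            sort_keys=True,
        )
    )
    cdir = d / "cells"
    cdir.mkdir(exist_ok=True)
    for cell in session.cells:
        t = np.concatenate((cell.ss_times, cell.cs_times))
        kind = np.array(["SS"] * cell.ss_times.size + ["CS"] * cell.cs_times.size)
        order = np.argsort(t, kind="stable")
        pd.DataFrame({"t_s": t[order], "kind": kind[order]}).to_csv(
            cdir / f"{cell.cell_id}.csv", index=False, float_format="%.9f"
        )
        (cdir / f"{cell.cell_id}.json").write_text(
            json.dumps(
                {
                    "grid_row": int(cell.grid_row),
                    "grid_col": int(cell.grid_col),
                    "region_tag": cell.region_tag,
                },
                indent=1,
                sort_keys=True,
            )
        )
    if session.port_trials:
        pd.DataFrame(
            {
                "trigger_lick_idx": [t.trigger_lick_index for t in session.port_trials],
                "move_onset_s": [t.move_onset for t in session.port_trials],
                "direction": [t.direction for t in session.port_trials],
                "displacement_mm": [t.displacement for t in session.port_trials],
            }
        ).to_csv(d / "port_trials.csv", index=False, float_format="%.9f")
    if session.opto_trials or session.opto_controls:
        rows = [
            (t.trigger_lick_index, t.onset_offset, t.duration, t.fibre)
            for t in session.opto_trials
        ] + [(i, np.nan, np.nan, "control") for i in session.opto_controls]
        pd.DataFrame(
            rows, columns=["trigger_lick_idx", "onset_offset_s", "duration_s", "fibre"]
        ).to_csv(d / "opto_trials.csv", index=False, float_format="%.9f")


def read_session(directory: str | Path) -> Session:
    """Read a session written by :func:`write_session`.

    Round-trips all times to 1 ns and coordinates to 1 nm (9 decimals
    written). Licks with NaN endpoints are retained with the endpoint
    marked missing; duplicated or non-monotonic times are rejected with
    the offending line number.
    """
    d = Path(directory)
    lick_path = d / "licks.csv"
    df = pd.read_csv(lick_path)
    _require_columns(df, ["t_detect_s"], lick_path)
    t = df["t_detect_s"].to_numpy(dtype=float)
    _check_monotonic(t, lick_path, "t_detect_s")
    meta = json.loads((d / "session.json").read_text())

    def _opt(col: str) -> Optional[np.ndarray]:
        if col in df.columns and np.isfinite(df[col]).any():
            return df[col].to_numpy(dtype=float)
        return None

    licks = LickTrain(
        detect_times=t,
        session_duration=float(meta["session_duration"]),
        endpoint_x=_opt("x_mm"),
        endpoint_y=_opt("y_mm"),
        max_protrusion_times=_opt("t_maxprot_s"),
    )
    cells = []
    cdir = d / "cells"
    if cdir.is_dir():
        for path in sorted(cdir.glob("*.csv")):
            cdf = pd.read_csv(path)
            _require_columns(cdf, ["t_s", "kind"], path)
            side = json.loads(path.with_suffix(".json").read_text())
            ts = cdf["t_s"].to_numpy(dtype=float)
            kinds = cdf["kind"].to_numpy()
            cells.append(
                CellRecording(
                    cell_id=path.stem,
                    ss_times=ts[kinds == "SS"],
                    cs_times=ts[kinds == "CS"],
                    grid_row=side["grid_row"],
                    grid_col=side["grid_col"],
                    region_tag=side["region_tag"],
                )
            )
    port_trials = []
    pt_path = d / "port_trials.csv"
    if pt_path.exists():
        pdf = pd.read_csv(pt_path)
        _require_columns(
            pdf, ["trigger_lick_idx", "move_onset_s", "direction", "displacement_mm"], pt_path
        )
        port_trials = [
            PortTrial(int(r.trigger_lick_idx), float(r.move_onset_s), str(r.direction),
                      float(r.displacement_mm))
            for r in pdf.itertuples()
        ]
    opto_trials: list[OptoTrial] = []
    opto_controls: list[int] = []
    ot_path = d / "opto_trials.csv"
    if ot_path.exists():
        odf = pd.read_csv(ot_path)
        _require_columns(
            odf, ["trigger_lick_idx", "onset_offset_s", "duration_s", "fibre"], ot_path
        )
        for r in odf.itertuples():
            if str(r.fibre) == "control":
                opto_controls.append(int(r.trigger_lick_idx))
            else:
                opto_trials.append(
                    OptoTrial(int(r.trigger_lick_idx), float(r.onset_offset_s),
                              float(r.duration_s), str(r.fibre))
                )
    return Session(
        licks=licks,
        cells=cells,
        port_trials=port_trials,
        opto_trials=opto_trials,
        opto_controls=opto_controls,
        metadata=meta.get("metadata", {}),
    )
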