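"""Tongue-endpoint "rosette" analysis.

Each session's maximal-protrusion endpoints are divided into tertiles on
both the left-right (x) and rostro-caudal (y) axes, adapting to the
animal's individual bias. Per zone of the resulting 3x3 grid, the mean
Z-scored simple-spike rate is computed in two pre-protrusion windows
(early: -150..-75 ms, late: -75..0 ms relative to max protrusion); the
late window carries the ipsiversive/contraversive comparison. Ipsiversive
means positive x (toward the recorded right hemisphere); set
``ipsi_positive_x=False`` for left-hemisphere data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_io import CellRecording, LickTrain
from .modulation import BASELINE_PER_LICK, PSTH_BIN_S, compute_psth, zscore_psth

EARLY_WINDOW = (-0.150, -0.075)
LATE_WINDOW = (-0.075, 0.0)
MIN_LICKS_FOR_ROSETTE = 9


@dataclass
class Rosette:
    """Per-session 3x3 tertile partition of tongue endpoints.

    Edges are the empirical 1/3 and 2/3 quantiles of this session's
    endpoints; zone assignment is half-open (a value equal to an edge goes
    to the upper tertile). ``zone_of_lick`` is 1..9 with row = y tertile
    (1 = caudal), col = x tertile (1 = left), zone = (row-1)*3 + col, and
    0 for licks without endpoints.
    """

    x_tertile_edges: np.ndarray
    y_tertile_edges: np.ndarray
    zone_of_lick: np.ndarray

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        z = self.zone_of_lick
        return (z - 1) // 3 + 1, (z - 1) % 3 + 1


def _tertile(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """0-based tertile index; values equal to an edge go up (half-open)."""
    return np.searchsorted(edges, values, side="right")


def build_rosette(licks: LickTrain) -> Rosette:
    """Tertile partition of the session's endpoint distribution."""
    if not licks.has_endpoints():
        raise ValueError("licks carry no endpoint coordinates")
    x, y = licks.endpoint_x, licks.endpoint_y
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < MIN_LICKS_FOR_ROSETTE:
        raise ValueError(
            f"only {int(ok.sum())} endpoints, need >= {MIN_LICKS_FOR_ROSETTE}"
        )
    xe = np.quantile(x[ok], [1 / 3, 2 / 3])
    ye = np.quantile(y[ok], [1 / 3, 2 / 3])
    zone = np.zeros(x.shape, dtype=int)
    col = _tertile(x[ok], xe)
    row = _tertile(y[ok], ye)
    zone[ok] = row * 3 + col + 1
    return Rosette(x_tertile_edges=xe, y_tertile_edges=ye, zone_of_lick=zone)


@dataclass
class ZoneMap:
    """Mean SS Z per rosette zone for the early and late windows."""

    early: np.ndarray  # 3x3, rows = y tertile, cols = x tertile
    late: np.ndarray
    n_licks: np.ndarray  # 3x3 zone occupancy
    per_lick_z_early: np.ndarray
    per_lick_z_late: np.ndarray
    x_marginal: np.ndarray  # late-window mean per x tertile
    y_marginal: np.ndarray


def per_lick_window_z(
    cell: CellRecording,
    licks: LickTrain,
    window: tuple[float, float],
    baseline: tuple[float, float] = BASELINE_PER_LICK,
) -> np.ndarray:
    """Per-lick SS rate in a window before max protrusion, Z-scored against
    the per-lick baseline (-1000..-250 ms before detection).

    Baseline statistics come from 10 ms binned rates; the window value is
    the rate over the whole window. Licks whose baseline SD is zero get NaN.
    """
    mp = licks.maxprot()
    t = licks.detect_times
    ss = cell.ss_times
    width = window[1] - window[0]
    n_base = int(round((baseline[1] - baseline[0]) / PSTH_BIN_S))
    out = np.full(t.shape, np.nan)
    for i in range(t.size):
        b0, b1 = t[i] + baseline[0], t[i] + baseline[1]
        if b0 < 0 or mp[i] + window[1] > licks.session_duration:
            continue
        edges = np.linspace(b0, b1, n_base + 1)
        base_rates = np.diff(np.searchsorted(ss, edges)) / PSTH_BIN_S
        mu, sd = base_rates.mean(), base_rates.std(ddof=0)
        if sd <= 0:
            continue
        w0, w1 = mp[i] + window[0], mp[i] + window[1]
        n_win = int(np.searchsorted(ss, w1, side="right") - np.searchsorted(ss, w0, side="left"))
        out[i] = (n_win / width - mu) / sd
    return out


def zone_ss_map(
    cell: CellRecording,
    licks: LickTrain,
    rosette: Optional[Rosette] = None,
    windows: tuple = (EARLY_WINDOW, LATE_WINDOW),
) -> ZoneMap:
    """Mean per-lick SS Z per rosette zone in the two pre-protrusion windows."""
    if rosette is None:
        rosette = build_rosette(licks)
    z_early = per_lick_window_z(cell, licks, windows[0])
    z_late = per_lick_window_z(cell, licks, windows[1])
    rows, cols = rosette.rows_cols()
    maps = []
    counts = np.zeros((3, 3), dtype=int)
    for z in (z_early, z_late):
        m = np.full((3, 3), np.nan)
        for r in range(3):
            for c in range(3):
                sel = (rows == r + 1) & (cols == c + 1) & np.isfinite(z)
                counts[r, c] = int(((rows == r + 1) & (cols == c + 1)).sum())
                if sel.any():
                    m[r, c] = float(np.mean(z[sel]))
        maps.append(m)
    x_marg = np.full(3, np.nan)
    y_marg = np.full(3, np.nan)
    for k in range(3):
        selx = (cols == k + 1) & np.isfinite(z_late)
        sely = (rows == k + 1) & np.isfinite(z_late)
        if selx.any():
            x_marg[k] = float(np.mean(z_late[selx]))
        if sely.any():
            y_marg[k] = float(np.mean(z_late[sely]))
    return ZoneMap(
        early=maps[0],
        late=maps[1],
        n_licks=counts,
        per_lick_z_early=z_early,
        per_lick_z_late=z_late,
        x_marginal=x_marg,
        y_marginal=y_marg,
    )


@dataclass
class LateralResult:
    """Per-cell ipsiversive vs contraversive SS statistics (late window)."""

    mean_ipsi: float
    mean_contra: float
    peak_ipsi: float
    peak_contra: float
    n_ipsi: int
    n_contra: int


def lateral_comparison(
    cell: CellRecording,
    licks: LickTrain,
    rosette: Optional[Rosette] = None,
    ipsi_positive_x: bool = True,
) -> LateralResult:
    """Mean and peak SS Z for licks bending ipsi- vs contraversively.

    Means are over per-lick late-window Z values of the outer x tertiles;
    peaks are the maxima of the per-group pooled PSTH (Z-scored against the
    per-lick baseline) within the late window before max protrusion.
    """
    if rosette is None:
        rosette = build_rosette(licks)
    _, cols = rosette.rows_cols()
    ipsi_col, contra_col = (3, 1) if ipsi_positive_x else (1, 3)
    z_late = per_lick_window_z(cell, licks, LATE_WINDOW)
    sel_i = (cols == ipsi_col) & np.isfinite(z_late)
    sel_c = (cols == contra_col) & np.isfinite(z_late)
    if not sel_i.any() or not sel_c.any():
        raise ValueError("a lateral tertile is empty")

    def _peak(mask: np.ndarray) -> float:
        mp = licks.maxprot()[mask]
        psth = compute_psth(
            cell.ss_times, mp, window=(-1.0, 0.1),
            valid_range=(0.0, licks.session_duration),
        )
        psth = zscore_psth(psth, BASELINE_PER_LICK)
        if not psth.z_defined:
            return np.nan
        sl = psth.window_slice((LATE_WINDOW[0], LATE_WINDOW[1] - 1e-9))
        return float(np.max(psth.z[sl]))

    return LateralResult(
        mean_ipsi=float(np.mean(z_late[sel_i])),
        mean_contra=float(np.mean(z_late[sel_c])),
        peak_ipsi=_peak(cols == ipsi_col),
        peak_contra=_peak(cols == contra_col),
        n_ipsi=int(sel_i.sum()),
        n_contra=int(sel_c.sum()),
    )
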