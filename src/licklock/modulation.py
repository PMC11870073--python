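"""PSTH construction, baseline Z-scoring and modulation statistics.

Z-scores are (value - baseline mean) / baseline SD, with the baseline window
depending on the analysis: -1000..-500 ms before bout onset for bout-start
modulation, +500..+1000 ms after bout end for bout-end modulation, and
-1000..-250 ms before the licks of interest for per-lick normalization.
Significance of a modulation is judged by the peak bin's Z exceeding 3
within the stated analysis window. Alignment events whose PSTH window would
cross the session edges are dropped whole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import Bout, CellRecording, LickTrain

PSTH_BIN_S = 0.010
Z_THRESHOLD = 3.0
MODULATION_WINDOW_S = 0.200
#: 300 ms interval centred on bout-transition lick detection
TRANSITION_WINDOW = (-0.150, 0.150)
BASELINE_BOUT_START = (-1.0, -0.5)
BASELINE_BOUT_END = (0.5, 1.0)
BASELINE_PER_LICK = (-1.0, -0.25)
#: complex spikes within this window before detection condition a lick
CS_CONDITION_WINDOW_S = 0.075


@dataclass
class Psth:
    """Binned event rate aligned to reference events.

    ``counts`` pools events over all alignments; ``rate`` is
    counts / (n_align * bin width) in Hz; ``z`` is present after
    :func:`zscore_psth`.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_align: int
    bin_width: float = PSTH_BIN_S
    z: Optional[np.ndarray] = None
    baseline_window: Optional[tuple] = None
    baseline_mean: float = np.nan
    baseline_sd: float = np.nan
    z_defined: bool = False

    @property
    def rate(self) -> np.ndarray:
        return self.counts / (self.n_align * self.bin_width)

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def window_slice(self, window: tuple[float, float]) -> slice:
        c = self.centers
        idx = np.flatnonzero((c >= window[0]) & (c <= window[1]))
        if idx.size == 0:
            raise ValueError(f"window {window} outside PSTH range")
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class ModulationResult:
    """Depth and significance of a PSTH modulation in a stated window."""

    depth: float
    peak_z: float
    significant: bool
    window: tuple
    n_align: int = 0
    z_defined: bool = True


def compute_psth(
    event_times: np.ndarray,
    align_times: np.ndarray,
    window: tuple[float, float],
    bin_width: float = PSTH_BIN_S,
    valid_range: Optional[tuple[float, float]] = None,
) -> Psth:
    """Pooled peri-event histogram of ``event_times`` around ``align_times``.

    ``window`` is (t0, t1) relative to each alignment; when ``valid_range``
    is given, alignments whose window would cross it are excluded whole.
    """
    event_times = np.sort(np.asarray(event_times, dtype=float))
    align_times = np.asarray(align_times, dtype=float)
    if valid_range is not None:
        ok = (align_times + window[0] >= valid_range[0]) & (
            align_times + window[1] <= valid_range[1]
        )
        align_times = align_times[ok]
    if align_times.size == 0:
        raise ValueError("no alignment events (after edge exclusion)")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    if n_bins < 1:
        raise ValueError("window does not cover a full bin")
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    lo = np.searchsorted(event_times, align_times + edges[0], side="left")
    hi = np.searchsorted(event_times, align_times + edges[-1], side="right")
    rel = [event_times[a:b] - t for t, a, b in zip(align_times, lo, hi)]
    if rel:
        allrel = np.concatenate(rel)
        counts, _ = np.histogram(allrel, bins=edges)
    return Psth(
        bin_edges=edges,
        counts=counts.astype(float),
        n_align=int(align_times.size),
        bin_width=bin_width,
    )


def zscore_psth(psth: Psth, baseline_window: tuple[float, float]) -> Psth:
    """Z-score the PSTH rate against its own baseline bins.

    A zero baseline SD leaves ``z`` undefined and flags the PSTH
    (``z_defined`` False); such cells are excluded from significance counts
    rather than silently inflated by an SD floor.
    """
    sl = psth.window_slice(baseline_window)
    if sl.stop - sl.start < 2:
        raise ValueError("baseline window must contain at least 2 bins")
    base = psth.rate[sl]
    mu = float(base.mean())
    sd = float(base.std(ddof=0))
    psth.baseline_window = baseline_window
    psth.baseline_mean = mu
    psth.baseline_sd = sd
    if sd > 0:
        psth.z = (psth.rate - mu) / sd
        psth.z_defined = True
    else:
        psth.z = np.full(psth.counts.shape, np.nan)
        psth.z_defined = False
    return psth


def modulation_depth(
    psth: Psth,
    window: tuple[float, float] = (-MODULATION_WINDOW_S / 2, MODULATION_WINDOW_S / 2),
    use_z: bool = True,
) -> ModulationResult:
    """Max - min of the mean modulation inside ``window`` (default 200 ms).

    Depth is measured on the Z-scored trace when available (Z units),
    otherwise on the rate (Hz). Significance requires the peak |Z| bin
    within the window to exceed 3.
    """
    sl = psth.window_slice(window)
    trace = psth.z[sl] if (use_z and psth.z_defined) else psth.rate[sl]
    depth = float(np.max(trace) - np.min(trace))
    if psth.z_defined and psth.z is not None:
        zw = psth.z[sl]
        peak_z = float(zw[np.argmax(np.abs(zw))])
        significant = bool(np.max(np.abs(zw)) > Z_THRESHOLD)
    else:
        peak_z = np.nan
        significant = False
    return ModulationResult(
        depth=depth,
        peak_z=peak_z,
        significant=significant,
        window=window,
        n_align=psth.n_align,
        z_defined=psth.z_defined,
    )


def poisson_calibrated_z(counts: np.ndarray, baseline_counts: np.ndarray) -> np.ndarray:
    """Per-bin Z equivalents of the exact Poisson upper tail.

    Low-rate PSTHs (complex spikes at ~1 Hz give only a few counts per
    10 ms bin) have strongly right-skewed bins, so the plain
    (value - mean)/SD score exceeds 3 far more often than a 3-sigma
    criterion implies. Here each bin count is referred to the exact
    Poisson tail at the baseline mean count, mapped back to a normal
    quantile: z = Phi^-1(P(K >= k)). For large counts this converges to
    (value - mean)/SD; for small counts it keeps the 3-sigma criterion
    calibrated.
    """
    lam = float(np.mean(baseline_counts))
    if lam <= 0:
        return np.full(np.shape(counts), np.nan)
    k = np.asarray(counts)
    # mid-P tail: P(K > k) + P(K = k)/2, approximately uniform under the null
    sf = stats.poisson.sf(k, lam) + 0.5 * stats.poisson.pmf(k, lam)
    return stats.norm.isf(np.clip(sf, 1e-300, 1.0 - 1e-16))


def bout_transition_response(
    cs_times: np.ndarray,
    bouts: Sequence[Bout],
    which: str,
    session_duration: Optional[float] = None,
    min_trials: int = 20,
) -> ModulationResult:
    """Complex-spike response at bout start or end.

    PSTH aligned on the first (or last) lick of each bout; Z against the
    -1000..-500 ms pre-start (or +500..+1000 ms post-end) baseline;
    significant when the peak Z within the 300 ms centred window exceeds 3,
    with the 3-sigma criterion evaluated through the exact Poisson tail of
    the bin counts (see :func:`poisson_calibrated_z`) so that it stays
    calibrated for sparse complex-spike histograms.
    """
    if which not in ("start", "end"):
        raise ValueError("which must be 'start' or 'end'")
    if len(bouts) < min_trials:
        raise ValueError(f"only {len(bouts)} bouts, need >= {min_trials}")
    align = np.array(
        [b.start_time if which == "start" else b.end_time for b in bouts]
    )
    baseline = BASELINE_BOUT_START if which == "start" else BASELINE_BOUT_END
    window = (-1.25, 1.25)
    valid = (0.0, session_duration) if session_duration is not None else None
    psth = compute_psth(cs_times, align, window, valid_range=valid)
    psth = zscore_psth(psth, baseline)
    sl = psth.window_slice(TRANSITION_WINDOW)
    base_counts = psth.counts[psth.window_slice(baseline)]
    zcal = poisson_calibrated_z(psth.counts[sl], base_counts)
    if np.isfinite(zcal).any():
        peak_z = float(np.nanmax(zcal))
        significant = bool(peak_z > Z_THRESHOLD)
    else:
        peak_z, significant = np.nan, False
    trace = psth.z[sl] if psth.z_defined else psth.rate[sl]
    return ModulationResult(
        depth=float(np.max(trace) - np.min(trace)),
        peak_z=peak_z,
        significant=significant,
        window=TRANSITION_WINDOW,
        n_align=psth.n_align,
        z_defined=psth.z_defined,
    )


@dataclass
class ConditionedResult:
    """Lick analysis split by the presence of a preceding complex spike."""

    n_with_cs: int
    n_without_cs: int
    mean_prelick_z_with: float     # SS Z over the 150 ms before detection
    mean_prelick_z_without: float
    endpoint_x_with: np.ndarray
    endpoint_x_without: np.ndarray
    endpoint_y_with: np.ndarray
    endpoint_y_without: np.ndarray
    incomplete: bool = False

    @property
    def mean_dx(self) -> float:
        return float(np.nanmean(self.endpoint_x_with) - np.nanmean(self.endpoint_x_without))

    @property
    def mean_dy(self) -> float:
        return float(np.nanmean(self.endpoint_y_with) - np.nanmean(self.endpoint_y_without))


def cs_conditioned_licks(
    cell: CellRecording,
    licks: LickTrain,
    cs_window: float = CS_CONDITION_WINDOW_S,
) -> ConditionedResult:
    """Split licks by whether a CS fell in the 75 ms before detection.

    Returns the mean SS Z-score of the 150 ms pre-detection interval per
    group (per-lick baseline -1000..-250 ms) and per-group endpoint
    coordinates. A single-group result is flagged incomplete.
    """
    t = licks.detect_times
    cs = cell.cs_times
    has_cs = np.zeros(t.shape, dtype=bool)
    if cs.size:
        lo = np.searchsorted(cs, t - cs_window, side="left")
        hi = np.searchsorted(cs, t, side="right")
        has_cs = hi > lo
    groups = {}
    for label, mask in (("with", has_cs), ("without", ~has_cs)):
        if mask.sum() == 0:
            groups[label] = (0, np.nan)
            continue
        psth = compute_psth(
            cell.ss_times,
            t[mask],
            window=(-1.0, 0.2),
            valid_range=(0.0, licks.session_duration),
        )
        psth = zscore_psth(psth, BASELINE_PER_LICK)
        sl = psth.window_slice((-0.150, -0.001))
        mean_z = float(np.mean(psth.z[sl])) if psth.z_defined else np.nan
        groups[label] = (int(mask.sum()), mean_z)
    ex = licks.endpoint_x if licks.endpoint_x is not None else np.full(t.shape, np.nan)
    ey = licks.endpoint_y if licks.endpoint_y is not None else np.full(t.shape, np.nan)
    return ConditionedResult(
        n_with_cs=groups["with"][0],
        n_without_cs=groups["without"][0],
        mean_prelick_z_with=groups["with"][1],
        mean_prelick_z_without=groups["without"][1],
        endpoint_x_with=ex[has_cs],
        endpoint_x_without=ex[~has_cs],
        endpoint_y_with=ey[has_cs],
        endpoint_y_without=ey[~has_cs],
        incomplete=(groups["with"][0] == 0 or groups["without"][0] == 0),
    )
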