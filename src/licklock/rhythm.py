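"""Phase transform onto the lick cycle and coherence at the lick fundamental.

The lick cycle is parameterized so that phase 0 marks protrusion start,
pi the moment of maximal protrusion and 2*pi the end of retraction. With
only the optical detection and the max-protrusion anchor available, the
cycle boundaries are placed at the temporal midpoints between neighbouring
max-protrusion anchors within a bout (bout-edge cycles use the bout's mean
half-cycle), which honours the anchors exactly and needs no free parameter.

Coherence between spiking and licking is computed on the *warped* axis
(units of lick cycles): spike and lick times are mapped through the phase
transform, which annihilates timing differences between individual licks.
The spike-lick cross-correlogram and the lick autocorrelogram are assembled
from per-lick rows (one ±2-cycle window per lick), and the magnitude-squared
coherence averages the per-lick cross and auto spectra — the events
themselves provide the averaging, so unlocked spiking has random spectral
phase across licks and msc collapses toward 0, while phase-locked spiking
keeps a consistent phase and msc approaches 1. Both msc and the
cross-spectrum phase are read at one cycle^-1, the lick fundamental.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core_io import Bout, LickTrain, segment_bouts

#: correlogram span on the warped axis, in lick cycles
CORR_WINDOW_CYCLES = 2.0
#: a cell is called coherent with licking when msc exceeds this (strictly)
COHERENCE_THRESHOLD = 0.5
#: minimal number of in-bout spikes for a classifiable coherence estimate
MIN_SPIKES_FOR_COHERENCE = 100


@dataclass
class PhaseMap:
    """Piecewise-linear map from time to lick-cycle phase.

    ``starts``, ``maxima``, ``ends`` hold the per-cycle anchors s_i < m_i < e_i
    (phase 0, pi, 2*pi). Cycles are contiguous within a bout and indexed
    globally, so ``warp`` returns a cumulative cycle coordinate
    (cycle index + phase / 2*pi) suitable for correlograms.
    """

    starts: np.ndarray
    maxima: np.ndarray
    ends: np.ndarray
    lick_indices: np.ndarray  # index into the LickTrain per cycle

    @property
    def n_cycles(self) -> int:
        return int(self.maxima.size)

    def _locate(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.starts, times, side="right") - 1
        idx = np.clip(idx, 0, max(self.n_cycles - 1, 0))
        valid = (
            (self.n_cycles > 0)
            & (times >= self.starts[idx])
            & (times <= self.ends[idx])
        )
        return idx, valid

    def phase(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Phase in [0, 2*pi) and a validity mask (False outside any cycle)."""
        times = np.asarray(times, dtype=float)
        idx, valid = self._locate(times)
        phi = np.full(times.shape, np.nan)
        if self.n_cycles == 0:
            return phi, valid
        s, m, e = self.starts[idx], self.maxima[idx], self.ends[idx]
        rising = times <= m
        with np.errstate(invalid="ignore", divide="ignore"):
            up = np.pi * (times - s) / (m - s)
            down = np.pi + np.pi * (times - m) / (e - m)
        phi = np.where(rising, up, down)
        phi[~valid] = np.nan
        return phi, valid

    def warp(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative cycle coordinate (cycle index + phase/2*pi) and mask."""
        idx, valid = self._locate(times)
        phi, _ = self.phase(times)
        return idx + phi / (2.0 * np.pi), valid

    def lick_positions(self) -> np.ndarray:
        """Warped coordinates of the lick anchors (max protrusion, phase pi)."""
        return np.arange(self.n_cycles) + 0.5


def build_phase_map(
    licks: LickTrain, bouts: Optional[Sequence[Bout]] = None
) -> PhaseMap:
    """Construct the lick-cycle phase map from max-protrusion anchors.

    Bouts with a single lick define no cycle: their licks carry no phase.
    """
    if bouts is None:
        bouts = segment_bouts(licks)
    mp = licks.maxprot()
    starts, maxima, ends, lidx = [], [], [], []
    for b in bouts:
        if b.n_licks < 2:
            continue
        m = mp[b.first_lick_index : b.last_lick_index + 1]
        half = float(np.mean(np.diff(m))) / 2.0
        mids = (m[:-1] + m[1:]) / 2.0
        s = np.concatenate(([m[0] - half], mids))
        e = np.concatenate((mids, [m[-1] + half]))
        starts.append(s)
        maxima.append(m)
        ends.append(e)
        lidx.append(np.arange(b.first_lick_index, b.last_lick_index + 1))
    if not starts:
        z = np.empty(0)
        return PhaseMap(z, z, z, np.empty(0, dtype=int))
    return PhaseMap(
        np.concatenate(starts),
        np.concatenate(maxima),
        np.concatenate(ends),
        np.concatenate(lidx),
    )


# ---------------------------------------------------------------------------
# correlograms
# ---------------------------------------------------------------------------

def _correlogram(
    source: np.ndarray,
    reference: np.ndarray,
    span: float,
    bin_width: float,
    exclude_zero_lag: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of (source - reference) lags within +/- span.

    Both inputs must be sorted. Returns (lag bin centres, counts per
    reference, i.e. counts / n_reference).
    """
    n_bins = int(round(2 * span / bin_width))
    edges = -span + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    if source.size == 0 or reference.size == 0:
        return (edges[:-1] + edges[1:]) / 2.0, counts
    lo = np.searchsorted(source, reference - span, side="left")
    hi = np.searchsorted(source, reference + span, side="right")
    diffs = []
    for r, a, b in zip(reference, lo, hi):
        d = source[a:b] - r
        if exclude_zero_lag:
            d = d[d != 0.0]
        diffs.append(d)
    if diffs:
        alld = np.concatenate(diffs)
        counts, _ = np.histogram(alld, bins=edges)
    return (edges[:-1] + edges[1:]) / 2.0, counts.astype(float) / reference.size


@dataclass
class CoherenceResult:
    """Magnitude-squared coherence and phase at the lick fundamental."""

    msc: float
    phase: float  # preferred lick-cycle phase, radians in [0, 2*pi)
    fundamental: float  # cycles^-1 on the warped axis
    n_spikes: int
    low_power: bool = False

    @property
    def coherent(self) -> bool:
        return (not self.low_power) and self.msc > COHERENCE_THRESHOLD


def lick_coherence(
    spike_times: np.ndarray,
    licks: LickTrain,
    phase_map: Optional[PhaseMap] = None,
    corr_window: float = CORR_WINDOW_CYCLES,
    min_spikes: int = MIN_SPIKES_FOR_COHERENCE,
) -> CoherenceResult:
    """Coherence between a spike train and licking at the lick fundamental.

    Spikes are phase-transformed onto the warped (cycle) axis. Each lick
    contributes one ±``corr_window``-cycle correlogram window; the cross
    (spike-lick) and auto (lick-lick) spectra are evaluated at 1 cycle^-1
    directly from the continuous lags with a Hann taper (which exactly
    annihilates a uniform background at the fundamental), and averaged over
    licks — the events provide the averaging, so an unlocked train has
    random spectral phase across licks and msc collapses toward 0, while a
    locked train keeps a consistent phase and msc approaches 1. The
    cross-spectrum phase is reported in the lick-cycle convention
    (pi = max protrusion). Results from fewer than ``min_spikes`` in-cycle
    spikes are flagged ``low_power`` and never classified as coherent.
    """
    if phase_map is None:
        phase_map = build_phase_map(licks)
    spike_times = np.asarray(spike_times, dtype=float)
    warped, valid = phase_map.warp(spike_times)
    sw = np.sort(warped[valid])
    lick_pos = phase_map.lick_positions()
    n_in = int(sw.size)
    if n_in < min_spikes or lick_pos.size < 4:
        return CoherenceResult(0.0, np.nan, 1.0, n_in, low_power=True)

    def _window_transforms(source: np.ndarray, exclude_self: bool) -> np.ndarray:
        """Per-lick tapered transform at 1 cycle^-1 of lags in ±corr_window."""
        lo = np.searchsorted(source, lick_pos - corr_window, side="left")
        hi = np.searchsorted(source, lick_pos + corr_window, side="right")
        out = np.zeros(lick_pos.size, dtype=complex)
        for i, (r, a, b) in enumerate(zip(lick_pos, lo, hi)):
            d = source[a:b] - r
            if exclude_self:
                d = d[d != 0.0]
            taper = 0.5 * (1.0 + np.cos(np.pi * d / corr_window))
            out[i] = np.sum(taper * np.exp(-2j * np.pi * d))
        return out

    fx = _window_transforms(sw, exclude_self=False)
    fy = _window_transforms(lick_pos, exclude_self=True)
    sxy = np.mean(np.conj(fx) * fy)
    sxx = float(np.mean(np.abs(fx) ** 2))
    syy = float(np.mean(np.abs(fy) ** 2))
    denom = sxx * syy
    msc = float(np.abs(sxy) ** 2 / denom) if denom > 0 else 0.0
    # lick anchors sit at phase pi on the warped axis; a spike bump at lag
    # delta cycles from the anchors has cross-spectrum angle 2*pi*delta
    phase = float(np.mod(np.angle(sxy) + np.pi, 2 * np.pi))
    return CoherenceResult(min(msc, 1.0), phase, 1.0, n_in)


# ---------------------------------------------------------------------------
# autocorrelogram power in vs out of bouts
# ---------------------------------------------------------------------------

@dataclass
class PowerResult:
    """Relative spectral power of SS autocorrelograms, in vs between bouts."""

    freq_grid: np.ndarray
    power_in_bout: np.ndarray
    power_out_bout: np.ndarray
    preferred_lick_freq: float
    power_at_pref_in: float
    power_at_pref_out: float
    flagged: bool = False


def _autocorr_power_spectrum(
    times: np.ndarray, span: float, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized power spectrum of a mean-removed, Hann-tapered autocorrelogram."""
    _, counts = _correlogram(times, times, span, bin_width, exclude_zero_lag=True)
    x = counts - counts.mean()
    x = x * signal.windows.hann(x.size)
    spec = np.abs(np.fft.rfft(x)) ** 2
    total = spec[1:].sum()
    if total > 0:
        spec = spec / total
    freqs = np.fft.rfftfreq(x.size, d=bin_width)
    return freqs, spec


def autocorr_power(
    ss_times: np.ndarray,
    licks: LickTrain,
    bouts: Optional[Sequence[Bout]] = None,
    span: float = 2.0,
    bin_width: float = 0.010,
    freq_band: tuple[float, float] = (3.0, 12.0),
) -> PowerResult:
    """Rhythmic SS power at the lick frequency, during vs between bouts.

    Autocorrelograms (lags +/- ``span`` s, ``bin_width`` bins, mean removed,
    Hann tapered) are computed separately from spikes inside bout epochs and
    between them; spectra are normalized to unit total power so the
    comparison is about rhythmicity, not firing rate. The preferred lick
    frequency is the argmax of the lick autocorrelogram spectrum in 3-12 Hz.
    """
    if bouts is None:
        bouts = segment_bouts(licks)
    ss_times = np.asarray(ss_times, dtype=float)
    mask = np.zeros(ss_times.shape, dtype=bool)
    total_in = 0.0
    for b in bouts:
        mask |= (ss_times >= b.start_time) & (ss_times <= b.end_time)
        total_in += b.end_time - b.start_time
    ss_in = ss_times[mask]
    ss_out = ss_times[~mask]
    total_out = licks.session_duration - total_in
    flagged = total_in < 2.0 or total_out < 2.0 or ss_in.size < 2 or ss_out.size < 2
    freqs, lick_spec = _autocorr_power_spectrum(licks.detect_times, span, bin_width)
    band = (freqs >= freq_band[0]) & (freqs <= freq_band[1])
    pref = float(freqs[band][np.argmax(lick_spec[band])]) if band.any() else np.nan
    _, p_in = _autocorr_power_spectrum(ss_in, span, bin_width)
    _, p_out = _autocorr_power_spectrum(ss_out, span, bin_width)
    k = int(np.argmin(np.abs(freqs - pref))) if np.isfinite(pref) else 0
    return PowerResult(
        freq_grid=freqs,
        power_in_bout=p_in,
        power_out_bout=p_out,
        preferred_lick_freq=pref,
        power_at_pref_in=float(p_in[k]),
        power_at_pref_out=float(p_out[k]),
        flagged=bool(flagged),
    )


# ---------------------------------------------------------------------------
# spatial grid summary
# ---------------------------------------------------------------------------

def grid_summary(values: np.ndarray) -> np.ndarray:
    """Reduce an 8x4 per-electrode value grid to a 7x3 matrix of 2x2 means.

    ``values`` is an 8x4 array with NaN for unoccupied electrodes. Output
    cell (i, j) is the mean of the available values in input rows {i, i+1}
    and columns {j, j+1}; an all-missing neighbourhood stays NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (8, 4):
        raise ValueError(f"expected an 8x4 grid, got {values.shape}")
    out = np.full((7, 3), np.nan)
    for i in range(7):
        for j in range(3):
            block = values[i : i + 2, j : j + 2]
            if np.isfinite(block).any():
                out[i, j] = np.nanmean(block)
    return out


def cell_grid(cells: Sequence, values: Sequence[float]) -> np.ndarray:
    """Arrange per-cell scalars onto the 8x4 grid (mean where cells share an
    electrode), ready for :func:`grid_summary`."""
    acc = np.zeros((8, 4))
    n = np.zeros((8, 4))
    for cell, v in zip(cells, values):
        if np.isfinite(v):
            acc[cell.grid_row - 1, cell.grid_col - 1] += v
            n[cell.grid_row - 1, cell.grid_col - 1] += 1
    with np.errstate(invalid="ignore"):
        out = acc / n
    out[n == 0] = np.nan
    return out
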