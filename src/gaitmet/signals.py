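"""Signal conditioning, stride segmentation and gait-cycle phase machinery.

All filtering is zero-phase (forward-backward Butterworth, 4th order before
doubling), the standard choice in gait processing because it does not shift
event timing.  Strides run from one ipsilateral heel strike to the next;
phases are first double support, single support, second double support and
swing, expressed as half-open fractions of the stride that partition [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class StrideEvents:
    """Gait event sample indices from both legs' vertical GRF."""

    ipsi_heel_strikes: np.ndarray
    ipsi_toe_offs: np.ndarray
    contra_heel_strikes: np.ndarray
    contra_toe_offs: np.ndarray

    def __post_init__(self):
        for name in ("ipsi_heel_strikes", "ipsi_toe_offs",
                     "contra_heel_strikes", "contra_toe_offs"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, arr)

    def n_strides(self):
        return len(self.ipsi_heel_strikes) - 1


@dataclass(frozen=True)
class PhaseBounds:
    """Phase intervals as half-open fractions of the stride; union is [0, 1)."""

    ds1: tuple
    ss: tuple
    ds2: tuple
    swing: tuple

    def __post_init__(self):
        seq = (self.ds1, self.ss, self.ds2, self.swing)
        if abs(seq[0][0]) > 1e-12 or abs(seq[-1][1] - 1.0) > 1e-9:
            raise ValueError("phases must span [0, 1)")
        for a, b in zip(seq, seq[1:]):
            if abs(a[1] - b[0]) > 1e-9:
                raise ValueError("phases must be contiguous and non-overlapping")
        for lo, hi in seq:
            if hi <= lo:
                raise ValueError("degenerate phase interval")

    def fractions(self):
        return {name: hi - lo for name, (lo, hi) in self.as_dict().items()}

    def as_dict(self):
        return {"ds1": self.ds1, "ss": self.ss, "ds2": self.ds2, "swing": self.swing}


#: Canonical phase bounds for symmetric gait with 65% stance.
CANONICAL_PHASES = PhaseBounds(ds1=(0.0, 0.15), ss=(0.15, 0.50),
                               ds2=(0.50, 0.65), swing=(0.65, 1.0))


def _butter_filtfilt(x, fs, cutoff, btype):
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cutoff} Hz cutoff")
    sos = sps.butter(4, cutoff / nyq, btype=btype, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def process_emg(raw, fs, highpass=20.0, lowpass=6.0):
    """EMG conditioning: 20 Hz high-pass, full-wave rectification, 6 Hz low-pass.

    Returns a nonnegative linear envelope.
    """
    if fs <= 2 * max(highpass, lowpass):
        raise ValueError(f"sampling rate {fs} Hz too low for the EMG filter cutoffs")
    hp = _butter_filtfilt(raw, fs, highpass, "highpass")
    env = _butter_filtfilt(np.abs(hp), fs, lowpass, "lowpass")
    return np.maximum(env, 0.0)


def normalize_emg(envelope, mvc):
    """Scale an envelope by its MVC value, mapping activation into [0, 1].

    If the trial maximum exceeds the MVC, the trial is re-normalized by its
    own maximum so the peak is exactly 1.
    """
    if mvc <= 0:
        raise ValueError("mvc must be positive")
    env = np.asarray(envelope, dtype=float)
    out = env / mvc
    peak = out.max(initial=0.0)
    if peak > 1.0:
        out = out / peak
    return out


def filter_grf(raw, fs, cutoff=6.0):
    """Zero-phase low-pass of a vertical ground reaction force series."""
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cutoff} Hz GRF cutoff")
    return _butter_filtfilt(raw, fs, cutoff, "lowpass")


def _contact_edges(grf, fs, threshold, min_duration):
    contact = np.asarray(grf, dtype=float) > threshold
    min_samples = max(int(round(min_duration * fs)), 1)
    # debounce: merge runs (of either state) shorter than the minimum duration
    edges = np.flatnonzero(np.diff(contact.astype(int)))
    runs = np.concatenate([[0], edges + 1, [contact.size]])
    state = contact.copy()
    for a, b in zip(runs[:-1], runs[1:]):
        if b - a < min_samples and a > 0:
            state[a:b] = state[a - 1]
    d = np.diff(state.astype(int))
    heel_strikes = np.flatnonzero(d == 1) + 1
    toe_offs = np.flatnonzero(d == -1) + 1
    return heel_strikes, toe_offs


def detect_strides(grf_ipsi, grf_contra, fs, threshold=20.0, min_duration=0.05):
    """Detect heel strikes and toe-offs from both legs' filtered vertical GRF.

    Heel strike is an upward crossing of ``threshold`` (N), toe-off a downward
    crossing; contacts or flight periods shorter than ``min_duration`` are
    treated as noise (debounce).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ihs, ito = _contact_edges(grf_ipsi, fs, threshold, min_duration)
    chs, cto = _contact_edges(grf_contra, fs, threshold, min_duration)
    if len(ihs) < 2:
        raise ValueError("fewer than 2 ipsilateral heel strikes detected")
    return StrideEvents(ipsi_heel_strikes=ihs, ipsi_toe_offs=ito,
                        contra_heel_strikes=chs, contra_toe_offs=cto)


def _first_in(arr, lo, hi):
    sel = arr[(arr >= lo) & (arr < hi)]
    return int(sel[0]) if sel.size else None


def partition_phases(events: StrideEvents, stride_index: int) -> PhaseBounds:
    """Phase bounds of one stride from its events.

    ds1 = [ipsi HS, contra TO); ss = [contra TO, contra HS);
    ds2 = [contra HS, ipsi TO); swing = [ipsi TO, next ipsi HS).
    """
    hs = events.ipsi_heel_strikes
    if stride_index < 0 or stride_index >= len(hs) - 1:
        raise IndexError("stride_index out of range")
    start, stop = int(hs[stride_index]), int(hs[stride_index + 1])
    cto = _first_in(events.contra_toe_offs, start, stop)
    chs = _first_in(events.contra_heel_strikes, start, stop)
    ito = _first_in(events.ipsi_toe_offs, start, stop)
    if cto is None or chs is None or ito is None:
        raise ValueError("missing contralateral or toe-off events within the stride")
    period = stop - start
    f = lambda s: (s - start) / period
    if not (start < cto < chs < ito < stop):
        raise ValueError("gait events out of order within the stride")
    return PhaseBounds(ds1=(0.0, f(cto)), ss=(f(cto), f(chs)),
                       ds2=(f(chs), f(ito)), swing=(f(ito), 1.0))


def time_normalize(series, start, stop, n_points=1001):
    """Resample one stride onto a uniform 0-100% grid by linear interpolation.

    ``start`` and ``stop`` are (possibly fractional) sample indices of the
    stride's heel strikes.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if stop <= start:
        raise ValueError("empty stride interval")
    grid = np.linspace(float(start), float(stop), int(n_points))
    x = np.arange(len(series), dtype=float)
    return np.interp(grid, x, np.asarray(series, dtype=float))


def stride_grid(n_points=1001):
    """Percent-of-stride axis matching :func:`time_normalize` output."""
    return np.linspace(0.0, 100.0, int(n_points))


def remove_outliers(values):
    """Drop values outside median +/- 3 x IQR; returns (retained, keep mask).

    IQR uses linear-interpolation quartiles.  A degenerate IQR of zero
    retains every value (a constant set is never discarded).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for the outlier rule")
    med = np.median(v)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if iqr == 0.0:
        keep = np.ones(v.size, dtype=bool)
    else:
        keep = (v >= med - 3.0 * iqr) & (v <= med + 3.0 * iqr)
    return v[keep], keep


#: Brockway-form energy equivalents (J per ml of O2 and CO2).
BROCKWAY_COEFFS = (16.58, 4.51)


def net_metabolic_rate(vo2, vco2, standing_rate, body_mass,
                       coeffs=BROCKWAY_COEFFS):
    """Net metabolic rate (W/kg) from gas exchange minus the standing rate.

    vo2, vco2 : ml/s; standing_rate : W/kg; body_mass : kg.
    """
    if vo2 < 0 or vco2 < 0:
        raise ValueError("gas exchange rates must be nonnegative")
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    gross = (coeffs[0] * vo2 + coeffs[1] * vco2) / body_mass
    return gross - standing_rate
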