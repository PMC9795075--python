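"""Per-trial f0 preprocessing and response-type classification.

Each 1.1-s analysis window comprises a 100-ms preshift baseline, the 200-ms
shift period and an 800-ms postshift period (110 samples at 10-ms sampling).
f0 is converted to cents relative to the preshift mean,
``cents = 1200 * log2(f0 / baseline)``, and a trial is labeled

* opposing  — the dominant post-onset excursion exceeds twice the preshift SD
  and its sign is opposite to the shift stimulus (a down-shift opposed by a
  pitch rise),
* following — threshold exceeded with the same sign as the stimulus,
* nonresponse — the threshold is never exceeded,
* error     — the track fails (too many missing frames or an implausible
  inter-frame jump).

For opposing/following trials the response onset is the earliest sample whose
supra-threshold excursion persists for 50 ms, and the peak is the first local
maximum of |cents| at or after the onset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import DIRECTION_CODES, OUTCOME_CODES, ResponseMatrix
from .simulate import F0Trace

log = logging.getLogger(__name__)

#: lower bound on the preshift SD so noiseless input keeps a usable threshold
SD_FLOOR = 1.0

PRESHIFT_SAMPLES = 10  # 100 ms
WINDOW_SAMPLES = 110  # 1.1 s
SHIFT_ONSET_INDEX = 10  # shift onset sits 100 ms into the window


def to_cents(f0, baseline):
    """Cents relative to a baseline frequency: 1200 * log2(f0 / baseline)."""
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0[~np.isnan(f0)] <= 0) or baseline <= 0:
        raise ValueError("frequencies must be positive")
    return 1200.0 * np.log2(f0 / baseline)


@dataclass
class TrialWindow:
    """1.1-s analysis window in cents (NaN = missing frame)."""

    cents: np.ndarray  # shape (110,)
    baseline_mean_f0: float
    preshift_sd: float
    shift_onset_index: int = SHIFT_ONSET_INDEX
    valid: bool = True  # False when the window could not be formed


@dataclass
class ResponseRecord:
    response_type: str
    onset_time: float = np.nan  # ms post shift onset
    peak_time: float = np.nan
    peak_amplitude: float = np.nan  # absolute cents


def extract_window(trace: F0Trace) -> TrialWindow:
    """Cut the 110-sample window starting 100 ms before shift onset and
    convert to cents against the preshift-mean baseline."""
    dt = trace.sample_period
    start = (trace.shift_onset - 100) // dt
    stop = start + WINDOW_SAMPLES
    if start < 0 or stop > trace.f0.size:
        return TrialWindow(np.full(WINDOW_SAMPLES, np.nan), np.nan, SD_FLOOR, valid=False)
    f0 = trace.f0[start:stop].astype(float)
    pre = f0[:PRESHIFT_SAMPLES]
    if np.all(np.isnan(pre)):
        return TrialWindow(np.full(WINDOW_SAMPLES, np.nan), np.nan, SD_FLOOR, valid=False)
    baseline = float(np.nanmean(pre))
    with np.errstate(invalid="ignore"):
        cents = 1200.0 * np.log2(f0 / baseline)
    pre_cents = cents[:PRESHIFT_SAMPLES]
    n_pre = np.sum(~np.isnan(pre_cents))
    sd = float(np.nanstd(pre_cents, ddof=1)) if n_pre > 1 else 0.0
    return TrialWindow(cents, baseline, max(sd, SD_FLOOR))


def _is_error(window: TrialWindow, missing_max: float, jump_cents: float) -> bool:
    if not window.valid:
        return True
    c = window.cents
    if np.mean(np.isnan(c)) > missing_max:
        return True
    present = np.where(~np.isnan(c))[0]
    adjacent = np.diff(present) == 1
    if adjacent.any():
        jumps = np.abs(np.diff(c[present]))[adjacent]
        if (jumps > jump_cents).any():
            return True
    return False


def classify_response(
    window: TrialWindow,
    shift_direction: str,
    *,
    missing_max: float = 0.2,
    jump_cents: float = 600.0,
    retention_ms: int = 50,
) -> ResponseRecord:
    """Map a window to exactly one response type; attach onset/peak measures
    for opposing/following trials."""
    if _is_error(window, missing_max, jump_cents):
        return ResponseRecord("error")
    c = window.cents[window.shift_onset_index:]
    threshold = 2.0 * window.preshift_sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        peak_abs = np.nanmax(np.abs(c))
    if not np.isfinite(peak_abs) or peak_abs <= threshold:
        return ResponseRecord("nonresponse")
    sign = np.sign(c[np.nanargmax(np.abs(c))])
    stimulus_sign = -1.0 if shift_direction == "down" else 1.0
    rtype = "opposing" if sign == -stimulus_sign else "following"
    onset = measure_onset(window, retention_ms=retention_ms)
    if np.isnan(onset):
        return ResponseRecord(rtype)
    peak_time, peak_amp = measure_peak(window, onset)
    return ResponseRecord(rtype, onset, peak_time, peak_amp)


def measure_onset(window: TrialWindow, *, retention_ms: int = 50) -> float:
    """Earliest time (ms post shift onset) at which |cents| exceeds twice the
    preshift SD and stays above it for ``retention_ms`` (5 consecutive samples
    at 10-ms sampling, including the onset sample). NaN if never."""
    dt = 10
    need = max(1, retention_ms // dt)
    a = np.abs(window.cents)
    thr = 2.0 * window.preshift_sd
    above = a > thr  # NaN compares False
    for t in range(window.shift_onset_index, WINDOW_SAMPLES - need + 1):
        if above[t:t + need].all():
            return float((t - window.shift_onset_index) * dt)
    return np.nan


def measure_peak(window: TrialWindow, onset_time: float) -> tuple[float, float]:
    """First local maximum of |cents| at or after the response onset.

    A plateau counts as one candidate and resolves to its earliest sample; a
    monotone excursion peaks at the window's last sample. Missing frames are
    skipped (comparison over present samples).
    """
    if np.isnan(onset_time):
        raise ValueError("onset_time must be present to measure a peak")
    start = window.shift_onset_index + int(onset_time) // 10
    a = np.abs(window.cents)
    idx = [t for t in range(start, WINDOW_SAMPLES) if not np.isnan(a[t])]
    v = a[idx]
    i, m = 0, len(v)
    while i < m:
        j = i
        while j + 1 < m and v[j + 1] == v[i]:
            j += 1  # plateau [i..j]
        rising_into = i == 0 or v[i] > v[i - 1]
        if j + 1 == m:  # ran off the window edge
            t = idx[i] if j > i else idx[j]
            return float((t - window.shift_onset_index) * 10), float(v[i])
        if v[j + 1] < v[i] and rising_into:
            return float((idx[i] - window.shift_onset_index) * 10), float(v[i])
        i = j + 1
    raise AssertionError("unreachable")  # pragma: no cover


def process_trace(trace: F0Trace, **kwargs) -> ResponseRecord:
    return classify_response(extract_window(trace), trace.shift_direction, **kwargs)


def process_dataset(traces: list[F0Trace]) -> tuple[ResponseMatrix | None, pd.DataFrame]:
    """Classify every trace; return the N x J response matrix (one row per
    participant x condition) and the long-format measures table."""
    rows = []
    for trace in traces:
        rec = process_trace(trace)
        rows.append({
            "participant_id": trace.participant_id,
            "condition": trace.condition,
            "trial": trace.trial_index,
            "shift_direction": trace.shift_direction,
            "response_type": rec.response_type,
            "onset_time": rec.onset_time,
            "peak_time": rec.peak_time,
            "peak_amplitude": rec.peak_amplitude,
        })
    measures = pd.DataFrame(rows, columns=[
        "participant_id", "condition", "trial", "shift_direction",
        "response_type", "onset_time", "peak_time", "peak_amplitude",
    ])
    if measures.empty:
        return None, measures

    wide = measures.pivot_table(
        index=["participant_id", "condition"], columns="trial",
        values="response_type", aggfunc="first", sort=True,
    )
    if wide.isna().any().any():
        log.warning("missing trials in the participant x condition grid; "
                    "coding them as 'error'")
        wide = wide.fillna("error")
    Y = wide.apply(lambda col: col.map(OUTCOME_CODES)).to_numpy(dtype=int)
    idx = wide.index.to_frame(index=False)
    matrix = ResponseMatrix(
        Y,
        covariate=[DIRECTION_CODES[c] for c in idx["condition"]],
        row_ids=[f"{p}:{c}" for p, c in zip(idx["participant_id"], idx["condition"])],
        conditions=idx["condition"].tolist(),
    )
    return matrix, measures
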