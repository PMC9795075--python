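"""Synthetic pitch-perturbation experiments with known latent structure.

The generator emulates the study design the downstream analysis assumes:
participants vocalize for 3 s while a single ±250-cent shift is applied to
their auditory feedback at a random time 500–700 ms after vocal onset for
200 ms, in three 30-trial condition blocks (down-only, up-only, random) with
counterbalanced block order. Each participant belongs to a latent class
(switcher / opposer / follower) whose class-conditional outcome probabilities
drive the per-trial response type; realized f0 traces carry a raised-cosine
response bump (opposing or following), pure baseline noise (nonresponse), or a
tracking-failure artifact (error).

Every sampling path is driven by ``numpy.random.SeedSequence`` spawning, so a
single master seed reproduces the full cohort byte-for-byte.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import DIRECTION_CODES, OUTCOME_CODES, ResponseMatrix

CONDITIONS = ("down_only", "up_only", "random")
OUTCOMES = ("opposing", "following", "nonresponse", "error")

#: counterbalanced block orders (a / b / c)
BLOCK_ORDERS = (
    ("down_only", "up_only", "random"),
    ("random", "down_only", "up_only"),
    ("up_only", "random", "down_only"),
)


# --------------------------------------------------------------------------- types
@dataclass(frozen=True)
class PerturbationSchedule:
    """Per-block experiment design: one pitch shift per trial."""

    condition: str
    n_trials: int
    shift_direction: tuple  # "down"/"up" per trial
    shift_onset: tuple  # ms post vocal onset, per trial
    shift_duration: int = 200
    shift_magnitude: float = 250.0
    sample_period: int = 10
    vocalization_length: int = 3000

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for t in self.shift_onset:
            if not (500 <= t <= 700):
                raise ValueError("shift onsets must lie in 500..700 ms")
            if t % self.sample_period:
                raise ValueError("shift onsets must align with the sample grid")
            if t + self.shift_duration + 800 > self.vocalization_length:
                raise ValueError("analysis window does not fit in the vocalization")


@dataclass(frozen=True)
class LatentProfile:
    """A latent class: its share and class-conditional outcome distribution.

    ``outcome_probs`` maps condition -> probabilities over
    (opposing, following, nonresponse, error). A single 4-vector is broadcast
    to all conditions. ``serial_dependence`` in [0, 1) adds first-order
    stickiness: with that probability a trial repeats the previous outcome,
    otherwise it is drawn fresh (stationary distribution = outcome_probs).
    """

    class_label: str
    class_share: float
    outcome_probs: dict
    serial_dependence: float = 0.0

    def __post_init__(self):
        probs = self.outcome_probs
        if not isinstance(probs, dict):
            probs = {c: probs for c in CONDITIONS}
            object.__setattr__(self, "outcome_probs", probs)
        for c, p in probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"outcome_probs[{c}] must be a length-4 simplex vector")
            probs[c] = p
        if not 0.0 <= self.serial_dependence < 1.0:
            raise ValueError("serial_dependence must lie in [0, 1)")


def default_profiles() -> list[LatentProfile]:
    """Switcher/opposer/follower profiles with the study's class shares."""
    return [
        LatentProfile("switcher", 0.57, (0.49, 0.49, 0.01, 0.01)),
        LatentProfile("opposer", 0.28, (0.85, 0.12, 0.02, 0.01)),
        LatentProfile("follower", 0.15, (0.12, 0.85, 0.02, 0.01)),
    ]


@dataclass(frozen=True)
class ResponseKinematics:
    """Shape parameters of the realized f0 response.

    Latencies are ms post shift-stimulus onset; amplitudes in cents. Defaults
    follow the measured response statistics of the modeled experiment: onset
    around 213 ms, peaks around 400–460 ms, peak amplitudes 30–90 cents.
    """

    onset_latency_mean: float = 213.0
    onset_latency_sd: float = 20.0
    peak_latency_mean: float = 430.0
    peak_latency_sd: float = 30.0
    peak_amplitude_mean: float = 40.0
    peak_amplitude_sd: float = 8.0
    min_amplitude: float = 30.0
    noise_sd: float = 3.0
    baseline_f0: float = 220.0
    error_missing_fraction: float = 0.3

    def __post_init__(self):
        if self.onset_latency_mean >= self.peak_latency_mean:
            raise ValueError("onset latency must precede peak latency")
        if self.min_amplitude <= 0 or self.peak_amplitude_mean <= 0:
            raise ValueError("peak amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.error_missing_fraction <= 1:
            raise ValueError("error_missing_fraction must lie in (0, 1]")


@dataclass
class F0Trace:
    """One vocalization's f0 time series (NaN = unvoiced/missing frame)."""

    participant_id: str
    condition: str
    trial_index: int
    shift_direction: str
    shift_onset: int  # ms
    f0: np.ndarray  # Hz, sampled every sample_period ms
    sample_period: int = 10


# --------------------------------------------------------------------- operations
def make_schedule(condition: str, n_trials: int = 30, seed: int = 0) -> PerturbationSchedule:
    """Draw a perturbation schedule: directions per condition, onsets uniform
    on the 10-ms grid within 500–700 ms. Deterministic given the seed."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    onsets = tuple(int(x) * 10 for x in rng.integers(50, 71, size=n_trials))
    if condition == "down_only":
        directions = ("down",) * n_trials
    elif condition == "up_only":
        directions = ("up",) * n_trials
    else:
        directions = tuple(np.where(rng.random(n_trials) < 0.5, "down", "up"))
    return PerturbationSchedule(condition, n_trials, directions, onsets)


def sample_response_sequence(
    profile: LatentProfile, schedule: PerturbationSchedule, seed: int = 0
) -> list[str]:
    """Draw the outcome-type sequence for one block from the class profile."""
    rng = np.random.default_rng(seed)
    probs = profile.outcome_probs[schedule.condition]
    s = profile.serial_dependence
    out: list[str] = []
    for j in range(schedule.n_trials):
        if j > 0 and s > 0 and rng.random() < s:
            out.append(out[-1])
        else:
            out.append(OUTCOMES[rng.choice(4, p=probs)])
    return out


def _bump_sign(outcome: str, direction: str) -> int:
    # opposing a down-shift raises pitch; following it lowers pitch
    up = 1 if direction == "down" else -1
    return up if outcome == "opposing" else -up


def threshold_crossing_ms(
    onset_latency: float, peak_latency: float, amplitude: float, threshold: float
) -> float:
    """Analytic first time (ms post shift onset) the raised-cosine bump
    exceeds ``threshold`` cents. Closed form, independent of any sampling."""
    rise = 2.0 * (peak_latency - onset_latency)  # full bump duration
    frac = math.acos(1.0 - 2.0 * threshold / amplitude) / (2.0 * math.pi)
    return onset_latency + rise * frac


def synthesize_trace(
    outcome: str,
    direction: str,
    shift_onset: int,
    kinematics: ResponseKinematics,
    seed: int = 0,
    *,
    participant_id: str = "p0",
    condition: str = "random",
    trial_index: int = 1,
    schedule: PerturbationSchedule | None = None,
) -> tuple[F0Trace, dict]:
    """Realize one trial as an f0 trace; returns (trace, ground-truth record).

    The ground-truth record carries the drawn kinematics: bump start, analytic
    2-cent threshold-crossing time, peak time and amplitude (all ms post shift
    onset / cents), or NaNs for nonresponse and error trials.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    k = kinematics
    dt = 10 if schedule is None else schedule.sample_period
    total = 3000 if schedule is None else schedule.vocalization_length
    n = total // dt
    rng = np.random.default_rng(seed)

    cents = rng.normal(0.0, k.noise_sd, size=n) if k.noise_sd > 0 else np.zeros(n)
    truth = {"bump_onset_ms": np.nan, "expected_onset_ms": np.nan,
             "peak_ms": np.nan, "amplitude": np.nan}

    if outcome in ("opposing", "following"):
        onset = round(rng.normal(k.onset_latency_mean, k.onset_latency_sd) / dt) * dt
        onset = int(np.clip(onset, 5 * dt, 400))
        peak = round(rng.normal(k.peak_latency_mean, k.peak_latency_sd) / dt) * dt
        # keep the full bump inside the 800-ms postshift analysis region
        peak = int(np.clip(peak, onset + 5 * dt, onset + (1000 - onset) // (2 * dt) * dt))
        amp = max(k.min_amplitude, rng.normal(k.peak_amplitude_mean, k.peak_amplitude_sd))
        sign = _bump_sign(outcome, direction)
        t_on = shift_onset + onset
        dur = 2 * (peak - onset)
        t = np.arange(n) * dt
        inside = (t >= t_on) & (t <= t_on + dur)
        phase = (t[inside] - t_on) / dur
        cents[inside] += sign * amp * 0.5 * (1.0 - np.cos(2.0 * math.pi * phase))
        truth.update(
            bump_onset_ms=float(onset),
            expected_onset_ms=threshold_crossing_ms(onset, peak, amp, 2.0),
            peak_ms=float(peak),
            amplitude=float(amp),
        )

    f0 = k.baseline_f0 * np.exp2(cents / 1200.0)

    if outcome == "error":
        # drop a contiguous run of frames inside the analysis window so the
        # missing-frame rule fires deterministically
        n_window = (100 + 1000) // dt
        n_drop = math.ceil(k.error_missing_fraction * n_window) + 1
        start = shift_onset // dt
        f0[start:start + n_drop] = np.nan

    trace = F0Trace(participant_id, condition, trial_index, direction, shift_onset, f0, dt)
    return trace, truth


def generate_dataset(
    n_participants: int = 36,
    profiles: list[LatentProfile] | None = None,
    kinematics: ResponseKinematics | None = None,
    seed: int = 0,
    *,
    n_trials: int = 30,
    condition_shares: dict | None = None,
    synthesize: bool = True,
) -> tuple[list[F0Trace], pd.DataFrame]:
    """Generate a full cohort: class assignments, counterbalanced condition
    blocks, per-trial outcomes, and (optionally) realized f0 traces.

    Returns ``(traces, truth)`` where ``truth`` is a long-format table with one
    row per trial: participant, condition, block position, latent class, trial,
    shift direction/onset, true outcome and bump kinematics. With
    ``synthesize=False`` the trace list is empty (fast categorical-only path).

    ``condition_shares`` optionally maps condition -> class-share vector so the
    class mixture may differ by condition (e.g. more followers under
    predictable down-shifts); by default each participant keeps one class for
    all three blocks.
    """
    profiles = default_profiles() if profiles is None else profiles
    kinematics = ResponseKinematics() if kinematics is None else kinematics
    shares = np.array([p.class_share for p in profiles], dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("class shares must sum to 1")
    if n_participants % 3:
        warnings.warn("n_participants not divisible by 3: counterbalancing is uneven")

    root = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    traces: list[F0Trace] = []
    rows = []
    for p in range(n_participants):
        pid = f"p{p:03d}"
        base_class = int(assign_rng.choice(len(profiles), p=shares))
        baseline = 120.0 if p % 2 else 220.0
        order = BLOCK_ORDERS[p % 3]
        for pos, condition in enumerate(order):
            block_seq = root.spawn(1)[0]
            sched_seed, seq_seed, *trial_seeds = [
                int(s.generate_state(1)[0] % (2**31)) for s in block_seq.spawn(2 + n_trials)
            ]
            if condition_shares is not None and condition in condition_shares:
                cshares = np.asarray(condition_shares[condition], dtype=float)
                cls = int(assign_rng.choice(len(profiles), p=cshares / cshares.sum()))
            else:
                cls = base_class
            profile = profiles[cls]
            schedule = make_schedule(condition, n_trials, sched_seed)
            outcomes = sample_response_sequence(profile, schedule, seq_seed)
            kin = replace(kinematics, baseline_f0=baseline)
            for j, outcome in enumerate(outcomes):
                truth = {"bump_onset_ms": np.nan, "expected_onset_ms": np.nan,
                         "peak_ms": np.nan, "amplitude": np.nan}
                if synthesize:
                    trace, truth = synthesize_trace(
                        outcome, schedule.shift_direction[j], schedule.shift_onset[j],
                        kin, trial_seeds[j], participant_id=pid, condition=condition,
                        trial_index=j + 1, schedule=schedule,
                    )
                    traces.append(trace)
                rows.append({
                    "participant_id": pid,
                    "condition": condition,
                    "block_position": pos + 1,
                    "latent_class": profile.class_label,
                    "trial": j + 1,
                    "shift_direction": schedule.shift_direction[j],
                    "shift_onset_ms": schedule.shift_onset[j],
                    "outcome": outcome,
                    **truth,
                })
    return traces, pd.DataFrame(rows)


def generate_class_sequences(
    n_obs: int,
    n_trials: int,
    profiles: list[LatentProfile] | None = None,
    seed: int = 0,
    *,
    beta=None,
    covariate_levels=(1.0, 2.0, 3.0),
    condition: str = "random",
) -> tuple[ResponseMatrix, np.ndarray]:
    """Draw categorical outcome sequences directly from the latent-class model.

    Without ``beta`` the class of each observation is drawn from the profile
    shares; with ``beta`` (array (R, 2): intercept and slope per class, row 0
    the reference) a covariate code is drawn uniformly from
    ``covariate_levels`` and class membership follows the multinomial logit.
    Returns ``(matrix, true_class_indices)``.
    """
    profiles = default_profiles() if profiles is None else profiles
    R = len(profiles)
    rng = np.random.default_rng(seed)
    if beta is None:
        shares = np.array([p.class_share for p in profiles], dtype=float)
        cls = rng.choice(R, size=n_obs, p=shares / shares.sum())
        x = None
    else:
        beta = np.asarray(beta, dtype=float)
        x = rng.choice(np.asarray(covariate_levels, dtype=float), size=n_obs)
        z = np.column_stack([np.ones(n_obs), x]) @ beta.T
        p = np.exp(z - z.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        cls = (rng.random(n_obs)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    outcome_probs = [np.asarray(p.outcome_probs[condition]) for p in profiles]
    Y = np.empty((n_obs, n_trials), dtype=int)
    for i in range(n_obs):
        Y[i] = rng.choice(4, size=n_trials, p=outcome_probs[cls[i]]) + 1
    return ResponseMatrix(Y, covariate=x), cls


def truth_to_matrix(truth: pd.DataFrame) -> ResponseMatrix:
    """Build the N = participants x conditions response matrix directly from a
    ground-truth table (bypassing trace synthesis and classification)."""
    wide = truth.pivot_table(
        index=["participant_id", "condition"], columns="trial", values="outcome",
        aggfunc="first", sort=True,
    )
    Y = wide.apply(lambda col: col.map(OUTCOME_CODES)).to_numpy(dtype=int)
    idx = wide.index.to_frame(index=False)
    return ResponseMatrix(
        Y,
        covariate=[DIRECTION_CODES[c] for c in idx["condition"]],
        row_ids=[f"{p}:{c}" for p, c in zip(idx["participant_id"], idx["condition"])],
        conditions=idx["condition"].tolist(),
    )


def traces_to_frame(traces: list[F0Trace]) -> pd.DataFrame:
    """Long-format trace table (participant_id, condition, trial, time_ms,
    f0_hz); missing frames become empty cells on CSV export."""
    frames = []
    for tr in traces:
        t = np.arange(tr.f0.size) * tr.sample_period
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "condition": tr.condition,
            "trial": tr.trial_index,
            "shift_direction": tr.shift_direction,
            "shift_onset_ms": tr.shift_onset,
            "time_ms": t,
            "f0_hz": tr.f0,
        }))
    return pd.concat(frames, ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[F0Trace]:
    traces = []
    keys = ["participant_id", "condition", "trial"]
    for (pid, cond, trial), g in df.groupby(keys, sort=False):
        g = g.sort_values("time_ms")
        dt = int(g["time_ms"].diff().dropna().iloc[0]) if len(g) > 1 else 10
        traces.append(F0Trace(
            str(pid), cond, int(trial), g["shift_direction"].iloc[0],
            int(g["shift_onset_ms"].iloc[0]), g["f0_hz"].to_numpy(float), dt,
        ))
    return traces
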