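"""Synthetic observers and session generators for the four experiments.

Each generator reproduces the printed trial architecture of its experiment
exactly (counts, per-level repeats, factor balance) and simulates behavior
from an observer whose ground-truth parameters are known, so every analysis
stage can be validated by parameter recovery:

* Experiment 1 — value-conditioned digit detection after a saccade: 500
  trials (400 eye-movement + 100 attention, randomly interleaved).  Saccade
  endpoints are drawn from the observer's endpoint distribution; detection
  behavior comes from an equal-variance SDT observer whose d' decays
  linearly with the gaze-to-target distance and whose criterion carries the
  value-conditioned shift.  Attention trials drive two QUEST staircases
  (50 trials per location) against Weibull observers with known contrast
  thresholds.
* Experiment 2 — two-interval speed discrimination with step-ramp pursuit:
  two blocks of 216 trials (standard 8 deg/s; comparison in
  {4,6,7,7.5,8,8.5,9,10,12} deg/s with 36/18 repeats), with raw 1000 Hz eye
  traces per interval.  A shared internal velocity estimate (sensory noise
  plus any perceptual bias) feeds both pursuit and the speed report; a
  response bias shifts the report decision only.  This is the generative
  counterpart of the dissociation logic: a perceptual bias must surface in
  both readouts, a response bias in reports alone.
* Experiment 3 — free viewing of ambiguous images with continuous percept
  report (34 trials, three phases).  The hidden percept alternates as a
  two-state semi-Markov process with exponential dwell times; gaze begins
  approaching the new percept's diagnostic point ``gaze_lead`` ms before
  the report flips.
* Experiment 4 — forced-fixation binary reports: a 40-trial illusion block
  and a composite block with 280 trials per fixation location, responses
  Bernoulli from a cumulative Gaussian in face-proportion with a
  fixation-conditioned PSE.

A single session seed expands into per-trial substreams
(``numpy.random.SeedSequence``) so trial-level reproducibility survives
reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pursuit import EyeTrace
from .quest import WeibullShape, quest_init, quest_next, quest_update, weibull_p_correct
from .sdt import score_trial

__all__ = [
    "ObserverExp1", "ObserverExp2", "ObserverExp3", "ObserverExp4",
    "SessionSpec", "sample_digit", "digit_distribution",
    "gen_exp1_session", "gen_exp2_session", "gen_exp3_session",
    "gen_exp4_session", "Exp1Session", "Exp2Session", "Exp3Session",
    "Exp4Session", "EXP2_VELOCITIES", "EXP2_DURATIONS", "EXP4_PROPORTIONS",
]

DIGITS = np.array([1, 2, 3, 4, 6, 7, 8, 9])
TARGET_Y = {"high": 3.0, "low": -3.0}        # deg from horizontal midline
TARGET_X = 6.0                               # post-saccadic disc eccentricity

EXP2_VELOCITIES = (4.0, 6.0, 7.0, 7.5, 8.0, 8.5, 9.0, 10.0, 12.0)
EXP2_STANDARD = 8.0
EXP2_DURATIONS = (540, 720, 900)             # ms
EXP2_DIFFICULT = (7.5, 8.0, 8.5)

EXP4_PROPORTIONS = (0.2, 0.33, 0.42, 0.48, 0.5, 0.52, 0.58, 0.66, 0.8)
EXP4_DIFFICULT = (0.42, 0.48, 0.5, 0.52, 0.58)
EXP4_EASY = (0.2, 0.33, 0.66, 0.8)


# ---------------------------------------------------------------------------
# observers

@dataclass(frozen=True)
class ObserverExp1:
    """Generative parameters for the digit-detection observer.

    ``endpoint_bias_mean`` is the mean vertical saccade endpoint in deg,
    positive toward the high-value target; d' at the probed disc is
    ``dprime_at_target - dprime_falloff * |endpoint_y - target_y|`` (floored
    at 0), coupling sensitivity to gaze linearly.  Criterion shifts are the
    value-conditioned response-bias offsets.  Attention thresholds are
    Michelson contrasts of the Weibull observer driving the staircases.
    """

    endpoint_bias_mean: float = 0.3
    endpoint_sd: float = 0.98
    dprime_at_target: float = 1.5
    dprime_falloff: float = 0.3
    criterion_shift_high: float = -0.24
    criterion_shift_low: float = -0.09
    attn_threshold_low: float = 0.15
    attn_threshold_high: float = 0.15
    lapse_rate: float = 0.02

    def __post_init__(self):
        if self.endpoint_sd <= 0:
            raise ValueError("endpoint_sd must be > 0")
        if self.dprime_at_target < 0:
            raise ValueError("dprime_at_target must be >= 0")
        for thr in (self.attn_threshold_low, self.attn_threshold_high):
            if not (0.01 < thr < 0.9):
                raise ValueError("attention thresholds must lie in (0.01, 0.9)")
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")


@dataclass(frozen=True)
class ObserverExp2:
    """Generative parameters for the pursuit/report observer.

    ``perceptual_bias`` (deg/s) shifts the shared internal velocity
    estimate of the rewarded-order interval in the biased block, feeding
    both pursuit and report; ``response_bias`` (deg/s equivalent) shifts
    the report decision only.  The closed-form PSEs of this observer give
    a bias index of 2*perceptual_bias (both readouts) or 2*response_bias
    (reports only).
    """

    pursuit_gain: float = 0.95
    pursuit_latency: float = 140.0       # ms
    motor_noise_sd: float = 4.0          # deg/s, white at the sampling rate
    sensory_noise_sd: float = 1.0        # deg/s, per interval
    response_bias: float = 0.0           # deg/s equivalent, report only
    perceptual_bias: float = 0.0         # deg/s, shared estimate
    catchup_rate: float = 2.0            # max catch-up saccades/s
    rise_tau: float = 60.0               # ms, pursuit onset time constant

    def __post_init__(self):
        if not (0.0 < self.pursuit_gain <= 1.2):
            raise ValueError("pursuit_gain must lie in (0, 1.2]")
        if not (80.0 <= self.pursuit_latency <= 300.0):
            raise ValueError("pursuit latency must lie in [80, 300] ms")
        if self.motor_noise_sd < 0 or self.sensory_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")


@dataclass(frozen=True)
class ObserverExp3:
    """Generative parameters for the ambiguous-viewing observer."""

    reversal_rate: float = 0.25          # reversals/s (exponential dwell)
    gaze_lead: float = 300.0             # ms gaze precedes the report flip
    fixation_jitter_sd: float = 0.7      # deg
    diagnostic_point_a: tuple[float, float] = (0.0, 1.5)    # face-diagnostic
    diagnostic_point_b: tuple[float, float] = (2.5, -2.0)   # house-diagnostic
    gaze_tau: float = 200.0              # ms, gaze relaxation constant

    def __post_init__(self):
        if self.reversal_rate < 0:
            raise ValueError("reversal_rate must be >= 0")
        if self.gaze_lead < 0:
            raise ValueError("gaze_lead must be >= 0")


@dataclass(frozen=True)
class ObserverExp4:
    """Generative parameters for the forced-fixation observer."""

    pse_fix_a: float = 0.43              # eye-region fixation
    pse_fix_b: float = 0.49              # house-feature fixation
    slope_sd: float = 0.12               # psychometric spread, proportion units
    lapse_rate: float = 0.02
    illusion_congruent_p: float = 0.65   # P(report congruent with fixation)

    def __post_init__(self):
        if not (0 < self.pse_fix_a < 1 and 0 < self.pse_fix_b < 1):
            raise ValueError("PSEs must lie in (0, 1)")
        if self.slope_sd <= 0:
            raise ValueError("slope_sd must be > 0")
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")


@dataclass(frozen=True)
class SessionSpec:
    """Which experiment, how many participants, and the session seed.

    Defaults reproduce the printed designs (Exp 1: 500 = 400 + 100 trials;
    Exp 2: 2 blocks x 216; Exp 3: 34 trials; Exp 4: 40 + 560).  Trial-count
    overrides scale sessions down for quick tests.
    """

    experiment_id: int
    n_participants: int = 1
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment_id not in (1, 2, 3, 4):
            raise ValueError("experiment_id must be 1..4")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for k, v in self.overrides.items():
            if k.startswith("n_") and (not float(v).is_integer() or v < 0):
                raise ValueError(f"trial-count override {k}={v} must be a "
                                 "non-negative integer")

    def get(self, key: str, default):
        return self.overrides.get(key, default)


# ---------------------------------------------------------------------------
# digit distribution (Experiment 1)

@lru_cache(maxsize=None)
def _digit_sd() -> float:
    """Spread of the discretized normal such that P(digit > 5) = 0.75."""
    def frac_above(sd: float) -> float:
        w = np.exp(-0.5 * ((DIGITS - 7.0) / sd) ** 2)
        return float(w[DIGITS > 5].sum() / w.sum())
    return float(optimize.brentq(lambda s: frac_above(s) - 0.75, 0.5, 60.0))


def digit_distribution(value_condition: str) -> tuple[np.ndarray, np.ndarray]:
    """(digits, probabilities) of the value-conditioned digit distribution.

    A normal centred at 7 (high value) or 3 (low value), discretized over
    {1..9}\\{5} and renormalized; the spread is solved numerically so that
    P(digit > 5) = 0.75 for the high-value condition (0.25 for low, by the
    symmetry of the digit set about 5).
    """
    if value_condition not in ("high", "low"):
        raise ValueError("value_condition must be 'high' or 'low'")
    center = 7.0 if value_condition == "high" else 3.0
    w = np.exp(-0.5 * ((DIGITS - center) / _digit_sd()) ** 2)
    return DIGITS.copy(), w / w.sum()


def sample_digit(value_condition: str, rng: np.random.Generator,
                 size: int | None = None):
    """Draw digits from the value-conditioned distribution."""
    digits, p = digit_distribution(value_condition)
    return rng.choice(digits, size=size, p=p)


# ---------------------------------------------------------------------------
# Experiment 1

@dataclass(frozen=True)
class Exp1Session:
    trials: pd.DataFrame        # all 500 rows, interleaved order preserved
    quest_states: dict          # location -> final QuestState
    observer: ObserverExp1
    seed: int

    @property
    def em_trials(self) -> pd.DataFrame:
        return self.trials[self.trials.trial_type == "em"]

    @property
    def attention_trials(self) -> pd.DataFrame:
        return self.trials[self.trials.trial_type == "attention"]


def gen_exp1_session(obs: ObserverExp1, spec: SessionSpec) -> Exp1Session:
    """Simulate one Experiment-1 session (400 EM + 100 attention trials)."""
    n_em = int(spec.get("n_em_trials", 400))
    n_attn_loc = int(spec.get("n_attention_per_location", 50))
    r_design, r_endpoint, r_digit, r_resp, r_attn = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(spec.seed).spawn(5))

    order = np.array(["em"] * n_em + ["attention"] * (2 * n_attn_loc))
    r_design.shuffle(order)
    attn_locs = np.array(["high"] * n_attn_loc + ["low"] * n_attn_loc)
    r_design.shuffle(attn_locs)
    probe = np.array(["high", "low"] * (n_em // 2) + ["high"] * (n_em % 2))
    r_design.shuffle(probe)

    quest = {loc: quest_init() for loc in ("high", "low")}
    true_thr = {"high": obs.attn_threshold_high, "low": obs.attn_threshold_low}
    shape = WeibullShape()

    rows = []
    i_em = i_attn = 0
    for i, ttype in enumerate(order):
        if ttype == "em":
            loc = probe[i_em]
            i_em += 1
            ey = r_endpoint.normal(obs.endpoint_bias_mean, obs.endpoint_sd)
            ex = r_endpoint.normal(TARGET_X, 0.8)
            present = {l: bool(r_digit.integers(2)) for l in ("high", "low")}
            value = {l: int(sample_digit(l, r_digit)) if present[l] else None
                     for l in ("high", "low")}
            dist = abs(ey - TARGET_Y[loc])
            dp = max(0.0, obs.dprime_at_target - obs.dprime_falloff * dist)
            c = obs.criterion_shift_high if loc == "high" else obs.criterion_shift_low
            if present[loc]:
                p_yes = stats.norm.cdf(dp / 2.0 - c)
            else:
                p_yes = stats.norm.cdf(-dp / 2.0 - c)
            resp = bool(r_resp.random() < p_yes)
            if r_resp.random() < obs.lapse_rate:
                resp = bool(r_resp.integers(2))
            score = score_trial(resp, present[loc], value[loc])
            rows.append(dict(
                trial=i, trial_type="em", probe_location=loc,
                digit_present=present[loc], digit_value=value[loc],
                digit_present_other=present["high" if loc == "low" else "low"],
                response_present=resp,
                correct=resp == present[loc], score=score,
                endpoint_x=ex, endpoint_y=ey,
                contrast=np.nan, attn_location=None))
        else:
            loc = attn_locs[i_attn]
            i_attn += 1
            intensity = quest_next(quest[loc])
            p_correct = float(weibull_p_correct(
                np.log10(intensity), np.log10(true_thr[loc]), shape))
            correct = bool(r_attn.random() < p_correct)
            quest[loc] = quest_update(quest[loc], intensity, correct)
            rows.append(dict(
                trial=i, trial_type="attention", probe_location=None,
                digit_present=None, digit_value=None,
                digit_present_other=None, response_present=None,
                correct=correct, score=5 if correct else -5,
                endpoint_x=np.nan, endpoint_y=np.nan,
                contrast=intensity, attn_location=loc))
    trials = pd.DataFrame(rows)
    return Exp1Session(trials=trials, quest_states=quest, observer=obs,
                       seed=spec.seed)


# ---------------------------------------------------------------------------
# Experiment 2

@dataclass(frozen=True)
class Exp2Session:
    design: pd.DataFrame        # one row per trial, both blocks
    traces: list                # (trace_first, trace_second) per trial
    observer: ObserverExp2
    reward_order: str           # "first" or "second"
    seed: int


def _exp2_block_design(rng: np.random.Generator, n_reps_scale: int = 1) -> pd.DataFrame:
    """Balanced 216-trial block: velocity x order x duration pair.

    Difficult comparisons (7.5, 8, 8.5 deg/s) appear 36 times, the rest 18,
    fully crossed with stimulus order and the two intervals' durations.
    """
    rows = []
    for v in EXP2_VELOCITIES:
        reps = (2 if v in EXP2_DIFFICULT else 1) * n_reps_scale
        for order in ("standard_first", "standard_second"):
            for d1 in EXP2_DURATIONS:
                for d2 in EXP2_DURATIONS:
                    rows.extend([dict(comparison=v, order=order,
                                      dur_first=d1, dur_second=d2)] * reps)
    df = pd.DataFrame(rows)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def _pursuit_trace(rng: np.random.Generator, obs: ObserverExp2,
                   target_velocity: float, perceived_velocity: float,
                   duration_ms: int, pre_ms: int = 200, post_ms: int = 100,
                   ) -> EyeTrace:
    """One 1000 Hz step-ramp interval: 1 deg leftward step, rightward ramp.

    Pursuit follows gain x perceived velocity after the latency with an
    exponential rise; catch-up saccades (16 ms raised-cosine velocity
    pulses) fire when the positional error exceeds 0.5 deg, subject to a
    refractory period of 1/catchup_rate.
    """
    dt = 1.0  # ms
    t = np.arange(-pre_ms, duration_ms + post_ms, dt)
    n = t.size
    drive = np.zeros(n)
    moving = (t >= obs.pursuit_latency) & (t < duration_ms + obs.pursuit_latency)
    rise = 1.0 - np.exp(-np.maximum(t - obs.pursuit_latency, 0.0) / obs.rise_tau)
    drive = np.where(moving, obs.pursuit_gain * perceived_velocity * rise, 0.0)
    v = drive + rng.normal(0.0, obs.motor_noise_sd, n)

    tgt = np.where((t >= 0) & (t < duration_ms),
                   -1.0 + target_velocity * t / 1000.0, np.nan)
    sacc_len = 16
    refractory = 1000.0 / obs.catchup_rate if obs.catchup_rate > 0 else np.inf
    pulse = (1.0 - np.cos(2 * np.pi * np.arange(sacc_len) / sacc_len))
    pulse /= pulse.sum() * (dt / 1000.0)          # unit-area velocity pulse
    last = -np.inf
    markers = {"target_onset": 0.0, "duration_ms": float(duration_ms)}
    k = 0
    for _ in range(6):
        pos = np.cumsum(v) * dt / 1000.0
        err = tgt - pos
        cand = np.flatnonzero((t > obs.pursuit_latency + 40) & (err > 0.5)
                              & (t > last + refractory)
                              & (t < duration_ms - sacc_len))
        if cand.size == 0:
            break
        i0 = cand[0]
        amp = float(err[i0]) + 0.8     # predictive overshoot keeps peaks realistic
        v[i0:i0 + sacc_len] += amp * pulse[:min(sacc_len, n - i0)]
        last = t[i0]
        markers[f"catchup_onset_{k}"] = float(t[i0])
        k += 1
    pos = np.cumsum(v) * dt / 1000.0
    x = pos
    y = rng.normal(0.0, 0.05) + np.zeros(n)
    return EyeTrace(t=t, x=x, y=y, markers=markers)


def gen_exp2_session(obs: ObserverExp2, spec: SessionSpec,
                     reward_order: str | None = None,
                     with_traces: bool = True) -> Exp2Session:
    """Simulate one two-block speed-discrimination session.

    The returned design table carries, per trial, the generative perceived
    velocities, the report, and the mean pursuit drive of each interval;
    ``traces`` holds the raw step-ramp eye traces (pairs, trial order) when
    ``with_traces`` is set.
    """
    subs = np.random.SeedSequence(spec.seed).spawn(4)
    r_design, r_sens, r_trace, r_misc = (np.random.default_rng(s) for s in subs)
    if reward_order is None:
        reward_order = "first" if r_misc.integers(2) else "second"
    if reward_order not in ("first", "second"):
        raise ValueError("reward_order must be 'first' or 'second'")
    scale = int(spec.get("n_reps_scale", 1))
    durations = spec.get("durations", EXP2_DURATIONS)
    if set(durations) - set(EXP2_DURATIONS):
        raise ValueError(f"durations outside the printed set: {durations}")

    frames = []
    traces = []
    for block in ("unbiased", "biased"):
        des = _exp2_block_design(r_design, scale)
        des.insert(0, "block", block)
        biased = block == "biased"
        std_first = (des.order == "standard_first").to_numpy()
        v_first = np.where(std_first, EXP2_STANDARD, des.comparison)
        v_second = np.where(std_first, des.comparison, EXP2_STANDARD)
        p_first = v_first + r_sens.normal(0, obs.sensory_noise_sd, len(des))
        p_second = v_second + r_sens.normal(0, obs.sensory_noise_sd, len(des))
        resp_term = 0.0
        if biased:
            sgn = 1.0 if reward_order == "first" else -1.0
            if obs.perceptual_bias != 0.0:
                if reward_order == "first":
                    p_first = p_first + obs.perceptual_bias
                else:
                    p_second = p_second + obs.perceptual_bias
            resp_term = sgn * obs.response_bias
        report_first = (p_first - p_second) + resp_term > 0
        des["v_first"] = v_first
        des["v_second"] = v_second
        des["perceived_first"] = p_first
        des["perceived_second"] = p_second
        des["report_first_faster"] = report_first
        des["report_comparison_faster"] = report_first != std_first
        if with_traces:
            for i in range(len(des)):
                tr1 = _pursuit_trace(r_trace, obs, v_first[i], p_first[i],
                                     int(des.dur_first.iloc[i]))
                tr2 = _pursuit_trace(r_trace, obs, v_second[i], p_second[i],
                                     int(des.dur_second.iloc[i]))
                traces.append((tr1, tr2))
        frames.append(des)
    design = pd.concat(frames, ignore_index=True)
    return Exp2Session(design=design, traces=traces, observer=obs,
                       reward_order=reward_order, seed=spec.seed)


# ---------------------------------------------------------------------------
# Experiment 3

@dataclass(frozen=True)
class Exp3Trial:
    trace: EyeTrace
    reversal_times: np.ndarray     # ms, report-flip times within phase 1
    reversal_to: np.ndarray        # "a"/"b" percept after each flip
    phase_bounds: tuple            # (phase1_end, phase2_end, phase3_end) ms
    instructed: tuple              # (phase2 percept, phase3 percept)
    hold_positions: dict           # percept -> mean (x, y) during the hold


@dataclass(frozen=True)
class Exp3Session:
    trials: list
    observer: ObserverExp3
    seed: int


def _relax_toward(targets_x, targets_y, tau_ms, jitter_sd, rng):
    """First-order relaxation of gaze toward a piecewise-constant target."""
    from scipy.signal import lfilter
    a = np.exp(-1.0 / tau_ms)
    b = [1 - a]
    aa = [1, -a]
    x = lfilter(b, aa, targets_x, zi=[a * targets_x[0]])[0]
    y = lfilter(b, aa, targets_y, zi=[a * targets_y[0]])[0]
    # AR(1) fixation jitter with stationary sd = jitter_sd
    rho = np.exp(-1.0 / 80.0)
    innov_sd = jitter_sd * np.sqrt(1 - rho ** 2)
    nx = lfilter([1.0], [1, -rho], rng.normal(0, innov_sd, x.size))
    ny = lfilter([1.0], [1, -rho], rng.normal(0, innov_sd, y.size))
    return x + nx, y + ny


def gen_exp3_session(obs: ObserverExp3, spec: SessionSpec) -> Exp3Session:
    """Simulate one ambiguous-viewing session (34 three-phase trials)."""
    n_trials = int(spec.get("n_trials", 34))
    phase1_ms = int(spec.get("phase1_ms", 8000))
    hold_ms = 2500
    settle_ms = int(spec.get("settle_ms", 1000))
    pts = {"a": obs.diagnostic_point_a, "b": obs.diagnostic_point_b}
    trials = []
    for tr_rng in (np.random.default_rng(s)
                   for s in np.random.SeedSequence(spec.seed).spawn(n_trials)):
        # hidden percept process: exponential dwells, alternating states
        percept0 = "a" if tr_rng.integers(2) else "b"
        percept = percept0
        flips, states = [], []
        tnow = 0.0
        while obs.reversal_rate > 0:
            tnow += tr_rng.exponential(1000.0 / obs.reversal_rate)
            if tnow >= phase1_ms:
                break
            percept_new = "b" if percept == "a" else "a"
            flips.append(tnow)
            states.append(percept_new)
            percept = percept_new
        phase2 = "a" if tr_rng.integers(2) else "b"
        phase3 = "b" if phase2 == "a" else "a"
        p2_len = settle_ms + hold_ms
        total = phase1_ms + 2 * p2_len
        t = np.arange(0.0, total, 1.0)

        # gaze target switches gaze_lead ms before each report flip
        tx = np.empty(t.size)
        ty = np.empty(t.size)
        bounds = [0.0] + [max(0.0, f - obs.gaze_lead) for f in flips] + [phase1_ms]
        bounds = np.maximum.accumulate(bounds).tolist()
        seq = [percept0] + states
        for k, st in enumerate(seq):
            sel = (t >= bounds[k]) & (t < bounds[k + 1])
            tx[sel], ty[sel] = pts[st]
        for phase, st in ((2, phase2), (3, phase3)):
            lo = phase1_ms + (phase - 2) * p2_len
            sel = (t >= lo) & (t < lo + p2_len)
            tx[sel], ty[sel] = pts[st]
        gx, gy = _relax_toward(tx, ty, obs.gaze_tau, obs.fixation_jitter_sd,
                               tr_rng)
        trace = EyeTrace(t=t, x=gx, y=gy,
                         markers={"phase1_end": float(phase1_ms),
                                  "phase2_end": float(phase1_ms + p2_len)})
        hold = {}
        for phase, st in ((2, phase2), (3, phase3)):
            lo = phase1_ms + (phase - 2) * p2_len + settle_ms
            sel = (t >= lo) & (t < lo + hold_ms)
            hold[st] = (float(gx[sel].mean()), float(gy[sel].mean()))
        trials.append(Exp3Trial(
            trace=trace, reversal_times=np.asarray(flips),
            reversal_to=np.asarray(states, dtype=object),
            phase_bounds=(phase1_ms, phase1_ms + p2_len, total),
            instructed=(phase2, phase3), hold_positions=hold))
    return Exp3Session(trials=trials, observer=obs, seed=spec.seed)


# ---------------------------------------------------------------------------
# Experiment 4

@dataclass(frozen=True)
class Exp4Session:
    illusion: pd.DataFrame      # 40 trials: stimulus, fixation, congruent
    composite: pd.DataFrame     # 560 trials: fixation, proportion, report_face
    observer: ObserverExp4
    seed: int


def gen_exp4_session(obs: ObserverExp4, spec: SessionSpec) -> Exp4Session:
    """Simulate one forced-fixation session (40 illusion + 560 composite trials)."""
    r_ill, r_comp = (np.random.default_rng(s)
                     for s in np.random.SeedSequence(spec.seed).spawn(2))
    reps_ill = int(spec.get("n_illusion_reps", 10))        # per stimulus
    rows = []
    for stim in range(1, 5):
        for fix in ("a", "b") * (reps_ill // 2):
            congruent = bool(r_ill.random() < obs.illusion_congruent_p)
            rows.append(dict(stimulus=stim, fixation=fix, congruent=congruent))
    illusion = pd.DataFrame(rows)
    illusion = illusion.iloc[r_ill.permutation(len(illusion))].reset_index(drop=True)

    scale = int(spec.get("n_comp_reps_scale", 1))
    rows = []
    pse = {"a": obs.pse_fix_a, "b": obs.pse_fix_b}
    for fix in ("a", "b"):
        props = (list(EXP4_DIFFICULT) * 40 + list(EXP4_EASY) * 20) * scale
        for x in props:
            p_face = (obs.lapse_rate / 2.0 + (1.0 - obs.lapse_rate)
                      * stats.norm.cdf((x - pse[fix]) / obs.slope_sd))
            rows.append(dict(fixation=fix, proportion=x,
                             report_face=bool(r_comp.random() < p_face)))
    composite = pd.DataFrame(rows)
    composite = composite.iloc[r_comp.permutation(len(composite))].reset_index(drop=True)
    return Exp4Session(illusion=illusion, composite=composite, observer=obs,
                       seed=spec.seed)


# ---------------------------------------------------------------------------
# cohorts

#: between-participant spreads used by :func:`sample_cohort` unless overridden.
#: Magnitudes follow the across-participant SDs the study reports where it
#: reports them (endpoints, criteria, Exp-4 PSEs); the rest are field-typical.
DEFAULT_BETWEEN = {
    ObserverExp1: {"endpoint_bias_mean": 0.98, "criterion_shift_high": 0.40,
                   "criterion_shift_low": 0.42, "dprime_at_target": 0.3,
                   "attn_threshold_low": 0.03, "attn_threshold_high": 0.03},
    ObserverExp2: {"pursuit_gain": 0.06, "pursuit_latency": 20.0,
                   "sensory_noise_sd": 0.15, "response_bias": 0.0,
                   "perceptual_bias": 0.0},
    ObserverExp3: {"reversal_rate": 0.08, "gaze_lead": 50.0,
                   "fixation_jitter_sd": 0.15},
    ObserverExp4: {"pse_fix_a": 0.075, "pse_fix_b": 0.068,
                   "slope_sd": 0.03, "illusion_congruent_p": 0.1},
}

_FIELD_BOUNDS = {
    "endpoint_sd": (0.05, None), "dprime_at_target": (0.0, None),
    "attn_threshold_low": (0.011, 0.89), "attn_threshold_high": (0.011, 0.89),
    "lapse_rate": (0.0, 0.1), "pursuit_gain": (0.4, 1.2),
    "pursuit_latency": (80.0, 300.0), "motor_noise_sd": (0.0, None),
    "sensory_noise_sd": (0.3, None), "reversal_rate": (0.02, None),
    "gaze_lead": (0.0, None), "fixation_jitter_sd": (0.1, None),
    "pse_fix_a": (0.05, 0.95), "pse_fix_b": (0.05, 0.95),
    "slope_sd": (0.03, None), "illusion_congruent_p": (0.02, 0.98),
}


def sample_cohort(base, n: int, seed: int, between: dict | None = None) -> list:
    """Draw ``n`` observers around ``base`` with between-participant spread.

    Each field named in ``between`` (default: :data:`DEFAULT_BETWEEN` for the
    observer's class) is drawn from a normal centred on the base value and
    clipped to its admissible range.
    """
    import dataclasses

    if between is None:
        between = DEFAULT_BETWEEN[type(base)]
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        kw = {}
        for name, sd in between.items():
            val = rng.normal(getattr(base, name), sd)
            lo, hi = _FIELD_BOUNDS.get(name, (None, None))
            if lo is not None:
                val = max(val, lo)
            if hi is not None:
                val = min(val, hi)
            kw[name] = float(val)
        cohort.append(dataclasses.replace(base, **kw))
    return cohort
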