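"""Synthetic dyad-motion, behavioural and fNIRS data with known ground truth.

The generators emulate the three data streams of a synchrony/audience
study: (1) video-derived upper-body keypoints for a participant-confederate
dyad playing a mirror game (synchronized regime) or taking turns moving
(control regime); (2) trial-level Go/NoGo logs for two groups over a
40-block schedule; (3) raw two-wavelength continuous-wave fNIRS with
block-evoked responses per ROI, shared systemic physiology (slow drift and
a Mayer-wave oscillation), and lag-1 autocorrelated noise.

Every generator is deterministic under a fixed seed, and each one is the
exact generative inverse of the corresponding analysis stage, so that
noise-free output is recovered to machine precision and noisy output
supports parameter-recovery testing.  Packaged default effect sizes are
calibrated so the analysis stages reproduce the reference estimates the
package documents (mean dyad similarity 0.80 synchronized / 0.43 control;
block-type RT effect 146.8 ms; group RT effect 18.1 ms; commission-error
group difference 2.93 per 80 NoGo trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fnirs import Montage, RawIntensity, haemoglobin_to_intensity, \
    HaemoSeries, task_regressor, ROIS
from .pose import KeypointSeries, N_JOINTS

__all__ = [
    "Schedule",
    "generate_task_schedule",
    "MotionParams",
    "generate_dyad_motion",
    "BehaviourParams",
    "generate_behaviour",
    "speed_accuracy_params",
    "FnirsParams",
    "generate_fnirs",
    "simulate_fnirs_cohort",
]


# --------------------------------------------------------------------------
# Go/NoGo task schedule
# --------------------------------------------------------------------------

N_BLOCKS = 40
TRIALS_PER_BLOCK = 12
NOGO_PER_MIXED = 4          # 33% of 12
CUE_S = 2.0                 # block-type announcement
RESPONSE_WINDOW_S = 1.0     # <=500 ms stimulus + <=500 ms blank
ITI_RANGE_S = (0.5, 1.5)
ISI_RANGE_S = (16.0, 22.0)


@dataclass
class Schedule:
    """Ordered Go/NoGo blocks and trials with onset times (seconds)."""

    trials: pd.DataFrame   # block_index, block_type, trial, trial_type, onset_s
    blocks: pd.DataFrame   # block_index, block_type, onset_s, duration_s

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_nogo(self) -> int:
        return int((self.trials["trial_type"] == "NoGo").sum())

    def events(self, boxcar_s: float = 16.0) -> pd.DataFrame:
        """Block events for the fNIRS design (onset, duration, condition)."""
        return pd.DataFrame({
            "onset_s": self.blocks["onset_s"],
            "duration_s": boxcar_s,
            "condition": self.blocks["block_type"],
        })


def generate_task_schedule(seed: int, n_blocks: int = N_BLOCKS) -> Schedule:
    """Randomized Go/NoGo schedule: half AllGo blocks, half Mixed.

    Each block holds 12 trials; Mixed blocks contain 4 NoGo and 8 Go
    trials in random positions.  Timing: 2-s block cue, 1-s response
    window per trial, ITI jittered uniform 0.5-1.5 s, inter-block ISI
    jittered uniform 16-22 s.  Block order and jitter are seeded.
    """
    if n_blocks % 2:
        raise ValueError("n_blocks must be even (half AllGo, half Mixed)")
    rng = np.random.default_rng(seed)
    kinds = ["AllGo"] * (n_blocks // 2) + ["Mixed"] * (n_blocks // 2)
    rng.shuffle(kinds)
    t = 0.0
    trial_rows = []
    block_rows = []
    for b, kind in enumerate(kinds, start=1):
        t += CUE_S
        block_start = t
        types = ["Go"] * TRIALS_PER_BLOCK
        if kind == "Mixed":
            nogo_pos = rng.choice(TRIALS_PER_BLOCK, NOGO_PER_MIXED,
                                  replace=False)
            for p in nogo_pos:
                types[p] = "NoGo"
        for k, tt in enumerate(types, start=1):
            t += rng.uniform(*ITI_RANGE_S)
            trial_rows.append(dict(block_index=b, block_type=kind, trial=k,
                                   trial_type=tt, onset_s=round(t, 4)))
            t += RESPONSE_WINDOW_S
        block_rows.append(dict(block_index=b, block_type=kind,
                               onset_s=round(block_start, 4),
                               duration_s=round(t - block_start, 4)))
        t += rng.uniform(*ISI_RANGE_S)
    return Schedule(pd.DataFrame(trial_rows), pd.DataFrame(block_rows))


# --------------------------------------------------------------------------
# Dyad motion
# --------------------------------------------------------------------------

@dataclass
class MotionParams:
    """Parameters of the dyadic upper-body motion generator.

    The synchronized regime produces a confederate trajectory that is a
    horizontally mirrored, lagged, noise-perturbed copy of the
    participant's arm movements; the control regime alternates a single
    mover (the other member sits near-still).  Defaults are the packaged
    calibration: 5 minutes at 30 fps (~9000 frames), mirroring lag and
    kinematic noise tuned once against the Laplacian scorer.
    """

    regime: str = "synchronized"
    duration_s: float = 300.0
    fps: float = 30.0
    mirror_lag_s: float = 0.08
    kinematic_noise_sd: float = 3.5
    dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("synchronized", "control"):
            raise ValueError("regime must be 'synchronized' or 'control'")
        vals = (self.duration_s, self.fps, self.mirror_lag_s,
                self.kinematic_noise_sd, self.dropout_rate)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("motion parameters must be finite")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.mirror_lag_s < 0 or self.kinematic_noise_sd < 0:
            raise ValueError("lag and noise sd must be non-negative")


# skeleton geometry (image pixels, y increasing downward)
_CENTRES_X = {"participant": 320.0, "confederate": 960.0}
_NECK_Y = 180.0
_SHOULDER_DX = 55.0
_SHOULDER_DY = 12.0
_ARM_REACH = 150.0
# movement-amplitude constants (radians / relative units); tuned once
# against the Laplacian scorer together with the MotionParams defaults
_MOVE_ANGLE_AMPLITUDE = 0.9
_IDLE_ANGLE_SD = 0.25
_IDLE_ANGLE_BASE = 0.0     # hands resting straight down with gentle sway


def _sinmix(rng, n, fps, fmin, fmax, k=3):
    """Smooth band-limited random series with unit-ish sd."""
    t = np.arange(n) / fps
    out = np.zeros(n)
    for _ in range(k):
        f = rng.uniform(fmin, fmax)
        ph = rng.uniform(0, 2 * np.pi)
        out += np.sin(2 * np.pi * f * t + ph)
    return out / np.sqrt(k / 2.0)


def _arm_tracks(rng, n, fps, moving):
    """Per-arm joint offsets relative to the shoulder.

    Returns (elbow_off, wrist_off), each (n, 2) with x measured outward
    (away from the body midline) so the same track describes either arm
    or its mirror image.  Angles are measured from straight-down.
    """
    if moving:
        theta = _MOVE_ANGLE_AMPLITUDE * _sinmix(rng, n, fps, 0.05, 0.45)
        reach = _ARM_REACH * (0.80 + 0.18 * np.tanh(_sinmix(rng, n, fps, 0.05, 0.3)))
    else:
        theta = _IDLE_ANGLE_BASE + _IDLE_ANGLE_SD * _sinmix(rng, n, fps, 0.05, 0.3)
        reach = (_ARM_REACH - 15.0) + 4.0 * _sinmix(rng, n, fps, 0.05, 0.2)
    wrist = np.column_stack([reach * np.sin(theta), reach * np.cos(theta)])
    bend = 30.0 * (0.6 + 0.25 * np.tanh(_sinmix(rng, n, fps, 0.1, 0.4)))
    # elbow: midway along the shoulder-wrist chord, flared outward
    norm = np.maximum(np.linalg.norm(wrist, axis=1), 1e-9)
    perp = np.column_stack([wrist[:, 1], -wrist[:, 0]]) / norm[:, None]
    elbow = 0.55 * wrist + bend[:, None] * perp
    return elbow, wrist


def _assemble(cx, sway, arms):
    """Build (n, 7, 2) joint stack from per-arm offset tracks.

    ``arms`` maps side ('r'/'l') to (elbow_off, wrist_off) in outward-x
    convention.  In image coordinates the person's right arm extends
    toward smaller x when they face the camera.
    """
    n = arms["r"][0].shape[0]
    xy = np.zeros((n, N_JOINTS, 2))
    neck = np.column_stack([np.full(n, cx), np.full(n, _NECK_Y)]) + sway
    xy[:, 0] = neck
    out_sign = {"r": -1.0, "l": +1.0}
    slot = {"r": (1, 2, 3), "l": (4, 5, 6)}
    for side in ("r", "l"):
        s = out_sign[side]
        sh = neck + np.array([s * _SHOULDER_DX, _SHOULDER_DY])
        elbow_off, wrist_off = arms[side]
        xy[:, slot[side][0]] = sh
        xy[:, slot[side][1]] = sh + np.column_stack(
            [s * elbow_off[:, 0], elbow_off[:, 1]])
        xy[:, slot[side][2]] = sh + np.column_stack(
            [s * wrist_off[:, 0], wrist_off[:, 1]])
    return xy


def _lagged(track, lag_frames):
    """Shift a track back in time, holding the first value at the start."""
    if lag_frames <= 0:
        return track
    out = np.empty_like(track)
    out[lag_frames:] = track[:-lag_frames or None][: len(track) - lag_frames]
    out[:lag_frames] = track[0]
    return out


def generate_dyad_motion(params: MotionParams):
    """Generate (participant, confederate) :class:`KeypointSeries`.

    Synchronized regime: the participant performs smooth random arm
    trajectories; the confederate mirrors them (left-right reflection
    about the inter-person axis) with lag ``mirror_lag_s`` and smooth
    kinematic noise of sd ``kinematic_noise_sd`` pixels.  Control regime:
    one member moves while the other sits near-still, swapping halfway
    (the confederate moves first).  Keypoints are dropped (confidence 0)
    at ``dropout_rate``.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fps))
    if n < 1:
        raise ValueError("duration too short for one frame")
    sway_p = 2.0 * np.column_stack([_sinmix(rng, n, params.fps, 0.05, 0.2),
                                    _sinmix(rng, n, params.fps, 0.05, 0.2)])
    sway_c = 2.0 * np.column_stack([_sinmix(rng, n, params.fps, 0.05, 0.2),
                                    _sinmix(rng, n, params.fps, 0.05, 0.2)])

    def noise_tracks():
        sd = params.kinematic_noise_sd
        return [sd * np.column_stack([_sinmix(rng, n, params.fps, 0.2, 1.0),
                                      _sinmix(rng, n, params.fps, 0.2, 1.0)])
                for _ in range(2)]

    if params.regime == "synchronized":
        arms_p = {"r": _arm_tracks(rng, n, params.fps, True),
                  "l": _arm_tracks(rng, n, params.fps, True)}
        lag = int(round(params.mirror_lag_s * params.fps))
        arms_c = {}
        # mirroring about the inter-person axis maps the participant's
        # outward-x offsets onto the confederate's outward-x offsets on the
        # opposite anatomical side; with offsets expressed in outward
        # coordinates (and detector labels following appearance), a perfect
        # mirror therefore reproduces the same labelled offset tracks
        for side in ("r", "l"):
            el, wr = arms_p[side]
            nel, nwr = noise_tracks()
            arms_c[side] = (_lagged(el, lag) + nel, _lagged(wr, lag) + nwr)
    else:
        half = n // 2
        def alternating(first_moves: bool):
            tracks = {}
            for side in ("r", "l"):
                el1, wr1 = _arm_tracks(rng, half, params.fps, first_moves)
                el2, wr2 = _arm_tracks(rng, n - half, params.fps,
                                       not first_moves)
                tracks[side] = (np.vstack([el1, el2]), np.vstack([wr1, wr2]))
            return tracks
        arms_c = alternating(True)    # confederate takes the first turn
        arms_p = alternating(False)

    xy_p = _assemble(_CENTRES_X["participant"], sway_p, arms_p)
    xy_c = _assemble(_CENTRES_X["confederate"], sway_c, arms_c)

    def finish(xy, pid):
        conf = rng.uniform(0.5, 0.95, size=(n, N_JOINTS))
        if params.dropout_rate > 0:
            drop = rng.random((n, N_JOINTS)) < params.dropout_rate
            conf[drop] = 0.0
            xy = xy.copy()
            xy[drop] = 0.0
        return KeypointSeries(pid, xy, conf)

    return finish(xy_p, "participant"), finish(xy_c, "confederate")


# --------------------------------------------------------------------------
# Go/NoGo behaviour
# --------------------------------------------------------------------------

#: Calibrated cell means E[RT] in ms.  Control/AllGo anchors the
#: descriptive reference (230 ms); the block-type and group effects are
#: 146.8 ms and 18.1 ms with no interaction.
DEFAULT_RT_CELL_MEANS_MS = {
    ("Control", "AllGo"): 230.0,
    ("Control", "Mixed"): 376.8,
    ("Synchronized", "AllGo"): 248.1,
    ("Synchronized", "Mixed"): 394.9,
}
#: Mean commission-error totals per 80 NoGo trials (the full task).
DEFAULT_CE_MEAN_PER_80 = {"Control": 19.70, "Synchronized": 16.70}
#: Packaged generating slope (log commission-error count per ms of mean
#: reaction time) for the exploratory speed-accuracy scenario.
DEFAULT_RT_CE_SLOPE = -0.005


def speed_accuracy_params(seed: int, n_per_group: int = 30,
                          slope: float = DEFAULT_RT_CE_SLOPE
                          ) -> "BehaviourParams":
    """Parameters for the speed-accuracy (RT-CE slope) recovery scenario.

    Group means are neutralized (averaged across groups) so that the
    participant-level coupling ``slope`` is the only link between
    reaction times and commission errors; with the two-group defaults the
    between-group speed-accuracy difference would add to the slope.
    """
    cells = DEFAULT_RT_CELL_MEANS_MS
    neutral_rt = {
        (g, bt): 0.5 * (cells[("Control", bt)] + cells[("Synchronized", bt)])
        for g in ("Control", "Synchronized") for bt in ("AllGo", "Mixed")}
    neutral_ce = {g: 0.5 * (DEFAULT_CE_MEAN_PER_80["Control"]
                            + DEFAULT_CE_MEAN_PER_80["Synchronized"])
                  for g in ("Control", "Synchronized")}
    return BehaviourParams(n_per_group=n_per_group,
                           rt_cell_means_ms=neutral_rt,
                           ce_mean_per_80=neutral_ce,
                           rt_ce_slope=slope, seed=seed)


@dataclass
class BehaviourParams:
    """Generative parameters for the Go/NoGo trial tables.

    Reaction times are lognormal with participant random intercepts and
    block-type random slopes on the log scale; commission errors are
    Poisson counts per participant with lognormal rate heterogeneity
    (or per-trial Bernoulli when ``ce_mode='bernoulli'``).
    """

    n_per_group: int = 30
    rt_cell_means_ms: dict = field(
        default_factory=lambda: dict(DEFAULT_RT_CELL_MEANS_MS))
    ce_mean_per_80: dict = field(
        default_factory=lambda: dict(DEFAULT_CE_MEAN_PER_80))
    rt_sigma_log: float = 0.20      # within-participant sd, log scale
    rt_re_sd_log: tuple = (0.05, 0.03)  # intercept / block-type slope sds
    rt_re_corr: float = 0.0
    ce_sd_log: float = 0.10         # participant rate heterogeneity
    p_go_response: float = 0.98
    ce_mode: str = "poisson"
    #: optional speed-accuracy coupling: log CE rate changes by this per
    #: ms of the participant's expected mean RT (None = no coupling)
    rt_ce_slope: float | None = None
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.rt_cell_means_ms.values()):
            raise ValueError("RT cell means must be positive")
        if any(v <= 0 for v in self.ce_mean_per_80.values()):
            raise ValueError("commission-error means must be positive")
        if (self.rt_sigma_log < 0 or any(s < 0 for s in self.rt_re_sd_log)
                or self.ce_sd_log < 0):
            raise ValueError("variance components must be non-negative")
        if not -1 < self.rt_re_corr < 1:
            raise ValueError("random-effect correlation must be in (-1, 1)")
        if self.ce_mode not in ("poisson", "bernoulli"):
            raise ValueError("ce_mode must be 'poisson' or 'bernoulli'")


def _rt_eta(params: BehaviourParams):
    """Log-scale cell locations chosen so that E[RT] hits the cell means."""
    s0, s1 = params.rt_re_sd_log
    rho = params.rt_re_corr
    var_u = {"AllGo": s0 ** 2,
             "Mixed": s0 ** 2 + 2 * rho * s0 * s1 + s1 ** 2}
    eta = {}
    for (group, bt), mean in params.rt_cell_means_ms.items():
        eta[(group, bt)] = np.log(mean) - 0.5 * (
            params.rt_sigma_log ** 2 + var_u[bt])
    return eta


def generate_behaviour(params: BehaviourParams,
                       schedule: Schedule) -> pd.DataFrame:
    """Trial table for both groups over one schedule.

    Columns: participant_id, group, block_index, block_type, trial,
    trial_type, responded, rt_ms (NaN when no response).  Go-trial RTs
    follow the hierarchical lognormal model; commission errors follow the
    Poisson (or Bernoulli) process; group and block-type means match the
    parameters in expectation.
    """
    rng = np.random.default_rng(params.seed)
    eta = _rt_eta(params)
    s0, s1 = params.rt_re_sd_log
    rho = params.rt_re_corr
    cov_u = np.array([[s0 ** 2, rho * s0 * s1],
                      [rho * s0 * s1, s1 ** 2]])
    trials = schedule.trials
    n_nogo = schedule.n_nogo
    go = trials[trials["trial_type"] == "Go"]
    w_mixed = float((go["block_type"] == "Mixed").mean())
    rows = []
    for group, tag in (("Control", "C"), ("Synchronized", "S")):
        for k in range(params.n_per_group):
            pid = f"{tag}{k + 1:02d}"
            u0, u1 = rng.multivariate_normal([0.0, 0.0], cov_u)
            ce_rate = (params.ce_mean_per_80[group] / 80.0) * np.exp(
                params.ce_sd_log * rng.standard_normal()
                - params.ce_sd_log ** 2 / 2.0)
            if params.rt_ce_slope is not None:
                # expected mean Go RT for this participant vs the group mean
                s2 = params.rt_sigma_log ** 2
                rt_i = sum(
                    w * np.exp(eta[(group, bt)] + u0
                               + u1 * (bt == "Mixed") + 0.5 * s2)
                    for bt, w in (("AllGo", 1 - w_mixed), ("Mixed", w_mixed)))
                rt_g = sum(
                    w * params.rt_cell_means_ms[(group, bt)]
                    for bt, w in (("AllGo", 1 - w_mixed), ("Mixed", w_mixed)))
                ce_rate *= np.exp(params.rt_ce_slope * (rt_i - rt_g))
            if params.ce_mode == "poisson":
                count = min(int(rng.poisson(ce_rate * n_nogo)), n_nogo)
                nogo_resp = np.zeros(n_nogo, dtype=bool)
                nogo_resp[rng.choice(n_nogo, count, replace=False)] = True
            else:
                nogo_resp = rng.random(n_nogo) < min(ce_rate, 1.0)
            ni = 0
            for t in trials.itertuples(index=False):
                bt = t.block_type
                is_mixed = 1.0 if bt == "Mixed" else 0.0
                if t.trial_type == "Go":
                    responded = rng.random() < params.p_go_response
                else:
                    responded = bool(nogo_resp[ni])
                    ni += 1
                rt = np.nan
                if responded:
                    mu = eta[(group, bt)] + u0 + u1 * is_mixed
                    rt = float(np.exp(mu + params.rt_sigma_log
                                      * rng.standard_normal()))
                    while rt > 1000.0:  # response window truncation
                        rt = float(np.exp(mu + params.rt_sigma_log
                                          * rng.standard_normal()))
                rows.append(dict(participant_id=pid, group=group,
                                 block_index=t.block_index, block_type=bt,
                                 trial=t.trial, trial_type=t.trial_type,
                                 responded=responded, rt_ms=rt))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fNIRS forward model
# --------------------------------------------------------------------------

#: Default peak evoked HbO amplitudes (uM) per (ROI, block type); the IFG
#: regions respond more strongly in Mixed (inhibition) blocks.
DEFAULT_HBO_AMPLITUDE = {
    ("LIFG", "AllGo"): 0.6, ("LIFG", "Mixed"): 2.0,
    ("LPFC", "AllGo"): 1.0, ("LPFC", "Mixed"): 0.6,
    ("MPFC", "AllGo"): 1.1, ("MPFC", "Mixed"): 0.7,
    ("RPFC", "AllGo"): 0.8, ("RPFC", "Mixed"): 0.8,
    ("RIFG", "AllGo"): 0.5, ("RIFG", "Mixed"): 1.6,
}


@dataclass
class FnirsParams:
    """Forward-model parameters for raw two-wavelength fNIRS.

    ``hbo_amplitude`` maps (ROI, block type) to the peak evoked HbO
    change in uM; HbR defaults to ``hbr_ratio`` times HbO (canonical
    polarity) unless ``hbr_amplitude`` overrides it.  The systemic
    component (slow drift + Mayer wave near ``mayer_freq``) is shared
    across channels with per-channel gains; it is present in short
    channels, which carry no evoked component.
    """

    hbo_amplitude: dict = field(
        default_factory=lambda: dict(DEFAULT_HBO_AMPLITUDE))
    hbr_amplitude: dict | None = None
    hbr_ratio: float = -1.0 / 3.0
    systemic_amplitude: float = 1.0   # uM, sd of the shared component
    mayer_freq: float = 0.095         # Hz
    ar1_rho: float = 0.4
    noise_sd: float = 0.3             # uM, stationary sd of the AR(1) noise
    sampling_rate: float = 4.5        # Hz
    seed: int = 0

    def __post_init__(self):
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0 or self.systemic_amplitude < 0:
            raise ValueError("noise and systemic amplitudes must be >= 0")
        if self.mayer_freq <= 0:
            raise ValueError("mayer_freq must be positive")

    def amplitude(self, roi, block_type, chromophore) -> float:
        a = self.hbo_amplitude.get((roi, block_type), 0.0)
        if chromophore == "hbo":
            return a
        if self.hbr_amplitude is not None:
            return self.hbr_amplitude.get((roi, block_type), 0.0)
        return self.hbr_ratio * a

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for roi in ROIS:
            for bt in ("AllGo", "Mixed"):
                for ch in ("hbo", "hbr"):
                    rows.append(dict(roi=roi, condition=bt, chromophore=ch,
                                     beta=self.amplitude(roi, bt, ch)))
        return pd.DataFrame(rows)


def _ar1_noise(rng, shape, rho, sd):
    """Stationary AR(1) noise with lag-1 coefficient rho and sd ``sd``."""
    w = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    out = np.empty(shape)
    out[..., 0] = w[..., 0]
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + np.sqrt(1 - rho ** 2) * w[..., t]
    return sd * out


def generate_fnirs(params: FnirsParams, schedule: Schedule,
                   montage: Montage) -> RawIntensity:
    """Raw two-wavelength intensity for one participant's recording.

    The evoked concentration in each long channel's ROI is the peak
    amplitude times the block regressor (16-s boxcar convolved with the
    canonical HRF); the systemic component and AR(1) noise are added in
    concentration space, and concentrations are forward-converted to
    intensity by inverting the Beer-Lambert step, so the analysis
    pipeline's inverse recovers them.
    """
    rng = np.random.default_rng(params.seed)
    events = schedule.events()
    onsets = events["onset_s"].to_numpy()
    order = np.argsort(onsets)
    ends = onsets[order] + schedule.blocks["duration_s"].to_numpy()[order]
    if (onsets[order][1:] < ends[:-1] - 1e-9).any():
        raise ValueError("schedule contains overlapping blocks")
    fs = params.sampling_rate
    duration = float(ends[-1] + 30.0)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    regressors = {}
    for bt in ("AllGo", "Mixed"):
        on = events.loc[events["condition"] == bt, "onset_s"].to_numpy()
        regressors[bt] = task_regressor(on, n, fs) if on.size else np.zeros(n)

    # shared systemic series, unit sd, then scaled per channel
    slow = np.sin(2 * np.pi * 0.004 * t + rng.uniform(0, 2 * np.pi))
    slow += 0.5 * (t / t[-1] - 0.5) * rng.choice([-1.0, 1.0])
    mayer = np.sin(2 * np.pi * params.mayer_freq * t + rng.uniform(0, 2 * np.pi))
    systemic = 0.7 * slow + 0.5 * mayer
    if params.systemic_amplitude > 0 and systemic.std() > 0:
        systemic = systemic / systemic.std() * params.systemic_amplitude
    else:
        systemic = np.zeros(n)

    ch_table = montage.channels
    n_ch = len(ch_table)
    hbo = np.zeros((n_ch, n))
    hbr = np.zeros((n_ch, n))
    for c in range(n_ch):
        row = ch_table.iloc[c]
        gain = rng.uniform(0.6, 1.4)
        if not row["is_short"] and row["roi"] is not None:
            for bt in ("AllGo", "Mixed"):
                hbo[c] += params.amplitude(row["roi"], bt, "hbo") * regressors[bt]
                hbr[c] += params.amplitude(row["roi"], bt, "hbr") * regressors[bt]
        hbo[c] += gain * systemic
        hbr[c] += 0.3 * gain * systemic
        hbo[c] += _ar1_noise(rng, (n,), params.ar1_rho, params.noise_sd)
        hbr[c] += _ar1_noise(rng, (n,), params.ar1_rho, 0.5 * params.noise_sd)

    haemo = HaemoSeries(hbo, hbr, montage, fs, events)
    baseline = rng.uniform(0.5, 2.0, size=(n_ch, 2))
    return haemoglobin_to_intensity(haemo, baseline)


def simulate_fnirs_cohort(n_per_group: int, schedule: Schedule,
                          montage: Montage,
                          base: FnirsParams | dict | None = None,
                          participant_sd=(0.3, 0.2), seed: int = 0):
    """Simulate a two-group cohort of fNIRS recordings.

    Each participant's evoked amplitudes are the group's base amplitudes
    plus a participant random intercept and block-type slope per
    chromophore (sds ``participant_sd``, the structure the second-level
    model assumes).  ``base`` may be a single :class:`FnirsParams` (both
    groups identical) or a dict mapping group name to its params.

    Yields tuples ``(participant_id, group, RawIntensity, truth)`` where
    ``truth`` is that participant's true amplitude table.
    """
    rng = np.random.default_rng(seed)
    if base is None:
        base = FnirsParams()
    if isinstance(base, FnirsParams):
        base = {"Control": base, "Synchronized": base}
    s0, s1 = participant_sd
    for group, tag in (("Control", "C"), ("Synchronized", "S")):
        bp = base[group]
        for k in range(n_per_group):
            pid = f"{tag}{k + 1:02d}"
            u = {ch: (rng.normal(0, s0), rng.normal(0, s1))
                 for ch in ("hbo", "hbr")}
            hbo_amp, hbr_amp = {}, {}
            for roi in ROIS:
                for bt in ("AllGo", "Mixed"):
                    m = 1.0 if bt == "Mixed" else 0.0
                    hbo_amp[(roi, bt)] = (bp.amplitude(roi, bt, "hbo")
                                          + u["hbo"][0] + u["hbo"][1] * m)
                    hbr_amp[(roi, bt)] = (bp.amplitude(roi, bt, "hbr")
                                          + u["hbr"][0] + u["hbr"][1] * m)
            pp = FnirsParams(hbo_amplitude=hbo_amp, hbr_amplitude=hbr_amp,
                             systemic_amplitude=bp.systemic_amplitude,
                             mayer_freq=bp.mayer_freq, ar1_rho=bp.ar1_rho,
                             noise_sd=bp.noise_sd,
                             sampling_rate=bp.sampling_rate,
                             seed=int(rng.integers(2 ** 31)))
            yield pid, group, generate_fnirs(pp, schedule, montage), \
                pp.truth_table()
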