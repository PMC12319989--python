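"""Synthetic study-input generator with known ground truth.

Emulates the full input bundle of a three-arm HD-tDCS motor-learning
experiment (0 / 4 / 6 mA over right M1): baseline typing-test logs, keypress
logs from a 36-trial sequence-learning task, pre/post EMG epochs containing
biphasic motor-evoked potentials (MEPs), pre/post EEG epochs containing
TMS-evoked potentials (TEPs), and per-subject sensation ratings.  Every
latent quantity (skill, substrate, planted amplitudes) is recorded in a
ground-truth table so downstream scoring and inference can be validated
against what was planted.

Conventions:

* Typing speed and latent motor skill are drawn from a bivariate normal with
  unit variances and correlation 0.62 (the pilot typing-performance
  correlation); all group dose effects are expressed in SD units (Cohen's d)
  on mean NCS.
* Learning follows a saturating exponential in trial index,
  ``rate_t = plateau * (1 - exp(-t/tau)) + baseline`` (tau = 5 trials by
  default; the empirical curve saturates within about 10 trials).
* MEP amplitudes are lognormal across trials (empirically they fail
  normality tests); the post/pre ratio of medians drifts by a configurable
  multiplicative offset, 1.19 by default.
* TEP templates carry peaks at 33/45/55/100/175 ms and a high-amplitude
  artifact confined to -3..10 ms around the pulse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import EpochSet

DEFAULT_SEQUENCE = (4, 1, 3, 2, 4)
N_TRIALS = 36
TRIAL_S = 10.0
N_TYPING_WORDS = 63

#: 32-channel 10-10 montage, symmetric across the midline, dense over motor strip.
DEFAULT_EEG_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
]

EMG_FS_SET = (500.0, 2000.0)


class ConfigurationError(ValueError):
    pass


@dataclass
class CausalModelParams:
    """Common-cause model: field -> substrate -> (MEP, performance).

    The substrate for subject *i* in dose level ``x`` is
    ``s_i = a * x + offset_i`` with ``offset_i ~ N(0, subject_offset_sd)``;
    both outcomes are ``b * s_i`` plus independent N(0, noise_sd) noise.
    """

    a: float = 1.0
    b1: float = 0.5
    b2: float = 0.5
    noise_sd: float = 1.0
    subject_offset_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.subject_offset_sd < 0:
            raise ConfigurationError("subject_offset_sd must be >= 0")


@dataclass
class EvokedTemplate:
    """Parametric evoked waveform: sum of Gaussian-shaped peaks.

    For EMG the two entries of ``peak_amplitudes`` are the positive and
    negative lobes of one biphasic MEP (second lobe ``lobe_sep_ms`` after the
    first); for EEG each entry is one TEP component.
    """

    peak_times_ms: tuple = (33.0, 45.0, 55.0, 100.0, 175.0)
    peak_amplitudes: tuple = (3.0, -4.0, 2.5, 5.0, -3.0)
    peak_widths_ms: tuple = (5.0, 6.0, 7.0, 12.0, 20.0)
    artifact_window_ms: tuple = (-3.0, 10.0)
    noise_sd: float = 1.0
    sampling_rate_hz: float = 5000.0

    def __post_init__(self):
        if np.any(np.diff(self.peak_times_ms) <= 0):
            raise ConfigurationError("peak times must be strictly increasing")
        if len(self.peak_amplitudes) != len(self.peak_times_ms):
            raise ConfigurationError("one amplitude per peak time required")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def waveform(self, time_ms: np.ndarray) -> np.ndarray:
        """Noiseless template evaluated at ``time_ms`` (no artifact)."""
        t = np.asarray(time_ms, dtype=float)
        out = np.zeros_like(t)
        widths = np.broadcast_to(
            np.asarray(self.peak_widths_ms, float), (len(self.peak_times_ms),)
        )
        for t0, a, w in zip(self.peak_times_ms, self.peak_amplitudes, widths):
            sigma = w / 2.0  # "width" is ~2 sigma of the lobe
            out += a * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        return out


def mep_template(
    latency_ms: float = 24.0,
    pos_mv: float = 1.0,
    neg_mv: float = -0.8,
    lobe_width_ms: float = 4.0,
    lobe_sep_ms: float = 7.0,
    noise_sd: float = 0.05,
    fs_hz: float = 2000.0,
) -> EvokedTemplate:
    """Biphasic MEP template: positive lobe at ``latency_ms``, negative lobe after."""
    if not 20.0 <= latency_ms <= 50.0 - lobe_sep_ms:
        raise ConfigurationError("MEP latency must leave both lobes in 20-50 ms")
    return EvokedTemplate(
        peak_times_ms=(latency_ms, latency_ms + lobe_sep_ms),
        peak_amplitudes=(pos_mv, neg_mv),
        peak_widths_ms=(lobe_width_ms, lobe_width_ms),
        artifact_window_ms=(-3.0, 3.0),
        noise_sd=noise_sd,
        sampling_rate_hz=fs_hz,
    )


def template_peak_to_peak(template: EvokedTemplate,
                          window_ms: tuple = (0.0, 80.0)) -> float:
    """Peak-to-peak of the noiseless waveform, evaluated on a 0.01-ms grid."""
    t = np.arange(window_ms[0], window_ms[1], 0.01)
    w = template.waveform(t)
    return float(w.max() - w.min())


# ---------------------------------------------------------------------------
# keypress / typing logs
# ---------------------------------------------------------------------------

def learning_rate_curve(trials: np.ndarray, plateau: float, baseline: float,
                        tau: float) -> np.ndarray:
    """Sequences-per-trial rate: ``plateau * (1 - exp(-t/tau)) + baseline``.

    ``tau -> 0`` gives a flat curve at ``plateau + baseline`` (no learning).
    """
    t = np.asarray(trials, dtype=float)
    if tau <= 1e-12:
        return np.full_like(t, plateau + baseline)
    return plateau * (1.0 - np.exp(-t / tau)) + baseline


def generate_keypress_log(
    rng: np.random.Generator,
    plateau_ncs: float,
    baseline_ncs: float = 1.0,
    tau_trials: float = 5.0,
    n_trials: int = N_TRIALS,
    trial_s: float = TRIAL_S,
    sequence: tuple = DEFAULT_SEQUENCE,
    error_p: float = 0.03,
    interval_cv: float = 0.25,
    subject_id: str = "S000",
    task_id: str = "L:S1",
) -> pd.DataFrame:
    """Simulate one subject's keypress log for the sequence-learning task.

    Presses arrive with gamma-distributed inter-press intervals whose rate
    follows the saturating learning curve; each press is the correct next
    sequence element with probability ``1 - error_p``.
    """
    if len(sequence) != 5 or any(k not in (1, 2, 3, 4) for k in sequence):
        raise ConfigurationError("sequence must be 5 digits from {1,2,3,4}")
    rows = []
    trials = np.arange(1, n_trials + 1)
    rates = learning_rate_curve(trials, plateau_ncs, baseline_ncs, tau_trials)
    for trial, ncs_rate in zip(trials, rates):
        press_rate = max(len(sequence) * ncs_rate / trial_s, 0.05)  # presses/s
        shape = max(1.0 / interval_cv**2, 1.0) if interval_cv > 0 else None
        t = 0.0
        pos = 0
        press_idx = 0
        while True:
            mean_gap = 1.0 / press_rate
            if shape is None:
                gap = mean_gap
            else:
                gap = rng.gamma(shape, mean_gap / shape)
            t += gap
            if t >= trial_s:
                break
            correct_key = sequence[pos % len(sequence)]
            if error_p > 0 and rng.random() < error_p:
                others = [k for k in (1, 2, 3, 4) if k != correct_key]
                key = int(rng.choice(others))
            else:
                key = int(correct_key)
            rows.append((subject_id, task_id, int(trial), press_idx, key,
                         round(t * 1000.0, 3)))
            pos += 1
            press_idx += 1
    return pd.DataFrame(
        rows, columns=["subject_id", "task_id", "trial", "press_idx", "key", "t_ms"]
    )


def expected_mean_ncs(plateau_ncs: float, baseline_ncs: float, tau_trials: float,
                      error_p: float = 0.03, n_trials: int = N_TRIALS) -> float:
    """Analytic expectation of mean NCS under the generator's rate curve."""
    rates = learning_rate_curve(np.arange(1, n_trials + 1), plateau_ncs,
                                baseline_ncs, tau_trials)
    return float(np.mean(rates) * (1.0 - error_p) ** 5)


def generate_typing_log(rng: np.random.Generator, wpm: float,
                        subject_id: str = "S000",
                        n_words: int = N_TYPING_WORDS) -> pd.DataFrame:
    """Word-completion timestamps for the 63-word baseline typing test.

    The final timestamp encodes the typing speed exactly:
    ``wpm = n_words / (last t_ms / 60000)``.
    """
    if wpm <= 0:
        raise ConfigurationError("wpm must be positive")
    total_ms = n_words / wpm * 60000.0
    # jittered but monotone word-completion times, pinned at the end
    raw = np.sort(rng.uniform(0.0, 1.0, size=n_words - 1))
    t = np.concatenate([raw * total_ms, [total_ms]])
    return pd.DataFrame({
        "subject_id": subject_id,
        "press_idx": np.arange(n_words),
        "t_ms": np.round(t, 3),
    })


# ---------------------------------------------------------------------------
# EMG epochs
# ---------------------------------------------------------------------------

def _band_limited_noise(rng: np.random.Generator, shape: tuple, fs_hz: float,
                        sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    cutoff = min(150.0, 0.35 * fs_hz)
    b, a = sps.butter(4, cutoff / (fs_hz / 2.0), btype="low")
    white = rng.standard_normal(shape)
    filt = sps.filtfilt(b, a, white, axis=-1)
    # renormalize so the output SD equals sd
    scale = sd / max(filt.std(), 1e-12)
    return filt * scale


def generate_emg_epochs(
    template: EvokedTemplate,
    n_trials: int = 60,
    lognormal_sigma: float = 0.5,
    median_scale: float = 1.0,
    rng: np.random.Generator | None = None,
    span_ms: tuple = (-50.0, 150.0),
    hand: str = "left",
    timepoint: str = "pre",
) -> EpochSet:
    """EMG epochs, one biphasic MEP per trial with lognormal amplitude scaling.

    The per-trial scale is ``median_scale * exp(sigma * z)`` so the planted
    median peak-to-peak equals ``median_scale *`` the template peak-to-peak.
    Ground truth lives in ``meta``: ``amplitudes_mv`` (true peak-to-peak per
    trial) and ``scales``.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    fs = template.sampling_rate_hz
    if fs not in EMG_FS_SET:
        raise ConfigurationError(f"EMG sampling rate must be in {EMG_FS_SET}")
    rng = np.random.default_rng() if rng is None else rng
    dt = 1000.0 / fs
    time_ms = np.arange(span_ms[0], span_ms[1] + dt / 2, dt)
    base = template.waveform(time_ms)
    p2p_base = template_peak_to_peak(template)
    scales = median_scale * np.exp(lognormal_sigma * rng.standard_normal(n_trials))
    data = scales[:, None] * base[None, :]
    data += _band_limited_noise(rng, data.shape, fs, template.noise_sd)
    es = EpochSet(data[:, None, :], time_ms, ["FDI"], fs, hand=hand,
                  timepoint=timepoint)
    es.meta["amplitudes_mv"] = scales * p2p_base
    es.meta["scales"] = scales
    return es


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

def motor_topography(channels: list[str], hemisphere: str = "right") -> np.ndarray:
    """Crude scalp weighting peaked over the M1 hand knob (C4 or C3)."""
    focus = {"right": {"C4": 1.0, "C2": 0.9, "C6": 0.6, "FC4": 0.55,
                       "CP4": 0.55, "FC2": 0.45, "CP2": 0.45, "Cz": 0.35,
                       "C1": 0.25, "C3": 0.1},
             "left": {"C3": 1.0, "C1": 0.9, "C5": 0.6, "FC3": 0.55,
                      "CP3": 0.55, "FC1": 0.45, "CP1": 0.45, "Cz": 0.35,
                      "C2": 0.25, "C4": 0.1}}[hemisphere]
    return np.array([focus.get(ch, 0.08) for ch in channels])


def generate_eeg_epochs(
    template: EvokedTemplate,
    channels: list[str],
    weights: np.ndarray,
    n_trials: int = 20,
    rng: np.random.Generator | None = None,
    span_ms: tuple = (-500.0, 500.0),
    artifact_amp_uv: float = 300.0,
    trial_gain_sd: float = 0.1,
    baseline_offset_sd: float = 2.0,
    hand: str = "left",
    timepoint: str = "pre",
) -> EpochSet:
    """EEG epochs: per-channel scaled TEP + confined TMS artifact + noise.

    The artifact is a high-amplitude damped deflection whose support is
    hard-masked to ``template.artifact_window_ms``; the symmetric per-trial
    gain jitter keeps the across-trial median equal to the template.
    The noiseless channel x time signal is stored in ``meta["clean"]``.
    """
    if span_ms[0] > -500.0 or span_ms[1] < 500.0:
        raise ConfigurationError("EEG epoch must cover -500..+500 ms")
    rng = np.random.default_rng() if rng is None else rng
    fs = template.sampling_rate_hz
    dt = 1000.0 / fs
    time_ms = np.arange(span_ms[0], span_ms[1] + dt / 2, dt)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(channels),):
        raise ConfigurationError("one topography weight per channel required")

    clean = weights[:, None] * template.waveform(time_ms)[None, :]

    lo, hi = template.artifact_window_ms
    in_art = (time_ms >= lo) & (time_ms <= hi)
    art_shape = np.zeros_like(time_ms)
    tt = time_ms[in_art]
    art_shape[in_art] = np.exp(-(tt - lo) / 3.0) * np.cos(2 * np.pi * (tt - lo) / 6.0)

    gains = 1.0 + trial_gain_sd * rng.standard_normal(n_trials)
    data = gains[:, None, None] * clean[None, :, :]
    data += artifact_amp_uv * art_shape[None, None, :]
    if baseline_offset_sd > 0:
        data += baseline_offset_sd * rng.standard_normal(
            (n_trials, len(channels), 1))
    if template.noise_sd > 0:
        data += template.noise_sd * rng.standard_normal(data.shape)
    es = EpochSet(data, time_ms, list(channels), fs, hand=hand,
                  timepoint=timepoint)
    es.meta["clean"] = clean
    return es


# ---------------------------------------------------------------------------
# sensation ratings
# ---------------------------------------------------------------------------

_SENSATION_OFFSETS = {"begin": 1.5, "mid": 0.8, "after": 0.4}
_SENSATION_CUTPOINTS = np.linspace(0.0, 5.4, 10)


def generate_sensation(rng: np.random.Generator, current_ma: float,
                       slope: float = 0.35) -> dict:
    """Ordered-logistic sensation ratings (0-10) at three timepoints.

    Latent intensity rises with current; ratings fade from the start of
    stimulation to after ramp-down.
    """
    out = {}
    for tp, off in _SENSATION_OFFSETS.items():
        latent = off + slope * current_ma + rng.logistic(0.0, 1.0)
        out[tp] = int(np.sum(latent > _SENSATION_CUTPOINTS))
    p_believe = 1.0 / (1.0 + np.exp(-(-0.5 + 0.4 * current_ma)))
    out["believed_stim"] = bool(rng.random() < p_believe)
    return out


# ---------------------------------------------------------------------------
# whole-cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Dose effects (``dose_effect_d``) are Cohen's d shifts of mean NCS per
    group, in SD units of the between-subject plateau spread.
    """

    n_per_group: int = 40
    group_currents: tuple = (0.0, 4.0, 6.0)
    dose_effect_d: tuple = (0.0, 0.0, 0.0)
    typing_nc_corr: float = 0.62
    learning_tau: float = 5.0
    plateau_mean: float = 4.0
    plateau_sd: float = 1.0
    baseline_ncs: float = 1.0
    error_p: float = 0.03
    wpm_mean: float = 33.5
    wpm_sd: float = 12.0
    common_cause: CausalModelParams | None = None
    mep_ratio_offset: float = 1.19
    mep_ratio_sigma: float = 0.15
    mep_dose_log_slope: float = 0.0
    mep_median_mv: float = 1.0
    mep_between_sigma: float = 0.4
    mep_lognormal_sigma: float = 0.5
    mep_n_trials: int = 60
    emg_fs_hz: float = 2000.0
    emg_noise_sd_mv: float = 0.05
    include_eeg: bool = False
    eeg_n_trials: int = 20
    eeg_channels: tuple = tuple(DEFAULT_EEG_CHANNELS)
    eeg_noise_sd_uv: float = 1.5
    tep_dose_shift_uv: float = 0.0
    sensation_slope: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not abs(self.typing_nc_corr) < 1:
            raise ConfigurationError("|typing_nc_corr| must be < 1")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        for name in ("plateau_sd", "wpm_sd", "mep_ratio_sigma",
                     "mep_between_sigma", "mep_lognormal_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.dose_effect_d) != len(self.group_currents):
            raise ConfigurationError("one dose effect per group required")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.common_cause is not None:
            d["common_cause"] = asdict(self.common_cause)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("group_currents", "dose_effect_d", "eeg_channels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("common_cause") is not None:
            d["common_cause"] = CausalModelParams(**d["common_cause"])
        return cls(**d)


@dataclass
class Cohort:
    config: CohortConfig
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    keypress_logs: pd.DataFrame
    typing_logs: pd.DataFrame
    emg: dict = field(default_factory=dict)   # (subject_id, timepoint) -> EpochSet
    eeg: dict = field(default_factory=dict)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete cohort bundle; deterministic given ``config.seed``.

    Subjects arrive in a random interleaved order and are allocated to arms
    by the same minimization routine the analysis uses (capped at
    ``n_per_group`` per arm so the design stays balanced).
    """
    from . import assignment  # deferred to avoid import cycle

    rng = np.random.default_rng(config.seed)
    n_groups = len(config.group_currents)
    n = n_groups * config.n_per_group

    corr = config.typing_nc_corr
    cov = np.array([[1.0, corr], [corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n,
                                method="cholesky")
    z_perf, z_type = z[:, 0], z[:, 1]
    wpm = np.maximum(config.wpm_mean + config.wpm_sd * z_type, 5.0)

    state = assignment.AssignmentState.fresh(n_groups)
    groups = np.empty(n, dtype=int)
    for i in range(n):
        gi, state = assignment.assign_group(
            state, float(wpm[i]), max_group_size=config.n_per_group)
        groups[i] = gi
    graded = groups.astype(float)
    currents = np.asarray(config.group_currents, float)[groups]
    d_shift = np.asarray(config.dose_effect_d, float)[groups]

    cc = config.common_cause
    if cc is not None:
        substrate = cc.a * graded + cc.subject_offset_sd * rng.standard_normal(n)
    else:
        substrate = np.zeros(n)

    perf_shift = d_shift + (cc.b2 * substrate if cc is not None else 0.0)
    plateau = config.plateau_mean + config.plateau_sd * (z_perf + perf_shift)
    plateau = np.maximum(plateau, 0.2)

    subject_ids = [f"S{i:03d}" for i in range(n)]
    manifest_rows, gt_rows = [], []
    keypress_frames, typing_frames = [], []
    emg, eeg = {}, {}

    pre_median = config.mep_median_mv * np.exp(
        config.mep_between_sigma * rng.standard_normal(n))
    ratio_noise = rng.standard_normal(n)
    if cc is not None:
        ratio_noise = ratio_noise + cc.b1 * substrate
    log_ratio = (np.log(config.mep_ratio_offset)
                 + config.mep_dose_log_slope * graded
                 + config.mep_ratio_sigma * ratio_noise)
    true_ratio = np.exp(log_ratio)

    if config.include_eeg:
        channels = list(config.eeg_channels)
        topo = motor_topography(channels, "right")

    for i, sid in enumerate(subject_ids):
        typing_frames.append(generate_typing_log(rng, float(wpm[i]), sid))
        keypress_frames.append(generate_keypress_log(
            rng, float(plateau[i]), config.baseline_ncs, config.learning_tau,
            error_p=config.error_p, subject_id=sid))

        for tp, med in (("pre", pre_median[i]),
                        ("post", pre_median[i] * true_ratio[i])):
            tpl = mep_template(noise_sd=config.emg_noise_sd_mv,
                               fs_hz=config.emg_fs_hz)
            emg[(sid, tp)] = generate_emg_epochs(
                tpl, config.mep_n_trials, config.mep_lognormal_sigma,
                median_scale=float(med) / template_peak_to_peak(tpl),
                rng=rng, timepoint=tp)

        if config.include_eeg:
            for tp in ("pre", "post"):
                amps = list(EvokedTemplate().peak_amplitudes)
                if tp == "post":
                    amps[1] -= config.tep_dose_shift_uv * graded[i]
                tpl = EvokedTemplate(peak_amplitudes=tuple(amps),
                                     noise_sd=config.eeg_noise_sd_uv)
                eeg[(sid, tp)] = generate_eeg_epochs(
                    tpl, channels, topo, config.eeg_n_trials, rng,
                    timepoint=tp)

        sens = generate_sensation(rng, float(currents[i]),
                                  config.sensation_slope)
        manifest_rows.append({
            "subject_id": sid, "group_mA": currents[i],
            "typing_wpm": round(float(wpm[i]), 3),
            "sensation_begin": sens["begin"], "sensation_mid": sens["mid"],
            "sensation_after": sens["after"],
            "believed_stim": sens["believed_stim"],
        })
        gt_rows.append({
            "subject_id": sid, "group_mA": currents[i], "graded": graded[i],
            "typing_z": z_type[i], "perf_z": z_perf[i],
            "substrate": substrate[i], "plateau": plateau[i],
            "true_mean_ncs": expected_mean_ncs(
                plateau[i], config.baseline_ncs, config.learning_tau,
                config.error_p),
            "pre_median_mv": pre_median[i], "true_ratio": true_ratio[i],
        })

    return Cohort(
        config=config,
        manifest=pd.DataFrame(manifest_rows),
        ground_truth=pd.DataFrame(gt_rows),
        keypress_logs=pd.concat(keypress_frames, ignore_index=True),
        typing_logs=pd.concat(typing_frames, ignore_index=True),
        emg=emg, eeg=eeg,
    )


# ---------------------------------------------------------------------------
# bundle IO
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(cohort.config.to_dict(), indent=2, sort_keys=True))
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    cohort.keypress_logs.to_csv(out / "keypress_logs.csv", index=False)
    cohort.typing_logs.to_csv(out / "typing_logs.csv", index=False)
    for name, store in (("emg", cohort.emg), ("eeg", cohort.eeg)):
        if store:
            (out / name).mkdir(exist_ok=True)
            for (sid, tp), es in store.items():
                es.to_hdf5(out / name / f"{sid}_{tp}.h5")


def read_cohort(indir) -> Cohort:
    src = Path(indir)
    config = CohortConfig.from_dict(json.loads((src / "config.json").read_text()))
    emg, eeg = {}, {}
    for name, store in (("emg", emg), ("eeg", eeg)):
        d = src / name
        if d.is_dir():
            for p in sorted(d.glob("*.h5")):
                sid, tp = p.stem.rsplit("_", 1)
                store[(sid, tp)] = EpochSet.from_hdf5(p)
    return Cohort(
        config=config,
        manifest=pd.read_csv(src / "manifest.csv"),
        ground_truth=pd.read_csv(src / "ground_truth.csv"),
        keypress_logs=pd.read_csv(src / "keypress_logs.csv"),
        typing_logs=pd.read_csv(src / "typing_logs.csv"),
        emg=emg, eeg=eeg,
    )
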