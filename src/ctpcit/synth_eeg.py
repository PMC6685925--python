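"""Synthetic epoched EEG and behavior with the structure the analysis assumes.

Each primary-task trial carries, on Pz, a baseline P300 bump common to every
stimulus plus a role/category-specific increment (probe > irrelevant for
guilty subjects, ordered forename > date > animal), embedded in background
noise (broadband + alpha oscillation + slow drift) with stereotyped blinks on
the EOG channels that leak weakly into the scalp channels.  Reaction times
follow a shifted lognormal with a per-category probe slowing; response errors
and gross artifacts occur at configurable rates.

Amplitude convention: a component's ``amplitude`` parameter is the
peak-to-peak score its noiseless waveform produces under the segment-search
measure (a raised-cosine bump's best 100 ms segment mean is ~0.95 of its
peak, so kernels are internally rescaled by the scored value of a unit
kernel).  This makes "inject 9.16 uV" mean "a noiseless probe-minus-irrelevant
peak-to-peak difference of 9.16 uV", which is what parameter-recovery checks
compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pools
from .containers import EpochSet
from .stimgen import SessionPlan, build_item_set, make_session_plan

__all__ = [
    "SubjectProfile", "NoiseModel", "SimulatedSubject",
    "p300_kernel", "simulate_session", "generate_cohort", "iter_cohort",
    "CHANNELS", "EOG_CHANNELS", "SCALP_CHANNELS",
]

SCALP_CHANNELS = ["Pz", "Cz", "Fz", "TP9", "TP10"]
EOG_CHANNELS = ["VEOGu", "VEOGl", "HEOGl", "HEOGr"]
CHANNELS = SCALP_CHANNELS + EOG_CHANNELS

# spatial gain of the P300 component per scalp channel (mastoids assumed
# signal-free so the linked-mastoid reference preserves Pz amplitudes)
_SIGNAL_GAIN = {"Pz": 1.0, "Cz": 0.8, "Fz": 0.5, "TP9": 0.0, "TP10": 0.0}
# blink leakage into scalp channels (fraction of the VEOG deflection)
_BLINK_LEAK = {"Pz": 0.05, "Cz": 0.10, "Fz": 0.18, "TP9": 0.02, "TP10": 0.02}


@dataclass
class SubjectProfile:
    """Ground-truth generative parameters of one simulated examinee.

    Amplitudes are in microvolts on the peak-to-peak scale (see module
    docstring); RTs in ms.  ``guilty=False`` forces all probe increments and
    probe RT slowing to zero (probes indistinguishable from irrelevants).

    ``late_negativity_uv`` is the depth of a negative slow wave following the
    P300 (peak ``late_peak_ms``, width ``late_width_ms``), common to every
    stimulus.  It is a standard feature of parietal ERPs and gives the
    min-segment search a genuine trough to settle on; without it the search
    runs over a flat tail and its pure-noise selection bias would not cancel
    between conditions with unequal trial counts.
    """

    guilty: bool = True
    probe_increment_uv: dict[str, float] = field(
        default_factory=lambda: {"forename": 9.16, "date": 5.66, "animal": 3.57}
    )
    irrelevant_base_uv: float = 2.8
    nontarget_base_uv: float = 4.5
    target_increment_uv: float = 6.7
    late_negativity_uv: float = 2.0
    late_peak_ms: float = 1000.0
    late_width_ms: float = 500.0
    probe_rt_slowing_ms: dict[str, float] = field(
        default_factory=lambda: {"forename": 13.9, "date": 8.4, "animal": -1.5}
    )
    rt_shift_ms: float = 200.0
    rt_mean_ms: float = 420.0
    rt_sd_ms: float = 100.0
    error_rate: dict[str, float] = field(
        default_factory=lambda: {
            "probe": 0.027, "irrelevant": 0.023,
            "target": 0.185, "nontarget": 0.025,
        }
    )
    artifact_rate: float = 0.08

    def __post_init__(self) -> None:
        if not self.guilty:
            self.probe_increment_uv = {k: 0.0 for k in self.probe_increment_uv}
            self.probe_rt_slowing_ms = {k: 0.0 for k in self.probe_rt_slowing_ms}
        if any(v < 0 for v in self.probe_increment_uv.values()):
            raise ValueError("probe increments must be nonnegative")

    @classmethod
    def innocent(cls, **kw) -> "SubjectProfile":
        return cls(guilty=False, **kw)


# Between-subject SDs of the probe increments, per category (truncated-normal
# draws in generate_cohort); values mirror printed group-level dispersion.
INCREMENT_SD_UV = {"forename": 4.43, "date": 4.14, "animal": 3.17}


@dataclass
class NoiseModel:
    """Background-activity parameters (all amplitudes in microvolts).

    Defaults emulate a clean laboratory recording: after 30-epoch averaging
    the residual noise is small relative to the P300 (segment-mean noise SD
    on the averaged waveform ~0.2 uV), the regime in which the peak-to-peak
    measure behaves approximately additively.
    """

    white_sd_uv: float = 2.0
    alpha_amp_uv: float = 1.5
    alpha_freq_hz: float = 10.0
    drift_amp_uv: float = 1.0
    blink_rate_per_min: float = 8.0
    blink_amp_uv: float = 120.0
    mastoid_noise_scale: float = 0.7
    eog_white_sd_uv: float = 5.0

    def __post_init__(self) -> None:
        for name in ("white_sd_uv", "alpha_amp_uv", "drift_amp_uv",
                     "blink_rate_per_min", "blink_amp_uv", "eog_white_sd_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        """All-zero noise, for noiseless oracle checks."""
        return cls(white_sd_uv=0, alpha_amp_uv=0, drift_amp_uv=0,
                   blink_rate_per_min=0, blink_amp_uv=0, eog_white_sd_uv=0)


def p300_kernel(
    peak_ms: float,
    width_ms: float,
    amplitude_uv: float,
    srate: float = 250.0,
    epoch_window: tuple[float, float] = (-100.0, 1400.0),
) -> np.ndarray:
    """Raised-cosine (Hann) bump: peak value ``amplitude_uv`` at ``peak_ms``,
    zero outside ``[peak - width/2, peak + width/2]``."""
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    t0, t1 = epoch_window
    if not (t0 <= peak_ms < t1):
        raise ValueError(f"peak {peak_ms} ms outside epoch window {epoch_window}")
    n = round((t1 - t0) / 1000.0 * srate)
    t = t0 + np.arange(n) * 1000.0 / srate
    x = (t - peak_ms) / width_ms
    wave = np.where(np.abs(x) <= 0.5,
                    amplitude_uv * 0.5 * (1.0 + np.cos(2 * np.pi * x)), 0.0)
    return wave


def _unit_pp_scale(peak_ms: float, width_ms: float, srate: float,
                   window: tuple[float, float]) -> float:
    """Peak amplitude needed for a kernel to score 1 uV peak-to-peak."""
    from .erp_score import SegmentSearchConfig, p300_pp

    unit = p300_kernel(peak_ms, width_ms, 1.0, srate, window)
    res = p300_pp(unit, srate=srate, tmin_ms=window[0], cfg=SegmentSearchConfig())
    if res.p300pp_uv <= 0:
        raise ValueError("unit kernel scores nonpositive peak-to-peak amplitude")
    return 1.0 / res.p300pp_uv


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _background_noise(
    n_epochs: int, n_samples: int, srate: float,
    noise: NoiseModel, rng: np.random.Generator, scale: float = 1.0,
) -> np.ndarray:
    """White + alpha + slow-drift background, (n_epochs, n_samples)."""
    out = np.zeros((n_epochs, n_samples))
    if noise.white_sd_uv:
        out += rng.normal(0.0, noise.white_sd_uv * scale, (n_epochs, n_samples))
    t = np.arange(n_samples) / srate
    if noise.alpha_amp_uv:
        amp = noise.alpha_amp_uv * scale * rng.rayleigh(np.sqrt(2 / np.pi), n_epochs)
        phase = rng.uniform(0, 2 * np.pi, n_epochs)
        out += amp[:, None] * np.sin(2 * np.pi * noise.alpha_freq_hz * t + phase[:, None])
    if noise.drift_amp_uv:
        freq = rng.uniform(0.1, 0.5, n_epochs)
        amp = noise.drift_amp_uv * scale * rng.normal(1.0, 0.3, n_epochs)
        phase = rng.uniform(0, 2 * np.pi, n_epochs)
        out += amp[:, None] * np.sin(2 * np.pi * freq[:, None] * t + phase[:, None])
    return out


def _make_epochs(
    amplitudes: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    srate: float,
    window: tuple[float, float],
    peak_ms: float,
    width_ms: float,
    artifact_mask: np.ndarray,
    late_wave: np.ndarray | None = None,
) -> np.ndarray:
    """Build (n, n_channels, n_samples) raw epochs for given per-trial
    peak-to-peak signal amplitudes on Pz (plus an optional common late
    wave)."""
    n = len(amplitudes)
    n_samp = round((window[1] - window[0]) / 1000.0 * srate)
    scale = _unit_pp_scale(peak_ms, width_ms, srate, window)
    kernel = p300_kernel(peak_ms, width_ms, scale, srate, window)
    data = np.zeros((n, len(CHANNELS), n_samp))
    signal = amplitudes[:, None] * kernel[None, :]
    if late_wave is not None:
        signal = signal + late_wave[None, :]
    for ci, ch in enumerate(SCALP_CHANNELS):
        ch_scale = noise.mastoid_noise_scale if ch in ("TP9", "TP10") else 1.0
        data[:, ci, :] = _SIGNAL_GAIN[ch] * signal + _background_noise(
            n, n_samp, srate, noise, rng, scale=ch_scale)
    for ci, ch in enumerate(EOG_CHANNELS, start=len(SCALP_CHANNELS)):
        if noise.eog_white_sd_uv:
            data[:, ci, :] = rng.normal(0, noise.eog_white_sd_uv, (n, n_samp))

    # stereotyped blinks: raised-cosine deflection on the vertical EOG pair,
    # leaking (scaled) into the scalp channels
    if noise.blink_rate_per_min and noise.blink_amp_uv:
        epoch_s = n_samp / srate
        p_blink = min(1.0, noise.blink_rate_per_min * epoch_s / 60.0)
        has_blink = rng.random(n) < p_blink
        t = window[0] + np.arange(n_samp) * 1000.0 / srate
        iu, il = CHANNELS.index("VEOGu"), CHANNELS.index("VEOGl")
        for i in np.flatnonzero(has_blink):
            center = rng.uniform(window[0] + 150, window[1] - 150)
            amp = noise.blink_amp_uv * rng.lognormal(0.0, 0.25)
            x = (t - center) / 300.0
            bump = np.where(np.abs(x) <= 0.5, amp * 0.5 * (1 + np.cos(2 * np.pi * x)), 0.0)
            data[i, iu, :] += bump
            data[i, il, :] -= 0.6 * bump
            for ch, leak in _BLINK_LEAK.items():
                data[i, CHANNELS.index(ch), :] += leak * bump

    # gross artifacts on a monitored channel -> amplitude rejection later
    for i in np.flatnonzero(artifact_mask):
        ch = rng.choice(["Pz", "TP9", "TP10"])
        center = rng.uniform(window[0] + 100, window[1] - 100)
        amp = rng.choice([-1, 1]) * rng.uniform(100, 250)
        t = window[0] + np.arange(n_samp) * 1000.0 / srate
        x = (t - center) / 200.0
        data[i, CHANNELS.index(ch), :] += np.where(
            np.abs(x) <= 0.5, amp * 0.5 * (1 + np.cos(2 * np.pi * x)), 0.0)
    return data


def simulate_session(
    plan: SessionPlan,
    profile: SubjectProfile,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator | None = None,
    srate: float = 250.0,
    epoch_window: tuple[float, float] = (-100.0, 1400.0),
    p300_peak_ms: float = 550.0,
    p300_width_ms: float = 400.0,
    include_secondary: bool = True,
) -> tuple[EpochSet, EpochSet | None, pd.DataFrame]:
    """Simulate one session: primary-stimulus epochs, secondary-stimulus
    epochs (optional), and a long-format behavior table.

    Returns ``(primary_epochs, secondary_epochs, behavior)``; behavior has one
    row per response with columns ``block, trial_index, category, task, role,
    item, rt_ms, correct``.
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sched = plan.to_frame()
    n = len(sched)

    mu, sg = _lognormal_params(profile.rt_mean_ms - profile.rt_shift_ms,
                               profile.rt_sd_ms)
    late = None
    if profile.late_negativity_uv:
        late = p300_kernel(profile.late_peak_ms, profile.late_width_ms,
                           -profile.late_negativity_uv, srate, epoch_window)

    # --- primary task -----------------------------------------------------
    is_probe = (sched["primary_role"] == "probe").to_numpy()
    cats = sched["category"].to_numpy()
    amp = np.full(n, profile.irrelevant_base_uv, dtype=float)
    amp[is_probe] += np.array([profile.probe_increment_uv[c]
                               for c in cats[is_probe]])
    artifacts = rng.random(n) < profile.artifact_rate
    prim_data = _make_epochs(amp, noise, rng, srate, epoch_window,
                             p300_peak_ms, p300_width_ms, artifacts, late)
    rt = profile.rt_shift_ms + rng.lognormal(mu, sg, n)
    rt[is_probe] += np.array([profile.probe_rt_slowing_ms[c]
                              for c in cats[is_probe]])
    err = np.array([profile.error_rate[r] for r in sched["primary_role"]])
    correct = rng.random(n) >= err
    prim_events = pd.DataFrame({
        "block": sched["block"],
        "trial_index": sched["trial_index"],
        "category": sched["category"],
        "task": "primary",
        "role": sched["primary_role"],
        "item": sched["primary_text"],
        "rt_ms": np.round(rt, 1),
        "correct": correct,
    })
    primary = EpochSet(prim_data, srate, list(CHANNELS), epoch_window[0],
                       prim_events.reset_index(drop=True))

    # --- secondary task ---------------------------------------------------
    secondary: EpochSet | None = None
    sec_events = None
    if include_secondary:
        is_target = (sched["secondary_role"] == "target").to_numpy()
        amp2 = np.full(n, profile.nontarget_base_uv, dtype=float)
        amp2[is_target] += profile.target_increment_uv
        artifacts2 = rng.random(n) < profile.artifact_rate
        sec_data = _make_epochs(amp2, noise, rng, srate, epoch_window,
                                p300_peak_ms, p300_width_ms, artifacts2, late)
        rt2 = profile.rt_shift_ms + rng.lognormal(mu, sg, n)
        rt2[is_target] += 60.0  # targets answered more slowly
        err2 = np.array([profile.error_rate[r] for r in sched["secondary_role"]])
        correct2 = rng.random(n) >= err2
        sec_events = pd.DataFrame({
            "block": sched["block"],
            "trial_index": sched["trial_index"],
            "category": sched["category"],
            "task": "secondary",
            "role": sched["secondary_role"],
            "item": sched["secondary_text"],
            "rt_ms": np.round(rt2, 1),
            "correct": correct2,
        })
        secondary = EpochSet(sec_data, srate, list(CHANNELS), epoch_window[0],
                             sec_events.reset_index(drop=True))

    behavior = (prim_events if sec_events is None
                else pd.concat([prim_events, sec_events], ignore_index=True))
    return primary, secondary, behavior


def simulate_epoch_pool(
    n_epochs: int,
    pp_amplitude_uv: float,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator | None = None,
    srate: float = 250.0,
    epoch_window: tuple[float, float] = (-100.0, 1400.0),
    p300_peak_ms: float = 550.0,
    p300_width_ms: float = 400.0,
    late_negativity_uv: float = 2.0,
    late_peak_ms: float = 1000.0,
    late_width_ms: float = 500.0,
) -> np.ndarray:
    """Single-channel (Pz-like) epoch pool: evoked template plus background
    noise, baseline-corrected; no EOG/artifact machinery.

    Intended for calibration studies and exchangeable-null experiments where
    the full multi-channel session would be overhead: every epoch carries the
    same peak-to-peak amplitude, so two pools with equal ``pp_amplitude_uv``
    are draws from the identical distribution.  Returns ``(n_epochs,
    n_samples)``.
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_samp = round((epoch_window[1] - epoch_window[0]) / 1000.0 * srate)
    scale = _unit_pp_scale(p300_peak_ms, p300_width_ms, srate, epoch_window)
    wave = pp_amplitude_uv * scale * p300_kernel(
        p300_peak_ms, p300_width_ms, 1.0, srate, epoch_window)
    if late_negativity_uv:
        wave = wave + p300_kernel(late_peak_ms, late_width_ms,
                                  -late_negativity_uv, srate, epoch_window)
    data = wave[None, :] + _background_noise(n_epochs, n_samp, srate, noise, rng)
    t = epoch_window[0] + np.arange(n_samp) * 1000.0 / srate
    bl = (t >= -100.0) & (t < 0.0)
    return data - data[:, bl].mean(axis=1, keepdims=True)


@dataclass
class SimulatedSubject:
    subject_id: int
    group: str
    guilty: bool
    profile: SubjectProfile
    plan: SessionPlan
    primary: EpochSet
    secondary: EpochSet | None
    behavior: pd.DataFrame


def _draw_profile(guilty: bool, rng: np.random.Generator,
                  base: SubjectProfile | None = None) -> SubjectProfile:
    """Between-subject variability: truncated-normal increments, jittered RT
    parameters."""
    base = base or SubjectProfile(guilty=guilty)
    if guilty:
        incs = {}
        for cat, m in base.probe_increment_uv.items():
            sd = INCREMENT_SD_UV.get(cat, 3.0)
            v = -1.0
            while v < 0:
                v = rng.normal(m, sd)
            incs[cat] = v
        slow = {c: rng.normal(m, 10.0) for c, m in base.probe_rt_slowing_ms.items()}
    else:
        incs = {c: 0.0 for c in base.probe_increment_uv}
        slow = {c: 0.0 for c in base.probe_rt_slowing_ms}
    return replace(
        base,
        guilty=guilty,
        probe_increment_uv=incs,
        probe_rt_slowing_ms=slow,
        irrelevant_base_uv=max(0.5, rng.normal(base.irrelevant_base_uv, 1.5)),
        rt_mean_ms=rng.normal(base.rt_mean_ms, 50.0),
    )


def iter_cohort(
    n_guilty: int,
    n_innocent: int,
    group: str = "standard",
    seed: int | None = None,
    noise: NoiseModel | None = None,
    base_profile: SubjectProfile | None = None,
    include_secondary: bool = True,
    reps: int = 30,
):
    """Yield :class:`SimulatedSubject` one at a time (memory-friendly).

    Guilty subjects come first; ground truth is in ``subject.guilty`` and
    ``subject.profile``.
    """
    if n_guilty < 0 or n_innocent < 0:
        raise ValueError("cohort counts must be nonnegative")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(n_guilty + n_innocent)
    for sid, child in enumerate(children):
        rng = np.random.default_rng(child)
        guilty = sid < n_guilty
        iset = build_item_set(
            forename=str(rng.choice(pools.FORENAMES)),
            birthday=(int(rng.integers(1, 13)), int(rng.integers(1, 29))),
            animal=str(rng.choice(pools.ANIMALS)),
            group=group, seed=rng,
        )
        plan = make_session_plan(iset, group, seed=int(rng.integers(2**31)),
                                 reps=reps)
        profile = _draw_profile(guilty, rng, base_profile)
        prim, sec, beh = simulate_session(
            plan, profile, noise, rng, include_secondary=include_secondary)
        yield SimulatedSubject(sid, group, guilty, profile, plan, prim, sec, beh)


def generate_cohort(*args, **kwargs) -> list[SimulatedSubject]:
    """Materialized version of :func:`iter_cohort` (small cohorts only)."""
    return list(iter_cohort(*args, **kwargs))
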