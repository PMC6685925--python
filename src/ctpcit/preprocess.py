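"""EEG processing chain: resample, band-pass, epoch, baseline, EOG
regression, amplitude rejection, linked-mastoid re-reference.

The continuous-input path follows the order
``resample -> filter -> epoch -> baseline -> EOG -> reject -> rereference``.
Epoched input (the synthetic generator emits epochs directly) enters the same
chain after the epoching step; there the band-pass is replaced by the 30 Hz
low-pass alone, because a 0.3 Hz high-pass kernel (~11 s at the default
transition width) is longer than a 1.5 s epoch — baseline correction takes
over the slow-drift removal that the high-pass performs on continuous data.

Filters are Hamming-windowed sinc FIRs with the half-amplitude (−6 dB)
cutoff convention, applied zero-phase (linear-phase kernel, group delay
compensated).  EOG correction is ordinary least-squares regression of the
scalp channels on the EOG channels, fit across all epochs of a session; the
adaptive recursive-least-squares variant used with real recordings is
deliberately replaced by this stationary fit (deterministic and sufficient
for stationary leakage), and the provenance log records the substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

from .containers import EpochSet, Recording

__all__ = [
    "FilterSpec", "RejectionLog", "PipelineConfig", "PipelineResult",
    "resample", "bandpass_fir", "extract_epochs", "baseline_correct",
    "regress_eog", "reject_amplitude", "rereference_linked_mastoids",
    "run_pipeline",
]

_HAMMING_TRANSITION = 3.3  # normalized transition width of a Hamming FIR


@dataclass(frozen=True)
class FilterSpec:
    """Windowed-sinc FIR band-pass design (−6 dB cutoff convention).

    Transition bandwidths default to the common heuristic
    ``min(max(0.25 * cutoff, 2 Hz), cutoff)`` per edge; the filter order is
    set by the narrower transition band.
    """

    l_freq: float | None = 0.3
    h_freq: float | None = 30.0
    l_trans_hz: float | None = None
    h_trans_hz: float | None = None

    def transitions(self) -> tuple[float | None, float | None]:
        lt = self.l_trans_hz
        ht = self.h_trans_hz
        if lt is None and self.l_freq is not None:
            lt = min(max(0.25 * self.l_freq, 2.0), self.l_freq)
        if ht is None and self.h_freq is not None:
            ht = min(max(0.25 * self.h_freq, 2.0), self.h_freq)
        return lt, ht

    def validate(self, srate: float) -> None:
        nyq = srate / 2.0
        if self.l_freq is not None and self.h_freq is not None:
            if not (0 < self.l_freq < self.h_freq):
                raise ValueError("need 0 < l_freq < h_freq")
        for f in (self.l_freq, self.h_freq):
            if f is not None and f >= nyq:
                raise ValueError(f"cutoff {f} Hz at or above Nyquist {nyq} Hz")


def design_fir(spec: FilterSpec, srate: float) -> np.ndarray:
    """Return the linear-phase FIR kernel (odd length) for ``spec``."""
    spec.validate(srate)
    lt, ht = spec.transitions()
    widths = [w for w in (lt, ht) if w is not None]
    if not widths:
        raise ValueError("at least one cutoff frequency required")
    ntaps = int(np.ceil(_HAMMING_TRANSITION * srate / min(widths)))
    ntaps += 1 - ntaps % 2  # odd
    if spec.l_freq is not None and spec.h_freq is not None:
        return scipy.signal.firwin(ntaps, [spec.l_freq, spec.h_freq],
                                   window="hamming", pass_zero=False, fs=srate)
    if spec.h_freq is not None:  # low-pass
        return scipy.signal.firwin(ntaps, spec.h_freq, window="hamming", fs=srate)
    return scipy.signal.firwin(ntaps, spec.l_freq, window="hamming",
                               pass_zero=False, fs=srate)


def _filtfir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase FIR application along the last axis with reflect padding."""
    n = data.shape[-1]
    half = len(taps) // 2
    pad = min(half, n - 1)
    if pad < half:
        raise ValueError(
            f"signal length {n} shorter than half the filter ({half} samples); "
            "filter continuous data or use a wider transition band")
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = scipy.signal.fftconvolve(padded, taps[(None,) * (data.ndim - 1)],
                                   mode="same", axes=-1)
    return out[..., pad:pad + n]


def bandpass_fir(
    data: Recording | EpochSet | np.ndarray,
    spec: FilterSpec | None = None,
    srate: float | None = None,
) -> Recording | EpochSet | np.ndarray:
    """Apply the windowed-sinc FIR zero-phase to a recording, epochs, or array."""
    spec = spec or FilterSpec()
    if isinstance(data, Recording):
        taps = design_fir(spec, data.srate)
        return Recording(_filtfir(data.data, taps), data.srate,
                         list(data.ch_names), data.events.copy())
    if isinstance(data, EpochSet):
        taps = design_fir(spec, data.srate)
        out = data.copy()
        out.data = _filtfir(out.data, taps)
        return out
    if srate is None:
        raise ValueError("srate required for raw arrays")
    return _filtfir(np.asarray(data, dtype=float), design_fir(spec, srate))


def resample(data: Recording | EpochSet, target_srate: float):
    """Polyphase anti-aliased downsampling; event indices are remapped."""
    if target_srate > data.srate:
        raise ValueError("upsampling is outside the pipeline's scope")
    if target_srate == data.srate:
        return data
    frac = Fraction(target_srate / data.srate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if isinstance(data, Recording):
        new = scipy.signal.resample_poly(data.data, up, down, axis=-1)
        events = data.events.copy()
        if "onset_sample" in events.columns:
            events["onset_sample"] = np.round(
                events["onset_sample"] * target_srate / data.srate).astype(int)
        return Recording(new, target_srate, list(data.ch_names), events)
    new = scipy.signal.resample_poly(data.data, up, down, axis=-1)
    return EpochSet(new, target_srate, list(data.ch_names), data.tmin_ms,
                    data.events.copy())


def extract_epochs(
    recording: Recording,
    events: pd.DataFrame | None = None,
    window_ms: tuple[float, float] = (-100.0, 1400.0),
) -> tuple[EpochSet, list[int]]:
    """Cut epochs around event onsets (half-open ``[t0, t1)`` convention).

    Per-epoch sample count is ``round((t1 - t0)/1000 * srate)``; the stimulus
    onset lands at sample ``round(-t0/1000 * srate)``.  Events whose window
    does not fit in the recording are skipped and returned as the second
    element.
    """
    events = recording.events if events is None else events
    sr = recording.srate
    t0, t1 = window_ms
    n_samp = round((t1 - t0) / 1000.0 * sr)
    offset = round(t0 / 1000.0 * sr)  # negative for pre-stimulus baseline
    kept_rows, data, skipped = [], [], []
    for i, row in events.reset_index(drop=True).iterrows():
        start = int(row["onset_sample"]) + offset
        if start < 0 or start + n_samp > recording.n_samples:
            skipped.append(i)
            continue
        data.append(recording.data[:, start:start + n_samp])
        kept_rows.append(row)
    if not data:
        raise ValueError("no event leaves room for a full epoch")
    epochs = EpochSet(np.stack(data), sr, list(recording.ch_names), t0,
                      pd.DataFrame(kept_rows).reset_index(drop=True))
    return epochs, skipped


def baseline_correct(
    epochs: EpochSet, baseline_ms: tuple[float, float] = (-100.0, 0.0)
) -> EpochSet:
    """Subtract, per epoch and channel, the mean over the baseline window."""
    t = epochs.times_ms
    mask = (t >= baseline_ms[0] - 1e-9) & (t < baseline_ms[1] - 1e-9)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def regress_eog(
    epochs: EpochSet,
    eog_channels: list[str] | None = None,
    scalp_channels: list[str] | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Subtract the least-squares EOG projection from each scalp channel.

    The regression is fit across all epochs jointly (stationary coefficients).
    All-zero (constant) EOG regressors are dropped; with no informative
    regressor the data pass through unchanged.  Returns the corrected epochs
    and the coefficient matrix (n_scalp x n_eog, zeros for dropped
    regressors).
    """
    if eog_channels is None:
        eog_channels = [c for c in epochs.ch_names if "EOG" in c.upper()]
    if not eog_channels:
        raise ValueError("at least one EOG channel required")
    if scalp_channels is None:
        scalp_channels = [c for c in epochs.ch_names if c not in eog_channels]
    ei = [epochs.channel_index(c) for c in eog_channels]
    si = [epochs.channel_index(c) for c in scalp_channels]
    n_ep, _, n_samp = epochs.data.shape
    # raw (not demeaned) regressors: epochs are baseline-corrected upstream,
    # and a raw fit lets exact leakage cancel exactly
    E = epochs.data[:, ei, :].transpose(1, 0, 2).reshape(len(ei), -1)  # eog x time
    S = epochs.data[:, si, :].transpose(1, 0, 2).reshape(len(si), -1)
    keep = np.abs(E).max(axis=1) > 1e-12
    beta = np.zeros((len(si), len(ei)))
    out = epochs.copy()
    if keep.any():
        Ek = E[keep]
        g = Ek @ Ek.T
        cond = np.linalg.cond(g)
        if cond > 1e10:
            raise np.linalg.LinAlgError("EOG regressor matrix is singular")
        b = np.linalg.solve(g, Ek @ S.T).T  # scalp x kept-eog
        beta[:, keep] = b
        S_corr = S - b @ Ek
        out.data[:, si, :] = S_corr.reshape(len(si), n_ep, n_samp).transpose(1, 0, 2)
    return out, beta


@dataclass
class RejectionLog:
    """Per-epoch keep/drop bookkeeping from amplitude rejection."""

    table: pd.DataFrame  # epoch, kept, channel, peak_abs_uv

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_dropped(self) -> int:
        return len(self.table) - self.n_kept


def reject_amplitude(
    epochs: EpochSet,
    threshold_uv: float = 75.0,
    channels: tuple[str, ...] = ("Pz", "TP9", "TP10"),
) -> tuple[EpochSet, RejectionLog]:
    """Drop epochs whose absolute amplitude exceeds the threshold on any
    monitored channel."""
    ci = [epochs.channel_index(c) for c in channels]
    sub = np.abs(epochs.data[:, ci, :])
    peak_per_ch = sub.max(axis=2)  # epochs x channels
    peak = peak_per_ch.max(axis=1)
    worst = np.argmax(peak_per_ch, axis=1)
    kept = peak <= threshold_uv
    log = RejectionLog(pd.DataFrame({
        "epoch": np.arange(epochs.n_epochs),
        "kept": kept,
        "channel": [channels[w] for w in worst],
        "peak_abs_uv": peak,
    }))
    return epochs.select(kept), log


def rereference_linked_mastoids(
    epochs: EpochSet,
    target: str = "Pz",
    mastoids: tuple[str, str] = ("TP9", "TP10"),
) -> EpochSet:
    """Re-express ``target`` against the mastoid average, samplewise:
    ``Pz' = Pz - (TP9 + TP10)/2``."""
    ti = epochs.channel_index(target)
    m1, m2 = (epochs.channel_index(m) for m in mastoids)
    out = epochs.copy()
    out.data[:, ti, :] = (epochs.data[:, ti, :]
                          - 0.5 * (epochs.data[:, m1, :] + epochs.data[:, m2, :]))
    return out


@dataclass
class PipelineConfig:
    target_srate: float = 250.0
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    epoch_window_ms: tuple[float, float] = (-100.0, 1400.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    reject_threshold_uv: float = 75.0
    reject_channels: tuple[str, ...] = ("Pz", "TP9", "TP10")
    eog_regression: bool = True
    filter_epoched: bool = True  # low-pass only, see module docstring


@dataclass
class PipelineResult:
    epochs: EpochSet
    rejection: RejectionLog
    steps: list[str]
    provenance: dict


def run_pipeline(
    data: Recording | EpochSet, cfg: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full chain in the canonical order and log every step."""
    cfg = cfg or PipelineConfig()
    steps: list[str] = []
    prov: dict = {"eog_method": "stationary OLS regression "
                                "(replaces adaptive recursive least squares)"}

    if isinstance(data, Recording):
        if data.srate > cfg.target_srate:
            data = resample(data, cfg.target_srate)
            steps.append("resample")
        data = bandpass_fir(data, cfg.filter_spec)
        steps.append("bandpass_fir")
        prov["filter"] = {"l_freq": cfg.filter_spec.l_freq,
                          "h_freq": cfg.filter_spec.h_freq}
        epochs, skipped = extract_epochs(data, window_ms=cfg.epoch_window_ms)
        steps.append("extract_epochs")
        prov["skipped_events"] = skipped
    else:
        epochs = data
        if epochs.srate > cfg.target_srate:
            epochs = resample(epochs, cfg.target_srate)
            steps.append("resample")
        if cfg.filter_epoched and cfg.filter_spec.h_freq is not None:
            lp = FilterSpec(l_freq=None, h_freq=cfg.filter_spec.h_freq,
                            h_trans_hz=cfg.filter_spec.transitions()[1])
            epochs = bandpass_fir(epochs, lp)
            steps.append("lowpass_fir")
            prov["filter"] = {"l_freq": None, "h_freq": lp.h_freq,
                              "note": "high-pass replaced by baseline "
                                      "correction on epoched input"}

    epochs = baseline_correct(epochs, cfg.baseline_ms)
    steps.append("baseline_correct")
    if cfg.eog_regression:
        epochs, beta = regress_eog(epochs)
        steps.append("regress_eog")
        prov["eog_beta"] = beta.tolist()
    epochs, rejection = reject_amplitude(
        epochs, cfg.reject_threshold_uv, cfg.reject_channels)
    steps.append("reject_amplitude")
    epochs = rereference_linked_mastoids(epochs)
    steps.append("rereference_linked_mastoids")
    prov["threshold_uv"] = cfg.reject_threshold_uv
    return PipelineResult(epochs=epochs, rejection=rejection,
                          steps=steps, provenance=prov)
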