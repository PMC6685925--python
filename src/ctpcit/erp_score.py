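"""Condition averaging and the peak-to-peak P300 (P300pp) measure.

The P300pp of an averaged waveform is found by a two-stage segment search:
the 100 ms segment with the highest mean lying entirely within 400-800 ms
post-stimulus, then, between that segment's midpoint and 1400 ms, the 100 ms
segment with the lowest mean.  P300pp = max-segment mean minus min-segment
mean.  The scan steps one sample at a time; ties go to the earliest segment.
The measure is offset-invariant (adding a constant cancels) and scales
linearly with the waveform when segment locations are unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "SegmentSearchConfig", "AverageERP", "P300ppResult",
    "average_epochs", "p300_pp", "p300_pp_batch", "score_subject",
]


@dataclass(frozen=True)
class SegmentSearchConfig:
    """Windows (ms, relative to stimulus onset) of the two-stage search.

    ``bound_whole_segment=True`` requires segments to lie entirely inside
    their window; ``False`` bounds only segment starts (config switch for the
    alternative reading of the search-window convention).
    """

    max_search_ms: tuple[float, float] = (400.0, 800.0)
    segment_ms: float = 100.0
    min_search_end_ms: float = 1400.0
    step_samples: int = 1
    bound_whole_segment: bool = True

    def __post_init__(self) -> None:
        if self.step_samples < 1:
            raise ValueError("step_samples must be >= 1")
        if self.segment_ms <= 0:
            raise ValueError("segment_ms must be positive")


@dataclass
class AverageERP:
    """Condition-averaged waveform (one channel) with provenance counts."""

    condition: str
    waveform: np.ndarray
    srate: float
    tmin_ms: float
    n_epochs: int

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(len(self.waveform)) * 1000.0 / self.srate


@dataclass
class P300ppResult:
    max_mean_uv: float
    max_mid_ms: float
    min_mean_uv: float
    min_mid_ms: float
    p300pp_uv: float
    edge_warning: bool = False


def average_epochs(
    epochs: EpochSet,
    selector,
    channel: str = "Pz",
    correct_only: bool = True,
    condition: str = "",
) -> AverageERP:
    """Samplewise mean over selected epochs of one channel.

    ``selector`` is a boolean mask, an integer index array, or a callable
    mapping the event table to a boolean mask.  With ``correct_only`` (the
    analysis default) incorrect-response trials are dropped before averaging.
    """
    if callable(selector):
        mask = np.asarray(selector(epochs.events), dtype=bool)
    else:
        mask = np.asarray(selector)
        if mask.dtype != bool:
            full = np.zeros(epochs.n_epochs, dtype=bool)
            full[mask] = True
            mask = full
    if correct_only and "correct" in epochs.events.columns:
        mask = mask & epochs.events["correct"].to_numpy(dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no epochs match condition {condition!r}")
    wave = epochs.channel(channel)[mask].mean(axis=0)
    return AverageERP(condition, wave, epochs.srate, epochs.tmin_ms, n)


def _segment_grid(n_samples: int, srate: float, tmin_ms: float,
                  cfg: SegmentSearchConfig):
    """Segment length in samples and the start-time array (ms)."""
    seg_n = round(cfg.segment_ms / 1000.0 * srate)
    if seg_n < 1:
        raise ValueError("segment shorter than one sample")
    starts_ms = tmin_ms + np.arange(n_samples - seg_n + 1) * 1000.0 / srate
    return seg_n, starts_ms


def p300_pp_batch(
    waveforms: np.ndarray,
    srate: float,
    tmin_ms: float,
    cfg: SegmentSearchConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized segment search over rows of ``waveforms``.

    Returns ``(max_mean, max_mid_ms, min_mean, min_mid_ms)`` arrays; the
    peak-to-peak amplitude is ``max_mean - min_mean``.
    """
    cfg = cfg or SegmentSearchConfig()
    W = np.atleast_2d(np.asarray(waveforms, dtype=float))
    n_samples = W.shape[1]
    dur_ms = 1000.0 * n_samples / srate
    if tmin_ms + dur_ms < cfg.min_search_end_ms - 1e-9:
        raise ValueError(
            f"epoch ends at {tmin_ms + dur_ms:.0f} ms; "
            f"min-search needs {cfg.min_search_end_ms:.0f} ms")
    seg_n, starts_ms = _segment_grid(n_samples, srate, tmin_ms, cfg)
    span_ms = cfg.segment_ms
    # sliding segment means; pairwise reduction identical to np.mean on each
    # contiguous slice, so results match a direct scan bit-for-bit
    seg_means = np.lib.stride_tricks.sliding_window_view(
        W, seg_n, axis=1).mean(axis=-1)  # (n_wave, n_starts)

    lo, hi = cfg.max_search_ms
    if cfg.bound_whole_segment:
        max_ok = (starts_ms >= lo - 1e-9) & (starts_ms + span_ms <= hi + 1e-9)
    else:
        max_ok = (starts_ms >= lo - 1e-9) & (starts_ms <= hi + 1e-9)
    idx_max_all = np.flatnonzero(max_ok)
    if idx_max_all.size == 0:
        raise ValueError("no admissible segment in the max-search window")
    sub = seg_means[:, idx_max_all]
    rel = np.argmax(sub, axis=1)  # first occurrence on ties
    i_max = idx_max_all[rel]
    max_mean = sub[np.arange(W.shape[0]), rel]
    mid_ms = starts_ms[i_max] + span_ms / 2.0
    # midpoint floored to the sample grid
    mid_idx = np.floor((mid_ms - tmin_ms) / 1000.0 * srate).astype(int)
    mid_grid_ms = tmin_ms + mid_idx * 1000.0 / srate

    end = cfg.min_search_end_ms
    if cfg.bound_whole_segment:
        ok = (starts_ms[None, :] >= mid_grid_ms[:, None] - 1e-9) & \
             (starts_ms[None, :] + span_ms <= end + 1e-9)
    else:
        ok = (starts_ms[None, :] >= mid_grid_ms[:, None] - 1e-9) & \
             (starts_ms[None, :] <= end + 1e-9)
    if not ok.any(axis=1).all():
        raise ValueError("min-search window shorter than one segment")
    masked = np.where(ok, seg_means, np.inf)
    j = np.argmin(masked, axis=1)  # earliest on ties
    rows = np.arange(W.shape[0])
    min_mean = seg_means[rows, j]
    min_mid = starts_ms[j] + span_ms / 2.0
    return max_mean, mid_ms, min_mean, min_mid


def p300_pp(
    avg: AverageERP | np.ndarray,
    cfg: SegmentSearchConfig | None = None,
    srate: float | None = None,
    tmin_ms: float | None = None,
) -> P300ppResult:
    """Score one averaged waveform; see module docstring for the algorithm.

    Emits a warning when the max segment abuts a search-window edge (the peak
    may fall outside the configured window)."""
    cfg = cfg or SegmentSearchConfig()
    if isinstance(avg, AverageERP):
        wave, srate, tmin_ms = avg.waveform, avg.srate, avg.tmin_ms
    else:
        wave = np.asarray(avg, dtype=float)
        if srate is None or tmin_ms is None:
            raise ValueError("srate and tmin_ms required for raw arrays")
    mx, mx_mid, mn, mn_mid = p300_pp_batch(wave[None, :], srate, tmin_ms, cfg)
    span = cfg.segment_ms
    lo, hi = cfg.max_search_ms
    dt = 1000.0 / srate
    edge = (mx_mid[0] - span / 2 <= lo + dt / 2) or \
           (mx_mid[0] + span / 2 >= hi - dt / 2)
    if edge:
        warnings.warn(
            f"max segment (midpoint {mx_mid[0]:.0f} ms) abuts the "
            f"[{lo:.0f}, {hi:.0f}] ms search window", stacklevel=2)
    return P300ppResult(
        max_mean_uv=float(mx[0]), max_mid_ms=float(mx_mid[0]),
        min_mean_uv=float(mn[0]), min_mid_ms=float(mn_mid[0]),
        p300pp_uv=float(mx[0] - mn[0]), edge_warning=edge)


def score_subject(
    primary: EpochSet,
    secondary: EpochSet | None = None,
    cfg: SegmentSearchConfig | None = None,
    channel: str = "Pz",
    subject: int | str | None = None,
) -> pd.DataFrame:
    """Per-condition P300pp table for one subject.

    One row per category for the probe and the pooled irrelevants (plus, when
    secondary epochs are given, per-category target/nontarget rows).  Probe
    rows carry ``p300pp_diff_uv`` = probe minus pooled-irrelevant P300pp of
    the same category.  Only correct-response epochs enter the averages.
    """
    cfg = cfg or SegmentSearchConfig()
    rows = []

    def add(epochs: EpochSet, cat: str, role: str) -> None:
        ev = epochs.events
        sel = (ev["category"] == cat) & (ev["role"] == role)
        avg = average_epochs(epochs, sel.to_numpy(), channel=channel,
                             condition=f"{cat}/{role}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = p300_pp(avg, cfg)
        rows.append({
            "subject": subject, "category": cat, "condition": role,
            "n_epochs": avg.n_epochs,
            "max_mean_uv": res.max_mean_uv, "max_mid_ms": res.max_mid_ms,
            "min_mean_uv": res.min_mean_uv, "min_mid_ms": res.min_mid_ms,
            "p300pp_uv": res.p300pp_uv,
        })

    cats = list(dict.fromkeys(primary.events["category"]))
    for cat in cats:
        add(primary, cat, "probe")
        add(primary, cat, "irrelevant")
        if secondary is not None:
            add(secondary, cat, "target")
            add(secondary, cat, "nontarget")
    out = pd.DataFrame(rows)
    diffs = []
    for _, row in out.iterrows():
        if row["condition"] == "probe":
            irr = out[(out["category"] == row["category"])
                      & (out["condition"] == "irrelevant")]["p300pp_uv"].iloc[0]
            diffs.append(row["p300pp_uv"] - irr)
        else:
            diffs.append(np.nan)
    out["p300pp_diff_uv"] = diffs
    return out
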