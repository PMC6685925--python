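"""Bootstrapped amplitude difference (BAD): per-subject diagnostic.

The classic individual diagnostic for P300 concealed-information data: on
each of B iterations, resample the subject's probe epochs and irrelevant
epochs with replacement (keeping the original counts), average each pool,
score both averages with the peak-to-peak P300 measure, and record whether
the probe exceeds the irrelevant.  The proportion of exceedances p-hat, with
a verdict "knowledgeable" when p-hat reaches the threshold theta (0.9 by
convention in this literature; B = 1000).

Two comparison modes: against the average of all irrelevants pooled
(default), or against the maximum per-item irrelevant score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import EpochSet
from .erp_score import SegmentSearchConfig, p300_pp_batch

__all__ = ["BootstrapConfig", "BootstrapResult", "bootstrap_bad",
           "bootstrap_bad_epochs", "cohort_rates"]


@dataclass(frozen=True)
class BootstrapConfig:
    iterations: int = 1000
    mode: str = "probe_vs_all_irrelevants"  # or "probe_vs_max_irrelevant"
    theta: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if self.mode not in ("probe_vs_all_irrelevants", "probe_vs_max_irrelevant"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class BootstrapResult:
    p_hat: float
    ci_low: float
    ci_high: float
    verdict: bool  # True = knowledgeable at theta
    iterations: int
    theta: float
    n_probe: int
    n_irrelevant: int


def _bootstrap_scores(
    pool: np.ndarray,
    n_draw: int,
    B: int,
    rng: np.random.Generator,
    srate: float,
    tmin_ms: float,
    cfg: SegmentSearchConfig,
) -> np.ndarray:
    """Peak-to-peak scores of B bootstrap averages of ``n_draw`` rows of
    ``pool`` (n_epochs x n_samples).

    A with-replacement resample average is the multinomial-weighted mean of
    the pool rows, so each iteration is one matrix product.
    """
    n = pool.shape[0]
    counts = rng.multinomial(n_draw, np.full(n, 1.0 / n), size=B)
    avgs = (counts @ pool) / n_draw
    mx, _, mn, _ = p300_pp_batch(avgs, srate, tmin_ms, cfg)
    return mx - mn


def bootstrap_bad(
    probe: np.ndarray,
    irrelevant: np.ndarray | dict[str, np.ndarray],
    srate: float,
    tmin_ms: float,
    cfg: BootstrapConfig | None = None,
    scorer_cfg: SegmentSearchConfig | None = None,
) -> BootstrapResult:
    """Run the bootstrap on raw epoch matrices (n_epochs x n_samples).

    ``irrelevant`` is a single pooled matrix, or (for the max-irrelevant
    mode) a dict of per-item matrices.  Deterministic under ``cfg.seed``.
    """
    cfg = cfg or BootstrapConfig()
    scorer_cfg = scorer_cfg or SegmentSearchConfig()
    rng = np.random.default_rng(cfg.seed)
    probe = np.atleast_2d(np.asarray(probe, dtype=float))
    if probe.shape[0] < 2:
        raise ValueError("need at least 2 probe epochs")
    B = cfg.iterations

    p_scores = _bootstrap_scores(
        probe, probe.shape[0], B, rng, srate, tmin_ms, scorer_cfg)

    if cfg.mode == "probe_vs_all_irrelevants":
        if isinstance(irrelevant, dict):
            irrelevant = np.concatenate(list(irrelevant.values()), axis=0)
        irrelevant = np.atleast_2d(np.asarray(irrelevant, dtype=float))
        if irrelevant.shape[0] < 2:
            raise ValueError("need at least 2 irrelevant epochs")
        i_scores = _bootstrap_scores(
            irrelevant, irrelevant.shape[0], B, rng, srate, tmin_ms, scorer_cfg)
        n_irr = irrelevant.shape[0]
    else:
        if not isinstance(irrelevant, dict):
            raise ValueError("max-irrelevant mode needs per-item epoch pools")
        per_item = []
        n_irr = 0
        for pool in irrelevant.values():
            pool = np.atleast_2d(np.asarray(pool, dtype=float))
            if pool.shape[0] < 2:
                raise ValueError("need at least 2 epochs per irrelevant item")
            per_item.append(_bootstrap_scores(
                pool, pool.shape[0], B, rng, srate, tmin_ms, scorer_cfg))
            n_irr += pool.shape[0]
        i_scores = np.max(np.stack(per_item), axis=0)

    wins = int(np.sum(p_scores > i_scores))
    p_hat = wins / B
    ci_low, ci_high = scipy.stats.binomtest(wins, B).proportion_ci(0.95)
    return BootstrapResult(
        p_hat=p_hat, ci_low=float(ci_low), ci_high=float(ci_high),
        verdict=bool(p_hat >= cfg.theta), iterations=B, theta=cfg.theta,
        n_probe=probe.shape[0], n_irrelevant=n_irr)


def bootstrap_bad_epochs(
    epochs: EpochSet,
    category: str,
    cfg: BootstrapConfig | None = None,
    scorer_cfg: SegmentSearchConfig | None = None,
    channel: str = "Pz",
    correct_only: bool = True,
) -> BootstrapResult:
    """Convenience wrapper: pull probe/irrelevant pools of one category out of
    a cleaned :class:`EpochSet` and run :func:`bootstrap_bad`."""
    cfg = cfg or BootstrapConfig()
    ev = epochs.events
    base = (ev["category"] == category)
    if correct_only and "correct" in ev.columns:
        base = base & ev["correct"].astype(bool)
    sig = epochs.channel(channel)
    probe = sig[(base & (ev["role"] == "probe")).to_numpy()]
    if cfg.mode == "probe_vs_max_irrelevant":
        irr_ev = ev[(base & (ev["role"] == "irrelevant")).to_numpy()]
        irrelevant: dict[str, np.ndarray] | np.ndarray = {
            item: sig[(base & (ev["role"] == "irrelevant")
                       & (ev["item"] == item)).to_numpy()]
            for item in irr_ev["item"].unique()
        }
    else:
        irrelevant = sig[(base & (ev["role"] == "irrelevant")).to_numpy()]
    return bootstrap_bad(probe, irrelevant, epochs.srate, epochs.tmin_ms,
                         cfg, scorer_cfg)


def cohort_rates(
    p_hats: list[float] | np.ndarray,
    truth: list[bool] | np.ndarray,
    theta: float = 0.9,
    theta_grid: np.ndarray | None = None,
) -> dict:
    """Hit rate and false-positive rate at ``theta``, plus an ROC over a
    threshold grid.

    ``truth`` marks genuinely knowledgeable cases.  Returns a dict with
    ``hit_rate``, ``false_positive_rate``, ``n_guilty``, ``n_innocent`` and a
    ``roc`` DataFrame (theta, hit_rate, false_positive_rate).
    """
    p_hats = np.asarray(p_hats, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if p_hats.size == 0:
        raise ValueError("empty cohort")
    if p_hats.shape != truth.shape:
        raise ValueError("labels do not align with results")
    guilty = p_hats[truth]
    innocent = p_hats[~truth]

    def rates(th: float) -> tuple[float, float]:
        hit = float(np.mean(guilty >= th)) if guilty.size else np.nan
        fpr = float(np.mean(innocent >= th)) if innocent.size else np.nan
        return hit, fpr

    hit, fpr = rates(theta)
    if theta_grid is None:
        theta_grid = np.linspace(0.0, 1.0, 101)
    roc = pd.DataFrame(
        [(th, *rates(th)) for th in theta_grid],
        columns=["theta", "hit_rate", "false_positive_rate"])
    return {
        "hit_rate": hit, "false_positive_rate": fpr, "theta": theta,
        "n_guilty": int(guilty.size), "n_innocent": int(innocent.size),
        "roc": roc,
    }
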