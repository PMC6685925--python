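"""Group-level statistics: behavioral summaries, difference scores, effect
sizes, mixed ANOVA with Greenhouse-Geisser correction, t-tests, exclusion
rules, and the design power computation.

Behavioral conventions: responses faster than 150 ms are invalid; accuracy is
correct / valid; RT means use correct valid trials only.  All probe-versus-
irrelevant contrasts beyond the overall item-type ANOVA are run on one
within-subject difference score per subject (RT_diff = RT_probe -
RT_irrelevant; same for the peak-to-peak P300).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats

__all__ = [
    "RT_VALID_MIN_MS", "BehavioralSummary", "PowerSpec", "ExclusionThresholds",
    "behavioral_summary", "diff_scores", "cohen_d_within", "mixed_anova",
    "paired_ttest", "independent_ttest", "power_mixed_interaction",
    "simulate_power_mixed", "apply_exclusions",
]

RT_VALID_MIN_MS = 150.0


@dataclass
class BehavioralSummary:
    """Tidy per-cell behavioral aggregates with empty-cell flags."""

    table: pd.DataFrame  # subject? x category x role: rt_mean_ms, accuracy, ...
    empty_cells: list[tuple]


def behavioral_summary(
    behavior: pd.DataFrame,
    by: tuple[str, ...] = ("category", "role"),
) -> BehavioralSummary:
    """Aggregate a long-format behavior table (columns ``rt_ms``, ``correct``
    plus the grouping keys).

    A trial is valid iff RT > 150 ms; accuracy = n_correct / n_valid; the RT
    mean is computed over correct valid trials.  Cells present in the grouping
    grid but left without valid trials are flagged, not dropped silently.
    """
    need = {"rt_ms", "correct", *by}
    missing = need - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table lacks columns {sorted(missing)}")
    valid = behavior[behavior["rt_ms"] > RT_VALID_MIN_MS]
    rows = []
    empty = []
    for keys, _grp in behavior.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        cell = valid
        for k, v in zip(by, keys):
            cell = cell[cell[k] == v]
        n_valid = len(cell)
        n_correct = int(cell["correct"].sum())
        correct_rt = cell.loc[cell["correct"].astype(bool), "rt_ms"]
        if n_valid == 0:
            empty.append(keys)
        rows.append({
            **dict(zip(by, keys)),
            "n_valid": n_valid,
            "n_correct": n_correct,
            "accuracy": n_correct / n_valid if n_valid else np.nan,
            "rt_mean_ms": correct_rt.mean() if len(correct_rt) else np.nan,
        })
    return BehavioralSummary(pd.DataFrame(rows), empty)


def diff_scores(
    table: pd.DataFrame,
    value: str,
    cond_col: str = "role",
    minuend: str = "probe",
    subtrahend: str = "irrelevant",
    by: tuple[str, ...] = ("subject", "category"),
) -> pd.DataFrame:
    """Per-group probe-minus-irrelevant difference of ``value``."""
    wide = table.pivot_table(index=list(by), columns=cond_col, values=value)
    out = wide.reset_index()
    out[f"{value}_diff"] = out[minuend] - out[subtrahend]
    return out


def cohen_d_within(
    diffs: np.ndarray | pd.Series,
    kind: str = "dz",
    sd_pair: tuple[float, float] | None = None,
) -> float:
    """Standardized within-subject effect size of a difference score.

    ``dz`` (default): mean of the differences over their sample SD (n-1).
    ``dav``: mean difference over the average of the two condition SDs
    (``sd_pair`` required).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 subjects")
    if kind == "dz":
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance in difference scores")
        return float(d.mean() / sd)
    if kind == "dav":
        if sd_pair is None:
            raise ValueError("dav needs the two condition SDs")
        denom = (sd_pair[0] + sd_pair[1]) / 2.0
        if denom == 0:
            raise ValueError("zero condition SDs")
        return float(d.mean() / denom)
    raise ValueError(f"unknown kind {kind!r}")


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
) -> pd.DataFrame:
    """Mixed (split-plot) ANOVA with Greenhouse-Geisser correction.

    Returns a tidy table with columns ``effect, SS, F, df1, df2, eps, p_unc,
    p_gg, np2``.  The within-factor epsilon is applied to both the within
    main effect and the interaction (their F-tests share the within-error
    term); for a two-level within factor epsilon is exactly 1.  Partial
    eta-squared is SS_effect / (SS_effect + SS_error).
    """
    k = data[within].nunique()
    counts = data.groupby([subject, within])[dv].count()
    if counts.min() != 1 or counts.max() != 1:
        raise ValueError("design must have exactly one observation per cell")
    if data.groupby(subject)[within].nunique().min() < k:
        raise ValueError("missing within-factor cells")
    # rename the dv internally: pingouin melts on within levels and a level
    # sharing the dv's name would collide
    work = data[[subject, between, within, dv]].rename(columns={dv: "_dv_"})
    aov = pg.mixed_anova(data=work, dv="_dv_", within=within, subject=subject,
                         between=between, correction=True, effsize="np2")
    aov = aov.set_index("Source")
    if k == 2:
        eps = 1.0
    else:
        wide = data.pivot_table(index=subject, columns=within, values=dv)
        wide.columns = [f"level_{i}" for i in range(len(wide.columns))]
        eps = float(pg.epsilon(wide, correction="gg"))
    rows = []
    name_map = {between: "between", within: "within", "Interaction": "interaction"}
    for src, row in aov.iterrows():
        is_within_term = src != between
        e = eps if is_within_term else 1.0
        df1, df2 = row["DF1"] * e, row["DF2"] * e
        p_gg = float(scipy.stats.f.sf(row["F"], df1, df2)) if is_within_term \
            else float(row["p_unc"])
        rows.append({
            "effect": name_map.get(src, src),
            "SS": row["SS"],
            "F": row["F"],
            "df1": df1,
            "df2": df2,
            "eps": e,
            "p_unc": row["p_unc"],
            "p_gg": p_gg,
            "np2": row["np2"],
        })
    return pd.DataFrame(rows)


def paired_ttest(x, y=None) -> tuple[float, int, float]:
    """Paired t-test (or one-sample on differences when ``y`` is None).
    Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 observations")
    if d.std(ddof=1) == 0:
        # identical samples are a well-defined null (t = 0); a constant
        # nonzero difference has no finite t
        if d.mean() == 0:
            return 0.0, d.size - 1, 1.0
        raise ValueError("zero variance with nonzero mean difference")
    res = scipy.stats.ttest_1samp(d, 0.0)
    return float(res.statistic), d.size - 1, float(res.pvalue)


def independent_ttest(x, y, pooled: bool = True) -> tuple[float, float, float]:
    """Two-sample t-test, pooled-variance by default (Welch optional).
    Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = scipy.stats.ttest_ind(x, y, equal_var=pooled)
    df = x.size + y.size - 2 if pooled else float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass(frozen=True)
class PowerSpec:
    """Within-between interaction power inputs (G*Power repeated-measures
    convention: f on the between-group SD scale, rho the mean correlation
    among repeated measures, eps the nonsphericity correction)."""

    f: float = 0.25
    alpha: float = 0.05
    n_total: int = 35
    groups: int = 2
    measurements: int = 2
    rho: float = 0.5
    eps: float = 1.0

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("f must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_total <= self.groups:
            raise ValueError("need more subjects than groups")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")


def power_mixed_interaction(spec: PowerSpec | None = None, **kwargs) -> float:
    """Noncentral-F power of the within-between interaction.

    lambda = f^2 * N * m / (1 - rho) * eps, df1 = (g-1)(m-1)eps,
    df2 = (N-g)(m-1)eps; power = P(F' > F_crit(alpha)).
    """
    spec = spec or PowerSpec(**kwargs)
    g, m, N = spec.groups, spec.measurements, spec.n_total
    lam = spec.f ** 2 * N * m / (1.0 - spec.rho) * spec.eps
    df1 = (g - 1) * (m - 1) * spec.eps
    df2 = (N - g) * (m - 1) * spec.eps
    crit = scipy.stats.f.isf(spec.alpha, df1, df2)
    if lam == 0:  # central case (scipy's ncf is unstable at nc=0)
        return float(spec.alpha)
    return float(scipy.stats.ncf.sf(crit, df1, df2, lam))


def simulate_power_mixed(
    spec: PowerSpec | None = None,
    n_reps: int = 5000,
    seed: int | None = None,
    **kwargs,
) -> float:
    """Monte-Carlo power of the same two-measurement mixed design.

    Subjects get correlated measurement pairs (unit variance, correlation
    rho); the interaction carries the effect: group 1 means (+d, -d), group 2
    (-d, +d) with d = f (so the interaction's Cohen's f equals ``spec.f``).
    For two measurements the interaction F-test is the squared two-sample
    t-test on within-subject differences — used here as an independent route.
    """
    spec = spec or PowerSpec(**kwargs)
    if spec.measurements != 2 or spec.groups != 2:
        raise NotImplementedError("Monte-Carlo route covers the 2x2 design")
    rng = np.random.default_rng(seed)
    n1 = spec.n_total // 2 + spec.n_total % 2
    n2 = spec.n_total - n1
    d = spec.f
    cov = np.array([[1.0, spec.rho], [spec.rho, 1.0]])
    L = np.linalg.cholesky(cov)
    crit = scipy.stats.f.isf(spec.alpha, 1, spec.n_total - 2)
    hits = 0
    for _ in range(n_reps):
        y1 = rng.standard_normal((n1, 2)) @ L.T + np.array([d, -d])
        y2 = rng.standard_normal((n2, 2)) @ L.T + np.array([-d, d])
        d1 = y1[:, 0] - y1[:, 1]
        d2 = y2[:, 0] - y2[:, 1]
        t, _, _ = independent_ttest(d1, d2, pooled=True)
        if t * t > crit:
            hits += 1
    return hits / n_reps


@dataclass(frozen=True)
class ExclusionThresholds:
    """Participant-level quality thresholds.

    The recall rule (exclude above 4 of 9 wrong) mirrors the attention-check
    convention; the accuracy cutoffs are package defaults for the analogous
    low-accuracy exclusions.
    """

    min_probe_accuracy: float = 0.75
    min_target_accuracy: float = 0.60
    max_recall_failures: int = 4
    recall_total: int = 9


def apply_exclusions(
    qc: pd.DataFrame, thresholds: ExclusionThresholds | None = None
) -> pd.DataFrame:
    """Flag subjects failing any threshold; returns the table with ``kept``
    and ``reasons`` columns.

    ``qc`` needs columns ``probe_accuracy``, ``target_accuracy``,
    ``recall_failures``.
    """
    th = thresholds or ExclusionThresholds()
    out = qc.copy()
    reasons = []
    for _, row in qc.iterrows():
        r = []
        if row["probe_accuracy"] < th.min_probe_accuracy:
            r.append(f"low probe accuracy ({row['probe_accuracy']:.0%})")
        if row["target_accuracy"] < th.min_target_accuracy:
            r.append(f"low target accuracy ({row['target_accuracy']:.0%})")
        if row["recall_failures"] > th.max_recall_failures:
            r.append(f"failed recall {int(row['recall_failures'])} of "
                     f"{th.recall_total} times")
        reasons.append("; ".join(r))
    out["reasons"] = reasons
    out["kept"] = [not r for r in reasons]
    return out
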