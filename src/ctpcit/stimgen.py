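"""Stimulus item sets and the constrained trial schedule.

A Complex Trial Protocol (CTP) session presents, on every trial, first a
secondary-task item (target or nontarget, keypress discrimination) and then a
primary-task item (the examinee's own detail = probe, or a matched foil =
irrelevant, all sharing one "I saw it" keypress).  Each of the three blocks
covers one item category (forename, date, animal) with one probe and five
irrelevants repeated 30 times each: 180 trials per block.

The schedule is constrained randomization:

* trials come in groups of six, each group a permutation of the six primary
  items;
* the same primary item never appears on two consecutive trials, nor does the
  same secondary item;
* precedence is balanced exactly: every primary item is preceded by each
  nontarget ``reps/5`` times and each target ``reps/10`` times (targets are
  half as frequent as nontargets, keeping the 1:4 target:nontarget ratio);
* both inter-stimulus intervals vary uniformly on 1500-1700 ms.

The constraints are satisfied by per-group shuffling for the primary stream
and a randomized backtracking assignment for the secondary stream, with
bounded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pools

__all__ = [
    "Item", "ItemSet", "TrialSpec", "BlockSequence", "SessionPlan",
    "InsufficientCandidatesError", "SequenceConstraintError",
    "build_candidate_pool", "select_irrelevants", "build_item_set",
    "generate_block", "make_session_plan", "schedule_recall_checks",
    "validate_sequence",
]

ISI_RANGE_MS = (1500.0, 1700.0)
CATEGORIES = ("forename", "date", "animal")


class InsufficientCandidatesError(ValueError):
    """Raised when a word pool cannot supply enough matched candidates."""


class SequenceConstraintError(RuntimeError):
    """Raised when constrained randomization exhausts its restart budget."""


@dataclass(frozen=True)
class Item:
    """One stimulus item.

    ``role`` is its function in the task (probe / irrelevant for the primary
    task; target / nontarget for the secondary task); ``visual_type``
    distinguishes letters-only words from mixed-character items (dates).
    """

    text: str
    category: str
    role: str
    visual_type: str = "letters_only"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("item text must be nonempty")
        if self.role not in ("probe", "irrelevant", "target", "nontarget"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class ItemSet:
    """Full item inventory of one session.

    Three categories x (1 probe + 5 irrelevants) = 18 unique primary items,
    plus 2 targets and 4 nontargets for the secondary task.
    """

    probes: dict[str, Item]
    irrelevants: dict[str, list[Item]]
    targets: list[Item]
    nontargets: list[Item]

    def __post_init__(self) -> None:
        for cat, probe in self.probes.items():
            if probe.role != "probe":
                raise ValueError(f"probe for {cat} has role {probe.role}")
        texts = []
        for cat, irr in self.irrelevants.items():
            if cat not in self.probes:
                raise ValueError(f"irrelevants for unknown category {cat}")
            texts += [it.text for it in irr] + [self.probes[cat].text]
        if len(set(texts)) != len(texts):
            raise ValueError("primary items must be unique")
        if len(self.targets) != 2 or len(self.nontargets) != 4:
            raise ValueError("secondary task needs exactly 2 targets and 4 nontargets")

    @property
    def n_primary(self) -> int:
        return sum(1 + len(v) for v in self.irrelevants.values())

    def primary_items(self, category: str) -> list[Item]:
        """Probe first, then the five irrelevants."""
        return [self.probes[category], *self.irrelevants[category]]

    def to_json(self) -> dict:
        def enc(it: Item) -> dict:
            return {"text": it.text, "category": it.category,
                    "role": it.role, "visual_type": it.visual_type}
        return {
            "probes": {c: enc(p) for c, p in self.probes.items()},
            "irrelevants": {c: [enc(i) for i in v] for c, v in self.irrelevants.items()},
            "targets": [enc(t) for t in self.targets],
            "nontargets": [enc(t) for t in self.nontargets],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ItemSet":
        dec = lambda d: Item(**d)  # noqa: E731
        return cls(
            probes={c: dec(p) for c, p in obj["probes"].items()},
            irrelevants={c: [dec(i) for i in v] for c, v in obj["irrelevants"].items()},
            targets=[dec(t) for t in obj["targets"]],
            nontargets=[dec(t) for t in obj["nontargets"]],
        )


@dataclass
class TrialSpec:
    trial_index: int
    secondary_item: Item
    primary_item: Item
    isi1_ms: float  # secondary -> primary interval
    isi2_ms: float  # primary -> next trial interval
    recall_check_after: bool = False


@dataclass
class BlockSequence:
    category: str
    trials: list[TrialSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self, block: int | None = None) -> pd.DataFrame:
        rows = [
            {
                "trial_index": t.trial_index,
                "block": block,
                "category": self.category,
                "secondary_text": t.secondary_item.text,
                "secondary_role": t.secondary_item.role,
                "primary_text": t.primary_item.text,
                "primary_role": t.primary_item.role,
                "isi1_ms": t.isi1_ms,
                "isi2_ms": t.isi2_ms,
                "recall_check": t.recall_check_after,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


@dataclass
class SessionPlan:
    """Ordered blocks for one session, with recall-check positions."""

    blocks: list[BlockSequence]
    group: str  # "standard" or "induced"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("standard", "induced"):
            raise ValueError("group must be 'standard' or 'induced'")

    @property
    def block_order(self) -> list[str]:
        return [b.category for b in self.blocks]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [b.to_frame(block=i) for i, b in enumerate(self.blocks)],
            ignore_index=True,
        )


# ---------------------------------------------------------------------------
# item selection
# ---------------------------------------------------------------------------

def build_candidate_pool(
    probe: Item,
    pool: list[str],
    n_candidates: int = 8,
    seed: int | np.random.Generator | None = None,
    letter_filter: bool = True,
) -> list[Item]:
    """Pick ``n_candidates`` foils length-matched to the probe.

    Candidates must differ from the probe text and (unless ``letter_filter``
    is off, as for month-bearing dates) must not share its initial letter.
    Selection prefers minimal ``|len(candidate) - len(probe)|``; the partially
    used distance tier is filled by a seeded random draw.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eligible = [w for w in dict.fromkeys(pool) if w != probe.text]
    if letter_filter:
        eligible = [w for w in eligible if w[0].upper() != probe.text[0].upper()]
    if len(eligible) < n_candidates:
        raise InsufficientCandidatesError(
            f"need {n_candidates} candidates for {probe.text!r}, "
            f"only {len(eligible)} remain after filtering"
        )
    dist = np.array([abs(len(w) - len(probe.text)) for w in eligible])
    chosen: list[str] = []
    for d in np.unique(dist):
        tier = [w for w, dd in zip(eligible, dist) if dd == d]
        need = n_candidates - len(chosen)
        if len(tier) <= need:
            chosen += tier
        else:
            chosen += list(rng.choice(tier, size=need, replace=False))
        if len(chosen) == n_candidates:
            break
    return [
        Item(text=w, category=probe.category, role="irrelevant",
             visual_type=probe.visual_type)
        for w in chosen
    ]


def select_irrelevants(
    candidates: list[Item],
    flagged: set[str] | None = None,
    n_select: int = 5,
    seed: int | np.random.Generator | None = None,
    max_flags: int = 2,
) -> list[Item]:
    """Randomly draw ``n_select`` task irrelevants from the unflagged candidates.

    ``flagged`` holds texts the examinee marked as personally meaningful; at
    most ``max_flags`` flags are allowed per category.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    flagged = set(flagged or ())
    if len(flagged) > max_flags:
        raise ValueError(f"at most {max_flags} flagged items allowed, got {len(flagged)}")
    unflagged = [c for c in candidates if c.text not in flagged]
    if len(unflagged) < n_select:
        raise InsufficientCandidatesError(
            f"need {n_select} unflagged candidates, only {len(unflagged)} remain"
        )
    idx = rng.choice(len(unflagged), size=n_select, replace=False)
    return [unflagged[i] for i in sorted(idx)]


def build_item_set(
    forename: str,
    birthday: tuple[int, int],
    animal: str,
    group: str = "standard",
    seed: int | np.random.Generator | None = None,
    flagged: dict[str, set[str]] | None = None,
) -> ItemSet:
    """Assemble the full 18-primary-item inventory plus secondary items.

    ``birthday`` is (month, day), 1-based.  The initial-letter filter is
    disabled for the date category (months would otherwise exhaust the pool).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    flagged = flagged or {}
    probes = {
        "forename": Item(forename.upper(), "forename", "probe"),
        "date": Item(pools.date_text(*birthday), "date", "probe", "mixed_character"),
        "animal": Item(animal.upper(), "animal", "probe"),
    }
    source = {
        "forename": pools.FORENAMES,
        "date": pools.date_pool(),
        "animal": pools.ANIMALS,
    }
    irrelevants = {}
    for cat in CATEGORIES:
        cands = build_candidate_pool(
            probes[cat], source[cat], n_candidates=8, seed=rng,
            letter_filter=(cat != "date"),
        )
        irrelevants[cat] = select_irrelevants(
            cands, flagged.get(cat, set()), n_select=5, seed=rng
        )
    if group == "standard":
        t_texts, nt_texts = pools.STANDARD_TARGETS, pools.STANDARD_NONTARGETS
    elif group == "induced":
        t_texts, nt_texts = pools.INDUCER_TARGETS, pools.INDUCER_NONTARGETS
    else:
        raise ValueError("group must be 'standard' or 'induced'")
    return ItemSet(
        probes=probes,
        irrelevants=irrelevants,
        targets=[Item(t, "secondary", "target") for t in t_texts],
        nontargets=[Item(t, "secondary", "nontarget") for t in nt_texts],
    )


# ---------------------------------------------------------------------------
# block sequence generation
# ---------------------------------------------------------------------------

def _precedence_quotas(
    primaries: list[Item], secondaries: list[Item], reps: int
) -> dict[int, int]:
    """Per (primary, secondary) precedence counts; targets half as frequent.

    Returns ``{secondary_index: quota}`` (identical for every primary item).
    """
    n_t = sum(1 for s in secondaries if s.role == "target")
    n_nt = len(secondaries) - n_t
    denom = 2 * n_nt + n_t  # in halves
    if (2 * reps) % denom:
        raise ValueError(
            f"reps={reps} does not yield integral precedence quotas for "
            f"{n_t} targets and {n_nt} nontargets"
        )
    q_nt2 = 2 * reps // denom  # nontarget quota
    if n_t and q_nt2 % 2:
        raise ValueError(
            f"reps={reps} gives non-integral target quota {q_nt2}/2"
        )
    return {
        j: (q_nt2 // 2 if s.role == "target" else q_nt2)
        for j, s in enumerate(secondaries)
    }


def _primary_order(
    primaries: list[Item], reps: int, rng: np.random.Generator
) -> list[int]:
    """reps groups, each a permutation of the primaries, no repeat across
    group boundaries."""
    n = len(primaries)
    order: list[int] = []
    prev = -1
    for _ in range(reps):
        for _attempt in range(200):
            perm = rng.permutation(n)
            if n == 1 or perm[0] != prev:
                break
        else:  # pragma: no cover - unreachable for n >= 2
            raise SequenceConstraintError("primary adjacency constraint unsatisfiable")
        order.extend(int(i) for i in perm)
        prev = order[-1]
    return order


def _assign_secondaries(
    primary_order: list[int],
    n_primary: int,
    quota_per_secondary: dict[int, int],
    rng: np.random.Generator,
    node_budget: int = 500_000,
) -> list[int] | None:
    """Backtracking assignment of secondary items to trials.

    Constraints: for each primary item, secondary ``j`` is used exactly
    ``quota_per_secondary[j]`` times; no two consecutive trials share a
    secondary item.  Returns None if the node budget is exhausted.
    """
    n_trials = len(primary_order)
    remaining = [dict(quota_per_secondary) for _ in range(n_primary)]
    assignment = [-1] * n_trials
    # stack of candidate lists (shuffled) per position
    stack: list[list[int]] = []
    pos = 0
    nodes = 0
    while pos < n_trials:
        if len(stack) == pos:
            p = primary_order[pos]
            prev = assignment[pos - 1] if pos else -1
            cands = [j for j, q in remaining[p].items() if q > 0 and j != prev]
            rng.shuffle(cands)
            stack.append(cands)
        cands = stack[pos]
        if cands:
            j = cands.pop()
            assignment[pos] = j
            remaining[primary_order[pos]][j] -= 1
            pos += 1
        else:
            stack.pop()
            pos -= 1
            if pos < 0:
                return None
            remaining[primary_order[pos]][assignment[pos]] += 1
            assignment[pos] = -1
        nodes += 1
        if nodes > node_budget:
            return None
    return assignment


def generate_block(
    item_set: ItemSet | None,
    category: str,
    reps: int = 30,
    seed: int | np.random.Generator | None = None,
    primaries: list[Item] | None = None,
    secondaries: list[Item] | None = None,
    max_restarts: int = 50,
) -> BlockSequence:
    """Generate one block of ``len(primaries) * reps`` constrained trials.

    Either pass an :class:`ItemSet` (the usual route) or explicit ``primaries``
    / ``secondaries`` lists (for degenerate or custom designs).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if primaries is None:
        assert item_set is not None
        primaries = item_set.primary_items(category)
    if secondaries is None:
        assert item_set is not None
        secondaries = [*item_set.targets, *item_set.nontargets]
    quotas = _precedence_quotas(primaries, secondaries, reps)

    for _restart in range(max_restarts):
        order = _primary_order(primaries, reps, rng)
        sec = _assign_secondaries(order, len(primaries), quotas, rng)
        if sec is not None:
            break
    else:
        raise SequenceConstraintError(
            "could not satisfy the secondary precedence/adjacency constraints "
            f"within {max_restarts} restarts"
        )

    n_trials = len(order)
    isi1 = np.round(rng.uniform(*ISI_RANGE_MS, size=n_trials))
    isi2 = np.round(rng.uniform(*ISI_RANGE_MS, size=n_trials))
    trials = [
        TrialSpec(
            trial_index=i,
            secondary_item=secondaries[sec[i]],
            primary_item=primaries[order[i]],
            isi1_ms=float(isi1[i]),
            isi2_ms=float(isi2[i]),
        )
        for i in range(n_trials)
    ]
    return BlockSequence(category=category, trials=trials)


def make_session_plan(
    item_set: ItemSet,
    group: str,
    seed: int | None = None,
    reps: int = 30,
    block_order: tuple[str, ...] | None = None,
    recall_checks_per_block: int = 3,
    recall_seed: int = 0,
) -> SessionPlan:
    """Build the 3-block session: counterbalanced block order, constrained
    blocks, and recall checks (``recall_seed`` is shared across participants,
    mirroring check positions being the same for everyone)."""
    rng = np.random.default_rng(seed)
    if block_order is None:
        from itertools import permutations
        orders = list(permutations(CATEGORIES))
        block_order = orders[rng.integers(len(orders))]
    blocks = [generate_block(item_set, cat, reps=reps, seed=rng) for cat in block_order]
    plan = SessionPlan(blocks=blocks, group=group, seed=seed)
    if recall_checks_per_block:
        plan = schedule_recall_checks(plan, recall_checks_per_block, recall_seed)
    return plan


def schedule_recall_checks(
    plan: SessionPlan, per_category: int = 3, seed: int = 0
) -> SessionPlan:
    """Mark ``per_category`` distinct trials per block for a recall check.

    Positions are a deterministic function of ``seed`` and block length only,
    so plans sharing the seed share check positions.
    """
    if per_category < 0:
        raise ValueError("per_category must be >= 0")
    new_blocks = []
    for bi, block in enumerate(plan.blocks):
        n = len(block)
        if per_category > n:
            raise ValueError(f"cannot place {per_category} checks in {n} trials")
        rng = np.random.default_rng([seed, bi])
        positions = set(rng.choice(n, size=per_category, replace=False).tolist())
        trials = [
            replace(t, recall_check_after=(i in positions))
            for i, t in enumerate(block.trials)
        ]
        new_blocks.append(BlockSequence(category=block.category, trials=trials))
    return SessionPlan(blocks=new_blocks, group=plan.group, seed=plan.seed)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    checks: dict[str, bool]
    failures: dict[str, list] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def validate_sequence(block: BlockSequence, reps: int | None = None) -> ValidationReport:
    """Check every generation postcondition on a block; report, don't raise."""
    trials = block.trials
    prim = [t.primary_item for t in trials]
    sec = [t.secondary_item for t in trials]
    uniq_prim = list(dict.fromkeys(p.text for p in prim))
    n_items = len(uniq_prim)
    checks: dict[str, bool] = {}
    failures: dict[str, list] = {}

    if reps is None:
        reps = len(trials) // max(n_items, 1)

    checks["trial_count"] = len(trials) == n_items * reps

    bad = [i for i in range(1, len(trials))
           if prim[i].text == prim[i - 1].text]
    checks["no_primary_repeat"] = not bad
    if bad:
        failures["no_primary_repeat"] = bad

    bad = [i for i in range(1, len(trials))
           if sec[i].text == sec[i - 1].text]
    checks["no_secondary_repeat"] = not bad
    if bad:
        failures["no_secondary_repeat"] = bad

    bad_groups = []
    for g in range(len(trials) // max(n_items, 1)):
        window = {p.text for p in prim[g * n_items:(g + 1) * n_items]}
        if len(window) != n_items:
            bad_groups.append(g)
    checks["complete_item_groups"] = not bad_groups
    if bad_groups:
        failures["complete_item_groups"] = bad_groups

    counts = pd.Series([p.text for p in prim]).value_counts()
    checks["primary_counts"] = bool((counts == reps).all())
    if not checks["primary_counts"]:
        failures["primary_counts"] = counts.to_dict()

    # exact precedence matrix
    sec_items = {s.text: s for s in sec}
    n_t = sum(1 for s in sec_items.values() if s.role == "target")
    n_nt = len(sec_items) - n_t
    ok = True
    offending = []
    if n_nt and reps:
        q_nt = 2 * reps / (2 * n_nt + n_t)
        pre = pd.crosstab(
            pd.Series([p.text for p in prim], name="primary"),
            pd.Series([s.text for s in sec], name="secondary"),
        )
        for s_text, s_item in sec_items.items():
            expect = q_nt / 2 if s_item.role == "target" else q_nt
            col = pre[s_text] if s_text in pre else 0
            if not np.all(col == expect):
                ok = False
                offending.append(s_text)
    checks["precedence_balance"] = ok
    if not ok:
        failures["precedence_balance"] = offending

    lo, hi = ISI_RANGE_MS
    bad = [t.trial_index for t in trials
           if not (lo <= t.isi1_ms <= hi and lo <= t.isi2_ms <= hi)]
    checks["isi_range"] = not bad
    if bad:
        failures["isi_range"] = bad

    return ValidationReport(checks=checks, failures=failures)
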