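"""IPPA and QUEST usability scoring and cohort statistics.

IPPA (Individually Prioritized Problem Assessment): each participant names
up to seven problematic daily activities and rates, per item, its importance
(1–5) and its difficulty (1–5) at baseline and again at follow-up with the
device.  The score for a phase is the mean of importance × difficulty
(range 1–25); the change score is baseline − follow-up (range −20 to +20,
because importance is fixed between phases).

QUEST (Quebec User Evaluation of Satisfaction with Assistive Technology):
1–5 satisfaction ratings on eight device characteristics; the total score is
the mean of the item scores.

The cohort statistics are a paired signed-rank (Wilcoxon) test on the
pre/follow-up scores, the paired effect size mean(change)/SD(change), and
per-participant large-effect counts (change divided by the cohort SD of
changes exceeding 0.8).

A 27-participant usability cohort of people with cervical spinal cord
lesion (levels C5–C7) is shipped as plain-text fixtures, together with its
published summary row; see :func:`load_ippa_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

QUEST_ITEMS = ("dimensions", "weight", "adjustments", "safety",
               "durability", "ease_of_use", "comfort", "effectiveness")

LEVEL_GROUPS = ("C5", "C6", "C7")

#: Threshold above which an individual standardized change counts as large.
LARGE_EFFECT = 0.8


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IppaItem:
    """One prioritized problem activity: importance and phase difficulties."""

    importance: int
    difficulty_baseline: int
    difficulty_followup: int

    def __post_init__(self):
        for name in ("importance", "difficulty_baseline", "difficulty_followup"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
                raise ValidationError(f"{name} must be an integer in [1, 5], got {v!r}")


@dataclass(frozen=True)
class IppaRecord:
    """One participant's items plus usefulness answer and neurological level."""

    id: str
    items: tuple
    q9: bool
    level: str

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        if not 1 <= len(self.items) <= 7:
            raise ValidationError("a participant names between 1 and 7 items")


@dataclass(frozen=True)
class QuestRecord:
    """One participant's eight 1–5 device-satisfaction ratings."""

    scores: dict

    def __post_init__(self):
        missing = set(QUEST_ITEMS) - set(self.scores)
        if missing:
            raise ValidationError(f"missing QUEST items: {sorted(missing)}")
        for item, v in self.scores.items():
            if not 1 <= v <= 5:
                raise ValidationError(f"QUEST item {item!r} score {v} outside [1, 5]")


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def ippa_score(items, phase: str) -> float:
    """Mean of importance × difficulty over the items, for one phase.

    The follow-up phase keeps the baseline importances and substitutes the
    with-device difficulties.
    """
    items = list(items)
    if not items:
        raise ValidationError("at least one problem item is required")
    if phase not in ("baseline", "followup"):
        raise ConfigurationError(f"unknown phase {phase!r}")
    products = [
        it.importance * (it.difficulty_baseline if phase == "baseline"
                         else it.difficulty_followup)
        for it in items
    ]
    return float(np.mean(products))


def ippa_change(baseline: float, followup: float) -> float:
    """Change score, baseline − followup; positive means the device helped."""
    for v in (baseline, followup):
        if not 1.0 <= v <= 25.0:
            raise ValidationError(f"IPPA score {v} outside [1, 25]")
    return float(baseline - followup)


def scores_from_records(records) -> pd.DataFrame:
    """Score a list of IppaRecord into the tabular (id, pre, fu, ...) layout."""
    rows = []
    for r in records:
        pre = ippa_score(r.items, "baseline")
        fu = ippa_score(r.items, "followup")
        rows.append({"id": r.id, "pre": pre, "fu": fu,
                     "change": ippa_change(pre, fu),
                     "q9": "Yes" if r.q9 else "No", "level": r.level})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def _level_group(level: str) -> str:
    token = str(level)[:2].upper()
    return token if token in LEVEL_GROUPS else "other"


def cohort_summary(records, sd_reference: float | None = None) -> dict:
    """Cohort statistics of the pre/follow-up IPPA scores.

    ``records`` is either a DataFrame with columns id, pre, fu (optionally
    change, q9, level) or a list of :class:`IppaRecord`.  When a change
    column is present its published values are used; otherwise change is
    recomputed as pre − fu.  ``sd_reference`` optionally replaces the
    computed SD of changes in the per-participant large-effect count (useful
    to reproduce counts published against a rounded summary SD).

    The Wilcoxon test is the paired signed-rank test with zero differences
    dropped and the tie-corrected normal approximation with continuity
    correction.
    """
    if not isinstance(records, pd.DataFrame):
        records = scores_from_records(records)
    df = records.copy()
    if len(df) < 2:
        raise ValidationError("cohort statistics need at least two records")
    if "change" not in df.columns:
        df["change"] = df["pre"] - df["fu"]
    change = df["change"].to_numpy(dtype=float)
    sd_change = float(np.std(change, ddof=1))
    sd_for_effect = sd_reference if sd_reference is not None else sd_change
    if np.any(df["pre"].to_numpy() != df["fu"].to_numpy()):
        wilcoxon = stats.wilcoxon(df["pre"], df["fu"], zero_method="wilcox",
                                  correction=True, method="approx")
        w_stat, w_p = float(wilcoxon.statistic), float(wilcoxon.pvalue)
    else:  # no paired difference anywhere: nothing to test
        w_stat, w_p = 0.0, 1.0
    out = {
        "n": int(len(df)),
        "mean_pre": float(df["pre"].mean()),
        "mean_fu": float(df["fu"].mean()),
        "mean_change": float(np.mean(change)),
        "sd_change": sd_change,
        "effect_size": (float(np.mean(change) / sd_change)
                        if sd_change > 0 else float("nan")),
        "n_effect_large": (int(np.sum(change / sd_for_effect > LARGE_EFFECT))
                           if sd_for_effect > 0 else 0),
        "n_positive_change": int(np.sum(change > 0)),
        "wilcoxon_statistic": w_stat,
        "wilcoxon_p": w_p,
    }
    if "q9" in df.columns:
        yes = df["q9"].astype(str).str.strip().str.lower() == "yes"
        out["q9_yes_total"] = int(yes.sum())
        if "level" in df.columns:
            groups = df["level"].map(_level_group)
            out["q9_by_level"] = {
                g: {"yes": int(yes[groups == g].sum()),
                    "total": int((groups == g).sum())}
                for g in LEVEL_GROUPS
            }
    return out


def effect_size(mean_change: float, sd_change: float) -> float:
    """Paired effect size (Cohen's d for paired data): mean / SD of change."""
    if sd_change <= 0:
        raise ValidationError("sd_change must be positive")
    return float(mean_change / sd_change)


def quest_summary(records) -> dict:
    """Per-item mean/SD and total QUEST score.

    Accepts respondent-level data (DataFrame with the eight item columns or
    a list of :class:`QuestRecord`) or an already aggregated item-statistics
    table (columns item, mean[, sd]), in which case the total is the mean of
    the published item means.  A single respondent yields undefined SDs,
    flagged with ``sd_defined = False``.
    """
    if isinstance(records, pd.DataFrame) and "mean" in records.columns:
        means = records["mean"].to_numpy(dtype=float)
        if len(means) == 0:
            raise ValidationError("empty item table")
        if np.any((means < 1) | (means > 5)):
            raise ValidationError("item means outside [1, 5]")
        items = list(records["item"]) if "item" in records.columns else list(range(len(means)))
        sds = records["sd"].tolist() if "sd" in records.columns else [None] * len(means)
        return {
            "per_item": {str(i): {"mean": float(m), "sd": None if s is None else float(s)}
                         for i, m, s in zip(items, means, sds)},
            "total": float(np.mean(means)),
            "n_respondents": None,
            "sd_defined": "sd" in records.columns,
        }
    if not isinstance(records, pd.DataFrame):
        records = list(records)
        if not records:
            raise ValidationError("no QUEST records")
        records = pd.DataFrame([r.scores for r in records])
    if records.empty:
        raise ValidationError("no QUEST records")
    bad = records[(records < 1) | (records > 5)].dropna(how="all")
    if not bad.empty:
        raise ValidationError(f"scores outside [1, 5] in rows {list(bad.index)}")
    n = len(records)
    means = records.mean()
    sds = records.std(ddof=1)
    return {
        "per_item": {c: {"mean": float(means[c]),
                         "sd": float(sds[c]) if n > 1 else None}
                     for c in records.columns},
        "total": float(means.mean()),
        "n_respondents": n,
        "sd_defined": n > 1,
    }


# ---------------------------------------------------------------------------
# Synthetic cohort generator
# ---------------------------------------------------------------------------

def make_synthetic_cohort(n: int, effect: float, seed,
                          items_per_record: int = 7) -> list:
    """Draw a synthetic IPPA cohort with a target expected mean change.

    Importances and baseline difficulties are uniform on 1–5.  Follow-up
    difficulties are reduced by a randomized scheme whose expected
    importance-weighted reduction equals ``effect`` exactly: for targets up
    to 6 each item drops to difficulty 1 with probability effect/6 (a
    uniform item has mean maximal change 6); larger targets blend in
    maximal items (importance 5, difficulty 5 → 1, change 20).  Negative
    targets mirror the construction (difficulty worsens).
    """
    if n < 2:
        raise ValidationError("need at least two records")
    if abs(effect) > 20:
        raise ValidationError("mean change cannot exceed 20 in magnitude")
    rng = np.random.default_rng(seed)
    sign = 1.0 if effect >= 0 else -1.0
    e = abs(effect)
    # w: share of forced maximal items; q: drop probability of uniform items
    if e <= 6:
        w, q = 0.0, e / 6.0
    else:
        w, q = (e - 6.0) / 14.0, 1.0
    records = []
    for i in range(n):
        items = []
        for _ in range(items_per_record):
            if rng.random() < w:
                imp, db, dfu = 5, 5, 1
            else:
                imp = int(rng.integers(1, 6))
                db = int(rng.integers(1, 6))
                dfu = 1 if rng.random() < q else db
            if sign < 0:
                db, dfu = dfu, db
            items.append(IppaItem(importance=imp, difficulty_baseline=db,
                                  difficulty_followup=dfu))
        records.append(IppaRecord(id=f"P{i + 1}", items=tuple(items),
                                  q9=bool(rng.random() < 0.5),
                                  level=str(rng.choice(LEVEL_GROUPS)) + "A"))
    return records


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture(name: str) -> pd.DataFrame:
    with resources.files("mecfes.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_ippa_fixture() -> pd.DataFrame:
    """Per-participant IPPA scores of the 27-person usability cohort."""
    return _fixture("ippa_cohort.csv")


def load_ippa_printed_summary() -> pd.DataFrame:
    """The cohort table's published summary row (means and SDs as printed).

    Kept separate because the published summary (mean change 4.6, SD 3.5)
    does not exactly match recomputation from the published per-participant
    rows (≈4.4, ≈2.7); both are surfaced rather than reconciled.
    """
    return _fixture("ippa_cohort_printed_summary.csv").set_index("stat")


def load_quest_fixture() -> pd.DataFrame:
    """Published per-item QUEST satisfaction means and SDs (item, mean, sd)."""
    return _fixture("quest_item_stats.csv")


def load_activity_fixture() -> pd.DataFrame:
    """Most frequently prioritized daily activities (descriptive only)."""
    return _fixture("activity_priorities.csv")
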