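"""Concordance triage and automated-assisted revision of a score panel.

The reader-study workflow: slides whose human scores differ by at least a
threshold (default 10 percentage points, inclusive) form the *discordant*
set; for each (slide, rater) whose score differs from the automated score by
at least the same threshold the slide is *revisited* by that rater; during
revision the rater may *rescore*, pulling toward the automated value. The
accounting distinguishes revisited (returned for review) from rescored
(actually changed) cases and reports before/after discordance with the
McNemar pair counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .concordance import mcnemar_test
from .errors import InvalidConfigError
from .synthetic import RaterProfile


@dataclass
class TriageConfig:
    """Difference threshold (percentage points) triggering discordance or a
    revisit; inclusive=True means a difference equal to the threshold
    triggers (concordant = strictly less than the threshold)."""

    threshold: float = 10.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise InvalidConfigError("threshold must be positive")

    def triggers(self, diff) -> np.ndarray | bool:
        d = np.abs(diff)
        return d >= self.threshold if self.inclusive else d > self.threshold


@dataclass
class TriageResult:
    concordant: pd.Series  # slide -> bool (only slides with >= 2 human readers)
    revisit: pd.DataFrame  # slide × rater -> bool
    config: TriageConfig

    @property
    def n_slides(self) -> int:
        return len(self.concordant)

    @property
    def n_concordant(self) -> int:
        return int(self.concordant.sum())

    @property
    def n_discordant(self) -> int:
        return int((~self.concordant).sum())

    @property
    def discordant_fraction(self) -> float:
        return self.n_discordant / self.n_slides if self.n_slides else 0.0


def classify_concordance(panel: pd.DataFrame, cfg: TriageConfig | None = None) -> pd.Series:
    """Per-slide concordance flags from a human score panel.

    A slide is discordant iff the maximum pairwise absolute difference among
    its (non-missing) human scores meets the threshold; equivalently
    max − min. Slides with fewer than two readers are excluded with a
    warning.
    """
    cfg = cfg or TriageConfig()
    counts = panel.notna().sum(axis=1)
    excluded = counts < 2
    if excluded.any():
        warnings.warn(f"{int(excluded.sum())} single-reader slide(s) excluded from triage", stacklevel=2)
    sub = panel[~excluded]
    spread = sub.max(axis=1) - sub.min(axis=1)
    return ~pd.Series(cfg.triggers(spread.to_numpy()), index=sub.index)


def flag_revisit(rater_score: float, automated_score: float, cfg: TriageConfig | None = None) -> bool:
    """Whether one rater's slide is returned for automated-assisted review."""
    cfg = cfg or TriageConfig()
    if automated_score is None or (isinstance(automated_score, float) and np.isnan(automated_score)):
        warnings.warn("missing automated score; no revisit flag", stacklevel=2)
        return False
    if rater_score is None or (isinstance(rater_score, float) and np.isnan(rater_score)):
        return False
    return bool(cfg.triggers(rater_score - automated_score))


def flag_revisits(panel: pd.DataFrame, automated: pd.Series, cfg: TriageConfig | None = None) -> pd.DataFrame:
    """Vectorized revisit flags: slide × rater boolean frame."""
    cfg = cfg or TriageConfig()
    auto = automated.reindex(panel.index)
    missing_auto = auto.isna() & panel.notna().any(axis=1)
    if missing_auto.any():
        warnings.warn(
            f"{int(missing_auto.sum())} slide(s) lack an automated score; not flagged", stacklevel=2
        )
    diff = panel.sub(auto, axis=0)
    flags = pd.DataFrame(cfg.triggers(diff.to_numpy()), index=panel.index, columns=panel.columns)
    return flags.where(panel.notna() & auto.notna().to_numpy()[:, None], False)


def triage(panel: pd.DataFrame, automated: pd.Series, cfg: TriageConfig | None = None) -> TriageResult:
    cfg = cfg or TriageConfig()
    return TriageResult(classify_concordance(panel, cfg), flag_revisits(panel, automated, cfg), cfg)


# ---------------------------------------------------------------------------
# Simulated revision
# ---------------------------------------------------------------------------


@dataclass
class RevisionOutcome:
    revised: pd.DataFrame  # slide × rater panel after revision
    changed: pd.DataFrame  # slide × rater boolean: score actually changed
    revisited: pd.DataFrame  # the triage revisit flags used


def simulate_revision(
    panel: pd.DataFrame,
    automated: pd.Series,
    profiles: Mapping[str, RaterProfile],
    triage_result: TriageResult,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.0,
) -> RevisionOutcome:
    """Simulate automated-assisted rescoring of flagged (slide, rater) cases.

    For each flagged entry, with probability q (the rater's revision_prob)
    the rater rescores to round((1 − w)·old + w·automated + ε) clamped to
    [0, 100], where w is the rater's reliance_weight and ε is optional
    Gaussian noise (sd ``noise_sd``); otherwise the old score stands.
    Unflagged entries are never altered.
    """
    rng = np.random.default_rng(seed)
    revised = panel.copy()
    flags = triage_result.revisit
    auto = automated.reindex(panel.index)
    for rater in panel.columns:
        prof = profiles[rater]
        flagged_slides = flags.index[flags[rater]]
        for slide in flagged_slides:
            if rng.random() >= prof.revision_prob:
                continue
            old = panel.at[slide, rater]
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            new = (1.0 - prof.reliance_weight) * old + prof.reliance_weight * auto.at[slide] + eps
            revised.at[slide, rater] = float(np.clip(np.round(new), 0.0, 100.0))
    changed = revised.ne(panel) & panel.notna()
    return RevisionOutcome(revised, changed, flags.copy())


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------


@dataclass
class AccountingReport:
    per_rater: pd.DataFrame  # n_evaluated, n_revisited, revisit_rate_pct, n_changed, change_rate_pct
    unique_revisited: int
    unique_revisited_pct: float
    multiplicity_strata: dict[int, int]  # raters-per-slide -> slide count (flagged slides only)
    n_slides: int
    discordant_before: int
    discordant_after: int
    discordant_before_pct: float
    discordant_after_pct: float
    mcnemar_b: int  # discordant before -> concordant after
    mcnemar_c: int  # concordant before -> discordant after
    mcnemar_p: float


def unique_from_strata(strata: Mapping[int, int]) -> int:
    """Unique revisited slides implied by multiplicity strata (slides
    reviewed by exactly k raters, k ≥ 1): the plain sum of the strata."""
    if any(k < 1 or v < 0 for k, v in strata.items()):
        raise ValueError("strata require k >= 1 raters and counts >= 0")
    return int(sum(strata.values()))


def percent(k: float, n: float) -> float:
    """100·k/n, the rate convention used throughout the accounting."""
    if n <= 0:
        return 0.0
    return 100.0 * k / n


def revision_accounting(
    triage_result: TriageResult,
    outcome: RevisionOutcome,
    panel: pd.DataFrame,
    cfg: TriageConfig | None = None,
) -> AccountingReport:
    """Revisited/rescored accounting and before/after discordance.

    Per-rater revisit rates are relative to the number of slides that rater
    evaluated; change (rescore) rates are relative to that rater's revisited
    slides (0 with an n = 0 annotation when nothing was flagged).
    """
    cfg = cfg or triage_result.config
    flags = outcome.revisited
    rows = []
    for rater in panel.columns:
        n_eval = int(panel[rater].notna().sum())
        n_rev = int(flags[rater].sum())
        n_chg = int(outcome.changed[rater].sum())
        rows.append(
            {
                "rater": rater,
                "n_evaluated": n_eval,
                "n_revisited": n_rev,
                "revisit_rate_pct": percent(n_rev, n_eval),
                "n_changed": n_chg,
                "change_rate_pct": percent(n_chg, n_rev),
            }
        )
    per_rater = pd.DataFrame(rows).set_index("rater")

    per_slide_mult = flags.sum(axis=1)
    flagged = per_slide_mult[per_slide_mult > 0]
    strata = {int(k): int(v) for k, v in flagged.value_counts().sort_index().items()}
    unique = int(len(flagged))
    assert unique == unique_from_strata(strata) if strata else unique == 0

    before = triage_result.concordant
    after = classify_concordance(outcome.revised, cfg)
    common = before.index.intersection(after.index)
    b = int(((~before[common]) & after[common]).sum())
    c = int((before[common] & ~after[common]).sum())
    n_slides = len(common)
    return AccountingReport(
        per_rater=per_rater,
        unique_revisited=unique,
        unique_revisited_pct=percent(unique, n_slides),
        multiplicity_strata=strata,
        n_slides=n_slides,
        discordant_before=int((~before[common]).sum()),
        discordant_after=int((~after[common]).sum()),
        discordant_before_pct=percent(int((~before[common]).sum()), n_slides),
        discordant_after_pct=percent(int((~after[common]).sum()), n_slides),
        mcnemar_b=b,
        mcnemar_c=c,
        mcnemar_p=mcnemar_test(b, c),
    )


def strata_summary(strata: Mapping[int, int], n_cohort: int) -> dict:
    """Summarize printed multiplicity strata: unique revisited slides and
    their percentage of an ``n_cohort``-slide cohort."""
    unique = unique_from_strata(strata)
    return {"unique_revisited": unique, "unique_revisited_pct": percent(unique, n_cohort)}
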