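"""Burnout-survey scoring, response definition, and responder categories.

A survey presents 10 burnout items on a 0-4 Likert scale. The burnout
score is the mean of the answered items rescaled to 0-10 (x2.5); a score
of at least 3.325 flags burnout symptoms. An invitation counts as a
*response* when at least 4 of the 10 items were answered; that single
rule defines "response" everywhere downstream (responder categories,
propensity outcome, prevalence denominators).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError

#: Number of burnout items in the instrument.
N_ITEMS = 10
#: Maximum Likert value of one item.
ITEM_MAX = 4
#: Items are rescaled from the 0-4 mean to a 0-10 score.
SCALE_FACTOR = 2.5
#: Scores at or above this value indicate burnout symptoms.
BURNOUT_THRESHOLD = 3.325
#: Minimum number of answered items for an invitation to count as a response.
MIN_ITEMS_FOR_RESPONSE = 4

ITEM_COLUMNS = [f"item_{i}" for i in range(N_ITEMS)]

CATEGORY_NEVER = "never"
CATEGORY_PARTIAL = "partial"
CATEGORY_ALWAYS = "always"


@dataclass(frozen=True)
class BurnoutScore:
    """Scored burnout battery for one invitation.

    ``score`` and ``burnout`` are defined iff ``is_response``.
    """

    score: Optional[float]
    is_response: bool
    burnout: Optional[bool]

    def __post_init__(self) -> None:
        if self.is_response:
            if self.score is None:
                raise ValidationError("score must be defined for a response")
        elif self.score is not None or self.burnout is not None:
            raise ValidationError("score/burnout must be undefined for a nonresponse")


def _validate_items(items: Sequence) -> list:
    if len(items) != N_ITEMS:
        raise ValidationError(
            f"expected {N_ITEMS} items, got {len(items)}"
        )
    cleaned = []
    for idx, val in enumerate(items):
        if val is None or (isinstance(val, float) and math.isnan(val)):
            cleaned.append(None)
            continue
        fval = float(val)
        if not fval.is_integer() or not (0 <= fval <= ITEM_MAX):
            raise ValidationError(
                f"item {idx} has value {val!r}, expected an integer in 0-{ITEM_MAX}"
            )
        cleaned.append(int(fval))
    return cleaned


def is_burnout(score: float) -> bool:
    """Dichotomize a 0-10 burnout score; exact at the 3.325 boundary."""
    return bool(score >= BURNOUT_THRESHOLD)


def score_pfi_burnout(items: Sequence) -> BurnoutScore:
    """Score one 10-item burnout battery.

    Parameters
    ----------
    items : sequence of length 10
        Item values in {0,...,4}; ``None``/NaN marks an unanswered item.

    Returns
    -------
    BurnoutScore
        ``is_response`` is true iff >=4 items were answered; then
        ``score`` is the mean of answered items times 2.5 and ``burnout``
        is ``score >= 3.325``.
    """
    cleaned = _validate_items(items)
    answered = [v for v in cleaned if v is not None]
    if len(answered) < MIN_ITEMS_FOR_RESPONSE:
        return BurnoutScore(score=None, is_response=False, burnout=None)
    score = float(np.mean(answered)) * SCALE_FACTOR
    return BurnoutScore(score=score, is_response=True, burnout=is_burnout(score))


def score_records(records: pd.DataFrame) -> pd.DataFrame:
    """Score every invitation in a records table.

    ``records`` must have columns ``physician_id``, ``wave`` and
    ``item_0`` .. ``item_9`` (NaN = unanswered). Returns one row per
    invitation with columns ``physician_id, wave, n_answered,
    is_response, score, burnout``.
    """
    items = records[ITEM_COLUMNS].to_numpy(dtype=float)
    finite = np.isfinite(items)
    bad = finite & ((items < 0) | (items > ITEM_MAX) | (items != np.round(items)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"record {r}: item {c} has value {items[r, c]!r}, "
            f"expected an integer in 0-{ITEM_MAX}"
        )
    n_answered = finite.sum(axis=1)
    is_response = n_answered >= MIN_ITEMS_FOR_RESPONSE
    sums = np.where(finite, items, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / n_answered
    score = np.where(is_response, means * SCALE_FACTOR, np.nan)
    burnout = np.where(is_response, score >= BURNOUT_THRESHOLD, np.nan)
    return pd.DataFrame(
        {
            "physician_id": records["physician_id"].to_numpy(),
            "wave": records["wave"].to_numpy(),
            "n_answered": n_answered,
            "is_response": is_response,
            "score": score,
            "burnout": burnout,
        }
    )


def categorize_responder(
    invited_waves: Iterable[int], responded_waves: Iterable[int]
) -> str:
    """Categorize one physician from invited and responded wave sets.

    never: zero responses; always: responses == invitations; partial:
    invited twice, responded exactly once.
    """
    invited = set(invited_waves)
    responded = set(responded_waves)
    if not invited:
        raise DomainError("physician has zero invitations")
    if not responded <= invited:
        raise ValidationError("responded waves must be a subset of invited waves")
    if not responded:
        return CATEGORY_NEVER
    if responded == invited:
        return CATEGORY_ALWAYS
    return CATEGORY_PARTIAL


def categorize_cohort(scores: pd.DataFrame) -> pd.Series:
    """Responder category per physician from a scored invitation table."""
    grouped = scores.groupby("physician_id")["is_response"]
    n_inv = grouped.size()
    n_resp = grouped.sum()
    out = pd.Series(CATEGORY_PARTIAL, index=n_inv.index, name="category")
    out[n_resp == 0] = CATEGORY_NEVER
    out[n_resp == n_inv] = CATEGORY_ALWAYS
    return out


def summarize_invitations(scores: pd.DataFrame) -> Mapping[str, float]:
    """Invitation-accounting summary for a scored cohort.

    Returns unique-physician, invitation and response counts plus the
    response rate as a percentage of administered surveys.
    """
    n_physicians = int(scores["physician_id"].nunique())
    n_invitations = int(len(scores))
    n_responses = int(scores["is_response"].sum())
    rate = 100.0 * n_responses / n_invitations if n_invitations else float("nan")
    return {
        "n_physicians": n_physicians,
        "n_invitations": n_invitations,
        "n_responses": n_responses,
        "response_rate_pct": rate,
    }
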