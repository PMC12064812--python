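"""Trial-level behavioral coding.

Compound insight scoring (suddenness + emotion + certainty, range 3-12),
per-subject median split into high/low insight classes, solution-time
trial filters, the three-gate compound subsequent-memory code,
misclassification estimation for the four-alternative response format,
chance adjustment of accuracy/memory proportions, and the recognition
false-alarm rate.
"""

from __future__ import annotations

import logging
import numbers

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "insight_composite",
    "median_split_insight",
    "filter_trials",
    "code_subsequent_memory",
    "estimate_misclassification",
    "chance_adjust",
    "false_alarm_rate",
    "RT_MIN",
    "RT_MAX",
]

#: Solved trials faster than this are treated as pure object recognition
#: (no insight component) and excluded.
RT_MIN = 1.5
#: Solved trials later than this are confounded by stimulus offset and
#: excluded.
RT_MAX = 9.5

_OLD_RESPONSES = {"definitely old", "probably old"}
_SOLVED_RESPONSES = {"definitely solved", "probably solved"}


def _check_rating(value, name: str) -> int:
    if isinstance(value, numbers.Real) and not isinstance(value, bool):
        iv = int(value)
        if iv == value and 1 <= iv <= 4:
            return iv
    raise ValueError(f"{name} rating must be an integer in 1..4, got {value!r}")


def insight_composite(suddenness, emotion, certainty) -> int:
    """Compound insight score: the sum of the three 4-point ratings.

    Returns an integer in [3, 12]. Symmetric and strictly monotone in
    each rating.
    """
    return (
        _check_rating(suddenness, "suddenness")
        + _check_rating(emotion, "emotion")
        + _check_rating(certainty, "certainty")
    )


def median_split_insight(table: pd.DataFrame) -> pd.DataFrame:
    """Label solved trials HI-I / LO-I by a per-subject median split.

    The split median is each subject's median compound insight over their
    solved (rated) trials; trials strictly above it are ``HI-I``, trials
    at or below it ``LO-I``. Unsolved trials are labeled ``unsolved``.
    Subjects with fewer than two solved trials cannot be split and get
    ``n/a`` with a warning.

    Returns a copy of the table with an ``insight_class`` column.
    """
    out = table.copy()
    out["insight_class"] = "unsolved"
    solved = out["solved"].astype(bool)
    for subject, sdf in out[solved].groupby("subject_id"):
        if len(sdf) < 2:
            logger.warning(
                "subject %s has < 2 solved trials; insight_class set to n/a",
                subject,
            )
            out.loc[sdf.index, "insight_class"] = "n/a"
            continue
        med = sdf["insight"].median()
        out.loc[sdf.index, "insight_class"] = np.where(
            sdf["insight"] > med, "HI-I", "LO-I"
        )
    return out


def filter_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Remove solved trials with out-of-window solution times.

    Solved trials faster than 1.5 s or slower than 9.5 s are dropped;
    unsolved trials are always retained. Idempotent. Retained counts per
    condition are logged.
    """
    solved = table["solved"].astype(bool)
    rt = table["solution_time"]
    drop = solved & ((rt < RT_MIN) | (rt > RT_MAX))
    kept = table.loc[~drop].copy()
    if "insight_class" in kept.columns:
        counts = kept.groupby("insight_class").size().to_dict()
    else:
        counts = {"solved": int(kept["solved"].sum()),
                  "unsolved": int((~kept["solved"].astype(bool)).sum())}
    logger.info(
        "filter_trials: removed %d of %d trials; retained per condition: %s",
        int(drop.sum()), len(table), counts,
    )
    return kept


def code_subsequent_memory(record) -> str:
    """Three-gate compound subsequent-memory code for one trial.

    A correctly solved item counts as *remembered* only if (1) the image
    was recognized as old (definitely/probably old), (2) reported as
    having been solved in the scanner (definitely/probably solved), and
    (3) the hidden object was correctly named. Anything else — including
    a confident but wrong recollection — is *forgotten*.

    ``record`` is any mapping (or namedtuple / Series) with fields
    ``correct``, ``recognition_response``, ``solved_memory_response``,
    ``recalled_name_correct``.
    """
    get = (record.get if hasattr(record, "get")
           else lambda k: getattr(record, k))
    if not bool(get("correct")):
        raise ValueError(
            "subsequent memory is defined only for correctly solved trials"
        )
    if str(get("recognition_response")).strip().lower() not in _OLD_RESPONSES:
        return "forgotten"
    if str(get("solved_memory_response")).strip().lower() not in _SOLVED_RESPONSES:
        return "forgotten"
    return "remembered" if bool(get("recalled_name_correct")) else "forgotten"


def _check_proportion(x, name: str) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be a proportion in [0, 1], got {x}")
    return x


def estimate_misclassification(p_aligned_correct, p_no_category) -> float:
    """Probability that an incorrect response is falsely scored correct.

    With a four-alternative category response, a wrong solution can be
    scored correct either because the wrong word happens to align with
    the correct category (``p_aligned_correct``) or because a response
    matching no category is a random guess with a 1-in-4 chance of
    landing on the correct one (``0.25 * p_no_category``).
    """
    a = _check_proportion(p_aligned_correct, "p_aligned_correct")
    b = _check_proportion(p_no_category, "p_no_category")
    if a + b > 1.0 + 1e-12:
        raise ValueError("proportions sum to more than 1")
    return a + 0.25 * b


def chance_adjust(raw_proportion, p_false) -> float:
    """Scale a raw correct/remembered proportion by (1 - p_false)."""
    raw = _check_proportion(raw_proportion, "raw_proportion")
    pf = _check_proportion(p_false, "p_false")
    return raw * (1.0 - pf)


def false_alarm_rate(new_item_responses) -> float:
    """Fraction of never-seen foil items called old.

    ``new_item_responses`` is an iterable (or Series) of recognition
    responses for one subject's foil items; "definitely old" and
    "probably old" count as false alarms.
    """
    responses = [str(r).strip().lower() for r in new_item_responses]
    if len(responses) == 0:
        raise ValueError("no new-item responses supplied")
    return sum(r in _OLD_RESPONSES for r in responses) / len(responses)
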