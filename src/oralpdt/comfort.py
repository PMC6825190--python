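"""Comfort-survey summaries for the applicator ergonomics study.

After wearing each applicator for ten minutes, subjects rated three
questions on an ordinal 1-5 scale (1 = no discomfort, 5 = intolerable):
physical discomfort, fatigue/numbness, and willingness to immediately repeat
the session (repeatability). This module validates the response table and
produces per-position, per-question means, sample SDs, score histograms and
"no tolerance" (score 5) counts.

Because individual responses in such studies are often published only as
mean +/- SD, :func:`reconstruct_score_multisets` searches exhaustively over
all integer score multisets of a given size for those consistent with a
printed summary — useful for feasibility checks and for rebuilding test
inputs from published summaries (such reconstructions are derived, not
ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyGroupError, InsufficientDataError, SurveyValidationError
from .stability import Position


class Question(str, Enum):
    DISCOMFORT = "discomfort"
    FATIGUE = "fatigue"
    REPEATABILITY = "repeatability"


_REQUIRED_COLUMNS = ["subject_id", "position", "question", "score"]


@dataclass
class ComfortSurvey:
    """Validated long-format survey table: one row per response."""

    records: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return self.records["subject_id"].nunique()

    def __len__(self) -> int:
        return len(self.records)

    def scores(self, position: Position | str, question: Question | str) -> np.ndarray:
        sel = self.records[
            (self.records["position"] == Position(position).value)
            & (self.records["question"] == Question(question).value)
        ]
        return sel["score"].to_numpy(int)


@dataclass
class ComfortSummary:
    """Summary of one (position, question) group on the 1-5 scale."""

    position: Position
    question: Question
    n: int
    mean: float
    sd: float                   # sample SD (n-1)
    level_counts: dict[int, int]   # histogram over scores 1..5
    n_no_tolerance: int         # responses at the intolerable end (score 5)


def load_survey(table: pd.DataFrame | str | Path) -> ComfortSurvey:
    """Validate a survey table (DataFrame or CSV path) into a ComfortSurvey.

    Rejects missing columns, unknown positions/questions, non-integer or
    out-of-range scores, and duplicated (subject, position, question) rows —
    each error names the offending row.
    """
    df = pd.read_csv(table) if isinstance(table, (str, Path)) else table.copy()
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyValidationError(f"survey table missing columns {sorted(missing)}")
    df = df[_REQUIRED_COLUMNS].copy()

    valid_positions = {p.value for p in Position}
    valid_questions = {q.value for q in Question}
    for i, row in enumerate(df.itertuples(index=False)):
        if row.position not in valid_positions:
            raise SurveyValidationError(f"row {i}: unknown position {row.position!r}")
        if row.question not in valid_questions:
            raise SurveyValidationError(f"row {i}: unknown question {row.question!r}")
        score = row.score
        if not float(score).is_integer() or not 1 <= int(score) <= 5:
            raise SurveyValidationError(
                f"row {i}: score {score!r} is not an integer in [1, 5]")
    df["score"] = df["score"].astype(int)

    dup = df.duplicated(subset=["subject_id", "position", "question"])
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0])
        raise SurveyValidationError(
            f"row {first}: duplicate (subject, position, question) response")
    return ComfortSurvey(df.reset_index(drop=True))


def summarize_scores(survey: ComfortSurvey, position: Position | str,
                     question: Question | str) -> ComfortSummary:
    """Mean, sample SD, level histogram and score-5 count for one group."""
    scores = survey.scores(position, question)
    if len(scores) == 0:
        raise EmptyGroupError(
            f"no responses for ({Position(position).value}, {Question(question).value})")
    if len(scores) < 2:
        raise InsufficientDataError("need >= 2 responses for a sample SD")
    counts = {level: int((scores == level).sum()) for level in range(1, 6)}
    return ComfortSummary(
        position=Position(position), question=Question(question),
        n=len(scores),
        mean=float(scores.mean()),
        sd=float(np.std(scores, ddof=1)),
        level_counts=counts,
        n_no_tolerance=counts[5],
    )


def summarize_all(survey: ComfortSurvey) -> pd.DataFrame:
    """Every (position, question) summary present in the survey, as a table."""
    rows = []
    for position in Position:
        for question in Question:
            if len(survey.scores(position, question)) == 0:
                continue
            s = summarize_scores(survey, position, question)
            rows.append({
                "position": position.value, "question": question.value,
                "n": s.n, "mean": s.mean, "sd": s.sd,
                "n_no_tolerance": s.n_no_tolerance,
            })
    return pd.DataFrame(rows)


def _printed_decimals(x: float, cap: int = 3) -> int:
    """Number of decimal places in the shortest decimal form of ``x``."""
    text = repr(float(x))
    return min(len(text.split(".")[1]), cap) if "." in text else 0


def reconstruct_score_multisets(mean: float, sd: float, n: int = 10,
                                decimals: int | None = None) -> list[tuple[int, ...]]:
    """All integer 1-5 score multisets of size ``n`` matching (mean, sd).

    Exhaustive search over score multisets; a match reproduces the rounded
    mean and sample SD at the precision each value was supplied with (its
    printed decimal places, overridable via ``decimals``). Returns multisets
    in lexicographic order (possibly empty when the printed pair is
    infeasible). For n = 10 there are only 1001 candidates, so this is
    instant.
    """
    mean_dec = decimals if decimals is not None else _printed_decimals(mean)
    sd_dec = decimals if decimals is not None else _printed_decimals(sd)
    matches = []
    for combo in combinations_with_replacement(range(1, 6), n):
        arr = np.array(combo, dtype=float)
        if (round(float(arr.mean()), mean_dec) == round(mean, mean_dec)
                and round(float(arr.std(ddof=1)), sd_dec) == round(sd, sd_dec)):
            matches.append(combo)
    return matches


def survey_from_summaries(summaries: dict[tuple[str, str], tuple[float, float]],
                          n: int = 10) -> ComfortSurvey:
    """Build a synthetic survey whose groups reproduce printed (mean, sd) pairs.

    For each (position, question) -> (mean, sd) entry the lexicographically
    smallest consistent score multiset is assigned to subjects S01..Snn.
    Raises if any summary is infeasible for ordinal 1-5 scores of size n.
    The result is a *reconstruction* for testing and demonstration, not the
    original raw data.
    """
    rows = []
    for (position, question), (mean, sd) in summaries.items():
        multisets = reconstruct_score_multisets(mean, sd, n=n)
        if not multisets:
            raise SurveyValidationError(
                f"no integer score multiset of size {n} matches "
                f"{mean} +/- {sd} for ({position}, {question})")
        for subject, score in zip(range(1, n + 1), multisets[0]):
            rows.append({"subject_id": f"S{subject:02d}",
                         "position": Position(position).value,
                         "question": Question(question).value,
                         "score": int(score)})
    return load_survey(pd.DataFrame(rows))
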