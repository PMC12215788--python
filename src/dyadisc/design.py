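"""Dyad-level design construction.

Participant-level sharing ratings (1-5) are binarized (1-2 low, >=3 high)
and combined per dyad into the three sharing categories LL / LH / HH; age,
gender and country similarity covariates are attached per dyad.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from dyadisc.exceptions import SchemaError

#: Ratings >= this value count as "high" sharing likelihood.
HIGH_THRESHOLD = 3

DESIGN_COLUMNS = [
    "subject_a",
    "subject_b",
    "video",
    "sharing_category",
    "age_similarity",
    "gender_match",
    "country_match",
]


def all_dyads(subjects: Iterable[str]) -> list[tuple[str, str]]:
    """All unordered subject pairs, each stored lexicographically ordered."""
    uniq = sorted(set(subjects))
    return list(combinations(uniq, 2))


def binarize_rating(rating: int, threshold: int = HIGH_THRESHOLD) -> str:
    """Map a 1-5 rating to 'low' (< threshold) or 'high' (>= threshold)."""
    if rating not in (1, 2, 3, 4, 5):
        raise SchemaError(f"rating must be an integer in 1..5, got {rating!r}")
    return "high" if rating >= threshold else "low"


def dyad_sharing_category(a: str, b: str) -> str:
    """Symmetric dyad category: LL, HH, or LH for mixed pairs."""
    levels = {"low", "high"}
    if a not in levels or b not in levels:
        raise SchemaError(f"levels must be 'low'/'high', got ({a!r}, {b!r})")
    if a == b:
        return "HH" if a == "high" else "LL"
    return "LH"


def age_similarity(
    ages: Mapping[str, float], dyads: Sequence[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Per-dyad age similarity: 1 - |age_a - age_b| / max over dyads |diff|.

    The maximum is taken over the supplied (retained) dyads, so values are
    cohort-relative. If every dyad has identical ages the division guard
    returns 1.0 for all dyads with a warning.
    """
    missing = sorted({s for d in dyads for s in d if s not in ages})
    if missing:
        raise SchemaError(f"subjects missing from age table: {missing}")
    diffs = {d: abs(float(ages[d[0]]) - float(ages[d[1]])) for d in dyads}
    max_diff = max(diffs.values(), default=0.0)
    if max_diff == 0.0:
        warnings.warn(
            "all dyads have identical ages; age similarity set to 1.0",
            stacklevel=2,
        )
        return {d: 1.0 for d in dyads}
    return {d: 1.0 - diff / max_diff for d, diff in diffs.items()}


def match_indicator(attr_a: str, attr_b: str) -> int:
    """1 if the two categorical labels are exactly equal, else 0.

    Comparison is case-sensitive; a case-insensitive match that fails the
    strict comparison triggers a normalization warning.
    """
    if attr_a is None or attr_b is None or attr_a == "" or attr_b == "":
        raise SchemaError("match_indicator requires non-missing labels")
    if attr_a == attr_b:
        return 1
    if str(attr_a).lower() == str(attr_b).lower():
        warnings.warn(
            f"labels {attr_a!r} and {attr_b!r} differ only by case; "
            f"treated as non-matching (normalize labels upstream if unintended)",
            stacklevel=2,
        )
    return 0


def build_dyad_design(
    ratings: pd.DataFrame,
    attrs: pd.DataFrame,
    dyads: Sequence[tuple[str, str]] | None = None,
    threshold: int = HIGH_THRESHOLD,
) -> pd.DataFrame:
    """One design row per (dyad, video) where both members rated the video.

    Parameters
    ----------
    ratings : table with columns subject, video, rating (integers 1-5)
    attrs : table with columns subject, age, gender, country
    dyads : optional explicit dyad list; defaults to all pairs of subjects
        appearing in `ratings`.
    """
    for col in ("subject", "video", "rating"):
        if col not in ratings.columns:
            raise SchemaError(f"ratings table missing column {col!r}")
    for col in ("subject", "age", "gender", "country"):
        if col not in attrs.columns:
            raise SchemaError(f"attributes table missing column {col!r}")
    if attrs["subject"].duplicated().any():
        dup = sorted(attrs.loc[attrs["subject"].duplicated(), "subject"])
        raise SchemaError(f"duplicate subjects in attributes: {dup}")

    if len(ratings) == 0:
        return pd.DataFrame(columns=DESIGN_COLUMNS)

    if dyads is None:
        dyads = all_dyads(ratings["subject"].unique())
    dyads = [tuple(sorted(d)) for d in dyads]

    attr_map = attrs.set_index("subject")
    dangling = sorted(
        {s for d in dyads for s in d if s not in attr_map.index}
    )
    if dangling:
        raise SchemaError(f"dyad subjects missing from attributes: {dangling}")

    ages = attr_map["age"].to_dict()
    sim = age_similarity(ages, dyads)

    # participant-level binarized label per (subject, video)
    level = {
        (row.subject, row.video): binarize_rating(int(row.rating), threshold)
        for row in ratings.itertuples()
    }

    videos = sorted(ratings["video"].unique())
    rows = []
    with warnings.catch_warnings():
        # case-mismatch warnings are surfaced once per pair at most
        warnings.simplefilter("once")
        for a, b in dyads:
            g = match_indicator(str(attr_map.at[a, "gender"]), str(attr_map.at[b, "gender"]))
            c = match_indicator(str(attr_map.at[a, "country"]), str(attr_map.at[b, "country"]))
            s = sim[(a, b)]
            for video in videos:
                la = level.get((a, video))
                lb = level.get((b, video))
                if la is None or lb is None:
                    continue
                rows.append(
                    (a, b, video, dyad_sharing_category(la, lb), s, g, c)
                )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)
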