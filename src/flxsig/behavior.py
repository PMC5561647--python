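"""Composite behavioral emotionality scoring and fluoxetine-response classification.

A three-test battery — elevated plus maze (EPM), novelty suppressed feeding
(NSF) and splash test (ST) — is collapsed into a single per-animal
*emotionality* z-score.  Each raw measure is standardized against the vehicle
control group of the same session, ``z = sign * (x - mu) / sigma``, where the
sign makes larger z always mean *higher* emotionality (less open-arm activity,
longer feeding latency, less grooming).  Measure z-scores are averaged within
each test and the three per-test means are averaged again, so every test
carries equal weight regardless of how many measures it contributes.

Fluoxetine-treated animals whose emotionality score drops by at least 50%
between the pre- and post-treatment sessions are classified as responders,
mirroring the clinical definition of antidepressant response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateReferenceError, MissingDataError

# canonical arm labels
VEH_V = "VEH/V"
CORT_V = "CORT/V"
CORT_FLX = "CORT/Flx"
ARMS = (VEH_V, CORT_V, CORT_FLX)

# proteomic group labels for the selected animals
GROUP_CORT = "CORT/V"
GROUP_R = "Flx-R"
GROUP_NR = "Flx-NR"

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
NOT_APPLICABLE = "not_applicable"

ID_COLS = ["animal_id", "group", "session"]


@dataclass(frozen=True)
class DirectionConvention:
    """Sign and test assignment for each scored behavioral measure.

    ``signs[m] = +1`` when a larger raw value means higher emotionality
    (NSF latency), ``-1`` when a larger value means lower emotionality
    (open-arm time/entries, grooming).  ``unscored`` measures (home-cage food
    consumption, the appetite confound control) never enter the composite.
    """

    signs: Mapping[str, int] = field(
        default_factory=lambda: {
            "epm_open_time_s": -1,
            "epm_open_entries": -1,
            "nsf_latency_s": +1,
            "st_grooming_s": -1,
        }
    )
    tests: Mapping[str, str] = field(
        default_factory=lambda: {
            "epm_open_time_s": "EPM",
            "epm_open_entries": "EPM",
            "nsf_latency_s": "NSF",
            "st_grooming_s": "ST",
        }
    )
    unscored: Sequence[str] = ("nsf_food_mg_per_g",)

    def __post_init__(self) -> None:
        if set(self.signs) != set(self.tests):
            raise ConfigurationError("every scored measure needs exactly one sign and one test")
        for m, s in self.signs.items():
            if s not in (-1, 1):
                raise ConfigurationError(f"sign for {m!r} must be +1 or -1, got {s!r}")

    @property
    def measures(self) -> list[str]:
        return list(self.signs)

    @property
    def test_names(self) -> list[str]:
        return sorted(set(self.tests.values()))


def zscore_measures(
    records: pd.DataFrame,
    control_group: str = VEH_V,
    convention: DirectionConvention | None = None,
) -> pd.DataFrame:
    """Standardize each scored measure against the same-session control group.

    Returns a copy of the identifier columns plus one ``z_<measure>`` column
    per scored measure.  The control group must contribute at least two
    animals per session and a nonzero standard deviation (unbiased, n-1) for
    every scored measure; otherwise a :class:`DegenerateReferenceError` is
    raised naming the offending measure.  Missing values raise
    :class:`MissingDataError` — measures are never silently imputed.
    """
    convention = convention or DirectionConvention()
    for col in ID_COLS:
        if col not in records.columns:
            raise MissingDataError(f"records table lacks required column {col!r}")
    for m in convention.measures:
        if m not in records.columns:
            raise MissingDataError(f"records table lacks measure column {m!r}")
        if records[m].isna().any():
            bad = records.loc[records[m].isna(), "animal_id"].tolist()
            raise MissingDataError(f"measure {m!r} missing for animals {bad}")

    out = records[ID_COLS].copy()
    for session, idx in records.groupby("session").groups.items():
        block = records.loc[idx]
        ctrl = block[block["group"] == control_group]
        if len(ctrl) < 2:
            raise DegenerateReferenceError(
                f"control group {control_group!r} has {len(ctrl)} animals in session {session}; need >= 2"
            )
        for m in convention.measures:
            mu = ctrl[m].mean()
            sigma = ctrl[m].std(ddof=1)
            if sigma == 0 or not np.isfinite(sigma):
                raise DegenerateReferenceError(
                    f"control sigma for measure {m!r} in session {session} is zero/non-finite"
                )
            out.loc[idx, f"z_{m}"] = convention.signs[m] * (block[m] - mu) / sigma
    return out


def emotionality(
    z_table: pd.DataFrame, convention: DirectionConvention | None = None
) -> pd.DataFrame:
    """Two-stage average: per-measure z -> per-test z -> composite emotionality.

    Output columns: identifiers, one ``z_<TEST>`` per behavioral test and the
    ``emotionality`` composite (unweighted mean of the per-test means).
    """
    convention = convention or DirectionConvention()
    out = z_table[ID_COLS].copy()
    per_test = {}
    for test in convention.test_names:
        members = [f"z_{m}" for m, t in convention.tests.items() if t == test]
        missing = [c for c in members if c not in z_table.columns]
        if missing or not members:
            raise MissingDataError(f"test {test!r} has no scored measure columns {missing}")
        per_test[test] = z_table[members].mean(axis=1)
        out[f"z_{test}"] = per_test[test]
    out["emotionality"] = pd.concat(per_test, axis=1).mean(axis=1)
    return out


def responder_rate(n_responders: int, n_treated: int) -> float:
    """Cohort responder rate as a percentage rounded to one decimal."""
    if n_treated <= 0 or n_responders < 0 or n_responders > n_treated:
        raise ConfigurationError("need 0 <= n_responders <= n_treated with n_treated > 0")
    return round(100.0 * n_responders / n_treated, 1)


@dataclass
class ResponseClassification:
    """Per-animal response labels plus the cohort responder rate (percent)."""

    labels: pd.DataFrame
    responder_rate_pct: float


def classify_response(
    scores: pd.DataFrame,
    cutoff: float = 0.5,
    treated_group: str = CORT_FLX,
    baseline_floor: float = 0.0,
    ambiguity_band: float = 0.0,
    na_in_denominator: bool = True,
) -> ResponseClassification:
    """Label treated animals responder/non-responder by the 50%-decrease rule.

    ``relative_change = (pre - post) / pre`` over the two sessions; an animal
    is a responder iff ``relative_change >= cutoff`` and its pre-treatment
    score exceeds ``baseline_floor`` (the relative rule is ill-defined at or
    below zero; such animals are labeled ``not_applicable``).  An optional
    ``ambiguity_band`` (full width, default off) marks animals whose relative
    change falls within ``cutoff +/- band/2`` as ``not_applicable`` as well.

    ``na_in_denominator=True`` keeps not-applicable animals in the cohort-rate
    denominator (as non-response), so the rate is responders over all treated
    animals.
    """
    if not 0 < cutoff < 1:
        raise ConfigurationError(f"cutoff must be in (0, 1), got {cutoff}")
    treated = scores[scores["group"] == treated_group]
    pre = treated[treated["session"] == 1].set_index("animal_id")["emotionality"]
    post = treated[treated["session"] == 2].set_index("animal_id")["emotionality"]
    both = sorted(set(pre.index) & set(post.index))
    missing = sorted(set(pre.index) ^ set(post.index))
    if missing:
        raise MissingDataError(f"treated animals missing a session: {missing}")

    rows = []
    for aid in both:
        p0, p1 = float(pre[aid]), float(post[aid])
        if p0 <= baseline_floor:
            rel = np.nan
            label = NOT_APPLICABLE
        else:
            rel = (p0 - p1) / p0
            if ambiguity_band > 0 and abs(rel - cutoff) < ambiguity_band / 2:
                label = NOT_APPLICABLE
            else:
                label = RESPONDER if rel >= cutoff else NON_RESPONDER
        rows.append(
            {
                "animal_id": aid,
                "label": label,
                "pre_score": p0,
                "post_score": p1,
                "relative_change": rel,
            }
        )
    labels = pd.DataFrame(rows, columns=["animal_id", "label", "pre_score", "post_score", "relative_change"])
    n_resp = int((labels["label"] == RESPONDER).sum())
    denom = len(labels) if na_in_denominator else int((labels["label"] != NOT_APPLICABLE).sum())
    rate = responder_rate(n_resp, denom) if denom else float("nan")
    return ResponseClassification(labels=labels, responder_rate_pct=rate)


DEFAULT_K_PER_GROUP = {GROUP_CORT: 5, GROUP_R: 7, GROUP_NR: 6}


def select_most_affected(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    k_per_group: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pick the 'most affected' animals per proteomic group for MS analysis.

    CORT/V and Flx-NR animals rank by descending post-treatment (session-2)
    emotionality — the most persistently affected; Flx-R animals rank by
    descending relative decrease — the clearest responders.  Ties break by
    animal_id so the selection is stable across runs.

    Returns a frame with ``animal_id``, proteomic ``group`` and ``rank``
    (1 = most affected) containing exactly ``k`` animals per group.
    """
    k_per_group = dict(DEFAULT_K_PER_GROUP if k_per_group is None else k_per_group)
    post = scores[scores["session"] == 2].set_index("animal_id")
    lab = labels.set_index("animal_id")

    def _pool(keys: pd.Series) -> pd.DataFrame:
        return pd.DataFrame(
            {"key": keys.to_numpy(), "animal_id": keys.index.to_numpy()}
        )

    cort = post[post["group"] == CORT_V]
    resp = lab[lab["label"] == RESPONDER]
    nonresp = lab[lab["label"] == NON_RESPONDER]
    nr_post = post.loc[post.index.intersection(nonresp.index)]
    pools = {
        GROUP_CORT: _pool(-cort["emotionality"]),
        GROUP_R: _pool(-resp["relative_change"]),
        GROUP_NR: _pool(-nr_post["emotionality"]),
    }

    out = []
    for grp, k in k_per_group.items():
        if grp not in pools:
            raise ConfigurationError(f"unknown proteomic group {grp!r}")
        pool = pools[grp].sort_values(["key", "animal_id"]).reset_index(drop=True)
        if k > len(pool):
            raise ConfigurationError(
                f"requested k={k} for group {grp!r} but only {len(pool)} animals available"
            )
        sel = pool.head(k)
        out.append(
            pd.DataFrame(
                {"animal_id": sel["animal_id"].values, "group": grp, "rank": np.arange(1, k + 1)}
            )
        )
    return pd.concat(out, ignore_index=True)
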