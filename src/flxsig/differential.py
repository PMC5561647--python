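"""Per-protein differential testing on spectral counts.

The group-effect test fits a log-linear Poisson model per protein,
``y_ij ~ Poisson(exp(beta_g(j) + o_j))`` with a group factor (and an optional
log total-count offset), against the intercept-only null.  With a single
categorical factor the maximum-likelihood rates are offset-weighted group
means, so the likelihood-ratio deviance has a closed form,

    D = 2 * sum_g S_g * log(lambda_g / lambda_0),

referred to a chi-square with (n_groups - 1) degrees of freedom.  Group-effect
p-values are adjusted across proteins by the Benjamini-Hochberg step-up
procedure.  Pairwise contrasts use classical two-sided pooled-variance
Student t-tests on the per-sample (optionally normalized) counts, and effect
directions are summarized as pseudocounted log2 mean ratios versus the
untreated corticosterone group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import behavior as bhv
from .errors import ConfigurationError, MissingDataError
from .inference import CountMatrix

GROUP_ORDER = (bhv.GROUP_CORT, bhv.GROUP_R, bhv.GROUP_NR)
CONTRASTS = (
    ("R_vs_CORT", bhv.GROUP_R, bhv.GROUP_CORT),
    ("NR_vs_CORT", bhv.GROUP_NR, bhv.GROUP_CORT),
    ("R_vs_NR", bhv.GROUP_R, bhv.GROUP_NR),
)


@dataclass(frozen=True)
class DesignSpec:
    """Sample-to-group design and normalization choices.

    ``normalization`` is ``"none"`` (raw counts) or ``"total-count"`` (log
    library-size offset in the Poisson model; counts scaled to the mean
    library size for the t-tests).  ``pseudocount`` guards the log2 ratios
    against zero means.
    """

    sample_groups: Mapping[str, str]
    normalization: str = "none"
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.normalization not in ("none", "total-count"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.pseudocount < 0:
            raise ConfigurationError("pseudocount must be non-negative")
        counts = pd.Series(dict(self.sample_groups)).value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ConfigurationError(f"groups with < 2 samples: {small.index.tolist()}")


def poisson_group_deviance(
    y: np.ndarray, groups: np.ndarray, offsets: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Closed-form LRT of a group effect in a Poisson log-linear model.

    Returns ``(deviance, p_value, df)``.  ``y`` may be 1-D (one protein) —
    use :func:`fit_group_poisson_matrix` for the vectorized many-protein path.
    All-zero rows are degenerate: deviance 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    exp_off = np.ones_like(y) if offsets is None else np.exp(np.asarray(offsets, dtype=float))
    labels = sorted(set(groups.tolist()))
    df = len(labels) - 1
    total = y.sum()
    if total == 0:
        return 0.0, 1.0, df
    lam0 = total / exp_off.sum()
    dev = 0.0
    for g in labels:
        m = np.asarray(groups) == g
        sg = y[m].sum()
        if sg > 0:
            lam_g = sg / exp_off[m].sum()
            dev += 2.0 * sg * np.log(lam_g / lam0)
    dev = max(dev, 0.0)
    return float(dev), float(stats.chi2.sf(dev, df)), df


def fit_group_poisson_matrix(
    counts: pd.DataFrame, design: DesignSpec
) -> pd.DataFrame:
    """Vectorized group-effect deviance test over all proteins.

    Returns a frame indexed like ``counts`` with ``deviance``, ``p_group``
    and a ``degenerate`` flag for all-zero rows.
    """
    groups = np.asarray([design.sample_groups[s] for s in counts.columns])
    y = counts.to_numpy(dtype=float)
    if design.normalization == "total-count":
        lib = y.sum(axis=0)
        if (lib <= 0).any():
            raise MissingDataError("total-count normalization needs nonzero library sizes")
        w = lib  # exp(offset) proportional to library size
    else:
        w = np.ones(y.shape[1])

    labels = [g for g in GROUP_ORDER if g in set(groups)] or sorted(set(groups))
    df = len(labels) - 1
    total = y.sum(axis=1)
    lam0 = total / w.sum()
    dev = np.zeros(len(y))
    for g in labels:
        m = groups == g
        sg = y[:, m].sum(axis=1)
        lam_g = sg / w[m].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            term = 2.0 * sg * np.log(lam_g / lam0)
        dev += np.where(sg > 0, np.nan_to_num(term), 0.0)
    dev = np.maximum(dev, 0.0)
    degenerate = total == 0
    p = np.where(degenerate, 1.0, stats.chi2.sf(dev, df))
    return pd.DataFrame(
        {"deviance": np.where(degenerate, 0.0, dev), "p_group": p, "degenerate": degenerate},
        index=counts.index,
    )


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test.

    Returns ``(p, mean_a - mean_b)``.  Degenerate zero-variance rows: p = 1
    when the means coincide, p = 0 when they differ (all mass on a point).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("need >= 2 samples on both sides of a t-test")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (1.0 if diff == 0 else 0.0), diff
    t = stats.ttest_ind(a, b, equal_var=True)
    return float(t.pvalue), diff


def log_change(
    counts_row: np.ndarray, group_mask: np.ndarray, ref_mask: np.ndarray, pseudocount: float = 0.5
) -> float:
    """Pseudocounted log2 ratio of group mean to reference mean."""
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be positive for log ratios")
    y = np.asarray(counts_row, dtype=float)
    return float(
        np.log2((y[group_mask].mean() + pseudocount) / (y[ref_mask].mean() + pseudocount))
    )


def run_differential(matrix: CountMatrix, design: DesignSpec | None = None) -> pd.DataFrame:
    """Full per-protein differential table.

    Columns: ``deviance, p_group, q_group`` (BH over the group-effect
    p-values), one ``p_<contrast>`` and ``diff_<contrast>`` per pairwise
    Student t-test, ``delta_R`` / ``delta_NR`` (log2 pseudocounted mean ratio
    vs CORT/V) and their sign columns.
    """
    if design is None:
        design = DesignSpec(sample_groups=dict(matrix.sample_groups))
    counts = matrix.counts
    res = fit_group_poisson_matrix(counts, design)
    res["q_group"] = adjust_bh(res["p_group"].to_numpy())

    groups = np.asarray([design.sample_groups[s] for s in counts.columns])
    y = counts.to_numpy(dtype=float)
    if design.normalization == "total-count":
        lib = y.sum(axis=0)
        y_norm = y / lib * lib.mean()
    else:
        y_norm = y

    masks = {g: groups == g for g in set(groups)}
    for name, ga, gb in CONTRASTS:
        pvals, diffs = [], []
        for row in y_norm:
            p, d = pairwise_ttest(row[masks[ga]], row[masks[gb]])
            pvals.append(p)
            diffs.append(d)
        res[f"p_{name}"] = pvals
        res[f"diff_{name}"] = diffs

    c = design.pseudocount if design.pseudocount > 0 else 0.5
    ref = masks[bhv.GROUP_CORT]
    res["delta_R"] = [log_change(row, masks[bhv.GROUP_R], ref, c) for row in y_norm]
    res["delta_NR"] = [log_change(row, masks[bhv.GROUP_NR], ref, c) for row in y_norm]
    res["sign_R"] = np.sign(res["delta_R"])
    res["sign_NR"] = np.sign(res["delta_NR"])
    return res
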