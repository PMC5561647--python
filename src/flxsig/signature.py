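"""Venn partitioning, directional correlations and response-signature selection.

Proteins significantly changed by fluoxetine in responders (R vs CORT/V) and
in non-responders (NR vs CORT/V) are partitioned into common, solely-R and
solely-NR subsets; Pearson correlations of the log2 changes over these
subsets quantify how response-independent most fluoxetine effects are.

The response-associated signature applies three criteria simultaneously: a
protein must differ significantly between responders and non-responders,
differ significantly between responders and untreated corticosterone animals,
and change either in the opposite direction in responders, or in the same
direction with greater amplitude — i.e. the responders' proteome moves away
from the corticosterone profile in a way the non-responders' does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, MissingDataError

ZERO_DELTA = 1e-12


@dataclass(frozen=True)
class VennPartition:
    """Two-set Venn decomposition of significant-protein sets."""

    set_R: frozenset
    set_NR: frozenset

    @property
    def common(self) -> frozenset:
        return self.set_R & self.set_NR

    @property
    def solely_R(self) -> frozenset:
        return self.set_R - self.set_NR

    @property
    def solely_NR(self) -> frozenset:
        return self.set_NR - self.set_R

    @property
    def union(self) -> frozenset:
        return self.set_R | self.set_NR

    @property
    def union_count(self) -> int:
        return len(self.union)

    def counts(self) -> dict[str, int]:
        return {
            "set_R": len(self.set_R),
            "set_NR": len(self.set_NR),
            "common": len(self.common),
            "solely_R": len(self.solely_R),
            "solely_NR": len(self.solely_NR),
            "union": self.union_count,
        }


def venn_partition(set_R: Iterable, set_NR: Iterable) -> VennPartition:
    """Exact set algebra over the two significance sets."""
    return VennPartition(set_R=frozenset(set_R), set_NR=frozenset(set_NR))


def venn_counts_from_sizes(n_R: int, n_NR: int, n_common: int) -> dict[str, int]:
    """Venn arithmetic from reported set sizes alone (no membership needed)."""
    if min(n_R, n_NR, n_common) < 0 or n_common > min(n_R, n_NR):
        raise ConfigurationError("need 0 <= n_common <= min(n_R, n_NR)")
    return {
        "set_R": n_R,
        "set_NR": n_NR,
        "common": n_common,
        "solely_R": n_R - n_common,
        "solely_NR": n_NR - n_common,
        "union": n_R + n_NR - n_common,
    }


def fraction_of_detected(n_subset: int, n_detected: int) -> float:
    """Subset share of all detected proteins, as a percentage (1 decimal)."""
    if n_detected <= 0 or n_subset < 0:
        raise ConfigurationError("need n_detected > 0 and n_subset >= 0")
    return round(100.0 * n_subset / n_detected, 1)


def directional_correlation(
    deltas_R: pd.Series | Sequence[float],
    deltas_NR: pd.Series | Sequence[float],
    subset: Iterable | None = None,
) -> tuple[float, float]:
    """Pearson correlation of responder vs non-responder log2 changes.

    ``subset`` restricts to a protein subset (index labels) when the deltas
    are Series.  Returns ``(r, p)`` with p from the usual t-distribution
    transform.  Zero variance on either axis is undefined and raises.
    """
    if subset is not None:
        deltas_R = pd.Series(deltas_R).loc[list(subset)]
        deltas_NR = pd.Series(deltas_NR).loc[list(subset)]
    x = np.asarray(deltas_R, dtype=float)
    y = np.asarray(deltas_NR, dtype=float)
    if len(x) < 3:
        raise ConfigurationError("correlation needs a subset of size >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ConfigurationError("correlation undefined: zero variance on one axis")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_signature(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the three-criterion response-signature rule per protein.

    Expects the differential table columns ``p_R_vs_NR``, ``p_R_vs_CORT``,
    ``delta_R`` and ``delta_NR``.  A protein is selected iff both p-values
    are below ``alpha`` and either the two deltas have opposite (nonzero)
    signs, or the same sign with ``|delta_R| > |delta_NR|``.  Deltas within
    1e-12 of zero count as neither.  Output is ordered by ``p_R_vs_NR``
    ascending, ties by accession, and carries the individual criterion flags.
    """
    required = ["p_R_vs_NR", "p_R_vs_CORT", "delta_R", "delta_NR"]
    missing = [c for c in required if c not in results.columns]
    if missing:
        raise MissingDataError(f"differential table lacks columns {missing}")
    bad = results[required].isna().any(axis=1)
    if bad.any():
        raise MissingDataError(
            f"missing contrast statistics for proteins {results.index[bad].tolist()[:5]}"
        )

    out = results[required].copy()
    dr = out["delta_R"].to_numpy()
    dnr = out["delta_NR"].to_numpy()
    nz = (np.abs(dr) > ZERO_DELTA) & (np.abs(dnr) > ZERO_DELTA)
    out["sig_R_vs_NR"] = out["p_R_vs_NR"] < alpha
    out["sig_R_vs_CORT"] = out["p_R_vs_CORT"] < alpha
    out["opposite_direction"] = nz & (np.sign(dr) * np.sign(dnr) < 0)
    out["greater_amplitude"] = nz & (np.sign(dr) == np.sign(dnr)) & (np.abs(dr) > np.abs(dnr))
    out["selected"] = (
        out["sig_R_vs_NR"]
        & out["sig_R_vs_CORT"]
        & (out["opposite_direction"] | out["greater_amplitude"])
    )
    out = out.rename_axis("accession").reset_index()
    return out.sort_values(["p_R_vs_NR", "accession"], kind="mergesort").reset_index(drop=True)
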