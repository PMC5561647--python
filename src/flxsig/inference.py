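"""Protein inference from peptide-spectrum matches and spectral-count assembly.

Identification filtering follows the two-peptide rule: a peptide-spectrum
match is retained when its peptide E-value is strictly below 0.01, and an
accession is retained when its protein E-value is strictly below 1e-4 and it
keeps at least two distinct peptide sequences.  Retained accessions sharing at
least one peptide are merged into protein groups (connected components of the
protein-peptide bipartite graph); within a group, any accession with at least
one peptide specific to it is reported as a subgroup — one subgroup stands for
one quantifiable protein.  Quantification is by spectral counting: a
subgroup's value in a sample is the summed spectra of its specific peptides
("unique-only" assignment; shared-peptide spectra are never counted twice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyResultError, MissingDataError

PSM_COLUMNS = (
    "peptide_sequence",
    "peptide_evalue",
    "protein_accessions",
    "protein_evalue",
    "sample_id",
    "spectra",
)


def _accession_list(value) -> list[str]:
    if isinstance(value, str):
        return [a for a in value.split(";") if a]
    return list(value)


def read_psm_table(path) -> pd.DataFrame:
    """Read a tab-delimited PSM table (accessions semicolon-joined)."""
    psms = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_COLUMNS if c not in psms.columns]
    if missing:
        raise MissingDataError(f"PSM table lacks columns {missing}")
    return psms


def filter_identifications(
    psms: pd.DataFrame,
    pep_e_max: float = 0.01,
    prot_e_max: float = 1e-4,
    min_peptides: int = 2,
    contaminants: Iterable[str] = (),
    contaminant_prefix: str | None = "CONT_",
) -> pd.DataFrame:
    """Apply identification thresholds and the distinct-peptide rule.

    PSMs with ``peptide_evalue >= pep_e_max`` are dropped (strict inequality);
    accessions are dropped when their protein E-value is not strictly below
    ``prot_e_max``, when they retain fewer than ``min_peptides`` distinct
    peptide sequences, or when they match the contaminant list/prefix.
    Rows whose accessions are all dropped disappear.  Raises
    :class:`EmptyResultError` if nothing survives.
    """
    if pep_e_max <= 0 or prot_e_max <= 0:
        raise ConfigurationError("E-value thresholds must be positive")
    if min_peptides < 1:
        raise ConfigurationError("min_peptides must be >= 1")

    kept = psms[psms["peptide_evalue"] < pep_e_max].copy()
    if kept.empty:
        raise EmptyResultError("no PSM passes the peptide E-value threshold")

    # fallback protein E-value: product of the unique peptides' (best) E-values,
    # used where the table does not provide one
    best_pep_e: dict[tuple[str, str], float] = {}
    for accs, pep, e in zip(
        kept["protein_accessions"], kept["peptide_sequence"], kept["peptide_evalue"]
    ):
        for a in _accession_list(accs):
            key = (a, pep)
            best_pep_e[key] = min(best_pep_e.get(key, np.inf), float(e))
    fallback_prot_e: dict[str, float] = {}
    for (a, _), e in best_pep_e.items():
        fallback_prot_e[a] = fallback_prot_e.get(a, 1.0) * e

    contaminants = set(contaminants)

    def bad_acc(acc: str, prot_e: float) -> bool:
        if acc in contaminants:
            return True
        if contaminant_prefix and acc.startswith(contaminant_prefix):
            return True
        if prot_e is None or not np.isfinite(prot_e):
            prot_e = fallback_prot_e.get(acc, np.inf)
        return not prot_e < prot_e_max

    # first pass: drop accessions failing E-value / contaminant rules
    kept["protein_accessions"] = [
        ";".join(a for a in _accession_list(accs) if not bad_acc(a, pe))
        for accs, pe in zip(kept["protein_accessions"], kept["protein_evalue"])
    ]
    kept = kept[kept["protein_accessions"] != ""]

    # second pass: enforce the distinct-peptide rule per accession, iterating
    # because removing an accession can orphan rows mapped only to it
    while True:
        pep_count: dict[str, set[str]] = {}
        for accs, pep in zip(kept["protein_accessions"], kept["peptide_sequence"]):
            for a in _accession_list(accs):
                pep_count.setdefault(a, set()).add(pep)
        weak = {a for a, peps in pep_count.items() if len(peps) < min_peptides}
        if not weak:
            break
        kept = kept.copy()
        kept["protein_accessions"] = [
            ";".join(a for a in _accession_list(accs) if a not in weak)
            for accs in kept["protein_accessions"]
        ]
        kept = kept[kept["protein_accessions"] != ""]
        if kept.empty:
            raise EmptyResultError("no accession satisfies the identification thresholds")
    return kept.reset_index(drop=True)


@dataclass
class ProteinGrouping:
    """Protein groups (shared-peptide components) and their subgroups.

    ``groups`` maps a deterministic group id (the lexicographically smallest
    member accession) to the sorted member accessions; ``subgroups`` lists,
    per group id, the members owning at least one specific peptide;
    ``peptide_to_accessions`` is the retained incidence map.
    """

    groups: dict[str, list[str]]
    subgroups: dict[str, list[str]]
    peptide_to_accessions: dict[str, list[str]]

    @property
    def accession_to_group(self) -> dict[str, str]:
        return {a: gid for gid, members in self.groups.items() for a in members}

    def specific_peptides(self, accession: str) -> list[str]:
        return sorted(
            p for p, accs in self.peptide_to_accessions.items() if accs == [accession]
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.groups):
            for acc in self.groups[gid]:
                rows.append(
                    {
                        "group_id": gid,
                        "accession": acc,
                        "is_subgroup": acc in self.subgroups[gid],
                        "n_specific_peptides": len(self.specific_peptides(acc)),
                    }
                )
        return pd.DataFrame(rows)


def group_proteins(filtered: pd.DataFrame) -> ProteinGrouping:
    """Group retained accessions by shared peptides; flag subgroups.

    Groups are the connected components of the accession-peptide bipartite
    graph.  An accession is a subgroup when at least one retained peptide maps
    to it alone.  Output is order-independent: shuffling PSM rows yields the
    same grouping.
    """
    if filtered.empty:
        raise EmptyResultError("cannot group an empty PSM table")
    pep_to_accs: dict[str, set[str]] = {}
    for accs, pep in zip(filtered["protein_accessions"], filtered["peptide_sequence"]):
        pep_to_accs.setdefault(pep, set()).update(_accession_list(accs))

    g = nx.Graph()
    for pep, accs in pep_to_accs.items():
        for a in accs:
            g.add_edge(("pep", pep), ("acc", a))
    groups: dict[str, list[str]] = {}
    for comp in nx.connected_components(g):
        members = sorted(n[1] for n in comp if n[0] == "acc")
        groups[members[0]] = members

    incidence = {p: sorted(a) for p, a in pep_to_accs.items()}
    subgroups = {
        gid: [
            acc
            for acc in members
            if any(accs == [acc] for accs in incidence.values())
        ]
        for gid, members in groups.items()
    }
    return ProteinGrouping(groups=groups, subgroups=subgroups, peptide_to_accessions=incidence)


@dataclass
class CountMatrix:
    """Spectral counts: subgroup proteins (rows) x samples (columns).

    ``counts`` is an integer DataFrame indexed by accession; ``sample_groups``
    maps each column to its design group; ``row_meta`` carries the group id
    and distinct-peptide count per row.
    """

    counts: pd.DataFrame
    sample_groups: pd.Series
    row_meta: pd.DataFrame

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# spectral count matrix (unique-peptide spectra)\n")
            fh.write("# groups:\t" + "\t".join(self.sample_groups.loc[self.counts.columns]) + "\n")
            self.counts.rename_axis("accession").to_csv(fh, sep="\t")


def build_count_matrix(
    filtered: pd.DataFrame,
    grouping: ProteinGrouping,
    sample_groups: Mapping[str, str] | pd.Series,
    mode: str = "unique-only",
) -> CountMatrix:
    """Sum spectra per subgroup protein and sample.

    ``unique-only`` (default) counts only peptides specific to a single
    subgroup, so no spectrum is counted twice; ``group-level`` adds one row
    per multi-member group holding its shared-peptide spectra.  Missing
    protein x sample combinations are zero.  Every sample must carry a design
    group label.
    """
    if mode not in ("unique-only", "group-level"):
        raise ConfigurationError(f"unknown shared-spectra mode {mode!r}")
    sample_groups = pd.Series(dict(sample_groups) if not isinstance(sample_groups, pd.Series) else sample_groups)
    samples = sorted(filtered["sample_id"].unique())
    unlabeled = [s for s in samples if s not in sample_groups.index]
    if unlabeled:
        raise MissingDataError(f"samples without a group label: {unlabeled}")

    incidence = grouping.peptide_to_accessions
    sub_accs = sorted({a for accs in grouping.subgroups.values() for a in accs})
    rows: dict[str, dict[str, int]] = {a: {} for a in sub_accs}
    shared_rows: dict[str, dict[str, int]] = {}
    for pep, sid, s in zip(
        filtered["peptide_sequence"],
        filtered["sample_id"],
        filtered["spectra"],
    ):
        owners = incidence[pep]
        if len(owners) == 1 and owners[0] in rows:
            rows[owners[0]][sid] = rows[owners[0]].get(sid, 0) + int(s)
        elif mode == "group-level" and len(owners) > 1:
            gid = grouping.accession_to_group[owners[0]]
            d = shared_rows.setdefault(f"group:{gid}", {})
            d[sid] = d.get(sid, 0) + int(s)

    all_rows = {**rows, **shared_rows}
    counts = pd.DataFrame(
        0, index=sorted(all_rows), columns=samples, dtype=int
    )
    for acc, per_sample in all_rows.items():
        for sid, s in per_sample.items():
            counts.loc[acc, sid] = s

    n_pep = {
        a: len({p for p, owners in incidence.items() if a in owners}) for a in sub_accs
    }
    acc_to_gid = grouping.accession_to_group
    row_meta = pd.DataFrame(
        {
            "group_id": [acc_to_gid.get(a.split(":", 1)[-1], a.split(":", 1)[-1]) for a in counts.index],
            "n_distinct_peptides": [n_pep.get(a, 0) for a in counts.index],
        },
        index=counts.index,
    )
    return CountMatrix(counts=counts, sample_groups=sample_groups.loc[samples], row_meta=row_meta)
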