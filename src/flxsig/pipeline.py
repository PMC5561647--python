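"""End-to-end orchestration: simulate -> score -> classify -> select -> infer
-> test -> signature -> multivariate, with a reproducible run manifest.

Every stage writes plain tab-delimited files into its own subdirectory of the
run directory, so any stage can be re-run or inspected independently.  The
manifest records the package version, a hash of the effective configuration,
the seed and per-stage row counts — identical configuration and seed produce
a byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import behavior as bhv
from . import differential as diff
from . import inference as inf
from . import multivariate as mv
from . import signature as sig
from . import synthetic as syn
from .errors import FlxsigError

ALL_STAGES = (
    "simulate_behavior",
    "score",
    "classify",
    "select",
    "simulate_proteome",
    "infer",
    "test",
    "signature",
    "multivariate",
)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, simulation parameters and stage toggles for one run."""

    out_dir: str = "flxsig_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    behavior: syn.BehavioralSimConfig = field(default_factory=syn.BehavioralSimConfig)
    proteome: syn.ProteomeSimConfig = field(default_factory=syn.ProteomeSimConfig)
    responder_cutoff: float = 0.5
    k_per_group: Mapping[str, int] = field(default_factory=lambda: dict(bhv.DEFAULT_K_PER_GROUP))
    pep_e_max: float = 0.01
    prot_e_max: float = 1e-4
    min_peptides: int = 2
    alpha: float = 0.05
    normalization: str = "none"
    pseudocount: float = 0.5

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        if "behavior" in raw:
            b = dict(raw["behavior"])
            if "n_per_group" in b:
                b["n_per_group"] = dict(b["n_per_group"])
            raw["behavior"] = syn.BehavioralSimConfig(**b)
        if "proteome" in raw:
            p = dict(raw["proteome"])
            for key in ("n_samples_per_group", "class_fractions"):
                if key in p:
                    p[key] = dict(p[key])
            for key in ("baseline_rate_range", "peptides_per_protein"):
                if key in p:
                    p[key] = tuple(p[key])
            raw["proteome"] = syn.ProteomeSimConfig(**p)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land does not change what they are
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def run_pipeline(config: RunConfig, log=None) -> str:
    """Execute the enabled stages in order; return the manifest text.

    Any stage failure re-raises with the stage name prefixed, so callers
    (and the CLI) can abort with a precise message.  Stage products land in
    ``<out_dir>/<stage>/``; the manifest is written to
    ``<out_dir>/manifest.txt``.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in ALL_STAGES if s in config.stages]
    counts: dict[str, int] = {}
    state: dict[str, object] = {}

    # seed every stochastic stage from the single run seed
    behav_cfg = replace(config.behavior, seed=config.seed)
    prot_cfg = replace(config.proteome, seed=(config.seed + 1) % (2**31))

    for stage in enabled:
        t0 = time.monotonic()
        try:
            counts[stage] = _run_stage(stage, config, behav_cfg, prot_cfg, state, out)
        except FlxsigError as err:
            raise FlxsigError(f"stage {stage!r} failed: {err}") from err
        log(f"[flxsig] {stage}: {counts[stage]} rows in {time.monotonic() - t0:.2f}s")

    lines = [
        f"flxsig_version\t{__version__}",
        f"config_hash\t{config.config_hash()}",
        f"seed\t{config.seed}",
    ]
    for s in ALL_STAGES:
        status = str(counts[s]) if s in counts else "skipped"
        lines.append(f"stage_rows\t{s}\t{status}")
    manifest = "\n".join(lines) + "\n"
    (out / "manifest.txt").write_text(manifest)
    return manifest


def _run_stage(stage, config, behav_cfg, prot_cfg, state, out: Path) -> int:
    if stage == "simulate_behavior":
        records = syn.simulate_behavior(behav_cfg)
        state["records"] = records
        return _write(records, out / stage / "behavior.tsv")

    if stage == "score":
        z = bhv.zscore_measures(state["records"])
        scores = bhv.emotionality(z)
        state["scores"] = scores
        _write(z, out / stage / "zscores.tsv")
        return _write(scores, out / stage / "emotionality.tsv")

    if stage == "classify":
        cls = bhv.classify_response(state["scores"], cutoff=config.responder_cutoff)
        state["classification"] = cls
        (out / stage).mkdir(parents=True, exist_ok=True)
        (out / stage / "responder_rate.txt").write_text(f"{cls.responder_rate_pct}\n")
        return _write(cls.labels, out / stage / "labels.tsv")

    if stage == "select":
        sel = bhv.select_most_affected(
            state["scores"], state["classification"].labels, config.k_per_group
        )
        state["selection"] = sel
        return _write(sel, out / stage / "selected_animals.tsv")

    if stage == "simulate_proteome":
        psms, truth = syn.simulate_psms(prot_cfg)
        state["psms"], state["truth"] = psms, truth
        state["design"] = syn.sample_design(prot_cfg)
        _write(truth, out / stage / "truth.tsv")
        _write(state["design"], out / stage / "design.tsv")
        return _write(psms, out / stage / "psms.tsv")

    if stage == "infer":
        filtered = inf.filter_identifications(
            state["psms"],
            pep_e_max=config.pep_e_max,
            prot_e_max=config.prot_e_max,
            min_peptides=config.min_peptides,
        )
        grouping = inf.group_proteins(filtered)
        design = state["design"].set_index("sample_id")["group"]
        matrix = inf.build_count_matrix(filtered, grouping, design)
        state["matrix"] = matrix
        _write(grouping.summary(), out / stage / "grouping.tsv")
        matrix.to_tsv(out / stage / "count_matrix.tsv")
        return len(matrix.counts)

    if stage == "test":
        design = diff.DesignSpec(
            sample_groups=dict(state["matrix"].sample_groups),
            normalization=config.normalization,
            pseudocount=config.pseudocount,
        )
        results = diff.run_differential(state["matrix"], design)
        state["results"] = results
        return _write(results, out / stage / "differential.tsv", index=True)

    if stage == "signature":
        res = state["results"]
        set_r = set(res.index[res["p_R_vs_CORT"] < config.alpha])
        set_nr = set(res.index[res["p_NR_vs_CORT"] < config.alpha])
        venn = sig.venn_partition(set_r, set_nr)
        table = sig.select_signature(res, alpha=config.alpha)
        state["signature"] = table
        (out / stage).mkdir(parents=True, exist_ok=True)
        (out / stage / "venn.txt").write_text(
            "".join(f"{k}\t{v}\n" for k, v in venn.counts().items())
        )
        corr_lines = []
        for name, subset in (
            ("common", venn.common),
            ("solely_R", venn.solely_R),
            ("solely_NR", venn.solely_NR),
            ("union", venn.union),
        ):
            if len(subset) >= 3:
                try:
                    r, p = sig.directional_correlation(res["delta_R"], res["delta_NR"], subset)
                    corr_lines.append(f"{name}\t{r:.4f}\t{p:.3g}\n")
                except FlxsigError:
                    corr_lines.append(f"{name}\tundefined\tundefined\n")
        (out / stage / "correlations.tsv").write_text("".join(corr_lines))
        return _write(table, out / stage / "signature.tsv")

    if stage == "multivariate":
        matrix = state["matrix"]
        clustering = mv.bicluster(matrix)
        ordination = mv.ordinate(matrix)
        (out / stage).mkdir(parents=True, exist_ok=True)
        (out / stage / "row_dendrogram.nwk").write_text(
            mv.linkage_to_newick(clustering.row_linkage, list(matrix.counts.index))
        )
        (out / stage / "col_dendrogram.nwk").write_text(
            mv.linkage_to_newick(clustering.col_linkage, list(matrix.counts.columns))
        )
        _write(ordination.scores, out / stage / "pca_scores.tsv", index=True)
        _write(ordination.loadings, out / stage / "pca_loadings.tsv", index=True)
        return len(ordination.scores)

    raise FlxsigError(f"unknown stage {stage!r}")
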