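"""Synthetic cohorts and spectral-count data with the structure the pipeline assumes.

The behavioral generator emulates the chronic-corticosterone mouse design:
three arms (vehicle control VEH/V, corticosterone CORT/V, corticosterone plus
fluoxetine CORT/Flx), two behavioral sessions (before and after the
antidepressant phase), and a latent ~65% responder subpopulation among the
treated animals.  Corticosterone shifts every emotionality-relevant measure in
the emotionality-increasing direction; fluoxetine reverses that shift at
session 2 in latent responders only.

The proteomic generator draws Poisson spectral counts for three sample groups
(CORT/V, Flx-R, Flx-NR) with planted effect classes — null, fluoxetine-common,
responder-only, non-responder-only, and two response-signature classes
(opposite direction, or same direction with greater amplitude in responders) —
and emits a peptide-spectrum-match table whose shared-peptide structure
exercises protein grouping downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import behavior as bhv
from .errors import ConfigurationError

EFFECT_CLASSES = (
    "null",
    "common_flx",
    "r_only",
    "nr_only",
    "signature_opposite",
    "signature_amplified",
)

# nominal control-group location and spread per raw measure; the corticosterone
# shift is expressed in multiples of these sigmas
MEASURE_BASELINES = {
    "epm_open_time_s": (60.0, 20.0),
    "epm_open_entries": (10.0, 3.0),
    "st_grooming_s": (80.0, 20.0),
    "nsf_food_mg_per_g": (5.0, 1.2),
}
NSF_LOG_MU = math.log(90.0)  # median control latency ~90 s of a 600 s test
NSF_LOG_SIGMA = 0.5

# share of residual variance carried by a stable per-animal trait (the rest is
# independent per measure and session)
TRAIT_VARIANCE_SHARE = 0.3


@dataclass(frozen=True)
class BehavioralSimConfig:
    """Study-design parameters for the behavioral cohort generator.

    ``cort_effect_sd`` is the corticosterone shift applied to every scored
    measure, in units of that measure's nominal control SD;
    ``measure_noise_sd`` scales all residual variation in the same units, so
    the observed effect size in z-score space is roughly their ratio.
    ``flx_recovery_fraction`` is the share of the shift reversed at session 2
    in latent responders; latent non-responders instead drift further by
    ``nr_drift_sd``.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {bhv.VEH_V: 14, bhv.CORT_V: 12, bhv.CORT_FLX: 46}
    )
    responder_fraction: float = 0.652
    cort_effect_sd: float = 1.5
    flx_recovery_fraction: float = 1.0
    measure_noise_sd: float = 0.6
    nr_drift_sd: float = 0.5
    nsf_ceiling_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in bhv.ARMS:
                raise ConfigurationError(f"unknown arm {g!r}")
            if n < 2:
                raise ConfigurationError(f"n_per_group[{g!r}] must be >= 2, got {n}")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigurationError("responder_fraction must lie in [0, 1]")
        if self.nsf_ceiling_s <= 0:
            raise ConfigurationError("nsf_ceiling_s must be positive")
        if self.measure_noise_sd < 0:
            raise ConfigurationError("measure_noise_sd must be non-negative")


def simulate_behavior(config: BehavioralSimConfig) -> pd.DataFrame:
    """Generate one row per animal x session with raw battery measures.

    Latent responder status is stored in the hidden-truth column
    ``latent_responder`` (True/False for CORT/Flx animals, NA otherwise); the
    classifier downstream never reads it.  NSF latencies are right-censored at
    ``nsf_ceiling_s``.
    """
    rng = np.random.default_rng(config.seed)
    nu = config.measure_noise_sd
    trait_sd = nu * math.sqrt(TRAIT_VARIANCE_SHARE)
    resid_sd = nu * math.sqrt(1.0 - TRAIT_VARIANCE_SHARE)

    rows = []
    for arm in bhv.ARMS:
        n = config.n_per_group[arm]
        latent = (
            rng.random(n) < config.responder_fraction if arm == bhv.CORT_FLX else np.full(n, np.nan)
        )
        traits = rng.normal(0.0, trait_sd, size=n)
        for i in range(n):
            aid = f"{arm.replace('/', '')}_{i + 1:03d}"
            for session in (1, 2):
                shift = 0.0
                if arm != bhv.VEH_V:
                    shift = config.cort_effect_sd
                    if arm == bhv.CORT_FLX and session == 2:
                        if latent[i] == 1.0:
                            shift *= 1.0 - config.flx_recovery_fraction
                        else:
                            shift += config.nr_drift_sd
                rec = {
                    "animal_id": aid,
                    "group": arm,
                    "session": session,
                    "latent_responder": bool(latent[i]) if arm == bhv.CORT_FLX else pd.NA,
                }
                # emotionality state per measure = group shift + stable trait + noise,
                # in nominal-SD units, mapped onto the raw scale with the measure's sign
                for m, (mu_m, sig_m) in MEASURE_BASELINES.items():
                    e = shift + traits[i] + rng.normal(0.0, resid_sd)
                    if m == "nsf_food_mg_per_g":
                        # appetite control: no emotionality loading
                        val = mu_m + rng.normal(0.0, nu) * sig_m
                    elif m == "epm_open_time_s" or m == "st_grooming_s":
                        val = mu_m - e * sig_m
                    else:  # epm_open_entries
                        val = mu_m - e * sig_m
                    val = max(val, 0.0)
                    if m == "epm_open_entries":
                        val = float(round(val))
                    rec[m] = val
                e_nsf = shift + traits[i] + rng.normal(0.0, resid_sd)
                lat = math.exp(NSF_LOG_MU + e_nsf * NSF_LOG_SIGMA)
                rec["nsf_latency_s"] = min(lat, config.nsf_ceiling_s)
                rows.append(rec)
    cols = [
        "animal_id",
        "group",
        "session",
        "epm_open_time_s",
        "epm_open_entries",
        "nsf_latency_s",
        "nsf_food_mg_per_g",
        "st_grooming_s",
        "latent_responder",
    ]
    return pd.DataFrame(rows)[cols]


# Default planted-class mix: most fluoxetine effects are common to responders
# and non-responders, solely-NR changes outnumber solely-R, and true
# response-signature proteins are a small minority of the proteome
DEFAULT_CLASS_FRACTIONS = {
    "null": 0.62,
    "common_flx": 0.22,
    "r_only": 0.04,
    "nr_only": 0.08,
    "signature_opposite": 0.02,
    "signature_amplified": 0.02,
}

# amplitude ratio delta_NR / delta_R for the greater-amplitude signature class
AMPLIFIED_NR_RATIO = 0.4


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Parameters for the Poisson spectral-count generator.

    Sample sizes default to the selected most-affected animals (5 CORT/V,
    7 Flx-R, 6 Flx-NR).  ``effect_log2fc`` is the planted |log2 fold change|
    of every non-null class relative to the CORT/V baseline rate, drawn
    uniformly from ``baseline_rate_range`` per protein.
    """

    n_proteins: int = 500
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {bhv.GROUP_CORT: 5, bhv.GROUP_R: 7, bhv.GROUP_NR: 6}
    )
    baseline_rate_range: tuple[float, float] = (5.0, 50.0)
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_log2fc: float = 1.5
    shared_peptide_fraction: float = 0.1
    peptides_per_protein: tuple[int, int] = (2, 5)
    overdispersion: float | None = None  # negative-binomial dispersion; None = pure Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ConfigurationError("class_fractions must be non-negative")
        unknown = set(self.class_fractions) - set(EFFECT_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown effect classes {sorted(unknown)}")
        lo, hi = self.baseline_rate_range
        if not 0 < lo <= hi:
            raise ConfigurationError("baseline_rate_range must satisfy 0 < lo <= hi")
        if not 0.0 <= self.shared_peptide_fraction <= 1.0:
            raise ConfigurationError("shared_peptide_fraction must lie in [0, 1]")


def _group_rates(base: float, cls: str, direction: int, fc: float) -> dict[str, float]:
    """Expected spectral counts per group for one protein of a planted class."""
    up = 2.0**fc
    mult = {bhv.GROUP_CORT: 1.0, bhv.GROUP_R: 1.0, bhv.GROUP_NR: 1.0}
    if cls == "common_flx":
        mult[bhv.GROUP_R] = mult[bhv.GROUP_NR] = up**direction
    elif cls == "r_only":
        mult[bhv.GROUP_R] = up**direction
    elif cls == "nr_only":
        mult[bhv.GROUP_NR] = up**direction
    elif cls == "signature_opposite":
        mult[bhv.GROUP_R] = up**direction
        mult[bhv.GROUP_NR] = up ** (-direction)
    elif cls == "signature_amplified":
        mult[bhv.GROUP_R] = up**direction
        mult[bhv.GROUP_NR] = 2.0 ** (fc * AMPLIFIED_NR_RATIO * direction)
    return {g: base * m for g, m in mult.items()}


def simulate_psms(config: ProteomeSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a PSM table and the truth table of planted effect classes.

    Returns ``(psms, truth)``.  ``psms`` has one row per retained
    (peptide, sample) pair with columns ``peptide_sequence, peptide_evalue,
    protein_accessions`` (semicolon-joined), ``protein_evalue, sample_id,
    spectra``.  Protein-level counts are planted on peptides specific to the
    protein, so the unique-only count matrix recovers them exactly in
    expectation; an additional ``shared_peptide_fraction`` of peptides map to
    two proteins each.  ``truth`` records accession, class, planted direction
    and the per-group Poisson rates.
    """
    rng = np.random.default_rng(config.seed)
    classes, fracs = zip(*sorted(config.class_fractions.items()))
    n_per_class = rng.multinomial(config.n_proteins, np.asarray(fracs))
    cls_of = np.repeat(classes, n_per_class)
    rng.shuffle(cls_of)

    samples: list[tuple[str, str]] = []
    for grp in (bhv.GROUP_CORT, bhv.GROUP_R, bhv.GROUP_NR):
        n = config.n_samples_per_group[grp]
        if n < 2:
            raise ConfigurationError(f"need >= 2 samples in group {grp!r}")
        samples += [(f"{grp.replace('/', '')}_s{i + 1}", grp) for i in range(n)]

    lo, hi = config.baseline_rate_range
    pmin, pmax = config.peptides_per_protein
    truth_rows, psm_rows = [], []
    pep_counter = 0
    accessions = [f"P{i:05d}" for i in range(config.n_proteins)]
    for i, acc in enumerate(accessions):
        cls = cls_of[i]
        direction = int(rng.choice([-1, 1])) if cls != "null" else 0
        base = float(rng.uniform(lo, hi))
        rates = _group_rates(base, cls, direction, config.effect_log2fc)
        truth_rows.append(
            {
                "accession": acc,
                "effect_class": cls,
                "direction": direction,
                "rate_cort": rates[bhv.GROUP_CORT],
                "rate_r": rates[bhv.GROUP_R],
                "rate_nr": rates[bhv.GROUP_NR],
            }
        )

        n_pep = int(rng.integers(pmin, pmax + 1))
        pep_ids = [f"PEP{pep_counter + j:06d}" for j in range(n_pep)]
        pep_counter += n_pep
        # split each sample's protein-level Poisson draw across its specific peptides
        weights = rng.dirichlet(np.ones(n_pep))
        pep_eval = 10.0 ** rng.uniform(-8, -3.2, size=n_pep)
        prot_eval = float(np.prod(pep_eval[: min(n_pep, 3)]))
        for sid, grp in samples:
            total = rng.poisson(rates[grp])
            if config.overdispersion:
                # gamma-mixed Poisson (negative binomial) for robustness checks
                lam = rng.gamma(1.0 / config.overdispersion, config.overdispersion * rates[grp])
                total = rng.poisson(lam)
            if total == 0:
                continue
            split = rng.multinomial(total, weights)
            for pep, e, s in zip(pep_ids, pep_eval, split):
                if s > 0:
                    psm_rows.append(
                        {
                            "peptide_sequence": pep,
                            "peptide_evalue": float(e),
                            "protein_accessions": acc,
                            "protein_evalue": prot_eval,
                            "sample_id": sid,
                            "spectra": int(s),
                        }
                    )

    # shared peptides: map to a protein pair, independent low-rate spectra
    n_shared = int(round(config.shared_peptide_fraction * pep_counter))
    if n_shared > 0 and config.n_proteins >= 2:
        for j in range(n_shared):
            a = int(rng.integers(0, config.n_proteins - 1))
            pair = f"{accessions[a]};{accessions[a + 1]}"
            pep = f"SHPEP{j:06d}"
            e = float(10.0 ** rng.uniform(-8, -3.2))
            for sid, grp in samples:
                s = int(rng.poisson(2.0))
                if s > 0:
                    psm_rows.append(
                        {
                            "peptide_sequence": pep,
                            "peptide_evalue": e,
                            "protein_accessions": pair,
                            "protein_evalue": e**2,
                            "sample_id": sid,
                            "spectra": s,
                        }
                    )

    psms = pd.DataFrame(
        psm_rows,
        columns=[
            "peptide_sequence",
            "peptide_evalue",
            "protein_accessions",
            "protein_evalue",
            "sample_id",
            "spectra",
        ],
    )
    truth = pd.DataFrame(truth_rows)
    return psms, truth


def simulate_counts(config: ProteomeSimConfig) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw the protein x sample count matrix directly, skipping the PSM layer.

    Same planted-class model as :func:`simulate_psms`, useful for large-scale
    statistical checks (type-I error, recovery) where peptide structure is
    irrelevant.  Returns ``(counts, sample_groups, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    classes, fracs = zip(*sorted(config.class_fractions.items()))
    n_per_class = rng.multinomial(config.n_proteins, np.asarray(fracs))
    cls_of = np.repeat(classes, n_per_class)
    rng.shuffle(cls_of)

    design = sample_design(config)
    groups = design["group"].to_numpy()
    lo, hi = config.baseline_rate_range
    base = rng.uniform(lo, hi, size=config.n_proteins)
    directions = np.where(cls_of == "null", 0, rng.choice([-1, 1], size=config.n_proteins))

    rates = np.empty((config.n_proteins, len(design)))
    truth_rows = []
    accs = [f"P{i:05d}" for i in range(config.n_proteins)]
    for i in range(config.n_proteins):
        r = _group_rates(base[i], cls_of[i], int(directions[i]), config.effect_log2fc)
        rates[i] = [r[g] for g in groups]
        truth_rows.append(
            {
                "accession": accs[i],
                "effect_class": cls_of[i],
                "direction": int(directions[i]),
                "rate_cort": r[bhv.GROUP_CORT],
                "rate_r": r[bhv.GROUP_R],
                "rate_nr": r[bhv.GROUP_NR],
            }
        )
    if config.overdispersion:
        lam = rng.gamma(1.0 / config.overdispersion, config.overdispersion * rates)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(rates)
    counts = pd.DataFrame(counts, index=accs, columns=design["sample_id"])
    sample_groups = design.set_index("sample_id")["group"]
    return counts, sample_groups, pd.DataFrame(truth_rows)


def sample_design(config: ProteomeSimConfig) -> pd.DataFrame:
    """Sample-to-group design table matching :func:`simulate_psms` sample ids."""
    rows = []
    for grp in (bhv.GROUP_CORT, bhv.GROUP_R, bhv.GROUP_NR):
        for i in range(config.n_samples_per_group[grp]):
            rows.append({"sample_id": f"{grp.replace('/', '')}_s{i + 1}", "group": grp})
    return pd.DataFrame(rows)


def with_seed(config, seed: int):
    """Return a copy of a simulation config with a different seed."""
    return replace(config, seed=seed)
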