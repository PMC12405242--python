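"""Synthetic cohort generator with planted ground truth.

Emulates the data structure of a small longitudinal HIV neurocognition
cohort: compositional species profiles and plasma metabolite intensities for
18 participants (3 with Lower, 15 with Higher NPZ-6 score), measured at
three timepoints (bsl, post, final), together with six cognitive-domain
z-scores and five functional outcome scales driven by one latent cognition
factor.

Species log-abundances get a participant random intercept (so repeated
measures correlate), a per-sample noise term, and — for planted discriminant
features — a shift along the continuous cognition gradient, normalized so
the Lower-group mean shift equals ``effect_size`` (in units of the total
within-group SD, attenuated over time) while the Higher-group mean shift is
zero. The within-group gradient is what lets the downstream indices
correlate with cognition beyond bare group membership, as biomarker panels
do in real cohorts. Metabolites are log-normal
intensities, median-scaled per feature (no closure: plasma intensities are
not compositional). Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    FeatureTable,
    CohortMetadata,
    TIMEPOINTS,
    DOMAIN_COLS,
    OUTCOME_SIGNS,
)
from .stats import npz6_score, classify_group
from . import io as io_core


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_lower: int = 3
    n_higher: int = 15
    n_species: int = 200
    n_metabolites: int = 1300
    n_discriminant_species: int = 6       # split evenly Lower/Higher-enriched
    n_discriminant_metabolites: int = 64  # split evenly up/down in Lower
    effect_size: float = 4.0              # group shift in total-SD units
    attenuation: tuple[float, ...] = (1.0, 0.5, 0.1)
    outcome_loading: float = 0.85         # latent-factor loading of each scale
    species_gradient: float = 0.7         # within-Higher cognition-gradient damping (species)
    sigma_subject: float = 0.5            # participant random intercept SD (log)
    sigma_noise: float = 0.5              # per-sample residual SD (log)
    detection_limit: float = 1e-6         # relative abundances below → 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lower < 2 or self.n_higher < 2:
            raise ValueError("each group needs at least 2 participants")
        for name in ("n_species", "n_metabolites", "n_discriminant_species",
                     "n_discriminant_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_discriminant_species > self.n_species:
            raise ValueError("more discriminant species than species")
        if self.n_discriminant_metabolites > self.n_metabolites:
            raise ValueError("more discriminant metabolites than metabolites")
        if len(self.attenuation) != len(TIMEPOINTS):
            raise ValueError("attenuation needs one multiplier per timepoint")
        if any(not 0.0 <= a <= 1.0 for a in self.attenuation):
            raise ValueError("attenuation multipliers must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    @property
    def total_sd(self) -> float:
        return math.hypot(self.sigma_subject, self.sigma_noise)


@dataclass
class GroundTruth:
    """Planted facts downstream recovery tests check against."""

    enriched_lower_species: list[str]
    enriched_higher_species: list[str]
    discriminant_metabolites_up: list[str]
    discriminant_metabolites_down: list[str]
    latent_cognition: dict[str, float]
    true_index_separation: dict[str, float]

    def __post_init__(self) -> None:
        a = set(self.enriched_lower_species) & set(self.enriched_higher_species)
        b = set(self.discriminant_metabolites_up) & set(self.discriminant_metabolites_down)
        if a or b:
            raise ValueError("planted enrichment lists must be disjoint")


@dataclass
class Cohort:
    """One simulated cohort: per-timepoint tables plus metadata and truth."""

    species: dict[str, FeatureTable]
    metabolites: dict[str, FeatureTable]
    metadata: CohortMetadata
    truth: GroundTruth
    config: SimulationConfig = field(repr=False, default=None)

    def sample_ids(self, timepoint: str) -> list[str]:
        return self.species[timepoint].sample_ids


def _sample_id(participant: str, timepoint: str) -> str:
    return f"{participant}_{timepoint}"


# target convergence point of the cognition trajectories
_COGNITION_ANCHOR = -0.2


def simulate_cohort(config: SimulationConfig) -> Cohort:
    rng = np.random.default_rng(config.seed)
    n = config.n_lower + config.n_higher
    participants = [f"P{i+1:02d}" for i in range(n)]
    lower_ids = participants[: config.n_lower]
    is_lower = np.array([p in lower_ids for p in participants])

    # --- latent cognition: Lower at or below the -0.5 threshold, Higher above
    latent = np.empty(n)
    latent[is_lower] = -0.5 - 0.2 - np.abs(rng.normal(0.4, 0.2, config.n_lower))
    latent[~is_lower] = -0.5 + 0.1 + np.abs(rng.normal(0.5, 0.3, config.n_higher))

    # --- species: log-normal with heavy-tailed base means, planted shifts
    species_ids = [f"s__Species_{j+1:04d}" for j in range(config.n_species)]
    k = config.n_discriminant_species
    k_lower = k - k // 2
    planted_lower = species_ids[:k_lower]
    planted_higher = species_ids[k_lower:k]
    base_mu = rng.normal(0.0, 2.5, config.n_species)
    # planted species get moderate base abundance (~0.5-2% after closure) so
    # they behave like the detectable discriminant species of real cohorts
    base_mu[:k] = rng.normal(3.8, 0.5, k)
    subj_fx_species = rng.normal(0.0, config.sigma_subject, (n, config.n_species))

    # --- metabolites
    met_ids = [f"M{j+1:04d}" for j in range(config.n_metabolites)]
    m = config.n_discriminant_metabolites
    m_up = m - m // 2
    planted_up = met_ids[:m_up]
    planted_down = met_ids[m_up:m]
    met_mu = rng.normal(0.0, 1.0, config.n_metabolites)
    subj_fx_met = rng.normal(0.0, config.sigma_subject, (n, config.n_metabolites))

    shift_unit = config.effect_size * config.total_sd

    species_tables: dict[str, FeatureTable] = {}
    met_frames: dict[str, pd.DataFrame] = {}
    meta_rows = []

    sex = ["F"] + ["M"] * (n - 1)  # the one female participant is in Lower
    arm = list(rng.permutation(np.array(
        ["No-intervention"] * min(3, n - 1) + ["Intervention"] * (n - min(3, n - 1))
    )))

    # group labels fixed from the baseline NPZ-6 trajectory value
    npz_base = _COGNITION_ANCHOR + config.attenuation[0] * (latent - _COGNITION_ANCHOR)
    group_label = [classify_group(v) for v in npz_base]

    # planted shifts follow the continuous cognition gradient, normalized so
    # the Lower-group mean shift is exactly effect_size x attenuation x SD
    # and the Higher-group mean shift is zero
    c_lo = latent[is_lower].mean()
    c_hi = latent[~is_lower].mean()
    severity = (c_hi - latent) / (c_hi - c_lo)
    # species: uniform full shift in Lower (discrete enrichment, as LEfSe-style
    # detection presumes) plus a damped gradient within Higher; metabolites:
    # fully gradient-coupled (plasma chemistry tracks cognition continuously)
    severity_species = np.where(is_lower, 1.0, config.species_gradient * severity)

    idx_lower_sp = np.arange(0, k_lower)
    idx_higher_sp = np.arange(k_lower, k)
    idx_up_met = np.arange(0, m_up)
    idx_down_met = np.arange(m_up, m)

    for t_idx, tp in enumerate(TIMEPOINTS):
        att = config.attenuation[t_idx]
        # species
        logx = base_mu[None, :] + subj_fx_species + rng.normal(
            0.0, config.sigma_noise, (n, config.n_species)
        )
        delta_sp = att * shift_unit * severity_species
        logx[:, idx_lower_sp] += delta_sp[:, None]
        logx[:, idx_higher_sp] -= delta_sp[:, None]
        raw = np.exp(logx)
        rel = raw / raw.sum(axis=1, keepdims=True)
        rel[rel < config.detection_limit] = 0.0
        rel = rel / rel.sum(axis=1, keepdims=True)
        sample_ids = [_sample_id(p, tp) for p in participants]
        species_tables[tp] = FeatureTable(
            pd.DataFrame(rel, index=sample_ids, columns=species_ids),
            kind="taxon",
            normalized=True,
        )
        # metabolites
        logm = met_mu[None, :] + subj_fx_met + rng.normal(
            0.0, config.sigma_noise, (n, config.n_metabolites)
        )
        delta_met = att * shift_unit * severity
        logm[:, idx_up_met] += delta_met[:, None]
        logm[:, idx_down_met] -= delta_met[:, None]
        met_frames[tp] = pd.DataFrame(
            np.exp(logm), index=sample_ids, columns=met_ids
        )

        # cognition trajectory: group contrast attenuates toward the anchor
        npz_t = _COGNITION_ANCHOR + att * (latent - _COGNITION_ANCHOR)
        if t_idx > 0:
            npz_t = npz_t + rng.normal(0.0, 0.1, n)
        for i, p in enumerate(participants):
            dom_noise = rng.normal(0.0, 0.4, 6)
            dom_noise -= dom_noise.mean()  # domains average exactly to NPZ-6
            domains = npz_t[i] + dom_noise
            score = npz6_score(domains)
            row = {
                "sample_id": _sample_id(p, tp),
                "participant": p,
                "timepoint": tp,
                "npz6_group": group_label[i],
                "sex": sex[i],
                "arm": arm[i],
                "npz6": score,
            }
            row.update({c: v for c, v in zip(DOMAIN_COLS, domains)})
            resid = math.sqrt(max(1.0 - config.outcome_loading**2, 0.0))
            for scale, sign in OUTCOME_SIGNS.items():
                row[scale] = (
                    sign * config.outcome_loading * npz_t[i]
                    + rng.normal(0.0, resid)
                )
            meta_rows.append(row)

    # median-scale metabolites per feature across all samples (Metabolon-like)
    all_met = pd.concat(met_frames.values(), axis=0)
    med = all_met.median(axis=0)
    metabolite_tables = {
        tp: FeatureTable(frame / med, kind="metabolite", normalized=False)
        for tp, frame in met_frames.items()
    }

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = CohortMetadata(meta)

    truth = GroundTruth(
        enriched_lower_species=list(planted_lower),
        enriched_higher_species=list(planted_higher),
        discriminant_metabolites_up=list(planted_up),
        discriminant_metabolites_down=list(planted_down),
        latent_cognition={p: float(v) for p, v in zip(participants, latent)},
        true_index_separation={
            tp: float(2.0 * config.attenuation[i] * shift_unit)
            for i, tp in enumerate(TIMEPOINTS)
        },
    )
    return Cohort(species_tables, metabolite_tables, metadata, truth, config)


def write_fixture(dir_path, cohort: Cohort) -> list[Path]:
    """Write the cohort as TSV tables + metadata + ground-truth JSON.

    The directory must already exist; nothing is written otherwise.
    """
    out = Path(dir_path)
    if not out.is_dir():
        raise FileNotFoundError(f"fixture directory {out} does not exist")
    written: list[Path] = []
    for tp in TIMEPOINTS:
        p = out / f"species_{tp}.tsv"
        io_core.write_feature_table(p, cohort.species[tp])
        written.append(p)
        p = out / f"metabolites_{tp}.tsv"
        io_core.write_feature_table(p, cohort.metabolites[tp])
        written.append(p)
    p = out / "metadata.tsv"
    io_core.write_metadata(p, cohort.metadata)
    written.append(p)
    p = out / "ground_truth.json"
    truth = asdict(cohort.truth)
    with open(p, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written


def read_fixture(dir_path) -> Cohort:
    """Read back a fixture written by :func:`write_fixture`."""
    d = Path(dir_path)
    species = {
        tp: io_core.read_feature_table(d / f"species_{tp}.tsv", kind="taxon")
        for tp in TIMEPOINTS
    }
    mets = {
        tp: io_core.read_feature_table(d / f"metabolites_{tp}.tsv", kind="metabolite")
        for tp in TIMEPOINTS
    }
    metadata = io_core.read_metadata(d / "metadata.tsv")
    with open(d / "ground_truth.json") as fh:
        truth = GroundTruth(**json.load(fh))
    return Cohort(species, mets, metadata, truth, None)
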