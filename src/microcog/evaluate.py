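"""Monte-Carlo evaluation of the pipeline on its own synthetic cohorts.

Everything here re-runs the actual pipeline stages on freshly generated
cohorts: planted-truth recovery of the selection cascade, null calibration
of its testing gates, PERMANOVA type-I error, attenuation tracking of the
balance indices, and the direction pattern of baseline index-outcome
correlations. Used by the test suite and the reproduction script; all
functions are deterministic given their base seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import binomtest, spearmanr

from .containers import OUTCOME_SIGNS
from .simulate import SimulationConfig, simulate_cohort, Cohort
from .stats import chi_square_test, exact_rank_sum
from .selection import lefse, fit_splsda, splsda_wilcoxon_filter, pca_pc1_select
from .balance import (
    IndexDefinition,
    UndefinedIndexError,
    build_microbial_index,
    build_metabolome_index,
    build_combined_index,
    index_values,
)

#: published cohort characteristics (Lower vs Higher group count tables)
TABLE1_COUNTS = {
    "sex": [[2, 1], [15, 0]],
    "ethnicity": [[2, 1], [14, 1]],
    "cns_comorbidities": [[2, 1], [10, 5]],
    "cart_regimen": [[2, 1, 0, 0], [9, 2, 3, 1]],
}


def table1_pvalues() -> dict[str, float]:
    """Chi-square p-values for the recomputable cohort characteristics."""
    return {name: chi_square_test(tab)[2] for name, tab in TABLE1_COUNTS.items()}


def _baseline(cohort: Cohort):
    meta = cohort.metadata.samples_at("bsl")
    return meta, meta["npz6_group"].to_numpy()


def true_index_definition(cohort: Cohort) -> IndexDefinition:
    t = cohort.truth
    feats = t.enriched_lower_species + t.enriched_higher_species
    return IndexDefinition(
        "true", tuple(t.enriched_lower_species),
        tuple(t.enriched_higher_species), {f: "taxon" for f in feats},
    )


def planted_recovery(n_seeds: int = 100, base_seed: int = 0,
                     config_kwargs: dict | None = None) -> dict:
    """Recovery of planted features by the full selection cascade.

    Returns mean recalls for the LDA-effect-size taxa selection and the
    sPLS-DA + rank-sum metabolite cascade, the fraction of seeds in which
    the baseline microbial-index definition fully contains both planted
    species sets, and the fraction reaching the minimal achievable baseline
    group-separation p.
    """
    kwargs = config_kwargs or {}
    lefse_recalls, met_recalls, set_hits, floor_hits = [], [], [], []
    for i in range(n_seeds):
        cohort = simulate_cohort(SimulationConfig(seed=base_seed + i, **kwargs))
        meta, groups = _baseline(cohort)
        truth = cohort.truth
        species = cohort.species["bsl"]
        planted_taxa = set(truth.enriched_lower_species) | set(
            truth.enriched_higher_species)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            taxa = lefse(species, groups, seed=base_seed + i)
        lefse_recalls.append(
            len(planted_taxa & set(taxa.features())) / len(planted_taxa))

        model = fit_splsda(cohort.metabolites["bsl"], groups,
                           seed=base_seed + i)
        met_set = splsda_wilcoxon_filter(model, cohort.metabolites["bsl"],
                                         groups)
        planted_met = set(truth.discriminant_metabolites_up) | set(
            truth.discriminant_metabolites_down)
        met_recalls.append(
            len(planted_met & set(met_set.features())) / len(planted_met))

        try:
            definition = build_microbial_index(species, groups)
        except UndefinedIndexError:
            set_hits.append(False)
            floor_hits.append(False)
            continue
        set_hits.append(
            set(truth.enriched_lower_species) <= set(definition.numerator)
            and set(truth.enriched_higher_species) <= set(definition.denominator))
        vals = index_values(species, definition)
        lower = groups == "Lower"
        _, p = exact_rank_sum(vals[lower], vals[~lower])
        floor_hits.append(abs(p - 2 / 816) < 1e-12)
    return {
        "lefse_recall": float(np.mean(lefse_recalls)),
        "metabolite_recall": float(np.mean(met_recalls)),
        "index_set_recovery_rate": float(np.mean(set_hits)),
        "index_separation_floor_rate": float(np.mean(floor_hits)),
        "n_seeds": n_seeds,
    }


def null_calibration(n_cohorts: int = 200, base_seed: int = 0) -> dict:
    """False-positive rates of the selection gates on signal-free cohorts.

    Rates are per feature entering the cascade: the Kruskal-Wallis alpha
    gate among testable species, the taxa retained after the full LDA
    screen, and the metabolites retained by the sPLS-DA + rank-sum cascade
    out of all metabolites.
    """
    kw_rates, lefse_rates, met_rates = [], [], []
    for i in range(n_cohorts):
        cohort = simulate_cohort(SimulationConfig(
            seed=base_seed + i, effect_size=0.0))
        meta, groups = _baseline(cohort)
        species = cohort.species["bsl"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from .selection import LefseSelector
            sel = LefseSelector(random_state=base_seed + i).fit(
                species.values, groups)
        testable = np.isfinite(sel.pvalues_)
        kw_rates.append((sel.pvalues_[testable] < sel.alpha).mean())
        lefse_rates.append(sel.support_.sum() / testable.sum())

        model = fit_splsda(cohort.metabolites["bsl"], groups,
                           seed=base_seed + i)
        met_set = splsda_wilcoxon_filter(model, cohort.metabolites["bsl"],
                                         groups)
        met_rates.append(len(met_set) / cohort.metabolites["bsl"].n_features)
    return {
        "kw_gate_rate": float(np.mean(kw_rates)),
        "lefse_retained_rate": float(np.mean(lefse_rates)),
        "metabolite_cascade_rate": float(np.mean(met_rates)),
        "n_cohorts": n_cohorts,
    }


def permanova_type1(n_cohorts: int = 1000, n_perm: int = 199,
                    base_seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate of Bray-Curtis PERMANOVA on signal-free cohorts."""
    from .associate import bray_curtis_permanova
    rejections = 0
    for i in range(n_cohorts):
        cohort = simulate_cohort(SimulationConfig(
            seed=base_seed + i, effect_size=0.0, n_metabolites=4,
            n_discriminant_metabolites=2))
        meta, groups = _baseline(cohort)
        res = bray_curtis_permanova(cohort.species["bsl"], groups,
                                    n_perm=n_perm, seed=base_seed + i)
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_cohorts, "n_cohorts": n_cohorts}


def attenuation_tracking(n_cohorts: int = 100, base_seed: int = 0) -> dict:
    """Between-group difference of the planted index across timepoints.

    Sign tests for the two comparisons the attenuation schedule implies
    (bsl > post and post > final).
    """
    diffs = {"bsl": [], "post": [], "final": []}
    for i in range(n_cohorts):
        cohort = simulate_cohort(SimulationConfig(
            seed=base_seed + i, n_metabolites=4, n_discriminant_metabolites=2))
        definition = true_index_definition(cohort)
        for tp in diffs:
            vals = index_values(cohort.species[tp], definition)
            meta = cohort.metadata.samples_at(tp)
            lower = (meta["npz6_group"] == "Lower").to_numpy()
            diffs[tp].append(float(vals[lower].median() - vals[~lower].median()))
    d = {tp: np.asarray(v) for tp, v in diffs.items()}
    p_bsl_post = binomtest((d["bsl"] > d["post"]).sum(), n_cohorts,
                           alternative="greater").pvalue
    p_post_final = binomtest((d["post"] > d["final"]).sum(), n_cohorts,
                             alternative="greater").pvalue
    return {
        "median_diff": {tp: float(np.median(v)) for tp, v in d.items()},
        "sign_test_p_bsl_post": float(p_bsl_post),
        "sign_test_p_post_final": float(p_post_final),
        "n_cohorts": n_cohorts,
    }


def build_all_indices(cohort: Cohort, seed: int) -> dict[str, IndexDefinition]:
    """Run the full baseline selection cascade and build the three indices."""
    meta, groups = _baseline(cohort)
    definitions = {}
    definitions["microbial"] = build_microbial_index(
        cohort.species["bsl"], groups)
    model = fit_splsda(cohort.metabolites["bsl"], groups, seed=seed)
    met_set = splsda_wilcoxon_filter(model, cohort.metabolites["bsl"], groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pc1 = pca_pc1_select(
            cohort.metabolites["bsl"].values[met_set.features()], groups)
    definitions["metabolome"] = build_metabolome_index(pc1)
    definitions["combined"] = build_combined_index(
        definitions["microbial"], definitions["metabolome"])
    return definitions


def sign_pattern(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Per-index rate of seeds reproducing the expected baseline direction
    pattern of index-outcome correlations (negative with quality of life and
    daily functioning, positive with the distress scales)."""
    matches = {"microbial": 0, "metabolome": 0, "combined": 0}
    usable = 0
    for i in range(n_seeds):
        cohort = simulate_cohort(SimulationConfig(seed=base_seed + i))
        meta, groups = _baseline(cohort)
        try:
            definitions = build_all_indices(cohort, seed=base_seed + i)
        except (UndefinedIndexError, ValueError):
            continue
        usable += 1
        tables = {"taxon": cohort.species["bsl"],
                  "metabolite": cohort.metabolites["bsl"]}
        for name, definition in definitions.items():
            needed = {k: tables[k] for k in set(definition.kinds.values())}
            vals = index_values(
                needed if len(needed) > 1 else next(iter(needed.values())),
                definition).to_numpy()
            ok = all(
                np.sign(spearmanr(vals, meta[scale].to_numpy())[0])
                == -np.sign(loading)
                for scale, loading in OUTCOME_SIGNS.items()
            )
            matches[name] += ok
    return {
        "match_rate": {k: v / usable for k, v in matches.items()},
        "n_usable": usable,
        "n_seeds": n_seeds,
    }
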