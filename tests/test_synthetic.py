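"""Synthetic EHR generator: determinism, marginals, membership structure,
documents, and gold-standard sampling."""

import numpy as np
import pandas as pd
import pytest

from cohortcapture import synthetic
from cohortcapture.textflag import flag_document, flag_patients, normalize_terms
from cohortcapture.synthetic import (
    DatabaseProfile,
    PopulationConfig,
    default_profiles,
    generate_documents,
    generate_membership,
    generate_population,
    profile_from_performance,
    sample_gold_standard,
)


def test_population_deterministic_for_fixed_seed(small_config):
    a = generate_population(small_config)
    b = generate_population(small_config)
    pd.testing.assert_frame_equal(a, b)


def test_population_marginals_converge(population, small_config):
    d = small_config.demographics
    female = (population["sex"] == "female").mean()
    assert female == pytest.approx(d.female_fraction, abs=0.02)
    assert (population["ethnicity"] == "white").mean() == pytest.approx(
        d.ethnicity_fractions[0], abs=0.02
    )
    assert population["imd_decile"].mean() == pytest.approx(d.imd_mean, abs=0.15)
    assert population["age"].min() >= d.age_min
    assert population["imd_decile"].between(1, 10).all()
    y0, y1 = small_config.year_range
    assert population["referral_year"].between(y0, y1).all()
    assert population["disease_status"].mean() == pytest.approx(
        small_config.disease_prevalence, abs=0.02
    )


def test_population_degenerate_prevalence_one():
    cfg = PopulationConfig(n_patients=1, disease_prevalence=0.999999, seed=0)
    pop = generate_population(cfg)
    assert len(pop) == 1 and bool(pop["disease_status"].iloc[0])


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_patients=0, disease_prevalence=0.3),
        dict(n_patients=10, disease_prevalence=0.0),
        dict(n_patients=10, disease_prevalence=0.3, year_range=(2023, 2007)),
    ],
)
def test_population_config_validation(kwargs):
    with pytest.raises(ValueError):
        PopulationConfig(**kwargs)


def test_membership_perfect_database_equals_disease(population):
    profile = DatabaseProfile("perfect", coverage=1.0, flag_sensitivity=1.0,
                              flag_false_positive_rate=0.0)
    mat = generate_membership(population, [profile], seed=0)
    assert (mat["perfect"].to_numpy()
            == population["disease_status"].to_numpy().astype(int)).all()


def test_membership_zero_coverage_all_zero(population):
    profile = DatabaseProfile("ghost", coverage=0.0, flag_sensitivity=1.0,
                              flag_false_positive_rate=1.0)
    mat = generate_membership(population, [profile], seed=0)
    assert (mat["ghost"] == 0).all()


def test_membership_duplicate_names_rejected(population):
    p = DatabaseProfile("dup", 0.5, 0.5, 0.1)
    with pytest.raises(ValueError, match="duplicate"):
        generate_membership(population, [p, p], seed=0)
    with pytest.raises(ValueError, match="non-empty"):
        generate_membership(population, [], seed=0)


def test_membership_missing_encoded_zero_and_deterministic(population, profiles):
    a = generate_membership(population, profiles, seed=5)
    b = generate_membership(population, profiles, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert not a.isna().any().any()
    assert set(np.unique(a.to_numpy())) <= {0, 1}


def test_membership_empirical_precision_near_generative_target(
    population, membership, disease_status
):
    """Per-column precision measured over the whole population lies close
    to the profile's generative target (binomial sampling error).

    The target is evaluated at the realized disease prevalence of the
    sampled population rather than the configured one, since prevalence
    sampling noise shifts the attainable precision."""
    disease = disease_status.loc[membership.index].to_numpy()
    prev = disease.mean()
    for prof in synthetic.default_profiles(0.344):
        se, fpr = prof.effective_sensitivity, prof.flag_false_positive_rate
        target = prev * se / (prev * se + (1 - prev) * fpr)
        flagged = membership[prof.name].to_numpy().astype(bool)
        n_flag = flagged.sum()
        emp = disease[flagged].mean()
        # 3 binomial standard errors around the generative target
        tol = 3 * np.sqrt(target * (1 - target) / n_flag) + 1e-9
        assert abs(emp - target) < max(tol, 0.02), prof.name


def test_profile_from_performance_precision_algebra():
    prof = profile_from_performance("x", 0.8, 0.9, 0.75, prevalence=0.3)
    se, fpr = prof.flag_sensitivity, prof.flag_false_positive_rate
    ppv = 0.3 * se / (0.3 * se + 0.7 * fpr)
    assert ppv == pytest.approx(0.75)
    with pytest.raises(ValueError):
        profile_from_performance("x", 0.8, 0.9, 0.2, prevalence=0.9)


def test_registry_profiles_flag_all_diseased_members():
    assert profile_from_performance("r", 0.5, 0.4, 0.97, 0.3, is_registry=True
                                    ).effective_sensitivity == 1.0


def test_default_profiles_are_eleven_named_databases():
    profs = default_profiles()
    assert len(profs) == 11
    assert len({p.name for p in profs}) == 11


def test_documents_disease_terms_and_confounders(population):
    docs = generate_documents(population, seed=3, p_disease_term=1.0,
                              confounder_fraction=1.0)
    assert set(docs["doc_type"]) <= {"letter", "endoscopy", "histopathology"}
    assert set(docs["patient_id"]) <= set(population["patient_id"])
    status = population.set_index("patient_id")["disease_status"]
    sick_letters = docs[(docs["doc_type"] == "letter")
                        & docs["patient_id"].map(status)]
    # after synonym normalization, every diseased patient's letter carries
    # a term the flagger matches (some templates use raw abbreviations)
    flagged = sick_letters["text"].map(
        lambda t: flag_document(normalize_terms(t)).flagged
    )
    assert flagged.all()
    well_letters = docs[(docs["doc_type"] == "letter")
                        & ~docs["patient_id"].map(status)]
    conf_rate = well_letters["text"].map(lambda t: flag_document(t).flagged).mean()
    assert conf_rate > 0.5  # confounder_fraction=1 concentrates in letters


def test_documents_empty_templates_rejected(population):
    with pytest.raises(ValueError, match="template"):
        generate_documents(population, templates={"positive": []}, seed=0)


def test_letter_precision_below_endoscopy_precision(population, disease_status):
    """Confounder phrases concentrated in letters push letter-flag
    precision below endoscopy-flag precision."""
    docs = generate_documents(population, seed=9)
    docs["text"] = [normalize_terms(t) for t in docs["text"]]
    index = population["patient_id"]
    disease = disease_status.loc[index].to_numpy()
    precisions = {}
    for doc_type in ("letter", "endoscopy"):
        flags = flag_patients(docs, doc_type, patient_index=index).to_numpy().astype(bool)
        precisions[doc_type] = disease[flags].mean()
    assert precisions["letter"] < precisions["endoscopy"]


def test_gold_standard_eligibility_split_and_prevalence(membership, disease_status, gold):
    row_sums = membership.loc[gold["patient_id"]].sum(axis=1)
    assert (row_sums >= 2).all()
    assert (gold["split"] == "validation").sum() == 300  # ceil(0.3 * 1000)
    assert gold["label"].mean() == pytest.approx(0.75, abs=0.01)
    truth = disease_status.loc[gold["patient_id"]].astype(int).to_numpy()
    assert (gold["label"].to_numpy() == truth).all()


def test_gold_standard_reference_split_arithmetic(population, membership, disease_status):
    """A 2800-patient gold standard at a 30% split yields 840 validation
    patients (given enough eligible patients)."""
    cfg = PopulationConfig(n_patients=20000, disease_prevalence=0.344, seed=2)
    pop = generate_population(cfg)
    mat = generate_membership(pop, default_profiles(cfg.disease_prevalence), seed=2)
    g = sample_gold_standard(mat, pop.set_index("patient_id")["disease_status"],
                             n=2800, seed=2)
    assert len(g) == 2800
    assert (g["split"] == "validation").sum() == 840


def test_gold_standard_min_databases_one_allows_everyone(membership, disease_status):
    g = sample_gold_standard(membership, disease_status, n=50,
                             min_databases=1, seed=1)
    assert (membership.loc[g["patient_id"]].sum(axis=1) >= 1).all()


def test_gold_standard_shortfall_error_names_counts(membership, disease_status):
    with pytest.raises(ValueError, match="not enough eligible"):
        sample_gold_standard(membership, disease_status, n=10**6, seed=0)


def test_gold_standard_deterministic(membership, disease_status):
    a = sample_gold_standard(membership, disease_status, n=200, seed=4)
    b = sample_gold_standard(membership, disease_status, n=200, seed=4)
    pd.testing.assert_frame_equal(a, b)
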