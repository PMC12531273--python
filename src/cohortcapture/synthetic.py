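"""Synthetic multi-database EHR population generator.

Emulates the statistical structure the downstream analysis assumes: a
referral population with a latent disease status, eleven partially
overlapping clinical databases that each flag a patient as suspected of
having the disease with database-specific sensitivity and false-positive
rate, template free-text documents carrying disease terms, synonyms and
confounder phrases, and a chart-reviewed gold-standard subcohort drawn
only from patients present in at least two databases (the sampling bias
of real validation cohorts, which induces the edge-node underprediction
the classifier audit looks for).

Everything is seeded and reproducible; missing database records are
encoded 0, never null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Demographics",
    "PopulationConfig",
    "DatabaseProfile",
    "profile_from_performance",
    "default_profiles",
    "default_templates",
    "generate_population",
    "generate_membership",
    "generate_documents",
    "sample_gold_standard",
]

ETHNICITY_LEVELS = ("white", "asian", "african", "other")


@dataclass(frozen=True)
class Demographics:
    """Marginal parameters of the referral population.

    Defaults reflect a UK secondary-care gastroenterology referral
    population: mean age at referral ~52 years with a wide, near-symmetric
    spread, ~60% female, ~85% white ethnicity, and a mildly
    affluence-tilted deprivation (IMD) decile distribution with mean ~5.9.
    """

    age_mean: float = 51.79
    age_sd: float = 24.0
    age_min: float = 18.0
    female_fraction: float = 0.6027
    ethnicity_fractions: tuple[float, ...] = (0.8504, 0.08, 0.04, 0.0296)
    imd_mean: float = 5.91

    def imd_probabilities(self) -> np.ndarray:
        """Linearly tilted decile distribution with the target mean.

        p_k ∝ 1 + s(k − 5.5) over k = 1..10, with the slope s chosen so
        the mean equals ``imd_mean`` (the variance of a uniform decile is
        8.25, hence s = (mean − 5.5)/8.25).
        """
        k = np.arange(1, 11)
        slope = (self.imd_mean - 5.5) / 8.25
        p = (1.0 + slope * (k - 5.5)) / 10.0
        if (p <= 0).any():
            raise ValueError("imd_mean too extreme for a linear tilt")
        return p / p.sum()


@dataclass(frozen=True)
class PopulationConfig:
    """Size, prevalence and demographic marginals of the population."""

    n_patients: int = 37947
    disease_prevalence: float = 0.344
    seed: int = 0
    year_range: tuple[int, int] = (2007, 2023)
    demographics: Demographics = field(default_factory=Demographics)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 < self.disease_prevalence < 1.0:
            raise ValueError("disease_prevalence must lie strictly in (0, 1)")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be ordered (first <= last)")


@dataclass(frozen=True)
class DatabaseProfile:
    """Flagging behaviour of one clinical database.

    ``coverage`` is the probability a patient has any record in the
    database; given coverage, a diseased patient is flagged with
    probability ``flag_sensitivity`` and a disease-free patient with
    probability ``flag_false_positive_rate``.  Registry databases
    (clinician-curated disease lists) flag every diseased member:
    sensitivity is forced to 1 among members.
    """

    name: str
    coverage: float
    flag_sensitivity: float
    flag_false_positive_rate: float
    is_registry: bool = False

    def __post_init__(self) -> None:
        for attr in ("coverage", "flag_sensitivity", "flag_false_positive_rate"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1], got {v}")

    @property
    def effective_sensitivity(self) -> float:
        return 1.0 if self.is_registry else self.flag_sensitivity


def profile_from_performance(
    name: str,
    coverage: float,
    sensitivity: float,
    precision: float,
    prevalence: float,
    is_registry: bool = False,
) -> DatabaseProfile:
    """Build a profile whose population-level precision hits a target.

    Among flagged patients the coverage term cancels, so
    PPV = π·se / (π·se + (1−π)·fpr); solving for the false-positive rate
    gives fpr = π·se·(1−PPV) / ((1−π)·PPV).  ``prevalence`` π is the
    population disease prevalence the matrix will be generated under.
    """
    if not 0.0 < precision <= 1.0:
        raise ValueError("precision must lie in (0, 1]")
    se = 1.0 if is_registry else sensitivity
    fpr = prevalence * se * (1.0 - precision) / ((1.0 - prevalence) * precision)
    if fpr > 1.0:
        raise ValueError(
            f"precision {precision} unattainable at prevalence {prevalence}"
        )
    return DatabaseProfile(
        name=name,
        coverage=coverage,
        flag_sensitivity=sensitivity,
        flag_false_positive_rate=fpr,
        is_registry=is_registry,
    )


# (coverage, sensitivity-within-covered, target precision, is_registry)
# calibrated to the observed per-database validation performance of an
# eleven-database inflammatory bowel disease cohort: coded billing data,
# two clinician-curated registries, event databases (prescriptions, flare
# line, appointments, stool biomarker) and three free-text sources.
_DEFAULT_PROFILE_PARAMS: dict[str, tuple[float, float, float, bool]] = {
    "ICD10 Codes": (0.9548, 0.95, 0.96, False),
    "OPCS4 Codes": (0.326, 0.17, 0.86, False),
    "Patient Portal": (0.5095, 1.0, 0.97, True),
    "EPR IBD Registry": (0.6798, 1.0, 0.97, True),
    "Cytokine Modulator Prescriptions": (0.2357, 1.0, 1.0, False),
    "Flare Calls": (0.6012, 1.0, 0.87, False),
    "IBD Clinic Appointments": (0.7905, 0.70, 0.80, False),
    "Calprotectin > 50": (0.6345, 0.70, 0.80, False),
    "Endoscopy Records": (0.879, 0.70, 0.95, False),
    "Clinical Letters": (0.945, 0.99, 0.79, False),
    "Histopathology Records": (0.6024, 0.89, 0.73, False),
}


def default_profiles(prevalence: float = 0.344) -> list[DatabaseProfile]:
    """The bundled eleven-database configuration at a given prevalence."""
    return [
        profile_from_performance(name, cov, se, ppv, prevalence, is_registry=reg)
        for name, (cov, se, ppv, reg) in _DEFAULT_PROFILE_PARAMS.items()
    ]


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Seeded referral population with demographics and latent disease status.

    Ages are drawn from a normal truncated at ``age_min`` (adults only);
    demographic fields are sampled independently — only marginals are
    targeted.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    d = config.demographics
    a = (d.age_min - d.age_mean) / d.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=d.age_mean, scale=d.age_sd, size=n, random_state=rng
    )
    eth_p = np.asarray(d.ethnicity_fractions, dtype=float)
    eth_p = eth_p / eth_p.sum()
    y0, y1 = config.year_range
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "disease_status": rng.random(n) < config.disease_prevalence,
            "age": np.round(age, 1),
            "sex": np.where(rng.random(n) < d.female_fraction, "female", "male"),
            "ethnicity": rng.choice(ETHNICITY_LEVELS, size=n, p=eth_p),
            "imd_decile": rng.choice(np.arange(1, 11), size=n, p=d.imd_probabilities()),
            "referral_year": rng.integers(y0, y1 + 1, size=n),
        }
    )


def generate_membership(
    population: pd.DataFrame,
    profiles: list[DatabaseProfile],
    seed: int = 0,
) -> pd.DataFrame:
    """Binary patient × database flag matrix.

    One column per database; a patient is flagged iff covered by the
    database *and* flagged according to their disease status.  Absent
    records are 0, never null, so the matrix is complete by construction.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate database names in profiles: {names}")
    rng = np.random.default_rng(seed)
    disease = population["disease_status"].to_numpy(dtype=bool)
    n = len(population)
    cols = {}
    for prof in profiles:
        covered = rng.random(n) < prof.coverage
        p_flag = np.where(
            disease, prof.effective_sensitivity, prof.flag_false_positive_rate
        )
        cols[prof.name] = (covered & (rng.random(n) < p_flag)).astype(int)
    return pd.DataFrame(cols, index=pd.Index(population["patient_id"], name="patient_id"))


# Template families; "{term}" is filled with a normalized disease term or
# a synonym surface form.  Confounders carry other colitides that the
# permissive 'olitis' pattern is known to over-match.
_DEFAULT_TEMPLATES: dict[str, list[str]] = {
    "positive": [
        "Diagnosis: {term}. Continues on current maintenance therapy.",
        "Known {term}, clinically stable at today's review.",
        "Features in keeping with {term}; plan repeat biomarkers in 3 months.",
    ],
    "synonym": [
        "Known {term}, seen in clinic today, no new symptoms.",
        "Background of {term}; medication compliance discussed.",
    ],
    "confounder": [
        "Appearances suggestive of ischaemic colitis in the splenic flexure.",
        "Findings consistent with ischemic colitis; no chronicity.",
        "Sigmoid diverticulosis with features of diverticular colitis.",
        "Histology shows infective colitis; no granulomata identified.",
    ],
    "negative": [
        "Normal colonoscopy to caecum. No abnormality seen.",
        "Unremarkable mucosa throughout; biopsies taken from the sigmoid.",
        "Review of reflux symptoms; gastroscopy shows mild gastritis only.",
        "Normal small bowel series. Reassured and discharged.",
    ],
}

_POSITIVE_TERMS = list(
    (
        "Ulcerative Colitis",
        "Crohn's Disease",
        "IBD",
        "Inflammatory Bowel Disease",
        "Proctitis",
    )
)
_SYNONYM_TERMS = ["UC", "crohns", "IBD-U", "ibdu"]


def default_templates() -> dict[str, list[str]]:
    return {k: list(v) for k, v in _DEFAULT_TEMPLATES.items()}


def generate_documents(
    population: pd.DataFrame,
    templates: dict[str, list[str]] | None = None,
    terms: list[str] | None = None,
    seed: int = 0,
    p_disease_term: float = 0.9,
    confounder_fraction: float = 0.10,
    doc_coverage: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Template clinical documents for the three free-text sources.

    Each diseased patient's documents carry a disease term (verbatim or as
    a synonym needing normalization) with probability ``p_disease_term``;
    a ``confounder_fraction`` of disease-free patients receive a
    confounder document (another colitis) — concentrated in clinic
    letters, so letter-flag precision sits below endoscopy precision, as
    observed in practice.
    """
    templates = templates or default_templates()
    for family in ("positive", "synonym", "confounder", "negative"):
        if not templates.get(family):
            raise ValueError(f"template set must include non-empty {family!r} variants")
    terms = terms or _POSITIVE_TERMS
    doc_coverage = doc_coverage or {
        "letter": 0.945,
        "endoscopy": 0.60,
        "histopathology": 0.45,
    }
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    disease = population["disease_status"].to_numpy(dtype=bool)
    for pid, sick in zip(population["patient_id"], disease):
        for doc_type, cov in doc_coverage.items():
            if rng.random() >= cov:
                continue
            # letters attract the bulk of loose confounder language
            conf_weight = 1.0 if doc_type == "letter" else 0.25
            if sick and rng.random() < p_disease_term:
                if rng.random() < 0.3:
                    text = rng.choice(templates["synonym"]).format(
                        term=rng.choice(_SYNONYM_TERMS)
                    )
                else:
                    text = rng.choice(templates["positive"]).format(
                        term=rng.choice(terms)
                    )
            elif not sick and rng.random() < confounder_fraction * conf_weight:
                text = rng.choice(templates["confounder"])
            else:
                text = rng.choice(templates["negative"])
            rows.append({"patient_id": pid, "doc_type": doc_type, "text": text})
    return pd.DataFrame(rows, columns=["patient_id", "doc_type", "text"])


def sample_gold_standard(
    membership: pd.DataFrame,
    disease_status: pd.Series,
    n: int = 2800,
    min_databases: int = 2,
    split_fraction: float = 0.3,
    target_prevalence: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Chart-review gold standard drawn from multi-database patients.

    Eligibility requires presence (a flag) in at least ``min_databases``
    databases — the sampling restriction real validation cohorts apply,
    which under-represents single-database patients.  Stratified sampling
    targets ``target_prevalence`` disease-positive labels; the labels are
    the true disease status (chart review is assumed perfect).  A seeded
    shuffle assigns ``split_fraction`` of the sample to the validation
    split (ceiling) and the rest to training.

    Returns a frame with ``patient_id``, ``label`` (0/1) and ``split``.
    """
    if min_databases < 1:
        raise ValueError("min_databases must be >= 1")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie strictly in (0, 1)")
    status = disease_status.reindex(membership.index)
    eligible = membership.sum(axis=1) >= min_databases
    pos_pool = membership.index[eligible & status.astype(bool)]
    neg_pool = membership.index[eligible & ~status.astype(bool)]
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * target_prevalence))
    n_neg = n - n_pos
    if len(pos_pool) < n_pos or len(neg_pool) < n_neg:
        raise ValueError(
            f"not enough eligible patients for a gold standard of {n}: need "
            f"{n_pos} positive (have {len(pos_pool)}) and {n_neg} negative "
            f"(have {len(neg_pool)}) with >= {min_databases} databases"
        )
    chosen = np.concatenate(
        [
            rng.choice(pos_pool, size=n_pos, replace=False),
            rng.choice(neg_pool, size=n_neg, replace=False),
        ]
    )
    rng.shuffle(chosen)
    n_val = int(np.ceil(split_fraction * n))
    split = np.array(["validation"] * n_val + ["training"] * (n - n_val))
    return pd.DataFrame(
        {
            "patient_id": chosen,
            "label": status.loc[chosen].astype(int).to_numpy(),
            "split": split,
        }
    )
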