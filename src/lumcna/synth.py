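"""Synthetic METABRIC-like luminal breast cancer cohort generator.

Emulates, at desk scale, the data the pipeline consumes: a discrete
gene-by-patient CNA call matrix whose per-patient alteration burden differs
by PAM50 subtype (luminal B tumours are stochastically more unstable than
luminal A), a clinical table with the covariates of the final multivariable
model, survival times drawn from a proportional-hazards model whose true
log-hazard coefficients default to the published model estimates, and
expression-quantile labels whose distribution shifts upward with the
patient's CNA burden.

Quartile membership entering the linear predictor is computed from the
*generated* scores through the real scoring path, so an end-to-end run
exercises exactly the code a real cohort would.

Censoring is administrative: patients enter uniformly over an accrual
window and follow-up is truncated at the study horizon (337 months), with
the entry window and baseline hazard calibrated so that mean follow-up is
about 130.5 months and roughly 35% of patients have a disease-specific
event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cna_score import score_and_quartile
from .io import DEFAULT_SCHEMA, ClinicalTable, CnaMatrix, QuantileLabels
from .survkit import PAPER_FORMULA, design_from_frame

#: True log-hazard coefficients: the published final multivariable model
#: (reference levels lumA, grade 1, HER2-negative, CNA Q1).
TABLE1_BETAS: dict[str, float] = {
    "pam50[lumB]": 1.069,
    "grade[2]": 0.381,
    "grade[3]": 0.528,
    "tumour_size": 0.015,
    "positive_lymph_nodes": 0.050,
    "age_at_diagnosis": 0.018,
    "her2_status[positive]": 0.541,
    "quartile[Q2]": 0.315,
    "quartile[Q3]": 0.767,
    "quartile[Q4]": 0.839,
    "quartile[Q2]:pam50[lumB]": -0.764,
    "quartile[Q3]:pam50[lumB]": -0.730,
    "quartile[Q4]:pam50[lumB]": -0.909,
}

_SUBSTREAMS = ("subtype", "cna", "covariates", "times", "censoring", "labels")


@dataclass
class CohortConfig:
    """Stated world of the generator; defaults are the METABRIC-like cohort."""

    n_patients: int = 1175
    n_genes: int = 22247  # gene count of the cBioPortal data_CNA file
    p_lumb: float = 0.42  # luminal-B fraction among luminal cases

    # Per-patient gene-alteration probability ~ Beta(a, b), by subtype.  The
    # beta spread stands in for the segment-level correlation of real CNA
    # profiles (whole chromosome arms gained/lost together), which is what
    # gives real burden scores their wide dispersion.
    alteration_beta_luma: tuple = (2.0, 9.1)  # mean 0.18
    alteration_beta_lumb: tuple = (2.5, 5.8)  # mean 0.30
    #: category weights over calls (-2, -1, +1, +2) given a gene is altered
    call_weights: tuple = (0.05, 0.45, 0.40, 0.10)

    # covariate marginals (independent draws; joint correlations unmodelled)
    age_mean: float = 61.0
    age_sd: float = 10.0
    size_log_mean: float = 3.1  # lognormal, median ~22 mm
    size_log_sd: float = 0.5
    nodes_nb_n: float = 0.8  # negative binomial positive-node count
    nodes_nb_p: float = 0.35
    grade_probs_luma: tuple = (0.20, 0.55, 0.25)
    grade_probs_lumb: tuple = (0.05, 0.40, 0.55)
    her2_pos_luma: float = 0.05
    her2_pos_lumb: float = 0.15

    #: true log-hazard coefficients keyed by design-column names
    coefficients: dict = field(default_factory=lambda: dict(TABLE1_BETAS))
    formula: str = PAPER_FORMULA

    # calibrated once by simulation to mean follow-up ~130.5 months with a
    # ~35% disease-specific event fraction under the default coefficients
    baseline_dist: str = "exponential"
    baseline_rate: float = 3.9e-3  # per month, after centring the linear predictor
    max_follow_up: float = 337.0  # administrative horizon, months
    accrual_fraction: float = 0.82  # entry uniform over this fraction of the horizon
    p_disease_death: float = 0.70  # P(death is disease-specific | death)

    quantile_noise: float = 1.5  # logistic noise on the score->quantile latent

    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_lumb,
            self.her2_pos_luma,
            self.her2_pos_lumb,
            self.p_disease_death,
            self.accrual_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        for a, b in (self.alteration_beta_luma, self.alteration_beta_lumb):
            # a == 0 is the degenerate "no alterations" case (rate exactly 0)
            if a < 0 or b <= 0:
                raise ValueError("beta parameters must be positive (a may be 0)")
        w = np.asarray(self.call_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("call weights must be a probability vector")
        for p in self.grade_probs_luma, self.grade_probs_lumb:
            if not np.isclose(sum(p), 1.0):
                raise ValueError("grade probabilities must sum to 1")
        if self.baseline_dist != "exponential":
            raise ValueError("only the exponential baseline is implemented")
        if self.baseline_rate <= 0 or self.max_follow_up <= 0:
            raise ValueError("baseline rate and follow-up horizon must be positive")

    def mean_abs_call(self) -> float:
        """E|call| for an altered gene."""
        w = np.asarray(self.call_weights)
        return float(w @ np.abs([-2, -1, 1, 2]))

    def expected_score(self, subtype: str) -> float:
        """Closed-form expected CNA Score for one subtype."""
        a, b = (
            self.alteration_beta_luma if subtype == "lumA" else self.alteration_beta_lumb
        )
        return self.n_genes * (a / (a + b)) * self.mean_abs_call()

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("alteration_beta_luma", "alteration_beta_lumb", "call_weights",
                    "grade_probs_luma", "grade_probs_lumb"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def default_metabric_like_config(seed: int = 0) -> CohortConfig:
    """The stated-world default: n = 1175, published-model true coefficients,
    censoring calibrated to mean follow-up ~130.5 months, maximum 337."""
    cfg = CohortConfig(seed=seed)
    cfg.validate()
    return cfg


def _rng(config: CohortConfig, name: str) -> np.random.Generator:
    """Named substream so components can be varied independently."""
    idx = _SUBSTREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(len(_SUBSTREAMS))[idx])


def _draw_subtypes(config: CohortConfig) -> np.ndarray:
    rng = _rng(config, "subtype")
    return np.where(rng.random(config.n_patients) < config.p_lumb, "lumB", "lumA")


def _patient_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def generate_cna_matrix(
    config: CohortConfig, subtypes: np.ndarray | None = None
) -> CnaMatrix:
    """Gene x patient call matrix with subtype-dependent alteration burden."""
    config.validate()
    if subtypes is None:
        subtypes = _draw_subtypes(config)
    rng = _rng(config, "cna")
    n, g = config.n_patients, config.n_genes
    a_a, b_a = config.alteration_beta_luma
    a_b, b_b = config.alteration_beta_lumb
    is_b = subtypes == "lumB"
    rate_a = rng.beta(a_a, b_a, size=n) if a_a > 0 else np.zeros(n)
    rate_b = rng.beta(a_b, b_b, size=n) if a_b > 0 else np.zeros(n)
    rates = np.where(is_b, rate_b, rate_a)
    # altered? then which category (searchsorted over cumulative weights)
    calls = np.zeros((g, n), dtype=np.float64)
    values = np.array([-2.0, -1.0, 1.0, 2.0])
    cum_w = np.cumsum(config.call_weights)
    # column-blocked to bound transient memory on large gene counts
    block = max(1, int(4e7) // max(g, 1))
    for start in range(0, n, block):
        stop = min(n, start + block)
        u = rng.random((g, stop - start))
        altered = u < rates[None, start:stop]
        v = rng.random((int(altered.sum()),))
        calls[:, start:stop][altered] = values[np.searchsorted(cum_w, v)]
    index = pd.MultiIndex.from_arrays(
        [[f"G{i:05d}" for i in range(1, g + 1)], [str(i) for i in range(1, g + 1)]],
        names=["gene_symbol", "gene_id"],
    )
    frame = pd.DataFrame(calls, index=index, columns=_patient_ids(n), copy=False)
    return CnaMatrix(frame)


def _draw_covariates(config: CohortConfig, subtypes: np.ndarray) -> pd.DataFrame:
    rng = _rng(config, "covariates")
    n = config.n_patients
    is_b = subtypes == "lumB"
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 25.0, 95.0)
    size = np.clip(rng.lognormal(config.size_log_mean, config.size_log_sd, n), 1.0, 180.0)
    nodes = rng.negative_binomial(config.nodes_nb_n, config.nodes_nb_p, n).astype(float)
    grade = np.empty(n, dtype=object)
    u = rng.random(n)
    for mask, probs in (
        (~is_b, np.cumsum(config.grade_probs_luma)),
        (is_b, np.cumsum(config.grade_probs_lumb)),
    ):
        grade[mask] = np.array(["1", "2", "3"])[np.searchsorted(probs, u[mask])]
    her2 = np.where(
        rng.random(n) < np.where(is_b, config.her2_pos_lumb, config.her2_pos_luma),
        "positive",
        "negative",
    )
    frame = pd.DataFrame(
        {
            "pam50": pd.Categorical(subtypes, categories=["lumA", "lumB"], ordered=True),
            "grade": pd.Categorical(grade, categories=["1", "2", "3"], ordered=True),
            "tumour_size": np.round(size, 1),
            "positive_lymph_nodes": nodes,
            "age_at_diagnosis": np.round(age, 1),
            "her2_status": pd.Categorical(
                her2, categories=["negative", "positive"], ordered=True
            ),
        },
        index=pd.Index(_patient_ids(n), name="patient_id"),
    )
    return frame


def generate_cohort(
    config: CohortConfig | None = None, return_truth: bool = False
):
    """Generate (CnaMatrix, ClinicalTable, QuantileLabels) from the config.

    Event times follow h(t) = h0 * exp(lp) with lp built from the patient's
    generated design row (quartiles computed from the generated scores via
    the real scoring path) and the configured true coefficients, centred
    over the cohort so the baseline rate is interpretable.  Disease-specific
    events are thinned from overall deaths with the configured probability;
    other-cause deaths are DSS-censored at the death time.
    """
    if config is None:
        config = default_metabric_like_config()
    config.validate()
    subtypes = _draw_subtypes(config)
    cna = generate_cna_matrix(config, subtypes)
    covs = _draw_covariates(config, subtypes)

    # real scoring path: scores -> ranked quartiles
    score = score_and_quartile(cna)
    frame = covs.join(score.table)
    design = design_from_frame(frame, config.formula)
    missing = [k for k in config.coefficients if k not in design.columns]
    if missing:
        raise ValueError(f"coefficient keys not in design: {missing}")
    beta = np.array([config.coefficients.get(c, 0.0) for c in design.columns])
    lp = design.to_numpy(dtype=float) @ beta
    lp_c = lp - lp.mean()

    rng_t = _rng(config, "times")
    death_time = rng_t.exponential(1.0 / (config.baseline_rate * np.exp(lp_c)))
    rng_c = _rng(config, "censoring")
    horizon = config.max_follow_up
    entry = rng_c.uniform(0.0, config.accrual_fraction * horizon, config.n_patients)
    censor_time = horizon - entry  # administrative follow-up window
    os_months = np.minimum(death_time, censor_time)
    os_event = (death_time <= censor_time).astype(int)
    disease = rng_t.random(config.n_patients) < config.p_disease_death
    dss_event = (os_event == 1) & disease
    clinical_frame = covs.copy()
    clinical_frame["os_months"] = np.round(os_months, 2)
    clinical_frame["os_event"] = os_event
    clinical_frame["dss_months"] = np.round(os_months, 2)
    clinical_frame["dss_event"] = dss_event.astype(int)
    clinical = ClinicalTable(clinical_frame, schema=DEFAULT_SCHEMA)

    # expression-quantile labels: latent = standardized score + logistic
    # noise, sliced into cohort quarters -> P(higher q) increases with score
    rng_l = _rng(config, "labels")
    z = (score.scores - score.scores.mean()) / max(score.scores.std(), 1e-12)
    latent = z.to_numpy() + rng_l.logistic(0.0, config.quantile_noise, config.n_patients)
    ranks = np.argsort(np.argsort(latent, kind="stable"), kind="stable")
    qlab = np.array(["q1", "q2", "q3", "q4"])[
        np.minimum(3, (4 * ranks) // config.n_patients)
    ]
    labels = QuantileLabels(
        pd.Series(qlab, index=clinical_frame.index, name="tish_quantile")
    )
    if return_truth:
        truth = {
            "lp": lp,
            "design_columns": list(design.columns),
            "beta": beta,
            "score": score,
            "subtypes": subtypes,
        }
        return cna, clinical, labels, truth
    return cna, clinical, labels
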