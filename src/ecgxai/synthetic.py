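"""Synthetic ECG-parameter populations with planted reduced-LVEF phenotypes.

Real paired ECG/echocardiography datasets of this kind are hospital data and
are not publicly deposited, so this module generates populations whose
structure mirrors them: roughly 9-10% prevalence of reduced LVEF, repeated
ECGs per patient, a paced-rhythm subpopulation, and -- crucially -- reduced-LVEF
*phenotype subgroups* whose parameter shifts realise recognisable combinations
of classic ECG findings (lateral T-wave inversion, low voltage, precordial Q
waves, ventricular activation time prolongation, S-wave prolongation in V2-3,
QTc prolongation).  Because the phenotype of every record is known, every
downstream stage (classification, attribution, clustering, decision-factor
extraction) has a ground truth to recover.

Model
-----
Each patient is drawn from a mixture: a healthy class plus K phenotype
classes.  Standardised parameter noise is equicorrelated within each lead
(coefficient ``correlation``) and independent across leads; phenotypes shift
the means of their affected parameters by a stated number of baseline SDs.
LVEF is drawn per record from the class's Gaussian (healthy ~N(62,8), diseased
~N(33,8) by default) and thresholded at 40% for the label -- so labels are
noisy relative to phenotype, keeping AUROC below 1 and criteria extraction
honest.  Pacing is independent of class and widens QRS duration.

Because every class shares one covariance, the true posterior
P(reduced LVEF | parameters) has a closed form; ``bayes_posterior_scores``
evaluates it, which gives a Monte-Carlo estimate of the Bayes-optimal AUROC
that learned classifiers can be benchmarked against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .datamodel import PairedDataset, REDUCED_LVEF_THRESHOLD
from .evalstats import ReaderStudy
from .schema import LEADS, ParameterSchema, default_schema, lead_param

# ---------------------------------------------------------------------------
# baseline population constants
# ---------------------------------------------------------------------------

#: baseline (mean, SD) per per-lead parameter kind -- conventional adult
#: resting-ECG magnitudes (amplitudes in mV, times in ms)
LEAD_KIND_BASELINES: dict[str, tuple[float, float]] = {
    "R_amp": (0.80, 0.35),
    "S_amp": (0.50, 0.30),      # magnitude of the S deflection
    "Q_amp": (0.05, 0.05),      # magnitude of the Q deflection
    "T_amp": (0.25, 0.15),
    "P_amp": (0.10, 0.05),
    "ST_level": (0.00, 0.05),
    "R_dur": (40.0, 12.0),
    "S_dur": (35.0, 12.0),
    "Q_dur": (10.0, 8.0),
    "P_dur": (100.0, 15.0),
    "T_dur": (160.0, 25.0),
    "VAT": (35.0, 10.0),
    "QTc_lead": (435.0, 34.0),
    "RR_lead": (828.0, 150.0),
}

#: baseline (mean, SD) per global parameter; HR/PR/QRS/QTc match the kind of
#: summary statistics reported for large hospital ECG populations
GLOBAL_BASELINES: dict[str, tuple[float, float]] = {
    "HR": (74.0, 15.4),
    "PR_interval": (171.5, 43.9),
    "QRS_duration": (105.8, 22.6),
    "QT_interval": (396.9, 40.0),
    "QTc": (435.0, 34.1),
    "QRS_axis": (28.1, 45.3),
    "P_axis": (41.5, 34.8),
    "RR_interval": (828.0, 150.0),
    "age": (63.4, 16.9),
    "sex": (0.565, 0.5),        # Bernoulli male fraction; SD nominal
}

MALE_FRACTION = 0.565
PACED_QRS_SHIFT_SD = 2.5        # pacing widens QRS by ~2.5 baseline SDs (~56 ms)
HEALTHY_LVEF = (62.0, 8.0)


def baseline_mean_sd(schema: ParameterSchema) -> tuple[np.ndarray, np.ndarray]:
    """Baseline mean and SD vectors aligned to the schema."""
    mean = np.empty(len(schema))
    sd = np.empty(len(schema))
    for i, e in enumerate(schema.entries):
        m, s = (GLOBAL_BASELINES if e.lead == "GLOBAL" else LEAD_KIND_BASELINES)[e.kind]
        mean[i], sd[i] = m, s
    return mean, sd


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSpec:
    """A reduced-LVEF subgroup with a planted ECG signature.

    ``affected_parameters`` maps schema names to signed shifts in baseline-SD
    units (negative = the parameter is pushed down).  ``finding_set`` names the
    canonical finding categories the signature realises.
    """

    name: str
    finding_set: tuple[str, ...]
    affected_parameters: list[tuple[str, float]]
    mixing_weight: float
    lvef_mean: float = 33.0
    lvef_sd: float = 8.0

    @property
    def affected_names(self) -> list[str]:
        return [n for n, _ in self.affected_parameters]


#: effect sizes in baseline SDs: findings *shared* between phenotypes are
#: planted at the overt-abnormality level, while each phenotype's hallmark
#: findings are planted stronger -- a cluster is defined by what sets it apart
SHARED_SHIFT = 2.5
HALLMARK_SHIFT = 3.5


def default_phenotypes() -> list[PhenotypeSpec]:
    """Five reduced-LVEF phenotypes with distinct, partially overlapping signatures.

    The five signatures realise the classic finding combinations seen in
    attribution clusters of reduced-LVEF classifiers: lateral negative T waves,
    low QRS voltage, precordial Q waves, VAT prolongation, S-wave prolongation
    in V2-3 and QTc prolongation, in five different arrangements (two of them
    sharing the same category combination but on different lead sets).  Mixing
    weights are equal before prevalence calibration.
    """
    s, h = SHARED_SHIFT, HALLMARK_SHIFT

    def tinv(leads):
        return [(lead_param("T_amp", ld), -s) for ld in leads]

    p1 = PhenotypeSpec(
        "tinv_lowvolt_sprol",
        ("NEG_T_INVERSION_I_V56", "LOW_VOLTAGE_I_II_V46", "S_PROLONG_V23"),
        tinv(["I", "V5", "V6"])
        + [(lead_param("R_amp", ld), -s) for ld in ["II", "V4", "V5"]]
        + [(lead_param("S_dur", ld), h) for ld in ["V2", "V3"]],
        mixing_weight=1.0,
    )
    p2 = PhenotypeSpec(
        "tinv_vat_qtc_right",
        ("NEG_T_INVERSION_I_V56", "VAT_PROLONG_I_V56", "S_PROLONG_V23", "QTC_PROLONG"),
        tinv(["I", "V5", "V6"])
        + [(lead_param("VAT", ld), h) for ld in ["V5", "V6"]]
        + [(lead_param("QTc_lead", ld), h) for ld in ["V1", "V2", "V3"]]
        + [(lead_param("S_dur", "V3"), s)],
        mixing_weight=1.0,
    )
    p3 = PhenotypeSpec(
        "lowvolt_qwave",
        ("LOW_VOLTAGE_I_II_V46", "Q_WAVE_V36"),
        [(lead_param("R_amp", ld), -s) for ld in ["II", "V4", "V5"]]
        + [(lead_param("Q_dur", ld), h) for ld in ["V4", "V5", "V6"]]
        + [(lead_param("Q_amp", "V4"), h)],
        mixing_weight=1.0,
    )
    p4 = PhenotypeSpec(
        "tinv_vat_qtc_wide",
        ("NEG_T_INVERSION_I_V56", "VAT_PROLONG_I_V56", "S_PROLONG_V23", "QTC_PROLONG"),
        tinv(["I", "V5", "V6"])
        + [(lead_param("VAT", ld), h) for ld in ["I", "aVL"]]
        + [(lead_param("QTc_lead", ld), h) for ld in ["III", "aVL", "V4", "V5"]]
        + [(lead_param("S_dur", "V2"), s)],
        mixing_weight=1.0,
    )
    p5 = PhenotypeSpec(
        "tinv_lowvolt_qwave",
        ("NEG_T_INVERSION_I_V56", "LOW_VOLTAGE_I_II_V46", "Q_WAVE_V36"),
        tinv(["I", "V5", "V6"])
        + [(lead_param("R_amp", ld), -s) for ld in ["II", "V4"]]
        + [(lead_param("Q_dur", ld), h) for ld in ["V3", "V4"]]
        + [(lead_param("Q_amp", "V3"), h)],
        mixing_weight=1.0,
    )
    return [p1, p2, p3, p4, p5]


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Population-level knobs of the generator.

    ``records_per_patient`` is ``("one_plus_poisson", lam)``: each patient
    contributes 1 + Poisson(lam) ECGs (lam=1 gives the ~2 records/patient seen
    in hospital ECG archives).  ``prevalence_target`` (percent) rescales the
    phenotype mixing weights so the expected label prevalence hits the target.
    ``noise_sd`` scales residual noise relative to the baseline SDs;
    ``correlation`` is the within-lead equicorrelation of that noise.
    """

    n_patients: int = 5000
    records_per_patient: tuple[str, float] = ("one_plus_poisson", 1.0)
    prevalence_target: float = 9.2
    paced_fraction: float = 0.05
    noise_sd: float = 1.0
    correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for f in (self.paced_fraction, self.correlation):
            if not 0.0 <= f < 1.0:
                raise ValueError("fractions must lie in [0, 1)")
        if not 0.0 < self.prevalence_target < 100.0:
            raise ValueError("prevalence_target is a percentage in (0, 100)")


def class_positive_probability(lvef_mean: float, lvef_sd: float) -> float:
    """P(LVEF < 40 | class) under the class's Gaussian LVEF draw."""
    return float(norm.cdf((REDUCED_LVEF_THRESHOLD - lvef_mean) / lvef_sd))


def expected_prevalence(phenotypes: Sequence[PhenotypeSpec],
                        healthy_lvef: tuple[float, float] = HEALTHY_LVEF) -> float:
    """Closed-form expected label prevalence (percent) of the mixture."""
    w = np.array([p.mixing_weight for p in phenotypes])
    if w.sum() >= 1.0:
        raise ValueError("phenotype weights must leave room for the healthy class")
    q = np.array([class_positive_probability(p.lvef_mean, p.lvef_sd) for p in phenotypes])
    qh = class_positive_probability(*healthy_lvef)
    return 100.0 * float((w * q).sum() + (1.0 - w.sum()) * qh)


def calibrate_weights(phenotypes: Sequence[PhenotypeSpec], cfg: GeneratorConfig,
                      healthy_lvef: tuple[float, float] = HEALTHY_LVEF
                      ) -> list[PhenotypeSpec]:
    """Rescale mixing weights so expected prevalence equals the config target."""
    w = np.array([p.mixing_weight for p in phenotypes], dtype=float)
    q = np.array([class_positive_probability(p.lvef_mean, p.lvef_sd) for p in phenotypes])
    qh = class_positive_probability(*healthy_lvef)
    target = cfg.prevalence_target / 100.0
    denom = float((w * (q - qh)).sum())
    if denom <= 0:
        raise ValueError("phenotypes are not more diseased than the healthy class")
    s = (target - qh) / denom
    if s <= 0 or s * w.sum() >= 1.0:
        raise ValueError("prevalence target unreachable with these phenotypes")
    return [replace(p, mixing_weight=float(s * wi)) for p, wi in zip(phenotypes, w)]


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def _class_shift_matrix(phenotypes: Sequence[PhenotypeSpec],
                        schema: ParameterSchema) -> np.ndarray:
    """(1 + K) x p matrix of mean shifts in SD units; row 0 is healthy."""
    shifts = np.zeros((1 + len(phenotypes), len(schema)))
    for k, ph in enumerate(phenotypes, start=1):
        for name, s in ph.affected_parameters:
            if name not in schema:
                raise ValueError(
                    f"phenotype {ph.name!r} shifts unknown parameter {name!r}")
            shifts[k, schema.index(name)] = s
    return shifts


def generate_population(cfg: GeneratorConfig,
                        phenotypes: Optional[Sequence[PhenotypeSpec]] = None,
                        schema: Optional[ParameterSchema] = None,
                        calibrate: bool = True,
                        ) -> tuple[PairedDataset, pd.DataFrame]:
    """Draw a patient population; returns (dataset, truth table).

    The truth table (record_id, patient_id, phenotype) is returned as a
    separate frame -- it is never written into the dataset, so downstream
    stages cannot read it accidentally.
    """
    schema = schema or default_schema()
    phenotypes = list(default_phenotypes() if phenotypes is None else phenotypes)
    if calibrate:
        phenotypes = calibrate_weights(phenotypes, cfg)
    rng = np.random.default_rng(cfg.seed)

    weights = np.array([p.mixing_weight for p in phenotypes])
    class_p = np.concatenate([[1.0 - weights.sum()], weights])
    class_names = ["healthy"] + [p.name for p in phenotypes]
    lvef_mean = np.array([HEALTHY_LVEF[0]] + [p.lvef_mean for p in phenotypes])
    lvef_sd = np.array([HEALTHY_LVEF[1]] + [p.lvef_sd for p in phenotypes])

    # patient-level draws
    n_pat = cfg.n_patients
    pat_class = rng.choice(len(class_p), size=n_pat, p=class_p)
    pat_paced = rng.random(n_pat) < cfg.paced_fraction
    dist, lam = cfg.records_per_patient
    if dist != "one_plus_poisson":
        raise ValueError(f"unknown records_per_patient distribution {dist!r}")
    n_rec_pat = 1 + rng.poisson(lam, size=n_pat)
    pat_sex = (rng.random(n_pat) < MALE_FRACTION).astype(float)

    rec_class = np.repeat(pat_class, n_rec_pat)
    rec_paced = np.repeat(pat_paced, n_rec_pat)
    rec_sex = np.repeat(pat_sex, n_rec_pat)
    rec_patient = np.repeat(np.arange(n_pat), n_rec_pat)
    n = len(rec_class)

    mean, sd = baseline_mean_sd(schema)
    shifts = _class_shift_matrix(phenotypes, schema)
    lead_of = np.array(
        [LEADS.index(e.lead) if e.lead != "GLOBAL" else -1 for e in schema.entries])

    g = rng.standard_normal((n, len(LEADS)))          # shared per-lead factors
    e = rng.standard_normal((n, len(schema)))         # independent residuals
    rho = cfg.correlation
    z = np.where(lead_of[None, :] >= 0,
                 np.sqrt(rho) * g[:, np.clip(lead_of, 0, None)] + np.sqrt(1 - rho) * e,
                 e)
    X = mean + shifts[rec_class] * sd + z * sd * cfg.noise_sd

    # non-Gaussian / deterministic columns
    if "sex" in schema:
        X[:, schema.index("sex")] = rec_sex
    if "age" in schema:
        j = schema.index("age")
        X[:, j] = np.clip(X[:, j], 18.0, None)
    if "QRS_duration" in schema:
        j = schema.index("QRS_duration")
        X[rec_paced, j] += PACED_QRS_SHIFT_SD * sd[j]

    lvef = rng.normal(lvef_mean[rec_class], lvef_sd[rec_class])
    lvef = np.clip(lvef, 0.0, 100.0)
    days = rng.integers(0, 29, size=n)

    df = pd.DataFrame(X, columns=schema.names)
    df.insert(0, "lvef", lvef)
    df.insert(0, "days_to_echo", days)
    df.insert(0, "paced", rec_paced)
    df.insert(0, "patient_id", [f"P{i:06d}" for i in rec_patient])
    df.insert(0, "record_id", [f"E{i:07d}" for i in range(n)])
    ds = PairedDataset(df, schema=schema)

    truth = pd.DataFrame({
        "record_id": ds.record_ids,
        "patient_id": ds.patient_ids,
        "phenotype": [class_names[c] for c in rec_class],
    })
    return ds, truth


# ---------------------------------------------------------------------------
# exact posterior (Bayes-optimal scores)
# ---------------------------------------------------------------------------

def bayes_posterior_scores(X: np.ndarray,
                           phenotypes: Sequence[PhenotypeSpec],
                           cfg: GeneratorConfig,
                           schema: Optional[ParameterSchema] = None,
                           calibrate: bool = True) -> np.ndarray:
    """Exact P(reduced LVEF | parameters) under the generator's own model.

    All classes share one covariance (within-lead equicorrelation), so only
    lead blocks containing at least one shifted parameter -- plus shifted
    Gaussian globals -- contribute to the posterior; sex, pacing and all
    unshifted blocks cancel exactly.
    """
    schema = schema or default_schema()
    phenotypes = list(phenotypes)
    if calibrate:
        phenotypes = calibrate_weights(phenotypes, cfg)
    weights = np.array([p.mixing_weight for p in phenotypes])
    priors = np.concatenate([[1.0 - weights.sum()], weights])
    q = np.array([class_positive_probability(*HEALTHY_LVEF)]
                 + [class_positive_probability(p.lvef_mean, p.lvef_sd)
                    for p in phenotypes])

    mean, sd = baseline_mean_sd(schema)
    shifts = _class_shift_matrix(phenotypes, schema)
    mu = mean + shifts * sd                         # (C, p) class means
    eff_sd = sd * cfg.noise_sd
    rho = cfg.correlation

    shifted_cols = np.flatnonzero((shifts != 0).any(axis=0))
    loglik = np.zeros((X.shape[0], len(priors)))

    # per-lead blocks touched by a shift: full equicorrelated quadratic form
    touched_leads = sorted({schema.entries[j].lead for j in shifted_cols
                            if schema.entries[j].lead != "GLOBAL"})
    for lead in touched_leads:
        cols = np.array([i for i, ent in enumerate(schema.entries) if ent.lead == lead])
        m = len(cols)
        # standardised residuals per class; R^-1 = a*I + b*J for equicorrelation
        a = 1.0 / (1.0 - rho)
        b = -rho / ((1.0 - rho) * (1.0 + (m - 1) * rho))
        for c in range(len(priors)):
            r = (X[:, cols] - mu[c, cols]) / eff_sd[cols]
            quad = a * (r ** 2).sum(axis=1) + b * r.sum(axis=1) ** 2
            loglik[:, c] += -0.5 * quad
    # shifted Gaussian globals (age etc.); sex/pacing columns never shift
    for j in shifted_cols:
        if schema.entries[j].lead == "GLOBAL":
            for c in range(len(priors)):
                loglik[:, c] += -0.5 * ((X[:, j] - mu[c, j]) / eff_sd[j]) ** 2

    logpost = np.log(priors) + loglik
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return np.exp(logpost) @ q


# ---------------------------------------------------------------------------
# reader studies
# ---------------------------------------------------------------------------

@dataclass
class ReaderStudyConfig:
    """Simulated multi-reader before/after ECG interpretation test.

    Sensitivities/specificities may be scalars (common to all readers) or
    per-reader sequences.  ``within_reader_correlation`` is the latent
    (Gaussian-copula) correlation between a reader's before and after reads of
    the same ECG.
    """

    n_readers: int = 7
    n_ecgs: int = 100
    positive_fraction: float = 0.5
    sens_before: Union[float, Sequence[float]] = 0.374
    spec_before: Union[float, Sequence[float]] = 0.883
    sens_after: Union[float, Sequence[float]] = 0.711
    spec_after: Union[float, Sequence[float]] = 0.766
    within_reader_correlation: float = 0.3
    seed: int = 0

    def _per_reader(self, v) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(v, dtype=float), (self.n_readers,)).copy()
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        return arr


def generate_reader_study(cfg: ReaderStudyConfig) -> ReaderStudy:
    """Draw a reader study with the configured marginal accuracies."""
    if not 0.0 <= cfg.within_reader_correlation <= 1.0:
        raise ValueError("within_reader_correlation must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    n_pos = int(round(cfg.positive_fraction * cfg.n_ecgs))
    truth = np.zeros(cfg.n_ecgs, dtype=bool)
    truth[:n_pos] = True
    rng.shuffle(truth)

    sens_b, spec_b = cfg._per_reader(cfg.sens_before), cfg._per_reader(cfg.spec_before)
    sens_a, spec_a = cfg._per_reader(cfg.sens_after), cfg._per_reader(cfg.spec_after)

    rho = cfg.within_reader_correlation
    frames = []
    for r in range(cfg.n_readers):
        h = rng.standard_normal(cfg.n_ecgs)
        zb = np.sqrt(rho) * h + np.sqrt(1 - rho) * rng.standard_normal(cfg.n_ecgs)
        za = np.sqrt(rho) * h + np.sqrt(1 - rho) * rng.standard_normal(cfg.n_ecgs)
        p_b = np.where(truth, sens_b[r], spec_b[r])
        p_a = np.where(truth, sens_a[r], spec_a[r])
        correct_b = norm.cdf(zb) < p_b
        correct_a = norm.cdf(za) < p_a
        frames.append(pd.DataFrame({
            "reader_id": f"R{r + 1}",
            "ecg_id": [f"E{i:04d}" for i in range(cfg.n_ecgs)],
            "truth": truth,
            "call_before": np.where(correct_b, truth, ~truth),
            "call_after": np.where(correct_a, truth, ~truth),
        }))
    return ReaderStudy(pd.concat(frames, ignore_index=True))


def expected_correct_rate(sens: float, spec: float, positive_fraction: float) -> float:
    """Closed-form marginal probability of a correct call."""
    return sens * positive_fraction + spec * (1.0 - positive_fraction)
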