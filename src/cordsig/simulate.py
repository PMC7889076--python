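"""Synthetic cohorts with planted effects for every pipeline stage.

Three generators share one ground truth derived from the seed:

* a collection of microarray-like expression datasets whose sizes and
  covariate-availability pattern mirror a realistic multi-study cord-blood
  compendium (11 studies, 16-146 samples, 605 samples total; each study
  reports only a subset of {sex, ga, bw, ppbmi});
* an RNA-seq replication cohort (counts, default 30 subjects) whose signal
  genes follow a negative-binomial log-linear trend in the perinatal
  risk-factor count;
* a subject-level outcome cohort (default 358 subjects) with two serum
  proteins — one linked to asthma and lung function, one null — plus the
  covariates required by adjustment models 1-3.

Signal genes carry a sign: +1 genes rise with risk (male sex, maternal
obesity, short gestation, low birthweight), -1 genes fall.  Covariates
absent from a dataset's metadata still drive its expression, since
availability is a property of the metadata, not of biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meta import COVARIATES, RISK_DIRECTION, ExpressionDataset
from .replication import count_risk_factors

#: default collection template: (dataset size, available covariates); sizes
#: and the availability pattern reproduce the column totals 386 (sex),
#: 386 (ga), 235 (bw), 164 (ppbmi) over 605 samples
DATASET_TEMPLATE = (
    (37, ("ppbmi",)),
    (20, ("sex",)),
    (64, ("ga", "bw", "ppbmi")),
    (47, ("ga", "bw", "ppbmi")),
    (48, ("ga", "bw")),
    (38, ("sex", "ga", "bw")),
    (38, ("sex", "ga", "bw")),
    (128, ("sex", "ga")),
    (16, ("sex", "ppbmi")),
    (23, ("ga",)),
    (146, ("sex",)),
)

# obstetric marginals (not estimates of any real cohort; configurable)
GA_MEAN, GA_SD = 39.2, 1.8
BW_MEAN, BW_SD = 3400.0, 500.0
GA_BW_CORR = 0.5
BMI_MEAN, BMI_SD = 26.5, 5.5
BMI_CUTS = (18.5, 25.0, 30.0)  # ordinal category 0-3


@dataclass
class SimulationConfig:
    n_datasets: int = len(DATASET_TEMPLATE)
    dataset_sizes: tuple = tuple(s for s, _ in DATASET_TEMPLATE)
    availability_mask: tuple = tuple(m for _, m in DATASET_TEMPLATE)
    n_genes: int = 2000
    n_signal_genes: int = 50
    signal_effect: float = 0.6
    noise_sd: float = 1.0
    rnaseq_n: int = 30
    rnaseq_dispersion: float = 0.1
    outcome_n: int = 358
    protein_log_or: float = math.log(0.5)
    fevfvc_beta: float = 1.15
    seed: int = 0
    ga_bw_corr: float = GA_BW_CORR
    protein_effect_modifier: str | None = None
    modifier_interaction: float = 0.0
    outcome_missing_rate: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_datasets": self.n_datasets,
            "n_genes": self.n_genes,
            "n_signal_genes": self.n_signal_genes,
            "rnaseq_n": self.rnaseq_n,
            "outcome_n": self.outcome_n,
        }
        for name, value in counts.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive")
        if len(self.dataset_sizes) != self.n_datasets:
            raise ValueError("dataset_sizes length must equal n_datasets")
        if len(self.availability_mask) != self.n_datasets:
            raise ValueError("availability_mask length must equal n_datasets")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        for mask in self.availability_mask:
            if not mask:
                raise ValueError("availability_mask entries must be non-empty")
            unknown = set(mask) - set(COVARIATES)
            if unknown:
                raise ValueError(f"unknown covariates in mask: {sorted(unknown)}")
        if any(s < 4 for s in self.dataset_sizes):
            raise ValueError("dataset sizes below 4 give no within-study variance")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.rnaseq_dispersion < 0:
            raise ValueError("rnaseq_dispersion must be nonnegative")


@dataclass
class GroundTruth:
    signal_genes: tuple
    signs: pd.Series = field(repr=False)  # +1 / -1 for signal genes, 0 otherwise
    protein_params: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = set(self.signs.loc[list(self.signal_genes)])
        if not vals <= {-1, 1}:
            raise ValueError("signal gene signs must be +/-1")
        if not set(self.signs.drop(list(self.signal_genes))) <= {0}:
            raise ValueError("non-signal genes must have effect 0")


def _gene_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"G{i:0{width}d}" for i in range(1, n + 1)], name="gene")


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_ids(config.n_genes)
    signs = pd.Series(0, index=genes, dtype=int)
    chosen = rng.choice(config.n_genes, config.n_signal_genes, replace=False)
    signs.iloc[np.sort(chosen)] = rng.choice([-1, 1], config.n_signal_genes)
    signal = tuple(genes[np.sort(chosen)])
    return GroundTruth(
        signal_genes=signal,
        signs=signs,
        protein_params={
            "protein_log_or": config.protein_log_or,
            "fevfvc_beta": config.fevfvc_beta,
        },
    )


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size)
    while True:
        bad = (out < low) | (out > high)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())


def _draw_perinatal_covariates(rng, n, ga_bw_corr):
    sex = rng.integers(0, 2, n)
    ga = _truncated_normal(rng, GA_MEAN, GA_SD, 24.0, 42.0, n)
    z_ga = (ga - GA_MEAN) / GA_SD
    bw = BW_MEAN + BW_SD * (
        ga_bw_corr * z_ga + math.sqrt(1.0 - ga_bw_corr**2) * rng.normal(size=n)
    )
    bmi = np.maximum(rng.normal(BMI_MEAN, BMI_SD, n), 14.0)
    ppbmi_cat = np.digitize(bmi, BMI_CUTS)
    return pd.DataFrame(
        {"sex": sex, "ga": ga, "bw": bw, "ppbmi": ppbmi_cat, "bmi": bmi}
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v, dtype=float)


def simulate_microarray_collection(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate the multi-dataset expression collection with planted effects.

    Expression = gene baseline + dataset shift + sum over covariates of
    sign * risk-direction * signal_effect * standardized covariate + noise.
    All four covariates always drive expression; each dataset's metadata only
    exposes its availability mask.
    """
    truth = _ground_truth(config)
    genes = truth.signs.index
    base_rng = np.random.default_rng([config.seed, 4])
    baseline = base_rng.normal(7.0, 1.0, config.n_genes)
    effect = truth.signs.to_numpy(float) * config.signal_effect
    datasets = []
    for k, (size, mask) in enumerate(
        zip(config.dataset_sizes, config.availability_mask)
    ):
        rng = np.random.default_rng([config.seed, 1, k])
        cov = _draw_perinatal_covariates(rng, size, config.ga_bw_corr)
        cov.index = pd.Index([f"ds{k + 1:02d}_s{j + 1:03d}" for j in range(size)],
                             name="sample")
        shift = rng.normal(0.0, 0.5)
        x = baseline[:, None] + shift + rng.normal(0.0, config.noise_sd,
                                                   (config.n_genes, size))
        for c in COVARIATES:
            std = _standardize(cov[c].to_numpy(float))
            x += np.outer(effect * RISK_DIRECTION[c], std)
        matrix = pd.DataFrame(x, index=genes, columns=cov.index)
        datasets.append(
            ExpressionDataset(
                dataset_id=f"ds{k + 1:02d}",
                matrix=matrix,
                covariates=cov[list(mask)],
                availability=frozenset(mask),
            )
        )
    return datasets, truth


def simulate_rnaseq_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Count matrix + covariates for the replication cohort.

    Counts are NB with log-mean linear in the risk-factor count for signal
    genes (slope = sign * signal_effect) and library sizes varying 2-fold.
    Returns (counts genes x subjects, covariate table, ground truth).
    """
    truth = _ground_truth(config)
    rng = np.random.default_rng([config.seed, 2])
    n = config.rnaseq_n
    cov = _draw_perinatal_covariates(rng, n, config.ga_bw_corr)
    cov["csection"] = (rng.random(n) < 0.25).astype(int)
    cov = cov.rename(columns={"ppbmi": "ppbmi_cat"}).rename(columns={"bmi": "ppbmi"})
    cov.index = pd.Index([f"subj{j + 1:02d}" for j in range(n)], name="subject")
    risk = count_risk_factors(cov[["sex", "ga", "bw", "ppbmi"]], "uih")
    cov["risk_count"] = risk

    log_base = rng.normal(5.0, 1.2, config.n_genes)
    slope = truth.signs.to_numpy(float) * config.signal_effect
    lib = rng.uniform(1.0, 2.0, n)
    risk_c = risk.to_numpy(float) - risk.to_numpy(float).mean()
    mu = lib[None, :] * np.exp(log_base[:, None] + np.outer(slope, risk_c))
    mu = np.minimum(mu, 1e7)
    alpha = config.rnaseq_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    counts = pd.DataFrame(counts, index=truth.signs.index, columns=cov.index)
    return counts, cov, truth


def simulate_outcome_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Subject-level cohort: two serum proteins, asthma and lung outcomes.

    ``pglyrp1`` (outcome-linked) and ``sil6ra`` (null) are mutually
    correlated (r ~ 0.2) log-normal concentrations.  Binary asthma follows a
    logistic model with log-odds ``protein_log_or`` per SD of standardized
    log10 pglyrp1; FEV1/FVC x 100 shifts by ``fevfvc_beta`` points per SD.
    Covariates cover adjustment models 1-3.
    """
    rng = np.random.default_rng([config.seed, 3])
    n = config.outcome_n
    cov = _draw_perinatal_covariates(rng, n, config.ga_bw_corr)
    cov.index = pd.Index([f"subj{j + 1:04d}" for j in range(n)], name="subject")
    df = pd.DataFrame(index=cov.index)
    df["ga"] = cov["ga"]
    df["female"] = 1 - cov["sex"]
    df["bw_z"] = rng.normal(size=n)  # birthweight-for-GA-and-sex z, generated directly
    df["csection"] = (rng.random(n) < 0.25).astype(int)
    races = np.array(["White", "Black", "Hispanic", "Other"])
    race_p = np.array([0.55, 0.20, 0.15, 0.10])
    df["maternal_race"] = rng.choice(races, n, p=race_p)
    same = rng.random(n) < 0.8
    df["child_race"] = np.where(same, df["maternal_race"], rng.choice(races, n, p=race_p))
    df["ppbmi"] = cov["bmi"]
    df["college_grad"] = (rng.random(n) < 0.65).astype(int)
    df["atopy"] = (rng.random(n) < 0.35).astype(int)
    df["antibiotics"] = (rng.random(n) < 0.30).astype(int)
    df["smoking"] = rng.choice(
        np.array(["never", "former", "during"]), n, p=[0.70, 0.20, 0.10]
    )

    z_ga = (df["ga"].to_numpy() - GA_MEAN) / GA_SD
    latent1 = (
        0.15 * z_ga + 0.15 * df["female"].to_numpy() - 0.10 * df["csection"].to_numpy()
        + rng.normal(0.0, 1.0, n)
    )
    z1 = _standardize(latent1)
    z2 = _standardize(0.2 * z1 + math.sqrt(1 - 0.2**2) * rng.normal(size=n))
    df["pglyrp1"] = 10.0 ** (2.0 + 0.30 * z1)
    df["sil6ra"] = 10.0 ** (4.0 + 0.25 * z2)

    lp = (
        math.log(0.18 / 0.82)
        + config.protein_log_or * z1
        + 0.30 * df["atopy"].to_numpy()
        + 0.25 * (1 - df["female"].to_numpy())
        - 0.15 * z_ga
        + 0.20 * (df["smoking"] == "during").to_numpy()
    )
    if config.protein_effect_modifier is not None:
        flag = (df[config.protein_effect_modifier] == 1).to_numpy(float)
        lp = lp + config.modifier_interaction * z1 * flag
    p_cur = 1.0 / (1.0 + np.exp(-lp))
    df["current_asthma"] = (rng.random(n) < p_cur).astype(float)
    p_ever = 1.0 / (1.0 + np.exp(-(lp + 0.4)))
    df["ever_asthma"] = np.maximum(
        df["current_asthma"], (rng.random(n) < p_ever).astype(float)
    )

    fev = (
        85.0
        + config.fevfvc_beta * z1
        - 0.8 * df["atopy"].to_numpy()
        - 0.5 * (1 - df["female"].to_numpy())
        + rng.normal(0.0, 6.0, n)
    )
    if config.protein_effect_modifier is not None:
        flag = (df[config.protein_effect_modifier] == 1).to_numpy(float)
        fev = fev + config.modifier_interaction * z1 * flag
    df["fev1fvc"] = fev
    df["bdr"] = rng.normal(2.0, 3.0, n)

    if config.outcome_missing_rate > 0:
        for col in ("current_asthma", "ever_asthma", "fev1fvc", "bdr"):
            miss = rng.random(n) < config.outcome_missing_rate
            df.loc[miss, col] = np.nan
    return df
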