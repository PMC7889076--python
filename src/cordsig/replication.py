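"""Replication of the pooled signature in an independent RNA-seq cohort.

Each subject gets a perinatal risk-factor count (strict-inequality rules,
e.g. gestational age < 37 weeks).  Gene counts are filtered (median count
across samples >= 10), library sizes are equalized by median sum scaling,
and per-gene negative-binomial log-linear models of expression on the risk
count yield Wald z-scores.  The replication score RS = z_pooled * z_rnaseq
is positive when the meta-analysis and the cohort agree in direction; genes
with RS above a cutoff (default 3) form the replicating signature, which is
summarized per subject by the first principal component of the standardized
passing-gene expression ("signature eigenvalue"), oriented so that positive
scores mean higher expression of low-risk genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class RiskRule:
    name: str
    covariate: str
    op: str  # "lt", "gt" or "eq"
    threshold: float

    def __call__(self, values: pd.Series) -> pd.Series:
        v = values.astype(float)
        if self.op == "lt":
            return (v < self.threshold).astype(int)
        if self.op == "gt":
            return (v > self.threshold).astype(int)
        if self.op == "eq":
            return (v == self.threshold).astype(int)
        raise ValueError(f"unknown operator {self.op!r}")


@dataclass
class RiskFactorConfig:
    rules: tuple = field(default_factory=tuple)

    @classmethod
    def preset(cls, name: str) -> "RiskFactorConfig":
        if name == "uih":
            return cls(
                (
                    RiskRule("preterm", "ga", "lt", 37.0),
                    RiskRule("low_birthweight", "bw", "lt", 3000.0),
                    RiskRule("maternal_obesity", "ppbmi", "gt", 30.0),
                    RiskRule("male", "sex", "eq", 1.0),
                )
            )
        if name == "olin":
            return cls(
                (
                    RiskRule("preterm", "ga", "lt", 37.0),
                    RiskRule("male", "sex", "eq", 1.0),
                    RiskRule("low_birthweight", "bw", "lt", 3000.0),
                    RiskRule("cesarean", "csection", "eq", 1.0),
                )
            )
        raise KeyError(f"unknown risk-factor preset {name!r}")


def count_risk_factors(
    covariates: pd.DataFrame, config: RiskFactorConfig | str = "uih"
) -> pd.Series:
    """Number of satisfied risk predicates per subject (boundaries do not count)."""
    if isinstance(config, str):
        config = RiskFactorConfig.preset(config)
    total = pd.Series(0, index=covariates.index, dtype=int)
    for rule in config.rules:
        if rule.covariate not in covariates.columns:
            raise KeyError(f"missing covariate {rule.covariate!r} for rule {rule.name!r}")
        total += rule(covariates[rule.covariate])
    total.name = "risk_count"
    return total


# ---------------------------------------------------------------------------
# counts: filtering, normalization, per-gene NB z
# ---------------------------------------------------------------------------

def filter_and_normalize_counts(counts: pd.DataFrame, min_median: float = 10.0):
    """Drop genes with median count < min_median; median-sum-scale samples.

    Each sample's counts are multiplied by (median library size)/(its library
    size), with library sizes taken over the unfiltered matrix.  Returns the
    normalized matrix and the kept-gene list.
    """
    x = counts.to_numpy(float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = x.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[totals == 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    keep = np.median(x, axis=1) >= min_median
    scale = np.median(totals) / totals
    norm = counts.loc[keep] * scale
    return norm, counts.index[keep].tolist()


def _nb_wald_z(y: np.ndarray, design: np.ndarray, offset: np.ndarray):
    """Wald z for the slope of a per-gene NB log-linear model.

    The NB dispersion is estimated by maximum likelihood (joint NB2 fit); if
    that diverges, a Poisson fit provides a method-of-moments dispersion and
    the model is refit as an NB GLM with that dispersion fixed.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(y, design, offset=offset).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.isfinite(res.bse[1]) \
                    and res.bse[1] > 0:
                return float(res.params[1]), float(res.params[1] / res.bse[1])
        except Exception:
            pass
        try:  # method-of-moments fallback
            pois = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset).fit()
            mu = pois.fittedvalues
            alpha = max(float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2)), 1e-8)
            res = sm.GLM(
                y, design, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=offset,
            ).fit()
            if np.isfinite(res.bse[1]) and res.bse[1] > 0:
                return float(res.params[1]), float(res.params[1] / res.bse[1])
        except Exception:
            pass
    return np.nan, np.nan


def rnaseq_z(counts: pd.DataFrame, risk_counts: pd.Series) -> pd.DataFrame:
    """Per-gene NB Wald z of (filtered, raw) counts on the risk-factor count.

    Library-size differences enter as an offset log(total/median total),
    which is the model form of median sum scaling.  Positive z means
    expression rises with the number of risk factors.  Genes whose fit fails
    even after the fallback get a missing z and ``converged=False``.
    """
    risk = risk_counts.reindex(counts.columns).to_numpy(float)
    if counts.shape[1] < 8:
        raise ValueError("need at least 8 subjects")
    if np.ptp(risk) == 0:
        raise ValueError("risk counts are constant")
    totals = counts.to_numpy(float).sum(axis=0)
    offset = np.log(totals / np.median(totals))
    design = sm.add_constant(risk)
    rows = []
    for gene, y in counts.iterrows():
        beta, z = _nb_wald_z(y.to_numpy(float), design, offset)
        rows.append({"gene": gene, "beta": beta, "z": z, "converged": np.isfinite(z)})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# replication score
# ---------------------------------------------------------------------------

def replication_score(
    pooled: pd.DataFrame,
    rnaseq: pd.DataFrame,
    cutoff: float = 3.0,
    method: str = "product",
) -> pd.DataFrame:
    """RS = z_pooled * z_rnaseq on the gene intersection; passes = RS > cutoff.

    ``method="rank"`` substitutes normal scores (inverse-normal transformed
    mid-ranks) of the two z vectors before taking the product, a rank-based
    variant that is robust to heavy-tailed z's.  The plain product is the
    default and the definition of record.
    """
    zp = (pooled["z_pooled"] if "z_pooled" in pooled else pooled["z"]).dropna()
    zr = rnaseq["z"].dropna()
    genes = zp.index.intersection(zr.index)
    if genes.empty:
        raise ValueError("empty gene intersection")
    zp, zr = zp.loc[genes].astype(float), zr.loc[genes].astype(float)
    if method == "rank":
        a = stats.norm.ppf((stats.rankdata(zp) - 0.5) / genes.size)
        b = stats.norm.ppf((stats.rankdata(zr) - 0.5) / genes.size)
        rs = pd.Series(a * b, index=genes)
    elif method == "product":
        rs = zp * zr
    else:
        raise ValueError(f"unknown replication-score method {method!r}")
    out = pd.DataFrame(
        {"z_pooled": zp, "z_rnaseq": zr, "rs": rs, "passes": rs > cutoff}
    )
    out.index.name = "gene"
    return out


def rs_cutoff_sweep(
    records: pd.DataFrame, cutoffs, p_tables: dict[str, pd.Series] | None = None
) -> pd.DataFrame:
    """Gene counts (and median source p-values) among RS passers per cutoff."""
    cutoffs = np.asarray(list(cutoffs), float)
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    p_tables = p_tables or {}
    rows = []
    for c in cutoffs:
        passers = records.index[records["rs"] > c]
        row = {"cutoff": c, "n_genes": passers.size}
        for name, ps in p_tables.items():
            vals = ps.reindex(passers).dropna()
            row[f"median_p_{name}"] = float(vals.median()) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signature eigenvalue and secondary correlations
# ---------------------------------------------------------------------------

def signature_eigenvalue(
    expression: pd.DataFrame, z_pooled: pd.Series | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """First-PC subject scores of the standardized passing-gene expression.

    ``expression`` is genes x subjects.  Rows are standardized to mean 0 /
    SD 1 across subjects (constant rows dropped with a warning) and the
    subject scores on the first principal component are returned, oriented so
    that the mean loading of low-risk genes (z_pooled < 0) is positive —
    positive eigenvalues then mean increased expression of low-risk genes.
    Returns (per-subject frame with ``eigenvalue``, variance-explained
    fractions of all components).
    """
    if expression.shape[0] < 2 or expression.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 subjects")
    x = expression.to_numpy(float)
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant gene rows")
        expression = expression.loc[~constant]
        x, sd = x[~constant], sd[~constant]
        if x.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant genes")
    zs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    # subjects as observations: PCA of the subject x gene matrix
    u, s, vt = np.linalg.svd(zs.T - zs.T.mean(axis=0), full_matrices=False)
    var_frac = s**2 / np.sum(s**2)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    orient = 1.0
    if z_pooled is not None:
        low = z_pooled.reindex(expression.index).to_numpy(float) < 0
        if low.any() and np.mean(loadings[low]) < 0:
            orient = -1.0
    elif loadings.sum() < 0:
        orient = -1.0
    out = pd.DataFrame(
        {"eigenvalue": orient * scores}, index=expression.columns
    )
    out.index.name = "subject"
    out["variance_explained"] = var_frac[0]
    return out, var_frac


def correlate_with_risk(
    values: pd.Series, risk_counts: pd.Series, n_tests: int = 1
) -> dict:
    """Pearson R with Fisher-z 95% CI, p, and Bonferroni-adjusted p."""
    joined = pd.concat([values, risk_counts], axis=1, join="inner").dropna()
    if joined.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    x, y = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "ci": (np.nan, np.nan), "p": np.nan, "p_adjusted": np.nan,
                "n": joined.shape[0]}
    r, p = stats.pearsonr(x, y)
    n = x.size
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    return {
        "r": float(r),
        "ci": ci,
        "p": float(p),
        "p_adjusted": float(min(1.0, p * n_tests)),
        "n": n,
    }


def clr_transform(composition: pd.DataFrame, pseudocount: bool = True) -> pd.DataFrame:
    """Centered log-ratio transform of subject x part compositions.

    Zero parts receive half the smallest nonzero part of the table when
    ``pseudocount`` is enabled; otherwise zeros are an error.  Each output
    row sums to zero.
    """
    x = composition.to_numpy(float)
    if (x < 0).any():
        raise ValueError("composition parts must be nonnegative")
    if (x == 0).any():
        if not pseudocount:
            raise ValueError("zero composition part with pseudo-counting disabled")
        x = x + 0.5 * x[x > 0].min()
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=composition.index, columns=composition.columns)
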