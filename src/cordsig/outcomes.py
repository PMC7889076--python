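"""Serum-protein / outcome association models with relative importance.

Protein concentrations are log10-transformed and standardized to an internal
z-score.  Binary outcomes (current/ever asthma) are fit by logistic
regression, continuous outcomes (FEV1/FVC x 100, bronchodilator response) by
linear regression, each under four covariate-adjustment models:

  univariate  protein only
  model1      child's birth characteristics and demographics
  model2      mother's demographics
  model3      model1 + model2 minus maternal race/ethnicity

Relative importance uses LMG for linear models (a predictor block's average
increment to R^2 over all orders of entry) and drop-one McFadden pseudo-R^2
for logistic models.  Subset analyses refit the univariate model within the
strata of a categorical covariate and flag heterogeneity when two strata
have disjoint confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: covariate blocks per adjustment model; categorical fields expand to dummy
#: blocks against the stated reference level
MODEL1_COVARIATES = ("ga", "bw_z", "csection", "female", "child_race")
MODEL2_COVARIATES = ("ppbmi", "maternal_race", "college_grad", "atopy",
                     "antibiotics", "smoking")
MODEL_COVARIATES = {
    "univariate": (),
    "model1": MODEL1_COVARIATES,
    "model2": MODEL2_COVARIATES,
    "model3": MODEL1_COVARIATES
    + tuple(c for c in MODEL2_COVARIATES if c != "maternal_race"),
}

#: reference levels for categorical covariates (dropped dummy)
REFERENCE_LEVELS = {
    "child_race": "White",
    "maternal_race": "White",
    "smoking": "never",
    "csection": 0,
    "female": 0,
    "college_grad": 0,
    "atopy": 0,
    "antibiotics": 0,
}

CATEGORICAL = ("child_race", "maternal_race", "smoking")

BINARY_OUTCOMES = ("current_asthma", "ever_asthma")


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    model: str
    estimate: float  # log-odds or slope per 1 SD predictor
    ci_low: float
    ci_high: float
    p: float
    n: int
    family: str  # "logistic" or "linear"

    @property
    def odds_ratio(self) -> float:
        if self.family != "logistic":
            raise ValueError("odds ratio only defined for logistic fits")
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def standardize_protein(concentrations: pd.Series) -> pd.Series:
    """Internal z-score of log10 concentration (sample SD, non-missing values)."""
    x = concentrations.astype(float)
    obs = x.dropna()
    if (obs <= 0).any():
        raise ValueError("concentrations must be positive")
    logs = np.log10(obs)
    sd = logs.std(ddof=1)
    if not sd > 0:
        raise ValueError("zero variance")
    z = (np.log10(x) - logs.mean()) / sd
    z.name = f"{concentrations.name}_z" if concentrations.name else "protein_z"
    return z


def _dummy_block(values: pd.Series, name: str) -> pd.DataFrame:
    ref = REFERENCE_LEVELS.get(name)
    levels = [lv for lv in pd.unique(values.dropna()) if lv != ref]
    return pd.DataFrame(
        {f"{name}[{lv}]": (values == lv).astype(float) for lv in sorted(map(str, levels))}
        if all(isinstance(lv, str) for lv in levels)
        else {f"{name}[{lv}]": (values == lv).astype(float) for lv in levels},
        index=values.index,
    )


def build_design(cohort: pd.DataFrame, covariates) -> tuple[pd.DataFrame, dict]:
    """Design matrix columns for the named covariates; returns (X, blocks).

    ``blocks`` maps covariate name -> list of design columns (a categorical
    covariate is one block of dummies against its reference level).
    """
    pieces, blocks = [], {}
    for name in covariates:
        if name not in cohort.columns:
            raise KeyError(f"covariate {name!r} not in cohort table")
        if name in CATEGORICAL:
            dummies = _dummy_block(cohort[name], name)
            pieces.append(dummies)
            blocks[name] = list(dummies.columns)
        else:
            pieces.append(cohort[[name]].astype(float))
            blocks[name] = [name]
    X = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=cohort.index)
    return X, blocks


def fit_outcome_model(
    cohort: pd.DataFrame,
    outcome: str,
    predictor: str,
    model: str = "model3",
) -> AssociationResult:
    """Fit one outcome ~ protein-z (+ model covariates) association.

    Complete-case: subjects missing the outcome, the predictor, or any
    active covariate are excluded.  Logistic fits report Wald CIs on the
    log-odds scale; linear fits report t-based CIs.
    """
    if model not in MODEL_COVARIATES:
        raise KeyError(f"unknown model {model!r}")
    covs = MODEL_COVARIATES[model]
    X_cov, _ = build_design(cohort, covs)
    frame = pd.concat([cohort[[outcome, predictor]], X_cov], axis=1).dropna()
    if frame.empty:
        raise ValueError("no complete cases")
    y = frame[outcome].astype(float)
    X = sm.add_constant(frame.drop(columns=[outcome]).astype(float))
    _check_design(X)
    family = "logistic" if outcome in BINARY_OUTCOMES or set(y.unique()) <= {0.0, 1.0} \
        else "linear"
    if family == "logistic":
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(res.bse).all() or np.any(np.abs(res.params) > 15):
            bad = X.columns[np.argmax(np.abs(res.params.to_numpy()))]
            raise ValueError(f"separation or singular design at term {bad!r}")
    else:
        res = sm.OLS(y, X).fit()
    ci = res.conf_int().loc[predictor]
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        model=model,
        estimate=float(res.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(res.pvalues[predictor]),
        n=int(frame.shape[0]),
        family=family,
    )


def _check_design(X: pd.DataFrame) -> None:
    x = X.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name one offending column: the first whose removal restores full rank
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy(float)) == rank:
                raise ValueError(f"singular design at term {col!r}")
        raise ValueError("singular design")


# ---------------------------------------------------------------------------
# relative importance
# ---------------------------------------------------------------------------

def _subset_r2(y: np.ndarray, cols_by_block: list[np.ndarray]) -> dict:
    """R^2 of OLS on every subset of predictor blocks (intercept always in)."""
    n = y.size
    yc = y - y.mean()
    sst = float(yc @ yc)
    r2 = {frozenset(): 0.0}
    p = len(cols_by_block)
    ones = np.ones((n, 1))
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            X = np.hstack([ones] + [cols_by_block[i] for i in subset])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            r2[frozenset(subset)] = 1.0 - float(resid @ resid) / sst
    return r2


def relative_importance_linear(
    y: pd.Series, X: pd.DataFrame, blocks: dict[str, list] | None = None
) -> pd.Series:
    """LMG decomposition of R^2 over predictor blocks.

    Each block's share is its average increment to R^2 over all orderings of
    block entry; shares are nonnegative (up to numerical noise in collinear
    designs) and sum to the full-model R^2.
    """
    frame = pd.concat([y, X], axis=1).dropna()
    yv = frame.iloc[:, 0].to_numpy(float)
    Xv = frame.iloc[:, 1:]
    if blocks is None:
        blocks = {c: [c] for c in Xv.columns}
    names = list(blocks)
    if len(names) < 2:
        raise ValueError("need at least 2 predictor blocks")
    if frame.shape[0] <= sum(len(v) for v in blocks.values()) + 1:
        raise ValueError("too few observations for the predictor count")
    cols = [Xv[blocks[b]].to_numpy(float) for b in names]
    _check_design(sm.add_constant(Xv.astype(float)))
    r2 = _subset_r2(yv, cols)
    p = len(names)
    shares = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        for size in range(0, p):
            weight = factorial(size) * factorial(p - size - 1) / factorial(p)
            for subset in combinations(others, size):
                s = frozenset(subset)
                shares[i] += weight * (r2[s | {i}] - r2[s])
    return pd.Series(shares, index=names, name="lmg_share")


def mcfadden_r2(y: pd.Series, X: pd.DataFrame) -> float:
    """McFadden pseudo-R^2 = 1 - logLik(model)/logLik(intercept-only)."""
    res = sm.Logit(y.astype(float), sm.add_constant(X.astype(float))).fit(
        disp=0, maxiter=200
    )
    return float(1.0 - res.llf / res.llnull)


def relative_importance_logistic(
    cohort: pd.DataFrame, outcome: str, predictor: str, model: str = "model3"
) -> pd.Series:
    """Drop-one McFadden pseudo-R^2 decrement per predictor block."""
    X_cov, blocks = build_design(cohort, MODEL_COVARIATES[model])
    blocks = {predictor: [predictor], **blocks}
    frame = pd.concat([cohort[[outcome, predictor]], X_cov], axis=1).dropna()
    y = frame[outcome]
    X_full = frame.drop(columns=[outcome])
    full = mcfadden_r2(y, X_full)
    drops = {}
    for name, cols in blocks.items():
        drops[name] = full - mcfadden_r2(y, X_full.drop(columns=cols))
    out = pd.Series(drops, name="mcfadden_drop")
    out.attrs["full_r2"] = full
    return out


# ---------------------------------------------------------------------------
# subsets and outcome definitions
# ---------------------------------------------------------------------------

def subset_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    predictor: str,
    stratifier: str,
    min_stratum: int = 10,
) -> tuple[list[AssociationResult], bool]:
    """Univariate model per stratum of a categorical variable.

    Strata with fewer than ``min_stratum`` non-missing-outcome subjects are
    skipped with a warning.  The heterogeneity flag is True when any two
    strata have disjoint 95% CIs.
    """
    import warnings as _warnings

    levels = pd.unique(cohort[stratifier].dropna())
    if len(levels) < 2:
        raise ValueError(f"stratifier {stratifier!r} is constant")
    results = []
    for level in levels:
        sub = cohort[cohort[stratifier] == level]
        n_usable = sub[[outcome, predictor]].dropna().shape[0]
        if n_usable < min_stratum:
            _warnings.warn(
                f"stratum {stratifier}={level!r} skipped ({n_usable} usable subjects)"
            )
            continue
        try:
            res = fit_outcome_model(sub, outcome, predictor, model="univariate")
        except ValueError as exc:
            _warnings.warn(f"stratum {stratifier}={level!r} not fit: {exc}")
            continue
        res.model = f"univariate[{stratifier}={level}]"
        results.append(res)
    heterogeneous = any(
        a.ci_high < b.ci_low or b.ci_high < a.ci_low
        for a, b in combinations(results, 2)
    )
    return results, heterogeneous


def define_outcomes(fields: pd.DataFrame) -> pd.DataFrame:
    """Questionnaire fields -> current/ever asthma with three-valued logic.

    Case: diagnosis yes AND (medication yes OR wheeze yes).  Comparison: no
    diagnosis AND no medication AND no wheeze.  Subjects matching neither
    (including through missing answers) are missing and excluded from
    models downstream.  Expected columns: ``diagnosis``, ``medication``,
    ``wheeze`` coded 1/0/NaN; ``diagnosis_teen`` optionally contributes to
    ever-asthma.
    """
    diag = fields["diagnosis"]
    med = fields["medication"]
    whz = fields["wheeze"]
    either = _or3(med, whz)
    current = pd.Series(np.nan, index=fields.index, name="current_asthma")
    current[(diag == 1) & (either == 1)] = 1.0
    current[(diag == 0) & (med == 0) & (whz == 0)] = 0.0
    out = pd.DataFrame({"current_asthma": current})
    diag_cols = [c for c in ("diagnosis", "diagnosis_teen") if c in fields.columns]
    any_yes = (fields[diag_cols] == 1).any(axis=1)
    all_no = (fields[diag_cols] == 0).all(axis=1)
    ever = pd.Series(np.nan, index=fields.index)
    ever[any_yes] = 1.0
    ever[all_no] = 0.0
    out["ever_asthma"] = ever
    return out


def _or3(a: pd.Series, b: pd.Series) -> pd.Series:
    """Three-valued OR: yes if either yes; no if both no; else missing."""
    out = pd.Series(np.nan, index=a.index)
    out[(a == 1) | (b == 1)] = 1.0
    out[(a == 0) & (b == 0)] = 0.0
    return out
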