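"""Per-gene effect sizes within studies and random-effects combination across them.

Each expression dataset contributes one standardized effect per gene and
covariate: Hedges' g (small-sample-corrected standardized mean difference)
for the binary covariate (newborn sex) and Fisher's z-transformed Pearson
correlation for the continuous/ordinal covariates (gestational age,
birthweight, maternal pre-pregnancy BMI category).  Effects are combined
with inverse-variance weights and the DerSimonian-Laird moment estimator of
the between-study variance tau^2, followed by Benjamini-Hochberg FDR control
across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: covariates recognized throughout the pipeline
COVARIATES = ("sex", "ga", "bw", "ppbmi")

#: +1 if higher values of the covariate carry higher asthma risk, -1 otherwise
#: (male sex and maternal obesity raise risk; longer gestation and higher
#: birthweight lower it).  Used by the pooled score, not by study effects.
RISK_DIRECTION = {"sex": +1, "ppbmi": +1, "ga": -1, "bw": -1}


class InsufficientDataError(ValueError):
    """Raised when a dataset cannot support an effect-size estimate."""


@dataclass
class ExpressionDataset:
    """One study's gene-by-sample log2 expression matrix plus covariates.

    ``matrix`` is indexed by gene with one column per sample; ``covariates``
    is indexed by sample and only carries the covariates in ``availability``
    (a covariate may drive expression in reality yet be absent from the
    metadata — availability is a metadata property).
    """

    dataset_id: str
    matrix: pd.DataFrame
    covariates: pd.DataFrame
    availability: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.availability = frozenset(self.availability)
        if self.matrix.shape[1] != self.covariates.shape[0]:
            raise ValueError(
                f"{self.dataset_id}: matrix has {self.matrix.shape[1]} samples "
                f"but covariate table has {self.covariates.shape[0]} rows"
            )
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError(f"{self.dataset_id}: non-finite expression values")
        if self.matrix.index.duplicated().any():
            raise ValueError(f"{self.dataset_id}: duplicated gene identifiers")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclass
class StudyEffect:
    dataset_id: str
    gene: str
    covariate: str
    effect: float
    variance: float
    n: int

    def __post_init__(self):
        if not self.variance > 0:
            raise ValueError("invalid variance")
        if self.n < 4:
            raise InsufficientDataError("insufficient data")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) to a common reference distribution.

    The reference is the mean of the column-sorted values; tied entries
    receive the mean of the reference quantiles they span (average ranks).
    """
    x = matrix.to_numpy(float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame, gene_ids) -> pd.DataFrame:
    """Collapse probe rows mapping to the same gene, keeping the max-mean row."""
    means = matrix.mean(axis=1).to_numpy()
    keep = (
        pd.DataFrame({"gene": np.asarray(gene_ids), "mean": means})
        .groupby("gene", sort=True)["mean"]
        .idxmax()
    )
    collapsed = matrix.iloc[keep.to_numpy()].copy()
    collapsed.index = keep.index
    return collapsed


def preprocess_dataset(
    raw: pd.DataFrame,
    covariates: pd.DataFrame,
    dataset_id: str = "dataset",
    normalized: bool = True,
    gene_ids=None,
    availability=None,
) -> ExpressionDataset:
    """Normalize a raw matrix if needed and collapse probes to genes.

    Non-normalized input (``normalized=False``) must be nonnegative; it is
    quantile normalized across samples then log2(x+1) transformed.
    """
    x = raw
    if np.ptp(x.to_numpy(float)) == 0:
        raise ValueError("degenerate expression")
    if not normalized:
        if (x.to_numpy(float) < 0).any():
            raise ValueError("raw intensities must be nonnegative")
        x = np.log2(quantile_normalize(x) + 1.0)
    if gene_ids is not None:
        x = collapse_probes(x, gene_ids)
    elif x.index.duplicated().any():
        x = collapse_probes(x, x.index)
    if availability is None:
        availability = frozenset(covariates.columns) & set(COVARIATES)
    return ExpressionDataset(dataset_id, x, covariates, availability)


# ---------------------------------------------------------------------------
# per-study effects
# ---------------------------------------------------------------------------

def hedges_g(x1: np.ndarray, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Hedges' g and its sampling variance for rows of x1 vs x0.

    g = J * (mean1 - mean0) / s_pooled with J = 1 - 3/(4*df - 1), df = n1+n0-2;
    var(g) = (n1+n0)/(n1*n0) + g^2 / (2*(n1+n0)).
    """
    x1 = np.atleast_2d(x1)
    x0 = np.atleast_2d(x0)
    n1, n0 = x1.shape[1], x0.shape[1]
    if min(n1, n0) < 2:
        raise InsufficientDataError("insufficient data")
    df = n1 + n0 - 2
    s_pooled = np.sqrt(
        ((n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1)) / df
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (x1.mean(axis=1) - x0.mean(axis=1)) / s_pooled
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var = (n1 + n0) / (n1 * n0) + g**2 / (2.0 * (n1 + n0))
    var = np.where(np.isfinite(g), var, np.nan)
    g = np.where(np.isfinite(g), g, np.nan)
    return g, var


def fisher_z(expr: np.ndarray, covariate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Fisher z = atanh(Pearson r) per expression row, var = 1/(n-3)."""
    expr = np.atleast_2d(expr)
    y = np.asarray(covariate, float)
    n = y.size
    if n <= 3:
        raise InsufficientDataError("insufficient data")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise InsufficientDataError("insufficient data")
    xc = expr - expr.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(r)
    z = np.where(sx > 0, z, np.nan)
    var = np.full(z.shape, 1.0 / (n - 3))
    var = np.where(np.isfinite(z), var, np.nan)
    return z, var


def study_effects(dataset: ExpressionDataset, covariate: str):
    """Effect and variance arrays (aligned to dataset.genes) for one covariate."""
    if covariate not in dataset.availability:
        raise KeyError(f"covariate {covariate!r} not available in {dataset.dataset_id}")
    y = dataset.covariates[covariate].to_numpy(float)
    x = dataset.matrix.to_numpy(float)
    if dataset.n_samples < 4:
        raise InsufficientDataError("insufficient data")
    if covariate == "sex":
        mask1 = y == 1
        if mask1.all() or (~mask1).all():
            raise InsufficientDataError("insufficient data")
        return hedges_g(x[:, mask1], x[:, ~mask1])
    return fisher_z(x, y)


def study_effect(dataset: ExpressionDataset, covariate: str, gene: str) -> StudyEffect:
    """Single-gene convenience wrapper around the vectorized estimators."""
    eff, var = study_effects(dataset, covariate)
    i = dataset.genes.get_loc(gene)
    if not np.isfinite(eff[i]) or not var[i] > 0:
        raise InsufficientDataError("insufficient data")
    return StudyEffect(dataset.dataset_id, gene, covariate, float(eff[i]), float(var[i]),
                       dataset.n_samples)


# ---------------------------------------------------------------------------
# DerSimonian-Laird combination
# ---------------------------------------------------------------------------

def dl_combine(effects: np.ndarray, variances: np.ndarray) -> dict:
    """Vectorized DerSimonian-Laird random-effects combination.

    ``effects`` and ``variances`` are (k_studies, n_genes); NaN marks a gene
    missing from a study.  Returns arrays k, mu, se, Q, tau2, z, p.  Genes
    observed in a single study pass through with tau2 = 0.
    """
    e = np.atleast_2d(np.asarray(effects, float))
    v = np.atleast_2d(np.asarray(variances, float))
    if np.nanmin(v, initial=np.inf) <= 0:
        raise ValueError("invalid variance")
    valid = np.isfinite(e) & np.isfinite(v)
    e = np.where(valid, e, np.nan)
    v = np.where(valid, v, np.nan)
    k = valid.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        w = 1.0 / v
        sw = np.nansum(w, axis=0)
        fe = np.nansum(w * e, axis=0) / sw
        q = np.nansum(w * (e - fe) ** 2, axis=0)
        c = sw - np.nansum(w**2, axis=0) / sw
        tau2 = np.where(k >= 2, np.maximum(0.0, (q - (k - 1)) / c), 0.0)
        ws = 1.0 / (v + tau2)
        sws = np.nansum(ws, axis=0)
        mu = np.nansum(ws * e, axis=0) / sws
        se = 1.0 / np.sqrt(sws)
        z = mu / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    empty = k == 0
    for arr in (mu, se, q, tau2, z):
        arr[empty] = np.nan
    p = np.where(empty, np.nan, p)
    q[k == 1] = 0.0
    return {"k": k, "mu": mu, "se": se, "Q": q, "tau2": tau2, "z": z, "p": p}


def random_effects_combine(effects: list[StudyEffect]) -> pd.Series:
    """Combine one gene/covariate's study effects; k = 1 passes through."""
    if not effects:
        raise ValueError("no study effects supplied")
    e = np.array([[s.effect] for s in effects])
    v = np.array([[s.variance] for s in effects])
    out = dl_combine(e, v)
    res = pd.Series({key: float(np.asarray(val).ravel()[0]) for key, val in out.items()})
    res["single_study"] = len(effects) == 1
    res["gene"] = effects[0].gene
    res["covariate"] = effects[0].covariate
    return res


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _effect_matrices(usable, covariate, genes, perms=None):
    """Stacked (k_datasets x n_genes) effect/variance arrays, optionally with
    each dataset's covariate vector permuted by the given index arrays."""
    k_ds = len(usable)
    eff = np.full((k_ds, genes.size), np.nan)
    var = np.full((k_ds, genes.size), np.nan)
    for i, d in enumerate(usable):
        y = d.covariates[covariate].to_numpy(float)
        if perms is not None:
            y = y[perms[i]]
        x = d.matrix.to_numpy(float)
        if covariate == "sex":
            mask1 = y == 1
            e, v = hedges_g(x[:, mask1], x[:, ~mask1])
        else:
            e, v = fisher_z(x, y)
        idx = genes.get_indexer(d.genes)
        eff[i, idx] = e
        var[i, idx] = v
    return eff, var


def meta_analyze(
    datasets: list[ExpressionDataset],
    covariate: str,
    p_method: str = "permutation",
    n_perm: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene random-effects meta-analysis of one covariate across datasets.

    Genes are combined over every dataset that contains both the gene and the
    covariate; genes seen in fewer than two such datasets are flagged via the
    ``single_study`` column.  BH q-values are appended over all tested genes.

    The closed-form normal p-value of the DL z is reported as ``p_normal``;
    because the tau^2 >= 0 truncation makes that reference conservative under
    homogeneity, the default ``p`` is calibrated against a null built by
    permuting each dataset's covariate labels (expression fixed) and pooling
    the resulting null z's across genes, the convention of permutation-based
    microarray meta-analysis.  ``p_method="normal"`` uses the closed form
    directly.
    """
    usable = [d for d in datasets if covariate in d.availability]
    if not usable:
        raise ValueError(f"no dataset exposes covariate {covariate!r}")
    for d in usable:
        if d.n_samples < 4:
            raise InsufficientDataError(f"{d.dataset_id}: insufficient data")
    genes = pd.Index(sorted(set().union(*(set(d.genes) for d in usable))))
    eff, var = _effect_matrices(usable, covariate, genes)
    combined = dl_combine(eff, var)
    table = pd.DataFrame(combined, index=genes)
    table.index.name = "gene"
    table["single_study"] = table["k"] < 2
    table = table.rename(columns={"p": "p_normal"})
    if p_method == "normal":
        table["p"] = table["p_normal"]
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        null_z = []
        for _ in range(n_perm):
            perms = [rng.permutation(d.n_samples) for d in usable]
            pe, pv = _effect_matrices(usable, covariate, genes, perms)
            null_z.append(dl_combine(pe, pv)["z"])
        null = np.abs(np.concatenate(null_z))
        null = np.sort(null[np.isfinite(null)])
        obs = np.abs(table["z"].to_numpy())
        counts = null.size - np.searchsorted(null, obs, side="left")
        p = (1.0 + counts) / (null.size + 1.0)
        table["p"] = np.where(np.isfinite(obs), p, np.nan)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    table["q"] = np.nan
    tested = table["p"].notna()
    table.loc[tested, "q"] = bh_fdr(table.loc[tested, "p"].to_numpy())
    return table
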