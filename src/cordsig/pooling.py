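"""Pooled multi-risk-factor z-score and its representativeness diagnostics.

The four univariate meta-analysis z-score vectors (male sex, maternal
pre-pregnancy BMI, gestational age, birthweight) are combined gene-wise as

    z_pooled = ((z_male + z_ppbmi) - (z_ga + z_bw)) / 4

so that positive pooled scores mark expression patterns associated with
higher asthma risk (male, higher maternal BMI, shorter gestation, lower
birthweight).  A gene absent from a component analysis contributes a z of
zero; the denominator stays 4 regardless, which deliberately shrinks the
pooled score of sparsely measured genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

POOL_COMPONENTS = ("sex", "ppbmi", "ga", "bw")
_SIGN = {"sex": +1.0, "ppbmi": +1.0, "ga": -1.0, "bw": -1.0}


def pooled_z(z_tables: dict[str, pd.Series | pd.DataFrame]) -> pd.DataFrame:
    """Combine per-covariate z-score tables into the pooled risk score.

    ``z_tables`` maps covariate name -> Series of z indexed by gene (or a
    DataFrame with a ``z`` column).  Returns a frame indexed by gene with the
    four components (0 where missing), ``n_missing``, ``missing_components``
    and ``z_pooled``.
    """
    unknown = set(z_tables) - set(POOL_COMPONENTS)
    if unknown:
        raise KeyError(f"unknown pooled-score components: {sorted(unknown)}")
    series = {}
    for name, tab in z_tables.items():
        s = tab["z"] if isinstance(tab, pd.DataFrame) else tab
        series[name] = s.dropna().astype(float)
    if not series or all(s.empty for s in series.values()):
        raise ValueError("empty gene universe")
    genes = pd.Index(sorted(set().union(*(set(s.index) for s in series.values()))))
    out = pd.DataFrame(index=genes)
    out.index.name = "gene"
    missing_lists = [[] for _ in range(genes.size)]
    for name in POOL_COMPONENTS:
        col = f"z_{'male' if name == 'sex' else name}"
        if name in series:
            aligned = series[name].reindex(genes)
            absent = aligned.isna().to_numpy()
            out[col] = aligned.fillna(0.0)
        else:
            absent = np.ones(genes.size, bool)
            out[col] = 0.0
        for i in np.flatnonzero(absent):
            missing_lists[i].append(name)
    out["n_missing"] = [len(m) for m in missing_lists]
    out["missing_components"] = [",".join(m) for m in missing_lists]
    out["z_pooled"] = (
        (out["z_male"] + out["z_ppbmi"]) - (out["z_ga"] + out["z_bw"])
    ) / 4.0
    return out


def correlation_diagnostics(pooled: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each component with the pooled score and with
    the risk-oriented mean of the other components.

    Components are risk-oriented first (ga and bw negated) so that a positive
    correlation means the component pulls in the same risk direction as the
    pool.  Constant vectors yield missing correlations.
    """
    comp_cols = {c: f"z_{'male' if c == 'sex' else c}" for c in POOL_COMPONENTS}
    oriented = {c: _SIGN[c] * pooled[col].to_numpy() for c, col in comp_cols.items()}
    zp = pooled["z_pooled"].to_numpy()
    if len(zp) < 2:
        raise ValueError("need at least two genes for diagnostics")
    rows = []
    for c in POOL_COMPONENTS:
        others = np.mean([oriented[o] for o in POOL_COMPONENTS if o != c], axis=0)
        rows.append(
            {
                "component": c,
                "rho_vs_pooled": _spearman(oriented[c], zp),
                "rho_vs_others": _spearman(oriented[c], others),
            }
        )
    return pd.DataFrame(rows).set_index("component")


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)
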