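"""End-to-end driver: simulation -> meta-analysis -> pooling -> replication.

Convenience orchestration used by the acceptance machinery and scripts; each
stage is the public function from the corresponding module, so results are
identical to running the stages by hand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .meta import COVARIATES, meta_analyze
from .pooling import pooled_z
from .replication import (
    correlate_with_risk,
    filter_and_normalize_counts,
    replication_score,
    rnaseq_z,
    signature_eigenvalue,
)
from .simulate import (
    SimulationConfig,
    simulate_microarray_collection,
    simulate_rnaseq_cohort,
)


def run_signature_pipeline(config: SimulationConfig, cutoff: float = 3.0) -> dict:
    """Run the full discovery/replication pipeline on one synthetic draw.

    Returns a dict with the ground truth, per-covariate meta tables, the
    pooled score, the RNA-seq z table, replication records, and (when at
    least two genes pass the cutoff) the subject signature scores and their
    Pearson correlation with the risk-factor count.
    """
    datasets, truth = simulate_microarray_collection(config)
    meta_tables = {
        c: meta_analyze(datasets, c, seed=config.seed * 10 + i)
        for i, c in enumerate(COVARIATES)
    }
    pooled = pooled_z({c: t["z"] for c, t in meta_tables.items()})
    counts, covariates, _ = simulate_rnaseq_cohort(config)
    normalized, kept = filter_and_normalize_counts(counts)
    rnaseq = rnaseq_z(counts.loc[kept], covariates["risk_count"])
    records = replication_score(pooled, rnaseq, cutoff=cutoff)
    out = {
        "truth": truth,
        "datasets": datasets,
        "meta_tables": meta_tables,
        "pooled": pooled,
        "counts_normalized": normalized,
        "rnaseq_covariates": covariates,
        "rnaseq": rnaseq,
        "records": records,
        "signature_scores": None,
        "risk_correlation": None,
        "variance_explained": np.nan,
    }
    passers = records.index[records["passes"]]
    passer_expr = normalized.loc[normalized.index.intersection(passers)]
    if passer_expr.shape[0] >= 2:
        scores, var_frac = signature_eigenvalue(passer_expr, pooled["z_pooled"])
        out["signature_scores"] = scores
        out["variance_explained"] = float(var_frac[0])
        out["risk_correlation"] = correlate_with_risk(
            scores["eigenvalue"], covariates["risk_count"]
        )
    return out
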