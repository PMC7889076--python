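"""TSV/GMT/YAML plumbing for the pipeline's on-disk interfaces.

All tables are tab-separated with a header row; expression and count
matrices have genes as rows and samples as columns, with the gene id in the
first column.  A simulation run writes ``expr_<k>.tsv`` / ``meta_<k>.tsv``
per dataset plus ``truth.tsv``, ``counts.tsv``, ``rnaseq_covariates.tsv``,
``cohort.tsv`` and a ``manifest.yaml`` recording the files and the config.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .meta import ExpressionDataset
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_microarray_collection,
    simulate_outcome_cohort,
    simulate_rnaseq_cohort,
)

FLOAT_FORMAT = "%.10g"


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_simulation(config: SimulationConfig, out_dir) -> dict:
    """Run all three generators and write their outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets, truth = simulate_microarray_collection(config)
    files = []
    for k, ds in enumerate(datasets):
        expr, meta = f"expr_{k + 1:02d}.tsv", f"meta_{k + 1:02d}.tsv"
        write_tsv(ds.matrix, out / expr)
        write_tsv(ds.covariates, out / meta)
        files += [expr, meta]
    truth_frame = truth.signs.to_frame("sign")
    truth_frame["is_signal"] = truth_frame["sign"] != 0
    write_tsv(truth_frame, out / "truth.tsv")
    counts, rcov, _ = simulate_rnaseq_cohort(config)
    write_tsv(counts, out / "counts.tsv")
    write_tsv(rcov, out / "rnaseq_covariates.tsv")
    cohort = simulate_outcome_cohort(config)
    write_tsv(cohort, out / "cohort.tsv")
    files += ["truth.tsv", "counts.tsv", "rnaseq_covariates.tsv", "cohort.tsv"]
    manifest = {
        "files": files,
        "config": dataclasses.asdict(config),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def load_collection(directory) -> list[ExpressionDataset]:
    """Read every expr_<k>.tsv / meta_<k>.tsv pair in a simulation directory."""
    directory = Path(directory)
    datasets = []
    for expr_path in sorted(directory.glob("expr_*.tsv")):
        k = expr_path.stem.split("_")[1]
        meta_path = directory / f"meta_{k}.tsv"
        matrix = read_matrix(expr_path)
        covariates = read_matrix(meta_path)
        datasets.append(
            ExpressionDataset(
                dataset_id=f"ds{k}",
                matrix=matrix,
                covariates=covariates,
                availability=frozenset(covariates.columns) - {"bmi"},
            )
        )
    if not datasets:
        raise FileNotFoundError(f"no expr_*.tsv files in {directory}")
    return datasets


def load_truth(directory) -> GroundTruth:
    frame = read_matrix(Path(directory) / "truth.tsv")
    signs = frame["sign"].astype(int)
    signal = tuple(signs.index[signs != 0])
    return GroundTruth(signal_genes=signal, signs=signs)
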