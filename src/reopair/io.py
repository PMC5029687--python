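"""TSV/JSON readers and writers for the pipeline's on-disk formats.

Matrices are stored features-in-rows, samples-in-columns (the layout of
typical expression and methylation distributions); in memory everything
is samples x features. The clinical table is one row per sample with NA
for missing values.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import CohortBundle

__all__ = [
    "write_matrix", "read_matrix", "write_clinical", "read_clinical",
    "write_bundle", "read_ground_truth",
]


def write_matrix(df: pd.DataFrame, path, index_name: str = "feature_id"):
    """Write a samples x features frame as a features x samples TSV."""
    out = df.T
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples TSV into a samples x features frame."""
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_clinical(clinical: pd.DataFrame, path):
    clinical.to_csv(path, sep="\t", na_rep="NA")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id",
                     na_values=["NA"])
    required = {"dfs_time", "dfs_event", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table lacks columns "
                         f"{sorted(missing)}")
    return df


def write_bundle(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write every layer of a synthetic cohort plus the truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "methylation": outdir / "methylation.tsv",
        "locus_gene_map": outdir / "locus_gene_map.tsv",
        "copy_number": outdir / "copy_number.tsv",
        "mutation": outdir / "mutation.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_matrix(bundle.expression, paths["expression"], "gene_id")
    write_clinical(bundle.clinical, paths["clinical"])
    write_matrix(bundle.methylation, paths["methylation"], "locus_id")
    bundle.locus_gene_map.to_csv(paths["locus_gene_map"], sep="\t",
                                 index=False)
    write_matrix(bundle.copy_number, paths["copy_number"], "gene_id")
    write_matrix(bundle.mutation, paths["mutation"], "gene_id")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(bundle.truth.as_dict(), fh, indent=1)
    return paths


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
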