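"""Spatial selection of expression samples and z-score summarisation.

Workflow: per-probe z-scores are computed over *all* samples of the
matrix (whole-brain normalisation), probe z-scores are averaged into
gene-level z-scores, samples falling inside a pathway mask are selected
by the shared world-to-voxel convention, and the per-pathway, per-gene
average z-score with its sample count n is reported.

Conventions that the source data format leaves open, all configurable:

* sigma is the population standard deviation (divide by n) by default;
* the mean/sd reference spans the whole matrix by default, not only the
  pathway samples;
* a gene's z at a sample is the arithmetic mean of its probes' z there,
  skipping missing values;
* probes with sigma = 0 yield missing z-scores and a counted warning,
  never a division error or a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .volume import AffineTransform, world_to_voxel_table


@dataclass
class SelectionResult:
    """Samples inside a pathway mask plus bookkeeping warnings."""

    sample_ids: list[str]
    n_out_of_bounds: int

    def __len__(self) -> int:
        return len(self.sample_ids)


def samples_in_pathway(
    samples: pd.DataFrame,
    mask: np.ndarray,
    affine: AffineTransform,
) -> SelectionResult:
    """Select the samples whose world coordinate falls in the mask.

    A sample is selected iff its world-mm point maps (inverse affine,
    floor) to an in-bounds voxel where ``mask`` is true.  Out-of-bounds
    samples are excluded and counted.
    """
    pts = samples[["x", "y", "z"]].to_numpy(dtype=float)
    idx, in_bounds = world_to_voxel_table(affine, pts, mask.shape)
    selected = np.zeros(len(samples), dtype=bool)
    ib = np.where(in_bounds)[0]
    selected[ib] = mask[idx[ib, 0], idx[ib, 1], idx[ib, 2]]
    return SelectionResult(
        sample_ids=samples.loc[selected, "sample_id"].tolist(),
        n_out_of_bounds=int((~in_bounds).sum()),
    )


def probe_zscores(
    matrix: pd.DataFrame,
    ddof: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe z = (x - mu) / sigma across all samples of the matrix.

    Returns ``(z, stats)`` where ``stats`` holds each probe's mean and
    standard deviation (``ddof=0``: population convention).  Probes with
    sigma = 0 get all-missing z rows; their count is in
    ``stats.attrs["n_sigma_zero"]``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    mu = values.mean(axis=1)
    sigma = values.std(axis=1, ddof=ddof)
    z = np.full_like(values, np.nan)
    ok = sigma > 0
    z[ok] = (values[ok] - mu[ok, None]) / sigma[ok, None]
    z_df = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    stats = pd.DataFrame({"mean": mu, "sd": sigma}, index=matrix.index)
    stats.attrs["n_sigma_zero"] = int((~ok).sum())
    return z_df, stats


def gene_zscores(
    z: pd.DataFrame,
    probe_gene: pd.DataFrame,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Gene x sample z-matrix: mean of each gene's probe z-scores.

    Missing probe values are skipped; a gene x sample cell is missing
    iff all its probes are missing there.  A requested gene with no
    probe in the map is a hard error.
    """
    gene_probes = probe_gene.groupby("gene")["probe_id"].apply(list).to_dict()
    missing = [g for g in genes if g not in gene_probes or not gene_probes[g]]
    if missing:
        raise ValueError(f"genes with no probes: {missing}")
    rows = []
    for g in genes:
        probes = [p for p in gene_probes[g] if p in z.index]
        if not probes:
            raise ValueError(f"genes with no probes: [{g!r}]")
        rows.append(z.loc[probes].mean(axis=0, skipna=True))
    return pd.DataFrame(rows, index=pd.Index(list(genes), name="gene"))


def pathway_average(
    gene_z: pd.DataFrame,
    selected_sample_ids: Sequence[str],
    pathway: str = "",
) -> pd.DataFrame:
    """Per-gene average z-score over the selected pathway samples.

    Implements the average-z summary: for each gene, the arithmetic mean
    of its z-scores over the n selected samples with non-missing values.
    Genes with n = 0 are omitted (counted in ``attrs["n_genes_dropped"]``);
    an empty selection yields a zero-row summary, mirroring pathways in
    which no sample lies.
    """
    ids = [s for s in selected_sample_ids if s in gene_z.columns]
    out_rows = []
    dropped = 0
    for gene, row in gene_z[ids].iterrows() if ids else []:
        vals = row.dropna()
        if len(vals) == 0:
            dropped += 1
            continue
        out_rows.append(
            {
                "pathway": pathway,
                "gene": gene,
                "average_z": float(vals.mean()),
                "n": int(len(vals)),
                "sample_ids": ",".join(vals.index),
            }
        )
    df = pd.DataFrame(
        out_rows, columns=["pathway", "gene", "average_z", "n", "sample_ids"]
    )
    df.attrs["n_genes_dropped"] = dropped
    return df


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Probe x sample matrix: first column probe ids, header sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_samples_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"sample table needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    return df
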