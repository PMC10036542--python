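"""Time-series expression handling: fold changes, DEG calls, clustering.

Differential expression is a pure fold-change rule: a gene is differentially
expressed at a timepoint when |log2 FC| versus the control meets a threshold
(default 1, boundary inclusive).  Fold changes are computed on replicate
means with a pseudocount so every value is finite; no dispersion-modelled
test is applied at this stage.

Profile clustering is agglomerative (average linkage, Euclidean distance on
z-scored profiles) cut at a cophenetic distance threshold (default 3), and
per-gene z-scores are taken across timepoint means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    timepoint: str
    log2fc: float
    direction: str  # "up" | "down"


class ExpressionMatrix:
    """Counts with (timepoint, replicate)-labelled samples.

    Sample ids follow `<timepoint>_<replicate>`; exactly one timepoint is
    designated the control.  Timepoint means and across-timepoint z-scores
    are derived lazily.
    """

    def __init__(self, counts: pd.DataFrame, timepoints: Sequence[str], control: str):
        if control not in timepoints:
            raise ValueError(f"control timepoint {control!r} not in {list(timepoints)}")
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        self.counts = counts
        self.timepoints = list(timepoints)
        self.control = control
        self._groups: dict[str, list[str]] = {t: [] for t in self.timepoints}
        for col in counts.columns:
            tp = col.rsplit("_", 1)[0]
            if tp not in self._groups:
                raise ValueError(f"sample {col!r} has unknown timepoint {tp!r}")
            self._groups[tp].append(col)
        for tp, cols in self._groups.items():
            if not cols:
                raise ValueError(f"timepoint {tp!r} has no replicates")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def replicates(self, timepoint: str) -> list[str]:
        if timepoint not in self._groups:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return list(self._groups[timepoint])

    def timepoint_means(self) -> pd.DataFrame:
        """Per-gene mean counts per timepoint, in timepoint order."""
        return pd.DataFrame(
            {tp: self.counts[self._groups[tp]].mean(axis=1) for tp in self.timepoints}
        )

    def zscores(self) -> pd.DataFrame:
        """Per-gene z-scores across timepoint means.

        Zero-variance genes get all-zero rows rather than NaN.
        """
        means = self.timepoint_means()
        mu = means.mean(axis=1)
        sd = means.std(axis=1, ddof=0)
        z = means.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        return z.fillna(0.0)


def compute_log2fc(
    matrix: ExpressionMatrix, timepoint: str, pseudocount: float = 1.0
) -> pd.Series:
    """log2((mean treated + c) / (mean control + c)) per gene."""
    if timepoint == matrix.control:
        raise ValueError("timepoint must differ from the control")
    treated = matrix.counts[matrix.replicates(timepoint)].mean(axis=1)
    control = matrix.counts[matrix.replicates(matrix.control)].mean(axis=1)
    return np.log2((treated + pseudocount) / (control + pseudocount))


def call_degs(
    log2fc: pd.Series, timepoint: str, threshold: float = 1.0
) -> list[DEGRecord]:
    """Genes with |log2FC| >= threshold, split into up/down (boundary in)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    records = []
    for gene, v in log2fc.items():
        if abs(v) >= threshold:
            records.append(
                DEGRecord(gene, timepoint, float(v), "up" if v > 0 else "down")
            )
    return records


def deg_table(matrix: ExpressionMatrix, threshold: float = 1.0,
              pseudocount: float = 1.0) -> pd.DataFrame:
    """DEG records for every post-control timepoint, as one tidy table."""
    rows = []
    for tp in matrix.timepoints:
        if tp == matrix.control:
            continue
        lfc = compute_log2fc(matrix, tp, pseudocount)
        rows.extend(
            (r.gene, r.timepoint, r.log2fc, r.direction)
            for r in call_degs(lfc, tp, threshold)
        )
    return pd.DataFrame(rows, columns=["gene", "timepoint", "log2fc", "direction"])


def cluster_expression(profiles: pd.DataFrame, linkage_cut: float = 3.0) -> pd.Series:
    """Agglomerative clustering of expression profiles.

    Profiles (genes x timepoints) are z-scored per gene, clustered with
    average linkage on Euclidean distances, and the dendrogram is cut at
    the given cophenetic distance.  Returns integer labels indexed by gene.
    """
    if len(profiles) == 1:
        return pd.Series([1], index=profiles.index, name="cluster")
    if len(profiles) < 1:
        raise ValueError("no profiles to cluster")
    mat = profiles.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    tree = linkage(z, method="average", metric="euclidean")
    labels = fcluster(tree, t=linkage_cut, criterion="distance")
    return pd.Series(labels, index=profiles.index, name="cluster")
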