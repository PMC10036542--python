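"""Per-timepoint transcriptional network modules.

The DEG signal at each timepoint is diffused over the regulatory network by
random-walk-with-restart propagation; each TF's influence is the Pearson
correlation between its propagated vector (unit seed at the TF) and the DEG
|log2 FC| magnitudes; TFs are then selected greedily in influence order,
each accepted only if it covers at least one not-yet-covered DEG target.
The selected TFs, the DEG targets they cover and the induced edges form the
timepoint's module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import DEGRecord
from .grn import GRN


@dataclass(frozen=True)
class PropagationConfig:
    restart: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.restart <= 1:
            raise ValueError("restart must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol and max_iter must be positive")


@dataclass
class PropagationOperator:
    """Column-normalized TF->target adjacency over a fixed node order."""

    nodes: list[str]
    matrix: np.ndarray  # W[i, j]: mass flowing j -> i
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.nodes)}


@dataclass
class NetworkModule:
    timepoint: str
    major_tfs: list[tuple[str, float]]  # greedy selection order, with influence
    targets: set[str]
    edges: set[tuple[str, str]]
    uncovered: set[str]  # DEGs no GRN TF reaches
    influence: dict[str, float] = field(default_factory=dict)

    @property
    def tf_ids(self) -> list[str]:
        return [tf for tf, _ in self.major_tfs]


def normalize_adjacency(grn: GRN) -> PropagationOperator:
    """Out-degree (column) normalization of the directed TF->target graph.

    Columns of nodes with no out-edges stay zero: during propagation their
    mass decays back to the restart distribution.  Normalizing an already
    normalized operator is a no-op.
    """
    if not grn.edges and not grn.tfs:
        raise ValueError("empty GRN")
    nodes = sorted(grn.tfs | grn.targets)
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for e in grn.edges:
        W[idx[e.target], idx[e.tf]] = 1.0
    colsum = W.sum(axis=0)
    nz = colsum > 0
    W[:, nz] /= colsum[nz]
    return PropagationOperator(nodes, W)


def propagate(
    seed: np.ndarray, operator: PropagationOperator, config: PropagationConfig = PropagationConfig()
) -> np.ndarray:
    """Random walk with restart: p <- (1-r) W p + r p0, iterated to a fixed point.

    The seed is normalized to sum 1 internally.  Converges in L1 within
    `tol`; if `max_iter` is hit first a warning is issued and the last
    iterate returned.
    """
    p0 = np.asarray(seed, dtype=float)
    if p0.shape != (len(operator.nodes),):
        raise ValueError("seed length does not match operator")
    if (p0 < 0).any() or p0.sum() == 0:
        raise ValueError("seed must be non-negative and not all zero")
    p0 = p0 / p0.sum()
    r = config.restart
    p = p0.copy()
    for _ in range(config.max_iter):
        p_next = (1 - r) * (operator.matrix @ p) + r * p0
        if np.abs(p_next - p).sum() < config.tol:
            return p_next
        p = p_next
    warnings.warn("propagation did not converge within max_iter", RuntimeWarning)
    return p


def _deg_magnitudes(deg_records: Sequence[DEGRecord], timepoint: str) -> dict[str, float]:
    return {r.gene: abs(r.log2fc) for r in deg_records if r.timepoint == timepoint}


def score_tf_influence(
    tf: str,
    grn: GRN,
    deg_magnitude: Mapping[str, float],
    operator: PropagationOperator,
    config: PropagationConfig = PropagationConfig(),
) -> float:
    """Pearson correlation of the TF's propagated vector with |log2FC|.

    Both vectors are restricted to the timepoint's DEG genes present in the
    network; degenerate cases (fewer than two DEGs in the network, or a
    constant vector on them) score 0.
    """
    if tf not in grn.tfs:
        raise KeyError(f"{tf!r} is not a TF of the GRN")
    deg_in_net = sorted(g for g in deg_magnitude if g in operator.index)
    if len(deg_in_net) < 2:
        return 0.0
    seed = np.zeros(len(operator.nodes))
    seed[operator.index[tf]] = 1.0
    p = propagate(seed, operator, config)
    x = np.array([p[operator.index[g]] for g in deg_in_net])
    y = np.array([deg_magnitude[g] for g in deg_in_net])
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def select_major_tfs(
    grn: GRN,
    deg_records: Sequence[DEGRecord],
    timepoint: str,
    config: PropagationConfig = PropagationConfig(),
) -> NetworkModule:
    """Greedy influence-maximization selection of a timepoint's major TFs.

    TFs are ranked by influence score (ties by id); walking down the
    ranking, a TF is selected iff it covers at least one not-yet-covered
    DEG target, stopping once every coverable DEG is covered.  DEGs no TF
    targets are reported separately as `uncovered`.
    """
    magnitude = _deg_magnitudes(deg_records, timepoint)
    if not magnitude:
        return NetworkModule(timepoint, [], set(), set(), set())
    operator = normalize_adjacency(grn)
    influence = {
        tf: score_tf_influence(tf, grn, magnitude, operator, config)
        for tf in sorted(grn.tfs)
    }
    degs = set(magnitude)
    coverable = {g for tf in grn.tfs for g in grn.targets_of(tf) & degs}
    ranked = sorted(influence, key=lambda tf: (-influence[tf], tf))
    selected: list[tuple[str, float]] = []
    covered: set[str] = set()
    for tf in ranked:
        gain = grn.targets_of(tf) & degs - covered
        if gain:
            selected.append((tf, influence[tf]))
            covered |= gain
        if covered == coverable:
            break
    edges = {
        (tf, t) for tf, _ in selected for t in grn.targets_of(tf) & covered
    }
    return NetworkModule(
        timepoint=timepoint,
        major_tfs=selected,
        targets=covered,
        edges=edges,
        uncovered=degs - coverable,
        influence=influence,
    )


def extract_modules(
    grn: GRN,
    deg_frame: pd.DataFrame,
    timepoints: Sequence[str],
    config: PropagationConfig = PropagationConfig(),
) -> dict[str, NetworkModule]:
    """Modules for every listed (post-control) timepoint from a DEG table."""
    records = [
        DEGRecord(r.gene, r.timepoint, float(r.log2fc), r.direction)
        for r in deg_frame.itertuples(index=False)
    ]
    return {tp: select_major_tfs(grn, records, tp, config) for tp in timepoints}


def membership_table(modules: Mapping[str, NetworkModule]) -> pd.DataFrame:
    """TF-by-timepoint membership indicator (the Venn-diagram data)."""
    tfs = sorted({tf for m in modules.values() for tf in m.tf_ids})
    data = {tp: [int(tf in m.tf_ids) for tf in tfs] for tp, m in modules.items()}
    return pd.DataFrame(data, index=pd.Index(tfs, name="tf"))
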