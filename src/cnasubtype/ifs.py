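"""Incremental feature selection over a ranked probe list.

Probes are added one by one from higher to lower rank; for every prefix size
i the nearest-neighbor classifier is re-evaluated by leave-one-out
cross-validation, giving the IFS curve (subset size vs. MCC).  The optimal
subset is the smallest prefix achieving the maximum MCC (parsimony on ties).
No early stopping: the full curve up to ``max_n`` is always produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import PerformanceMetrics, loocv, metrics
from .io import CNAMatrix
from .mrmr import RankedProbeList

DEFAULT_MAX_N = 1000


@dataclass(frozen=True)
class IFSRecord:
    """Jackknife metrics of the top-*i* prefix of the ranking."""

    i: int
    sn: float
    sp: float
    acc: float
    mcc: float


@dataclass
class IFSTable:
    """The full IFS curve: one record per prefix size, 1..N contiguous."""

    records: list[IFSRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records:
            if self.records[0].i != 1:
                raise ValueError("IFS table must start at subset size 1")
            for prev, rec in zip(self.records, self.records[1:]):
                if rec.i != prev.i + 1:
                    raise ValueError(
                        f"IFS subset sizes must be contiguous; gap after i={prev.i}"
                    )

    @property
    def mcc(self) -> np.ndarray:
        return np.asarray([r.mcc for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class OptimalSubset:
    """The prefix with the best cross-validated MCC."""

    size: int
    probe_ids: list[str]
    metrics: PerformanceMetrics

    def __post_init__(self) -> None:
        if self.size != len(self.probe_ids):
            raise ValueError("size must equal the number of probe ids")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def run_ifs(
    matrix: CNAMatrix,
    ranked: RankedProbeList,
    max_n: int | None = None,
) -> IFSTable:
    """Evaluate LOOCV on every prefix of the ranking, sizes 1..max_n.

    Each prefix is evaluated with a fresh jackknife pass so every row is
    exactly reproducible by a standalone :func:`~cnasubtype.classify.loocv`
    call on the same probes.  Deterministic: no randomness anywhere.
    """
    if len(ranked) == 0:
        raise ValueError("ranking is empty")
    if max_n is None:
        max_n = min(DEFAULT_MAX_N, len(ranked))
    if not 1 <= max_n <= len(ranked):
        raise ValueError(f"max_n must be in 1..{len(ranked)}, got {max_n}")
    # fail fast, naming the first ranked probe missing from the matrix
    matrix.probe_indices(ranked.probe_ids[:max_n])

    records = []
    for i in range(1, max_n + 1):
        m = metrics(loocv(matrix, ranked.probe_ids[:i]))
        records.append(
            IFSRecord(i=i, sn=m.sensitivity, sp=m.specificity, acc=m.accuracy, mcc=m.mcc)
        )
    return IFSTable(
        records=records,
        provenance={
            "ranking_method": ranked.method,
            "n_samples": matrix.n_samples,
            "n_probes": matrix.n_probes,
            "max_n": max_n,
        },
    )


def select_optimal(table: IFSTable, ranked: RankedProbeList) -> OptimalSubset:
    """Smallest prefix size achieving the maximum MCC, with its probes/metrics."""
    if not table.records:
        raise ValueError("IFS table is empty")
    mccs = table.mcc
    best = int(np.argmax(mccs))  # first max -> smallest i on ties
    rec = table.records[best]
    return OptimalSubset(
        size=rec.i,
        probe_ids=list(ranked.probe_ids[: rec.i]),
        metrics=PerformanceMetrics(rec.sn, rec.sp, rec.acc, rec.mcc),
    )


def export_heatmap_data(
    matrix: CNAMatrix,
    subset: OptimalSubset,
    path=None,
) -> pd.DataFrame:
    """Probes x samples matrix for heatmap display, per-probe standardized.

    Rows are the optimal probes (ranking order), columns the samples grouped
    positive class first; each row is centered to mean 0 and scaled to unit
    sample standard deviation.  A zero-variance probe is emitted as zeros
    with a warning.
    """
    idx = matrix.probe_indices(subset.probe_ids)
    order = np.concatenate([np.flatnonzero(matrix.y), np.flatnonzero(~matrix.y)])
    X = matrix.values[np.ix_(order, idx)].T  # probes x samples
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance probe(s) emitted as all-zero rows",
            stacklevel=2,
        )
    Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    df = pd.DataFrame(
        Z,
        index=subset.probe_ids,
        columns=[matrix.sample_ids[i] for i in order],
    )
    df.index.name = "probe_id"
    if path is not None:
        df.to_csv(path, sep="\t")
    return df
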