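"""Probe discretization, mutual information, and MaxRel / mRMR rankings.

Copy-number values are reduced to three states per probe around the probe's
own mean: state -1 below ``mean - alpha*sd``, +1 above ``mean + alpha*sd``,
0 in between (sample standard deviation, n-1 denominator; alpha defaults to
1.0, the convention of the classic mRMR software for continuous inputs).
Mutual information is then the discrete plug-in estimate in bits.

MaxRel ranks probes purely by relevance I(probe; class).  mRMR ranks them
greedily: each round picks the unselected probe maximizing

    relevance - redundancy  =  I(probe; class) - mean_{s in selected} I(probe; s)

(the difference combination, "MID"; the quotient form is available behind a
flag for sensitivity analysis).  Ties at every step are broken by input
probe order, making both rankings fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CNAMatrix

DEFAULT_ALPHA = 1.0
DEFAULT_TOP_N = 1000


@dataclass
class DiscreteMatrix:
    """Three-state discretization of a CNA matrix.

    ``states`` has the source shape with cells in {-1, 0, +1}; ``means`` and
    ``sds`` record the per-probe thresholds used (``mean +/- alpha*sd``).
    """

    states: np.ndarray
    probe_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    alpha: float

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_probes(self) -> int:
        return self.states.shape[1]


@dataclass
class RankedProbeList:
    """Ordered probe ids with scores; rank h starts at 1.

    ``score`` is the relevance I(probe; class) for MaxRel and the greedy
    criterion value (relevance - redundancy, or their quotient) at the round
    of selection for mRMR.
    """

    probe_ids: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.probe_ids) != len(self.scores):
            raise ValueError("probe_ids and scores must have equal length")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("ranked list contains duplicate probe ids")

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.probe_ids) + 1)

    def top(self, n: int) -> list[str]:
        return self.probe_ids[:n]

    def __len__(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(matrix: CNAMatrix, alpha: float = DEFAULT_ALPHA) -> DiscreteMatrix:
    """Map each probe to three states around its mean +/- alpha*sd thresholds.

    A zero-variance probe (or a single-sample matrix, where the sample sd is
    undefined) maps entirely to state 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    X = matrix.values
    means = X.mean(axis=0)
    if X.shape[0] > 1:
        sds = X.std(axis=0, ddof=1)
    else:
        sds = np.zeros(X.shape[1])
    states = np.zeros(X.shape, dtype=np.int8)
    ok = sds > 0
    lo = means - alpha * sds
    hi = means + alpha * sds
    states[:, ok] = np.where(
        X[:, ok] < lo[ok], -1, np.where(X[:, ok] > hi[ok], 1, 0)
    ).astype(np.int8)
    return DiscreteMatrix(
        states=states,
        probe_ids=list(matrix.probe_ids),
        means=means,
        sds=sds,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Mutual information (plug-in, bits)
# ---------------------------------------------------------------------------

def mutual_information(x: Sequence, y: Sequence) -> float:
    """I(x; y) in bits from the empirical joint distribution.

    Plug-in estimate over observed joint cells; 0*log(.) terms contribute 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}")
    if len(x) == 0:
        raise ValueError("vectors must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    return float(_mi_columns(xi[:, None], yi)[0])


def _mi_columns(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI (bits) between every column of *codes* and the vector *y*.

    Both arguments hold small non-negative integer state codes.  Vectorized
    over columns: one boolean pass per (x-state, y-state) pair.
    """
    n = len(y)
    mi = np.zeros(codes.shape[1])
    x_states = np.unique(codes)
    y_states = np.unique(y)
    px = {s: (codes == s).mean(axis=0) for s in x_states}
    for c in y_states:
        mask_y = y == c
        py = mask_y.mean()
        for s in x_states:
            joint = ((codes == s) & mask_y[:, None]).sum(axis=0) / n
            with np.errstate(divide="ignore", invalid="ignore"):
                term = joint * np.log2(joint / (px[s] * py))
            mi += np.where(joint > 0, term, 0.0)
    # tiny negative values can arise from float cancellation on independent pairs
    return np.maximum(mi, 0.0)


def _label_codes(matrix_or_labels) -> np.ndarray:
    if isinstance(matrix_or_labels, CNAMatrix):
        matrix_or_labels.require_both_classes()
        return matrix_or_labels.y.astype(np.int8)
    y = np.asarray(matrix_or_labels)
    _, codes = np.unique(y, return_inverse=True)
    if len(np.unique(codes)) < 2:
        raise ValueError("both classes must be present in labels")
    return codes


def relevance(dmatrix: DiscreteMatrix, labels) -> np.ndarray:
    """I(probe; class) per probe, in bits."""
    y = _label_codes(labels)
    if len(y) != dmatrix.n_samples:
        raise ValueError("labels length does not match matrix sample count")
    # shift states {-1,0,1} -> {0,1,2} for the code-based kernel
    return _mi_columns(dmatrix.states.astype(np.int8) + 1, y)


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------

def max_rel_rank(
    dmatrix: DiscreteMatrix, labels, top_n: int = DEFAULT_TOP_N
) -> RankedProbeList:
    """Rank probes by relevance to the class label, descending.

    Ties keep input probe order (stable sort); the list is truncated to
    *top_n* probes.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    rel = relevance(dmatrix, labels)
    order = np.argsort(-rel, kind="stable")[:top_n]
    return RankedProbeList(
        probe_ids=[dmatrix.probe_ids[i] for i in order],
        scores=rel[order],
        method="maxrel",
    )


def mrmr_rank(
    dmatrix: DiscreteMatrix,
    labels,
    top_n: int = DEFAULT_TOP_N,
    combination: str = "difference",
) -> RankedProbeList:
    """Greedy minimum-redundancy maximum-relevance ranking.

    Round 1 picks the maximum-relevance probe; round m+1 picks the unselected
    probe maximizing ``D - R`` (or ``D / R`` with ``combination="quotient"``)
    where D is the probe's relevance and R its mean mutual information with
    the m already-selected probes.  Ties break by input probe order.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if combination not in ("difference", "quotient"):
        raise ValueError(f"unknown combination {combination!r}")
    y = _label_codes(labels)
    if len(y) != dmatrix.n_samples:
        raise ValueError("labels length does not match matrix sample count")
    p = dmatrix.n_probes
    if top_n > p:
        warnings.warn(
            f"top_n={top_n} exceeds probe count {p}; truncating to {p}",
            stacklevel=2,
        )
        top_n = p

    codes = dmatrix.states.astype(np.int8) + 1  # {0,1,2}
    rel = _mi_columns(codes, y)

    selected: list[int] = []
    scores: list[float] = []
    cum_red = np.zeros(p)  # sum of MI(probe, s) over selected s
    remaining = np.ones(p, dtype=bool)

    for round_no in range(top_n):
        if round_no == 0:
            crit = rel.copy()
        else:
            mean_red = cum_red / round_no
            if combination == "difference":
                crit = rel - mean_red
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    crit = np.where(mean_red > 0, rel / mean_red, np.inf)
        crit = np.where(remaining, crit, -np.inf)
        best = int(np.argmax(crit))  # first max wins: input-order tie-break
        selected.append(best)
        scores.append(float(crit[best]))
        remaining[best] = False
        if round_no < top_n - 1:
            cum_red += _mi_columns(codes, codes[:, best])

    return RankedProbeList(
        probe_ids=[dmatrix.probe_ids[i] for i in selected],
        scores=np.asarray(scores),
        method="mrmr",
    )


def write_ranking(ranked: RankedProbeList, path) -> None:
    """Write a ranking as TSV: rank, probe_id, score."""
    with open(path, "w", newline="") as fh:
        fh.write("rank\tprobe_id\tscore\n")
        for h, (pid, s) in enumerate(zip(ranked.probe_ids, ranked.scores), start=1):
            fh.write(f"{h}\t{pid}\t{float(s)!r}\n")


def read_ranking(path, method: str = "mrmr") -> RankedProbeList:
    """Read a TSV ranking written by :func:`write_ranking`."""
    ids: list[str] = []
    scores: list[float] = []
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["rank", "probe_id", "score"]:
            raise ValueError(f"{path}: unexpected ranking header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            rank_s, pid, score_s = line.rstrip("\n").split("\t")
            if int(rank_s) != len(ids) + 1:
                raise ValueError(f"{path}: line {lineno}: ranks must be contiguous from 1")
            ids.append(pid)
            scores.append(float(score_s))
    return RankedProbeList(probe_ids=ids, scores=np.asarray(scores), method=method)
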