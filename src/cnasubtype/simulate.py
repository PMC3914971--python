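"""Synthetic two-class copy-number cohorts with known ground truth.

The generator emulates the structure of a two-class SNP-array CNA study:
a large background of class-independent probes, a small planted set of
class-informative probes whose class means differ by a fixed effect size
(alternating between gains and losses in the positive class),
and, for each informative probe, a block of redundant near-copies (parent
plus small independent jitter).  The planted/redundant structure creates
exactly the relevance/redundancy trade-off that mRMR ranking is designed to
exploit, so "parents rank above their copies" is a testable property.

Defaults mirror the cohort the pipeline targets: 208 positive (ACA) versus
93 negative (SCC) samples, a diploid baseline of 2.0, Gaussian measurement
noise, and 10 informative probes with 4 redundant partners each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import NEGATIVE_LABEL, POSITIVE_LABEL, CNAMatrix, GeneModel, GeneSet, ProbeAnnotation

#: genomic spacing between consecutive synthetic probes (bp)
PROBE_SPACING = 10_000
#: half-width of the synthetic gene span around its probe (bp)
GENE_HALF_SPAN = 500


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_pos, n_neg
        Samples in the positive (ACA) and negative (SCC) class.
    p_total
        Total probe count, informative + redundant + background.
    informative
        Planted class-informative probe column indices.
    effect_size
        Magnitude of the class-mean shift of each informative probe, in units
        of ``noise_sd`` (a standardized effect size); the positive class is
        shifted up on even-indexed planted probes and down on odd-indexed
        ones, emulating subtype-specific gains and losses.
    block_size
        Redundant near-copies generated per informative probe.
    noise_sd
        Standard deviation of the Gaussian measurement noise (copy-number units).
    baseline
        Diploid baseline copy number.
    jitter_sd
        Noise added to each redundant partner on top of its parent; the
        default ``noise_sd / 3`` keeps parent/partner Pearson correlation
        above 0.9 by construction.
    seed
        Single integer seed; every draw flows from one generator.
    """

    n_pos: int = 208
    n_neg: int = 93
    p_total: int = 2000
    informative: tuple[int, ...] = tuple(range(10))
    effect_size: float = 2.0
    block_size: int = 4
    noise_sd: float = 0.3
    baseline: float = 2.0
    jitter_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "informative", tuple(int(i) for i in self.informative))
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 samples per class")
        if len(set(self.informative)) != len(self.informative):
            raise ValueError("informative probe indices must be unique")
        if any(i < 0 or i >= self.p_total for i in self.informative):
            raise ValueError("informative probe index out of range")
        if self.p_total < len(self.informative) * (1 + self.block_size):
            raise ValueError(
                "p_total must be >= n_informative * (1 + block_size) "
                f"({self.p_total} < {len(self.informative) * (1 + self.block_size)})"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.jitter_sd is not None and self.jitter_sd <= 0:
            raise ValueError("jitter_sd must be > 0")
        if self.block_size < 0:
            raise ValueError("block_size must be >= 0")

    @property
    def effective_jitter_sd(self) -> float:
        return self.noise_sd / 3.0 if self.jitter_sd is None else self.jitter_sd

    @property
    def n_samples(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    informative: tuple[str, ...]
    partners: dict[str, tuple[str, ...]]  # parent probe id -> redundant copies
    spec: SyntheticSpec

    @property
    def all_planted(self) -> frozenset[str]:
        """Informative parents plus every redundant partner."""
        out = set(self.informative)
        for copies in self.partners.values():
            out.update(copies)
        return frozenset(out)


def probe_name(j: int) -> str:
    return f"P{j:06d}"


def gene_name(j: int) -> str:
    return f"G{j:06d}"


def _partner_indices(spec: SyntheticSpec) -> dict[int, list[int]]:
    """Assign each informative probe its redundant-partner columns.

    Partners take the smallest column indices not already used by an
    informative probe, in parent order — deterministic given the spec.
    """
    used = set(spec.informative)
    pool = (j for j in range(spec.p_total) if j not in used)
    return {
        parent: [next(pool) for _ in range(spec.block_size)]
        for parent in spec.informative
    }


def generate(spec: SyntheticSpec) -> tuple[CNAMatrix, SyntheticTruth]:
    """Generate one cohort; byte-identical output for equal specs."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.p_total
    values = spec.baseline + rng.normal(0.0, spec.noise_sd, size=(n, p))

    # Alternate gain/loss across the planted probes: subtype contrasts are
    # mixtures of copy-number gains and losses, and the direction contrast is
    # what an angle-based (cosine) classifier can see.
    shift = spec.effect_size * spec.noise_sd
    pos = np.arange(n) < spec.n_pos
    for k, j in enumerate(spec.informative):
        values[pos, j] += shift if k % 2 == 0 else -shift

    partners = _partner_indices(spec)
    for parent, copies in partners.items():
        for j in copies:
            values[:, j] = values[:, parent] + rng.normal(
                0.0, spec.effective_jitter_sd, size=n
            )

    labels = np.where(pos, POSITIVE_LABEL, NEGATIVE_LABEL).astype(object)
    matrix = CNAMatrix(
        values=values,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        probe_ids=[probe_name(j) for j in range(p)],
        labels=labels,
    )
    truth = SyntheticTruth(
        informative=tuple(probe_name(j) for j in spec.informative),
        partners={
            probe_name(parent): tuple(probe_name(j) for j in copies)
            for parent, copies in partners.items()
        },
        spec=spec,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Companion annotation: each probe gets its own gene on one synthetic chromosome
# ---------------------------------------------------------------------------

def generate_annotation(
    spec: SyntheticSpec,
) -> tuple[list[ProbeAnnotation], list[GeneModel]]:
    """Probe positions and one gene per probe, on a single synthetic chromosome.

    Probe *j* sits at ``j * PROBE_SPACING`` and its gene spans +/-
    ``GENE_HALF_SPAN`` around it; with the default 2 kb mapping extension each
    probe maps to exactly its own gene.
    """
    probes = [
        ProbeAnnotation(probe_name(j), "chrS", j * PROBE_SPACING)
        for j in range(spec.p_total)
    ]
    genes = [
        GeneModel(
            gene_name(j),
            "chrS",
            max(0, j * PROBE_SPACING - GENE_HALF_SPAN),
            j * PROBE_SPACING + GENE_HALF_SPAN,
        )
        for j in range(spec.p_total)
    ]
    return probes, genes


def generate_genesets(
    truth: SyntheticTruth,
    n_null_sets: int = 50,
    set_size: int = 20,
    seed: int = 0,
) -> tuple[list[GeneSet], list[str]]:
    """One planted gene set plus random null sets, with the gene universe.

    The planted set holds the genes of every planted probe (informative
    parents and their redundant partners — the partners carry the same class
    signal), padded with random universe genes up to *set_size*; null sets
    are uniform draws from the universe.  Returns ``(gene_sets, universe)``.
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    rng = np.random.default_rng(seed)
    spec = truth.spec
    universe = [gene_name(j) for j in range(spec.p_total)]
    if set_size > len(universe):
        raise ValueError(
            f"set_size {set_size} exceeds universe size {len(universe)}"
        )

    planted_genes = {
        gene_name(int(pid[1:])) for pid in truth.all_planted
    }
    padding_pool = [g for g in universe if g not in planted_genes]
    n_pad = max(0, set_size - len(planted_genes))
    padding = rng.choice(len(padding_pool), size=n_pad, replace=False)
    planted = GeneSet(
        "PLANTED",
        "genes of the planted probes, parents and partners (padded)",
        frozenset(planted_genes | {padding_pool[i] for i in padding}),
    )

    sets = [planted]
    for k in range(n_null_sets):
        idx = rng.choice(len(universe), size=set_size, replace=False)
        sets.append(
            GeneSet(
                f"NULL{k:03d}",
                "random gene set",
                frozenset(universe[i] for i in idx),
            )
        )
    return sets, universe
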