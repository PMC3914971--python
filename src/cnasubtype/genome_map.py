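"""Probe-to-gene interval mapping with symmetric flank extension.

A probe maps to a gene when it lies on the same chromosome within the gene
span extended by a fixed flank (default 2 kb) on both sides — strand is
ignored, the extension is symmetric.  All coordinates are 0-based half-open:
probe p maps to gene g iff ``start(g) - ext <= pos(p) < end(g) + ext``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import GeneModel, ProbeAnnotation
from .ifs import OptimalSubset

DEFAULT_EXTENSION = 2000


@dataclass
class ProbeGeneMap:
    """Many-to-many probe/gene pairs from one mapping run."""

    pairs: list[tuple[str, str]]
    extension: int

    def genes_for(self, probe_id: str) -> list[str]:
        return sorted({g for p, g in self.pairs if p == probe_id})

    @property
    def as_dict(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, g in self.pairs:
            out.setdefault(p, set()).add(g)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def map_probes_to_genes(
    probes: Sequence[ProbeAnnotation],
    genes: Sequence[GeneModel],
    extension: int = DEFAULT_EXTENSION,
) -> ProbeGeneMap:
    """All (probe, gene) pairs where the probe falls in the extended gene span.

    Sorted-sweep per chromosome: probe positions are sorted once and each
    gene's extended interval is located with binary search, so the result is
    identical to the all-pairs interval check at O((n+m) log n) cost.
    Pairs are returned sorted by (probe_id, gene_id).
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    by_chrom: dict[str, list[ProbeAnnotation]] = {}
    for p in probes:
        by_chrom.setdefault(p.chromosome, []).append(p)
    sorted_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.position)
        sorted_chrom[chrom] = (
            np.asarray([p.position for p in plist]),
            [p.probe_id for p in plist],
        )

    pairs: list[tuple[str, str]] = []
    for g in genes:
        if g.chromosome not in sorted_chrom:
            continue
        positions, ids = sorted_chrom[g.chromosome]
        lo = max(0, g.start - extension)  # clip: positions are never negative
        hi = g.end + extension
        a = int(np.searchsorted(positions, lo, side="left"))
        b = int(np.searchsorted(positions, hi, side="left"))
        pairs.extend((ids[k], g.gene_id) for k in range(a, b))
    pairs.sort()
    return ProbeGeneMap(pairs=pairs, extension=extension)


def genes_of_subset(
    subset: OptimalSubset | Iterable[str], pmap: ProbeGeneMap
) -> list[str]:
    """Sorted unique genes hit by the subset's probes (unmapped probes drop out)."""
    probe_ids = subset.probe_ids if isinstance(subset, OptimalSubset) else list(subset)
    lookup = pmap.as_dict
    out: set[str] = set()
    for pid in probe_ids:
        out.update(lookup.get(pid, ()))
    return sorted(out)


def write_map(pmap: ProbeGeneMap, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("probe_id\tgene_id\n")
        for p, g in pmap.pairs:
            fh.write(f"{p}\t{g}\n")
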