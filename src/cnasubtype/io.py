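"""Core data types and readers/writers for the file formats the pipeline touches.

The canonical in-memory container is :class:`CNAMatrix` — a samples x probes
real-valued copy-number matrix with one binary class label per sample.  The
positive class is lung adenocarcinoma (ACA), the negative class squamous cell
carcinoma (SCC); sensitivity is therefore the ACA recall and specificity the
SCC recall.

All genomic coordinates are 0-based half-open internally.  BED input is
already 0-based half-open and is taken as-is.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

POSITIVE_LABEL = "ACA"
NEGATIVE_LABEL = "SCC"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CNAMatrix:
    """Samples x probes copy-number matrix with per-sample class labels.

    Parameters
    ----------
    values
        Real-valued array of shape ``(n_samples, n_probes)``.  The copy-number
        scale (raw copy number vs. log-ratio) is not interpreted anywhere in
        the pipeline; only ordinal structure and vector angles are used.
    sample_ids, probe_ids
        Unique identifiers for rows and columns.
    labels
        One class label per sample; exactly the strings ``positive_label`` or
        ``negative_label``.
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    labels: np.ndarray
    positive_label: str = POSITIVE_LABEL
    negative_label: str = NEGATIVE_LABEL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x probes array")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.probe_ids) != p:
            raise ValueError(
                f"{len(self.probe_ids)} probe ids for {p} matrix columns"
            )
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        for name, ids in (("sample", self.sample_ids), ("probe", self.probe_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "missing/non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, probe {self.probe_ids[bad[1]]!r}"
            )
        allowed = {self.positive_label, self.negative_label}
        unknown = set(self.labels) - allowed
        if unknown:
            raise ValueError(
                f"unknown class label(s) {sorted(unknown)}; expected {sorted(allowed)}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Boolean vector: True where the sample is in the positive class."""
        return self.labels == self.positive_label

    def require_both_classes(self) -> None:
        y = self.y
        if not y.any() or y.all():
            raise ValueError(
                "both classes must be present "
                f"(got {int(y.sum())} positive / {int((~y).sum())} negative)"
            )

    def probe_indices(self, probe_ids: Sequence[str]) -> np.ndarray:
        """Column indices of *probe_ids*, erroring on the first unknown probe."""
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        idx = []
        for pid in probe_ids:
            if pid not in lookup:
                raise KeyError(f"probe {pid!r} not present in matrix")
            idx.append(lookup[pid])
        return np.asarray(idx, dtype=int)

    def subset(self, probe_ids: Sequence[str]) -> np.ndarray:
        """Values restricted to *probe_ids*, in the order given."""
        return self.values[:, self.probe_indices(probe_ids)]

    def __eq__(self, other: object) -> bool:  # value equality, for round-trips
        if not isinstance(other, CNAMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.probe_ids == other.probe_ids
            and list(self.labels) == list(other.labels)
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class ProbeAnnotation:
    """A single SNP-array probe location (0-based)."""

    probe_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"probe {self.probe_id!r}: negative position")


@dataclass(frozen=True)
class GeneModel:
    """A gene span, 0-based half-open."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative start")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} must be < end {self.end}"
            )


@dataclass
class GeneSet:
    """A named collection of gene ids (KEGG pathway, GO term, cytoband, ...)."""

    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


# ---------------------------------------------------------------------------
# Matrix IO
# ---------------------------------------------------------------------------

LABEL_KEY = "class"


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _read_header_ids(path: Path) -> list[str]:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    return header[1:]


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> class TSV (no header required)."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if row[0] in out:
                raise ValueError(f"{path}: duplicate sample id {row[0]!r}")
            out[row[0]] = row[1]
    return out


def read_matrix(
    path: str | Path,
    orientation: str = "samples",
    labels_path: str | Path | None = None,
    positive_label: str = POSITIVE_LABEL,
    negative_label: str = NEGATIVE_LABEL,
) -> CNAMatrix:
    """Read a TSV copy-number matrix into the canonical samples-as-rows layout.

    Parameters
    ----------
    orientation
        ``"samples"`` when rows are samples (canonical), ``"probes"`` when rows
        are probes (GEO series-matrix style); the latter is transposed on read.
    labels_path
        Optional two-column sample -> class file.  If omitted, the matrix must
        embed a label line keyed ``"class"`` (a column in samples-as-rows
        layout, a row in probes-as-rows layout).
    """
    path = Path(path)
    if orientation not in ("samples", "probes"):
        raise ValueError(f"orientation must be 'samples' or 'probes', got {orientation!r}")
    header_ids = _read_header_ids(path)
    dup = _first_duplicate(header_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate column id {dup!r}")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
    dup_idx = df.index[df.index.duplicated()]
    if len(dup_idx):
        raise ValueError(f"{path}: duplicate row id {dup_idx[0]!r}")
    if orientation == "probes":
        df = df.T

    # Peel off the embedded label column, if present.
    labels_by_sample: dict[str, str]
    if LABEL_KEY in df.columns:
        labels_by_sample = {str(s): str(v) for s, v in df[LABEL_KEY].items()}
        df = df.drop(columns=[LABEL_KEY])
    elif labels_path is not None:
        labels_by_sample = read_labels(labels_path)
    else:
        raise ValueError(
            f"{path}: no '{LABEL_KEY}' label line embedded and no labels file given"
        )

    sample_ids = [str(s) for s in df.index]
    probe_ids = [str(p) for p in df.columns]

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric or blank cell at row {sample_ids[i]!r}, "
            f"column {probe_ids[j]!r}"
        )

    labels = []
    for s in sample_ids:
        if s not in labels_by_sample:
            raise ValueError(f"missing class label for sample {s!r}")
        labels.append(labels_by_sample[s])

    return CNAMatrix(
        values=numeric.to_numpy(dtype=float),
        sample_ids=sample_ids,
        probe_ids=probe_ids,
        labels=np.asarray(labels, dtype=object),
        positive_label=positive_label,
        negative_label=negative_label,
    )


def write_matrix(matrix: CNAMatrix, path: str | Path) -> None:
    """Write the canonical samples-as-rows TSV with an embedded class column."""
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.probe_ids)
    df.insert(0, LABEL_KEY, list(matrix.labels))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# IFS table IO  (duck-typed on .records to keep io free of downstream imports)
# ---------------------------------------------------------------------------

IFS_COLUMNS = ("i", "Sn", "Sp", "Acc", "MCC")


def write_ifs_table(table, path: str | Path) -> None:
    """Write an incremental-feature-selection table as TSV.

    One row per subset size *i* with the four cross-validated metrics at full
    float precision, plus 4-decimal display columns mirroring the reporting
    convention of the metrics.
    """
    records = list(table.records)
    if not records:
        raise ValueError("cannot write an empty IFS table")
    if records[0].i != 1:
        raise ValueError(f"IFS table must start at subset size 1, got {records[0].i}")
    for prev, rec in zip(records, records[1:]):
        if rec.i != prev.i + 1:
            raise ValueError(f"IFS subset sizes must be contiguous; gap after i={prev.i}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(IFS_COLUMNS + ("Sn_4dp", "Sp_4dp", "Acc_4dp", "MCC_4dp"))
        for r in records:
            w.writerow(
                [r.i] + [repr(float(v)) for v in (r.sn, r.sp, r.acc, r.mcc)]
                + [f"{v:.4f}" for v in (r.sn, r.sp, r.acc, r.mcc)]
            )


def read_ifs_table(path: str | Path) -> list[tuple[int, float, float, float, float]]:
    """Read back the full-precision columns written by :func:`write_ifs_table`."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header[:5]) != IFS_COLUMNS:
            raise ValueError(f"{path}: unexpected IFS table header {header[:5]}")
        for row in reader:
            rows.append((int(row[0]),) + tuple(float(v) for v in row[1:5]))
    return rows


# ---------------------------------------------------------------------------
# GMT and BED IO
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, ``set_id TAB description TAB gene...``.

    Duplicate members within one line are collapsed.
    """
    sets: list[GeneSet] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            sets.append(GeneSet(fields[0], fields[1], frozenset(fields[2:])))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def read_probe_bed(path: str | Path) -> list[ProbeAnnotation]:
    """Read probe positions from BED3+1 (chrom, start, start+1, probe_id)."""
    probes: list[ProbeAnnotation] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith(("#", "track", "browser")):
                continue
            if len(row) < 4:
                raise ValueError(f"{path}: line {lineno}: need 4 BED columns")
            pid = row[3]
            if pid in seen:
                raise ValueError(f"{path}: duplicate probe id {pid!r}")
            seen.add(pid)
            probes.append(ProbeAnnotation(pid, row[0], int(row[1])))
    return probes


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED3+1 (chrom, start, end, gene_id)."""
    genes: list[GeneModel] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith(("#", "track", "browser")):
                continue
            if len(row) < 4:
                raise ValueError(f"{path}: line {lineno}: need 4 BED columns")
            genes.append(GeneModel(row[3], row[0], int(row[1]), int(row[2])))
    return genes


def write_probe_bed(probes: Sequence[ProbeAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for p in probes:
            fh.write(f"{p.chromosome}\t{p.position}\t{p.position + 1}\t{p.probe_id}\n")


def write_gene_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\n")
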