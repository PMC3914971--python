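"""End-to-end orchestration: simulate/load -> rank -> IFS -> map -> enrich.

One plain-text (YAML) config drives every stage; all intermediate artifacts
are written to the output directory and listed in a machine-readable
manifest.  Identical config and inputs give an identical manifest (the run
is deterministic end to end given the seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import classify, enrichment, genome_map, ifs, io, mrmr, simulate

log = logging.getLogger("cnasubtype")

DEFAULTS = {
    "alpha": mrmr.DEFAULT_ALPHA,
    "top_n": mrmr.DEFAULT_TOP_N,
    "max_n": None,  # default: min(1000, top_n)
    "extension": genome_map.DEFAULT_EXTENSION,
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run.

    Either ``matrix`` (+ optional ``labels``) points at an existing TSV
    cohort, or ``simulate`` holds a :class:`~cnasubtype.simulate.SyntheticSpec`
    field block and the cohort is generated.
    """

    out_dir: str = "results"
    matrix: str | None = None
    labels: str | None = None
    orientation: str = "samples"
    simulate: dict | None = None
    probe_bed: str | None = None
    gene_bed: str | None = None
    gmt: str | None = None
    universe: str | None = None
    alpha: float = DEFAULTS["alpha"]
    top_n: int = DEFAULTS["top_n"]
    max_n: int | None = DEFAULTS["max_n"]
    extension: int = DEFAULTS["extension"]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.matrix is None and self.simulate is None:
            raise ValueError("config needs either 'matrix' or a 'simulate' block")
        for key in ("matrix", "labels", "probe_bed", "gene_bed", "gmt", "universe"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config key {key!r}: no such file: {val}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "files": {}, "input_hashes": {}}

    def emit(key: str, path: Path) -> None:
        manifest["files"][key] = str(path)

    # ---- stage: input -----------------------------------------------------
    @_stage("input")
    def load() -> tuple[io.CNAMatrix, simulate.SyntheticTruth | None]:
        if config.matrix is not None:
            for key in ("matrix", "labels"):
                val = getattr(config, key)
                if val:
                    manifest["input_hashes"][key] = _sha256(Path(val))
            m = io.read_matrix(
                config.matrix, orientation=config.orientation, labels_path=config.labels
            )
            log.info("loaded %d samples x %d probes", m.n_samples, m.n_probes)
            return m, None
        spec_kwargs = dict(config.simulate or {})
        spec_kwargs.setdefault("seed", config.seed)
        if "informative" in spec_kwargs:
            spec_kwargs["informative"] = tuple(spec_kwargs["informative"])
        spec = simulate.SyntheticSpec(**spec_kwargs)
        m, truth = simulate.generate(spec)
        io.write_matrix(m, out / "matrix.tsv")
        emit("matrix", out / "matrix.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("parent\tpartners\n")
            for pid in truth.informative:
                fh.write(f"{pid}\t{','.join(truth.partners.get(pid, ()))}\n")
        emit("truth", out / "truth.tsv")
        log.info("simulated %d samples x %d probes (seed %d)",
                 m.n_samples, m.n_probes, spec.seed)
        return m, truth

    matrix, truth = load()

    # ---- stage: rank ------------------------------------------------------
    @_stage("rank")
    def rank() -> mrmr.RankedProbeList:
        d = mrmr.discretize(matrix, alpha=config.alpha)
        maxrel = mrmr.max_rel_rank(d, matrix, top_n=config.top_n)
        mrmr.write_ranking(maxrel, out / "maxrel.tsv")
        emit("maxrel", out / "maxrel.tsv")
        ranked = mrmr.mrmr_rank(d, matrix, top_n=config.top_n)
        mrmr.write_ranking(ranked, out / "mrmr.tsv")
        emit("mrmr", out / "mrmr.tsv")
        return ranked

    ranked = rank()

    # ---- stage: ifs -------------------------------------------------------
    @_stage("ifs")
    def run_ifs_stage() -> ifs.OptimalSubset:
        max_n = config.max_n or min(ifs.DEFAULT_MAX_N, len(ranked))
        table = ifs.run_ifs(matrix, ranked, max_n=max_n)
        io.write_ifs_table(table, out / "ifs_table.tsv")
        emit("ifs_table", out / "ifs_table.tsv")
        best = ifs.select_optimal(table, ranked)
        (out / "optimal_probes.txt").write_text(
            "\n".join(best.probe_ids) + "\n"
        )
        emit("optimal_probes", out / "optimal_probes.txt")
        ifs.export_heatmap_data(matrix, best, out / "heatmap_data.tsv")
        emit("heatmap_data", out / "heatmap_data.tsv")
        m = best.metrics.rounded()
        log.info(
            "optimum: %d probes, Sn=%.4f Sp=%.4f Acc=%.4f MCC=%.4f",
            best.size, m.sensitivity, m.specificity, m.accuracy, m.mcc,
        )
        manifest["optimum"] = {
            "size": best.size,
            "sensitivity": best.metrics.sensitivity,
            "specificity": best.metrics.specificity,
            "accuracy": best.metrics.accuracy,
            "mcc": best.metrics.mcc,
        }
        return best

    best = run_ifs_stage()

    # ---- stage: map -------------------------------------------------------
    gene_list: list[str] | None = None
    use_synthetic_annotation = truth is not None and config.probe_bed is None

    @_stage("map")
    def run_map() -> list[str]:
        if use_synthetic_annotation:
            probes, genes = simulate.generate_annotation(truth.spec)
        else:
            manifest["input_hashes"]["probe_bed"] = _sha256(Path(config.probe_bed))
            manifest["input_hashes"]["gene_bed"] = _sha256(Path(config.gene_bed))
            probes = io.read_probe_bed(config.probe_bed)
            genes = io.read_gene_bed(config.gene_bed)
        pmap = genome_map.map_probes_to_genes(probes, genes, extension=config.extension)
        genome_map.write_map(pmap, out / "probe_gene.tsv")
        emit("probe_gene", out / "probe_gene.tsv")
        gl = genome_map.genes_of_subset(best, pmap)
        (out / "gene_list.txt").write_text("\n".join(gl) + ("\n" if gl else ""))
        emit("gene_list", out / "gene_list.txt")
        log.info("optimal probes map to %d gene(s)", len(gl))
        return gl

    if use_synthetic_annotation or (config.probe_bed and config.gene_bed):
        gene_list = run_map()

    # ---- stage: enrich ----------------------------------------------------
    @_stage("enrich")
    def run_enrich() -> None:
        if config.gmt is not None:
            manifest["input_hashes"]["gmt"] = _sha256(Path(config.gmt))
            collections = io.read_gmt(config.gmt)
            if config.universe is not None:
                universe = [
                    ln.strip() for ln in Path(config.universe).read_text().splitlines()
                    if ln.strip()
                ]
            else:
                universe = None
        elif truth is not None:
            collections, universe = simulate.generate_genesets(truth, seed=config.seed)
        else:
            return
        results = enrichment.enrich(gene_list, collections, universe=universe)
        enrichment.write_enrichment(results, out / "enrichment.tsv")
        emit("enrichment", out / "enrichment.tsv")
        manifest["top_enrichment"] = [
            {"set_id": r.set_id, "p_value": r.p_value} for r in results[:5]
        ]

    if gene_list:
        run_enrich()

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("manifest written to %s", manifest_path)
    return manifest
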