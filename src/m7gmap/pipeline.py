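"""End-to-end runner: simulate -> preprocess -> align -> count -> test -> call.

Each stage reads and writes only documented formats (FASTA/FASTQ/SAM/TSV),
so stages are independently usable; the runner adds configuration
validation, per-stage statistics, conservation checks and a
machine-readable run report. Simulation-driven runs with the same seed are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import align as align_mod
from . import diffcleave, fragments, preprocess, simulate as sim_mod, sitecall
from .reference import ReferenceSet, collapse_isodecoders, load_trna_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of every stage, flat, with validated ranges."""

    reference_fasta: str = ""
    out_dir: str = "m7gmap_run"
    sample_sheet: str = ""  # empty => simulate
    seed: int = 0
    # simulation
    simulate: bool = True
    depth: int = sim_mod.DEFAULT_DEPTH
    replicates: int = 3
    cleavage_efficiency: float = 0.3
    background_cleavage_rate: float = 0.02
    dispersion: float = 0.05
    error_rate: float = 0.001
    read_length: int = sim_mod.DEFAULT_READ_LENGTH
    random_end_len: int = 4
    sim_methylated_ids: list | None = None
    # preprocessing
    adapter: str = sim_mod.DEFAULT_ADAPTER
    min_len: int = 23
    n_end: int = 4
    min_overlap: int = 3
    max_error_rate: float = 0.1
    filter_after_end_trim: bool = False
    # alignment
    max_mismatches: int = 2
    max_hits: int = 500
    allow_revcomp: bool = False
    seed_k: int = 12
    # counting
    min_total: float = 10.0
    pseudocount: float = 1.0
    full_length_threshold: float = 0.7
    # testing / site calling
    alpha: float = 0.05
    min_log2fc: float = 1.0
    starts_only: bool = False
    collapse: bool = True
    numbering_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        for name in ("cleavage_efficiency", "background_cleavage_rate",
                     "error_rate", "max_error_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("depth", "min_len", "read_length", "max_hits", "seed_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_end", "max_mismatches", "min_total", "pseudocount",
                     "random_end_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.full_length_threshold <= 1:
            raise ValueError("full_length_threshold must be in (0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_sample_sheet(path) -> tuple[list[fragments.SampleDesign], dict[str, Path]]:
    """Parse and validate the sample sheet TSV.

    Required columns: sample_id, fastq, condition, treated, replicate.
    Errors on missing columns, duplicate sample ids, or any empty
    (condition, treated) cell of the 2x2 design.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "fastq", "condition", "treated", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    design = []
    fastqs: dict[str, Path] = {}
    base = Path(path).parent
    for _, row in df.iterrows():
        treated = str(row["treated"]).strip().lower() in ("true", "1", "yes", "treated")
        d = fragments.SampleDesign(
            sample_id=row["sample_id"],
            condition=str(row["condition"]).strip(),
            treated=treated,
            replicate=int(row["replicate"]),
        )
        design.append(d)
        fq = Path(row["fastq"])
        fastqs[d.sample_id] = fq if fq.is_absolute() else base / fq
    fragments.check_design(design)
    return design, fastqs


def run_pipeline(config: PipelineConfig, refs: ReferenceSet | None = None) -> dict:
    """Execute all stages; returns the run report (also written as JSON).

    Conservation invariants re-checked here: preprocess read accounting,
    multi-map weight totals versus aligned reads, and SAM-to-matrix mass;
    any violation fails the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "conservation": {},
    }
    if refs is None:
        if not config.reference_fasta:
            raise ValueError("reference_fasta is required")
        refs = load_trna_fasta(
            config.reference_fasta,
            numbering_overrides=config.numbering_overrides or None,
            seed_k=config.seed_k,
        )
    if config.collapse:
        refs = collapse_isodecoders(refs)
    report["stages"]["reference"] = {"n_references": len(refs)}

    if config.sample_sheet:
        design, fastqs = validate_sample_sheet(config.sample_sheet)
    elif config.simulate:
        truth = sim_mod.uniform_truth(
            refs,
            methylated_ids=config.sim_methylated_ids,
            cleavage_efficiency=config.cleavage_efficiency,
            background_cleavage_rate=config.background_cleavage_rate,
            dispersion=config.dispersion,
            adapter=config.adapter,
            random_end_len=config.random_end_len,
            error_rate=config.error_rate,
            read_length=config.read_length,
            seed=config.seed,
        )
        specs = sim_mod.default_design(config.depth, config.replicates)
        manifest = sim_mod.simulate_experiment(refs, truth, specs, out / "sim")
        design, fastqs = validate_sample_sheet(manifest["sample_sheet"])
        report["stages"]["simulate"] = {
            "n_libraries": len(specs),
            "truth": str(manifest["truth"]),
        }
    else:
        raise ValueError("either sample_sheet or simulate is required")

    trimmed_dir = out / "trimmed"
    trimmed_dir.mkdir(exist_ok=True)
    pp_stats = {}
    for d in design:
        out_fq = trimmed_dir / f"{d.sample_id}.fastq"
        stats = preprocess.preprocess_fastq(
            fastqs[d.sample_id],
            out_fq,
            adapter=config.adapter,
            min_len=config.min_len,
            n_end=config.n_end,
            min_overlap=config.min_overlap,
            max_error_rate=config.max_error_rate,
            filter_after_end_trim=config.filter_after_end_trim,
        )
        if stats.written != stats.input_reads - stats.discarded_short:
            raise RuntimeError(f"preprocess conservation violated for {d.sample_id}")
        pp_stats[d.sample_id] = dataclasses.asdict(stats)
    report["stages"]["preprocess"] = pp_stats

    aligned_dir = out / "aligned"
    aligned_dir.mkdir(exist_ok=True)
    al_stats = {}
    per_sample_maps = {}
    for d in design:
        sam_path = aligned_dir / f"{d.sample_id}.sam"
        summary = align_mod.align_fastq(
            trimmed_dir / f"{d.sample_id}.fastq",
            refs,
            sam_path,
            max_mismatches=config.max_mismatches,
            max_hits=config.max_hits,
            allow_revcomp=config.allow_revcomp,
        )
        al_stats[d.sample_id] = dataclasses.asdict(summary)
        frag_map = fragments.hits_to_fragments(sam_path, refs)
        mass = sum(frag_map.values())
        if abs(mass - summary.aligned) > 1e-6 * max(1, summary.aligned):
            raise RuntimeError(
                f"mass conservation violated for {d.sample_id}: "
                f"{mass} fragment weight vs {summary.aligned} aligned reads"
            )
        report["conservation"][d.sample_id] = {
            "aligned_reads": summary.aligned,
            "fragment_mass": mass,
        }
        per_sample_maps[d.sample_id] = frag_map
    report["stages"]["align"] = al_stats

    matrix = fragments.build_count_matrix(per_sample_maps, design)
    annot = fragments.annotate_fragments(
        matrix, refs, full_length_threshold=config.full_length_threshold
    )
    fragments.write_count_matrix(matrix, out / "counts_raw.tsv")
    annot.to_csv(out / "fragment_annotation.tsv", sep="\t")
    filtered = fragments.filter_and_pseudocount(
        matrix, min_total=config.min_total, pseudocount=config.pseudocount
    )
    trfs = fragments.subset_trfs(
        filtered, refs, full_length_threshold=config.full_length_threshold
    )
    fragments.write_count_matrix(trfs, out / "counts_trf.tsv")
    report["stages"]["count"] = {
        "n_fragments": int(matrix.df.shape[0]),
        "n_after_filter": int(filtered.df.shape[0]),
        "n_trf_tested": int(trfs.df.shape[0]),
    }

    results = diffcleave.run_interaction_test(trfs)
    results.to_csv(out / "results.tsv", sep="\t", index_label="fragment")
    report["stages"]["test"] = {
        "n_tested": int(results["converged"].sum()),
        "n_not_converged": int((~results["converged"]).sum()),
    }

    mass_per_ref = pd.Series(0.0, index=refs.ids())
    for frag_map in per_sample_maps.values():
        for key, w in frag_map.items():
            mass_per_ref[key.ref_id] += w
    sites, summary_df = sitecall.call_sites(
        results,
        refs,
        alpha=config.alpha,
        min_log2fc=config.min_log2fc,
        starts_only=config.starts_only,
        fragment_mass=mass_per_ref,
    )
    sitecall.write_sites(sites, out / "sites.tsv")
    sitecall.write_sites_bed(sites, out / "sites.bed")
    summary_df.to_csv(out / "summary.tsv", sep="\t")
    n_meth = int((summary_df["verdict"] == "methylated").sum())
    report["stages"]["callsites"] = {
        "n_sites": len(sites),
        "n_methylated_refs": n_meth,
        "n_references": len(refs),
    }
    report["sites"] = [
        {"ref_id": s.ref_id, "position": s.position, "n_evidence": len(s.evidence),
         "min_padj": s.min_padj, "max_log2fc": s.max_log2fc}
        for s in sites
    ]
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
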