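"""Synthetic NaBH4/aniline small-RNA-seq libraries with ground truth.

Emulates the 12-library design {WT, KO} x {treated, untreated} x 3
replicates. The chemistry being modelled: NaBH4 reduces m7G to an
abasic-like site and aniline cleaves the backbone there, excising the
methylated guanosine — so a treated, methylated molecule yields a 5' piece
ending at position p-1 and a 3' piece starting at p+1 (1-based mature
coordinates). Only WT molecules carry the methyl mark; KO and untreated
libraries see background fragmentation only.

Libraries are NEXTFLEX-style: 4 random nucleotides ligated to both ends of
the insert, then the 3' adapter, read out to a fixed read length with
constant base quality and an optional uniform substitution error rate.

Read names encode provenance (reference, piece type, cleavage position) for
truth-based assertions in tests; downstream stages never parse read names.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .reference import ReferenceSet

# NEXTFLEX Small RNA-Seq v3 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_READ_LENGTH = 75
DEFAULT_DEPTH = 50_000

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReferenceTruth:
    """Ground-truth methylation state of one reference."""

    ref_id: str
    methylated: bool
    m7g_position: int | None  # 1-based; required when methylated
    relative_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.methylated and self.m7g_position is None:
            raise ValueError(f"{self.ref_id}: methylated but no m7G position")
        if self.relative_abundance <= 0:
            raise ValueError(f"{self.ref_id}: relative_abundance must be positive")


@dataclass
class SimulationTruth:
    """Generative parameters for one simulated experiment."""

    per_reference: dict[str, ReferenceTruth]
    cleavage_efficiency: float = 0.3
    background_cleavage_rate: float = 0.02
    dispersion: float = 0.05
    adapter: str = DEFAULT_ADAPTER
    random_end_len: int = 4
    error_rate: float = 0.001
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cleavage_efficiency", "background_cleavage_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.random_end_len < 0:
            raise ValueError("random_end_len must be >= 0")


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library of the condition x treatment x replicate design."""

    sample_id: str
    condition: str  # "WT" | "KO"
    treated: bool
    replicate: int
    depth: int = DEFAULT_DEPTH

    def __post_init__(self) -> None:
        if self.condition not in ("WT", "KO"):
            raise ValueError(f"condition must be WT or KO, got {self.condition!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def default_design(depth: int = DEFAULT_DEPTH, replicates: int = 3) -> list[LibrarySpec]:
    """The standard 12-library design: {WT, KO} x {treated, untreated} x reps."""
    specs = []
    for condition in ("WT", "KO"):
        for treated in (True, False):
            for rep in range(1, replicates + 1):
                tag = "T" if treated else "U"
                specs.append(
                    LibrarySpec(f"{condition}_{tag}_{rep}", condition, treated, rep, depth)
                )
    return specs


def uniform_truth(refs: ReferenceSet, methylated_ids: Sequence[str] | None = None,
                  **kwargs) -> SimulationTruth:
    """Truth with equal abundances; methylated refs use their annotated position.

    ``methylated_ids=None`` methylates every reference that carries a
    candidate m7G position annotation.
    """
    per_ref = {}
    for ref in refs:
        if methylated_ids is None:
            meth = ref.candidate_m7g_position is not None
        else:
            meth = ref.id in methylated_ids
        if meth and ref.candidate_m7g_position is None:
            raise ValueError(f"{ref.id}: requested methylated but no m7G position annotated")
        per_ref[ref.id] = ReferenceTruth(
            ref.id, meth, ref.candidate_m7g_position if meth else None
        )
    return SimulationTruth(per_reference=per_ref, **kwargs)


def _open_out(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _random_tails(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if length == 0:
        return [""] * n
    codes = _LETTERS[rng.integers(0, 4, size=(n, length))]
    return [codes[i].tobytes().decode("ascii") for i in range(n)]


def _apply_errors(rng: np.random.Generator, reads: list[str], rate: float) -> list[str]:
    if rate <= 0 or not reads:
        return reads
    lens = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    n_err = rng.binomial(lens, rate)
    for i in np.nonzero(n_err)[0]:
        s = bytearray(reads[i], "ascii")
        for pos in rng.integers(0, len(s), size=n_err[i]):
            s[pos] = _LETTERS[rng.integers(0, 4)]
        reads[i] = s.decode("ascii")
    return reads


def _simulate_library(
    refs: ReferenceSet,
    truth: SimulationTruth,
    spec: LibrarySpec,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Generate (name, sequence) pairs for one library.

    Per molecule: (1) reference drawn by relative abundance with
    NB-dispersed per-reference totals; (2) treated AND WT AND methylated
    molecules are cleaved at the m7G with probability cleavage_efficiency
    (the G is excised; 5' or 3' piece sequenced with equal odds);
    (3) otherwise a background break at a uniform internal phosphodiester
    with probability background_cleavage_rate (either side sequenced);
    (4) otherwise full length. Then 4-nt random ends, 3' adapter, truncation
    to read length, and uniform substitution errors.
    """
    states = [truth.per_reference[r.id] for r in refs]
    weights = np.array([s.relative_abundance for s in states], dtype=float)
    weights = weights / weights.sum()
    mu = spec.depth * weights
    if truth.dispersion > 0:
        r_nb = 1.0 / truth.dispersion
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    else:
        counts = rng.poisson(mu)

    # (ref_id, fragment sequence, piece type, cleavage position, multiplicity)
    fragments: list[tuple[str, str, str, int, int]] = []
    for ref, state, n_mol in zip(refs, states, counts):
        if n_mol == 0:
            continue
        seq = ref.sequence
        L = len(seq)
        n_m7g = 0
        if spec.treated and spec.condition == "WT" and state.methylated:
            n_m7g = rng.binomial(n_mol, truth.cleavage_efficiency)
        n_rest = n_mol - n_m7g
        n_bg = rng.binomial(n_rest, truth.background_cleavage_rate) if n_rest else 0
        n_full = n_rest - n_bg

        if n_m7g:
            p = state.m7g_position
            n5 = rng.binomial(n_m7g, 0.5)
            if n5:
                fragments.append((ref.id, seq[: p - 1], "m7g5p", p, n5))
            if n_m7g - n5:
                fragments.append((ref.id, seq[p:], "m7g3p", p, n_m7g - n5))
        if n_bg:
            # break between j and j+1 (1-based), j uniform on 1..L-1
            js = rng.integers(1, L, size=n_bg)
            sides = rng.integers(0, 2, size=n_bg)
            for j, side in zip(js, sides):
                if side == 0:
                    fragments.append((ref.id, seq[: int(j)], "bg5p", int(j), 1))
                else:
                    fragments.append((ref.id, seq[int(j) :], "bg3p", int(j), 1))
        if n_full:
            fragments.append((ref.id, seq, "full", 0, n_full))

    n_reads = sum(f[4] for f in fragments)
    tails5 = _random_tails(rng, n_reads, truth.random_end_len)
    tails3 = _random_tails(rng, n_reads, truth.random_end_len)
    reads: list[str] = []
    names: list[str] = []
    i = 0
    for ref_id, frag_seq, piece, cpos, n in fragments:
        for _ in range(n):
            full = tails5[i] + frag_seq + tails3[i] + truth.adapter
            reads.append(full[: truth.read_length])
            names.append(f"{spec.sample_id}.{i}|ref={ref_id}|piece={piece}|cpos={cpos}")
            i += 1
    reads = _apply_errors(rng, reads, truth.error_rate)
    return list(zip(names, reads))


def simulate_experiment(
    refs: ReferenceSet,
    truth: SimulationTruth,
    specs: Sequence[LibrarySpec],
    out_dir,
    gzip_fastq: bool = False,
) -> dict:
    """Write one FASTQ per library plus sample sheet and truth TSVs.

    Returns a manifest dict with ``sample_sheet``, ``truth`` and ``fastqs``
    paths. Deterministic: the same seed, references and specs produce
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = [r.id for r in refs if r.id not in truth.per_reference]
    if missing:
        raise ValueError(f"truth missing references: {missing}")
    for state in truth.per_reference.values():
        if state.methylated and state.ref_id in refs:
            ref = refs[state.ref_id]
            if ref.sequence[state.m7g_position - 1] != "G":
                raise ValueError(
                    f"{state.ref_id}: methylated position {state.m7g_position} is not G"
                )
    keys = [(s.condition, s.treated, s.replicate) for s in specs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (condition, treated, replicate) in library specs")

    child_seeds = np.random.SeedSequence(truth.seed).spawn(len(specs))
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    fastqs: dict[str, Path] = {}
    for spec, ss in zip(specs, child_seeds):
        rng = np.random.default_rng(ss)
        records = _simulate_library(refs, truth, spec, rng)
        path = out_dir / f"{spec.sample_id}{ext}"
        with _open_out(path) as fh:
            for name, seq in records:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
        fastqs[spec.sample_id] = path

    sheet = out_dir / "samples.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\tfastq\tcondition\ttreated\treplicate\n")
        for spec in specs:
            fh.write(
                f"{spec.sample_id}\t{fastqs[spec.sample_id].name}\t{spec.condition}"
                f"\t{str(spec.treated).lower()}\t{spec.replicate}\n"
            )

    truth_path = out_dir / "truth.tsv"
    write_truth(truth, truth_path)
    return {"sample_sheet": sheet, "truth": truth_path, "fastqs": fastqs}


_GLOBAL_FIELDS = (
    "cleavage_efficiency",
    "background_cleavage_rate",
    "dispersion",
    "adapter",
    "random_end_len",
    "error_rate",
    "read_length",
    "seed",
)
_TRUTH_COLUMNS = ("ref_id", "methylated", "m7g_position", "relative_abundance")


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        for name in _GLOBAL_FIELDS:
            fh.write(f"#{name}={getattr(truth, name)}\n")
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for state in truth.per_reference.values():
            pos = "" if state.m7g_position is None else str(state.m7g_position)
            fh.write(
                f"{state.ref_id}\t{str(state.methylated).lower()}\t{pos}"
                f"\t{state.relative_abundance}\n"
            )


def read_truth(path) -> SimulationTruth:
    """Round-trip loader for the truth TSV written by simulate_experiment."""
    globals_: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                globals_[key] = val
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in _TRUTH_COLUMNS:
                    if col not in header:
                        raise ValueError(f"truth file missing column {col!r}")
                continue
            rows.append(dict(zip(header, fields)))
    if header is None:
        raise ValueError(f"truth file {path} has no table")
    for name in _GLOBAL_FIELDS:
        if name not in globals_:
            raise ValueError(f"truth file missing parameter {name!r}")
    per_ref = {}
    for row in rows:
        pos = row["m7g_position"]
        per_ref[row["ref_id"]] = ReferenceTruth(
            ref_id=row["ref_id"],
            methylated=row["methylated"] == "true",
            m7g_position=int(pos) if pos else None,
            relative_abundance=float(row["relative_abundance"]),
        )
    return SimulationTruth(
        per_reference=per_ref,
        cleavage_efficiency=float(globals_["cleavage_efficiency"]),
        background_cleavage_rate=float(globals_["background_cleavage_rate"]),
        dispersion=float(globals_["dispersion"]),
        adapter=globals_["adapter"],
        random_end_len=int(globals_["random_end_len"]),
        error_rate=float(globals_["error_rate"]),
        read_length=int(globals_["read_length"]),
        seed=int(globals_["seed"]),
    )
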