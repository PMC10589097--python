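"""Mature tRNA reference handling.

Loads GtRNAdb-style mature tRNA FASTA files, validates sequences, collapses
identical-sequence genes into isodecoder representatives, and builds the
exact-match k-mer seed index used by the aligner.

Coordinates: all user-facing positions are 1-based on the mature sequence;
internal arithmetic is 0-based half-open. The canonical variable-loop m7G
position is 46; tRNAs whose long variable loop or intron shifts that
position take an explicit per-id override rather than structural
(Sprinzl) renumbering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

CANONICAL_M7G_POSITION = 46
DEFAULT_SEED_K = 12

_VALID_BASES = set("ACGT")
# e.g. "tRNA-Cys-GCA-1-1", ">Homo_sapiens_tRNA-Ala-AGC-2-2"
_ISOACCEPTOR_RE = re.compile(r"tRNA-([A-Za-z]{3}|iMet|SeC|Sup)-([A-Za-z]{3})", re.IGNORECASE)

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_BASE_TO_CODE[ord("N")] = 254  # mismatches everything


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 numpy array for Hamming scans."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class TRNAReference:
    """One mature tRNA (or collapsed isodecoder representative)."""

    id: str
    sequence: str
    isoacceptor: str = "unknown"
    member_gene_ids: tuple[str, ...] = ()
    candidate_m7g_position: int | None = None
    noncanonical_numbering: bool = False
    bed_provenance: dict | None = None  # genomic metadata only, never computed on

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.member_gene_ids:
            self.member_gene_ids = (self.id,)
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.id}: non-ACGTU characters {sorted(bad)}")
        if not 60 <= len(self.sequence) <= 120:
            raise ValueError(
                f"{self.id}: mature tRNA length {len(self.sequence)} outside [60, 120]"
            )
        p = self.candidate_m7g_position
        if p is not None:
            if not 1 <= p <= len(self.sequence):
                raise ValueError(f"{self.id}: m7G position {p} outside sequence")
            if self.sequence[p - 1] != "G":
                raise ValueError(
                    f"{self.id}: base at candidate m7G position {p} is "
                    f"{self.sequence[p - 1]}, not G"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def guanosine_positions(ref: TRNAReference) -> list[int]:
    """All 1-based positions of G in the mature sequence, ascending."""
    return [i + 1 for i, b in enumerate(ref.sequence) if b == "G"]


def _parse_isoacceptor(header: str) -> str:
    m = _ISOACCEPTOR_RE.search(header)
    if m is None:
        return "unknown"
    return f"{m.group(1)}-{m.group(2).upper()}"


class ReferenceSet:
    """Ordered, id-unique collection of references with a k-mer seed index.

    The index maps every length-k substring of every reference to its
    (reference index, offset) postings; the aligner combines it with
    brute-force verification for short reads so that no placement with at
    most ``max_mismatches`` differences is ever missed.
    """

    def __init__(self, references: Sequence[TRNAReference], seed_k: int = DEFAULT_SEED_K):
        ids = [r.id for r in references]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate reference ids: {sorted(dupes)}")
        self.references: list[TRNAReference] = list(references)
        self.seed_k = seed_k
        self._by_id = {r.id: r for r in self.references}
        self._encoded = [encode_sequence(r.sequence) for r in self.references]
        self._window_cache: dict[tuple[int, int], np.ndarray] = {}
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ridx, ref in enumerate(self.references):
            seq = ref.sequence
            for off in range(len(seq) - seed_k + 1):
                self.index.setdefault(seq[off : off + seed_k], []).append((ridx, off))

    def __len__(self) -> int:
        return len(self.references)

    def __iter__(self):
        return iter(self.references)

    def __getitem__(self, ref_id: str) -> TRNAReference:
        return self._by_id[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def ids(self) -> list[str]:
        return [r.id for r in self.references]

    def encoded(self, ridx: int) -> np.ndarray:
        return self._encoded[ridx]

    def windows(self, ridx: int, m: int) -> np.ndarray:
        """(n_offsets, m) sliding-window view of reference ``ridx``, cached."""
        key = (ridx, m)
        w = self._window_cache.get(key)
        if w is None:
            enc = self._encoded[ridx]
            if len(enc) < m:
                w = np.empty((0, m), dtype=np.uint8)
            else:
                w = np.lib.stride_tricks.sliding_window_view(enc, m)
            self._window_cache[key] = w
        return w


def load_trna_fasta(
    path,
    numbering_overrides: Mapping[str, int] | None = None,
    bed_path=None,
    seed_k: int = DEFAULT_SEED_K,
) -> ReferenceSet:
    """Load and validate mature tRNA references from FASTA.

    U is normalised to T; records with other non-ACGT characters are
    rejected with a warning. Every reference whose sequence has a G at the
    canonical position 46 gets ``candidate_m7g_position=46`` unless
    ``numbering_overrides`` maps its id to another (G) position, in which
    case the override wins and the reference is flagged as noncanonically
    numbered. An empty file or a duplicate id is a hard error.
    """
    overrides = dict(numbering_overrides or {})
    bed_meta = _read_bed6(bed_path) if bed_path is not None else {}
    references: list[TRNAReference] = []
    seen: set[str] = set()
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        rid = rec.id
        if rid in seen:
            raise ValueError(f"duplicate reference id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper().replace("U", "T")
        if set(seq) - _VALID_BASES:
            logger.warning("skipping %s: non-ACGTU characters in sequence", rid)
            continue
        isoacceptor = _parse_isoacceptor(rec.description)
        if isoacceptor == "unknown":
            logger.warning("could not parse isoacceptor from header of %s", rid)
        if rid in overrides:
            pos = overrides[rid]
            ref = TRNAReference(
                id=rid,
                sequence=seq,
                isoacceptor=isoacceptor,
                candidate_m7g_position=pos,
                noncanonical_numbering=True,
                bed_provenance=bed_meta.get(rid),
            )
        else:
            pos = (
                CANONICAL_M7G_POSITION
                if len(seq) >= CANONICAL_M7G_POSITION
                and seq[CANONICAL_M7G_POSITION - 1] == "G"
                else None
            )
            ref = TRNAReference(
                id=rid,
                sequence=seq,
                isoacceptor=isoacceptor,
                candidate_m7g_position=pos,
                bed_provenance=bed_meta.get(rid),
            )
        references.append(ref)
    if n_records == 0:
        raise ValueError(f"empty FASTA: {path}")
    return ReferenceSet(references, seed_k=seed_k)


def collapse_isodecoders(refs: ReferenceSet) -> ReferenceSet:
    """Merge genes with byte-identical mature sequences into one representative.

    The representative keeps the first gene's id and annotations and carries
    all member gene ids. Idempotent; the set of distinct sequences is
    preserved.
    """
    by_seq: dict[str, TRNAReference] = {}
    order: list[str] = []
    for ref in refs:
        rep = by_seq.get(ref.sequence)
        if rep is None:
            by_seq[ref.sequence] = replace(ref, member_gene_ids=tuple(ref.member_gene_ids))
            order.append(ref.sequence)
        else:
            by_seq[ref.sequence] = replace(
                rep, member_gene_ids=rep.member_gene_ids + ref.member_gene_ids
            )
    return ReferenceSet([by_seq[s] for s in order], seed_k=refs.seed_k)


def write_fasta(refs: Iterable[TRNAReference], path) -> None:
    """Write references back out; round-trips with load_trna_fasta."""
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.id} {ref.isoacceptor}\n")
            for i in range(0, len(ref.sequence), 70):
                fh.write(ref.sequence[i : i + 70] + "\n")


def _read_bed6(path) -> dict[str, dict]:
    """BED6 provenance: chrom/start/end/name/score/strand, keyed by name.

    Coordinates are carried as metadata only and never enter computation.
    """
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED6 line with {len(f)} fields: {line!r}")
            meta[f[3]] = {
                "chrom": f[0],
                "start": int(f[1]),
                "end": int(f[2]),
                "score": f[4],
                "strand": f[5],
            }
    return meta
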