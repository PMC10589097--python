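"""Ungapped end-to-end alignment of small-RNA reads to mature tRNAs.

Mirrors bowtie's ``-v``/``-m`` semantics: every end-to-end placement with at
most ``max_mismatches`` (default 2) is reported, and a read with more than
``max_hits`` (default 500) placements is suppressed entirely. Multi-mapping
reads get fractional weights 1/n_hits so total read mass is conserved.

Completeness contract: no placement with <= max_mismatches is ever missed.
Reads long enough to be split into three seed blocks of the index k-mer
size are searched by seed-and-verify (with 2 mismatches, at least one block
is mismatch-free by pigeonhole); shorter reads are verified brute-force
against every offset of every reference with a vectorised Hamming scan.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import ReferenceSet, encode_sequence

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MAX_HITS = 500

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ref_id: str
    start: int  # 0-based on the mature sequence
    end: int  # exclusive
    mismatches: int
    n_hits: int
    reverse: bool = False

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits


@dataclass
class AlignSummary:
    total: int = 0
    aligned: int = 0
    multi: int = 0
    suppressed: int = 0
    unaligned: int = 0


def _placements(
    seq: str, refs: ReferenceSet, max_mismatches: int
) -> list[tuple[int, int, int]]:
    """All (ref_index, start, mismatches) placements of ``seq``."""
    m = len(seq)
    if m == 0:
        return []
    enc = encode_sequence(seq)
    k = refs.seed_k
    out: list[tuple[int, int, int]] = []
    if m < 3 * k:
        # brute force: guaranteed complete for any mismatch budget
        for ridx in range(len(refs)):
            windows = refs.windows(ridx, m)
            if windows.shape[0] == 0:
                continue
            mism = (windows != enc).sum(axis=1)
            for start in np.nonzero(mism <= max_mismatches)[0]:
                out.append((ridx, int(start), int(mism[start])))
        return out
    # seed-and-verify: one k-mer per third of the read; with <= 2 mismatches
    # at least one queried k-mer is exact (pigeonhole over 3 blocks >= k)
    seen: set[tuple[int, int]] = set()
    for off in (0, m // 3, (2 * m) // 3):
        for ridx, roff in refs.index.get(seq[off : off + k], ()):
            start = roff - off
            if start < 0 or (ridx, start) in seen:
                continue
            ref_enc = refs.encoded(ridx)
            if start + m > len(ref_enc):
                continue
            seen.add((ridx, start))
            mism = int((ref_enc[start : start + m] != enc).sum())
            if mism <= max_mismatches:
                out.append((ridx, start, mism))
    return out


def align_read(
    read_id: str,
    sequence: str,
    refs: ReferenceSet,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_hits: int = DEFAULT_MAX_HITS,
    allow_revcomp: bool = False,
) -> list[AlignmentHit]:
    """All valid placements of one read, or [] if none / suppressed.

    Hits are sorted by (ref_id, start); every placement with at most
    ``max_mismatches`` counts toward the ``max_hits`` suppression threshold,
    matching bowtie's -v/-m accounting over all valid alignments.
    """
    seq = sequence.upper()
    placements = [(r, s, mm, False) for r, s, mm in _placements(seq, refs, max_mismatches)]
    if allow_revcomp:
        rc = seq.translate(_COMPLEMENT)[::-1]
        placements += [(r, s, mm, True) for r, s, mm in _placements(rc, refs, max_mismatches)]
    if not placements or len(placements) > max_hits:
        return []
    n = len(placements)
    m = len(seq)
    hits = [
        AlignmentHit(read_id, refs.references[ridx].id, start, start + m, mm, n, rev)
        for ridx, start, mm, rev in placements
    ]
    hits.sort(key=lambda h: (h.ref_id, h.start))
    return hits


def _open(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def align_fastq(
    in_path,
    refs: ReferenceSet,
    sam_path,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_hits: int = DEFAULT_MAX_HITS,
    allow_revcomp: bool = False,
    include_unmapped: bool = False,
) -> AlignSummary:
    """Stream a preprocessed FASTQ against the reference set into SAM.

    Output records carry NH (number of placements for the read) and NM
    (mismatches) tags. Identical read sequences share one placement lookup,
    which makes deeply sequenced small-RNA libraries cheap to align.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": r.id, "LN": len(r)} for r in refs],
        }
    )
    tid = {r.id: i for i, r in enumerate(refs.references)}
    summary = AlignSummary()
    cache: dict[str, tuple[list[AlignmentHit], str]] = {}
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam, _open(in_path) as fin:
        for title, seq, qual in FastqGeneralIterator(fin):
            summary.total += 1
            read_id = title.split()[0]
            seq = seq.upper()
            cached = cache.get(seq)
            if cached is None:
                hits = align_read(
                    "", seq, refs, max_mismatches, max_hits, allow_revcomp
                )
                if hits:
                    status = "aligned"
                elif seq and (
                    _placements(seq, refs, max_mismatches)
                    or (
                        allow_revcomp
                        and _placements(
                            seq.translate(_COMPLEMENT)[::-1], refs, max_mismatches
                        )
                    )
                ):
                    status = "suppressed"
                else:
                    status = "unaligned"
                cached = (hits, status)
                cache[seq] = cached
            hits, status = cached
            if not hits:
                if status == "suppressed":
                    summary.suppressed += 1
                else:
                    summary.unaligned += 1
                if include_unmapped:
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = read_id
                    rec.query_sequence = seq
                    rec.query_qualities = pysam.qualitystring_to_array(qual)
                    rec.flag = 4
                    sam.write(rec)
                continue
            summary.aligned += 1
            if len(hits) > 1:
                summary.multi += 1
            for hit in hits:
                rec = pysam.AlignedSegment(header)
                rec.query_name = read_id
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                rec.flag = 16 if hit.reverse else 0
                rec.reference_id = tid[hit.ref_id]
                rec.reference_start = hit.start
                rec.mapping_quality = 255
                rec.cigartuples = [(0, len(seq))]
                rec.set_tags([("NH", hit.n_hits), ("NM", hit.mismatches)])
                sam.write(rec)
    return summary
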