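"""Adapter trimming, fixed end removal and minimum-length filtering.

Order of operations for a NEXTFLEX-style library: 3' adapter trim, then the
minimum-length filter (default 23 nt, applied to the adapter-trimmed
length), then removal of a fixed number of bases (default 4) from both ends
— the random nucleotides the ligation protocol adds. The alternative order
(length filter after end trimming) is available via ``filter_after_end_trim``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import encode_sequence

DEFAULT_MIN_LEN = 23
DEFAULT_N_END = 4
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MAX_ERROR_RATE = 0.1


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.id}: quality/sequence length mismatch")


@dataclass
class PreprocessStats:
    input_reads: int = 0
    adapter_found: int = 0
    discarded_short: int = 0
    written: int = 0

    def check(self) -> None:
        assert self.written == self.input_reads - self.discarded_short


def _adapter_match_start(
    seq: str, adapter: str, min_overlap: int, max_error_rate: float
) -> int | None:
    """Leftmost start of a 3'-adapter match, or None.

    A match at position i aligns adapter[:overlap] with seq[i:i+overlap]
    where overlap = min(len(adapter), len(seq) - i); it counts if
    overlap >= min_overlap and mismatches/overlap <= max_error_rate.
    N counts as a mismatch everywhere.
    """
    n, a = len(seq), len(adapter)
    if n == 0:
        return None
    enc = encode_sequence(seq)
    aenc = encode_sequence(adapter)
    # positions where the whole adapter fits, vectorised
    if n >= a:
        windows = np.lib.stride_tricks.sliding_window_view(enc, a)
        mism = (windows != aenc).sum(axis=1)
        hits = np.nonzero(mism <= max_error_rate * a)[0]
        if hits.size:
            return int(hits[0])
    # 3'-end positions with a partial (>= min_overlap) adapter prefix
    for i in range(max(0, n - a + 1), n - min_overlap + 1):
        overlap = n - i
        mism = int((enc[i:] != aenc[:overlap]).sum())
        if mism <= max_error_rate * overlap:
            return i
    return None


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> ReadRecord:
    """Remove the leftmost 3'-adapter match and everything 3' of it."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    i = _adapter_match_start(read.sequence, adapter, min_overlap, max_error_rate)
    if i is None:
        return read
    return ReadRecord(read.id, read.sequence[:i], read.quality[:i])


def trim_fixed_ends(read: ReadRecord, n: int = DEFAULT_N_END) -> ReadRecord:
    """Remove n bases from each end; reads shorter than 2n become empty."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if len(read.sequence) < 2 * n:
        return ReadRecord(read.id, "", "")
    end = len(read.sequence) - n
    return ReadRecord(read.id, read.sequence[n:end], read.quality[n:end])


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def preprocess_fastq(
    in_path,
    out_path,
    adapter: str,
    min_len: int = DEFAULT_MIN_LEN,
    n_end: int = DEFAULT_N_END,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    filter_after_end_trim: bool = False,
) -> PreprocessStats:
    """Adapter-trim, length-filter and end-trim a FASTQ file.

    Default semantics: a read is discarded when its adapter-trimmed length
    is below ``min_len``; survivors lose ``n_end`` bases from each end.
    With ``filter_after_end_trim`` the length filter applies to the
    end-trimmed length instead.
    """
    stats = PreprocessStats()
    adapter = adapter.upper()
    with _open(in_path) as fin, _open(out_path, "wt") as fout:
        try:
            for title, seq, qual in FastqGeneralIterator(fin):
                stats.input_reads += 1
                seq = seq.upper()
                i = _adapter_match_start(seq, adapter, min_overlap, max_error_rate)
                if i is not None:
                    stats.adapter_found += 1
                    seq, qual = seq[:i], qual[:i]
                if not filter_after_end_trim and len(seq) < min_len:
                    stats.discarded_short += 1
                    continue
                if len(seq) < 2 * n_end:
                    seq, qual = "", ""
                else:
                    seq = seq[n_end : len(seq) - n_end]
                    qual = qual[n_end : len(qual) - n_end]
                if filter_after_end_trim and len(seq) < min_len:
                    stats.discarded_short += 1
                    continue
                stats.written += 1
                fout.write(f"@{title}\n{seq}\n+\n{qual}\n")
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record near record {stats.input_reads + 1} "
                f"in {in_path}: {exc}"
            ) from exc
    stats.check()
    return stats
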