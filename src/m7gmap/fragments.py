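"""Fragment species extraction, classification and the count matrix.

A fragment species is the exact (reference, start, end) interval a read
maps to; multi-mapping reads contribute fractional weight 1/NH to each
placement so read mass is conserved from SAM through the matrix. Rows are
filtered on their pre-pseudocount total over all samples (strict < 10 by
default) before a pseudocount of 1 is added to every remaining cell, and
only fragments shorter than 0.7 of the full tRNA length enter the
differential test.

Classification into 5' halves (anticodon-loop cleavage), short 5'
fragments (D-loop cleavage), 3' fragments and full-length-like species is
reporting-only and never gates the statistics. The default windows
(D loop 14-21, anticodon loop 32-38, 1-based inclusive) are
canonical-cloverleaf positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .reference import ReferenceSet, TRNAReference

DEFAULT_MIN_TOTAL = 10
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_FULL_LENGTH_THRESHOLD = 0.7
DEFAULT_D_LOOP_WINDOW = (14, 21)
DEFAULT_ANTICODON_WINDOW = (32, 38)

FCLASSES = (
    "five_prime_half",
    "five_prime_short",
    "three_prime_fragment",
    "internal",
    "full_length_like",
)


@dataclass(frozen=True, order=True)
class FragmentKey:
    ref_id: str
    start: int  # 0-based
    end: int  # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start

    def label(self) -> str:
        return f"{self.ref_id}:{self.start}-{self.end}"

    @classmethod
    def from_label(cls, label: str) -> "FragmentKey":
        ref_id, _, span = label.rpartition(":")
        start, _, end = span.partition("-")
        return cls(ref_id, int(start), int(end))


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    condition: str  # "WT" | "KO"
    treated: bool
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in ("WT", "KO"):
            raise ValueError(f"condition must be WT or KO, got {self.condition!r}")


def check_design(design: Iterable[SampleDesign]) -> None:
    """Every (condition, treated) cell of the 2x2 design must be populated."""
    design = list(design)
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design")
    cells = {(d.condition, d.treated) for d in design}
    missing = [
        c
        for c in [("WT", True), ("WT", False), ("KO", True), ("KO", False)]
        if c not in cells
    ]
    if missing:
        raise ValueError(f"design cells unpopulated: {missing}; interaction unidentifiable")


@dataclass
class CountMatrix:
    """Fragments x samples weighted counts with processing-state flags."""

    df: pd.DataFrame  # index: fragment labels; columns: sample_ids
    design: list[SampleDesign]
    pseudocount_applied: bool = False
    filtered: bool = False

    @property
    def fragments(self) -> list[FragmentKey]:
        return [FragmentKey.from_label(lbl) for lbl in self.df.index]

    def length_fractions(self, refs: ReferenceSet) -> pd.Series:
        vals = [k.length / len(refs[k.ref_id]) for k in self.fragments]
        return pd.Series(vals, index=self.df.index, name="length_fraction")


def hits_to_fragments(sam_path, refs: ReferenceSet) -> dict[FragmentKey, float]:
    """Accumulate per-placement weights 1/NH into (ref, start, end) species."""
    counts: dict[FragmentKey, float] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            ref_id = rec.reference_name
            start, end = rec.reference_start, rec.reference_end
            if ref_id not in refs or start < 0 or end > len(refs[ref_id]):
                raise ValueError(
                    f"alignment {rec.query_name} at {ref_id}:{start}-{end} "
                    "exceeds reference bounds"
                )
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            key = FragmentKey(ref_id, start, end)
            counts[key] = counts.get(key, 0.0) + 1.0 / nh
    return counts


def classify_fragment(
    key: FragmentKey,
    ref: TRNAReference,
    full_length_threshold: float = DEFAULT_FULL_LENGTH_THRESHOLD,
    d_loop_window: tuple[int, int] = DEFAULT_D_LOOP_WINDOW,
    anticodon_window: tuple[int, int] = DEFAULT_ANTICODON_WINDOW,
) -> str:
    """Assign one of the five fragment classes.

    Windows are 1-based inclusive mature positions tested against the
    fragment's last base (its 0-based exclusive end equals the 1-based
    position of that base).
    """
    if key.ref_id != ref.id:
        raise ValueError(f"fragment {key.label()} does not belong to {ref.id}")
    frac = key.length / len(ref)
    if frac >= full_length_threshold:
        return "full_length_like"
    if key.start == 0 and anticodon_window[0] <= key.end <= anticodon_window[1]:
        return "five_prime_half"
    if key.start == 0 and d_loop_window[0] <= key.end <= d_loop_window[1]:
        return "five_prime_short"
    if key.start > 0 and key.end == len(ref):
        return "three_prime_fragment"
    return "internal"


def annotate_fragments(
    matrix: CountMatrix,
    refs: ReferenceSet,
    full_length_threshold: float = DEFAULT_FULL_LENGTH_THRESHOLD,
    d_loop_window: tuple[int, int] = DEFAULT_D_LOOP_WINDOW,
    anticodon_window: tuple[int, int] = DEFAULT_ANTICODON_WINDOW,
) -> pd.DataFrame:
    """Per-row class and length fraction, aligned to the matrix index."""
    rows = []
    for key in matrix.fragments:
        ref = refs[key.ref_id]
        rows.append(
            {
                "fragment": key.label(),
                "fclass": classify_fragment(
                    key, ref, full_length_threshold, d_loop_window, anticodon_window
                ),
                "length_fraction": key.length / len(ref),
            }
        )
    return pd.DataFrame(rows).set_index("fragment")


def build_count_matrix(
    per_sample: Mapping[str, Mapping[FragmentKey, float]],
    design: Iterable[SampleDesign],
) -> CountMatrix:
    """Union fragment keys over samples into a dense matrix; missing -> 0."""
    design = list(design)
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design")
    missing = [s for s in ids if s not in per_sample]
    if missing:
        raise ValueError(f"no fragment map for samples: {missing}")
    keys = sorted({k for m in per_sample.values() for k in m})
    data = {
        sid: [per_sample[sid].get(k, 0.0) for k in keys] for sid in ids
    }
    df = pd.DataFrame(data, index=[k.label() for k in keys], columns=ids, dtype=float)
    return CountMatrix(df=df, design=design)


def filter_and_pseudocount(
    matrix: CountMatrix,
    min_total: float = DEFAULT_MIN_TOTAL,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CountMatrix:
    """Drop rows with all-sample total < min_total, then add the pseudocount.

    The filter sees pre-pseudocount (fractional) totals with a strict <.
    Calling this twice is a hard error.
    """
    if matrix.pseudocount_applied:
        raise ValueError("pseudocount already applied to this matrix")
    totals = matrix.df.sum(axis=1)
    kept = matrix.df.loc[totals >= min_total].copy()
    kept += pseudocount
    return CountMatrix(
        df=kept, design=matrix.design, pseudocount_applied=True, filtered=True
    )


def subset_trfs(
    matrix: CountMatrix,
    refs: ReferenceSet,
    full_length_threshold: float = DEFAULT_FULL_LENGTH_THRESHOLD,
) -> CountMatrix:
    """Keep only tRF rows: fragments shorter than the full-length threshold."""
    frac = matrix.length_fractions(refs)
    kept = matrix.df.loc[frac < full_length_threshold]
    if kept.empty:
        import logging

        logging.getLogger(__name__).warning(
            "no fragments below length fraction %.2f", full_length_threshold
        )
    return replace(matrix, df=kept.copy())


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="fragment")


def read_count_matrix(path, design: Iterable[SampleDesign]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="fragment")
    design = list(design)
    df = df[[d.sample_id for d in design]]
    return CountMatrix(df=df, design=design)
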