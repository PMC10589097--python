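"""m7G site calling from WT-specific treatment-induced fragments.

The NaBH4/aniline chemistry excises the methylated guanosine, so a
significant fragment that starts at mature position p+1 (start-anchored
evidence, the 3' piece) or ends at position p-1 (end-anchored evidence,
the 5' piece) both point at a methylated G at position p. Candidates are
only accepted when the reference base at p is G; near-miss positions
(+/- 1 that are G when p is not) are reported in a diagnostics column but
never called, which guards against boundary-convention drift.

A reference is called methylated when at least one aggregated candidate
position is supported by fragments passing both the BH-adjusted
significance cut and the WT-specific (positive) fold-change cut; a
reference with no aligned fragment mass at all is "no_data".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentKey
from .reference import ReferenceSet, TRNAReference

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_LOG2FC = 1.0


@dataclass
class SiteCall:
    ref_id: str
    position: int  # 1-based mature coordinate of the inferred methylated G
    evidence: list[tuple[str, str]]  # (fragment label, "start-anchored"|"end-anchored")
    min_padj: float
    max_log2fc: float
    near_miss: str = ""  # diagnostics: adjacent G positions for rejected candidates


def fragment_boundary_to_site(
    frag: FragmentKey, ref: TRNAReference
) -> list[tuple[int, str]]:
    """Candidate methylated positions implied by a fragment's boundaries.

    Start-anchored: the base immediately 5' of the fragment start (1-based
    position == 0-based start). End-anchored: the base immediately 3' of
    the fragment end (1-based position == 0-based exclusive end + 1).
    A candidate is returned only when that base is G.
    """
    candidates: list[tuple[int, str]] = []
    if frag.start > 0:
        pos = frag.start  # 1-based position of the base 5' of the fragment
        if ref.sequence[pos - 1] == "G":
            candidates.append((pos, "start-anchored"))
    if frag.end < len(ref):
        pos = frag.end + 1  # base immediately 3' of the fragment's last base
        if ref.sequence[pos - 1] == "G":
            candidates.append((pos, "end-anchored"))
    return candidates


def _near_misses(frag: FragmentKey, ref: TRNAReference) -> list[int]:
    """G positions adjacent to rejected boundary candidates (diagnostics)."""
    out = []
    for anchor_pos in (frag.start, frag.end + 1):
        if not 1 <= anchor_pos <= len(ref) or ref.sequence[anchor_pos - 1] == "G":
            continue
        for q in (anchor_pos - 1, anchor_pos + 1):
            if 1 <= q <= len(ref) and ref.sequence[q - 1] == "G":
                out.append(q)
    return sorted(set(out))


def call_sites(
    results: pd.DataFrame,
    refs: ReferenceSet,
    alpha: float = DEFAULT_ALPHA,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    starts_only: bool = False,
    fragment_mass: pd.Series | None = None,
) -> tuple[list[SiteCall], pd.DataFrame]:
    """Aggregate significant WT-specific fragments into site calls.

    ``results`` is the per-fragment table from the interaction test
    (indexed by fragment label). A fragment supports a candidate when
    p_adjusted <= alpha and log2fc_interaction >= min_log2fc (the sign gate
    excludes KO-enriched fragments). With ``starts_only`` end-anchored
    evidence is ignored. ``fragment_mass`` (per-reference aligned weight)
    distinguishes not_methylated from no_data in the summary.

    Returns the site calls and a per-reference summary table (the
    per-isoacceptor methylated/non-methylated overview) with one verdict
    per reference: methylated | not_methylated | no_data.
    """
    per_site: dict[tuple[str, int], SiteCall] = {}
    refs_with_fragments: set[str] = set()
    for label, row in results.iterrows():
        frag = FragmentKey.from_label(label)
        refs_with_fragments.add(frag.ref_id)
        if not np.isfinite(row["p_adjusted"]):
            continue
        if row["p_adjusted"] > alpha or row["log2fc_interaction"] < min_log2fc:
            continue
        ref = refs[frag.ref_id]
        candidates = fragment_boundary_to_site(frag, ref)
        if starts_only:
            candidates = [c for c in candidates if c[1] == "start-anchored"]
        misses = _near_misses(frag, ref)
        for pos, anchor in candidates:
            site = per_site.get((frag.ref_id, pos))
            if site is None:
                site = SiteCall(frag.ref_id, pos, [], np.inf, -np.inf)
                per_site[(frag.ref_id, pos)] = site
            site.evidence.append((label, anchor))
            site.min_padj = min(site.min_padj, float(row["p_adjusted"]))
            site.max_log2fc = max(site.max_log2fc, float(row["log2fc_interaction"]))
            if misses:
                site.near_miss = ",".join(str(q) for q in misses)
    sites = sorted(per_site.values(), key=lambda s: (s.ref_id, s.position))

    if fragment_mass is not None:
        refs_with_fragments |= set(fragment_mass.index[fragment_mass > 0])
    summary_rows = []
    called = {}
    for s in sites:
        best = called.get(s.ref_id)
        if best is None or s.min_padj < best.min_padj:
            called[s.ref_id] = s
    for ref in refs:
        if ref.id in called:
            verdict, pos = "methylated", called[ref.id].position
        elif ref.id in refs_with_fragments:
            verdict, pos = "not_methylated", None
        else:
            verdict, pos = "no_data", None
        summary_rows.append(
            {
                "ref_id": ref.id,
                "isoacceptor": ref.isoacceptor,
                "verdict": verdict,
                "position": pos,
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("ref_id")
    return sites, summary


def write_sites(sites: list[SiteCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\tposition\tn_evidence\tmin_padj\tmax_log2fc\tnear_miss\n")
        for s in sites:
            fh.write(
                f"{s.ref_id}\t{s.position}\t{len(s.evidence)}\t{s.min_padj:.6g}"
                f"\t{s.max_log2fc:.4f}\t{s.near_miss}\n"
            )


def write_sites_bed(sites: list[SiteCall], path) -> None:
    """BED6 of called sites in mature-tRNA coordinates: [pos-1, pos)."""
    with open(path, "w") as fh:
        for s in sites:
            score = min(1000, int(-10 * np.log10(max(s.min_padj, 1e-100))))
            fh.write(
                f"{s.ref_id}\t{s.position - 1}\t{s.position}\tm7G\t{score}\t+\n"
            )
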