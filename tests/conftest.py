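"""Shared fixtures: synthetic tRNA references and small simulated runs.

All sequences here are synthetic stand-ins generated programmatically from
fixed seeds; they mimic mature tRNA lengths and the canonical variable-loop
guanosine at position 46 but are not real gene sequences.
"""

from __future__ import annotations

import numpy as np
import pytest

from m7gmap.reference import ReferenceSet, TRNAReference

AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]


def synth_trna_seq(seed: int, length: int = 76, g_at: int | None = 46) -> str:
    """Random tRNA-length sequence with an optional guaranteed G."""
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    if g_at is not None:
        seq = seq[: g_at - 1] + "G" + seq[g_at:]
    return seq


def make_panel(
    n: int = 20,
    n_methylated: int | None = None,
    length: int = 76,
    seed: int = 100,
) -> tuple[ReferenceSet, list[str]]:
    """A panel of synthetic isoacceptors; the first half carry m7G46.

    Returns the reference set and the ids of the methylated references.
    Non-methylated references get no candidate position (no G forced at
    46; if one lands there by chance the annotation is still omitted).
    """
    if n_methylated is None:
        n_methylated = n // 2
    refs, meth_ids = [], []
    for i in range(n):
        methylated = i < n_methylated
        aa = AMINO_ACIDS[i % len(AMINO_ACIDS)]
        anticodon = "".join("ACGT"[j] for j in np.random.default_rng(seed + 1000 + i).integers(0, 4, 3))
        rid = f"tRNA-{aa}-{anticodon}-syn{i + 1}"
        seq = synth_trna_seq(seed + i, length, g_at=46 if methylated else None)
        refs.append(
            TRNAReference(
                id=rid,
                sequence=seq,
                isoacceptor=f"{aa}-{anticodon}",
                candidate_m7g_position=46 if methylated else None,
            )
        )
        if methylated:
            meth_ids.append(rid)
    return ReferenceSet(refs), meth_ids


@pytest.fixture
def canonical_ref() -> TRNAReference:
    """One 76-nt reference with the variable-loop G at canonical position 46."""
    return TRNAReference(
        id="tRNA-Cys-GCA-syn1",
        sequence=synth_trna_seq(1),
        isoacceptor="Cys-GCA",
        candidate_m7g_position=46,
    )


@pytest.fixture
def canonical_refs(canonical_ref) -> ReferenceSet:
    return ReferenceSet([canonical_ref])
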