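"""Reference-anchored numbering, clade-diagnostic features and the A/B/C classifier.

Clade calls are transparent unweighted rule scores:

* Clade A: signature residue K, long C-terminal extension (> 100 aa),
  positively charged tail (K+R fraction >= 0.15).
* Clade B: signature residue N, short C-terminal region (< 50 aa).
* Clade C: signature residue other than K/N, short C-terminal region.

A gap (or missing) signature residue contributes to no clade.  The winning
clade must beat the runner-up by at least ``min_margin``, otherwise the call
is ``unclassified``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .alignment import GAP, Alignment
from .errors import ValidationError
from .sequences import AMINO_ACIDS, DomainSegmentation, ProteinRecord

MAX_ENTROPY_BITS = math.log2(20)
POSITIVE = set("KR")
NEGATIVE = set("DE")


@dataclass(frozen=True)
class ReferenceAnchor:
    """Mapping from 1-based reference residue positions to alignment columns."""

    reference_id: str
    anchored_positions: Tuple[int, ...]
    column_of_position: Dict[int, int]


@dataclass(frozen=True)
class CladeFeatureVector:
    id: str
    linker_length: int
    cterm_length: int
    signature_residue: str  # single letter, '-' for gap/missing
    cterm_positive_fraction: float
    cterm_net_charge: int


@dataclass(frozen=True)
class ClassifierRules:
    signature_position: int = 285
    clade_a_residue: str = "K"
    clade_b_residue: str = "N"
    linker_long_boundary: int = 200  # long iff strictly greater
    cterm_long_min: int = 100  # long-tail criterion iff strictly greater
    cterm_short_max: int = 50  # short-tail criterion iff strictly smaller
    positive_fraction_min: float = 0.15
    min_margin: int = 1

    def __post_init__(self) -> None:
        if not self.cterm_short_max < self.cterm_long_min:
            raise ValidationError("cterm_short_max must be < cterm_long_min")
        if min(self.linker_long_boundary, self.cterm_long_min, self.cterm_short_max) <= 0:
            raise ValidationError("length boundaries must be positive")


@dataclass(frozen=True)
class CladeCall:
    id: str
    call: str  # one of A, B, C, unclassified
    scores: Dict[str, int]
    evidence: Tuple[str, ...]


@dataclass(frozen=True)
class EntropyProfile:
    entropy_bits: np.ndarray
    information_bits: np.ndarray
    gap_fraction: np.ndarray
    frequencies: np.ndarray  # (columns, 20) over AMINO_ACIDS order
    all_gap: np.ndarray  # boolean per column


def linker_class(linker_length: int, rules: ClassifierRules = ClassifierRules()) -> str:
    """Binarize linker length: 'long' iff strictly greater than the boundary."""
    return "long" if linker_length > rules.linker_long_boundary else "short"


def anchor_positions(
    aln: Alignment, reference_id: str, positions: Sequence[int] = (285,)
) -> ReferenceAnchor:
    """Map reference residue positions to alignment columns (both 1-based).

    Columns are located by counting non-gap characters along the reference row.
    """
    row = aln.row(reference_id)
    ungapped_len = len(row) - row.count(GAP)
    mapping: Dict[int, int] = {}
    wanted = set(positions)
    for pos in wanted:
        if not 1 <= pos <= ungapped_len:
            raise ValidationError(
                f"anchored position {pos} exceeds reference length {ungapped_len}"
            )
    residue_no = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            residue_no += 1
            if residue_no in wanted:
                mapping[residue_no] = col
    return ReferenceAnchor(reference_id, tuple(positions), mapping)


def extract_features(
    record: ProteinRecord,
    seg: DomainSegmentation,
    anchor: ReferenceAnchor,
    aln: Alignment,
    signature_position: Optional[int] = None,
) -> CladeFeatureVector:
    """Assemble the diagnostic feature vector for one aligned record."""
    row = aln.row(record.id)
    if signature_position is None:
        signature_position = anchor.anchored_positions[0]
    try:
        col = anchor.column_of_position[signature_position]
    except KeyError:
        raise ValidationError(
            f"position {signature_position} not anchored (have "
            f"{sorted(anchor.column_of_position)})"
        ) from None
    signature = row[col - 1]
    if seg.cterm_span is not None:
        lo, hi = seg.cterm_span
        tail = record.sequence[lo - 1 : hi]
    else:
        tail = ""
    positives = sum(1 for c in tail if c in POSITIVE)
    negatives = sum(1 for c in tail if c in NEGATIVE)
    fraction = positives / len(tail) if tail else 0.0
    return CladeFeatureVector(
        id=record.id,
        linker_length=seg.linker_length,
        cterm_length=seg.cterm_length,
        signature_residue=signature,
        cterm_positive_fraction=fraction,
        cterm_net_charge=positives - negatives,
    )


def classify_clade(
    features: CladeFeatureVector, rules: ClassifierRules = ClassifierRules()
) -> CladeCall:
    """Score the three clade archetypes and call the winner (margin-gated)."""
    sig = features.signature_residue
    ct = features.cterm_length
    evidence: List[str] = []
    scores = {"A": 0, "B": 0, "C": 0}

    if sig == rules.clade_a_residue:
        scores["A"] += 1
        evidence.append(f"signature_{rules.clade_a_residue}")
    if ct > rules.cterm_long_min:
        scores["A"] += 1
        evidence.append("long_cterm")
    if features.cterm_positive_fraction >= rules.positive_fraction_min:
        scores["A"] += 1
        evidence.append("positive_cterm")

    if sig == rules.clade_b_residue:
        scores["B"] += 1
        evidence.append(f"signature_{rules.clade_b_residue}")
    if ct < rules.cterm_short_max:
        scores["B"] += 1
        scores["C"] += 1
        evidence.append("short_cterm")

    if sig not in {rules.clade_a_residue, rules.clade_b_residue, GAP, ""}:
        scores["C"] += 1
        evidence.append("signature_other")

    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    (top_clade, top), (_, second) = ranked[0], ranked[1]
    call = top_clade if top - second >= rules.min_margin and top > 0 else "unclassified"
    return CladeCall(features.id, call, scores, tuple(evidence))


# -- conservation -----------------------------------------------------------


def column_entropy(aln: Alignment) -> EntropyProfile:
    """Per-column Shannon entropy (base 2) over non-gap residues.

    Gaps (and unknown 'X' residues) are excluded from the frequency
    distribution; the gap fraction is tracked separately.  All-gap columns are
    flagged.
    """
    cols = aln.column_count
    counts = np.zeros((cols, len(AMINO_ACIDS)))
    gap_counts = np.zeros(cols)
    aa_index = {c: i for i, c in enumerate(AMINO_ACIDS)}
    for row in aln.rows:
        for pos, ch in enumerate(row):
            if ch == GAP:
                gap_counts[pos] += 1
            elif ch in aa_index:
                counts[pos, aa_index[ch]] += 1
    totals = counts.sum(axis=1)
    all_gap = totals == 0
    safe_totals = np.where(all_gap, 1.0, totals)
    freqs = counts / safe_totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logs).sum(axis=1)
    entropy = np.where(all_gap, 0.0, entropy)
    return EntropyProfile(
        entropy_bits=entropy,
        information_bits=MAX_ENTROPY_BITS - entropy,
        gap_fraction=gap_counts / aln.n_rows,
        frequencies=freqs,
        all_gap=all_gap,
    )


def logo_matrix(
    aln: Alignment, clade_members: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Information-content logo heights: frequency x information bits.

    Returns a (columns x 20) data frame, indexed by 1-based column, with
    all-gap columns dropped.  When ``clade_members`` is given the alignment is
    restricted to those rows first.
    """
    if clade_members is not None:
        members = [rid for rid in aln.row_ids if rid in set(clade_members)]
        if not members:
            raise ValidationError("clade member set matches no alignment rows")
        aln = aln.subset(members)
    profile = column_entropy(aln)
    heights = profile.frequencies * profile.information_bits[:, None]
    df = pd.DataFrame(
        heights, columns=list(AMINO_ACIDS), index=np.arange(1, aln.column_count + 1)
    )
    df.index.name = "column"
    return df[~profile.all_gap]


def entropy_table(aln: Alignment) -> pd.DataFrame:
    profile = column_entropy(aln)
    return pd.DataFrame(
        {
            "column": np.arange(1, aln.column_count + 1),
            "entropy_bits": profile.entropy_bits,
            "information_bits": profile.information_bits,
            "gap_fraction": profile.gap_fraction,
            "all_gap": profile.all_gap,
        }
    )


def feature_table(
    features: Sequence[CladeFeatureVector],
    calls: Sequence[CladeCall],
    rules: ClassifierRules = ClassifierRules(),
) -> pd.DataFrame:
    rows = []
    for fv, call in zip(features, calls):
        rows.append(
            {
                "id": fv.id,
                "linker_length": fv.linker_length,
                "linker_class": linker_class(fv.linker_length, rules),
                "cterm_length": fv.cterm_length,
                "signature_residue": fv.signature_residue,
                "cterm_positive_fraction": round(fv.cterm_positive_fraction, 6),
                "cterm_net_charge": fv.cterm_net_charge,
                "call": call.call,
                "score_A": call.scores["A"],
                "score_B": call.scores["B"],
                "score_C": call.scores["C"],
                "evidence": ";".join(call.evidence),
            }
        )
    return pd.DataFrame(rows)
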