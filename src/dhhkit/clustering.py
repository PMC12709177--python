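"""Greedy incremental identity clustering (CD-HIT-style redundancy reduction).

Identity between two sequences is the number of identical aligned residue
pairs in the optimal global alignment divided by the length of the shorter
sequence (CD-HIT's denominator convention).  Records are processed longest
first and each joins the first existing cluster whose representative is at
least ``identity_threshold`` identical (inclusive comparison, matching
CD-HIT's ``-c`` cutoff); otherwise it founds a new cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import pandas as pd

from .alignment import AlignmentParams, global_align
from .errors import ValidationError
from .sequences import ProteinRecord

#: Identity thresholds used for the two source-database profiles.
PROFILE_THRESHOLDS = {"prokaryote": 0.70, "eukaryote": 0.90}


@dataclass(frozen=True)
class ClusteringConfig:
    identity_threshold: float = 0.70
    word_length: int = 3
    use_prefilter: bool = False
    alignment_params: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValidationError("identity_threshold must be in (0, 1]")
        if self.word_length < 1:
            raise ValidationError("word_length must be >= 1")

    @classmethod
    def for_profile(cls, profile: str) -> "ClusteringConfig":
        try:
            return cls(identity_threshold=PROFILE_THRESHOLDS[profile])
        except KeyError:
            raise ValidationError(
                f"unknown clustering profile {profile!r}; "
                f"choose from {sorted(PROFILE_THRESHOLDS)}"
            ) from None


@dataclass
class Cluster:
    representative_id: str
    member_ids: List[str]
    identities: List[float]


def pairwise_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    params: AlignmentParams = AlignmentParams(),
) -> float:
    """Fraction of identical aligned pairs over the shorter sequence length."""
    if not a.sequence or not b.sequence:
        raise ValidationError("pairwise identity requires non-empty sequences")
    aln = global_align(a.sequence, b.sequence, params)
    matches = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-"
    )
    return matches / min(len(a.sequence), len(b.sequence))


def _kmer_counter(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def _prefilter_rejects(
    short_len: int, ca: Counter, cb: Counter, k: int, threshold: float
) -> bool:
    """Conservative shared-k-mer bound: skip alignment only when identity
    provably falls below the threshold.

    If identity >= c then at least ceil(c * short_len) residues of the shorter
    sequence match, and each non-matching column can destroy at most k of its
    k-mers, so the sequences must share at least
    (short_len - k + 1) - k * floor((1 - c) * short_len) k-mers.
    """
    needed = (short_len - k + 1) - k * int((1 - threshold) * short_len)
    if needed <= 0:
        return False
    shared = sum((ca & cb).values())
    return shared < needed


def greedy_cluster(
    records: Sequence[ProteinRecord], config: ClusteringConfig = ClusteringConfig()
) -> List[Cluster]:
    """Greedy incremental clustering; clusters are returned in founding order."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate record ids")
    if not records:
        raise ValidationError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: List[Cluster] = []
    reps: List[ProteinRecord] = []
    kmers = {}
    if config.use_prefilter:
        kmers = {r.id: _kmer_counter(r.sequence, config.word_length) for r in ordered}
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if config.use_prefilter and _prefilter_rejects(
                min(len(rec.sequence), len(rep.sequence)),
                kmers[rec.id],
                kmers[rep.id],
                config.word_length,
                config.identity_threshold,
            ):
                continue
            identity = pairwise_identity(rec, rep, config.alignment_params)
            if identity >= config.identity_threshold:
                cluster.member_ids.append(rec.id)
                cluster.identities.append(identity)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [rec.id], [1.0]))
            reps.append(rec)
    return clusters


def representatives(
    records: Sequence[ProteinRecord], clusters: Sequence[Cluster]
) -> List[ProteinRecord]:
    """Representative records in cluster founding order."""
    by_id = {r.id: r for r in records}
    return [by_id[c.representative_id] for c in clusters]


def cluster_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster_index": idx,
            "representative_id": c.representative_id,
            "member_id": member,
            "identity": round(identity, 6),
        }
        for idx, c in enumerate(clusters)
        for member, identity in zip(c.member_ids, c.identities)
    ]
    return pd.DataFrame(rows)
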