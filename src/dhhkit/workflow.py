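"""End-to-end pipeline composition: scan -> cluster -> align -> filter -> tree
-> clades -> features -> classify.

Convenience glue used by the CLI, the test suite and the acceptance script;
each step is an ordinary public function from the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

from .alignment import Alignment, AlignmentParams, filter_gap_columns, progressive_msa
from .clustering import Cluster, ClusteringConfig, greedy_cluster, representatives
from .errors import ValidationError
from .features import (
    CladeCall,
    CladeFeatureVector,
    ClassifierRules,
    anchor_positions,
    classify_clade,
    extract_features,
)
from .phylogeny import (
    PhyloConfig,
    distance_matrix,
    extract_major_clades,
    midpoint_root,
    neighbor_joining,
)
from .sequences import (
    ProteinRecord,
    SegmentationOffsets,
    is_standalone_dhh_dhha1,
    scan_motifs,
    segment_domains,
)
from .tree import PhyloTree


@dataclass
class PipelineResult:
    kept_records: List[ProteinRecord]
    clusters: List[Cluster]
    representatives: List[ProteinRecord]
    alignment: Alignment
    filtered_alignment: Alignment
    tree: PhyloTree
    rooted_tree: PhyloTree
    clades: List[Set[str]]
    features: List[CladeFeatureVector]
    calls: List[CladeCall]

    @property
    def calls_by_id(self) -> Dict[str, str]:
        return {c.id: c.call for c in self.calls}


def run_pipeline(
    records: Sequence[ProteinRecord],
    *,
    offsets: SegmentationOffsets = SegmentationOffsets(),
    clustering: ClusteringConfig = ClusteringConfig(),
    alignment_params: AlignmentParams = AlignmentParams(),
    phylo: PhyloConfig = PhyloConfig(bootstrap_replicates=0),
    reference_id: Optional[str] = None,
    signature_position: int = 285,
    rules: Optional[ClassifierRules] = None,
) -> PipelineResult:
    """Run the full analysis pipeline on raw protein records."""
    if rules is None:
        rules = ClassifierRules(signature_position=signature_position)
    kept: List[ProteinRecord] = []
    segs = {}
    for rec in records:
        hits = scan_motifs(rec)
        if is_standalone_dhh_dhha1(rec, hits, offsets).standalone:
            kept.append(rec)
            segs[rec.id] = segment_domains(rec, hits, offsets)
    if len(kept) < 3:
        raise ValidationError(
            f"only {len(kept)} standalone DHH-DHHA1 records; need >= 3"
        )
    clusters = greedy_cluster(kept, clustering)
    reps = representatives(kept, clusters)
    aln = progressive_msa(reps, alignment_params)
    filtered = filter_gap_columns(aln, alignment_params)
    D = distance_matrix(filtered, phylo.distance_model, phylo.max_distance)
    tree = neighbor_joining(D)
    rooted = midpoint_root(tree)
    clades = extract_major_clades(rooted, phylo)
    if reference_id is None:
        reference_id = reps[0].id
    # anchor on the unfiltered alignment: the gap filter may drop columns that
    # hold rare reference residues, which would shift reference numbering
    anchor = anchor_positions(aln, reference_id, (signature_position,))
    features = [
        extract_features(rep, segs[rep.id], anchor, aln, signature_position)
        for rep in reps
    ]
    calls = [classify_clade(fv, rules) for fv in features]
    return PipelineResult(
        kept_records=kept,
        clusters=clusters,
        representatives=reps,
        alignment=aln,
        filtered_alignment=filtered,
        tree=tree,
        rooted_tree=rooted,
        clades=clades,
        features=features,
        calls=calls,
    )


def clade_purity(clades: Sequence[Set[str]], labels: Dict[str, str]) -> float:
    """Fraction of clade members sharing their clade's majority truth label."""
    total = 0
    agree = 0
    for clade in clades:
        votes: Dict[str, int] = {}
        for member in clade:
            votes[labels[member]] = votes.get(labels[member], 0) + 1
        agree += max(votes.values())
        total += len(clade)
    return agree / total if total else 0.0


def call_accuracy(calls: Sequence[CladeCall], labels: Dict[str, str]) -> float:
    """Fraction of classifier calls matching truth labels."""
    if not calls:
        return 0.0
    return sum(1 for c in calls if c.call == labels.get(c.id)) / len(calls)
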