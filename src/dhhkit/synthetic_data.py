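"""Synthetic DHH-DHHA1 protein families and assay tables for pipeline testing.

Three clade archetypes (A/B/C) are built on a shared scaffold so that the
conserved core aligns across clades, then evolved along simulated Yule trees
with per-site substitutions.  The architecture mirrors the segmentation
offsets used by :mod:`dhhkit.sequences`, so a generated clade-A protein
measures a clade-A linker and C-terminal tail by construction:

    [N-terminal core, signature residue at a fixed position]
    [DHH][k1 core][linker][k2 core][GGGH][k3 core][C-terminal tail]

Truth labels ride in record labels / a sidecar TSV; the analysis pipeline
never reads them outside of tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sequences import (
    AMINO_ACIDS,
    ProteinRecord,
    SegmentationOffsets,
    fasta_string,
    scan_motifs,
    primary_hit,
)
from .tree import Node, PhyloTree

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

NTERM_LENGTH = 150
SIGNATURE_POSITION = 100  # 1-based, within the conserved N-terminal core
DHH_MOTIF_POSITION = NTERM_LENGTH + 1


@dataclass(frozen=True)
class CladeArchetypeSpec:
    name: str
    linker_length_range: Tuple[int, int]
    cterm_length_range: Tuple[int, int]
    signature_residue: Optional[str]  # None -> sampled excluding K and N
    cterm_kr_enrichment: float
    dhh_motif_position: int = DHH_MOTIF_POSITION
    signature_position: int = SIGNATURE_POSITION

    def __post_init__(self) -> None:
        for lo, hi in (self.linker_length_range, self.cterm_length_range):
            if lo > hi or lo < 0:
                raise ValidationError(f"invalid range ({lo}, {hi})")
        if not 0 <= self.cterm_kr_enrichment <= 1:
            raise ValidationError("cterm_kr_enrichment must be in [0, 1]")


DEFAULT_ARCHETYPES: Tuple[CladeArchetypeSpec, ...] = (
    CladeArchetypeSpec("A", (120, 180), (105, 160), "K", 0.30),
    CladeArchetypeSpec("B", (60, 120), (10, 45), "N", 0.05),
    CladeArchetypeSpec("C", (40, 90), (10, 45), None, 0.05),
)

#: Variant clade-A spec exercising the >200 aa linker binarization class.
LONG_LINKER_ARCHETYPE = replace(
    DEFAULT_ARCHETYPES[0], name="A_long_linker", linker_length_range=(210, 260)
)


@dataclass(frozen=True)
class GeneratorConfig:
    seqs_per_clade: int = 20
    substitution_rate: float = 0.05
    protected_rate_factor: float = 0.01
    clade_depth: float = 8.75
    clade_divergence: float = 1.0
    root_stem_length: float = 1.0
    seed: int = 1234
    # family-level quality control (generate_dataset only): a clade family is
    # redrawn when its diversity profile would make the three families either
    # collapse under 70%-identity clustering or blur the clade/whole-tree
    # distance contrast.  Bounds are on greedy hamming-identity representative
    # counts and their mean Poisson-corrected spread.
    qc_min_reps: int = 8
    qc_max_reps: int = 12
    qc_max_spread: float = 0.79
    qc_identity: float = 0.70
    qc_max_attempts: int = 60
    # assay-table parameters
    n_traces: int = 3
    trace_times_min: Tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 60.0)
    depletion_noise: float = 0.05
    curve_slope: float = 0.01
    curve_intercept: float = 0.05
    curve_noise: float = 0.005
    curve_concentrations_uM: Tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 20.0, 40.0)

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 1:
            raise ValidationError("substitution_rate must be in [0, 1]")
        if not 0 <= self.protected_rate_factor <= 1:
            raise ValidationError("protected_rate_factor must be in [0, 1]")
        if self.seqs_per_clade < 1:
            raise ValidationError("seqs_per_clade must be >= 1")


# -- sequence assembly ------------------------------------------------------


def _random_aa(rng: np.random.Generator, n: int) -> List[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), n)]


def _scrub_spurious_motifs(seq: List[str], keep: set) -> None:
    """Destroy stray DHH/GGGH string matches outside ``keep`` (0-based set).

    Replacement residue 'L' cannot recreate either motif, so one sweep per
    pattern suffices; deterministic (no RNG involved).
    """
    text = "".join(seq)
    for pattern in ("DHH", "GGGH"):
        pos = text.find(pattern)
        while pos != -1:
            span = range(pos, pos + len(pattern))
            if not set(span) <= keep:
                target = next(i for i in span if i not in keep)
                seq[target] = "L"
                text = "".join(seq)
                pos = text.find(pattern, pos)
            else:
                pos = text.find(pattern, pos + 1)


def _sample_tail(rng: np.random.Generator, n: int, kr_fraction: float) -> List[str]:
    others = [a for a in AMINO_ACIDS if a not in "KR"]
    out = []
    for _ in range(n):
        if rng.random() < kr_fraction:
            out.append("K" if rng.random() < 0.5 else "R")
        else:
            out.append(others[rng.integers(0, len(others))])
    return out


@dataclass
class _Scaffold:
    """Shared conserved regions from which all clade archetypes are derived."""

    nterm: List[str]
    k1_core: List[str]
    k2_core: List[str]
    k3_core: List[str]

    @classmethod
    def sample(cls, rng: np.random.Generator, offsets: SegmentationOffsets) -> "_Scaffold":
        return cls(
            nterm=_random_aa(rng, NTERM_LENGTH),
            k1_core=_random_aa(rng, offsets.k1),
            k2_core=_random_aa(rng, offsets.k2),
            k3_core=_random_aa(rng, offsets.k3),
        )

    def diverged(
        self,
        rng: np.random.Generator,
        p: float,
        anchor_stride: int = 10,
        conserved_block: Tuple[int, int] = (
            SIGNATURE_POSITION - 8,
            SIGNATURE_POSITION + 8,
        ),
    ) -> "_Scaffold":
        """Clade-specific scaffold copy: mutate each position with probability
        ``p``, keeping every ``anchor_stride``-th position plus a contiguous
        active-site-like block around the signature position invariant.

        The invariant positions mimic domain-conserved residues shared by all
        clades; the conserved block ensures the signature column registers
        across clades in the multiple alignment even at high divergence.
        """
        lo, hi = conserved_block  # 1-based positions within the N-terminal core

        def mut(region: List[str], block: bool) -> List[str]:
            out = list(region)
            for i in range(len(out)):
                if anchor_stride and i % anchor_stride == 0:
                    continue
                if block and lo <= i + 1 <= hi:
                    continue
                if rng.random() < p:
                    choices = AMINO_ACIDS.replace(out[i], "")
                    out[i] = choices[rng.integers(0, len(choices))]
            return out

        return _Scaffold(
            mut(self.nterm, True),
            mut(self.k1_core, False),
            mut(self.k2_core, False),
            mut(self.k3_core, False),
        )


def _assemble(
    spec: CladeArchetypeSpec,
    scaffold: _Scaffold,
    rng: np.random.Generator,
) -> ProteinRecord:
    lo, hi = spec.linker_length_range
    linker_len = int(rng.integers(lo, hi + 1))
    lo, hi = spec.cterm_length_range
    tail_len = int(rng.integers(lo, hi + 1))
    signature = spec.signature_residue
    if signature is None:
        pool = [a for a in AMINO_ACIDS if a not in "KN"]
        signature = pool[rng.integers(0, len(pool))]
    seq = (
        list(scaffold.nterm)
        + list("DHH")
        + list(scaffold.k1_core)
        + _random_aa(rng, linker_len)
        + list(scaffold.k2_core)
        + list("GGGH")
        + list(scaffold.k3_core)
        + _sample_tail(rng, tail_len, spec.cterm_kr_enrichment)
    )
    seq[spec.signature_position - 1] = signature
    protected = _protected_positions(spec, linker_len)
    _scrub_spurious_motifs(seq, protected)
    return ProteinRecord(
        id=f"{spec.name}_archetype",
        sequence="".join(seq),
        description=f"clade={spec.name}",
        label=spec.name,
    )


def _protected_positions(spec: CladeArchetypeSpec, linker_len: int) -> set:
    """0-based positions of the motif residues and the signature residue."""
    dhh0 = spec.dhh_motif_position - 1
    offsets = SegmentationOffsets()
    gggh0 = dhh0 + 3 + offsets.k1 + linker_len + offsets.k2
    return (
        set(range(dhh0, dhh0 + 3))
        | set(range(gggh0, gggh0 + 4))
        | {spec.signature_position - 1}
    )


def make_archetype(
    spec: CladeArchetypeSpec, rng: np.random.Generator
) -> ProteinRecord:
    """Generate one clade archetype with its own (unshared) scaffold."""
    return _assemble(spec, _Scaffold.sample(rng, SegmentationOffsets()), rng)


def protected_positions_of(record: ProteinRecord, signature_position: int) -> set:
    """Derive protected 0-based positions from a record's primary motif hits."""
    hits = scan_motifs(record)
    protected = {signature_position - 1}
    for name in ("DHH", "GGGH"):
        hit = primary_hit(hits, name)
        if hit is not None:
            protected |= set(range(hit.start - 1, hit.end))
    return protected


# -- tree simulation and evolution -----------------------------------------


def _yule_tree(n: int, depth: float, rng: np.random.Generator) -> PhyloTree:
    """Ultrametric pure-birth tree with ``n`` leaves scaled to ``depth``."""
    root = Node()
    if n == 1:
        root.add_child(Node(length=depth))
        return PhyloTree(root, rooted=True)
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        victim = active.pop(int(rng.integers(0, len(active))))
        for _ in range(2):
            child = victim.add_child(Node())
            birth[id(child)] = t
            active.append(child)
    total = t + rng.exponential(1.0 / n)
    scale = depth / total
    for node in root.children:
        _set_lengths(node, birth, total, scale, parent_time=birth[id(root)])
    return PhyloTree(root, rooted=True)


def _set_lengths(node: Node, birth, total, scale, parent_time) -> None:
    own = birth[id(node)]
    end = own if node.children else total
    # branch spans from this node's birth to its split (or the present)
    node.length = (end - parent_time) * scale
    for child in node.children:
        _set_lengths(child, birth, total, scale, parent_time=end)


def _mutate(
    sequence: str,
    branch_length: float,
    rate: float,
    protected: set,
    protected_factor: float,
    rng: np.random.Generator,
) -> str:
    p = min(1.0, rate * branch_length)
    p_protected = min(1.0, p * protected_factor)
    seq = list(sequence)
    draws = rng.random(len(seq))
    for i, u in enumerate(draws):
        threshold = p_protected if i in protected else p
        if u < threshold:
            choices = AMINO_ACIDS.replace(seq[i], "")
            seq[i] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


def evolve_family(
    archetype: ProteinRecord,
    n: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    signature_position: int = SIGNATURE_POSITION,
) -> Tuple[List[ProteinRecord], PhyloTree]:
    """Evolve ``n`` leaves from the archetype along a simulated Yule subtree.

    Substitutions are independent per site (uniform replacement over the other
    19 residues); motif and signature positions mutate at the reduced
    protected rate.  Leaf names are ``<label>_<k>`` and the true subtree is
    returned with its branch lengths.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    protected = protected_positions_of(archetype, signature_position)
    tree = _yule_tree(n, config.clade_depth, rng)
    label = archetype.label or archetype.id
    sequences: Dict[int, str] = {id(tree.root): archetype.sequence}
    records: List[ProteinRecord] = []
    counter = 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_seq = sequences[id(node.parent)]
        seq = _mutate(
            parent_seq,
            node.length,
            config.substitution_rate,
            protected,
            config.protected_rate_factor,
            rng,
        )
        sequences[id(node)] = seq
        if node.is_leaf:
            counter += 1
            node.name = f"{label}_{counter:02d}"
            records.append(
                ProteinRecord(
                    id=node.name,
                    sequence=seq,
                    description=f"clade={label}",
                    label=label,
                )
            )
    return records, tree


def _family_diversity(
    records: Sequence[ProteinRecord], identity: float
) -> Tuple[int, float]:
    """Alignment-free family diversity proxy.

    Greedy hamming-identity clustering (same ordering rule as the real
    clustering stage) yields a representative count; the mean Poisson-corrected
    hamming distance among representatives summarizes their spread.
    """
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: List[ProteinRecord] = []
    for rec in order:
        for rep in reps:
            matches = sum(a == b for a, b in zip(rec.sequence, rep.sequence))
            if matches / min(len(rec.sequence), len(rep.sequence)) >= identity:
                break
        else:
            reps.append(rec)
    dists = []
    for i, x in enumerate(reps):
        for y in reps[i + 1 :]:
            p = 1.0 - sum(a == b for a, b in zip(x.sequence, y.sequence)) / min(
                len(x.sequence), len(y.sequence)
            )
            dists.append(-math.log(max(1.0 - p, 1e-3)))
    spread = float(np.mean(dists)) if dists else 0.0
    return len(reps), spread


def _family_ok(records: Sequence[ProteinRecord], config: GeneratorConfig) -> bool:
    n_reps, spread = _family_diversity(records, config.qc_identity)
    return (
        config.qc_min_reps <= n_reps <= config.qc_max_reps
        and spread <= config.qc_max_spread
    )


# -- dataset emission -------------------------------------------------------


@dataclass
class SyntheticDataset:
    records: List[ProteinRecord]
    labels: Dict[str, str]
    true_tree: PhyloTree
    archetypes: List[ProteinRecord]
    signature_position: int = SIGNATURE_POSITION
    reference_id: str = ""


def generate_dataset(
    config: GeneratorConfig = GeneratorConfig(),
    archetype_specs: Sequence[CladeArchetypeSpec] = DEFAULT_ARCHETYPES,
) -> SyntheticDataset:
    """Three clade families on a shared scaffold, joined by a deep root.

    Deterministic for a given config: the same seed yields byte-identical
    FASTA output.
    """
    rng = np.random.default_rng(config.seed)
    base = _Scaffold.sample(rng, SegmentationOffsets())
    records: List[ProteinRecord] = []
    labels: Dict[str, str] = {}
    archetypes: List[ProteinRecord] = []
    root = Node()
    for spec in archetype_specs:
        scaffold = base.diverged(rng, config.clade_divergence)
        archetype = _assemble(spec, scaffold, rng)
        archetypes.append(archetype)
        protected = protected_positions_of(archetype, spec.signature_position)
        cleaned: List[ProteinRecord] = []
        subtree = None
        for _attempt in range(max(1, config.qc_max_attempts)):
            family, subtree = evolve_family(
                archetype,
                config.seqs_per_clade,
                config,
                rng,
                signature_position=spec.signature_position,
            )
            cleaned = []
            for rec in family:
                seq = list(rec.sequence)
                # emitted datasets guarantee intact anchors: undo the (rare)
                # protected-site substitutions the evolution model still allows
                for pos in protected:
                    seq[pos] = archetype.sequence[pos]
                _scrub_spurious_motifs(seq, protected)
                cleaned.append(
                    ProteinRecord(rec.id, "".join(seq), rec.description, rec.label)
                )
            if _family_ok(cleaned, config):
                break
        records.extend(cleaned)
        labels.update({rec.id: rec.label for rec in cleaned})
        subroot = subtree.root
        subroot.length = config.root_stem_length
        root.add_child(subroot)
    true_tree = PhyloTree(root, rooted=True)
    return SyntheticDataset(
        records=records,
        labels=labels,
        true_tree=true_tree,
        archetypes=archetypes,
        signature_position=archetype_specs[0].signature_position,
        reference_id=records[0].id,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> Dict[str, Path]:
    """Write FASTA + labels TSV + true-tree Newick; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "dataset.fasta",
        "labels": out / "labels.tsv",
        "tree": out / "true_tree.nwk",
    }
    paths["fasta"].write_text(fasta_string(dataset.records))
    with open(paths["labels"], "w") as fh:
        fh.write("id\tclade\n")
        for rec in dataset.records:
            fh.write(f"{rec.id}\t{dataset.labels[rec.id]}\n")
    paths["tree"].write_text(dataset.true_tree.to_newick() + "\n")
    return paths


# -- assay tables -----------------------------------------------------------


@dataclass
class SyntheticAssays:
    depletion: pd.DataFrame  # columns: trace_id, time_min, intensity
    standard_curve: pd.DataFrame  # columns: conc_uM, a620
    true_decay_rates: Dict[str, float]
    true_slope: float
    true_intercept: float


def generate_assay_tables(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> SyntheticAssays:
    """Exponential-decay depletion traces plus a linear phosphate curve.

    Depletion noise is multiplicative log-normal; curve noise additive
    Gaussian.  True parameters are returned for recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    rates: Dict[str, float] = {}
    times = np.asarray(config.trace_times_min)
    for t in range(config.n_traces):
        trace_id = f"trace_{t + 1}"
        k = float(rng.uniform(0.02, 0.15))
        i0 = float(rng.uniform(5_000, 20_000))
        rates[trace_id] = k
        noise = np.exp(config.depletion_noise * rng.standard_normal(len(times)))
        intensities = i0 * np.exp(-k * times) * noise
        for time, inten in zip(times, intensities):
            rows.append(
                {"trace_id": trace_id, "time_min": time, "intensity": float(inten)}
            )
    conc = np.asarray(config.curve_concentrations_uM)
    a620 = (
        config.curve_slope * conc
        + config.curve_intercept
        + config.curve_noise * rng.standard_normal(len(conc))
    )
    curve = pd.DataFrame({"conc_uM": conc, "a620": a620})
    return SyntheticAssays(
        depletion=pd.DataFrame(rows),
        standard_curve=curve,
        true_decay_rates=rates,
        true_slope=config.curve_slope,
        true_intercept=config.curve_intercept,
    )


def write_assay_tables(assays: SyntheticAssays, out_dir) -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "depletion": out / "depletion.tsv",
        "standard_curve": out / "standard_curve.tsv",
    }
    assays.depletion.to_csv(paths["depletion"], sep="\t", index=False)
    assays.standard_curve.to_csv(paths["standard_curve"], sep="\t", index=False)
    return paths
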