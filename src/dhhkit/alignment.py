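"""Pairwise global alignment, progressive multiple alignment, gap-column filter.

This is a self-contained progressive aligner (shared-k-mer UPGMA guide tree +
profile-profile affine global alignment) standing in for an external MSA tool,
so the pipeline runs without subprocess dependencies.  Externally produced
alignments can be imported via :func:`read_alignment`.

Terminal gaps are scored like internal gaps (documented simplification).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from ._affine import affine_align
from .errors import ValidationError
from .sequences import ProteinRecord
from .tree import Node, PhyloTree

GAP = "-"


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and filtering parameters.

    ``max_gap_fraction`` drives the column filter: a column is removed when its
    gap fraction is *strictly greater* than this value (default 0.95, i.e.
    ">95% gaps are removed" with exactly 95% retained).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    max_gap_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap costs must be positive")
        if self.gap_extend > self.gap_open:
            raise ValidationError("gap_extend must be <= gap_open")
        if not 0 < self.max_gap_fraction <= 1:
            raise ValidationError("max_gap_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float


class Alignment:
    """Gapped rows over the protein alphabet plus '-'.

    ``source_column_map`` (0-based original column indices, strictly
    increasing) records provenance after column filtering; TSV export is
    1-based.
    """

    def __init__(
        self,
        row_ids: Sequence[str],
        rows: Sequence[str],
        source_column_map: Optional[Sequence[int]] = None,
    ) -> None:
        if len(row_ids) != len(rows):
            raise ValidationError("row_ids and rows must have equal length")
        if len(set(row_ids)) != len(row_ids):
            raise ValidationError("duplicate row ids in alignment")
        if not rows:
            raise ValidationError("alignment must have at least one row")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValidationError("alignment rows must have equal length")
        self.row_ids = list(row_ids)
        self.rows = [r.upper() for r in rows]
        if source_column_map is not None:
            scm = list(source_column_map)
            if any(b <= a for a, b in zip(scm, scm[1:])):
                raise ValidationError("source_column_map must be strictly increasing")
            if len(scm) != self.column_count:
                raise ValidationError("source_column_map length mismatch")
            self.source_column_map = scm
        else:
            self.source_column_map = None

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.row_ids.index(row_id)]
        except ValueError:
            raise ValidationError(f"row id {row_id!r} not in alignment") from None

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def column(self, index: int) -> str:
        return "".join(row[index] for row in self.rows)

    def gap_fractions(self) -> np.ndarray:
        arr = self.to_array()
        return (arr == ord(GAP)).mean(axis=0)

    def to_array(self) -> np.ndarray:
        """Rows as a (n_rows, columns) uint8 matrix of character codes."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_rows, self.column_count)

    def subset(self, row_ids: Sequence[str]) -> "Alignment":
        rows = [self.row(rid) for rid in row_ids]
        return Alignment(list(row_ids), rows, self.source_column_map)


# -- substitution matrix ----------------------------------------------------


@lru_cache(maxsize=4)
def _load_matrix(name: str) -> Tuple[str, np.ndarray]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    dense = np.array(mat, dtype=np.float64)
    return alphabet, dense


@lru_cache(maxsize=4)
def _char_index(name: str) -> Dict[str, int]:
    alphabet, _ = _load_matrix(name)
    return {c: i for i, c in enumerate(alphabet)}


def _encode(seq: str, matrix_name: str) -> np.ndarray:
    index = _char_index(matrix_name)
    try:
        return np.array([index[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(
            f"residue {exc.args[0]!r} not in substitution matrix {matrix_name}"
        ) from None


# -- pairwise ---------------------------------------------------------------


def global_align(
    a: str, b: str, params: AlignmentParams = AlignmentParams()
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment with deterministic traceback.

    Empty sequences are allowed and produce all-gap alignments with the
    closed-form gap score.
    """
    a, b = a.upper(), b.upper()
    _, dense = _load_matrix(params.substitution_matrix)
    ia, ib = _encode(a, params.substitution_matrix), _encode(b, params.substitution_matrix)
    M = dense[np.ix_(ia, ib)] if len(a) and len(b) else np.zeros((len(a), len(b)))
    score, ops = affine_align(M, params.gap_open, params.gap_extend)
    out_a, out_b = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif op == 1:
            out_a.append(a[i])
            out_b.append(GAP)
            i += 1
        else:
            out_a.append(GAP)
            out_b.append(b[j])
            j += 1
    return PairwiseAlignment("".join(out_a), "".join(out_b), float(score))


# -- guide tree -------------------------------------------------------------


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - |shared k-mers| / min(k-mer count); 1.0 when a sequence is too short."""
    ca, cb = _kmer_counts(a, k), _kmer_counts(b, k)
    denom = min(sum(ca.values()), sum(cb.values()))
    if denom == 0:
        return 1.0
    shared = sum((ca & cb).values())
    return 1.0 - shared / denom


def build_guide_tree(records: Sequence[ProteinRecord], k: int = 3) -> PhyloTree:
    """UPGMA tree on fractional shared-k-mer distances; id-lexicographic tie-break."""
    if len(records) < 2:
        raise ValidationError("guide tree requires at least 2 records")
    dist: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            d = kmer_distance(a.sequence, b.sequence, k)
            dist[(a.id, b.id)] = dist[(b.id, a.id)] = d
    return upgma([r.id for r in records], dist)


def upgma(ids: Sequence[str], dist: Dict[Tuple[str, str], float]) -> PhyloTree:
    """Average-linkage agglomeration; ties broken by the lexicographically
    smallest (min-member-id) pair of clusters."""
    clusters: List[dict] = [
        {"key": i, "node": Node(i), "size": 1, "height": 0.0} for i in sorted(ids)
    ]
    d = {
        (a["key"], b["key"]): dist[(a["key"], b["key"])]
        for i, a in enumerate(clusters)
        for b in clusters[i + 1 :]
    }

    def get(x: str, y: str) -> float:
        return d[(x, y)] if (x, y) in d else d[(y, x)]

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ki, kj = clusters[i]["key"], clusters[j]["key"]
                pair = tuple(sorted((ki, kj)))
                cand = (get(ki, kj), pair)
                if best is None or cand < best:
                    best = cand
                    bi, bj = i, j
        ci, cj = clusters[bi], clusters[bj]
        height = best[0] / 2.0
        parent = Node()
        for c in (ci, cj):
            c["node"].length = max(0.0, height - c["height"])
            parent.add_child(c["node"])
        merged = {
            "key": min(ci["key"], cj["key"]),
            "node": parent,
            "size": ci["size"] + cj["size"],
            "height": height,
        }
        rest = [c for idx, c in enumerate(clusters) if idx not in (bi, bj)]
        for c in rest:
            dk = (
                get(ci["key"], c["key"]) * ci["size"]
                + get(cj["key"], c["key"]) * cj["size"]
            ) / (ci["size"] + cj["size"])
            d[(merged["key"], c["key"])] = dk
        clusters = rest + [merged]
    return PhyloTree(clusters[0]["node"], rooted=True)


# -- progressive MSA --------------------------------------------------------


def _profile(rows: Sequence[str], matrix_name: str) -> np.ndarray:
    """Column frequency matrix over matrix alphabet + gap (gap scores zero)."""
    index = _char_index(matrix_name)
    n_sym = len(index) + 1
    gap_idx = n_sym - 1
    length = len(rows[0])
    counts = np.zeros((length, n_sym))
    for row in rows:
        for pos, ch in enumerate(row):
            counts[pos, gap_idx if ch == GAP else index[ch]] += 1
    return counts / len(rows)


def _merge(
    left: Tuple[List[str], List[str]],
    right: Tuple[List[str], List[str]],
    params: AlignmentParams,
) -> Tuple[List[str], List[str]]:
    ids_a, rows_a = left
    ids_b, rows_b = right
    name = params.substitution_matrix
    _, dense = _load_matrix(name)
    n_sym = dense.shape[0] + 1
    ext = np.zeros((n_sym, n_sym))
    ext[: dense.shape[0], : dense.shape[1]] = dense
    fa = _profile(rows_a, name)
    fb = _profile(rows_b, name)
    M = fa @ ext @ fb.T  # mean pairwise matrix score, gap pairs contribute 0
    _, ops = affine_align(M, params.gap_open, params.gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        take_a, take_b = op != 2, op != 1
        for r, row in enumerate(rows_a):
            out_a[r].append(row[i] if take_a else GAP)
        for r, row in enumerate(rows_b):
            out_b[r].append(row[j] if take_b else GAP)
        i += take_a
        j += take_b
    return ids_a + ids_b, ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def progressive_msa(
    records: Sequence[ProteinRecord], params: AlignmentParams = AlignmentParams()
) -> Alignment:
    """Progressive profile-profile alignment along a UPGMA guide tree.

    Row order follows the input record order; de-gapping any row reproduces
    its input sequence exactly.
    """
    if len(records) < 2:
        raise ValidationError("progressive MSA requires at least 2 records")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValidationError("duplicate record ids")
    guide = build_guide_tree(records)

    merged: Dict[int, Tuple[List[str], List[str]]] = {}
    for node in guide.postorder():
        if node.is_leaf:
            merged[id(node)] = ([node.name], [by_id[node.name].sequence])
        else:
            acc = merged.pop(id(node.children[0]))
            for child in node.children[1:]:
                acc = _merge(acc, merged.pop(id(child)), params)
            merged[id(node)] = acc
    ids, rows = merged[id(guide.root)]
    # restore input record order
    row_of = dict(zip(ids, rows))
    return Alignment([r.id for r in records], [row_of[r.id] for r in records])


def sum_of_pairs_score(aln: Alignment, params: AlignmentParams = AlignmentParams()) -> float:
    """Sum over row pairs of affine-scored alignment columns (evaluation only)."""
    total = 0.0
    _, dense = _load_matrix(params.substitution_matrix)
    index = _char_index(params.substitution_matrix)
    for i in range(aln.n_rows):
        for j in range(i + 1, aln.n_rows):
            total += _pair_score(aln.rows[i], aln.rows[j], dense, index, params)
    return total


def _pair_score(a: str, b: str, dense, index, params: AlignmentParams) -> float:
    score = 0.0
    gap_a = gap_b = False
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            continue
        if ca == GAP:
            score -= params.gap_extend if gap_a else params.gap_open
            gap_a, gap_b = True, False
        elif cb == GAP:
            score -= params.gap_extend if gap_b else params.gap_open
            gap_b, gap_a = True, False
        else:
            score += dense[index[ca], index[cb]]
            gap_a = gap_b = False
    return score


# -- gap-column filter ------------------------------------------------------


def filter_gap_columns(
    aln: Alignment, params: AlignmentParams = AlignmentParams()
) -> Alignment:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_fraction``."""
    fractions = aln.gap_fractions()
    keep = [i for i, f in enumerate(fractions) if f <= params.max_gap_fraction]
    rows = ["".join(row[i] for i in keep) for row in aln.rows]
    if aln.source_column_map is not None:
        scm = [aln.source_column_map[i] for i in keep]
    else:
        scm = keep
    return _ZeroColumnSafeAlignment(aln.row_ids, rows, scm)


class _ZeroColumnSafeAlignment(Alignment):
    """Alignment subclass tolerating zero columns (filter may remove all)."""

    def __init__(self, row_ids, rows, source_column_map=None):
        if rows and all(len(r) == 0 for r in rows):
            self.row_ids = list(row_ids)
            self.rows = list(rows)
            self.source_column_map = list(source_column_map or [])
        else:
            super().__init__(row_ids, rows, source_column_map)

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0


# -- aligned FASTA I/O ------------------------------------------------------


def read_alignment(path) -> Alignment:
    """Read a gapped FASTA (or A2M; dots are converted to gaps) alignment."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", GAP))
    if not ids:
        raise ValidationError(f"{path}: no alignment rows found")
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.row_ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def write_column_map(aln: Alignment, path) -> None:
    """TSV of retained-column provenance (1-based on both sides)."""
    with open(path, "w") as fh:
        fh.write("column\tsource_column\n")
        scm = aln.source_column_map or range(aln.column_count)
        for new, old in enumerate(scm):
            fh.write(f"{new + 1}\t{old + 1}\n")
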