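"""FASTA I/O, motif-signature scanning and motif-anchored domain segmentation.

All residue coordinates in this module (and everywhere else in dhhkit) are
1-based and intervals are closed, following biological convention.

The DHH phosphoesterase domain is anchored by the literal ``DHH`` motif and
the DHHA1 domain by the literal ``GGGH`` motif.  Domain boundaries are
operationalized with configurable offsets around those anchors
(:class:`SegmentationOffsets`); the linker is everything between the two
derived regions and the C-terminal tail everything after the DHHA1 region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, SegmentationError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Allowed residue alphabet: the 20 canonical amino acids plus X (unknown).
ALPHABET = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a unique identifier.

    ``label`` carries a ground-truth clade tag for synthetic data only; the
    analysis pipeline never reads it.
    """

    id: str
    sequence: str
    description: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifDefinition:
    """An exact residue pattern with an optional fractional search window.

    ``search_window`` is an interval of fraction-of-length in which a hit must
    *start*; ``(0.0, 1.0)`` (or ``None``) accepts hits anywhere.
    """

    name: str
    pattern: str
    search_window: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValidationError(f"motif {self.name!r}: pattern length must be >= 3")
        if self.search_window is not None:
            lo, hi = self.search_window
            if not (0.0 <= lo < hi <= 1.0):
                raise ValidationError(
                    f"motif {self.name!r}: window bounds must satisfy 0 <= start < end <= 1"
                )


# Windows suppress spurious C-terminal "DHH" / N-terminal "GGGH" string matches.
DHH_MOTIF = MotifDefinition("DHH", "DHH", (0.0, 0.7))
GGGH_MOTIF = MotifDefinition("GGGH", "GGGH", (0.2, 1.0))
DEFAULT_MOTIFS = (DHH_MOTIF, GGGH_MOTIF)


@dataclass(frozen=True)
class MotifHit:
    """An exact motif occurrence; ``start``/``end`` are 1-based inclusive."""

    motif_name: str
    start: int
    end: int
    primary: bool = False


@dataclass(frozen=True)
class SegmentationOffsets:
    """Offsets that turn motif anchors into domain boundaries.

    k1: residues the DHH region extends past the DHH motif end.
    k2: residues the DHHA1 region begins before the GGGH motif start.
    k3: residues the DHHA1 region extends past the GGGH motif end.
    min_length / max_standalone_length: total-length bounds used by the
    standalone DHH-DHHA1 inclusion filter (the length cap is a proxy for
    "lacks additional domains": multi-domain GdpP-like proteins are longer).
    """

    k1: int = 10
    k2: int = 10
    k3: int = 30
    max_standalone_length: int = 700
    min_length: int = 250

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3) < 0:
            raise ValidationError("segmentation offsets must be >= 0")
        if not self.min_length < self.max_standalone_length:
            raise ValidationError("min_length must be < max_standalone_length")


@dataclass(frozen=True)
class DomainSegmentation:
    """Derived domain spans for one protein (1-based closed intervals)."""

    dhh_hit: MotifHit
    gggh_hit: MotifHit
    dhh_region_end: int
    dhha1_region_start: int
    dhha1_region_end: int
    linker_span: Optional[Tuple[int, int]]
    linker_length: int
    cterm_span: Optional[Tuple[int, int]]
    cterm_length: int
    offsets: SegmentationOffsets = field(default_factory=SegmentationOffsets)


@dataclass(frozen=True)
class StandaloneCall:
    """Decision of the standalone DHH-DHHA1 filter with a human-readable reason."""

    standalone: bool
    reason: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.standalone


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are upper-cased.  Raises :class:`ParseError` for empty sequences
    (naming the record index) and :class:`ValidationError` for duplicate ids.
    """
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not raw:
        raise ParseError(f"{path}: no FASTA records found")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for idx, rec in enumerate(raw):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: record {idx}: empty header")
        if not seq:
            raise ParseError(f"{path}: record {idx} ({rec.id!r}): empty sequence")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as multi-FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        fh.write(fasta_string(records, width=width))


def fasta_string(records: Iterable[ProteinRecord], width: int = 60) -> str:
    buf = io.StringIO()
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        buf.write(f">{header}\n")
        for i in range(0, len(rec.sequence), width):
            buf.write(rec.sequence[i : i + width] + "\n")
    return buf.getvalue()


def scan_motifs(
    record: ProteinRecord, motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS
) -> list[MotifHit]:
    """Find all exact in-window occurrences of each motif.

    For each motif the most N-terminal hit inside its search window is flagged
    ``primary``.  Hits are returned sorted by start position.  A motif with no
    hit simply contributes nothing.
    """
    if not motifs:
        raise ValidationError("motif list must be non-empty")
    seq = record.sequence
    length = len(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        lo, hi = motif.search_window if motif.search_window else (0.0, 1.0)
        first = True
        pos = seq.find(motif.pattern)
        while pos != -1:
            frac = pos / length
            if lo <= frac <= hi:
                hits.append(
                    MotifHit(
                        motif_name=motif.name,
                        start=pos + 1,
                        end=pos + len(motif.pattern),
                        primary=first,
                    )
                )
                first = False
            pos = seq.find(motif.pattern, pos + 1)
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def primary_hit(hits: Iterable[MotifHit], motif_name: str) -> Optional[MotifHit]:
    """Return the primary hit for ``motif_name``, or None."""
    for hit in hits:
        if hit.motif_name == motif_name and hit.primary:
            return hit
    return None


def segment_domains(
    record: ProteinRecord,
    hits: Sequence[MotifHit],
    offsets: SegmentationOffsets = SegmentationOffsets(),
) -> DomainSegmentation:
    """Derive DHH-region / linker / DHHA1-region / C-terminal spans from motif hits.

    Requires primary DHH and GGGH hits with DHH strictly upstream of GGGH;
    raises :class:`SegmentationError` otherwise.
    """
    dhh = primary_hit(hits, "DHH")
    gggh = primary_hit(hits, "GGGH")
    if dhh is None:
        raise SegmentationError(f"record {record.id!r}: missing DHH motif anchor")
    if gggh is None:
        raise SegmentationError(f"record {record.id!r}: missing GGGH motif anchor")
    if not dhh.end < gggh.start:
        raise SegmentationError(
            f"record {record.id!r}: DHH motif (end {dhh.end}) must precede "
            f"GGGH motif (start {gggh.start})"
        )
    length = len(record.sequence)
    dhha1_start = max(gggh.start - offsets.k2, dhh.end + 1)
    dhh_region_end = min(dhh.end + offsets.k1, dhha1_start - 1)
    dhha1_end = min(length, gggh.end + offsets.k3)

    linker_length = max(0, dhha1_start - dhh_region_end - 1)
    linker_span = (dhh_region_end + 1, dhha1_start - 1) if linker_length else None
    cterm_length = max(0, length - dhha1_end)
    cterm_span = (dhha1_end + 1, length) if cterm_length else None
    return DomainSegmentation(
        dhh_hit=dhh,
        gggh_hit=gggh,
        dhh_region_end=dhh_region_end,
        dhha1_region_start=dhha1_start,
        dhha1_region_end=dhha1_end,
        linker_span=linker_span,
        linker_length=linker_length,
        cterm_span=cterm_span,
        cterm_length=cterm_length,
        offsets=offsets,
    )


def is_standalone_dhh_dhha1(
    record: ProteinRecord,
    hits: Sequence[MotifHit],
    offsets: SegmentationOffsets = SegmentationOffsets(),
) -> StandaloneCall:
    """Decide whether ``record`` is a standalone DHH-DHHA1 protein.

    True iff both primary signatures are present in order and the total length
    lies within ``[min_length, max_standalone_length]``.  The reason text names
    the first criterion that fails.
    """
    dhh = primary_hit(hits, "DHH")
    gggh = primary_hit(hits, "GGGH")
    if dhh is None:
        return StandaloneCall(False, "missing DHH signature")
    if gggh is None:
        return StandaloneCall(False, "missing GGGH signature")
    if not dhh.end < gggh.start:
        return StandaloneCall(
            False, f"DHH (end {dhh.end}) does not precede GGGH (start {gggh.start})"
        )
    length = len(record.sequence)
    if length < offsets.min_length:
        return StandaloneCall(
            False, f"length {length} below minimum {offsets.min_length}"
        )
    if length > offsets.max_standalone_length:
        return StandaloneCall(
            False, f"length {length} exceeds cap {offsets.max_standalone_length}"
        )
    return StandaloneCall(True, "ok")


def segmentation_table(
    records: Sequence[ProteinRecord],
    offsets: SegmentationOffsets = SegmentationOffsets(),
    motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS,
) -> pd.DataFrame:
    """Scan, segment and filter every record; tabulate results for TSV export.

    Records whose anchors cannot be segmented get empty span columns and
    ``standalone=False`` with the filter's reason.
    """
    rows = []
    for rec in records:
        hits = scan_motifs(rec, motifs)
        call = is_standalone_dhh_dhha1(rec, hits, offsets)
        row = {
            "id": rec.id,
            "length": len(rec.sequence),
            "dhh_start": pd.NA,
            "dhh_end": pd.NA,
            "gggh_start": pd.NA,
            "gggh_end": pd.NA,
            "linker_length": pd.NA,
            "cterm_length": pd.NA,
            "standalone": call.standalone,
            "reason": call.reason,
        }
        try:
            seg = segment_domains(rec, hits, offsets)
        except SegmentationError:
            seg = None
        if seg is not None:
            row.update(
                dhh_start=seg.dhh_hit.start,
                dhh_end=seg.dhh_hit.end,
                gggh_start=seg.gggh_hit.start,
                gggh_end=seg.gggh_hit.end,
                linker_length=seg.linker_length,
                cterm_length=seg.cterm_length,
            )
        rows.append(row)
    return pd.DataFrame(rows)
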