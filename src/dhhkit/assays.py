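"""Exonuclease degradation ladders, polarity inference and assay quantification.

The ladder model is purely compositional: residues are removed one at a time
from the chosen terminus, a cleavage is forbidden when it would sever a
blocked (e.g. phosphorothioate) internucleotide linkage, and no kinetics are
modelled.  Linkage ``i`` joins residues ``i`` and ``i + 1`` (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import FitError, ValidationError

RNA_ALPHABET = frozenset("ACGU")

THREE_TO_FIVE = "three_to_five"
FIVE_TO_THREE = "five_to_three"
NO_PROCESSING = "no_processing"
AMBIGUOUS = "ambiguous"
INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class RnaSubstrate:
    """A 5'->3' RNA sequence with optional 5' label and blocked linkages."""

    sequence: str
    label: str = "five_prime_32P"
    blocked_linkages: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValidationError(f"invalid RNA residues {sorted(bad)!r}")
        if self.label not in {"five_prime_32P", "none"}:
            raise ValidationError(f"unknown label {self.label!r}")
        object.__setattr__(self, "blocked_linkages", frozenset(self.blocked_linkages))
        for link in self.blocked_linkages:
            if not 1 <= link <= len(seq) - 1:
                raise ValidationError(
                    f"blocked linkage {link} out of range 1..{len(seq) - 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DegradationLadder:
    polarity: str
    labeled_species: Tuple[int, ...]
    final_products: Tuple[str, ...]
    stall_product: Optional[str]


@dataclass(frozen=True)
class DepletionTrace:
    times_min: Tuple[float, ...]
    intensities: Tuple[float, ...]
    normalized: Tuple[float, ...]


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    residual_rms: float
    conc_range: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise FitError("phosphate standard curve must have positive slope")


def simulate_exo_ladder(substrate: RnaSubstrate, polarity: str) -> DegradationLadder:
    """Remove residues one at a time until done or a blocked linkage is reached.

    3'->5': the enzyme removes the 3'-terminal residue; severing linkage
    ``L-1`` of the current fragment.  With a block at linkage ``i`` the stall
    product is the 5' prefix of length ``i + 1``.

    5'->3': the first removed species is the (labeled) 5' mononucleotide; with
    a block at linkage ``i`` the stall product is the 3' suffix starting at
    residue ``i``.
    """
    if polarity not in {THREE_TO_FIVE, FIVE_TO_THREE}:
        raise ValidationError(f"unknown polarity {polarity!r}")
    seq = substrate.sequence
    length = len(seq)
    if length == 1:
        return DegradationLadder(polarity, (), (seq,), None)
    blocked = substrate.blocked_linkages
    labeled = substrate.label == "five_prime_32P"
    removed: List[str] = []
    labeled_species: List[int] = []

    if polarity == THREE_TO_FIVE:
        end = length  # current 3'-terminal residue index
        while end > 1 and (end - 1) not in blocked:
            removed.append(seq[end - 1])
            end -= 1
            if labeled:
                labeled_species.append(end)
        if end == 1:
            # complete degradation to mononucleotides
            products = tuple(removed) + (seq[0],)
            return DegradationLadder(polarity, tuple(labeled_species), products, None)
        stall = seq[:end]
        return DegradationLadder(
            polarity, tuple(labeled_species), tuple(removed) + (stall,), stall
        )

    start = 1  # current 5'-terminal residue index
    while start < length and start not in blocked:
        removed.append(seq[start - 1])
        if labeled and start == 1:
            labeled_species.append(1)  # label departs on the 5' mononucleotide
        start += 1
    if start == length:
        products = tuple(removed) + (seq[-1],)
        return DegradationLadder(polarity, tuple(labeled_species), products, None)
    stall = seq[start - 1 :]
    return DegradationLadder(
        polarity, tuple(labeled_species), tuple(removed) + (stall,), stall
    )


@dataclass(frozen=True)
class PolarityCall:
    polarity: str
    residues_removed: int


def infer_polarity(substrate: str, intermediate: str) -> PolarityCall:
    """Infer exonuclease polarity from a substrate/intermediate pair.

    A proper 5'-anchored prefix implies 3'->5' processing; a proper 3'-anchored
    suffix implies 5'->3'; both (degenerate termini) is ambiguous; neither is
    inconsistent; identity means no processing.
    """
    substrate = substrate.upper().replace("T", "U")
    intermediate = intermediate.upper().replace("T", "U")
    if not substrate or not intermediate:
        raise ValidationError("substrate and intermediate must be non-empty")
    if len(intermediate) > len(substrate):
        raise ValidationError("intermediate longer than substrate")
    if intermediate == substrate:
        return PolarityCall(NO_PROCESSING, 0)
    removed = len(substrate) - len(intermediate)
    is_prefix = substrate.startswith(intermediate)
    is_suffix = substrate.endswith(intermediate)
    if is_prefix and is_suffix:
        return PolarityCall(AMBIGUOUS, removed)
    if is_prefix:
        return PolarityCall(THREE_TO_FIVE, removed)
    if is_suffix:
        return PolarityCall(FIVE_TO_THREE, removed)
    return PolarityCall(INCONSISTENT, removed)


def normalize_depletion(
    times_min: Sequence[float], intensities: Sequence[float]
) -> DepletionTrace:
    """Divide every band intensity by the first time point's intensity."""
    if len(times_min) != len(intensities):
        raise ValidationError("times and intensities must have equal length")
    if not times_min:
        raise ValidationError("trace must contain at least one point")
    if any(v < 0 for v in intensities):
        raise ValidationError("intensities must be non-negative")
    first = intensities[0]
    if first <= 0:
        raise ValidationError("first time point intensity must be positive")
    return DepletionTrace(
        times_min=tuple(float(t) for t in times_min),
        intensities=tuple(float(v) for v in intensities),
        normalized=tuple(float(v) / first for v in intensities),
    )


def fit_standard_curve(
    points: Sequence[Tuple[float, float]]
) -> StandardCurve:
    """Ordinary least squares line: absorbance = slope * concentration + intercept."""
    if len(points) < 2:
        raise FitError("standard curve needs at least 2 points")
    conc = np.asarray([p[0] for p in points], dtype=float)
    absorb = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(conc, conc[0]):
        raise FitError("all concentrations identical; line is underdetermined")
    result = stats.linregress(conc, absorb)
    predicted = result.slope * conc + result.intercept
    rms = float(np.sqrt(np.mean((absorb - predicted) ** 2)))
    return StandardCurve(
        slope=float(result.slope),
        intercept=float(result.intercept),
        residual_rms=rms,
        conc_range=(float(conc.min()), float(conc.max())),
    )


@dataclass(frozen=True)
class Inversion:
    concentration_uM: float
    extrapolated: bool


def invert_standard_curve(curve: StandardCurve, absorbance: float) -> Inversion:
    """Solve the fitted line for concentration; flag out-of-range extrapolation."""
    conc = (absorbance - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    return Inversion(float(conc), not lo <= conc <= hi)


def cdiamp_expected_phosphate(c_di_amp_conc_uM: float, processing: str) -> float:
    """Upper bound on phosphatase-released phosphate from c-di-AMP processing.

    Intact c-di-AMP exposes no phosphate; linearization to pApA exposes one 5'
    phosphate per molecule; full processing to AMP yields two.
    """
    if c_di_amp_conc_uM < 0:
        raise ValidationError("concentration must be >= 0")
    factors = {"none": 0.0, "linearized": 1.0, "to_AMP": 2.0}
    try:
        return factors[processing] * c_di_amp_conc_uM
    except KeyError:
        raise ValidationError(
            f"unknown processing mode {processing!r}; choose from {sorted(factors)}"
        ) from None
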