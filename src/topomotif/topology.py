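"""C-terminus classification and membrane-distance arithmetic.

The census keeps only proteins whose final residue lies in a topological
domain annotated "Cytoplasmic", and (for the bileucine sub-parse) only
motifs lying at least a minimum number of residues from the nearest
membrane segment — the sequence-level proxy for the physical reach a
recycling complex needs to engage its cargo motif.

Conventions (fixed here, documented in the methods note):

* C-terminus classification reads the TOPO_DOM note with case-insensitive
  prefix semantics, so "Cytoplasmic; in dimer" still counts as cytoplasmic.
* Membrane distance is the count of residues strictly between the motif
  and the nearest flanking TRANSMEM/INTRAMEM boundary, minimized over both
  flanks.  A motif starting immediately after a membrane segment has
  distance 0; one overlapping a segment also has distance 0.
* A protein with no membrane segment at all has UNDEFINED distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .records import MEMBRANE_KINDS, FeatureKind, ProteinRecord, TopoFeature

__all__ = [
    "CTermClass",
    "MembraneDistance",
    "classify_cterm",
    "enclosing_cytoplasmic_domain",
    "membrane_distance",
]

CYTOPLASMIC_PREFIX = "cytoplasmic"
EXTRACELLULAR_PREFIX = "extracellular"


class CTermClass(Enum):
    CYTOPLASMIC = "cytoplasmic"
    EXTRACELLULAR = "extracellular"
    OTHER_ANNOTATED = "other_annotated"
    UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class MembraneDistance:
    """Residues between a motif and the nearest membrane-segment boundary.

    ``residues`` is None when the record carries no flanking membrane
    segment (peripheral or lipid-anchored proteins).
    """

    residues: int | None

    @property
    def defined(self) -> bool:
        return self.residues is not None

    def satisfies(self, minimum: int) -> bool:
        """UNDEFINED passes any threshold (flagged upstream), else compare."""
        return self.residues is None or self.residues >= minimum

    def __str__(self) -> str:
        return "NA" if self.residues is None else str(self.residues)


UNDEFINED_DISTANCE = MembraneDistance(residues=None)


def _is_cytoplasmic(note: str) -> bool:
    return note.strip().lower().startswith(CYTOPLASMIC_PREFIX)


def classify_cterm(record: ProteinRecord) -> CTermClass:
    """Classify the topological location of a protein's final residue."""
    last = len(record.sequence)
    for f in record.features_of(FeatureKind.TOPO_DOM):
        if f.covers(last):
            note = f.note.strip().lower()
            if note.startswith(CYTOPLASMIC_PREFIX):
                return CTermClass.CYTOPLASMIC
            if note.startswith(EXTRACELLULAR_PREFIX):
                return CTermClass.EXTRACELLULAR
            return CTermClass.OTHER_ANNOTATED
    return CTermClass.UNANNOTATED


def enclosing_cytoplasmic_domain(
    record: ProteinRecord, start: int, end: int
) -> TopoFeature | None:
    """The cytoplasmic TOPO_DOM fully containing [start, end], or None.

    A match straddling a transmembrane boundary is contained by no single
    domain and returns None.
    """
    for f in record.features_of(FeatureKind.TOPO_DOM):
        if _is_cytoplasmic(f.note) and f.contains(start, end):
            return f
    return None


def membrane_distance(record: ProteinRecord, start: int, end: int) -> MembraneDistance:
    """Strict-gap distance from [start, end] to the nearest membrane segment.

    Let U be the end of the nearest TRANSMEM/INTRAMEM segment ending
    before ``start`` and D the start of the nearest segment starting
    after ``end``; the distance is min(start − U − 1, D − end − 1) over
    the defined flanks.  An interval overlapping a membrane segment has
    distance 0; a record whose membrane segments flank the interval on
    neither side gets UNDEFINED.
    """
    gaps: list[int] = []
    overlap = False
    for f in record.features_of(*MEMBRANE_KINDS):
        if f.start <= end and start <= f.end:
            overlap = True
        elif f.end < start:
            gaps.append(start - f.end - 1)
        else:  # f.start > end
            gaps.append(f.start - end - 1)
    if overlap:
        return MembraneDistance(residues=0)
    if not gaps:
        return UNDEFINED_DISTANCE
    return MembraneDistance(residues=min(gaps))
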