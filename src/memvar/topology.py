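"""Topological domain assignment and the membrane-proximal window.

Curated topology features (signal peptide / extracellular / transmembrane /
cytoplasmic) partition a protein; positions covered by no feature are
"unannotated" rather than inferred.  The membrane-proximal (juxtamembrane)
window is, for each transmembrane span, the first ``width`` residues of the
abutting cytoplasmic feature — on the C-terminal side for type I
orientation, on the N-terminal side for type II — and is what qualifies a
phosphotyrosine motif as membrane-proximal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consequence import CoordinateMap
from .reference_store import ProteinRecord, TopologyFeature

UNANNOTATED = "unannotated"


class PositionBoundsError(ValueError):
    """Protein position outside 1..len(sequence)."""


def domain_at(record: ProteinRecord, pos: int) -> str:
    """Kind of the feature covering ``pos``, else "unannotated"."""
    if not 1 <= pos <= len(record.sequence):
        raise PositionBoundsError(
            f"{record.protein_id}: position {pos} outside 1-{len(record.sequence)}"
        )
    for feature in record.topology:
        if pos in feature:
            return feature.kind
    return UNANNOTATED


@dataclass(frozen=True)
class ProximalWindow:
    """Union of juxtamembrane cytoplasmic intervals (1-based inclusive)."""

    intervals: tuple[tuple[int, int], ...]
    width: int

    def __contains__(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)


def proximal_window(record: ProteinRecord, width: int = 80) -> ProximalWindow:
    """Juxtamembrane window: ``width`` residues of cytoplasm abutting each TM.

    A cytoplasmic feature starting right after a TM end contributes its
    first ``width`` residues (type I side); one ending right before a TM
    start contributes its last ``width`` residues (type II side).  Intervals
    are clipped to their cytoplasmic feature; TMs with no abutting
    cytoplasmic feature contribute nothing.
    """
    if width < 0:
        raise ValueError("width must be non-negative")
    intervals: list[tuple[int, int]] = []
    if width > 0:
        cyto = [f for f in record.topology if f.kind == "cytoplasmic"]
        for tm in record.transmembrane_features:
            for c in cyto:
                if c.start == tm.end + 1:
                    intervals.append((c.start, min(c.start + width - 1, c.end)))
                if c.end == tm.start - 1:
                    intervals.append((max(c.end - width + 1, c.start), c.end))
    return ProximalWindow(tuple(sorted(set(intervals))), width)


def carry_topology(
    record: ProteinRecord, cmap: CoordinateMap, mutant_sequence: str
) -> tuple[TopologyFeature, ...]:
    """Project topology features onto a mutant protein through ``cmap``.

    Each feature keeps the mapped extent of its surviving positions;
    features wholly lost to truncation are dropped.  Novel sequence (e.g. a
    frameshift tail) has no feature and is therefore unannotated.
    """
    n = len(mutant_sequence)
    out = []
    for f in record.topology:
        mapped = [m for p in range(f.start, f.end + 1) if (m := cmap(p)) is not None]
        mapped = [m for m in mapped if 1 <= m <= n]
        if mapped:
            out.append(TopologyFeature(f.kind, min(mapped), max(mapped)))
    return tuple(out)
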