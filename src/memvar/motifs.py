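"""Phosphotyrosine signalling-motif scanning and wild-type/mutant diffing.

The three tyrosine-based sequence motif (TBSM) classes scanned by default:

* ITAM  — Y-x-x-[I/L] - gap(6..12) - Y-x-x-[I/L]; the tandem motif docking
  Syk-family tandem-SH2 kinases.  The gap counts residues strictly between
  the fourth residue of the first half and the tyrosine of the second half;
  every admissible gap length yields a distinct hit.
* ITIM  — [S/I/V/L]-x-Y-x-x-[I/V/L]; recruits SH2 phosphatases.
* YXXQ  — Y-x-x-Q; the STAT3-recruiting docking site.

'x' means any of the 20 standard residues; 'X' (unknown) and non-standard
letters match no constraint, so motifs never match through an 'X'.
Patterns are data ([MotifPattern]) and may be loaded from a YAML config, so
gap bounds and residue sets are adjustable without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import yaml

from .consequence import CoordinateMap
from .reference_store import ProteinRecord
from .topology import ProximalWindow, proximal_window

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

CREATED = "created"
DELETED = "deleted"
RETAINED = "retained"


class MotifSpecError(ValueError):
    """Malformed motif pattern specification."""


@dataclass(frozen=True)
class Gap:
    """A bounded run of any-standard residues (lo..hi, inclusive)."""

    lo: int
    hi: int


@dataclass(frozen=True)
class MotifPattern:
    """Ordered positional constraints: residue sets and bounded gaps."""

    motif_class: str
    elements: tuple  # frozenset[str] | Gap


def _res(s: str) -> frozenset:
    return frozenset(s)


ANY = frozenset(STANDARD_AA)

ITAM = MotifPattern(
    "ITAM",
    (_res("Y"), ANY, ANY, _res("IL"), Gap(6, 12), _res("Y"), ANY, ANY, _res("IL")),
)
ITIM = MotifPattern(
    "ITIM",
    (_res("SIVL"), ANY, _res("Y"), ANY, ANY, _res("IVL")),
)
YXXQ = MotifPattern("YXXQ", (_res("Y"), ANY, ANY, _res("Q")))

DEFAULT_PATTERNS: tuple[MotifPattern, ...] = (ITAM, ITIM, YXXQ)


def itam_pattern(gap_lo: int = 6, gap_hi: int = 12) -> MotifPattern:
    """The tandem ITAM consensus with configurable spacer bounds."""
    return MotifPattern(
        "ITAM",
        (_res("Y"), ANY, ANY, _res("IL"), Gap(gap_lo, gap_hi),
         _res("Y"), ANY, ANY, _res("IL")),
    )


@dataclass(frozen=True)
class MotifHit:
    motif_class: str
    start: int  # 1-based inclusive
    end: int
    matched: str
    tyrosines: tuple[int, ...]  # positions of the pattern's Y residues
    membrane_proximal: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class MotifChange:
    motif_class: str
    status: str  # created | deleted | retained
    wt_hit: MotifHit | None = None
    mut_hit: MotifHit | None = None

    @property
    def hit(self) -> MotifHit:
        """The representative hit: wild-type if present, else mutant."""
        return self.wt_hit if self.wt_hit is not None else self.mut_hit

    @property
    def membrane_proximal(self) -> bool:
        return self.hit.membrane_proximal


class CompiledPattern:
    """Exhaustive matcher enumerating every (start, end) satisfying a spec."""

    def __init__(self, spec: MotifPattern):
        if not spec.elements:
            raise MotifSpecError(f"{spec.motif_class}: empty element list")
        for el in spec.elements:
            if isinstance(el, Gap):
                if not (0 <= el.lo <= el.hi):
                    raise MotifSpecError(
                        f"{spec.motif_class}: invalid gap bounds ({el.lo},{el.hi})"
                    )
            elif isinstance(el, frozenset):
                if not el or not el <= STANDARD_AA:
                    raise MotifSpecError(
                        f"{spec.motif_class}: residue set {sorted(el)} not within "
                        "the 20 standard residues"
                    )
            else:
                raise MotifSpecError(f"{spec.motif_class}: bad element {el!r}")
        self.spec = spec
        self.motif_class = spec.motif_class

    def finditer(self, protein: str) -> Iterable[MotifHit]:
        """All matches, overlapping included, each gap length distinct."""
        seq = protein
        n = len(seq)
        elements = self.spec.elements

        def extend(pos: int, idx: int, ys: tuple[int, ...], start: int):
            if idx == len(elements):
                yield MotifHit(
                    self.motif_class,
                    start + 1,
                    pos,
                    seq[start:pos],
                    ys,
                )
                return
            el = elements[idx]
            if isinstance(el, Gap):
                for g in range(el.lo, el.hi + 1):
                    if pos + g > n:
                        break
                    if all(seq[pos + k] in STANDARD_AA for k in range(g)):
                        yield from extend(pos + g, idx + 1, ys, start)
            else:
                if pos < n and seq[pos] in el:
                    new_ys = ys + (pos + 1,) if el == frozenset("Y") else ys
                    yield from extend(pos + 1, idx + 1, new_ys, start)

        for start in range(n):
            yield from extend(start, 0, (), start)


def compile_pattern(spec: MotifPattern) -> CompiledPattern:
    return CompiledPattern(spec)


def scan_motifs(
    protein: str,
    patterns: Sequence[MotifPattern] | None = None,
    record: ProteinRecord | None = None,
    width: int = 80,
    window: ProximalWindow | None = None,
) -> list[MotifHit]:
    """Scan a protein for all TBSM hits, overlapping matches included.

    When a ``record`` (or explicit ``window``) is supplied, each hit's
    ``membrane_proximal`` flag is set iff its first tyrosine lies inside the
    juxtamembrane window of width ``width``.  Hits are ordered by
    (start, motif_class, end).
    """
    protein = protein.upper()
    if patterns is None:
        patterns = DEFAULT_PATTERNS
    if window is None and record is not None and record.transmembrane_features:
        window = proximal_window(record, width)
    hits: list[MotifHit] = []
    for spec in patterns:
        compiled = compile_pattern(spec)
        for hit in compiled.finditer(protein):
            if window is not None and hit.tyrosines:
                proximal = hit.tyrosines[0] in window
                if proximal:
                    hit = MotifHit(hit.motif_class, hit.start, hit.end,
                                   hit.matched, hit.tyrosines, True)
            hits.append(hit)
    hits.sort(key=lambda h: (h.start, h.motif_class, h.end))
    return hits


def diff_motifs(
    wt_hits: Sequence[MotifHit],
    mut_hits: Sequence[MotifHit],
    cmap: CoordinateMap,
) -> list[MotifChange]:
    """Classify each motif as retained, deleted, or created across an edit.

    A wild-type hit whose every position survives the coordinate map and
    whose mapped span carries a same-class mutant hit is retained (the two
    are paired); otherwise it is deleted.  Mutant hits paired to no
    wild-type hit are created.  By construction
    |retained| + |deleted| == |wt_hits| and
    |retained| + |created| == |mut_hits|.
    """
    changes: list[MotifChange] = []
    unpaired = {id(h): h for h in mut_hits}
    by_span = {(h.motif_class, h.start, h.end): id(h) for h in mut_hits}
    for wt in wt_hits:
        mapped = cmap.map_span(wt.start, wt.end)
        partner_id = by_span.get((wt.motif_class, *mapped)) if mapped else None
        if partner_id is not None and partner_id in unpaired:
            changes.append(
                MotifChange(wt.motif_class, RETAINED, wt, unpaired.pop(partner_id))
            )
        else:
            changes.append(MotifChange(wt.motif_class, DELETED, wt, None))
    for mut in unpaired.values():
        changes.append(MotifChange(mut.motif_class, CREATED, None, mut))
    changes.sort(key=lambda c: (c.hit.start, c.motif_class, c.hit.end, c.status))
    return changes


# ---------------------------------------------------------------------------
# YAML pattern config
# ---------------------------------------------------------------------------
#
# motifs:
#   - class: ITAM
#     elements: [Y, x, x, IL, "gap(6,12)", Y, x, x, IL]

def _parse_element(token: str):
    token = str(token).strip()
    if token == "x":
        return ANY
    if token.startswith("gap(") and token.endswith(")"):
        try:
            lo, hi = (int(t) for t in token[4:-1].split(","))
        except ValueError as exc:
            raise MotifSpecError(f"malformed gap element {token!r}") from exc
        return Gap(lo, hi)
    residues = frozenset(token.upper())
    if not residues:
        raise MotifSpecError("empty residue set element")
    return residues


def load_motif_config(path) -> list[MotifPattern]:
    """Load motif patterns from a YAML file (see module docstring format)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "motifs" not in doc:
        raise MotifSpecError(f"{path}: expected a top-level 'motifs' list")
    patterns = []
    for entry in doc["motifs"]:
        try:
            cls = entry["class"]
            elements = tuple(_parse_element(t) for t in entry["elements"])
        except (KeyError, TypeError) as exc:
            raise MotifSpecError(f"{path}: malformed motif entry {entry!r}") from exc
        pattern = MotifPattern(str(cls), elements)
        compile_pattern(pattern)  # validate eagerly
        patterns.append(pattern)
    return patterns


def dump_motif_config(patterns: Sequence[MotifPattern], path) -> None:
    """Write patterns to the YAML config format read by load_motif_config."""
    def fmt(el):
        if isinstance(el, Gap):
            return f"gap({el.lo},{el.hi})"
        if el == ANY:
            return "x"
        return "".join(sorted(el))

    doc = {
        "motifs": [
            {"class": p.motif_class, "elements": [fmt(e) for e in p.elements]}
            for p in patterns
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
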