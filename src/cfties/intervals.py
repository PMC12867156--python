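"""Genomic interval engine and BED I/O.

All coordinates are BED-convention 0-based half-open.  A shared 1-bp boundary
(``a.end == b.start``) is *not* an overlap: two intervals overlap iff they
share at least one base pair.  Merging, by contrast, follows the union of
covered bases on the integer line, so book-ended intervals coalesce (the
bedtools-merge default).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .errors import BedParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "SiteSet",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "overlap_intersect",
    "subtract_overlapping",
    "extend_and_merge",
    "resize_centered",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    Orders by ``(chrom, start, end)``; ``name`` and ``score`` do not take part
    in comparison or equality.
    """

    chrom: str
    start: int
    end: int
    name: str = field(default="", compare=False)
    score: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of the interval centre (deterministic for even widths)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class SiteSet:
    """An ordered, deduplicated collection of :class:`GenomicInterval`.

    Sites are sorted by ``(chrom, start, end)``; exact duplicate
    ``(chrom, start, end)`` triples are dropped at construction.  ``mark``
    records the assay the sites refer to (e.g. ``H3K4me3``, ``H3K27ac``,
    ``TFBS``, ``DHS``) and ``label`` their provenance (e.g. ``tRCC-up``).
    """

    def __init__(
        self,
        sites: Iterable[GenomicInterval] = (),
        mark: Optional[str] = None,
        label: str = "",
    ) -> None:
        uniq = {}
        for iv in sites:
            uniq[(iv.chrom, iv.start, iv.end)] = iv
        self.sites: List[GenomicInterval] = sorted(uniq.values())
        self.mark = mark
        self.label = label
        self._index: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.sites)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.sites[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteSet):
            return NotImplemented
        return self.sites == other.sites

    def __repr__(self) -> str:
        return (
            f"SiteSet(n={len(self)}, mark={self.mark!r}, label={self.label!r})"
        )

    def total_bp(self) -> int:
        return sum(iv.width for iv in self.sites)

    def replace(self, sites: Iterable[GenomicInterval]) -> "SiteSet":
        """A new SiteSet with the same mark/label but different members."""
        return SiteSet(sites, mark=self.mark, label=self.label)

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends)`` arrays, sorted by start (cached)."""
        if self._index is None:
            idx: Dict[str, Tuple[List[int], List[int]]] = {}
            for iv in self.sites:
                s, e = idx.setdefault(iv.chrom, ([], []))
                s.append(iv.start)
                e.append(iv.end)
            self._index = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in idx.items()
            }
        return self._index


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path, mark: Optional[str] = None, label: str = "") -> SiteSet:
    """Read a BED3/BED6 file into a sorted :class:`SiteSet`.

    Lines starting with ``track``, ``browser`` or ``#`` and blank lines are
    skipped; columns beyond the sixth are ignored.  Malformed coordinates
    raise :class:`BedParseError` naming the line number.
    """
    sites: List[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if not (0 <= start < end):
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            score = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            sites.append(GenomicInterval(chrom, start, end, name, score))
    return SiteSet(sites, mark=mark, label=label)


def write_bed(sites: SiteSet, path) -> None:
    """Write a SiteSet as BED (3 cols, plus name/score when present)."""
    with _open_text(path, "wt") as fh:
        for iv in sites:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name or iv.score is not None:
                cols.append(iv.name or ".")
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a two-column ``name<TAB>length`` chromosome-sizes file."""
    sizes: Dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer length"
                ) from exc
    return sizes


# ---------------------------------------------------------------------------
# Set operations
# ---------------------------------------------------------------------------

def _overlap_mask(a: SiteSet, b: SiteSet) -> np.ndarray:
    """Boolean mask over ``a.sites``: True where the member overlaps b >=1 bp.

    Per chromosome, b's intervals are sorted by start; an interval [s, e)
    overlaps some member of b iff among the b-intervals with start < e the
    running maximum of ends exceeds s.
    """
    mask = np.zeros(len(a), dtype=bool)
    b_idx = b.by_chrom()
    cummax: Dict[str, np.ndarray] = {
        c: np.maximum.accumulate(ends) for c, (starts, ends) in b_idx.items()
    }
    for i, iv in enumerate(a.sites):
        entry = b_idx.get(iv.chrom)
        if entry is None:
            continue
        starts, _ = entry
        k = int(np.searchsorted(starts, iv.end, side="left"))
        if k > 0 and cummax[iv.chrom][k - 1] > iv.start:
            mask[i] = True
    return mask


def overlap_intersect(a: SiteSet, b: SiteSet) -> SiteSet:
    """Members of ``a`` sharing >=1 bp with any member of ``b``.

    An asymmetric filter: output coordinates are ``a``'s, unmodified.
    """
    mask = _overlap_mask(a, b)
    return a.replace(iv for iv, m in zip(a.sites, mask) if m)


def subtract_overlapping(a: SiteSet, b: SiteSet) -> SiteSet:
    """Members of ``a`` with no >=1-bp overlap in ``b``."""
    mask = _overlap_mask(a, b)
    return a.replace(iv for iv, m in zip(a.sites, mask) if not m)


def extend_and_merge(points: SiteSet, flank: int) -> SiteSet:
    """Widen each interval by ``flank`` bp on both sides (floored at 0) and
    merge into maximal disjoint intervals.

    Merging follows the union of covered bases: overlapping *and* book-ended
    widened intervals coalesce.
    """
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    widened = sorted(
        (iv.chrom, max(0, iv.start - flank), iv.end + flank) for iv in points
    )
    merged: List[GenomicInterval] = []
    cur = None
    for chrom, s, e in widened:
        if cur is not None and chrom == cur[0] and s <= cur[2]:
            cur = (chrom, cur[1], max(cur[2], e))
        else:
            if cur is not None:
                merged.append(GenomicInterval(*cur))
            cur = (chrom, s, e)
    if cur is not None:
        merged.append(GenomicInterval(*cur))
    return points.replace(merged)


def resize_centered(
    sites: SiteSet,
    width: int,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> SiteSet:
    """Replace each interval by ``[c - width//2, c - width//2 + width)`` where
    ``c`` is the floor midpoint; clipped at chromosome start 0 (and at the
    chromosome end when ``chrom_sizes`` is given)."""
    if width <= 0:
        raise ValidationError("width must be > 0")
    half = width // 2
    out: List[GenomicInterval] = []
    for iv in sites:
        c = iv.midpoint
        start = c - half
        end = start + width
        if start < 0:
            start = 0
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        out.append(GenomicInterval(iv.chrom, start, end, iv.name, iv.score))
    return sites.replace(out)
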