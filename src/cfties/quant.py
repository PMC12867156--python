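"""Plasma cf-ChIP signal quantification over a site set.

A plasma sample enters as a set of sequenced cfDNA fragments (BED-like
chrom/start/end records).  Quantification proceeds in four steps:

1. fragments are collapsed to their 1-bp midpoints, so each fragment can be
   counted at most once per site window;
2. every site is re-centred to a fixed window (default 3 kb) and split into
   fixed-width bins (default 40 bp); midpoint counts are aggregated across
   all sites into a single per-bin profile;
3. "shoulder" normalisation estimates the flat background from the outermost
   bins of the window and sums the background-subtracted central bins
   (negative bins floored at 0);
4. the central signal is divided by the same quantity computed over a
   housekeeping (DNase-hypersensitive) reference set, yielding a
   depth-invariant signal.

The shoulder geometry defaults to the outermost 20% of bins on each side and
a central region of the middle third of the window (+/-500 bp of a 3-kb
window); both are configurable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np

from .errors import BedParseError, UnquantifiableSampleError, ValidationError
from .intervals import GenomicInterval, SiteSet, resize_centered

__all__ = [
    "FragmentSet",
    "Midpoints",
    "AggregateProfile",
    "QuantConfig",
    "midpoints",
    "profile",
    "shoulder_normalize",
    "dhs_reference",
    "site_signal",
]


class FragmentSet:
    """Sequenced cfDNA fragments of one sample/assay, stored per chromosome
    as parallel ``(starts, ends)`` int64 arrays sorted by start."""

    def __init__(
        self,
        sample_id: str,
        mark: str,
        by_chrom: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    ) -> None:
        self.sample_id = sample_id
        self.mark = mark
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends) in by_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if starts.shape != ends.shape:
                raise ValidationError("starts/ends length mismatch")
            if starts.size == 0:
                continue
            if np.any(ends <= starts):
                raise ValidationError("fragment length must be > 0")
            order = np.lexsort((ends, starts))
            self._by_chrom[chrom] = (starts[order], ends[order])

    @property
    def n_fragments(self) -> int:
        return sum(s.size for s, _ in self._by_chrom.values())

    def __len__(self) -> int:
        return self.n_fragments

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        return self._by_chrom[chrom]

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            starts, ends = self._by_chrom[chrom]
            for s, e in zip(starts, ends):
                yield GenomicInterval(chrom, int(s), int(e))

    @classmethod
    def from_intervals(
        cls, sample_id: str, mark: str, fragments: Iterable[GenomicInterval]
    ) -> "FragmentSet":
        acc: Dict[str, Tuple[List[int], List[int]]] = {}
        for iv in fragments:
            s, e = acc.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        return cls(sample_id, mark, {c: (np.array(s), np.array(e)) for c, (s, e) in acc.items()})

    @classmethod
    def from_bed(cls, path, sample_id: str, mark: str) -> "FragmentSet":
        opener = gzip.open if str(path).endswith(".gz") else open
        acc: Dict[str, Tuple[List[int], List[int]]] = {}
        with opener(str(path), "rt") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise BedParseError(
                        f"{path}: line {lineno}: expected >=3 columns"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}: line {lineno}: non-integer coordinate"
                    ) from exc
                if end <= start or start < 0:
                    raise BedParseError(
                        f"{path}: line {lineno}: invalid fragment {start}-{end}"
                    )
                s, e = acc.setdefault(fields[0], ([], []))
                s.append(start)
                e.append(end)
        return cls(sample_id, mark, {c: (np.array(s), np.array(e)) for c, (s, e) in acc.items()})

    def to_bed(self, path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(str(path), "wt") as fh:
            for chrom in self.chroms:
                starts, ends = self._by_chrom[chrom]
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def subsample(self, n: int, rng: np.random.Generator) -> "FragmentSet":
        """Draw ``n`` fragments without replacement (deterministic given rng)."""
        total = self.n_fragments
        if n > total:
            raise ValidationError(f"cannot draw {n} of {total} fragments")
        pick = np.sort(rng.choice(total, size=n, replace=False))
        out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        offset = 0
        for chrom in self.chroms:
            starts, ends = self._by_chrom[chrom]
            lo = np.searchsorted(pick, offset, side="left")
            hi = np.searchsorted(pick, offset + starts.size, side="left")
            local = pick[lo:hi] - offset
            if local.size:
                out[chrom] = (starts[local], ends[local])
            offset += starts.size
        return FragmentSet(self.sample_id, self.mark, out)

    @classmethod
    def concat(
        cls, parts: Iterable["FragmentSet"], sample_id: str, mark: Optional[str] = None
    ) -> "FragmentSet":
        acc: Dict[str, Tuple[List[np.ndarray], List[np.ndarray]]] = {}
        mk = mark
        for fs in parts:
            mk = mk or fs.mark
            for chrom in fs.chroms:
                starts, ends = fs.arrays(chrom)
                s, e = acc.setdefault(chrom, ([], []))
                s.append(starts)
                e.append(ends)
        merged = {
            c: (np.concatenate(s), np.concatenate(e)) for c, (s, e) in acc.items()
        }
        return cls(sample_id, mk or "", merged)


class Midpoints:
    """Per-chromosome sorted fragment-midpoint positions (1-bp points)."""

    def __init__(self, by_chrom: Mapping[str, np.ndarray]) -> None:
        self._by_chrom = {
            c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()
        }

    @property
    def n_points(self) -> int:
        return sum(p.size for p in self._by_chrom.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self._by_chrom.get(chrom, np.empty(0, dtype=np.int64))

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def to_site_set(self, label: str = "midpoints") -> SiteSet:
        return SiteSet(
            (
                GenomicInterval(c, int(p), int(p) + 1)
                for c in self.chroms
                for p in self._by_chrom[c]
            ),
            label=label,
        )


def midpoints(f: FragmentSet) -> Midpoints:
    """Collapse each fragment to the 1-bp point at its floor midpoint, so a
    fragment can be counted at only one position."""
    return Midpoints(
        {c: (f.arrays(c)[0] + f.arrays(c)[1]) // 2 for c in f.chroms}
    )


@dataclass
class QuantConfig:
    """Geometry of the aggregate-profile quantification.

    window: width (bp) every site is re-centred to before binning.
    bin_width: bin size (bp); window must be divisible by it.
    shoulder_frac: fraction of bins on *each* side used as background.
    central_frac: central fraction of bins summed as signal.
    """

    window: int = 3000
    bin_width: int = 40
    shoulder_frac: float = 0.2
    central_frac: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.window % self.bin_width != 0:
            raise ValidationError("window must be divisible by bin_width")
        n = self.window // self.bin_width
        n_sh = int(round(n * self.shoulder_frac))
        n_c = int(round(n * self.central_frac))
        if n_sh < 1 or n_c < 1:
            raise ValidationError("shoulder and central regions need >=1 bin")
        if 2 * n_sh + n_c > n:
            raise ValidationError("shoulder and central bins must be disjoint")

    @property
    def n_bins(self) -> int:
        return self.window // self.bin_width

    @property
    def n_shoulder_bins(self) -> int:
        return int(round(self.n_bins * self.shoulder_frac))

    def central_slice(self) -> slice:
        n_c = int(round(self.n_bins * self.central_frac))
        start = (self.n_bins - n_c) // 2
        return slice(start, start + n_c)


@dataclass
class AggregateProfile:
    """Summed midpoint counts per bin across all (re-centred) sites."""

    site_set_label: str
    bin_width: int
    window: int
    bin_counts: np.ndarray
    shoulder_level: Optional[float] = None
    central_signal: Optional[float] = None
    normalized_signal: Optional[float] = None

    @property
    def n_bins(self) -> int:
        return self.window // self.bin_width


def profile(
    sites: SiteSet,
    pts: Midpoints,
    window: int = 3000,
    bin_width: int = 40,
) -> AggregateProfile:
    """Aggregate midpoint counts over all sites, each re-centred to
    ``window`` bp and binned at ``bin_width`` bp.

    A midpoint at position ``pos`` inside a re-centred site starting at ``s``
    falls in bin ``(pos - s) // bin_width``.  A midpoint inside several
    (overlapping) re-centred windows counts once per window.
    """
    if len(sites) == 0:
        raise ValidationError("sites must be nonempty")
    if window % bin_width != 0:
        raise ValidationError("window must be divisible by bin_width")
    n_bins = window // bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    # resize per raw site (not via SiteSet, which would deduplicate windows)
    for iv in sites:
        c = iv.midpoint
        rstart = max(0, c - window // 2)
        pos = pts.positions(iv.chrom)
        lo = int(np.searchsorted(pos, rstart, side="left"))
        hi = int(np.searchsorted(pos, rstart + window, side="left"))
        if hi > lo:
            bins = (pos[lo:hi] - rstart) // bin_width
            np.add.at(counts, bins, 1)
    return AggregateProfile(
        site_set_label=sites.label,
        bin_width=bin_width,
        window=window,
        bin_counts=counts,
    )


def shoulder_normalize(
    p: AggregateProfile,
    shoulder_frac: float = 0.2,
    central_frac: float = 1.0 / 3.0,
) -> AggregateProfile:
    """Background-correct an aggregate profile using its shoulders.

    The shoulder level is the mean bin count over the outermost
    ``shoulder_frac`` of bins on each side; the central signal sums
    ``max(bin - shoulder_level, 0)`` over the central ``central_frac`` of
    bins.  An additive flat background therefore cancels exactly.
    """
    cfg = QuantConfig(
        window=p.window,
        bin_width=p.bin_width,
        shoulder_frac=shoulder_frac,
        central_frac=central_frac,
    )
    counts = np.asarray(p.bin_counts, dtype=float)
    n_sh = cfg.n_shoulder_bins
    shoulder = np.concatenate([counts[:n_sh], counts[len(counts) - n_sh :]])
    level = float(shoulder.mean())
    central = counts[cfg.central_slice()]
    signal = float(np.maximum(central - level, 0.0).sum())
    return replace(p, shoulder_level=level, central_signal=signal)


def _central_signal(pts: Midpoints, sites: SiteSet, cfg: QuantConfig) -> float:
    prof = profile(sites, pts, window=cfg.window, bin_width=cfg.bin_width)
    normed = shoulder_normalize(
        prof, shoulder_frac=cfg.shoulder_frac, central_frac=cfg.central_frac
    )
    return float(normed.central_signal)


def _as_midpoints(sample) -> Midpoints:
    if isinstance(sample, Midpoints):
        return sample
    return midpoints(sample)


def dhs_reference(
    sample, dhs_sites: SiteSet, cfg: Optional[QuantConfig] = None
) -> float:
    """Shoulder-normalised central signal over the housekeeping (DHS)
    reference set.  Must be positive; otherwise the sample cannot be
    depth-normalised and :class:`UnquantifiableSampleError` is raised."""
    cfg = cfg or QuantConfig()
    if len(dhs_sites) == 0:
        raise ValidationError("dhs_sites must be nonempty")
    pts = _as_midpoints(sample)
    if pts.n_points == 0:
        raise UnquantifiableSampleError("sample has no fragments")
    ref = _central_signal(pts, dhs_sites, cfg)
    if ref <= 0:
        raise UnquantifiableSampleError(
            "housekeeping reference signal is not positive"
        )
    return ref


def site_signal(
    sample,
    sites: SiteSet,
    dhs_sites: SiteSet,
    cfg: Optional[QuantConfig] = None,
) -> float:
    """Depth-invariant signal of a sample over ``sites``: the
    shoulder-normalised central signal divided by the DHS reference signal.
    ``sample`` may be a :class:`FragmentSet` or precomputed
    :class:`Midpoints`."""
    cfg = cfg or QuantConfig()
    pts = _as_midpoints(sample)
    ref = dhs_reference(pts, dhs_sites, cfg)
    return _central_signal(pts, sites, cfg) / ref
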