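"""Synthetic cell-line and plasma cohorts with the statistical structure the
analysis assumes, so every stage of the pipeline is testable offline.

What is emulated
----------------
* signature site sets (promoter-mark up, enhancer-mark up, fusion TFBS,
  housekeeping DHS, and a rival-subtype "up" set) placed on a toy genome,
  with a configurable fraction of TFBSs overlapping the enhancer-up set to
  exercise the double-counting deduplication;
* negative-binomial per-peak cell-line counts with a group effect at chosen
  peaks, the ground truth for differential-recovery tests;
* plasma fragment sets: each fragment is tumor-derived with probability
  equal to the sample's tumor fraction; tumor-derived fragment midpoints
  enrich the label's signature sites at rate ``enrichment`` relative to a
  uniform genomic background, while all other fragments follow a shared
  housekeeping enrichment at DHS sites or the uniform background; fragment
  lengths are truncated-normal mononucleosomal (167 +/- 20 bp by default);
* longitudinal tumor-fraction trajectories that rise across intervals
  labelled progression and fall across response.

All randomness flows from one master seed through named substreams, so the
same configuration reproduces byte-identical fragment files.
"""

from __future__ import annotations

import datetime as _dt
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError
from .intervals import GenomicInterval, SiteSet, write_bed
from .quant import FragmentSet
from .scoring import MARK_K27, MARK_K4
from .signatures import CountMatrix

__all__ = [
    "CohortConfig",
    "SyntheticSites",
    "PlasmaSample",
    "CohortResult",
    "make_sites",
    "simulate_fusion_peak_sets",
    "simulate_cell_line_counts",
    "simulate_plasma_sample",
    "simulate_cohort",
]


def _substream(seed: int, *names) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    keys = [int(seed)]
    for n in names:
        if isinstance(n, str):
            keys.append(zlib.crc32(n.encode()))
        else:
            keys.append(int(n))
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    enrichment is the rate of tumor-derived fragment midpoints at the
    label's signature sites relative to uniform background (per bp);
    dhs_enrichment plays the same role for the housekeeping signal shared
    by every sample.  Tumor fractions for tRCC/ccRCC samples are drawn
    log-uniformly from ``tf_range``; healthy samples have tumor fraction 0.
    """

    genome: Tuple[Tuple[str, int], ...] = (("chrS", 10_000_000),)
    n_k4_sites: int = 60
    n_k27_sites: int = 80
    n_tfbs_sites: int = 100
    n_dhs_sites: int = 150
    n_ccrcc_sites: int = 60
    tfbs_k27_overlap_frac: float = 0.13
    site_width_range: Tuple[int, int] = (200, 1000)
    site_min_separation: int = 3000
    enrichment: float = 20.0
    dhs_enrichment: float = 30.0
    n_fragments_per_sample: int = 100_000
    tf_range: Tuple[float, float] = (0.005, 0.30)
    fragment_length_mean: float = 167.0
    fragment_length_sd: float = 20.0
    fragment_length_bounds: Tuple[int, int] = (50, 400)
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_k4_sites", "n_k27_sites", "n_tfbs_sites", "n_dhs_sites",
            "n_ccrcc_sites", "n_fragments_per_sample",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 <= self.tfbs_k27_overlap_frac <= 1):
            raise ValidationError("tfbs_k27_overlap_frac must lie in [0, 1]")

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.genome)

    def chrom_sizes(self) -> Dict[str, int]:
        return dict(self.genome)


@dataclass
class SyntheticSites:
    k4_up: SiteSet
    k27_up: SiteSet
    tfbs_raw: SiteSet
    dhs: SiteSet
    ccrcc_up: SiteSet

    def as_dict(self) -> Dict[str, SiteSet]:
        return {
            "k4_up": self.k4_up,
            "k27_up": self.k27_up,
            "tfbs_raw": self.tfbs_raw,
            "dhs": self.dhs,
            "ccrcc_up": self.ccrcc_up,
        }


# ---------------------------------------------------------------------------
# site placement
# ---------------------------------------------------------------------------

_EDGE_MARGIN = 2_000  # keep sites clear of chromosome ends (> window/2)
_MAX_TRIES = 2_000


class _Placer:
    """Rejection-sampling placement of non-overlapping intervals.

    ``margin`` keeps placed intervals at least that many bp apart, so the
    fixed aggregate window around one site sees only flat background from
    the others (the shoulder-normalisation assumption)."""

    def __init__(
        self, cfg: CohortConfig, rng: np.random.Generator, margin: int = 0
    ) -> None:
        self.cfg = cfg
        self.rng = rng
        self.margin = margin
        self.placed: Dict[str, List[Tuple[int, int]]] = {}

    def _collides(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.placed.get(chrom, ()):
            if start < e + self.margin and s - self.margin < end:
                return True
        return False

    def _random_span(self) -> Tuple[str, int, int]:
        lo_w, hi_w = self.cfg.site_width_range
        w = int(self.rng.integers(lo_w, hi_w + 1))
        chroms = self.cfg.genome
        weights = np.array([length for _, length in chroms], dtype=float)
        ci = int(self.rng.choice(len(chroms), p=weights / weights.sum()))
        chrom, length = chroms[ci]
        if length < 2 * _EDGE_MARGIN + w:
            raise PlacementError("chromosome too short for configured sites")
        start = int(self.rng.integers(_EDGE_MARGIN, length - _EDGE_MARGIN - w))
        return chrom, start, start + w

    def place(self, n: int, register: bool = True) -> List[GenomicInterval]:
        out: List[GenomicInterval] = []
        for _ in range(n):
            for _try in range(_MAX_TRIES):
                chrom, s, e = self._random_span()
                if not self._collides(chrom, s, e):
                    if register:
                        self.placed.setdefault(chrom, []).append((s, e))
                    out.append(GenomicInterval(chrom, s, e))
                    break
            else:
                raise PlacementError(
                    "could not place sites without forbidden overlaps; "
                    "increase the genome size or lower the site counts"
                )
        return out

    def place_overlapping(
        self, anchors: Sequence[GenomicInterval], n: int
    ) -> List[GenomicInterval]:
        """Place ``n`` intervals each overlapping (>=1 bp) a distinct anchor."""
        idx = self.rng.choice(len(anchors), size=n, replace=False)
        lo_w, hi_w = self.cfg.site_width_range
        out: List[GenomicInterval] = []
        for i in idx:
            a = anchors[int(i)]
            w = int(self.rng.integers(lo_w, hi_w + 1))
            # any start in [a.start - w + 1, a.end - 1] yields >=1 bp overlap
            start = int(self.rng.integers(a.start - w + 1, a.end))
            start = max(start, 0)
            out.append(GenomicInterval(a.chrom, start, start + w))
            self.placed.setdefault(a.chrom, []).append((start, start + w))
        return out


def make_sites(cfg: CohortConfig) -> SyntheticSites:
    """Place the five site sets on the toy genome.

    All sets are mutually non-overlapping except that exactly
    ``round(tfbs_k27_overlap_frac * n_tfbs_sites)`` TFBSs are placed
    overlapping enhancer-up sites (to exercise deduplication); the DHS set
    is disjoint from every signature set.
    """
    rng = _substream(cfg.seed, "sites")
    placer = _Placer(cfg, rng, margin=cfg.site_min_separation)
    k4 = placer.place(cfg.n_k4_sites)
    k27 = placer.place(cfg.n_k27_sites)
    ccrcc = placer.place(cfg.n_ccrcc_sites)
    dhs = placer.place(cfg.n_dhs_sites)
    n_shared = int(round(cfg.tfbs_k27_overlap_frac * cfg.n_tfbs_sites))
    if n_shared > cfg.n_k27_sites:
        raise ValidationError("more shared TFBSs requested than k27 sites")
    tfbs_shared = placer.place_overlapping(k27, n_shared)
    tfbs_free = placer.place(cfg.n_tfbs_sites - n_shared)
    return SyntheticSites(
        k4_up=SiteSet(k4, mark=MARK_K4, label="tRCC-up"),
        k27_up=SiteSet(k27, mark=MARK_K27, label="tRCC-up"),
        tfbs_raw=SiteSet(tfbs_shared + tfbs_free, mark="TFBS",
                         label="fusion-occupied"),
        dhs=SiteSet(dhs, mark="DHS", label="housekeeping"),
        ccrcc_up=SiteSet(ccrcc, mark=MARK_K27, label="ccRCC-up"),
    )


def simulate_fusion_peak_sets(
    cfg: CohortConfig,
    tfbs_raw: SiteSet,
    n_extra_known: int = 40,
    n_lines: int = 3,
    include_prob: float = 0.9,
    jitter: int = 50,
    n_noise_peaks: int = 20,
) -> Tuple[SiteSet, List[SiteSet]]:
    """Fabricate a known-TFBS catalogue and per-cell-line fusion ChIP peaks.

    The catalogue is the true fusion-occupied set plus ``n_extra_known``
    decoy sites the fusion does not bind; each simulated cell line re-detects
    each true site with probability ``include_prob`` (jittered coordinates)
    and adds private noise peaks.  Intersecting catalogue and peak union
    should therefore recover (almost exactly) the true set.
    """
    rng = _substream(cfg.seed, "fusion-peaks")
    placer = _Placer(cfg, rng)
    for iv in tfbs_raw:
        placer.placed.setdefault(iv.chrom, []).append((iv.start, iv.end))
    extra = placer.place(n_extra_known)
    known = SiteSet(list(tfbs_raw) + extra, mark="TFBS", label="known")

    lines: List[SiteSet] = []
    for li in range(n_lines):
        peaks: List[GenomicInterval] = []
        for iv in tfbs_raw:
            if rng.random() < include_prob:
                ds = int(rng.integers(-jitter, jitter + 1))
                de = int(rng.integers(-jitter, jitter + 1))
                s = max(0, iv.start + ds)
                e = max(s + 50, iv.end + de)
                peaks.append(GenomicInterval(iv.chrom, s, e))
        noise_placer = _Placer(cfg, rng)
        peaks.extend(noise_placer.place(n_noise_peaks, register=False))
        lines.append(SiteSet(peaks, mark="TFE3", label=f"fusion-line-{li + 1}"))
    return known, lines


def make_decoy_peaks(
    cfg: CohortConfig,
    avoid: Sequence[SiteSet],
    n: int,
    mark: Optional[str] = None,
    stream: str = "decoys",
) -> SiteSet:
    """Place ``n`` background peaks avoiding the given site sets (used to
    pad consensus peak sets so differential recovery is nontrivial)."""
    rng = _substream(cfg.seed, stream)
    placer = _Placer(cfg, rng)
    for ss in avoid:
        for iv in ss:
            placer.placed.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return SiteSet(placer.place(n), mark=mark, label="background")


# ---------------------------------------------------------------------------
# cell-line count matrices
# ---------------------------------------------------------------------------

def simulate_cell_line_counts(
    cfg: CohortConfig,
    consensus: SiteSet,
    true_up: SiteSet,
    log2fc_true: float,
    n_per_group: int,
    true_down: Optional[SiteSet] = None,
    baseline_log_mean: float = float(np.log(300.0)),
    baseline_log_sd: float = 0.8,
    stream: str = "cell-line-counts",
) -> CountMatrix:
    """Negative-binomial counts over ``consensus`` with a tRCC-group mean
    multiplied by ``2**log2fc_true`` at ``true_up`` peaks (and divided by it
    at ``true_down`` peaks when given)."""
    up_keys = {(iv.chrom, iv.start, iv.end) for iv in true_up}
    if not up_keys <= {(iv.chrom, iv.start, iv.end) for iv in consensus}:
        raise ValidationError("true_up must be a subset of consensus")
    down_keys = (
        {(iv.chrom, iv.start, iv.end) for iv in true_down} if true_down else set()
    )
    rng = _substream(cfg.seed, stream)
    n_peaks = len(consensus)
    mu0 = rng.lognormal(mean=baseline_log_mean, sigma=baseline_log_sd,
                        size=n_peaks)
    fc = np.ones(n_peaks)
    for i, iv in enumerate(consensus):
        key = (iv.chrom, iv.start, iv.end)
        if key in up_keys:
            fc[i] = 2.0 ** log2fc_true
        elif key in down_keys:
            fc[i] = 2.0 ** (-log2fc_true)

    r = 1.0 / cfg.nb_dispersion

    def _nb(mu: np.ndarray, n_cols: int) -> np.ndarray:
        mu_mat = np.repeat(mu[:, None], n_cols, axis=1)
        p = r / (r + mu_mat)
        return rng.negative_binomial(r, p)

    counts_trcc = _nb(mu0 * fc, n_per_group)
    counts_ccrcc = _nb(mu0, n_per_group)
    samples = [f"TRCC_CL{i + 1}" for i in range(n_per_group)] + [
        f"CCRCC_CL{i + 1}" for i in range(n_per_group)
    ]
    groups = ["tRCC"] * n_per_group + ["ccRCC"] * n_per_group
    return CountMatrix(
        peaks=consensus,
        samples=samples,
        counts=np.hstack([counts_trcc, counts_ccrcc]),
        group=groups,
    )


# ---------------------------------------------------------------------------
# plasma fragments
# ---------------------------------------------------------------------------

def _global_offsets(cfg: CohortConfig) -> Tuple[List[str], np.ndarray]:
    names = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return names, offsets


def _sites_global(cfg: CohortConfig, site_sets: Sequence[SiteSet]) -> Tuple[np.ndarray, np.ndarray]:
    """Global-coordinate (starts, widths) of the union of site sets."""
    names, offsets = _global_offsets(cfg)
    index = {n: offsets[i] for i, n in enumerate(names)}
    starts: List[int] = []
    widths: List[int] = []
    for ss in site_sets:
        for iv in ss:
            starts.append(index[iv.chrom] + iv.start)
            widths.append(iv.width)
    return np.asarray(starts, dtype=np.int64), np.asarray(widths, dtype=np.int64)


def _draw_lengths(cfg: CohortConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.fragment_length_bounds
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd,
                          size=n - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        k = keep.size
        out[filled:filled + k] = np.round(keep).astype(np.int64)
        filled += k
    return out


def _enriched_positions(
    n: int,
    starts: np.ndarray,
    widths: np.ndarray,
    rate: float,
    genome_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Midpoint positions (global coords): with probability proportional to
    ``rate`` per site bp, inside a site (width-weighted, uniform within);
    otherwise uniform over the genome."""
    total_site_bp = int(widths.sum()) if widths.size else 0
    if total_site_bp == 0 or rate <= 0:
        return rng.integers(0, genome_size, size=n)
    p_site = rate * total_site_bp / (
        rate * total_site_bp + (genome_size - total_site_bp)
    )
    at_site = rng.random(n) < p_site
    pos = rng.integers(0, genome_size, size=n)
    k = int(at_site.sum())
    if k:
        site_idx = rng.choice(
            widths.size, size=k, p=widths / widths.sum()
        )
        within = (rng.random(k) * widths[site_idx]).astype(np.int64)
        pos[at_site] = starts[site_idx] + within
    return pos


_TARGETS = {
    ("tRCC", MARK_K4): ("k4_up",),
    ("tRCC", MARK_K27): ("k27_up", "tfbs_raw"),
    ("ccRCC", MARK_K4): ("ccrcc_up",),
    ("ccRCC", MARK_K27): ("ccrcc_up",),
    ("healthy", MARK_K4): (),
    ("healthy", MARK_K27): (),
}


def simulate_plasma_sample(
    cfg: CohortConfig,
    sites: SyntheticSites,
    label: str,
    tf: float,
    mark: str,
    sample_id: str,
    rng: Optional[np.random.Generator] = None,
) -> FragmentSet:
    """One plasma fragment set for ``sample_id`` at the given assay.

    Each fragment is tumor-derived with probability ``tf``; tumor-derived
    midpoints enrich the label's signature sites for this mark at rate
    ``cfg.enrichment``; all other midpoints follow the shared housekeeping
    enrichment at DHS sites (rate ``cfg.dhs_enrichment``) over a uniform
    background.  Deterministic given the generator.
    """
    if not (0 <= tf <= 1):
        raise ValidationError("tumor fraction must lie in [0, 1]")
    if (label, mark) not in _TARGETS:
        raise ValidationError(f"unknown label/mark combination {(label, mark)}")
    rng = rng if rng is not None else _substream(cfg.seed, "plasma", sample_id, mark)
    n = cfg.n_fragments_per_sample
    G = cfg.genome_size
    names, offsets = _global_offsets(cfg)

    tumor = rng.random(n) < tf
    n_t = int(tumor.sum())
    n_b = n - n_t
    mids = np.empty(n, dtype=np.int64)

    target_names = _TARGETS[(label, mark)]
    tstarts, twidths = _sites_global(
        cfg, [getattr(sites, nm) for nm in target_names]
    )
    mids[tumor] = _enriched_positions(
        n_t, tstarts, twidths, cfg.enrichment, G, rng
    )
    dstarts, dwidths = _sites_global(cfg, [sites.dhs])
    mids[~tumor] = _enriched_positions(
        n_b, dstarts, dwidths, cfg.dhs_enrichment, G, rng
    )

    lengths = _draw_lengths(cfg, n, rng)
    ci = np.searchsorted(offsets, mids, side="right") - 1
    local_mid = mids - offsets[ci]
    starts = local_mid - lengths // 2
    chrom_len = np.array([dict(cfg.genome)[names[i]] for i in ci])
    starts = np.clip(starts, 0, chrom_len - lengths)
    ends = starts + lengths

    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for k, name in enumerate(names):
        sel = ci == k
        if sel.any():
            by_chrom[name] = (starts[sel], ends[sel])
    return FragmentSet(sample_id, mark, by_chrom)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class PlasmaSample:
    sample_id: str
    patient_id: str
    label: str
    tumor_fraction: float
    draw_date: str
    status: str
    frags: Dict[str, FragmentSet] = field(default_factory=dict)


@dataclass
class CohortResult:
    cfg: CohortConfig
    sites: SyntheticSites
    samples: List[PlasmaSample]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for mark in sorted(s.frags):
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "patient_id": s.patient_id,
                        "label": s.label,
                        "mark": mark,
                        "tumor_fraction": s.tumor_fraction,
                        "draw_date": s.draw_date,
                        "status": s.status,
                        "fragments": f"fragments/{s.sample_id}_{mark}.bed",
                    }
                )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "fragments").mkdir(parents=True, exist_ok=True)
        (outdir / "sites").mkdir(parents=True, exist_ok=True)
        for name, ss in self.sites.as_dict().items():
            write_bed(ss, outdir / "sites" / f"{name}.bed")
        with open(outdir / "chrom.sizes", "w") as fh:
            for chrom, length in self.cfg.genome:
                fh.write(f"{chrom}\t{length}\n")
        for s in self.samples:
            for mark, fs in s.frags.items():
                fs.to_bed(outdir / "fragments" / f"{s.sample_id}_{mark}.bed")
        self.sample_sheet().to_csv(
            outdir / "sample_sheet.tsv", sep="\t", index=False
        )


def _draw_tf(cfg: CohortConfig, rng: np.random.Generator) -> float:
    lo, hi = cfg.tf_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


_STATUS_FACTORS = {
    "progression": (1.8, 2.8),
    "stable": (0.9, 1.1),
    "response": (0.25, 0.55),
}


def simulate_cohort(
    cfg: CohortConfig,
    n_trcc: int,
    n_ccrcc: int,
    n_healthy: int,
    longitudinal: Optional[Sequence[Sequence[str]]] = None,
    sites: Optional[SyntheticSites] = None,
) -> CohortResult:
    """Simulate a plasma cohort (both marks per sample).

    ``longitudinal`` is an optional list of per-patient clinical interval
    status sequences (values ``progression``/``stable``/``response``); each
    sequence of length k adds one tRCC patient with k+1 ordered draws whose
    tumor fraction rises across progression intervals and falls across
    response intervals.
    """
    if min(n_trcc, n_ccrcc, n_healthy) < 0:
        raise ValidationError("cohort sizes must be >= 0")
    sites = sites or make_sites(cfg)
    samples: List[PlasmaSample] = []
    t0 = _dt.date(2024, 1, 1)

    def _add(sample_id, patient_id, label, tf, date, status):
        s = PlasmaSample(
            sample_id=sample_id,
            patient_id=patient_id,
            label=label,
            tumor_fraction=tf,
            draw_date=date.isoformat(),
            status=status,
        )
        for mark in (MARK_K4, MARK_K27):
            s.frags[mark] = simulate_plasma_sample(
                cfg, sites, label, tf, mark, sample_id
            )
        samples.append(s)

    tf_rng = _substream(cfg.seed, "tumor-fractions")
    for i in range(n_trcc):
        _add(f"TRCC{i + 1:02d}", f"TRCC{i + 1:02d}", "tRCC",
             _draw_tf(cfg, tf_rng), t0, "")
    for i in range(n_ccrcc):
        _add(f"CCRCC{i + 1:02d}", f"CCRCC{i + 1:02d}", "ccRCC",
             _draw_tf(cfg, tf_rng), t0, "")
    for i in range(n_healthy):
        _add(f"HP{i + 1:02d}", f"HP{i + 1:02d}", "healthy", 0.0, t0, "")

    if longitudinal:
        traj_rng = _substream(cfg.seed, "trajectories")
        for pi, statuses in enumerate(longitudinal):
            pid = f"LP{pi + 1:02d}"
            tf = _draw_tf(cfg, traj_rng)
            _add(f"{pid}_d1", pid, "tRCC", tf, t0, "baseline")
            for k, status in enumerate(statuses, start=2):
                if status not in _STATUS_FACTORS:
                    raise ValidationError(f"unknown interval status {status!r}")
                lo, hi = _STATUS_FACTORS[status]
                tf = min(0.5, tf * float(traj_rng.uniform(lo, hi)))
                _add(f"{pid}_d{k}", pid, "tRCC", tf,
                     t0 + _dt.timedelta(days=90 * (k - 1)), status)

    return CohortResult(cfg=cfg, sites=sites, samples=samples)
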