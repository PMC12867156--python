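"""In silico dilution of tumor plasma into healthy plasma to estimate the
limit of detection of the integrated score.

For a tumor/healthy pair the read budget is N = min(|tumor|, |healthy|);
round(N*DL) fragments are drawn without replacement from the tumor sample
and round(N*(1-DL)) from the healthy sample, where the dilution level DL is
the tumor fraction *of reads* in the mixture.  The mixture's expected tumor
fraction is the tumor sample's tumor fraction times DL.  Mixtures are binned
by expected tumor fraction (default 0.4% bins with open terminal bins
<0.4% and >3.2%) and each bin's scores are compared with the undiluted
healthy samples' scores by a two-sided rank-sum test.  The limit of
detection is the lowest-TF bin that is significant with every higher
populated bin also significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .evaluation import group_compare
from .intervals import SiteSet
from .quant import FragmentSet, QuantConfig
from .scoring import MARK_K27, MARK_K4, TiesConfig, score_sample
from .signatures import SignatureBundle

__all__ = [
    "DEFAULT_DILUTION_LEVELS",
    "DilutionSpec",
    "DilutionMixture",
    "TfBin",
    "LodResult",
    "dilute_pair",
    "assign_bin",
    "dilution_experiment",
]

# 11 levels: 0.9 .. 0.1 in steps of 0.1, plus 0.05 and 0.01
DEFAULT_DILUTION_LEVELS: Tuple[float, ...] = (
    0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01,
)


@dataclass
class DilutionSpec:
    dilution_levels: Tuple[float, ...] = DEFAULT_DILUTION_LEVELS
    bin_width_tf: float = 0.004
    tf_min_bin: float = 0.004   # lower open bin: expected TF below this
    tf_max_bin: float = 0.032   # upper open bin: expected TF at/above this
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < dl < 1 for dl in self.dilution_levels):
            raise ValidationError("all dilution levels must lie in (0, 1)")
        if self.bin_width_tf <= 0:
            raise ValidationError("bin_width_tf must be > 0")


@dataclass
class DilutionMixture:
    tumor_id: str
    healthy_id: str
    dl: float
    n_reads: int
    expected_tf: float
    ties: float = float("nan")
    fragments: Optional[Dict[str, FragmentSet]] = None


@dataclass
class TfBin:
    lo: Optional[float]  # None for the open "<min" bin
    hi: Optional[float]  # None for the open ">=max" bin
    n: int = 0
    ties_values: List[float] = field(default_factory=list)
    p_value: Optional[float] = None

    def label(self, as_percent: bool = True) -> str:
        f = 100.0 if as_percent else 1.0
        unit = "%" if as_percent else ""
        if self.lo is None:
            return f"<{self.hi * f:g}{unit}"
        if self.hi is None:
            return f">={self.lo * f:g}{unit}"
        return f"[{self.lo * f:g}{unit}, {self.hi * f:g}{unit})"


@dataclass
class LodResult:
    mixtures: List[DilutionMixture]
    bins: List[TfBin]                 # ordered by increasing TF
    healthy_ties: List[float]
    lod_bin: Optional[TfBin]          # None when no bin qualifies


def _mix_one_mark(
    tumor: FragmentSet,
    healthy: FragmentSet,
    dl: float,
    rng: np.random.Generator,
    sample_id: str,
) -> FragmentSet:
    n = min(tumor.n_fragments, healthy.n_fragments)
    n_t = int(round(n * dl))
    n_h = int(round(n * (1 - dl)))
    assert n_t <= tumor.n_fragments and n_h <= healthy.n_fragments
    part_t = tumor.subsample(n_t, rng)
    part_h = healthy.subsample(n_h, rng)
    return FragmentSet.concat([part_t, part_h], sample_id, mark=tumor.mark)


def dilute_pair(
    tumor_frags: Mapping[str, FragmentSet],
    tumor_tf: float,
    healthy_frags: Mapping[str, FragmentSet],
    dl: float,
    seed: int,
    tumor_id: str = "tumor",
    healthy_id: str = "healthy",
) -> DilutionMixture:
    """Mix one tumor/healthy pair at dilution level ``dl`` (per mark).

    Deterministic given ``seed``.  ``expected_tf = tumor_tf * dl``.
    """
    if not (0 < dl < 1):
        raise ValidationError("dl must lie in (0, 1)")
    if not tumor_frags or not healthy_frags:
        raise ValidationError("both samples need fragments")
    mixed: Dict[str, FragmentSet] = {}
    n_reads = 0
    for k, mark in enumerate(sorted(tumor_frags)):
        if mark not in healthy_frags:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), k])
        )
        fs = _mix_one_mark(
            tumor_frags[mark],
            healthy_frags[mark],
            dl,
            rng,
            sample_id=f"{tumor_id}x{healthy_id}@{dl:g}",
        )
        mixed[mark] = fs
        n_reads += fs.n_fragments
    if not mixed:
        raise ValidationError("no shared marks between tumor and healthy sample")
    return DilutionMixture(
        tumor_id=tumor_id,
        healthy_id=healthy_id,
        dl=dl,
        n_reads=n_reads,
        expected_tf=float(tumor_tf) * float(dl),
        fragments=mixed,
    )


def make_bins(spec: DilutionSpec) -> List[TfBin]:
    bins: List[TfBin] = [TfBin(lo=None, hi=spec.tf_min_bin)]
    edge = spec.tf_min_bin
    while edge < spec.tf_max_bin - 1e-12:
        bins.append(TfBin(lo=edge, hi=edge + spec.bin_width_tf))
        edge += spec.bin_width_tf
    bins.append(TfBin(lo=spec.tf_max_bin, hi=None))
    return bins


def assign_bin(expected_tf: float, spec: DilutionSpec) -> int:
    """Index (into :func:`make_bins` order) of the bin holding ``expected_tf``."""
    if expected_tf < spec.tf_min_bin:
        return 0
    if expected_tf >= spec.tf_max_bin:
        n_inner = int(round((spec.tf_max_bin - spec.tf_min_bin) / spec.bin_width_tf))
        return n_inner + 1
    return 1 + int((expected_tf - spec.tf_min_bin) / spec.bin_width_tf)


def dilution_experiment(
    tumors: Sequence[Tuple[str, float, Mapping[str, FragmentSet]]],
    healthies: Sequence[Tuple[str, Mapping[str, FragmentSet]]],
    spec: DilutionSpec,
    bundle: SignatureBundle,
    dhs: SiteSet,
    quant_cfg: Optional[QuantConfig] = None,
    ties_cfg: Optional[TiesConfig] = None,
    healthy_ties: Optional[Sequence[float]] = None,
) -> LodResult:
    """Run the full dilution grid and per-bin rank-sum comparison.

    ``tumors`` are ``(id, tumor_fraction, {mark: FragmentSet})`` triples
    (callers should already have applied the tumor-fraction inclusion rule);
    ``healthies`` are ``(id, {mark: FragmentSet})``.  Every tumor x healthy
    pair is mixed at every dilution level and scored; each expected-TF bin
    is compared against the undiluted healthy samples' scores (computed here
    unless supplied).
    """
    if not tumors or not healthies:
        raise ValidationError("need nonempty tumor and healthy lists")
    quant_cfg = quant_cfg or QuantConfig()
    ties_cfg = ties_cfg or TiesConfig()

    if healthy_ties is None:
        healthy_ties = [
            score_sample(
                frags, bundle, dhs, quant_cfg, ties_cfg, sample_id=hid
            ).ties
            for hid, frags in healthies
        ]
    healthy_ties = list(healthy_ties)

    mixtures: List[DilutionMixture] = []
    for ti, (tid, tf, tfrags) in enumerate(tumors):
        for hi, (hid, hfrags) in enumerate(healthies):
            for di, dl in enumerate(spec.dilution_levels):
                seed = int(
                    np.random.SeedSequence(
                        [spec.seed, ti, hi, di]
                    ).generate_state(1)[0] % (2**31)
                )
                mix = dilute_pair(
                    tfrags, tf, hfrags, dl, seed, tumor_id=tid, healthy_id=hid
                )
                mix.ties = score_sample(
                    mix.fragments, bundle, dhs, quant_cfg, ties_cfg,
                    sample_id=f"{tid}x{hid}@{dl:g}",
                ).ties
                mix.fragments = None  # drop fragment payload once scored
                mixtures.append(mix)

    bins = make_bins(spec)
    for mix in mixtures:
        b = bins[assign_bin(mix.expected_tf, spec)]
        b.n += 1
        b.ties_values.append(mix.ties)
    for b in bins:
        if b.n > 0:
            _, b.p_value = group_compare(b.ties_values, healthy_ties)

    # lowest-TF populated bin significant with all higher populated bins
    # significant too
    lod_bin: Optional[TfBin] = None
    populated = [b for b in bins if b.n > 0]
    for i, b in enumerate(populated):
        if all(x.p_value is not None and x.p_value < spec.alpha
               for x in populated[i:]):
            lod_bin = b
            break
    return LodResult(
        mixtures=mixtures,
        bins=bins,
        healthy_ties=healthy_ties,
        lod_bin=lod_bin,
    )
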