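import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfties.errors import UnquantifiableSampleError, ValidationError
from cfties.intervals import GenomicInterval
from cfties.quant import (
    AggregateProfile,
    FragmentSet,
    QuantConfig,
    dhs_reference,
    midpoints,
    profile,
    shoulder_normalize,
    site_signal,
)
from cfties.scoring import MARK_K27
from cfties.synthetic import make_sites, simulate_plasma_sample

from conftest import to_siteset
from oracles import naive_profile


def _frags(triplets, sample_id="s", mark="H3K27ac"):
    return FragmentSet.from_intervals(
        sample_id, mark, (GenomicInterval(c, s, e) for c, s, e in triplets)
    )


class TestMidpoints:
    @pytest.mark.parametrize(
        "frag,mid",
        [(("chr1", 100, 300), 200), (("chr1", 100, 101), 100), (("chr1", 0, 3), 1)],
    )
    def test_floor_midpoint(self, frag, mid):
        pts = midpoints(_frags([frag]))
        assert list(pts.positions(frag[0])) == [mid]

    def test_every_midpoint_inside_its_fragment(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 100_000, size=1000)
        lengths = rng.integers(1, 400, size=1000)
        fs = _frags([("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)])
        for iv in fs.intervals():
            assert iv.start <= iv.midpoint < iv.end

    def test_point_count_matches_fragment_count(self):
        fs = _frags([("chr1", 0, 10), ("chr2", 5, 9), ("chr1", 0, 10)])
        assert midpoints(fs).n_points == fs.n_fragments == 3


class TestProfile:
    def test_single_midpoint_bin_index(self):
        sites = to_siteset([("chr1", 0, 3000)])  # center 1500, window 0..3000
        pts = midpoints(_frags([("chr1", 1400, 1600)]))  # midpoint 1500
        p = profile(sites, pts, window=3000, bin_width=40)
        assert p.bin_counts[37] == 1
        assert p.bin_counts.sum() == 1

    def test_no_midpoints_all_zero(self):
        sites = to_siteset([("chr1", 0, 3000)])
        p = profile(sites, midpoints(_frags([("chr2", 0, 100)])), 3000, 40)
        assert p.bin_counts.sum() == 0

    def test_empty_sites_error(self):
        with pytest.raises(ValidationError):
            profile(to_siteset([]), midpoints(_frags([("chr1", 0, 10)])), 3000, 40)

    def test_indivisible_window_error(self):
        with pytest.raises(ValidationError):
            profile(to_siteset([("chr1", 0, 10)]), midpoints(_frags([("chr1", 0, 10)])), 3000, 37)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_site_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        site_t = [
            ("chrT", int(s), int(s + w))
            for s, w in zip(
                rng.integers(2000, 50_000, size=15), rng.integers(100, 900, size=15)
            )
        ]
        mids = sorted(int(x) for x in rng.integers(0, 55_000, size=2000))
        fs = _frags([("chrT", m, m + 1) for m in mids])
        pts = midpoints(fs)
        got = profile(to_siteset(site_t), pts, window=2000, bin_width=40)
        expected = naive_profile(site_t, {"chrT": mids}, 2000, 40)
        np.testing.assert_array_equal(got.bin_counts, expected)
        # totals conserve (midpoint, resized-site) incidences
        assert got.bin_counts.sum() == expected.sum()


class TestShoulderNormalize:
    def _profile(self, counts):
        counts = np.asarray(counts)
        return AggregateProfile("x", 40, 40 * len(counts), counts)

    def test_flat_profile_gives_zero(self):
        p = shoulder_normalize(self._profile(np.full(75, 7.0)))
        assert p.central_signal == 0.0
        assert p.shoulder_level == 7.0

    def test_central_spike_measured_exactly(self):
        counts = np.full(75, 5.0)
        counts[35:40] += 11.0  # 5 central bins, height 11
        p = shoulder_normalize(self._profile(counts))
        assert p.central_signal == pytest.approx(5 * 11.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        base=st.lists(st.integers(0, 50), min_size=75, max_size=75),
        c=st.integers(0, 100),
    )
    def test_additive_background_invariance(self, base, c):
        base = np.asarray(base, dtype=float)
        p0 = shoulder_normalize(self._profile(base))
        p1 = shoulder_normalize(self._profile(base + c))
        assert p1.central_signal == pytest.approx(p0.central_signal)

    def test_shoulder_and_central_must_be_disjoint(self):
        with pytest.raises(ValidationError):
            QuantConfig(shoulder_frac=0.4, central_frac=0.5)


class TestDhsReferenceAndSiteSignal:
    def test_zero_fragment_sample_unquantifiable(self):
        dhs = to_siteset([("chr1", 0, 3000)])
        with pytest.raises(UnquantifiableSampleError):
            dhs_reference(_frags([]), dhs)

    def test_doubling_fragments_doubles_reference(self, small_cfg, small_sites):
        fs = simulate_plasma_sample(
            small_cfg, small_sites, "healthy", 0.0, MARK_K27, "H1"
        )
        ref1 = dhs_reference(fs, small_sites.dhs)
        doubled = FragmentSet.concat([fs, fs], "H1x2", mark=MARK_K27)
        assert dhs_reference(doubled, small_sites.dhs) == pytest.approx(2 * ref1)

    def test_site_signal_depth_invariant(self, small_cfg, small_sites):
        fs = simulate_plasma_sample(
            small_cfg, small_sites, "tRCC", 0.1, MARK_K27, "T1"
        )
        s1 = site_signal(fs, small_sites.k27_up, small_sites.dhs)
        tripled = FragmentSet.concat([fs, fs, fs], "T1x3", mark=MARK_K27)
        s3 = site_signal(tripled, small_sites.k27_up, small_sites.dhs)
        assert s3 == pytest.approx(s1, rel=1e-12)

    def test_no_signal_near_sites_gives_zero(self):
        # strong DHS signal far from the scored sites, nothing at the sites
        dhs = to_siteset([("chr1", 100_000, 100_600)])
        sites = to_siteset([("chr1", 10_000, 10_600)])
        frag_t = [("chr1", 100_250, 100_350)] * 200
        s = site_signal(_frags(frag_t), sites, dhs)
        assert s == 0.0

    def test_monotone_in_enrichment(self, small_cfg, small_sites):
        signals = []
        for lam in (1.0, 5.0, 20.0, 60.0):
            cfg = dataclasses.replace(small_cfg, enrichment=lam)
            fs = simulate_plasma_sample(
                cfg, small_sites, "tRCC", 0.2, MARK_K27, f"L{lam}"
            )
            signals.append(site_signal(fs, small_sites.k27_up, small_sites.dhs))
        assert signals == sorted(signals)

    def test_uniform_background_barely_moves_signal(self, small_cfg, small_sites):
        """Adding genome-wide uniform fragments changes the normalised signal
        only marginally (shoulders absorb the flat component)."""
        fs = simulate_plasma_sample(
            small_cfg, small_sites, "tRCC", 0.2, MARK_K27, "T1"
        )
        s0 = site_signal(fs, small_sites.k27_up, small_sites.dhs)
        rng = np.random.default_rng(1)
        g = small_cfg.genome_size
        extra_pos = rng.integers(0, g - 200, size=small_cfg.n_fragments_per_sample // 10)
        extra = _frags([("chrS", int(p), int(p) + 160) for p in extra_pos])
        s1 = site_signal(
            FragmentSet.concat([fs, extra], "T1+bg", mark=MARK_K27),
            small_sites.k27_up,
            small_sites.dhs,
        )
        assert abs(s1 - s0) / s0 < 0.05
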