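import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest

from cfties.errors import PlacementError, ValidationError
from cfties.evaluation import group_compare
from cfties.intervals import overlap_intersect
from cfties.quant import site_signal
from cfties.scoring import MARK_K27, MARK_K4
from cfties.signatures import assemble_bundle
from cfties.synthetic import (
    CohortConfig,
    make_sites,
    simulate_cell_line_counts,
    simulate_cohort,
    simulate_fusion_peak_sets,
    simulate_plasma_sample,
)

from conftest import triples


class TestMakeSites:
    def test_configured_tfbs_k27_overlap_is_exact(self, small_cfg, small_sites):
        expected = round(
            small_cfg.tfbs_k27_overlap_frac * small_cfg.n_tfbs_sites
        )
        got = len(overlap_intersect(small_sites.tfbs_raw, small_sites.k27_up))
        assert got == expected

    def test_zero_overlap_leaves_bundle_unchanged(self):
        cfg = CohortConfig(seed=2, tfbs_k27_overlap_frac=0.0, n_k4_sites=10,
                           n_k27_sites=10, n_tfbs_sites=10, n_dhs_sites=10,
                           n_ccrcc_sites=10)
        sites = make_sites(cfg)
        bundle = assemble_bundle(sites.k4_up, sites.k27_up, sites.tfbs_raw)
        assert triples(bundle.tfbs) == triples(sites.tfbs_raw)

    def test_dhs_disjoint_from_signature_sets(self, small_sites):
        for other in (small_sites.k4_up, small_sites.k27_up,
                      small_sites.tfbs_raw, small_sites.ccrcc_up):
            assert len(overlap_intersect(small_sites.dhs, other)) == 0

    def test_same_seed_reproduces_sites(self, small_cfg):
        s1 = make_sites(small_cfg)
        s2 = make_sites(small_cfg)
        for name, ss in s1.as_dict().items():
            assert triples(ss) == triples(s2.as_dict()[name])

    def test_impossible_placement_raises(self):
        cfg = CohortConfig(genome=(("tiny", 40_000),), n_k4_sites=50,
                           n_k27_sites=50, n_tfbs_sites=50, n_dhs_sites=50,
                           n_ccrcc_sites=50)
        with pytest.raises(PlacementError):
            make_sites(cfg)


class TestCellLineCounts:
    def test_counts_are_nonnegative_integers(self, small_cfg, small_sites):
        cm = simulate_cell_line_counts(
            small_cfg, small_sites.k27_up,
            small_sites.k27_up.replace(small_sites.k27_up.sites[:5]), 3.0, 4,
        )
        assert cm.counts.dtype.kind in "iu"
        assert (cm.counts >= 0).all()
        assert cm.counts.shape == (len(small_sites.k27_up), 8)

    def test_true_up_must_be_subset(self, small_cfg, small_sites):
        with pytest.raises(ValidationError):
            simulate_cell_line_counts(
                small_cfg, small_sites.k27_up, small_sites.k4_up, 3.0, 4
            )


class TestFusionPeaks:
    def test_recovers_true_fusion_occupied_set(self, small_cfg, small_sites):
        from cfties.signatures import fusion_occupied_tfbs

        known, lines = simulate_fusion_peak_sets(small_cfg, small_sites.tfbs_raw)
        assert len(known) == len(small_sites.tfbs_raw) + 40
        recovered = fusion_occupied_tfbs(known, lines)
        truth = set(triples(small_sites.tfbs_raw))
        got = set(triples(recovered))
        # each true site is missed by all 3 lines with prob 0.1^3
        assert len(got & truth) >= 0.98 * len(truth)


class TestPlasmaSample:
    def test_fragment_length_distribution(self, small_sites):
        cfg = CohortConfig(seed=5, n_fragments_per_sample=100_000)
        fs = simulate_plasma_sample(cfg, small_sites, "healthy", 0.0, MARK_K27, "H")
        lengths = np.concatenate(
            [fs.arrays(c)[1] - fs.arrays(c)[0] for c in fs.chroms]
        )
        assert abs(lengths.mean() - 167.0) < 3.0

    def test_null_construction_indistinguishable(self, small_cfg, small_sites):
        """At tumor fraction 0 the signal at tumor signature sites does not
        separate samples labelled tRCC from healthy ones."""
        sig_t, sig_h = [], []
        for i in range(8):
            t = simulate_plasma_sample(
                small_cfg, small_sites, "tRCC", 0.0, MARK_K27, f"T{i}"
            )
            h = simulate_plasma_sample(
                small_cfg, small_sites, "healthy", 0.0, MARK_K27, f"H{i}"
            )
            sig_t.append(site_signal(t, small_sites.k27_up, small_sites.dhs))
            sig_h.append(site_signal(h, small_sites.k27_up, small_sites.dhs))
        _, p = group_compare(sig_t, sig_h)
        assert p > 0.05

    def test_high_tf_sample_clearly_separates(self, small_cfg, small_sites):
        t = simulate_plasma_sample(
            small_cfg, small_sites, "tRCC", 0.3, MARK_K27, "T"
        )
        sig_t = site_signal(t, small_sites.k27_up, small_sites.dhs)
        healthy = [
            site_signal(
                simulate_plasma_sample(
                    small_cfg, small_sites, "healthy", 0.0, MARK_K27, f"H{i}"
                ),
                small_sites.k27_up,
                small_sites.dhs,
            )
            for i in range(10)
        ]
        assert sig_t > np.quantile(healthy, 0.95)

    def test_ccrcc_enriches_its_own_sites_not_trcc_sites(self, small_cfg, small_sites):
        c = simulate_plasma_sample(
            small_cfg, small_sites, "ccRCC", 0.3, MARK_K27, "C"
        )
        own = site_signal(c, small_sites.ccrcc_up, small_sites.dhs)
        cross = site_signal(c, small_sites.k27_up, small_sites.dhs)
        assert own > 5 * max(cross, 1e-6)


class TestCohort:
    def test_sample_and_file_counts(self, small_cfg, tmp_path):
        cfg = dataclasses.replace(small_cfg, n_fragments_per_sample=2000)
        coh = simulate_cohort(cfg, 10, 5, 5)
        assert len(coh.samples) == 20
        sheet = coh.sample_sheet()
        assert len(sheet) == 40  # one row per (sample, mark)
        coh.write(tmp_path)
        assert len(list((tmp_path / "fragments").glob("*.bed"))) == 40
        assert (tmp_path / "sample_sheet.tsv").exists()

    def test_longitudinal_statuses_shape_tf_trajectory(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, n_fragments_per_sample=1000)
        coh = simulate_cohort(
            cfg, 0, 0, 0, longitudinal=[["response", "progression"]]
        )
        draws = sorted(
            (s for s in coh.samples), key=lambda s: s.draw_date
        )
        tfs = [s.tumor_fraction for s in draws]
        assert len(tfs) == 3
        assert tfs[1] < tfs[0]       # response interval: falling
        assert tfs[2] > tfs[1]       # progression interval: rising

    def test_byte_identical_outputs_for_same_seed(self, small_cfg, tmp_path):
        cfg = dataclasses.replace(small_cfg, n_fragments_per_sample=3000)

        def _digest(d):
            h = hashlib.sha256()
            for p in sorted(Path(d).rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        for sub in ("a", "b"):
            coh = simulate_cohort(cfg, 2, 1, 1)
            coh.write(tmp_path / sub)
        assert _digest(tmp_path / "a") == _digest(tmp_path / "b")

    def test_effect_dose_response(self, small_sites):
        """End-to-end separation grows with enrichment and tumor fraction."""
        from cfties.scoring import roc_auc, score_sample

        aucs = []
        for lam in (2.0, 40.0):
            cfg = CohortConfig(seed=21, enrichment=lam,
                               n_fragments_per_sample=10_000,
                               tf_range=(0.05, 0.3))
            bundle = assemble_bundle(
                small_sites.k4_up, small_sites.k27_up, small_sites.tfbs_raw
            )
            scores, labels = [], []
            for i in range(6):
                for label, tf in (("tRCC", 0.1), ("healthy", 0.0)):
                    frags = {
                        m: simulate_plasma_sample(
                            cfg, small_sites, label, tf, m, f"{label}{i}"
                        )
                        for m in (MARK_K4, MARK_K27)
                    }
                    scores.append(
                        score_sample(frags, bundle, small_sites.dhs).ties
                    )
                    labels.append(label)
            aucs.append(roc_auc(scores, labels, positive="tRCC").auc)
        assert aucs[0] <= aucs[1]


def test_null_cohort_score_distributions_coincide(small_cfg, small_sites):
    """With tumor fraction forced to zero, the end-to-end score distribution
    of samples labelled tRCC matches that of healthy samples."""
    from scipy import stats as sps

    from cfties.pipeline import score_cohort
    from cfties.synthetic import simulate_cohort

    cfg = dataclasses.replace(small_cfg, tf_range=(1e-9, 1e-9))
    bundle = assemble_bundle(
        small_sites.k4_up, small_sites.k27_up, small_sites.tfbs_raw
    )
    coh = simulate_cohort(cfg, 12, 0, 12, sites=small_sites)
    df = score_cohort(coh.samples, bundle, small_sites.dhs)
    t = df[df.label == "tRCC"].ties
    h = df[df.label == "healthy"].ties
    ks = sps.ks_2samp(t, h)
    assert ks.pvalue > 0.01
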