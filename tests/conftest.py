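import numpy as np
import pytest

from cfties.intervals import GenomicInterval, SiteSet
from cfties.synthetic import CohortConfig, make_sites


def to_siteset(triples, mark=None, label=""):
    return SiteSet(
        (GenomicInterval(c, s, e) for c, s, e in triples), mark=mark, label=label
    )


def triples(siteset):
    return [(iv.chrom, iv.start, iv.end) for iv in siteset]


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully structured cohort: quick to simulate, yet with
    enough depth for the housekeeping reference to be solidly positive."""
    return CohortConfig(
        n_k4_sites=20,
        n_k27_sites=25,
        n_tfbs_sites=30,
        n_dhs_sites=40,
        n_ccrcc_sites=20,
        n_fragments_per_sample=30_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sites(small_cfg):
    return make_sites(small_cfg)
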