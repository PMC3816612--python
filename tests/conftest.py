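import logging

import numpy as np
import pytest

from estvolve.synthetic import SimulationConfig

logging.getLogger("estvolve").setLevel(logging.ERROR)
logging.getLogger("estvolve.snp").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_sim_config():
    """Noise-free, full-length-read configuration: every planted SNP column
    has 2x monomorphic coverage in every accession."""
    return SimulationConfig(
        seed=11,
        n_families=20,
        family_codons=150,
        n_fraction=0.0,
        coverage_per_accession=2,
        est_length_mean=1500.0,
        est_length_sd=0.0,
        snp_rate=0.02,
    )


# The published marker tables, used as worked-example inputs for the
# reporting and classification code paths.

MEMBER_DISTRIBUTION_ROWS = [
    (1, 33_322, 33_322),
    (2, 22_758, 45_516),
    (3, 7_451, 22_353),
    (4, 5_668, 22_672),
    (5, 3_023, 15_115),
    (6, 2_446, 14_676),
    (7, 1_661, 11_627),
    (8, 1_306, 10_448),
    (9, 1_044, 9_396),
    (10, 851, 8_510),
    ("11-30", 4_710, 78_071),
    ("31-50", 649, 24_663),
    ("51-70", 140, 8_220),
    ("71-90", 33, 2_593),
    ("91-110", 8, 800),
    (">110", 13, 3_039),
]

SSR_TYPE_COUNTS = {
    "di": 5_918,
    "tri": 6_651,
    "tetra": 170,
    "penta": 63,
    "hexa": 50,
    "compound": 718,
}

SSR_REPEAT_COUNTS = {5: 4_117, 6: 3_959, 7: 1_992, 8: 1_067, 9: 602, 10: 340}

SSR_TOP_CLASSES = {
    "TC": 2_440, "AG": 2_384, "TCT": 841, "GAA": 776, "CTT": 711, "GAT": 468,
}

SNP_SUBSTITUTION_COUNTS = [
    (("A", "G"), 7_515),   # A<->G and C<->T are published as one
    (("C", "T"), 7_514),   # transition row totalling 15,029
    (("A", "C"), 2_433),
    (("A", "T"), 2_828),
    (("C", "G"), 2_276),
    (("G", "T"), 2_514),
    (("T", "-"), 1_288),
    (("A", "-"), 1_172),
    (("C", "-"), 611),
    (("G", "-"), 607),
]
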