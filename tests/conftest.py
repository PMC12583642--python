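import math

import numpy as np
import pytest

from dpcrkit import AssayPanelConfig, DropletWellCounts
from dpcrkit.assays import AssayEntry
from dpcrkit.kinetics import RateCoefficients, RepairRates


def expected_count_well(
    lam_link: float,
    lam_fam_free: float,
    lam_hex_free: float,
    n_total: float = 1e6,
    **ids,
) -> DropletWellCounts:
    """A well holding the *exact expected* droplet class counts for given
    linked/free concentrations (float counts; no sampling noise)."""
    p_neg = math.exp(-(lam_link + lam_fam_free + lam_hex_free))
    p_fam_neg = math.exp(-(lam_link + lam_fam_free))  # FAM-negative fraction
    p_hex_neg = math.exp(-(lam_link + lam_hex_free))
    n_negative = p_neg * n_total
    n_hex_only = p_fam_neg * n_total - n_negative
    n_fam_only = p_hex_neg * n_total - n_negative
    n_double = n_total - n_negative - n_fam_only - n_hex_only
    return DropletWellCounts(
        n_total=n_total,
        n_double=n_double,
        n_fam_only=n_fam_only,
        n_hex_only=n_hex_only,
        n_negative=n_negative,
        **ids,
    )


@pytest.fixture
def default_panel() -> AssayPanelConfig:
    return AssayPanelConfig(
        locus="locusA",
        mock_sample_id="mock",
        assays=[
            AssayEntry("edge1", "edge", {"fam": "cleavage", "hex": "distal"}),
            AssayEntry("flank1", "flanking",
                       {"fam": "flank5", "hex": "flank3"}, distance_bp=120),
            AssayEntry("ref1", "reference", {"fam": "ref"}),
            AssayEntry("ref2", "reference", {"fam": "ref"}),
            AssayEntry("aneu1", "aneuploidy", {"fam": "p", "hex": "q"}),
        ],
    )


@pytest.fixture
def reconstructed_rates() -> RateCoefficients:
    """Coefficient set consistent with the published summary statistics:
    generation half-life 1.1 h, resolution half-life ~0.96 h, and
    6.9 / 11.1 cleavage events per indel / large deletion."""
    k_in = 0.105
    K = k_in * 6.9
    k_ld = K / 11.1
    k_pr = K - k_in - k_ld
    return RateCoefficients(
        k_dsb=math.log(2) / 1.1,
        tau=0.5,
        conditions={
            "untreated": RepairRates(k_pr=k_pr, k_in=k_in, k_ld=k_ld),
            "inhibited": RepairRates(k_pr=0.1, k_in=0.005, k_ld=0.03),
        },
    )


@pytest.fixture
def random_rate_sets():
    """100 random coefficient sets over a physically plausible range."""
    rng = np.random.default_rng(12345)
    sets = []
    for _ in range(100):
        k = 10.0 ** rng.uniform(-3, math.log10(3.0), size=5)
        tau = rng.uniform(0.0, 2.0)
        sets.append(
            dict(k_dsb=k[0], tau=tau, k_pr=k[1], k_in=k[2], k_ld=k[3],
                 k_ti=k[4])
        )
    return sets
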