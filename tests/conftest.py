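from __future__ import annotations

import numpy as np
import pytest

from ishquant.domain_model import Stage
from ishquant import reference

BL, EG, MG, LG, EP, PL, LP = Stage

PERIODS = [(BL, EG), (EG, MG), (MG, LG), (LG, EP), (EP, PL), (PL, LP)]

# Published per-period sums and integer percentages, frozen from the printed
# period-summary tables for the four pairwise matrices in ishquant.reference.
PUBLISHED_PERIOD_SUMMARIES = {
    "R1": {
        "counts": [(22, 2, 1), (9, 4, 0), (8, 2, 0), (5, 2, 0), (11, 2, 0), (9, 1, 0)],
        "percentages": [(88, 8, 4), (69, 31, 0), (80, 20, 0), (71, 29, 0),
                        (85, 15, 0), (90, 10, 0)],
    },
    "R2": {
        "counts": [(9, 1, 0), (9, 3, 0), (13, 3, 0), (8, 3, 0), (7, 1, 1), (4, 0, 0)],
        "percentages": [(90, 10, 0), (75, 25, 0), (81, 19, 0), (73, 27, 0),
                        (78, 11, 11), (100, 0, 0)],
    },
    "R3": {
        "counts": [(0, 0, 0), (4, 2, 0), (5, 1, 0), (6, 1, 0), (5, 1, 0), (2, 1, 0)],
        "percentages": [(0, 0, 0), (67, 33, 0), (83, 17, 0), (86, 14, 0),
                        (83, 17, 0), (67, 33, 0)],
    },
    "all": {
        "counts": [(31, 5, 3, 1, 1), (23, 11, 8, 0, 1), (28, 11, 15, 0, 0),
                   (22, 12, 15, 0, 0), (28, 8, 9, 1, 0), (18, 5, 1, 0, 0)],
        "percentages": [(76, 12, 7, 2, 2), (53, 26, 19, 0, 2), (52, 20, 28, 0, 0),
                        (45, 24, 31, 0, 0), (61, 17, 20, 2, 0), (75, 21, 4, 0, 0)],
    },
}

REFERENCE_MATRICES = {
    "R1": reference.central_domain_pairwise_counts,
    "R2": reference.oral_ring_pairwise_counts,
    "R3": reference.vegetal_pairwise_counts,
    "all": reference.all_regions_pairwise_counts,
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
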