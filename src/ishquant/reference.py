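"""Published reference data for the *N. vectensis* expression-pattern study.

These are the curated pairwise transition-count matrices tallied from the
Kahi Kai ISH expression summaries (73 genes with images at two or more of
the seven stages), plus the stage-specific dendrogram cut thresholds and the
per-stage counts of quantified profiles.  The count matrices are inputs to
:func:`ishquant.transition_analysis.aggregate_periods`; the period sums and
percentages are *derived* from them at run time, never stored here.

Cell key is ``(initial stage, final stage)``; region-filtered matrices carry
(minor, major, vanished) triples, the all-regions matrix carries
(minor, major, appeared, vanished, none) 5-tuples.
"""

from __future__ import annotations

from .domain_model import Stage
from .transition_analysis import PairwiseCountMatrix

__all__ = [
    "STAGE_CUTOFFS",
    "PROFILES_PER_STAGE",
    "central_domain_pairwise_counts",
    "oral_ring_pairwise_counts",
    "vegetal_pairwise_counts",
    "all_regions_pairwise_counts",
]

BL, EG, MG, LG, EP, PL, LP = Stage

# Dendrogram cut thresholds per stage on the 1 - r scale.
STAGE_CUTOFFS = {
    BL: 0.7, EG: 1.3, MG: 1.1, LG: 0.6, EP: 0.9, PL: 0.9, LP: 0.9,
}

# Number of standardized profiles quantified at each stage.
PROFILES_PER_STAGE = {
    BL: 112, EG: 52, MG: 18, LG: 25, EP: 15, PL: 17, LP: 13,
}


def central_domain_pairwise_counts() -> PairwiseCountMatrix:
    """Genes initially expressed only in the central domain / endoderm (R1)."""
    return PairwiseCountMatrix("R1", {
        (BL, EG): (21, 1, 1),
        (BL, MG): (1, 0, 0), (EG, MG): (4, 2, 0),
        (BL, LG): (0, 0, 0), (EG, LG): (4, 1, 0), (MG, LG): (3, 0, 0),
        (BL, EP): (0, 1, 0), (EG, EP): (0, 0, 0), (MG, EP): (1, 0, 0),
        (LG, EP): (0, 0, 0),
        (BL, PL): (0, 0, 0), (EG, PL): (0, 0, 0), (MG, PL): (0, 0, 0),
        (LG, PL): (4, 1, 0), (EP, PL): (7, 0, 0),
        (BL, LP): (0, 0, 0), (EG, LP): (0, 0, 0), (MG, LP): (0, 0, 0),
        (LG, LP): (0, 0, 0), (EP, LP): (0, 1, 0), (PL, LP): (9, 0, 0),
    })


def oral_ring_pairwise_counts() -> PairwiseCountMatrix:
    """Genes initially limited to the central/external ring / oral ectoderm (R2)."""
    return PairwiseCountMatrix("R2", {
        (BL, EG): (8, 0, 0),
        (BL, MG): (0, 0, 0), (EG, MG): (5, 0, 0),
        (BL, LG): (1, 0, 0), (EG, LG): (2, 2, 0), (MG, LG): (8, 0, 0),
        (BL, EP): (0, 1, 0), (EG, EP): (1, 0, 0), (MG, EP): (1, 0, 0),
        (LG, EP): (4, 1, 0),
        (BL, PL): (0, 0, 0), (EG, PL): (0, 0, 0), (MG, PL): (0, 0, 0),
        (LG, PL): (2, 1, 0), (EP, PL): (4, 0, 1),
        (BL, LP): (0, 0, 0), (EG, LP): (0, 0, 0), (MG, LP): (0, 0, 0),
        (LG, LP): (0, 0, 0), (EP, LP): (1, 0, 0), (PL, LP): (3, 0, 0),
    })


def vegetal_pairwise_counts() -> PairwiseCountMatrix:
    """Genes initially limited to the vegetal hemisphere / aboral ectoderm (R3)."""
    return PairwiseCountMatrix("R3", {
        (BL, EG): (0, 0, 0),
        (BL, MG): (0, 0, 0), (EG, MG): (2, 1, 0),
        (BL, LG): (0, 0, 0), (EG, LG): (2, 0, 0), (MG, LG): (1, 0, 0),
        (BL, EP): (0, 0, 0), (EG, EP): (0, 0, 0), (MG, EP): (1, 0, 0),
        (LG, EP): (3, 0, 0),
        (BL, PL): (0, 0, 0), (EG, PL): (0, 1, 0), (MG, PL): (1, 0, 0),
        (LG, PL): (1, 0, 0), (EP, PL): (2, 0, 0),
        (BL, LP): (0, 0, 0), (EG, LP): (0, 0, 0), (MG, LP): (0, 0, 0),
        (LG, LP): (0, 0, 0), (EP, LP): (1, 0, 0), (PL, LP): (1, 1, 0),
    })


def all_regions_pairwise_counts() -> PairwiseCountMatrix:
    """Every gene pair, five categories (minor:major:appeared:vanished:none)."""
    return PairwiseCountMatrix("all", {
        (BL, EG): (29, 3, 1, 1, 1),
        (BL, MG): (1, 0, 2, 0, 0), (EG, MG): (12, 3, 0, 0, 1),
        (BL, LG): (1, 0, 0, 0, 0), (EG, LG): (8, 3, 2, 0, 0),
        (MG, LG): (12, 0, 1, 0, 0),
        (BL, EP): (0, 2, 0, 0, 0), (EG, EP): (1, 0, 1, 0, 0),
        (MG, EP): (4, 1, 4, 0, 0), (LG, EP): (8, 2, 1, 0, 0),
        (BL, PL): (0, 0, 0, 0, 0), (EG, PL): (0, 3, 3, 0, 0),
        (MG, PL): (2, 0, 3, 0, 0), (LG, PL): (7, 2, 2, 0, 0),
        (EP, PL): (17, 0, 0, 1, 0),
        (BL, LP): (0, 0, 0, 0, 0), (EG, LP): (0, 0, 0, 0, 0),
        (MG, LP): (0, 2, 1, 0, 0), (LG, LP): (0, 0, 0, 0, 0),
        (EP, LP): (2, 1, 0, 0, 0), (PL, LP): (16, 2, 0, 0, 0),
    })
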