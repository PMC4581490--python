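"""Developmental stages, expression-domain vocabulary and major regions.

*Nematostella vectensis* embryos are described at seven ordered stages
(blastula through late planula).  At each stage a gene's expression pattern
is summarized as a set of named domains along the oral-aboral axis
(``Cd`` central domain, ``Cr`` central ring, ``En`` endoderm, ...).  Domains
are grouped into three coarse *major regions* that persist through
development:

``R1``
    central domain / endoderm,
``R2``
    central ring + external ring / oral ectoderm,
``R3``
    vegetal hemisphere / aboral ectoderm.

The module also provides a rule-based annotator that turns a standardized
1D profile into a domain set, which bridges image quantification and the
domain-table statistics in fully synthetic runs.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Stage",
    "StageRecord",
    "DomainTable",
    "MajorRegionMap",
    "DomainError",
    "DEFAULT_VOCABULARY",
    "REGION_REPRESENTATIVES",
    "REGIONS",
    "map_domains_to_regions",
    "annotate_profile",
]

REGIONS = ("R1", "R2", "R3")


class DomainError(ValueError):
    """Raised for unknown stages or domain names."""


class Stage(enum.IntEnum):
    """The seven ordered developmental stages, blastula = 0 .. late planula = 6."""

    BLASTULA = 0
    EARLY_GASTRULA = 1
    MID_GASTRULA = 2
    LATE_GASTRULA = 3
    EARLY_PLANULA = 4
    PLANULA = 5
    LATE_PLANULA = 6

    @property
    def label(self) -> str:
        return self.name.lower().replace("_", " ")

    @classmethod
    def parse(cls, text: "str | Stage | int") -> "Stage":
        """Canonicalize a stage name (case-insensitive, fixed synonym list).

        Unknown names raise :class:`DomainError` listing the legal names;
        they are never guessed.
        """
        if isinstance(text, Stage):
            return text
        if isinstance(text, (int, np.integer)) and not isinstance(text, bool):
            return cls(int(text))
        norm = " ".join(str(text).strip().lower().replace("_", " ").replace("-", " ").split())
        norm = _STAGE_SYNONYMS.get(norm, norm)
        for stage in cls:
            if stage.label == norm:
                return stage
        legal = ", ".join(s.label for s in cls)
        raise DomainError(f"unknown stage {text!r}; legal names: {legal}")


_STAGE_SYNONYMS = {
    "gastrula (early)": "early gastrula",
    "gastrula (mid)": "mid gastrula",
    "gastrula (late)": "late gastrula",
    "planula (early)": "early planula",
    "planula (late)": "late planula",
    "earlygastrula": "early gastrula",
    "midgastrula": "mid gastrula",
    "lategastrula": "late gastrula",
    "earlyplanula": "early planula",
    "lateplanula": "late planula",
}


# Legal domain names per stage.  Blastula territories are concentric around
# the animal pole; after gastrulation the germ-layer names take over.
DEFAULT_VOCABULARY: dict[Stage, tuple[str, ...]] = {
    Stage.BLASTULA: ("AnHe", "VeHe", "An", "Ve", "Cd", "Cr", "Er"),
    Stage.EARLY_GASTRULA: ("AnHe", "VeHe", "An", "Ve", "pEn", "bEc", "Ec", "Vr"),
    Stage.MID_GASTRULA: ("En", "OrEc", "AbEc", "Ec", "Ve", "Vr", "bEc"),
    Stage.LATE_GASTRULA: (
        "En", "OrEc", "AbEc", "PhEc", "PhEn", "Ec", "Ve", "At", "OrHe", "AbHe",
    ),
    Stage.EARLY_PLANULA: (
        "En", "OrEc", "AbEc", "PhEc", "PhEn", "At", "AtEc", "AtEn", "Ec", "M",
        "BwEc", "BwEn", "OrHe", "AbHe",
    ),
    Stage.PLANULA: (
        "En", "OrEc", "AbEc", "PhEc", "PhEn", "At", "AtEc", "AtEn", "Ec", "M",
        "BwEc", "BwEn", "OrHe", "AbHe", "MeEc", "MeEn", "TeB",
    ),
    Stage.LATE_PLANULA: (
        "En", "OrEc", "AbEc", "PhEc", "PhEn", "At", "AtEc", "AtEn", "Ec", "M",
        "BwEc", "BwEn", "OrHe", "AbHe", "MeEc", "MeEn", "TeB", "TeEc", "TeEn",
        "Si", "TeTi", "TeBa",
    ),
}


# One representative domain name per major region at each stage; used by the
# synthetic generator and the profile annotator.
REGION_REPRESENTATIVES: dict[Stage, dict[str, str]] = {
    Stage.BLASTULA: {"R1": "Cd", "R2": "Cr", "R3": "VeHe"},
    Stage.EARLY_GASTRULA: {"R1": "pEn", "R2": "bEc", "R3": "Ve"},
    Stage.MID_GASTRULA: {"R1": "En", "R2": "OrEc", "R3": "AbEc"},
    Stage.LATE_GASTRULA: {"R1": "En", "R2": "OrEc", "R3": "AbEc"},
    Stage.EARLY_PLANULA: {"R1": "En", "R2": "OrEc", "R3": "AbEc"},
    Stage.PLANULA: {"R1": "En", "R2": "OrEc", "R3": "AbEc"},
    Stage.LATE_PLANULA: {"R1": "En", "R2": "OrEc", "R3": "AbEc"},
}


_DEFAULT_REGION_OF = {
    # R1: central domain and its endodermal descendants
    "Cd": "R1", "pEn": "R1", "En": "R1", "PhEn": "R1", "BwEn": "R1",
    "MeEn": "R1", "TeEn": "R1", "AtEn": "R1", "An": "R1",
    # R2: rings around the central domain and the oral ectoderm lineage
    "Cr": "R2", "Er": "R2", "bEc": "R2", "OrEc": "R2", "PhEc": "R2", "M": "R2",
    # R3: vegetal hemisphere and the aboral ectoderm lineage
    "VeHe": "R3", "Ve": "R3", "Vr": "R3", "AbEc": "R3", "At": "R3", "AtEc": "R3",
    # pan-regional or uncertain names stay unmapped by default; the body-wall
    # ectoderm lineage in particular cannot be pinned to one region.
    "AnHe": None, "Ec": None, "BwEc": None, "TeEc": None, "OrHe": None,
    "AbHe": None, "MeEc": None, "TeB": None, "Si": None, "TeTi": None,
    "TeBa": None,
}


@dataclass(frozen=True)
class MajorRegionMap:
    """Lookup from domain name to major region (or ``None`` = unmapped).

    The default map is an inference from the coarse three-region grouping and
    is deliberately user-overridable (pass a modified ``mapping`` or use
    :meth:`with_overrides`).
    """

    mapping: Mapping[str, "str | None"] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_OF)
    )

    def __post_init__(self) -> None:
        for name, region in self.mapping.items():
            if region is not None and region not in REGIONS:
                raise DomainError(f"illegal region {region!r} for domain {name!r}")

    def region_of(self, name: str) -> "str | None":
        try:
            return self.mapping[name]
        except KeyError:
            raise DomainError(f"unknown domain name {name!r}") from None

    def with_overrides(self, **overrides: "str | None") -> "MajorRegionMap":
        merged = dict(self.mapping)
        merged.update(overrides)
        return MajorRegionMap(merged)


def map_domains_to_regions(
    domains: Iterable[str], region_map: "MajorRegionMap | None" = None
) -> tuple[frozenset, frozenset]:
    """Map a set of domain names to major regions.

    Returns ``(regions, unmapped)`` where ``unmapped`` collects names with no
    region assignment — they are reported, never silently dropped.  Unknown
    names raise :class:`DomainError`.
    """
    region_map = region_map or MajorRegionMap()
    regions, unmapped = set(), set()
    for name in domains:
        region = region_map.region_of(name)
        if region is None:
            unmapped.add(name)
        else:
            regions.add(region)
    return frozenset(regions), frozenset(unmapped)


@dataclass(frozen=True)
class StageRecord:
    """One gene's expression description at one stage."""

    stage: Stage
    domains: frozenset
    noncylindrical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage.parse(self.stage))
        object.__setattr__(self, "domains", frozenset(self.domains))


@dataclass
class DomainTable:
    """Per-gene ordered expression descriptions across available stages.

    Genes flagged noncylindrical are carried through (their transitions are
    still tallied) but are excluded from 1D profile quantification.
    """

    records: dict

    def __post_init__(self) -> None:
        for gene, recs in self.records.items():
            recs = sorted(recs, key=lambda r: r.stage)
            stages = [r.stage for r in recs]
            if len(set(stages)) != len(stages):
                raise DomainError(f"gene {gene!r} lists a stage twice")
            self.records[gene] = recs

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> list:
        return sorted(self.records)

    def validate_vocabulary(
        self, vocabulary: "Mapping[Stage, Sequence[str]] | None" = None
    ) -> None:
        vocab = vocabulary or DEFAULT_VOCABULARY
        for gene, recs in self.records.items():
            for rec in recs:
                legal = set(vocab[rec.stage])
                bad = rec.domains - legal
                if bad:
                    raise DomainError(
                        f"gene {gene!r}, stage {rec.stage.label!r}: "
                        f"illegal domain names {sorted(bad)}"
                    )

    def analyzable_genes(self) -> list:
        """Genes with at least two available stages (transition analysis)."""
        return sorted(g for g, recs in self.records.items() if len(recs) >= 2)


def annotate_profile(
    values: np.ndarray,
    windows: Sequence[tuple],
    threshold: float = 0.5,
) -> frozenset:
    """Rule-based domain call from a standardized profile.

    ``windows`` is a list of ``(name, start, end)`` intervals that must cover
    [0, 1] without overlap.  A domain is called present when the mean profile
    value over its window is at least ``threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    _check_cover(windows)
    positions = np.linspace(0.0, 1.0, values.size)
    present = set()
    for name, start, end in windows:
        sel = (positions >= start) & (positions < end)
        if end >= 1.0 - 1e-12:
            sel |= positions >= end
        if sel.any() and values[sel].mean() >= threshold:
            present.add(name)
    return frozenset(present)


def _check_cover(windows: Sequence[tuple]) -> None:
    if not windows:
        raise ValueError("no annotation windows given")
    ordered = sorted(windows, key=lambda w: w[1])
    if abs(ordered[0][1]) > 1e-9 or abs(ordered[-1][2] - 1.0) > 1e-9:
        raise ValueError("windows must cover [0, 1]")
    for (_, _, e_prev), (_, s_next, _) in zip(ordered, ordered[1:]):
        if abs(e_prev - s_next) > 1e-9:
            raise ValueError("windows must tile [0, 1] without gaps or overlap")
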