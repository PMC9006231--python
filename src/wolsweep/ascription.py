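"""Strain ascription under contact contingency and adaptive decay.

Contact contingency: whenever a host fig community contains at least two
putative species, each receives a distinct synthetic *Wolbachia* strain
(bidirectional CI demands distinguishable cytotypes only where incipient
species are in contact); a community with a single putative species is
entirely uninfected.

Adaptive decay: at a given purge threshold, a putative species loses its
ascribed strain when every other putative species of its community lies
strictly farther away than the threshold (min-linkage patristic distance)
— CI is redundant once all neighbours are deeply diverged.  Purging acts
on whole putative species: all members keep the strain or all lose it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .design import StudyDesign
from .enumeration import PSC, PutativeSpecies
from .io import PhyloDistances

log = logging.getLogger(__name__)

#: Label for putative species carrying no ascribed strain.
UNINFECTED = "uninfected"

#: Sentinel for "no purging".  The sweep's zero point disables the purge
#: rather than applying a numeric 0 threshold (a literal 0 with strict
#: exceedance would purge every species, which is not what "no purging"
#: means).
PURGE_DISABLED = None

PspKey = tuple[str, tuple[int, ...]]  # (host_fig, occupancy)


def min_linkage_distance(
    psp_a: PutativeSpecies, psp_b: PutativeSpecies, distances: PhyloDistances
) -> float:
    """Minimum patristic distance over all cross pairs of member tips.

    For |A| = 5 and |B| = 3 members this is the minimum of 15 pairwise
    tip distances.
    """
    if not psp_a.member_tips or not psp_b.member_tips:
        raise ValueError("min-linkage distance needs non-empty member sets")
    ia = [distances.index(t) for t in psp_a.member_tips]
    ib = [distances.index(t) for t in psp_b.member_tips]
    return float(distances.matrix[np.ix_(ia, ib)].min())


@dataclass(frozen=True)
class PutativeDistanceTable:
    """Pairwise min-linkage distances among a community's putative species."""

    community: str
    species: tuple[PutativeSpecies, ...]
    matrix: np.ndarray  # (k, k), symmetric, zero diagonal

    def distance(self, a: PspKey, b: PspKey) -> float:
        keys = [s.key() for s in self.species]
        return float(self.matrix[keys.index(a), keys.index(b)])


def community_distance_tables(
    psc: PSC, design: StudyDesign, distances: PhyloDistances
) -> dict[str, PutativeDistanceTable]:
    """Min-linkage distance tables per community for one PSC."""
    tables: dict[str, PutativeDistanceTable] = {}
    for comm in design.communities:
        sps = tuple(
            sp
            for host in comm.host_figs
            for sp in psc.species_by_host.get(host.name, ())
        )
        k = len(sps)
        mat = np.zeros((k, k), dtype=float)
        for i in range(k):
            for j in range(i + 1, k):
                d = min_linkage_distance(sps[i], sps[j], distances)
                mat[i, j] = mat[j, i] = d
        tables[comm.name] = PutativeDistanceTable(comm.name, sps, mat)
    return tables


@dataclass(frozen=True)
class StrainAscription:
    """Synthetic strain (or uninfected) per putative species of one PSC.

    ``labels`` maps each putative-species key to a strain token ``w1``,
    ``w2``, … (globally unique across the study) or :data:`UNINFECTED`.
    ``by_tip`` resolves the same label per member individual.
    """

    labels: Mapping[PspKey, str]
    by_tip: Mapping[str, str]
    purge_threshold: float | None = PURGE_DISABLED

    def label_of(self, psp: PutativeSpecies) -> str:
        return self.labels[psp.key()]


def ascribe(psc: PSC, design: StudyDesign) -> StrainAscription:
    """Pre-purge contact-contingency ascription.

    Counting is at community level (a species complex is one community):
    if a community holds >= 2 putative species across its hosts, each gets
    a fresh distinct strain; a single-species community is uninfected.
    Labels are assigned in community / host / start-site order so output
    is reproducible.
    """
    labels: dict[PspKey, str] = {}
    by_tip: dict[str, str] = {}
    counter = 0
    for comm in design.communities:
        sps = [
            sp
            for host in comm.host_figs
            for sp in psc.species_by_host.get(host.name, ())
        ]
        if len(sps) >= 2:
            for sp in sps:
                counter += 1
                labels[sp.key()] = f"w{counter}"
        else:
            for sp in sps:
                labels[sp.key()] = UNINFECTED
        for sp in sps:
            for tip in sp.member_tips:
                by_tip[tip] = labels[sp.key()]
    return StrainAscription(labels=labels, by_tip=by_tip)


def purge(
    ascription: StrainAscription,
    tables: Mapping[str, PutativeDistanceTable],
    threshold: float | None,
    max_distance: float | None = None,
) -> StrainAscription:
    """Apply the adaptive-decay purge at one threshold.

    A putative species is set to uninfected iff its distance to *every*
    other putative species of its community strictly exceeds the
    threshold; equality keeps the strain (the purge is conservative).
    ``PURGE_DISABLED`` returns the ascription unchanged, as do communities
    that were already uninfected.  If ``max_distance`` (the whole-tree
    maximum patristic distance) is given, thresholds beyond it are
    rejected.
    """
    if threshold is PURGE_DISABLED:
        return ascription
    if threshold < 0:
        raise ValueError("purge threshold must be non-negative")
    if max_distance is not None and threshold > max_distance:
        raise ValueError(
            f"threshold {threshold} exceeds maximum patristic distance {max_distance}"
        )
    labels = dict(ascription.labels)
    for table in tables.values():
        k = len(table.species)
        if k < 2:
            continue
        for i, sp in enumerate(table.species):
            if labels[sp.key()] == UNINFECTED:
                continue
            others = np.delete(table.matrix[i], i)
            if others.size and float(others.min()) > threshold:
                labels[sp.key()] = UNINFECTED
    by_tip: dict[str, str] = {}
    for table in tables.values():
        for sp in table.species:
            for tip in sp.member_tips:
                by_tip[tip] = labels[sp.key()]
    # preserve tips of species outside any community table (none in practice)
    for tip, lab in ascription.by_tip.items():
        by_tip.setdefault(tip, lab)
    return StrainAscription(labels=labels, by_tip=by_tip, purge_threshold=threshold)


def threshold_grid(
    distances: PhyloDistances, n_steps: int = 100
) -> list[float | None]:
    """Purge-threshold sweep grid.

    The first element is :data:`PURGE_DISABLED` ("zero = no purging"),
    followed by ``n_steps`` evenly spaced values from the smallest
    positive tip-to-tip patristic distance to the whole-tree maximum.
    A degenerate tree (all distances zero) yields the sentinel alone.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    lo, hi = distances.min_positive, distances.max_distance
    if hi <= 0:
        log.warning("degenerate tree: all patristic distances are zero")
        return [PURGE_DISABLED]
    return [PURGE_DISABLED] + list(np.linspace(lo, hi, n_steps))
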