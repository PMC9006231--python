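"""Enumeration of putative species and their combinations (PSCs).

A putative species is one contiguous run of elevation sites within one
host fig, written as an occupancy bit vector over the host's ordered
sites (``1110`` = present at the first three of four sites).  Because real
fig-wasp species never overlap in elevation within a host, a delimitation
hypothesis for a host is an ordered partition of its site line into
contiguous blocks — a composition — of which there are 2**(n-1) for n
sites.  A PSC (putative species combination) picks one composition per
host; the study-wide set is the cartesian product across hosts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .design import IndividualRecord, StudyDesign

Occupancy = tuple[int, ...]


@dataclass(frozen=True)
class PutativeSpecies:
    """A contiguous-elevation-range species hypothesis within one host."""

    host_fig: str
    occupancy: Occupancy
    member_tips: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not any(self.occupancy):
            raise ValueError("putative species must occupy at least one site")
        if not _is_contiguous(self.occupancy):
            raise ValueError(
                f"occupancy {self.occupancy} has an internal gap"
            )

    @property
    def start(self) -> int:
        return self.occupancy.index(1)

    @property
    def width(self) -> int:
        return sum(self.occupancy)

    def key(self) -> tuple[str, Occupancy]:
        return (self.host_fig, self.occupancy)


@dataclass(frozen=True)
class PSC:
    """One complete delimitation hypothesis: a composition per host."""

    index: int
    species_by_host: dict[str, tuple[PutativeSpecies, ...]]

    def all_species(self) -> Iterator[PutativeSpecies]:
        for sps in self.species_by_host.values():
            yield from sps

    def n_species(self) -> int:
        return sum(len(s) for s in self.species_by_host.values())

    def richness_by_host(self) -> dict[str, int]:
        return {h: len(s) for h, s in self.species_by_host.items()}


def _is_contiguous(occ: Sequence[int]) -> bool:
    ones = [i for i, b in enumerate(occ) if b]
    return bool(ones) and ones[-1] - ones[0] + 1 == len(ones)


def enumerate_putative_species(n_sites: int) -> list[Occupancy]:
    """All contiguous, non-empty occupancy vectors over ``n_sites`` sites.

    There are n(n+1)/2 of them.  Order: by width descending, then start
    site — so for four sites: 1111, 1110, 0111, 1100, 0110, 0011, 1000,
    0100, 0010, 0001.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    out: list[Occupancy] = []
    for width in range(n_sites, 0, -1):
        for start in range(n_sites - width + 1):
            occ = tuple(
                1 if start <= i < start + width else 0 for i in range(n_sites)
            )
            out.append(occ)
    return out


def enumerate_host_pscs(n_sites: int) -> list[tuple[Occupancy, ...]]:
    """All compositions of the site line into contiguous blocks.

    Each composition covers every site exactly once; there are 2**(n-1)
    for n sites.  Order is lexicographic by block boundaries (splitting
    after site i or not, most-significant boundary first), which puts the
    single-block delimitation first and the all-singletons one last.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    out: list[tuple[Occupancy, ...]] = []
    for mask in range(2 ** (n_sites - 1)):
        # bit k of mask (MSB first) = cut between site k and k+1
        cuts = [
            k
            for k in range(n_sites - 1)
            if mask >> (n_sites - 2 - k) & 1
        ]
        bounds = [0] + [c + 1 for c in cuts] + [n_sites]
        blocks = tuple(
            tuple(1 if a <= i < b else 0 for i in range(n_sites))
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        out.append(blocks)
    return out


def members_at(
    records: Sequence[IndividualRecord], host: str, sites: Sequence[str]
) -> frozenset[str]:
    wanted = set(sites)
    return frozenset(
        r.tip_id
        for r in records
        if r.host_fig == host and r.elevation_site in wanted
    )


def attach_members(
    host_name: str,
    site_labels: Sequence[str],
    occupancy: Occupancy,
    records: Sequence[IndividualRecord],
) -> PutativeSpecies:
    """Build a PutativeSpecies with its member tips filled in."""
    occupied = [s for s, bit in zip(site_labels, occupancy) if bit]
    return PutativeSpecies(
        host_fig=host_name,
        occupancy=occupancy,
        member_tips=members_at(records, host_name, occupied),
    )


def n_study_pscs(design: StudyDesign) -> int:
    total = 1
    for host in design.hosts:
        total *= 2 ** (host.n_sites - 1)
    return total


def enumerate_study_pscs(
    design: StudyDesign,
    records: Sequence[IndividualRecord] = (),
) -> Iterator[PSC]:
    """Lazily yield every study-wide PSC with a stable mixed-radix index.

    The index enumerates hosts in design order, the last host varying
    fastest; it is reproducible across runs and appears in output tables.
    """
    hosts = design.hosts
    per_host: list[list[tuple[PutativeSpecies, ...]]] = []
    for host in hosts:
        comps = enumerate_host_pscs(host.n_sites)
        per_host.append(
            [
                tuple(
                    attach_members(host.name, host.elevation_sites, occ, records)
                    for occ in comp
                )
                for comp in comps
            ]
        )
    radices = [len(c) for c in per_host]

    def emit(idx: int) -> PSC:
        rem = idx
        choice: list[int] = [0] * len(hosts)
        for pos in range(len(hosts) - 1, -1, -1):
            choice[pos] = rem % radices[pos]
            rem //= radices[pos]
        return PSC(
            index=idx,
            species_by_host={
                host.name: per_host[pos][choice[pos]]
                for pos, host in enumerate(hosts)
            },
        )

    total = n_study_pscs(design)
    for idx in range(total):
        yield emit(idx)
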