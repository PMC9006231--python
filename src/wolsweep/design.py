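"""Study-design and per-individual domain types.

A study comprises *communities* of host fig species; each host is sampled
at an ordered series of elevation sites.  Hosts that belong to a recent
species complex (and may therefore share endosymbionts through host
"mistakes") are grouped into a single community.  Individual wasps are the
tips of the phylogeny; each carries an empirical species label and an
empirical *Wolbachia* strain label (a reserved none-token for uninfected).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

#: Reserved empirical-strain token for uninfected individuals.  It is never
#: matchable as a positive strain.
NONE_TOKEN = "none"


@dataclass(frozen=True)
class HostFig:
    """One host fig species with its ordered elevation sites.

    Elevation labels are opaque ordered tokens (e.g. ``"200"``); their order
    comes from this list, ascending, and is never parsed numerically.
    """

    name: str
    elevation_sites: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.elevation_sites:
            raise ValueError(f"host {self.name!r} has no elevation sites")
        if len(set(self.elevation_sites)) != len(self.elevation_sites):
            raise ValueError(f"host {self.name!r} has duplicate elevation sites")

    @property
    def n_sites(self) -> int:
        return len(self.elevation_sites)


@dataclass(frozen=True)
class Community:
    """A set of host figs whose wasps can exchange endosymbionts."""

    name: str
    host_figs: tuple[HostFig, ...]

    def __post_init__(self) -> None:
        if not self.host_figs:
            raise ValueError(f"community {self.name!r} has no hosts")


@dataclass(frozen=True)
class StudyDesign:
    """All communities of a study; hosts are unique across communities."""

    communities: tuple[Community, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.communities]
        if len(set(names)) != len(names):
            raise ValueError("community names are not unique")
        hosts = [h.name for h in self.hosts]
        if len(set(hosts)) != len(hosts):
            raise ValueError("host fig names are not unique across communities")

    @property
    def hosts(self) -> tuple[HostFig, ...]:
        return tuple(h for c in self.communities for h in c.host_figs)

    def host(self, name: str) -> HostFig:
        for h in self.hosts:
            if h.name == name:
                return h
        raise KeyError(f"unknown host fig {name!r}")

    def community_of(self, host_name: str) -> Community:
        for c in self.communities:
            if any(h.name == host_name for h in c.host_figs):
                return c
        raise KeyError(f"no community contains host {host_name!r}")

    def has_site(self, host_name: str, elevation: str) -> bool:
        try:
            return elevation in self.host(host_name).elevation_sites
        except KeyError:
            return False


@dataclass(frozen=True)
class IndividualRecord:
    """One sequenced wasp, matching a tip of the phylogeny."""

    tip_id: str
    host_fig: str
    elevation_site: str
    empirical_species: str
    empirical_strain: str = NONE_TOKEN

    @property
    def infected(self) -> bool:
        return self.empirical_strain != NONE_TOKEN


def validate_records(records: Sequence[IndividualRecord], design: StudyDesign) -> None:
    """Raise ``ValueError`` listing every record at an unknown (host, site)
    cell and every duplicated tip id."""
    bad = [
        r.tip_id
        for r in records
        if not design.has_site(r.host_fig, r.elevation_site)
    ]
    if bad:
        raise ValueError(f"records at unknown (host, elevation) cells: {bad}")
    seen: set[str] = set()
    dups = []
    for r in records:
        if r.tip_id in seen:
            dups.append(r.tip_id)
        seen.add(r.tip_id)
    if dups:
        raise ValueError(f"duplicate tip ids: {dups}")


def default_study_design() -> StudyDesign:
    """The six-host fig-wasp study layout on the New Guinea elevation gradient.

    Four communities: three single-host communities plus the recent species
    complex treated as one community of three hosts.  Site labels are metres
    above sea level.
    """

    def sites(*elevs: str) -> tuple[str, ...]:
        return tuple(elevs)

    return StudyDesign(
        communities=(
            Community(
                "arfakensis",
                (HostFig("F_arfakensis", sites("200", "700", "1200", "1700")),),
            ),
            Community(
                "itoana",
                (
                    HostFig("F_umbrae", sites("200")),
                    HostFig("F_itoana", sites("200", "700")),
                    HostFig("F_microdictya", sites("1200", "1700")),
                ),
            ),
            Community(
                "trichocerasa",
                (HostFig("F_trichocerasa", sites("700", "1200", "1700", "2200")),),
            ),
            Community(
                "wassa",
                (
                    HostFig(
                        "F_wassa",
                        sites("200", "700", "1200", "1700", "2200", "2700"),
                    ),
                ),
            ),
        )
    )


def read_design(path: str | Path) -> StudyDesign:
    """Read a study design from CSV with columns community,host_fig,elevation.

    Rows for a host must appear in ascending elevation order; hosts of a
    community may be interleaved with other communities' rows but each host
    belongs to exactly one community.
    """
    order: list[str] = []  # community order of first appearance
    hosts_by_comm: dict[str, dict[str, list[str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"community", "host_fig", "elevation"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"design file needs columns {sorted(required)}")
        for row in reader:
            comm, host, elev = row["community"], row["host_fig"], row["elevation"]
            if comm not in hosts_by_comm:
                hosts_by_comm[comm] = {}
                order.append(comm)
            hosts_by_comm[comm].setdefault(host, []).append(elev)
    communities = tuple(
        Community(
            comm,
            tuple(
                HostFig(host, tuple(elevs))
                for host, elevs in hosts_by_comm[comm].items()
            ),
        )
        for comm in order
    )
    return StudyDesign(communities)


def write_design(design: StudyDesign, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["community", "host_fig", "elevation"])
        for comm in design.communities:
            for host in comm.host_figs:
                for elev in host.elevation_sites:
                    writer.writerow([comm.name, host.name, elev])
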