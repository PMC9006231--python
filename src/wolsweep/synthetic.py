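"""Synthetic fig-wasp studies with known ground truth.

The generator emulates the features of the empirical system that the
prediction pipeline exercises: a phylogeny whose clades mirror
communities and elevations, a planted species delimitation built from
contiguous elevation blocks, distinct dominant strains for sympatric
incipient species applied with partial penetrance (dominant strains are
never at 100% fixation), fully uninfected single-species communities,
and rare "horizontal transfer" noise tips carrying a foreign strain.

Trees are clade-per-species with a community backbone; branch lengths
are scaled to substitutions-per-site magnitudes (maximum patristic
distance of order 0.1–1) so purge thresholds sweep realistic ranges.
Within-species distances are kept strictly below between-species
distances, making min-linkage clustering well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .design import (
    NONE_TOKEN,
    IndividualRecord,
    StudyDesign,
    default_study_design,
    write_design,
)
from .io import write_metadata

Block = tuple[str, ...]  # contiguous run of a host's elevation labels


def default_true_delimitation() -> dict[str, tuple[Block, ...]]:
    """Planted delimitation mirroring the empirical lowland/highland splits.

    Nine true species: the three single-host communities each split into a
    lowland and a highland species; the species-complex hosts are one
    species each (the complex community still holds three species, so its
    members carry strains under contact contingency).
    """
    return {
        "F_arfakensis": (("200", "700"), ("1200", "1700")),
        "F_umbrae": (("200",),),
        "F_itoana": (("200", "700"),),
        "F_microdictya": (("1200", "1700"),),
        "F_trichocerasa": (("700", "1200"), ("1700", "2200")),
        "F_wassa": (("200", "700", "1200"), ("1700", "2200", "2700")),
    }


def default_host_totals() -> dict[str, int]:
    """Sampled individuals per host (study-scale totals, 253 wasps)."""
    return {
        "F_arfakensis": 64,
        "F_umbrae": 32,
        "F_itoana": 22,
        "F_microdictya": 35,
        "F_trichocerasa": 48,
        "F_wassa": 52,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    design: StudyDesign = field(default_factory=default_study_design)
    true_delimitation: Mapping[str, tuple[Block, ...]] = field(
        default_factory=default_true_delimitation
    )
    host_totals: Mapping[str, int] = field(default_factory=default_host_totals)
    #: probability an individual of an infected species carries its strain
    penetrance: float = 0.8
    #: probability a tip is overwritten with a random foreign strain
    noise_rate: float = 0.02
    #: upper bound on within-species tip branch lengths (subs/site)
    within_scale: float = 0.004
    #: scale of species stem branches (subs/site)
    between_scale: float = 0.25
    #: scale of community backbone branches (subs/site)
    community_scale: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must lie in [0, 1]")
        for host, blocks in self.true_delimitation.items():
            sites = list(self.design.host(host).elevation_sites)
            covered = [s for b in blocks for s in b]
            if covered != sites:
                raise ValueError(
                    f"delimitation for {host!r} must cover its sites in order"
                )
        if any(t < 1 for t in self.host_totals.values()):
            raise ValueError("every host needs at least one individual")


@dataclass(frozen=True)
class TruthRecord:
    """The planted ground truth: delimitation and species -> strain map."""

    delimitation: Mapping[str, tuple[Block, ...]]
    strain_of_species: Mapping[str, str]
    species_of_tip: Mapping[str, str]


@dataclass(frozen=True)
class SyntheticStudy:
    tree: dendropy.Tree
    records: tuple[IndividualRecord, ...]
    truth: TruthRecord
    design: StudyDesign

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.newick())
        write_metadata(self.records, self.design, out / "meta.csv")
        write_design(self.design, out / "design.csv")
        lines = ["tip_id,true_species,true_strain"]
        for r in self.records:
            sp = self.truth.species_of_tip[r.tip_id]
            lines.append(
                f"{r.tip_id},{sp},{self.truth.strain_of_species.get(sp, NONE_TOKEN)}"
            )
        (out / "truth.csv").write_text("\n".join(lines) + "\n")


def _allocate(total: int, n_sites: int) -> list[int]:
    """Spread a host total over its sites as evenly as possible."""
    base, extra = divmod(total, n_sites)
    return [base + (1 if i < extra else 0) for i in range(n_sites)]


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Draw one synthetic study: tree, metadata and its truth record.

    Same config (including seed) gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design

    # species bookkeeping: name, host, sites, strain
    species: list[dict] = []
    strain_counter = 0
    strain_of_species: dict[str, str] = {}
    for comm in design.communities:
        comm_species = []
        for host in comm.host_figs:
            blocks = config.true_delimitation[host.name]
            for k, block in enumerate(blocks, start=1):
                name = f"{host.name}_sp{k}"
                comm_species.append(
                    {"name": name, "host": host.name, "sites": block, "community": comm.name}
                )
        infected = len(comm_species) >= 2
        for sp in comm_species:
            if infected:
                strain_counter += 1
                strain_of_species[sp["name"]] = f"S{strain_counter}"
            species.append(sp)
    all_strains = sorted(strain_of_species.values())

    # individuals per (host, site)
    counts: dict[tuple[str, str], int] = {}
    for host in design.hosts:
        alloc = _allocate(config.host_totals[host.name], host.n_sites)
        for site, n in zip(host.elevation_sites, alloc):
            counts[(host.name, site)] = n

    # build the tree: root -> community node -> species clade -> tips
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    records: list[IndividualRecord] = []
    species_of_tip: dict[str, str] = {}
    tip_counter = 0
    for comm in design.communities:
        comm_node = tree.seed_node.new_child(
            edge_length=config.community_scale * rng.uniform(0.5, 1.0)
        )
        for sp in [s for s in species if s["community"] == comm.name]:
            stem = config.between_scale * rng.uniform(0.5, 1.0)
            sp_node = comm_node.new_child(edge_length=stem)
            strain = strain_of_species.get(sp["name"], NONE_TOKEN)
            for site in sp["sites"]:
                for _ in range(counts[(sp["host"], site)]):
                    tip_counter += 1
                    tip_id = f"T{tip_counter:03d}"
                    leaf = sp_node.new_child(
                        edge_length=config.within_scale * rng.uniform(0.2, 1.0)
                    )
                    leaf.taxon = taxon_namespace.new_taxon(label=tip_id)
                    empirical = strain if (
                        strain != NONE_TOKEN and rng.random() < config.penetrance
                    ) else NONE_TOKEN
                    if all_strains and rng.random() < config.noise_rate:
                        empirical = str(rng.choice(all_strains))
                    records.append(
                        IndividualRecord(
                            tip_id=tip_id,
                            host_fig=sp["host"],
                            elevation_site=site,
                            empirical_species=sp["name"],
                            empirical_strain=empirical,
                        )
                    )
                    species_of_tip[tip_id] = sp["name"]
    truth = TruthRecord(
        delimitation=dict(config.true_delimitation),
        strain_of_species=strain_of_species,
        species_of_tip=species_of_tip,
    )
    return SyntheticStudy(
        tree=tree, records=tuple(records), truth=truth, design=design
    )


def true_psc_occupancies(
    config: GeneratorConfig,
) -> dict[str, tuple[tuple[int, ...], ...]]:
    """The planted delimitation as occupancy bit vectors per host."""
    out: dict[str, tuple[tuple[int, ...], ...]] = {}
    for host in config.design.hosts:
        sites = host.elevation_sites
        blocks = config.true_delimitation[host.name]
        out[host.name] = tuple(
            tuple(1 if s in set(block) else 0 for s in sites) for block in blocks
        )
    return out


def six_wasp_example() -> tuple[list[str], list[str]]:
    """The worked six-wasp scoring example: two putative species ascribed
    strains w1/w2 against three empirically typed strains.

    Returns (ascribed, empirical) label vectors aligned by individual;
    the constrained matching score of their contingency matrix is 4 of 6.
    """
    ascribed = ["w1", "w1", "w1", "w2", "w2", "w2"]
    empirical = ["W1", "W1", "W2", "W3", "W3", "W2"]
    return ascribed, empirical
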