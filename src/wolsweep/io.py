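"""Tree and metadata I/O.

Trees are newick with branch lengths on every edge; tips are individual
wasps.  Metadata is comma-separated with the fixed header
``tip_id,host_fig,community,elevation,species,strain``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .design import NONE_TOKEN, IndividualRecord, StudyDesign, validate_records

log = logging.getLogger(__name__)

METADATA_HEADER = ["tip_id", "host_fig", "community", "elevation", "species", "strain"]


class TreeFormatError(ValueError):
    """Malformed tree input (e.g. an edge without a branch length)."""


@dataclass(frozen=True)
class PhyloDistances:
    """Square symmetric patristic-distance matrix indexed by tip label.

    Entries are sums of branch lengths along tip-to-tip paths, in
    substitutions per site.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray  # (n, n) float

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown tip {label!r}") from None

    def between(self, a: str, b: str) -> float:
        return float(self.matrix[self.index(a), self.index(b)])

    @property
    def max_distance(self) -> float:
        return float(self.matrix.max()) if self.matrix.size else 0.0

    @property
    def min_positive(self) -> float:
        pos = self.matrix[self.matrix > 0]
        return float(pos.min()) if pos.size else 0.0


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree, requiring branch lengths on all edges.

    Unrooted input is accepted and midpoint-rooted with a warning; patristic
    distances are rooting-invariant so downstream scores are unaffected.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except OSError:
        raise
    except Exception as exc:  # dendropy raises its own DataError hierarchy
        raise TreeFormatError(f"could not parse newick file {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise TreeFormatError(
                f"edge leading to {name!r} has no branch length"
            )
    # plain newick carries no rooting flag; a bifurcating root is taken as
    # rooted, a root polytomy as genuinely unrooted
    if tree.is_rooted is not True and len(tree.seed_node.child_nodes()) > 2:
        log.warning("input tree is unrooted; midpoint-rooting it")
        tree.reroot_at_midpoint(update_bipartitions=True)
    tree.is_rooted = True
    return tree


def tip_labels(tree: dendropy.Tree) -> tuple[str, ...]:
    return tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())


def patristic_matrix(tree: dendropy.Tree) -> PhyloDistances:
    """Patristic (path-length) distances between every pair of tips."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = tip_labels(tree)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    mat = np.zeros((n, n), dtype=float)
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return PhyloDistances(labels=labels, matrix=mat)


def read_metadata(
    path: str | Path,
    design: StudyDesign,
    none_token: str = NONE_TOKEN,
) -> list[IndividualRecord]:
    """Read and validate per-individual metadata.

    ``none_token`` marks uninfected individuals in the strain column and is
    normalised to the package-wide :data:`~wolsweep.design.NONE_TOKEN`.
    Rows at unknown (host, elevation) cells or with duplicate tip ids raise
    ``ValueError`` listing the offenders.
    """
    records: list[IndividualRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != METADATA_HEADER:
            raise ValueError(
                f"metadata header must be {','.join(METADATA_HEADER)!r}"
            )
        for row in reader:
            strain = row["strain"].strip()
            if strain == none_token or not strain:
                strain = NONE_TOKEN
            records.append(
                IndividualRecord(
                    tip_id=row["tip_id"].strip(),
                    host_fig=row["host_fig"].strip(),
                    elevation_site=row["elevation"].strip(),
                    empirical_species=row["species"].strip(),
                    empirical_strain=strain,
                )
            )
    if not records:
        log.warning("metadata file %s is empty", path)
    validate_records(records, design)
    return records


def write_metadata(
    records: Sequence[IndividualRecord], design: StudyDesign, path: str | Path
) -> None:
    """Write records in the fixed CSV layout (round-trips with read_metadata)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.tip_id,
                    r.host_fig,
                    design.community_of(r.host_fig).name,
                    r.elevation_site,
                    r.empirical_species,
                    r.empirical_strain,
                ]
            )


def check_tips_match(
    records: Sequence[IndividualRecord], distances: PhyloDistances
) -> None:
    """Every metadata tip must be present in the tree."""
    missing = sorted(set(r.tip_id for r in records) - set(distances.labels))
    if missing:
        raise ValueError(f"metadata tips absent from tree: {missing}")
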