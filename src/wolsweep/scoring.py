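"""Contingency matrices and the constrained row/column matching score.

The accuracy score between an ascribed labelling and an empirical one is
the largest total count obtainable by picking at most one cell per row
and at most one cell per column of their contingency matrix — a
maximum-weight bipartite matching, solved exactly.  With a perfect
one-to-one correspondence the score equals the number of individuals.

Three scores use this machinery:

* WIA — positive *Wolbachia* infection accuracy: ascribed strains (rows)
  against empirical strains (columns), uninfected individuals excluded
  from both axes; denominator = empirically infected count.
* uWIA — uninfected accuracy: individuals predicted uninfected whose
  empirical typing is the none-token; denominator = empirically
  uninfected count.
* PSC accuracy — putative species against empirical species over all
  individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .design import IndividualRecord
from .enumeration import PSC
from .ascription import UNINFECTED, StrainAscription


@dataclass(frozen=True)
class ContingencyMatrix:
    """Counts of individuals per (ascribed row label, empirical column label)."""

    row_labels: tuple[Hashable, ...]
    col_labels: tuple[Hashable, ...]
    counts: np.ndarray  # (r, c) non-negative ints

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ScoreReport:
    """The three accuracy counts with their denominators for one run."""

    wia: int
    wia_denominator: int
    uwia: int
    uwia_denominator: int
    psc_accuracy: int
    psc_denominator: int


def build_contingency(
    ascribed_labels: Sequence[Hashable], empirical_labels: Sequence[Hashable]
) -> ContingencyMatrix:
    """Tally aligned label vectors into a contingency matrix.

    Row/column orders follow first appearance, which keeps worked examples
    readable; the matching score is permutation-invariant anyway.
    """
    if len(ascribed_labels) != len(empirical_labels):
        raise ValueError("label vectors must have equal length")
    rows: list[Hashable] = []
    cols: list[Hashable] = []
    for a in ascribed_labels:
        if a not in rows:
            rows.append(a)
    for e in empirical_labels:
        if e not in cols:
            cols.append(e)
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for a, e in zip(ascribed_labels, empirical_labels):
        counts[rows.index(a), cols.index(e)] += 1
    return ContingencyMatrix(tuple(rows), tuple(cols), counts)


def constrained_match_score(matrix: ContingencyMatrix | np.ndarray) -> int:
    """Maximum total selecting at most one cell per row and per column.

    Solved exactly as a rectangular assignment problem; an empty matrix
    scores 0.  Because counts are non-negative the optimum over partial
    matchings is attained by a maximum matching, so the assignment
    solution is the score.
    """
    counts = matrix.counts if isinstance(matrix, ContingencyMatrix) else np.asarray(matrix)
    if counts.size == 0:
        return 0
    if (counts < 0).any():
        raise ValueError("contingency counts must be non-negative")
    ri, ci = linear_sum_assignment(counts, maximize=True)
    return int(counts[ri, ci].sum())


def greedy_match_score(matrix: ContingencyMatrix | np.ndarray) -> int:
    """Greedy strike-out variant of the matching score.

    Rows are visited in descending order of their row maximum; each takes
    its highest cell in a still-unused column (clashes fall through to the
    next-highest cell from unused columns).  Kept for comparison with the
    exact solver; the two agree on the worked examples but the greedy rule
    is not guaranteed optimal in general.
    """
    counts = matrix.counts if isinstance(matrix, ContingencyMatrix) else np.asarray(matrix)
    if counts.size == 0:
        return 0
    order = np.argsort(-counts.max(axis=1), kind="stable")
    used_cols: set[int] = set()
    total = 0
    for r in order:
        candidates = [
            (counts[r, c], -c) for c in range(counts.shape[1]) if c not in used_cols
        ]
        if not candidates:
            break
        val, negc = max(candidates)
        if val > 0:
            used_cols.add(-negc)
            total += int(val)
    return total


def _ascribed_by_tip(
    ascription: StrainAscription, records: Sequence[IndividualRecord]
) -> list[str]:
    out = []
    for r in records:
        try:
            out.append(ascription.by_tip[r.tip_id])
        except KeyError:
            raise ValueError(
                f"record {r.tip_id!r} has no ascribed label in this PSC"
            ) from None
    return out


def wia_score(
    ascription: StrainAscription,
    records: Sequence[IndividualRecord],
    per_community: Mapping[str, str] | None = None,
) -> tuple[int, int]:
    """Positive-infection accuracy (WIA) and its denominator.

    The matrix is built only over individuals that are both ascribed a
    positive strain and empirically infected; the none-token is never a
    matchable column.  By default the matching is global — one matrix
    across all communities with each empirical strain column usable once.
    Passing ``per_community`` (tip id -> community name) switches to
    per-community matching, summing the community scores; empirical
    strains shared between communities may then be credited in each.
    """
    ascribed = _ascribed_by_tip(ascription, records)
    denominator = sum(1 for r in records if r.infected)
    pairs = [
        (a, r.empirical_strain, r.tip_id)
        for a, r in zip(ascribed, records)
        if a != UNINFECTED and r.infected
    ]
    if not pairs:
        return 0, denominator
    if per_community is None:
        m = build_contingency([p[0] for p in pairs], [p[1] for p in pairs])
        return constrained_match_score(m), denominator
    score = 0
    comms = sorted({per_community[t] for _, _, t in pairs})
    for comm in comms:
        sub = [p for p in pairs if per_community[p[2]] == comm]
        m = build_contingency([p[0] for p in sub], [p[1] for p in sub])
        score += constrained_match_score(m)
    return score, denominator


def uwia_score(
    ascription: StrainAscription, records: Sequence[IndividualRecord]
) -> tuple[int, int]:
    """Uninfected accuracy (uWIA): predicted-uninfected hits over the
    empirically uninfected count."""
    ascribed = _ascribed_by_tip(ascription, records)
    hits = sum(
        1
        for a, r in zip(ascribed, records)
        if a == UNINFECTED and not r.infected
    )
    denominator = sum(1 for r in records if not r.infected)
    return hits, denominator


def score_report(
    psc: PSC,
    ascription: StrainAscription,
    records: Sequence[IndividualRecord],
) -> ScoreReport:
    """All three accuracy counts for one (PSC, ascription) pair."""
    wia, wd = wia_score(ascription, records)
    uwia, ud = uwia_score(ascription, records)
    pacc, pdenom = psc_accuracy_score(psc, records)
    return ScoreReport(
        wia=wia,
        wia_denominator=wd,
        uwia=uwia,
        uwia_denominator=ud,
        psc_accuracy=pacc,
        psc_denominator=pdenom,
    )


def psc_accuracy_score(
    psc: PSC, records: Sequence[IndividualRecord]
) -> tuple[int, int]:
    """Delimitation accuracy: putative species against empirical species.

    Same constrained matching, rows = putative species, columns =
    empirical species; denominator = all individuals.
    """
    tip_to_psp: dict[str, tuple] = {}
    for sp in psc.all_species():
        for tip in sp.member_tips:
            tip_to_psp[tip] = sp.key()
    ascribed = []
    for r in records:
        if r.tip_id not in tip_to_psp:
            raise ValueError(f"record {r.tip_id!r} not covered by the PSC")
        ascribed.append(tip_to_psp[r.tip_id])
    m = build_contingency(ascribed, [r.empirical_species for r in records])
    return constrained_match_score(m), len(records)
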