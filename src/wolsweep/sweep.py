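"""Full experiment orchestration: every PSC x every purge threshold.

For each delimitation hypothesis (PSC) and each purge threshold the
pipeline ascribes strains under contact contingency, applies the
adaptive-decay purge, and scores WIA, uWIA and PSC accuracy against the
empirical typing.  Statistical evaluation (OLS regression of accuracy
relationships, a label-shuffling null, Welch's t-test) operates on the
resulting table.

The sweep factorises work by community: a community's putative-species
distances, purge survivals and per-threshold contingency rows depend
only on its own hosts' compositions, so they are precomputed once per
community-level combination and reassembled per global PSC.  Only the
global WIA matching (empirical strain columns usable once across the
whole study) is solved per (PSC, threshold).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment
from scipy import stats

from .ascription import PURGE_DISABLED
from .design import IndividualRecord, StudyDesign, validate_records
from .enumeration import attach_members, enumerate_host_pscs
from .io import PhyloDistances, check_tips_match, patristic_matrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepResult:
    """One row per (psc_id, threshold) with all accuracy metrics."""

    frame: pd.DataFrame
    thresholds: tuple[float | None, ...]
    wia_denominator: int
    uwia_denominator: int

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def best_wia_row(self) -> pd.Series:
        return self.frame.loc[self.frame["wia"].idxmax()]


class _CommunityPlan:
    """Per-community precomputation shared across the global sweep."""

    def __init__(
        self,
        community,
        design: StudyDesign,
        records: Sequence[IndividualRecord],
        dist: PhyloDistances,
        strain_index: dict[str, int],
        species_index: dict[str, int],
    ) -> None:
        self.name = community.name
        self.hosts = community.host_figs
        tip_idx = {lab: i for i, lab in enumerate(dist.labels)}

        # candidate putative species per host, keyed by (host_pos, psp_pos)
        self.host_comps: list[list[tuple[int, ...]]] = []  # composition as psp ids
        psp_members: list[np.ndarray] = []
        psp_strain_counts: list[np.ndarray] = []
        psp_species_counts: list[np.ndarray] = []
        psp_none_counts: list[int] = []
        psp_sizes: list[int] = []
        self._psp_registry: dict[tuple[str, tuple[int, ...]], int] = {}
        recs_by_tip = {r.tip_id: r for r in records}

        def register(sp) -> int:
            key = sp.key()
            if key in self._psp_registry:
                return self._psp_registry[key]
            pid = len(psp_members)
            self._psp_registry[key] = pid
            members = np.array(
                sorted(tip_idx[t] for t in sp.member_tips), dtype=int
            )
            psp_members.append(members)
            sc = np.zeros(len(strain_index), dtype=int)
            spc = np.zeros(len(species_index), dtype=int)
            none = 0
            for t in sp.member_tips:
                r = recs_by_tip[t]
                if r.infected:
                    sc[strain_index[r.empirical_strain]] += 1
                else:
                    none += 1
                spc[species_index[r.empirical_species]] += 1
            psp_strain_counts.append(sc)
            psp_species_counts.append(spc)
            psp_none_counts.append(none)
            psp_sizes.append(len(sp.member_tips))
            return pid

        for host in self.hosts:
            comps = enumerate_host_pscs(host.n_sites)
            comp_ids = []
            for comp in comps:
                ids = tuple(
                    register(
                        attach_members(host.name, host.elevation_sites, occ, records)
                    )
                    for occ in comp
                )
                comp_ids.append(ids)
            self.host_comps.append(comp_ids)
        self.radices = [len(c) for c in self.host_comps]
        self.n_local = int(np.prod(self.radices))

        self.psp_strain_counts = np.array(psp_strain_counts, dtype=int)
        self.psp_species_counts = np.array(psp_species_counts, dtype=int)
        self.psp_none_counts = np.array(psp_none_counts, dtype=int)
        self.psp_sizes = np.array(psp_sizes, dtype=int)

        # pairwise min-linkage distances among every candidate psp
        k = len(psp_members)
        self.psp_dist = np.zeros((k, k), dtype=float)
        for i in range(k):
            for j in range(i + 1, k):
                sub = dist.matrix[np.ix_(psp_members[i], psp_members[j])]
                d = float(sub.min()) if sub.size else np.inf
                self.psp_dist[i, j] = self.psp_dist[j, i] = d

    def local_combos(self) -> list[tuple[int, ...]]:
        """psp-id tuples for every community-level combination, in mixed-radix
        order over this community's hosts (last host fastest)."""
        out = []
        for choice in itertools.product(*[range(r) for r in self.radices]):
            ids: tuple[int, ...] = ()
            for host_pos, comp_idx in enumerate(choice):
                ids = ids + self.host_comps[host_pos][comp_idx]
            out.append(ids)
        return out

    def precompute(
        self, thresholds: Sequence[float | None]
    ) -> tuple[list[dict], np.ndarray]:
        """For each local combo: psc-accuracy part, per-threshold WIA rows
        and uWIA hit counts."""
        combos = self.local_combos()
        cache = []
        for ids in combos:
            ids_arr = np.array(ids, dtype=int)
            infected = len(ids) >= 2
            spm = self.psp_species_counts[ids_arr]
            ri, ci = linear_sum_assignment(spm, maximize=True)
            psc_part = int(spm[ri, ci].sum())
            wia_rows: list[np.ndarray] = []
            uwia_hits: list[int] = []
            if infected:
                d = self.psp_dist[np.ix_(ids_arr, ids_arr)].copy()
                np.fill_diagonal(d, np.inf)
                nearest = d.min(axis=1)
                for thr in thresholds:
                    if thr is PURGE_DISABLED:
                        survive = np.ones(len(ids), dtype=bool)
                    else:
                        survive = ~(nearest > thr)
                    wia_rows.append(self.psp_strain_counts[ids_arr[survive]])
                    uwia_hits.append(
                        int(self.psp_none_counts[ids_arr[~survive]].sum())
                    )
            else:
                empty = np.zeros((0, self.psp_strain_counts.shape[1]), dtype=int)
                all_none = int(self.psp_none_counts[ids_arr].sum())
                for _ in thresholds:
                    wia_rows.append(empty)
                    uwia_hits.append(all_none)
            cache.append(
                {
                    "psc_part": psc_part,
                    "n_species": len(ids),
                    "wia_rows": wia_rows,
                    "uwia_hits": np.array(uwia_hits, dtype=int),
                }
            )
        return cache, np.array([c["uwia_hits"] for c in cache])


def run_sweep(
    tree: dendropy.Tree | PhyloDistances,
    records: Sequence[IndividualRecord],
    design: StudyDesign,
    thresholds: Sequence[float | None],
    out_path: str | Path | None = None,
    progress: bool = False,
) -> SweepResult:
    """Score every PSC at every purge threshold.

    ``thresholds`` normally comes from
    :func:`wolsweep.ascription.threshold_grid` (first entry the disabled
    sentinel).  The result is deterministic given the inputs; the table
    can be streamed to ``out_path`` as CSV.
    """
    validate_records(records, design)
    dist = tree if isinstance(tree, PhyloDistances) else patristic_matrix(tree)
    check_tips_match(records, dist)

    strains = sorted({r.empirical_strain for r in records if r.infected})
    species = sorted({r.empirical_species for r in records})
    strain_index = {s: i for i, s in enumerate(strains)}
    species_index = {s: i for i, s in enumerate(species)}
    wia_denom = sum(1 for r in records if r.infected)
    uwia_denom = len(records) - wia_denom

    plans = [
        _CommunityPlan(comm, design, records, dist, strain_index, species_index)
        for comm in design.communities
    ]
    caches = [plan.precompute(thresholds)[0] for plan in plans]
    n_thresholds = len(thresholds)

    rows: list[tuple] = []
    total = int(np.prod([p.n_local for p in plans]))
    log.info("sweeping %d PSCs x %d thresholds", total, n_thresholds)
    psc_id = 0
    host_names = [h.name for p in plans for h in p.hosts]
    for combo in itertools.product(*[range(p.n_local) for p in plans]):
        entries = [caches[c][combo[c]] for c in range(len(plans))]
        psc_acc = sum(e["psc_part"] for e in entries)
        n_species = sum(e["n_species"] for e in entries)
        wia_per_t = np.zeros(n_thresholds, dtype=int)
        uwia_per_t = np.zeros(n_thresholds, dtype=int)
        for t in range(n_thresholds):
            mats = [e["wia_rows"][t] for e in entries if e["wia_rows"][t].size]
            if mats:
                stacked = np.vstack(mats)
                ri, ci = linear_sum_assignment(stacked, maximize=True)
                wia_per_t[t] = int(stacked[ri, ci].sum())
            uwia_per_t[t] = sum(int(e["uwia_hits"][t]) for e in entries)
        base_uwia = uwia_per_t[0]
        base_wia = wia_per_t[0]
        for t, thr in enumerate(thresholds):
            improvement = int(uwia_per_t[t] - base_uwia)
            no_loss = improvement if wia_per_t[t] >= base_wia else 0
            rows.append(
                (
                    psc_id,
                    t,
                    np.nan if thr is PURGE_DISABLED else float(thr),
                    int(wia_per_t[t]),
                    int(uwia_per_t[t]),
                    psc_acc,
                    improvement,
                    no_loss,
                    n_species,
                )
            )
        psc_id += 1
        if progress and psc_id % 1024 == 0:
            log.info("  %d / %d PSCs done", psc_id, total)

    frame = pd.DataFrame(
        rows,
        columns=[
            "psc_id",
            "threshold_index",
            "threshold",
            "wia",
            "uwia",
            "psc_accuracy",
            "uwia_improvement",
            "uwia_improvement_no_wia_loss",
            "n_species",
        ],
    )
    frame["wia_denominator"] = wia_denom
    frame["uwia_denominator"] = uwia_denom
    frame["psc_denominator"] = len(records)
    result = SweepResult(
        frame=frame,
        thresholds=tuple(thresholds),
        wia_denominator=wia_denom,
        uwia_denominator=uwia_denom,
    )
    if out_path is not None:
        result.to_csv(out_path)
    return result


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    adj_r_squared: float
    f_statistic: float
    p_value: float
    n: int


_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda y: y,
    "cube": lambda y: y**3,
}


def regress(
    sweep: SweepResult | pd.DataFrame,
    response: str,
    predictor: str,
    transform: str | Callable[[np.ndarray], np.ndarray] = "identity",
) -> RegressionResult:
    """OLS of transform(response) on predictor over the sweep table.

    ``transform='cube'`` is the variance-stabilising choice for accuracy
    counts (picked from residual diagnostics); adjusted R^2 uses the
    standard n-and-parameters correction.
    """
    frame = sweep.frame if isinstance(sweep, SweepResult) else sweep
    if len(frame) < 3:
        raise ValueError("regression needs at least 3 rows")
    x = frame[predictor].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    fn = _TRANSFORMS[transform] if isinstance(transform, str) else transform
    y = fn(frame[response].to_numpy(dtype=float))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adj_r_squared=float(model.rsquared_adj),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=len(frame),
    )


def randomized_null(
    records: Sequence[IndividualRecord],
    seed: int,
    mode: str = "strain",
) -> list[IndividualRecord]:
    """Shuffled copy of the metadata for the null comparison.

    ``mode='strain'`` permutes empirical strain labels across individuals
    (uniform seeded permutation, multiset preserved); ``mode='clade'``
    permutes (species, strain) pairs jointly, breaking the tree-to-label
    association while keeping species/strain co-occurrence.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    out = []
    for i, r in enumerate(records):
        src = records[perm[i]]
        if mode == "strain":
            out.append(
                IndividualRecord(
                    tip_id=r.tip_id,
                    host_fig=r.host_fig,
                    elevation_site=r.elevation_site,
                    empirical_species=r.empirical_species,
                    empirical_strain=src.empirical_strain,
                )
            )
        elif mode == "clade":
            out.append(
                IndividualRecord(
                    tip_id=r.tip_id,
                    host_fig=r.host_fig,
                    elevation_site=r.elevation_site,
                    empirical_species=src.empirical_species,
                    empirical_strain=src.empirical_strain,
                )
            )
        else:
            raise ValueError(f"unknown null mode {mode!r}")
    return out


def two_sample_t(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
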