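"""Pairwise clonotype sharing, public-clonotype detection, and the
power-law-normalized sharing statistic.

The number of clonotypes Y shared between two repertoires grows with the
number of clonotypes sampled from each: across unrelated donors Y is well
described by Y = aX², with X the repertoire size.  Sharing between samples
of unequal depth is therefore compared on the normalized scale

    NormY_ij = Y_ij / ((X_i + X_j)/2)²

which estimates the constant a.  Pairs can share zero clonotypes, so a
pseudocount ψ (default 0.01) is added uniformly before normalizing:

    NormψY_ij = (Y_ij + ψ) / ((X_i + X_j)/2)²

A clonotype found in two or more *different* individuals is a public
clonotype; one recurring only across samples of a single individual (e.g.
at different timepoints) is a within-individual shared clonotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import pandas as pd
from scipy import stats

from .clonotyping import Repertoire
from .types import ConfigurationError, DegenerateInputError, InputError, SampleMeta

__all__ = [
    "SharingResult",
    "PublicClonotype",
    "PublicReport",
    "shared_count",
    "normalize_sharing",
    "pairwise_sharing",
    "find_public",
    "sharing_per_donor",
    "export_sharing_graph",
    "compare_sharing_groups",
    "GroupTestResult",
]

Relation = Literal["within_individual", "between_individual"]


@dataclass(frozen=True)
class SharingResult:
    """Sharing between one unordered sample pair.

    Y is the size of the clonotype-key intersection; X_i and X_j the unique
    clonotype counts of the two members; norm_Y and norm_psi_Y the
    normalized statistics without and with the pseudocount.  ``relation``
    is ``within_individual`` when both samples come from the same person.
    """

    sample_i: str
    sample_j: str
    Y: int
    X_i: int
    X_j: int
    norm_Y: float
    norm_psi_Y: float
    relation: Relation


@dataclass(frozen=True)
class PublicClonotype:
    """A clonotype key with the individuals/samples/timepoints carrying it.

    ``individuals`` has >= 2 members for a public clonotype; exactly 1 for
    a within-individual shared clonotype (same key in >= 2 samples of one
    person).  ``v_calls`` reports observed gene usage without being part of
    clonal identity.
    """

    key: str
    individuals: frozenset[str]
    samples: frozenset[str]
    timepoints: frozenset[int]
    v_calls: frozenset[str]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


class PublicReport(NamedTuple):
    """Public clonotypes plus the complementary within-individual set."""

    public: list[PublicClonotype]
    within_individual: list[PublicClonotype]


def shared_count(rep_i: Repertoire, rep_j: Repertoire) -> int:
    """Size of the clonotype-key intersection of two repertoires.

    Both repertoires must have been collapsed with the same key mode;
    intersecting CDR3-only keys with V+CDR3 keys would silently undercount.
    """
    if rep_i.key_mode != rep_j.key_mode:
        raise ConfigurationError(
            f"key_mode mismatch: {rep_i.sample_id!r} uses {rep_i.key_mode!r}, "
            f"{rep_j.sample_id!r} uses {rep_j.key_mode!r}"
        )
    return len(rep_i.keys() & rep_j.keys())


def normalize_sharing(Y: int, X_i: int, X_j: int, pseudocount: float = 0.01) -> float:
    """(Y + ψ) / ((X_i + X_j)/2)² — the power-law-normalized sharing count.

    ``pseudocount=0`` gives the un-shifted NormY.  Zero-size repertoires
    make the statistic undefined and raise rather than return NaN.
    """
    if X_i <= 0 or X_j <= 0:
        raise DegenerateInputError(
            f"normalization undefined for empty repertoire (X_i={X_i}, X_j={X_j})"
        )
    if pseudocount < 0:
        raise InputError(f"pseudocount must be >= 0, got {pseudocount}")
    mean_X = (X_i + X_j) / 2.0
    return (Y + pseudocount) / (mean_X * mean_X)


def _meta_map(meta: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


def pairwise_sharing(
    reps: Sequence[Repertoire],
    meta: Iterable[SampleMeta],
    pseudocount: float = 0.01,
) -> list[SharingResult]:
    """Sharing statistics for every unordered pair of repertoires.

    n repertoires yield exactly n(n-1)/2 results (self-pairs excluded),
    ordered by (sample_i, sample_j) with each pair's members sorted, so
    output is deterministic and symmetric by construction.
    """
    by_id = _meta_map(meta)
    for rep in reps:
        if rep.sample_id not in by_id:
            raise InputError(f"no metadata for sample {rep.sample_id!r}")
        if rep.X == 0:
            raise DegenerateInputError(
                f"sample {rep.sample_id!r} has no clonotypes; "
                "sharing normalization is undefined"
            )
    results = []
    for rep_i, rep_j in combinations(sorted(reps, key=lambda r: r.sample_id), 2):
        Y = shared_count(rep_i, rep_j)
        relation: Relation = (
            "within_individual"
            if by_id[rep_i.sample_id].individual_id == by_id[rep_j.sample_id].individual_id
            else "between_individual"
        )
        results.append(
            SharingResult(
                sample_i=rep_i.sample_id,
                sample_j=rep_j.sample_id,
                Y=Y,
                X_i=rep_i.X,
                X_j=rep_j.X,
                norm_Y=normalize_sharing(Y, rep_i.X, rep_j.X, pseudocount=0.0),
                norm_psi_Y=normalize_sharing(Y, rep_i.X, rep_j.X, pseudocount),
                relation=relation,
            )
        )
    return results


def find_public(
    reps: Sequence[Repertoire],
    meta: Iterable[SampleMeta],
    min_individuals: int = 2,
    timepoint_filter: Optional[set[int]] = None,
) -> PublicReport:
    """Classify every multi-sample clonotype as public or within-individual.

    A key carried by >= ``min_individuals`` distinct individuals (among the
    samples passing ``timepoint_filter``, when given) is public.  A key
    carried by >= 2 samples of exactly one individual is within-individual
    shared.  Keys seen in a single sample appear in neither list.
    """
    if min_individuals < 2:
        raise InputError(f"min_individuals must be >= 2, got {min_individuals}")
    by_id = _meta_map(meta)
    key_mode = {rep.key_mode for rep in reps}
    if len(key_mode) > 1:
        raise ConfigurationError(f"mixed key modes in repertoires: {sorted(key_mode)}")

    carriers: dict[str, set[str]] = {}
    for rep in reps:
        m = by_id.get(rep.sample_id)
        if m is None:
            raise InputError(f"no metadata for sample {rep.sample_id!r}")
        if timepoint_filter is not None and m.timepoint_days not in timepoint_filter:
            continue
        for key in rep.clonotypes:
            carriers.setdefault(key, set()).add(rep.sample_id)

    public, within = [], []
    for key in sorted(carriers):
        samples = carriers[key]
        if len(samples) < 2:
            continue
        individuals = {by_id[s].individual_id for s in samples}
        v_calls: set[str] = set()
        timepoints = {by_id[s].timepoint_days for s in samples}
        for rep in reps:
            if rep.sample_id in samples:
                v_calls |= set(rep.v_annotations.get(key, ()))
        clone = PublicClonotype(
            key=key,
            individuals=frozenset(individuals),
            samples=frozenset(samples),
            timepoints=frozenset(timepoints),
            v_calls=frozenset(v_calls),
        )
        if len(individuals) >= min_individuals:
            public.append(clone)
        elif len(individuals) == 1:
            within.append(clone)
    return PublicReport(public=public, within_individual=within)


def sharing_per_donor(
    reps: Sequence[Repertoire],
    meta: Iterable[SampleMeta],
    timepoints: Optional[set[int]] = None,
) -> pd.DataFrame:
    """Per-individual, per-timepoint counts of cross-donor shared clonotypes.

    For each individual and timepoint: how many of their clonotype keys are
    also carried by some *other* individual's sample at that timepoint.  A
    key shared by donors P and Q contributes 1 to each.

    Returns a DataFrame with columns individual_id, timepoint_days,
    shared_count, sorted for deterministic output.
    """
    by_id = _meta_map(meta)
    all_tps = sorted({by_id[r.sample_id].timepoint_days for r in reps
                      if r.sample_id in by_id})
    use_tps = sorted(timepoints) if timepoints is not None else all_tps

    rows = []
    for tp in use_tps:
        at_tp = [r for r in reps if by_id[r.sample_id].timepoint_days == tp]
        keys_by_ind: dict[str, set[str]] = {}
        for rep in at_tp:
            ind = by_id[rep.sample_id].individual_id
            keys_by_ind.setdefault(ind, set()).update(rep.clonotypes)
        for ind in sorted(keys_by_ind):
            others: set[str] = set()
            for other_ind, keys in keys_by_ind.items():
                if other_ind != ind:
                    others |= keys
            rows.append(
                {
                    "individual_id": ind,
                    "timepoint_days": tp,
                    "shared_count": len(keys_by_ind[ind] & others),
                }
            )
    return pd.DataFrame(rows, columns=["individual_id", "timepoint_days", "shared_count"])


def export_sharing_graph(
    reps: Sequence[Repertoire],
    meta: Iterable[SampleMeta],
    timepoint_filter: Optional[set[int]] = None,
) -> pd.DataFrame:
    """Edge list of clonotype-sharing links for Circos-style plots.

    One edge per (sample pair, shared key): a key present in k samples
    yields k(k-1)/2 edges.  Columns: sample_i, sample_j, key, relation;
    rows sorted lexicographically for deterministic output.
    """
    by_id = _meta_map(meta)
    carriers: dict[str, list[str]] = {}
    for rep in reps:
        m = by_id.get(rep.sample_id)
        if m is None:
            raise InputError(f"no metadata for sample {rep.sample_id!r}")
        if timepoint_filter is not None and m.timepoint_days not in timepoint_filter:
            continue
        for key in rep.clonotypes:
            carriers.setdefault(key, []).append(rep.sample_id)

    rows = []
    for key in sorted(carriers):
        samples = sorted(set(carriers[key]))
        for s_i, s_j in combinations(samples, 2):
            relation = (
                "within_individual"
                if by_id[s_i].individual_id == by_id[s_j].individual_id
                else "between_individual"
            )
            rows.append({"sample_i": s_i, "sample_j": s_j, "key": key,
                         "relation": relation})
    df = pd.DataFrame(rows, columns=["sample_i", "sample_j", "key", "relation"])
    return df.sort_values(["sample_i", "sample_j", "key"], ignore_index=True)


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of a between-group comparison, labeled with the test used."""

    test: str
    statistic: float
    pvalue: float
    group_sizes: tuple[int, ...]


def compare_sharing_groups(
    groups: dict[str, Sequence[float]],
    test: Literal["kruskal_wallis", "unpaired_t", "mann_whitney"] = "kruskal_wallis",
) -> GroupTestResult:
    """Compare sharing statistics (NormψY values or counts) between groups.

    A thin, explicitly-labeled wrapper over scipy.stats so pipeline reports
    state which test produced each p-value.  ``unpaired_t`` and
    ``mann_whitney`` require exactly two groups; the t test additionally
    needs >= 2 observations per group to estimate variances.
    """
    if len(groups) < 2:
        raise InputError(f"need >= 2 groups, got {len(groups)}")
    names = sorted(groups)
    values = [list(map(float, groups[name])) for name in names]
    if any(len(v) == 0 for v in values):
        empty = [n for n, v in zip(names, values) if not v]
        raise InputError(f"empty group(s): {empty}")

    if test == "kruskal_wallis":
        try:
            stat, p = stats.kruskal(*values)
        except ValueError:
            stat, p = math.nan, math.nan
        if math.isnan(stat):
            # All observations identical across groups: no rank variance,
            # which is the null case.
            stat, p = 0.0, 1.0
    elif test == "unpaired_t":
        if len(values) != 2:
            raise InputError("unpaired_t requires exactly 2 groups")
        if any(len(v) < 2 for v in values):
            raise InputError("unpaired_t requires >= 2 observations per group")
        stat, p = stats.ttest_ind(values[0], values[1])
    elif test == "mann_whitney":
        if len(values) != 2:
            raise InputError("mann_whitney requires exactly 2 groups")
        # exact permutation null for small samples, asymptotic otherwise
        method = "exact" if max(map(len, values)) <= 8 else "asymptotic"
        stat, p = stats.mannwhitneyu(values[0], values[1],
                                     alternative="two-sided", method=method)
    else:
        raise InputError(f"unknown test {test!r}")
    return GroupTestResult(
        test=test,
        statistic=float(stat),
        pvalue=float(p),
        group_sizes=tuple(len(v) for v in values),
    )
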