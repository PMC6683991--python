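"""IgHG clonotype filtering and somatic-hypermutation (SHM) profiling.

Antibody-secreting cells that arise directly from memory B cells outside
the germinal center carry fewer V-region mutations than germinal-center
emigrants.  This module summarizes per-clonotype mutation counts (FR1-FR3,
CDR3 excluded — counted upstream against germline; this package never
aligns sequences) into five-bin histograms and a headline "percentage of
clonotypes with <= 10 mutations", and splits individuals into high/low
antibody responders by their titer rise.

All summaries are clonotype-weighted: each clonotype counts once however
many reads support it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from scipy import stats

from .types import ClonotypeRecord, DegenerateInputError, InputError

__all__ = [
    "DEFAULT_BIN_EDGES",
    "IgClonotype",
    "MutationProfile",
    "ResponderLabel",
    "PairedDeltaResult",
    "filter_ig",
    "mutation_histogram",
    "low_mutation_pct",
    "paired_low_mutation_change",
    "label_responders",
]

logger = logging.getLogger(__name__)

#: Closed integer mutation-count bins; the upper edge of the last bin is
#: open-ended.  The 6-10 boundary aligns with the <= 10 headline cutoff.
DEFAULT_BIN_EDGES: tuple[tuple[int, Optional[int]], ...] = (
    (0, 5),
    (6, 10),
    (11, 15),
    (16, 20),
    (21, None),
)


@dataclass(frozen=True)
class IgClonotype:
    """An IgHG clonotype retained by the quality filter."""

    key: str
    isotype: str
    productive: bool
    complete_v: bool
    v_mutations: int
    fraction: float


@dataclass(frozen=True)
class MutationProfile:
    """Binned mutation histogram plus the low-mutation headline fraction."""

    bin_edges: tuple[tuple[int, Optional[int]], ...]
    bin_fractions: tuple[float, ...]
    pct_low: float
    low_cutoff: int
    n_clonotypes: int


@dataclass(frozen=True)
class ResponderLabel:
    """High/low antibody-responder call from the titer rise (day 84 - day 0)."""

    individual_id: str
    delta_titer: float
    label: str  # "high" | "low"


@dataclass(frozen=True)
class PairedDeltaResult:
    """Per-individual pct_low changes with a paired t test on the deltas."""

    deltas: dict[str, float]
    mean_delta: float
    statistic: float
    pvalue: float
    n_pairs: int
    zero_variance: bool
    unmatched: tuple[str, ...]


def filter_ig(records: Iterable[ClonotypeRecord]) -> list[IgClonotype]:
    """Keep productive, complete-V, IGHG* clonotypes; log removal tallies.

    Records must carry isotype/productive/complete_v annotations — a table
    without them cannot be filtered, so missing fields raise rather than
    silently pass.  Read fractions are computed over the *retained* set.
    """
    records = list(records)
    removed = {"non_productive": 0, "incomplete_v": 0, "non_ighg": 0}
    kept: list[ClonotypeRecord] = []
    for r in records:
        if r.productive is None or r.complete_v is None or r.isotype is None:
            raise InputError(
                f"record {r.cdr3_aa!r} lacks isotype/productive/complete_v "
                "annotations required for IgHG filtering"
            )
        if not r.productive:
            removed["non_productive"] += 1
        elif not r.complete_v:
            removed["incomplete_v"] += 1
        elif not r.isotype.upper().startswith("IGHG"):
            removed["non_ighg"] += 1
        else:
            kept.append(r)
    if any(removed.values()):
        logger.info("filter_ig removed %s of %d records", removed, len(records))

    total = sum(r.read_count for r in kept)
    out = []
    for r in kept:
        if r.v_mutations is None:
            raise InputError(f"record {r.cdr3_aa!r} lacks a v_mutations count")
        out.append(
            IgClonotype(
                key=r.cdr3_aa,
                isotype=r.isotype,
                productive=True,
                complete_v=True,
                v_mutations=r.v_mutations,
                fraction=(r.read_count / total) if total else 0.0,
            )
        )
    return out


def _bin_index(
    value: int, edges: Sequence[tuple[int, Optional[int]]]
) -> int:
    for i, (lo, hi) in enumerate(edges):
        if value >= lo and (hi is None or value <= hi):
            return i
    raise InputError(f"mutation count {value} falls outside bins {edges}")


def mutation_histogram(
    clonotypes: Sequence[IgClonotype],
    edges: Sequence[tuple[int, Optional[int]]] = DEFAULT_BIN_EDGES,
    low_cutoff: int = 10,
) -> MutationProfile:
    """Clonotype-weighted histogram of V-region mutation counts.

    Bins are closed integer intervals covering 0..inf exhaustively and
    exclusively (the last bin is open-ended), so every clonotype lands in
    exactly one bin and fractions sum to 1.
    """
    if not clonotypes:
        raise DegenerateInputError("mutation_histogram requires >= 1 clonotype")
    edges = tuple((int(lo), None if hi is None else int(hi)) for lo, hi in edges)
    for (lo, hi), (nlo, _) in zip(edges, edges[1:]):
        if hi is None or nlo != hi + 1:
            raise InputError(f"bins {edges} are not contiguous closed intervals")
    counts = [0] * len(edges)
    for c in clonotypes:
        counts[_bin_index(c.v_mutations, edges)] += 1
    n = len(clonotypes)
    return MutationProfile(
        bin_edges=edges,
        bin_fractions=tuple(c / n for c in counts),
        pct_low=low_mutation_pct(clonotypes, cutoff=low_cutoff),
        low_cutoff=low_cutoff,
        n_clonotypes=n,
    )


def low_mutation_pct(clonotypes: Sequence[IgClonotype], cutoff: int = 10) -> float:
    """100 x fraction of clonotypes with v_mutations <= cutoff (inclusive)."""
    if not clonotypes:
        raise DegenerateInputError("low_mutation_pct requires >= 1 clonotype")
    n_low = sum(1 for c in clonotypes if c.v_mutations <= cutoff)
    return 100.0 * n_low / len(clonotypes)


ProfileOrPct = Union[MutationProfile, float]


def _pct(value: ProfileOrPct) -> float:
    return value.pct_low if isinstance(value, MutationProfile) else float(value)


def paired_low_mutation_change(
    day0: Mapping[str, ProfileOrPct],
    post: Mapping[str, ProfileOrPct],
) -> PairedDeltaResult:
    """Per-individual change in pct_low with a paired two-sided t test.

    delta = pct_low(post) - pct_low(day0), paired on individual_id.
    Individuals present at only one timepoint are excluded with a warning
    and listed in ``unmatched``.  When every delta is identical the t
    statistic is undefined (zero variance); the all-zero case is reported
    as the exact null (p = 1) with ``zero_variance`` flagged.
    """
    shared = sorted(set(day0) & set(post))
    unmatched = tuple(sorted(set(day0) ^ set(post)))
    if unmatched:
        logger.warning("paired_low_mutation_change: excluding unmatched "
                       "individuals %s", unmatched)
    if len(shared) < 2:
        raise InputError(
            f"paired test needs >= 2 complete pairs, got {len(shared)}"
        )
    deltas = {ind: _pct(post[ind]) - _pct(day0[ind]) for ind in shared}
    vals = [deltas[ind] for ind in shared]
    mean_delta = sum(vals) / len(vals)
    var = sum((v - mean_delta) ** 2 for v in vals)
    if var == 0.0:
        # Degenerate: identical deltas leave the t statistic undefined.
        pvalue = 1.0 if mean_delta == 0.0 else 0.0
        return PairedDeltaResult(
            deltas=deltas, mean_delta=mean_delta,
            statistic=0.0 if mean_delta == 0.0 else math.inf,
            pvalue=pvalue, n_pairs=len(shared), zero_variance=True,
            unmatched=unmatched,
        )
    stat, p = stats.ttest_rel([_pct(post[i]) for i in shared],
                              [_pct(day0[i]) for i in shared])
    return PairedDeltaResult(
        deltas=deltas, mean_delta=mean_delta, statistic=float(stat),
        pvalue=float(p), n_pairs=len(shared), zero_variance=False,
        unmatched=unmatched,
    )


def label_responders(
    titers: Mapping[str, Mapping[int, float]],
    cutoff: float = 500.0,
    day_pre: int = 0,
    day_post: int = 84,
) -> list[ResponderLabel]:
    """Split individuals by antibody-titer rise (default: > 500 AU gain
    between day 0 and day 84 makes a high responder; the boundary itself
    is low).

    ``titers`` maps individual_id -> {day: AU}.  Individuals missing either
    timepoint are excluded with a warning.
    """
    labels = []
    for ind in sorted(titers):
        t = titers[ind]
        if day_pre not in t or day_post not in t:
            logger.warning("label_responders: individual %s missing day %d or "
                           "%d titer; excluded", ind, day_pre, day_post)
            continue
        delta = float(t[day_post]) - float(t[day_pre])
        labels.append(
            ResponderLabel(
                individual_id=ind,
                delta_titer=delta,
                label="high" if delta > cutoff else "low",
            )
        )
    return labels
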