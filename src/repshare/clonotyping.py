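"""Amino-acid-level clonotype collapsing and clonal-expansion summaries.

Sequencing a few hundred sorted cells yields many nucleotide-level variants
that translate to the same CDR3 amino-acid sequence.  Collapsing at the
amino-acid level pools their read support; a minimum-support filter
(default: strictly more than five reads, i.e. ``min_reads=6``) then removes
keys too weakly supported to be called a clonotype.  The unique-key count X
of the filtered repertoire is the quantity the sharing normalization is
built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

from .types import ClonotypeRecord, DegenerateInputError, InputError

__all__ = [
    "KEY_SEPARATOR",
    "Repertoire",
    "CloneFrequency",
    "collapse",
    "unique_count",
    "frequencies",
    "expanded_clones",
    "top_n_profile",
    "subsample",
]

KeyMode = Literal["cdr3_aa", "v_plus_cdr3_aa"]

#: Separator between the V call and the CDR3 in ``v_plus_cdr3_aa`` keys.
#: Never occurs in an amino-acid alphabet, so the mapping is unambiguous.
KEY_SEPARATOR = "|"

#: Key for the residual-mass entry appended by :func:`top_n_profile`.
#: Lower-case, so it cannot collide with an upper-cased CDR3.
OTHER_KEY = "other"


def make_key(record: ClonotypeRecord, key_mode: KeyMode) -> str:
    if key_mode == "v_plus_cdr3_aa":
        return f"{record.v_call}{KEY_SEPARATOR}{record.cdr3_aa}"
    return record.cdr3_aa


@dataclass
class Repertoire:
    """Collapsed clonotype set for one sample.

    ``clonotypes`` maps the clonotype key (CDR3 amino-acid string, or
    ``V|CDR3`` under ``key_mode='v_plus_cdr3_aa'``) to its aggregated read
    count.  ``v_annotations`` records every V call observed for a key even
    when the V gene is not part of clonal identity, so gene usage can be
    reported per shared clonotype.
    """

    sample_id: str
    clonotypes: dict[str, int]
    key_mode: KeyMode = "cdr3_aa"
    min_reads: int = 6
    v_annotations: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.clonotypes.values())

    @property
    def X(self) -> int:
        """Number of unique clonotypes (distinct keys)."""
        return len(self.clonotypes)

    def keys(self) -> set[str]:
        return set(self.clonotypes)

    def sorted_keys(self) -> list[str]:
        """Keys by descending count, ties lexicographic — the package-wide
        deterministic ordering."""
        return sorted(self.clonotypes, key=lambda k: (-self.clonotypes[k], k))

    def split_key(self, key: str) -> tuple[str, str]:
        """Return (cdr3_aa, v_call) for a key; v_call is the annotation's
        sole V when identity is CDR3-only and unambiguous."""
        if self.key_mode == "v_plus_cdr3_aa":
            v, cdr3 = key.split(KEY_SEPARATOR, 1)
            return cdr3, v
        vs = sorted(self.v_annotations.get(key, ()))
        return key, ",".join(vs)

    def as_records(self) -> list[ClonotypeRecord]:
        """Re-emit the repertoire as one record per clonotype (used by the
        collapse-idempotence property and the writers)."""
        out = []
        for key in self.sorted_keys():
            cdr3, v = self.split_key(key)
            out.append(
                ClonotypeRecord(
                    sample_id=self.sample_id,
                    cdr3_aa=cdr3,
                    read_count=self.clonotypes[key],
                    v_call=v.split(",")[0] if v else "",
                )
            )
        return out


@dataclass(frozen=True)
class CloneFrequency:
    """A clonotype key with its fraction of total repertoire reads."""

    key: str
    fraction: float


def collapse(
    records: Iterable[ClonotypeRecord],
    key_mode: KeyMode = "cdr3_aa",
    min_reads: int = 6,
    filter_before_collapse: bool = False,
) -> Repertoire:
    """Sum records by clonotype key and apply the read-support filter.

    Parameters
    ----------
    records
        Records from one sample (mixed sample_ids are an error).
    key_mode
        ``cdr3_aa`` (default) keys clones by CDR3 amino-acid sequence alone;
        ``v_plus_cdr3_aa`` additionally requires identical V calls.
    min_reads
        Minimum aggregated read support to keep a key.  The default 6 keeps
        clonotypes with *more than five* reads.
    filter_before_collapse
        When True the threshold is applied to each input record before
        pooling (sensitivity analysis); default applies it to the pooled
        amino-acid-level counts, so nucleotide variants of one clonotype
        combine their support before thresholding.

    Returns
    -------
    Repertoire
        Keys with aggregated count >= min_reads, with per-key V-call
        annotations.
    """
    records = list(records)
    if min_reads < 1:
        raise InputError(f"min_reads must be >= 1, got {min_reads}")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise InputError(
            f"collapse expects a single sample, got sample_ids {sorted(sample_ids)}"
        )
    sample_id = sample_ids.pop() if sample_ids else ""

    if filter_before_collapse:
        records = [r for r in records if r.read_count >= min_reads]

    counts: dict[str, int] = {}
    v_ann: dict[str, set[str]] = {}
    for r in records:
        key = make_key(r, key_mode)
        counts[key] = counts.get(key, 0) + r.read_count
        if r.v_call:
            v_ann.setdefault(key, set()).add(r.v_call)

    kept = {k: c for k, c in counts.items() if c >= min_reads}
    return Repertoire(
        sample_id=sample_id,
        clonotypes=kept,
        key_mode=key_mode,
        min_reads=min_reads,
        v_annotations={k: frozenset(v) for k, v in v_ann.items() if k in kept},
    )


def unique_count(rep: Repertoire) -> int:
    """Number of unique clonotypes X in the repertoire."""
    return rep.X


def frequencies(rep: Repertoire) -> list[CloneFrequency]:
    """Per-clone read fractions, descending, ties lexicographic by key.

    Raises
    ------
    DegenerateInputError
        If the repertoire has no reads (fractions undefined).
    """
    total = rep.total_reads
    if total == 0:
        raise DegenerateInputError(
            f"sample {rep.sample_id!r}: repertoire has zero reads"
        )
    return [CloneFrequency(k, rep.clonotypes[k] / total) for k in rep.sorted_keys()]


def expanded_clones(rep: Repertoire, threshold: float = 0.02) -> list[CloneFrequency]:
    """Clones at or above ``threshold`` of total reads (default 2%).

    The boundary is inclusive — a clone at exactly 2.000% counts as
    expanded.  Comparison is done on integer counts (count >= threshold *
    total) to avoid float round-off at the boundary.
    """
    if not 0 < threshold <= 1:
        raise InputError(f"threshold must be in (0, 1], got {threshold}")
    total = rep.total_reads
    if total == 0:
        raise DegenerateInputError(
            f"sample {rep.sample_id!r}: repertoire has zero reads"
        )
    out = [
        cf for cf in frequencies(rep)
        if rep.clonotypes[cf.key] >= threshold * total - 1e-9
    ]
    return out


def top_n_profile(rep: Repertoire, n: int) -> list[CloneFrequency]:
    """The ``n`` most abundant clones plus one residual ``other`` entry.

    The profile always sums to 1: the residual entry carries the read mass
    outside the top n (0 when X <= n).  Ties at rank n resolve by the
    package-wide ordering (descending count, then lexicographic key).
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    freqs = frequencies(rep)
    head = freqs[:n]
    other = 1.0 - sum(cf.fraction for cf in head)
    head.append(CloneFrequency(OTHER_KEY, max(other, 0.0)))
    return head


def subsample(rep: Repertoire, fraction: float, seed: int) -> Repertoire:
    """Uniformly subsample clonotype keys (each kept independently with
    probability ``fraction``), preserving counts of kept keys.

    Used to check that the power-law sharing normalization is invariant
    under shallower clonotype sampling.
    """
    if not 0 <= fraction <= 1:
        raise InputError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    kept = {}
    for key in sorted(rep.clonotypes):
        if rng.random() < fraction:
            kept[key] = rep.clonotypes[key]
    return Repertoire(
        sample_id=rep.sample_id,
        clonotypes=kept,
        key_mode=rep.key_mode,
        min_reads=rep.min_reads,
        v_annotations={k: v for k, v in rep.v_annotations.items() if k in kept},
    )
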