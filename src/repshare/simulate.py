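"""Seeded synthetic repertoire, sharing, SHM, and titer generators.

The generator provides a desk-scale ground truth for every analysis stage:

* per-sample repertoires of a few hundred cells with a skewed clone-size
  distribution, so unique-clonotype counts and 2%-expansion calls can be
  checked against planted truth;
* within-individual clone persistence across timepoints and planted
  cross-individual (public) clonotypes, so public-clonotype detection has
  known sensitivity/specificity;
* pair-level sharing counts drawn with E[Y] = a·((X_i+X_j)/2)², the power
  law underlying the NormY statistic;
* two-component mutation-count mixtures (low-SHM memory-derived vs
  higher-SHM components) and antibody-titer tables with planted high/low
  responders.

Private clonotype keys are random 12-mers carrying a 2-letter prefix unique
to each individual, with a separate reserved prefix for planted public
keys: chance cross-individual collisions are structurally impossible, so
any between-individual sharing the pipeline reports traces back to the
planted truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np

from .io import write_airr
from .types import AMINO_ACIDS, ClonotypeRecord, InputError, SampleMeta, Tissue

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_repertoires",
    "simulate_power_law_pairs",
    "simulate_shared_pair",
    "simulate_shm_table",
    "simulate_titers",
    "write_dataset",
]

#: Reserved 2-letter prefix for planted public clonotype keys.
PUBLIC_PREFIX = "WW"

KEY_LENGTH = 12


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort, with the study conditions as
    defaults: 8 individuals sampled at days 0/63/84, ~200 sorted cells per
    sample, 6 public clonotypes planted in 5 individuals at day 63 only.

    ``clone_size_exponent`` controls the discrete power law for cells per
    clone (truncated at ``cells_per_sample``); the default 3.3 gives a mean
    clone size of ~1.25 cells, i.e. ~160 unique clonotypes from 200 cells.
    Reads per cell are 1 + Poisson(``reads_per_cell_mean`` - 1) so the
    more-than-five-reads support filter retains nearly all true clones
    while still being exercised.
    """

    n_individuals: int = 8
    timepoints: tuple[int, ...] = (0, 63, 84)
    cells_per_sample: int = 200
    clone_size_model: Literal["power_law", "dirichlet"] = "power_law"
    clone_size_exponent: float = 3.3
    dirichlet_concentration: float = 0.5
    dirichlet_n_clones: int = 250
    reads_per_cell_mean: float = 20.0
    n_public_keys: int = 6
    public_prevalence: int = 5
    public_timepoints: tuple[int, ...] = (63,)
    public_cells: int = 2
    persistence_rate: float = 0.2
    sharing_constant_a: float = 0.001
    # SHM mixture: Poisson means of the low/high-mutation components and
    # the low-component weight at day 0 vs post-vaccination.
    shm_mean_low: float = 6.0
    shm_mean_high: float = 20.0
    shm_weight_low_day0: float = 0.3
    shm_weight_low_post: float = 0.6
    shm_clonotypes_per_sample: int = 300
    shm_post_day: int = 63
    # Titers (AU): log-normal baseline; planted high responders gain a
    # boost well past the 500 AU responder cutoff, low responders stay under.
    titer_baseline_mean_log: float = 4.0
    titer_baseline_sd_log: float = 0.5
    titer_boost_high: tuple[float, float] = (800.0, 2500.0)
    titer_boost_low: tuple[float, float] = (0.0, 300.0)
    n_high_responders: int = 7
    n_low_responders: int = 4
    min_reads: int = 6
    group: str = "GLA-SE"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.persistence_rate <= 1:
            raise InputError("persistence_rate must be in [0, 1]")
        if self.public_prevalence > self.n_individuals:
            raise InputError(
                f"public_prevalence {self.public_prevalence} exceeds "
                f"n_individuals {self.n_individuals}"
            )
        for w in (self.shm_weight_low_day0, self.shm_weight_low_post):
            if not 0 <= w <= 1:
                raise InputError("SHM mixture weights must be in [0, 1]")
        if self.cells_per_sample < 1 or self.n_individuals < 1:
            raise InputError("cells_per_sample and n_individuals must be >= 1")


@dataclass
class SimResult:
    """Synthetic dataset plus its planted truth."""

    records: list[ClonotypeRecord]
    meta: list[SampleMeta]
    truth: dict


def _individual_ids(n: int) -> list[str]:
    return [f"D{i + 1:02d}" for i in range(n)]


def _individual_prefixes(n: int) -> list[str]:
    prefixes = [a + b for a, b in product(AMINO_ACIDS, repeat=2)
                if a + b != PUBLIC_PREFIX]
    if n > len(prefixes):
        raise InputError(f"at most {len(prefixes)} individuals supported")
    return prefixes[:n]


def _random_key(rng: np.random.Generator, prefix: str) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=KEY_LENGTH - len(prefix))
    return prefix + "".join(AMINO_ACIDS[i] for i in idx)


def _draw_clone_sizes(rng: np.random.Generator, config: SimConfig) -> list[int]:
    """Cell counts per clone summing exactly to cells_per_sample."""
    n_cells = config.cells_per_sample
    if config.clone_size_model == "power_law":
        sizes_support = np.arange(1, n_cells + 1)
        p = sizes_support.astype(float) ** -config.clone_size_exponent
        p /= p.sum()
        sizes: list[int] = []
        remaining = n_cells
        while remaining > 0:
            batch = rng.choice(sizes_support, size=max(16, remaining), p=p)
            for s in batch:
                s = min(int(s), remaining)  # clip the last clone to fill exactly
                sizes.append(s)
                remaining -= s
                if remaining == 0:
                    break
        return sizes
    # dirichlet: fixed clone pool with Dirichlet proportions, multinomial cells
    props = rng.dirichlet(
        np.full(config.dirichlet_n_clones, config.dirichlet_concentration)
    )
    counts = rng.multinomial(n_cells, props)
    return [int(c) for c in counts if c > 0]


def _reads_for_cells(rng: np.random.Generator, n_cells: int,
                     mean: float) -> int:
    """Total reads over n_cells cells, each 1 + Poisson(mean - 1)."""
    lam = max(mean - 1.0, 0.0)
    return int(n_cells + rng.poisson(lam, size=n_cells).sum())


def simulate_repertoires(config: SimConfig) -> SimResult:
    """Generate one cohort of per-sample clonotype records with truth.

    Each individual owns a private key universe (distinct 2-letter
    prefix).  Public keys (reserved prefix) are planted into
    ``public_prevalence`` randomly chosen carriers at the configured
    timepoints with ``public_cells`` cells each.  Within an individual,
    each non-public clone reuses a previously seen key with probability
    ``persistence_rate``.

    Records are emitted one per clone (read support already summed over
    the clone's cells); the truth record lists every planted public key
    with its carriers and marks carriers whose sampled read support fell
    below ``config.min_reads`` as drop-outs.
    """
    rng = np.random.default_rng(config.seed)
    individuals = _individual_ids(config.n_individuals)
    prefixes = dict(zip(individuals, _individual_prefixes(config.n_individuals)))

    public_keys = sorted(
        _random_key(rng, PUBLIC_PREFIX) for _ in range(config.n_public_keys)
    )
    carriers: dict[str, list[str]] = {}
    for key in public_keys:
        chosen = rng.choice(individuals, size=config.public_prevalence,
                            replace=False)
        carriers[key] = sorted(str(c) for c in chosen)

    v_pool = [f"TRBV{i}" for i in range(1, 31)]
    key_v: dict[str, str] = {}

    records: list[ClonotypeRecord] = []
    meta: list[SampleMeta] = []
    truth_public: dict[str, dict] = {
        k: {"individuals": carriers[k], "timepoints": sorted(config.public_timepoints),
            "dropouts": []}
        for k in public_keys
    }
    truth_expanded: dict[str, list[str]] = {}
    truth_unique: dict[str, int] = {}

    for ind in individuals:
        seen_keys: list[str] = []
        for tp in config.timepoints:
            sample_id = f"{ind}_d{tp}"
            meta.append(
                SampleMeta(sample_id=sample_id, individual_id=ind,
                           timepoint_days=tp, tissue=Tissue.blood,
                           population="cTfh", group=config.group)
            )
            clone_cells: dict[str, int] = {}
            if tp in config.public_timepoints:
                for key in public_keys:
                    if ind in carriers[key]:
                        clone_cells[key] = config.public_cells
            budget = config.cells_per_sample - sum(clone_cells.values())
            sizes = _draw_clone_sizes(
                rng, replace(config, cells_per_sample=budget)
            ) if budget > 0 else []
            used = set(clone_cells)
            for s in sizes:
                # public keys never persist outside their planted timepoints,
                # so planted truth stays exact
                reusable = [k for k in seen_keys
                            if k not in used and not k.startswith(PUBLIC_PREFIX)]
                if reusable and rng.random() < config.persistence_rate:
                    key = reusable[int(rng.integers(len(reusable)))]
                else:
                    key = _random_key(rng, prefixes[ind])
                    while key in used:
                        key = _random_key(rng, prefixes[ind])
                clone_cells[key] = clone_cells.get(key, 0) + s
                used.add(key)

            sample_reads: dict[str, int] = {}
            for key in sorted(clone_cells):
                if key not in key_v:
                    key_v[key] = v_pool[int(rng.integers(len(v_pool)))]
                reads = _reads_for_cells(rng, clone_cells[key],
                                         config.reads_per_cell_mean)
                sample_reads[key] = reads
                records.append(
                    ClonotypeRecord(
                        sample_id=sample_id, cdr3_aa=key, read_count=reads,
                        v_call=key_v[key], productive=True,
                    )
                )
            seen_set = set(seen_keys)
            for key in sorted(clone_cells):
                if key not in seen_set:
                    seen_keys.append(key)
                    seen_set.add(key)

            for key, ind_list in carriers.items():
                if (ind in ind_list and tp in config.public_timepoints
                        and sample_reads.get(key, 0) < config.min_reads):
                    truth_public[key]["dropouts"].append(sample_id)
            total = sum(sample_reads.values())
            truth_expanded[sample_id] = sorted(
                k for k, r in sample_reads.items() if r >= 0.02 * total
            )
            truth_unique[sample_id] = sum(
                1 for r in sample_reads.values() if r >= config.min_reads
            )

    truth = {
        "public_keys": truth_public,
        "expanded_clones": truth_expanded,
        "unique_clonotypes": truth_unique,
        "individual_prefixes": prefixes,
        "seed": config.seed,
    }
    return SimResult(records=records, meta=meta, truth=truth)


def simulate_power_law_pairs(
    a: float,
    X_values: Sequence[int],
    noise: Literal["poisson", "none"] = "poisson",
    seed: int = 0,
    n_pairs: Optional[int] = None,
) -> list[tuple[int, int, int]]:
    """Draw (X_i, X_j, Y) triples with E[Y] = a·((X_i+X_j)/2)².

    With ``noise='none'`` Y is the rounded expectation; with ``'poisson'``
    it is Poisson-distributed around it.  ``n_pairs`` random (X_i, X_j)
    pairs are sampled from ``X_values`` (default: all ordered pairs once).
    """
    if a < 0:
        raise InputError(f"a must be >= 0, got {a}")
    if any(x <= 0 for x in X_values):
        raise InputError("X values must be > 0")
    rng = np.random.default_rng(seed)
    if n_pairs is None:
        pairs = [(int(xi), int(xj)) for xi in X_values for xj in X_values]
    else:
        xs = rng.choice(np.asarray(X_values), size=(n_pairs, 2), replace=True)
        pairs = [(int(xi), int(xj)) for xi, xj in xs]
    out = []
    for xi, xj in pairs:
        mean_Y = a * ((xi + xj) / 2.0) ** 2
        y = int(rng.poisson(mean_Y)) if noise == "poisson" else int(round(mean_Y))
        out.append((xi, xj, y))
    return out


def simulate_shared_pair(
    X_i: int, X_j: int, Y: int, seed: int = 0
) -> tuple[set[str], set[str]]:
    """Two explicit key sets of sizes X_i, X_j overlapping in exactly Y keys.

    Used by subsampling-invariance checks that need real sets, not just
    counts.
    """
    if Y > min(X_i, X_j):
        raise InputError(f"Y={Y} exceeds min(X_i, X_j)={min(X_i, X_j)}")
    rng = np.random.default_rng(seed)
    n = X_i + X_j - Y
    keys: set[str] = set()
    while len(keys) < n:
        idx = rng.integers(0, len(AMINO_ACIDS), size=(n - len(keys) + 8, KEY_LENGTH))
        for row in idx:
            keys.add("".join(AMINO_ACIDS[i] for i in row))
    pool = sorted(keys)[:n]
    shared = pool[:Y]
    only_i = pool[Y:X_i]
    only_j = pool[X_i:X_i + X_j - Y]
    return set(shared + only_i), set(shared + only_j)


def simulate_shm_table(config: SimConfig) -> tuple[list[ClonotypeRecord], dict]:
    """Annotated IgHG clonotype tables with a two-component SHM mixture.

    For every individual, a day-0 and a post-vaccination (``shm_post_day``)
    sample of ``shm_clonotypes_per_sample`` clonotypes is drawn.  Mutation
    counts come from a Poisson mixture: the low component (memory-derived,
    mean ``shm_mean_low``) has weight ``shm_weight_low_day0`` at day 0; for
    planted high responders the post-vaccination weight rises to
    ``shm_weight_low_post``, for low responders it stays at the day-0
    value.  A sprinkling of non-IGHG / non-productive / incomplete records
    exercises the quality filter; the truth records component labels and
    the analytic expected pct_low per sample.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_high_responders + config.n_low_responders
    individuals = _individual_ids(n)
    high_set = set(individuals[: config.n_high_responders])

    from scipy.stats import poisson as poisson_dist

    def analytic_pct_low(weight_low: float, cutoff: int = 10) -> float:
        p = (weight_low * poisson_dist.cdf(cutoff, config.shm_mean_low)
             + (1 - weight_low) * poisson_dist.cdf(cutoff, config.shm_mean_high))
        return 100.0 * float(p)

    records: list[ClonotypeRecord] = []
    truth_samples: dict[str, dict] = {}
    labels: dict[str, list[str]] = {}
    for ind in individuals:
        for tp in (0, config.shm_post_day):
            sample_id = f"{ind}_d{tp}"
            if tp == 0:
                w = config.shm_weight_low_day0
            else:
                w = (config.shm_weight_low_post if ind in high_set
                     else config.shm_weight_low_day0)
            comp_labels = []
            for i in range(config.shm_clonotypes_per_sample):
                low = bool(rng.random() < w)
                mean = config.shm_mean_low if low else config.shm_mean_high
                muts = int(rng.poisson(mean))
                comp_labels.append("low" if low else "high")
                # ~10% of rows fail one of the quality filters
                roll = rng.random()
                isotype = f"IGHG{int(rng.integers(1, 5))}"
                productive, complete = True, True
                if roll < 0.04:
                    isotype = "IGHM"
                elif roll < 0.07:
                    productive = False
                elif roll < 0.10:
                    complete = False
                records.append(
                    ClonotypeRecord(
                        sample_id=sample_id,
                        cdr3_aa=_random_key(rng, ""),
                        read_count=int(1 + rng.poisson(10)),
                        v_call=f"IGHV{int(rng.integers(1, 8))}",
                        isotype=isotype,
                        productive=productive,
                        complete_v=complete,
                        v_mutations=muts,
                    )
                )
            truth_samples[sample_id] = {
                "individual_id": ind,
                "timepoint_days": tp,
                "weight_low": w,
                "expected_pct_low": analytic_pct_low(w),
            }
            labels[sample_id] = comp_labels

    truth = {
        "samples": truth_samples,
        "component_labels": labels,
        "high_responders": sorted(high_set),
        "low_responders": sorted(set(individuals) - high_set),
    }
    return records, truth


def simulate_titers(config: SimConfig) -> tuple[dict[str, dict[int, float]], dict]:
    """Per-individual day-0/day-84 antibody titers (AU) with planted labels.

    High responders gain a boost drawn from ``titer_boost_high`` (all above
    the 500 AU cutoff); low responders from ``titer_boost_low`` (all below).
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_high_responders + config.n_low_responders
    individuals = _individual_ids(n)
    high_set = set(individuals[: config.n_high_responders])
    titers: dict[str, dict[int, float]] = {}
    for ind in individuals:
        baseline = float(rng.lognormal(config.titer_baseline_mean_log,
                                       config.titer_baseline_sd_log))
        lo, hi = (config.titer_boost_high if ind in high_set
                  else config.titer_boost_low)
        boost = float(rng.uniform(lo, hi))
        titers[ind] = {0: round(baseline, 2), 84: round(baseline + boost, 2)}
    truth = {
        "high_responders": sorted(high_set),
        "low_responders": sorted(set(individuals) - high_set),
    }
    return titers, truth


def write_dataset(result: SimResult, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write a simulated cohort as AIRR TSV + metadata CSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.airr.tsv",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.json",
    }
    write_airr(result.records, paths["records"])
    import pandas as pd

    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "individual_id": m.individual_id,
                "timepoint_days": m.timepoint_days,
                "tissue": m.tissue.value,
                "population": m.population,
                "group": m.group,
            }
            for m in result.meta
        ]
    ).to_csv(paths["metadata"], index=False, lineterminator="\n")
    paths["truth"].write_text(json.dumps(result.truth, indent=2, sort_keys=True))
    return paths
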