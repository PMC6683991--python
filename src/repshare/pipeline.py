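"""End-to-end analysis orchestration with deterministic, auditable outputs.

The analyses have many small stated thresholds (more-than-five-reads
support, 2% expansion, ψ = 0.01, ≤10 mutations, >500 AU responder cutoff);
``RunConfig`` collects them in one serializable place and every run writes
the config it actually used next to its tables, so results can be re-run
to identical bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import clonotyping, io, sharing, shm
from .types import InputError, RepertoireError, SampleMeta

__all__ = ["RunConfig", "run_tcr_analysis", "run_bcr_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All analysis settings for one pipeline run."""

    clonotype_tables: list[str] = field(default_factory=list)
    metadata: str = ""
    titers: Optional[str] = None
    input_format: str = "airr"  # "airr" | "vdjtools"
    key_mode: str = "cdr3_aa"
    min_reads: int = 6
    expansion_threshold: float = 0.02
    pseudocount: float = 0.01
    public_min_individuals: int = 2
    public_timepoint: Optional[int] = None
    top_n: int = 100
    shm_low_cutoff: int = 10
    shm_post_day: int = 63
    responder_cutoff: float = 500.0
    outdir: str = "repshare_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise InputError("min_reads must be >= 1")
        if not 0 < self.expansion_threshold <= 1:
            raise InputError("expansion_threshold must be in (0, 1]")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be >= 0")
        if self.public_min_individuals < 2:
            raise InputError("public_min_individuals must be >= 2")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _load_records(config: RunConfig):
    reader = io.read_airr if config.input_format == "airr" else io.read_vdjtools
    records = []
    for path in config.clonotype_tables:
        records.extend(reader(path))
    return records


def _collapse_by_sample(records, meta: list[SampleMeta], config: RunConfig):
    by_sample: dict[str, list] = {}
    known = {m.sample_id for m in meta}
    for r in records:
        if r.sample_id not in known:
            raise InputError(f"record references unknown sample {r.sample_id!r}")
        by_sample.setdefault(r.sample_id, []).append(r)
    reps = []
    for sid in sorted(by_sample):
        rep = clonotyping.collapse(by_sample[sid], key_mode=config.key_mode,
                                   min_reads=config.min_reads)
        if rep.X == 0:
            raise RepertoireError(
                f"sample {sid!r}: no clonotype passed the "
                f">= {config.min_reads}-read support filter"
            )
        reps.append(rep)
    return reps


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_tcr_analysis(config: RunConfig, meta: Optional[list[SampleMeta]] = None,
                     records=None) -> dict:
    """Load → collapse → diversity/expansion → sharing → public clonotypes.

    ``meta``/``records`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the paths in the config.  Writes
    deterministic TSV/JSON tables into ``config.outdir`` along with the
    serialized config, and returns the report as a dict of DataFrames and
    summaries.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    stage = "load"
    try:
        if meta is None:
            meta = io.load_metadata(config.metadata)
        if records is None:
            records = _load_records(config)

        stage = "collapse"
        reps = _collapse_by_sample(records, meta, config)
        diversity = pd.DataFrame(
            [{"sample_id": r.sample_id, "unique_clonotypes": r.X,
              "total_reads": r.total_reads} for r in reps]
        )

        stage = "expansion"
        expanded_rows = []
        for rep in reps:
            for cf in clonotyping.expanded_clones(rep, config.expansion_threshold):
                expanded_rows.append({"sample_id": rep.sample_id, "key": cf.key,
                                      "fraction": cf.fraction})
        expanded = pd.DataFrame(expanded_rows,
                                columns=["sample_id", "key", "fraction"])

        stage = "sharing"
        results = sharing.pairwise_sharing(reps, meta,
                                           pseudocount=config.pseudocount)
        sharing_df = pd.DataFrame([asdict(r) for r in results])

        stage = "public"
        tp_filter = ({config.public_timepoint}
                     if config.public_timepoint is not None else None)
        report = sharing.find_public(
            reps, meta, min_individuals=config.public_min_individuals,
            timepoint_filter=tp_filter,
        )
        public_df = pd.DataFrame(
            [{"key": p.key, "n_individuals": p.n_individuals,
              "individuals": ",".join(sorted(p.individuals)),
              "samples": ",".join(sorted(p.samples)),
              "timepoints": ",".join(map(str, sorted(p.timepoints))),
              "v_calls": ",".join(sorted(p.v_calls))}
             for p in report.public],
            columns=["key", "n_individuals", "individuals", "samples",
                     "timepoints", "v_calls"],
        )
        per_donor = sharing.sharing_per_donor(reps, meta, timepoints=tp_filter)
        edges = sharing.export_sharing_graph(reps, meta, timepoint_filter=tp_filter)

        stage = "group-tests"
        by_group: dict[str, list[float]] = {}
        meta_by_id = {m.sample_id: m for m in meta}
        for r in results:
            gi = meta_by_id[r.sample_i].group
            gj = meta_by_id[r.sample_j].group
            if gi == gj:
                by_group.setdefault(gi, []).append(r.norm_psi_Y)
        group_test = None
        if len(by_group) >= 2:
            group_test = sharing.compare_sharing_groups(by_group,
                                                        test="kruskal_wallis")

        _write_tsv(diversity, outdir / "diversity.tsv")
        _write_tsv(expanded, outdir / "expanded_clones.tsv")
        _write_tsv(sharing_df, outdir / "pairwise_sharing.tsv")
        _write_tsv(public_df, outdir / "public_clonotypes.tsv")
        _write_tsv(per_donor, outdir / "sharing_per_donor.tsv")
        _write_tsv(edges, outdir / "sharing_graph.tsv")
        summary = {
            "n_samples": len(reps),
            "n_pairs": len(results),
            "n_public_clonotypes": len(report.public),
            "n_within_individual_shared": len(report.within_individual),
            "group_test": asdict(group_test) if group_test else None,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    except RepertoireError as exc:
        raise RepertoireError(f"[stage: {stage}] {exc}") from exc

    return {
        "diversity": diversity,
        "expanded": expanded,
        "sharing": sharing_df,
        "public": report.public,
        "within_individual": report.within_individual,
        "per_donor": per_donor,
        "edges": edges,
        "group_test": group_test,
        "summary": summary,
    }


def run_bcr_analysis(config: RunConfig, meta: Optional[list[SampleMeta]] = None,
                     records=None,
                     titers: Optional[dict] = None) -> dict:
    """IgHG filtering → top-N profiles → SHM histograms → paired deltas.

    Individuals are stratified by responder label when titers are
    available; otherwise stratification is skipped with a warning and the
    rest of the report still completes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    stage = "load"
    try:
        if meta is None:
            meta = io.load_metadata(config.metadata)
        if records is None:
            records = _load_records(config)

        stage = "ig-filter"
        by_sample: dict[str, list] = {}
        for r in records:
            by_sample.setdefault(r.sample_id, []).append(r)
        meta_by_id = {m.sample_id: m for m in meta}

        profiles: dict[str, shm.MutationProfile] = {}
        profile_rows, top_rows = [], []
        ig_by_sample: dict[str, list[shm.IgClonotype]] = {}
        for sid in sorted(by_sample):
            ig = shm.filter_ig(by_sample[sid])
            if not ig:
                raise RepertoireError(
                    f"sample {sid!r}: no clonotype passed the IgHG filter"
                )
            ig_by_sample[sid] = ig
            profile = shm.mutation_histogram(ig, low_cutoff=config.shm_low_cutoff)
            profiles[sid] = profile
            for (lo, hi), frac in zip(profile.bin_edges, profile.bin_fractions):
                profile_rows.append(
                    {"sample_id": sid,
                     "bin": f"{lo}-{hi}" if hi is not None else f">{lo - 1}",
                     "fraction": frac}
                )
            rep = clonotyping.collapse(by_sample[sid], min_reads=1)
            for cf in clonotyping.top_n_profile(rep, config.top_n):
                top_rows.append({"sample_id": sid, "key": cf.key,
                                 "fraction": cf.fraction})

        stage = "paired-deltas"
        pct_df = pd.DataFrame(
            [{"sample_id": sid,
              "individual_id": meta_by_id[sid].individual_id,
              "timepoint_days": meta_by_id[sid].timepoint_days,
              "pct_low": profiles[sid].pct_low,
              "n_clonotypes": profiles[sid].n_clonotypes}
             for sid in sorted(profiles) if sid in meta_by_id]
        )
        day0 = {row.individual_id: row.pct_low
                for row in pct_df.itertuples() if row.timepoint_days == 0}
        post = {row.individual_id: row.pct_low
                for row in pct_df.itertuples()
                if row.timepoint_days == config.shm_post_day}
        paired = shm.paired_low_mutation_change(day0, post)

        stage = "responders"
        by_label = None
        if titers is None and config.titers:
            titer_df = pd.read_csv(config.titers)
            titers = {}
            for row in titer_df.itertuples():
                titers.setdefault(str(row.individual_id), {})[int(row.day)] = \
                    float(row.AU)
        if titers:
            labels = shm.label_responders(titers, cutoff=config.responder_cutoff)
            label_map = {l.individual_id: l.label for l in labels}
            by_label = {}
            for lab in ("high", "low"):
                inds = [i for i in sorted(set(day0) & set(post))
                        if label_map.get(i) == lab]
                if len(inds) >= 2:
                    by_label[lab] = shm.paired_low_mutation_change(
                        {i: day0[i] for i in inds}, {i: post[i] for i in inds}
                    )
        else:
            logger.warning("no titer table provided; responder "
                           "stratification skipped")

        _write_tsv(pd.DataFrame(profile_rows), outdir / "mutation_histograms.tsv")
        _write_tsv(pd.DataFrame(top_rows), outdir / "top_clone_profiles.tsv")
        _write_tsv(pct_df, outdir / "pct_low.tsv")
        deltas_out = {
            "deltas": paired.deltas, "mean_delta": paired.mean_delta,
            "statistic": paired.statistic, "pvalue": paired.pvalue,
            "n_pairs": paired.n_pairs, "zero_variance": paired.zero_variance,
            "by_responder_label": {
                lab: {"mean_delta": res.mean_delta, "pvalue": res.pvalue,
                      "n_pairs": res.n_pairs}
                for lab, res in (by_label or {}).items()
            },
        }
        (outdir / "paired_deltas.json").write_text(
            json.dumps(deltas_out, indent=2, sort_keys=True) + "\n"
        )
    except RepertoireError as exc:
        raise RepertoireError(f"[stage: {stage}] {exc}") from exc

    return {
        "profiles": profiles,
        "pct_low": pct_df,
        "paired": paired,
        "by_responder_label": by_label,
        "ig_by_sample": ig_by_sample,
    }
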