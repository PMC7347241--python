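"""End-to-end workflows: filtering, clustering, and the scaled-down study.

``run_pipeline`` applies the full inference chain (productive filter,
collapse to unique sequences, VJ(l)-grouping, spectral clustering) and
``scaled_study`` reproduces the simulation benchmark at desk scale: five
synthetic repertoires are generated, each clustered under the requested
configurations, and pairwise sensitivity/specificity/precision are
macro-averaged over repertoires.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import pandas as pd

from .airr_io import RearrangementSet, collapse_identical, filter_productive
from .evaluate import confusion_metrics, pairwise_confusion
from .simulate import (
    SimulationParams,
    default_shm_targeting,
    simulate_repertoire,
    toy_germline_pool,
)
from .spectral import ClonePartition, ClusterConfig, assign_clones


@dataclass
class PipelineResult:
    unique: RearrangementSet
    partition: ClonePartition

    @property
    def expanded(self) -> dict[str, str]:
        return self.partition.expand(self.unique.collapse_map)


def run_pipeline(rs: RearrangementSet, config: ClusterConfig) -> PipelineResult:
    """Filter, collapse, and cluster a rearrangement set."""
    filtered = filter_productive(rs)
    unique = collapse_identical(filtered)
    partition = assign_clones(unique, config)
    return PipelineResult(unique=unique, partition=partition)


def evaluate_partition(result: PipelineResult, truth: pd.DataFrame, expanded: bool = False):
    """Pairwise metrics against the truth labelling.

    By default pairs are evaluated over unique sequences (the clustering
    substrate); ``expanded=True`` propagates clone ids to every collapsed
    duplicate first (duplicate-weighted evaluation).
    """
    truth_map = dict(zip(truth["sequence_id"], truth["clone_id"]))
    if expanded:
        p = result.expanded
        t = {i: truth_map[i] for i in p}
    else:
        unique_ids = result.unique.ids()
        t = {i: truth_map[i] for i in unique_ids}
        p = {i: result.partition.assignments[i] for i in unique_ids}
    return confusion_metrics(pairwise_confusion(t, p))


def shared_shm_prevalence(unique: RearrangementSet, truth: pd.DataFrame) -> float:
    """Fraction of non-singleton true clones with >= 1 pairwise shared mutation.

    Clones are taken over unique sequences; a clone counts as sharing when
    some (position, substituted base) outside the junction occurs in at
    least two members relative to the clone's own germline — exactly the
    condition for the pairwise shared-mutation matrix H to have a non-zero
    entry.
    """
    truth_map = dict(zip(truth["sequence_id"], truth["clone_id"]))
    clones: dict[str, list] = {}
    for r in unique:
        clones.setdefault(truth_map[r.sequence_id], []).append(r)
    n_nonsingleton = 0
    n_sharing = 0
    for members in clones.values():
        if len(members) < 2:
            continue
        n_nonsingleton += 1
        span = members[0].junction_span()
        seen: dict[tuple[int, str], int] = {}
        shared = False
        for r in members:
            germ = r.germline_alignment
            seq = r.sequence_alignment
            start, end = span if span else (0, 0)
            for n, (a, b) in enumerate(zip(germ, seq)):
                if start <= n < end:
                    continue
                if a in "ACGT" and b in "ACGT" and a != b:
                    seen[(n, b)] = seen.get((n, b), 0) + 1
                    if seen[(n, b)] >= 2:
                        shared = True
            if shared:
                break
        n_sharing += shared
    return n_sharing / n_nonsingleton if n_nonsingleton else float("nan")


STUDY_CONFIGS = ("ham-junc", "ham-cdr3", "ham-shm-cdr3")


def config_from_name(name: str, seed: int = 0, tm=None) -> ClusterConfig:
    """Build a ClusterConfig from its study name (ham[-shm]-{junc,cdr3})."""
    mapping = {
        "ham-junc": ("recomb", "junction"),
        "ham-cdr3": ("recomb", "cdr3"),
        "ham-shm-junc": ("integrated", "junction"),
        "ham-shm-cdr3": ("integrated", "cdr3"),
    }
    if name not in mapping:
        raise ValueError(f"unknown configuration name: {name!r}")
    method, target = mapping[name]
    return ClusterConfig(method=method, target=target, seed=seed, targeting_model=tm)


def scaled_study(
    seed: int,
    n_repertoires: int = 5,
    configs: tuple = STUDY_CONFIGS,
    params: SimulationParams | None = None,
) -> pd.DataFrame:
    """The desk-scale simulation benchmark.

    Generates ``n_repertoires`` synthetic repertoires with derived seeds,
    clusters each under every named configuration, and returns per-
    repertoire metrics plus the shared-SHM prevalence of the true clones.
    """
    pool = toy_germline_pool()
    tm = default_shm_targeting()
    base_params = params or SimulationParams()
    rows = []
    for rep in range(n_repertoires):
        rep_seed = (seed * 1000 + rep) % (2**31 - 1)
        sim_params = dc_replace(base_params, seed=rep_seed)
        rs, truth, _meta = simulate_repertoire(sim_params, pool=pool, tm=tm)
        unique_cache = None
        for name in configs:
            config = config_from_name(name, seed=seed, tm=tm)
            result = run_pipeline(rs, config)
            unique_cache = result.unique
            metrics = evaluate_partition(result, truth)
            rows.append(
                {
                    "repertoire": rep,
                    "config": name,
                    "n_unique": len(result.unique),
                    "sensitivity": metrics.sensitivity,
                    "specificity": metrics.specificity,
                    "precision": metrics.precision,
                }
            )
        prevalence = shared_shm_prevalence(unique_cache, truth)
        for row in rows:
            if row["repertoire"] == rep and "shared_shm_prevalence" not in row:
                row["shared_shm_prevalence"] = prevalence
    return pd.DataFrame(rows)


def macro_average(study: pd.DataFrame) -> pd.DataFrame:
    """Macro-averaged metrics per configuration (mean over repertoires)."""
    return (
        study.groupby("config")[["sensitivity", "specificity", "precision"]]
        .mean()
        .reset_index()
    )
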