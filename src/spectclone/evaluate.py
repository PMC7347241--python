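"""Evaluation of inferred clonal partitions.

Performance is measured over unordered sequence pairs: a pair is a true
positive when truth and prediction both place it in one clone, a true
negative when both separate it, and so on.  Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), precision = TP/(TP+FP).

Two protocol-level checks are also provided: a negative-control experiment
that compares each true clone's mean pairwise shared-mutation level H
against size-matched random samples from the same VJ(l)-group, and a
cross-individual spike-in protocol that estimates specificity on data
without ground truth (sequences from different individuals can never be
clonally related, so any grouping of a spiked foreign sequence is a false
positive).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from math import comb

import numpy as np
import pandas as pd

from .airr_io import RearrangementSet
from .grouping import build_vjl_groups
from .shm_model import mutation_matrices
from .spectral import ClusterConfig, _alignment_mask, assign_clones


@dataclass(frozen=True)
class ConfusionCounts:
    """Pairwise confusion counts over unordered sequence pairs."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class PartitionMetrics:
    sensitivity: float | None
    specificity: float | None
    precision: float | None


def pairwise_confusion(truth: dict, predicted: dict) -> ConfusionCounts:
    """Classify every unordered pair by (same-truth?, same-predicted?)."""
    if set(truth) != set(predicted):
        raise ValueError("truth and prediction must cover the same sequence ids")
    ids = sorted(truth)
    df = pd.DataFrame(
        {"t": [truth[i] for i in ids], "p": [predicted[i] for i in ids]}
    )
    n = len(ids)
    total = comb(n, 2)
    same_truth = int(sum(comb(c, 2) for c in df["t"].value_counts()))
    same_pred = int(sum(comb(c, 2) for c in df["p"].value_counts()))
    tp = int(sum(comb(c, 2) for c in df.groupby(["t", "p"]).size()))
    fn = same_truth - tp
    fp = same_pred - tp
    tn = total - tp - fn - fp
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_metrics(cc: ConfusionCounts) -> PartitionMetrics:
    """Sensitivity, specificity, precision; None where the denominator is 0."""
    return PartitionMetrics(
        sensitivity=_ratio(cc.TP, cc.TP + cc.FN),
        specificity=_ratio(cc.TN, cc.TN + cc.FP),
        precision=_ratio(cc.TP, cc.TP + cc.FP),
    )


def _mean_upper(H: np.ndarray, idx: np.ndarray) -> float:
    sub = H[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def negative_control_enrichment(
    rs: RearrangementSet,
    truth: dict,
    n_controls: int = 100,
    n_top_groups: int = 20,
    seed: int = 0,
    grouping_mode: str = "chain",
) -> pd.DataFrame:
    """Shared-SHM enrichment of true clones over size-matched negative controls.

    For every clone (>= 2 members) in the ``n_top_groups`` largest
    VJ(l)-groups, the observed mean upper-triangular H over its members is
    compared with ``n_controls`` random same-size samples drawn without
    replacement from the same group (excluding the clone's exact member
    set); the empirical p-value is the fraction of controls with mean H at
    least as large.  H is computed over the V and J segments (junction
    masked).  Clones whose group offers no distinct control sample are
    skipped.
    """
    rng = np.random.default_rng(seed)
    groups = build_vjl_groups(rs, mode=grouping_mode)
    groups = sorted(groups, key=lambda g: (-len(g), g.group_id))[:n_top_groups]
    sequences = {r.sequence_id: r.sequence_alignment for r in rs}
    rows = []
    for group in groups:
        if len(group) < 2:
            continue
        mask = _alignment_mask(group, sequences[group.member_ids[0]], "junction")
        _T, H = mutation_matrices(group, sequences, mask)
        member_index = {sid: i for i, sid in enumerate(group.member_ids)}
        clones: dict[str, list[int]] = {}
        for sid in group.member_ids:
            clones.setdefault(truth[sid], []).append(member_index[sid])
        for clone_id, idx in clones.items():
            size = len(idx)
            if size < 2 or size >= len(group):
                continue
            observed = _mean_upper(H, np.array(idx))
            own = frozenset(idx)
            control_means = []
            for _ in range(n_controls):
                sample = rng.choice(len(group), size=size, replace=False)
                if frozenset(sample.tolist()) == own:
                    continue
                control_means.append(_mean_upper(H, sample))
            if not control_means:
                continue
            control_means = np.array(control_means)
            p = float((control_means >= observed).mean())
            rows.append(
                {
                    "group_id": group.group_id,
                    "clone_id": clone_id,
                    "size": size,
                    "observed_mean_H": observed,
                    "control_mean_H": float(control_means.mean()),
                    "empirical_p": p,
                }
            )
    return pd.DataFrame(rows)


def cross_individual_specificity(
    repertoires: list[RearrangementSet],
    base_index: int = 0,
    cycles: int = 10,
    seed: int = 0,
    config: ClusterConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Spike-in specificity across individuals.

    Per cycle one random sequence from each non-base repertoire is added to
    the base repertoire and clones are assigned; spiked sequences ending up
    as singletons are true negatives, spiked sequences grouped into larger
    clones are false positives.  Returns the mean specificity over cycles
    and the per-cycle counts.
    """
    if len(repertoires) < 2:
        raise ValueError("need at least two repertoires")
    base = repertoires[base_index]
    if len(base) < 2:
        raise ValueError("base repertoire must contain at least 2 sequences")
    config = config or ClusterConfig(seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for cycle in range(cycles):
        spiked_records = []
        spiked_ids = []
        for r_idx, rep in enumerate(repertoires):
            if r_idx == base_index:
                continue
            pick = rep.records[int(rng.integers(0, len(rep)))]
            new_id = f"spike_{r_idx}_{cycle}_{pick.sequence_id}"
            spiked_records.append(dc_replace(pick, sequence_id=new_id))
            spiked_ids.append(new_id)
        combined = RearrangementSet(
            records=list(base.records) + spiked_records,
            provenance=f"spike:cycle={cycle}",
        )
        partition = assign_clones(combined, dc_replace(config, seed=seed))
        clone_sizes = pd.Series(list(partition.assignments.values())).value_counts()
        tn = sum(1 for sid in spiked_ids if clone_sizes[partition.assignments[sid]] == 1)
        fp = len(spiked_ids) - tn
        rows.append({"cycle": cycle, "TN": tn, "FP": fp, "specificity": tn / (tn + fp)})
    detail = pd.DataFrame(rows)
    return float(detail["specificity"].mean()), detail
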