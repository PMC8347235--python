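"""Per-target funnels, cross-target consensus and novelty selection.

Each target gets its own funnel (bioactivity filter, then pharmacophore,
then — where docked poses exist — electrostatic similarity); a compound
becomes a consensus hit when it survives the full funnel for at least two
targets.  Consensus hits are then clustered together with known actives on
fingerprint Jaccard distance, clusters containing a known active are
discarded (those hits are not novel chemotypes), and at most one hit per
remaining cluster is selected, ranked by the number of targets it hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import HDBSCAN

from mmpscreen.core_chem import MoleculeRecord, morgan_fingerprint

__all__ = [
    "FunnelStage",
    "FunnelReport",
    "HitRecord",
    "ClusterAssignment",
    "run_target_funnel",
    "collect_consensus",
    "cluster_with_known_actives",
    "select_novel_hits",
]


@dataclass
class FunnelStage:
    """A named filter stage: records in, surviving records out."""

    name: str
    apply: Callable[[list[MoleculeRecord]], list[MoleculeRecord]]


@dataclass
class FunnelReport:
    """Per-stage survivor bookkeeping for one target's funnel."""

    target_id: str
    stage_names: list[str]
    survivors: list[set[str]]  # id-set per stage, index-aligned with names

    def counts(self) -> list[int]:
        return [len(s) for s in self.survivors]

    @property
    def final_survivors(self) -> set[str]:
        return self.survivors[-1]

    def validate(self) -> None:
        for prev, cur in zip(self.survivors, self.survivors[1:]):
            if not cur <= prev:
                raise ValueError(
                    f"funnel for {self.target_id} is not monotone: a stage "
                    "gained compounds absent from the previous stage"
                )


@dataclass
class HitRecord:
    compound_id: str
    target_flags: dict[str, bool]

    @property
    def n_targets_hit(self) -> int:
        return sum(self.target_flags.values())


@dataclass
class ClusterAssignment:
    compound_id: str
    cluster_label: int
    contains_known_active: bool


def run_target_funnel(
    library: Sequence[MoleculeRecord],
    stages: Sequence[FunnelStage],
    target_id: str = "",
) -> FunnelReport:
    """Apply the configured stages in order and record every survivor set.

    The stage list is per-target configuration: a ligand-only target (no
    usable docked poses) simply configures fewer stages.  Any exception in
    a stage is re-raised with the stage named.
    """
    current = list(library)
    names = ["initial"]
    survivors = [set(r.id for r in current)]
    for stage in stages:
        try:
            nxt = list(stage.apply(current))
        except Exception as exc:
            raise RuntimeError(
                f"funnel stage {stage.name!r} failed for target "
                f"{target_id!r}: {exc}"
            ) from exc
        prev_ids = {r.id for r in current}
        nxt = [r for r in nxt if r.id in prev_ids]
        current = nxt
        names.append(stage.name)
        survivors.append({r.id for r in current})
    report = FunnelReport(target_id, names, survivors)
    report.validate()
    return report


def collect_consensus(
    reports: Sequence[FunnelReport], min_targets: int = 2
) -> list[HitRecord]:
    """Compounds surviving the full funnel for at least ``min_targets``.

    The default 2 defines the main consensus tier; 3 gives the stricter
    shortlist tier.  Returns hits sorted by id.
    """
    if len(reports) < 2:
        raise ValueError("consensus needs at least two target funnels")
    all_ids: set[str] = set()
    for rep in reports:
        all_ids |= rep.final_survivors
    hits = []
    for cid in sorted(all_ids):
        flags = {
            rep.target_id: cid in rep.final_survivors for rep in reports
        }
        if sum(flags.values()) >= min_targets:
            hits.append(HitRecord(compound_id=cid, target_flags=flags))
    return hits


def cluster_with_known_actives(
    hits: Sequence[MoleculeRecord],
    known_actives: Sequence[MoleculeRecord],
    min_cluster_size: int = 2,
    seed: int = 0,
    fp_radius: int = 2,
    fp_nbits: int = 2048,
) -> list[ClusterAssignment]:
    """Cluster hits together with known actives on fingerprint distance.

    Density-based hierarchical clustering (HDBSCAN) on the Jaccard
    distance matrix of Morgan fingerprints.  A cluster is flagged when any
    member is a known active: hits in flagged clusters resemble known
    chemotypes.  Noise points become singleton clusters (flagged only if
    the point itself is a known active), so structurally isolated hits
    stay eligible for selection.  Deterministic for fixed inputs.
    """
    records = list(hits) + list(known_actives)
    is_active = [False] * len(hits) + [True] * len(known_actives)
    n = len(records)
    if n == 0:
        return []
    fps = np.stack(
        [
            morgan_fingerprint(r, radius=fp_radius, nbits=fp_nbits).bits
            for r in records
        ]
    ).astype(bool)
    if n < max(min_cluster_size, 2):
        labels = np.arange(n)  # everything a singleton
    else:
        inter = (fps[:, None, :] & fps[None, :, :]).sum(axis=2)
        union = (fps[:, None, :] | fps[None, :, :]).sum(axis=2)
        dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        np.fill_diagonal(dist, 0.0)
        raw = HDBSCAN(
            min_cluster_size=min_cluster_size, metric="precomputed", copy=True
        ).fit_predict(dist)
        labels = raw.copy()
        next_label = (raw.max() + 1) if (raw >= 0).any() else 0
        for i in range(n):
            if raw[i] == -1:  # noise -> its own singleton cluster
                labels[i] = next_label
                next_label += 1
    flagged: dict[int, bool] = {}
    for lab, act in zip(labels, is_active):
        flagged[lab] = flagged.get(lab, False) or act
    return [
        ClusterAssignment(
            compound_id=rec.id,
            cluster_label=int(lab),
            contains_known_active=flagged[int(lab)],
        )
        for rec, lab in zip(records, labels)
    ]


def select_novel_hits(
    assignments: Sequence[ClusterAssignment],
    hits: Sequence[HitRecord],
    n_select: int = 20,
) -> list[HitRecord]:
    """Pick up to ``n_select`` novel hits, one per unflagged cluster.

    Hits sharing a cluster with a known active are excluded outright.
    Within each remaining cluster the hit seen in the most target funnels
    wins (ties by ascending compound id); the per-cluster winners are then
    ranked the same way and the top ``n_select`` returned.
    """
    by_id = {h.compound_id: h for h in hits}
    cluster_of = {a.compound_id: a for a in assignments}
    best_per_cluster: dict[int, HitRecord] = {}
    for hit in hits:
        a = cluster_of.get(hit.compound_id)
        if a is None or a.contains_known_active:
            continue
        cur = best_per_cluster.get(a.cluster_label)
        if cur is None or (
            (-hit.n_targets_hit, hit.compound_id)
            < (-cur.n_targets_hit, cur.compound_id)
        ):
            best_per_cluster[a.cluster_label] = hit
    ranked = sorted(
        best_per_cluster.values(),
        key=lambda h: (-h.n_targets_hit, h.compound_id),
    )
    return ranked[:n_select]
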