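"""Run three per-target funnels, extract consensus hits and select novel ones.

Each toy funnel applies a seeded random filter per stage; hits surviving
the full funnel for at least two targets are clustered together with
known actives, and at most one hit per active-free cluster is selected.
"""

import numpy as np

from mmpscreen import (
    cluster_with_known_actives,
    collect_consensus,
    run_target_funnel,
    select_novel_hits,
)
from mmpscreen.consensus import FunnelStage
from mmpscreen.fixtures import make_classification_set

rng = np.random.default_rng(0)
actives, decoys = make_classification_set(30, 30, seed=0)
library = actives[10:] + decoys  # 20 actives + 30 decoys as the "library"
known_actives = actives[:10]

reports = []
for target in ("MMP-8-like", "MMP-12-like", "MMP-13-like"):
    stages = []
    for stage_name in ("rf", "pharmacophore", "electrostatics"):
        keep = {r.id for r in library if rng.random() < 0.7}
        stages.append(
            FunnelStage(stage_name,
                        lambda recs, kp=keep: [r for r in recs
                                               if r.id in kp])
        )
    report = run_target_funnel(library, stages, target_id=target)
    reports.append(report)
    print(f"{target}: survivors per stage {report.counts()}")
# Counts shrink monotonically: each stage only removes compounds.

hits = collect_consensus(reports, min_targets=2)
print(f"\nconsensus: {len(hits)} compounds passed >= 2 funnels")

hit_records = [r for r in library
               if r.id in {h.compound_id for h in hits}]
assignments = cluster_with_known_actives(hit_records, known_actives,
                                         min_cluster_size=2, seed=0)
selected = select_novel_hits(assignments, hits, n_select=5)
print(f"selected novel hits (<= 1 per cluster, most funnels first):")
for h in selected:
    print(f"  {h.compound_id}: hit in {h.n_targets_hit} funnels")
# Hits clustering with a known active are excluded as non-novel
# chemotypes; the survivors are ranked by screening breadth.
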