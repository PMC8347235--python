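"""Serialization: hypotheses as JSON, poses as SDF, reports as TSV/JSON.

Only plain-text formats are used so that every artifact diffs cleanly and
round-trips without a binary dependency.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from mmpscreen.consensus import FunnelReport
from mmpscreen.electrostatics import Atom, CutoffCalibration, Pose, PotentialGrid
from mmpscreen.pharmacophore import Hypothesis, ScreenMatch, Site
from mmpscreen.rf_filter import ClassifierMetrics

__all__ = [
    "hypothesis_to_json",
    "hypothesis_from_json",
    "write_pose_sdf",
    "read_pose_sdf",
    "write_grid_dx",
    "calibration_to_json",
    "write_calibration_histogram",
    "write_funnel_report",
    "write_metrics_table",
    "write_screen_matches",
]

CHARGE_PROP = "PARTIAL_CHARGES"

# Table-2 column order for metric reports
METRIC_COLUMNS = [
    "sensitivity", "specificity", "precision", "fall_out",
    "false_negative_rate", "false_discovery_rate", "accuracy",
    "f1_score", "matthews_cc",
]


def hypothesis_to_json(hyp: Hypothesis, path: str | None = None) -> str:
    payload = {
        "id": hyp.id,
        "provenance": hyp.provenance,
        "min_optional_matches": hyp.min_optional_matches,
        "sites": [
            {
                "kind": s.kind,
                "position": None if s.position is None
                else [float(x) for x in s.position],
                "tolerance": s.tolerance,
                "required": s.required,
                "weight": s.weight,
            }
            for s in hyp.sites
        ],
    }
    text = json.dumps(payload, indent=2)
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def hypothesis_from_json(text_or_path: str) -> Hypothesis:
    try:
        payload = json.loads(text_or_path)
    except json.JSONDecodeError:
        with open(text_or_path) as fh:
            payload = json.load(fh)
    sites = [
        Site(
            kind=s["kind"],
            position=None if s["position"] is None
            else np.asarray(s["position"], dtype=float),
            tolerance=s["tolerance"],
            required=s["required"],
            weight=s.get("weight", 0.0),
        )
        for s in payload["sites"]
    ]
    return Hypothesis(
        id=payload["id"],
        sites=sites,
        provenance=payload.get("provenance", "structure_based"),
        min_optional_matches=payload.get("min_optional_matches", 0),
    )


def write_pose_sdf(poses: Sequence[Pose], path: str) -> None:
    """Write poses as SDF V2000 with charges in a named property block."""
    writer = Chem.SDWriter(path)
    writer.SetKekulize(False)
    for pose in poses:
        mol = Chem.RWMol()
        conf = Chem.Conformer(len(pose.atoms))
        for i, atom in enumerate(pose.atoms):
            mol.AddAtom(Chem.Atom(atom.element))
            conf.SetAtomPosition(i, [float(x) for x in atom.xyz])
        m = mol.GetMol()
        m.AddConformer(conf)
        m.SetProp("_Name", pose.pose_id)
        m.SetProp("COMPOUND_ID", pose.compound_id)
        m.SetProp("TARGET_ID", pose.target_id)
        m.SetProp(
            CHARGE_PROP,
            " ".join(f"{a.charge:.6f}" for a in pose.atoms),
        )
        if pose.score is not None:
            m.SetProp("DOCKING_SCORE", f"{pose.score:.6f}")
        writer.write(m)
    writer.close()


def read_pose_sdf(path: str) -> list[Pose]:
    """Read poses from SDF; charges come from the property block if present."""
    poses = []
    for mol in Chem.SDMolSupplier(path, sanitize=False, removeHs=False):
        if mol is None:
            continue
        conf = mol.GetConformer()
        charges = None
        if mol.HasProp(CHARGE_PROP):
            charges = [float(x) for x in mol.GetProp(CHARGE_PROP).split()]
        atoms = []
        for i, atom in enumerate(mol.GetAtoms()):
            pos = conf.GetAtomPosition(i)
            atoms.append(
                Atom(
                    element=atom.GetSymbol(),
                    xyz=np.array([pos.x, pos.y, pos.z]),
                    charge=charges[i] if charges else 0.0,
                )
            )
        poses.append(
            Pose(
                compound_id=mol.GetProp("COMPOUND_ID")
                if mol.HasProp("COMPOUND_ID") else mol.GetProp("_Name"),
                atoms=atoms,
                target_id=mol.GetProp("TARGET_ID")
                if mol.HasProp("TARGET_ID") else "",
                pose_id=mol.GetProp("_Name"),
                score=float(mol.GetProp("DOCKING_SCORE"))
                if mol.HasProp("DOCKING_SCORE") else None,
            )
        )
    return poses


def write_grid_dx(grid: PotentialGrid, path: str) -> None:
    """Export a potential grid as OpenDX-style volumetric text."""
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    s = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {s:.6f} 0.0 0.0\n")
        fh.write(f"delta 0.0 {s:.6f} 0.0\n")
        fh.write(f"delta 0.0 0.0 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items "
            f"{nx * ny * nz} data follows\n"
        )
        vals = grid.values
        for i in range(0, len(vals), 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[i:i + 3]) + "\n")


def calibration_to_json(cal: CutoffCalibration, path: str | None = None) -> str:
    payload = {
        "target_id": cal.target_id,
        "cutoff": cal.cutoff,
        "provenance": cal.provenance,
        "youden_j": cal.youden_j,
        "discriminating": cal.discriminating,
    }
    text = json.dumps(payload, indent=2)
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_calibration_histogram(cal: CutoffCalibration, path: str) -> None:
    pd.DataFrame(
        {
            "bin_left": cal.histogram["bin_left"],
            "decoy_count": cal.histogram["decoy"],
            "act_lt4": cal.histogram["act_lt4"],
            "act_4to7": cal.histogram["act_4to7"],
            "act_gt7": cal.histogram["act_gt7"],
        }
    ).to_csv(path, sep="\t", index=False)


def write_funnel_report(reports: Sequence[FunnelReport], path: str) -> None:
    """Stages-by-targets survivor-count table (funnel overview)."""
    all_stages: list[str] = []
    for rep in reports:
        for name in rep.stage_names:
            if name not in all_stages:
                all_stages.append(name)
    data = {}
    for rep in reports:
        col = {}
        for name, surv in zip(rep.stage_names, rep.survivors):
            col[name] = len(surv)
        data[rep.target_id] = [col.get(s, "-") for s in all_stages]
    pd.DataFrame(data, index=all_stages).to_csv(
        path, sep="\t", index_label="stage"
    )


def write_metrics_table(
    metrics: dict[str, ClassifierMetrics], path: str
) -> None:
    rows = {name: m.as_dict() for name, m in metrics.items()}
    pd.DataFrame(rows).T[METRIC_COLUMNS].to_csv(
        path, sep="\t", index_label="model"
    )


def write_screen_matches(matches: Sequence[ScreenMatch], path: str) -> None:
    pd.DataFrame(
        [
            {
                "compound": m.compound_id,
                "pose": m.pose_id,
                "rmsd": m.rmsd,
                "matched_sites": ";".join(
                    f"{i}->{j}" for i, j in sorted(m.assignment.items())
                ),
            }
            for m in matches
        ]
    ).to_csv(path, sep="\t", index=False)
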