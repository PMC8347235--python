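"""Seeded generators for every synthetic input the suite and examples need.

The generators emit small, valence-legal structures and geometries with
known ground truth — scaffold-sharing actives versus scaffold-free
MW-matched decoys, poses planted to match (or violate) a pharmacophore
hypothesis, charged toy poses for the field Tanimoto, synthetic
electrostatic-similarity validation distributions, and dose-response
curves.  Every generator is a pure function of its arguments: the same
seed always reproduces the same output.  They test the pipeline's
contracts, not pharmacology.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from mmpscreen.assay import InhibitionMeasurement, predict_velocity_ratio
from mmpscreen.core_chem import MoleculeRecord, standardize_molecule
from mmpscreen.electrostatics import ET_MIN, Atom, Pose
from mmpscreen.pharmacophore import (
    FEATURE_KINDS,
    Feature,
    Hypothesis,
    PharmacophorePose,
    Site,
)

__all__ = [
    "make_classification_set",
    "make_random_hypothesis",
    "make_planted_pose_set",
    "make_charged_pose",
    "make_et_validation_set",
    "make_inhibition_curve",
]

# aryl substituents used to decorate the shared active scaffold
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "OC", "OCC", "Cl", "F",
    "C(C)C", "C(F)(F)F", "OC(C)C",
]

# pX strata proportions for generated actives: weak (<4) / mid (4-7) /
# potent (>7)
_PX_PROPORTIONS = (0.25, 0.35, 0.40)


def _sample_px(rng: np.random.Generator) -> float:
    u = rng.random()
    if u < _PX_PROPORTIONS[0]:
        return float(rng.uniform(1.0, 4.0))
    if u < _PX_PROPORTIONS[0] + _PX_PROPORTIONS[1]:
        return float(rng.uniform(4.0, 7.0))
    return float(rng.uniform(7.0, 13.0))


def make_classification_set(
    n_actives: int, n_decoys: int, seed: int
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Scaffold-sharing actives and MW-matched scaffold-free decoys.

    Actives decorate a common N-aryl sulfonamide / benzoic-acid scaffold
    (so they share Morgan bits by construction); decoys are linear alkyl
    esters whose chain length is tuned to match an active's mass within
    25 Da while staying inside the 300-600 Da screening window.  Actives
    carry a pX sampled from the stated strata proportions.
    """
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    actives: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    while len(actives) < n_actives:
        attempts += 1
        r1 = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        r2 = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        r3 = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        smiles = (
            f"O=S(=O)(Nc1ccc({r2})c({r3})c1C(=O)O)c1ccc({r1})cc1"
        )
        rec = standardize_molecule(
            smiles,
            id=f"act{len(actives):05d}",
            role="active",
            activity_px=_sample_px(rng),
            source="synthetic-scaffold",
        )
        # substituent combinations can collide after canonicalization
        if rec.smiles in seen and attempts < 50 * n_actives:
            continue
        seen.add(rec.smiles)
        actives.append(rec)

    # ester chain mass: mw(c) ~= 242.403 + 14.027 * (c - 14) total carbons
    decoys: list[MoleculeRecord] = []
    for i in range(n_decoys):
        target_mw = actives[int(rng.integers(len(actives)))].mw
        c = int(round((target_mw - 242.403) / 14.027)) + 14
        while 242.403 + 14.027 * (c - 14) < 300.0:
            c += 1
        b = int(rng.integers(2, 6))
        a = max(1, c - b)
        decoys.append(
            standardize_molecule(
                "C" * a + "OC(=O)" + "C" * b,
                id=f"dec{i:05d}",
                role="decoy",
                source="synthetic-ester",
            )
        )
    return actives, decoys


def make_random_hypothesis(
    kinds: str = "AAR",
    tolerance: float = 2.0,
    seed: int = 0,
    box: float = 15.0,
    min_separation_factor: float = 2.6,
) -> Hypothesis:
    """A hypothesis with well-separated random site positions.

    Same-kind sites are kept more than ``min_separation_factor * tolerance``
    apart so that a feature planted near one site can never satisfy
    another — the separation the planted-pose generator relies on.
    """
    rng = np.random.default_rng(seed)
    for k in kinds:
        if k not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {k!r}")
    min_sep = min_separation_factor * tolerance
    positions: list[np.ndarray] = []
    for _ in range(10000):
        cand = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(cand - p) > min_sep for p in positions):
            positions.append(cand)
        if len(positions) == len(kinds):
            break
    else:
        raise ValueError("could not place well-separated sites; enlarge box")
    sites = [
        Site(kind=k, position=p, tolerance=tolerance, required=True)
        for k, p in zip(kinds, positions)
    ]
    return Hypothesis(id=f"planted_{kinds}_{seed}", sites=sites,
                      provenance="structure_based")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_planted_pose_set(
    hypothesis: Hypothesis,
    n_match: int,
    n_nonmatch: int,
    seed: int,
    n_distractors: int = 2,
) -> tuple[list[PharmacophorePose], list[bool]]:
    """Poses with ground-truth match labels for a coordinated hypothesis.

    Matching poses place a same-kind feature within 0.4x tolerance of
    every site; non-matching poses displace one required site's feature by
    more than tolerance + 0.5 A (and away from every other same-kind
    site).  Distractor features of random kinds are sprinkled far from
    all same-kind sites.  Requires same-kind sites to be well separated,
    as :func:`make_random_hypothesis` guarantees.
    """
    rng = np.random.default_rng(seed)
    sites = hypothesis.sites
    for s in sites:
        if s.position is None:
            raise ValueError("hypothesis sites must carry coordinates")
    for i, si in enumerate(sites):
        for sj in sites[i + 1:]:
            if si.kind == sj.kind:
                gap = np.linalg.norm(si.position - sj.position)
                if gap <= 2.0 * si.tolerance:
                    raise ValueError(
                        "same-kind sites too close for unambiguous planting"
                    )

    def far_point(kind: str, min_dist_extra: float = 1.0) -> np.ndarray:
        same = [s for s in sites if s.kind == kind]
        for _ in range(1000):
            anchor = sites[int(rng.integers(len(sites)))].position
            cand = anchor + _random_unit(rng) * rng.uniform(6.0, 12.0)
            if all(
                np.linalg.norm(cand - s.position)
                > s.tolerance + 0.5 + min_dist_extra
                for s in same
            ):
                return cand
        raise RuntimeError("could not place a far feature")  # pragma: no cover

    poses: list[PharmacophorePose] = []
    labels: list[bool] = []
    required_idx = [i for i, s in enumerate(sites) if s.required]
    for k in range(n_match + n_nonmatch):
        is_match = k < n_match
        feats: list[Feature] = []
        violate = (
            required_idx[int(rng.integers(len(required_idx)))]
            if not is_match
            else -1
        )
        for i, site in enumerate(sites):
            if i == violate:
                feats.append(Feature(site.kind, far_point(site.kind)))
            else:
                offset = _random_unit(rng) * rng.uniform(
                    0.0, 0.4 * site.tolerance
                )
                feats.append(Feature(site.kind, site.position + offset))
        for _ in range(n_distractors):
            kind = FEATURE_KINDS[int(rng.integers(len(FEATURE_KINDS)))]
            feats.append(Feature(kind, far_point(kind)))
        poses.append(
            PharmacophorePose(
                pose_id=f"pose{k:04d}",
                compound_id=f"cpd{k:04d}",
                features=feats,
                score=float(rng.uniform(-10, -1)),
            )
        )
        labels.append(is_match)
    return poses, labels


_CHARGE_PROFILES = ("net-neutral", "dipolar", "monopolar", "random")


def make_charged_pose(
    n_atoms: int,
    charge_profile: str = "net-neutral",
    seed: int = 0,
    compound_id: str = "toy",
) -> Pose:
    """A toy pose: carbons at random positions in a 10 A box.

    Profiles: ``net-neutral`` (random charges recentred to sum exactly
    zero), ``dipolar`` (half positive, half negative), ``monopolar`` (all
    one sign), ``random``.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if charge_profile not in _CHARGE_PROFILES:
        raise ValueError(
            f"unknown profile {charge_profile!r}; one of {_CHARGE_PROFILES}"
        )
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(0.0, 10.0, size=(n_atoms, 3))
    if charge_profile == "net-neutral":
        q = rng.normal(0.0, 0.2, size=n_atoms)
        q -= q.mean()
    elif charge_profile == "dipolar":
        q = np.where(np.arange(n_atoms) < n_atoms // 2, 0.2, -0.2)
        if n_atoms % 2:
            q[-1] = 0.0
    elif charge_profile == "monopolar":
        q = rng.uniform(0.05, 0.3, size=n_atoms)
    else:
        q = rng.uniform(-0.3, 0.3, size=n_atoms)
    atoms = [Atom("C", xyz[i], float(q[i])) for i in range(n_atoms)]
    return Pose(compound_id=compound_id, atoms=atoms, pose_id=compound_id)


def make_et_validation_set(
    n_act: int, n_dec: int, shift: float, seed: int
) -> dict:
    """Synthetic per-compound best-pose Tanimoto values with pX strata.

    Decoys (and weak actives, pX < 4) draw from Normal(0.3, 0.1)
    truncated to [-1/3, 1]; mid actives (4 <= pX <= 7) are shifted by
    half of ``shift`` and potent actives (pX > 7) by the full ``shift`` —
    emulating the empirical pattern that field similarity to reference
    inhibitors tracks potency.  Returns arrays ``active_et``,
    ``active_px``, ``decoy_et``.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    rng = np.random.default_rng(seed)

    def tnorm(mean: float, n: int) -> np.ndarray:
        a = (ET_MIN - mean) / 0.1
        b = (1.0 - mean) / 0.1
        return truncnorm.rvs(a, b, loc=mean, scale=0.1, size=n,
                             random_state=rng)

    px = np.array([_sample_px(rng) for _ in range(n_act)])
    act = np.empty(n_act)
    lt4 = px < 4
    mid = (px >= 4) & (px <= 7)
    gt7 = px > 7
    act[lt4] = tnorm(0.3, int(lt4.sum()))
    act[mid] = tnorm(0.3 + shift / 2.0, int(mid.sum()))
    act[gt7] = tnorm(0.3 + shift, int(gt7.sum()))
    dec = tnorm(0.3, n_dec)
    return {"active_et": act, "active_px": px, "decoy_et": dec}


def make_inhibition_curve(
    ic50: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[InhibitionMeasurement]:
    """Dose points from vi/vo = 1/(1+[I]/IC50) with multiplicative noise."""
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    rng = np.random.default_rng(seed)
    out = []
    for i, c in enumerate(concentrations):
        ratio = predict_velocity_ratio(ic50, float(c))
        if noise_sd > 0:
            ratio *= 1.0 + rng.normal(0.0, noise_sd)
        out.append(
            InhibitionMeasurement(
                concentration=float(c),
                velocity_ratio=max(ratio, 0.0),
                replicate=f"r{i}",
            )
        )
    return out
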