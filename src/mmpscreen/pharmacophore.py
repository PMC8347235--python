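"""Pharmacophore perception, hypothesis generation and 3D screening.

A pharmacophore hypothesis is an ordered set of interaction sites —
hydrogen-bond acceptors (A) and donors (D), aromatic rings (R), negatively
(N) and positively (P) charged groups, and hydrophobic clusters (H) — each
with 3D coordinates and a matching tolerance.  Two generation routes are
provided: a structure-based route that clusters features pooled from
docked, scored fragment poses (the e-pharmacophore idea), and a
ligand-based route that recovers feature arrangements shared by a majority
of known actives.  Screening either keeps poses fixed in the receptor
frame (``screen_inplace``) or superposes conformers onto the hypothesis by
a proper rigid motion (``screen_flexible``).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "FEATURE_KINDS",
    "DEFAULT_FEATURE_SMARTS",
    "Feature",
    "Site",
    "Hypothesis",
    "ScreenMatch",
    "PharmacophorePose",
    "perceive_features",
    "pose_from_mol",
    "parse_hypothesis_string",
    "generate_epharmacophore",
    "generate_ligand_hypothesis",
    "screen_inplace",
    "screen_flexible",
    "validate_and_select",
]

FEATURE_KINDS = ("A", "D", "R", "N", "H", "P")

# Feature definitions: SMARTS per kind, matched atoms contribute one feature
# per match (centroid of the matched atoms).  R (aromatic rings) and H
# (hydrophobic clusters) are perceived structurally, not by SMARTS.
# Amide nitrogens are excluded from acceptors.
DEFAULT_FEATURE_SMARTS: dict[str, list[str]] = {
    "D": ["[#7;!H0]", "[#8;!H0]", "[#16;!H0]"],
    "A": [
        "[OX1]",
        "[OX2H1]",
        "[OX2H0]",
        "[nX2]",
        "[NX2;!$(N=O);!$(NC=O)]",
        "[NX3;H0;!a;!$(NC=O);!$(N=*);!$(N[O])]",
    ],
    "N": [
        "[CX3](=O)[O-]",
        "[SX4](=O)(=O)[O-]",
        "[PX4](=O)([O-])[O-,OX2H1]",
        "c1nnn[n-]1",
    ],
    "P": ["[#7+;!$([n+][O-]);!$([N+][O-])]"],
}

DEFAULT_TOLERANCE = 2.0  # Angstrom matching radius when a site states none


@dataclass(frozen=True)
class Feature:
    """A perceived pharmacophoric point: kind, xyz (A) and parent atoms."""

    kind: str
    position: np.ndarray
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )
        if not np.all(np.isfinite(self.position)):
            raise ValueError("feature position must be finite")


@dataclass
class Site:
    """One hypothesis site: a feature kind at a position with a tolerance."""

    kind: str
    position: np.ndarray | None = None
    tolerance: float = DEFAULT_TOLERANCE
    required: bool = True
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("site tolerance must be > 0")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)


@dataclass
class Hypothesis:
    """An ordered set of sites with provenance and optional-match quota."""

    id: str
    sites: list[Site]
    provenance: str = "structure_based"
    min_optional_matches: int = 0

    @property
    def n_required(self) -> int:
        return sum(1 for s in self.sites if s.required)

    def signature(self) -> str:
        """Table-style string, e.g. ``A (+) A (-) R (+)``."""
        return " ".join(
            f"{s.kind} ({'+' if s.required else '-'})" for s in self.sites
        )


@dataclass
class ScreenMatch:
    """A pose that satisfied a hypothesis, with its site assignment."""

    compound_id: str
    pose_id: str
    assignment: dict[int, int]  # site index -> feature index (injective)
    rmsd: float


@dataclass
class PharmacophorePose:
    """A 3D conformation reduced to its pharmacophoric features.

    ``score`` is an optional per-pose scalar (docking convention: lower is
    better) used by the e-pharmacophore generator.
    """

    pose_id: str
    compound_id: str
    features: list[Feature]
    score: float | None = None


# ---------------------------------------------------------------------------
# feature perception


def _hydrophobic_clusters(mol: Chem.Mol) -> list[tuple[int, ...]]:
    # contiguous clusters of >= 3 apolar, non-aromatic carbons
    polar = {7, 8, 9, 15, 16, 17, 35, 53}
    apolar = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if atom.GetFormalCharge() != 0:
            continue
        if any(nb.GetAtomicNum() in polar for nb in atom.GetNeighbors()):
            continue
        apolar.add(atom.GetIdx())
    clusters = []
    seen: set[int] = set()
    for start in sorted(apolar):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            comp.append(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in apolar and j not in seen:
                    stack.append(j)
        if len(comp) >= 3:
            clusters.append(tuple(sorted(comp)))
    return clusters


def perceive_features(
    mol: Chem.Mol,
    conf_id: int = -1,
    catalogue: dict[str, list[str]] | None = None,
) -> list[Feature]:
    """Locate pharmacophoric features on a molecule with a 3D conformer.

    A/D/N/P features come from the SMARTS catalogue (feature position =
    centroid of the matched atoms; for single-atom patterns that is the
    heavy atom itself).  R features sit at aromatic-ring centroids and H
    features at centroids of contiguous apolar-carbon clusters of three or
    more atoms.  Output is sorted by (kind, atoms), hence deterministic.
    """
    catalogue = catalogue if catalogue is not None else DEFAULT_FEATURE_SMARTS
    conf = mol.GetConformer(conf_id)
    coords = conf.GetPositions()
    feats: list[Feature] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()
    for kind, patterns in catalogue.items():
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS in catalogue: {smarts!r}")
            for match in mol.GetSubstructMatches(patt):
                atoms = tuple(sorted(match))
                key = (kind, atoms)
                if key in seen:
                    continue
                seen.add(key)
                feats.append(
                    Feature(kind, coords[list(atoms)].mean(axis=0), atoms)
                )
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            atoms = tuple(sorted(ring))
            feats.append(Feature("R", coords[list(atoms)].mean(axis=0), atoms))
    for cluster in _hydrophobic_clusters(mol):
        feats.append(
            Feature("H", coords[list(cluster)].mean(axis=0), cluster)
        )
    feats.sort(key=lambda f: (f.kind, f.atom_indices))
    return feats


def pose_from_mol(
    mol: Chem.Mol,
    pose_id: str,
    compound_id: str | None = None,
    conf_id: int = -1,
    score: float | None = None,
) -> PharmacophorePose:
    """Reduce an RDKit molecule conformer to a :class:`PharmacophorePose`."""
    return PharmacophorePose(
        pose_id=pose_id,
        compound_id=compound_id or pose_id,
        features=perceive_features(mol, conf_id=conf_id),
        score=score,
    )


# ---------------------------------------------------------------------------
# hypothesis strings

_TOKEN_RE = re.compile(r"([A-Za-z])\s*\(\s*([+\-−–])\s*\)")


def parse_hypothesis_string(
    text: str,
    id: str = "",
    provenance: str = "structure_based",
    tolerance: float = DEFAULT_TOLERANCE,
) -> Hypothesis:
    """Parse a hypothesis skeleton like ``"A (+) A (-) R (+)"``.

    ``+`` marks a required site, ``-`` an optional one.  The result has
    kinds and flags but no coordinates; those come from a generator or a
    serialized hypothesis file.
    """
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise ValueError(f"no KIND(+/-) tokens found in {text!r}")
    sites = []
    for kind, sign in tokens:
        kind = kind.upper()
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind in token {kind}({sign})")
        sites.append(
            Site(kind=kind, tolerance=tolerance, required=(sign == "+"))
        )
    return Hypothesis(id=id or text, sites=sites, provenance=provenance)


# ---------------------------------------------------------------------------
# structure-based (e-pharmacophore) generation


def _allocate_clusters(counts: dict[str, int], total: int) -> dict[str, int]:
    # one cluster per kind present, remainder proportional to feature counts
    kinds = sorted(counts)
    alloc = {k: 1 for k in kinds}
    n_feat = sum(counts.values())
    remaining = total - len(kinds)
    if remaining > 0 and n_feat:
        shares = {k: remaining * counts[k] / n_feat for k in kinds}
        for k in kinds:
            alloc[k] += int(shares[k])
        leftover = remaining - sum(int(shares[k]) for k in kinds)
        by_frac = sorted(
            kinds, key=lambda k: (shares[k] - int(shares[k])), reverse=True
        )
        for k in by_frac[:leftover]:
            alloc[k] += 1
    return {k: min(alloc[k], counts[k]) for k in kinds}


def generate_epharmacophore(
    fragment_poses: list[PharmacophorePose],
    n_clusters: int = 15,
    max_sites: int = 8,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[Hypothesis]:
    """Build structure-based hypotheses from scored docked fragment poses.

    Features pooled from all poses are clustered kind-wise into at most
    ``n_clusters`` groups; each cluster is scored by the sum of the
    docking scores of the poses contributing to it (lower = better) and
    the best ``max_sites`` clusters become sites positioned at
    score-weighted centroids.  One hypothesis is returned per site count
    from 1 up to ``max_sites`` (or the number of clusters found), the
    k-site hypothesis holding the k best sites.
    """
    if not fragment_poses:
        raise ValueError("no fragment poses given")
    pooled: list[tuple[Feature, float]] = []
    for pose in fragment_poses:
        if pose.score is None:
            raise ValueError(f"pose {pose.pose_id} carries no docking score")
        for feat in pose.features:
            pooled.append((feat, pose.score))
    if not pooled:
        raise ValueError("no features perceived on any fragment pose")
    by_kind: dict[str, list[tuple[Feature, float]]] = {}
    for feat, score in pooled:
        by_kind.setdefault(feat.kind, []).append((feat, score))
    counts = {k: len(v) for k, v in by_kind.items()}
    if sum(counts.values()) < n_clusters:
        warnings.warn(
            f"only {sum(counts.values())} feature points for "
            f"{n_clusters} requested clusters; using fewer",
            stacklevel=2,
        )
    alloc = _allocate_clusters(counts, n_clusters)

    clusters: list[tuple[str, float, np.ndarray]] = []  # (kind, score, pos)
    for kind in sorted(by_kind):
        items = by_kind[kind]
        X = np.stack([f.position for f, _ in items])
        scores = np.array([s for _, s in items])
        k = alloc[kind]
        if len(items) == 1 or k == 1:
            labels = np.zeros(len(items), dtype=int)
        else:
            labels = AgglomerativeClustering(
                n_clusters=k, linkage="average"
            ).fit_predict(X)
        for lab in np.unique(labels):
            mask = labels == lab
            csum = float(scores[mask].sum())
            # weight better (more negative) scores more strongly
            shifted = scores[mask].max() - scores[mask]
            if shifted.sum() <= 0:
                w = np.ones(mask.sum())
            else:
                w = shifted
            pos = np.average(X[mask], axis=0, weights=w)
            clusters.append((kind, csum, pos))
    clusters.sort(key=lambda c: (c[1], c[0]))  # ascending score sum
    top = clusters[:max_sites]
    hypotheses = []
    for n in range(1, len(top) + 1):
        sites = [
            Site(kind=k, position=p, tolerance=tolerance, required=True,
                 weight=s)
            for k, s, p in top[:n]
        ]
        hypotheses.append(
            Hypothesis(
                id=f"epharm_{n}site",
                sites=sites,
                provenance="structure_based",
            )
        )
    return hypotheses


# ---------------------------------------------------------------------------
# rigid alignment and screening


def _kabsch_rmsd(
    src: np.ndarray, dst: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares proper rigid motion of src onto dst.

    Returns the transformed src points and the RMSD.  The rotation is
    constrained to det(R) = +1: reflections are not rigid motions of a
    molecule.
    """
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    P, Q = src - sc, dst - dc
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (R @ P.T).T + dc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - dst) ** 2, axis=1))))
    return moved, rmsd


def _site_tolerances(hypothesis: Hypothesis, default: float) -> list[float]:
    return [s.tolerance if s.tolerance else default for s in hypothesis.sites]


def _match_inplace(
    hypothesis: Hypothesis, pose: PharmacophorePose, tolerance_default: float
) -> ScreenMatch | None:
    """Injective site->feature assignment without moving the pose.

    Solved as a rectangular assignment problem: required sites carry a
    large bonus so the optimum matches as many required sites as possible
    first, then as many optional sites as possible; squared distances
    break ties.  Dummy columns let a site stay unassigned.
    """
    sites = hypothesis.sites
    feats = pose.features
    n_s, n_f = len(sites), len(feats)
    REQ, OPT = 1e6, 1.0
    cost = np.zeros((n_s, n_f + n_s))
    cost[:, :n_f] = 1e9  # invalid pairing
    for i, site in enumerate(sites):
        if site.position is None:
            raise ValueError(f"site {i} of {hypothesis.id} has no coordinates")
        tol = site.tolerance or tolerance_default
        for j, feat in enumerate(feats):
            if feat.kind != site.kind:
                continue
            d2 = float(np.sum((feat.position - site.position) ** 2))
            if d2 <= tol * tol:
                bonus = REQ if site.required else OPT
                cost[i, j] = -bonus + 1e-4 * d2
    rows, cols = linear_sum_assignment(cost)
    assignment: dict[int, int] = {}
    n_opt = 0
    for i, j in zip(rows, cols):
        if j < n_f and cost[i, j] < 0:
            assignment[i] = j
            if not sites[i].required:
                n_opt += 1
        elif sites[i].required:
            return None
    if n_opt < hypothesis.min_optional_matches:
        return None
    d2s = [
        float(np.sum((feats[j].position - sites[i].position) ** 2))
        for i, j in assignment.items()
    ]
    rmsd = float(np.sqrt(np.mean(d2s))) if d2s else 0.0
    return ScreenMatch(pose.compound_id, pose.pose_id, assignment, rmsd)


def screen_inplace(
    hypothesis: Hypothesis,
    poses: list[PharmacophorePose],
    tolerance_default: float = DEFAULT_TOLERANCE,
) -> list[ScreenMatch]:
    """Screen docked poses against a hypothesis without re-alignment.

    Poses are assumed to share the receptor frame with the hypothesis
    (docking against superposed structures).  A pose matches iff every
    required site is satisfied by a distinct same-kind feature within its
    tolerance and at least ``min_optional_matches`` optional sites are
    satisfied too.
    """
    matches = []
    for pose in poses:
        m = _match_inplace(hypothesis, pose, tolerance_default)
        if m is not None:
            matches.append(m)
    return matches


def _enumerate_assignments(
    sites: list[Site],
    feats: list[Feature],
    min_optional: int,
    cap: int = 20000,
):
    """Yield injective site->feature maps covering all required sites."""
    options = []
    for site in sites:
        cands = [j for j, f in enumerate(feats) if f.kind == site.kind]
        if site.required and not cands:
            return
        options.append((site.required, cands))
    count = 0

    def rec(i: int, used: set[int], current: dict[int, int], n_opt: int):
        nonlocal count
        if count >= cap:
            return
        if i == len(sites):
            if n_opt >= min_optional:
                count += 1
                yield dict(current)
            return
        required, cands = options[i]
        for j in cands:
            if j in used:
                continue
            used.add(j)
            current[i] = j
            yield from rec(i + 1, used, current, n_opt + (0 if required else 1))
            used.discard(j)
            del current[i]
        if not required:  # optional site left unassigned
            yield from rec(i + 1, used, current, n_opt)

    yield from rec(0, set(), {}, 0)


def screen_flexible(
    hypothesis: Hypothesis,
    conformers: dict[str, list[PharmacophorePose]],
    max_conformers: int = 10,
    tolerance_default: float = DEFAULT_TOLERANCE,
) -> list[ScreenMatch]:
    """Screen conformer ensembles with rigid-body superposition.

    For each conformer (at most ``max_conformers`` per compound) every
    injective same-kind assignment of features to sites is tried: the
    assigned features are superposed onto the sites by a proper rigid
    motion (rotation + translation, no reflection) and the assignment is
    accepted if every post-alignment distance is within the site
    tolerance.  The best (lowest-RMSD) conformer per compound is reported.
    """
    results: list[ScreenMatch] = []
    for compound_id in conformers:
        best: ScreenMatch | None = None
        for pose in conformers[compound_id][:max_conformers]:
            feats = pose.features
            for assignment in _enumerate_assignments(
                hypothesis.sites, feats, hypothesis.min_optional_matches
            ):
                if not assignment:
                    continue
                idx_sites = sorted(assignment)
                src = np.stack(
                    [feats[assignment[i]].position for i in idx_sites]
                )
                dst = np.stack(
                    [hypothesis.sites[i].position for i in idx_sites]
                )
                moved, rmsd = _kabsch_rmsd(src, dst)
                tols = [
                    hypothesis.sites[i].tolerance or tolerance_default
                    for i in idx_sites
                ]
                dists = np.linalg.norm(moved - dst, axis=1)
                if np.all(dists <= np.array(tols)):
                    if best is None or rmsd < best.rmsd:
                        best = ScreenMatch(
                            pose.compound_id, pose.pose_id, dict(assignment),
                            rmsd,
                        )
        if best is not None:
            results.append(best)
    return results


# ---------------------------------------------------------------------------
# ligand-based generation


def _hypothesis_key(sites: list[Site]) -> tuple:
    kinds = tuple(s.kind for s in sites)
    pos = np.stack([s.position for s in sites])
    dists = np.round(
        np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1), 2
    )
    return kinds, tuple(sorted(dists[np.triu_indices(len(sites), k=1)]))


def generate_ligand_hypothesis(
    actives: dict[str, list[PharmacophorePose]],
    min_active_fraction: float = 0.5,
    n_features: tuple[int, int] = (3, 5),
    tolerance: float = DEFAULT_TOLERANCE,
    max_conformers: int = 10,
    max_subsets_per_reference: int = 500,
) -> list[Hypothesis]:
    """Derive ligand-based hypotheses shared by a fraction of actives.

    Candidate hypotheses are feature subsets (3-5 features by default)
    taken from each active's first conformer; each candidate is screened
    flexibly against all actives and kept iff it matches at least
    ``min_active_fraction`` of them.  Results are deduplicated by feature
    kinds and internal distances, and sorted by matched fraction (then by
    more features — richer hypotheses are more specific).
    """
    if not actives:
        raise ValueError("no actives given")
    lo, hi = n_features
    n_act = len(actives)
    kept: list[tuple[float, int, Hypothesis]] = []
    seen_keys: set = set()
    for ref_id in actives:
        if not actives[ref_id]:
            continue
        ref = actives[ref_id][0]
        feats = ref.features
        n_sub = 0
        for k in range(min(hi, len(feats)), lo - 1, -1):
            for combo in itertools.combinations(range(len(feats)), k):
                if n_sub >= max_subsets_per_reference:
                    break
                n_sub += 1
                sites = [
                    Site(
                        kind=feats[j].kind,
                        position=feats[j].position.copy(),
                        tolerance=tolerance,
                        required=True,
                    )
                    for j in combo
                ]
                key = _hypothesis_key(sites)
                if key in seen_keys:
                    continue
                seen_keys.add(key)
                hyp = Hypothesis(
                    id=f"lig_{ref_id}_{'-'.join(map(str, combo))}",
                    sites=sites,
                    provenance="ligand_based",
                )
                matched = screen_flexible(
                    hyp, actives, max_conformers=max_conformers
                )
                frac = len({m.compound_id for m in matched}) / n_act
                if frac >= min_active_fraction:
                    kept.append((frac, k, hyp))
    if not kept:
        warnings.warn("no common feature arrangement found", stacklevel=2)
        return []
    kept.sort(key=lambda t: (-t[0], -t[1], t[2].id))
    return [h for _, _, h in kept]


# ---------------------------------------------------------------------------
# validation


def validate_and_select(
    hypotheses: list[Hypothesis],
    actives: dict[str, list[PharmacophorePose]] | list[PharmacophorePose],
    decoys: dict[str, list[PharmacophorePose]] | list[PharmacophorePose],
    mode: str = "inplace",
):
    """Validate hypotheses on screened actives/decoys and pick the best.

    A compound counts as predicted-active iff any of its poses matches.
    Sensitivity is the selection criterion (the funnel's pharmacophore
    stage is meant to lose as few true actives as possible); ties break by
    specificity, then by fewer sites.  Returns ``(best, metrics_by_id)``.
    """
    from mmpscreen.rf_filter import compute_metrics

    if not hypotheses:
        raise ValueError("no hypotheses to validate")

    def to_posedict(x):
        if isinstance(x, dict):
            return x
        out: dict[str, list[PharmacophorePose]] = {}
        for p in x:
            out.setdefault(p.compound_id, []).append(p)
        return out

    act, dec = to_posedict(actives), to_posedict(decoys)
    if not act or not dec:
        raise ValueError("validation set must contain actives and decoys")

    def matched_ids(hyp, posedict):
        if mode == "inplace":
            all_poses = [p for ps in posedict.values() for p in ps]
            return {m.compound_id for m in screen_inplace(hyp, all_poses)}
        return {m.compound_id for m in screen_flexible(hyp, posedict)}

    metrics: dict[str, "object"] = {}
    for hyp in hypotheses:
        hit_act = matched_ids(hyp, act)
        hit_dec = matched_ids(hyp, dec)
        tp, fn = len(hit_act), len(act) - len(hit_act)
        fp, tn = len(hit_dec), len(dec) - len(hit_dec)
        metrics[hyp.id] = compute_metrics(tp, fp, tn, fn)

    def sort_key(hyp):
        m = metrics[hyp.id]
        spec = m.specificity if np.isfinite(m.specificity) else -1.0
        return (-m.sensitivity, -spec, len(hyp.sites), hyp.id)

    best = min(hypotheses, key=sort_key)
    return best, metrics
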