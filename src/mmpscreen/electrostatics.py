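"""Electrostatic-potential fields and the continuous field Tanimoto.

The funnel's strictest stage compares the electrostatic potential of a
docked pose with those of high-affinity reference ligand poses that share
the same receptor frame.  The similarity metric is a continuous Tanimoto
coefficient over the two sampled fields,

    T(a, b) = <a, b> / (<a, a> + <b, b> - <a, b>),

which is 1 for identical fields and bounded below by -1/3 (reached exactly
when b = -a, i.e. a perfect charge inversion).  The default field model is
a screened Coulomb potential with a distance-dependent dielectric
eps(d) = 4d, sampled on a regular grid with the region inside the van der
Waals envelope masked out; the comparison layer only needs two fields on a
common grid, so any external Poisson-Boltzmann solver can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import ks_2samp

__all__ = [
    "BONDI_RADII",
    "Atom",
    "Pose",
    "GridSpec",
    "PotentialGrid",
    "ETResult",
    "CutoffCalibration",
    "assign_partial_charges",
    "shared_grid_spec",
    "compute_potential_grid",
    "electrostatic_tanimoto",
    "best_reference_similarity",
    "triage_references",
    "calibrate_cutoff",
    "apply_cutoff",
    "ET_MIN",
]

ET_MIN = -1.0 / 3.0

# Bondi van der Waals radii (Angstrom) for common organic elements
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


@dataclass
class Atom:
    element: str
    xyz: np.ndarray
    charge: float = 0.0
    radius: float | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be finite")
        if not np.isfinite(self.charge):
            raise ValueError("atom charge must be finite")
        if self.radius is None:
            self.radius = BONDI_RADII.get(self.element, DEFAULT_RADIUS)


@dataclass
class Pose:
    """A 3D ligand pose with per-atom coordinates and partial charges."""

    compound_id: str
    atoms: list[Atom]
    target_id: str = ""
    pose_id: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("pose must contain at least one atom")
        if not self.pose_id:
            self.pose_id = self.compound_id

    @property
    def coords(self) -> np.ndarray:
        return np.stack([a.xyz for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    def with_charges(self, charges: Sequence[float]) -> "Pose":
        atoms = [
            Atom(a.element, a.xyz.copy(), float(q), a.radius)
            for a, q in zip(self.atoms, charges)
        ]
        return Pose(self.compound_id, atoms, self.target_id, self.pose_id,
                    self.score)


# ---------------------------------------------------------------------------
# charges


def _gasteiger_charges(pose: Pose) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = getattr(pose, "mol", None)
    if mol is None:
        raise ValueError(
            "gasteiger charging requires a pose built from an RDKit "
            "molecule (pose.mol); use method='as-given' for bare poses"
        )
    mol = Chem.AddHs(Chem.Mol(mol))
    AllChem.ComputeGasteigerCharges(mol)
    # heavy atoms absorb their hydrogens' charges so atom lists align
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    charges = []
    for a in heavy:
        q = a.GetDoubleProp("_GasteigerCharge")
        for nb in a.GetNeighbors():
            if nb.GetAtomicNum() == 1:
                q += nb.GetDoubleProp("_GasteigerCharge")
        charges.append(q)
    if len(charges) != len(pose.atoms):
        raise ValueError("pose atom count does not match its molecule")
    return np.array(charges)


CHARGE_SCHEMES: dict[str, Callable[[Pose], np.ndarray]] = {
    "as-given": lambda pose: pose.charges,
    "zero": lambda pose: np.zeros(len(pose.atoms)),
    "gasteiger": _gasteiger_charges,
}


def assign_partial_charges(pose: Pose, method: str = "as-given") -> Pose:
    """Fill per-atom partial charges by the named empirical scheme.

    ``as-given`` trusts the charges already on the pose (e.g. read from an
    SDF property block); ``gasteiger`` recomputes them from the pose's
    RDKit molecule with hydrogens collapsed onto their heavy atoms.
    """
    if method not in CHARGE_SCHEMES:
        raise ValueError(
            f"unknown charge scheme {method!r}; "
            f"available: {sorted(CHARGE_SCHEMES)}"
        )
    if method == "as-given":
        return pose
    return pose.with_charges(CHARGE_SCHEMES[method](pose))


# ---------------------------------------------------------------------------
# grids


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]


@dataclass
class PotentialGrid:
    """A sampled scalar potential with a validity mask.

    ``values`` holds the potential at unmasked points (arbitrary but
    consistent units: e / (eps * Angstrom)); ``mask`` is True where the
    point is valid (outside every van der Waals envelope considered).
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    values: np.ndarray
    mask: np.ndarray

    def compatible_with(self, other: "PotentialGrid") -> bool:
        return (
            np.allclose(self.origin, other.origin)
            and self.spacing == other.spacing
            and self.dims == other.dims
        )


def shared_grid_spec(
    poses: Sequence[Pose], spacing: float = 0.5, padding: float = 4.0
) -> GridSpec:
    """Grid covering the union bounding box of several poses plus padding."""
    coords = np.vstack([p.coords for p in poses])
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return GridSpec(origin=tuple(lo), spacing=spacing, dims=dims)


def _grid_points(spec: GridSpec) -> np.ndarray:
    ax = [
        np.asarray(spec.origin)[i] + spec.spacing * np.arange(spec.dims[i])
        for i in range(3)
    ]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def compute_potential_grid(
    pose: Pose,
    spacing: float = 0.5,
    padding: float = 4.0,
    grid: GridSpec | None = None,
    mask_poses: Sequence[Pose] = (),
    dielectric: str = "distance",
    epsilon: float = 1.0,
) -> PotentialGrid:
    """Sample the pose's electrostatic potential on a regular grid.

    V(r) = sum_i q_i / (eps(d_i) * d_i) with eps(d) = 4d by default
    (``dielectric="distance"``) or a constant (``dielectric="constant"``,
    vacuum for ``epsilon=1``).  Grid points inside the van der Waals
    envelope of the pose — or of any pose in ``mask_poses`` (the partner
    molecule, when two fields share a box) — are masked out, which also
    removes the Coulomb singularities.
    """
    if grid is None:
        grid = shared_grid_spec([pose], spacing=spacing, padding=padding)
    pts = _grid_points(grid)
    n = pts.shape[0]
    values = np.zeros(n)
    mask = np.ones(n, dtype=bool)
    for p in (pose, *mask_poses):
        for atom in p.atoms:
            d = np.linalg.norm(pts - atom.xyz, axis=1)
            mask &= d >= atom.radius
    for atom in pose.atoms:
        d = np.linalg.norm(pts - atom.xyz, axis=1)
        d = np.where(d < 1e-9, 1e-9, d)
        if dielectric == "distance":
            values += atom.charge / (4.0 * d * d)
        elif dielectric == "constant":
            values += atom.charge / (epsilon * d)
        else:
            raise ValueError(f"unknown dielectric model {dielectric!r}")
    values = np.where(mask, values, 0.0)
    return PotentialGrid(
        origin=np.asarray(grid.origin, dtype=float),
        spacing=grid.spacing,
        dims=grid.dims,
        values=values,
        mask=mask,
    )


def electrostatic_tanimoto(a: PotentialGrid, b: PotentialGrid) -> float:
    """Continuous Tanimoto overlap of two fields on a common grid.

    T = sum(ab) / (sum(a^2) + sum(b^2) - sum(ab)) over the intersection of
    the two validity masks.  Symmetric; lies in [-1/3, 1] with T = 1 for
    identical fields and T = -1/3 for exactly opposite ones.
    """
    if not a.compatible_with(b):
        raise ValueError("grids differ in origin, spacing or dimensions")
    common = a.mask & b.mask
    va, vb = a.values[common], b.values[common]
    aa = float(np.dot(va, va))
    bb = float(np.dot(vb, vb))
    ab = float(np.dot(va, vb))
    denom = aa + bb - ab
    if denom == 0.0:
        raise ValueError(
            "both fields are identically zero on the common grid"
        )
    return ab / denom


@dataclass
class ETResult:
    """Best reference similarity for one compound (one pose kept)."""

    compound_id: str
    best_reference_id: str
    et_pb: float
    pose_id: str

    def __post_init__(self) -> None:
        if not (ET_MIN - 1e-9 <= self.et_pb <= 1.0 + 1e-9):
            raise ValueError(f"et_pb {self.et_pb} outside [-1/3, 1]")


def best_reference_similarity(
    compound_poses: Sequence[Pose],
    references: Sequence[Pose],
    spacing: float = 0.5,
    padding: float = 4.0,
    dielectric: str = "distance",
) -> ETResult:
    """Keep the single pose with the highest field Tanimoto to any reference.

    Every (pose, reference) pair is evaluated on a grid shared by that
    pair (union bounding box, mutual van der Waals masking); only the best
    pose per compound is kept, regardless of which reference produced it.
    """
    if not references:
        raise ValueError("no reference poses given")
    if not compound_poses:
        raise ValueError("no compound poses given")
    best: tuple[float, str, str] | None = None
    for pose in compound_poses:
        for ref in references:
            spec = shared_grid_spec([pose, ref], spacing, padding)
            ga = compute_potential_grid(
                pose, grid=spec, mask_poses=[ref], dielectric=dielectric
            )
            gb = compute_potential_grid(
                ref, grid=spec, mask_poses=[pose], dielectric=dielectric
            )
            t = electrostatic_tanimoto(ga, gb)
            if best is None or t > best[0]:
                best = (t, ref.pose_id, pose.pose_id)
    t, ref_id, pose_id = best
    return ETResult(
        compound_id=compound_poses[0].compound_id,
        best_reference_id=ref_id,
        et_pb=t,
        pose_id=pose_id,
    )


# ---------------------------------------------------------------------------
# reference triage and cutoff calibration


def triage_references(
    reference_scores: dict[str, dict],
    min_separation: float = 0.25,
) -> tuple[list[str], list[dict]]:
    """Discard references that do not separate potent actives from decoys.

    ``reference_scores`` maps reference id to ``{"active_et": array,
    "active_px": array, "decoy_et": array}``: the per-compound best-pose
    Tanimoto values obtained with that reference as the query.  A
    reference is kept iff the two-sample Kolmogorov-Smirnov statistic
    between the et_pb of potent actives (pX > 7) and that of decoys is at
    least ``min_separation`` — references whose active and decoy
    distributions look alike carry no usable cutoff.
    """
    kept: list[str] = []
    audit: list[dict] = []
    for ref_id in sorted(reference_scores):
        data = reference_scores[ref_id]
        act_et = np.asarray(data["active_et"], dtype=float)
        act_px = np.asarray(data["active_px"], dtype=float)
        dec_et = np.asarray(data["decoy_et"], dtype=float)
        potent = act_et[act_px > 7]
        if len(potent) == 0 or len(dec_et) == 0:
            audit.append(
                {"reference": ref_id, "kept": False, "ks": None,
                 "note": "empty stratum (pX>7 actives or decoys)"}
            )
            continue
        ks = float(ks_2samp(potent, dec_et).statistic)
        keep = ks >= min_separation
        if keep:
            kept.append(ref_id)
        audit.append(
            {"reference": ref_id, "kept": keep, "ks": ks, "note": ""}
        )
    return kept, audit


@dataclass
class CutoffCalibration:
    """A per-target et_pb cutoff with its supporting histograms."""

    target_id: str
    cutoff: float
    provenance: str  # "youden" or "manual"
    youden_j: float
    discriminating: bool
    histogram: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (ET_MIN - 1e-9 <= self.cutoff <= 1.0 + 1e-9):
            raise ValueError(f"cutoff {self.cutoff} outside [-1/3, 1]")


def _histogram_bins(
    decoys: np.ndarray, actives: np.ndarray, px: np.ndarray,
    width: float = 0.05,
) -> dict:
    edges = np.arange(ET_MIN, 1.0 + width, width)
    edges[-1] = max(edges[-1], 1.0 + 1e-12)
    strata = {
        "decoy": decoys,
        "act_lt4": actives[px < 4],
        "act_4to7": actives[(px >= 4) & (px <= 7)],
        "act_gt7": actives[px > 7],
    }
    return {
        "bin_left": edges[:-1].tolist(),
        **{
            name: np.histogram(vals, bins=edges)[0].tolist()
            for name, vals in strata.items()
        },
    }


def calibrate_cutoff(
    active_et: Sequence[float],
    active_px: Sequence[float],
    decoy_et: Sequence[float],
    target_id: str = "",
    manual_cutoff: float | None = None,
    min_j: float = 0.25,
) -> CutoffCalibration:
    """Choose the et_pb cutoff separating potent actives from decoys.

    Candidate cutoffs are the midpoints between adjacent distinct values
    in the pooled (pX > 7 actives + decoys) sample; the candidate
    maximizing Youden's J = sensitivity + specificity - 1 is chosen (on a
    tie, the lowest such cutoff, which favours sensitivity).  If the best
    J falls below ``min_j`` the calibration is flagged non-discriminating.
    Histogram bins of width 0.05 over [-1/3, 1] for decoys and the three
    pX strata (<4, 4-7, >7) are attached for plotting.  A manual override
    skips the search but keeps the histograms.
    """
    act = np.asarray(active_et, dtype=float)
    px = np.asarray(active_px, dtype=float)
    dec = np.asarray(decoy_et, dtype=float)
    potent = act[px > 7]
    if len(potent) == 0:
        raise ValueError("empty stratum: no actives with pX > 7")
    if len(dec) == 0:
        raise ValueError("empty stratum: no decoys")
    hist = _histogram_bins(dec, act, px)

    def youden(c: float) -> float:
        sens = float(np.mean(potent >= c))
        spec = float(np.mean(dec < c))
        return sens + spec - 1.0

    if manual_cutoff is not None:
        return CutoffCalibration(
            target_id=target_id,
            cutoff=float(manual_cutoff),
            provenance="manual",
            youden_j=youden(float(manual_cutoff)),
            discriminating=youden(float(manual_cutoff)) >= min_j,
            histogram=hist,
        )
    pooled = np.unique(np.concatenate([potent, dec]))
    if len(pooled) == 1:
        candidates = pooled
    else:
        candidates = (pooled[:-1] + pooled[1:]) / 2.0
    js = np.array([youden(c) for c in candidates])
    best_j = float(js.max())
    cutoff = float(candidates[int(np.argmax(js))])  # lowest argmax
    return CutoffCalibration(
        target_id=target_id,
        cutoff=cutoff,
        provenance="youden",
        youden_j=best_j,
        discriminating=best_j >= min_j,
        histogram=hist,
    )


def apply_cutoff(
    results: Sequence[ETResult], cutoff: float
) -> list[ETResult]:
    """Keep results with et_pb >= cutoff (boundary inclusive)."""
    return [r for r in results if r.et_pb >= cutoff]
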