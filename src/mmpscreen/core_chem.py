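"""Compound ingestion, standardization, fingerprints and structural alerts.

Everything downstream of this module works on :class:`MoleculeRecord`
objects whose SMILES are canonical, so that identity comparisons,
fingerprints and substructure alerts are deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

__all__ = [
    "MoleculeRecord",
    "Fingerprint",
    "StandardizationError",
    "standardize_molecule",
    "mw_filter",
    "morgan_fingerprint",
    "tanimoto_similarity",
    "select_mw_decoys",
    "DecoySelection",
    "pains_flag",
    "read_smiles_file",
    "write_smiles_file",
    "read_validation_csv",
    "read_sdf_records",
]

ROLES = ("library", "active", "decoy")


class StandardizationError(ValueError):
    """Raised when an input structure cannot be parsed or sanitized."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized compound.

    Parameters
    ----------
    id : str
        Opaque compound identifier.
    smiles : str
        Canonical SMILES (as produced by :func:`standardize_molecule`).
    mw : float
        Molecular mass in Da.
    role : str
        One of ``library``, ``active``, ``decoy``.
    activity_px : float or None
        pX = -log10(IC50 or Ki in molar) for curated actives; in the
        curated sets used here pX lies in [1, 13].
    source : str
        Free-text provenance tag.
    """

    id: str
    smiles: str
    mw: float
    role: str = "library"
    activity_px: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not self.mw > 0:
            raise ValueError(f"mw must be positive, got {self.mw}")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary Morgan (ECFP-style) fingerprint."""

    bits: np.ndarray  # uint8 0/1 vector of length nbits
    nbits: int
    radius: int

    def popcount(self) -> int:
        return int(self.bits.sum())


def standardize_molecule(
    raw_structure: str,
    id: str = "",
    role: str = "library",
    activity_px: float | None = None,
    source: str = "",
) -> MoleculeRecord:
    """Parse a SMILES, canonicalize it and return a :class:`MoleculeRecord`.

    The canonical form is RDKit's canonical isomeric SMILES after
    sanitization; explicit charges in the input are trusted and preserved
    (no protonation-state or tautomer enumeration is attempted).
    Applying the operation to its own output is a no-op.

    Raises
    ------
    StandardizationError
        If the structure does not parse, with the offending input echoed.
    """
    mol = Chem.MolFromSmiles(raw_structure)
    if mol is None:
        raise StandardizationError(f"unparseable structure: {raw_structure!r}")
    canonical = Chem.MolToSmiles(mol)
    mw = Descriptors.MolWt(mol)
    return MoleculeRecord(
        id=id or canonical,
        smiles=canonical,
        mw=mw,
        role=role,
        activity_px=activity_px,
        source=source,
    )


def mw_filter(
    records: Iterable[MoleculeRecord], lo: float, hi: float
) -> list[MoleculeRecord]:
    """Keep records with ``lo <= mw <= hi`` (bounds inclusive).

    The screening libraries use the 300-600 Da window; a compound of
    exactly 300 or 600 Da survives.
    """
    if not lo < hi:
        raise ValueError(f"lo must be < hi, got [{lo}, {hi}]")
    return [r for r in records if lo <= r.mw <= hi]


def _mol_from_record(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:  # pragma: no cover - record invariant guards this
        raise StandardizationError(f"record {record.id} has invalid SMILES")
    return mol


def morgan_fingerprint(
    record: MoleculeRecord, radius: int = 2, nbits: int = 2048
) -> Fingerprint:
    """Morgan fingerprint of the given radius folded to ``nbits`` bits.

    Radius 2 corresponds to ECFP4-style atom environments.  The result is
    a pure function of the canonical structure, radius and length.
    """
    mol = _mol_from_record(record)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(nbits, dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return Fingerprint(bits=arr, nbits=nbits, radius=radius)


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity |a n b| / |a u b| of two equal-length fingerprints.

    Two all-zero vectors are defined to have similarity 0 (avoids 0/0).
    """
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 0.0
    return inter / union


@dataclass
class DecoySelection:
    """Result of MW-matched decoy selection with a per-active audit trail."""

    decoys: list[MoleculeRecord]
    audit: list[dict] = field(default_factory=list)


def select_mw_decoys(
    actives: Sequence[MoleculeRecord],
    pool: Sequence[MoleculeRecord],
    tol: float = 25.0,
    ratio: int = 1,
    seed: int = 0,
) -> DecoySelection:
    """Select up to ``ratio`` MW-matched decoys per active from ``pool``.

    For each active, pool members with ``|MW_pool - MW_active| <= tol`` are
    eligible; ``ratio`` of them are drawn without replacement (a compound
    is used for at most one active).  Shortfalls are recorded in the audit
    list.  Deterministic for a fixed seed and input order.
    """
    rng = np.random.default_rng(seed)
    active_smiles = {a.smiles for a in actives}
    available = [p for p in pool if p.smiles not in active_smiles]
    taken: set[str] = set()
    decoys: list[MoleculeRecord] = []
    audit: list[dict] = []
    for active in actives:
        eligible = [
            p
            for p in available
            if p.id not in taken and abs(p.mw - active.mw) <= tol
        ]
        n_pick = min(ratio, len(eligible))
        picks = []
        if n_pick:
            idx = rng.choice(len(eligible), size=n_pick, replace=False)
            picks = [eligible[i] for i in sorted(idx)]
        for p in picks:
            taken.add(p.id)
            decoys.append(replace(p, role="decoy"))
        audit.append(
            {
                "active_id": active.id,
                "requested": ratio,
                "selected": n_pick,
                "shortfall": ratio - n_pick,
                "decoy_ids": [p.id for p in picks],
            }
        )
    return DecoySelection(decoys=decoys, audit=audit)


_PAINS_CATALOG: FilterCatalog | None = None


def _pains_catalog() -> FilterCatalog:
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog(params)
    return _PAINS_CATALOG


def pains_flag(record: MoleculeRecord) -> tuple[bool, list[str]]:
    """Flag pan-assay interference (PAINS) substructures.

    Matches the record against the PAINS alert catalogue (families A-C)
    and returns ``(flagged, matched_alert_names)``.  Promiscuous
    assay-artifact scaffolds among screening hits are reported, not
    removed: the caller decides their fate.
    """
    mol = _mol_from_record(record)
    catalog = _pains_catalog()
    matches = catalog.GetMatches(mol)
    names = sorted(m.GetDescription() for m in matches)
    return (len(names) > 0, names)


# ---------------------------------------------------------------------------
# readers / writers


def read_smiles_file(path: str, role: str = "library") -> list[MoleculeRecord]:
    """Read a ``SMILES<TAB>id`` file, one record per line."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else ""
            records.append(standardize_molecule(smiles, id=mol_id, role=role))
    return records


def write_smiles_file(records: Iterable[MoleculeRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.id}\n")


def read_validation_csv(path: str) -> list[MoleculeRecord]:
    """Read a validation set CSV with header ``id,smiles,role,px``."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            px = row.get("px", "")
            records.append(
                standardize_molecule(
                    row["smiles"],
                    id=row["id"],
                    role=row["role"],
                    activity_px=float(px) if px not in ("", None) else None,
                )
            )
    return records


def read_sdf_records(path: str, role: str = "library") -> list[MoleculeRecord]:
    """Read an SDF (V2000); the record id is taken from the title line."""
    records = []
    for mol in Chem.SDMolSupplier(path):
        if mol is None:
            continue
        records.append(
            standardize_molecule(
                Chem.MolToSmiles(mol), id=mol.GetProp("_Name"), role=role
            )
        )
    return records
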