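"""Encoding of the combinatorial photocatalyst library.

A candidate cyanopyridine (CNP) photocatalyst is defined by a pair of
substituents grafted onto a common cyanopyridine core: an Ra group (from the
beta-keto nitrile component of the Hantzsch synthesis) and an Rb group (from
the aromatic aldehyde).  Each candidate is characterized by 16 computed
thermodynamic / optoelectronic / excited-state descriptors which are consumed
here as plain numbers; the quantum chemistry that produces them is out of
scope.

This module provides the library enumeration, Morgan fingerprints and
Tanimoto distances, the thermodynamic feasibility screen against the
substrate-oxidation and nickel-reduction windows, and Kennard-Stone max-min
diversity selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

from .errors import DimensionError, SmilesParseError, ValidationError

RDLogger.DisableLog("rdApp.*")

#: Canonical ordering of the 16 molecular descriptors.  Column names in
#: candidate tables and feature orderings in models follow this order.
DESCRIPTOR_FIELDS: tuple[str, ...] = (
    "ip",            # adiabatic ionization potential (V)
    "ea",            # adiabatic electron affinity == E1/2red[CNP/CNP-] (V vs SHE)
    "ip_star",       # excited-state ionization potential (V)
    "ea_star",       # exciton electron affinity == E1/2red[CNP*/CNP-] (V vs SHE)
    "de_s1_s0",      # optical gap, S1 <- S0 (eV)
    "osc_strength",  # oscillator strength f of S1 (dimensionless)
    "delta_dipole",  # dipole change between S1 and S0 (Debye)
    "h_ct",          # hole/electron extension along the CT direction (Angstrom)
    "h_index",       # H index (Angstrom)
    "t_index",       # t index (Angstrom)
    "delta_sigma",   # difference in electron/hole spatial extent (Angstrom)
    "s_r",           # electron-hole overlap integral, in [0, 1]
    "d_index",       # electron-hole centroid distance (Angstrom)
    "e_coulomb",     # electron-hole Coulomb attraction (eV)
    "de_s1_t1",      # singlet-triplet gap (eV)
    "lambda_reorg",  # internal reorganization energy of the radical anion (eV)
)

RA_CLASSES = frozenset({"ED", "EW", "X"})
RB_CLASSES = frozenset({"PAH", "PA", "CZ"})


@dataclass(frozen=True)
class DescriptorVector:
    """The 16 computed molecular properties encoding one catalyst candidate."""

    ip: float
    ea: float
    ip_star: float
    ea_star: float
    de_s1_s0: float
    osc_strength: float
    delta_dipole: float
    h_ct: float
    h_index: float
    t_index: float
    delta_sigma: float
    s_r: float
    d_index: float
    e_coulomb: float
    de_s1_t1: float
    lambda_reorg: float

    def __post_init__(self):
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("descriptor vector contains non-finite values")
        if self.de_s1_s0 <= 0:
            raise ValidationError("optical gap de_s1_s0 must be positive")
        if not (0.0 <= self.s_r <= 1.0):
            raise ValidationError("electron-hole overlap s_r must lie in [0, 1]")
        if self.d_index < 0:
            raise ValidationError("d_index must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in DESCRIPTOR_FIELDS], dtype=float)

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "DescriptorVector":
        return cls(**{f: float(m[f]) for f in DESCRIPTOR_FIELDS})


@dataclass(frozen=True)
class Substituent:
    """One Ra or Rb moiety: an id, a class label and an optional SMILES fragment."""

    id: str
    label: str
    smiles: str | None = None


@dataclass
class SubstituentSet:
    """The Ra x Rb vocabulary defining the combinatorial catalyst library."""

    ra: list[Substituent]
    rb: list[Substituent]

    def __post_init__(self):
        for name, entries, classes in (("ra", self.ra, RA_CLASSES), ("rb", self.rb, RB_CLASSES)):
            seen: set[str] = set()
            for s in entries:
                if s.id in seen:
                    raise ValidationError(f"duplicate {name} substituent id: {s.id!r}")
                seen.add(s.id)
                if s.label not in classes:
                    raise ValidationError(
                        f"{name} substituent {s.id!r} has class {s.label!r}; "
                        f"expected one of {sorted(classes)}"
                    )


@dataclass
class CandidateMolecule:
    """One library member: an (Ra, Rb) combination on the cyanopyridine core."""

    id: str
    ra_id: str
    rb_id: str
    smiles: str | None = None
    descriptors: DescriptorVector | None = None


#: SMILES template for assembling a candidate from two substituent fragments.
#: Ring-closure digits 1 belong to the core; fragments use 2+ within their
#: own branches.
CORE_TEMPLATE = "N#Cc1cc({ra})cc({rb})n1"


def enumerate_library(
    substituents: SubstituentSet, template: str = CORE_TEMPLATE
) -> list[CandidateMolecule]:
    """Enumerate all Ra x Rb combinations as candidate molecules.

    Ordering is deterministic: Ra-major, then Rb, in the order the
    substituent lists were given.  Ids are assigned sequentially
    (``CNP-1`` ... ``CNP-{n}``) in that order.  SMILES are assembled from the
    core template when both fragments provide one.
    """
    if not substituents.ra or not substituents.rb:
        raise ValidationError("both substituent lists must be non-empty")
    out: list[CandidateMolecule] = []
    k = 0
    for ra in substituents.ra:
        for rb in substituents.rb:
            k += 1
            smiles = None
            if ra.smiles is not None and rb.smiles is not None:
                smiles = template.format(ra=ra.smiles, rb=rb.smiles)
            out.append(
                CandidateMolecule(id=f"CNP-{k}", ra_id=ra.id, rb_id=rb.id, smiles=smiles)
            )
    return out


# ---------------------------------------------------------------------------
# Fingerprints


@dataclass(frozen=True)
class Fingerprint:
    """A Morgan (circular) fingerprint bit vector."""

    bits: np.ndarray  # boolean vector
    radius: int
    source_smiles: str  # canonical SMILES of the fingerprinted molecule

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def nbits(self) -> int:
        return self.bits.size

    def popcount(self) -> int:
        return int(self.bits.sum())


def morgan_fingerprint(smiles: str, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Morgan fingerprint (default radius 2, 2,048 bits) of a SMILES string.

    The input is canonicalized first, so any SMILES spelling of the same
    molecule yields the identical bit vector.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    canonical = Chem.MolToSmiles(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(nbits, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return Fingerprint(bits=bits, radius=radius, source_smiles=canonical)


def _as_bits(fp) -> np.ndarray:
    if isinstance(fp, Fingerprint):
        return fp.bits
    return np.asarray(fp, dtype=bool)


def tanimoto_distance(a, b) -> float:
    """Tanimoto distance 1 - |a AND b| / |a OR b| between two bit vectors.

    Two all-zero vectors are identical bit sets and have distance 0.
    """
    xa, xb = _as_bits(a), _as_bits(b)
    if xa.shape != xb.shape:
        raise DimensionError(f"fingerprint length mismatch: {xa.size} vs {xb.size}")
    union = int(np.logical_or(xa, xb).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(xa, xb).sum())
    return 1.0 - inter / union


def tanimoto_matrix(fps: Sequence) -> np.ndarray:
    """Pairwise Tanimoto distance matrix for a list of fingerprints."""
    B = np.stack([_as_bits(f) for f in fps]).astype(np.float64)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# Thermodynamic feasibility screen


@dataclass(frozen=True)
class FeasibilityThresholds:
    """Redox windows the catalyst must straddle to drive both catalytic cycles.

    The excited catalyst must oxidize the amino-acid substrate
    (E_red = +1.19 V vs SHE) and the reduced catalyst must regenerate the
    nickel co-catalyst (Ni(I)/Ni(0) at -1.17 V, Ni(II)/Ni(I) at -1.02 V vs SHE).
    """

    substrate_ox_potential: float = 1.19
    ni_I_0_potential: float = -1.17
    ni_II_I_potential: float = -1.02

    def __post_init__(self):
        if not (
            self.substrate_ox_potential > 0 > self.ni_II_I_potential > self.ni_I_0_potential
        ):
            raise ValidationError(
                "thresholds must satisfy substrate_ox > 0 > Ni(II/I) > Ni(I/0)"
            )


@dataclass(frozen=True)
class FeasibilityRecord:
    oxidation_ok: bool  # EA* exceeds the substrate oxidation potential
    reduction_ok: bool  # EA below the Ni(I)/Ni(0) potential
    feasible: bool


def thermodynamic_feasibility(
    d: DescriptorVector, t: FeasibilityThresholds = FeasibilityThresholds()
) -> FeasibilityRecord:
    """Check whether (EA, EA*) straddle the substrate-oxidation / Ni-reduction window."""
    ox = bool(d.ea_star > t.substrate_ox_potential)
    red = bool(d.ea < t.ni_I_0_potential)
    return FeasibilityRecord(oxidation_ok=ox, reduction_ok=red, feasible=ox and red)


def screen_library(
    library: Iterable[CandidateMolecule],
    thresholds: FeasibilityThresholds = FeasibilityThresholds(),
):
    """Screen every candidate; returns (records dict, summary dict).

    Screening is annotation only — the window is a necessary thermodynamic
    condition, not a sufficient one, so candidates are never filtered out here.
    """
    records: dict[str, FeasibilityRecord] = {}
    for mol in library:
        if mol.descriptors is None:
            raise ValidationError(f"candidate {mol.id!r} has no descriptors")
        records[mol.id] = thermodynamic_feasibility(mol.descriptors, thresholds)
    n = len(records)
    summary = {
        "n_total": n,
        "n_fail_oxidation": sum(not r.oxidation_ok for r in records.values()),
        "n_fail_reduction": sum(not r.reduction_ok for r in records.values()),
        "n_feasible": sum(r.feasible for r in records.values()),
    }
    return records, summary


# ---------------------------------------------------------------------------
# Kennard-Stone diversity selection


def kennard_stone_select(distances: np.ndarray, k: int) -> list[int]:
    """Kennard-Stone max-min selection of ``k`` indices from a distance matrix.

    The first two picks are the most distant pair (lexicographically smallest
    pair on ties); every subsequent pick maximizes the minimum distance to the
    already-selected set, breaking ties by lowest index.  Fully deterministic.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    n = D.shape[0]
    if k < 2:
        raise ValidationError("k must be at least 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds matrix size {n}")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValidationError("distance matrix must have zero diagonal")

    iu = np.triu_indices(n, k=1)
    dmax = D[iu].max() if iu[0].size else 0.0
    # lexicographically smallest maximal pair
    hits = np.argwhere(np.isclose(D, dmax) & (np.arange(n)[:, None] < np.arange(n)[None, :]))
    i0, j0 = min(map(tuple, hits))
    selected = [int(i0), int(j0)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    mind = np.minimum(D[i0], D[j0])
    while len(selected) < k:
        cand = np.where(remaining)[0]
        best = cand[np.argmax(mind[cand])]  # argmax returns first max -> lowest index
        selected.append(int(best))
        remaining[best] = False
        mind = np.minimum(mind, D[best])
    return selected


def standardize_descriptors(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score a descriptor matrix per column; returns (Z, mean, std).

    Constant columns get std 1 so they map to zero rather than NaN.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def descriptor_matrix(library: Sequence[CandidateMolecule]) -> np.ndarray:
    """Stack library descriptors into an (n, 16) matrix in canonical order."""
    rows = []
    for mol in library:
        if mol.descriptors is None:
            raise ValidationError(f"candidate {mol.id!r} has no descriptors")
        rows.append(mol.descriptors.to_array())
    return np.stack(rows)


def euclidean_distance_matrix(X: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Pairwise Euclidean distances, by default on z-scored columns."""
    from scipy.spatial.distance import squareform, pdist

    X = np.asarray(X, dtype=float)
    if standardize:
        X, _, _ = standardize_descriptors(X)
    return squareform(pdist(X))
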