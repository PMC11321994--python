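"""The formulation condition space: (catalyst, ligand, Ni loading) triples.

A reaction condition combines one photocatalyst, one nickel-coordinating
pyridyl ligand and one integer Ni loading (mol%).  Conditions are compared by
a combined distance with four components: the scalar gap between the
catalysts' electronic features (computed electron affinity or measured
reduction potential), the Tanimoto distance between the catalysts' Morgan
fingerprints, the Tanimoto distance between the ligands' fingerprints, and
the scalar gap between the Ni loadings.  Each component is min-max normalized
over the materialized space so it lies in [0, 1]; the normalizers are frozen
at construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemspace import Fingerprint, morgan_fingerprint, tanimoto_matrix
from .errors import LookupMissError, ValidationError

COMPONENT_NAMES = ("electronic", "fp_cnp", "fp_ligand", "conc")


@dataclass(frozen=True)
class CatalystEntry:
    """A catalyst as it enters the formulation space."""

    id: str
    smiles: str | None
    electronic_feature: float  # EA or measured E1/2red[CNP/CNP-], V vs SHE
    fingerprint: Fingerprint | None = None


@dataclass(frozen=True)
class LigandEntry:
    id: str
    smiles: str | None
    fingerprint: Fingerprint | None = None


@dataclass(frozen=True)
class ReactionCondition:
    """One formulation point, the unit of the discrete search space."""

    cnp_id: str
    ligand_id: str
    ni_conc: int
    electronic_feature: float


def _resolve_fp(entry, kind: str) -> Fingerprint:
    if entry.fingerprint is not None:
        return entry.fingerprint
    if entry.smiles is None:
        raise ValidationError(f"{kind} {entry.id!r} has neither SMILES nor fingerprint")
    return morgan_fingerprint(entry.smiles)


class ConditionSpace:
    """The materialized |catalysts| x |ligands| x |loadings| condition grid.

    Stores per-entity fingerprints and the frozen per-component min-max
    normalizers; pairwise distances between arbitrary index subsets are
    computed on demand from small per-entity distance matrices, so the full
    N x N matrix is only built when explicitly requested.
    """

    def __init__(
        self,
        catalysts: Sequence[CatalystEntry],
        ligands: Sequence[LigandEntry],
        conc_grid: Sequence[int],
    ):
        if not catalysts or not ligands or not len(conc_grid):
            raise ValidationError("catalysts, ligands and conc_grid must be non-empty")
        if len({c.id for c in catalysts}) != len(catalysts):
            raise ValidationError("duplicate catalyst ids")
        if len({l.id for l in ligands}) != len(ligands):
            raise ValidationError("duplicate ligand ids")
        self.catalysts = list(catalysts)
        self.ligands = list(ligands)
        self.conc_grid = [int(c) for c in conc_grid]
        if len(set(self.conc_grid)) != len(self.conc_grid):
            raise ValidationError("duplicate Ni loadings in grid")

        cat_fps = [_resolve_fp(c, "catalyst") for c in self.catalysts]
        lig_fps = [_resolve_fp(l, "ligand") for l in self.ligands]
        self._d_fp_cat = tanimoto_matrix(cat_fps)
        self._d_fp_lig = tanimoto_matrix(lig_fps)
        self._electronic = np.array([c.electronic_feature for c in self.catalysts])

        nc, nl, ng = len(self.catalysts), len(self.ligands), len(self.conc_grid)
        # enumeration order: catalyst-major, then ligand, then loading
        self.cat_idx = np.repeat(np.arange(nc), nl * ng)
        self.lig_idx = np.tile(np.repeat(np.arange(nl), ng), nc)
        self.conc = np.tile(np.array(self.conc_grid, dtype=float), nc * nl)
        self.ids = [
            f"P-{i + 1}" for i in range(nc * nl * ng)
        ]
        self._id_to_index = {pid: i for i, pid in enumerate(self.ids)}
        self._triple_to_index = {
            (self.catalysts[self.cat_idx[i]].id, self.ligands[self.lig_idx[i]].id, int(self.conc[i])): i
            for i in range(len(self.ids))
        }

        # frozen min-max normalizers per component (max pairwise distance)
        e_range = float(self._electronic.max() - self._electronic.min())
        c_range = float(max(self.conc_grid) - min(self.conc_grid))
        self.component_normalizers = {
            "electronic": e_range if e_range > 0 else 1.0,
            "fp_cnp": float(self._d_fp_cat.max()) if self._d_fp_cat.max() > 0 else 1.0,
            "fp_ligand": float(self._d_fp_lig.max()) if self._d_fp_lig.max() > 0 else 1.0,
            "conc": c_range if c_range > 0 else 1.0,
        }

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, target) -> int:
        """Resolve a condition id, an index, or a (cnp, ligand, conc) triple."""
        if isinstance(target, (int, np.integer)):
            return int(target)
        if isinstance(target, str):
            try:
                return self._id_to_index[target]
            except KeyError:
                raise LookupMissError(f"unknown condition id {target!r}") from None
        if isinstance(target, ReactionCondition):
            key = (target.cnp_id, target.ligand_id, int(target.ni_conc))
        else:
            key = (target[0], target[1], int(target[2]))
        try:
            return self._triple_to_index[key]
        except KeyError:
            raise LookupMissError(f"condition {key!r} not in space") from None

    def condition(self, i: int) -> ReactionCondition:
        ci = self.cat_idx[i]
        return ReactionCondition(
            cnp_id=self.catalysts[ci].id,
            ligand_id=self.ligands[self.lig_idx[i]].id,
            ni_conc=int(self.conc[i]),
            electronic_feature=float(self._electronic[ci]),
        )

    @property
    def conditions(self) -> list[ReactionCondition]:
        return [self.condition(i) for i in range(len(self))]

    def component_dists(self, I, J) -> np.ndarray:
        """Normalized component distance tensor of shape (4, |I|, |J|).

        Order follows :data:`COMPONENT_NAMES`.  Every entry lies in [0, 1].
        """
        I = np.asarray(I, dtype=int)
        J = np.asarray(J, dtype=int)
        norm = self.component_normalizers
        ci, cj = self.cat_idx[I], self.cat_idx[J]
        d_e = np.abs(self._electronic[ci][:, None] - self._electronic[cj][None, :])
        d_e /= norm["electronic"]
        d_m = self._d_fp_cat[np.ix_(ci, cj)] / norm["fp_cnp"]
        d_l = self._d_fp_lig[np.ix_(self.lig_idx[I], self.lig_idx[J])] / norm["fp_ligand"]
        d_c = np.abs(self.conc[I][:, None] - self.conc[J][None, :]) / norm["conc"]
        return np.stack([d_e, d_m, d_l, d_c])

    def distance(self, p, q) -> float:
        """Combined distance: sum of the four normalized component distances."""
        i, j = self.index_of(p), self.index_of(q)
        return float(self.component_dists([i], [j]).sum())

    def distance_matrix(self, indices=None) -> np.ndarray:
        """Materialize the symmetric combined-distance matrix (optionally on a subset)."""
        if indices is None:
            indices = np.arange(len(self))
        return self.component_dists(indices, indices).sum(axis=0)


def build_condition_space(
    cnps: Sequence[CatalystEntry],
    ligands: Sequence[LigandEntry],
    conc_grid: Sequence[int],
) -> ConditionSpace:
    """Construct the full condition grid with frozen component normalizers."""
    return ConditionSpace(cnps, ligands, conc_grid)


def condition_distance(p: ReactionCondition, q: ReactionCondition, space: ConditionSpace) -> float:
    """Combined normalized distance between two conditions of the same space."""
    return space.distance(p, q)
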