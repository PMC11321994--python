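"""Bundled synthetic presets at the sizes of the real campaigns.

These generators produce, at import-free runtime cost of a few seconds:

* a 20 x 28 = 560-member combinatorial catalyst library with simple but valid
  SMILES and a full 16-descriptor table;
* a set of 25 pyridyl nickel ligands;
* the 18 (catalyst) x 25 (ligand) x 10 (loading) = 4,500-point formulation
  condition space.

The descriptor table is a statistical emulation of a computed library, not
quantum-chemistry output: descriptors are smooth functions of latent
substituent properties (donor strength of Ra, conjugation of Rb) plus seeded
noise.  The emulation deliberately reproduces the feasibility-screen
population statistics of the real library — exactly 4 of 560 molecules fail
the excited-state oxidation window (EA* <= 1.19 V vs SHE) and exactly 1
fails the ground-state reduction window (EA >= -1.17 V vs SHE) — so the
screening pipeline can be exercised end-to-end against known counts.
"""

from __future__ import annotations

import numpy as np

from .chemspace import (
    CandidateMolecule,
    DescriptorVector,
    Substituent,
    SubstituentSet,
    enumerate_library,
)
from .conditions import CatalystEntry, ConditionSpace, LigandEntry, build_condition_space

# --- substituent vocabularies -------------------------------------------------

_RA_ED = ["C", "CC", "OC", "OCC", "N", "N(C)C", "CO"]                      # 7 electron donors
_RA_EW = ["C(F)(F)F", "C#N", "[N+](=O)[O-]", "C(=O)C", "S(=O)(=O)C"]       # 5 withdrawers
_RA_X = ["F", "Cl", "Br", "I", "CF", "CCl", "CBr", "CI"]                   # 8 halogenated

_RB_PAH = (
    ["c2ccccc2"]
    + [f"c2ccc({g})cc2" for g in [
        "C", "CC", "OC", "F", "Cl", "Br", "C(C)(C)C", "C#N", "C(F)(F)F",
        "OCC", "I", "CO", "SC", "C=C",
    ]]
    + ["c2ccc3ccccc3c2", "c2cccc3ccccc23", "c2ccc3cc4ccccc4cc3c2"]
)  # 18 polyaromatics
_RB_PA = [
    "c2ccc(N)cc2", "c2ccc(NC)cc2", "c2ccc(N(C)C)cc2",
    "c2ccc(N(c3ccccc3)c3ccccc3)cc2", "N(c2ccccc2)c2ccccc2",
]  # 5 phenylamines
_RB_CZ = [
    "n2c3ccccc3c3ccccc32",
    "n2c3ccc(C)cc3c3ccc(C)cc32",
    "n2c3ccc(C(C)(C)C)cc3c3ccc(C(C)(C)C)cc32",
    "n2c3ccc(OC)cc3c3ccc(OC)cc32",
    "n2c3ccc(Br)cc3c3ccc(Br)cc32",
]  # 5 carbazoles


def default_substituents() -> SubstituentSet:
    """The bundled 20-Ra / 28-Rb vocabulary (7 ED + 5 EW + 8 X; 18 PAH + 5 PA + 5 CZ)."""
    ra = (
        [Substituent(f"Ra{i + 1:02d}", "ED", s) for i, s in enumerate(_RA_ED)]
        + [Substituent(f"Ra{i + 8:02d}", "EW", s) for i, s in enumerate(_RA_EW)]
        + [Substituent(f"Ra{i + 13:02d}", "X", s) for i, s in enumerate(_RA_X)]
    )
    rb = (
        [Substituent(f"Rb{i + 1:02d}", "PAH", s) for i, s in enumerate(_RB_PAH)]
        + [Substituent(f"Rb{i + 19:02d}", "PA", s) for i, s in enumerate(_RB_PA)]
        + [Substituent(f"Rb{i + 24:02d}", "CZ", s) for i, s in enumerate(_RB_CZ)]
    )
    return SubstituentSet(ra=ra, rb=rb)


# latent substituent properties driving the descriptor emulation
_RA_DONOR = {"ED": 1.0, "EW": -1.0, "X": -0.2}
_RB_CONJ = {"PAH": 0.4, "PA": 0.9, "CZ": 1.2}


def synthetic_catalyst_library(seed: int = 0) -> list[CandidateMolecule]:
    """The bundled 560-molecule library with SMILES and emulated descriptors."""
    subs = default_substituents()
    library = enumerate_library(subs)
    rng = np.random.default_rng(seed)

    ra_lat = {s.id: _RA_DONOR[s.label] + 0.3 * rng.standard_normal() for s in subs.ra}
    rb_lat = {s.id: _RB_CONJ[s.label] + 0.3 * rng.standard_normal() for s in subs.rb}

    n = len(library)
    d_vals = np.zeros((n, 16))
    for k, mol in enumerate(library):
        a, b = ra_lat[mol.ra_id], rb_lat[mol.rb_id]
        e = rng.standard_normal(16) * 0.08
        gap = max(2.2 - 0.35 * b - 0.10 * a + 0.25 * e[0], 1.4)   # optical gap (eV)
        d_vals[k] = [
            1.45 + 0.20 * a + 0.3 * e[1],                         # ip
            min(-1.55 + 0.12 * a + 0.08 * e[2], -1.25),           # ea (plant exception later)
            -0.80 + 0.15 * a + 0.3 * e[3],                        # ip_star
            max(1.55 + 0.15 * b + 0.10 * e[4], 1.25),             # ea_star (plant later)
            gap,
            max(0.15 + 0.30 * abs(b) + 0.1 * abs(e[5]), 0.01),    # osc_strength
            max(4.0 + 2.0 * b + 1.5 * a + 2.0 * e[6], 0.1),       # delta_dipole (D)
            max(1.5 + 0.8 * b + 0.5 * e[7], 0.1),                 # h_ct
            max(2.0 + 0.5 * b + 0.4 * e[8], 0.2),                 # h_index
            max(0.5 + 0.6 * b + 0.4 * e[9], 0.0),                 # t_index
            max(1.0 + 0.5 * b + 0.4 * e[10], 0.0),                # delta_sigma
            float(np.clip(0.55 - 0.12 * b - 0.05 * a + 0.08 * e[11], 0.05, 0.95)),  # s_r
            max(1.8 + 1.0 * b + 0.4 * a + 0.6 * e[12], 0.0),      # d_index
            max(2.8 - 0.4 * b + 0.3 * e[13], 0.5),                # e_coulomb
            max(0.45 - 0.08 * b + 0.08 * e[14], 0.05),            # de_s1_t1
            max(0.30 + 0.05 * a + 0.05 * e[15], 0.05),            # lambda_reorg
        ]

    # Plant the library-level screen statistics: 4 oxidation-window failures
    # (EA* below +1.19 V) and 1 reduction-window failure (EA above -1.17 V).
    cols = {name: i for i, name in enumerate(
        ("ip", "ea", "ip_star", "ea_star"))}
    fail_ox = rng.choice(n, size=4, replace=False)
    d_vals[fail_ox, cols["ea_star"]] = rng.uniform(0.95, 1.15, size=4)
    remaining = np.setdiff1d(np.arange(n), fail_ox)
    fail_red = rng.choice(remaining, size=1, replace=False)
    d_vals[fail_red, cols["ea"]] = rng.uniform(-1.10, -1.00, size=1)

    from .chemspace import DESCRIPTOR_FIELDS

    for k, mol in enumerate(library):
        mol.descriptors = DescriptorVector(**dict(zip(DESCRIPTOR_FIELDS, d_vals[k])))
    return library


# --- ligands and the formulation space ---------------------------------------

_PY_SUBS = ["C", "CC", "C(C)(C)C", "OC", "F", "Cl", "Br", "C#N", "N(C)C",
            "c2ccccc2", "C(F)(F)F", "OCC"]


def synthetic_ligands() -> list[LigandEntry]:
    """25 pyridyl ligands: pyridine, 12 4-substituted pyridines, bipyridine,
    10 4,4'-disubstituted bipyridines and 1,10-phenanthroline."""
    smiles = (
        ["c1ccncc1"]
        + [f"c1cc({g})ccn1" for g in _PY_SUBS]
        + ["c1ccnc(-c2ccccn2)c1"]
        + [f"c1c({g})ccnc1-c1cc({g})ccn1" for g in _PY_SUBS[:10]]
        + ["c1ccc2ccc3cccnc3c2n1"]
    )
    return [LigandEntry(id=f"L{i + 1}", smiles=s) for i, s in enumerate(smiles)]


def formulation_catalysts(
    library: list[CandidateMolecule] | None = None, n: int = 18, seed: int = 0
) -> list[CatalystEntry]:
    """Pick n carbazole-bearing catalysts spanning a wide EA range.

    Mirrors the real second campaign, which used 18 carbazole catalysts of
    widely varying activity selected from the first campaign.
    """
    library = library if library is not None else synthetic_catalyst_library(seed)
    subs = default_substituents()
    cz_ids = {s.id for s in subs.rb if s.label == "CZ"}
    pool = [m for m in library if m.rb_id in cz_ids]
    pool.sort(key=lambda m: m.descriptors.ea)
    take = np.linspace(0, len(pool) - 1, n).round().astype(int)
    return [
        CatalystEntry(id=pool[i].id, smiles=pool[i].smiles,
                      electronic_feature=pool[i].descriptors.ea)
        for i in take
    ]


def default_condition_space(seed: int = 0) -> ConditionSpace:
    """The bundled 18 x 25 x 10 = 4,500-condition formulation space."""
    library = synthetic_catalyst_library(seed)
    cats = formulation_catalysts(library, n=18, seed=seed)
    return build_condition_space(cats, synthetic_ligands(), list(range(1, 11)))
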