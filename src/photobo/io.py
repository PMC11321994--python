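"""Table schemas, configuration validation and log serialization.

All yields are percentages stored as numbers in [0, 100]; there is no
fraction/percent dual convention anywhere in the package.  Results-table
parsing defaults to strict mode (any bad row rejects the file); lenient mode
drops bad rows with a logged warning, because deposited spreadsheets vary in
hygiene.
"""

from __future__ import annotations

import json
import logging
import secrets
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemspace import (
    CandidateMolecule,
    DESCRIPTOR_FIELDS,
    DescriptorVector,
)
from .conditions import CatalystEntry, LigandEntry
from .errors import TableValidationError, ValidationError
from .oracles import ReplayTable

logger = logging.getLogger("photobo")

CANDIDATE_COLUMNS = ("id", "ra_id", "rb_id", "smiles") + DESCRIPTOR_FIELDS


# ---------------------------------------------------------------------------
# Candidate / ligand / condition tables


def write_candidate_table(library, path) -> None:
    rows = []
    for m in library:
        row = {"id": m.id, "ra_id": m.ra_id, "rb_id": m.rb_id, "smiles": m.smiles or ""}
        if m.descriptors is not None:
            row.update({f: getattr(m.descriptors, f) for f in DESCRIPTOR_FIELDS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_candidate_table(path) -> list[CandidateMolecule]:
    df = pd.read_csv(path)
    missing = [c for c in ("id", "ra_id", "rb_id") if c not in df.columns]
    if missing:
        raise ValidationError(f"candidate table missing columns: {missing}")
    have_desc = all(c in df.columns for c in DESCRIPTOR_FIELDS)
    out = []
    for _, r in df.iterrows():
        desc = (DescriptorVector.from_mapping(r) if have_desc else None)
        smiles = r.get("smiles")
        smiles = None if (pd.isna(smiles) or smiles == "") else str(smiles)
        out.append(CandidateMolecule(id=str(r["id"]), ra_id=str(r["ra_id"]),
                                     rb_id=str(r["rb_id"]), smiles=smiles,
                                     descriptors=desc))
    return out


def write_ligand_table(ligands, path) -> None:
    pd.DataFrame([{"id": l.id, "smiles": l.smiles} for l in ligands]).to_csv(path, index=False)


def read_ligand_table(path) -> list[LigandEntry]:
    df = pd.read_csv(path)
    return [LigandEntry(id=str(r["id"]), smiles=str(r["smiles"])) for _, r in df.iterrows()]


def write_condition_table(space, path) -> None:
    rows = [{"condition_id": pid, "cnp_id": c.cnp_id, "ligand_id": c.ligand_id,
             "ni_conc": c.ni_conc}
            for pid, c in zip(space.ids, space.conditions)]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Results / replay tables


def parse_results_table(path, column_map: dict | None = None, strict: bool = True):
    """Parse a measured-yields CSV into a ReplayTable plus a row report.

    The default schema is ``target_id, rep1, rep2, rep3`` (missing replicate
    cells allowed; at least one per row).  ``column_map`` renames foreign
    headers onto that schema, e.g. ``{"Sample": "target_id", "Yield": "rep1"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "target_id" not in df.columns:
        raise ValidationError("results table needs a target_id column (or a column_map)")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise ValidationError("results table has no replicate columns (rep1, rep2, ...)")

    replicates: dict[str, list[float]] = {}
    errors: list[str] = []
    for i, r in df.iterrows():
        tid = str(r["target_id"])
        reps = [float(r[c]) for c in rep_cols if pd.notna(r[c])]
        if not reps:
            errors.append(f"row {i}: no replicate values for {tid!r}")
            continue
        bad = [v for v in reps if v < 0 or v > 100]
        if bad:
            errors.append(f"row {i}: yield out of [0, 100] for {tid!r}: {bad}")
            continue
        if tid in replicates:
            errors.append(f"row {i}: duplicate target id {tid!r}")
            continue
        replicates[tid] = reps

    report = {"n_rows": len(df), "n_accepted": len(replicates),
              "n_rejected": len(df) - len(replicates), "errors": errors}
    if errors and strict:
        raise TableValidationError(report)
    for msg in errors:
        logger.warning("results-table row dropped: %s", msg)
    table = ReplayTable(replicates=replicates, provenance=str(path))
    return table, report


def write_replay_table(table: ReplayTable, path) -> None:
    nmax = max(len(v) for v in table.replicates.values())
    rows = []
    for tid, reps in table.replicates.items():
        row = {"target_id": tid}
        row.update({f"rep{i + 1}": reps[i] if i < len(reps) else None for i in range(nmax)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Campaign config


_KNOWN_KEYS = {
    "preset", "paths", "kernel", "acquisition", "stop", "oracle", "seeds",
    "replicates", "init", "selection",
}

_PRESET_DEFAULTS = {
    # catalyst-discovery campaign: 12 proposals/step, human picks a subset
    "catalyst": {"portfolio_size": 12, "init_k": 6},
    # formulation campaign: 8 acquisitions/step from an explicit seed batch
    "formulation": {"portfolio_size": 8, "init_k": 19},
    "custom": {"portfolio_size": 12, "init_k": 6},
}


@dataclass
class CampaignConfig:
    preset: str = "catalyst"
    paths: dict = field(default_factory=dict)
    kernel: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    stop: dict = field(default_factory=dict)
    oracle: dict = field(default_factory=lambda: {"kind": "synthetic"})
    seeds: dict = field(default_factory=dict)
    replicates: int = 3
    init: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(raw: dict) -> CampaignConfig:
    """Validate a raw config mapping, filling defaults and materializing seeds.

    Unknown keys are rejected with an aggregated report.  Every stochastic
    component receives a named seed; absent seeds are auto-generated (and
    echoed back in the returned config, so the run stays reproducible).
    """
    problems = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        problems.append(f"unknown config keys: {sorted(unknown)}")
    preset = raw.get("preset", "catalyst")
    if preset not in _PRESET_DEFAULTS:
        problems.append(f"unknown preset {preset!r}")
    acq = dict(raw.get("acquisition", {}))
    if preset in _PRESET_DEFAULTS:
        acq.setdefault("portfolio_size", _PRESET_DEFAULTS[preset]["portfolio_size"])
    acq.setdefault("beta_scale", 1.0)
    if acq.get("beta_scale", 1.0) <= 0:
        problems.append("acquisition.beta_scale must be positive")
    stop = dict(raw.get("stop", {}))
    stop.setdefault("patience", 5)
    stop.setdefault("max_steps", 10)
    init = dict(raw.get("init", {}))
    if "ids" not in init and preset in _PRESET_DEFAULTS:
        init.setdefault("k", _PRESET_DEFAULTS[preset]["init_k"])
    if problems:
        raise ValidationError("; ".join(problems))

    seeds = dict(raw.get("seeds", {}))
    for name in ("campaign", "landscape", "baseline"):
        if name not in seeds:
            seeds[name] = secrets.randbelow(2**31)
    return CampaignConfig(
        preset=preset, paths=dict(raw.get("paths", {})), kernel=dict(raw.get("kernel", {})),
        acquisition=acq, stop=stop, oracle=dict(raw.get("oracle", {"kind": "synthetic"})),
        seeds=seeds, replicates=int(raw.get("replicates", 3)), init=init,
        selection=dict(raw.get("selection", {})),
    )


def load_config(path) -> CampaignConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    return validate_config(raw or {})
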