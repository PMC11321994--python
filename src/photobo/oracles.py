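"""Stand-ins for the laboratory: synthetic yield landscapes and replay tables.

The synthetic landscape is a generated ground-truth yield function with a
known optimum.  Its structure echoes the qualitative experimental findings:
additive descriptor effects with fixed signs (small optical gap and low
electron affinity are good, a large electron-hole distance and oscillator
strength are good), a low-rank catalyst x ligand interaction, a concave
response to the nickel loading, and a logistic squash mapping the latent
score to a yield in [0, 100]%.  Measurements are triplicate with additive
Gaussian noise and clamping, mirroring how wet-lab yields were reported.

The replay oracle returns previously measured replicates verbatim and
refuses ids absent from the measured table — an optimizer replaying a
historical campaign can only visit conditions that were actually run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemspace import (
    CandidateMolecule,
    DESCRIPTOR_FIELDS,
    descriptor_matrix,
    standardize_descriptors,
)
from .conditions import ConditionSpace
from .errors import NotMeasuredError, ValidationError


@dataclass
class YieldObservation:
    """One (possibly replicated) yield measurement for a target id."""

    target_id: str
    replicate_yields: list[float]
    step_index: int = 0
    arm: str = "bo"  # "bo" | "random" | "seed"
    mean_yield: float = field(init=False)

    def __post_init__(self):
        reps = [float(v) for v in self.replicate_yields]
        if not reps:
            raise ValidationError("observation needs at least one replicate")
        if any(v < 0 or v > 100 for v in reps):
            raise ValidationError("yields must lie in [0, 100]%")
        self.replicate_yields = reps
        self.mean_yield = float(np.mean(reps))


# ---------------------------------------------------------------------------
# Synthetic landscape

#: Required signs for the descriptor effect weights (positive weight means
#: larger descriptor value raises the latent yield).
REQUIRED_SIGNS = {"de_s1_s0": -1, "ea": -1, "d_index": +1, "osc_strength": +1}


@dataclass
class LandscapeConfig:
    """Tunable structure of the synthetic yield surface.

    Weights act on z-scored descriptors.  The loading response is a concave
    quadratic peaking at ``conc_peak`` mol%; ``interaction_scale`` sets the
    strength of a rank-``interaction_rank`` catalyst x ligand interaction.
    ``noise_sd`` is the per-replicate measurement noise in yield percentage
    points.
    """

    weights: dict = field(default_factory=lambda: {
        "de_s1_s0": -1.0, "ea": -0.8, "d_index": 0.6, "osc_strength": 0.5,
    })
    interaction_rank: int = 2
    interaction_scale: float = 0.5
    conc_peak: float = 4.0
    conc_curvature: float = 1.0
    noise_sd: float = 3.0
    squash_slope: float = 1.2
    squash_shift: float = -0.7
    allow_sign_override: bool = False

    def __post_init__(self):
        if not self.allow_sign_override:
            for name, sign in REQUIRED_SIGNS.items():
                w = self.weights.get(name, 0.0)
                if w != 0.0 and np.sign(w) != sign:
                    raise ValidationError(
                        f"weight for {name} must have sign {sign:+d} "
                        "(set allow_sign_override to relax)"
                    )
        unknown = set(self.weights) - set(DESCRIPTOR_FIELDS)
        if unknown:
            raise ValidationError(f"unknown descriptor weights: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def _squash(z: np.ndarray, cfg: LandscapeConfig) -> np.ndarray:
    """Standardize the latent score and map through a logistic to [0, 100]%."""
    sd = z.std()
    zc = (z - z.mean()) / (sd if sd > 0 else 1.0)
    return 100.0 / (1.0 + np.exp(-(cfg.squash_slope * zc + cfg.squash_shift)))


@dataclass
class SyntheticLandscape:
    """Ground-truth noiseless yields over a discrete space, with a known argmax."""

    ids: list[str]
    latent: dict  # id -> noiseless yield (%)
    noise_sd: float
    argmax_id: str
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = np.array([self.latent[i] for i in self.ids])
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValidationError("noiseless yields must lie in [0, 100]")
        true_best = self.ids[int(np.argmax(vals))]
        if true_best != self.argmax_id:
            raise ValidationError("recorded argmax disagrees with exhaustive evaluation")

    def latent_yield(self, target_id: str) -> float:
        try:
            return self.latent[target_id]
        except KeyError:
            raise NotMeasuredError(target_id) from None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"target_id": self.ids,
                             "latent_yield": [self.latent[i] for i in self.ids]})


def make_catalyst_landscape(
    library: Sequence[CandidateMolecule],
    cfg: LandscapeConfig | None = None,
    seed: int = 0,
) -> SyntheticLandscape:
    """Yield surface over the catalyst library from additive descriptor effects."""
    cfg = cfg or LandscapeConfig()
    X = descriptor_matrix(library)
    Z, _, _ = standardize_descriptors(X)
    w = np.array([cfg.weights.get(f, 0.0) for f in DESCRIPTOR_FIELDS])
    g = Z @ w
    y = _squash(g, cfg)
    ids = [m.id for m in library]
    latent = {i: float(v) for i, v in zip(ids, y)}
    return SyntheticLandscape(
        ids=ids, latent=latent, noise_sd=cfg.noise_sd,
        argmax_id=ids[int(np.argmax(y))], seed=seed,
        meta={"kind": "catalyst", "weights": dict(cfg.weights)},
    )


def make_formulation_landscape(
    space: ConditionSpace,
    descriptors: Mapping[str, "DescriptorVector"],
    cfg: LandscapeConfig | None = None,
    seed: int = 0,
) -> SyntheticLandscape:
    """Yield surface over a condition space.

    Latent score = descriptor effects of the catalyst + low-rank
    catalyst x ligand interaction + concave quadratic loading response,
    squashed to [0, 100].
    """
    cfg = cfg or LandscapeConfig()
    rng = np.random.default_rng(seed)
    cat_ids = [c.id for c in space.catalysts]
    missing = [c for c in cat_ids if c not in descriptors]
    if missing:
        raise ValidationError(f"descriptors missing for catalysts: {missing}")
    X = np.stack([descriptors[c].to_array() for c in cat_ids])
    Z, _, _ = standardize_descriptors(X)
    w = np.array([cfg.weights.get(f, 0.0) for f in DESCRIPTOR_FIELDS])
    g_cat = Z @ w

    r = cfg.interaction_rank
    U = rng.normal(size=(len(space.catalysts), r))
    V = rng.normal(size=(len(space.ligands), r))
    inter = cfg.interaction_scale * (U @ V.T) / np.sqrt(r)

    conc = space.conc
    span = max(space.conc_grid) - min(space.conc_grid) or 1
    g_conc = -cfg.conc_curvature * ((conc - cfg.conc_peak) / span) ** 2

    g = g_cat[space.cat_idx] + inter[space.cat_idx, space.lig_idx] + g_conc
    y = _squash(g, cfg)
    latent = {pid: float(v) for pid, v in zip(space.ids, y)}
    return SyntheticLandscape(
        ids=list(space.ids), latent=latent, noise_sd=cfg.noise_sd,
        argmax_id=space.ids[int(np.argmax(y))], seed=seed,
        meta={"kind": "formulation", "weights": dict(cfg.weights),
              "conc_peak": cfg.conc_peak},
    )


def make_landscape(space, cfg=None, seed: int = 0, descriptors=None) -> SyntheticLandscape:
    """Dispatch to the catalyst- or formulation-space landscape generator."""
    if isinstance(space, ConditionSpace):
        if descriptors is None:
            raise ValidationError("formulation landscape needs per-catalyst descriptors")
        return make_formulation_landscape(space, descriptors, cfg, seed)
    return make_catalyst_landscape(space, cfg, seed)


# ---------------------------------------------------------------------------
# Replay oracle


@dataclass
class ReplayTable:
    """Measured replicates keyed by target id; the lookup-table 'experiment'."""

    replicates: dict  # id -> list of yields (%)
    provenance: str = ""

    def __post_init__(self):
        for tid, reps in self.replicates.items():
            if not reps:
                raise ValidationError(f"target {tid!r} has no replicates")
            if any(v < 0 or v > 100 for v in reps):
                raise ValidationError(f"target {tid!r} has out-of-range yields")

    @property
    def ids(self) -> list[str]:
        return list(self.replicates)

    @classmethod
    def from_log(cls, log, provenance: str = "campaign log") -> "ReplayTable":
        return cls(
            replicates={o.target_id: list(o.replicate_yields) for o in log.observations},
            provenance=provenance,
        )


def replay_oracle(table: ReplayTable) -> ReplayTable:
    """A validated replay table already behaves as an oracle; returned as-is."""
    return table


# ---------------------------------------------------------------------------
# Measurement


def _target_rng(seed: int, target_id: str) -> np.random.Generator:
    # pure function of (seed, id): repeated queries agree exactly
    h = zlib.crc32(str(target_id).encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), h]))


def measure(oracle, target_id: str, replicates: int = 3, seed: int = 0) -> YieldObservation:
    """Query an oracle for a (by default triplicate) yield observation.

    Synthetic landscapes add clamped Gaussian noise per replicate; replay
    tables return the stored replicates verbatim (ignoring ``replicates``).
    """
    if isinstance(oracle, ReplayTable):
        try:
            reps = oracle.replicates[target_id]
        except KeyError:
            raise NotMeasuredError(target_id) from None
        return YieldObservation(target_id=target_id, replicate_yields=list(reps))
    latent = oracle.latent_yield(target_id)
    if oracle.noise_sd == 0:
        reps = [latent] * replicates
    else:
        rng = _target_rng(seed, target_id)
        noise = rng.normal(0.0, oracle.noise_sd, size=replicates)
        reps = list(np.clip(latent + noise, 0.0, 100.0))
    return YieldObservation(target_id=target_id, replicate_yields=reps)
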