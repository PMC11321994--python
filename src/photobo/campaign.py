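"""The closed-loop engine: UCB portfolio acquisition and batched campaigns.

At each optimization step the surrogate is refit on every observation so far,
a portfolio of upper-confidence-bound acquisition functions

    alpha_UCB(x) = mu(x) + beta * sigma(x)

is instantiated with beta values drawn from an exponential distribution
(small beta exploits the predicted mean, large beta explores uncertainty),
and each beta proposes the arg-max over the not-yet-observed candidates,
with duplicates within the batch falling through to the next-best candidate.
A pluggable selection mask models the human-in-the-loop step in which
chemists pick a subset of the proposed batch; the default accepts all
proposals.  Every stochastic component draws from a named, logged seed so
campaign logs are byte-identical across reruns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import SpaceExhaustedError, ValidationError
from .gp import GPModel, KernelSpec, fit_gp
from .oracles import YieldObservation, measure


# ---------------------------------------------------------------------------
# Acquisition


def ucb_score(mu, sigma, beta: float):
    """Upper confidence bound mu + beta*sigma (vectorized)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValidationError("sigma must be non-negative")
    if beta < 0:
        raise ValidationError("beta must be non-negative")
    out = np.asarray(mu, dtype=float) + beta * sigma
    return float(out) if out.ndim == 0 else out


@dataclass
class AcquisitionConfig:
    """Portfolio of UCB instances run in parallel at each step."""

    portfolio_size: int = 12
    beta_scale: float = 1.0
    explicit_betas: list | None = None
    batch_select_size: int | None = None  # top-k mask; None = accept all proposals
    seed: int = 0

    def __post_init__(self):
        if self.portfolio_size < 1:
            raise ValidationError("portfolio_size must be >= 1")
        if self.beta_scale <= 0:
            raise ValidationError("beta_scale must be positive")
        if self.explicit_betas is not None and any(b < 0 for b in self.explicit_betas):
            raise ValidationError("explicit betas must be non-negative")


def sample_beta_portfolio(cfg: AcquisitionConfig, rng: np.random.Generator | None = None) -> list[float]:
    """Draw the per-step beta portfolio (sorted ascending for logging)."""
    if cfg.explicit_betas is not None:
        return [float(b) for b in cfg.explicit_betas]
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    draws = rng.exponential(cfg.beta_scale, size=cfg.portfolio_size)
    return sorted(float(b) for b in draws)


def propose_from_posterior(
    mu: np.ndarray,
    sigma: np.ndarray,
    candidate_ids: Sequence[str],
    observed: Iterable[str],
    betas: Sequence[float],
) -> list[tuple[str, float, float]]:
    """Per-beta arg-max with within-batch deduplication.

    For each beta in order, the highest-scoring unobserved candidate not
    already proposed in this batch is chosen (ties go to the earliest
    candidate).  Returns (candidate_id, beta, score) triples; the batch is
    truncated when the pool runs dry.
    """
    observed = set(observed)
    avail = [i for i, cid in enumerate(candidate_ids) if cid not in observed]
    if not avail:
        raise SpaceExhaustedError("every candidate in the space has been observed")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    taken: set[int] = set()
    out: list[tuple[str, float, float]] = []
    for beta in betas:
        pool = [i for i in avail if i not in taken]
        if not pool:
            break
        scores = ucb_score(mu[pool], sigma[pool], beta)
        best = pool[int(np.argmax(scores))]
        taken.add(best)
        out.append((candidate_ids[best], float(beta), float(scores[int(np.argmax(scores))])))
    return out


def propose_batch(model: GPModel, design, observed: Iterable[str], betas: Sequence[float]):
    """Propose one batch from a fitted surrogate over a design's candidates."""
    mu, sigma = design.predict(model, design.ids)
    return propose_from_posterior(mu, sigma, design.ids, observed, betas)


# ---------------------------------------------------------------------------
# Designs: bind candidate ids to a GP encoding


class DescriptorDesign:
    """Catalyst campaign design: ids plus a descriptor matrix, Matern surrogate."""

    def __init__(self, ids: Sequence[str], X: np.ndarray, spec: KernelSpec | None = None):
        if len(ids) != len(X):
            raise ValidationError("ids and descriptor matrix length mismatch")
        self.ids = list(ids)
        self.X = np.asarray(X, dtype=float)
        self.spec = spec or KernelSpec(kind="matern_descriptor")
        self._row = {cid: i for i, cid in enumerate(self.ids)}

    def fit(self, obs_ids: Sequence[str], y: Sequence[float], seed: int) -> GPModel:
        rows = [self._row[c] for c in obs_ids]
        return fit_gp(self.X[rows], y, self.spec, seed=seed)

    def predict(self, model: GPModel, ids: Sequence[str]):
        rows = [self._row[c] for c in ids]
        return model.predict(self.X[rows])

    def ks_matrix(self, metric: str = "euclidean") -> np.ndarray:
        from .chemspace import euclidean_distance_matrix

        if metric != "euclidean":
            raise ValidationError("DescriptorDesign supports the euclidean KS metric")
        return euclidean_distance_matrix(self.X, standardize=True)


class FormulationDesign:
    """Formulation campaign design over a condition space, custom-RBF surrogate."""

    def __init__(self, space, spec: KernelSpec | None = None):
        self.space = space
        self.ids = list(space.ids)
        self.spec = spec or KernelSpec(kind="formulation_rbf")
        if self.spec.kind != "formulation_rbf":
            raise ValidationError("FormulationDesign requires the formulation_rbf kernel")

    def fit(self, obs_ids: Sequence[str], y: Sequence[float], seed: int) -> GPModel:
        idx = [self.space.index_of(c) for c in obs_ids]
        return fit_gp(idx, y, self.spec, seed=seed, space=self.space)

    def predict(self, model: GPModel, ids: Sequence[str]):
        idx = [self.space.index_of(c) for c in ids]
        return model.predict(idx)

    def ks_matrix(self, metric: str = "combined") -> np.ndarray:
        return self.space.distance_matrix()


# ---------------------------------------------------------------------------
# Campaign log


@dataclass
class StepRecord:
    step: int
    betas: list[float]
    proposals: list[tuple[str, float, float]]  # (id, beta, score)
    selected: list[str]


@dataclass
class CampaignLog:
    """Complete audit trail of one closed-loop run."""

    config: dict
    seeds: dict
    steps: list[StepRecord] = field(default_factory=list)
    observations: list[YieldObservation] = field(default_factory=list)

    @property
    def observed_ids(self) -> list[str]:
        return [o.target_id for o in self.observations]

    def best_trace(self) -> list[float]:
        """Running maximum of the mean yields, in observation order."""
        best, out = -np.inf, []
        for o in self.observations:
            best = max(best, o.mean_yield)
            out.append(best)
        return out

    def validate(self) -> None:
        ids = self.observed_ids
        if len(ids) != len(set(ids)):
            raise ValidationError("campaign log observed a target id twice")

    def to_jsonl(self) -> str:
        lines = [json.dumps({"event": "config", "config": self.config, "seeds": self.seeds},
                            sort_keys=True)]
        for s in self.steps:
            lines.append(json.dumps({"event": "step", **asdict(s)}, sort_keys=True))
        for o in self.observations:
            lines.append(json.dumps({"event": "observation", **asdict(o)}, sort_keys=True))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "CampaignLog":
        log = None
        for line in text.strip().splitlines():
            rec = json.loads(line)
            ev = rec.pop("event")
            if ev == "config":
                log = cls(config=rec["config"], seeds=rec["seeds"])
            elif ev == "step":
                log.steps.append(StepRecord(
                    step=rec["step"], betas=rec["betas"],
                    proposals=[tuple(p) for p in rec["proposals"]],
                    selected=rec["selected"],
                ))
            else:
                rec.pop("mean_yield", None)  # derived field, recomputed on init
                log.observations.append(YieldObservation(**rec))
        return log

    def observations_frame(self):
        """Flat tabular view (step, target_id, yield_mean, arm, best_so_far)."""
        import pandas as pd

        trace = self.best_trace()
        return pd.DataFrame({
            "step": [o.step_index for o in self.observations],
            "target_id": [o.target_id for o in self.observations],
            "yield_mean": [o.mean_yield for o in self.observations],
            "arm": [o.arm for o in self.observations],
            "best_so_far": trace,
        })


# ---------------------------------------------------------------------------
# Selection masks (the human-in-the-loop step)


def accept_all(proposals):
    return [p[0] for p in proposals]


def top_k_by_score(k: int) -> Callable:
    def mask(proposals):
        ranked = sorted(proposals, key=lambda p: -p[2])
        keep = {p[0] for p in ranked[:k]}
        return [p[0] for p in proposals if p[0] in keep]

    return mask


def explicit_selection(ids_per_step: Sequence[Sequence[str]]) -> Callable:
    """Replays a fixed per-step selection (e.g. a historical campaign)."""
    it = iter([list(x) for x in ids_per_step])

    def mask(proposals):
        chosen = set(next(it))
        return [p[0] for p in proposals if p[0] in chosen]

    return mask


# ---------------------------------------------------------------------------
# Stop criteria and the loop itself


@dataclass
class StopConfig:
    max_steps: int = 10
    budget: int | None = None        # max total observations incl. the seed batch
    patience: int | None = 5         # steps without best-so-far improvement
    target_yield: float | None = None

    def __post_init__(self):
        if self.max_steps < 0:
            raise ValidationError("max_steps must be >= 0")


def run_closed_loop(
    design,
    oracle,
    acq_cfg: AcquisitionConfig,
    stop_cfg: StopConfig,
    *,
    init_ids: Sequence[str] | None = None,
    init_k: int | None = None,
    selection: Callable | None = None,
    replicates: int = 3,
    seed: int = 0,
) -> CampaignLog:
    """Run a full fit -> propose -> select -> observe loop against an oracle.

    Seeding is either an explicit id list or Kennard-Stone selection of
    ``init_k`` diverse points from the design's distance matrix.  All
    randomness (beta portfolio, oracle noise, GP restarts) derives from
    named child seeds of ``seed``; identical inputs give byte-identical logs.
    """
    from .chemspace import kennard_stone_select

    ss = np.random.SeedSequence(seed)
    seed_beta, seed_oracle, seed_fit = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    rng_beta = np.random.default_rng(seed_beta)

    if init_ids is None:
        if init_k is None:
            raise ValidationError("provide init_ids or init_k")
        idx = kennard_stone_select(design.ks_matrix(), init_k)
        init_ids = [design.ids[i] for i in idx]
    init_ids = list(init_ids)
    if selection is None:
        selection = (top_k_by_score(acq_cfg.batch_select_size)
                     if acq_cfg.batch_select_size else accept_all)

    log = CampaignLog(
        config={
            "acquisition": asdict(acq_cfg),
            "stop": asdict(stop_cfg),
            "replicates": replicates,
            "init_ids": init_ids,
        },
        seeds={"campaign": seed, "beta": seed_beta, "oracle": seed_oracle, "fit": seed_fit},
    )

    observed: dict[str, float] = {}

    def observe(cid: str, step: int, arm: str):
        obs = measure(oracle, cid, replicates=replicates, seed=seed_oracle)
        obs = YieldObservation(
            target_id=cid, replicate_yields=obs.replicate_yields,
            step_index=step, arm=arm,
        )
        log.observations.append(obs)
        observed[cid] = obs.mean_yield

    for cid in init_ids:
        observe(cid, 0, "seed")

    best = max(observed.values()) if observed else -np.inf
    stale = 0
    for step in range(1, stop_cfg.max_steps + 1):
        if stop_cfg.budget is not None and len(observed) >= stop_cfg.budget:
            break
        if stop_cfg.patience is not None and stale >= stop_cfg.patience:
            break
        if stop_cfg.target_yield is not None and best >= stop_cfg.target_yield:
            break
        model = design.fit(list(observed), list(observed.values()), seed=seed_fit)
        betas = sample_beta_portfolio(acq_cfg, rng_beta)
        try:
            proposals = propose_batch(model, design, observed, betas)
        except SpaceExhaustedError:
            break
        chosen = selection(proposals)
        if stop_cfg.budget is not None:
            room = stop_cfg.budget - len(observed)
            chosen = chosen[:room]
        log.steps.append(StepRecord(step=step, betas=list(betas),
                                    proposals=proposals, selected=list(chosen)))
        if not chosen:
            break
        for cid in chosen:
            observe(cid, step, "bo")
        new_best = max(observed.values())
        stale = stale + 1 if new_best <= best else 0
        best = max(best, new_best)

    log.validate()
    return log


def random_baseline(ids: Sequence[str], n: int, seed: int, exclude: Iterable[str] = ()) -> list[str]:
    """Uniform sample of n candidate ids without replacement (reproducible)."""
    pool = [c for c in ids if c not in set(exclude)]
    if n > len(pool):
        raise ValidationError(f"requested {n} of only {len(pool)} available candidates")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in pick]


def enrichment_stats(observations, yield_threshold: float) -> dict:
    """Enrichment summary: how many observations beat a yield threshold.

    Accepts a CampaignLog, a list of YieldObservation, or anything with a
    ``yield_mean``/``mean_yield`` column or attribute.  ``n_above`` counts
    strictly greater than the threshold.
    """
    if isinstance(observations, CampaignLog):
        yields = [o.mean_yield for o in observations.observations]
    elif hasattr(observations, "columns"):  # DataFrame
        col = "yield_mean" if "yield_mean" in observations.columns else "mean_yield"
        yields = list(observations[col].astype(float))
    else:
        yields = [o.mean_yield if isinstance(o, YieldObservation) else float(o)
                  for o in observations]
    if not yields:
        raise ValidationError("no observations to summarize")
    trace, best = [], -np.inf
    for v in yields:
        best = max(best, v)
        trace.append(best)
    n_above = sum(v > yield_threshold for v in yields)
    return {
        "n_total": len(yields),
        "n_above": n_above,
        "fraction": n_above / len(yields),
        "max_yield": max(yields),
        "best_so_far_trace": trace,
    }
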