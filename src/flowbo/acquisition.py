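"""Acquisition functions and parallel batch proposals.

The campaign loop mirrors parallel screening in a flow lab: fit the GP on
all observed conditions, propose a batch of q conditions at once, run the
q experiments, append the yields, repeat.

Acquisition functions score candidate conditions on the yield
(maximization) scale:

* ``lcb`` — optimistic confidence bound μ(x) + β·σ(x).  The name follows
  the convention of phrasing the rule as the *lower* confidence bound of
  the loss −yield; both orientations are the same rule.
* ``ei`` — expected improvement of yield over the incumbent best (plus an
  optional margin ξ) under the Gaussian posterior.

Batches are built by sequential kriging-believer hallucination: after each
selection the surrogate is conditioned on its own posterior-mean prediction
at the selected point (which shrinks the posterior variance there without
moving the mean), and the acquisition is re-optimized.  The inner
optimization runs over the relaxed encoded box: a seeded uniform candidate
pool plus local refinement of the best few, then every candidate is snapped
to a feasible lab-grid condition, deduplicated against the history and the
growing batch, and the acquisition is re-evaluated at the snapped points —
the proposal's score is the score of the condition actually proposed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, qmc

from . import gp
from .param_space import (
    Condition,
    ParameterSpace,
    ValidationError,
)

__all__ = [
    "AcquisitionConfig",
    "BatchProposal",
    "CampaignState",
    "ExhaustionError",
    "acq_lcb",
    "acq_ei",
    "propose_batch",
    "advance_round",
    "run_closed_loop",
    "initial_design",
]

log = logging.getLogger("flowbo.acquisition")


class ExhaustionError(RuntimeError):
    """Fewer distinct feasible grid points remain than the batch requires."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Settings for one proposal round.

    ``kind`` in {lcb, ei, parallel_lcb, parallel_ei}; the parallel variants
    use kriging-believer hallucination between in-batch selections, the
    single variants re-optimize the unchanged acquisition (and therefore
    only produce distinct batch points through deduplication).
    """

    kind: str = "parallel_lcb"
    beta: float = 2.0
    xi: float = 0.0
    batch_size: int = 3
    n_candidates: int = 4096
    n_refine: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"lcb", "ei", "parallel_lcb", "parallel_ei"}:
            raise ValidationError(f"unknown acquisition kind {self.kind!r}")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be ≥ 1")
        if self.beta < 0 or self.xi < 0:
            raise ValidationError("beta and xi must be ≥ 0")

    @property
    def hallucinate(self) -> bool:
        return self.kind.startswith("parallel_")

    @property
    def base_kind(self) -> str:
        return self.kind.removeprefix("parallel_")


@dataclass(frozen=True)
class BatchProposal:
    round: int
    conditions: tuple[Condition, ...]
    acquisition_values: tuple[float, ...]
    config: AcquisitionConfig


@dataclass
class CampaignState:
    """A running campaign: the space, all observed records, the round count."""

    space: ParameterSpace
    conditions: list[Condition]
    yields: list[float]
    round: int = 0
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.yields):
            raise ValidationError("conditions and yields length mismatch")
        for c in self.conditions:
            self.space.validate(c)
        for y in self.yields:
            if not 0.0 <= y <= 100.0:
                raise ValidationError(f"yield {y} outside [0, 100]")

    def fit_model(self) -> gp.SurrogateModel:
        X = self.space.encode_matrix(self.conditions)
        return gp.fit(X, np.asarray(self.yields), seed=self.config.seed)


# ---------------------------------------------------------------------- #
# pointwise acquisition values


def _check_sd(sd) -> np.ndarray:
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValidationError("posterior sd must be ≥ 0")
    return sd


def acq_lcb(mean, sd, beta: float = 2.0):
    """Optimistic confidence bound μ + β·σ (larger = more promising)."""
    sd = _check_sd(sd)
    if beta < 0:
        raise ValidationError("beta must be ≥ 0")
    return np.asarray(mean, float) + beta * sd


def acq_ei(mean, sd, best_observed: float, xi: float = 0.0):
    """Expected improvement of yield over ``best_observed + xi``.

    Closed form E[max(y − y⁺, 0)] = Δ·Φ(Δ/σ) + σ·φ(Δ/σ) with
    Δ = μ − (y⁺ + ξ); at σ = 0 it degenerates to max(Δ, 0).
    """
    sd = _check_sd(sd)
    if xi < 0:
        raise ValidationError("xi must be ≥ 0")
    mean = np.asarray(mean, dtype=float)
    delta = mean - (best_observed + xi)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = delta / safe_sd
    ei = np.where(
        sd > 0,
        delta * norm.cdf(z) + sd * norm.pdf(z),
        np.maximum(delta, 0.0),
    )
    return ei


def _acq_fn(config: AcquisitionConfig, best_observed: float) -> Callable:
    if config.base_kind == "lcb":
        return lambda mean, sd: acq_lcb(mean, sd, config.beta)
    return lambda mean, sd: acq_ei(mean, sd, best_observed, config.xi)


# ---------------------------------------------------------------------- #
# batch proposal


def _candidate_pool(
    space: ParameterSpace, config: AcquisitionConfig, rng: np.random.Generator
) -> np.ndarray:
    return rng.uniform(size=(config.n_candidates, space.encoded_dim))


def _refine(
    model: gp.SurrogateModel, score: Callable, x0: np.ndarray
) -> np.ndarray:
    d = len(x0)

    def neg(x):
        mean, sd = model.predict_arrays(x.reshape(1, -1))
        return -float(score(mean, sd)[0])

    res = minimize(neg, x0, method="L-BFGS-B", bounds=[(0.0, 1.0)] * d)
    return np.clip(res.x, 0.0, 1.0)


def _key(row: np.ndarray) -> bytes:
    return np.round(row, 10).tobytes()


def propose_batch(
    state: CampaignState, model: gp.SurrogateModel | None = None
) -> BatchProposal:
    """Select q lab-grid conditions by sequential acquisition maximization.

    Deterministic given (history, config, seed): the candidate pool RNG is
    derived from the config seed and the round index.
    """
    config = state.config
    space = state.space
    if not state.conditions:
        raise ValidationError("cannot propose from an empty history")
    if model is None:
        model = state.fit_model()
    if model.n != len(state.conditions):
        raise ValidationError("model was not fitted on the campaign history")

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), state.round])
    )
    best_observed = float(np.max(state.yields))
    score = _acq_fn(config, best_observed)

    taken = {_key(r) for r in space.snap_encoded(space.encode_matrix(state.conditions))}
    chosen_X: list[np.ndarray] = []
    chosen_vals: list[float] = []
    current = model

    for _ in range(config.batch_size):
        pool = _candidate_pool(space, config, rng)
        mean, sd = current.predict_arrays(pool)
        vals = score(mean, sd)
        top = np.argsort(vals)[::-1][: config.n_refine]
        refined = np.array([_refine(current, score, pool[i]) for i in top])
        snapped = space.snap_encoded(np.vstack([pool, refined]))
        # dedupe: unique grid points not already observed or selected
        uniq: dict[bytes, np.ndarray] = {}
        for row in snapped:
            k = _key(row)
            if k not in taken and k not in uniq:
                uniq[k] = row
        if not uniq:
            raise ExhaustionError(
                "no unused lab-grid point remains among the candidates"
            )
        cand = np.array(sorted(uniq.values(), key=lambda r: tuple(r)))
        m2, s2 = current.predict_arrays(cand)
        v2 = score(m2, s2)
        best = int(np.argmax(v2))
        x_sel = cand[best]
        chosen_X.append(x_sel)
        chosen_vals.append(float(v2[best]))
        taken.add(_key(x_sel))
        if config.hallucinate:
            lie = float(current.predict_arrays(x_sel.reshape(1, -1))[0][0])
            current = current.condition_on(x_sel, lie)

    conds = tuple(space.snap_to_lab_grid(space.decode(x)) for x in chosen_X)
    log.info(
        "round %d proposal (%s): %s", state.round + 1, config.kind,
        "; ".join(f"{c} [acq={v:.2f}]" for c, v in zip(conds, chosen_vals)),
    )
    return BatchProposal(
        round=state.round + 1,
        conditions=conds,
        acquisition_values=tuple(chosen_vals),
        config=config,
    )


def advance_round(
    state: CampaignState, proposal: BatchProposal, observed_yields: Sequence[float]
) -> CampaignState:
    """Append the observed yields for a proposal and bump the round counter."""
    if len(proposal.conditions) == 0:
        raise ValidationError("proposal is empty")
    if len(observed_yields) != len(proposal.conditions):
        raise ValidationError(
            f"{len(proposal.conditions)} conditions but "
            f"{len(observed_yields)} observed yields"
        )
    for y in observed_yields:
        if not 0.0 <= float(y) <= 100.0:
            raise ValidationError(f"yield {y} outside [0, 100]")
    return CampaignState(
        space=state.space,
        conditions=state.conditions + list(proposal.conditions),
        yields=state.yields + [float(y) for y in observed_yields],
        round=state.round + 1,
        config=state.config,
    )


# ---------------------------------------------------------------------- #
# campaign state serialization (structured text, versioned)

STATE_SCHEMA_VERSION = 1


def save_state(state: CampaignState, path) -> None:
    doc = {
        "schema_version": STATE_SCHEMA_VERSION,
        "round": state.round,
        "config": {
            "kind": state.config.kind,
            "beta": state.config.beta,
            "xi": state.config.xi,
            "batch_size": state.config.batch_size,
            "n_candidates": state.config.n_candidates,
            "n_refine": state.config.n_refine,
            "seed": state.config.seed,
        },
        "records": [
            {"condition": dict(c.assignments), "yield_pct": y}
            for c, y in zip(state.conditions, state.yields)
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)


def load_state(space: ParameterSpace, path) -> CampaignState:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != STATE_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported campaign state schema: {doc.get('schema_version')!r}"
        )
    return CampaignState(
        space=space,
        conditions=[Condition(r["condition"]) for r in doc["records"]],
        yields=[float(r["yield_pct"]) for r in doc["records"]],
        round=int(doc["round"]),
        config=AcquisitionConfig(**doc["config"]),
    )


# ---------------------------------------------------------------------- #
# closed loop against an in-silico objective


def initial_design(
    space: ParameterSpace, n: int, seed: int
) -> list[Condition]:
    """Seeded Latin-hypercube over continuous dims with balanced categorical
    coverage (choices cycled in order), snapped to the lab grid."""
    n_cont = len(space.continuous)
    rng_seed = int(seed) % (2**31)
    if n_cont:
        sampler = qmc.LatinHypercube(d=n_cont, seed=rng_seed)
        U = sampler.random(n)
    else:
        U = np.zeros((n, 0))
    conds = []
    for i in range(n):
        assignments: dict[str, object] = {}
        for j, p in enumerate(space.continuous):
            assignments[p.name] = p.low + U[i, j] * (p.high - p.low)
        for c in space.categorical:
            assignments[c.name] = c.choices[i % len(c.choices)]
        conds.append(space.snap_to_lab_grid(Condition(assignments)))
    return conds


@dataclass
class CampaignHistory:
    """Full record of a closed-loop run: conditions in evaluation order,
    observed (possibly noisy) yields, true noiseless surface values, and
    the best-so-far trace of the true values."""

    conditions: list[Condition]
    observed: np.ndarray
    true_values: np.ndarray
    best_so_far: np.ndarray
    n_init: int


def run_closed_loop(
    space: ParameterSpace,
    objective,
    init_design: Sequence[Condition],
    rounds: int,
    config: AcquisitionConfig,
) -> CampaignHistory:
    """Run ``rounds`` cycles of fit → propose → evaluate → append.

    ``objective`` is any callable Condition → observed yield exposing
    ``true_value(cond)`` for the noiseless surface (the synthetic benchmark
    objective does).  The best-so-far trace is over true values, so it
    measures real optimization progress rather than lucky noise.
    """
    if not init_design:
        raise ValidationError("initial design must be nonempty")
    conds = list(init_design)
    observed = [float(objective(c)) for c in conds]
    state = CampaignState(
        space=space, conditions=conds, yields=[_clip01(y) for y in observed],
        config=config,
    )
    for r in range(rounds):
        try:
            proposal = propose_batch(state)
            ys = [float(objective(c)) for c in proposal.conditions]
        except Exception as exc:
            raise RuntimeError(f"closed loop failed in round {r + 1}") from exc
        observed.extend(ys)
        state = advance_round(state, proposal, [_clip01(y) for y in ys])
    true_vals = np.array(
        [objective.true_value(c) if hasattr(objective, "true_value") else np.nan
         for c in state.conditions]
    )
    trace_src = true_vals if np.all(np.isfinite(true_vals)) else np.array(observed)
    return CampaignHistory(
        conditions=state.conditions,
        observed=np.array(observed),
        true_values=true_vals,
        best_so_far=np.maximum.accumulate(trace_src),
        n_init=len(init_design),
    )


def _clip01(y: float) -> float:
    return float(min(max(y, 0.0), 100.0))
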