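"""Synthetic multi-scorer sleep-staging data.

Every analysis in this package is testable without any recording
download by simulating the three layers of a multi-annotated dataset:

1. a ground-truth hypnogram, sampled from a first-order Markov chain
   over the five stages with strong self-transition (sleep is sticky:
   stages persist for minutes, not epochs);
2. S human scorers, each relabelling every epoch through a row-stochastic
   confusion matrix — with a *separate, noisier* confusion row inside a
   window around stage transitions, emulating the well-documented
   concentration of inter-scorer disagreement at stage boundaries;
3. M probabilistic models, each emitting a per-epoch Dirichlet draw
   centered on a (possibly confused) version of the true stage, with a
   concentration parameter controlling sharpness, an optional softmax
   temperature for miscalibration, and an optional near-transition
   regime (lower concentration / separate confusion) so that model
   uncertainty, like human disagreement, peaks at stage boundaries.

A companion generator draws covariate-linked performance outcomes from
an inflated-Beta or Normal regression, for exercising the bias audit.
All generators are pure functions of (parameters, seed); the seed fans
out to per-scorer / per-model substreams via ``numpy`` seed-sequence
spawning, so adding a scorer never perturbs existing scorers' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .hypnodata import STAGES, Hypnodensity, Hypnogram, MultiScorerRecord

__all__ = [
    "SleepDynamics",
    "ScorerNoiseModel",
    "ModelNoiseModel",
    "default_dynamics",
    "uniform_error_confusion",
    "simulate_hypnogram",
    "simulate_scorers",
    "simulate_model_probs",
    "simulate_record",
    "simulate_performance_table",
]

N_STAGES = len(STAGES)


def uniform_error_confusion(accuracy: float) -> np.ndarray:
    """Row-stochastic confusion with ``accuracy`` on the diagonal and the
    remaining mass spread evenly over the other four stages."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    off = (1.0 - accuracy) / (N_STAGES - 1)
    return np.full((N_STAGES, N_STAGES), off) + (accuracy - off) * np.eye(N_STAGES)


def _check_stochastic(matrix: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(matrix, float)
    if m.shape != (N_STAGES, N_STAGES):
        raise ValueError(f"{name} must be {N_STAGES}x{N_STAGES}")
    if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"{name} must be row-stochastic")
    return m


@dataclass(frozen=True)
class SleepDynamics:
    """Markov-chain hypnogram model: initial distribution, per-epoch
    5x5 stage transition matrix and recording length in epochs."""

    initial: np.ndarray
    transition: np.ndarray
    n_epochs: int
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        init = np.asarray(self.initial, float)
        if init.shape != (N_STAGES,) or np.any(init < 0) or not np.isclose(
            init.sum(), 1.0, atol=1e-9
        ):
            raise ValueError("initial must be a length-5 probability vector")
        trans = _check_stochastic(self.transition, "transition matrix")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        object.__setattr__(self, "initial", init)
        object.__setattr__(self, "transition", trans)


def default_dynamics(n_epochs: int = 960, epoch_seconds: float = 30.0) -> SleepDynamics:
    """A plausible overnight stage-dynamics fixture.

    High self-transition (0.85-0.95) with transitions favouring the
    usual W -> N1 -> N2 -> N3 and N2 -> REM routes. The values are a
    convenience fixture for simulation, not estimates of any cohort.
    """
    #            W     N1    N2    N3    REM
    transition = np.array(
        [
            [0.90, 0.08, 0.02, 0.00, 0.00],  # W
            [0.05, 0.85, 0.09, 0.00, 0.01],  # N1
            [0.01, 0.03, 0.90, 0.04, 0.02],  # N2
            [0.00, 0.01, 0.06, 0.92, 0.01],  # N3
            [0.02, 0.02, 0.03, 0.00, 0.93],  # REM
        ]
    )
    initial = np.array([0.90, 0.10, 0.0, 0.0, 0.0])
    return SleepDynamics(initial, transition, n_epochs, epoch_seconds)


@dataclass(frozen=True)
class ScorerNoiseModel:
    """Per-epoch scorer confusion, with a noisier regime near transitions.

    ``base_confusion`` applies away from stage changes of the truth;
    within ``transition_window`` epochs of a change the corresponding
    row of ``transition_confusion`` is used instead.
    """

    base_confusion: np.ndarray = field(
        default_factory=lambda: uniform_error_confusion(0.95)
    )
    transition_confusion: np.ndarray = field(
        default_factory=lambda: uniform_error_confusion(0.60)
    )
    transition_window: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "base_confusion",
            _check_stochastic(self.base_confusion, "base confusion"),
        )
        object.__setattr__(
            self, "transition_confusion",
            _check_stochastic(self.transition_confusion, "transition confusion"),
        )
        if self.transition_window < 0:
            raise ValueError("transition window must be >= 0")


@dataclass(frozen=True)
class ModelNoiseModel:
    """Probabilistic-stager emulation.

    Each epoch's probability row is a Dirichlet draw with parameter
    ``concentration * target`` where ``target`` mixes a one-hot at the
    (confusion-resampled) true stage with a uniform floor. Lower
    concentration means flatter, more variable rows. ``temperature``
    rescales rows as p^(1/temperature) (renormalized): > 1 flattens
    (underconfident), < 1 sharpens. Near stage transitions of the truth
    an optional separate confusion matrix applies and the concentration
    is multiplied by ``transition_concentration_scale``, so model
    uncertainty concentrates at boundaries like human disagreement does.
    """

    concentration: float = 15.0
    confusion: np.ndarray = field(default_factory=lambda: np.eye(N_STAGES))
    target_floor: float = 0.05
    temperature: float = 1.0
    transition_window: int = 0
    transition_concentration_scale: float = 1.0
    transition_confusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        object.__setattr__(
            self, "confusion", _check_stochastic(self.confusion, "confusion")
        )
        if self.transition_confusion is not None:
            object.__setattr__(
                self,
                "transition_confusion",
                _check_stochastic(self.transition_confusion, "transition confusion"),
            )
        if not 0.0 <= self.target_floor < 1.0:
            raise ValueError("target_floor must lie in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.transition_concentration_scale <= 0:
            raise ValueError("transition concentration scale must be positive")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _near_transition(stages: np.ndarray, window: int) -> np.ndarray:
    """Epochs within ``window`` epochs of a stage change of the sequence."""
    t = stages.size
    near = np.zeros(t, dtype=bool)
    if window <= 0:
        changes = np.nonzero(stages[1:] != stages[:-1])[0]
        near[changes] = True
        near[changes + 1] = True
        return near
    for b in np.nonzero(stages[1:] != stages[:-1])[0] + 1:
        near[max(0, b - window): min(t, b + window)] = True
    return near


def simulate_hypnogram(
    dyn: SleepDynamics, seed: int | np.random.Generator
) -> Hypnogram:
    """Sample one ground-truth hypnogram from the Markov chain."""
    rng = _rng(seed)
    stages = np.empty(dyn.n_epochs, dtype=np.int64)
    u = rng.random(dyn.n_epochs)
    cum_init = dyn.initial.cumsum()
    cum_trans = dyn.transition.cumsum(axis=1)
    stages[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, dyn.n_epochs):
        stages[t] = np.searchsorted(cum_trans[stages[t - 1]], u[t], side="right")
    return Hypnogram.from_stages(
        stages, epoch_seconds=dyn.epoch_seconds, source_id="truth"
    )


def simulate_scorers(
    truth: Hypnogram,
    noise: ScorerNoiseModel,
    n_scorers: int,
    seed: int,
) -> list[Hypnogram]:
    """Draw S independent noisy scorings of the truth.

    Scorer i consumes the i-th spawned substream of ``seed``, so
    enlarging S leaves earlier scorers' annotations unchanged.
    """
    if n_scorers < 1:
        raise ValueError("need at least one scorer")
    stages = truth.stages
    near = _near_transition(stages, noise.transition_window)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_scorers)
    scorers = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        rows = np.where(
            near[:, None],
            noise.transition_confusion[stages],
            noise.base_confusion[stages],
        )
        u = rng.random(truth.n_epochs)
        drawn = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        scorers.append(
            Hypnogram.from_stages(
                drawn,
                epoch_seconds=truth.epoch_seconds,
                source_id=f"scorer{i + 1}",
                mask=truth.mask,
            )
        )
    return scorers


def simulate_model_probs(
    truth: Hypnogram,
    noise: ModelNoiseModel | list[ModelNoiseModel],
    n_models: int,
    seed: int,
) -> list[Hypnodensity]:
    """Draw M model hypnodensities around the truth.

    ``noise`` may be a single model shared by all members or one per
    member. Model j consumes the j-th spawned substream of ``seed``.
    """
    if n_models < 1:
        raise ValueError("need at least one model")
    noises = noise if isinstance(noise, list) else [noise] * n_models
    if len(noises) != n_models:
        raise ValueError("need one noise model per member")
    stages = truth.stages
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_models)
    out = []
    for j, (nm, stream) in enumerate(zip(noises, streams)):
        rng = np.random.default_rng(stream)
        near = _near_transition(stages, nm.transition_window)
        base_rows = nm.confusion[stages]
        if nm.transition_confusion is not None:
            rows = np.where(
                near[:, None], nm.transition_confusion[stages], base_rows
            )
        else:
            rows = base_rows
        u = rng.random(truth.n_epochs)
        center = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        target = np.full((truth.n_epochs, N_STAGES), nm.target_floor / N_STAGES)
        target[np.arange(truth.n_epochs), center] += 1.0 - nm.target_floor
        conc = np.full(truth.n_epochs, nm.concentration)
        conc[near] *= nm.transition_concentration_scale
        alpha = conc[:, None] * target
        probs = rng.gamma(shape=alpha)
        probs /= probs.sum(axis=1, keepdims=True)
        if nm.temperature != 1.0:
            probs = np.clip(probs, 1e-300, None) ** (1.0 / nm.temperature)
            probs /= probs.sum(axis=1, keepdims=True)
        out.append(
            Hypnodensity(
                probs,
                epoch_seconds=truth.epoch_seconds,
                source_id=f"model{j + 1}",
                mask=truth.mask,
            )
        )
    return out


def simulate_record(
    record_id: str,
    dyn: SleepDynamics,
    scorer_noise: ScorerNoiseModel,
    model_noise: ModelNoiseModel | list[ModelNoiseModel],
    n_scorers: int,
    n_models: int,
    seed: int,
) -> tuple[MultiScorerRecord, Hypnogram]:
    """Simulate one multi-scorer recording; returns (record, truth).

    The seed spawns three independent substreams (truth, scorers,
    models), so changing S or M never perturbs the ground truth.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    truth = simulate_hypnogram(dyn, np.random.default_rng(ss[0]))
    scorers = simulate_scorers(truth, scorer_noise, n_scorers, seed=ss[1])
    models = (
        simulate_model_probs(truth, model_noise, n_models, seed=ss[2])
        if n_models > 0
        else []
    )
    return (
        MultiScorerRecord(record_id, tuple(scorers), tuple(models)),
        truth,
    )


def simulate_performance_table(
    coefficients: dict,
    n: int,
    seed: int,
    family: str = "inflated-beta",
    age_range: tuple[float, float] = (0.0, 88.0),
    male_fraction: float = 0.65,
    ahi_mean_sd: tuple[float, float] = (17.7, 19.2),
    plmi_mean_sd: tuple[float, float] = (12.1, 21.9),
) -> pd.DataFrame:
    """Covariate table plus outcomes drawn from a distributional model.

    Covariates emulate a heterogeneous clinical registry: age uniform
    over ``age_range`` years, gender Bernoulli (male = 1), AHI and PLMI
    gamma-distributed with the given mean/SD (events per hour).

    ``coefficients`` holds link-scale coefficient dicts per parameter,
    e.g. ``{"mu": {"intercept": 1.12, "gender": -0.06, "ahi10": -0.05},
    "sigma": {"intercept": -1.51}, "log_nu": -22.54, "log_tau": -22.63}``.
    Unmentioned covariate effects are zero; outcomes come from the
    implied inflated-Beta (columns in [0, 1]) or Normal model.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    age = rng.uniform(*age_range, size=n)
    gender = (rng.random(n) < male_fraction).astype(float)  # male = 1

    def gamma_draw(mean: float, sd: float) -> np.ndarray:
        if mean <= 0:  # degenerate: a cohort without events
            return np.zeros(n)
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, size=n)

    ahi = gamma_draw(*ahi_mean_sd)
    plmi = gamma_draw(*plmi_mean_sd)
    table = pd.DataFrame(
        {"age": age, "gender": gender, "ahi": ahi, "plmi": plmi}
    )
    cov = {
        "age_c": age - 50.0,
        "gender": gender,
        "ahi10": ahi / 10.0,
        "plmi10": plmi / 10.0,
    }

    def eta(block: dict) -> np.ndarray:
        e = np.full(n, float(block.get("intercept", 0.0)))
        for name, value in block.items():
            if name != "intercept":
                e = e + float(value) * cov[name]
        return e

    eta_mu = eta(coefficients.get("mu", {}))
    eta_sigma = eta(coefficients.get("sigma", {}))
    if family == "normal":
        outcome = rng.normal(eta_mu, np.exp(eta_sigma))
    elif family == "inflated-beta":
        mu = special.expit(eta_mu)
        sigma = special.expit(eta_sigma)
        nu = np.exp(float(coefficients.get("log_nu", -np.inf)))
        tau = np.exp(float(coefficients.get("log_tau", -np.inf)))
        denom = 1.0 + nu + tau
        p0, p1 = nu / denom, tau / denom
        common = (1.0 - sigma**2) / sigma**2
        draw = stats.beta.rvs(mu * common, (1 - mu) * common, random_state=rng)
        u = rng.random(n)
        outcome = np.where(u < p0, 0.0, np.where(u < p0 + p1, 1.0, draw))
    else:
        raise ValueError("family must be 'inflated-beta' or 'normal'")
    table["outcome"] = outcome
    return table
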