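"""Generative simulator for emergence-trial datasets.

The simulator draws per-individual behavioural effects from group-level
normal hyper-distributions and then simulates trials under the hurdle
process: a Bernoulli stay-or-emerge draw per trial, and for emerged trials a
gaussian latency truncated to the recordable window [1, limit - 1] seconds
and rounded to whole seconds.  An optional per-trial mortality hazard with
same-sex replacement emulates attrition in the infected group.

The four per-individual effects are, throughout the package:

``a``  intercept of the stay logit (stay = did NOT emerge), at the average
       experience level;
``b``  slope of the stay logit per trial of experience;
``c``  latency intercept (seconds) given emergence;
``d``  latency slope (seconds per trial of experience).

Effects are mutually independent normals; no intercept-slope correlation is
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .trial_data import Dataset, Group, Sex, TrialRecord

__all__ = [
    "GroupHyper",
    "IndividualEffects",
    "StudyDesign",
    "sample_individual_effects",
    "simulate_trials",
    "simulate_dataset",
    "default_scenario",
    "EFFECT_NAMES",
]

EFFECT_NAMES = ("a", "b", "c", "d")


@dataclass(frozen=True)
class GroupHyper:
    """Group-level mean and SD of the four per-individual effects.

    ``mu_a``/``sigma_a``: stay-logit intercepts; ``mu_b``/``sigma_b``:
    stay-logit slopes; ``mu_c``/``sigma_c``: latency intercepts (s);
    ``mu_d``/``sigma_d``: latency slopes (s per trial).
    """

    mu_a: float
    sigma_a: float
    mu_b: float
    sigma_b: float
    mu_c: float
    sigma_c: float
    mu_d: float
    sigma_d: float

    def __post_init__(self) -> None:
        for name in EFFECT_NAMES:
            sig = getattr(self, f"sigma_{name}")
            if sig < 0:
                raise ValueError(f"sigma_{name} must be >= 0, got {sig}")

    def mu(self, name: str) -> float:
        return getattr(self, f"mu_{name}")

    def sigma(self, name: str) -> float:
        return getattr(self, f"sigma_{name}")


@dataclass(frozen=True)
class IndividualEffects:
    """One individual's latent behavioural parameters."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in EFFECT_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"effect {name} must be finite")


@dataclass(frozen=True)
class StudyDesign:
    """Design of a simulated study.

    ``n_per_group_sex`` maps (group, sex) to the number of individuals
    enrolled at the start.  ``trials_per_individual`` is either a fixed
    count or an inclusive (low, high) range sampled per individual.
    ``mortality_per_trial`` is a per-trial death hazard applied to infected
    individuals only; when ``replacement`` is on, each death enrols a fresh
    same-sex individual (new identity, new effects) that starts at trial 1.
    ``force_all_emerge`` short-circuits the Bernoulli stay draw so every
    trial emerges (used for noise-free checks of the latency process).
    """

    n_per_group_sex: dict[tuple[Group, Sex], int]
    trials_per_individual: Union[int, tuple[int, int]] = 8
    observation_limit_s: float = 600.0
    residual_sd: float = 60.0
    mortality_per_trial: float = 0.0
    replacement: bool = True
    force_all_emerge: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.trial_range()
        if not (1 <= lo <= hi <= 50):
            raise ValueError("trials_per_individual must lie within [1, 50]")
        if self.observation_limit_s <= 1:
            raise ValueError("observation_limit_s must be > 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not (0 <= self.mortality_per_trial < 1):
            raise ValueError("mortality_per_trial must be in [0, 1)")

    def trial_range(self) -> tuple[int, int]:
        if isinstance(self.trials_per_individual, int):
            return (self.trials_per_individual, self.trials_per_individual)
        lo, hi = self.trials_per_individual
        return (int(lo), int(hi))

    def n_individuals(self, group: Optional[Group] = None) -> int:
        return sum(
            n
            for (g, _), n in self.n_per_group_sex.items()
            if group is None or g == group
        )


def sample_individual_effects(
    hyper: GroupHyper, n: int, seed: Union[int, np.random.Generator]
) -> list[IndividualEffects]:
    """Draw ``n`` independent effect quadruples from the hyper-distribution.

    Each of a, b, c, d is an independent ``Normal(mu_*, sigma_*)`` draw;
    reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    draws = {
        name: rng.normal(hyper.mu(name), hyper.sigma(name), size=n)
        for name in EFFECT_NAMES
    }
    return [
        IndividualEffects(draws["a"][i], draws["b"][i], draws["c"][i], draws["d"][i])
        for i in range(n)
    ]


def _sample_truncated_latency(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Gaussian draw truncated to [lo, hi] by rejection, with an
    inverse-CDF fallback when the acceptance region is far in the tail."""
    if sd == 0:
        return min(max(mean, lo), hi)
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if lo <= value <= hi:
            return value
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    return mean + sd * stats.norm.ppf(u)


def simulate_trials(
    effects: dict[Group, list[tuple[Sex, IndividualEffects]]],
    design: StudyDesign,
    hypers: Optional[dict[Group, GroupHyper]] = None,
    seed: Optional[int] = None,
) -> Dataset:
    """Simulate a full dataset from known per-individual effects.

    Parameters
    ----------
    effects
        For each group, a list of (sex, effects) pairs, one per enrolled
        individual.
    design
        Study design; ``design.seed`` is used unless ``seed`` is given.
    hypers
        Group hyper-distributions, required only when the mortality +
        replacement process needs to draw effects for replacement
        individuals.
    seed
        Overrides ``design.seed``.

    The experience covariate is centred at the mean trial index over all
    simulated records, matching what the model computes at fit time.
    Latencies are truncated to [1, limit - 1] and rounded to whole seconds.
    """
    if not effects or all(len(v) == 0 for v in effects.values()):
        raise ValueError("effects must contain at least one individual")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lo_t, hi_t = design.trial_range()

    # Phase 1: build the roster (who exists, which trials) independently of
    # behavioural outcomes, so the covariate centring constant is known
    # before outcomes are drawn.
    roster: list[tuple[str, Group, Sex, IndividualEffects, list[int]]] = []
    counter = 0
    for group in (Group.VIRUS_FREE, Group.INFECTED):
        queue: list[tuple[Sex, IndividualEffects]] = list(effects.get(group, []))
        qi = 0
        while qi < len(queue):
            sex, eff = queue[qi]
            qi += 1
            counter += 1
            iid = f"{'vf' if group == Group.VIRUS_FREE else 'inf'}{counter:03d}"
            n_trials = int(rng.integers(lo_t, hi_t + 1)) if lo_t != hi_t else lo_t
            trials = list(range(1, n_trials + 1))
            if group == Group.INFECTED and design.mortality_per_trial > 0:
                completed: list[int] = []
                died = False
                for t in trials:
                    completed.append(t)
                    if rng.uniform() < design.mortality_per_trial:
                        died = True
                        break
                trials = completed
                if died and design.replacement:
                    if hypers is None or group not in hypers:
                        raise ValueError(
                            "replacement requires hypers for group "
                            f"{group.value}"
                        )
                    new_eff = sample_individual_effects(hypers[group], 1, rng)[0]
                    queue.append((sex, new_eff))
            roster.append((iid, group, sex, eff, trials))

    all_trials = np.concatenate([np.asarray(tr, float) for *_, tr in roster])
    centring = float(all_trials.mean())

    lat_lo, lat_hi = 1.0, design.observation_limit_s - 1.0
    records: list[TrialRecord] = []
    for iid, group, sex, eff, trials in roster:
        for t in trials:
            x = t - centring
            if design.force_all_emerge:
                stay = False
            else:
                eta = eff.a + eff.b * x
                stay = rng.uniform() < 1.0 / (1.0 + np.exp(-eta))
            if stay:
                records.append(
                    TrialRecord(iid, group, sex, t, emerged=False, latency_s=None)
                )
            else:
                latent = _sample_truncated_latency(
                    eff.c + eff.d * x, design.residual_sd, lat_lo, lat_hi, rng
                )
                latency = float(np.clip(round(latent), lat_lo, lat_hi))
                records.append(
                    TrialRecord(iid, group, sex, t, emerged=True, latency_s=latency)
                )
    return Dataset(records)


def simulate_dataset(
    hypers: dict[Group, GroupHyper],
    design: StudyDesign,
    seed: Optional[int] = None,
) -> tuple[Dataset, dict[Group, list[tuple[Sex, IndividualEffects]]]]:
    """Sample effects from the hyper-distributions, then simulate trials.

    Returns the dataset together with the true effects so that
    parameter-recovery tests can compare against the generating values.
    All randomness flows from one seed (``design.seed`` unless overridden).
    """
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    effect_seed, trial_seed = root.spawn(2)
    rng_eff = np.random.default_rng(effect_seed)
    effects: dict[Group, list[tuple[Sex, IndividualEffects]]] = {}
    for group in (Group.VIRUS_FREE, Group.INFECTED):
        pairs: list[tuple[Sex, IndividualEffects]] = []
        for sex in (Sex.MALE, Sex.FEMALE):
            n = design.n_per_group_sex.get((group, sex), 0)
            if n > 0:
                if group not in hypers:
                    raise ValueError(f"no hyperparameters for group {group.value}")
                for eff in sample_individual_effects(hypers[group], n, rng_eff):
                    pairs.append((sex, eff))
        if pairs:
            effects[group] = pairs
    ds = simulate_trials(
        effects, design, hypers=hypers, seed=np.random.default_rng(trial_seed).integers(2**31)
    )
    return ds, effects


def default_scenario() -> tuple[dict[Group, GroupHyper], StudyDesign]:
    """The study-like scenario used as the package-wide default truth.

    Hyperparameters are set to the published posterior means for each group;
    50 virus-free (26 M / 24 F) and 37 infected (19 M / 18 F) individuals,
    8 trials each, a 600 s observation window, and a 60 s residual latency
    SD (the residual SD is not published; 60 s is an order-of-magnitude
    placeholder that recovery tests treat as a free truth parameter).
    """
    hypers = {
        Group.VIRUS_FREE: GroupHyper(
            mu_a=-2.49,
            sigma_a=2.20,
            mu_b=-0.032,
            sigma_b=0.382,
            mu_c=149.0,
            sigma_c=75.1,
            mu_d=-10.8,
            sigma_d=5.33,
        ),
        Group.INFECTED: GroupHyper(
            mu_a=0.845,
            sigma_a=0.661,
            mu_b=-0.046,
            sigma_b=0.328,
            mu_c=284.0,
            sigma_c=64.3,
            mu_d=2.52,
            sigma_d=26.1,
        ),
    }
    design = StudyDesign(
        n_per_group_sex={
            (Group.VIRUS_FREE, Sex.MALE): 26,
            (Group.VIRUS_FREE, Sex.FEMALE): 24,
            (Group.INFECTED, Sex.MALE): 19,
            (Group.INFECTED, Sex.FEMALE): 18,
        },
        trials_per_individual=8,
        observation_limit_s=600.0,
        residual_sd=60.0,
        mortality_per_trial=0.0,
        replacement=True,
    )
    return hypers, design
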