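"""Posterior derived quantities: group comparisons, exceedance
probabilities, personality scores, prediction curves, sex disaggregation.

Group comparisons are computed by draw-wise subtraction of one group's
posterior from the other's (virus-free minus infected), and exceedance
probabilities as the fraction of aligned draws in which the infected value
exceeds the virus-free one (exact ties count one half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import expit

from .hurdle import PosteriorSamples
from .synthetic import EFFECT_NAMES
from .trial_data import Dataset, Group

__all__ = [
    "GroupComparison",
    "PredictionCurve",
    "group_difference",
    "exceedance_probability",
    "personality_scores",
    "disaggregate_by_sex",
    "predict_curves",
    "marginal_stay_probability",
    "summary_table",
]

_REFERENCE = Group.VIRUS_FREE.value  # difference orientation: reference - other
_OTHER = Group.INFECTED.value

#: Hyperparameter families comparable between groups.
COMPARABLE = [f"{kind}_{fam}" for fam in EFFECT_NAMES for kind in ("mu", "sigma")]


@dataclass(frozen=True)
class GroupComparison:
    """Draw-wise posterior comparison of one hyperparameter between groups."""

    parameter: str
    difference_draws: np.ndarray  # virus_free - infected, aligned draws
    difference_mean: float
    difference_sd: float
    exceedance: float  # P(infected > virus_free)


@dataclass(frozen=True)
class PredictionCurve:
    """Population-level prediction across a grid of trial numbers."""

    group: str
    trial_grid: np.ndarray
    emergence_mean: np.ndarray
    emergence_lo: np.ndarray
    emergence_hi: np.ndarray
    latency_mean: np.ndarray
    latency_lo: np.ndarray
    latency_hi: np.ndarray


def _aligned_group_draws(
    ps: PosteriorSamples, parameter: str
) -> tuple[np.ndarray, np.ndarray]:
    ref_name = f"{parameter}[{_REFERENCE}]"
    oth_name = f"{parameter}[{_OTHER}]"
    for name in (ref_name, oth_name):
        if name not in ps.hyper_draws:
            raise ValueError(
                f"parameter {parameter!r} is not available for both groups "
                f"(missing {name!r})"
            )
    return ps.stacked(ref_name), ps.stacked(oth_name)


def exceedance_probability(ps: PosteriorSamples, parameter: str) -> float:
    """P(infected > virus-free), draw-wise; exact ties count as one half."""
    ref, oth = _aligned_group_draws(ps, parameter)
    return float(np.mean((oth > ref) + 0.5 * (oth == ref)))


def group_difference(ps: PosteriorSamples, parameter: str) -> GroupComparison:
    """Posterior of (virus-free minus infected) for one hyperparameter."""
    ref, oth = _aligned_group_draws(ps, parameter)
    diff = ref - oth
    return GroupComparison(
        parameter=parameter,
        difference_draws=diff,
        difference_mean=float(diff.mean()),
        difference_sd=float(diff.std(ddof=1)),
        exceedance=float(np.mean((oth > ref) + 0.5 * (oth == ref))),
    )


def personality_scores(ps: PosteriorSamples, ds: Dataset) -> pd.DataFrame:
    """Posterior-mean effect values per individual (one row each).

    Columns: ``individual_id``, ``group``, ``sex`` and the four score
    columns ``a``, ``b``, ``c``, ``d``.
    """
    info = ds.individuals
    for iid in info:
        if iid not in ps.individual_ids:
            raise ValueError(f"individual {iid!r} missing from the posterior")
    means = {fam: ps.effect_matrix(fam).mean(axis=0) for fam in EFFECT_NAMES}
    rows = []
    for j, iid in enumerate(ps.individual_ids):
        if iid not in info:
            continue
        rows.append(
            {
                "individual_id": iid,
                "group": info[iid].group.value,
                "sex": info[iid].sex.value if info[iid].sex is not None else None,
                **{fam: float(means[fam][j]) for fam in EFFECT_NAMES},
            }
        )
    return pd.DataFrame(rows)


def disaggregate_by_sex(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, sex) summaries of personality scores.

    Returns one row per stratum with counts, mean/SD of each score, and the
    number of individuals with a positive latency slope (``d``).  Missing
    sex raises, naming the individuals.
    """
    missing = table.loc[table["sex"].isna(), "individual_id"].tolist()
    if missing:
        raise ValueError(
            "sex unknown for individuals: " + ", ".join(map(str, missing))
        )
    rows = []
    for (group, sex), sub in table.groupby(["group", "sex"], sort=True):
        row: dict = {"group": group, "sex": sex, "n": len(sub)}
        for fam in EFFECT_NAMES:
            row[f"{fam}_mean"] = float(sub[fam].mean())
            row[f"{fam}_sd"] = float(sub[fam].std(ddof=1)) if len(sub) > 1 else 0.0
        row["n_positive_d"] = int((sub["d"] > 0).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def predict_curves(
    ps: PosteriorSamples,
    group: str,
    trial_grid: Optional[Sequence[int]] = None,
) -> PredictionCurve:
    """Population-level prediction curves over trial numbers.

    For every posterior draw and grid point the emergence probability is
    ``1 - logistic(mu_a + mu_b * x)`` and the expected latency given
    emergence ``mu_c + mu_d * x``, with ``x`` centred using the constant
    stored with the fit.  Curves report the draw-wise mean and the central
    95% interval.
    """
    group = group.value if isinstance(group, Group) else str(group)
    if group not in ps.groups:
        raise ValueError(f"group {group!r} absent from the posterior")
    grid = np.asarray(
        list(trial_grid) if trial_grid is not None else range(1, 11), dtype=float
    )
    x = grid - ps.centring_constant
    mu_a = ps.stacked(f"mu_a[{group}]")[:, None]
    mu_b = ps.stacked(f"mu_b[{group}]")[:, None]
    mu_c = ps.stacked(f"mu_c[{group}]")[:, None]
    mu_d = ps.stacked(f"mu_d[{group}]")[:, None]
    emergence = 1.0 - expit(mu_a + mu_b * x[None, :])
    latency = mu_c + mu_d * x[None, :]

    def _summ(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            draws.mean(axis=0),
            np.quantile(draws, 0.025, axis=0),
            np.quantile(draws, 0.975, axis=0),
        )

    e_mean, e_lo, e_hi = _summ(emergence)
    l_mean, l_lo, l_hi = _summ(latency)
    return PredictionCurve(
        group=group,
        trial_grid=grid.astype(int),
        emergence_mean=e_mean,
        emergence_lo=e_lo,
        emergence_hi=e_hi,
        latency_mean=l_mean,
        latency_lo=l_lo,
        latency_hi=l_hi,
    )


def marginal_stay_probability(mu: float, sigma: float) -> float:
    """E[logistic(Z)] for Z ~ Normal(mu, sigma^2), by adaptive quadrature.

    This is the population-level stay probability marginalised over
    individual heterogeneity on the logit scale.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    # below ~1e-8 the heterogeneity correction (O(sigma^2)) is lost in
    # floating point and the integration interval can collapse entirely
    if sigma < 1e-8:
        return float(expit(mu))
    norm_const = 1.0 / (sigma * np.sqrt(2 * np.pi))

    def integrand(z: float) -> float:
        return expit(z) * norm_const * np.exp(-0.5 * ((z - mu) / sigma) ** 2)

    value, _ = integrate.quad(
        integrand,
        mu - 12 * sigma,
        mu + 12 * sigma,
        epsrel=1e-10,
        epsabs=1e-12,
        limit=200,
    )
    return float(value)


_FAMILY_LABELS = {
    "a": "binomial intercept",
    "b": "binomial slope",
    "c": "gaussian intercept",
    "d": "gaussian slope",
}


def summary_table(ps: PosteriorSamples) -> pd.DataFrame:
    """Posterior summary table in the published layout.

    One row per (effect family x {mean, st.dev}) with, per group, the
    posterior mean +/- SD of the hyperparameter, the virus-free-minus-
    infected difference, and the exceedance probability
    P(infected > virus-free).  Requires both groups in the posterior.
    """
    rows = []
    for fam in EFFECT_NAMES:
        for kind, kind_label in (("mu", "mean"), ("sigma", "st.dev")):
            parameter = f"{kind}_{fam}"
            ref, oth = _aligned_group_draws(ps, parameter)
            comp = group_difference(ps, parameter)
            rows.append(
                {
                    "parameter": _FAMILY_LABELS[fam],
                    "summary": kind_label,
                    "virus_free_mean": float(ref.mean()),
                    "virus_free_sd": float(ref.std(ddof=1)),
                    "infected_mean": float(oth.mean()),
                    "infected_sd": float(oth.std(ddof=1)),
                    "difference_mean": comp.difference_mean,
                    "difference_sd": comp.difference_sd,
                    "prob_infected_gt_virus_free": comp.exceedance,
                }
            )
    return pd.DataFrame(rows)
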