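"""Posterior predictive checks.

For each selected posterior draw a replicate dataset is simulated under the
fitted model at the observed design — same individuals, same trial indices,
same covariate centring, conditioning on that draw's individual effects
(within-sample check) — and a scalar test statistic is compared between the
observed data and the replicates.  The Bayesian p-value is the fraction of
replicates with ``T_rep >= T_obs``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy import stats as sps

from .hurdle import PosteriorSamples
from .synthetic import _sample_truncated_latency
from .trial_data import Dataset, TrialRecord

__all__ = ["PPCResult", "posterior_predictive_check", "STATISTICS"]


def _latencies(ds: Dataset) -> np.ndarray:
    return np.array([r.latency_s for r in ds.records if r.emerged], dtype=float)


def stay_fraction(ds: Dataset) -> float:
    """Fraction of trials in which the animal did not emerge."""
    return float(np.mean([not r.emerged for r in ds.records]))


def latency_mean(ds: Dataset) -> float:
    lat = _latencies(ds)
    return float(lat.mean()) if lat.size else float("nan")


def latency_sd(ds: Dataset) -> float:
    lat = _latencies(ds)
    return float(lat.std(ddof=1)) if lat.size > 1 else float("nan")


def latency_skewness(ds: Dataset) -> float:
    lat = _latencies(ds)
    if lat.size < 3 or lat.std() == 0:
        return float("nan")
    return float(sps.skew(lat))


def latency_frac_gt_300(ds: Dataset) -> float:
    lat = _latencies(ds)
    return float(np.mean(lat > 300.0)) if lat.size else float("nan")


def record_count(ds: Dataset) -> float:
    return float(len(ds))


STATISTICS: dict[str, Callable[[Dataset], float]] = {
    "stay_fraction": stay_fraction,
    "latency_mean": latency_mean,
    "latency_sd": latency_sd,
    "latency_skewness": latency_skewness,
    "latency_frac_gt_300": latency_frac_gt_300,
    "record_count": record_count,
}


@dataclass
class PPCResult:
    """Outcome of one posterior predictive check."""

    statistic: str
    observed: float
    replicates: np.ndarray
    p_value: float  # fraction of replicates >= observed
    n_skipped: int = 0  # replicates on which the statistic was not computable


def _replicate(
    ds: Dataset,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    sigma_res: float,
    id_index: dict[str, int],
    centring: float,
    obs_limit: float,
    rng: np.random.Generator,
) -> Dataset:
    records = []
    lat_lo, lat_hi = 1.0, obs_limit - 1.0
    for rec in ds.records:
        j = id_index[rec.individual_id]
        x = rec.trial_index - centring
        eta = a[j] + b[j] * x
        stay = rng.uniform() < 1.0 / (1.0 + np.exp(-eta))
        if stay:
            records.append(
                TrialRecord(
                    rec.individual_id, rec.group, rec.sex, rec.trial_index,
                    emerged=False, latency_s=None,
                )
            )
        else:
            latent = _sample_truncated_latency(
                c[j] + d[j] * x, sigma_res, lat_lo, lat_hi, rng
            )
            records.append(
                TrialRecord(
                    rec.individual_id, rec.group, rec.sex, rec.trial_index,
                    emerged=True,
                    latency_s=float(np.clip(round(latent), lat_lo, lat_hi)),
                )
            )
    return Dataset(records)


def posterior_predictive_check(
    ps: PosteriorSamples,
    ds: Dataset,
    statistic: Union[str, Callable[[Dataset], float]],
    draws: int = 500,
    seed: int = 0,
    observation_limit_s: float = 600.0,
) -> PPCResult:
    """Run one posterior predictive check.

    ``statistic`` is a name from :data:`STATISTICS` or any callable mapping
    a :class:`Dataset` to a scalar.  ``draws`` posterior draws are selected
    evenly across the stacked chains; replicates on which the statistic is
    not computable (NaN) are skipped and counted in ``n_skipped``.
    """
    if isinstance(statistic, str):
        if statistic not in STATISTICS:
            raise ValueError(
                f"unknown statistic {statistic!r}; built-ins: "
                + ", ".join(STATISTICS)
            )
        name, func = statistic, STATISTICS[statistic]
    else:
        name, func = getattr(statistic, "__name__", "custom"), statistic

    observed = float(func(ds))
    if not np.isfinite(observed):
        raise ValueError(f"statistic {name!r} is not computable on the observed data")

    rng = np.random.default_rng(seed)
    a = ps.effect_matrix("a")
    b = ps.effect_matrix("b")
    c = ps.effect_matrix("c")
    d = ps.effect_matrix("d")
    sr = ps.stacked("sigma_res")
    total = a.shape[0]
    n_use = min(draws, total)
    sel = np.linspace(0, total - 1, n_use).round().astype(int)
    id_index = {iid: j for j, iid in enumerate(ps.individual_ids)}
    for rec in ds.records:
        if rec.individual_id not in id_index:
            raise ValueError(
                f"individual {rec.individual_id!r} missing from the posterior"
            )
    centring = ps.centring_constant

    reps = []
    skipped = 0
    for k in sel:
        rep = _replicate(
            ds, a[k], b[k], c[k], d[k], float(sr[k]),
            id_index, centring, observation_limit_s, rng,
        )
        value = float(func(rep))
        if np.isfinite(value):
            reps.append(value)
        else:
            skipped += 1
    replicates = np.asarray(reps)
    if replicates.size == 0:
        raise ValueError(
            f"statistic {name!r} was not computable on any replicate"
        )
    p_value = float(np.mean(replicates >= observed))
    return PPCResult(
        statistic=name,
        observed=observed,
        replicates=replicates,
        p_value=p_value,
        n_skipped=skipped,
    )
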