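"""Inference core: joint density, priors, MCMC fitting and diagnostics.

Model
-----
For individual ``i`` at experience ``t`` with centred covariate
``x = t - centring_constant``::

    stay_it ~ Bernoulli(logistic(a_i + b_i * x))      # stay = did NOT emerge
    latency_it | emerged ~ Normal(c_i + d_i * x, sigma_res)

Each effect family ``f in {a, b, c, d}`` has a group-specific normal
hyper-distribution ``f_i ~ Normal(mu_f[g], sigma_f[g])``.  Priors are
minimally informative: wide normals on the means, half-normals on the SDs
(:class:`PriorConfig`).  The latency likelihood is a plain (untruncated)
gaussian.

Sampler
-------
Metropolis-within-Gibbs with conjugate block updates where available:

* ``(c_i, d_i)`` — exact bivariate-normal Gibbs draw per individual;
* ``(a_i, b_i)`` — joint random-walk Metropolis, scale adapted per
  individual during warmup;
* group means — conjugate normal draws;
* group SDs and the residual SD — univariate slice sampling;
* additionally every group SD (and, for the gaussian families, the group
  mean) is re-updated in the non-centred parameterisation and the effects
  back-transformed.  This interweaving breaks the funnel-shaped dependence
  between a hierarchical SD and its effects that otherwise makes plain
  Gibbs samplers sticky when the SD is small.

Convergence is gated on split-chain rank-normalised R-hat and bulk
effective sample size (via :mod:`arviz`) for every free hyperparameter.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

from .synthetic import EFFECT_NAMES, GroupHyper, IndividualEffects
from .trial_data import Dataset, Group

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "SamplerConfig",
    "PosteriorSamples",
    "ConvergenceError",
    "centre_experience",
    "hurdle_loglik",
    "log_prior",
    "fit",
    "diagnostics",
]

_LOG_2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    """Raised when a fit fails the R-hat / ESS gate and ``force`` is off."""


@dataclass(frozen=True)
class PriorConfig:
    """Scales of the minimally informative priors.

    Normal(0, scale^2) on group means, half-Normal(scale) on group SDs and
    on the residual SD.  Logit-scale parameters (a, b) get tighter scales
    than second-scale parameters (c, d).
    """

    mu_ab_scale: float = 10.0
    mu_cd_scale: float = 1000.0
    sigma_ab_scale: float = 5.0
    sigma_cd_scale: float = 200.0
    residual_scale: float = 200.0

    def mu_scale(self, family: str) -> float:
        return self.mu_ab_scale if family in ("a", "b") else self.mu_cd_scale

    def sigma_scale(self, family: str) -> float:
        return self.sigma_ab_scale if family in ("a", "b") else self.sigma_cd_scale

    def scaled(self, factor: float) -> "PriorConfig":
        return PriorConfig(
            self.mu_ab_scale * factor,
            self.mu_cd_scale * factor,
            self.sigma_ab_scale * factor,
            self.sigma_cd_scale * factor,
            self.residual_scale * factor,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Description of a fitted model, stored with its posterior."""

    groups: tuple[str, ...]
    centring_constant: float
    priors: PriorConfig = PriorConfig()
    residual_sd_shared: bool = True


@dataclass
class SamplerConfig:
    """MCMC configuration.

    ``chain_seeds`` may be given explicitly (must be pairwise distinct);
    by default chains get independent streams spawned from ``seed``.
    ``fixed`` clamps hyperparameters by name (e.g. ``"mu_a[virus_free]"``,
    ``"sigma_res"``); fixing a ``sigma_*`` to exactly 0 pins the family's
    effects at the (also fixed) group mean.  ``force`` bypasses the
    convergence gate.
    """

    chains: int = 4
    warmup: int = 1000
    iterations: int = 2000
    seed: int = 0
    force: bool = False
    mh_sweeps: int = 5
    target_accept: float = 0.33
    thin: int = 1
    fixed: dict[str, float] = field(default_factory=dict)
    chain_seeds: Optional[Sequence[int]] = None
    rhat_max: float = 1.01
    ess_min: float = 400.0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if self.iterations < 2 or self.warmup < 0:
            raise ValueError("invalid warmup/iterations")
        if self.chain_seeds is not None:
            seeds = list(self.chain_seeds)
            if len(seeds) != self.chains:
                raise ValueError("chain_seeds must have one entry per chain")
            if len(set(seeds)) != len(seeds):
                raise ValueError(
                    "chains must have distinct seeds; identical chain seeds "
                    "would produce identical, non-exchangeable chains"
                )


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------


class PosteriorSamples:
    """MCMC draws with chain structure, parameter names and diagnostics.

    ``hyper_draws`` maps hyperparameter names (``mu_a[virus_free]``, ...,
    ``sigma_res``) to ``(chain, draw)`` arrays; ``effect_draws`` maps each
    family letter to a ``(chain, draw, individual)`` array aligned with
    ``individual_ids``.
    """

    def __init__(
        self,
        hyper_draws: dict[str, np.ndarray],
        effect_draws: dict[str, np.ndarray],
        individual_ids: Sequence[str],
        individual_groups: Sequence[str],
        meta: Optional[dict] = None,
        diagnostics_table: Optional[pd.DataFrame] = None,
    ):
        self.hyper_draws = {k: np.asarray(v, float) for k, v in hyper_draws.items()}
        self.effect_draws = {k: np.asarray(v, float) for k, v in effect_draws.items()}
        self.individual_ids = list(individual_ids)
        self.individual_groups = list(individual_groups)
        self.meta = dict(meta or {})
        self.diagnostics_table = diagnostics_table
        shapes = {v.shape[:2] for v in self.hyper_draws.values()} | {
            v.shape[:2] for v in self.effect_draws.values()
        }
        if len(shapes) > 1:
            raise ValueError("all draw arrays must share (chain, draw) shape")
        if shapes:
            self.n_chains, self.n_draws = shapes.pop()
            if self.n_chains < 2:
                raise ValueError("PosteriorSamples requires >= 2 chains")

    # -- access ------------------------------------------------------------

    @property
    def groups(self) -> list[str]:
        return list(self.meta.get("groups", sorted(set(self.individual_groups))))

    @property
    def centring_constant(self) -> float:
        return float(self.meta["centring_constant"])

    def parameter_names(self) -> list[str]:
        return list(self.hyper_draws)

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one named parameter, flattened over chains.

        ``name`` is either a hyperparameter name or an individual effect
        like ``"a[vf001]"``.
        """
        if name in self.hyper_draws:
            return self.hyper_draws[name].reshape(-1)
        if "[" in name and name.endswith("]"):
            fam, iid = name[:-1].split("[", 1)
            if fam in self.effect_draws and iid in self.individual_ids:
                j = self.individual_ids.index(iid)
                return self.effect_draws[fam][:, :, j].reshape(-1)
        raise KeyError(f"unknown parameter {name!r}")

    def effect_matrix(self, family: str) -> np.ndarray:
        """(total draws, n individuals) matrix for one effect family."""
        arr = self.effect_draws[family]
        return arr.reshape(-1, arr.shape[2])

    def hyper_name(self, kind: str, family: str, group: str) -> str:
        return f"{kind}_{family}[{group}]"

    # -- interop / persistence ---------------------------------------------

    def to_inference_data(self) -> "az.InferenceData":
        posterior = {k: v for k, v in self.hyper_draws.items()}
        coords = {"individual": self.individual_ids}
        dims = {}
        for fam, arr in self.effect_draws.items():
            posterior[fam] = arr
            dims[fam] = ["individual"]
        return az.from_dict(posterior=posterior, coords=coords, dims=dims)

    def save(self, path: Union[str, Path]) -> None:
        """Persist as a self-describing ``.npz`` (arrays + JSON header)."""
        payload: dict[str, np.ndarray] = {}
        for k, v in self.hyper_draws.items():
            payload[f"hyper::{k}"] = v
        for k, v in self.effect_draws.items():
            payload[f"effect::{k}"] = v
        header = {
            "individual_ids": self.individual_ids,
            "individual_groups": self.individual_groups,
            "meta": self.meta,
        }
        if self.diagnostics_table is not None:
            header["diagnostics"] = self.diagnostics_table.to_dict(orient="list")
        payload["__header__"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PosteriorSamples":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"].tobytes()).decode())
            hyper = {
                k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("hyper::")
            }
            effects = {
                k.split("::", 1)[1]: data[k]
                for k in data.files
                if k.startswith("effect::")
            }
        diag = None
        if "diagnostics" in header:
            diag = pd.DataFrame(header["diagnostics"])
        return cls(
            hyper,
            effects,
            header["individual_ids"],
            header["individual_groups"],
            header["meta"],
            diag,
        )


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def centre_experience(ds: Dataset) -> float:
    """Mean trial index over all records; the covariate is centred on it."""
    if len(ds) == 0:
        raise ValueError("cannot centre experience on an empty dataset")
    return float(np.mean([rec.trial_index for rec in ds.records]))


def hurdle_loglik(
    ds: Dataset,
    effects: Mapping[str, IndividualEffects],
    residual_sd: float,
    centring_constant: float,
) -> float:
    """Joint log-likelihood of the hurdle model at given effects.

    Every record contributes a Bernoulli term for the stay indicator
    (stay = 1 iff the animal did not emerge); emerged records additionally
    contribute a gaussian term for the latency.
    """
    if residual_sd <= 0:
        raise ValueError("residual_sd must be > 0")
    total = 0.0
    for rec in ds.records:
        if rec.individual_id not in effects:
            raise ValueError(
                f"no effects supplied for individual {rec.individual_id!r}"
            )
        eff = effects[rec.individual_id]
        x = rec.trial_index - centring_constant
        eta = eff.a + eff.b * x
        stay = 0.0 if rec.emerged else 1.0
        total += stay * eta - np.logaddexp(0.0, eta)
        if rec.emerged:
            mu = eff.c + eff.d * x
            z = (rec.latency_s - mu) / residual_sd
            total += -0.5 * z * z - math.log(residual_sd) - 0.5 * _LOG_2PI
    return float(total)


def _normal_logpdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return (
        0.5 * math.log(2.0 / math.pi)
        - math.log(scale)
        - 0.5 * (x / scale) ** 2
    )


def _get(h, key: str) -> float:
    if isinstance(h, Mapping):
        return float(h[key])
    return float(getattr(h, key))


def log_prior(
    hypers: Mapping[Group, object],
    effects: Mapping[str, IndividualEffects],
    group_of: Mapping[str, Group],
    residual_sd: float,
    priors: PriorConfig = PriorConfig(),
) -> float:
    """Log prior density: hyper priors + random-effects terms + residual SD.

    ``hypers`` maps each group to a :class:`GroupHyper` or a plain mapping
    with ``mu_*`` / ``sigma_*`` keys (the latter admits out-of-support
    values).  Any ``sigma_* <= 0`` or ``residual_sd <= 0`` yields ``-inf``
    (support violation), never an exception.
    """
    total = 0.0
    for group, h in hypers.items():
        for fam in EFFECT_NAMES:
            sigma = _get(h, f"sigma_{fam}")
            if sigma <= 0:
                return -math.inf
            mu = _get(h, f"mu_{fam}")
            total += _normal_logpdf(mu, 0.0, priors.mu_scale(fam))
            total += _halfnormal_logpdf(sigma, priors.sigma_scale(fam))
    if residual_sd <= 0:
        return -math.inf
    total += _halfnormal_logpdf(residual_sd, priors.residual_scale)
    for iid, eff in effects.items():
        h = hypers[group_of[iid]]
        for fam in EFFECT_NAMES:
            total += _normal_logpdf(
                getattr(eff, fam), _get(h, f"mu_{fam}"), _get(h, f"sigma_{fam}")
            )
    return float(total)


# ---------------------------------------------------------------------------
# Internal data layout
# ---------------------------------------------------------------------------


@dataclass
class _FitData:
    ids: list[str]
    group_labels: list[str]  # per individual, group value string
    groups: list[str]  # group values present, stable order
    ind_group_idx: np.ndarray  # (n_ind,) int
    rec_ind: np.ndarray  # (n_rec,) int
    rec_x: np.ndarray
    rec_stay: np.ndarray  # 1.0 = stayed (not emerged)
    em_ind: np.ndarray  # emerged records only
    em_x: np.ndarray
    em_y: np.ndarray
    # per-individual gaussian sufficient stats over emerged records
    g_n: np.ndarray
    g_sx: np.ndarray
    g_sxx: np.ndarray
    g_sy: np.ndarray
    g_sxy: np.ndarray
    # per-group record views (binomial) and emerged views (gaussian)
    grp_rec: list[np.ndarray]
    grp_em: list[np.ndarray]
    grp_ind: list[np.ndarray]
    centring: float


def _prepare(ds: Dataset) -> _FitData:
    if len(ds) == 0:
        raise ValueError("cannot fit an empty dataset")
    centring = centre_experience(ds)
    ids: list[str] = []
    group_labels: list[str] = []
    index: dict[str, int] = {}
    for rec in ds.records:
        if rec.individual_id not in index:
            index[rec.individual_id] = len(ids)
            ids.append(rec.individual_id)
            group_labels.append(rec.group.value)
    groups = sorted(set(group_labels), key=group_labels.index)

    n_rec = len(ds)
    rec_ind = np.empty(n_rec, dtype=np.int64)
    rec_x = np.empty(n_rec)
    rec_stay = np.empty(n_rec)
    em_rows = []
    for r, rec in enumerate(ds.records):
        rec_ind[r] = index[rec.individual_id]
        rec_x[r] = rec.trial_index - centring
        rec_stay[r] = 0.0 if rec.emerged else 1.0
        if rec.emerged:
            em_rows.append((index[rec.individual_id], rec_x[r], rec.latency_s))
    emerged_inds = {row[0] for row in em_rows}
    for g in groups:
        gi = {i for i, lbl in enumerate(group_labels) if lbl == g}
        if not (gi & emerged_inds):
            raise ValueError(
                f"group {g!r} has no emerged trials: the latency process is "
                "unidentifiable for this group"
            )
    em_ind = np.array([r[0] for r in em_rows], dtype=np.int64)
    em_x = np.array([r[1] for r in em_rows])
    em_y = np.array([r[2] for r in em_rows])

    n_ind = len(ids)
    g_n = np.bincount(em_ind, minlength=n_ind).astype(float)
    g_sx = np.bincount(em_ind, weights=em_x, minlength=n_ind)
    g_sxx = np.bincount(em_ind, weights=em_x**2, minlength=n_ind)
    g_sy = np.bincount(em_ind, weights=em_y, minlength=n_ind)
    g_sxy = np.bincount(em_ind, weights=em_x * em_y, minlength=n_ind)

    ind_group_idx = np.array([groups.index(lbl) for lbl in group_labels])
    grp_rec = [np.where(ind_group_idx[rec_ind] == gi)[0] for gi in range(len(groups))]
    grp_em = [np.where(ind_group_idx[em_ind] == gi)[0] for gi in range(len(groups))]
    grp_ind = [np.where(ind_group_idx == gi)[0] for gi in range(len(groups))]

    return _FitData(
        ids,
        group_labels,
        groups,
        ind_group_idx,
        rec_ind,
        rec_x,
        rec_stay,
        em_ind,
        em_x,
        em_y,
        g_n,
        g_sx,
        g_sxx,
        g_sy,
        g_sxy,
        grp_rec,
        grp_em,
        grp_ind,
        centring,
    )


# ---------------------------------------------------------------------------
# Slice sampler (Neal 2003, stepping out + shrinkage)
# ---------------------------------------------------------------------------


def _slice_sample(
    x0: float,
    logf: Callable[[float], float],
    w: float,
    rng: np.random.Generator,
    max_steps: int = 30,
) -> float:
    logy = logf(x0) - rng.exponential()
    u = rng.uniform(0.0, w)
    left, right = x0 - u, x0 + u
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and logf(left) > logy:
        left -= w
        j -= 1
    while k > 0 and logf(right) > logy:
        right += w
        k -= 1
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pathological shrinkage; keep current point


def _trunc_normal_pos(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Draw from Normal(mean, sd) truncated to (0, inf).

    Plain rejection when the positive region has decent mass; exponential
    tilting (Robert 1995) when it is a far tail.
    """
    alpha = -mean / sd
    if alpha < 1.0:
        for _ in range(100):
            z = rng.standard_normal()
            if z > alpha:
                return mean + sd * z
    lam = 0.5 * (alpha + math.sqrt(alpha * alpha + 4.0))
    while True:
        z = alpha + rng.exponential() / lam
        if math.log(rng.uniform()) <= -0.5 * (z - lam) ** 2:
            return mean + sd * z


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


_HYPER_KINDS = ("mu", "sigma")


def _hyper_names(groups: Sequence[str]) -> list[str]:
    names = []
    for fam in EFFECT_NAMES:
        for kind in _HYPER_KINDS:
            for g in groups:
                names.append(f"{kind}_{fam}[{g}]")
    names.append("sigma_res")
    return names


class _ChainState:
    __slots__ = ("eff", "mu", "sig", "sigma_res", "mh_scale", "mh_accept")

    def __init__(self, n_ind: int, n_grp: int):
        self.eff = {f: np.zeros(n_ind) for f in EFFECT_NAMES}
        self.mu = {f: np.zeros(n_grp) for f in EFFECT_NAMES}
        self.sig = {f: np.ones(n_grp) for f in EFFECT_NAMES}
        self.sigma_res = 50.0
        self.mh_scale = np.full(n_ind, 1.0)
        self.mh_accept = np.zeros(n_ind)


def _binom_ll_by_ind(
    a: np.ndarray, b: np.ndarray, data: _FitData, n_ind: int
) -> np.ndarray:
    eta = a[data.rec_ind] + b[data.rec_ind] * data.rec_x
    ll = data.rec_stay * eta - np.logaddexp(0.0, eta)
    return np.bincount(data.rec_ind, weights=ll, minlength=n_ind)


def _run_chain(
    data: _FitData,
    cfg: SamplerConfig,
    priors: PriorConfig,
    rng: np.random.Generator,
    fixed: dict[str, float],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    n_ind = len(data.ids)
    n_grp = len(data.groups)
    st = _ChainState(n_ind, n_grp)

    def is_fixed(kind: str, fam: str, g: int) -> bool:
        return f"{kind}_{fam}[{data.groups[g]}]" in fixed

    def pinned(fam: str) -> np.ndarray:
        """Per-individual mask: family effect pinned to the group mean."""
        mask = np.zeros(n_ind, dtype=bool)
        for g in range(n_grp):
            if is_fixed("sigma", fam, g) and fixed[f"sigma_{fam}[{data.groups[g]}]"] == 0.0:
                mask |= data.ind_group_idx == g
        return mask

    pinned_mask = {f: pinned(f) for f in EFFECT_NAMES}
    for fam in EFFECT_NAMES:
        for g in range(n_grp):
            if (
                is_fixed("sigma", fam, g)
                and fixed[f"sigma_{fam}[{data.groups[g]}]"] == 0.0
                and not is_fixed("mu", fam, g)
            ):
                raise ValueError(
                    f"sigma_{fam}[{data.groups[g]}] fixed at 0 requires fixing "
                    f"mu_{fam}[{data.groups[g]}] as well"
                )

    # ----- initial values --------------------------------------------------
    n_stay = np.bincount(data.rec_ind, weights=data.rec_stay, minlength=n_ind)
    n_tot = np.bincount(data.rec_ind, minlength=n_ind).astype(float)
    p_hat = (n_stay + 0.5) / (n_tot + 1.0)
    st.eff["a"] = np.log(p_hat / (1 - p_hat)) + 0.2 * rng.standard_normal(n_ind)
    st.eff["b"] = 0.05 * rng.standard_normal(n_ind)
    mean_lat = np.where(data.g_n > 0, data.g_sy / np.maximum(data.g_n, 1), np.nan)
    overall = np.nanmean(mean_lat) if np.isfinite(mean_lat).any() else 200.0
    st.eff["c"] = np.where(np.isnan(mean_lat), overall, mean_lat)
    st.eff["c"] = st.eff["c"] + 5.0 * rng.standard_normal(n_ind)
    st.eff["d"] = 2.0 * rng.standard_normal(n_ind)
    for fam in EFFECT_NAMES:
        for g in range(n_grp):
            sel = data.ind_group_idx == g
            st.mu[fam][g] = float(np.mean(st.eff[fam][sel]))
            st.sig[fam][g] = float(max(np.std(st.eff[fam][sel]), 0.1))
    resid = data.em_y - st.eff["c"][data.em_ind] - st.eff["d"][data.em_ind] * data.em_x
    st.sigma_res = float(max(np.std(resid), 5.0))

    # apply fixed values / pins
    def apply_fixed() -> None:
        for fam in EFFECT_NAMES:
            for g in range(n_grp):
                key_mu = f"mu_{fam}[{data.groups[g]}]"
                key_sig = f"sigma_{fam}[{data.groups[g]}]"
                if key_mu in fixed:
                    st.mu[fam][g] = fixed[key_mu]
                if key_sig in fixed:
                    st.sig[fam][g] = fixed[key_sig]
        if "sigma_res" in fixed:
            st.sigma_res = fixed["sigma_res"]
        for fam in EFFECT_NAMES:
            mask = pinned_mask[fam]
            if mask.any():
                st.eff[fam][mask] = st.mu[fam][data.ind_group_idx[mask]]

    apply_fixed()

    mu_scale = {f: priors.mu_scale(f) for f in EFFECT_NAMES}
    sig_scale = {f: priors.sigma_scale(f) for f in EFFECT_NAMES}

    # ----- update blocks ---------------------------------------------------

    def update_gaussian_effects() -> None:
        free_c = ~pinned_mask["c"]
        free_d = ~pinned_mask["d"]
        if not (free_c.any() or free_d.any()):
            return
        gi = data.ind_group_idx
        muc, sigc = st.mu["c"][gi], st.sig["c"][gi]
        mud, sigd = st.mu["d"][gi], st.sig["d"][gi]
        ivr = 1.0 / st.sigma_res**2
        both = free_c & free_d
        if both.any():
            with np.errstate(divide="ignore"):
                a11 = data.g_n * ivr + 1.0 / sigc**2
                a12 = data.g_sx * ivr
                a22 = data.g_sxx * ivr + 1.0 / sigd**2
                r1 = data.g_sy * ivr + muc / sigc**2
                r2 = data.g_sxy * ivr + mud / sigd**2
            det = a11 * a22 - a12**2
            c11, c12, c22 = a22 / det, -a12 / det, a11 / det
            m1 = c11 * r1 + c12 * r2
            m2 = c12 * r1 + c22 * r2
            l11 = np.sqrt(c11)
            l21 = c12 / l11
            l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-300))
            z1 = rng.standard_normal(n_ind)
            z2 = rng.standard_normal(n_ind)
            newc = m1 + l11 * z1
            newd = m2 + l21 * z1 + l22 * z2
            st.eff["c"][both] = newc[both]
            st.eff["d"][both] = newd[both]
        only_c = free_c & ~free_d
        if only_c.any():
            prec = data.g_n * ivr + 1.0 / sigc**2
            rhs = (data.g_sy - st.eff["d"] * data.g_sx) * ivr + muc / sigc**2
            mean = rhs / prec
            draw = mean + rng.standard_normal(n_ind) / np.sqrt(prec)
            st.eff["c"][only_c] = draw[only_c]
        only_d = free_d & ~free_c
        if only_d.any():
            prec = data.g_sxx * ivr + 1.0 / sigd**2
            rhs = (data.g_sxy - st.eff["c"] * data.g_sx) * ivr + mud / sigd**2
            mean = rhs / prec
            draw = mean + rng.standard_normal(n_ind) / np.sqrt(prec)
            st.eff["d"][only_d] = draw[only_d]

    def update_binomial_effects(adapt: bool, step: int) -> None:
        free_a = ~pinned_mask["a"]
        free_b = ~pinned_mask["b"]
        if not (free_a.any() or free_b.any()):
            return
        gi = data.ind_group_idx
        mua, siga = st.mu["a"][gi], st.sig["a"][gi]
        mub, sigb = st.mu["b"][gi], st.sig["b"][gi]
        for _ in range(cfg.mh_sweeps):
            cur_ll = _binom_ll_by_ind(st.eff["a"], st.eff["b"], data, n_ind)
            step_a = np.where(free_a, st.mh_scale, 0.0)
            step_b = np.where(free_b, 0.35 * st.mh_scale, 0.0)
            prop_a = st.eff["a"] + step_a * rng.standard_normal(n_ind)
            prop_b = st.eff["b"] + step_b * rng.standard_normal(n_ind)
            prop_ll = _binom_ll_by_ind(prop_a, prop_b, data, n_ind)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_prior = np.zeros(n_ind)
                if free_a.any():
                    d_prior += np.where(
                        free_a,
                        ((st.eff["a"] - mua) ** 2 - (prop_a - mua) ** 2)
                        / (2 * np.maximum(siga, 1e-300) ** 2),
                        0.0,
                    )
                if free_b.any():
                    d_prior += np.where(
                        free_b,
                        ((st.eff["b"] - mub) ** 2 - (prop_b - mub) ** 2)
                        / (2 * np.maximum(sigb, 1e-300) ** 2),
                        0.0,
                    )
            log_alpha = prop_ll - cur_ll + d_prior
            accept = np.log(rng.uniform(size=n_ind)) < log_alpha
            accept &= free_a | free_b
            st.eff["a"][accept] = prop_a[accept]
            st.eff["b"][accept] = prop_b[accept]
            if adapt:
                gamma = (step + 1.0) ** -0.6
                st.mh_scale *= np.exp(
                    gamma * (accept.astype(float) - cfg.target_accept)
                )
                np.clip(st.mh_scale, 1e-3, 50.0, out=st.mh_scale)

    def update_hypers_centred() -> None:
        for fam in EFFECT_NAMES:
            for g in range(n_grp):
                sel = data.grp_ind[g]
                e = st.eff[fam][sel]
                n_g = len(e)
                if not is_fixed("mu", fam, g):
                    sig = st.sig[fam][g]
                    prec = n_g / sig**2 + 1.0 / mu_scale[fam] ** 2
                    mean = (e.sum() / sig**2) / prec
                    st.mu[fam][g] = mean + rng.standard_normal() / math.sqrt(prec)
                if not is_fixed("sigma", fam, g):
                    mu = st.mu[fam][g]
                    sse = float(np.sum((e - mu) ** 2))
                    s_h = sig_scale[fam]

                    def logf(s: float) -> float:
                        if s <= 0:
                            return -math.inf
                        return (
                            -n_g * math.log(s)
                            - sse / (2 * s * s)
                            - s * s / (2 * s_h * s_h)
                        )

                    w = max(st.sig[fam][g] / 2.0, 0.05)
                    st.sig[fam][g] = _slice_sample(st.sig[fam][g], logf, w, rng)

    def update_hypers_noncentred() -> None:
        # gaussian families: conjugate truncated-normal / normal updates
        ivr = 1.0 / st.sigma_res**2
        for g in range(n_grp):
            em = data.grp_em[g]
            ind = data.em_ind[em]
            x = data.em_x[em]
            y = data.em_y[em]
            # family c
            if not is_fixed("sigma", "c", g):
                mu, sig = st.mu["c"][g], st.sig["c"][g]
                tilde = np.zeros(n_ind)
                sel = data.grp_ind[g]
                tilde[sel] = (st.eff["c"][sel] - mu) / sig
                z = tilde[ind]
                r = y - st.eff["d"][ind] * x - mu
                prec = float(np.sum(z * z)) * ivr + 1.0 / sig_scale["c"] ** 2
                mean = float(np.sum(z * r)) * ivr / prec
                new_sig = _trunc_normal_pos(mean, 1.0 / math.sqrt(prec), rng)
                if not is_fixed("mu", "c", g):
                    r2 = y - st.eff["d"][ind] * x - new_sig * z
                    prec2 = len(y) * ivr + 1.0 / mu_scale["c"] ** 2
                    mean2 = float(np.sum(r2)) * ivr / prec2
                    mu = mean2 + rng.standard_normal() / math.sqrt(prec2)
                    st.mu["c"][g] = mu
                st.sig["c"][g] = new_sig
                st.eff["c"][sel] = mu + new_sig * tilde[sel]
            # family d
            if not is_fixed("sigma", "d", g):
                mu, sig = st.mu["d"][g], st.sig["d"][g]
                tilde = np.zeros(n_ind)
                sel = data.grp_ind[g]
                tilde[sel] = (st.eff["d"][sel] - mu) / sig
                z = tilde[ind] * x
                r = y - st.eff["c"][ind] - mu * x
                prec = float(np.sum(z * z)) * ivr + 1.0 / sig_scale["d"] ** 2
                mean = float(np.sum(z * r)) * ivr / prec
                new_sig = _trunc_normal_pos(mean, 1.0 / math.sqrt(prec), rng)
                if not is_fixed("mu", "d", g):
                    r2 = y - st.eff["c"][ind] - new_sig * z
                    prec2 = float(np.sum(x * x)) * ivr + 1.0 / mu_scale["d"] ** 2
                    mean2 = float(np.sum(x * r2)) * ivr / prec2
                    mu = mean2 + rng.standard_normal() / math.sqrt(prec2)
                    st.mu["d"][g] = mu
                st.sig["d"][g] = new_sig
                st.eff["d"][sel] = mu + new_sig * tilde[sel]
        # binomial families: slice updates of sigma (and mu) given ancillary
        for g in range(n_grp):
            recs = data.grp_rec[g]
            ind = data.rec_ind[recs]
            x = data.rec_x[recs]
            stay = data.rec_stay[recs]
            sel = data.grp_ind[g]
            # family a
            if not is_fixed("sigma", "a", g):
                mu, sig = st.mu["a"][g], st.sig["a"][g]
                tilde = np.zeros(n_ind)
                tilde[sel] = (st.eff["a"][sel] - mu) / sig
                tz = tilde[ind]
                bx = st.eff["b"][ind] * x

                def logf_sig_a(s: float) -> float:
                    if s <= 0:
                        return -math.inf
                    eta = mu + s * tz + bx
                    ll = float(np.sum(stay * eta - np.logaddexp(0.0, eta)))
                    return ll - s * s / (2 * sig_scale["a"] ** 2)

                sig = _slice_sample(sig, logf_sig_a, max(sig / 2.0, 0.1), rng)
                if not is_fixed("mu", "a", g):
                    stz = sig * tz

                    def logf_mu_a(m: float) -> float:
                        eta = m + stz + bx
                        ll = float(np.sum(stay * eta - np.logaddexp(0.0, eta)))
                        return ll - m * m / (2 * mu_scale["a"] ** 2)

                    mu = _slice_sample(mu, logf_mu_a, 1.0, rng)
                    st.mu["a"][g] = mu
                st.sig["a"][g] = sig
                st.eff["a"][sel] = mu + sig * tilde[sel]
            # family b
            if not is_fixed("sigma", "b", g):
                mu, sig = st.mu["b"][g], st.sig["b"][g]
                tilde = np.zeros(n_ind)
                tilde[sel] = (st.eff["b"][sel] - mu) / sig
                tzx = tilde[ind] * x
                aa = st.eff["a"][ind]

                def logf_sig_b(s: float) -> float:
                    if s <= 0:
                        return -math.inf
                    eta = aa + mu * x + s * tzx
                    ll = float(np.sum(stay * eta - np.logaddexp(0.0, eta)))
                    return ll - s * s / (2 * sig_scale["b"] ** 2)

                sig = _slice_sample(sig, logf_sig_b, max(sig / 2.0, 0.05), rng)
                if not is_fixed("mu", "b", g):
                    stzx = sig * tzx

                    def logf_mu_b(m: float) -> float:
                        eta = aa + m * x + stzx
                        ll = float(np.sum(stay * eta - np.logaddexp(0.0, eta)))
                        return ll - m * m / (2 * mu_scale["b"] ** 2)

                    mu = _slice_sample(mu, logf_mu_b, 0.3, rng)
                    st.mu["b"][g] = mu
                st.sig["b"][g] = sig
                st.eff["b"][sel] = mu + sig * tilde[sel]

    def update_sigma_res() -> None:
        if "sigma_res" in fixed:
            return
        r = (
            data.em_y
            - st.eff["c"][data.em_ind]
            - st.eff["d"][data.em_ind] * data.em_x
        )
        ssr = float(np.sum(r * r))
        n = len(r)
        s_h = priors.residual_scale

        def logf(s: float) -> float:
            if s <= 0:
                return -math.inf
            return -n * math.log(s) - ssr / (2 * s * s) - s * s / (2 * s_h * s_h)

        st.sigma_res = _slice_sample(
            st.sigma_res, logf, max(st.sigma_res / 4.0, 1.0), rng
        )

    # ----- main loop -------------------------------------------------------
    total = cfg.warmup + cfg.iterations
    hyper_names = _hyper_names(data.groups)
    hyper_out = {name: np.empty(cfg.iterations) for name in hyper_names}
    eff_out = {f: np.empty((cfg.iterations, n_ind)) for f in EFFECT_NAMES}

    for it in range(total):
        adapt = it < cfg.warmup
        update_gaussian_effects()
        update_binomial_effects(adapt, it)
        update_hypers_centred()
        apply_fixed()
        update_hypers_noncentred()
        apply_fixed()
        update_sigma_res()
        if it >= cfg.warmup:
            k = it - cfg.warmup
            for fam in EFFECT_NAMES:
                for g in range(n_grp):
                    hyper_out[f"mu_{fam}[{data.groups[g]}]"][k] = st.mu[fam][g]
                    hyper_out[f"sigma_{fam}[{data.groups[g]}]"][k] = st.sig[fam][g]
                eff_out[fam][k] = st.eff[fam]
            hyper_out["sigma_res"][k] = st.sigma_res
    return hyper_out, eff_out


def fit(
    ds: Dataset,
    config: Optional[SamplerConfig] = None,
    priors: PriorConfig = PriorConfig(),
) -> PosteriorSamples:
    """Fit the hierarchical hurdle model by MCMC.

    Raises :class:`ConvergenceError` if any free hyperparameter has
    split-chain R-hat above the gate or bulk ESS below it, unless
    ``config.force`` is set.  Chains use independent random streams
    spawned from ``config.seed`` (or explicit distinct ``chain_seeds``).
    """
    cfg = config or SamplerConfig()
    data = _prepare(ds)
    if cfg.chain_seeds is not None:
        rngs = [np.random.default_rng(s) for s in cfg.chain_seeds]
    else:
        rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(cfg.chains)]

    fixed = dict(cfg.fixed)
    hyper_chains: dict[str, list[np.ndarray]] = {}
    eff_chains: dict[str, list[np.ndarray]] = {f: [] for f in EFFECT_NAMES}
    for rng in rngs:
        hyper_out, eff_out = _run_chain(data, cfg, priors, rng, fixed)
        for name, arr in hyper_out.items():
            hyper_chains.setdefault(name, []).append(arr)
        for fam in EFFECT_NAMES:
            eff_chains[fam].append(eff_out[fam])

    hyper_draws = {name: np.stack(chains) for name, chains in hyper_chains.items()}
    effect_draws = {fam: np.stack(chains) for fam, chains in eff_chains.items()}

    meta = {
        "groups": data.groups,
        "centring_constant": data.centring,
        "seed": cfg.seed,
        "chains": cfg.chains,
        "warmup": cfg.warmup,
        "iterations": cfg.iterations,
        "fixed": fixed,
        "priors": dataclasses.asdict(priors),
    }
    ps = PosteriorSamples(
        hyper_draws,
        effect_draws,
        data.ids,
        data.group_labels,
        meta,
    )
    free_hypers = [n for n in hyper_draws if n not in fixed]
    diag = _diagnostics_for(
        {n: hyper_draws[n] for n in free_hypers}
    )
    ps.diagnostics_table = diag
    bad = diag[(diag["rhat"] > cfg.rhat_max) | (diag["ess"] < cfg.ess_min)]
    if len(bad) and not cfg.force:
        worst = ", ".join(
            f"{r.parameter} (rhat={r.rhat:.3f}, ess={r.ess:.0f})"
            for r in bad.itertuples()
        )
        raise ConvergenceError(
            f"fit failed the convergence gate (R-hat <= {cfg.rhat_max}, "
            f"ESS >= {cfg.ess_min:.0f}): {worst}. Increase iterations or set "
            "force=True to keep the draws anyway."
        )
    return ps


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _diagnostics_for(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in draws.items():
            rhat = float(az.rhat(arr.reshape(arr.shape[0], arr.shape[1], -1)[..., 0]))
            ess = float(az.ess(arr.reshape(arr.shape[0], arr.shape[1], -1)[..., 0]))
            rows.append({"parameter": name, "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])


def diagnostics(ps: PosteriorSamples, include_effects: bool = False) -> pd.DataFrame:
    """Split-chain rank-normalised R-hat and bulk ESS per parameter."""
    if ps.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    if ps.n_draws < 4:
        raise ValueError("diagnostics require at least 4 iterations per chain")
    draws = dict(ps.hyper_draws)
    if include_effects:
        for fam, arr in ps.effect_draws.items():
            for j, iid in enumerate(ps.individual_ids):
                draws[f"{fam}[{iid}]"] = arr[:, :, j]
    return _diagnostics_for(draws)
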