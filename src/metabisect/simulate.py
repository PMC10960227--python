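"""Forward generative model of an observer in the bisection/metacognition task.

Each trial the observer produces two bisection estimates

    I1 ~ Normal(phi, sigma_i1),   I2 ~ Normal(phi, sigma_i2),

truncated to [0, total_duration] (a button release cannot precede stimulus
onset or follow its offset), where ``phi`` is the observer's subjective
midpoint. The second-order choice compares the perceived errors
``Delta_k = |I_k - phi|`` through a noisy difference

    dDelta_hat ~ Normal(Delta_1 - Delta_2, sigma_meta)

and interval 1 is chosen with probability P(dDelta_hat < 0), i.e. a probit
in the error difference. As ``sigma_meta -> 0`` the observer becomes the
ideal chooser of their own smaller-error interval.

Default parameter scales (phi = 0.75 s, sigma_i ~ 0.15 s, sigma_meta ~ 0.5 s,
rho ~ 0.6) correspond to typical subject-level values in the 1500 ms
duration condition of the paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .trials import CONDITIONS, ScheduleSpec, SessionDataset, TrialRecord, ideal_choice

__all__ = [
    "ObserverParams",
    "GroupParams",
    "choice_probability",
    "simulate_trial",
    "simulate_session",
    "simulate_study",
    "sample_observers",
]


def _per_condition(value, conditions=CONDITIONS) -> dict:
    if isinstance(value, dict):
        return {c: float(value[c]) for c in value}
    return {c: float(value) for c in conditions}


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic observer.

    ``phi``, ``sigma_i1``, ``sigma_i2`` and ``sigma_meta`` map each modality
    condition to, respectively, the subjective midpoint (s), the two
    interval-estimate SDs (s) and the metacognitive SD (s). Scalars are
    broadcast to all conditions. ``drift`` optionally specifies an initial
    learning transient ``(offset_s, decay_trials)`` added to the midpoint,
    off by default to match the static-midpoint assumption of the
    measurement model.
    """

    phi: dict = field(default_factory=lambda: _per_condition(0.75))
    sigma_i1: dict = field(default_factory=lambda: _per_condition(0.15))
    sigma_i2: dict = field(default_factory=lambda: _per_condition(0.15))
    sigma_meta: dict = field(default_factory=lambda: _per_condition(0.5))
    rho: float = 0.6
    drift: tuple[float, float] | None = None
    subject_id: str = "sim"

    def __post_init__(self):
        object.__setattr__(self, "phi", _per_condition(self.phi))
        for name in ("sigma_i1", "sigma_i2", "sigma_meta"):
            d = _per_condition(getattr(self, name))
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, d)
        if any(v <= 0 for v in self.phi.values()):
            raise ValueError("phi must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


@dataclass(frozen=True)
class GroupParams:
    """Group-level distribution from which observers are sampled.

    Subject midpoints are Normal(phi, phi_sd) per condition; the three SD
    parameters vary between subjects lognormally (median = the group value,
    log-scale spread ``sigma_spread``) with cross-condition correlation
    ``rho`` within each role, mirroring the repeated-measures coupling of
    the measurement model.
    """

    phi: dict = field(default_factory=lambda: _per_condition(0.75))
    sigma_i1: dict = field(default_factory=lambda: _per_condition(0.15))
    sigma_i2: dict = field(default_factory=lambda: _per_condition(0.15))
    sigma_meta: dict = field(default_factory=lambda: _per_condition(0.5))
    phi_sd: float = 0.02
    sigma_spread: float = 0.2
    rho: float = 0.6

    def __post_init__(self):
        object.__setattr__(self, "phi", _per_condition(self.phi))
        for name in ("sigma_i1", "sigma_i2", "sigma_meta"):
            object.__setattr__(self, name, _per_condition(getattr(self, name)))
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.phi_sd < 0 or self.sigma_spread < 0:
            raise ValueError("spreads must be nonnegative")


def choice_probability(delta1, delta2, sigma_meta):
    """P(interval 1 chosen) for perceived errors ``delta1``, ``delta2``.

    Equals the mass of Normal(delta1 - delta2, sigma_meta) below zero,
    i.e. ``ndtr(-(delta1 - delta2) / sigma_meta)``. At ``sigma_meta == 0``
    the deterministic limit applies: 1 if delta1 < delta2, 0 if
    delta1 > delta2, 0.5 at equality.
    """
    d = np.asarray(delta1, float) - np.asarray(delta2, float)
    sigma = np.asarray(sigma_meta, float)
    if np.any(sigma < 0):
        raise ValueError("sigma_meta must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(
            sigma > 0,
            ndtr(-d / np.where(sigma > 0, sigma, 1.0)),
            np.where(d < 0, 1.0, np.where(d > 0, 0.0, 0.5)),
        )
    if p.ndim == 0:
        return float(p)
    return p


def _truncated_normal(rng, mean, sd, low, high, size):
    """Normal draws truncated to [low, high] by resampling."""
    mean = np.broadcast_to(np.asarray(mean, float), size).copy()
    if np.all(sd == 0):
        return np.clip(mean, low, high)
    x = rng.normal(mean, sd, size=size)
    bad = (x < low) | (x > high)
    while bad.any():
        x[bad] = rng.normal(mean[bad] if mean.ndim else mean, sd, size=int(bad.sum()))
        bad = (x < low) | (x > high)
    return x


def simulate_session(
    obs: ObserverParams,
    condition: str = "V",
    total_duration: float = 1.5,
    schedule: ScheduleSpec | None = None,
    seed=None,
    signed_errors: bool = False,
) -> SessionDataset:
    """Simulate one full session (default 500 trials in blocks of 100).

    A fixed ``seed`` (or a ``numpy.random.Generator``) makes the output
    fully deterministic. ``signed_errors`` switches the metacognitive
    comparison from ``|I_k - phi|`` to the signed residuals, retained only
    for sensitivity analysis.
    """
    schedule = schedule or ScheduleSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.n_trials
    phi = obs.phi[condition]
    s1, s2 = obs.sigma_i1[condition], obs.sigma_i2[condition]
    sm = obs.sigma_meta[condition]

    t = np.arange(n, dtype=float)
    phi_eff = np.full(n, phi)
    if obs.drift is not None:
        offset, decay = obs.drift
        phi_eff = phi + offset * np.exp(-t / decay)

    i1 = _truncated_normal(rng, phi_eff, s1, 0.0, total_duration, n)
    i2 = _truncated_normal(rng, phi_eff, s2, 0.0, total_duration, n)
    if signed_errors:
        d1, d2 = i1 - phi_eff, i2 - phi_eff
    else:
        d1, d2 = np.abs(i1 - phi_eff), np.abs(i2 - phi_eff)
    p1 = np.asarray(choice_probability(d1, d2, sm))
    choice = np.where(rng.random(n) < p1, 1, 2)

    import pandas as pd

    frame = pd.DataFrame(
        {
            "subject_id": obs.subject_id,
            "condition": condition,
            "total_duration": float(total_duration),
            "trial_index": np.arange(1, n + 1),
            "estimate1": i1,
            "estimate2": i2,
            "meta_choice": choice,
            "feedback_correct": choice == ideal_choice(i1, i2, total_duration),
        }
    )
    return SessionDataset(frame, schedule).validate()


def simulate_trial(
    obs: ObserverParams,
    condition: str = "V",
    total_duration: float = 1.5,
    rng=None,
    trial_index: int = 1,
    signed_errors: bool = False,
) -> TrialRecord:
    """Simulate a single trial pair; see :func:`simulate_session`."""
    ds = simulate_session(
        obs,
        condition,
        total_duration,
        ScheduleSpec(n_trials=1, block_size=0),
        seed=rng,
        signed_errors=signed_errors,
    )
    rec = ds.records[0]
    return replace(rec, trial_index=trial_index)


def simulate_study(
    observers,
    conditions=CONDITIONS,
    total_duration: float = 1.5,
    schedule: ScheduleSpec | None = None,
    seed=None,
    signed_errors: bool = False,
) -> SessionDataset:
    """Simulate several observers across conditions into one tidy dataset."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = None
    for obs in observers:
        for cond in conditions:
            ds = simulate_session(
                obs, cond, total_duration, schedule, seed=rng,
                signed_errors=signed_errors,
            )
            out = ds if out is None else out.concat(ds)
    return out.validate()


def sample_observers(group: GroupParams, n_subjects: int, seed=None) -> list[ObserverParams]:
    """Draw observers from the group-level distribution.

    For each SD role the per-subject log-values across the conditions are
    multivariate normal with compound-symmetric correlation ``group.rho``,
    so precisions are coupled across modalities exactly as the hierarchical
    measurement model assumes; positivity is automatic on the log scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conds = list(group.phi)
    k = len(conds)
    corr = np.full((k, k), group.rho)
    np.fill_diagonal(corr, 1.0)
    cov = (group.sigma_spread ** 2) * corr
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("infeasible cross-condition covariance") from exc

    observers = []
    for s in range(n_subjects):
        phi = {
            c: float(
                _truncated_normal(rng, group.phi[c], group.phi_sd, 1e-6, np.inf, 1)[0]
            )
            for c in conds
        }
        sds = {}
        for name in ("sigma_i1", "sigma_i2", "sigma_meta"):
            mu = np.log([getattr(group, name)[c] for c in conds])
            z = mu + chol @ rng.standard_normal(k)
            sds[name] = dict(zip(conds, np.exp(z)))
        observers.append(
            ObserverParams(
                phi=phi,
                rho=group.rho,
                subject_id=f"S{s + 1:02d}",
                **sds,
            )
        )
    return observers
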