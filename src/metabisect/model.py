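"""Hierarchical Bayesian measurement model of bisection precision and
metacognitive precision.

The model treats each observer's two interval estimates per trial as
normal draws around a latent subjective midpoint and the second-order
choice as a Bernoulli whose probability is a probit in the difference of
the perceived absolute errors:

    I1 ~ Normal(phi, sigma_I1),  I2 ~ Normal(phi, sigma_I2)
    Delta_k = |I_k - phi|,  dDelta = Delta_1 - Delta_2
    p = P(Normal(dDelta, sigma_meta) < 0),  choice ~ Bernoulli(p)

All spreads are parameterised as precisions (1/sigma^2) with Uniform(0, 100)
group-level priors; subject-level log-precisions are coupled across the
modality conditions by a multivariate normal with a shared scale, a
subject-specific correlation rho, and an epsilon-regularised covariance
(epsilon = 0.1). Midpoints are themselves hierarchical: subject midpoints
around condition midpoints around a grand midpoint around the veridical
bisection point. The *constrained* variant forces each precision to be
equal across the modality conditions; comparing it to the *full* variant by
DIC asks whether modality genuinely moves bisection or metacognitive
precision. Each base-duration condition is fitted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._sampler import ROLES, BlockData, GibbsSampler
from .trials import CONDITIONS, SessionDataset
from .results import HierarchicalBisectionResults

__all__ = [
    "ModelSpec",
    "ModelParams",
    "InsufficientDataError",
    "log_likelihood",
    "HierarchicalBisectionModel",
    "compare_dic",
]

P_FLOOR = 1e-12  # Bernoulli probabilities are clamped to [floor, 1 - floor]


class InsufficientDataError(ValueError):
    """Too few trials (or an incomplete subject-condition grid) to fit."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of the measurement model."""

    variant: str = "full"  # or "constrained"
    true_mid: float | None = None  # defaults to total_duration / 2
    epsilon: float = 0.1
    prior_precision_upper: float = 100.0
    scale_upper: float = 10.0
    signed_errors: bool = False

    def __post_init__(self):
        if self.variant not in ("full", "constrained"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not self.prior_precision_upper > 0:
            raise ValueError("prior precision range must be positive")


@dataclass(frozen=True)
class ModelParams:
    """A single point in parameter space, for likelihood evaluation.

    Each mapping is keyed by ``(subject_id, condition)``.
    """

    phi: dict
    sigma_i1: dict
    sigma_i2: dict
    sigma_meta: dict


def log_likelihood(
    data: SessionDataset,
    params: ModelParams,
    signed_errors: bool = False,
    p_floor: float = P_FLOOR,
) -> float:
    """Total data log-likelihood at ``params``.

    Sums, over trials, the two normal log-densities of the interval
    estimates and the Bernoulli log-mass of the metacognitive choice under
    the probit choice probability. Probabilities are clamped at ``p_floor``
    (a choice that the model deems impossible contributes ``log(p_floor)``
    rather than ``-inf``; a warning is emitted when the clamp engages).
    """
    f = data.frame
    total = 0.0
    clamped = 0
    for (sid, cond), g in f.groupby(["subject_id", "condition"], sort=False):
        key = (sid, cond)
        phi = params.phi[key]
        s1, s2 = params.sigma_i1[key], params.sigma_i2[key]
        sm = params.sigma_meta[key]
        i1 = g["estimate1"].to_numpy(float)
        i2 = g["estimate2"].to_numpy(float)
        y1 = g["meta_choice"].to_numpy(int) == 1
        for x, sd in ((i1, s1), (i2, s2)):
            z = (x - phi) / sd
            total += float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * np.log(2 * np.pi)))
        if signed_errors:
            dd = i1 - i2
        else:
            dd = np.abs(i1 - phi) - np.abs(i2 - phi)
        p = ndtr(-dd / sm)
        clipped = np.clip(p, p_floor, 1.0 - p_floor)
        clamped += int(np.sum(clipped != p))
        total += float(np.log(clipped[y1]).sum() + np.log1p(-clipped[~y1]).sum())
    if clamped:
        warnings.warn(
            f"{clamped} Bernoulli probabilities clamped at the {p_floor} floor"
        )
    return total


class HierarchicalBisectionModel:
    """Hierarchical model of one duration condition's trial data.

    Parameters
    ----------
    data : SessionDataset or DataFrame
        Trials of a *single* total duration, for one or more subjects with
        a complete subject x modality-condition grid.
    spec : ModelSpec, optional
        Structural settings; keyword arguments override its fields.

    Examples
    --------
    >>> model = HierarchicalBisectionModel(dataset, variant="full")
    >>> res = model.fit(seed=1)
    >>> res.summary().head()
    """

    def __init__(self, data, spec: ModelSpec | None = None, **kwargs):
        if spec is None:
            spec = ModelSpec(**kwargs)
        elif kwargs:
            raise TypeError("pass either spec or keyword overrides, not both")
        if isinstance(data, pd.DataFrame):
            data = SessionDataset(data.reset_index(drop=True))
            data._recompute_feedback()
        data.validate()
        f = data.frame
        if len(f) == 0:
            raise InsufficientDataError("empty dataset")
        durations = f["total_duration"].unique()
        if len(durations) > 1:
            raise InsufficientDataError(
                "data span multiple total durations; fit each separately "
                "(see HierarchicalBisectionModel.per_duration)"
            )
        self.total_duration = float(durations[0])
        self.spec = spec
        self.true_mid = (
            spec.true_mid if spec.true_mid is not None else self.total_duration / 2.0
        )
        self.data = data

        self.subjects = sorted(f["subject_id"].unique())
        present = set(f["condition"].unique())
        self.conditions = [c for c in CONDITIONS if c in present] + sorted(
            present - set(CONDITIONS)
        )
        self._blocks = []
        for sid in self.subjects:
            row = []
            for cond in self.conditions:
                g = f[(f["subject_id"] == sid) & (f["condition"] == cond)]
                if len(g) < 2:
                    raise InsufficientDataError(
                        f"subject {sid!r} condition {cond!r} has {len(g)} trial(s); "
                        "need at least 2 per subject-condition"
                    )
                row.append(
                    BlockData(
                        g["estimate1"].to_numpy(float),
                        g["estimate2"].to_numpy(float),
                        g["meta_choice"].to_numpy(int),
                    )
                )
            self._blocks.append(row)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs):
        return cls(frame, **kwargs)

    @classmethod
    def per_duration(cls, data: SessionDataset, **kwargs):
        """One model per base duration present in the data."""
        f = data.frame if isinstance(data, SessionDataset) else data
        return {
            float(d): cls(data.subset(total_duration=d), **kwargs)
            for d in sorted(f["total_duration"].unique())
        }

    def fit(
        self,
        n_chains: int = 2,
        burn_in: int = 2000,
        samples: int = 5000,
        thin: int = 20,
        seed=None,
        rhat_threshold: float = 1.05,
    ) -> HierarchicalBisectionResults:
        """Sample the posterior by adaptive Metropolis-within-Gibbs.

        Defaults mirror the reference analysis (2 chains, 2000 burn-in,
        5000 sampling iterations thinned by 20). Non-convergence
        (max split-R-hat above ``rhat_threshold``) flags the result and
        emits a warning rather than failing silently.
        """
        if n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if samples < 2 * thin:
            raise ValueError("too few sampling iterations for the chosen thinning")
        sampler = GibbsSampler(
            self._blocks,
            true_mid=self.true_mid,
            variant=self.spec.variant,
            epsilon=self.spec.epsilon,
            tau_upper=self.spec.prior_precision_upper,
            scale_upper=self.spec.scale_upper,
            signed_errors=self.spec.signed_errors,
            p_floor=P_FLOOR,
        )
        draws, loglik = sampler.run(
            n_chains=n_chains, burn_in=burn_in, samples=samples, thin=thin, seed=seed
        )
        return HierarchicalBisectionResults(
            model=self,
            draws=draws,
            loglik=loglik,
            n_chains=n_chains,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            rhat_threshold=rhat_threshold,
        )

    # roles exposed for results naming
    roles = ROLES


def compare_dic(
    data,
    variants=("full", "constrained"),
    convention: str = "literal",
    seed=None,
    spec_kwargs: dict | None = None,
    **fit_kwargs,
):
    """Fit each model variant to the same data and compare by DIC.

    Returns ``{variant: (results, DICResult)}``; the variant with the
    smallest DIC is preferred.
    """
    out = {}
    ss = np.random.SeedSequence(seed)
    for variant, child in zip(variants, ss.spawn(len(variants))):
        model = HierarchicalBisectionModel(
            data, variant=variant, **(spec_kwargs or {})
        )
        res = model.fit(seed=child, **fit_kwargs)
        out[variant] = (res, res.dic(convention=convention))
    return out
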