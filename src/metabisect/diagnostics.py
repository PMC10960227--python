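"""Posterior diagnostics: convergence, interval summaries, and DIC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["rhat", "hdi", "DICResult", "dic_from_loglik"]


def rhat(chains) -> float:
    """Rank-normalized split Gelman-Rubin potential scale reduction.

    Parameters
    ----------
    chains : array-like, shape (n_chains, n_draws)
        Post-warmup draws of one scalar parameter.

    Values near 1 indicate that the chains have mixed; by convention values
    above ~1.05 are treated as non-convergence.
    """
    x = np.atleast_2d(np.asarray(chains, float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 draws per chain")
    if np.allclose(x.var(axis=1), 0.0):
        raise ValueError("zero within-chain variance: diagnostic undefined")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.rhat(az.convert_to_dataset(x))["x"].values))


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Computed by scanning every window of ``ceil(mass * n)`` consecutive
    order statistics and keeping the narrowest, which is exact for unimodal
    posteriors and the standard empirical HDI otherwise.
    """
    x = np.sort(np.asarray(samples, float).ravel())
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass(frozen=True)
class DICResult:
    """Deviance summaries for one fitted model variant.

    ``dbar`` is the posterior mean deviance, ``p_d`` the effective number
    of parameters, and ``dic`` their penalised combination; smaller DIC is
    preferred in model comparison.
    """

    dbar: float
    p_d: float
    dic: float
    convention: str


def dic_from_loglik(loglik_draws, convention: str = "literal") -> DICResult:
    """Deviance Information Criterion from per-draw total log-likelihoods.

    ``convention`` selects the composition (always with
    p_D = 2 var[log L], the variance-based effective-parameter count):

    - ``"literal"``: DIC = D-bar + 2 p_D — the double-penalty composition
      some published analyses of this paradigm use, kept as the default
      for comparability with them;
    - ``"spiegelhalter"`` / ``"gelman"``: the standard DIC = D-bar + p_D.

    Only relative ordering between model variants matters for selection,
    and it is unaffected by the choice whenever the same convention is used
    on both sides.
    """
    ll = np.asarray(loglik_draws, float).ravel()
    if len(ll) < 2:
        raise ValueError("need at least 2 posterior draws")
    dbar = float(np.mean(-2.0 * ll))
    p_d = float(2.0 * np.var(ll, ddof=1))
    if convention == "literal":
        dic = dbar + 2.0 * p_d
    elif convention in ("spiegelhalter", "gelman"):
        dic = dbar + p_d
    else:
        raise ValueError(f"unknown DIC convention {convention!r}")
    return DICResult(dbar=dbar, p_d=p_d, dic=dic, convention=convention)
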