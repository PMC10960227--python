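"""Posterior results container for the hierarchical bisection model."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diagnostics import dic_from_loglik, hdi as _hdi, rhat as _rhat
from .trials import ScheduleSpec

__all__ = ["HierarchicalBisectionResults"]


class HierarchicalBisectionResults:
    """MCMC draws over all model parameters, with diagnostics and summaries.

    Parameters are exposed under readable names on the SD scale
    (precisions transformed to sigma = 1/sqrt(tau)):

    - ``phi_overall``, ``phi_cond[V]``, ``phi_subj[S01,V]`` — midpoints (s)
    - ``sigma_mid``, ``sigma_phi``, ``sigma_subj`` — midpoint-layer spreads
    - ``sigma[I1,S01,V]`` etc. — subject-level likelihood SDs per role
      (``I1``, ``I2``, ``meta``); the condition label is ``all`` in the
      constrained variant
    - ``group_sigma[I1,V]`` — group-level SDs, ``1/sqrt(mu_tau)``
    - ``scale`` — spread of subject log-precisions; ``rho[S01]`` — subject
      cross-condition correlations (full variant only)
    """

    def __init__(self, model, draws, loglik, n_chains, burn_in, thin, seed,
                 rhat_threshold=1.05):
        self.model = model
        self._draws = draws
        self.loglik = loglik
        self.n_chains = n_chains
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self._params = self._name_parameters()
        self._rhat_cache = None
        if self.max_rhat > rhat_threshold:
            warnings.warn(
                f"chains may not have converged: max R-hat = {self.max_rhat:.4f} "
                f"> {rhat_threshold}",
                stacklevel=2,
            )

    # -- naming ------------------------------------------------------------

    def _name_parameters(self) -> dict[str, np.ndarray]:
        m, d = self.model, self._draws
        subs, conds = m.subjects, m.conditions
        full = m.spec.variant == "full"
        lam_conds = conds if full else ["all"]
        p: dict[str, np.ndarray] = {"phi_overall": d["mu0"]}
        for ci, c in enumerate(conds):
            p[f"phi_cond[{c}]"] = d["muc"][:, :, ci]
        for si, s in enumerate(subs):
            for ci, c in enumerate(conds):
                p[f"phi_subj[{s},{c}]"] = d["mus"][:, :, si, ci]
        for name, key in (("sigma_mid", "tau_mid"), ("sigma_phi", "tau_phi"),
                          ("sigma_subj", "tau_sub")):
            p[name] = 1.0 / np.sqrt(d[key])
        for si, s in enumerate(subs):
            for ci, c in enumerate(lam_conds):
                for ri, r in enumerate(m.roles):
                    p[f"sigma[{r},{s},{c}]"] = np.exp(-0.5 * d["lam"][:, :, si, ci, ri])
        for ci, c in enumerate(lam_conds):
            for ri, r in enumerate(m.roles):
                p[f"group_sigma[{r},{c}]"] = 1.0 / np.sqrt(d["mu_tau"][:, :, ci, ri])
        p["scale"] = d["scale"]
        if full:
            for si, s in enumerate(subs):
                p[f"rho[{s}]"] = d["rho"][:, :, si]
        return p

    # -- basic access ------------------------------------------------------

    @property
    def parameter_names(self) -> list[str]:
        return list(self._params)

    def get(self, name: str, flat: bool = True) -> np.ndarray:
        """Draws of one named parameter; shape (n,) or (chains, draws)."""
        x = self._params[name]
        return x.reshape(-1) if flat else x

    @property
    def n_draws(self) -> int:
        return int(self.loglik.size)

    # -- diagnostics -------------------------------------------------------

    @property
    def rhat(self) -> dict[str, float]:
        """Rank-normalized split R-hat per named parameter."""
        if self._rhat_cache is None:
            self._rhat_cache = {
                k: _rhat(v) for k, v in self._params.items()
            }
        return self._rhat_cache

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat <= self.rhat_threshold

    def hdi(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        return _hdi(self.get(name), mass)

    @property
    def hdi95(self) -> dict[str, tuple[float, float]]:
        return {k: self.hdi(k) for k in self._params}

    # -- summaries ---------------------------------------------------------

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        """Tidy per-parameter table: mean, sd, HDI bounds, R-hat."""
        rows = []
        rh = self.rhat
        for name in self._params:
            x = self.get(name)
            lo, hi = self.hdi(name, mass)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)),
                    "hdi_low": lo,
                    "hdi_high": hi,
                    "rhat": rh[name],
                }
            )
        return pd.DataFrame(rows)

    def dic(self, convention: str = "literal"):
        """Deviance Information Criterion of this fit (smaller preferred)."""
        return dic_from_loglik(self.loglik, convention=convention)

    def summarize_midpoints(self, relative: bool = False, mass: float = 0.95) -> pd.DataFrame:
        """Posterior midpoint summaries per condition, overall, and subject.

        ``relative=True`` rescales by the total duration, so 0.5 marks
        veridical bisection.
        """
        m = self.model
        scale = 1.0 / m.total_duration if relative else 1.0
        rows = []

        def add(level, label, x):
            x = x * scale
            lo, hi = _hdi(x, mass)
            rows.append(
                {"level": level, "label": label, "mean": float(x.mean()),
                 "hdi_low": lo, "hdi_high": hi}
            )

        cond_stack = []
        for c in m.conditions:
            x = self.get(f"phi_cond[{c}]")
            cond_stack.append(self._params[f"phi_cond[{c}]"])
            add("condition", c, x)
        add("group", "overall", np.mean(cond_stack, axis=0).reshape(-1))
        for s in m.subjects:
            for c in m.conditions:
                add("subject", f"{s},{c}", self.get(f"phi_subj[{s},{c}]"))
        return pd.DataFrame(rows)

    # -- posterior predictive ---------------------------------------------

    def posterior_predictive_mci(
        self,
        n_trials: int = 100,
        seed=None,
        max_draws: int | None = None,
        mass: float = 0.95,
    ) -> dict:
        """Posterior-predictive Metacognitive Index per modality condition.

        For each retained draw, a fresh session of ``n_trials`` trial pairs
        is simulated for every subject and condition at that draw's
        subject-level parameters; the MCI is computed exactly as for data
        and averaged across subjects. Returns, per condition, the draw-wise
        group MCI values, their HDI, and the count of draws dropped for
        degenerate variances.
        """
        from .descriptives import DegenerateVarianceError, mci_from_dataset
        from .simulate import ObserverParams, simulate_session

        m = self.model
        full = m.spec.variant == "full"
        rng = np.random.default_rng(seed)
        d = self._draws
        nch, nd = d["mu0"].shape
        idx = [(ch, i) for ch in range(nch) for i in range(nd)]
        if max_draws is not None and max_draws < len(idx):
            sel = rng.choice(len(idx), size=max_draws, replace=False)
            idx = [idx[i] for i in sorted(sel)]
        schedule = ScheduleSpec(n_trials=n_trials, block_size=0)

        out = {c: [] for c in m.conditions}
        dropped = {c: 0 for c in m.conditions}
        for ch, i in idx:
            lam = d["lam"][ch, i]
            mus = d["mus"][ch, i]
            per_cond = {c: [] for c in m.conditions}
            for si, sid in enumerate(m.subjects):
                for ci, c in enumerate(m.conditions):
                    ce = ci if full else 0
                    sig = np.exp(-0.5 * lam[si, ce])
                    obs = ObserverParams(
                        phi={c: float(mus[si, ci])},
                        sigma_i1={c: float(sig[0])},
                        sigma_i2={c: float(sig[1])},
                        sigma_meta={c: float(sig[2])},
                        rho=float(d["rho"][ch, i, si]) if full else 0.0,
                        subject_id=sid,
                    )
                    ds = simulate_session(
                        obs, c, m.total_duration, schedule, seed=rng,
                        signed_errors=m.spec.signed_errors,
                    )
                    try:
                        per_cond[c].append(mci_from_dataset(ds, m.true_mid).mci)
                    except DegenerateVarianceError:
                        dropped[c] += 1
            for c in m.conditions:
                if per_cond[c]:
                    out[c].append(float(np.mean(per_cond[c])))
        result = {}
        for c in m.conditions:
            x = np.asarray(out[c])
            result[c] = {
                "draws": x,
                "median": float(np.median(x)) if len(x) else np.nan,
                "hdi": _hdi(x, mass) if len(x) > 1 else (np.nan, np.nan),
                "dropped": dropped[c],
            }
        return result

    # -- persistence and plotting -----------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """All draws as a tidy DataFrame (chain, draw, one column/parameter)."""
        nch, nd = self._draws["mu0"].shape
        cols = {
            "chain": np.repeat(np.arange(nch), nd),
            "draw": np.tile(np.arange(nd), nch),
            "loglik": self.loglik.reshape(-1),
        }
        for name, x in self._params.items():
            cols[name] = x.reshape(-1)
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        """Persist draws as CSV (readable back with pandas)."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def plot_posterior(self, names=None, ax=None):
        """Histogram panels of posterior draws for the given parameters."""
        import matplotlib.pyplot as plt

        if names is None:
            names = [n for n in self._params if n.startswith("group_sigma")]
        if isinstance(names, str):
            names = [names]
        if ax is None:
            fig, axes = plt.subplots(
                1, len(names), figsize=(3 * len(names), 2.5), squeeze=False
            )
            axes = axes[0]
        else:
            axes = [ax]
        for a, name in zip(axes, names):
            x = self.get(name)
            a.hist(x, bins=40, density=True)
            lo, hi = self.hdi(name)
            a.axvline(lo, ls="--", lw=0.8)
            a.axvline(hi, ls="--", lw=0.8)
            a.set_title(name, fontsize=8)
        return axes[0].figure
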