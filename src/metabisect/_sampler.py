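"""Metropolis-within-Gibbs engine for the hierarchical bisection model.

The posterior factorises over (subject, condition) data blocks; each block
contributes two normal likelihoods (the interval estimates) and one
Bernoulli-probit likelihood (the metacognitive choice). Midpoint
hyperparameters and the precision hyperpriors have conjugate normal/gamma
conditionals and are Gibbs-updated; everything else uses componentwise
random-walk Metropolis with per-parameter step sizes adapted during burn-in
(target acceptance ~0.44) and frozen afterwards.

Parameterisation (one duration condition; S subjects, C modality
conditions, roles r in {I1, I2, meta}):

- ``mu0``            grand subjective midpoint, prior Normal(true_mid, 1/sqrt(tau_mid))
- ``muc[c]``         condition midpoints, Normal(mu0, 1/sqrt(tau_phi))
- ``mus[s, c]``      subject midpoints, Normal(muc[c], 1/sqrt(tau_sub))
- ``tau_mid/phi/sub`` Uniform(0, tau_upper) precisions of the midpoint layers
- ``lam[s, c, r]``   log-precision of the likelihood SD; per subject and
  role the vector across conditions is multivariate normal around
  ``log(mu_tau[:, r])`` with compound-symmetric covariance
  ``scale^2 * R(rho[s]) + eps * I`` (full variant), or a single shared
  value per role with Normal(log mu_tau[r], sqrt(scale^2 + eps))
  (constrained variant)
- ``mu_tau[c, r]``   group-level precisions, Uniform(0, tau_upper)
- ``scale``          shared spread of subject log-precisions, Uniform(0, scale_upper)
- ``rho[s]``         subject-specific cross-condition correlation, Uniform(0, 1)
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from scipy import stats as sp_stats

LOG2PI = float(np.log(2.0 * np.pi))

ROLES = ("I1", "I2", "meta")


def _norm_lp(x, m, tau):
    return 0.5 * (np.log(tau) - LOG2PI) - 0.5 * tau * (x - m) ** 2


def _cs_mvn_lp(d, k, scale2, rho, eps):
    """Log-density (up to none) of MVN(0, scale2*R(rho) + eps*I) at vector d.

    R(rho) is the compound-symmetric correlation matrix; the closed form
    uses its two distinct eigenvalues.
    """
    a = scale2 * (1.0 - rho) + eps  # off-spectrum eigenvalue direction
    b = scale2 * rho
    apkb = a + k * b
    logdet = (k - 1) * np.log(a) + np.log(apkb)
    ssum = float(np.sum(d))
    quad = float(np.dot(d, d)) / a - b * ssum * ssum / (a * apkb)
    return -0.5 * (k * LOG2PI + logdet + quad)


def _trunc_gamma(rng, shape, rate, upper):
    """One draw from Gamma(shape, rate) truncated to (0, upper)."""
    rate = max(rate, 1e-300)
    f_up = sp_stats.gamma.cdf(upper, shape, scale=1.0 / rate)
    if f_up > 1e-12:
        u = rng.uniform(0.0, f_up)
        x = float(sp_stats.gamma.ppf(u, shape, scale=1.0 / rate))
        return min(max(x, 1e-12), upper)
    # Essentially no gamma mass below `upper`: the truncated density is
    # dominated by the x^(shape-1) factor; sample the power law and
    # correct the (mild) exponential tilt by rejection.
    while True:
        x = upper * rng.uniform() ** (1.0 / shape)
        if np.log(rng.uniform()) < -rate * x:
            return float(x)


class BlockData:
    """Sufficient statistics and raw arrays for one (subject, condition)."""

    __slots__ = ("n", "s1", "ss1", "s2", "ss2", "i1", "i2", "y1")

    def __init__(self, i1, i2, choice):
        self.i1 = np.asarray(i1, float)
        self.i2 = np.asarray(i2, float)
        self.y1 = np.asarray(choice, int) == 1
        self.n = len(self.i1)
        self.s1 = float(self.i1.sum())
        self.ss1 = float(np.dot(self.i1, self.i1))
        self.s2 = float(self.i2.sum())
        self.ss2 = float(np.dot(self.i2, self.i2))


class GibbsSampler:
    def __init__(
        self,
        blocks,  # nested list [s][c] of BlockData
        true_mid: float,
        variant: str = "full",
        epsilon: float = 0.1,
        tau_upper: float = 100.0,
        scale_upper: float = 10.0,
        signed_errors: bool = False,
        p_floor: float = 1e-12,
    ):
        self.blocks = blocks
        self.S = len(blocks)
        self.C = len(blocks[0])
        self.true_mid = float(true_mid)
        if variant not in ("full", "constrained"):
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.Ceff = self.C if variant == "full" else 1
        self.eps = float(epsilon)
        self.tau_upper = float(tau_upper)
        self.scale_upper = float(scale_upper)
        self.signed = bool(signed_errors)
        self.p_floor = float(p_floor)

    # -- likelihood pieces -------------------------------------------------

    def _ll_norm(self, blk, which, phi, lam):
        if which == 0:
            s, ss = blk.s1, blk.ss1
        else:
            s, ss = blk.s2, blk.ss2
        q = ss - 2.0 * phi * s + blk.n * phi * phi
        return 0.5 * blk.n * (lam - LOG2PI) - 0.5 * np.exp(lam) * q

    def _dd(self, blk, phi):
        if self.signed:
            return blk.i1 - blk.i2
        return np.abs(blk.i1 - phi) - np.abs(blk.i2 - phi)

    def _ll_meta(self, dd, lam, y1):
        p = ndtr(-dd * np.exp(0.5 * lam))
        p = np.clip(p, self.p_floor, 1.0 - self.p_floor)
        return float(np.log(p[y1]).sum() + np.log1p(-p[~y1]).sum())

    # -- state -------------------------------------------------------------

    def _lam_index(self, c):
        return c if self.variant == "full" else 0

    def init_state(self, rng, jitter=0.05):
        S, C = self.S, self.C
        mus = np.empty((S, C))
        lam = np.empty((S, self.Ceff, 3))
        lam_acc = np.zeros((S, self.Ceff, 3))
        lam_cnt = np.zeros((S, self.Ceff, 3))
        for s in range(S):
            for c in range(C):
                blk = self.blocks[s][c]
                both = np.concatenate([blk.i1, blk.i2])
                mus[s, c] = both.mean()
        for s in range(S):
            for ce in range(self.Ceff):
                cs = [ce] if self.variant == "full" else range(C)
                v1 = np.mean([max(np.var(self.blocks[s][c].i1), 1e-4) for c in cs])
                v2 = np.mean([max(np.var(self.blocks[s][c].i2), 1e-4) for c in cs])
                lam[s, ce, 0] = -np.log(v1)
                lam[s, ce, 1] = -np.log(v2)
                lam[s, ce, 2] = np.log(4.0)  # sigma_meta ~ 0.5 s to start
        mus += rng.normal(0.0, jitter * 0.1, mus.shape)
        lam += rng.normal(0.0, jitter * 4.0, lam.shape)
        muc = mus.mean(axis=0) + rng.normal(0.0, jitter * 0.1, C)
        mu0 = float(muc.mean() + rng.normal(0.0, jitter * 0.1))
        mu_tau = np.clip(np.exp(lam).mean(axis=0), 0.5, 0.9 * self.tau_upper)
        state = {
            "mu0": mu0,
            "muc": muc,
            "mus": mus,
            "tau_mid": 25.0 * np.exp(rng.normal(0.0, jitter)),
            "tau_phi": 25.0 * np.exp(rng.normal(0.0, jitter)),
            "tau_sub": 25.0 * np.exp(rng.normal(0.0, jitter)),
            "lam": lam,
            "mu_tau": mu_tau,
            "scale": 0.5 * np.exp(rng.normal(0.0, jitter)),
            "rho": np.clip(0.5 + rng.normal(0.0, jitter, self.S), 0.05, 0.95),
        }
        steps = {
            "mus": np.full((S, C), 0.01),
            "lam": np.full((S, self.Ceff, 3), 0.15),
            "mu_tau": np.full((self.Ceff, 3), 0.3),
            "shift": np.full((self.Ceff, 3), 0.25),
            "scale": np.array(0.3),
            "rho": np.full(S, 0.15),
        }
        self._acc = {k: np.zeros_like(v) for k, v in steps.items()}
        self._cnt = {k: np.zeros_like(v) for k, v in steps.items()}
        # likelihood caches
        ll = np.empty((S, C, 3))
        dd = [[None] * C for _ in range(S)]
        for s in range(S):
            for c in range(C):
                blk = self.blocks[s][c]
                ce = self._lam_index(c)
                ll[s, c, 0] = self._ll_norm(blk, 0, mus[s, c], lam[s, ce, 0])
                ll[s, c, 1] = self._ll_norm(blk, 1, mus[s, c], lam[s, ce, 1])
                dd[s][c] = self._dd(blk, mus[s, c])
                ll[s, c, 2] = self._ll_meta(dd[s][c], lam[s, ce, 2], blk.y1)
        self._ll = ll
        self._ddc = dd
        return state, steps

    # -- priors ------------------------------------------------------------

    def _lp_lam_subject_role(self, state, s, r, lam_vec=None, rho=None, scale=None):
        lam = state["lam"][s, :, r] if lam_vec is None else lam_vec
        mu = np.log(state["mu_tau"][:, r])
        scale = state["scale"] if scale is None else scale
        if self.variant == "full":
            rho_s = state["rho"][s] if rho is None else rho
            return _cs_mvn_lp(lam - mu, self.C, scale * scale, rho_s, self.eps)
        v = scale * scale + self.eps
        d = lam - mu
        return float(np.sum(-0.5 * (LOG2PI + np.log(v) + d * d / v)))

    # -- MH helpers ----------------------------------------------------------

    def _mh(self, key, idx, logratio, rng):
        self._cnt[key][idx] += 1
        if np.log(rng.uniform()) < logratio:
            self._acc[key][idx] += 1
            return True
        return False

    def _adapt(self, steps):
        for k, step in steps.items():
            cnt = self._cnt[k]
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(cnt > 0, self._acc[k] / np.maximum(cnt, 1), 0.44)
            np.multiply(step, np.exp(0.66 * (rate - 0.44)), out=step, casting="unsafe")
            np.clip(step, 1e-4, 10.0, out=step)
            self._acc[k][...] = 0.0
            self._cnt[k][...] = 0.0

    # -- one sweep -----------------------------------------------------------

    def sweep(self, state, steps, rng):
        S, C = self.S, self.C
        mus, lam = state["mus"], state["lam"]
        ll, ddc = self._ll, self._ddc

        # subject midpoints (MH; all three likelihood components move)
        for s in range(S):
            for c in range(C):
                blk = self.blocks[s][c]
                cur = mus[s, c]
                prop = cur + rng.normal(0.0, steps["mus"][s, c])
                ce = self._lam_index(c)
                lp_cur = _norm_lp(cur, state["muc"][c], state["tau_sub"]) + ll[s, c].sum()
                dd_new = self._dd(blk, prop)
                new0 = self._ll_norm(blk, 0, prop, lam[s, ce, 0])
                new1 = self._ll_norm(blk, 1, prop, lam[s, ce, 1])
                new2 = self._ll_meta(dd_new, lam[s, ce, 2], blk.y1)
                lp_new = _norm_lp(prop, state["muc"][c], state["tau_sub"]) + new0 + new1 + new2
                if self._mh("mus", (s, c), lp_new - lp_cur, rng):
                    mus[s, c] = prop
                    ll[s, c, 0], ll[s, c, 1], ll[s, c, 2] = new0, new1, new2
                    ddc[s][c] = dd_new

        # log-precisions (MH per scalar; prior couples the role vector)
        for s in range(S):
            for ce in range(self.Ceff):
                targets = [ce] if self.variant == "full" else list(range(C))
                for r in range(3):
                    cur = lam[s, ce, r]
                    # mixture proposal: occasional 5x jumps help traverse the
                    # heavy upper tail of weakly identified meta precisions
                    width = steps["lam"][s, ce, r] * (5.0 if rng.uniform() < 0.1 else 1.0)
                    prop = cur + rng.normal(0.0, width)
                    lam_vec = lam[s, :, r].copy()
                    lam_vec[ce] = prop
                    dprior = self._lp_lam_subject_role(
                        state, s, r, lam_vec=lam_vec
                    ) - self._lp_lam_subject_role(state, s, r)
                    news, dll = [], 0.0
                    for c in targets:
                        blk = self.blocks[s][c]
                        if r < 2:
                            new = self._ll_norm(blk, r, mus[s, c], prop)
                        else:
                            new = self._ll_meta(ddc[s][c], prop, blk.y1)
                        news.append(new)
                        dll += new - ll[s, c, r]
                    if self._mh("lam", (s, ce, r), dprior + dll, rng):
                        lam[s, ce, r] = prop
                        for c, new in zip(targets, news):
                            ll[s, c, r] = new

        # group-level precisions (MH on log scale, uniform prior on (0, upper))
        for ce in range(self.Ceff):
            for r in range(3):
                cur = state["mu_tau"][ce, r]
                prop = cur * np.exp(rng.normal(0.0, steps["mu_tau"][ce, r]))
                if 0.0 < prop < self.tau_upper:
                    mu_new = state["mu_tau"].copy()
                    mu_new[ce, r] = prop
                    old = sum(self._lp_lam_subject_role(state, s, r) for s in range(S))
                    saved = state["mu_tau"]
                    state["mu_tau"] = mu_new
                    new = sum(self._lp_lam_subject_role(state, s, r) for s in range(S))
                    state["mu_tau"] = saved
                    # log-scale proposal: Jacobian term log(prop/cur)
                    if self._mh("mu_tau", (ce, r), new - old + np.log(prop / cur), rng):
                        state["mu_tau"] = mu_new
                else:
                    self._cnt["mu_tau"][ce, r] += 1

        # joint shift of a group precision with all its subject log-precisions
        # (the prior depends only on lam - log mu_tau, so this move crosses
        # the hierarchical ridge that componentwise updates walk slowly)
        for ce in range(self.Ceff):
            targets = [ce] if self.variant == "full" else list(range(C))
            for r in range(3):
                delta = rng.normal(0.0, steps["shift"][ce, r])
                mt_new = state["mu_tau"][ce, r] * np.exp(delta)
                if not 0.0 < mt_new < self.tau_upper:
                    self._cnt["shift"][ce, r] += 1
                    continue
                news, dll = [], 0.0
                for s in range(S):
                    prop = lam[s, ce, r] + delta
                    for c in targets:
                        blk = self.blocks[s][c]
                        if r < 2:
                            new = self._ll_norm(blk, r, mus[s, c], prop)
                        else:
                            new = self._ll_meta(ddc[s][c], prop, blk.y1)
                        news.append((s, c, new))
                        dll += new - ll[s, c, r]
                if self._mh("shift", (ce, r), dll + delta, rng):
                    lam[:, ce, r] += delta
                    state["mu_tau"][ce, r] = mt_new
                    for s, c, new in news:
                        ll[s, c, r] = new

        # shared spread of subject log-precisions
        cur = float(state["scale"])
        prop = cur * np.exp(rng.normal(0.0, float(steps["scale"])))
        if 0.0 < prop < self.scale_upper:
            old = sum(
                self._lp_lam_subject_role(state, s, r)
                for s in range(S) for r in range(3)
            )
            new = sum(
                self._lp_lam_subject_role(state, s, r, scale=prop)
                for s in range(S) for r in range(3)
            )
            if self._mh("scale", (), new - old + np.log(prop / cur), rng):
                state["scale"] = prop
        else:
            self._cnt["scale"][()] += 1

        # subject correlations (full variant only)
        if self.variant == "full":
            for s in range(S):
                cur = state["rho"][s]
                prop = cur + rng.normal(0.0, steps["rho"][s])
                if 0.0 <= prop <= 1.0:
                    old = sum(self._lp_lam_subject_role(state, s, r) for r in range(3))
                    new = sum(
                        self._lp_lam_subject_role(state, s, r, rho=prop)
                        for r in range(3)
                    )
                    if self._mh("rho", (s,), new - old, rng):
                        state["rho"][s] = prop
                else:
                    self._cnt["rho"][(s,)] += 1

        # conjugate Gibbs: condition midpoints, grand midpoint
        tau_phi, tau_sub, tau_mid = state["tau_phi"], state["tau_sub"], state["tau_mid"]
        for c in range(C):
            tpost = tau_phi + S * tau_sub
            mean = (tau_phi * state["mu0"] + tau_sub * mus[:, c].sum()) / tpost
            state["muc"][c] = rng.normal(mean, 1.0 / np.sqrt(tpost))
        tpost = tau_mid + C * tau_phi
        mean = (tau_mid * self.true_mid + tau_phi * state["muc"].sum()) / tpost
        state["mu0"] = rng.normal(mean, 1.0 / np.sqrt(tpost))

        # conjugate Gibbs: truncated-gamma precisions of the midpoint layers
        d = mus - state["muc"][None, :]
        state["tau_sub"] = _trunc_gamma(
            rng, 1.0 + 0.5 * S * C, 0.5 * float(np.sum(d * d)), self.tau_upper
        )
        d = state["muc"] - state["mu0"]
        state["tau_phi"] = _trunc_gamma(
            rng, 1.0 + 0.5 * C, 0.5 * float(np.sum(d * d)), self.tau_upper
        )
        d = state["mu0"] - self.true_mid
        state["tau_mid"] = _trunc_gamma(
            rng, 1.5, 0.5 * d * d, self.tau_upper
        )

    def total_loglik(self):
        return float(self._ll.sum())

    # -- driver --------------------------------------------------------------

    def run(self, n_chains=2, burn_in=2000, samples=5000, thin=20, seed=None,
            jitter=0.05):
        """Run ``n_chains`` independent chains; returns (draws, loglik).

        ``draws`` maps state-array names to arrays of shape
        ``(n_chains, n_retained, ...)``; ``loglik`` holds the total data
        log-likelihood at each retained draw.
        """
        if isinstance(seed, np.random.SeedSequence):
            ss = seed
        else:
            ss = np.random.SeedSequence(seed)
        chain_seeds = ss.spawn(n_chains)
        keys = ("mu0", "muc", "mus", "tau_mid", "tau_phi", "tau_sub",
                "lam", "mu_tau", "scale", "rho")
        all_draws, all_ll = [], []
        for ch in range(n_chains):
            rng = np.random.default_rng(chain_seeds[ch])
            state, steps = self.init_state(rng, jitter=jitter)
            retained = {k: [] for k in keys}
            lls = []
            for it in range(burn_in + samples):
                self.sweep(state, steps, rng)
                if it < burn_in:
                    if (it + 1) % 25 == 0:
                        self._adapt(steps)
                elif (it - burn_in) % thin == 0:
                    for k in keys:
                        v = state[k]
                        retained[k].append(
                            v.copy() if isinstance(v, np.ndarray) else float(v)
                        )
                    lls.append(self.total_loglik())
            all_draws.append({k: np.asarray(v) for k, v in retained.items()})
            all_ll.append(np.asarray(lls))
        draws = {k: np.stack([d[k] for d in all_draws]) for k in keys}
        return draws, np.stack(all_ll)
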