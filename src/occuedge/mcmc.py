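"""Adaptive Metropolis-within-Gibbs sampling for the occupancy model.

The sampler exploits the model's conditional structure so that one sweep
costs only a handful of vectorised likelihood passes:

* persistence/occupancy parameters (alpha, beta, u, v, psi, gamma) change
  only the per-pair four-term marginal, so the per-(pair, period)
  detection sums ``logA`` are cached across those updates;
* detection parameters (delta_t, delta1-3) require one observation-level
  pass each, after which the cache is refreshed;
* species random effects are proposed as whole vectors and accepted
  species-by-species (pairs are independent across species given the
  top-level parameters), giving S parallel one-dimensional updates for
  the price of one likelihood pass;
* random-effect hypermeans are conjugate-normal Gibbs draws; standard
  deviations take random-walk steps on the log scale against their
  half-Normal priors.

Proposal scales adapt toward a 0.44 acceptance rate during burn-in
(Robbins-Monro) and are frozen afterwards, so retained draws come from a
fixed-kernel chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import HYPERMEAN_FAMILIES, RANDOM_EFFECT_FAMILIES

TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings.  Defaults are the desk-scale configuration
    (3 chains, 4,000 burn-in, 4,000 retained draws at thinning 2)."""

    draws: int = 4000
    burn: int = 4000
    thin: int = 2
    chains: int = 3
    seed: int = 0
    method: str = "marginal"

    def __post_init__(self):
        if self.thin < 1 or self.draws < 1 or self.burn < 0:
            raise ValueError("invalid MCMC settings")
        if self.chains < 2:
            raise ValueError("at least two chains are needed for convergence checks")
        if self.method not in ("marginal", "augmented"):
            raise ValueError(f"unknown sampler method {self.method!r}")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: array of shape (chains, draws, dim)."""

    draws: np.ndarray
    names: list
    settings: MCMCSettings
    accept_rates: dict

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws for one named parameter, shape (chains, draws)."""
        j = self.names.index(name)
        return self.draws[:, :, j]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    def stacked(self) -> np.ndarray:
        """All chains concatenated: (chains * draws, dim)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self):
        """Columnar layout: chain and draw indices plus one column per parameter."""
        import pandas as pd

        m, n, d = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(m * n, d), columns=self.names)
        df.insert(0, "draw", np.tile(np.arange(n), m))
        df.insert(0, "chain", np.repeat(np.arange(m), n))
        return df

    @classmethod
    def from_frame(cls, df, settings: "MCMCSettings | None" = None) -> "PosteriorDraws":
        names = [c for c in df.columns if c not in ("chain", "draw")]
        m = int(df["chain"].max()) + 1
        n = len(df) // m
        draws = df[names].to_numpy(dtype=float).reshape(m, n, len(names))
        if settings is None:
            settings = MCMCSettings(draws=n, chains=max(m, 2), seed=0)
        return cls(draws=draws, names=names, settings=settings, accept_rates={})


def rw_metropolis(logpdf, x0: float, n: int, rng, scale: float = 1.0, adapt: int = 0):
    """Scalar adaptive random-walk Metropolis sampler.

    Generic workhorse used for simple one-parameter posteriors (and by the
    test-suite against closed-form oracles).  The first ``adapt``
    iterations tune the step size toward 0.44 acceptance.
    """
    x = float(x0)
    lp = logpdf(x)
    out = np.empty(n)
    for i in range(n):
        prop = x + scale * rng.standard_normal()
        lp_prop = logpdf(prop)
        a = min(1.0, np.exp(min(lp_prop - lp, 0.0)))
        if rng.random() < a:
            x, lp = prop, lp_prop
        if i < adapt:
            scale *= np.exp(min(0.1, 1.0 / np.sqrt(i + 1.0)) * (a - TARGET_ACCEPT))
        out[i] = x
    return out


def _init_state(model, rng):
    """Overdispersed but prior-plausible chain initialisation."""
    S = model.n_species
    state = {
        "alpha": rng.normal(0.0, 1.0, 4),
        "beta": rng.normal(0.0, 1.0, 4),
        "delta_t": float(rng.normal(0.0, 0.5)),
        "mu": {fam: float(rng.normal(0.0, 1.0)) for fam in HYPERMEAN_FAMILIES},
        "sigma": {fam: float(0.5 * np.exp(rng.normal(0.0, 0.3))) for fam in RANDOM_EFFECT_FAMILIES},
    }
    for fam in RANDOM_EFFECT_FAMILIES:
        mu = state["mu"].get(fam, 0.0)
        state[fam] = mu + rng.normal(0.0, 0.3, S)
    return state


class _ChainRunner:
    """One chain of the Metropolis-within-Gibbs sweep."""

    def __init__(self, model, rng, method: str = "marginal"):
        self.m = model
        self.rng = rng
        self.method = method
        self.pr = model.priors
        S = model.n_species
        self.state = _init_state(model, rng)
        # proposal scales
        self.scale_fixed = {f"alpha{j}": 0.2 for j in range(4)}
        self.scale_fixed.update({f"beta{j}": 0.4 for j in range(4)})
        self.scale_fixed["delta_t"] = 0.1
        self.scale_vec = {fam: np.full(S, 0.3) for fam in RANDOM_EFFECT_FAMILIES}
        self.scale_sig = {fam: 0.3 for fam in RANDOM_EFFECT_FAMILIES}
        self.accept_count: dict = {k: 0.0 for k in self.scale_fixed}
        self.accept_tries = 0
        # caches
        self.z1 = self.z2 = None
        self._refresh_all()

    # cache helpers --------------------------------------------------------

    def _detection_params(self):
        s = self.state
        return s["delta_t"], s["delta1"], s["delta2"], s["delta3"]

    def _pair_ll_given(self, alpha=None, beta=None, u=None, v=None, lpsi=None, lgamma=None, logA=None):
        s = self.state
        args = (
            s["alpha"] if alpha is None else alpha,
            s["beta"] if beta is None else beta,
            s["u"] if u is None else u,
            s["v"] if v is None else v,
            s["lpsi"] if lpsi is None else lpsi,
            s["lgamma"] if lgamma is None else lgamma,
        )
        logA = self.logA if logA is None else logA
        if self.method == "augmented":
            return self.m.compute_pair_ll_z(*args, logA, self.z1, self.z2)
        return self.m.compute_pair_ll(*args, logA)

    def _refresh_all(self):
        self.logA = self.m.compute_logA(*self._detection_params())
        if self.method == "augmented":
            sa = self.m._state_arrays(self.state)
            self.z1, self.z2 = self.m.sample_z(sa, self.logA, self.rng)
        self.pair_ll = self._pair_ll_given()

    # update blocks --------------------------------------------------------

    def _update_fixed_scalar(self, name, adapting):
        """Single fixed effect (alpha_j, beta_j or delta_t) by RW Metropolis."""
        s = self.state
        rng = self.rng
        step = self.scale_fixed[name] * rng.standard_normal()
        if name == "delta_t":
            prop = s["delta_t"] + step
            logA_prop = self.m.compute_logA(prop, s["delta1"], s["delta2"], s["delta3"])
            pll_prop = self._pair_ll_given(logA=logA_prop)
            dprior = -0.5 * ((prop / self.pr.fixed_sd) ** 2 - (s["delta_t"] / self.pr.fixed_sd) ** 2)
            dll = pll_prop.sum() - self.pair_ll.sum()
            a = np.exp(min(0.0, dll + dprior))
            if rng.random() < a:
                s["delta_t"], self.logA, self.pair_ll = prop, logA_prop, pll_prop
        else:
            block, j = name[:-1], int(name[-1])
            vec = s[block].copy()
            old = vec[j]
            vec[j] = old + step
            pll_prop = self._pair_ll_given(**{block: vec})
            dprior = -0.5 * ((vec[j] / self.pr.fixed_sd) ** 2 - (old / self.pr.fixed_sd) ** 2)
            dll = pll_prop.sum() - self.pair_ll.sum()
            a = np.exp(min(0.0, dll + dprior))
            if rng.random() < a:
                s[block] = vec
                self.pair_ll = pll_prop
        if adapting:
            self.scale_fixed[name] *= np.exp(self._adapt_rate * (a - TARGET_ACCEPT))
        self.accept_count[name] += a

    def _species_sums(self, pll):
        return np.bincount(self.m._pair_species, weights=pll, minlength=self.m.n_species)

    def _update_vector(self, fam, adapting):
        """All species' effects in one family, accepted species-by-species."""
        s = self.state
        rng = self.rng
        S = self.m.n_species
        cur = s[fam]
        prop = cur + self.scale_vec[fam] * rng.standard_normal(S)
        detection = fam in ("delta1", "delta2", "delta3")
        if detection:
            d = {k: s[k] for k in ("delta1", "delta2", "delta3")}
            d[fam] = prop
            logA_prop = self.m.compute_logA(s["delta_t"], d["delta1"], d["delta2"], d["delta3"])
            pll_prop = self._pair_ll_given(logA=logA_prop)
        else:
            pll_prop = self._pair_ll_given(**{fam: prop})
        dll = self._species_sums(pll_prop) - self._species_sums(self.pair_ll)
        mu = s["mu"].get(fam, 0.0)
        sig = s["sigma"][fam]
        dprior = -0.5 * (((prop - mu) / sig) ** 2 - ((cur - mu) / sig) ** 2)
        a = np.exp(np.minimum(0.0, dll + dprior))
        accept = rng.random(S) < a
        if np.any(accept):
            s[fam] = np.where(accept, prop, cur)
            pair_acc = accept[self.m._pair_species]
            self.pair_ll = np.where(pair_acc, pll_prop, self.pair_ll)
            if detection:
                self.logA = np.where(pair_acc[:, None], logA_prop, self.logA)
        if adapting:
            self.scale_vec[fam] *= np.exp(self._adapt_rate * (a - TARGET_ACCEPT))

    def _update_hyper(self, adapting):
        """Hypermeans by conjugate Gibbs; SDs by log-scale RW Metropolis."""
        s = self.state
        rng = self.rng
        S = self.m.n_species
        for fam in HYPERMEAN_FAMILIES:
            sig = s["sigma"][fam]
            prec = S / sig**2 + 1.0 / self.pr.hypermean_sd**2
            mean = (s[fam].sum() / sig**2) / prec
            s["mu"][fam] = float(mean + rng.standard_normal() / np.sqrt(prec))
        for fam in RANDOM_EFFECT_FAMILIES:
            mu = s["mu"].get(fam, 0.0)
            e = s[fam] - mu
            sse = float(np.sum(e**2))

            def logtarget(log_sig):
                sig = np.exp(log_sig)
                return (
                    -S * log_sig
                    - 0.5 * sse / sig**2
                    - 0.5 * (sig / self.pr.sd_scale) ** 2
                    + log_sig  # Jacobian of the log transform
                )

            cur = np.log(s["sigma"][fam])
            prop = cur + self.scale_sig[fam] * rng.standard_normal()
            a = np.exp(min(0.0, logtarget(prop) - logtarget(cur)))
            if rng.random() < a:
                s["sigma"][fam] = float(np.exp(prop))
            if adapting:
                self.scale_sig[fam] *= np.exp(self._adapt_rate * (a - TARGET_ACCEPT))

    def sweep(self, iteration: int, adapting: bool):
        self._adapt_rate = min(0.25, 2.0 / np.sqrt(iteration + 1.0))
        if self.method == "augmented":
            # refresh latent occupancy states from their exact conditional
            sa = self.m._state_arrays(self.state)
            self.z1, self.z2 = self.m.sample_z(sa, self.logA, self.rng)
            self.pair_ll = self._pair_ll_given()
        for name in self.scale_fixed:
            self._update_fixed_scalar(name, adapting)
        for fam in RANDOM_EFFECT_FAMILIES:
            self._update_vector(fam, adapting)
        self._update_hyper(adapting)
        self.accept_tries += 1


def sample_posterior(model, settings: MCMCSettings, progress: bool = False) -> PosteriorDraws:
    """Run the full MCMC: ``chains`` independent adaptive MWG chains.

    Reproducible: chain c uses ``np.random.default_rng([seed, c])``.  The
    retained draws are ``settings.draws`` per chain, taken every
    ``settings.thin`` sweeps after ``settings.burn`` burn-in sweeps.
    """
    idx = model.index
    n_keep = settings.draws
    out = np.empty((settings.chains, n_keep, idx.dim))
    accept_rates = {}
    for c in range(settings.chains):
        rng = np.random.default_rng([settings.seed, c])
        runner = _ChainRunner(model, rng, method=settings.method)
        total = settings.burn + settings.draws * settings.thin
        kept = 0
        iterator = range(total)
        if progress:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=f"chain {c}")
        for it in iterator:
            runner.sweep(it, adapting=it < settings.burn)
            if it >= settings.burn and (it - settings.burn) % settings.thin == settings.thin - 1:
                out[c, kept] = idx.pack(runner.state)
                kept += 1
        assert kept == n_keep
        accept_rates[c] = {
            k: v / max(runner.accept_tries, 1) for k, v in runner.accept_count.items()
        }
    return PosteriorDraws(draws=out, names=idx.names, settings=settings, accept_rates=accept_rates)
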