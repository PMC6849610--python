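"""Posterior products of a fitted occupancy model.

An :class:`OccupancyResults` wraps the retained MCMC draws and computes the
derived quantities reported by the analysis: the parameter summary table
(mean, SD, 95% interval, Rhat, sign-consistency f), extinction-rate versus
range-position curves by realm x conversion stratum, per-cell species
richness change with a continuous confidence measure, and the per-species
extinction-rate / edge-proneness / range-size table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import f_statistic, gelman_rubin, posterior_summary
from .mcmc import PosteriorDraws
from .model import RANDOM_EFFECT_FAMILIES, inv_logit


class OccupancyResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    def __init__(self, model, posterior: PosteriorDraws):
        self.model = model
        self.posterior = posterior
        self._index = model.index

    # -- draws access -------------------------------------------------------

    def get(self, name: str) -> np.ndarray:
        """Draws of one scalar parameter, shape (chains, draws)."""
        return self.posterior.get(name)

    def block(self, family: str) -> np.ndarray:
        """Draws of a species-effect family, shape (chains, draws, S)."""
        sl = self._index.slices[family]
        return self.posterior.draws[:, :, sl]

    # -- summaries ----------------------------------------------------------

    def _summary_series(self) -> dict:
        """Per-draw series for every reported row of the summary table.

        Species-level colonisation and detection parameters are reported
        as means across species within each draw; Gamma is the across-
        species mean colonisation probability.
        """
        out = {}
        for nm in ("alpha0", "alpha1", "alpha2", "alpha3", "beta0", "beta1", "beta2", "beta3"):
            out[nm] = self.get(nm)
        out["Gamma"] = inv_logit(self.block("lgamma")).mean(axis=2)
        out["delta_t"] = self.get("delta_t")
        for fam, label in (("delta1", "delta1"), ("delta2", "delta2"), ("delta3", "delta3")):
            out[label] = self.block(fam).mean(axis=2)
        for fam in RANDOM_EFFECT_FAMILIES:
            out[f"sigma_{fam}"] = self.get(f"sigma_{fam}")
        return out

    def summary(self, round_to: int | None = 3) -> pd.DataFrame:
        """Posterior summary table: mean, SD, 2.5%, 97.5%, Rhat, f."""
        return posterior_summary(self._summary_series(), round_to=round_to)

    def rhat(self, monitored: list | None = None) -> pd.Series:
        """Gelman-Rubin statistic per monitored top-level parameter."""
        names = monitored or self._index.monitored
        return pd.Series({nm: gelman_rubin(self.get(nm)) for nm in names})

    def max_rhat(self) -> float:
        return float(self.rhat().max())

    def f(self, name: str) -> float:
        return f_statistic(self.get(name).ravel())

    # -- extinction-rate curves (average species) ---------------------------

    def extinction_curve(self, R: int, C: int, dprime_grid=None, levels=(0.1, 0.5, 0.9)) -> pd.DataFrame:
        """Posterior extinction rate 1 - phi versus D' for one stratum.

        The curve is for the average species (random effects at zero).
        Each draw's parameters are transformed to an extinction rate at
        every D' value and the per-D' draws are then summarised by their
        median and 80% credible interval — transform first, summarise
        second.
        """
        if (R, C) not in {(0, 0), (0, 1), (1, 0), (1, 1)}:
            raise ValueError(f"unknown stratum (R={R}, C={C})")
        if dprime_grid is None:
            mask = (self.model.dataset.pair_R == R) & (self.model.dataset.pair_C == C)
            lo = self.model.dataset.pair_dprime[mask].min() if np.any(mask) else 0.2
            dprime_grid = np.linspace(lo, 1.0, 41)
        dprime_grid = np.asarray(dprime_grid, dtype=float)
        alpha = self.get("alpha0") * (1 - R) + self.get("alpha1") * R
        alpha = alpha + self.get("alpha2") * (1 - R) * C + self.get("alpha3") * R * C
        beta = self.get("beta0") * (1 - R) + self.get("beta1") * R
        beta = beta + self.get("beta2") * (1 - R) * C + self.get("beta3") * R * C
        x = dprime_grid - 0.5 if self.model.center_dprime else dprime_grid
        lphi = alpha.ravel()[:, None] + beta.ravel()[:, None] * x[None, :]
        ext = 1.0 - inv_logit(lphi)
        q10, med, q90 = np.quantile(ext, levels, axis=0)
        return pd.DataFrame(
            {"R": R, "C": C, "Dprime": dprime_grid, "median": med, "q10": q10, "q90": q90}
        )

    def extinction_curves(self, dprime_grid=None) -> pd.DataFrame:
        """All four realm x conversion strata stacked."""
        return pd.concat(
            [self.extinction_curve(R, C, dprime_grid) for R in (0, 1) for C in (0, 1)],
            ignore_index=True,
        )

    # -- richness change ----------------------------------------------------

    def impute_z(self, seed: int, stride: int = 1) -> np.ndarray:
        """Posterior draws of the latent occupancy states z.

        For each retained draw (optionally strided), z for every pair and
        period is sampled from its exact conditional given that draw's
        parameters and the pair's detection history (posterior-predictive
        imputation).  Returns an int8 array (n_draws, n_pairs, 2).
        """
        rng = np.random.default_rng(seed)
        model = self.model
        thetas = self.posterior.stacked()[::stride]
        out = np.empty((thetas.shape[0], model.n_pairs, 2), dtype=np.int8)
        for d, theta in enumerate(thetas):
            s = model.index.unpack(theta)
            logA = model.compute_logA(s["delta_t"], s["delta1"], s["delta2"], s["delta3"])
            z1, z2 = model.sample_z(model._state_arrays(s), logA, rng)
            out[d, :, 0] = z1
            out[d, :, 1] = z2
        return out

    def richness_change(self, seed: int, stride: int = 1, tie_half_weight: bool = False) -> pd.DataFrame:
        """Per-cell species richness before/after with a confidence measure.

        Richness in a draw is the number of in-range species with z = 1 at
        the cell.  Confidence is the proportion of draws in which richness
        is strictly higher after the period boundary than before; with
        ``tie_half_weight`` draws with equal richness contribute 1/2
        instead of 0.
        """
        z = self.impute_z(seed, stride)
        ds = self.model.dataset
        n_draws = z.shape[0]
        J = ds.n_cells
        rich = np.zeros((n_draws, J, 2), dtype=np.int64)
        for t in (0, 1):
            for d in range(n_draws):
                rich[d, :, t] = np.bincount(ds.pair_cell, weights=z[d, :, t], minlength=J)
        higher = (rich[:, :, 1] > rich[:, :, 0]).mean(axis=0)
        if tie_half_weight:
            higher = higher + 0.5 * (rich[:, :, 1] == rich[:, :, 0]).mean(axis=0)
        mean_before = rich[:, :, 0].mean(axis=0)
        mean_after = rich[:, :, 1].mean(axis=0)
        return pd.DataFrame(
            {
                "cell_id": ds.cell_ids,
                "mean_before": mean_before,
                "mean_after": mean_after,
                "change": mean_after - mean_before,
                "confidence": higher,
            }
        )

    # -- species-level table -------------------------------------------------

    def species_effects(self, ranges: dict | None = None) -> pd.DataFrame:
        """Per-species relative extinction rate, edge proneness, range size.

        Relative extinction rate is the posterior mean of 1 - u_i (higher
        than 1 means the species loses cells faster than the average
        species after realm/conversion adjustment); edge proneness is the
        posterior mean of the random slope v_i, negative when extinctions
        concentrate toward the range edge.  Range size is the species'
        total range-cell count when ``ranges`` is given, else the in-model
        pair count.
        """
        ds = self.model.dataset
        u = self.block("u").reshape(-1, ds.n_species)
        v = self.block("v").reshape(-1, ds.n_species)
        sizes = []
        for i, sp in enumerate(ds.species_ids):
            if ranges is not None and sp in ranges:
                sizes.append(int(ranges[sp].size))
            else:
                sizes.append(int(np.sum(ds.pair_species == i)))
        return pd.DataFrame(
            {
                "species_id": ds.species_ids,
                "extinction_rate": (1.0 - u).mean(axis=0),
                "edge_proneness": v.mean(axis=0),
                "range_size": sizes,
            }
        )

    # -- plotting ------------------------------------------------------------

    def plot_extinction_curves(self, ax=None):
        """Extinction rate vs D' per stratum (median line, 80% band)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = {0: "Palearctic-like", 1: "Indo-Malaya-like"}
        for R in (0, 1):
            for C in (0, 1):
                cur = self.extinction_curve(R, C)
                lab = f"{labels[R]}, {'human-dominated' if C else 'unconverted'}"
                (line,) = ax.plot(cur["Dprime"], cur["median"], label=lab)
                ax.fill_between(cur["Dprime"], cur["q10"], cur["q90"], alpha=0.2, color=line.get_color())
        ax.set_xlabel("range position D' (1 = edge)")
        ax.set_ylabel("local extinction rate 1 - phi")
        ax.legend(fontsize=8)
        return ax

    def plot_species_effects(self, ranges=None, ax=None):
        """Edge proneness vs extinction rate, points sized by range size."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.species_effects(ranges)
        size = 10 + 40 * tab["range_size"] / tab["range_size"].max()
        ax.scatter(tab["extinction_rate"], tab["edge_proneness"], s=size, alpha=0.6)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("relative extinction rate (1 - u)")
        ax.set_ylabel("edge proneness v (negative = edge-prone)")
        return ax
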