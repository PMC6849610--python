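"""Synthetic opportunistic-record datasets with known truth.

Emulates the statistical structure of a historical ornithological record
compilation: uneven opportunistic sampling effort, surveys that are
single-species, short (2-3) or long (>3) lists, two eras of records split
at 1980, species ranges as contiguous cell blocks spanning two
biogeographic realms and two land-conversion classes.  Occupancy dynamics
and detection follow the generative reading of the occupancy model, so
every pipeline stage and the parameter-recovery study can run end-to-end
with no external data.

The default configuration is the package's benchmark: 30 species on a
20 x 20 mid-latitude grid block (~400 retained cells) with true effects
alpha = (3, 1.5, -0.5, 0.5) and beta = (-3, 0, 0, 2) on the logit scale —
strong Palearctic-like persistence that falls toward the range edge, and a
core-concentrated extinction pattern in converted Indo-Malaya-like cells —
chosen so extinction events are frequent enough to estimate at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grid import GridSpec, load_cell_attributes
from .model import detection_logit, inv_logit, persistence_logit
from .ranges import SpeciesRangeCells, attach_dprime

PERIOD1_YEARS = (1900, 1979)
PERIOD2_YEARS = (1980, 2008)


@dataclass(frozen=True)
class TrueParams:
    """Generative parameter values (logit scale unless noted)."""

    alpha: tuple = (3.0, 1.5, -0.5, 0.5)
    beta: tuple = (-3.0, 0.0, 0.0, 2.0)
    delta_t: float = 0.1
    mu_delta1: float = -0.5
    mu_delta2: float = 1.0
    mu_delta3: float = 2.0
    mu_lpsi: float = 1.0
    mu_lgamma: float = -2.0
    sigma_u: float = 0.5
    sigma_v: float = 0.5
    sigma_delta1: float = 0.3
    sigma_delta2: float = 0.3
    sigma_delta3: float = 0.3
    sigma_lpsi: float = 0.5
    sigma_lgamma: float = 0.5

    def named(self) -> dict:
        """Truth keyed by the model's top-level parameter names."""
        out = {f"alpha{j}": self.alpha[j] for j in range(4)}
        out.update({f"beta{j}": self.beta[j] for j in range(4)})
        d = asdict(self)
        for k, v in d.items():
            if k not in ("alpha", "beta"):
                out[k] = v
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the generator (defaults = benchmark)."""

    n_rows: int = 20
    n_cols: int = 20
    n_species: int = 30
    # contiguous-block range sizes: one single-cell range is always
    # included; the rest are log-normal between the bounds
    range_size_min: int = 4
    range_size_max: int = 200
    range_size_log_mean: float = 4.2
    range_size_log_sd: float = 0.7
    # landscape
    lon_center: float = 90.0
    lat_center: float = 35.0
    conversion_smoothing: float = 2.0
    # survey effort: surveys per cell-period ~ zero-truncated NegBin
    mean_surveys: float = 3.0
    dispersion: float = 1.5
    # latent per-survey effort classes driving detection (single/short/long)
    effort_probs: tuple = (0.35, 0.35, 0.30)
    params: TrueParams = field(default_factory=TrueParams)
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if not np.isclose(sum(self.effort_probs), 1.0):
            raise ValueError("effort_probs must sum to 1")
        if self.range_size_max > self.n_rows * self.n_cols:
            raise ValueError("range larger than grid")


def _block_origin(config: SimulationConfig) -> tuple[int, int]:
    """Grid (row, col) of the block's lower-left cell."""
    g = config.grid
    center = g.point_to_cell(config.lon_center, config.lat_center)
    r, c = g.rowcol(center)
    return int(r - config.n_rows // 2), int(c - config.n_cols // 2)


def block_cells(config: SimulationConfig) -> np.ndarray:
    """Cell ids of the simulated grid block, row-major."""
    r0, c0 = _block_origin(config)
    rows = np.arange(r0, r0 + config.n_rows)
    cols = np.arange(c0, c0 + config.n_cols)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return config.grid.cell_id(rr.ravel(), cc.ravel())


def generate_landscape(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Cell-attribute table: realm label, converted fraction, R and C.

    The western half of the block is Palearctic-like (R = 0), the eastern
    half Indo-Malaya-like (R = 1).  The converted-land fraction is a
    spatially autocorrelated field (smoothed white noise, rank-mapped to
    uniform [0, 1]), so both conversion classes appear in coherent
    patches.  Deterministic given the seed.
    """
    from scipy import ndimage

    rng = np.random.default_rng([seed, 11])
    cells = block_cells(config)
    ncell = cells.size
    _, c0 = _block_origin(config)
    _, col = config.grid.rowcol(cells)
    realm = np.where(col - c0 < config.n_cols // 2, "Palearctic", "Indo-Malaya")
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    smooth = ndimage.gaussian_filter(noise, sigma=config.conversion_smoothing, mode="wrap")
    frac = (np.argsort(np.argsort(smooth.ravel())) + 0.5) / ncell
    df = pd.DataFrame({"cell_id": cells, "realm": realm, "converted_fraction": frac})
    attrs = load_cell_attributes(df)
    for name, mask in (
        ("realm 0", attrs["R"] == 0),
        ("realm 1", attrs["R"] == 1),
        ("unconverted", attrs["C"] == 0),
        ("converted", attrs["C"] == 1),
    ):
        if mask.mean() < 0.10:
            raise ValueError(f"landscape config leaves <10% of cells in class {name}")
    return attrs.reset_index()


def generate_ranges(config: SimulationConfig, seed: int) -> dict:
    """Contiguous (rook-connected) cell-block ranges of varied sizes.

    Species 0 always gets a single-cell range so the D' = 1 convention for
    tiny ranges is exercised; remaining sizes are log-normal, clipped to
    the configured bounds.  Grown by seeded random accretion.
    """
    rng = np.random.default_rng([seed, 23])
    g = config.grid
    r0, c0 = _block_origin(config)
    sizes = [1] + [
        int(np.clip(np.round(np.exp(rng.normal(config.range_size_log_mean, config.range_size_log_sd))),
                    config.range_size_min, config.range_size_max))
        for _ in range(config.n_species - 1)
    ]
    ranges = {}
    for i, size in enumerate(sizes):
        start = (rng.integers(config.n_rows), rng.integers(config.n_cols))
        cells = {start}
        frontier = {start}
        while len(cells) < size:
            candidates = set()
            for (r, c) in frontier:
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb = (r + dr, c + dc)
                    if 0 <= nb[0] < config.n_rows and 0 <= nb[1] < config.n_cols and nb not in cells:
                        candidates.add(nb)
            if not candidates:
                break
            pick_n = min(len(candidates), size - len(cells), max(1, len(candidates) // 2))
            cand = np.array(sorted(candidates))
            picks = {tuple(cand[k]) for k in rng.choice(len(cand), size=pick_n, replace=False)}
            cells |= picks
            frontier = picks
        ids = np.sort(g.cell_id([r0 + r for r, _ in cells], [c0 + c for _, c in cells]))
        sp = f"sp{i:03d}"
        ranges[sp] = attach_dprime(SpeciesRangeCells(species_id=sp, cells=ids), g)
    return ranges


@dataclass
class SyntheticTruth:
    """Known generative state behind one synthetic dataset."""

    config: SimulationConfig
    params: TrueParams
    ranges: dict
    cells: pd.DataFrame  # indexed by cell_id, with R, C
    species_ids: list
    species_effects: dict  # family -> (S,) array
    # per in-range pair
    pair_species: np.ndarray  # index into species_ids
    pair_cell: np.ndarray  # cell ids
    pair_dprime: np.ndarray
    phi: np.ndarray
    z1: np.ndarray
    z2: np.ndarray

    def z_lookup(self) -> dict:
        """(species_id, cell_id, period) -> z, for consistency checks."""
        out = {}
        for p in range(self.pair_species.size):
            sp = self.species_ids[self.pair_species[p]]
            out[(sp, int(self.pair_cell[p]), 1)] = int(self.z1[p])
            out[(sp, int(self.pair_cell[p]), 2)] = int(self.z2[p])
        return out


def simulate_truth(ranges: dict, cells: pd.DataFrame, params: TrueParams, seed: int,
                   config: SimulationConfig) -> SyntheticTruth:
    """Draw species effects and latent occupancy states.

    z1 ~ Bernoulli(psi_i); z2 ~ Bernoulli(z1 phi_ij + (1 - z1) gamma_i)
    with phi from the persistence predictor at the pair's true D', realm
    and conversion class.
    """
    rng = np.random.default_rng([seed, 37])
    species_ids = sorted(ranges, key=str)
    S = len(species_ids)
    eff = {
        "u": rng.normal(0.0, params.sigma_u, S),
        "v": rng.normal(0.0, params.sigma_v, S),
        "delta1": rng.normal(params.mu_delta1, params.sigma_delta1, S),
        "delta2": rng.normal(params.mu_delta2, params.sigma_delta2, S),
        "delta3": rng.normal(params.mu_delta3, params.sigma_delta3, S),
        "lpsi": rng.normal(params.mu_lpsi, params.sigma_lpsi, S),
        "lgamma": rng.normal(params.mu_lgamma, params.sigma_lgamma, S),
    }
    attrs = cells.set_index("cell_id") if "cell_id" in cells.columns else cells
    ps, pc, pdp = [], [], []
    for i, sp in enumerate(species_ids):
        rng_sp = ranges[sp]
        for cid, dp in zip(rng_sp.cells, rng_sp.dprime):
            ps.append(i)
            pc.append(int(cid))
            pdp.append(float(dp))
    pair_species = np.asarray(ps, dtype=np.int64)
    pair_cell = np.asarray(pc, dtype=np.int64)
    pair_dprime = np.asarray(pdp, dtype=float)
    R = attrs.loc[pair_cell, "R"].to_numpy()
    C = attrs.loc[pair_cell, "C"].to_numpy()
    lphi = persistence_logit(
        pair_dprime, R, C, np.asarray(params.alpha), np.asarray(params.beta),
        u=eff["u"][pair_species], v=eff["v"][pair_species],
    )
    phi = inv_logit(lphi)
    psi = inv_logit(eff["lpsi"][pair_species])
    gamma = inv_logit(eff["lgamma"][pair_species])
    z1 = (rng.random(pair_species.size) < psi).astype(np.int8)
    z2 = (rng.random(pair_species.size) < np.where(z1 == 1, phi, gamma)).astype(np.int8)
    return SyntheticTruth(
        config=config, params=params, ranges=ranges, cells=attrs,
        species_ids=species_ids, species_effects=eff,
        pair_species=pair_species, pair_cell=pair_cell, pair_dprime=pair_dprime,
        phi=phi, z1=z1, z2=z2,
    )


def _sample_ztnb(rng, mean: float, dispersion: float) -> int:
    """Zero-truncated Negative-Binomial draw via rejection."""
    p = dispersion / (dispersion + mean)
    while True:
        n = int(rng.negative_binomial(dispersion, p))
        if n > 0:
            return n


def simulate_surveys(truth: SyntheticTruth, config: SimulationConfig, seed: int):
    """Generate the opportunistic record table and survey bookkeeping.

    Each cell-period draws a zero-truncated Negative-Binomial number of
    surveys at distinct years.  A survey's latent effort class
    (single-ish / short-ish / long-ish) sets the list-length indicators in
    the detection predictor; each species present (z = 1) is then detected
    independently with its own probability, in a single pass.  Surveys
    with no detections leave no records — opportunistic data only exist
    where something was recorded.

    Returns (records, surveys): records in the raw input schema
    (species_id, lon, lat, year, period_flag, native) and the generator's
    internal per-survey bookkeeping (cell_id, year, period, realized list
    length and category).
    """
    from .surveys import categorize_list

    rng = np.random.default_rng([seed, 53])
    g = config.grid
    p = truth.params
    eff = truth.species_effects
    # species present per (cell, period)
    present: dict = {}
    for idx in range(truth.pair_species.size):
        cid = int(truth.pair_cell[idx])
        if truth.z1[idx]:
            present.setdefault((cid, 1), []).append(truth.pair_species[idx])
        if truth.z2[idx]:
            present.setdefault((cid, 2), []).append(truth.pair_species[idx])
    cells = np.sort(truth.cells.index.to_numpy())
    lon, lat = g.cell_centroid_lonlat(cells)
    cell_pos = {int(c): k for k, c in enumerate(cells)}
    rec_rows, svy_rows = [], []
    for cid in cells:
        for period, (y0, y1) in ((1, PERIOD1_YEARS), (2, PERIOD2_YEARS)):
            n_svy = min(_sample_ztnb(rng, config.mean_surveys, config.dispersion), y1 - y0 + 1)
            years = rng.choice(np.arange(y0, y1 + 1), size=n_svy, replace=False)
            who = present.get((int(cid), period), [])
            for year in sorted(int(y) for y in years):
                effort = int(rng.choice(3, p=config.effort_probs))
                short, long = int(effort == 1), int(effort == 2)
                detected = []
                for i in who:
                    lp = detection_logit(
                        short, long, period, p.delta_t, eff["delta1"][i],
                        eff["delta2"][i], eff["delta3"][i],
                    )
                    if rng.random() < inv_logit(lp):
                        detected.append(i)
                if not detected:
                    continue
                k = cell_pos[int(cid)]
                for i in detected:
                    rec_rows.append(
                        {
                            "species_id": truth.species_ids[i],
                            "lon": float(lon[k]),
                            "lat": float(lat[k]),
                            "year": year,
                            "period_flag": "",
                            "native": True,
                        }
                    )
                svy_rows.append(
                    {
                        "cell_id": int(cid),
                        "year": year,
                        "period": period,
                        "list_length": len(detected),
                        "category": categorize_list(len(detected)),
                    }
                )
    records = pd.DataFrame(rec_rows, columns=["species_id", "lon", "lat", "year", "period_flag", "native"])
    surveys = pd.DataFrame(svy_rows, columns=["cell_id", "year", "period", "list_length", "category"])
    return records, surveys


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0):
    """One end-to-end synthetic dataset in the pipeline's input schemas.

    Returns (records, species_cells, cell_attrs, truth): the record table,
    the species_id/cell_id range table standing in for range polygons, the
    cell-attribute table, and the :class:`SyntheticTruth` behind them.
    """
    config = config or SimulationConfig()
    cells = generate_landscape(config, seed)
    ranges = generate_ranges(config, seed)
    truth = simulate_truth(ranges, cells, config.params, seed, config)
    records, _ = simulate_surveys(truth, config, seed)
    species_cells = pd.concat(
        [pd.DataFrame({"species_id": sp, "cell_id": rng.cells}) for sp, rng in ranges.items()],
        ignore_index=True,
    )
    cell_attrs = cells[["cell_id", "realm", "converted_fraction"]]
    return records, species_cells, cell_attrs, truth


#: Replicate fits in the recovery study use the benchmark data conditions
#: but shortened two-chain runs, so twenty independent
#: simulate-assemble-fit cycles stay within a single-CPU desk budget.
RECOVERY_FIT = dict(draws=1500, burn=1500, thin=1, chains=2)


def recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    config: SimulationConfig | None = None,
    fit_kwargs: dict | None = None,
    parameters: tuple = ("alpha0", "alpha1", "alpha2", "alpha3", "beta0", "beta3"),
) -> pd.DataFrame:
    """Replicated parameter-recovery experiment.

    Each replicate simulates a fresh dataset (varying the data seed),
    fits the model, and scores bias / 95%-interval coverage / posterior-
    mean sign for the requested top-level parameters.  Returns the
    concatenated per-replicate scores with a ``replicate`` column.
    """
    from .diagnostics import posterior_summary
    from .model import DynamicOccupancyModel
    from .pipeline import assemble

    config = config or SimulationConfig()
    fit_kwargs = dict(RECOVERY_FIT, **(fit_kwargs or {}))
    truth_named = config.params.named()
    out = []
    for rep in range(n_replicates):
        data_seed = seed + 1000 * rep
        records, species_cells, cell_attrs, truth = simulate_dataset(config, seed=data_seed)
        _, _, _, dataset = assemble(records, species_cells, cell_attrs, config.grid, 1980)
        model = DynamicOccupancyModel(dataset)
        res = model.fit(seed=data_seed + 1, **fit_kwargs)
        summary = posterior_summary({nm: res.get(nm) for nm in parameters})
        score = recovery_score(summary, {nm: truth_named[nm] for nm in parameters})
        score = score.reset_index()
        score.insert(0, "replicate", rep)
        out.append(score)
    return pd.concat(out, ignore_index=True)


def recovery_score(summary: pd.DataFrame, truth: dict) -> pd.DataFrame:
    """Bias and 95%-interval coverage of a fit against known truth.

    ``summary`` must carry mean / q2.5 / q97.5 rows indexed by parameter
    name (as from :func:`occuedge.diagnostics.posterior_summary`); truth
    at an interval endpoint counts as covered (closed interval).
    """
    rows = []
    for name, tv in truth.items():
        if name not in summary.index:
            raise KeyError(f"parameter {name!r} missing from summary")
        r = summary.loc[name]
        rows.append(
            {
                "parameter": name,
                "truth": tv,
                "mean": r["mean"],
                "bias": r["mean"] - tv,
                "q2.5": r["q2.5"],
                "q97.5": r["q97.5"],
                "covered": bool(r["q2.5"] <= tv <= r["q97.5"]),
                "sign_match": bool(np.sign(r["mean"]) == np.sign(tv)) if tv != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
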