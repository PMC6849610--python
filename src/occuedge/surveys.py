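"""Survey assembly: cell:year surveys, list lengths, filters, model dataset.

Opportunistic records are grouped into *surveys*: the de-duplicated set of
species recorded in one grid cell in one year.  The number of species on a
survey (its list length) proxies survey effort and drives the detection
submodel through two indicators: short (2-3 species) and long (>3 species)
lists; a single-species list is the baseline.  Time is split into two
periods at 1980.  Cells without observations in both periods carry no
information about persistence between the periods and are dropped, as are
species never recorded in a retained in-range cell in each period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PERIOD_BOUNDARY_DEFAULT = 1980

#: Pseudo-years used to pool records dated only to an era into one survey
#: per cell and period (they cannot join a real cell:year survey).
PSEUDO_YEAR = {1: -1, 2: -2}


def assign_period(year=None, period_flag=None, boundary: int = PERIOD_BOUNDARY_DEFAULT):
    """Period index: 1 before the boundary year, 2 from it onwards.

    Records carrying only an era flag use that flag; records with neither a
    year nor a flag are unusable (returns 0, callers drop and count them).
    """
    if year is not None and not (isinstance(year, float) and np.isnan(year)):
        return 1 if int(year) < boundary else 2
    if period_flag in ("pre1980", "pre"):
        return 1
    if period_flag in ("post1980", "post"):
        return 2
    return 0


def categorize_list(list_length: int) -> str:
    if list_length == 1:
        return "single"
    if list_length in (2, 3):
        return "short"
    return "long"


def build_surveys(records: pd.DataFrame, boundary: int = PERIOD_BOUNDARY_DEFAULT) -> pd.DataFrame:
    """Group records into cell:year surveys with list-length categories.

    ``records`` needs columns species_id, cell_id and year (and optionally
    period_flag for year-less records; those pool into one pseudo-survey per
    cell and period).  Native and non-native records both count toward a
    survey's species list — every record is evidence of effort.

    Returns one row per survey: cell_id, year, period, species (sorted
    tuple), list_length, category, short, long.
    """
    df = records.copy()
    if "period_flag" not in df.columns:
        df["period_flag"] = None
    years = df["year"]
    period = np.array(
        [
            assign_period(y if pd.notna(y) else None, f, boundary)
            for y, f in zip(years, df["period_flag"])
        ],
        dtype=np.int64,
    )
    n_dropped = int((period == 0).sum())
    if n_dropped:
        log.info("dropping %d records with neither year nor period flag", n_dropped)
    df = df.loc[period > 0].copy()
    df["period"] = period[period > 0]
    # era-flagged records without a year pool into a per-period pseudo-survey
    yr = df["year"].to_numpy(dtype=object)
    no_year = pd.isna(df["year"]).to_numpy()
    yr[no_year] = [PSEUDO_YEAR[p] for p in df.loc[no_year, "period"]]
    df["survey_year"] = pd.array(yr, dtype="int64")

    rows = []
    for (cell, year), sub in df.groupby(["cell_id", "survey_year"], sort=True):
        species = tuple(sorted(set(sub["species_id"]), key=str))
        ll = len(species)
        cat = categorize_list(ll)
        rows.append(
            {
                "cell_id": int(cell),
                "year": int(year),
                "period": int(sub["period"].iloc[0]),
                "species": species,
                "list_length": ll,
                "category": cat,
                "short": int(cat == "short"),
                "long": int(cat == "long"),
            }
        )
    return pd.DataFrame(rows)


def filter_cells_both_periods(surveys: pd.DataFrame):
    """Retain cells with at least one survey in each period.

    Returns (sorted retained cell array, counts dict logging the drop
    classes: cells seen only before and only after the period boundary).
    """
    per_cell = surveys.groupby("cell_id")["period"].agg(set)
    retained = sorted(c for c, s in per_cell.items() if {1, 2} <= s)
    only1 = sum(1 for s in per_cell.values if s == {1})
    only2 = sum(1 for s in per_cell.values if s == {2})
    counts = {
        "cells_retained": len(retained),
        "cells_only_period1": only1,
        "cells_only_period2": only2,
    }
    log.info("cell filter: %s", counts)
    if not retained:
        raise ValueError("no cells with observations in both periods")
    return np.asarray(retained, dtype=np.int64), counts


def filter_species(ranges: dict, retained_cells: np.ndarray, surveys: pd.DataFrame):
    """Retain species detected in retained, in-range cells in both periods.

    A species whose records all fall in dropped cells — or only on one side
    of the period boundary — contributes nothing to the persistence model
    and is excluded.
    """
    retained_set = set(int(c) for c in retained_cells)
    range_sets = {sp: set(int(c) for c in rng.cells) for sp, rng in ranges.items()}
    periods_seen: dict = {sp: set() for sp in ranges}
    for cell, period, species in zip(surveys["cell_id"], surveys["period"], surveys["species"]):
        cell = int(cell)
        if cell not in retained_set:
            continue
        for sp in species:
            if sp in range_sets and cell in range_sets[sp]:
                periods_seen[sp].add(int(period))
    retained = sorted((sp for sp in ranges if periods_seen[sp] == {1, 2}), key=str)
    dropped = sorted((sp for sp in ranges if sp not in set(retained)), key=str)
    if dropped:
        log.info("species filter: excluding %s", dropped)
    if not retained:
        raise ValueError("no species detected in-range in both periods")
    return retained, dropped


@dataclass
class ModelDataset:
    """Indexed detection histories for the occupancy model.

    Pairs are the in-range (species, cell) combinations at retained cells;
    observations are one binary detection per survey x in-range species at
    that survey's cell.  All arrays are integer indexes into ``species_ids``
    / ``cell_ids`` / the pair and survey tables, ordered deterministically
    (species, then cell, then year).
    """

    species_ids: list
    cell_ids: np.ndarray
    # pairs
    pair_species: np.ndarray
    pair_cell: np.ndarray
    pair_dprime: np.ndarray
    pair_R: np.ndarray
    pair_C: np.ndarray
    # surveys
    survey_cell: np.ndarray
    survey_year: np.ndarray
    survey_period: np.ndarray  # 1 or 2
    survey_short: np.ndarray
    survey_long: np.ndarray
    # observations
    obs_pair: np.ndarray
    obs_survey: np.ndarray
    obs_y: np.ndarray
    counts: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    @property
    def n_pairs(self) -> int:
        return int(self.pair_species.size)

    @property
    def n_surveys(self) -> int:
        return int(self.survey_cell.size)

    @property
    def n_obs(self) -> int:
        return int(self.obs_pair.size)

    def validate(self) -> None:
        """Internal consistency assertions (cheap; used by tests and the CLI)."""
        assert self.pair_dprime.min() > 0 and self.pair_dprime.max() <= 1.0
        # every retained cell has surveys in both periods
        for t in (1, 2):
            cells_t = set(self.survey_cell[self.survey_period == t].tolist())
            assert cells_t == set(range(self.n_cells)), f"cell without survey in period {t}"
        # y=1 only where the pair's species was on the survey's list
        assert set(np.unique(self.obs_y)) <= {0, 1}


def build_model_dataset(
    ranges: dict,
    surveys: pd.DataFrame,
    cell_attrs: pd.DataFrame,
    boundary: int = PERIOD_BOUNDARY_DEFAULT,
) -> ModelDataset:
    """Apply the cell and species filters and index the model dataset.

    Detections of a species at a cell outside its range (or of an excluded
    species) still count toward list length — effort — but produce no
    binary observation.
    """
    retained_cells, cell_counts = filter_cells_both_periods(surveys)
    # keep only cells with known covariates
    retained_cells = np.asarray(
        [c for c in retained_cells if c in cell_attrs.index], dtype=np.int64
    )
    retained_species, dropped_species = filter_species(ranges, retained_cells, surveys)

    species_index = {sp: i for i, sp in enumerate(retained_species)}
    cell_index = {int(c): j for j, c in enumerate(retained_cells)}

    # pairs: in-range (species, cell) at retained cells, species-major order
    ps, pc, pd_, pr, pcv = [], [], [], [], []
    for sp in retained_species:
        rng = ranges[sp]
        for cid, dp in zip(rng.cells, rng.dprime):
            j = cell_index.get(int(cid))
            if j is None:
                continue
            ps.append(species_index[sp])
            pc.append(j)
            pd_.append(float(dp))
            pr.append(int(cell_attrs.at[int(cid), "R"]))
            pcv.append(int(cell_attrs.at[int(cid), "C"]))
    if not ps:
        raise ValueError("no in-range species-cell pairs at retained cells")
    pair_species = np.asarray(ps, dtype=np.int64)
    pair_cell = np.asarray(pc, dtype=np.int64)
    pair_dprime = np.asarray(pd_, dtype=float)
    if np.any(~np.isfinite(pair_dprime)):
        raise ValueError("in-range pair with missing D'")

    sv = surveys[surveys["cell_id"].isin(cell_index)].sort_values(["cell_id", "year"]).reset_index(drop=True)
    survey_cell = np.asarray([cell_index[int(c)] for c in sv["cell_id"]], dtype=np.int64)
    survey_year = sv["year"].to_numpy(dtype=np.int64)
    survey_period = sv["period"].to_numpy(dtype=np.int64)
    survey_short = sv["short"].to_numpy(dtype=np.int64)
    survey_long = sv["long"].to_numpy(dtype=np.int64)

    # observations: every (survey, in-range species at its cell)
    pairs_at_cell: dict = {}
    for p in range(pair_species.size):
        pairs_at_cell.setdefault(int(pair_cell[p]), []).append(p)
    obs_pair, obs_survey, obs_y = [], [], []
    species_sets = [set(s) for s in sv["species"]]
    for k in range(len(sv)):
        for p in pairs_at_cell.get(int(survey_cell[k]), ()):  # species-ordered
            sp = retained_species[pair_species[p]]
            obs_pair.append(p)
            obs_survey.append(k)
            obs_y.append(1 if sp in species_sets[k] else 0)

    ds = ModelDataset(
        species_ids=list(retained_species),
        cell_ids=retained_cells,
        pair_species=pair_species,
        pair_cell=pair_cell,
        pair_dprime=pair_dprime,
        pair_R=np.asarray(pr, dtype=np.int64),
        pair_C=np.asarray(pcv, dtype=np.int64),
        survey_cell=survey_cell,
        survey_year=survey_year,
        survey_period=survey_period,
        survey_short=survey_short,
        survey_long=survey_long,
        obs_pair=np.asarray(obs_pair, dtype=np.int64),
        obs_survey=np.asarray(obs_survey, dtype=np.int64),
        obs_y=np.asarray(obs_y, dtype=np.int8),
        counts={
            **cell_counts,
            "species_retained": len(retained_species),
            "species_dropped": len(dropped_species),
            "pairs": int(pair_species.size),
            "surveys": int(len(sv)),
            "binary_observations": int(len(obs_y)),
            "period_boundary": boundary,
        },
    )
    log.info("model dataset: %s", ds.counts)
    return ds
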