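"""Predator-prey mass ratio metrics.

Two individual-level metrics are distinguished:

* ``r_num`` — number-weighted: the mean over prey items of the per-link mass
  ratio M/m_j.  Dominated by numerous small prey; the quantity that maps
  onto preference kernels of dynamic size-spectrum models.
* ``r_bio`` — biomass-weighted: predator mass over the mean individual prey
  mass, equivalently the biomass-weighted mean of per-link ratios.  This is
  the energetically relevant ratio used by equilibrium size-spectrum theory.

By the arithmetic-harmonic mean inequality r_num >= r_bio, with equality iff
all prey in the stomach have the same mass.

Group-level weighted means pool individuals within (species, 0.1-wide log10
body-mass bin, subregion) cells: R_num weights each predator by its share of
prey counts, R_bio weights by specific total prey mass (g prey per g
predator).  Groups need a minimum number of predators (default 10) to enter
the analysis table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, NoPreyError
from .records import PredatorRecord

BIN_WIDTH = 0.1
DEFAULT_MIN_PREDATORS = 10

GROUP_TABLE_COLUMNS = [
    "species", "family", "order", "region", "subregion", "bin_lo_log10g",
    "n_pred", "mean_mass_numw_g", "mean_mass_biow_g", "R_num", "R_bio",
    "fish_prop_mass", "fish_prop_count",
]


@dataclass
class IndividualPPMR:
    """Per-predator PPMR summary used as input to group aggregation."""

    predator_id: str
    M: float          # predator mass, g
    n_prey: int
    w: float          # total prey biomass, g
    r_num: float
    r_bio: float
    fish_prop_mass: float
    fish_prop_count: float


def r_num(M: float, prey_masses) -> float:
    """Number-weighted individual PPMR: mean of per-link ratios M/m_j."""
    m = _checked(M, prey_masses)
    return float(np.mean(M / m))


def r_bio(M: float, prey_masses) -> float:
    """Biomass-weighted individual PPMR: M over the mean prey mass."""
    m = _checked(M, prey_masses)
    return float(M / np.mean(m))


def r_bio_linkwise(M: float, prey_masses) -> float:
    """Biomass-weighted PPMR via explicit per-link weighting.

    Sum over prey of (M/m_j) * (m_j/w) with w the total prey biomass;
    algebraically identical to :func:`r_bio` and kept as an independent
    formulation for cross-checking.
    """
    m = _checked(M, prey_masses)
    w = m.sum()
    return float(np.sum((M / m) * (m / w)))


def _checked(M, prey_masses) -> np.ndarray:
    m = np.asarray(list(prey_masses), dtype=float)
    if m.size == 0:
        raise NoPreyError("empty prey list")
    if M <= 0 or np.any(m <= 0):
        raise InvalidMeasurementError("masses must be positive")
    return m


def assign_mass_bin(M: float) -> float:
    """Lower bound (log10 g) of the half-open 0.1-wide mass bin holding M.

    Bins are [k*0.1, k*0.1 + 0.1); the lower edge is inclusive.  A small
    epsilon guards against log10 landing infinitesimally below an exact
    bin edge (e.g. M = 10**2.3).
    """
    if M <= 0:
        raise InvalidMeasurementError(f"mass must be positive, got {M}")
    idx = np.floor(np.log10(M) / BIN_WIDTH + 1e-9)
    return round(idx * BIN_WIDTH, 10)


def individual_ppmr(pred: PredatorRecord) -> IndividualPPMR:
    """Summarise one preprocessed predator record.

    Every prey record must carry resolved individual masses at this point.
    """
    masses, groups = [], []
    for prey in pred.prey:
        masses.extend(prey.individual_masses)
        groups.extend([prey.prey_group] * len(prey.individual_masses))
    m = _checked(pred.body_mass if pred.body_mass is not None else -1.0, masses)
    is_fish = np.asarray([g == "fish" for g in groups])
    return IndividualPPMR(
        predator_id=pred.predator_id,
        M=float(pred.body_mass),
        n_prey=int(m.size),
        w=float(m.sum()),
        r_num=r_num(pred.body_mass, m),
        r_bio=r_bio(pred.body_mass, m),
        fish_prop_mass=float(m[is_fish].sum() / m.sum()),
        fish_prop_count=float(is_fish.mean()),
    )


def group_R_num(members: list[IndividualPPMR]) -> float:
    """Group number-weighted mean PPMR: sum of r_num_i * n_i / N."""
    n = np.asarray([ind.n_prey for ind in members], dtype=float)
    r = np.asarray([ind.r_num for ind in members])
    return float(np.sum(r * n) / n.sum())


def group_R_bio(members: list[IndividualPPMR]) -> float:
    """Group biomass-weighted mean PPMR, weights p_i = (w_i/M_i)/sum(w/M)."""
    s = np.asarray([ind.w / ind.M for ind in members], dtype=float)
    r = np.asarray([ind.r_bio for ind in members])
    return float(np.sum(r * s / s.sum()))


def _weighted(values, weights) -> float:
    w = np.asarray(weights, dtype=float)
    return float(np.sum(np.asarray(values, dtype=float) * w) / w.sum())


def build_group_table(
    predators: list[PredatorRecord],
    min_n: int = DEFAULT_MIN_PREDATORS,
    drop_log=None,
) -> pd.DataFrame:
    """Aggregate predators into the (species, mass bin, subregion) table.

    Groups with fewer than ``min_n`` predators are dropped (and logged when a
    drop log is supplied).  Weighted mean predator masses follow the same
    weighting as the corresponding metric: prey-count weights for the
    number-weighted column, specific-prey-mass weights for the biomass one.
    """
    cells: dict[tuple, dict] = {}
    for pred in predators:
        if not pred.prey:
            continue
        ind = individual_ppmr(pred)
        key = (pred.species, pred.family, pred.order, pred.region,
               pred.subregion, assign_mass_bin(ind.M))
        cells.setdefault(key, {"members": []})["members"].append(ind)

    rows = []
    for key in sorted(cells):
        members = cells[key]["members"]
        if len(members) < min_n:
            if drop_log is not None:
                drop_log.add(
                    "|".join(str(k) for k in key),
                    f"group-below-min-n:{len(members)}",
                )
            continue
        n_w = [ind.n_prey for ind in members]
        b_w = [ind.w / ind.M for ind in members]
        rows.append({
            "species": key[0], "family": key[1], "order": key[2],
            "region": key[3], "subregion": key[4], "bin_lo_log10g": key[5],
            "n_pred": len(members),
            "mean_mass_numw_g": _weighted([i.M for i in members], n_w),
            "mean_mass_biow_g": _weighted([i.M for i in members], b_w),
            "R_num": group_R_num(members),
            "R_bio": group_R_bio(members),
            "fish_prop_mass": _weighted([i.fish_prop_mass for i in members], b_w),
            "fish_prop_count": _weighted([i.fish_prop_count for i in members], n_w),
        })
    return pd.DataFrame(rows, columns=GROUP_TABLE_COLUMNS)
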