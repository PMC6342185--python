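"""Community-wide mean PPMR: biomass-weighted aggregation of predictions.

For every (mass bin, region) the fitted hierarchical model predicts group
PPMR per species and subregion; these are averaged on the ratio scale per
posterior draw, weighted first by each subregion's share of that species'
biomass within the region (region-species step) and then by each species'
share of community biomass in the bin (community step).  Because the
weights are proportional within the nesting, the two-stage average equals a
single biomass-weighted sum over (species, subregion) cells.

When the model was never trained on a cell's subregion (or region, or
species) labels, prediction falls back up the nesting ladder:
subregion -> region -> species -> family -> order -> fixed effects; the
level actually used is recorded per cell, and the summary reports the
biomass fraction covered at species level or deeper.

Posterior uncertainty propagates through the weighting draw by draw; the
summary reports the median and the 5th/95th percentiles (linear
interpolation between order statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoBiomassError
from .hier_model import PosteriorFit

FALLBACK_LADDER = ("subregion", "region", "species", "family", "order", "fixed")

BIOMASS_COLUMNS = ["species", "region", "subregion", "bin_lo_log10g", "density_kg_km"]

COMMUNITY_COLUMNS = [
    "region", "bin_lo_log10g", "metric", "median", "q05", "q95", "coverage",
]


@dataclass
class CommunityPPMR:
    region: str
    bin_lo_log10g: float
    metric: str
    median: float
    q05: float
    q95: float
    coverage: float


def region_species_R(draws_by_subregion: dict, biomass_by_subregion: dict) -> np.ndarray:
    """Biomass-weighted average of subregion draws within one region/species.

    ``draws_by_subregion`` maps subregion label -> (S,) draw vector;
    ``biomass_by_subregion`` maps the same labels to biomass densities.
    """
    labels = [d for d in draws_by_subregion if biomass_by_subregion.get(d, 0.0) > 0]
    total = sum(biomass_by_subregion.get(d, 0.0) for d in draws_by_subregion)
    if total <= 0 or not labels:
        raise NoBiomassError("all subregion biomasses are zero")
    out = np.zeros_like(next(iter(draws_by_subregion.values())), dtype=float)
    for d in labels:
        out = out + draws_by_subregion[d] * (biomass_by_subregion[d] / total)
    return out


def community_R(draws_by_species: dict, biomass_by_species: dict) -> np.ndarray:
    """Biomass-weighted average of species-level draws within a region/bin."""
    return region_species_R(draws_by_species, biomass_by_species)


def fallback_predict(
    fit: PosteriorFit,
    species: str,
    region: str,
    subregion: str,
    bin_lo: float,
    family: str | None = None,
    order: str | None = None,
) -> tuple[np.ndarray, str]:
    """Predict R for one cell at the deepest trained nesting level.

    Walks subregion -> region -> species -> family -> order -> fixed and
    returns (posterior draws on ratio scale, level used).  The fixed level
    is always available, so the operation is total.
    """
    kw = dict(species=species, family=family, order=order,
              region=region, subregion=subregion)
    for level in FALLBACK_LADDER[:-1]:
        if fit.has_group(level, **kw):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                draws = fit.predict_R(mass_bin_lo=bin_lo, level=level, **kw)
            return draws, level
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit.predict_R(mass_bin_lo=bin_lo, level="fixed", **kw), "fixed"


def summarize_community(draws: np.ndarray) -> tuple[float, float, float]:
    """(median, 5th, 95th percentile) of a draw vector, linear interpolation."""
    if draws.size < 100:
        raise ValueError("need at least 100 draws to summarise")
    q05, med, q95 = np.percentile(draws, [5, 50, 95], method="linear")
    return float(med), float(q05), float(q95)


def compute_community(
    fit: PosteriorFit,
    biomass: pd.DataFrame,
    metric: str | None = None,
    taxonomy: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Community-wide mean PPMR per (region, mass bin) with uncertainty.

    ``biomass`` has columns (species, region, subregion, bin_lo_log10g,
    density_kg_km).  ``taxonomy`` optionally maps species -> (order, family)
    for species the model never saw (needed to use family/order fallback);
    trained species resolve their taxonomy from the fit itself.

    Returns (community table, per-cell level-used table).
    """
    metric = metric or fit.response
    taxonomy = taxonomy or {}
    trained_taxo = fit.species_taxonomy()

    rows, cell_rows = [], []
    for (region, bin_lo), chunk in biomass.groupby(
        ["region", "bin_lo_log10g"], sort=True
    ):
        total_b = chunk["density_kg_km"].sum()
        if total_b <= 0:
            continue
        covered_b = 0.0
        species_draws: dict[str, np.ndarray] = {}
        species_biomass: dict[str, float] = {}
        for species, sp_chunk in chunk.groupby("species", sort=True):
            draws_by_sub, biomass_by_sub = {}, {}
            order, family = trained_taxo.get(
                species, taxonomy.get(species, (None, None))
            )
            for row in sp_chunk.itertuples(index=False):
                if row.density_kg_km <= 0:
                    continue
                draws, level = fallback_predict(
                    fit, species, region, row.subregion, bin_lo,
                    family=family, order=order,
                )
                draws_by_sub[row.subregion] = draws
                biomass_by_sub[row.subregion] = row.density_kg_km
                if level in ("subregion", "region", "species"):
                    covered_b += row.density_kg_km
                cell_rows.append({
                    "region": region, "bin_lo_log10g": bin_lo,
                    "species": species, "subregion": row.subregion,
                    "level_used": level, "density_kg_km": row.density_kg_km,
                })
            if not draws_by_sub:
                continue
            # region-species step: average subregion draws by biomass share
            species_draws[species] = region_species_R(draws_by_sub, biomass_by_sub)
            species_biomass[species] = sum(biomass_by_sub.values())
        if not species_draws:
            continue
        # community step: average species draws by biomass share
        acc = community_R(species_draws, species_biomass)
        med, q05, q95 = summarize_community(acc)
        rows.append({
            "region": region, "bin_lo_log10g": bin_lo, "metric": metric,
            "median": med, "q05": q05, "q95": q95,
            "coverage": covered_b / total_b,
        })
    return (
        pd.DataFrame(rows, columns=COMMUNITY_COLUMNS),
        pd.DataFrame(cell_rows),
    )


def community_R_bruteforce(
    fit: PosteriorFit, biomass: pd.DataFrame, region: str, bin_lo: float
) -> np.ndarray:
    """Independent single-pass oracle: weighted sum over (species, subregion).

    Uses subregion-level predictions only (no fallback); equals the
    two-stage region-species -> community computation exactly because the
    nested weights are proportional.
    """
    chunk = biomass[
        (biomass["region"] == region) & (biomass["bin_lo_log10g"] == bin_lo)
    ]
    total = chunk["density_kg_km"].sum()
    if total <= 0:
        raise NoBiomassError(f"no biomass for region {region}, bin {bin_lo}")
    acc = None
    for row in chunk.itertuples(index=False):
        if row.density_kg_km <= 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit.predict_R(
                species=row.species, region=region, subregion=row.subregion,
                mass_bin_lo=bin_lo, level="subregion",
            )
        term = draws * (row.density_kg_km / total)
        acc = term if acc is None else acc + term
    return acc
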