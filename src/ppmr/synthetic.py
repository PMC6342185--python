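"""Synthetic stomach-content data with known ground truth.

The generator emulates the structure of groundfish trawl-survey diet data:

* predators spanning ~4 orders of magnitude in body mass, organised in a
  five-level nested hierarchy (order / family / species / region /
  subregion) with level-specific random deviations of the PPMR-mass curve;
* individual prey whose log10 masses follow a species-specific log-normal
  feeding kernel centred ``log10 M - log10 beta`` below the predator mass,
  which produces the numeric dominance of small prey (and hence
  r_num > r_bio) characteristic of real diets;
* a share of invertebrate records reported only as aggregate count + total
  mass, and a further share as total mass only;
* partially digested records (< 75% intact), with lengths recoverable for
  fish and crab prey so their mass can be reconstructed;
* predators missing a direct mass measurement (length only);
* a biomass-density table per (species, region, subregion, mass bin).

Because the kernel is log-normal, the true group-level metrics have closed
forms: with kernel centre mu = log10 M - log10 beta and width sigma (log10
units), E[m] = 10**(mu + sigma^2 ln10 / 2), so

    R_bio* = beta * 10**(-sigma^2 ln10 / 2)
    R_num* = beta * 10**(+sigma^2 ln10 / 2)

and R_num*/R_bio* = 10**(sigma^2 ln10) independent of beta.  These truths
are stored in :class:`GroundTruth` and drive every recovery test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .records import DIET_COLUMNS

LN10 = math.log(10.0)

#: allometric truths used to emit lengths (and to check reconstruction)
PREY_LW = {"fish": (1e-5, 3.0), "crab": (1e-4, 3.0)}   # g per mm**b
PRED_LW = (0.01, 3.0)                                   # g per cm**b


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic data generator."""

    n_orders: int = 3
    families_per_order: int = 2
    species_per_family: int = 4
    n_regions: int = 2
    subregions_per_region: int = 2
    n_mass_bins: int = 6
    n_predators_per_group: int = 20

    # random-effect sds per level: (intercept, linear, quadratic), log10 scale
    order_effect_sds: tuple = (0.15, 0.03, 0.03)
    family_effect_sds: tuple = (0.15, 0.05, 0.05)
    species_effect_sds: tuple = (0.45, 0.10, 0.10)
    region_effect_sds: tuple = (0.05, 0.02, 0.02)
    subregion_effect_sds: tuple = (0.10, 0.03, 0.03)

    #: fixed curve of log10 kernel-centre PPMR vs scaled log10 mass
    fixed_coefs: tuple = (2.7, 0.05, -0.2)
    #: group-level residual sd (log10), used by the group-table shortcut
    resid_sd: float = 0.08

    kernel_width_sigma: float = 0.5          # sd of log10 prey mass
    prey_per_stomach_mean: float = 10.0
    frac_aggregated: float = 0.64            # invert rows as count+total
    frac_total_only: float = 0.19            # invert rows as total only
    frac_digested: float = 0.10
    frac_pred_length_only: float = 0.46
    frac_fish_prey: float = 0.20
    frac_crab_prey: float = 0.05
    mass_range_log10: tuple = (0.5, 4.5)     # log10 g
    seed: int = 0

    def validate(self) -> None:
        if self.n_orders * self.families_per_order * self.species_per_family < 1:
            raise InvalidConfigError("config yields zero species")
        if self.n_regions < 1 or self.subregions_per_region < 1:
            raise InvalidConfigError("need at least one region and subregion")
        for name in ("order", "family", "species", "region", "subregion"):
            if any(s < 0 for s in getattr(self, f"{name}_effect_sds")):
                raise InvalidConfigError(f"negative sd for level {name}")
        for name in ("frac_aggregated", "frac_total_only", "frac_digested",
                     "frac_pred_length_only", "frac_fish_prey", "frac_crab_prey"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidConfigError(f"{name} outside [0, 1]")
        if self.frac_aggregated + self.frac_total_only > 1:
            raise InvalidConfigError("aggregated + total-only fractions exceed 1")
        lo, hi = self.mass_range_log10
        if hi - lo <= 1:
            raise InvalidConfigError("mass range must span more than one decade")
        if self.kernel_width_sigma < 0 or self.prey_per_stomach_mean < 1:
            raise InvalidConfigError("invalid kernel width or prey mean")


def _bin_los(cfg: SimConfig) -> np.ndarray:
    lo, hi = cfg.mass_range_log10
    edges = np.linspace(lo, hi - 0.1, cfg.n_mass_bins)
    return np.round(np.round(edges / 0.1) * 0.1, 10)


@dataclass
class GroundTruth:
    """Everything needed to check pipeline output against construction."""

    config: SimConfig
    center: float                      # generator scaler: midpoint of range
    scale: float                       # generator scaler: sd of uniform mass
    species_paths: list               # (order, family, species)
    effects: dict                      # level -> {path tuple: (3,) array}
    group_truth: pd.DataFrame = field(default=None)

    def z(self, u):
        return (np.asarray(u, dtype=float) - self.center) / self.scale

    def kernel_log10_ppmr(self, species: str, u, region=None, subregion=None,
                          depth: str = "subregion") -> np.ndarray:
        """log10 of the kernel-centre PPMR curve at log10 mass u.

        ``depth`` controls which nested deviations are summed
        ("fixed", "order", "family", "species", "region", "subregion").
        """
        path = next(p for p in self.species_paths if p[2] == species)
        coefs = np.array(self.config.fixed_coefs, dtype=float)
        ladder = [
            ("order", path[:1]),
            ("family", path[:2]),
            ("species", path[:3]),
            ("region", path[:3] + (region,)),
            ("subregion", path[:3] + (region, subregion)),
        ]
        depths = ["fixed", "order", "family", "species", "region", "subregion"]
        want = depths.index(depth)
        for i, (level, key) in enumerate(ladder, start=1):
            if i > want:
                break
            coefs = coefs + self.effects[level][key]
        zz = self.z(u)
        return coefs[0] + coefs[1] * zz + coefs[2] * zz ** 2

    def _kernel_shift(self) -> float:
        s = self.config.kernel_width_sigma
        return 0.5 * s * s * LN10

    def true_R_bio(self, species, u, region, subregion) -> np.ndarray:
        c = self.kernel_log10_ppmr(species, u, region, subregion)
        return 10.0 ** (c - self._kernel_shift())

    def true_R_num(self, species, u, region, subregion) -> np.ndarray:
        c = self.kernel_log10_ppmr(species, u, region, subregion)
        return 10.0 ** (c + self._kernel_shift())

    def fixed_coefs_raw(self, metric: str = "none") -> np.ndarray:
        """Fixed curve as raw polynomial coefficients in u = log10 mass.

        ``metric`` "R_bio"/"R_num" applies the log-normal kernel shift to
        the intercept; "none" returns the kernel-centre curve itself.
        """
        b0, b1, b2 = self.config.fixed_coefs
        c, s = self.center, self.scale
        a2 = b2 / s ** 2
        a1 = b1 / s - 2 * b2 * c / s ** 2
        a0 = b0 - b1 * c / s + b2 * c ** 2 / s ** 2
        if metric == "R_bio":
            a0 -= self._kernel_shift()
        elif metric == "R_num":
            a0 += self._kernel_shift()
        return np.array([a0, a1, a2])

    def truth_community_R(self, biomass: pd.DataFrame,
                          metric: str = "R_bio") -> pd.DataFrame:
        """Independent oracle: biomass-weighted true community R per region/bin.

        Brute-force single pass over (species, subregion) cells, no
        fallback ladder.
        """
        fn = self.true_R_bio if metric == "R_bio" else self.true_R_num
        rows = []
        for (region, bin_lo), chunk in biomass.groupby(
            ["region", "bin_lo_log10g"], sort=True
        ):
            total = chunk["density_kg_km"].sum()
            if total <= 0:
                continue
            u_mid = bin_lo + 0.05
            val = 0.0
            for row in chunk.itertuples(index=False):
                r = float(fn(row.species, u_mid, region, row.subregion))
                val += r * row.density_kg_km / total
            rows.append({"region": region, "bin_lo_log10g": bin_lo,
                         "metric": metric, "R_true": val})
        return pd.DataFrame(rows)


def _draw_effects(cfg: SimConfig, rng) -> tuple[list, dict]:
    orders = [f"ord{i+1}" for i in range(cfg.n_orders)]
    effects = {l: {} for l in ("order", "family", "species", "region", "subregion")}
    species_paths = []
    regions = [f"reg{r+1}" for r in range(cfg.n_regions)]
    subregions = {
        r: [f"{r}_sub{s+1}" for s in range(cfg.subregions_per_region)]
        for r in regions
    }
    for o in orders:
        effects["order"][(o,)] = rng.normal(0, cfg.order_effect_sds, 3)
        for j in range(cfg.families_per_order):
            f = f"{o}_fam{j+1}"
            effects["family"][(o, f)] = rng.normal(0, cfg.family_effect_sds, 3)
            for k in range(cfg.species_per_family):
                sp = f"{f}_sp{k+1}"
                path = (o, f, sp)
                species_paths.append(path)
                effects["species"][path] = rng.normal(0, cfg.species_effect_sds, 3)
                for r in regions:
                    effects["region"][path + (r,)] = rng.normal(
                        0, cfg.region_effect_sds, 3
                    )
                    for sub in subregions[r]:
                        effects["subregion"][path + (r, sub)] = rng.normal(
                            0, cfg.subregion_effect_sds, 3
                        )
    return species_paths, effects


def make_truth(cfg: SimConfig, rng) -> GroundTruth:
    lo, hi = cfg.mass_range_log10
    species_paths, effects = _draw_effects(cfg, rng)
    truth = GroundTruth(
        config=cfg,
        center=(lo + hi) / 2.0,
        scale=(hi - lo) / math.sqrt(12.0),
        species_paths=species_paths,
        effects=effects,
    )
    rows = []
    regions = sorted({k[3] for k in effects["region"]})
    for path in species_paths:
        for r in regions:
            subs = sorted(k[4] for k in effects["subregion"] if k[:4] == path + (r,))
            for sub in subs:
                for bin_lo in _bin_los(cfg):
                    u = bin_lo + 0.05
                    rows.append({
                        "order": path[0], "family": path[1], "species": path[2],
                        "region": r, "subregion": sub,
                        "bin_lo_log10g": float(bin_lo),
                        "R_bio_true": float(truth.true_R_bio(path[2], u, r, sub)),
                        "R_num_true": float(truth.true_R_num(path[2], u, r, sub)),
                    })
    truth.group_truth = pd.DataFrame(rows)
    return truth


def _prey_rows(cfg, rng, pred_base, M, log10_beta):
    """Emit the CSV rows for one stomach; returns list of row dicts."""
    n_prey = 1 + rng.poisson(cfg.prey_per_stomach_mean - 1.0)
    mu = math.log10(M) - log10_beta
    log_m = rng.normal(mu, cfg.kernel_width_sigma, n_prey)
    masses = 10.0 ** log_m
    u = rng.random(n_prey)
    groups = np.where(
        u < cfg.frac_fish_prey, "fish",
        np.where(u < cfg.frac_fish_prey + cfg.frac_crab_prey, "crab", "other_invert"),
    )
    rows = []
    # group individuals into taxon records (taxa are decade size bands)
    taxa = {}
    for m, g in zip(masses, groups):
        t = f"{g}_sz{int(math.floor(math.log10(m)))}"
        taxa.setdefault((g, t), []).append(m)
    for (g, taxon), ms in sorted(taxa.items()):
        ms = np.asarray(ms)
        digested = rng.random() < cfg.frac_digested
        row = dict(pred_base)
        row.update(prey_taxon=taxon, life_stage="adult", prey_group=g)
        if g in ("fish", "crab"):
            a, b = PREY_LW[g]
            lengths = (ms / a) ** (1.0 / b)
            lengths = lengths * 10.0 ** rng.normal(0, 0.01, ms.size)
            if digested:
                row.update(
                    pct_intact=round(rng.uniform(10, 74.9), 1),
                    prey_count=str(ms.size), prey_total_mass_g="",
                    prey_ind_mass_g="",
                    prey_ind_length_mm=";".join(format(x, ".6g") for x in lengths),
                )
            else:
                row.update(
                    pct_intact=round(rng.uniform(80, 100), 1),
                    prey_count=str(ms.size),
                    prey_total_mass_g=format(ms.sum(), ".6g"),
                    prey_ind_mass_g=";".join(format(x, ".6g") for x in ms),
                    prey_ind_length_mm=";".join(format(x, ".6g") for x in lengths),
                )
        else:
            if digested:
                row.update(
                    pct_intact=round(rng.uniform(10, 74.9), 1),
                    prey_count=str(ms.size), prey_total_mass_g="",
                    prey_ind_mass_g="", prey_ind_length_mm="",
                )
            else:
                mode = rng.random()
                common = dict(
                    pct_intact=round(rng.uniform(80, 100), 1),
                    prey_ind_length_mm="",
                )
                if mode < cfg.frac_aggregated:
                    common.update(
                        prey_count=str(ms.size),
                        prey_total_mass_g=format(ms.sum(), ".6g"),
                        prey_ind_mass_g="",
                    )
                elif mode < cfg.frac_aggregated + cfg.frac_total_only:
                    common.update(
                        prey_count="",
                        prey_total_mass_g=format(ms.sum(), ".6g"),
                        prey_ind_mass_g="",
                    )
                else:
                    common.update(
                        prey_count=str(ms.size),
                        prey_total_mass_g=format(ms.sum(), ".6g"),
                        prey_ind_mass_g=";".join(format(x, ".6g") for x in ms),
                    )
                row.update(common)
        rows.append(row)
    return rows


def simulate_dataset(cfg: SimConfig, seed: int | None = None):
    """Generate (raw diet table, biomass table, ground truth).

    Fully deterministic given (cfg, seed); the same inputs produce
    byte-identical CSV output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = make_truth(cfg, rng)
    a_pred, b_pred = PRED_LW

    diet_rows = []
    pid = 0
    for path in truth.species_paths:
        order, family, species = path
        region_keys = sorted(k for k in truth.effects["region"] if k[:3] == path)
        for rkey in region_keys:
            region = rkey[3]
            sub_keys = sorted(
                k for k in truth.effects["subregion"] if k[:4] == rkey
            )
            for skey in sub_keys:
                sub = skey[4]
                for bin_lo in _bin_los(cfg):
                    for _ in range(cfg.n_predators_per_group):
                        pid += 1
                        u = rng.uniform(bin_lo, bin_lo + 0.1)
                        M = 10.0 ** u
                        L_cm = (M / a_pred) ** (1.0 / b_pred)
                        length_only = rng.random() < cfg.frac_pred_length_only
                        base = dict(
                            predator_id=f"p{pid:07d}",
                            species=species, family=family, order=order,
                            region=region, subregion=sub,
                            pred_mass_g="" if length_only else format(M, ".6g"),
                            pred_length_cm=format(L_cm, ".6g"),
                        )
                        log10_beta = float(
                            truth.kernel_log10_ppmr(species, u, region, sub)
                        )
                        diet_rows.extend(_prey_rows(cfg, rng, base, M, log10_beta))
    diet = pd.DataFrame(diet_rows, columns=DIET_COLUMNS)

    biomass_rows = []
    for path in truth.species_paths:
        for rkey in sorted(k for k in truth.effects["region"] if k[:3] == path):
            for skey in sorted(k for k in truth.effects["subregion"] if k[:4] == rkey):
                for bin_lo in _bin_los(cfg):
                    biomass_rows.append({
                        "species": path[2], "region": rkey[3],
                        "subregion": skey[4], "bin_lo_log10g": float(bin_lo),
                        "density_kg_km": float(
                            np.exp(rng.normal(math.log(50.0), 1.0))
                        ),
                    })
    biomass = pd.DataFrame(biomass_rows)
    return diet, biomass, truth


def simulate_group_table(cfg: SimConfig, seed: int | None = None):
    """Shortcut generator: draw the group-level PPMR table directly.

    Simulates log10 R from the linear mixed model itself (fixed curve +
    nested deviations + Normal(0, resid_sd) group noise), bypassing the
    stomach-level machinery.  Used for fast model-recovery studies; the
    returned truth carries the same effects so fitted parameters are
    directly comparable.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = make_truth(cfg, rng)
    rows = []
    for row in truth.group_truth.itertuples(index=False):
        u = row.bin_lo_log10g + 0.05
        log_r = math.log10(row.R_bio_true) + rng.normal(0, cfg.resid_sd)
        mass = 10.0 ** u
        rows.append({
            "species": row.species, "family": row.family, "order": row.order,
            "region": row.region, "subregion": row.subregion,
            "bin_lo_log10g": row.bin_lo_log10g,
            "n_pred": cfg.n_predators_per_group,
            "mean_mass_numw_g": mass, "mean_mass_biow_g": mass,
            "R_num": 10.0 ** (log_r + cfg.kernel_width_sigma ** 2 * LN10),
            "R_bio": 10.0 ** log_r,
            "fish_prop_mass": 0.0, "fish_prop_count": 0.0,
        })
    return pd.DataFrame(rows), truth
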