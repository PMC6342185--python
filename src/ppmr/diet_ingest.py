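"""Preprocessing of raw stomach-content records into analysis-ready data.

The steps mirror standard groundfish diet-database practice:

1. fit length-weight (LW) models to largely undigested (> digestion
   threshold) fish and crab prey that carry both mass and length;
2. reconstruct the undigested mass of partially digested fish/crab prey
   from their lengths via those models;
3. exclude remaining largely digested prey (< threshold intact);
4. impute individual prey masses for aggregated records: if both count and
   total mass were recorded, individuals get total/count; if only a total
   mass was recorded, individuals get the mean mass of that taxon/stage
   computed from fully enumerated records, with the count back-imputed;
5. estimate missing predator body mass from length via species-specific
   LW models fitted to predators with both measurements.

Every exclusion is written once to a drop log with a reason code, and
provenance flags on records make the whole pipeline idempotent.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientLWDataError, InvalidMeasurementError
from .records import LengthWeightModel, PredatorRecord, PreyRecord

DEFAULT_DIGESTION_THRESHOLD = 75.0
DEFAULT_LW_MIN_N = 10


@dataclass
class IngestConfig:
    digestion_threshold: float = DEFAULT_DIGESTION_THRESHOLD
    lw_min_n: int = DEFAULT_LW_MIN_N
    #: lookup order for mean-mass imputation; regional means first to keep
    #: spatial diet structure, then global per-stage, then per-taxon.
    mean_mass_fallback_order: tuple[str, ...] = (
        "taxon_stage_region", "taxon_stage", "taxon",
    )


@dataclass
class DropEntry:
    record_id: str
    reason: str


@dataclass
class DropLog:
    entries: list[DropEntry] = field(default_factory=list)

    def add(self, record_id: str, reason: str) -> None:
        self.entries.append(DropEntry(record_id, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.record_id, e.reason) for e in self.entries],
            columns=["record_id", "reason"],
        )

    def __len__(self) -> int:
        return len(self.entries)


def _prey_id(pred: PredatorRecord, prey: PreyRecord) -> str:
    return f"{pred.predator_id}/{prey.prey_taxon}/{prey.life_stage}"


def fit_length_weight(
    pairs,
    min_n: int = DEFAULT_LW_MIN_N,
    species_or_taxon: str = "",
    life_stage: str = "any",
) -> LengthWeightModel:
    """OLS fit of log10(mass) = log10(a) + b*log10(length).

    ``pairs`` is an iterable of (length, mass) tuples.  No back-transform
    bias correction is applied.
    """
    pairs = list(pairs)
    if len(pairs) < min_n:
        raise InsufficientLWDataError(
            f"{len(pairs)} length-weight pairs < required {min_n}",
            n=len(pairs), min_n=min_n,
        )
    lengths = np.asarray([p[0] for p in pairs], dtype=float)
    masses = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(lengths <= 0) or np.any(masses <= 0):
        raise InvalidMeasurementError("lengths and masses must be positive")
    if np.all(lengths == lengths[0]):
        raise InvalidMeasurementError("all lengths identical; slope undefined")
    res = stats.linregress(np.log10(lengths), np.log10(masses))
    return LengthWeightModel(
        species_or_taxon=species_or_taxon,
        life_stage=life_stage,
        coef_a=10.0 ** res.intercept,
        exponent_b=float(res.slope),
        n_fit=len(pairs),
    )


def reconstruct_digested_mass(
    prey: PreyRecord,
    lw: LengthWeightModel | None,
    threshold: float = DEFAULT_DIGESTION_THRESHOLD,
) -> PreyRecord:
    """Replace the digested mass of fish/crab prey with LW-predicted mass.

    Applies only to fish and crab prey below the digestion threshold with at
    least one individual length; otherwise the record passes through
    unchanged (and, when digested without a usable length, is flagged so the
    digestion filter will drop it).
    """
    if "mass_reconstructed" in prey.flags:
        return prey
    if prey.prey_group not in ("fish", "crab") or prey.pct_intact >= threshold:
        return prey
    if not prey.individual_lengths or lw is None:
        prey.flags.add("no-length-for-reconstruction")
        return prey
    prey.individual_masses = [lw.predict_mass(L) for L in prey.individual_lengths]
    prey.count = len(prey.individual_masses)
    prey.total_mass = float(sum(prey.individual_masses))
    prey.flags.add("mass_reconstructed")
    return prey


def filter_digestion(
    predators: list[PredatorRecord],
    threshold: float = DEFAULT_DIGESTION_THRESHOLD,
    drop_log: DropLog | None = None,
) -> tuple[list[PredatorRecord], DropLog]:
    """Exclude largely digested prey (strictly below ``threshold`` intact).

    Prey whose mass was reconstructed from length are retained.  Predators
    left with no prey are removed from downstream computation and logged.
    """
    log = drop_log if drop_log is not None else DropLog()
    kept: list[PredatorRecord] = []
    for pred in predators:
        retained = []
        for prey in pred.prey:
            if prey.pct_intact < threshold and "mass_reconstructed" not in prey.flags:
                log.add(_prey_id(pred, prey), "digested")
            else:
                retained.append(prey)
        pred.prey = retained
        if retained:
            kept.append(pred)
        else:
            log.add(pred.predator_id, "no-prey-after-digestion-filter")
    return kept, log


def build_mean_mass_table(predators: list[PredatorRecord]) -> dict:
    """Pooled mean prey mass per (taxon, stage, region), with coarser keys.

    Uses records that carry both a total mass and a count ("fully
    enumerated" aggregated records); the mean is total biomass over total
    count, pooled within each key.
    """
    sums: dict[tuple, list[float]] = {}

    def _acc(key, w, n):
        s = sums.setdefault(key, [0.0, 0.0])
        s[0] += w
        s[1] += n

    for pred in predators:
        for prey in pred.prey:
            if prey.individual_masses:
                w, n = sum(prey.individual_masses), len(prey.individual_masses)
            elif prey.total_mass is not None and prey.count is not None:
                w, n = prey.total_mass, prey.count
            else:
                continue
            _acc(("taxon_stage_region", prey.prey_taxon, prey.life_stage, pred.region), w, n)
            _acc(("taxon_stage", prey.prey_taxon, prey.life_stage), w, n)
            _acc(("taxon", prey.prey_taxon), w, n)
    return {k: v[0] / v[1] for k, v in sums.items() if v[1] > 0}


def lookup_mean_mass(
    table: dict,
    taxon: str,
    stage: str,
    region: str,
    fallback_order=IngestConfig().mean_mass_fallback_order,
) -> float | None:
    keys = {
        "taxon_stage_region": ("taxon_stage_region", taxon, stage, region),
        "taxon_stage": ("taxon_stage", taxon, stage),
        "taxon": ("taxon", taxon),
    }
    for level in fallback_order:
        val = table.get(keys[level])
        if val is not None:
            return val
    return None


def impute_prey_mass(
    prey: PreyRecord,
    mean_mass: float | None = None,
) -> PreyRecord:
    """Assign individual masses to an aggregated prey record.

    Case A (count and total mass recorded): every individual gets
    total/count.  Case B (total mass only): the count is imputed as
    round(total / mean_mass) with a floor of 1, and the recorded total is
    divided evenly across the imputed individuals — the measured biomass is
    preserved and only the count is inferred from the table mean.  Records
    that cannot be resolved are flagged ``unresolvable`` for the caller to
    drop.
    """
    if prey.individual_masses:
        return prey
    if prey.count is not None and prey.total_mass is not None:
        m = prey.total_mass / prey.count
        prey.individual_masses = [m] * prey.count
        prey.flags.add("mass_imputed")
        return prey
    if prey.total_mass is not None:
        if mean_mass is None:
            prey.flags.add("unresolvable")
            return prey
        n = max(1, round(prey.total_mass / mean_mass))
        prey.individual_masses = [prey.total_mass / n] * n
        prey.count = n
        prey.flags.add("count_imputed")
        prey.flags.add("mass_imputed")
        return prey
    prey.flags.add("unresolvable")
    return prey


def estimate_predator_mass(
    predator: PredatorRecord, lw: LengthWeightModel | None
) -> PredatorRecord:
    """Fill a missing predator body mass from length via the species LW model."""
    if predator.body_mass is not None:
        return predator
    if predator.body_length is None or predator.body_length <= 0:
        raise InvalidMeasurementError(
            f"predator {predator.predator_id}: no usable length"
        )
    if lw is None:
        predator.flags.add("no-LW-model")
        return predator
    predator.body_mass = lw.predict_mass(predator.body_length)
    predator.flags.add("mass_estimated")
    return predator


def _fit_prey_lw_models(
    predators: list[PredatorRecord], cfg: IngestConfig
) -> dict[tuple[str, str], LengthWeightModel]:
    """LW models per (taxon, stage) from intact fish/crab prey; pooled-stage
    fallback under key (taxon, "any")."""
    pairs: dict[tuple[str, str], list] = {}
    for pred in predators:
        for prey in pred.prey:
            if prey.prey_group not in ("fish", "crab"):
                continue
            if prey.pct_intact < cfg.digestion_threshold:
                continue
            if len(prey.individual_masses) != len(prey.individual_lengths):
                continue
            for L, m in zip(prey.individual_lengths, prey.individual_masses):
                pairs.setdefault((prey.prey_taxon, prey.life_stage), []).append((L, m))
                pairs.setdefault((prey.prey_taxon, "any"), []).append((L, m))
    models = {}
    for key, pts in pairs.items():
        try:
            models[key] = fit_length_weight(
                pts, min_n=cfg.lw_min_n,
                species_or_taxon=key[0], life_stage=key[1],
            )
        except (InsufficientLWDataError, InvalidMeasurementError):
            continue
    return models


def _fit_predator_lw_models(
    predators: list[PredatorRecord], cfg: IngestConfig
) -> dict[str, LengthWeightModel]:
    pairs: dict[str, list] = {}
    for pred in predators:
        if pred.body_mass is not None and pred.body_length is not None:
            pairs.setdefault(pred.species, []).append((pred.body_length, pred.body_mass))
    models = {}
    for sp, pts in pairs.items():
        try:
            models[sp] = fit_length_weight(pts, min_n=cfg.lw_min_n, species_or_taxon=sp)
        except (InsufficientLWDataError, InvalidMeasurementError):
            continue
    return models


def preprocess(
    predators: list[PredatorRecord],
    cfg: IngestConfig | None = None,
    copy_input: bool = True,
) -> tuple[list[PredatorRecord], DropLog]:
    """Run the full preprocessing chain; returns (clean predators, drop log).

    The input list is deep-copied by default so no stage mutates its input.
    Re-running on its own output is a no-op (provenance flags gate every
    transforming step).
    """
    cfg = cfg or IngestConfig()
    if copy_input:
        predators = copy.deepcopy(predators)
    log = DropLog()

    prey_lw = _fit_prey_lw_models(predators, cfg)
    for pred in predators:
        for prey in pred.prey:
            lw = prey_lw.get((prey.prey_taxon, prey.life_stage)) or prey_lw.get(
                (prey.prey_taxon, "any")
            )
            reconstruct_digested_mass(prey, lw, threshold=cfg.digestion_threshold)

    predators, log = filter_digestion(predators, cfg.digestion_threshold, log)

    table = build_mean_mass_table(predators)
    for pred in predators:
        resolved = []
        for prey in pred.prey:
            mean = lookup_mean_mass(
                table, prey.prey_taxon, prey.life_stage, pred.region,
                cfg.mean_mass_fallback_order,
            )
            impute_prey_mass(prey, mean)
            if "unresolvable" in prey.flags:
                log.add(_prey_id(pred, prey), "unresolvable")
            else:
                resolved.append(prey)
        pred.prey = resolved

    pred_lw = _fit_predator_lw_models(predators, cfg)
    clean: list[PredatorRecord] = []
    for pred in predators:
        if not pred.prey:
            log.add(pred.predator_id, "no-prey-after-imputation")
            continue
        if pred.body_mass is None:
            try:
                estimate_predator_mass(pred, pred_lw.get(pred.species))
            except InvalidMeasurementError:
                log.add(pred.predator_id, "invalid-measurement")
                continue
            if pred.body_mass is None:
                log.add(pred.predator_id, "no-LW-model-for-predator")
                continue
        clean.append(pred)
    return clean, log
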