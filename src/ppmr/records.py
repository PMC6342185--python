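"""Domain records for individual diet data.

A :class:`PredatorRecord` is one sampled predator (with its taxonomy, spatial
labels and body size) holding a list of :class:`PreyRecord` observations from
its stomach.  Masses are grams throughout; predator length is cm, prey length
mm (trawl-survey convention).  Provenance flags accumulate on records as
preprocessing steps touch them, which both documents what happened and makes
the preprocessing idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Recognised prey groups; only fish and crab prey ever have their digested
#: mass reconstructed from length.
PREY_GROUPS = ("fish", "crab", "other_invert")

DIET_COLUMNS = [
    "predator_id", "species", "family", "order", "region", "subregion",
    "pred_mass_g", "pred_length_cm", "prey_taxon", "life_stage",
    "prey_count", "prey_total_mass_g", "prey_ind_mass_g",
    "prey_ind_length_mm", "pct_intact", "prey_group",
]


@dataclass
class PreyRecord:
    """One prey observation (one taxon x life stage) inside one stomach."""

    prey_taxon: str
    life_stage: str
    count: int | None = None
    total_mass: float | None = None          # grams
    individual_masses: list[float] = field(default_factory=list)   # grams
    individual_lengths: list[float] = field(default_factory=list)  # mm
    pct_intact: float = 100.0
    prey_group: str = "other_invert"
    flags: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if self.count is not None and self.count < 1:
            raise SchemaError(f"prey count must be >= 1, got {self.count}")
        for m in self.individual_masses:
            if m <= 0:
                raise SchemaError(f"non-positive prey mass {m}")
        if self.total_mass is not None and self.total_mass <= 0:
            raise SchemaError(f"non-positive total mass {self.total_mass}")
        if not 0 <= self.pct_intact <= 100:
            raise SchemaError(f"pct_intact outside [0, 100]: {self.pct_intact}")
        if self.prey_group not in PREY_GROUPS:
            raise SchemaError(f"unknown prey group {self.prey_group!r}")
        # tolerance absorbs CSV round-tripping at 6 significant digits
        if self.individual_masses and self.total_mass is not None:
            if sum(self.individual_masses) > self.total_mass * (1 + 1e-3):
                raise SchemaError(
                    "individual masses exceed recorded total mass "
                    f"for {self.prey_taxon}"
                )


@dataclass
class PredatorRecord:
    """One sampled predator with taxonomy, location, body size and prey."""

    predator_id: str
    species: str
    family: str
    order: str
    region: str
    subregion: str
    body_mass: float | None = None     # grams
    body_length: float | None = None   # cm
    prey: list[PreyRecord] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if self.body_mass is None and self.body_length is None:
            raise SchemaError(
                f"predator {self.predator_id}: neither mass nor length present"
            )
        for p in self.prey:
            p.validate()


@dataclass
class LengthWeightModel:
    """Allometric mass-at-length model, mass = a * L**b on natural scale.

    Fitted by ordinary least squares on log10(mass) vs log10(length).  Unit
    convention is fixed by the table the model came from: g per mm**b for
    prey, g per cm**b for predators.
    """

    species_or_taxon: str
    life_stage: str = "any"
    coef_a: float = 0.0
    exponent_b: float = 0.0
    n_fit: int = 0

    def predict_mass(self, length: float) -> float:
        return self.coef_a * length ** self.exponent_b


def _split_list(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return [float(tok) for tok in str(cell).split(";") if tok != ""]


def _join_list(values) -> str:
    return ";".join(format(v, ".6g") for v in values)


def _opt_float(cell) -> float | None:
    if cell is None or cell == "":
        return None
    v = float(cell)
    return None if np.isnan(v) else v


def _opt_int(cell) -> int | None:
    v = _opt_float(cell)
    return None if v is None else int(round(v))


def read_diet_csv(path) -> list[PredatorRecord]:
    """Read a raw diet table (one row per prey record) into predator records.

    Raises :class:`SchemaError` naming any unknown or missing column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in DIET_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s) in diet CSV: {', '.join(unknown)}")
    missing = [c for c in DIET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) in diet CSV: {', '.join(missing)}")
    return frame_to_predators(df)


def frame_to_predators(df: pd.DataFrame) -> list[PredatorRecord]:
    predators: dict[str, PredatorRecord] = {}
    fam_of_species: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header=line 1
        try:
            pid = str(row.predator_id)
            if pid not in predators:
                predators[pid] = PredatorRecord(
                    predator_id=pid,
                    species=row.species, family=row.family, order=row.order,
                    region=row.region, subregion=row.subregion,
                    body_mass=_opt_float(row.pred_mass_g),
                    body_length=_opt_float(row.pred_length_cm),
                )
                prev = fam_of_species.setdefault(row.species, row.family)
                if prev != row.family:
                    raise SchemaError(
                        f"species {row.species!r} appears under two families"
                    )
            if row.prey_taxon == "":
                continue  # predator row with an empty stomach
            prey = PreyRecord(
                prey_taxon=row.prey_taxon,
                life_stage=row.life_stage or "any",
                count=_opt_int(row.prey_count),
                total_mass=_opt_float(row.prey_total_mass_g),
                individual_masses=_split_list(row.prey_ind_mass_g),
                individual_lengths=_split_list(row.prey_ind_length_mm),
                pct_intact=float(row.pct_intact) if row.pct_intact != "" else 100.0,
                prey_group=row.prey_group,
            )
            predators[pid].prey.append(prey)
        except SchemaError as err:
            raise SchemaError(f"row {i}: {err}") from None
        except ValueError as err:
            raise SchemaError(f"row {i}: {err}") from None
    for rec in predators.values():
        rec.validate()
    return list(predators.values())


def predators_to_frame(predators: list[PredatorRecord]) -> pd.DataFrame:
    """Flatten predator records back to the one-row-per-prey CSV schema."""
    rows = []
    for pred in predators:
        base = dict(
            predator_id=pred.predator_id, species=pred.species,
            family=pred.family, order=pred.order,
            region=pred.region, subregion=pred.subregion,
            pred_mass_g="" if pred.body_mass is None else format(pred.body_mass, ".6g"),
            pred_length_cm="" if pred.body_length is None else format(pred.body_length, ".6g"),
        )
        if not pred.prey:
            rows.append({**base, "prey_taxon": "", "life_stage": "",
                         "prey_count": "", "prey_total_mass_g": "",
                         "prey_ind_mass_g": "", "prey_ind_length_mm": "",
                         "pct_intact": "", "prey_group": ""})
        for p in pred.prey:
            rows.append({
                **base,
                "prey_taxon": p.prey_taxon,
                "life_stage": p.life_stage,
                "prey_count": "" if p.count is None else str(p.count),
                "prey_total_mass_g": "" if p.total_mass is None else format(p.total_mass, ".6g"),
                "prey_ind_mass_g": _join_list(p.individual_masses),
                "prey_ind_length_mm": _join_list(p.individual_lengths),
                "pct_intact": format(p.pct_intact, ".6g"),
                "prey_group": p.prey_group,
            })
    return pd.DataFrame(rows, columns=DIET_COLUMNS)
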