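"""Delta/Delta-cap arithmetic, per-plant Cd mass balance and treatment averaging.

Conventions
-----------
* delta114 values are permil deviations of the 114Cd/110Cd ratio from the
  bracketing isotope standard (NIST SRM-3108).
* Uncertainties are stored as 2sd (the reporting convention of MC-ICP-MS
  work); inverse-variance weights use sigma = two_sd / 2.
* Units are fixed: dry mass g, concentration mg/kg dry weight, Cd mass ug,
  delta and Delta in permil.

A plant record holds up to three organ measurements (root, stem, leaf).
``plant_totals`` turns it into organ Cd masses, a Cd-mass-weighted total
delta, partition fractions f and the translocation factor; ``treatment_summary``
computes within-plant fractionations (Delta pairs and the per-plant
sequestration-mobilisation epsilon) first and then averages across biological
replicates, inverse-variance weighting the isotope quantities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORGANS",
    "DELTA_KEYS",
    "DeltaValue",
    "OrganMeasurement",
    "PlantRecord",
    "PlantDerived",
    "SolutionState",
    "TreatmentSummary",
    "delta_from_ratio",
    "ratio_from_delta",
    "capital_delta",
    "ivw_mean",
    "organ_cd_mass",
    "plant_totals",
    "translocation_factor",
    "plant_fractionation",
    "treatment_summary",
    "grand_means",
    "summaries_to_frame",
    "derived_to_frame",
    "plants_from_frame",
    "solution_after_uptake",
    "final_solution_state",
]

ORGANS = ("root", "stem", "leaf")

#: Within-plant / plant-solution fractionation pairs reported by the pipeline.
DELTA_KEYS = ("leaf_stem", "stem_root", "leaf_root", "tot_sol", "leaf_tot", "shoot_tot")


@dataclass(frozen=True)
class DeltaValue:
    """A delta114 value (permil) with its analytical 2sd and replicate count."""

    value: float
    two_sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.two_sd < 0:
            raise ValueError("two_sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")

    @property
    def sigma(self) -> float:
        """1sd in permil."""
        return self.two_sd / 2.0


def _as_delta(x: "DeltaValue | float") -> DeltaValue:
    return x if isinstance(x, DeltaValue) else DeltaValue(float(x))


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Permil deviation of a sample ratio from the standard ratio."""
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be strictly positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta_permil: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if r_standard <= 0:
        raise ValueError("standard ratio must be strictly positive")
    return (delta_permil / 1000.0 + 1.0) * r_standard


def capital_delta(delta_a: "DeltaValue | float", delta_b: "DeltaValue | float") -> DeltaValue:
    """Apparent fractionation between two pools: delta_A - delta_B.

    The 2sd of the difference combines the two uncertainties in quadrature.
    """
    a, b = _as_delta(delta_a), _as_delta(delta_b)
    return DeltaValue(
        a.value - b.value,
        math.hypot(a.two_sd, b.two_sd),
        n=min(a.n, b.n),
    )


def ivw_mean(values: Sequence[DeltaValue]) -> DeltaValue:
    """Inverse-variance weighted mean of replicate delta values.

    Weights are 1/sigma^2 with sigma = two_sd/2; the combined 2sd is
    2/sqrt(sum of weights). If any input lacks a positive uncertainty the
    mean degrades to equal weighting (flagged by a warning) and the combined
    2sd to the rms spread convention sd of the values.
    """
    values = list(values)
    if not values:
        raise ValueError("ivw_mean of an empty sequence")
    if len(values) == 1:
        return values[0]
    x = np.array([v.value for v in values])
    sig = np.array([v.sigma for v in values])
    n_total = sum(v.n for v in values)
    if np.any(sig <= 0):
        warnings.warn(
            "missing uncertainties: falling back to the unweighted mean", stacklevel=2
        )
        return DeltaValue(float(x.mean()), float(2.0 * x.std(ddof=1)), n=n_total)
    w = 1.0 / sig**2
    mean = float(np.dot(w, x) / w.sum())
    return DeltaValue(mean, float(2.0 / math.sqrt(w.sum())), n=n_total)


@dataclass(frozen=True)
class OrganMeasurement:
    """One organ's dry biomass, Cd concentration and isotope composition."""

    organ: str
    dry_mass_g: float
    conc_mg_per_kg: float
    delta: DeltaValue

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"organ must be one of {ORGANS}, got {self.organ!r}")
        if self.dry_mass_g <= 0:
            raise ValueError("dry_mass_g must be positive")
        if self.conc_mg_per_kg < 0:
            raise ValueError("conc_mg_per_kg must be non-negative")


@dataclass(frozen=True)
class PlantRecord:
    """A replicate plant: its treatment design flags and organ measurements."""

    treatment_id: str
    replicate_id: str
    organs: Mapping[str, OrganMeasurement]
    hydro_fe: bool = False
    hydro_zn: bool = False
    foliar_fe: bool = False
    foliar_zn: bool = False

    def __post_init__(self) -> None:
        if not self.organs:
            raise ValueError("a plant record needs at least one organ")
        for key, meas in self.organs.items():
            if key != meas.organ:
                raise ValueError(f"organ key {key!r} does not match measurement {meas.organ!r}")


def organ_cd_mass(m: OrganMeasurement) -> float:
    """Cd mass (ug) in one organ: conc (mg/kg) x dry mass (g)."""
    return m.conc_mg_per_kg * m.dry_mass_g


@dataclass(frozen=True)
class PlantDerived:
    """Mass-balance quantities derived from one plant record."""

    treatment_id: str
    replicate_id: str
    cd_mass_per_organ: Mapping[str, float]  # ug
    total_cd_ug: float
    delta_total: DeltaValue
    fractions: Mapping[str, float]  # of total plant Cd, over present organs
    f_shoot: float
    tf_percent: float | None  # None when the root is missing
    missing_organs: tuple[str, ...] = ()
    hydro_fe: bool = False
    hydro_zn: bool = False
    foliar_fe: bool = False
    foliar_zn: bool = False


def plant_totals(p: PlantRecord) -> PlantDerived:
    """Total Cd, Cd-mass-weighted total delta, partition fractions and TF.

    Plants missing an organ are handled: fractions are computed over the
    organs present and the record is flagged through ``missing_organs``
    (TF additionally requires the root).
    """
    masses = {organ: organ_cd_mass(m) for organ, m in p.organs.items()}
    total = sum(masses.values())
    if total <= 0:
        raise ValueError(f"plant {p.treatment_id}/{p.replicate_id} carries no Cd")
    weights = {organ: mass / total for organ, mass in masses.items()}
    mean = sum(w * p.organs[o].delta.value for o, w in weights.items())
    two_sd = math.sqrt(sum((w * p.organs[o].delta.two_sd) ** 2 for o, w in weights.items()))
    fractions = dict(weights)
    f_shoot = fractions.get("leaf", 0.0) + fractions.get("stem", 0.0)
    missing = tuple(o for o in ORGANS if o not in p.organs)
    tf: float | None = None
    if "root" in masses and masses["root"] > 0:
        tf = (masses.get("leaf", 0.0) + masses.get("stem", 0.0)) / masses["root"] * 100.0
    return PlantDerived(
        treatment_id=p.treatment_id,
        replicate_id=p.replicate_id,
        cd_mass_per_organ=masses,
        total_cd_ug=total,
        delta_total=DeltaValue(mean, two_sd),
        fractions=fractions,
        f_shoot=f_shoot,
        tf_percent=tf,
        missing_organs=missing,
        hydro_fe=p.hydro_fe,
        hydro_zn=p.hydro_zn,
        foliar_fe=p.foliar_fe,
        foliar_zn=p.foliar_zn,
    )


def translocation_factor(d: PlantDerived) -> float:
    """(leaf Cd + stem Cd) / root Cd x 100, the root-to-shoot TF in percent."""
    root = d.cd_mass_per_organ.get("root", 0.0)
    if root <= 0:
        raise ValueError("translocation factor undefined: no root Cd mass")
    shoot = d.cd_mass_per_organ.get("leaf", 0.0) + d.cd_mass_per_organ.get("stem", 0.0)
    return shoot / root * 100.0


def plant_fractionation(
    p: PlantRecord, delta_sol: "DeltaValue | float"
) -> tuple[PlantDerived, dict[str, DeltaValue], float | None]:
    """Per-plant Delta pairs and the sequestration-mobilisation epsilon.

    Returns the derived mass balance, the Delta set (leaf-stem, stem-root,
    leaf-root, total-solution, leaf-total, shoot-total, permil) and the
    per-plant epsilon_seq-mob = Delta_leaf-tot / ln f_leaf (leaf as sink,
    total plant as source; None when leaf data are missing or f_leaf = 1).
    """
    derived = plant_totals(p)
    sol = _as_delta(delta_sol)
    d = {o: p.organs[o].delta for o in p.organs}
    out: dict[str, DeltaValue] = {}
    if "leaf" in d and "stem" in d:
        out["leaf_stem"] = capital_delta(d["leaf"], d["stem"])
    if "stem" in d and "root" in d:
        out["stem_root"] = capital_delta(d["stem"], d["root"])
    if "leaf" in d and "root" in d:
        out["leaf_root"] = capital_delta(d["leaf"], d["root"])
    out["tot_sol"] = capital_delta(derived.delta_total, sol)
    if "leaf" in d:
        out["leaf_tot"] = capital_delta(d["leaf"], derived.delta_total)
    if not derived.missing_organs:
        shoot_mass = derived.cd_mass_per_organ["leaf"] + derived.cd_mass_per_organ["stem"]
        wl = derived.cd_mass_per_organ["leaf"] / shoot_mass
        ws = derived.cd_mass_per_organ["stem"] / shoot_mass
        delta_shoot = DeltaValue(
            wl * d["leaf"].value + ws * d["stem"].value,
            math.hypot(wl * d["leaf"].two_sd, ws * d["stem"].two_sd),
        )
        out["shoot_tot"] = capital_delta(delta_shoot, derived.delta_total)
    eps: float | None = None
    f_leaf = derived.fractions.get("leaf")
    if f_leaf is not None and 0.0 < f_leaf < 1.0:
        eps = out["leaf_tot"].value / math.log(f_leaf)
    return derived, out, eps


@dataclass(frozen=True)
class TreatmentSummary:
    """Replicate-averaged quantities for one treatment."""

    treatment_id: str
    n_plants: int
    replicate_ids: tuple[str, ...]
    hydro_fe: bool
    hydro_zn: bool
    foliar_fe: bool
    foliar_zn: bool
    delta_organ: Mapping[str, DeltaValue]  # ivw across replicates
    delta_total: DeltaValue
    conc_organ: Mapping[str, float]  # arithmetic mean, mg/kg
    cd_total_ug: float  # arithmetic mean, ug
    deltas: Mapping[str, DeltaValue]  # per-plant Delta pairs, ivw-averaged
    eps_seq_mob: float | None  # arithmetic mean of per-plant epsilons
    tf_percent: float | None
    fractions: Mapping[str, float]
    f_shoot: float


def treatment_summary(
    plants: Iterable[PlantRecord], delta_sol: "DeltaValue | float"
) -> list[TreatmentSummary]:
    """Summarise replicate plants per treatment.

    Fractionations are computed per plant first and then averaged across the
    biological replicates of each treatment — inverse-variance weighting for
    the isotope quantities, arithmetic means for masses, concentrations,
    fractions, TF and epsilon.
    """
    plants = list(plants)
    if not plants:
        raise ValueError("no plants supplied")
    by_treatment: dict[str, list[PlantRecord]] = {}
    for p in plants:
        by_treatment.setdefault(p.treatment_id, []).append(p)

    summaries = []
    for tid, group in by_treatment.items():
        per_plant = [plant_fractionation(p, delta_sol) for p in group]
        deriveds = [d for d, _, _ in per_plant]
        delta_organ = {
            o: ivw_mean([p.organs[o].delta for p in group if o in p.organs])
            for o in ORGANS
            if any(o in p.organs for p in group)
        }
        conc_organ = {
            o: float(np.mean([p.organs[o].conc_mg_per_kg for p in group if o in p.organs]))
            for o in ORGANS
            if any(o in p.organs for p in group)
        }
        delta_keys = set().union(*(set(ds) for _, ds, _ in per_plant))
        deltas = {
            k: ivw_mean([ds[k] for _, ds, _ in per_plant if k in ds])
            for k in DELTA_KEYS
            if k in delta_keys
        }
        eps_values = [e for _, _, e in per_plant if e is not None]
        tf_values = [d.tf_percent for d in deriveds if d.tf_percent is not None]
        organs_present = set().union(*(set(d.fractions) for d in deriveds))
        fractions = {
            o: float(np.mean([d.fractions[o] for d in deriveds if o in d.fractions]))
            for o in organs_present
        }
        first = group[0]
        summaries.append(
            TreatmentSummary(
                treatment_id=tid,
                n_plants=len(group),
                replicate_ids=tuple(p.replicate_id for p in group),
                hydro_fe=first.hydro_fe,
                hydro_zn=first.hydro_zn,
                foliar_fe=first.foliar_fe,
                foliar_zn=first.foliar_zn,
                delta_organ=delta_organ,
                delta_total=ivw_mean([d.delta_total for d in deriveds]),
                conc_organ=conc_organ,
                cd_total_ug=float(np.mean([d.total_cd_ug for d in deriveds])),
                deltas=deltas,
                eps_seq_mob=float(np.mean(eps_values)) if eps_values else None,
                tf_percent=float(np.mean(tf_values)) if tf_values else None,
                fractions=fractions,
                f_shoot=float(np.mean([d.f_shoot for d in deriveds])),
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[TreatmentSummary]) -> pd.DataFrame:
    """Flatten treatment summaries into one row per treatment."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "treatment_id": s.treatment_id,
            "n_plants": s.n_plants,
            "hydro_fe": s.hydro_fe,
            "hydro_zn": s.hydro_zn,
            "foliar_fe": s.foliar_fe,
            "foliar_zn": s.foliar_zn,
            "cd_total_ug": s.cd_total_ug,
            "tf_percent": s.tf_percent,
            "f_shoot": s.f_shoot,
            "eps_seq_mob": s.eps_seq_mob,
        }
        for o in ORGANS:
            if o in s.conc_organ:
                row[f"conc_{o}"] = s.conc_organ[o]
            if o in s.delta_organ:
                row[f"delta_{o}"] = s.delta_organ[o].value
            if o in s.fractions:
                row[f"f_{o}"] = s.fractions[o]
        row["delta_total"] = s.delta_total.value
        for k in DELTA_KEYS:
            if k in s.deltas:
                row[f"d_{k}"] = s.deltas[k].value
        rows.append(row)
    return pd.DataFrame(rows).sort_values("treatment_id").reset_index(drop=True)


def grand_means(frame: pd.DataFrame) -> pd.Series:
    """Across-treatment arithmetic means of every numeric summary column."""
    return frame.select_dtypes("number").mean()


def derived_to_frame(deriveds: Sequence[PlantDerived]) -> pd.DataFrame:
    """One row per plant with masses, fractions, delta_total and TF."""
    rows = []
    for d in deriveds:
        row: dict[str, object] = {
            "treatment_id": d.treatment_id,
            "replicate_id": d.replicate_id,
            "hydro_fe": d.hydro_fe,
            "hydro_zn": d.hydro_zn,
            "foliar_fe": d.foliar_fe,
            "foliar_zn": d.foliar_zn,
            "total_cd_ug": d.total_cd_ug,
            "delta_total": d.delta_total.value,
            "delta_total_2sd": d.delta_total.two_sd,
            "f_shoot": d.f_shoot,
            "tf_percent": d.tf_percent,
        }
        for o in ORGANS:
            row[f"cd_{o}_ug"] = d.cd_mass_per_organ.get(o)
            row[f"f_{o}"] = d.fractions.get(o)
        rows.append(row)
    return pd.DataFrame(rows)


def plants_from_frame(df: pd.DataFrame) -> list[PlantRecord]:
    """Build plant records from the long-format plants table.

    Expected columns: treatment_id, replicate_id, hydro_fe, hydro_zn,
    foliar_fe, foliar_zn, organ, dry_mass_g, conc_mg_per_kg, delta114_permil,
    two_sd_permil.
    """
    records = []
    for (tid, rid), g in df.groupby(["treatment_id", "replicate_id"], sort=True):
        organs = {}
        for _, row in g.iterrows():
            organs[row["organ"]] = OrganMeasurement(
                organ=row["organ"],
                dry_mass_g=float(row["dry_mass_g"]),
                conc_mg_per_kg=float(row["conc_mg_per_kg"]),
                delta=DeltaValue(float(row["delta114_permil"]), float(row["two_sd_permil"])),
            )
        first = g.iloc[0]
        records.append(
            PlantRecord(
                treatment_id=str(tid),
                replicate_id=str(rid),
                organs=organs,
                hydro_fe=bool(first["hydro_fe"]),
                hydro_zn=bool(first["hydro_zn"]),
                foliar_fe=bool(first["foliar_fe"]),
                foliar_zn=bool(first["foliar_zn"]),
            )
        )
    return records


@dataclass(frozen=True)
class SolutionState:
    """Closed-reservoir bookkeeping for one hydroponic container."""

    delta_init: DeltaValue
    cd_mass_init_ug: float
    delta_final: float
    f_remaining: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_remaining <= 1.0:
            raise ValueError("f_remaining must lie in (0, 1]")


def solution_after_uptake(
    delta_init: float, delta_removed: float, f_remaining: float
) -> float:
    """Final-solution delta by exact two-pool mass balance.

    Solves f*delta_final + (1-f)*delta_removed = delta_init for delta_final.
    """
    if not 0.0 < f_remaining <= 1.0:
        raise ValueError("f_remaining must lie in (0, 1]")
    if f_remaining == 1.0:
        return delta_init
    return (delta_init - (1.0 - f_remaining) * delta_removed) / f_remaining


def final_solution_state(
    delta_init: "DeltaValue | float",
    cd_mass_init_ug: float,
    plants: Sequence[PlantDerived],
) -> SolutionState:
    """Reservoir state after the plants of one container have taken up Cd.

    The removed pool is the Cd-mass-weighted blend of the plants' total
    deltas; adsorption to root surfaces is neglected.
    """
    if cd_mass_init_ug <= 0:
        raise ValueError("initial solution Cd mass must be positive")
    init = _as_delta(delta_init)
    taken = sum(p.total_cd_ug for p in plants)
    if taken >= cd_mass_init_ug:
        raise ValueError(
            f"plants contain {taken:.1f} ug Cd, more than the {cd_mass_init_ug:.1f} ug reservoir"
        )
    f = 1.0 - taken / cd_mass_init_ug
    if taken == 0:
        return SolutionState(init, cd_mass_init_ug, init.value, 1.0)
    delta_plants = sum(p.total_cd_ug * p.delta_total.value for p in plants) / taken
    return SolutionState(
        init,
        cd_mass_init_ug,
        solution_after_uptake(init.value, delta_plants, f),
        f,
    )
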