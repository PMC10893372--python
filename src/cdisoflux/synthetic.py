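"""Synthetic closed-system hydroponic Cd experiments.

Generates complete experiments with the statistical structure the analysis
pipeline assumes, so every downstream stage can be exercised and calibrated
without any external data:

* a finite Cd reservoir per treatment container (3 L x 2.25 mg/L by
  default) starting at delta114Cd = -0.36 permil;
* uptake of a few percent of the reservoir by three plants, fractionating
  by eps_uptake (~-0.29 permil) as a single closed-system Rayleigh step, so
  the plants' pooled Cd follows the accumulated-product composition and the
  residual solution closes the mass balance exactly;
* within-plant partitioning in which the leaf (sink) obeys
  Delta_leaf-tot = eps_seq_mob * ln f_leaf exactly at zero noise, the stem
  sits a configurable leaf-stem offset below the leaf, and the root closes
  the plant's isotope mass balance;
* a phenomenological hydroponic-Fe effect: higher uptake (x multiplier,
  geometrically centred so the cross-treatment mean stays at the base
  uptake fraction) and a higher shoot fraction, reproducing the observed
  grouping (Fe-present plants above ~100 ug Cd and TF > 100%, Fe-absent
  below);
* Gaussian analytical noise applied last (2sd ~0.05 permil on delta,
  ~5% relative on concentrations).

Ground truth (per-treatment uptake fractions, per-plant fractions and
noise-free compositions) is emitted alongside the measurement tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .double_spike import IsotopeSystem, alpha_from_delta, forward_mix
from .rayleigh import accumulated_product_delta
from .tables import treatment_design

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_experiment",
    "synthesize_spiked_measurement",
    "default_treatments",
]

PLANTS_COLUMNS = [
    "treatment_id", "replicate_id",
    "hydro_fe", "hydro_zn", "foliar_fe", "foliar_zn",
    "organ", "dry_mass_g", "conc_mg_per_kg", "delta114_permil", "two_sd_permil",
]


def default_treatments() -> tuple[tuple[str, bool, bool, bool, bool], ...]:
    """The eight-treatment Fe/Zn design, as (id, hydro_fe, hydro_zn, foliar_fe, foliar_zn)."""
    return tuple(treatment_design().itertuples(index=False, name=None))


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of one synthetic experiment.

    Defaults are the study conditions of the emulated hydroponic design:
    3 L of solution at 2.25 mg/L Cd per container of three seedlings,
    delta_init = -0.36 permil, mean container uptake 5% with an Fe
    multiplier of 1.7, eps_uptake = -0.29 permil, eps_seq_mob = -0.13
    permil, total dry biomass 0.57-0.99 g of which leaves carry 63-78%,
    and analytical noise of 0.05 permil (2sd) on delta and 5% (relative sd)
    on concentrations.
    """

    treatments: tuple[tuple[str, bool, bool, bool, bool], ...] = field(
        default_factory=default_treatments
    )
    replicates_grown: int = 3
    replicates_analysed: int = 2
    solution_volume_l: float = 3.0
    solution_conc_mg_per_l: float = 2.25
    delta_init: float = -0.36
    delta_init_2sd: float = 0.04
    epsilon_uptake: float = -0.29
    epsilon_seq_mob: float = -0.13
    base_uptake_fraction: float = 0.05  # of the reservoir, per 3-plant container
    uptake_spread: float = 0.2  # relative uniform jitter on the uptake fraction
    fe_uptake_multiplier: float = 1.7
    f_shoot_fe: float = 0.55  # mean shoot Cd fraction with hydroponic Fe
    fe_fshoot_shift: float = 0.25  # subtracted without hydroponic Fe
    f_shoot_jitter: float = 0.05
    leaf_share_of_shoot: float = 0.65
    leaf_share_jitter: float = 0.05
    delta_leaf_stem: float = 0.23  # permil, within-shoot offset
    biomass_total_g: tuple[float, float] = (0.57, 0.99)
    leaf_biomass_share: tuple[float, float] = (0.63, 0.78)
    stem_share_of_rest: tuple[float, float] = (0.4, 0.6)
    noise_delta_2sd: float = 0.05  # permil
    noise_conc_rel: float = 0.05  # relative sd

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ValueError("at least one treatment is required")
        if not 0 < self.base_uptake_fraction < 0.5:
            raise ValueError("base_uptake_fraction must lie in (0, 0.5)")
        if self.fe_uptake_multiplier <= 0:
            raise ValueError("fe_uptake_multiplier must be positive")
        if not 1 <= self.replicates_analysed <= self.replicates_grown:
            raise ValueError("replicates_analysed must be in [1, replicates_grown]")
        for name in ("f_shoot_fe", "leaf_share_of_shoot"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 < self.f_shoot_fe - self.fe_fshoot_shift < 1:
            raise ValueError("fe_fshoot_shift pushes the shoot fraction out of (0, 1)")

    @property
    def reservoir_cd_ug(self) -> float:
        return self.solution_volume_l * self.solution_conc_mg_per_l * 1000.0


@dataclass
class SimResult:
    """Measurement tables plus the generating ground truth."""

    plants: pd.DataFrame  # long format, analysed replicates only
    solutions: pd.DataFrame  # one row per treatment container
    truth: dict


def _simulate_plant(
    cfg: SimConfig, rng: np.random.Generator, hydro_fe: bool, delta_tot: float
) -> dict:
    """Noise-free partitioning and biomass of a single plant."""
    f_shoot_mean = cfg.f_shoot_fe - (0.0 if hydro_fe else cfg.fe_fshoot_shift)
    f_shoot = float(
        np.clip(f_shoot_mean + rng.uniform(-1, 1) * cfg.f_shoot_jitter, 0.05, 0.90)
    )
    leaf_share = float(
        np.clip(
            cfg.leaf_share_of_shoot + rng.uniform(-1, 1) * cfg.leaf_share_jitter,
            0.05,
            0.95,
        )
    )
    f_leaf = f_shoot * leaf_share
    f_stem = f_shoot - f_leaf
    f_root = 1.0 - f_shoot

    delta_leaf = delta_tot + cfg.epsilon_seq_mob * math.log(f_leaf)
    delta_stem = delta_leaf - cfg.delta_leaf_stem
    delta_root = (delta_tot - f_leaf * delta_leaf - f_stem * delta_stem) / f_root

    mass_total = rng.uniform(*cfg.biomass_total_g)
    mass_leaf = mass_total * rng.uniform(*cfg.leaf_biomass_share)
    rest = mass_total - mass_leaf
    mass_stem = rest * rng.uniform(*cfg.stem_share_of_rest)
    mass_root = rest - mass_stem

    return {
        "fractions": {"root": f_root, "stem": f_stem, "leaf": f_leaf},
        "deltas": {"root": delta_root, "stem": delta_stem, "leaf": delta_leaf},
        "dry_mass_g": {"root": mass_root, "stem": mass_stem, "leaf": mass_leaf},
        "delta_total": delta_tot,
    }


def simulate_experiment(config: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Generate one synthetic experiment.

    Identical (config, seed) pairs give bit-identical outputs. All random
    draws are consumed in a fixed order regardless of which replicates end
    up in the analysed subset.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    sqrt_mult = math.sqrt(cfg.fe_uptake_multiplier)

    plant_rows: list[dict] = []
    solution_rows: list[dict] = []
    truth_treatments: list[dict] = []

    for tid, hydro_fe, hydro_zn, foliar_fe, foliar_zn in cfg.treatments:
        mult = sqrt_mult if hydro_fe else 1.0 / sqrt_mult
        uptake = cfg.base_uptake_fraction * mult * (
            1.0 + rng.uniform(-1, 1) * cfg.uptake_spread
        )
        uptake = float(np.clip(uptake, 1e-3, 0.45))
        f_remaining = 1.0 - uptake
        taken_ug = uptake * cfg.reservoir_cd_ug
        # every plant in the container samples the same accumulated pool
        delta_tot = accumulated_product_delta(
            cfg.delta_init, cfg.epsilon_uptake, f_remaining
        )
        delta_final = cfg.delta_init + cfg.epsilon_uptake * math.log(f_remaining)

        shares = 1.0 + rng.uniform(-1, 1, size=cfg.replicates_grown) * 0.2
        shares /= shares.sum()
        plants_truth = []
        for r in range(cfg.replicates_grown):
            plant = _simulate_plant(cfg, rng, hydro_fe, delta_tot)
            plant["replicate_id"] = f"P{r + 1}"
            plant["total_cd_ug"] = float(taken_ug * shares[r])
            plants_truth.append(plant)

        # noise draws, in fixed order, for the analysed replicates
        for plant in plants_truth[: cfg.replicates_analysed]:
            for organ in ("root", "stem", "leaf"):
                cd_ug = plant["total_cd_ug"] * plant["fractions"][organ]
                conc = cd_ug / plant["dry_mass_g"][organ]
                conc_noisy = conc * (1.0 + rng.normal() * cfg.noise_conc_rel)
                delta_noisy = plant["deltas"][organ] + rng.normal() * (
                    cfg.noise_delta_2sd / 2.0
                )
                plant_rows.append(
                    {
                        "treatment_id": tid,
                        "replicate_id": plant["replicate_id"],
                        "hydro_fe": hydro_fe,
                        "hydro_zn": hydro_zn,
                        "foliar_fe": foliar_fe,
                        "foliar_zn": foliar_zn,
                        "organ": organ,
                        "dry_mass_g": plant["dry_mass_g"][organ],
                        "conc_mg_per_kg": max(conc_noisy, 0.0),
                        "delta114_permil": delta_noisy,
                        "two_sd_permil": cfg.noise_delta_2sd,
                    }
                )

        solution_rows.append(
            {
                "treatment_id": tid,
                "cd_init_ug": cfg.reservoir_cd_ug,
                "delta_init": cfg.delta_init,
                "uptake_fraction": uptake,
                "f_remaining": f_remaining,
                "delta_final": delta_final,
                "delta_plants": delta_tot,
            }
        )
        truth_treatments.append(
            {
                "treatment_id": tid,
                "uptake_fraction": uptake,
                "f_remaining": f_remaining,
                "delta_total": delta_tot,
                "delta_final": delta_final,
                "plants": [
                    {
                        "replicate_id": p["replicate_id"],
                        "total_cd_ug": p["total_cd_ug"],
                        "fractions": p["fractions"],
                        "deltas": p["deltas"],
                        "dry_mass_g": p["dry_mass_g"],
                    }
                    for p in plants_truth
                ],
            }
        )

    truth = {
        "seed": seed,
        "config": {
            k: v for k, v in asdict(cfg).items() if not isinstance(v, tuple) or k != "treatments"
        },
        "treatments": truth_treatments,
    }
    truth["config"]["treatments"] = [list(t) for t in cfg.treatments]
    return SimResult(
        plants=pd.DataFrame(plant_rows, columns=PLANTS_COLUMNS),
        solutions=pd.DataFrame(solution_rows),
        truth=truth,
    )


def synthesize_spiked_measurement(
    natural_cd_ng: float,
    delta_permil: float,
    spike_cd_ng: float,
    system: IsotopeSystem,
    beta: float = 1.5,
    noise_rel: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, float]:
    """Forward-simulate one spiked MC-ICP-MS measurement.

    Mixes ``natural_cd_ng`` of Cd at the given delta with ``spike_cd_ng`` of
    the double spike, applies instrumental mass bias ``beta`` and optional
    multiplicative ratio noise. Returns (measured ratio triple, true p,
    true alpha) for round-trip exercises of the reduction stage.
    """
    if natural_cd_ng <= 0 or spike_cd_ng <= 0:
        raise ValueError("natural and spike Cd amounts must be positive")
    alpha = alpha_from_delta(delta_permil)
    nat_ratios = np.asarray(system.reference_ratios) * system.mass_ratios**alpha
    x110_nat = system.abundances(nat_ratios)[0]
    n110_nat = natural_cd_ng / system.atomic_mass(nat_ratios) * x110_nat
    spk_ratios = np.asarray(system.spike_ratios)
    x110_spk = system.abundances(spk_ratios)[0]
    n110_spk = spike_cd_ng / system.atomic_mass(spk_ratios) * x110_spk
    p = n110_spk / (n110_spk + n110_nat)
    measured = forward_mix(p, alpha, beta, system)
    if noise_rel > 0:
        if rng is None:
            rng = np.random.default_rng()
        measured = measured * (1.0 + rng.normal(size=3) * noise_rel)
    return measured, float(p), float(alpha)
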