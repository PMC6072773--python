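"""Seeded synthetic-data generators for every pipeline stage.

Three generators mirror the statistical structure the analysis assumes, so
each consuming module is testable without external data:

* noisy oral-dose plasma concentration observations (proportional
  log-normal residual error, the standard model for concentration data),
* pain-relief scores from a Hill curve plus additive Gaussian noise,
* small toy inhibition networks whose uninhibited steady state has a closed
  form (flux balance of a Michaelis-Menten chain).

All generators are pure functions of their configuration: a fixed seed
yields byte-identical output.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import network as net
from . import pbpk

__all__ = [
    "PkSynthConfig",
    "PainSynthConfig",
    "ToyNetworkConfig",
    "SynthConfig",
    "gen_pk_observations",
    "gen_pain_relief",
    "gen_toy_network",
    "toy_one_compartment_drug",
    "toy_physiology",
]


class PkSynthConfig(BaseModel):
    dose_mg: float = Field(default=100.0, gt=0)
    route: str = "oral"
    sampling_times_min: list[float] = Field(
        default=[10, 20, 30, 45, 60, 90, 120, 180, 240, 360, 480, 720]
    )
    noise_cv: float = Field(default=0.10, ge=0, description="lognormal sigma")


class PainSynthConfig(BaseModel):
    a: float = 2.8
    b: float = 4.4
    c: float = 37.2
    n: int = Field(default=50, ge=1)
    sigma: float = Field(default=0.1, ge=0)
    x_max: float = Field(default=100.0, gt=0)


class ToyNetworkConfig(BaseModel):
    toy_id: str = "chain"
    input_flux: float = Field(default=0.02, gt=0, description="umol/L/min")
    km: float = Field(default=50.0, gt=0)
    vmax_cox: float = Field(default=1.0, gt=0)
    vmax_deg: float = Field(default=2.0, gt=0)


class SynthConfig(BaseModel):
    seed: int = 0
    pk: PkSynthConfig = PkSynthConfig()
    pain: PainSynthConfig = PainSynthConfig()
    network: ToyNetworkConfig = ToyNetworkConfig()


# ---------------------------------------------------------------------------
# toy PBPK fixtures
# ---------------------------------------------------------------------------

def toy_physiology(volume: float = 10.0, with_gut: bool = False) -> pbpk.Physiology:
    """Minimal physiology: a single venous pool (optionally a gut lumen for
    oral dosing).  Used for closed-form one-compartment oracles."""
    comps = [pbpk.Compartment(name="venous_plasma", volume=volume)]
    if with_gut:
        comps.append(pbpk.Compartment(name="gut_lumen", volume=1.0))
    return pbpk.Physiology(body_weight=73.0, hematocrit=0.45, compartments=comps)


def toy_one_compartment_drug(
    ke_per_min: float = 0.1 / 60.0,
    ka_per_min: Optional[float] = None,
    molecular_weight: float = 300.0,
    name: str = "toydrug",
) -> pbpk.DrugSpec:
    """One-compartment drug with first-order renal elimination (rate ``ke``)
    and optional first-order absorption."""
    processes = []
    if ke_per_min > 0:
        processes.append(
            pbpk.AdmeProcess(
                kind="clearance_renal",
                site="venous_plasma",
                kinetics=pbpk.Kinetics(rate=ke_per_min),
            )
        )
    absorption = (
        pbpk.Absorption(ka=ka_per_min) if ka_per_min is not None else None
    )
    return pbpk.DrugSpec(
        name=name,
        molecular_weight=molecular_weight,
        fraction_unbound_plasma=1.0,
        absorption=absorption,
        processes=processes,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_pk_observations(cfg: SynthConfig) -> pd.DataFrame:
    """Noisy concentration observations from the toy one-compartment model.

    C_obs = C_true * exp(eps), eps ~ Normal(0, CV), one draw per sample.
    Returns a tidy table (time_min, conc_true, conc_obs) plus the true
    parameters in ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(cfg.seed)
    ke = 0.1 / 60.0
    ka = 3.0 / 60.0
    phys = toy_physiology(volume=40.0, with_gut=cfg.pk.route == "oral")
    drug = toy_one_compartment_drug(
        ke_per_min=ke, ka_per_min=ka if cfg.pk.route == "oral" else None
    )
    model = pbpk.build_model(phys, drug)
    span = max(cfg.pk.sampling_times_min) + 1.0
    dose = pbpk.DoseEvent(route=cfg.pk.route if cfg.pk.route in ("oral", "intravenous")
                          else "oral", amount=cfg.pk.dose_mg, time=0.0)
    prof = pbpk.simulate(model, [dose], span)
    conc = prof.total(drug.name, "venous_plasma")
    t = np.asarray(cfg.pk.sampling_times_min, dtype=float)
    if np.any(t > prof.times[-1]) or np.any(t < prof.times[0]):
        raise ValueError("sampling times outside the simulated span")
    c_true = np.interp(t, prof.times, conc)
    eps = rng.normal(0.0, cfg.pk.noise_cv, size=len(t)) if cfg.pk.noise_cv > 0 else 0.0
    c_obs = c_true * np.exp(eps)
    out = pd.DataFrame({"time_min": t, "conc_true": c_true, "conc_obs": c_obs})
    out.attrs["true_params"] = {"ke_per_min": ke, "ka_per_min": ka,
                                "volume_l": 40.0, "dose_mg": cfg.pk.dose_mg}
    return out


def gen_pain_relief(cfg: SynthConfig):
    """Synthetic (PGE2 decrease, pain relief) pairs from a Hill curve plus
    additive Gaussian noise; x sampled uniformly over (0, x_max]."""
    from .correlation import PkpdPair, evaluate_hill

    if cfg.pain.n < 5:
        raise ValueError("need n >= 5 synthetic pairs")
    rng = np.random.default_rng(cfg.seed)
    x = np.sort(rng.uniform(0.0, cfg.pain.x_max, size=cfg.pain.n))
    y = evaluate_hill((cfg.pain.a, cfg.pain.b, cfg.pain.c), x)
    if cfg.pain.sigma > 0:
        y = y + rng.normal(0.0, cfg.pain.sigma, size=cfg.pain.n)
    return PkpdPair(x=x, y=y, dose_label="synthetic")


def gen_toy_network(cfg: SynthConfig) -> tuple[net.NetworkModel, dict[str, float]]:
    """Toy inhibition network with a closed-form uninhibited steady state.

    A constant arachidonic-acid input feeds a COX-2 conversion to PGE2 and a
    5-LOX conversion to wLTB4; both mediators degrade enzymatically.  At
    steady state every reaction carries half the input flux J (the branches
    split evenly by construction), so each Michaelis-Menten step solves
    V*S/(K+S) = J/2  =>  S = (J/2)*K / (V - J/2), which is the returned
    closed form.
    """
    if cfg.network.toy_id != "chain":
        raise ValueError(f"unknown toy network id {cfg.network.toy_id!r}")
    j = cfg.network.input_flux
    km = cfg.network.km
    v_cox = cfg.network.vmax_cox
    v_deg = cfg.network.vmax_deg
    if v_cox <= j or v_deg <= j:
        raise ValueError("Vmax must exceed the input flux for a steady state")
    half = j / 2.0
    # AA is removed by two identical MM branches: 2*v_cox*S/(K+S) = J
    s_aa = j * km / (2.0 * v_cox - j)
    s_pge2 = half * km / (v_deg - half)
    s_ltb4 = half * km / (v_deg - half)
    model = net.NetworkModel(
        species=[
            net.Species(name="AA", initial=s_aa),
            net.Species(name="PGE2", initial=s_pge2),
            net.Species(name="wLTB4", initial=s_ltb4),
        ],
        reactions=[
            net.MMReaction(substrate=None, product="AA", enzyme="input",
                           vmax=j, km=1.0),
            net.MMReaction(substrate="AA", product="PGE2", enzyme="COX-2",
                           vmax=v_cox, km=km),
            net.MMReaction(substrate="AA", product="wLTB4", enzyme="5-LOX",
                           vmax=v_cox, km=km),
            net.MMReaction(substrate="PGE2", product=None, enzyme="PGE2-deg",
                           vmax=v_deg, km=km),
            net.MMReaction(substrate="wLTB4", product=None, enzyme="LTB4-deg",
                           vmax=v_deg, km=km),
        ],
        provenance="toy",
    )
    steady = {"AA": s_aa, "PGE2": s_pge2, "wLTB4": s_ltb4}
    return model, steady
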