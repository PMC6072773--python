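"""Reduced whole-body PBPK engine.

Builds and integrates the ODE system for a parent drug and its metabolites
over a configurable compartment graph with ADME processes (metabolism,
transport, renal/hepatic/biliary clearance), and computes non-compartmental
PK metrics (Cmax, Tmax, AUC(0->inf)).

The default physiology is a reduced layout for a 73 kg adult: venous and
arterial plasma, blood cells, gut lumen, gut wall, liver (vascular /
interstitial / intracellular sub-compartments), kidney, and a lumped
periphery.  Circulation is flow-limited on plasma concentrations; organs
partition with tissue:plasma coefficients Kp; the liver exchanges between
its sub-compartments with fast passive permeability so that metabolism acts
on the unbound intracellular concentration.

Internal unit system: concentrations in umol/L, time in minutes, amounts in
umol.  Conversion to ng/ml happens only at metric reporting, via the
molecular weight.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.integrate import solve_ivp

__all__ = [
    "ConfigurationError",
    "SolverError",
    "Physiology",
    "Compartment",
    "DrugSpec",
    "AdmeProcess",
    "DoseEvent",
    "PBPKModel",
    "ProfileSet",
    "PkMetrics",
    "build_model",
    "simulate",
    "pk_metrics",
    "apply_cyp_induction",
    "expand_doses",
    "load_physiology",
    "load_drug",
    "packaged_physiology",
    "packaged_drug",
    "packaged_drug_names",
]

# ---------------------------------------------------------------------------
# configuration constants (solver contract and exchange kinetics)
# ---------------------------------------------------------------------------

#: stiff-capable solver settings used for every PBPK integration
SOLVER_METHOD = "LSODA"
RTOL = 1e-8
ATOL = 1e-10
#: default dense-output resolution (min)
GRID_DT = 1.0
#: passive exchange rate between organ sub-compartments and between venous
#: plasma and blood cells, per litre of well volume (1/min); fast relative to
#: perfusion so distribution is effectively equilibrated
EXCHANGE_RATE = 2.0

VENOUS = "venous_plasma"
ARTERIAL = "arterial_plasma"
BLOOD_CELLS = "blood_cells"
GUT_LUMEN = "gut_lumen"
GUT_WALL = "gut_wall"
LIVER = "liver"

SUBCOMPARTMENT_NAMES = ("vascular", "interstitial", "intracellular")


class ConfigurationError(ValueError):
    """Raised when a physiology/drug configuration is inconsistent."""


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails; carries the failure time."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class Subcompartments(BaseModel):
    """Fractional volumes of the vascular/interstitial/intracellular wells."""

    vascular: float = Field(gt=0, lt=1)
    interstitial: float = Field(gt=0, lt=1)
    intracellular: float = Field(gt=0, lt=1)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "Subcompartments":
        total = self.vascular + self.interstitial + self.intracellular
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subcompartment fractions sum to {total}, expected 1")
        return self


class Compartment(BaseModel):
    name: str
    volume: float = Field(gt=0, description="L")
    blood_flow: float = Field(default=0.0, ge=0, description="plasma flow, L/min")
    subcompartments: Optional[Subcompartments] = None


class Physiology(BaseModel):
    """Body-level parameterization: compartments, flows and enzyme abundance.

    ``enzyme_expression`` maps enzyme name -> {compartment: relative
    abundance}, liver-normalized.  Unlisted (enzyme, compartment) pairs
    default to 1.0 in the liver and 0.0 elsewhere.
    """

    body_weight: float = Field(gt=0, description="kg")
    hematocrit: float = Field(gt=0, lt=1)
    compartments: list[Compartment]
    enzyme_expression: dict[str, dict[str, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _unique_names(self) -> "Physiology":
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names")
        for enzyme, sites in self.enzyme_expression.items():
            for site in sites:
                if site not in names:
                    raise ValueError(
                        f"enzyme_expression[{enzyme}] refers to unknown compartment {site!r}"
                    )
        return self

    def compartment(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown compartment {name!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    def expression(self, enzyme: str, site: str) -> float:
        sites = self.enzyme_expression.get(enzyme)
        if sites is not None and site in sites:
            return sites[site]
        return 1.0 if site == LIVER else 0.0


ProcessKind = Literal[
    "metabolism",
    "transport_influx",
    "transport_efflux",
    "clearance_renal",
    "clearance_hepatic",
    "clearance_biliary",
]


class Kinetics(BaseModel):
    """Kinetic constants: (kcat, enzyme_scale, km) for metabolism, first-order
    ``rate`` (1/min) for clearances and transport."""

    kcat: Optional[float] = Field(default=None, ge=0, description="1/min")
    enzyme_scale: float = Field(default=1.0, ge=0, description="umol enzyme")
    km: Optional[float] = Field(default=None, gt=0, description="umol/L")
    rate: Optional[float] = Field(default=None, ge=0, description="1/min")


class AdmeProcess(BaseModel):
    kind: ProcessKind
    enzyme_or_transporter: Optional[str] = None
    site: str
    kinetics: Kinetics
    product: Optional[str] = None
    terminal: bool = False

    @model_validator(mode="after")
    def _kind_consistency(self) -> "AdmeProcess":
        if self.kind == "metabolism":
            if self.kinetics.kcat is None or self.kinetics.km is None:
                raise ValueError("metabolism requires kcat and km")
            if self.enzyme_or_transporter is None:
                raise ValueError("metabolism requires an enzyme name")
            if self.product is None and not self.terminal:
                raise ValueError("metabolism must name a product or be marked terminal")
        else:
            if self.kinetics.rate is None:
                raise ValueError(f"{self.kind} requires a first-order rate")
        return self


class Absorption(BaseModel):
    ka: float = Field(gt=0, description="1/min")
    lag: float = Field(default=0.0, ge=0, description="min")
    formulation: Literal["dissolved", "solid"] = "dissolved"


class DoseRepeat(BaseModel):
    interval: float = Field(gt=0, description="min")
    count: int = Field(ge=1)


class DoseEvent(BaseModel):
    route: Literal["oral", "intravenous"]
    amount: float = Field(gt=0, description="mg")
    time: float = Field(default=0.0, description="min")
    repeat: Optional[DoseRepeat] = None


class DrugSpec(BaseModel):
    """Drug (or metabolite) specification; metabolites are nested DrugSpecs."""

    name: str
    molecular_weight: float = Field(gt=0, description="g/mol")
    fraction_unbound_plasma: float = Field(gt=0, le=1)
    fraction_unbound_cellular: Optional[float] = Field(default=None, gt=0, le=1)
    partition_coefficients: dict[str, float] = Field(default_factory=dict)
    absorption: Optional[Absorption] = None
    metabolites: list["DrugSpec"] = Field(default_factory=list)
    processes: list[AdmeProcess] = Field(default_factory=list)

    @field_validator("partition_coefficients")
    @classmethod
    def _positive_kp(cls, v: dict[str, float]) -> dict[str, float]:
        for comp, kp in v.items():
            if kp <= 0:
                raise ValueError(f"partition coefficient for {comp!r} must be > 0")
        return v

    @property
    def fu_cell(self) -> float:
        return (
            self.fraction_unbound_cellular
            if self.fraction_unbound_cellular is not None
            else self.fraction_unbound_plasma
        )

    def kp(self, compartment: str) -> float:
        return self.partition_coefficients.get(compartment, 1.0)

    def all_compounds(self) -> list["DrugSpec"]:
        """Parent followed by all metabolites, depth-first; checks acyclicity."""
        out: list[DrugSpec] = []
        seen: set[str] = set()

        def walk(d: DrugSpec) -> None:
            if d.name in seen:
                raise ConfigurationError(
                    f"metabolite graph is cyclic or reuses name {d.name!r}"
                )
            seen.add(d.name)
            out.append(d)
            for m in d.metabolites:
                walk(m)

        walk(self)
        return out

    def n_processes(self) -> int:
        return sum(len(c.processes) for c in self.all_compounds())


DrugSpec.model_rebuild()


class PkMetrics(BaseModel):
    cmax: float = Field(ge=0, description="ng/ml")
    tmax: float = Field(ge=0, description="h")
    auc_inf: float = Field(ge=0, description="ng*h/ml")
    extrapolated_fraction: float = Field(default=0.0, ge=0)
    extrapolation_refused: bool = False


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

@dataclass
class _MetabolismSlot:
    compound_idx: int
    well_idx: int
    product_idx: Optional[int]
    enzyme: str
    kcat: float
    scale: float
    km: float
    expression: float
    fu: float
    kp: float
    flux_state: int  # index of the cumulative-flux accumulator state
    elim_state: Optional[int]  # set for terminal metabolism


@dataclass
class _FirstOrderSlot:
    compound_idx: int
    well_idx: int
    rate: float
    elim_state: Optional[int]  # elimination accumulator, None for transports
    target_well: Optional[int]  # for transports


@dataclass
class PBPKModel:
    """Compiled PBPK ODE system for one drug (plus metabolites)."""

    physiology: Physiology
    drug: DrugSpec
    compounds: list[DrugSpec]
    wells: list[str]
    well_volumes: np.ndarray
    linear_ops: list[np.ndarray]          # per compound, n_wells x n_wells
    absorption: list[Optional[tuple[int, int, float, float]]]
    # (lumen well, target well, ka, lag) per compound, None if not absorbable
    metabolism: list[_MetabolismSlot]
    first_order: list[_FirstOrderSlot]
    elim_routes: list[tuple[int, str]]    # (compound_idx, route) per elim state
    n_amount_states: int
    n_states: int
    folds: dict[str, Callable[[float], float]] = field(default_factory=dict)

    # -- helpers -----------------------------------------------------------
    def compound_index(self, name: str) -> int:
        for i, c in enumerate(self.compounds):
            if c.name == name:
                return i
        raise ConfigurationError(f"unknown compound {name!r}")

    def well_index(self, label: str) -> int:
        try:
            return self.wells.index(label)
        except ValueError:
            raise ConfigurationError(f"unknown well {label!r}") from None

    @property
    def n_processes(self) -> int:
        return self.drug.n_processes()

    def amount_index(self, compound_idx: int, well_idx: int) -> int:
        return compound_idx * len(self.wells) + well_idx

    # -- right-hand side ---------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n_wells = len(self.wells)
        dy = np.zeros_like(y)
        for ci in range(len(self.compounds)):
            a = y[ci * n_wells : (ci + 1) * n_wells]
            dy[ci * n_wells : (ci + 1) * n_wells] += self.linear_ops[ci] @ a
        # absorption (first order out of gut lumen)
        for ci, ab in enumerate(self.absorption):
            if ab is None:
                continue
            lumen, target, ka, _lag = ab
            flux = ka * y[self.amount_index(ci, lumen)]
            dy[self.amount_index(ci, lumen)] -= flux
            dy[self.amount_index(ci, target)] += flux
        # Michaelis-Menten metabolism on unbound driving concentration
        for m in self.metabolism:
            idx = self.amount_index(m.compound_idx, m.well_idx)
            conc = y[idx] / self.well_volumes[m.well_idx]
            cu = m.fu * conc / m.kp
            fold = self.folds.get(m.enzyme)
            f = fold(t) if fold is not None else 1.0
            v = m.kcat * m.scale * m.expression * f * cu / (m.km + cu)
            dy[idx] -= v
            if m.product_idx is not None:
                dy[self.amount_index(m.product_idx, m.well_idx)] += v
            else:
                dy[m.elim_state] += v
            dy[m.flux_state] += v
        # first-order clearances and transports
        for p in self.first_order:
            idx = self.amount_index(p.compound_idx, p.well_idx)
            v = p.rate * y[idx]
            dy[idx] -= v
            if p.target_well is not None:
                dy[self.amount_index(p.compound_idx, p.target_well)] += v
            else:
                dy[p.elim_state] += v
        return dy


def _well_labels(physiology: Physiology) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    volumes: list[float] = []
    for c in physiology.compartments:
        if c.subcompartments is not None:
            for sub in SUBCOMPARTMENT_NAMES:
                labels.append(f"{c.name}_{sub}")
                volumes.append(c.volume * getattr(c.subcompartments, sub))
        else:
            labels.append(c.name)
            volumes.append(c.volume)
    return labels, np.asarray(volumes)


def _site_well(physiology: Physiology, wells: list[str], site: str) -> int:
    """Well where an intracellular process acts for a given compartment."""
    comp = physiology.compartment(site)
    label = f"{site}_intracellular" if comp.subcompartments is not None else site
    return wells.index(label)


def build_model(physiology: Physiology, drug: DrugSpec) -> PBPKModel:
    """Compile the ODE system for ``drug`` (and its metabolites) on ``physiology``.

    Raises :class:`ConfigurationError` naming the offender when a process
    site or compartment is unknown.
    """
    compounds = drug.all_compounds()
    comp_index = {c.name: i for i, c in enumerate(compounds)}
    wells, volumes = _well_labels(physiology)
    n_wells = len(wells)
    names = set(physiology.names)

    has_circulation = VENOUS in names and ARTERIAL in names
    organ_names = [
        c.name
        for c in physiology.compartments
        if c.name not in (VENOUS, ARTERIAL, BLOOD_CELLS, GUT_LUMEN) and c.blood_flow > 0
    ]

    def widx(label: str) -> int:
        return wells.index(label)

    linear_ops: list[np.ndarray] = []
    for comp in compounds:
        L = np.zeros((n_wells, n_wells))

        def add(dst: int, src: int, coeff_on_conc: float) -> None:
            # contribution to dA_dst/dt of coeff * C_src
            L[dst, src] += coeff_on_conc / volumes[src]

        if has_circulation:
            i_ven, i_art = widx(VENOUS), widx(ARTERIAL)
            q_total = 0.0
            i_liver_in = None
            if LIVER in names:
                lc = physiology.compartment(LIVER)
                i_liver_in = (
                    widx(f"{LIVER}_vascular") if lc.subcompartments else widx(LIVER)
                )
            for organ in organ_names:
                oc = physiology.compartment(organ)
                q = oc.blood_flow
                q_total += q
                if oc.subcompartments is not None:
                    i_vas = widx(f"{organ}_vascular")
                    i_int = widx(f"{organ}_interstitial")
                    i_cel = widx(f"{organ}_intracellular")
                    add(i_vas, i_art, q)
                    # organ venous return handled below (liver collects portal)
                    out_dst = i_ven
                    add(out_dst, i_vas, q)
                    add(i_vas, i_vas, -q)
                    ps = EXCHANGE_RATE * oc.volume
                    kp = comp.kp(organ)
                    # vascular <-> interstitial (total concentrations)
                    add(i_vas, i_int, ps)
                    add(i_int, i_vas, ps)
                    add(i_vas, i_vas, -ps)
                    add(i_int, i_int, -ps)
                    # interstitial <-> intracellular with partitioning
                    add(i_int, i_cel, ps / kp)
                    add(i_cel, i_int, ps)
                    add(i_int, i_int, -ps)
                    add(i_cel, i_cel, -ps / kp)
                else:
                    i_o = widx(organ)
                    kp = comp.kp(organ)
                    add(i_o, i_art, q)
                    if organ == GUT_WALL and i_liver_in is not None:
                        add(i_liver_in, i_o, q / kp)  # portal inflow to liver
                    else:
                        add(i_ven, i_o, q / kp)
                    add(i_o, i_o, -q / kp)
            # portal flow also exits the liver: route it with hepatic outflow
            if GUT_WALL in organ_names and i_liver_in is not None:
                q_gw = physiology.compartment(GUT_WALL).blood_flow
                add(i_ven, i_liver_in, q_gw)
                add(i_liver_in, i_liver_in, -q_gw)
            # arterial <-> venous via cardiac plasma flow
            add(i_art, i_ven, q_total)
            add(i_art, i_art, -q_total)
            add(i_ven, i_ven, -q_total)

        if BLOOD_CELLS in names and VENOUS in names:
            i_bc, i_ven = widx(BLOOD_CELLS), widx(VENOUS)
            ps = EXCHANGE_RATE * physiology.compartment(BLOOD_CELLS).volume
            kp_bc = comp.kp(BLOOD_CELLS)
            add(i_bc, i_ven, ps)
            add(i_ven, i_bc, ps / kp_bc)
            add(i_bc, i_bc, -ps / kp_bc)
            add(i_ven, i_ven, -ps)

        linear_ops.append(L)

    # absorption routing per compound
    absorption: list[Optional[tuple[int, int, float, float]]] = []
    for comp in compounds:
        if comp.absorption is None:
            absorption.append(None)
            continue
        if GUT_LUMEN not in names:
            raise ConfigurationError(
                f"drug {comp.name!r} has oral absorption but physiology lacks {GUT_LUMEN!r}"
            )
        lumen = widx(GUT_LUMEN)
        if GUT_WALL in names:
            target = widx(GUT_WALL)
        elif VENOUS in names:
            target = widx(VENOUS)
        else:
            raise ConfigurationError("no absorption target compartment available")
        absorption.append((lumen, target, comp.absorption.ka, comp.absorption.lag))

    # processes
    n_amount = len(compounds) * n_wells
    metabolism: list[_MetabolismSlot] = []
    first_order: list[_FirstOrderSlot] = []
    elim_routes: list[tuple[int, str]] = []
    flux_counter = 0
    # first pass: count metabolism slots to place accumulator states
    total_metabolism = sum(
        1 for c in compounds for p in c.processes if p.kind == "metabolism"
    )
    flux_base = n_amount
    elim_base = n_amount + total_metabolism

    def new_elim(ci: int, route: str) -> int:
        elim_routes.append((ci, route))
        return elim_base + len(elim_routes) - 1

    for ci, comp in enumerate(compounds):
        for proc in comp.processes:
            if proc.site not in names:
                raise ConfigurationError(
                    f"process on {comp.name!r}: unknown compartment {proc.site!r}"
                )
            if proc.kind == "metabolism":
                if proc.product is not None and proc.product not in comp_index:
                    raise ConfigurationError(
                        f"metabolism on {comp.name!r} names unknown product {proc.product!r}"
                    )
                well = _site_well(physiology, wells, proc.site)
                slot = _MetabolismSlot(
                    compound_idx=ci,
                    well_idx=well,
                    product_idx=(
                        comp_index[proc.product] if proc.product is not None else None
                    ),
                    enzyme=proc.enzyme_or_transporter,
                    kcat=proc.kinetics.kcat,
                    scale=proc.kinetics.enzyme_scale,
                    km=proc.kinetics.km,
                    expression=physiology.expression(
                        proc.enzyme_or_transporter, proc.site
                    ),
                    fu=comp.fu_cell,
                    kp=comp.kp(proc.site),
                    flux_state=flux_base + flux_counter,
                    elim_state=None,
                )
                if proc.product is None:
                    slot.elim_state = new_elim(ci, "metabolism")
                flux_counter += 1
                metabolism.append(slot)
            elif proc.kind in ("transport_influx", "transport_efflux"):
                pcomp = physiology.compartment(proc.site)
                if pcomp.subcompartments is None:
                    raise ConfigurationError(
                        f"transport on {comp.name!r}: site {proc.site!r} has no subcompartments"
                    )
                i_int = widx(f"{proc.site}_interstitial")
                i_cel = widx(f"{proc.site}_intracellular")
                src, dst = (
                    (i_int, i_cel)
                    if proc.kind == "transport_influx"
                    else (i_cel, i_int)
                )
                first_order.append(
                    _FirstOrderSlot(ci, src, proc.kinetics.rate, None, dst)
                )
            else:  # clearances
                route = proc.kind.removeprefix("clearance_")
                well = _site_well(physiology, wells, proc.site)
                first_order.append(
                    _FirstOrderSlot(
                        ci, well, proc.kinetics.rate, new_elim(ci, route), None
                    )
                )

    n_states = n_amount + total_metabolism + len(elim_routes)
    return PBPKModel(
        physiology=physiology,
        drug=drug,
        compounds=compounds,
        wells=wells,
        well_volumes=volumes,
        linear_ops=linear_ops,
        absorption=absorption,
        metabolism=metabolism,
        first_order=first_order,
        elim_routes=elim_routes,
        n_amount_states=n_amount,
        n_states=n_states,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class ProfileSet:
    """Dense concentration-time profiles plus elimination bookkeeping."""

    model: PBPKModel
    times: np.ndarray                       # min
    amounts: np.ndarray                     # n_states x n_times
    administered: dict[str, float]          # compound -> umol dosed
    dose_schedule: list[tuple[float, float]] = field(default_factory=list)
    # (time_min, umol) per applied dose jump

    def _amount(self, compound: str, well: str) -> np.ndarray:
        ci = self.model.compound_index(compound)
        wi = self.model.well_index(well)
        return self.amounts[self.model.amount_index(ci, wi)]

    def total(self, compound: str, well: str) -> np.ndarray:
        """Total concentration (umol/L) of ``compound`` in ``well``."""
        wi = self.model.well_index(well)
        return self._amount(compound, well) / self.model.well_volumes[wi]

    def unbound(self, compound: str, well: str) -> np.ndarray:
        """Unbound concentration (umol/L).

        Plasma and interstitial wells: fu_plasma * total.  Blood cells:
        fu_cellular * total (the cells' unbound fraction defaults to the
        plasma value).  Intracellular wells: fu_cellular * total / Kp, i.e.
        referenced to cell water after partitioning.
        """
        comp = self.model.compounds[self.model.compound_index(compound)]
        c = self.total(compound, well)
        if well == BLOOD_CELLS:
            return comp.fu_cell * c
        if well.endswith("_intracellular"):
            organ = well.removesuffix("_intracellular")
            return comp.fu_cell * c / comp.kp(organ)
        return comp.fraction_unbound_plasma * c

    def eliminated(self, compound: str, route: Optional[str] = None) -> np.ndarray:
        ci = self.model.compound_index(compound)
        out = np.zeros_like(self.times)
        for k, (cidx, r) in enumerate(self.model.elim_routes):
            if cidx == ci and (route is None or r == route):
                out = out + self.amounts[self.model.n_amount_states
                                         + len(self.model.metabolism) + k]
        return out

    def formed(self, process_index: int) -> np.ndarray:
        """Cumulative flux (umol) through the i-th metabolism process."""
        return self.amounts[self.model.n_amount_states + process_index]

    def mass_balance_error(self) -> float:
        """Max relative error of (amount in system + eliminated) against the
        cumulative administered amount at each grid time."""
        total_dosed = sum(self.administered.values())
        if total_dosed == 0:
            return 0.0
        dosed_t = np.zeros_like(self.times)
        for jt, umol in self.dose_schedule:
            dosed_t += np.where(self.times >= jt - 1e-9, umol, 0.0)
        n_wells = len(self.model.wells)
        in_system = self.amounts[: self.model.n_amount_states].reshape(
            len(self.model.compounds), n_wells, -1
        ).sum(axis=(0, 1))
        elim = np.zeros_like(self.times)
        base = self.model.n_amount_states + len(self.model.metabolism)
        for k in range(len(self.model.elim_routes)):
            elim = elim + self.amounts[base + k]
        total = in_system + elim
        return float(np.max(np.abs(total - dosed_t)) / total_dosed)

    def to_frame(self):
        """Tidy DataFrame: time_min, compound, compartment, total/unbound umol/L."""
        import pandas as pd

        rows = []
        for comp in self.model.compounds:
            for well in self.model.wells:
                rows.append(
                    pd.DataFrame(
                        {
                            "time_min": self.times,
                            "compound": comp.name,
                            "compartment": well,
                            "total_umol_L": self.total(comp.name, well),
                            "unbound_umol_L": self.unbound(comp.name, well),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def expand_doses(doses: list[DoseEvent]) -> list[tuple[float, str, float]]:
    """Expand repeat specifications into (time, route, amount_mg) sorted events."""
    events: list[tuple[float, str, float]] = []
    for d in doses:
        n = d.repeat.count if d.repeat else 1
        dt = d.repeat.interval if d.repeat else 0.0
        for k in range(n):
            events.append((d.time + k * dt, d.route, d.amount))
    events.sort(key=lambda e: e[0])
    return events


def simulate(
    model: PBPKModel,
    doses: list[DoseEvent],
    span: float,
    t0: float = 0.0,
    grid_dt: float = GRID_DT,
) -> ProfileSet:
    """Integrate the model over ``[t0, t0 + span]`` minutes.

    Doses are applied as state discontinuities (integration restarts); oral
    doses enter the gut lumen after the formulation lag, iv doses enter
    venous plasma.  Dense output on a ``grid_dt`` grid.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    t_end = t0 + span
    events = expand_doses(doses)
    # apply absorption lag by shifting oral event times
    jumps: list[tuple[float, int, int, float]] = []  # (time, ci, well, umol)
    administered: dict[str, float] = {c.name: 0.0 for c in model.compounds}
    parent_ci = 0
    parent = model.compounds[parent_ci]
    for t_ev, route, mg in events:
        umol = mg * 1000.0 / parent.molecular_weight
        if route == "oral":
            ab = model.absorption[parent_ci]
            if ab is None:
                raise ConfigurationError(
                    f"drug {parent.name!r} has no absorption spec for oral dosing"
                )
            lumen, _target, _ka, lag = ab
            jumps.append((t_ev + lag, parent_ci, lumen, umol))
        else:
            jumps.append((t_ev, parent_ci, model.well_index(VENOUS), umol))
        administered[parent.name] += umol
    jumps.sort(key=lambda j: j[0])
    if jumps and jumps[0][0] < t0:
        raise ValueError("dose before simulation start")

    grid = np.arange(t0, t_end + 0.5 * grid_dt, grid_dt)
    grid[-1] = min(grid[-1], t_end)
    y = np.zeros(model.n_states)
    out = np.zeros((model.n_states, len(grid)))

    boundaries = sorted({t0, t_end, *[j[0] for j in jumps if t0 <= j[0] < t_end]})
    for k, (seg_start, seg_end) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        for jt, ci, wi, umol in jumps:
            if abs(jt - seg_start) < 1e-9:
                y[model.amount_index(ci, wi)] += umol
        # grid points belong to the segment where they are >= start and < end;
        # the global end point goes to the last segment (post-jump at doses)
        last = k == len(boundaries) - 2
        mask = (grid >= seg_start - 1e-9) & (
            (grid <= seg_end + 1e-9) if last else (grid < seg_end - 1e-9)
        )
        t_eval = np.clip(grid[mask], seg_start, seg_end)
        sol = solve_ivp(
            model.rhs,
            (seg_start, seg_end),
            y,
            method=SOLVER_METHOD,
            rtol=RTOL,
            atol=ATOL,
            t_eval=t_eval if len(t_eval) else None,
            dense_output=False,
        )
        if not sol.success:
            t_fail = sol.t[-1] if len(sol.t) else seg_start
            raise SolverError(
                f"integration failed at t~{t_fail:.2f} min: {sol.message} "
                "(stiffness hint: reduce exchange rates or switch to BDF)"
            )
        if len(t_eval):
            out[:, mask] = sol.y
        if sol.t[-1] < seg_end - 1e-9:
            # t_eval may not include seg_end; finish the segment for the state
            sol2 = solve_ivp(
                model.rhs, (sol.t[-1], seg_end), sol.y[:, -1],
                method=SOLVER_METHOD, rtol=RTOL, atol=ATOL,
            )
            if not sol2.success:
                raise SolverError(
                    f"integration failed at t~{sol2.t[-1]:.2f} min: {sol2.message}"
                )
            y = sol2.y[:, -1].copy()
        else:
            y = sol.y[:, -1].copy()
    return ProfileSet(
        model=model, times=grid, amounts=out, administered=administered,
        dose_schedule=[(jt, umol) for jt, _ci, _wi, umol in jumps],
    )


# ---------------------------------------------------------------------------
# PK metrics
# ---------------------------------------------------------------------------

def pk_metrics(
    profile: ProfileSet,
    compound: str,
    compartment: str = VENOUS,
    terminal_fraction: float = 0.25,
    max_extrapolated_fraction: float = 0.5,
) -> PkMetrics:
    """Non-compartmental Cmax/Tmax/AUC(0->inf) in reporting units.

    AUC by trapezoid over the grid plus log-linear terminal extrapolation
    (C_last / lambda_z, lambda_z from a regression on the trailing
    ``terminal_fraction`` of the profile).  Extrapolation is refused — AUC
    to the last point is reported with ``extrapolation_refused`` set — when
    the terminal phase does not decay, or when the extrapolated tail would
    dominate the total (fraction above ``max_extrapolated_fraction``, i.e.
    the window does not cover a reliable terminal phase).
    """
    comp = profile.model.compounds[profile.model.compound_index(compound)]
    conc = profile.total(compound, compartment) * comp.molecular_weight  # ng/ml
    t_h = (profile.times - profile.times[0]) / 60.0
    i_max = int(np.argmax(conc))
    cmax = float(conc[i_max])
    tmax = float(t_h[i_max])
    auc = float(np.trapezoid(conc, t_h))
    tail_start = max(i_max + 1, int(len(t_h) * (1.0 - terminal_fraction)))
    tail_c = conc[tail_start:]
    tail_t = t_h[tail_start:]
    refused = True
    extrap = 0.0
    if len(tail_c) >= 3 and np.all(tail_c > 0):
        slope, _ = np.polyfit(tail_t, np.log(tail_c), 1)
        if slope < -1e-12:
            lam = -slope
            candidate = float(tail_c[-1] / lam)
            if candidate <= max_extrapolated_fraction * (auc + candidate):
                extrap = candidate
                auc += extrap
                refused = False
    return PkMetrics(
        cmax=cmax,
        tmax=tmax,
        auc_inf=auc,
        extrapolated_fraction=extrap / auc if auc > 0 else 0.0,
        extrapolation_refused=refused,
    )


# ---------------------------------------------------------------------------
# CYP induction hook
# ---------------------------------------------------------------------------

def apply_cyp_induction(
    model: PBPKModel,
    folds: dict[str, Callable[[float], float]],
    check_grid: Optional[np.ndarray] = None,
) -> PBPKModel:
    """Return a copy of ``model`` whose metabolism kcat values are scaled by
    time-dependent activity folds, per enzyme, in every compartment
    expressing that enzyme (extrahepatic metabolism included).

    Folds must be >= 1 everywhere (induction only); values < 1 are rejected.
    """
    grid = check_grid if check_grid is not None else np.linspace(0.0, 360.0, 25)
    for enzyme, fold in folds.items():
        vals = np.asarray([fold(t) for t in grid], dtype=float)
        if np.any(vals < 1.0 - 1e-9):
            raise ValueError(
                f"induction fold for {enzyme} drops below 1 (min {vals.min():.4f}); "
                "inhibition is out of scope"
            )
    merged = dict(model.folds)
    for enzyme, fold in folds.items():
        if enzyme in merged:
            prev = merged[enzyme]
            merged[enzyme] = (lambda p, f: (lambda t: p(t) * f(t)))(prev, fold)
        else:
            merged[enzyme] = fold
    import copy

    new = copy.copy(model)
    new.folds = merged
    return new


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def load_physiology(path) -> Physiology:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return Physiology.model_validate(data)


def load_drug(path) -> DrugSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return DrugSpec.model_validate(data)


def _data_dir():
    from importlib.resources import files

    return files("aaqsp") / "data"


def packaged_physiology() -> Physiology:
    """The default reduced physiology of a 73 kg adult."""
    return Physiology.model_validate(
        yaml.safe_load((_data_dir() / "physiology.yaml").read_text())
    )


def packaged_drug_names() -> list[str]:
    d = _data_dir() / "drugs"
    return sorted(p.name.removesuffix(".yaml") for p in d.iterdir()
                  if p.name.endswith(".yaml"))


def packaged_drug(name: str) -> DrugSpec:
    path = _data_dir() / "drugs" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ConfigurationError(
            f"no packaged drug {name!r}; available: {packaged_drug_names()}"
        ) from None
    return DrugSpec.model_validate(yaml.safe_load(text))
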