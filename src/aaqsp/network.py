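"""ODE network of arachidonic-acid metabolism with competitive inhibition.

The network couples a shared arachidonic-acid pool to a COX-2 branch ending
in prostaglandin E2 (PGE2) and a 5-LOX branch ending in omega-oxidized
leukotriene B4 (wLTB4), with positive/negative feedback regulation.  Drugs
enter as time-resolved unbound concentrations that competitively inhibit the
enzyme of a reaction by scaling its Michaelis constant:

    Km_eff(t) = Km * (1 + sum_i I_i(t) / Ki_i)

Multiple inhibitors of one enzyme combine additively in the inhibition term.
Inhibition of COX-2 and 5-LOX is assumed unsaturated: substrate levels in
the packaged surrogate sit far below Km, so the competitive factor dominates
the rate response.

A reduced surrogate network ships with the package (all parameters
repo-defined and documented in the YAML); an SBML Level 3 import/export path
covers literature models restricted to explicit Michaelis-Menten or
mass-action kinetic laws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import yaml
from lxml import etree
from pydantic import BaseModel, Field, model_validator
from scipy.integrate import solve_ivp

__all__ = [
    "MMReaction",
    "FeedbackEdge",
    "NetworkModel",
    "InhibitorSignal",
    "MediatorProfile",
    "UnsupportedKineticLawError",
    "NetworkValidationError",
    "load_network",
    "effective_km",
    "simulate_network",
    "equilibrate",
    "write_sbml",
    "read_sbml",
]

RTOL = 1e-8
ATOL = 1e-12
GRID_DT = 1.0
#: maximum burn-in when integrating to the pre-dose steady state (min)
BURN_IN_MAX = 24.0 * 60.0
#: relative drift per hour below which the baseline counts as stationary
STEADY_TOL = 1e-6
#: default onset delay after oral dosing (min): residence in the oral cavity
#: before inhibitory effects begin
ORAL_ONSET_DELAY = 5.0

PGE2 = "PGE2"
WLTB4 = "wLTB4"


class NetworkValidationError(ValueError):
    """Raised when a network definition does not validate."""


class UnsupportedKineticLawError(ValueError):
    """Raised on SBML import when a kinetic law is outside the subset."""


class MMReaction(BaseModel):
    """Michaelis-Menten reaction.

    ``substrate=None`` denotes a zeroth-order source (rate = Vmax);
    ``product=None`` denotes a degradation sink.
    """

    substrate: Optional[str] = None
    product: Optional[str] = None
    enzyme: str
    vmax: float = Field(ge=0, description="umol/L/min")
    km: float = Field(gt=0, description="umol/L")

    @model_validator(mode="after")
    def _not_both_none(self) -> "MMReaction":
        if self.substrate is None and self.product is None:
            raise ValueError("reaction needs a substrate or a product")
        return self


class FeedbackEdge(BaseModel):
    """Regulatory edge: the regulator species multiplies the target reaction
    rate by (1 + strength*R) for positive sign or 1/(1 + strength*R) for
    negative sign (strength in L/umol)."""

    regulator: str
    target_reaction: int = Field(ge=0, description="index into reactions")
    sign: Literal["positive", "negative"]
    strength: float = Field(ge=0, description="L/umol")


class Species(BaseModel):
    name: str
    initial: float = Field(ge=0, description="umol/L")


class NetworkModel(BaseModel):
    species: list[Species]
    reactions: list[MMReaction]
    feedback_edges: list[FeedbackEdge] = Field(default_factory=list)
    provenance: Literal["sbml_import", "packaged_surrogate", "toy"] = (
        "packaged_surrogate"
    )

    @model_validator(mode="after")
    def _resolve(self) -> "NetworkModel":
        names = {s.name for s in self.species}
        if len(names) != len(self.species):
            raise ValueError("duplicate species names")
        for i, r in enumerate(self.reactions):
            for side in (r.substrate, r.product):
                if side is not None and side not in names:
                    raise ValueError(
                        f"reaction {i}: unknown species {side!r}"
                    )
        for e in self.feedback_edges:
            if e.regulator not in names:
                raise ValueError(f"feedback regulator {e.regulator!r} unknown")
            if e.target_reaction >= len(self.reactions):
                raise ValueError("feedback target reaction out of range")
        return self

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise NetworkValidationError(f"unknown species {name!r}") from None

    def require_mediators(self) -> None:
        for name in (PGE2, WLTB4):
            if name not in self.species_names:
                raise NetworkValidationError(
                    f"network must contain mediator species {name!r}"
                )


@dataclass
class InhibitorSignal:
    """Time-resolved unbound drug concentration bound to a target enzyme.

    ``concentration`` maps time (min, relative to dosing) to unbound
    concentration (umol/L).  The contribution is exactly zero for
    ``t < onset_delay`` (oral-cavity residence)."""

    drug: str
    target_enzyme: str
    ki: float  # umol/L
    concentration: Callable[[float], float]
    onset_delay: float = ORAL_ONSET_DELAY

    def __post_init__(self) -> None:
        if self.ki <= 0:
            raise ValueError("Ki must be positive")

    def __call__(self, t: float) -> float:
        if t < self.onset_delay:
            return 0.0
        c = self.concentration(t)
        return c if c > 0.0 else 0.0


@dataclass
class MediatorProfile:
    """Mediator (and full species) trajectories from one network run."""

    times: np.ndarray
    concentrations: np.ndarray  # n_species x n_times
    species_names: list[str]
    label: str = "control"

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[self.species_names.index(name)]

    @property
    def pge2(self) -> np.ndarray:
        return self.species(PGE2)

    @property
    def wltb4(self) -> np.ndarray:
        return self.species(WLTB4)

    def at(self, name: str, t: float) -> float:
        return float(np.interp(t, self.times, self.species(name)))


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def effective_km(
    reaction: MMReaction, signals: Sequence[InhibitorSignal], t: float
) -> float:
    """Competitive-inhibition effective Km at time ``t``.

    Km_eff = Km * (1 + sum I_i(t)/Ki_i) over the signals targeting this
    reaction's enzyme; inhibitors combine additively.
    """
    term = 0.0
    for s in signals:
        if s.target_enzyme == reaction.enzyme:
            term += s(t) / s.ki
    return reaction.km * (1.0 + term)


def _rhs_factory(
    model: NetworkModel, signals: Sequence[InhibitorSignal]
) -> Callable[[float, np.ndarray], np.ndarray]:
    n = len(model.species)
    sub_idx = np.array(
        [model.index(r.substrate) if r.substrate else -1 for r in model.reactions]
    )
    prod_idx = np.array(
        [model.index(r.product) if r.product else -1 for r in model.reactions]
    )
    vmax = np.array([r.vmax for r in model.reactions])
    km = np.array([r.km for r in model.reactions])
    by_reaction: list[list[InhibitorSignal]] = [
        [s for s in signals if s.target_enzyme == r.enzyme] for r in model.reactions
    ]
    fb: list[list[FeedbackEdge]] = [[] for _ in model.reactions]
    for e in model.feedback_edges:
        fb[e.target_reaction].append(e)
    reg_idx = {e.regulator: model.index(e.regulator) for e in model.feedback_edges}

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n)
        for j in range(len(vmax)):
            kme = km[j]
            if by_reaction[j]:
                term = 0.0
                for s in by_reaction[j]:
                    term += s(t) / s.ki
                kme = km[j] * (1.0 + term)
            if sub_idx[j] >= 0:
                s_conc = max(y[sub_idx[j]], 0.0)
                v = vmax[j] * s_conc / (kme + s_conc)
            else:
                v = vmax[j]
            for e in fb[j]:
                r_conc = max(y[reg_idx[e.regulator]], 0.0)
                if e.sign == "positive":
                    v *= 1.0 + e.strength * r_conc
                else:
                    v /= 1.0 + e.strength * r_conc
            if sub_idx[j] >= 0:
                dy[sub_idx[j]] -= v
            if prod_idx[j] >= 0:
                dy[prod_idx[j]] += v
        return dy

    return rhs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def equilibrate(
    model: NetworkModel,
    max_time: float = BURN_IN_MAX,
    chunk: float = 360.0,
    tol: float = STEADY_TOL,
) -> np.ndarray:
    """Integrate the drug-free network to its pre-dose baseline.

    Runs in ``chunk``-minute pieces up to ``max_time`` (24 h default),
    stopping early when the largest relative rate of change drops below
    ``tol`` per minute.  Returns the baseline state vector.
    """
    rhs = _rhs_factory(model, [])
    y = np.array([s.initial for s in model.species], dtype=float)
    t = 0.0
    while t < max_time:
        sol = solve_ivp(rhs, (t, t + chunk), y, method="LSODA", rtol=RTOL, atol=ATOL)
        if not sol.success:
            raise RuntimeError(f"burn-in failed: {sol.message}")
        y = sol.y[:, -1]
        t += chunk
        dy = rhs(t, y)
        scale = np.maximum(np.abs(y), 1e-9)
        if np.max(np.abs(dy) / scale) < tol:
            break
    return y


def simulate_network(
    model: NetworkModel,
    signals: Sequence[InhibitorSignal],
    span: float,
    y0: Optional[np.ndarray] = None,
    grid_dt: float = GRID_DT,
    label: Optional[str] = None,
) -> MediatorProfile:
    """Simulate mediator trajectories under time-varying competitive inhibition.

    ``y0`` is the pre-equilibrated baseline (computed if omitted).  The
    control run is the same call with empty ``signals``; integration is
    deterministic, so repeated control runs are bit-identical.
    """
    model.require_mediators()
    if y0 is None:
        y0 = equilibrate(model)
    rhs = _rhs_factory(model, signals)
    grid = np.arange(0.0, span + 0.5 * grid_dt, grid_dt)
    # break integration at inhibitor onset times so the solver never steps
    # across the discontinuity in Km_eff(t)
    onsets = sorted({s.onset_delay for s in signals if 0.0 < s.onset_delay < span})
    boundaries = [0.0, *onsets, span]
    y = np.asarray(y0, dtype=float).copy()
    out = np.zeros((len(model.species), len(grid)))
    for k, (a, b) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        last = k == len(boundaries) - 2
        mask = (grid >= a - 1e-9) & ((grid <= b + 1e-9) if last else (grid < b - 1e-9))
        t_eval = np.clip(grid[mask], a, b)
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", rtol=RTOL, atol=ATOL,
            t_eval=t_eval if len(t_eval) else None,
        )
        if not sol.success:
            raise RuntimeError(f"network integration failed at t~{sol.t[-1]:.1f}: {sol.message}")
        if len(t_eval):
            out[:, mask] = sol.y
        if sol.t[-1] < b - 1e-9:
            sol2 = solve_ivp(rhs, (sol.t[-1], b), sol.y[:, -1],
                             method="LSODA", rtol=RTOL, atol=ATOL)
            y = sol2.y[:, -1].copy()
        else:
            y = sol.y[:, -1].copy()
    neg = out.min()
    if neg < -1e-6:
        i = int(np.unravel_index(np.argmin(out), out.shape)[0])
        raise RuntimeError(
            f"negative excursion ({neg:.3g}) in species {model.species_names[i]!r}"
        )
    np.clip(out, 0.0, None, out=out)
    return MediatorProfile(
        times=grid,
        concentrations=out,
        species_names=model.species_names,
        label=label or ("control" if not signals else "drug-treated"),
    )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_network(source) -> NetworkModel:
    """Load a network from the packaged surrogate id, a YAML file, or SBML.

    ``source`` may be the string ``"surrogate"``, a path ending in
    ``.yaml``/``.yml``, or a path to an SBML ``.xml``/``.sbml`` file.
    """
    if source == "surrogate":
        from importlib.resources import files

        text = (files("aaqsp") / "data" / "network" / "surrogate.yaml").read_text()
        model = NetworkModel.model_validate(yaml.safe_load(text))
    else:
        p = str(source)
        if p.endswith((".yaml", ".yml")):
            with open(p) as fh:
                model = NetworkModel.model_validate(yaml.safe_load(fh))
        elif p.endswith((".xml", ".sbml")):
            model = read_sbml(p)
        else:
            raise NetworkValidationError(
                f"unrecognized network source {source!r} "
                "(expected 'surrogate', YAML, or SBML path)"
            )
    model.require_mediators()
    return model


# ---------------------------------------------------------------------------
# SBML subset I/O (Level 3 Version 2)
# ---------------------------------------------------------------------------

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
AAQSP_NS = "https://aaqsp.invalid/sbml-annotations"


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def write_sbml(model: NetworkModel, path) -> None:
    """Export the network as SBML L3V2 with explicit MM kinetic laws.

    Sources are written as constant-rate laws, sinks and conversions as
    ``Vmax*S/(Km+S)`` with local parameters Vmax and Km.  Feedback edges are
    carried in a package annotation (they are regulatory multipliers, not
    mass-action reactions).
    """
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap, level="3", version="2")
    sbml_model = etree.SubElement(root, f"{{{SBML_NS}}}model", id="aa_network")
    if model.feedback_edges:
        ann = etree.SubElement(sbml_model, f"{{{SBML_NS}}}annotation")
        fb = etree.SubElement(ann, f"{{{AAQSP_NS}}}feedbackEdges",
                              nsmap={"aaqsp": AAQSP_NS})
        for e in model.feedback_edges:
            etree.SubElement(
                fb, f"{{{AAQSP_NS}}}edge",
                regulator=e.regulator, target=str(e.target_reaction),
                sign=e.sign, strength=repr(e.strength),
            )
    comps = etree.SubElement(sbml_model, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(comps, f"{{{SBML_NS}}}compartment", id="cell", size="1",
                     constant="true")
    sp_list = etree.SubElement(sbml_model, f"{{{SBML_NS}}}listOfSpecies")
    for s in model.species:
        etree.SubElement(
            sp_list, f"{{{SBML_NS}}}species", id=s.name, compartment="cell",
            initialConcentration=repr(s.initial), hasOnlySubstanceUnits="false",
            boundaryCondition="false", constant="false",
        )
    rx_list = etree.SubElement(sbml_model, f"{{{SBML_NS}}}listOfReactions")
    for j, r in enumerate(model.reactions):
        rx = etree.SubElement(rx_list, f"{{{SBML_NS}}}reaction",
                              id=f"r{j}", name=r.enzyme, reversible="false")
        if r.substrate:
            lo = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            etree.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                             species=r.substrate, stoichiometry="1",
                             constant="true")
        if r.product:
            lo = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            etree.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                             species=r.product, stoichiometry="1",
                             constant="true")
        kl = etree.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, _m("math"), nsmap={None: MATHML_NS})
        if r.substrate is None:
            ci = etree.SubElement(math, _m("ci"))
            ci.text = " Vmax "
        else:
            # Vmax * S / (Km + S)
            outer = etree.SubElement(math, _m("apply"))
            etree.SubElement(outer, _m("divide"))
            times = etree.SubElement(outer, _m("apply"))
            etree.SubElement(times, _m("times"))
            etree.SubElement(times, _m("ci")).text = " Vmax "
            etree.SubElement(times, _m("ci")).text = f" {r.substrate} "
            plus = etree.SubElement(outer, _m("apply"))
            etree.SubElement(plus, _m("plus"))
            etree.SubElement(plus, _m("ci")).text = " Km "
            etree.SubElement(plus, _m("ci")).text = f" {r.substrate} "
        lp = etree.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        etree.SubElement(lp, f"{{{SBML_NS}}}localParameter", id="Vmax",
                         value=repr(r.vmax))
        if r.substrate is not None:
            etree.SubElement(lp, f"{{{SBML_NS}}}localParameter", id="Km",
                             value=repr(r.km))
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)


def _mathml_signature(math: etree._Element) -> tuple[str, Optional[str]]:
    """Classify a kinetic-law MathML tree.

    Returns ("constant", None), ("mm", substrate) for Vmax*S/(Km+S), or
    ("mass_action", substrate) for k*S.  Anything else is unsupported.
    """
    children = [c for c in math if isinstance(c.tag, str)]
    if len(children) != 1:
        raise UnsupportedKineticLawError(etree.tostring(math, encoding="unicode"))
    node = children[0]

    def tag(el: etree._Element) -> str:
        return etree.QName(el).localname

    def ci(el: etree._Element) -> Optional[str]:
        return el.text.strip() if tag(el) == "ci" and el.text else None

    if tag(node) == "ci":
        return "constant", None
    if tag(node) != "apply":
        raise UnsupportedKineticLawError(etree.tostring(math, encoding="unicode"))
    parts = [c for c in node if isinstance(c.tag, str)]
    op = tag(parts[0])
    if op == "divide" and len(parts) == 3:
        num, den = parts[1], parts[2]
        if tag(num) == "apply" and tag(den) == "apply":
            nparts = [c for c in num if isinstance(c.tag, str)]
            dparts = [c for c in den if isinstance(c.tag, str)]
            if (
                tag(nparts[0]) == "times"
                and len(nparts) == 3
                and tag(dparts[0]) == "plus"
                and len(dparts) == 3
            ):
                s_num = ci(nparts[2])
                s_den = ci(dparts[2])
                if (
                    ci(nparts[1]) == "Vmax"
                    and ci(dparts[1]) == "Km"
                    and s_num is not None
                    and s_num == s_den
                ):
                    return "mm", s_num
    if op == "times" and len(parts) == 3:
        a, b = ci(parts[1]), ci(parts[2])
        if a is not None and b is not None:
            return "mass_action", b
    raise UnsupportedKineticLawError(etree.tostring(math, encoding="unicode"))


def read_sbml(path) -> NetworkModel:
    """Import an SBML L3 model restricted to the supported kinetic-law subset
    (explicit Michaelis-Menten with local Vmax/Km, constant sources, simple
    mass action k*S).  Unsupported laws raise
    :class:`UnsupportedKineticLawError` listing the offending law."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = {"s": etree.QName(root).namespace, "m": MATHML_NS, "a": AAQSP_NS}
    species = [
        Species(
            name=el.get("id"),
            initial=float(el.get("initialConcentration", "0") or 0.0),
        )
        for el in root.findall(".//s:listOfSpecies/s:species", ns)
    ]
    global_params = {
        el.get("id"): float(el.get("value", "nan"))
        for el in root.findall(".//s:listOfParameters/s:parameter", ns)
    }
    reactions: list[MMReaction] = []
    for rx in root.findall(".//s:listOfReactions/s:reaction", ns):
        substrate = None
        product = None
        ref = rx.find("s:listOfReactants/s:speciesReference", ns)
        if ref is not None:
            substrate = ref.get("species")
        ref = rx.find("s:listOfProducts/s:speciesReference", ns)
        if ref is not None:
            product = ref.get("species")
        kl = rx.find("s:kineticLaw", ns)
        if kl is None:
            raise UnsupportedKineticLawError(f"reaction {rx.get('id')}: no kinetic law")
        local = dict(global_params)
        for lp in kl.findall("s:listOfLocalParameters/s:localParameter", ns) + \
                kl.findall("s:listOfParameters/s:parameter", ns):
            local[lp.get("id")] = float(lp.get("value", "nan"))
        math = kl.find("m:math", ns)
        if math is None:
            raise UnsupportedKineticLawError(f"reaction {rx.get('id')}: no math")
        kind, s_name = _mathml_signature(math)
        enzyme = rx.get("name") or rx.get("id")
        if kind == "constant":
            reactions.append(
                MMReaction(substrate=None, product=product, enzyme=enzyme,
                           vmax=local["Vmax"], km=1.0)
            )
        elif kind == "mm":
            if s_name != substrate:
                raise UnsupportedKineticLawError(
                    f"reaction {rx.get('id')}: kinetic-law species {s_name!r} "
                    f"does not match reactant {substrate!r}"
                )
            reactions.append(
                MMReaction(substrate=substrate, product=product, enzyme=enzyme,
                           vmax=local["Vmax"], km=local["Km"])
            )
        else:  # mass action k*S: represent as MM in the linear regime
            k = next(iter(local.values()))
            big_km = 1e6
            reactions.append(
                MMReaction(substrate=substrate, product=product, enzyme=enzyme,
                           vmax=k * big_km, km=big_km)
            )
    feedback = []
    for edge in root.findall(".//a:feedbackEdges/a:edge", ns):
        feedback.append(
            FeedbackEdge(
                regulator=edge.get("regulator"),
                target_reaction=int(edge.get("target")),
                sign=edge.get("sign"),
                strength=float(edge.get("strength")),
            )
        )
    return NetworkModel(
        species=species, reactions=reactions, feedback_edges=feedback,
        provenance="sbml_import",
    )
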