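"""Whole-body PBPK circulation network and patient/protocol scaling rules.

The model is a directed graph of well-stirred organ/vessel compartments
connected by blood flow, in the tradition of the Bae contrast-kinetics
models: peripheral vein -> right heart -> lungs -> left heart -> systemic
organs -> veins -> right heart.  The reference network describes a 60-kg,
1.7-m adult with a left-heart output of 6500 ml/min; the stomach, spleen,
pancreas and myocardium are modelled as distinct compartments with resting
regional-flow fractions.  Simulating another subject scales all flows and
volumes in direct proportion to body weight and then rescales every flow so
the left-heart output matches the target cardiac output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PatientModel",
    "ContrastAgent",
    "InjectionProtocol",
    "CompartmentSpec",
    "PBPKNetwork",
    "NetworkConfigError",
    "estimate_cardiac_output",
    "body_surface_area",
    "required_cm_volume",
    "build_reference_network",
    "scale_to_weight",
    "adjust_to_cardiac_output",
    "IOPAMIDOL_370",
    "SIMULATION_AGENT_350",
    "REFERENCE_WEIGHT_KG",
    "REFERENCE_LEFT_HEART_OUTPUT",
    "reference_subject",
    "representative_subject",
    "test_bolus_protocol",
]

#: Body weight (kg) of the subject the reference parameter table describes.
REFERENCE_WEIGHT_KG = 60.0
#: Left-heart output (ml/min) of the unscaled reference network.
REFERENCE_LEFT_HEART_OUTPUT = 6500.0

#: Name of the left-heart compartment in the shipped parameter table.
LEFT_HEART = "left_heart"
#: Compartment receiving the intravenous injection (antecubital vein).
INJECTION_SITE = "peripheral_vein"

SALINE_OSMOLALITY = 290.0  # mOsm/kg H2O, physiological saline reference


class NetworkConfigError(ValueError):
    """Malformed compartment/topology parameter file."""


# --------------------------------------------------------------------------
# scalar anthropometric formulas
# --------------------------------------------------------------------------

def estimate_cardiac_output(height: float, weight: float) -> float:
    """Estimate cardiac output (ml/min) from height (cm) and weight (kg).

    Power-law allometric estimate ``25.3 * H**0.725 * W**0.425`` used when
    no measured cardiac output is available.
    """
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    return 25.3 * height**0.725 * weight**0.425


def body_surface_area(height: float, weight: float) -> float:
    """DuBois body surface area (m^2) from height (cm) and weight (kg)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * height**0.725 * weight**0.425


def required_cm_volume(iodine_dose: float, weight: float,
                       concentration: float) -> float:
    """Contrast volume (ml, to 0.1 ml) delivering ``iodine_dose`` mgI/kg.

    ``dose * weight / concentration`` for an agent of ``concentration``
    mgI/ml; e.g. 245 mgI/kg in a 65-kg subject with a 350 mgI/ml agent
    requires 45.5 ml.
    """
    if iodine_dose < 0 or weight <= 0:
        raise ValueError("dose must be >= 0 and weight positive")
    if concentration <= 0:
        raise ValueError("iodine concentration must be positive")
    return round(iodine_dose * weight / concentration, 1)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientModel:
    """Anthropometrics and circulatory state of one simulated subject.

    ``cardiac_output`` (ml/min) is estimated from height and weight when
    not given.  ``pulse_rate`` is carried for provenance but plays no role
    in the kinetic model.  Derived quantities: DuBois ``body_surface_area``
    (m^2) and ``cardiac_index`` (l/min/m^2).
    """

    height: float
    weight: float
    cardiac_output: float | None = None
    pulse_rate: float | None = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if self.cardiac_output is None:
            object.__setattr__(
                self, "cardiac_output",
                estimate_cardiac_output(self.height, self.weight))
        if self.cardiac_output <= 0:
            raise ValueError("cardiac_output must be positive")

    @property
    def body_surface_area(self) -> float:
        return body_surface_area(self.height, self.weight)

    @property
    def cardiac_index(self) -> float:
        """Cardiac output per body surface area, l/min/m^2."""
        return self.cardiac_output / self.body_surface_area / 1000.0

    @classmethod
    def from_cardiac_index(cls, height: float, weight: float,
                           cardiac_index: float,
                           pulse_rate: float | None = None) -> "PatientModel":
        co = cardiac_index * body_surface_area(height, weight) * 1000.0
        return cls(height, weight, cardiac_output=co, pulse_rate=pulse_rate)


@dataclass(frozen=True)
class ContrastAgent:
    """Physicochemical description of an iodinated contrast material.

    The osmotic ratio (osmolality relative to saline) and viscosity drive
    the agent-specific diffusion-speed scaling; either ``osmotic_ratio`` or
    an absolute ``osmolality`` (mOsm/kg H2O, divided by 290 for saline) may
    be given.
    """

    name: str
    iodine_concentration: float  # mgI/ml
    viscosity: float             # mPa*s
    osmotic_ratio: float | None = None
    osmolality: float | None = None

    def __post_init__(self) -> None:
        if self.iodine_concentration <= 0:
            raise ValueError("iodine_concentration must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.osmotic_ratio is None:
            if self.osmolality is None:
                raise ValueError("give osmotic_ratio or osmolality")
            object.__setattr__(self, "osmotic_ratio",
                               self.osmolality / SALINE_OSMOLALITY)
        if self.osmotic_ratio <= 0:
            raise ValueError("osmotic_ratio must be positive")


#: Reference agent used for calibration (370 mgI/ml, osmotic ratio 2.76,
#: viscosity 9.1 mPa*s).
IOPAMIDOL_370 = ContrastAgent("Iopamidol-370", 370.0, 9.1, osmotic_ratio=2.76)

#: Agent of the cardiac-index sweep studies: 350 mgI/ml, 590 mOsm/kg H2O.
#: Viscosity of a typical 350 mgI/ml nonionic monomer at body temperature.
SIMULATION_AGENT_350 = ContrastAgent("CM-350", 350.0, 7.0, osmolality=590.0)


@dataclass(frozen=True)
class InjectionProtocol:
    """Uniphasic contrast injection followed by a saline flush.

    Exactly one of ``injection_duration`` (s) or ``injection_rate`` (ml/s)
    is given; the other is derived from ``cm_volume`` (ml).  The flush
    carries volumetric flow but no iodine.
    """

    cm_volume: float
    agent: ContrastAgent
    injection_duration: float | None = None
    injection_rate: float | None = None
    flush_volume: float = 0.0
    flush_rate: float | None = None

    def __post_init__(self) -> None:
        if self.cm_volume < 0:
            raise ValueError("cm_volume must be >= 0")
        given = (self.injection_duration is not None,
                 self.injection_rate is not None)
        if sum(given) != 1:
            raise ValueError(
                "give exactly one of injection_duration or injection_rate")
        if self.injection_duration is None:
            if self.injection_rate <= 0:
                raise ValueError("injection_rate must be positive")
            object.__setattr__(self, "injection_duration",
                               self.cm_volume / self.injection_rate)
        else:
            if self.injection_duration <= 0:
                raise ValueError("injection_duration must be positive")
            object.__setattr__(self, "injection_rate",
                               self.cm_volume / self.injection_duration)
        if self.flush_volume < 0:
            raise ValueError("flush_volume must be >= 0")
        if self.flush_rate is None:
            # flush delivered at the contrast rate, the usual clinical setup
            object.__setattr__(self, "flush_rate", self.injection_rate)

    @property
    def flush_duration(self) -> float:
        if self.flush_volume == 0:
            return 0.0
        return self.flush_volume / self.flush_rate

    @property
    def total_iodine(self) -> float:
        """Total injected iodine mass (mg)."""
        return self.cm_volume * self.agent.iodine_concentration


@dataclass(frozen=True)
class CompartmentSpec:
    """Flows and volumes of one organ or vessel compartment.

    ``blood_flow`` Q (ml/min), intravascular volume ``v_iv`` (ml),
    extracellular volume ``v_ec`` (ml), ``n_sub`` equal sub-compartments in
    series (axial transmission), and first-order transcapillary exchange
    coefficient ``k_tc`` (1/min) with the extracellular pool.
    """

    name: str
    blood_flow: float
    v_iv: float
    v_ec: float = 0.0
    n_sub: int = 15
    k_tc: float = 0.0

    def __post_init__(self) -> None:
        if self.blood_flow < 0 or self.v_iv < 0 or self.v_ec < 0:
            raise ValueError(f"{self.name}: flows and volumes must be >= 0")
        if self.n_sub < 1:
            raise ValueError(f"{self.name}: n_sub must be >= 1")
        if self.k_tc < 0:
            raise ValueError(f"{self.name}: k_tc must be >= 0")


@dataclass(frozen=True)
class PBPKNetwork:
    """Directed circulation graph of compartments connected by blood flow."""

    compartments: tuple[CompartmentSpec, ...]
    edges: tuple[tuple[str, str, float], ...]  # (source, destination, ml/min)
    injection_site: str = INJECTION_SITE
    roi_map: dict[str, str] = field(default_factory=dict)
    left_heart: str = LEFT_HEART

    def __post_init__(self) -> None:
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise NetworkConfigError("duplicate compartment names")
        idx = set(names)
        for s, d, q in self.edges:
            if s not in idx or d not in idx:
                raise NetworkConfigError(f"edge {s}->{d} references unknown "
                                         "compartment")
            if q < 0:
                raise NetworkConfigError(f"edge {s}->{d} has negative flow")
        if self.injection_site not in idx:
            raise NetworkConfigError(
                f"injection site {self.injection_site!r} not in network")
        for roi, comp in self.roi_map.items():
            if comp not in idx:
                raise NetworkConfigError(f"roi {roi!r} maps to unknown "
                                         f"compartment {comp!r}")

    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def inflow(self, name: str) -> float:
        return sum(q for _, d, q in self.edges if d == name)

    def outflow(self, name: str) -> float:
        return sum(q for s, _, q in self.edges if s == name)

    def outflow_edges(self, name: str) -> list[tuple[str, float]]:
        return [(d, q) for s, d, q in self.edges if s == name]

    def inflow_edges(self, name: str) -> list[tuple[str, float]]:
        return [(s, q) for s, d, q in self.edges if d == name]

    @property
    def left_heart_output(self) -> float:
        return self.outflow(self.left_heart)

    def flow_imbalance(self) -> dict[str, float]:
        """Relative |inflow - outflow| / max(inflow, outflow) per node."""
        out = {}
        for c in self.compartments:
            fin, fout = self.inflow(c.name), self.outflow(c.name)
            scale = max(fin, fout, 1e-300)
            out[c.name] = abs(fin - fout) / scale
        return out

    def check_flow_balance(self, rtol: float = 1e-6) -> None:
        bad = {n: v for n, v in self.flow_imbalance().items() if v > rtol}
        if bad:
            raise NetworkConfigError(f"flow imbalance at {sorted(bad)}")

    def is_strongly_connected(self) -> bool:
        """True if every compartment is reachable round the circulation."""
        adj: dict[str, list[str]] = {c.name: [] for c in self.compartments}
        radj: dict[str, list[str]] = {c.name: [] for c in self.compartments}
        for s, d, q in self.edges:
            if q > 0:
                adj[s].append(d)
                radj[d].append(s)

        def reach(start: str, graph: dict[str, list[str]]) -> set[str]:
            seen, stack = {start}, [start]
            while stack:
                for nxt in graph[stack.pop()]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            return seen

        start = self.compartments[0].name
        n = len(self.compartments)
        return len(reach(start, adj)) == n and len(reach(start, radj)) == n


# --------------------------------------------------------------------------
# network construction and scaling
# --------------------------------------------------------------------------

def _data_path(filename: str) -> Path:
    return Path(resources.files("ctbolus").joinpath("data", filename))


def build_reference_network(
    compartment_file: str | Path | None = None,
    topology_file: str | Path | None = None,
) -> PBPKNetwork:
    """Load the reference 60-kg network from the shipped parameter tables.

    Users may substitute their own tables; the loader validates per-node
    flow balance, consistency between the compartment flow column and the
    edge list, and the 6500 ml/min left-heart output of the reference.
    """
    cpath = Path(compartment_file) if compartment_file else _data_path(
        "compartments.tsv")
    tpath = Path(topology_file) if topology_file else _data_path(
        "topology.tsv")
    try:
        ctab = pd.read_csv(cpath, sep="\t", comment="#")
        ttab = pd.read_csv(tpath, sep="\t", comment="#")
    except Exception as exc:  # noqa: BLE001 - surfaced as config error
        raise NetworkConfigError(f"cannot read parameter tables: {exc}")

    required = {"name", "blood_flow", "v_iv", "v_ec", "n_sub", "k_tc"}
    if not required.issubset(ctab.columns):
        raise NetworkConfigError(
            f"compartment table must have columns {sorted(required)}")
    comps = []
    for row in ctab.itertuples(index=False):
        try:
            comps.append(CompartmentSpec(
                name=str(row.name), blood_flow=float(row.blood_flow),
                v_iv=float(row.v_iv), v_ec=float(row.v_ec),
                n_sub=int(row.n_sub), k_tc=float(row.k_tc)))
        except (TypeError, ValueError) as exc:
            raise NetworkConfigError(f"compartment {row.name!r}: {exc}")

    edges = tuple((str(r.source), str(r.destination), float(r.flow))
                  for r in ttab.itertuples(index=False))
    net = PBPKNetwork(
        compartments=tuple(comps), edges=edges,
        roi_map={"ascending_aorta": "ascending_aorta",
                 "abdominal_aorta": "abdominal_aorta",
                 "aorta": "ascending_aorta"})

    for c in net.compartments:
        if not math.isclose(net.inflow(c.name), c.blood_flow, rel_tol=1e-6):
            raise NetworkConfigError(
                f"compartment {c.name!r}: blood_flow column "
                f"{c.blood_flow} disagrees with edge inflow "
                f"{net.inflow(c.name)}")
    net.check_flow_balance()
    if not math.isclose(net.left_heart_output,
                        REFERENCE_LEFT_HEART_OUTPUT, rel_tol=1e-9):
        raise NetworkConfigError(
            f"reference left-heart output is {net.left_heart_output}, "
            f"expected {REFERENCE_LEFT_HEART_OUTPUT}")
    if not net.is_strongly_connected():
        raise NetworkConfigError("circulation graph is not a closed loop")
    return net


def scale_to_weight(reference: PBPKNetwork, weight: float) -> PBPKNetwork:
    """Scale every flow and volume in direct proportion to body weight.

    The reference table describes a 60-kg subject; a ``weight``-kg subject
    gets all blood flows, intravascular and extracellular volumes
    multiplied by ``weight / 60``.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    f = weight / REFERENCE_WEIGHT_KG
    comps = tuple(replace(c, blood_flow=c.blood_flow * f, v_iv=c.v_iv * f,
                          v_ec=c.v_ec * f)
                  for c in reference.compartments)
    edges = tuple((s, d, q * f) for s, d, q in reference.edges)
    return replace(reference, compartments=comps, edges=edges)


def adjust_to_cardiac_output(network: PBPKNetwork,
                             target_co: float) -> PBPKNetwork:
    """Rescale all flows so the left-heart output equals ``target_co``.

    The adjustment factor is ``target_co`` divided by the network's current
    left-heart output (for the unscaled reference that divisor is 6500
    ml/min); volumes are unchanged, so flow balance is preserved and the
    post-condition left-heart output == target always holds.
    """
    if target_co <= 0:
        raise ValueError("target cardiac output must be positive")
    f = target_co / network.left_heart_output
    comps = tuple(replace(c, blood_flow=c.blood_flow * f)
                  for c in network.compartments)
    edges = tuple((s, d, q * f) for s, d, q in network.edges)
    return replace(network, compartments=comps, edges=edges)


def patient_network(patient: PatientModel,
                    reference: PBPKNetwork | None = None) -> PBPKNetwork:
    """Weight-scaled, CO-adjusted network for one patient."""
    ref = reference if reference is not None else build_reference_network()
    return adjust_to_cardiac_output(scale_to_weight(ref, patient.weight),
                                    patient.cardiac_output)


# --------------------------------------------------------------------------
# named presets
# --------------------------------------------------------------------------

def reference_subject() -> PatientModel:
    """The 60-kg, 1.7-m subject the reference parameter table describes."""
    return PatientModel(height=170.0, weight=60.0)


def representative_subject(cardiac_index: float | None = None) -> PatientModel:
    """The 166-cm, 65.0-kg representative male of the sweep studies."""
    if cardiac_index is None:
        return PatientModel(height=166.0, weight=65.0)
    return PatientModel.from_cardiac_index(166.0, 65.0, cardiac_index)


def test_bolus_protocol() -> InjectionProtocol:
    """Timing bolus: 20 ml Iopamidol-370 at 4.0 ml/s + 20 ml saline flush."""
    return InjectionProtocol(cm_volume=20.0, agent=IOPAMIDOL_370,
                             injection_rate=4.0, flush_volume=20.0,
                             flush_rate=4.0)
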