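"""Lumped-parameter (0D) model of the multi-tear dissected aorta.

The dissected aorta is reduced to a node/element network: true-lumen
and false-lumen segment chains (Poiseuille resistance + inertance),
tear orifices connecting them (linear + quadratic pressure loss),
arch-branch and distal outlets closed by three-element Windkessels,
and a prescribed periodic inlet flow.  The wall is rigid, so all
compliance resides in the outlets.

Per time step (implicit Euler on the outlet compliance states and the
segment inertances) the nonlinear nodal system — Kirchhoff flow balance
at every node — is solved by Newton's method with an analytic Jacobian.
Cycles are repeated until the cycle-mean nodal pressures change by less
than a periodicity tolerance.

Element laws (SI internally; interfaces in mm, L/min, mmHg):

* segment:  dP = R Q + L dQ/dt,  R = 8 eta(gamma_ref) l / (pi r^4),
  L = rho l / A
* tear:     dP = R_lin Q + (rho / (2 Cd^2 A^2)) Q |Q|   (odd in Q)
* outlet:   three-element Windkessel (see :mod:`dissectflow.windkessel`)
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .rheology import FluidProperties, PowerLawParams, apparent_viscosity
from .units import LMIN_TO_M3S, M3S_TO_LMIN, MMHG_TO_PA, PA_TO_MMHG
from .waveform import FlowWaveform
from .windkessel import WindkesselParams, _R_TO_SI, _C_TO_SI

__all__ = [
    "Segment",
    "Tear",
    "Outlet",
    "DissectionNetwork",
    "NetworkSolution",
    "segment_resistance",
    "segment_inertance",
    "tear_element",
    "build_network",
    "solve",
    "occlude_tear",
    "report_metrics",
]


def segment_resistance(length_mm: float, radius_mm: float,
                       rheology: PowerLawParams,
                       reference_shear_rate: float = 100.0) -> float:
    """Poiseuille resistance 8 eta L / (pi r^4) in Pa·s/m^3.

    The power-law viscosity is frozen at a reference shear rate
    (default 100 1/s), linearizing the segment law.
    """
    if length_mm <= 0 or radius_mm <= 0:
        raise ValueError("segment geometry must be positive")
    eta = apparent_viscosity(rheology, reference_shear_rate)
    l_m = length_mm * 1e-3
    r_m = radius_mm * 1e-3
    return 8.0 * eta * l_m / (np.pi * r_m**4)


def segment_inertance(length_mm: float, radius_mm: float,
                      density: float = 1022.0) -> float:
    """Blood column inertance rho L / A in Pa·s^2/m^3."""
    l_m = length_mm * 1e-3
    area = np.pi * (radius_mm * 1e-3) ** 2
    return density * l_m / area


def tear_element(diameter_mm: float, discharge_coefficient: float = 0.6,
                 density: float = 1022.0, flap_thickness_mm: float = 2.0,
                 rheology: PowerLawParams | None = None,
                 reference_shear_rate: float = 100.0,
                 ) -> tuple[float, float]:
    """Orifice law coefficients ``(R_lin, k_quad)`` for a flap tear.

    dP = R_lin Q + k_quad Q |Q| — an odd, strictly increasing function
    of Q with dP(0) = 0.  The linear term is Poiseuille flow through the
    flap thickness; the quadratic term is the sharp-edged orifice loss
    rho / (2 Cd^2 A^2).
    """
    if diameter_mm <= 0:
        raise ValueError("tear diameter must be > 0")
    if not (0 < discharge_coefficient <= 1):
        raise ValueError("discharge coefficient must be in (0, 1]")
    if rheology is None:
        rheology = PowerLawParams()
    area = np.pi * (diameter_mm * 1e-3 / 2.0) ** 2
    r_lin = segment_resistance(flap_thickness_mm, diameter_mm / 2.0,
                               rheology, reference_shear_rate)
    k_quad = density / (2.0 * discharge_coefficient**2 * area**2)
    return r_lin, k_quad


def tear_pressure_drop(q_m3s, r_lin: float, k_quad: float):
    """Orifice pressure drop (Pa) for a signed flow (m^3/s)."""
    q = np.asarray(q_m3s, dtype=float)
    out = r_lin * q + k_quad * q * np.abs(q)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class Segment:
    name: str
    node_from: str
    node_to: str
    resistance: float   # Pa·s/m^3
    inertance: float    # Pa·s^2/m^3
    lumen: str = "TL"


@dataclass
class Tear:
    name: str
    node_from: str  # TL side; positive flow is TL -> FL
    node_to: str
    r_lin: float
    k_quad: float
    open: bool = True
    diameter_mm: float = 5.0
    kind: str = "re-entry"


@dataclass
class Outlet:
    name: str
    node: str
    params: WindkesselParams


@dataclass
class DissectionNetwork:
    """Node/element graph of the dissected aorta with one inlet."""

    nodes: list
    segments: list
    tears: list
    outlets: list
    inlet_node: str
    inflow: FlowWaveform
    stations: dict = field(default_factory=dict)
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.nodes)}
        if self.inlet_node not in self._index:
            raise ValueError("inlet node is not part of the network")
        self.validate()

    # ---- structural checks ----

    def _adjacency(self, include_closed: bool = False) -> dict:
        adj = {n: set() for n in self.nodes}
        for s in self.segments:
            adj[s.node_from].add(s.node_to)
            adj[s.node_to].add(s.node_from)
        for t in self.tears:
            if t.open or include_closed:
                adj[t.node_from].add(t.node_to)
                adj[t.node_to].add(t.node_from)
        return adj

    def _reachable(self, start: str, adj: dict) -> set:
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    def validate(self) -> None:
        adj_all = self._adjacency(include_closed=True)
        reach = self._reachable(self.inlet_node, adj_all)
        if set(self.nodes) - reach:
            raise ValueError(
                f"disconnected nodes: {sorted(set(self.nodes) - reach)}")
        # sealed-pouch islands: nodes unreachable via *open* elements
        adj_open = self._adjacency(include_closed=False)
        reach_open = self._reachable(self.inlet_node, adj_open)
        self.sealed_nodes = sorted(set(self.nodes) - reach_open)
        self.sealed_pouch = bool(self.sealed_nodes)

    def element_by_name(self, name: str):
        for e in list(self.segments) + list(self.tears):
            if e.name == name:
                return e
        raise KeyError(f"no element named {name!r}")


def occlude_tear(network: DissectionNetwork, tear_name: str,
                 ) -> DissectionNetwork:
    """Return a copy of the network with one open tear occluded.

    The occluded tear carries identically zero flow; every other
    element is untouched.
    """
    new = copy.deepcopy(network)
    for t in new.tears:
        if t.name == tear_name:
            if not t.open:
                raise ValueError(f"tear {tear_name!r} is already closed")
            t.open = False
            new.validate()
            return new
    raise KeyError(f"no tear named {tear_name!r}")


# Cycle-representative shear rate for the assembled aorta model.
# Diastole occupies most of the cycle at near-zero flow, where the
# shear-thinning viscosity is several-fold higher than at systolic wall
# shear (~70 1/s); evaluating segment resistance at this lower rate
# keeps the inter-lumen loop damped as it is in vivo.
DEFAULT_REFERENCE_SHEAR_RATE = 30.0


def build_network(case, outlet_params: dict, inflow: FlowWaveform,
                  fluid: FluidProperties | None = None,
                  discharge_coefficient: float = 0.6,
                  flap_thickness_mm: float = 2.0,
                  reference_shear_rate: float = DEFAULT_REFERENCE_SHEAR_RATE,
                  ) -> DissectionNetwork:
    """Assemble a solvable network from a case definition.

    ``outlet_params`` maps outlet node names (the arch branch nodes and
    the distal node) to :class:`WindkesselParams`.
    """
    if fluid is None:
        fluid = FluidProperties()
    rheo = fluid.rheology
    nodes = sorted({s["from"] for s in case.segments}
                   | {s["to"] for s in case.segments}
                   | {t["from"] for t in case.tears}
                   | {t["to"] for t in case.tears})
    segments = [
        Segment(
            name=s["name"], node_from=s["from"], node_to=s["to"],
            resistance=segment_resistance(s["length_mm"], s["radius_mm"],
                                          rheo, reference_shear_rate),
            inertance=segment_inertance(s["length_mm"], s["radius_mm"],
                                        fluid.density),
            lumen=s["lumen"],
        )
        for s in case.segments
    ]
    tears = []
    for t in case.tears:
        r_lin, k_quad = tear_element(
            t["diameter_mm"], discharge_coefficient, fluid.density,
            flap_thickness_mm, rheo, reference_shear_rate)
        tears.append(Tear(name=t["name"], node_from=t["from"],
                          node_to=t["to"], r_lin=r_lin, k_quad=k_quad,
                          open=bool(t["open"]), diameter_mm=t["diameter_mm"],
                          kind=t.get("kind", "re-entry")))
    outlets = [Outlet(name=f"out_{node}", node=node, params=p)
               for node, p in outlet_params.items()]
    return DissectionNetwork(
        nodes=nodes, segments=segments, tears=tears, outlets=outlets,
        inlet_node=case.inlet_node, inflow=inflow,
        stations=dict(case.stations), fluid=fluid)


@dataclass
class NetworkSolution:
    """Final-cycle waveforms and convergence report."""

    time_s: np.ndarray
    period_s: float
    pressures_mmHg: dict      # node -> (n_steps,) array
    flows_L_min: dict         # element name -> (n_steps,) array
    cycles_run: int
    max_rel_residual: float
    sealed_pouch: bool
    sealed_nodes: list

    def node_pressure_mean(self, node: str) -> float:
        t = np.append(self.time_s, self.time_s[0] + self.period_s)
        p = np.append(self.pressures_mmHg[node], self.pressures_mmHg[node][0])
        return float(np.trapezoid(p, t) / self.period_s)

    def element_waveform(self, name: str) -> FlowWaveform:
        return FlowWaveform(self.time_s, self.flows_L_min[name],
                            self.period_s)


class NetworkStepper:
    """One implicit-Euler step of the network as a nonlinear system.

    Exposes ``residual`` and ``jacobian`` in nodal pressures (Pa) so
    the per-step system can also be solved by an external dense solver
    (the equivalence oracle in the test suite).
    """

    def __init__(self, network: DissectionNetwork, dt: float):
        self.net = network
        self.dt = dt
        self.n = len(network.nodes)
        self.idx = network._index
        self.open_tears = [t for t in network.tears if t.open]
        # state; outlet compliance pressures start at their DC values
        # under a conductance-proportional share of the mean inflow,
        # which keeps the start-up transient small
        self.q_seg = {s.name: 0.0 for s in network.segments}
        q_mean = network.inflow.cycle_mean() * LMIN_TO_M3S
        conds = {o.name: 1.0 / (o.params.total_resistance * _R_TO_SI)
                 for o in network.outlets}
        g_total = sum(conds.values()) or 1.0
        self.pc = {}
        for o in network.outlets:
            share = q_mean * conds[o.name] / g_total
            self.pc[o.name] = (o.params.distal_pressure_Pout * MMHG_TO_PA
                               + share * o.params.distal_resistance_Rd
                               * _R_TO_SI)
        self.pinned = [network._index[n] for n in network.sealed_nodes]

    # -- element flows for a candidate pressure vector (Pa) --

    def _segment_flow(self, s: Segment, dp: float) -> tuple[float, float]:
        denom = s.resistance + s.inertance / self.dt
        q = (dp + (s.inertance / self.dt) * self.q_seg[s.name]) / denom
        return q, 1.0 / denom

    @staticmethod
    def _tear_flow(t: Tear, dp: float) -> tuple[float, float]:
        a, k = t.r_lin, t.k_quad
        if k == 0.0:
            return dp / a, 1.0 / a
        q = np.sign(dp) * (-a + np.sqrt(a * a + 4.0 * k * abs(dp))) / (2.0 * k)
        return q, 1.0 / (a + 2.0 * k * abs(q))

    def _outlet_flow(self, o: Outlet, p_node: float) -> tuple[float, float]:
        rp = o.params.proximal_resistance_Rp * _R_TO_SI
        rd = o.params.distal_resistance_Rd * _R_TO_SI
        c = o.params.compliance_C * _C_TO_SI
        pout = o.params.distal_pressure_Pout * MMHG_TO_PA
        a_fac = 1.0 + self.dt / (rd * c)
        d_fac = self.dt / c + a_fac * rp
        b_fac = self.pc[o.name] + self.dt * pout / (rd * c)
        q = (a_fac * p_node - b_fac) / d_fac
        return q, a_fac / d_fac

    def residual(self, p: np.ndarray, q_in: float) -> np.ndarray:
        """Nodal flow imbalance (m^3/s) at pressures ``p`` (Pa)."""
        r = np.zeros(self.n)
        for s in self.net.segments:
            i, j = self.idx[s.node_from], self.idx[s.node_to]
            q, _ = self._segment_flow(s, p[i] - p[j])
            r[i] += q
            r[j] -= q
        for t in self.open_tears:
            i, j = self.idx[t.node_from], self.idx[t.node_to]
            q, _ = self._tear_flow(t, p[i] - p[j])
            r[i] += q
            r[j] -= q
        for o in self.net.outlets:
            i = self.idx[o.node]
            q, _ = self._outlet_flow(o, p[i])
            r[i] += q
        r[self.idx[self.net.inlet_node]] -= q_in
        for i in self.pinned:
            r[i] = 0.0  # pressure pinned; no balance equation
        return r

    def jacobian(self, p: np.ndarray) -> np.ndarray:
        jac = np.zeros((self.n, self.n))
        for s in self.net.segments:
            i, j = self.idx[s.node_from], self.idx[s.node_to]
            _, g = self._segment_flow(s, p[i] - p[j])
            jac[i, i] += g
            jac[j, j] += g
            jac[i, j] -= g
            jac[j, i] -= g
        for t in self.open_tears:
            i, j = self.idx[t.node_from], self.idx[t.node_to]
            _, g = self._tear_flow(t, p[i] - p[j])
            jac[i, i] += g
            jac[j, j] += g
            jac[i, j] -= g
            jac[j, i] -= g
        for o in self.net.outlets:
            i = self.idx[o.node]
            _, g = self._outlet_flow(o, p[i])
            jac[i, i] += g
        for i in self.pinned:
            jac[i, :] = 0.0
            jac[:, i] = 0.0
            jac[i, i] = 1.0
        return jac

    def newton_step(self, p: np.ndarray, q_in: float, tol_abs: float,
                    max_iter: int = 50) -> tuple[np.ndarray, float, int]:
        """Solve one implicit step; returns (pressures, residual, iters)."""
        p = p.copy()
        for it in range(max_iter):
            r = self.residual(p, q_in)
            res = float(np.abs(r).max())
            if res < tol_abs:
                return p, res, it
            dp = np.linalg.solve(self.jacobian(p), r)
            p -= dp
        raise RuntimeError(
            f"Newton failed to converge in {max_iter} iterations "
            f"(residual {res:.3e} m^3/s)")

    def commit(self, p: np.ndarray) -> dict:
        """Accept a converged step: update states, return element flows."""
        flows = {}
        for s in self.net.segments:
            i, j = self.idx[s.node_from], self.idx[s.node_to]
            q, _ = self._segment_flow(s, p[i] - p[j])
            self.q_seg[s.name] = q
            flows[s.name] = q
        for t in self.net.tears:
            if t.open:
                i, j = self.idx[t.node_from], self.idx[t.node_to]
                q, _ = self._tear_flow(t, p[i] - p[j])
            else:
                q = 0.0
            flows[t.name] = q
        for o in self.net.outlets:
            i = self.idx[o.node]
            q, _ = self._outlet_flow(o, p[i])
            self.pc[o.name] = p[i] - o.params.proximal_resistance_Rp \
                * _R_TO_SI * q
            flows[o.name] = q
        return flows


def solve(network: DissectionNetwork, dt: float = 0.001,
          max_cycles: int = 50, periodicity_tol: float = 1e-3,
          residual_rel_tol: float = 1e-10) -> NetworkSolution:
    """Integrate the network to a periodic solution.

    Implicit Euler in time; Newton per step; stops when the cycle-mean
    nodal pressures change by less than ``periodicity_tol`` (relative)
    between consecutive cycles.  The Newton tolerance is
    ``residual_rel_tol`` times the peak inlet flow, keeping the
    Kirchhoff imbalance at every node far below the flow scale.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    inflow = network.inflow
    n_steps = max(int(round(inflow.period_s / dt)), 4)
    dt = inflow.period_s / n_steps
    times = dt * np.arange(n_steps + 1)

    t_ext = np.append(inflow.time_s, inflow.time_s[0] + inflow.period_s)
    q_ext = np.append(inflow.flow_L_min, inflow.flow_L_min[0])
    q_in = np.interp(np.mod(times, inflow.period_s), t_ext, q_ext) \
        * LMIN_TO_M3S
    q_peak = float(np.abs(q_in).max())
    tol_abs = residual_rel_tol * max(q_peak, 1e-12)

    stepper = NetworkStepper(network, dt)
    n_nodes = len(network.nodes)
    # start all nodes at the mean initial outlet compliance pressure
    p = np.full(n_nodes, float(np.mean(list(stepper.pc.values()))))

    prev_means = None
    max_res = 0.0
    for cyc in range(max_cycles):
        p_hist = np.empty((n_steps + 1, n_nodes))
        flow_hist: dict = {}
        p_hist[0] = p
        flows0 = None
        for k in range(1, n_steps + 1):
            p, res, _ = stepper.newton_step(p, q_in[k], tol_abs)
            max_res = max(max_res, res)
            p_hist[k] = p
            flows = stepper.commit(p)
            if flows0 is None:
                for name in flows:
                    flow_hist[name] = np.empty(n_steps + 1)
                flows0 = flows
            for name, q in flows.items():
                flow_hist[name][k] = q
        for name in flow_hist:  # periodic closure for step 0
            flow_hist[name][0] = flow_hist[name][n_steps]
        p_hist[0] = p_hist[n_steps]

        means = np.trapezoid(p_hist, times, axis=0) / inflow.period_s
        if prev_means is not None:
            denom = np.maximum(np.abs(means), 1.0)
            if np.max(np.abs(means - prev_means) / denom) < periodicity_tol:
                pressures = {
                    node: p_hist[:-1, i] * PA_TO_MMHG
                    for node, i in network._index.items()}
                flows_lmin = {name: arr[:-1] * M3S_TO_LMIN
                              for name, arr in flow_hist.items()}
                return NetworkSolution(
                    time_s=times[:-1], period_s=inflow.period_s,
                    pressures_mmHg=pressures, flows_L_min=flows_lmin,
                    cycles_run=cyc + 1,
                    max_rel_residual=max_res / max(q_peak, 1e-12),
                    sealed_pouch=network.sealed_pouch,
                    sealed_nodes=list(network.sealed_nodes))
        prev_means = means
    raise RuntimeError(
        f"network did not reach a periodic solution in {max_cycles} cycles")


def report_metrics(solution: NetworkSolution, stations: dict) -> dict:
    """Per-station hemodynamic summary of a converged solution.

    For each station with both lumina: TL/FL percentages of cycle-mean
    flow, the RFI of each lumen waveform, the cycle-mean false-lumen
    pressure and the cross-lumen pressure difference (CLPD, P_FL - P_TL)
    waveform with its cycle peak.
    """
    from .flow_metrics import flow_distribution, rfi

    out = {}
    for name, st in stations.items():
        if st.get("fl_node") is None or st.get("fl_element") is None:
            continue
        if st["tl_node"] not in solution.pressures_mmHg:
            raise KeyError(f"station {name!r} references unknown node "
                           f"{st['tl_node']!r}")
        tl_wf = solution.element_waveform(st["tl_element"])
        fl_wf = solution.element_waveform(st["fl_element"])
        dist = flow_distribution(tl_wf, fl_wf)
        clpd = (solution.pressures_mmHg[st["fl_node"]]
                - solution.pressures_mmHg[st["tl_node"]])
        out[name] = {
            "tl_percent": dist.tl_percent,
            "fl_percent": dist.fl_percent,
            "rfi_tl": rfi(tl_wf),
            "rfi_fl": rfi(fl_wf),
            "mean_fl_pressure_mmHg": solution.node_pressure_mean(
                st["fl_node"]),
            "peak_clpd_mmHg": float(clpd.max()),
            "clpd_mmHg": clpd,
        }
    return out
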