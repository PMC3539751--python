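"""Equivalent-circuit electrotonics of a reduced three-compartment pyramidal neuron.

A cortical pyramidal neuron is modelled as three lumped compartments — apical
dendritic tree (excitatory AMPA synapses), soma/perisomatic basal tree
(inhibitory GABA synapses) and axon hillock (leaky integrate-and-fire unit) —
coupled by longitudinal cytoplasm resistances (``R_A``, ``R_B``) and
extracellular resistances (``R_C``, ``R_D``).  The dendritic dipole current
``I_D`` flowing through ``R_D`` generates the single-cell dendritic field
potential (DFP) ``V = R_D * I_D``.

This module derives every lumped coefficient of that circuit:

* the passive resistances from cell geometry and medium resistivities,
* the synaptic coupling coefficients (``alpha``, per-synapse ``R_E``) and the
  total dendritic conductances ``g_E``, ``g_I`` aligned to a phenomenological
  efficacy table,
* the membrane-equation parameters (``tau``, ``w_E``, ``w_I``) and the
  capacitance that realises a target membrane time constant,
* the DFP observation weights (``wt_E``, ``wt_I``, ``xi``).

Unit system (coherent, no hidden factors): mV, ms, GOhm, nS, pA, pF.
GOhm*nS and nS*GOhm products are dimensionless; GOhm*pF = ms; mV/GOhm = pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


OHM_PER_OHMCM_UM = 1.0e4  # 1 Ohm*cm * um / um**2 = 1e4 Ohm
GOHM = 1.0e9  # Ohm per GOhm


class AlignmentError(ValueError):
    """Raised when the efficacy table cannot be realised by the circuit."""


@dataclass(frozen=True)
class Geometry:
    """Cell geometry in micrometres.

    The dendritic trunk is a cylinder of total length ``2 * dendrite_half_length_um``
    and radius ``dendrite_radius_um``; basal and apical halves are symmetric.
    The axon hillock is a cylinder of length ``hillock_length_um`` and radius
    ``hillock_radius_um``; its membrane is a thin shell of thickness
    ``membrane_thickness_um`` through which leak current flows radially.
    """

    dendrite_half_length_um: float = 10.0
    dendrite_radius_um: float = 7.0
    hillock_length_um: float = 20.0
    hillock_radius_um: float = 0.5
    membrane_thickness_um: float = 0.01

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"Geometry.{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class Resistivities:
    """Specific resistivities in Ohm*cm of membrane, cytoplasm and extracellular fluid."""

    rho_membrane_ohm_cm: float = 5.0e7
    rho_cytoplasm_ohm_cm: float = 200.0
    rho_extracellular_ohm_cm: float = 333.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"Resistivities.{name} must be strictly positive, got {value}")


@dataclass
class CircuitParameters:
    """Lumped resistances (GOhm) and hillock capacitance (pF) of the equivalent circuit.

    ``R_A``/``R_B`` are the longitudinal cytoplasm resistances of the apical and
    basal dendritic halves, ``R_C``/``R_D`` the corresponding extracellular
    return paths, ``R_M`` the membrane leak at the axon hillock.  The resting
    potential is gauged to ``E_M = 0``.  ``C_pf`` stays ``None`` until
    :func:`solve_capacitance` fixes it.
    """

    R_A_gohm: float
    R_B_gohm: float
    R_C_gohm: float
    R_D_gohm: float
    R_M_gohm: float
    C_pf: float | None = None
    E_M_mv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R_A_gohm", "R_B_gohm", "R_C_gohm", "R_D_gohm", "R_M_gohm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CircuitParameters.{name} must be strictly positive")
        if self.C_pf is not None and not self.C_pf > 0:
            raise ValueError("CircuitParameters.C_pf must be strictly positive when set")


@dataclass(frozen=True)
class EfficacyTable:
    """Phenomenological synaptic efficacies (mV) by channel and target population.

    ``v_mv`` is the voltage unit converting efficacies to dimensionless weights
    (w = J / v); ``g_gaba_ns`` is the unitary GABA conductance fixing the
    passive coupling factor r = w_inh / g_gaba.
    """

    j_gaba_on_int_mv: float = 2.7
    j_gaba_on_pyr_mv: float = 1.7
    j_ampa_rec_on_int_mv: float = 0.7
    j_ampa_rec_on_pyr_mv: float = 0.42
    j_ampa_thal_on_int_mv: float = 0.95
    j_ampa_thal_on_pyr_mv: float = 0.55
    v_mv: float = 1.0
    g_gaba_ns: float = 1.0

    def __post_init__(self) -> None:
        if not self.v_mv > 0:
            raise ValueError("EfficacyTable.v_mv must be strictly positive")
        if not self.g_gaba_ns > 0:
            raise ValueError("EfficacyTable.g_gaba_ns must be strictly positive")


@dataclass
class DerivedCoefficients:
    """All coefficients of the membrane law and DFP observation model.

    Weights ``w_*`` enter the membrane equation
    ``tau dU/dt + U = sum w_E E_E - sum w_I E_I``;
    DFP weights ``wt_*`` and ``xi`` enter the observation equation
    ``V = sum wt_E E_E + sum wt_I E_I + xi U`` where both synapse types raise V.
    """

    r_gohm: float
    w_exc_cortical: float
    w_exc_thalamic: float
    w_inh: float
    alpha_cortical_ns: float
    alpha_thalamic_ns: float
    g_E_ns: float
    g_I_ns: float
    R_E_cortical_gohm: float
    R_E_thalamic_gohm: float
    p_eff: float
    q_eff: float
    # set by the later pipeline stages
    beta_pf: float | None = None
    gamma_ns: float | None = None
    tau_ms: float | None = None
    wt_exc_cortical: float | None = None
    wt_exc_thalamic: float | None = None
    wt_inh: float | None = None
    xi: float | None = None


def volume_resistance(rho_ohm_cm: float, length_um: float, area_um2: float) -> float:
    """Resistance (Ohm) of a volume conductor, R = rho * length / area.

    With rho in Ohm*cm, length in um and cross-section in um**2 the result is
    rho*l/A * 1e4 Ohm.
    """
    if not rho_ohm_cm > 0:
        raise ValueError(f"resistivity must be strictly positive, got {rho_ohm_cm}")
    if length_um < 0:
        raise ValueError(f"length must be non-negative, got {length_um}")
    if not area_um2 > 0:
        raise ValueError(f"cross-section area must be strictly positive, got {area_um2}")
    return rho_ohm_cm * length_um / area_um2 * OHM_PER_OHMCM_UM


def hex_packed_extracellular_area(a_um: float) -> float:
    """Extracellular cross-section (um**2) around one trunk of radius ``a_um``.

    Dendritic trunks are parallel cylinders in hexagonal dense packing; the
    interstitial space surrounding one trunk has area (12*sqrt(3) - 3*pi) * a**2.
    """
    if a_um < 0:
        raise ValueError(f"radius must be non-negative, got {a_um}")
    return (12.0 * math.sqrt(3.0) - 3.0 * math.pi) * a_um * a_um


def circuit_resistances(
    geom: Geometry,
    rho: Resistivities,
    *,
    r_m_length: str = "membrane_thickness",
) -> CircuitParameters:
    """Estimate the circuit resistances (GOhm) from geometry and resistivities.

    ``R_A = R_B``: cytoplasm over one dendritic half-length, cross-section pi*a**2.
    ``R_C = R_D``: extracellular fluid over the same length, hexagonal-packing
    interstitial cross-section.  ``R_M``: membrane resistivity across the
    hillock's lateral cylinder surface (no end caps); the conduction length is
    the membrane thickness by default (``r_m_length="membrane_thickness"``) or,
    alternatively, the hillock length (``r_m_length="hillock_length"``).
    """
    a_d = geom.dendrite_radius_um
    half = geom.dendrite_half_length_um
    r_plasma = volume_resistance(rho.rho_cytoplasm_ohm_cm, half, math.pi * a_d**2) / GOHM
    r_extra = volume_resistance(
        rho.rho_extracellular_ohm_cm, half, hex_packed_extracellular_area(a_d)
    ) / GOHM
    hillock_lateral = 2.0 * math.pi * geom.hillock_radius_um * geom.hillock_length_um
    if r_m_length == "membrane_thickness":
        ell_m = geom.membrane_thickness_um
    elif r_m_length == "hillock_length":
        ell_m = geom.hillock_length_um
    else:
        raise ValueError(f"unknown r_m_length choice: {r_m_length!r}")
    r_m = volume_resistance(rho.rho_membrane_ohm_cm, ell_m, hillock_lateral) / GOHM
    return CircuitParameters(
        R_A_gohm=r_plasma, R_B_gohm=r_plasma, R_C_gohm=r_extra, R_D_gohm=r_extra, R_M_gohm=r_m
    )


def align_from_efficacies(
    eff: EfficacyTable,
    circ: CircuitParameters,
    p_exc_cortical: float = 800.0,
    p_exc_thalamic: float = 800.0,
    q_eff: float = 200.0,
) -> DerivedCoefficients:
    """Map the efficacy table onto circuit coefficients.

    Weights are w = J/v; the passive coupling factor is r = w_inh / g_gaba
    (1.7 GOhm with defaults); per-synapse couplings alpha = w_E / r (0.25 nS
    cortical, 0.32 nS thalamic to two decimals).  The total excitatory
    conductance g_E solves the self-consistency relation
    ``g_E [1 - (R_A + R_D) * sum(alpha)] = sum(alpha)`` over the p_eff
    excitatory synapses, and the per-synapse plasma resistances follow from
    ``R_E = [1 + g_E (R_A + R_D)] / alpha``.  The inhibitory conductance is
    ``g_I = q_eff * g_gaba``.

    ``p_exc_cortical`` and ``p_exc_thalamic`` default to the expected
    in-degrees of the reference network (P*K = 0.2*4000 recurrent synapses and
    800 thalamic fibres); ``q_eff`` defaults to P*L = 200.
    """
    if p_exc_cortical < 0 or p_exc_thalamic < 0 or q_eff < 0:
        raise ValueError("effective synapse counts must be non-negative")
    w_exc_c = eff.j_ampa_rec_on_pyr_mv / eff.v_mv
    w_exc_t = eff.j_ampa_thal_on_pyr_mv / eff.v_mv
    w_inh = eff.j_gaba_on_pyr_mv / eff.v_mv
    r = w_inh / eff.g_gaba_ns  # GOhm: dimensionless / nS
    alpha_c = w_exc_c / r
    alpha_t = w_exc_t / r
    sum_alpha = p_exc_cortical * alpha_c + p_exc_thalamic * alpha_t
    ra_rd = circ.R_A_gohm + circ.R_D_gohm
    denom = 1.0 - ra_rd * sum_alpha
    if denom <= 0:
        raise AlignmentError(
            "efficacy table infeasible: 1 - (R_A + R_D) * sum(alpha) = "
            f"{denom:.4g} <= 0; reduce synapse counts or efficacies"
        )
    g_E = sum_alpha / denom
    load = 1.0 + g_E * ra_rd
    return DerivedCoefficients(
        r_gohm=r,
        w_exc_cortical=w_exc_c,
        w_exc_thalamic=w_exc_t,
        w_inh=w_inh,
        alpha_cortical_ns=alpha_c,
        alpha_thalamic_ns=alpha_t,
        g_E_ns=g_E,
        g_I_ns=q_eff * eff.g_gaba_ns,
        R_E_cortical_gohm=1.0 / (alpha_c * load) if alpha_c > 0 else math.inf,
        R_E_thalamic_gohm=1.0 / (alpha_t * load) if alpha_t > 0 else math.inf,
        p_eff=p_exc_cortical + p_exc_thalamic,
        q_eff=q_eff,
    )


def interface_coefficients(
    g_E_ns: float, circ: CircuitParameters, R_E_gohm: float | None = None
) -> tuple[float | None, float, float]:
    """Coefficients of the interface (dipole-current) equation.

    Returns ``(alpha, beta, gamma)`` with
    ``alpha = 1 / (R_E [1 + g_E (R_A + R_D)])`` (``None`` if ``R_E_gohm`` is
    not given), ``beta = C g_E (R_B + R_C) / [1 + g_E (R_A + R_D)]`` (pF) and
    ``gamma = g_E (R_M + R_B + R_C) / (R_M [1 + g_E (R_A + R_D)])`` (nS).
    Requires the capacitance to be set on ``circ``.
    """
    if g_E_ns < 0:
        raise ValueError("g_E must be non-negative")
    if circ.C_pf is None:
        raise ValueError("capacitance must be set before computing beta")
    load = 1.0 + g_E_ns * (circ.R_A_gohm + circ.R_D_gohm)
    rb_rc = circ.R_B_gohm + circ.R_C_gohm
    alpha = None
    if R_E_gohm is not None:
        alpha = 1.0 / (R_E_gohm * load)
    beta = circ.C_pf * g_E_ns * rb_rc / load
    gamma = g_E_ns * (circ.R_M_gohm + rb_rc) / (circ.R_M_gohm * load)
    return alpha, beta, gamma


def dynamics_parameters(coef: DerivedCoefficients, circ: CircuitParameters) -> tuple[float, float, float]:
    """Membrane-equation parameters ``(tau, w_E_cortical, w_I)``.

    ``tau = r {C [1 - g_I (R_B + R_C)] + beta}`` (ms);
    ``w_E = r * alpha``; ``w_I = r * g_gaba`` (= r / R_I per inhibitory synapse).
    """
    if circ.C_pf is None or coef.beta_pf is None:
        raise ValueError("capacitance and beta must be known before tau")
    rb_rc = circ.R_B_gohm + circ.R_C_gohm
    tau = coef.r_gohm * (circ.C_pf * (1.0 - coef.g_I_ns * rb_rc) + coef.beta_pf)
    if tau <= 0:
        raise AlignmentError(f"non-positive membrane time constant tau = {tau:.4g} ms")
    w_E = coef.r_gohm * coef.alpha_cortical_ns
    w_I = coef.r_gohm * (coef.g_I_ns / coef.q_eff if coef.q_eff > 0 else 0.0)
    return tau, w_E, w_I


def solve_capacitance(
    tau_target_ms: float, coef: DerivedCoefficients, circ: CircuitParameters
) -> float:
    """Capacitance (pF) realising a target membrane time constant.

    The time-constant relation is linear in C:
    ``tau = r C [D + (R_B + R_C)(g_E - g_I D)] / D`` with
    ``D = 1 + g_E (R_A + R_D)``, so
    ``C = tau D / (r [D + (R_B + R_C)(g_E - g_I D)])``.
    """
    if not tau_target_ms > 0:
        raise ValueError("tau_target_ms must be strictly positive")
    D = 1.0 + coef.g_E_ns * (circ.R_A_gohm + circ.R_D_gohm)
    rb_rc = circ.R_B_gohm + circ.R_C_gohm
    bracket = D + rb_rc * (coef.g_E_ns - coef.g_I_ns * D)
    c = tau_target_ms * D / (coef.r_gohm * bracket)
    if not c > 0:
        raise AlignmentError(
            f"alignment infeasible: capacitance solving tau = {tau_target_ms} ms is {c:.4g} pF"
        )
    return c


def tau_forward(coef: DerivedCoefficients, circ: CircuitParameters) -> float:
    """Forward evaluation of the time constant from C, g_E, g_I and the resistances."""
    if circ.C_pf is None:
        raise ValueError("capacitance must be set")
    D = 1.0 + coef.g_E_ns * (circ.R_A_gohm + circ.R_D_gohm)
    rb_rc = circ.R_B_gohm + circ.R_C_gohm
    return coef.r_gohm * circ.C_pf * (D + rb_rc * (coef.g_E_ns - coef.g_I_ns * D)) / D


def dfp_weights(coef: DerivedCoefficients, circ: CircuitParameters) -> tuple[float, float, float]:
    """DFP observation weights ``(wt_E_cortical, wt_I, xi)``.

    ``wt_E = R_D w_E (1/r - beta/tau)``; ``wt_I = R_D w_I beta/tau``;
    ``xi = R_D (beta/tau - gamma)``.  All dimensionless (GOhm*nS products).
    """
    if coef.beta_pf is None or coef.tau_ms is None or coef.gamma_ns is None:
        raise ValueError("beta, gamma and tau must be known before the DFP weights")
    bt = coef.beta_pf / coef.tau_ms  # pF/ms = nS
    w_E = coef.r_gohm * coef.alpha_cortical_ns
    w_I = coef.w_inh
    wt_E = circ.R_D_gohm * w_E * (1.0 / coef.r_gohm - bt)
    wt_I = circ.R_D_gohm * w_I * bt
    xi = circ.R_D_gohm * (bt - coef.gamma_ns)
    return wt_E, wt_I, xi


def r_circuit_diagnostic(coef: DerivedCoefficients, circ: CircuitParameters) -> tuple[float, float]:
    """Circuit-formula value of r and its relative discrepancy from the aligned value.

    The circuit derivation gives ``r = R_M / (1 - g_I (R_B + R_C + R_M) + R_M gamma)``,
    which with realistic geometry disagrees with the efficacy-aligned
    r = w_I / g_gaba by orders of magnitude.  The aligned value is used for
    dynamics and observation; this diagnostic surfaces the inconsistency.
    """
    if coef.gamma_ns is None:
        raise ValueError("gamma must be known for the diagnostic")
    rb_rc = circ.R_B_gohm + circ.R_C_gohm
    denom = 1.0 - coef.g_I_ns * (rb_rc + circ.R_M_gohm) + circ.R_M_gohm * coef.gamma_ns
    r_circuit = circ.R_M_gohm / denom
    rel = abs(r_circuit - coef.r_gohm) / coef.r_gohm
    return r_circuit, rel


def derive_parameters(
    geom: Geometry | None = None,
    rho: Resistivities | None = None,
    eff: EfficacyTable | None = None,
    *,
    tau_target_ms: float = 20.0,
    p_exc_cortical: float = 800.0,
    p_exc_thalamic: float = 800.0,
    q_eff: float = 200.0,
    r_m_length: str = "membrane_thickness",
) -> tuple[CircuitParameters, DerivedCoefficients]:
    """Run the full derivation pipeline with consistent ordering.

    geometry -> resistances -> efficacy alignment (r, alpha, g_E, g_I, R_E)
    -> capacitance solving tau = tau_target -> beta, gamma -> tau (forward,
    equals the target by construction) -> DFP weights.
    """
    geom = geom or Geometry()
    rho = rho or Resistivities()
    eff = eff or EfficacyTable()
    circ = circuit_resistances(geom, rho, r_m_length=r_m_length)
    coef = align_from_efficacies(
        eff, circ, p_exc_cortical=p_exc_cortical, p_exc_thalamic=p_exc_thalamic, q_eff=q_eff
    )
    circ.C_pf = solve_capacitance(tau_target_ms, coef, circ)
    _, beta, gamma = interface_coefficients(coef.g_E_ns, circ)
    coef.beta_pf = beta
    coef.gamma_ns = gamma
    coef.tau_ms, _, _ = dynamics_parameters(coef, circ)
    wt_E, wt_I, xi = dfp_weights(coef, circ)
    coef.wt_exc_cortical = wt_E
    coef.wt_exc_thalamic = circ.R_D_gohm * coef.r_gohm * coef.alpha_thalamic_ns * (
        1.0 / coef.r_gohm - coef.beta_pf / coef.tau_ms
    )
    coef.wt_inh = wt_I
    coef.xi = xi
    return circ, coef


def coefficients_report(circ: CircuitParameters, coef: DerivedCoefficients) -> dict:
    """Flat JSON-ready report of all derived quantities with units in key names."""
    r_circuit, rel = r_circuit_diagnostic(coef, circ)
    out = {
        "R_A_GOhm": circ.R_A_gohm,
        "R_B_GOhm": circ.R_B_gohm,
        "R_C_GOhm": circ.R_C_gohm,
        "R_D_GOhm": circ.R_D_gohm,
        "R_M_GOhm": circ.R_M_gohm,
        "C_pF": circ.C_pf,
        "E_M_mV": circ.E_M_mv,
        "r_GOhm": coef.r_gohm,
        "r_circuit_GOhm": r_circuit,
        "r_relative_discrepancy": rel,
        "alpha_cortical_nS": coef.alpha_cortical_ns,
        "alpha_thalamic_nS": coef.alpha_thalamic_ns,
        "w_exc_cortical": coef.w_exc_cortical,
        "w_exc_thalamic": coef.w_exc_thalamic,
        "w_inh": coef.w_inh,
        "g_E_nS": coef.g_E_ns,
        "g_I_nS": coef.g_I_ns,
        "R_E_cortical_GOhm": coef.R_E_cortical_gohm,
        "R_E_thalamic_GOhm": coef.R_E_thalamic_gohm,
        "p_eff": coef.p_eff,
        "q_eff": coef.q_eff,
        "beta_pF": coef.beta_pf,
        "gamma_nS": coef.gamma_ns,
        "tau_ms": coef.tau_ms,
        "wt_exc_cortical": coef.wt_exc_cortical,
        "wt_exc_thalamic": coef.wt_exc_thalamic,
        "wt_inh": coef.wt_inh,
        "xi": coef.xi,
    }
    return out
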