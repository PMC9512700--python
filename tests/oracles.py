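"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's propagator code paths: the CPMG
closed form is transcribed from the literature expression, and the
brute-force simulators advance the Bloch-McConnell equations in fixed micro
steps with scipy's generic matrix exponential.
"""

import numpy as np
from scipy.linalg import expm


def effective_nu(T_cpmg, nu):
    """Realized CPMG frequency N / (2 T) for the integer pulse count N."""
    nu = np.asarray(nu, dtype=float)
    return np.round(2.0 * T_cpmg * nu) / (2.0 * T_cpmg)


def carver_richards_r2eff(p_GS, k_ex, dw, R2_0, nu_cpmg):
    """Closed-form two-site SQ CPMG R2,eff for equal intrinsic rates.

    Standard Carver-Richards/Davis expression with tau_cp = 1/(2 nu):
    R2eff = R2_0 + kex/2 - nu * arccosh(D+ cosh(eta+) - D- cos(eta-)).
    """
    p_ES = 1.0 - p_GS
    nu = np.asarray(nu_cpmg, dtype=float)
    psi = k_ex**2 - dw**2
    zeta = -2.0 * dw * k_ex * (p_GS - p_ES)
    root = np.sqrt(psi**2 + zeta**2)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root)
    tau_cp = 1.0 / (2.0 * nu)
    eta_plus = tau_cp / np.sqrt(2.0) * np.sqrt(psi + root)
    eta_minus = tau_cp / np.sqrt(2.0) * np.sqrt(-psi + root)
    return R2_0 + k_ex / 2.0 - nu * np.arccosh(
        d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
    )


def _sq_matrix(p_GS, k_ex, dw, R2_0):
    k_ge = (1.0 - p_GS) * k_ex
    k_eg = p_GS * k_ex
    return np.array(
        [[-R2_0 - k_ge, k_eg], [k_ge, -R2_0 - k_eg + 1j * dw]], dtype=complex
    )


def brute_force_sq_r2eff(p_GS, k_ex, dw, R2_0, T_cpmg, nu, dt=1e-6):
    """SQ CPMG by small-time-step propagation (pulses = conjugation)."""
    n_pulse = int(round(2.0 * T_cpmg * nu))
    tau = T_cpmg / n_pulse
    n_sub = max(int(np.ceil((tau / 2.0) / dt)), 1)
    step = expm(_sq_matrix(p_GS, k_ex, dw, R2_0) * (tau / 2.0 / n_sub))
    m = np.array([p_GS, 1.0 - p_GS], dtype=complex)
    for _ in range(n_pulse):
        for _ in range(n_sub):
            m = step @ m
        m = np.conj(m)
        for _ in range(n_sub):
            m = step @ m
    return -np.log(abs(m.sum())) / T_cpmg


def brute_force_mq_r2eff(p_GS, k_ex, dw_H, dw_C, R2_0, T_cpmg, nu, dt=1e-6):
    """MQ CPMG by small-time-step ZQ/DQ propagation.

    Carbon pulses swap the ZQ and DQ amplitude vectors; a single proton pulse
    at T/2 swaps them with complex conjugation; detection is the mean
    magnitude of the two summed coherence signals.
    """
    n_pulse = int(round(2.0 * T_cpmg * nu))
    assert n_pulse % 2 == 0, "proton pulse must fall between carbon blocks"
    tau = T_cpmg / n_pulse
    n_sub = max(int(np.ceil((tau / 2.0) / dt)), 1)
    step_dq = expm(_sq_matrix(p_GS, k_ex, dw_H + dw_C, R2_0) * (tau / 2.0 / n_sub))
    step_zq = expm(_sq_matrix(p_GS, k_ex, dw_H - dw_C, R2_0) * (tau / 2.0 / n_sub))
    m0 = np.array([p_GS, 1.0 - p_GS], dtype=complex)
    a_dq, a_zq = m0.copy(), m0.copy()

    def half_block(a_dq, a_zq):
        for _ in range(n_sub):
            a_dq, a_zq = step_dq @ a_dq, step_zq @ a_zq
        return a_dq, a_zq

    def carbon_block(a_dq, a_zq):
        a_dq, a_zq = half_block(a_dq, a_zq)
        a_dq, a_zq = a_zq, a_dq  # carbon pi: ZQ <-> DQ
        return half_block(a_dq, a_zq)

    for _ in range(n_pulse // 2):
        a_dq, a_zq = carbon_block(a_dq, a_zq)
    a_dq, a_zq = np.conj(a_zq), np.conj(a_dq)  # proton pi at T/2
    for _ in range(n_pulse // 2):
        a_dq, a_zq = carbon_block(a_dq, a_zq)
    signal = 0.5 * (abs(a_dq.sum()) + abs(a_zq.sum()))
    return -np.log(signal) / T_cpmg
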