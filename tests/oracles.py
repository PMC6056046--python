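"""Independent brute-force / iterative oracles used to validate closed forms.

Everything here deliberately avoids the package's analytic expressions:
steady states are reached by iterating the underlying magnetization
recursions, rank correlation is counted pair by pair, and optima are found
by dense grid search.
"""

from __future__ import annotations

import math


def gre_steady_state(tr_ms: float, fa_deg: float, t1_ms: float,
                     tol: float = 1e-14, max_iter: int = 100000) -> float:
    """Longitudinal steady state of an ideally spoiled GRE by fixed-point iteration.

    Recursion: M+ = cosθ·M after the pulse, then M(TR) = 1 + (M+ − 1)·E1.
    """
    cos_t = math.cos(math.radians(fa_deg))
    e1 = math.exp(-tr_ms / t1_ms)
    m = 1.0
    for _ in range(max_iter):
        m_next = 1.0 + (cos_t * m - 1.0) * e1
        if abs(m_next - m) < tol:
            return m_next
        m = m_next
    raise RuntimeError("GRE fixed-point iteration did not converge")


def mprage_cycle_signal(p, t, tol: float = 1e-12, max_cycles: int = 100000) -> float:
    """MP-RAGE signal by explicit cycle simulation to steady state.

    One cycle: inversion, TI recovery, then N readouts each applying cosθ
    saturation followed by an echo-spacing recovery, then a TD recovery.
    The magnetization just before the reported readout pulse is recorded and
    iterated until it stabilizes; the observed signal applies
    sinθ·exp(−TE/T2*).
    """
    theta = math.radians(p.fa_deg)
    cos_t = math.cos(theta)
    delta = math.exp(-p.esp_ms / t.t1_ms)
    gamma = math.exp(-p.ti_ms / t.t1_ms)
    phi = math.exp(-p.td_ms / t.t1_ms)
    m = 1.0
    m_report_prev = None
    for _ in range(max_cycles):
        m = -m
        m = 1.0 + (m - 1.0) * gamma
        m_report = None
        for k in range(1, p.n_readouts + 1):
            if k == p.readout_index:
                m_report = m
            m = cos_t * m
            m = 1.0 + (m - 1.0) * delta
        m = 1.0 + (m - 1.0) * phi
        if m_report_prev is not None and abs(m_report - m_report_prev) < tol:
            return m_report * math.sin(theta) * math.exp(-p.te_ms / t.t2star_ms)
        m_report_prev = m_report
    raise RuntimeError("MP-RAGE cycle simulation did not converge")


def fse_steady_state_bloch(tr_ms: float, esp_ms: float, etl: int, t1_ms: float,
                           tol: float = 1e-14, max_cycles: int = 100000) -> float:
    """FSE longitudinal magnetization at excitation by step-by-step recovery.

    Exact ideal-pulse simulation: the 90° sets Mz to 0; each 180° refocusing
    pulse (at ESP/2, 3ESP/2, …) inverts the recovering Mz; free recovery
    fills the remaining TR.  Agrees with the first-order closed form
    1 − exp(−(TR − ETL·ESP)/T1) to O(ESP/T1).
    """

    def recover(m: float, dt_ms: float) -> float:
        return 1.0 + (m - 1.0) * math.exp(-dt_ms / t1_ms)

    m = 1.0
    prev = None
    for _ in range(max_cycles):
        m = 0.0  # ideal 90° excitation
        m = recover(m, esp_ms / 2.0)
        for _ in range(etl - 1):
            m = -m  # refocusing pulse
            m = recover(m, esp_ms)
        m = -m
        m = recover(m, esp_ms / 2.0)  # to the end of the train
        m = recover(m, tr_ms - etl * esp_ms)
        if prev is not None and abs(m - prev) < tol:
            return m
        prev = m
    raise RuntimeError("FSE Bloch iteration did not converge")


def kendall_tau_brute(x, y) -> float:
    """Tau-a by explicit enumeration of all pairs; ties contribute zero."""
    n = len(x)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[j] > x[i]) - int(x[j] < x[i])
            dy = int(y[j] > y[i]) - int(y[j] < y[i])
            total += dx * dy
    return total / (n * (n - 1) / 2)
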