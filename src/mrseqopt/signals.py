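"""Closed-form steady-state signals for FSE, FLAIR, spoiled GRE and MP-RAGE.

All signals are expressed in units of the equilibrium magnetization M0 and
are SIGNED by default (inversion-recovery sequences can cross zero); take
``abs`` — or use the renderer's magnitude mode — where magnitude images are
wanted.  The model assumes ideal instantaneous RF pulses with exact flip
angles, complete spoiling/decay of transverse magnetization before each TR,
no stimulated echoes, and a Cartesian readout.

Conventions
-----------
* FSE / FLAIR: the longitudinal term recovers over the interval
  ``TD = TR − ETL·ESP`` between the end of the echo train and the next
  excitation; transverse decay enters through ``exp(−TE_eff/T2)``.
* GRE: spoiled steady state ``(1−E1)/(1−cosθ·E1)`` with ``E1 = exp(−TR/T1)``
  and ``exp(−TE/T2*)`` decay.
* MP-RAGE: inversion, then N low-angle readouts each followed by an
  echo-spacing recovery, then a delay TD, cyclically; the closed-form steady
  state is derived from that recursion (the timing constraint
  ``TR = TI + N·ESP + TD`` is enforced).  The reported readout defaults to
  the center of the train, which fills the k-space center under linear
  phase encoding.

All times are in milliseconds, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TimingError",
    "FSEParams",
    "FLAIRParams",
    "GREParams",
    "MPRAGEParams",
    "MprageTerms",
    "SignalResult",
    "fse_signal",
    "flair_signal",
    "flair_null_ti",
    "gre_signal",
    "ernst_angle",
    "mprage_terms",
    "mprage_signal",
    "sequence_signal",
]


class TimingError(ValueError):
    """A sequence's timing parameters are mutually inconsistent."""


@dataclass(frozen=True)
class SignalResult:
    """Longitudinal term ``M/M0`` and observed signal ``S/M0`` (both signed)."""

    m_over_m0: float
    s_over_m0: float


@dataclass(frozen=True)
class FSEParams:
    """Fast-spin-echo timing: 90° excitation, ETL refocused echoes ESP apart."""

    tr_ms: float
    esp_ms: float
    etl: int
    te_eff_ms: float

    def __post_init__(self) -> None:
        if self.etl < 1 or int(self.etl) != self.etl:
            raise ValueError(f"etl must be an integer >= 1, got {self.etl!r}")
        if self.esp_ms <= 0:
            raise ValueError("esp_ms must be positive")
        if self.te_eff_ms < 0:
            raise ValueError("te_eff_ms must be >= 0")
        if not self.tr_ms > self.etl * self.esp_ms:
            raise TimingError(
                f"tr_ms ({self.tr_ms}) must exceed etl*esp_ms "
                f"({self.etl * self.esp_ms})"
            )

    @property
    def td_ms(self) -> float:
        """Recovery interval between the end of the echo train and the next TR."""
        return self.tr_ms - self.etl * self.esp_ms


@dataclass(frozen=True)
class FLAIRParams(FSEParams):
    """FSE readout preceded by a 180° inversion: adds the inversion time TI."""

    ti_ms: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.ti_ms <= 0:
            raise ValueError("ti_ms must be positive")
        if not self.ti_ms + self.etl * self.esp_ms < self.tr_ms:
            raise TimingError(
                f"ti_ms + etl*esp_ms ({self.ti_ms + self.etl * self.esp_ms}) "
                f"must be < tr_ms ({self.tr_ms})"
            )


@dataclass(frozen=True)
class GREParams:
    """Spoiled gradient echo: flip angle θ, echo time TE, repetition time TR."""

    tr_ms: float
    te_ms: float
    fa_deg: float

    def __post_init__(self) -> None:
        if not self.tr_ms > self.te_ms > 0:
            raise TimingError(
                f"need tr_ms > te_ms > 0, got tr_ms={self.tr_ms}, te_ms={self.te_ms}"
            )
        if not 0.0 <= self.fa_deg <= 180.0:
            raise ValueError(f"fa_deg must lie in [0, 180], got {self.fa_deg}")


@dataclass(frozen=True)
class MPRAGEParams:
    """Magnetization-prepared rapid gradient echo timing.

    One cycle is: 180° inversion — recovery TI — N readout pulses of angle θ,
    each followed by an echo-spacing recovery — delay TD — next inversion.
    ``esp_ms`` defaults to ``(TR − TI − TD)/N``; when given explicitly the
    timing identity ``TR = TI + N·ESP + TD`` must hold to 1e−6 ms.  The echo
    time ``te_ms`` enters only the T2* decay factor and is allowed to exceed
    ESP (vendor protocols quote it independently).
    """

    tr_ms: float
    ti_ms: float
    n_readouts: int
    fa_deg: float
    te_ms: float
    td_ms: float = 0.0
    esp_ms: float | None = None
    readout_index: int | None = None  # defaults to the center readout ceil(N/2)

    def __post_init__(self) -> None:
        if self.n_readouts < 1 or int(self.n_readouts) != self.n_readouts:
            raise ValueError(f"n_readouts must be an integer >= 1, got {self.n_readouts!r}")
        if not 0.0 <= self.fa_deg <= 180.0:
            raise ValueError(f"fa_deg must lie in [0, 180], got {self.fa_deg}")
        if self.ti_ms <= 0 or self.te_ms <= 0 or self.td_ms < 0:
            raise ValueError("ti_ms and te_ms must be positive, td_ms >= 0")
        if self.esp_ms is None:
            esp = (self.tr_ms - self.ti_ms - self.td_ms) / self.n_readouts
            if esp <= 0:
                raise TimingError(
                    f"tr_ms ({self.tr_ms}) leaves no room for {self.n_readouts} "
                    f"readouts after ti_ms={self.ti_ms} and td_ms={self.td_ms}"
                )
            object.__setattr__(self, "esp_ms", esp)
        else:
            residual = self.tr_ms - (self.ti_ms + self.n_readouts * self.esp_ms + self.td_ms)
            if abs(residual) > 1e-6:
                raise TimingError(
                    "TR must equal TI + N*ESP + TD; residual = "
                    f"{residual:.6g} ms"
                )
        index = self.readout_index
        if index is None:
            object.__setattr__(self, "readout_index", math.ceil(self.n_readouts / 2))
        elif not 1 <= index <= self.n_readouts:
            raise ValueError(
                f"readout_index must lie in [1, {self.n_readouts}], got {index}"
            )


@dataclass(frozen=True)
class MprageTerms:
    """Dimensionless recursion factors of the MP-RAGE steady state."""

    delta: float      # exp(−ESP/T1): recovery over one echo spacing
    mu: float         # δ·cosθ: per-readout longitudinal propagator
    gamma: float      # exp(−TI/T1)
    phi: float        # exp(−TD/T1)
    rho: float        # exp(−TR/T1)
    meq_over_m0: float


def fse_signal(p: FSEParams, t) -> SignalResult:
    """FSE steady-state signal (first-order approximation, ESP << T1).

    ``M/M0 = 1 − exp(−(TR − ETL·ESP)/T1)``; the observed signal applies
    ``exp(−TE_eff/T2)`` transverse decay at the contrast-determining echo.
    """
    m = 1.0 - math.exp(-p.td_ms / t.t1_ms)
    s = m * math.exp(-p.te_eff_ms / t.t2_ms)
    return SignalResult(m, s)


def flair_signal(p: FLAIRParams, t) -> SignalResult:
    """FLAIR signal: inversion recovery over TI on top of the FSE cycle.

    ``M/M0 = 1 − 2·exp(−TI/T1) + exp(−(TR − ETL·ESP)/T1)``, signed; tissues
    with ``TI`` below their null point give negative M.
    """
    m = 1.0 - 2.0 * math.exp(-p.ti_ms / t.t1_ms) + math.exp(-p.td_ms / t.t1_ms)
    s = m * math.exp(-p.te_eff_ms / t.t2_ms)
    return SignalResult(m, s)


def flair_null_ti(t, tr_ms: float, etl: int, esp_ms: float) -> float:
    """Inversion time nulling a tissue's FLAIR signal.

    Closed-form root of the FLAIR longitudinal term:
    ``TI_null = T1·ln(2 / (1 + exp(−(TR − ETL·ESP)/T1)))``.
    """
    if not tr_ms > etl * esp_ms:
        raise TimingError(f"tr_ms ({tr_ms}) must exceed etl*esp_ms ({etl * esp_ms})")
    td = tr_ms - etl * esp_ms
    return t.t1_ms * math.log(2.0 / (1.0 + math.exp(-td / t.t1_ms)))


def gre_signal(p: GREParams, t) -> SignalResult:
    """Spoiled-GRE steady state: ``M/M0 = (1−E1)/(1−cosθ·E1)``, ``E1 = exp(−TR/T1)``.

    The observed signal is ``M·sinθ·exp(−TE/T2*)``.
    """
    theta = math.radians(p.fa_deg)
    e1 = math.exp(-p.tr_ms / t.t1_ms)
    m = (1.0 - e1) / (1.0 - math.cos(theta) * e1)
    s = m * math.sin(theta) * math.exp(-p.te_ms / t.t2star_ms)
    return SignalResult(m, s)


def ernst_angle(tr_ms: float, t1_ms: float) -> float:
    """Flip angle (degrees) maximizing the spoiled-GRE signal: arccos(exp(−TR/T1))."""
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("tr_ms and t1_ms must be positive")
    return math.degrees(math.acos(math.exp(-tr_ms / t1_ms)))


def _geom_sum(mu: float, k: int) -> float:
    """(1 − μ^k)/(1 − μ) with the μ→1 limit handled."""
    if abs(1.0 - mu) < 1e-12:
        return float(k)
    return (1.0 - mu**k) / (1.0 - mu)


def mprage_terms(p: MPRAGEParams, t) -> MprageTerms:
    """Recursion factors and cyclic steady state of the MP-RAGE train.

    Propagating M through one steady-state cycle (inversion, TI recovery,
    N × [cosθ saturation + ESP recovery], TD recovery) and solving the fixed
    point gives

        Meq/M0 = [1 − φ + φ(1−δ)(1−μ^N)/(1−μ) + φμ^N(1−γ)] / (1 + γφμ^N),

    where the denominator equals ``1 + ρ·cos^N θ`` under TR = TI + N·ESP + TD.
    ``Meq`` is the longitudinal magnetization just before each inversion.
    """
    theta = math.radians(p.fa_deg)
    cos_t = math.cos(theta)
    n = p.n_readouts
    delta = math.exp(-p.esp_ms / t.t1_ms)
    mu = delta * cos_t
    gamma = math.exp(-p.ti_ms / t.t1_ms)
    phi = math.exp(-p.td_ms / t.t1_ms)
    rho = math.exp(-p.tr_ms / t.t1_ms)
    mu_n = mu**n
    num = 1.0 - phi + phi * (1.0 - delta) * _geom_sum(mu, n) + phi * mu_n * (1.0 - gamma)
    den = 1.0 + gamma * phi * mu_n
    return MprageTerms(delta, mu, gamma, phi, rho, num / den)


def mprage_signal(p: MPRAGEParams, t) -> SignalResult:
    """MP-RAGE signal at the reported readout of the steady-state train.

    The longitudinal magnetization just before the n-th readout pulse is

        M_n/M0 = (1−δ)(1−μ^{n−1})/(1−μ) + μ^{n−1}·[(1−γ) − γ·Meq/M0],

    and the observed signal applies ``sinθ·exp(−TE/T2*)``.
    """
    terms = mprage_terms(p, t)
    theta = math.radians(p.fa_deg)
    n = p.readout_index
    mu_pow = terms.mu ** (n - 1)
    m = (1.0 - terms.delta) * _geom_sum(terms.mu, n - 1) + mu_pow * (
        (1.0 - terms.gamma) - terms.gamma * terms.meq_over_m0
    )
    s = m * math.sin(theta) * math.exp(-p.te_ms / t.t2star_ms)
    return SignalResult(m, s)


def sequence_signal(p, t) -> SignalResult:
    """Dispatch on the parameter record's type (FLAIR before its FSE base)."""
    if isinstance(p, FLAIRParams):
        return flair_signal(p, t)
    if isinstance(p, FSEParams):
        return fse_signal(p, t)
    if isinstance(p, GREParams):
        return gre_signal(p, t)
    if isinstance(p, MPRAGEParams):
        return mprage_signal(p, t)
    raise TypeError(f"unsupported sequence parameter type: {type(p).__name__}")
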