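"""Geometry-aware SNR/CNR, scan-time and averaging model.

The simulated SNR follows the voxel-volume/readout-duty heuristic

    SNR ∝ FOVx · FOVy · Δz · F_sequence · (NSA / (BW · N_FE · N_PE))^p

with ``F_sequence`` the relative signal from :mod:`mrseqopt.signals` and the
exponent ``p`` configurable (default 1; the square-root reading 0.5 is also
supported).  Only ratios of bandwidth values ever matter, so BW units are
treated as opaque.  CNR between two regions is the signed difference of
their SNRs.  The scan-time model is the Cartesian shots-per-average count:
``TR · ceil(N_PE/ETL) · NSA`` for 2D multi-slice sequences and
``TR · Nz · NSA`` for the 3D MP-RAGE, computed in exact rational arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .signals import FSEParams, GREParams, MPRAGEParams

__all__ = [
    "AcquisitionGeometry",
    "SnrConfig",
    "EspBwTable",
    "InfeasibleBudgetError",
    "effective_te",
    "snr",
    "cnr",
    "scan_time_s",
    "max_nsa_under_budget",
    "bw_for_esp",
    "format_min_sec",
    "GEOMETRY_2D",
    "GEOMETRY_3D",
]


class InfeasibleBudgetError(ValueError):
    """Even a single average exceeds the scan-time budget."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Field of view, matrix and bandwidth of an acquisition.

    ``dz_mm`` is the slice thickness (2D) or FOVz/Nz (3D);
    ``n_slices_or_nz`` is the slice count (2D) or the second phase-encode
    count (3D).  ``bw`` is the receiver bandwidth in the scanner's units,
    used only through ratios.
    """

    fov_x_mm: float
    fov_y_mm: float
    dz_mm: float
    n_fe: int
    n_pe: int
    n_slices_or_nz: int
    mode: str = "2D"
    bw: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("2D", "3D"):
            raise ValueError(f"mode must be '2D' or '3D', got {self.mode!r}")
        for name in ("fov_x_mm", "fov_y_mm", "dz_mm", "n_fe", "n_pe",
                     "n_slices_or_nz", "bw"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


# The study's fixed geometries: 192x192x29 over a 20x20 mm^2 FOV with 0.5 mm
# slices in 2D, and an isotropic 20 mm / 128^3 volume for the 3D MP-RAGE.
GEOMETRY_2D = AcquisitionGeometry(20.0, 20.0, 0.5, 192, 192, 29, "2D", bw=50.0)
GEOMETRY_3D = AcquisitionGeometry(20.0, 20.0, 20.0 / 128, 128, 128, 128, "3D", bw=75.0)


@dataclass(frozen=True)
class SnrConfig:
    """Exponent applied to the sampling factor NSA/(BW·N_FE·N_PE)."""

    exponent_p: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.exponent_p <= 1.0:
            raise ValueError(f"exponent_p must lie in (0, 1], got {self.exponent_p}")


@dataclass(frozen=True)
class EspBwTable:
    """Explicit echo-spacing → bandwidth coupling (longer ESP, narrower BW)."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        esp = [e for e, _ in self.pairs]
        bw = [b for _, b in self.pairs]
        if any(b <= a for a, b in zip(esp, esp[1:])) or any(
            b >= a for a, b in zip(bw, bw[1:])
        ):
            raise ValueError(
                "esp values must be strictly increasing and bw strictly decreasing"
            )


def bw_for_esp(table: EspBwTable, esp_ms: float) -> float:
    """Exact (no interpolation) bandwidth lookup for an echo spacing."""
    for e, b in table.pairs:
        if math.isclose(e, esp_ms, rel_tol=0.0, abs_tol=1e-9):
            return b
    raise KeyError(f"esp {esp_ms} ms not in table; available pairs: {table.pairs}")


def effective_te(esp_ms: float, etl: int) -> float:
    """Effective echo time of a linearly ordered echo train.

    The center echo, index ``ceil((ETL+1)/2)``, fills the k-space center and
    sets the contrast: ``TE_eff = ESP · ceil((ETL+1)/2)``.
    """
    if esp_ms <= 0:
        raise ValueError("esp_ms must be positive")
    if etl < 1 or int(etl) != etl:
        raise ValueError(f"etl must be an integer >= 1, got {etl!r}")
    return esp_ms * math.ceil((etl + 1) / 2)


def snr(s_over_m0: float, geom: AcquisitionGeometry, nsa: int,
        cfg: SnrConfig = SnrConfig(), bw: float | None = None) -> float:
    """Signed SNR in arbitrary consistent units; zero signal gives zero.

    ``bw`` overrides the geometry's bandwidth (used by ESP↔BW-coupled sweeps).
    """
    if nsa < 1 or int(nsa) != nsa:
        raise ValueError(f"nsa must be an integer >= 1, got {nsa!r}")
    bw_val = geom.bw if bw is None else bw
    factor = (nsa / (bw_val * geom.n_fe * geom.n_pe)) ** cfg.exponent_p
    return geom.fov_x_mm * geom.fov_y_mm * geom.dz_mm * s_over_m0 * factor


def cnr(snr1: float, snr2: float) -> float:
    """Signed contrast-to-noise ratio between two regions: SNR1 − SNR2."""
    return snr1 - snr2


def _shots_per_average(seq, geom: AcquisitionGeometry) -> int:
    if isinstance(seq, MPRAGEParams) or (
        getattr(seq, "mode", None) == "3D"
    ):
        return geom.n_slices_or_nz
    if isinstance(seq, FSEParams):  # covers FLAIR via inheritance
        return math.ceil(geom.n_pe / seq.etl)
    if isinstance(seq, GREParams):
        return geom.n_pe
    raise TypeError(f"unsupported sequence parameter type: {type(seq).__name__}")


def scan_time_s(seq, geom: AcquisitionGeometry, nsa: int) -> float:
    """Total acquisition time in seconds (exact rational arithmetic).

    2D multi-slice: ``TR · ceil(N_PE/ETL) · NSA`` (ETL = 1 for GRE);
    3D MP-RAGE: ``TR · Nz · NSA`` (one inversion-readout cycle per second
    phase encode).
    """
    if nsa < 1 or int(nsa) != nsa:
        raise ValueError(f"nsa must be an integer >= 1, got {nsa!r}")
    tr_s = Fraction(str(float(seq.tr_ms))) / 1000
    return float(tr_s * _shots_per_average(seq, geom) * nsa)


def max_nsa_under_budget(seq, geom: AcquisitionGeometry, budget_s: float) -> int:
    """Largest integer NSA whose scan time stays within the budget."""
    if budget_s <= 0:
        raise ValueError("budget_s must be positive")
    per_average = Fraction(str(float(seq.tr_ms))) / 1000 * _shots_per_average(seq, geom)
    # tolerate float rounding when the budget is itself a computed scan time
    ratio = Fraction(str(float(budget_s))) / per_average
    nsa = int(ratio * (1 + Fraction(1, 10**12)))
    if nsa < 1:
        raise InfeasibleBudgetError(
            f"a single average takes {float(per_average):.1f} s, over the "
            f"{budget_s} s budget"
        )
    return nsa


def format_min_sec(seconds: float) -> str:
    """Display ``mm : ss`` rounded to the nearest second."""
    total = round(seconds)
    return f"{total // 60} : {total % 60:02d}"
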