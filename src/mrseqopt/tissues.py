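"""Tissue relaxation constants for the glioblastoma mouse model at 7 T.

The built-in catalog holds cohort-mean T1/T2/T2* values (ms) for brain
parenchyma, CSF and tumor under pre- and post-contrast (Gd-DTPA) conditions,
together with the between-mouse standard deviations, as measured by
variable-TR/multi-echo relaxometry on 8 tumor-bearing mice.  White and gray
matter converge in relaxation at high field, so the contralateral hemisphere
is represented by a single "brain_parenchyma" tissue.

A seeded cohort sampler draws synthetic animals from independent
truncated-normal marginals (only marginal SDs are available; no covariance).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "TissueRelaxation",
    "TissueCohortSpec",
    "TISSUES",
    "CONDITIONS",
    "get_tissue",
    "catalog",
    "sample_cohort",
    "write_catalog_csv",
    "read_catalog_csv",
]

TISSUES = ("brain_parenchyma", "csf", "tumor")
CONDITIONS = ("pre", "post")


@dataclass(frozen=True)
class TissueRelaxation:
    """Relaxation times of one tissue under one contrast condition.

    All times in milliseconds.  For physically meaningful tissues
    ``t2star_ms <= t2_ms <= t1_ms``; only strict positivity is enforced so
    that user-defined or perturbed entries remain representable.
    """

    name: str
    condition: str
    t1_ms: float
    t2_ms: float
    t2star_ms: float

    def __post_init__(self) -> None:
        for field in ("t1_ms", "t2_ms", "t2star_ms"):
            value = getattr(self, field)
            if not value > 0:
                raise ValueError(f"{field} must be strictly positive, got {value!r}")

    def scaled(self, factor: float) -> "TissueRelaxation":
        """Return a copy with all three relaxation times multiplied by ``factor``."""
        return replace(
            self,
            t1_ms=self.t1_ms * factor,
            t2_ms=self.t2_ms * factor,
            t2star_ms=self.t2star_ms * factor,
        )


@dataclass(frozen=True)
class TissueCohortSpec:
    """Specification for drawing a synthetic cohort around a mean tissue.

    Draws are independent normals per field, truncated at zero (redraw on
    non-positive values), with a fixed integer seed for reproducibility.
    """

    mean: TissueRelaxation
    sd_t1_ms: float = 0.0
    sd_t2_ms: float = 0.0
    sd_t2star_ms: float = 0.0
    n: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_t1_ms, self.sd_t2_ms, self.sd_t2star_ms) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (isinstance(self.n, int) and self.n >= 1):
            raise ValueError(f"cohort size n must be an integer >= 1, got {self.n!r}")


# Cohort means (and between-mouse SDs) at 7 T: (t1, t2, t2star) in ms.
_CATALOG: dict[tuple[str, str], TissueRelaxation] = {}
_CATALOG_SD: dict[tuple[str, str], tuple[float, float, float]] = {}


def _register(name: str, condition: str, t1: float, t2: float, t2s: float,
              sd_t1: float, sd_t2: float, sd_t2s: float) -> None:
    _CATALOG[(name, condition)] = TissueRelaxation(name, condition, t1, t2, t2s)
    _CATALOG_SD[(name, condition)] = (sd_t1, sd_t2, sd_t2s)


_register("brain_parenchyma", "pre", 2565.13, 46.04, 27.46, 161.81, 1.02, 1.60)
_register("csf", "pre", 3553.53, 165.75, 91.91, 125.49, 16.20, 25.20)
_register("tumor", "pre", 3221.08, 68.67, 37.71, 118.61, 2.15, 1.86)
_register("brain_parenchyma", "post", 2491.88, 47.38, 26.29, 76.09, 2.07, 0.86)
_register("csf", "post", 3477.46, 154.08, 82.88, 137.74, 7.06, 15.51)
_register("tumor", "post", 1032.96, 63.79, 34.33, 49.19, 5.47, 0.99)


def get_tissue(name: str, condition: str) -> TissueRelaxation:
    """Look up a built-in tissue record.

    Parameters
    ----------
    name : one of ``brain_parenchyma``, ``csf``, ``tumor``
    condition : ``pre`` or ``post`` (Gd-DTPA contrast)

    Raises
    ------
    KeyError
        If the tissue/condition pair is not in the catalog; the message lists
        the valid keys.
    """
    try:
        return _CATALOG[(name, condition)]
    except KeyError:
        raise KeyError(
            f"unknown tissue {(name, condition)!r}; valid tissues: {TISSUES}, "
            f"valid conditions: {CONDITIONS}"
        ) from None


def get_tissue_sd(name: str, condition: str) -> tuple[float, float, float]:
    """Between-mouse SDs ``(sd_t1, sd_t2, sd_t2star)`` for a catalog entry."""
    get_tissue(name, condition)  # validate key
    return _CATALOG_SD[(name, condition)]


def catalog(condition: str | None = None) -> dict[str, TissueRelaxation]:
    """All catalog entries, keyed by tissue name (one condition) or
    ``name/condition`` (both conditions when ``condition`` is None)."""
    if condition is not None:
        if condition not in CONDITIONS:
            raise KeyError(f"unknown condition {condition!r}; valid: {CONDITIONS}")
        return {name: _CATALOG[(name, condition)] for name in TISSUES}
    return {f"{n}/{c}": t for (n, c), t in _CATALOG.items()}


def cohort_spec(name: str, condition: str, n: int, seed: int = 0) -> TissueCohortSpec:
    """Cohort spec using the catalog's published mean and SD for a tissue."""
    sd_t1, sd_t2, sd_t2s = get_tissue_sd(name, condition)
    return TissueCohortSpec(get_tissue(name, condition), sd_t1, sd_t2, sd_t2s, n, seed)


def sample_cohort(spec: TissueCohortSpec) -> list[TissueRelaxation]:
    """Draw ``spec.n`` synthetic tissue records around the cohort mean.

    Each field is drawn independently from N(mean, sd) truncated at zero by
    rejection; with all SDs zero this is the identity on the mean.  Identical
    seeds give identical draws.
    """
    rng = np.random.default_rng(spec.seed)
    mean = spec.mean

    def draw(mu: float, sd: float) -> float:
        if sd == 0.0:
            return mu
        while True:
            value = rng.normal(mu, sd)
            if value > 0:
                return float(value)

    out = []
    for _ in range(spec.n):
        out.append(
            TissueRelaxation(
                mean.name,
                mean.condition,
                draw(mean.t1_ms, spec.sd_t1_ms),
                draw(mean.t2_ms, spec.sd_t2_ms),
                draw(mean.t2star_ms, spec.sd_t2star_ms),
            )
        )
    return out


_CSV_COLUMNS = ["name", "condition", "t1_ms", "t2_ms", "t2star_ms"]


def write_catalog_csv(path: str | Path, records: Iterable[TissueRelaxation] | None = None) -> None:
    """Write tissue records (default: the built-in catalog) as CSV."""
    records = list(records) if records is not None else list(_CATALOG.values())
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for t in records:
            writer.writerow([t.name, t.condition, t.t1_ms, t.t2_ms, t.t2star_ms])


def read_catalog_csv(path: str | Path) -> list[TissueRelaxation]:
    """Read tissue records from a CSV with the canonical column header."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_COLUMNS:
            raise ValueError(
                f"expected columns {_CSV_COLUMNS}, got {reader.fieldnames}"
            )
        return [
            TissueRelaxation(
                row["name"], row["condition"],
                float(row["t1_ms"]), float(row["t2_ms"]), float(row["t2star_ms"]),
            )
            for row in reader
        ]
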