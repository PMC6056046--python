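"""Grid sweeps over scanning parameters and the staged CNR optimization.

A :class:`SweepSpec` names a sequence, one varying parameter with an explicit
grid, fixed parameters, and optional linked rules (ESP→BW table, TR→ETL
schedule, NSA maximization under a scan-time budget).  :func:`run_sweep`
evaluates signal, SNR and pairwise CNR at every grid point;
:func:`argmax_cnr` picks the winning row of a signed CNR (or single-tissue
SNR) objective with deterministic tie-breaking; :func:`stepwise_optimize`
chains sweeps, pinning each stage's winner — or a user override emulating an
in-vivo adjustment — for subsequent stages.  :func:`compare_parameters`
implements the computed-vs-in-vivo parameter comparison and
:func:`kendall_tau` the rank agreement between two CNR curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acquisition import (
    AcquisitionGeometry,
    EspBwTable,
    SnrConfig,
    bw_for_esp,
    cnr,
    effective_te,
    max_nsa_under_budget,
    scan_time_s,
    snr,
)
from .signals import (
    FLAIRParams,
    FSEParams,
    GREParams,
    MPRAGEParams,
    sequence_signal,
)
from .tissues import TissueRelaxation

__all__ = [
    "SweepSpec",
    "SweepResult",
    "ComparisonOutcome",
    "OptimizationReport",
    "build_sequence",
    "run_sweep",
    "argmax_cnr",
    "stepwise_optimize",
    "compare_parameters",
    "kendall_tau",
    "objective_column",
]

SEQUENCES = ("fse", "flair", "gre", "mprage")

# Parameters each sequence understands (beyond the varying/linked ones).
_PARAM_KEYS = {
    "fse": {"tr_ms", "esp_ms", "etl", "te_eff_ms", "nsa", "bw"},
    "flair": {"tr_ms", "esp_ms", "etl", "te_eff_ms", "ti_ms", "nsa", "bw"},
    "gre": {"tr_ms", "te_ms", "fa_deg", "nsa", "bw"},
    "mprage": {"tr_ms", "ti_ms", "n_readouts", "td_ms", "fa_deg", "te_ms",
               "esp_ms", "readout_index", "nsa", "bw"},
}


@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep: a grid for ``varying`` on top of ``fixed`` values.

    ``objective`` is either a ``(tissue_a, tissue_b)`` pair — maximize signed
    CNR(a) − CNR(b) — or a single tissue name (maximize its signed SNR).
    ``pairs`` lists additional CNR columns to tabulate.  Linked rules:

    * ``esp_bw``: bandwidth looked up from the resolved echo spacing;
    * ``etl_schedule``: explicit TR → ETL coupling applied after resolution;
    * ``nsa_budget_s``: NSA set to the largest value within the budget
      (otherwise the fixed ``nsa``, default 1, is used).
    """

    sequence: str
    varying: str
    grid: tuple[float, ...]
    objective: tuple[str, str] | str
    fixed: Mapping[str, float] = field(default_factory=dict)
    pairs: tuple[tuple[str, str], ...] = ()
    esp_bw: EspBwTable | None = None
    etl_schedule: Mapping[float, int] | None = None
    nsa_budget_s: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise ValueError(f"unknown sequence {self.sequence!r}; valid: {SEQUENCES}")
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        object.__setattr__(self, "grid", tuple(self.grid))
        object.__setattr__(self, "fixed", dict(self.fixed))
        known = _PARAM_KEYS[self.sequence] | {"nsa"}
        unknown = (set(self.fixed) | {self.varying}) - known
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {sorted(unknown)} for sequence "
                f"{self.sequence!r}; valid: {sorted(known)}"
            )


@dataclass(frozen=True)
class SweepResult:
    """Evaluated sweep: one table row per grid point."""

    spec: SweepSpec
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class ComparisonOutcome:
    """Per-parameter verdicts of the computed-vs-in-vivo comparison."""

    verdicts: dict[str, tuple[bool, float, float]]  # name -> (matched, computed, invivo)

    @property
    def matched(self) -> list[str]:
        return [k for k, (ok, _, _) in self.verdicts.items() if ok]

    @property
    def mismatched(self) -> list[str]:
        """Parameters to pin to their in-vivo values and re-run."""
        return [k for k, (ok, _, _) in self.verdicts.items() if not ok]

    def as_dict(self) -> dict:
        return {
            k: {"matched": ok, "computed": comp, "invivo": viv}
            for k, (ok, comp, viv) in self.verdicts.items()
        }


@dataclass(frozen=True)
class OptimizationReport:
    """Stages of a stepwise optimization with their winners."""

    stages: list[dict]
    results: list[SweepResult]
    final_params: dict[str, float]


def objective_column(objective: tuple[str, str] | str) -> str:
    if isinstance(objective, str):
        return f"snr_{objective}"
    a, b = objective
    return f"cnr_{a}_minus_{b}"


def _resolve_point(spec: SweepSpec, value: float) -> dict:
    params = dict(spec.fixed)
    params[spec.varying] = value
    if spec.etl_schedule is not None and "tr_ms" in params:
        try:
            params["etl"] = spec.etl_schedule[params["tr_ms"]]
        except KeyError:
            raise ValueError(
                f"TR {params['tr_ms']} not covered by the ETL schedule "
                f"{dict(spec.etl_schedule)}"
            ) from None
    if spec.esp_bw is not None and "esp_ms" in params:
        params["bw"] = bw_for_esp(spec.esp_bw, params["esp_ms"])
    return params


def build_sequence(sequence: str, params: Mapping[str, float]):
    """Construct a typed sequence-parameter record from a flat mapping.

    Applies the module's conventions: the effective TE of FSE/FLAIR defaults
    to the center echo of the train, and MP-RAGE timing is resolved from the
    identity TR = TI + N·ESP + TD (TR derived when omitted, scanner-style).
    """
    if sequence not in SEQUENCES:
        raise ValueError(f"unknown sequence {sequence!r}; valid: {SEQUENCES}")
    try:
        if sequence in ("fse", "flair"):
            esp = params["esp_ms"]
            etl = int(params["etl"])
            te_eff = params.get("te_eff_ms")
            if te_eff is None:
                te_eff = effective_te(esp, etl)
            if sequence == "fse":
                return FSEParams(params["tr_ms"], esp, etl, te_eff)
            return FLAIRParams(params["tr_ms"], esp, etl, te_eff, params["ti_ms"])
        if sequence == "gre":
            return GREParams(params["tr_ms"], params["te_ms"], params["fa_deg"])
        # MP-RAGE: TR may be derived from the timing identity (minTR rule)
        n = int(params["n_readouts"])
        td = params.get("td_ms", 0.0)
        esp = params.get("esp_ms")
        tr = params.get("tr_ms")
        if tr is None:
            if esp is None:
                raise ValueError("mprage needs tr_ms or esp_ms to resolve timing")
            tr = params["ti_ms"] + n * esp + td
        return MPRAGEParams(
            tr_ms=tr, ti_ms=params["ti_ms"], n_readouts=n,
            fa_deg=params["fa_deg"], te_ms=params["te_ms"], td_ms=td,
            esp_ms=esp,
            readout_index=int(params["readout_index"]) if "readout_index" in params else None,
        )
    except KeyError as exc:
        raise ValueError(
            f"sequence {sequence!r} is missing parameter {exc.args[0]!r}"
        ) from None


def run_sweep(
    spec: SweepSpec,
    tissues: Mapping[str, TissueRelaxation],
    geom: AcquisitionGeometry,
    cfg: SnrConfig = SnrConfig(),
    convention: str = "signed",
) -> SweepResult:
    """Evaluate signal, SNR and CNR at every grid point (deterministic).

    ``convention`` is ``signed`` (default) or ``magnitude`` (absolute signal
    before the SNR prefactor, as in a magnitude image).
    """
    if convention not in ("signed", "magnitude"):
        raise ValueError("convention must be 'signed' or 'magnitude'")
    pairs = list(spec.pairs)
    if isinstance(spec.objective, tuple) and spec.objective not in pairs:
        pairs.insert(0, spec.objective)
    for pair in pairs:
        for name in pair:
            if name not in tissues:
                raise ValueError(f"objective tissue {name!r} not among {sorted(tissues)}")

    rows = []
    for value in spec.grid:
        try:
            params = _resolve_point(spec, value)
            seq = build_sequence(spec.sequence, params)
            if spec.nsa_budget_s is not None:
                nsa = max_nsa_under_budget(seq, geom, spec.nsa_budget_s)
            else:
                nsa = int(params.get("nsa", 1))
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"grid point {spec.varying}={value}: {exc}"
            ) from exc
        bw = params.get("bw")
        row: dict = {spec.varying: value}
        for key in ("tr_ms", "esp_ms", "etl", "ti_ms", "fa_deg", "te_ms",
                    "te_eff_ms", "n_readouts", "td_ms", "readout_index"):
            if hasattr(seq, key):
                row[key] = getattr(seq, key)
        row["bw"] = bw if bw is not None else geom.bw
        row["nsa"] = nsa
        row["scan_time_s"] = scan_time_s(seq, geom, nsa)
        snr_by_tissue = {}
        for name, tissue in tissues.items():
            sig = sequence_signal(seq, tissue)
            s = abs(sig.s_over_m0) if convention == "magnitude" else sig.s_over_m0
            row[f"s_{name}"] = s
            snr_by_tissue[name] = snr(s, geom, nsa, cfg, bw=bw)
            row[f"snr_{name}"] = snr_by_tissue[name]
        for a, b in pairs:
            row[f"cnr_{a}_minus_{b}"] = cnr(snr_by_tissue[a], snr_by_tissue[b])
        rows.append(row)
    return SweepResult(spec, pd.DataFrame(rows))


def argmax_cnr(
    result: SweepResult,
    objective: tuple[str, str] | str | None = None,
) -> pd.Series:
    """Row maximizing the signed objective, with deterministic tie-breaking.

    Ties in the objective are broken by (1) smaller scan time, then
    (2) smaller value of the varying parameter.
    """
    table = result.table
    if len(table) == 0:
        raise ValueError("sweep result is empty")
    col = objective_column(objective if objective is not None else result.spec.objective)
    if col not in table.columns:
        raise KeyError(f"objective column {col!r} not tabulated; have {list(table.columns)}")
    ordered = table.sort_values(
        by=["scan_time_s", result.spec.varying], kind="stable"
    )
    return ordered.loc[ordered[col].idxmax()]


def stepwise_optimize(
    plan: Sequence[SweepSpec],
    tissues: Mapping[str, TissueRelaxation],
    geom: AcquisitionGeometry,
    cfg: SnrConfig = SnrConfig(),
    overrides: Mapping[str, float] | None = None,
    convention: str = "signed",
) -> OptimizationReport:
    """Run sweep stages in order, carrying each stage's winner forward.

    ``overrides`` pins parameters to externally chosen (in-vivo) values: an
    overridden parameter is never swept — its stage is recorded as pinned —
    and the pinned value is injected into every stage's fixed parameters.
    """
    overrides = dict(overrides or {})
    carry: dict[str, float] = dict(overrides)
    stages: list[dict] = []
    results: list[SweepResult] = []
    for spec in plan:
        if spec.varying in overrides:
            stages.append({
                "name": spec.name or spec.varying,
                "varying": spec.varying,
                "pinned": True,
                "winner": overrides[spec.varying],
            })
            continue
        fixed = dict(spec.fixed)
        fixed.update({k: v for k, v in carry.items() if k != spec.varying and k in _PARAM_KEYS[spec.sequence]})
        staged = SweepSpec(
            sequence=spec.sequence, varying=spec.varying, grid=spec.grid,
            objective=spec.objective, fixed=fixed, pairs=spec.pairs,
            esp_bw=spec.esp_bw, etl_schedule=spec.etl_schedule,
            nsa_budget_s=spec.nsa_budget_s, name=spec.name,
        )
        result = run_sweep(staged, tissues, geom, cfg, convention)
        winner = argmax_cnr(result)
        value = winner[spec.varying]
        carry[spec.varying] = (
            int(value) if spec.varying in ("etl", "n_readouts", "nsa") else float(value)
        )
        if staged.etl_schedule is not None and "etl" in winner.index:
            carry["etl"] = int(winner["etl"])
        if staged.nsa_budget_s is not None:
            carry["nsa"] = int(winner["nsa"])
        stages.append({
            "name": staged.name or staged.varying,
            "varying": staged.varying,
            "pinned": False,
            "winner": carry[spec.varying],
            "objective_value": winner[objective_column(staged.objective)],
            "row": winner.to_dict(),
        })
        results.append(result)
    return OptimizationReport(stages, results, dict(carry))


def compare_parameters(
    computed: Mapping[str, float],
    invivo: Mapping[str, float],
    tol: float = 0.0,
) -> ComparisonOutcome:
    """Per-parameter equality verdicts between computed and in-vivo optima.

    Grid-valued parameters compare exactly (``tol`` = 0); mismatched
    parameters are exactly those to pin and re-run in the workflow's
    feedback branch.
    """
    if set(computed) != set(invivo):
        raise ValueError(
            f"parameter names differ: computed has {sorted(set(computed) - set(invivo))} "
            f"extra, in-vivo has {sorted(set(invivo) - set(computed))} extra"
        )
    verdicts = {}
    for key in computed:
        a, b = float(computed[key]), float(invivo[key])
        verdicts[key] = (abs(a - b) <= tol, a, b)
    return ComparisonOutcome(verdicts)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-a rank correlation over all pairs; ties contribute zero.

    ``tau = (concordant − discordant) / (n(n−1)/2)`` for two equally long
    curves sampled at the same parameter values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    iu = np.triu_indices(n, k=1)
    dx = np.sign(x[:, None] - x[None, :])[iu]
    dy = np.sign(y[:, None] - y[None, :])[iu]
    return float(np.sum(dx * dy) / (n * (n - 1) / 2))
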