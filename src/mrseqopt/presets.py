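"""Ready-made sweep plans mirroring the study's optimization experiments.

Each plan is the staged in-silico counterpart of one scanner experiment on
the glioblastoma mouse model: FSE T2- and T1-weighted, FLAIR, spoiled GRE
and 3D MP-RAGE, in pre- or post-contrast conditions.  Grids, initial values,
couplings (ESP→BW, TR→ETL) and scan-time budgets are the published protocol
settings.  The CNR objective of every stage puts the brighter tissue first
so that signed maximization selects the contrast-maximizing parameter.

``IN_VIVO_OPTIMA`` holds the published optimal in-vivo scanning parameters
against which computed winners are compared.
"""

from __future__ import annotations

from .acquisition import GEOMETRY_2D, GEOMETRY_3D, AcquisitionGeometry, EspBwTable
from .sweep import SweepSpec

__all__ = [
    "ESP_BW_T2",
    "ESP_BW_T1",
    "FLAIR_TR_ETL_SCHEDULE",
    "IN_VIVO_OPTIMA",
    "T1_MAPPING_TR_MS",
    "T2_MAPPING_TE_MS",
    "T2STAR_MAPPING_TE_MS",
    "plan",
    "plan_geometry",
    "PLAN_NAMES",
]

# Echo-spacing grids with their receiver-bandwidth couplings.  The published
# anchors are 5.4→100, 7.4→50, 13.4→20 and 17.4→13.5; intermediate bandwidths
# follow the scanner's stepped readout settings (see docs/methods.md).
ESP_BW_T2 = EspBwTable((
    (5.4, 100.0), (6.0, 75.0), (7.4, 50.0), (9.4, 33.0),
    (11.4, 25.0), (13.4, 20.0), (15.4, 16.0), (17.4, 13.5),
))
ESP_BW_T1 = EspBwTable(ESP_BW_T2.pairs[:6])  # 5.4 … 13.4 ms, 100 → 20

# FLAIR long-TR experiment: minimum ETL admissible at each TR under the
# 10-minute limit.
FLAIR_TR_ETL_SCHEDULE = {
    6000.0: 2, 7000.0: 3, 8000.0: 3, 9000.0: 3, 10000.0: 4,
    11000.0: 4, 15000.0: 5, 20000.0: 7, 25000.0: 9,
}

FIVE_MIN_S = 300.0
TEN_MIN_S = 600.0

# Relaxometry protocol grids (ms).
T1_MAPPING_TR_MS = (278.0, 400.0, 800.0, 1500.0, 3000.0, 5500.0, 7000.0)
T2_MAPPING_TE_MS = (8.5, 25.5, 42.5, 59.5, 76.5)
T2STAR_MAPPING_TE_MS = tuple(2.4 + 4.0 * k for k in range(15))

# Published optimal in-vivo scanning parameters (grid-valued subset).
IN_VIVO_OPTIMA = {
    "fset2_pre": {"esp_ms": 7.4, "etl": 15, "tr_ms": 7000.0, "nsa": 3},
    "fset1_pre": {"esp_ms": 7.4, "etl": 1, "tr_ms": 500.0, "nsa": 3},
    "fset1_post": {"esp_ms": 7.4, "tr_ms": 500.0, "nsa": 3},
    "flair_pre": {"ti_ms": 1700.0, "tr_ms": 9000.0},
    "gre_pre": {"fa_deg": 60.0, "tr_ms": 350.0, "nsa": 4},
    "gre_post": {"fa_deg": 90.0, "tr_ms": 275.0, "nsa": 5},
    "mprage_pre": {"ti_ms": 1700.0, "fa_deg": 10.0, "nsa": 1},
    "mprage_post": {"ti_ms": 1700.0, "fa_deg": 10.0, "nsa": 1},
}

# MP-RAGE minTR timing: at the published TR = 1983 ms, TI = 1700 ms, TD = 0
# and N = 128 readouts, the echo spacing is (1983 − 1700)/128 ms; the TI
# sweep keeps ESP fixed and derives TR per grid point (scanner minTR rule).
MPRAGE_N = 128
MPRAGE_ESP_MS = (1983.0 - 1700.0) / MPRAGE_N
MPRAGE_TE_MS = 2.3


def _fset2_plan(condition: str) -> list[SweepSpec]:
    objective = ("tumor", "brain_parenchyma")  # T2w: tumor hyperintense
    return [
        SweepSpec(
            "fse", "esp_ms", tuple(e for e, _ in ESP_BW_T2.pairs), objective,
            fixed={"tr_ms": 6000.0, "etl": 13, "nsa": 1},
            esp_bw=ESP_BW_T2, name="esp",
        ),
        SweepSpec(
            "fse", "etl", tuple(float(k) for k in range(10, 21)), objective,
            fixed={"tr_ms": 6000.0, "nsa": 1}, name="etl",
        ),
        SweepSpec(
            "fse", "tr_ms", tuple(float(tr) for tr in range(4000, 10001, 1000)),
            objective, fixed={}, nsa_budget_s=FIVE_MIN_S, name="tr",
        ),
    ]


def _fset1_plan(condition: str) -> list[SweepSpec]:
    # T1w: parenchyma brighter pre-contrast, enhancing tumor brighter post.
    objective = (
        ("brain_parenchyma", "tumor") if condition == "pre"
        else ("tumor", "brain_parenchyma")
    )
    return [
        SweepSpec(
            "fse", "esp_ms", tuple(e for e, _ in ESP_BW_T1.pairs), objective,
            fixed={"tr_ms": 700.0, "etl": 1, "nsa": 3},
            esp_bw=ESP_BW_T1, name="esp",
        ),
        SweepSpec(
            "fse", "etl", (1.0, 2.0, 3.0, 4.0, 5.0), objective,
            fixed={"tr_ms": 700.0, "nsa": 3}, name="etl",
        ),
        SweepSpec(
            "fse", "tr_ms", (500.0, 600.0, 700.0, 800.0), objective,
            fixed={}, nsa_budget_s=FIVE_MIN_S, name="tr",
        ),
    ]


def _flair_plan(condition: str) -> list[SweepSpec]:
    objective = ("brain_parenchyma", "csf")
    return [
        SweepSpec(
            "flair", "ti_ms", tuple(float(ti) for ti in range(1100, 3101, 200)),
            objective,
            fixed={"tr_ms": 8000.0, "esp_ms": 7.4, "etl": 1, "nsa": 1, "bw": 50.0},
            name="ti",
        ),
        SweepSpec(
            "flair", "tr_ms", tuple(sorted(FLAIR_TR_ETL_SCHEDULE)), objective,
            fixed={"esp_ms": 7.4, "nsa": 1, "bw": 50.0},
            etl_schedule=FLAIR_TR_ETL_SCHEDULE, name="tr",
        ),
    ]


def _gre_plan(condition: str) -> list[SweepSpec]:
    objective = (
        ("brain_parenchyma", "tumor") if condition == "pre"
        else ("tumor", "brain_parenchyma")
    )
    return [
        SweepSpec(
            "gre", "fa_deg", tuple(float(fa) for fa in range(10, 91, 10)),
            objective, fixed={"tr_ms": 275.0, "te_ms": 3.5, "nsa": 3}, name="fa",
        ),
        SweepSpec(
            "gre", "tr_ms", (275.0, 350.0, 500.0, 700.0, 1000.0), objective,
            fixed={"te_ms": 3.5}, nsa_budget_s=FIVE_MIN_S, name="tr",
        ),
    ]


def _mprage_plan(condition: str) -> list[SweepSpec]:
    objective = (
        ("brain_parenchyma", "tumor") if condition == "pre"
        else ("tumor", "brain_parenchyma")
    )
    fixed = {
        "n_readouts": MPRAGE_N, "td_ms": 0.0, "te_ms": MPRAGE_TE_MS,
        "esp_ms": MPRAGE_ESP_MS, "fa_deg": 10.0, "nsa": 1,
    }
    return [
        SweepSpec(
            "mprage", "ti_ms", tuple(float(ti) for ti in range(500, 3501, 500)),
            objective, fixed=dict(fixed), name="ti",
        ),
        SweepSpec(
            "mprage", "fa_deg", tuple(float(fa) for fa in range(10, 91, 10)),
            objective,
            fixed={k: v for k, v in fixed.items() if k != "fa_deg"} | {"ti_ms": 1700.0},
            nsa_budget_s=FIVE_MIN_S, name="fa",
        ),
    ]


_PLANS = {
    "fset2": _fset2_plan,
    "fset1": _fset1_plan,
    "flair": _flair_plan,
    "gre": _gre_plan,
    "mprage": _mprage_plan,
}

PLAN_NAMES = tuple(
    f"{seq}_{cond}"
    for seq in _PLANS
    for cond in (("pre",) if seq == "flair" else ("pre", "post"))
)


def plan(name: str) -> list[SweepSpec]:
    """Staged sweep plan for a preset like ``fset1_pre`` or ``mprage_post``."""
    if name not in PLAN_NAMES:
        raise KeyError(f"unknown plan {name!r}; available: {PLAN_NAMES}")
    seq, condition = name.rsplit("_", 1)
    return _PLANS[seq](condition)


def plan_geometry(name: str) -> AcquisitionGeometry:
    """The study geometry a preset plan was acquired with."""
    if name not in PLAN_NAMES:
        raise KeyError(f"unknown plan {name!r}; available: {PLAN_NAMES}")
    return GEOMETRY_3D if name.startswith("mprage") else GEOMETRY_2D
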