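"""Synthetic plates, cohorts and serial-resistance scenarios.

Every stage of the analysis can be exercised without patient data by
simulating 384-well viability screens from a known ground-truth quadratic
surface: raw well signals are the surface value at each design point times
a luminescence scale, plus noise, with untreated negative-control wells at
baseline and cytotoxic positive-control wells near zero.  Clinical labels
are tied to the same ground truth (regimen NCV below the response cutoff)
with a configurable label-flip probability, so concordance estimates have
a known target (sensitivity and specificity both 1 - eps) — the generator
tests pipeline correctness, not biological validity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DrugPanel, DesignMatrix, generate_oacd
from .plate import DESIGN, NEGATIVE, POSITIVE, PlateReadout
from .concordance import NCV_CUTOFF
from .surface import (
    QuadraticSurfaceRegressor,
    predict_regimen_ncv,
    surface_from_coefficients,
)

__all__ = [
    "SimulationConfig",
    "aml_panel",
    "sample_truth_surface",
    "simulate_plate",
    "simulate_cohort",
    "simulate_serial_resistance",
    "SyntheticPatient",
    "Cohort",
]

#: the 12-drug AML screening panel the default simulations mirror; the
#: names are labels only — no pharmacology is attached to them
AML_DRUGS = (
    "azacytidine",
    "venetoclax",
    "cytarabine",
    "fludarabine",
    "daunorubicin",
    "idarubicin",
    "etoposide",
    "cladribine",
    "midostaurin",
    "gilteritinib",
    "sorafenib",
    "decitabine",
)

#: regimens sampled for synthetic patients (hypomethylating agent +
#: venetoclax doublet most frequent, as in AML practice)
DEFAULT_REGIMENS: tuple[tuple[frozenset[str], float], ...] = (
    (frozenset({"azacytidine", "venetoclax"}), 0.38),
    (frozenset({"cytarabine", "daunorubicin"}), 0.22),
    (frozenset({"fludarabine", "cytarabine"}), 0.15),
    (frozenset({"azacytidine"}), 0.10),
    (frozenset({"cytarabine", "idarubicin"}), 0.08),
    (frozenset({"midostaurin", "cytarabine", "daunorubicin"}), 0.07),
)


def aml_panel() -> DrugPanel:
    """Default 12-drug panel with plausible molar dose triples; the top
    dose of each drug is 10% of its nominal Cmax."""
    # (low, high) tested concentrations in micromolar
    um = {
        "azacytidine": (1.0, 5.0),
        "venetoclax": (0.1, 1.0),
        "cytarabine": (0.5, 5.0),
        "fludarabine": (0.5, 3.0),
        "daunorubicin": (0.05, 0.5),
        "idarubicin": (0.02, 0.2),
        "etoposide": (1.0, 8.0),
        "cladribine": (0.05, 0.5),
        "midostaurin": (0.1, 1.0),
        "gilteritinib": (0.05, 0.5),
        "sorafenib": (0.5, 2.0),
        "decitabine": (0.5, 2.5),
    }
    doses = tuple((0.0, lo * 1e-6, hi * 1e-6) for lo, hi in (um[d] for d in AML_DRUGS))
    cmax = {d: um[d][1] * 1e-5 for d in AML_DRUGS}  # top dose == 10% Cmax
    return DrugPanel(AML_DRUGS, doses, cmax=cmax)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screens.

    noise_sd is additive Gaussian noise on the NCV scale applied per well
    (default 0.05, a realistic replicate CV for luminescence viability
    screens); label_flip_eps is the probability a clinical label
    contradicts the true-surface prediction (default 0.1, i.e. true
    sensitivity/specificity 0.9); synergy_pairs inject fixed negative
    interaction terms on named drug pairs.
    """

    k: int = 12
    seed: int = 0
    noise_sd: float = 0.05
    noise_model: str = "additive"  # or "lognormal" (multiplicative)
    synergy_pairs: tuple[tuple[tuple[str, str], float], ...] = (
        (("fludarabine", "cytarabine"), -0.12),
        (("fludarabine", "venetoclax"), -0.08),
    )
    resistance_drift: float = 0.1
    label_flip_eps: float = 0.1
    cohort_size: int = 29
    #: alternate patients between true responders and true non-responders
    #: (by redrawing the surface), so the cohort is balanced in true
    #: response status and estimated sensitivity and specificity share the
    #: same calibration target 1 - label_flip_eps
    balance_true_classes: bool = True
    n_replicates: int = 2
    n_negative: int = 12
    n_positive: int = 12
    control_scale: float = 10_000.0  # RLU of an untreated well
    positive_level: float = 0.02     # residual viability of the cytotoxic control
    cutoff: float = NCV_CUTOFF

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.label_flip_eps <= 0.5:
            raise ValueError("label_flip_eps must be in [0, 0.5]")
        if self.noise_model not in ("additive", "lognormal"):
            raise ValueError("noise_model must be 'additive' or 'lognormal'")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


# ---------------------------------------------------------------------------
# ground-truth surfaces
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _cached_design(k: int) -> DesignMatrix:
    return generate_oacd(k)


def sample_truth_surface(
    config: SimulationConfig,
    panel: DrugPanel | None = None,
    rng: np.random.Generator | None = None,
) -> QuadraticSurfaceRegressor:
    """Draw a patient-specific ground-truth surface.

    Intercept exactly 1 (untreated NCV); linear terms negative (every
    drug kills on its own, to varying degree); quadratic terms small.
    Pairwise terms default to the product of the two single-drug effects
    — the second-order expansion of multiplicative (Bliss-independent)
    viability, which keeps combined kill sub-additive and the surface
    bounded on the dose cube — plus weak noise and the configured synergy
    terms.  A final saturation rescale of the non-intercept coefficients
    guarantees the surface is nonnegative at every composite-design test
    point, so simulated raw signals never need truncation in the
    noiseless limit.
    """
    panel = panel if panel is not None else aml_panel()
    if panel.k != config.k:
        raise ValueError("panel size does not match config.k")
    rng = rng if rng is not None else config.rng(stream=1)
    k = config.k
    names = list(panel.drugs)
    linear = -rng.uniform(0.05, 0.35, size=k)
    quadratic = rng.normal(0.0, 0.01, size=k)
    iu, ju = np.triu_indices(k, 1)
    interaction = linear[iu] * linear[ju] + rng.normal(0.0, 0.01, size=len(iu))
    pair_pos = {(int(i), int(j)): idx for idx, (i, j) in enumerate(zip(iu, ju))}
    for (a, b), beta in config.synergy_pairs:
        if a not in names or b not in names:
            continue
        i, j = sorted((names.index(a), names.index(b)))
        interaction[pair_pos[(i, j)]] += beta
    truth = surface_from_coefficients(1.0, linear, quadratic, interaction, drug_names=names)

    # saturation floor: keep the surface >= floor at the design points by
    # uniformly shrinking the kill terms (an affine rescale in kill space,
    # so the surface stays exactly quadratic)
    floor = 0.02
    y_min = float(truth.predict(_cached_design(k).codes).min())
    if y_min < floor:
        s = (1.0 - floor) / (1.0 - y_min)
        truth = surface_from_coefficients(
            1.0, linear * s, quadratic * s, interaction * s, drug_names=names
        )
    return truth


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------


def _well_ids(n: int) -> list[str]:
    """Row-major 384-well ids A1..P24 (wrapping onto further plates if n
    exceeds 384, which the default layout never does)."""
    ids = []
    for i in range(n):
        plate, pos = divmod(i, 384)
        row, col = divmod(pos, 24)
        prefix = "" if plate == 0 else f"P{plate + 1}:"
        ids.append(f"{prefix}{chr(ord('A') + row)}{col + 1}")
    return ids


def _noisy(values: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "additive":
        out = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    else:
        out = values * rng.lognormal(0.0, config.noise_sd, size=values.shape)
    return np.clip(out, 0.0, None)


def simulate_plate(
    truth: QuadraticSurfaceRegressor,
    design: DesignMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PlateReadout:
    """Simulate raw well signals for one screening run.

    Treated wells carry the truth-surface NCV at their design row (noisy,
    truncated at 0) times the luminescence scale; negative controls sit at
    the scale itself, positive controls near zero.
    """
    if design.k != truth.k:
        raise ValueError("design and truth surface disagree on drug count")
    rng = rng if rng is not None else config.rng(stream=2)
    y_true = truth.predict(design.codes)

    rows, signals, roles, reps = [], [], [], []
    for rep in range(config.n_replicates):
        vals = _noisy(y_true, config, rng)
        signals.extend(config.control_scale * vals)
        rows.extend(range(design.n_rows))
        roles.extend([DESIGN] * design.n_rows)
        reps.extend([rep] * design.n_rows)
    neg = _noisy(np.ones(config.n_negative), config, rng)
    pos = _noisy(np.full(config.n_positive, config.positive_level), config, rng)
    signals.extend(config.control_scale * neg)
    roles.extend([NEGATIVE] * config.n_negative)
    rows.extend([pd.NA] * config.n_negative)
    reps.extend([0] * config.n_negative)
    signals.extend(config.control_scale * pos)
    roles.extend([POSITIVE] * config.n_positive)
    rows.extend([pd.NA] * config.n_positive)
    reps.extend([0] * config.n_positive)

    wells = pd.DataFrame(
        {
            "well": _well_ids(len(signals)),
            "signal": np.asarray(signals, dtype=float),
            "role": roles,
            "design_row": pd.array(rows, dtype="Int64"),
            "replicate": reps,
        }
    )
    return PlateReadout(wells)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticPatient:
    patient: str
    truth: QuadraticSurfaceRegressor
    plate: PlateReadout
    regimen: frozenset[str]
    clinical_label: str  # CR or NR
    tags: dict[str, str]
    true_regimen_ncv: float


@dataclass(frozen=True)
class Cohort:
    patients: tuple[SyntheticPatient, ...]
    design: DesignMatrix
    panel: DrugPanel
    config: SimulationConfig

    def clinical_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": [p.patient for p in self.patients],
                "regimen": [";".join(sorted(p.regimen)) for p in self.patients],
                "clinical_response": [p.clinical_label for p in self.patients],
                "status": [p.tags["status"] for p in self.patients],
                "eln_risk": [p.tags["eln_risk"] for p in self.patients],
            }
        )


def simulate_cohort(
    config: SimulationConfig,
    panel: DrugPanel | None = None,
    design: DesignMatrix | None = None,
    regimens: Sequence[tuple[frozenset[str], float]] | None = None,
) -> Cohort:
    """Simulate a clinical cohort: per patient a truth surface, a plate,
    an administered regimen, and a clinical label equal to the true-surface
    prediction (regimen NCV < cutoff) XOR a flip with probability eps.

    Disease status is ND with probability 0.69 (else R/R) and ELN risk
    favorable/intermediate/adverse at 0.25/0.40/0.35, mirroring the mix of
    a real-world AML screening cohort.
    """
    panel = panel if panel is not None else aml_panel()
    design = design if design is not None else generate_oacd(config.k)
    regimens = list(regimens if regimens is not None else DEFAULT_REGIMENS)
    names, weights = zip(*regimens)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    rng = config.rng(stream=3)

    patients = []
    for i in range(config.cohort_size):
        target = (i % 2 == 0) if config.balance_true_classes else None
        for _ in range(64):  # redraw until the target true class is hit
            truth = sample_truth_surface(config, panel, rng=rng)
            regimen = names[int(rng.choice(len(names), p=weights))]
            true_ncv = predict_regimen_ncv(truth, regimen)
            if target is None or (true_ncv < config.cutoff) == target:
                break
        plate = simulate_plate(truth, design, config, rng=rng)
        responds = true_ncv < config.cutoff
        if rng.random() < config.label_flip_eps:
            responds = not responds
        patients.append(
            SyntheticPatient(
                patient=f"SYN{i + 1:04d}",
                truth=truth,
                plate=plate,
                regimen=regimen,
                clinical_label="CR" if responds else "NR",
                tags={
                    "status": "ND" if rng.random() < 0.69 else "RR",
                    "eln_risk": ["favorable", "intermediate", "adverse"][
                        int(rng.choice(3, p=[0.25, 0.40, 0.35]))
                    ],
                },
                true_regimen_ncv=float(true_ncv),
            )
        )
    return Cohort(tuple(patients), design, panel, config)


# ---------------------------------------------------------------------------
# serial resistance
# ---------------------------------------------------------------------------


def simulate_serial_resistance(
    config: SimulationConfig,
    n_runs: int,
    drug: str = "midostaurin",
    start_coefficient: float = -0.5,
    panel: DrugPanel | None = None,
    design: DesignMatrix | None = None,
) -> list[tuple[QuadraticSurfaceRegressor, PlateReadout]]:
    """Serial screens of one patient developing resistance to one drug.

    The named drug's linear coefficient starts at ``start_coefficient``
    and moves toward 0 by ``resistance_drift`` per consecutive run (all
    other coefficients held fixed), so the true single-drug NCV at top
    dose increases strictly run over run.
    """
    if config.resistance_drift <= 0:
        raise ValueError("resistance_drift must be > 0 for a resistance scenario")
    panel = panel if panel is not None else aml_panel()
    if drug not in panel.drugs:
        raise KeyError(f"{drug!r} not in panel")
    design = design if design is not None else generate_oacd(config.k)
    rng = config.rng(stream=4)
    base = sample_truth_surface(config, panel, rng=rng)
    idx = list(panel.drugs).index(drug)
    runs = []
    for r in range(n_runs):
        linear = base.coef_linear_.copy()
        linear[idx] = start_coefficient + r * config.resistance_drift
        truth = surface_from_coefficients(
            base.intercept_, linear, base.coef_quadratic_,
            base.coef_interaction_, drug_names=list(panel.drugs),
        )
        plate = simulate_plate(truth, design, config, rng=rng)
        runs.append((truth, plate))
    return runs


# ---------------------------------------------------------------------------
# file emission (same formats the analysis consumes)
# ---------------------------------------------------------------------------


def write_plate_files(plate: PlateReadout, readout_path: str | Path, layout_path: str | Path) -> None:
    df = plate.wells
    df[["well", "signal"]].to_csv(readout_path, index=False)
    layout = df[["well", "role", "design_row"]].copy()
    layout["replicate"] = df["replicate"] if "replicate" in df.columns else 0
    layout.to_csv(layout_path, index=False)
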