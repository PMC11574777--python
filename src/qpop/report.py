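"""Per-patient report generation and cohort-level concordance evaluation.

``run_qpop`` executes the full single-run analysis — normalize, QC gate,
surface fit, exhaustive ranking, top-combination extraction and the
pairwise-interaction matrix — and fails soft (status "excluded") when the
assay window is inadequate.  ``evaluate_cohort`` scores each evaluable
patient's administered regimen on their fitted surface, compares the
dichotomized prediction with the clinical outcome, and assembles the
overall and subgroup confusion summaries, Fisher test, ROC analysis, and
the cohort-wide top-pair frequency table, with explicit exclusion
accounting (QC-failed, out-of-panel regimen, missing outcome).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import concordance as conc
from .design import DesignMatrix, DrugPanel, read_design
from .plate import NormalizedResponse, PlateReadout, QCMetrics, ZPRIME_GATE, normalize_to_controls, qc_gate, read_plate
from .surface import (
    CombinationRanking,
    QuadraticSurfaceRegressor,
    enumerate_and_rank,
    fit_quadratic_surface,
    pairwise_interaction_matrix,
    predict_regimen_ncv,
    top_combinations,
)

__all__ = ["PatientReport", "ConcordanceReport", "run_qpop", "evaluate_cohort"]

log = logging.getLogger("qpop")

TOP_N = 10  # combinations reported per order


def _hash_panel(panel: DrugPanel) -> str:
    payload = json.dumps({"drugs": list(panel.drugs), "doses": [list(d) for d in panel.doses]})
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class PatientReport:
    """Patient-facing drug-sensitivity report for one screening run."""

    patient: str
    status: str  # "ok" or "excluded"
    qc: QCMetrics
    panel_hash: str
    adj_r2: float | None = None
    n_obs: int | None = None
    model: QuadraticSurfaceRegressor | None = None
    ranking: CombinationRanking | None = None
    single_drug: pd.DataFrame | None = None     # per drug, NCV at codes 1 and 2
    top_pairs: pd.DataFrame | None = None       # top-N order-2 combinations
    top_triples: pd.DataFrame | None = None     # top-N order-3 combinations
    interactions: pd.DataFrame | None = None    # polygonogram matrix

    def to_json(self) -> str:
        payload: dict = {
            "patient": self.patient,
            "status": self.status,
            "qc": {
                "zprime": self.qc.zprime,
                "ssmd": self.qc.ssmd,
                "passed": self.qc.passed,
                "threshold": self.qc.threshold,
            },
            "panel_hash": self.panel_hash,
        }
        if self.status == "ok":
            payload.update(
                adj_r2=self.adj_r2,
                n_obs=self.n_obs,
                single_drug=self.single_drug.to_dict(orient="records"),
                top_pairs=self.top_pairs.to_dict(orient="records"),
                top_triples=self.top_triples.to_dict(orient="records"),
                interactions=self.interactions.round(6).to_dict(),
            )
        return json.dumps(payload, indent=1, default=float)

    def to_markdown(self) -> str:
        lines = [
            f"# Drug sensitivity report — {self.patient}",
            "",
            f"QC: Z' = {self.qc.zprime:.3f}, SSMD = {self.qc.ssmd:.2f} "
            f"({'PASS' if self.qc.passed else 'EXCLUDED'}; gate Z' >= {self.qc.threshold})",
        ]
        if self.status != "ok":
            lines.append("\nRun excluded: assay window below quality gate; no model fitted.")
            return "\n".join(lines)
        lines += [
            f"Model: adjusted R^2 = {self.adj_r2:.3f} on {self.n_obs} test points",
            "",
            "## Top two-drug combinations (predicted NCV, ascending)",
            self.top_pairs.to_markdown(index=False),
            "",
            "## Top three-drug combinations",
            self.top_triples.to_markdown(index=False),
        ]
        return "\n".join(lines)


def _single_drug_table(model: QuadraticSurfaceRegressor) -> pd.DataFrame:
    names = model.drug_names()
    k = model.k
    rows = []
    for i, name in enumerate(names):
        entry = {"drug": name}
        for code, label in ((1, "ncv_low"), (2, "ncv_high")):
            v = np.zeros(k, dtype=int)
            v[i] = code
            entry[label] = float(model.predict(v.reshape(1, -1))[0])
        rows.append(entry)
    return pd.DataFrame(rows)


def run_qpop(
    readout_file: str | Path,
    layout_file: str | Path,
    design: DesignMatrix | str | Path,
    panel: DrugPanel,
    patient: str = "anonymous",
    zprime_threshold: float = ZPRIME_GATE,
    top_n: int = TOP_N,
) -> PatientReport:
    """Full per-run analysis: normalize -> QC gate -> fit -> enumerate ->
    top combinations + interaction matrix.  A failing QC gate yields a
    structured "excluded" report rather than an exception."""
    if not isinstance(design, DesignMatrix):
        design = read_design(design)
    plate = read_plate(readout_file, layout_file)
    return analyze_plate(plate, design, panel, patient, zprime_threshold, top_n)


def analyze_plate(
    plate: PlateReadout,
    design: DesignMatrix,
    panel: DrugPanel,
    patient: str = "anonymous",
    zprime_threshold: float = ZPRIME_GATE,
    top_n: int = TOP_N,
) -> PatientReport:
    """In-memory variant of :func:`run_qpop`."""
    panel_hash = _hash_panel(panel)
    metrics = qc_gate(plate, threshold=zprime_threshold)
    log.info("patient=%s stage=qc zprime=%.4f ssmd=%.2f passed=%s",
             patient, metrics.zprime, metrics.ssmd, metrics.passed)
    if not metrics.passed:
        return PatientReport(patient=patient, status="excluded", qc=metrics, panel_hash=panel_hash)
    response = normalize_to_controls(plate)
    model = fit_quadratic_surface(design, response, drug_names=panel.drugs)
    log.info("patient=%s stage=fit adj_r2=%.4f n_obs=%d", patient, model.adj_r2_, model.n_obs_)
    ranking = enumerate_and_rank(model)
    return PatientReport(
        patient=patient,
        status="ok",
        qc=metrics,
        panel_hash=panel_hash,
        adj_r2=float(model.adj_r2_),
        n_obs=int(model.n_obs_),
        model=model,
        ranking=ranking,
        single_drug=_single_drug_table(model),
        top_pairs=top_combinations(ranking, order=2, n=top_n),
        top_triples=top_combinations(ranking, order=3, n=top_n),
        interactions=pairwise_interaction_matrix(model),
    )


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceReport:
    """Cohort-level predicted-vs-clinical concordance."""

    records: tuple[conc.ConcordanceRecord, ...]
    overall: conc.ConfusionSummary
    subgroups: Mapping[str, conc.ConfusionSummary]
    fisher_p: float
    roc: conc.ROCResult | None
    top_pairs: pd.DataFrame
    exclusions: pd.DataFrame  # patient, reason

    @property
    def n_evaluated(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    def to_json(self) -> str:
        payload = {
            "n_evaluated": self.n_evaluated,
            "n_excluded": self.n_excluded,
            "overall": self.overall.to_dict(),
            "fisher_p": self.fisher_p,
            "auc": None if self.roc is None else self.roc.auc,
            "optimal_cutoff": None if self.roc is None else self.roc.optimal_cutoff,
            "subgroups": {k: v.to_dict() for k, v in self.subgroups.items()},
            "top_pairs": self.top_pairs.to_dict(orient="records"),
            "exclusions": self.exclusions.to_dict(orient="records"),
            "records": [
                {
                    "patient": r.patient,
                    "regimen": sorted(r.regimen),
                    "predicted_ncv": r.predicted_ncv,
                    "predicted_label": r.predicted_label,
                    "clinical_label": r.clinical_label,
                    **dict(r.tags),
                }
                for r in self.records
            ],
        }
        return json.dumps(payload, indent=1, default=float)


def evaluate_cohort(
    reports: Sequence[PatientReport],
    clinical: pd.DataFrame,
    panel: DrugPanel,
    cutoff: float = conc.NCV_CUTOFF,
    top_n: int = TOP_N,
) -> ConcordanceReport:
    """Match clinical records to passing reports and evaluate concordance.

    ``clinical`` needs columns patient, regimen (semicolon-separated drug
    names) and clinical_response (CR/CRi/PR/NR); optional subgroup columns
    status (ND/RR) and eln_risk.  Patients whose run failed QC, whose
    regimen falls outside the panel, or who lack an outcome are excluded
    and logged, never silently dropped; patients_in = evaluated + excluded.
    """
    by_patient = {r.patient: r for r in reports}
    records: list[conc.ConcordanceRecord] = []
    excluded: list[tuple[str, str]] = []
    for _, row in clinical.iterrows():
        pid = str(row["patient"])
        report = by_patient.get(pid)
        if report is None:
            excluded.append((pid, "no matching run"))
            continue
        if report.status != "ok":
            excluded.append((pid, "qc_failed"))
            continue
        raw = row.get("clinical_response")
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            excluded.append((pid, "missing outcome"))
            continue
        regimen = frozenset(d.strip() for d in str(row["regimen"]).split(";") if d.strip())
        if not regimen <= set(panel.drugs):
            excluded.append((pid, "regimen outside panel"))
            continue
        tags = {
            key: str(row[key])
            for key in ("status", "eln_risk")
            if key in clinical.columns and pd.notna(row[key])
        }
        records.append(
            conc.ConcordanceRecord(
                patient=pid,
                regimen=regimen,
                predicted_ncv=predict_regimen_ncv(report.model, regimen),
                clinical_label=str(raw),
                tags=tags,
                cutoff=cutoff,
            )
        )

    overall = conc.confusion_summary(records)
    subgroups: dict[str, conc.ConfusionSummary] = {}
    for key in ("status", "eln_risk"):
        values = {r.tags.get(key) for r in records} - {None}
        for value in sorted(values):  # type: ignore[type-var]
            subset = [r for r in records if r.tags.get(key) == value]
            subgroups[f"{key}={value}"] = conc.confusion_summary(subset)

    fisher_p = (
        conc.fisher_exact_2x2(overall.as_table()) if overall.n >= 1 else float("nan")
    )
    responses = [r.clinical_response for r in records]
    roc = None
    if any(responses) and not all(responses):
        roc = conc.roc_analysis([r.predicted_ncv for r in records], responses)
    rankings = [by_patient[r.patient].ranking for r in records]
    top_pairs = conc.top_pair_frequency(rankings, top_n=top_n)
    exclusions = pd.DataFrame(excluded, columns=["patient", "reason"])
    assert len(records) + len(exclusions) == len(clinical)
    return ConcordanceReport(
        records=tuple(records),
        overall=overall,
        subgroups=subgroups,
        fisher_p=fisher_p,
        roc=roc,
        top_pairs=top_pairs,
        exclusions=exclusions,
    )
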