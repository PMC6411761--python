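"""End-to-end validation pipeline: reliability, validity, responsiveness.

``run_validation`` takes either recorded data (responses + metadata CSVs)
or a simulation configuration, scores every sheet, and produces a
:class:`ValidationReport` holding

* per-score test-retest ICCs on the control group,
* Cronbach's alpha of the 24 owner-questionnaire items at T0,
* the ROC block discriminating control dogs from surgical dogs at T0,
* the Spearman correlation matrix of scores at T0 with qualitative bands,
* the longitudinal block (pairwise Wilcoxon tests, Kruskal-Wallis across
  age groups, median/IQR per timepoint),
* chi-squared comparisons of sex and affected limb between groups.

Every statistic is labelled with its method variant (ICC form, tie
handling, CI type) and analyses that are impossible on the given data
(too few subjects, zero variance) become per-analysis skip entries rather
than a global failure.  Given a seed the report is byte-identical across
runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SimulationConfig, SyntheticCohort, simulate_cohort
from .errors import ConfigurationError, DegenerateInputError
from .instrument import (
    InstrumentDefinition,
    ResponseSheet,
    load_default_instrument,
    score_table,
)
from .io import read_metadata, read_responses
from .reliability import cronbach_alpha, icc_test_retest
from .responsiveness import (
    age_group_tests,
    chi_square_independence,
    median_iqr_table,
    paired_timepoint_tests,
)
from .validity import roc_analysis, spearman_matrix

logger = logging.getLogger("bhsii")

SCORE_COLUMNS = ["P", "S", "F", "V", "M", "OQ", "CR", "total"]


@dataclass(frozen=True)
class RunConfig:
    """What to analyse and how.

    Exactly one of (``responses_path`` + ``metadata_path``) or
    ``simulation`` must be supplied.
    """

    responses_path: Optional[str] = None
    metadata_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    missing_policy: str = "strict"
    icc_form: str = "agreement"
    holm: bool = False
    seed: int = 0

    def validate(self) -> None:
        from_files = self.responses_path is not None
        if from_files != (self.metadata_path is not None):
            raise ConfigurationError(
                "responses_path and metadata_path must be supplied together"
            )
        if from_files == (self.simulation is not None):
            raise ConfigurationError(
                "supply exactly one of input paths or a simulation config"
            )


@dataclass
class ValidationReport:
    """Structured results of the full validation pipeline."""

    report: Dict

    @property
    def n_skipped(self) -> int:
        return len(self.report.get("skipped", []))

    @property
    def n_completed(self) -> int:
        return len(self.report.get("completed", []))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.report, indent=indent, sort_keys=True)


def _round(x: float, nd: int = 4) -> float:
    return float(np.round(x, nd))


def _sheet_item_matrix(
    sheets: Sequence[ResponseSheet], item_ids: Sequence[str]
) -> np.ndarray:
    return np.array(
        [[s.values.get(i, np.nan) for i in item_ids] for s in sheets], dtype=float
    )


def run_validation(
    config: RunConfig,
    instrument: Optional[InstrumentDefinition] = None,
) -> ValidationReport:
    """Run the complete validation pipeline and assemble the report."""
    config.validate()
    if instrument is None:
        instrument = load_default_instrument()

    if config.simulation is not None:
        sim = config.simulation.with_seed(config.seed)
        cohort = simulate_cohort(sim, instrument)
        metadata = cohort.metadata
        sheets = cohort.sheets
        source = {"kind": "simulation", "seed": config.seed}
    else:
        sheets = read_responses(config.responses_path, instrument)
        metadata = read_metadata(config.metadata_path)
        source = {
            "kind": "files",
            "responses": str(config.responses_path),
            "metadata": str(config.metadata_path),
        }
    logger.info("loaded %d sheets for %d subjects", len(sheets), len(metadata))

    scores = score_table(sheets, instrument, config.missing_policy)
    group_of = dict(zip(metadata["subject_id"], metadata["group"]))
    scores["group"] = scores["subject_id"].map(group_of)
    cg = scores[scores["group"] == "CG"]
    sg = scores[scores["group"] == "SG"]
    sg_t0 = sg[sg["timepoint"] == "T0"]

    completed: List[str] = []
    skipped: List[Dict[str, str]] = []

    def _skip(name: str, reason: str) -> None:
        skipped.append({"analysis": name, "reason": reason})
        logger.info("skipped %s: %s", name, reason)

    report: Dict = {
        "package_version": __version__,
        "source": source,
        "method_labels": {
            "icc": "two-way random effects ANOVA, single measure",
            "alpha": "Cronbach, unbiased variances",
            "roc": "empirical Mann-Whitney AUC, ties 1/2; Clopper-Pearson 95% CIs",
            "spearman": "midranks, two-sided t-approximation p; BMJ bands; "
                        "no multiple-testing correction across the matrix",
            "wilcoxon": "zero differences discarded, midrank ties, exact <= 15 "
                        "pairs else tie-corrected normal approximation, two-sided",
            "kruskal_wallis": "tie-corrected H, chi-squared p",
            "chi_squared": "Pearson, no continuity correction",
            "missing_policy": config.missing_policy,
        },
        "n_sheets": {"CG": int(len(cg)), "SG": int(len(sg))},
    }

    # ---- test-retest reliability (control group) ---------------------
    icc_block: Dict[str, Dict] = {}
    for col in SCORE_COLUMNS:
        name = f"icc[{col}]"
        try:
            tab = cg.pivot(index="subject_id", columns="timepoint", values=col)
            if "test" not in tab or "retest" not in tab:
                raise DegenerateInputError("control group lacks test/retest sheets")
            pair = tab[["test", "retest"]].dropna()
            res = icc_test_retest(pair["test"], pair["retest"], form=config.icc_form)
            icc_block[col] = {
                "icc": _round(res.icc_value),
                "model": res.model_label,
                "n_subjects": res.n_subjects,
                "ms_subjects": _round(res.ms_subjects, 6),
                "ms_administrations": _round(res.ms_administrations, 6),
                "ms_residual": _round(res.ms_residual, 6),
                "acceptable": bool(res.acceptable),
            }
            completed.append(name)
        except DegenerateInputError as exc:
            _skip(name, str(exc))
    report["reliability"] = {"icc": icc_block, "threshold": 0.7}

    # ---- internal consistency (OQ items at T0) -----------------------
    oq_item_ids = [
        i.item_id for i in instrument.items
        if instrument.domain(i.domain_code).section == "OQ"
    ]
    try:
        t0_sheets = [
            s for s in sheets
            if s.timepoint == "T0" and group_of.get(s.subject_id) == "SG"
        ]
        matrix = _sheet_item_matrix(t0_sheets, oq_item_ids)
        if matrix.size == 0:
            raise DegenerateInputError("no surgical T0 sheets")
        res_a = cronbach_alpha(matrix)
        report["reliability"]["cronbach_alpha"] = {
            "alpha": _round(res_a.alpha),
            "k_items": res_a.k,
            "n_subjects": len(t0_sheets),
            "section": "OQ",
            "acceptable": bool(res_a.acceptable),
        }
        completed.append("cronbach_alpha")
    except DegenerateInputError as exc:
        _skip("cronbach_alpha", str(exc))

    # ---- construct validity ------------------------------------------
    try:
        cg_totals = cg[cg["timepoint"] == "test"]["total"].dropna().to_numpy()
        sg_totals = sg_t0["total"].dropna().to_numpy()
        roc = roc_analysis(sg_totals, cg_totals)
        report["validity"] = {
            "roc": {
                "auc": _round(roc.auc),
                "threshold": _round(roc.threshold, 3),
                "sensitivity": _round(roc.sensitivity, 3),
                "specificity": _round(roc.specificity, 3),
                "sensitivity_ci95": [_round(v, 3) for v in roc.sensitivity_ci],
                "specificity_ci95": [_round(v, 3) for v in roc.specificity_ci],
                "n_diseased": roc.n_diseased,
                "n_healthy": roc.n_healthy,
                "separating_interval": (
                    None if roc.separating_interval is None
                    else [_round(v, 3) for v in roc.separating_interval]
                ),
                "acceptable_accuracy": bool(roc.acceptable_accuracy),
            }
        }
        completed.append("roc")
    except DegenerateInputError as exc:
        report["validity"] = {}
        _skip("roc", str(exc))

    try:
        matrix_cells = spearman_matrix(sg_t0[SCORE_COLUMNS])
        report["validity"]["spearman_t0"] = {
            a: {
                b: (
                    None if cell is None else {
                        "r_s": _round(cell.r_s),
                        "p_value": float(f"{cell.p_value:.3e}"),
                        "band": cell.band,
                        "significant": bool(cell.significant),
                    }
                )
                for b, cell in row.items()
            }
            for a, row in matrix_cells.items()
        }
        completed.append("spearman_t0")
    except DegenerateInputError as exc:
        _skip("spearman_t0", str(exc))

    # ---- responsiveness ----------------------------------------------
    timepoints = ("T0", "T1", "T3", "T6")
    try:
        if sg.empty:
            raise DegenerateInputError("no surgical sheets")
        wilcoxon = paired_timepoint_tests(sg, SCORE_COLUMNS, timepoints, holm=config.holm)
        medians = median_iqr_table(
            sg, SCORE_COLUMNS,
            timepoints=[t for t in timepoints if (sg["timepoint"] == t).any()],
        )
        resp: Dict = {
            "wilcoxon": wilcoxon.round(6).to_dict(orient="records"),
            "median_iqr": medians.round(4).to_dict(orient="records"),
        }
        if "age_group" in metadata.columns and metadata["age_group"].astype(bool).any():
            kw = age_group_tests(sg, metadata, SCORE_COLUMNS, timepoints)
            resp["kruskal_wallis_age_groups"] = kw.round(6).to_dict(orient="records")
        report["responsiveness"] = resp
        completed.append("responsiveness")
    except DegenerateInputError as exc:
        _skip("responsiveness", str(exc))

    # ---- demographics -------------------------------------------------
    demo: Dict = {}
    for var in ("sex", "limb"):
        if var not in metadata.columns:
            continue
        try:
            table = pd.crosstab(metadata["group"], metadata[var]).to_numpy()
            stat, df, p = chi_square_independence(table)
            demo[f"{var}_by_group"] = {
                "statistic": _round(stat),
                "df": df,
                "p_value": _round(p, 6),
            }
            completed.append(f"chi2_{var}")
        except DegenerateInputError as exc:
            _skip(f"chi2_{var}", str(exc))
    if demo:
        report["demographics"] = demo

    report["completed"] = sorted(completed)
    report["skipped"] = skipped
    logger.info(
        "validation finished: %d analyses completed, %d skipped",
        len(completed), len(skipped),
    )
    return ValidationReport(report=report)
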