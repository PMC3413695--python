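"""End-to-end analysis driver: cohort → ΔCt → statistics → ROC → panels → report.

Mirrors the analysis flow of a marker-panel diagnostic study: quantify
relative expression, compare groups, correlate markers within groups,
derive per-marker ROC cutoffs (or take fixed ones), then evaluate every
configured combination rule — single markers, 1/2/3-of-3 gene votes,
dichotomized cytology, and cytology OR 2-of-3 — as a binary classifier
with full 2×2 performance and confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from . import io_tables, metrics, panel, qpcr, roc
from .cohort import CohortSpec, default_cohort_spec, generate_cohort
from .io_tables import CtRecord, Cytology, Group, percent_field
from .metrics import DiagnosticPerformance
from .panel import PanelRule
from .qpcr import DeltaCtMatrix

__all__ = ["RunConfig", "standard_rules", "run", "performance_to_dict"]

logger = logging.getLogger("brushdx")

#: The diagnostic trio carried into combination analysis.
CORE_MARKERS = ["HOXB7", "IGF2BP3", "NEK2"]


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Exactly one input source: ``input_path`` (a Ct CSV) or a synthetic
    ``cohort_spec`` (``None`` for both means the packaged defaults).
    ``fixed_cutoffs`` maps marker → ΔCt cutoff; when ``None``, cutoffs
    are derived per marker by ROC/Youden (requires truth labels).
    """

    input_path: str | None = None
    cohort_spec: CohortSpec | None = None
    reference: str = "GAPDH"
    markers: Sequence[str] = field(default_factory=lambda: list(CORE_MARKERS))
    fixed_cutoffs: Mapping[str, float] | None = None
    ci_method: str = "wilson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_path is not None and self.cohort_spec is not None:
            raise ValueError("give either an input path or a cohort spec, not both")
        if self.fixed_cutoffs is not None:
            missing = set(self.markers) - set(self.fixed_cutoffs)
            if missing:
                raise ValueError(f"fixed cutoffs missing for markers {sorted(missing)}")


def standard_rules(cutoffs: Mapping[str, float]) -> list[PanelRule]:
    """The study's rule set: cytology read-outs, single markers, gene votes,
    and the cytology-OR-(2-of-3) combination."""
    markers = list(cutoffs)
    rules = [
        PanelRule(cytology_mode="M_only", name="cytology_M"),
        PanelRule(cytology_mode="S_and_M", name="cytology_SM"),
    ]
    for marker in markers:
        rules.append(
            PanelRule(
                marker_cutoffs={marker: cutoffs[marker]},
                combination="any_one",
                name=f"single_{marker}",
            )
        )
    n = len(markers)
    for m in range(1, n + 1):
        rules.append(
            PanelRule(
                marker_cutoffs=dict(cutoffs),
                combination="m_of_n",
                m=m,
                name=f"{m}_of_{n}",
            )
        )
    rules.append(
        PanelRule(
            marker_cutoffs=dict(cutoffs),
            combination="m_of_n",
            m=min(2, n),
            cytology_mode="S_and_M",
            cytology_combination="or_with_panel",
            name=f"cytology_or_2_of_{n}",
        )
    )
    return rules


def _num(x: float) -> float | None:
    return None if (isinstance(x, float) and math.isnan(x)) else float(x)


def performance_to_dict(perf: DiagnosticPerformance) -> dict[str, Any]:
    cm = perf.cm
    out: dict[str, Any] = {
        "counts": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "prevalence": _num(perf.prevalence),
        "ci_method": perf.ci_method,
    }
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        est = getattr(perf, name)
        entry = percent_field(_num(est.value))
        entry["k"] = est.k
        entry["n"] = est.n
        entry["ci95"] = [_num(est.ci95[0]), _num(est.ci95[1])]
        out[name] = entry
    return out


def _load_records(config: RunConfig) -> tuple[list[CtRecord], str]:
    if config.input_path is not None:
        logger.info("loading Ct table from %s", config.input_path)
        return (
            io_tables.read_ct_table(config.input_path, reference=config.reference),
            f"file:{config.input_path}",
        )
    spec = config.cohort_spec or default_cohort_spec()
    spec = spec.with_seed(config.seed)
    logger.info(
        "simulating cohort: %d malignant / %d benign, seed %d",
        spec.n_malignant, spec.n_benign, spec.seed,
    )
    return generate_cohort(spec), f"synthetic:seed={spec.seed}"


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the structured report.

    Stages: load/simulate → ΔCt normalization → group comparison
    (means/SDs/medians/ΔΔCt/fold/Welch test) → within-group Spearman
    matrices → per-marker ROC with Youden cutoffs (or fixed cutoffs) →
    panel classification under every standard rule → performance tables.
    Deterministic for a given config and seed.
    """
    records, source = _load_records(config)
    matrix = qpcr.compute_delta_ct(records, reference=config.reference)
    logger.info("ΔCt computed for %d patients (%d rejected)",
                matrix.n_patients, len(matrix.rejected))
    markers = [m for m in config.markers if m in matrix.markers]
    if set(markers) != set(config.markers):
        raise ValueError(
            f"markers {sorted(set(config.markers) - set(markers))} absent from input"
        )

    comparison = qpcr.group_comparison(matrix)
    correlations: dict[str, Any] = {}
    for grp in (Group.MALIGNANT, Group.BENIGN):
        try:
            correlations[grp.value] = qpcr.spearman_matrix(matrix, grp)
        except ValueError as exc:  # e.g. group too small for rank correlation
            logger.warning("Spearman skipped for %s: %s", grp.value, exc)
            correlations[grp.value] = str(exc)

    truth = np.array([g == Group.MALIGNANT for g in matrix.groups])
    roc_results: dict[str, roc.RocResult] = {}
    for marker in markers:
        j = matrix.marker_index(marker)
        ok = ~np.isnan(matrix.dct[:, j])
        roc_results[marker] = roc.analyze_marker(
            marker, matrix.dct[ok, j], truth[ok], "lower_is_positive"
        )
        logger.info("ROC %s: AUC %.3f, cutoff %.2f", marker,
                    roc_results[marker].auc, roc_results[marker].optimal_cutoff)

    if config.fixed_cutoffs is not None:
        cutoffs = {m: float(config.fixed_cutoffs[m]) for m in markers}
    else:
        cutoffs = {m: roc_results[m].optimal_cutoff for m in markers}

    cytology = {r.patient_id: r.cytology for r in records}
    rules_report: dict[str, Any] = {}
    for rule in standard_rules(cutoffs):
        calls = panel.apply_rule(matrix, cytology, rule)
        cm, excluded = metrics.confusion(
            [c.final_call for c in calls],
            [matrix.groups[matrix.patient_ids.index(c.patient_id)] for c in calls],
        )
        perf = metrics.performance(cm, ci_method=config.ci_method)
        entry = performance_to_dict(perf)
        entry["rule"] = rule.to_dict()
        entry["n_excluded_unknown_truth"] = len(excluded)
        entry["n_flagged_missing_markers"] = sum(1 for c in calls if c.missing_markers)
        rules_report[rule.name] = entry
        logger.info("rule %-22s sens %s spec %s", rule.name,
                    entry["sensitivity"]["display"], entry["specificity"]["display"])

    report: dict[str, Any] = {
        "source": source,
        "seed": config.seed,
        "reference_gene": config.reference,
        "markers": markers,
        "cutoff_source": "fixed" if config.fixed_cutoffs is not None else "derive_by_roc",
        "n_patients": matrix.n_patients,
        "n_rejected": len(matrix.rejected),
        "rejected": [list(r) for r in matrix.rejected],
        "group_comparison": {
            marker: {k: _num(v) if isinstance(v, float) else int(v)
                     for k, v in row.items()}
            for marker, row in comparison.to_dict(orient="index").items()
        },
        "spearman": {
            grp: c if isinstance(c, str) else {
                "rho": {a: {b: _num(c.rho.loc[a, b]) for b in c.rho.columns}
                        for a in c.rho.index},
                "p_value": {a: {b: _num(c.p_value.loc[a, b]) for b in c.p_value.columns}
                            for a in c.p_value.index},
                "undefined": [list(u) for u in c.undefined],
            }
            for grp, c in correlations.items()
        },
        "roc": {
            marker: {
                "auc": _num(res.auc),
                "auc_se": _num(res.auc_se),
                "auc_ci95": [_num(res.auc_ci95[0]), _num(res.auc_ci95[1])],
                "optimal_cutoff": _num(res.optimal_cutoff),
                "sens_at_cutoff": percent_field(res.sens_at_cutoff),
                "spec_at_cutoff": percent_field(res.spec_at_cutoff),
                "useless_marker": res.useless_marker,
            }
            for marker, res in roc_results.items()
        },
        "cutoffs": {m: _num(c) for m, c in cutoffs.items()},
        "rules": rules_report,
    }
    return report
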