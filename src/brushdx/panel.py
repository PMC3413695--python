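"""Boolean multi-marker panel rules, with optional cytology integration.

A panel rule fixes a ΔCt cutoff per marker (positive means
ΔCt ≤ cutoff, inclusive — over-expression in malignancy), a Boolean
combination over the markers (any-one / all / m-of-n voting), and how
routine cytology enters: either not at all, counting only outright
malignant read-outs as positive (``M_only``), or counting suspicious
plus malignant (``S_and_M``).  When cytology is combined with the gene
panel it does so as a logical OR.

Handling of indeterminate inputs keeps the cohort denominators fixed:
atypical, inadequate and missing cytology count as test-negative, and a
missing marker value counts as marker-negative while flagging the
patient (an ``exclude`` policy is available instead).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Mapping

import numpy as np
import yaml

from .io_tables import Cytology
from .qpcr import DeltaCtMatrix

__all__ = [
    "PanelRule",
    "PatientCall",
    "classify_marker",
    "classify_cytology",
    "classify_panel",
    "apply_rule",
]

CytologyMode = Literal["none", "M_only", "S_and_M"]
Combination = Literal["any_one", "all", "m_of_n"]

CYTOLOGY_POSITIVE_SETS: dict[str, frozenset[Cytology]] = {
    "M_only": frozenset({Cytology.POSITIVE}),
    "S_and_M": frozenset({Cytology.POSITIVE, Cytology.SUSPICIOUS}),
}


@dataclass(frozen=True)
class PanelRule:
    """A binary classifier built from marker cutoffs and a combination rule.

    ``m`` is required for (and only for) ``m_of_n`` combination.  A rule
    with no markers (``marker_cutoffs={}``, combination ``none``) is a
    pure-cytology rule.
    """

    marker_cutoffs: Mapping[str, float] = field(default_factory=dict)
    combination: Combination | Literal["none"] = "none"
    m: int | None = None
    cytology_mode: CytologyMode = "none"
    cytology_combination: Literal["none", "or_with_panel"] = "none"
    missing_policy: Literal["negative", "exclude"] = "negative"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_cutoffs", dict(self.marker_cutoffs))
        if self.combination == "m_of_n":
            if self.m is None or not 1 <= self.m <= len(self.marker_cutoffs):
                raise ValueError(
                    f"m_of_n requires 1 <= m <= {len(self.marker_cutoffs)}, got {self.m}"
                )
        elif self.m is not None:
            raise ValueError("m is only meaningful for m_of_n combination")
        if self.combination == "none" and self.marker_cutoffs:
            raise ValueError("marker cutoffs given but no combination rule")
        if self.combination != "none" and not self.marker_cutoffs:
            raise ValueError(f"combination {self.combination!r} needs markers")
        if self.cytology_combination == "or_with_panel" and self.cytology_mode == "none":
            raise ValueError("or_with_panel requires a cytology mode")
        if self.combination == "none" and self.cytology_mode == "none":
            raise ValueError("rule classifies nothing")

    @property
    def markers(self) -> list[str]:
        return list(self.marker_cutoffs)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "marker_cutoffs": dict(self.marker_cutoffs),
            "combination": self.combination,
            "m": self.m,
            "cytology_mode": self.cytology_mode,
            "cytology_combination": self.cytology_combination,
            "missing_policy": self.missing_policy,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PanelRule":
        return cls(
            marker_cutoffs=d.get("marker_cutoffs", {}),
            combination=d.get("combination", "none"),
            m=d.get("m"),
            cytology_mode=d.get("cytology_mode", "none"),
            cytology_combination=d.get("cytology_combination", "none"),
            missing_policy=d.get("missing_policy", "negative"),
            name=d.get("name", ""),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PanelRule":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


@dataclass
class PatientCall:
    """Per-patient classification trace under one rule."""

    patient_id: str
    marker_positives: dict[str, bool | None]
    cytology_positive: bool | None
    final_call: bool
    missing_markers: list[str] = field(default_factory=list)


def classify_marker(dct: float, cutoff: float) -> bool:
    """Marker positive iff ΔCt ≤ cutoff (inclusive).

    Censored ΔCt values are legitimate inputs: they sit high on the ΔCt
    scale (low expression) and classify negative for any realistic
    cutoff.
    """
    if math.isnan(dct):
        raise ValueError("missing ΔCt has no positivity; handle via classify_panel")
    return dct <= cutoff


def classify_cytology(category: Cytology | str, mode: str) -> bool:
    """Dichotomize the five-category cytology read-out.

    ``M_only``: positive iff outright malignant; ``S_and_M``: suspicious
    also counts as positive.  Atypical, negative, inadequate and missing
    are all test-negative.
    """
    try:
        positives = CYTOLOGY_POSITIVE_SETS[mode]
    except KeyError:
        raise ValueError(f"unknown cytology mode {mode!r}") from None
    return Cytology(category) in positives


def classify_panel(
    marker_positives: Mapping[str, bool | None],
    cytology_positive: bool | None,
    rule: PanelRule,
) -> bool:
    """Evaluate the Boolean combination for one patient.

    ``None`` marker positivity (missing measurement) counts as negative
    under the default policy.  Raises if the rule references a marker
    absent from the patient's calls.
    """
    panel_positive = False
    if rule.combination != "none":
        calls: list[bool] = []
        for marker in rule.markers:
            if marker not in marker_positives:
                raise ValueError(f"rule references marker {marker!r} missing from calls")
            calls.append(bool(marker_positives[marker]))
        k = sum(calls)
        if rule.combination == "any_one":
            panel_positive = k >= 1
        elif rule.combination == "all":
            panel_positive = k == len(calls)
        else:  # m_of_n
            panel_positive = k >= int(rule.m)  # type: ignore[arg-type]

    if rule.cytology_mode == "none":
        return panel_positive
    cyto = bool(cytology_positive)
    if rule.combination == "none":
        return cyto
    if rule.cytology_combination == "or_with_panel":
        return cyto or panel_positive
    return panel_positive


def apply_rule(
    matrix: DeltaCtMatrix,
    cytology: Mapping[str, Cytology | str],
    rule: PanelRule,
) -> list[PatientCall]:
    """Classify every patient in a ΔCt matrix under one rule.

    ``cytology`` maps patient_id → category (only consulted when the
    rule uses cytology; absent entries count as missing).  Under the
    ``exclude`` missing policy, patients lacking any rule marker are
    dropped from the output.
    """
    for marker in rule.markers:
        if marker not in matrix.markers:
            raise ValueError(f"rule references marker {marker!r} not in matrix")
    calls: list[PatientCall] = []
    for i, pid in enumerate(matrix.patient_ids):
        marker_pos: dict[str, bool | None] = {}
        missing: list[str] = []
        for marker in rule.markers:
            val = matrix.dct[i, matrix.marker_index(marker)]
            if np.isnan(val):
                marker_pos[marker] = None
                missing.append(marker)
            else:
                marker_pos[marker] = classify_marker(float(val), rule.marker_cutoffs[marker])
        if missing and rule.missing_policy == "exclude":
            continue
        cyto_pos: bool | None = None
        if rule.cytology_mode != "none":
            category = Cytology(cytology.get(pid, Cytology.MISSING))
            cyto_pos = classify_cytology(category, rule.cytology_mode)
        final = classify_panel(marker_pos, cyto_pos, rule)
        calls.append(PatientCall(pid, marker_pos, cyto_pos, final, missing))
    return calls
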