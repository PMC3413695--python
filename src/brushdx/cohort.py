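"""Seeded synthetic cohorts with the study's statistical structure.

The generator emulates a two-group (malignant / benign biliary
stricture) brush-cytology cohort at the patient level: per group it
draws marker ΔCt values from normal marginals coupled through a
Gaussian copula calibrated to target Spearman rank correlations, draws
a reference-gene (GAPDH) Ct per patient, reconstructs target Ct values
as reference + ΔCt (censoring at the 40-cycle limit), and draws a
routine-cytology category from a per-group categorical distribution,
independent of the marker values.

The copula calibration uses the exact Gaussian-rank relation
ρ_linear = 2·sin(π·ρ_spearman/6), so the generated data hit the target
Spearman values in expectation.  Seeding is hierarchical: every
(group, variable) pair gets its own deterministic substream derived
from the master seed, so adding a marker never perturbs the draws of
existing ones.

The packaged :func:`default_cohort_spec` carries the study-calibrated
parameter set (group sizes 72/47, reported ΔCt moments, within-group
Spearman matrices, cytology category frequencies).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .io_tables import MAX_CYCLES, CtRecord, CtValue, Cytology, Group
from .qpcr import compute_delta_ct, spearman_matrix

__all__ = [
    "CohortSpec",
    "default_cohort_spec",
    "spearman_to_linear",
    "generate_cohort",
    "recover_parameters",
]

CYTOLOGY_ORDER = [
    Cytology.POSITIVE,
    Cytology.SUSPICIOUS,
    Cytology.ATYPICAL,
    Cytology.NEGATIVE,
    Cytology.INADEQUATE,
]

_GROUPS = (Group.MALIGNANT, Group.BENIGN)


@dataclass
class CohortSpec:
    """Complete parameterization of a synthetic two-group cohort.

    ``dct_mean``/``dct_sd`` map group → marker → cycles;
    ``spearman`` maps group → markers × markers rank-correlation matrix
    (aligned with ``markers``); ``cytology_probs`` maps group →
    category → probability (summing to 1 per group).
    """

    n_malignant: int
    n_benign: int
    markers: list[str]
    dct_mean: dict[Group, dict[str, float]]
    dct_sd: dict[Group, dict[str, float]]
    spearman: dict[Group, np.ndarray]
    cytology_probs: dict[Group, dict[Cytology, float]]
    reference_ct_mean: float = 18.0
    reference_ct_sd: float = 1.5
    reference_gene: str = "GAPDH"
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.markers)
        for grp in _GROUPS:
            for marker in self.markers:
                if self.dct_sd[grp][marker] < 0:
                    raise ValueError(f"negative SD for {marker} in {grp.value}")
            r = np.asarray(self.spearman[grp], dtype=float)
            if r.shape != (k, k):
                raise ValueError(f"{grp.value} correlation matrix must be {k}x{k}")
            if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
                raise ValueError(f"{grp.value} correlation matrix not symmetric/unit-diagonal")
            if np.abs(r).max() > 1:
                raise ValueError("|spearman rho| must not exceed 1")
            self.spearman[grp] = r
            total = sum(self.cytology_probs[grp].values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{grp.value} cytology probabilities sum to {total}, not 1")
        if self.reference_ct_sd < 0:
            raise ValueError("reference Ct SD must be non-negative")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def spearman_to_linear(rho_s: float) -> float:
    """Gaussian-copula conversion: the linear (Pearson) correlation of the
    latent bivariate normal whose Spearman correlation equals ``rho_s``,
    i.e. 2·sin(π·ρ_s/6)."""
    if abs(rho_s) > 1:
        raise ValueError(f"|rho_s| must be <= 1, got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The packaged study-calibrated parameter set (see the bundled YAML)."""
    with resources.files("brushdx.data").joinpath("default_cohort.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    markers: list[str] = list(raw["markers"])
    k = len(markers)
    dct_mean: dict[Group, dict[str, float]] = {}
    dct_sd: dict[Group, dict[str, float]] = {}
    spearman: dict[Group, np.ndarray] = {}
    cyto: dict[Group, dict[Cytology, float]] = {}
    for grp in _GROUPS:
        moments = raw["dct_moments"][grp.value]
        dct_mean[grp] = {m: float(moments[m]["mean"]) for m in markers}
        dct_sd[grp] = {m: float(moments[m]["sd"]) for m in markers}
        r = np.eye(k)
        for a, b, rho in raw["spearman"][grp.value]:
            i, j = markers.index(a), markers.index(b)
            r[i, j] = r[j, i] = float(rho)
        spearman[grp] = r
        counts = raw["cytology_counts"][grp.value]
        total = sum(counts.values())
        cyto[grp] = {c: counts.get(c.value, 0) / total for c in CYTOLOGY_ORDER}
    return CohortSpec(
        n_malignant=int(raw["n_malignant"]),
        n_benign=int(raw["n_benign"]),
        markers=markers,
        dct_mean=dct_mean,
        dct_sd=dct_sd,
        spearman=spearman,
        cytology_probs=cyto,
        reference_ct_mean=float(raw["reference_ct"]["mean"]),
        reference_ct_sd=float(raw["reference_ct"]["sd"]),
        seed=seed,
    )


def _stream(seed: int, group: Group, label: str) -> np.random.Generator:
    # stable per-(group, variable) substream: adding markers never
    # perturbs existing draws
    key = zlib.crc32(f"{group.value}/{label}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def _copula_cholesky(spearman: np.ndarray, repair: bool) -> np.ndarray:
    linear = np.array(
        [[spearman_to_linear(float(r)) for r in row] for row in spearman]
    )
    np.fill_diagonal(linear, 1.0)
    try:
        return np.linalg.cholesky(linear)
    except np.linalg.LinAlgError:
        if not repair:
            raise ValueError(
                "converted correlation matrix is not positive semidefinite; "
                "pass repair=True to project onto the nearest PSD matrix"
            ) from None
        w, v = np.linalg.eigh(linear)
        w = np.clip(w, 1e-10, None)
        fixed = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        return np.linalg.cholesky(fixed)


def generate_cohort(spec: CohortSpec, repair: bool = False) -> list[CtRecord]:
    """Draw a full synthetic cohort of :class:`CtRecord` patients.

    Deterministic given ``spec.seed``.  Target Ct values exceeding the
    40-cycle limit are censored at 40 (their read-back ΔCt becomes
    40 − reference Ct, flagged).
    """
    records: list[CtRecord] = []
    k = len(spec.markers)
    for grp, n, prefix in (
        (Group.MALIGNANT, spec.n_malignant, "M"),
        (Group.BENIGN, spec.n_benign, "B"),
    ):
        chol = _copula_cholesky(spec.spearman[grp], repair)
        # one iid standard-normal column per marker, from its own stream
        z = np.column_stack(
            [_stream(spec.seed, grp, f"marker/{m}").standard_normal(n) for m in spec.markers]
        ) if k else np.empty((n, 0))
        latent = z @ chol.T
        means = np.array([spec.dct_mean[grp][m] for m in spec.markers])
        sds = np.array([spec.dct_sd[grp][m] for m in spec.markers])
        dct = means + sds * latent
        ref = spec.reference_ct_mean + spec.reference_ct_sd * _stream(
            spec.seed, grp, "reference"
        ).standard_normal(n)
        probs = np.array([spec.cytology_probs[grp][c] for c in CYTOLOGY_ORDER])
        cyto_idx = _stream(spec.seed, grp, "cytology").choice(
            len(CYTOLOGY_ORDER), size=n, p=probs / probs.sum()
        )
        for i in range(n):
            ct: dict[str, CtValue] = {spec.reference_gene: CtValue(float(ref[i]))}
            for j, marker in enumerate(spec.markers):
                target = ref[i] + dct[i, j]
                if target > MAX_CYCLES:
                    ct[marker] = CtValue(MAX_CYCLES, censored=True)
                else:
                    ct[marker] = CtValue(float(target))
            records.append(
                CtRecord(
                    patient_id=f"{prefix}{i + 1:04d}",
                    group=grp,
                    cytology=CYTOLOGY_ORDER[cyto_idx[i]],
                    ct=ct,
                )
            )
    return records


def recover_parameters(records: list[CtRecord], reference: str = "GAPDH") -> CohortSpec:
    """Re-estimate the generating parameters from a cohort (round-trip check).

    Moments use uncensored ΔCt values; Spearman matrices include
    censored values at their censored ΔCt; cytology probabilities are
    the observed category frequencies.  Raises if either group is
    absent.
    """
    matrix = compute_delta_ct(records, reference=reference)
    dct_mean: dict[Group, dict[str, float]] = {}
    dct_sd: dict[Group, dict[str, float]] = {}
    spearman: dict[Group, np.ndarray] = {}
    cyto: dict[Group, dict[Cytology, float]] = {}
    counts = {grp: 0 for grp in _GROUPS}
    for grp in _GROUPS:
        n = int(matrix.group_mask(grp).sum())
        if n == 0:
            raise ValueError(f"group {grp.value!r} absent from cohort")
        counts[grp] = n
        dct_mean[grp] = {}
        dct_sd[grp] = {}
        for marker in matrix.markers:
            vals = matrix.column(marker, grp, drop_censored=True)
            dct_mean[grp][marker] = float(np.mean(vals))
            dct_sd[grp][marker] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        corr = spearman_matrix(matrix, grp)
        rho = corr.rho.to_numpy(dtype=float)
        rho = np.where(np.isnan(rho), 0.0, rho)
        np.fill_diagonal(rho, 1.0)
        spearman[grp] = rho
        members = [r for r in records if r.group == grp]
        cyto[grp] = {
            c: sum(1 for r in members if r.cytology == c) / n for c in CYTOLOGY_ORDER
        }
    ref_cts = [r.ct[reference].value for r in records if not r.ct[reference].is_missing]
    return CohortSpec(
        n_malignant=counts[Group.MALIGNANT],
        n_benign=counts[Group.BENIGN],
        markers=list(matrix.markers),
        dct_mean=dct_mean,
        dct_sd=dct_sd,
        spearman=spearman,
        cytology_probs=cyto,
        reference_ct_mean=float(np.mean(ref_cts)),
        reference_ct_sd=float(np.std(ref_cts, ddof=1)) if len(ref_cts) > 1 else 0.0,
        reference_gene=reference,
    )
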