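"""ΔCt normalization, ΔΔCt fold-change estimation and group statistics.

Relative expression is quantified on the threshold-cycle scale:
ΔCt = Ct(target) − Ct(reference gene), so one cycle corresponds to a
two-fold difference in template abundance and *lower* ΔCt means *higher*
expression.  Group-level over-expression is summarized as
ΔΔCt = median ΔCt(benign) − median ΔCt(malignant) with fold change
2^ΔΔCt, oriented so that fold change > 1 means over-expression in the
malignant group.

Censoring policy: a target that never amplified within the 40-cycle
protocol carries ΔCt = 40 − Ct(reference) with a censored flag.  Such
values are rank-meaningful (censoring means undetectably low expression,
i.e. high ΔCt) and therefore participate in medians and Spearman ranks
at their censored value, but are excluded from means, SDs and t-tests,
where they would bias moment estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CtRecord, Group

__all__ = [
    "DeltaCtMatrix",
    "CorrelationMatrix",
    "compute_delta_ct",
    "compute_ddct",
    "group_t_test",
    "group_comparison",
    "spearman_matrix",
]


@dataclass
class DeltaCtMatrix:
    """Patients × markers ΔCt values (cycles) with group labels.

    ``dct[i, j]`` is Ct(marker j) − Ct(reference) for patient i; NaN
    marks a missing measurement and ``censored[i, j]`` flags values
    derived from a censored target Ct.  The marker list never contains
    the reference gene.  ``rejected`` lists ``(patient_id, reason)`` for
    records that could not be normalized.
    """

    patient_ids: list[str]
    groups: np.ndarray  # dtype object, Group per patient
    markers: list[str]
    dct: np.ndarray  # float (n, m), NaN = missing
    censored: np.ndarray  # bool (n, m)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in matrix") from None

    def group_mask(self, group: Group | str) -> np.ndarray:
        group = Group(group)
        return np.array([g == group for g in self.groups], dtype=bool)

    def column(self, marker: str, group: Group | str | None = None,
               drop_missing: bool = True, drop_censored: bool = False) -> np.ndarray:
        """ΔCt values for one marker, optionally restricted to a group."""
        j = self.marker_index(marker)
        mask = np.ones(self.n_patients, dtype=bool)
        if group is not None:
            mask &= self.group_mask(group)
        values = self.dct[mask, j]
        cens = self.censored[mask, j]
        keep = np.ones(values.shape, dtype=bool)
        if drop_missing:
            keep &= ~np.isnan(values)
        if drop_censored:
            keep &= ~cens
        return values[keep]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dct, columns=self.markers)
        df.insert(0, "patient_id", self.patient_ids)
        df.insert(1, "group", [g.value for g in self.groups])
        return df


def compute_delta_ct(records: Iterable[CtRecord], reference: str = "GAPDH") -> DeltaCtMatrix:
    """Normalize target Ct values by the reference gene: ΔCt = Ct_target − Ct_ref.

    Records whose reference-gene Ct is missing or censored cannot be
    normalized and are rejected with a reason (listed in ``rejected``).
    Censored targets yield ΔCt = 40 − Ct_ref with the censored flag
    propagated; missing targets propagate missing (NaN).
    """
    records = list(records)
    markers: list[str] = []
    for rec in records:
        for g in rec.ct:
            if g != reference and g not in markers:
                markers.append(g)

    ids: list[str] = []
    groups: list[Group] = []
    rows: list[list[float]] = []
    cens_rows: list[list[bool]] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        ref = rec.ct.get(reference)
        if ref is None or ref.is_missing:
            rejected.append((rec.patient_id, "reference Ct missing"))
            continue
        if ref.censored:
            rejected.append((rec.patient_id, "reference Ct censored"))
            continue
        row: list[float] = []
        cens: list[bool] = []
        for marker in markers:
            cv = rec.ct.get(marker)
            if cv is None or cv.is_missing:
                row.append(np.nan)
                cens.append(False)
            else:
                row.append(cv.value - ref.value)
                cens.append(cv.censored)
        ids.append(rec.patient_id)
        groups.append(rec.group)
        rows.append(row)
        cens_rows.append(cens)

    n, m = len(ids), len(markers)
    return DeltaCtMatrix(
        patient_ids=ids,
        groups=np.array(groups, dtype=object),
        markers=markers,
        dct=np.array(rows, dtype=float).reshape(n, m),
        censored=np.array(cens_rows, dtype=bool).reshape(n, m),
        rejected=rejected,
    )


def compute_ddct(matrix: DeltaCtMatrix, marker: str) -> tuple[float, float]:
    """Group ΔΔCt and fold change for one marker.

    ΔΔCt = median ΔCt(benign) − median ΔCt(malignant); fold change is
    2^ΔΔCt, so values above 1 mean over-expression in malignancy.
    Medians use the midpoint convention for even n and include censored
    values at their censored ΔCt.
    """
    mal = matrix.column(marker, Group.MALIGNANT)
    ben = matrix.column(marker, Group.BENIGN)
    for name, vals in (("malignant", mal), ("benign", ben)):
        if vals.size == 0:
            raise ValueError(f"group {name!r} has no ΔCt values for {marker}")
    ddct = float(np.median(ben) - np.median(mal))
    return ddct, float(2.0 ** ddct)


def group_t_test(matrix: DeltaCtMatrix, marker: str) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test of malignant vs benign ΔCt.

    Censored values are excluded (moment-based statistic).  Requires at
    least two uncensored values per group.
    """
    mal = matrix.column(marker, Group.MALIGNANT, drop_censored=True)
    ben = matrix.column(marker, Group.BENIGN, drop_censored=True)
    for name, vals in (("malignant", mal), ("benign", ben)):
        if vals.size < 2:
            raise ValueError(
                f"group {name!r} has n={vals.size} < 2 uncensored values for {marker}"
            )
    res = stats.ttest_ind(mal, ben, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def group_comparison(matrix: DeltaCtMatrix) -> pd.DataFrame:
    """Per-marker group summary: moments, medians, ΔΔCt, fold change, Welch test.

    Means/SDs use uncensored values only; medians include censored
    values.  Returns a DataFrame indexed by marker.
    """
    rows = []
    for marker in matrix.markers:
        mal_u = matrix.column(marker, Group.MALIGNANT, drop_censored=True)
        ben_u = matrix.column(marker, Group.BENIGN, drop_censored=True)
        mal = matrix.column(marker, Group.MALIGNANT)
        ben = matrix.column(marker, Group.BENIGN)
        ddct, fold = compute_ddct(matrix, marker)
        t, p = group_t_test(matrix, marker)
        rows.append({
            "marker": marker,
            "n_malignant": mal.size,
            "n_benign": ben.size,
            "mean_malignant": float(np.mean(mal_u)),
            "sd_malignant": float(np.std(mal_u, ddof=1)),
            "mean_benign": float(np.mean(ben_u)),
            "sd_benign": float(np.std(ben_u, ddof=1)),
            "median_malignant": float(np.median(mal)),
            "median_benign": float(np.median(ben)),
            "ddct": ddct,
            "fold_change": fold,
            "t_statistic": t,
            "p_value": p,
        })
    return pd.DataFrame(rows).set_index("marker")


@dataclass
class CorrelationMatrix:
    """Markers × markers Spearman rank correlations with two-sided p-values."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n: pd.DataFrame
    undefined: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        r = self.rho.to_numpy(dtype=float)
        finite = np.isfinite(r)
        if not np.allclose(r[finite], r.T[finite.T]):
            raise ValueError("Spearman matrix must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")


def spearman_matrix(matrix: DeltaCtMatrix, group: Group | str) -> CorrelationMatrix:
    """Pairwise Spearman rank correlations between markers within one group.

    Average-rank tie handling; two-sided p-values via the t
    approximation.  Censored ΔCt values keep their (rank-meaningful)
    censored value; missing values are dropped pairwise.  A constant
    column makes rho undefined for its pairs, which are reported in
    ``undefined`` with the reason and returned as NaN.
    """
    markers = matrix.markers
    k = len(markers)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    undefined: list[tuple[str, str, str]] = []
    mask = matrix.group_mask(group)
    if mask.sum() < 3:
        raise ValueError(f"group {Group(group).value!r} has n < 3")
    sub = matrix.dct[mask]
    for i in range(k):
        rho[i, i] = 1.0
        nmat[i, i] = int(np.sum(~np.isnan(sub[:, i])))
        for j in range(i + 1, k):
            pair = sub[:, [i, j]]
            ok = ~np.isnan(pair).any(axis=1)
            x, y = pair[ok, 0], pair[ok, 1]
            nmat[i, j] = nmat[j, i] = int(ok.sum())
            if ok.sum() < 3:
                undefined.append((markers[i], markers[j], "fewer than 3 complete pairs"))
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                undefined.append((markers[i], markers[j], "constant marker column"))
                continue
            r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = float(r)
            pval[i, j] = pval[j, i] = float(p)
    idx = pd.Index(markers, name="marker")
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_value=pd.DataFrame(pval, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
        undefined=undefined,
    )
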