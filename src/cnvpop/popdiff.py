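"""Population differentiation of copy number: V_ST and the t-test scan.

V_ST is the copy-number analogue of F_ST: for a locus with pooled CN
variance V_T and sample-size-weighted mean within-population variance
V_S, ``V_ST = (V_T - V_S) / V_T``. Loci in the top tail of V_ST whose CN
distributions also differ by a Student's t-test are flagged as
population-differentiated — the dual criterion used for both the
domestication (wild vs domestic) and the altitude (high vs low) contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    """A population with fewer than two samples cannot contribute a variance."""


@dataclass
class VstResult:
    cnvr_id: str
    v_t: float
    v_s: float
    v_st: float
    defined: bool  # False when V_T = 0 (no CN variance at the locus)
    t_p: float = float("nan")
    selected: bool = False


def vst(cn_a: np.ndarray, cn_b: np.ndarray, cnvr_id: str = "", ddof: int = 0) -> VstResult:
    """V_ST between two CN vectors.

    Variances are population variances (``ddof=0``) by default, the form
    under which the sample-size weighting of V_S is stated; ``ddof=1``
    gives the sample-variance variant. ``V_T = 0`` leaves V_ST undefined
    (reported as 0 and flagged).
    """
    cn_a = np.asarray(cn_a, dtype=float)
    cn_b = np.asarray(cn_b, dtype=float)
    if cn_a.size < 2 or cn_b.size < 2:
        raise InsufficientDataError(
            f"need >= 2 samples per population, got {cn_a.size} and {cn_b.size}"
        )
    n_a, n_b = cn_a.size, cn_b.size
    v_t = float(np.var(np.concatenate([cn_a, cn_b]), ddof=ddof))
    v_s = float(
        (n_a * np.var(cn_a, ddof=ddof) + n_b * np.var(cn_b, ddof=ddof)) / (n_a + n_b)
    )
    if v_t == 0.0:
        return VstResult(cnvr_id=cnvr_id, v_t=0.0, v_s=v_s, v_st=0.0, defined=False)
    return VstResult(cnvr_id=cnvr_id, v_t=v_t, v_s=v_s, v_st=(v_t - v_s) / v_t, defined=True)


def cn_ttest(cn_a: np.ndarray, cn_b: np.ndarray, welch: bool = False) -> float:
    """Two-sided two-sample t-test p on CN vectors (pooled by default).

    Degenerate loci (zero pooled variance) return p = 1 for equal means
    and p = 0 otherwise, so fixed between-group differences are never
    discarded by an undefined statistic.
    """
    cn_a = np.asarray(cn_a, dtype=float)
    cn_b = np.asarray(cn_b, dtype=float)
    if cn_a.size < 2 or cn_b.size < 2:
        raise InsufficientDataError("need >= 2 samples per population")
    if np.ptp(cn_a) == 0.0 and np.ptp(cn_b) == 0.0:
        return 1.0 if cn_a[0] == cn_b[0] else 0.0
    p = stats.ttest_ind(cn_a, cn_b, equal_var=not welch).pvalue
    return float(p)


def select_differentiated(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    top_frac: float = 0.05,
    alpha: float = 0.05,
    welch: bool = False,
    ddof: int = 0,
) -> list[VstResult]:
    """Scan a CN matrix for population-differentiated CNVRs.

    ``assignment`` maps each matrix column to one of exactly two group
    labels. A row is selected when its V_ST reaches the ``1 - top_frac``
    quantile of all *defined* V_ST values (linear interpolation; ties at
    the threshold included) and its t-test p < ``alpha``. Undefined rows
    are never selected.
    """
    groups = assignment.reindex(matrix.columns)
    if groups.isna().any():
        missing = list(matrix.columns[groups.isna()])
        raise KeyError(f"samples without population assignment: {missing}")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {labels}")
    cols_a = matrix.columns[groups == labels[0]]
    cols_b = matrix.columns[groups == labels[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise InsufficientDataError("need >= 2 samples per population")
    results: list[VstResult] = []
    for cnvr_id, row in matrix.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        res = vst(a, b, cnvr_id=str(cnvr_id), ddof=ddof)
        res.t_p = cn_ttest(a, b, welch=welch)
        results.append(res)
    defined = [r.v_st for r in results if r.defined]
    if defined:
        threshold = float(np.quantile(defined, 1.0 - top_frac))
        for r in results:
            r.selected = r.defined and r.v_st >= threshold and r.t_p < alpha
    return results


def results_frame(results: list[VstResult]) -> pd.DataFrame:
    """VstResults as a ranked DataFrame (descending V_ST)."""
    df = pd.DataFrame(
        {
            "cnvr_id": [r.cnvr_id for r in results],
            "v_t": [r.v_t for r in results],
            "v_s": [r.v_s for r in results],
            "v_st": [r.v_st for r in results],
            "defined": [r.defined for r in results],
            "t_p": [r.t_p for r in results],
            "selected": [r.selected for r in results],
        }
    )
    return df.sort_values("v_st", ascending=False, ignore_index=True)
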