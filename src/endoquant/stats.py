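"""Statistical layer: t-based summaries, t-tests, and two-stage FDR.

Implements exactly the inference used downstream of the imaging and BRET
pipelines:

* ``mean_ci95`` — mean with a two-sided Student-t 95% confidence half-width,
  the form reported for per-vesicle density ratios (mean ± 95% CI);
* ``unpaired_t`` — classical two-sample t-test, pooled variance by default
  (Welch available via ``equal_var=False``);
* ``paired_t_fdr`` — per-pair two-sided paired t-tests followed by the
  two-stage linear step-up false-discovery-rate procedure of Benjamini,
  Krieger and Yekutieli (BKY), at a nominal FDR of 1% by default.

The BKY procedure is implemented directly (not through a generic
multiple-testing wrapper): stage one applies the linear step-up procedure
at level q' = q/(1+q) to estimate the number of true nulls m0 = m - r1;
stage two re-applies it at level q'·m/m0.  The p-value arithmetic of the
t-tests is written out explicitly so each routine can be cross-checked
against an independent reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, PairingError, ParameterError

__all__ = [
    "TestResult",
    "FdrDecision",
    "mean_ci95",
    "median",
    "unpaired_t",
    "paired_t",
    "paired_t_fdr",
    "bky_two_stage",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    test_kind: str


@dataclass
class FdrDecision:
    p_values: np.ndarray
    q: float
    rejected: np.ndarray
    method: str = "BKY two-stage"

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def _clean(values, name="values") -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} must be non-empty and finite")
    return arr


def mean_ci95(values) -> tuple[float, float]:
    """Mean and two-sided 95% t-confidence half-width.

    halfwidth = t(0.975, n-1) * sd / sqrt(n).  Requires n >= 2.
    """
    arr = _clean(values)
    n = arr.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 values for a 95% CI, got {n}")
    m = float(arr.mean())
    sd = float(arr.std(ddof=1))
    hw = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return m, hw


def median(values) -> float:
    return float(np.median(_clean(values)))


def unpaired_t(a, b, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test (pooled variance unless ``equal_var=False``)."""
    a = _clean(a, "a")
    b = _clean(b, "b")
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InsufficientDataError(f"each sample needs n >= 2, got {na} and {nb}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0 and a.mean() == b.mean():
        # identical degenerate samples: no evidence of a difference
        df = na + nb - 2 if equal_var else na + nb - 2
        return TestResult(0.0, 1.0, float(df), "unpaired t (pooled)" if equal_var else "Welch t")
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0.0:
            raise InsufficientDataError("both samples are constant; t is undefined")
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        kind = "unpaired t (pooled)"
    else:
        se2a, se2b = va / na, vb / nb
        se = np.sqrt(se2a + se2b)
        if se == 0.0:
            raise InsufficientDataError("both samples are constant; t is undefined")
        df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
        kind = "Welch t"
    t = (a.mean() - b.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), float(df), kind)


def paired_t(treated, control) -> TestResult:
    """Two-sided paired t-test on matched replicate vectors."""
    treated = _clean(treated, "treated")
    control = _clean(control, "control")
    if treated.size != control.size:
        raise PairingError(
            f"treated and control must be matched, got lengths {treated.size} and {control.size}"
        )
    n = treated.size
    if n < 2:
        raise InsufficientDataError(f"paired t needs n >= 2 matched replicates, got {n}")
    d = treated - control
    sd = d.std(ddof=1)
    if sd == 0.0:
        p = 1.0 if d.mean() == 0.0 else 0.0
        return TestResult(0.0 if d.mean() == 0.0 else np.inf, p, float(n - 1), "paired t")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(min(p, 1.0)), float(n - 1), "paired t")


def _step_up(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear step-up (BH) procedure at ``level``."""
    m = p_sorted.size
    thresh = level * (np.arange(1, m + 1) / m)
    passing = np.nonzero(p_sorted <= thresh)[0]
    return int(passing[-1] + 1) if passing.size else 0


def bky_two_stage(p_values, q: float = 0.01) -> FdrDecision:
    """Two-stage linear step-up FDR procedure (Benjamini–Krieger–Yekutieli).

    Stage 1: linear step-up at q' = q/(1+q); r1 rejections.  If r1 = 0,
    reject nothing; if r1 = m, reject everything.  Otherwise stage 2:
    linear step-up at q'·m/(m−r1).  The rejected set is a step-up set by
    construction (all p-values below the largest rejected one are rejected).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ParameterError("p_values must be non-empty")
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ParameterError("p_values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ParameterError(f"q must lie in (0, 1), got {q}")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    m = p.size
    q1 = q / (1.0 + q)
    r1 = _step_up(p_sorted, q1)
    if r1 == 0:
        k = 0
    elif r1 == m:
        k = m
    else:
        q2 = q1 * m / (m - r1)
        k = _step_up(p_sorted, q2)
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return FdrDecision(p_values=p, q=q, rejected=rejected)


def paired_t_fdr(pairs, q: float = 0.01) -> tuple[list[TestResult], FdrDecision]:
    """Paired t-tests over (treated, control) replicate pairs with BKY FDR.

    ``pairs`` is a sequence of (treated, control) matched replicate vectors.
    Returns the per-pair test results and the joint FDR decision at level
    ``q`` (default 1%).
    """
    if len(pairs) == 0:
        raise ParameterError("pairs must be non-empty")
    results = [paired_t(t, c) for t, c in pairs]
    decision = bky_two_stage([r.p_value for r in results], q=q)
    return results, decision
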