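"""Bidirectional Granger-causality scans between audience and stage series.

A predictor x "Granger causes" a response y if lagged values of x improve
the prediction of y beyond what lagged values of y alone achieve. The
test is a nested-OLS F test at a single lag order L:

* restricted:   y_t ~ 1 + y_{t-1..t-L}
* unrestricted: y_t ~ 1 + y_{t-1..t-L} + x_{t-1..t-L}

    F = ((RSS_r - RSS_u) / L) / (RSS_u / (T - 2L - 1))

with df1 = L and df2 = T - 2L - 1, where T is the length of the aligned
(differenced) series; the first L rows are trimmed before fitting. Series
are first-differenced before testing to remove trends; scans run both
directions over lags 1..9 s at 1 Hz, reported per lag without
multiple-testing correction (a Bonferroni column is included as a
clearly-labeled extra). Matched versus deliberately mismatched
audience/stage pairings serve as a specificity control: couplings that
survive random mismatching are not performance-specific.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tsa.stattools import adfuller

from .flow import InputError, MotionSeries

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG = 9  # samples (= seconds at 1 Hz)
DEFAULT_ALPHA = 0.05


class DegenerateModelError(ValueError):
    """Raised when the unrestricted model fits the response perfectly."""


def _values(series) -> np.ndarray:
    if isinstance(series, MotionSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def difference_series(series):
    """First difference: out_t = in_{t+1} - in_t (length n - 1).

    Motion series must be gap-free; a NaN anywhere is an error instructing
    the caller to window the series rather than silently imputing.
    """
    x = _values(series)
    if x.ndim != 1 or len(x) < 2:
        raise InputError("differencing needs a 1-D series of length >= 2")
    if not np.isfinite(x).all():
        raise InputError(
            "series contains missing samples; extract a gap-free window "
            "before differencing"
        )
    return np.diff(x)


@dataclasses.dataclass
class GCResult:
    """One directional Granger test at one lag order."""

    direction: str  # "x->y" | "y->x"
    lag: int  # samples (seconds at 1 Hz)
    F: float
    df1: int
    df2: int
    p: float


def _lag_matrix(z: np.ndarray, lag: int) -> np.ndarray:
    """Columns z_{t-1}, ..., z_{t-lag} for t = lag..T-1."""
    return np.column_stack([z[lag - k : len(z) - k] for k in range(1, lag + 1)])


def gc_test(x, y, lag: int) -> GCResult:
    """Does x Granger-cause y at lag order ``lag``?

    Both models are fitted by OLS on the T - lag rows that have a full
    lag history; the F statistic and its reference distribution use
    df2 = T - 2*lag - 1, the package's (and the field's common) counting
    of the denominator degrees of freedom against the aligned series
    length T. Inputs must be stationary (differenced) already.
    """
    xv, yv = _values(x), _values(y)
    if len(xv) != len(yv):
        raise InputError("series lengths differ")
    T = len(yv)
    if lag < 1:
        raise InputError("lag must be >= 1")
    if not T > 3 * lag + 10:
        raise InputError(f"series too short (T={T}) for lag {lag}")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise InputError(
            "missing samples in the analysis window; extract a gap-free "
            "window first"
        )
    resp = yv[lag:]
    ylags = _lag_matrix(yv, lag)
    xlags = _lag_matrix(xv, lag)
    X_r = sm.add_constant(ylags, has_constant="add")
    X_u = sm.add_constant(np.column_stack([ylags, xlags]), has_constant="add")
    if np.linalg.matrix_rank(X_u) < X_u.shape[1]:
        raise InputError("perfectly collinear regressors in the GC design")
    rss_r = sm.OLS(resp, X_r).fit().ssr
    rss_u = sm.OLS(resp, X_u).fit().ssr
    if rss_u <= 0:
        raise DegenerateModelError("unrestricted model has zero residual sum")
    df1 = lag
    df2 = T - 2 * lag - 1
    F = ((rss_r - rss_u) / df1) / (rss_u / df2)
    F = max(F, 0.0)
    p = float(scipy.stats.f.sf(F, df1, df2))
    return GCResult(direction="x->y", lag=lag, F=float(F), df1=df1, df2=df2, p=p)


def stationarity_diagnostic(series) -> float:
    """Augmented Dickey-Fuller p-value, logged for information only.

    Differencing is the package's sole stationarity treatment; this
    diagnostic never gates a test.
    """
    p = float(adfuller(_values(series), autolag="AIC")[1])
    logger.info("ADF stationarity diagnostic: p = %.4f", p)
    return p


@dataclasses.dataclass
class ScanReport:
    """Both-direction GC results over lags 1..max_lag for one series pair."""

    part: str
    x_label: str  # audience series label
    y_label: str  # stage/dancer series label
    results: list[GCResult]
    pairing: str = "matched"  # "matched" | "mismatched"
    alpha: float = DEFAULT_ALPHA

    def to_frame(self) -> pd.DataFrame:
        n_tests = len(self.results)
        rows = []
        for r in self.results:
            rows.append(
                {
                    "part": self.part,
                    "pairing": self.pairing,
                    "direction": (
                        f"{self.x_label}->{self.y_label}"
                        if r.direction == "x->y"
                        else f"{self.y_label}->{self.x_label}"
                    ),
                    "lag_s": r.lag,
                    "F": r.F,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p": r.p,
                    f"significant_{self.alpha:g}": r.p <= self.alpha,
                    # Extra, clearly labeled: Bonferroni over this scan.
                    "p_bonferroni": min(1.0, r.p * n_tests),
                }
            )
        return pd.DataFrame(rows)

    @property
    def n_significant(self) -> int:
        return sum(r.p <= self.alpha for r in self.results)


def gc_scan(
    audience,
    dancers,
    max_lag: int = DEFAULT_MAX_LAG,
    *,
    part: str = "part",
    alpha: float = DEFAULT_ALPHA,
    pairing: str = "matched",
) -> ScanReport:
    """Scan both directions at every lag 1..max_lag.

    ``audience -> dancers`` results carry direction ``x->y``; the reverse
    carry ``y->x``. Results are reported per lag with no multiple-testing
    correction, flagged at p <= alpha.
    """
    if max_lag < 1:
        raise InputError("max_lag must be >= 1")
    a, d = _values(audience), _values(dancers)
    results = []
    for lag in range(1, max_lag + 1):
        try:
            fwd = gc_test(a, d, lag)
            rev = gc_test(d, a, lag)
        except (InputError, DegenerateModelError) as exc:
            raise type(exc)(f"lag {lag}: {exc}") from exc
        results.append(fwd)
        results.append(dataclasses.replace(rev, direction="y->x"))
    return ScanReport(
        part=part, x_label="audience", y_label="dancers",
        results=results, pairing=pairing, alpha=alpha,
    )


def _derangement(labels: list[str], rng: np.random.Generator) -> dict[str, str]:
    """A seeded permutation with no fixed point; unique swap for 2 labels."""
    if len(labels) == 2:
        return {labels[0]: labels[1], labels[1]: labels[0]}
    while True:
        perm = rng.permutation(len(labels))
        if not np.any(perm == np.arange(len(labels))):
            return {labels[i]: labels[perm[i]] for i in range(len(labels))}


def mismatch_control(
    audience: Mapping[str, Sequence[float]],
    dancers: Mapping[str, Sequence[float]],
    seed: int,
    max_lag: int = DEFAULT_MAX_LAG,
    *,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[ScanReport], list[ScanReport], pd.DataFrame]:
    """Matched and randomly mismatched GC scans over performance parts.

    ``audience`` and ``dancers`` map part labels to (differenced,
    gap-free) series. Matched scans pair equal labels; mismatched scans
    pair each audience part with a deranged dancer part (seeded), after
    truncating each pair to its common length. Returns the two report
    lists and a per-part summary of significant-lag counts.
    """
    labels = sorted(audience)
    if sorted(dancers) != labels:
        raise InputError("audience and dancer part labels differ")
    if len(labels) < 2:
        raise InputError("mismatch control needs >= 2 parts (no derangement)")
    rng = np.random.default_rng(seed)
    mapping = _derangement(labels, rng)

    def _scan(a_label: str, d_label: str, pairing: str) -> ScanReport:
        a = _values(audience[a_label])
        d = _values(dancers[d_label])
        n = min(len(a), len(d))
        return gc_scan(
            a[:n], d[:n], max_lag,
            part=a_label, alpha=alpha, pairing=pairing,
        )

    matched = [_scan(lbl, lbl, "matched") for lbl in labels]
    mismatched = [_scan(lbl, mapping[lbl], "mismatched") for lbl in labels]
    rows = []
    for rep_m, rep_x in zip(matched, mismatched):
        rows.append(
            {
                "part": rep_m.part,
                "mismatched_with": mapping[rep_m.part],
                "n_tests": len(rep_m.results),
                "significant_matched": rep_m.n_significant,
                "significant_mismatched": rep_x.n_significant,
            }
        )
    return matched, mismatched, pd.DataFrame(rows)
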