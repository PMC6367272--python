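"""Engagement statistics: clip selection, mixed models, exact Spearman.

The engagement analysis asks whether audiences look more or less engaged
while they move. Short clips are cut at the extremes (most and least
moving) of the upper-body movement series, rated by participants on a
0-10 engagement scale, and the ratings are modeled with a linear mixed
model: movement state and connection-to-dance as fixed factors,
participant and yearly attendance as random factors, with a
likelihood-ratio chi-square (maximum-likelihood nested fits) for the
movement-state effect. At the whole-performance scale, the link between
average audience movement and preference ranking across four performance
parts is a Spearman rank correlation whose p-value, at n = 4, must come
from full enumeration of all 4! rank permutations.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .flow import InputError, MotionSeries

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 10.0  # clip length; the source design says only "short"
DEFAULT_K_PER_POLARITY = 3  # 3 max + 3 min = 6 clips per part

MAX_EXACT_N = 8  # 8! = 40320 permutations


# ---------------------------------------------------------------------------
# Movement-extreme clip selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClipWindow:
    """One selected clip window within a performance part."""

    part: str
    start: float  # seconds
    duration: float  # seconds
    polarity: str  # "max" | "min"
    mean_movement: float  # px/s at 1 Hz


def select_extreme_windows(
    series: MotionSeries,
    k_per_polarity: int = DEFAULT_K_PER_POLARITY,
    window: float = DEFAULT_WINDOW_S,
    *,
    part: str = "part",
) -> list[ClipWindow]:
    """Greedy selection of the k most- and k least-moving windows.

    Windows are ``window`` seconds long on the series' sample grid,
    pairwise non-overlapping (max and min windows jointly). Selection is
    greedy by window mean; ties break toward the earliest start.
    """
    w = int(round(window * series.rate))
    if w < 1:
        raise InputError("window shorter than one sample")
    n = len(series.values)
    if n < 2 * k_per_polarity * w:
        raise InputError(
            f"series of {n} samples cannot hold {2 * k_per_polarity} "
            f"disjoint windows of {w} samples"
        )
    values = np.nan_to_num(series.values, nan=0.0)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    means = (csum[w:] - csum[:-w]) / w  # mean of window starting at i
    taken = np.zeros(n, dtype=bool)
    out: list[ClipWindow] = []

    def _pick(polarity: str) -> None:
        for _ in range(k_per_polarity):
            best_i, best_v = None, None
            for i in range(n - w + 1):
                if taken[i : i + w].any():
                    continue
                v = means[i]
                better = (
                    best_i is None
                    or (v > best_v if polarity == "max" else v < best_v)
                )
                if better:
                    best_i, best_v = i, v
            if best_i is None:
                raise InputError("ran out of non-overlapping windows")
            taken[best_i : best_i + w] = True
            out.append(
                ClipWindow(
                    part=part,
                    start=series.t0 + best_i / series.rate,
                    duration=w / series.rate,
                    polarity=polarity,
                    mean_movement=float(best_v),
                )
            )

    _pick("max")
    _pick("min")
    return out


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    df: float
    t: float


@dataclasses.dataclass
class ModelReport:
    """Fitted mixed-model summary with an LRT for the factor of interest.

    ``random_structure`` names the random factors the final fit retained;
    singular fits are reduced (with a warning) rather than reported with
    degenerate variance components.
    """

    fixed_effects: list[FixedEffect]
    lrt_factor: str
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    random_structure: str
    n_obs: int

    def effect(self, prefix: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name.startswith(prefix):
                return fe
        raise KeyError(prefix)


def _fit_ml(formula: str, data: pd.DataFrame, random_terms: dict[str, str]):
    """One ML MixedLM fit.

    A single random factor uses the native grouping route (its variance is
    profiled efficiently and the optimizer is reliable there); two or more
    factors are fitted as crossed variance components within one trivial
    group. Several optimizers are tried because the variance-component
    likelihood surface is flat near zero variances. Returns None if no
    optimizer converges to a finite likelihood.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(random_terms) == 1:
                (column,) = random_terms.values()
                model = smf.mixedlm(formula, data, groups=data[column])
            else:
                vc = {
                    name: f"0 + C({col})" for name, col in random_terms.items()
                }
                model = smf.mixedlm(
                    formula, data, groups=np.ones(len(data)),
                    vc_formula=vc, re_formula="0",
                )
            best = None
            for method in ("bfgs", "lbfgs", "cg"):
                try:
                    fit = model.fit(reml=False, method=method, maxiter=500)
                except Exception:
                    continue
                if np.isfinite(fit.llf) and (best is None or fit.llf > best.llf):
                    best = fit
            return best
    except Exception:
        return None


def _fit_ols(formula: str, data: pd.DataFrame):
    return smf.ols(formula, data).fit()


def _mixed_lrt(
    data: pd.DataFrame,
    response: str,
    focus_term: str,
    other_fixed: list[str],
    random_terms: dict[str, str],
) -> ModelReport:
    """ML fit of the full model and LRT against the model without the
    focus term, reducing the random structure if the full fit is singular."""
    fixed = " + ".join([focus_term] + other_fixed) if other_fixed else focus_term
    full_f = f"{response} ~ {fixed}"
    null_fixed = " + ".join(other_fixed) if other_fixed else "1"
    null_f = f"{response} ~ {null_fixed}"

    attempts: list[tuple[str, dict[str, str] | None]] = [
        ("+".join(random_terms), random_terms)
    ]
    if len(random_terms) > 1:
        first = dict(list(random_terms.items())[:1])
        attempts.append(("+".join(first), first))
    attempts.append(("none (OLS)", None))

    for structure, terms in attempts:
        if terms is None:
            full = _fit_ols(full_f, data)
            null = _fit_ols(null_f, data)
            warnings.warn(
                "singular random-effects fit; reporting fixed-effects-only "
                "(OLS) model",
                stacklevel=3,
            )
        else:
            full = _fit_ml(full_f, data, terms)
            null = _fit_ml(null_f, data, terms)
            if full is None or null is None:
                continue
            if not np.isfinite(full.llf - null.llf):
                continue
            # The nested model can never have the higher ML likelihood; a
            # visibly negative difference marks a failed optimization.
            if 2.0 * (full.llf - null.llf) < -1e-6:
                continue
            if structure != attempts[0][0]:
                warnings.warn(
                    f"singular random-effects fit; reduced to: {structure}",
                    stacklevel=3,
                )
        chi2 = max(0.0, 2.0 * (full.llf - null.llf))
        focus_levels = sum(
            1 for name in full.params.index if name.startswith(_term_prefix(focus_term))
        )
        lrt_df = max(1, focus_levels)
        p = float(scipy.stats.chi2.sf(chi2, lrt_df))
        resid_df = full.df_resid if hasattr(full, "df_resid") else np.nan
        fes = []
        bse = full.bse
        tvals = full.tvalues
        for name in full.params.index:
            if name == "Group Var" or name.endswith(" Var"):
                continue
            fes.append(
                FixedEffect(
                    name=name,
                    estimate=float(full.params[name]),
                    se=float(bse[name]),
                    df=float(resid_df),
                    t=float(tvals[name]),
                )
            )
        return ModelReport(
            fixed_effects=fes,
            lrt_factor=focus_term,
            lrt_chi2=float(chi2),
            lrt_df=lrt_df,
            lrt_p=p,
            random_structure=structure,
            n_obs=len(data),
        )
    raise RuntimeError("all model fits failed")  # pragma: no cover


def _term_prefix(term: str) -> str:
    # "C(movement_state)" -> "C(movement_state)[", plain names unchanged.
    return term + "[" if term.startswith("C(") else term


def engagement_model(ratings: pd.DataFrame) -> ModelReport:
    """Mixed model of engagement ratings on movement state.

    Fixed factors: movement state (moving vs non-moving) and connection
    to dance (performer vs non-performer). Random factors: participant
    and yearly attendance (0-4), as crossed random intercepts. The
    headline statistic is the likelihood-ratio chi-square for movement
    state from ML-fitted nested models.
    """
    required = {
        "participant_id", "movement_state", "engagement",
        "dance_connection", "attendance",
    }
    missing = required - set(ratings.columns)
    if missing:
        raise InputError(f"ratings table missing columns: {sorted(missing)}")
    if ratings["participant_id"].nunique() < 2:
        raise InputError("need >= 2 participants")
    if ratings["movement_state"].nunique() < 2:
        raise InputError("both movement states must be present")
    return _mixed_lrt(
        ratings,
        response="engagement",
        focus_term="C(movement_state)",
        other_fixed=["C(dance_connection)"],
        random_terms={
            "participant": "participant_id",
            "attendance": "attendance",
        },
    )


def state_model(data: pd.DataFrame, *, response: str = "value") -> ModelReport:
    """Mixed model of any per-person sampled response on a two-level state.

    Expects columns ``person_id``, ``state`` and the response (default
    ``value``; e.g. movement, or ingested facial-expression percentages
    with state = performance vs non-performance). State is the fixed
    factor; person is a random intercept.
    """
    for col in ("person_id", "state", response):
        if col not in data.columns:
            raise InputError(f"missing column {col!r}")
    if data["person_id"].nunique() < 2:
        raise InputError("random factor needs >= 2 persons")
    if data["state"].nunique() < 2:
        raise InputError("both states must be present")
    return _mixed_lrt(
        data,
        response=response,
        focus_term="C(state)",
        other_fixed=[],
        random_terms={"person": "person_id"},
    )


# ---------------------------------------------------------------------------
# Exact small-n Spearman
# ---------------------------------------------------------------------------

def spearman_exact(a, b) -> tuple[float, float]:
    """Spearman rho with an exact permutation p-value for n <= 8.

    rho = 1 - 6 * sum(d^2) / (n (n^2 - 1)) on the ranks; the two-sided
    p-value doubles the exact one-sided tail probability (share of the
    n! rank permutations at least as extreme as observed, in the observed
    direction), capped at 1. Ties are midranked with a warning that the
    exact tail assumes distinct ranks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("inputs must be equal-length 1-D")
    n = len(a)
    if n < 3:
        raise InputError("need n >= 3")
    if n > MAX_EXACT_N:
        raise InputError(
            f"n = {n} > {MAX_EXACT_N}: use an approximate method "
            "(scipy.stats.spearmanr) for larger samples"
        )
    if len(np.unique(a)) < n or len(np.unique(b)) < n:
        warnings.warn(
            "ties present: midranks used; the exact p-value assumes no ties",
            stacklevel=2,
        )
    ra = scipy.stats.rankdata(a)
    rb = scipy.stats.rankdata(b)

    def _rho(r1: np.ndarray, r2: np.ndarray) -> float:
        d2 = float(((r1 - r2) ** 2).sum())
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))

    rho = _rho(ra, rb)
    tol = 1e-12
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(rb):
        r = _rho(ra, np.array(perm))
        if rho >= 0:
            count += r >= rho - tol
        else:
            count += r <= rho + tol
    p = min(1.0, 2.0 * count / total)
    return float(rho), float(p)
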