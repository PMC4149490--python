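"""Percent-positive matrix assembly and screening statistics.

The screen's central product is a sample x antigen matrix of
percent-positive values.  On top of it this module implements:

* the 1% nominal-detection-limit filter (an antigen is "detected" when at
  least 1% of gated cells stain);
* the dual-criterion treatment-lability classifier - an antigen counts as
  altered by a preparation step when the absolute change is at least 5
  percentage points AND the fold change (bidirectional max/min ratio,
  denominators clamped at the detection limit) is at least 2;
* replicate reproducibility as the Spearman rank correlation of two runs'
  profiles;
* differential candidate-marker ranking (high in a pure reference
  population, low in the comparison fraction).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Antibody, PanelPlateMap

__all__ = [
    "ScreenCriteria",
    "assemble_matrix",
    "detectability_filter",
    "classify_treatment_effect",
    "screen_treatment",
    "screen_summary",
    "replicate_reproducibility",
    "rank_candidates",
]

CATEGORIES = ("undetected", "unaffected", "abs_only", "fold_only", "both")


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the screen's fixed-criterion classifier."""

    detection_limit_percent: float = 1.0
    min_absolute_delta_percent: float = 5.0
    min_fold_change: float = 2.0
    fold_floor_percent: float | None = None  # defaults to the detection limit

    def __post_init__(self) -> None:
        if self.detection_limit_percent <= 0 or self.min_absolute_delta_percent <= 0:
            raise ValueError("criteria must be strictly positive")
        if self.min_fold_change <= 1:
            raise ValueError("min_fold_change must be > 1")

    @property
    def floor(self) -> float:
        return (
            self.fold_floor_percent
            if self.fold_floor_percent is not None
            else self.detection_limit_percent
        )


def assemble_matrix(
    summaries: Iterable[Mapping],
    pmap: PanelPlateMap,
) -> pd.DataFrame:
    """Join per-well gate summaries into a sample x antigen percent matrix.

    Each summary needs ``sample_id``, ``plate``, ``well``,
    ``percent_positive`` and ``qc_pass``; wells failing QC become missing
    (NaN), not zero, so imputation can handle them downstream.  Column
    order follows the plate map; duplicate sample/antigen measurements
    are an error.
    """
    antigen_of = {
        k: e.antigen_name for k, e in pmap.wells.items() if isinstance(e, Antibody)
    }
    cells: dict[tuple[str, str], float] = {}
    samples: list[str] = []
    for s in summaries:
        key = (s["plate"], s["well"])
        if key not in antigen_of:
            continue  # control or unmapped wells carry no antigen measurement
        antigen = antigen_of[key]
        sample = s["sample_id"]
        if sample not in samples:
            samples.append(sample)
        if (sample, antigen) in cells:
            raise ValueError(f"antigen {antigen!r} measured twice for sample {sample!r}")
        cells[(sample, antigen)] = (
            float(s["percent_positive"]) if s.get("qc_pass", True) else np.nan
        )
    antigens = pmap.antigens
    mat = pd.DataFrame(
        [[cells.get((smp, ag), np.nan) for ag in antigens] for smp in samples],
        index=pd.Index(samples, name="sample"),
        columns=antigens,
    )
    return mat


def detectability_filter(
    profile: pd.Series, criteria: ScreenCriteria = ScreenCriteria()
) -> set[str]:
    """Antigens expressed at or above the nominal detection limit (inclusive).

    Missing values count as undetected.
    """
    if profile.empty:
        raise ValueError("profile is empty")
    detected = profile[profile >= criteria.detection_limit_percent]
    return set(detected.index)


def classify_treatment_effect(
    untreated: float,
    treated: float,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> dict:
    """Classify one antigen's response to a preparation step.

    Fold change is the bidirectional ratio max/min of the two values after
    clamping each from below at the detection limit, so losses and gains
    are treated symmetrically and sub-detection values cannot blow up the
    ratio.  Category: ``undetected`` (both below the limit), ``both``
    (delta and fold criteria met), ``abs_only``, ``fold_only``, or
    ``unaffected``.
    """
    if untreated is None or treated is None or math.isnan(untreated) or math.isnan(treated):
        return {
            "untreated_percent": untreated,
            "treated_percent": treated,
            "absolute_delta": np.nan,
            "fold_change": np.nan,
            "direction": 0,
            "category": "missing",
        }
    delta = abs(treated - untreated)
    u = max(untreated, criteria.floor)
    t = max(treated, criteria.floor)
    fold = max(u, t) / min(u, t)
    abs_hit = delta >= criteria.min_absolute_delta_percent
    fold_hit = fold >= criteria.min_fold_change
    if untreated < criteria.detection_limit_percent and treated < criteria.detection_limit_percent:
        category = "undetected"
    elif abs_hit and fold_hit:
        category = "both"
    elif abs_hit:
        category = "abs_only"
    elif fold_hit:
        category = "fold_only"
    else:
        category = "unaffected"
    return {
        "untreated_percent": untreated,
        "treated_percent": treated,
        "absolute_delta": delta,
        "fold_change": fold,
        "direction": int(np.sign(treated - untreated)),
        "category": category,
    }


def screen_treatment(
    untreated: pd.Series,
    treated: pd.Series,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> pd.DataFrame:
    """Apply the lability classifier to every shared antigen of two profiles."""
    shared = [ag for ag in untreated.index if ag in treated.index]
    if not shared:
        raise ValueError("profiles share no antigens")
    rows = {
        ag: classify_treatment_effect(untreated[ag], treated[ag], criteria)
        for ag in shared
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "antigen"
    return out


def screen_summary(results: pd.DataFrame) -> dict:
    """Counts per category plus the influenced fraction of detected antigens.

    "Influenced" = altered by the absolute criterion, the fold criterion,
    or both; the denominator is every antigen at or above the detection
    limit in either condition.
    """
    if len(results) == 0:
        counts = {c: 0 for c in CATEGORIES}
        return {"counts": counts, "n_detected": 0, "n_influenced": 0, "influenced_fraction": np.nan}
    counts = {c: int((results["category"] == c).sum()) for c in CATEGORIES}
    n_detected = int(
        (~results["category"].isin(["undetected", "missing"])).sum()
    )
    n_influenced = counts["abs_only"] + counts["fold_only"] + counts["both"]
    frac = n_influenced / n_detected if n_detected else np.nan
    return {
        "counts": counts,
        "n_detected": n_detected,
        "n_influenced": n_influenced,
        "influenced_fraction": frac,
    }


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    observed = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def replicate_reproducibility(
    run_a: pd.Series, run_b: pd.Series, exact_max_n: int = 8
) -> dict:
    """Spearman rank correlation between two replicate profiles.

    Pairs with a missing value in either run are dropped; ties get average
    ranks.  The p-value is an exact permutation enumeration for n at most
    ``exact_max_n`` and the large-sample approximation otherwise; the
    method used is reported alongside the result.
    """
    shared = [ag for ag in run_a.index if ag in run_b.index]
    a = run_a[shared].to_numpy(dtype=float)
    b = run_b[shared].to_numpy(dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError(f"only {len(a)} shared non-missing antigens (<3)")
    rho, p_asymptotic = stats.spearmanr(a, b)
    if len(a) <= exact_max_n:
        p = _exact_spearman_pvalue(a, b, rho)
        method = "exact-permutation"
    else:
        p = float(p_asymptotic)
        method = "large-sample"
    return {"rho": float(rho), "p_value": p, "n": int(len(a)), "method": method}


def rank_candidates(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    min_reference_percent: float = 50.0,
    max_target_percent: float = 20.0,
) -> pd.DataFrame:
    """Differential candidate markers: high in the pure reference population,
    low in the comparison fraction.

    Candidates satisfy mean(reference) >= min_reference_percent and
    mean(target) <= max_target_percent, ranked by the mean difference
    descending; ties break alphabetically by antigen.
    """
    if len(reference) == 0 or len(target) == 0:
        raise ValueError("need >= 1 reference and >= 1 target row")
    shared = [ag for ag in reference.columns if ag in target.columns]
    if not shared:
        raise ValueError("reference and target share no antigens")
    ref_mean = reference[shared].mean(axis=0, skipna=True)
    tgt_mean = target[shared].mean(axis=0, skipna=True)
    keep = (ref_mean >= min_reference_percent) & (tgt_mean <= max_target_percent)
    out = pd.DataFrame(
        {
            "reference_mean": ref_mean[keep],
            "target_mean": tgt_mean[keep],
            "score": ref_mean[keep] - tgt_mean[keep],
        }
    )
    out.index.name = "antigen"
    # alphabetical first, then a stable sort on score => ties break A-Z
    return out.sort_index().sort_values("score", ascending=False, kind="stable")
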