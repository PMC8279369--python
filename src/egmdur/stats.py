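"""Diagnostic statistics and the three-parameter grid search.

Segment-level validation treats ablation (performed during the clinical case)
as the reference marker of arrhythmogenic substrate and the abnormal-duration
flag as the test. Pooling all patients' non-empty segments gives a 2x2 table
(abnormal x ablated) from which the diagnostic odds ratio

    DOR = (TP * TN) / (FN * FP)

summarizes test performance in one number; its 95% confidence interval uses
the log-normal approximation exp(ln DOR +/- z * sqrt(1/TP+1/FN+1/FP+1/TN)),
with the Haldane-Anscombe 0.5 continuity correction applied to all cells when
any cell is zero (flagged in the output). The operating point of the duration
algorithm is the (window, threshold, cutoff) triple with the maximum DOR over
the tested lattice (w 10-45 ms step 5, theta 0.10-0.50 step 0.05, c 60-80 ms
step 5); ties resolve to the smallest window, then threshold, then cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aha17 import assign_segments, summarize_segments
from .duration import DurationParams, detect_onset_offset_matrix, sliding_sd_matrix, window_samples
from .errors import DataError, GridSearchError, ParameterError
from .filtering import FilterSpec, preprocess_matrix
from .model import ElectroanatomicMap


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: abnormal-duration flag x ablated flag."""

    tp: float  # abnormal and ablated
    fn: float  # normal and ablated
    fp: float  # abnormal and not ablated
    tn: float  # normal and not ablated

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DataError("contingency counts must be >= 0")
        if self.total == 0:
            raise DataError("contingency table is empty")

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


@dataclass(frozen=True)
class DorResult:
    dor: float
    ci_low: float
    ci_high: float
    corrected: bool
    p_value: float


@dataclass(frozen=True)
class GridSearchResult:
    best_params: DurationParams
    best_dor: float
    surface: pd.DataFrame  # one row per (w, theta, c) with table cells and DOR


def contingency(summaries: Iterable[pd.DataFrame]) -> ContingencyTable:
    """Pool 2x2 counts over patients' non-empty segment summaries."""
    tp = fn = fp = tn = 0
    any_rows = False
    for df in summaries:
        live = df[(df["n_points"] > 0) & (df["voltage_class"] != "empty")]
        if len(live) == 0:
            continue
        any_rows = True
        abnormal = live["abnormal"].to_numpy(dtype=bool)
        ablated = live["ablated"].to_numpy(dtype=bool)
        tp += int(np.sum(abnormal & ablated))
        fn += int(np.sum(~abnormal & ablated))
        fp += int(np.sum(abnormal & ~ablated))
        tn += int(np.sum(~abnormal & ~ablated))
    if not any_rows:
        raise DataError("all segments are empty; nothing to tabulate")
    return ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)


def diagnostic_odds_ratio(table: ContingencyTable, alpha: float = 0.05) -> DorResult:
    """DOR with log-normal CI and two-sided z-test on ln DOR.

    Zero cells get the Haldane-Anscombe correction (+0.5 to every cell),
    reported via ``corrected``.
    """
    cells = np.array([table.tp, table.fn, table.fp, table.tn], dtype=float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    tp, fn, fp, tn = cells
    dor = (tp * tn) / (fn * fp)
    se = float(np.sqrt((1.0 / cells).sum()))
    z = sps.norm.ppf(1 - alpha / 2.0)
    log_dor = np.log(dor)
    ci_low = float(np.exp(log_dor - z * se))
    ci_high = float(np.exp(log_dor + z * se))
    p_value = float(2.0 * sps.norm.sf(abs(log_dor) / se))
    return DorResult(dor=float(dor), ci_low=ci_low, ci_high=ci_high,
                     corrected=corrected, p_value=p_value)


def sensitivity_specificity(table: ContingencyTable) -> tuple[float, float]:
    """(sensitivity, specificity) as fractions."""
    if table.tp + table.fn == 0:
        raise DataError("no ablated segments: sensitivity undefined")
    if table.fp + table.tn == 0:
        raise DataError("no non-ablated segments: specificity undefined")
    return table.tp / (table.tp + table.fn), table.tn / (table.fp + table.tn)


def chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DataError("chi-square undefined: a table margin is zero")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def binomial_test(k: int, n: int, p0: float, sided: str = "two") -> float:
    """Exact binomial test.

    ``sided='two'`` uses the minimum-likelihood two-sided p-value (sum of
    P(X=j) over all j no more likely than the observed k); ``sided='one'``
    tests the lower tail P(X <= k) under p0.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ParameterError("need 0 <= k <= n with n > 0")
    if not 0 < p0 < 1:
        raise ParameterError("p0 must be in (0, 1)")
    alternative = {"two": "two-sided", "one": "less"}.get(sided)
    if alternative is None:
        raise ParameterError("sided must be 'one' or 'two'")
    return float(sps.binomtest(k, n, p0, alternative=alternative).pvalue)


DEFAULT_W_RANGE_MS: tuple[float, ...] = tuple(range(10, 50, 5))
DEFAULT_THETA_RANGE: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))
DEFAULT_C_RANGE_MS: tuple[float, ...] = tuple(range(60, 85, 5))


def _patient_cache(emap: ElectroanatomicMap, filter_spec: FilterSpec | None):
    """Precompute everything (w, theta, c)-independent for one patient."""
    x = emap.trace_matrix()
    rate = emap.sampling_rate_hz
    if filter_spec is not None:
        x = preprocess_matrix(x, filter_spec, rate)
    seg_of_point = assign_segments(emap.positions(), emap.landmarks)
    voltages = emap.voltages()
    lesions = emap.lesion_positions()
    lesion_segs = (
        set(assign_segments(lesions, emap.landmarks).tolist()) if len(lesions) else set()
    )
    return x, rate, seg_of_point, voltages, lesion_segs


def _segment_mean_durations(duration_ms, degenerate, seg_of_point) -> np.ndarray:
    """Mean duration per segment 1..17 (nan where no valid point), index 0 unused."""
    valid = ~degenerate
    sums = np.bincount(seg_of_point[valid], weights=duration_ms[valid], minlength=18)
    counts = np.bincount(seg_of_point[valid], minlength=18).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def grid_search(
    maps: Sequence[ElectroanatomicMap],
    w_range: Sequence[float] = DEFAULT_W_RANGE_MS,
    theta_range: Sequence[float] = DEFAULT_THETA_RANGE,
    c_range: Sequence[float] = DEFAULT_C_RANGE_MS,
    filter_spec: FilterSpec | None = FilterSpec(),
) -> GridSearchResult:
    """Maximize the pooled DOR over the (w, theta, c) lattice.

    Per patient, traces are filtered once; the SD transform is recomputed per
    window, thresholding per theta, and the cutoff sweep reuses the segment
    mean durations (which do not depend on c). The full DOR surface is
    returned alongside the argmax triple.
    """
    if not maps or not len(w_range) or not len(theta_range) or not len(c_range):
        raise GridSearchError("need a non-empty cohort and non-empty parameter ranges")

    caches = [_patient_cache(m, filter_spec) for m in maps]
    if not any(lesion_segs for *_, lesion_segs in caches):
        raise GridSearchError(
            "no ablated segment anywhere in the cohort: the DOR is undefined "
            "for every parameter triple"
        )

    rows = []
    best: tuple[DurationParams, float] | None = None
    for w in w_range:
        sd_curves = []
        for x, rate, *_ in caches:
            win = window_samples(w, rate)
            sd_curves.append(sliding_sd_matrix(x, win))
        for theta in theta_range:
            # per patient: segment mean durations and per-segment presence
            per_patient = []
            for (x, rate, seg_of_point, _voltages, lesion_segs), curves in zip(caches, sd_curves):
                onset, offset, degenerate = detect_onset_offset_matrix(curves, theta)
                duration_ms = np.where(degenerate, 0.0, (offset - onset) * 1000.0 / rate)
                seg_mean = _segment_mean_durations(duration_ms, degenerate, seg_of_point)
                present = np.bincount(seg_of_point, minlength=18) > 0
                per_patient.append((seg_mean, present, lesion_segs))
            for c in c_range:
                tp = fn = fp = tn = 0
                for seg_mean, present, lesion_segs in per_patient:
                    for seg in range(1, 18):
                        if not present[seg]:
                            continue
                        abnormal = bool(np.isfinite(seg_mean[seg]) and seg_mean[seg] > c)
                        ablated = seg in lesion_segs
                        if abnormal and ablated:
                            tp += 1
                        elif ablated:
                            fn += 1
                        elif abnormal:
                            fp += 1
                        else:
                            tn += 1
                table = ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)
                res = diagnostic_odds_ratio(table)
                rows.append((w, theta, c, tp, fn, fp, tn,
                             res.dor, res.ci_low, res.ci_high, res.corrected))
                if best is None or res.dor > best[1]:
                    best = (DurationParams(sd_window_ms=w, sd_threshold_frac=theta,
                                           duration_cutoff_ms=c), res.dor)

    surface = pd.DataFrame(
        rows,
        columns=["w_ms", "theta", "c_ms", "tp", "fn", "fp", "tn",
                 "dor", "ci_low", "ci_high", "corrected"],
    )
    assert best is not None
    return GridSearchResult(best_params=best[0], best_dor=best[1], surface=surface)


def cohort_statistics(
    maps: Sequence[ElectroanatomicMap],
    params: DurationParams = DurationParams(),
    filter_spec: FilterSpec | None = FilterSpec(),
    lesion_radius_mm: float = 0.0,
) -> dict:
    """Pooled segment statistics of a cohort at one parameter triple.

    Convenience wrapper: per-patient durations and segment summaries, pooled
    contingency, DOR with CI, sensitivity/specificity, chi-square, and the
    prolonged-segment proportion.
    """
    from .duration import map_durations  # local import to avoid cycle at import time

    summaries = []
    for emap in maps:
        dur = map_durations(emap, params, filter_spec)
        summaries.append(
            summarize_segments(emap, dur, cutoff_ms=params.duration_cutoff_ms,
                               lesion_radius_mm=lesion_radius_mm)
        )
    table = contingency(summaries)
    dor = diagnostic_odds_ratio(table)
    sens, spec = sensitivity_specificity(table)
    chi2, chi2_p = chi_square(table)
    n_segments = int(table.total)
    n_prolonged = int(table.tp + table.fp)
    return {
        "table": table,
        "dor": dor,
        "sensitivity": sens,
        "specificity": spec,
        "chi_square": chi2,
        "chi_square_p": chi2_p,
        "n_segments": n_segments,
        "n_prolonged_segments": n_prolonged,
        "prolonged_fraction": n_prolonged / n_segments,
        "summaries": summaries,
    }
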