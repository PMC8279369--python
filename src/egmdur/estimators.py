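"""scikit-learn style estimators wrapping the duration pipeline.

:class:`EgmDurationEstimator` is a stateless transformer: rows of ``X`` are
uniformly sampled EGM traces, and ``transform`` returns onset, offset,
duration and the derived flags per trace, so it composes with sklearn
pipelines and model selection. :class:`DorGridSearch` fits the three
algorithm parameters on a cohort of electroanatomic maps by maximizing the
pooled diagnostic odds ratio against ablated segments.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .duration import DurationParams, durations_matrix
from .filtering import FilterSpec
from .model import ElectroanatomicMap
from .stats import (
    DEFAULT_C_RANGE_MS,
    DEFAULT_THETA_RANGE,
    DEFAULT_W_RANGE_MS,
    grid_search,
)

FEATURE_NAMES_OUT = ("onset_ms", "offset_ms", "duration_ms", "prolonged", "degenerate")


class EgmDurationEstimator(TransformerMixin, BaseEstimator):
    """Sliding-SD EGM duration transformer.

    Parameters
    ----------
    sd_window_ms : float, default=40.0
        Sliding-SD window length in ms.
    sd_threshold_frac : float, default=0.15
        Onset/offset threshold as a fraction of the SD-curve maximum.
    duration_cutoff_ms : float, default=70.0
        Durations strictly greater than this are flagged prolonged.
    sampling_rate_hz : float, default=1000.0
        Sampling rate of the trace rows of ``X``.
    apply_filter : bool, default=True
        Run the 30-250 Hz bandpass + mains notch before the SD transform.
    filter_spec : FilterSpec or None
        Preprocessing configuration; ``None`` uses the defaults.

    Examples
    --------
    >>> est = EgmDurationEstimator().fit(X)      # X: (n_traces, n_samples) mV
    >>> out = est.transform(X)                   # (n_traces, 5) array
    """

    def __init__(
        self,
        sd_window_ms: float = 40.0,
        sd_threshold_frac: float = 0.15,
        duration_cutoff_ms: float = 70.0,
        sampling_rate_hz: float = 1000.0,
        apply_filter: bool = True,
        filter_spec: FilterSpec | None = None,
    ) -> None:
        self.sd_window_ms = sd_window_ms
        self.sd_threshold_frac = sd_threshold_frac
        self.duration_cutoff_ms = duration_cutoff_ms
        self.sampling_rate_hz = sampling_rate_hz
        self.apply_filter = apply_filter
        self.filter_spec = filter_spec

    def _params(self) -> DurationParams:
        return DurationParams(
            sd_window_ms=self.sd_window_ms,
            sd_threshold_frac=self.sd_threshold_frac,
            duration_cutoff_ms=self.duration_cutoff_ms,
        )

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self._params()  # validate parameters early
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Columns: onset_ms, offset_ms, duration_ms, prolonged, degenerate."""
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        return self.results_frame(X).to_numpy(dtype=float)

    def results_frame(self, X) -> pd.DataFrame:
        """Like :meth:`transform` but as a typed DataFrame."""
        spec = self.filter_spec if self.filter_spec is not None else FilterSpec()
        return durations_matrix(
            np.asarray(X, dtype=float),
            self._params(),
            self.sampling_rate_hz,
            spec if self.apply_filter else None,
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES_OUT, dtype=object)


class DorGridSearch(BaseEstimator):
    """Select (window, threshold, cutoff) by maximum pooled DOR.

    ``fit`` takes a sequence of :class:`~egmdur.model.ElectroanatomicMap` (a
    cohort) rather than a feature matrix: the search criterion is a
    segment-level association with ablation, which only exists map-wise.

    Attributes
    ----------
    best_params_ : DurationParams
    best_dor_ : float
    surface_ : DataFrame with one row per lattice triple.
    """

    def __init__(
        self,
        w_values: Sequence[float] = DEFAULT_W_RANGE_MS,
        theta_values: Sequence[float] = DEFAULT_THETA_RANGE,
        c_values: Sequence[float] = DEFAULT_C_RANGE_MS,
        apply_filter: bool = True,
        filter_spec: FilterSpec | None = None,
    ) -> None:
        self.w_values = w_values
        self.theta_values = theta_values
        self.c_values = c_values
        self.apply_filter = apply_filter
        self.filter_spec = filter_spec

    def fit(self, X: Sequence[ElectroanatomicMap], y=None):
        spec = self.filter_spec if self.filter_spec is not None else FilterSpec()
        result = grid_search(
            list(X),
            w_range=self.w_values,
            theta_range=self.theta_values,
            c_range=self.c_values,
            filter_spec=spec if self.apply_filter else None,
        )
        self.best_params_ = result.best_params
        self.best_dor_ = result.best_dor
        self.surface_ = result.surface
        return self

    def best_estimator(self, sampling_rate_hz: float = 1000.0) -> EgmDurationEstimator:
        """An :class:`EgmDurationEstimator` configured at the fitted optimum."""
        check_is_fitted(self, "best_params_")
        p = self.best_params_
        return EgmDurationEstimator(
            sd_window_ms=p.sd_window_ms,
            sd_threshold_frac=p.sd_threshold_frac,
            duration_cutoff_ms=p.duration_cutoff_ms,
            sampling_rate_hz=sampling_rate_hz,
            apply_filter=self.apply_filter,
            filter_spec=self.filter_spec,
        )
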