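"""Multiplicative correction of feature data back to the reference delay time.

For a sample with pre-centrifugation time ``t`` and a feature belonging to
drift cluster ``c``, the corrected intensity is ``x / g_c(t)``: since the
drift functions are anchored fold-changes relative to the 1 h reference
state, division restores each feature to its expected reference-time level.
Times may come from recorded handling metadata (metadata-approach) or from
random-forest predictions of temperature and time (prediction-approach, the
legacy-sample use case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import FeatureTable
from .drift_model import DriftModel
from .handling_predict import PredictionModel, rdcv_predict


class CorrectionError(ValueError):
    pass


@dataclass
class CorrectionResult:
    """Corrected table plus per-sample provenance of the times used."""

    corrected: FeatureTable
    #: per-sample hours actually used (after clamping to the model range)
    times_used: pd.Series
    #: 'metadata' or 'predicted'
    time_source: str
    #: per-sample flag: requested time fell outside the model's time range
    clamped: pd.Series
    #: features passed through unchanged (excluded from the drift model or
    #: absent from it)
    passthrough_features: list[str]


def correct(
    table: FeatureTable,
    model: DriftModel,
    times: pd.Series | np.ndarray,
    time_source: str = "metadata",
    feature_tolerance: float = 0.95,
) -> CorrectionResult:
    """Correct intensities to the reference state using per-sample times.

    Features in a drift cluster are divided by the cluster drift function at
    the sample's time; features the model excluded as irreproducible (or that
    the model has never seen) pass through unchanged and are reported.  Times
    outside the model's fitted range are clamped to the boundary with a
    warning.  Correction refuses to run when less than ``feature_tolerance``
    of the model's features are present in the table.
    """
    if isinstance(times, pd.Series):
        missing = [s for s in table.sample_ids if s not in times.index]
        if missing:
            raise CorrectionError(f"time missing for samples {missing[:5]}")
        t = times.loc[table.sample_ids].to_numpy(dtype=float)
    else:
        t = np.asarray(times, dtype=float)
        if t.shape != (table.n_samples,):
            raise CorrectionError(
                f"need one time per sample: got {t.shape}, {table.n_samples} samples"
            )
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise CorrectionError("pre-centrifugation times must be positive and finite")

    model_features = set(model.feature_ids)
    present = model_features & set(table.feature_ids)
    if model_features and len(present) / len(model_features) < feature_tolerance:
        raise CorrectionError(
            f"only {len(present)}/{len(model_features)} model features present "
            f"in table (tolerance {feature_tolerance:.0%})"
        )

    t_min = min(model.time_points)
    t_max = max(model.time_points)
    clamped = (t < t_min) | (t > t_max)
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} sample time(s) outside [{t_min}, {t_max}] h "
            "clamped to the model boundary",
            stacklevel=2,
        )
    t_used = np.clip(t, t_min, t_max)

    corrected = table.data.copy()
    corrected_cols = set()
    for cluster in model.clusters:
        g = cluster.drift_fn(t_used)  # per-sample drift factor
        cols = [f for f in cluster.member_features if f in corrected.columns]
        if cols:
            corrected[cols] = corrected[cols].div(g, axis=0)
            corrected_cols.update(cols)
    passthrough = [f for f in table.feature_ids if f not in corrected_cols]

    return CorrectionResult(
        corrected=FeatureTable(corrected),
        times_used=pd.Series(t_used, index=table.data.index, name="time_h"),
        time_source=time_source,
        clamped=pd.Series(clamped, index=table.data.index, name="clamped"),
        passthrough_features=passthrough,
    )


def correct_with_predicted_times(
    table: FeatureTable,
    temp_model: PredictionModel,
    time_models: dict[float, PredictionModel],
    drift_models: dict[float, DriftModel],
    feature_tolerance: float = 0.95,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Prediction-approach correction for samples without handling metadata.

    Per sample: classify the pre-centrifugation temperature, regress the
    pre-centrifugation time with the temperature-matched model, clamp to the
    drift model's fitted range, and apply :func:`correct` with the
    temperature-matched drift model.  Returns the corrected table and a
    per-sample provenance frame (predicted temperature, predicted and used
    time, clamping flag).
    """
    for temp in time_models:
        if temp not in drift_models:
            raise CorrectionError(f"no drift model for temperature {temp} degC")

    pred_temp = rdcv_predict(temp_model, table)
    temps = pd.Series(pred_temp, index=table.data.index).astype(float)
    for temp in temps.unique():
        if temp not in drift_models:
            raise CorrectionError(
                f"predicted temperature class {temp} has no drift model"
            )

    corrected = table.data.copy()
    prov_rows = []
    for temp, ids in temps.groupby(temps).groups.items():
        sub = table.subset(samples=list(ids))
        pred_time = np.asarray(rdcv_predict(time_models[temp], sub), dtype=float)
        pred_time = np.maximum(pred_time, np.finfo(float).tiny)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = correct(
                sub,
                drift_models[temp],
                pred_time,
                time_source="predicted",
                feature_tolerance=feature_tolerance,
            )
        corrected.loc[list(ids), :] = res.corrected.data
        for sid, raw, used, cl in zip(
            ids, pred_time, res.times_used.to_numpy(), res.clamped.to_numpy()
        ):
            prov_rows.append(
                {
                    "sample_id": sid,
                    "predicted_temperature_c": float(temp),
                    "predicted_time_h": float(raw),
                    "time_used_h": float(used),
                    "clamped": bool(cl),
                }
            )
    prov = (
        pd.DataFrame(prov_rows)
        .set_index("sample_id")
        .loc[table.sample_ids]
        .reset_index()
    )
    return FeatureTable(corrected), prov
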