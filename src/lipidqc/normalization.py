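"""QC-anchored LOESS drift correction and cross-batch median normalization.

Within each batch, each ion's QC peak heights are regressed on injection
order with local-linear LOESS (tricube weights over the span-fraction
nearest neighbours); the span is chosen per curve by leave-one-out cross
validation to avoid overfitting.  Every sample's value is divided by the
LOESS prediction at its injection order and re-anchored so the batch QC
median is preserved exactly.  A median normalization then rescales each
batch so that, per ion, all batch QC medians coincide with the pooled QC
median.  Normalization performance is scored by the k-fold cross-validated
QC RSD: models are refit without each QC fold and the held-out QCs are
corrected by them, so the score cannot benefit from peeking.

Blanks are never used in, nor corrected by, normalization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix

__all__ = [
    "DEFAULT_SPAN_GRID",
    "loess_predict",
    "select_span_loocv",
    "correct_batch_drift",
    "median_normalize_batches",
    "normalize",
    "cv_rsd",
]

DEFAULT_SPAN_GRID = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
MIN_QC_FOR_LOESS = 4  # below this the correction falls back to the batch median
MIN_QC_FOR_LOOCV = 5


def loess_predict(
    x: np.ndarray,
    y: np.ndarray,
    span: float,
    x_new: np.ndarray | float,
    degree: int = 1,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each query point the ``ceil(span * n)`` nearest neighbours (at least
    3) define the bandwidth; a weighted degree-``degree`` polynomial is
    fitted and evaluated there.  Queries beyond ``[min(x), max(x)]`` are
    clamped to the boundary, so extrapolation returns the boundary fit value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < MIN_QC_FOR_LOESS:
        raise ValueError(f"need at least {MIN_QC_FOR_LOESS} points, got {n}")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if np.all(x == x[0]):
        raise ValueError("degenerate predictor: all x values identical")

    scalar = np.isscalar(x_new)
    queries = np.atleast_1d(np.asarray(x_new, dtype=float))
    queries = np.clip(queries, x.min(), x.max())
    k = min(n, max(degree + 2, int(np.ceil(span * n))))
    out = np.empty(queries.shape)
    for i, x0 in enumerate(queries):
        d = np.abs(x - x0)
        bandwidth = np.partition(d, k - 1)[k - 1]
        if bandwidth == 0:
            bandwidth = max(d.max() * 1e-9, 1e-12)
        w = np.clip(1.0 - (d / bandwidth) ** 3, 0.0, None) ** 3
        active = w > 0
        if active.sum() <= degree:  # too few points for the polynomial: mean
            out[i] = np.average(y, weights=np.maximum(w, 1e-12))
            continue
        coeffs = np.polyfit(x[active], y[active], degree, w=np.sqrt(w[active]))
        out[i] = np.polyval(coeffs, x0)
    return float(out[0]) if scalar else out


def select_span_loocv(
    x: np.ndarray,
    y: np.ndarray,
    span_grid: tuple[float, ...] = DEFAULT_SPAN_GRID,
    degree: int = 1,
) -> float:
    """Span minimizing the leave-one-out mean squared prediction error.

    Ties are broken toward the largest (smoothest) span so noiseless data do
    not select an aggressively local fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < MIN_QC_FOR_LOOCV:
        raise ValueError(
            f"need at least {MIN_QC_FOR_LOOCV} points for leave-one-out "
            f"span selection, got {n}"
        )
    if np.all(x == x[0]):
        raise ValueError("degenerate predictor: all x values identical")
    mses: dict[float, float] = {}
    for span in span_grid:
        errors = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            pred = loess_predict(x[keep], y[keep], span, x[i], degree=degree)
            errors[i] = y[i] - pred
        mses[span] = float(np.mean(errors**2))
    best = min(mses.values())
    # spans within floating-point jitter of the best MSE count as ties and
    # resolve to the largest (smoothest) span
    tol = 1e-10 * (best + float(np.mean(y**2)))
    return max(s for s in span_grid if mses[s] <= best + tol)


@dataclasses.dataclass
class _IonBatchFit:
    span: float | None
    n_qc: int
    fallback: str  # "" when the LOESS path was used
    factors: pd.Series  # multiplicative correction per sample (corrected/raw)
    pre_rsd: float
    post_rsd: float


def _rsd(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return np.nan
    mean = values.mean()
    if mean == 0:
        return np.nan
    return 100.0 * values.std(ddof=1) / mean


def _correct_ion_batch(
    qc_orders: np.ndarray,
    qc_values: np.ndarray,
    target_orders: np.ndarray,
    qc_target_mask: np.ndarray,
    raw: np.ndarray,
    span_grid: tuple[float, ...],
) -> _IonBatchFit:
    """Correction factors for one (ion, batch) from its QC series.

    ``target_orders`` are the injection orders of all samples to correct;
    ``qc_target_mask`` marks which of them are QCs (used for re-anchoring).
    On fewer than 4 usable QCs, or on non-positive LOESS predictions, the
    batch-median fallback leaves values unchanged (factor 1), recorded in
    the audit.
    """
    ok = np.isfinite(qc_values)
    qc_orders, qc_values = qc_orders[ok], qc_values[ok]
    n_qc = len(qc_values)
    pre = _rsd(qc_values)
    identity = pd.Series(np.ones(len(target_orders)))

    def _fallback(reason: str) -> _IonBatchFit:
        return _IonBatchFit(
            span=None, n_qc=n_qc, fallback=reason, factors=identity,
            pre_rsd=pre, post_rsd=pre,
        )

    if n_qc < MIN_QC_FOR_LOESS:
        return _fallback("too_few_qc")
    if np.any(qc_values <= 0):
        return _fallback("nonpositive_qc")
    if n_qc >= MIN_QC_FOR_LOOCV:
        span = select_span_loocv(qc_orders, qc_values, span_grid)
    else:
        span = 1.0
    pred = loess_predict(qc_orders, qc_values, span, target_orders)
    if np.any(pred <= 0):
        return _fallback("nonpositive_prediction")
    ratio = raw / pred
    qc_ratio = ratio[qc_target_mask]
    anchor = np.median(qc_values) / np.median(qc_ratio[np.isfinite(qc_ratio)])
    factors = pd.Series(anchor / pred)
    corrected_qc = ratio[qc_target_mask] * anchor
    return _IonBatchFit(
        span=span, n_qc=n_qc, fallback="", factors=factors,
        pre_rsd=pre, post_rsd=_rsd(corrected_qc),
    )


def correct_batch_drift(
    fm: FeatureMatrix,
    span_grid: tuple[float, ...] = DEFAULT_SPAN_GRID,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Remove within-batch intensity drift, ion by ion and batch by batch.

    Returns the corrected matrix and a per-(ion, batch) audit table with the
    chosen span, QC count, pre/post QC RSD, the correction-factor range and
    the fallback reason where the LOESS path was not usable.  Blank rows are
    passed through unchanged.
    """
    values = fm.values.copy()
    samples = fm.samples
    if not (samples["sample_type"] == "qc").any():
        raise ValueError("no QC injections: drift correction is undefined")
    audit_rows = []
    for batch, grp in samples.groupby("batch"):
        nonblank = grp[grp["sample_type"] != "blank"]
        if not (nonblank["sample_type"] == "qc").any():
            raise ValueError(f"batch {batch} contains no QC injections")
        orders = nonblank["injection_order"].to_numpy(dtype=float)
        qc_mask = (nonblank["sample_type"] == "qc").to_numpy()
        idx = nonblank.index
        for ion_id in fm.ion_ids:
            raw = fm.values.loc[idx, ion_id].to_numpy(dtype=float)
            fit = _correct_ion_batch(
                qc_orders=orders[qc_mask],
                qc_values=raw[qc_mask],
                target_orders=orders,
                qc_target_mask=qc_mask,
                raw=raw,
                span_grid=span_grid,
            )
            values.loc[idx, ion_id] = raw * fit.factors.to_numpy()
            audit_rows.append(
                dict(
                    ion_id=ion_id,
                    batch=batch,
                    n_qc=fit.n_qc,
                    span=fit.span,
                    fallback=fit.fallback,
                    pre_qc_rsd=fit.pre_rsd,
                    post_qc_rsd=fit.post_rsd,
                    factor_min=float(fit.factors.min()),
                    factor_max=float(fit.factors.max()),
                )
            )
    audit = pd.DataFrame(audit_rows)
    corrected = fm.copy_with(values=values, provenance="drift_corrected")
    return corrected, audit


def median_normalize_batches(
    fm: FeatureMatrix,
) -> tuple[FeatureMatrix, list[str]]:
    """Equalize per-ion QC medians across batches.

    Each batch's values are scaled so its QC median matches the pooled
    (all-batch) QC median of that ion.  Ions with a non-positive or missing
    batch QC median are left unscaled and reported in the returned flag
    list.  Blanks are passed through unchanged.
    """
    values = fm.values.copy()
    samples = fm.samples
    qc = fm.qc_values()
    flagged: list[str] = []
    targets = qc.median(axis=0, skipna=True)
    for ion_id in fm.ion_ids:
        target = targets[ion_id]
        if not np.isfinite(target) or target <= 0:
            flagged.append(ion_id)
            continue
        for batch, grp in samples.groupby("batch"):
            nonblank_idx = grp.index[grp["sample_type"] != "blank"]
            qc_idx = grp.index[grp["sample_type"] == "qc"]
            batch_median = fm.values.loc[qc_idx, ion_id].median(skipna=True)
            if not np.isfinite(batch_median) or batch_median <= 0:
                if ion_id not in flagged:
                    flagged.append(ion_id)
                continue
            values.loc[nonblank_idx, ion_id] = (
                fm.values.loc[nonblank_idx, ion_id] * (target / batch_median)
            )
    out = fm.copy_with(values=values, provenance=fm.provenance + "+median_normalized")
    return out, flagged


def normalize(
    fm: FeatureMatrix,
    span_grid: tuple[float, ...] = DEFAULT_SPAN_GRID,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """LOESS drift correction followed by cross-batch median normalization."""
    corrected, audit = correct_batch_drift(fm, span_grid=span_grid)
    normalized, flagged = median_normalize_batches(corrected)
    audit = audit.copy()
    audit["median_norm_flagged"] = audit["ion_id"].isin(flagged)
    return normalized, audit


def cv_rsd(
    fm: FeatureMatrix,
    k: int = 5,
    span_grid: tuple[float, ...] = DEFAULT_SPAN_GRID,
    seed: int | None = None,
) -> pd.Series:
    """k-fold cross-validated QC RSD of the normalization, per ion.

    QCs, ordered by injection, are dealt into ``k`` interleaved folds (a
    deterministic partition; pass ``seed`` to shuffle instead).  For each
    fold the drift and median-normalization models are refit on the
    remaining QCs only, the held-out QCs are corrected by them, and the RSD
    of the pooled held-out corrected values is reported.  With ``k`` equal
    to the number of QCs this is the leave-one-out variant.
    """
    samples = fm.samples
    qc_ids = samples.index[samples["sample_type"] == "qc"]
    qc_ids = list(
        samples.loc[qc_ids].sort_values("injection_order").index
    )
    n_qc = len(qc_ids)
    if n_qc < k:
        raise ValueError(f"{n_qc} QC injections but k={k} folds requested")
    positions = np.arange(n_qc)
    if seed is not None:
        positions = np.random.default_rng(seed).permutation(n_qc)
    folds: list[list[str]] = [[] for _ in range(k)]
    for rank, pos in enumerate(positions):
        folds[rank % k].append(qc_ids[pos])

    held_out: dict[str, list[np.ndarray]] = {ion: [] for ion in fm.ion_ids}
    for fold in folds:
        fold_set = set(fold)
        # per-batch drift fits on training QCs; apply to held-out QCs
        corrected_fold: dict[str, pd.Series] = {}
        train_corrected: dict[str, pd.Series] = {}
        for batch, grp in samples.groupby("batch"):
            qc_grp = grp[grp["sample_type"] == "qc"]
            train = qc_grp.index[~qc_grp.index.isin(fold_set)]
            test = qc_grp.index[qc_grp.index.isin(fold_set)]
            orders_train = qc_grp.loc[train, "injection_order"].to_numpy(dtype=float)
            orders_all = qc_grp["injection_order"].to_numpy(dtype=float)
            qc_target_mask = ~qc_grp.index.isin(fold_set)
            for ion_id in fm.ion_ids:
                y_train = fm.values.loc[train, ion_id].to_numpy(dtype=float)
                raw_all = fm.values.loc[qc_grp.index, ion_id].to_numpy(dtype=float)
                fit = _correct_ion_batch(
                    qc_orders=orders_train,
                    qc_values=y_train,
                    target_orders=orders_all,
                    qc_target_mask=qc_target_mask,
                    raw=raw_all,
                    span_grid=span_grid,
                )
                corr = pd.Series(
                    raw_all * fit.factors.to_numpy(), index=qc_grp.index
                )
                corrected_fold.setdefault(ion_id, pd.Series(dtype=float))
                train_corrected.setdefault(ion_id, pd.Series(dtype=float))
                corrected_fold[ion_id] = pd.concat(
                    [corrected_fold[ion_id], corr.loc[test]]
                )
                train_corrected[ion_id] = pd.concat(
                    [train_corrected[ion_id], corr.loc[train]]
                )
        # cross-batch median step anchored on training QCs only
        for ion_id in fm.ion_ids:
            train_corr = train_corrected[ion_id]
            target = train_corr.median(skipna=True)
            if not np.isfinite(target) or target <= 0:
                held_out[ion_id].append(corrected_fold[ion_id].to_numpy())
                continue
            scaled = corrected_fold[ion_id].copy()
            batches = samples.loc[scaled.index, "batch"]
            for batch in batches.unique():
                batch_train_ids = [
                    s for s in train_corr.index if samples.loc[s, "batch"] == batch
                ]
                m = train_corr.loc[batch_train_ids].median(skipna=True)
                sel = batches.index[batches == batch]
                if np.isfinite(m) and m > 0:
                    scaled.loc[sel] = scaled.loc[sel] * (target / m)
            held_out[ion_id].append(scaled.to_numpy())

    return pd.Series(
        {
            ion_id: _rsd(np.concatenate(chunks))
            for ion_id, chunks in held_out.items()
        },
        name="cv_rsd",
    )
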