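"""Per-fraction filtering, normalization and two-regime imputation.

Each fraction is treated as its own sub-experiment: the minimum-valid
filter, the loess normalization and both imputation steps all operate
within one fraction at a time. Missing values are imputed in two steps
according to their nature: cells missing within a group that still has
observed replicates are treated as missing completely at random and
imputed from nearest-neighbour features; cells of groups that are missing
entirely are treated as missing not at random (below detection) and
imputed with a deterministic low quantile of the sample's observed
intensities.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import QuantTable

__all__ = [
    "filter_min_valid",
    "cyclic_loess_normalize",
    "impute_partial",
    "impute_absent",
    "preprocess",
]

log = logging.getLogger(__name__)


def _group_columns(table: QuantTable) -> list[tuple[int, str, list[str]]]:
    return [
        (f, c, list(samples)) for f, c, samples in table.design.groups()
        if all(s in table.values.columns for s in samples)
    ]


def filter_min_valid(table: QuantTable, min_valid: int = 3) -> QuantTable:
    """Keep a (feature, fraction) block iff some condition group within that
    fraction holds at least ``min_valid`` observed values.

    Features retained in no fraction at all are dropped from the table.
    Cells of non-retained blocks are blanked so later stages cannot use
    them; the block-level mask is recorded on ``retained``.
    """
    groups = _group_columns(table)
    largest = max(len(s) for _, _, s in groups)
    if min_valid > largest:
        raise ValueError(
            f"min_valid={min_valid} exceeds the largest group size {largest}"
        )
    fractions = table.design.fractions
    retained = pd.DataFrame(False, index=table.features, columns=fractions)
    for fraction, _condition, samples in groups:
        counts = table.values[samples].notna().sum(axis=1)
        retained[fraction] |= counts >= min_valid

    keep = retained.any(axis=1)
    values = table.values.loc[keep].copy()
    retained = retained.loc[keep]
    observed = table.observed.loc[keep].copy()

    frac_of = table.design.frame.loc[values.columns, "fraction"]
    for s in values.columns:
        blank = ~retained[frac_of[s]]
        values.loc[blank, s] = np.nan
    out = QuantTable(values, table.design, observed, retained)
    log.info(
        "filter_min_valid: kept %d/%d features (min_valid=%d)",
        keep.sum(), len(keep), min_valid,
    )
    return out


def cyclic_loess_normalize(
    table: QuantTable, span: float = 0.7, iterations: int = 3
) -> QuantTable:
    """Remove intensity-dependent per-sample bias within each fraction.

    For each sample the deviation from the per-feature row mean (the
    reference) is smoothed against the reference intensity with a lowess
    curve fitted on complete rows, and the fitted trend is subtracted;
    the cycle repeats ``iterations`` times. Missing cells stay missing.
    Fractions with fewer than 10 complete rows fall back to median
    centering with a warning.
    """
    values = table.values.copy()
    frac_of = table.design.frame.loc[values.columns, "fraction"]
    for fraction in table.design.fractions:
        cols = [s for s in values.columns if frac_of[s] == fraction]
        if len(cols) < 2:
            continue
        block = values[cols]
        complete = block.notna().all(axis=1)
        if complete.sum() < 10:
            warnings.warn(
                f"fraction {fraction}: only {int(complete.sum())} complete rows; "
                "falling back to median centering",
                stacklevel=2,
            )
            medians = block.median(axis=0)
            values[cols] = block - (medians - medians.mean())
            continue
        for _ in range(iterations):
            block = values[cols]
            ref = block.mean(axis=1)                 # evaluation reference
            ref_fit = block.loc[complete].mean(axis=1)
            for s in cols:
                diff = block.loc[complete, s] - ref_fit
                fit = lowess(
                    diff.to_numpy(), ref_fit.to_numpy(), frac=span, return_sorted=True
                )
                obs = block[s].notna()
                offsets = np.interp(ref[obs].to_numpy(), fit[:, 0], fit[:, 1])
                values.loc[obs, s] = block.loc[obs, s] - offsets
    return QuantTable(values, table.design, table.observed.copy(),
                      None if table.retained is None else table.retained.copy())


def _mcar_mask(table: QuantTable) -> pd.DataFrame:
    """Cells missing within a group that still has observed values
    (restricted to retained blocks)."""
    mask = pd.DataFrame(False, index=table.features, columns=table.values.columns)
    retained_cells = table.retained_mask_cells()
    for _fraction, _condition, samples in _group_columns(table):
        block = table.values[samples]
        any_obs = block.notna().any(axis=1)
        for s in samples:
            mask[s] = mask[s] | (block[s].isna() & any_obs)
    return mask & retained_cells


def impute_partial(table: QuantTable, k_neighbors: int = 10) -> QuantTable:
    """Impute partially observed (missing-completely-at-random) cells.

    Within each fraction, a missing cell is filled with the average of the
    corresponding sample's values over the k nearest features, distances
    taken as masked Euclidean over the fraction's samples. Cells of groups
    that are missing entirely are left alone for the censored-value step.
    Observed values are never altered.
    """
    mcar = _mcar_mask(table)
    if not mcar.any().any():
        return table.copy()
    values = table.values.copy()
    frac_of = table.design.frame.loc[values.columns, "fraction"]
    for fraction in table.design.fractions:
        cols = [s for s in values.columns if frac_of[s] == fraction]
        if not mcar[cols].any().any():
            continue
        block = values[cols]
        rows = block.notna().any(axis=1)
        sub = block.loc[rows]
        k = min(k_neighbors, max(1, len(sub) - 1))
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        filled = pd.DataFrame(
            imputer.fit_transform(sub.to_numpy()), index=sub.index, columns=cols
        )
        target = mcar.loc[rows, cols]
        n_left = int((target & filled.isna()).sum().sum())
        if n_left:
            log.info(
                "impute_partial: %d cells in fraction %s had no usable neighbors",
                n_left, fraction,
            )
        block = block.where(~target, filled)
        values.loc[rows, cols] = block.loc[rows, cols]
    return QuantTable(values, table.design, table.observed.copy(),
                      None if table.retained is None else table.retained.copy())


def impute_absent(table: QuantTable, quantile: float = 0.025) -> QuantTable:
    """Impute whole-group-missing (censored, missing-not-at-random) cells.

    Every such cell in sample j is set to the q-th quantile (linear
    interpolation between order statistics) of sample j's observed values.
    Deterministic. Only retained (feature, fraction) blocks are filled.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must lie in [0, 1]")
    values = table.values.copy()
    retained_cells = table.retained_mask_cells()
    fillable = values.isna() & retained_cells
    if not fillable.any().any():
        return table.copy()
    for s in values.columns:
        col = values[s]
        needs = fillable[s]
        if not needs.any():
            continue
        observed = col.dropna()
        if len(observed) < 10:
            raise ValueError(
                f"sample {s!r} has only {len(observed)} observed values; "
                "cannot estimate a detection-limit quantile"
            )
        values.loc[needs, s] = float(np.quantile(observed, quantile))
    n_filled = int(fillable.sum().sum())
    log.info("impute_absent: filled %d censored cells at quantile %g",
             n_filled, quantile)
    return QuantTable(values, table.design, table.observed.copy(),
                      None if table.retained is None else table.retained.copy())


def preprocess(
    table: QuantTable,
    min_valid: int = 3,
    span: float = 0.7,
    iterations: int = 3,
    k_neighbors: int = 10,
    quantile: float = 0.025,
    normalize: bool = True,
) -> QuantTable:
    """Convenience chain: filter -> loess normalize -> KNN -> quantile impute."""
    out = filter_min_valid(table, min_valid=min_valid)
    if normalize:
        out = cyclic_loess_normalize(out, span=span, iterations=iterations)
    out = impute_partial(out, k_neighbors=k_neighbors)
    out = impute_absent(out, quantile=quantile)
    return out
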