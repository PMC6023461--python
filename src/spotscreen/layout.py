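"""Spot-ROI detection, layout validation and readout aggregation.

On cell arrays the transfection spot is visible in the Cy3 marker channel
(fluorescently labelled siRNA was mixed into the spotting solution), which
allows a region-of-interest mask restricting the analysis to cells that
settled on the spot.  Well images have no marker and use the whole field.

Per-field readouts are pooled into per-position (spot or well) rows
cell-weighted, i.e. total class counts divided by total cells, matching a
readout defined as "the average of all cells acquired" in a well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segment import label_components, relabel_sequential, threshold_global_otsu
from .synth import LAYOUT_COLUMNS, SUBPOSITIONS

__all__ = [
    "SpotROI",
    "validate_layout",
    "detect_spot_roi",
    "restrict_to_roi",
    "filter_features_to_roi",
    "aggregate_position",
    "aggregate_screen",
    "normalize_egf",
    "normalize_cell_counts",
    "READOUT_COLUMNS",
]

READOUT_COLUMNS = [
    "replicate",
    "platform",
    "position",
    "condition",
    "n_cells",
    "frac_normal",
    "frac_spindle",
    "frac_cytokinesis",
    "mean_egf",
    "n_subpositions",
]


@dataclass(frozen=True)
class SpotROI:
    """Transfection-spot region of interest: a disk in field coordinates.

    ``source`` records whether the disk was detected from the marker
    channel or fell back to the nominal printed-spot geometry.
    """

    center: tuple[float, float]
    radius: float
    source: str = "detected"

    def contains(self, r, c) -> np.ndarray:
        dr = np.asarray(r, float) - self.center[0]
        dc = np.asarray(c, float) - self.center[1]
        return dr * dr + dc * dc <= self.radius * self.radius


def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    """Check a layout table; errors carry the 1-based data row number."""
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout is missing column {missing[0]!r}")
    for i, row in enumerate(layout.itertuples(index=False), start=1):
        if row.platform not in SUBPOSITIONS:
            raise ValueError(f"layout row {i}: unknown platform {row.platform!r}")
        try:
            int(row.replicate)
            int(row.subposition)
        except (TypeError, ValueError):
            raise ValueError(
                f"layout row {i}: replicate/subposition must be integers"
            ) from None
    keys = layout[["replicate", "position", "subposition"]]
    dup = keys.duplicated()
    if dup.any():
        i = int(np.argmax(dup.to_numpy())) + 1
        raise ValueError(f"layout row {i}: duplicate (replicate, position, subposition)")
    spots = layout[layout["platform"] == "array_spot"]
    n_sub = spots.groupby(["replicate", "position"])["subposition"].nunique()
    if (n_sub > 1).any():
        pos = n_sub[n_sub > 1].index[0]
        raise ValueError(f"array spot {pos} has more than one subposition")
    return layout


def detect_spot_roi(
    marker: np.ndarray,
    pixel_size: float = 1.0,
    spot_diameter_um: float = 300.0,
) -> SpotROI:
    """Detect the transfection spot in the Cy3 marker channel.

    Otsu-thresholds the marker, takes the largest connected component and
    returns its centroid with the equivalent-circle radius.  If the
    threshold is not meaningful (unimodal blank marker, Otsu separation
    effectiveness < 0.75) or the foreground covers < 1% or > 90% of the
    field (blank or saturated marker), falls back to a centered disk with
    the nominal printed-spot radius (300 um diameter).
    """
    marker = np.asarray(marker, dtype=float)
    center = ((marker.shape[0] - 1) / 2.0, (marker.shape[1] - 1) / 2.0)
    fallback = SpotROI(center, (spot_diameter_um / 2.0) / pixel_size, "fallback")
    try:
        thr = threshold_global_otsu(marker)
    except ValueError:
        return fallback
    mask = marker >= thr
    frac = mask.mean()
    if frac < 0.01 or frac > 0.90:
        return fallback
    eta = (
        frac * (1 - frac) * (marker[mask].mean() - marker[~mask].mean()) ** 2
        / marker.var()
    )
    if eta < 0.75:
        return fallback
    labels = label_components(mask, connectivity=8)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    k = int(np.argmax(sizes))
    rr, cc = np.nonzero(labels == k)
    radius = math.sqrt(sizes[k] / math.pi)
    return SpotROI((float(rr.mean()), float(cc.mean())), radius, "detected")


def restrict_to_roi(labels: np.ndarray, roi: SpotROI) -> tuple[np.ndarray, np.ndarray]:
    """Keep nuclei whose centroid lies inside the ROI disk.

    Returns the contiguously relabelled map and the array of kept original
    labels (index i -> old label of new label i+1).
    """
    labels = np.asarray(labels)
    K = int(labels.max())
    if K == 0:
        return labels.copy(), np.array([], dtype=int)
    idx = np.arange(1, K + 1)
    cms = np.asarray(ndi.center_of_mass(labels > 0, labels, idx), dtype=float)
    inside = roi.contains(cms[:, 0], cms[:, 1])
    kept = idx[inside]
    out = np.where(np.isin(labels, kept), labels, 0)
    return relabel_sequential(out), kept


def filter_features_to_roi(features: pd.DataFrame, roi: SpotROI) -> pd.DataFrame:
    """Feature rows whose centroid lies inside the ROI disk."""
    inside = roi.contains(
        features["centroid_r"].to_numpy(), features["centroid_c"].to_numpy()
    )
    return features.loc[inside].reset_index(drop=True)


def _pool(rows: pd.DataFrame) -> dict:
    n = int(rows["n_cells"].sum())
    out = {
        "n_cells": n,
        "n_subpositions": len(rows),
        "frac_normal": math.nan,
        "frac_spindle": math.nan,
        "frac_cytokinesis": math.nan,
        "mean_egf": math.nan,
    }
    if n > 0:
        for cls in ("normal", "spindle", "cytokinesis"):
            out[f"frac_{cls}"] = float(rows[f"n_{cls}"].sum()) / n
    if "mean_egf" in rows and "n_egf_cells" in rows:
        ok = rows["mean_egf"].notna() & (rows["n_egf_cells"] > 0)
        ncells = rows.loc[ok, "n_egf_cells"].to_numpy(float)
        if ncells.sum() > 0:
            vals = rows.loc[ok, "mean_egf"].to_numpy(float)
            out["mean_egf"] = float((vals * ncells).sum() / ncells.sum())
    return out


def aggregate_position(field_rows: pd.DataFrame) -> dict:
    """Pool the subposition readouts of one (replicate, position).

    Fractions and the EGF mean are cell-weighted: pooled totals divided by
    total cells, equal to recomputation from the concatenated per-cell
    labels and invariant to subposition order.
    """
    if len(field_rows) == 0:
        raise ValueError("no subpositions to aggregate")
    return _pool(field_rows)


def aggregate_screen(field_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-field table into the per-position readout table.

    Positions with zero total cells are flagged with a warning and
    excluded (their fractions are undefined).
    """
    rows = []
    for (rep, platform, pos, cond), grp in field_table.groupby(
        ["replicate", "platform", "position", "condition"], sort=True
    ):
        pooled = _pool(grp)
        if pooled["n_cells"] == 0:
            warnings.warn(
                f"position {pos!r} (replicate {rep}) has zero cells; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {"replicate": rep, "platform": platform, "position": pos, "condition": cond}
            | pooled
        )
    return pd.DataFrame(rows, columns=READOUT_COLUMNS)


def normalize_egf(
    table: pd.DataFrame, mode: str = "percent_of_nc", nc_condition: str = "NC"
) -> pd.DataFrame:
    """Add a ``mean_egf_pct`` column normalized per replicate.

    Modes: ``percent_of_nc`` (100 = mean over the negative-control
    positions of that replicate), ``percent_of_max_position`` (100 = the
    brightest position) or ``raw`` (copy of mean_egf).
    """
    if mode not in ("percent_of_nc", "percent_of_max_position", "raw"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = table.copy()
    out["mean_egf_pct"] = np.nan
    for rep, grp in table.groupby("replicate"):
        if mode == "raw":
            baseline = 100.0
        elif mode == "percent_of_nc":
            nc = grp.loc[grp["condition"] == nc_condition, "mean_egf"]
            if len(nc) == 0:
                raise ValueError(
                    f"no {nc_condition!r} positions in replicate {rep}"
                )
            baseline = float(nc.mean())
        else:
            baseline = float(grp["mean_egf"].max())
        if not baseline or not np.isfinite(baseline):
            raise ValueError(f"zero or undefined baseline in replicate {rep}")
        out.loc[grp.index, "mean_egf_pct"] = 100.0 * grp["mean_egf"] / baseline
    return out


def normalize_cell_counts(
    table: pd.DataFrame,
    nc_condition: str = "NC",
    replicates: list | None = None,
) -> pd.DataFrame:
    """Remaining-cell percentage per condition relative to the negative
    control: per replicate, 100 * mean position cell count / mean NC cell
    count, then averaged over the selected replicates."""
    if replicates is not None:
        table = table[table["replicate"].isin(replicates)]
    per_rep = []
    for rep, grp in table.groupby("replicate"):
        nc = grp.loc[grp["condition"] == nc_condition, "n_cells"]
        if len(nc) == 0:
            raise ValueError(f"no {nc_condition!r} positions in replicate {rep}")
        base = float(nc.mean())
        means = grp.groupby("condition")["n_cells"].mean()
        per_rep.append(100.0 * means / base)
    merged = pd.concat(per_rep, axis=1).mean(axis=1)
    return merged.rename("pct_of_nc").reset_index()
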