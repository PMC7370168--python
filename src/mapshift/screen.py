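"""Plate-based antigen-import screen analytics.

The readout per well is the percentage of live cells with a high
blue/green fluorescence ratio (cytosolic arrival of a beta-lactamase
reporter).  Each 96-well plate carries three media-only, DMSO (vehicle),
enhancer-control and inhibitor-control wells.  Analysis steps: cell-count
QC, per-plate normalization to the media-well mean, fold-change hit calling
against vehicle, monotone-spline dose-response EC50 estimation for the
validation screen, Fisher-exact target/class enrichment, and a
physicochemical lysosomotropism flag (weakly basic amphiphilic compounds,
pKa 6.5-11 and logP > 2, accumulate in acidic endolysosomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

WELL_TYPES = ("media", "vehicle", "enhancer_control", "inhibitor_control", "compound")
DEFAULT_MIN_CELLS = 500
DEFAULT_FOLD_CUT = 2.0
DOSE_SERIES_UM = (1.25, 2.5, 5.0, 10.0, 20.0, 40.0)


@dataclass
class DoseResponse:
    """Per-compound dose-response summary.

    ``ec50_um`` is None when censored; ``censored`` is ``"above_max"`` when
    the half-effect is not reached within the tested range, ``"below_min"``
    when the lowest dose is already past it, and ``None`` otherwise.
    ``not_plateaued`` warns that the fitted curve is still rising at the top
    concentration, so the EC50 may be underestimated.
    """

    compound_id: str
    concentrations_um: np.ndarray
    responses: np.ndarray
    ec50_um: float | None
    censored: str | None = None
    not_plateaued: bool = False


def qc_wells(wells: pd.DataFrame, min_cells: int = DEFAULT_MIN_CELLS) -> pd.DataFrame:
    """Drop wells with fewer than ``min_cells`` cells; log removals per plate."""
    low = wells["n_cells"] < min_cells
    if low.any():
        for plate, n in wells.loc[low, "plate_id"].value_counts().items():
            logger.info("qc_wells: plate %s: excluded %d low-count wells", plate, n)
    return wells.loc[~low].copy()


def normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Divide each well's response by its own plate's media-well mean.

    Removes multiplicative plate effects exactly; plates without a surviving
    media well cannot be normalized and are dropped with an error record in
    the ``excluded_plates`` attribute of the returned frame.
    """
    out = []
    excluded = []
    for plate, sub in wells.groupby("plate_id", sort=False):
        media = sub.loc[sub["well_type"] == "media", "response"]
        if media.empty:
            excluded.append(plate)
            logger.error("normalize_plate: plate %s has no media wells; excluded", plate)
            continue
        sub = sub.copy()
        sub["normalized_response"] = sub["response"] / media.mean()
        out.append(sub)
    if not out:
        raise ValueError("no plate with media wells")
    result = pd.concat(out, ignore_index=True)
    result.attrs["excluded_plates"] = excluded
    return result


def call_primary_hits(
    normalized: pd.DataFrame, fold_cut: float = DEFAULT_FOLD_CUT
) -> pd.DataFrame:
    """Fold change of each compound over its plate's vehicle mean; rank hits.

    Fold >= ``fold_cut`` ("at least 2-fold", inclusive) marks a hit.
    Compounds measured on several plates/wells are averaged after the
    per-plate vehicle referencing.
    """
    rows = []
    for plate, sub in normalized.groupby("plate_id", sort=False):
        vehicle = sub.loc[sub["well_type"] == "vehicle", "normalized_response"]
        if vehicle.empty:
            raise ValueError(f"plate {plate} has no vehicle wells")
        ref = vehicle.mean()
        compounds = sub[sub["well_type"] == "compound"].copy()
        compounds["fold_change"] = compounds["normalized_response"] / ref
        rows.append(compounds)
    folds = (
        pd.concat(rows, ignore_index=True)
        .groupby("compound_id", sort=False)["fold_change"]
        .mean()
        .sort_values(ascending=False)
    )
    return pd.DataFrame({"fold_change": folds, "hit": folds >= fold_cut})


def fit_ec50(
    concentrations_um,
    responses,
    compound_id: str = "",
    plateau_tol: float = 0.05,
    baseline: float | None = 1.0,
) -> DoseResponse:
    """Monotone spline dose-response fit and half-effect EC50.

    Responses (normalized, possibly in duplicate per concentration) are
    log2(x+1) transformed, averaged per concentration, forced monotone by
    isotonic regression and interpolated with a monotone cubic (PCHIP) spline
    against log concentration.  The EC50 is the concentration at which the
    fitted curve, back on the raw response scale, crosses halfway between
    the curve bottom and its maximum (50% of maximal activity).  Because
    plate normalization maps the no-drug response to 1, the bottom is the
    known ``baseline`` (or the fitted minimum if that lies below it); pass
    ``baseline=None`` to use the fitted minimum alone.  Censoring flags mark
    series that never reach (or start beyond) the half-effect, and
    ``not_plateaued`` marks curves still rising at the top dose, where the
    maximal effect -- and hence the EC50 -- may be underestimated.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    resp = np.asarray(responses, dtype=float)
    keep = np.isfinite(conc) & np.isfinite(resp)
    conc, resp = conc[keep], resp[keep]
    levels = np.unique(conc)
    if levels.size < 4:
        raise ValueError("need at least 4 usable concentration points")
    transformed = np.log2(resp + 1.0)
    means = np.array([transformed[conc == c].mean() for c in levels])
    x = np.log10(levels)

    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(x, means)
    if not np.allclose(fitted, means, atol=0.25 * max(np.ptp(means), 1e-12)):
        logger.warning("fit_ec50(%s): markedly non-monotone series", compound_id)
    # strictly increasing x, monotone y -> monotone interpolant; the spline is
    # fit on the variance-stabilized log2(x+1) scale, then mapped back to the
    # raw response scale where the half-effect is defined
    spline = PchipInterpolator(x, fitted)
    grid = np.linspace(x[0], x[-1], 512)
    curve = np.exp2(spline(grid)) - 1.0

    lo, hi = curve.min(), curve.max()
    if baseline is not None:
        lo = min(lo, baseline)
    half = lo + 0.5 * (hi - lo)
    span = hi - lo
    flat = span <= 1e-9 * max(abs(hi), 1.0)

    # plateau check: still rising over the last half-log step at the top dose
    tail_rise = curve[-1] - (np.exp2(spline(max(grid[-1] - 0.5, grid[0]))) - 1.0)
    not_plateaued = (not flat) and tail_rise > plateau_tol * span

    if flat:
        return DoseResponse(compound_id, levels, resp, None, "above_max", False)
    above = curve >= half
    if above[0]:
        return DoseResponse(compound_id, levels, resp, float(levels[0]),
                            "below_min", not_plateaued)
    if not above.any():
        return DoseResponse(compound_id, levels, resp, None, "above_max", not_plateaued)
    j = int(np.argmax(above))
    # linear interpolation of the crossing in log-concentration
    x0, x1 = grid[j - 1], grid[j]
    y0, y1 = curve[j - 1], curve[j]
    x_half = x0 + (half - y0) / (y1 - y0) * (x1 - x0)
    return DoseResponse(
        compound_id, levels, resp, float(10**x_half), None, not_plateaued
    )


def enrichment_fisher(
    compounds: pd.DataFrame,
    active_col: str = "active",
    annotation_col: str = "primary_target",
) -> pd.DataFrame:
    """Per-annotation Fisher exact enrichment of active compounds.

    Each compound contributes at most one primary annotation.  For every
    annotation a 2x2 table (active/inactive x has/lacks the annotation) is
    tested two-sided; odds ratios of degenerate tables are reported as NaN.
    p-values are reported raw and Benjamini-Hochberg adjusted.
    """
    active = compounds[active_col].astype(bool)
    annotations = compounds[annotation_col]
    rows = []
    for target in sorted(annotations.dropna().unique()):
        has = annotations == target
        table = np.array(
            [
                [int((active & has).sum()), int((active & ~has).sum())],
                [int((~active & has).sum()), int((~active & ~has).sum())],
            ]
        )
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            odds = np.nan  # degenerate margin: odds ratio undefined
        rows.append(
            {
                annotation_col: target,
                "n_active_with": table[0, 0],
                "n_active_without": table[0, 1],
                "n_inactive_with": table[1, 0],
                "n_inactive_without": table[1, 1],
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        _, p_adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["p_adj"] = p_adj
    return out


def lysosomotropic_flag(pka: float | None, logp: float | None) -> bool | None:
    """Physicochemical lysosomotropism rule: 6.5 <= pKa <= 11 and logP > 2.

    Returns None (unknown) when either property is missing.
    """
    if pka is None or logp is None or not np.isfinite(pka) or not np.isfinite(logp):
        return None
    return bool(6.5 <= pka <= 11.0 and logp > 2.0)


def summarize_screen(
    primary_hits: int, validated: int, library_size: int
) -> tuple[int, int]:
    """Validation rate (% of primary hits confirmed) and overall hit rate
    (% of the library validated), both rounded to the nearest integer."""
    if not 0 <= validated <= primary_hits <= library_size:
        raise ValueError("require 0 <= validated <= primary_hits <= library_size")
    if primary_hits == 0:
        logger.warning("summarize_screen: no primary hits; rates defined as 0")
        return 0, 0
    validation_rate = round(100.0 * validated / primary_hits)
    hit_rate = round(100.0 * validated / library_size)
    return int(validation_rate), int(hit_rate)
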