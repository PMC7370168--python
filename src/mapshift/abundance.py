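"""Whole-cell / cytosol ratio analyses and proteomic-ruler copy numbers.

Drug-induced abundance changes are read out from per-replicate log2
treatment-vs-reference ratios: a percentile-based robust outlier test
("Significance A") calls per-replicate changes, replicate-consistent calls
become hits, and cytosolic leakage shows up as a mean treatment-minus-control
shift that is restricted to the cytosol fraction.  Distributional contrasts
(e.g. soluble lysosomal proteins versus the whole proteome) use the
two-sample Kolmogorov-Smirnov test.  Absolute copy numbers per cell are
anchored to chromatin via the proteomic ruler: total histone MS intensity is
equated with the cell's DNA mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23
MEAN_BASE_PAIR_MASS_G_PER_MOL = 615.8771
DEFAULT_GENOME_SIZE_BP = 2_700_000_000  # mouse haploid genome
DEFAULT_PLOIDY = 2


def median_normalize(ratios: pd.DataFrame) -> pd.DataFrame:
    """Linearly normalize each experiment (column) to a median ratio of 1.

    Expects linear (not log) ratios; apply before taking logs.
    """
    med = ratios.median(axis=0)
    if (med <= 0).any():
        raise ValueError("non-positive column median")
    return ratios / med


def significance_a(
    log_ratios: Sequence[float] | pd.Series, two_sided: bool = True
) -> pd.Series:
    """Percentile-based robust outlier p-values for log ratios.

    With r0 the median, r1 the 84.13th and r-1 the 15.87th percentile, the
    robust z of a value r is (r - r0)/(r1 - r0) above the median and
    (r0 - r)/(r0 - r-1) below it; the percentile spread plays the role of an
    asymmetric standard deviation.  The one-sided tail is
    0.5*erfc(z/sqrt(2)); the default doubles it so that p is uniform on (0,1)
    for symmetric null input, which is what downstream FDR control consumes.
    """
    values = pd.Series(log_ratios, dtype=float)
    if values.notna().sum() < 30:
        raise ValueError("need at least 30 values for stable percentiles")
    finite = values.dropna()
    r_lo, r0, r_hi = np.percentile(finite, [15.87, 50.0, 84.13])
    if r_hi == r0 or r0 == r_lo:
        raise ValueError("degenerate percentiles: no spread around the median")
    z = np.where(
        values >= r0, (values - r0) / (r_hi - r0), (r0 - values) / (r0 - r_lo)
    )
    p = 0.5 * special.erfc(z / np.sqrt(2.0))
    if two_sided:
        p = np.minimum(2.0 * p, 1.0)
    return pd.Series(p, index=values.index, name="p")


@dataclass
class RatioExperiment:
    """One replicate of a ratio readout: per-protein log2 ratios.

    ``condition`` is ``whole_cell`` or ``cytosol``; ``drug`` names the
    treatment in the light channel (``vehicle`` for DMSO controls).
    """

    condition: str
    drug: str
    replicate: int
    log2_ratios: pd.Series  # index protein_id
    min_events_ok: pd.Series | None = None  # quantification-event filter


def _significant(log2_ratios: pd.Series, fdr: float) -> pd.Series:
    p = significance_a(log2_ratios)
    reject, _, _, _ = multipletests(p.to_numpy(), alpha=fdr, method="fdr_bh")
    return pd.Series(reject, index=log2_ratios.index)


def call_whole_cell_hits(
    experiments: Iterable[RatioExperiment], fdr: float = 0.05
) -> tuple[dict[str, pd.Index], pd.Index]:
    """Replicate-consistent whole-cell abundance hits per drug.

    A protein is a hit for one drug when Significance A flags it at the given
    Benjamini-Hochberg FDR within *each* of that drug's replicates and the
    direction of change agrees.  Common hits additionally require
    significance and a consistent direction in all four measurements (both
    replicates of both drugs).
    """
    by_drug: dict[str, list[RatioExperiment]] = {}
    for exp in experiments:
        if exp.condition != "whole_cell":
            raise ValueError("call_whole_cell_hits expects whole_cell experiments")
        by_drug.setdefault(exp.drug, []).append(exp)

    hits: dict[str, pd.Index] = {}
    per_exp: list[tuple[pd.Series, pd.Series]] = []
    for drug, exps in by_drug.items():
        flags, signs = [], []
        for exp in exps:
            sig = _significant(exp.log2_ratios, fdr)
            sign = np.sign(exp.log2_ratios)
            flags.append(sig)
            signs.append(sign)
            per_exp.append((sig, sign))
        all_sig = pd.concat(flags, axis=1).all(axis=1)
        sign_frame = pd.concat(signs, axis=1)
        consistent = (sign_frame.nunique(axis=1) == 1) & (sign_frame.iloc[:, 0] != 0)
        hits[drug] = all_sig.index[all_sig & consistent]

    sig_all = pd.concat([s for s, _ in per_exp], axis=1).all(axis=1)
    sign_all = pd.concat([g for _, g in per_exp], axis=1)
    consistent_all = (sign_all.nunique(axis=1) == 1) & (sign_all.iloc[:, 0] != 0)
    common = sig_all.index[sig_all & consistent_all]
    return hits, common


def cytosol_shift(
    experiments: Iterable[RatioExperiment], min_events: int = 3
) -> pd.DataFrame:
    """Mean treatment-minus-control cytosolic log ratio per drug.

    Averages each protein's median-normalized log ratios over the four
    replicates of each condition and subtracts the vehicle average from each
    treatment average.  Proteins lacking ``min_events`` quantification events
    in any replicate of the conditions being compared are dropped.
    """
    by_drug: dict[str, list[RatioExperiment]] = {}
    for exp in experiments:
        if exp.condition != "cytosol":
            raise ValueError("cytosol_shift expects cytosol experiments")
        by_drug.setdefault(exp.drug, []).append(exp)
    if "vehicle" not in by_drug:
        raise ValueError("a vehicle (DMSO) condition is required")

    def mean_and_ok(exps: list[RatioExperiment]) -> tuple[pd.Series, pd.Series]:
        ratios = pd.concat([e.log2_ratios for e in exps], axis=1)
        if any(e.min_events_ok is not None for e in exps):
            ok = pd.concat(
                [
                    e.min_events_ok
                    if e.min_events_ok is not None
                    else pd.Series(True, index=ratios.index)
                    for e in exps
                ],
                axis=1,
            ).fillna(False).all(axis=1)
        else:
            ok = ratios.notna().all(axis=1)
        return ratios.mean(axis=1), ok

    control_mean, control_ok = mean_and_ok(by_drug["vehicle"])
    out = {}
    for drug, exps in by_drug.items():
        if drug == "vehicle":
            continue
        treat_mean, treat_ok = mean_and_ok(exps)
        keep = control_ok & treat_ok
        out[drug] = (treat_mean - control_mean).where(keep)
    return pd.DataFrame(out)


def compare_group_distribution(
    group_values: Sequence[float], all_values: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov contrast of a protein group vs background.

    Returns (D, p).  Used e.g. to compare soluble lysosomal proteins' cytosol
    shifts against all detected proteins.
    """
    group = np.asarray(group_values, dtype=float)
    background = np.asarray(all_values, dtype=float)
    if group.size == 0 or background.size == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.ks_2samp(group, background, method="asymp")
    return float(result.statistic), float(result.pvalue)


def normalize_replicate_intensities(replicates: pd.DataFrame) -> pd.DataFrame:
    """Linearly rescale replicate intensity columns to a common summed total."""
    totals = replicates.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("non-positive replicate intensity total")
    return replicates * (totals.mean() / totals)


def proteomic_ruler(
    intensities: pd.Series,
    molecular_weights_kda: pd.Series,
    histone_ids: Iterable[str],
    genome_size_bp: int = DEFAULT_GENOME_SIZE_BP,
    ploidy: int = DEFAULT_PLOIDY,
    cell_volume_l: float | None = None,
) -> pd.DataFrame:
    """Estimate protein copies per cell by anchoring histones to DNA mass.

    Intensities are scaled to molecular mass (I/MW tracks molar amount); the
    summed histone intensity is equated with the cell's DNA mass
    m_DNA = genome_size_bp * ploidy * 615.8771 g/mol / N_A, giving

        copies_i = (I_i / MW_i[Da]) * m_DNA * N_A / sum_h I_h .

    Copy numbers are invariant to a global intensity rescaling and linear in
    I_i/MW_i.  If ``cell_volume_l`` is given, a molar cellular concentration
    column is added.
    """
    histones = [h for h in histone_ids if h in intensities.index]
    if not histones:
        raise ValueError("no histone anchor proteins found in the intensity table")
    mw_da = molecular_weights_kda.loc[intensities.index] * 1000.0
    if (mw_da <= 0).any():
        raise ValueError("molecular weights must be positive")
    m_dna_g = genome_size_bp * ploidy * MEAN_BASE_PAIR_MASS_G_PER_MOL / AVOGADRO
    histone_intensity = float(intensities.loc[histones].sum())
    copies = (intensities / mw_da) * m_dna_g * AVOGADRO / histone_intensity
    out = pd.DataFrame({"copies_per_cell": copies})
    if cell_volume_l is not None:
        out["concentration_nM"] = copies / AVOGADRO / cell_volume_l * 1e9
    return out
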