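"""MR (movement / reproducibility) analysis of comparative organellar maps.

Detects drug-induced protein translocations by contrasting treatment maps
against control maps that share a single heavy-labelled reference fraction.
The procedure:

1. normalize the six maps onto a common scale (column-median, ratio
   inversion, fraction-yield weighting, prep-yield equalization);
2. form per-protein "delta" profiles (treatment minus control, per
   replicate) after a within-treatment rescaling of each protein's twenty
   data points;
3. score movement (M) as -log10 of the Benjamini-Hochberg adjusted p-value
   of a robust multivariate outlier test on the ten-point combined delta,
   and reproducibility (R) as the Pearson correlation of the two replicate
   deltas;
4. call hits at M > 4 and R > 0.8.

An M score of 4 corresponds to an FDR of 0.01%; R = 0.8 is the critical
one-sided Pearson correlation at p = 0.05 for five paired points (3 df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_M_CUT = 4.0
DEFAULT_R_CUT = 0.8


@dataclass
class MapSet:
    """Per-(condition, replicate) 5-fraction matrices over a shared protein set.

    ``values`` holds raw H/L ratios before :func:`mr_normalize` and
    normalized abundances afterwards.  ``fraction_yields`` is the protein
    mass recovered in each pellet (BCA assay), one 5-vector per map.
    """

    values: dict[tuple[str, int], pd.DataFrame]
    fraction_yields: dict[tuple[str, int], np.ndarray]
    normalized: bool = False
    prep_yield_factors: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = list(self.values)
        if not keys:
            raise ValueError("empty map set")
        index = self.values[keys[0]].index
        for key in keys[1:]:
            if not self.values[key].index.equals(index):
                raise ValueError("all maps must share an identical protein index")
        for key, y in self.fraction_yields.items():
            y = np.asarray(y, dtype=float)
            if y.shape != (self.values[key].shape[1],) or np.any(y <= 0):
                raise ValueError(f"fraction yields for map {key} must be positive")
            self.fraction_yields[key] = y

    @property
    def conditions(self) -> list[str]:
        return sorted({condition for condition, _ in self.values})

    @property
    def proteins(self) -> pd.Index:
        return next(iter(self.values.values())).index

    def replicates(self, condition: str) -> list[int]:
        return sorted(r for c, r in self.values if c == condition)


@dataclass
class DeltaProfileSet:
    """Per-protein treatment-minus-control profiles.

    ``deltas`` maps replicate -> protein x 5 frame; ``combined`` is the
    10-column concatenation of the two replicate deltas, in replicate order.
    """

    treatment: str
    control: str
    deltas: dict[int, pd.DataFrame]
    combined: pd.DataFrame


def mr_normalize(mapset: MapSet) -> MapSet:
    """Normalize raw H/L ratio maps onto a common abundance scale.

    In order: (1) within each fraction (column) of each map, divide ratios by
    the column median; (2) invert each ratio (heavy is the shared reference,
    so the inverse tracks the light subfraction's abundance); (3) weight each
    fraction by its measured yield; (4) sum each map (its "prep yield"), set
    the smallest prep yield to one, and divide every map by its correction
    factor relative to that smallest yield.  Afterwards all map grand totals
    are equal.
    """
    if mapset.normalized:
        raise ValueError("map set is already normalized")
    weighted: dict[tuple[str, int], pd.DataFrame] = {}
    for key, frame in mapset.values.items():
        values = frame.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)) or np.any(values <= 0):
            raise ValueError(f"map {key} contains missing or non-positive ratios")
        medians = np.median(values, axis=0)
        if np.any(medians == 0):
            raise ValueError(f"map {key} has a zero column median")
        values = values / medians
        values = 1.0 / values
        if np.any(~np.isfinite(values)):
            raise ValueError(f"map {key} produced non-finite inverted ratios")
        values = values * mapset.fraction_yields[key]
        weighted[key] = pd.DataFrame(values, index=frame.index, columns=frame.columns)

    prep_yields = {key: float(frame.to_numpy().sum()) for key, frame in weighted.items()}
    smallest = min(prep_yields.values())
    factors = {key: y / smallest for key, y in prep_yields.items()}
    normalized = {key: frame / factors[key] for key, frame in weighted.items()}
    return MapSet(
        values=normalized,
        fraction_yields=dict(mapset.fraction_yields),
        normalized=True,
        prep_yield_factors=factors,
    )


def compute_deltas(
    normalized: MapSet, treatment: str, control: str = "control"
) -> DeltaProfileSet:
    """Form delta profiles for one treatment against the shared control.

    Per protein, the ten treatment and ten control data points are divided by
    their joint sum (a within-treatment normalization), then the control
    profile is subtracted from the treatment profile within each replicate.
    """
    if not normalized.normalized:
        raise ValueError("run mr_normalize first")
    reps = normalized.replicates(treatment)
    if reps != normalized.replicates(control) or len(reps) != 2:
        raise ValueError("expected two matched replicates per condition")

    stacked = np.concatenate(
        [normalized.values[(treatment, r)].to_numpy(dtype=float) for r in reps]
        + [normalized.values[(control, r)].to_numpy(dtype=float) for r in reps],
        axis=1,
    )  # n x 20
    totals = stacked.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("non-positive per-protein total in delta normalization")
    stacked = stacked / totals

    n_frac = normalized.values[(treatment, reps[0])].shape[1]
    deltas: dict[int, pd.DataFrame] = {}
    pieces = []
    index = normalized.proteins
    for i, r in enumerate(reps):
        t = stacked[:, i * n_frac : (i + 1) * n_frac]
        c = stacked[:, (2 + i) * n_frac : (3 + i) * n_frac]
        delta = t - c
        columns = [f"rep{r}_{f}" for f in normalized.values[(treatment, r)].columns]
        deltas[r] = pd.DataFrame(delta, index=index, columns=columns)
        pieces.append(deltas[r])
    combined = pd.concat(pieces, axis=1)
    return DeltaProfileSet(
        treatment=treatment, control=control, deltas=deltas, combined=combined
    )


def robust_outlier_pvalues(
    combined_deltas: pd.DataFrame | np.ndarray,
    iterations: int = 101,
    subset_quantile: float = 0.75,
    seed: int | None = None,
    ridge: float = 1e-10,
) -> pd.Series:
    """Robust multivariate outlier p-values for combined delta profiles.

    An iterated trimmed estimator: starting from the classical mean and
    covariance, each iteration recomputes both from the ``subset_quantile``
    fraction of rows with the smallest current squared Mahalanobis distance,
    for ``iterations`` rounds or until the retained subset stabilizes.
    Distances are rescaled so the retained subset's median distance matches
    the corresponding chi-squared quantile (df = number of columns), then
    converted to upper-tail chi-squared p-values.

    ``seed`` only breaks distance ties in the subset selection; the
    estimator is otherwise deterministic.
    """
    X = np.asarray(
        combined_deltas.to_numpy() if hasattr(combined_deltas, "to_numpy") else combined_deltas,
        dtype=float,
    )
    n, d = X.shape
    if n <= 4 * d:
        raise ValueError(f"need more than {4 * d} rows to estimate a {d}-dim scatter")
    rng = np.random.default_rng(seed)
    h = int(np.ceil(n * subset_quantile))

    def mahal_sq(center: np.ndarray, cov: np.ndarray) -> np.ndarray:
        cov = cov.copy()
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            logger.warning("singular robust covariance; adding ridge term")
            cov[np.diag_indices_from(cov)] += ridge * max(np.trace(cov) / d, 1.0)
            chol = np.linalg.cholesky(cov)
        y = np.linalg.solve(chol, (X - center).T)
        return np.einsum("ij,ij->j", y, y)

    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    subset = None
    d2 = mahal_sq(center, cov)
    for _ in range(iterations):
        # random jitter breaks exact distance ties deterministically per seed
        order = np.argsort(d2 + rng.uniform(0, 1e-12, size=n), kind="stable")
        new_subset = np.sort(order[:h])
        if subset is not None and np.array_equal(new_subset, subset):
            break
        subset = new_subset
        center = X[subset].mean(axis=0)
        cov = np.cov(X[subset], rowvar=False)
        d2 = mahal_sq(center, cov)

    # consistency: the subset median sits at overall quantile ~h/(2n)
    target = stats.chi2.ppf(h / (2.0 * n), df=d)
    scale = target / np.median(d2[subset])
    p = stats.chi2.sf(d2 * scale, df=d)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    index = (
        combined_deltas.index
        if isinstance(combined_deltas, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    return pd.Series(p, index=index, name="p_raw")


def m_scores(p_raw: pd.Series) -> pd.DataFrame:
    """Benjamini-Hochberg adjust raw p-values and convert to M scores.

    M = -log10(adjusted p); the adjustment family is all proteins tested for
    one treatment.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("raw p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"p_raw": p, "p_adj": p_adj, "M": -np.log10(p_adj)}, index=p_raw.index
    )


def r_scores(deltas: DeltaProfileSet) -> pd.Series:
    """Pearson correlation of the two replicate delta profiles per protein.

    A constant delta in either replicate leaves R undefined (NaN); such
    proteins are flagged non-reproducible and never called as hits.
    """
    reps = sorted(deltas.deltas)
    a = deltas.deltas[reps[0]].to_numpy(dtype=float)
    b = deltas.deltas[reps[1]].to_numpy(dtype=float)
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum(axis=1) * (b_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a_c * b_c).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return pd.Series(r, index=deltas.combined.index, name="R")


def call_translocations(
    results: dict[str, pd.DataFrame],
    m_cut: float = DEFAULT_M_CUT,
    r_cut: float = DEFAULT_R_CUT,
) -> tuple[dict[str, pd.Index], pd.Index]:
    """Hits per treatment (M > m_cut and R > r_cut) and the shared-hit set."""
    hits: dict[str, pd.Index] = {}
    shared: pd.Index | None = None
    for treatment, frame in results.items():
        flag = (frame["M"] > m_cut) & (frame["R"] > r_cut)
        flag &= frame["R"].notna()
        hits[treatment] = frame.index[flag]
        shared = hits[treatment] if shared is None else shared.intersection(
            hits[treatment]
        )
    return hits, shared if shared is not None else pd.Index([])


def run_mr(
    mapset: MapSet,
    treatments: list[str] | None = None,
    control: str = "control",
    iterations: int = 101,
    subset_quantile: float = 0.75,
    m_cut: float = DEFAULT_M_CUT,
    r_cut: float = DEFAULT_R_CUT,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Full MR pipeline: normalize, delta, outlier test, M/R scores, hits.

    Returns one frame per treatment with columns p_raw, p_adj, M, R, hit.
    """
    normalized = mr_normalize(mapset) if not mapset.normalized else mapset
    if treatments is None:
        treatments = [c for c in normalized.conditions if c != control]
    results: dict[str, pd.DataFrame] = {}
    for treatment in treatments:
        deltas = compute_deltas(normalized, treatment, control)
        p_raw = robust_outlier_pvalues(
            deltas.combined,
            iterations=iterations,
            subset_quantile=subset_quantile,
            seed=seed,
        )
        frame = m_scores(p_raw)
        frame["R"] = r_scores(deltas)
        frame["hit"] = (frame["M"] > m_cut) & (frame["R"] > r_cut) & frame["R"].notna()
        results[treatment] = frame
    return results
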