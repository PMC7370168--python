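"""Synthetic data with ground truth for every analysis stage.

Emulates the study design end to end: 5-fraction SILAC fractionation
profiles clustered by organellar compartment across three conditions
(control plus two drug treatments) in duplicate with one shared heavy
reference, injected translocating proteins, per-fraction and per-map yields;
whole-cell and cytosol ratio experiments with a planted "leaked" subset; and
a plate-based small-molecule screen with dose-responsive hits.

All generators are deterministic given (config, seed), and every generated
dataset is accompanied by its ground truth.  Ground truth is consumed only
by tests and benchmarks, never by the analysis modules themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .mapping import MarkerSet
from .mr_analysis import MapSet
from .profiles_io import MAP_FRACTIONS

N_FRACTIONS = len(MAP_FRACTIONS)


@dataclass
class ScreenConfig:
    n_compounds: int = 786
    compounds_per_plate: int = 84  # + 3 wells each of 4 control types = 96
    true_hit_fraction: float = 0.045
    primary_dose_um: float = 20.0
    dose_series_um: tuple[float, ...] = (1.25, 2.5, 5.0, 10.0, 20.0, 40.0)
    baseline_response_pct: float = 5.0
    max_fold_low: float = 3.0
    max_fold_high: float = 6.0
    ec50_low_um: float = 2.0
    ec50_high_um: float = 30.0
    hill: float = 2.5
    response_cv: float = 0.10
    plate_effect_sd: float = 0.15  # sd of log plate factor
    low_cell_fraction: float = 0.02
    mean_cells: int = 2000
    min_cells_low: int = 100
    min_cells_high: int = 499


@dataclass
class AbundanceConfig:
    n_proteins: int = 2000
    n_leaked: int = 100
    leak_log2_shift: float = 2.0
    n_whole_cell_changed: int = 0
    whole_cell_log2_change: float = 2.0
    ratio_noise_sd: float = 0.3  # sd of null log2 ratios
    replicate_offset_sd: float = 0.2  # per-replicate global log2 offset


@dataclass
class SimulationConfig:
    """Default parameters mirror the study conditions: ~2000 mapped proteins,
    559 markers over 12 compartments, duplicate maps for a control and two
    treatments sharing one reference, and a 786-compound screen."""

    seed: int = 0
    n_proteins: int = 2000
    n_compartments: int = 12
    n_markers: int = 559
    profile_noise_sd: float = 0.02
    protein_heterogeneity_sd: float = 0.05  # protein-specific offset from its
    # compartment mean, constant across maps (multi-localization, gradients);
    # cancels in treatment-control deltas but spreads clusters realistically
    treatments: tuple[str, ...] = ("tamoxifen", "prazosin")
    n_replicates: int = 2
    n_movers: int = 20
    shared_mover_fraction: float = 0.4  # movers common to both treatments
    mover_theta: float = 0.5
    min_compartment_l1_sep: float = 0.45
    minor_axis_shrink: float = 0.35  # near-planar centroid geometry of real maps
    profile_floor: float = 0.10  # uniform admixture: reference spiking keeps
    # every protein detectable in every fraction, so per-map profiles have a
    # soft floor rather than true zeros
    abundance_lognormal_sd: float = 1.0
    map_scale_low: float = 0.5
    map_scale_high: float = 2.0
    n_decoy_flagged: int = 10
    n_low_quality: int = 10
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    abundance: AbundanceConfig = field(default_factory=AbundanceConfig)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        screen = ScreenConfig(**raw.pop("screen", {}))
        abund = AbundanceConfig(**raw.pop("abundance", {}))
        return cls(screen=screen, abundance=abund, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)


# ---------------------------------------------------------------------------
# organellar map sets


@dataclass
class MapSetTruth:
    mapset: MapSet  # raw H/L ratios + measured fraction yields
    compartments: pd.Series  # protein -> true compartment
    markers: MarkerSet  # labelled subset
    true_profiles: dict[tuple[str, int], pd.DataFrame]  # normalized, sum to 1
    movers: dict[str, pd.DataFrame]  # treatment -> (protein, source, dest, theta)
    config: SimulationConfig


def _compartment_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Compartment mean profiles: separated, near-planar, floored.

    Differential centrifugation orders organelles along a pelleting
    continuum, so real cluster centroids lie close to a plane in the
    standardized metric the map visualization uses.  A Dirichlet candidate
    pool (with a uniform-admixture floor, since the spiked reference keeps
    every protein detectable in every fraction) is flattened by shrinking
    its minor principal axes in that metric, and the means are a greedy
    farthest-point subset with the configured minimum pairwise L1
    separation.
    """
    uniform = np.full(N_FRACTIONS, 1.0 / N_FRACTIONS)
    sep = config.min_compartment_l1_sep
    k = config.n_compartments
    best: np.ndarray | None = None
    best_min = -np.inf
    for _ in range(20):
        pool = rng.dirichlet(np.ones(N_FRACTIONS) * 0.8, size=3000)
        pool = (1 - config.profile_floor) * pool + config.profile_floor * uniform
        # flatten in the per-fraction standardized metric, the same metric
        # the unit-scaled PCA visualization uses
        center = pool.mean(axis=0)
        col_sd = pool.std(axis=0)
        scaled = (pool - center) / col_sd
        _, _, vt = np.linalg.svd(scaled, full_matrices=False)
        rotated = scaled @ vt.T
        rotated[:, 2:] *= config.minor_axis_shrink
        flat = np.clip(center + (rotated @ vt) * col_sd, 1e-3, None)
        flat /= flat.sum(axis=1, keepdims=True)
        # greedy farthest-point subset in L1
        chosen = [int(np.argmax(np.abs(flat - flat.mean(axis=0)).sum(axis=1)))]
        for _ in range(k - 1):
            d = np.abs(flat[:, None, :] - flat[chosen][None, :, :]).sum(axis=2).min(axis=1)
            chosen.append(int(np.argmax(d)))
        means = flat[chosen]
        dists = np.abs(means[:, None, :] - means[None, :, :]).sum(axis=2)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= sep:
            return means
        if dists.min() > best_min:
            best, best_min = means, dists.min()
    raise RuntimeError(
        f"could not reach pairwise L1 separation {sep} "
        f"(best {best_min:.3f}); lower min_compartment_l1_sep or n_compartments"
    )


def _noisy_profiles(
    means: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    raw = means + rng.normal(0.0, noise_sd, size=means.shape)
    raw = np.clip(raw, 1e-4, None)
    return raw / raw.sum(axis=1, keepdims=True)


def generate_mapset(config: SimulationConfig, seed: int | None = None) -> MapSetTruth:
    """Simulate raw H/L ratio maps with known compartments and movers.

    The measurement model follows the experimental design: each light
    subfraction is mixed with an equal protein mass of the shared heavy
    reference, so the observed ratio H/L for protein i in fraction f of map m
    is  scale_m * yield_{f,m} * reference_i / amount_{i,f,m}, where the
    reference abundance is proportional to whole-cell abundance.  Movers in
    treatment maps draw their mean profile from the convex mixture
    (1-theta)*source + theta*destination.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_proteins
    proteins = pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")

    means = _compartment_means(config, rng)
    # compartment sizes: Dirichlet-weighted with a floor so markers fit
    per_comp_markers = np.full(config.n_compartments, config.n_markers // config.n_compartments)
    per_comp_markers[: config.n_markers % config.n_compartments] += 1
    floor = per_comp_markers + 5
    weights = rng.dirichlet(np.ones(config.n_compartments) * 5.0)
    extra = n - floor.sum()
    if extra < 0:
        raise ValueError("n_proteins too small for the marker set")
    sizes = floor + rng.multinomial(extra, weights)
    labels = np.repeat(np.arange(config.n_compartments), sizes)
    rng.shuffle(labels)
    compartments = pd.Series(
        [f"compartment_{k:02d}" for k in labels], index=proteins, name="compartment"
    )

    marker_ids: list[str] = []
    for k in range(config.n_compartments):
        members = proteins[labels == k]
        marker_ids.extend(
            rng.choice(members, size=per_comp_markers[k], replace=False)
        )
    markers = MarkerSet(entries=compartments.loc[sorted(marker_ids)].copy())

    # movers: non-marker proteins; treatments share a fraction of their
    # mover sets (drugs with a common mechanism move overlapping proteins,
    # so the per-treatment hit lists partially overlap)
    non_markers = proteins.difference(pd.Index(marker_ids))
    n_shared = int(round(config.shared_mover_fraction * config.n_movers))
    shared = rng.choice(non_markers, size=n_shared, replace=False)
    remaining = non_markers.difference(pd.Index(shared))

    def mover_frame(chosen: np.ndarray) -> pd.DataFrame:
        source = labels[proteins.get_indexer(chosen)]
        dest = np.array(
            [
                rng.choice([k for k in range(config.n_compartments) if k != s])
                for s in source
            ],
            dtype=int,
        )
        return pd.DataFrame(
            {
                "protein_id": chosen,
                "source": [f"compartment_{k:02d}" for k in source],
                "destination": [f"compartment_{k:02d}" for k in dest],
                "dest_index": dest,
                "theta": config.mover_theta,
            }
        ).set_index("protein_id")

    shared_frame = mover_frame(shared)
    movers: dict[str, pd.DataFrame] = {}
    for treatment in config.treatments:
        own = rng.choice(remaining, size=config.n_movers - n_shared, replace=False)
        movers[treatment] = pd.concat([shared_frame, mover_frame(own)])

    abundances = rng.lognormal(mean=2.0, sigma=config.abundance_lognormal_sd, size=n)
    reference = abundances  # total-membrane reference tracks abundance

    # protein-specific baseline profile: compartment mean plus a fixed
    # per-protein offset shared by all six maps
    base = means[labels] + rng.normal(
        0.0, config.protein_heterogeneity_sd, size=(n, N_FRACTIONS)
    )
    base = np.clip(base, 1e-4, None)
    base /= base.sum(axis=1, keepdims=True)

    conditions = ("control",) + tuple(config.treatments)
    ratio_maps: dict[tuple[str, int], pd.DataFrame] = {}
    yields: dict[tuple[str, int], np.ndarray] = {}
    true_profiles: dict[tuple[str, int], pd.DataFrame] = {}
    for condition in conditions:
        mean_per_protein = base
        if condition != "control" and len(movers[condition]):
            mv = movers[condition]
            idx = proteins.get_indexer(mv.index)
            theta = mv["theta"].to_numpy()[:, None]
            mean_per_protein = mean_per_protein.copy()
            mean_per_protein[idx] = (1 - theta) * mean_per_protein[idx] + theta * means[
                mv["dest_index"].to_numpy()
            ]
        for replicate in range(1, config.n_replicates + 1):
            profiles = _noisy_profiles(mean_per_protein, config.profile_noise_sd, rng)
            amounts = abundances[:, None] * profiles
            fraction_yield = amounts.sum(axis=0)
            scale = rng.uniform(config.map_scale_low, config.map_scale_high)
            ratios = scale * fraction_yield[None, :] * reference[:, None] / amounts
            key = (condition, replicate)
            ratio_maps[key] = pd.DataFrame(
                ratios, index=proteins, columns=list(MAP_FRACTIONS)
            )
            yields[key] = fraction_yield
            true_profiles[key] = pd.DataFrame(
                profiles, index=proteins, columns=list(MAP_FRACTIONS)
            )

    mapset = MapSet(values=ratio_maps, fraction_yields=yields)
    return MapSetTruth(
        mapset=mapset,
        compartments=compartments,
        markers=markers,
        true_profiles=true_profiles,
        movers=movers,
        config=config,
    )


def protein_groups_frame(
    truth: MapSetTruth, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[str, int, str]]]:
    """Render a map-set simulation as a proteinGroups-dialect table.

    Adds decoy rows (reverse / contaminant / site-only flagged) and
    low-quality rows (few quantification events) so the identification and
    high-quality filters are exercised; returns the table and the
    experiment-column schema understood by ``parse_protein_groups``.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    keys = sorted(truth.mapset.values)
    schema = {
        f"{condition}{replicate}_{fraction}": (condition, replicate, fraction)
        for condition, replicate in keys
        for fraction in MAP_FRACTIONS
    }

    proteins = truth.mapset.proteins
    n = len(proteins)
    n_decoy, n_lowq = config.n_decoy_flagged, config.n_low_quality
    all_ids = list(proteins) + [f"DECOY{i:03d}" for i in range(n_decoy)] + [
        f"LOWQ{i:03d}" for i in range(n_lowq)
    ]
    total = len(all_ids)

    frame = pd.DataFrame(
        {
            "Protein IDs": [f"{p};{p}-2" for p in all_ids],
            "Gene names": [p.lower() for p in all_ids],
            "Mol. weight [kDa]": np.round(rng.uniform(10, 250, size=total), 3),
            "Reverse": "",
            "Potential contaminant": "",
            "Only identified by site": "",
        }
    )
    flag_cols = ["Reverse", "Potential contaminant", "Only identified by site"]
    for i in range(n_decoy):
        frame.loc[n + i, flag_cols[i % 3]] = "+"

    quant_columns: dict[str, np.ndarray] = {}
    for exp_key, (condition, replicate, fraction) in schema.items():
        col_ratio = truth.mapset.values[(condition, replicate)][fraction]
        ratios = np.empty(total)
        ratios[:n] = col_ratio.to_numpy()
        ratios[n:] = rng.uniform(0.2, 5.0, size=total - n)
        counts = rng.integers(3, 12, size=total)
        variability = np.round(rng.uniform(2.0, 25.0, size=total), 2)
        # low-quality rows: one or two events with too-high variability
        counts[n + n_decoy :] = rng.integers(1, 3, size=n_lowq)
        variability[n + n_decoy :] = np.round(rng.uniform(35.0, 80.0, size=n_lowq), 2)
        quant_columns[f"Ratio H/L {exp_key}"] = np.round(ratios, 6)
        quant_columns[f"Ratio H/L count {exp_key}"] = counts
        quant_columns[f"Ratio H/L variability [%] {exp_key}"] = variability
        quant_columns[f"Intensity {exp_key}"] = np.round(
            rng.lognormal(20, 1, size=total), 1
        )
    frame = pd.concat([frame, pd.DataFrame(quant_columns)], axis=1)
    return frame, schema


def write_protein_groups(truth: MapSetTruth, path) -> dict[str, tuple[str, int, str]]:
    frame, schema = protein_groups_frame(truth)
    frame.to_csv(path, sep="\t", index=False)
    return schema


# ---------------------------------------------------------------------------
# whole-cell / cytosol ratio experiments


@dataclass
class RatioExperimentTruth:
    whole_cell: dict[tuple[str, int], pd.Series]  # (drug, replicate) -> linear ratios
    cytosol: dict[tuple[str, int], pd.Series]  # (drug, replicate) -> linear ratios
    leaked: pd.Index  # proteins leaking into the cytosol under treatment
    whole_cell_changed: pd.Index
    config: SimulationConfig


def generate_ratio_experiment(
    config: SimulationConfig, seed: int | None = None
) -> RatioExperimentTruth:
    """Simulate whole-cell (2 replicates/drug) and cytosol (4 replicates per
    condition) linear SILAC ratio tables.

    Null log2 ratios are Gaussian; a planted "leaked" subset is shifted in
    the cytosol of treated cells only, so its whole-cell ratios stay centered
    at zero.  Each replicate carries a global multiplicative offset that the
    per-experiment median normalization must remove.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ac = config.abundance
    proteins = pd.Index(
        [f"P{i:05d}" for i in range(ac.n_proteins)], name="protein_id"
    )
    leaked = pd.Index(rng.choice(proteins, size=ac.n_leaked, replace=False)).sort_values()
    changed = pd.Index(
        rng.choice(proteins.difference(leaked), size=ac.n_whole_cell_changed, replace=False)
    ).sort_values()
    change_sign = pd.Series(
        rng.choice([-1.0, 1.0], size=len(changed)), index=changed
    )

    def replicate(shift: pd.Series | None) -> pd.Series:
        log2 = rng.normal(0.0, ac.ratio_noise_sd, size=ac.n_proteins)
        series = pd.Series(log2, index=proteins)
        if shift is not None:
            series.loc[shift.index] += shift
        series += rng.normal(0.0, ac.replicate_offset_sd)  # global offset
        return np.exp2(series)

    whole_cell: dict[tuple[str, int], pd.Series] = {}
    for drug in ("tamoxifen", "prazosin"):
        wc_shift = (
            change_sign * ac.whole_cell_log2_change if len(changed) else None
        )
        for rep in (1, 2):
            whole_cell[(drug, rep)] = replicate(wc_shift)

    cytosol: dict[tuple[str, int], pd.Series] = {}
    leak_shift = pd.Series(ac.leak_log2_shift, index=leaked)
    for drug in ("vehicle", "tamoxifen", "prazosin"):
        for rep in (1, 2, 3, 4):
            cytosol[(drug, rep)] = replicate(None if drug == "vehicle" else leak_shift)

    return RatioExperimentTruth(
        whole_cell=whole_cell,
        cytosol=cytosol,
        leaked=leaked,
        whole_cell_changed=changed,
        config=config,
    )


# ---------------------------------------------------------------------------
# small-molecule screen


@dataclass
class ScreenTruth:
    primary: pd.DataFrame  # well-level table
    secondary: pd.DataFrame  # well-level table for selected compounds
    compounds: pd.DataFrame  # ground truth incl. true_hit, true_ec50_um
    config: SimulationConfig


def _logistic_fold(conc: np.ndarray, max_fold: float, ec50: float, hill: float) -> np.ndarray:
    """Fold change over baseline of a 4-parameter logistic with bottom 1."""
    c = np.asarray(conc, dtype=float)
    return 1.0 + (max_fold - 1.0) * c**hill / (c**hill + ec50**hill)


def generate_screen(config: SimulationConfig, seed: int | None = None) -> ScreenTruth:
    """Simulate primary and secondary screen plates with known hits.

    Hit compounds follow a four-parameter logistic in concentration; plates
    carry multiplicative plate effects, wells carry a fixed response CV, and
    a configurable fraction of wells falls below the cell-count QC limit.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sc = config.screen
    n = sc.n_compounds
    ids = [f"C{i + 1:04d}" for i in range(n)]
    n_hits = int(round(n * sc.true_hit_fraction))
    hit_mask = np.zeros(n, dtype=bool)
    hit_mask[rng.choice(n, size=n_hits, replace=False)] = True
    ec50 = np.where(
        hit_mask,
        np.exp(rng.uniform(np.log(sc.ec50_low_um), np.log(sc.ec50_high_um), size=n)),
        np.nan,
    )
    max_fold = np.where(hit_mask, rng.uniform(sc.max_fold_low, sc.max_fold_high, size=n), 1.0)

    # annotations: hits enriched for one primary target; physicochemistry
    # drawn so most hits satisfy the lysosomotropism rule
    targets = np.array([f"target_{rng.integers(0, 30):02d}" for _ in range(n)], dtype=object)
    targets[hit_mask & (rng.random(n) < 0.4)] = "target_enriched"
    pka = np.where(hit_mask, rng.uniform(7.0, 10.5, size=n), rng.uniform(2.0, 12.0, size=n))
    logp = np.where(hit_mask, rng.uniform(2.5, 6.0, size=n), rng.uniform(-1.0, 5.0, size=n))

    compounds = pd.DataFrame(
        {
            "compound_id": ids,
            "true_hit": hit_mask,
            "true_ec50_um": ec50,
            "max_fold": max_fold,
            "primary_target": targets,
            "pka": np.round(pka, 2),
            "logp": np.round(logp, 2),
        }
    ).set_index("compound_id")

    def well_rows(plate_id, entries, plate_factor):
        rows = []
        for well, (well_type, compound_id, conc, fold) in enumerate(entries):
            noise = rng.normal(1.0, sc.response_cv)
            response = sc.baseline_response_pct * fold * plate_factor * max(noise, 0.05)
            response = float(np.clip(response, 0.0, 100.0))
            if rng.random() < sc.low_cell_fraction:
                n_cells = int(rng.integers(sc.min_cells_low, sc.min_cells_high + 1))
            else:
                n_cells = int(rng.poisson(sc.mean_cells))
            rows.append(
                {
                    "plate_id": plate_id,
                    "well": f"W{well + 1:02d}",
                    "well_type": well_type,
                    "compound_id": compound_id,
                    "concentration_um": conc,
                    "n_cells": n_cells,
                    "response": response,
                }
            )
        return rows

    def control_entries():
        return (
            [("media", None, np.nan, 1.0)] * 3
            + [("vehicle", None, np.nan, 1.0)] * 3
            + [("enhancer_control", "DbeQ", 4.0, 4.0)] * 3
            + [("inhibitor_control", "PR-619", 10.0, 0.3)] * 3
        )

    primary_rows = []
    for start in range(0, n, sc.compounds_per_plate):
        plate_id = f"PP{start // sc.compounds_per_plate + 1:02d}"
        plate_factor = float(np.exp(rng.normal(0.0, sc.plate_effect_sd)))
        entries = control_entries()
        for i in range(start, min(start + sc.compounds_per_plate, n)):
            fold = (
                _logistic_fold(sc.primary_dose_um, max_fold[i], ec50[i], sc.hill)
                if hit_mask[i]
                else 1.0
            )
            entries.append(("compound", ids[i], sc.primary_dose_um, float(fold)))
        primary_rows.extend(well_rows(plate_id, entries, plate_factor))
    primary = pd.DataFrame(primary_rows)

    # secondary screen: all true hits plus an equal number of inactive
    # compounds, each at the full dose series in duplicate
    inactive = [i for i in range(n) if not hit_mask[i]]
    followup = sorted(
        np.flatnonzero(hit_mask).tolist()
        + rng.choice(inactive, size=min(n_hits, len(inactive)), replace=False).tolist()
    )
    secondary_rows = []
    per_plate = 7  # 7 compounds x 12 dose-wells + 12 control wells = 96
    for p, start in enumerate(range(0, len(followup), per_plate)):
        for rep_plate in (1, 2):
            plate_id = f"SP{p + 1:02d}_{rep_plate}"
            plate_factor = float(np.exp(rng.normal(0.0, sc.plate_effect_sd)))
            entries = control_entries()
            for i in followup[start : start + per_plate]:
                for conc in sc.dose_series_um:
                    fold = (
                        _logistic_fold(conc, max_fold[i], ec50[i], sc.hill)
                        if hit_mask[i]
                        else 1.0
                    )
                    entries.append(("compound", ids[i], conc, float(fold)))
            secondary_rows.extend(well_rows(plate_id, entries, plate_factor))
    secondary = pd.DataFrame(secondary_rows)

    return ScreenTruth(
        primary=primary, secondary=secondary, compounds=compounds, config=config
    )
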