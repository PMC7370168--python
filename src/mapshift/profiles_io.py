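"""Parsing, filtering and normalization of quantitative protein-group tables.

Input tables follow the MaxQuant ``proteinGroups.txt`` dialect: one row per
protein group, tab-delimited, with per-experiment quantification columns
(``Ratio H/L <exp>``, ``Ratio H/L count <exp>``,
``Ratio H/L variability [%] <exp>``, ``Intensity <exp>``) and "+"-valued flag
columns for reverse hits, contaminants and site-only identifications.

The downstream mapping pipeline works on 5-fraction abundance profiles, one
per differential-centrifugation pellet (4K, 10K, 20K, 40K and 80K x g).  A
profile is obtained by inverting the heavy/light SILAC ratios (heavy is the
spiked-in reference, so 1/ratio is proportional to the protein's abundance in
the light subfraction) and normalizing the five values to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Differential-centrifugation pellets, in spin order.
MAP_FRACTIONS: tuple[str, ...] = ("4K", "10K", "20K", "40K", "80K")

#: Flag columns of the proteinGroups dialect ("+" means true).
FLAG_COLUMNS: Mapping[str, str] = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "modified_only",
}


class SchemaError(ValueError):
    """A mandatory column is absent from the input table."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the 1-based file line number."""


@dataclass
class QuantTable:
    """Per-protein metadata plus long-format quantification measurements.

    ``proteins``: indexed by canonical protein id, with columns
    ``protein_group``, ``gene_name``, ``molecular_weight`` (kDa) and the three
    boolean flags.  ``measurements``: one row per
    (protein, condition, replicate, fraction) with ``ratio_hl``,
    ``ratio_count``, ``ratio_variability_pct`` and ``intensity``; absent
    numeric cells are NaN, never 0.
    """

    proteins: pd.DataFrame
    measurements: pd.DataFrame

    def __len__(self) -> int:
        return len(self.proteins)


def _canonical_id(group: str) -> str:
    # first accession of the semicolon-separated group is the canonical key
    return str(group).split(";")[0]


def _parse_numeric(raw: pd.Series, column: str) -> pd.Series:
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header line, one for 1-based numbering
        raise ParseError(
            f"unparseable value {raw.iloc[row]!r} in column {column!r} "
            f"at line {row + 2}"
        )
    return values


def parse_protein_groups(
    path,
    experiment_schema: Mapping[str, tuple[str, int, str]],
) -> QuantTable:
    """Read a proteinGroups-dialect table.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    experiment_schema
        Maps the experiment suffix used in the quantification column names to
        a ``(condition, replicate, fraction)`` triple, e.g.
        ``{"Con1_4K": ("control", 1, "4K"), ...}``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)

    mandatory = ["Protein IDs", "Mol. weight [kDa]", *FLAG_COLUMNS]
    for column in mandatory:
        if column not in raw.columns:
            raise SchemaError(f"mandatory column {column!r} missing")
    for exp in experiment_schema:
        for template in ("Ratio H/L {}", "Ratio H/L count {}"):
            column = template.format(exp)
            if column not in raw.columns:
                raise SchemaError(f"mandatory column {column!r} missing")

    proteins = pd.DataFrame(
        {
            "protein_group": raw["Protein IDs"],
            "gene_name": raw.get("Gene names", pd.Series("", index=raw.index)),
            "molecular_weight": _parse_numeric(
                raw["Mol. weight [kDa]"], "Mol. weight [kDa]"
            ),
        }
    )
    for column, name in FLAG_COLUMNS.items():
        proteins[name] = raw[column].fillna("").str.strip() == "+"
    proteins.index = pd.Index(
        [_canonical_id(g) for g in raw["Protein IDs"]], name="protein_id"
    )

    blocks = []
    for exp, (condition, replicate, fraction) in experiment_schema.items():
        block = pd.DataFrame(
            {
                "protein_id": proteins.index,
                "condition": condition,
                "replicate": int(replicate),
                "fraction": fraction,
                "ratio_hl": _parse_numeric(
                    raw[f"Ratio H/L {exp}"], f"Ratio H/L {exp}"
                ).to_numpy(),
                "ratio_count": _parse_numeric(
                    raw[f"Ratio H/L count {exp}"], f"Ratio H/L count {exp}"
                )
                .fillna(0)
                .astype(int)
                .to_numpy(),
                "ratio_variability_pct": _parse_numeric(
                    raw.get(
                        f"Ratio H/L variability [%] {exp}",
                        pd.Series(np.nan, index=raw.index),
                    ),
                    f"Ratio H/L variability [%] {exp}",
                ).to_numpy(),
                "intensity": _parse_numeric(
                    raw.get(f"Intensity {exp}", pd.Series(np.nan, index=raw.index)),
                    f"Intensity {exp}",
                ).to_numpy(),
            }
        )
        blocks.append(block)
    measurements = pd.concat(blocks, ignore_index=True)
    return QuantTable(proteins=proteins, measurements=measurements)


def filter_identifications(table: QuantTable) -> QuantTable:
    """Drop reverse hits, contaminants and site-only identifications.

    Idempotent; all surviving records pass through unchanged.
    """
    flags = table.proteins[["reverse", "contaminant", "modified_only"]].any(axis=1)
    dropped = int(flags.sum())
    if dropped:
        logger.info("filter_identifications: removed %d flagged groups", dropped)
    keep_ids = set(table.proteins.index[~flags])
    return QuantTable(
        proteins=table.proteins.loc[~flags.to_numpy()],
        measurements=table.measurements[
            table.measurements["protein_id"].isin(keep_ids)
        ].reset_index(drop=True),
    )


def select_high_quality(
    table: QuantTable,
    min_events: int = 3,
    two_event_var_max_pct: float = 30.0,
) -> pd.DataFrame:
    """Per-(protein, condition, replicate, fraction) high-quality ratio mask.

    A SILAC ratio is high quality if it was computed from ``min_events`` or
    more quantification events, or from exactly two events with a ratio
    variability below ``two_event_var_max_pct`` percent.

    Returns a boolean frame indexed by protein with a
    (condition, replicate, fraction) column MultiIndex.
    """
    m = table.measurements
    ok = (m["ratio_count"] >= min_events) | (
        (m["ratio_count"] == 2)
        & (m["ratio_variability_pct"] < two_event_var_max_pct)
    )
    ok &= m["ratio_hl"].notna()
    mask = (
        m.assign(ok=ok)
        .pivot_table(
            index="protein_id",
            columns=["condition", "replicate", "fraction"],
            values="ok",
            aggfunc="first",
            fill_value=False,
        )
        .astype(bool)
    )
    return mask.reindex(table.proteins.index, fill_value=False)


def complete_proteins(mask: pd.DataFrame) -> pd.Index:
    """Proteins whose mask is true in every subfraction of every map."""
    return mask.index[mask.all(axis=1)]


def ratio_matrices(
    table: QuantTable,
    proteins: Iterable[str] | None = None,
    fractions: Sequence[str] = MAP_FRACTIONS,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Pivot measurements into per-(condition, replicate) protein x fraction
    H/L ratio matrices with a shared protein index."""
    m = table.measurements
    index = pd.Index(proteins) if proteins is not None else table.proteins.index
    out: dict[tuple[str, int], pd.DataFrame] = {}
    for (condition, replicate), sub in m.groupby(["condition", "replicate"]):
        wide = sub.pivot_table(
            index="protein_id", columns="fraction", values="ratio_hl", aggfunc="first"
        )
        out[(condition, int(replicate))] = wide.reindex(
            index=index, columns=list(fractions)
        )
    return out


def build_profile(ratios_hl: Sequence[float]) -> np.ndarray:
    """Turn five H/L ratios into a per-map normalized abundance profile.

    Ratios are inverted (the heavy channel is the shared reference) and the
    inverted values divided by their sum, so the result sums to one.
    """
    r = np.asarray(ratios_hl, dtype=float)
    if r.shape != (len(MAP_FRACTIONS),):
        raise ValueError(f"expected {len(MAP_FRACTIONS)} ratios, got {r.shape}")
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("all ratios must be present and positive")
    inv = 1.0 / r
    return inv / inv.sum()


def build_profiles(ratios: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`build_profile` over a protein x fraction ratio matrix."""
    values = ratios.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("all ratios must be present and positive")
    inv = 1.0 / values
    inv /= inv.sum(axis=1, keepdims=True)
    return pd.DataFrame(inv, index=ratios.index, columns=ratios.columns)


def zero_one_normalize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale each protein's concatenated profile to [0, 1].

    Applied per protein across all columns (e.g. the ten values of two
    concatenated control maps).  A constant profile has no dynamic range and
    is mapped to all zeros (logged).
    """
    values = profiles.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        logger.warning(
            "zero_one_normalize: %d constant profiles set to all zeros",
            int(flat.sum()),
        )
    span[flat] = 1.0
    out = (values - lo) / span
    out[flat.nonzero()[0], :] = 0.0
    return pd.DataFrame(out, index=profiles.index, columns=profiles.columns)


def profiles_to_tidy(profiles: Mapping[tuple[str, int], pd.DataFrame]) -> pd.DataFrame:
    """Flatten per-map profile matrices into a tidy long table."""
    rows = []
    for (condition, replicate), frame in profiles.items():
        long = frame.reset_index().melt(
            id_vars="protein_id", var_name="fraction", value_name="value"
        )
        long.insert(1, "condition", condition)
        long.insert(2, "replicate", replicate)
        rows.append(long)
    return pd.concat(rows, ignore_index=True)


def write_tidy_profiles(profiles, path) -> None:
    profiles_to_tidy(profiles).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tidy_profiles(path) -> dict[tuple[str, int], pd.DataFrame]:
    tidy = pd.read_csv(path, sep="\t")
    out = {}
    for (condition, replicate), sub in tidy.groupby(["condition", "replicate"]):
        out[(condition, int(replicate))] = sub.pivot_table(
            index="protein_id", columns="fraction", values="value", aggfunc="first"
        )[[f for f in MAP_FRACTIONS if f in set(sub["fraction"])]]
    return out
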