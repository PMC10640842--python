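"""Reading, validating and assembling plot-level interaction networks.

The raw currency of the pipeline is a long-format table of flower-visit
records: one row per (plot, plant species, insect species) with the number
of individual insects collected.  Season aggregation is by summation over
all sampling events, so duplicated (plot, plant, insect) rows are summed on
ingestion.  Each plot belongs to exactly one experimental block and one
treatment (C = control, F = fertilizer, H = herbicide, HF = both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("C", "F", "H", "HF")

#: Default column names for interaction CSVs.
INTERACTION_COLUMNS = {
    "plot": "plot",
    "block": "block",
    "treatment": "treatment",
    "plant": "plant",
    "insect": "insect",
    "count": "count",
}

#: Column order of the per-network metrics table (see :func:`write_metrics_table`).
METRICS_COLUMNS = [
    "plot",
    "block",
    "treatment",
    "abundance",
    "insect_richness",
    "plant_richness",
    "species_total",
    "links",
    "unweighted_degree",
    "weighted_degree",
    "connectance",
    "nodf",
    "nodfc",
    "modularity",
    "display",
    "display_log",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """An input row violates the interaction-table contract."""


class EmptyNetworkError(ValueError):
    """A plot has no interaction records (mirrors the one field plot that
    received too few visitors to form a network)."""


@dataclass(frozen=True)
class PlotMetadata:
    """Per-plot covariates used downstream of network construction.

    ``display`` is the floral display size: total inflorescence count
    multiplied by the mean inflorescence area (mm^2).  ``plants_bloomed``
    counts plant species that bloomed in the plot (out of the 7 planted),
    including species that received no visits — the experiment-wide
    connectance denominator needs bloomed plants, not visited plants.
    """

    plot_id: str
    block_id: str
    treatment: str
    plants_bloomed: int
    display: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment {self.treatment!r} for plot {self.plot_id}"
            )
        if not 0 <= self.plants_bloomed <= 7:
            raise ValidationError(
                f"plants_bloomed must be in [0, 7], got {self.plants_bloomed}"
            )

    @property
    def display_log(self) -> float:
        """Natural log of the floral display size."""
        return float(np.log(self.display))


@dataclass
class InteractionTable:
    """Season-aggregated visit records, one row per (plot, plant, insect).

    Wraps a :class:`pandas.DataFrame` with columns
    ``plot, block, treatment, plant, insect, count``; counts are strictly
    positive integers and (plot, plant, insect) triples are unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_interactions(self.data)

    @property
    def total_count(self) -> int:
        """Total number of insect specimens across all plots."""
        return int(self.data["count"].sum())

    @property
    def insect_species(self) -> list[str]:
        return sorted(self.data["insect"].unique())

    @property
    def plant_species(self) -> list[str]:
        return sorted(self.data["plant"].unique())

    @property
    def plots(self) -> list[str]:
        return sorted(self.data["plot"].unique())

    def for_plot(self, plot_id: str) -> pd.DataFrame:
        return self.data[self.data["plot"] == plot_id]

    def for_treatment(self, treatment: str) -> pd.DataFrame:
        if treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment code {treatment!r}")
        return self.data[self.data["treatment"] == treatment]

    def abundance_vector(self, treatment: str | None = None) -> pd.Series:
        """Pooled per-insect-species specimen counts (optionally one treatment)."""
        sub = self.data if treatment is None else self.for_treatment(treatment)
        return sub.groupby("insect")["count"].sum().sort_index()


@dataclass
class PlotNetwork:
    """One plot's weighted plant x insect visitation matrix.

    Rows are plant species with >= 1 visit, columns insect species with
    >= 1 specimen in the plot, both in sorted label order so that network
    construction is order-independent.  Entries are visit counts.
    """

    matrix: np.ndarray
    plants: list[str]
    insects: list[str]
    meta: PlotMetadata

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValidationError("network matrix must be 2-D")
        if self.matrix.size == 0:
            raise EmptyNetworkError(f"plot {self.meta.plot_id}: empty matrix")
        if (self.matrix < 0).any():
            raise ValidationError("negative visit counts")
        if (self.matrix.sum(axis=1) == 0).any() or (self.matrix.sum(axis=0) == 0).any():
            raise ValidationError(
                f"plot {self.meta.plot_id}: all-zero row or column in network"
            )

    @property
    def total_weight(self) -> int:
        """Total visitor abundance in the plot."""
        return int(self.matrix.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_links(self) -> int:
        """Number of realized (plant, insect) interactions."""
        return int(np.count_nonzero(self.matrix))

    def binary(self) -> np.ndarray:
        return (self.matrix > 0).astype(int)


def _validate_interactions(df: pd.DataFrame) -> pd.DataFrame:
    required = ["plot", "block", "treatment", "plant", "insect", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[required].copy()

    counts = df["count"]
    as_num = pd.to_numeric(counts, errors="coerce")
    bad = as_num.isna() | (as_num != np.floor(as_num))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"non-integer count at row {row}: {counts.iloc[row]!r}")
    if (as_num < 0).any():
        row = int(np.flatnonzero((as_num < 0).to_numpy())[0])
        raise ValidationError(f"negative count at row {row}")
    df["count"] = as_num.astype(int)

    n_zero = int((df["count"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-count row(s)", n_zero)
        df = df[df["count"] > 0]

    # each plot maps to exactly one block and one treatment
    assign = df.groupby("plot")[["block", "treatment"]].nunique()
    conflicted = assign[(assign > 1).any(axis=1)]
    if len(conflicted):
        raise ValidationError(
            f"plot(s) with conflicting block/treatment assignment: "
            f"{', '.join(conflicted.index.astype(str))}"
        )
    bad_tr = set(df["treatment"].unique()) - set(TREATMENTS)
    if bad_tr:
        raise ValidationError(f"unknown treatment code(s): {sorted(bad_tr)}")

    # season aggregation: sum duplicated (plot, plant, insect) triples
    n_before = len(df)
    df = (
        df.groupby(["plot", "block", "treatment", "plant", "insect"], as_index=False)[
            "count"
        ]
        .sum()
        .sort_values(["plot", "plant", "insect"], kind="stable")
        .reset_index(drop=True)
    )
    if len(df) < n_before:
        logger.info("merged %d duplicated interaction row(s)", n_before - len(df))
    return df


def read_interactions(
    path, schema: dict[str, str] | None = None
) -> InteractionTable:
    """Read a long-format interaction CSV into a validated table.

    Parameters
    ----------
    path
        CSV with a header row; comma-separated, UTF-8.
    schema
        Mapping from canonical names (``plot, block, treatment, plant,
        insect, count``) to the column names used in the file.  Defaults to
        the canonical names themselves.

    Duplicate (plot, plant, insect) rows are summed (season aggregation);
    zero-count rows are dropped with a logged warning.
    """
    schema = {**INTERACTION_COLUMNS, **(schema or {})}
    df = pd.read_csv(path, dtype=str)
    rename = {v: k for k, v in schema.items()}
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=rename)
    if df.empty:
        logger.warning("interaction file %s contains a header only", path)
        df = pd.DataFrame(columns=list(INTERACTION_COLUMNS))
        df["count"] = df["count"].astype(int)
    return InteractionTable(df)


def read_metadata(path) -> dict[str, PlotMetadata]:
    """Read per-plot metadata (plot, block, treatment, plants_bloomed,
    inflorescence count and mean area) keyed by plot id.

    The floral display is computed as ``n_inflorescences * mean_area`` when
    those two columns are present; a precomputed ``display`` column is also
    accepted.
    """
    df = pd.read_csv(path)
    required = ["plot", "block", "treatment", "plants_bloomed"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "display" in df.columns:
        display = df["display"].astype(float)
    elif {"n_inflorescences", "mean_inflorescence_area"} <= set(df.columns):
        display = df["n_inflorescences"].astype(float) * df[
            "mean_inflorescence_area"
        ].astype(float)
    else:
        raise SchemaError(
            "need either a 'display' column or "
            "'n_inflorescences' + 'mean_inflorescence_area'"
        )
    out = {}
    for i, row in df.iterrows():
        out[str(row["plot"])] = PlotMetadata(
            plot_id=str(row["plot"]),
            block_id=str(row["block"]),
            treatment=str(row["treatment"]),
            plants_bloomed=int(row["plants_bloomed"]),
            display=float(display.iloc[df.index.get_loc(i)]),
        )
    return out


def _matrix_from_records(records: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    mat = records.pivot_table(
        index="plant", columns="insect", values="count", aggfunc="sum", fill_value=0
    ).sort_index(axis=0).sort_index(axis=1)
    return mat.to_numpy(dtype=int), list(mat.index), list(mat.columns)


def build_plot_network(
    table: InteractionTable, plot_id: str, meta: PlotMetadata
) -> PlotNetwork:
    """Assemble the weighted bipartite matrix for one plot.

    Rows/columns are restricted to species with at least one visit in the
    plot; labels are sorted so the result is invariant to input row order.
    """
    records = table.for_plot(plot_id)
    if records.empty:
        raise EmptyNetworkError(f"plot {plot_id} has no interaction records")
    matrix, plants, insects = _matrix_from_records(records)
    return PlotNetwork(matrix=matrix, plants=plants, insects=insects, meta=meta)


def pool_by_treatment(table: InteractionTable, treatment: str) -> PlotNetwork:
    """Sum visit counts across all plots of one treatment into a single
    treatment-level network (used for aggregate visualization/diversity)."""
    records = table.for_treatment(treatment)
    if records.empty:
        raise EmptyNetworkError(f"no records for treatment {treatment}")
    matrix, plants, insects = _matrix_from_records(records)
    meta = PlotMetadata(
        plot_id=f"pooled:{treatment}",
        block_id="pooled",
        treatment=treatment,
        plants_bloomed=7,
        display=float("nan"),
    )
    return PlotNetwork(matrix=matrix, plants=plants, insects=insects, meta=meta)


def build_all_networks(
    table: InteractionTable, metadata: dict[str, PlotMetadata]
) -> dict[str, PlotNetwork]:
    """Build networks for every plot with at least one record.

    Plots listed in the metadata but absent from the table (no visitors) are
    skipped with a log message, mirroring the excluded field plot.
    """
    networks = {}
    for plot_id, meta in metadata.items():
        try:
            networks[plot_id] = build_plot_network(table, plot_id, meta)
        except EmptyNetworkError:
            logger.info("plot %s received no visitors; excluded", plot_id)
    return networks


def write_metrics_table(rows: list[dict], path) -> pd.DataFrame:
    """Write per-network metric rows to CSV (lossless round-trip).

    Rows are dictionaries keyed by :data:`METRICS_COLUMNS` entries; extra
    keys are appended as additional columns.
    """
    if rows:
        extra = [k for k in rows[0] if k not in METRICS_COLUMNS]
        cols = [c for c in METRICS_COLUMNS if c in rows[0]] + extra
        df = pd.DataFrame(rows)[cols]
    else:
        df = pd.DataFrame(columns=METRICS_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
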