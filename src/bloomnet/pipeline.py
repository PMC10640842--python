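"""End-to-end orchestration: networks -> metrics -> nulls -> diversity -> stats.

``run_all`` drives the full analysis from a :class:`PipelineConfig`, which
either points at interaction/metadata CSVs or embeds a
:class:`~bloomnet.simulate.SimulationConfig`.  Every stochastic stage takes
its seed from the config, so a run is deterministic end to end; outputs are
CSVs plus a JSON manifest recording the config hash and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as _div
from . import io as _io
from . import metrics as _metrics
from . import nulls as _nulls
from . import stats as _stats
from .simulate import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "STAGES"]

STAGES = ("metrics", "nulls", "diversity", "stats")

#: Mixed-model responses mirroring the headline effect table.
MODEL_RESPONSES: list[_stats.ModelSpec] = [
    _stats.ModelSpec("display_log", include_display=False, test_interaction=False),
    _stats.ModelSpec("abundance", log_response=True),
    _stats.ModelSpec("insect_richness"),
    _stats.ModelSpec("weighted_degree"),
    _stats.ModelSpec("unweighted_degree"),
    _stats.ModelSpec("connectance"),
    _stats.ModelSpec("nodf"),
    _stats.ModelSpec("nodfc"),
    _stats.ModelSpec("modularity"),
]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    interactions_path: str | None = None
    metadata_path: str | None = None
    simulation: SimulationConfig | None = None
    i_total: int | None = None          # experiment-wide insect pool; None = observed
    n_null: int = 500
    seed: int = 0
    modularity_restarts: int = 20
    null_modularity_restarts: int = 4
    top_species: int = 10               # Kruskal-Wallis family size
    skip: tuple[str, ...] = ()
    outdir: str = "bloomnet_out"

    def __post_init__(self) -> None:
        self.skip = tuple(self.skip)
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) in skip: {sorted(unknown)}")
        has_files = self.interactions_path and self.metadata_path
        if not has_files and self.simulation is None:
            raise ValueError(
                "config needs either interaction+metadata paths or a simulation block"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None, **raw
        )
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["skip"] = list(raw["skip"])
        if self.simulation is not None:
            raw["simulation"] = asdict(self.simulation)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        table, metadata, _truth = simulate_experiment(config.simulation)
        source = f"simulation(seed={config.simulation.seed})"
    else:
        table = _io.read_interactions(config.interactions_path)
        metadata = _io.read_metadata(config.metadata_path)
        source = str(config.interactions_path)
    return table, metadata, source


def _metrics_stage(networks, i_total, seed, restarts):
    rng = np.random.default_rng(seed)
    rows = []
    for plot_id in sorted(networks):
        net = networks[plot_id]
        pm = _metrics.compute_all(
            net, i_total=i_total, seed=int(rng.integers(2**31)), restarts=restarts
        )
        row = pm.as_dict()
        row.update(
            plot=plot_id,
            block=net.meta.block_id,
            treatment=net.meta.treatment,
            display=net.meta.display,
            display_log=net.meta.display_log,
        )
        del row["plot_id"]
        rows.append(row)
    return pd.DataFrame(rows), rows


def _nulls_stage(networks, metrics_df, config, i_total):
    rng = np.random.default_rng(config.seed + 1)
    z_rows, ensembles = [], {}
    for plot_id in sorted(networks):
        ens = _nulls.null_ensemble(
            networks[plot_id],
            n_null=config.n_null,
            seed=int(rng.integers(2**31)),
            i_total=i_total,
            modularity_restarts=config.null_modularity_restarts,
        )
        obs_row = metrics_df[metrics_df["plot"] == plot_id].iloc[0].to_dict()
        obs_row["plot_id"] = plot_id
        zs = _nulls.z_scores(obs_row, ens)
        ensembles[plot_id] = ens
        z_rows.append(
            {"plot": plot_id,
             "treatment": networks[plot_id].meta.treatment,
             "block": networks[plot_id].meta.block_id,
             **{f"z_{m}": zs.z[m] for m in ens.draws}}
        )
    z_df = pd.DataFrame(z_rows)

    dep_rows = []
    for tr in _io.TREATMENTS:
        sub = z_df[z_df["treatment"] == tr]
        for m in _nulls.NULL_METRICS:
            col = sub[f"z_{m}"].dropna()
            if len(col) < 2:
                dep_rows.append({"treatment": tr, "metric": m,
                                 "mean_z": np.nan, "sd_z": np.nan,
                                 "departs_from_null": None})
                continue
            dep_rows.append({
                "treatment": tr, "metric": m,
                "mean_z": float(col.mean()), "sd_z": float(col.std(ddof=1)),
                "departs_from_null": _nulls.null_departure(col.to_numpy()),
            })
    return z_df, pd.DataFrame(dep_rows), ensembles


def _diversity_stage(table: _io.InteractionTable):
    rows = []
    for tr in _io.TREATMENTS:
        series = table.abundance_vector(tr)
        if series.empty:
            continue
        v = _div.AbundanceVector.from_series(series)
        row = {"treatment": tr, "n_specimens": v.n}
        for q in (0, 1, 2):
            row[f"hill_q{q}"] = _div.hill_number(v, q)
        row["coverage"] = _div.sample_coverage(v)
        rows.append(row)
    return pd.DataFrame(rows)


def _effects_frame(tables: list[_stats.EffectTable]) -> pd.DataFrame:
    frames = []
    for et in tables:
        df = et.rows.copy()
        df.insert(0, "response", et.response)
        df["r2m"], df["r2c"] = et.r2m, et.r2c
        df["interaction_retained"] = et.interaction_retained
        df["converged"] = et.converged
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _stats_stage(table, metrics_df, z_df, config):
    effects = []
    for spec in MODEL_RESPONSES:
        if spec.response not in metrics_df.columns:
            continue
        try:
            effects.append(_stats.fit_lmm(metrics_df, spec))
        except Exception as exc:  # degenerate synthetic runs can defeat a fit
            logger.warning("model for %s failed: %s", spec.response, exc)
    effect_df = _effects_frame(effects)

    z_effects = []
    if z_df is not None:
        for m in _nulls.NULL_METRICS:
            col = f"z_{m}"
            sub = z_df.dropna(subset=[col])
            if sub.empty or sub["block"].nunique() < 2:
                continue
            spec = _stats.ModelSpec(col, include_display=False,
                                    test_interaction=False)
            try:
                z_effects.append(_stats.fit_lmm(sub, spec))
            except Exception as exc:
                logger.warning("z-score model for %s failed: %s", m, exc)
    z_effect_df = _effects_frame(z_effects) if z_effects else pd.DataFrame()

    # per-species foraging breadth across treatments (top species by abundance)
    top = (
        table.data.groupby("insect")["count"].sum()
        .sort_values(ascending=False)
        .head(config.top_species)
        .index
    )
    kw_rows = []
    breadth = (
        table.data.groupby(["insect", "plot", "treatment"])["plant"]
        .nunique()
        .reset_index(name="n_plants_visited")
    )
    plots = table.data[["plot", "treatment"]].drop_duplicates()
    for sp in top:
        sub = breadth[breadth["insect"] == sp][["plot", "n_plants_visited"]]
        full = plots.merge(sub, on="plot", how="left").fillna(
            {"n_plants_visited": 0}
        )
        try:
            kw = _stats.kruskal_pairwise(
                full["n_plants_visited"], full["treatment"],
                bonferroni_m=config.top_species,
            )
        except ValueError:
            continue
        kw.insert(0, "insect", sp)
        kw["kruskal_H"] = kw.attrs["kruskal_H"]
        kw["kruskal_p"] = kw.attrs["kruskal_p"]
        kw_rows.append(kw)
    kw_df = pd.concat(kw_rows, ignore_index=True) if kw_rows else pd.DataFrame()

    corr_vars = [
        "abundance", "insect_richness", "unweighted_degree", "weighted_degree",
        "connectance", "nodf", "nodfc", "modularity", "display_log",
    ]
    corr_df = _stats.correlation_matrix(
        metrics_df, [v for v in corr_vars if v in metrics_df.columns]
    )
    return effect_df, z_effect_df, kw_df, corr_df


def run_all(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every enabled stage and write CSV outputs plus a manifest.

    Returns the in-memory tables keyed by output name.  A stage failure
    raises with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, metadata, source = _load_inputs(config)
    i_total = config.i_total or len(table.insect_species)

    networks = _io.build_all_networks(table, metadata)
    logger.info("built %d networks from %d plots", len(networks), len(metadata))
    outputs: dict[str, pd.DataFrame] = {}

    metrics_df = None
    if "metrics" not in config.skip:
        try:
            metrics_df, rows = _metrics_stage(
                networks, i_total, config.seed, config.modularity_restarts
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'metrics' failed: {exc}") from exc
        _io.write_metrics_table(rows and metrics_df.to_dict("records"),
                                outdir / "network_metrics.csv")
        outputs["network_metrics"] = metrics_df

    z_df = None
    if "nulls" not in config.skip:
        if metrics_df is None:
            raise RuntimeError("stage 'nulls' needs the metrics stage")
        try:
            z_df, dep_df, _ = _nulls_stage(networks, metrics_df, config, i_total)
        except Exception as exc:
            raise RuntimeError(f"stage 'nulls' failed: {exc}") from exc
        z_df.to_csv(outdir / "z_scores.csv", index=False)
        dep_df.to_csv(outdir / "null_departure.csv", index=False)
        outputs["z_scores"], outputs["null_departure"] = z_df, dep_df

    if "diversity" not in config.skip:
        try:
            div_df = _diversity_stage(table)
        except Exception as exc:
            raise RuntimeError(f"stage 'diversity' failed: {exc}") from exc
        div_df.to_csv(outdir / "diversity.csv", index=False)
        outputs["diversity"] = div_df

    if "stats" not in config.skip:
        if metrics_df is None:
            raise RuntimeError("stage 'stats' needs the metrics stage")
        try:
            effect_df, z_effect_df, kw_df, corr_df = _stats_stage(
                table, metrics_df, z_df, config
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
        effect_df.to_csv(outdir / "effects.csv", index=False)
        z_effect_df.to_csv(outdir / "z_effects.csv", index=False)
        kw_df.to_csv(outdir / "kruskal_breadth.csv", index=False)
        corr_df.to_csv(outdir / "correlations.csv", index=False)
        outputs.update(effects=effect_df, z_effects=z_effect_df,
                       kruskal_breadth=kw_df, correlations=corr_df)

    manifest = {
        "config_digest": config.digest(),
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "input_source": source,
        "i_total": int(i_total),
        "n_plots": len(metadata),
        "n_networks": len(networks),
        "total_specimens": table.total_count,
        "n_insect_species": len(table.insect_species),
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return outputs
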