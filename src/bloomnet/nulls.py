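"""Fixed-margin null models and z-score standardization.

Observed networks are compared against ensembles of random integer
contingency tables with the observed row and column sums (the Patefield
algorithm; the classic ``r2dtable`` null).  Each null matrix is scored with
the same structural metrics as the observed network, and observed values
are standardized as z = (observed - null mean) / null sd.

Margins fix total abundance and both species counts, so any metric that is
a function of the margins alone (weighted degree = N_v / S in particular)
is identical across all null draws; such metrics are flagged as
not-standardizable rather than reported as infinite z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import PlotNetwork, PlotMetadata
from . import metrics as _metrics

__all__ = [
    "NULL_METRICS",
    "NullEnsemble",
    "ZScores",
    "patefield_sample",
    "null_ensemble",
    "z_scores",
    "null_departure",
]

#: Metrics scored on every null draw.
NULL_METRICS = (
    "connectance",
    "weighted_degree",
    "unweighted_degree",
    "modularity",
    "nodf",
    "nodfc",
)


def _is_degenerate(draws: np.ndarray) -> bool:
    """Null spread indistinguishable from zero (metric fixed by the margins)."""
    sd = float(np.std(draws, ddof=1))
    scale = max(1.0, float(np.abs(draws).max(initial=0.0)))
    return sd <= 1e-10 * scale


def patefield_sample(
    row_sums: np.ndarray, col_sums: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One random non-negative integer table with the given margins.

    Uses Patefield's conditional row-by-row construction (the ``r2dtable``
    null): individual specimens are shuffled uniformly across cells subject
    to the margins, so tables follow the Fisher-Yates (multiple
    hypergeometric) distribution conditional on the row and column sums.
    """
    r = np.asarray(row_sums, dtype=int)
    c = np.asarray(col_sums, dtype=int)
    if r.sum() != c.sum():
        raise ValueError(f"margin mismatch: rows sum to {r.sum()}, cols to {c.sum()}")
    if r.sum() <= 0:
        raise ValueError("margins must sum to a positive total")
    if len(r) == 1:
        return c[None, :].copy()
    if len(c) == 1:
        return r[:, None].copy()
    return sps.random_table(r, c).rvs(random_state=rng, method="patefield").astype(int)


@dataclass
class NullEnsemble:
    """Null-model metric distributions for one plot network."""

    plot_id: str
    n_null: int
    draws: dict[str, np.ndarray]            # metric -> (n_null,) values
    observed: dict[str, float]
    degenerate: list[str] = field(default_factory=list)  # sd == 0 metrics

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(np.mean(v)) for m, v in self.draws.items()}

    @property
    def sd(self) -> dict[str, float]:
        return {m: float(np.std(v, ddof=1)) for m, v in self.draws.items()}


@dataclass
class ZScores:
    """Standardized observed metrics; None where the null sd is zero."""

    plot_id: str
    z: dict[str, float | None]


def _score_null(
    matrix: np.ndarray,
    meta: PlotMetadata,
    plants: list[str],
    insects: list[str],
    i_total: int,
    seed: int,
    restarts: int,
    which: tuple[str, ...],
) -> dict[str, float]:
    net = PlotNetwork(matrix=matrix, plants=plants, insects=insects, meta=meta)
    out: dict[str, float] = {}
    if "connectance" in which:
        out["connectance"] = _metrics.connectance_experiment_wide(net, i_total)
    if "unweighted_degree" in which or "weighted_degree" in which:
        uw, w = _metrics.degrees(net)
        out["unweighted_degree"] = uw
        out["weighted_degree"] = w
    if "nodf" in which:
        out["nodf"] = _metrics.nodf(matrix)
    if "nodfc" in which:
        out["nodfc"] = _metrics.nodfc(matrix)
    if "modularity" in which:
        q, _ = _metrics.bipartite_modularity(net, seed=seed, restarts=restarts)
        out["modularity"] = q
    return {m: out[m] for m in which}


def null_ensemble(
    network: PlotNetwork,
    n_null: int = 500,
    seed: int = 0,
    i_total: int = 92,
    modularity_restarts: int = 4,
    which: tuple[str, ...] = NULL_METRICS,
) -> NullEnsemble:
    """Score ``n_null`` fixed-margin null matrices of one network.

    Reproducible for a given master seed; each draw's modularity optimizer
    gets a fresh seed derived from the master.  Metrics whose null
    distribution has zero spread (determined by the margins) are listed in
    ``degenerate``.
    """
    rng = np.random.default_rng(seed)
    r = network.matrix.sum(axis=1)
    c = network.matrix.sum(axis=0)
    draws: dict[str, list[float]] = {m: [] for m in which}
    for _ in range(n_null):
        mat = patefield_sample(r, c, rng)
        mod_seed = int(rng.integers(2**31))
        scores = _score_null(
            mat, network.meta, network.plants, network.insects,
            i_total, mod_seed, modularity_restarts, which,
        )
        for m in which:
            draws[m].append(scores[m])
    arrays = {m: np.asarray(v, dtype=float) for m, v in draws.items()}
    observed = _score_null(
        network.matrix, network.meta, network.plants, network.insects,
        i_total, seed, max(modularity_restarts, 20), which,
    )
    degenerate = [m for m, v in arrays.items() if _is_degenerate(v)]
    return NullEnsemble(
        plot_id=network.meta.plot_id,
        n_null=n_null,
        draws=arrays,
        observed=observed,
        degenerate=degenerate,
    )


def z_scores(observed: _metrics.PlotMetrics | dict, ensemble: NullEnsemble) -> ZScores:
    """Standardize observed metrics against the null ensemble.

    Metrics with zero null spread come back as ``None`` (explicit missing),
    never as infinity.
    """
    obs = observed.as_dict() if hasattr(observed, "as_dict") else dict(observed)
    if obs.get("plot_id", ensemble.plot_id) != ensemble.plot_id:
        raise ValueError(
            f"plot id mismatch: observed {obs.get('plot_id')!r} vs "
            f"ensemble {ensemble.plot_id!r}"
        )
    mu, sd = ensemble.mean, ensemble.sd
    z: dict[str, float | None] = {}
    for m in ensemble.draws:
        if _is_degenerate(ensemble.draws[m]):
            z[m] = None
        else:
            z[m] = (float(obs[m]) - mu[m]) / sd[m]
    return ZScores(plot_id=ensemble.plot_id, z=z)


def null_departure(z_values: np.ndarray) -> bool:
    """Departure-from-null rule for one metric across one treatment's plots:
    flag when mean(z) +/- sd(z) excludes zero."""
    z = np.asarray([v for v in z_values if v is not None], dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 networks to assess departure")
    mean, sd = z.mean(), z.std(ddof=1)
    return bool(mean - sd > 0 or mean + sd < 0)
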