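"""Synthetic field experiments and agrochemical dose arithmetic.

The generator emulates the study design end to end: 8 blocks (site-years),
one plot per treatment (C = water control, F = fertilizer, H = herbicide,
HF = both) in each block, a fixed community of 7 flowering plant species,
and a regional pool of ~90 flower-visiting insect species with log-normal
activity (so most species are rare).  Floral display sizes are log-normal
and independent of treatment (the treatments changed floral chemistry, not
display size).  Visitation is a two-stage process per plot:

1. *inclusion* — each insect species forages in the plot with a
   probability increasing in its activity; the fertilizer treatment
   multiplies the inclusion odds (attractiveness up, so a larger realized
   fraction of the species pool visits), which drives added richness;
2. *visit counts* — each included species deposits negative-binomial
   visit counts on each bloomed plant, with mean proportional to species
   activity x plant attractiveness x floral display, and reduced by a
   factor exp(-delta_H) under herbicide (abundance down, richness barely
   affected).

Dose arithmetic converts the weekly application schedule (mg/L in 10 L of
water over a 4 m^2 plot, four applications a month for three months) into
total seasonal mass per area, for comparison with standard field rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import InteractionTable, PlotMetadata, PlotNetwork, TREATMENTS

__all__ = [
    "ApplicationSchedule",
    "DEFAULT_SCHEDULES",
    "total_application",
    "SimulationConfig",
    "simulate_experiment",
    "make_fixture_networks",
]


# ---------------------------------------------------------------------------
# dose arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApplicationSchedule:
    """Seasonal application schedule for one compound.

    ``monthly_mg_per_l`` holds the concentration applied in each of the
    three months of the flowering season, highest first (the schedule
    tapers to emulate a spring field application followed by decay).
    """

    monthly_mg_per_l: tuple[float, ...]
    applications_per_month: int = 4
    volume_l: float = 10.0
    plot_area_m2: float = 4.0

    def __post_init__(self) -> None:
        if self.plot_area_m2 <= 0:
            raise ValueError("plot area must be positive")
        if self.applications_per_month <= 0 or self.volume_l <= 0:
            raise ValueError("applications and volume must be positive")
        if any(c < 0 for c in self.monthly_mg_per_l):
            raise ValueError("concentrations must be non-negative")
        if list(self.monthly_mg_per_l) != sorted(
            self.monthly_mg_per_l, reverse=True
        ):
            raise ValueError("concentrations must be non-increasing across months")


#: The study's schedules: N-P-K fertilizer components and glyphosate.
DEFAULT_SCHEDULES: dict[str, ApplicationSchedule] = {
    "N": ApplicationSchedule((30.0, 20.0, 10.0)),
    "P": ApplicationSchedule((15.0, 10.0, 5.0)),
    "K": ApplicationSchedule((5.5, 3.0, 1.0)),
    "glyphosate": ApplicationSchedule((0.7, 0.3, 0.1)),
}


def total_application(
    schedule: ApplicationSchedule, reference_g_per_ha: float | None = None
) -> tuple[float, float | None]:
    """Total seasonal application in g/m^2 and, optionally, as a percent of
    a reference annual field rate given in g/ha.

    total = sum_months conc(mg/L) * volume(L) * applications / area(m^2),
    converted mg -> g.
    """
    total_mg = sum(
        c * schedule.volume_l * schedule.applications_per_month
        for c in schedule.monthly_mg_per_l
    )
    g_per_m2 = total_mg / schedule.plot_area_m2 / 1000.0
    percent = None
    if reference_g_per_ha is not None:
        if reference_g_per_ha <= 0:
            raise ValueError("reference field rate must be positive")
        percent = g_per_m2 * 10_000.0 / reference_g_per_ha * 100.0
    return g_per_m2, percent


# ---------------------------------------------------------------------------
# synthetic experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Effect multipliers:

    ``herbicide_decrement``
        delta_H, the log-scale decrement of per-link visit intensity under
        herbicide; total visitor abundance scales by exp(-delta_H).
    ``fertilizer_odds``
        rho_F, the multiplier on each insect species' inclusion odds under
        fertilizer; drives added realized richness.  rho_F = 1 means no
        effect.

    The remaining defaults reproduce the scale of the field study: ~60
    specimens and ~16 insect species per control plot, hence roughly 1,900
    specimens over the 31-32 plot networks.
    """

    n_blocks: int = 8
    n_plants: int = 7
    pool_size: int = 90
    plant_attractiveness: tuple[float, ...] = (
        0.30, 0.20, 0.15, 0.12, 0.10, 0.08, 0.05,
    )
    activity_sdlog: float = 0.8          # log-normal insect activity spread
    inclusion_halfsat: float = 2.0       # c in pi = a / (a + c)
    display_meanlog: float = 9.2         # floral display, log mm^2
    display_sdlog: float = 0.5
    display_exponent: float = 1.0        # beta: count mean ~ display^beta
    visit_rate: float = 0.24             # lambda0: baseline per-link mean
    dispersion: float = 15.0             # negative-binomial size theta
    herbicide_decrement: float = 0.33    # delta_H
    fertilizer_odds: float = 1.5         # rho_F
    bloom_failure_rate: float = 0.05     # chance a plant fails to bloom
    seed: int = 0

    def __post_init__(self) -> None:
        self.plant_attractiveness = tuple(self.plant_attractiveness)
        if len(self.plant_attractiveness) != self.n_plants:
            raise ValueError("attractiveness vector length must equal n_plants")
        if self.fertilizer_odds <= 0 or self.dispersion <= 0:
            raise ValueError("multipliers and dispersion must be positive")
        if self.herbicide_decrement < 0:
            raise ValueError("herbicide decrement must be non-negative")


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    """Negative binomial draws parameterized by mean and size (theta)."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[InteractionTable, dict[str, PlotMetadata], dict]:
    """Simulate one full field season.

    Returns the long-format interaction table, per-plot metadata, and a
    ground-truth record of every parameter (for recovery tests).  Fully
    deterministic for a given ``config.seed``.  Plots that attract no
    visitors are possible (and mirror the one excluded field plot); they
    simply contribute no records.
    """
    rng = np.random.default_rng(config.seed)
    plants = [f"plant_{i + 1:02d}" for i in range(config.n_plants)]
    insects = [f"insect_{s + 1:03d}" for s in range(config.pool_size)]

    activity = rng.lognormal(mean=0.0, sigma=config.activity_sdlog,
                             size=config.pool_size)
    act_norm = activity / activity.mean()
    incl_base = activity / (activity + config.inclusion_halfsat)
    w = np.asarray(config.plant_attractiveness)
    w = w / w.sum()
    d0 = float(np.exp(config.display_meanlog + config.display_sdlog**2 / 2))

    records = []
    metadata: dict[str, PlotMetadata] = {}
    for b in range(config.n_blocks):
        block_id = f"block_{b + 1}"
        for tr in TREATMENTS:
            plot_id = f"{block_id}_{tr}"
            display = float(
                rng.lognormal(config.display_meanlog, config.display_sdlog)
            )
            bloomed_mask = rng.random(config.n_plants) > config.bloom_failure_rate
            if not bloomed_mask.any():
                bloomed_mask[rng.integers(config.n_plants)] = True
            metadata[plot_id] = PlotMetadata(
                plot_id=plot_id,
                block_id=block_id,
                treatment=tr,
                plants_bloomed=int(bloomed_mask.sum()),
                display=display,
            )

            pi = incl_base.copy()
            if "F" in tr:
                odds = config.fertilizer_odds * pi / (1.0 - pi)
                pi = odds / (1.0 + odds)
            # the realized species quota concentrates at its expectation
            # (fixed-effort surveys have sub-binomial richness noise); which
            # species fill it stays proportional to inclusion probability
            expected = pi.sum()
            n_incl = int(np.floor(expected))
            n_incl += int(rng.random() < expected - n_incl)
            n_incl = min(max(n_incl, 1), config.pool_size)
            chosen = rng.choice(
                config.pool_size, size=n_incl, replace=False, p=pi / pi.sum()
            )
            included = np.zeros(config.pool_size, dtype=bool)
            included[chosen] = True

            herb = np.exp(-config.herbicide_decrement) if "H" in tr else 1.0
            disp_factor = (display / d0) ** config.display_exponent
            for s in np.flatnonzero(included):
                mu = (
                    config.visit_rate
                    * act_norm[s]
                    * w[bloomed_mask]
                    * len(w)            # attractiveness is a share of plants
                    * disp_factor
                    * herb
                )
                counts = _negbin(rng, mu, config.dispersion)
                for p_idx, cnt in zip(np.flatnonzero(bloomed_mask), counts):
                    if cnt > 0:
                        records.append(
                            (plot_id, block_id, tr, plants[p_idx],
                             insects[s], int(cnt))
                        )

    df = pd.DataFrame(
        records,
        columns=["plot", "block", "treatment", "plant", "insect", "count"],
    )
    truth = {
        "config": asdict(config),
        "activity": activity.tolist(),
        "plants": plants,
        "insects": insects,
    }
    return InteractionTable(df), metadata, truth


# ---------------------------------------------------------------------------
# deterministic fixtures for metric tests
# ---------------------------------------------------------------------------

def make_fixture_networks(
    kind: str, dims: tuple[int, int] = (4, 6), seed: int = 0
) -> PlotNetwork:
    """Small networks with known structure for metric unit tests.

    kinds: ``nested`` (strictly decreasing prefix fills, NODF = 100),
    ``checkerboard`` (disjoint fills, NODF = 0), ``modular`` (two
    disconnected complete bipartite blocks), ``random`` (Bernoulli links
    with Poisson weights, no empty rows/columns).
    """
    m, n = dims
    if m < 1 or n < 1:
        raise ValueError("dims must be at least 1x1")
    rng = np.random.default_rng(seed)
    if kind == "nested":
        if m < 2 or n < m:
            raise ValueError("nested fixture needs n >= m >= 2")
        b = np.zeros((m, n), dtype=int)
        for i in range(m):
            fill = n - round(i * (n - 1) / (m - 1))
            b[i, :fill] = 1
    elif kind == "checkerboard":
        if n < m:
            raise ValueError("checkerboard fixture needs n >= m")
        b = np.zeros((m, n), dtype=int)
        for j in range(n):
            b[j % m, j] = 1
    elif kind == "modular":
        if m < 2 or n < 2:
            raise ValueError("modular fixture needs at least 2x2")
        b = np.zeros((m, n), dtype=int)
        b[: m // 2, : n // 2] = 1
        b[m // 2:, n // 2:] = 1
    elif kind == "random":
        while True:
            b = (rng.random((m, n)) < 0.45).astype(int)
            if b.sum() and not (b.sum(0) == 0).any() and not (b.sum(1) == 0).any():
                break
        b = b * (1 + rng.poisson(1.5, size=b.shape))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    meta = PlotMetadata(
        plot_id=f"fixture_{kind}",
        block_id="fixture",
        treatment="C",
        plants_bloomed=min(7, m),
        display=1000.0,
    )
    return PlotNetwork(
        matrix=b,
        plants=[f"plant_{i + 1:02d}" for i in range(m)],
        insects=[f"insect_{j + 1:03d}" for j in range(n)],
        meta=meta,
    )
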