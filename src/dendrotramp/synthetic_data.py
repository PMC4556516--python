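"""Synthetic ring-width generator emulating a trampling-impact study design.

Generates multi-plot, two-zone (track vs control) spruce-like ring-width
datasets with the statistical structure the downstream analyses assume:

* a per-tree negative-exponential age trend (fast juvenile growth
  declining to a level k, in mm);
* a shared within-plot "climate" year effect, AR(1) on the log scale;
* a trampling suppression applied to track-zone trees only: a log-scale
  deficit delta <= 0 that ramps in linearly over ``ramp_years`` from the
  onset year (emulating the gradual build-up of mass tourist traffic);
* multiplicative lognormal observation noise, keeping widths positive;
* a fraction of "flawed" trees (cored but unusable), either Bernoulli
  with probability pi or exact per-group counts.

The default ``study_shape`` preset mirrors the study design this
generator emulates: two study plots with 25+25 and 20+20 bored trees,
15 of the 90 flawed (6/7/1/1 per plot x zone), last ring 2007,
suppression onset 1970.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import RingDataset, RingSeries
from .representativeness import SamplingPool


@dataclass(frozen=True)
class PlotConfig:
    """Per-plot design: tree counts, recruitment window and age trend."""

    plot_id: str
    n_track: int
    n_control: int
    birth_range: tuple[int, int]  # uniform recruitment years (inclusive)
    a: float = 3.0  # initial juvenile increment above the level, mm
    b: float = 0.02  # age-trend decay rate, 1/yr
    k: float = 0.5  # mature increment level, mm
    multiplier: float = 1.0  # site productivity scaling


@dataclass(frozen=True)
class GeneratorConfig:
    plots: tuple[PlotConfig, ...]
    last_year: int = 2007
    phi: float = 0.3  # AR(1) coefficient of the shared log-scale year effect
    sigma_climate: float = 0.15  # innovation SD of the year effect (log scale)
    onset_year: int = 1970  # trampling suppression onset
    delta: float = -0.3  # log-scale suppression at full ramp (<= 0)
    ramp_years: int = 10  # years from onset to full suppression
    sigma_noise: float = 0.2  # per-ring lognormal observation noise (log scale)
    flaw_prob: float = 1.0 / 6.0  # Bernoulli flaw probability per tree
    flaw_counts: dict | None = None  # exact {(plot_id, zone): count}; overrides flaw_prob

    def __post_init__(self) -> None:
        if self.delta > 0:
            raise ValueError("delta must be <= 0 (suppression)")
        if not 0 <= self.flaw_prob <= 1:
            raise ValueError("flaw_prob must be in [0, 1]")
        if self.sigma_climate < 0 or self.sigma_noise < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.onset_year > self.last_year:
            raise ValueError("onset_year must be <= last_year")
        if self.ramp_years < 0:
            raise ValueError("ramp_years must be >= 0")


def study_shape() -> GeneratorConfig:
    """The two-plot study design: 90 bored trees, exactly 15 flawed.

    Plot MW (subalpine, low productivity): 25 track + 25 control trees,
    recruitment 1770-1930, flawed 6/7.  Plot K (montane, higher
    productivity): 20 + 20, recruitment 1830-1950, flawed 1/1.
    """
    return GeneratorConfig(
        plots=(
            PlotConfig("MW", 25, 25, (1770, 1930), a=1.8, b=0.015, k=0.35),
            PlotConfig("K", 20, 20, (1830, 1950), a=3.6, b=0.02, k=0.8),
        ),
        flaw_counts={("MW", "track"): 6, ("MW", "control"): 7, ("K", "track"): 1, ("K", "control"): 1},
    )


def trampling_ramp(years: np.ndarray, onset: int, ramp_years: int) -> np.ndarray:
    """Ramp r(t) in [0, 1]: 0 before onset, linear rise over ramp_years,
    then 1 (instant step when ramp_years = 0)."""
    if ramp_years == 0:
        return (years >= onset).astype(float)
    return np.clip((years - onset + 1) / ramp_years, 0.0, 1.0) * (years >= onset)


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    c = np.empty(n)
    stat_sd = sigma / np.sqrt(max(1.0 - phi**2, 1e-12)) if abs(phi) < 1 else sigma
    c[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, sigma, n - 1)
    for t in range(1, n):
        c[t] = phi * c[t - 1] + innov[t - 1]
    return c


def generate_dataset(
    config: GeneratorConfig, seed: int = 0
) -> tuple[RingDataset, dict]:
    """Generate a full dataset plus a truth record of every latent value.

    Ring widths follow
    w_i(t) = m_p * (a_p*exp(-b_p*(t - B_i)) + k_p)
             * exp(c_{p,t} + delta*r(t)*[zone == track]) * exp(eps_{i,t})
    with B_i the tree's recruitment year, c the plot's shared AR(1) year
    effect, r the trampling ramp and eps iid Normal(0, sigma_noise^2).
    Byte-identical output for equal (config, seed).
    """
    rng = np.random.default_rng(seed)
    series: list[RingSeries] = []
    truth: dict = {
        "seed": seed,
        "delta": config.delta,
        "onset_year": config.onset_year,
        "ramp_years": config.ramp_years,
        "climate": {},
        "trees": {},
    }
    for plot in config.plots:
        y0 = plot.birth_range[0]
        plot_years = np.arange(y0, config.last_year + 1)
        climate = _ar1(rng, plot_years.size, config.phi, config.sigma_climate)
        truth["climate"][plot.plot_id] = dict(zip(plot_years.tolist(), climate.tolist()))
        ramp = trampling_ramp(plot_years, config.onset_year, config.ramp_years)

        zone_counts = (("track", plot.n_track), ("control", plot.n_control))
        for zone, n_trees in zone_counts:
            births = rng.integers(plot.birth_range[0], plot.birth_range[1] + 1, n_trees)
            if config.flaw_counts is not None:
                k = config.flaw_counts.get((plot.plot_id, zone), 0)
                flawed_idx = set(rng.choice(n_trees, size=k, replace=False).tolist())
                flawed_flags = [i in flawed_idx for i in range(n_trees)]
            else:
                flawed_flags = (rng.random(n_trees) < config.flaw_prob).tolist()
            for i in range(n_trees):
                birth = int(births[i])
                years = np.arange(birth, config.last_year + 1)
                sel = years - y0  # positions into the plot-level year axes
                age = years - birth
                base = plot.multiplier * (plot.a * np.exp(-plot.b * age) + plot.k)
                log_effect = climate[sel]
                if zone == "track":
                    log_effect = log_effect + config.delta * ramp[sel]
                eps = rng.normal(0.0, config.sigma_noise, years.size)
                widths = base * np.exp(log_effect + eps)
                zone_code = "T" if zone == "track" else "C"
                tid = f"{plot.plot_id}_{zone_code}_{i + 1}"
                series.append(
                    RingSeries(tid, plot.plot_id, zone, birth, widths, flawed=flawed_flags[i])
                )
                truth["trees"][tid] = {
                    "birth_year": birth,
                    "flawed": bool(flawed_flags[i]),
                    "zone": zone,
                    "plot": plot.plot_id,
                    "eps_sd": config.sigma_noise,
                }
    return RingDataset(tuple(series)), truth


def generate_pool(
    config: GeneratorConfig | None = None,
    n_total: int | None = None,
    n_flawed: int | None = None,
    seed: int = 0,
) -> SamplingPool:
    """Virtual-object pool for the representativeness simulation.

    Either pass explicit (n_total, n_flawed) — e.g. the study values
    (90, 15) — or a generator config, in which case a dataset is drawn
    and its realized flawed count used.
    """
    if n_total is not None:
        if n_flawed is None:
            raise ValueError("n_flawed required with explicit n_total")
        return SamplingPool(n_total, n_flawed)
    if config is None:
        raise ValueError("pass a config or explicit counts")
    dataset, _ = generate_dataset(config, seed=seed)
    return SamplingPool(len(dataset), sum(s.flawed for s in dataset))


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON-serializable form (flaw_counts keys flattened to 'plot/zone')."""
    d = asdict(config)
    if d.get("flaw_counts"):
        d["flaw_counts"] = {f"{p}/{z}": v for (p, z), v in config.flaw_counts.items()}
    return d
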