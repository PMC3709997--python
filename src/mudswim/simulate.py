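"""Synthetic survey generator with the statistical structure the analyses assume.

The generator emulates the field design — 9 mudflat sites sampled over 3
summer rounds, 3 nights per round, 3 plankton nets per site-night (with
rare net loss giving 7-9 nets per site x round), and 12 sediment cores per
site x round — so that every downstream analysis has an input whose
generating parameters are known.

Generating model
----------------
A latent log10 resident density is assigned to every site x round x night
x net position as a grand mean plus independent normal effects at the
Round, Site, Round x Site, Night(Round), Site x Night(Round) and Error
(net) levels; the variance at each level is a configured fraction of a
configured total (defaults follow the hierarchy typical of these surveys,
with Site dominating).  Cores observe the site x round part of this field.
The expected swimmer density of each stage follows a power law of resident
density (a configured log-log slope per stage, sub-linear by default),
scaled by a stage-specific swimming-propensity multiplier; stages can
additionally be coupled to the resident density of another group (e.g.
large-juvenile swimming suppressed by resident adults).  Counts are
negative-binomial around their expectations (field counts are aggregated,
hence overdispersed relative to Poisson), catches exceeding a processing
target are Folsom-split to a power-of-two subsample fraction, and body
lengths are drawn from truncated normals within stage bounds.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .individuals import FEMALE, INTERSEX, JUVENILE, MALE, Individual
from .samples import CORE_AREA_7CM_M2, CoreSample, NetSample

__all__ = [
    "STAGES",
    "SurveyConfig",
    "TruthRecord",
    "SimulatedCounts",
    "simulate_counts",
    "generate_survey",
    "generate_null_swimmers",
    "sample_resident_lengths",
    "simulate_anova_responses",
]

#: Generator stages (resident composition categories).
STAGES = (
    "small_juvenile",
    "medium_juvenile",
    "large_juvenile",
    "small_male",
    "large_male",
    "small_nonovigerous_female",
    "large_nonovigerous_female",
    "ovigerous_female",
)

ADULT_STAGE_NAMES = STAGES[3:]

_VARIANCE_LEVELS = ("round", "site", "round_x_site", "night", "site_x_night", "error")


class ConfigError(ValueError):
    """Raised for impossible survey configurations."""


def _default_variance_fractions() -> dict[str, float]:
    # Site-dominated hierarchy, as observed for total swimmer density.
    return {"round": 0.097, "site": 0.563, "round_x_site": 0.138,
            "night": 0.038, "site_x_night": 0.097, "error": 0.067}


def _default_slopes() -> dict[str, float]:
    # Sub-linear log-log density dependence, steepest for small juveniles.
    return {"small_juvenile": 0.30, "medium_juvenile": 0.22,
            "large_juvenile": 0.18, "small_male": 0.15, "large_male": 0.06,
            "small_nonovigerous_female": 0.15,
            "large_nonovigerous_female": 0.06, "ovigerous_female": 0.03}


def _default_overrep() -> dict[str, float]:
    # Small juveniles and small adults (especially females) overrepresented
    # among swimmers; large adults and ovigerous females underrepresented.
    return {"small_juvenile": 2.5, "medium_juvenile": 1.0,
            "large_juvenile": 1.5, "small_male": 1.2, "large_male": 0.4,
            "small_nonovigerous_female": 1.5,
            "large_nonovigerous_female": 0.4, "ovigerous_female": 0.5}


def _default_length_params() -> dict[str, tuple[float, float, float, float]]:
    # (mean, sd, lower, upper) of truncated normal body length per stage, mm.
    return {
        "small_juvenile": (1.2, 0.25, 1.0, 1.5),
        "medium_juvenile": (2.0, 0.30, 1.5, 2.5),
        "large_juvenile": (3.2, 0.40, 2.5, 4.0),
        "small_male": (5.0, 0.50, 4.05, 6.0),
        "large_male": (7.0, 0.80, 6.0, 11.0),
        "small_nonovigerous_female": (5.0, 0.50, 4.05, 6.0),
        "large_nonovigerous_female": (7.0, 0.80, 6.0, 11.0),
        "ovigerous_female": (6.5, 1.20, 4.7, 10.8),
    }


def _default_coupling() -> dict[str, tuple[str, float]]:
    # Swimming of large juveniles suppressed by resident adults; swimming of
    # small non-ovigerous females suppressed by resident small males.
    return {"large_juvenile": ("adult", -0.6),
            "small_nonovigerous_female": ("small_male", -0.6)}


@dataclass(frozen=True)
class SurveyConfig:
    """All knobs of the synthetic survey; defaults emulate the study design."""

    n_sites: int = 9
    n_rounds: int = 3
    n_nights_per_round: int = 3
    n_nets: int = 3
    n_cores: int = 12
    core_area_m2: float = CORE_AREA_7CM_M2

    variance_fractions: Mapping[str, float] = field(
        default_factory=_default_variance_fractions)
    total_log10_variance: float = 0.703
    resident_log10_mean: float = 3.7

    dd_slope_by_stage: Mapping[str, float] = field(default_factory=_default_slopes)
    overrep_multipliers: Mapping[str, float] = field(default_factory=_default_overrep)
    propensity_coupling: Mapping[str, tuple[str, float]] = field(
        default_factory=_default_coupling)
    base_swimmer_density: float = 30.0

    sex_ratio_female_to_male: float = 2.0
    ovigerous_fraction: float = 0.3
    juvenile_fractions: tuple[float, float, float] = (0.30, 0.20, 0.15)
    small_adult_fraction: float = 0.7
    intersex_fraction_swimmers: float = 0.02
    intersex_fraction_residents: float = 0.0

    nb_dispersion: float = 5.0
    stage_mix_jitter: float = 0.15
    mean_log10_volume: float = 1.6
    sd_log10_volume: float = 0.15
    net_dropout_prob: float = 2.0 / 243.0
    subsample_target: int = 200
    max_splits: int = 9

    length_params: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=_default_length_params)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_rounds, self.n_nights_per_round,
               self.n_nets, self.n_cores) < 1:
            raise ConfigError("all design counts must be >= 1")
        fr = {k: float(self.variance_fractions[k]) for k in _VARIANCE_LEVELS}
        if any(v < 0 for v in fr.values()):
            raise ConfigError("variance fractions must be non-negative")
        tot = sum(fr.values())
        if not tot > 0:
            raise ConfigError("variance fractions must not all be zero")
        object.__setattr__(self, "variance_fractions",
                           {k: v / tot for k, v in fr.items()})
        if any(float(self.dd_slope_by_stage.get(s, 0.0)) < 0 for s in STAGES):
            raise ConfigError("density-dependence slopes must be >= 0")
        juv = self.juvenile_fractions
        if len(juv) != 3 or any(f < 0 for f in juv) or sum(juv) > 1:
            raise ConfigError(
                f"juvenile fractions must be >= 0 and sum to <= 1, got {juv}")
        for name, val in [("ovigerous_fraction", self.ovigerous_fraction),
                          ("small_adult_fraction", self.small_adult_fraction)]:
            if not 0 <= val <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if not self.sex_ratio_female_to_male > 0:
            raise ConfigError("sex ratio must be positive")

    @property
    def stage_mix(self) -> dict[str, float]:
        """Nominal resident composition over the eight generator stages."""
        sj, mj, lj = self.juvenile_fractions
        adults = 1.0 - (sj + mj + lj)
        male = adults / (1.0 + self.sex_ratio_female_to_male)
        female = adults - male
        ovig = female * self.ovigerous_fraction
        nof = female - ovig
        sf = self.small_adult_fraction
        return {
            "small_juvenile": sj, "medium_juvenile": mj, "large_juvenile": lj,
            "small_male": male * sf, "large_male": male * (1 - sf),
            "small_nonovigerous_female": nof * sf,
            "large_nonovigerous_female": nof * (1 - sf),
            "ovigerous_female": ovig,
        }


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters and per-cell latent state of one survey."""

    config: SurveyConfig
    cells: pd.DataFrame  # index (site, round): z, expected swimmer density/stage
    seed: int | None = None


@dataclass(frozen=True)
class SimulatedCounts:
    """Vectorised survey realisation: counts only, no Individual objects.

    ``net_table`` has one row per retained net with the filtered volume,
    Folsom fraction, raw (pre-split) and processed (post-split) counts per
    stage; ``core_table`` has one row per core with counts per stage.
    """

    truth: TruthRecord
    net_table: pd.DataFrame
    core_table: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and dispersion ``k`` (var =
    mean + mean^2/k); Poisson in the limit of large k."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = k / (k + mean[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def _folsom_fraction(total: int, target: int, max_splits: int) -> float:
    """Power-of-two fraction leaving at most ``target`` individuals."""
    if total <= target:
        return 1.0
    splits = min(max_splits, math.ceil(math.log2(total / target)))
    return 0.5**splits


def simulate_counts(config: SurveyConfig, *, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> SimulatedCounts:
    """Generate one survey as stage-count tables (fast, fully vectorised)."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed if seed is None else seed)

    a, b, c, nets = (config.n_sites, config.n_rounds,
                     config.n_nights_per_round, config.n_nets)
    vf = config.variance_fractions
    sd = {k: math.sqrt(vf[k] * config.total_log10_variance)
          for k in _VARIANCE_LEVELS}
    mu = config.resident_log10_mean

    eff_round = rng.normal(0, sd["round"], size=b)
    eff_site = rng.normal(0, sd["site"], size=a)
    eff_rs = rng.normal(0, sd["round_x_site"], size=(a, b))
    eff_night = rng.normal(0, sd["night"], size=(b, c))
    eff_sn = rng.normal(0, sd["site_x_night"], size=(a, b, c))
    eff_net = rng.normal(0, sd["error"], size=(a, b, c, nets))

    z_cell = mu + eff_site[:, None] + eff_round[None, :] + eff_rs      # (a,b)
    z_net = (z_cell[:, :, None, None] + eff_night[None, :, :, None]
             + eff_sn[:, :, :, None] + eff_net)                        # (a,b,c,nets)

    mix_nominal = config.stage_mix
    mix_vec = np.array([mix_nominal[s] for s in STAGES])
    # Per-cell logistic-normal jitter on the resident composition.
    jitter = rng.normal(0, config.stage_mix_jitter, size=(a, b, len(STAGES)))
    mix_cell = mix_vec[None, None, :] * 10.0**jitter
    mix_cell /= mix_cell.sum(axis=2, keepdims=True)                    # (a,b,S)

    resident_density_cell = mix_cell * 10.0**z_cell[:, :, None]        # ind/m2

    # Covariate groups for propensity coupling.  The coupling acts on the
    # covariate's compositional anomaly (log share relative to nominal), so
    # it perturbs stage-specific propensity without altering the density
    # dependence of the total on the latent field.
    group_share = {
        "adult": mix_cell[:, :, 3:].sum(axis=2),
        "male": mix_cell[:, :, 3:5].sum(axis=2),
        "small_male": mix_cell[:, :, 3],
    }
    nominal_group_mix = {
        "adult": sum(mix_vec[3:]), "male": sum(mix_vec[3:5]),
        "small_male": mix_vec[3],
    }

    slopes = np.array([float(config.dd_slope_by_stage.get(s, 0.0)) for s in STAGES])
    over = np.array([float(config.overrep_multipliers.get(s, 1.0)) for s in STAGES])
    amp = mix_vec * over
    amp = config.base_swimmer_density * amp / amp.sum()                # ind/m3 at mu

    coupling_term = np.zeros((a, b, len(STAGES)))
    for s_idx, s in enumerate(STAGES):
        if s in config.propensity_coupling:
            cov, coef = config.propensity_coupling[s]
            if cov not in group_share:
                raise ConfigError(f"unknown coupling covariate {cov!r}")
            anomaly = (np.log10(group_share[cov])
                       - math.log10(nominal_group_mix[cov]))
            coupling_term[:, :, s_idx] = coef * anomaly

    log_swim_net = (np.log10(amp)[None, None, None, None, :]
                    + slopes[None, None, None, None, :]
                    * (z_net[:, :, :, :, None] - mu)
                    + coupling_term[:, :, None, None, :])              # (a,b,c,n,S)
    expected_swim_cell = (10.0**(np.log10(amp)[None, None, :]
                                 + slopes[None, None, :] * (z_cell[:, :, None] - mu)
                                 + coupling_term))

    # --- nets -------------------------------------------------------------
    volumes = 10.0**rng.normal(config.mean_log10_volume,
                               config.sd_log10_volume, size=(a, b, c, nets))
    lam = 10.0**log_swim_net * volumes[:, :, :, :, None]
    raw = _nb_draw(rng, lam, config.nb_dispersion)                     # (a,b,c,n,S)

    drop = rng.random(size=(a, b, c, nets)) < config.net_dropout_prob
    for i in range(a):                                    # keep >=1 net per cell
        for j in range(b):
            for kk in range(c):
                if drop[i, j, kk].all():
                    drop[i, j, kk, 0] = False

    rows = []
    for i in range(a):
        for j in range(b):
            for kk in range(c):
                for l in range(nets):
                    if drop[i, j, kk, l]:
                        continue
                    raw_s = raw[i, j, kk, l]
                    total = int(raw_s.sum())
                    frac = _folsom_fraction(total, config.subsample_target,
                                            config.max_splits)
                    obs_s = (raw_s if frac == 1.0
                             else rng.binomial(raw_s, frac))
                    rows.append((f"S{i+1}", f"R{j+1}", f"N{kk+1}", f"net{l+1}",
                                 volumes[i, j, kk, l], frac, *raw_s, *obs_s))
    net_table = pd.DataFrame(rows, columns=[
        "site", "round", "night", "net", "volume_m3", "fraction",
        *[f"raw_{s}" for s in STAGES], *[f"obs_{s}" for s in STAGES]])

    # --- cores ------------------------------------------------------------
    core_mean = resident_density_cell * config.core_area_m2            # (a,b,S)
    core_lam = np.broadcast_to(core_mean[:, :, None, :],
                               (a, b, config.n_cores, len(STAGES)))
    core_counts = _nb_draw(rng, core_lam, config.nb_dispersion)
    crows = []
    for i in range(a):
        for j in range(b):
            for q in range(config.n_cores):
                crows.append((f"S{i+1}", f"R{j+1}", f"core{q+1}",
                              *core_counts[i, j, q]))
    core_table = pd.DataFrame(crows, columns=["site", "round", "core",
                                              *[f"count_{s}" for s in STAGES]])

    cell_index = pd.MultiIndex.from_product(
        [[f"S{i+1}" for i in range(a)], [f"R{j+1}" for j in range(b)]],
        names=["site", "round"])
    cells = pd.DataFrame(
        {"z_log10_resident": z_cell.reshape(-1),
         **{f"resident_density_{s}": resident_density_cell[:, :, si].reshape(-1)
            for si, s in enumerate(STAGES)},
         **{f"expected_swim_{s}": expected_swim_cell[:, :, si].reshape(-1)
            for si, s in enumerate(STAGES)}},
        index=cell_index)
    truth = TruthRecord(config=config, cells=cells, seed=seed)
    return SimulatedCounts(truth=truth, net_table=net_table, core_table=core_table)


# ---------------------------------------------------------------------------
# Individual-level realisation
# ---------------------------------------------------------------------------

def _stage_lengths(stage: str, n: int, config: SurveyConfig,
                   rng: np.random.Generator) -> np.ndarray:
    mean, sdev, lo, hi = config.length_params[stage]
    aa, bb = (lo - mean) / sdev, (hi - mean) / sdev
    return stats.truncnorm.rvs(aa, bb, loc=mean, scale=sdev, size=n,
                               random_state=rng)


def _stage_individuals(stage: str, n: int, config: SurveyConfig,
                       rng: np.random.Generator, *, swimmers: bool
                       ) -> list[Individual]:
    if n == 0:
        return []
    lengths = _stage_lengths(stage, n, config, rng)
    if stage.endswith("juvenile"):
        return [Individual(float(x), JUVENILE) for x in lengths]
    if "male" in stage and "female" not in stage:
        p_ix = (config.intersex_fraction_swimmers if swimmers
                else config.intersex_fraction_residents)
        ix = rng.random(n) < p_ix
        return [Individual(float(x), INTERSEX if flag else MALE)
                for x, flag in zip(lengths, ix)]
    ovig = stage == "ovigerous_female"
    return [Individual(float(x), FEMALE, ovigerous=ovig) for x in lengths]


def generate_survey(config: SurveyConfig | None = None, *,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[NetSample], list[CoreSample], TruthRecord]:
    """Generate a complete survey of net and core samples plus its truth.

    Deterministic for a given ``(config, seed)``.
    """
    config = config or SurveyConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    sim = simulate_counts(config, rng=rng)

    nets: list[NetSample] = []
    for row in sim.net_table.itertuples(index=False):
        individuals: list[Individual] = []
        for s in STAGES:
            individuals.extend(_stage_individuals(
                s, int(getattr(row, f"obs_{s}")), config, rng, swimmers=True))
        nets.append(NetSample(site=row.site, round=row.round, night=row.night,
                              net_id=row.net, subsample_fraction=row.fraction,
                              filtered_volume_m3=row.volume_m3,
                              individuals=tuple(individuals)))

    cores: list[CoreSample] = []
    for row in sim.core_table.itertuples(index=False):
        individuals = []
        for s in STAGES:
            individuals.extend(_stage_individuals(
                s, int(getattr(row, f"count_{s}")), config, rng, swimmers=False))
        cores.append(CoreSample(site=row.site, round=row.round, core_id=row.core,
                                core_area_m2=config.core_area_m2,
                                individuals=tuple(individuals)))
    return nets, cores, sim.truth


def generate_null_swimmers(core_samples: list[CoreSample], m: int,
                           rng: np.random.Generator | None = None, *,
                           replace: bool = True) -> list[Individual]:
    """Draw ``m`` swimmers from the pooled resident pool.

    Under this null (swimmers are a random subsample of the residents) a
    correctly calibrated size-distribution comparison flags about 5% of
    classes.  ``replace=False`` with ``m`` equal to the pool size returns a
    permutation of the residents.
    """
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    pool = [ind for core in core_samples for ind in core.individuals]
    if not pool:
        raise ValueError("resident pool is empty")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.choice(len(pool), size=m, replace=replace)
    return [pool[i] for i in idx]


def sample_resident_lengths(config: SurveyConfig, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """``n`` body lengths from the nominal resident stage mixture."""
    mix = config.stage_mix
    probs = np.array([mix[s] for s in STAGES])
    counts = rng.multinomial(n, probs / probs.sum())
    parts = [_stage_lengths(s, int(c), config, rng)
             for s, c in zip(STAGES, counts) if c]
    return np.concatenate(parts) if parts else np.empty(0)


def simulate_anova_responses(components: Mapping[str, float], *,
                             a: int = 9, b: int = 3, c: int = 3, n: int = 3,
                             grand_mean: float = 0.0,
                             rng: np.random.Generator | None = None
                             ) -> pd.DataFrame:
    """Replicate-level responses drawn directly from the random-effects
    model with the given variance ``components`` (keys as in
    :data:`mudswim.anova.SOURCES`).  Used to study the variance-component
    estimators themselves, free of count noise."""
    if rng is None:
        rng = np.random.default_rng()
    sd = {k: math.sqrt(float(components.get(k, 0.0))) for k in _VARIANCE_LEVELS}
    y = (grand_mean
         + rng.normal(0, sd["site"], size=(a, 1, 1, 1))
         + rng.normal(0, sd["round"], size=(1, b, 1, 1))
         + rng.normal(0, sd["round_x_site"], size=(a, b, 1, 1))
         + rng.normal(0, sd["night"], size=(1, b, c, 1))
         + rng.normal(0, sd["site_x_night"], size=(a, b, c, 1))
         + rng.normal(0, sd["error"], size=(a, b, c, n)))
    idx = pd.MultiIndex.from_product(
        [[f"S{i+1}" for i in range(a)], [f"R{j+1}" for j in range(b)],
         [f"N{k+1}" for k in range(c)], range(n)],
        names=["site", "round", "night", "rep"])
    return pd.DataFrame({"y": y.reshape(-1)}, index=idx).reset_index()
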