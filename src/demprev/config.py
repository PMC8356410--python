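"""Pipeline configuration: one structured YAML file drives every stage.

All randomness flows from a single master seed; each stochastic stage draws
its own seed from the master by a fixed offset so stages are individually
reproducible without user-side seed bookkeeping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# Fixed per-stage seed offsets (stage seeds = (master + offset) mod 2**31).
STAGE_OFFSETS = {
    "bank": 57,
    "population": 101,
    "sampling": 202,
    "responses": 303,
    "missingness": 404,
    "crossval": 505,
    "draws": 606,
}


def stage_seed(master_seed: int, stage: str) -> int:
    if stage not in STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    return (int(master_seed) + STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class ScenarioConfig:
    """Synthetic-scenario knobs.

    Defaults echo the study's scale: a frame of 20,000 persons aged 70+, a
    large self-weighting survey (n ~ 6000) and a small validation subsample
    (expected n ~ 750) oversampled at low cognition, 20 cognition items (12
    anchors, 2 continuous) and 12 function items (8 anchors).
    """

    n_population: int = 20_000
    age_max: int = 103
    # population shares of the 70-79 / 80-89 / 90+ age bands
    age_band_probs: tuple[float, float, float] = (0.70, 0.27, 0.03)
    rho: float = 0.6
    # latent decline per year of age past 70, in reference-SD units
    age_slope_cog: float = -0.04
    age_slope_fun: float = -0.05
    sex_effect_cog: float = 0.0
    sex_effect_fun: float = 0.0
    # diagnosis model: logit p = b0 + b_cog*theta_cog + b_fun*theta_fun
    #                            + b_age*(age-70) + b_sex*sex
    b0: float = -7.5
    b_cog: float = -3.5066  # ln(0.03) per SD
    b_fun: float = -0.7985  # ln(0.45) per SD
    b_age: float = 0.0  # age acts only through the latent traits by default
    b_sex: float = 0.26  # ln(1.3), female vs male
    n_sample_a: int = 6000
    target_n_b: int = 750
    # relative sampling rates for validation draw: cognition tertile (low,
    # mid, high) crossed with age band (70-79, 80-89, 90+)
    oversample_cog: tuple[float, float, float] = (3.0, 1.5, 1.0)
    oversample_age: tuple[float, float, float] = (1.0, 1.5, 2.0)
    psu_block_size: int = 30
    n_cog_items: int = 20
    n_cog_anchors: int = 12
    n_fun_items: int = 12
    n_fun_anchors: int = 8
    n_cog_continuous: int = 2
    ordinal_fraction: float = 0.25
    n_low_loading_items: int = 1
    low_loading_slope: float = 0.2
    missing_rate_cog: float = 0.05
    missing_rate_fun: float = 0.05


@dataclass
class PrepSettings:
    n_bins: int = 10
    min_prop: float = 0.05


@dataclass
class IRTSettings:
    n_nodes: int = 31
    node_bound: float = 5.0
    tol: float = 1e-4
    ll_tol: float = 5e-4  # stop when a cycle improves the loglik less than this
    max_cycles: int = 800
    newton_max_iter: int = 50
    prune_threshold: float = 0.3
    d_scale: float = 1.702


@dataclass
class ClassifierSettings:
    k_folds: int = 10
    n_draws: int = 1000
    threshold: float = 0.5
    weighted_metrics: bool = True


@dataclass
class PrevalenceSettings:
    age_bands: tuple[tuple[int, int], ...] = ((70, 79), (80, 89), (90, 200))
    ci_scale: str = "proportion"  # or "logit"


@dataclass
class PipelineConfig:
    master_seed: int = 20260928
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    prep: PrepSettings = field(default_factory=PrepSettings)
    irt: IRTSettings = field(default_factory=IRTSettings)
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)
    prevalence: PrevalenceSettings = field(default_factory=PrevalenceSettings)

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_cls, section):
            if section is None:
                return dc_cls()
            names = {f.name for f in dataclasses.fields(dc_cls)}
            unknown = set(section) - names
            if unknown:
                raise KeyError(
                    f"unknown {dc_cls.__name__} keys: {sorted(unknown)}"
                )
            kwargs = {}
            for f in dataclasses.fields(dc_cls):
                if f.name not in section:
                    continue
                v = section[f.name]
                if isinstance(v, list):
                    v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kwargs[f.name] = v
            return dc_cls(**kwargs)

        return cls(
            master_seed=int(raw.get("master_seed", cls.master_seed)),
            scenario=build(ScenarioConfig, raw.get("scenario")),
            prep=build(PrepSettings, raw.get("prep")),
            irt=build(IRTSettings, raw.get("irt")),
            classifier=build(ClassifierSettings, raw.get("classifier")),
            prevalence=build(PrevalenceSettings, raw.get("prevalence")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})


def recovery_config(master_seed: int = 20260928, n_per_group: int = 3000) -> PipelineConfig:
    """Scenario for parameter-recovery checks.

    Both samples are drawn self-weighting and latent age trends are switched
    off, so the validation (reference) group's latent distribution matches
    the generating standard bivariate normal and fitted item parameters are
    directly comparable to the generating bank.
    """
    cfg = PipelineConfig(master_seed=master_seed)
    sc = cfg.scenario
    sc.n_population = max(4 * n_per_group, 2 * n_per_group + 1000)
    # A keeps ~n_per_group persons after the nested validation draw is
    # deduplicated out of it
    sc.n_sample_a = 2 * n_per_group
    sc.target_n_b = n_per_group
    sc.age_slope_cog = 0.0
    sc.age_slope_fun = 0.0
    sc.oversample_cog = (1.0, 1.0, 1.0)
    sc.oversample_age = (1.0, 1.0, 1.0)
    sc.missing_rate_cog = 0.0
    sc.missing_rate_fun = 0.0
    return cfg
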