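"""Synthetic expression datasets with a known regulatory ground truth.

The generator emulates the statistical structure of the lupin floral
induction time courses: a handful of sampling terms over roughly two
weeks, per-point standard deviations of the size a 3-replicate qRT-PCR
experiment produces, strongly expressed FTc1 versus near-zero FTa2/FTc2,
vernalization-induced increases, and morning/evening differences.  FT-like
profiles are built from templates; AGL8 is then *generated* from a
ground-truth model spec and parameter vector, never templated, so every
pipeline stage can be tested against a known answer.

By default the recorded means are noiseless (the resampling stage supplies
all stochasticity, matching the mean +- s.d. data model); Gaussian
observation noise on the recorded means can be switched on.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_data import (
    BLOCKS,
    FT_GENES,
    TARGET_GENE,
    ConditionKey,
    ExperimentDataset,
    ExpressionSeries,
)
from .reg_models import ModelSpec, ParameterVector, predict_agl8

__all__ = [
    "ProfileTemplate",
    "TruthConfig",
    "SCENARIOS",
    "generate_ft_profiles",
    "generate_agl8",
    "make_dataset",
    "make_scenario",
]

SHAPES = ("flat_low", "flat_high", "rising", "vernalization_induced", "evening_elevated")

#: flat_low genes stay at or below this fraction of the highest flat_high base.
FLAT_LOW_MAX_RATIO = 0.05


@dataclasses.dataclass
class ProfileTemplate:
    """Qualitative expression regime of one FT-like gene.

    The mean level at time t in block (v, d) is

        base_profile(t) * (induction_factor if v == 'V' else 1) + (daytime_offset if d == 'evening' else 0)

    where base_profile is constant at ``base_level`` for the flat shapes
    and a linear ramp from ``base_level`` to ``rise_factor * base_level``
    over the horizon for ``rising``.  The per-point s.d. is
    ``max(noise_cv * mean, sd_floor)``.
    """

    gene: str
    shape: str
    base_level: float
    induction_factor: float = 1.0
    daytime_offset: float = 0.0
    noise_cv: float = 0.1
    sd_floor: float = 0.005
    rise_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.induction_factor < 1.0:
            raise ValueError("induction_factor must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.shape == "vernalization_induced" and self.induction_factor == 1.0:
            raise ValueError("vernalization_induced shape needs induction_factor > 1")
        if self.shape == "evening_elevated" and self.daytime_offset == 0.0:
            raise ValueError("evening_elevated shape needs a nonzero daytime_offset")

    def mean_at(self, t: np.ndarray, block: tuple[str, str], horizon: float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.shape == "rising":
            base = self.base_level * (1.0 + (self.rise_factor - 1.0) * t / horizon)
        else:
            base = np.full_like(t, self.base_level)
        if block[0] == "V":
            base = base * self.induction_factor
        if block[1] == "evening":
            base = base + self.daytime_offset
        return base

    def sd_at(self, mean: np.ndarray) -> np.ndarray:
        return np.maximum(self.noise_cv * np.abs(mean), self.sd_floor)


@dataclasses.dataclass
class TruthConfig:
    """Ground truth for one synthetic experiment.

    ``spec``/``params`` define the generative AGL8 model; ``templates``
    give each FT-like gene its profile.  AGL8's s.d. is set from its own
    generated mean via ``agl8_noise_cv``/``agl8_sd_floor`` (AGL8 means are
    always model output, never a template).
    """

    spec: ModelSpec
    params: ParameterVector
    templates: dict[str, ProfileTemplate]
    n_terms: int = 4
    horizon_days: float = 14.0
    seed: int = 0
    line: str = "synthetic"
    photoperiod: str = "SD_8h"
    agl8_noise_cv: float = 0.1
    agl8_sd_floor: float = 0.005
    noisy_means: bool = False
    clamp_negative: bool = False

    def __post_init__(self) -> None:
        if not 2 <= self.n_terms <= 4:
            raise ValueError("n_terms must be within 2-4 sampling terms")
        missing = [g for g in self.spec.included_genes if g not in self.templates]
        if missing:
            raise ValueError(f"templates missing for truth genes {missing}")
        if TARGET_GENE in self.templates:
            raise ValueError("AGL8 is generated from the truth model, never templated")
        highs = [
            t.base_level for t in self.templates.values() if t.shape == "flat_high"
        ]
        if highs:
            cap = FLAT_LOW_MAX_RATIO * max(highs)
            for t in self.templates.values():
                if t.shape == "flat_low" and t.base_level > cap:
                    raise ValueError(
                        f"{t.gene}: flat_low base {t.base_level} exceeds "
                        f"{FLAT_LOW_MAX_RATIO:.0%} of the flat_high base"
                    )

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon_days, self.n_terms)

    @property
    def term_labels(self) -> tuple[str, ...]:
        return tuple(f"T{i + 1}" for i in range(self.n_terms))


def _series(cfg: TruthConfig, block, gene, mean, sd) -> ExpressionSeries:
    cond = ConditionKey(cfg.line, cfg.photoperiod, block[0], block[1])
    return ExpressionSeries(
        condition=cond,
        gene=gene,
        terms=cfg.term_labels,
        time_days=cfg.times,
        mean=mean,
        sd=sd,
    )


def generate_ft_profiles(cfg: TruthConfig) -> ExperimentDataset:
    """FT-like series for all 4 blocks from the templates (no AGL8 yet).

    With ``noisy_means`` on, Gaussian noise of one template s.d. is added
    to the recorded means; otherwise generation is deterministic.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    series = {}
    t = cfg.times
    for block in BLOCKS:
        for gene in FT_GENES:
            tpl = cfg.templates.get(gene)
            if tpl is None:
                # genes outside the truth model default to near-zero noise floor
                tpl = ProfileTemplate(gene=gene, shape="flat_low", base_level=0.01)
            mean = tpl.mean_at(t, block, cfg.horizon_days)
            sd = tpl.sd_at(mean)
            if cfg.noisy_means:
                mean = mean + rng.normal(0.0, sd)
                if cfg.clamp_negative:
                    mean = np.maximum(mean, 0.0)
            series[(block, gene)] = _series(cfg, block, gene, mean, sd)
    return ExperimentDataset(line=cfg.line, photoperiod=cfg.photoperiod, series=series)


def generate_agl8(
    cfg: TruthConfig, ft_data: ExperimentDataset
) -> dict[tuple[tuple[str, str], str], ExpressionSeries]:
    """AGL8 series predicted by the ground-truth model from the FT means."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    out = {}
    for block in BLOCKS:
        t = ft_data.get(block, cfg.spec.included_genes[0]).time_days
        ft = {g: ft_data.get(block, g).mean for g in cfg.spec.included_genes}
        mean = np.asarray(
            predict_agl8(cfg.spec, cfg.params, block, ft, t - t[0]), dtype=float
        )
        if np.any(mean < 0) and cfg.clamp_negative:
            import warnings

            warnings.warn(
                f"block {block}: negative truth AGL8 clamped at 0", RuntimeWarning
            )
            mean = np.maximum(mean, 0.0)
        sd = np.maximum(cfg.agl8_noise_cv * np.abs(mean), cfg.agl8_sd_floor)
        if cfg.noisy_means:
            mean = mean + rng.normal(0.0, sd)
        out[(block, TARGET_GENE)] = _series(cfg, block, TARGET_GENE, mean, sd)
    return out


def make_dataset(cfg: TruthConfig) -> ExperimentDataset:
    """Full validated dataset: templated FT profiles + generated AGL8."""
    ds = generate_ft_profiles(cfg)
    ds.series.update(generate_agl8(cfg, ds))
    ds.validate()
    return ds


# -- canned scenarios ------------------------------------------------------


def _params(spec: ModelSpec, c0: dict, c: dict) -> ParameterVector:
    return ParameterVector(c0=dict(c0), c=dict(c))


def _flat_low(gene: str) -> ProfileTemplate:
    return ProfileTemplate(gene=gene, shape="flat_low", base_level=0.01)


def _scenario_ku_like_sd(seed: int) -> TruthConfig:
    """Early-flowering line under short days: FTc1 is the sole activator.

    FTc1 is strongly expressed, rises toward flowering, is slightly
    vernalization-induced and higher in the evening; the other three
    FT-like genes sit at ~1% of its level.  Truth is the single-gene model
    (H5) with a condition-independent regulatory coefficient.
    """
    spec = ModelSpec.hypothesis("H5")
    params = _params(
        spec,
        c0={b: 0.5 for b in BLOCKS},
        c={(0, "V"): 2.0, (0, "N"): 2.0},
    )
    templates = {
        "FTc1": ProfileTemplate(
            gene="FTc1",
            shape="rising",
            base_level=1.0,
            rise_factor=2.0,
            induction_factor=1.3,
            daytime_offset=0.5,
        ),
        "FTa1": _flat_low("FTa1"),
        "FTa2": _flat_low("FTa2"),
        "FTc2": _flat_low("FTc2"),
    }
    return TruthConfig(spec=spec, params=params, templates=templates, seed=seed, line="Ku_like")


def _scenario_pal_like_sd(seed: int) -> TruthConfig:
    """Intermediate line: FTc1-dominant with vernalization-dependent c1.

    The regulatory coefficient is twice as large after vernalization
    (c1(V) = 2 c1(N)), emulating partially retained vernalization
    sensitivity; intercepts differ across all four blocks.
    """
    spec = ModelSpec.hypothesis("H5")
    params = _params(
        spec,
        c0={
            ("V", "morning"): 0.8,
            ("V", "evening"): 0.6,
            ("N", "morning"): 0.5,
            ("N", "evening"): 0.4,
        },
        c={(0, "V"): 3.0, (0, "N"): 1.5},
    )
    templates = {
        "FTc1": ProfileTemplate(
            gene="FTc1",
            shape="rising",
            base_level=1.0,
            rise_factor=3.0,
            daytime_offset=0.3,
            noise_cv=0.05,
        ),
        "FTa1": _flat_low("FTa1"),
        "FTa2": _flat_low("FTa2"),
        "FTc2": _flat_low("FTc2"),
    }
    return TruthConfig(
        spec=spec,
        params=params,
        templates=templates,
        seed=seed,
        line="Pal_like",
        agl8_noise_cv=0.05,
    )


def _scenario_ku_wild_ld(seed: int) -> TruthConfig:
    """Wild (late-flowering) line under long days: FTc1 + FTa1 joint drive.

    Both genes carry substantial, vernalization-induced expression and the
    shared regulatory coefficient is vernalization-stratified, so neither
    gene alone explains AGL8.
    """
    spec = ModelSpec.model("M1", included_genes=("FTc1", "FTa1"))
    params = _params(
        spec,
        c0={b: 0.4 for b in BLOCKS},
        c={(0, "V"): 2.5, (0, "N"): 1.2},
    )
    templates = {
        "FTc1": ProfileTemplate(
            gene="FTc1",
            shape="rising",
            base_level=0.8,
            rise_factor=2.5,
            induction_factor=2.0,
            daytime_offset=0.3,
        ),
        "FTa1": ProfileTemplate(
            gene="FTa1",
            shape="rising",
            base_level=0.6,
            rise_factor=3.5,
            induction_factor=1.5,
            daytime_offset=0.4,
        ),
        "FTa2": _flat_low("FTa2"),
        "FTc2": _flat_low("FTc2"),
    }
    return TruthConfig(
        spec=spec,
        params=params,
        templates=templates,
        seed=seed,
        line="ku_like",
        photoperiod="LD_16h",
    )


def _scenario_null_equal(seed: int) -> TruthConfig:
    """Full model truth with all four genes contributing equally.

    Every gene gets an identical rising template and one shared,
    condition-independent coefficient: excluding any single gene is
    compensable by rescaling, which makes this the reference scenario for
    type-I calibration of the knockout test.
    """
    spec = ModelSpec.hypothesis("H0")
    params = _params(
        spec,
        c0={b: 0.5 for b in BLOCKS},
        c={(0, "V"): 1.0, (0, "N"): 1.0},
    )
    tpl = lambda g: ProfileTemplate(  # noqa: E731
        gene=g, shape="rising", base_level=0.5, rise_factor=2.0, noise_cv=0.05
    )
    templates = {g: tpl(g) for g in FT_GENES}
    return TruthConfig(
        spec=spec,
        params=params,
        templates=templates,
        seed=seed,
        line="null_equal",
        agl8_noise_cv=0.05,
    )


def _scenario_time_gated(seed: int) -> TruthConfig:
    """Truth in which the FT influence grows linearly with time (family M7)."""
    spec = ModelSpec.model("M7")
    params = _params(
        spec,
        c0={b: 0.5 for b in BLOCKS},
        c={(0, "V"): 0.3, (0, "N"): 0.3},
    )
    templates = {
        "FTc1": ProfileTemplate(
            gene="FTc1", shape="rising", base_level=1.0, rise_factor=2.0
        ),
        "FTa1": ProfileTemplate(
            gene="FTa1", shape="vernalization_induced", base_level=0.5, induction_factor=2.0
        ),
        "FTa2": _flat_low("FTa2"),
        "FTc2": _flat_low("FTc2"),
    }
    return TruthConfig(spec=spec, params=params, templates=templates, seed=seed, line="time_gated")


SCENARIOS = {
    "Ku_like_SD": _scenario_ku_like_sd,
    "Pal_like_SD": _scenario_pal_like_sd,
    "ku_like_LD": _scenario_ku_wild_ld,
    "null_equal": _scenario_null_equal,
    "time_gated": _scenario_time_gated,
}


def make_scenario(
    name: str, seed: int = 0, noise_cv: float | None = None
) -> TruthConfig:
    """A catalogued, reproducible TruthConfig by name.

    ``noise_cv`` overrides the relative measurement noise of every gene
    (including AGL8) — used e.g. for noise-ladder recovery studies.
    """
    try:
        factory = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    cfg = factory(seed)
    if noise_cv is not None:
        cfg = dataclasses.replace(
            cfg,
            templates={
                g: dataclasses.replace(t, noise_cv=noise_cv)
                for g, t in cfg.templates.items()
            },
            agl8_noise_cv=noise_cv,
        )
    return cfg
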