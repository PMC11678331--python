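"""Regression models of AGL8 activation by FT-like florigen genes.

The floral integrator *AGL8* is modelled at each time point as a linear
combination of (transformed) FT-like expression levels, with coefficients
stratified by experimental condition:

    AGL8 = c0[block] + sum_g c[g, stratum(block)] * r_g(FT, t)

* ``c0`` takes a separate value in each of the four (vernalization x
  daytime) condition blocks, absorbing non-FT regulation.
* ``c`` (the regulatory coefficients) are shared across blocks, or vary
  between vernalized/non-vernalized or morning/evening strata, per the
  :class:`ShareScheme`.
* ``r_g`` is the regulator term of group ``g``: a plain sum of the group's
  FT levels (families M1-M3), a sum of squares (M4), an exponential (M5),
  a logarithm (M6), or a time-gated sum (M7).

Families differ in how the four predictors are grouped:

* **M1** — one group, all included genes share a single coefficient;
* **M2** — FTc1 singled out as the major regulator, the rest pooled;
* **M3** — four singleton groups, one coefficient per gene;
* **M4-M7** — one group, as M1, with a nonlinear or time-dependent term.

The in-silico knockout hypotheses H0-H5 are members of the M1 family with
genes removed from the regulator sum: H0 keeps all four (pure M1), H1-H4
each drop one gene (FTa2, FTa1, FTc2, FTc1 respectively) and H5 keeps only
FTc1.  All six have the same number of free parameters.

Every family is linear in its parameters (the nonlinearity sits in the
regressor transform only), so the fitting cost is a quadratic form with a
unique minimum whenever the design has full rank.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .core_data import BLOCKS, FT_GENES, TARGET_GENE
from .preprocess import DenseDataset, ResampledDataset

__all__ = [
    "FAMILIES",
    "HYPOTHESES",
    "ShareScheme",
    "ModelSpec",
    "ParameterVector",
    "ModelDomainError",
    "count_parameters",
    "group_regressors",
    "regressor",
    "predict_agl8",
    "cost",
    "block_arrays",
]

FAMILIES: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5", "M6", "M7")
HYPOTHESES: tuple[str, ...] = ("H0", "H1", "H2", "H3", "H4", "H5")

#: Gene excluded by each single-knockout hypothesis.
_HYP_EXCLUDED: dict[str, tuple[str, ...]] = {
    "H0": (),
    "H1": ("FTa2",),
    "H2": ("FTa1",),
    "H3": ("FTc2",),
    "H4": ("FTc1",),
    "H5": ("FTa1", "FTc2", "FTa2"),
}

M6_EPSILON = 1e-9
M5_MAX_EXPONENT = 700.0


class ModelDomainError(ValueError):
    """A regressor transform was evaluated outside its domain."""


@dataclasses.dataclass(frozen=True)
class ShareScheme:
    """How coefficients are shared across the four condition blocks.

    ``c0`` always stratifies by all four blocks; only the regulatory
    coefficients' stratifier is switchable (none / vernalization /
    daytime), which is exactly the sharing-variant comparison the
    condition-stratified design supports.
    """

    c1_varies_by: str = "vernalization"

    def __post_init__(self) -> None:
        if self.c1_varies_by not in ("none", "vernalization", "daytime"):
            raise ValueError(f"unknown c1_varies_by {self.c1_varies_by!r}")

    @property
    def strata(self) -> tuple[str, ...]:
        if self.c1_varies_by == "none":
            return ("all",)
        if self.c1_varies_by == "vernalization":
            return ("V", "N")
        return ("morning", "evening")

    def stratum_of(self, block: tuple[str, str]) -> str:
        if self.c1_varies_by == "none":
            return "all"
        if self.c1_varies_by == "vernalization":
            return block[0]
        return block[1]


def _default_groups(family: str, included: tuple[str, ...]) -> tuple[tuple[str, ...], ...]:
    if family == "M2":
        major = ("FTc1",)
        rest = tuple(g for g in included if g != "FTc1")
        return (major, rest) if rest else (major,)
    if family == "M3":
        return tuple((g,) for g in included)
    return (included,)


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One member of the model family, fully determining the free parameters."""

    family: str
    included_genes: tuple[str, ...]
    regulator_groups: tuple[tuple[str, ...], ...]
    share: ShareScheme = ShareScheme()
    hypothesis_label: str | None = None
    #: M4 regressor form: sum of squared inputs (default) or squared sum.
    m4_square_of_sum: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        bad = [g for g in self.included_genes if g not in FT_GENES]
        if bad:
            raise ValueError(f"genes {bad} are not FT-like predictors")
        if TARGET_GENE in self.included_genes:
            raise ValueError("AGL8 is the target and never a predictor")
        flat = [g for grp in self.regulator_groups for g in grp]
        if sorted(flat) != sorted(self.included_genes):
            raise ValueError("regulator_groups must partition included_genes")
        if self.family in ("M1", "M4", "M5", "M6", "M7") and len(self.regulator_groups) != 1:
            raise ValueError(f"{self.family} uses a single regulator group")

    # -- constructors -----------------------------------------------------

    @classmethod
    def model(
        cls,
        family: str,
        included_genes: tuple[str, ...] = FT_GENES,
        c1_varies_by: str = "vernalization",
        **kw,
    ) -> "ModelSpec":
        included = tuple(included_genes)
        return cls(
            family=family,
            included_genes=included,
            regulator_groups=_default_groups(family, included),
            share=ShareScheme(c1_varies_by),
            **kw,
        )

    @classmethod
    def hypothesis(cls, label: str, c1_varies_by: str = "vernalization") -> "ModelSpec":
        if label not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {label!r}")
        excluded = _HYP_EXCLUDED[label]
        included = tuple(g for g in FT_GENES if g not in excluded)
        return cls(
            family="M1",
            included_genes=included,
            regulator_groups=(included,),
            share=ShareScheme(c1_varies_by),
            hypothesis_label=label,
        )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "excluded_genes": [g for g in FT_GENES if g not in self.included_genes],
            "c1_varies_by": self.share.c1_varies_by,
            "hypothesis": self.hypothesis_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        if d.get("hypothesis"):
            return cls.hypothesis(d["hypothesis"], d.get("c1_varies_by", "vernalization"))
        excluded = tuple(d.get("excluded_genes", ()))
        included = tuple(g for g in FT_GENES if g not in excluded)
        return cls.model(
            d["family"], included, d.get("c1_varies_by", "vernalization")
        )

    @property
    def label(self) -> str:
        return self.hypothesis_label or self.family

    @property
    def n_groups(self) -> int:
        return len(self.regulator_groups)


@dataclasses.dataclass
class ParameterVector:
    """Free parameters of one spec: 4 block intercepts + grouped coefficients.

    ``c0`` maps each (vernalization, daytime) block to its intercept;
    ``c`` maps (group_index, stratum_label) to a regulatory coefficient.
    Values are unconstrained in sign.
    """

    c0: dict[tuple[str, str], float]
    c: dict[tuple[int, str], float]

    def to_array(self, spec: ModelSpec) -> np.ndarray:
        vals = [self.c0[b] for b in BLOCKS]
        for gi in range(spec.n_groups):
            for s in spec.share.strata:
                vals.append(self.c[(gi, s)])
        return np.array(vals, dtype=float)

    @classmethod
    def from_array(cls, spec: ModelSpec, arr: np.ndarray) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        if arr.size != count_parameters(spec):
            raise ValueError(
                f"expected {count_parameters(spec)} parameters, got {arr.size}"
            )
        c0 = {b: float(arr[i]) for i, b in enumerate(BLOCKS)}
        c = {}
        i = len(BLOCKS)
        for gi in range(spec.n_groups):
            for s in spec.share.strata:
                c[(gi, s)] = float(arr[i])
                i += 1
        return cls(c0=c0, c=c)

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "ParameterVector":
        return cls.from_array(spec, np.zeros(count_parameters(spec)))


def count_parameters(spec: ModelSpec) -> int:
    """4 block intercepts plus one coefficient per (group, stratum)."""
    return len(BLOCKS) + spec.n_groups * len(spec.share.strata)


def group_regressors(
    spec: ModelSpec,
    ft_levels: dict[str, np.ndarray],
    t: np.ndarray | float = 0.0,
) -> list[np.ndarray]:
    """The transformed regulator term of each group, per the model family.

    ``ft_levels`` maps gene name -> expression level(s); ``t`` is time in
    days since the block's first sampling term (used by M7 only).
    """
    missing = [g for g in spec.included_genes if g not in ft_levels]
    if missing:
        raise ValueError(f"ft_levels missing genes {missing}")
    t = np.asarray(t, dtype=float)
    out = []
    for group in spec.regulator_groups:
        levels = [np.asarray(ft_levels[g], dtype=float) for g in group]
        total = np.sum(levels, axis=0)
        if spec.family in ("M1", "M2", "M3"):
            r = total
        elif spec.family == "M4":
            r = total**2 if spec.m4_square_of_sum else np.sum(
                [lv**2 for lv in levels], axis=0
            )
        elif spec.family == "M5":
            expo = np.asarray(total, dtype=float)
            if np.any(expo > M5_MAX_EXPONENT):
                warnings.warn(
                    "M5 exponent clamped at 700 to avoid overflow",
                    RuntimeWarning,
                    stacklevel=2,
                )
                expo = np.minimum(expo, M5_MAX_EXPONENT)
            r = np.exp(expo)
        elif spec.family == "M6":
            arg = total + M6_EPSILON
            if np.any(arg <= 0):
                raise ModelDomainError(
                    "M6 log regressor: sum of FT levels + epsilon <= 0"
                )
            r = np.log(arg)
        elif spec.family == "M7":
            r = t * total
        else:  # pragma: no cover
            raise AssertionError(spec.family)
        out.append(np.asarray(r, dtype=float))
    return out


def regressor(
    spec: ModelSpec,
    ft_levels: dict[str, np.ndarray],
    t: np.ndarray | float = 0.0,
    group: int = 0,
) -> np.ndarray:
    """Regulator term of one group (the only group for M1/M4-M7)."""
    return group_regressors(spec, ft_levels, t)[group]


def predict_agl8(
    spec: ModelSpec,
    params: ParameterVector,
    block: tuple[str, str],
    ft_levels: dict[str, np.ndarray],
    t: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Model AGL8 level(s) in one condition block."""
    stratum = spec.share.stratum_of(block)
    pred = np.asarray(params.c0[block], dtype=float)
    for gi, r in enumerate(group_regressors(spec, ft_levels, t)):
        pred = pred + params.c[(gi, stratum)] * r
    return pred


# -- cost function --------------------------------------------------------


def block_arrays(
    data: ResampledDataset | DenseDataset | "ExperimentDataset",
    block: tuple[str, str],
    genes: tuple[str, ...],
):
    """(ft_levels, agl8, sigma, t_rel) arrays of one block, for any data kind.

    For a resampled draw, expression values come from the draw and sigmas
    from its dense reference; for observed/dense data, values are the
    recorded means.  ``t_rel`` is time since the block's first term.
    """
    if isinstance(data, ResampledDataset):
        ref = data.reference
        ft = {g: data.get(block, g) for g in genes}
        agl8 = data.get(block, TARGET_GENE)
        sigma = ref.get(block, TARGET_GENE).sd
        t = ref.get(block, TARGET_GENE).time_days
    else:
        ft = {g: data.get(block, g).mean for g in genes}
        s = data.get(block, TARGET_GENE)
        agl8, sigma, t = s.mean, s.sd, s.time_days
    return ft, agl8, sigma, t - t[0]


def block_weights(
    data, sd_floor: float = 1e-6
) -> dict[tuple[str, str], float]:
    """Per-block weight 1 / sum(sigma^2), with a floor applied to sigma."""
    w = {}
    for block in BLOCKS:
        _, _, sigma, _ = block_arrays(data, block, ())
        sig = np.maximum(sigma, sd_floor)
        total = float(np.sum(sig**2))
        if total <= 0:
            raise ValueError(f"block {block}: summed AGL8 variance is zero")
        w[block] = 1.0 / total
    return w


def cost(
    spec: ModelSpec,
    params: ParameterVector,
    data: ResampledDataset | DenseDataset | "ExperimentDataset",
    sd_floor: float = 1e-6,
) -> float:
    """Block-weighted fitting cost F.

    Over the four (vernalization x daytime) blocks, each block contributes
    its residual sum of squares divided by its *summed* AGL8 variance —
    a single weight per block, not per-point weighting:

        F = sum_b  sum_i (AGL8_data_bi - AGL8_model_bi)^2 / sum_i sigma_bi^2

    Points with sigma = 0 enter the denominator at ``sd_floor`` (sampling
    is never floored).
    """
    weights = block_weights(data, sd_floor)
    total = 0.0
    for block in BLOCKS:
        ft, agl8, _, t = block_arrays(data, block, spec.included_genes)
        pred = predict_agl8(spec, params, block, ft, t)
        res = agl8 - pred
        total += float(np.sum(res**2)) * weights[block]
    return total
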