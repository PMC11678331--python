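"""Time-grid densification and parametric resampling of expression data.

Sampling terms are sparse (2-4 per block), so before fitting, each series
is linearly interpolated over time to a denser grid, and an ensemble of
pseudo-datasets is drawn by sampling every (block, gene, time) value from
Normal(mean, sd) of the corresponding dense point.  Fitting each draw and
summarising over the ensemble propagates the measurement uncertainty of
the qRT-PCR means into the regression parameters (a parametric bootstrap).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_data import (
    ALL_GENES,
    BLOCKS,
    ExperimentDataset,
    ExpressionSeries,
)

__all__ = ["DenseSeries", "DenseDataset", "ResampledDataset", "interpolate", "resample"]


@dataclasses.dataclass
class DenseSeries:
    """An expression series on an enlarged time grid.

    ``observed`` flags which points come from the experiment; the others
    are linear interpolants (both mean and s.d. interpolated linearly).
    """

    base: ExpressionSeries
    time_days: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    observed: np.ndarray  # bool mask

    @property
    def gene(self) -> str:
        return self.base.gene

    @property
    def n_points(self) -> int:
        return self.time_days.size


@dataclasses.dataclass
class DenseDataset:
    """Interpolated counterpart of :class:`ExperimentDataset`."""

    line: str
    photoperiod: str
    series: dict[tuple[tuple[str, str], str], DenseSeries]
    n_intermediate: int

    def get(self, block: tuple[str, str], gene: str) -> DenseSeries:
        return self.series[(block, gene)]

    def block_times(self, block: tuple[str, str]) -> np.ndarray:
        from .core_data import TARGET_GENE

        return self.get(block, TARGET_GENE).time_days

    @property
    def n_points_total(self) -> int:
        """Total AGL8 data points over the four blocks (the AICc sample size m)."""
        from .core_data import TARGET_GENE

        return sum(self.get(b, TARGET_GENE).n_points for b in BLOCKS)


@dataclasses.dataclass
class ResampledDataset:
    """One Monte-Carlo draw of expression levels from a dense dataset.

    ``values`` maps (block, gene) to an array aligned with the dense time
    grid.  Draws are untruncated Gaussian, so values may be negative.
    """

    replicate_index: int
    values: dict[tuple[tuple[str, str], str], np.ndarray]
    reference: DenseDataset

    def get(self, block: tuple[str, str], gene: str) -> np.ndarray:
        return self.values[(block, gene)]


def _dense_grid(t: np.ndarray, n_intermediate: int) -> np.ndarray:
    if n_intermediate == 0:
        return t.copy()
    pieces = []
    for i in range(t.size - 1):
        seg = np.linspace(t[i], t[i + 1], n_intermediate + 2)
        pieces.append(seg[:-1])
    pieces.append(t[-1:])
    return np.concatenate(pieces)


def interpolate(ds: ExperimentDataset, n_intermediate: int = 3) -> DenseDataset:
    """Insert ``n_intermediate`` equally spaced interior points per interval.

    Means and standard deviations are both interpolated linearly; observed
    points are kept bit-exact.  A series with n observed terms yields
    ``n + n_intermediate * (n - 1)`` dense points.
    """
    if n_intermediate < 0:
        raise ValueError("n_intermediate must be >= 0")
    dense: dict[tuple[tuple[str, str], str], DenseSeries] = {}
    for key, s in ds.series.items():
        t = s.time_days
        grid = _dense_grid(t, n_intermediate)
        # exact on observed points: np.interp is, at segment endpoints
        mean = np.interp(grid, t, s.mean)
        sd = np.interp(grid, t, s.sd)
        observed = np.isin(grid, t)
        mean[observed] = s.mean
        sd[observed] = s.sd
        dense[key] = DenseSeries(
            base=s, time_days=grid, mean=mean, sd=sd, observed=observed
        )
    return DenseDataset(
        line=ds.line,
        photoperiod=ds.photoperiod,
        series=dense,
        n_intermediate=n_intermediate,
    )


def resample(
    dense: DenseDataset, n_samples: int, seed: int
) -> list[ResampledDataset]:
    """Draw ``n_samples`` pseudo-datasets, one Normal(mean, sd) value per point.

    One global seed spawns independent per-replicate substreams, so the
    ensemble is reproducible as a whole and each replicate individually.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_samples)
    out = []
    keys = sorted(dense.series.keys(), key=_key_order)
    for r, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        values = {}
        for key in keys:
            s = dense.series[key]
            values[key] = rng.normal(s.mean, s.sd)
        out.append(ResampledDataset(replicate_index=r, values=values, reference=dense))
    return out


def _key_order(key: tuple[tuple[str, str], str]) -> tuple[int, int]:
    block, gene = key
    return (BLOCKS.index(block), ALL_GENES.index(gene))
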