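import numpy as np
import pytest

from floralfit.core_data import (
    ALL_GENES,
    BLOCKS,
    ConditionKey,
    ExperimentDataset,
    ExpressionSeries,
)


def make_series(block, gene, time, mean, sd, line="L", photoperiod="SD_8h"):
    time = np.asarray(time, dtype=float)
    return ExpressionSeries(
        condition=ConditionKey(line, photoperiod, block[0], block[1]),
        gene=gene,
        terms=tuple(f"T{i + 1}" for i in range(time.size)),
        time_days=time,
        mean=np.asarray(mean, dtype=float),
        sd=np.asarray(sd, dtype=float),
    )


def build_dataset(values, line="L", photoperiod="SD_8h"):
    """Dataset from {(block, gene): (time, mean, sd)} triples."""
    series = {
        key: make_series(key[0], key[1], t, m, s, line, photoperiod)
        for key, (t, m, s) in values.items()
    }
    return ExperimentDataset(line=line, photoperiod=photoperiod, series=series)


@pytest.fixture
def toy_dataset():
    """Complete 5-gene x 4-block dataset, 3 terms, deterministic values.

    AGL8 satisfies AGL8 = 1 + 2 * FTc1 exactly; the other genes carry
    small distinct profiles.
    """
    values = {}
    t = np.array([0.0, 5.0, 10.0])
    for bi, block in enumerate(BLOCKS):
        ftc1 = np.array([1.0, 2.0, 3.0]) + 0.1 * bi
        profiles = {
            "FTc1": ftc1,
            "FTa1": np.array([0.2, 0.3, 0.25]),
            "FTc2": np.array([0.01, 0.02, 0.015]),
            "FTa2": np.array([0.03, 0.01, 0.02]),
            "AGL8": 1.0 + 2.0 * ftc1,
        }
        for gene in ALL_GENES:
            values[(block, gene)] = (t, profiles[gene], np.full(3, 0.1))
    return build_dataset(values)
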