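from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from overlayde import (
    CountMatrix,
    ExpressionMatrix,
    GeneLengthTable,
    SampleDesign,
    SynthConfig,
    analyze,
    generate_counts,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def small_counts() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            {"s1": [10, 20, 5], "s2": [5, 0, 40]},
            index=["gA", "gB", "gC"],
        )
    )


@pytest.fixture
def small_lengths() -> GeneLengthTable:
    return GeneLengthTable(
        pd.Series([1000.0, 2000.0, 500.0], index=["gA", "gB", "gC"])
    )


@pytest.fixture
def two_cond_design() -> SampleDesign:
    return SampleDesign(
        pd.DataFrame(
            {
                "condition": ["cond1", "cond1", "cond2", "cond2"],
                "replicate": ["r1", "r2", "r1", "r2"],
            },
            index=["cond1_r1", "cond1_r2", "cond2_r1", "cond2_r2"],
        )
    )


def make_expression(values: dict, design: SampleDesign | None = None,
                    scale: str = "linear") -> ExpressionMatrix:
    df = pd.DataFrame(values)
    df.index = [f"g{i + 1:03d}" for i in range(len(df))]
    return ExpressionMatrix(df, scale=scale, design=design)


@pytest.fixture(scope="session")
def calibration_dataset():
    """The default synthetic study: 2000 genes, 15% replicate CV,
    200 DE genes at >= 4-fold, fixed seed."""
    cfg = SynthConfig(seed=1)
    cm, gl, design, truth = generate_counts(cfg)
    return cfg, cm, gl, design, truth


@pytest.fixture(scope="session")
def calibration_analysis(calibration_dataset):
    _, cm, gl, design, truth = calibration_dataset
    return analyze(cm, gl, design), truth
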