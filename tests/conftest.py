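"""Shared fixtures: small on-the-fly data files and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icvnorm.synthetic import (
    RegionParams,
    SyntheticSpec,
    calibrate_sigma,
    simulate_table,
)

#: Sample-weighted mean ICV of the default 49M/92F cohort, used to place
#: scale constants in single-region test specs.
MEAN_ICV = (49 * 1712.01 + 92 * 1513.88) / 141


def make_region(beta: float, target_se: float, typical_vol: float) -> RegionParams:
    """Single-region ground truth with sigma calibrated to a target SE."""
    alpha = typical_vol / MEAN_ICV**beta
    return RegionParams(
        alpha=alpha, beta=beta, sigma=calibrate_sigma(beta, alpha, target_se)
    )


def one_region_data(
    beta: float,
    target_se: float = 0.10,
    typical_vol: float = 3.5,
    seed: int = 0,
    n_male: int = 49,
    n_female: int = 92,
    noise_mode: str = "additive_normal",
) -> tuple[np.ndarray, np.ndarray, RegionParams]:
    """Simulate one region; returns (icv, voi, true_params)."""
    p = make_region(beta, target_se, typical_vol)
    spec = SyntheticSpec(
        n_male=n_male, n_female=n_female, regions={"roi": p},
        noise_mode=noise_mode, seed=seed,
    )
    icv, voi = simulate_table(spec).pairs("roi")
    return icv, voi, p


@pytest.fixture
def csv_minimal(tmp_path):
    """3-subject CSV with one region, volumes in cc."""
    path = tmp_path / "vols.csv"
    pd.DataFrame(
        {"id": ["a", "b", "c"], "icv": [1500.0, 1600.0, 1700.0],
         "caudate": [3.2, 3.5, 3.8]}
    ).to_csv(path, index=False)
    return path


ASEG_TEXT = """\
# Title Segmentation Statistics
# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, 1600000.0, mm^3
# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean
  1  11  3000  1700.0  Left-Caudate   80.1
  2  50  3100  1800.0  Right-Caudate  79.8
  3  17  4000  2100.0  Left-Hippocampus 71.2
  4  53  3900  2000.0  Right-Hippocampus 70.9
"""

APARC_TEXT = """\
# Table of FreeSurfer cortical parcellation anatomical statistics
# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg
precuneus  5000  3300  9800.0  2.35
superiorfrontal  9000  6100  21500.0  2.65
"""


@pytest.fixture
def aseg_file(tmp_path):
    p = tmp_path / "aseg.stats"
    p.write_text(ASEG_TEXT)
    return p


@pytest.fixture
def aparc_file(tmp_path):
    p = tmp_path / "lh.aparc.stats"
    p.write_text(APARC_TEXT)
    return p
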