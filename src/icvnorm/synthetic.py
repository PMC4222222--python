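"""Synthetic volumetric cohorts with power-law structure.

Generates per-subject tables that mimic the statistical shape of a
FreeSurfer-derived control cohort: ICV drawn from sex-specific normals, and
each regional volume following VOI = alpha * ICV**beta + eps with additive
homoscedastic Gaussian noise (the model's own assumption), or optionally
alpha * ICV**beta * exp(eta) with log-normal noise whose scatter grows with
head size (the assumption implicit in log-log regression).  Every other
module of the package is testable against these tables because the ground
truth (alpha, beta, sigma) is known.

The default cohort reproduces published control-sample conditions: 49 males
and 92 females; ICV means (SD) of 1712.01 (138.54) cc for males and 1513.88
(122.12) cc for females; and 43 regions whose generating exponents equal
the published estimates for the 9 subcortical and 34 cortical volumes.  Per
region, alpha is placed so the typical simulated volume is a plausible cc
magnitude, and sigma is calibrated so that the fitted exponent's standard
error at n = 141 approximates the published SE.  The alpha values are
plausible scales, not estimates from any cohort, and the sigma calibration
is approximate.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._regions import REGION_DEFAULTS
from .exceptions import ValidationError
from .io import VolumeTable

__all__ = ["RegionParams", "SyntheticSpec", "default_spec", "simulate_table"]

#: Table-1-style demographics used by :func:`default_spec`.
DEFAULT_N_MALE = 49
DEFAULT_N_FEMALE = 92
DEFAULT_ICV_MALE = (1712.01, 138.54)
DEFAULT_ICV_FEMALE = (1513.88, 122.12)
DEFAULT_AGE_MALE = (42.68, 10.41)
DEFAULT_AGE_FEMALE = (44.78, 10.41)

# internal seed for the fixed reference ICV sample the sigma calibration
# uses; independent of user seeds so calibration never drifts
_CALIBRATION_SEED = 20141106
_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class RegionParams:
    """Ground-truth generator parameters for one region.

    ``sigma`` is the additive noise SD in cc under ``additive_normal`` and
    the log-scale SD under ``multiplicative_lognormal``.
    """

    alpha: float
    beta: float
    sigma: float


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort; identical specs (including
    seed) always produce identical tables."""

    n_male: int = DEFAULT_N_MALE
    n_female: int = DEFAULT_N_FEMALE
    icv_male: tuple[float, float] = DEFAULT_ICV_MALE
    icv_female: tuple[float, float] = DEFAULT_ICV_FEMALE
    regions: dict[str, RegionParams] = field(default_factory=dict)
    noise_mode: str = "additive_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_mode not in ("additive_normal", "multiplicative_lognormal"):
            raise ValidationError(f"unknown noise_mode {self.noise_mode!r}")
        if self.n_male < 0 or self.n_female < 0:
            raise ValidationError("counts must be nonnegative")
        if self.n_male + self.n_female < 3:
            raise ValidationError("need n_male + n_female >= 3 for downstream fitting")
        for name, (mu, sd) in (("icv_male", self.icv_male), ("icv_female", self.icv_female)):
            if sd <= 0 or mu <= 0:
                raise ValidationError(f"{name}: mean and sd must be positive")
        for r, p in self.regions.items():
            if not np.isfinite(p.beta):
                raise ValidationError(f"region {r!r}: beta must be finite")
            if p.sigma < 0 or p.alpha <= 0:
                raise ValidationError(f"region {r!r}: need sigma >= 0 and alpha > 0")

    # -- (de)serialization ----------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "n_male": self.n_male,
            "n_female": self.n_female,
            "icv_male": list(self.icv_male),
            "icv_female": list(self.icv_female),
            "regions": {
                r: {"alpha": p.alpha, "beta": p.beta, "sigma": p.sigma}
                for r, p in self.regions.items()
            },
            "noise_mode": self.noise_mode,
            "seed": self.seed,
        }
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["regions"] = {r: RegionParams(**v) for r, v in d["regions"].items()}
        d["icv_male"] = tuple(d["icv_male"])
        d["icv_female"] = tuple(d["icv_female"])
        return cls(**d)


def _reference_icv_sample() -> np.ndarray:
    """Fixed n=141 ICV sample (49 M, 92 F) used only for sigma calibration."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    m = rng.normal(*DEFAULT_ICV_MALE, DEFAULT_N_MALE)
    f = rng.normal(*DEFAULT_ICV_FEMALE, DEFAULT_N_FEMALE)
    return np.concatenate([m, f])


def _se_beta_unit_sigma(icv: np.ndarray, alpha: float, beta: float) -> float:
    """SE of the fitted exponent per unit of noise SD, from the Gauss-Newton
    covariance at the true parameters (computed on a geometric-mean-scaled
    axis; the exponent's SE is invariant to that scaling)."""
    g = np.exp(np.mean(np.log(icv)))
    z = icv / g
    a = alpha * g**beta
    zb = z**beta
    J = np.column_stack([zb, a * zb * np.log(z)])
    cov = np.linalg.inv(J.T @ J)
    return float(np.sqrt(cov[1, 1]))


def calibrate_sigma(beta: float, alpha: float, target_se: float) -> float:
    """Noise SD (cc) that makes the exponent's SE approximate ``target_se``
    on the fixed 141-subject reference cohort."""
    icv = _reference_icv_sample()
    return target_se / _se_beta_unit_sigma(icv, alpha, beta)


def default_spec(
    *,
    noise_mode: str = "additive_normal",
    seed: int = 0,
    regions: Mapping[str, tuple[float, float, float]] | None = None,
) -> SyntheticSpec:
    """Cohort spec matching the published study conditions.

    49 males / 92 females with the published sex-specific ICV normals, and
    the 43 catalogued regions at their published exponents.  ``regions`` may
    override the catalogue with a mapping region -> (beta, se_beta,
    typical_volume_cc); per region, alpha = typical_volume / mean_icv**beta
    and sigma is calibrated so the fitted SE at n = 141 is near se_beta.
    """
    catalogue = dict(regions) if regions is not None else REGION_DEFAULTS
    mean_icv = (
        DEFAULT_N_MALE * DEFAULT_ICV_MALE[0] + DEFAULT_N_FEMALE * DEFAULT_ICV_FEMALE[0]
    ) / (DEFAULT_N_MALE + DEFAULT_N_FEMALE)
    region_params = {}
    for name, (beta, se, vol) in catalogue.items():
        alpha = vol / mean_icv**beta
        sigma = calibrate_sigma(beta, alpha, se)
        region_params[name] = RegionParams(alpha=alpha, beta=beta, sigma=sigma)
    return SyntheticSpec(regions=region_params, noise_mode=noise_mode, seed=seed)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label stream: adding a region never perturbs the
    draws of another."""
    return np.random.default_rng([seed, zlib.crc32(label.encode()), 1])


def _draw_positive(
    rng: np.random.Generator, draw, n: int, what: str
) -> tuple[np.ndarray, int]:
    """Draw n values, resampling nonpositive ones; bounded retries."""
    out = draw(rng, n)
    n_resampled = 0
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = out <= 0
        if not bad.any():
            return out, n_resampled
        n_resampled += int(bad.sum())
        out[bad] = draw(rng, int(bad.sum()))
    raise ValidationError(
        f"{what}: could not draw positive values after "
        f"{_MAX_RESAMPLE_ROUNDS} resampling rounds; noise SD is implausibly large"
    )


def simulate_table(spec: SyntheticSpec) -> VolumeTable:
    """Draw one cohort from a spec.

    ICV per sex from the stated normals; each region's volume from the
    power law plus the chosen noise.  Nonpositive draws are resampled (the
    normal model technically allows them) and the resample count is
    recorded in ``table.rejections``; a large count signals an unrealistic
    sigma.  The same spec always yields the identical table.
    """
    n = spec.n_male + spec.n_female
    rng_icv = _substream(spec.seed, "__icv__")
    icv_m, rs_m = _draw_positive(
        rng_icv, lambda r, k: r.normal(*spec.icv_male, k), spec.n_male, "male ICV"
    )
    icv_f, rs_f = _draw_positive(
        rng_icv, lambda r, k: r.normal(*spec.icv_female, k), spec.n_female, "female ICV"
    )
    icv = np.concatenate([icv_m, icv_f])
    sex = np.array(["male"] * spec.n_male + ["female"] * spec.n_female)

    rng_age = _substream(spec.seed, "__age__")
    age = np.concatenate([
        rng_age.normal(*DEFAULT_AGE_MALE, spec.n_male),
        rng_age.normal(*DEFAULT_AGE_FEMALE, spec.n_female),
    ]).clip(min=18.0)

    ids = [f"S{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(
        {"icv": icv, "sex": sex, "age": np.round(age, 1), "group": "control"},
        index=pd.Index(ids, name="subject_id"),
    )

    resample_log: list[tuple[str, str]] = []
    if rs_m + rs_f:
        resample_log.append(("__icv__", f"{rs_m + rs_f} nonpositive ICV draws resampled"))
    for region, p in spec.regions.items():
        mean = p.alpha * icv**p.beta
        rng_r = _substream(spec.seed, region)
        if spec.noise_mode == "additive_normal":
            vol = mean + rng_r.normal(0.0, p.sigma, n)
            n_rs = 0
            for _ in range(_MAX_RESAMPLE_ROUNDS):
                bad = vol <= 0
                if not bad.any():
                    break
                n_rs += int(bad.sum())
                vol[bad] = mean[bad] + rng_r.normal(0.0, p.sigma, int(bad.sum()))
            else:
                raise ValidationError(
                    f"region {region!r}: sigma={p.sigma} too large to keep volumes positive"
                )
        else:
            vol = mean * np.exp(rng_r.normal(0.0, p.sigma, n))
            n_rs = 0
        if n_rs:
            resample_log.append((region, f"{n_rs} nonpositive volume draws resampled"))
        df[region] = vol

    table = VolumeTable(df)
    table.rejections = resample_log
    return table
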