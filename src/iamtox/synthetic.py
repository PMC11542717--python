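"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, all pure functions of a :class:`SyntheticConfig`:

* ``gen_training_set`` — a linear descriptor→toxicity training set with
  Gaussian noise at the published residual scales (s = 0.384 p-units for the
  fish model, 0.335 for the daphnia model), descriptor values uniform over
  the CHI range of the pharmaceutical training compounds.
* ``gen_calibration_run`` — a gradient calibration run: standards on a linear
  t_r↔CHI relation with retention-time jitter (SD 0.005 min, the reported
  repeatability) plus a CHI-scale calibration residual (default SD 0.3 CHI,
  the midpoint of the 0.1–0.8 CHI standard-error band reported for real
  runs; retention jitter alone cannot produce that band at a realistic
  gradient slope).
* ``gen_compound_panel`` — compound records with the UV-filter panel's
  two-cluster structure: a neutral lipophilic cluster (log P 4.5–7.5,
  strong phospholipid binding, CHI > 45) and an anionic hydrophilic cluster
  (log P 0.2–3.0, fully ionized at pH 7.4, CHI < 20).

Random streams are split per generator from the one seed (spawn keys), so
adding a call to one generator never shifts another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import CompoundRecord
from .chi_calibration import CalibrationStandard

__all__ = [
    "SyntheticConfig",
    "gen_training_set",
    "gen_calibration_run",
    "gen_compound_panel",
    "FISH_NOISE_SD",
    "DAPHNIA_NOISE_SD",
]

#: Residual standard deviations of the published fish / daphnia CHI models.
FISH_NOISE_SD = 0.384
DAPHNIA_NOISE_SD = 0.335

_STREAM = {"training": 0, "calibration": 1, "panel": 2}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic generators.

    Defaults reflect the published study conditions: n = 29 training
    compounds, fish-model coefficients near the recovered line
    (2.4 + 0.048·CHI), noise at the published fish s, CHI spanning [1, 60].
    """

    seed: int = 0
    n: int = 29
    beta0: float = 2.4
    beta1: float = 0.048
    noise_sd: float = FISH_NOISE_SD
    x_range: tuple[float, float] = (1.0, 60.0)
    class_mix: float = 0.5
    # calibration-run knobs
    n_standards: int = 10
    t_r_jitter_sd: float = 0.005  # minutes, reported injection repeatability
    chi_residual_sd: float = 0.3  # CHI units, mid reported 0.1-0.8 SE band
    cal_slope: float = 20.0  # CHI per minute
    cal_intercept: float = -10.0
    n_samples: int = 10

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.x_range[1] > self.x_range[0]):
            raise ValueError("x_range must be non-degenerate")
        if not (0.0 <= self.class_mix <= 1.0):
            raise ValueError("class_mix must be in [0, 1]")


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STREAM[stream],))
    return np.random.default_rng(ss)


def gen_training_set(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) with x ~ U(x_range) and y = beta0 + beta1·x + N(0, noise_sd²)."""
    rng = _rng(config, "training")
    x = rng.uniform(config.x_range[0], config.x_range[1], size=config.n)
    y = config.beta0 + config.beta1 * x + rng.normal(0.0, config.noise_sd, size=config.n)
    return x, y


def gen_calibration_run(
    config: SyntheticConfig,
) -> tuple[list[CalibrationStandard], np.ndarray, np.ndarray]:
    """Standards plus sample retention times for a gradient run.

    Returns ``(standards, sample_t_r, sample_true_chi)``. Standards sit on
    the line ``chi = cal_slope·t_r + cal_intercept`` spanning the calibration
    CHI range; their *measured* retention times carry jitter and their
    reference CHI values a calibration residual. Sample compounds have true
    CHI uniform over ``x_range`` with jittered retention times.
    """
    rng = _rng(config, "calibration")
    lo, hi = config.x_range
    chi_grid = np.linspace(lo, hi, config.n_standards)
    t_r_true = (chi_grid - config.cal_intercept) / config.cal_slope
    t_r_meas = t_r_true + rng.normal(0.0, config.t_r_jitter_sd, config.n_standards)
    chi_ref = chi_grid + rng.normal(0.0, config.chi_residual_sd, config.n_standards)
    standards = [
        CalibrationStandard(name=f"std{i+1}", t_r=float(t), chi_ref=float(c))
        for i, (t, c) in enumerate(zip(t_r_meas, chi_ref))
    ]
    true_chi = rng.uniform(lo, hi, size=config.n_samples)
    sample_t_r = (true_chi - config.cal_intercept) / config.cal_slope
    sample_t_r = sample_t_r + rng.normal(0.0, config.t_r_jitter_sd, config.n_samples)
    return standards, sample_t_r, true_chi


def gen_compound_panel(config: SyntheticConfig) -> list[CompoundRecord]:
    """Compound records with the two-cluster UV-filter property structure."""
    rng = _rng(config, "panel")
    n_anionic = int(round(config.class_mix * config.n))
    n_neutral = config.n - n_anionic
    records: list[CompoundRecord] = []

    def _draw(cluster: str, idx: int) -> CompoundRecord:
        if cluster == "neutral":
            log_p = rng.uniform(4.5, 7.5)
            f_minus = 0.0
            # strong binders: CHI linear in log P, kept above 45
            chi = 45.0 + (log_p - 4.5) * 5.0 + rng.normal(0.0, 1.0)
            chi = max(chi, 45.1)
            log_d = log_p
            tpsa = rng.uniform(29.0, 53.0)
            a = rng.uniform(0.0, 0.2)
            b = rng.uniform(0.4, 1.1)
            hbd = float(rng.integers(0, 3))
            hba = 3.0
        else:
            log_p = rng.uniform(0.2, 3.0)
            f_minus = 1.0
            chi = 1.0 + log_p * 6.0 + rng.normal(0.0, 1.0)
            chi = float(np.clip(chi, 0.5, 19.9))
            log_d = log_p - rng.uniform(2.0, 5.0)
            tpsa = rng.uniform(57.0, 110.0)
            a = rng.uniform(0.4, 1.0)
            b = rng.uniform(0.4, 1.5)
            hbd = float(rng.integers(2, 4))
            hba = float(rng.integers(3, 7))
        mw = rng.uniform(137.0, 361.0)
        return CompoundRecord(
            name=f"synthetic_{cluster}_{idx}",
            mw=float(mw),
            log_p=float(log_p),
            log_d74=float(log_d),
            tpsa=float(tpsa),
            f_minus=float(f_minus),
            f_plus=0.0,
            f_zwit=0.0,
            abraham_a=float(a),
            abraham_b=float(b),
            hbd=hbd,
            hba=hba,
            chi_iam=float(chi),
        )

    for i in range(n_neutral):
        records.append(_draw("neutral", i))
    for i in range(n_anionic):
        records.append(_draw("anionic", i))
    return records
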