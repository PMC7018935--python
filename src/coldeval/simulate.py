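"""Synthetic phenotype generator with a known latent tolerance trait.

Every simulated variety carries a scalar latent tolerance t (uniform or
standard-normal); each evaluation index is an affine function of t with the
sign set by its polarity plus additive Gaussian noise:

    value(v, j) = baseline_j + sign_j · loading_j · t_v + ε,   ε ~ N(0, sd_j²)

so the whole pipeline (PCA → μ → D → ranking → indicator selection) can be
tested for rank recovery against the ground truth. A raw-trial mode emulates
the paired control/treated greenhouse design (binomial survival out of 30
sown grains, depressed meter readings, withering fractions rising as
tolerance falls).

The default configuration mirrors the original screening study: 133
varieties scored on the five morphological indices (two lower-is-better
withering degrees on the ordinal 1–9 range, and the three higher-is-better
recovery ratios SR, CRI, NRI), with per-index noise at 5% of the loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import HIGHER_IS_BETTER, LOWER_IS_BETTER, IndexMatrix, RawMeasurements


@dataclass(frozen=True)
class IndexSpec:
    """One simulated evaluation index: polarity, loading on t, noise, baseline."""

    name: str
    polarity: str = HIGHER_IS_BETTER
    loading: float = 1.0
    noise_sd: float = 0.0
    baseline: float = 0.0

    @property
    def sign(self) -> float:
        return 1.0 if self.polarity == HIGHER_IS_BETTER else -1.0


def default_morphological_specs(noise_ratio: float = 0.05) -> list[IndexSpec]:
    """The five-index morphological panel with noise_sd = noise_ratio·|loading|.

    Withering degrees span the ordinal 1–9 range (baseline 9, loading 8, so a
    fully tolerant plant scores ≈ 1); recovery ratios rise from a stressed
    floor toward 1 for tolerant varieties.
    """

    def spec(name, pol, loading, baseline):
        return IndexSpec(name, pol, loading, noise_ratio * abs(loading), baseline)

    return [
        spec("LWD7", LOWER_IS_BETTER, 8.0, 9.0),
        spec("RLWD7", LOWER_IS_BETTER, 8.0, 9.0),
        spec("SR", HIGHER_IS_BETTER, 0.9, 0.1),
        spec("CRI", HIGHER_IS_BETTER, 0.7, 0.3),
        spec("NRI", HIGHER_IS_BETTER, 0.7, 0.3),
    ]


@dataclass
class SyntheticConfig:
    """Study-design parameters for the simulator.

    The index panel, variety count and latent-trait distribution drive
    :func:`generate`; the trailing block parameterizes the raw control/treated
    trial emulated by :func:`generate_raw_trial` (30 grains sown per variety,
    near-complete control survival, treated readings depressed in proportion
    to 1 − t).
    """

    n_varieties: int = 133
    indices: list[IndexSpec] = field(default_factory=default_morphological_specs)
    latent: str = "uniform"  # "uniform" -> U(0,1), "normal" -> N(0,1)
    rng_seed: int = 0
    # raw control/treated trial channels
    sown_count: int = 30
    control_survival_prob: float = 0.95
    survival_floor: float = 0.0
    control_chlorophyll: float = 40.0
    control_nitrogen: float = 30.0
    stress_depression: float = 0.6
    meter_noise_sd: float = 1.0
    stochastic_counts: bool = True

    def __post_init__(self) -> None:
        if self.n_varieties < 1:
            raise ValueError("n_varieties must be positive")
        if len(self.indices) < 2:
            raise ValueError("need at least 2 indices")
        if not any(s.loading != 0 for s in self.indices):
            raise ValueError("at least one index must load on the latent trait")
        bad = [s.name for s in self.indices if s.noise_sd < 0]
        if bad:
            raise ValueError(f"negative noise_sd for index(es): {bad}")
        names = [s.name for s in self.indices]
        if len(set(names)) != len(names):
            raise ValueError("duplicate index names in config")
        if self.latent not in ("uniform", "normal"):
            raise ValueError(f"unknown latent distribution {self.latent!r}")
        if not 0.0 <= self.survival_floor <= 1.0 or not 0.0 <= self.control_survival_prob <= 1.0:
            raise ValueError("survival probabilities must lie in [0, 1]")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, rng_seed=int(seed))


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation: latent tolerance per variety + the config."""

    latent: pd.Series
    config: SyntheticConfig


def _draw_latent(config: SyntheticConfig, rng: np.random.Generator) -> pd.Series:
    ids = [f"V{i + 1:03d}" for i in range(config.n_varieties)]
    if config.latent == "uniform":
        t = rng.uniform(0.0, 1.0, config.n_varieties)
    else:
        t = rng.normal(0.0, 1.0, config.n_varieties)
    return pd.Series(t, index=ids, name="t")


def generate(config: SyntheticConfig) -> tuple[IndexMatrix, SyntheticTruth]:
    """Simulate a variety × index matrix from the latent tolerance trait.

    Fully determined by ``config.rng_seed``: the same config yields a
    bit-identical matrix.
    """
    rng = np.random.default_rng(config.rng_seed)
    t = _draw_latent(config, rng)
    cols = {}
    for spec in config.indices:
        noise = rng.normal(0.0, spec.noise_sd, config.n_varieties) if spec.noise_sd > 0 else 0.0
        cols[spec.name] = spec.baseline + spec.sign * spec.loading * t.to_numpy() + noise
    df = pd.DataFrame(cols, index=t.index)
    polarity = {s.name: s.polarity for s in config.indices}
    return IndexMatrix(df, polarity), SyntheticTruth(t, config)


def generate_raw_trial(
    config: SyntheticConfig,
) -> tuple[list[RawMeasurements], list[RawMeasurements], SyntheticTruth]:
    """Simulate paired control/treated raw measurements per variety.

    Control plants survive with ``control_survival_prob`` and read near the
    baseline meter values; treated survival probability scales with tolerance
    (``floor + (1 − floor)·t``), treated readings are depressed by
    ``stress_depression·(1 − t)``, and withered leaf fractions equal 1 − t
    during stress (partially recovered afterwards). With
    ``stochastic_counts=False`` and ``meter_noise_sd=0`` the trial is the
    noiseless expectation (counts rounded), so a fully tolerant variety has
    treated ≡ control.
    """
    rng = np.random.default_rng(config.rng_seed)
    t = _draw_latent(config, rng).clip(0.0, 1.0)
    control: list[RawMeasurements] = []
    treated: list[RawMeasurements] = []

    def survivors(p: float) -> int:
        if config.stochastic_counts:
            return int(rng.binomial(config.sown_count, p))
        return int(round(config.sown_count * p))

    def reading(mean: float) -> float:
        if config.meter_noise_sd > 0:
            mean += rng.normal(0.0, config.meter_noise_sd)
        return max(mean, 0.0)

    for vid, tv in t.items():
        control.append(
            RawMeasurements(
                variety_id=vid,
                sown_count=config.sown_count,
                surviving_count=survivors(config.control_survival_prob),
                chlorophyll_reading=reading(config.control_chlorophyll),
                nitrogen_reading=reading(config.control_nitrogen),
                withered_fraction_day7=0.0,
                withered_fraction_recovery7=0.0,
            )
        )
        s_t = config.survival_floor + (1.0 - config.survival_floor) * tv
        depress = 1.0 - config.stress_depression * (1.0 - tv)
        withered = float(np.clip(1.0 - tv, 0.0, 1.0))
        treated.append(
            RawMeasurements(
                variety_id=vid,
                sown_count=config.sown_count,
                surviving_count=survivors(config.control_survival_prob * s_t),
                chlorophyll_reading=reading(config.control_chlorophyll * depress),
                nitrogen_reading=reading(config.control_nitrogen * depress),
                withered_fraction_day7=withered,
                withered_fraction_recovery7=float(np.clip(0.8 * withered, 0.0, 1.0))
                if withered < 1.0
                else 1.0,
            )
        )
    return control, treated, SyntheticTruth(t, config)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Sidecar CSV of the ground truth (variety, t) with the seed recorded."""
    df = truth.latent.rename("t").to_frame()
    df.index.name = "variety"
    with open(path, "w") as fh:
        fh.write(f"# rng_seed={truth.config.rng_seed} latent={truth.config.latent}\n")
        df.to_csv(fh)
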