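"""Simulation configuration for the breeding-design generators.

The design emulated here is a nuclear-family breeding experiment: three
replicate lines selected for high group polarization plus three control
lines, each line contributing ~33 families of mother, father and three
offspring of each sex (195 families, 1,560 individuals in total).
Phenotypes are sociability scores on a unit-variance scale with additive
genetic, line, family (common-environment), stimulus-group-use and
residual components.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_SEED = 20231120


@dataclass
class FixedEffects:
    """Fixed-effect sizes on the phenotype scale.

    regime_f / regime_m: effect of being from a polarization-selected line,
    per sex (selection acted on females only, so the male default is 0).
    sex: male minus female intercept difference.
    generation: offspring minus parent shift (fish were assayed at
    different ages).
    activity_slope: slope on the (standardized) wild-type group activity
    covariate.
    """

    intercept: float = 1.0
    regime_f: float = 0.2
    regime_m: float = 0.0
    sex: float = -0.08
    generation: float = 0.1
    activity_slope: float = 0.1


@dataclass
class SimConfig:
    n_lines_per_regime: int = 3
    families_per_line: int = 33  # 32 or 33 per line; 195 total by default
    n_families_total: int = 195
    offspring_per_sex: int = 3
    va_f: float = 0.3
    va_m: float = 0.3
    r_fm: float = 0.5
    v_line: float = 0.05
    v_family: float = 0.02
    v_groupuse: float = 0.02
    v_res_f: float = 0.61
    v_res_m: float = 0.61
    max_group_uses: int = 7
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        counts = dict(
            n_lines_per_regime=self.n_lines_per_regime,
            families_per_line=self.families_per_line,
            n_families_total=self.n_families_total,
            offspring_per_sex=self.offspring_per_sex,
            max_group_uses=self.max_group_uses,
        )
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        variances = dict(
            va_f=self.va_f,
            va_m=self.va_m,
            v_line=self.v_line,
            v_family=self.v_family,
            v_groupuse=self.v_groupuse,
            v_res_f=self.v_res_f,
            v_res_m=self.v_res_m,
        )
        for name, value in variances.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if abs(self.r_fm) > 1:
            raise ValueError(f"|r_fm| must be <= 1, got {self.r_fm!r}")
        if self.n_families_total > self.families_per_line * 2 * self.n_lines_per_regime:
            raise ValueError("n_families_total exceeds families_per_line * n_lines")

    @property
    def genetic_covariance(self) -> np.ndarray:
        """2x2 cross-sex additive covariance matrix G."""
        cov = self.r_fm * np.sqrt(self.va_f * self.va_m)
        g = np.array([[self.va_f, cov], [cov, self.va_m]])
        if np.linalg.eigvalsh(g).min() < -1e-12:
            raise ValueError("genetic covariance matrix is not PSD")
        return g

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimConfig":
        if isinstance(source, (str, bytes)) and "\n" not in str(source):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(io.StringIO(source))
        fe = data.pop("fixed_effects", None)
        cfg = cls(**data)
        if fe is not None:
            cfg.fixed_effects = FixedEffects(**fe)
        return cfg


def config_for_h2(
    h2_f: float,
    h2_m: float,
    r_fm: float,
    v_line: float = 0.05,
    v_family: float = 0.02,
    v_groupuse: float = 0.02,
    seed: int = DEFAULT_SEED,
    **kwargs,
) -> SimConfig:
    """Build a config with unit phenotypic variance per sex.

    The additive variance for each sex is set to the requested
    heritability and the sex-specific residual variance absorbs the
    remainder, so the simulated additive fraction equals ``h2_f`` /
    ``h2_m`` exactly.
    """
    v_common = v_line + v_family + v_groupuse
    for name, h2 in (("h2_f", h2_f), ("h2_m", h2_m)):
        if not 0 <= h2 <= 1 - v_common:
            raise ValueError(f"{name}={h2} incompatible with unit phenotypic variance")
    return SimConfig(
        va_f=h2_f,
        va_m=h2_m,
        r_fm=r_fm,
        v_line=v_line,
        v_family=v_family,
        v_groupuse=v_groupuse,
        v_res_f=1.0 - h2_f - v_common,
        v_res_m=1.0 - h2_m - v_common,
        seed=seed,
        **kwargs,
    )
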