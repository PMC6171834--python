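"""Normative cohort configuration: published per-metric moments.

Holds, for every metric in the normative battery, the cohort mean, SD and
range, the male/female group means, and the Pearson correlation with age,
as published for the 167-eye normal cohort. These numbers parameterize the
synthetic cohort generators and are the reference values the statistics
pipeline is checked against.

One published inconsistency is corrected here: the male juxtafoveal nasal
EZ-RPE mean prints as 31.10 µm, but the printed cohort total (34.92) and
female mean (35.41) imply 34.17 µm, and only the latter is consistent with
the printed p = 0.17; the derived value is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["MetricSpec", "NormativeConfig", "default_normative_config",
           "METRIC_ORDER"]


@dataclass(frozen=True)
class MetricSpec:
    """Published moments of one cohort metric.

    ``family`` is "normal" for thickness/area/volume metrics and
    "zero_inflated_gamma" for the right-skewed, non-negative en face
    attenuation percentages (whose printed ranges hug zero and are grossly
    incompatible with a normal marginal). ``zero_p`` is the point mass at
    exactly zero for the gamma family.
    """

    name: str
    unit: str
    mean: float
    sd: float
    vmin: float
    vmax: float
    male_mean: float
    female_mean: float
    age_r: float
    family: str = "normal"
    zero_p: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if not -1.0 <= self.age_r <= 1.0:
            raise ValueError(f"{self.name}: |age_r| must be <= 1")
        if not self.vmin <= self.mean <= self.vmax:
            raise ValueError(f"{self.name}: need vmin <= mean <= vmax")
        if self.family not in ("normal", "zero_inflated_gamma"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")

    @property
    def sex_gap(self) -> float:
        """Male minus female mean."""
        return self.male_mean - self.female_mean


def _m(name, unit, mean, sd, vmin, vmax, male, female, r,
       family="normal", zero_p=0.0) -> MetricSpec:
    return MetricSpec(name, unit, mean, sd, vmin, vmax, male, female, r,
                      family, zero_p)


# Cohort battery: (mean, sd, min, max), male/female means, Pearson r vs age.
_METRICS: tuple[MetricSpec, ...] = (
    # Total retina (ILM-RPE), µm
    _m("ilm_rpe_central_um", "um", 200.58, 19.22, 158.4, 264.0, 204.06, 198.30, -0.07),
    _m("ilm_rpe_nasal_um", "um", 327.14, 19.04, 267.8, 397.1, 329.71, 325.45, -0.14),
    _m("ilm_rpe_temporal_um", "um", 307.73, 17.85, 250.9, 353.9, 312.53, 304.59, -0.20),
    # Inner retina (ILM to proximal ONL/HFL boundary), µm
    _m("ilm_opl_central_um", "um", 21.47, 13.60, 0.0, 78.2, 23.52, 20.13, -0.39),
    _m("ilm_opl_nasal_um", "um", 201.56, 23.74, 138.8, 287.7, 203.40, 200.36, -0.21),
    _m("ilm_opl_temporal_um", "um", 174.60, 18.81, 103.6, 234.6, 179.62, 171.32, -0.33),
    # Outer retina (ONL/HFL-RPE), µm
    _m("onl_rpe_central_um", "um", 179.11, 18.52, 125.2, 228.8, 180.54, 178.17, 0.20),
    _m("onl_rpe_nasal_um", "um", 125.57, 18.43, 84.0, 166.2, 126.31, 125.09, 0.12),
    _m("onl_rpe_temporal_um", "um", 133.13, 16.26, 69.1, 172.1, 132.91, 133.27, 0.16),
    # Ellipsoid zone (EZ-RPE), µm; male nasal mean derived (see module docstring)
    _m("ez_rpe_central_um", "um", 50.58, 6.01, 37.1, 68.4, 50.42, 50.68, -0.06),
    _m("ez_rpe_nasal_um", "um", 34.92, 5.52, 19.6, 48.9, 34.17, 35.41, 0.10),
    _m("ez_rpe_temporal_um", "um", 33.39, 5.47, 21.5, 58.7, 33.67, 33.20, 0.10),
    # Foveal B-scan areas, mm^2; panmacular volumes, mm^3
    _m("onl_ez_area_mm2", "mm2", 0.55, 0.05, 0.43, 0.73, 0.55, 0.55, 0.16),
    _m("onl_ez_volume_mm3", "mm3", 2.87, 0.22, 2.41, 3.57, 2.87, 2.88, 0.09),
    _m("ez_rpe_area_mm2", "mm2", 0.21, 0.02, 0.16, 0.31, 0.21, 0.21, 0.03),
    _m("ez_rpe_volume_mm3", "mm3", 1.20, 0.10, 0.97, 1.68, 1.20, 1.20, 0.05),
    _m("onl_rpe_area_mm2", "mm2", 0.76, 0.06, 0.63, 0.96, 0.77, 0.76, 0.15),
    _m("onl_rpe_volume_mm3", "mm3", 4.08, 0.27, 3.53, 4.84, 4.07, 4.08, 0.09),
    # En face EZ map coverage, %
    _m("ez_attenuation_pct", "%", 0.87, 1.13, 0.01, 4.94, 0.99, 0.78, -0.48,
       family="zero_inflated_gamma", zero_p=0.0),
    _m("ez_total_loss_pct", "%", 0.12, 0.14, 0.0, 1.10, 0.10, 0.13, 0.06,
       family="zero_inflated_gamma", zero_p=0.10),
)

METRIC_ORDER: tuple[str, ...] = tuple(m.name for m in _METRICS)

#: Best-corrected visual acuity category counts in the 167-eye cohort.
BCVA_COUNTS: tuple[tuple[str, int], ...] = (
    ("20/15", 5), ("20/20", 126), ("20/25", 23), ("20/30", 11), ("20/40", 2),
)


@dataclass(frozen=True)
class NormativeConfig:
    """Full configuration of the normative cohort generator."""

    metrics: tuple[MetricSpec, ...] = _METRICS
    age_min: float = 10.0
    age_max: float = 85.0
    sex_proportion_female: float = 0.605
    proportion_od: float = 0.521
    spherical_equivalent_mean: float = -0.48
    spherical_equivalent_sd: float = 1.8
    spherical_equivalent_range: tuple[float, float] = (-5.63, 4.3)
    #: optional left-skewed two-component age mixture (weight, lo, hi) pairs;
    #: None keeps the default uniform age distribution.
    age_mixture: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.sex_proportion_female < 1.0:
            raise ValueError("sex_proportion_female must be in (0, 1)")
        if self.age_min >= self.age_max:
            raise ValueError("need age_min < age_max")

    def metric(self, name: str) -> MetricSpec:
        for m in self.metrics:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.metrics)

    def with_metric(self, name: str, **changes) -> "NormativeConfig":
        """A copy with one metric's fields replaced."""
        new = tuple(replace(m, **changes) if m.name == name else m
                    for m in self.metrics)
        if name not in self.metric_names:
            raise KeyError(name)
        return replace(self, metrics=new)


def default_normative_config() -> NormativeConfig:
    return NormativeConfig()
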