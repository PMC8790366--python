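"""Run configuration: classifier thresholds, allometric coefficients,
chick-demand split, lipid correction and MCMC settings.

All parameters carry study-condition defaults and can be overridden from a
YAML mapping (see :meth:`RunConfig.from_yaml`).  Allometric coefficients are
configuration, not code: the field metabolic rate (FMR) and basal metabolic
rate (BMR) allometries used for the calibration are transcriptions from the
seabird energetics literature and each carries a provenance string.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class ClassifierParams:
    """Thresholds for dive / take-off detection from tri-axial acceleration.

    Units are g for thresholds and seconds for windows.  A dive starts where
    the running mean of the surge (X) axis drops below ``dive_mean_x_max``
    while its running SD exceeds ``dive_sd_x_min``; it ends at the lagged
    extremum of pitch change within ``dive_end_search_s``.  A take-off is
    active while heave (Z) running SD exceeds ``takeoff_sd_z_min`` and surge
    SD exceeds ``takeoff_sd_x_min``, and has ended once both fall below the
    ``takeoff_end_*`` values.  Dives shorter than ``dive_type_split_s`` are
    plunge dives, the rest pursuit dives.
    """

    mean_window_s: float = 2.0
    sd_window_s: float = 2.0
    dive_mean_x_max: float = 0.0
    dive_sd_x_min: float = 1.4
    dive_end_search_s: float = 60.0
    dive_end_lag_s: float = 1.0
    takeoff_sd_z_min: float = 1.8
    takeoff_sd_x_min: float = 1.0
    takeoff_end_sd_z_max: float = 1.4
    takeoff_end_sd_x_max: float = 1.4
    dive_type_split_s: float = 5.0
    tdr_match_tol_s: float = 5.0
    takeoff_horizon_s: float = 120.0
    pitch_delta_spacing_s: float = 1.0
    #: "offset": dive end = (time of max |dpitch|) + lag.
    #: "series": dive end = time of max of the lag-shifted |dpitch| series.
    dive_end_mode: str = "offset"

    def __post_init__(self) -> None:
        for name in ("mean_window_s", "sd_window_s", "dive_end_search_s",
                     "takeoff_horizon_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.takeoff_end_sd_z_max >= self.takeoff_sd_z_min:
            raise ValueError("take-off end threshold for Z must be below the "
                             "start threshold")
        if self.dive_end_mode not in ("offset", "series"):
            raise ValueError("dive_end_mode must be 'offset' or 'series'")


@dataclass
class AllometricParams:
    """Coefficients for the BMR and FMR allometries.

    BMR (kJ/day) = ``bmr_a * mass_kg ** bmr_b``.
    log10 FMR (kJ/day) = ``fmr_b0 + fmr_b1*log10(mass_g) + fmr_b2*|lat|``.

    Defaults are transcriptions from the seabird energetics literature
    (Ellis & Gabrielsen-type BMR allometry; mass- and latitude-corrected
    seabird FMR allometry); they are inputs, not assertions of ground truth,
    and should be re-derived from the cited sources for other systems.
    """

    bmr_a: float = 381.8
    bmr_b: float = 0.721
    fmr_b0: float = 0.65
    fmr_b1: float = 0.71
    fmr_b2: float = 0.0087
    bmr_provenance: str = ("seabird BMR allometry, kJ/day on mass in kg "
                           "(Ellis & Gabrielsen 2001 family)")
    fmr_provenance: str = ("seabird FMR allometry, log10 kJ/day on log10 mass "
                           "in g and |colony latitude| (seabird FMR calculator "
                           "family)")

    def validate(self, mass_range_kg: tuple[float, float] = (2.0, 3.5),
                 latitude_deg: float = 52.0) -> None:
        """Check FMR > BMR across the plausible adult mass range."""
        import numpy as np

        masses = np.linspace(*mass_range_kg, 16)
        bmr = self.bmr_a * masses ** self.bmr_b
        fmr = 10.0 ** (self.fmr_b0 + self.fmr_b1 * np.log10(1000.0 * masses)
                       + self.fmr_b2 * abs(latitude_deg))
        if not (fmr > bmr).all():
            raise ValueError(
                "allometric coefficients predict FMR <= BMR within the adult "
                f"mass range {mass_range_kg} at latitude {latitude_deg}")


@dataclass
class DemandParams:
    """Chick provisioning demand and its split between the sexes.

    The daily energetic demand of a four-week-old chick is split unequally:
    the female covers ``female_share`` of it and the male the remainder.
    """

    chick_demand_kj_day: float = 1397.14
    female_share: float = 0.60
    male_share: float = 0.40

    def __post_init__(self) -> None:
        if self.chick_demand_kj_day <= 0:
            raise ValueError("chick_demand_kj_day must be > 0")
        if abs(self.female_share + self.male_share - 1.0) > 1e-9:
            raise ValueError("female_share and male_share must sum to 1")

    def share(self, sex: str) -> float:
        if sex == "female":
            return self.female_share
        if sex == "male":
            return self.male_share
        raise ValueError(f"no chick-demand share defined for sex {sex!r}")


@dataclass
class LipidCorrectionParams:
    """Linear C:N normalisation of delta-13C for tissue lipid content.

    ``corrected = d13C + b0 + b1 * (C:N)`` whenever C:N exceeds
    ``cn_threshold`` (lipid-free tissue is left untouched).  Coefficient
    defaults follow the common linear C:N normalisation for fish tissue;
    both are plain configuration.
    """

    b0: float = -3.32
    b1: float = 0.99
    cn_threshold: float = 3.5


@dataclass
class MCMCSettings:
    """Sampler settings for the isotope mixing model.

    ``chains`` independent ensembles are run for the Gelman-Rubin
    diagnostic; ``length`` is the number of recorded steps per walker after
    ``burn_in`` steps are discarded, thinned by ``thinning``.
    """

    chains: int = 3
    length: int = 700
    burn_in: int = 400
    thinning: int = 2
    n_walkers: int = 16
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chains < 1 or self.length < 1 or self.n_walkers < 4:
            raise ValueError("invalid MCMC settings")


@dataclass
class RunConfig:
    """Top-level configuration shared by the CLI subcommands."""

    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    allometry: AllometricParams = field(default_factory=AllometricParams)
    demand: DemandParams = field(default_factory=DemandParams)
    lipid: LipidCorrectionParams = field(default_factory=LipidCorrectionParams)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    assimilation_efficiency: float = 0.761
    source_filter_threshold_pct: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.assimilation_efficiency <= 1.0:
            raise ValueError("assimilation_efficiency must lie in (0, 1]")

    # -- YAML round trip -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "classifier": ClassifierParams,
            "allometry": AllometricParams,
            "demand": DemandParams,
            "lipid": LipidCorrectionParams,
            "mcmc": MCMCSettings,
        }
        for key, klass in sections.items():
            if key in raw:
                kwargs[key] = klass(**raw[key])
        for key in ("assimilation_efficiency", "source_filter_threshold_pct"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))
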