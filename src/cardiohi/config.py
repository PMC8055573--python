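"""Configuration objects for the Hypertrophic Index pipeline.

All tunable parameters of the simulation, QC, cutoff scan and biomarker
rules live in small dataclasses so that a whole run is reproducible from a
single YAML file plus one integer seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "GROUPS",
    "SimConfig",
    "QCParams",
    "BiomarkerRules",
    "PipelineConfig",
    "ConfigurationError",
]

#: Canonical subject groups: healthy controls, hereditary transthyretin
#: amyloidosis with predominantly neuropathic (PN) or cardiac (CA)
#: phenotype, and wild-type disease.
GROUPS = ("Ctrl", "ATTRv-PN", "ATTRv-CA", "ATTRwt")


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its documented domain."""


def _default_group_sizes() -> dict[str, int]:
    return {"Ctrl": 16, "ATTRv-PN": 23, "ATTRv-CA": 36, "ATTRwt": 30}


def _default_group_hi_latent() -> dict[str, float]:
    # Mean latent relative PE growth per group, on the linear scale, so the
    # linear-display HI group means land near 39/36/32/28%.
    return {"Ctrl": 0.39, "ATTRv-PN": 0.36, "ATTRv-CA": 0.32, "ATTRwt": 0.28}


def _default_biomarker_params() -> dict[str, dict[str, tuple[float, float]]]:
    # Per-group (mean, SE) pairs for the simulated patient characteristics;
    # SEs are converted to SDs via sqrt(n) at draw time.  sex is the male
    # proportion (second entry unused).
    return {
        "age": {
            "Ctrl": (50.6, 3.7),
            "ATTRv-PN": (57.5, 3.2),
            "ATTRv-CA": (59.4, 1.6),
            "ATTRwt": (76.3, 1.2),
        },
        "male_frac": {
            "Ctrl": (7 / 16, 0.0),
            "ATTRv-PN": (17 / 23, 0.0),
            "ATTRv-CA": (26 / 36, 0.0),
            "ATTRwt": (26 / 30, 0.0),
        },
        "gfr": {
            "Ctrl": (91.6, 24.3),
            "ATTRv-PN": (87.0, 25.4),
            "ATTRv-CA": (78.5, 26.7),
            "ATTRwt": (52.6, 15.9),
        },
        "ctnt": {
            "Ctrl": (7.2, 2.7),
            "ATTRv-PN": (20.9, 11.0),
            "ATTRv-CA": (51.9, 19.8),
            "ATTRwt": (67.1, 6.8),
        },
        "ntprobnp": {
            "Ctrl": (117.3, 75.6),
            "ATTRv-PN": (1427.3, 457.4),
            "ATTRv-CA": (1451.3, 328.9),
            "ATTRwt": (4254.1, 561.9),
        },
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort, plate and outcome generator.

    The defaults emulate the study design the pipeline was built for: four
    subject groups (36/23/30/16), two plasma concentrations (5% and 20%
    v/v), phenylephrine (PE) stimulation on/off, three independent
    experiments with quadruplicate wells, FCS control wells on every plate,
    and a 24-month follow-up with a strong protective effect of a preserved
    hypertrophic response (high-vs-low hazard ratio 0.24).
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    group_hi_latent: dict[str, float] = field(default_factory=_default_group_hi_latent)
    #: SD of the patient-level latent relative growth within each group.
    latent_sd: float = 0.06
    plasma_pcts: tuple[int, ...] = (5, 20)
    #: multiplicative PE growth factor is 1 + latent_hi; this scales the
    #: latent effect (1.0 = use latent_hi as-is).
    pe_effect_scale: float = 1.0
    #: PE response at 20% plasma is attenuated relative to 5% by this factor
    plasma20_attenuation: float = 0.4
    n_experiments: int = 3
    wells_per_condition: int = 4
    cells_seeded_per_well: int = 20_000  # metadata only; not all are measured
    cells_measured_per_well: float = 400.0  # Poisson mean of measured cells
    #: baseline median cell area, arbitrary squared-micron-like units
    base_cell_area: float = 2000.0
    area_lognormal_sigma: float = 0.40
    plate_effect_sd: float = 0.08
    #: FCS control wells per plate and batch size of samples sharing a plate
    fcs_wells_per_plate: int = 4
    samples_per_plate: int = 8
    dead_fraction: float = 0.10
    #: live-cell nuclear stain: uniform on center +/- halfwidth
    dapi_center: float = 500.0
    dapi_halfwidth: float = 100.0
    hazard_hr_high_vs_low: float = 0.24
    #: latent HI below this value puts a patient in the poor-response
    #: (high-hazard) generative stratum; ~30% of patients at defaults.
    latent_threshold: float = 0.29
    baseline_event_rate: float = 0.028  # MACE events per month, low-HI stratum
    htx_share: float = 0.3  # fraction of the MACE hazard attributable to HTX
    followup_horizon_months: float = 24.0
    biomarker_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_biomarker_params
    )
    seed: int = 0

    def validate(self) -> "SimConfig":
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ConfigurationError(
                    f"unknown group {g!r} in group_sizes; expected one of {GROUPS}"
                )
        for g in self.group_hi_latent:
            if g not in GROUPS:
                raise ConfigurationError(
                    f"unknown group {g!r} in group_hi_latent; expected one of {GROUPS}"
                )
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be >= 0")
        if not set(self.plasma_pcts) <= {5, 20}:
            raise ConfigurationError("plasma_pcts must be a subset of {5, 20}")
        if not (0.0 <= self.dead_fraction < 1.0):
            raise ConfigurationError("dead_fraction must be in [0, 1)")
        if self.hazard_hr_high_vs_low <= 0:
            raise ConfigurationError("hazard_hr_high_vs_low must be > 0")
        if self.followup_horizon_months <= 0:
            raise ConfigurationError("followup_horizon_months must be > 0")
        if self.baseline_event_rate <= 0:
            raise ConfigurationError("baseline_event_rate must be > 0")
        if self.wells_per_condition <= 0:
            raise ConfigurationError("wells_per_condition must be >= 1")
        if self.n_experiments <= 0:
            raise ConfigurationError("n_experiments must be >= 1")
        if not (0.0 < self.htx_share < 1.0):
            raise ConfigurationError("htx_share must be in (0, 1)")
        return self


@dataclass
class QCParams:
    """Single-cell vitality filter settings.

    ``ratio_min`` is the inclusive lower bound on the cell-to-nucleus area
    ratio.  DAPI intensity bounds default to plate-local robust limits
    (median +/- 3 MAD of the FCS-well intensities); set ``dapi_low``/
    ``dapi_high`` to override with absolute values.
    """

    ratio_min: float = 1.5
    dapi_low: float | None = None
    dapi_high: float | None = None
    dapi_mad_k: float = 3.0
    min_cells_per_well: int = 30

    def validate(self) -> "QCParams":
        if self.ratio_min <= 0:
            raise ConfigurationError("ratio_min must be > 0")
        if (
            self.dapi_low is not None
            and self.dapi_high is not None
            and not self.dapi_low < self.dapi_high
        ):
            raise ConfigurationError("dapi_low must be < dapi_high")
        if self.min_cells_per_well < 1:
            raise ConfigurationError("min_cells_per_well must be >= 1")
        return self


@dataclass
class BiomarkerRules:
    """Biomarker-derived subcohort rules.

    cTnT positivity is strict ``> tnt_cutoff`` (pg/ml; 1 ng/l = 1 pg/ml).
    NTproBNP is first adjusted for renal function,
    adjusted = measured / exp(a - b * GFR), then compared against an
    age-band cutoff table which has no invented defaults and must be
    supplied when NTproBNP subcohorting is requested.  The table maps the
    inclusive upper age bound of each band to its cutoff in pg/ml, e.g.
    ``{50: 450, 75: 900, 999: 1800}``.
    """

    tnt_cutoff: float = 50.0
    ntprobnp_a: float = 1.892
    ntprobnp_b: float = 0.025
    age_cutoff_table: dict[float, float] | None = None

    def validate(self) -> "BiomarkerRules":
        if self.tnt_cutoff <= 0:
            raise ConfigurationError("tnt_cutoff must be > 0")
        if self.ntprobnp_b <= 0:
            raise ConfigurationError("ntprobnp_b must be > 0")
        return self


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (see :mod:`cardiohi.pipeline`)."""

    out_dir: str = "cardiohi_out"
    #: directory with cells.csv/wells.csv/patients.csv/outcomes.csv; when
    #: None the synthetic generator produces them.
    input_dir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCParams = field(default_factory=QCParams)
    hi_mode: str = "log"  # "log" for inference, "linear" for display parity
    hi_plasma_pct: int = 5  # the concentration carried into endpoint analysis
    cutoff_endpoint: str = "MACE"
    cutoff_min_group_frac: float = 0.1
    cutoff_level: str = "well_level"  # or "patient_level"
    biomarkers: BiomarkerRules = field(default_factory=BiomarkerRules)
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.hi_mode not in ("log", "linear"):
            raise ConfigurationError("hi_mode must be 'log' or 'linear'")
        if self.cutoff_level not in ("well_level", "patient_level"):
            raise ConfigurationError(
                "cutoff_level must be 'well_level' or 'patient_level'"
            )
        if self.cutoff_endpoint not in ("HTX", "DMP", "MACE"):
            raise ConfigurationError("cutoff_endpoint must be HTX, DMP or MACE")
        self.sim.validate()
        self.qc.validate()
        self.biomarkers.validate()
        return self

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return _tuples_to_lists(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], Mapping):
            d["sim"] = _dataclass_from_mapping(SimConfig, d["sim"])
        if "qc" in d and isinstance(d["qc"], Mapping):
            d["qc"] = _dataclass_from_mapping(QCParams, d["qc"])
        if "biomarkers" in d and isinstance(d["biomarkers"], Mapping):
            d["biomarkers"] = _dataclass_from_mapping(BiomarkerRules, d["biomarkers"])
        return _dataclass_from_mapping(cls, d).validate()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _tuples_to_lists(obj):
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, list):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    return obj


def _dataclass_from_mapping(cls, d: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    kwargs = dict(d)
    # YAML round-trips tuples as lists
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            if f.name == "plasma_pcts":
                kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)
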