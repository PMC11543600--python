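"""Scenario configuration: schema-validated parameter trees and presets.

A scenario bundles every parameter of the synthetic generators and analysis
stages under one global seed.  Presets encode the experimental arms the
pipeline emulates: a strongly photoblueing red dye under confocal or STED
illumination, a photostable control dye, oxygen depletion (suppressed
conversion rate), a photoblueing membrane-packing probe in cells, its
exchangeable (PAINT-mode) counterpart, and antibody FLIM with one or two
conjugated dyes.  Unknown keys are rejected everywhere.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .spectral import LogNormalComponent, SpectralBinning
from .synth import AntibodyEnsembleConfig, PhotoKineticsParams, TraceSimConfig

__all__ = ["ScenarioConfig", "preset", "PRESET_NAMES"]

#: Default suppression of the red->blue conversion rate under oxygen
#: depletion (conversion is reported suppressed; no rate is measured).
OXYGEN_SUPPRESSION_FACTOR = 0.1


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsSection(_Section):
    """Photoreaction rates (per frame) and the length of the series."""

    k_blue: float = 0.03
    k_bleach_red: float = 0.05
    k_bleach_blue: float = 0.01
    brightness_ratio_blue: float = 0.02
    replenishment: bool = False
    n_frames: int = 30

    def to_params(self) -> PhotoKineticsParams:
        return PhotoKineticsParams(
            k_blue=self.k_blue,
            k_bleach_red=self.k_bleach_red,
            k_bleach_blue=self.k_bleach_blue,
            brightness_ratio_blue=self.brightness_ratio_blue,
            replenishment=self.replenishment,
        )


class ComponentSection(_Section):
    """One log-normal emission component."""

    amplitude: float = 1000.0
    lambda_max: float = 655.0
    w: float = 45.0
    a: float = 0.24

    def to_component(self) -> LogNormalComponent:
        return LogNormalComponent(self.amplitude, self.lambda_max, self.w, self.a)


class SpectrumSection(_Section):
    """Spectral-series generation and unmixing settings."""

    red: ComponentSection = Field(default_factory=ComponentSection)
    blue: ComponentSection = Field(
        default_factory=lambda: ComponentSection(amplitude=1000.0, lambda_max=633.0, w=42.0)
    )
    bins_start: float = 575.0
    bin_width: float = 12.5
    n_bins: int = 16
    total_counts_initial: float = 200_000.0
    emission_weight_blue: float = 1.0
    noise: bool = True

    def to_binning(self) -> SpectralBinning:
        import numpy as np

        return SpectralBinning(
            self.bins_start + self.bin_width * np.arange(self.n_bins), self.bin_width
        )


class TraceSection(_Section):
    """FCS trace simulation and correlation settings."""

    n_molecules: int = 135
    omega0: float = 240.0
    diffusion_coeff: float = 1.0
    box_size: float = 3000.0
    T: float = 0.0
    tau_triplet: float = 5e-6
    counts_per_molecule: float = 30_000.0
    bin_time: float = 1e-4
    duration: float = 10.0
    m: int = 16
    n_segments: int = 10
    fit_max_lag: float | None = 0.1
    use_triplet_fit: bool = False
    measure_frames: list[int] = Field(default_factory=lambda: [0, 5, 10])

    def to_sim_config(self, seed: int, n_molecules: int | None = None) -> TraceSimConfig:
        return TraceSimConfig(
            n_molecules=self.n_molecules if n_molecules is None else n_molecules,
            omega0=self.omega0,
            diffusion_coeff=self.diffusion_coeff,
            box_size=self.box_size,
            T=self.T,
            tau_triplet=self.tau_triplet,
            counts_per_molecule=self.counts_per_molecule,
            bin_time=self.bin_time,
            duration=self.duration,
            seed=seed,
        )


class ImageSection(_Section):
    """Two-channel membrane image series settings."""

    height: int = 64
    width: int = 64
    stripe_start: int = 24
    stripe_stop: int = 40
    gp_true: float = -0.3
    n_frames: int = 30
    counts: float = 500.0
    saturation: float = 65535.0
    background_counts: float = 5.0
    threshold_fraction: float = 0.2
    pixel_size: float = 40.0


class FlimSection(_Section):
    """Antibody-ensemble FLIM settings."""

    dyes_per_antibody: int = 2
    tau_unquenched: float = 3.5
    tau_quenched: float = 2.3
    bleach_prob: float = 0.12
    quenched_yield: float = 0.3
    n_antibodies: int = 4000
    n_frames: int = 12
    photons_per_unit_intensity: float = 20_000.0
    irf_sigma: float = 0.0
    method: Literal["mean_arrival", "mono_exp_fit"] = "mean_arrival"

    def to_ensemble_config(self, seed: int) -> AntibodyEnsembleConfig:
        return AntibodyEnsembleConfig(
            dyes_per_antibody=self.dyes_per_antibody,
            tau_unquenched=self.tau_unquenched,
            tau_quenched=self.tau_quenched,
            bleach_prob=self.bleach_prob,
            quenched_yield=self.quenched_yield,
            n_antibodies=self.n_antibodies,
            seed=seed,
        )


Stage = Literal["kinetics", "spectral", "fcs", "gp", "flim"]


class ScenarioConfig(_Section):
    """Full parameter tree of one simulate-and-analyze run."""

    name: str = "custom"
    seed: int = 0
    stages: list[Stage] = Field(default_factory=lambda: ["kinetics", "spectral"])
    kinetics: KineticsSection = Field(default_factory=KineticsSection)
    spectrum: SpectrumSection = Field(default_factory=SpectrumSection)
    trace: TraceSection = Field(default_factory=TraceSection)
    image: ImageSection = Field(default_factory=ImageSection)
    flim: FlimSection = Field(default_factory=FlimSection)

    def resolved_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, indent=2)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_json().encode()).hexdigest()[:16]


_PRESETS: dict[str, dict] = {
    # Strongly photoconverting red dye, confocal illumination: ~20 % of the
    # initial molecules photoblued after ten frames.
    "star_red_confocal": {
        "stages": ["kinetics", "spectral", "fcs"],
        "kinetics": {"k_blue": 0.03, "k_bleach_red": 0.05, "k_bleach_blue": 0.01,
                     "brightness_ratio_blue": 0.02, "n_frames": 30},
    },
    # STED adds depletion-laser dose: all photoreaction rates scaled up.
    "star_red_sted": {
        "stages": ["kinetics", "spectral", "fcs"],
        "kinetics": {"k_blue": 0.05, "k_bleach_red": 0.09, "k_bleach_blue": 0.02,
                     "brightness_ratio_blue": 0.02, "n_frames": 30},
    },
    # Photostable control dye: negligible conversion.
    "atto655_confocal": {
        "stages": ["kinetics", "spectral", "fcs"],
        "kinetics": {"k_blue": 0.002, "k_bleach_red": 0.01, "k_bleach_blue": 0.01,
                     "brightness_ratio_blue": 0.02, "n_frames": 30},
    },
    # Oxygen depletion suppresses the conversion pathway (rate scaled down).
    "oxygen_depleted": {
        "stages": ["kinetics", "spectral", "fcs"],
        "kinetics": {"k_blue": 0.03 * OXYGEN_SUPPRESSION_FACTOR, "k_bleach_red": 0.05,
                     "k_bleach_blue": 0.01, "brightness_ratio_blue": 0.02, "n_frames": 30},
    },
    # Membrane-packing probe in cells: photoblueing biases GP upward.
    "nr12a_cells": {
        "stages": ["kinetics", "gp"],
        "kinetics": {"k_blue": 0.02, "k_bleach_red": 0.02, "k_bleach_blue": 0.005,
                     "n_frames": 30},
        "image": {"n_frames": 30, "gp_true": -0.3},
    },
    # Exchangeable probe (PAINT mode): pool replenished, GP stays true.
    "nr4a_exchangeable": {
        "stages": ["kinetics", "gp"],
        "kinetics": {"k_blue": 0.02, "k_bleach_red": 0.02, "k_bleach_blue": 0.005,
                     "replenishment": True, "n_frames": 30},
        "image": {"n_frames": 30, "gp_true": -0.3},
    },
    # Antibody carrying two mutually quenching dyes: lifetime rises as one
    # dye bleaches; intensity rises then falls.
    "atto647n_antibody_flim": {
        "stages": ["flim"],
        "flim": {"dyes_per_antibody": 2},
    },
    # Single-dye conjugation: the FLIM artifact-mitigation control.
    "single_dye_flim": {
        "stages": ["flim"],
        "flim": {"dyes_per_antibody": 1},
    },
    # Null scenario: no photoreactions at all.
    "null": {
        "stages": ["kinetics", "spectral", "gp", "flim"],
        "kinetics": {"k_blue": 0.0, "k_bleach_red": 0.0, "k_bleach_blue": 0.0},
        "flim": {"dyes_per_antibody": 1, "bleach_prob": 0.0},
    },
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Build a named preset scenario, optionally overriding top-level keys."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    data = json.loads(json.dumps(_PRESETS[name]))  # deep copy
    data["name"] = name
    data["seed"] = seed
    data.update(overrides)
    return ScenarioConfig(**data)
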