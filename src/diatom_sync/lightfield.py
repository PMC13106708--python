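"""Multiband illumination protocols and the photoreceptor state they induce.

A :class:`LightField` is a set of :class:`SpectralBand` objects, each either
constant or sinusoidally modulated in time.  An :class:`ActionSpectrum` maps
wavelength to activation/deactivation cross-sections of a two-state
photoreceptor; :func:`dph_steady_state` evaluates the photostationary
activation fraction under a field.  The photostationary approximation is used
because photoconversion is fast relative to the ~140 s behavioural
timescale, and it makes the activation ratiometric in band irradiances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigurationError, RangeError, ValidationError

__all__ = [
    "Modulation",
    "SpectralBand",
    "LightField",
    "ActionSpectrum",
    "DphState",
    "evaluate_lightfield",
    "dph_steady_state",
    "DEFAULT_ACTIVATION_WEIGHTS",
    "DEFAULT_DEACTIVATION_WEIGHTS",
    "default_action_spectrum",
]

#: Default photoreceptor cross-sections (arbitrary units) at the five
#: standard LED wavelengths.  Activation peaks in the blue and far-red,
#: deactivation in the red/amber; the small activation weight at 660 nm
#: models the overlap of the two absorption bands, so the photostationary
#: activation under pure red light is small but nonzero (~0.048).
DEFAULT_ACTIVATION_WEIGHTS = {430.0: 1.0, 530.0: 0.0, 617.0: 0.0, 660.0: 0.05, 780.0: 1.0}
DEFAULT_DEACTIVATION_WEIGHTS = {430.0: 0.0, 530.0: 0.0, 617.0: 0.3, 660.0: 1.0, 780.0: 0.0}


@dataclass(frozen=True)
class Modulation:
    """Temporal profile of one spectral band.

    ``kind`` is ``"constant"`` or ``"sinusoid"``.  For sinusoids the band
    irradiance follows ``I0 * (1 + depth*sin(2*pi*t/period + phase)) / norm``
    where ``norm`` is 1 in ``"mean"`` normalization (stated irradiance is the
    time average) and ``1 + depth`` in ``"max"`` normalization (stated
    irradiance is the crest value).
    """

    kind: str = "constant"
    period_s: float = 140.0
    depth: float = 0.0
    phase_rad: float = 0.0
    normalization: str = "mean"

    def __post_init__(self):
        if self.kind not in ("constant", "sinusoid"):
            raise ValidationError(f"unknown modulation kind {self.kind!r}")
        if self.kind == "sinusoid":
            if not self.period_s > 0:
                raise ValidationError("sinusoid period must be positive")
            if not 0.0 <= self.depth <= 1.0:
                raise ValidationError("sinusoid depth must lie in [0, 1]")
        if self.normalization not in ("mean", "max"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class SpectralBand:
    """One illumination band: wavelength, irradiance and temporal profile.

    Irradiance is in µmol photons m⁻² s⁻¹ and must be nonnegative.
    """

    wavelength_nm: float
    irradiance: float
    modulation: Modulation = dc_field(default_factory=Modulation)

    def __post_init__(self):
        if not self.wavelength_nm > 0:
            raise ValidationError("wavelength must be positive")
        if not self.irradiance >= 0:
            raise ValidationError("irradiance must be nonnegative")

    def irradiance_at(self, t):
        """Instantaneous irradiance at time ``t`` (s); vectorized over t."""
        m = self.modulation
        if m.kind == "constant" or m.depth == 0.0:
            return self.irradiance * np.ones_like(np.asarray(t, dtype=float))
        wave = 1.0 + m.depth * np.sin(2.0 * math.pi * np.asarray(t, dtype=float) / m.period_s + m.phase_rad)
        if m.normalization == "max":
            wave = wave / (1.0 + m.depth)
        return self.irradiance * wave

    def sinusoid_amplitude(self) -> float:
        """Amplitude of the sinusoidal irradiance component (0 if constant)."""
        m = self.modulation
        if m.kind != "sinusoid" or m.depth == 0.0:
            return 0.0
        amp = self.irradiance * m.depth
        if m.normalization == "max":
            amp /= 1.0 + m.depth
        return amp


@dataclass(frozen=True)
class LightField:
    """A multiband illumination protocol of finite duration (s)."""

    bands: tuple[SpectralBand, ...]
    duration_s: float

    def __post_init__(self):
        if len(self.bands) == 0:
            raise ValidationError("a light field needs at least one band")
        if not self.duration_s > 0:
            raise ValidationError("duration must be positive")
        object.__setattr__(self, "bands", tuple(self.bands))

    def evaluate(self, t: float) -> dict[float, float]:
        """Per-band instantaneous irradiance at time ``t`` ∈ [0, duration]."""
        if not 0.0 <= t <= self.duration_s:
            raise RangeError(f"t={t} outside [0, {self.duration_s}]")
        return {b.wavelength_nm: float(b.irradiance_at(t)) for b in self.bands}

    def sinusoidal_component(self):
        """(amplitude, period_s, phase_rad) of the first modulated band.

        Returns ``(0.0, None, 0.0)`` when no band is sinusoidally modulated.
        The forcing phase convention: the modulated irradiance deviation is
        ``amplitude * sin(2*pi*t/period + phase)``.
        """
        for b in self.bands:
            amp = b.sinusoid_amplitude()
            if amp > 0.0:
                return amp, b.modulation.period_s, b.modulation.phase_rad
        return 0.0, None, 0.0

    # -- JSON round-trip ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "duration_s": self.duration_s,
                "bands": [
                    {
                        "wavelength_nm": b.wavelength_nm,
                        "irradiance": b.irradiance,
                        "modulation": {
                            "type": b.modulation.kind,
                            "period_s": b.modulation.period_s,
                            "depth": b.modulation.depth,
                            "phase_rad": b.modulation.phase_rad,
                            "normalization": b.modulation.normalization,
                        },
                    }
                    for b in self.bands
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "LightField":
        obj = json.loads(text)
        bands = []
        for b in obj["bands"]:
            mod = b.get("modulation", {}) or {}
            bands.append(
                SpectralBand(
                    wavelength_nm=float(b["wavelength_nm"]),
                    irradiance=float(b["irradiance"]),
                    modulation=Modulation(
                        kind=mod.get("type", "constant"),
                        period_s=float(mod.get("period_s", 140.0)),
                        depth=float(mod.get("depth", 0.0)),
                        phase_rad=float(mod.get("phase_rad", 0.0)),
                        normalization=mod.get("normalization", "mean"),
                    ),
                )
            )
        return cls(bands=tuple(bands), duration_s=float(obj["duration_s"]))


def constant_field(wavelength_nm: float, irradiance: float, duration_s: float) -> LightField:
    """Single constant monochromatic band."""
    return LightField((SpectralBand(wavelength_nm, irradiance),), duration_s)


def pulsed_field(
    wavelength_nm: float,
    irradiance: float,
    duration_s: float,
    period_s: float = 140.0,
    depth: float = 1.0,
    phase_rad: float = 0.0,
    normalization: str = "mean",
) -> LightField:
    """Single sinusoidally modulated monochromatic band."""
    band = SpectralBand(
        wavelength_nm,
        irradiance,
        Modulation("sinusoid", period_s=period_s, depth=depth, phase_rad=phase_rad, normalization=normalization),
    )
    return LightField((band,), duration_s)


class ActionSpectrum:
    """Activation/deactivation cross-sections versus wavelength.

    Weights are tabulated at discrete wavelengths and linearly interpolated
    in between.  Querying a wavelength outside the tabulated range raises
    :class:`ConfigurationError` — extrapolating an action spectrum is never
    safe.
    """

    def __init__(self, activation: dict[float, float], deactivation: dict[float, float]):
        for name, table in (("activation", activation), ("deactivation", deactivation)):
            if not table:
                raise ConfigurationError(f"{name} table is empty")
            if any(w < 0 for w in table.values()):
                raise ConfigurationError(f"{name} weights must be nonnegative")
        self._act_wl = np.array(sorted(activation), dtype=float)
        self._act_w = np.array([activation[w] for w in sorted(activation)], dtype=float)
        self._deact_wl = np.array(sorted(deactivation), dtype=float)
        self._deact_w = np.array([deactivation[w] for w in sorted(deactivation)], dtype=float)

    def _lookup(self, wl_grid, w_grid, wavelength, name):
        if wavelength < wl_grid[0] or wavelength > wl_grid[-1]:
            raise ConfigurationError(
                f"wavelength {wavelength} nm outside tabulated {name} range "
                f"[{wl_grid[0]}, {wl_grid[-1]}] nm"
            )
        return float(np.interp(wavelength, wl_grid, w_grid))

    def activation_weight(self, wavelength_nm: float) -> float:
        return self._lookup(self._act_wl, self._act_w, wavelength_nm, "activation")

    def deactivation_weight(self, wavelength_nm: float) -> float:
        return self._lookup(self._deact_wl, self._deact_w, wavelength_nm, "deactivation")


def default_action_spectrum() -> ActionSpectrum:
    return ActionSpectrum(dict(DEFAULT_ACTIVATION_WEIGHTS), dict(DEFAULT_DEACTIVATION_WEIGHTS))


@dataclass(frozen=True)
class DphState:
    """Fraction of the photoreceptor pool in the active conformation."""

    activation: float

    def __post_init__(self):
        if not 0.0 <= self.activation <= 1.0:
            raise ValidationError("activation must lie in [0, 1]")


def evaluate_lightfield(field: LightField, t: float) -> dict[float, float]:
    """Map band wavelength → instantaneous irradiance at time ``t``."""
    return field.evaluate(t)


def dph_steady_state(
    field: LightField,
    spectrum: ActionSpectrum,
    t: float,
    dark_activation: float = 0.0,
) -> DphState:
    """Photostationary activation fraction under ``field`` at time ``t``.

    activation = K_act / (K_act + K_deact) with
    K_act = Σ_b act(λ_b)·I_b(t) and K_deact = Σ_b deact(λ_b)·I_b(t).
    In darkness (both sums zero) the configured ``dark_activation`` is
    returned.  Because both sums are linear in irradiance the result is
    invariant under uniform intensity scaling (ratiometric sensing).
    """
    irr = field.evaluate(t)
    k_act = sum(spectrum.activation_weight(wl) * i for wl, i in irr.items())
    k_deact = sum(spectrum.deactivation_weight(wl) * i for wl, i in irr.items())
    total = k_act + k_deact
    if total == 0.0:
        return DphState(dark_activation)
    return DphState(k_act / total)
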