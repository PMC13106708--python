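"""Config-driven experiment families: simulate → observe → analyze.

Each family mirrors one of the bench protocols: a wavelength scan under
constant light, composed red+blue light at varying ratios, pulsed red /
far-red light at the natural wobble period, and two-band autofluorescence
recording.  Runs are replicated (default triplicate) with per-run seeds
derived deterministically from (base seed, arm); summaries
report mean ± sample SD across replicates.  The mixing phase is excluded
from every spectral analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .fluorescence import emit
from .ld_forward import (
    CellGeometry,
    RatioSeries,
    SizeClassGrid,
    observe,
    ratio_series,
)
from .lightfield import (
    ActionSpectrum,
    LightField,
    Modulation,
    SpectralBand,
    constant_field,
    default_action_spectrum,
    pulsed_field,
)
from .population_sim import (
    Genotype,
    SimConfig,
    genotype_from_label,
    simulate,
)
from .spectra import (
    PowerSpectrum,
    SpectralPeakSummary,
    characterize_peak,
    entrainment_index,
    power_spectrum,
    preprocess,
)

__all__ = [
    "ExperimentSpec",
    "PipelineResult",
    "run_pipeline",
    "run_wavelength_scan",
    "run_composed_rb",
    "run_pulsed",
    "run_fluorescence",
    "run_experiment",
    "FAMILIES",
    "OUTPUT_SCHEMAS",
    "validate_output",
]

log = logging.getLogger("diatom_sync")

FAMILIES = ("wavelength_scan", "composed_rb", "pulsed", "fluorescence")

#: Protocol constants per family (wavelengths nm, irradiances
#: µmol photons m⁻² s⁻¹, durations s).
WAVELENGTH_SCAN_DEFAULTS = {
    "wavelengths_nm": [430.0, 530.0, 617.0, 660.0, 780.0],
    "irradiance": 8.0,
    "duration_s": 7200.0,
}
COMPOSED_RB_DEFAULTS = {
    "blue_nm": 430.0,
    "red_nm": 660.0,
    "blue_irradiance": 8.0,
    "red_irradiances": [0.0, 2.0, 4.0, 6.0],
    "control_irradiances": [8.0, 10.0, 12.0, 14.0],
    "duration_s": 7200.0,
}
PULSED_DEFAULTS = {
    "wavelengths_nm": [660.0, 780.0],
    "irradiance": 8.0,
    "period_s": 140.0,
    "depth": 1.0,
    "duration_s": 7200.0,
    "blue_reference_nm": 430.0,
}
FLUORESCENCE_DEFAULTS = {
    "excitation_nm": 430.0,
    "excitation_irradiance": 30.0,
    "duration_s": 2700.0,
    "anisotropy": 0.5,
}

#: Minimal output schemas (required summary-table columns) per family.
OUTPUT_SCHEMAS = {
    "wavelength_scan": [
        "wavelength_nm",
        "genotype",
        "normalized_amplitude_mean",
        "normalized_amplitude_sd",
        "mean_period_s_mean",
        "mean_period_s_sd",
        "fit_mode_main_peak_count",
    ],
    "composed_rb": [
        "arm",
        "rb_ratio",
        "total_irradiance",
        "normalized_amplitude_mean",
        "relative_amplitude_mean",
        "mean_period_s_mean",
    ],
    "pulsed": [
        "genotype",
        "wavelength_nm",
        "pk_pulsed_mean",
        "pk_constant_mean",
        "entrainment_index_mean",
        "pk_vs_constant_blue_mean",
        "f0_pulsed_mean",
    ],
    "fluorescence": [
        "genotype",
        "f0_red_hz",
        "f0_farred_hz",
        "band_correlation",
        "pk_red",
        "pk_farred",
    ],
}


def validate_output(family: str, frame: pd.DataFrame) -> None:
    """Check that a family summary table carries its required columns."""
    missing = [c for c in OUTPUT_SCHEMAS[family] if c not in frame.columns]
    if missing:
        raise ValidationError(f"{family} summary is missing columns: {missing}")


@dataclass
class ExperimentSpec:
    """One experiment-family run request."""

    family: str
    genotypes: tuple[str, ...] = ("WT", "KO")
    replicates: int = 3
    seeds: tuple[int, ...] = (1, 2, 3)
    protocol: dict = dc_field(default_factory=dict)
    sim_overrides: dict = dc_field(default_factory=dict)
    noise_cv: float = 0.02
    output_dir: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.replicates != len(self.seeds):
            raise ConfigurationError("replicates must equal len(seeds)")
        for g in self.genotypes:
            genotype_from_label(g)
        if self.family == "composed_rb":
            proto = {**COMPOSED_RB_DEFAULTS, **self.protocol}
            if proto["blue_nm"] >= 550.0 or proto["red_nm"] <= 550.0:
                raise ConfigurationError("composed_rb needs one blue and one red band")

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "genotypes": list(self.genotypes),
                "replicates": self.replicates,
                "seeds": list(self.seeds),
                "protocol": self.protocol,
                "sim_overrides": self.sim_overrides,
                "noise_cv": self.noise_cv,
                "output_dir": self.output_dir,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExperimentSpec":
        d = json.loads(text)
        d["genotypes"] = tuple(d.get("genotypes", ("WT", "KO")))
        d["seeds"] = tuple(d.get("seeds", (1, 2, 3)))
        return cls(**d)


def derive_seed(base_seed: int, arm: int) -> int:
    """Deterministic per-run seed from (base seed, arm index).

    The replicate index is deliberately NOT mixed in: listing the same base
    seed twice must reproduce the identical run (zero replicate SD).
    """
    return int(np.random.SeedSequence(entropy=(base_seed, arm)).generate_state(1)[0])


@dataclass
class PipelineResult:
    """Everything produced by one simulate → observe → analyze run."""

    config: SimConfig
    field: LightField
    ratio: RatioSeries
    spectrum: PowerSpectrum
    summary: SpectralPeakSummary
    size_series: object = None
    trajectory: object = None


def _config_hash(config: SimConfig, field: LightField) -> str:
    blob = (config.to_json() + field.to_json()).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(
    config: SimConfig,
    field: LightField,
    spectrum: ActionSpectrum | None = None,
    noise_cv: float = 0.02,
    geometry: CellGeometry | None = None,
    grid: SizeClassGrid | None = None,
    keep_trajectory: bool = False,
) -> PipelineResult:
    """Full chain on one configuration; mixing phase excluded from analysis."""
    spectrum = spectrum or default_action_spectrum()
    t0 = time.perf_counter()
    traj = simulate(config, field, spectrum)
    series = observe(traj, geometry=geometry, grid=grid, noise_cv=noise_cv)
    ratio = ratio_series(series)

    mask = traj.sedimentation_mask()
    analysis_ratio = RatioSeries(
        times=ratio.times[mask], ratio=ratio.ratio[mask], valid=ratio.valid[mask]
    )
    sig, dt, _ = preprocess(analysis_ratio)
    ps = power_spectrum(sig, dt)
    summary = characterize_peak(ps)
    log.info(
        "pipeline config=%s seed=%d genotype=%s runtime=%.2fs fit_mode=%s",
        _config_hash(config, field),
        config.seed,
        config.genotype.label,
        time.perf_counter() - t0,
        summary.fit_mode,
    )
    return PipelineResult(
        config=config,
        field=field,
        ratio=ratio,
        spectrum=ps,
        summary=summary,
        size_series=series,
        trajectory=traj if keep_trajectory else None,
    )


def _sim_config(spec: ExperimentSpec, genotype: Genotype, seed: int, duration_s: float) -> SimConfig:
    kwargs = dict(spec.sim_overrides)
    kwargs.setdefault("duration_s", duration_s)
    return SimConfig(genotype=genotype, seed=seed, **kwargs)


def _agg(values):
    values = np.asarray(values, dtype=float)
    return float(values.mean()), float(values.std(ddof=1)) if len(values) > 1 else 0.0


# ---------------------------------------------------------------------------
# wavelength scan (constant monochromatic light)
# ---------------------------------------------------------------------------

def run_wavelength_scan(spec: ExperimentSpec, action: ActionSpectrum | None = None):
    """Per-wavelength × genotype spectral summaries under constant light."""
    proto = {**WAVELENGTH_SCAN_DEFAULTS, **spec.protocol}
    action = action or default_action_spectrum()
    rows = []
    runs = {}
    for gi, glabel in enumerate(spec.genotypes):
        genotype = genotype_from_label(glabel)
        for wi, wl in enumerate(proto["wavelengths_nm"]):
            field = constant_field(wl, proto["irradiance"], proto["duration_s"])
            results = []
            for ri, base in enumerate(spec.seeds):
                seed = derive_seed(base, 100 * gi + wi)
                cfg = _sim_config(spec, genotype, seed, proto["duration_s"])
                results.append(run_pipeline(cfg, field, action, noise_cv=spec.noise_cv))
            runs[(glabel, wl)] = results
            amp_m, amp_sd = _agg([r.summary.normalized_amplitude for r in results])
            per_m, per_sd = _agg([r.summary.mean_period_s for r in results])
            rows.append(
                {
                    "wavelength_nm": wl,
                    "genotype": glabel,
                    "normalized_amplitude_mean": amp_m,
                    "normalized_amplitude_sd": amp_sd,
                    "mean_period_s_mean": per_m,
                    "mean_period_s_sd": per_sd,
                    "fit_mode_main_peak_count": sum(
                        r.summary.fit_mode == "main_peak" for r in results
                    ),
                }
            )
    table = pd.DataFrame(rows)
    validate_output("wavelength_scan", table)
    _maybe_write(spec, "wavelength_scan", table, runs)
    return table, runs


# ---------------------------------------------------------------------------
# composed red + blue light
# ---------------------------------------------------------------------------

def _ols_with_ci(x, y, alpha=0.05):
    """Ordinary least squares slope with a (1−alpha) CI; degenerate inputs
    (zero residual variance) return a zero-width CI at the fitted slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.linregress(x, y)
    dof = len(x) - 2
    if dof <= 0 or not np.isfinite(res.stderr) or res.stderr == 0:
        return res.slope, res.slope, res.slope
    half = stats.t.ppf(1 - alpha / 2, dof) * res.stderr
    return res.slope, res.slope - half, res.slope + half


def run_composed_rb(spec: ExperimentSpec, action: ActionSpectrum | None = None):
    """R:B-ratio arm plus intensity-matched blue-control arm.

    Amplitudes are normalized per replicate to the blue-only (R:B = 0)
    baseline run of that replicate.  Returns (summary table, fits dict).
    """
    proto = {**COMPOSED_RB_DEFAULTS, **spec.protocol}
    action = action or default_action_spectrum()
    genotype = genotype_from_label(spec.genotypes[0] if spec.genotypes else "WT")
    duration = proto["duration_s"]
    blue = proto["blue_irradiance"]

    rows = []
    arm_points = {"rb": [], "control": []}
    baseline = {}

    # R:B arm, including the shared baseline at red irradiance 0
    for ai, red_irr in enumerate(proto["red_irradiances"]):
        rb = red_irr / blue
        bands = [SpectralBand(proto["blue_nm"], blue)]
        if red_irr > 0:
            bands.append(SpectralBand(proto["red_nm"], red_irr))
        field = LightField(tuple(bands), duration)
        reps = []
        for ri, base in enumerate(spec.seeds):
            seed = derive_seed(base, ai)
            cfg = _sim_config(spec, genotype, seed, duration)
            result = run_pipeline(cfg, field, action, noise_cv=spec.noise_cv)
            reps.append(result)
            if red_irr == 0:
                baseline[ri] = result.summary.normalized_amplitude
        rel = [
            r.summary.normalized_amplitude / baseline[ri]
            for ri, r in enumerate(reps)
        ]
        arm_points["rb"].extend((rb, v) for v in rel)
        amp_m, amp_sd = _agg([r.summary.normalized_amplitude for r in reps])
        rel_m, rel_sd = _agg(rel)
        per_m, per_sd = _agg([r.summary.mean_period_s for r in reps])
        rows.append(
            {
                "arm": "rb",
                "rb_ratio": rb,
                "total_irradiance": blue + red_irr,
                "normalized_amplitude_mean": amp_m,
                "normalized_amplitude_sd": amp_sd,
                "relative_amplitude_mean": rel_m,
                "relative_amplitude_sd": rel_sd,
                "mean_period_s_mean": per_m,
                "mean_period_s_sd": per_sd,
            }
        )

    # blue-only control arm at the matched total intensities
    for ai, total in enumerate(proto["control_irradiances"]):
        rb_label = (total - blue) / blue  # plotted at the matched R:B position
        field = constant_field(proto["blue_nm"], total, duration)
        reps = []
        for ri, base in enumerate(spec.seeds):
            seed = derive_seed(base, 100 + ai)
            cfg = _sim_config(spec, genotype, seed, duration)
            reps.append(run_pipeline(cfg, field, action, noise_cv=spec.noise_cv))
        rel = [
            r.summary.normalized_amplitude / baseline[ri]
            for ri, r in enumerate(reps)
        ]
        arm_points["control"].extend((rb_label, v) for v in rel)
        amp_m, amp_sd = _agg([r.summary.normalized_amplitude for r in reps])
        rel_m, rel_sd = _agg(rel)
        per_m, per_sd = _agg([r.summary.mean_period_s for r in reps])
        rows.append(
            {
                "arm": "control",
                "rb_ratio": rb_label,
                "total_irradiance": total,
                "normalized_amplitude_mean": amp_m,
                "normalized_amplitude_sd": amp_sd,
                "relative_amplitude_mean": rel_m,
                "relative_amplitude_sd": rel_sd,
                "mean_period_s_mean": per_m,
                "mean_period_s_sd": per_sd,
            }
        )

    fits = {}
    for arm, pts in arm_points.items():
        x = [p[0] for p in pts]
        y = [p[1] for p in pts]
        slope, lo, hi = _ols_with_ci(x, y)
        fits[arm] = {"slope": slope, "ci_low": lo, "ci_high": hi}

    table = pd.DataFrame(rows)
    validate_output("composed_rb", table)
    _maybe_write(spec, "composed_rb", table, extra_json={"linear_fits": fits})
    return table, fits


# ---------------------------------------------------------------------------
# pulsed red / far-red light
# ---------------------------------------------------------------------------

def run_pulsed(spec: ExperimentSpec, action: ActionSpectrum | None = None):
    """Pulsed R/FR versus constant references for each genotype."""
    proto = {**PULSED_DEFAULTS, **spec.protocol}
    for wl in proto["wavelengths_nm"]:
        if wl not in (660.0, 780.0):
            raise ConfigurationError("pulsed family supports 660 and 780 nm only")
    action = action or default_action_spectrum()
    duration = proto["duration_s"]
    rows = []
    runs = {}

    for gi, glabel in enumerate(spec.genotypes):
        genotype = genotype_from_label(glabel)
        # constant blue reference for this genotype
        blue_field = constant_field(proto["blue_reference_nm"], proto["irradiance"], duration)
        blue_pk = []
        for ri, base in enumerate(spec.seeds):
            seed = derive_seed(base, 1000 + gi)
            cfg = _sim_config(spec, genotype, seed, duration)
            result = run_pipeline(cfg, blue_field, action, noise_cv=spec.noise_cv)
            blue_pk.append(result.summary.pk)
            runs[(glabel, "constant_blue", ri)] = result

        for wi, wl in enumerate(proto["wavelengths_nm"]):
            pulsed = pulsed_field(
                wl, proto["irradiance"], duration, period_s=proto["period_s"], depth=proto["depth"]
            )
            const = constant_field(wl, proto["irradiance"], duration)
            pk_p, pk_c, idx, f0s, vs_blue = [], [], [], [], []
            for ri, base in enumerate(spec.seeds):
                seed_p = derive_seed(base, 10 * gi + wi)
                seed_c = derive_seed(base, 500 + 10 * gi + wi)
                res_p = run_pipeline(
                    _sim_config(spec, genotype, seed_p, duration), pulsed, action, spec.noise_cv
                )
                res_c = run_pipeline(
                    _sim_config(spec, genotype, seed_c, duration), const, action, spec.noise_cv
                )
                runs[(glabel, f"pulsed_{int(wl)}", ri)] = res_p
                runs[(glabel, f"constant_{int(wl)}", ri)] = res_c
                pk_p.append(res_p.summary.pk)
                pk_c.append(res_c.summary.pk)
                f0s.append(res_p.summary.f0_hz)
                idx.append(entrainment_index(res_p.summary, res_c.summary).pk_ratio)
                vs_blue.append(res_p.summary.pk / blue_pk[ri] if blue_pk[ri] > 0 else np.nan)
            rows.append(
                {
                    "genotype": glabel,
                    "wavelength_nm": wl,
                    "pk_pulsed_mean": _agg(pk_p)[0],
                    "pk_pulsed_sd": _agg(pk_p)[1],
                    "pk_constant_mean": _agg(pk_c)[0],
                    "pk_constant_sd": _agg(pk_c)[1],
                    "entrainment_index_mean": _agg(idx)[0],
                    "entrainment_index_sd": _agg(idx)[1],
                    "pk_vs_constant_blue_mean": _agg(vs_blue)[0],
                    "f0_pulsed_mean": _agg(f0s)[0],
                }
            )

    table = pd.DataFrame(rows)
    validate_output("pulsed", table)
    _maybe_write(spec, "pulsed", table, runs)
    return table, runs


# ---------------------------------------------------------------------------
# two-band autofluorescence
# ---------------------------------------------------------------------------

def run_fluorescence(spec: ExperimentSpec, action: ActionSpectrum | None = None):
    """Two-band fluorescence series and spectra per genotype."""
    proto = {**FLUORESCENCE_DEFAULTS, **spec.protocol}
    action = action or default_action_spectrum()
    duration = proto["duration_s"]
    field = constant_field(proto["excitation_nm"], proto["excitation_irradiance"], duration)
    rows = []
    outputs = {}
    for gi, glabel in enumerate(spec.genotypes):
        genotype = genotype_from_label(glabel)
        seed = derive_seed(spec.seeds[0], 2000 + gi)
        cfg = _sim_config(spec, genotype, seed, duration)
        traj = simulate(cfg, field, action)
        fluo = emit(
            traj,
            excitation_irradiance=proto["excitation_irradiance"],
            anisotropy=proto["anisotropy"],
        )
        mask = traj.sedimentation_mask()
        summaries = {}
        spectra_out = {}
        for name, values in (("red", fluo.band_r), ("farred", fluo.band_fr)):
            sig, dt, _ = preprocess((fluo.times[mask], values[mask]))
            ps = power_spectrum(sig, dt)
            spectra_out[name] = ps
            summaries[name] = characterize_peak(ps)
        corr = float(np.corrcoef(fluo.band_r[mask], fluo.band_fr[mask])[0, 1])
        outputs[glabel] = {"series": fluo, "spectra": spectra_out, "summaries": summaries}
        rows.append(
            {
                "genotype": glabel,
                "f0_red_hz": summaries["red"].f0_hz,
                "f0_farred_hz": summaries["farred"].f0_hz,
                "band_correlation": corr,
                "pk_red": summaries["red"].pk,
                "pk_farred": summaries["farred"].pk,
                "fit_mode_red": summaries["red"].fit_mode,
                "fit_mode_farred": summaries["farred"].fit_mode,
            }
        )
    table = pd.DataFrame(rows)
    validate_output("fluorescence", table)
    _maybe_write(spec, "fluorescence", table)
    if spec.output_dir:
        out = Path(spec.output_dir)
        for glabel, data in outputs.items():
            data["series"].to_csv(out / f"fluorescence_{glabel}.csv")
            for band, ps in data["spectra"].items():
                ps.to_csv(out / f"fluorescence_{glabel}_{band}_spectrum.csv")
    return table, outputs


_RUNNERS = {
    "wavelength_scan": run_wavelength_scan,
    "composed_rb": run_composed_rb,
    "pulsed": run_pulsed,
    "fluorescence": run_fluorescence,
}


def run_experiment(spec: ExperimentSpec, action: ActionSpectrum | None = None):
    """Dispatch to the family runner."""
    return _RUNNERS[spec.family](spec, action)


def _maybe_write(spec: ExperimentSpec, family: str, table: pd.DataFrame, runs=None, extra_json=None):
    if not spec.output_dir:
        return
    out = Path(spec.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{family}_summary.csv", index=False, float_format="%.10g")
    (out / f"{family}_spec.json").write_text(spec.to_json())
    if extra_json:
        (out / f"{family}_fits.json").write_text(json.dumps(extra_json, indent=1))
    if isinstance(runs, dict):
        for key, results in runs.items():
            if isinstance(results, list):
                for ri, r in enumerate(results):
                    tag = "_".join(str(k) for k in key) + f"_rep{ri + 1}"
                    r.ratio.to_csv(out / f"{family}_{tag}_ratio.csv")
            elif isinstance(results, PipelineResult):
                tag = "_".join(str(k) for k in key)
                results.ratio.to_csv(out / f"{family}_{tag}_ratio.csv")
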