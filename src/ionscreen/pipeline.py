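"""End-to-end pipeline: windows → profiles → decomposition → scaling factors.

Two execution modes:

``md``
    run the constrained polarizable-MD windows (charged) and the
    zero-charge LJ reference windows, then push both through TI,
    volume-entropy correction, subtraction and the two-region fit;
``analytic``
    skip MD and synthesize window force series from the screened-Coulomb
    oracle f(r) = s²·k_C·q²/r² + f_vdW(r) plus Gaussian noise — the
    closed-form closure used to validate the whole extraction chain.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import COULOMB_CONSTANT
from .decompose import CoulombProfile
from .dielectric import alpha_for_epsilon, scaling_from_epsilon
from .profiles import FreeEnergyProfile, add_entropy_correction, integrate_mean_force, window_mean_force
from .scaling import (
    DEFAULT_BOUNDARY,
    ScaledCoulombModel,
    ScaledCoulombResults,
    ScalingFactor,
    bootstrap_scaling_error,
)
from .species import SpeciesTable, default_species_table
from .windows import MeanForceWindow, WindowConfig, run_window

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "synthesize_analytic_windows", "load_pipeline_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full study configuration; ``seed`` is mandatory for reproducibility."""

    seed: int
    mode: str = "analytic"  # "md" | "analytic"
    window_distances: Tuple[float, ...] = tuple(np.round(np.linspace(3.6, 8.6, 10), 4))
    ion_species: str = "Na"
    n_solvent: int = 128
    number_density: float = 21.228  # nm^-3
    temperature: float = 300.0
    epsilon_el: float = 1.52
    timestep: float = 2.0
    equilibration_steps: int = 2500
    production_steps: int = 12500
    scheme: str = "none"
    boundary: float = DEFAULT_BOUNDARY
    block_fs: float = 1000.0
    n_resamples: int = 1000
    noise_sigma: float = 20.0  # analytic mode: per-sample force noise, kJ/mol/Å
    outdir: Optional[str] = None
    table: Optional[SpeciesTable] = None

    def __post_init__(self) -> None:
        if self.mode not in ("md", "analytic"):
            raise ValueError("mode must be 'md' or 'analytic'")
        d = np.asarray(self.window_distances)
        if len(d) < 4 or np.any(np.diff(d) <= 0):
            raise ValueError("window distances must be a strictly increasing list (>= 4)")

    def species_table(self) -> SpeciesTable:
        if self.table is not None:
            return self.table
        alpha = alpha_for_epsilon(self.epsilon_el, self.number_density * 1e-3)
        return default_species_table(alpha)

    def ion_charge(self) -> float:
        return self.species_table()[self.ion_species].charge

    def config_hash(self) -> str:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("outdir", "table")
        }
        if self.table is not None:
            payload["table"] = [
                (sp.name, sp.mass, sp.charge, sp.polarizability_volume, sp.lj_sigma, sp.lj_epsilon)
                for sp in self.table
            ]
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineReport:
    """All pipeline products plus provenance."""

    charged_profile: FreeEnergyProfile
    zerocharge_profile: FreeEnergyProfile
    coulomb_profile: CoulombProfile
    results: ScaledCoulombResults
    bootstrap: Dict[str, ScalingFactor]
    charged_windows: List[MeanForceWindow]
    zerocharge_windows: List[MeanForceWindow]
    provenance: Dict[str, object]

    def summary_dict(self) -> Dict[str, object]:
        out = dict(self.provenance)
        out["regions"] = {}
        for label in ("short", "long"):
            f = self.results.fits[label]
            sf = self.bootstrap[label]
            out["regions"][label] = {
                "s": round(sf.s, 6),
                "stderr_1p96sigma": round(sf.stderr, 6),
                "slope_kJ_A_mol": round(f.slope_a, 4),
                "intercept_kJ_mol": round(f.intercept_b, 4),
                "residual_rms_kJ_mol": round(f.residual_rms, 4),
                "n_points": f.n_points,
            }
        return out


def _window_seed(seed: int, index: int, mode_tag: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(index), int(mode_tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def synthesize_analytic_windows(
    config: PipelineConfig,
) -> Tuple[List[MeanForceWindow], List[MeanForceWindow]]:
    """Screened-Coulomb oracle windows with i.i.d. Gaussian force noise.

    The charged mean force is s²·k_C·q²/r² plus a short-range LJ-derived
    vdW force shared with the zero-charge windows, with
    s = 1/sqrt(ε_el) taken from the configured dielectric target.
    """
    s = scaling_from_epsilon(config.epsilon_el)
    q = abs(config.ion_charge())
    sigma_vdw, eps_vdw = 2.9, 0.5  # representative ion-pair vdW scale

    def f_vdw(r: float) -> float:
        s6 = (sigma_vdw / r) ** 6
        return 24.0 * eps_vdw * (2.0 * s6 * s6 - s6) / r

    charged, zero = [], []
    n = config.production_steps
    for i, r in enumerate(config.window_distances):
        for mode_tag, out, mean in (
            (1, charged, s**2 * COULOMB_CONSTANT * q * q / r**2 + f_vdw(r)),
            (2, zero, f_vdw(r)),
        ):
            rng = np.random.default_rng(_window_seed(config.seed, i, mode_tag))
            series = mean + config.noise_sigma * rng.standard_normal(n)
            out.append(
                MeanForceWindow(
                    target_distance=float(r),
                    projected_forces=series,
                    timestep=config.timestep,
                    production_steps=n,
                    equilibration_steps=0,
                    mode="polarizable_charged" if mode_tag == 1 else "zerocharge_lj",
                    seed=_window_seed(config.seed, i, mode_tag),
                )
            )
    return charged, zero


def _run_md_windows(config: PipelineConfig):
    alpha = alpha_for_epsilon(config.epsilon_el, config.number_density * 1e-3)
    charged, zero = [], []
    for i, r in enumerate(config.window_distances):
        base = dict(
            target_distance=float(r),
            ion_species=config.ion_species,
            n_solvent=config.n_solvent,
            number_density=config.number_density,
            temperature=config.temperature,
            timestep=config.timestep,
            equilibration_steps=config.equilibration_steps,
            production_steps=config.production_steps,
            scheme=config.scheme,
            solvent_polarizability=alpha,
            table=config.table,
        )
        charged.append(
            run_window(WindowConfig(seed=_window_seed(config.seed, i, 1),
                                    mode="polarizable_charged", **base))
        )
        zero.append(
            run_window(WindowConfig(seed=_window_seed(config.seed, i, 2),
                                    mode="zerocharge_lj", **base))
        )
    return charged, zero


def run_pipeline(config: PipelineConfig, progress=None) -> PipelineReport:
    """Run the full extraction chain and (optionally) write all artifacts.

    ``progress`` is an optional callable receiving status strings.
    """
    log = progress or (lambda msg: None)
    log(f"mode={config.mode} windows={len(config.window_distances)} seed={config.seed}")
    if config.mode == "analytic":
        charged_w, zero_w = synthesize_analytic_windows(config)
    else:
        charged_w, zero_w = _run_md_windows(config)
    log("windows done; integrating mean forces")

    def profile_of(windows):
        triples = [
            (w.target_distance, *window_mean_force(w, config.block_fs)) for w in windows
        ]
        prof = integrate_mean_force(triples, temperature=config.temperature)
        return add_entropy_correction(prof, config.temperature)

    charged_p = profile_of(charged_w)
    zero_p = profile_of(zero_w)
    q = abs(config.ion_charge())
    model = ScaledCoulombModel.from_profiles(
        charged_p, zero_p, charges=(q, q), boundary=config.boundary
    )
    results = model.fit()
    log("fit done; bootstrapping")
    boot = bootstrap_scaling_error(
        charged_w,
        zero_w,
        temperature=config.temperature,
        boundary=config.boundary,
        charges=(q, q),
        block_fs=config.block_fs,
        n_resamples=config.n_resamples,
        seed=_window_seed(config.seed, 9999, 3),
    )
    results.attach_bootstrap(boot)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "epsilon_el": config.epsilon_el,
        "expected_s": round(scaling_from_epsilon(config.epsilon_el), 6),
        "ion_species": config.ion_species,
        "n_windows": len(config.window_distances),
    }
    report = PipelineReport(
        charged_profile=charged_p,
        zerocharge_profile=zero_p,
        coulomb_profile=model.profile,
        results=results,
        bootstrap=boot,
        charged_windows=charged_w,
        zerocharge_windows=zero_w,
        provenance=provenance,
    )
    if config.outdir is not None:
        _write_report(config, report)
    return report


def _write_report(config: PipelineConfig, report: PipelineReport) -> None:
    from . import io as iomod

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iomod.write_profile(report.charged_profile, outdir / "free_energy_charged.tsv")
    iomod.write_profile(report.zerocharge_profile, outdir / "free_energy_zerocharge.tsv")
    iomod.write_coulomb_profile(report.coulomb_profile, outdir / "coulomb_profile.tsv")
    for tag, windows in (
        ("charged", report.charged_windows),
        ("zerocharge", report.zerocharge_windows),
    ):
        for w in windows:
            iomod.write_window(w, outdir / f"window_{tag}_r{w.target_distance:.2f}.tsv")
    with open(outdir / "scaling_factors.tsv", "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        fh.write("region\ts\tstderr_1p96sigma\tslope_kJ_A_mol\tintercept_kJ_mol\t"
                 "residual_rms_kJ_mol\tn_points\n")
        for label in ("short", "long"):
            f = report.results.fits[label]
            sf = report.bootstrap[label]
            fh.write(
                f"{label}\t{sf.s:.6f}\t{sf.stderr:.6f}\t{f.slope_a:.4f}\t"
                f"{f.intercept_b:.4f}\t{f.residual_rms:.4f}\t{f.n_points}\n"
            )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- TOML configuration ------------------------------------------------------

def load_pipeline_config(path) -> PipelineConfig:
    """Read a TOML pipeline configuration.

    Recognized sections: ``[pipeline]`` (mode, seed — mandatory, windows,
    boundary, resamples, outdir, noise_sigma), ``[system]`` (ion, n_solvent,
    density, temperature, epsilon_el, scheme), ``[run]`` (timestep_fs,
    equilibration_steps, production_steps), ``[species.NAME]`` parameter
    overrides, plus ``[constraint]`` (distances — alias for the window list)
    and ``[thermostat]`` (temperature — alias for the system temperature).
    """
    import tomllib

    from .species import SpeciesParams

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    pipe = raw.get("pipeline", {})
    system = raw.get("system", {})
    run = raw.get("run", {})
    if "distances" in raw.get("constraint", {}):
        pipe.setdefault("windows", raw["constraint"]["distances"])
    if "temperature" in raw.get("thermostat", {}):
        system.setdefault("temperature", raw["thermostat"]["temperature"])
    if "seed" not in pipe:
        raise ValueError(f"{path}: [pipeline].seed is mandatory for reproducibility")

    table = None
    if "species" in raw:
        eps = system.get("epsilon_el", 1.52)
        dens = system.get("density", 21.228)
        base = default_species_table(alpha_for_epsilon(eps, dens * 1e-3))
        for name, fields in raw["species"].items():
            current = base[name] if name in base else SpeciesParams(name, mass=1.0)
            base = base.with_species(
                replace(
                    current,
                    **{
                        {"sigma": "lj_sigma", "epsilon": "lj_epsilon",
                         "alpha": "polarizability_volume"}.get(k, k): v
                        for k, v in fields.items()
                    },
                )
            )
        table = base

    kwargs = dict(
        seed=int(pipe["seed"]),
        mode=pipe.get("mode", "analytic"),
        boundary=float(pipe.get("boundary", DEFAULT_BOUNDARY)),
        n_resamples=int(pipe.get("resamples", 1000)),
        outdir=pipe.get("outdir"),
        noise_sigma=float(pipe.get("noise_sigma", 20.0)),
        ion_species=system.get("ion", "Na"),
        n_solvent=int(system.get("n_solvent", 128)),
        number_density=float(system.get("density", 21.228)),
        temperature=float(system.get("temperature", 300.0)),
        epsilon_el=float(system.get("epsilon_el", 1.52)),
        scheme=system.get("scheme", "none"),
        timestep=float(run.get("timestep_fs", 2.0)),
        equilibration_steps=int(run.get("equilibration_steps", 2500)),
        production_steps=int(run.get("production_steps", 12500)),
        table=table,
    )
    if "windows" in pipe:
        kwargs["window_distances"] = tuple(float(x) for x in pipe["windows"])
    return PipelineConfig(**kwargs)
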