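"""Reproducible end-to-end workflows: configuration, canned pipelines
(slab stiffness recovery, circular-halo recovery, inclusion profiles), a
run directory with CSV/JSON artifacts, and a plotted report.

A run is fully determined by its :class:`RunConfig` (one root seed feeds
every stochastic stage through spawned child streams), so re-running an
identical config reproduces identical artifacts for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .capillary import (Spectrum, StiffnessFit, fit_stiffness, flat_spectrum,
                        circular_spectrum, theory_spectrum)
from .configuration import PointConfiguration2D
from .constants import (GRID_SPACING_DEFAULT, K_MAX_DEFAULT, XI_DEFAULT)
from .interface import (extract_interface, height_function, radius_function)
from .order import (bulk_levels, coarse_grain, compute_phi, radial_profile)
from .synth import (HEX_JITTER_FRACTION, HEX_SPACING, RHO_DISORDERED,
                    RMIN_DISORDERED, HeightSample, gen_capillary_circle,
                    gen_capillary_flat, gen_disordered, gen_hexagonal,
                    gen_inclusion, gen_slab)

__all__ = [
    "RunConfig", "run_pipeline", "report",
    "calibrate_levels", "slab_capillary_pipeline",
    "inclusion_capillary_pipeline",
]

log = logging.getLogger("premelt")

KNOWN_KINDS = ("slab-recovery", "circle-recovery", "inclusion-profile")


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    kind: str
    seed: int
    outdir: str
    temperature: float | None = 294.0      # K
    gamma_true: float | None = 11.5        # pN (synthetic ground truth)
    n_frames: int = 50
    xi: float = XI_DEFAULT
    delta: float = GRID_SPACING_DEFAULT
    k_max: float = K_MAX_DEFAULT
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in KNOWN_KINDS:
            raise ValueError(f"unknown run kind {self.kind!r}; "
                             f"one of {KNOWN_KINDS}")
        if self.kind in ("slab-recovery", "circle-recovery"):
            if self.temperature is None:
                raise ValueError(
                    f"run kind {self.kind!r} fits a stiffness and requires "
                    "a temperature")
            if self.gamma_true is None or self.gamma_true <= 0:
                raise ValueError("gamma_true must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def calibrate_levels(a: float = HEX_SPACING, sigma: float | None = None,
                     rho0: float = RHO_DISORDERED,
                     r_min: float = RMIN_DISORDERED,
                     box: Sequence[float] = (15.0, 15.0), *,
                     seed: int) -> tuple[float, float]:
    """Bulk levels (phi_d, phi_o) of the coarse-grained order density for
    the synthetic phases, from one pure sample of each."""
    ss = np.random.SeedSequence(seed)
    s_hex, s_dis = (int(c.generate_state(1)[0] % 2**31)
                    for c in ss.spawn(2))
    ordered = gen_hexagonal(a, sigma, box, seed=s_hex)
    disordered = gen_disordered(rho0, r_min, box, seed=s_dis)
    phi_o, _ = bulk_levels(ordered)
    phi_d, _ = bulk_levels(disordered)
    return phi_d, phi_o


def _frame_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def slab_capillary_pipeline(gamma: float, T: float, *, seed: int,
                            n_frames: int = 100, L: float = 80.0,
                            Lx: float = 24.0, fraction_ordered: float = 0.5,
                            a: float = HEX_SPACING,
                            sigma: float | None = None,
                            rho0: float = RHO_DISORDERED,
                            xi: float = XI_DEFAULT,
                            delta: float = GRID_SPACING_DEFAULT,
                            n_bins: int = 128, k_max: float = 0.35,
                            deconvolve: bool = True) -> dict:
    """Full point-cloud round trip for a flat interface.

    Generates capillary height profiles at the given stiffness, builds slab
    point configurations whose two boundaries are displaced by them, then
    recovers the stiffness through per-particle order -> coarse-graining ->
    level-set extraction -> height binning -> Fourier spectrum -> weighted
    fit (with the Gaussian coarse-graining deconvolved by default).

    Returns a dict with the fit, the spectrum, the calibrated levels, and
    per-frame diagnostics.
    """
    if sigma is None:
        sigma = HEX_JITTER_FRACTION * a
    seeds = _frame_seeds(seed, n_frames + 2)
    phi_d, phi_o = calibrate_levels(a, sigma, rho0, seed=seeds[-1])
    heights = gen_capillary_flat(L=L, gamma=gamma, T=T, n_grid=256,
                                 n_frames=2 * n_frames, seed=seeds[-2])
    samples: list[HeightSample] = []
    per_boundary: list[list[np.ndarray]] = [[], []]
    n_skipped = 0
    for i in range(n_frames):
        profiles = (heights[2 * i].values, heights[2 * i + 1].values)
        cfg = gen_slab(a, sigma, rho0, fraction_ordered, (Lx, L),
                       seed=seeds[i], boundary_profiles=profiles)
        phi = compute_phi(cfg).phi
        fld = coarse_grain(cfg, phi, xi, delta)
        curves = [c for c in extract_interface(fld, phi_d, phi_o,
                                               frame_id=i)
                  if not c.closed and c.spanning_axis == 1]
        if len(curves) != 2:
            n_skipped += 1
            log.warning("frame %d: found %d spanning curves, expected 2; "
                        "skipped", i, len(curves))
            continue
        curves.sort(key=lambda c: float(
            np.mod(c.vertices[:, 0], cfg.box[0]).mean()))
        for b, curve in enumerate(curves):
            hf = height_function(curve, axis=1, n_bins=n_bins)
            samples.append(HeightSample(hf.h, L, "flat", T, gamma))
            per_boundary[b].append(hf.h)
    if len(samples) < 4:
        raise RuntimeError("too few usable interface frames for a spectrum")
    spectrum = flat_spectrum(samples)
    fit = fit_stiffness(spectrum, T, k_max=k_max,
                        xi=(xi if deconvolve else None))
    return {"fit": fit, "spectrum": spectrum, "phi_d": phi_d,
            "phi_o": phi_o, "gamma_true": gamma, "n_skipped": n_skipped,
            "per_boundary": per_boundary}


def inclusion_capillary_pipeline(gamma: float, T: float, *, seed: int,
                                 n_frames: int = 80, R: float = 1.5,
                                 R0: float = 6.0,
                                 box: Sequence[float] = (26.0, 26.0),
                                 a: float = HEX_SPACING,
                                 sigma: float | None = None,
                                 rho0: float = RHO_DISORDERED,
                                 xi: float = XI_DEFAULT,
                                 delta: float = GRID_SPACING_DEFAULT,
                                 n_bins: int = 128,
                                 k_max: float = K_MAX_DEFAULT,
                                 n_modes: int = 6,
                                 deconvolve: bool = True,
                                 fit: bool = True) -> dict:
    """Point-cloud round trip for the circular halo boundary around an
    inclusion: capillary radius profiles -> inclusion configurations ->
    extraction -> R(theta) -> angular spectrum (-> stiffness fit)."""
    if sigma is None:
        sigma = HEX_JITTER_FRACTION * a
    seeds = _frame_seeds(seed, n_frames + 2)
    phi_d, phi_o = calibrate_levels(a, sigma, rho0, seed=seeds[-1])
    rsamp = gen_capillary_circle(R0=R0, gamma=gamma, T=T, n_modes=n_modes,
                                 n_frames=n_frames, seed=seeds[-2])
    samples: list[HeightSample] = []
    n_skipped = 0
    center = None
    for i in range(n_frames):
        cfg = gen_inclusion(R, R0, a, sigma, rho0, box, seed=seeds[i],
                            radius_profile=rsamp[i].values - R0)
        center = cfg.metadata["center"]
        phi = compute_phi(cfg).phi
        fld = coarse_grain(cfg, phi, xi, delta)
        loops = [c for c in extract_interface(fld, phi_d, phi_o,
                                              frame_id=i) if c.closed]
        if not loops:
            n_skipped += 1
            continue
        # the halo boundary is the closed loop nearest the target radius
        def _mean_r(c):
            rel = c.vertices - np.asarray(center)
            return abs(float(np.hypot(rel[:, 0], rel[:, 1]).mean()) - R0)
        loop = min(loops, key=_mean_r)
        rf = radius_function(loop, center, n_bins=n_bins)
        samples.append(HeightSample(rf.R, rf.R0, "circle", T, gamma))
    if len(samples) < 4:
        raise RuntimeError("too few usable halo contours for a spectrum")
    spectrum = circular_spectrum(samples, n_modes=n_modes)
    out = {"spectrum": spectrum, "phi_d": phi_d, "phi_o": phi_o,
           "gamma_true": gamma, "n_skipped": n_skipped, "center": center}
    if fit:
        out["fit"] = fit_stiffness(spectrum, T, k_max=k_max,
                                   xi=(xi if deconvolve else None))
    return out


def _write_spectrum(spectrum: Spectrum, path) -> None:
    pd.DataFrame({"m": spectrum.m.astype(int), "k": spectrum.k,
                  "amplitude": spectrum.amplitude,
                  "stderr": spectrum.stderr}).to_csv(path, index=False)


def _write_fit(fit: StiffnessFit, path) -> None:
    with open(path, "w") as fh:
        json.dump({"gamma_pN": fit.gamma, "stderr_pN": fit.stderr,
                   "k_max": fit.k_max, "T_K": fit.temperature,
                   "geometry": fit.geometry, "n_modes": fit.n_modes,
                   "chi2_reduced": fit.chi2_reduced}, fh, indent=2)


def run_pipeline(config: RunConfig) -> Path:
    """Execute a canned workflow and write every artifact plus a JSON
    manifest into the run directory.  Any stage error aborts with the
    stage name; artifacts written so far are preserved."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    manifest: dict = {"version": __version__, "kind": config.kind,
                      "seed": config.seed, "stages": []}
    t0 = time.time()
    stage = "setup"
    try:
        if config.kind == "slab-recovery":
            stage = "slab-recovery"
            res = slab_capillary_pipeline(
                config.gamma_true, config.temperature, seed=config.seed,
                n_frames=config.n_frames, xi=config.xi, delta=config.delta,
                **config.params)
            _write_spectrum(res["spectrum"], outdir / "spectrum.csv")
            _write_fit(res["fit"], outdir / "fit.json")
            manifest.update(gamma_true=res["gamma_true"],
                            gamma_fit=res["fit"].gamma,
                            gamma_se=res["fit"].stderr,
                            phi_d=res["phi_d"], phi_o=res["phi_o"],
                            n_skipped=res["n_skipped"])
        elif config.kind == "circle-recovery":
            stage = "circle-recovery"
            res = inclusion_capillary_pipeline(
                config.gamma_true, config.temperature, seed=config.seed,
                n_frames=config.n_frames, xi=config.xi, delta=config.delta,
                **config.params)
            _write_spectrum(res["spectrum"], outdir / "spectrum.csv")
            if "fit" in res:
                _write_fit(res["fit"], outdir / "fit.json")
                manifest.update(gamma_fit=res["fit"].gamma,
                                gamma_se=res["fit"].stderr)
            manifest.update(gamma_true=res["gamma_true"],
                            phi_d=res["phi_d"], phi_o=res["phi_o"])
        elif config.kind == "inclusion-profile":
            stage = "inclusion-profile"
            params = dict(config.params)
            R = params.pop("R", 1.5)
            R0 = params.pop("R0", 4.0)
            box = params.pop("box", (26.0, 26.0))
            seeds = _frame_seeds(config.seed, config.n_frames)
            frames = [gen_inclusion(R, R0, box=box, seed=s, **params)
                      for s in seeds[:config.n_frames]]
            center = frames[0].metadata["center"]
            prof = radial_profile(frames, center, xi=config.xi,
                                  delta=config.delta)
            pd.DataFrame({
                "r": prof.r, "mean_phi": prof.mean_phi,
                "mean_rho": prof.mean_rho, "ratio": prof.ratio,
                "particle_phi": prof.particle_phi,
                "counts": prof.counts,
            }).to_csv(outdir / "profile.csv", index=False)
            manifest.update(R=R, R0=R0, center=list(center))
        manifest["stages"].append({"name": stage,
                                   "wall_s": time.time() - t0})
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    digests = {}
    for f in sorted(outdir.glob("*.csv")):
        digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest["artifact_sha256"] = digests
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def report(run_dir) -> Path:
    """Render a summary (markdown + PNG figures) from a completed run
    directory.  Missing artifacts are listed; a partial report is still
    produced."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    lines = ["# premelt run report", ""]
    missing = []
    manifest = {}
    if (run_dir / "manifest.json").exists():
        manifest = json.loads((run_dir / "manifest.json").read_text())
        lines += [f"- kind: {manifest.get('kind')}",
                  f"- seed: {manifest.get('seed')}",
                  f"- version: {manifest.get('version')}", ""]
    else:
        missing.append("manifest.json")
    spec_path = run_dir / "spectrum.csv"
    if spec_path.exists():
        df = pd.read_csv(spec_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(df["k"], df["amplitude"], yerr=df["stderr"], fmt="o",
                    label="measured")
        gamma = manifest.get("gamma_true")
        T = manifest.get("T_K", 294.0)
        if (run_dir / "fit.json").exists():
            fit = json.loads((run_dir / "fit.json").read_text())
            T = fit.get("T_K", T)
            kk = np.asarray(df["k"], dtype=float)
            from .constants import KB
            if fit["geometry"] == "flat":
                L = 2 * np.pi * df["m"].iloc[0] / df["k"].iloc[0]
                ax.plot(kk, KB * T / (L * fit["gamma_pN"] * kk ** 2), "-",
                        label=f"capillary theory, "
                              f"gamma={fit['gamma_pN']:.2f} pN")
            else:
                R0 = df["m"].iloc[0] / df["k"].iloc[0]
                ax.plot(kk, KB * T / (2 * np.pi * R0 * fit["gamma_pN"]
                                      * kk ** 2), "-",
                        label=f"capillary theory, "
                              f"gamma={fit['gamma_pN']:.2f} pN")
            lines += [f"- fitted stiffness: {fit['gamma_pN']:.3f} "
                      f"+- {fit['stderr_pN']:.3f} pN "
                      f"(k_max {fit['k_max']} 1/nm, "
                      f"{fit['n_modes']} modes)"]
            if gamma is not None:
                lines += [f"- generator stiffness: {gamma} pN"]
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("k (1/nm)")
        ax.set_ylabel("mode amplitude (nm^2)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "spectrum.png", dpi=120)
        plt.close(fig)
        lines += ["", "![spectrum](spectrum.png)", ""]
    else:
        missing.append("spectrum.csv")
    prof_path = run_dir / "profile.csv"
    if prof_path.exists():
        df = pd.read_csv(prof_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(df["r"], df["ratio"], "o-", label="phi_bar / rho_bar")
        finite = df["ratio"].dropna()
        if len(finite):
            ax.axhline(finite.iloc[:3].mean(), ls="--", c="gray",
                       label="inner plateau")
            ax.axhline(finite.iloc[-3:].mean(), ls=":", c="gray",
                       label="outer plateau")
        ax.set_xlabel("r (nm)")
        ax.set_ylabel("order ratio")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "profile.png", dpi=120)
        plt.close(fig)
        lines += ["![profile](profile.png)", ""]
    elif manifest.get("kind") == "inclusion-profile":
        missing.append("profile.csv")
    if missing:
        lines += ["## Missing artifacts", ""]
        lines += [f"- {m}" for m in missing]
    if not manifest and not spec_path.exists() and not prof_path.exists():
        lines += ["## No artifacts", "",
                  "The run directory contains no recognizable artifacts."]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
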