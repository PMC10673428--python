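"""Reproducible end-to-end pipeline: simulate -> fit -> rigidity.

A :class:`RunConfig` captures every knob (stage parameters, root seed,
output directory); all stage randomness derives deterministically from
the root seed, and a machine-readable manifest records versions, seeds
and SHA-256 checksums of every output so identical configurations yield
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .curve_models import fit_thermal, fit_titration
from .datatypes import BaselineParams, NoiseSpec, TransitionParams
from .io import write_curve, write_structure, write_thermogram
from .rigidity import fuzzy_ensemble, unfold
from .state_models import fit_dsc, fit_thermofluor
from .synthetic_data import (
    HelixFixtureSpec,
    make_helix_structure,
    make_thermofluor_trace,
    make_thermogram,
    make_titration_curve,
)

log = logging.getLogger("unfoldkit.pipeline")

#: Default simulated study conditions: DSC transitions, thermal-shift
#: transition and baselines, pH titration, and thermal CD-style scan.
DEFAULT_STAGE_PARAMS: dict = {
    "dsc": {"tm1": 52.3, "dh1": 55.0, "tm2": 69.8, "dh2": 50.0,
            "grid": [25.0, 90.0, 0.2], "noise_sd": 0.2},
    "thermofluor": {"tm": 71.3, "dh": 120.0,
                    "baselines": [100.0, -0.1, 900.0, -0.5],
                    "grid": [25.0, 90.0, 0.5], "noise_sd": None},
    "titration": {"pka": 4.0, "n": 1.0, "xa": 1.0, "xb": 0.0,
                  "grid": [2.0, 8.0, 0.25], "noise_sd": 0.02},
    "thermal": {"tm": 66.0, "dh": 60.0,
                "baselines": [1.0, -0.002, 0.2, -0.001],
                "grid": [25.0, 80.0, 0.2], "noise_sd": None},
    "rigidity": {"n_residues": 12, "n_topologies": 20, "sigma_e": 0.2,
                 "step": 0.1},
}


@dataclass
class RunConfig:
    """Serializable pipeline configuration (JSON round-trip identical)."""

    seed: int = 1
    output_dir: str = "unfoldkit_out"
    stages: list[str] = field(default_factory=lambda: ["simulate", "fit", "rigidity"])
    stage_params: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_STAGE_PARAMS)))
    inputs: dict = field(default_factory=dict)   # optional measured-curve paths
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the root seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def _grid(spec) -> np.ndarray:
    lo, hi, step = spec
    return np.arange(lo, hi + step / 2, step)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest (also written
    to ``manifest.json`` in the output directory)."""
    logging.basicConfig(level=config.log_level)
    for key, p in config.inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {key!r} not found: {p}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = config.stage_params
    results: dict = {}
    timings: dict[str, float] = {}

    produced: dict[str, Path] = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        log.info("stage %s starting (seed %d)", stage, config.stage_seed(stage))
        if stage == "simulate":
            seed = config.stage_seed(stage)
            p = sp["dsc"]
            tg = make_thermogram(
                [TransitionParams(p["tm1"], p["dh1"]), TransitionParams(p["tm2"], p["dh2"])],
                _grid(p["grid"]), NoiseSpec(sd=p["noise_sd"], seed=seed))
            write_thermogram(tg, outdir / "dsc.csv")
            p = sp["thermofluor"]
            tf = make_thermofluor_trace(
                TransitionParams(p["tm"], p["dh"]), BaselineParams(*p["baselines"]),
                _grid(p["grid"]), NoiseSpec(sd=p["noise_sd"], seed=seed + 1))
            write_curve(tf, outdir / "thermofluor.csv")
            p = sp["titration"]
            ti = make_titration_curve(p["pka"], p["n"], p["xa"], p["xb"],
                                      _grid(p["grid"]),
                                      NoiseSpec(sd=p["noise_sd"], seed=seed + 2))
            write_curve(ti, outdir / "titration.csv")
            p = sp["thermal"]
            th = make_thermofluor_trace(
                TransitionParams(p["tm"], p["dh"]), BaselineParams(*p["baselines"]),
                _grid(p["grid"]), NoiseSpec(sd=p["noise_sd"], seed=seed + 3))
            write_curve(th, outdir / "thermal.csv")
            helix = make_helix_structure(
                HelixFixtureSpec(sp["rigidity"]["n_residues"]))
            write_structure(helix, outdir / "helix.pdb")
            for name in ("dsc.csv", "dsc.csv.json", "thermofluor.csv", "thermofluor.csv.json",
                         "titration.csv", "titration.csv.json", "thermal.csv",
                         "thermal.csv.json", "helix.pdb"):
                produced[name] = outdir / name
            results["simulate"] = {"outputs": sorted(produced)}
        elif stage == "fit":
            from .io import read_curve, read_thermogram
            tg = read_thermogram(produced.get("dsc.csv", outdir / "dsc.csv"))
            dsc = fit_dsc(tg)
            tf = read_curve(produced.get("thermofluor.csv", outdir / "thermofluor.csv"),
                            "temperature_C")
            tff = fit_thermofluor(tf)
            ti = read_curve(produced.get("titration.csv", outdir / "titration.csv"), "pH")
            tif = fit_titration(ti)
            th = read_curve(produced.get("thermal.csv", outdir / "thermal.csv"),
                            "temperature_C")
            thf = fit_thermal(th, fix_dcp=0.0)
            results["fit"] = {
                "dsc": {"Tm1": dsc.transitions[0].Tm, "dH1": dsc.transitions[0].dH,
                        "Tm2": dsc.transitions[1].Tm, "dH2": dsc.transitions[1].dH,
                        "success": dsc.success},
                "thermofluor": {"Tm": tff.Tm, "dH": tff.dH, "success": tff.success},
                "titration": {"pKa": tif.pKa, "n": tif.n, "success": tif.success},
                "thermal": {"Tm": thf.Tm, "dHm": thf.dHm, "success": thf.success},
            }
            (outdir / "fits.json").write_text(json.dumps(results["fit"], indent=1, sort_keys=True))
            produced["fits.json"] = outdir / "fits.json"
        elif stage == "rigidity":
            import pandas as pd
            p = sp["rigidity"]
            helix = make_helix_structure(HelixFixtureSpec(p["n_residues"]))
            trace = unfold(helix, step=p["step"])
            pd.DataFrame({
                "E": trace.energies, "T_C": trace.temperatures,
                "phi": trace.phi, "sigma": trace.sigma, "pi": trace.pi,
            }).to_csv(outdir / "unfolding_trace.tsv", sep="\t", index=False)
            ens = fuzzy_ensemble(helix, n_topologies=p["n_topologies"],
                                 sigma_E=p["sigma_e"], seed=config.stage_seed(stage),
                                 step=p["step"])
            pd.DataFrame({
                "residue": ens.profile.residues, "P": ens.profile.P,
                "R": ens.profile.R, "F": ens.profile.F,
            }).to_csv(outdir / "residue_profile.tsv", sep="\t", index=False)
            results["rigidity"] = {
                "sigma_transition_E": ens.sigma_mean, "sigma_sd": ens.sigma_sd,
                "pi_transition_E": ens.pi_mean, "pi_sd": ens.pi_sd,
                "pi_transition_T_C": ens.pi_temperature,
            }
            (outdir / "rigidity.json").write_text(
                json.dumps(results["rigidity"], indent=1, sort_keys=True))
            for name in ("unfolding_trace.tsv", "residue_profile.tsv", "rigidity.json"):
                produced[name] = outdir / name
        else:
            raise ValueError(f"unknown stage {stage!r}")
        timings[stage] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", stage, timings[stage])

    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "parameters": sp,
        "checksums": {name: _sha256(path) for name, path in sorted(produced.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("timings: %s", {k: round(v, 2) for k, v in timings.items()})
    return manifest
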