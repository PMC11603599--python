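"""Config-driven orchestration of the lambda-scan calibration.

A single YAML (or dict) config drives the full chain: obtain per-lambda
RDF runs (synthesised from a pair potential whose well depth follows the
scaling law, or ingested from user .xvg files), estimate tail-corrected
B23 per lambda, interpolate the scan at the experimental target, and
optionally evaluate stability (Delta B23, Kd(C)) and dissociation-rate
blocks.  Every stage writes its table under ``output_dir`` and the run
ends with a JSON manifest listing inputs, parameters, seeds and a
content hash of every output file.

Config schema (top-level keys)::

    seed: 1                    # master seed; per-run seeds derive from it
    output_dir: out
    rdf:
      mode: synthetic          # or "files"
      n_runs: 4                # synthetic: independent noisy runs per lambda
      noise_sd: 0.005
      bin_width: 0.1
      r_max: 10.0
      lambdas: [0.0, 0.5, 1.0]
      epsilon_floor: 2.0       # kJ/mol, lambda=0 well depth
      potential:               # synthetic mode only
        kind: square_well
        sigma: 2.0
        epsilon_original: 6.0  # kJ/mol, lambda=1 well depth
        well_range: 1.25
      files:                   # files mode only
        - {lambda: 0.15, paths: [run1.xvg, run2.xvg]}
    virial:
      delta: 2.0
      plateau_window: [8.0, 10.0]
      r_star_step: 0.1
    target: {B23: 12.0, sem: 2.0}
    stability:                 # optional
      kd0: 2.0e-5              # M
      concentrations: [0.0, 0.25, 0.5, 1.0]
      B_mon: 5.0               # L/mol (or mon_files/dim_files xvg lists)
      B_dim: 9.0
    rates:                     # optional
      record: dimer_runs.tsv   # duration / event_time TSV
      ka: 1.0e9                # M^-1 s^-1 diffusion-limited association
"""

from __future__ import annotations

import hashlib
import json
import time
from glob import glob
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import diffusion_limited_rate, kd_model, ml_dissociation_rate
from .calibration import LambdaScan, ScanPoint, fit_lambda
from .io import read_dimer_tsv, read_xvg, write_xvg
from .potentials import PairPotentialModel, PotentialKind
from .synthetic import SyntheticRdfSpec, gen_analytic_rdf
from .virial import plateau_estimate

__all__ = ["ConfigError", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """The pipeline config is missing a key or holds an invalid value."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _require(cfg: dict, key: str, where: str = "config"):
    if key not in cfg:
        raise ConfigError(f"{where} is missing required key {key!r}")
    return cfg[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scaled_potential(pot_cfg: dict, lam: float, eps_floor: float) -> PairPotentialModel:
    kind = PotentialKind(_require(pot_cfg, "kind", "rdf.potential"))
    eps_orig = float(_require(pot_cfg, "epsilon_original", "rdf.potential"))
    eps = eps_floor + lam * (eps_orig - eps_floor)
    return PairPotentialModel(
        kind=kind,
        sigma=float(_require(pot_cfg, "sigma", "rdf.potential")),
        epsilon=eps,
        well_range=pot_cfg.get("well_range"),
    )


def _gather_rdfs(cfg: dict, seed: int, outdir: Path, log) -> dict[float, list]:
    rdf_cfg = _require(cfg, "rdf")
    mode = rdf_cfg.get("mode", "synthetic")
    per_lambda: dict[float, list] = {}
    if mode == "synthetic":
        lambdas = [float(l) for l in _require(rdf_cfg, "lambdas", "rdf")]
        n_runs = int(rdf_cfg.get("n_runs", 4))
        eps_floor = float(rdf_cfg.get("epsilon_floor", 2.0))
        pot_cfg = _require(rdf_cfg, "potential", "rdf")
        rng = np.random.default_rng(seed)
        for lam in lambdas:
            pot = _scaled_potential(pot_cfg, lam, eps_floor)
            runs = []
            for k in range(n_runs):
                spec = SyntheticRdfSpec(
                    potential=pot,
                    baseline=float(rdf_cfg.get("baseline", 1.0)),
                    noise_sd=float(rdf_cfg.get("noise_sd", 0.0)),
                    bin_width=float(rdf_cfg.get("bin_width", 0.1)),
                    r_max=float(rdf_cfg.get("r_max", 10.0)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                rdf = gen_analytic_rdf(spec, run_id=f"lam{lam:g}_run{k}")
                out = outdir / f"rdf_lam{lam:g}_run{k}.xvg"
                write_xvg(rdf, out)
                runs.append(rdf)
            per_lambda[lam] = runs
            log(f"synthesised {n_runs} RDF runs at lambda={lam:g} "
                f"(well depth {pot.epsilon:g} kJ/mol)")
    elif mode == "files":
        for block in _require(rdf_cfg, "files", "rdf"):
            lam = float(_require(block, "lambda", "rdf.files[]"))
            paths: list[str] = []
            for pattern in _require(block, "paths", "rdf.files[]"):
                hits = sorted(glob(str(pattern)))
                if not hits:
                    raise ConfigError(f"no RDF files match {pattern!r}")
                paths.extend(hits)
            per_lambda[lam] = [read_xvg(p) for p in paths]
            log(f"ingested {len(paths)} RDF runs at lambda={lam:g}")
    else:
        raise ConfigError(f"rdf.mode must be 'synthetic' or 'files', got {mode!r}")
    if len(per_lambda) < 2:
        raise ConfigError("need at least 2 lambda values to calibrate")
    return per_lambda


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the calibration pipeline; returns the manifest dict.

    ``config`` may be a dict or a YAML path.  All randomness derives
    from ``config['seed']``; rerunning with identical config and seed
    reproduces every result table byte for byte.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or _require(config, "output_dir"))
    outdir.mkdir(parents=True, exist_ok=True)

    log_lines: list[str] = []
    stages: list[dict] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def stage(name: str):
        t0 = time.perf_counter()

        def done():
            stages.append({"name": name, "wall_time_s": time.perf_counter() - t0})

        return done

    target_cfg = _require(config, "target")
    target = (float(_require(target_cfg, "B23", "target")),
              float(target_cfg.get("sem", 0.0)))

    try:
        done = stage("rdf")
        per_lambda = _gather_rdfs(config, seed, outdir, log)
        done()

        done = stage("virial")
        vir_cfg = config.get("virial", {})
        delta = float(vir_cfg.get("delta", 2.0))
        window = tuple(float(x) for x in vir_cfg.get("plateau_window", (8.0, 10.0)))
        step = float(vir_cfg.get("r_star_step", 0.1))
        rows = []
        points = []
        for lam in sorted(per_lambda):
            est = plateau_estimate(
                per_lambda[lam], delta=delta, plateau_window=window, r_star_step=step
            )
            rows.append(
                {
                    "lambda": lam,
                    "B23": est.plateau_mean,
                    "sem": est.plateau_sem,
                    "n_runs": est.n_runs,
                }
            )
            points.append(
                ScanPoint(lam, est.plateau_mean, est.plateau_sem, est.run_ids)
            )
            log(f"lambda={lam:g}: B23 = {est.plateau_mean:.4f} "
                f"+/- {est.plateau_sem:.4f} L/mol ({est.n_runs} runs)")
        scan_df = pd.DataFrame(rows)
        scan_path = outdir / "lambda_scan.tsv"
        scan_df.to_csv(scan_path, sep="\t", index=False, float_format="%.10g")
        done()

        done = stage("calibration")
        scan = LambdaScan(points=points, target=target)
        result = fit_lambda(scan)
        calib = {
            "lambda_star": result.lambda_star,
            "lambda_interval": list(result.lambda_interval),
            "method": result.method,
            "monotone": result.monotone,
            "consistent_lambdas": result.consistent_lambdas,
            "target_B23": target[0],
            "target_sem": target[1],
        }
        calib_path = outdir / "calibration.json"
        calib_path.write_text(json.dumps(calib, indent=2, sort_keys=True) + "\n")
        log(f"calibrated lambda* = {result.lambda_star:.4f} "
            f"interval {result.lambda_interval}")
        done()

        extra_outputs: list[Path] = []
        if "stability" in config:
            done = stage("stability")
            st = config["stability"]
            if "B_mon" in st:
                B_mon, B_dim = float(st["B_mon"]), float(_require(st, "B_dim", "stability"))
            else:
                mon = [read_xvg(p) for pat in _require(st, "mon_files", "stability")
                       for p in sorted(glob(str(pat)))]
                dim = [read_xvg(p) for pat in _require(st, "dim_files", "stability")
                       for p in sorted(glob(str(pat)))]
                B_mon = plateau_estimate(mon, delta=delta, plateau_window=window,
                                         r_star_step=step).plateau_mean
                B_dim = plateau_estimate(dim, delta=delta, plateau_window=window,
                                         r_star_step=step).plateau_mean
            dB = 2.0 * B_mon - B_dim
            kd0 = float(_require(st, "kd0", "stability"))
            conc = [float(c) for c in st.get("concentrations", [0.0])]
            stab_df = pd.DataFrame(
                {"C": conc, "Kd": [kd_model(kd0, dB, c) for c in conc]}
            )
            stab_path = outdir / "stability.tsv"
            stab_df.to_csv(stab_path, sep="\t", index=False, float_format="%.10g")
            (outdir / "stability.json").write_text(
                json.dumps(
                    {"B_mon": B_mon, "B_dim": B_dim, "delta_B23": dB, "kd0": kd0},
                    indent=2, sort_keys=True,
                ) + "\n"
            )
            extra_outputs += [stab_path, outdir / "stability.json"]
            log(f"stability: delta_B23 = {dB:.4f} L/mol")
            done()

        if "rates" in config:
            done = stage("rates")
            rt = config["rates"]
            record = read_dimer_tsv(_require(rt, "record", "rates"))
            est = ml_dissociation_rate(record)
            rates = {
                "rate_per_us": est.rate,
                "mean_lifetime_us": None if est.zero_events else 1.0 / est.rate,
                "n_events": est.n_events,
                "total_time_us": est.total_time,
                "zero_events": est.zero_events,
                "rule_of_three_upper_per_us": est.upper_bound_rule_of_three,
            }
            if "Kd" in rt:
                k_dl = diffusion_limited_rate(float(rt["Kd"]), float(rt.get("ka", 1e9)))
                rates["diffusion_limited_rate_per_s"] = k_dl
            rates_path = outdir / "rates.json"
            rates_path.write_text(json.dumps(rates, indent=2, sort_keys=True) + "\n")
            extra_outputs.append(rates_path)
            log(f"dissociation rate = {est.rate:.6g} /us ({est.n_events} events)")
            done()
    except Exception as exc:
        # Preserve partial outputs; surface the failing stage.
        failed = stages[-1]["name"] if stages else "setup"
        (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed after stage {failed!r}: {exc}") from exc

    log_path = outdir / "pipeline.log"
    log_path.write_text("\n".join(log_lines) + "\n")

    outputs = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": "osmocal",
        "version": __version__,
        "seed": seed,
        "config": config,
        "target": {"B23": target[0], "sem": target[1]},
        "stages": stages,
        "outputs": [{"path": p.name, "sha256": _sha256(p)} for p in outputs],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest
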