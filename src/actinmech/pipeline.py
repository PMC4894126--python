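"""End-to-end orchestration: config validation, stage execution, reports.

A run is described by a YAML/JSON config (see ``examples/demo.yaml``).
Stages execute in dependency order — simulate first, then the analysis
stages on its outputs — and every artefact (input CSV/XYZ files, result
tables, ``report.json``, ``summary.txt``) lands in the output directory.
Runs are idempotent: the same config and seed reproduce every stochastic
output exactly, and ``report.json`` carries the config hash, derived
seeds and library versions as provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .core import ActinMechError, D_LOOP
from .geometry import (
    D_LOOP_TARGETS,
    TABLE_CONTACTS,
    contact_table,
    count_contacts,
    trajectory_cg_summary,
)
from .io import write_csv_trajectory, write_xyz_trajectory
from .mechanics import (
    estimate_helical_parameters,
    estimate_persistence_length,
)
from .motility import (
    compare_groups,
    fit_mixture,
    summarize,
    threshold_split,
    write_speed_csv,
)
from .simulate import (
    HelixEnsembleParams,
    PeakSimParams,
    SpeedSimParams,
    WLCParams,
    generate_filament_ensemble,
    generate_helix_ensemble,
    generate_peak_profile,
    generate_speed_sample,
    generate_wlc_trajectory,
    synthetic_subunit,
)
from .xray import (
    Calibration,
    fit_gaussian_peak,
    intensity_fold_change,
    spacing_percent_shift,
    subtract_background,
    write_profile_csv,
)

__all__ = ["ConfigError", "PipelineError", "load_config", "run", "demo_config"]

log = logging.getLogger("actinmech")


class ConfigError(ActinMechError):
    """The run configuration failed schema validation."""


class PipelineError(ActinMechError):
    """A pipeline stage failed; the stage name is in the message."""


# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

_ANY = "__any_key__"

_SCHEMA = {
    "seed": None,
    "outdir": None,
    "stages": {
        "simulate": {
            "wlc": {"n_nodes": None, "b": None, "lp_um": None,
                    "n_frames": None, "rho": None},
            "helix": {"n_subunits": None, "rise": None, "twist": None,
                      "radius": None, "sigma_xyz": None, "n_frames": None},
            "filament": {"n_subunits": None, "rise": None, "twist": None,
                         "sigma_xyz": None, "n_frames": None,
                         "n_residues": None},
            "profiles": {_ANY: {"n_pixels": None, "centre": None,
                                "sigma": None, "amplitude": None,
                                "slope": None, "intercept": None,
                                "noise_sd": None, "second": None}},
            "speeds": {_ANY: {"weights": None, "means": None, "sds": None,
                              "n": None}},
        },
        "mechanics": {"k_max": None, "k_star": None, "min_corr": None},
        "geometry": {"cutoff": None, "representation": None, "ddof": None},
        "xray": {"centre_px": None, "windows": None,
                 "flanks": {"left": None, "right": None},
                 "pairs": None, "fold_bands": None},
        "motility": {"threshold": None, "n_restarts": None},
        "stats": {"alpha_normality": None, "compare": None},
    },
}


def _validate(cfg, schema, path=""):
    if schema is None:
        return
    if not isinstance(cfg, dict):
        raise ConfigError(f"config section {path or '<root>'} must be a mapping")
    dynamic = schema.get(_ANY)
    for key, value in cfg.items():
        here = f"{path}.{key}" if path else str(key)
        if key in schema:
            _validate(value, schema[key], here) if isinstance(
                schema[key], dict
            ) else None
        elif dynamic is not None:
            _validate(value, dynamic, here) if isinstance(dynamic, dict) else None
        else:
            raise ConfigError(f"unknown config key {here!r}")


def load_config(path) -> dict:
    """Load and validate a YAML or JSON run configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    _validate(cfg, _SCHEMA)
    return cfg


def _stage_seed(base_seed: int, name: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    digest = hashlib.sha256(f"{base_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# Demo configuration (the shipped end-to-end example)
# --------------------------------------------------------------------------

def demo_config(seed: int = 0, outdir: str = "actinmech_demo") -> dict:
    """The shipped demonstration config: every stage on synthetic data.

    The simulated conditions follow the filament parameters used
    throughout the package: WLC at Lp = 12.21 μm with b = 55 Å, a
    13-subunit helix at 27.5 Å / -166.15° with 0.5 Å thermal noise, a
    narrow (σ≈5.5 px) shifting reflection vs a two-population composite
    with a broad (σ≈9.5 px) static component, and a 58/42 speed mixture
    at 2.5/4.5 μm/s.  Simulation sizes are trimmed for a desk-scale run.
    """
    return {
        "seed": seed,
        "outdir": outdir,
        "stages": {
            "simulate": {
                "wlc": {"n_nodes": 800, "b": 55.0, "lp_um": 12.21,
                        "n_frames": 150, "rho": 0.0},
                "helix": {"n_subunits": 13, "rise": 27.5, "twist": -166.15,
                          "radius": 25.0, "sigma_xyz": 0.5, "n_frames": 200},
                "filament": {"n_subunits": 5, "rise": 27.5, "twist": -166.15,
                             "sigma_xyz": 0.3, "n_frames": 20,
                             "n_residues": 375},
                "profiles": {
                    "wt_rest": {"centre": 100.0, "sigma": 5.5,
                                "amplitude": 1000.0, "slope": -0.5,
                                "intercept": 300.0, "noise_sd": 10.0},
                    "wt_act": {"centre": 98.2, "sigma": 5.5,
                               "amplitude": 1400.0, "slope": -0.5,
                               "intercept": 300.0, "noise_sd": 10.0},
                    "mut_rest": {"centre": 100.0, "sigma": 5.5,
                                 "amplitude": 600.0, "slope": -0.5,
                                 "intercept": 300.0, "noise_sd": 10.0,
                                 "second": [100.5, 9.5, 400.0]},
                    "mut_act": {"centre": 98.2, "sigma": 5.5,
                                "amplitude": 600.0, "slope": -0.5,
                                "intercept": 300.0, "noise_sd": 10.0,
                                "second": [100.5, 9.5, 400.0]},
                },
                "speeds": {
                    "wt": {"weights": [1.0], "means": [2.6], "sds": [0.5],
                           "n": 150},
                    "mut": {"weights": [0.58, 0.42], "means": [2.5, 4.5],
                            "sds": [0.4, 0.4], "n": 150},
                },
            },
            "mechanics": {},
            "geometry": {"cutoff": 8.0, "representation": "ca", "ddof": 0},
            "xray": {
                "centre_px": -900.0,
                "windows": [3, 4],
                "flanks": {"left": [40, 60], "right": [140, 160]},
                "pairs": [
                    {"label": "wt", "rest": "wt_rest", "act": "wt_act"},
                    {"label": "mut", "rest": "mut_rest", "act": "mut_act"},
                ],
                "fold_bands": [
                    {"label": "wt_activation", "a": "wt_rest", "b": "wt_act",
                     "band": [85, 115]},
                ],
            },
            "motility": {"threshold": 3.5, "n_restarts": 8},
            "stats": {
                "alpha_normality": 0.05,
                "compare": [{"label": "wt_vs_mut", "x": "wt", "y": "mut"}],
            },
        },
    }


# --------------------------------------------------------------------------
# Run
# --------------------------------------------------------------------------

@dataclass
class RunReport:
    """All stage results plus provenance for one pipeline run."""

    results: dict
    provenance: dict
    outdir: Path

    def to_json(self) -> str:
        return json.dumps(
            {"results": self.results, "provenance": self.provenance},
            indent=2,
            sort_keys=True,
        )


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def run(config: dict, outdir=None) -> RunReport:
    """Execute the configured stages and write all artefacts.

    Raises :class:`PipelineError` naming the failing stage; partial
    outputs are kept next to a ``FAILED`` marker file.
    """
    cfg = copy.deepcopy(config)
    _validate(cfg, _SCHEMA)
    seed = int(cfg.get("seed", 0))
    out = Path(outdir if outdir is not None else cfg.get("outdir", "actinmech_out"))
    out.mkdir(parents=True, exist_ok=True)
    (out / "inputs").mkdir(exist_ok=True)
    stages = cfg.get("stages", {})
    results: dict = {}
    data: dict = {}
    order = ["simulate", "mechanics", "geometry", "xray", "motility", "stats"]
    try:
        for stage in order:
            if stage not in stages:
                continue
            log.info("running stage %s", stage)
            handler = globals()[f"_stage_{stage}"]
            results[stage] = handler(stages[stage] or {}, seed, data, out)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (out / "FAILED").write_text(f"stage {stage!r} failed: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    provenance = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stage_seeds": {s: _stage_seed(seed, s) for s in stages},
        "versions": {
            "actinmech": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    report = RunReport(results=results, provenance=provenance, outdir=out)
    (out / "report.json").write_text(report.to_json())
    (out / "summary.txt").write_text(_render_summary(results))
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return report


# -- stages ----------------------------------------------------------------

def _stage_simulate(cfg, seed, data, out):
    info = {}
    if "wlc" in cfg:
        c = dict(cfg["wlc"])
        p = WLCParams(
            n_nodes=int(c.get("n_nodes", 800)),
            b=float(c.get("b", 55.0)),
            lp=float(c.get("lp_um", 12.21)) * 1e4,
            n_frames=int(c.get("n_frames", 150)),
            seed=_stage_seed(seed, "wlc"),
            rho=float(c.get("rho", 0.0)),
        )
        data["wlc"] = generate_wlc_trajectory(p)
        write_xyz_trajectory(data["wlc"], out / "inputs" / "wlc.xyz")
        info["wlc"] = {"n_nodes": p.n_nodes, "n_frames": p.n_frames,
                       "b_A": p.b, "lp_um_true": p.lp / 1e4, "seed": p.seed}
    if "helix" in cfg:
        c = dict(cfg["helix"])
        p = HelixEnsembleParams(
            n_subunits=int(c.get("n_subunits", 13)),
            rise=float(c.get("rise", 27.5)),
            twist=float(c.get("twist", -166.15)),
            radius=float(c.get("radius", 25.0)),
            sigma_xyz=float(c.get("sigma_xyz", 0.5)),
            n_frames=int(c.get("n_frames", 200)),
            seed=_stage_seed(seed, "helix"),
        )
        data["helix"] = generate_helix_ensemble(p)
        info["helix"] = {"rise_true_A": p.rise, "twist_true_deg": p.twist,
                         "sigma_xyz_A": p.sigma_xyz, "n_frames": p.n_frames,
                         "seed": p.seed}
    if "filament" in cfg:
        c = dict(cfg["filament"])
        sub = synthetic_subunit(
            seed=_stage_seed(seed, "subunit"),
            n_residues=int(c.get("n_residues", 375)),
        )
        data["filament"] = generate_filament_ensemble(
            sub,
            n_subunits=int(c.get("n_subunits", 5)),
            rise=float(c.get("rise", 27.5)),
            twist=float(c.get("twist", -166.15)),
            sigma_xyz=float(c.get("sigma_xyz", 0.3)),
            n_frames=int(c.get("n_frames", 20)),
            seed=_stage_seed(seed, "filament"),
        )
        write_csv_trajectory(
            data["filament"], out / "inputs" / "filament.csv"
        )
        info["filament"] = {k: c.get(k) for k in c}
    data["profiles"] = {}
    for name, c in (cfg.get("profiles") or {}).items():
        c = dict(c)
        second = c.pop("second", None)
        p = PeakSimParams(
            n_pixels=int(c.get("n_pixels", 201)),
            centre=float(c.get("centre", 100.0)),
            sigma=float(c.get("sigma", 5.0)),
            amplitude=float(c.get("amplitude", 1000.0)),
            slope=float(c.get("slope", 0.0)),
            intercept=float(c.get("intercept", 0.0)),
            noise_sd=float(c.get("noise_sd", 0.0)),
            second=tuple(second) if second else None,
            seed=_stage_seed(seed, f"profile:{name}"),
        )
        prof = generate_peak_profile(p)
        data["profiles"][name] = prof
        write_profile_csv(prof, out / "inputs" / f"profile_{name}.csv")
    data["speeds"] = {}
    for name, c in (cfg.get("speeds") or {}).items():
        p = SpeedSimParams(
            weights=tuple(c["weights"]),
            means=tuple(c["means"]),
            sds=tuple(c["sds"]),
            n=int(c["n"]),
            seed=_stage_seed(seed, f"speeds:{name}"),
        )
        sample = generate_speed_sample(p, label=name)
        data["speeds"][name] = sample
        write_speed_csv(sample, out / "inputs" / f"speeds_{name}.csv")
    return info


def _stage_mechanics(cfg, seed, data, out):
    res = {}
    if "wlc" in data:
        fit = estimate_persistence_length(
            data["wlc"],
            k_max=cfg.get("k_max"),
            k_star=cfg.get("k_star"),
            min_corr=float(cfg.get("min_corr", 0.9)),
        )
        res["persistence_length"] = {
            "lp_um": fit.lp_um,
            "sd_um": fit.sd_um,
            "fit_range": fit.fit_range,
            "n_frames": fit.n_frames_used,
            "beyond_resolvable": fit.beyond_resolvable,
        }
        fit.correlations.to_csv(out / "tangent_correlation.csv", index=False)
        if fit.block_result is not None:
            fit.block_result.as_frame().to_csv(
                out / "lp_block_average.csv", index=False
            )
    if "helix" in data:
        hel = estimate_helical_parameters(data["helix"])
        res["helix"] = {
            "rise_A": hel.rise, "rise_sd_A": hel.rise_sd,
            "twist_deg": hel.twist, "twist_sd_deg": hel.twist_sd,
            "crossover_A": hel.crossover, "crossover_sd_A": hel.crossover_sd,
            "n_frames": hel.n_frames,
        }
        hel.per_frame.to_csv(out / "helix_per_frame.csv", index=False)
    return res


def _stage_geometry(cfg, seed, data, out):
    if "filament" not in data:
        raise ValueError("geometry stage needs a simulated filament ensemble")
    traj = data["filament"]
    rep = cfg.get("representation", "ca")
    ddof = int(cfg.get("ddof", 0))
    cutoff = float(cfg.get("cutoff", 8.0))
    specs = [replace(s, representation=rep) for s in TABLE_CONTACTS]
    contacts = contact_table(traj, specs, ddof=ddof)
    contacts.to_csv(out / "contact_distances.csv", index=False)
    cg = trajectory_cg_summary(traj, representation="ca", ddof=ddof)
    cg.to_csv(out / "cg_geometry.csv", index=False)
    counts = [
        count_contacts(f, D_LOOP, D_LOOP_TARGETS, 2, cutoff, "ca").mean_count
        for f in traj.frames
    ]
    return {
        "contact_table_rows": len(contacts),
        "cg_rows": len(cg),
        "dloop_contact_count_mean": float(np.mean(counts)),
        "dloop_contact_cutoff_A": cutoff,
    }


def _stage_xray(cfg, seed, data, out):
    profiles = data.get("profiles", {})
    if not profiles:
        raise ValueError("xray stage needs simulated profiles")
    calib = Calibration(centre_px=float(cfg.get("centre_px", -900.0)))
    windows = [int(w) for w in cfg.get("windows", [3, 4])]
    flanks = cfg.get("flanks")
    prepared = {}
    for name, prof in profiles.items():
        if flanks:
            prof = subtract_background(
                prof, tuple(flanks["left"]), tuple(flanks["right"])
            )
        prepared[name] = prof
    res = {"fits": {}, "shifts": {}, "fold_changes": {}}
    fits = {}
    for name, prof in prepared.items():
        fits[name] = {}
        for w in windows:
            fit = fit_gaussian_peak(prof, w=w)
            fits[name][w] = fit
            res["fits"][f"{name}_w{w}"] = {
                "mu_px": fit.mu, "sigma_px": fit.sigma,
                "amplitude": fit.amplitude, "asymmetry": fit.asymmetry,
            }
    for pair in cfg.get("pairs") or []:
        for w in windows:
            shift = spacing_percent_shift(
                fits[pair["rest"]][w], fits[pair["act"]][w], calib
            )
            res["shifts"][f"{pair['label']}_w{w}"] = {
                "spacing_change_pct": shift.percent,
                "r_rest_px": shift.r_rest,
                "r_act_px": shift.r_act,
            }
    for band in cfg.get("fold_bands") or []:
        change = intensity_fold_change(
            prepared[band["a"]], prepared[band["b"]], tuple(band["band"])
        )
        res["fold_changes"][band["label"]] = change.fold
    return res


def _stage_motility(cfg, seed, data, out):
    samples = data.get("speeds", {})
    if not samples:
        raise ValueError("motility stage needs simulated speed samples")
    threshold = float(cfg.get("threshold", 3.5))
    n_restarts = int(cfg.get("n_restarts", 10))
    res = {}
    for name, sample in samples.items():
        mean, se, n = summarize(sample)
        split = threshold_split(sample, threshold)
        entry = {
            "mean_um_s": mean, "se_um_s": se, "n": n,
            "fraction_below": split.fraction_below,
            "fraction_above": split.fraction_above,
            "n_ties": split.n_ties,
            "threshold_um_s": threshold,
        }
        for k in (1, 2):
            fit = fit_mixture(
                sample, k, n_restarts=n_restarts,
                seed=_stage_seed(seed, f"em:{name}:{k}"),
            )
            entry[f"k{k}"] = {
                "bic": fit.bic, "loglike": fit.loglike,
                "weights": fit.weights.tolist(),
                "means": fit.means.tolist(),
                "sds": fit.sds.tolist(),
            }
        entry["selected_k"] = 1 if entry["k1"]["bic"] <= entry["k2"]["bic"] else 2
        res[name] = entry
    return res


def _stage_stats(cfg, seed, data, out):
    samples = data.get("speeds", {})
    alpha = float(cfg.get("alpha_normality", 0.05))
    res = {}
    for cmp_cfg in cfg.get("compare") or []:
        x = samples[cmp_cfg["x"]].speeds
        y = samples[cmp_cfg["y"]].speeds
        t = compare_groups(x, y, alpha_normality=alpha)
        res[cmp_cfg["label"]] = {
            "test": t.test, "statistic": t.statistic, "pvalue": t.pvalue,
            "ks_pvalues": list(t.ks_pvalues),
        }
    return res


def _render_summary(results: dict) -> str:
    lines = ["actinmech pipeline summary", "=" * 30]
    mech = results.get("mechanics", {})
    if "persistence_length" in mech:
        p = mech["persistence_length"]
        lines.append(
            f"persistence length: {p['lp_um']:.2f} +/- {p['sd_um']:.2f} um "
            f"(k* = {p['fit_range']}, {p['n_frames']} frames)"
        )
    if "helix" in mech:
        h = mech["helix"]
        lines.append(
            f"helix: rise {h['rise_A']:.3f} +/- {h['rise_sd_A']:.3f} A, "
            f"twist {h['twist_deg']:.3f} +/- {h['twist_sd_deg']:.3f} deg, "
            f"crossover {h['crossover_A']:.2f} +/- {h['crossover_sd_A']:.2f} A"
        )
    if "geometry" in results:
        g = results["geometry"]
        lines.append(
            f"geometry: {g['contact_table_rows']} contact rows, "
            f"{g['cg_rows']} CG rows, D-loop contact count "
            f"{g['dloop_contact_count_mean']:.2f} "
            f"(cutoff {g['dloop_contact_cutoff_A']} A)"
        )
    for label, s in results.get("xray", {}).get("shifts", {}).items():
        lines.append(f"xray shift {label}: {s['spacing_change_pct']:+.3f} %")
    for label, f in results.get("xray", {}).get("fold_changes", {}).items():
        lines.append(f"xray fold change {label}: {f:.3f}")
    for name, m in results.get("motility", {}).items():
        lines.append(
            f"motility {name}: mean {m['mean_um_s']:.2f} +/- {m['se_um_s']:.2f} "
            f"um/s (n={m['n']}), below/above {m['threshold_um_s']} um/s: "
            f"{m['fraction_below']:.2f}/{m['fraction_above']:.2f}, "
            f"BIC-selected k={m['selected_k']}"
        )
    for label, t in results.get("stats", {}).items():
        lines.append(
            f"stats {label}: {t['test']} p = {t['pvalue']:.3g}"
        )
    return "\n".join(lines) + "\n"
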