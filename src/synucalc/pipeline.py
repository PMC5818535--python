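"""End-to-end orchestration: simulate, analyse, and report.

A run config (TOML file or plain dict) selects stages and per-stage
parameters; each stage writes its inputs and outputs under the run
directory and contributes to a combined JSON report that records the
package version, seed and a hash of the fully-resolved config, so reruns
with identical settings produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np

import synucalc
from synucalc import cest, io, ms, nmr_csp, simulate, smlm, tht, vesicles
from synucalc.errors import InputError
from synucalc.smlm import Rect

logger = logging.getLogger(__name__)

STAGES = ("titration", "cest", "storm", "vesicles", "tht", "ms")


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the requested stages; return (and write) the combined report.

    ``config`` keys: ``seed`` (int), ``stages`` (list of stage names),
    and optional per-stage tables with parameter overrides. Inputs may be
    simulated (default) or read from files given as ``<stage>.input``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise InputError(f"unknown stages: {sorted(unknown)}")
    report: dict = {
        "package": "synucalc",
        "version": synucalc.__version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    for stage in stages:
        params = dict(config.get(stage, {}))
        logger.info("running stage %s", stage)
        runner = _RUNNERS[stage]
        report["stages"][stage] = runner(params, seed, out)
    io.write_json(report, out / "report.json")
    return report


def _stage_titration(params: dict, seed: int, out: Path) -> dict:
    if "input" in params:
        series = io.read_peaklist(params["input"], params.get("protein_conc", 200.0))
        truth = None
    else:
        series, truth = simulate.generate_titration(
            seed=seed, preset=params.get("preset", "calcium_binding")
        )
        io.write_peaklist(series, out / "titration.csv")
        io.write_json(truth, out / "titration_truth.json")
    fit = nmr_csp.fit_binding(series)
    table, summary = nmr_csp.fit_report(fit, series)
    table.to_csv(out / "titration_fit.csv", index=False)
    io.write_json(summary, out / "titration_fit.json")
    return summary


def _stage_cest(params: dict, seed: int, out: Path) -> dict:
    if "input_ca" in params and "input_noca" in params:
        df_ca = io.read_cest(params["input_ca"])
        df_no = io.read_cest(params["input_noca"])
    else:
        df_no, _ = simulate.generate_cest(seed=seed, preset="no_ca")
        df_ca, _ = simulate.generate_cest(seed=seed + 1, preset="plus_ca")
        df_no.to_csv(out / "cest_noca.csv", index=False)
        df_ca.to_csv(out / "cest_ca.csv", index=False)
    s_ca = cest.score_profiles(cest.normalize_cest(df_ca))
    s_no = cest.score_profiles(cest.normalize_cest(df_no))
    cest.scores_to_frame(s_ca).to_csv(out / "cest_scores_ca.csv", index=False)
    cest.scores_to_frame(s_no).to_csv(out / "cest_scores_noca.csv", index=False)
    comp = cest.compare_regions(s_ca, s_no)
    io.write_json(comp, out / "cest_regions.json")
    return comp


def _stage_storm(params: dict, seed: int, out: Path) -> dict:
    if "input" in params:
        table = io.read_localizations(params["input"])
    else:
        table, truth = simulate.generate_synaptosome_locs(
            seed=seed, preset=params.get("preset", "clustered")
        )
        table.to_csv(out / "storm_locs.csv", index=False)
        io.write_json(truth, out / "storm_truth.json")
    rois = smlm.segment_rois(
        table,
        linkage=params.get("linkage", 200.0),
        min_locs=params.get("min_locs", 50),
    )
    radii = []
    for i, roi in enumerate(rois):
        res = smlm.cluster_radius(
            roi,
            bin_width=params.get("bin", 10.0),
            n_rand=params.get("nrand", 50),
            seed=seed + i,
        )
        radii.append(
            {"roi": i, "radius_nm": res.radius, "n_points": res.n_points,
             "reliable": res.reliable}
        )
    import pandas as pd

    pd.DataFrame(radii).to_csv(out / "storm_radii.csv", index=False)
    return {"n_rois": len(rois), "radii_nm": [r["radius_nm"] for r in radii]}


def _stage_vesicles(params: dict, seed: int, out: Path) -> dict:
    radius = params.get("radius", 250.0)
    if "input" in params:
        spots = io.read_spots(params["input"])
        dist = vesicles.classify_clusters(spots, radius=radius)
        summary = {"single_field": dist.__dict__}
    else:
        n_fields = int(params.get("n_fields", 5))
        presets = params.get("presets", ["egta", "calcium", "asyn_ca"])
        dists = {}
        for preset in presets:
            reps = []
            for i in range(n_fields):
                spots, _ = simulate.generate_vesicle_field(seed=seed + i, preset=preset)
                reps.append(vesicles.classify_clusters(spots, radius=radius))
            dists[preset] = reps
        vesicles.distribution_frame(dists).to_csv(out / "vesicle_summary.csv", index=False)
        comparison = vesicles.compare_conditions(dists)
        summary = {
            "mean_pct_singles": {
                c: float(np.mean([d.pct_singles for d in reps]))
                for c, reps in dists.items()
            },
            "comparison": comparison,
        }
    io.write_json(summary, out / "vesicles.json")
    return summary


def _stage_tht(params: dict, seed: int, out: Path) -> dict:
    if "input" in params:
        curves = io.read_tht(params["input"])
        conditions = sorted({c.condition for c in curves})
        pool = curves
    else:
        conditions = params.get("presets", ["ca_only", "egta_sv"])
        pool = []
        for i, preset in enumerate(conditions):
            cs, _ = simulate.generate_tht(seed=seed + i, preset=preset)
            pool.extend(cs)
        simulate.tht_to_frame(pool).to_csv(out / "tht.csv", index=False)
    results = {}
    for cond in conditions:
        mean_curve = tht.average_curves(pool, condition=cond)
        fit = tht.fit_fw(mean_curve)
        lag = tht.lag_time_tangent(mean_curve)
        results[cond] = {
            "A0": fit.A0, "k1_per_h": fit.k1, "k2_per_h_per_unit": fit.k2,
            "lag_h": lag.lag, "rss": fit.rss,
        }
    if len(conditions) == 2:
        a, b = conditions
        results["fold_changes"] = {
            "k1": tht.fold_change(results[a]["k1_per_h"], results[b]["k1_per_h"]),
            "k2": tht.fold_change(results[a]["k2_per_h_per_unit"],
                                  results[b]["k2_per_h_per_unit"]),
        }
    io.write_json(results, out / "tht_fits.json")
    return results


def _stage_ms(params: dict, seed: int, out: Path) -> dict:
    protein_mass = params.get("protein_mass", simulate.DEFAULT_PROTEIN_MASS)
    if "input" in params:
        spec = io.read_spectrum(params["input"])
    else:
        spec, truth = simulate.generate_spectrum(
            seed=seed, preset=params.get("preset", "calcium_ladder"),
            protein_mass=protein_mass, noise=params.get("noise", 0.0),
        )
        io.write_json(truth, out / "ms_truth.json")
    species = ms.charge_deconvolve(
        spec,
        mass_range=(protein_mass - 60.0, protein_mass + 12 * ms.CA_MASS_SHIFT),
    )
    n_max = ms.count_stoichiometry(species, protein_mass=protein_mass)
    result = {
        "max_calcium_stoichiometry": n_max,
        "species": [s.__dict__ for s in species],
        "adduct_convention": "each Ca2+ displaces 2 protons; shift 38.063 Da",
    }
    io.write_json(result, out / "ms_stoichiometry.json")
    return result


_RUNNERS = {
    "titration": _stage_titration,
    "cest": _stage_cest,
    "storm": _stage_storm,
    "vesicles": _stage_vesicles,
    "tht": _stage_tht,
    "ms": _stage_ms,
}
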