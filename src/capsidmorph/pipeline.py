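"""Pipeline orchestration: run the analysis stages from one config file.

A single YAML config declares per-stage parameter blocks; every block is
validated against the stage's preconditions before any stage runs, and
unknown keys are rejected (they are almost always typos).  Stage outputs
land under one output directory together with a JSON manifest recording
inputs, parameters, the seed, the package version and SHA-256 checksums
of every output file — rerunning the same config reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import time
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import helical, morphometry, rings, rnaquant, stability, synthetic

log = logging.getLogger("capsidmorph")

STAGES = ("simulate", "geometry", "rings", "lengths", "melt", "rnaquant")

_KNOWN_KEYS = {
    "": {"log_level", "simulate", "geometry", "rings", "lengths", "melt", "rnaquant"},
    "simulate": {"seed", "trajectory", "lengths", "melt", "rnaquant"},
    "geometry": {"params_table", "rna_nt", "nt_per_subunit", "length_rise_label", "axial_pair"},
    "rings": {"contact_threshold"},
    "lengths": {"n_components", "n_restarts", "multiple_rel_tol"},
    "melt": {"mode"},
    "rnaquant": {"mapq", "three_prime_window", "smooth_window"},
}


class ConfigError(ValueError):
    pass


def load_config(path: Union[str, Path]) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    """Reject unknown keys and violated stage preconditions before running."""
    _check_keys(config, "")
    for stage in STAGES:
        block = config.get(stage, {})
        if not isinstance(block, dict):
            raise ConfigError(f"stage block {stage!r} must be a mapping")
        _check_keys(block, stage)
    rq = config.get("rnaquant", {})
    if rq.get("smooth_window", 40) < 1:
        raise ConfigError("rnaquant.smooth_window must be >= 1")
    if not (0 <= rq.get("mapq", 60) <= 60):
        raise ConfigError("rnaquant.mapq must lie in 0..60")
    if rq.get("three_prime_window", 50) < 0:
        raise ConfigError("rnaquant.three_prime_window must be >= 0")
    if config.get("rings", {}).get("contact_threshold", 12.0) <= 0:
        raise ConfigError("rings.contact_threshold must be > 0")
    lengths = config.get("lengths", {})
    if lengths.get("n_components", 1) < 1:
        raise ConfigError("lengths.n_components must be >= 1")
    if config.get("melt", {}).get("mode", "min") not in ("min", "max", "auto"):
        raise ConfigError("melt.mode must be min, max or auto")
    # simulate block: construct the specs now so invalid parameters abort early
    _simulate_specs(config, seed_override=None)


def _check_keys(block: dict, stage: str) -> None:
    unknown = set(block) - _KNOWN_KEYS[stage]
    if unknown:
        where = stage or "top level"
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def demo_config_path() -> Path:
    return Path(importlib.resources.files("capsidmorph") / "data" / "demo.yaml")


def bundled_params_path() -> Path:
    return Path(importlib.resources.files("capsidmorph") / "data" / "helical_params.tsv")


# ---------------------------------------------------------------------------
# Stage implementations.  Each returns {filename: Path} of outputs written.


def _simulate_specs(config: dict, seed_override: int | None):
    sim = config.get("simulate", {})
    seed = int(seed_override if seed_override is not None else sim.get("seed", 0))
    traj_kw = dict(sim.get("trajectory", {}))
    lengths_kw = dict(sim.get("lengths", {}))
    melt_kw = dict(sim.get("melt", {}))
    rq_kw = dict(sim.get("rnaquant", {}))
    if "components" in lengths_kw:
        lengths_kw["components"] = tuple(tuple(c) for c in lengths_kw["components"])
    if "references" in rq_kw:
        rq_kw["references"] = tuple(tuple(r) for r in rq_kw["references"])
    if "composition" in rq_kw:
        rq_kw["composition"] = tuple(rq_kw["composition"])
    if "t_range" in melt_kw:
        melt_kw["t_range"] = tuple(melt_kw["t_range"])
    if "read_length_dist" in rq_kw:
        rq_kw["read_length_dist"] = tuple(rq_kw["read_length_dist"])
    return (
        synthetic.TrajectorySpec(seed=seed, **traj_kw),
        synthetic.LengthMixtureSpec(seed=seed + 1, **lengths_kw)
        if lengths_kw.get("components")
        else None,
        synthetic.MeltCurveSpec(seed=seed + 2, **melt_kw),
        synthetic.AlignmentSimSpec(seed=seed + 3, **rq_kw) if rq_kw.get("references") else None,
    )


def _stage_simulate(config: dict, outdir: Path, seed: int | None) -> dict[str, Path]:
    traj_spec, len_spec, melt_spec, aln_spec = _simulate_specs(config, seed)
    out: dict[str, Path] = {}

    traj = synthetic.gen_ring_trajectory(traj_spec)
    out["trajectory.tsv"] = outdir / "trajectory.tsv"
    synthetic.write_trajectory_tsv(traj, out["trajectory.tsv"])

    if len_spec is not None:
        sample = synthetic.gen_length_sample(len_spec)
        out["lengths.tsv"] = outdir / "lengths.tsv"
        pd.Series(sample.lengths).to_csv(out["lengths.tsv"], sep="\t", index=False, header=False)

    curve = synthetic.gen_melt_curve(melt_spec)
    out["melt.tsv"] = outdir / "melt.tsv"
    pd.DataFrame(
        {"temperature": curve.temperatures, "fluorescence": curve.fluorescence}
    ).to_csv(out["melt.tsv"], sep="\t", index=False)

    if aln_spec is not None:
        refs = aln_spec.reference_set()
        for rep, alns in enumerate(synthetic.gen_read_alignments(aln_spec), start=1):
            out[f"alignments_rep{rep}.tsv"] = outdir / f"alignments_rep{rep}.tsv"
            alns.to_csv(out[f"alignments_rep{rep}.tsv"], sep="\t", index=False)
            out[f"alignments_rep{rep}.sam"] = outdir / f"alignments_rep{rep}.sam"
            synthetic.write_alignments_sam(alns, refs, out[f"alignments_rep{rep}.sam"])
        out["references.tsv"] = outdir / "references.tsv"
        pd.DataFrame(
            [
                {"ref_id": rid, "length": length, "class": refs.class_of(rid)}
                for rid, length in refs.lengths.items()
            ]
        ).to_csv(out["references.tsv"], sep="\t", index=False)
    return out


def _stage_geometry(config: dict, outdir: Path, seed: int | None) -> dict[str, Path]:
    geo = config.get("geometry", {})
    table = geo.get("params_table") or bundled_params_path()
    params = helical.load_helical_params(table)
    report: dict[str, Any] = {"per_class": {}}
    for label, hp in params.items():
        entry = {
            "rise": hp.rise,
            "twist": hp.twist,
            "cyclic_symmetry": hp.cyclic_symmetry,
            "handedness": hp.handedness,
            "architecture": helical.classify_architecture(hp),
        }
        if hp.twist != 0:
            entry["units_per_turn"] = helical.units_per_turn(hp)
            entry["pitch"] = helical.pitch(hp)
        report["per_class"][label] = entry
    rise_label = geo.get("length_rise_label")
    if geo.get("rna_nt") and rise_label in params:
        pred = helical.expected_filament_length(
            int(geo["rna_nt"]), geo.get("nt_per_subunit", 5), params[rise_label].rise
        )
        report["length_prediction"] = {
            "n_nt": pred.n_nt,
            "nt_per_subunit": pred.nt_per_subunit,
            "rise": pred.rise,
            "n_subunits": pred.n_subunits,
            "length_nm": pred.length_nm,
            "length_nm_rounded": pred.length_nm_rounded,
        }
    pair = geo.get("axial_pair")
    if pair and all(p in params for p in pair):
        diff = helical.axial_repeat_difference(params[pair[0]], params[pair[1]])
        report["axial_repeat_difference"] = {
            "pair": list(pair),
            "signed": diff.signed,
            "magnitude_rounded": diff.magnitude_rounded,
        }
    out = outdir / "geometry.json"
    out.write_text(json.dumps(report, indent=2, sort_keys=True))
    return {"geometry.json": out}


def _stage_rings(config: dict, outdir: Path, seed: int | None) -> dict[str, Path]:
    threshold = config.get("rings", {}).get("contact_threshold", rings.DEFAULT_CONTACT_THRESHOLD)
    traj = synthetic.read_trajectory_tsv(outdir / "trajectory.tsv")
    trips = rings.triplet_time_series(traj, threshold)
    summary = rings.frame_summary(traj, threshold)
    t_out = outdir / "triplets.tsv"
    s_out = outdir / "ring_summary.tsv"
    trips.to_csv(t_out, sep="\t", index=False)
    summary.to_csv(s_out, sep="\t", index=False)
    return {"triplets.tsv": t_out, "ring_summary.tsv": s_out}


def _stage_lengths(config: dict, outdir: Path, seed: int | None) -> dict[str, Path]:
    block = config.get("lengths", {})
    sample = morphometry.sample_from_tsv(outdir / "lengths.tsv")
    fit = morphometry.fit_gaussian_mixture(
        sample,
        K=block.get("n_components", 1),
        n_restarts=block.get("n_restarts", 5),
        seed=int(seed if seed is not None else 0),
    )
    report = {
        "summary": morphometry.length_summary(sample),
        "fit": {
            "K": fit.K,
            "weights": fit.weights.tolist(),
            "means": fit.means.tolist(),
            "sds": fit.sds.tolist(),
            "log_likelihood": fit.log_likelihood,
            "converged": fit.converged,
        },
    }
    if fit.K >= 2:
        multiples = morphometry.check_peak_multiples(fit, block.get("multiple_rel_tol", 0.12))
        report["peak_multiples"] = multiples.to_dict("records")
    comp_out = outdir / "length_components.tsv"
    fit.components().to_csv(comp_out, sep="\t", index=False)
    json_out = outdir / "lengths.json"
    json_out.write_text(json.dumps(report, indent=2, sort_keys=True))
    return {"lengths.json": json_out, "length_components.tsv": comp_out}


def _stage_melt(config: dict, outdir: Path, seed: int | None) -> dict[str, Path]:
    mode = config.get("melt", {}).get("mode", "min")
    table = pd.read_csv(outdir / "melt.tsv", sep="\t")
    curve = stability.MeltCurve(
        temperatures=table["temperature"].to_numpy(),
        fluorescence=table["fluorescence"].to_numpy(),
    )
    result = stability.compute_tm(curve, mode=mode)
    out = outdir / "melt.json"
    out.write_text(
        json.dumps(
            {"tm": result.tm, "mode": result.mode, "at_boundary": result.at_boundary},
            indent=2,
        )
    )
    return {"melt.json": out}


def _stage_rnaquant(config: dict, outdir: Path, seed: int | None) -> dict[str, Path]:
    block = config.get("rnaquant", {})
    ref_table = pd.read_csv(outdir / "references.tsv", sep="\t")
    refs = rnaquant.ReferenceSet(
        lengths=dict(zip(ref_table["ref_id"], ref_table["length"].astype(int))),
        classes=dict(zip(ref_table["ref_id"], ref_table["class"])),
    )
    reps = [
        rnaquant.read_alignments_tsv(outdir / f"alignments_rep{i}.tsv") for i in (1, 2)
    ]
    result = rnaquant.quantify_replicates(
        reps,
        refs,
        mapq=block.get("mapq", 60),
        three_prime_window=block.get("three_prime_window", 50),
        smooth_window=block.get("smooth_window", 40),
    )
    quant = pd.DataFrame(
        {
            "count_rep1": result.counts[0],
            "count_rep2": result.counts[1],
            "tpm_rep1": result.tpm[0],
            "tpm_rep2": result.tpm[1],
        }
    )
    quant = quant.join(result.adjusted.add_prefix("adjusted_"), how="left")
    q_out = outdir / "quant.tsv"
    quant.rename_axis("ref_id").to_csv(q_out, sep="\t")
    cls_out = outdir / "class_percent.json"
    cls_out.write_text(json.dumps(result.bp_percent, indent=2, sort_keys=True))
    raw_bg = outdir / "coverage_raw.bedgraph"
    norm_bg = outdir / "coverage_norm.bedgraph"
    rnaquant.write_bedgraph(result.coverage_raw, raw_bg)
    rnaquant.write_bedgraph(result.coverage_norm, norm_bg)
    smooth_out = outdir / "coverage_smooth.tsv"
    with open(smooth_out, "w") as fh:
        fh.write("ref_id\tposition\tsmoothed\n")
        for rid, track in result.coverage_smooth.items():
            for pos, val in enumerate(track):
                fh.write(f"{rid}\t{pos}\t{val:.6g}\n")
    return {
        "quant.tsv": q_out,
        "class_percent.json": cls_out,
        "coverage_raw.bedgraph": raw_bg,
        "coverage_norm.bedgraph": norm_bg,
        "coverage_smooth.tsv": smooth_out,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "geometry": _stage_geometry,
    "rings": _stage_rings,
    "lengths": _stage_lengths,
    "melt": _stage_melt,
    "rnaquant": _stage_rnaquant,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(
    config: Union[dict, str, Path],
    subcommand: str = "all",
    outdir: Union[str, Path] = "capsidmorph_out",
    seed: int | None = None,
) -> dict:
    """Run one stage (or ``all``) and return the manifest.

    Stage outputs are written under ``outdir``; the manifest (also written
    to ``outdir/manifest.json``, appending to earlier stage entries) maps
    each stage to its parameters and output checksums.
    """
    if subcommand not in STAGES and subcommand != "all":
        raise ValueError(f"unknown subcommand {subcommand!r}")
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if subcommand == "all" else [subcommand]
    required_inputs = {
        "rings": ["trajectory.tsv"],
        "lengths": ["lengths.tsv"],
        "melt": ["melt.tsv"],
        "rnaquant": ["alignments_rep1.tsv", "alignments_rep2.tsv", "references.tsv"],
    }
    if subcommand in required_inputs:
        missing = [f for f in required_inputs[subcommand] if not (outdir / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"stage {subcommand!r} inputs missing from {outdir}: {missing}; "
                "run 'simulate' first or point --outdir at existing stage outputs"
            )

    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "version": __version__,
        "stages": {},
    }
    for stage in stages:
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](config, outdir, seed)
        elapsed = time.perf_counter() - t0
        log.info("stage %s: %d output(s) in %.2f s", stage, len(outputs), elapsed)
        manifest["stages"][stage] = {
            "parameters": config.get(stage, {}),
            "seed": seed if seed is not None else config.get("simulate", {}).get("seed", 0),
            "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
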