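"""End-to-end orchestration: simulate -> segment -> stage -> score -> analyze.

A single YAML config drives all stages; per-stage and per-subject seeds are
derived from one master seed through ``numpy.random.SeedSequence`` spawn
keys, so every stage is independently reproducible.  Each stage writes its
outputs under the run directory and is skipped on resume when they already
exist (unless an upstream stage re-ran); the run manifest records the config
snapshot, seeds, software version, SHA-256 of every output file, and
wall-clock time per stage.  Images are written as uncompressed NIfTI so
byte-level hashes are reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cognition, dc_segment, lesion_volumes, phantom
from . import longitudinal_stats as lstats
from .imaging_io import read_channel, read_mask, write_channel, write_mask
from .phantom import TISSUES

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "volumes", "cognition", "analyze")

DEFAULT_CONFIG = {
    "master_seed": 0,
    "cohort": {"n_subjects": 8},
    "phantom": {
        "grid_shape": [64, 64, 16],
        "voxel_size_mm": [2.0, 2.0, 6.0],
        "noise_sigma": 4.0,
        "bias_field_amplitude": 0.05,
        "n_lesion_foci_range": [3, 8],
        "core_radius_range_mm": [5.0, 8.0],
        "rim_width_mm": 4.0,
        "growth_rate_mm_per_year": 1.5,
        "n_visits": 4,
    },
    "segmentation": {
        "k": 4,
        "lambda_label": 10.0,
        "confidence_fraction": 0.10,
        "max_iter": 100,
        "tol": 1e-4,
    },
    "staging": {"k_sd": 2.5, "min_component_voxels": 5},
    "cognition": {
        "effect_main": -0.15,
        "effect_interaction": -0.05,
        "dropout_rate_last_visit": 0.28,
        "subtest_noise_sd": 0.4,
    },
    "analysis": {
        "predictors": ["V_DC33", "V_DC66", "V_DC100"],
        "outcomes": [
            "mmse_total", "vadas_total",
            "compound_speed", "compound_executive", "compound_memory",
        ],
        "adjust_vflair": [False, True],
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master_seed: int, stage: str, subject: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(STAGES.index(stage), subject))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage, outputs, wall_clock_s, skipped):
        self.stages[stage] = {
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "wall_clock_s": wall_clock_s,
            "skipped": skipped,
        }

    def output_hashes(self) -> dict:
        out = {}
        for st in self.stages.values():
            out.update(st["outputs"])
        return out

    def hash_equal(self, other: "RunManifest", root_a=None, root_b=None) -> bool:
        a = self.output_hashes()
        b = other.output_hashes()
        if root_a and root_b:
            a = {str(Path(k).relative_to(root_a)): v for k, v in a.items()}
            b = {str(Path(k).relative_to(root_b)): v for k, v in b.items()}
        return a == b

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "master_seed": self.master_seed,
                 "version": self.version, "stages": self.stages},
                fh, indent=2, default=str,
            )


def _subject_ids(n):
    return [f"S{i:04d}" for i in range(n)]


def _expected_outputs(cfg, out: Path) -> dict:
    n = cfg["cohort"]["n_subjects"]
    nv = cfg["phantom"]["n_visits"]
    subs = _subject_ids(n)
    exp = {s: [] for s in STAGES}
    for sid in subs:
        sd = out / "subjects" / sid
        exp["simulate"].append(sd / "truth.json")
        for v in range(nv):
            vd = sd / f"visit{v}"
            for ch in ("flair", "t2", "mt"):
                exp["simulate"].append(vd / f"{ch}.nii")
            exp["simulate"].append(vd / "mask.nii")
            exp["simulate"].append(vd / "truth_lesion_fraction.nii")
            for t in TISSUES:
                exp["segment"].append(vd / f"prob_{t.lower()}.nii")
            exp["segment"].append(vd / "segmentation_report.json")
            exp["volumes"].append(vd / "categories.nii")
            exp["volumes"].append(vd / "flair_lesion_mask.nii")
    exp["volumes"] += [out / "volumes.csv", out / "progression.csv"]
    exp["cognition"] += [out / "cognition.csv", out / "compounds.csv",
                         out / "data_dictionary.json"]
    exp["analyze"] += [out / "merged.csv", out / "model_grid.csv",
                       out / "model_details.json", out / "phantom_evaluation.json"]
    return exp


def _run_simulate(cfg, out: Path):
    n = cfg["cohort"]["n_subjects"]
    ph = cfg["phantom"]
    for i, sid in enumerate(_subject_ids(n)):
        ss = _stage_seed(cfg["master_seed"], "simulate", i)
        rng = np.random.default_rng(ss)
        n_foci = int(rng.integers(ph["n_lesion_foci_range"][0],
                                  ph["n_lesion_foci_range"][1] + 1))
        core = float(rng.uniform(*ph["core_radius_range_mm"]))
        pc = phantom.PhantomConfig(
            grid_shape=tuple(ph["grid_shape"]),
            voxel_size_mm=tuple(ph["voxel_size_mm"]),
            noise_sigma=ph["noise_sigma"],
            bias_field_amplitude=ph["bias_field_amplitude"],
            n_lesion_foci=n_foci,
            focus_core_radius_mm=core,
            rim_width_mm=ph["rim_width_mm"],
            growth_rate_mm_per_year=ph["growth_rate_mm_per_year"],
            n_visits=ph["n_visits"],
            rng_seed=_seed_int(ss),
        )
        volumes, truth = phantom.generate_longitudinal_phantom(pc)
        sd = out / "subjects" / sid
        for v, msv in enumerate(volumes):
            vd = sd / f"visit{v}"
            write_channel(msv.get_channel("FLAIR"), vd / "flair.nii")
            write_channel(msv.get_channel("T2"), vd / "t2.nii")
            write_channel(msv.get_channel("MT"), vd / "mt.nii")
            write_mask(msv.brain_mask, msv.voxel_size_mm, msv.affine, vd / "mask.nii")
            frac = truth.fraction_maps[v]["LESION"]
            write_channel(
                phantom.ChannelImage(frac, msv.voxel_size_mm, msv.affine, "FLAIR"),
                vd / "truth_lesion_fraction.nii",
            )
        with open(sd / "truth.json", "w") as fh:
            json.dump({
                "true_volumes_cm3": truth.true_volumes.tolist(),
                "n_foci": n_foci,
                "core_radius_mm": core,
                "foci": [
                    {"center_mm": list(f["center_mm"]),
                     "core_radius_mm": f["core_radius_mm"]}
                    for f in truth.lesion_foci
                ],
            }, fh, indent=2)


def _load_msv(vd: Path):
    from .imaging_io import assemble_multispectral
    chans = [
        read_channel(vd / "flair.nii", "FLAIR"),
        read_channel(vd / "t2.nii", "T2"),
        read_channel(vd / "mt.nii", "MT"),
    ]
    mask = read_mask(vd / "mask.nii")
    return assemble_multispectral(chans, mask)


def _run_segment(cfg, out: Path):
    n = cfg["cohort"]["n_subjects"]
    nv = cfg["phantom"]["n_visits"]
    sg = cfg["segmentation"]
    for i, sid in enumerate(_subject_ids(n)):
        seed = _seed_int(_stage_seed(cfg["master_seed"], "segment", i))
        for v in range(nv):
            vd = out / "subjects" / sid / f"visit{v}"
            msv = _load_msv(vd)
            tpm, model, seeds = dc_segment.segment_volume(
                msv, K=sg["k"], lambda_label=sg["lambda_label"],
                confidence_fraction=sg["confidence_fraction"],
                max_iter=sg["max_iter"], tol=sg["tol"], seed=seed,
            )
            for t in TISSUES:
                write_channel(
                    phantom.ChannelImage(
                        tpm.to_volume(t), msv.voxel_size_mm, msv.affine, "FLAIR"
                    ),
                    vd / f"prob_{t.lower()}.nii",
                )
            sizes = np.bincount(model.assignments, minlength=model.K)
            with open(vd / "segmentation_report.json", "w") as fh:
                json.dump({
                    "objective_trace": model.objective_trace,
                    "n_iter": model.n_iter,
                    "converged": model.converged,
                    "temperature": model.temperature,
                    "cluster_sizes": sizes.tolist(),
                    "n_seeds": int(seeds.rows.size),
                    "seed_fraction": seeds.confidence_fraction,
                }, fh, indent=2)


def _load_tpm(vd: Path):
    probs_vols = [read_channel(vd / f"prob_{t.lower()}.nii", "FLAIR").data
                  for t in TISSUES]
    mask = read_mask(vd / "mask.nii")
    idx = np.argwhere(mask)
    probs = np.column_stack([pv[mask] for pv in probs_vols])
    ref = read_channel(vd / "flair.nii", "FLAIR")
    return dc_segment.TissueProbabilityMap(
        probs=probs, voxel_indices=idx, grid_shape=mask.shape,
        voxel_size_mm=ref.voxel_size_mm, affine=ref.affine,
    )


def _run_volumes(cfg, out: Path):
    n = cfg["cohort"]["n_subjects"]
    nv = cfg["phantom"]["n_visits"]
    st = cfg["staging"]
    vol_rows, prog_rows = [], []
    for sid in _subject_ids(n):
        cats = []
        tpm0 = None
        for v in range(nv):
            vd = out / "subjects" / sid / f"visit{v}"
            tpm = _load_tpm(vd)
            if v == 0:
                tpm0 = tpm
            cat = lesion_volumes.categorize_voxels(tpm)
            cats.append(cat)
            flair = read_channel(vd / "flair.nii", "FLAIR")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fl_mask = lesion_volumes.segment_flair_conventional(
                    flair, cat.mask, k_sd=st["k_sd"],
                    min_component_voxels=st["min_component_voxels"],
                )
            write_mask(fl_mask, flair.voxel_size_mm, flair.affine,
                       vd / "flair_lesion_mask.nii")
            write_channel(
                phantom.ChannelImage(cat.codes.astype(float),
                                     flair.voxel_size_mm, flair.affine, "FLAIR"),
                vd / "categories.nii",
            )
            vs = lesion_volumes.compute_volumes(cat, fl_mask)
            vol_rows.append({
                "subject_id": sid, "visit_year": v,
                "V_DC33": vs.V_DC33, "V_DC66": vs.V_DC66,
                "V_DC100": vs.V_DC100, "V_DCHARD": vs.V_DCHARD,
                "V_FLAIR": vs.V_FLAIR,
                "dice_flair_dchard": vs.dice_flair_dchard,
            })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prog = lesion_volumes.progression_overlap(cats[0], cats[-1], tpm0)
        prog_rows.append({
            "subject_id": sid,
            "n_dc33_baseline": prog.n_dc33_baseline,
            "fraction_dc33_to_lesion": prog.fraction_dc33_to_lesion,
            "chance_rate": prog.chance_rate,
            "enrichment": prog.enrichment,
        })
    pd.DataFrame(vol_rows).to_csv(out / "volumes.csv", index=False)
    pd.DataFrame(prog_rows).to_csv(out / "progression.csv", index=False)


def _run_cognition(cfg, out: Path):
    n = cfg["cohort"]["n_subjects"]
    cg = cfg["cognition"]
    true_vols = []
    for sid in _subject_ids(n):
        with open(out / "subjects" / sid / "truth.json") as fh:
            true_vols.append(json.load(fh)["true_volumes_cm3"][0])
    ss = _stage_seed(cfg["master_seed"], "cognition", 0)
    sim = phantom.CognitionSimConfig(
        n_subjects=n,
        effect_main=cg["effect_main"],
        effect_interaction=cg["effect_interaction"],
        dropout_rate_last_visit=cg["dropout_rate_last_visit"],
        subtest_noise_sd=cg["subtest_noise_sd"],
        n_visits=cfg["phantom"]["n_visits"],
        rng_seed=_seed_int(ss),
    )
    vols = np.maximum(np.asarray(true_vols), 1e-3)
    df = phantom.generate_cohort_cognition(vols, sim)
    df.to_csv(out / "cognition.csv", index=False)
    scored, norms = cognition.score_cohort(df)
    scored.to_csv(out / "compounds.csv", index=False)
    with open(out / "data_dictionary.json", "w") as fh:
        json.dump({
            "subject_id": "subject identifier",
            "visit_year": "assessment year (0 = baseline)",
            "age_baseline": "age at baseline (years)",
            "sex": "F or M",
            "education": "education (years)",
            "lesion_volume_cm3": "true baseline lesion volume (cm^3)",
            "compound_speed": "speed/motor compound (baseline z-units)",
            "compound_executive": "executive compound (baseline z-units)",
            "compound_memory": "memory compound (baseline z-units)",
            "mmse_total": "MMSE total (0-30)",
            "vadas_total": "VADAS-cog total (higher = worse)",
            "baseline_norms": norms.table,
        }, fh, indent=2)


def _run_analyze(cfg, out: Path):
    n = cfg["cohort"]["n_subjects"]
    nv = cfg["phantom"]["n_visits"]
    vols = pd.read_csv(out / "volumes.csv")
    base = vols[vols["visit_year"] == 0][
        ["subject_id", "V_DC33", "V_DC66", "V_DC100", "V_DCHARD", "V_FLAIR"]
    ]
    compounds = pd.read_csv(out / "compounds.csv")
    merged = compounds.merge(base, on="subject_id", how="left")
    merged.to_csv(out / "merged.csv", index=False)

    an = cfg["analysis"]
    grid = lstats.run_model_grid(
        merged,
        predictors=an["predictors"],
        outcomes=an["outcomes"],
        adjust_vflair=an["adjust_vflair"],
    )
    grid.to_csv(out / "model_grid.csv", index=False)

    details = {}
    for pred in an["predictors"]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = lstats.fit_and_test(
                    merged,
                    lstats.ModelSpec(outcome="compound_executive", predictor=pred),
                )
            details[pred] = {
                "fixed_effects": res.fixed_effects.to_dict(orient="records"),
                "sigma_hat": res.sigma_hat.tolist(),
                "reml_loglik": float(res.reml_loglik),
                "converged": bool(res.converged),
            }
        except Exception as exc:
            details[pred] = {"error": str(exc)}
    with open(out / "model_details.json", "w") as fh:
        json.dump(details, fh, indent=2)

    # phantom-evaluation report on the first subject
    sid = _subject_ids(n)[0]
    vd0 = out / "subjects" / sid / "visit0"
    tpm0 = _load_tpm(vd0)
    truth_frac = read_channel(vd0 / "truth_lesion_fraction.nii", "FLAIR").data
    p_lesion = tpm0.to_volume("LESION")
    rim = (truth_frac > 0.05) & (truth_frac < 0.95)
    if rim.sum() > 2:
        r = float(np.corrcoef(truth_frac[rim], p_lesion[rim])[0, 1])
    else:
        r = float("nan")
    cat0 = lesion_volumes.categorize_voxels(tpm0)
    dice_truth = lesion_volumes.dice(cat0.hard_lesion_mask, truth_frac > 0.5)
    prog = pd.read_csv(out / "progression.csv")
    with open(out / "phantom_evaluation.json", "w") as fh:
        json.dump({
            "subject": sid,
            "dice_dc_hard_vs_truth": dice_truth,
            "pv_recovery_pearson_r": r,
            "median_progression_enrichment": float(
                np.nanmedian(prog["enrichment"].replace(np.inf, np.nan))
            ),
            "n_subjects": n, "n_visits": nv,
        }, fh, indent=2)


_STAGE_FUNCS = {
    "simulate": _run_simulate,
    "segment": _run_segment,
    "volumes": _run_volumes,
    "cognition": _run_cognition,
    "analyze": _run_analyze,
}


def run_pipeline(config, out_dir, master_seed: int = None, resume: bool = True) -> RunManifest:
    """Execute all stages in order, with caching and a hashed manifest.

    ``config`` may be a dict or a YAML path.  A stage is skipped when all its
    expected outputs already exist and no upstream stage re-ran.  Stage
    failures abort with the stage name; earlier outputs are preserved.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else copy.deepcopy(cfg_dict(config))
    if master_seed is not None:
        cfg["master_seed"] = int(master_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)

    manifest = RunManifest(config=cfg, master_seed=cfg["master_seed"])
    expected = _expected_outputs(cfg, out)
    upstream_ran = False
    for stage in STAGES:
        outputs = expected[stage]
        have_all = all(Path(p).exists() for p in outputs)
        skip = resume and have_all and not upstream_ran
        t0 = time.perf_counter()
        if not skip:
            logger.info("running stage %s", stage)
            try:
                _STAGE_FUNCS[stage](cfg, out)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            upstream_ran = True
        else:
            logger.info("stage %s: outputs present, skipped", stage)
        manifest.record(stage, outputs, time.perf_counter() - t0, skip)
    manifest.save(out / "manifest.json")
    return manifest


def cfg_dict(config) -> dict:
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg
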