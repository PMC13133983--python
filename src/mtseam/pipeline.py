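"""End-to-end pipeline orchestration.

Stages between the external refinement steps are independent entry points;
``run_pipeline`` chains them in processing order on a synthetic dataset so
the whole metadata path — pick repair, architecture smoothing, angle
unification, symmetry expansion, register merging, seam finding and
un-expansion — can be exercised and validated without microscope data.

Each stage writes its output table (STAR) and a JSON summary (record
counts, parameters, seed) into the run directory; the returned dict
aggregates the summaries.  Every source of randomness derives from the
single configured seed, so a re-run with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import unify_phi, unify_psi
from .classes import assign_filament_architecture, regroup_stretches, smooth_classes
from .expand import shift_register, symmetry_expand, unexpand_at_seam
from .lattice import HelicalArchitecture, derive_symmetry, wrap_angle
from .particles import (
    REGISTER_A,
    REGISTER_B,
    ParticleTable,
    write_star,
)
from .seam import find_seams, seam_table
from .simulate import make_micrograph_picks
from .trace import trace_extend

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = dict(
    seed=1,
    lattice=dict(n_pf=14, n_starts=3, monomer_repeat_A=41.0),
    simulate=dict(
        n_micrographs=2,
        n_filaments=3,
        field_px=4096,
        spacing_A=82.0,
        pixel_size=1.0,
        jitter_px=1.0,
        dropout_frac=0.15,
        id_swap_frac=0.10,
        class_error=0.15,
        psi_noise_deg=2.0,
        psi_outlier_frac=0.05,
        phi_line_noise_deg=3.0,
        register_flip_rate=0.10,
    ),
    trace=dict(diameter_A=360.0, max_psi_jump_deg=10.0, quad_fallback_frac=0.10),
    smooth=dict(window=7, stretch_frac=0.70),
    angles=dict(psi_window_deg=10.0, n_phi_rounds=2),
    register=dict(shift_A=41.0),
)


def _merge_config(base: dict, override: dict | None) -> dict:
    out = {}
    for key, val in base.items():
        if isinstance(val, dict):
            out[key] = _merge_config(val, (override or {}).get(key))
        else:
            out[key] = val
    for key, val in (override or {}).items():
        if key not in out:
            out[key] = val
        elif not isinstance(out[key], dict):
            out[key] = val
    return out


def _simulate_dataset(cfg: dict, rng: np.random.Generator):
    """Synthetic picks for several micrographs, plus per-pick ground truth.

    Classes, angle scatter and seam registers are planted later, each at the
    pipeline position where the real pipeline would receive them from an
    external refinement.
    """
    sim = cfg["simulate"]
    tables, truths = [], []
    for m in range(sim["n_micrographs"]):
        tab, truth = make_micrograph_picks(
            n_filaments=sim["n_filaments"],
            field_px=sim["field_px"],
            spacing_A=sim["spacing_A"],
            pixel_size=sim["pixel_size"],
            jitter_px=sim["jitter_px"],
            dropout_frac=sim["dropout_frac"],
            id_swap_frac=sim["id_swap_frac"],
            seed=int(rng.integers(2**31 - 1)),
            micrograph_id=f"synthetic_{m:06d}.mrc",
        )
        truth["micrograph_id"] = f"synthetic_{m:06d}.mrc"
        tables.append(tab.df)
        truths.append(truth)
    table = ParticleTable(
        pd.concat(tables, ignore_index=True).assign(
            particle_id=lambda d: np.arange(len(d))
        ),
        provenance="simulate",
    )
    return table, pd.concat(truths, ignore_index=True)


def _plant_classes(table: ParticleTable, cfg: dict, rng: np.random.Generator):
    """Per-filament true architecture class with misclassification noise."""
    df = table.df
    err = cfg["simulate"]["class_error"]
    true_class = {}
    class_ids = [1, 2]  # two candidate architectures is enough structure
    for i, (key, _) in enumerate(df.groupby(["micrograph_id", "filament_id"], sort=True)):
        true_class[key] = class_ids[0] if rng.uniform() < 0.8 else class_ids[1]
    labels = []
    for _, row in df.iterrows():
        c = true_class[(row["micrograph_id"], row["filament_id"])]
        if rng.uniform() < err:
            c = class_ids[1] if c == class_ids[0] else class_ids[0]
        labels.append(c)
    df["class_id"] = pd.array(labels, dtype="Int64")
    return ParticleTable(df), true_class


def _plant_angle_noise(table: ParticleTable, cfg: dict, rng: np.random.Generator, n_pf: int):
    """Scatter psi with outliers and phi over the N-line family, with truth."""
    sim = cfg["simulate"]
    df = table.order_along_filaments().df
    psi_true = df["psi"].to_numpy(float).copy()
    psi = psi_true + rng.normal(0, sim["psi_noise_deg"], len(df))
    outl = rng.uniform(size=len(df)) < sim["psi_outlier_frac"]
    psi[outl] = rng.uniform(-180, 180, outl.sum())
    df["psi"] = wrap_angle(psi)
    period = 360.0 / n_pf
    phi0 = {}
    for key, grp in df.groupby(["micrograph_id", "filament_id"], sort=True):
        phi0[key] = float(rng.uniform(0, period))
        j = rng.integers(0, n_pf, len(grp))
        phi = phi0[key] + j * period + rng.normal(0, sim["phi_line_noise_deg"], len(grp))
        df.loc[grp.index, "rot"] = wrap_angle(phi)
    return ParticleTable(df), psi_true, phi0


def _plant_registers(expanded: ParticleTable, cfg: dict, rng: np.random.Generator, n_pf: int):
    """Planted per-microtubule seam with register-classification noise."""
    df = expanded.df
    flip = cfg["simulate"]["register_flip_rate"]
    seams = {}
    regs = np.empty(len(df), dtype=object)
    for key, grp in df.groupby(["micrograph_id", "filament_id"], sort=True):
        seam = int(rng.integers(0, n_pf))
        seams[(key[0], int(key[1]))] = seam
        k = grp["pf_index"].to_numpy(dtype=int)
        r = np.where(k < seam, REGISTER_A, REGISTER_B)
        flipped = rng.uniform(size=len(r)) < flip
        r[flipped] = np.where(r[flipped] == REGISTER_A, REGISTER_B, REGISTER_A)
        regs[grp.index.to_numpy()] = r
    df["register"] = regs
    return ParticleTable(df), seams


STAGE_ORDER = (
    "simulate",
    "trace_extend",
    "smooth_classes",
    "unify_psi",
    "unify_phi",
    "expand",
    "register_merge",
    "seam_find",
    "unexpand",
)


class PipelineInputError(RuntimeError):
    """A stage was requested without the artifact it consumes."""

    def __init__(self, stage: str, artifact: str):
        super().__init__(f"stage {stage!r}: missing input, expected {artifact}")
        self.stage = stage
        self.artifact = artifact


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "pipeline_out",
    strict: bool = False,
) -> dict:
    """Run the synthetic end-to-end pipeline; returns the aggregate report.

    Stage order: simulate -> trace-extend -> smooth-classes -> unify-psi ->
    unify-phi -> expand -> register-merge -> seam-find -> unexpand.  Inputs
    that the real pipeline receives from external refinements (class labels,
    angle scatter, register labels) are planted at the corresponding stage
    boundaries with configured noise, and the planted truth is written as
    sidecar CSVs so closure can be verified.

    ``config['stages']`` selects a subset in canonical order (default: all;
    an empty list is a no-op that still writes the report).  A requested
    stage whose input-producing stage was not run raises
    :class:`PipelineInputError` naming the stage and the missing artifact.
    With ``strict=True`` per-stage conservation rules are asserted.
    """
    cfg = _merge_config(DEFAULT_CONFIG, config)
    requested = cfg.get("stages")
    if requested is None:
        requested = list(STAGE_ORDER)
    unknown = [s for s in requested if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid: {list(STAGE_ORDER)}")
    requested = [s for s in STAGE_ORDER if s in requested]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg["seed"])
    report: dict = {"config": cfg, "stages": {}, "stage_list": requested}

    arch = HelicalArchitecture(
        cfg["lattice"]["n_pf"], cfg["lattice"]["n_starts"], cfg["lattice"]["monomer_repeat_A"]
    )
    sym = derive_symmetry(arch)
    n_pf = arch.n_protofilaments
    state: dict = {}

    def record(stage: str, table: ParticleTable, **extra):
        write_star(table, out / f"{stage}.star")
        summary = dict(n_records=len(table), **extra)
        report["stages"][stage] = summary
        (out / f"{stage}.json").write_text(json.dumps(summary, indent=2, default=str))
        logger.info("stage %s: %d records", stage, len(table))

    def need(stage: str, key: str, artifact: str):
        if key not in state:
            raise PipelineInputError(stage, artifact)
        return state[key]

    def st_simulate():
        table, truth = _simulate_dataset(cfg, rng)
        truth.to_csv(out / "truth_picks.csv", index=False)
        state["table"] = table
        record("simulate", table, seed=cfg["seed"])

    def st_trace_extend():
        table = need("trace_extend", "table", "particle table (simulate output)")
        n_in = len(table)
        table = trace_extend(
            table,
            field_px=cfg["simulate"]["field_px"],
            spacing_A=cfg["simulate"]["spacing_A"],
            diameter_A=cfg["trace"]["diameter_A"],
            max_psi_jump_deg=cfg["trace"]["max_psi_jump_deg"],
            quad_fallback_frac=cfg["trace"]["quad_fallback_frac"],
        )
        if strict and len(table) < n_in:
            raise AssertionError("trace_extend lost records")
        state["table"] = table
        record("trace_extend", table, n_input=n_in)

    def st_smooth_classes():
        table = need("smooth_classes", "table", "particle table (trace_extend output)")
        table, _ = _plant_classes(table, cfg, rng)
        n_in = len(table)
        table = smooth_classes(table, window=cfg["smooth"]["window"])
        table = regroup_stretches(table, stretch_frac=cfg["smooth"]["stretch_frac"])
        if strict and len(table) != n_in:
            raise AssertionError("class smoothing changed the record count")
        mapping, class_report = assign_filament_architecture(table)
        class_report.to_csv(out / "class_report.csv", index=False)
        state["table"] = table
        record("smooth_classes", table, n_filaments=len(mapping))

    def st_unify_psi():
        table = need("unify_psi", "table", "particle table with class labels")
        table, psi_true, _ = _plant_angle_noise(table, cfg, rng, n_pf)
        table = unify_psi(table, inlier_window_deg=cfg["angles"]["psi_window_deg"])
        # Picker psi is direction-ambiguous (a filament has no polarity
        # yet), so the recovery metric folds differences modulo 180 degrees.
        err = wrap_angle(table.df["psi"].to_numpy(float) - psi_true)
        err = (err + 90.0) % 180.0 - 90.0
        state["table"] = table
        record(
            "unify_psi",
            table,
            psi_rms_error_deg=float(np.sqrt(np.mean(err**2))),
            psi_median_abs_error_deg=float(np.median(np.abs(err))),
        )

    def st_unify_phi():
        table = need("unify_phi", "table", "particle table with unified psi")
        table = unify_phi(table, n_pf=n_pf, n_rounds=cfg["angles"]["n_phi_rounds"])
        state["table"] = table
        record("unify_phi", table)

    def st_expand():
        table = need("expand", "table", "unexpanded particle table")
        n_before = len(table)
        table = symmetry_expand(table, sym, n_pf)
        if strict and len(table) != n_pf * n_before:
            raise AssertionError("expansion count conservation violated")
        state["table"] = table
        record("expand", table, n_parents=n_before, n_pf=n_pf)

    def st_register_merge():
        table = need("register_merge", "table", "expanded particle table")
        table, seam_truth = _plant_registers(table, cfg, rng, n_pf)
        table.df["_premerge_register"] = table.df["register"].copy()
        pd.DataFrame(
            [(m, f, s) for (m, f), s in seam_truth.items()],
            columns=["micrograph_id", "filament_id", "seam_index"],
        ).to_csv(out / "truth_seams.csv", index=False)
        n_b = int((table.df["register"] == REGISTER_B).sum())
        table = shift_register(table, which=REGISTER_B, shift_A=cfg["register"]["shift_A"])
        if strict and (table.df["register"] == REGISTER_B).any():
            raise AssertionError("register merge left class-B records")
        state["table"] = table
        state["seam_truth"] = seam_truth
        record("register_merge", table, n_shifted=n_b)

    def st_seam_find():
        table = need("seam_find", "table", "expanded table with register labels")
        seam_truth = state.get("seam_truth", {})
        profiles = find_seams(
            ParticleTable(table.df.assign(register=np.asarray(_premerge_registers(table)))),
            n_pf,
        )
        seams = {(p.micrograph_id, p.filament_id): p.seam_index for p in profiles}
        seam_table(profiles).to_csv(out / "seams.csv", index=False)
        n_correct = sum(seams.get(k) == v for k, v in seam_truth.items())
        state["seams"] = seams
        summary = dict(
            n_microtubules=len(profiles),
            n_seams_matching_truth=n_correct,
            mean_confidence=float(np.mean([p.confidence for p in profiles]))
            if profiles
            else float("nan"),
        )
        report["stages"]["seam_find"] = summary
        (out / "seam_find.json").write_text(json.dumps(summary, indent=2))
        if seam_truth:
            report["seam_recovery"] = n_correct / len(seam_truth)

    def st_unexpand():
        table = need("unexpand", "table", "expanded particle table")
        seams = need("unexpand", "seams", "per-microtubule seam indices (seam_find output)")
        final = unexpand_at_seam(table, seams)
        if strict:
            per_parent = final.df.groupby("particle_id").size()
            if (per_parent > 1).any():
                raise AssertionError("unexpand kept multiple copies of a parent")
        state["table"] = final
        record("unexpand", final, n_microtubules=len(seams))

    runners = {
        "simulate": st_simulate,
        "trace_extend": st_trace_extend,
        "smooth_classes": st_smooth_classes,
        "unify_psi": st_unify_psi,
        "unify_phi": st_unify_phi,
        "expand": st_expand,
        "register_merge": st_register_merge,
        "seam_find": st_seam_find,
        "unexpand": st_unexpand,
    }
    for stage in requested:
        runners[stage]()

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _premerge_registers(table: ParticleTable):
    """Register labels as they stood before merging (for seam scoring).

    The register merge relabels the shifted class, so the seam signal lives
    in the pre-merge labels; the real pipeline scores seams from the 3D
    classification output, which this mirrors.
    """
    return table.df["_premerge_register"] if "_premerge_register" in table.df else table.df["register"]
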