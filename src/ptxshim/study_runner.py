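"""Cohort orchestration: per-patient optimization across coil configurations,
robustness experiments, and cohort statistics.

A synthetic cohort mirrors the study design: nine patients (five with
left-lateralized, four with right-lateralized implants), each evaluated
under the reference volume-coil quadrature excitation and under 4- and
8-channel pTx with the full precheck / lambda-sweep / selection
pipeline.  Robustness experiments re-apply previously optimized weights
either averaged within a lateralization group or after a random
rigid-body displacement of the patient geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .bioheat import BoundaryCondition, peak_tip_delta_t, pennes_simulate
from .core_model import (
    DEFAULT_SPACING,
    Grid3D,
    LeadModel,
    TissueModel,
    VoiSpec,
    build_rom_mask,
    build_voi_mask,
)
from .sar_metrics import cov_b1, local_1g_sar, raw_sar, whole_head_sar
from .shim_core import CoilFieldMaps, ShimWeights, combine_fields, normalize_weights, quadrature_weights
from .shim_optimize import OptimizationConfig, lambda_sweep, quadrature_precheck, select_solution
from .synthetic_em import (
    HeadEllipsoid,
    SyntheticConfig,
    apply_rigid_transform,
    birdcage_array,
    compute_coil_maps,
    generate_coil_array,
    generate_head_phantom,
    generate_lead_trajectory,
)

__all__ = [
    "CohortConfig",
    "SyntheticPatient",
    "make_patient",
    "make_cohort",
    "patient_maps",
    "evaluate_weights",
    "run_patient",
    "run_cohort",
    "cohort_statistics",
    "average_group_weights",
    "run_averaged_weights_study",
    "draw_rigid_shift",
    "shift_experiment",
    "run_shift_study",
    "wilcoxon_signed_rank",
    "box_summary",
    "percent_reduction",
]

#: Shift-experiment sampling bounds: +-10 degrees per axis, +-4 cm per axis.
SHIFT_MAX_ANGLE_DEG = 10.0
SHIFT_MAX_TRANSLATION = 0.04


@dataclass
class CohortConfig:
    """Study-level configuration shared by every patient."""

    grid_dims: tuple[int, int, int] = (48, 56, 48)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    head: HeadEllipsoid = field(default_factory=HeadEllipsoid)
    voi: VoiSpec = field(default_factory=VoiSpec)
    n_patients: int = 9
    n_left: int = 5
    channel_counts: tuple[int, ...] = (4, 8)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    optimization: OptimizationConfig = field(default_factory=OptimizationConfig)
    thermal_duration: float = 360.0
    thermal_bc: BoundaryCondition = field(default_factory=BoundaryCondition)
    include_thermal: bool = True
    master_seed: int = 0

    def grid(self) -> Grid3D:
        return Grid3D.centered(self.grid_dims, self.spacing)

    def patient_seed(self, index: int) -> int:
        return int((self.master_seed * 9973 + 131 * index + 7) % (2**31 - 1))

    def lateralization(self, index: int) -> str:
        return "left" if index < self.n_left else "right"


@dataclass
class SyntheticPatient:
    """One synthetic patient: seeded lead trajectory in the shared phantom."""

    pid: str
    lateralization: str
    seed: int
    grid: Grid3D
    head: HeadEllipsoid
    lead: LeadModel
    tissue: TissueModel


def make_patient(cfg: CohortConfig, index: int) -> SyntheticPatient:
    grid = cfg.grid()
    lat = cfg.lateralization(index)
    seed = cfg.patient_seed(index)
    lead = generate_lead_trajectory(lat, head=cfg.head, seed=seed)
    tissue = generate_head_phantom(grid, cfg.head, lead=lead)
    return SyntheticPatient(
        pid=f"P{index + 1:02d}",
        lateralization=lat,
        seed=seed,
        grid=grid,
        head=cfg.head,
        lead=lead,
        tissue=tissue,
    )


def make_cohort(cfg: CohortConfig) -> list[SyntheticPatient]:
    return [make_patient(cfg, i) for i in range(cfg.n_patients)]


def _coil_for(config_name: str):
    if config_name == "birdcage":
        return birdcage_array()
    if config_name.startswith("ptx"):
        return generate_coil_array(int(config_name[3:]))
    raise ValueError(f"unknown coil configuration {config_name!r}")


def patient_maps(
    patient: SyntheticPatient, cfg: CohortConfig, config_name: str
) -> CoilFieldMaps:
    """Synthesize the per-channel maps of one coil configuration for a patient."""
    maps = compute_coil_maps(
        _coil_for(config_name), patient.tissue, patient.lead, patient.grid, cfg.synthetic
    )
    maps.meta["config"] = config_name
    maps.meta["patient"] = patient.pid
    return maps


def evaluate_weights(
    weights: ShimWeights,
    maps: CoilFieldMaps,
    patient: SyntheticPatient,
    cfg: CohortConfig,
) -> dict:
    """All four study metrics for a (weights, maps) pair.

    ``weights`` are applied as given (absolute drives); normalize first
    if a 1 uT shim target is intended.
    """
    voi = build_voi_mask(patient.grid, cfg.voi)
    combined = combine_fields(weights, maps)
    sar = raw_sar(combined, patient.tissue)
    metrics = {
        "rom_1g_sar": local_1g_sar(sar, patient.tissue, patient.lead),
        "cov": cov_b1(combined, voi),
        "whole_head_sar": whole_head_sar(sar, patient.tissue),
        "peak_tip_delta_t": np.nan,
    }
    if cfg.include_thermal:
        thermal = pennes_simulate(
            patient.tissue, sar, cfg.thermal_duration, bc=cfg.thermal_bc
        )
        metrics["peak_tip_delta_t"] = peak_tip_delta_t(thermal, patient.lead)
    return metrics


def run_patient(patient: SyntheticPatient, cfg: CohortConfig) -> dict:
    """Full per-patient pipeline for every coil configuration.

    The reference excitation is evaluated in quadrature; each pTx
    configuration goes through quadrature precheck, the lambda sweep and
    safety-limited selection.  Failures of a single configuration are
    recorded with their reason rather than aborting the patient.
    """
    voi = build_voi_mask(patient.grid, cfg.voi)
    record: dict = {"pid": patient.pid, "lateralization": patient.lateralization}
    configs: dict = {}

    maps_bc = patient_maps(patient, cfg, "birdcage")
    w_bc = normalize_weights(
        quadrature_weights(maps_bc.n_channels), maps_bc, voi,
        cfg.optimization.target_mean_b1,
    )
    configs["birdcage"] = {
        "mode": "quadrature",
        "weights": w_bc,
        **evaluate_weights(w_bc, maps_bc, patient, cfg),
    }
    del maps_bc

    for n in cfg.channel_counts:
        name = f"ptx{n}"
        try:
            maps = patient_maps(patient, cfg, name)
            decision, quad_sar = quadrature_precheck(
                maps, patient.tissue, patient.lead, voi, cfg.optimization.sar_limit
            )
            if decision == "safe-skip":
                w = normalize_weights(
                    quadrature_weights(n), maps, voi, cfg.optimization.target_mean_b1
                )
                configs[name] = {
                    "mode": "quadrature-safe",
                    "weights": w,
                    "quadrature_rom_1g_sar": quad_sar,
                    **evaluate_weights(w, maps, patient, cfg),
                }
                continue
            rom = build_rom_mask(patient.grid, patient.lead, patient.tissue)
            sweep = lambda_sweep(maps, voi, rom, cfg.optimization, tissue=patient.tissue)
            selected = select_solution(sweep, cfg.optimization)
            configs[name] = {
                "mode": "optimized",
                "weights": selected.weights,
                "lambda": selected.lam,
                "quadrature_rom_1g_sar": quad_sar,
                "sweep": [
                    {
                        "lambda": r.lam,
                        "cov": r.cov,
                        "rom_term": r.rom_term,
                        "rom_1g_sar": r.rom_1g_sar,
                        "error": r.error,
                    }
                    for r in sweep
                ],
                **evaluate_weights(selected.weights, maps, patient, cfg),
            }
        except Exception as exc:
            configs[name] = {"mode": "failed", "reason": str(exc)}
        finally:
            maps = None
    record["configs"] = configs
    return record


def run_cohort(cfg: CohortConfig, patients=None) -> dict:
    """Run every patient and tabulate the four metrics per configuration."""
    patients = patients or make_cohort(cfg)
    records = [run_patient(p, cfg) for p in patients]
    rows = []
    for rec in records:
        for name, c in rec["configs"].items():
            if c["mode"] == "failed":
                continue
            rows.append(
                {
                    "pid": rec["pid"],
                    "lateralization": rec["lateralization"],
                    "config": name,
                    "mode": c["mode"],
                    "lambda": c.get("lambda", np.nan),
                    "rom_1g_sar": c["rom_1g_sar"],
                    "cov": c["cov"],
                    "whole_head_sar": c["whole_head_sar"],
                    "peak_tip_delta_t": c["peak_tip_delta_t"],
                    "quadrature_rom_1g_sar": c.get("quadrature_rom_1g_sar", np.nan),
                }
            )
    table = pd.DataFrame(rows)
    return {"records": records, "table": table, "patients": patients}


def cohort_statistics(table: pd.DataFrame) -> dict:
    """Cohort medians, box summaries, percent reductions and paired tests."""
    stats: dict = {"configs": {}}
    for name, grp in table.groupby("config"):
        stats["configs"][name] = {
            metric: box_summary(grp[metric].dropna().to_numpy())
            for metric in ("rom_1g_sar", "cov", "whole_head_sar", "peak_tip_delta_t")
            if grp[metric].notna().any()
        }
    ref = table[table.config == "birdcage"].set_index("pid")
    for name in stats["configs"]:
        if name == "birdcage":
            continue
        cmp = table[table.config == name].set_index("pid")
        shared = ref.index.intersection(cmp.index)
        if len(shared) == 0:
            continue
        entry = stats["configs"][name]
        entry["percent_reduction_rom_1g_sar"] = percent_reduction(
            stats["configs"]["birdcage"]["rom_1g_sar"]["median"],
            entry["rom_1g_sar"]["median"],
        )
        try:
            w, p = wilcoxon_signed_rank(
                ref.loc[shared, "rom_1g_sar"].to_numpy(),
                cmp.loc[shared, "rom_1g_sar"].to_numpy(),
            )
            entry["wilcoxon_rom_1g_sar"] = {"W": w, "p": p}
        except ValueError:
            pass
    return stats


# --------------------------------------------------------------------------
# Robustness experiments
# --------------------------------------------------------------------------


def average_group_weights(
    weights_list: list[ShimWeights], mode: str = "circular"
) -> ShimWeights:
    """Generic ("one size fits all") weights for a patient group.

    Amplitudes are averaged arithmetically per channel; phases are
    averaged circularly (argument of the mean unit phasor) by default,
    since arithmetic averaging of wrapped angles is ill-defined at the
    0/2 pi seam.  ``mode='arithmetic'`` averages the raw phase values
    instead, for comparison.
    """
    if len(weights_list) < 2:
        raise ValueError("need at least two weight sets to average")
    n = weights_list[0].n_channels
    if any(w.n_channels != n for w in weights_list):
        raise ValueError("channel counts differ across the group")
    amps = np.mean([w.amplitudes for w in weights_list], axis=0)
    if mode == "circular":
        phasors = np.mean([np.exp(1j * w.phases) for w in weights_list], axis=0)
        if np.any(np.abs(phasors) < 1e-6):
            raise ValueError("phase average undefined: mean unit phasor near zero")
        phases = np.angle(phasors)
    elif mode == "arithmetic":
        phases = np.mean([w.phases for w in weights_list], axis=0)
    else:
        raise ValueError("mode must be 'circular' or 'arithmetic'")
    return ShimWeights(amps, phases)


def run_averaged_weights_study(
    cfg: CohortConfig, cohort: dict, mode: str = "circular"
) -> pd.DataFrame:
    """Apply lateralization-group-averaged weights to every group member."""
    patients = {p.pid: p for p in cohort["patients"]}
    rows = []
    for lat in ("left", "right"):
        group = [
            rec for rec in cohort["records"] if rec["lateralization"] == lat
        ]
        for name in [f"ptx{n}" for n in cfg.channel_counts]:
            member_weights = [
                rec["configs"][name]["weights"]
                for rec in group
                if rec["configs"][name].get("weights") is not None
            ]
            if len(member_weights) < 2:
                continue
            avg = average_group_weights(member_weights, mode=mode)
            for rec in group:
                patient = patients[rec["pid"]]
                maps = patient_maps(patient, cfg, name)
                metrics = evaluate_weights(avg, maps, patient, cfg)
                rows.append(
                    {
                        "pid": rec["pid"],
                        "lateralization": lat,
                        "config": name,
                        "weights": "group-average",
                        **metrics,
                    }
                )
    return pd.DataFrame(rows)


def draw_rigid_shift(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random rigid displacement: per-axis rotation in [-10, 10] degrees and
    translation in [-4, 4] cm (uniform)."""
    angles = rng.uniform(-SHIFT_MAX_ANGLE_DEG, SHIFT_MAX_ANGLE_DEG, 3)
    trans = rng.uniform(-SHIFT_MAX_TRANSLATION, SHIFT_MAX_TRANSLATION, 3)
    return angles, trans


def shift_experiment(
    patient: SyntheticPatient,
    weights_by_config: dict[str, ShimWeights],
    cfg: CohortConfig,
    seed: int,
    max_retries: int = 50,
) -> dict:
    """Displace the patient rigidly and re-apply the original-pose weights.

    The transform is redrawn (bounded retries) whenever the displaced
    head would leave the grid; maps are regenerated for the displaced
    geometry and the original weights applied unchanged.
    """
    rng = np.random.default_rng(seed)
    grid = patient.grid
    for _ in range(max_retries):
        angles, trans = draw_rigid_shift(rng)
        try:
            head = apply_rigid_transform(patient.head, angles, trans, grid=grid)
            lead = apply_rigid_transform(patient.lead, angles, trans)
            break
        except ValueError:
            continue
    else:
        raise ValueError("could not draw a rigid shift keeping the head in the grid")
    tissue = generate_head_phantom(grid, head, lead=lead)
    shifted = replace(
        patient, head=head, lead=lead, tissue=tissue, pid=patient.pid
    )
    out = {
        "pid": patient.pid,
        "rotation_deg": angles.tolist(),
        "translation_m": trans.tolist(),
        "configs": {},
    }
    for name, weights in weights_by_config.items():
        maps = patient_maps(shifted, cfg, name)
        out["configs"][name] = evaluate_weights(weights, maps, shifted, cfg)
    return out


def run_shift_study(cfg: CohortConfig, cohort: dict, seed: int = 1234) -> pd.DataFrame:
    """Shift experiment over the whole cohort (one draw per patient)."""
    patients = {p.pid: p for p in cohort["patients"]}
    rows = []
    for i, rec in enumerate(cohort["records"]):
        weights = {
            name: c["weights"]
            for name, c in rec["configs"].items()
            if c.get("weights") is not None
        }
        res = shift_experiment(
            patients[rec["pid"]], weights, cfg, seed=seed + 977 * i
        )
        for name, metrics in res["configs"].items():
            rows.append(
                {
                    "pid": rec["pid"],
                    "lateralization": rec["lateralization"],
                    "config": name,
                    **metrics,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cohort statistics primitives
# --------------------------------------------------------------------------


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test with exact two-sided p for small samples.

    Zero differences are discarded; absolute differences are ranked with
    midranks for ties; W is the sum of positive-difference ranks.  For
    n <= 15 the two-sided p-value comes from full enumeration of the 2^n
    sign assignments (2 * min tail probability, capped at 1); larger
    samples use the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 15:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        dist = signs @ ranks
        p_low = np.mean(dist <= w + 1e-12)
        p_high = np.mean(dist >= w - 1e-12)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= np.sum(counts**3 - counts) / 48.0
        z = (w - mean) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return w, float(p)


def box_summary(values) -> dict:
    """Median, linearly interpolated quartiles, IQR and 1.5*IQR outliers."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "median": float(med),
        "Q1": float(q1),
        "Q3": float(q3),
        "IQR": float(iqr),
        "outliers": v[(v < lo) | (v > hi)].tolist(),
    }


def percent_reduction(reference: float, value: float) -> float:
    """100 * (1 - value / reference); the fractional drop from a reference."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (1.0 - value / reference)
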