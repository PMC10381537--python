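"""End-to-end pipeline: trace a volume, and run ground-truthed benchmarks.

``trace_volume`` chains the two tracer stages (gap-bridging extraction,
then skeletonization + topology) into a RootSystem.  ``run_benchmark``
generates seeded synthetic cases, traces each, and scores the
reconstruction against the known ground truth — the synthetic analogue
of validating tracings against an independent reference measurement.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .extraction import TraceConfig, compute_cost_field, extract_connected_volume, find_start_voxel
from .hydraulics import HydraulicScenario, equivalent_conductance, zsuf
from .measures import DEFAULT_CONTAINER_VOLUME_CM3, compute_measures
from .rootsystem import RootSystem
from .skeleton import skeletonize
from .synthetic import (
    GapSpec,
    NoiseSpec,
    SyntheticSpec,
    default_grid,
    make_benchmark_case,
)
from .topology import build_skeleton_graph, extract_root_system, nearest_vertex
from .volume import Volume3D

__all__ = [
    "BenchmarkConfig",
    "benchmark_spec",
    "benchmark_grid",
    "trace_volume",
    "run_benchmark",
]


def trace_volume(
    vol: Volume3D,
    cfg: TraceConfig | None = None,
    plant_age_days: float = 10.0,
    smooth: bool = False,
) -> RootSystem:
    """Full automated tracing of an intensity volume to a RootSystem."""
    cfg = cfg or TraceConfig()
    fld = compute_cost_field(vol, cfg)
    mask, fld = extract_connected_volume(fld, cfg)
    skel = skeletonize(mask)
    graph = build_skeleton_graph(skel, fld, mask=mask)
    start = cfg.start_voxel if cfg.start_voxel is not None else find_start_voxel(fld)
    collar = nearest_vertex(graph, tuple(int(s) for s in start))
    return extract_root_system(graph, collar, plant_age_days=plant_age_days, smooth=smooth)


# ---------------------------------------------------------------------------
# benchmark


def benchmark_grid() -> Volume3D:
    """Desk-scale benchmark grid: 64^3 voxels at 0.5 x 0.5 x 1.0 mm
    (32 x 32 x 64 mm field of view, anisotropic like an MRI stack)."""
    return default_grid(shape=(64, 64, 64), spacing=(0.5, 0.5, 1.0))


def benchmark_spec(seed: int) -> SyntheticSpec:
    """Scaled-down lupine-like system that fits the benchmark grid."""
    return SyntheticSpec(
        container_height_mm=60.0,
        container_radius_mm=14.0,
        tap_length_range_mm=(40.0, 55.0),
        segment_step_mm=2.0,
        direction_persistence=0.8,
        gravitropism_weight=0.6,
        branch_spacing_mean_mm=8.0,
        branching_angle_deg=(40.0, 75.0),
        max_order=1,
        base_radius_mm=(1.1, 0.7),
        taper_per_mm=0.004,
        lateral_length_factor=(0.2, 0.45),
        seed=seed,
    )


@dataclass
class BenchmarkConfig:
    n_cases: int = 20
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    gaps: GapSpec = field(default_factory=GapSpec)
    trace: TraceConfig = field(default_factory=TraceConfig)
    container_volume_cm3: float = DEFAULT_CONTAINER_VOLUME_CM3
    hydraulics: bool = True


def _case_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(max(n, 1) * 3)][: n * 3]


def run_benchmark(cfg: BenchmarkConfig) -> dict:
    """Run ``n_cases`` seeded synthetic benchmark cases through the tracer.

    Per case: ground-truth RL, traced RL, recovery (traced/true RL in %),
    root counts and the count identity total = 1 + sum(laterals), and —
    optionally — K_rs and zSUF for traced vs truth under both hydraulic
    scenarios.  Fully deterministic given ``cfg.seed``.
    """
    grid = benchmark_grid()
    seeds = _case_seeds(cfg.seed, cfg.n_cases)
    cases = []
    failures = 0
    container_cm3 = np.pi * (1.4) ** 2 * 6.0  # the benchmark container, in cm
    for i in range(cfg.n_cases):
        s_spec, s_noise, s_gap = seeds[3 * i : 3 * i + 3]
        spec = benchmark_spec(s_spec)
        noise = replace(cfg.noise, seed=s_noise)
        gaps = replace(cfg.gaps, seed=s_gap)
        record: dict = {"case": i, "seed": s_spec}
        try:
            vol, truth, collar = make_benchmark_case(spec, noise, gaps, grid)
            # a gap may blank the collar voxel itself; fall back to the
            # automatic uppermost-shoot start in that case
            thr = cfg.trace.min_intensity_frac * float(np.max(vol.data))
            start = collar if vol.data[collar] >= thr else None
            tc = replace(cfg.trace, start_voxel=start)
            # smoothing counteracts the step-like trajectory inflation of
            # voxel-grid skeletons on noisy tubes
            traced = trace_volume(vol, tc, smooth=True)
            true_rl = truth.total_length_cm()
            traced_ms = compute_measures(
                traced, float(container_cm3), reference_length_cm=true_rl
            )
            counts = traced.counts_per_order()
            laterals = sum(n for o, n in counts.items() if o > 0)
            record.update(
                true_RL_cm=true_rl,
                traced_RL_cm=traced_ms.RL_cm,
                recovery_pct=traced_ms.recovery_pct,
                RLD=traced_ms.RLD_cm_per_cm3,
                HMD=traced_ms.HMD_cm,
                r_mean_mm=traced_ms.r_mean_mm,
                n_roots=len(traced.roots),
                counts_per_order={str(k): v for k, v in counts.items()},
                count_identity=(len(traced.roots) == 1 + laterals),
            )
            if cfg.hydraulics:
                for name, sc in (
                    ("constant", HydraulicScenario(mode="constant")),
                    ("variable", HydraulicScenario(mode="variable")),
                ):
                    record[f"Krs_{name}_traced"] = equivalent_conductance(traced, sc)
                    record[f"Krs_{name}_truth"] = equivalent_conductance(truth, sc)
                    record[f"zSUF_{name}_traced"] = zsuf(traced, sc)
                    record[f"zSUF_{name}_truth"] = zsuf(truth, sc)
            record["status"] = "ok"
        except Exception as exc:  # a failed case is recorded, not fatal
            failures += 1
            record.update(status="error", error=f"{type(exc).__name__}: {exc}")
        cases.append(record)

    ok = [c for c in cases if c.get("status") == "ok"]
    aggregate: dict = {"n_cases": cfg.n_cases, "n_ok": len(ok), "n_failed": failures}
    if ok:
        aggregate.update(
            mean_recovery_pct=float(np.mean([c["recovery_pct"] for c in ok])),
            min_recovery_pct=float(np.min([c["recovery_pct"] for c in ok])),
            mean_true_RL_cm=float(np.mean([c["true_RL_cm"] for c in ok])),
            mean_traced_RL_cm=float(np.mean([c["traced_RL_cm"] for c in ok])),
            count_identity_all=bool(all(c["count_identity"] for c in ok)),
        )
    return {
        "config": {
            "n_cases": cfg.n_cases,
            "seed": cfg.seed,
            "noise": asdict(cfg.noise),
            "gaps": asdict(cfg.gaps),
            "trace": asdict(cfg.trace),
        },
        "cases": cases,
        "aggregate": aggregate,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
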