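"""The study run matrix and its comparison tables.

{forward, reverse} x {normal, sal_x100, sal_ossified, rwm_x100,
rwm_ossified} x {125 ... 4000 Hz} = 60 cells.  The normal-forward runs are
solved first and cached: their CF locations and amplitudes are the
reference against which every other cell's relative amplitude (the
hearing-threshold-change proxy) is expressed.  Pathology stages act on the
window boundary impedances only — the SAL mode moves z_ow, the RWM mode
moves z_rw — while the BM partition is identical across scenarios, and the
equal-force stimulus per pathway is scenario-independent (a fixed
transducer drive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import EC_LEVEL_DB_SPL, spl_to_pressure
from .fixtures import (
    PAPER_FREQUENCIES_HZ,
    SCENARIO_NAMES,
    GeometrySpec,
    Materials,
    ScenarioSpec,
    default_geometry,
    default_materials,
    make_scenario,
)
from .metrics import (
    CFMap,
    TransferMetrics,
    amplitude_at,
    cochlear_input_impedance,
    extract_cf,
    max_displacement_db,
    metf,
    phase_re_base,
    relative_amplitude_at_cf,
    reverse_middle_ear_impedance,
)
from .solver import (
    SolutionField,
    assemble,
    calibrated_stiffness_constant,
    conservation_check,
    make_stimulus,
    solve,
    solution_to_frame,
)

__all__ = [
    "RunRecord",
    "run_matrix",
    "run_cell",
    "records_to_frame",
    "pathway_advantage",
    "pathology_decrement",
    "ordering_checks",
    "write_matrix_outputs",
]


@dataclass(frozen=True)
class RunRecord:
    """One cell of the run matrix with all its metrics."""

    scenario: ScenarioSpec
    pathway: str
    frequency: float
    metrics: TransferMetrics
    cf: CFMap
    max_disp_db: float  # dB re 1 m (relative comparisons only)
    rel_amp_db: float  # dB re normal-forward at the reference CF place
    conservation: float
    residual: float


def run_cell(
    scenario: ScenarioSpec,
    pathway: str,
    frequency: float,
    geometry: GeometrySpec,
    materials: Materials,
    stiffness_const: float,
) -> SolutionField:
    model = assemble(
        geometry,
        materials,
        frequency,
        scenario=scenario,
        stiffness_const=stiffness_const,
    )
    return solve(model, make_stimulus(pathway, frequency, geometry))


def run_matrix(
    geometry: GeometrySpec | None = None,
    materials: Materials | None = None,
    *,
    scenarios: Sequence[str] = SCENARIO_NAMES,
    pathways: Sequence[str] = ("forward", "reverse"),
    frequencies: Sequence[float] = PAPER_FREQUENCIES_HZ,
    keep_solutions: bool = False,
) -> list[RunRecord]:
    """Run the full matrix; returns one record per cell, deterministic.

    The reference (normal, forward) runs are always solved, regardless of
    the requested subset, so relative amplitudes are well defined.
    """
    geometry = geometry or default_geometry()
    materials = materials or default_materials()
    C = calibrated_stiffness_constant(geometry, materials)
    p_ec = spl_to_pressure(EC_LEVEL_DB_SPL)

    # Reference: normal model, forward stimulation.
    normal = make_scenario("normal")
    ref_loc: dict[float, float] = {}
    ref_amp: dict[float, float] = {}
    ref_solutions: dict[float, SolutionField] = {}
    for f in frequencies:
        sol = run_cell(normal, "forward", f, geometry, materials, C)
        loc, _ = extract_cf(np.abs(sol.d))
        ref_loc[f] = loc
        ref_amp[f] = amplitude_at(sol.d, loc)
        ref_solutions[f] = sol

    records: list[RunRecord] = []
    solutions: list[SolutionField] = []
    for name in scenarios:
        scenario = make_scenario(name)
        for pathway in pathways:
            for f in frequencies:
                if name == "normal" and pathway == "forward":
                    sol = ref_solutions[f]
                else:
                    sol = run_cell(scenario, pathway, f, geometry, materials, C)
                records.append(
                    _record_from_solution(sol, scenario, pathway, p_ec, ref_loc, ref_amp)
                )
                if keep_solutions:
                    solutions.append(sol)
    if keep_solutions:
        return records, solutions  # type: ignore[return-value]
    return records


def _record_from_solution(
    sol: SolutionField,
    scenario: ScenarioSpec,
    pathway: str,
    p_ec: float,
    ref_loc: dict[float, float],
    ref_amp: dict[float, float],
) -> RunRecord:
    f = sol.frequency
    if pathway == "forward":
        tm = TransferMetrics(
            frequency=f,
            metf=metf(sol.d_stapes, p_ec),
            z_c=cochlear_input_impedance(sol.p_sv_probe, sol.u_ow),
            z_me_r=None,
            vol_ratio=abs(sol.u_rw) / abs(sol.u_ow),
        )
    else:
        # In reverse runs the stapes volume velocity is outward through the
        # OW; use the outward sign so the impedance has a passive real part.
        tm = TransferMetrics(
            frequency=f,
            metf=None,
            z_c=None,
            z_me_r=reverse_middle_ear_impedance(sol.p_sv_probe, -sol.u_ow),
            vol_ratio=abs(sol.u_ow) / abs(sol.u_rw),
        )
    loc, peak = extract_cf(np.abs(sol.d))
    cf = CFMap(
        frequency=f,
        cf_location=loc,
        peak_displacement=peak,
        phase_at_cf=phase_re_base(sol, loc),
    )
    return RunRecord(
        scenario=scenario,
        pathway=pathway,
        frequency=f,
        metrics=tm,
        cf=cf,
        max_disp_db=max_displacement_db(sol),
        rel_amp_db=relative_amplitude_at_cf(sol, ref_loc, ref_amp),
        conservation=conservation_check(sol),
        residual=sol.residual,
    )


def records_to_frame(records: Iterable[RunRecord]) -> pd.DataFrame:
    """Headered table, one row per (scenario, pathway, frequency)."""
    rows = []
    for rec in records:
        tm = rec.metrics
        rows.append(
            {
                "scenario": rec.scenario.name,
                "pathway": rec.pathway,
                "frequency_hz": rec.frequency,
                "metf_db": tm.metf,
                "z_c_abs": abs(tm.z_c) if tm.z_c is not None else None,
                "z_c_phase_cycles": (
                    float(np.angle(tm.z_c)) / (2 * np.pi) if tm.z_c is not None else None
                ),
                "z_me_r_abs": abs(tm.z_me_r) if tm.z_me_r is not None else None,
                "z_me_r_phase_cycles": (
                    float(np.angle(tm.z_me_r)) / (2 * np.pi)
                    if tm.z_me_r is not None
                    else None
                ),
                "vol_ratio": tm.vol_ratio,
                "cf_location": rec.cf.cf_location,
                "peak_displacement_m": rec.cf.peak_displacement,
                "phase_at_cf_cycles": rec.cf.phase_at_cf,
                "max_disp_db_re_1m": rec.max_disp_db,
                "rel_amp_db": rec.rel_amp_db,
                "conservation": rec.conservation,
                "residual": rec.residual,
            }
        )
    return pd.DataFrame(rows)


def _require_complete(records: Sequence[RunRecord]) -> pd.DataFrame:
    df = records_to_frame(records)
    cells = df.groupby(["scenario", "pathway"])["frequency_hz"].nunique()
    n_freq = df["frequency_hz"].nunique()
    scen = df["scenario"].nunique()
    path = df["pathway"].nunique()
    if len(df) != scen * path * n_freq or (cells != n_freq).any():
        raise ValueError("incomplete run matrix: need every scenario x pathway x frequency cell")
    if path < 2:
        raise ValueError("incomplete run matrix: both pathways are required")
    return df


def pathway_advantage(records: Sequence[RunRecord]) -> pd.DataFrame:
    """Reverse-minus-forward max-BM-displacement difference (dB) per cell.

    Columns: scenario, frequency_hz, advantage_db, violates (True where
    reverse < forward — expected at most in the rwm_ossified scenario).
    """
    df = _require_complete(records)
    piv = df.pivot_table(
        index=["scenario", "frequency_hz"], columns="pathway", values="max_disp_db_re_1m"
    )
    out = piv.reset_index()
    out["advantage_db"] = out["reverse"] - out["forward"]
    out["violates"] = out["advantage_db"] < 0
    return out[["scenario", "frequency_hz", "advantage_db", "violates"]]


def pathology_decrement(records: Sequence[RunRecord]) -> pd.DataFrame:
    """Relative amplitude vs the normal-forward baseline, per cell.

    ``decrement_db`` is the positive-valued amplitude loss
    (-rel_amp_db); the normal-forward cells are 0 by construction.
    """
    df = _require_complete(records)
    out = df[["scenario", "pathway", "frequency_hz", "rel_amp_db"]].copy()
    out["decrement_db"] = -out["rel_amp_db"]
    return out


def ordering_checks(records: Sequence[RunRecord]) -> dict[str, bool]:
    """The study's qualitative orderings as boolean checks.

    The decrement comparisons are made on the amplitude *loss*,
    max(0, -rel_amp_db): a decrement is by definition a reduction, so a
    cell where stiffening slightly amplifies the response (a sub-dB effect
    of window-reactance cancellation at high frequency in this lumped
    model) counts as zero loss rather than a negative one.

    sal_ge_rwm_forward : SAL-stiffened loss >= RWM-stiffened loss at
        matched stage and frequency under forward stimulation.
    low_freq_emphasis : for each stiffened scenario and pathway, the 125-Hz
        loss is >= the 4-kHz loss.
    stage_monotonic : ossified loss >= x100 loss at every frequency and
        pathway for both window pathologies.
    reverse_advantage : reverse max displacement exceeds forward in every
        scenario except rwm_ossified (the stated exception).
    """
    dec = (
        pathology_decrement(records)
        .set_index(["scenario", "pathway", "frequency_hz"])["decrement_db"]
        .clip(lower=0.0)
    )
    adv = pathway_advantage(records).set_index(["scenario", "frequency_hz"])["advantage_db"]
    freqs = sorted({rec.frequency for rec in records})
    pathways = ("forward", "reverse")

    sal_ge_rwm = all(
        dec[("sal_" + stage, "forward", f)] >= dec[("rwm_" + stage, "forward", f)] - 1e-9
        for stage in ("x100", "ossified")
        for f in freqs
    )
    low_emph = all(
        dec[(scen, pw, min(freqs))] >= dec[(scen, pw, max(freqs))] - 1e-9
        for scen in SCENARIO_NAMES
        if scen != "normal"
        for pw in pathways
    )
    stage_mono = all(
        dec[(window + "_ossified", pw, f)] >= dec[(window + "_x100", pw, f)] - 1e-9
        for window in ("sal", "rwm")
        for pw in pathways
        for f in freqs
    )
    rev_adv = all(
        adv[(scen, f)] > 0
        for scen in SCENARIO_NAMES
        if scen != "rwm_ossified"
        for f in freqs
    )
    return {
        "sal_ge_rwm_forward": bool(sal_ge_rwm),
        "low_freq_emphasis": bool(low_emph),
        "stage_monotonic": bool(stage_mono),
        "reverse_advantage": bool(rev_adv),
    }


def write_matrix_outputs(
    records: Sequence[RunRecord],
    outdir: str | Path,
    *,
    solutions: Sequence[SolutionField] | None = None,
) -> None:
    """Write records.csv, pathway_advantage.csv, pathology_decrement.csv
    (and per-run BM profiles when solutions are provided)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(outdir / "records.csv", index=False)
    pathway_advantage(records).to_csv(outdir / "pathway_advantage.csv", index=False)
    pathology_decrement(records).to_csv(outdir / "pathology_decrement.csv", index=False)
    if solutions is not None:
        profdir = outdir / "profiles"
        profdir.mkdir(exist_ok=True)
        for rec, sol in zip(records, solutions):
            name = f"{rec.scenario.name}_{rec.pathway}_{int(rec.frequency)}Hz.csv"
            solution_to_frame(sol).to_csv(profdir / name, index=False)
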