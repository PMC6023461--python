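"""Reference study scenarios at the published screen regimes.

Each function generates a synthetic screen under a regime stated in the
study being emulated (cell-array density ~156 cells/spot, 9 spots x 3
replicas; EGF assay ~93 cells/spot, 5 spots x 3 replicas with a 60-70%
uptake reduction under EGFR knock-down; array spindle-arrest frequency
around 30% at 24-30 h), runs the full analysis pipeline and reports the
recovered quantity next to the configured truth.
"""

from __future__ import annotations

import numpy as np

from .layout import normalize_egf
from .phenotype import train_default_model
from .pipeline import AnalysisConfig, analyze_screen
from .stats import games_howell
from .synth import (
    CargoModel,
    ConditionEffect,
    SceneSpec,
    generate_screen,
    make_array_layout,
)

__all__ = [
    "spindle_recovery_scenario",
    "cell_density_scenario",
    "egf_knockdown_scenario",
]

#: array spindle-arrest regime at the 24-30 h time point
ARRAY_SPINDLE_MIX = (0.64, 0.30, 0.06)

#: negative-control phenotype mixture on arrays
NC_ARRAY_MIX = (0.823, 0.097, 0.080)


def _subseed(seed: int, tag: str) -> int:
    return int(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, abs(hash(tag)) & 0xFFFF]).generate_state(1)[0]
        >> 1
    )


def spindle_recovery_scenario(
    seed: int = 42,
    spots: int = 9,
    replicates: int = 3,
    expected_cells: float = 156.0,
    true_mix: tuple[float, float, float] = ARRAY_SPINDLE_MIX,
    model=None,
) -> dict:
    """Recover the spindle-phenotype percentage on synthetic array spots.

    Generates ``spots x replicates`` spot fields at the array cell density
    with the given true phenotype mixture, runs segmentation +
    classification + spot aggregation and returns the grand mean spindle
    percentage over positions alongside the configured and realized truth.
    """
    if model is None:
        model = train_default_model(seed=_subseed(seed, "train"))
    layout = make_array_layout(["KIF11"], spots, replicates)
    effects = {"KIF11": ConditionEffect(phenotype_mix=true_mix)}
    base = SceneSpec(expected_cells=expected_cells)
    fields, truths = generate_screen(layout, effects, base, master_seed=seed)
    _, readout = analyze_screen(fields, model, AnalysisConfig())
    true_frac = float(np.mean([t.fractions()[1] for t in truths if t.n_cells]))
    return {
        "estimated_spindle_pct": 100.0 * float(readout["frac_spindle"].mean()),
        "configured_spindle_pct": 100.0 * true_mix[1],
        "realized_spindle_pct": 100.0 * true_frac,
        "n_fields": len(fields),
        "readout": readout,
    }


def cell_density_scenario(
    seed: int = 7,
    spots: int = 9,
    replicates: int = 3,
    expected_cells: float = 156.0,
    model=None,
) -> dict:
    """Recover the per-spot cell density of the array cell-cycle assay.

    Negative-control mixture, marker channel present; reports the mean
    number of detected nuclei per spot after spot-ROI restriction.
    """
    if model is None:
        model = train_default_model(seed=_subseed(seed, "train"))
    layout = make_array_layout(["NC"], spots, replicates)
    effects = {"NC": ConditionEffect(phenotype_mix=NC_ARRAY_MIX)}
    base = SceneSpec(expected_cells=expected_cells)
    fields, truths = generate_screen(layout, effects, base, master_seed=seed)
    _, readout = analyze_screen(fields, model, AnalysisConfig())
    return {
        "mean_detected_per_spot": float(readout["n_cells"].mean()),
        "configured_cells_per_spot": expected_cells,
        "mean_true_per_spot": float(np.mean([t.n_cells for t in truths])),
        "n_fields": len(fields),
        "readout": readout,
    }


def egf_knockdown_scenario(
    seed: int = 11,
    spots: int = 5,
    replicates: int = 3,
    expected_cells: float = 93.0,
    reduction: float = 0.65,
    model=None,
) -> dict:
    """Recover an injected EGF-uptake reduction under EGFR knock-down.

    Two conditions (negative control and EGFR knock-down with perinuclear
    ring intensity scaled by ``1 - reduction``) at the EGF-assay spot
    density; returns the estimated percent reduction of the mean
    perinuclear EGF signal and the Games-Howell p-value of the knock-down
    vs the negative control on position-level readouts.
    """
    if model is None:
        model = train_default_model(seed=_subseed(seed, "train"))
    layout = make_array_layout(["NC", "EGFR"], spots, replicates)
    effects = {
        "NC": ConditionEffect(phenotype_mix=NC_ARRAY_MIX),
        "EGFR": ConditionEffect(phenotype_mix=NC_ARRAY_MIX, cargo_scale=1.0 - reduction),
    }
    base = SceneSpec(expected_cells=expected_cells, cargo_model=CargoModel())
    fields, _ = generate_screen(layout, effects, base, master_seed=seed)
    _, readout = analyze_screen(fields, model, AnalysisConfig())
    normalized = normalize_egf(readout, mode="percent_of_nc")
    per_rep = normalized.groupby(["replicate", "condition"])["mean_egf_pct"].mean()
    kd_pct = float(per_rep.xs("EGFR", level="condition").mean())
    groups = {
        cond: grp["mean_egf"].to_numpy(float)
        for cond, grp in readout.groupby("condition")
    }
    pair = games_howell(groups)[0]
    return {
        "estimated_reduction_pct": 100.0 - kd_pct,
        "configured_reduction_pct": 100.0 * reduction,
        "games_howell_p": pair.p,
        "n_fields": len(fields),
        "readout": readout,
    }
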