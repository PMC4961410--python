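"""End-to-end workflows: simulate -> (render/process) -> gate -> evaluate.

These functions chain the stage modules exactly the way the CLI does, so
the same code path is exercised by tests, the command line and the
reproduction script. Thresholds are derived once on the representative
sample (the first of the batch unless configured otherwise) and applied
uniformly; per-stage event counts are logged at info level as the audit
trail.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .biomarkers import BiomarkerSummary, pdl1_summary
from .core import EventTable, GroundTruth
from .gating import (
    ThresholdSet,
    classify_leukocyte_axes,
    classify_strict,
    derive_thresholds,
)
from .imaging import match_to_truth, run_image_pipeline
from .io import PipelineConfig
from .synthetic import (
    ImageParams,
    SampleScenario,
    make_scenario,
    render_sample,
    sample_events,
)

logger = logging.getLogger("ctcgate")

__all__ = [
    "simulate_batch",
    "image_batch",
    "gate_batch",
    "evaluate_batch",
    "recover_fold_changes",
    "recover_cd11b_fractions",
    "recover_fp_fractions",
]


def simulate_batch(config: PipelineConfig) -> list[tuple[SampleScenario, EventTable, GroundTruth]]:
    """Generate the event tables of a preset (event mode)."""
    scenarios = make_scenario(config.preset, seed=config.seed,
                              n_cells=config.n_cells)
    out = []
    for sc in scenarios:
        events, truth = sample_events(sc)
        logger.info("simulated %s: %d events", sc.sample_id, len(events))
        out.append((sc, events, truth))
    return out


def image_batch(config: PipelineConfig,
                scenarios: Optional[Sequence[SampleScenario]] = None
                ) -> list[tuple[SampleScenario, EventTable, GroundTruth]]:
    """Render each scenario to tiles, run the image pipeline, and attach
    ground-truth classes to the segmented events by nearest center."""
    if scenarios is None:
        scenarios = make_scenario(config.preset, seed=config.seed,
                                  n_cells=config.n_cells)
    params = ImageParams(field_shape=config.field_shape,
                         grid_shape=config.grid_shape,
                         overlap_frac=config.overlap_frac,
                         background=config.background,
                         noise_sd=config.noise_sd,
                         touching_rate=config.touching_rate)
    out = []
    for sc in scenarios:
        events, truth = sample_events(sc)
        grid, truth = render_sample(events, truth, params)
        measured = run_image_pipeline(grid, config.image_pipeline_config())
        measured.provenance["id_marker"] = sc.id_marker
        measured = match_to_truth(measured, truth)
        logger.info("imaged %s: %d cells rendered, %d events segmented",
                    sc.sample_id, len(events), len(measured))
        out.append((sc, measured, truth))
    return out


def _representative(tables: Sequence[EventTable],
                    config: PipelineConfig) -> EventTable:
    if config.representative_sample is None:
        return tables[0]
    for t in tables:
        if t.sample_id == config.representative_sample:
            return t
    raise ValueError(f"representative sample {config.representative_sample!r} "
                     "not in batch")


def gate_batch(tables: Sequence[EventTable], config: PipelineConfig,
               id_marker: str = "pck"
               ) -> tuple[list[EventTable], ThresholdSet]:
    """Derive thresholds on the representative sample, classify every
    sample (strict tree + CD45/CD11b quadrants), return labeled tables."""
    channels = list(config.gating_channels)
    if id_marker not in channels:
        channels.append(id_marker)
    rep = _representative(tables, config)
    thresholds = derive_thresholds(rep, channels, manual=config.manual_cutoffs)
    labeled = []
    for t in tables:
        if config.rederive_per_sample and t.sample_id != rep.sample_id:
            thr = derive_thresholds(t, channels, manual=config.manual_cutoffs)
        else:
            thr = thresholds
        out = t.copy()
        out.data["label_strict"] = classify_strict(out, thr, id_marker=id_marker)
        out.data["label_quadrant"] = classify_leukocyte_axes(out, thr)
        counts = out.data["label_strict"].value_counts().to_dict()
        logger.info("gated %s: %s", t.sample_id, counts)
        labeled.append(out)
    return labeled, thresholds


def evaluate_batch(labeled: Sequence[EventTable],
                   thresholds: ThresholdSet) -> list[BiomarkerSummary]:
    """Per-sample biomarker summaries under both CTC criteria."""
    pdl1_cut = thresholds.cutoffs.get("pdl1")
    cd11b_cut = thresholds.cutoffs.get("cd11b")
    return [pdl1_summary(t, pdl1_cutoff=pdl1_cut, cd11b_cutoff=cd11b_cut)
            for t in labeled]


# ---------------------------------------------------------------------------
# parameter-recovery workflows (simulated "figure" reproductions)
# ---------------------------------------------------------------------------

def recover_fold_changes(seed: int = 0, n_cells: int = 5000,
                         channel: str = "pck") -> dict:
    """Flow-style fold-change recovery over the three simulated patients.

    For each patient: gate on CD45/CD11b quadrants with data-derived
    cutoffs, then take the ratio of mean MFI between the CD11b+ (CD45-low
    myeloid) gate and the CD11b-/CD45- population.
    """
    from .biomarkers import population_fold_change

    config = PipelineConfig(preset="fig1_flow", seed=seed, n_cells=n_cells)
    batch = simulate_batch(config)
    tables = [ev for _, ev, _ in batch]
    labeled, _ = gate_batch(tables, config)
    ratios = []
    for (sc, _, _), table in zip(batch, labeled):
        r = population_fold_change(table, "CD11B_POS", "DN", channel)
        ratios.append(r)
    ratios = [r for r in ratios if r is not None]
    return {"ratios": ratios,
            "mean": float(np.mean(ratios)) if ratios else None,
            "planted": [sc.planted[f"{channel}_fold_change"]
                        for sc, _, _ in batch]}


def recover_cd11b_fractions(preset: str, seed: int = 0,
                            n_cells: Optional[int] = None,
                            mode: str = "events",
                            config: Optional[PipelineConfig] = None) -> dict:
    """CD11b+ capture-fraction recovery for a capture-comparison preset."""
    from .biomarkers import cd11b_fraction

    cfg = config or PipelineConfig(preset=preset, seed=seed, n_cells=n_cells,
                                   mode=mode)
    batch = image_batch(cfg) if cfg.mode == "images" else simulate_batch(cfg)
    tables = [ev for _, ev, _ in batch]
    labeled, thresholds = gate_batch(tables, cfg)
    cut = thresholds["cd11b"]
    per_sample = {}
    for (sc, _, _), table in zip(batch, labeled):
        per_sample[sc.sample_id] = {
            "capture_antibody": sc.capture_antibody,
            "observed": cd11b_fraction(table, cut),
            "planted": sc.planted["myeloid_fraction"],
        }
    return {"per_sample": per_sample, "cd11b_cutoff": cut}


def recover_fp_fractions(preset: str, seed: int = 0,
                         n_cells: Optional[int] = None,
                         capture_antibody: Optional[str] = None) -> dict:
    """False-positive-fraction recovery (contamination of the standard
    CTC pool) for the fig3-style and surface-identification presets."""
    from .biomarkers import false_positive_fraction

    scenarios = make_scenario(preset, seed=seed, n_cells=n_cells,
                              capture_antibody=capture_antibody)
    cfg = PipelineConfig(preset=preset, seed=seed, n_cells=n_cells)
    batch = [(sc, *sample_events(sc)) for sc in scenarios]
    tables = [ev for _, ev, _ in batch]
    id_marker = scenarios[0].id_marker
    labeled, thresholds = gate_batch(tables, cfg, id_marker=id_marker)
    per_sample = {}
    for (sc, _, _), table in zip(batch, labeled):
        per_sample[sc.sample_id] = {
            "capture_antibody": sc.capture_antibody,
            "observed": false_positive_fraction(table),
            "planted": sc.planted["contamination_fraction"],
        }
    observed = [v["observed"] for v in per_sample.values()
                if v["observed"] is not None]
    return {"per_sample": per_sample,
            "mean": float(np.mean(observed)) if observed else None,
            "thresholds": thresholds.cutoffs}
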