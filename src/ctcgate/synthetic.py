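"""Seeded simulator for CTC-enrichment samples.

Real samples in this assay are blood-derived cell suspensions enriched with
a capture antibody (EpCAM, MUC1 or vimentin), stained for the marker panel
and read out either by flow cytometry (per-cell event tables) or by tiled
fluorescence microscopy. No raw patient data are available, so this module
plants a fully known ground truth and lets every downstream stage be tested
by parameter recovery.

The simulator draws three to four cell classes per sample:

* ``WBC`` — CD45-bright leukocytes (lymphocyte-like);
* ``MYELOID`` — CD45-low, CD11b-bright granulocytic cells with elevated
  *non-specific* intracellular staining (pCK and isotype) — the population
  that the standard pCK+/CD45- CTC definition misidentifies as tumor cells;
* ``CTC`` — CD45-/CD11b- epithelial cells, pCK-bright, variable PD-L1;
* ``OTHER`` — CD45-/CD11b-/pCK- cells (the comparison population for
  fold-change measurements).

Per-marker intensities are log-normal, parameterized by median and
geometric SD (right-skewed and strictly positive, as fluorescence data
are in practice). Scenario presets plant the per-figure summary values
(mixture fractions, fold-changes) used throughout the test suite.

Image mode renders each cell as a filled nuclear disc (Hoechst) plus a
dilated cytoplasmic disc (all other markers) on a 16-bit field with
constant background and Gaussian read noise, then cuts the field into an
overlapping tile grid — the same input shape a stitched microscopy scan
provides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk

from .core import (
    CAPTURE_ANTIBODIES,
    CHANNELS,
    TRUTH_CLASSES,
    CapacityError,
    ConfigurationError,
    EventTable,
    GroundTruth,
    LookupError_,
    ValidationError,
)
from .imaging import TileGrid

__all__ = [
    "LogNormalParams",
    "PopulationSpec",
    "SampleScenario",
    "ImageParams",
    "sample_events",
    "render_sample",
    "make_scenario",
    "compute_planted_summaries",
    "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# distributions and population specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal law given as (median, geometric SD).

    ``gsd == 1`` is the degenerate point mass at the median; otherwise
    ``log(X) ~ Normal(log(median), log(gsd))``.
    """

    median: float
    gsd: float = 1.0

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValidationError(f"median must be > 0, got {self.median}")
        if self.gsd < 1.0:
            raise ValidationError(f"geometric SD must be >= 1, got {self.gsd}")

    @property
    def sigma(self) -> float:
        return math.log(self.gsd)

    @property
    def mean(self) -> float:
        """Arithmetic mean: median * exp(sigma^2 / 2)."""
        return self.median * math.exp(self.sigma ** 2 / 2.0)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(size))


@dataclass(frozen=True)
class PopulationSpec:
    """One planted cell population.

    ``standard_positive`` records whether cells of this population satisfy
    the *standard* CTC definition (identification marker bright, CD45 dim)
    given their planted medians — bookkeeping used to compute the planted
    contamination fraction analytically.
    """

    name: str
    frequency: float
    channel_params: dict[str, LogNormalParams]
    size_params: LogNormalParams
    truth_class: str
    standard_positive: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.frequency <= 1.0):
            raise ValidationError(f"frequency must be in [0,1]: {self.frequency}")
        if self.truth_class not in TRUTH_CLASSES:
            raise ValidationError(f"unknown truth class {self.truth_class!r}")
        missing = set(CHANNELS) - set(self.channel_params)
        if missing:
            raise ValidationError(f"population {self.name!r} missing channels {sorted(missing)}")
        if self.size_params.median < 2.0:
            raise ValidationError("cell radius median must be >= 2 px")


@dataclass(frozen=True)
class SampleScenario:
    """Fully parameterized simulated sample.

    ``id_marker`` is the channel used as the positive identification marker
    in standard CTC classification (``pck`` for intracellular cytokeratin,
    ``capture`` when CTCs are identified by surface capture-antigen
    staining). ``planted`` holds analytically known summaries, recomputable
    from the populations via :func:`compute_planted_summaries`.
    """

    sample_id: str
    capture_antibody: str
    populations: tuple[PopulationSpec, ...]
    n_cells: int
    seed: int
    id_marker: str = "pck"
    patient_id: str = ""
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.capture_antibody not in CAPTURE_ANTIBODIES:
            raise ValidationError(f"unknown capture antibody {self.capture_antibody!r}")
        total = sum(p.frequency for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"population frequencies must sum to 1, got {total!r}")
        if not self.planted:
            object.__setattr__(self, "planted",
                               compute_planted_summaries(self.populations))


def compute_planted_summaries(populations: Sequence[PopulationSpec]) -> dict:
    """Analytic summaries implied by the planted populations.

    Keys:

    * ``class_fractions`` — frequency per ground-truth class;
    * ``myeloid_fraction`` — planted CD11b+ share of all cells;
    * ``contamination_fraction`` — myeloid share of cells meeting the
      standard CTC definition (the planted false-positive fraction), or
      ``None`` when nothing is standard-positive;
    * ``pck_fold_change`` / ``isotype_fold_change`` — ratio of arithmetic
      mean MFI, MYELOID over OTHER (``None`` if a class is absent);
    * ``mean_by_class`` — per class, per channel arithmetic-mean MFI
      (frequency-weighted over the class's populations).
    """
    class_fractions = {c: 0.0 for c in TRUTH_CLASSES}
    for p in populations:
        class_fractions[p.truth_class] += p.frequency

    pos_total = sum(p.frequency for p in populations if p.standard_positive)
    pos_myeloid = sum(p.frequency for p in populations
                      if p.standard_positive and p.truth_class == "MYELOID")
    contamination = pos_myeloid / pos_total if pos_total > 0 else None

    mean_by_class: dict[str, dict[str, float]] = {}
    for cls in TRUTH_CLASSES:
        pops = [p for p in populations if p.truth_class == cls]
        if not pops:
            continue
        w = np.array([p.frequency for p in pops])
        if w.sum() == 0:
            continue
        w = w / w.sum()
        mean_by_class[cls] = {
            ch: float(sum(wi * p.channel_params[ch].mean for wi, p in zip(w, pops)))
            for ch in CHANNELS
        }

    def _fold(channel: str) -> Optional[float]:
        if "MYELOID" not in mean_by_class or "OTHER" not in mean_by_class:
            return None
        return mean_by_class["MYELOID"][channel] / mean_by_class["OTHER"][channel]

    return {
        "class_fractions": class_fractions,
        "myeloid_fraction": class_fractions["MYELOID"],
        "contamination_fraction": contamination,
        "pck_fold_change": _fold("pck"),
        "isotype_fold_change": _fold("isotype"),
        "mean_by_class": mean_by_class,
    }


# ---------------------------------------------------------------------------
# event-mode sampling
# ---------------------------------------------------------------------------

def _event_rng(seed: int) -> np.random.Generator:
    # substream 0: memberships, intensities, radii (shared by both modes)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))


def _render_rng(seed: int) -> np.random.Generator:
    # substream 1: placement and pixel noise, so image mode reuses the
    # event-mode intensities unchanged
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))


def sample_events(scenario: SampleScenario) -> tuple[EventTable, GroundTruth]:
    """Draw the per-cell event table for a scenario.

    Population membership is multinomial in ``frequency``; each marker is
    then drawn log-normally from the member population's parameters.
    Returns the event table (flow-cytometry-like: NaN centroids) and the
    ground truth with per-cell planted medians and radii.
    """
    rng = _event_rng(scenario.seed)
    pops = scenario.populations
    n = scenario.n_cells
    freqs = np.array([p.frequency for p in pops])

    member = rng.choice(len(pops), size=n, p=freqs)

    r_med = np.array([p.size_params.median for p in pops])[member]
    r_sig = np.array([p.size_params.sigma for p in pops])[member]
    radius = r_med * np.exp(r_sig * rng.standard_normal(n))

    med = np.array([[p.channel_params[ch].median for ch in CHANNELS] for p in pops])
    sig = np.array([[p.channel_params[ch].sigma for ch in CHANNELS] for p in pops])
    z = rng.standard_normal((n, len(CHANNELS)))
    values = med[member] * np.exp(sig[member] * z)

    truth_class = np.array([p.truth_class for p in pops])[member]
    event_id = np.arange(1, n + 1)

    data = pd.DataFrame({
        "event_id": event_id,
        "row": np.full(n, np.nan),
        "col": np.full(n, np.nan),
        "area": np.round(np.pi * radius ** 2).astype(int),
    })
    for j, ch in enumerate(CHANNELS):
        data[ch] = values[:, j]
    data["truth_class"] = truth_class

    truth = pd.DataFrame({
        "event_id": event_id,
        "truth_class": truth_class,
        "radius_px": radius,
    })
    for j, ch in enumerate(CHANNELS):
        truth[f"planted_{ch}"] = med[member][:, j]

    table = EventTable(
        sample_id=scenario.sample_id,
        capture_antibody=scenario.capture_antibody,
        data=data,
        provenance={"seed": scenario.seed, "mode": "events",
                    "id_marker": scenario.id_marker,
                    "patient_id": scenario.patient_id or scenario.sample_id},
    )
    return table, GroundTruth(table=truth)


# ---------------------------------------------------------------------------
# image-mode rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageParams:
    """Microscopy rendering parameters.

    Defaults: 16-bit field with constant background 500 AU, Gaussian read
    noise SD 50 AU, 5% of cells placed touching a neighbour, cytoplasm
    rendered 4 px beyond the nucleus, field cut into a 2x2 tile grid with
    10% linear overlap.
    """

    field_shape: tuple[int, int] = (1024, 1024)
    grid_shape: tuple[int, int] = (2, 2)
    overlap_frac: float = 0.10
    background: float = 500.0
    noise_sd: float = 50.0
    touching_rate: float = 0.05
    cyto_margin: int = 4
    min_gap: float = 3.0
    max_retries: int = 500
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.overlap_frac < 0:
            raise ValidationError("tile overlap must be >= 0")
        if self.noise_sd < 0 or self.background < 0:
            raise ValidationError("background and noise must be >= 0")


def _place_cells(radii: np.ndarray, params: ImageParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping centers (touching pairs allowed
    at ``touching_rate``). Returns (n, 2) array of (row, col)."""
    h, w = params.field_shape
    n = len(radii)
    centers = np.empty((n, 2))
    margin = radii + params.cyto_margin + 1
    for i in range(n):
        ri = radii[i]
        placed = centers[:i]
        placed_r = radii[:i]
        done = False
        if i > 0 and rng.random() < params.touching_rate:
            # deliberately place touching a random earlier cell
            j = int(rng.integers(i))
            for _ in range(params.max_retries):
                d = (ri + radii[j]) * rng.uniform(0.75, 0.95)
                theta = rng.uniform(0, 2 * np.pi)
                cand = centers[j] + d * np.array([np.sin(theta), np.cos(theta)])
                if not (margin[i] <= cand[0] <= h - margin[i] - 1
                        and margin[i] <= cand[1] <= w - margin[i] - 1):
                    continue
                others = np.delete(np.arange(i), j)
                if len(others):
                    dist = np.hypot(*(placed[others] - cand).T)
                    if np.any(dist < ri + placed_r[others] + params.min_gap):
                        continue
                centers[i] = cand
                done = True
                break
        if not done:
            for _ in range(params.max_retries):
                cand = np.array([
                    rng.uniform(margin[i], h - margin[i] - 1),
                    rng.uniform(margin[i], w - margin[i] - 1),
                ])
                if i:
                    dist = np.hypot(*(placed - cand).T)
                    if np.any(dist < ri + placed_r + params.min_gap):
                        continue
                centers[i] = cand
                done = True
                break
        if not done:
            raise CapacityError(
                f"could not place cell {i + 1}/{n} after "
                f"{params.max_retries} retries; field too crowded")
    return centers


def _tile_layout(field_shape: tuple[int, int], grid_shape: tuple[int, int],
                 overlap_frac: float) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    """Tile size and (row, col) pixel offsets covering the field exactly."""
    sizes = []
    offsets_1d = []
    for extent, ntiles in zip(field_shape, grid_shape):
        if ntiles == 1:
            sizes.append(extent)
            offsets_1d.append([0])
            continue
        t = math.ceil(extent / (ntiles - (ntiles - 1) * overlap_frac))
        step = (extent - t) / (ntiles - 1)
        offs = [round(k * step) for k in range(ntiles)]
        offs[-1] = extent - t
        sizes.append(t)
        offsets_1d.append(offs)
    layout = [(r, c) for r in offsets_1d[0] for c in offsets_1d[1]]
    return (sizes[0], sizes[1]), layout


def render_sample(events: EventTable, truth: GroundTruth,
                  image_params: Optional[ImageParams] = None
                  ) -> tuple[TileGrid, GroundTruth]:
    """Render an event table as tiled 16-bit microscopy images.

    Each cell contributes its Hoechst intensity over a filled nuclear disc
    of its planted radius and every other marker over a cytoplasmic disc
    dilated by ``cyto_margin``. Pixel value = background + signal +
    Gaussian noise, clipped to [0, 65535]. The per-pixel truth mask
    (nucleus labels, ties to the nearest center, emitted before noise) is
    attached to the returned :class:`GroundTruth`, together with the
    noise-free un-tiled field for oracle comparisons.
    """
    params = image_params or ImageParams()
    seed = params.seed if params.seed is not None else events.provenance.get("seed")
    if seed is None:
        raise ValidationError("render_sample needs a seed (ImageParams.seed "
                              "or events.provenance['seed'])")
    rng = _render_rng(int(seed))

    n = len(events)
    radii = truth.table["radius_px"].to_numpy()
    radii = np.clip(np.round(radii), 2, None).astype(int)
    centers = _place_cells(radii.astype(float), params, rng)

    h, w = params.field_shape
    n_ch = len(events.channel_names)
    field_arr = np.zeros((n_ch, h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.int32)
    best_d2 = np.full((h, w), np.inf)

    amplitudes = events.data[list(events.channel_names)].to_numpy()
    hoechst_idx = events.channel_names.index("hoechst")

    for i in range(n):
        cy, cx = centers[i]
        r = radii[i]
        rr, cc = disk((cy, cx), r, shape=(h, w))
        field_arr[hoechst_idx, rr, cc] += amplitudes[i, hoechst_idx]
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        closer = d2 < best_d2[rr, cc]
        mask[rr[closer], cc[closer]] = i + 1
        best_d2[rr[closer], cc[closer]] = d2[closer]
        rr2, cc2 = disk((cy, cx), r + params.cyto_margin, shape=(h, w))
        for j in range(n_ch):
            if j != hoechst_idx:
                field_arr[j, rr2, cc2] += amplitudes[i, j]

    clean_field = field_arr + params.background
    noisy = clean_field + rng.normal(0.0, params.noise_sd, size=field_arr.shape) \
        if params.noise_sd > 0 else clean_field.copy()
    noisy = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)

    tile_shape, offsets = _tile_layout(params.field_shape, params.grid_shape,
                                       params.overlap_frac)
    th, tw = tile_shape
    tiles = [noisy[:, r0:r0 + th, c0:c0 + tw].copy() for (r0, c0) in offsets]

    grid = TileGrid(tiles=tiles, offsets=offsets,
                    channel_names=events.channel_names,
                    meta={"sample_id": events.sample_id,
                          "capture_antibody": events.capture_antibody,
                          "field_shape": params.field_shape,
                          "background": params.background,
                          "noise_sd": params.noise_sd,
                          "seed": int(seed)})

    out_truth_table = truth.table.copy()
    out_truth_table["row"] = centers[:, 0]
    out_truth_table["col"] = centers[:, 1]
    out_truth = GroundTruth(table=out_truth_table, mask=mask)
    # noise-free field retained for stitching oracles
    out_truth.clean_field = np.clip(clean_field, 0, 65535)  # type: ignore[attr-defined]
    return grid, out_truth


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

# Class-level staining defaults (median AU, geometric SD), chosen so that
# gated channels separate by at least one decade between their planted
# positive and negative classes (as the clearly separated clusters in real
# gating plots do): CD45 WBC 3000 vs MYELOID 80 ("CD45-low") vs CTC 8;
# CD11b MYELOID 1200 vs everything else ~12-15; pCK CTC 400 vs negatives 10.
_BASE: dict[str, dict[str, tuple[float, float]]] = {
    "WBC": {"hoechst": (3000, 1.3), "cd45": (3000, 1.45), "cd11b": (15, 1.7),
            "pck": (10, 1.6), "pdl1": (20, 1.6), "isotype": (8, 1.6),
            "capture": (15, 1.7)},
    "MYELOID": {"hoechst": (3000, 1.3), "cd45": (80, 1.4), "cd11b": (1200, 1.5),
                "pck": (150, 1.6), "pdl1": (800, 1.6), "isotype": (100, 1.6),
                "capture": (20, 1.7)},
    "CTC": {"hoechst": (3000, 1.3), "cd45": (8, 1.8), "cd11b": (12, 1.7),
            "pck": (400, 1.6), "pdl1": (300, 1.7), "isotype": (8, 1.6),
            "capture": (500, 1.6)},
    "OTHER": {"hoechst": (3000, 1.3), "cd45": (8, 1.8), "cd11b": (12, 1.7),
              "pck": (10, 1.6), "pdl1": (20, 1.6), "isotype": (8, 1.6),
              "capture": (15, 1.7)},
}
_RADII: dict[str, tuple[float, float]] = {
    "WBC": (7, 1.10), "MYELOID": (11, 1.10), "CTC": (9, 1.12), "OTHER": (7, 1.10),
}


def _pop(cls: str, frequency: float, *, name: Optional[str] = None,
         standard_positive: Optional[bool] = None,
         **channel_overrides: tuple[float, float]) -> PopulationSpec:
    params = dict(_BASE[cls])
    params.update(channel_overrides)
    if standard_positive is None:
        standard_positive = cls in ("CTC", "MYELOID")
    return PopulationSpec(
        name=name or cls,
        frequency=frequency,
        channel_params={ch: LogNormalParams(*params[ch]) for ch in CHANNELS},
        size_params=LogNormalParams(*_RADII[cls]),
        truth_class=cls,
        standard_positive=standard_positive,
    )


def _seed_for(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# Per-figure planted vectors. Printed sources give the endpoints and means;
# middle values are constrained choices (see docs/methods.md).
FIG1_PCK_RATIOS = (8.0, 9.0, 22.0)          # mean 13
FIG1_ISOTYPE_RATIOS = (12.0, 19.0, 38.0)    # mean 23
FIG2D_MYELOID_FRACTIONS = {"EpCAM": 0.22, "MUC1": 0.27, "Vim": 0.47}
FIG2E_MYELOID_FRACTIONS = {
    "Vim":   (0.45, 0.30, 0.66, 0.61, 0.03),   # mean 0.41
    "EpCAM": (0.18, 0.10, 0.32, 0.26, 0.04),   # mean 0.18
    "MUC1":  (0.20, 0.12, 0.35, 0.28, 0.05),   # mean 0.20
}
FIG3_CONTAMINATION = {
    "EpCAM": (0.33, 0.71, 1.00, 1.00),          # mean 0.76
    "MUC1":  (0.33, 0.63, 1.00, 1.00),          # mean 0.74
}
S1_FP_FRACTIONS = (0.10, 0.12, 0.10, 0.20)      # mean 0.13
FIG4_MYELOID_FRACTIONS = (0.05, 0.10, 0.03, 0.08, 0.15, 0.06, 0.12)
FIG4_CTC_PDL1_MEDIANS = (500, 80, 1200, 200, 50, 900, 300)


def _preset_fig1_flow(base_seed: int, n_cells: int) -> list[SampleScenario]:
    """Three buffy-coat 'patients' for the flow-style fold-change analysis.

    CD45-depleted buffy coat: residual WBCs, a large CD45-low/CD11b+
    myeloid population, and CD11b-/CD45- comparison cells; no CTCs. The
    myeloid pCK and isotype medians are the OTHER-class medians scaled by
    the planted fold-changes (equal geometric SDs, so the ratio of
    arithmetic means equals the ratio of medians).
    """
    scenarios = []
    for i, (r_pck, r_iso) in enumerate(zip(FIG1_PCK_RATIOS, FIG1_ISOTYPE_RATIOS)):
        pops = (
            _pop("WBC", 0.30),
            _pop("MYELOID", 0.35, pck=(10 * r_pck, 1.6), isotype=(8 * r_iso, 1.6)),
            _pop("OTHER", 0.35),
        )
        scenarios.append(SampleScenario(
            sample_id=f"fig1-patient{i + 1}", capture_antibody="EpCAM",
            patient_id=f"p{i + 1}",
            populations=pops, n_cells=n_cells, seed=_seed_for(base_seed, i)))
    return scenarios


def _capture_mix(myeloid_frac: float, ctc_frac: float = 0.05,
                 ctc_overrides: Optional[dict] = None) -> tuple[PopulationSpec, ...]:
    wbc = 1.0 - myeloid_frac - ctc_frac
    pops = [_pop("WBC", round(wbc, 10)), _pop("MYELOID", myeloid_frac)]
    if ctc_frac > 0:
        pops.append(_pop("CTC", ctc_frac, **(ctc_overrides or {})))
    return tuple(pops)


def _preset_fig2d(base_seed: int, n_cells: int) -> list[SampleScenario]:
    """One patient, three parallel captures (EpCAM / MUC1 / Vim)."""
    return [
        SampleScenario(sample_id=f"fig2d-{ab}", capture_antibody=ab,
                       patient_id="p1",
                       populations=_capture_mix(FIG2D_MYELOID_FRACTIONS[ab]),
                       n_cells=n_cells, seed=_seed_for(base_seed, i))
        for i, ab in enumerate(("EpCAM", "MUC1", "Vim"))
    ]


def _preset_fig2e(base_seed: int, n_cells: int) -> list[SampleScenario]:
    """Five patients x three captures; Vim mean CD11b+ fraction 41%."""
    scenarios = []
    i = 0
    for ab in ("EpCAM", "MUC1", "Vim"):
        for pat, frac in enumerate(FIG2E_MYELOID_FRACTIONS[ab]):
            scenarios.append(SampleScenario(
                sample_id=f"fig2e-p{pat + 1}-{ab}", capture_antibody=ab,
                patient_id=f"p{pat + 1}", populations=_capture_mix(frac),
                n_cells=n_cells, seed=_seed_for(base_seed, i)))
            i += 1
    return scenarios


def _preset_fig3(base_seed: int, n_cells: int) -> list[SampleScenario]:
    """Four patients x two captures; planted contamination of the
    standard-identified CTC pool (pCK+/CD45-) set per patient."""
    scenarios = []
    i = 0
    pos_total = 0.18  # planted share of cells meeting the standard definition
    for ab in ("EpCAM", "MUC1"):
        for pat, contam in enumerate(FIG3_CONTAMINATION[ab]):
            f_mye = round(contam * pos_total, 10)
            f_ctc = round((1.0 - contam) * pos_total, 10)
            pops = [_pop("WBC", 0.60), _pop("OTHER", 0.22),
                    _pop("MYELOID", f_mye)]
            if f_ctc > 0:
                pops.append(_pop("CTC", f_ctc))
            scenarios.append(SampleScenario(
                sample_id=f"fig3-p{pat + 1}-{ab}", capture_antibody=ab,
                patient_id=f"p{pat + 1}",
                populations=tuple(pops), n_cells=n_cells,
                seed=_seed_for(base_seed, i)))
            i += 1
    return scenarios


def _preset_fig4(base_seed: int, n_cells: int) -> list[SampleScenario]:
    """Seven MUC1-captured patients with per-patient CTC PD-L1 levels; the
    myeloid class carries bright PD-L1, so including false-positives skews
    the CTC PD-L1 readout by a patient-dependent amount."""
    scenarios = []
    for i, (f_mye, pdl1_med) in enumerate(zip(FIG4_MYELOID_FRACTIONS,
                                              FIG4_CTC_PDL1_MEDIANS)):
        pops = (
            _pop("WBC", round(0.92 - f_mye - 0.25, 10)),
            _pop("OTHER", 0.25),
            _pop("MYELOID", f_mye),
            _pop("CTC", 0.08, pdl1=(float(pdl1_med), 1.7)),
        )
        scenarios.append(SampleScenario(
            sample_id=f"fig4-p{i + 1}", capture_antibody="MUC1",
            patient_id=f"p{i + 1}",
            populations=pops, n_cells=n_cells, seed=_seed_for(base_seed, i)))
    return scenarios


def _preset_s1(base_seed: int, n_cells: int) -> list[SampleScenario]:
    """Surface-marker identification: CTCs called MUC1+/CD45- instead of
    pCK+/CD45-. Only the small MUC1-bright myeloid subset contaminates the
    identified pool, planting low false-positive fractions."""
    scenarios = []
    f_ctc = 0.09
    f_mye_total = 0.12
    for i, fp in enumerate(S1_FP_FRACTIONS):
        f_pos = round(fp / (1.0 - fp) * f_ctc, 10)   # MUC1-bright myeloid
        pops = (
            _pop("WBC", 0.59),
            _pop("OTHER", 0.20),
            _pop("MYELOID", round(f_mye_total - f_pos, 10),
                 name="MYELOID_capture_neg", standard_positive=False),
            _pop("MYELOID", f_pos, name="MYELOID_capture_pos",
                 capture=(450, 1.6), standard_positive=True),
            _pop("CTC", f_ctc),
        )
        scenarios.append(SampleScenario(
            sample_id=f"s1-p{i + 1}", capture_antibody="MUC1",
            patient_id=f"p{i + 1}",
            populations=pops, n_cells=n_cells, seed=_seed_for(base_seed, i),
            id_marker="capture"))
    return scenarios


_PRESETS = {
    "fig1_flow": (_preset_fig1_flow, 5000),
    "fig2d_capture": (_preset_fig2d, 1200),
    "fig2e_capture": (_preset_fig2e, 2000),
    "fig3_falsepos": (_preset_fig3, 2000),
    "fig4_pdl1": (_preset_fig4, 3000),
    "s1_muc1": (_preset_s1, 4000),
}
PRESET_NAMES = tuple(_PRESETS)


def make_scenario(preset_name: str, *, seed: int = 0,
                  n_cells: Optional[int] = None,
                  capture_antibody: Optional[str] = None,
                  sample_id: Optional[str] = None) -> list[SampleScenario]:
    """Build the scenarios of a named preset.

    ``seed`` is a base seed; each scenario gets an independent derived
    seed, so the whole preset is reproducible from one integer. Optional
    filters restrict by capture antibody or sample id.
    """
    try:
        builder, default_n = _PRESETS[preset_name]
    except KeyError:
        raise LookupError_(f"unknown preset {preset_name!r}; "
                           f"known: {sorted(_PRESETS)}") from None
    scenarios = builder(seed, n_cells or default_n)
    if capture_antibody is not None:
        scenarios = [s for s in scenarios if s.capture_antibody == capture_antibody]
    if sample_id is not None:
        scenarios = [s for s in scenarios if s.sample_id == sample_id]
    return scenarios
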