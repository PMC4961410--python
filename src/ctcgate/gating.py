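"""Sequential gating and data-driven thresholding.

Flow-cytometry practice separates populations by drawing gates through the
low-density valleys between clusters on intensity axes. This module
automates that rationale: a positive/negative cutoff per channel is placed
at the kernel-density valley between the two dominant modes of the
log-transformed intensities of a *representative* sample, then applied
uniformly across the batch. Classification trees mirror the published
gating strategies:

* standard CTC definition — identification marker bright, CD45 dim
  (pCK+/CD45-);
* strict definition — additionally CD11b dim, relabeling CD11b-bright
  "standard CTCs" as myeloid false-positives.

CD45-low and CD45-negative cells are deliberately not distinguished: both
fall below the CD45 cutoff, as in the two-sided CD45 gate of the source
workflow. Boundary values always belong to the positive side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.stats import gaussian_kde
from shapely.geometry import Polygon

from .core import (
    LABEL_CTC_STANDARD,
    LABEL_CTC_STRICT,
    LABEL_MYELOID_FP,
    LABEL_OTHER,
    LABEL_WBC,
    ConfigurationError,
    EventTable,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "ValleyResult",
    "ThresholdSet",
    "Gate",
    "GatingStrategy",
    "derive_threshold",
    "derive_thresholds",
    "apply_gate",
    "run_strategy",
    "classify_standard",
    "classify_strict",
    "classify_leukocyte_axes",
]

MIN_VALUES_FOR_THRESHOLD = 50
#: depth a valley must reach relative to the lower of its two modes
_VALLEY_DEPTH_FACTOR = 0.9
#: minimum mode separation (decades) for a split to count as two populations
_MIN_MODE_SEPARATION = 0.25
#: a mode must reach this fraction of the dominant mode's density to count
#: as a population rather than a sampling wiggle in the tail
_MIN_MODE_HEIGHT_FRACTION = 0.05


# ---------------------------------------------------------------------------
# threshold derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValleyResult:
    """Outcome of density-valley threshold derivation.

    ``status`` is ``"ok"`` or ``"no_valley"`` (unimodal input); ``cutoff``
    is on the original intensity scale.
    """

    status: str
    cutoff: Optional[float] = None
    modes: tuple[float, ...] = ()

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def derive_threshold(values: Sequence[float], method: str = "kde_valley",
                     grid_size: int = 512) -> ValleyResult:
    """Place a positive/negative cutoff at the density valley.

    Intensities are log10-transformed (with +1 offset so zeros are legal),
    a Gaussian KDE with Silverman bandwidth is evaluated on a grid, and
    the cutoff is the density minimum between the two highest-density
    modes, mapped back to the intensity scale. Unimodal data (or a dip
    too shallow to call a valley) yields ``no_valley`` rather than a
    cutoff.
    """
    if method != "kde_valley":
        raise ValidationError(f"unknown threshold method {method!r}")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < MIN_VALUES_FOR_THRESHOLD:
        raise InsufficientDataError(
            f"need >= {MIN_VALUES_FOR_THRESHOLD} values, got {len(v)}")
    if np.any(v < 0):
        raise ValidationError("intensities must be >= 0")
    x = np.log10(v + 1.0)
    if np.ptp(x) == 0:
        return ValleyResult("no_valley")
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min() - 0.1, x.max() + 0.1, grid_size)
    dens = kde(grid)

    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    peaks = interior[is_max]
    peaks = peaks[dens[peaks] >= _MIN_MODE_HEIGHT_FRACTION * dens.max()]
    if len(peaks) < 2:
        return ValleyResult("no_valley")

    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if grid[hi] - grid[lo] < _MIN_MODE_SEPARATION:
        return ValleyResult("no_valley")
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    if dens[valley] >= _VALLEY_DEPTH_FACTOR * min(dens[lo], dens[hi]):
        return ValleyResult("no_valley")
    cutoff = float(10 ** grid[valley] - 1.0)
    return ValleyResult("ok", cutoff=cutoff,
                        modes=(float(10 ** grid[lo] - 1), float(10 ** grid[hi] - 1)))


@dataclass
class ThresholdSet:
    """Per-channel cutoffs plus their provenance.

    Derived once on a representative sample and applied verbatim to every
    sample of a batch.
    """

    cutoffs: dict[str, float]
    source_sample: str = ""
    method: str = "kde_valley"

    def __post_init__(self) -> None:
        for ch, c in self.cutoffs.items():
            if not np.isfinite(c) or c <= 0:
                raise ValidationError(f"cutoff for {ch!r} must be finite and > 0")

    def __getitem__(self, channel: str) -> float:
        try:
            return self.cutoffs[channel]
        except KeyError:
            raise ConfigurationError(f"no cutoff derived for channel {channel!r}") from None

    def __contains__(self, channel: str) -> bool:
        return channel in self.cutoffs


def derive_thresholds(events: EventTable, channels: Sequence[str],
                      manual: Optional[dict[str, float]] = None) -> ThresholdSet:
    """Derive a :class:`ThresholdSet` from one representative sample.

    ``manual`` cutoffs override derivation per channel. Channels whose
    distribution shows no valley are omitted (accessing them later raises
    a configuration error).
    """
    manual = manual or {}
    cutoffs: dict[str, float] = {}
    for ch in channels:
        if ch in manual:
            cutoffs[ch] = float(manual[ch])
            continue
        res = derive_threshold(events.data[ch].to_numpy())
        if res.ok:
            cutoffs[ch] = res.cutoff  # type: ignore[assignment]
    return ThresholdSet(cutoffs=cutoffs, source_sample=events.sample_id)


# ---------------------------------------------------------------------------
# gates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gate:
    """One include/exclude region on one or two event-table axes.

    ``region`` is either a 1-D threshold ``("ge"|"lt", value)`` on
    ``x_axis``, an axis-aligned rectangle ``(xmin, xmax, ymin, ymax)``, or
    a polygon (sequence of (x, y) vertices, implicitly closed). Boundary
    points count as inside the region.
    """

    name: str
    x_axis: str
    region: tuple
    y_axis: Optional[str] = None
    kind: str = "threshold"          # threshold | rectangle | polygon
    mode: str = "include"            # include | exclude

    def __post_init__(self) -> None:
        if self.mode not in ("include", "exclude"):
            raise ValidationError(f"gate mode must be include/exclude: {self.mode}")
        if self.kind == "threshold":
            op, _ = self.region
            if op not in ("ge", "lt"):
                raise ValidationError(f"threshold polarity must be ge/lt: {op}")
        elif self.kind == "rectangle":
            xmin, xmax, ymin, ymax = self.region
            if xmin > xmax or ymin > ymax:
                raise ValidationError("rectangle bounds must be ordered")
            if self.y_axis is None:
                raise ValidationError("rectangle gate needs y_axis")
        elif self.kind == "polygon":
            if self.y_axis is None:
                raise ValidationError("polygon gate needs y_axis")
            poly = Polygon(self.region)
            if not poly.is_valid:
                raise ValidationError("polygon must be non-self-intersecting")
        else:
            raise ValidationError(f"unknown gate kind {self.kind!r}")


def apply_gate(events: EventTable, gate: Gate) -> np.ndarray:
    """Per-event retention booleans for one gate.

    Include-mode retains events inside the region; exclude-mode retains
    events outside it. Points on the region boundary are inside.
    """
    df = events.data
    if gate.x_axis not in df.columns:
        raise ValidationError(f"axis {gate.x_axis!r} not in event table")
    x = df[gate.x_axis].to_numpy(dtype=float)
    if gate.kind == "threshold":
        op, value = gate.region
        inside = x >= value if op == "ge" else x < value
    else:
        if gate.y_axis not in df.columns:
            raise ValidationError(f"axis {gate.y_axis!r} not in event table")
        y = df[gate.y_axis].to_numpy(dtype=float)
        if gate.kind == "rectangle":
            xmin, xmax, ymin, ymax = gate.region
            inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        else:
            poly = Polygon(gate.region)
            pts = shapely.points(x, y)
            inside = shapely.covers(poly, pts)  # covers: boundary is inside
    return inside if gate.mode == "include" else ~inside


@dataclass
class GatingStrategy:
    """Ordered gates; events failing a gate take its ``exclude_label`` and
    never re-enter, events passing every gate take ``retained_label``."""

    gates: list[Gate]
    exclude_labels: list[str]
    retained_label: str = LABEL_CTC_STANDARD

    def __post_init__(self) -> None:
        if not self.gates:
            raise ValidationError("strategy needs at least one gate")
        if len(self.gates) != len(self.exclude_labels):
            raise ValidationError("one exclude label per gate required")


def run_strategy(events: EventTable, strategy: GatingStrategy
                 ) -> tuple[EventTable, pd.DataFrame]:
    """Apply gates sequentially; returns the labeled table and an audit
    trail (event_id, gate name that excluded it, or retained)."""
    labels = np.full(len(events), strategy.retained_label, dtype=object)
    excluded_by = np.full(len(events), "", dtype=object)
    alive = np.ones(len(events), dtype=bool)
    for gate, excl_label in zip(strategy.gates, strategy.exclude_labels):
        retained = apply_gate(events, gate)
        newly_out = alive & ~retained
        labels[newly_out] = excl_label
        excluded_by[newly_out] = gate.name
        alive &= retained
    out = events.copy()
    out.data["label"] = labels
    audit = pd.DataFrame({
        "event_id": events.data["event_id"].to_numpy(),
        "label": labels,
        "excluded_by": excluded_by,
    })
    return out, audit


# ---------------------------------------------------------------------------
# CTC classification trees
# ---------------------------------------------------------------------------

def _required(thresholds: ThresholdSet, channels: Sequence[str]) -> None:
    missing = [c for c in channels if c not in thresholds]
    if missing:
        raise ConfigurationError(f"missing cutoffs for channels: {missing}")


def classify_standard(events: EventTable, thresholds: ThresholdSet,
                      id_marker: str = "pck") -> pd.Series:
    """Standard CTC identification (no myeloid exclusion).

    ``CTC_standard`` if the identification marker is at/above its cutoff
    and CD45 below its cutoff; ``WBC`` if CD45 at/above cutoff; ``OTHER``
    otherwise.
    """
    _required(thresholds, [id_marker, "cd45"])
    df = events.data
    pos = df[id_marker].to_numpy() >= thresholds[id_marker]
    cd45_hi = df["cd45"].to_numpy() >= thresholds["cd45"]
    labels = np.where(cd45_hi, LABEL_WBC,
                      np.where(pos, LABEL_CTC_STANDARD, LABEL_OTHER))
    return pd.Series(labels, index=df.index, name="label_standard")


def classify_strict(events: EventTable, thresholds: ThresholdSet,
                    id_marker: str = "pck") -> pd.Series:
    """Strict CTC identification with CD11b exclusion.

    As :func:`classify_standard`, then standard CTCs with CD11b at/above
    its cutoff are relabeled ``MYELOID_FP``; the rest become
    ``CTC_strict``. By construction the strict set is a subset of the
    standard set and the two differ exactly by the false-positives.
    """
    _required(thresholds, [id_marker, "cd45", "cd11b"])
    std = classify_standard(events, thresholds, id_marker=id_marker).to_numpy()
    cd11b_hi = events.data["cd11b"].to_numpy() >= thresholds["cd11b"]
    labels = std.copy()
    is_std = std == LABEL_CTC_STANDARD
    labels[is_std & cd11b_hi] = LABEL_MYELOID_FP
    labels[is_std & ~cd11b_hi] = LABEL_CTC_STRICT
    return pd.Series(labels, index=events.data.index, name="label_strict")


def classify_leukocyte_axes(events: EventTable, thresholds: ThresholdSet
                            ) -> pd.Series:
    """CD45/CD11b quadrant labels for fold-change comparisons.

    ``CD11B_POS`` — CD11b at/above cutoff (the CD45-low myeloid gate);
    ``CD45_POS`` — CD11b dim but CD45 bright; ``DN`` — double negative
    (the CD11b-/CD45- comparison population).
    """
    _required(thresholds, ["cd45", "cd11b"])
    df = events.data
    cd11b_hi = df["cd11b"].to_numpy() >= thresholds["cd11b"]
    cd45_hi = df["cd45"].to_numpy() >= thresholds["cd45"]
    labels = np.where(cd11b_hi, "CD11B_POS",
                      np.where(cd45_hi, "CD45_POS", "DN"))
    return pd.Series(labels, index=df.index, name="label_quadrant")
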