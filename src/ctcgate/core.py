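"""Shared types, errors and the marker panel.

The pipeline quantifies per-cell mean fluorescence intensity (MFI) for a
fixed immunofluorescence panel used in circulating-tumor-cell (CTC)
analysis:

* ``hoechst`` — nuclear stain, used for segmentation only;
* ``cd45``    — pan-leukocyte antigen, the traditional CTC exclusion marker;
* ``cd11b``   — myeloid integrin, the additional exclusion marker that
  separates CD45-low myeloid cells from true CTCs;
* ``pck``     — pan-cytokeratin, the traditional positive CTC marker;
* ``pdl1``    — PD-L1, the checkpoint biomarker quantified on CTCs;
* ``isotype`` — isotype control, measures non-specific intracellular staining;
* ``capture`` — the antigen targeted by the capture antibody
  (EpCAM, MUC1 or vimentin depending on the sample).

Intensities are in arbitrary fluorescence units (AU). Pixel coordinates are
0-based ``(row, col)``; regions are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Ordered marker panel; event tables carry one MFI column per channel.
CHANNELS: tuple[str, ...] = (
    "hoechst", "cd45", "cd11b", "pck", "pdl1", "isotype", "capture",
)

#: Ground-truth cell classes planted by the simulator.
TRUTH_CLASSES: tuple[str, ...] = ("WBC", "MYELOID", "CTC", "OTHER")

#: Capture antibodies the enrichment step can use.
CAPTURE_ANTIBODIES: tuple[str, ...] = ("EpCAM", "MUC1", "Vim")

# Classification labels produced by gating.
LABEL_CTC_STANDARD = "CTC_standard"
LABEL_CTC_STRICT = "CTC_strict"
LABEL_MYELOID_FP = "MYELOID_FP"
LABEL_WBC = "WBC"
LABEL_OTHER = "OTHER"


class CtcGateError(Exception):
    """Base class for all package errors."""


class ValidationError(CtcGateError, ValueError):
    """Malformed input (shapes, missing columns, bad values)."""


class ConfigurationError(CtcGateError, ValueError):
    """Inconsistent configuration (frequencies, missing cutoffs, ...)."""


class LayoutError(CtcGateError, ValueError):
    """Tile layout missing or inconsistent."""


class CapacityError(CtcGateError, RuntimeError):
    """Cell placement failed: field too crowded for the requested count."""


class PairingError(CtcGateError, ValueError):
    """Paired comparison requested on unalignable sample sets."""


class InsufficientDataError(CtcGateError, ValueError):
    """Too few observations for the requested estimate."""


class DegenerateInputError(CtcGateError, ValueError):
    """Statistic undefined on this input (e.g. zero-variance differences)."""


class LookupError_(CtcGateError, KeyError):
    """Unknown preset or named resource."""


@dataclass
class EventTable:
    """One row per cell event.

    ``data`` columns: ``event_id``, ``row``, ``col``, ``area`` plus one MFI
    column per entry of ``channel_names`` and, when ground truth is known,
    ``truth_class``. Event-mode tables (the flow-cytometry emulation) carry
    NaN centroids.
    """

    sample_id: str
    capture_antibody: str
    data: pd.DataFrame
    channel_names: tuple[str, ...] = CHANNELS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("event_id", *self.channel_names)
                   if c not in self.data.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        if self.data["event_id"].duplicated().any():
            raise ValidationError("event_ids must be unique")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_truth(self) -> bool:
        return "truth_class" in self.data.columns

    def copy(self) -> "EventTable":
        return EventTable(self.sample_id, self.capture_antibody,
                          self.data.copy(), self.channel_names,
                          dict(self.provenance))


@dataclass
class GroundTruth:
    """Planted truth for a simulated sample.

    ``table`` has one row per cell: ``event_id``, ``truth_class``, planted
    per-channel medians (``planted_<channel>``) and the drawn radius.
    ``mask`` (image mode only) is the per-pixel label image emitted before
    noise: 0 = background, k = cell k, labels never share a pixel.
    """

    table: pd.DataFrame
    mask: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return len(self.table)


def require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
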