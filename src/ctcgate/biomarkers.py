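"""Per-sample and batch biomarker quantities.

Computes the headline numbers of the analysis: what share of captured
cells are CD11b+, how much of the standard-identified CTC pool is actually
myeloid (the false-positive fraction), population MFI fold-changes, and
PD-L1 level / positivity of the CTC pool under the standard versus the
strict (CD11b-excluding) definition.

Undefined ratios (empty denominators) are flagged ``None``, never silently
zero, so batch means are not skewed by degenerate samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    LABEL_CTC_STRICT,
    LABEL_MYELOID_FP,
    EventTable,
    PairingError,
    ValidationError,
    require_columns,
)

__all__ = [
    "BiomarkerSummary",
    "false_positive_fraction",
    "cd11b_fraction",
    "population_fold_change",
    "pdl1_summary",
    "batch_compare",
    "BatchTable",
]


@dataclass
class BiomarkerSummary:
    """One sample's counts and PD-L1 readout under both CTC criteria.

    ``None`` marks quantities whose denominator was empty (no standard
    CTCs, etc.); ``n_ctc_strict + n_myeloid_fp == n_ctc_standard`` always.
    """

    sample_id: str
    capture_antibody: str
    patient_id: str
    n_events: int
    n_ctc_standard: int
    n_ctc_strict: int
    n_myeloid_fp: int
    cd11b_fraction: Optional[float]
    fp_fraction: Optional[float]
    pdl1_mfi_standard: Optional[float]
    pdl1_mfi_strict: Optional[float]
    pdl1_pos_freq_standard: Optional[float]
    pdl1_pos_freq_strict: Optional[float]
    pdl1_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_ctc_strict + self.n_myeloid_fp != self.n_ctc_standard:
            raise ValidationError("strict + false-positive counts must equal standard count")
        for name in ("cd11b_fraction", "fp_fraction",
                     "pdl1_pos_freq_standard", "pdl1_pos_freq_strict"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} out of [0,1]: {v}")


def _strict_labels(events: EventTable) -> np.ndarray:
    if "label_strict" not in events.data.columns:
        raise ValidationError("events lack strict classification labels "
                              "(run gating.classify_strict first)")
    return events.data["label_strict"].to_numpy()


def false_positive_fraction(events: EventTable) -> Optional[float]:
    """Myeloid share of the standard-identified CTC pool.

    ``n_MYELOID_FP / n_CTC_standard``; ``None`` (flagged undefined) when no
    event met the standard definition.
    """
    labels = _strict_labels(events)
    n_fp = int((labels == LABEL_MYELOID_FP).sum())
    n_std = n_fp + int((labels == LABEL_CTC_STRICT).sum())
    if n_std == 0:
        return None
    return n_fp / n_std


def cd11b_fraction(events: EventTable, cd11b_cutoff: float) -> Optional[float]:
    """Share of all captured events that are CD11b+ (at/above cutoff)."""
    require_columns(events.data, ["cd11b"])
    n = len(events)
    if n == 0:
        return None
    return float((events.data["cd11b"].to_numpy() >= cd11b_cutoff).mean())


def population_fold_change(events: EventTable, group_a: str, group_b: str,
                           channel: str, label_col: str = "label_quadrant"
                           ) -> Optional[float]:
    """Ratio of arithmetic-mean MFI between two labeled groups (a over b).

    ``None`` when either group is empty or the denominator mean is zero.
    """
    require_columns(events.data, [channel, label_col])
    df = events.data
    a = df.loc[df[label_col] == group_a, channel].to_numpy(dtype=float)
    b = df.loc[df[label_col] == group_b, channel].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        return None
    denom = b.mean()
    if denom == 0:
        return None
    return float(a.mean() / denom)


def pdl1_summary(events: EventTable, pdl1_cutoff: Optional[float],
                 cd11b_cutoff: Optional[float] = None) -> BiomarkerSummary:
    """Fill a :class:`BiomarkerSummary` from a strictly classified table.

    PD-L1 MFI is the arithmetic mean over the respective CTC set; the
    positive frequency is the share of that set at/above ``pdl1_cutoff``
    (omitted when no cutoff is available). Standard-criterion quantities
    are computed over strict CTCs plus myeloid false-positives — i.e. the
    standard pool — so the two criteria are reported side by side.
    """
    labels = _strict_labels(events)
    require_columns(events.data, ["pdl1"])
    pdl1 = events.data["pdl1"].to_numpy(dtype=float)

    strict = labels == LABEL_CTC_STRICT
    fp = labels == LABEL_MYELOID_FP
    standard = strict | fp

    def _mfi(sel: np.ndarray) -> Optional[float]:
        return float(pdl1[sel].mean()) if sel.any() else None

    def _posfreq(sel: np.ndarray) -> Optional[float]:
        if pdl1_cutoff is None or not sel.any():
            return None
        return float((pdl1[sel] >= pdl1_cutoff).mean())

    cd11b_frac = None
    if cd11b_cutoff is not None:
        cd11b_frac = cd11b_fraction(events, cd11b_cutoff)

    return BiomarkerSummary(
        sample_id=events.sample_id,
        capture_antibody=events.capture_antibody,
        patient_id=str(events.provenance.get("patient_id", "")
                       or events.sample_id),
        n_events=len(events),
        n_ctc_standard=int(standard.sum()),
        n_ctc_strict=int(strict.sum()),
        n_myeloid_fp=int(fp.sum()),
        cd11b_fraction=cd11b_frac,
        fp_fraction=false_positive_fraction(events),
        pdl1_mfi_standard=_mfi(standard),
        pdl1_mfi_strict=_mfi(strict),
        pdl1_pos_freq_standard=_posfreq(standard),
        pdl1_pos_freq_strict=_posfreq(strict),
        pdl1_cutoff=pdl1_cutoff,
    )


def summaries_to_frame(summaries: Sequence[BiomarkerSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


@dataclass
class BatchTable:
    """Group-wise batch comparison ready for significance testing.

    ``wide`` is sample x group (one value per cell, NaN where missing);
    ``stats`` holds per-group mean and range over defined values.
    """

    value: str
    group_key: str
    wide: pd.DataFrame
    stats: pd.DataFrame
    paired: bool = False

    def paired_groups(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        """Aligned per-sample values for two groups (drops samples missing
        either); raises :class:`PairingError` if nothing aligns."""
        if a not in self.wide.columns or b not in self.wide.columns:
            raise PairingError(f"groups {a!r}/{b!r} not both present")
        sub = self.wide[[a, b]].dropna()
        if len(sub) < 2:
            raise PairingError(f"fewer than 2 paired samples for {a!r} vs {b!r}")
        return sub[a].to_numpy(), sub[b].to_numpy()


def batch_compare(summaries: Sequence[BiomarkerSummary], value: str,
                  group_key: str = "capture_antibody",
                  pair_on: str = "patient_id", paired: bool = False
                  ) -> BatchTable:
    """Aggregate per-sample summaries into a per-group batch table.

    ``value`` names a BiomarkerSummary field; flagged-undefined (None)
    entries stay missing. With ``paired=True`` every group must cover the
    same sample set, otherwise a :class:`PairingError` is raised.
    """
    if len(summaries) < 2:
        raise ValidationError("batch comparison needs >= 2 summaries")
    df = summaries_to_frame(list(summaries))
    if value not in df.columns:
        raise ValidationError(f"unknown summary field {value!r}")
    if group_key not in df.columns:
        raise ValidationError(f"unknown group key {group_key!r}")

    if group_key == "criterion":
        raise ValidationError("use the *_standard/*_strict fields to compare criteria")

    wide = df.pivot_table(index=pair_on, columns=group_key, values=value,
                          aggfunc="first", dropna=False)
    wide = wide.sort_index()
    if paired and wide.isna().any().any():
        raise PairingError(
            "paired comparison requested but sample sets differ between groups")

    rows = []
    for g in sorted(wide.columns):
        vals = wide[g].dropna().to_numpy(dtype=float)
        rows.append({
            group_key: g,
            "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "min": float(vals.min()) if len(vals) else np.nan,
            "max": float(vals.max()) if len(vals) else np.nan,
        })
    stats = pd.DataFrame(rows)
    return BatchTable(value=value, group_key=group_key, wide=wide,
                      stats=stats, paired=paired)
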