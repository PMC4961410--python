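"""Significance testing and per-figure comparison reports.

Group comparisons use Student's t-test, matching the original analysis:
paired tests on per-patient differences, unpaired tests in the Welch
(unequal-variance) form, one- or two-tailed as each comparison requires.
No multiple-testing correction is applied; reports state the number of
tests performed. Significance is called at alpha = 0.05 and starred (*)
in report output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .biomarkers import BatchTable
from .core import DegenerateInputError, ValidationError

__all__ = ["TestResult", "t_test", "build_report", "ALPHA"]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """t statistic, degrees of freedom, p-value and the significance call."""

    statistic: float
    df: float
    p_value: float
    tails: int
    paired: bool
    alternative: str = "two-sided"
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def stars(self) -> str:
        return "*" if self.significant else ""


def t_test(x: Sequence[float], y: Sequence[float], *, paired: bool = False,
           tails: int = 2, alternative: str = "greater") -> TestResult:
    """Student's t-test between two samples.

    Paired: classical one-sample t on the differences, ``df = n - 1``.
    Unpaired: Welch's unequal-variance form with Welch-Satterthwaite
    degrees of freedom. ``tails=1`` tests the direction given by
    ``alternative`` ("greater": mean(x) > mean(y); "less": the reverse);
    ``tails=2`` ignores ``alternative``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tails not in (1, 2):
        raise ValidationError("tails must be 1 or 2")
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")

    if paired:
        if len(x) != len(y):
            raise ValidationError(
                f"paired test needs equal lengths, got {len(x)} and {len(y)}")
        if len(x) < 2:
            raise ValidationError("paired test needs n >= 2")
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError("zero-variance differences: t undefined")
        stat = d.mean() / (sd / np.sqrt(len(d)))
        df = float(len(d) - 1)
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValidationError("unpaired test needs n >= 2 per group")
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx == 0 and vy == 0:
            raise DegenerateInputError("zero variance in both groups: t undefined")
        se2x, se2y = vx / len(x), vy / len(y)
        stat = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
        df = (se2x + se2y) ** 2 / (
            se2x ** 2 / (len(x) - 1) + se2y ** 2 / (len(y) - 1))

    if tails == 2:
        p = 2.0 * t_dist.sf(abs(stat), df)
    elif alternative == "greater":
        p = float(t_dist.sf(stat, df))
    else:
        p = float(t_dist.cdf(stat, df))

    return TestResult(statistic=float(stat), df=float(df), p_value=float(p),
                      tails=tails, paired=paired,
                      alternative="two-sided" if tails == 2 else alternative)


# Per-figure test settings: (paired, tails, alternative).
_FIGURE_TESTS: dict[str, tuple[bool, int, str]] = {
    "fig1": (True, 1, "greater"),
    "fig2e": (True, 1, "greater"),
    "fig3d": (True, 2, "greater"),
    "fig4": (True, 2, "greater"),
    "s1": (True, 2, "greater"),
}


@dataclass
class Report:
    """Deterministic tabular comparison report (markdown + data frame)."""

    figure_key: str
    table: pd.DataFrame
    tests: pd.DataFrame
    markdown: str


def build_report(batch: BatchTable, figure_key: str) -> Report:
    """Group means/ranges plus all pairwise significance tests for one
    figure-style comparison. Deterministic ordering throughout."""
    if batch.wide.empty:
        raise ValidationError("empty batch table")
    if figure_key not in _FIGURE_TESTS:
        raise ValidationError(
            f"unknown figure key {figure_key!r}; known: {sorted(_FIGURE_TESTS)}")
    paired, tails, alternative = _FIGURE_TESTS[figure_key]

    groups = sorted(batch.wide.columns)
    means = {g: batch.wide[g].dropna().mean() for g in groups}
    test_rows = []
    if len(groups) >= 2 and len(batch.wide) >= 2:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a, b = ga, gb
                if tails == 1 and means[b] > means[a]:
                    # one-tailed tests ask whether the larger-mean group
                    # exceeds the other
                    a, b = b, a
                try:
                    xa, xb = batch.paired_groups(a, b)
                    res = t_test(xa, xb, paired=paired, tails=tails,
                                 alternative=alternative)
                    test_rows.append({
                        "group_a": a, "group_b": b, "n_pairs": len(xa),
                        "t": res.statistic, "df": res.df, "p": res.p_value,
                        "tails": tails, "significant": res.significant,
                        "stars": res.stars,
                    })
                except (ValidationError, DegenerateInputError) as exc:
                    test_rows.append({
                        "group_a": a, "group_b": b, "n_pairs": 0,
                        "t": np.nan, "df": np.nan, "p": np.nan,
                        "tails": tails, "significant": False,
                        "stars": "", "note": str(exc),
                    })
    tests = pd.DataFrame(test_rows)

    lines = [f"# Report: {figure_key} ({batch.value} by {batch.group_key})", ""]
    lines.append("| group | n | mean | min | max |")
    lines.append("|---|---|---|---|---|")
    for _, r in batch.stats.iterrows():
        lines.append(f"| {r[batch.group_key]} | {int(r['n'])} | "
                     f"{r['mean']:.4g} | {r['min']:.4g} | {r['max']:.4g} |")
    lines.append("")
    if len(tests):
        kind = ("paired" if paired else "unpaired") + f", {tails}-tailed t-test"
        lines.append(f"{len(tests)} {kind}(s), alpha = {ALPHA} "
                     "(no multiple-testing correction):")
        lines.append("")
        lines.append("| comparison | t | df | p | |")
        lines.append("|---|---|---|---|---|")
        for _, r in tests.iterrows():
            lines.append(f"| {r['group_a']} vs {r['group_b']} | {r['t']:.3f} | "
                         f"{r['df']:.2f} | {r['p']:.4g} | {r['stars']} |")
    else:
        lines.append("No tests performed (single group or single sample).")
    markdown = "\n".join(lines) + "\n"

    return Report(figure_key=figure_key, table=batch.stats.copy(),
                  tests=tests, markdown=markdown)
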