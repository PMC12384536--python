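"""Reprogramming-efficiency summary statistics from printed colony counts.

The packaged fixture holds iPSC colony counts for two adult-fibroblast
lines (AF) and three placental-fibroblast lines (PF) at days 10, 14 and
18 after induction.  Summaries are mean +/- sample SD (n-1 denominator),
rounded half-up to one decimal to match the reporting style; group
comparisons use the pooled-variance (not Welch) unpaired Student t-test,
the variant consistent with the reported day-10 significance bound at
these tiny group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ColonyTable",
    "load_colony_table",
    "colony_summary",
    "pooled_t_test",
    "cloning_efficiency",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at one decimal), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ColonyTable:
    """Long-format colony counts: cell_line, group (AF/PF), day, colony_count."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"cell_line", "group", "day", "colony_count"}
        if not need <= set(self.rows.columns):
            raise ValueError(f"colony table needs columns {sorted(need)}")
        counts = self.rows["colony_count"]
        if (counts < 0).any() or (counts != counts.astype(int)).any():
            raise ValueError("colony counts must be non-negative integers")

    def counts(self, group: str, day: int) -> np.ndarray:
        sel = self.rows[(self.rows["group"] == group) & (self.rows["day"] == day)]
        if sel.empty:
            raise ValueError(f"no rows for group={group!r}, day={day}")
        return sel["colony_count"].to_numpy(dtype=float)


def load_colony_table(path: str | Path | None = None) -> ColonyTable:
    """Load the packaged colony-count fixture (or a user TSV of the same shape)."""
    if path is None:
        ref = resources.files("hybridase").joinpath("data/colony_counts.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return ColonyTable(df)


def colony_summary(table: ColonyTable, group: str, day: int) -> tuple[float, float | None]:
    """Mean and sample SD (n-1) of colony counts, rounded half-up to 1 decimal.

    With a single matching line the SD is undefined and returned as None.
    """
    x = table.counts(group, day)
    mean = round_half_up(float(np.mean(x)))
    if x.size < 2:
        return mean, None
    return mean, round_half_up(float(np.std(x, ddof=1)))


def pooled_t_test(a, b) -> tuple[float, int, float]:
    """Unpaired pooled-variance Student t-test, two-sided.

    Returns (t, df, p) with df = n_a + n_b - 2.  Raises if either group
    has fewer than two observations or the pooled variance is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t is undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def cloning_efficiency(successes: int, total: int) -> float:
    """Percentage of picked colonies yielding stable lines, 1 decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    return round_half_up(100.0 * successes / total)
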