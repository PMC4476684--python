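"""Continuous-variable discretization and univariate variable screening.

Continuous predictors are discretized with the recursive minimum
description length (MDL) entropy method: within each interval the binary
cut maximizing information gain is found (candidate cuts are midpoints
between adjacent distinct values), and the cut is kept only if its gain
exceeds the MDL coding cost

    gain > log2(N - 1)/N + [log2(3^k - 2) - (k H - k1 H1 - k2 H2)]/N,

where k, k1, k2 count the classes present in the interval and its two
halves and H, H1, H2 are the corresponding entropies.  Accepted cuts are
refined recursively until no further cut passes.

Discrete predictors can be screened by the Pearson chi-square statistic of
their contingency table with the target (no continuity correction) — a
ranking device for wide genotype tables, not a significance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .core import DiscreteDataset, class_counts
from .scoring import entropy_bits

__all__ = ["CutPointSet", "mdl_best_cut", "mdl_accepts", "discretize_recursive",
           "apply_cuts", "bin_label", "chi2_rank", "learn_cuts", "discretize_frame"]


@dataclass
class CutPointSet:
    """Per-variable sorted thresholds defining half-open bins (lo, hi].

    Variables with zero accepted cuts become single-bin (constant) and are
    listed in ``uninformative``.
    """

    cuts: dict = field(default_factory=dict)        # name -> tuple of floats
    uninformative: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, cs in self.cuts.items():
            if any(b <= a for a, b in zip(cs, cs[1:])):
                raise ValueError(f"thresholds for {name!r} not strictly increasing")

    # plain-text sidecar: one line per variable, name then thresholds
    def to_text(self) -> str:
        lines = []
        for name, cs in sorted(self.cuts.items()):
            lines.append("\t".join([name] + [repr(float(c)) for c in cs]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CutPointSet":
        cuts = {}
        for line in text.strip().splitlines():
            parts = line.split("\t")
            cuts[parts[0]] = tuple(float(x) for x in parts[1:])
        return cls(cuts=cuts,
                   uninformative=[n for n, c in cuts.items() if not c])


def _encode_labels(labels) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes


def mdl_best_cut(values, labels):
    """Best binary cut of a continuous variable, or None.

    Returns ``(cut, gain_bits)`` maximizing the information gain of the
    induced two-part split, with candidate cuts at midpoints between
    adjacent distinct values whose class compositions differ (a midpoint
    between two groups pure in the same class can never be optimal).
    Returns None when all labels are identical or no candidate exists.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    y = _encode_labels(labels)
    if values.shape[0] != y.shape[0]:
        raise ValueError("values and labels misaligned")
    k = int(y.max()) + 1 if y.size else 0
    if k < 2:
        return None
    order = np.argsort(values, kind="stable")
    v_sorted, y_sorted = values[order], y[order]
    uniq, starts = np.unique(v_sorted, return_index=True)
    if uniq.size < 2:
        return None
    # per-distinct-value class count blocks, then prefix sums
    blocks = np.zeros((uniq.size, k), dtype=np.int64)
    grp = np.searchsorted(uniq, v_sorted)
    np.add.at(blocks, (grp, y_sorted), 1)
    prefix = np.cumsum(blocks, axis=0)
    total = prefix[-1]
    n = total.sum()
    h_parent = entropy_bits(total)
    best = None
    for g in range(uniq.size - 1):
        left_pure = (blocks[g] > 0).sum() == 1
        right_pure = (blocks[g + 1] > 0).sum() == 1
        if left_pure and right_pure and np.argmax(blocks[g]) == np.argmax(blocks[g + 1]):
            continue  # same-class boundary: cannot host the optimum
        c_left = prefix[g]
        n_left = c_left.sum()
        c_right = total - c_left
        gain = (h_parent
                - n_left / n * entropy_bits(c_left)
                - (n - n_left) / n * entropy_bits(c_right))
        if best is None or gain > best[1]:
            best = ((uniq[g] + uniq[g + 1]) / 2.0, float(gain))
    return best


def mdl_accepts(gain: float, n: int, k: int, k1: int, k2: int,
                h: float, h1: float, h2: float) -> bool:
    """MDL acceptance test for a candidate cut (gain in bits)."""
    if n < 2:
        return False
    delta = np.log2(3.0**k - 2.0) - (k * h - k1 * h1 - k2 * h2)
    return gain > (np.log2(n - 1.0) + delta) / n


def _recurse(values: np.ndarray, y: np.ndarray, k_total: int, out: list) -> None:
    best = mdl_best_cut(values, y)
    if best is None:
        return
    cut, gain = best
    left = values <= cut
    counts = np.bincount(y, minlength=k_total)
    c1 = np.bincount(y[left], minlength=k_total)
    c2 = counts - c1
    ok = mdl_accepts(
        gain, values.shape[0],
        int((counts > 0).sum()), int((c1 > 0).sum()), int((c2 > 0).sum()),
        entropy_bits(counts), entropy_bits(c1), entropy_bits(c2),
    )
    if not ok:
        return
    out.append(float(cut))
    _recurse(values[left], y[left], k_total, out)
    _recurse(values[~left], y[~left], k_total, out)


def discretize_recursive(values, labels) -> tuple:
    """All accepted cut points for one variable, sorted ascending.

    Missing (NaN) values are ignored while learning; an empty tuple means
    the variable is uninformative under the MDL test.
    """
    values = np.asarray(values, dtype=float)
    y = _encode_labels(labels)
    keep = np.isfinite(values)
    out: list = []
    yk = y[keep]
    if yk.size:
        _recurse(values[keep], yk, int(yk.max()) + 1, out)
    return tuple(sorted(out))


def bin_label(cuts: tuple, value: float) -> str:
    """Bin label for a value under half-open (lo, hi] intervals."""
    if not cuts:
        return "all"
    i = int(np.searchsorted(np.asarray(cuts), value, side="left"))
    lo = "-inf" if i == 0 else f"{cuts[i - 1]:g}"
    hi = f"{cuts[i]:g}" if i < len(cuts) else "inf"
    return f"({lo},{hi}]"


def apply_cuts(df: pd.DataFrame, cuts: CutPointSet) -> pd.DataFrame:
    """Replace continuous columns by their bin labels; missing stays missing."""
    out = df.copy()
    for name, cs in cuts.cuts.items():
        col = pd.to_numeric(out[name], errors="coerce")
        bad = col.isna() & out[name].notna()
        if bad.any():
            raise ValueError(f"non-numeric value in continuous column {name!r}")
        out[name] = [None if pd.isna(v) else bin_label(cs, v) for v in col]
    return out


def learn_cuts(df: pd.DataFrame, target: str, continuous: list) -> CutPointSet:
    """Learn MDL cuts for each named continuous column against the target."""
    tmask = df[target].notna()
    cuts, flat = {}, []
    for name in continuous:
        vals = pd.to_numeric(df.loc[tmask, name], errors="coerce").to_numpy()
        labels = df.loc[tmask, target].to_numpy()
        cs = discretize_recursive(vals, labels)
        cuts[name] = cs
        if not cs:
            flat.append(name)
    return CutPointSet(cuts=cuts, uninformative=flat)


def discretize_frame(df: pd.DataFrame, target: str, continuous: list) -> tuple:
    """Learn cuts on ``df`` and return (binned frame, CutPointSet)."""
    cps = learn_cuts(df, target, continuous)
    return apply_cuts(df, cps), cps


def chi2_rank(data: DiscreteDataset, top_n: int | None = None) -> list:
    """Rank predictors by the Pearson chi-square statistic vs. the target.

    Rows missing a variable are excluded from that variable's table.
    Returns up to ``top_n`` of (name, statistic), descending; a constant
    (single-level) variable scores 0.  Ties keep schema order.
    """
    stats = []
    for j, spec in enumerate(data.schema):
        col = data.X[:, j]
        present = col >= 0
        table = np.zeros((len(spec.domain), data.n_classes), dtype=np.int64)
        np.add.at(table, (col[present], data.y[present]), 1)
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            stat = 0.0
        else:
            stat = float(chi2_contingency(table, correction=False)[0])
        stats.append((spec.name, stat))
    order = sorted(range(len(stats)), key=lambda i: (-stats[i][1], i))
    if top_n is None or top_n >= len(stats):
        return [stats[i] for i in order]
    return [stats[i] for i in order[:top_n]]
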