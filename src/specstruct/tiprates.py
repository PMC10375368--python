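"""Tip speciation-rate statistics.

The DR (inverse equal-splits) statistic is computed here; model-based tip
rates (CLaDS, BAMM) are produced by external programs and imported from CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = ["dr_statistic", "import_tip_rates", "rate_cv"]

VALID_METHODS = ("DR", "CLaDS", "BAMM", "imported")


def dr_statistic(tree: Phylogeny) -> pd.DataFrame:
    """Inverse equal-splits (DR) speciation-rate statistic, one value per tip.

    For a tip whose root-ward path has edges ``l_1 .. l_N`` (pendant edge
    first), the equal-splits length is ``ES = sum_j l_j * 2**-(j-1)`` and
    ``DR = 1/ES``.  Edges nearer the root contribute with geometrically
    halved weight, so DR is dominated by recent branch lengths — short
    pendant edges give high tip rates.

    Returns a DataFrame with columns ``tip, rate, method``.
    """
    rows = []
    for tip in tree.tips:
        lens = tree.tip_path_lengths(tip)
        weights = 0.5 ** np.arange(len(lens))
        es = float(np.dot(lens, weights))
        if es <= 0:
            raise ValueError(f"tip {tip!r} has zero equal-splits path length; DR undefined")
        rows.append((tip, 1.0 / es, "DR"))
    return pd.DataFrame(rows, columns=["tip", "rate", "method"])


def import_tip_rates(path, tree: Phylogeny, method: str = "imported") -> pd.DataFrame:
    """Read a ``tip,rate`` CSV of externally computed tip rates and validate it.

    Every CSV tip must be a tree tip; tree tips absent from the CSV are
    reported in the returned frame's ``attrs['unmatched_tree_tips']``.
    """
    if method not in VALID_METHODS:
        raise ValueError(f"method must be one of {VALID_METHODS}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no tip-rate rows found")
    if not {"tip", "rate"}.issubset(df.columns):
        raise ValueError(f"{path}: CSV must have columns tip,rate")
    tree_tips = set(tree.tips)
    unknown = sorted(set(df["tip"]) - tree_tips)
    if unknown:
        raise ValueError(f"{path}: tip labels not in tree: {unknown}")
    rates = pd.to_numeric(df["rate"], errors="coerce")
    bad = df.index[rates.isna() | (rates <= 0) | ~np.isfinite(rates)]
    if len(bad):
        # +2: header line plus 1-based indexing
        lines = [int(i) + 2 for i in bad]
        raise ValueError(f"{path}: nonpositive or nonnumeric rate at line(s) {lines}")
    out = pd.DataFrame({"tip": df["tip"], "rate": rates.astype(float), "method": method})
    if out["tip"].duplicated().any():
        dups = sorted(out.loc[out["tip"].duplicated(), "tip"])
        raise ValueError(f"{path}: duplicate tips {dups}")
    out.attrs["unmatched_tree_tips"] = sorted(tree_tips - set(out["tip"]))
    return out


def rate_cv(table: pd.DataFrame) -> float:
    """Coefficient of variation (sample sd / mean) of the tip rates."""
    rates = np.asarray(table["rate"], dtype=float)
    if len(rates) < 2:
        raise ValueError("coefficient of variation needs at least 2 rates")
    return float(np.std(rates, ddof=1) / np.mean(rates))
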