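"""Concordance between the two observation methods.

The substrate is the paired 0.5 s interval table: for each interval both
sources contribute one area label, and agreement is quantified as

* the *matching proportion* — the percentage of coded intervals where both
  sources assign the identical area (sextant and surface);
* the pooled *confusion matrix* over all area labels (combined closed-jaw
  codes included), with each off-diagonal cell classed as an *adjacent*
  confusion (neighbouring sextants on the same surface, or the
  occlusal-vs-smooth decision within a sextant) or a *non-adjacent*, more
  problematic one (e.g. opposite sides of the mouth, vestibular vs oral);
* unweighted Cohen's kappa on the full code or on its sextant/surface
  projections;
* the distribution of per-session matching proportions (median (min; max),
  fractions of sessions reaching 80% / 90%, and histogram export).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import PairedIntervalTable
from .areas import (
    ALL_AREAS_WITH_COMBINED,
    OCCLUSAL,
    VESTIBULAR,
    AreaCode,
    parse_area_code,
    sextants_adjacent,
)
from .errors import UndefinedResultError

MATCH = "match"
ADJACENT = "adjacent"
NON_ADJACENT = "non_adjacent"


def matching_proportion(paired: PairedIntervalTable) -> float:
    """Percentage of coded interval pairs with identical area labels."""
    pairs = paired.coded_pairs()
    if len(pairs) == 0:
        raise UndefinedResultError(
            "matching proportion is undefined: no interval is coded by both sources"
        )
    same = (pairs["vo_label"] == pairs["mt_label"]).mean()
    return 100.0 * float(same)


def confusion_matrix(paired_tables) -> pd.DataFrame:
    """Pooled VO-by-MT cross-tabulation of coded interval labels.

    Rows are VO labels, columns MT labels, both in the fixed area order
    (18 single areas then the combined codes).  Entries sum to the number
    of coded pairs pooled over the supplied sessions.
    """
    if isinstance(paired_tables, PairedIntervalTable):
        paired_tables = [paired_tables]
    labels = list(ALL_AREAS_WITH_COMBINED)
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for paired in paired_tables:
        pairs = paired.coded_pairs()
        ct = pd.crosstab(pairs["vo_label"], pairs["mt_label"])
        mat = mat.add(ct.reindex(index=labels, columns=labels, fill_value=0), fill_value=0)
    mat.index.name = "vo_label"
    mat.columns.name = "mt_label"
    return mat.astype(int)


def adjacency_class(a, b) -> str:
    """Classify a VO/MT label pair as match, adjacent or non-adjacent.

    Adjacent confusions are the benign ones the tracking geometry makes
    likely: same surface in neighbouring sextants (consecutive within an
    arch or vertically opposing), or the occlusal-vs-smooth decision within
    one sextant.  A combined closed-jaw code is adjacent to the vestibular
    area of either member sextant.  Everything else — notably vestibular vs
    oral and opposite sides of the mouth — is non-adjacent.  Symmetric in
    its arguments.
    """
    if not isinstance(a, AreaCode):
        a = parse_area_code(a)
    if not isinstance(b, AreaCode):
        b = parse_area_code(b)
    if a == b:
        return MATCH
    if a.is_combined or b.is_combined:
        comb, other = (a, b) if a.is_combined else (b, a)
        if other.surface == VESTIBULAR and other.sextant in comb.member_sextants:
            return ADJACENT
        return NON_ADJACENT
    if a.surface == b.surface and sextants_adjacent(a.sextant, b.sextant):
        return ADJACENT
    if a.sextant == b.sextant and OCCLUSAL in (a.surface, b.surface):
        return ADJACENT
    return NON_ADJACENT


def heatmap_table(confusion: pd.DataFrame) -> pd.DataFrame:
    """Annotation table for the mismatch heat map.

    One row per *off-diagonal, nonzero* cell (matches on the diagonal are
    excluded; empty cells are omitted), with the mismatch count, a grey
    intensity proportional to count (1.0 for the largest cell) and the
    adjacency class that decides grey-vs-red shading.
    """
    rows = []
    off_max = 0
    for vo in confusion.index:
        for mt in confusion.columns:
            if vo == mt:
                continue
            c = int(confusion.loc[vo, mt])
            if c > 0:
                rows.append({"vo_label": vo, "mt_label": mt, "count": c})
                off_max = max(off_max, c)
    for row in rows:
        row["intensity"] = row["count"] / off_max
        row["adjacency"] = adjacency_class(row["vo_label"], row["mt_label"])
    return pd.DataFrame(rows, columns=["vo_label", "mt_label", "count", "intensity", "adjacency"])


def plot_heatmap(confusion: pd.DataFrame, path=None):
    """Render the mismatch heat map (grey by count, red for non-adjacent).

    Requires matplotlib; the diagonal is drawn white, as the match counts
    would otherwise dwarf every mismatch.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ann = heatmap_table(confusion)
    n = len(confusion)
    img = np.ones((n, n, 3))
    pos = {lab: i for i, lab in enumerate(confusion.index)}
    for _, row in ann.iterrows():
        i, j = pos[row["vo_label"]], pos[row["mt_label"]]
        shade = 1.0 - 0.85 * row["intensity"]
        if row["adjacency"] == NON_ADJACENT:
            img[i, j] = (1.0, shade, shade)
        else:
            img[i, j] = (shade, shade, shade)
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(img, interpolation="nearest")
    ax.set_xticks(range(n), confusion.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(n), confusion.index, fontsize=7)
    ax.set_xlabel("MT label")
    ax.set_ylabel("VO label")
    for _, row in ann.iterrows():
        i, j = pos[row["vo_label"]], pos[row["mt_label"]]
        ax.text(j, i, str(row["count"]), ha="center", va="center", fontsize=5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def _project(codes, dimension: str) -> np.ndarray:
    codes = pd.Series(np.asarray(codes, dtype=object)).astype(str)
    if dimension == "area":
        return codes.to_numpy()
    if dimension == "sextant":
        return codes.str[:2].to_numpy()
    if dimension == "surface":
        return codes.str[2:].to_numpy()
    raise ValueError(f"unknown dimension {dimension!r}")


def cohen_kappa(codes_a, codes_b, dimension: str = "area") -> float:
    """Unweighted Cohen's kappa between two coded sequences.

    ``dimension`` selects the full area code or its sextant / surface
    projection.  kappa = (po - pe) / (1 - pe) with po the observed and pe
    the chance agreement from the marginal label frequencies.  Two
    identical constant sequences have pe = 1; that degenerate case is
    defined as perfect agreement (1.0) with a warning.
    """
    a = _project(codes_a, dimension)
    b = _project(codes_b, dimension)
    if a.size != b.size:
        raise ValueError("sequences must have equal length")
    if a.size == 0:
        raise UndefinedResultError("kappa is undefined for empty sequences")
    po = float(np.mean(a == b))
    labels = np.union1d(a, b)
    pa = np.array([np.mean(a == lab) for lab in labels])
    pb = np.array([np.mean(b == lab) for lab in labels])
    pe = float(pa @ pb)
    if pe >= 1.0 - 1e-12:
        warnings.warn(
            "both sequences are a single identical label; chance agreement "
            "is 1 and kappa is defined as 1.0 by convention"
        )
        return 1.0
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class AgreementSummary:
    """Study-level distribution of per-session matching proportions."""

    median_pct: float
    min_pct: float
    max_pct: float
    fraction_ge_80: float  # percent of sessions with >= 80% matches
    fraction_ge_90: float  # percent of sessions with >= 90% matches
    n_sessions: int
    histogram_edges: tuple
    histogram_counts: tuple

    def __str__(self):
        return (
            f"matching {self.median_pct:.1f}% ({self.min_pct:.1f}; "
            f"{self.max_pct:.1f}), >=80%: {self.fraction_ge_80:.1f}% of "
            f"{self.n_sessions} sessions, >=90%: {self.fraction_ge_90:.1f}%"
        )


def matching_distribution(per_session_pcts) -> AgreementSummary:
    """Summarize per-session matching percentages across a study.

    Reports median (min; max), the inclusive fractions of sessions at or
    above 80% and 90%, and a histogram on 2.5%-wide bins for plotting.
    """
    pcts = np.asarray(list(per_session_pcts), dtype=float)
    if pcts.size == 0:
        raise UndefinedResultError("no sessions supplied")
    edges = np.arange(0.0, 100.0 + 2.5, 2.5)
    counts, _ = np.histogram(pcts, bins=edges)
    return AgreementSummary(
        median_pct=float(np.median(pcts)),
        min_pct=float(pcts.min()),
        max_pct=float(pcts.max()),
        fraction_ge_80=100.0 * float(np.mean(pcts >= 80.0)),
        fraction_ge_90=100.0 * float(np.mean(pcts >= 90.0)),
        n_sessions=int(pcts.size),
        histogram_edges=tuple(edges),
        histogram_counts=tuple(int(c) for c in counts),
    )
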