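"""Deterministic assignment of 3' splice sites to binding clusters C1-C10.

Per site, RT-stop counts over a +/- ``span`` display-coordinate window are
converted into a vector of binding fractions.  Nine major clusters C1..C9
correspond to maximal binding at display positions -6..+2 (C_k at position
k - 7); sites whose maximum lies outside that window, or below a 10%
binding fraction, fall into C10.  Sites supported by 10 or fewer total RT
stops are excluded.  A *cluster switch* is a site assigned to two different
major clusters in the two conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import DISPLAY_OFFSET, RTStopTrack, ValidationError, site_profiles, to_internal

MAJOR_WINDOW = (-6, 2)   # display coordinates covered by C1..C9
EXCLUDED = "excluded"


def fraction_vector(counts: np.ndarray) -> np.ndarray:
    """Convert binding amplitudes to fractions summing to 1 over the span."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("no binding: profile has zero total stops")
    return counts / total


def assign_cluster(fractions: np.ndarray, total_stops: int,
                   offsets_display: np.ndarray,
                   window: tuple[int, int] = MAJOR_WINDOW,
                   min_frac: float = 0.10,
                   min_total: int = 10) -> tuple[str, float, int]:
    """Cluster label, max fraction, and argmax display offset for one site.

    ``total_stops > min_total`` is required (strict, after the source
    figure's "RT stops >10" rule); the global argmax must fall inside the
    major window with fraction >= ``min_frac`` for a major cluster,
    otherwise C10.  Argmax ties break toward the most intronic (most
    negative) offset.
    """
    if total_stops <= min_total:
        return EXCLUDED, np.nan, 0
    offsets_display = np.asarray(offsets_display)
    order = np.argsort(offsets_display, kind="stable")
    fracs = np.asarray(fractions)[order]
    offs = offsets_display[order]
    imax = int(np.argmax(fracs))        # first maximum = most negative offset
    max_frac = float(fracs[imax])
    argmax_off = int(offs[imax])
    lo, hi = window
    if lo <= argmax_off <= hi and max_frac >= min_frac:
        cluster = f"C{argmax_off - lo + 1}"
    else:
        cluster = "C10"
    return cluster, max_frac, argmax_off


def assign_clusters(track: RTStopTrack, sites: pd.DataFrame, span: int = 25,
                    min_frac: float = 0.10, min_total: int = 10,
                    window: tuple[int, int] = MAJOR_WINDOW,
                    display_offset: int = DISPLAY_OFFSET) -> pd.DataFrame:
    """Cluster assignment for every site of one condition's track."""
    disp = np.arange(-span, span + 1)
    internal = to_internal(disp, display_offset)
    profiles = site_profiles(track, sites, int(np.abs(internal).max()))
    cols = np.searchsorted(profiles.offsets, internal)
    counts = profiles.counts[:, cols]

    rows = []
    for i, site_id in enumerate(profiles.site_ids):
        total = int(counts[i].sum())
        if total <= min_total:
            rows.append((site_id, EXCLUDED, np.nan, np.nan, total))
            continue
        cluster, max_frac, argmax_off = assign_cluster(
            fraction_vector(counts[i]), total, disp, window, min_frac, min_total
        )
        rows.append((site_id, cluster, max_frac, argmax_off, total))
    out = pd.DataFrame(
        rows,
        columns=["site_id", "cluster", "max_fraction", "argmax_display", "total_stops"],
    )
    out.insert(1, "condition", track.condition_label)
    return out


def detect_switches(assignments_wt: pd.DataFrame, assignments_mut: pd.DataFrame,
                    majors_only: bool = True) -> pd.DataFrame:
    """Per-site cluster-switch table between two conditions.

    With ``majors_only`` (the default) sites that are C10 or
    excluded in either condition are dropped; a switch is two *different*
    major clusters.
    """
    merged = assignments_wt.merge(
        assignments_mut, on="site_id", suffixes=("_wt", "_mut")
    )
    majors = [f"C{k}" for k in range(1, 10)]
    both_major = merged["cluster_wt"].isin(majors) & merged["cluster_mut"].isin(majors)
    if majors_only:
        merged = merged[both_major].copy()
        merged["switch"] = merged["cluster_wt"] != merged["cluster_mut"]
    else:
        merged = merged.copy()
        merged["switch"] = both_major & (merged["cluster_wt"] != merged["cluster_mut"])
    return merged[["site_id", "cluster_wt", "cluster_mut", "switch"]].reset_index(drop=True)


def cluster_composition(assignments: pd.DataFrame) -> pd.Series:
    """Counts per cluster for one condition's assignment table."""
    order = [f"C{k}" for k in range(1, 11)] + [EXCLUDED]
    counts = assignments["cluster"].value_counts()
    return counts.reindex(order, fill_value=0)


def modal_major_position(assignments: pd.DataFrame,
                         window: tuple[int, int] = MAJOR_WINDOW) -> int:
    """Display position of the most populated major cluster (C1..C9)."""
    majors = [f"C{k}" for k in range(1, 10)]
    counts = cluster_composition(assignments).loc[majors]
    if counts.sum() == 0:
        raise ValidationError("no sites in major clusters")
    modal = counts.idxmax()
    return window[0] + int(modal[1:]) - 1
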