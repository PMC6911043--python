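"""3' splice-site occupancy saturation analysis and metagene cross-link profile.

A 3'SS is *occupied* when at least one RT stop falls within a closed
+/- 20-nt window of the junction.  Per-gene CLIP binding density is the
average number of unique RT-stop positions per 3'SS.  Sorting genes by
density and smoothing with a rolling window of 40 genes yields a saturation
curve whose plateau estimates the maximal occupied fraction of 3'SS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DISPLAY_OFFSET, RTStopTrack, ValidationError, site_profiles, to_display


def call_occupied_sites(track: RTStopTrack, sites: pd.DataFrame,
                        window_nt: int = 20) -> pd.Series:
    """Flag each site occupied iff any RT stop lies within the closed
    junction-offset interval ``[-window_nt, +window_nt]``."""
    if window_nt < 0:
        raise ValidationError("window_nt must be >= 0")
    profiles = site_profiles(track, sites, max(window_nt, 1))
    in_window = np.abs(profiles.offsets) <= window_nt
    occupied = profiles.counts[:, in_window].sum(axis=1) > 0
    return pd.Series(occupied, index=sites["site_id"].to_numpy(), name="occupied")


def gene_clip_density(track: RTStopTrack, sites: pd.DataFrame,
                      window_assign: float = 20) -> pd.Series:
    """Average number of unique RT stops per 3'SS for each gene.

    A stop position is assigned to the gene whose nearest site is closest,
    provided the distance is at most ``window_assign`` (may be ``np.inf``
    to assign every stop on a contig/strand shared with the gene's sites);
    the gene accumulates the position's unique RT-stop count.
    Density = assigned unique RT stops / number of 3'SS.
    """
    n_sites = sites.groupby("gene_id").size()
    assigned = dict.fromkeys(n_sites.index, 0)
    for (contig, strand), site_grp in sites.groupby(["contig", "strand"], sort=False):
        pos, cnt = track.positions(contig, strand)
        if len(pos) == 0:
            continue
        junctions = site_grp["junction"].to_numpy()
        genes = site_grp["gene_id"].to_numpy()
        # distance from every stop to every site of this contig/strand
        dist = np.abs(pos[:, None] - junctions[None, :])
        nearest = np.argmin(dist, axis=1)
        mind = dist[np.arange(len(pos)), nearest]
        keep = mind <= window_assign
        for gene in np.unique(genes[nearest[keep]]):
            assigned[gene] += int(cnt[keep][genes[nearest[keep]] == gene].sum())
    density = pd.Series(assigned, name="density").astype(float) / n_sites
    return density.sort_index()


@dataclass
class OccupancyCurve:
    """Density-sorted rolling saturation curve with a plateau estimate."""

    genes: pd.DataFrame          # gene_id, density, occupied_fraction (sorted)
    rolling_density: np.ndarray  # rolling quantile-q of density
    rolling_occupancy: np.ndarray
    plateau_estimate: float
    window: int
    quantile: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rolling_density": self.rolling_density,
            "rolling_occupancy": self.rolling_occupancy,
        })


def saturation_curve(densities: pd.Series, occupied_fractions: pd.Series,
                     window: int = 40, q: float = 0.75,
                     occupancy_stat: str = "mean",
                     plateau_decile: float = 0.10) -> OccupancyCurve:
    """Rolling saturation analysis over genes sorted by CLIP density.

    Genes are sorted ascending by density; the density axis is smoothed with
    a rolling quantile ``q`` over ``window`` genes.  Occupancy is aggregated
    per window by the mean occupied fraction (``occupancy_stat="quantile"``
    applies the same order statistic to the fractions instead).  The plateau
    estimate is the mean rolling occupancy over the top-decile-density
    windows.
    """
    genes = pd.DataFrame({
        "density": densities, "occupied_fraction": occupied_fractions
    }).dropna()
    if len(genes) < window:
        raise ValidationError(
            f"need at least window={window} genes, got {len(genes)}"
        )
    genes = genes.rename_axis("gene_id").reset_index()
    genes = genes.sort_values(["density", "gene_id"], kind="mergesort").reset_index(drop=True)

    dens = genes["density"].rolling(window).quantile(q).to_numpy()[window - 1:]
    frac = genes["occupied_fraction"].rolling(window)
    if occupancy_stat == "mean":
        occ = frac.mean().to_numpy()[window - 1:]
    elif occupancy_stat == "quantile":
        occ = frac.quantile(q).to_numpy()[window - 1:]
    else:
        raise ValidationError(f"unknown occupancy_stat {occupancy_stat!r}")

    k = max(1, int(np.ceil(plateau_decile * len(occ))))
    plateau = float(np.mean(occ[-k:]))   # densities ascend, so the tail is top-decile
    return OccupancyCurve(genes, dens, occ, plateau, window, q)


def metagene_profile(track: RTStopTrack, sites: pd.DataFrame, L: int = 50,
                     display_offset: int = DISPLAY_OFFSET) -> pd.Series:
    """Average per-site-normalized RT-stop density across 3'SS, scaled to max 1.

    Each covered site's count vector over junction offsets ``[-L, +L]`` is
    normalized to sum 1; sites with no stops in the window are skipped.
    Returned series is indexed by display coordinates.
    """
    profiles = site_profiles(track, sites, L)
    totals = profiles.totals()
    covered = totals > 0
    if not covered.any():
        raise ValidationError("no covered sites: the track has no stops near any 3'SS")
    fractions = profiles.counts[covered] / totals[covered, None]
    mean_profile = fractions.mean(axis=0)
    mean_profile = mean_profile / mean_profile.max()
    index = to_display(profiles.offsets, display_offset)
    return pd.Series(mean_profile, index=index, name=track.condition_label)


def metagene_profiles(tracks: dict[str, RTStopTrack], sites: pd.DataFrame,
                      L: int = 50, display_offset: int = DISPLAY_OFFSET) -> pd.DataFrame:
    """Metagene profiles for several conditions, one column per track."""
    return pd.DataFrame({
        label: metagene_profile(track, sites, L, display_offset)
        for label, track in tracks.items()
    })
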