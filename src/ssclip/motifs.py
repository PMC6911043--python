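"""Hexamer Z-score analysis with a resampling null, trinucleotide sliding
windows, positional base frequencies, and the preferential binding score.

The null distribution of hexamer frequencies is built by uniformly sampling
``M`` annotated 3' splice sites ``n`` times and counting hexamers whose
start falls within a +/- ``flank`` junction-offset window.  ``M`` is set to
the number of unique occupied 3'SS in the sample being scored, so the null
resamples match the observed sample size.  The observed frequency of each
hexamer counts hexamers starting within a 5-bp window centred on each
inferred RT stop, and

    z = (f_observed - mu_null) / sigma_null

per hexamer.  Hexamers with a degenerate null (sigma = 0) get a missing z
rather than +/- infinity.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import Genome, RTStopTrack, ValidationError

ALL_HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]
ALL_TRINUCLEOTIDES = ["".join(p) for p in product("ACGT", repeat=3)]

_BASE_LOOKUP = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_LOOKUP[ord(_b)] = _i


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers of ``seq`` (base-4 encoding); -1 where the
    window contains a non-ACGT character.  Length ``len(seq) - k + 1``."""
    idx = _BASE_LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(idx) < k:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(idx, k)
    powers = 4 ** np.arange(k - 1, -1, -1)
    codes = (windows * powers).sum(axis=1)
    codes[(windows < 0).any(axis=1)] = -1
    return codes


def _site_codes(genome: Genome, row, lo: int, hi: int, k: int) -> tuple[np.ndarray, int]:
    """k-mer codes starting at junction offsets ``lo..hi`` (clamped to the
    contig); returns (codes, actual_lo).  Truncated windows are dropped."""
    length = len(genome[row.contig])
    if row.strand == "+":
        lo_ok = max(lo, -row.junction)
        hi_ok = min(hi, length - row.junction - k)
    else:
        lo_ok = max(lo, row.junction - length + 1)
        hi_ok = min(hi, row.junction - (k - 1))
    if hi_ok < lo_ok:
        return np.empty(0, dtype=np.int64), lo
    seq = genome.transcript_window(row.contig, row.strand, row.junction,
                                   lo_ok, hi_ok + k - 1)
    return kmer_codes(seq, k), lo_ok


def build_hexamer_null(all_sites: pd.DataFrame, genome: Genome, M: int,
                       n: int = 50, flank: int = 20, seed: int = 0) -> pd.DataFrame:
    """Resampled null mean/SD of hexamer frequencies over 3'SS windows.

    Each of ``n`` resamples draws ``M`` sites uniformly without replacement
    and counts hexamers whose start offset lies in ``[-flank, +flank]``.
    """
    if M > len(all_sites):
        raise ValidationError(f"M={M} exceeds the {len(all_sites)} annotated sites")
    if M < 1 or n < 2:
        raise ValidationError("need M >= 1 and n >= 2")
    rng = np.random.default_rng(seed)
    per_site = [
        _site_codes(genome, row, -flank, flank, 6)[0]
        for row in all_sites.itertuples(index=False)
    ]
    freqs = np.zeros((n, 4096))
    for r in range(n):
        chosen = rng.choice(len(per_site), size=M, replace=False)
        codes = np.concatenate([per_site[i] for i in chosen])
        codes = codes[codes >= 0]
        counts = np.bincount(codes, minlength=4096)
        total = counts.sum()
        if total == 0:
            raise ValidationError("resample produced no valid hexamer windows")
        freqs[r] = counts / total
    return pd.DataFrame({
        "hexamer": ALL_HEXAMERS,
        "mu": freqs.mean(axis=0),
        "sigma": freqs.std(axis=0, ddof=1),
    })


def _stop_window_counts(track: RTStopTrack, sites: pd.DataFrame, genome: Genome,
                        k: int, rel_offsets: np.ndarray, assign_window: int,
                        weighted: bool, per_site_norm: bool = True
                        ) -> tuple[np.ndarray, float]:
    """Count k-mers starting at ``RT + d`` for every RT stop within
    +/- ``assign_window`` of a site and every ``d`` in ``rel_offsets``.

    Returns a (len(rel_offsets), 4**k) count matrix and the number of RT
    stops used.  With ``weighted`` (the default) each position contributes
    its unique-RT-stop count -- every deduplicated cross-link event counts
    once; ``weighted=False`` counts each covered position once instead.
    With ``per_site_norm`` (the default) every site's windows are rescaled
    to unit total weight so each occupied site contributes equally, matching
    the site-uniform sampling design of the resampling null; otherwise
    heavily covered sites dominate the frequencies.
    """
    lo = -assign_window + int(rel_offsets.min())
    hi = assign_window + int(rel_offsets.max())
    counts = np.zeros((len(rel_offsets), 4 ** k))
    n_stops = 0.0
    for row in sites.itertuples(index=False):
        stop_counts = track.window_counts(row.contig, row.strand, row.junction,
                                          -assign_window, assign_window)
        present = np.nonzero(stop_counts)[0]
        if len(present) == 0:
            continue
        codes, lo_ok = _site_codes(genome, row, lo, hi, k)
        if len(codes) == 0:
            continue
        stop_offs = present - assign_window
        weights = stop_counts[present].astype(float) if weighted else np.ones(len(present))
        n_stops += weights.sum()
        if per_site_norm:
            weights = weights / weights.sum()
        starts = stop_offs[:, None] + rel_offsets[None, :]   # (n_stops, n_rel)
        idx = starts - lo_ok
        valid = (idx >= 0) & (idx < len(codes))
        for j in range(len(rel_offsets)):
            v = valid[:, j]
            c = codes[idx[v, j]]
            w = weights[v][c >= 0]
            c = c[c >= 0]
            if len(c):
                counts[j] += np.bincount(c, weights=w, minlength=4 ** k)
    return counts, n_stops


def hexamer_zscores(occupied_sites: pd.DataFrame, track: RTStopTrack,
                    genome: Genome, null: pd.DataFrame, window: int = 5,
                    assign_window: int = 20, weighted: bool = True,
                    anchor: str = "cover") -> pd.DataFrame:
    """Observed hexamer frequencies around RT stops and their null Z-scores.

    Hexamers are counted for every RT stop within +/- ``assign_window`` of
    an occupied site.  With ``anchor="cover"`` (default) every hexamer
    overlapping the ``window``-bp interval centred on the stop is counted;
    this keeps the set of counted hexamers symmetric around the cross-link,
    so a single-nucleotide peak shift between conditions does not by itself
    change how often acceptor-spanning hexamers are seen.
    ``anchor="start"`` restricts to hexamers *starting* inside that
    interval instead.
    """
    half = window // 2
    if anchor == "cover":
        rel = np.arange(-half - 5, half + 1)
    elif anchor == "start":
        rel = np.arange(-half, half + 1)
    else:
        raise ValidationError(f"unknown anchor {anchor!r}")
    counts, n_stops = _stop_window_counts(
        track, occupied_sites, genome, 6, rel, assign_window, weighted
    )
    totals = counts.sum()
    if totals == 0:
        raise ValidationError("no hexamer windows around RT stops")
    f = counts.sum(axis=0) / totals
    out = null[["hexamer", "mu", "sigma"]].copy()
    out["f_obs"] = f
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (f - out["mu"].to_numpy()) / out["sigma"].to_numpy()
    z[out["sigma"].to_numpy() == 0] = np.nan
    out["z"] = z
    out.attrs.update({
        "sample": track.condition_label,
        "M": len(occupied_sites),
        "n_windows": float(totals),
        "n_stops": n_stops,
    })
    return out


def trinucleotide_profile(track: RTStopTrack, genome: Genome,
                          sites: pd.DataFrame, span: int = 25,
                          assign_window: int = 20,
                          weighted: bool = True) -> pd.DataFrame:
    """Trinucleotide frequencies in size-3 windows sliding over
    ``[RT - span, RT + span]`` around RT stops near 3'SS.

    Rows are window start offsets relative to the RT stop and sum to 1
    (over windows fully inside the contig).
    """
    rel = np.arange(-span, span + 1)
    counts, _ = _stop_window_counts(track, sites, genome, 3, rel, assign_window, weighted)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), np.nan)
    return pd.DataFrame(freqs, index=pd.Index(rel, name="offset_from_rt"),
                        columns=ALL_TRINUCLEOTIDES)


def preferential_binding_score(stats_mut: pd.DataFrame, stats_wt: pd.DataFrame,
                               pseudocount: float | None = None,
                               support_quantile: float = 0.75) -> pd.DataFrame:
    """log2 mutant/wild-type frequency ratio per hexamer, ranked descending
    (top = most mutant-preferred).

    The default pseudocount is ``1 / (4 * 4096 * total windows)`` over both
    samples.  Only hexamers whose pooled observed frequency reaches the
    ``support_quantile`` across hexamers enter the ranking: the ratio is a
    relative binding preference among sequences actually bound, and poorly
    observed hexamers would otherwise dominate both tails through sampling
    noise alone (``support_quantile=0`` ranks everything).
    """
    merged = stats_mut[["hexamer", "f_obs"]].merge(
        stats_wt[["hexamer", "f_obs"]], on="hexamer", suffixes=("_mut", "_wt")
    )
    if pseudocount is None:
        total = stats_mut.attrs.get("n_windows", 0) + stats_wt.attrs.get("n_windows", 0)
        pseudocount = 1.0 / (4 * 4096 * max(total, 1.0))
    pooled = (merged["f_obs_mut"] + merged["f_obs_wt"]) / 2
    if support_quantile > 0:
        merged = merged[pooled >= pooled.quantile(support_quantile)]
    merged = merged.copy()
    merged["score"] = np.log2(
        (merged["f_obs_mut"] + pseudocount) / (merged["f_obs_wt"] + pseudocount)
    )
    return merged.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)


def selectively_enriched(stats_mut: pd.DataFrame, stats_wt: pd.DataFrame,
                         top_fraction: float = 0.035) -> pd.DataFrame:
    """Hexamers in the top ``top_fraction`` of |z_mut - z_wt| (both z finite)."""
    merged = stats_mut[["hexamer", "z"]].merge(
        stats_wt[["hexamer", "z"]], on="hexamer", suffixes=("_mut", "_wt")
    ).dropna()
    merged["dz"] = (merged["z_mut"] - merged["z_wt"]).abs()
    k = max(1, int(round(top_fraction * len(merged))))
    return merged.nlargest(k, "dz").reset_index(drop=True)


def positional_base_frequency(track: RTStopTrack, sites: pd.DataFrame,
                              genome: Genome, window: tuple[int, int] = (-10, 5),
                              assign_window: int = 20) -> pd.DataFrame:
    """Stop-weighted base frequencies at junction offsets ``window[0]..window[1]``.

    Each site contributes its acceptor-region sequence weighted by its total
    RT-stop count within +/- ``assign_window``; rows (offsets) sum to 1.
    The matrix is the numeric equivalent of a sequence logo.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    counts = np.zeros((len(offsets), 4))
    total_weight = 0.0
    for row in sites.itertuples(index=False):
        w = track.window_counts(row.contig, row.strand, row.junction,
                                -assign_window, assign_window).sum()
        if w == 0:
            continue
        seq = genome.transcript_window(row.contig, row.strand, row.junction, lo, hi)
        idx = _BASE_LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = idx >= 0
        counts[np.arange(len(offsets))[valid], idx[valid]] += float(w)
        total_weight += float(w)
    if total_weight == 0:
        raise ValidationError("no stops near any site: cannot weight base frequencies")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freqs, index=pd.Index(offsets, name="offset"),
                        columns=list("ACGT"))
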