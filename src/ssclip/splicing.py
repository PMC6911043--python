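"""Differential-splicing calling from psi / read-count inputs.

Two layers of analysis:

* **Two-condition calls** (cell-line style): psi = inclusion /
  (inclusion + exclusion) per condition, a Beta(1,1)-binomial marginal-
  likelihood Bayes factor against the shared-psi hypothesis, and the
  standard gates |delta psi| >= 0.10, BF >= 5, >= 10 supporting reads.
* **Cohort calls** (TCGA style): per-event Welch t-test between two sample
  groups plus an absolute group-median psi difference of >= 0.025, the
  acceptor CAG/TAG co-association Fisher test, per-event Z-scores of
  mutant samples against the wild-type group, and the cross-data-set
  direction-overlap Fisher test at |Z| > 1.64.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln

from .io import EVENT_TYPES, Genome, PsiMatrix, ValidationError

logger = logging.getLogger(__name__)

Z_THRESHOLD = 1.64   # right tail of the standard normal at p = 0.05


@dataclass
class ContingencyResult:
    """A 2x2 test outcome (Fisher, binomial or chi-squared)."""

    table: np.ndarray
    odds_ratio: float
    p: float
    test: str

    def __repr__(self):
        return (f"ContingencyResult(test={self.test}, table={self.table.tolist()}, "
                f"odds_ratio={self.odds_ratio:.4g}, p={self.p:.4g})")


def fisher_2x2(table: np.ndarray, test_name: str = "fisher") -> ContingencyResult:
    """Two-sided Fisher's exact test; degenerate margins give p = 1."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("need a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table (zero margin): p = 1")
        a, b, c, d = table.ravel()
        odds = np.nan if b * c == 0 and a * d == 0 else (
            np.inf if b * c == 0 else a * d / (b * c)
        )
        return ContingencyResult(table, odds, 1.0, test_name)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyResult(table, float(odds), float(p), test_name)


# ---------------------------------------------------------------------------
# Two-condition analysis


def psi_from_counts(inclusion, exclusion):
    """psi = inclusion / (inclusion + exclusion); NaN where no reads."""
    inclusion = np.asarray(inclusion, dtype=float)
    exclusion = np.asarray(exclusion, dtype=float)
    total = inclusion + exclusion
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, inclusion / np.where(total == 0, 1, total), np.nan)
    return psi if psi.ndim else float(psi)


def bayes_factor(counts_a: tuple[int, int], counts_b: tuple[int, int]) -> float:
    """Beta(1,1)-binomial Bayes factor: independent-psi vs shared-psi models.

    BF = B(i_a+1, e_a+1) B(i_b+1, e_b+1) / [B(1,1) B(i_a+i_b+1, e_a+e_b+1)]

    computed with log-Beta identities.  BF > 1 favours different inclusion
    levels; a condition with zero reads contributes nothing and yields
    BF = 1 (uninformative).
    """
    ia, ea = counts_a
    ib, eb = counts_b
    if min(ia, ea, ib, eb) < 0:
        raise ValidationError("read counts must be nonnegative")
    log_bf = (
        betaln(ia + 1, ea + 1) + betaln(ib + 1, eb + 1)
        - betaln(1, 1) - betaln(ia + ib + 1, ea + eb + 1)
    )
    return float(np.exp(log_bf))


def call_differential_events(events: pd.DataFrame,
                             conditions: tuple[str, str] = ("wild_type", "mutant"),
                             dpsi_min: float = 0.10, bf_min: float = 5.0,
                             reads_min: int = 10) -> pd.DataFrame:
    """Differential-splicing calls from a long two-condition count table.

    ``events`` needs columns event_id, event_type, site_id, condition,
    inclusion_reads, exclusion_reads.  An event is called when
    |psi_mut - psi_wt| >= ``dpsi_min``, BF >= ``bf_min`` and each condition
    has at least ``reads_min`` supporting reads.
    """
    cond_a, cond_b = conditions
    wide = events.pivot_table(
        index=["event_id", "event_type", "site_id"],
        columns="condition",
        values=["inclusion_reads", "exclusion_reads"],
        aggfunc="sum",
    )
    for cond in conditions:
        if ("inclusion_reads", cond) not in wide.columns:
            raise ValidationError(f"condition {cond!r} absent from event table")
    inc_a = wide[("inclusion_reads", cond_a)].to_numpy(np.int64)
    exc_a = wide[("exclusion_reads", cond_a)].to_numpy(np.int64)
    inc_b = wide[("inclusion_reads", cond_b)].to_numpy(np.int64)
    exc_b = wide[("exclusion_reads", cond_b)].to_numpy(np.int64)

    psi_a = psi_from_counts(inc_a, exc_a)
    psi_b = psi_from_counts(inc_b, exc_b)
    dpsi = psi_b - psi_a
    bf = np.array([
        bayes_factor((ia, ea), (ib, eb))
        for ia, ea, ib, eb in zip(inc_a, exc_a, inc_b, exc_b)
    ])
    supporting = np.minimum(inc_a + exc_a, inc_b + exc_b)

    passed = (np.abs(dpsi) >= dpsi_min) & (bf >= bf_min) & (supporting >= reads_min)
    call = np.where(~passed, "none",
                    np.where(dpsi > 0, "mut_preferred", "wt_preferred"))

    out = wide.index.to_frame(index=False)
    out["psi_wt"] = psi_a
    out["psi_mut"] = psi_b
    out["dpsi"] = dpsi
    out["bayes_factor"] = bf
    out["supporting_reads"] = supporting
    out["call"] = call
    return out


def event_type_frequency_test(calls: pd.DataFrame,
                              annotation_event_counts: dict[str, int]
                              ) -> tuple[pd.DataFrame, float, float]:
    """Chi-squared goodness-of-fit of called-event types vs the annotation mix.

    Returns (per-type table with observed/expected percentages, chi2, p).
    Event types with zero expected count are merged into the smallest
    nonzero expected category (with a warning).
    """
    called = calls[calls["call"] != "none"]
    observed = called["event_type"].value_counts()
    types = [t for t in EVENT_TYPES if t in annotation_event_counts
             or t in observed.index]
    expected_raw = pd.Series(
        {t: annotation_event_counts.get(t, 0) for t in types}, dtype=float
    )
    obs = observed.reindex(types, fill_value=0).astype(float)
    zero_exp = expected_raw[expected_raw == 0].index
    if len(zero_exp) and obs[zero_exp].sum() > 0:
        target = expected_raw[expected_raw > 0].idxmin()
        logger.warning("merging zero-expected categories %s into %s",
                       list(zero_exp), target)
        obs[target] += obs[zero_exp].sum()
    obs = obs.drop(zero_exp)
    expected_raw = expected_raw.drop(zero_exp)

    exp_prop = expected_raw / expected_raw.sum()
    exp_counts = exp_prop * obs.sum()
    chi2, p = stats.chisquare(obs, exp_counts)
    table = pd.DataFrame({
        "event_type": obs.index,
        "observed": obs.to_numpy(int),
        "observed_pct": 100 * obs.to_numpy() / max(obs.sum(), 1),
        "expected_pct": 100 * exp_prop.to_numpy(),
    })
    return table, float(chi2), float(p)


def se_3ss_trinucleotides(calls: pd.DataFrame, sites: pd.DataFrame,
                          genome: Genome | None = None) -> pd.DataFrame:
    """Acceptor-trinucleotide frequencies of called skipped-exon events,
    stratified by inclusion direction (dpsi > 0 = increased in mutant)."""
    se = calls[(calls["event_type"] == "SE") & (calls["call"] != "none")]
    if se.empty:
        logger.warning("no called SE events; trinucleotide table is empty")
        return pd.DataFrame(columns=["trinucleotide", "increased", "decreased"])
    merged = se.merge(sites[["site_id", "acceptor"]], on="site_id", how="left")
    merged["direction"] = np.where(merged["dpsi"] > 0, "increased", "decreased")
    freq = (
        merged.groupby(["acceptor", "direction"]).size().unstack(fill_value=0)
        .reindex(columns=["increased", "decreased"], fill_value=0)
    )
    freq = freq / freq.sum(axis=0).replace(0, 1)
    return freq.rename_axis("trinucleotide").reset_index()


# ---------------------------------------------------------------------------
# Cohort (two-group PSI matrix) analysis


def cohort_call(psi: PsiMatrix, groups: tuple[str, str] = ("mutant", "wild_type"),
                p_max: float = 0.05, dmedian_min: float = 0.025) -> pd.DataFrame:
    """Per-event two-group comparison on a PSI matrix.

    Welch's t-test on per-sample psi plus a group-median difference gate;
    events with fewer than two non-missing values in either group are
    skipped (``tested = False``).  ``dmedian`` is median(group I) -
    median(group II) with group I = ``groups[0]``.
    """
    g1, g2 = groups
    a = psi.values[psi.samples_in(g1)].to_numpy(float)
    b = psi.values[psi.samples_in(g2)].to_numpy(float)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    tested = (n1 >= 2) & (n2 >= 2)
    if (~tested).any():
        logger.info("skipping %d events with <2 non-missing psi in a group",
                    int((~tested).sum()))
    with np.errstate(invalid="ignore"):
        med1 = np.nanmedian(np.where(np.isnan(a), np.nan, a), axis=1)
        med2 = np.nanmedian(np.where(np.isnan(b), np.nan, b), axis=1)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    pvals = np.asarray(res.pvalue, dtype=float)
    dmed = med1 - med2
    called = tested & (pvals < p_max) & (np.abs(dmed) >= dmedian_min)
    return pd.DataFrame({
        "event_id": psi.values.index,
        "n_group_I": n1,
        "n_group_II": n2,
        "median_I": med1,
        "median_II": med2,
        "dmedian": dmed,
        "t_p": pvals,
        "tested": tested,
        "called": called,
        "direction": np.where(dmed > 0, "increased", "decreased"),
    }).reset_index(drop=True)


def cohort_cag_tag_test(cohort_calls: pd.DataFrame, sites: pd.DataFrame,
                        dpsi_thresh: float = 0.025) -> ContingencyResult:
    """Fisher co-association of acceptor CAG/TAG with the sign of the
    group-median psi difference among called events.

    ``cohort_calls`` must carry a ``site_id`` column (events linked to the
    3'SS of the alternative exon); only CAG/TAG acceptors enter the table,
    stratified by dmedian > ``dpsi_thresh`` vs <= -``dpsi_thresh``.
    """
    if "site_id" not in cohort_calls.columns:
        raise ValidationError("cohort_calls needs a site_id column to map acceptors")
    calls = cohort_calls[cohort_calls["called"]]
    merged = calls.merge(sites[["site_id", "acceptor"]], on="site_id", how="left")
    merged = merged[merged["acceptor"].isin(["CAG", "TAG"])]
    up = merged["dmedian"] > dpsi_thresh
    down = merged["dmedian"] <= -dpsi_thresh
    table = np.array([
        [int(((merged["acceptor"] == "CAG") & up).sum()),
         int(((merged["acceptor"] == "CAG") & down).sum())],
        [int(((merged["acceptor"] == "TAG") & up).sum()),
         int(((merged["acceptor"] == "TAG") & down).sum())],
    ])
    return fisher_2x2(table)


def event_zscores(psi: PsiMatrix, wt_group: str = "wild_type") -> pd.DataFrame:
    """Z-score of each non-reference sample's psi against the reference
    (wild-type) group mean/SD, per event.

    Z is missing where the reference SD is 0 or fewer than two reference
    values are present.
    """
    wt_samples = psi.samples_in(wt_group)
    other = [s for s in psi.values.columns if s not in wt_samples]
    wt = psi.values[wt_samples].to_numpy(float)
    n_wt = np.sum(~np.isnan(wt), axis=1)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(wt, axis=1)
        sd = np.nanstd(wt, axis=1, ddof=1)
    valid = (n_wt >= 2) & (sd > 1e-9)   # tolerance absorbs float noise on ties
    z = (psi.values[other].to_numpy(float) - mu[:, None]) / np.where(
        valid, sd, np.nan
    )[:, None]
    return pd.DataFrame(z, index=psi.values.index, columns=other)


def overlap_association(reference_calls: pd.DataFrame, zscores: pd.DataFrame,
                        z_thresh: float = Z_THRESHOLD) -> ContingencyResult:
    """Direction-overlap Fisher test between a reference differential-
    splicing call set and cohort event Z-scores.

    Event x sample pairs with Z > ``z_thresh`` or Z < -``z_thresh`` are
    pooled and crossed with the reference inclusion direction (the sign of
    ``dpsi`` for events called in the reference set).
    """
    ref = reference_calls[reference_calls.get("call", "x") != "none"] \
        if "call" in reference_calls.columns else reference_calls
    directions = pd.Series(
        np.where(ref["dpsi"].to_numpy(float) > 0, "increased", "decreased"),
        index=ref["event_id"],
    )
    shared = zscores.index.intersection(directions.index)
    if shared.empty:
        raise ValidationError("no shared events between reference calls and Z-scores")
    z = zscores.loc[shared].to_numpy(float)
    inc = (directions.loc[shared] == "increased").to_numpy()[:, None]
    high = z > z_thresh
    low = z < -z_thresh
    table = np.array([
        [int((high & inc).sum()), int((high & ~inc).sum())],
        [int((low & inc).sum()), int((low & ~inc).sum())],
    ])
    if table.sum() == 0:
        raise ValidationError("empty contingency: no |Z| beyond threshold")
    return fisher_2x2(table)
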