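"""Synthetic genomes, 3'SS annotations, RT-stop tracks, PSI cohorts and
gene-level quantifications with the statistical structure the downstream
analyses assume.

The generator emulates the phenomena the analyses were designed around:

* a tunable fraction of occupied 3' splice sites per condition
  (defaults 0.86 wild-type / 0.70 mutant),
* condition-specific cross-link peak positions in display coordinates
  (wild-type main peak at -5, mutant shifted one nucleotide to -4, with
  smaller flanking peaks at -12 and +1),
* acceptor-trinucleotide-dependent binding weights (mutant prefers CAG
  over TAG),
* two-group PSI cohorts whose effect-size sign is coupled to the 3'SS
  trinucleotide, and
* per-gene CLIP/expression tables with planted fold changes.

Every operation is deterministic given its seed; condition-specific random
streams are derived from the seed and a stable hash of the condition label.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import (
    EVENT_COUNT_COLUMNS,
    Genome,
    PsiMatrix,
    RTStopTrack,
    ValidationError,
    annotate_sites,
    revcomp,
    to_internal,
)

_BASES = np.array(list("ACGT"))
_TRINUCS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_OTHER_TRINUCS = [t for t in _TRINUCS if t not in ("CAG", "TAG", "AAG")]


def _stable_int(label: str) -> int:
    """Deterministic 31-bit integer from a string (stable across sessions)."""
    return int.from_bytes(hashlib.md5(label.encode()).digest()[:4], "big") % (2**31)


def _substream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _stable_int(label)])


@dataclass
class ConditionConfig:
    """Binding behaviour of one condition (e.g. wild-type or S34F mutant).

    ``peaks`` maps display-coordinate offsets to multinomial weights for RT
    stops at occupied sites; ``background_weight`` is spread uniformly over
    the +/- ``bg_span`` offset window.  ``trinuc_multipliers`` scale the
    per-site occupancy probability by acceptor trinucleotide (missing
    acceptors default to 1.0); they are renormalized so the marginal
    occupied fraction stays ``occupancy``.
    """

    occupancy: float = 0.86
    peaks: dict = field(default_factory=lambda: {-5: 0.6, -12: 0.2, 1: 0.1})
    background_weight: float = 0.1
    trinuc_multipliers: dict = field(default_factory=dict)


def _default_conditions() -> dict:
    return {
        "wild_type": ConditionConfig(),
        "mutant": ConditionConfig(
            occupancy=0.70,
            # main peak shifted one nucleotide toward the junction; flanks
            # preserved at reduced relative amplitude
            peaks={-4: 0.72, -12: 0.12, 1: 0.06},
            background_weight=0.10,
            trinuc_multipliers={"CAG": 2.0, "TAG": 0.5},
        ),
    }


@dataclass
class CohortConfig:
    """Two-group PSI cohort (group sizes follow the TCGA LUAD split)."""

    n_events: int = 500
    group_sizes: dict = field(default_factory=lambda: {"mutant": 125, "wild_type": 175})
    psi_beta: tuple = (2.0, 2.0)
    dpsi: float = 0.3
    affected_fraction: float = 0.2
    #: P(shift is +) = 0.5 + coupling/2 for CAG acceptors, 0.5 - coupling/2 for TAG
    coupling: float = 0.8
    depth: int = 100
    missing_rate: float = 0.05
    event_type_probs: dict = field(default_factory=lambda: {
        "SE": 0.4, "RI": 0.2, "A3SS": 0.15, "A5SS": 0.15, "NAGNAG": 0.1,
    })


@dataclass
class GeneQuantConfig:
    """Per-gene CLIP counts and expression values for two conditions."""

    frac_binding_mut: float = 0.15
    frac_binding_wt: float = 0.08
    frac_expression_mut: float = 0.10
    frac_expression_wt: float = 0.05
    true_fold_change: float = 2.5
    noise_log_sd: float = 0.25
    expr_log_mean: float = 2.0
    expr_log_sd: float = 1.5
    clip_per_expr: float = 2.0


@dataclass
class SimConfig:
    """All generator parameters; defaults are the emulated experimental conditions."""

    n_genes: int = 2000
    sites_per_gene: int = 10
    intron_length: int = 200
    exon_length: int = 150
    contig_flank: int = 100
    acceptor_composition: dict = field(default_factory=lambda: {
        "CAG": 0.55, "TAG": 0.30, "AAG": 0.10, "other": 0.05,
    })
    # polypyrimidine tract upstream of the acceptor (junction offsets
    # -(3 + ppt_length) .. -4), the U2AF2-binding consensus of real 3'SS
    ppt_length: int = 15
    ppt_composition: dict = field(default_factory=lambda: {
        "C": 0.35, "T": 0.45, "A": 0.10, "G": 0.10,
    })
    mean_stops_per_site: float = 40.0
    dispersion: float = 0.3          # negative-binomial dispersion of stop totals
    coverage_log_sd: float = 2.5     # sd of log per-gene coverage factor
    background_site_rate: float = 0.05  # expected background stops per unoccupied site
    bg_span: int = 50                # background spread, internal offsets +/- bg_span
    display_offset: int = -3
    conditions: dict = field(default_factory=_default_conditions)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gene_quant: GeneQuantConfig = field(default_factory=GeneQuantConfig)

    def __post_init__(self):
        comp = sum(self.acceptor_composition.values())
        if not np.isclose(comp, 1.0):
            raise ValidationError("acceptor_composition probabilities must sum to 1")
        for name, cond in self.conditions.items():
            if isinstance(cond, dict):
                self.conditions[name] = cond = ConditionConfig(**cond)
            if not 0.0 <= cond.occupancy <= 1.0:
                raise ValidationError(f"occupancy of {name!r} outside [0, 1]")
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if isinstance(self.gene_quant, dict):
            self.gene_quant = GeneQuantConfig(**self.gene_quant)
        if min(self.n_genes, self.sites_per_gene, self.intron_length,
               self.exon_length) <= 0:
            raise ValidationError("all counts/lengths must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Reference (genome + splice sites)


def simulate_reference(config: SimConfig, seed: int) -> tuple[Genome, pd.DataFrame]:
    """One contig per gene with ``sites_per_gene`` 3'SS; acceptor
    trinucleotides drawn from ``acceptor_composition``; strands mixed."""
    rng = _substream(seed, "reference")
    names = list(config.acceptor_composition)
    probs = np.array([config.acceptor_composition[k] for k in names])
    intron, exon = config.intron_length, config.exon_length
    unit = intron + exon
    contig_len = 2 * config.contig_flank + config.sites_per_gene * unit

    seqs: dict[str, str] = {}
    rows = []
    for g in range(config.n_genes):
        gene_id = f"g{g:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        # transcript-oriented sequence, acceptors planted at t-3..t-1
        tseq = _BASES[rng.integers(0, 4, contig_len)]
        # systematic allocation: every gene matches the acceptor composition
        # up to rounding, so gene-level composition carries no multinomial noise
        points = (rng.random() + np.arange(config.sites_per_gene)) / config.sites_per_gene
        cats = np.searchsorted(np.cumsum(probs), points, side="right")
        cats = cats[rng.permutation(len(cats))]
        ppt_bases = list(config.ppt_composition)
        ppt_probs = np.array([config.ppt_composition[b] for b in ppt_bases])
        for k in range(config.sites_per_gene):
            t_junc = config.contig_flank + (k + 1) * intron + k * exon
            cat = names[cats[k]]
            acceptor = cat if cat != "other" else _OTHER_TRINUCS[rng.integers(len(_OTHER_TRINUCS))]
            if config.ppt_length > 0:
                ppt = np.array(ppt_bases)[
                    rng.choice(len(ppt_bases), config.ppt_length, p=ppt_probs)
                ]
                tseq[t_junc - 3 - config.ppt_length:t_junc - 3] = ppt
            tseq[t_junc - 3:t_junc] = list(acceptor)
            junction = t_junc if strand == "+" else contig_len - 1 - t_junc
            rows.append((f"{gene_id}_ss{k:02d}", gene_id, strand, junction, gene_id, acceptor))
        transcript = "".join(tseq)
        seqs[gene_id] = transcript if strand == "+" else revcomp(transcript)

    sites = pd.DataFrame(
        rows, columns=["site_id", "contig", "strand", "junction", "gene_id", "acceptor"]
    )
    genome = Genome(seqs)
    return genome, annotate_sites(sites, genome)


# ---------------------------------------------------------------------------
# RT stops


def _occupancy_probs(cond: ConditionConfig, acceptors: pd.Series) -> np.ndarray:
    """Per-site occupancy probabilities: trinucleotide multipliers scaled so
    the marginal occupied fraction equals ``cond.occupancy`` exactly.

    Scaling can push individual probabilities past 1; those are capped at 1
    and the remainder rescaled (water-filling) to preserve the marginal.
    """
    mult = acceptors.map(lambda a: cond.trinuc_multipliers.get(a, 1.0)).to_numpy(float)
    target = cond.occupancy * len(mult)
    probs = cond.occupancy * mult / mult.mean()
    for _ in range(100):
        over = probs >= 1.0
        if not (probs > 1.0 + 1e-12).any():
            break
        remainder = target - over.sum()
        free = probs[~over]
        if remainder < 0 or (free.sum() == 0 and remainder > 0):
            raise ValidationError(
                "occupancy x trinucleotide multipliers cannot reach the "
                "requested marginal occupied fraction"
            )
        probs = np.where(over, 1.0, probs * remainder / free.sum())
    return np.clip(probs, 0.0, 1.0)


def _balanced_occupancy(p_occ: np.ndarray, gene_idx: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw occupied flags with per-site inclusion probability ``p_occ`` by
    systematic probability-proportional-to-size sampling within each gene.

    Each site keeps its marginal occupancy probability, but the number of
    occupied sites per gene is fixed to its expectation (up to the
    fractional remainder), so the per-gene occupied fraction carries no
    binomial noise.  This keeps the saturation plateau identifiable from
    genes ranked by CLIP density, which would otherwise be upward-biased by
    selecting genes with luckier occupancy draws.
    """
    occupied = np.zeros(len(p_occ), dtype=bool)
    for g in np.unique(gene_idx):
        idx = np.nonzero(gene_idx == g)[0]
        idx = idx[rng.permutation(len(idx))]
        p = p_occ[idx]
        total = p.sum()
        if total <= 0:
            continue
        points = rng.random() + np.arange(int(np.ceil(total)))
        points = points[points < total]
        chosen = np.searchsorted(np.cumsum(p), points, side="right")
        occupied[idx[np.unique(chosen)]] = True
    return occupied


def simulate_rt_stops(genome: Genome, sites: pd.DataFrame, config: SimConfig,
                      condition: str, seed: int) -> tuple[RTStopTrack, pd.DataFrame]:
    """Simulate an RT-stop track for one condition.

    Occupied sites receive negative-binomially dispersed stop totals whose
    expectation scales with a log-normal per-gene coverage factor; stop
    offsets follow the condition's peak profile plus uniform background.
    Unoccupied sites receive only sparse Poisson background.
    Returns the track and a per-site truth table.
    """
    if condition not in config.conditions:
        raise ValidationError(f"unknown condition {condition!r}")
    cond = config.conditions[condition]
    rng = _substream(seed, f"rt_stops/{condition}")

    genes = sites["gene_id"].to_numpy()
    gene_ids, gene_idx = np.unique(genes, return_inverse=True)
    # coverage emulates transcript abundance: a property of the gene shared
    # by both conditions, so its stream depends on the seed only
    sd = config.coverage_log_sd
    coverage = _substream(seed, "coverage").lognormal(-0.5 * sd**2, sd, len(gene_ids))

    p_occ = _occupancy_probs(cond, sites["acceptor"])
    occupied = _balanced_occupancy(p_occ, gene_idx, rng)

    # stop totals at occupied sites: NB(mean = mean_stops * gene coverage)
    lam = config.mean_stops_per_site * coverage[gene_idx]
    r = 1.0 / config.dispersion
    n_stops = np.where(
        occupied, rng.negative_binomial(r, r / (r + lam)), 0
    )

    # offsets in internal junction coordinates
    peak_disp = np.array(sorted(cond.peaks))
    peak_int = to_internal(peak_disp, config.display_offset)
    weights = np.array([cond.peaks[d] for d in peak_disp], float)
    weights = np.append(weights, cond.background_weight)
    weights = weights / weights.sum()
    split = rng.multinomial(n_stops, weights)          # (n_sites, n_peaks + 1)

    bg_offsets = np.arange(-config.bg_span, config.bg_span + 1)
    bg_counts = rng.multinomial(
        split[:, -1], np.full(len(bg_offsets), 1.0 / len(bg_offsets))
    )
    n_unocc = int((~occupied).sum())
    bg_unocc = rng.multinomial(
        rng.poisson(config.background_site_rate, n_unocc),
        np.full(len(bg_offsets), 1.0 / len(bg_offsets)),
    )

    offsets_all = np.concatenate([peak_int, bg_offsets])
    counts = np.zeros((len(sites), len(offsets_all)), dtype=np.int64)
    counts[:, : len(peak_int)] = split[:, :-1]
    counts[:, len(peak_int):] += bg_counts
    counts[~occupied, len(peak_int):] += bg_unocc

    # scatter to genomic coordinates
    sidx, oidx = np.nonzero(counts)
    junctions = sites["junction"].to_numpy()[sidx]
    strands = sites["strand"].to_numpy()[sidx]
    offs = offsets_all[oidx]
    pos = np.where(strands == "+", junctions + offs, junctions - offs)
    df = pd.DataFrame({
        "contig": sites["contig"].to_numpy()[sidx],
        "strand": strands,
        "pos": pos,
        "count": counts[sidx, oidx],
    })
    track = RTStopTrack(condition, df)

    main_peak = (peak_disp[np.argmax([cond.peaks[d] for d in peak_disp])]
                 if len(peak_disp) else np.nan)
    truth = pd.DataFrame({
        "site_id": sites["site_id"],
        "gene_id": sites["gene_id"],
        "occupied": occupied,
        "p_occupied": p_occ,
        "n_stops": n_stops,
        "true_peak_display": main_peak,
    })
    return track, truth


# ---------------------------------------------------------------------------
# PSI cohorts and two-condition event counts


def simulate_psi_cohort(sites: pd.DataFrame, config: SimConfig,
                        seed: int) -> tuple[PsiMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group PSI cohort plus matching two-condition counts.

    Unaffected events share a Beta-distributed baseline psi; affected events
    shift the mutant group by +/- ``dpsi`` with the sign coupled to the
    acceptor trinucleotide of the linked 3'SS (positively for CAG,
    negatively for TAG).  Per-sample psi values are binomial read-sampling
    estimates at the configured depth.
    """
    cc = config.cohort
    if len(cc.group_sizes) != 2:
        raise ValidationError("cohort requires exactly two groups")
    rng = _substream(seed, "psi_cohort")

    n = cc.n_events
    site_rows = sites.iloc[np.arange(n) % len(sites)].reset_index(drop=True)
    types = list(cc.event_type_probs)
    type_p = np.array([cc.event_type_probs[t] for t in types])
    event_types = np.array(types)[rng.choice(len(types), n, p=type_p)]
    event_ids = np.array([f"ev{i:05d}" for i in range(n)])

    a, b = cc.psi_beta
    psi0 = rng.beta(a, b, n)
    affected = rng.random(n) < cc.affected_fraction
    acc = site_rows["acceptor"].to_numpy()
    p_plus = np.where(acc == "CAG", 0.5 + cc.coupling / 2,
                      np.where(acc == "TAG", 0.5 - cc.coupling / 2, 0.5))
    sign = np.where(rng.random(n) < p_plus, 1.0, -1.0)
    psi_mut = np.where(affected, np.clip(psi0 + sign * cc.dpsi, 0.02, 0.98), psi0)
    psi_wt = psi0

    group_names = list(cc.group_sizes)
    samples, labels = [], []
    for gname in group_names:
        for i in range(cc.group_sizes[gname]):
            samples.append(f"{gname[:3]}{i:03d}")
            labels.append(gname)
    truth_psi = {"mutant": psi_mut, "wild_type": psi_wt}

    values = np.empty((n, len(samples)))
    col = 0
    for gname in group_names:
        target = truth_psi.get(gname, psi_wt)
        for _ in range(cc.group_sizes[gname]):
            depth = rng.poisson(cc.depth, n)
            inc = rng.binomial(np.maximum(depth, 1), target)
            psi = np.where(depth > 0, inc / np.maximum(depth, 1), np.nan)
            miss = rng.random(n) < cc.missing_rate
            psi[miss] = np.nan
            values[:, col] = psi
            col += 1
    psi_matrix = PsiMatrix(
        pd.DataFrame(values, index=event_ids, columns=samples),
        pd.Series(labels, index=samples),
    )

    # two-condition read counts (cell-line style comparison)
    counts_rows = []
    for cond, target in (("wild_type", psi_wt), ("mutant", psi_mut)):
        depth = rng.poisson(cc.depth, n)
        inc = rng.binomial(np.maximum(depth, 1), target)
        inc = np.where(depth > 0, inc, 0)
        counts_rows.append(pd.DataFrame({
            "event_id": event_ids,
            "event_type": event_types,
            "site_id": site_rows["site_id"],
            "condition": cond,
            "inclusion_reads": inc,
            "exclusion_reads": depth - inc,
        }))
    event_counts = pd.concat(counts_rows, ignore_index=True)[EVENT_COUNT_COLUMNS]

    truth = pd.DataFrame({
        "event_id": event_ids,
        "site_id": site_rows["site_id"],
        "event_type": event_types,
        "acceptor": acc,
        "affected": affected,
        "true_dpsi": psi_mut - psi_wt,
    })
    return psi_matrix, event_counts, truth


# ---------------------------------------------------------------------------
# Gene-level CLIP / expression quantification


def simulate_gene_quant(sites: pd.DataFrame, config: SimConfig,
                        seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene CLIP counts and expression values for the two conditions.

    Log-normal expression; CLIP counts proportional to expression with
    log-normal noise; disjoint gene subsets carry true binding and true
    expression fold changes (drawn independently so binding and expression
    ratios are uncorrelated across the transcriptome).
    """
    gq = config.gene_quant
    rng = _substream(seed, "gene_quant")
    gene_ids = sites["gene_id"].drop_duplicates().to_numpy()
    n = len(gene_ids)

    expr_base = rng.lognormal(gq.expr_log_mean, gq.expr_log_sd, n)
    u = rng.random(n)
    bind_class = np.where(u < gq.frac_binding_mut, "mut_preferred",
                          np.where(u < gq.frac_binding_mut + gq.frac_binding_wt,
                                   "wt_preferred", "neutral"))
    v = rng.random(n)
    expr_class = np.where(v < gq.frac_expression_mut, "mut_preferred",
                          np.where(v < gq.frac_expression_mut + gq.frac_expression_wt,
                                   "wt_preferred", "neutral"))
    fc = gq.true_fold_change
    bind_fc = np.where(bind_class == "mut_preferred", fc,
                       np.where(bind_class == "wt_preferred", 1 / fc, 1.0))
    expr_fc = np.where(expr_class == "mut_preferred", fc,
                       np.where(expr_class == "wt_preferred", 1 / fc, 1.0))

    def noisy(mean):
        if gq.noise_log_sd == 0:
            return mean
        return mean * rng.lognormal(-0.5 * gq.noise_log_sd**2, gq.noise_log_sd, n)

    clip_base = gq.clip_per_expr * expr_base
    quant = pd.DataFrame({
        "gene_id": gene_ids,
        "clip_wt": np.round(noisy(clip_base)).astype(int),
        "clip_mut": np.round(noisy(clip_base * bind_fc)).astype(int),
        "expr_wt": noisy(expr_base),
        "expr_mut": noisy(expr_base * expr_fc),
    })
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "true_binding_class": bind_class,
        "true_expression_class": expr_class,
    })
    return quant, truth


def simulate_binding_splicing_link(n_events: int, switch_rate: float,
                                   coupling: float, seed: int
                                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic strong-splicing calls coupled to binding cluster switches.

    Emits a splicing-call table (event_id, site_id, bayes_factor, dpsi) and a
    cluster-switch table; P(strong | switch) is elevated by ``coupling``.
    Used to exercise the binding-splicing co-association test with a known
    positive effect.
    """
    rng = _substream(seed, "binding_splicing_link")
    site_ids = np.array([f"s{i:05d}" for i in range(n_events)])
    switch = rng.random(n_events) < switch_rate
    p_strong = np.where(switch, 0.2 + coupling, 0.2)
    strong = rng.random(n_events) < np.clip(p_strong, 0, 1)
    calls = pd.DataFrame({
        "event_id": [f"ev{i:05d}" for i in range(n_events)],
        "site_id": site_ids,
        "bayes_factor": np.where(strong, 50.0, 1.5),
        "dpsi": np.where(strong, 0.3, 0.02) * np.where(rng.random(n_events) < 0.5, 1, -1),
    })
    switches = pd.DataFrame({"site_id": site_ids, "switch": switch})
    return calls, switches
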