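"""Shared fixtures: tiny hand-built references and a small simulated data set."""

import numpy as np
import pandas as pd
import pytest

from ssclip import synthetic
from ssclip.io import Genome, RTStopTrack, annotate_sites, revcomp


def make_sites(rows):
    """Build a site table from (site_id, contig, strand, junction, gene_id) tuples."""
    return pd.DataFrame(
        rows, columns=["site_id", "contig", "strand", "junction", "gene_id"]
    ).assign(acceptor="")


def make_track(label, rows):
    """Build a track from (contig, strand, pos, count) tuples."""
    return RTStopTrack(label, pd.DataFrame(
        rows, columns=["contig", "strand", "pos", "count"]
    ))


def mirror_genome(genome: Genome) -> Genome:
    """Reverse-complement every contig."""
    return Genome({name: revcomp(genome[name]) for name in genome})


def mirror_sites(sites: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Flip strands and junctions to match a reverse-complemented genome."""
    out = sites.copy()
    lengths = out["contig"].map(lambda c: len(genome[c]))
    out["junction"] = lengths - 1 - out["junction"]
    out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    return out


def mirror_track(track: RTStopTrack, genome: Genome) -> RTStopTrack:
    df = track.df.copy()
    lengths = df["contig"].map(lambda c: len(genome[c]))
    df["pos"] = lengths - 1 - df["pos"]
    df["strand"] = df["strand"].map({"+": "-", "-": "+"})
    return RTStopTrack(track.condition_label, df)


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimConfig(n_genes=60)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return synthetic.simulate_reference(small_config, seed=11)


@pytest.fixture(scope="session")
def small_tracks(small_config, small_reference):
    genome, sites = small_reference
    return {
        cond: synthetic.simulate_rt_stops(genome, sites, small_config, cond, seed=11)
        for cond in ("wild_type", "mutant")
    }


@pytest.fixture(scope="session")
def larger_motif_run():
    """Hexamer statistics for both conditions on a 500-gene simulation;
    shared by the motif-direction tests that need decent counting depth."""
    from ssclip import motifs, occupancy
    cfg = synthetic.SimConfig(n_genes=500)
    genome, sites = synthetic.simulate_reference(cfg, seed=2)
    out = {}
    for cond in ("wild_type", "mutant"):
        track, _ = synthetic.simulate_rt_stops(genome, sites, cfg, cond, seed=2)
        occ = occupancy.call_occupied_sites(track, sites)
        occupied = sites[occ.to_numpy()]
        null = motifs.build_hexamer_null(sites, genome, M=len(occupied),
                                         n=50, seed=2)
        out[cond] = motifs.hexamer_zscores(occupied, track, genome, null)
    return out


@pytest.fixture(scope="session")
def toy_genome_sites():
    """One + and one - strand site sharing an identical transcript context."""
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    fwd = "".join(bases[rng.integers(0, 4, 200)])
    fwd = fwd[:97] + "CAG" + fwd[100:]          # acceptor before junction 100
    genome = Genome({"cA": fwd, "cB": revcomp(fwd)})
    sites = make_sites([
        ("sA", "cA", "+", 100, "gA"),
        ("sB", "cB", "-", 99, "gB"),            # same junction on the revcomp
    ])
    return genome, annotate_sites(sites, genome)
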