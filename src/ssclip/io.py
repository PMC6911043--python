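"""Readers, writers, and coordinate conventions shared by the whole pipeline.

Coordinate convention
---------------------
All genomic intervals are 0-based, half-open (the BED dialect).  Around a
3' splice site we work in *junction offsets*: offset 0 is the first exonic
nucleotide, -1 the last intronic nucleotide (the G of the AG acceptor),
-2 the A, and -3 the C of CAG (or the T of TAG).  Minus-strand sites are
reverse-complemented so offsets are always transcript-oriented.

Metagene figures for U2AF1 conventionally label the wild-type main
cross-link peak (the A of the AG) at position -5 and the S34F-mutant peak
(the G) at -4.  A configurable
``display_offset`` (default -3) converts internal junction offsets to those
display coordinates: ``display = internal + display_offset``.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
EVENT_TYPES = ("SE", "RI", "A3SS", "A5SS", "NAGNAG")

#: default conversion from internal junction offsets to display coordinates
DISPLAY_OFFSET = -3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class CoordinateError(ValueError):
    """A genomic coordinate falls outside its contig."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. psi outside [0, 1])."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_display(internal_offset, display_offset: int = DISPLAY_OFFSET):
    """Convert internal junction offsets to display (figure) coordinates."""
    return np.asarray(internal_offset) + display_offset


def to_internal(display, display_offset: int = DISPLAY_OFFSET):
    """Convert display coordinates back to internal junction offsets."""
    return np.asarray(display) - display_offset


# ---------------------------------------------------------------------------
# Genome


class Genome(Mapping):
    """Mapping of contig name -> uppercase nucleotide string (A,C,G,T,N).

    ``fetch`` returns forward-strand slices; ``transcript_window`` returns
    transcript-oriented sequence around a junction in junction offsets.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise FormatError("genome contains no sequences")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = str(seq).upper()
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise FormatError(f"contig {name!r} contains non-IUPAC characters {bad}")
            self._seqs[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self._seqs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(
                f"[{start}, {end}) outside contig {contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    def transcript_window(self, contig: str, strand: str, junction: int,
                          lo: int, hi: int) -> str:
        """Sequence at junction offsets ``lo..hi`` inclusive, transcript-oriented.

        Positions beyond the contig raise :class:`CoordinateError`.
        """
        if strand == "+":
            return self.fetch(contig, junction + lo, junction + hi + 1)
        if strand == "-":
            return revcomp(self.fetch(contig, junction - hi, junction - lo + 1))
        raise ValidationError(f"invalid strand {strand!r}")


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences uppercased)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return Genome(records)


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Splice sites

SITE_COLUMNS = ["site_id", "contig", "strand", "junction", "gene_id", "acceptor"]


def acceptor_trinucleotide(genome: Genome, contig: str, strand: str,
                           junction: int) -> str:
    """The three intronic bases at junction offsets -3..-1 (e.g. CAG)."""
    return genome.transcript_window(contig, strand, junction, -3, -1)


def annotate_sites(sites: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Populate/refresh the ``acceptor`` column from the genome and validate."""
    sites = sites.copy()
    if sites["site_id"].duplicated().any():
        dups = sites.loc[sites["site_id"].duplicated(), "site_id"].tolist()
        raise ValidationError(f"duplicate site_id(s): {dups[:5]}")
    acceptors = []
    for row in sites.itertuples(index=False):
        try:
            acceptors.append(
                acceptor_trinucleotide(genome, row.contig, row.strand, row.junction)
            )
        except CoordinateError as exc:
            raise CoordinateError(f"site {row.site_id!r}: {exc}") from exc
    sites["acceptor"] = acceptors
    return sites[SITE_COLUMNS].reset_index(drop=True)


def read_splice_sites(path, genome: Genome) -> pd.DataFrame:
    """Read 3'SS annotations from BED6 (name field ``site_id;gene_id``).

    The interval start is the junction on ``+``; ``end - 1`` on ``-``.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected BED6, got {len(parts)} fields")
            contig, start, end, name, _score, strand = parts[:6]
            if strand not in "+-":
                raise FormatError(f"{path}:{ln}: invalid strand {strand!r}")
            site_id, _, gene_id = name.partition(";")
            if not gene_id:
                gene_id = site_id
            junction = int(start) if strand == "+" else int(end) - 1
            rows.append((site_id, contig, strand, junction, gene_id, ""))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return annotate_sites(df, genome)


def write_splice_sites(sites: pd.DataFrame, path) -> None:
    """Write sites as BED6 single-base intervals (name = ``site_id;gene_id``)."""
    with open(path, "w") as fh:
        for row in sites.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.junction}\t{row.junction + 1}\t"
                f"{row.site_id};{row.gene_id}\t0\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# RT-stop tracks


class RTStopTrack:
    """Strand-aware per-position unique RT-stop counts for one condition.

    Positions are 0-based genomic coordinates; each count is the number of
    unique RT stops (cross-link truncation events) supporting that nucleotide.
    """

    def __init__(self, condition_label: str, df: pd.DataFrame):
        df = df.loc[df["count"] > 0, ["contig", "strand", "pos", "count"]]
        if (df["count"] < 0).any():
            raise FormatError("negative RT-stop count")
        df = (
            df.groupby(["contig", "strand", "pos"], as_index=False, sort=True)["count"]
            .sum()
        )
        self.condition_label = condition_label
        self.df = df.reset_index(drop=True)
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (contig, strand), grp in df.groupby(["contig", "strand"], sort=False):
            self._index[(contig, strand)] = (
                grp["pos"].to_numpy(np.int64),
                grp["count"].to_numpy(np.int64),
            )

    def __len__(self) -> int:
        return len(self.df)

    def total(self) -> int:
        return int(self.df["count"].sum())

    def positions(self, contig: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        return self._index.get((contig, strand), (np.empty(0, np.int64), np.empty(0, np.int64)))

    def window_counts(self, contig: str, strand: str, junction: int,
                      lo: int, hi: int) -> np.ndarray:
        """Counts at junction offsets ``lo..hi`` inclusive, transcript-oriented."""
        pos, cnt = self.positions(contig, strand)
        out = np.zeros(hi - lo + 1, dtype=np.int64)
        if len(pos) == 0:
            return out
        if strand == "+":
            start, end = junction + lo, junction + hi
            i, j = np.searchsorted(pos, [start, end + 1])
            out[pos[i:j] - start] = cnt[i:j]
        else:
            start, end = junction - hi, junction - lo
            i, j = np.searchsorted(pos, [start, end + 1])
            # genomic position p maps to offset junction - p
            out[(hi - lo) - (pos[i:j] - start)] = cnt[i:j]
        return out

    def filtered(self, min_support: int) -> "RTStopTrack":
        """Drop positions supported by fewer than ``min_support`` RT stops."""
        return RTStopTrack(
            self.condition_label, self.df[self.df["count"] >= min_support]
        )


def read_rt_stops(path, condition_label: str, strand: str | None = None,
                  min_support: int = 1) -> RTStopTrack:
    """Read RT stops from BED6 (score = count) or bedGraph (needs ``strand``).

    Overlapping/duplicate intervals are summed (with a logged warning).
    Zero-count lines are dropped; negative counts raise :class:`FormatError`.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) >= 6:
                contig, start, end, _name, score, strnd = parts[:6]
            elif len(parts) == 4:
                if strand is None:
                    raise FormatError(
                        f"{path}:{ln}: bedGraph input requires an explicit strand"
                    )
                contig, start, end, score = parts
                strnd = strand
            else:
                raise FormatError(f"{path}:{ln}: expected BED6 or bedGraph fields")
            count = float(score)
            if count != int(count) or int(count) < 0:
                raise FormatError(f"{path}:{ln}: count must be a nonnegative integer")
            count = int(count)
            if count == 0:
                continue
            for pos in range(int(start), int(end)):
                rows.append((contig, strnd, pos, count))
    df = pd.DataFrame(rows, columns=["contig", "strand", "pos", "count"])
    if df.duplicated(["contig", "strand", "pos"]).any():
        logger.warning("%s: duplicate positions found; counts summed", path)
    track = RTStopTrack(condition_label, df)
    if min_support > 1:
        track = track.filtered(min_support)
    return track


def write_rt_stops(track: RTStopTrack, path) -> None:
    """Write a track as BED6 single-base intervals with score = count."""
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.pos}\t{row.pos + 1}\t"
                f"{track.condition_label}\t{row.count}\t{row.strand}\n"
            )


@dataclass
class SiteProfiles:
    """Per-site RT-stop count vectors over junction offsets ``-L..+L``."""

    site_ids: np.ndarray
    offsets: np.ndarray            # internal junction offsets, ascending
    counts: np.ndarray             # shape (n_sites, 2L + 1)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def site_profiles(track: RTStopTrack, sites: pd.DataFrame, L: int) -> SiteProfiles:
    """Extract transcript-oriented count vectors of length ``2L + 1`` per site.

    Offsets falling outside the contig are filled with zeros (the track simply
    has no positions there).
    """
    if L < 1:
        raise ValidationError("L must be >= 1")
    offsets = np.arange(-L, L + 1)
    counts = np.zeros((len(sites), 2 * L + 1), dtype=np.int64)
    for i, row in enumerate(sites.itertuples(index=False)):
        counts[i] = track.window_counts(row.contig, row.strand, row.junction, -L, L)
    return SiteProfiles(sites["site_id"].to_numpy(), offsets, counts)


# ---------------------------------------------------------------------------
# PSI matrices and event counts


@dataclass
class PsiMatrix:
    """Events x samples table of psi in [0, 1] (NaN = missing) plus group labels."""

    values: pd.DataFrame                 # index event_id, columns sample_id
    groups: pd.Series = field(default=None)  # sample_id -> group label

    def __post_init__(self):
        vals = self.values.to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bad = (vals < 0) | (vals > 1)
        if np.nansum(bad) > 0:
            raise ValidationError("psi values must lie in [0, 1]")
        if self.groups is None:
            raise ValidationError("sample group labels are required")
        self.values.index.name = "event_id"
        self.values.columns.name = None
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValidationError(f"samples without group labels: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[self.values.columns]

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def write_psi_matrix(psi: PsiMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#group\t" + "\t".join(psi.groups.astype(str)) + "\n")
        fh.write("event_id\t" + "\t".join(psi.values.columns) + "\n")
        for event_id, row in psi.values.iterrows():
            cells = ["NA" if pd.isna(v) else format(v, ".6g") for v in row]
            fh.write(str(event_id) + "\t" + "\t".join(cells) + "\n")


def read_psi_matrix(path) -> PsiMatrix:
    with open(path) as fh:
        group_line = fh.readline().rstrip("\n")
        if not group_line.startswith("#group\t"):
            raise FormatError(f"{path}: missing '#group' header line")
        group_labels = group_line.split("\t")[1:]
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
    if len(group_labels) != df.shape[1]:
        raise FormatError(f"{path}: group header does not match sample columns")
    groups = pd.Series(group_labels, index=df.columns)
    return PsiMatrix(df, groups)


EVENT_COUNT_COLUMNS = [
    "event_id", "event_type", "site_id", "condition",
    "inclusion_reads", "exclusion_reads",
]


def validate_event_counts(events: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVENT_COUNT_COLUMNS) - set(events.columns)
    if missing:
        raise ValidationError(f"event-count table missing columns {sorted(missing)}")
    if (events[["inclusion_reads", "exclusion_reads"]] < 0).any().any():
        raise ValidationError("read counts must be nonnegative")
    bad_types = set(events["event_type"]) - set(EVENT_TYPES)
    if bad_types:
        raise ValidationError(f"unknown event type(s): {sorted(bad_types)}")
    return events[EVENT_COUNT_COLUMNS].reset_index(drop=True)


def write_table(df: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    """Write a TSV with a '#'-prefixed header line (the pipeline's output dialect)."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"## {line}\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (or any plain TSV with header)."""
    header = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                skip += 1
                continue
            header = line.rstrip("\n").lstrip("#").split("\t")
            skip += 1
            break
    if header is None:
        raise FormatError(f"{path}: empty file")
    return pd.read_csv(path, sep="\t", names=header, skiprows=skip, na_values=["NA"])


def read_event_counts(path) -> pd.DataFrame:
    return validate_event_counts(read_table(path))


def write_event_counts(events: pd.DataFrame, path) -> None:
    write_table(validate_event_counts(events), path)
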