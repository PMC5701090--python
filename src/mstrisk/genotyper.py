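"""Flank-anchored repeat-length genotyping from targeted amplicon reads.

Reads are treated as unaligned: each cataloged locus is located in a read
by exact match of the ``flank_len`` reference bases on either side of the
repeat tract, and the allele is the length in bp of the pure motif run
between the anchors.  Per-locus allele-length histograms are then reduced
to diploid genotypes with a fraction threshold that absorbs PCR stutter
(reads off by one repeat unit) without probabilistic correction — at the
high depths this pipeline targets, sub-threshold stutter peaks are simply
discarded.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .catalog import Panel, RepeatLocus

__all__ = [
    "Genotype",
    "AlleleHistogram",
    "GenotypeMatrix",
    "trim_reads",
    "extract_repeat_length",
    "call_genotype",
    "genotype_cohort",
    "coverage_summary",
]

MISSING = "."


@dataclass(frozen=True, order=True)
class Genotype:
    """Unordered pair of repeat-tract lengths (bp) with supporting depth.

    Equality used throughout screening is exact equality of the ordered
    (a1, a2) pair; depth is excluded from equality and ordering.
    """

    a1: int
    a2: int
    depth: int = field(default=0, compare=False)

    def __post_init__(self):
        if self.a1 > self.a2:
            raise ValueError("alleles must satisfy a1 <= a2; use Genotype.of()")
        if self.a1 < 0:
            raise ValueError("allele lengths must be non-negative")

    @classmethod
    def of(cls, a: int, b: int, depth: int = 0) -> "Genotype":
        return cls(min(a, b), max(a, b), depth)

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.a1, self.a2)

    def __str__(self) -> str:
        return f"{self.a1}/{self.a2}:{self.depth}"

    @classmethod
    def parse(cls, text: str) -> Optional["Genotype"]:
        if text == MISSING:
            return None
        pair, _, depth = text.partition(":")
        a, _, b = pair.partition("/")
        return cls.of(int(a), int(b), int(depth) if depth else 0)


@dataclass
class AlleleHistogram:
    """Read support per repeat-tract length (bp) at one locus."""

    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def add(self, length: int, n: int = 1) -> None:
        self.counts[length] = self.counts.get(length, 0) + n

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def trim_reads(
    reads: Iterable[SeqRecord],
    window: int = 4,
    min_q: int = 20,
    min_len: int = 36,
) -> list[SeqRecord]:
    """Sliding-window 3' quality trimming.

    Scanning 5'->3', a read is cut at the start of the first length-
    ``window`` window whose mean quality drops below ``min_q``; the cut
    point then advances over any immediately following bases that
    individually meet ``min_q``.  Reads shorter than ``min_len`` after
    trimming are dropped.
    """
    kept = []
    for rec in reads:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(rec.seq):
            raise ValueError(f"read {rec.id}: missing or mismatched quality string")
        cut = len(quals)
        for i in range(0, len(quals) - window + 1):
            if sum(quals[i : i + window]) / window < min_q:
                cut = i
                while cut < len(quals) and quals[cut] >= min_q:
                    cut += 1
                break
        if cut >= min_len:
            kept.append(rec[:cut] if cut < len(quals) else rec)
    return kept


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def _is_pure_run(segment: str, motif: str) -> bool:
    """True if segment is a (possibly partial-copy) run of some rotation."""
    if not segment:
        return True
    reps = math.ceil(len(segment) / len(motif))
    return any((rot * reps)[: len(segment)] == segment for rot in _rotations(motif))


def extract_repeat_length(
    read_seq: str,
    locus: RepeatLocus,
    left_flank: str,
    right_flank: str,
    flank_len: int = 10,
) -> Optional[int]:
    """Measure the repeat-tract length spanned by one read.

    Returns the number of bases strictly between exact, unique matches of
    the two anchoring flanks, provided that segment is a pure run of the
    locus motif (in any rotation).  Returns None (no measurement) when an
    anchor is absent, ambiguous, or the segment is impure.
    """
    if flank_len < 6:
        raise ValueError("flank_len < 6: anchoring unreliable")
    if len(left_flank) != flank_len or len(right_flank) != flank_len:
        raise ValueError("flank sequences must have length flank_len")
    read_seq = read_seq.upper()
    li = read_seq.find(left_flank)
    if li < 0 or read_seq.find(left_flank, li + 1) >= 0:
        return None
    ri = read_seq.find(right_flank)
    if ri < 0 or read_seq.find(right_flank, ri + 1) >= 0:
        return None
    seg_start = li + flank_len
    if ri < seg_start:
        return None
    segment = read_seq[seg_start:ri]
    if not _is_pure_run(segment, locus.motif):
        return None
    return len(segment)


def call_genotype(
    hist: AlleleHistogram,
    min_depth: int = 10,
    min_allele_frac: float = 0.25,
) -> Optional[Genotype]:
    """Reduce an allele histogram to a diploid genotype.

    Alleles supported by fewer than ``min_allele_frac`` of the locus reads
    are treated as PCR stutter and dropped.  Two or more surviving alleles
    give a heterozygote of the two best-supported lengths (count ties
    prefer the shorter length); exactly one gives a homozygote.  Loci with
    total depth below ``min_depth``, or no surviving allele, are missing.
    """
    total = hist.total_reads
    if total < min_depth or total == 0:
        return None
    retained = [
        (length, cnt) for length, cnt in hist.counts.items() if cnt / total >= min_allele_frac
    ]
    if not retained:
        return None
    retained.sort(key=lambda lc: (-lc[1], lc[0]))
    if len(retained) == 1:
        a = retained[0][0]
        return Genotype.of(a, a, total)
    return Genotype.of(retained[0][0], retained[1][0], total)


@dataclass
class GenotypeMatrix:
    """Samples x loci table of diploid repeat-length genotypes.

    ``labels`` maps every sample to ``"case"`` or ``"control"``; missing
    calls are simply absent from ``calls``.
    """

    sample_ids: list[str]
    labels: dict[str, str]
    loci: list[str]
    calls: dict[tuple[str, str], Genotype] = field(default_factory=dict)
    uncallable_loci: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing_labels = [s for s in self.sample_ids if s not in self.labels]
        if missing_labels:
            raise ValueError(f"samples without cohort label: {missing_labels[:5]}")
        bad = {lab for lab in self.labels.values()} - {"case", "control"}
        if bad:
            raise ValueError(f"labels must be 'case' or 'control', got {sorted(bad)}")

    def get(self, sample_id: str, locus_id: str) -> Optional[Genotype]:
        return self.calls.get((sample_id, locus_id))

    def sample_calls(self, sample_id: str) -> dict[str, Optional[Genotype]]:
        return {loc: self.calls.get((sample_id, loc)) for loc in self.loci}

    def locus_calls(self, locus_id: str, label: Optional[str] = None) -> list[Optional[Genotype]]:
        ids = self.sample_ids if label is None else [
            s for s in self.sample_ids if self.labels[s] == label
        ]
        return [self.calls.get((s, locus_id)) for s in ids]

    def call_rate(self, locus_id: str) -> float:
        calls = self.locus_calls(locus_id)
        return sum(c is not None for c in calls) / len(calls) if calls else 0.0

    def samples_by_label(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.labels[s] == label]

    def drop_sample(self, sample_id: str) -> "GenotypeMatrix":
        keep = [s for s in self.sample_ids if s != sample_id]
        return GenotypeMatrix(
            sample_ids=keep,
            labels={s: self.labels[s] for s in keep},
            loci=list(self.loci),
            calls={k: v for k, v in self.calls.items() if k[0] != sample_id},
            uncallable_loci=list(self.uncallable_loci),
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            loc: [str(g) if (g := self.calls.get((s, loc))) else MISSING for s in self.sample_ids]
            for loc in self.loci
        }
        df = pd.DataFrame(data, index=self.sample_ids)
        df.index.name = "sample_id"
        return df

    def to_tsv(self, path, labels_path=None) -> None:
        self.to_dataframe().to_csv(path, sep="\t")
        if labels_path is not None:
            with open(labels_path, "w") as fh:
                fh.write("sample_id\tlabel\n")
                for s in self.sample_ids:
                    fh.write(f"{s}\t{self.labels[s]}\n")

    @classmethod
    def from_tsv(cls, path, labels_path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        lab = pd.read_csv(labels_path, sep="\t", index_col=0)
        labels = lab.iloc[:, 0].to_dict()
        calls = {}
        for s in df.index:
            for loc in df.columns:
                g = Genotype.parse(df.at[s, loc])
                if g is not None:
                    calls[(s, loc)] = g
        return cls(
            sample_ids=list(df.index),
            labels={s: labels[s] for s in df.index},
            loci=list(df.columns),
            calls=calls,
        )


def locus_flanks(
    locus: RepeatLocus, reference: Mapping[str, str], flank_len: int = 10
) -> Optional[tuple[str, str]]:
    """Reference bases anchoring a locus; None when they fall off-contig."""
    seq = reference.get(locus.chrom)
    if seq is None or locus.start < flank_len or locus.end + flank_len > len(seq):
        return None
    return (
        str(seq[locus.start - flank_len : locus.start]).upper(),
        str(seq[locus.end : locus.end + flank_len]).upper(),
    )


def read_fasta(path) -> dict[str, str]:
    with _open_maybe_gzip(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def _reads_from(source) -> Iterable[SeqRecord]:
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as fh:
            yield from SeqIO.parse(fh, "fastq")
    else:
        yield from source


def genotype_cohort(
    samples: Mapping[str, object],
    panel: Panel,
    reference: Mapping[str, str] | str | Path,
    labels: Mapping[str, str],
    flank_len: int = 10,
    min_depth: int = 10,
    min_allele_frac: float = 0.25,
    trim: bool = True,
    trim_kwargs: Optional[dict] = None,
) -> GenotypeMatrix:
    """Genotype every sample at every panel locus.

    ``samples`` maps sample ids to FASTQ paths (gzip-aware) or iterables
    of Biopython SeqRecords.  Reads are assigned to loci by their left
    anchor flank, so anchor flanks must be unique across the panel; loci
    whose flanks cannot be extracted from the reference are flagged
    uncallable rather than failing the run.
    """
    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)

    flanks: dict[str, tuple[str, str]] = {}
    uncallable = []
    left_index: dict[str, RepeatLocus] = {}
    for locus in panel.loci:
        fl = locus_flanks(locus, reference, flank_len)
        if fl is None:
            uncallable.append(locus.locus_id)
            continue
        if fl[0] in left_index:
            raise ValueError(
                f"left anchor flank of {locus.locus_id} collides with "
                f"{left_index[fl[0]].locus_id}; increase flank_len"
            )
        flanks[locus.locus_id] = fl
        left_index[fl[0]] = locus

    sample_ids = list(samples)
    calls: dict[tuple[str, str], Genotype] = {}
    for sid, source in samples.items():
        reads = _reads_from(source)
        if trim:
            reads = trim_reads(reads, **(trim_kwargs or {}))
        hists: dict[str, AlleleHistogram] = {}
        for rec in reads:
            seq = str(rec.seq).upper()
            for i in range(len(seq) - flank_len + 1):
                locus = left_index.get(seq[i : i + flank_len])
                if locus is None:
                    continue
                lf, rf = flanks[locus.locus_id]
                length = extract_repeat_length(seq, locus, lf, rf, flank_len)
                if length is not None:
                    hists.setdefault(locus.locus_id, AlleleHistogram(locus.locus_id)).add(length)
                break
        for locus_id, hist in hists.items():
            gt = call_genotype(hist, min_depth=min_depth, min_allele_frac=min_allele_frac)
            if gt is not None:
                calls[(sid, locus_id)] = gt

    return GenotypeMatrix(
        sample_ids=sample_ids,
        labels={s: labels[s] for s in sample_ids},
        loci=[l.locus_id for l in panel.loci if l.locus_id not in uncallable],
        calls=calls,
        uncallable_loci=uncallable,
    )


def coverage_summary(matrix: GenotypeMatrix, min_call_rate: float = 0.93) -> pd.DataFrame:
    """Per-locus call rate and depth statistics.

    Loci whose call rate falls below ``min_call_rate`` are flagged; depth
    statistics are over non-missing calls only (NaN where a locus has no
    calls at all).
    """
    if not matrix.sample_ids or not matrix.loci:
        raise ValueError("empty genotype matrix")
    rows = []
    for loc in matrix.loci:
        calls = [c for c in matrix.locus_calls(loc) if c is not None]
        depths = np.array([c.depth for c in calls], dtype=float)
        rate = len(calls) / len(matrix.sample_ids)
        rows.append(
            {
                "locus_id": loc,
                "call_rate": rate,
                "mean_depth": depths.mean() if len(depths) else np.nan,
                "sd_depth": depths.std(ddof=1) if len(depths) > 1 else np.nan,
                "min_depth": depths.min() if len(depths) else np.nan,
                "flagged": rate < min_call_rate,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")
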