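"""Tandem-repeat catalogs: detection, panel assembly and BED-like I/O.

A microsatellite (MST) locus is a tract of a short (1-6 bp) unit repeated
in tandem.  This module detects *perfect* (ungapped, mismatch-free) tandem
tracts in reference sequences, manages catalogs of such loci, and merges
marker lists from several sources into a de-duplicated enrichment panel.

Coordinates are 0-based half-open internally; the 1-based inclusive
``chrN:a-b`` textual style used in marker tables is accepted on input and
produced on output via :func:`parse_region` / :func:`format_region`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "RepeatLocus",
    "Panel",
    "canonical_motif",
    "scan_tandem_repeats",
    "assemble_panel",
    "read_catalog",
    "write_catalog",
    "parse_region",
    "format_region",
]

_VALID_SEQ = re.compile(r"^[ACGTN]*$")
_REGION = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


def canonical_motif(unit: str) -> str:
    """Lexicographically minimal rotation of a repeat unit.

    ``AC`` and ``CA`` describe the same dinucleotide repeat read in a
    different phase; catalogs store the minimal rotation so that
    de-duplication treats them as one motif.
    """
    if not unit:
        raise ValueError("empty repeat unit")
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _primitive_period(unit: str) -> int:
    """Smallest p such that unit is a whole-number repeat of unit[:p]."""
    n = len(unit)
    for p in range(1, n + 1):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return p
    return n


@dataclass(frozen=True)
class RepeatLocus:
    """One cataloged microsatellite tract.

    ``motif`` is the canonical (minimal-rotation) unit; ``phase_motif``
    records the unit as it occurs at ``start``.  ``ref_tract_len`` is the
    total tract length in bp and always equals ``end - start``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str
    source_tag: str = "unspecified"
    phase_motif: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: end must exceed start")
        if not re.fullmatch(r"[ACGT]{1,6}", self.motif):
            raise ValueError(f"{self.locus_id}: motif must be 1-6 uppercase ACGT bases")
        if self.motif != canonical_motif(self.motif):
            raise ValueError(f"{self.locus_id}: motif {self.motif!r} is not canonical")
        if self.ref_tract_len % self.unit_len:
            raise ValueError(f"{self.locus_id}: tract length not a multiple of unit length")
        if self.unit_len >= 2 and self.copy_number < 2:
            raise ValueError(f"{self.locus_id}: fewer than 2 copies of a multi-base unit")
        if not self.phase_motif:
            object.__setattr__(self, "phase_motif", self.motif)

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    @property
    def ref_tract_len(self) -> int:
        return self.end - self.start

    @property
    def copy_number(self) -> int:
        return self.ref_tract_len // self.unit_len

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def region_string(self) -> str:
        return format_region(self.chrom, self.start, self.end)


@dataclass
class Panel:
    """A de-duplicated marker panel with per-source bookkeeping.

    A locus contributed by several sources keeps every tag (comma-joined
    in ``source_tag``); ``counts_by_source`` counts unique loci per tag,
    so the counts sum to the panel size exactly when sources are disjoint.
    """

    loci: list[RepeatLocus] = field(default_factory=list)
    counts_by_source: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loci)

    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive ``chrN:a-b`` span to 0-based half-open."""
    m = _REGION.match(text.strip())
    if not m:
        raise ValueError(f"malformed region string: {text!r}")
    start1, end1 = int(m["start"]), int(m["end"])
    if end1 < start1 or start1 < 1:
        raise ValueError(f"invalid coordinates in region string: {text!r}")
    return m["chrom"], start1 - 1, end1


def format_region(chrom: str, start: int, end: int) -> str:
    """0-based half-open span -> 1-based inclusive ``chrN:a-b``."""
    return f"{chrom}:{start + 1}-{end}"


def scan_tandem_repeats(
    seq: str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_tract_bp: int = 10,
    chrom: str = "seq",
    source_tag: str = "scan",
) -> list[RepeatLocus]:
    """Detect maximal perfect tandem tracts of 1-6 bp units.

    A reported tract is a whole-number repeat of a primitive unit,
    ``min_tract_bp`` or longer, that cannot be extended by a full unit in
    either direction.  When tracts of different unit sizes overlap, the
    smallest unit that explains the tract wins; remaining ties go to the
    leftmost, then longest, tract.  Tracts containing N are never called.
    """
    seq = seq.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    if not (1 <= min_unit <= max_unit <= 6):
        raise ValueError("require 1 <= min_unit <= max_unit <= 6")
    # every reported tract needs >= 2 whole copies; units larger than
    # min_tract_bp // 2 are subject to that stricter per-unit floor
    if min_tract_bp < 2 * min_unit:
        raise ValueError("min_tract_bp must be at least 2 * min_unit")

    n = len(seq)
    candidates: list[tuple[int, int, int, str]] = []  # (unit_len, start, tract_len, unit)
    for u in range(min_unit, max_unit + 1):
        i = 0
        while i + u < n:
            if seq[i] != seq[i + u] or seq[i] == "N":
                i += 1
                continue
            # maximal run of period-u matches beginning at i
            j = i
            while j + u < n and seq[j] == seq[j + u] and seq[j + u] != "N":
                j += 1
            run_len = (j - i) + u          # full span including partial copy
            tract_len = (run_len // u) * u  # trim to whole copies
            unit = seq[i : i + u]
            if (
                tract_len >= min_tract_bp
                and tract_len // u >= 2
                and _primitive_period(unit) == u
                and "N" not in unit
            ):
                candidates.append((u, i, tract_len, unit))
            i = j + 1

    # smallest unit first, then leftmost, then longest
    candidates.sort(key=lambda c: (c[0], c[1], -c[2]))
    accepted: list[tuple[int, int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for u, s, L, unit in candidates:
        if any(s < e0 and s + L > s0 for s0, e0 in occupied):
            continue
        accepted.append((u, s, L, unit))
        occupied.append((s, s + L))

    loci = []
    for u, s, L, unit in sorted(accepted, key=lambda c: c[1]):
        canon = canonical_motif(unit)
        loci.append(
            RepeatLocus(
                locus_id=f"{chrom}_{s}_{canon}",
                chrom=chrom,
                start=s,
                end=s + L,
                motif=canon,
                phase_motif=unit,
                source_tag=source_tag,
            )
        )
    return loci


def scan_reference(
    sequences: dict[str, str] | Iterable[tuple[str, str]],
    min_unit: int = 1,
    max_unit: int = 6,
    min_tract_bp: int = 10,
    source_tag: str = "scan",
) -> list[RepeatLocus]:
    """Run :func:`scan_tandem_repeats` over named sequences, sorted output."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    out: list[RepeatLocus] = []
    for name, seq in items:
        out.extend(
            scan_tandem_repeats(
                seq, min_unit, max_unit, min_tract_bp, chrom=name, source_tag=source_tag
            )
        )
    return sorted(out, key=lambda l: (l.chrom, l.start))


class CatalogError(ValueError):
    """Inconsistent or malformed catalog input."""


def assemble_panel(
    lung: Sequence[RepeatLocus],
    other_cancer: Sequence[RepeatLocus] = (),
    control: Sequence[RepeatLocus] = (),
) -> Panel:
    """Union of marker lists with exact-coordinate de-duplication.

    The three inputs carry the conventional source tags
    ``lung_signature`` / ``other_cancer`` / ``control_panel`` unless their
    loci already declare tags.  A locus present in several inputs keeps
    all tags; identical coordinates with conflicting motifs are a catalog
    inconsistency.  Idempotent and order-independent in its locus set.
    """
    default_tags = ("lung_signature", "other_cancer", "control_panel")
    merged: dict[tuple[str, int, int], RepeatLocus] = {}
    tags: dict[tuple[str, int, int], list[str]] = {}
    for group, default_tag in zip((lung, other_cancer, control), default_tags):
        for loc in group:
            tag = loc.source_tag if loc.source_tag != "unspecified" else default_tag
            if loc.key in merged:
                if merged[loc.key].motif != loc.motif:
                    raise CatalogError(
                        f"conflicting motifs at {loc.region_string()}: "
                        f"{merged[loc.key].motif} vs {loc.motif}"
                    )
                for t in tag.split(","):
                    if t not in tags[loc.key]:
                        tags[loc.key].append(t)
            else:
                merged[loc.key] = loc
                tags[loc.key] = list(dict.fromkeys(tag.split(",")))

    loci = []
    counts: dict[str, int] = {}
    for key in sorted(merged, key=lambda k: (k[0], k[1])):
        tag_list = tags[key]
        loci.append(replace(merged[key], source_tag=",".join(tag_list)))
        for t in tag_list:
            counts[t] = counts.get(t, 0) + 1
    return Panel(loci=loci, counts_by_source=counts)


def write_catalog(loci: Sequence[RepeatLocus], path) -> None:
    """Write a 6-column BED-like catalog (tab-separated, '#' comments)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlocus_id\tmotif\tsource_tag\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t"
                f"{loc.motif}\t{loc.source_tag}\n"
            )


def read_catalog(path) -> list[RepeatLocus]:
    """Read a BED-like catalog.

    Each data line is either the 6-column BED form
    (chrom, 0-based start, end, locus_id, motif, source_tag) or a
    4-column form whose first field is a 1-based inclusive
    ``chrN:a-b`` region string.
    """
    loci: list[RepeatLocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if ":" in fields[0]:
                    if len(fields) != 4:
                        raise ValueError("region-string lines need 4 columns")
                    chrom, start, end = parse_region(fields[0])
                    locus_id, motif, tag = fields[1], fields[2], fields[3]
                else:
                    if len(fields) != 6:
                        raise ValueError("BED lines need 6 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    locus_id, motif, tag = fields[3], fields[4], fields[5]
                if end <= start:
                    raise ValueError(f"end ({end}) must exceed start ({start})")
                loci.append(
                    RepeatLocus(
                        locus_id=locus_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        motif=canonical_motif(motif.upper()),
                        phase_motif=motif.upper(),
                        source_tag=tag,
                    )
                )
            except ValueError as exc:
                raise CatalogError(f"{path}, line {lineno}: {exc}") from exc
    return loci
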