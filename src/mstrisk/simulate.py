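"""Synthetic references, cohorts and reads with a truth manifest.

Everything the pipeline consumes can be generated here: reference contigs
with planted microsatellite tracts, case/control cohorts whose genotype
distributions carry a configurable set of informative loci, and amplicon
reads with depth, PCR-stutter and base-error models.  Every generator is
deterministic given the config seed, and a machine-readable
:class:`TruthManifest` records the planted truth so that recovery tests
have an exact oracle.

The default configuration mirrors the targeted-enrichment study design
this package models: a 347-locus panel, 30 case and 89 control samples,
a 13-locus informative signature, and per-locus read depth drawn from a
truncated normal with mean 579, s.d. 315 and floor 83.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .catalog import RepeatLocus, canonical_motif
from .genotyper import Genotype, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "simulate_reference",
    "simulate_cohort_genotypes",
    "simulate_reads",
    "simulate_all",
    "write_truth_manifest",
    "read_truth_manifest",
]

MANIFEST_VERSION = 1
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Full parameter set for one synthetic study.

    Cohort sizes, signature size and the depth model default to the
    targeted-enrichment design this package emulates (30 cases, 89
    controls, 13 informative loci out of a 347-locus panel, depth
    ~N(579, 315) floored at 83).  ``control_modal_freq`` is the frequency
    of the top control genotype at every locus; at informative loci the
    cases carry a shifted top genotype at ``case_shift_freq``.
    """

    seed: int = 0
    n_loci: int = 347
    n_informative: int = 13
    unit_len_weights: dict[int, float] = field(default_factory=lambda: {1: 0.75, 2: 0.25})
    tract_len_range: tuple[int, int] = (12, 26)
    flank_len: int = 10
    contig_pad: int = 30
    n_cases: int = 30
    n_controls: int = 89
    control_modal_freq: float = 0.8
    case_shift_freq: float = 0.7
    allele_spread: int = 2
    depth_mean: float = 579.0
    depth_sd: float = 315.0
    depth_min: int = 83
    stutter_rate: float = 0.02
    base_error_rate: float = 0.001
    errors_in_flanks: bool = False
    read_len: int = 100
    min_tract_bp: int = 10

    def __post_init__(self):
        if self.n_informative > self.n_loci:
            raise ValueError("n_informative cannot exceed n_loci")
        for name in ("control_modal_freq", "case_shift_freq"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.depth_min < 1:
            raise ValueError("depth_min must be >= 1")
        lo, hi = self.tract_len_range
        if lo < self.min_tract_bp or hi < lo:
            raise ValueError("tract_len_range must be ordered and >= min_tract_bp")
        max_tract = hi + 2 * self.allele_spread * max(self.unit_len_weights)
        if max_tract + 2 * self.flank_len > self.read_len:
            raise ValueError("tract + 2*flank_len must fit within read_len")
        if self.case_shift_freq <= 0.5:
            import warnings

            warnings.warn(
                "case_shift_freq <= 0.5: planted loci may not satisfy the "
                ">50% predominance rule",
                stacklevel=2,
            )

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["unit_len_weights"] = {int(k): v for k, v in raw.get("unit_len_weights", {1: 1.0}).items()}
        raw["tract_len_range"] = tuple(raw["tract_len_range"])
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class TruthManifest:
    """Planted truth: per-locus distributions and per-sample genotypes."""

    version: int
    seed: int
    informative_loci: list[str]
    # locus_id -> {"control": {genotype-str: prob}, "case": {...}}
    locus_distributions: dict[str, dict[str, dict[str, float]]]
    # sample_id -> {"label": ..., "genotypes": {locus_id: "a1/a2"}}
    samples: dict[str, dict]


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _random_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _contig_for_locus(
    rng: np.random.Generator, motif: str, copies: int, pad: int, min_tract_bp: int
) -> tuple[str, int]:
    """Pad + tract + pad, rejection-sampled so the tract is the only repeat.

    The scanner used for recovery requires that flanks neither extend the
    tract nor contain tandem tracts of their own.
    """
    from .catalog import scan_tandem_repeats

    tract = motif * copies
    for _ in range(200):
        left = _random_flank(rng, pad)
        right = _random_flank(rng, pad)
        contig = left + tract + right
        found = scan_tandem_repeats(contig, 1, 6, min_tract_bp)
        if (
            len(found) == 1
            and found[0].start == pad
            and found[0].end == pad + len(tract)
            and found[0].motif == canonical_motif(motif)
        ):
            return contig, pad
    raise RuntimeError("could not construct clean flanks (pad too small?)")


def simulate_reference(config: SimulationConfig) -> tuple[dict[str, str], list[RepeatLocus]]:
    """One contig per locus with unique, repeat-free flanks.

    Returns the reference as a name->sequence mapping plus the exact
    locus catalog.  Deterministic given the config seed.
    """
    rng = _rng_for(config.seed, 1)
    units = sorted(config.unit_len_weights)
    weights = np.array([config.unit_len_weights[u] for u in units], dtype=float)
    weights /= weights.sum()

    reference: dict[str, str] = {}
    catalog: list[RepeatLocus] = []
    seen_left_flanks: set[str] = set()
    for i in range(config.n_loci):
        unit_len = int(rng.choice(units, p=weights))
        motif = ""
        while _unit_not_primitive(motif):
            motif = "".join(_BASES[b] for b in rng.integers(0, 4, size=unit_len))
        lo, hi = config.tract_len_range
        copies = max(2, int(rng.integers(lo, hi + 1)) // unit_len)
        if copies * unit_len < config.min_tract_bp:
            copies = -(-config.min_tract_bp // unit_len)
        contig_name = f"locus{i:04d}"
        for _ in range(200):
            contig, start = _contig_for_locus(
                rng, motif, copies, config.contig_pad, config.min_tract_bp
            )
            left_anchor = contig[start - config.flank_len : start]
            if left_anchor not in seen_left_flanks:
                seen_left_flanks.add(left_anchor)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not find a unique left anchor flank")
        reference[contig_name] = contig
        catalog.append(
            RepeatLocus(
                locus_id=contig_name,
                chrom=contig_name,
                start=start,
                end=start + copies * unit_len,
                motif=canonical_motif(motif),
                phase_motif=motif,
                source_tag="synthetic",
            )
        )
    return reference, catalog


def _unit_not_primitive(unit: str) -> bool:
    if not unit:
        return True
    n = len(unit)
    return any(n % p == 0 and unit == unit[:p] * (n // p) for p in range(1, n))


def _genotype_str(g: tuple[int, int]) -> str:
    return f"{g[0]}/{g[1]}"


def _parse_genotype_str(text: str) -> tuple[int, int]:
    a, _, b = text.partition("/")
    return (int(a), int(b))


def _locus_genotype_space(locus: RepeatLocus, spread: int) -> list[tuple[int, int]]:
    """Candidate genotypes: unordered pairs of alleles within ``spread`` units."""
    u = locus.unit_len
    ref = locus.ref_tract_len
    alleles = [ref + k * u for k in range(-spread, spread + 1) if ref + k * u >= u]
    pairs = set()
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            pairs.add((a, b))
    return sorted(pairs)


def _cohort_distribution(
    space: list[tuple[int, int]], top: tuple[int, int], top_freq: float
) -> dict[str, float]:
    others = [g for g in space if g != top]
    rest = (1.0 - top_freq) / len(others) if others else 0.0
    dist = {_genotype_str(top): top_freq}
    for g in others:
        dist[_genotype_str(g)] = rest
    return dist


def simulate_cohort_genotypes(
    config: SimulationConfig, catalog: list[RepeatLocus]
) -> tuple[GenotypeMatrix, TruthManifest]:
    """Draw true genotypes for every sample at every locus.

    Controls draw from a distribution whose top genotype (the reference
    homozygote) has frequency ``control_modal_freq``; at the
    ``n_informative`` planted loci, cases draw a *different* top genotype
    (the one-unit-expanded homozygote) at ``case_shift_freq``.  Remaining
    probability mass is spread uniformly over the other genotypes built
    from alleles within ``allele_spread`` units of the reference.
    """
    rng = _rng_for(config.seed, 2)
    informative_ids = [loc.locus_id for loc in catalog[: config.n_informative]]

    sample_ids = [f"case{i:03d}" for i in range(config.n_cases)] + [
        f"ctrl{i:03d}" for i in range(config.n_controls)
    ]
    labels = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}

    locus_distributions: dict[str, dict[str, dict[str, float]]] = {}
    samples: dict[str, dict] = {
        s: {"label": labels[s], "genotypes": {}} for s in sample_ids
    }
    calls: dict[tuple[str, str], Genotype] = {}

    for loc in catalog:
        space = _locus_genotype_space(loc, config.allele_spread)
        ref_hom = (loc.ref_tract_len, loc.ref_tract_len)
        control_dist = _cohort_distribution(space, ref_hom, config.control_modal_freq)
        if loc.locus_id in informative_ids:
            shifted = (loc.ref_tract_len + loc.unit_len, loc.ref_tract_len + loc.unit_len)
            case_dist = _cohort_distribution(space, shifted, config.case_shift_freq)
        else:
            case_dist = control_dist
        locus_distributions[loc.locus_id] = {"control": control_dist, "case": case_dist}

        for dist, cohort in ((case_dist, "case"), (control_dist, "control")):
            genotypes = list(dist)
            probs = np.array([dist[g] for g in genotypes])
            cohort_samples = [s for s in sample_ids if labels[s] == cohort]
            draws = rng.choice(len(genotypes), size=len(cohort_samples), p=probs)
            for s, d in zip(cohort_samples, draws):
                g = _parse_genotype_str(genotypes[d])
                samples[s]["genotypes"][loc.locus_id] = genotypes[d]
                calls[(s, loc.locus_id)] = Genotype(g[0], g[1], depth=0)

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        labels=labels,
        loci=[loc.locus_id for loc in catalog],
        calls=calls,
    )
    manifest = TruthManifest(
        version=MANIFEST_VERSION,
        seed=config.seed,
        informative_loci=informative_ids,
        locus_distributions=locus_distributions,
        samples=samples,
    )
    return matrix, manifest


def _truncated_normal_depth(
    rng: np.random.Generator, mean: float, sd: float, floor: int, size: int
) -> np.ndarray:
    """Normal draws rounded and raised to the floor.

    Clamping (rather than redrawing) keeps the mean close to the nominal
    value and reproduces a hard per-locus depth minimum.
    """
    out = np.rint(rng.normal(mean, sd, size=size)).astype(int)
    return np.maximum(out, floor)


def simulate_reads(
    matrix: GenotypeMatrix,
    catalog: list[RepeatLocus],
    reference: dict[str, str],
    config: SimulationConfig,
) -> dict[str, list[tuple[str, str, str]]]:
    """Per-sample amplicon reads as (name, sequence, quality) triples.

    Per sample and locus, depth is drawn from the truncated normal depth
    model; each read picks one of the two true alleles with equal
    probability, suffers one-unit stutter (contraction or expansion,
    equal probability) at ``stutter_rate``, and substitution errors at
    ``base_error_rate`` per base.  Errors are excluded from the
    ``flank_len`` anchor bases adjacent to the tract unless
    ``errors_in_flanks`` is set.  Read names encode sample, locus and the
    true allele for debugging.  Deterministic given the config seed.
    """
    rng = _rng_for(config.seed, 3)
    by_id = {loc.locus_id: loc for loc in catalog}
    reads_per_sample: dict[str, list[tuple[str, str, str]]] = {s: [] for s in matrix.sample_ids}

    for sample_id in matrix.sample_ids:
        for locus_id in matrix.loci:
            truth = matrix.get(sample_id, locus_id)
            if truth is None:
                continue
            loc = by_id[locus_id]
            contig = reference[loc.chrom]
            unit = loc.phase_motif or loc.motif
            u = len(unit)
            left_ctx_len = min(loc.start, (config.read_len - loc.ref_tract_len) // 2)
            left_ctx = contig[loc.start - left_ctx_len : loc.start]
            right_ctx = contig[loc.end :]

            depth = int(
                _truncated_normal_depth(
                    rng, config.depth_mean, config.depth_sd, config.depth_min, 1
                )[0]
            )
            allele_pick = rng.integers(0, 2, size=depth)
            stutter_hit = rng.random(depth) < config.stutter_rate
            stutter_dir = rng.integers(0, 2, size=depth) * 2 - 1
            for r in range(depth):
                allele = truth.alleles[allele_pick[r]]
                length = allele
                if stutter_hit[r]:
                    length = max(u, allele + int(stutter_dir[r]) * u)
                tract = (unit * (length // u + 2))[:length]
                seq = (left_ctx + tract + right_ctx)[: config.read_len]
                if config.base_error_rate > 0:
                    if config.errors_in_flanks:
                        protected = []
                    else:
                        # spare only the two anchor windows; tract errors are allowed
                        protected = [
                            (len(left_ctx) - config.flank_len, len(left_ctx)),
                            (
                                len(left_ctx) + length,
                                len(left_ctx) + length + config.flank_len,
                            ),
                        ]
                    seq = _apply_base_errors(seq, rng, config.base_error_rate, protected)
                name = f"{sample_id}|{locus_id}|allele={allele}|read={r}"
                reads_per_sample[sample_id].append((name, seq, "I" * len(seq)))
    return reads_per_sample


def _apply_base_errors(
    seq: str,
    rng: np.random.Generator,
    rate: float,
    protected: list[tuple[int, int]],
) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        if any(lo <= i < hi for lo, hi in protected):
            continue
        choices = [b for b in _BASES if b != chars[i]]
        chars[i] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_fasta(reference: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n{seq}\n")


def write_truth_manifest(manifest: TruthManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=1, sort_keys=True)


def read_truth_manifest(path) -> TruthManifest:
    with open(path) as fh:
        raw = json.load(fh)
    if raw.get("version") != MANIFEST_VERSION:
        raise ValueError(
            f"manifest version {raw.get('version')!r} != expected {MANIFEST_VERSION}"
        )
    return TruthManifest(**raw)


def simulate_all(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate reference, catalog, reads, labels and manifest on disk."""
    from .catalog import write_catalog

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, catalog = simulate_reference(config)
    matrix, manifest = simulate_cohort_genotypes(config, catalog)
    reads = simulate_reads(matrix, catalog, reference, config)

    paths = {
        "reference": outdir / "reference.fasta",
        "catalog": outdir / "catalog.bed",
        "labels": outdir / "labels.tsv",
        "manifest": outdir / "truth_manifest.json",
        "truth_matrix": outdir / "truth_genotypes.tsv",
    }
    write_fasta(reference, paths["reference"])
    write_catalog(catalog, paths["catalog"])
    write_truth_manifest(manifest, paths["manifest"])
    matrix.to_tsv(paths["truth_matrix"], labels_path=paths["labels"])
    fastq_dir = outdir / "reads"
    fastq_dir.mkdir(exist_ok=True)
    for sample_id, sample_reads in reads.items():
        p = fastq_dir / f"{sample_id}.fastq"
        write_fastq(sample_reads, p)
        paths[f"fastq:{sample_id}"] = p
    return paths
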