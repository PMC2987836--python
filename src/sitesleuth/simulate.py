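"""Seeded generators: random genomes, coding masks, planted motifs, training sets.

The generators emulate the study design every stage of the package expects:
a genome with annotated coding intervals, a set of true binding sites of a
single transcription factor planted in the non-coding portion (the
consensus with per-position substitution noise, on either strand), and
training sets of those positives plus uniformly sampled non-coding negative
windows.  Everything is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sitesleuth.genome import (
    GenomeAnnotation,
    NonCodingRegions,
    extract_noncoding,
    sample_negative_windows,
)
from sitesleuth.mapping import SiteOrigin, SiteSequence, reverse_complement

BASES = "ACGT"


@dataclass(frozen=True)
class MotifSpec:
    """A consensus L-mer with an i.i.d. per-position substitution probability."""

    consensus: str
    theta: float = 0.0

    def __post_init__(self) -> None:
        if set(self.consensus) - set(BASES):
            raise ValueError("consensus must be over ACGT")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("substitution probability must be in [0, 1)")

    @property
    def L(self) -> int:
        return len(self.consensus)


@dataclass
class PlantedGenome:
    """A genome with coding intervals and a truth set of planted sites."""

    sequence: str
    coding: list[tuple[int, int]]
    truth: list[tuple[int, int, str]]  # (start, end, strand)
    seed: int
    seq_id: str = "synth_chr"

    def annotation(self, circular: bool = False) -> GenomeAnnotation:
        return GenomeAnnotation(sequences={self.seq_id: self.sequence},
                                coding={self.seq_id: list(self.coding)},
                                circular={self.seq_id: circular})

    def truth_sites(self) -> list[SiteSequence]:
        """The planted sites as strand-resolved sites with genuine genome context."""
        out = []
        g = self.sequence
        for s, e, strand in self.truth:
            if strand == "+":
                out.append(SiteSequence(core=g[s:e], left_context=g[s - 1],
                                        right_context=g[e],
                                        origin=SiteOrigin(self.seq_id, s, e, "+")))
            else:
                out.append(SiteSequence(core=reverse_complement(g[s:e]),
                                        left_context=reverse_complement(g[e]),
                                        right_context=reverse_complement(g[s - 1]),
                                        origin=SiteOrigin(self.seq_id, s, e, "-")))
        return out


def generate_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """i.i.d. random genome with P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2."""
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be strictly between 0 and 1")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2
    gc = gc_fraction / 2
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(BASES[i] for i in draws)


def random_coding_intervals(length: int, fraction: float = 0.5, n_intervals: int = 20,
                            seed: int = 0) -> list[tuple[int, int]]:
    """Evenly spread, non-overlapping coding intervals covering roughly
    ``fraction`` of the sequence (bacterial genomes are gene-dense; half
    coding keeps plenty of both classes at fixture scale)."""
    rng = np.random.default_rng(seed)
    block = length // n_intervals
    intervals = []
    for i in range(n_intervals):
        span = int(block * fraction)
        if span < 1:
            continue
        lo = i * block
        start = lo + int(rng.integers(0, block - span + 1))
        intervals.append((start, start + span))
    return intervals


def _mutate(consensus: str, theta: float, rng: np.random.Generator) -> str:
    out = []
    for b in consensus:
        if theta > 0 and rng.random() < theta:
            out.append(rng.choice([c for c in BASES if c != b]))
        else:
            out.append(b)
    return "".join(out)


def plant_motifs(genome: str, coding: list[tuple[int, int]], spec: MotifSpec,
                 n_sites: int, seed: int = 0, seq_id: str = "synth_chr") -> PlantedGenome:
    """Plant ``n_sites`` noisy copies of the consensus at non-overlapping
    non-coding positions (with one base of context available), on uniformly
    random strands.  Returns the modified genome plus the truth set.
    """
    L = spec.L
    rng = np.random.default_rng(seed)
    annotation = GenomeAnnotation(sequences={seq_id: genome}, coding={seq_id: coding})
    regions = extract_noncoding(annotation)
    candidates = []
    for rid, s, e in regions.regions:
        for start in range(max(s, 1), min(e - L + 1, len(genome) - L)):
            candidates.append(start)
    rng.shuffle(candidates)
    chosen: list[int] = []
    for start in candidates:
        if len(chosen) == n_sites:
            break
        if all(abs(start - c) >= L for c in chosen):
            chosen.append(start)
    if len(chosen) < n_sites:
        raise ValueError(
            f"not enough non-overlapping non-coding space for {n_sites} plants")
    chosen.sort()
    seq = list(genome)
    truth = []
    for start in chosen:
        instance = _mutate(spec.consensus, spec.theta, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = instance if strand == "+" else reverse_complement(instance)
        seq[start:start + L] = placed
        truth.append((start, start + L, strand))
    return PlantedGenome(sequence="".join(seq), coding=list(coding), truth=truth,
                         seed=seed, seq_id=seq_id)


def make_training_sets(pg: PlantedGenome, n_negatives: int = 10000,
                       seed: int = 0) -> dict:
    """Positives (truth sites with genome context) and sampled negatives.

    Negative windows exclude anything overlapping a truth interval, so the
    two sets are disjoint by construction.
    """
    if not pg.truth:
        raise ValueError("truth set is empty")
    annotation = pg.annotation()
    regions = extract_noncoding(annotation)
    exclude = [(pg.seq_id, s, e) for s, e, _ in pg.truth]
    negatives = sample_negative_windows(annotation, regions,
                                        L=pg.truth[0][1] - pg.truth[0][0],
                                        count=n_negatives, seed=seed,
                                        exclude=exclude)
    return {"positives": pg.truth_sites(), "negatives": negatives}


def write_scenario(pg: PlantedGenome, outdir: str | Path) -> None:
    """Write genome.fa, coding.bed, truth.bed, sites.fa for a planted genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        fh.write(f">{pg.seq_id}\n")
        for i in range(0, len(pg.sequence), 70):
            fh.write(pg.sequence[i:i + 70] + "\n")
    with open(outdir / "coding.bed", "w") as fh:
        for s, e in pg.coding:
            fh.write(f"{pg.seq_id}\t{s}\t{e}\n")
    with open(outdir / "truth.bed", "w") as fh:
        for i, (s, e, strand) in enumerate(pg.truth):
            fh.write(f"{pg.seq_id}\t{s}\t{e}\tsite_{i}\t0\t{strand}\n")
    with open(outdir / "sites.fa", "w") as fh:
        for i, site in enumerate(pg.truth_sites()):
            o = site.origin
            fh.write(f">site_{i} {o.seq_id}:{o.start}-{o.end}:{o.strand}\n{site.core}\n")
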