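"""Reading the standard formats the pipelines consume: FASTA, BED, site TSV."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from sitesleuth.genome import GenomeAnnotation
from sitesleuth.mapping import SiteOrigin, SiteSequence, plus_strand_site, minus_strand_site, site_from_sequence


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED intervals (first three columns), 0-based half-open, grouped by sequence."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return out


def read_bed_stranded(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "+"
            out.append((f[0], int(f[1]), int(f[2]), strand))
    return out


def load_annotation(genome_fa: str | Path, coding_bed: str | Path,
                    circular: bool = False) -> GenomeAnnotation:
    seqs = read_fasta(genome_fa)
    coding = read_bed(coding_bed)
    return GenomeAnnotation(sequences=seqs, coding=coding,
                            circular={k: circular for k in seqs})


def sites_from_bed(bed_path: str | Path, genome: dict[str, str]) -> list[SiteSequence]:
    """Stranded intervals resolved to sites with genuine genome context."""
    out = []
    for seq_id, start, end, strand in read_bed_stranded(bed_path):
        seq = genome[seq_id]
        if strand == "-":
            out.append(minus_strand_site(seq_id, seq, start, end))
        else:
            out.append(plus_strand_site(seq_id, seq, start, end))
    return out


def sites_from_fasta(path: str | Path, genome: dict[str, str] | None = None) -> list[SiteSequence]:
    """Site sequences from FASTA; IDs may carry ``chrom:start-end:strand``.

    When coordinates resolve against a supplied genome, genuine context is
    extracted; otherwise the core is padded (5' G / 3' C).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        core = str(rec.seq).upper()
        origin = _parse_origin(rec.description)
        if origin is not None and genome is not None and origin.seq_id in genome:
            seq = genome[origin.seq_id]
            if origin.strand == "-":
                out.append(minus_strand_site(origin.seq_id, seq, origin.start, origin.end))
            else:
                out.append(plus_strand_site(origin.seq_id, seq, origin.start, origin.end))
        else:
            out.append(site_from_sequence(core, origin=origin))
    return out


def _parse_origin(description: str) -> SiteOrigin | None:
    for token in description.split():
        parts = token.split(":")
        if len(parts) == 3 and "-" in parts[1]:
            try:
                start, end = parts[1].split("-")
                return SiteOrigin(parts[0], int(start), int(end), parts[2])
            except ValueError:
                continue
    return None
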