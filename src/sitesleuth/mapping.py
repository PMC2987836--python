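"""Map an L-base DNA site (with one base of flanking context per side) to its
feature vector.

Each of the L core positions contributes 8 chemical features for the 3-mer
centred on it, 8 chemical features for that 3-mer's reverse complement (the
other strand reads the same helix), and 6 base-pair geometry features; each
of the L-1 steps contributes 6 base-step geometry features looked up by the
4-mer covering the step with one base of context on either side.  The vector
therefore has 16L + 6L + 6(L-1) = 28L - 6 components.  The first and last
windows reach into the flanking context, which is why one genuine (or
padded) base per side is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from sitesleuth.tables import FeatureTableBundle

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


def _check_alphabet(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise SequenceAlphabetError(f"{what} contains non-ACGT character(s): {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Integer codes (base-4, A=0..T=3) of every k-mer of ``seq``, in order."""
    _check_alphabet(seq)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for b, v in _BASE_CODE.items():
        lut[ord(b)] = v
    vals = lut[codes]
    n = len(seq) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * 4 + vals[j:j + n]
    return out


def kmer_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = code * 4 + _BASE_CODE[b]
    return code


@dataclass(frozen=True)
class SiteOrigin:
    """Genomic provenance of a site: 0-based half-open interval plus strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class SiteSequence:
    """An L-base core sequence with at least one base of context per side."""

    core: str
    left_context: str
    right_context: str
    origin: Optional[SiteOrigin] = None

    def __post_init__(self) -> None:
        _check_alphabet(self.core, "core")
        _check_alphabet(self.left_context, "left context")
        _check_alphabet(self.right_context, "right context")
        if len(self.core) < 2:
            raise ValueError(f"core length must be >= 2, got {len(self.core)}")
        if not self.left_context or not self.right_context:
            raise ValueError("both flanking contexts must be non-empty")

    @property
    def L(self) -> int:
        return len(self.core)

    def extended(self) -> str:
        """Core flanked by exactly one context base per side."""
        return self.left_context[-1] + self.core + self.right_context[0]


def site_from_sequence(seq: str, pad: bool = True,
                       origin: Optional[SiteOrigin] = None) -> SiteSequence:
    """Build a :class:`SiteSequence` from a bare core sequence.

    Context-free sites (e.g. training sites given as plain sequences) are by
    default padded with G on the 5' side and C on the 3' side, mirroring the
    GC capping used when the real feature tables were computed; with
    ``pad=False`` the missing context is an error instead.
    """
    if not pad:
        raise ValueError("sequence has no flanking context and padding is disabled")
    logger.debug("padding context-free site %s with G/C flanks", seq)
    return SiteSequence(core=seq, left_context="G", right_context="C", origin=origin)


def feature_dimension(L: int) -> int:
    """Number of feature components for a site of length L: 28L - 6."""
    if L < 1:
        raise ValueError(f"site length must be >= 1, got {L}")
    return 28 * L - 6


@dataclass(frozen=True)
class FeatureLayout:
    """Index arithmetic for the fixed block order of a feature vector.

    Layout: per-position chemical blocks [fwd(8), rev(8)] for j = 0..L-1,
    then base-geometry blocks (6) for j = 0..L-1, then step-geometry blocks
    (6) for s = 0..L-2.
    """

    L: int

    @property
    def n_total(self) -> int:
        return feature_dimension(self.L)

    @property
    def n_chemical(self) -> int:
        return 16 * self.L

    @property
    def n_base(self) -> int:
        return 6 * self.L

    @property
    def n_step(self) -> int:
        return 6 * (self.L - 1)

    @property
    def chemical_slice(self) -> slice:
        return slice(0, self.n_chemical)

    @property
    def base_slice(self) -> slice:
        return slice(self.n_chemical, self.n_chemical + self.n_base)

    @property
    def step_slice(self) -> slice:
        return slice(self.n_chemical + self.n_base, self.n_total)

    def chem_fwd_block(self, j: int) -> slice:
        self._check_pos(j)
        return slice(16 * j, 16 * j + 8)

    def chem_rev_block(self, j: int) -> slice:
        self._check_pos(j)
        return slice(16 * j + 8, 16 * j + 16)

    def base_block(self, j: int) -> slice:
        self._check_pos(j)
        off = self.n_chemical
        return slice(off + 6 * j, off + 6 * (j + 1))

    def step_block(self, s: int) -> slice:
        if not 0 <= s < self.L - 1:
            raise IndexError(f"step index {s} out of range for L={self.L}")
        off = self.n_chemical + self.n_base
        return slice(off + 6 * s, off + 6 * (s + 1))

    def _check_pos(self, j: int) -> None:
        if not 0 <= j < self.L:
            raise IndexError(f"position {j} out of range for L={self.L}")


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: FeatureLayout

    def __post_init__(self) -> None:
        if len(self.values) != self.layout.n_total:
            raise ValueError(
                f"vector length {len(self.values)} != layout size {self.layout.n_total}")


def site_kmers(site: SiteSequence) -> tuple[list[str], list[str]]:
    """The L 3-mers (one centred on each core base) and L-1 step 4-mers."""
    ext = site.extended()
    L = site.L
    triplets = [ext[j:j + 3] for j in range(L)]
    quads = [ext[s:s + 4] for s in range(L - 1)]
    return triplets, quads


def map_sequence_to_features(site: SiteSequence,
                             tables: FeatureTableBundle) -> FeatureVector:
    """Assemble the 28L-6 feature vector for a site via table lookups."""
    chem, base, step = tables.arrays()
    layout = FeatureLayout(site.L)
    triplets, quads = site_kmers(site)
    out = np.empty(layout.n_total)
    for j, t in enumerate(triplets):
        c = kmer_code(t)
        c_rc = kmer_code(reverse_complement(t))
        out[layout.chem_fwd_block(j)] = chem[c]
        out[layout.chem_rev_block(j)] = chem[c_rc]
        out[layout.base_block(j)] = base[c]
    for s, q in enumerate(quads):
        out[layout.step_block(s)] = step[kmer_code(q)]
    return FeatureVector(values=out, layout=layout)


def map_sites_matrix(sites: list[SiteSequence],
                     tables: FeatureTableBundle) -> np.ndarray:
    """Stack feature vectors for equal-length sites into an (N, 28L-6) matrix."""
    if not sites:
        raise ValueError("no sites given")
    L = sites[0].L
    if any(s.L != L for s in sites):
        raise ValueError("sites have unequal lengths")
    return np.stack([map_sequence_to_features(s, tables).values for s in sites])


def minus_strand_site(seq_id: str, genome: str, start: int, end: int) -> SiteSequence:
    """Extract a minus-strand site: reverse-complemented core with swapped contexts."""
    if start < 1 or end > len(genome) - 1:
        raise ValueError("context unavailable at sequence terminus")
    core = reverse_complement(genome[start:end])
    left = reverse_complement(genome[end:end + 1])
    right = reverse_complement(genome[start - 1:start])
    return SiteSequence(core=core, left_context=left, right_context=right,
                        origin=SiteOrigin(seq_id, start, end, "-"))


def plus_strand_site(seq_id: str, genome: str, start: int, end: int) -> SiteSequence:
    if start < 1 or end > len(genome) - 1:
        raise ValueError("context unavailable at sequence terminus")
    return SiteSequence(core=genome[start:end],
                        left_context=genome[start - 1:start],
                        right_context=genome[end:end + 1],
                        origin=SiteOrigin(seq_id, start, end, "+"))
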