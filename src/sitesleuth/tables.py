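"""Per-k-mer feature tables: data model, TSV I/O, PCA reduction, synthesis.

Every DNA 3-mer carries six base-pair geometry parameters (for its middle
base pair) and a set of chemical features describing the molecular
interaction field around the middle base; every 4-mer carries six base-step
geometry parameters for its central step.  The chemical features start life
as a 64 x 62 matrix of raw probe interaction quantities (a minimum
interaction energy P_i and an integrated interaction score Q_i for each of
31 chemical probes) and are reduced to 8 principal-component scores per
3-mer.  Real tables come from molecular-dynamics / interaction-field
calculations performed once and tabulated; this module also provides a
seeded synthetic generator so the full pipeline runs without those inputs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
KMERS3 = ["".join(p) for p in itertools.product(BASES, repeat=3)]
KMERS4 = ["".join(p) for p in itertools.product(BASES, repeat=4)]

BASE_GEOMETRY_COLUMNS = ("shear", "buckle", "stretch", "propeller", "stagger", "opening")
STEP_GEOMETRY_COLUMNS = ("shift", "tilt", "slide", "roll", "rise", "twist")
#: angular parameters (degrees); the rest are translations (Angstrom)
ANGULAR_BASE = ("buckle", "propeller", "opening")
ANGULAR_STEP = ("tilt", "roll", "twist")

RAW_CHEMICAL_COLUMNS = tuple(
    f"{kind}{i:02d}" for kind in ("P", "Q") for i in range(1, 32)
)
CHEMICAL_COLUMNS = tuple(f"c{i}" for i in range(1, 9))

# text format that round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


class FeatureTableError(ValueError):
    """Raised for structurally invalid feature tables."""


def _check_kmer_index(df: pd.DataFrame, expected: list[str], what: str) -> None:
    keys = list(df.index)
    bad = [k for k in keys if not (isinstance(k, str) and set(k) <= set(BASES))]
    if bad:
        raise FeatureTableError(f"{what}: non-ACGT k-mer key(s): {bad[:5]}")
    seen = set()
    for k in keys:
        if k in seen:
            raise FeatureTableError(f"{what}: duplicate k-mer key {k!r}")
        seen.add(k)
    missing = [k for k in expected if k not in seen]
    if missing:
        raise FeatureTableError(f"{what}: missing k-mer key(s), e.g. {missing[0]!r} "
                                f"({len(missing)} missing of {len(expected)})")
    extra = seen - set(expected)
    if extra:
        raise FeatureTableError(f"{what}: unexpected k-mer key(s): {sorted(extra)[:5]}")


@dataclass
class RawChemicalMatrix:
    """64 x 62 matrix of raw probe interaction features, one row per 3-mer.

    Columns pair a minimum interaction energy P_i with an interaction score
    Q_i for each of 31 probes.
    """

    values: pd.DataFrame
    probe_labels: tuple[str, ...] = tuple(f"probe{i:02d}" for i in range(1, 32))

    def __post_init__(self) -> None:
        _check_kmer_index(self.values, KMERS3, "raw chemical matrix")
        if self.values.shape[1] != 62:
            raise FeatureTableError(
                f"raw chemical matrix needs 62 columns, got {self.values.shape[1]}")
        if len(self.probe_labels) != 31:
            raise FeatureTableError("need exactly 31 probe labels")
        self.values = self.values.loc[KMERS3].astype(float)


@dataclass
class ChemicalFeatureTable:
    """Map 3-mer -> PCA score components (dimensionless; 8 for feature mapping)."""

    values: pd.DataFrame
    variance_explained: float = float("nan")
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        _check_kmer_index(self.values, KMERS3, "chemical table")
        if not 1 <= self.values.shape[1] <= 62:
            raise FeatureTableError(
                f"chemical table needs 1-62 components per 3-mer, got {self.values.shape[1]}")
        self.values = self.values.loc[KMERS3].astype(float)


@dataclass
class BaseGeometryTable:
    """Map 3-mer -> (shear, buckle, stretch, propeller, stagger, opening)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_kmer_index(self.values, KMERS3, "base-geometry table")
        if tuple(self.values.columns) != BASE_GEOMETRY_COLUMNS:
            raise FeatureTableError(
                f"base-geometry columns must be {BASE_GEOMETRY_COLUMNS}, "
                f"got {tuple(self.values.columns)}")
        self.values = self.values.loc[KMERS3].astype(float)


@dataclass
class StepGeometryTable:
    """Map 4-mer -> (shift, tilt, slide, roll, rise, twist)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_kmer_index(self.values, KMERS4, "step-geometry table")
        if tuple(self.values.columns) != STEP_GEOMETRY_COLUMNS:
            raise FeatureTableError(
                f"step-geometry columns must be {STEP_GEOMETRY_COLUMNS}, "
                f"got {tuple(self.values.columns)}")
        self.values = self.values.loc[KMERS4].astype(float)


@dataclass
class FeatureTableBundle:
    """The complete lookup substrate for sequence-to-feature mapping."""

    chemical: ChemicalFeatureTable
    base_geometry: BaseGeometryTable
    step_geometry: StepGeometryTable
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        # dataclass constructors of the member tables enforce completeness;
        # re-check shapes so a mutated bundle fails fast before any mapping
        if self.chemical.values.shape != (64, 8):
            raise FeatureTableError("chemical table incomplete")
        if self.base_geometry.values.shape != (64, 6):
            raise FeatureTableError("base-geometry table incomplete")
        if self.step_geometry.values.shape != (256, 6):
            raise FeatureTableError("step-geometry table incomplete")

    # dense arrays in canonical k-mer code order, for vectorized lookups
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        self.validate()
        return (
            self.chemical.values.to_numpy(),
            self.base_geometry.values.to_numpy(),
            self.step_geometry.values.to_numpy(),
        )

    def equals(self, other: "FeatureTableBundle") -> bool:
        return (
            self.chemical.values.equals(other.chemical.values)
            and self.base_geometry.values.equals(other.base_geometry.values)
            and self.step_geometry.values.equals(other.step_geometry.values)
        )


def reduce_chemical_features(raw: RawChemicalMatrix, k: int = 8) -> ChemicalFeatureTable:
    """Reduce the 64 x 62 raw probe matrix to per-3-mer PCA scores.

    Each column is standardized to mean 0, sd 1 across the 64 rows (constant
    columns are dropped with a warning), the correlation-matrix eigensystem
    is computed, and each 3-mer receives the projections of its standardized
    row onto the top-``k`` eigenvectors, ordered by descending eigenvalue.
    Eigenvector signs are fixed so the largest-magnitude component of each
    eigenvector is positive, making tables reproducible across linear-algebra
    backends.

    Returns a :class:`ChemicalFeatureTable` whose ``variance_explained`` is
    the fraction of total variance captured by the ``k`` retained components.
    """
    X = raw.values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [raw.values.columns[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d zero-variance column(s): %s", len(dropped), dropped)
    X = X[:, keep]
    if X.shape[1] == 0:
        raise FeatureTableError("all columns have zero variance")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int(np.sum(evals > 1e-12))
    if n_pos < k:
        raise FeatureTableError(
            f"correlation matrix has only {n_pos} positive eigenvalues; "
            f"cannot extract k={k} components")
    top = evecs[:, :k].copy()
    # sign convention: dominant loading of each eigenvector is positive
    flip = np.sign(top[np.abs(top).argmax(axis=0), np.arange(k)])
    top *= flip
    scores = Z @ top
    var = float(evals[:k].sum() / evals.sum())
    df = pd.DataFrame(scores, index=list(raw.values.index),
                      columns=[f"c{i}" for i in range(1, k + 1)])
    return ChemicalFeatureTable(values=df, variance_explained=var,
                                provenance="reduced")


# ---------------------------------------------------------------------------
# TSV I/O

_FILENAMES = {
    "chemical": "chemical.tsv",
    "base_geometry": "base_geometry.tsv",
    "step_geometry": "step_geometry.tsv",
}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    df.index.name = "kmer"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _read_tsv(path: Path, n_cols: int, what: str) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col="kmer", dtype={"kmer": str},
                     float_precision="round_trip")
    df.index.name = None
    if df.shape[1] != n_cols:
        raise FeatureTableError(
            f"{what} at {path}: expected {n_cols} value columns, got {df.shape[1]}")
    return df


def write_feature_tables(bundle: FeatureTableBundle, path: str | Path) -> None:
    """Write the three tables as TSV files under directory ``path``."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.chemical.values, path / _FILENAMES["chemical"])
    _write_tsv(bundle.base_geometry.values, path / _FILENAMES["base_geometry"])
    _write_tsv(bundle.step_geometry.values, path / _FILENAMES["step_geometry"])


def load_feature_tables(path: str | Path) -> FeatureTableBundle:
    """Load a bundle from the TSV files written by :func:`write_feature_tables`."""
    path = Path(path)
    chem = _read_tsv(path / _FILENAMES["chemical"], 8, "chemical table")
    base = _read_tsv(path / _FILENAMES["base_geometry"], 6, "base-geometry table")
    step = _read_tsv(path / _FILENAMES["step_geometry"], 6, "step-geometry table")
    return FeatureTableBundle(
        chemical=ChemicalFeatureTable(values=chem, provenance="loaded"),
        base_geometry=BaseGeometryTable(values=base),
        step_geometry=StepGeometryTable(values=step),
        metadata={"source": str(path)},
    )


def write_raw_chemical(raw: RawChemicalMatrix, path: str | Path) -> None:
    _write_tsv(raw.values, Path(path))


def load_raw_chemical(path: str | Path) -> RawChemicalMatrix:
    df = _read_tsv(Path(path), 62, "raw chemical matrix")
    return RawChemicalMatrix(values=df)


# ---------------------------------------------------------------------------
# synthesis

def synthesize_raw_chemical(seed: int) -> RawChemicalMatrix:
    """Seeded stand-in for the probe interaction-field matrix.

    Draws correlated columns (a low-rank latent structure plus noise) so that
    PCA reduction on the result is non-trivial, as it is for real probe data.
    """
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((64, 8))
    loadings = rng.standard_normal((8, 62))
    noise = 0.3 * rng.standard_normal((64, 62))
    X = latent @ loadings + noise
    df = pd.DataFrame(X, index=KMERS3, columns=list(RAW_CHEMICAL_COLUMNS))
    return RawChemicalMatrix(values=df)


def synthesize_feature_tables(seed: int) -> FeatureTableBundle:
    """Deterministic synthetic bundle: PCA-reduced seeded chemical matrix plus
    geometry tables drawn from plausible ranges (angles in [-30, 40] degrees,
    translations in [-2, 2] Angstrom).  These ranges are fixture conventions,
    chosen to resemble tabulated DNA geometry scales, not measured values.
    """
    raw = synthesize_raw_chemical(seed)
    chemical = reduce_chemical_features(raw, k=8)
    chemical.provenance = "synthetic"

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))

    def geometry(kmers: list[str], columns: tuple[str, ...], angular: tuple[str, ...]) -> pd.DataFrame:
        data = {}
        for col in columns:
            lo, hi = (-30.0, 40.0) if col in angular else (-2.0, 2.0)
            data[col] = rng.uniform(lo, hi, size=len(kmers))
        return pd.DataFrame(data, index=kmers, columns=list(columns))

    base = BaseGeometryTable(values=geometry(KMERS3, BASE_GEOMETRY_COLUMNS, ANGULAR_BASE))
    step = StepGeometryTable(values=geometry(KMERS4, STEP_GEOMETRY_COLUMNS, ANGULAR_STEP))
    return FeatureTableBundle(
        chemical=chemical,
        base_geometry=base,
        step_geometry=step,
        metadata={"source": "synthetic", "seed": int(seed)},
    )
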