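"""Connectivity-matrix and cohort-manifest containers, file round-trips, vectorization.

On-disk dialects
----------------
* Matrix files: comma-delimited text, no header, one row per node, named
  ``<subject_id>.<weighting>.csv``. Entries printed with ``%.17g`` so a write/read
  round-trip is bit-exact.
* Manifest files: comma-delimited with header ``subject_id,site,age,sex``.

Harmonization operates on the "vectorized" form: the lower-triangle-including-diagonal
entries (i, j) with i >= j of every subject's matrix stacked into a features-by-subjects
table — for 84-node matrices and 168 subjects, a 3570 x 168 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STREAMLINE_COUNT = "streamline_count"
MEAN_LENGTH = "mean_length"
WEIGHTINGS = (STREAMLINE_COUNT, MEAN_LENGTH)

SITES = ("site1", "site2")
SITE_CODES = {"site1": 1, "site2": 2}
SEXES = ("F", "M")
SEX_CODES = {"F": 0, "M": 1}

#: relative tolerance for accepting (and averaging away) numerical asymmetry
SYMMETRY_RTOL = 1e-9

# type alias kept for readability in signatures
Weighting = str


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files or invalid matrix values."""


class ManifestError(ValueError):
    """Raised for malformed cohort manifests."""


@dataclass
class ConnectivityMatrix:
    """One subject's square symmetric nonnegative connectivity matrix.

    Parameters
    ----------
    subject_id : str
    weighting : {"streamline_count", "mean_length"}
        Streamline counts are dimensionless; mean lengths are in mm-equivalent units.
    values : (n, n) ndarray
        Symmetric within relative tolerance 1e-9 (exactly symmetrized on construction),
        nonnegative, n >= 2.
    """

    subject_id: str
    weighting: Weighting
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}; expected one of {WEIGHTINGS}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixFormatError(f"matrix must be square, got shape {v.shape}")
        if v.shape[0] < 2:
            raise MatrixFormatError(f"matrix must have n >= 2 nodes, got n={v.shape[0]}")
        bad = np.argwhere(~np.isfinite(v))
        if bad.size:
            i, j = bad[0]
            raise MatrixFormatError(f"non-finite entry at ({i}, {j})")
        neg = np.argwhere(v < 0)
        if neg.size:
            i, j = neg[0]
            raise MatrixFormatError(f"negative entry {v[i, j]} at ({i}, {j})")
        scale = float(np.abs(v).max()) or 1.0
        asym = float(np.abs(v - v.T).max())
        if asym > SYMMETRY_RTOL * scale:
            raise MatrixFormatError(
                f"matrix asymmetric beyond tolerance: max |A - A.T| = {asym:g} (scale {scale:g})"
            )
        # remove numerical asymmetry exactly
        self.values = (v + v.T) / 2.0

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class CohortManifest:
    """Subject table: one row of (subject_id, site, age, sex) per subject.

    ``age_range`` bounds what counts as a plausible age (years).
    """

    table: pd.DataFrame
    age_range: tuple[float, float] = (0.0, 120.0)

    COLUMNS = ("subject_id", "site", "age", "sex")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.COLUMNS if c not in t.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        t = t.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        t["subject_id"] = t["subject_id"].astype(str)
        dup = t["subject_id"][t["subject_id"].duplicated()]
        if len(dup):
            raise ManifestError(f"duplicate subject_id: {dup.iloc[0]!r}")
        bad_site = set(t["site"]) - set(SITES)
        if bad_site:
            raise ManifestError(f"unknown site label(s): {sorted(bad_site)}; expected {SITES}")
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise ManifestError(f"unknown sex label(s): {sorted(bad_sex)}; expected {SEXES}")
        ages = t["age"].astype(float)
        lo, hi = self.age_range
        if ((ages < lo) | (ages > hi)).any():
            bad = ages[(ages < lo) | (ages > hi)].iloc[0]
            raise ManifestError(f"age {bad} outside plausible range [{lo}, {hi}]")
        t["age"] = ages
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def subset(self, site: str) -> "CohortManifest":
        """Rows of a single site, in manifest order."""
        if site not in SITES:
            raise ManifestError(f"unknown site {site!r}")
        return CohortManifest(self.table[self.table["site"] == site].reset_index(drop=True),
                              age_range=self.age_range)


@dataclass
class VectorizedCohort:
    """Feature-by-subject table of the i >= j triangle of each subject's matrix.

    features : (f, s) ndarray with f = n(n+1)/2
    index_map : (f, 2) int ndarray of (i, j) pairs, row-major over i = 0..n-1, j = 0..i
    batch : (s,) int ndarray, site1 -> 1, site2 -> 2
    covariates : (s, 2) float ndarray, columns (age, sex code F -> 0 / M -> 1)
    """

    features: np.ndarray
    index_map: np.ndarray
    batch: np.ndarray
    covariates: np.ndarray
    subject_ids: list[str]
    weighting: Weighting
    n_nodes: int = field(default=0)

    def __post_init__(self) -> None:
        f, s = self.features.shape
        n = int((math.isqrt(8 * f + 1) - 1) // 2)
        if n * (n + 1) // 2 != f:
            raise ValueError(f"feature count {f} is not a triangular number n(n+1)/2")
        self.n_nodes = n
        if len(self.index_map) != f:
            raise ValueError("index_map length must equal feature count")
        if len(self.batch) != s or self.covariates.shape[0] != s or len(self.subject_ids) != s:
            raise ValueError("batch/covariates/subject_ids must align with feature columns")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[1]


def triangle_index_map(n: int) -> np.ndarray:
    """(i, j) pairs with i >= j in row-major order over i = 0..n-1, j = 0..i."""
    return np.array([(i, j) for i in range(n) for j in range(i + 1)], dtype=int)


def read_matrix(path: str | Path, weighting: Weighting, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a comma-delimited square matrix file into a validated ConnectivityMatrix.

    The subject id defaults to the file stem up to the first dot.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment="#", float_precision="round_trip")
    except Exception as exc:  # ragged rows, empty file, ...
        raise MatrixFormatError(f"{path}: cannot parse as a numeric matrix: {exc}") from exc
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        col = next(c for c, d in df.dtypes.items() if not np.issubdtype(d, np.number))
        raise MatrixFormatError(f"{path}: non-numeric value in column {col}")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise MatrixFormatError(f"{path}: non-square matrix of shape {values.shape}")
    if subject_id is None:
        subject_id = path.name.split(".")[0]
    try:
        return ConnectivityMatrix(subject_id, weighting, values)
    except MatrixFormatError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc


def write_matrix(m: ConnectivityMatrix, path: str | Path, header_comment: str | None = None) -> None:
    """Write a matrix as comma-delimited text with full float precision (%.17g).

    An optional comment (e.g. the generating seed) is written as a '#' header
    line, which readers skip.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, m.values, fmt="%.17g", delimiter=",",
               header=header_comment or "", comments="# " if header_comment else "# ")


def matrix_filename(subject_id: str, weighting: Weighting) -> str:
    return f"{subject_id}.{weighting}.csv"


def read_manifest(path: str | Path, age_range: tuple[float, float] = (0.0, 120.0)) -> CohortManifest:
    """Read a ``subject_id,site,age,sex`` CSV into a validated CohortManifest."""
    df = pd.read_csv(path, dtype={"subject_id": str}, comment="#")
    return CohortManifest(df, age_range=age_range)


def write_manifest(manifest: CohortManifest, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        manifest.table.to_csv(fh, index=False)


def read_cohort(
    matrix_dir: str | Path, manifest: CohortManifest, weighting: Weighting
) -> list[ConnectivityMatrix]:
    """Read one matrix per manifest row (in manifest order) from ``matrix_dir``."""
    matrix_dir = Path(matrix_dir)
    out = []
    for sid in manifest.subject_ids:
        p = matrix_dir / matrix_filename(sid, weighting)
        if not p.exists():
            raise FileNotFoundError(f"subject {sid!r} has no {weighting} matrix at {p}")
        out.append(read_matrix(p, weighting, subject_id=sid))
    return out


def write_cohort(matrices: Iterable[ConnectivityMatrix], matrix_dir: str | Path) -> None:
    matrix_dir = Path(matrix_dir)
    for m in matrices:
        write_matrix(m, matrix_dir / matrix_filename(m.subject_id, m.weighting))


def vectorize_cohort(
    matrices: Sequence[ConnectivityMatrix], manifest: CohortManifest
) -> VectorizedCohort:
    """Stack the i >= j triangle of each subject's matrix into a features-by-subjects table.

    Columns follow manifest order; the batch vector codes site1 -> 1, site2 -> 2 and the
    covariates are (age, sex) with sex coded F -> 0, M -> 1.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    by_id = {m.subject_id: m for m in matrices}
    if len(by_id) != len(matrices):
        raise ValueError("duplicate subject_id among matrices")
    weighting = matrices[0].weighting
    n = matrices[0].n_nodes
    for m in matrices:
        if m.weighting != weighting:
            raise ValueError(f"mixed weightings: {m.subject_id} has {m.weighting}, expected {weighting}")
        if m.n_nodes != n:
            raise ValueError(f"dimension mismatch: {m.subject_id} has n={m.n_nodes}, expected n={n}")
    missing = [sid for sid in manifest.subject_ids if sid not in by_id]
    if missing:
        raise ValueError(f"manifest subjects missing a matrix: {missing[:5]}")
    idx = triangle_index_map(n)
    ii, jj = idx[:, 0], idx[:, 1]
    cols = [by_id[sid].values[ii, jj] for sid in manifest.subject_ids]
    features = np.column_stack(cols)
    t = manifest.table
    batch = t["site"].map(SITE_CODES).to_numpy(dtype=int)
    covariates = np.column_stack(
        [t["age"].to_numpy(dtype=float), t["sex"].map(SEX_CODES).to_numpy(dtype=float)]
    )
    return VectorizedCohort(
        features=features,
        index_map=idx,
        batch=batch,
        covariates=covariates,
        subject_ids=manifest.subject_ids,
        weighting=weighting,
    )


def devectorize_cohort(v: VectorizedCohort, clamp_negatives: bool = False) -> list[ConnectivityMatrix]:
    """Reassemble each feature column into its symmetric matrix.

    With ``clamp_negatives`` every negative entry is set to exactly 0 (the convention
    applied after harmonization, before graph-measure computation).
    """
    n = v.n_nodes
    ii, jj = v.index_map[:, 0], v.index_map[:, 1]
    out = []
    for k, sid in enumerate(v.subject_ids):
        col = v.features[:, k]
        if clamp_negatives:
            col = np.maximum(col, 0.0)
        mat = np.zeros((n, n))
        mat[ii, jj] = col
        mat[jj, ii] = col
        out.append(ConnectivityMatrix(sid, v.weighting, mat))
    return out
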