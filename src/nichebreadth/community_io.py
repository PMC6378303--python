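"""Reading, writing and preprocessing of OTU count tables and sample metadata.

The central container is :class:`OTUTable`, an integer taxa x samples count
matrix with unique string identifiers. Preprocessing follows the usual
amplicon workflow: column-normalisation to relative abundances, rarefaction
to a common read depth by without-replacement subsampling, and removal of
very rare taxa whose mean relative abundance falls below a threshold (such
taxa can masquerade as habitat specialists purely through undersampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates the expected table format."""


REQUIRED_METADATA_COLUMNS = ("sample_id", "elevation_m", "x_m", "y_m", "gradient")


@dataclass
class OTUTable:
    """Taxa x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    taxon_ids : array-like of str
        Unique taxon (OTU) identifiers, one per row of ``counts``.
    sample_ids : array-like of str
        Unique sample identifiers, one per column of ``counts``.
    counts : ndarray of int, shape (n_taxa, n_samples)
    taxonomy : dict, optional
        Optional taxon_id -> lineage string mapping.
    """

    taxon_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray
    taxonomy: dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.taxon_ids = np.asarray(self.taxon_ids, dtype=str)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D taxa x samples matrix")
        if not np.issubdtype(counts.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if not np.allclose(counts, np.round(counts)):
            raise FormatError("counts must be integers")
        self.counts = counts.astype(np.int64)
        if self.counts.shape != (self.taxon_ids.size, self.sample_ids.size):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.taxon_ids.size} taxa x {self.sample_ids.size} samples"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            uniq, cnt = np.unique(ids, return_counts=True)
            if np.any(cnt > 1):
                raise FormatError(f"duplicate {name} ids: {list(uniq[cnt > 1])}")

    # -- basic structure -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return int(self.taxon_ids.size)

    @property
    def n_samples(self) -> int:
        return int(self.sample_ids.size)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset_taxa(self, taxon_ids) -> "OTUTable":
        """Return a new table restricted to ``taxon_ids`` (order preserved)."""
        wanted = pd.Index(self.taxon_ids).get_indexer(list(taxon_ids))
        if np.any(wanted < 0):
            missing = [t for t, i in zip(taxon_ids, wanted) if i < 0]
            raise KeyError(f"unknown taxon ids: {missing[:5]}")
        tax = None
        if self.taxonomy is not None:
            tax = {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
        return OTUTable(self.taxon_ids[wanted], self.sample_ids,
                        self.counts[wanted], tax)

    def subset_samples(self, sample_ids) -> "OTUTable":
        wanted = pd.Index(self.sample_ids).get_indexer(list(sample_ids))
        if np.any(wanted < 0):
            missing = [s for s, i in zip(sample_ids, wanted) if i < 0]
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return OTUTable(self.taxon_ids, self.sample_ids[wanted],
                        self.counts[:, wanted], self.taxonomy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.taxon_ids, name="#OTU_ID"),
                            columns=self.sample_ids)

    # -- IO ---------------------------------------------------------------

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        if self.taxonomy is not None:
            df = df.assign(taxonomy=[self.taxonomy.get(t, "") for t in self.taxon_ids])
        df.to_csv(path, sep="\t")


@dataclass
class AbundanceProfile:
    """Relative abundances P_ij: each sample column sums to one."""

    taxon_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = v.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each sample column must sum to 1")
        self.values = v

    def mean_per_taxon(self) -> np.ndarray:
        """Mean relative abundance of each taxon across samples."""
        return self.values.mean(axis=1)


class SampleMetadata:
    """Per-sample design and environment: elevation, coordinates, gradient
    group and named soil variables (pH, ST, SWC, EC, TN, TC, C/N, SOC,
    NH4-N, NO3-N, NO2-N or any numeric columns supplied)."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "sample_id":
            if "sample_id" not in frame.columns:
                raise FormatError("metadata requires a sample_id column")
            frame = frame.set_index("sample_id")
        frame.index = frame.index.astype(str)
        for col in ("elevation_m", "x_m", "y_m", "gradient"):
            if col not in frame.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        if frame.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        coords = frame[["x_m", "y_m"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise FormatError("non-finite sample coordinates")
        self.frame = frame

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def elevation(self) -> np.ndarray:
        return self.frame["elevation_m"].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x_m", "y_m"]].to_numpy(dtype=float)

    @property
    def gradient(self) -> np.ndarray:
        return self.frame["gradient"].to_numpy(dtype=str)

    @property
    def env(self) -> pd.DataFrame:
        """Numeric environmental variables (everything beyond the design columns)."""
        drop = [c for c in ("elevation_m", "x_m", "y_m", "gradient") if c in self.frame]
        env = self.frame.drop(columns=drop)
        return env.select_dtypes(include=[np.number])

    def align_to(self, table: OTUTable) -> "SampleMetadata":
        """Reorder to the table's samples; every table sample must be present."""
        missing = set(table.sample_ids) - set(self.frame.index)
        if missing:
            raise KeyError(f"metadata missing samples: {sorted(missing)}")
        return SampleMetadata(self.frame.loc[list(table.sample_ids)].reset_index())

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def read_otu_table(path, format_id: str = "tsv") -> OTUTable:
    """Read an OTU table from ``tsv`` (rows = taxa, header = sample ids,
    optional trailing ``taxonomy`` column) or ``biom`` (BIOM 2.x HDF5)."""
    if format_id == "tsv":
        return _read_tsv(path)
    if format_id == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format_id!r}; expected 'tsv' or 'biom'")


def _read_tsv(path) -> OTUTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = dict(zip(df.index, df["taxonomy"].astype(str)))
        df = df.drop(columns=["taxonomy"])
    try:
        counts = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric counts in {path}: {exc}") from None
    if np.any(~np.isfinite(counts)):
        r, c = np.argwhere(~np.isfinite(counts))[0]
        raise FormatError(
            f"missing/non-numeric count at taxon {df.index[r]!r}, sample {df.columns[c]!r}")
    if np.any(counts < 0):
        r, c = np.argwhere(counts < 0)[0]
        raise FormatError(
            f"negative count at taxon {df.index[r]!r}, sample {df.columns[c]!r}")
    return OTUTable(df.index.to_numpy(), df.columns.to_numpy(), counts, taxonomy)


def _read_biom(path) -> OTUTable:
    # BIOM 2.x stores the matrix CSR by observation under /observation/matrix.
    import h5py

    with h5py.File(path, "r") as fh:
        taxa = [t.decode() if isinstance(t, bytes) else str(t)
                for t in fh["observation/ids"][:]]
        samples = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in fh["sample/ids"][:]]
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
    from scipy.sparse import csr_matrix

    mat = csr_matrix((data, indices, indptr), shape=(len(taxa), len(samples)))
    return OTUTable(np.asarray(taxa), np.asarray(samples), mat.toarray())


def relative_abundances(table: OTUTable) -> AbundanceProfile:
    """Column-normalise counts to per-sample relative abundances."""
    sums = table.sample_sums().astype(float)
    if np.any(sums <= 0):
        empty = list(table.sample_ids[sums <= 0])
        raise ValueError(f"samples with zero total counts: {empty}")
    return AbundanceProfile(table.taxon_ids, table.sample_ids, table.counts / sums)


def rarefy(table: OTUTable, depth: int, seed=None,
           drop_below_depth: bool = True) -> OTUTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning
    (``drop_below_depth=False`` raises instead). The draw is multivariate
    hypergeometric per sample, i.e. read-level resampling.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    if not np.any(keep):
        raise ValueError(f"all samples have fewer than {depth} reads")
    if not np.all(keep):
        shallow = list(table.sample_ids[~keep])
        if not drop_below_depth:
            raise ValueError(f"samples below rarefaction depth {depth}: {shallow}")
        warnings.warn(f"dropping {len(shallow)} sample(s) below depth {depth}: {shallow}")
    cols = []
    for j in np.flatnonzero(keep):
        col = table.counts[:, j]
        if col.sum() == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    return OTUTable(table.taxon_ids, table.sample_ids[keep],
                    np.column_stack(cols), table.taxonomy)


def filter_rare(profile: AbundanceProfile | None, table: OTUTable,
                threshold: float = 2e-5) -> tuple[OTUTable, list[str]]:
    """Drop taxa whose mean relative abundance is strictly below ``threshold``.

    Equality with the threshold retains the taxon (the removal rule is a
    strict inequality). Returns the filtered table and the removed ids.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if profile is None:
        profile = relative_abundances(table)
    means = profile.mean_per_taxon()
    keep = means >= threshold
    removed = list(np.asarray(profile.taxon_ids)[~keep])
    if not np.any(keep):
        warnings.warn("rare-taxon filter removed every taxon")
    kept_ids = list(np.asarray(profile.taxon_ids)[keep])
    return table.subset_taxa(kept_ids), removed
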