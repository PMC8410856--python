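"""Feature tables, metadata, and the filtering / normalization steps.

Tables are features x samples, the orientation QIIME-style TSV exports use:
first column is the feature identifier, remaining columns are samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "RelAbundTable",
    "CohortMetadata",
    "StratifiedContributions",
    "TableError",
    "read_table",
    "write_table",
    "read_metadata",
    "write_metadata",
    "min_depth_filter",
    "prevalence_filter",
    "to_relative",
    "rarefy",
    "taxon_attribution",
]

FEATURE_ID_COL = "#FeatureID"


class TableError(ValueError):
    """Raised for malformed tables, degenerate filters, or schema mismatches."""


@dataclass
class CountTable:
    """Non-negative integer feature table (features x samples).

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique feature ids, columns by unique sample ids.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise TableError(f"duplicate feature id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise TableError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy()
        if values.size and (values < 0).any():
            row = df.index[np.where((values < 0).any(axis=1))[0][0]]
            raise TableError(f"negative count in feature {row!r}")
        self.data = df.astype(np.int64, copy=False)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass
class RelAbundTable:
    """Per-sample relative abundances; every sample column sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=0).to_numpy(dtype=float)
        if self.data.shape[1] and not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.data.columns[int(np.argmax(np.abs(sums - 1.0)))]
            raise TableError(f"sample {bad!r} does not sum to 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class CohortMetadata:
    """Per-sample binary exposure label and optional binary covariate."""

    frame: pd.DataFrame  # index sample_id; columns: exposure [, covariate]

    def __post_init__(self) -> None:
        if "exposure" not in self.frame.columns:
            raise TableError("metadata must have an 'exposure' column")
        exp = set(self.frame["exposure"].unique())
        if not exp <= {0, 1}:
            raise TableError(f"exposure labels must be 0/1, got {sorted(exp)}")
        if exp != {0, 1}:
            raise TableError("both exposure classes must be non-empty")
        if "covariate" in self.frame.columns:
            cov = set(self.frame["covariate"].dropna().unique())
            if not cov <= {0, 1}:
                raise TableError("covariate must be binary 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def exposure_for(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise TableError(f"samples missing from metadata: {missing[:3]}")
        return self.frame.loc[list(sample_ids), "exposure"].to_numpy(dtype=int)

    def covariate_for(self, sample_ids) -> np.ndarray | None:
        if "covariate" not in self.frame.columns:
            return None
        return self.frame.loc[list(sample_ids), "covariate"].to_numpy(dtype=int)

    def subset(self, sample_ids) -> "CohortMetadata":
        return CohortMetadata(self.frame.loc[list(sample_ids)].copy())


@dataclass
class StratifiedContributions:
    """Per-(sample, pathway) decomposition of pathway abundance into taxa.

    ``values[t, p, s]`` is the (unrounded) contribution of taxon ``t`` to
    pathway ``p`` in sample ``s``; summing over taxa recovers the pathway's
    total abundance in that sample.
    """

    values: np.ndarray  # taxa x pathways x samples, float, >= 0
    taxon_ids: list[str]
    pathway_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise TableError("stratified contributions must be non-negative")
        expected = (len(self.taxon_ids), len(self.pathway_ids), len(self.sample_ids))
        if self.values.shape != expected:
            raise TableError(
                f"stratified array shape {self.values.shape} != ids {expected}"
            )

    def pathway_totals(self) -> np.ndarray:
        """Unrounded pathway x sample totals."""
        return self.values.sum(axis=0)

    def to_long(self) -> pd.DataFrame:
        """Long-format (sample, pathway, taxon, contribution) frame."""
        t, p, s = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.taxon_ids, self.pathway_ids, self.sample_ids],
            names=["taxon", "pathway", "sample"],
        )
        frame = pd.DataFrame({"contribution": self.values.reshape(-1)}, index=idx)
        return frame.reset_index()[["sample", "pathway", "taxon", "contribution"]]


# ---------------------------------------------------------------------------
# IO


def read_table(path) -> CountTable:
    """Read a feature-table TSV (``#FeatureID`` column + one column/sample)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = FEATURE_ID_COL
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[int(vals.isna().to_numpy().argmax())]
            raise TableError(f"non-numeric count at feature {row!r}, sample {col!r}")
        df[col] = vals
    return CountTable(df)


def write_table(table: CountTable | RelAbundTable, path) -> None:
    out = table.data.copy()
    out.index.name = FEATURE_ID_COL
    out.to_csv(path, sep="\t")


def read_metadata(path) -> CohortMetadata:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    frame = frame.set_index("sample_id")
    return CohortMetadata(frame)


def write_metadata(meta: CohortMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_stratified(strat: StratifiedContributions, path) -> None:
    strat.to_long().to_csv(path, sep="\t", index=False)


def read_stratified(path) -> StratifiedContributions:
    long = pd.read_csv(path, sep="\t", dtype={"sample": str, "pathway": str, "taxon": str})
    taxa = list(pd.unique(long["taxon"]))
    pathways = list(pd.unique(long["pathway"]))
    samples = list(pd.unique(long["sample"]))
    cube = (
        long.set_index(["taxon", "pathway", "sample"])["contribution"]
        .unstack(["pathway", "sample"])  # noqa: PD010 - explicit reshape
        .reindex(taxa)
        .to_numpy()
        .reshape(len(taxa), len(pathways), len(samples))
    )
    return StratifiedContributions(np.nan_to_num(cube), taxa, pathways, samples)


# ---------------------------------------------------------------------------
# Filters and transforms


def min_depth_filter(table: CountTable, min_depth: int) -> CountTable:
    """Drop samples whose total feature count is below ``min_depth``.

    Mirrors the upstream QC step that removes shallowly sequenced samples
    (the pipeline default is 1000 reads).
    """
    if min_depth < 1:
        raise TableError("min_depth must be >= 1")
    keep = table.sample_sums() >= min_depth
    if not keep.any():
        raise TableError(f"all samples below depth {min_depth}")
    return CountTable(table.data.loc[:, keep[keep].index])


def prevalence_filter(tables, threshold: float):
    """Keep features found (count > 0) in at least ``threshold`` of samples.

    Accepts a single table or a sequence of tables. With several tables the
    filter is *joint*: a feature must meet the threshold in every table, and
    the returned tables share the (order-preserved) intersection feature set.
    Used both for the 10% pre-test filter and the stricter cross-cohort
    harmonization cut-offs (30% taxa / 50% pathways).
    """
    if not 0 < threshold <= 1:
        raise TableError("threshold must be in (0, 1]")
    single = isinstance(tables, (CountTable, RelAbundTable))
    tlist = [tables] if single else list(tables)
    common = [f for f in tlist[0].feature_ids
              if all(f in t.data.index for t in tlist[1:])]
    keep = []
    for f in common:
        ok = True
        for t in tlist:
            prev = (t.data.loc[f].to_numpy() > 0).mean()
            if prev < threshold:
                ok = False
                break
        if ok:
            keep.append(f)
    if not keep:
        raise TableError("no features pass the prevalence filter")
    out = [type(t)(t.data.loc[keep]) for t in tlist]
    return out[0] if single else tuple(out)


def to_relative(table: CountTable) -> RelAbundTable:
    """Convert counts to per-sample proportions."""
    sums = table.sample_sums()
    if (sums == 0).any():
        bad = sums.index[int((sums == 0).to_numpy().argmax())]
        raise TableError(f"sample {bad!r} has zero total count")
    return RelAbundTable(table.data / sums)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped. One multivariate-
    hypergeometric draw per sample, deterministic given ``seed``.
    """
    if depth < 1:
        raise TableError("depth must be >= 1")
    sums = table.sample_sums()
    keep = sums[sums >= depth].index
    if len(keep) == 0:
        raise TableError(f"no sample reaches depth {depth}")
    rng = np.random.default_rng(seed)
    cols = {}
    for s in table.sample_ids:
        if s not in set(keep):
            continue
        counts = table.data[s].to_numpy()
        if counts.sum() == depth:
            cols[s] = counts
        else:
            cols[s] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame(cols, index=table.data.index)
    return CountTable(out)


def taxon_attribution(strat: StratifiedContributions, taxon: str,
                      exposure: np.ndarray | None = None):
    """Fraction of each pathway's abundance attributable to one taxon.

    Returns a DataFrame (pathways x samples) of fractions in [0, 1]; entries
    where the pathway's total abundance in a sample is zero are NaN (flagged
    undefined, not 0). When ``exposure`` (one 0/1 label per sample) is given,
    a second DataFrame of per-group mean fractions is returned as well.
    """
    if taxon not in strat.taxon_ids:
        raise TableError(f"unknown taxon {taxon!r}")
    t = strat.taxon_ids.index(taxon)
    totals = strat.pathway_totals()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, strat.values[t] / totals, np.nan)
    frame = pd.DataFrame(frac, index=strat.pathway_ids, columns=strat.sample_ids)
    if exposure is None:
        return frame
    exposure = np.asarray(exposure, dtype=int)
    groups = pd.DataFrame(
        {
            "exposed_mean": np.nanmean(np.where(exposure == 1, frac, np.nan), axis=1),
            "control_mean": np.nanmean(np.where(exposure == 0, frac, np.nan), axis=1),
        },
        index=strat.pathway_ids,
    )
    return frame, groups
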