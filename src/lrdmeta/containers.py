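"""Core domain containers shared across the pipeline.

The analysis operates on taxon-by-sample count tables (metatranscriptomic
read counts and 16S rRNA gene / OTU counts), a factorial sample design
(oil O, dispersant D, nutrients N, timepoint t), and square distance
matrices over samples (Bray-Curtis, MPD, MNTD) or taxa (patristic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: absolute tolerance for symmetry / normalization checks
TOL = 1e-9

#: treatment name -> (O, D, N) factor flags
TREATMENT_FLAGS: dict[str, tuple[int, int, int]] = {
    "BC": (0, 0, 0),
    "DISP": (0, 1, 0),
    "WAF": (1, 0, 0),
    "CEWAF": (1, 1, 0),
    "CEWAFN": (1, 1, 1),
}

#: timepoint index -> day of the microcosm experiment
TIMEPOINT_DAYS: dict[int, int] = {0: 0, 1: 7, 2: 17, 3: 28, 4: 42}

#: distance flavors whose self-comparison may legitimately be nonzero
_NONHOLLOW_FLAVORS = {"mpd", "mntd"}


class CountTable:
    """A taxa x samples matrix of nonnegative counts (or proportions).

    Parameters
    ----------
    data
        DataFrame with taxon labels as the index and sample ids as columns,
        or anything :class:`pandas.DataFrame` accepts.
    require_positive_columns
        If True (default), every sample column must contain at least one
        positive entry.
    """

    def __init__(self, data: pd.DataFrame, *, require_positive_columns: bool = True):
        df = pd.DataFrame(data).copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate taxon labels: {dups}")
        if df.columns.duplicated().any():
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count table body must be numeric")
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative entry {values[i, j]!r} at taxon {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        if require_positive_columns:
            zero_cols = df.columns[(values.sum(axis=0) <= 0)]
            if len(zero_cols):
                raise ValueError(f"all-zero sample column(s): {list(zero_cols)}")
        self.df = df

    @property
    def taxon_labels(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def relative_abundance(self) -> "CountTable":
        """Per-sample fractions: divide each column by its total.

        Idempotent within 1e-9. Raises on an all-zero column.
        """
        totals = self.df.sum(axis=0)
        zero = totals.index[totals <= 0]
        if len(zero):
            raise ValueError(f"cannot normalize all-zero sample(s): {list(zero)}")
        return CountTable(self.df / totals)

    def equals(self, other: "CountTable") -> bool:
        return self.df.equals(other.df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountTable({self.shape[0]} taxa x {self.shape[1]} samples)"


@dataclass(frozen=True)
class SampleDesign:
    """Factor assignment of one sample in the microcosm design.

    O, D, N are 0/1 flags for oil (water-accommodated fraction), dispersant
    and inorganic nutrients; ``t_index`` is the ordinal timepoint with its
    day value; ``replicate`` numbers replicate libraries within a cell.
    """

    sample_id: str
    treatment: str
    O: int
    D: int
    N: int
    t_index: int
    day: int
    replicate: int = 1

    def __post_init__(self):
        flags = TREATMENT_FLAGS.get(self.treatment)
        if flags is None:
            raise ValueError(f"unknown treatment {self.treatment!r} for sample "
                             f"{self.sample_id!r}; known: {sorted(TREATMENT_FLAGS)}")
        if (self.O, self.D, self.N) != flags:
            raise ValueError(
                f"sample {self.sample_id!r}: (O,D,N)=({self.O},{self.D},{self.N}) "
                f"inconsistent with treatment {self.treatment} {flags}"
            )
        if self.day not in TIMEPOINT_DAYS.values():
            raise ValueError(f"sample {self.sample_id!r}: day {self.day} not in "
                             f"{sorted(TIMEPOINT_DAYS.values())}")


def design_frame(designs: list[SampleDesign]) -> pd.DataFrame:
    """Tabulate a design list (one row per sample, metadata column order)."""
    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "treatment": d.treatment,
                "O": d.O,
                "D": d.D,
                "N": d.N,
                "t_index": d.t_index,
                "day": d.day,
                "replicate": d.replicate,
            }
            for d in designs
        ]
    )


@dataclass
class DistanceMatrix:
    """Square symmetric matrix over samples (or taxa, for patristic).

    ``flavor`` is one of ``bray-curtis``, ``mpd``, ``mntd``, ``patristic``.
    MPD/MNTD self-comparisons are computed by the same double-sum formula
    and may be nonzero; all other flavors must have a zero diagonal.
    """

    ids: list[str]
    values: np.ndarray
    flavor: str = "bray-curtis"

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=TOL):
            raise ValueError("matrix is not symmetric within tolerance")
        if (v < -TOL).any():
            raise ValueError("negative distances")
        if self.flavor not in _NONHOLLOW_FLAVORS:
            if np.abs(np.diag(v)).max(initial=0.0) > TOL:
                raise ValueError(f"{self.flavor} matrix must have a zero diagonal")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def filter(self, ids: list[str]) -> "DistanceMatrix":
        """Reorder/subset to the given ids."""
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.flavor)


@dataclass
class OrdinationResult:
    """Principal-coordinates (classical MDS) embedding of a distance matrix."""

    ids: list[str]
    coordinates: np.ndarray          # samples x reported axes, eigval-descending
    eigenvalues: np.ndarray          # all eigenvalues, descending (incl. negative)
    proportion_explained: np.ndarray  # per reported axis, over positive-eigval total
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)
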