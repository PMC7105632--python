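"""Feature containers: named vectors and sample-by-feature matrices.

Feature names carry a block prefix (``ggdc|``, ``pseaac|``, ``gtpc|``,
``ctd|``) so the provenance of every column survives concatenation,
selection and persistence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PhageHydroError

__all__ = ["FeatureVector", "FeatureMatrix"]


@dataclass
class FeatureVector:
    """An ordered, named numeric descriptor of one sequence."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise PhageHydroError(
                f"feature names ({len(self.names)}) and values "
                f"({self.values.shape[0]}) differ in length"
            )
        if len(set(self.names)) != len(self.names):
            raise PhageHydroError("feature names are not unique")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class FeatureMatrix:
    """Samples x features matrix with aligned ids, names and optional labels.

    ``labels`` is a binary 0/1 vector aligned to ``sample_ids``; its semantics
    (enzyme vs non-enzyme, hydrolase vs other enzyme) depend on the stage the
    matrix was built for.
    """

    sample_ids: list[str]
    names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PhageHydroError("feature matrix must be two-dimensional")
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise PhageHydroError("sample_ids length does not match row count")
        if len(self.names) != d:
            raise PhageHydroError("names length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise PhageHydroError("sample ids are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise PhageHydroError("labels length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "FeatureMatrix":
        """Restrict to the given feature names, in the given order."""
        index = {name: i for i, name in enumerate(self.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise PhageHydroError(f"unknown feature names: {missing[:5]}")
        cols = [index[n] for n in names]
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            names=list(names),
            values=self.values[:, cols].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def block_prefixes(self) -> list[str]:
        """Distinct block prefixes (text before the first ``|``), in order."""
        seen: list[str] = []
        for name in self.names:
            prefix = name.split("|", 1)[0]
            if prefix not in seen:
                seen.append(prefix)
        return seen

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "id", self.sample_ids)
        return df

    def to_tsv(self, path) -> None:
        """Write as TSV with an ``id`` first column; round-trips losslessly."""
        if self.n_samples == 0:
            raise PhageHydroError("refusing to write an empty feature matrix")
        # pandas' default shortest-repr float formatting round-trips exactly
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, labels: dict[str, int] | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if df.columns[0] != "id":
            raise PhageHydroError(f"{path}: first column must be 'id'")
        ids = df["id"].astype(str).tolist()
        values = df.drop(columns="id").to_numpy(dtype=float)
        label_vec = None
        if labels is not None:
            missing = [i for i in ids if i not in labels]
            if missing:
                raise PhageHydroError(f"no label for sample ids: {missing[:5]}")
            label_vec = np.array([labels[i] for i in ids], dtype=int)
        return cls(ids, [str(c) for c in df.columns[1:]], values, label_vec)
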