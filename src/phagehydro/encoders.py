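"""Protein-sequence descriptor blocks and their concatenations.

Four encoders transform a validated sequence into fixed-length numeric
blocks:

``ggdc``
    g-gap dipeptide composition: frequencies of the 400 ordered residue
    pairs separated by ``g`` intervening residues (default g=2), each
    count divided by the number of g-gap pairs, ``L - g - 1``.  Captures
    longer-range pairwise correlation than adjacent dipeptides.
``pseaac``
    Sequence-order correlation features in the pseudo-amino-acid
    composition style: for each lag j = 1..lambda (default 15) and each of
    10 physicochemical property scales, the mean over the sequence of the
    property correlation between residues j apart.  150 features; the
    plain amino-acid-composition terms are deliberately excluded (single
    -residue composition is already covered by the CTD block).
``gtpc``
    Grouped tripeptide composition: overlapping tripeptides mapped into 5
    physicochemical residue classes, giving 125 class-triple frequencies
    normalized by the tripeptide count ``L - 2``.
``ctd``
    CTD composition: for each of 13 physicochemical groupings that
    partition the 20 residues into 3 classes, the per-class residue
    fractions (13 x 3 = 39 features; each triple sums to 1).

Block order in concatenations is always GGDC, PseAAC, GTPC, CTD, and
feature names are deterministic, so selected-feature lists persist across
runs.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EncodingError, LengthError
from .features import FeatureMatrix, FeatureVector
from .seq_io import ALPHABET, Dataset

__all__ = [
    "PropertyScale",
    "GroupingTable",
    "load_property_scales",
    "load_gtpc_classes",
    "load_ctd_groupings",
    "encode_ggdc",
    "encode_pseaac",
    "encode_gtpc",
    "encode_ctdc",
    "encode_sequence",
    "encode_combined",
    "scheme_dimension",
    "SCHEMES",
]

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class PropertyScale:
    """One physicochemical property scale over the 20 residues.

    ``normalized_values`` are the raw values standardized to mean 0 and
    unit (population) variance across the 20 residues — the form used in
    the correlation products.
    """

    name: str
    raw_values: dict[str, float]
    normalized_values: dict[str, float]

    @classmethod
    def from_raw(cls, name: str, raw: dict[str, float]) -> "PropertyScale":
        if set(raw) != set(ALPHABET):
            missing = sorted(set(ALPHABET) - set(raw))
            raise ConfigError(f"property scale {name!r} missing residues: {missing}")
        vals = np.array([raw[a] for a in ALPHABET], dtype=float)
        std = vals.std()
        if std == 0:
            raise ConfigError(f"property scale {name!r} is constant over residues")
        norm = (vals - vals.mean()) / std
        return cls(name, dict(raw), {a: float(v) for a, v in zip(ALPHABET, norm)})


@dataclass(frozen=True)
class GroupingTable:
    """A named partition of the 20 residues into disjoint covering classes."""

    name: str
    classes: dict[str, str]  # class name -> residue string

    def __post_init__(self) -> None:
        all_res = "".join(self.classes.values())
        if sorted(all_res) != sorted(ALPHABET):
            raise ConfigError(
                f"grouping {self.name!r}: classes must partition the 20 residues "
                f"(got {''.join(sorted(all_res))!r})"
            )

    def class_of(self) -> dict[str, str]:
        return {res: cls for cls, residues in self.classes.items() for res in residues}


def _data_path(filename: str):
    return resources.files("phagehydro.data").joinpath(filename)


@lru_cache(maxsize=None)
def load_property_scales() -> tuple[PropertyScale, ...]:
    """The 10 bundled property scales, in file order."""
    with resources.as_file(_data_path("property_scales.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    scales = []
    for _, row in df.iterrows():
        raw = {aa: float(row[aa]) for aa in ALPHABET}
        scales.append(PropertyScale.from_raw(str(row["property"]), raw))
    return tuple(scales)


@lru_cache(maxsize=None)
def load_gtpc_classes() -> GroupingTable:
    with resources.as_file(_data_path("gtpc_classes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    classes = {str(r["class"]): str(r["residues"]) for _, r in df.iterrows()}
    return GroupingTable("gtpc", classes)


@lru_cache(maxsize=None)
def load_ctd_groupings() -> tuple[GroupingTable, ...]:
    with resources.as_file(_data_path("ctd_groupings.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    tables = []
    for name, sub in df.groupby("grouping", sort=False):
        classes = {str(r["class"]): str(r["residues"]) for _, r in sub.iterrows()}
        tables.append(GroupingTable(str(name), classes))
    return tuple(tables)


# --------------------------------------------------------------------------
# feature-name universes (deterministic, computed once)


@lru_cache(maxsize=None)
def _ggdc_names() -> tuple[str, ...]:
    return tuple(f"ggdc|{a}{b}" for a, b in product(ALPHABET, repeat=2))


@lru_cache(maxsize=None)
def _pseaac_names(lam: int, n_props: int) -> tuple[str, ...]:
    props = [s.name for s in load_property_scales()[:n_props]]
    return tuple(f"pseaac|lag{j:02d}|{p}" for j in range(1, lam + 1) for p in props)


@lru_cache(maxsize=None)
def _gtpc_names() -> tuple[str, ...]:
    classes = list(load_gtpc_classes().classes)
    return tuple(f"gtpc|{r}.{s}.{t}" for r, s, t in product(classes, repeat=3))


@lru_cache(maxsize=None)
def _ctd_names() -> tuple[str, ...]:
    names = []
    for table in load_ctd_groupings():
        for cls in table.classes:
            names.append(f"ctd|{table.name}|{cls}")
    return tuple(names)


# --------------------------------------------------------------------------
# encoders


def encode_ggdc(sequence: str, g: int = 2, seq_id: str = "?") -> FeatureVector:
    """g-gap dipeptide composition (400 features, sums to 1).

    Entry (a, b) counts positions i with ``sequence[i] == a`` and
    ``sequence[i + g + 1] == b``, divided by ``L - g - 1``.
    """
    if g < 0:
        raise ConfigError(f"g must be non-negative, got {g}")
    L = len(sequence)
    if L < g + 2:
        raise LengthError(
            f"record {seq_id!r}: length {L} < g+2 = {g + 2}; no {g}-gap pair exists"
        )
    counts = np.zeros((20, 20), dtype=float)
    for i in range(L - g - 1):
        counts[_AA_INDEX[sequence[i]], _AA_INDEX[sequence[i + g + 1]]] += 1
    return FeatureVector(list(_ggdc_names()), counts.ravel() / (L - g - 1))


def encode_pseaac(
    sequence: str,
    lam: int = 15,
    scales: tuple[PropertyScale, ...] | None = None,
    correlation: str = "product",
    seq_id: str = "?",
) -> FeatureVector:
    """Lag-correlation pseudo-amino-acid features (lambda x n_scales).

    For each lag j in 1..lambda and property p:
    ``tau(j, p) = (1 / (L - j)) * sum_k H_p(s_k, s_{k+j})``.
    The default correlation is the product of z-scored property values,
    ``H_p(x, y) = h_p(x) * h_p(y)``; ``correlation="squared-diff"``
    substitutes ``(h_p(x) - h_p(y)) ** 2``.
    """
    if lam < 1:
        raise ConfigError(f"lambda must be positive, got {lam}")
    if correlation not in ("product", "squared-diff"):
        raise ConfigError(f"unknown correlation form {correlation!r}")
    scales = load_property_scales() if scales is None else tuple(scales)
    L = len(sequence)
    if L < lam + 1:
        raise LengthError(f"record {seq_id!r}: length {L} <= lambda = {lam}; need L >= lambda+1")
    # residues -> per-scale normalized values, shape (n_scales, L)
    h = np.array([[s.normalized_values[c] for c in sequence] for s in scales])
    values = np.empty(lam * len(scales))
    for j in range(1, lam + 1):
        if correlation == "product":
            corr = h[:, : L - j] * h[:, j:]
        else:
            corr = (h[:, : L - j] - h[:, j:]) ** 2
        values[(j - 1) * len(scales) : j * len(scales)] = corr.mean(axis=1)
    return FeatureVector(list(_pseaac_names(lam, len(scales))), values)


def encode_gtpc(sequence: str, denominator: str = "tripeptides", seq_id: str = "?") -> FeatureVector:
    """Grouped tripeptide composition (125 features).

    Residues map into 5 physicochemical classes; entry (r, s, t) is the
    count of overlapping tripeptides with that class triple divided by the
    tripeptide count ``L - 2`` (so the block sums to 1).
    ``denominator="n-1"`` divides by ``L - 1`` instead, for replicating
    pipelines that use that convention.
    """
    if denominator not in ("tripeptides", "n-1"):
        raise ConfigError(f"unknown GTPC denominator {denominator!r}")
    L = len(sequence)
    if L < 3:
        raise LengthError(f"record {seq_id!r}: length {L} < 3; no tripeptide exists")
    table = load_gtpc_classes()
    class_names = list(table.classes)
    cls_index = {res: class_names.index(c) for res, c in table.class_of().items()}
    counts = np.zeros((5, 5, 5), dtype=float)
    for i in range(L - 2):
        counts[
            cls_index[sequence[i]], cls_index[sequence[i + 1]], cls_index[sequence[i + 2]]
        ] += 1
    denom = (L - 2) if denominator == "tripeptides" else (L - 1)
    return FeatureVector(list(_gtpc_names()), counts.ravel() / denom)


def encode_ctdc(sequence: str, seq_id: str = "?") -> FeatureVector:
    """CTD composition (39 features; each grouping's class triple sums to 1)."""
    L = len(sequence)
    if L < 1:
        raise LengthError(f"record {seq_id!r}: empty sequence")
    values = []
    for table in load_ctd_groupings():
        for residues in table.classes.values():
            values.append(sum(sequence.count(r) for r in residues) / L)
    return FeatureVector(list(_ctd_names()), np.array(values))


#: Scheme name -> ordered encoder blocks.
SCHEMES: dict[str, tuple[str, ...]] = {
    "ggdc+pseaac": ("ggdc", "pseaac"),
    "gtpc+ctd": ("gtpc", "ctd"),
    "all": ("ggdc", "pseaac", "gtpc", "ctd"),
}


def scheme_dimension(scheme: str, g: int = 2, lam: int = 15) -> int:
    """Total feature count of a scheme (550, 164 or 714 at defaults)."""
    dims = {"ggdc": 400, "pseaac": lam * len(load_property_scales()), "gtpc": 125, "ctd": 39}
    return sum(dims[b] for b in _scheme_blocks(scheme))


def _scheme_blocks(scheme: str) -> tuple[str, ...]:
    key = scheme.lower()
    if key not in SCHEMES:
        raise ConfigError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    return SCHEMES[key]


def encode_sequence(
    sequence: str,
    scheme: str = "all",
    g: int = 2,
    lam: int = 15,
    seq_id: str = "?",
    correlation: str = "product",
) -> FeatureVector:
    """Encode one sequence under a scheme; blocks concatenate in fixed order."""
    parts: list[FeatureVector] = []
    for block in _scheme_blocks(scheme):
        if block == "ggdc":
            parts.append(encode_ggdc(sequence, g=g, seq_id=seq_id))
        elif block == "pseaac":
            parts.append(encode_pseaac(sequence, lam=lam, seq_id=seq_id, correlation=correlation))
        elif block == "gtpc":
            parts.append(encode_gtpc(sequence, seq_id=seq_id))
        else:
            parts.append(encode_ctdc(sequence, seq_id=seq_id))
    names = [n for p in parts for n in p.names]
    return FeatureVector(names, np.concatenate([p.values for p in parts]))


def encode_combined(
    dataset: Dataset,
    scheme: str = "all",
    g: int = 2,
    lam: int = 15,
    correlation: str = "product",
) -> FeatureMatrix:
    """Encode every record of a dataset into one :class:`FeatureMatrix`.

    Any record failing an encoder's length precondition is collected and
    reported in a single aggregated :class:`EncodingError`.
    """
    rows: list[np.ndarray] = []
    names: list[str] | None = None
    failures: list[str] = []
    messages: list[str] = []
    for rec in dataset:
        try:
            fv = encode_sequence(
                rec.sequence, scheme=scheme, g=g, lam=lam, seq_id=rec.id, correlation=correlation
            )
        except LengthError as exc:
            failures.append(rec.id)
            messages.append(str(exc))
            continue
        rows.append(fv.values)
        names = fv.names
    if failures:
        raise EncodingError(
            f"{len(failures)} record(s) failed encoding under scheme {scheme!r}: "
            + "; ".join(messages[:5]),
            failed_ids=failures,
        )
    if names is None:
        raise EncodingError("dataset is empty; nothing to encode")
    ok_ids = [r.id for r in dataset]
    labels = dataset.labels
    return FeatureMatrix(
        sample_ids=ok_ids,
        names=names,
        values=np.vstack(rows),
        labels=None if labels is None else np.array(labels),
    )
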