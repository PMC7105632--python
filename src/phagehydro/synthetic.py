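"""Synthetic two-class protein datasets with plantable compositional biases.

The generator emits sequences from a residue background model (uniform by
default, optionally Swiss-Prot-like frequencies).  Positive-class
sequences are built by rejection-free mixture sampling: at each emission
step, with probability ``effect_size`` a planted motif is emitted — a
g-gap residue pair, a tripeptide over the 5 GTPC classes, or a residue
from a chosen CTD composition class — otherwise a single background
residue.  ``effect_size = 0`` therefore makes the two classes
exchangeable, and larger values shift exactly the feature channels named
by the bias targets.  Everything is reproducible from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoders import load_ctd_groupings, load_gtpc_classes
from .exceptions import ConfigError
from .seq_io import ALPHABET, Dataset, ProteinRecord

__all__ = [
    "GapPairBias",
    "TripeptideBias",
    "CompositionBias",
    "GeneratorConfig",
    "generate_dataset",
    "generate_cascade_datasets",
    "SWISSPROT_FREQUENCIES",
]

#: Approximate Swiss-Prot residue frequencies (fractions; UniProt statistics).
SWISSPROT_FREQUENCIES: dict[str, float] = {
    "A": 0.0825, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0707, "H": 0.0227, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class GapPairBias:
    """Excess of the ordered g-gap residue pair (first, ..g gap.., second)."""

    first: str = "A"
    second: str = "A"
    g: int = 2


@dataclass(frozen=True)
class TripeptideBias:
    """Excess of a tripeptide whose residues come from three GTPC classes."""

    classes: tuple[str, str, str] = ("g1", "g1", "g2")


@dataclass(frozen=True)
class CompositionBias:
    """Excess of residues from one class of one CTD grouping."""

    grouping: str = "charge"
    cls: str = "positive"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic two-class dataset.

    Lengths must allow every encoder at defaults (lambda=15, g=2), hence
    the minimum of 17 residues.  ``effect_size`` is the per-step motif
    emission probability for the positive class and must lie in [0, 1].
    """

    n_pos: int = 60
    n_neg: int = 60
    length_range: tuple[int, int] = (50, 150)
    effect_size: float = 0.3
    bias_targets: tuple = (GapPairBias(),)
    seed: int = 0
    background: str = "uniform"  # or "swissprot"
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 17:
            raise ConfigError(f"minimum length must be >= 17 (encoder preconditions), got {lo}")
        if hi < lo:
            raise ConfigError(f"length_range max {hi} < min {lo}")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ConfigError(
                f"effect_size is a probability mass and must lie in [0, 1], got {self.effect_size}"
            )
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("each class needs at least one sample")
        if self.background not in ("uniform", "swissprot"):
            raise ConfigError(f"unknown background model {self.background!r}")
        if not self.bias_targets:
            raise ConfigError("at least one bias target is required")


def _background_probs(background: str) -> np.ndarray:
    if background == "uniform":
        return np.full(20, 1 / 20)
    probs = np.array([SWISSPROT_FREQUENCIES[a] for a in ALPHABET])
    return probs / probs.sum()


def _emit_motif(target, rng: np.random.Generator, probs: np.ndarray) -> str:
    alphabet = np.array(list(ALPHABET))
    if isinstance(target, GapPairBias):
        gap = "".join(rng.choice(alphabet, size=target.g, p=probs))
        return target.first + gap + target.second
    if isinstance(target, TripeptideBias):
        classes = load_gtpc_classes().classes
        out = []
        for c in target.classes:
            if c not in classes:
                raise ConfigError(f"unknown GTPC class {c!r}")
            residues = classes[c]
            out.append(residues[rng.integers(len(residues))])
        return "".join(out)
    if isinstance(target, CompositionBias):
        for table in load_ctd_groupings():
            if table.name == target.grouping:
                if target.cls not in table.classes:
                    raise ConfigError(f"grouping {target.grouping!r} has no class {target.cls!r}")
                residues = table.classes[target.cls]
                return residues[rng.integers(len(residues))]
        raise ConfigError(f"unknown CTD grouping {target.grouping!r}")
    raise ConfigError(f"unknown bias target type {type(target).__name__}")


def _emit_sequence(
    length: int, effect: float, targets, rng: np.random.Generator, probs: np.ndarray
) -> str:
    alphabet = np.array(list(ALPHABET))
    chunks: list[str] = []
    total = 0
    while total < length:
        if effect > 0 and rng.random() < effect:
            chunk = _emit_motif(targets[rng.integers(len(targets))], rng, probs)
        else:
            chunk = str(alphabet[rng.choice(20, p=probs)])
        chunks.append(chunk)
        total += len(chunk)
    return "".join(chunks)[:length]


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Draw a labelled dataset; positives carry the planted biases."""
    rng = np.random.default_rng(config.seed)
    probs = _background_probs(config.background)
    lo, hi = config.length_range
    records = []
    for i in range(config.n_pos):
        L = int(rng.integers(lo, hi + 1))
        seq = _emit_sequence(L, config.effect_size, config.bias_targets, rng, probs)
        records.append(ProteinRecord(f"{config.id_prefix}_pos_{i:04d}", seq, label=1))
    for i in range(config.n_neg):
        L = int(rng.integers(lo, hi + 1))
        seq = _emit_sequence(L, 0.0, config.bias_targets, rng, probs)
        records.append(ProteinRecord(f"{config.id_prefix}_neg_{i:04d}", seq, label=0))
    return Dataset(records, stage_tag="synthetic")


def generate_cascade_datasets(
    seed: int = 0,
    n_per_class: int = 30,
    effect_stage1: float = 0.3,
    effect_stage2: float = 0.3,
    length_range: tuple[int, int] = (50, 150),
) -> tuple[Dataset, Dataset]:
    """Two stage-labelled datasets emulating the nested enzyme/hydrolase design.

    Enzyme-like sequences carry a planted 2-gap A..A excess at rate
    ``effect_stage1``; hydrolases are enzymes that additionally carry a
    2-gap K..E excess at rate ``effect_stage2`` (so the hydrolase class is
    nested inside the enzyme class, as in the benchmark design, and the two
    stages discriminate on different feature channels).

    Returns ``(set1, set2)``: set1 is enzymes (hydrolases plus other
    enzymes, 2 * ``n_per_class`` of them) vs as many background
    non-enzymes; set2 relabels exactly set1's enzymes as hydrolase vs
    other enzyme — so set2's sequences are a subset of set1's, as in the
    benchmark design.

    The mixture sampler picks uniformly among a sequence's bias targets, so
    hydrolases are emitted with total motif rate ``effect_stage1 +
    effect_stage2`` over both motifs; with the two rates equal this plants
    each motif at exactly its stage's rate.
    """
    if effect_stage1 + effect_stage2 > 1.0:
        raise ConfigError("effect_stage1 + effect_stage2 must not exceed 1")
    aa, ke = GapPairBias("A", "A", 2), GapPairBias("K", "E", 2)
    hydrolases = [
        r
        for r in generate_dataset(
            GeneratorConfig(
                n_pos=n_per_class,
                n_neg=1,  # discarded; the generator requires one negative
                effect_size=effect_stage1 + effect_stage2,
                bias_targets=(aa, ke),
                length_range=length_range,
                seed=seed,
                id_prefix="hyd",
            )
        )
        if r.label == 1
    ]
    other_enzymes = [
        r
        for r in generate_dataset(
            GeneratorConfig(
                n_pos=n_per_class,
                n_neg=1,
                effect_size=effect_stage1,
                bias_targets=(aa,),
                length_range=length_range,
                seed=seed + 1,
                id_prefix="oenz",
            )
        )
        if r.label == 1
    ]
    non_enzymes = [
        r
        for r in generate_dataset(
            GeneratorConfig(
                n_pos=1,
                n_neg=2 * n_per_class,
                effect_size=0.0,
                bias_targets=(aa,),
                length_range=length_range,
                seed=seed + 2,
                id_prefix="bg",
            )
        )
        if r.label == 0
    ]
    enzymes = hydrolases + other_enzymes
    set1 = Dataset(
        [ProteinRecord(r.id, r.sequence, label=1) for r in enzymes] + non_enzymes,
        stage_tag="enzyme",
    )
    set2 = Dataset(
        [ProteinRecord(r.id, r.sequence, label=1) for r in hydrolases]
        + [ProteinRecord(r.id, r.sequence, label=0) for r in other_enzymes],
        stage_tag="hydrolase",
    )
    return set1, set2


def replace_stage(dataset: Dataset, tag: str) -> Dataset:
    return Dataset(list(dataset.records), stage_tag=tag)
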