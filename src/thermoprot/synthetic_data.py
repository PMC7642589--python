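"""Synthetic two-class protein datasets with controllable composition.

Real thermophilic and non-thermophilic proteomes differ most strongly in
charged-residue content: lysine frequency concentrates near 0.08 in
thermophilic proteins versus near 0.03 in non-thermophilic ones, with
aspartate and the leucine-lysine dipeptide next in discriminative power.
The generator emulates exactly that signal: residues are drawn i.i.d. from a
class-conditional frequency profile, optionally tilted by a first-order
Markov multiplier that enriches one dipeptide (LK by default in the positive
class).  It makes no attempt at domain structure, homology or realistic
length/composition covariation — it exists so the whole
encode/select/classify pipeline is testable without external downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import LabeledDataset, ProteinSequence
from .tables import AA_INDEX, AMINO_ACIDS

__all__ = ["ClassProfile", "default_profiles", "generate"]


@dataclass
class ClassProfile:
    """Residue frequencies, a uniform length range, and an optional dipeptide tilt."""

    frequencies: dict[str, float]
    min_length: int = 50
    max_length: int = 600
    enriched_dipeptide: str | None = None
    enrichment: float = 2.0

    def __post_init__(self) -> None:
        if sorted(self.frequencies) != sorted(AMINO_ACIDS):
            raise ValueError("profile must assign a frequency to all 20 residues")
        freqs = np.array([self.frequencies[a] for a in AMINO_ACIDS])
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")
        if self.min_length < 3 or self.max_length < self.min_length:
            raise ValueError("need 3 <= min_length <= max_length")
        if self.enriched_dipeptide is not None:
            d = self.enriched_dipeptide
            if len(d) != 2 or any(c not in AMINO_ACIDS for c in d):
                raise ValueError("enriched_dipeptide must be two canonical residues")
            if self.enrichment <= 0:
                raise ValueError("enrichment must be positive")

    def frequency_vector(self) -> np.ndarray:
        return np.array([self.frequencies[a] for a in AMINO_ACIDS])

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic residue transition matrix implementing the tilt.

        Every row equals the base frequency vector; for an enriched
        dipeptide "XY" the X row has its Y entry multiplied and is
        renormalized.
        """
        base = self.frequency_vector()
        P = np.tile(base, (20, 1))
        if self.enriched_dipeptide is not None:
            i = AA_INDEX[self.enriched_dipeptide[0]]
            j = AA_INDEX[self.enriched_dipeptide[1]]
            P[i, j] *= self.enrichment
            P[i] /= P[i].sum()
        return P

    def to_dict(self) -> dict:
        return {
            "frequencies": self.frequencies,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "enriched_dipeptide": self.enriched_dipeptide,
            "enrichment": self.enrichment,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassProfile":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _uniform_background(fixed: dict[str, float]) -> dict[str, float]:
    rest = 1.0 - sum(fixed.values())
    others = [a for a in AMINO_ACIDS if a not in fixed]
    freqs = {a: rest / len(others) for a in others}
    freqs.update(fixed)
    return freqs


def default_profiles(
    min_length: int = 50, max_length: int = 600
) -> tuple[ClassProfile, ClassProfile]:
    """The default thermophilic-like / non-thermophilic-like profile pair.

    Positive (thermophilic-like): f(K) = 0.08, elevated f(D) = 0.060, and a
    2x leucine->lysine transition tilt.  Negative: f(K) = 0.03 and
    f(D) = 0.045.  All remaining mass is uniform over the other residues.
    """
    positive = ClassProfile(
        frequencies=_uniform_background({"K": 0.08, "D": 0.060}),
        min_length=min_length,
        max_length=max_length,
        enriched_dipeptide="LK",
        enrichment=2.0,
    )
    negative = ClassProfile(
        frequencies=_uniform_background({"K": 0.03, "D": 0.045}),
        min_length=min_length,
        max_length=max_length,
    )
    return positive, negative


def _sample_sequence(profile: ClassProfile, rng: np.random.Generator) -> str:
    n = int(rng.integers(profile.min_length, profile.max_length + 1))
    base = profile.frequency_vector()
    if profile.enriched_dipeptide is None:
        codes = rng.choice(20, size=n, p=base)
    else:
        # inverse-CDF sampling down the Markov chain
        cum = np.cumsum(profile.transition_matrix(), axis=1)
        cum[:, -1] = 1.0
        u = rng.random(n)
        codes = np.empty(n, dtype=np.intp)
        codes[0] = np.searchsorted(np.cumsum(base), u[0], side="right")
        for t in range(1, n):
            codes[t] = np.searchsorted(cum[codes[t - 1]], u[t], side="right")
    return "".join(AMINO_ACIDS[c] for c in codes)


def generate(
    profile_pos: ClassProfile,
    profile_neg: ClassProfile,
    n_pos: int,
    n_neg: int,
    seed: int | None = None,
) -> LabeledDataset:
    """Draw a labeled dataset: ``n_pos`` positives and ``n_neg`` negatives.

    Reproducible under ``seed``; ids are ``pos_0001`` / ``neg_0001`` style and
    every sequence is over the canonical alphabet by construction.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    sequences = [
        ProteinSequence(f"pos_{i + 1:04d}", _sample_sequence(profile_pos, rng), 1)
        for i in range(n_pos)
    ]
    sequences += [
        ProteinSequence(f"neg_{i + 1:04d}", _sample_sequence(profile_neg, rng), 0)
        for i in range(n_neg)
    ]
    return LabeledDataset(sequences)
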