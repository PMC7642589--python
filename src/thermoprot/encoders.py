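"""The ten protein descriptor encoders, as named ordered feature vectors.

Every encoder maps a sequence of length ``n`` to a fixed-dimension vector of
named features:

========  ====  =================================================================
encoder   dim   definition
========  ====  =================================================================
AAC         20  residue frequencies n(i)/n
DPC        400  overlapping dipeptide frequencies n_xy/(n-1)
TPC       8000  overlapping tripeptide frequencies n_xyz/(n-2)
DDE        400  dipeptide deviation from expected mean: (D_c - T_m)/sqrt(T_v),
                T_m = (C_x/61)(C_y/61) from codon counts, T_v = T_m(1-T_m)/(n-1)
GDPC        25  dipeptide frequencies on the 5-group recoded alphabet
GTPC       125  tripeptide frequencies on the 5-group recoded alphabet
CKSAAGP    150  5-group pair frequencies at residue separations k=0..5,
                denominator n-k-1 per gap block
CTDC        39  per-property 3-group composition, 13 physicochemical properties
CTDT        39  per-property between-group transition frequencies
                (n(x,y)+n(y,x))/(n-1) for the pairs (1,2),(2,3),(3,1)
CTriad     343  7-class conjoint-triad frequencies n_abc/(n-2)
========  ====  =================================================================

Feature names follow the canon ``token`` within an encoder and
``ENCODER:token`` once assembled into a matrix, with tokens in lexicographic
alphabet order — so the lysine composition is addressable as ``AAC:K`` and the
leucine–lysine dipeptide as ``DPC:LK``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence_io import LabeledDataset, ProteinSequence
from .tables import AA_INDEX, AMINO_ACIDS, PropertyTable, default_property_table

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "ProteinFeatureEncoder",
    "encode_aac",
    "encode_dpc",
    "encode_tpc",
    "encode_dde",
    "encode_gdpc",
    "encode_gtpc",
    "encode_cksaagp",
    "encode_ctdc",
    "encode_ctdt",
    "encode_ctriad",
    "encode_dataset",
    "ENCODER_NAMES",
]


@dataclass
class FeatureVector:
    """Named, ordered descriptor values produced by one encoder."""

    names: list[str]
    values: np.ndarray
    encoder_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values must align")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _codes(seq: ProteinSequence) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in seq.residues], dtype=np.intp)
    except KeyError as exc:  # encoders require validated sequences
        raise ValueError(
            f"sequence {seq.id!r} contains non-canonical residue {exc.args[0]!r}"
        ) from exc


def _require_length(seq: ProteinSequence, n_min: int, encoder: str) -> None:
    if len(seq) < n_min:
        raise ValueError(
            f"{encoder} requires length >= {n_min}; sequence {seq.id!r} has {len(seq)}"
        )


# --- canonical name lists, built once -------------------------------------

_AAC_NAMES = list(AMINO_ACIDS)
_DPC_NAMES = ["".join(p) for p in product(AMINO_ACIDS, repeat=2)]
_TPC_NAMES = ["".join(p) for p in product(AMINO_ACIDS, repeat=3)]


def encode_aac(seq: ProteinSequence) -> FeatureVector:
    """Amino acid composition: 20 residue frequencies, summing to 1."""
    _require_length(seq, 1, "AAC")
    counts = np.bincount(_codes(seq), minlength=20)
    return FeatureVector(_AAC_NAMES, counts / len(seq), "AAC")


def encode_dpc(seq: ProteinSequence) -> FeatureVector:
    """Dipeptide composition: 400 overlapping-pair frequencies over n-1 windows."""
    _require_length(seq, 2, "DPC")
    c = _codes(seq)
    idx = 20 * c[:-1] + c[1:]
    counts = np.bincount(idx, minlength=400)
    return FeatureVector(_DPC_NAMES, counts / (len(seq) - 1), "DPC")


def encode_tpc(seq: ProteinSequence) -> FeatureVector:
    """Tripeptide composition: 8000 overlapping-triplet frequencies over n-2 windows."""
    _require_length(seq, 3, "TPC")
    c = _codes(seq)
    idx = 400 * c[:-2] + 20 * c[1:-1] + c[2:]
    counts = np.bincount(idx, minlength=8000)
    return FeatureVector(_TPC_NAMES, counts / (len(seq) - 2), "TPC")


def encode_dde(
    seq: ProteinSequence, props: PropertyTable | None = None
) -> FeatureVector:
    """Dipeptide deviation from expected mean.

    Standardizes each observed dipeptide frequency D_c against its
    codon-usage expectation T_m = (C_x/C_n)(C_y/C_n) with theoretical variance
    T_v = T_m(1-T_m)/(n-1); C_n = 61 sense codons.  Values are signed and the
    sign tracks D_c - T_m.
    """
    _require_length(seq, 2, "DDE")
    props = props or default_property_table()
    c = _codes(seq)
    n = len(seq)
    dc = np.bincount(20 * c[:-1] + c[1:], minlength=400) / (n - 1)
    codons = np.array([props.codon_counts[a] for a in AMINO_ACIDS], dtype=float)
    cn = codons.sum()
    tm = np.outer(codons / cn, codons / cn).ravel()  # row-major: x then y
    tv = tm * (1.0 - tm) / (n - 1)
    return FeatureVector(_DPC_NAMES, (dc - tm) / np.sqrt(tv), "DDE")


def _group_recode(props: PropertyTable) -> tuple[np.ndarray, list[str]]:
    """Residue-index -> 5-group-index lookup, plus ordered group names."""
    names = list(props.aa_groups_5)
    lookup = np.empty(20, dtype=np.intp)
    for gi, members in enumerate(props.aa_groups_5.values()):
        for aa in members:
            lookup[AA_INDEX[aa]] = gi
    return lookup, names


def encode_gdpc(
    seq: ProteinSequence, props: PropertyTable | None = None
) -> FeatureVector:
    """Grouped dipeptide composition on the 5-group alphabet (25 features)."""
    _require_length(seq, 2, "GDPC")
    props = props or default_property_table()
    lookup, names = _group_recode(props)
    g = lookup[_codes(seq)]
    counts = np.bincount(5 * g[:-1] + g[1:], minlength=25)
    feat_names = [f"{x}{y}" for x, y in product(names, repeat=2)]
    return FeatureVector(feat_names, counts / (len(seq) - 1), "GDPC")


def encode_gtpc(
    seq: ProteinSequence, props: PropertyTable | None = None
) -> FeatureVector:
    """Grouped tripeptide composition on the 5-group alphabet (125 features)."""
    _require_length(seq, 3, "GTPC")
    props = props or default_property_table()
    lookup, names = _group_recode(props)
    g = lookup[_codes(seq)]
    counts = np.bincount(25 * g[:-2] + 5 * g[1:-1] + g[2:], minlength=125)
    feat_names = [f"{x}{y}{z}" for x, y, z in product(names, repeat=3)]
    return FeatureVector(feat_names, counts / (len(seq) - 2), "GTPC")


def encode_cksaagp(
    seq: ProteinSequence, props: PropertyTable | None = None, max_gap: int = 5
) -> FeatureVector:
    """Composition of k-spaced amino-acid group pairs, gaps 0..max_gap.

    For gap k the 25 group-pair frequencies are counted over the n-k-1
    positions pairing residue i with residue i+k+1, so each gap block sums
    to 1.  The gap-0 block coincides with GDPC.
    """
    props = props or default_property_table()
    _require_length(seq, max_gap + 2, f"CKSAAGP(max_gap={max_gap})")
    lookup, names = _group_recode(props)
    g = lookup[_codes(seq)]
    n = len(seq)
    blocks, feat_names = [], []
    for k in range(max_gap + 1):
        idx = 5 * g[: n - k - 1] + g[k + 1 :]
        blocks.append(np.bincount(idx, minlength=25) / (n - k - 1))
        feat_names.extend(f"{x}{y}.k{k}" for x, y in product(names, repeat=2))
    return FeatureVector(feat_names, np.concatenate(blocks), "CKSAAGP")


def _ctd_lookup(props: PropertyTable) -> list[tuple[str, np.ndarray]]:
    out = []
    for prop, groups in props.ctd_properties.items():
        lookup = np.empty(20, dtype=np.intp)
        for gi, members in enumerate(groups):
            for aa in members:
                lookup[AA_INDEX[aa]] = gi
        out.append((prop, lookup))
    return out


def encode_ctdc(
    seq: ProteinSequence, props: PropertyTable | None = None
) -> FeatureVector:
    """CTD composition: per-property fractions of the 3 groups (13 x 3 = 39)."""
    _require_length(seq, 1, "CTDC")
    props = props or default_property_table()
    c = _codes(seq)
    n = len(seq)
    names, values = [], []
    for prop, lookup in _ctd_lookup(props):
        counts = np.bincount(lookup[c], minlength=3)
        values.extend(counts / n)
        names.extend(f"{prop}.G{g}" for g in (1, 2, 3))
    return FeatureVector(names, np.array(values), "CTDC")


def encode_ctdt(
    seq: ProteinSequence, props: PropertyTable | None = None
) -> FeatureVector:
    """CTD transition: per-property frequencies of adjacent between-group pairs.

    T(x,y) = (n(x,y) + n(y,x)) / (n - 1) for the group pairs (1,2), (2,3)
    and (3,1); 13 properties x 3 transitions = 39 features.
    """
    _require_length(seq, 2, "CTDT")
    props = props or default_property_table()
    c = _codes(seq)
    n = len(seq)
    names, values = [], []
    pairs = [(0, 1), (1, 2), (2, 0)]
    for prop, lookup in _ctd_lookup(props):
        g = lookup[c]
        a, b = g[:-1], g[1:]
        for x, y in pairs:
            count = np.sum((a == x) & (b == y)) + np.sum((a == y) & (b == x))
            values.append(count / (n - 1))
        names.extend(
            f"{prop}.Tr{x + 1}{y + 1}" for x, y in pairs
        )
    return FeatureVector(names, np.array(values), "CTDT")


def encode_ctriad(
    seq: ProteinSequence, props: PropertyTable | None = None
) -> FeatureVector:
    """Conjoint triad: frequencies of 7-class triads, n_abc/(n-2) (343 features)."""
    _require_length(seq, 3, "CTriad")
    props = props or default_property_table()
    lookup = np.empty(20, dtype=np.intp)
    for ci, members in enumerate(props.ctriad_classes):
        for aa in members:
            lookup[AA_INDEX[aa]] = ci
    t = lookup[_codes(seq)]
    counts = np.bincount(49 * t[:-2] + 7 * t[1:-1] + t[2:], minlength=343)
    names = [f"{a}{b}{c}" for a, b, c in product("1234567", repeat=3)]
    return FeatureVector(names, counts / (len(seq) - 2), "CTriad")


# --- registry and dataset-level assembly ----------------------------------

_EncoderFn = Callable[[ProteinSequence, PropertyTable], FeatureVector]


def _no_props(fn: Callable[[ProteinSequence], FeatureVector]) -> _EncoderFn:
    return lambda seq, props: fn(seq)


# name -> (function, minimum sequence length)
_REGISTRY: dict[str, tuple[_EncoderFn, int]] = {
    "AAC": (_no_props(encode_aac), 1),
    "DPC": (_no_props(encode_dpc), 2),
    "TPC": (_no_props(encode_tpc), 3),
    "DDE": (encode_dde, 2),
    "GDPC": (encode_gdpc, 2),
    "GTPC": (encode_gtpc, 3),
    "CKSAAGP": (encode_cksaagp, 7),
    "CTDC": (encode_ctdc, 1),
    "CTDT": (encode_ctdt, 2),
    "CTriad": (encode_ctriad, 3),
}

ENCODER_NAMES: tuple[str, ...] = tuple(_REGISTRY)
_CANON = {name.upper(): name for name in _REGISTRY}


def resolve_encoder_name(name: str) -> str:
    try:
        return _CANON[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown encoder {name!r}; valid encoders: {', '.join(_REGISTRY)}"
        ) from None


@dataclass
class FeatureMatrix:
    """Sequences x named features, with an optional binary label vector."""

    X: pd.DataFrame
    y: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.y is not None:
            if isinstance(self.y, pd.Series) and not self.y.index.equals(self.X.index):
                self.y = self.y.to_numpy()  # positional labels, ids differ
            self.y = pd.Series(self.y, index=self.X.index, name="label").astype(int)
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def select(self, features: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.X.loc[:, list(features)].copy(), self.y)

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: first column id, named features, last column label."""
        df = self.X.copy()
        if self.y is not None:
            df["label"] = self.y
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        y = None
        if "label" in df.columns:
            y = df.pop("label")
        return cls(df, y)

    def to_libsvm(self, path: str | Path) -> None:
        """Write the sparse LIBSVM format (label idx:value, 1-based indices)."""
        if self.y is None:
            raise ValueError("LIBSVM output requires labels")
        lines = []
        values = self.X.to_numpy()
        for row, label in zip(values, self.y.to_numpy()):
            nz = np.flatnonzero(row)
            pairs = " ".join(f"{j + 1}:{row[j]:.12g}" for j in nz)
            lines.append(f"{label} {pairs}".rstrip())
        Path(path).write_text("\n".join(lines) + "\n")


def encode_dataset(
    data: LabeledDataset | Sequence[ProteinSequence],
    encoder_names: Sequence[str],
    props: PropertyTable | None = None,
) -> FeatureMatrix:
    """Encode every sequence with every requested encoder, columns concatenated.

    Column names are prefixed ``ENCODER:token`` in request order.  A sequence
    shorter than an encoder's minimum length is an error naming both.
    """
    props = props or default_property_table()
    names = [resolve_encoder_name(n) for n in encoder_names]
    if not names:
        raise ValueError("at least one encoder is required")
    sequences = list(data)
    if not sequences:
        raise ValueError("no sequences to encode")
    for name in names:
        _, n_min = _REGISTRY[name]
        for seq in sequences:
            if len(seq) < n_min:
                raise ValueError(
                    f"sequence {seq.id!r} (length {len(seq)}) is too short for "
                    f"encoder {name} (minimum {n_min})"
                )
    columns: list[str] = []
    rows = [[] for _ in sequences]
    for name in names:
        fn, _ = _REGISTRY[name]
        first = fn(sequences[0], props)
        columns.extend(f"{first.encoder_tag}:{t}" for t in first.names)
        rows[0].append(first.values)
        for i, seq in enumerate(sequences[1:], start=1):
            rows[i].append(fn(seq, props).values)
    X = pd.DataFrame(
        np.vstack([np.concatenate(parts) for parts in rows]),
        index=[s.id for s in sequences],
        columns=columns,
    )
    labels = [s.label for s in sequences]
    y = pd.Series(labels, index=X.index) if all(l is not None for l in labels) else None
    return FeatureMatrix(X, y)


class ProteinFeatureEncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer from protein sequences to descriptor columns.

    Parameters
    ----------
    encoders : list of str, default ("AAC",)
        Encoder names applied in order; their feature blocks are concatenated.
    props : PropertyTable, optional
        Alternative residue groupings / codon counts.

    The input to :meth:`transform` is a sequence of :class:`ProteinSequence`
    objects (or raw residue strings, which are wrapped with synthetic ids).
    """

    def __init__(
        self,
        encoders: Sequence[str] = ("AAC",),
        props: PropertyTable | None = None,
    ) -> None:
        self.encoders = encoders
        self.props = props

    def fit(self, X, y=None) -> "ProteinFeatureEncoder":
        self.encoder_names_ = [resolve_encoder_name(n) for n in self.encoders]
        mat = self._encode(X)
        self.feature_names_out_ = np.asarray(mat.feature_names, dtype=object)
        return self

    def _encode(self, X) -> FeatureMatrix:
        seqs = [
            s if isinstance(s, ProteinSequence) else ProteinSequence(f"seq{i}", str(s))
            for i, s in enumerate(X)
        ]
        return encode_dataset(seqs, list(self.encoders), self.props)

    def transform(self, X) -> pd.DataFrame:
        return self._encode(X).X

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return self.feature_names_out_
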