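"""Residue partition tables and codon counts shared by the descriptor encoders.

The tables here are the fixed biological lookup data behind the encoders:

* ``CODON_COUNTS`` — how many sense codons of the standard genetic code encode
  each amino acid (61 total after excluding the three stop codons).  The DDE
  descriptor uses these counts to form the codon-usage expectation of each
  dipeptide.
* ``CTD_PROPERTIES`` — thirteen physicochemical attributes, each partitioning
  the 20 residues into three groups (Tomii–Kanehisa amino-acid-index
  clustering, as conventionally used by protein descriptor toolkits).  These
  drive the composition (CTDC) and transition (CTDT) encodings.
* ``AA_GROUPS_5`` — the five-group physicochemical alphabet (aliphatic,
  aromatic, positively charged, negatively charged, uncharged) used by the
  grouped dipeptide/tripeptide and k-spaced group-pair encoders.
* ``CTRIAD_CLASSES`` — the seven electrostatics/volume classes of the conjoint
  triad descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Sense codons per residue in the standard genetic code; sums to 61.
CODON_COUNTS: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2,
    "G": 4, "H": 2, "I": 3, "K": 2, "L": 6,
    "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6,
    "S": 6, "T": 4, "V": 4, "W": 1, "Y": 2,
}

# 13 attributes x 3 groups; each row is a partition of the 20 residues.
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

# Five-group physicochemical alphabet for GDPC / GTPC / CKSAAGP.
AA_GROUPS_5: dict[str, str] = {
    "g1": "GAVLMI",   # aliphatic
    "g2": "FYW",      # aromatic
    "g3": "KRH",      # positively charged
    "g4": "DE",       # negatively charged
    "g5": "STCPNQ",   # uncharged
}

# Seven conjoint-triad classes (dipole / side-chain volume clustering).
CTRIAD_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")


def _check_partition(groups: tuple[str, ...] | list[str], context: str) -> None:
    joined = "".join(groups)
    if sorted(joined) != sorted(AMINO_ACIDS):
        raise ValueError(f"{context}: groups {groups!r} do not partition the 20 residues")


@dataclass(frozen=True)
class PropertyTable:
    """The fixed lookup tables consumed by the encoders.

    All fields default to the standard tables above; alternative groupings can
    be supplied for sensitivity analyses.  Invariants (each CTD attribute and
    each grouping is a partition of the 20 residues; codon counts sum to 61)
    are enforced at construction.
    """

    codon_counts: dict[str, int] = field(default_factory=lambda: dict(CODON_COUNTS))
    ctd_properties: dict[str, tuple[str, str, str]] = field(
        default_factory=lambda: dict(CTD_PROPERTIES)
    )
    aa_groups_5: dict[str, str] = field(default_factory=lambda: dict(AA_GROUPS_5))
    ctriad_classes: tuple[str, ...] = CTRIAD_CLASSES

    def __post_init__(self) -> None:
        if sorted(self.codon_counts) != sorted(AMINO_ACIDS):
            raise ValueError("codon_counts must cover exactly the 20 canonical residues")
        if sum(self.codon_counts.values()) != 61:
            raise ValueError("codon_counts must sum to 61 (sense codons)")
        for prop, groups in self.ctd_properties.items():
            if len(groups) != 3:
                raise ValueError(f"CTD property {prop!r} must have 3 groups")
            _check_partition(groups, f"CTD property {prop!r}")
        _check_partition(tuple(self.aa_groups_5.values()), "aa_groups_5")
        _check_partition(self.ctriad_classes, "ctriad_classes")


_DEFAULT_TABLE = PropertyTable()


def default_property_table() -> PropertyTable:
    """Return the shared default :class:`PropertyTable` instance."""
    return _DEFAULT_TABLE
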