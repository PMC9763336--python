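"""Numeric feature encodings for peptide sequences.

Four per-residue feature schemes, concatenated from three blocks:

* **bpf** (d=20) - binary profile feature: one-hot over the 20 amino acids
  in alphabetical order (A, C, D, ..., Y).
* **quanc** (d=26) - bpf + six z-scored quantitative properties (molecular
  mass, isoelectric point, pk1, pk2, pKa, van der Waals volume).  The raw
  property table ships as a CSV resource; standardization uses the
  population standard deviation over the 20 amino-acid rows, so the
  encoding is a fixed function of the residue, independent of any dataset.
* **qualc** (d=30) - bpf + ten one-hot indicators for four categorical
  properties (hydrophobicity Y/N, polarity Y/N, charge -/+/neutral,
  aromatic/aliphatic/neither).
* **mix** (d=36) - bpf + quanc block + qualc block.

A fifth scheme name, **embedding** (d=36), denotes a trainable per-residue
lookup learned inside the network; it has no fixed encoder here.

A peptide of length l becomes an Lmax x d matrix: rows 1..l encode the
residues, the remaining rows are filled with the pad value 0.0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import ALPHABET, LMAX, LMIN, Peptide, PeptideDataset

QUANT_PROPERTIES = (
    "molecular_mass",
    "isoelectric_point",
    "pk1",
    "pk2",
    "pka",
    "vdw_volume",
)

QUALC_CHANNELS = (
    "hydrophobicity_Y",
    "hydrophobicity_N",
    "polarity_Y",
    "polarity_N",
    "charge_negative",
    "charge_positive",
    "charge_N",
    "aromatic",
    "aliphatic",
    "aromatic_aliphatic_N",
)

SCHEME_DIMS = {"bpf": 20, "quanc": 26, "qualc": 30, "mix": 36, "embedding": 36}
#: "quanl" appears in some tabulations as an alias for the bpf+qualc scheme.
SCHEME_ALIASES = {"quanl": "qualc"}

PAD_VALUE = 0.0

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("acpkit").joinpath("data", name)))


def _read_csv_rows(name: str) -> list[dict[str, str]]:
    with open(_data_path(name)) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(lines))


@dataclass(frozen=True)
class QuantPropertyTable:
    """Raw 20 x 6 quantitative property table (values as printed)."""

    values: np.ndarray  # (20, 6), rows ordered by ALPHABET
    row_order: tuple[str, ...]

    @classmethod
    def load(cls) -> "QuantPropertyTable":
        rows = _read_csv_rows("quantitative_properties.csv")
        by_aa = {r["amino_acid"]: r for r in rows}
        if set(by_aa) != set(ALPHABET):
            raise ValueError("property table must cover exactly the 20 amino acids")
        values = np.array(
            [[float(by_aa[aa][p]) for p in QUANT_PROPERTIES] for aa in ALPHABET]
        )
        return cls(values=values, row_order=tuple(ALPHABET))

    def value(self, residue: str, prop: str) -> float:
        return float(self.values[_AA_INDEX[residue], QUANT_PROPERTIES.index(prop)])


@dataclass(frozen=True)
class StandardizedTable:
    """Column-standardized property table with its mean/std snapshot."""

    z: np.ndarray      # (20, 6)
    mu: np.ndarray     # (6,)
    sigma: np.ndarray  # (6,)

    def row(self, residue: str) -> np.ndarray:
        return self.z[_AA_INDEX[residue]]

    def to_dict(self) -> dict:
        return {"z": self.z.tolist(), "mu": self.mu.tolist(), "sigma": self.sigma.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizedTable":
        return cls(np.asarray(d["z"]), np.asarray(d["mu"]), np.asarray(d["sigma"]))


def standardize_table(raw: QuantPropertyTable) -> StandardizedTable:
    """Per-column z-score with population variance (divide by 20)."""
    x = raw.values
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)  # population std: ddof=0
    if np.any(sigma == 0):
        zero = [QUANT_PROPERTIES[j] for j in np.flatnonzero(sigma == 0)]
        raise ValueError(f"zero variance in column(s) {zero}; cannot standardize")
    return StandardizedTable(z=(x - mu) / sigma, mu=mu, sigma=sigma)


def default_standardized_table() -> StandardizedTable:
    return standardize_table(QuantPropertyTable.load())


def _load_qual_table() -> dict[str, np.ndarray]:
    """Map residue -> 10-dim qualitative one-hot vector."""
    rows = _read_csv_rows("qualitative_properties.csv")
    blocks = {
        "hydrophobicity": ("Y", "N"),
        "polarity": ("Y", "N"),
        "charge": ("Negative", "Positive", "N"),
        "aromatic_aliphatic": ("Aromatic", "Aliphatic", "N"),
    }
    table: dict[str, np.ndarray] = {}
    for r in rows:
        vec: list[float] = []
        for prop, cats in blocks.items():
            if r[prop] not in cats:
                raise ValueError(f"{r['amino_acid']}: bad {prop} category {r[prop]!r}")
            vec.extend(1.0 if r[prop] == c else 0.0 for c in cats)
        table[r["amino_acid"]] = np.array(vec)
    if set(table) != set(ALPHABET):
        raise ValueError("qualitative table must cover exactly the 20 amino acids")
    return table


_QUAL_TABLE = _load_qual_table()


@dataclass(frozen=True)
class FeatureScheme:
    """A named per-residue feature layout with its channel labels."""

    name: str

    def __post_init__(self) -> None:
        canonical = SCHEME_ALIASES.get(self.name, self.name)
        if canonical not in SCHEME_DIMS:
            raise ValueError(
                f"unknown scheme {self.name!r}; choose from {sorted(SCHEME_DIMS)}"
            )
        object.__setattr__(self, "name", canonical)

    @property
    def d(self) -> int:
        return SCHEME_DIMS[self.name]

    @property
    def uses_quanc(self) -> bool:
        return self.name in ("quanc", "mix")

    @property
    def uses_qualc(self) -> bool:
        return self.name in ("qualc", "mix")

    @property
    def channel_names(self) -> list[str]:
        if self.name == "embedding":
            return [f"emb_{i}" for i in range(self.d)]
        names = [f"bpf_{aa}" for aa in ALPHABET]
        if self.uses_quanc:
            names += [f"quanc_{p}" for p in QUANT_PROPERTIES]
        if self.uses_qualc:
            names += list(QUALC_CHANNELS)
        return names


def channel_names(scheme: FeatureScheme | str) -> list[str]:
    """Ordered channel labels matching :func:`encode_sequence` column order."""
    if isinstance(scheme, str):
        scheme = FeatureScheme(scheme)
    return scheme.channel_names


def bpf_encode(residue: str) -> np.ndarray:
    """One-hot 20-vector at the residue's alphabetical index."""
    if residue not in _AA_INDEX:
        raise ValueError(f"unknown residue {residue!r}")
    v = np.zeros(20)
    v[_AA_INDEX[residue]] = 1.0
    return v


def qualc_encode(residue: str) -> np.ndarray:
    """10-vector of one-hot categorical property blocks (each sums to 1)."""
    if residue not in _QUAL_TABLE:
        raise ValueError(f"unknown residue {residue!r}")
    return _QUAL_TABLE[residue].copy()


@dataclass(frozen=True)
class EncodedPeptide:
    """Fixed-size Lmax x d matrix encoding one peptide."""

    matrix: np.ndarray
    true_length: int
    scheme: FeatureScheme
    id: str = ""


def _residue_row(residue: str, scheme: FeatureScheme, std: StandardizedTable) -> np.ndarray:
    parts = [bpf_encode(residue)]
    if scheme.uses_quanc:
        parts.append(std.row(residue))
    if scheme.uses_qualc:
        parts.append(qualc_encode(residue))
    return np.concatenate(parts)


def encode_sequence(
    peptide: Peptide,
    scheme: FeatureScheme | str,
    std: StandardizedTable | None = None,
    lmax: int = LMAX,
) -> EncodedPeptide:
    """Encode a validated peptide into an lmax x d matrix, zero-padded.

    The embedding scheme has no fixed encoder (its per-residue vectors are
    trainable network parameters) and is rejected here.
    """
    if isinstance(scheme, str):
        scheme = FeatureScheme(scheme)
    if scheme.name == "embedding":
        raise ValueError(
            "embedding rows are trainable network parameters; "
            "encode with scheme='bpf' and use an embedding model"
        )
    peptide.validate(lmin=LMIN, lmax=lmax)
    std = std or default_standardized_table()
    matrix = np.full((lmax, scheme.d), PAD_VALUE)
    for i, residue in enumerate(peptide.sequence):
        matrix[i] = _residue_row(residue, scheme, std)
    return EncodedPeptide(
        matrix=matrix, true_length=len(peptide), scheme=scheme, id=peptide.id
    )


def encode_dataset(
    dataset: PeptideDataset,
    scheme: FeatureScheme | str,
    std: StandardizedTable | None = None,
    lmax: int = LMAX,
) -> np.ndarray:
    """Stack encodings of a whole dataset into an (N, lmax, d) array."""
    if isinstance(scheme, str):
        scheme = FeatureScheme(scheme)
    std = std or default_standardized_table()
    return np.stack(
        [encode_sequence(p, scheme, std, lmax=lmax).matrix for p in dataset]
    )


def decode_bpf(encoded: EncodedPeptide) -> str:
    """Recover the sequence from the BPF block of the first true_length rows."""
    block = encoded.matrix[: encoded.true_length, :20]
    if not np.all(block.sum(axis=1) == 1):
        raise ValueError("BPF block is not one-hot; cannot decode")
    return "".join(ALPHABET[j] for j in block.argmax(axis=1))
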