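"""Peptide feature encodings: tripeptide composition + PseAAC correlations.

A peptide P = R1 R2 ... RL is represented by a vector of 8,000 + n*lambda
components: the normalized occurrence frequencies f_i of the 8,000 possible
tripeptides, followed by n*lambda sequence-order correlation factors tau_j
computed from n standardized physicochemical property profiles at gaps
1..lambda. With weight factor w the final vector is

    P_u = f_u / (sum_i f_i + w * sum_j tau_j)            u <= 8,000
    P_u = w * tau_{u-8000} / (sum_i f_i + w * sum_j tau_j)   otherwise

so all components sum to one whenever the denominator is positive. A plain
dipeptide-composition encoder (400 features) is provided as a baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peptides import AA_INDEX, AMINO_ACIDS, Peptide

#: All 8,000 tripeptides in lexicographic order over the alphabetical residue order.
TRIPEPTIDES: list[str] = [
    "".join(t) for t in itertools.product(AMINO_ACIDS, repeat=3)
]
TRIPEPTIDE_INDEX = {t: i for i, t in enumerate(TRIPEPTIDES)}
DIPEPTIDES: list[str] = ["".join(t) for t in itertools.product(AMINO_ACIDS, repeat=2)]

N_TRIPEPTIDES = 8000
N_DIPEPTIDES = 400

DEFAULT_PROPERTIES = (
    "hydrophobicity",
    "hydrophilicity",
    "mass",
    "pK1",
    "pK2",
    "pI",
    "rigidity",
    "flexibility",
    "irreplaceability",
)


class EncodingError(ValueError):
    """Raised for invalid encoding configurations or degenerate inputs."""


def standardize_values(raw: np.ndarray) -> np.ndarray:
    """Standard conversion of one 20-value property row.

    Values are centred on the 20-residue mean and divided by the root of
    the *sum* of squared deviations (not the variance), i.e. each
    standardized row has zero mean and unit Euclidean norm. The resulting
    h values are a factor sqrt(20) smaller than z-scores, which keeps the
    correlation-factor sum small enough that the encoding normalizer
    1 + w * sum(tau) stays positive across the whole w tuning grid; a
    z-score convention makes it go non-positive on ordinary 7-mers.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (20,):
        raise EncodingError(f"expected 20 values per property, got {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise EncodingError("property values must be finite")
    centered = raw - raw.mean()
    norm = np.sqrt(np.sum(centered**2))
    if norm == 0:
        raise EncodingError("property is constant across the 20 residues")
    return centered / norm


@dataclass(frozen=True)
class PropertyTable:
    """Physicochemical property scales over the 20 residues.

    ``raw`` and ``standardized`` are (n_properties, 20) arrays with columns
    in alphabetical single-letter residue order. Standardization is the
    zero-mean / unit-norm conversion of :func:`standardize_values`, so any
    affine transform of a raw scale yields identical standardized values
    (up to sign for a negative rescaling).
    """

    names: tuple[str, ...]
    raw: np.ndarray
    standardized: np.ndarray
    sources: tuple[str, ...] = ()
    version: str = "custom"

    @property
    def n_properties(self) -> int:
        return len(self.names)

    @classmethod
    def from_raw(
        cls,
        names: Sequence[str],
        raw: np.ndarray,
        sources: Sequence[str] = (),
        version: str = "custom",
    ) -> "PropertyTable":
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if raw.shape != (len(names), 20):
            raise EncodingError(
                f"raw table must be ({len(names)}, 20), got {raw.shape}"
            )
        std = np.vstack([standardize_values(row) for row in raw])
        return cls(tuple(names), raw, std, tuple(sources), version)

    @classmethod
    def from_tsv(cls, path: str | Path, version: str | None = None) -> "PropertyTable":
        """Load a (property, residue, raw_value, source) TSV."""
        df = pd.read_csv(path, sep="\t")
        names = list(dict.fromkeys(df["property"]))
        raw = np.empty((len(names), 20))
        sources = []
        for k, name in enumerate(names):
            sub = df[df["property"] == name].set_index("residue")
            missing = set(AMINO_ACIDS) - set(sub.index)
            if missing:
                raise EncodingError(f"{name}: missing residues {sorted(missing)}")
            raw[k] = [sub.loc[aa, "raw_value"] for aa in AMINO_ACIDS]
            sources.append(str(sub["source"].iloc[0]) if "source" in sub else "")
        return cls.from_raw(
            names, raw, sources, version or Path(path).stem
        )

    @classmethod
    def default(cls) -> "PropertyTable":
        """The packaged nine-property table (see data/properties.tsv)."""
        ref = resources.files("prtup.data").joinpath("properties.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, version="builtin-9prop-v1")

    def values(self, name: str) -> np.ndarray:
        """Standardized 20-vector for one property."""
        return self.standardized[self.names.index(name)]

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "raw": self.raw.tolist(),
            "sources": list(self.sources),
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PropertyTable":
        return cls.from_raw(d["names"], np.asarray(d["raw"]), d.get("sources", ()), d.get("version", "custom"))


def standardize_properties(
    raw: np.ndarray, names: Sequence[str] = DEFAULT_PROPERTIES, **kw
) -> PropertyTable:
    """Build a PropertyTable from raw values (rows = properties)."""
    return PropertyTable.from_raw(names, raw, **kw)


TRIPEPTIDE_MODE = "tripeptide+pseaac"
DIPEPTIDE_MODE = "dipeptide"


@dataclass(frozen=True)
class EncodingConfig:
    """Encoder parameters: correlation depth lambda, weight w, mode.

    The tuning grid of the method explores 1 <= lambda <= 6 and
    0.05 <= w <= 0.70; other positive values are accepted.
    """

    lam: int = 3
    w: float = 0.15
    mode: str = TRIPEPTIDE_MODE

    def __post_init__(self) -> None:
        if self.mode not in (TRIPEPTIDE_MODE, DIPEPTIDE_MODE):
            raise EncodingError(f"unknown mode {self.mode!r}")
        if self.mode == TRIPEPTIDE_MODE:
            if self.lam < 1:
                raise EncodingError("lambda must be >= 1")
            if self.w < 0:
                raise EncodingError("w must be >= 0")

    def dimension(self, n_properties: int) -> int:
        if self.mode == DIPEPTIDE_MODE:
            return N_DIPEPTIDES
        return N_TRIPEPTIDES + n_properties * self.lam

    def to_dict(self) -> dict:
        return {"lam": self.lam, "w": self.w, "mode": self.mode}

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingConfig":
        return cls(**d)


def _indices(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))


def _kmer_frequencies(seq: str, k: int, n_out: int) -> np.ndarray:
    L = len(seq)
    n_windows = L - k + 1
    if n_windows < 1:
        raise EncodingError(f"sequence length {L} too short for {k}-mer windows")
    idx = _indices(seq)
    out = np.zeros(n_out)
    # lexicographic rank of each window in base 20
    codes = np.zeros(n_windows, dtype=np.intp)
    for j in range(k):
        codes = codes * 20 + idx[j : j + n_windows]
    np.add.at(out, codes, 1.0)
    return out / n_windows


def tripeptide_frequencies(p: Peptide | str) -> np.ndarray:
    """Normalized counts of the L-2 width-3 windows; sums to 1."""
    seq = p.sequence if isinstance(p, Peptide) else p
    if len(seq) < 3:
        raise EncodingError(f"tripeptide composition needs L >= 3, got L = {len(seq)}")
    return _kmer_frequencies(seq, 3, N_TRIPEPTIDES)


def dipeptide_frequencies(p: Peptide | str) -> np.ndarray:
    seq = p.sequence if isinstance(p, Peptide) else p
    if len(seq) < 2:
        raise EncodingError(f"dipeptide composition needs L >= 2, got L = {len(seq)}")
    return _kmer_frequencies(seq, 2, N_DIPEPTIDES)


# Baseline encoder (no PseAAC block).
encode_dipeptide = dipeptide_frequencies


def correlation_factors(
    p: Peptide | str, table: PropertyTable, lam: int
) -> np.ndarray:
    """Sequence-order correlation factors tau_1..tau_{n*lam}.

    Tier-major ordering: the n properties at gap 1 first, then gap 2, up to
    gap lam. tau at gap g for property k is the average over the L-g residue
    pairs (i, i+g) of h_k(R_i) * h_k(R_{i+g}).
    """
    seq = p.sequence if isinstance(p, Peptide) else p
    L = len(seq)
    if L - lam < 1:
        raise EncodingError(
            f"lambda = {lam} requires L - lambda >= 1 but L = {L}"
        )
    idx = _indices(seq)
    H = table.standardized[:, idx]  # (n, L) property profile of the peptide
    taus = np.empty((lam, table.n_properties))
    for g in range(1, lam + 1):
        taus[g - 1] = (H[:, :-g] * H[:, g:]).mean(axis=1)
    return taus.ravel()


def encode(
    p: Peptide | str,
    config: EncodingConfig = EncodingConfig(),
    table: PropertyTable | None = None,
) -> np.ndarray:
    """Encode one peptide into its feature vector.

    In tripeptide+pseaac mode the result has 8,000 + n*lambda components
    that sum to one (the tripeptide frequencies already sum to one, so the
    shared denominator is 1 + w * sum(tau)).
    """
    if config.mode == DIPEPTIDE_MODE:
        return dipeptide_frequencies(p)
    if table is None:
        table = PropertyTable.default()
    f = tripeptide_frequencies(p)
    tau = correlation_factors(p, table, config.lam)
    denom = f.sum() + config.w * tau.sum()
    if denom <= 0:
        raise EncodingError(
            f"non-positive normalizer {denom:.4g} (w = {config.w}, "
            f"sum tau = {tau.sum():.4g})"
        )
    return np.concatenate([f, config.w * tau]) / denom


def feature_names(
    config: EncodingConfig = EncodingConfig(), table: PropertyTable | None = None
) -> list[str]:
    """Column names matching :func:`encode` output order."""
    if config.mode == DIPEPTIDE_MODE:
        return list(DIPEPTIDES)
    if table is None:
        table = PropertyTable.default()
    names = list(TRIPEPTIDES)
    for g in range(1, config.lam + 1):
        for prop in table.names:
            names.append(f"tau_g{g}_p{prop}")
    return names


def encode_dataset(
    peptides: Sequence[Peptide | str],
    config: EncodingConfig = EncodingConfig(),
    table: PropertyTable | None = None,
) -> np.ndarray:
    """Encode many peptides into a dense (n_samples, n_features) matrix."""
    if table is None and config.mode == TRIPEPTIDE_MODE:
        table = PropertyTable.default()
    return np.vstack([encode(p, config, table) for p in peptides])
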