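"""Dinucleotide physicochemical encoding and DFT amplitude features.

Each RNA window S = (s1 … sN) is encoded twice, once per physicochemical
property: every overlapping dinucleotide s_j s_{j+1} is replaced by its
tabulated free-energy or hydrophilicity value, giving a numeric profile of
length N-1. A discrete Fourier transform of the (zero-padded) profile is
taken and the modulus of every coefficient kept, so a set whose longest
window has length N yields 2(N-1) nonnegative features per sequence:
the N-1 free-energy amplitudes followed by the N-1 hydrophilicity
amplitudes. A 21-bp window set thus produces 40 features, a 31-bp set 60.

The amplitude at k = 0 (the DC component) equals |Σ h(n)|, the absolute sum
of the profile; higher k capture periodic composition structure in the
flanks, which differs between Ψ-site windows (U-rich flanks) and non-site
windows (A-rich flanks).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import LabeledSequenceSet, RnaSequence

# Dinucleotide physicochemical constants for RNA: stacking free energy
# (kcal/mol) and hydrophilicity, one value per ordered dinucleotide.
FREE_ENERGY: dict[str, float] = {
    "GG": -3.260, "GA": -2.350, "GC": -3.420, "GU": -2.240,
    "AG": -2.080, "AA": -0.930, "AC": -2.240, "AU": -1.100,
    "CG": -2.360, "CA": -2.110, "CC": -3.260, "CU": -2.080,
    "UG": -2.110, "UA": -1.330, "UC": -2.350, "UU": -0.930,
}

HYDROPHILICITY: dict[str, float] = {
    "GG": 0.170, "GA": 0.100, "GC": 0.260, "GU": 0.270,
    "AG": 0.080, "AA": 0.040, "AC": 0.140, "AU": 0.140,
    "CG": 0.350, "CA": 0.210, "CC": 0.490, "CU": 0.520,
    "UG": 0.340, "UA": 0.210, "UC": 0.480, "UU": 0.440,
}

#: The shipped property table: property name -> {dinucleotide -> value}.
PROPERTY_TABLE: dict[str, dict[str, float]] = {
    "free_energy": FREE_ENERGY,
    "hydrophilicity": HYDROPHILICITY,
}

#: Concatenation order of the per-property feature blocks.
PROPERTY_ORDER: tuple[str, str] = ("free_energy", "hydrophilicity")

_PROPERTY_LABEL = {"free_energy": "FreeEnergy", "hydrophilicity": "Hydrophilicity"}


def validate_property_table(table: Mapping[str, Mapping[str, float]]) -> None:
    """Check that every property maps all 16 dinucleotides to a value."""
    expected = {a + b for a in "ACGU" for b in "ACGU"}
    for prop, mapping in table.items():
        missing = expected - set(mapping)
        extra = set(mapping) - expected
        if missing or extra:
            raise ValueError(
                f"property {prop!r}: missing dinucleotides {sorted(missing)}, "
                f"unexpected keys {sorted(extra)}"
            )


def encode_property(
    seq: RnaSequence | str,
    property_name: str,
    table: Mapping[str, Mapping[str, float]] | None = None,
) -> np.ndarray:
    """Encode a sequence as the numeric profile of one property.

    Returns an array of length N-1 whose j-th entry is the tabulated value
    of the overlapping dinucleotide at positions (j, j+1), left to right.
    """
    table = PROPERTY_TABLE if table is None else table
    if property_name not in table:
        raise KeyError(
            f"unknown property {property_name!r}; available: {sorted(table)}"
        )
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    mapping = table[property_name]
    return np.array(
        [mapping[residues[j : j + 2]] for j in range(len(residues) - 1)], dtype=float
    )


def pad_profile(profile: np.ndarray | Sequence[float], target_length: int) -> np.ndarray:
    """Right-pad a numeric profile with zeros to ``target_length``.

    Padding is applied to the numeric profile, never to the nucleotide
    string: there is no "zero" nucleotide.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("cannot pad an empty profile")
    if target_length < profile.size:
        raise ValueError(
            f"target_length {target_length} < profile length {profile.size}"
        )
    return np.concatenate([profile, np.zeros(target_length - profile.size)])


def dft(profile: np.ndarray | Sequence[float]) -> np.ndarray:
    """Discrete Fourier transform of a numeric profile.

    H(k) = sum_{n=0}^{L-1} h(n) exp(-i 2π k n / L), k = 0 … L-1.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("cannot transform an empty profile")
    return np.fft.fft(profile)


def amplitude_spectrum(spectrum: np.ndarray) -> np.ndarray:
    """Elementwise modulus Z_k = sqrt(x_k² + y_k²) of a complex spectrum."""
    spectrum = np.asarray(spectrum)
    if spectrum.size == 0:
        raise ValueError("empty spectrum")
    return np.abs(spectrum)


def feature_names(profile_length: int) -> list[str]:
    """Column names for a 2·L feature vector, free energy block first."""
    names = []
    for prop in PROPERTY_ORDER:
        label = _PROPERTY_LABEL[prop]
        names.extend(f"{label}_Amp_{k}" for k in range(1, profile_length + 1))
    return names


def sequence_features(
    seq: RnaSequence | str,
    profile_length: int,
    table: Mapping[str, Mapping[str, float]] | None = None,
) -> np.ndarray:
    """The 2·profile_length amplitude features of a single sequence."""
    parts = []
    for prop in PROPERTY_ORDER:
        profile = encode_property(seq, prop, table)
        padded = pad_profile(profile, profile_length)
        parts.append(amplitude_spectrum(dft(padded)))
    return np.concatenate(parts)


def extract_features(
    sset: LabeledSequenceSet,
    table: Mapping[str, Mapping[str, float]] | None = None,
    standardize: bool = False,
) -> pd.DataFrame:
    """Feature matrix for a labeled set: one row per sequence, in set order.

    Columns are ``id``, ``label``, then the 2(max_length-1) named amplitude
    features (free-energy block first, then hydrophilicity). Shorter
    sequences are zero-padded at the profile level before the transform.

    ``standardize=True`` z-scores each feature column (off by default; the
    amplitudes are used raw).
    """
    if len(sset) == 0:
        raise ValueError("cannot extract features from an empty set")
    if table is not None:
        validate_property_table(table)
    length = sset.max_length - 1
    rows = np.stack(
        [sequence_features(seq, length, table) for seq, _ in sset]
    )
    if standardize:
        sd = rows.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        rows = (rows - rows.mean(axis=0)) / sd
    df = pd.DataFrame(rows, columns=feature_names(length))
    df.insert(0, "label", sset.labels)
    df.insert(0, "id", [seq.id for seq, _ in sset])
    return df


def feature_arrays(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, ids) for model fitting."""
    cols = [c for c in features.columns if c not in ("id", "label")]
    X = features[cols].to_numpy(dtype=float)
    y = features["label"].to_numpy(dtype=int)
    return X, y, list(features["id"])


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as TSV, round-trip exact at 17 significant digits."""
    features.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps the 17-significant-digit TSV bit-exact
    return pd.read_csv(path, sep="\t", dtype={"id": str}, float_precision="round_trip")
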