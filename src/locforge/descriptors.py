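"""Classical protein sequence descriptors organized as a named registry.

Seven descriptor families are provided: amino-acid composition (AAC),
dipeptide composition (DPC), sequence autocorrelation (Moreau-Broto /
Moran / Geary), composition-transition-distribution (CTD),
quasi-sequence-order (QSO), and Chou's pseudo amino acid composition in
its plain (PAAC) and amphiphilic (APAAC) variants.

Every descriptor has a stable, human-readable name (``"AAC:A"``,
``"CTD:hydrophobicity:T:12"``, ``"QSO:grantham:tau:3"``), and the full
profile of a protein is the deterministic concatenation of the enabled
families.  The per-residue property scales that parameterize the
autocorrelation, QSO and PAAC families ship as packaged, versioned data
(:mod:`locforge.data`), so descriptor values are reproducible without
any download.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALPHABET",
    "DescriptorConfig",
    "FeatureVector",
    "InvalidSequenceError",
    "sanitize_sequence",
    "load_property_scales",
    "grantham_distance_matrix",
    "physchem_distance_matrix",
    "compute_aac",
    "compute_dpc",
    "compute_autocorrelation",
    "compute_ctd",
    "compute_qso",
    "compute_paac",
    "compute_descriptor_profile",
    "profile_length",
    "feature_table",
]

logger = logging.getLogger(__name__)

#: Canonical one-letter amino-acid alphabet, in alphabetical order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

FAMILIES = ("AAC", "DPC", "AUTOCORR", "CTD", "QSO", "PAAC", "APAAC")

# Three-class residue partitions for the CTD family (Dubchak-style
# attributes).  Each attribute partitions the 20 canonical residues into
# exactly three disjoint classes.
CTD_ATTRIBUTES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

AUTOCORR_METHODS = ("moreau-broto", "moran", "geary")

#: Scales used by the autocorrelation family (in registry order).
DEFAULT_AUTOCORR_SCALES = (
    "kyte_doolittle",
    "hopp_woods",
    "side_chain_mass",
    "grantham_polarity",
    "grantham_volume",
    "isoelectric_point",
)

#: Scales used by PAAC (Chou's classical triple).
PAAC_SCALES = ("chou_hydrophobicity", "hopp_woods", "side_chain_mass")
#: Scales used by the amphiphilic correlation terms of APAAC.
APAAC_SCALES = ("chou_hydrophobicity", "hopp_woods")

QSO_MATRICES = ("grantham", "physchem")


class InvalidSequenceError(ValueError):
    """Raised when a sequence cannot satisfy a descriptor precondition."""


def load_property_scales() -> dict[str, dict[str, float]]:
    """Load the packaged per-residue property scales.

    Returns a mapping ``scale name -> {residue: value}`` covering all 20
    canonical residues for every scale.
    """
    with resources.files("locforge.data").joinpath("aa_scales.json").open() as fh:
        payload = json.load(fh)
    scales = payload["scales"]
    for name, table in scales.items():
        missing = set(ALPHABET) - set(table)
        if missing:
            raise ValueError(f"scale {name!r} missing residues {sorted(missing)}")
    return scales


_SCALES_CACHE: dict[str, dict[str, float]] | None = None


def _scales() -> dict[str, dict[str, float]]:
    global _SCALES_CACHE
    if _SCALES_CACHE is None:
        _SCALES_CACHE = load_property_scales()
    return _SCALES_CACHE


def _scale_array(name: str, scales: Mapping[str, Mapping[str, float]] | None = None) -> np.ndarray:
    table = (scales or _scales())[name]
    return np.array([table[aa] for aa in ALPHABET], dtype=float)


def _standardize(values: np.ndarray) -> np.ndarray:
    # Standardization over the 20 canonical residues with population std,
    # the convention of Chou's pseudo amino acid composition.
    mean = values.mean()
    std = values.std()
    if std == 0:
        return np.zeros_like(values)
    return (values - mean) / std


def grantham_distance_matrix() -> np.ndarray:
    """Grantham's chemical distance between residue pairs.

    Computed from his published formula
    ``D_ij = rho * sqrt(alpha (c_i-c_j)^2 + beta (p_i-p_j)^2 + gamma (v_i-v_j)^2)``
    with alpha=1.833, beta=0.1018, gamma=0.000399 and rho=50.723 applied to
    the packaged composition/polarity/volume scales (unrounded values;
    the printed table rounds to integers, e.g. Leu-Ile -> 5, Arg-Leu -> 102).
    """
    c = _scale_array("grantham_composition")
    p = _scale_array("grantham_polarity")
    v = _scale_array("grantham_volume")
    dc = c[:, None] - c[None, :]
    dp = p[:, None] - p[None, :]
    dv = v[:, None] - v[None, :]
    return 50.723 * np.sqrt(1.833 * dc**2 + 0.1018 * dp**2 + 0.000399 * dv**2)


def physchem_distance_matrix() -> np.ndarray:
    """Euclidean distance between residues in standardized property space.

    This package's own physicochemical distance: residues are embedded by
    their standardized hydrophobicity, hydrophilicity and side-chain mass
    and the matrix is the pairwise Euclidean distance.  It plays the role
    of a second sequence-order coupling matrix alongside Grantham's.
    """
    coords = np.stack(
        [_standardize(_scale_array(n)) for n in PAAC_SCALES], axis=1
    )
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


_MATRIX_BUILDERS = {
    "grantham": grantham_distance_matrix,
    "physchem": physchem_distance_matrix,
}


def sanitize_sequence(sequence: str, *, warn: bool = True) -> str:
    """Uppercase ``sequence`` and drop residues outside the 20-letter alphabet.

    Ambiguity codes (B, J, Z, X), non-canonical residues (O, U) and gap or
    whitespace characters are removed; a warning is logged when anything
    is dropped.
    """
    upper = sequence.upper()
    kept = [ch for ch in upper if ch in _AA_INDEX]
    dropped = len(upper) - len(kept)
    if dropped and warn:
        logger.warning(
            "dropped %d non-canonical residue(s) during sanitization", dropped
        )
    return "".join(kept)


@dataclass(frozen=True)
class DescriptorConfig:
    """Configuration of the descriptor registry.

    Parameters
    ----------
    families:
        Ordered subset of :data:`FAMILIES` to compute.
    autocorr_method:
        One of ``moreau-broto``, ``moran``, ``geary``.
    autocorr_lag_max, qso_lag_max, paac_lambda:
        Maximum sequence-separation of the correlation terms; every
        accepted sequence must be strictly longer than each enabled
        family's maximum lag.
    qso_weight, paac_weight:
        Weight ``w`` of the sequence-order terms relative to composition.
    autocorr_scales:
        Names of packaged property scales used by the autocorrelation
        family.
    """

    families: tuple[str, ...] = FAMILIES
    autocorr_method: str = "moreau-broto"
    autocorr_lag_max: int = 30
    qso_lag_max: int = 30
    qso_weight: float = 0.1
    paac_lambda: int = 30
    paac_weight: float = 0.05
    autocorr_scales: tuple[str, ...] = DEFAULT_AUTOCORR_SCALES

    def __post_init__(self) -> None:
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise ValueError(f"unknown descriptor families: {unknown}")
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate families in config")
        if self.autocorr_method not in AUTOCORR_METHODS:
            raise ValueError(f"unknown autocorrelation method {self.autocorr_method!r}")
        for attr in ("autocorr_lag_max", "qso_lag_max", "paac_lambda"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be positive")
        if self.qso_weight <= 0 or self.paac_weight <= 0:
            raise ValueError("weights must be positive")

    def with_families(self, families: Iterable[str]) -> "DescriptorConfig":
        return replace(self, families=tuple(families))

    @property
    def min_sequence_length(self) -> int:
        """Smallest sequence length accepted by every enabled family."""
        need = 1
        if "DPC" in self.families or "CTD" in self.families:
            need = max(need, 2)
        if "AUTOCORR" in self.families:
            need = max(need, self.autocorr_lag_max + 1)
        if "QSO" in self.families:
            need = max(need, self.qso_lag_max + 1)
        if "PAAC" in self.families or "APAAC" in self.families:
            need = max(need, self.paac_lambda + 1)
        return need


@dataclass
class FeatureVector:
    """An ordered, named real-valued descriptor vector."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor values must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    @staticmethod
    def concat(parts: Sequence["FeatureVector"]) -> "FeatureVector":
        names = list(itertools.chain.from_iterable(p.names for p in parts))
        values = np.concatenate([p.values for p in parts]) if parts else np.empty(0)
        return FeatureVector(names, values)


def _check_sequence(sequence: str, min_len: int, family: str) -> str:
    if not isinstance(sequence, str):
        raise TypeError("sequence must be a string")
    bad = set(sequence) - set(ALPHABET)
    if bad:
        raise InvalidSequenceError(
            f"{family}: sequence contains non-canonical residues {sorted(bad)}; "
            "sanitize it first (sanitize_sequence)"
        )
    if len(sequence) < min_len:
        raise InvalidSequenceError(
            f"{family}: sequence length {len(sequence)} < required minimum {min_len}"
        )
    return sequence


def compute_aac(sequence: str) -> FeatureVector:
    """Amino-acid composition: 20 residue frequencies summing to 1."""
    seq = _check_sequence(sequence, 1, "AAC")
    counts = np.zeros(20)
    for ch in seq:
        counts[_AA_INDEX[ch]] += 1
    return FeatureVector([f"AAC:{aa}" for aa in ALPHABET], counts / len(seq))


def compute_dpc(sequence: str) -> FeatureVector:
    """Dipeptide composition: 400 overlapping-dipeptide frequencies."""
    seq = _check_sequence(sequence, 2, "DPC")
    counts = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        counts[_AA_INDEX[a], _AA_INDEX[b]] += 1
    names = [f"DPC:{a}{b}" for a in ALPHABET for b in ALPHABET]
    return FeatureVector(names, counts.ravel() / (len(seq) - 1))


def _property_series(seq: str, scale: np.ndarray) -> np.ndarray:
    idx = np.fromiter((_AA_INDEX[ch] for ch in seq), dtype=int, count=len(seq))
    return scale[idx]


def compute_autocorrelation(sequence: str, config: DescriptorConfig) -> FeatureVector:
    """Sequence autocorrelation descriptors over the configured scales.

    Property values are standardized over the 20 residues, then one of the
    classical statistics is evaluated for each lag ``d = 1..lag_max``:

    * Moreau-Broto (normalized): ``sum_i p_i p_{i+d} / (L-d)``
    * Moran: lagged autocovariance over sequence variance
    * Geary: half mean squared lagged difference over unbiased variance

    Moran and Geary return 0 for a zero-variance property series.
    """
    lag_max = config.autocorr_lag_max
    seq = _check_sequence(sequence, lag_max + 1, "AUTOCORR")
    method = config.autocorr_method
    names: list[str] = []
    values: list[float] = []
    for scale_name in config.autocorr_scales:
        p = _property_series(seq, _standardize(_scale_array(scale_name)))
        L = len(p)
        pbar = p.mean()
        centered = p - pbar
        var_seq = float((centered**2).sum())
        # constant series leave rounding dust in the variance; treat as zero
        if var_seq <= 1e-12 * L * (pbar**2 + 1.0):
            var_seq = 0.0
        for d in range(1, lag_max + 1):
            head, tail = p[: L - d], p[d:]
            if method == "moreau-broto":
                val = float((head * tail).sum() / (L - d))
            elif method == "moran":
                if var_seq == 0:
                    val = 0.0
                else:
                    num = float((centered[: L - d] * centered[d:]).sum()) / (L - d)
                    val = num / (var_seq / L)
            else:  # geary
                if var_seq == 0:
                    val = 0.0
                else:
                    num = float(((head - tail) ** 2).sum()) / (2 * (L - d))
                    val = num / (var_seq / (L - 1))
            names.append(f"AUTOCORR:{method}:{scale_name}:{d}")
            values.append(val)
    return FeatureVector(names, np.array(values))


def _ctd_classes(attribute: str) -> np.ndarray:
    """Class index (0/1/2) per alphabet position for a CTD attribute."""
    klass = np.empty(20, dtype=int)
    for ci, members in enumerate(CTD_ATTRIBUTES[attribute]):
        for aa in members:
            klass[_AA_INDEX[aa]] = ci
    return klass


def compute_ctd(sequence: str, config: DescriptorConfig | None = None) -> FeatureVector:
    """Composition / Transition / Distribution descriptors.

    For each of the seven physicochemical attributes the residues fall in
    one of three classes; the descriptor block holds the 3 class fractions
    (C), the 3 boundary-crossing fractions of adjacent pairs (T), and the
    relative sequence positions (percent of length) of the first, 25%,
    50%, 75% and last occurrence of each class (D, 15 values).  A class
    absent from the sequence contributes zeros to its D slots.
    """
    seq = _check_sequence(sequence, 2, "CTD")
    L = len(seq)
    idx = np.fromiter((_AA_INDEX[ch] for ch in seq), dtype=int, count=L)
    names: list[str] = []
    values: list[float] = []
    pair_names = ("12", "13", "23")
    for attr in CTD_ATTRIBUTES:
        cls = _ctd_classes(attr)[idx]
        # Composition
        for ci in range(3):
            names.append(f"CTD:{attr}:C:{ci + 1}")
            values.append(float((cls == ci).sum()) / L)
        # Transition
        a, b = cls[:-1], cls[1:]
        for (c1, c2), pname in zip(((0, 1), (0, 2), (1, 2)), pair_names):
            crossings = ((a == c1) & (b == c2)) | ((a == c2) & (b == c1))
            names.append(f"CTD:{attr}:T:{pname}")
            values.append(float(crossings.sum()) / (L - 1))
        # Distribution
        for ci in range(3):
            pos = np.nonzero(cls == ci)[0] + 1  # 1-based
            n = len(pos)
            for q in (0, 25, 50, 75, 100):
                names.append(f"CTD:{attr}:D:{ci + 1}:{q}")
                if n == 0:
                    values.append(0.0)
                else:
                    rank = 1 if q == 0 else math.ceil(q / 100 * n)
                    values.append(100.0 * pos[rank - 1] / L)
    return FeatureVector(names, np.array(values))


def _coupling_sums(seq: str, matrix: np.ndarray, lag_max: int, power: int) -> np.ndarray:
    idx = np.fromiter((_AA_INDEX[ch] for ch in seq), dtype=int, count=len(seq))
    taus = np.empty(lag_max)
    for d in range(1, lag_max + 1):
        pair_d = matrix[idx[:-d], idx[d:]]
        taus[d - 1] = float((pair_d**power).sum())
    return taus


def compute_qso(sequence: str, config: DescriptorConfig) -> FeatureVector:
    """Quasi-sequence-order descriptors.

    For each packaged residue-distance matrix ``D`` the coupling term at
    lag ``d`` is ``tau_d = sum_i D(R_i, R_{i+d})^2``; the descriptor block
    is ``f_r / (1 + w * sum(tau))`` for the 20 residue frequencies plus
    ``w * tau_d / (1 + w * sum(tau))`` for ``d = 1..lag_max``, so each
    block sums to exactly 1 and reduces to AAC as ``w -> 0``.
    """
    seq = _check_sequence(sequence, config.qso_lag_max + 1, "QSO")
    w = config.qso_weight
    freqs = compute_aac(seq).values
    names: list[str] = []
    values: list[float] = []
    for mname in QSO_MATRICES:
        taus = _coupling_sums(seq, _MATRIX_BUILDERS[mname](), config.qso_lag_max, 2)
        denom = 1.0 + w * taus.sum()
        names.extend(f"QSO:{mname}:AAC:{aa}" for aa in ALPHABET)
        values.extend(freqs / denom)
        names.extend(f"QSO:{mname}:tau:{d}" for d in range(1, config.qso_lag_max + 1))
        values.extend(w * taus / denom)
    return FeatureVector(names, np.array(values))


def compute_paac(
    sequence: str, config: DescriptorConfig, amphiphilic: bool = False
) -> FeatureVector:
    """Chou's pseudo amino acid composition (plain or amphiphilic).

    Plain PAAC: the tier-``j`` correlation is the mean over adjacent-tier
    pairs of the mean squared standardized-property difference across the
    hydrophobicity / hydrophilicity / side-chain-mass scales; APAAC keeps
    hydrophobicity and hydrophilicity separate and uses products of
    standardized values instead of squared differences.
    """
    lam = config.paac_lambda
    family = "APAAC" if amphiphilic else "PAAC"
    seq = _check_sequence(sequence, lam + 1, family)
    w = config.paac_weight
    freqs = compute_aac(seq).values
    L = len(seq)
    idx = np.fromiter((_AA_INDEX[ch] for ch in seq), dtype=int, count=L)

    if amphiphilic:
        scales = [_standardize(_scale_array(n)) for n in APAAC_SCALES]
        taus = []  # order: lag-major, scale-minor
        tau_names = []
        for j in range(1, lam + 1):
            for sname, scale in zip(APAAC_SCALES, scales):
                p = scale[idx]
                taus.append(float((p[:-j] * p[j:]).sum()) / (L - j))
                tau_names.append(f"APAAC:tau:{sname}:{j}")
        taus_arr = np.array(taus)
        denom = 1.0 + w * taus_arr.sum()
        names = [f"APAAC:{aa}" for aa in ALPHABET] + tau_names
        values = np.concatenate([freqs / denom, w * taus_arr / denom])
        return FeatureVector(names, values)

    scales = [_standardize(_scale_array(n)) for n in PAAC_SCALES]
    coords = np.stack(scales, axis=1)  # 20 x 3
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        diff = coords[idx[:-j]] - coords[idx[j:]]
        theta[j - 1] = float((diff**2).mean(axis=1).sum()) / (L - j)
    denom = 1.0 + w * theta.sum()
    names = [f"PAAC:{aa}" for aa in ALPHABET] + [
        f"PAAC:theta:{j}" for j in range(1, lam + 1)
    ]
    values = np.concatenate([freqs / denom, w * theta / denom])
    return FeatureVector(names, values)


def _family_lengths(config: DescriptorConfig) -> dict[str, int]:
    return {
        "AAC": 20,
        "DPC": 400,
        "AUTOCORR": len(config.autocorr_scales) * config.autocorr_lag_max,
        "CTD": 21 * len(CTD_ATTRIBUTES),
        "QSO": len(QSO_MATRICES) * (20 + config.qso_lag_max),
        "PAAC": 20 + config.paac_lambda,
        "APAAC": 20 + 2 * config.paac_lambda,
    }


def profile_length(config: DescriptorConfig) -> int:
    """Total descriptor count for ``config`` (a pure function of it)."""
    lengths = _family_lengths(config)
    return sum(lengths[f] for f in config.families)


def compute_descriptor_profile(sequence: str, config: DescriptorConfig) -> FeatureVector:
    """Concatenate all enabled descriptor families in registry order.

    The sequence must already be sanitized (canonical residues only) and
    long enough for every enabled family; violations raise
    :class:`InvalidSequenceError` naming the offending family.
    """
    computers = {
        "AAC": lambda s: compute_aac(s),
        "DPC": lambda s: compute_dpc(s),
        "AUTOCORR": lambda s: compute_autocorrelation(s, config),
        "CTD": lambda s: compute_ctd(s, config),
        "QSO": lambda s: compute_qso(s, config),
        "PAAC": lambda s: compute_paac(s, config, amphiphilic=False),
        "APAAC": lambda s: compute_paac(s, config, amphiphilic=True),
    }
    parts = [computers[family](sequence) for family in config.families]
    return FeatureVector.concat(parts)


def feature_table(
    sequences: Mapping[str, str], config: DescriptorConfig | None = None
) -> pd.DataFrame:
    """Descriptor profiles for many proteins as a proteins x descriptors table."""
    config = config or DescriptorConfig()
    rows = {}
    for pid, seq in sequences.items():
        fv = compute_descriptor_profile(seq, config)
        rows[pid] = fv.values
        names = fv.names
    if not rows:
        raise InvalidSequenceError("no sequences supplied")
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)
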