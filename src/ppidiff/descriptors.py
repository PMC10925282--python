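"""Physicochemical descriptor families computed from primary sequence.

Implements the descriptor inventory used for sequence-only PPI prediction:

* **AAC** — amino-acid composition (20 features).
* **DPC** — dipeptide composition: the 400 overlapping-dipeptide
  frequencies, each count divided by ``N - 1``.
* **MoranAuto** — Moran's autocorrelation of a per-residue property at lags
  ``d = 1..max_lag``, normalized by the property's sequence variance.
* **PAAC / APAAC** — (amphiphilic) pseudo amino-acid composition following
  the standard published definitions, with sequence-order correlation terms
  over hydrophobicity/hydrophilicity/side-chain-mass tables.
* **CTD** — composition, transition and distribution over three-class
  physicochemical alphabets (hydrophobicity, van der Waals volume,
  polarity, polarizability, charge, secondary structure and solvent
  accessibility).

Property scales ship as TSV resources under ``ppidiff/data/scales`` and are
standardized to zero mean / unit standard deviation over the 20 letters
before autocorrelation (Moran's statistic is invariant to affine rescaling
of the scale, so this is a convention, not a modelling choice).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .seq_io import STANDARD_AA, ProteinRecord

logger = logging.getLogger(__name__)

ALL_FAMILIES = ("AAC", "DPC", "MoranAuto", "PAAC", "APAAC", "CTD")

#: Dipeptide names in fixed (row-major) order: AA, AC, ..., YY.
DIPEPTIDES = tuple(a + b for a in STANDARD_AA for b in STANDARD_AA)
_DIPEPTIDE_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}
_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}


class DescriptorError(ValueError):
    """A sequence fails a descriptor family's length or alphabet contract."""


# ---------------------------------------------------------------------------
# Property scales
# ---------------------------------------------------------------------------

_SCALE_FILES = {
    "Mutability": "mutability.tsv",
    "Steric": "steric.tsv",
    "Hydrophobicity": "hydrophobicity.tsv",
    "Polarizability": "polarizability.tsv",
    "FreeEnergy": "free_energy.tsv",
    "ResidueASA": "residue_asa.tsv",
    "ResidueVol": "residue_volume.tsv",
    "Polarity": "polarity.tsv",
    # tables used only by PAAC/APAAC
    "PAACHydrophobicity": "paac_hydrophobicity.tsv",
    "PAACHydrophilicity": "paac_hydrophilicity.tsv",
    "SideChainMass": "sidechain_mass.tsv",
}

#: Scales offered for Moran autocorrelation (the PAAC tables are internal).
MORAN_SCALES = (
    "Mutability",
    "Steric",
    "Hydrophobicity",
    "Polarizability",
    "FreeEnergy",
    "ResidueASA",
    "ResidueVol",
    "Polarity",
)


@dataclass(frozen=True)
class PropertyScale:
    """A named mapping from each of the 20 standard letters to a real value."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise DescriptorError(
                f"scale {self.name!r}: needs exactly one value per standard "
                f"amino acid"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise DescriptorError(f"scale {self.name!r}: non-finite values")

    def as_array(self) -> np.ndarray:
        """Values ordered by :data:`STANDARD_AA`."""
        return np.array([self.values[a] for a in STANDARD_AA], dtype=float)

    def standardized(self) -> "PropertyScale":
        """Zero-mean / unit-sd version over the 20 letters (population sd)."""
        arr = self.as_array()
        sd = arr.std()
        if sd == 0:
            raise DescriptorError(f"scale {self.name!r} is constant")
        arr = (arr - arr.mean()) / sd
        return PropertyScale(self.name, dict(zip(STANDARD_AA, arr)))


def load_scale(name: str) -> PropertyScale:
    """Load a bundled property scale by name (see :data:`MORAN_SCALES`)."""
    try:
        fname = _SCALE_FILES[name]
    except KeyError:
        raise DescriptorError(
            f"unknown property scale {name!r}; available: {sorted(_SCALE_FILES)}"
        ) from None
    values: dict[str, float] = {}
    text = (
        resources.files("ppidiff.data.scales").joinpath(fname).read_text("utf-8")
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        letter, value = line.split("\t")
        values[letter] = float(value)
    return PropertyScale(name, values)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorConfig:
    """Which descriptor families to compute and their parameters.

    Parameters
    ----------
    families
        Subset of :data:`ALL_FAMILIES`, kept in canonical order.
    moran_scales
        Property scales for Moran autocorrelation (default: all eight
        bundled scales).
    moran_max_lag
        Largest lag ``d``; sequences must be strictly longer than this.
    paac_lambda
        Number of sequence-order correlation tiers for PAAC/APAAC.
    paac_weight
        Weight ``w`` of the correlation terms in PAAC/APAAC.
    """

    families: tuple[str, ...] = ALL_FAMILIES
    moran_scales: tuple[str, ...] = MORAN_SCALES
    moran_max_lag: int = 30
    paac_lambda: int = 10
    paac_weight: float = 0.05

    def __post_init__(self) -> None:
        bad = set(self.families) - set(ALL_FAMILIES)
        if bad:
            raise DescriptorError(f"unknown descriptor families: {sorted(bad)}")
        # canonical family order, independent of the order given
        object.__setattr__(
            self,
            "families",
            tuple(f for f in ALL_FAMILIES if f in set(self.families)),
        )
        object.__setattr__(self, "moran_scales", tuple(self.moran_scales))
        if self.moran_max_lag < 1:
            raise DescriptorError("moran_max_lag must be >= 1")
        if self.paac_lambda < 0:
            raise DescriptorError("paac_lambda must be >= 0")
        if self.paac_weight <= 0:
            raise DescriptorError("paac_weight must be > 0")
        for s in self.moran_scales:
            if s not in MORAN_SCALES:
                raise DescriptorError(f"unknown Moran scale {s!r}")

    @property
    def schema_id(self) -> str:
        """Stable digest identifying the feature schema this config produces."""
        payload = json.dumps(
            {
                "families": self.families,
                "moran_scales": self.moran_scales,
                "moran_max_lag": self.moran_max_lag,
                "paac_lambda": self.paac_lambda,
                "paac_weight": self.paac_weight,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def min_length(self) -> int:
        """Smallest sequence length every enabled family accepts."""
        n = 1
        if "DPC" in self.families or "CTD" in self.families:
            n = max(n, 2)
        if "MoranAuto" in self.families:
            n = max(n, self.moran_max_lag + 1)
        if "PAAC" in self.families or "APAAC" in self.families:
            n = max(n, self.paac_lambda + 1)
        return n


@dataclass(frozen=True)
class DescriptorVector:
    """Named, ordered feature values for one protein under one schema."""

    protein_id: str
    features: Mapping[str, float]
    schema_id: str

    def names(self) -> tuple[str, ...]:
        return tuple(self.features)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.features.values()), dtype=float)


# ---------------------------------------------------------------------------
# Individual families
# ---------------------------------------------------------------------------

def _codes(record: ProteinRecord) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in record.sequence], dtype=np.intp)
    except KeyError as exc:
        raise DescriptorError(
            f"protein {record.id!r}: non-standard residue {exc.args[0]!r}; "
            f"run filter_natural first"
        ) from exc


def compute_aac(record: ProteinRecord) -> dict[str, float]:
    """Amino-acid composition: ``count(a) / N`` for each standard letter."""
    codes = _codes(record)
    counts = np.bincount(codes, minlength=20)
    frac = counts / len(codes)
    return {f"AAC_{a}": float(frac[i]) for i, a in enumerate(STANDARD_AA)}


def compute_dpc(record: ProteinRecord) -> dict[str, float]:
    """Dipeptide composition: each overlapping-dipeptide count over ``N - 1``.

    The 400 components lie in [0, 1] and sum to 1 for any sequence with at
    least one dipeptide.
    """
    codes = _codes(record)
    n = len(codes)
    if n < 2:
        raise DescriptorError(
            f"protein {record.id!r}: length {n} < 2, no dipeptides"
        )
    pair_codes = codes[:-1] * 20 + codes[1:]
    counts = np.bincount(pair_codes, minlength=400)
    frac = counts / (n - 1)
    return {f"DPC_{dp}": float(frac[i]) for i, dp in enumerate(DIPEPTIDES)}


def compute_moran(record: ProteinRecord, scale: PropertyScale, d: int) -> float:
    """Moran's autocorrelation of a property at lag *d*.

    ``Moran(d) = [ (1/(N-d)) sum_{i<=N-d} (M_i - Mbar)(M_{i+d} - Mbar) ]
    / [ (1/N) sum_i (M_i - Mbar)^2 ]`` where ``Mbar`` is the sequence mean
    of the property.  A constant property (zero variance) returns 0, the
    no-autocorrelation neutral value.
    """
    n = len(record)
    if not 1 <= d <= n - 1:
        raise DescriptorError(
            f"protein {record.id!r}: lag {d} out of range for length {n}"
        )
    m = scale.as_array()[_codes(record)]
    if np.ptp(m) == 0.0:  # constant property along the sequence
        return 0.0
    centred = m - m.mean()
    denom = float(centred @ centred) / n
    num = float(centred[:-d] @ centred[d:]) / (n - d)
    return num / denom


def compute_moran_profile(
    record: ProteinRecord, config: DescriptorConfig
) -> dict[str, float]:
    """Moran autocorrelation at every (scale, lag) in the config.

    Feature names follow the ``MoranAuto_<Scale><lag>`` convention, e.g.
    ``MoranAuto_Mutability27``.  Scales are standardized over the 20
    letters before use.
    """
    n = len(record)
    if n <= config.moran_max_lag:
        raise DescriptorError(
            f"protein {record.id!r}: length {n} <= max lag "
            f"{config.moran_max_lag}"
        )
    out: dict[str, float] = {}
    codes = _codes(record)
    for scale_name in config.moran_scales:
        m = load_scale(scale_name).standardized().as_array()[codes]
        constant = np.ptp(m) == 0.0
        centred = m - m.mean()
        denom = float(centred @ centred) / n
        for d in range(1, config.moran_max_lag + 1):
            if constant:
                val = 0.0
            else:
                val = (float(centred[:-d] @ centred[d:]) / (n - d)) / denom
            out[f"MoranAuto_{scale_name}{d}"] = val
    return out


def _paac_theta(
    codes: np.ndarray, tables: Sequence[np.ndarray], lam: int
) -> np.ndarray:
    """Squared-difference correlation tiers theta_1..theta_lambda."""
    theta = np.empty(lam)
    per_residue = np.stack([t[codes] for t in tables])  # (n_props, N)
    for d in range(1, lam + 1):
        diff = per_residue[:, :-d] - per_residue[:, d:]
        theta[d - 1] = float(np.mean(diff**2, axis=0).mean())
    return theta


def compute_paac(
    record: ProteinRecord, config: DescriptorConfig
) -> dict[str, float]:
    """Pseudo amino-acid composition (standard definition).

    The first 20 components are composition-like; the last ``paac_lambda``
    are sequence-order correlation terms built from standardized
    hydrophobicity, hydrophilicity and side-chain-mass tables.  All
    components are non-negative and sum to 1.
    """
    lam, w = config.paac_lambda, config.paac_weight
    n = len(record)
    if n <= lam:
        raise DescriptorError(
            f"protein {record.id!r}: length {n} <= paac_lambda {lam}"
        )
    codes = _codes(record)
    freqs = np.bincount(codes, minlength=20) / n
    if lam == 0:
        vals = freqs
    else:
        tables = [
            load_scale(s).standardized().as_array()
            for s in ("PAACHydrophobicity", "PAACHydrophilicity", "SideChainMass")
        ]
        theta = _paac_theta(codes, tables, lam)
        denom = 1.0 + w * theta.sum()
        vals = np.concatenate([freqs / denom, w * theta / denom])
    return {f"PAAC{k + 1}": float(v) for k, v in enumerate(vals)}


def compute_apaac(
    record: ProteinRecord, config: DescriptorConfig
) -> dict[str, float]:
    """Amphiphilic pseudo amino-acid composition (standard definition).

    As PAAC but with two correlation tracks per lag — a hydrophobicity and
    a hydrophilicity product term — for ``20 + 2*paac_lambda`` components
    that sum to 1 (the product terms may be negative).
    """
    lam, w = config.paac_lambda, config.paac_weight
    n = len(record)
    if n <= lam:
        raise DescriptorError(
            f"protein {record.id!r}: length {n} <= paac_lambda {lam}"
        )
    codes = _codes(record)
    freqs = np.bincount(codes, minlength=20) / n
    if lam == 0:
        vals = freqs
    else:
        h1 = load_scale("PAACHydrophobicity").standardized().as_array()[codes]
        h2 = load_scale("PAACHydrophilicity").standardized().as_array()[codes]
        tau = np.empty(2 * lam)
        for d in range(1, lam + 1):
            tau[2 * d - 2] = float(h1[:-d] @ h1[d:]) / (n - d)
            tau[2 * d - 1] = float(h2[:-d] @ h2[d:]) / (n - d)
        denom = 1.0 + w * tau.sum()
        vals = np.concatenate([freqs / denom, w * tau / denom])
    return {f"APAAC{k + 1}": float(v) for k, v in enumerate(vals)}


# three-class alphabets for composition/transition/distribution
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "Hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "NormalizedVDWV": ("GASCTPD", "NVEQIL", "MHKFRYW"),
    "Polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "Polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "Charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "SecondaryStr": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "SolventAccessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

_CTD_CLASS_MAPS = {
    prop: {a: c for c, letters in enumerate(classes, start=1) for a in letters}
    for prop, classes in CTD_PROPERTIES.items()
}


def compute_ctd(record: ProteinRecord) -> dict[str, float]:
    """Composition, transition and distribution descriptors.

    For each property the residues are mapped to 3 classes; composition is
    the class fractions (sum to 1), transition the fraction of adjacent
    pairs joining two different classes (one value per unordered class
    pair), and distribution the relative sequence positions (in % of N) of
    the first, 25%, 50%, 75% and last occurrence of each class (0 when the
    class is absent).
    """
    n = len(record)
    if n < 2:
        raise DescriptorError(
            f"protein {record.id!r}: length {n} < 2, no transitions"
        )
    out: dict[str, float] = {}
    for prop, class_map in _CTD_CLASS_MAPS.items():
        cls = np.array([class_map[a] for a in record.sequence], dtype=np.intp)
        # composition
        for c in (1, 2, 3):
            out[f"CTD_{prop}_C_{c}"] = float(np.mean(cls == c))
        # transition
        a, b = cls[:-1], cls[1:]
        for c1, c2 in ((1, 2), (1, 3), (2, 3)):
            crossings = np.sum(((a == c1) & (b == c2)) | ((a == c2) & (b == c1)))
            out[f"CTD_{prop}_T_{c1}{c2}"] = float(crossings / (n - 1))
        # distribution
        for c in (1, 2, 3):
            positions = np.flatnonzero(cls == c) + 1  # 1-based
            for pct in (1, 25, 50, 75, 100):
                name = f"CTD_{prop}_D_{c}_{pct}"
                if positions.size == 0:
                    out[name] = 0.0
                    continue
                k = max(1, math.ceil(pct / 100 * positions.size))
                out[name] = float(positions[k - 1] / n * 100.0)
    return out


# ---------------------------------------------------------------------------
# Full schema
# ---------------------------------------------------------------------------

_FAMILY_FUNCS = {
    "AAC": lambda rec, cfg: compute_aac(rec),
    "DPC": lambda rec, cfg: compute_dpc(rec),
    "MoranAuto": compute_moran_profile,
    "PAAC": compute_paac,
    "APAAC": compute_apaac,
    "CTD": lambda rec, cfg: compute_ctd(rec),
}


def compute_all(
    record: ProteinRecord, config: DescriptorConfig | None = None
) -> DescriptorVector:
    """Concatenate every enabled family in canonical order for one protein.

    The feature-name list depends only on the config, so every protein
    computed under the same schema has identical feature names and order.
    """
    config = config or DescriptorConfig()
    features: dict[str, float] = {}
    for family in config.families:
        features.update(_FAMILY_FUNCS[family](record, config))
    return DescriptorVector(record.id, features, config.schema_id)


def feature_names(config: DescriptorConfig | None = None) -> list[str]:
    """Feature names a config produces, without touching any sequence."""
    config = config or DescriptorConfig()
    probe = ProteinRecord("__probe__", STANDARD_AA * 3)  # length 60 > defaults
    if len(probe) < config.min_length():
        probe = ProteinRecord(
            "__probe__", (STANDARD_AA * (config.min_length() // 20 + 1))
        )
    return list(compute_all(probe, config).features)


def compute_matrix(
    records: Iterable[ProteinRecord], config: DescriptorConfig | None = None
) -> pd.DataFrame:
    """Descriptor matrix for a protein collection (rows indexed by id).

    Proteins failing any enabled family's length precondition are excluded
    with a logged reason rather than zero-padded.
    """
    config = config or DescriptorConfig()
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        try:
            rows[rec.id] = dict(compute_all(rec, config).features)
        except DescriptorError as exc:
            logger.warning("excluding protein from feature matrix: %s", exc)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a feature matrix as TSV (first column ``id``), full precision."""
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col="id")


class DescriptorTransformer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer from protein records to descriptor features.

    Parameters mirror :class:`DescriptorConfig`.  ``transform`` accepts an
    iterable of :class:`ProteinRecord` and returns a DataFrame indexed by
    protein id; the fitted attribute ``feature_names_`` records the schema.
    """

    def __init__(
        self,
        families: tuple[str, ...] = ALL_FAMILIES,
        moran_scales: tuple[str, ...] = MORAN_SCALES,
        moran_max_lag: int = 30,
        paac_lambda: int = 10,
        paac_weight: float = 0.05,
    ):
        self.families = families
        self.moran_scales = moran_scales
        self.moran_max_lag = moran_max_lag
        self.paac_lambda = paac_lambda
        self.paac_weight = paac_weight

    def _config(self) -> DescriptorConfig:
        return DescriptorConfig(
            families=tuple(self.families),
            moran_scales=tuple(self.moran_scales),
            moran_max_lag=self.moran_max_lag,
            paac_lambda=self.paac_lambda,
            paac_weight=self.paac_weight,
        )

    def fit(self, X: Iterable[ProteinRecord], y=None) -> "DescriptorTransformer":
        config = self._config()
        self.config_ = config
        self.feature_names_ = feature_names(config)
        return self

    def transform(self, X: Iterable[ProteinRecord]) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit(X)
        return compute_matrix(X, self.config_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
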