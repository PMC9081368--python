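"""Mixed protein-sequence descriptors.

Implements the five descriptor families whose concatenation forms the mixed
feature vector used for MHC classification:

* **188D** (SVMProt-style): 20 amino-acid frequencies plus, for each of 8
  three-class physicochemical partitions, 21 composition/transition/
  distribution (CTD) values — 20 + 8 x 21 = 188 features.
* **APAAC** (amphiphilic pseudo amino-acid composition): AAC plus 2*lambda
  hydrophobicity/hydrophilicity sequence-order correlation factors, jointly
  normalized so the vector sums to 1.
* **KSCTriad**: conjoint-triad class triples (7^3 cells) with members
  separated by exactly k residues, one min-max-normalized block per
  k in 0..k_max.
* **CKSAAGP**: frequencies of ordered side-chain-group pairs (5 x 5 cells)
  separated by exactly k residues, one block per k.
* **PAAC** (type-1 pseudo amino-acid composition): AAC plus lambda
  correlation factors built from averaged squared differences of three
  standardized residue scales.

The ungrouped **CKSAAP** (20 x 20 pairs) base encoder is also provided.

All encoders are defined only over the 20 standard residues; sequences
shorter than an encoder's order parameter are rejected, never zero-padded.
Feature names follow the stable ``block.subblock.item`` schema and are part
of the trained-model contract.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import DataError, EncodingError
from .seqio import ALPHABET, LabeledDataset, ProteinSequence

# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------

#: Quantile levels of the CTD distribution descriptor.
_DIST_POINTS = ("first", "p25", "p50", "p75", "p100")


@dataclass(frozen=True)
class PropertyTables:
    """Fixed lookup tables backing the descriptors.

    ``ctd_partitions`` maps 8 property names to per-residue class indices
    (1..3); ``sidechain_groups`` maps 5 group names to residue sets;
    ``triad_classes`` maps each residue to its conjoint-triad class (1..7);
    ``scales`` holds hydrophobicity / hydrophilicity / side-chain-mass
    values standardized to mean 0 and unit population SD over the 20
    residues.
    """

    ctd_partitions: dict[str, dict[str, int]]
    sidechain_groups: dict[str, frozenset[str]]
    triad_classes: dict[str, int]
    scales: dict[str, dict[str, float]]

    @property
    def ctd_property_names(self) -> tuple[str, ...]:
        return tuple(self.ctd_partitions)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.sidechain_groups)

    def group_of(self) -> dict[str, str]:
        return {r: g for g, rs in self.sidechain_groups.items() for r in rs}


def _standardize(values: dict[str, float]) -> dict[str, float]:
    arr = np.array([values[a] for a in ALPHABET])
    mu, sd = arr.mean(), arr.std()  # population SD, as in Chou's formulation
    return {a: float((values[a] - mu) / sd) for a in ALPHABET}


def _check_partition(name: str, groups: list[str]) -> None:
    joined = "".join(groups)
    if sorted(joined) != sorted(ALPHABET):
        raise DataError(f"partition {name!r} does not cover the alphabet exactly once")


def load_property_tables() -> PropertyTables:
    """Load and validate the packaged plain-text property tables."""
    text = (
        resources.files("mhcvote").joinpath("data/property_tables.txt").read_text()
    )
    partitions: dict[str, dict[str, int]] = {}
    groups: dict[str, frozenset[str]] = {}
    triads: dict[str, int] = {}
    scales: dict[str, dict[str, float]] = {}
    triad_groups: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        section, key, value = line.split("\t")
        if section == "ctd_partition":
            cls_groups = value.split("|")
            if len(cls_groups) != 3:
                raise DataError(f"partition {key!r}: expected 3 classes")
            _check_partition(key, cls_groups)
            partitions[key] = {
                r: i + 1 for i, grp in enumerate(cls_groups) for r in grp
            }
        elif section == "sidechain_group":
            groups[key] = frozenset(value)
        elif section == "triad_class":
            triad_groups.append(value)
            triads.update({r: int(key) for r in value})
        elif section == "scale":
            raw = dict(p.split(":") for p in value.split(","))
            scales[key] = _standardize({a: float(raw[a]) for a in ALPHABET})
        else:
            raise DataError(f"unknown section {section!r} in property tables")
    if len(partitions) != 8:
        raise DataError(f"expected 8 CTD partitions, found {len(partitions)}")
    _check_partition("sidechain_groups", ["".join(sorted(g)) for g in groups.values()])
    _check_partition("triad_classes", triad_groups)
    return PropertyTables(
        ctd_partitions=partitions,
        sidechain_groups=groups,
        triad_classes=triads,
        scales=scales,
    )


_DEFAULT_TABLES: PropertyTables | None = None


def default_tables() -> PropertyTables:
    """Shared, lazily-loaded instance of the packaged tables."""
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_property_tables()
    return _DEFAULT_TABLES


# ---------------------------------------------------------------------------
# Encoder configuration and the feature-vector container
# ---------------------------------------------------------------------------

#: The fixed concatenation order of the mixed feature.
BLOCK_ORDER = ("d188", "apaac", "ksctriad", "cksaagp", "paac")


@dataclass(frozen=True)
class EncoderConfig:
    """Parameters of the mixed encoder.

    lambda_apaac, lambda_paac
        Maximum correlation rank of the pseudo-composition blocks
        (default 30, Chou's canonical value).
    weight_apaac, weight_paac
        Weight of the correlation factors relative to composition
        (default 0.05).
    kmax_ksctriad, kmax_cksaagp
        Largest residue spacing of the triad / group-pair blocks
        (defaults 0 and 5).
    enabled
        Ordered subset of blocks to concatenate; order is always the
        canonical ``BLOCK_ORDER``.
    """

    lambda_apaac: int = 30
    weight_apaac: float = 0.05
    lambda_paac: int = 30
    weight_paac: float = 0.05
    kmax_ksctriad: int = 0
    kmax_cksaagp: int = 5
    enabled: tuple[str, ...] = BLOCK_ORDER

    def __post_init__(self) -> None:
        if self.lambda_apaac < 1 or self.lambda_paac < 1:
            raise ValueError("lambda parameters must be >= 1")
        for w in (self.weight_apaac, self.weight_paac):
            if not 0 < w < 1:
                raise ValueError(f"weight must be in (0,1), got {w}")
        if self.kmax_ksctriad < 0 or self.kmax_cksaagp < 0:
            raise ValueError("k_max parameters must be >= 0")
        unknown = set(self.enabled) - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown blocks {sorted(unknown)}")
        if not self.enabled:
            raise ValueError("at least one block must be enabled")
        # canonicalize order
        object.__setattr__(
            self, "enabled", tuple(b for b in BLOCK_ORDER if b in self.enabled)
        )

    @property
    def block_dims(self) -> dict[str, int]:
        return {
            "d188": 188,
            "apaac": 20 + 2 * self.lambda_apaac,
            "ksctriad": 343 * (self.kmax_ksctriad + 1),
            "cksaagp": 25 * (self.kmax_cksaagp + 1),
            "paac": 20 + self.lambda_paac,
        }

    @property
    def dimension(self) -> int:
        dims = self.block_dims
        return sum(dims[b] for b in self.enabled)

    @property
    def min_length(self) -> int:
        """Smallest sequence length encodable under the enabled blocks."""
        reqs = {
            "d188": 1,
            "apaac": self.lambda_apaac + 1,
            "ksctriad": 2 * self.kmax_ksctriad + 3,
            "cksaagp": self.kmax_cksaagp + 2,
            "paac": self.lambda_paac + 1,
        }
        return max(reqs[b] for b in self.enabled)

    def to_dict(self) -> dict:
        return {
            "lambda_apaac": self.lambda_apaac,
            "weight_apaac": self.weight_apaac,
            "lambda_paac": self.lambda_paac,
            "weight_paac": self.weight_paac,
            "kmax_ksctriad": self.kmax_ksctriad,
            "kmax_cksaagp": self.kmax_cksaagp,
            "enabled": list(self.enabled),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        if "enabled" in d:
            d["enabled"] = tuple(d["enabled"])
        return cls(**d)


@dataclass
class FeatureVector:
    """Ordered real feature values with stable, named labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.labels):
            raise ValueError("values and labels must be 1-D and aligned")
        if not np.all(np.isfinite(self.values)):
            raise EncodingError("non-finite feature values")

    def __len__(self) -> int:
        return len(self.values)


def _require_length(seq: ProteinSequence, minimum: int, encoder: str) -> None:
    if len(seq) < minimum:
        raise EncodingError(
            f"{encoder}: sequence {seq.id!r} has length {len(seq)}, "
            f"minimum {minimum} required"
        )


# ---------------------------------------------------------------------------
# 188D (AAC + CTD over 8 physicochemical partitions)
# ---------------------------------------------------------------------------

def _ctd_property(seq: str, classes: dict[str, int]) -> list[float]:
    """21 CTD values for one three-class property partition.

    Composition (3): fraction of residues in each class.
    Transition (3): adjacent pairs crossing each unordered class pair,
    divided by L-1 (0 when L == 1).
    Distribution (15): for each class, positions of the 1st and the 25%,
    50%, 75% and 100% occurrences, as percent of L (1-based positions;
    quantile occurrence index = max(1, ceil(q*n))); all 0 for an absent
    class.
    """
    L = len(seq)
    cls = [classes[r] for r in seq]
    comp = [cls.count(c) / L for c in (1, 2, 3)]
    trans = []
    for a, b in ((1, 2), (1, 3), (2, 3)):
        n = sum(
            1
            for i in range(L - 1)
            if {cls[i], cls[i + 1]} == {a, b}
        )
        trans.append(n / (L - 1) if L > 1 else 0.0)
    dist = []
    for c in (1, 2, 3):
        positions = [i + 1 for i, x in enumerate(cls) if x == c]
        if not positions:
            dist.extend([0.0] * 5)
            continue
        n = len(positions)
        occ = [1, max(1, math.ceil(0.25 * n)), max(1, math.ceil(0.5 * n)),
               max(1, math.ceil(0.75 * n)), n]
        dist.extend(positions[o - 1] / L * 100.0 for o in occ)
    return comp + trans + dist


def encode_188d(
    seq: ProteinSequence, tables: PropertyTables | None = None
) -> FeatureVector:
    """SVMProt-style 188-dimensional descriptor: 20 AAC + 8 x 21 CTD values."""
    tables = tables or default_tables()
    _require_length(seq, 1, "d188")
    L = len(seq)
    values = [seq.residues.count(a) / L for a in ALPHABET]
    labels = [f"d188.AAC.{a}" for a in ALPHABET]
    for prop in tables.ctd_property_names:
        values.extend(_ctd_property(seq.residues, tables.ctd_partitions[prop]))
        labels.extend(f"d188.{prop}.C{c}" for c in (1, 2, 3))
        labels.extend(f"d188.{prop}.T{a}{b}" for a, b in ((1, 2), (1, 3), (2, 3)))
        labels.extend(
            f"d188.{prop}.D{c}.{q}" for c in (1, 2, 3) for q in _DIST_POINTS
        )
    return FeatureVector(np.array(values), labels)


# ---------------------------------------------------------------------------
# APAAC / PAAC (pseudo amino-acid composition)
# ---------------------------------------------------------------------------

def encode_apaac(
    seq: ProteinSequence,
    lam: int = 30,
    w: float = 0.05,
    tables: PropertyTables | None = None,
) -> FeatureVector:
    """Amphiphilic pseudo amino-acid composition, dimension 20 + 2*lambda.

    The 2*lambda correlation factors are
    ``tau_{2j-1} = mean_i H1(R_i) H1(R_{i+j})`` and ``tau_{2j}`` the same
    with the hydrophilicity scale H2; the full vector is normalized by
    ``sum(f) + w * sum(tau)`` so that it sums to 1.
    """
    tables = tables or default_tables()
    _require_length(seq, lam + 1, "apaac")
    h1 = tables.scales["hydrophobicity"]
    h2 = tables.scales["hydrophilicity"]
    L = len(seq)
    s1 = np.array([h1[r] for r in seq.residues])
    s2 = np.array([h2[r] for r in seq.residues])
    taus: list[float] = []
    for j in range(1, lam + 1):
        taus.append(float(np.mean(s1[:-j] * s1[j:])))
        taus.append(float(np.mean(s2[:-j] * s2[j:])))
    freqs = np.array([seq.residues.count(a) / L for a in ALPHABET])
    denom = freqs.sum() + w * sum(taus)
    if denom <= 0:
        raise EncodingError(
            f"apaac: non-positive normalizer for sequence {seq.id!r}; "
            "reduce lambda or the weight"
        )
    values = np.concatenate([freqs / denom, w * np.array(taus) / denom])
    labels = [f"apaac.AAC.{a}" for a in ALPHABET] + [
        f"apaac.tau.{j}" for j in range(1, 2 * lam + 1)
    ]
    return FeatureVector(values, labels)


def encode_paac(
    seq: ProteinSequence,
    lam: int = 30,
    w: float = 0.05,
    tables: PropertyTables | None = None,
) -> FeatureVector:
    """Type-1 pseudo amino-acid composition, dimension 20 + lambda.

    ``theta_j`` averages, over all residue pairs at distance j, the mean
    squared difference of the three standardized scales (hydrophobicity,
    hydrophilicity, side-chain mass).
    """
    tables = tables or default_tables()
    _require_length(seq, lam + 1, "paac")
    L = len(seq)
    scales = [
        np.array([tables.scales[name][r] for r in seq.residues])
        for name in ("hydrophobicity", "hydrophilicity", "sidechain_mass")
    ]
    thetas: list[float] = []
    for j in range(1, lam + 1):
        diff_sq = sum((s[j:] - s[:-j]) ** 2 for s in scales) / 3.0
        thetas.append(float(np.mean(diff_sq)))
    freqs = np.array([seq.residues.count(a) / L for a in ALPHABET])
    denom = freqs.sum() + w * sum(thetas)
    values = np.concatenate([freqs / denom, w * np.array(thetas) / denom])
    labels = [f"paac.AAC.{a}" for a in ALPHABET] + [
        f"paac.theta.{j}" for j in range(1, lam + 1)
    ]
    return FeatureVector(values, labels)


# ---------------------------------------------------------------------------
# KSCTriad (k-spaced conjoint triad)
# ---------------------------------------------------------------------------

def _triad_labels(kmax: int) -> list[str]:
    return [
        f"ksctriad.k{k}.{a}-{b}-{c}"
        for k in range(kmax + 1)
        for a, b, c in itertools.product(range(1, 8), repeat=3)
    ]


def encode_ksctriad(
    seq: ProteinSequence,
    kmax: int = 0,
    tables: PropertyTables | None = None,
    normalize: str = "minmax",
) -> FeatureVector:
    """k-spaced conjoint triad, dimension 343 * (kmax + 1).

    Residues map to 7 physicochemical classes; for each k the triples
    ``(s_i, s_{i+k+1}, s_{i+2(k+1)})`` are counted.  Each k-block is
    normalized per ``normalize``: ``"minmax"`` (default) applies
    ``(c - min) / max`` within the block, ``"window"`` divides by the
    number of windows; an all-zero block stays zero.
    """
    tables = tables or default_tables()
    if normalize not in ("minmax", "window"):
        raise ValueError(f"unknown normalization {normalize!r}")
    _require_length(seq, 2 * kmax + 3, "ksctriad")
    cls = np.array([tables.triad_classes[r] for r in seq.residues])
    L = len(cls)
    blocks = []
    for k in range(kmax + 1):
        step = k + 1
        counts = np.zeros((7, 7, 7))
        n_windows = L - 2 * step
        for i in range(n_windows):
            counts[cls[i] - 1, cls[i + step] - 1, cls[i + 2 * step] - 1] += 1
        flat = counts.ravel()
        if normalize == "minmax":
            if flat.max() > 0:
                flat = (flat - flat.min()) / flat.max()
        else:
            flat = flat / n_windows
        blocks.append(flat)
    return FeatureVector(np.concatenate(blocks), _triad_labels(kmax))


# ---------------------------------------------------------------------------
# CKSAAGP / CKSAAP (k-spaced pair compositions)
# ---------------------------------------------------------------------------

def encode_cksaagp(
    seq: ProteinSequence,
    kmax: int = 5,
    tables: PropertyTables | None = None,
) -> FeatureVector:
    """Composition of k-spaced side-chain-group pairs, dimension 25*(kmax+1).

    For each k, the 5 x 5 ordered group-pair counts over windows
    ``(R_i, R_{i+k+1})`` are divided by the window count L-k-1, so each
    k-block is a probability distribution.
    """
    tables = tables or default_tables()
    _require_length(seq, kmax + 2, "cksaagp")
    names = tables.group_names
    gidx = {g: i for i, g in enumerate(names)}
    group_of = tables.group_of()
    g = np.array([gidx[group_of[r]] for r in seq.residues])
    L = len(g)
    blocks, labels = [], []
    for k in range(kmax + 1):
        counts = np.zeros((5, 5))
        step = k + 1
        for i in range(L - step):
            counts[g[i], g[i + step]] += 1
        blocks.append(counts.ravel() / (L - step))
        labels.extend(f"cksaagp.k{k}.{a}|{b}" for a in names for b in names)
    return FeatureVector(np.concatenate(blocks), labels)


def encode_cksaap(seq: ProteinSequence, kmax: int = 5) -> FeatureVector:
    """Ungrouped k-spaced amino-acid pair composition, dimension 400*(kmax+1)."""
    _require_length(seq, kmax + 2, "cksaap")
    aidx = {a: i for i, a in enumerate(ALPHABET)}
    x = np.array([aidx[r] for r in seq.residues])
    L = len(x)
    blocks, labels = [], []
    for k in range(kmax + 1):
        counts = np.zeros((20, 20))
        step = k + 1
        for i in range(L - step):
            counts[x[i], x[i + step]] += 1
        blocks.append(counts.ravel() / (L - step))
        labels.extend(f"cksaap.k{k}.{a}{b}" for a in ALPHABET for b in ALPHABET)
    return FeatureVector(np.concatenate(blocks), labels)


# ---------------------------------------------------------------------------
# Mixed encoding
# ---------------------------------------------------------------------------

def encode_mixed(
    seq: ProteinSequence,
    cfg: EncoderConfig | None = None,
    tables: PropertyTables | None = None,
) -> FeatureVector:
    """Concatenate the enabled blocks in the fixed order d188, apaac,
    ksctriad, cksaagp, paac."""
    cfg = cfg or EncoderConfig()
    tables = tables or default_tables()
    encoders = {
        "d188": lambda s: encode_188d(s, tables),
        "apaac": lambda s: encode_apaac(s, cfg.lambda_apaac, cfg.weight_apaac, tables),
        "ksctriad": lambda s: encode_ksctriad(s, cfg.kmax_ksctriad, tables),
        "cksaagp": lambda s: encode_cksaagp(s, cfg.kmax_cksaagp, tables),
        "paac": lambda s: encode_paac(s, cfg.lambda_paac, cfg.weight_paac, tables),
    }
    parts: list[FeatureVector] = []
    for block in cfg.enabled:
        try:
            parts.append(encoders[block](seq))
        except EncodingError as e:
            raise EncodingError(f"block {block!r} failed: {e}") from e
    values = np.concatenate([p.values for p in parts])
    labels = [lab for p in parts for lab in p.labels]
    assert len(values) == cfg.dimension
    return FeatureVector(values, labels)


def encode_dataset(
    ds: LabeledDataset,
    cfg: EncoderConfig | None = None,
    tables: PropertyTables | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Encode every sequence; returns (X, y, ids, feature_labels).

    Raises :class:`EncodingError` listing all offending IDs if any
    sequence is unencodable — sequences are never silently dropped.
    """
    cfg = cfg or EncoderConfig()
    tables = tables or default_tables()
    if len(ds) == 0:
        raise DataError("cannot encode an empty dataset")
    too_short = [s.id for s in ds.sequences if len(s) < cfg.min_length]
    if too_short:
        raise EncodingError(
            f"{len(too_short)} sequence(s) shorter than the minimum encodable "
            f"length {cfg.min_length}: {too_short[:10]}"
        )
    rows, labels = [], None
    for s in ds.sequences:
        fv = encode_mixed(s, cfg, tables)
        rows.append(fv.values)
        if labels is None:
            labels = fv.labels
    X = np.vstack(rows)
    y = np.asarray(ds.labels, dtype=int)
    return X, y, ds.ids, labels
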