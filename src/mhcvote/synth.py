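"""Seeded synthetic two-class protein datasets with tunable separation.

Negatives are drawn i.i.d. from a baseline residue distribution (uniform
over the 20 letters by default; a SwissProt-like background is available).
Positives come from the mixture ``(1 - delta) * baseline + delta * biased``
where the biased distribution is fixed (uniform over the first ten alphabet
residues A,C,D,E,F,G,H,I,K,L), so ``delta`` in [0, 1] dials the class
separation continuously from indistinguishable to strongly skewed residue
usage.  An optional short motif can additionally be written into each
positive at a random position (replacing residues, so lengths are
unchanged).

Everything is deterministic for a fixed seed; IDs encode class and index
(``pos_0001`` / ``neg_0001``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError
from .seqio import ALPHABET, LabeledDataset, ProteinSequence, write_fasta

#: Residues over-represented in positives when delta > 0.
BIASED_RESIDUES = "ACDEFGHIKL"

#: Approximate SwissProt background frequencies (optional baseline).
SWISSPROT_FREQS = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0661, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw."""

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (80, 200)
    delta: float = 0.5
    motif: str | None = None
    seed: int = 0
    baseline: str = "uniform"  # "uniform" or "swissprot"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_pos < 1 or self.n_neg < 1:
            raise DataError("n_pos and n_neg must be >= 1")
        if lo < 1 or hi < lo:
            raise DataError(f"invalid length_range {self.length_range}")
        if not 0 <= self.delta <= 1:
            raise DataError(f"delta must be in [0,1], got {self.delta}")
        if self.baseline not in ("uniform", "swissprot"):
            raise DataError(f"unknown baseline {self.baseline!r}")
        if self.motif is not None:
            if not self.motif or set(self.motif) - set(ALPHABET):
                raise DataError("motif must be non-empty over the 20-letter alphabet")
            if len(self.motif) > lo:
                raise DataError("motif longer than the minimum sequence length")

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "length_range": list(self.length_range),
            "delta": self.delta,
            "motif": self.motif,
            "seed": self.seed,
            "baseline": self.baseline,
        }


def _baseline_probs(kind: str) -> np.ndarray:
    if kind == "swissprot":
        p = np.array([SWISSPROT_FREQS[a] for a in ALPHABET])
        return p / p.sum()
    return np.full(20, 1 / 20)


def class_distributions(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Residue-emission probabilities (negative, positive) implied by ``spec``."""
    base = _baseline_probs(spec.baseline)
    biased = np.array([1 / len(BIASED_RESIDUES) if a in BIASED_RESIDUES else 0.0
                       for a in ALPHABET])
    pos = (1 - spec.delta) * base + spec.delta * biased
    return base, pos / pos.sum()


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled two-class dataset; fully deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    neg_p, pos_p = class_distributions(spec)
    lo, hi = spec.length_range
    letters = np.array(list(ALPHABET))

    def draw(n: int, probs: np.ndarray, prefix: str, with_motif: bool):
        out = []
        for i in range(n):
            L = int(rng.integers(lo, hi + 1))
            chars = rng.choice(letters, size=L, p=probs)
            if with_motif and spec.motif:
                start = int(rng.integers(0, L - len(spec.motif) + 1))
                chars[start : start + len(spec.motif)] = list(spec.motif)
            out.append(
                ProteinSequence(id=f"{prefix}_{i + 1:04d}", residues="".join(chars))
            )
        return out

    pos = draw(spec.n_pos, pos_p, "pos", with_motif=True)
    neg = draw(spec.n_neg, neg_p, "neg", with_motif=False)
    return LabeledDataset(
        sequences=pos + neg, labels=[1] * len(pos) + [0] * len(neg)
    )


def write_dataset(
    ds: LabeledDataset, spec: SyntheticSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Write pos/neg FASTA files plus a JSON manifest of the spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = [s for s, l in zip(ds.sequences, ds.labels) if l == 1]
    neg = [s for s, l in zip(ds.sequences, ds.labels) if l == 0]
    paths = {
        "pos": out_dir / "pos.fasta",
        "neg": out_dir / "neg.fasta",
        "manifest": out_dir / "manifest.json",
    }
    write_fasta(pos, paths["pos"])
    write_fasta(neg, paths["neg"])
    paths["manifest"].write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return paths
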